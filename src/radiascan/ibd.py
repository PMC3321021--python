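"""Geographic distances and simple Mantel tests for isolation by distance."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .io import SampleTable
from .phylo import DistanceMatrix

__all__ = ["MantelResult", "geodesic_km_matrix", "mantel_test"]

EARTH_RADIUS_KM = 6371.0


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    n: int
    tail: str
    exact: bool = False


def geodesic_km_matrix(table: SampleTable) -> DistanceMatrix:
    """Great-circle distances (spherical earth, R = 6371 km) between
    population sites; multi-sample populations use the coordinate centroid."""
    coords = table.population_coordinates()
    pops = sorted(coords)
    lat = np.radians([coords[p][0] for p in pops])
    lon = np.radians([coords[p][1] for p in pops])
    # haversine, vectorized over the pair grid
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(pops, (d + d.T) / 2, kind="km")


def _upper(v: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu]


def mantel_test(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 1_000_000,
    seed: int = 0,
    tail: str = "positive",
    exact_max_n: int = 7,
) -> MantelResult:
    """Simple Mantel test: Pearson r over upper triangles, permutation p.

    Rows+columns of ``b`` are permuted simultaneously.  For n <=
    ``exact_max_n`` the full n! enumeration replaces sampling.  ``tail`` is
    ``positive`` (default; the isolation-by-distance direction),
    ``negative`` or ``two-sided``.
    """
    if a.ids != b.ids:
        raise ValueError("matrices must share ids in the same order")
    n = a.n
    if n < 4:
        raise ValueError("need >= 4 populations")
    if tail not in ("positive", "negative", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")

    x = _upper(a.values)
    y = _upper(b.values)
    if x.std() == 0:
        raise ValueError("zero variance in first matrix: r undefined")
    if y.std() == 0:
        raise ValueError("zero variance in second matrix: r undefined")
    # permuting rows+columns leaves the triangle's multiset (hence mean/std)
    # unchanged, so both matrices can be normalized once up front
    m = n * (n - 1) / 2
    xn = (a.values - x.mean()) / x.std()
    yn = (b.values - y.mean()) / y.std()
    np.fill_diagonal(xn, 0.0)
    np.fill_diagonal(yn, 0.0)

    def corr(perm) -> float:
        return float((xn * yn[np.ix_(perm, perm)]).sum() / (2 * m))

    r_obs = corr(range(n))

    def extreme(r_perm: float) -> bool:
        if tail == "positive":
            return r_perm >= r_obs - 1e-15
        if tail == "negative":
            return r_perm <= r_obs + 1e-15
        return abs(r_perm) >= abs(r_obs) - 1e-15

    if n <= exact_max_n:
        hits = total = 0
        for perm in permutations(range(n)):
            total += 1
            if extreme(corr(perm)):
                hits += 1
        return MantelResult(r=r_obs, p=hits / total, n_perm=total, n=n,
                            tail=tail, exact=True)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if extreme(corr(rng.permutation(n))):
            hits += 1
    return MantelResult(r=r_obs, p=(hits + 1) / (n_perm + 1), n_perm=n_perm,
                        n=n, tail=tail, exact=False)
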