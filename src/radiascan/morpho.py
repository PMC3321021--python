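"""Landmark-based shape analysis.

Generalized Procrustes alignment (translation, unit centroid-size scaling,
iterative SVD rotation to the consensus), centroid sizes, PCA of the
aligned coordinates, leave-one-out CVA/Mahalanobis assignment with
typicality probabilities, and Goodall's F for two-group shape comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "ShapeSpace",
    "gpa",
    "procrustes_distance",
    "shape_pca",
    "cva_assign",
    "goodall_f",
    "read_tps",
]


@dataclass
class ShapeSpace:
    aligned: np.ndarray            # (n, k, 2) Procrustes coordinates
    centroid_sizes: np.ndarray     # (n,) in original units
    consensus: np.ndarray          # (k, 2), centered, unit centroid size
    ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    def tangent(self) -> np.ndarray:
        """Flattened residuals from the consensus (tangent-space coords)."""
        return (self.aligned - self.consensus[None]).reshape(self.n, -1)


def centroid_size(config: np.ndarray) -> float:
    c = config - config.mean(axis=0)
    return float(np.sqrt((c ** 2).sum()))


def _rotate_onto(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation (no reflection) of x onto target."""
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return x @ r


def gpa(configs: np.ndarray | list[np.ndarray], ids: list[str] | None = None,
        tol: float = 1e-10, max_iter: int = 100) -> ShapeSpace:
    """Generalized Procrustes alignment of (n, k, 2) configurations."""
    arr = np.asarray(configs, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ValueError("configs must be (n, k, 2)")
    n, k, _ = arr.shape
    if n < 2:
        raise ValueError("need >= 2 specimens")
    if k < 3:
        raise ValueError("need >= 3 landmarks")

    sizes = np.empty(n)
    shapes = np.empty_like(arr)
    for i in range(n):
        c = arr[i] - arr[i].mean(axis=0)
        s = np.sqrt((c ** 2).sum())
        if s < 1e-12:
            raise ValueError(f"degenerate configuration at index {i}")
        sizes[i] = s
        shapes[i] = c / s

    consensus = shapes[0].copy()
    for _ in range(max_iter):
        aligned = np.array([_rotate_onto(s, consensus) for s in shapes])
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        norm = np.sqrt((new_consensus ** 2).sum())
        if norm < 1e-12:
            raise ValueError("degenerate consensus (landmarks collapse)")
        new_consensus /= norm
        if np.abs(new_consensus - consensus).max() < tol:
            consensus = new_consensus
            break
        consensus = new_consensus
    aligned = np.array([_rotate_onto(s, consensus) for s in shapes])
    return ShapeSpace(aligned=aligned, centroid_sizes=sizes, consensus=consensus,
                      ids=ids or [f"sp{i + 1}" for i in range(n)])


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two raw configurations
    (translation, scale and rotation removed)."""
    ca = a - a.mean(axis=0)
    cb = b - b.mean(axis=0)
    ca /= np.sqrt((ca ** 2).sum())
    cb /= np.sqrt((cb ** 2).sum())
    return float(np.linalg.norm(_rotate_onto(ca, cb) - cb))


def shape_pca(space: ShapeSpace) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the tangent coordinates: (scores, loadings, variance fractions)."""
    if space.n < 2:
        raise ValueError("need >= 2 specimens")
    X = space.tangent()
    X = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s ** 2 / (space.n - 1)
    total = var.sum()
    if total <= 1e-24:
        raise ValueError("no shape variation: PCA undefined")
    keep = var > total * 1e-12
    scores = u[:, keep] * s[keep]
    return scores, vt[keep], var[keep] / total


@dataclass
class AssignmentResult:
    assigned: list[str]
    success_rate: dict[str, float]
    overall_success: float
    significant: list[bool]            # typicality rule per specimen
    n_significant: int
    excluded_groups: list[str] = field(default_factory=list)


def cva_assign(space: ShapeSpace, labels: list[str] | np.ndarray,
               min_group_size: int = 3, ridge: float = 1e-8) -> AssignmentResult:
    """Leave-one-out assignment to the nearest group mean in the pooled
    within-group Mahalanobis metric (equivalent to Euclidean distance in CV
    space), with the typicality-probability significance rule: an
    assignment is significant when the winning group's typicality p > 0.05
    and every other group's is <= 0.05."""
    labels = np.asarray(labels).astype(str)
    import warnings as _w
    groups, counts = np.unique(labels, return_counts=True)
    excluded = [g for g, c in zip(groups, counts) if c < min_group_size]
    if excluded:
        _w.warn(f"groups below size {min_group_size} excluded: {excluded}",
                stacklevel=2)
    keep = ~np.isin(labels, excluded)
    X_all = space.tangent()
    X = X_all[keep]
    y = labels[keep]
    groups = [g for g in np.unique(y)]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups of sufficient size")

    # reduce to the span of the data to keep the pooled covariance
    # invertible; the within-group df (n - g, minus one held out) caps the
    # usable dimensionality
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-9).sum())
    rank = min(rank, max(1, len(X) - len(groups) - 1))
    basis = vt[:rank]
    Z = Xc @ basis.T
    df_chi = rank

    n = Z.shape[0]
    assigned, signif = [], []
    for i in range(n):
        mask = np.arange(n) != i
        Zi, yi = Z[mask], y[mask]
        means = {g: Zi[yi == g].mean(axis=0) for g in groups}
        W = np.zeros((rank, rank))
        for g in groups:
            R = Zi[yi == g] - means[g]
            W += R.T @ R
        W /= (len(Zi) - len(groups))
        W += ridge * np.trace(W) / rank * np.eye(rank)
        Winv = np.linalg.pinv(W)
        d2 = {g: float((Z[i] - means[g]) @ Winv @ (Z[i] - means[g])) for g in groups}
        best = min(d2, key=lambda g: (d2[g], g))
        assigned.append(best)
        typ = {g: 1.0 - stats.chi2.cdf(d2[g], df=df_chi) for g in groups}
        ok = typ[best] > 0.05 and all(typ[g] <= 0.05 for g in groups if g != best)
        signif.append(bool(ok))

    success = {
        g: float(np.mean([a == g for a, t in zip(assigned, y) if t == g]))
        for g in groups
    }
    return AssignmentResult(
        assigned=assigned,
        success_rate=success,
        overall_success=float(np.mean([a == t for a, t in zip(assigned, y)])),
        significant=signif,
        n_significant=int(sum(signif)),
        excluded_groups=excluded,
    )


@dataclass
class GoodallResult:
    f: float
    df1: int
    df2: int
    p_param: float
    p_perm: float
    n_perm: int


def goodall_f(space: ShapeSpace, labels, group_a: str, group_b: str,
              n_perm: int = 999, seed: int = 0) -> GoodallResult:
    """Goodall's F comparing the mean shapes of two groups.

    F = [D^2 / (1/nA + 1/nB)] / [(SSwA + SSwB) / (nA + nB - 2)] with D the
    Procrustes distance between group consensus shapes; df1 = 2k - 4,
    df2 = (nA + nB - 2)(2k - 4).  Permutation p alongside the parametric p.
    """
    labels = np.asarray(labels).astype(str)
    idx = np.flatnonzero(np.isin(labels, [group_a, group_b]))
    if idx.size < 3:
        raise ValueError("need at least 3 specimens across the two groups")
    X = space.aligned[idx]
    y = labels[idx]
    k = space.k

    def stat(yv: np.ndarray) -> float:
        a = X[yv == group_a]
        b = X[yv == group_b]
        na, nb = len(a), len(b)
        ma, mb = a.mean(axis=0), b.mean(axis=0)
        d2 = ((ma - mb) ** 2).sum()
        ssw = ((a - ma) ** 2).sum() + ((b - mb) ** 2).sum()
        if ssw <= 0:
            return np.inf if d2 > 0 else 0.0
        return (d2 / (1 / na + 1 / nb)) / (ssw / (na + nb - 2))

    na = int((y == group_a).sum())
    nb = int((y == group_b).sum())
    if na < 2 or nb < 2:
        raise ValueError("both groups need >= 2 specimens")
    f_obs = stat(y)
    df1 = 2 * k - 4
    df2 = (na + nb - 2) * df1
    p_param = float(stats.f.sf(f_obs, df1, df2))

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if stat(y[rng.permutation(y.size)]) >= f_obs - 1e-15:
            hits += 1
    p_perm = (hits + 1) / (n_perm + 1)
    return GoodallResult(f=float(f_obs), df1=df1, df2=df2,
                         p_param=p_param, p_perm=p_perm, n_perm=n_perm)


# ---------------------------------------------------------------------------
# TPS input
# ---------------------------------------------------------------------------

def read_tps(path: str | Path) -> tuple[list[np.ndarray], list[str]]:
    """Minimal TPS reader: LM=<k>, k coordinate lines, optional ID=<name>."""
    configs: list[np.ndarray] = []
    ids: list[str] = []
    cur: list[list[float]] = []
    expect = 0
    name = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        up = line.upper()
        if up.startswith("LM="):
            if cur:
                configs.append(np.array(cur))
                ids.append(name or f"sp{len(configs)}")
            expect = int(line.split("=", 1)[1])
            cur, name = [], None
        elif up.startswith("ID="):
            name = line.split("=", 1)[1]
        elif up.startswith(("IMAGE=", "SCALE=")):
            continue
        else:
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"bad TPS coordinate line: {raw!r}")
            cur.append([float(parts[0]), float(parts[1])])
    if cur:
        configs.append(np.array(cur))
        ids.append(name or f"sp{len(configs)}")
    if not configs:
        raise ValueError(f"{path}: no configurations")
    for i, c in enumerate(configs):
        if expect and c.shape[0] != expect:
            pass  # TPS files may vary LM= per record; equal-k enforced by gpa
    return configs, ids
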