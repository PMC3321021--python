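"""Synthetic data with the statistical structure the pipeline assumes.

The marker generator follows a Balding–Nichols hierarchy: ancestral
presence-allele frequencies p_i are drawn from a truncated Beta prior,
population frequencies p_ij from Beta(p_i*theta_ij, (1-p_i)*theta_ij) with
theta_ij = (1-F_ij)/F_ij and logit(F_ij) = alpha_i + logit(F_j), and a
diploid individual shows a band with probability 1-(1-p_ij)^2 (dominance
under Hardy–Weinberg).  A spatial mode replaces independent population
draws by sequential drift along a 1-D stepping stone, which produces
isolation by distance in expectation.

All generators take an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .io import MISSING, MarkerMatrix, SampleTable, SequenceSet

__all__ = [
    "SimParams",
    "TruthRecord",
    "IntensityParams",
    "simulate_metapopulation",
    "corrupt_and_replicate",
    "simulate_peak_profiles",
    "simulate_sequences",
    "simulate_landmarks",
]


@dataclass
class SimParams:
    n_pops: int = 4
    n_ind: int = 20
    n_loci: int = 200
    #: per-population drift parameter(s) F_j in (0,1); scalar broadcast
    fst: float | Sequence[float] = 0.1
    #: per-locus selection effects alpha_i on the logit-F scale (0 = neutral)
    alpha: Sequence[float] | None = None
    #: Beta(a, b) ancestral-frequency prior, truncated to [lo, hi]
    prior_a: float = 1.0
    prior_b: float = 1.0
    prior_lo: float = 0.05
    prior_hi: float = 0.95
    #: map population index -> group label (optional MOTU structure)
    group_of: dict[int, str] | None = None
    e01: float = 0.0
    e10: float = 0.0
    replicate_fraction: float = 0.0
    #: spatial stepping-stone mode: 1-D positions in km + per-km drift rate
    spatial: bool = False
    positions_km: Sequence[float] | None = None
    drift_per_km: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.broadcast_to(np.asarray(self.fst, dtype=float), (self.n_pops,))
        if np.any((f <= 0) | (f >= 1)):
            raise ValueError("F_j must lie in (0,1)")
        for r in (self.e01, self.e10, self.replicate_fraction):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0,1]")
        if self.n_loci < 1:
            raise ValueError("n_loci >= 1 required")
        if not (0 <= self.prior_lo < self.prior_hi <= 1):
            raise ValueError("degenerate ancestral-frequency prior truncation")
        if self.prior_lo == self.prior_hi:
            raise ValueError("prior mass concentrated at a point")

    @property
    def fst_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.fst, dtype=float), (self.n_pops,)).copy()

    @property
    def alpha_array(self) -> np.ndarray:
        if self.alpha is None:
            return np.zeros(self.n_loci)
        a = np.asarray(self.alpha, dtype=float)
        if a.shape != (self.n_loci,):
            raise ValueError("alpha must have length n_loci")
        return a


@dataclass
class TruthRecord:
    """Ground truth retained for parameter-recovery tests."""

    p_anc: np.ndarray                      # (n_loci,) ancestral frequencies
    p_pop: np.ndarray                      # (n_pops, n_loci) realized frequencies
    selected: np.ndarray                   # indices of loci with alpha != 0
    pop_of_sample: dict[str, str]
    group_of_pop: dict[str, str]
    e01: float = 0.0
    e10: float = 0.0

    def band_freq(self) -> np.ndarray:
        """Expected band frequency per population/locus under dominance."""
        return 1.0 - (1.0 - self.p_pop) ** 2

    def wc_fst(self) -> float:
        """Moment-style F_ST from the realized allele frequencies.

        Ratio of the among-population variance of p_ij to p_bar(1-p_bar),
        averaged over loci (ratio of sums, the usual multilocus form).
        """
        pbar = self.p_pop.mean(axis=0)
        num = self.p_pop.var(axis=0, ddof=1)
        den = pbar * (1 - pbar)
        ok = den > 0
        return float(num[ok].sum() / den[ok].sum())


def _truncated_beta(rng: np.random.Generator, a: float, b: float,
                    lo: float, hi: float, size: int) -> np.ndarray:
    dist = stats.beta(a, b)
    u = rng.uniform(dist.cdf(lo), dist.cdf(hi), size=size)
    return dist.ppf(u)


def _bn_draw(rng: np.random.Generator, p_anc: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Balding–Nichols draw: Beta(p*theta, (1-p)*theta), theta=(1-F)/F."""
    theta = (1.0 - f) / f
    a = np.clip(p_anc * theta, 1e-12, None)
    b = np.clip((1.0 - p_anc) * theta, 1e-12, None)
    return np.clip(rng.beta(a, b), 1e-12, 1 - 1e-12)


def simulate_metapopulation(params: SimParams) -> tuple[MarkerMatrix, SampleTable, TruthRecord]:
    """Generate a marker matrix, its metadata, and the generating truth."""
    rng = np.random.default_rng(params.seed)
    J, L, n = params.n_pops, params.n_loci, params.n_ind
    alpha = params.alpha_array
    f_pop = params.fst_array

    p_anc = _truncated_beta(rng, params.prior_a, params.prior_b,
                            params.prior_lo, params.prior_hi, L)

    if params.spatial:
        pos = (np.asarray(params.positions_km, dtype=float)
               if params.positions_km is not None
               else np.arange(J, dtype=float) * 25.0)
        if pos.shape != (J,):
            raise ValueError("positions_km must have length n_pops")
        order = np.argsort(pos)
        p_pop = np.empty((J, L))
        # seed deme drifts from the ancestral pool, then sequential drift
        f0 = np.clip(expit(alpha + logit(0.02)), 1e-4, 0.98)
        p_pop[order[0]] = _bn_draw(rng, p_anc, f0)
        for a_idx, b_idx in zip(order[:-1], order[1:]):
            step_km = abs(pos[b_idx] - pos[a_idx])
            f_step = 1.0 - math.exp(-params.drift_per_km * step_km)
            f_step = min(max(f_step, 1e-4), 0.98)
            f_i = np.clip(expit(alpha + logit(f_step)), 1e-4, 0.98)
            p_pop[b_idx] = _bn_draw(rng, p_pop[a_idx], f_i)
    else:
        beta_j = logit(f_pop)
        p_pop = np.empty((J, L))
        for j in range(J):
            f_ij = np.clip(expit(alpha + beta_j[j]), 1e-6, 1 - 1e-6)
            p_pop[j] = _bn_draw(rng, p_anc, f_ij)

    band_p = 1.0 - (1.0 - p_pop) ** 2
    calls = np.empty((J * n, L), dtype=np.int8)
    sample_ids, pops = [], []
    for j in range(J):
        calls[j * n:(j + 1) * n] = (
            rng.random((n, L)) < band_p[j][None, :]
        ).astype(np.int8)
        for i in range(n):
            sample_ids.append(f"P{j + 1}_{i + 1}")
            pops.append(f"P{j + 1}")

    group_of = params.group_of or {}
    group_of_pop = {f"P{j + 1}": str(group_of.get(j, f"G{j + 1}")) for j in range(J)}
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "population_id": pops,
        "group_id": [group_of_pop[p] for p in pops],
    })
    if params.spatial:
        pos = (np.asarray(params.positions_km, dtype=float)
               if params.positions_km is not None
               else np.arange(J, dtype=float) * 25.0)
        # place demes along the equator; 1 deg lon ~ 111.195 km
        lon_of = {f"P{j + 1}": pos[j] / 111.19492664455873 for j in range(J)}
        meta["latitude"] = 0.0
        meta["longitude"] = [lon_of[p] for p in pops]

    mm = MarkerMatrix(sample_ids, [f"L{i + 1}" for i in range(L)], calls)
    truth = TruthRecord(
        p_anc=p_anc,
        p_pop=p_pop,
        selected=np.flatnonzero(alpha != 0),
        pop_of_sample=dict(zip(sample_ids, pops)),
        group_of_pop=group_of_pop,
        e01=params.e01,
        e10=params.e10,
    )
    out = mm
    if params.e01 or params.e10 or params.replicate_fraction:
        out = corrupt_and_replicate(mm, params.e01, params.e10,
                                    params.replicate_fraction,
                                    seed=int(rng.integers(2 ** 31)))
    return out, SampleTable(meta), truth


def corrupt_and_replicate(mm: MarkerMatrix, e01: float, e10: float,
                          replicate_fraction: float, seed: int) -> MarkerMatrix:
    """Apply genotyping error and append replicate re-scores.

    The input matrix is treated as the error-free truth.  Every returned
    call (main rows and replicate rows alike) is an independent corruption
    of the underlying true call: present -> absent w.p. ``e10``,
    absent -> present w.p. ``e01``.  A ``replicate_fraction`` of samples is
    re-scored as additional ``<id>_rep1`` rows.
    """
    if not (0 <= e01 < 1 and 0 <= e10 < 1):
        raise ValueError("error rates must lie in [0,1)")
    if not 0 <= replicate_fraction <= 1:
        raise ValueError("replicate_fraction must lie in [0,1]")
    rng = np.random.default_rng(seed)

    def corrupt(rows: np.ndarray) -> np.ndarray:
        out = rows.copy()
        u = rng.random(rows.shape)
        flip10 = (rows == 1) & (u < e10)
        flip01 = (rows == 0) & (u < e01)
        out[flip10] = 0
        out[flip01] = 1
        return out

    n = mm.n_samples
    n_rep = int(round(replicate_fraction * n))
    rep_rows = np.sort(rng.choice(n, size=n_rep, replace=False)) if n_rep else np.array([], int)

    main = corrupt(mm.calls)
    reps = corrupt(mm.calls[rep_rows]) if n_rep else np.empty((0, mm.n_loci), np.int8)

    sample_ids = list(mm.sample_ids)
    replicate_of = dict(mm.replicate_of)
    for i in rep_rows:
        rid = f"{mm.sample_ids[i]}_rep1"
        sample_ids.append(rid)
        replicate_of[rid] = mm.sample_ids[i]
    return MarkerMatrix(sample_ids, list(mm.locus_ids),
                        np.vstack([main, reps]), replicate_of)


# ---------------------------------------------------------------------------
# peak profiles
# ---------------------------------------------------------------------------

@dataclass
class IntensityParams:
    """Fluorescence model for synthetic electropherogram peak lists."""

    present_height_mean: float = 5000.0
    present_height_cv: float = 0.2        # lognormal coefficient of variation
    noise_rate: float = 0.0               # Poisson mean of noise peaks/profile
    noise_height_max: float = 45.0        # noise heights ~ U(1, max)
    jitter_sd: float = 0.0                # fragment-size jitter, bases

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ValueError("jitter sd must be >= 0")
        if self.noise_rate < 0:
            raise ValueError("noise rate must be >= 0")


def locus_sizes(mm: MarkerMatrix, size_range: tuple[float, float] = (60.0, 550.0)) -> np.ndarray:
    """Fragment size per locus: parsed from numeric locus ids, else an even
    grid over ``size_range`` (spacing must exceed typical bin widths)."""
    try:
        sizes = np.array([float(l) for l in mm.locus_ids])
    except ValueError:
        lo, hi = size_range
        sizes = np.linspace(lo + 0.5, hi - 0.5, mm.n_loci)
    if mm.n_loci > 1 and np.diff(np.sort(sizes)).min() <= 0.75:
        raise ValueError("locus sizes closer than the 0.75 b bin cap; reduce n_loci")
    return sizes


def simulate_peak_profiles(
    mm: MarkerMatrix,
    intensity: IntensityParams,
    seed: int,
    size_range: tuple[float, float] = (60.0, 550.0),
) -> dict[str, list[tuple[float, float]]]:
    """Per-sample (fragment size, height) peak lists for the given matrix.

    One jittered peak per present call plus Poisson-distributed noise peaks
    at uniform random sizes with sub-threshold heights.
    """
    rng = np.random.default_rng(seed)
    sizes = locus_sizes(mm, size_range)
    sigma = math.sqrt(math.log(1 + intensity.present_height_cv ** 2))
    mu = math.log(intensity.present_height_mean) - sigma ** 2 / 2
    profiles: dict[str, list[tuple[float, float]]] = {}
    for i, sid in enumerate(mm.sample_ids):
        present = np.flatnonzero(mm.calls[i] == 1)
        pk_sizes = sizes[present] + rng.normal(0, intensity.jitter_sd, present.size) \
            if intensity.jitter_sd > 0 else sizes[present].astype(float)
        heights = np.exp(rng.normal(mu, sigma, present.size))
        peaks = list(zip(pk_sizes.tolist(), heights.tolist()))
        n_noise = rng.poisson(intensity.noise_rate) if intensity.noise_rate > 0 else 0
        if n_noise:
            ns = rng.uniform(size_range[0], size_range[1], n_noise)
            nh = rng.uniform(1.0, intensity.noise_height_max, n_noise)
            peaks += list(zip(ns.tolist(), nh.tolist()))
        peaks.sort()
        profiles[sid] = peaks
    return profiles


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _jc_mutate(seq: np.ndarray, p_sub: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site w.p. ``p_sub``, uniformly to a different base."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < p_sub)
    if hit.size:
        shift = rng.integers(1, 4, hit.size)
        out[hit] = (out[hit] + shift) % 4
    return out


def _jc_branch_psub(p_dist: float) -> float:
    """Per-branch substitution probability so that two tips separated by two
    such branches show expected p-distance ``p_dist`` (Jukes–Cantor)."""
    if not 0 <= p_dist < 0.75:
        raise ValueError("divergence must lie in [0, 0.75)")
    t2 = -0.75 * math.log1p(-4.0 * p_dist / 3.0)      # total path length
    return 0.75 * (1.0 - math.exp(-4.0 * (t2 / 2.0) / 3.0))


def simulate_sequences(n_clusters: int, seqs_per_cluster: int, length: int,
                       within_div: float, between_div: float, seed: int) -> SequenceSet:
    """Star-of-stars sequence clusters with controlled p-distance levels."""
    if not 0 <= within_div < between_div <= 0.75:
        raise ValueError("require 0 <= within_div < between_div <= 0.75")
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, length)
    p_between = _jc_branch_psub(min(between_div, 0.7499))
    p_within = _jc_branch_psub(within_div) if within_div > 0 else 0.0
    ids, seqs = [], []
    for c in range(n_clusters):
        anc = _jc_mutate(root, p_between, rng)
        for k in range(seqs_per_cluster):
            leaf = _jc_mutate(anc, p_within, rng) if p_within > 0 else anc
            ids.append(f"C{c + 1}_{k + 1}")
            seqs.append("".join(_BASES[leaf]))
    return SequenceSet(ids, seqs, aligned=True)


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def simulate_landmarks(n_groups: int, per_group: int, n_landmarks: int,
                       shape_offset: float, noise_sd: float,
                       nuisance: bool, seed: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """(configs, labels): configs is (n_groups*per_group, k, 2).

    Group mean shapes sit ``shape_offset`` apart (Procrustes-tangent norm)
    around a common base shape; individuals add isotropic landmark noise;
    with ``nuisance`` each configuration is randomly rotated, scaled and
    translated.
    """
    if n_landmarks < 3:
        raise ValueError("need >= 3 landmarks")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    ang = 2 * np.pi * np.arange(n_landmarks) / n_landmarks
    base = np.column_stack([np.cos(ang), np.sin(ang)])
    # slight irregularity so the base shape has no rotational symmetry
    base += rng.normal(0, 0.05, base.shape)
    base -= base.mean(axis=0)
    base /= np.linalg.norm(base)

    means = []
    for g in range(n_groups):
        d = rng.normal(0, 1, base.shape)
        d -= d.mean(axis=0)
        d -= base * np.sum(d * base)          # remove scale direction
        d /= np.linalg.norm(d)
        means.append(base + shape_offset * d)

    configs, labels = [], []
    for g in range(n_groups):
        for _ in range(per_group):
            x = means[g] + rng.normal(0, noise_sd, base.shape)
            if nuisance:
                th = rng.uniform(0, 2 * np.pi)
                rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
                s = rng.uniform(0.5, 2.0)
                t = rng.uniform(-5, 5, 2)
                x = s * x @ rot.T + t
            configs.append(x)
            labels.append(g)
    return np.array(configs), np.array(labels)
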