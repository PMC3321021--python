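"""Hierarchical analysis of molecular variance for binary marker phenotypes.

Variance components are estimated from pairwise squared distances (for 0/1
band vectors the mismatch count *is* the squared Euclidean distance),
following the Excoffier–Smouse–Quattro sums-of-squares decomposition with
unequal sample sizes.  Significance is assessed by permutation: individuals
among populations (Phi_ST), individuals among populations within groups
(Phi_SC), and whole populations among groups (Phi_CT), with the +1
correction on p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, MarkerMatrix
from .phylo import DistanceMatrix

__all__ = ["Hierarchy", "AmovaResult", "amova", "pairwise_fst", "mismatch_d2"]


@dataclass
class Hierarchy:
    """sample -> population map, optionally populations -> groups."""

    pop_of_sample: dict[str, str]
    group_of_pop: dict[str, str] | None = None

    def __post_init__(self) -> None:
        pops = set(self.pop_of_sample.values())
        if len(pops) < 2:
            raise ValueError("need >= 2 populations")
        if self.group_of_pop is not None:
            missing = pops - set(self.group_of_pop)
            if missing:
                raise ValueError(f"populations without group assignment: {sorted(missing)}")

    @property
    def two_level(self) -> bool:
        if self.group_of_pop is None:
            return False
        return len(set(self.group_of_pop.values())) > 1


@dataclass
class AmovaResult:
    components: dict[str, float]        # sigma2_a (two-level only), sigma2_b, sigma2_c
    percentages: dict[str, float]
    phi: dict[str, float]               # F_CT/F_SC (two-level), F_ST
    p_values: dict[str, float]
    df: dict[str, int]
    n_permutations: int
    negative_components: bool = False
    excluded_populations: list[str] = field(default_factory=list)


def mismatch_d2(mm: MarkerMatrix) -> np.ndarray:
    """Pairwise mismatch counts; with missing calls, rescaled by
    (total loci / comparable loci) so magnitudes stay commensurate."""
    X = mm.calls
    P = (X == 1).astype(np.float64)
    A = (X == 0).astype(np.float64)
    M = (X != MISSING).astype(np.float64)
    mism = P @ A.T + A @ P.T
    comp = M @ M.T
    if (comp == 0).any():
        bad = np.argwhere(comp == 0)
        bad = [b for b in bad if b[0] != b[1]]
        if bad:
            i, j = bad[0]
            raise ValueError(
                f"no comparable loci for pair ({mm.sample_ids[i]!r}, {mm.sample_ids[j]!r})"
            )
    d2 = mism * (mm.n_loci / np.maximum(comp, 1))
    np.fill_diagonal(d2, 0.0)
    return d2


def _within_sums(d2: np.ndarray, labels: np.ndarray, n_lab: int) -> np.ndarray:
    """Sum of d2 over unordered pairs inside each label class."""
    out = np.empty(n_lab)
    for k in range(n_lab):
        idx = np.flatnonzero(labels == k)
        sub = d2[np.ix_(idx, idx)]
        out[k] = sub.sum() / 2.0
    return out


def _components(d2: np.ndarray, pop: np.ndarray, grp_of_pop: np.ndarray | None):
    """Variance components from squared distances.

    Returns (sigma_a, sigma_b, sigma_c, df) — one-level results put the
    among-population component in sigma_b and set sigma_a to None.
    """
    N = d2.shape[0]
    pops, pop_idx = np.unique(pop, return_inverse=True)
    J = len(pops)
    n_p = np.bincount(pop_idx, minlength=J).astype(float)

    ss_total = d2.sum() / (2.0 * N)
    within_pop = _within_sums(d2, pop_idx, J)
    ssd_wp = (within_pop / n_p).sum()

    if grp_of_pop is None:
        df_ap, df_wp = J - 1, N - J
        ssd_ap = ss_total - ssd_wp
        sigma_c = ssd_wp / df_wp
        n_prime = (N - (n_p ** 2).sum() / N) / df_ap
        sigma_b = (ssd_ap / df_ap - sigma_c) / n_prime
        return None, sigma_b, sigma_c, {"among_pops": df_ap, "within_pops": df_wp}

    grp_labels, grp_of_pop_idx = np.unique(grp_of_pop, return_inverse=True)
    G = len(grp_labels)
    grp_of_ind = grp_of_pop_idx[pop_idx]
    N_g = np.bincount(grp_of_ind, minlength=G).astype(float)
    within_grp = _within_sums(d2, grp_of_ind, G)
    ssd_grp_inner = (within_grp / N_g).sum()

    ssd_ag = ss_total - ssd_grp_inner
    ssd_apwg = ssd_grp_inner - ssd_wp
    df_ag, df_apwg, df_wp = G - 1, J - G, N - J

    sum_np2_over_Ng = sum(
        (n_p[grp_of_pop_idx == g] ** 2).sum() / N_g[g] for g in range(G)
    )
    n1 = (N - sum_np2_over_Ng) / df_apwg
    n2 = (sum_np2_over_Ng - (n_p ** 2).sum() / N) / df_ag
    n3 = (N - (N_g ** 2).sum() / N) / df_ag

    sigma_c = ssd_wp / df_wp
    sigma_b = (ssd_apwg / df_apwg - sigma_c) / n1
    sigma_a = (ssd_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c, {
        "among_groups": df_ag, "among_pops_within_groups": df_apwg, "within_pops": df_wp,
    }


def _phis(sigma_a, sigma_b, sigma_c):
    if sigma_a is None:
        tot = sigma_b + sigma_c
        return {"F_ST": sigma_b / tot if tot != 0 else np.nan}
    tot = sigma_a + sigma_b + sigma_c
    return {
        "F_CT": sigma_a / tot if tot != 0 else np.nan,
        "F_SC": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else np.nan,
        "F_ST": (sigma_a + sigma_b) / tot if tot != 0 else np.nan,
    }


def amova(
    mm: MarkerMatrix,
    hierarchy: Hierarchy,
    n_perm: int = 20022,
    seed: int = 0,
    min_pop_size: int = 5,
) -> AmovaResult:
    """One- or two-level AMOVA with permutation p-values.

    Populations smaller than ``min_pop_size`` are excluded before analysis.
    Replicate rows never enter the analysis.
    """
    mm = mm.drop_replicates()
    pop_of = hierarchy.pop_of_sample
    samples = [s for s in mm.sample_ids if s in pop_of]
    if len(samples) < mm.n_samples:
        warnings.warn(
            f"{mm.n_samples - len(samples)} samples missing from hierarchy; dropped",
            stacklevel=2,
        )
    from collections import Counter
    counts = Counter(pop_of[s] for s in samples)
    excluded = sorted(p for p, c in counts.items() if c < min_pop_size)
    if excluded:
        warnings.warn(f"populations below size {min_pop_size} excluded: {excluded}",
                      stacklevel=2)
    samples = [s for s in samples if pop_of[s] not in set(excluded)]
    kept_pops = sorted({pop_of[s] for s in samples})
    if len(kept_pops) < 2:
        raise ValueError("fewer than 2 populations remain after filtering")

    mm = mm.subset_samples(samples)
    d2 = mismatch_d2(mm)
    pop_names = kept_pops
    pop_index = {p: k for k, p in enumerate(pop_names)}
    pop = np.array([pop_index[pop_of[s]] for s in samples])

    two_level = hierarchy.two_level and hierarchy.group_of_pop is not None
    grp_of_pop_arr = None
    if two_level:
        gmap = hierarchy.group_of_pop
        grp_names = sorted({gmap[p] for p in pop_names})
        if len(grp_names) < 2:
            two_level = False
        else:
            gidx = {g: k for k, g in enumerate(grp_names)}
            grp_of_pop_arr = np.array([gidx[gmap[p]] for p in pop_names])

    sigma_a, sigma_b, sigma_c, df = _components(d2, pop, grp_of_pop_arr)
    phi = _phis(sigma_a, sigma_b, sigma_c)

    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}
    J = len(pop_names)

    if not two_level:
        obs = phi["F_ST"]
        hits = 0
        for _ in range(n_perm):
            perm_pop = pop[rng.permutation(pop.size)]
            _, sb, sc, _ = _components(d2, perm_pop, None)
            if _phis(None, sb, sc)["F_ST"] >= obs - 1e-15:
                hits += 1
        p_values["F_ST"] = (hits + 1) / (n_perm + 1)
        components = {"sigma2_b": sigma_b, "sigma2_c": sigma_c}
        tot = sigma_b + sigma_c
        percentages = {"among_pops": 100 * sigma_b / tot, "within_pops": 100 * sigma_c / tot}
    else:
        obs_ct, obs_sc, obs_st = phi["F_CT"], phi["F_SC"], phi["F_ST"]
        hits_ct = hits_sc = hits_st = 0
        grp_of_ind = grp_of_pop_arr[pop]
        for _ in range(n_perm):
            # F_ST: individuals among populations, unrestricted
            perm_pop = pop[rng.permutation(pop.size)]
            sa, sb, sc, _ = _components(d2, perm_pop, grp_of_pop_arr)
            if _phis(sa, sb, sc)["F_ST"] >= obs_st - 1e-15:
                hits_st += 1
            # F_SC: individuals among populations within their group
            perm_pop2 = pop.copy()
            for g in np.unique(grp_of_ind):
                idx = np.flatnonzero(grp_of_ind == g)
                perm_pop2[idx] = pop[idx][rng.permutation(idx.size)]
            sa, sb, sc, _ = _components(d2, perm_pop2, grp_of_pop_arr)
            if _phis(sa, sb, sc)["F_SC"] >= obs_sc - 1e-15:
                hits_sc += 1
            # F_CT: whole populations among groups
            perm_grp = grp_of_pop_arr[rng.permutation(J)]
            sa, sb, sc, _ = _components(d2, pop, perm_grp)
            if _phis(sa, sb, sc)["F_CT"] >= obs_ct - 1e-15:
                hits_ct += 1
        p_values = {
            "F_CT": (hits_ct + 1) / (n_perm + 1),
            "F_SC": (hits_sc + 1) / (n_perm + 1),
            "F_ST": (hits_st + 1) / (n_perm + 1),
        }
        components = {"sigma2_a": sigma_a, "sigma2_b": sigma_b, "sigma2_c": sigma_c}
        tot = sigma_a + sigma_b + sigma_c
        percentages = {
            "among_groups": 100 * sigma_a / tot,
            "among_pops_within_groups": 100 * sigma_b / tot,
            "within_pops": 100 * sigma_c / tot,
        }

    return AmovaResult(
        components=components,
        percentages=percentages,
        phi=phi,
        p_values=p_values,
        df=df,
        n_permutations=n_perm,
        negative_components=any(v < 0 for v in components.values()),
        excluded_populations=excluded,
    )


def pairwise_fst(
    mm: MarkerMatrix,
    hierarchy: Hierarchy,
    n_perm: int = 0,
    seed: int = 0,
    min_pop_size: int = 2,
) -> tuple[DistanceMatrix, dict[tuple[str, str], float]]:
    """Phi_ST for every population pair (two-population one-level AMOVA).

    Returns a DistanceMatrix with negative estimates clamped to 0 for
    downstream Mantel use, plus the raw (unclamped) values per pair.
    """
    mm = mm.drop_replicates()
    pop_of = hierarchy.pop_of_sample
    from collections import Counter
    counts = Counter(pop_of.get(s) for s in mm.sample_ids if s in pop_of)
    pops = sorted(p for p, c in counts.items() if c >= min_pop_size)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations of sufficient size")
    raw: dict[tuple[str, str], float] = {}
    n = len(pops)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair = {pops[i], pops[j]}
            samples = [s for s in mm.sample_ids if pop_of.get(s) in pair]
            sub = mm.subset_samples(samples)
            d2 = mismatch_d2(sub)
            pop = np.array([0 if pop_of[s] == pops[i] else 1 for s in samples])
            _, sb, sc, _ = _components(d2, pop, None)
            fst = _phis(None, sb, sc)["F_ST"]
            raw[(pops[i], pops[j])] = float(fst)
            vals[i, j] = vals[j, i] = max(fst, 0.0)
    return DistanceMatrix(pops, vals, kind="fst"), raw
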