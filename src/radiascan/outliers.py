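"""Bayesian F-model genome scan for dominant markers (population pairs).

Hierarchical model per locus i and population j: ancestral presence-allele
frequency p_i ~ Beta(1,1); population frequency p_ij ~ Beta(p_i*theta_ij,
(1-p_i)*theta_ij) with theta_ij = (1-F_ij)/F_ij and logit(F_ij) =
delta_i*alpha_i + beta_j; band counts are Binomial with band probability
1-(1-p_ij)^2 (dominance under HWE).  The selection indicator delta_i has
prior P(delta=1) = 1/(1+prior_odds); its posterior mean is the per-locus
probability of selection.  Inference is Metropolis-within-Gibbs with an
exact Gibbs update for delta (alpha is refreshed from its prior while
excluded, the standard pseudo-prior construction).

Outliers from several population pairs of the same MOTU pair are
aggregated by intersection ("consistent outliers").
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit, betaln

from .io import MISSING, MarkerMatrix

__all__ = [
    "FModelConfig",
    "PairScan",
    "OutlierReport",
    "band_to_allele_model",
    "fit_fmodel_pair",
    "consistent_outliers",
    "scan_motu_pairs",
]


@dataclass
class FModelConfig:
    prior_odds: float = 10.0           # prior odds for neutrality
    n_iter: int = 50_000               # kept iterations (post burn-in sweeps)
    burn_in: int = 5_000
    thin: int = 10
    cutoff: float = 0.95               # posterior-probability outlier cutoff
    sd_alpha_prior: float = 2.0        # N(0, sd^2) prior on locus effects
    mean_beta_prior: float = -1.0      # N(mean, sd^2) prior on population effects
    sd_beta_prior: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must lie in (0,1)")
        if self.n_iter <= 0 or self.burn_in < 0:
            raise ValueError("iteration counts must be positive")
        if self.prior_odds <= 0:
            raise ValueError("prior odds must be positive")


@dataclass
class PairScan:
    pop_a: str
    pop_b: str
    locus_ids: list[str]
    posterior_prob: np.ndarray          # P(delta=1 | data) per locus
    alpha_mean: np.ndarray              # posterior mean of delta*alpha
    beta_mean: np.ndarray               # (2,) posterior means of beta_j
    cutoff: float
    skipped_monomorphic: list[str] = field(default_factory=list)
    acceptance: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def outliers(self) -> set[str]:
        return {
            l for l, p in zip(self.locus_ids, self.posterior_prob) if p > self.cutoff
        }


@dataclass
class OutlierReport:
    motu_a: str
    motu_b: str
    scans: list[PairScan]
    avg_n_outliers: float
    consistent: set[str]
    caveats: list[str] = field(default_factory=list)


def band_to_allele_model(n_present: np.ndarray, n_total: np.ndarray,
                         p: np.ndarray) -> np.ndarray:
    """Log-likelihood of band counts given presence-allele frequency p.

    Band probability under HWE dominance is 1-(1-p)^2; counts are binomial
    (the combinatorial constant is omitted — it cancels in all ratios).
    """
    n_present = np.asarray(n_present)
    n_total = np.asarray(n_total)
    if np.any(n_present > n_total):
        raise ValueError("n_present exceeds n_total")
    q = np.clip(1.0 - (1.0 - p) ** 2, 1e-300, 1 - 1e-15)
    return n_present * np.log(q) + (n_total - n_present) * np.log1p(-q)


def _beta_logpdf(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a - 1) * np.log(x) + (b - 1) * np.log1p(-x) - betaln(a, b)


def _pop_counts(mm: MarkerMatrix, pop_of: dict[str, str], pop: str):
    rows = [i for i, s in enumerate(mm.sample_ids) if pop_of.get(s) == pop]
    sub = mm.calls[rows]
    n_pres = (sub == 1).sum(axis=0)
    n_tot = (sub != MISSING).sum(axis=0)
    return n_pres.astype(float), n_tot.astype(float), len(rows)


class _PairSampler:
    """Vectorized Metropolis-within-Gibbs over loci for one population pair."""

    def __init__(self, n_pres: np.ndarray, n_tot: np.ndarray, cfg: FModelConfig):
        self.n_pres = n_pres            # (L, 2)
        self.n_tot = n_tot
        self.cfg = cfg
        self.L = n_pres.shape[0]
        self.rng = np.random.default_rng(cfg.seed)
        L = self.L
        self.p = np.full(L, 0.5)
        self.pj = np.clip((n_pres + 0.5) / (n_tot + 1.0), 0.01, 0.99)
        self.pj = 1.0 - np.sqrt(1.0 - self.pj)       # invert dominance map
        self.alpha = np.zeros(L)
        self.delta = np.zeros(L, dtype=bool)
        self.beta = np.full(2, cfg.mean_beta_prior)
        self.s_p, self.s_pj, self.s_alpha, self.s_beta = 0.8, 0.5, 0.8, 0.15
        self.acc = {"p": [0, 0], "pj": [0, 0], "alpha": [0, 0], "beta": [0, 0]}

    # -- pieces ------------------------------------------------------------

    def _theta(self, alpha_term: np.ndarray) -> np.ndarray:
        f = np.clip(expit(alpha_term[:, None] + self.beta[None, :]), 1e-6, 1 - 1e-6)
        return (1.0 - f) / f

    def _beta_terms(self, p=None, pj=None, alpha_term=None) -> np.ndarray:
        p = self.p if p is None else p
        pj = self.pj if pj is None else pj
        at = self.delta * self.alpha if alpha_term is None else alpha_term
        th = self._theta(at)
        a = np.clip(p[:, None] * th, 1e-10, None)
        b = np.clip((1 - p)[:, None] * th, 1e-10, None)
        return _beta_logpdf(np.clip(pj, 1e-12, 1 - 1e-12), a, b)

    # -- update blocks -----------------------------------------------------

    def update_p(self) -> None:
        z = logit(self.p)
        z_new = z + self.rng.normal(0, self.s_p, self.L)
        p_new = np.clip(expit(z_new), 1e-12, 1 - 1e-12)
        cur = self._beta_terms().sum(axis=1)
        new = self._beta_terms(p=p_new).sum(axis=1)
        # flat prior on p => logit-scale Jacobian p(1-p)
        logr = new - cur + np.log(p_new * (1 - p_new)) - np.log(self.p * (1 - self.p))
        acc = np.log(self.rng.random(self.L)) < logr
        self.p[acc] = p_new[acc]
        self.acc["p"][0] += int(acc.sum())
        self.acc["p"][1] += self.L

    def update_pj(self) -> None:
        z = logit(np.clip(self.pj, 1e-12, 1 - 1e-12))
        z_new = z + self.rng.normal(0, self.s_pj, z.shape)
        pj_new = np.clip(expit(z_new), 1e-12, 1 - 1e-12)
        cur = self._beta_terms() + band_to_allele_model(self.n_pres, self.n_tot, self.pj)
        new = self._beta_terms(pj=pj_new) + band_to_allele_model(self.n_pres, self.n_tot, pj_new)
        logr = (new - cur
                + np.log(pj_new * (1 - pj_new))
                - np.log(self.pj * (1 - self.pj)))
        acc = np.log(self.rng.random(z.shape)) < logr
        self.pj[acc] = pj_new[acc]
        self.acc["pj"][0] += int(acc.sum())
        self.acc["pj"][1] += acc.size

    def update_alpha(self) -> None:
        cfg = self.cfg
        # included loci: random-walk Metropolis
        a_new = self.alpha + self.rng.normal(0, self.s_alpha, self.L)
        cur = self._beta_terms().sum(axis=1)
        new = self._beta_terms(alpha_term=self.delta * a_new).sum(axis=1)
        logr = (new - cur
                + (self.alpha ** 2 - a_new ** 2) / (2 * cfg.sd_alpha_prior ** 2))
        acc = (np.log(self.rng.random(self.L)) < logr) & self.delta
        self.alpha[acc] = a_new[acc]
        self.acc["alpha"][0] += int(acc.sum())
        self.acc["alpha"][1] += max(int(self.delta.sum()), 1)
        # excluded loci: refresh from the prior (pseudo-prior)
        out = ~self.delta
        self.alpha[out] = self.rng.normal(0, cfg.sd_alpha_prior, int(out.sum()))

    def update_delta(self) -> None:
        ll1 = self._beta_terms(alpha_term=self.alpha).sum(axis=1)
        ll0 = self._beta_terms(alpha_term=np.zeros(self.L)).sum(axis=1)
        log_prior_ratio = -np.log(self.cfg.prior_odds)
        prob1 = expit(ll1 - ll0 + log_prior_ratio)
        self.delta = self.rng.random(self.L) < prob1

    def update_beta(self) -> None:
        cfg = self.cfg
        for j in (0, 1):
            b_new = self.beta.copy()
            b_new[j] += self.rng.normal(0, self.s_beta)
            cur = self._beta_terms()[:, j].sum()
            old = self.beta[j]
            self.beta[j] = b_new[j]
            new = self._beta_terms()[:, j].sum()
            logr = (new - cur
                    + ((old - cfg.mean_beta_prior) ** 2
                       - (b_new[j] - cfg.mean_beta_prior) ** 2)
                    / (2 * cfg.sd_beta_prior ** 2))
            if np.log(self.rng.random()) < logr:
                self.acc["beta"][0] += 1
            else:
                self.beta[j] = old
            self.acc["beta"][1] += 1

    def sweep(self) -> None:
        self.update_p()
        self.update_pj()
        self.update_beta()
        self.update_alpha()
        self.update_delta()

    def adapt(self) -> None:
        for name, attr in (("p", "s_p"), ("pj", "s_pj"),
                           ("alpha", "s_alpha"), ("beta", "s_beta")):
            a, t = self.acc[name]
            if t == 0:
                continue
            rate = a / t
            scale = getattr(self, attr)
            if rate < 0.2:
                setattr(self, attr, scale * 0.7)
            elif rate > 0.5:
                setattr(self, attr, scale * 1.4)
            self.acc[name] = [0, 0]


def run_pair_sampler(
    n_pres: np.ndarray, n_tot: np.ndarray, cfg: FModelConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, float]]:
    """Run the pair MCMC on raw (L, 2) band-count arrays.

    Returns (posterior selection probabilities, posterior mean of
    delta*alpha, posterior mean of beta, acceptance rates).  No
    polymorphism filtering is applied here.
    """
    sampler = _PairSampler(np.asarray(n_pres, float), np.asarray(n_tot, float), cfg)
    for it in range(cfg.burn_in):
        sampler.sweep()
        if it and it % 200 == 0:
            sampler.adapt()
    L = sampler.L
    prob = np.zeros(L)
    alpha_sum = np.zeros(L)
    beta_sum = np.zeros(2)
    kept = 0
    for it in range(cfg.n_iter):
        sampler.sweep()
        if it % cfg.thin == 0:
            prob += sampler.delta
            alpha_sum += sampler.delta * sampler.alpha
            beta_sum += sampler.beta
            kept += 1
    acc = {k: (a / t if t else float("nan")) for k, (a, t) in sampler.acc.items()}
    return prob / kept, alpha_sum / kept, beta_sum / kept, acc


def fit_fmodel_pair(
    mm: MarkerMatrix,
    pop_a: str,
    pop_b: str,
    pop_of: dict[str, str],
    config: FModelConfig | None = None,
) -> PairScan:
    """MCMC scan of one population pair; returns per-locus posterior
    probabilities of selection and posterior means of the model effects."""
    cfg = config or FModelConfig()
    mm = mm.drop_replicates()
    pres_a, tot_a, na = _pop_counts(mm, pop_of, pop_a)
    pres_b, tot_b, nb = _pop_counts(mm, pop_of, pop_b)
    if na < 2 or nb < 2:
        raise ValueError("both populations need >= 2 individuals")

    n_pres = np.column_stack([pres_a, pres_b])
    n_tot = np.column_stack([tot_a, tot_b])
    # loci monomorphic across the pair carry no differentiation signal
    poly = ~((n_pres.sum(axis=1) == 0) | (n_pres == n_tot).all(axis=1))
    skipped = [l for l, keep in zip(mm.locus_ids, poly) if not keep]
    locus_ids = [l for l, keep in zip(mm.locus_ids, poly) if keep]
    if len(locus_ids) < 10:
        raise ValueError("need >= 10 polymorphic loci for the scan")

    prob, alpha_mean, beta_mean, acc_rates = run_pair_sampler(
        n_pres[poly], n_tot[poly], cfg
    )

    warns = []
    for name, rate in acc_rates.items():
        if not 0.1 <= rate <= 0.7:
            warns.append(f"{name} acceptance rate {rate:.2f} outside [0.1, 0.7]")
    if warns:
        warnings.warn("; ".join(warns), stacklevel=2)

    return PairScan(
        pop_a=pop_a, pop_b=pop_b, locus_ids=locus_ids,
        posterior_prob=prob, alpha_mean=alpha_mean, beta_mean=beta_mean,
        cutoff=cfg.cutoff, skipped_monomorphic=skipped,
        acceptance=acc_rates, warnings=warns,
    )


def consistent_outliers(
    scans: list[PairScan],
    motu_of_pop: dict[str, str],
    pops_of_motu: dict[str, list[str]] | None = None,
) -> list[OutlierReport]:
    """Aggregate pair scans into per-MOTU-pair reports.

    For each MOTU pair every cross-MOTU population-pair combination must be
    present; the consistent set is the intersection of the per-pair outlier
    sets and the average outlier count is the mean over pairs.
    """
    if pops_of_motu is None:
        pops_of_motu = {}
        for pop, motu in motu_of_pop.items():
            pops_of_motu.setdefault(motu, []).append(pop)
        pops_of_motu = {m: sorted(ps) for m, ps in pops_of_motu.items()}

    by_motu_pair: dict[tuple[str, str], dict[frozenset, PairScan]] = {}
    for scan in scans:
        ma, mb = motu_of_pop[scan.pop_a], motu_of_pop[scan.pop_b]
        if ma == mb:
            continue
        key = tuple(sorted((ma, mb)))
        by_motu_pair.setdefault(key, {})[frozenset((scan.pop_a, scan.pop_b))] = scan

    reports = []
    for (ma, mb), pair_scans in sorted(by_motu_pair.items()):
        required = [
            frozenset((a, b))
            for a, b in itertools.product(pops_of_motu[ma], pops_of_motu[mb])
        ]
        for req in required:
            if req not in pair_scans:
                raise ValueError(
                    f"MOTU pair ({ma}, {mb}): missing population pair "
                    f"{tuple(sorted(req))}"
                )
        ordered = [pair_scans[r] for r in required]
        outlier_sets = [s.outliers for s in ordered]
        consistent = set.intersection(*outlier_sets) if outlier_sets else set()
        caveats = []
        for m in (ma, mb):
            if len(pops_of_motu[m]) == 1:
                caveats.append(
                    f"MOTU {m} has a single population: outliers may reflect "
                    "population-specific demographic history"
                )
        reports.append(OutlierReport(
            motu_a=ma, motu_b=mb, scans=ordered,
            avg_n_outliers=float(np.mean([len(s) for s in outlier_sets])),
            consistent=consistent, caveats=caveats,
        ))
    return reports


def scan_motu_pairs(
    mm: MarkerMatrix,
    pop_of: dict[str, str],
    motu_of_pop: dict[str, str],
    config: FModelConfig | None = None,
    min_pop_size: int = 2,
) -> list[OutlierReport]:
    """Scan every cross-MOTU population pair and aggregate the results."""
    cfg = config or FModelConfig()
    from collections import Counter
    counts = Counter(pop_of.get(s) for s in mm.drop_replicates().sample_ids)
    pops = sorted(p for p in motu_of_pop if counts.get(p, 0) >= min_pop_size)
    pops_of_motu: dict[str, list[str]] = {}
    for p in pops:
        pops_of_motu.setdefault(motu_of_pop[p], []).append(p)
    scans = []
    rng = np.random.default_rng(cfg.seed)
    for ma, mb in itertools.combinations(sorted(pops_of_motu), 2):
        for pa, pb in itertools.product(pops_of_motu[ma], pops_of_motu[mb]):
            pair_cfg = FModelConfig(**{**cfg.__dict__, "seed": int(rng.integers(2 ** 31))})
            scans.append(fit_fmodel_pair(mm, pa, pb, pop_of, pair_cfg))
    return consistent_outliers(scans, motu_of_pop, pops_of_motu)
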