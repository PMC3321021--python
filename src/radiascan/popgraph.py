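"""Population Graphs: conditional genetic covariance networks.

The saturated graph over populations is pruned by edge-exclusion deviance
(EED): population mean marker profiles give an among-population covariance
matrix; its inverse yields partial correlations rho_ij given the rest; an
edge survives when EED = -N ln(1 - rho_ij^2) exceeds the chi-square(1)
critical value at the chosen alpha.  Node size is the mean squared
distance of individuals to their population centroid; edge weight is
-ln(rho^2), so stronger conditional covariance gives shorter edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy import stats

from .io import MISSING, MarkerMatrix

__all__ = ["PopGraph", "build_population_graph", "write_graphml"]


@dataclass
class PopGraph:
    graph: nx.Graph
    alpha: float
    node_variance: dict[str, float]
    edges: list[tuple[str, str, float, float, float]]   # (a, b, weight, eed, p)
    components: list[set[str]]
    dropped_populations: list[str] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_population_graph(
    mm: MarkerMatrix,
    pop_of: dict[str, str],
    alpha: float = 0.05,
    min_pop_size: int = 3,
    eed_n: str = "individuals",
) -> PopGraph:
    """Prune the saturated population graph by edge-exclusion deviance.

    ``eed_n`` selects the sample-size convention in the deviance: the total
    number of ``individuals`` (default) or the number of ``loci`` used to
    estimate the among-population covariance.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    mm = mm.drop_replicates()
    from collections import Counter
    counts = Counter(pop_of.get(s) for s in mm.sample_ids if s in pop_of)
    pops = sorted(p for p, c in counts.items() if c >= min_pop_size)
    dropped = sorted(p for p, c in counts.items() if c < min_pop_size)
    if dropped:
        warnings.warn(f"populations below size {min_pop_size} dropped: {dropped}",
                      stacklevel=2)
    if len(pops) < 3:
        raise ValueError("need >= 3 populations above the size cutoff")

    samples = [s for s in mm.sample_ids if pop_of.get(s) in set(pops)]
    sub = mm.subset_samples(samples)
    X = np.where(sub.calls == MISSING, np.nan, sub.calls).astype(float)

    pop_idx = {p: i for i, p in enumerate(pops)}
    labels = np.array([pop_idx[pop_of[s]] for s in samples])
    P, L = len(pops), sub.n_loci
    means = np.empty((P, L))
    node_var = {}
    for p, i in pop_idx.items():
        rows = X[labels == i]
        means[i] = np.nanmean(rows, axis=0)
        resid = rows - means[i][None, :]
        node_var[p] = float(np.nanmean(np.nansum(resid ** 2, axis=1)))

    # Among-population covariance of the band-frequency profiles over loci.
    # Profiles are deliberately NOT centered by the per-locus grand mean:
    # that centering forces the population deviations to sum to zero at
    # every locus, which makes the correlation matrix exactly singular and
    # every conditional correlation degenerate (+-1).  The shared per-locus
    # mean acts as a common component that the conditioning on the other
    # populations absorbs.
    cov = np.cov(means)
    try:
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        omega = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        warnings.warn("singular among-population covariance; ridge fallback",
                      stacklevel=2)
        ridge = 1e-8 * np.trace(cov) * np.eye(P)
        cov = cov + ridge
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        omega = np.linalg.inv(corr)

    dd = np.sqrt(np.diag(omega))
    partial = -omega / np.outer(dd, dd)
    np.fill_diagonal(partial, 1.0)

    n_eff = len(samples) if eed_n == "individuals" else L
    crit = stats.chi2.ppf(1 - alpha, df=1)

    g = nx.Graph()
    for p in pops:
        g.add_node(p, variance=node_var[p])
    edge_rows = []
    for i in range(P):
        for j in range(i + 1, P):
            rho2 = min(partial[i, j] ** 2, 1 - 1e-12)
            eed = -n_eff * np.log1p(-rho2)
            pval = float(stats.chi2.sf(eed, df=1))
            if eed > crit:
                weight = float(-np.log(max(rho2, 1e-300)))
                g.add_edge(pops[i], pops[j], weight=weight, eed=float(eed), p=pval)
                edge_rows.append((pops[i], pops[j], weight, float(eed), pval))

    comps = [set(c) for c in nx.connected_components(g)]
    return PopGraph(graph=g, alpha=alpha, node_variance=node_var,
                    edges=edge_rows, components=comps, dropped_populations=dropped)


def write_graphml(pg: PopGraph, path) -> None:
    nx.write_graphml(pg.graph, path)
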