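"""AFLP scoring, marker selection and replicate-based error estimation.

Implements the automated marker-selection procedure for dominant marker
bins: relative-noise filtering of peak profiles, fixed-width binning,
detection-threshold scoring, replicate repeatability, the four exclusion
rules (low repeatability, null-allele-only bins, unconfirmed bins,
monomorphic markers) and the per-marker mismatch error rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, MarkerMatrix, _detect_replicates

__all__ = [
    "QcConfig",
    "QcReport",
    "score_profiles",
    "assess_repeatability",
    "select_markers",
    "genotyping_error_rate",
]


@dataclass
class QcConfig:
    #: peaks below this fraction of the 2nd-largest peak's height are noise
    relative_noise_fraction: float = 0.01
    #: minimum fluorescence for a scored presence
    detection_threshold: float = 50.0
    size_range: tuple[float, float] = (60.0, 550.0)
    max_bin_width: float = 0.75
    min_repeatability: float = 0.81
    drop_null_allele_only_bins: bool = True
    drop_unconfirmed_bins: bool = True
    drop_monomorphic: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.relative_noise_fraction < 1:
            raise ValueError("relative_noise_fraction must lie in (0,1)")
        if not 0 < self.min_repeatability <= 1:
            raise ValueError("min_repeatability must lie in (0,1]")
        if not self.size_range[0] < self.size_range[1]:
            raise ValueError("size_range must be ordered")


@dataclass
class QcReport:
    """Ledger of the marker-selection procedure."""

    repeatability: dict[str, float] = field(default_factory=dict)   # NaN = undefined
    null_only: set[str] = field(default_factory=set)
    confirmed_present: set[str] = field(default_factory=set)
    no_evaluable_pairs: list[str] = field(default_factory=list)
    dropped: dict[str, list[str]] = field(default_factory=dict)     # rule -> loci
    retained: list[str] = field(default_factory=list)
    mean_error_rate_pct: float | None = None

    def n_dropped(self) -> int:
        return sum(len(v) for v in self.dropped.values())


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_profiles(
    profiles: dict[str, list[tuple[float, float]]],
    config: QcConfig | None = None,
) -> MarkerMatrix:
    """Score peak profiles into a binary marker matrix.

    Per profile, peaks below ``relative_noise_fraction`` times the height of
    the second-largest peak are discarded (>= keeps a boundary peak), as are
    peaks outside ``size_range``.  Global bins are then built greedily over
    the sorted union of retained peak sizes, opening a new bin whenever
    adding a peak would stretch the bin beyond ``max_bin_width``.  A sample
    scores present in a bin iff one of its retained peaks with height >=
    ``detection_threshold`` falls inside it.
    """
    config = config or QcConfig()
    lo, hi = config.size_range
    retained: dict[str, np.ndarray] = {}
    for sid, peaks in profiles.items():
        arr = np.asarray(peaks, dtype=float).reshape(-1, 2)
        if arr.shape[0] < 2:
            warnings.warn(
                f"profile {sid!r} has fewer than 2 peaks; scored all-absent",
                stacklevel=2,
            )
            retained[sid] = np.empty((0, 2))
            continue
        heights = np.sort(arr[:, 1])[::-1]
        floor = config.relative_noise_fraction * heights[1]
        keep = (arr[:, 1] >= floor) & (arr[:, 0] >= lo) & (arr[:, 0] <= hi)
        retained[sid] = arr[keep]

    all_sizes = np.sort(np.concatenate(
        [r[:, 0] for r in retained.values() if r.size] or [np.empty(0)]
    ))
    if all_sizes.size == 0:
        raise ValueError("no peaks survive filtering; cannot build bins")

    # greedy left-to-right binning with the width cap
    edges: list[tuple[float, float]] = []
    start = all_sizes[0]
    last = all_sizes[0]
    for s in all_sizes[1:]:
        if s - start > config.max_bin_width:
            edges.append((start, last))
            start = s
        last = s
    edges.append((start, last))

    locus_ids = []
    seen: dict[str, int] = {}
    for a, b in edges:
        name = f"{(a + b) / 2:.2f}"
        if name in seen:
            seen[name] += 1
            name = f"{name}.{seen[name]}"
        else:
            seen[name] = 0
        locus_ids.append(name)

    sample_ids = list(profiles)
    calls = np.zeros((len(sample_ids), len(edges)), dtype=np.int8)
    starts = np.array([a for a, _ in edges])
    ends = np.array([b for _, b in edges])
    for i, sid in enumerate(sample_ids):
        r = retained[sid]
        if not r.size:
            continue
        strong = r[r[:, 1] >= config.detection_threshold]
        for size, _h in strong:
            j = np.searchsorted(starts, size, side="right") - 1
            if j >= 0 and size <= ends[j] + 1e-12:
                calls[i, j] = 1
    return MarkerMatrix(sample_ids, locus_ids, calls,
                        _detect_replicates(sample_ids))


# ---------------------------------------------------------------------------
# repeatability and selection
# ---------------------------------------------------------------------------

def assess_repeatability(mm: MarkerMatrix) -> QcReport:
    """Per-marker repeatability over replicate pairs, with evidence flags."""
    pairs = mm.replicate_pairs()
    if not pairs:
        raise ValueError("matrix carries no replicate pairs")
    rep = QcReport()
    a = mm.calls[[i for i, _ in pairs]]
    b = mm.calls[[j for _, j in pairs]]
    ok = (a != MISSING) & (b != MISSING)
    conc = ok & (a == b)
    both_present = ok & (a == 1) & (b == 1)
    any_present = ((a == 1) & (a != MISSING)) | ((b == 1) & (b != MISSING))
    n_ok = ok.sum(axis=0)
    n_conc = conc.sum(axis=0)
    for j, locus in enumerate(mm.locus_ids):
        if n_ok[j] == 0:
            rep.repeatability[locus] = float("nan")
            rep.no_evaluable_pairs.append(locus)
            continue
        rep.repeatability[locus] = n_conc[j] / n_ok[j]
        if both_present[:, j].any():
            rep.confirmed_present.add(locus)
        if not any_present[:, j].any():
            rep.null_only.add(locus)
    return rep


def select_markers(
    mm: MarkerMatrix, report: QcReport, config: QcConfig | None = None
) -> tuple[MarkerMatrix, QcReport]:
    """Apply the exclusion rules in their fixed order and return the
    filtered matrix plus a per-rule removal ledger.

    Rules: (1) repeatability strictly below the cutoff; (2) bins with no
    presence among replicate rows (null-allele-only); (3) bins with no
    confirmed present/present replicate pair; (4) markers monomorphic over
    the non-replicate samples.
    """
    config = config or QcConfig()
    dropped: dict[str, list[str]] = {
        "low_repeatability": [], "null_allele_only": [],
        "unconfirmed": [], "monomorphic": [],
    }
    remaining = list(mm.locus_ids)

    def take(rule: str, pred) -> None:
        nonlocal remaining
        hit = [l for l in remaining if pred(l)]
        dropped[rule].extend(hit)
        remaining = [l for l in remaining if l not in set(hit)]

    r = report.repeatability
    take("low_repeatability",
         lambda l: not np.isnan(r.get(l, np.nan)) and r[l] < config.min_repeatability)
    if config.drop_null_allele_only_bins:
        take("null_allele_only", lambda l: l in report.null_only)
    if config.drop_unconfirmed_bins:
        take("unconfirmed", lambda l: l not in report.confirmed_present)

    main = mm.drop_replicates()
    jmap = {l: j for j, l in enumerate(mm.locus_ids)}
    if config.drop_monomorphic:
        def mono(l: str) -> bool:
            col = main.calls[:, jmap[l]]
            vals = np.unique(col[col != MISSING])
            return len(vals) <= 1
        take("monomorphic", mono)

    if not remaining:
        raise ValueError(
            "all loci removed by QC; inspect thresholds "
            f"(dropped per rule: { {k: len(v) for k, v in dropped.items()} })"
        )
    out = mm.subset_loci(remaining)
    new_report = QcReport(
        repeatability=dict(report.repeatability),
        null_only=set(report.null_only),
        confirmed_present=set(report.confirmed_present),
        no_evaluable_pairs=list(report.no_evaluable_pairs),
        dropped=dropped,
        retained=remaining,
    )
    assert new_report.n_dropped() + len(remaining) == mm.n_loci
    return out, new_report


def genotyping_error_rate(
    mm: MarkerMatrix, method: str = "per_marker_mean"
) -> float:
    """Average genotyping error rate, as a percentage.

    Per-marker rate = discordant replicate pairs / evaluable pairs (the
    Bonin mismatch rate).  ``per_marker_mean`` (default) averages the
    per-marker rates over markers with at least one evaluable pair;
    ``pooled`` divides total mismatches by total comparisons.
    """
    pairs = mm.replicate_pairs()
    if not pairs:
        raise ValueError("no replicate pairs to estimate error from")
    a = mm.calls[[i for i, _ in pairs]]
    b = mm.calls[[j for _, j in pairs]]
    ok = (a != MISSING) & (b != MISSING)
    disc = ok & (a != b)
    n_ok = ok.sum(axis=0)
    if not n_ok.any():
        raise ValueError("no evaluable replicate comparisons")
    if method == "per_marker_mean":
        with np.errstate(invalid="ignore"):
            rates = np.where(n_ok > 0, disc.sum(axis=0) / np.maximum(n_ok, 1), np.nan)
        return float(np.nanmean(rates) * 100.0)
    if method == "pooled":
        return float(disc.sum() / ok.sum() * 100.0)
    raise ValueError(f"unknown method {method!r}")
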