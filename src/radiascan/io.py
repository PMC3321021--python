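"""Data model and file-format boundary.

Core objects (:class:`MarkerMatrix`, :class:`SampleTable`,
:class:`SequenceSet`) plus readers/writers for the delimited-text marker
matrix, sample metadata tables, FASTA and Newick.  All validation happens
here, at the boundary; downstream modules may assume the invariants hold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import dendropy
from Bio import SeqIO

__all__ = [
    "MISSING",
    "MarkerMatrix",
    "SampleTable",
    "SequenceSet",
    "read_aflp_matrix",
    "write_aflp_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_fasta",
    "write_fasta",
    "read_tree_newick",
    "write_tree_newick",
]

#: sentinel used in the int8 call matrix for a missing genotype call
MISSING: int = -1

_REP_SUFFIX = re.compile(r"^(?P<base>.+)_rep\d+$")


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class MarkerMatrix:
    """Samples x loci binary presence/absence matrix.

    ``calls`` is an int8 array with entries 1 (present), 0 (absent) and
    -1 (missing).  ``replicate_of`` maps a replicate row's sample id to the
    id of the original sample it re-genotypes.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    replicate_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = self.calls.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {n} matrix rows"
            )
        if len(self.locus_ids) != m:
            raise ValueError(
                f"{len(self.locus_ids)} locus ids but {m} matrix columns"
            )
        if n < 1 or m < 1:
            raise ValueError("need at least 1 sample and 1 locus")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.locus_ids)) != m:
            raise ValueError("duplicate locus ids")
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call {self.calls[i, j]} at sample "
                f"{self.sample_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )
        known = set(self.sample_ids)
        for rep, orig in self.replicate_of.items():
            if rep not in known:
                raise ValueError(f"replicate id {rep!r} not in sample_ids")
            if orig not in known:
                raise ValueError(
                    f"replicate {rep!r} points at unknown original {orig!r}"
                )

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def replicate_pairs(self) -> list[tuple[int, int]]:
        """(original_row, replicate_row) index pairs."""
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        return [(idx[orig], idx[rep]) for rep, orig in sorted(self.replicate_of.items())]

    def drop_replicates(self) -> "MarkerMatrix":
        """Matrix restricted to non-replicate rows."""
        keep = [i for i, s in enumerate(self.sample_ids) if s not in self.replicate_of]
        return self.subset_samples([self.sample_ids[i] for i in keep])

    def subset_samples(self, ids: Sequence[str]) -> "MarkerMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in ids]
        kept = set(ids)
        reps = {r: o for r, o in self.replicate_of.items() if r in kept and o in kept}
        return MarkerMatrix(list(ids), list(self.locus_ids), self.calls[rows], reps)

    def subset_loci(self, loci: Sequence[str]) -> "MarkerMatrix":
        idx = {l: j for j, l in enumerate(self.locus_ids)}
        cols = [idx[l] for l in loci]
        return MarkerMatrix(
            list(self.sample_ids), list(loci), self.calls[:, cols], dict(self.replicate_of)
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.sample_ids, columns=self.locus_ids)


@dataclass
class SampleTable:
    """Per-sample metadata: population, optional group (MOTU), island, coords."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "population_id")
    OPTIONAL = ("group_id", "island", "latitude", "longitude")

    def __post_init__(self) -> None:
        df = self.table
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"sample table lacks required column {col!r}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        blank = df["population_id"].isna() | (df["population_id"].astype(str).str.strip() == "")
        if blank.any():
            rows = (df.index[blank] + 0).tolist()
            raise ValueError(f"empty population_id in rows {rows}")
        if "latitude" in df.columns:
            lat = pd.to_numeric(df["latitude"], errors="coerce")
            ok = lat.isna() | ((lat >= -90) & (lat <= 90))
            if not ok.all():
                raise ValueError(f"latitude out of [-90,90]: {lat[~ok].tolist()}")
        if "longitude" in df.columns:
            lon = pd.to_numeric(df["longitude"], errors="coerce")
            ok = lon.isna() | ((lon >= -180) & (lon <= 180))
            if not ok.all():
                raise ValueError(f"longitude out of [-180,180]: {lon[~ok].tolist()}")
        self.table = df.reset_index(drop=True)

    def population_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"].astype(str), self.table["population_id"].astype(str)))

    def group_of_population(self) -> dict[str, str]:
        """population -> group map (requires a group_id column)."""
        if "group_id" not in self.table.columns:
            raise ValueError("sample table has no group_id column")
        out: dict[str, str] = {}
        for pop, grp in zip(self.table["population_id"], self.table["group_id"]):
            pop = str(pop)
            grp = str(grp)
            if pop in out and out[pop] != grp:
                raise ValueError(f"population {pop!r} assigned to multiple groups")
            out[pop] = grp
        return out

    def population_coordinates(self) -> dict[str, tuple[float, float]]:
        """Population -> (lat, lon); centroid when several samples carry coords."""
        df = self.table
        if "latitude" not in df.columns or "longitude" not in df.columns:
            raise ValueError("sample table lacks latitude/longitude columns")
        lat = pd.to_numeric(df["latitude"], errors="coerce")
        lon = pd.to_numeric(df["longitude"], errors="coerce")
        coords: dict[str, tuple[float, float]] = {}
        missing = []
        for pop, sub in pd.DataFrame(
            {"pop": df["population_id"].astype(str), "lat": lat, "lon": lon}
        ).groupby("pop"):
            good = sub.dropna()
            if good.empty:
                missing.append(pop)
            else:
                coords[pop] = (float(good["lat"].mean()), float(good["lon"].mean()))
        if missing:
            raise ValueError(f"populations without coordinates: {missing}")
        return coords


@dataclass
class SequenceSet:
    """Nucleotide records, optionally flagged as aligned (equal length)."""

    ids: list[str]
    seqs: list[str]
    aligned: bool = False

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids/seqs length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        self.seqs = [s.upper() for s in self.seqs]
        if self.aligned and len({len(s) for s in self.seqs}) > 1:
            lens = sorted({len(s) for s in self.seqs})
            raise ValueError(f"aligned flag set but lengths differ: {lens}")

    def __len__(self) -> int:
        return len(self.ids)


# ---------------------------------------------------------------------------
# marker matrix IO
# ---------------------------------------------------------------------------

def _detect_replicates(sample_ids: Iterable[str]) -> dict[str, str]:
    ids = list(sample_ids)
    known = set(ids)
    reps = {}
    for s in ids:
        m = _REP_SUFFIX.match(s)
        if m and m.group("base") in known:
            reps[s] = m.group("base")
    return reps


def read_aflp_matrix(
    path: str | Path,
    dialect: str = "wide",
    missing_token: str = "?",
    replicate_map: Mapping[str, str] | None = None,
) -> MarkerMatrix:
    """Read a binary marker matrix from delimited text.

    Dialects:

    ``wide``
        header row of locus ids, then one row per sample:
        ``sample_id<TAB>0<TAB>1...`` (tab or comma separated).
    ``string``
        two columns without header: sample id and a concatenated 0/1
        string, one character per locus.

    Replicate rows are recognised by the ``_rep<k>`` id suffix unless an
    explicit ``replicate_map`` (replicate id -> original id) is supplied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    sep = "\t" if "\t" in lines[0] else ","

    if dialect == "wide":
        header = lines[0].split(sep)
        locus_ids = [h.strip() for h in header[1:]]
        sample_ids, rows = [], []
        for r, ln in enumerate(lines[1:], start=2):
            parts = [p.strip() for p in ln.split(sep)]
            if len(parts) != len(locus_ids) + 1:
                raise FormatError(
                    f"{path}: ragged row {r} ({len(parts) - 1} entries, "
                    f"expected {len(locus_ids)})"
                )
            sample_ids.append(parts[0])
            row = []
            for j, tok in enumerate(parts[1:]):
                if tok == "0":
                    row.append(0)
                elif tok == "1":
                    row.append(1)
                elif tok == missing_token:
                    row.append(MISSING)
                else:
                    raise FormatError(
                        f"{path}: invalid entry {tok!r} at row {r}, "
                        f"locus {locus_ids[j]!r}"
                    )
            rows.append(row)
    elif dialect == "string":
        sample_ids, rows = [], []
        start = 0
        # tolerate a 2-column header
        first = lines[0].split(sep)
        if len(first) == 2 and any(c not in "01" + missing_token for c in first[1]):
            start = 1
        width = None
        for r, ln in enumerate(lines[start:], start=start + 1):
            parts = [p.strip() for p in ln.split(sep)]
            if len(parts) != 2:
                raise FormatError(f"{path}: row {r} is not two columns")
            sid, s = parts
            if width is None:
                width = len(s)
            elif len(s) != width:
                raise FormatError(
                    f"{path}: ragged row {r} (length {len(s)}, expected {width})"
                )
            row = []
            for j, ch in enumerate(s):
                if ch == "0":
                    row.append(0)
                elif ch == "1":
                    row.append(1)
                elif ch == missing_token:
                    row.append(MISSING)
                else:
                    raise FormatError(
                        f"{path}: invalid character {ch!r} at row {r}, column {j + 1}"
                    )
            sample_ids.append(sid)
            rows.append(row)
        locus_ids = [f"L{j + 1}" for j in range(width or 0)]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if len(set(sample_ids)) != len(sample_ids):
        seen, dups = set(), []
        for s in sample_ids:
            if s in seen:
                dups.append(s)
            seen.add(s)
        raise FormatError(f"{path}: duplicate sample ids {dups}")

    reps = dict(replicate_map) if replicate_map is not None else _detect_replicates(sample_ids)
    return MarkerMatrix(sample_ids, locus_ids, np.array(rows, dtype=np.int8), reps)


def write_aflp_matrix(mm: MarkerMatrix, path: str | Path, missing_token: str = "?") -> None:
    path = Path(path)
    tok = {1: "1", 0: "0", MISSING: missing_token}
    with path.open("w") as fh:
        fh.write("sample_id\t" + "\t".join(mm.locus_ids) + "\n")
        for sid, row in zip(mm.sample_ids, mm.calls):
            fh.write(sid + "\t" + "\t".join(tok[int(v)] for v in row) + "\n")


def read_peak_lists(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Read electropherogram peak lists from TSV (sample, size_b, height)."""
    profiles: dict[str, list[tuple[float, float]]] = {}
    lines = Path(path).read_text().splitlines()
    for ln in lines:
        if not ln.strip():
            continue
        parts = ln.split("\t") if "\t" in ln else ln.split(",")
        if len(parts) != 3:
            raise FormatError(f"peak list line is not three columns: {ln!r}")
        sid, size, height = (p.strip() for p in parts)
        if sid.lower() in ("sample", "sample_id"):
            continue
        profiles.setdefault(sid, []).append((float(size), float(height)))
    if not profiles:
        raise FormatError(f"{path}: no peaks")
    return {s: sorted(pk) for s, pk in profiles.items()}


def write_peak_lists(profiles: Mapping[str, Sequence[tuple[float, float]]],
                     path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample\tsize_b\theight\n")
        for sid, peaks in profiles.items():
            for size, height in peaks:
                fh.write(f"{sid}\t{size:.4f}\t{height:.2f}\n")


def read_replicate_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (replicate_id, original_id), optional header."""
    out = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.split("\t") if "\t" in ln else ln.split(",")
        if len(parts) != 2:
            raise FormatError(f"replicate map line is not two columns: {ln!r}")
        a, b = (p.strip() for p in parts)
        if a.lower() in ("replicate_id", "replicate"):
            continue
        out[a] = b
    return out


# ---------------------------------------------------------------------------
# sample table IO
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path) -> SampleTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "population_id": str})
    return SampleTable(df)


def write_sample_table(st: SampleTable, path: str | Path) -> None:
    st.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, aligned: bool = False) -> SequenceSet:
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return SequenceSet(
        [r.id for r in records], [str(r.seq).upper() for r in records], aligned=aligned
    )


def write_fasta(ss: SequenceSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sid, seq in zip(ss.ids, ss.seqs):
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)
# ---------------------------------------------------------------------------

def write_tree_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Serialize a tree; bootstrap supports ride on internal node labels."""
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and not np.isfinite(edge.length):
            raise ValueError("non-finite branch length in tree")
    s = tree.as_string(schema="newick", suppress_rooting=True)
    Path(path).write_text(s)


def read_tree_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
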