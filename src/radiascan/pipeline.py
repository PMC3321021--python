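"""End-to-end pipeline orchestration from a single YAML config.

Stages run in dependency order; each stage declares its output files,
which are hashed into a run manifest.  Rerunning with the same config and
seed reproduces the hashes of deterministic stages; a stage is re-executed
only when one of its outputs is missing or an upstream stage reran.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .amova import Hierarchy, amova as run_amova, pairwise_fst
from .ibd import geodesic_km_matrix, mantel_test
from .io import (MarkerMatrix, read_aflp_matrix, read_sample_table,
                 write_aflp_matrix, write_sample_table, write_tree_newick)
from .mixture import evanno_delta_k, likelihood_profile
from .phylo import nei_li_distance, neighbor_joining
from .popgraph import build_population_graph, write_graphml
from .qc import QcConfig, assess_repeatability, genotyping_error_rate, select_markers
from .simulate import SimParams, simulate_metapopulation

log = logging.getLogger("radiascan")

STAGE_ORDER = ["simulate", "qc", "distances", "amova", "ibd", "clusterk", "popgraph"]
STAGE_DEPS = {
    "simulate": [],
    "qc": ["simulate"],
    "distances": ["qc"],
    "amova": ["qc"],
    "ibd": ["qc"],
    "clusterk": ["qc"],
    "popgraph": ["qc"],
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    if "seed" not in cfg:
        raise ValueError("config must set a global seed")
    cfg.setdefault("outdir", "radiascan_out")
    return cfg


class _Ctx:
    def __init__(self, cfg: dict, outdir: Path):
        self.cfg = cfg
        self.outdir = outdir

    def matrix(self, stage: str) -> MarkerMatrix:
        name = {"simulate": "markers_raw.tsv", "qc": "markers_qc.tsv"}[stage]
        path = self.outdir / name
        if not path.exists():
            raise FileNotFoundError(
                f"stage input missing: {path} (upstream stage {stage!r})"
            )
        return read_aflp_matrix(path)

    def samples(self):
        path = self.outdir / "samples.tsv"
        if not path.exists():
            raise FileNotFoundError(f"stage input missing: {path} (upstream stage 'simulate')")
        return read_sample_table(path)


def _stage_simulate(ctx: _Ctx) -> list[Path]:
    c = dict(ctx.cfg.get("simulate", {}))
    c.setdefault("seed", ctx.cfg["seed"])
    params = SimParams(**c)
    mm, st, truth = simulate_metapopulation(params)
    write_aflp_matrix(mm, ctx.outdir / "markers_raw.tsv")
    write_sample_table(st, ctx.outdir / "samples.tsv")
    (ctx.outdir / "truth.json").write_text(json.dumps({
        "p_anc": truth.p_anc.tolist(),
        "p_pop": truth.p_pop.tolist(),
        "selected": truth.selected.tolist(),
        "group_of_pop": truth.group_of_pop,
        "e01": truth.e01, "e10": truth.e10,
    }))
    return [ctx.outdir / p for p in ("markers_raw.tsv", "samples.tsv", "truth.json")]


def _stage_qc(ctx: _Ctx) -> list[Path]:
    mm = ctx.matrix("simulate")
    cfg = QcConfig(**ctx.cfg.get("qc", {}))
    if mm.replicate_of:
        report = assess_repeatability(mm)
        filtered, report = select_markers(mm, report, cfg)
        err = genotyping_error_rate(filtered)
        report_dict = {
            "mean_error_rate_pct": err,
            "dropped": {k: len(v) for k, v in report.dropped.items()},
            "n_retained": len(report.retained),
        }
    else:
        log.warning("no replicates: QC pass-through (monomorphic filter only)")
        keep = [l for j, l in enumerate(mm.locus_ids)
                if len(np.unique(mm.calls[:, j][mm.calls[:, j] >= 0])) > 1]
        filtered = mm.subset_loci(keep)
        report_dict = {"mean_error_rate_pct": None,
                       "dropped": {"monomorphic": mm.n_loci - len(keep)},
                       "n_retained": len(keep)}
    write_aflp_matrix(filtered.drop_replicates(), ctx.outdir / "markers_qc.tsv")
    (ctx.outdir / "qc_report.json").write_text(json.dumps(report_dict, indent=1))
    return [ctx.outdir / "markers_qc.tsv", ctx.outdir / "qc_report.json"]


def _stage_distances(ctx: _Ctx) -> list[Path]:
    mm = ctx.matrix("qc")
    dm = nei_li_distance(mm)
    dm.to_tsv(ctx.outdir / "nei_li.tsv")
    boot = ctx.cfg.get("distances", {}).get("bootstrap", 100)
    tree = neighbor_joining(dm, bootstrap=(mm, boot, ctx.cfg["seed"]))
    write_tree_newick(tree, ctx.outdir / "nj.nwk")
    return [ctx.outdir / "nei_li.tsv", ctx.outdir / "nj.nwk"]


def _stage_amova(ctx: _Ctx) -> list[Path]:
    mm = ctx.matrix("qc")
    st = ctx.samples()
    c = ctx.cfg.get("amova", {})
    hier = Hierarchy(st.population_of(),
                               st.group_of_population() if "group_id" in st.table.columns else None)
    res = run_amova(mm, hier, n_perm=c.get("n_perm", 999),
                          seed=ctx.cfg["seed"], min_pop_size=c.get("min_pop_size", 5))
    out = ctx.outdir / "amova.json"
    out.write_text(json.dumps({
        "components": res.components, "percentages": res.percentages,
        "phi": res.phi, "p_values": res.p_values, "df": res.df,
        "n_permutations": res.n_permutations,
        "excluded_populations": res.excluded_populations,
    }, indent=1))
    return [out]


def _stage_ibd(ctx: _Ctx) -> list[Path]:
    mm = ctx.matrix("qc")
    st = ctx.samples()
    c = ctx.cfg.get("ibd", {})
    hier = Hierarchy(st.population_of())
    fst, _raw = pairwise_fst(mm, hier,
                                       min_pop_size=c.get("min_pop_size", 2))
    km = geodesic_km_matrix(st).submatrix(fst.ids)
    res = mantel_test(km, fst, n_perm=c.get("n_perm", 9999),
                              seed=ctx.cfg["seed"])
    iu = np.triu_indices(fst.n, k=1)
    scatter = pd.DataFrame({
        "pop_a": [fst.ids[i] for i in iu[0]],
        "pop_b": [fst.ids[j] for j in iu[1]],
        "km": km.values[iu], "fst": fst.values[iu],
    })
    scatter.to_csv(ctx.outdir / "ibd_scatter.tsv", sep="\t", index=False)
    (ctx.outdir / "mantel.json").write_text(json.dumps({
        "r": res.r, "p": res.p, "n_perm": res.n_perm, "n": res.n,
        "tail": res.tail, "exact": res.exact,
    }, indent=1))
    return [ctx.outdir / "ibd_scatter.tsv", ctx.outdir / "mantel.json"]


def _stage_clusterk(ctx: _Ctx) -> list[Path]:
    mm = ctx.matrix("qc")
    c = ctx.cfg.get("clusterk", {})
    runs = likelihood_profile(mm, range(c.get("k_min", 1), c.get("k_max", 5) + 1),
                              n_runs=c.get("n_runs", 10), seed=ctx.cfg["seed"])
    dk = evanno_delta_k(runs)
    dk.table.to_csv(ctx.outdir / "delta_k.tsv", sep="\t", index=False)
    (ctx.outdir / "delta_k_best.json").write_text(json.dumps({"best_k": dk.best_k}))
    return [ctx.outdir / "delta_k.tsv", ctx.outdir / "delta_k_best.json"]


def _stage_popgraph(ctx: _Ctx) -> list[Path]:
    mm = ctx.matrix("qc")
    st = ctx.samples()
    c = ctx.cfg.get("popgraph", {})
    pg = build_population_graph(mm, st.population_of(),
                                alpha=c.get("alpha", 0.05),
                                min_pop_size=c.get("min_pop_size", 3))
    write_graphml(pg, ctx.outdir / "popgraph.graphml")
    pd.DataFrame(pg.edges, columns=["pop_a", "pop_b", "weight", "eed", "p"]) \
        .to_csv(ctx.outdir / "popgraph_edges.tsv", sep="\t", index=False)
    return [ctx.outdir / "popgraph.graphml", ctx.outdir / "popgraph_edges.tsv"]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "distances": _stage_distances,
    "amova": _stage_amova,
    "ibd": _stage_ibd,
    "clusterk": _stage_clusterk,
    "popgraph": _stage_popgraph,
}

_STAGE_OUTPUTS = {
    "simulate": ["markers_raw.tsv", "samples.tsv", "truth.json"],
    "qc": ["markers_qc.tsv", "qc_report.json"],
    "distances": ["nei_li.tsv", "nj.nwk"],
    "amova": ["amova.json"],
    "ibd": ["ibd_scatter.tsv", "mantel.json"],
    "clusterk": ["delta_k.tsv", "delta_k_best.json"],
    "popgraph": ["popgraph.graphml", "popgraph_edges.tsv"],
}


def run_pipeline(config: dict | str | Path, stages: list[str] | None = None) -> dict:
    """Execute the requested stages and return the run manifest."""
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    if "seed" not in cfg:
        raise ValueError("config must set a global seed")
    outdir = Path(cfg.get("outdir", "radiascan_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    ctx = _Ctx(cfg, outdir)

    requested = stages or [s for s in STAGE_ORDER if s in cfg or s in ("qc", "distances")]
    requested = [s for s in STAGE_ORDER if s in requested]
    for s in requested:
        for dep in STAGE_DEPS[s]:
            if dep not in requested and not all(
                (outdir / f).exists() for f in _STAGE_OUTPUTS[dep]
            ):
                raise ValueError(f"stage {s!r} requires upstream stage {dep!r}")

    manifest: dict = {"config": {k: v for k, v in cfg.items()}, "stages": {}}
    reran: set[str] = set()
    for stage in requested:
        outputs = [outdir / f for f in _STAGE_OUTPUTS[stage]]
        need = (any(not p.exists() for p in outputs)
                or any(d in reran for d in STAGE_DEPS[stage]))
        if need:
            log.info("running stage %s", stage)
            try:
                outputs = _STAGE_FN[stage](ctx)
            except FileNotFoundError as e:
                raise RuntimeError(f"stage {stage!r} failed: {e}") from e
            reran.add(stage)
        else:
            log.info("stage %s up to date", stage)
        manifest["stages"][stage] = {
            "reran": stage in reran,
            "outputs": {str(p): _sha256(p) for p in outputs},
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
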