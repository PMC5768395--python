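"""End-to-end orchestration of the screening pipeline.

Stage order mirrors the screening funnel: (optional) simulation ->
reliability QC -> (optional) HRM triage -> representative-unit selection ->
per-marker ROC (overall and per tumor stage) -> top-k ranking -> m-of-k
panel sweep -> two-way clustering.  Every stage's parameters, seeds and
discard lists are written to a JSON run manifest so each under-specified
default is auditable; the same config and seed reproduce the report bundle
bit for bit.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cluster import cluster_purity, cluster_two_way
from .errors import ConfigError
from .hrm import StandardCurve, screen_sites
from .io import (MethylationMatrix, SampleMeta, SiteAnnotation, read_annotation,
                 read_matrix, read_meta, write_annotation, write_matrix, write_meta)
from .panel import derive_thresholds, sweep_panel
from .qc import apply_qc
from .roc import MarkerRocAnalyzer, results_table
from .selection import RepresentativeUnitReducer, rank_markers
from .simulate import SimConfig, simulate_hrm_observations, simulate_study

logger = logging.getLogger(__name__)


def _derived_seed(seed: int, offset: int) -> int:
    # independent per-stage streams, kept below 2**31
    return int(np.random.SeedSequence([seed, offset]).generate_state(1)[0] % (2**31))


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("pipeline config must be a mapping")
    return cfg


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> dict:
    """Run the full pipeline; returns the manifest dictionary.

    ``config`` keys (all optional unless noted):

    * ``seed`` — master seed, default 0
    * ``simulate`` — SimConfig fields; when present the study is simulated
    * ``inputs`` — paths (matrix, meta, sites, unit_map) when not simulating
    * ``qc`` — min_unit_fraction / max_sample_missing
    * ``hrm`` — noise_sd / min_fraction, or ``null`` to skip the triage
    * ``roc`` — spec_levels / n_boot / ci
    * ``panel`` — top_k / vote_m / spec_level
    * ``cluster`` — distance / linkage / pseudocount
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict[str, Any] = {"package_version": __version__, "seed": seed,
                                "stages": {}}

    # ---- inputs ----------------------------------------------------------
    truth = None
    if "simulate" in config and config["simulate"] is not None:
        sim_kwargs = dict(config["simulate"])
        sim_kwargs.setdefault("seed", _derived_seed(seed, 1))
        if "units_per_site" in sim_kwargs:
            sim_kwargs["units_per_site"] = tuple(sim_kwargs["units_per_site"])
        sim_cfg = SimConfig(**sim_kwargs)
        study = simulate_study(sim_cfg)
        matrix, meta, annotation = study.matrix, study.meta, study.annotation
        truth = study
        write_matrix(matrix, out / "matrix.tsv")
        write_meta(meta, out / "meta.tsv")
        write_annotation(annotation, out / "sites.tsv", out / "unit_map.tsv")
        manifest["stages"]["simulate"] = {
            "seed": sim_cfg.seed, "n_normal": sim_cfg.n_normal,
            "n_tumor": sim_cfg.n_tumor, "n_sites": sim_cfg.n_sites,
            "n_hyper": sim_cfg.n_hyper, "n_hypo": sim_cfg.n_hypo,
            "missing_rate": sim_cfg.missing_rate,
        }
    elif "inputs" in config:
        paths = config["inputs"]
        matrix = read_matrix(paths["matrix"])
        meta = read_meta(paths["meta"])
        annotation = read_annotation(paths["sites"], paths["unit_map"])
        manifest["stages"]["inputs"] = {k: str(v) for k, v in paths.items()}
    else:
        raise ConfigError("config needs either a 'simulate' or an 'inputs' block")

    # ---- QC --------------------------------------------------------------
    qc_cfg = config.get("qc", {})
    min_uf = float(qc_cfg.get("min_unit_fraction", 0.30))
    max_sm = float(qc_cfg.get("max_sample_missing", 0.30))
    matrix, discards = apply_qc(matrix, min_uf, max_sm)
    pd.Series(discards["units"], name="unit_id").to_csv(
        out / "discarded_units.tsv", sep="\t", index=False)
    pd.Series(discards["samples"], name="sample_id").to_csv(
        out / "discarded_samples.tsv", sep="\t", index=False)
    manifest["stages"]["qc"] = {
        "min_unit_fraction": min_uf, "max_sample_missing": max_sm,
        "order": "units first, then samples on surviving units",
        "n_units_discarded": len(discards["units"]),
        "n_samples_discarded": len(discards["samples"]),
    }

    # ---- HRM triage (optional; needs a simulated study for observations) --
    hrm_cfg = config.get("hrm", None)
    if hrm_cfg is not None and truth is not None:
        noise_sd = float(hrm_cfg.get("noise_sd", 0.05))
        min_fraction = float(hrm_cfg.get("min_fraction", 0.60))
        obs, curve = simulate_hrm_observations(
            truth, noise_sd=noise_sd, seed=_derived_seed(seed, 2))
        triage = screen_sites(obs, curve, meta, min_fraction=min_fraction)
        triage.to_csv(out / "hrm_triage.tsv", sep="\t", index=False)
        passing = triage.loc[triage["passed"], "site_id"].tolist()
        directions = triage.set_index("site_id")["direction"].to_dict()
        keep_sites = annotation.sites.index.intersection(passing)
        sites = annotation.sites.loc[keep_sites].copy()
        sites["direction"] = [directions.get(s, d) or d
                              for s, d in zip(sites.index, sites["direction"])]
        umap = annotation.unit_map[annotation.unit_map.isin(keep_sites)]
        annotation = SiteAnnotation(sites.reset_index(), umap)
        manifest["stages"]["hrm"] = {
            "noise_sd": noise_sd, "min_fraction": min_fraction,
            "n_sites_passing": len(passing),
        }
    else:
        manifest["stages"]["hrm"] = "skipped"

    # ---- representative unit per site ------------------------------------
    y = meta.classes_for(matrix.sample_ids).to_numpy()
    reducer = RepresentativeUnitReducer(annotation).fit(matrix, y)
    site_matrix = reducer.transform(matrix)
    pd.Series(reducer.representative_units_, name="unit_id").rename_axis(
        "site_id").reset_index().to_csv(out / "site_units.tsv", sep="\t", index=False)
    manifest["stages"]["select"] = {
        "rule": "highest oriented AUC per site, ties lexicographic",
        "n_sites": site_matrix.shape[1],
        "dropped_sites": reducer.dropped_sites_,
    }

    # ---- ROC per marker, overall and per stage ---------------------------
    roc_cfg = config.get("roc", {})
    spec_levels = tuple(float(s) for s in roc_cfg.get("spec_levels", (0.95,)))
    n_boot = int(roc_cfg.get("n_boot", 1000))
    ci = float(roc_cfg.get("ci", 0.95))
    directions_map = {s: annotation.direction_of(s)
                      for s in site_matrix.columns
                      if annotation.direction_of(s) in ("hyper", "hypo")}
    analyzer = MarkerRocAnalyzer(
        spec_levels=spec_levels, n_boot=n_boot, ci=ci,
        directions=directions_map, seed=_derived_seed(seed, 3),
    ).fit(site_matrix, y)
    analyzer.table_.to_csv(out / "roc_overall.tsv", sep="\t", index=False)

    stage_tables = []
    stages = meta.stages_for(site_matrix.index)
    for st in ("adenoma", "I", "II", "III"):
        mask = (y == "normal") | (stages == st).to_numpy()
        if (stages == st).sum() == 0:
            continue
        sub = MarkerRocAnalyzer(
            spec_levels=spec_levels, n_boot=n_boot, ci=ci,
            directions=directions_map, seed=_derived_seed(seed, 10 + len(stage_tables)),
        ).fit(site_matrix.loc[mask], y[mask])
        t = sub.table_.copy()
        t.insert(0, "stage", st)
        stage_tables.append(t)
    if stage_tables:
        pd.concat(stage_tables, ignore_index=True).to_csv(
            out / "roc_by_stage.tsv", sep="\t", index=False)
    manifest["stages"]["roc"] = {
        "spec_levels": list(spec_levels), "n_boot": n_boot, "ci": ci,
        "p_method": "delong",
    }

    # ---- ranking + panel --------------------------------------------------
    panel_cfg = config.get("panel", {})
    top_k = min(int(panel_cfg.get("top_k", 5)), site_matrix.shape[1])
    vote_m = int(panel_cfg.get("vote_m", 2))
    spec_level = float(panel_cfg.get("spec_level", 0.95))
    ranking = rank_markers(analyzer.table_, k=None)
    pd.Series(ranking, name="marker").to_csv(out / "ranking.tsv", sep="\t",
                                             index=False)
    top = ranking[:top_k]
    spec = derive_thresholds(site_matrix, meta, top, spec_level=spec_level,
                             directions=directions_map, vote_m=vote_m)
    result = sweep_panel(site_matrix, meta, spec)
    result.table.reset_index().to_csv(out / "panel_sweep.tsv", sep="\t", index=False)
    result.counts.reset_index().to_csv(out / "panel_counts.tsv", sep="\t", index=False)
    manifest["stages"]["panel"] = {
        "markers": top, "vote_m": vote_m, "spec_level": spec_level,
        "thresholds": {m: {"threshold": t.threshold, "direction": t.direction}
                       for m, t in spec.thresholds.items()},
        "excluded_samples": result.excluded_samples,
    }

    # ---- clustering --------------------------------------------------------
    cl_cfg = config.get("cluster", {})
    distance = cl_cfg.get("distance", "braycurtis")
    linkage = cl_cfg.get("linkage", "average")
    pseudocount = float(cl_cfg.get("pseudocount", 0.005))
    cres = cluster_two_way(MethylationMatrix(site_matrix), meta,
                           distance=distance, linkage=linkage,
                           pseudocount=pseudocount)
    comp, mis = cluster_purity(cres, meta)
    cres.labels.reset_index().to_csv(out / "cluster_labels.tsv", sep="\t",
                                     index=False)
    comp.to_csv(out / "cluster_composition.tsv", sep="\t", index=False)
    manifest["stages"]["cluster"] = {
        "distance": distance, "linkage": linkage, "pseudocount": pseudocount,
        "misassigned": mis,
    }

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    _write_summary(out, analyzer.table_, result, mis)
    return manifest


def _write_summary(out: Path, roc_table: pd.DataFrame, panel_result, mis: int) -> None:
    lines = ["ctcfmeth pipeline summary", "=" * 30, "",
             "Top markers by AUC:"]
    top = roc_table.sort_values("auc", ascending=False).head(5)
    for _, r in top.iterrows():
        lines.append(f"  {r['marker']:<12} AUC={r['auc']:.3f} ({r['direction']})")
    lines += ["", "Panel sweep (percent):",
              panel_result.table.round(2).to_string(),
              "", f"Two-way clustering misassignments: {mis}"]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
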