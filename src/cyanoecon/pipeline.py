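"""End-to-end analysis workflow tying the stages together.

``run_pipeline`` executes filter -> classify -> cluster -> enrich ->
quantify on a proteomics table and/or model fit -> light response ->
constrained-fraction experiments on growth observations, writes TSV/JSON
outputs and a machine-readable run manifest (seeds, parameters and counts
at every stage).  Outputs are regenerated identically from the same
inputs, configuration and seeds.
"""

from __future__ import annotations

import json
import platform
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import io
from .fitting import FitGrid, LightResponseModel
from .growth import ConstraintSpec, light_response, light_response_frame
from .params import ModelParameters
from .proteome import (calls_frame, classify_growth_dependence,
                       cluster_profiles, enrich_go_slim, enrichment_frame,
                       filter_protein_groups, map_go_slim)
from .quant import CalibrationSpec, calibrate_absolute, normalize_ibaq


@dataclass
class PipelineConfig:
    """Paths, grids, thresholds and toggles of one pipeline run."""

    out_dir: str | Path = "results"
    seed: int = 0
    # proteomics branch
    protein_groups: str | Path | None = None
    group_map: Mapping[str, str] | None = None
    annotations: str | Path | None = None
    slim_map: str | Path | None = None
    alpha: float = 0.05
    missing_rule: str = "keep_complete_group"
    correction: str | None = None
    n_clusters: int | None = None
    calibration: CalibrationSpec | None = None
    # model branch
    observations: str | Path | None = None
    params: ModelParameters = field(default_factory=ModelParameters)
    fit_grid: FitGrid | None = None
    response_I_grid: tuple[float, ...] = ()
    constrain_classes: tuple[str, ...] = ()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    On a stage failure the outputs of completed stages are preserved and
    the manifest records the failure point.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "python": platform.python_version(),
        "stages": {},
        "parameters": config.params.to_dict(),
    }
    try:
        if config.protein_groups is not None:
            _run_proteomics(config, out, manifest)
        if config.observations is not None:
            _run_model(config, out, manifest)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest["traceback"] = traceback.format_exc()
        io.write_json(manifest, out / "manifest.json")
        raise
    io.write_json(manifest, out / "manifest.json")
    return manifest


def _run_proteomics(config: PipelineConfig, out: Path, manifest: dict) -> None:
    matrix = io.load_protein_groups(config.protein_groups,
                                    groups=config.group_map)
    if len(matrix) == 0:
        raise ValueError("empty proteomics input")
    manifest["stages"]["load"] = {"proteins": len(matrix),
                                  "samples": len(matrix.samples)}
    filtered, report = filter_protein_groups(
        matrix, missing_rule=config.missing_rule)
    manifest["stages"]["filter"] = report

    calls, summary = classify_growth_dependence(
        filtered, alpha=config.alpha, correction=config.correction)
    io.write_table(calls_frame(calls), out / "dependence_calls.tsv")
    manifest["stages"]["classify"] = summary

    dependent_ids = [c.protein_id for c in calls if c.dependent]
    if dependent_ids:
        result = cluster_profiles(filtered.subset(dependent_ids),
                                  k=config.n_clusters, seed=config.seed)
        clusters = result.assignments.rename_axis("protein_id").reset_index()
        io.write_table(clusters, out / "clusters.tsv")
        io.write_table(result.centroids.reset_index(names="cluster"),
                       out / "cluster_centroids.tsv")
        manifest["stages"]["cluster"] = {
            "k": result.k, "clustered": len(result.assignments),
            "excluded": len(result.excluded)}

    if config.annotations and config.slim_map:
        slim_annotations, unknown = map_go_slim(
            io.load_annotations(config.annotations),
            io.load_slim_map(config.slim_map))
        rows = enrich_go_slim(calls, slim_annotations, alpha=config.alpha)
        io.write_table(enrichment_frame(rows), out / "enrichment.tsv")
        manifest["stages"]["enrich"] = {
            "categories": len(rows),
            "significant": sum(r.significant for r in rows),
            "unknown_terms": len(unknown)}

    if config.calibration is not None:
        normalized = normalize_ibaq(filtered.ibaq, config.calibration)
        copies = calibrate_absolute(normalized, config.calibration)
        io.write_table(copies.rename_axis("protein_id").reset_index(),
                       out / "copies_per_cell.tsv")
        manifest["stages"]["quantify"] = {"proteins": len(copies)}


def _run_model(config: PipelineConfig, out: Path, manifest: dict) -> None:
    obs = io.load_observations(config.observations)
    model = LightResponseModel(obs, base_params=config.params)
    res = model.fit(config.fit_grid)
    io.write_table(res.table, out / "fit_grid.tsv")
    io.write_json({"theta": res.params, "l": res.llf,
                   "grid_table": "fit_grid.tsv"}, out / "fit_report.json")
    manifest["stages"]["fit"] = {"theta": res.params, "l": res.llf}

    I_grid = (list(config.response_I_grid)
              or sorted({o.I for o in obs}))
    params = res.fitted_parameters
    states = light_response(params, I_grid)
    frame = light_response_frame(states)
    io.write_table(frame, out / "light_response.tsv")
    manifest["stages"]["response"] = {
        "points": len(frame),
        "mu_max": float(frame["mu"].max())}

    if config.constrain_classes:
        mu_un = dict(zip(frame["I"], frame["mu"]))
        peak = frame.loc[frame["mu"].idxmax()]
        deficits = {}
        for z in config.constrain_classes:
            cs = ConstraintSpec(z, float(peak[f"fraction_{z}"]))
            cstates = light_response(params, I_grid, constraint=cs)
            cframe = light_response_frame(cstates)
            cframe["mu_unconstrained"] = [mu_un[i] for i in cframe["I"]]
            io.write_table(cframe, out / f"constrained_{z}.tsv")
            deficits[z] = float(max(
                1.0 - mu / mu_un[i] if mu_un[i] > 0 else 0.0
                for i, mu in zip(cframe["I"], cframe["mu"])))
        manifest["stages"]["constrain"] = {"max_relative_deficit": deficits}
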