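"""End-to-end orchestration: synth -> quantify -> calibrate -> classify -> survival.

:func:`run_all` executes the whole pipeline on synthetic data (or
user-supplied calibration references), writing every intermediate table,
the analysis report, and a manifest with SHA-256 checksums of all
outputs.  Given the same configuration and seed, a rerun produces
bit-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import (
    DEFAULT_CALIBRATION,
    build_calibration,
    load_calibration,
    save_calibration,
)
from .classify import (
    aggregate_patient_profile,
    assign_clusters,
    classify_cells,
    compare_timepoints,
    quartile_strata,
)
from .cohortstats import AnalysisPlan, analyze_cohort, report_to_json
from .io import write_csv
from .quantify import QuantifyConfig, quantify_sample
from .synthgen import (
    SceneSpec,
    default_class_models,
    render_scene,
    sample_cell_table,
    sample_reference_line,
    simulate_survival_for_profiles,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "load_pipeline_config", "default_pipeline_config"]

_KNOWN_KEYS = {
    "seed", "n_patients", "timepoints", "imaging", "write_images",
    "scene", "patient_model", "calibration", "survival", "plan", "quantify",
}
_PATIENT_MODEL_KEYS = {
    "mean_single_epithelial", "mean_single_mesenchymal", "n_pbmc",
    "cluster_prob", "cluster_size_range",
}
_SURVIVAL_KEYS = {
    "endpoints", "log_hazard_ratios", "censoring_rate", "followup_horizon_months",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    seed: int = 0
    n_patients: int = 20
    timepoints: tuple = ("D1", "D8")
    imaging: bool = True
    write_images: bool = False
    scene: dict = field(default_factory=dict)  # SceneSpec field overrides
    patient_model: dict = field(
        default_factory=lambda: {
            "mean_single_epithelial": 2.0,
            "mean_single_mesenchymal": 2.0,
            "n_pbmc": 25,
            "cluster_prob": 0.45,
            "cluster_size_range": [2, 4],
        }
    )
    calibration: str | dict = "default"
    survival: dict = field(
        default_factory=lambda: {
            "endpoints": {"OS": {"dist": "exponential", "rate_per_month": 0.06},
                          "PFS": {"dist": "exponential", "rate_per_month": 0.25}},
            "log_hazard_ratios": {"has_cluster_mctc": 1.638},
            "censoring_rate": 0.3,
            "followup_horizon_months": 60.0,
        }
    )
    plan: dict = field(default_factory=dict)
    quantify: dict = field(default_factory=dict)  # QuantifyConfig overrides

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in d.items()})
        pm_unknown = set(cfg.patient_model) - _PATIENT_MODEL_KEYS
        if pm_unknown:
            raise ValueError(f"unknown patient_model keys: {sorted(pm_unknown)}")
        sv_unknown = set(cfg.survival) - _SURVIVAL_KEYS
        if sv_unknown:
            raise ValueError(f"unknown survival keys: {sorted(sv_unknown)}")
        cfg.timepoints = tuple(cfg.timepoints)
        return cfg


def default_pipeline_config() -> PipelineConfig:
    """The packaged demo configuration (small, runs in seconds)."""
    from importlib import resources

    with resources.files("ctcpheno.data").joinpath("demo_pipeline.yaml").open() as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


def load_pipeline_config(path: str | Path, *, seed: int | None = None) -> PipelineConfig:
    cfg = PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))
    if seed is not None:
        cfg.seed = int(seed)
    return cfg


def _patient_scene(cfg: PipelineConfig, rng: np.random.Generator, seed: int) -> SceneSpec:
    pm = cfg.patient_model
    n_e = int(rng.poisson(pm["mean_single_epithelial"]))
    n_m = int(rng.poisson(pm["mean_single_mesenchymal"]))
    clusters = []
    if rng.random() < pm["cluster_prob"]:
        lo, hi = pm["cluster_size_range"]
        clusters.append(("mesenchymal-CTC", int(rng.integers(lo, hi + 1))))
    scene_kwargs = dict(
        image_height_px=256,
        image_width_px=256,
        n_cells_per_class={
            "epithelial-CTC": n_e, "mesenchymal-CTC": n_m, "pbmc": int(pm["n_pbmc"]),
        },
        cluster_spec=tuple(clusters),
        gaussian_noise_sd=0.5,
        seed=seed,
    )
    scene_kwargs.update(cfg.scene)
    return SceneSpec(**scene_kwargs)


def _resolve_calibration(cfg: PipelineConfig, rng: np.random.Generator):
    if cfg.calibration == "default" or cfg.calibration is None:
        logger.info("using packaged default calibration (published reference ranges)")
        return DEFAULT_CALIBRATION
    if cfg.calibration == "fitted-synthetic":
        epi = sample_reference_line("epithelial", 120, seed=int(rng.integers(2**31)))
        mes = sample_reference_line("mesenchymal", 120, seed=int(rng.integers(2**31)))
        return build_calibration(epi, mes)
    if isinstance(cfg.calibration, dict) and "path" in cfg.calibration:
        return load_calibration(cfg.calibration["path"])
    raise ValueError(f"unrecognized calibration source: {cfg.calibration!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full pipeline; returns the manifest dictionary.

    Artifacts written to ``outdir``: calibration.yaml, cells.csv,
    ground_truth.csv, phenotypes.csv, clusters.csv, profiles.csv,
    timepoint_deltas.csv, survival.csv, report.json, manifest.json
    (plus per-patient OME-TIFFs when ``write_images`` is on).  On stage
    failure the manifest records the failure point and partial artifacts
    are retained; the exception propagates.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": [],
        "outputs": {},
        "failure": None,
    }
    rng = np.random.default_rng(cfg.seed)

    def _done(stage: str) -> None:
        manifest["stages"].append(stage)

    try:
        # --- calibrate -----------------------------------------------------
        calib = _resolve_calibration(cfg, rng)
        save_calibration(calib, out / "calibration.yaml")
        _done("calibrate")

        # --- synth + quantify ----------------------------------------------
        qcfg_kwargs = dict(cfg.quantify)
        all_cells, all_truth = [], []
        sample_meta = {}  # (patient, timepoint) -> (cells_df, labels or None, scene)
        for i in range(cfg.n_patients):
            pid = f"P{i:04d}"
            for tp in cfg.timepoints:
                scene_seed = int(rng.integers(2**31))
                scene = _patient_scene(cfg, rng, scene_seed)
                if cfg.imaging:
                    stack, truth = render_scene(scene)
                    qcfg = QuantifyConfig(
                        sample_id=f"{pid}_{tp}",
                        dilation_px=scene.cell_radius_px - scene.nucleus_radius_px + 2,
                        min_peak_distance=max(2, int(scene.nucleus_radius_px)),
                        **qcfg_kwargs,
                    )
                    result = quantify_sample(stack, qcfg)
                    cells = result.cells
                    labels = result.cell_labels
                    if cfg.write_images:
                        from .io import write_stack

                        write_stack(stack, out / f"scene_{pid}_{tp}.ome.tiff")
                else:
                    cells, truth = sample_cell_table(scene)
                    cells = cells.assign(sample_id=f"{pid}_{tp}")
                    labels = None
                cells = cells.assign(patient_id=pid, timepoint=tp)
                truth = truth.assign(patient_id=pid, timepoint=tp)
                all_cells.append(cells)
                all_truth.append(truth)
                sample_meta[(pid, tp)] = (cells, labels, scene)
        cells_df = pd.concat(all_cells, ignore_index=True)
        truth_df = pd.concat(all_truth, ignore_index=True)
        write_csv(cells_df, out / "cells.csv")
        write_csv(truth_df, out / "ground_truth.csv")
        _done("synth+quantify")

        # --- classify ------------------------------------------------------
        all_calls, all_cluster_rows, profiles = [], [], {}
        for (pid, tp), (cells, labels, scene) in sample_meta.items():
            calls = classify_cells(cells, calib, compute_quartiles=False)
            ctc_ids = calls.loc[calls["is_ctc"], "cell_id"].astype(int).tolist()
            if labels is not None:
                assignment = assign_clusters(ctc_ids, label_image=labels, adjacency_px=2)
            else:
                cents = cells.set_index("cell_id").loc[ctc_ids, ["x", "y"]].to_numpy()
                assignment = assign_clusters(
                    ctc_ids, centroids=cents,
                    max_centroid_distance=2.0 * scene.nucleus_radius_px,
                )
            profiles[(pid, tp)] = aggregate_patient_profile(calls, assignment, pid, tp)
            calls = calls.assign(
                patient_id=pid, timepoint=tp,
                cluster_id=calls["cell_id"].map(
                    lambda c: assignment.cell_to_cluster.get(int(c), 0)
                ),
            )
            all_calls.append(calls)
            for cid, members in assignment.clusters.items():
                all_cluster_rows.append(
                    {"patient_id": pid, "timepoint": tp, "cluster_id": cid,
                     "size": len(members), "member_cell_ids": ";".join(map(str, members))}
                )
        calls_df = pd.concat(all_calls, ignore_index=True)
        # cohort-level vim/ker quartile strata per timepoint
        for tp in cfg.timepoints:
            sel = (calls_df["timepoint"] == tp) & calls_df["is_ctc"]
            if sel.any():
                calls_df.loc[sel, "quartile_stratum"] = quartile_strata(
                    calls_df.loc[sel, "vim_ker_ratio"].to_numpy()
                )
        write_csv(calls_df, out / "phenotypes.csv")
        write_csv(
            pd.DataFrame(
                all_cluster_rows,
                columns=["patient_id", "timepoint", "cluster_id", "size", "member_cell_ids"],
            ),
            out / "clusters.csv",
        )
        profiles_df = pd.DataFrame([p.to_row() for p in profiles.values()])
        write_csv(profiles_df, out / "profiles.csv")

        deltas = []
        if "D1" in cfg.timepoints and "D8" in cfg.timepoints:
            for pid in {k[0] for k in profiles}:
                deltas.append(compare_timepoints(profiles[(pid, "D1")], profiles[(pid, "D8")]))
        if deltas:
            write_csv(pd.concat(deltas, ignore_index=True), out / "timepoint_deltas.csv")
        _done("classify")

        # --- survival ------------------------------------------------------
        base_tp = cfg.timepoints[0]
        d1 = profiles_df.loc[profiles_df["timepoint"] == base_tp].reset_index(drop=True)
        surv_frames = []
        for endpoint, baseline in cfg.survival["endpoints"].items():
            surv_frames.append(
                simulate_survival_for_profiles(
                    d1,
                    log_hazard_ratios=cfg.survival.get("log_hazard_ratios", {}),
                    baseline_hazard=baseline,
                    censoring_rate=cfg.survival.get("censoring_rate", 0.0),
                    followup_horizon_months=cfg.survival.get("followup_horizon_months", 60.0),
                    seed=int(rng.integers(2**31)),
                    endpoint=endpoint,
                )
            )
        survival_df = pd.concat(surv_frames, ignore_index=True)
        write_csv(survival_df, out / "survival.csv")

        plan = AnalysisPlan.from_dict(cfg.plan) if cfg.plan else AnalysisPlan(
            endpoints=tuple(cfg.survival["endpoints"]),
        )
        report = analyze_cohort(d1, survival_df, plan)
        report_to_json(report, out / "report.json")
        _done("cohortstats")
    except Exception as exc:
        manifest["failure"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(manifest, out)
        raise

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
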