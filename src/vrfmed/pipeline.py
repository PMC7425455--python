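"""End-to-end orchestration: simulate -> score -> cohort stats -> voxel-wise
GLMs -> cluster correction -> conjunction -> ROI extraction -> mediation.

Driven by a single YAML config; every run writes a JSON manifest with the
seed, settings, and SHA-256 hashes of all artifacts so that identical
configs can be verified to reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import apply_cluster_correction, estimate_smoothness, simulate_cluster_null
from .cohort_stats import (
    anova_oneway,
    chi_square_counts,
    partial_correlation,
    posthoc_pairwise,
    summarize_groups,
)
from .conjunction import RoiSet, conjunction, extract_roi_means, split_rois
from .glm import build_design, fit_ancova, fit_glm
from .mediation import panel_to_frame, run_mediation_panel
from .scoring import load_weights, score_cohort
from .synthetic import GroundTruth, generate_cohort, generate_gmv_images

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

_STAGES = ("simulate", "score", "cohort_stats", "glm", "cluster", "conjunction", "mediation")


@dataclass
class PipelineConfig:
    """Flat per-stage settings; see ``validate_config`` for the constraints."""

    out_dir: str = "vrfmed_run"
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in _STAGES})
    synthetic: dict[str, Any] = field(default_factory=dict)  # GroundTruth overrides
    weights_path: str | None = None  # None -> unit weights
    glm_covariates: list[str] = field(
        default_factory=lambda: ["age", "gender", "education_years", "apoe"]
    )
    ancova_covariates: list[str] = field(default_factory=lambda: ["age", "gender", "apoe"])
    voxel_p: float = 0.01
    alpha: float = 0.05
    cluster_n_iter: int = 1000
    connectivity: int = 6
    min_roi_size: int = 5
    outcomes: list[str] = field(default_factory=lambda: ["mmse", "adascog"])
    n_boot: int = 1000
    ci_level: float = 0.95
    save_images: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        stages = {s: True for s in _STAGES}
        stages.update(cfg.stages or {})
        cfg.stages = stages
        return cfg

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def validate_config(config: PipelineConfig) -> list[str]:
    """Empty list iff the config is runnable; each problem names its field."""
    problems: list[str] = []
    if not 0 < config.voxel_p < 1:
        problems.append(f"voxel_p out of (0,1): {config.voxel_p}")
    if not 0 < config.alpha <= 1:
        problems.append(f"alpha out of (0,1]: {config.alpha}")
    if config.cluster_n_iter < 1:
        problems.append(f"cluster_n_iter must be >= 1: {config.cluster_n_iter}")
    if config.connectivity not in (6, 18, 26):
        problems.append(f"connectivity must be 6/18/26: {config.connectivity}")
    if config.n_boot < 1:
        problems.append(f"n_boot must be >= 1: {config.n_boot}")
    if not 0 < config.ci_level < 1:
        problems.append(f"ci_level out of (0,1): {config.ci_level}")
    if config.min_roi_size < 1:
        problems.append(f"min_roi_size must be >= 1: {config.min_roi_size}")
    unknown_stages = set(config.stages) - set(_STAGES)
    if unknown_stages:
        problems.append(f"unknown stages: {sorted(unknown_stages)}")
    if config.weights_path is not None and not Path(config.weights_path).exists():
        problems.append(f"weights_path does not exist: {config.weights_path}")
    if config.synthetic:
        try:
            _truth_from_config(config)
        except (TypeError, ValueError) as exc:
            problems.append(f"synthetic: {exc}")
    for out in config.outcomes:
        if out not in ("mmse", "adascog"):
            problems.append(f"unknown outcome: {out}")
    # imaging stages need their upstream stages
    order = {s: i for i, s in enumerate(_STAGES)}
    enabled = [s for s in _STAGES if config.stages.get(s, True)]
    for dep, users in [
        ("simulate", ["score", "cohort_stats", "glm"]),
        ("glm", ["cluster"]),
        ("cluster", ["conjunction"]),
        ("conjunction", ["mediation"]),
    ]:
        for user in users:
            if user in enabled and dep not in enabled:
                problems.append(f"stage '{user}' requires stage '{dep}'")
    return problems


def _truth_from_config(config: PipelineConfig) -> GroundTruth:
    overrides = dict(config.synthetic or {})
    for key in ("group_sizes", "grid_shape", "voxel_size_mm", "group_atrophy", "group_names"):
        if key in overrides:
            overrides[key] = tuple(overrides[key])
    if "roi_specs" in overrides:
        overrides["roi_specs"] = tuple(
            (name, tuple(center), float(radius)) for name, center, radius in overrides["roi_specs"]
        )
    if "vrf_prevalence" in overrides:
        overrides["vrf_prevalence"] = tuple(tuple(row) for row in overrides["vrf_prevalence"])
    overrides.setdefault("seed", config.seed)
    return GroundTruth(**overrides)


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _sha256_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the enabled stages in order; return the run manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    def record(stage: str, outputs: dict[str, Any], t0: float) -> None:
        manifest["stages"][stage] = {
            "outputs": outputs,
            "seconds": round(time.time() - t0, 3),
        }
        logger.info("stage %s done in %.2fs", stage, time.time() - t0)

    state: dict[str, Any] = {}
    for stage in _STAGES:
        if not config.stages.get(stage, True):
            continue
        t0 = time.time()
        try:
            outputs = _STAGE_FUNCS[stage](config, state, out_dir)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            _write_manifest(manifest, out_dir)
            raise PipelineError(stage, str(exc)) from exc
        record(stage, outputs, t0)
    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict[str, Any], out_dir: Path) -> None:
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


# --------------------------------------------------------------------- stages


def _stage_simulate(config: PipelineConfig, state: dict, out_dir: Path) -> dict:
    truth = _truth_from_config(config)
    cohort = generate_cohort(truth)
    bundle = generate_gmv_images(cohort, truth)
    state.update(truth=truth, cohort=bundle.cohort, bundle=bundle)
    cohort_path = out_dir / "cohort.csv"
    bundle.cohort.to_csv(cohort_path, index=False)
    truth_path = truth.save(out_dir / "ground_truth.yaml")
    mask_path = bundle.brain_mask.save(out_dir / "brain_mask.nii.gz")
    outputs = {
        "cohort.csv": _sha256_file(cohort_path),
        "ground_truth.yaml": _sha256_file(truth_path),
        "brain_mask.nii.gz": _sha256_file(mask_path),
        "images": _sha256_array(np.stack([im.data for im in bundle.images])),
    }
    if config.save_images:
        img_dir = out_dir / "images"
        img_dir.mkdir(exist_ok=True)
        for im in bundle.images:
            im.save(img_dir / f"{im.subject_id}.nii.gz")
        outputs["images_dir"] = str(img_dir)
    return outputs


def _stage_score(config: PipelineConfig, state: dict, out_dir: Path) -> dict:
    weights = load_weights(config.weights_path) if config.weights_path else None
    scored = score_cohort(state["cohort"], weights=weights)
    state["cohort"] = scored
    path = out_dir / "cohort_scored.csv"
    scored.to_csv(path, index=False)
    return {"cohort_scored.csv": _sha256_file(path)}


def _stage_cohort_stats(config: PipelineConfig, state: dict, out_dir: Path) -> dict:
    cohort: pd.DataFrame = state["cohort"]
    bundle = state["bundle"]
    groups = {g: sub["vrf_score"].to_numpy(float) for g, sub in cohort.groupby("group", sort=False)}
    anova = anova_oneway(groups)
    posthoc = posthoc_pairwise(groups, alpha_family=0.05, reference=list(groups)[-1])
    gender_counts = pd.crosstab(cohort["group"], cohort["gender"]).to_numpy()
    apoe_counts = pd.crosstab(cohort["group"], cohort["apoe"]).to_numpy()
    # total GM volume (mm^3) per subject as a covariate for the partial correlations
    mask = bundle.brain_mask.data.astype(bool)
    voxvol = bundle.brain_mask.voxel_volume_mm3
    total_gm = np.array([im.data[mask].sum() * voxvol for im in bundle.images])
    covs = np.column_stack(
        [cohort["age"].to_numpy(float), cohort["gender"].to_numpy(float),
         cohort["apoe"].to_numpy(float), total_gm]
    )
    pc = {
        outcome: partial_correlation(
            cohort["vrf_score"].to_numpy(float), cohort[outcome].to_numpy(float), covs
        )
        for outcome in config.outcomes
    }
    results = {
        "anova_vrf_score": dataclasses.asdict(anova),
        "chi_square_gender": dataclasses.asdict(chi_square_counts(gender_counts)),
        "chi_square_apoe": dataclasses.asdict(chi_square_counts(apoe_counts)),
        "posthoc": [dataclasses.asdict(r) for r in posthoc],
        "partial_correlation": {k: dataclasses.asdict(v) for k, v in pc.items()},
    }
    json_path = out_dir / "cohort_stats.json"
    json_path.write_text(json.dumps(results, indent=2, default=str))
    # Table-1-like summary
    rows = []
    for var in ("age", "vrf_score", "mmse", "adascog"):
        s = summarize_groups({g: sub[var].to_numpy(float) for g, sub in cohort.groupby("group", sort=False)})
        s.insert(0, "variable", var)
        rows.append(s)
    table_path = out_dir / "table1.tsv"
    pd.concat(rows, ignore_index=True).to_csv(table_path, sep="\t", index=False)
    return {"cohort_stats.json": _sha256_file(json_path), "table1.tsv": _sha256_file(table_path)}


def _stage_glm(config: PipelineConfig, state: dict, out_dir: Path) -> dict:
    cohort: pd.DataFrame = state["cohort"]
    bundle = state["bundle"]
    mask = bundle.brain_mask
    outputs = {}
    state["glm"] = {}
    for predictor in ["vrf_score", *config.outcomes]:
        design = build_design(cohort, predictor, config.glm_covariates)
        design.to_tsv(out_dir / f"design_{predictor}.tsv")
        res = fit_glm(bundle.images, mask, design)
        state["glm"][predictor] = res
        zpath = res.z.to_volume().save(out_dir / f"zmap_{predictor}.nii.gz")
        outputs[zpath.name] = _sha256_file(zpath)
    covs = cohort[config.ancova_covariates].to_numpy(float)
    fmap = fit_ancova(bundle.images, mask, cohort["group"].tolist(), covs)
    fpath = fmap.to_volume().save(out_dir / "fmap_group.nii.gz")
    state["glm"]["ancova_f"] = fmap
    outputs[fpath.name] = _sha256_file(fpath)
    return outputs


def _stage_cluster(config: PipelineConfig, state: dict, out_dir: Path) -> dict:
    bundle = state["bundle"]
    res_vrf = state["glm"]["vrf_score"]
    smooth = estimate_smoothness(
        res_vrf.residuals, bundle.brain_mask.data.astype(bool), bundle.brain_mask.voxel_size_mm
    )
    table = simulate_cluster_null(
        bundle.brain_mask,
        fwhm_mm=smooth.mean_fwhm_mm,
        voxel_p=config.voxel_p,
        alpha=config.alpha,
        n_iter=config.cluster_n_iter,
        seed=config.seed,
        connectivity=config.connectivity,
    )
    table_path = table.to_json(out_dir / "cluster_thresholds.json")
    state["cluster_table"] = table
    state["corrected"] = {}
    outputs = {"cluster_thresholds.json": _sha256_file(table_path), "fwhm_mm": smooth.fwhm_mm}
    for predictor in ["vrf_score", *config.outcomes]:
        binary, clusters = apply_cluster_correction(
            state["glm"][predictor].z, table, config.voxel_p, config.alpha
        )
        state["corrected"][predictor] = binary
        from .images import VolumeImage

        vol = VolumeImage(binary.astype(np.float32), bundle.brain_mask.voxel_size_mm)
        bpath = vol.save(out_dir / f"corrected_{predictor}.nii.gz")
        outputs[bpath.name] = _sha256_file(bpath)
        outputs[f"n_clusters_{predictor}"] = len(clusters)
    return outputs


def _stage_conjunction(config: PipelineConfig, state: dict, out_dir: Path) -> dict:
    bundle = state["bundle"]
    outputs = {}
    state["roisets"] = {}
    state["roi_means"] = {}
    for outcome in config.outcomes:
        conj = conjunction(state["corrected"]["vrf_score"], state["corrected"][outcome])
        roiset = split_rois(
            conj,
            connectivity=config.connectivity,
            min_size=config.min_roi_size,
            voxel_size_mm=bundle.brain_mask.voxel_size_mm,
        )
        state["roisets"][outcome] = roiset
        outputs[f"n_rois_{outcome}"] = len(roiset)
        if len(roiset):
            roiset.save(
                out_dir / f"rois_{outcome}.nii.gz", out_dir / f"roi_names_{outcome}.json"
            )
            means = extract_roi_means(bundle.images, roiset)
            means_path = out_dir / f"roi_means_{outcome}.csv"
            means.to_csv(means_path, index=False)
            state["roi_means"][outcome] = means
            outputs[means_path.name] = _sha256_file(means_path)
    return outputs


def _stage_mediation(config: PipelineConfig, state: dict, out_dir: Path) -> dict:
    cohort: pd.DataFrame = state["cohort"]
    outputs = {}
    frames = []
    for outcome in config.outcomes:
        means = state["roi_means"].get(outcome)
        if means is None:
            logger.warning("no ROIs for outcome %s; skipping its mediation panel", outcome)
            continue
        results = run_mediation_panel(
            cohort,
            means,
            outcomes=[outcome],
            n_boot=config.n_boot,
            seed=config.seed,
            ci_level=config.ci_level,
        )
        frames.append(panel_to_frame(results))
    if frames:
        panel = pd.concat(frames, ignore_index=True)
        tsv_path = out_dir / "mediation.tsv"
        panel.to_csv(tsv_path, sep="\t", index=False)
        json_path = out_dir / "mediation_forest.json"
        json_path.write_text(panel.to_json(orient="records", indent=2))
        state["mediation"] = panel
        outputs = {
            "mediation.tsv": _sha256_file(tsv_path),
            "mediation_forest.json": _sha256_file(json_path),
        }
    return outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "score": _stage_score,
    "cohort_stats": _stage_cohort_stats,
    "glm": _stage_glm,
    "cluster": _stage_cluster,
    "conjunction": _stage_conjunction,
    "mediation": _stage_mediation,
}
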