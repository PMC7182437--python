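"""End-to-end orchestration: cohort -> preprocessing -> correspondences ->
shape model -> weights -> angles/labels -> statistical report.

Configuration is a single YAML/dict document validated against a strict
schema (unknown keys rejected) before any compute.  Every stage writes its
outputs under the configured output directory together with a manifest that
records the configuration hash and per-stage timings; a rerun with the same
configuration reuses cached stage outputs and reproduces the report
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import mesh as meshmod
from . import ssm as ssmmod
from . import synthetic
from .angles import ANGLE_NAMES, ClinicalAngles, StabilityThresholds, \
    compute_angles, label_stability
from .core import KneeSample
from .registration import CPDConfig, CorrespondenceSet, \
    build_correspondences, select_reference
from .stability import AnalysisReport, run_analysis

__all__ = ["PipelineConfig", "cmd_generate", "cmd_run", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DistConfig(_Strict):
    mean: float
    sd: float
    lower: Optional[float] = None
    upper: Optional[float] = None

    def to_dist(self) -> synthetic.ParamDist:
        return synthetic.ParamDist(self.mean, self.sd, self.lower, self.upper)


class SyntheticConfig(_Strict):
    n: int = 20
    fraction_left: float = 0.5
    resolution: float = 1.0
    distributions: dict[str, DistConfig] = Field(default_factory=dict)


class PreprocessConfig(_Strict):
    smooth_iterations: int = 5
    target_vertices: Optional[int] = None     # decimate when above this
    reference_edge_mm: Optional[float] = None  # remesh reference when set


class CPDSettings(_Strict):
    beta: float = 2.0
    lam: float = 3.0
    w: float = 0.1
    max_iter: int = 150
    tol: float = 1e-5
    low_rank: int = 60
    low_rank_min: int = 500
    gate_mm: float = 5.0

    def to_config(self) -> CPDConfig:
        return CPDConfig(beta=self.beta, lam=self.lam, w=self.w,
                         max_iter=self.max_iter, tol=self.tol,
                         low_rank=self.low_rank, low_rank_min=self.low_rank_min)


class PipelineConfig(_Strict):
    """Validated pipeline configuration (desk-scale defaults: n=20 synthetic
    cohort at ~1000 vertices/bone)."""

    outdir: str = "kneessm_out"
    seed: int = 0
    cohort_dir: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    cpd: CPDSettings = Field(default_factory=CPDSettings)
    ev_threshold: float = 0.95
    reference_id: Optional[str] = None
    thresholds: dict[str, tuple[float, float]] = Field(default_factory=dict)
    subset_sizes: tuple[int, ...] = (3, 4)
    shrinkage: float = 0.1

    @model_validator(mode="after")
    def _check_source(self):
        if (self.cohort_dir is None) == (self.synthetic is None):
            raise ValueError("configure exactly one of cohort_dir or synthetic")
        if not 0 < self.ev_threshold <= 1:
            raise ValueError("ev_threshold must be in (0, 1]")
        return self

    def stability_thresholds(self) -> StabilityThresholds:
        base = StabilityThresholds()
        if self.thresholds:
            merged = dict(base.ranges)
            merged.update({k: tuple(v) for k, v in self.thresholds.items()})
            return StabilityThresholds(ranges=merged)
        return base

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _cohort_spec(cfg: PipelineConfig) -> synthetic.CohortSpec:
    sy = cfg.synthetic
    dists = dict(synthetic.DEFAULT_DISTRIBUTIONS)
    dists.update({k: v.to_dist() for k, v in sy.distributions.items()})
    return synthetic.CohortSpec(n=sy.n, seed=cfg.seed, distributions=dists,
                                fraction_left=sy.fraction_left,
                                resolution=sy.resolution)


def cmd_generate(cfg: PipelineConfig) -> Path:
    """Generate the synthetic cohort directory (meshes + cohort/landmark CSVs)."""
    if cfg.synthetic is None:
        raise ValueError("no synthetic cohort configured")
    outdir = Path(cfg.outdir) / "cohort"
    samples = synthetic.sample_cohort(_cohort_spec(cfg))
    synthetic.write_cohort(samples, outdir)
    return outdir


def _load_cohort(cfg: PipelineConfig) -> list[KneeSample]:
    if cfg.synthetic is not None:
        cdir = Path(cfg.outdir) / "cohort"
        if not (cdir / "cohort.csv").exists():
            cmd_generate(cfg)
        return synthetic.read_cohort(cdir)
    return synthetic.read_cohort(cfg.cohort_dir)


def preprocess_sample(sample: KneeSample, pre: PreprocessConfig) -> KneeSample:
    """Right-side convention, smoothing, and decimation to the vertex budget."""
    s = sample.to_right()
    for bone in ("femur", "tibia"):
        m = getattr(s, bone)
        if pre.smooth_iterations:
            m = meshmod.smooth(m, pre.smooth_iterations)
        if pre.target_vertices and len(m.vertices) > pre.target_vertices:
            m = meshmod.decimate(m, pre.target_vertices)
        setattr(s, bone, m)
    return s


def _angle_table(samples: list[KneeSample],
                 thresholds: StabilityThresholds) -> pd.DataFrame:
    rows = []
    for s in samples:
        ang = s.angles if s.angles is not None else compute_angles(s.landmarks)
        labels = label_stability(ang, thresholds)
        row = {"id": s.sample_id, **ang.as_dict()}
        row.update({f"{k}_stable": labels[k] for k in ANGLE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


def cmd_run(cfg: PipelineConfig, force: bool = False) -> dict:
    """Execute the full pipeline, caching stages under ``outdir``.

    Returns a manifest dict with stage timings and key result paths; raises
    on stage failure after recording partial state in the manifest.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    manifest_path = outdir / "manifest.json"
    manifest = {"config_hash": chash, "stages": {}, "status": "running"}

    def record(stage, t0, **extra):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), **extra}
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))

    try:
        t0 = time.time()
        cohort = _load_cohort(cfg)
        record("cohort", t0, n=len(cohort))

        t0 = time.time()
        thresholds = cfg.stability_thresholds()
        cohort = [preprocess_sample(s, cfg.preprocess) for s in cohort]
        angles_df = _angle_table(cohort, thresholds)
        angles_df.to_csv(outdir / "angles.csv", index=False)
        record("preprocess+angles", t0)

        t0 = time.time()
        ref = select_reference(cohort, thresholds, cfg.reference_id)
        if cfg.preprocess.reference_edge_mm:
            ref = ref.copy()
            ref.femur = meshmod.remesh_to_edge_length(
                ref.femur, cfg.preprocess.reference_edge_mm)
            ref.tibia = meshmod.remesh_to_edge_length(
                ref.tibia, cfg.preprocess.reference_edge_mm)
        record("reference", t0, reference_id=ref.sample_id)

        corr_prefix = outdir / "correspondences"
        t0 = time.time()
        if not force and corr_prefix.with_suffix(".json").exists() and \
                _cache_valid(corr_prefix.with_suffix(".json"), chash):
            corr = CorrespondenceSet.load(corr_prefix)
            record("correspondences", t0, cached=True)
        else:
            corr = build_correspondences(cohort, ref, cfg.cpd.to_config(),
                                         gate_mm=cfg.cpd.gate_mm)
            corr.save(corr_prefix)
            meta = json.loads(corr_prefix.with_suffix(".json").read_text())
            meta["config_hash"] = chash
            corr_prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))
            record("correspondences", t0, cached=False)

        t0 = time.time()
        model = ssmmod.fit_ssm(corr)
        model.save(outdir / "model.npz")
        if model.n_modes == 0:
            manifest["status"] = "degenerate"
            manifest["message"] = ("all shapes identical: zero-mode model, "
                                   "analysis skipped")
            record("ssm", t0, n_modes=0)
            return manifest
        k = model.n_modes_for(cfg.ev_threshold)
        recon = ssmmod.reconstruction_errors(model, corr, k)
        record("ssm", t0, n_modes=model.n_modes, retained=k,
               recon=recon["summary"])

        t0 = time.time()
        W = np.array([ssmmod.project(model, s, n_modes=k)
                      for s in corr.as_matrix()])
        wdf = pd.DataFrame(W, columns=[f"mov{i+1}" for i in range(k)])
        wdf.insert(0, "id", corr.ids)
        wdf.to_csv(outdir / "weights.csv", index=False)
        record("project", t0)

        t0 = time.time()
        adf = angles_df.set_index("id").loc[corr.ids]
        report = run_analysis(W, adf, thresholds,
                              subset_sizes=cfg.subset_sizes,
                              shrinkage=cfg.shrinkage)
        (outdir / "report.json").write_text(report.to_json())
        _report_tables(report, outdir)
        record("analysis", t0, warnings=report.warnings)

        manifest["status"] = "ok"
        manifest["retained_modes"] = k
        manifest["explained_variance"] = model.explained_variance[:k].tolist()
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise


def _cache_valid(meta_path: Path, chash: str) -> bool:
    try:
        return json.loads(meta_path.read_text()).get("config_hash") == chash
    except (OSError, json.JSONDecodeError):
        return False


def _report_tables(report: AnalysisReport, outdir: Path) -> None:
    """Flat CSV views of the report (one row per variable x classifier, and
    one per mode x variable correlation)."""
    rows = []
    for var, kinds in report.classification.items():
        for kind, m in kinds.items():
            rows.append({"variable": var, "classifier": kind, **m})
    pd.DataFrame(rows).to_csv(outdir / "classification.csv", index=False)
    crows = []
    for var, pairs in report.correlations.items():
        for j, (c, p) in enumerate(pairs):
            crows.append({"variable": var, "mode": j + 1, "spearman_c": c,
                          "p_value": p})
    pd.DataFrame(crows).to_csv(outdir / "correlations.csv", index=False)
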