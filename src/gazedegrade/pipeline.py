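"""End-to-end orchestration: simulate -> metrics -> calibrate -> degrade -> assess.

The pipeline is deliberately file-based: every stage reads and writes
the documented CSV/JSON formats, never mutates its inputs, and records
its parameters and output hashes in a run manifest so a rerun with the
same configuration reproduces every artifact bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .degrade import (
    CalibrationModel,
    DegradationPlan,
    PlanConfig,
    degrade,
    fit_noise_regression,
    plan_baseline_degradation,
    plan_percentile_degradation,
)
from .io import GazeValidationError
from .quality import QualityConfig, quality_profile
from .realism import one_nn_two_sample, summarize_repeats
from .sim import CorpusSpec, ParamDist, simulate_corpus

__all__ = ["RunConfig", "run_end_to_end", "load_run_config", "write_corpus", "read_corpus"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one end-to-end synthetic study."""

    out_dir: Path
    seed: int = 0
    n_source_files: int = 200
    n_target_files: int = 200
    n_targets_per_file: int = 10
    source_rate_hz: float = 1000.0
    target_rate_hz: float = 250.0
    dwell_ms: tuple[float, float] = (1000.0, 1500.0)
    # per-file quality distributions (lab-grade source, VR-grade target)
    source_noise_sd: ParamDist = field(default_factory=lambda: ParamDist("lognormal", (0.1, 0.35)))
    source_bias: ParamDist = field(default_factory=lambda: ParamDist("normal", (0.0, 0.2)))
    target_noise_sd: ParamDist = field(default_factory=lambda: ParamDist("lognormal", (0.4, 0.3)))
    target_bias: ParamDist = field(default_factory=lambda: ParamDist("normal", (0.0, 0.5)))
    target_jitter_sd_ms: float = 0.35
    # calibration refit
    # grid spans the operating range of requisite marginal degradations
    # for the default source/target quality regimes
    n_calibration_files: int = 8
    sigma0_sq_grid: tuple[float, ...] = (0.05, 0.1, 0.15, 0.22, 0.3, 0.4, 0.5, 0.65)
    n_1nn_repeats: int = 5
    log_level: str = "INFO"


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; distribution fields as [family, params...]."""
    raw = yaml.safe_load(Path(path).read_text())
    for key in ("source_noise_sd", "source_bias", "target_noise_sd", "target_bias"):
        if key in raw:
            family, *params = raw[key]
            raw[key] = ParamDist(str(family), tuple(float(p) for p in params))
    if "dwell_ms" in raw and isinstance(raw["dwell_ms"], list):
        raw["dwell_ms"] = tuple(raw["dwell_ms"])
    if "sigma0_sq_grid" in raw:
        raw["sigma0_sq_grid"] = tuple(raw["sigma0_sq_grid"])
    raw["out_dir"] = Path(raw["out_dir"])
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_corpus(pairs, out_dir: Path) -> pd.DataFrame:
    """Write gaze/stimulus CSV pairs plus a manifest table."""
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, stim in pairs:
        gaze_path = out_dir / f"{rec.recording_id}_gaze.csv"
        stim_path = out_dir / f"{rec.recording_id}_stim.csv"
        gio.write_gaze_csv(rec, gaze_path)
        gio.write_stimulus_csv(stim, stim_path)
        rows.append(
            {
                "recording_id": rec.recording_id,
                "gaze_file": gaze_path.name,
                "stimulus_file": stim_path.name,
                "n_samples": rec.n_samples,
                "nominal_rate_hz": rec.nominal_rate,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_corpus(corpus_dir: Path) -> list:
    """Read a corpus written by :func:`write_corpus`."""
    corpus_dir = Path(corpus_dir)
    manifest = pd.read_csv(corpus_dir / "manifest.csv")
    pairs = []
    for row in manifest.itertuples(index=False):
        rate = float(row.nominal_rate_hz) if "nominal_rate_hz" in manifest.columns else None
        rec = gio.read_gaze_csv(
            corpus_dir / row.gaze_file, recording_id=str(row.recording_id), nominal_rate=rate
        )
        stim = gio.read_stimulus_csv(corpus_dir / row.stimulus_file)
        pairs.append((rec, stim))
    return pairs


def _metrics_for(pairs, config: QualityConfig, stage: str) -> list:
    profiles = []
    for rec, stim in pairs:
        try:
            profiles.append(quality_profile(rec, stim, config))
        except GazeValidationError as exc:
            raise GazeValidationError(f"stage {stage}: {exc}") from exc
    return profiles


def run_end_to_end(config: RunConfig) -> dict:
    """Run the whole synthetic study; returns the manifest dictionary.

    Stages: simulate source and target corpora; compute quality tables
    for both; build target percentile profiles; refit the noise-variance
    calibration on a sample of source files; degrade the source corpus
    with both the baseline and the percentile-matching model; compute
    degraded quality tables; assess both against the target with the
    1-NN two-sample test.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    qc = QualityConfig()
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        logger.info("stage %s done", stage)

    # -- simulate
    source_spec = CorpusSpec(
        n_files=config.n_source_files,
        dwell_ms=config.dwell_ms,
        n_targets=config.n_targets_per_file,
        rate_hz=config.source_rate_hz,
        noise_sd_dist=config.source_noise_sd,
        bias_dist=config.source_bias,
        seed=config.seed,
    )
    target_spec = CorpusSpec(
        n_files=config.n_target_files,
        dwell_ms=config.dwell_ms,
        n_targets=config.n_targets_per_file,
        rate_hz=config.target_rate_hz,
        noise_sd_dist=config.target_noise_sd,
        bias_dist=config.target_bias,
        jitter_sd_dist=ParamDist("constant", (config.target_jitter_sd_ms,)),
        seed=config.seed + 1,
    )
    source = simulate_corpus(source_spec)
    target = simulate_corpus(target_spec)
    record("simulate", n_source=len(source), n_target=len(target))

    # -- metrics
    source_quality = _metrics_for(source, qc, "metrics:source")
    target_quality = _metrics_for(target, qc, "metrics:target")
    gio.write_quality_table(source_quality, out / "source_quality.csv")
    gio.write_quality_table(target_quality, out / "target_quality.csv")
    target_profiles = gio.profiles_from_quality_table(target_quality)
    gio.write_percentile_profiles(target_profiles, out / "target_profiles.csv")
    record(
        "metrics",
        source_table=_sha256(out / "source_quality.csv"),
        target_table=_sha256(out / "target_quality.csv"),
    )

    # -- calibrate
    calibration = fit_noise_regression(
        source[: config.n_calibration_files],
        np.asarray(config.sigma0_sq_grid),
        target_rate_hz=config.target_rate_hz,
        quality_config=qc,
        seed=config.seed + 2,
    )
    (out / "calibration.json").write_text(
        json.dumps(
            {
                "slope": calibration.slope,
                "intercept": calibration.intercept,
                "diagnostics": calibration.fit_diagnostics,
            },
            indent=2,
        )
    )
    record("calibrate", slope=calibration.slope, intercept=calibration.intercept)

    # -- degrade (both models)
    plan_cfg = PlanConfig(target_rate_hz=config.target_rate_hz, seed=config.seed + 3)
    degraded_quality = {}
    for mode, planner in (
        ("baseline", plan_baseline_degradation),
        ("percentile", plan_percentile_degradation),
    ):
        plans = planner(source_quality, target_profiles, calibration, plan_cfg)
        pd.DataFrame([asdict(p) for p in plans]).to_csv(
            out / f"plans_{mode}.csv", index=False
        )
        degraded = [
            (degrade(rec, stim, plan, mode=mode, quality_config=qc), stim)
            for (rec, stim), plan in zip(source, plans)
        ]
        degraded_quality[mode] = _metrics_for(degraded, qc, f"metrics:degraded-{mode}")
        gio.write_quality_table(degraded_quality[mode], out / f"degraded_{mode}_quality.csv")
        record(f"degrade:{mode}", quality_table=_sha256(out / f"degraded_{mode}_quality.csv"))

    # -- assess
    target_mat = np.array([p.as_vector() for p in target_quality])
    assessment = {}
    for mode, quality in degraded_quality.items():
        synth_mat = np.array([p.as_vector() for p in quality])
        results = one_nn_two_sample(
            target_mat, synth_mat, n_repeats=config.n_1nn_repeats, seed=config.seed + 4
        )
        assessment[mode] = summarize_repeats(results)
    (out / "assessment.json").write_text(json.dumps(assessment, indent=2))
    record("assess", **{m: a["combined_accuracy"] for m, a in assessment.items()})

    manifest_path = out / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
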