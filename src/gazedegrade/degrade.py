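"""Synthetic degradation of gaze recordings toward a lower-quality device.

Two transformation models are provided.

Baseline (central-tendency) model
    filter -> resample -> additive white Gaussian noise.  Bandwidth is
    reduced with a zero-phase Butterworth low-pass at 0.8x the Nyquist
    frequency of the target rate, the signal is resampled by first-order
    spline (linear) interpolation onto a regular target grid, and a
    single corpus-level noise variance sigma0^2 is added to every file.
    By construction this matches the target's spatial precision only in
    central tendency: the source corpus' across-file dispersion is
    carried over unchanged.

Percentile-matching model
    For each source file, the percentile rank p of its combined spatial
    precision MAD_c within the source corpus is computed; the MAD_c at
    the same rank in the target corpus defines the requisite marginal
    degradation dMAD_c, converted to a per-file noise variance through a
    linear calibration

        sigma0^2 = slope * dMAD_c + intercept

    (packaged defaults slope=1.2904, intercept=0.0356, fitted for a
    1000 Hz lab tracker degraded to a 250 Hz VR headset; refitting on
    the corpus at hand is first-class via :func:`fit_noise_regression`).
    Spatial accuracy is degraded analogously per channel: the marginal
    offset dtheta is percentile-matched, and each fixation receives an
    offset drawn from N(dtheta, (rel_tol*dtheta/z)^2) — z chosen so a
    ``coverage`` fraction of draws lies within ``rel_tol`` of dtheta —
    applied with a random +/- sign.  Temporal precision is degraded by
    jittering the resampling grid with zero-mean Gaussian noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .io import (
    GazeRecording,
    GazeValidationError,
    PercentileProfile,
    QualityProfile,
    StimulusTrack,
)
from .quality import (
    QualityConfig,
    estimate_saccade_latency,
    extract_fixation_windows,
    quality_profile,
)

__all__ = [
    "NoiseModel",
    "CalibrationModel",
    "DEFAULT_CALIBRATION",
    "DegradationPlan",
    "PlanConfig",
    "antialias_filter",
    "resample_spline",
    "eccentricity_weight",
    "add_precision_noise",
    "fit_noise_regression",
    "required_noise_variance",
    "percentile_rank",
    "quantile_lookup",
    "plan_percentile_degradation",
    "plan_baseline_degradation",
    "draw_fixation_degradations",
    "inject_accuracy_offsets",
    "jitter_timestamps",
    "degrade",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian precision-noise model.

    The optional eccentricity weighting scales the noise variance with
    the radial distance r_s of the gaze sample from the screen centre:
    alpha = exp(-(r_s - r_max)^2 / (2 sigma_s^2)), so noise is strongest
    at the screen edge.  It is disabled by default (flat noise field).
    """

    sigma0_sq: float  # maximum additive noise variance, dva^2
    eccentricity_enabled: bool = False
    sigma_s: float | None = None  # dispersion of the Gaussian weighting, dva
    r_max: float | None = None  # maximum radial screen dimension, dva

    def __post_init__(self) -> None:
        if self.sigma0_sq < 0:
            raise ValueError("sigma0_sq must be >= 0")
        if self.eccentricity_enabled and not (
            self.sigma_s is not None and self.sigma_s > 0 and self.r_max is not None
        ):
            raise ValueError("eccentricity weighting requires sigma_s > 0 and r_max")


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map from requisite marginal MAD_c degradation to sigma0^2."""

    slope: float = 1.2904  # dva^2 per dva of dMAD_c
    intercept: float = 0.0356  # dva^2
    fit_diagnostics: dict | None = None

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("calibration slope must be positive for a usable model")


#: Packaged default coefficients (1000 Hz source -> 250 Hz target pairing).
DEFAULT_CALIBRATION = CalibrationModel()


@dataclass
class DegradationPlan:
    """Everything needed to degrade one source recording."""

    recording_id: str
    target_rate_hz: float
    sigma0_sq: float = 0.0
    delta_theta_h: float = 0.0
    delta_theta_v: float = 0.0
    percentile: float = float("nan")  # rank p of the file's MAD_c in the source set
    jitter_sd_ms: float = 0.0
    cutoff_factor: float = 0.8
    filter_order: int = 4
    accuracy_rel_tol: float = 0.2
    accuracy_coverage: float = 0.9973
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.sigma0_sq, self.delta_theta_h, self.delta_theta_v, self.jitter_sd_ms) < 0:
            raise ValueError(f"{self.recording_id}: plan quantities must be >= 0")


@dataclass(frozen=True)
class PlanConfig:
    """Corpus-level options for building degradation plans."""

    target_rate_hz: float = 250.0
    cutoff_factor: float = 0.8
    filter_order: int = 4
    accuracy_rel_tol: float = 0.2
    accuracy_coverage: float = 0.9973
    #: calibrated mode divides the target ISI sd by sqrt(2) so the
    #: *measured* temporal precision of the output matches the target;
    #: literal mode uses the target value as the per-stamp draw sd.
    jitter_mode: str = "calibrated"  # "calibrated" | "literal"
    seed: int | None = None


# ---------------------------------------------------------------------------
# Benchmark model stages


def antialias_filter(
    rec: GazeRecording,
    target_rate_hz: float,
    cutoff_factor: float = 0.8,
    order: int = 4,
) -> GazeRecording:
    """Zero-phase Butterworth low-pass ahead of downsampling.

    The cutoff is ``cutoff_factor`` x the Nyquist frequency of the
    *target* rate.  Invalid samples are linearly interpolated before
    filtering (the filter needs a gapless series) and re-flagged
    afterwards; timestamps are unchanged.
    """
    if target_rate_hz >= rec.nominal_rate:
        raise ValueError(
            f"target rate {target_rate_hz} Hz must be below source rate "
            f"{rec.nominal_rate} Hz (no upsampling path)"
        )
    cutoff_hz = cutoff_factor * target_rate_hz / 2.0
    sos = sp_signal.butter(order, cutoff_hz, btype="low", fs=rec.nominal_rate, output="sos")

    x = rec.x.copy()
    y = rec.y.copy()
    if not np.all(rec.validity):
        if not np.any(rec.validity):
            raise GazeValidationError(f"{rec.recording_id}: no valid samples to filter")
        t = rec.timestamps
        valid = rec.validity
        x[~valid] = np.interp(t[~valid], t[valid], x[valid])
        y[~valid] = np.interp(t[~valid], t[valid], y[valid])
    x = sp_signal.sosfiltfilt(sos, x)
    y = sp_signal.sosfiltfilt(sos, y)
    return rec.replace(x=x, y=y, validity=rec.validity.copy())


def resample_spline(rec: GazeRecording, new_timestamps_ms: np.ndarray) -> GazeRecording:
    """Resample both channels by first-order (linear) spline interpolation.

    ``new_timestamps_ms`` must be strictly increasing and lie within the
    source time support; a resampled sample is valid only when both of
    its bracketing source samples are valid.
    """
    new_t = np.asarray(new_timestamps_ms, dtype=float)
    if new_t.size >= 2 and not np.all(np.diff(new_t) > 0):
        raise ValueError("new timestamps must be strictly increasing")
    t = rec.timestamps
    if new_t[0] < t[0] - 1e-9 or new_t[-1] > t[-1] + 1e-9:
        raise ValueError(
            f"{rec.recording_id}: resampling grid [{new_t[0]}, {new_t[-1]}] extends "
            f"outside the source support [{t[0]}, {t[-1]}]"
        )
    x = np.interp(new_t, t, rec.x)
    y = np.interp(new_t, t, rec.y)
    valid = np.interp(new_t, t, rec.validity.astype(float)) >= 1.0 - 1e-12
    return GazeRecording(
        timestamps=new_t,
        x=x,
        y=y,
        nominal_rate=rec.nominal_rate,
        recording_id=rec.recording_id,
        validity=valid,
    )


def eccentricity_weight(x_s: np.ndarray, y_s: np.ndarray, model: NoiseModel) -> np.ndarray:
    """Gaussian eccentricity weight alpha(x_s, y_s) in (0, 1].

    alpha = exp(-(r_s - r_max)^2 / (2 sigma_s^2)) with r_s the radial
    gaze position; equals 1 at the screen edge r_s = r_max.  Returns 1
    everywhere when the model has eccentricity weighting disabled.
    """
    x_s = np.asarray(x_s, dtype=float)
    if not model.eccentricity_enabled:
        return np.ones_like(x_s)
    r_s = np.hypot(x_s, np.asarray(y_s, dtype=float))
    return np.exp(-((r_s - model.r_max) ** 2) / (2.0 * model.sigma_s**2))


def add_precision_noise(
    rec: GazeRecording, model: NoiseModel, rng: np.random.Generator
) -> GazeRecording:
    """Add i.i.d. zero-mean Gaussian noise of variance alpha*sigma0^2 per channel."""
    if model.sigma0_sq == 0.0:
        return rec.replace(x=rec.x.copy(), y=rec.y.copy(), validity=rec.validity.copy())
    sd = np.sqrt(model.sigma0_sq * eccentricity_weight(rec.x, rec.y, model))
    x = rec.x + np.where(rec.validity, rng.standard_normal(rec.n_samples) * sd, 0.0)
    y = rec.y + np.where(rec.validity, rng.standard_normal(rec.n_samples) * sd, 0.0)
    return rec.replace(x=x, y=y, validity=rec.validity.copy())


# ---------------------------------------------------------------------------
# Calibration of the noise variance


def required_noise_variance(
    delta_mad_c: float, model: CalibrationModel = DEFAULT_CALIBRATION
) -> float:
    """sigma0^2 needed for a marginal MAD_c degradation, clamped at zero.

    Negative requisite degradations (source already worse than its
    matched target quantile) map to zero: quality cannot be improved by
    adding noise.
    """
    return max(0.0, model.slope * float(delta_mad_c) + model.intercept)


def fit_noise_regression(
    sample_recs: list[tuple[GazeRecording, StimulusTrack]],
    sigma0_sq_grid: np.ndarray,
    target_rate_hz: float = 250.0,
    cutoff_factor: float = 0.8,
    filter_order: int = 4,
    quality_config: QualityConfig = QualityConfig(),
    seed: int | None = None,
) -> CalibrationModel:
    """Fit the linear sigma0^2 <- dMAD_c calibration on sample recordings.

    For each grid value of sigma0^2 the full filter -> resample -> noise
    chain is run on every sample recording and the achieved marginal
    combined-precision degradation dMAD_c (mean degraded MAD_c minus
    mean source MAD_c) is measured with the metric pipeline; ordinary
    least squares of sigma0^2 on dMAD_c yields the coefficients.
    Measuring after the full chain makes the calibration self-consistent
    with the degradation path it will parameterize.
    """
    grid = np.asarray(sigma0_sq_grid, dtype=float)
    if grid.size < 3:
        raise ValueError("need >= 3 sigma0^2 grid points")
    if not sample_recs:
        raise ValueError("need >= 1 sample recording")
    rng = np.random.default_rng(seed)

    source_mad = np.mean(
        [quality_profile(r, s, quality_config).mad_c for r, s in sample_recs]
    )
    achieved = np.empty(grid.size)
    for i, s0 in enumerate(grid):
        model = NoiseModel(sigma0_sq=float(s0))
        mads = []
        for rec, stim in sample_recs:
            out = _filter_resample(rec, target_rate_hz, cutoff_factor, filter_order)
            out = add_precision_noise(out, model, rng)
            mads.append(quality_profile(out, stim, quality_config).mad_c)
        achieved[i] = np.mean(mads) - source_mad
    if np.ptp(achieved) <= 1e-12:
        raise ValueError("degenerate grid: no spread in achieved dMAD_c")
    slope, intercept = np.polyfit(achieved, grid, 1)
    predicted = slope * achieved + intercept
    resid = grid - predicted
    ss_tot = float(np.sum((grid - grid.mean()) ** 2))
    diagnostics = {
        "n_grid": int(grid.size),
        "n_samples": len(sample_recs),
        "residual_sd": float(np.std(resid)),
        "r_squared": 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0,
        "delta_mad_range": (float(achieved.min()), float(achieved.max())),
    }
    return CalibrationModel(
        slope=float(slope), intercept=float(intercept), fit_diagnostics=diagnostics
    )


# ---------------------------------------------------------------------------
# Percentile matching


def percentile_rank(value: float, profile: PercentileProfile) -> float:
    """Empirical percentile rank of ``value`` in a profile, in [0, 1].

    Ranks interpolate linearly between order statistics at plotting
    positions (i - 0.5)/n; values outside the observed range clamp to 0
    or 1.
    """
    values = profile.sorted_values
    if value < values[0]:
        return 0.0
    if value > values[-1]:
        return 1.0
    positions = (np.arange(values.size) + 0.5) / values.size
    return float(np.interp(value, values, positions))


def quantile_lookup(p: float, profile: PercentileProfile) -> float:
    """Value at percentile rank ``p`` — the inverse of :func:`percentile_rank`."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"percentile rank must be in [0, 1], got {p}")
    values = profile.sorted_values
    positions = (np.arange(values.size) + 0.5) / values.size
    return float(np.interp(p, positions, values))


def plan_percentile_degradation(
    source_profiles: list[QualityProfile],
    target_profiles: dict[str, PercentileProfile],
    calibration: CalibrationModel = DEFAULT_CALIBRATION,
    config: PlanConfig = PlanConfig(),
) -> list[DegradationPlan]:
    """Build per-file percentile-matching plans for a source corpus.

    Requires target profiles for ``mad_c``, ``theta_h``, ``theta_v`` and
    ``temporal_precision_ms``.  Each file's MAD_c rank within the source
    corpus selects the matched target MAD_c; the (clamped, non-negative)
    difference parameterizes the additive-noise variance through the
    calibration.  Accuracy deltas are matched per channel the same way.
    The resampling-jitter sd replicates the target corpus' central ISI
    variability (its median temporal precision), divided by sqrt(2) in
    calibrated mode so the measured output ISI sd lands on the target.
    """
    if len(source_profiles) < 2:
        raise ValueError("need >= 2 source files to form a source distribution")
    required = ("mad_c", "theta_h", "theta_v", "temporal_precision_ms")
    missing = [m for m in required if m not in target_profiles]
    if missing:
        raise ValueError(f"missing target percentile profile(s): {missing}")

    from .io import percentile_profile_from_values

    src = {
        m: percentile_profile_from_values([p.metric(m) for p in source_profiles], m)
        for m in ("mad_c", "theta_h", "theta_v")
    }
    target_tp = quantile_lookup(0.5, target_profiles["temporal_precision_ms"])
    jitter_sd = target_tp / np.sqrt(2.0) if config.jitter_mode == "calibrated" else target_tp

    root = np.random.SeedSequence(config.seed)
    seeds = root.generate_state(len(source_profiles)) >> np.uint32(1)

    plans = []
    for i, prof in enumerate(source_profiles):
        p = percentile_rank(prof.mad_c, src["mad_c"])
        delta_mad = max(0.0, quantile_lookup(p, target_profiles["mad_c"]) - prof.mad_c)
        deltas = {}
        for ch in ("theta_h", "theta_v"):
            p_ch = percentile_rank(prof.metric(ch), src[ch])
            deltas[ch] = max(
                0.0, quantile_lookup(p_ch, target_profiles[ch]) - prof.metric(ch)
            )
        plans.append(
            DegradationPlan(
                recording_id=prof.recording_id,
                target_rate_hz=config.target_rate_hz,
                sigma0_sq=required_noise_variance(delta_mad, calibration),
                delta_theta_h=deltas["theta_h"],
                delta_theta_v=deltas["theta_v"],
                percentile=p,
                jitter_sd_ms=float(jitter_sd),
                cutoff_factor=config.cutoff_factor,
                filter_order=config.filter_order,
                accuracy_rel_tol=config.accuracy_rel_tol,
                accuracy_coverage=config.accuracy_coverage,
                seed=int(seeds[i]),
            )
        )
    return plans


def plan_baseline_degradation(
    source_profiles: list[QualityProfile],
    target_profiles: dict[str, PercentileProfile],
    calibration: CalibrationModel = DEFAULT_CALIBRATION,
    config: PlanConfig = PlanConfig(),
) -> list[DegradationPlan]:
    """Central-tendency (benchmark) plans: one sigma0^2 for the whole corpus.

    The requisite marginal degradation is the difference of the target
    and source median MAD_c; no accuracy or timestamp degradation.
    """
    if not source_profiles:
        raise ValueError("need >= 1 source file")
    if "mad_c" not in target_profiles:
        raise ValueError("missing target percentile profile: mad_c")
    src_median = float(np.median([p.mad_c for p in source_profiles]))
    delta_mad = max(0.0, quantile_lookup(0.5, target_profiles["mad_c"]) - src_median)
    sigma0_sq = required_noise_variance(delta_mad, calibration)
    root = np.random.SeedSequence(config.seed)
    seeds = root.generate_state(len(source_profiles)) >> np.uint32(1)
    return [
        DegradationPlan(
            recording_id=prof.recording_id,
            target_rate_hz=config.target_rate_hz,
            sigma0_sq=sigma0_sq,
            cutoff_factor=config.cutoff_factor,
            filter_order=config.filter_order,
            seed=int(seeds[i]),
        )
        for i, prof in enumerate(source_profiles)
    ]


# ---------------------------------------------------------------------------
# Accuracy and timestamp degradation


def draw_fixation_degradations(
    delta_theta: float,
    n: int,
    rng: np.random.Generator,
    rel_tol: float = 0.2,
    coverage: float = 0.9973,
) -> np.ndarray:
    """Per-fixation degradation magnitudes d ~ N(dtheta, (rel_tol*dtheta/z)^2).

    z is the two-sided normal quantile putting ``coverage`` of the draws
    within ``rel_tol`` (relative) of dtheta; the default coverage 0.9973
    gives the 3-sigma rule, i.e. 99.73% of draws within 20% of the
    requisite value at rel_tol=0.2.
    """
    if delta_theta < 0:
        raise ValueError("delta_theta must be >= 0")
    if delta_theta == 0.0:
        return np.zeros(n)
    z = sp_stats.norm.ppf(0.5 + coverage / 2.0)
    sd = rel_tol * delta_theta / z
    return rng.normal(delta_theta, sd, size=n)


def inject_accuracy_offsets(
    rec: GazeRecording,
    windows: list,
    delta_theta_h: float,
    delta_theta_v: float,
    rng: np.random.Generator,
    rel_tol: float = 0.2,
    coverage: float = 0.9973,
    shared_sign: bool = False,
) -> GazeRecording:
    """Add randomized constant offsets to each fixation window.

    Per fixation and channel a magnitude is drawn around the requisite
    marginal accuracy degradation (see
    :func:`draw_fixation_degradations`) and applied with a uniformly
    random +/- sign to every sample of the window; samples outside
    fixation windows are untouched.  With ``shared_sign`` the two
    channels of a fixation share one sign draw.
    """
    if delta_theta_h < 0 or delta_theta_v < 0:
        raise ValueError("accuracy deltas must be >= 0")
    x = rec.x.copy()
    y = rec.y.copy()
    if (delta_theta_h == 0.0 and delta_theta_v == 0.0) or not windows:
        return rec.replace(x=x, y=y, validity=rec.validity.copy())
    n_w = len(windows)
    d_h = draw_fixation_degradations(delta_theta_h, n_w, rng, rel_tol, coverage)
    d_v = draw_fixation_degradations(delta_theta_v, n_w, rng, rel_tol, coverage)
    s_h = rng.choice([-1.0, 1.0], size=n_w)
    s_v = s_h if shared_sign else rng.choice([-1.0, 1.0], size=n_w)
    for k, window in enumerate(windows):
        lo = int(np.searchsorted(rec.timestamps, window.start_ms, side="left"))
        hi = int(np.searchsorted(rec.timestamps, window.end_ms, side="left"))
        x[lo:hi] += s_h[k] * d_h[k]
        y[lo:hi] += s_v[k] * d_v[k]
    return rec.replace(x=x, y=y, validity=rec.validity.copy())


def jitter_timestamps(
    nominal_ms: np.ndarray, jitter_sd_ms: float, rng: np.random.Generator
) -> np.ndarray:
    """Perturb a nominal timestamp grid with i.i.d. zero-mean Gaussian noise.

    The first stamp is left unperturbed.  Draws exceeding 0.45x the
    nominal ISI in magnitude are redrawn (rather than sorted, which
    would distort the jitter distribution's tails) so the output is
    strictly increasing for every seed; ``jitter_sd_ms`` must stay below
    ISI/6 to leave redrawing headroom.
    """
    nominal = np.asarray(nominal_ms, dtype=float)
    if jitter_sd_ms < 0:
        raise ValueError("jitter_sd_ms must be >= 0")
    if jitter_sd_ms == 0.0 or nominal.size < 2:
        return nominal.copy()
    isi = float(np.median(np.diff(nominal)))
    if jitter_sd_ms >= isi / 6.0:
        raise ValueError(
            f"jitter sd {jitter_sd_ms} ms too large for a {isi} ms ISI "
            f"(must be < ISI/6 = {isi / 6.0:.3g} ms)"
        )
    bound = 0.45 * isi
    draws = rng.normal(0.0, jitter_sd_ms, size=nominal.size)
    draws[0] = 0.0
    for _ in range(100):
        bad = np.abs(draws) > bound
        bad[0] = False
        if not np.any(bad):
            break
        draws[bad] = rng.normal(0.0, jitter_sd_ms, size=int(bad.sum()))
    else:  # pragma: no cover - unreachable with sd < ISI/6
        raise RuntimeError("could not enforce timestamp monotonicity")
    return nominal + draws


# ---------------------------------------------------------------------------
# Full transformation


def _filter_resample(
    rec: GazeRecording,
    target_rate_hz: float,
    cutoff_factor: float,
    filter_order: int,
    jitter_sd_ms: float = 0.0,
    rng: np.random.Generator | None = None,
) -> GazeRecording:
    filtered = antialias_filter(rec, target_rate_hz, cutoff_factor, filter_order)
    step = 1000.0 / target_rate_hz
    t0, t1 = filtered.timestamps[0], filtered.timestamps[-1]
    if jitter_sd_ms > 0:
        # keep headroom so jittered stamps stay inside the source support
        grid = np.arange(t0, t1 - 0.5 * step, step)
        grid = jitter_timestamps(grid, jitter_sd_ms, rng)
    else:
        grid = np.arange(t0, t1 + 1e-9, step)
    out = resample_spline(filtered, grid)
    return out.replace(nominal_rate=target_rate_hz)


def degrade(
    rec: GazeRecording,
    stim: StimulusTrack,
    plan: DegradationPlan,
    mode: str = "percentile",
    quality_config: QualityConfig = QualityConfig(),
) -> GazeRecording:
    """Degrade one recording according to a plan.

    ``mode="baseline"``: filter -> resample onto a regular target grid ->
    additive noise (the plan's sigma0^2, normally corpus-level).

    ``mode="percentile"``: filter -> resample onto a jittered grid ->
    additive noise with the per-file sigma0^2 -> per-fixation accuracy
    offsets.  Fixation windows for the offsets come from the same
    shift-based latency alignment used by the metric pipeline, run on
    the degraded signal.  Noise is added after resampling so the
    anti-alias filter cannot attenuate it, keeping the calibration
    between sigma0^2 and achieved dMAD_c valid.
    """
    if mode not in ("baseline", "percentile"):
        raise ValueError(f"unknown degradation mode {mode!r}")
    rng = np.random.default_rng(plan.seed)
    jitter = plan.jitter_sd_ms if mode == "percentile" else 0.0
    out = _filter_resample(
        rec, plan.target_rate_hz, plan.cutoff_factor, plan.filter_order, jitter, rng
    )
    out = add_precision_noise(out, NoiseModel(sigma0_sq=plan.sigma0_sq), rng)
    if mode == "percentile" and (plan.delta_theta_h > 0 or plan.delta_theta_v > 0):
        latency = estimate_saccade_latency(out, stim, quality_config.latency_search_ms)
        windows = extract_fixation_windows(
            stim, latency, quality_config.discard_ms, quality_config.span_ms
        )
        out = inject_accuracy_offsets(
            out,
            windows,
            plan.delta_theta_h,
            plan.delta_theta_v,
            rng,
            plan.accuracy_rel_tol,
            plan.accuracy_coverage,
        )
    return out.replace(recording_id=rec.recording_id)
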