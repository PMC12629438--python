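"""Per-file eye-tracking signal-quality metrics.

The pipeline follows the fixation-based definition of signal quality for
guided-viewing (random saccade) tasks: no algorithmic event detection is
used.  Instead, a single average saccade latency is estimated per file by
shifting the gaze trace against the piecewise-constant target track and
minimizing their Euclidean separation.  Fixation analysis windows are
then carved out of each target dwell — the first 400 ms after the
latency-adjusted fixation start are discarded (to absorb residual
latency variability) and the following 500 ms are analysed.  Within each
window, samples whose distance to the window centroid falls outside
Tukey's fences or beyond 2 dva are removed in a single pass before the
spatial metrics are computed.

Metrics per fixation window (all in dva):

* spatial accuracy  theta_h, theta_v — mean absolute per-channel error
  against the target; theta_c — mean Euclidean error;
* spatial precision MAD_h, MAD_v — median absolute deviation about the
  channel median; MAD_c = sqrt(MAD_h^2 + MAD_v^2).

Per-file values are the arithmetic mean over valid fixation windows.
Temporal precision is file-level: the (population) standard deviation of
the inter-sample interval, in ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import GazeRecording, GazeValidationError, QualityProfile, StimulusTrack

__all__ = [
    "QualityConfig",
    "FixationWindow",
    "LatencyEstimate",
    "estimate_saccade_latency",
    "extract_fixation_windows",
    "remove_outliers",
    "spatial_accuracy",
    "spatial_precision",
    "temporal_precision",
    "quality_profile",
]

logger = logging.getLogger(__name__)

#: MAD of a unit Gaussian = Phi^-1(0.75); handy for tests and calibration.
GAUSSIAN_MAD_FACTOR = 0.6744897501960817


@dataclass(frozen=True)
class QualityConfig:
    """Tunable parameters of the quality-metric pipeline.

    defaults: 400 ms discarded after each latency-adjusted fixation
    start, 500 ms analysed, 2 dva distance-to-centroid cap, latency
    searched over [0, 500) ms in steps of one nominal ISI.
    """

    discard_ms: float = 400.0
    span_ms: float = 500.0
    outlier_cap_dva: float = 2.0
    latency_search_ms: tuple[float, float] = (0.0, 500.0)
    min_window_samples: int = 4


@dataclass
class FixationWindow:
    """One fixation analysis window of a recording."""

    start_ms: float
    end_ms: float
    target_x: float
    target_y: float
    sample_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    n: int = 0  # retained samples after outlier removal

    @property
    def span_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class LatencyEstimate:
    """Per-file average saccade latency from shift-based alignment."""

    latency_ms: float
    objective: float  # summed Euclidean separation at the optimum


def estimate_saccade_latency(
    rec: GazeRecording,
    stim: StimulusTrack,
    search_range_ms: tuple[float, float] = (0.0, 500.0),
    step_ms: float | None = None,
) -> LatencyEstimate:
    """Estimate the per-file saccade latency by shift-based alignment.

    For each candidate latency L on a grid of integer multiples of the
    nominal ISI over ``search_range_ms``, the gaze at time t is compared
    with the target position at t - L, and the candidate minimizing the
    summed Euclidean separation over valid samples is returned.  Ties
    resolve to the smallest latency.
    """
    if step_ms is None:
        step_ms = 1000.0 / rec.nominal_rate
    lo, hi = search_range_ms
    if not hi > lo:
        raise ValueError("empty latency search range")
    k0 = int(np.ceil(lo / step_ms - 1e-12))
    k1 = int(np.floor((hi - 1e-12) / step_ms))
    grid = np.arange(k0, k1 + 1, dtype=float) * step_ms
    if grid.size == 0:
        raise ValueError("latency search grid is empty for this step size")

    valid = rec.validity
    if not np.any(valid):
        raise GazeValidationError(
            f"{rec.recording_id or 'recording'}: no valid samples for latency estimation"
        )
    t = rec.timestamps[valid]
    gx = rec.x[valid]
    gy = rec.y[valid]

    # The objective for a candidate L sums, segment by segment of the
    # L-shifted stimulus, the distances of the samples falling in that
    # segment to its target.  Prefix sums of the per-target distance
    # matrix make each candidate an O(n_segments) gather instead of an
    # O(n_samples) scan.
    n, m = t.size, stim.n_segments
    prefix = np.empty((n + 1, m))
    prefix[0] = 0.0
    np.cumsum(
        np.hypot(gx[:, None] - stim.target_x[None, :], gy[:, None] - stim.target_y[None, :]),
        axis=0,
        out=prefix[1:],
    )
    # segment k of the shifted stimulus covers [trans[k] + L, trans[k+1] + L)
    # (segment 0 also holds before its onset, the last one to the end)
    bounds = np.empty((grid.size, m + 1), dtype=int)
    bounds[:, 0] = 0
    bounds[:, -1] = n
    if m > 1:
        shifted = stim.transition_times[None, 1:] + grid[:, None]
        bounds[:, 1:-1] = np.searchsorted(t, shifted.ravel()).reshape(grid.size, m - 1)
    seg = np.arange(m)
    objective = (prefix[bounds[:, 1:], seg] - prefix[bounds[:, :-1], seg]).sum(axis=1)
    best = int(np.argmin(objective))  # argmin takes the first (smallest) latency
    return LatencyEstimate(latency_ms=float(grid[best]), objective=float(objective[best]))


def extract_fixation_windows(
    stim: StimulusTrack,
    latency: LatencyEstimate | float,
    discard_ms: float = 400.0,
    span_ms: float = 500.0,
    rec: GazeRecording | None = None,
) -> list[FixationWindow]:
    """Carve fixation analysis windows out of each target dwell.

    A window starts ``latency + discard_ms`` after the dwell onset and
    spans ``span_ms``; dwells too short to contain a full window before
    the next target transition are skipped.  When ``rec`` is given each
    window's ``sample_indices`` holds the valid samples inside
    ``[start_ms, end_ms)``.
    """
    lat = latency.latency_ms if isinstance(latency, LatencyEstimate) else float(latency)
    windows: list[FixationWindow] = []
    for dwell_start, dwell_end, tx, ty in stim.dwells():
        start = dwell_start + lat + discard_ms
        end = start + span_ms
        if end > dwell_end + 1e-9:
            logger.debug(
                "skipping dwell at %.0f ms: %.0f ms too short for a %.0f ms window",
                dwell_start,
                dwell_end - dwell_start,
                lat + discard_ms + span_ms,
            )
            continue
        window = FixationWindow(start_ms=start, end_ms=end, target_x=tx, target_y=ty)
        if rec is not None:
            lo = int(np.searchsorted(rec.timestamps, start, side="left"))
            hi = int(np.searchsorted(rec.timestamps, end, side="left"))
            idx = np.arange(lo, hi)
            window.sample_indices = idx[rec.validity[idx]]
            window.n = int(window.sample_indices.size)
        windows.append(window)
    return windows


def remove_outliers(
    x: np.ndarray, y: np.ndarray, cap_dva: float = 2.0
) -> np.ndarray:
    """Single-pass outlier mask for one fixation window.

    Distances to the window centroid (mean of the provided samples) are
    screened against Tukey's fences (quartiles by linear interpolation)
    and against a hard ``cap_dva`` ceiling; returns a boolean keep-mask.
    No re-centering is performed after removal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise GazeValidationError(
            f"outlier screening needs >= 4 samples, got {x.size}"
        )
    d = np.hypot(x - x.mean(), y - y.mean())
    q1, q3 = np.percentile(d, [25.0, 75.0])
    iqr = q3 - q1
    keep = (d >= q1 - 1.5 * iqr) & (d <= q3 + 1.5 * iqr) & (d <= cap_dva)
    return keep


def spatial_accuracy(
    x: np.ndarray, y: np.ndarray, target_x: float, target_y: float
) -> tuple[float, float, float]:
    """(theta_h, theta_v, theta_c): mean absolute and mean Euclidean error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise GazeValidationError("spatial accuracy undefined for empty window")
    ex = x - target_x
    ey = y - target_y
    return (
        float(np.mean(np.abs(ex))),
        float(np.mean(np.abs(ey))),
        float(np.mean(np.hypot(ex, ey))),
    )


def spatial_precision(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(MAD_h, MAD_v, MAD_c): per-channel MAD about the median, RSS combined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise GazeValidationError("spatial precision undefined for empty window")
    mad_h = float(np.median(np.abs(x - np.median(x))))
    mad_v = float(np.median(np.abs(y - np.median(y))))
    return mad_h, mad_v, float(np.hypot(mad_h, mad_v))


def temporal_precision(timestamps_ms: np.ndarray) -> float:
    """Population sd of the inter-sample interval over a whole file, ms.

    Returns NaN for files with fewer than three timestamps, where the
    dispersion of the ISI is undefined.
    """
    timestamps_ms = np.asarray(timestamps_ms, dtype=float)
    if timestamps_ms.size < 3:
        return float("nan")
    return float(np.std(np.diff(timestamps_ms)))


def quality_profile(
    rec: GazeRecording,
    stim: StimulusTrack,
    config: QualityConfig = QualityConfig(),
) -> QualityProfile:
    """Run the full metric pipeline on one recording.

    Raises :class:`GazeValidationError` naming the recording when no
    dwell yields a valid fixation window.
    """
    latency = estimate_saccade_latency(rec, stim, config.latency_search_ms)
    windows = extract_fixation_windows(
        stim, latency, config.discard_ms, config.span_ms, rec=rec
    )
    acc = []
    prec = []
    n_valid = 0
    for window in windows:
        idx = window.sample_indices
        if idx.size < config.min_window_samples:
            continue
        x = rec.x[idx]
        y = rec.y[idx]
        keep = remove_outliers(x, y, config.outlier_cap_dva)
        if keep.sum() < 1:
            continue
        x, y = x[keep], y[keep]
        window.n = int(keep.sum())
        window.sample_indices = idx[keep]
        acc.append(spatial_accuracy(x, y, window.target_x, window.target_y))
        prec.append(spatial_precision(x, y))
        n_valid += 1
    if n_valid == 0:
        raise GazeValidationError(
            f"{rec.recording_id or 'recording'}: no valid fixation windows"
        )
    theta_h, theta_v, theta_c = np.mean(acc, axis=0)
    mad_h, mad_v, _ = np.mean(prec, axis=0)
    return QualityProfile(
        recording_id=rec.recording_id,
        theta_h=float(theta_h),
        theta_v=float(theta_v),
        theta_c=float(theta_c),
        mad_h=float(mad_h),
        mad_v=float(mad_v),
        mad_c=float(np.hypot(mad_h, mad_v)),
        temporal_precision_ms=temporal_precision(rec.timestamps),
        n_valid_fixations=n_valid,
    )
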