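"""Domain types and plain-text I/O for monocular gaze data.

Conventions used throughout the package:

* Gaze coordinates are in degrees of visual angle (dva), screen-centred,
  horizontal positive rightward and vertical positive upward.
* Timestamps are in milliseconds and strictly increasing within a file.
* Missing or untracked samples are kept in place with ``validity=False``
  (never silently dropped) so that temporal precision and resampling see
  the true time axis.

File formats (all comma-separated with a header row):

* Gaze CSV: ``t_ms,x_dva,y_dva`` — one row per sample; empty or
  non-numeric gaze cells mark tracking loss.
* Stimulus CSV: ``t_ms,x_dva,y_dva`` — one row per dwell onset of a
  piecewise-constant target track.
* Quality table CSV: ``recording_id,theta_h,theta_v,theta_c,mad_h,mad_v,
  mad_c,temporal_precision_ms,n_valid_fixations``.
* Percentile profile CSV: long format ``metric,value`` with one row per
  (metric, per-file value) pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GazeFormatError",
    "GazeValidationError",
    "GazeRecording",
    "StimulusTrack",
    "QualityProfile",
    "PercentileProfile",
    "infer_nominal_rate",
    "read_gaze_csv",
    "write_gaze_csv",
    "read_stimulus_csv",
    "write_stimulus_csv",
    "read_quality_table",
    "write_quality_table",
    "percentile_profile_from_values",
    "read_percentile_profiles",
    "write_percentile_profiles",
    "QUALITY_METRIC_NAMES",
]

GAZE_COLUMNS = ("t_ms", "x_dva", "y_dva")

#: Canonical order of the seven per-file signal-quality metrics.
QUALITY_METRIC_NAMES = (
    "theta_h",
    "theta_v",
    "theta_c",
    "mad_h",
    "mad_v",
    "mad_c",
    "temporal_precision_ms",
)


class GazeFormatError(ValueError):
    """A file could not be parsed in the documented text format."""


class GazeValidationError(ValueError):
    """Parsed data violates a domain invariant (e.g. non-monotone time)."""


def infer_nominal_rate(timestamps_ms: np.ndarray) -> float:
    """Nominal sampling rate in Hz as 1 / median inter-sample interval."""
    timestamps_ms = np.asarray(timestamps_ms, dtype=float)
    if timestamps_ms.size < 2:
        raise GazeValidationError("need at least 2 timestamps to infer a rate")
    median_isi = float(np.median(np.diff(timestamps_ms)))
    if median_isi <= 0:
        raise GazeValidationError("non-positive median ISI")
    return 1000.0 / median_isi


@dataclass
class GazeRecording:
    """A timestamped monocular gaze trace.

    Parameters
    ----------
    timestamps:
        Sample times in ms, strictly increasing.
    x, y:
        Horizontal / vertical gaze position in dva. May contain NaN at
        invalid samples.
    nominal_rate:
        Nominal sampling rate in Hz (1000 for an EyeLink-class lab
        tracker, 250 for the VR-headset class of device).
    recording_id:
        Free-form identifier used in error messages and tables.
    validity:
        Boolean per-sample flag; False marks tracking loss. Defaults to
        finiteness of both gaze channels.
    """

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    nominal_rate: float
    recording_id: str = ""
    validity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.timestamps.size
        if self.x.size != n or self.y.size != n:
            raise GazeValidationError(
                f"{self.recording_id or 'recording'}: timestamps, x, y must "
                f"have equal length (got {n}, {self.x.size}, {self.y.size})"
            )
        if n >= 2 and not np.all(np.diff(self.timestamps) > 0):
            bad = int(np.flatnonzero(np.diff(self.timestamps) <= 0)[0]) + 1
            raise GazeValidationError(
                f"{self.recording_id or 'recording'}: timestamps not strictly "
                f"increasing at sample {bad}"
            )
        if not np.all(np.isfinite(self.timestamps)):
            raise GazeValidationError(
                f"{self.recording_id or 'recording'}: non-finite timestamp"
            )
        if not self.nominal_rate > 0:
            raise GazeValidationError("nominal_rate must be positive")
        if self.validity is None:
            self.validity = np.isfinite(self.x) & np.isfinite(self.y)
        else:
            self.validity = np.asarray(self.validity, dtype=bool)
            if self.validity.size != n:
                raise GazeValidationError("validity length mismatch")

    @property
    def n_samples(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration_ms(self) -> float:
        if self.n_samples < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    def isi(self) -> np.ndarray:
        """Successive timestamp differences in ms."""
        return np.diff(self.timestamps)

    def replace(self, **changes) -> "GazeRecording":
        """Return a copy with the given fields replaced."""
        fields = dict(
            timestamps=self.timestamps,
            x=self.x,
            y=self.y,
            nominal_rate=self.nominal_rate,
            recording_id=self.recording_id,
            validity=self.validity,
        )
        fields.update(changes)
        return GazeRecording(**fields)


@dataclass
class StimulusTrack:
    """Piecewise-constant target positions of a random-saccade task.

    ``transition_times[k]`` is the onset of dwell segment *k*; the target
    holds ``(target_x[k], target_y[k])`` until the next onset.  ``end_ms``
    closes the final dwell; when absent it defaults to the last onset plus
    the median of the preceding dwell durations (1000 ms for a
    single-segment track), which is a convention of this package — the
    on-disk format stores onsets only.
    """

    transition_times: np.ndarray
    target_x: np.ndarray
    target_y: np.ndarray
    end_ms: float | None = None
    screen_extent: float | None = None  # r_max, dva

    def __post_init__(self) -> None:
        self.transition_times = np.asarray(self.transition_times, dtype=float)
        self.target_x = np.asarray(self.target_x, dtype=float)
        self.target_y = np.asarray(self.target_y, dtype=float)
        n = self.transition_times.size
        if n == 0:
            raise GazeValidationError("stimulus track must have >= 1 segment")
        if self.target_x.size != n or self.target_y.size != n:
            raise GazeValidationError("one (target_x, target_y) pair per segment required")
        if n >= 2 and not np.all(np.diff(self.transition_times) > 0):
            raise GazeValidationError("transition_times must be strictly increasing")
        if self.end_ms is None:
            if n >= 2:
                self.end_ms = float(
                    self.transition_times[-1] + np.median(np.diff(self.transition_times))
                )
            else:
                self.end_ms = float(self.transition_times[0] + 1000.0)
        if self.end_ms <= self.transition_times[-1]:
            raise GazeValidationError("end_ms must lie after the final transition")

    @property
    def n_segments(self) -> int:
        return int(self.transition_times.size)

    def position_at(self, t_ms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Target position at the given times (held before the first onset)."""
        t_ms = np.asarray(t_ms, dtype=float)
        idx = np.searchsorted(self.transition_times, t_ms, side="right") - 1
        idx = np.clip(idx, 0, self.n_segments - 1)
        return self.target_x[idx], self.target_y[idx]

    def dwells(self) -> Iterator[tuple[float, float, float, float]]:
        """Yield (start_ms, end_ms, target_x, target_y) per dwell segment."""
        bounds = np.append(self.transition_times, self.end_ms)
        for k in range(self.n_segments):
            yield (
                float(bounds[k]),
                float(bounds[k + 1]),
                float(self.target_x[k]),
                float(self.target_y[k]),
            )


@dataclass
class QualityProfile:
    """The seven per-file signal-quality metrics of one recording.

    Spatial accuracy theta (mean absolute error per channel, mean
    Euclidean error combined) and spatial precision MAD (median absolute
    deviation per channel, root-sum-square combined) are in dva; temporal
    precision (sd of the inter-sample interval) is in ms and may be NaN
    for degenerate files with fewer than three samples.
    """

    recording_id: str
    theta_h: float
    theta_v: float
    theta_c: float
    mad_h: float
    mad_v: float
    mad_c: float
    temporal_precision_ms: float
    n_valid_fixations: int = 0

    def __post_init__(self) -> None:
        for name in ("theta_h", "theta_v", "theta_c", "mad_h", "mad_v", "mad_c"):
            value = getattr(self, name)
            if not (value >= 0):
                raise GazeValidationError(
                    f"{self.recording_id}: {name} must be >= 0, got {value}"
                )
        tol = 1e-9 + 1e-6 * max(self.theta_h + self.theta_v, 1.0)
        if self.theta_c > self.theta_h + self.theta_v + tol:
            raise GazeValidationError(
                f"{self.recording_id}: theta_c exceeds theta_h + theta_v"
            )
        rss = math.hypot(self.mad_h, self.mad_v)
        if abs(self.mad_c - rss) > 1e-9 + 1e-6 * max(rss, 1.0):
            raise GazeValidationError(
                f"{self.recording_id}: mad_c must equal hypot(mad_h, mad_v)"
            )

    def metric(self, name: str) -> float:
        if name not in QUALITY_METRIC_NAMES:
            raise KeyError(f"unknown quality metric {name!r}")
        return float(getattr(self, name))

    def as_vector(self, metrics: Sequence[str] = QUALITY_METRIC_NAMES) -> np.ndarray:
        return np.array([self.metric(m) for m in metrics], dtype=float)


@dataclass
class PercentileProfile:
    """Empirical across-file distribution of one quality metric.

    Stores the sorted per-file values of a metric over a corpus; supports
    rank <-> value lookups used by the percentile-matching degradation
    (see :mod:`gazedegrade.degrade`).
    """

    metric_name: str
    sorted_values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.sorted_values, dtype=float)
        if values.size < 2:
            raise GazeValidationError(
                f"percentile profile {self.metric_name!r} needs >= 2 values"
            )
        if not np.all(np.isfinite(values)):
            raise GazeValidationError(
                f"percentile profile {self.metric_name!r} has non-finite values"
            )
        if np.any(np.diff(values) < 0):
            raise GazeValidationError("sorted_values must be ascending")
        self.sorted_values = values

    @property
    def n(self) -> int:
        return int(self.sorted_values.size)


def percentile_profile_from_values(
    values: Iterable[float], metric_name: str
) -> PercentileProfile:
    """Build a :class:`PercentileProfile` from unordered per-file values.

    Non-finite entries are dropped; at least two finite values are
    required for a meaningful empirical distribution.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise GazeValidationError(
            f"need >= 2 finite values for profile {metric_name!r}, got {arr.size}"
        )
    return PercentileProfile(metric_name=metric_name, sorted_values=np.sort(arr))


# ---------------------------------------------------------------------------
# Gaze and stimulus CSV


def read_gaze_csv(
    path: str | Path,
    recording_id: str | None = None,
    nominal_rate: float | None = None,
) -> GazeRecording:
    """Read a gaze CSV (``t_ms,x_dva,y_dva``).

    Rows whose gaze cells are empty or non-numeric become samples with
    ``validity=False``; a row whose *timestamp* does not parse, or
    timestamps that are not strictly increasing, raise with the
    offending line number. ``nominal_rate`` is inferred from the median
    ISI when not given.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GazeFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in GAZE_COLUMNS if c not in frame.columns]
    if missing:
        raise GazeFormatError(f"{path}: missing column(s) {missing}")

    t = pd.to_numeric(frame["t_ms"], errors="coerce").to_numpy(dtype=float)
    bad_t = np.flatnonzero(~np.isfinite(t))
    if bad_t.size:
        # +2: one for the header line, one for 1-based numbering
        raise GazeFormatError(f"{path}: malformed timestamp on line {bad_t[0] + 2}")
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        # sample i sits on line i + 2 (header + 1-based numbering)
        bad_line = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 3
        raise GazeValidationError(
            f"{path}: timestamps not strictly increasing at line {bad_line}"
        )

    x = pd.to_numeric(frame["x_dva"], errors="coerce").to_numpy(dtype=float)
    y = pd.to_numeric(frame["y_dva"], errors="coerce").to_numpy(dtype=float)
    if nominal_rate is None:
        nominal_rate = infer_nominal_rate(t)
    return GazeRecording(
        timestamps=t,
        x=x,
        y=y,
        nominal_rate=nominal_rate,
        recording_id=recording_id if recording_id is not None else path.stem,
    )


def write_gaze_csv(rec: GazeRecording, path: str | Path) -> Path:
    """Write a recording to gaze CSV; invalid samples serialize as empty cells."""
    path = Path(path)
    x = np.where(rec.validity, rec.x, np.nan)
    y = np.where(rec.validity, rec.y, np.nan)
    frame = pd.DataFrame({"t_ms": rec.timestamps, "x_dva": x, "y_dva": y})
    frame.to_csv(path, index=False, float_format="%.9g")
    return path


def read_stimulus_csv(path: str | Path, screen_extent: float | None = None) -> StimulusTrack:
    """Read a stimulus CSV with one row per dwell onset."""
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in GAZE_COLUMNS if c not in frame.columns]
    if missing:
        raise GazeFormatError(f"{path}: missing column(s) {missing}")
    return StimulusTrack(
        transition_times=frame["t_ms"].to_numpy(dtype=float),
        target_x=frame["x_dva"].to_numpy(dtype=float),
        target_y=frame["y_dva"].to_numpy(dtype=float),
        screen_extent=screen_extent,
    )


def write_stimulus_csv(stim: StimulusTrack, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        {"t_ms": stim.transition_times, "x_dva": stim.target_x, "y_dva": stim.target_y}
    )
    frame.to_csv(path, index=False, float_format="%.9g")
    return path


# ---------------------------------------------------------------------------
# Quality tables and percentile profiles


def write_quality_table(profiles: Sequence[QualityProfile], path: str | Path) -> Path:
    """Write one row per recording; NaN temporal precision serializes as ``NA``."""
    if not profiles:
        raise GazeValidationError("cannot write an empty quality table")
    path = Path(path)
    rows = [
        {
            "recording_id": p.recording_id,
            **{m: p.metric(m) for m in QUALITY_METRIC_NAMES},
            "n_valid_fixations": p.n_valid_fixations,
        }
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, index=False, na_rep="NA", float_format="%.9g")
    return path


def read_quality_table(path: str | Path) -> list[QualityProfile]:
    path = Path(path)
    frame = pd.read_csv(path, na_values=["NA"])
    required = {"recording_id", *QUALITY_METRIC_NAMES, "n_valid_fixations"}
    missing = required - set(frame.columns)
    if missing:
        raise GazeFormatError(f"{path}: missing column(s) {sorted(missing)}")
    profiles = []
    for row in frame.itertuples(index=False):
        profiles.append(
            QualityProfile(
                recording_id=str(row.recording_id),
                theta_h=float(row.theta_h),
                theta_v=float(row.theta_v),
                theta_c=float(row.theta_c),
                mad_h=float(row.mad_h),
                mad_v=float(row.mad_v),
                mad_c=float(row.mad_c),
                temporal_precision_ms=float(row.temporal_precision_ms),
                n_valid_fixations=int(row.n_valid_fixations),
            )
        )
    return profiles


def write_percentile_profiles(
    profiles: Mapping[str, PercentileProfile], path: str | Path
) -> Path:
    """Write a set of percentile profiles in long ``metric,value`` format."""
    if not profiles:
        raise GazeValidationError("cannot write an empty profile set")
    path = Path(path)
    rows = [
        {"metric": name, "value": float(v)}
        for name, profile in profiles.items()
        for v in profile.sorted_values
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")
    return path


def read_percentile_profiles(path: str | Path) -> dict[str, PercentileProfile]:
    path = Path(path)
    frame = pd.read_csv(path)
    if not {"metric", "value"} <= set(frame.columns):
        raise GazeFormatError(f"{path}: expected columns metric,value")
    out: dict[str, PercentileProfile] = {}
    for name, group in frame.groupby("metric", sort=False):
        out[str(name)] = percentile_profile_from_values(
            group["value"].to_numpy(dtype=float), str(name)
        )
    return out


def profiles_from_quality_table(
    profiles: Sequence[QualityProfile],
    metrics: Sequence[str] = QUALITY_METRIC_NAMES,
) -> dict[str, PercentileProfile]:
    """Collapse per-recording quality profiles into per-metric percentile profiles."""
    return {
        m: percentile_profile_from_values([p.metric(m) for p in profiles], m)
        for m in metrics
    }
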