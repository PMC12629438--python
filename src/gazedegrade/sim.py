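"""Synthetic random-saccade-task corpora with controllable signal quality.

The simulator emulates the guided-viewing regime the metric pipeline is
built for: a target jumps between uniformly placed screen positions,
dwelling 1000 ms (fixed) or 1000-1500 ms (uniform) per position; the eye
follows after a saccade latency of about 200 ms.  Saccades are modelled
as 30 ms linear ramps centred on the latency-adjusted transition — the
quality metrics only ever look at fixation samples well after saccade
onset, so oculomotor dynamics (main sequence, overshoot) are deliberately
out of scope, and the centred ramp keeps the shift-based latency
estimator's optimum at the planted latency.

Per recording, signal quality is controlled by three knobs mirroring the
quality metrics themselves: an accuracy bias (constant per-channel
offset, dva), a fixation noise sd (i.i.d. per-channel Gaussian, dva) and
a timestamp jitter sd (Gaussian perturbation of the nominal sampling
grid, ms).  Across a corpus these are drawn per file from configurable
distributions — lognormal for the noise sd (strictly positive,
right-skewed, like empirical across-file precision distributions) and
Gaussian for the bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .degrade import jitter_timestamps
from .io import GazeRecording, StimulusTrack

__all__ = [
    "ParamDist",
    "SimQualitySpec",
    "CorpusSpec",
    "simulate_stimulus",
    "simulate_recording",
    "simulate_corpus",
]

SACCADE_RAMP_MS = 30.0


@dataclass(frozen=True)
class ParamDist:
    """A named scalar distribution for per-file quality parameters.

    Families: ``constant`` (value), ``normal`` (mean, sd), ``lognormal``
    (median, sigma_log — the sd of log-values), ``uniform`` (low, high).
    """

    family: str
    params: tuple[float, ...]

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "constant":
            return float(self.params[0])
        if self.family == "normal":
            mean, sd = self.params
            return float(rng.normal(mean, sd))
        if self.family == "lognormal":
            median, sigma_log = self.params
            return float(rng.lognormal(np.log(median), sigma_log))
        if self.family == "uniform":
            low, high = self.params
            return float(rng.uniform(low, high))
        raise ValueError(f"unknown distribution family {self.family!r}")


@dataclass(frozen=True)
class SimQualitySpec:
    """Signal-quality knobs of one simulated recording."""

    fixation_noise_sd: float = 0.05  # dva, per channel
    accuracy_bias: tuple[float, float] = (0.0, 0.0)  # dva, (horizontal, vertical)
    latency_ms: float = 200.0
    rate_hz: float = 1000.0
    isi_jitter_sd_ms: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.fixation_noise_sd < 0 or self.isi_jitter_sd_ms < 0:
            raise ValueError("dispersions must be >= 0")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")


@dataclass(frozen=True)
class CorpusSpec:
    """Across-file description of a simulated corpus.

    ``dwell_ms`` is either a fixed duration or a (min, max) uniform
    range; defaults mirror the two random-saccade regimes of interest
    (1000 ms fixed for the lab device, 1000-1500 ms uniform for the VR
    one).  Per-file quality parameters are drawn from ``noise_sd_dist``
    (noise sd, dva), ``bias_dist`` (per-channel bias, dva) and
    ``jitter_sd_dist`` (timestamp jitter sd, ms).
    """

    n_files: int = 10
    dwell_ms: float | tuple[float, float] = (1000.0, 1500.0)
    n_targets: int = 10
    amplitude_dva: float = 15.0
    rate_hz: float = 1000.0
    latency_ms: float = 200.0
    noise_sd_dist: ParamDist = ParamDist("lognormal", (0.1, 0.35))
    bias_dist: ParamDist = ParamDist("normal", (0.0, 0.2))
    jitter_sd_dist: ParamDist = ParamDist("constant", (0.0,))
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_files < 1 or self.n_targets < 1:
            raise ValueError("n_files and n_targets must be >= 1")
        if isinstance(self.dwell_ms, tuple):
            lo, hi = self.dwell_ms
            if not 0 < lo <= hi:
                raise ValueError("dwell range must satisfy 0 < min <= max")
        elif not self.dwell_ms > 0:
            raise ValueError("dwell duration must be positive")


def simulate_stimulus(
    n_targets: int,
    dwell_ms: float | tuple[float, float],
    amplitude_dva: float,
    rng: np.random.Generator,
    start_ms: float = 0.0,
) -> StimulusTrack:
    """Draw a random-saccade stimulus track.

    Target positions are uniform on the square [-amplitude, amplitude]^2;
    dwell durations are fixed or uniform on the given range.  The first
    dwell starts at ``start_ms``.
    """
    if isinstance(dwell_ms, tuple):
        durations = rng.uniform(dwell_ms[0], dwell_ms[1], size=n_targets)
    else:
        durations = np.full(n_targets, float(dwell_ms))
    onsets = start_ms + np.concatenate([[0.0], np.cumsum(durations[:-1])])
    return StimulusTrack(
        transition_times=onsets,
        target_x=rng.uniform(-amplitude_dva, amplitude_dva, size=n_targets),
        target_y=rng.uniform(-amplitude_dva, amplitude_dva, size=n_targets),
        end_ms=float(start_ms + durations.sum()),
        screen_extent=float(amplitude_dva * np.sqrt(2.0)),
    )


def _latency_adjusted_position(
    t_ms: np.ndarray, stim: StimulusTrack, latency_ms: float, ramp_ms: float
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless eye position: target delayed by latency, centred linear ramps."""
    u = np.asarray(t_ms, dtype=float) - latency_ms
    trans = stim.transition_times
    idx = np.clip(np.searchsorted(trans, u, side="right") - 1, 0, stim.n_segments - 1)
    x = stim.target_x[idx].copy()
    y = stim.target_y[idx].copy()
    half = ramp_ms / 2.0

    # second ramp half: just entered segment idx (>0), blending from idx-1
    since = u - trans[idx]
    entering = (idx > 0) & (since < half) & (u >= trans[0])
    frac = 0.5 + since[entering] / ramp_ms
    prev = idx[entering] - 1
    x[entering] = stim.target_x[prev] + frac * (stim.target_x[idx[entering]] - stim.target_x[prev])
    y[entering] = stim.target_y[prev] + frac * (stim.target_y[idx[entering]] - stim.target_y[prev])

    # first ramp half: about to leave segment idx for idx+1
    nxt = idx + 1
    has_next = nxt < stim.n_segments
    until = np.where(has_next, trans[np.minimum(nxt, stim.n_segments - 1)] - u, np.inf)
    leaving = has_next & (until <= half) & ~entering
    frac = 0.5 - until[leaving] / ramp_ms
    cur = idx[leaving]
    x[leaving] = stim.target_x[cur] + frac * (stim.target_x[cur + 1] - stim.target_x[cur])
    y[leaving] = stim.target_y[cur] + frac * (stim.target_y[cur + 1] - stim.target_y[cur])
    return x, y


def simulate_recording(
    stim: StimulusTrack,
    quality: SimQualitySpec,
    rng: np.random.Generator | None = None,
    recording_id: str = "sim",
) -> GazeRecording:
    """Synthesize one gaze recording following a stimulus track.

    gaze = latency-delayed target (30 ms centred linear ramps at
    transitions) + constant per-channel accuracy bias + i.i.d. Gaussian
    fixation noise; timestamps = nominal grid at ``rate_hz``, optionally
    jittered (first stamp fixed, strict monotonicity enforced).
    """
    if rng is None:
        rng = np.random.default_rng(quality.seed)
    step = 1000.0 / quality.rate_hz
    t = np.arange(stim.transition_times[0], stim.end_ms, step)
    if quality.isi_jitter_sd_ms > 0:
        t = jitter_timestamps(t, quality.isi_jitter_sd_ms, rng)
    x, y = _latency_adjusted_position(t, stim, quality.latency_ms, SACCADE_RAMP_MS)
    x = x + quality.accuracy_bias[0]
    y = y + quality.accuracy_bias[1]
    if quality.fixation_noise_sd > 0:
        x = x + rng.normal(0.0, quality.fixation_noise_sd, size=t.size)
        y = y + rng.normal(0.0, quality.fixation_noise_sd, size=t.size)
    return GazeRecording(
        timestamps=t,
        x=x,
        y=y,
        nominal_rate=quality.rate_hz,
        recording_id=recording_id,
        validity=np.ones(t.size, dtype=bool),
    )


def simulate_corpus(spec: CorpusSpec) -> list[tuple[GazeRecording, StimulusTrack]]:
    """Simulate a corpus of (recording, stimulus) pairs.

    One root seed spawns an independent child stream per file, so the
    corpus is reproducible and editing the draws of file k leaves every
    other file unchanged.
    """
    root = np.random.SeedSequence(spec.seed)
    pairs: list[tuple[GazeRecording, StimulusTrack]] = []
    for k, child in enumerate(root.spawn(spec.n_files)):
        rng = np.random.default_rng(child)
        stim = simulate_stimulus(spec.n_targets, spec.dwell_ms, spec.amplitude_dva, rng)
        quality = SimQualitySpec(
            fixation_noise_sd=max(0.0, spec.noise_sd_dist.sample(rng)),
            accuracy_bias=(spec.bias_dist.sample(rng), spec.bias_dist.sample(rng)),
            latency_ms=spec.latency_ms,
            rate_hz=spec.rate_hz,
            isi_jitter_sd_ms=max(0.0, spec.jitter_sd_dist.sample(rng)),
        )
        rec = simulate_recording(stim, quality, rng, recording_id=f"sim_{k:04d}")
        pairs.append((rec, stim))
    return pairs
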