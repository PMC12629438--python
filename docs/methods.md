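# Methods

This note records the models implemented by `gazedegrade`, the numerical
conventions chosen where the underlying procedures are genuinely open,
and what the synthetic study corpora do and do not establish.

## Quality-metric pipeline

Signal quality of a random-saccade recording is summarized by seven
per-file numbers: spatial accuracy θh, θv (mean absolute per-channel
error against the target, dva) and θc (mean Euclidean error); spatial
precision MADh, MADv (median absolute deviation about the channel
median) and MADc = √(MADh² + MADv²); and temporal precision (sd of the
inter-sample interval, ms, over the whole file). The combined precision
satisfies MADc² = MADh² + MADv² by definition, and θc obeys
max(θh, θv) ≤ θc ≤ θh + θv per window; both are enforced as invariants.

Fixation intervals are located without event detection. A single average
saccade latency per file is estimated by shifting the gaze trace against
the piecewise-constant target track and minimizing the summed Euclidean
separation; the search grid runs over 0–500 ms in steps of one nominal
ISI (the procedure itself fixes no range; 0–500 ms covers human saccade
latencies with margin), ties resolving to the smallest latency. The
implementation evaluates the objective through per-target-segment prefix
sums, which is algebraically identical to the direct per-candidate scan
(a brute-force oracle test pins this down) but O(n·segments) instead of
O(n·candidates).

Each target dwell then contributes one analysis window: start = dwell
onset + latency + 400 ms, span 500 ms; windows that would cross the next
target transition are skipped, so dwells shorter than latency + 900 ms
yield no window. Within a window, samples whose distance to the window
centroid (mean of valid samples) lies outside Tukey's fences
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] or beyond 2 dva are removed in one pass —
no re-centering or iteration, so the screening cannot cascade. Quartiles
use linear interpolation. Windows with fewer than 4 valid samples are
dropped. Per-file spatial metrics are arithmetic means over valid
windows (the aggregator is a package convention); file-level MADc is the
root-sum-square of the mean per-channel MADs so the Eq-identity holds at
file level too.

## Degradation models

**Benchmark model.** Bandwidth reduction: zero-phase (forward–backward)
Butterworth low-pass, order 4 (configurable; the order is a package
default), cutoff 0.8× the Nyquist frequency of the target rate;
tracking-loss gaps are linearly interpolated before filtering and
re-flagged after. Resampling: first-order spline (linear interpolation)
onto a regular grid at the target rate. Precision degradation: additive
white Gaussian noise of variance σ² per channel; an optional Gaussian
eccentricity weight α = exp(−(r_s − r_max)²/(2σ_s²)) can scale the
variance toward the screen edge but is disabled by default (flat noise
field). One corpus-level σ₀², chosen from the difference of target and
source median MADc, is applied to every file — which is exactly why the
model reproduces only the target's central tendency.

**Calibration.** The map from a requisite marginal degradation ΔMADc to
σ₀² is linear: σ₀² = slope·ΔMADc + intercept, with packaged defaults
(1.2904, 0.0356) appropriate to a 1000 Hz→250 Hz device pairing. Because
these constants are pairing-specific, refitting is first-class:
`fit_noise_regression` runs the full filter→resample→noise chain on
sample recordings over a σ₀² grid, measures the achieved ΔMADc with the
metric pipeline, and fits OLS of σ₀² on ΔMADc. Measuring *after* the
full chain makes the calibration self-consistent with the degradation
path (the filter/resample stage itself reduces the source MAD, and the
noise is injected after it). The true σ₀²↔ΔMADc relation is convex
(MADs add in quadrature), so a linear fit is a chord approximation; the
calibration grid should span the operating range of requisite
degradations — the default grid (0.05–0.65 dva²) does so for the
default study regimes, and diagnostics (R², residual sd, achieved ΔMAD
range) are returned with the model.

**Percentile matching.** Per file, the rank p of MADc within the source
corpus is computed by linear interpolation between order statistics at
plotting positions (i − 0.5)/n, clamping outside the observed range;
the value at rank p in the target profile (same convention, exact
inverse) minus the file's MADc is the requisite ΔMADc, clamped at zero
(degradation can only add noise, never improve a file). σ₀² follows from
the calibration. Accuracy is matched analogously per channel (θh, θv
separately); each fixation window then receives an offset drawn from
N(Δθ, (0.2·Δθ/z)²) with z the two-sided normal quantile putting 99.73%
of draws within 20% of Δθ (z = 3 at the default coverage), applied with
an independent uniform ± sign per channel (a shared-sign option exists;
the underlying procedure is ambiguous on this point). Windows come from
the same shift-based latency alignment as the metrics, run on the
degraded signal.

**Temporal precision.** The resampling grid's stamps are perturbed with
i.i.d. zero-mean Gaussian noise; draws beyond ±0.45·ISI are redrawn
(sorting would distort the tails) so the grid stays strictly increasing,
and the first stamp is fixed. Perturbing each stamp with sd σ yields a
*measured* ISI sd of √2·σ (variance of a difference of independent
terms), so the default "calibrated" mode divides the target temporal
precision by √2 before drawing — matching the intent of replicating the
observed ISI variation; a "literal" mode uses the target value directly
as the draw sd and overshoots the measured ISI sd by √2 by construction.

**Stage order** is filter → (jittered) resample → precision noise →
accuracy offsets. Injecting noise after resampling prevents the
anti-alias filter from attenuating it, which would invalidate the
calibration; accuracy offsets are constant within a window and unharmed
by any earlier stage.

## Evaluation machinery

The 1-NN two-sample test classifies each pooled quality-feature vector
by its nearest Euclidean neighbour excluding itself; 50% combined
accuracy means real and synthetic sets are indistinguishable at this
granularity. The larger class is subsampled to the smaller per repeat
(5 repeats by default; median ± range reported). Features are z-scored
on the pooled subsample by default — without scaling, the metric with
the largest units dominates the distance; a flag disables it. Distance
ties resolve to the smallest index, making results seed-deterministic.

Biometric score metrics operate on genuine/impostor similarity scores
oriented "higher = more similar": d′ uses sample sds in the decidability
form |μ_g − μ_i|/√((σ_g² + σ_i²)/2); the ROC is swept over all distinct
scores with FAR = P(impostor ≥ τ) and FRR = P(genuine < τ); EER is
linearly interpolated between the bracketing operating points; FRR@FAR
interpolates FRR as a function of FAR, taking the smallest FRR at tied
FAR values, and flags extrapolation when the impostor set is smaller
than 1/FAR-level. No convex-hull ROC smoothing is applied.

## Simulator and study conditions

The simulator emulates the random-saccade regime the metrics require:
targets uniform on ±15 dva, dwelling 1000 ms fixed or uniform
1000–1500 ms per position, gaze following with a 200 ms latency.
Saccades are 30 ms linear ramps centred on the latency-adjusted
transition; since analysis windows start 400 ms after fixation onset,
saccade shape is immaterial to the metrics, and centring keeps the
shift-based latency estimator's optimum at the planted value. Fixation
noise is white Gaussian per channel (recovered by the metrics as
MAD = Φ⁻¹(0.75)·σ ≈ 0.6745σ per channel, 0.9539σ combined); accuracy
bias is constant per recording; clock jitter reuses the same truncated
Gaussian mechanism as the degradation stage. Per-file parameters are
drawn from lognormal (noise sd — strictly positive and right-skewed,
like empirical across-file precision distributions) and Gaussian (bias)
families; one root seed spawns independent per-file streams.

Default study conditions: a 1000 Hz source corpus with per-file noise
sd ~ lognormal(median 0.1 dva, σ_log 0.35) and bias ~ N(0, 0.2 dva) —
lab-tracker grade; a 250 Hz target regime with MADc ~ lognormal(median
0.4 dva, σ_log 0.3), per-channel accuracy ~ |N(0, 0.6 dva)| and temporal
precision ≈ 0.5 ms — VR-headset grade. Synthetic experiments use corpora
of 300 files with 10 targets per file (tests) or 200 files (the demo
end-to-end configuration); these sizes give stable per-file metric
estimates (≈8 valid windows of ≈125–500 samples each) while keeping any
experiment within minutes on one CPU.

Because dwells must exceed latency + 900 ms to yield a window, corpora
meant for metric computation use the 1000–1500 ms uniform dwell rule
(≈80% of dwells yield windows); a fixed 1000 ms dwell with a 200 ms
latency yields none under the strict no-boundary-crossing rule.

What the simulator does *not* model — microsaccades, drift, tremor
spectra, blinks, main-sequence saccade dynamics, eccentricity-dependent
precision, binocular effects, non-Gaussian or temporally correlated
instrument noise. Consequently, passing tests establish that the
machinery is self-consistent (planted quantities are recovered, the
percentile map preserves ranks and reproduces a target distribution far
better than central-tendency matching) — not that degraded recordings
are indistinguishable from any particular real device, which additionally
depends on all the unmodelled structure above.

## Degenerate inputs and numerical conventions

Timestamps must be strictly increasing; missing samples are kept with
`validity=False` and excluded from all window computations, so the time
axis seen by temporal precision and resampling is the true one.
Temporal precision is NaN below 3 timestamps (serialized as `NA`).
Percentile profiles require ≥ 2 finite values; constant profiles are
valid and map every rank to the constant. `required_noise_variance`
clamps at zero. The jitter sd must stay below ISI/6, leaving redraw
headroom; the resampling grid keeps half an ISI of margin at the file
end so jittered stamps never leave the source support. Outlier screening
needs ≥ 4 valid samples (quartiles undefined below). The latency
objective's ties — e.g. a constant stimulus, where it is flat — resolve
to the smallest grid latency.

## Known limitations

The linear calibration is a chord of a convex relation, so
percentile-matched corpora land slightly above the target quantile at
mid-range ΔMADc (visible as a small positive median offset in the
distribution-matching tests); a quadratic calibration would reduce this
but is not part of the implemented procedure. Accuracy injection
perturbs whole windows only — inter-fixation samples keep source-level
accuracy. The 1-NN test with equal class sizes performs no subsampling,
so its repeats coincide; variability then reflects only the draw of the
feature sets themselves.
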