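"""Application-agnostic realism assessment: leave-one-out 1-NN two-sample test.

Real and synthetic recordings are represented by their signal-quality
feature vectors (by default all seven metrics).  The pooled points are
classified by the label of their nearest Euclidean neighbour, excluding
the query point itself.  If the synthetic set is indistinguishable from
the real one, the classifier cannot beat chance and the combined
accuracy sits at 50%; accuracies near 100% expose synthetic data living
in its own region of quality space.

Because the test needs equally sized classes, the larger class is
randomly subsampled to match the smaller one, and the procedure is
repeated (five times by default) to expose the sampling variability;
results are summarized as median and range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["TwoSampleResult", "one_nn_two_sample", "summarize_repeats"]


@dataclass(frozen=True)
class TwoSampleResult:
    """Accuracies of one leave-one-out 1-NN two-sample repeat."""

    combined_accuracy: float
    real_accuracy: float
    synthetic_accuracy: float
    n_per_class: int
    repeat_index: int


def _check_features(name: str, mat: np.ndarray, ids: Sequence[str] | None) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2:
        raise ValueError(f"{name} feature matrix must be 2-D")
    bad = np.flatnonzero(~np.isfinite(mat).all(axis=1))
    if bad.size:
        label = ids[bad[0]] if ids is not None else f"row {bad[0]}"
        raise ValueError(f"non-finite features in {name} set ({label})")
    return mat


def one_nn_two_sample(
    real: np.ndarray,
    synthetic: np.ndarray,
    n_repeats: int = 5,
    seed: int | None = None,
    standardize: bool = True,
    real_ids: Sequence[str] | None = None,
    synthetic_ids: Sequence[str] | None = None,
) -> list[TwoSampleResult]:
    """Run the leave-one-out 1-NN two-sample test.

    Per repeat, the larger class is subsampled without replacement to
    the smaller class' size, features are z-scored on the pooled
    subsample (so no metric dominates the Euclidean distance through its
    units; disable with ``standardize=False``), and every point is
    classified by its nearest other point.  Distance ties resolve to the
    smallest pooled index, so results are deterministic given the seed.
    """
    real = _check_features("real", real, real_ids)
    synthetic = _check_features("synthetic", synthetic, synthetic_ids)
    if real.shape[1] != synthetic.shape[1]:
        raise ValueError("real and synthetic feature dimensionality differ")
    if min(real.shape[0], synthetic.shape[0]) < 10:
        raise ValueError("need >= 10 recordings per class")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")

    rng = np.random.default_rng(seed)
    n = min(real.shape[0], synthetic.shape[0])
    results = []
    for repeat in range(n_repeats):
        r = real[rng.choice(real.shape[0], size=n, replace=False)] if real.shape[0] > n else real
        s = (
            synthetic[rng.choice(synthetic.shape[0], size=n, replace=False)]
            if synthetic.shape[0] > n
            else synthetic
        )
        pooled = np.vstack([r, s])
        labels = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
        if standardize:
            sd = pooled.std(axis=0)
            sd[sd == 0] = 1.0
            pooled = (pooled - pooled.mean(axis=0)) / sd
        dist = cdist(pooled, pooled)
        np.fill_diagonal(dist, np.inf)
        nearest = np.argmin(dist, axis=1)  # ties -> smallest index
        correct = labels[nearest] == labels
        results.append(
            TwoSampleResult(
                combined_accuracy=float(correct.mean()),
                real_accuracy=float(correct[labels == 0].mean()),
                synthetic_accuracy=float(correct[labels == 1].mean()),
                n_per_class=n,
                repeat_index=repeat,
            )
        )
    return results


def summarize_repeats(results: Sequence[TwoSampleResult]) -> dict[str, dict[str, float]]:
    """Median and range (max - min) per accuracy type across repeats."""
    if not results:
        raise ValueError("need >= 1 result")
    out: dict[str, dict[str, float]] = {}
    for name in ("combined_accuracy", "real_accuracy", "synthetic_accuracy"):
        values = np.array([getattr(r, name) for r in results], dtype=float)
        out[name] = {
            "median": float(np.median(values)),
            "range": float(values.max() - values.min()),
        }
    return out
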