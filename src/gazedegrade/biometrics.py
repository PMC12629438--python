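"""Score-level biometric verification metrics.

Operates on similarity scores of embedding pairs: genuine scores come
from same-subject pairs, impostor scores from different-subject pairs.
Scores are oriented "higher = more similar" (e.g. cosine similarity);
a verification attempt is accepted when its score reaches a threshold.

Metrics:

* d-prime (decidability index): |mu_g - mu_i| / sqrt((s_g^2 + s_i^2)/2),
  the separation of the two score distributions in pooled-sd units;
* ROC: false acceptance rate (FAR, impostor scores at or above the
  threshold) against false rejection rate (FRR, genuine scores below);
* EER: the operating point where FAR = FRR (0% ideal, 50% chance);
* FRR at a fixed FAR — by default 1-in-10000, the security level of a
  4-digit PIN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "BiometricScoreSet",
    "BiometricMetrics",
    "FrrAtFar",
    "d_prime",
    "roc_points",
    "eer",
    "frr_at_far",
    "biometric_metrics",
]


@dataclass(frozen=True)
class BiometricScoreSet:
    """Genuine (same-subject) and impostor (different-subject) scores."""

    genuine: np.ndarray
    impostor: np.ndarray

    def __post_init__(self) -> None:
        for name in ("genuine", "impostor"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size == 0:
                raise ValueError(f"{name} score set must be non-empty")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} scores contain non-finite values")
            object.__setattr__(self, name, arr)


class FrrAtFar(NamedTuple):
    frr_pct: float
    extrapolated: bool  # too few impostor scores to resolve the FAR level


@dataclass(frozen=True)
class BiometricMetrics:
    """Summary metrics of one genuine/impostor score set."""

    d_prime: float
    eer_pct: float
    frr_at_far_pct: float
    far_level: float
    frr_extrapolated: bool


def d_prime(scores: BiometricScoreSet) -> float:
    """Decidability index |mu_g - mu_i| / sqrt((s_g^2 + s_i^2) / 2).

    Uses sample standard deviations.  Identical degenerate distributions
    give 0; zero pooled variance with distinct means is flagged as an
    error (infinite separation).
    """
    g, i = scores.genuine, scores.impostor
    if g.size < 2 or i.size < 2:
        raise ValueError("d-prime needs >= 2 scores per class")
    pooled = (g.std(ddof=1) ** 2 + i.std(ddof=1) ** 2) / 2.0
    diff = abs(float(g.mean() - i.mean()))
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0
        raise ValueError("zero score variance with unequal means: infinite separation")
    return diff / float(np.sqrt(pooled))


def roc_points(scores: BiometricScoreSet) -> np.ndarray:
    """ROC operating points as an array of (threshold, FAR, FRR) rows.

    Thresholds are all distinct scores plus -inf/+inf sentinels; at a
    threshold tau, FAR is the impostor fraction with score >= tau and
    FRR the genuine fraction with score < tau.  FAR is non-increasing
    and FRR non-decreasing in tau.
    """
    g, i = scores.genuine, scores.impostor
    thresholds = np.concatenate(
        [[-np.inf], np.unique(np.concatenate([g, i])), [np.inf]]
    )
    g_sorted = np.sort(g)
    i_sorted = np.sort(i)
    far = 1.0 - np.searchsorted(i_sorted, thresholds, side="left") / i.size
    frr = np.searchsorted(g_sorted, thresholds, side="left") / g.size
    return np.column_stack([thresholds, far, frr])


def eer(scores: BiometricScoreSet) -> float:
    """Equal error rate in percent.

    Walks the ROC from permissive to strict thresholds and linearly
    interpolates between the two operating points bracketing FAR = FRR.
    Perfectly separated score sets give 0%.
    """
    points = roc_points(scores)
    far, frr = points[:, 1], points[:, 2]
    diff = far - frr  # starts at +1, ends at -1
    k = int(np.flatnonzero(diff <= 0)[0])
    if diff[k] == 0.0 or k == 0:
        return float(far[k]) * 100.0
    f1, r1 = far[k - 1], frr[k - 1]
    f2, r2 = far[k], frr[k]
    s = (f1 - r1) / ((f1 - r1) - (f2 - r2))
    return float(f1 + s * (f2 - f1)) * 100.0


def frr_at_far(scores: BiometricScoreSet, far_level: float = 1e-4) -> FrrAtFar:
    """FRR (percent) at a fixed FAR operating point.

    The FRR is linearly interpolated between the ROC points bracketing
    ``far_level``; at a FAR attained by several thresholds the smallest
    FRR (the best achievable operating point) is used.  When the
    impostor set is too small to resolve the level (fewer than
    1/far_level scores) the FRR at the FAR = 0 operating point is
    returned with the extrapolation flag set.
    """
    if not 0 < far_level < 1:
        raise ValueError("far_level must be in (0, 1)")
    points = roc_points(scores)
    far, frr = points[:, 1], points[:, 2]
    order = np.argsort(far, kind="stable")
    far_sorted, frr_sorted = far[order], frr[order]
    # best (lowest) FRR per distinct FAR
    best_far, first_idx = np.unique(far_sorted, return_index=True)
    best_frr = np.minimum.reduceat(frr_sorted, first_idx)
    value = float(np.interp(far_level, best_far, best_frr))
    extrapolated = scores.impostor.size < 1.0 / far_level
    if extrapolated:
        value = float(best_frr[0])  # FRR at FAR = 0
    return FrrAtFar(frr_pct=value * 100.0, extrapolated=extrapolated)


def biometric_metrics(scores: BiometricScoreSet, far_level: float = 1e-4) -> BiometricMetrics:
    """Compute all score-level metrics for one score set."""
    frr = frr_at_far(scores, far_level)
    return BiometricMetrics(
        d_prime=d_prime(scores),
        eer_pct=eer(scores),
        frr_at_far_pct=frr.frr_pct,
        far_level=far_level,
        frr_extrapolated=frr.extrapolated,
    )
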