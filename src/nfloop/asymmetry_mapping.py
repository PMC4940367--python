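"""Left-minus-right DL-PFC asymmetry and the per-block adaptive feedback map.

The neurofeedback signal is the difference between the mean oxygenated
hemoglobin change over the left-group channels and the right-group
channels, in uMol/L, updated at the acquisition rate. For each block a
feedback map (Min, Max) is fit on the View epoch's (delayed-window,
outlier-trimmed) asymmetry values:

    Min = mean + 1.28 * SD      (no feedback for ~90% of View values
                                 under a Gaussian assumption)
    Max = Min + (max - min)     (the View variation range)

During NF, asymmetry is mapped linearly onto [0, 1] between Min and Max,
clamped at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DegenerateMapError
from .signal_core import ChannelMontage, HemoTimeSeries

__all__ = [
    "AsymmetrySeries",
    "FeedbackMap",
    "asymmetry_score",
    "remove_outliers",
    "fit_feedback_map",
    "normalize_feedback",
    "stream_feedback",
]


@dataclass
class AsymmetrySeries:
    """Per-sample asymmetry (uMol/L) with a per-sample validity flag."""

    time: np.ndarray
    value: np.ndarray
    valid: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    def window(self, i0: int, i1: int) -> np.ndarray:
        """Valid values within the half-open sample range [i0, i1)."""
        v = self.value[i0:i1]
        return v[self.valid[i0:i1]]


@dataclass(frozen=True)
class FeedbackMap:
    """Per-block linear map from asymmetry to normalized feedback."""

    min_point: float
    max_point: float
    source_block: int | None = None

    def __post_init__(self) -> None:
        if not self.max_point > self.min_point:
            raise DegenerateMapError(
                f"degenerate feedback map: Max ({self.max_point}) must exceed "
                f"Min ({self.min_point})"
            )


def asymmetry_score(
    series: HemoTimeSeries, montage: ChannelMontage | None = None
) -> AsymmetrySeries:
    """Mean left-group HbO minus mean right-group HbO, per sample.

    Artifact-masked channels are dropped from each side's mean; a sample is
    invalid when either side has no usable channel at that instant.
    """
    montage = montage or ChannelMontage()
    if series.n_channels < max(max(montage.left_group), max(montage.right_group)):
        raise ConfigError("montage references channels beyond the series")
    value = np.full(series.n_samples, np.nan)
    valid = np.zeros(series.n_samples, dtype=bool)
    sides = []
    for idx in (montage.left_idx, montage.right_idx):
        vals = series.hbo[:, idx]
        ok = ~series.artifact_mask[:, idx]
        cnt = ok.sum(axis=1)
        s = np.where(ok, vals, 0.0).sum(axis=1)
        mean = np.divide(s, cnt, out=np.full(len(s), np.nan), where=cnt > 0)
        sides.append((mean, cnt > 0))
    (lmean, lok), (rmean, rok) = sides
    valid = lok & rok
    value[valid] = lmean[valid] - rmean[valid]
    return AsymmetrySeries(series.time, value, valid, series.fs)


def remove_outliers(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Single-pass trim: drop values more than ``k`` sample-SDs from the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise DegenerateMapError("need at least 3 values for outlier trimming")
    if np.isinf(k):
        return v.copy()
    sd = v.std(ddof=1)
    keep = np.abs(v - v.mean()) <= k * sd
    out = v[keep]
    if out.size < 3:
        raise DegenerateMapError("fewer than 3 values survive outlier trimming")
    return out


def fit_feedback_map(
    view_values: np.ndarray,
    z_factor: float = 1.28,
    source_block: int | None = None,
    population_sd: bool = False,
) -> FeedbackMap:
    """Fit (Min, Max) from the trimmed View-window asymmetry values.

    ``Min = mean + z_factor * SD`` and ``Max = Min + range``; SD is the
    sample SD unless ``population_sd`` is set.
    """
    v = np.asarray(view_values, dtype=float)
    if v.size < 3:
        raise DegenerateMapError("need at least 3 View values to fit a map")
    sd = v.std(ddof=0 if population_sd else 1)
    rng = v.max() - v.min()
    if sd == 0 or rng == 0:
        raise DegenerateMapError(
            "View asymmetry has zero spread; block cannot provide feedback"
        )
    mn = v.mean() + z_factor * sd
    return FeedbackMap(mn, mn + rng, source_block)


def normalize_feedback(a, fmap: FeedbackMap):
    """Linear map of asymmetry onto [0, 1], clamped outside [Min, Max]."""
    a = np.asarray(a, dtype=float)
    score = (a - fmap.min_point) / (fmap.max_point - fmap.min_point)
    out = np.clip(score, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def stream_feedback(
    asym: AsymmetrySeries, fmap: FeedbackMap, i0: int = 0, i1: int | None = None
) -> np.ndarray:
    """Per-tick feedback scores over [i0, i1); invalid samples hold the last score.

    Before the first valid sample the score is 0 (agent idle).
    """
    i1 = asym.value.size if i1 is None else i1
    scores = np.zeros(i1 - i0)
    last = 0.0
    for j, i in enumerate(range(i0, i1)):
        if asym.valid[i]:
            last = normalize_feedback(asym.value[i], fmap)
        scores[j] = last
    return scores
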