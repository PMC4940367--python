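"""Raw-optics to hemoglobin conversion, low-pass filtering and artifact masking.

The measurement chain is the standard continuous-wave fNIRS one: detector
intensities at two wavelengths are converted to optical-density changes
relative to an epoch-start reference, the modified Beer-Lambert law (MBLL)
turns the two optical densities into oxygenated / deoxygenated hemoglobin
concentration changes (uMol/L), a linear-phase FIR low-pass removes cardiac
and high-frequency noise, and a sliding-window statistic flags motion
artifacts (SMAR-style rejection).

All per-sample arrays are shaped ``(n_samples, n_channels)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as _sig

from .errors import (
    ChannelUnusableError,
    ConfigError,
    SignalError,
    TooShortToFilterError,
)

__all__ = [
    "ChannelMontage",
    "MbllConstants",
    "FilterSpec",
    "HemoTimeSeries",
    "intensities_to_od",
    "od_to_concentrations",
    "concentrations_to_od",
    "design_lowpass",
    "lowpass_filter",
    "detect_motion_artifacts",
    "rebase_to_baseline",
]


@dataclass(frozen=True)
class ChannelMontage:
    """Sensor layout: which 1-based channels sit over left / right DL-PFC.

    The default emulates a 16-channel prefrontal band where the four
    left-most and four right-most channels cover the dorsolateral
    prefrontal cortex on each side.
    """

    n_channels: int = 16
    left_group: tuple[int, ...] = (1, 2, 3, 4)
    right_group: tuple[int, ...] = (13, 14, 15, 16)
    wavelengths: tuple[float, float] = (730.0, 850.0)

    def __post_init__(self) -> None:
        left, right = set(self.left_group), set(self.right_group)
        if not left or not right:
            raise ConfigError("montage groups must be non-empty")
        if left & right:
            raise ConfigError("left and right montage groups overlap")
        valid = set(range(1, self.n_channels + 1))
        if not (left <= valid and right <= valid):
            raise ConfigError(
                f"montage groups must be subsets of 1..{self.n_channels}"
            )

    @property
    def left_idx(self) -> np.ndarray:
        """0-based column indices of the left group."""
        return np.asarray(self.left_group, dtype=int) - 1

    @property
    def right_idx(self) -> np.ndarray:
        return np.asarray(self.right_group, dtype=int) - 1


# Molar extinction coefficients in 1/(mM*cm) at (730, 850) nm, rows are
# wavelengths, columns (HbO, HbR).  Tabulated compilation values; they scale
# concentrations but cancel in the sign of the left-right difference.
_DEFAULT_EXTINCTION = np.array(
    [
        [0.446, 1.1022],  # 730 nm
        [1.058, 0.6913],  # 850 nm
    ]
)


@dataclass(frozen=True)
class MbllConstants:
    """Constants of the modified Beer-Lambert law.

    ``extinction[i, j]`` is the molar extinction coefficient of species j
    (HbO, HbR) at wavelength i, in 1/(mM*cm); ``pathlength`` is the
    source-detector separation in cm and ``dpf`` the differential
    pathlength factor per wavelength.
    """

    extinction: np.ndarray = field(
        default_factory=lambda: _DEFAULT_EXTINCTION.copy()
    )
    pathlength: float = 2.5
    dpf: tuple[float, float] = (6.0, 6.0)

    def __post_init__(self) -> None:
        ext = np.asarray(self.extinction, dtype=float)
        if ext.shape != (2, 2):
            raise ConfigError("extinction must be a 2x2 matrix")
        if self.pathlength <= 0 or min(self.dpf) <= 0:
            raise ConfigError("pathlength and dpf must be positive")
        if np.linalg.cond(self.system_matrix()) > 1e12:
            raise ConfigError("extinction matrix is singular")
        object.__setattr__(self, "extinction", ext)

    def system_matrix(self) -> np.ndarray:
        """2x2 matrix A with dOD = A @ (dHbO, dHbR) in mM."""
        ext = np.asarray(self.extinction, dtype=float)
        L = self.pathlength * np.asarray(self.dpf, dtype=float)
        return ext * L[:, None]


@dataclass(frozen=True)
class FilterSpec:
    """Linear-phase FIR low-pass: ``order + 1`` taps, windowed-sinc design."""

    order: int = 20
    cutoff: float = 0.1
    fs: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.cutoff < self.fs / 2):
            raise ConfigError("cutoff must lie in (0, fs/2)")
        if self.order < 2 or self.order % 2:
            raise ConfigError("order must be even and >= 2")

    @property
    def numtaps(self) -> int:
        return self.order + 1


@dataclass
class HemoTimeSeries:
    """Per-channel hemoglobin concentration changes at a fixed rate.

    ``hbo``/``hbr`` are (n_samples, n_channels) in uMol/L relative to a
    baseline window; ``artifact_mask`` is True where a sample is unusable.
    """

    time: np.ndarray
    hbo: np.ndarray
    hbr: np.ndarray
    artifact_mask: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        if self.hbo.shape[0] == 1 and self.time.size > 1:
            self.hbo = self.hbo.T
        if self.hbr is None:
            self.hbr = np.zeros_like(self.hbo)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.hbo.shape, dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if not (self.hbo.shape == self.hbr.shape == self.artifact_mask.shape):
            raise SignalError("hbo/hbr/mask shapes disagree")
        if self.time.shape[0] != self.hbo.shape[0]:
            raise SignalError("time axis does not match sample axis")

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[1]

    def copy(self) -> "HemoTimeSeries":
        return HemoTimeSeries(
            self.time.copy(),
            self.hbo.copy(),
            self.hbr.copy(),
            self.artifact_mask.copy(),
            self.fs,
        )


def intensities_to_od(
    intensity: np.ndarray, reference: np.ndarray | float
) -> np.ndarray:
    """Optical-density change: ``-log10(I / I_ref)`` elementwise.

    Raises :class:`SignalError` naming the offending (sample, channel)
    positions when any intensity or reference is non-positive.
    """
    I = np.asarray(intensity, dtype=float)
    ref = np.asarray(reference, dtype=float)
    bad = ~(I > 0)
    if bad.any():
        where = np.argwhere(bad)[:5].tolist()
        raise SignalError(f"non-positive intensity at (sample, channel) {where}")
    if not np.all(ref > 0):
        raise SignalError("non-positive reference intensity")
    return -np.log10(I / ref)


def od_to_concentrations(
    od_pair: np.ndarray, constants: MbllConstants | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the MBLL: OD changes at both wavelengths -> (dHbO, dHbR) in uMol/L.

    ``od_pair`` has shape (2, ...) with axis 0 the wavelength. The per-sample
    2x2 system dOD(lambda) = (eps_HbO*dHbO + eps_HbR*dHbR) * pathlength *
    dpf(lambda) is solved exactly; the 1e3 factor converts the mM solution
    to uMol/L.
    """
    constants = constants or MbllConstants()
    od = np.asarray(od_pair, dtype=float)
    if od.shape[0] != 2:
        raise SignalError("od_pair must have the two wavelengths on axis 0")
    A_inv = np.linalg.inv(constants.system_matrix())
    flat = od.reshape(2, -1)
    conc_mM = A_inv @ flat
    conc = (conc_mM * 1e3).reshape(od.shape)
    return conc[0], conc[1]


def concentrations_to_od(
    hbo: np.ndarray, hbr: np.ndarray, constants: MbllConstants | None = None
) -> np.ndarray:
    """Forward MBLL projection, the exact inverse of :func:`od_to_concentrations`."""
    constants = constants or MbllConstants()
    A = constants.system_matrix()
    conc_mM = np.stack([np.asarray(hbo), np.asarray(hbr)]) * 1e-3
    flat = conc_mM.reshape(2, -1)
    return (A @ flat).reshape(conc_mM.shape)


def design_lowpass(spec: FilterSpec) -> np.ndarray:
    """FIR taps: Hamming windowed-sinc, unit DC gain, ``order + 1`` taps."""
    return _sig.firwin(spec.numtaps, spec.cutoff, window="hamming", fs=spec.fs)


def _filter_array(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    order = taps.size - 1
    pad = order // 2
    xp = np.pad(x, [(pad, pad)] + [(0, 0)] * (x.ndim - 1), mode="edge")
    y = _sig.lfilter(taps, 1.0, xp, axis=0)
    # group delay of a linear-phase FIR is order/2 samples
    return y[2 * pad:]


def lowpass_filter(
    series: HemoTimeSeries, spec: FilterSpec | None = None
) -> HemoTimeSeries:
    """Zero-lag low-pass: linear-phase FIR with group-delay compensation.

    Edge samples are edge-padded before filtering so the output is
    time-aligned and the same length as the input.
    """
    spec = spec or FilterSpec(fs=series.fs)
    if series.n_samples <= spec.order:
        raise TooShortToFilterError(
            f"series of {series.n_samples} samples is too short to filter "
            f"with {spec.numtaps} taps"
        )
    taps = design_lowpass(spec)
    out = series.copy()
    out.hbo = _filter_array(series.hbo, taps)
    out.hbr = _filter_array(series.hbr, taps)
    return out


def detect_motion_artifacts(
    data: np.ndarray,
    fs: float,
    window_s: float = 10.0,
    z_thresh: float = 3.0,
    max_reject: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window motion-artifact rejection.

    A window of ``window_s`` seconds advances sample-by-sample over each
    channel; a window whose internal (sample) SD exceeds ``z_thresh`` times
    the channel's reference SD — the median of all rolling SDs over the
    recording — is flagged, and the mask covers every sample of flagged
    windows. Channels with more than ``max_reject`` of samples flagged are
    reported unusable.

    Returns ``(mask, channel_usable)`` with ``mask`` shaped like ``data``.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    n, c = x.shape
    win = max(2, int(round(window_s * fs)))
    if win > n:
        win = n
    mask = np.zeros((n, c), dtype=bool)
    # (n - win + 1, c, win) view; SD per window, ddof=1
    sw = sliding_window_view(x, win, axis=0)
    sds = sw.std(axis=-1, ddof=1)
    ref = np.median(sds, axis=0)
    if np.isinf(z_thresh):
        return mask, np.ones(c, dtype=bool)
    flagged = sds > z_thresh * ref[None, :]
    for ch in range(c):
        starts = np.flatnonzero(flagged[:, ch])
        for s in starts:
            mask[s:s + win, ch] = True
    usable = mask.mean(axis=0) <= max_reject
    return mask, usable


def rebase_to_baseline(
    series: HemoTimeSeries, baseline: tuple[float, float]
) -> HemoTimeSeries:
    """Re-reference each channel to its unmasked mean over ``baseline`` seconds.

    After rebasing the baseline-window mean of every channel is zero. A
    channel whose baseline window is fully masked invalidates the block.
    """
    t0, t1 = baseline
    sel = (series.time >= t0) & (series.time < t1)
    if not sel.any():
        raise SignalError(f"baseline window [{t0}, {t1}) outside the series")
    out = series.copy()
    for hb in ("hbo", "hbr"):
        arr = getattr(out, hb)
        for ch in range(series.n_channels):
            ok = sel & ~series.artifact_mask[:, ch]
            if not ok.any():
                raise ChannelUnusableError(
                    f"channel {ch + 1}: baseline window fully artifact-masked"
                )
            arr[:, ch] -= arr[ok, ch].mean()
    return out
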