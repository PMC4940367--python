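"""CSV/JSON/YAML input-output, configuration loading and run manifests.

Two time-series dialects are supported:

* ``raw``: columns ``time_s, channel, i730, i850`` (long format, one row
  per sample per channel, detector counts);
* ``hbo``: columns ``time_s, ch01..chNN`` (wide format, uMol/L).

Markers are ``time_s, label`` with labels REST_START, PROMPT, VIEW_START,
NF_START, NF_END, BLOCK_END. The sampling rate is inferred from the median
time step and must agree with the configured rate within 1%.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError
from .signal_core import ChannelMontage, HemoTimeSeries
from .session_model import SessionConfig

__all__ = [
    "read_hbo_csv",
    "write_hbo_csv",
    "read_raw_csv",
    "write_raw_csv",
    "read_markers_csv",
    "write_markers_csv",
    "load_config",
    "RunManifest",
]

_MARKER_LABELS = {
    "REST_START", "PROMPT", "VIEW_START", "NF_START", "NF_END", "BLOCK_END",
}


def _check_fs(time_s: np.ndarray, expected_fs: float | None) -> float:
    dt = np.diff(time_s)
    if dt.size == 0:
        raise ParseError("time series has fewer than 2 samples")
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise ParseError("time_s not strictly increasing", line=int(bad[0]) + 3)
    fs = 1.0 / float(np.median(dt))
    if expected_fs is not None and abs(fs - expected_fs) > 0.01 * expected_fs:
        raise ParseError(
            f"inferred sampling rate {fs:.3g} Hz does not match configured "
            f"{expected_fs:.3g} Hz"
        )
    return fs


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}", line=1)


def read_hbo_csv(
    path, expected_fs: float | None = None
) -> HemoTimeSeries:
    """Read a wide-format HbO table into a :class:`HemoTimeSeries`."""
    df = pd.read_csv(path)
    _require_columns(df, ["time_s"], path)
    ch_cols = [c for c in df.columns if c.startswith("ch")]
    if not ch_cols:
        raise ParseError(f"{path}: no ch01..chNN columns", line=1)
    ch_cols = sorted(ch_cols)
    t = df["time_s"].to_numpy(dtype=float)
    fs = _check_fs(t, expected_fs)
    hbo = df[ch_cols].to_numpy(dtype=float)
    return HemoTimeSeries(
        time=t, hbo=hbo, hbr=np.zeros_like(hbo),
        artifact_mask=np.zeros(hbo.shape, dtype=bool), fs=fs,
    )


def write_hbo_csv(path, series: HemoTimeSeries) -> None:
    cols = {"time_s": series.time}
    for ch in range(series.n_channels):
        cols[f"ch{ch + 1:02d}"] = series.hbo[:, ch]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def read_raw_csv(
    path, expected_fs: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Read a long-format raw-intensity table.

    Returns ``(time, i730, i850, fs)`` with intensities shaped
    (n_samples, n_channels).
    """
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "channel", "i730", "i850"], path)
    if (df[["i730", "i850"]].to_numpy() <= 0).any():
        row = int(np.argwhere(
            (df[["i730", "i850"]].to_numpy() <= 0).any(axis=1))[0][0])
        raise ParseError(f"{path}: non-positive intensity", line=row + 2)
    wide730 = df.pivot(index="time_s", columns="channel", values="i730")
    wide850 = df.pivot(index="time_s", columns="channel", values="i850")
    t = wide730.index.to_numpy(dtype=float)
    fs = _check_fs(t, expected_fs)
    return t, wide730.to_numpy(float), wide850.to_numpy(float), fs


def write_raw_csv(path, time_s, i730, i850) -> None:
    n, c = np.asarray(i730).shape
    rows = {
        "time_s": np.repeat(time_s, c),
        "channel": np.tile(np.arange(1, c + 1), n),
        "i730": np.asarray(i730).ravel(),
        "i850": np.asarray(i850).ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def read_markers_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "label"], path)
    bad = ~df["label"].isin(_MARKER_LABELS)
    if bad.any():
        raise ParseError(
            f"{path}: unknown marker label {df['label'][bad].iloc[0]!r}",
            line=int(np.flatnonzero(bad)[0]) + 2,
        )
    return df


def write_markers_csv(path, markers: pd.DataFrame) -> None:
    markers.to_csv(path, index=False)


def load_config(path) -> tuple[SessionConfig, dict]:
    """Load a YAML/JSON session config; unknown keys are returned untouched.

    Recognised keys mirror :class:`SessionConfig`; ``montage`` may be a
    mapping with ``n_channels``, ``left_group``, ``right_group``,
    ``wavelengths``.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    known = {f.name for f in SessionConfig.__dataclass_fields__.values()}
    kwargs = {}
    extra = {}
    for k, v in data.items():
        if k == "montage" and isinstance(v, dict):
            v = {kk: tuple(vv) if isinstance(vv, list) else vv
                 for kk, vv in v.items()}
            kwargs["montage"] = ChannelMontage(**v)
        elif k in known:
            kwargs[k] = v
        else:
            extra[k] = v
    return SessionConfig(**kwargs), extra


@dataclass
class RunManifest:
    """Reproducibility record emitted once per CLI run."""

    command: str
    seed: int | None
    config_hash: str
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    timings_s: dict = field(default_factory=dict)
    version: str = "0.1.0"

    @staticmethod
    def config_digest(config: SessionConfig) -> str:
        d = asdict(config)
        d["montage"] = {
            "n_channels": config.montage.n_channels,
            "left_group": list(config.montage.left_group),
            "right_group": list(config.montage.right_group),
            "wavelengths": list(config.montage.wavelengths),
        }
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


class StageTimer:
    """Context helper recording wall-clock per pipeline stage."""

    def __init__(self, manifest: RunManifest, stage: str):
        self.manifest = manifest
        self.stage = stage

    def __enter__(self):
        self._t0 = _time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.manifest.timings_s[self.stage] = round(
            _time.perf_counter() - self._t0, 4)
        return False
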