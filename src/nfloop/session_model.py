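"""Block/epoch protocol model and hemodynamically-delayed analysis windows.

A session is a sequence of identical blocks, each a contiguous run of
epochs: an initial Rest (whose last seconds provide the per-block
baseline), a prompt, a View epoch (reference task: backward counting while
watching the agent), a short Rest, a second prompt, the Neurofeedback (NF)
epoch, and a final Rest. Because the hemodynamic response lags the task by
roughly 7 s, analysis windows for View and NF are the epoch extent shifted
forward by that delay: data from the first 7 s of each epoch are excluded
and the first 7 s after the epoch are included instead.

Times are seconds from session start; intervals are half-open; sample index
= floor(t * fs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .errors import ConfigError
from .signal_core import ChannelMontage

__all__ = [
    "EpochKind",
    "EpochSpec",
    "BlockRecord",
    "SessionConfig",
    "build_block_schedule",
    "extract_epoch_window",
    "baseline_window",
    "blocks_to_markers",
    "markers_to_blocks",
]


class EpochKind(str, Enum):
    REST = "REST"
    PROMPT = "PROMPT"
    VIEW = "VIEW"
    NF = "NF"


@dataclass(frozen=True)
class EpochSpec:
    kind: EpochKind
    start: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError("epoch duration must be positive")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class BlockRecord:
    """One Rest-View-NF cycle with its epoch boundaries."""

    block_index: int
    epochs: tuple[EpochSpec, ...]
    hemodynamic_delay: float = 7.0

    def __post_init__(self) -> None:
        kinds = [e.kind for e in self.epochs]
        if kinds.count(EpochKind.VIEW) != 1 or kinds.count(EpochKind.NF) != 1:
            raise ConfigError("block must contain exactly one VIEW and one NF")
        if abs(self.view.duration - self.nf.duration) > 1e-9:
            raise ConfigError("VIEW and NF epochs must be matched for length")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if abs(a.end - b.start) > 1e-9:
                raise ConfigError("epochs within a block must be contiguous")

    def _one(self, kind: EpochKind) -> EpochSpec:
        return next(e for e in self.epochs if e.kind == kind)

    @property
    def view(self) -> EpochSpec:
        return self._one(EpochKind.VIEW)

    @property
    def nf(self) -> EpochSpec:
        return self._one(EpochKind.NF)

    @property
    def first_rest(self) -> EpochSpec:
        return next(e for e in self.epochs if e.kind == EpochKind.REST)

    @property
    def start(self) -> float:
        return self.epochs[0].start

    @property
    def end(self) -> float:
        return self.epochs[-1].end


@dataclass(frozen=True)
class SessionConfig:
    """Protocol timing and montage; defaults give the 8-block, 2 Hz session."""

    n_blocks: int = 8
    fs: float = 2.0
    rest1_s: float = 20.0
    prompt_s: float = 3.0
    view_s: float = 40.0
    inter_rest_s: float = 10.0
    nf_s: float = 40.0
    final_rest_s: float = 7.0
    baseline_tail_s: float = 10.0
    hemodynamic_delay_s: float = 7.0
    montage: ChannelMontage = field(default_factory=ChannelMontage)

    def __post_init__(self) -> None:
        durations = (
            self.rest1_s, self.prompt_s, self.view_s,
            self.inter_rest_s, self.nf_s, self.final_rest_s,
        )
        if min(durations) <= 0 or self.n_blocks < 1 or self.fs <= 0:
            raise ConfigError("durations, n_blocks and fs must be positive")
        if self.baseline_tail_s > self.rest1_s:
            raise ConfigError("baseline tail longer than the first Rest epoch")

    @property
    def block_duration(self) -> float:
        return (
            self.rest1_s + self.prompt_s + self.view_s
            + self.inter_rest_s + self.prompt_s + self.nf_s
            + self.final_rest_s
        )

    @property
    def session_duration(self) -> float:
        return self.n_blocks * self.block_duration


def build_block_schedule(config: SessionConfig) -> list[BlockRecord]:
    """Lay out ``n_blocks`` REST-PROMPT-VIEW-REST-PROMPT-NF-REST blocks from t=0."""
    blocks: list[BlockRecord] = []
    t = 0.0
    plan = (
        (EpochKind.REST, config.rest1_s),
        (EpochKind.PROMPT, config.prompt_s),
        (EpochKind.VIEW, config.view_s),
        (EpochKind.REST, config.inter_rest_s),
        (EpochKind.PROMPT, config.prompt_s),
        (EpochKind.NF, config.nf_s),
        (EpochKind.REST, config.final_rest_s),
    )
    for b in range(1, config.n_blocks + 1):
        epochs = []
        for kind, dur in plan:
            epochs.append(EpochSpec(kind, t, dur))
            t += dur
        blocks.append(
            BlockRecord(b, tuple(epochs), config.hemodynamic_delay_s)
        )
    return blocks


def extract_epoch_window(
    epoch: EpochSpec,
    delay: float,
    fs: float,
    n_total: int | None = None,
    strict: bool = False,
) -> tuple[int, int]:
    """Half-open sample range for ``[start + delay, end + delay)``.

    At 2 Hz and a 40-s epoch this is exactly 80 samples. If the shifted
    window runs past ``n_total`` samples it is truncated, or rejected when
    ``strict`` is set.
    """
    if delay < 0:
        raise ConfigError("hemodynamic delay must be non-negative")
    i0 = math.floor((epoch.start + delay) * fs + 1e-9)
    i1 = math.floor((epoch.end + delay) * fs + 1e-9)
    if n_total is not None and i1 > n_total:
        if strict:
            raise ConfigError(
                f"analysis window [{i0}, {i1}) exceeds recording of "
                f"{n_total} samples"
            )
        i1 = n_total
    return i0, i1


def baseline_window(
    block: BlockRecord, config: SessionConfig
) -> tuple[float, float]:
    """Last ``baseline_tail_s`` seconds of the block's first Rest epoch."""
    rest = block.first_rest
    if rest.duration + 1e-9 < config.baseline_tail_s:
        raise ConfigError("first Rest epoch shorter than the baseline tail")
    return rest.end - config.baseline_tail_s, rest.end


_START_LABEL = {
    EpochKind.REST: "REST_START",
    EpochKind.PROMPT: "PROMPT",
    EpochKind.VIEW: "VIEW_START",
    EpochKind.NF: "NF_START",
}
_LABEL_KIND = {v: k for k, v in _START_LABEL.items()}


def blocks_to_markers(blocks: list[BlockRecord]) -> pd.DataFrame:
    """Emit the marker stream (columns ``time_s``, ``label``) for a schedule."""
    rows: list[tuple[float, str]] = []
    for blk in blocks:
        prev_kind = None
        for ep in blk.epochs:
            # NF_END already marks the start of the trailing Rest
            if not (prev_kind == EpochKind.NF and ep.kind == EpochKind.REST):
                rows.append((ep.start, _START_LABEL[ep.kind]))
            if ep.kind == EpochKind.NF:
                rows.append((ep.end, "NF_END"))
            prev_kind = ep.kind
        rows.append((blk.end, "BLOCK_END"))
    return pd.DataFrame(rows, columns=["time_s", "label"])


def markers_to_blocks(
    markers: pd.DataFrame, hemodynamic_delay: float = 7.0
) -> list[BlockRecord]:
    """Reconstruct the block schedule from a marker stream.

    Inverse of :func:`blocks_to_markers`: each epoch-start label opens an
    epoch that ends at the next marker time; ``NF_END`` opens the final Rest
    which runs to ``BLOCK_END``.
    """
    blocks: list[BlockRecord] = []
    epochs: list[EpochSpec] = []
    pending: tuple[EpochKind, float] | None = None
    index = 1
    for _, row in markers.sort_values("time_s", kind="stable").iterrows():
        t, label = float(row["time_s"]), str(row["label"])
        if pending is not None:
            kind, start = pending
            epochs.append(EpochSpec(kind, start, t - start))
            pending = None
        if label in _LABEL_KIND:
            pending = (_LABEL_KIND[label], t)
        elif label == "NF_END":
            pending = (EpochKind.REST, t)
        elif label == "BLOCK_END":
            blocks.append(
                BlockRecord(index, tuple(epochs), hemodynamic_delay)
            )
            epochs = []
            index += 1
        else:
            raise ConfigError(f"unknown marker label {label!r}")
    return blocks
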