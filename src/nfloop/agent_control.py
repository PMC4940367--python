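"""Virtual-agent expression control: engagement levels, behaviors, blending.

The scalar feedback score in [0, 1] drives a small repertoire of eight
non-verbal behaviors organised into four engagement levels (negative /
disengaged, neutral, mildly positive, highly positive). Each behavior is a
set of FACS action units (AUs) with intensities plus MPEG-4 body animation
parameters (BAPs, normalized joint angles). A score of exactly 0 keeps the
agent in its disengaged idle; increasing score moves it through neutral and
smiling behaviors up to open delight.

To avoid a frozen, uncanny agent, a new behavior of the same level is
selected whenever the level is held for about 2 s (deterministic
round-robin), and every behavior change is blended with a smooth
cross-fade so the previous expression fades while the next appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "EngagementLevel",
    "BehaviorSpec",
    "BEHAVIORS",
    "behaviors_by_level",
    "quantize_engagement",
    "BehaviorSelector",
    "smoothstep",
    "blend_behaviors",
    "generate_timeline",
]


class EngagementLevel(IntEnum):
    NEGATIVE = 0
    NEUTRAL = 1
    MILD_POSITIVE = 2
    HIGH_POSITIVE = 3


@dataclass(frozen=True)
class BehaviorSpec:
    """One agent behavior: engagement level + AU intensities + BAP angles."""

    id: str
    level: EngagementLevel
    au_set: dict[str, float] = field(default_factory=dict)
    bap_set: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.au_set.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{self.id}: AU intensity {k}={v} outside [0,1]")


# AU12 (lip-corner puller) carries the smile; mild smiles use a reduced gain.
_MILD_SMILE = 0.6

# Eight behaviors. Negative behaviors draw on the lip-lowering /
# gaze-aversion family (AU15 lip-corner depressor, AU17 chin raiser, AU18
# lip pucker, AU23/24 lip tightener/pressor, AU43 eyes closed, AU61/62/64
# gaze left/right/down) with cervical and lumbar vertebra movements; the
# positive behaviors combine brow raisers (AU1/AU2), upper-lid raiser
# (AU5), cheek raiser (AU6), smile (AU12), parted lips (AU25) and jaw drop
# (AU26).
BEHAVIORS: tuple[BehaviorSpec, ...] = (
    # Gazes away to the right, head tilted, lip pout.
    BehaviorSpec("Neg1", EngagementLevel.NEGATIVE,
                 {"AU18": 1.0, "AU23": 1.0, "AU62": 1.0},
                 {"vc1roll": 0.3}),
    # Gazes completely down, eyes nearly closed.
    BehaviorSpec("Neg2", EngagementLevel.NEGATIVE,
                 {"AU43": 1.0, "AU64": 1.0},
                 {"vc1tilt": -0.3}),
    # Turns the body away, lip corners lowered.
    BehaviorSpec("Neg3", EngagementLevel.NEGATIVE,
                 {"AU15": 1.0, "AU17": 1.0, "AU24": 1.0, "AU61": 1.0},
                 {"vc1torsion": 0.3, "vl1torsion": 0.3}),
    # Neutral face, gaze and body towards the user.
    BehaviorSpec("Neutral", EngagementLevel.NEUTRAL, {}, {}),
    # Direct gaze, mild smile.
    BehaviorSpec("MildPos1", EngagementLevel.MILD_POSITIVE,
                 {"AU5": 0.5, "AU12": _MILD_SMILE, "AU25": 0.5}, {}),
    # Head tilted to the left, mild smile, lips slightly parted.
    BehaviorSpec("MildPos2", EngagementLevel.MILD_POSITIVE,
                 {"AU5": 0.5, "AU12": _MILD_SMILE, "AU25": 0.5, "AU26": 0.3},
                 {"vc1roll": -0.3}),
    # Wide smile with raised cheeks (crow's feet), head tilted back.
    BehaviorSpec("HighPos1", EngagementLevel.HIGH_POSITIVE,
                 {"AU5": 0.5, "AU6": 1.0, "AU12": 1.0, "AU25": 0.7},
                 {"vc1tilt": 0.3}),
    # Wide smile, mouth open, eyebrows raised.
    BehaviorSpec("HighPos2", EngagementLevel.HIGH_POSITIVE,
                 {"AU1": 1.0, "AU2": 1.0, "AU5": 0.5, "AU12": 1.0,
                  "AU25": 0.7, "AU26": 0.5}, {}),
)


def behaviors_by_level(
    specs: Sequence[BehaviorSpec] = BEHAVIORS,
) -> dict[EngagementLevel, list[BehaviorSpec]]:
    out: dict[EngagementLevel, list[BehaviorSpec]] = {
        lvl: [] for lvl in EngagementLevel
    }
    for s in specs:
        out[s.level].append(s)
    return out


DEFAULT_BINS: tuple[tuple[float, float, EngagementLevel], ...] = (
    (0.0, 1 / 3, EngagementLevel.NEUTRAL),
    (1 / 3, 2 / 3, EngagementLevel.MILD_POSITIVE),
    (2 / 3, 1.0, EngagementLevel.HIGH_POSITIVE),
)


def quantize_engagement(
    score: float,
    bins: tuple[tuple[float, float, EngagementLevel], ...] = DEFAULT_BINS,
) -> EngagementLevel:
    """Map a feedback score to an engagement level.

    Exactly 0 (no feedback) is the disengaged idle; otherwise bins are
    half-open on the left: (0, 1/3] neutral, (1/3, 2/3] mild positive,
    (2/3, 1] high positive by default.
    """
    if not 0.0 <= score <= 1.0:
        raise ConfigError(f"feedback score {score} outside [0, 1]")
    if score == 0.0:
        return EngagementLevel.NEGATIVE
    for lo, hi, lvl in bins:
        if lo < score <= hi:
            return lvl
    return bins[-1][2]


def smoothstep(t: float) -> float:
    """C1 ease 3t^2 - 2t^3 on [0, 1]."""
    t = min(max(t, 0.0), 1.0)
    return t * t * (3.0 - 2.0 * t)


def blend_behaviors(
    prev: BehaviorSpec,
    nxt: BehaviorSpec,
    t: float,
    ease: Callable[[float], float] = smoothstep,
) -> tuple[dict[str, float], dict[str, float]]:
    """Cross-fade two behaviors at progress ``t`` in [0, 1].

    Per AU/BAP key, value = (1 - w) * prev + w * nxt with w = ease(t);
    keys missing on one side contribute 0, so the union of both key sets
    appears in the output.
    """
    if not 0.0 <= t <= 1.0:
        raise ConfigError(f"blend progress {t} outside [0, 1]")
    w = ease(t)
    out = []
    for attr in ("au_set", "bap_set"):
        a, b = getattr(prev, attr), getattr(nxt, attr)
        merged = {
            k: (1.0 - w) * a.get(k, 0.0) + w * b.get(k, 0.0)
            for k in sorted(set(a) | set(b))
        }
        out.append(merged)
    return out[0], out[1]


class BehaviorSelector:
    """Stateful behavior choice with dwell-based round-robin variation.

    On a level change the next behavior of the new level is chosen
    immediately; if the level is held for ``dwell_s`` seconds the selector
    advances round-robin within the level (never repeating the immediately
    preceding behavior when the level offers more than one). Selection is
    fully deterministic unless a seeded ``rng`` is supplied, in which case
    the within-level choice is random (still excluding the previous id).
    """

    def __init__(
        self,
        dwell_s: float = 2.0,
        specs: Sequence[BehaviorSpec] = BEHAVIORS,
        rng: np.random.Generator | None = None,
    ):
        self.dwell_s = dwell_s
        self.by_level = behaviors_by_level(specs)
        for lvl, lst in self.by_level.items():
            if not lst:
                raise ConfigError(f"no behavior for level {lvl.name}")
        self.rng = rng
        self._level: EngagementLevel | None = None
        self._pos: dict[EngagementLevel, int] = {
            lvl: 0 for lvl in self.by_level
        }
        self._since: float = 0.0
        self.current: BehaviorSpec | None = None

    def _advance(self, level: EngagementLevel) -> BehaviorSpec:
        pool = self.by_level[level]
        if len(pool) == 1:
            return pool[0]
        if self.rng is not None:
            choices = [s for s in pool if self.current is None
                       or s.id != self.current.id]
            return choices[self.rng.integers(len(choices))]
        i = self._pos[level]
        cand = pool[i % len(pool)]
        if self.current is not None and cand.id == self.current.id:
            i += 1
            cand = pool[i % len(pool)]
        self._pos[level] = i + 1
        return cand

    def step(self, level: EngagementLevel, t: float) -> tuple[BehaviorSpec, bool]:
        """Advance to time ``t``; returns (active behavior, changed-now flag)."""
        if self._level is None or level != self._level:
            self._level = level
            self.current = self._advance(level)
            self._since = t
            return self.current, True
        if (t - self._since >= self.dwell_s
                and len(self.by_level[level]) > 1):
            self.current = self._advance(level)
            self._since = t
            return self.current, True
        return self.current, False


def generate_timeline(
    scores: np.ndarray,
    score_fs: float = 2.0,
    render_fps: float = 25.0,
    transition_s: float = 1.0,
    dwell_s: float = 2.0,
    bins=DEFAULT_BINS,
    specs: Sequence[BehaviorSpec] = BEHAVIORS,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Render a feedback-score stream into an AU/BAP frame timeline.

    The 2 Hz score is held between ticks (zero-order hold); every behavior
    change starts a ``transition_s`` cross-fade from the previous frame's
    behavior; frames are emitted at ``render_fps``. Columns: ``frame_time_s``,
    ``behavior_id``, then one column per AU code and BAP name that any
    shipped behavior uses.
    """
    scores = np.asarray(scores, dtype=float)
    au_keys = sorted({k for s in specs for k in s.au_set})
    bap_keys = sorted({k for s in specs for k in s.bap_set})
    cols = ["frame_time_s", "behavior_id"] + au_keys + bap_keys
    if scores.size == 0:
        return pd.DataFrame(columns=cols)

    selector = BehaviorSelector(dwell_s, specs, rng)
    n_frames = int(round(scores.size / score_fs * render_fps))
    rows = []
    prev_spec: BehaviorSpec | None = None
    switch_t = 0.0
    for f in range(n_frames):
        t = f / render_fps
        score = scores[min(int(t * score_fs), scores.size - 1)]
        level = quantize_engagement(score, bins)
        before = selector.current
        active, changed = selector.step(level, t)
        if changed:
            prev_spec = before if before is not None else active
            switch_t = t
        u = 1.0 if transition_s <= 0 else min((t - switch_t) / transition_s, 1.0)
        au, bap = blend_behaviors(prev_spec or active, active, u)
        row = [t, active.id]
        row += [au.get(k, 0.0) for k in au_keys]
        row += [bap.get(k, 0.0) for k in bap_keys]
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)
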