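"""Fishing-game state machine.

A fish appears in one of three depth lanes; deeper fish need more reels
(lane 1 -> 1 reel, lane 2 -> 2, lane 3 -> 3) and any fish escapes after
three unreels.  Each trial is a 2-s preparation phase followed by a 2-s
input window; the window closes at MI detection or at timeout, and the
resolved feedback advances the encounter: positive reels one lane,
extra-positive (augmented) two, neutral holds position, negative unreels.
Hook positioning by arrow keys is abstracted away (the simulated player
always hooks correctly).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .decoder import DetectionResult

__all__ = ["FeedbackKind", "EncounterState", "GameConfig", "FishEncounter",
           "TrialTiming", "apply_feedback", "run_trial_timeline", "spawn_fish"]


class FeedbackKind(Enum):
    POSITIVE = "positive"
    EXTRA_POSITIVE = "extra_positive"
    NEUTRAL = "neutral"
    NEGATIVE = "negative"


class EncounterState(Enum):
    HOOKED = "hooked"
    CAUGHT = "caught"
    ESCAPED = "escaped"


@dataclass(frozen=True)
class GameConfig:
    n_lanes: int = 3
    reels_to_catch_by_depth: tuple[int, ...] = (1, 2, 3)  # lane 1..3
    unreels_to_escape: int = 3
    prep_duration: float = 2.0
    input_window: float = 2.0
    post_key_delay: float = 2.0

    def __post_init__(self) -> None:
        if self.n_lanes < 1 or len(self.reels_to_catch_by_depth) != self.n_lanes:
            raise ValueError("need one reel requirement per lane")
        if min(self.reels_to_catch_by_depth) < 1 or self.unreels_to_escape < 1:
            raise ValueError("counts must be >= 1")
        if min(self.prep_duration, self.input_window, self.post_key_delay) <= 0:
            raise ValueError("durations must be positive")

    def reels_needed(self, lane: int) -> int:
        return self.reels_to_catch_by_depth[lane - 1]


@dataclass(frozen=True)
class FishEncounter:
    depth_lane: int
    reel_progress: int = 0
    unreel_count: int = 0
    state: EncounterState = EncounterState.HOOKED


@dataclass(frozen=True)
class TrialTiming:
    prep_start: float = 0.0
    window_open: float = 2.0
    window_close: float = 4.0


def spawn_fish(rng: np.random.Generator, cfg: GameConfig | None = None) -> FishEncounter:
    """Hook a fresh fish in a uniformly random lane."""
    cfg = cfg or GameConfig()
    lane = int(rng.integers(1, cfg.n_lanes + 1))
    return FishEncounter(depth_lane=lane)


def apply_feedback(enc: FishEncounter, fb: FeedbackKind,
                   cfg: GameConfig | None = None) -> FishEncounter:
    """Advance an encounter by one resolved trial's feedback.

    Extra-positive progress caps at the catch requirement (no carry-over);
    state transitions are applied after the increment.
    """
    cfg = cfg or GameConfig()
    if enc.state is not EncounterState.HOOKED:
        raise ValueError(f"cannot apply feedback to a {enc.state.value} encounter")
    need = cfg.reels_needed(enc.depth_lane)
    reel, unreel = enc.reel_progress, enc.unreel_count
    if fb is FeedbackKind.POSITIVE:
        reel = min(reel + 1, need)
    elif fb is FeedbackKind.EXTRA_POSITIVE:
        reel = min(reel + 2, need)
    elif fb is FeedbackKind.NEGATIVE:
        unreel += 1
    state = EncounterState.HOOKED
    if reel >= need:
        state = EncounterState.CAUGHT
    elif unreel >= cfg.unreels_to_escape:
        state = EncounterState.ESCAPED
    return replace(enc, reel_progress=reel, unreel_count=unreel, state=state)


def run_trial_timeline(cfg: GameConfig, detection: DetectionResult
                       ) -> tuple[bool, TrialTiming]:
    """Resolve one trial attempt from a detection result.

    Success iff MI was detected; the input window closes at the detection
    latency, or at its full length when nothing was detected.
    """
    open_t = cfg.prep_duration
    if detection.detected:
        close = open_t + min(detection.latency, cfg.input_window)
        return True, TrialTiming(0.0, open_t, close)
    return False, TrialTiming(0.0, open_t, open_t + cfg.input_window)
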