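"""Per-condition summary variables and Likert recoding.

Reduces a condition's trial logs and fish encounters to the explanatory
variables of the analysis: MI conversion rate (fraction of trials whose
outcome the user genuinely caused), positive-feedback rate (fraction of
trials delivering a positive outcome, whatever its cause), help (PAM) rate,
and the fish/reel counts.  All rates are over the condition's 20 trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SessionRecord", "RatingRecord", "recode_rating", "normalize_rating",
           "summarize_condition"]


def recode_rating(normalized):
    """Map a 0-1 normalized 7-point rating back to its ordinal level 1-7.

    Inverse of ``(level - 1) / 6``; round-half-up so the printed two-decimal
    grid values (0.17, 0.33, ...) land on their exact levels.
    """
    arr = np.asarray(normalized, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("normalized ratings must lie in [0, 1]")
    levels = np.floor(1.0 + 6.0 * arr + 0.5).astype(int)
    levels = np.clip(levels, 1, 7)
    return levels if levels.ndim else int(levels)


def normalize_rating(level):
    """Map ordinal level 1-7 to the 0-1 display scale."""
    arr = np.asarray(level, dtype=float)
    if np.any((arr < 1) | (arr > 7) | (arr != np.round(arr))):
        raise ValueError("levels must be integers in [1, 7]")
    out = (arr - 1.0) / 6.0
    return out if out.ndim else float(out)


@dataclass
class RatingRecord:
    """Post-condition 7-point Likert ratings."""

    perceived_control: int
    frustration: int

    def __post_init__(self) -> None:
        for v in (self.perceived_control, self.frustration):
            if not (isinstance(v, (int, np.integer)) and 1 <= v <= 7):
                raise ValueError(f"rating level {v!r} outside 1..7")


@dataclass
class SessionRecord:
    """One participant-condition row of explanatory variables."""

    participant: str | int
    condition: str
    mi_conversion_rate: float
    positive_feedback: float
    pam_rate: float
    fish_caught: int
    fish_lost: int
    fish_reel: int
    fish_unreel: int

    def __post_init__(self) -> None:
        for name in ("mi_conversion_rate", "positive_feedback", "pam_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("fish_caught", "fish_lost", "fish_reel", "fish_unreel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} negative")


def summarize_condition(trials, encounters, participant="sim",
                        condition: str | None = None) -> SessionRecord:
    """Reduce one condition's trial logs + encounters to a SessionRecord.

    An extra-positive (augmented) outcome counts as a single positive trial
    for the positive-feedback rate but advances the reel count by two.  Any
    encounter not caught (escaped, or still hooked when trials ran out)
    counts as lost.
    """
    from .game import EncounterState, FeedbackKind
    from .scheduler import TrialBehavior

    if not trials:
        raise ValueError("empty trial list")
    n = len(trials)
    mi = sum(t.attempt for t in trials) / n
    pos = sum(t.feedback in (FeedbackKind.POSITIVE, FeedbackKind.EXTRA_POSITIVE)
              for t in trials) / n
    pam = sum(t.behavior is TrialBehavior.SPECIAL for t in trials) / n
    reel = sum(2 if t.feedback is FeedbackKind.EXTRA_POSITIVE
               else 1 if t.feedback is FeedbackKind.POSITIVE else 0 for t in trials)
    unreel = sum(t.feedback is FeedbackKind.NEGATIVE for t in trials)
    caught = sum(e.state is EncounterState.CAUGHT for e in encounters)
    lost = len(encounters) - caught
    cond = condition or (trials[0].condition if hasattr(trials[0], "condition") else "?")
    return SessionRecord(participant=participant, condition=cond,
                         mi_conversion_rate=mi, positive_feedback=pos, pam_rate=pam,
                         fish_caught=caught, fish_lost=lost,
                         fish_reel=reel, fish_unreel=unreel)
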