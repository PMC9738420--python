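"""Urn-model trial scheduler for the helped (PAM) conditions.

Each condition is 20 trials.  Helped conditions are planned with 30% special
(help) trials shuffled among normal trials; after every resolved trial the
urn re-evaluates the remaining plan: forced rejections are inserted when the
player's projected positive-feedback fraction would exceed the 70% control
cap, and an augmented-success special that failed to trigger (it needs a
genuine success) is re-inserted uniformly among the remaining slots.

Outcome-change bookkeeping follows the help taxonomy: e.g. an input-override
special on a failed attempt is logged "Negative to Positive (IO)", a forced
rejection of a success "Positive to Negative".

Two scheduler modes exist: ``experiment`` (input-override and
mitigated-failure specials disregard the user's input, guaranteeing the help
quota) and ``deployment`` (those specials only trigger on failed attempts
and are rescheduled otherwise, like augmented success).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable

import numpy as np

from .game import (EncounterState, FeedbackKind, FishEncounter, GameConfig,
                   apply_feedback, spawn_fish)

__all__ = ["PamKind", "TrialBehavior", "UrnState", "ConditionPlan", "TrialLog",
           "ConditionResult", "plan_condition", "resolve_attempt",
           "replan_after_failure", "enforce_control_cap", "condition_order",
           "run_condition"]


class PamKind(Enum):
    NONE = "none"
    AUGMENTED_SUCCESS = "augmented_success"
    MITIGATED_FAILURE = "mitigated_failure"
    INPUT_OVERRIDE = "input_override"


class TrialBehavior(Enum):
    NORMAL = "normal"
    REJECT = "reject"
    SPECIAL = "special"


@dataclass
class UrnState:
    """Running counts the urn keeps while a condition plays out."""

    n_trials: int = 20
    help_target: float = 0.30
    control_cap: float = 0.70
    positive: int = 0
    negative: int = 0
    neutral: int = 0
    special: int = 0          # specials actually delivered
    successes: int = 0        # genuine BCI successes observed
    trials_done: int = 0
    dropped_specials: int = 0

    @property
    def remaining(self) -> int:
        return self.n_trials - self.trials_done

    @property
    def max_positive(self) -> int:
        # hard ceiling: final positive fraction may not exceed cap + 1/n
        return int(np.floor(self.control_cap * self.n_trials)) + 1


@dataclass
class ConditionPlan:
    """Ordered trial behaviors with a play cursor; mutated by replanning."""

    behaviors: list[TrialBehavior]
    cursor: int = 0

    def current(self) -> TrialBehavior:
        return self.behaviors[self.cursor]

    def remaining_indices(self, kind: TrialBehavior | None = None,
                          include_current: bool = False) -> list[int]:
        """Indices of unplayed slots.  During trial resolution the cursor
        slot is in play and excluded; after the cursor has advanced the slot
        at the cursor is the next unplayed one (``include_current=True``)."""
        idx = range(self.cursor if include_current else self.cursor + 1,
                    len(self.behaviors))
        if kind is None:
            return list(idx)
        return [i for i in idx if self.behaviors[i] is kind]

    def pending_special(self) -> int:
        return sum(b is TrialBehavior.SPECIAL
                   for b in self.behaviors[self.cursor:])


@dataclass
class TrialLog:
    trial: int
    behavior: TrialBehavior      # behavior as resolved (AS misfire -> NORMAL)
    pam: PamKind
    attempt: bool                # genuine BCI outcome
    feedback: FeedbackKind
    change_label: str
    condition: str = ""


@dataclass
class ConditionResult:
    pam: PamKind
    trials: list[TrialLog]
    encounters: list[FishEncounter]
    urn: UrnState
    seed: int


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def plan_condition(pam: PamKind, urn: UrnState,
                   rng: np.random.Generator | int) -> ConditionPlan:
    """Plan a fresh condition: specials uniformly shuffled among normals.

    The reference condition is all normal trials; helped conditions get
    ``round(help_target * n_trials)`` specials (round half up, exact 6 for
    the 30%-of-20 default).
    """
    if urn.trials_done:
        raise ValueError("urn must be freshly initialized")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if pam is PamKind.NONE:
        return ConditionPlan([TrialBehavior.NORMAL] * urn.n_trials)
    n_special = _round_half_up(urn.help_target * urn.n_trials)
    behaviors = ([TrialBehavior.SPECIAL] * n_special
                 + [TrialBehavior.NORMAL] * (urn.n_trials - n_special))
    rng.shuffle(behaviors)
    return ConditionPlan(behaviors)


def replan_after_failure(plan: ConditionPlan, urn: UrnState,
                         rng: np.random.Generator) -> bool:
    """Re-insert an augmented-success special that failed to trigger.

    The current slot has already resolved as a normal failure; the owed
    special moves to a uniformly random remaining normal slot.  Returns
    False (and logs the deficit on the urn) when no slot remains.
    """
    slots = plan.remaining_indices(TrialBehavior.NORMAL)
    if not slots:
        urn.dropped_specials += 1
        return False
    plan.behaviors[int(rng.choice(slots))] = TrialBehavior.SPECIAL
    return True


def _success_rate(urn: UrnState) -> float:
    """Shrunk running success-rate estimate (two pseudo-failures).

    The shrinkage keeps one early lucky success from projecting a weak user
    over the cap; the estimate still converges to the true rate, so strong
    users are capped in time.
    """
    return urn.successes / (urn.trials_done + 2)


def _projected_positive(plan: ConditionPlan, urn: UrnState, pam: PamKind) -> float:
    """Project the final positive-trial count assuming the user keeps
    succeeding at the observed (shrunk) rate."""
    rate = _success_rate(urn)
    n_norm = len(plan.remaining_indices(TrialBehavior.NORMAL, include_current=True))
    n_spec = plan.pending_special()
    if pam is PamKind.INPUT_OVERRIDE:
        spec_pos = float(n_spec)            # IO delivers positive regardless
    elif pam is PamKind.AUGMENTED_SUCCESS:
        spec_pos = rate * n_spec            # AS needs a genuine success
    else:
        spec_pos = 0.0                      # MF delivers neutral
    return urn.positive + rate * n_norm + spec_pos


def enforce_control_cap(plan: ConditionPlan, urn: UrnState, pam: PamKind,
                        rng: np.random.Generator,
                        projector: Callable[..., float] = _projected_positive) -> int:
    """Convert upcoming normal slots to forced rejections when the projected
    positive-feedback fraction would exceed the control cap.

    Called after each resolved trial in helped conditions; special slots are
    never converted.  The projection strategy is injectable.  Returns the
    number of slots converted.
    """
    if pam is PamKind.NONE:
        return 0
    converted = 0
    # hard backstop: specials cannot be converted, so once the delivered
    # positives plus the remaining positive-capable specials reach the
    # ceiling, every remaining normal slot must become a rejection.
    capable = (plan.pending_special()
               if pam in (PamKind.INPUT_OVERRIDE, PamKind.AUGMENTED_SUCCESS) else 0)
    if urn.positive + capable >= urn.max_positive:
        for i in plan.remaining_indices(TrialBehavior.NORMAL, include_current=True):
            plan.behaviors[i] = TrialBehavior.REJECT
            converted += 1
        return converted
    if _success_rate(urn) <= 0.0:
        return 0
    while True:
        projected = projector(plan, urn, pam)
        if projected <= urn.max_positive + 1e-9:
            break
        slots = plan.remaining_indices(TrialBehavior.NORMAL, include_current=True)
        if not slots:
            break
        plan.behaviors[int(rng.choice(slots))] = TrialBehavior.REJECT
        converted += 1
    return converted


def resolve_attempt(plan: ConditionPlan, urn: UrnState, pam: PamKind,
                    attempt: bool, rng: np.random.Generator,
                    mode: str = "experiment") -> TrialLog:
    """Resolve the current trial slot against the user's genuine attempt.

    Applies the outcome-change taxonomy, updates the urn counts, reschedules
    specials that could not trigger, and advances the plan cursor.
    """
    if plan.cursor >= len(plan.behaviors):
        raise ValueError("no trial slots remain")
    if mode not in ("experiment", "deployment"):
        raise ValueError(f"unknown scheduler mode {mode!r}")
    behavior = plan.current()
    if behavior is TrialBehavior.SPECIAL and pam is PamKind.NONE:
        raise ValueError("special trial scheduled in the reference condition")

    resolved = behavior
    if behavior is TrialBehavior.SPECIAL:
        needs_reschedule = (
            (pam is PamKind.AUGMENTED_SUCCESS and not attempt)
            or (mode == "deployment" and attempt
                and pam in (PamKind.INPUT_OVERRIDE, PamKind.MITIGATED_FAILURE)))
        if needs_reschedule:
            replan_after_failure(plan, urn, rng)
            resolved = TrialBehavior.NORMAL

    if resolved is TrialBehavior.NORMAL:
        if attempt:
            feedback, label = FeedbackKind.POSITIVE, "Positive (No Change)"
        else:
            feedback, label = FeedbackKind.NEGATIVE, "Negative (No Change)"
    elif resolved is TrialBehavior.REJECT:
        feedback = FeedbackKind.NEGATIVE
        label = "Positive to Negative" if attempt else "Negative (No Change)"
    else:  # SPECIAL that triggers
        if pam is PamKind.INPUT_OVERRIDE:
            feedback = FeedbackKind.POSITIVE
            label = ("Positive to Positive (IO)" if attempt
                     else "Negative to Positive (IO)")
        elif pam is PamKind.MITIGATED_FAILURE:
            feedback = FeedbackKind.NEUTRAL
            label = ("Positive to Neutral (MF)" if attempt
                     else "Negative to Neutral (MF)")
        else:  # AUGMENTED_SUCCESS, attempt is True here
            feedback = FeedbackKind.EXTRA_POSITIVE
            label = "Positive to Extra Positive (AS)"

    urn.trials_done += 1
    urn.successes += int(attempt)
    if feedback in (FeedbackKind.POSITIVE, FeedbackKind.EXTRA_POSITIVE):
        urn.positive += 1
    elif feedback is FeedbackKind.NEUTRAL:
        urn.neutral += 1
    else:
        urn.negative += 1
    if resolved is TrialBehavior.SPECIAL:
        urn.special += 1
    log = TrialLog(trial=urn.trials_done, behavior=resolved, pam=pam,
                   attempt=attempt, feedback=feedback, change_label=label,
                   condition=pam.value)
    plan.cursor += 1
    if plan.pending_special() > len(plan.behaviors) - plan.cursor:
        raise AssertionError("more specials scheduled than slots remain")
    return log


def condition_order(participant_index: int) -> list[PamKind]:
    """Condition sequence: reference first, then a 3x3 Latin-square rotation
    of the three help conditions indexed by participant."""
    if participant_index < 0:
        raise ValueError("participant index must be >= 0")
    pams = [PamKind.AUGMENTED_SUCCESS, PamKind.INPUT_OVERRIDE,
            PamKind.MITIGATED_FAILURE]
    r = participant_index % 3
    return [PamKind.NONE] + pams[r:] + pams[:r]


def run_condition(pam: PamKind, attempt_rate: float | None = None,
                  attempt_fn: Callable[[], bool] | None = None,
                  seed: int = 0, mode: str = "experiment",
                  cfg: GameConfig | None = None,
                  urn: UrnState | None = None) -> ConditionResult:
    """Play one full 20-trial condition.

    The attempt model is either Bernoulli(``attempt_rate``) or an arbitrary
    callable (e.g. a :class:`~bcipam.decoder.SimulatedBCIUser`).  A fish
    still hooked when the trials run out counts as lost.
    """
    if (attempt_rate is None) == (attempt_fn is None):
        raise ValueError("provide exactly one of attempt_rate / attempt_fn")
    if attempt_rate is not None and not 0.0 <= attempt_rate <= 1.0:
        raise ValueError("attempt_rate must lie in [0, 1]")
    cfg = cfg or GameConfig()
    urn = urn or UrnState()
    rng = np.random.default_rng(seed)
    plan = plan_condition(pam, urn, rng)
    trials: list[TrialLog] = []
    encounters: list[FishEncounter] = []
    current: FishEncounter | None = None
    for _ in range(urn.n_trials):
        if current is None or current.state is not EncounterState.HOOKED:
            current = spawn_fish(rng, cfg)
            encounters.append(current)
        attempt = (bool(rng.random() < attempt_rate) if attempt_rate is not None
                   else bool(attempt_fn()))
        log = resolve_attempt(plan, urn, pam, attempt, rng, mode=mode)
        trials.append(log)
        current = apply_feedback(current, log.feedback, cfg)
        encounters[-1] = current
        enforce_control_cap(plan, urn, pam, rng)
    # trials exhausted: a still-hooked final fish escapes
    if current is not None and current.state is EncounterState.HOOKED:
        from dataclasses import replace
        encounters[-1] = replace(current, state=EncounterState.ESCAPED)
    return ConditionResult(pam=pam, trials=trials, encounters=encounters,
                           urn=urn, seed=seed)
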