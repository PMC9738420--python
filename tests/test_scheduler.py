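from collections import Counter

import numpy as np
import pytest

from bcipam.game import FeedbackKind
from bcipam.metrics import summarize_condition
from bcipam.scheduler import (ConditionPlan, PamKind, TrialBehavior, UrnState,
                              condition_order, enforce_control_cap,
                              plan_condition, replan_after_failure,
                              resolve_attempt, run_condition)

HELPED = [PamKind.AUGMENTED_SUCCESS, PamKind.INPUT_OVERRIDE,
          PamKind.MITIGATED_FAILURE]


class TestPlanning:
    @pytest.mark.parametrize("pam", HELPED)
    def test_helped_plans_have_exactly_six_specials(self, pam):
        for seed in range(50):
            plan = plan_condition(pam, UrnState(), seed)
            assert sum(b is TrialBehavior.SPECIAL for b in plan.behaviors) == 6
            assert len(plan.behaviors) == 20

    def test_reference_plan_all_normal(self):
        plan = plan_condition(PamKind.NONE, UrnState(), 0)
        assert all(b is TrialBehavior.NORMAL for b in plan.behaviors)

    def test_seeds_permute_same_multiset(self):
        a = plan_condition(PamKind.INPUT_OVERRIDE, UrnState(), 1)
        b = plan_condition(PamKind.INPUT_OVERRIDE, UrnState(), 2)
        assert Counter(a.behaviors) == Counter(b.behaviors)
        assert a.behaviors != b.behaviors  # generally a different order

    def test_used_urn_rejected(self):
        urn = UrnState(trials_done=3)
        with pytest.raises(ValueError):
            plan_condition(PamKind.NONE, urn, 0)

    def test_round_half_up_for_other_configs(self):
        plan = plan_condition(PamKind.INPUT_OVERRIDE,
                              UrnState(n_trials=15, help_target=0.30), 0)
        # 0.30 * 15 = 4.5 -> 5 specials
        assert sum(b is TrialBehavior.SPECIAL for b in plan.behaviors) == 5


class TestResolution:
    @pytest.mark.parametrize("behavior,pam,attempt,feedback,label", [
        (TrialBehavior.NORMAL, PamKind.NONE, True,
         FeedbackKind.POSITIVE, "Positive (No Change)"),
        (TrialBehavior.NORMAL, PamKind.NONE, False,
         FeedbackKind.NEGATIVE, "Negative (No Change)"),
        (TrialBehavior.REJECT, PamKind.INPUT_OVERRIDE, True,
         FeedbackKind.NEGATIVE, "Positive to Negative"),
        (TrialBehavior.REJECT, PamKind.INPUT_OVERRIDE, False,
         FeedbackKind.NEGATIVE, "Negative (No Change)"),
        (TrialBehavior.SPECIAL, PamKind.INPUT_OVERRIDE, False,
         FeedbackKind.POSITIVE, "Negative to Positive (IO)"),
        (TrialBehavior.SPECIAL, PamKind.INPUT_OVERRIDE, True,
         FeedbackKind.POSITIVE, "Positive to Positive (IO)"),
        (TrialBehavior.SPECIAL, PamKind.MITIGATED_FAILURE, False,
         FeedbackKind.NEUTRAL, "Negative to Neutral (MF)"),
        (TrialBehavior.SPECIAL, PamKind.MITIGATED_FAILURE, True,
         FeedbackKind.NEUTRAL, "Positive to Neutral (MF)"),
        (TrialBehavior.SPECIAL, PamKind.AUGMENTED_SUCCESS, True,
         FeedbackKind.EXTRA_POSITIVE, "Positive to Extra Positive (AS)"),
    ])
    def test_outcome_change_taxonomy(self, behavior, pam, attempt, feedback, label):
        plan = ConditionPlan([behavior] + [TrialBehavior.NORMAL] * 19)
        urn = UrnState()
        log = resolve_attempt(plan, urn, pam, attempt, np.random.default_rng(0))
        assert log.feedback is feedback
        assert log.change_label == label
        assert urn.trials_done == 1

    def test_as_failure_resolves_normal_and_reschedules(self):
        plan = ConditionPlan([TrialBehavior.SPECIAL] + [TrialBehavior.NORMAL] * 19)
        urn = UrnState()
        log = resolve_attempt(plan, urn, PamKind.AUGMENTED_SUCCESS, False,
                              np.random.default_rng(0))
        assert log.behavior is TrialBehavior.NORMAL
        assert log.feedback is FeedbackKind.NEGATIVE
        assert plan.pending_special() == 1  # still owed

    def test_as_failure_on_final_trial_drops_special(self):
        plan = ConditionPlan([TrialBehavior.NORMAL] * 19 + [TrialBehavior.SPECIAL],
                             cursor=19)
        urn = UrnState(trials_done=19)
        resolve_attempt(plan, urn, PamKind.AUGMENTED_SUCCESS, False,
                        np.random.default_rng(0))
        assert urn.dropped_specials == 1

    def test_special_in_reference_condition_raises(self):
        plan = ConditionPlan([TrialBehavior.SPECIAL] * 20)
        with pytest.raises(ValueError):
            resolve_attempt(plan, UrnState(), PamKind.NONE, True,
                            np.random.default_rng(0))

    def test_normal_success_counts_positive(self):
        plan = ConditionPlan([TrialBehavior.NORMAL] * 20)
        urn = UrnState()
        resolve_attempt(plan, urn, PamKind.NONE, True, np.random.default_rng(0))
        assert urn.positive == 1 and urn.negative == 0

    def test_deployment_mode_reschedules_specials_on_success(self):
        plan = ConditionPlan([TrialBehavior.SPECIAL] + [TrialBehavior.NORMAL] * 19)
        urn = UrnState()
        log = resolve_attempt(plan, urn, PamKind.INPUT_OVERRIDE, True,
                              np.random.default_rng(0), mode="deployment")
        assert log.feedback is FeedbackKind.POSITIVE
        assert log.behavior is TrialBehavior.NORMAL
        assert plan.pending_special() == 1


class TestControlCap:
    @pytest.mark.parametrize("pam", HELPED)
    def test_perfect_user_capped(self, pam):
        for seed in range(300):
            res = run_condition(pam, attempt_rate=1.0, seed=seed)
            rec = summarize_condition(res.trials, res.encounters)
            assert rec.positive_feedback <= 0.75 + 1e-9

    def test_always_failing_user_never_rejected(self):
        for pam in HELPED:
            for seed in range(50):
                res = run_condition(pam, attempt_rate=0.0, seed=seed)
                assert not any(t.behavior is TrialBehavior.REJECT for t in res.trials)

    def test_weak_user_rejections_vanishingly_rare(self):
        total = 0
        for seed in range(300):
            res = run_condition(PamKind.INPUT_OVERRIDE, attempt_rate=0.1, seed=seed)
            total += sum(t.behavior is TrialBehavior.REJECT for t in res.trials)
        assert total <= 0.01 * 300 * 20

    def test_reference_condition_cap_inert(self):
        for seed in range(50):
            res = run_condition(PamKind.NONE, attempt_rate=1.0, seed=seed)
            rec = summarize_condition(res.trials, res.encounters)
            assert rec.positive_feedback == 1.0  # no cap in the reference game
            assert not any(t.behavior is TrialBehavior.REJECT for t in res.trials)

    def test_cap_never_converts_specials(self):
        for seed in range(100):
            res = run_condition(PamKind.INPUT_OVERRIDE, attempt_rate=1.0, seed=seed)
            assert sum(t.behavior is TrialBehavior.SPECIAL for t in res.trials) == 6


class TestReplanInvariants:
    def test_always_failing_as_user_gets_zero_specials(self):
        for seed in range(100):
            res = run_condition(PamKind.AUGMENTED_SUCCESS, attempt_rate=0.0, seed=seed)
            rec = summarize_condition(res.trials, res.encounters)
            assert rec.pam_rate == 0.0

    def test_specials_never_exceed_remaining_slots(self, rng):
        for seed in range(50):
            urn = UrnState()
            plan = plan_condition(PamKind.AUGMENTED_SUCCESS, urn, seed)
            local = np.random.default_rng(seed)
            for _ in range(20):
                resolve_attempt(plan, urn, PamKind.AUGMENTED_SUCCESS,
                                bool(local.random() < 0.5), local)
                enforce_control_cap(plan, urn, PamKind.AUGMENTED_SUCCESS, local)
                assert plan.pending_special() <= 20 - plan.cursor

    def test_reference_condition_labels_unchanged_only(self):
        res = run_condition(PamKind.NONE, attempt_rate=0.5, seed=9)
        labels = {t.change_label for t in res.trials}
        assert labels <= {"Positive (No Change)", "Negative (No Change)"}


class TestConditionOrder:
    def test_reference_always_first_and_base_rotation(self):
        assert condition_order(0) == [PamKind.NONE, PamKind.AUGMENTED_SUCCESS,
                                      PamKind.INPUT_OVERRIDE,
                                      PamKind.MITIGATED_FAILURE]

    def test_latin_square_each_pam_each_position(self):
        rows = [condition_order(i)[1:] for i in range(3)]
        for pos in range(3):
            assert {row[pos] for row in rows} == set(HELPED)

    def test_periodicity(self):
        assert condition_order(3) == condition_order(0)


def test_cohort_normal_condition_label_frequencies(study_table):
    """Simulated cohort at the packaged conversion rates reproduces the
    no-help outcome split (57% positive / 42% negative, whole-percent)."""
    ref = study_table.complete[study_table.complete.condition == "normal"]
    rates = dict(zip(ref.participant, ref.mi_conversion_rate))
    cnt = Counter()
    for s in range(10):
        for i, (pid, rate) in enumerate(sorted(rates.items())):
            res = run_condition(PamKind.NONE, attempt_rate=rate, seed=s * 100 + i)
            for t in res.trials:
                cnt[t.change_label] += 1
    tot = sum(cnt.values())
    assert cnt["Positive (No Change)"] / tot == pytest.approx(0.575, abs=0.03)
    assert cnt["Negative (No Change)"] / tot == pytest.approx(0.425, abs=0.03)
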