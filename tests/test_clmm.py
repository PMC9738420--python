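import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from bcipam.clmm import (CumulativeLinkMixedModel, CumulativeLinkModel,
                         OrdinalDataset, build_design, forward_stepwise,
                         laplace_loglik, lr_test, simulate_clmm_data)
from bcipam.data import to_ordinal_dataset

from ._oracles import exhaustive_forward_oracle, gauss_hermite_loglik


@pytest.fixture(scope="module")
def small_sim():
    return simulate_clmm_data(n_subjects=10, n_obs=4, beta=0.6, sigma=1.0, seed=3)


class TestFixedEffectsModel:
    def test_null_thresholds_are_empirical_cutpoints(self, rng):
        y = rng.integers(1, 8, size=200)
        fit = CumulativeLinkModel().fit(np.zeros((200, 0)), y)
        cum = np.cumsum(np.bincount(y, minlength=8)[1:8])[:-1] / 200
        np.testing.assert_allclose(fit.thresholds_, logit(cum), atol=1e-5)

    def test_zero_covariate_gives_zero_beta(self, rng):
        y = rng.integers(1, 8, size=200)
        fit = CumulativeLinkModel().fit(np.zeros((200, 1)), y)
        assert fit.coef_[0] == pytest.approx(0.0, abs=1e-5)

    def test_gradient_vanishes_at_optimum(self, small_sim):
        fit = CumulativeLinkModel().fit(small_sim[["x"]], small_sim["y"])
        assert fit._grad_norm_ < 1e-6

    def test_two_level_response_is_logistic_regression(self, rng):
        x = rng.normal(size=300)
        p = 1 / (1 + np.exp(-(0.8 * x - 0.3)))
        y = (rng.random(300) < p).astype(int) + 1
        fit = CumulativeLinkModel().fit(x[:, None], y)
        sm = pytest.importorskip("statsmodels.api")
        glm = sm.Logit(y - 1, sm.add_constant(x)).fit(disp=0)
        # P(y=2) = logistic(x beta - theta): slope matches, threshold = -const
        assert fit.coef_[0] == pytest.approx(glm.params[1], abs=1e-4)
        assert fit.thresholds_[0] == pytest.approx(-glm.params[0], abs=1e-4)

    def test_matches_statsmodels_ordered_model(self, small_sim):
        om = pytest.importorskip("statsmodels.miscmodels.ordinal_model")
        fit = CumulativeLinkModel().fit(small_sim[["x"]], small_sim["y"])
        sm_fit = om.OrderedModel(small_sim["y"], small_sim[["x"]],
                                 distr="logit").fit(method="bfgs", disp=0)
        assert fit.loglik_ == pytest.approx(sm_fit.llf, abs=1e-4)
        assert fit.coef_[0] == pytest.approx(sm_fit.params["x"], abs=1e-3)


class TestMixedModel:
    def test_sigma_to_zero_recovers_fixed_fit(self, small_sim):
        X = small_sim[["x"]].to_numpy()
        y = small_sim["y"].to_numpy()
        fixed = CumulativeLinkModel().fit(X, y)
        ll0 = laplace_loglik(X, y, small_sim["subject"], fixed.thresholds_,
                             fixed.coef_, sigma=1e-6)
        assert ll0 == pytest.approx(fixed.loglik_, abs=1e-6)

    def test_laplace_close_to_gauss_hermite(self):
        """Laplace evaluation agrees with 50-node quadrature at known
        parameters on small random-intercept datasets."""
        theta = np.linspace(-2.5, 2.5, 6)
        levels = np.arange(1, 8)
        for seed in range(4):
            df = simulate_clmm_data(n_subjects=10, n_obs=4, beta=0.6,
                                    sigma=0.5, seed=seed)
            args = (df[["x"]], df["y"], df["subject"], theta, [0.6], 0.5)
            lap = laplace_loglik(*args, levels=levels)
            gh = gauss_hermite_loglik(*args, levels=levels)
            assert lap == pytest.approx(gh, abs=0.05)

    def test_aic_identity_and_parameter_count(self, small_sim):
        fit = CumulativeLinkMixedModel().fit(small_sim[["x"]].to_numpy(),
                                             small_sim["y"].to_numpy(),
                                             small_sim["subject"].to_numpy())
        J = len(np.unique(small_sim["y"]))
        assert fit.k_ == (J - 1) + 1 + 1
        assert fit.aic_ == 2 * fit.k_ - 2 * fit.loglik_  # identity, exact

    def test_thresholds_strictly_increasing(self, small_sim):
        fit = CumulativeLinkMixedModel().fit(small_sim[["x"]].to_numpy(),
                                             small_sim["y"].to_numpy(),
                                             small_sim["subject"].to_numpy())
        assert np.all(np.diff(fit.thresholds_) > 0)

    def test_monotone_relabel_invariance(self, study_table):
        """Relabeling ordinal levels by a strictly monotone map leaves the
        likelihood and AIC unchanged."""
        ds = to_ordinal_dataset(study_table, "frustration", ["fish_lost"])
        fit = CumulativeLinkMixedModel().fit(ds.covariates.to_numpy(),
                                             ds.response, ds.group)
        relabeled = np.array([1, 2, 5, 10, 11, 20, 40])[ds.response - 1]
        fit2 = CumulativeLinkMixedModel().fit(ds.covariates.to_numpy(),
                                              relabeled, ds.group)
        assert fit2.loglik_ == pytest.approx(fit.loglik_, abs=1e-4)
        assert fit2.aic_ == pytest.approx(fit.aic_, abs=1e-3)

    def test_single_group_rejected(self, small_sim):
        with pytest.raises(ValueError):
            CumulativeLinkMixedModel().fit(small_sim[["x"]].to_numpy(),
                                           small_sim["y"].to_numpy(),
                                           np.zeros(len(small_sim)))


class TestLRTest:
    def test_identical_fits_give_zero(self, small_sim):
        fit = CumulativeLinkMixedModel().fit(small_sim[["x"]].to_numpy(),
                                             small_sim["y"].to_numpy(),
                                             small_sim["subject"].to_numpy())
        alt = CumulativeLinkMixedModel().fit(small_sim[["x"]].to_numpy(),
                                             small_sim["y"].to_numpy(),
                                             small_sim["subject"].to_numpy())
        alt.k_ = fit.k_ + 1  # same loglik, one extra parameter
        res = lr_test(fit, alt)
        assert res.lr == pytest.approx(0.0, abs=1e-8) and res.p == pytest.approx(1.0)

    def test_arithmetic_identity(self, study_table):
        """LR between nested study fits equals twice the loglik difference."""
        ds0 = to_ordinal_dataset(study_table, "perceived_control", ["fish_lost"])
        ds1 = to_ordinal_dataset(study_table, "perceived_control",
                                 ["fish_lost", "condition"])
        f0 = CumulativeLinkMixedModel().fit(ds0.covariates.to_numpy(),
                                            ds0.response, ds0.group)
        f1 = CumulativeLinkMixedModel().fit(ds1.covariates.to_numpy(),
                                            ds1.response, ds1.group)
        res = lr_test(f0, f1)
        assert res.df == 3
        assert res.lr == pytest.approx(2 * (f1.loglik_ - f0.loglik_))
        assert res.lr == pytest.approx(16.32, abs=0.15)

    def test_non_nested_rejected(self, small_sim):
        fit = CumulativeLinkMixedModel().fit(small_sim[["x"]].to_numpy(),
                                             small_sim["y"].to_numpy(),
                                             small_sim["subject"].to_numpy())
        with pytest.raises(ValueError):
            lr_test(fit, fit)


class TestStepwise:
    def test_first_selected_term_for_perceived_control(self, study_table):
        trace = forward_stepwise(study_table.complete, "perceived_control_level",
                                 "participant",
                                 ["fish_lost", "fish_caught", "positive_feedback",
                                  "mi_conversion_rate"])
        assert trace.selected[0] == "fish_lost"

    def test_empty_candidates_trace_only_null(self, study_table):
        trace = forward_stepwise(study_table.complete, "frustration_level",
                                 "participant", [])
        assert trace.selected == []
        assert [r["terms"] for r in trace.records] == ["<null>"]

    def test_matches_exhaustive_search_oracle(self, study_table):
        """Forward selection equals a brute-force enumeration at depth 2."""
        df = study_table.complete
        candidates = ["fish_lost", "fish_caught", "mi_conversion_rate"]
        trace = forward_stepwise(df, "frustration_level", "participant",
                                 candidates)

        def fit_fun(terms):
            X = build_design(df, terms)
            m = CumulativeLinkMixedModel()
            return m.fit(X.to_numpy(), df["frustration_level"].to_numpy(),
                         df["participant"].to_numpy())

        oracle = exhaustive_forward_oracle(fit_fun, lr_test, candidates)
        assert trace.selected[:2] == oracle[:2]


def test_simulated_data_well_formed():
    df = simulate_clmm_data(n_subjects=5, n_obs=3, seed=0)
    assert len(df) == 15
    assert set(df.columns) == {"subject", "x", "y"}
    assert df["y"].between(1, 7).all()


def test_ordinal_dataset_validates_alignment():
    with pytest.raises(ValueError):
        OrdinalDataset(response=np.array([1, 2]),
                       covariates=pd.DataFrame({"x": [1.0]}),
                       group=np.array([1, 1]))
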