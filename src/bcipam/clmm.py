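"""Cumulative link (mixed) models for ordinal Likert responses.

Implements proportional-odds regression for 7-point ratings with an optional
subject-level random intercept, the repeated-measures structure of a
within-subject game study.  The mixed model maximizes the Laplace-approximated
marginal likelihood

    L_i(theta, beta, sigma) = int prod_j P(y_ij | b) phi(b; 0, sigma^2) db

with the per-subject integral expanded to second order around the conditional
mode of ``b`` (found by damped Newton iterations).  Model comparison uses AIC
(2k - 2 logL, with the random-intercept variance always counted in k) and
likelihood-ratio chi-square tests; :func:`forward_stepwise` performs
AIC-guided forward selection gated on LR significance.

Cumulative probabilities follow the logit link:

    P(y <= j | b) = logistic(theta_j - x' beta - b),   theta_1 < ... < theta_{J-1}

so positive coefficients shift mass toward higher categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CumulativeLinkModel",
    "CumulativeLinkMixedModel",
    "OrdinalDataset",
    "LRTestResult",
    "StepwiseTrace",
    "lr_test",
    "forward_stepwise",
    "build_design",
    "simulate_clmm_data",
]

CONDITION_LEVELS = ["normal", "augmented_success", "input_override", "mitigated_failure"]


@dataclass
class OrdinalDataset:
    """Ordinal response + covariate frame + grouping factor, row-aligned."""

    response: np.ndarray
    covariates: pd.DataFrame
    group: np.ndarray

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response)
        self.group = np.asarray(self.group)
        n = len(self.response)
        if len(self.covariates) != n or len(self.group) != n:
            raise ValueError("response, covariates and group must be row-aligned")
        if np.any(pd.isna(self.response)):
            raise ValueError("missing values in the response")

    @property
    def n_levels(self) -> int:
        return len(np.unique(self.response))


def build_design(data: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Expand model terms into a numeric design frame (no intercept).

    A ``condition`` term expands to indicator contrasts for the three helped
    conditions against the ``normal`` reference level; every other term must
    name a numeric column of ``data``.
    """
    cols: dict[str, np.ndarray] = {}
    for term in terms:
        if term == "condition":
            cond = pd.Categorical(data["condition"], categories=CONDITION_LEVELS)
            if cond.isna().any():
                bad = set(data["condition"]) - set(CONDITION_LEVELS)
                raise ValueError(f"unknown condition levels: {sorted(bad)}")
            for level in CONDITION_LEVELS[1:]:
                cols[f"condition[{level}]"] = (cond == level).astype(float)
        else:
            col = pd.to_numeric(data[term], errors="raise")
            cols[term] = col.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=data.index)


# ---------------------------------------------------------------------------
# likelihood primitives
# ---------------------------------------------------------------------------

def _loglik_terms(eta: np.ndarray, y_idx: np.ndarray, theta: np.ndarray):
    """Per-observation log P(y), d/deta, d2/deta2 for the cumulative logit.

    ``y_idx`` holds 0-based category indices; ``theta`` the J-1 thresholds.
    """
    theta_ext = np.concatenate(([-np.inf], theta, [np.inf]))
    u = theta_ext[y_idx + 1] - eta
    lo = theta_ext[y_idx] - eta
    Fu, Fl = expit(u), expit(lo)
    fu = Fu * (1.0 - Fu)
    fl = Fl * (1.0 - Fl)
    fpu = fu * (1.0 - 2.0 * Fu)
    fpl = fl * (1.0 - 2.0 * Fl)
    p = np.clip(Fu - Fl, 1e-300, None)
    logp = np.log(p)
    d1 = -(fu - fl) / p
    d2 = (fpu - fpl) / p - d1 * d1
    return logp, d1, d2


def _pack(theta: np.ndarray, beta: np.ndarray, extra: list[float]) -> np.ndarray:
    incr = np.diff(theta)
    if np.any(incr <= 0):
        raise ValueError("thresholds must be strictly increasing")
    return np.concatenate(([theta[0]], np.log(incr), beta, extra))


def _unpack(psi: np.ndarray, n_thresh: int, n_beta: int):
    a1 = psi[0]
    incr = np.exp(psi[1 : n_thresh])
    theta = a1 + np.concatenate(([0.0], np.cumsum(incr)))
    beta = psi[n_thresh : n_thresh + n_beta]
    extra = psi[n_thresh + n_beta :]
    return theta, beta, extra


def _central_grad(fun, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    g = np.empty_like(x)
    for i in range(len(x)):
        step = np.zeros_like(x)
        step[i] = eps * max(1.0, abs(x[i]))
        g[i] = (fun(x + step) - fun(x - step)) / (2.0 * step[i])
    return g


def _numeric_hessian(fun, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    h = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        for j in range(i, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _start_thresholds(y_idx: np.ndarray, n_levels: int) -> np.ndarray:
    """Empirical cumulative-logit cut-points (the beta=0 ML solution)."""
    counts = np.bincount(y_idx, minlength=n_levels)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    theta = np.log(cum / (1 - cum))
    # enforce strict increase in degenerate corners
    for j in range(1, len(theta)):
        if theta[j] <= theta[j - 1]:
            theta[j] = theta[j - 1] + 1e-6
    return theta


# ---------------------------------------------------------------------------
# fixed-effects-only ordered logit
# ---------------------------------------------------------------------------

class CumulativeLinkModel(BaseEstimator):
    """Proportional-odds ordinal regression (no random effects), ML fit.

    Serves as the sigma=0 reference for the mixed model and supplies its
    starting values.  ``fit`` accepts a design matrix with no intercept
    column (the thresholds absorb location).
    """

    def __init__(self, gtol: float = 1e-8, maxiter: int = 500):
        self.gtol = gtol
        self.maxiter = maxiter

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] == 0:
            X = X.reshape(len(y), 0)
        y = np.asarray(y)
        self.levels_ = np.unique(y)
        J = len(self.levels_)
        if J < 2:
            raise ValueError("response needs at least two observed levels")
        y_idx = np.searchsorted(self.levels_, y)
        n_thresh = J - 1
        n_beta = X.shape[1]

        def nll(psi: np.ndarray) -> float:
            theta, beta, _ = _unpack(psi, n_thresh, n_beta)
            eta = X @ beta
            logp, _, _ = _loglik_terms(eta, y_idx, theta)
            return -float(logp.sum())

        psi0 = _pack(_start_thresholds(y_idx, J), np.zeros(n_beta), [])
        res = optimize.minimize(
            nll, psi0, jac=lambda p: _central_grad(nll, p),
            method="BFGS", options={"gtol": self.gtol, "maxiter": self.maxiter},
        )
        theta, beta, _ = _unpack(res.x, n_thresh, n_beta)
        self.converged_ = bool(res.success) or res.status == 2  # precision loss near optimum
        if not res.success and np.linalg.norm(res.jac) > 1e-3:
            raise RuntimeError(f"ordered logit did not converge: {res.message}")
        self.thresholds_ = theta
        self.coef_ = beta
        self.loglik_ = -float(res.fun)
        self.k_ = n_thresh + n_beta
        self.aic_ = 2.0 * self.k_ - 2.0 * self.loglik_
        self._psi_ = res.x
        self._grad_norm_ = float(np.linalg.norm(_central_grad(nll, res.x)))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "thresholds_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        eta = X @ self.coef_
        theta_ext = np.concatenate(([-np.inf], self.thresholds_, [np.inf]))
        cum = expit(theta_ext[None, :] - eta[:, None])
        return np.diff(cum, axis=1)


# ---------------------------------------------------------------------------
# Laplace-approximated mixed model
# ---------------------------------------------------------------------------

class CumulativeLinkMixedModel(BaseEstimator):
    """Cumulative logit model with a subject random intercept, Laplace ML.

    Parameters
    ----------
    n_starts : int
        Number of optimizer starts; the first uses the fixed-effects solution
        with sigma = 1, the rest jitter it (seeded) to guard against local
        optima.
    seed : int
        Seed for the start-value jitter only; the fit itself is deterministic.
    inner_tol : float
        Convergence tolerance (max gradient) for the per-subject Newton
        solve of the conditional modes.
    gtol : float
        Outer gradient tolerance for the quasi-Newton maximization.

    Attributes
    ----------
    thresholds_ : (J-1,) strictly increasing cut-points.
    coef_ : fixed-effect estimates (log odds per unit covariate).
    sigma_ : random-intercept standard deviation.
    loglik_ : maximized Laplace marginal log-likelihood.
    k_ : parameter count (J-1 thresholds + len(coef_) + 1 variance).
    aic_ : 2 k_ - 2 loglik_.
    bse_, zvalues_, pvalues_ : Wald statistics for the fixed effects.
    ranef_ : conditional modes of the subject intercepts.
    boundary_ : True when sigma_ collapsed to (numerically) zero.
    """

    def __init__(self, n_starts: int = 3, seed: int = 0, inner_tol: float = 1e-10,
                 gtol: float = 1e-6, maxiter: int = 500, jitter: float = 0.2):
        self.n_starts = n_starts
        self.seed = seed
        self.inner_tol = inner_tol
        self.gtol = gtol
        self.maxiter = maxiter
        self.jitter = jitter

    # -- Laplace machinery ----------------------------------------------

    def _solve_modes(self, eta0, y_idx, theta, s2, g_idx, n_groups):
        """Per-group Newton for the conditional modes; returns (b, pll, curv).

        pll is each group's penalized log-likelihood at the mode (without the
        Gaussian normalizing constant), curv the negative second derivative.
        """
        b = np.zeros(n_groups)

        def parts(bvec):
            logp, d1, d2 = _loglik_terms(eta0 + bvec[g_idx], y_idx, theta)
            pll = np.bincount(g_idx, weights=logp, minlength=n_groups) - bvec**2 / (2 * s2)
            g1 = np.bincount(g_idx, weights=d1, minlength=n_groups) - bvec / s2
            g2 = np.bincount(g_idx, weights=d2, minlength=n_groups) - 1.0 / s2
            return pll, g1, g2

        pll, g1, g2 = parts(b)
        for _ in range(100):
            if np.max(np.abs(g1)) < self.inner_tol:
                break
            step = -g1 / g2  # g2 < 0: log-concave likelihood
            damp = np.ones(n_groups)
            for _ in range(30):  # per-group step halving
                b_new = b + damp * step
                pll_new, g1_new, g2_new = parts(b_new)
                worse = pll_new < pll - 1e-12
                if not np.any(worse):
                    break
                damp[worse] *= 0.5
            b, pll, g1, g2 = b_new, pll_new, g1_new, g2_new
        return b, pll, -g2

    def _laplace_nll(self, psi, X, y_idx, g_idx, n_groups, n_thresh, n_beta):
        theta, beta, extra = _unpack(psi, n_thresh, n_beta)
        s2 = float(np.exp(2.0 * extra[0]))
        eta0 = X @ beta
        b, pll, curv = self._solve_modes(eta0, y_idx, theta, s2, g_idx, n_groups)
        # log L_i = pll_i - 0.5 log(sigma^2 * curv_i)
        ll = pll.sum() - 0.5 * np.sum(np.log(s2 * curv))
        self._last_modes_ = b
        return -float(ll)

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y, groups):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.size == 0:
            X = X.reshape(len(y), 0)
        y = np.asarray(y)
        groups = np.asarray(groups)
        uniq_groups, g_idx = np.unique(groups, return_inverse=True)
        if len(uniq_groups) < 2:
            raise ValueError("need at least two groups for a random intercept")
        self.levels_ = np.unique(y)
        J = len(self.levels_)
        y_idx = np.searchsorted(self.levels_, y)
        n_thresh, n_beta = J - 1, X.shape[1]
        n_groups = len(uniq_groups)

        fixed = CumulativeLinkModel().fit(X, y)
        psi0 = _pack(fixed.thresholds_, fixed.coef_, [0.0])  # log sigma = 0

        nll = lambda p: self._laplace_nll(p, X, y_idx, g_idx, n_groups, n_thresh, n_beta)
        rng = np.random.default_rng(self.seed)
        best = None
        for s in range(self.n_starts):
            start = psi0 if s == 0 else psi0 + rng.normal(0.0, self.jitter, len(psi0))
            res = optimize.minimize(
                nll, start, jac=lambda p: _central_grad(nll, p),
                method="L-BFGS-B",
                bounds=[(None, None)] * (n_thresh + n_beta) + [(-8.0, 8.0)],
                options={"maxiter": self.maxiter, "ftol": 1e-13, "gtol": self.gtol},
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res

        theta, beta, extra = _unpack(best.x, n_thresh, n_beta)
        self.thresholds_ = theta
        self.coef_ = beta
        self.sigma_ = float(np.exp(extra[0]))
        self.loglik_ = -float(best.fun)
        self.k_ = n_thresh + n_beta + 1
        self.aic_ = 2.0 * self.k_ - 2.0 * self.loglik_
        self.converged_ = bool(best.success)
        self.boundary_ = self.sigma_ < 1e-3
        self.groups_ = uniq_groups
        nll(best.x)
        self.ranef_ = pd.Series(self._last_modes_, index=uniq_groups)
        self._psi_ = best.x
        self._wald(X, y_idx, g_idx, n_groups, n_thresh, n_beta)
        return self

    def _wald(self, X, y_idx, g_idx, n_groups, n_thresh, n_beta):
        """Standard errors from the observed information at the optimum."""
        if n_beta == 0:
            self.bse_ = np.array([])
            self.zvalues_ = np.array([])
            self.pvalues_ = np.array([])
            return

        def nll_nat(par):
            theta = par[:n_thresh]
            beta = par[n_thresh : n_thresh + n_beta]
            psi = _pack(theta, beta, [par[-1]])
            return self._laplace_nll(psi, X, y_idx, g_idx, n_groups, n_thresh, n_beta)

        par = np.concatenate([self.thresholds_, self.coef_, [np.log(self.sigma_)]])
        try:
            H = _numeric_hessian(nll_nat, par)
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov)[n_thresh : n_thresh + n_beta], 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(n_beta, np.nan)
        self.bse_ = se
        with np.errstate(divide="ignore", invalid="ignore"):
            self.zvalues_ = self.coef_ / se
        self.pvalues_ = 2.0 * norm.sf(np.abs(self.zvalues_))

    def summary_frame(self, names: list[str] | None = None) -> pd.DataFrame:
        check_is_fitted(self, "coef_")
        if names is None:
            names = [f"x{i}" for i in range(len(self.coef_))]
        return pd.DataFrame(
            {"estimate": self.coef_, "std_error": self.bse_,
             "z": self.zvalues_, "p": self.pvalues_},
            index=names,
        )


def laplace_loglik(X, y, groups, thresholds, beta, sigma,
                   inner_tol: float = 1e-10,
                   levels: np.ndarray | None = None) -> float:
    """Evaluate the Laplace-approximated marginal log-likelihood at given
    parameter values (no fitting).

    ``levels`` fixes the category set when not every level occurs in ``y``;
    it must have exactly one more entry than ``thresholds``.
    """
    model = CumulativeLinkMixedModel(inner_tol=inner_tol)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        X = X.reshape(len(y), 0)
    y = np.asarray(y)
    levels = np.unique(y) if levels is None else np.asarray(levels)
    if len(levels) != len(thresholds) + 1:
        raise ValueError("need exactly one threshold fewer than levels")
    y_idx = np.searchsorted(levels, y)
    _, g_idx = np.unique(np.asarray(groups), return_inverse=True)
    psi = _pack(np.asarray(thresholds, dtype=float),
                np.asarray(beta, dtype=float), [float(np.log(sigma))])
    return -model._laplace_nll(psi, X, y_idx, g_idx, g_idx.max() + 1,
                               len(levels) - 1, X.shape[1])


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

@dataclass
class LRTestResult:
    lr: float
    df: int
    p: float


def lr_test(null_fit, alt_fit) -> LRTestResult:
    """Likelihood-ratio chi-square test for nested fits on the same rows."""
    df = alt_fit.k_ - null_fit.k_
    if df < 1:
        raise ValueError("alternative must have more parameters than the null")
    lr = 2.0 * (alt_fit.loglik_ - null_fit.loglik_)
    lr = max(lr, 0.0)  # optimizer tolerance can leave a tiny negative
    return LRTestResult(lr=lr, df=df, p=float(chi2.sf(lr, df)))


@dataclass
class StepwiseTrace:
    """Record of every model evaluated during forward selection."""

    records: list[dict] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    fits: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def _fit_terms(data: pd.DataFrame, response: str, group: str, terms: list[str],
               seed: int = 0, n_starts: int = 3) -> CumulativeLinkMixedModel:
    X = build_design(data, terms)
    model = CumulativeLinkMixedModel(seed=seed, n_starts=n_starts)
    model.fit(X.to_numpy(), data[response].to_numpy(), data[group].to_numpy())
    model.term_names_ = list(X.columns)
    return model


def forward_stepwise(data: pd.DataFrame, response: str, group: str,
                     candidates: list[str], alpha: float = 0.05,
                     seed: int = 0) -> StepwiseTrace:
    """AIC-guided forward selection over mixed-model fixed effects.

    Starts from the subject-only null; at each step fits every remaining
    candidate added to the current terms, keeps the addition with the lowest
    AIC among those whose LR test against the current model has p < alpha,
    and stops when no candidate qualifies.  AIC ties break toward the larger
    LR, then the lexicographically smaller term name.
    """
    trace = StepwiseTrace()
    current_terms: list[str] = []
    current = _fit_terms(data, response, group, current_terms, seed=seed)
    trace.fits["<null>"] = current
    trace.records.append({"step": 0, "terms": "<null>", "aic": current.aic_,
                          "loglik": current.loglik_, "lr": np.nan, "p": np.nan,
                          "selected": False})
    step = 0
    remaining = list(candidates)
    while remaining:
        step += 1
        evals = []
        for term in remaining:
            fit = _fit_terms(data, response, group, current_terms + [term], seed=seed)
            test = lr_test(current, fit)
            label = " + ".join(current_terms + [term])
            trace.fits[label] = fit
            trace.records.append({"step": step, "terms": label, "aic": fit.aic_,
                                  "loglik": fit.loglik_, "lr": test.lr,
                                  "p": test.p, "selected": False})
            evals.append((term, fit, test))
        qualifying = [e for e in evals if e[2].p < alpha]
        if not qualifying:
            break
        qualifying.sort(key=lambda e: (e[1].aic_, -e[2].lr, e[0]))
        term, fit, _ = qualifying[0]
        current_terms.append(term)
        current = fit
        remaining.remove(term)
        trace.selected.append(term)
        for rec in trace.records:
            if rec["step"] == step and rec["terms"] == " + ".join(current_terms):
                rec["selected"] = True
    return trace


# ---------------------------------------------------------------------------
# simulation (for calibration / parameter-recovery studies)
# ---------------------------------------------------------------------------

def simulate_clmm_data(n_subjects: int, n_obs: int, beta: float = 0.6,
                       sigma: float = 1.0,
                       thresholds: np.ndarray | None = None,
                       seed: int = 0) -> pd.DataFrame:
    """Draw ordinal data from the random-intercept cumulative logit model.

    One standard-normal covariate ``x`` per observation; subject intercepts
    N(0, sigma^2); default thresholds evenly spaced over [-2.5, 2.5] giving
    J = 7 categories.
    """
    if thresholds is None:
        thresholds = np.linspace(-2.5, 2.5, 6)
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sigma, n_subjects)
    rows = []
    theta_ext = np.concatenate(([-np.inf], thresholds, [np.inf]))
    for i in range(n_subjects):
        x = rng.normal(0.0, 1.0, n_obs)
        eta = beta * x + b[i]
        cum = expit(theta_ext[None, :] - eta[:, None])
        probs = np.diff(cum, axis=1)
        y = np.array([rng.choice(len(p), p=p / p.sum()) for p in probs]) + 1
        for xi, yi in zip(x, y):
            rows.append({"subject": i, "x": xi, "y": yi})
    return pd.DataFrame(rows)
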