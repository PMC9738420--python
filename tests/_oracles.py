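"""Independent oracles used by the tests.

Each oracle re-derives a quantity by a route independent of the package
implementation it checks: brute-force enumeration for dwell detection,
Gauss-Hermite quadrature for the random-intercept marginal likelihood,
Welch periodograms for band power, and exhaustive model enumeration for the
stepwise selection.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.signal import welch
from scipy.special import expit


def brute_force_detect(values, threshold: float, need: int, rate: float = 16.0):
    """Enumerate every length-``need`` window; first fully super-threshold
    window wins.  Returns (detected, latency)."""
    values = np.asarray(values)
    for start in range(0, len(values) - need + 1):
        win = values[start:start + need]
        if np.all(win >= threshold):
            return True, (start + need) / rate
    return False, None


def band_power_welch(x: np.ndarray, fs: float, band=(8.0, 30.0)) -> float:
    """Mean Welch PSD power inside the band for a single-channel trace."""
    f, p = welch(x, fs=fs, nperseg=min(len(x), 256))
    sel = (f >= band[0]) & (f <= band[1])
    return float(np.trapezoid(p[sel], f[sel]))


def gauss_hermite_loglik(X, y, groups, thresholds, beta, sigma,
                         n_nodes: int = 50, levels=None) -> float:
    """Marginal log-likelihood of the random-intercept cumulative logit via
    Gauss-Hermite quadrature (change of variable b = sqrt(2) sigma t)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        X = X.reshape(len(y), 0)
    y = np.asarray(y)
    groups = np.asarray(groups)
    levels = np.unique(y) if levels is None else np.asarray(levels)
    y_idx = np.searchsorted(levels, y)
    theta_ext = np.concatenate(([-np.inf], thresholds, [np.inf]))
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    eta0 = X @ np.asarray(beta, dtype=float)
    total = 0.0
    for g in np.unique(groups):
        sel = groups == g
        u = theta_ext[y_idx[sel] + 1]
        lo = theta_ext[y_idx[sel]]
        # log prod_j p(y_j | b_k) at each node
        b = np.sqrt(2.0) * sigma * nodes
        eta = eta0[sel][None, :] + b[:, None]
        p = expit(u[None, :] - eta) - expit(lo[None, :] - eta)
        logp = np.log(np.clip(p, 1e-300, None)).sum(axis=1)
        m = logp.max()
        total += m + np.log(np.sum(weights * np.exp(logp - m)) / np.sqrt(np.pi))
    return float(total)


def exhaustive_forward_oracle(fit_fun, lr_fun, candidates, alpha=0.05,
                              max_depth: int = 2):
    """Re-derive forward selection by exhaustive enumeration.

    ``fit_fun(terms)`` returns a fitted model with ``aic_``/``k_``/``loglik_``;
    ``lr_fun(null, alt)`` an object with ``lr`` and ``p``.  At each depth the
    oracle evaluates every not-yet-included candidate added to the current
    set and keeps the lowest-AIC significant addition (ties: larger LR, then
    term name).  Returns the selected term sequence.
    """
    selected: list[str] = []
    current = fit_fun([])
    for _ in range(max_depth):
        options = []
        for term in candidates:
            if term in selected:
                continue
            fit = fit_fun(selected + [term])
            test = lr_fun(current, fit)
            if test.p < alpha:
                options.append((fit.aic_, -test.lr, term, fit))
        if not options:
            break
        options.sort()
        _, _, term, fit = options[0]
        selected.append(term)
        current = fit
    return selected
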