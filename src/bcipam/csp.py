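"""Common spatial patterns by generalized eigendecomposition.

CSP finds spatial filters w maximizing the variance ratio between two
classes: w' S_a w / w' (S_a + S_b) w is extremal at the generalized
eigenvectors of (S_a, S_a + S_b).  Filters are normalized so the projected
pooled covariance is the identity (the whitening property W (S_a + S_b) W' = I),
and components are taken in pairs from both ends of the eigenvalue spectrum
(most class-a-dominant and most class-b-dominant directions).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["CSP", "fit_csp"]


def _class_covariance(X: np.ndarray, reg: float) -> np.ndarray:
    """Average per-epoch covariance with diagonal loading for stability."""
    n_ep, n_ch, n_t = X.shape
    S = np.zeros((n_ch, n_ch))
    for ep in X:
        S += ep @ ep.T / n_t
    S /= n_ep
    return S + reg * np.trace(S) / n_ch * np.eye(n_ch)


class CSP(BaseEstimator, TransformerMixin):
    """Two-class CSP transformer returning log-variance features.

    Parameters
    ----------
    n_components : int
        Even number of spatial filters, half from each end of the spectrum.
    reg : float
        Diagonal loading factor (times mean diagonal) added to each class
        covariance; guards against singular pooled covariance.

    Attributes
    ----------
    filters_ : (n_components, n_channels) selected spatial filters (rows).
    all_filters_ : full whitened eigenbasis, eigenvalue-ascending.
    eigenvalues_ : class-a variance fractions, ascending in (0, 1).
    """

    def __init__(self, n_components: int = 6, reg: float = 1e-6):
        self.n_components = n_components
        self.reg = reg

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be [epoch x channel x time]")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("CSP requires exactly two classes")
        if np.sum(y == classes[0]) == 0 or np.sum(y == classes[1]) == 0:
            raise ValueError("one class is empty")
        n_ch = X.shape[1]
        if self.n_components % 2 or not 0 < self.n_components <= n_ch:
            raise ValueError("n_components must be even and <= channel count")
        self.classes_ = classes
        Sa = _class_covariance(X[np.asarray(y) == classes[0]], self.reg)
        Sb = _class_covariance(X[np.asarray(y) == classes[1]], self.reg)
        evals, evecs = eigh(Sa, Sa + Sb)  # ascending; evecs' (Sa+Sb) evecs = I
        self.eigenvalues_ = evals
        self.all_filters_ = evecs.T
        half = self.n_components // 2
        idx = np.r_[np.arange(half), np.arange(n_ch - half, n_ch)]
        self.component_indices_ = idx
        self.filters_ = evecs.T[idx]
        return self

    def apply_filters(self, X) -> np.ndarray:
        """Project epochs onto the selected spatial components."""
        check_is_fitted(self, "filters_")
        X = np.asarray(X, dtype=float)
        return np.einsum("ck,nkt->nct", self.filters_, X)

    def transform(self, X) -> np.ndarray:
        """Log-variance of each projected component, per epoch."""
        proj = self.apply_filters(X)
        return np.log(np.clip(proj.var(axis=2), 1e-30, None))


def fit_csp(epochs, n_components: int = 6, reg: float = 1e-6) -> CSP:
    """Fit CSP on an :class:`~bcipam.eeg.EpochSet` (MI vs idle)."""
    return CSP(n_components=n_components, reg=reg).fit(epochs.samples, epochs.labels)
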