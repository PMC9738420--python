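"""Simulated online motor-imagery decoder.

Calibration pipeline: causal 5th-order Butterworth band-pass (8-30 Hz) ->
CSP -> log-variance features -> linear discriminant, trained with stratified
cross-validation.  Online operation emits one decision value in [0, 1] every
1/16 s (the logistic of the signed discriminant score on a 1-s sliding
analysis buffer); motor imagery is declared once the value stays at or above
the probability threshold for a dwell time of 0.5 consecutive seconds
(8 decisions at 16 Hz) inside the input window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, lfilter
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .csp import CSP
from .eeg import CHANNELS, EpochSet, generate_synthetic_eeg

__all__ = ["DecisionTrace", "DetectionResult", "MIDecoder", "calibrate",
           "detect_mi", "stream_decode", "tune_threshold", "SimulatedBCIUser"]


@dataclass
class DecisionTrace:
    """Decoder output values in [0, 1] at the decision rate; t0 marks the
    input-window start relative to the underlying signal."""

    values: np.ndarray
    t0: float = 0.0
    rate: float = 16.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("trace values must lie in [0, 1]")


@dataclass
class DetectionResult:
    """Dwell-threshold detection outcome; latency in seconds from window
    start (None when not detected)."""

    detected: bool
    latency: float | None = None


class MIDecoder(BaseEstimator, ClassifierMixin):
    """Band-pass -> CSP -> log-variance -> LDA motor-imagery classifier.

    Parameters
    ----------
    band : (low, high) passband edges in Hz.
    order : Butterworth filter order.
    n_components : CSP component count (even).
    threshold : probability threshold in (0, 1) for online detection.
    dwell : required consecutive super-threshold time in seconds; dwell *
        decision_rate must be a whole number of decisions.
    decision_rate : online decisions per second.
    buffer : sliding analysis buffer length in seconds.
    sample_rate : EEG sampling rate in Hz.

    Attributes
    ----------
    csp_ : fitted :class:`~bcipam.csp.CSP`.
    lda_ : fitted linear discriminant on log-variance features.
    classes_ : ("idle", "mi") label order; "mi" is the positive class.
    """

    def __init__(self, band=(8.0, 30.0), order: int = 5, n_components: int = 6,
                 threshold: float = 0.5, dwell: float = 0.5,
                 decision_rate: float = 16.0, buffer: float = 1.0,
                 sample_rate: float = 250.0, reg: float = 1e-6):
        self.band = band
        self.order = order
        self.n_components = n_components
        self.threshold = threshold
        self.dwell = dwell
        self.decision_rate = decision_rate
        self.buffer = buffer
        self.sample_rate = sample_rate
        self.reg = reg

    # -- helpers ---------------------------------------------------------

    @property
    def dwell_count(self) -> int:
        n = self.dwell * self.decision_rate
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError("dwell * decision_rate must be a positive integer")
        return int(round(n))

    def _validate(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly in (0, 1)")
        self.dwell_count  # noqa: B018  (validates)

    def _bandpass(self, X: np.ndarray) -> np.ndarray:
        b, a = butter(self.order, self.band, btype="bandpass", fs=self.sample_rate)
        return lfilter(b, a, X, axis=-1)

    def _features(self, X3d: np.ndarray) -> np.ndarray:
        return self.csp_.transform(self._bandpass(X3d))

    # -- calibration -----------------------------------------------------

    def fit(self, X, y):
        """Fit the full pipeline on epochs [epoch x channel x time]."""
        self._validate()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        Xf = self._bandpass(X)
        self.csp_ = CSP(n_components=self.n_components, reg=self.reg).fit(Xf, y)
        feats = self.csp_.transform(Xf)
        if np.any(feats.std(axis=0) < 1e-12):
            raise RuntimeError("calibration failure: degenerate (zero-variance) features")
        self.lda_ = LinearDiscriminantAnalysis().fit(feats, y)
        self.classes_ = self.lda_.classes_
        # online decisions score 1-buffer-long windows, whose log-variance
        # features are shifted relative to full epochs; recenter the online
        # cut on buffer-length segments of the calibration data so a chance
        # decoder sits at 0.5 online as well.
        buf_n = int(round(self.buffer * self.sample_rate))
        n_sub = Xf.shape[2] // buf_n
        subs = np.concatenate([Xf[:, :, i * buf_n:(i + 1) * buf_n]
                               for i in range(n_sub)], axis=0)
        sub_y = np.tile(y, n_sub)
        raw = self._raw_score(self.csp_.transform(subs))
        self._online_offset_ = -0.5 * (raw[sub_y == "mi"].mean()
                                       + raw[sub_y != "mi"].mean())
        return self

    def _raw_score(self, feats: np.ndarray) -> np.ndarray:
        score = self.lda_.decision_function(feats)
        if self.classes_[1] != "mi":  # orient so larger = more MI-like
            score = -score
        return score

    def decision_value(self, feats: np.ndarray) -> np.ndarray:
        """Map LDA scores to [0, 1]: logistic of the signed, online-centered
        discriminant score toward the MI class."""
        check_is_fitted(self, "lda_")
        return expit(self._raw_score(feats) + self._online_offset_)

    def predict(self, X):
        feats = self._features(np.asarray(X, dtype=float))
        return self.lda_.predict(feats)

    def predict_proba(self, X):
        feats = self._features(np.asarray(X, dtype=float))
        return self.lda_.predict_proba(feats)

    # -- online operation ------------------------------------------------

    def stream_decode(self, signal: np.ndarray, t0: float | None = None) -> DecisionTrace:
        """Decode a continuous multichannel signal into a decision trace.

        ``signal`` is [channel x time] and must include one analysis buffer
        of context ahead of the input window; decision k is computed from
        the buffer ending at time ``buffer + k / decision_rate`` and the
        trace covers ``floor((duration - buffer) * decision_rate)`` values.
        """
        check_is_fitted(self, "lda_")
        signal = np.asarray(signal, dtype=float)
        if signal.ndim != 2:
            raise ValueError("signal must be [channel x time]")
        fs = self.sample_rate
        n = signal.shape[1]
        buf_n = int(round(self.buffer * fs))
        if n < buf_n:
            raise ValueError("signal shorter than one analysis buffer")
        n_dec = int(np.floor((n / fs - self.buffer) * self.decision_rate + 1e-9))
        if n_dec < 1:
            raise ValueError("signal must cover at least one decision period")
        filt = self._bandpass(signal)
        buffers = np.empty((n_dec, signal.shape[0], buf_n))
        for k in range(1, n_dec + 1):
            end = int(round((self.buffer + k / self.decision_rate) * fs))
            buffers[k - 1] = filt[:, end - buf_n:end]
        feats = self.csp_.transform(buffers)
        values = self.decision_value(feats)
        return DecisionTrace(values=values, t0=self.buffer if t0 is None else t0,
                             rate=self.decision_rate)

    def detect(self, trace: DecisionTrace) -> DetectionResult:
        """Scan the trace left to right for the first dwell-long run at or
        above threshold; latency is the time of that run's last decision."""
        self._validate()
        values = np.asarray(trace.values)
        if values.size == 0:
            raise ValueError("empty decision trace")
        need = self.dwell_count
        run = 0
        for i, v in enumerate(values):
            run = run + 1 if v >= self.threshold else 0
            if run >= need:
                return DetectionResult(detected=True, latency=(i + 1) / trace.rate)
        return DetectionResult(detected=False)


def calibrate(epochs: EpochSet, n_components: int = 6, folds: int = 5,
              seed: int = 0, **decoder_params) -> tuple[MIDecoder, float]:
    """Calibrate a decoder with stratified cross-validation.

    Returns the decoder refit on all epochs plus the mean held-out accuracy
    over ``folds`` stratified folds (the CSP and LDA are refit inside every
    fold; no leakage from the held-out epochs).
    """
    if folds < 2:
        raise ValueError("need at least two folds")
    y = epochs.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < folds:
        raise ValueError("both classes must have at least `folds` epochs")
    proto = MIDecoder(n_components=n_components,
                      sample_rate=epochs.rate, **decoder_params)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(np.zeros(len(y)), y):
        model = clone(proto).fit(epochs.samples[tr], y[tr])
        accs.append(np.mean(model.predict(epochs.samples[te]) == y[te]))
    final = proto.fit(epochs.samples, y)
    return final, float(np.mean(accs))


def stream_decode(model: MIDecoder, signal: np.ndarray) -> DecisionTrace:
    return model.stream_decode(signal)


def detect_mi(trace: DecisionTrace, model: MIDecoder) -> DetectionResult:
    return model.detect(trace)


def tune_threshold(model: MIDecoder, erd_depth: float, noise_sd: float = 1.0,
                   n_windows: int = 40, seed: int = 1,
                   grid: np.ndarray | None = None,
                   criterion: str = "fpr_cap", fpr_cap: float = 0.15) -> float:
    """Emulated short online test: subject-specific probability threshold.

    Plays held-out synthetic MI and idle windows through the full online
    loop and grid-searches the threshold.  The default criterion picks the
    lowest threshold whose estimated false-positive (idle-window detection)
    rate stays at or below ``fpr_cap`` — false positives are minimized while
    activation stays possible — falling back to the highest grid point when
    no threshold qualifies.  ``criterion="youden"`` instead maximizes
    TPR - FPR.
    """
    if grid is None:
        grid = np.round(np.arange(0.2, 0.951, 0.05), 2)
    user = SimulatedBCIUser(model, erd_depth=erd_depth, noise_sd=noise_sd, seed=seed)
    traces_mi = [user.play_window(perform_mi=True) for _ in range(n_windows)]
    traces_idle = [user.play_window(perform_mi=False) for _ in range(n_windows)]

    def rates(thr: float) -> tuple[float, float]:
        probe = clone(model)
        probe.threshold = float(thr)
        probe.csp_, probe.lda_, probe.classes_ = model.csp_, model.lda_, model.classes_
        probe._online_offset_ = model._online_offset_
        tpr = float(np.mean([probe.detect(t).detected for t in traces_mi]))
        fpr = float(np.mean([probe.detect(t).detected for t in traces_idle]))
        return tpr, fpr

    if criterion == "youden":
        best_j, best_t = -np.inf, model.threshold
        for thr in grid:
            tpr, fpr = rates(thr)
            if tpr - fpr > best_j:
                best_j, best_t = tpr - fpr, float(thr)
        return best_t
    if criterion != "fpr_cap":
        raise ValueError(f"unknown tuning criterion {criterion!r}")
    for thr in grid:
        _, fpr = rates(thr)
        if fpr <= fpr_cap:
            return float(thr)
    return float(grid[-1])


class SimulatedBCIUser:
    """A simulated player: produces per-trial BCI attempts through the full
    generate -> stream-decode -> dwell-detect loop.

    Each attempt synthesizes one analysis buffer of idle context followed by
    the 2-s input window containing MI-modulated (or idle) signal drawn from
    the same generative model as the calibration data.
    """

    def __init__(self, model: MIDecoder, erd_depth: float, noise_sd: float = 1.0,
                 window: float = 2.0, seed: int = 0):
        self.model = model
        self.erd_depth = erd_depth
        self.noise_sd = noise_sd
        self.window = window
        self.rng = np.random.default_rng(seed)

    def play_window(self, perform_mi: bool = True) -> DecisionTrace:
        dur = self.model.buffer + self.window
        sub = int(self.rng.integers(0, 2**31 - 1))
        label_n = int(np.ceil(dur / 4.0))
        mi_n = label_n if perform_mi else 0
        # build a continuous strip from epoch-generator draws of the needed class
        eps = generate_synthetic_eeg(max(mi_n, 1), max(label_n - mi_n, 1),
                                     erd_depth=self.erd_depth,
                                     noise_sd=self.noise_sd, seed=sub)
        want = "mi" if perform_mi else "idle"
        segs = eps.samples[eps.labels == want]
        strip = np.concatenate(list(segs), axis=1)
        need = int(round(dur * self.model.sample_rate))
        mi_sig = strip[:, :need]
        if perform_mi:
            # idle context before the window: replace the pre-window buffer
            idle = generate_synthetic_eeg(1, 1, erd_depth=self.erd_depth,
                                          noise_sd=self.noise_sd, seed=sub + 1)
            idle_seg = idle.samples[idle.labels == "idle"][0]
            buf_n = int(round(self.model.buffer * self.model.sample_rate))
            mi_sig = mi_sig.copy()
            mi_sig[:, :buf_n] = idle_seg[:, :buf_n]
        return self.model.stream_decode(mi_sig)

    def attempt(self) -> DetectionResult:
        """One trial attempt: MI during the input window; dwell detection."""
        return self.model.detect(self.play_window(perform_mi=True))

    def __call__(self) -> bool:
        return self.attempt().detected
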