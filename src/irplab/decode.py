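"""Single-trial decoding with sliding-window CSP/CSSP features.

Common spatial patterns (CSP) finds spatial filters w maximizing the
variance ratio between two classes, i.e. the generalized eigenvectors of
(Sigma_a, Sigma_a + Sigma_b) where Sigma_c are trace-normalized average
class covariances.  The common spatial-spectral pattern (CSSP) variant runs
CSP on channels augmented with copies delayed by tau, which lets the filters
realize an implicit FIR spectral filter per channel.

Decoding proceeds per 200 ms window (100 ms shift): band-pass 1-6 Hz,
delay-embed, fit CSP on the training folds only, extract log-variance
features and classify with a linear support-vector machine under
stratified 5-fold cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, signal
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .preprocess import EpochSet

__all__ = [
    "WindowScheme", "SpatialFilterBank", "AccuracyCurve",
    "butter_band", "select_channels", "delay_embed", "fit_csp",
    "logvar_features", "crossval_decode",
    "CHANNEL_SELECTION",
]

#: Channels kept per region for modality-specific decoding (first k channels
#: of each region in montage order).  Visual processing engages frontal,
#: parietal and occipital regions (24 channels); auditory engages frontal,
#: parietal and temporal regions (22 channels).
CHANNEL_SELECTION: dict[str, dict[str, int]] = {
    "visual": {"FL": 4, "FR": 4, "PL": 4, "PR": 4, "OL": 4, "OR": 4},
    "auditory": {"FL": 4, "FR": 4, "PL": 4, "PR": 4, "TL": 3, "TR": 3},
}

_VAR_FLOOR = 1e-20  # guards log() for degenerate (constant) projections


@dataclass(frozen=True)
class WindowScheme:
    """Evenly spaced sliding windows, default 200 ms length / 100 ms shift."""

    length: float = 0.2
    shift: float = 0.1

    def starts(self, tmin: float, tmax: float) -> np.ndarray:
        """Window start times covering [tmin, tmax], clipped to fit."""
        if self.length <= 0 or self.shift <= 0:
            raise ValueError("window length and shift must be > 0")
        out = []
        t = tmin
        while t + self.length <= tmax + 1e-9:
            out.append(round(t, 9))
            t += self.shift
        if not out:
            raise ValueError("no window fits inside the epoch")
        return np.array(out)


@dataclass(frozen=True)
class SpatialFilterBank:
    """Fitted CSP/CSSP projection.

    ``filters`` holds the 2*n_pairs selected projection vectors (rows,
    eigenvalue-descending); ``all_filters``/``all_eigenvalues`` the complete
    eigensystem.  Eigenvalues are the class-A variance fractions on the
    normalized composite covariance, so lambda_A = 1 - lambda_B.
    """

    filters: np.ndarray
    eigenvalues: np.ndarray
    all_filters: np.ndarray
    all_eigenvalues: np.ndarray
    tau: float = 0.0
    n_pairs: int = 3


@dataclass(frozen=True)
class AccuracyCurve:
    """Cross-validated accuracy per sliding window."""

    window_starts: np.ndarray
    mean_acc: np.ndarray
    sd_acc: np.ndarray
    n_samples: int
    length: float = 0.2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"window_start_s": self.window_starts,
                             "mean_acc": self.mean_acc,
                             "sd_acc": self.sd_acc,
                             "n": self.n_samples})

    @property
    def peak_window(self) -> tuple[float, float]:
        i = int(np.argmax(self.mean_acc))
        t0 = float(self.window_starts[i])
        return (t0, t0 + self.length)


def butter_band(epochs: EpochSet, low: float = 1.0, high: float = 6.0,
                order: int = 4) -> EpochSet:
    """Zero-phase (forward-backward) Butterworth band-pass on epochs."""
    nyq = epochs.fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"invalid band ({low}, {high}) at fs={epochs.fs}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=epochs.fs,
                        output="sos")
    return replace(epochs, data=signal.sosfiltfilt(sos, epochs.data, axis=-1))


def select_channels(epochs: EpochSet, modality: str) -> EpochSet:
    """Keep the modality-specific channel subset (see CHANNEL_SELECTION)."""
    if modality not in CHANNEL_SELECTION:
        raise ValueError(f"unknown modality {modality!r}")
    if epochs.montage is None:
        raise ValueError("channel selection requires a montage")
    picks: list[int] = []
    labels: list[str] = []
    for region, k in CHANNEL_SELECTION[modality].items():
        idx = epochs.montage.indices_in(region)
        if len(idx) < k:
            raise ValueError(f"region {region} has {len(idx)} channels, "
                             f"need {k}")
        picks.extend(idx[:k])
        labels.extend(epochs.montage.channel_labels[i] for i in idx[:k])
    return replace(epochs, data=epochs.data[:, picks], montage=None,
                   channel_labels=tuple(labels))


def delay_embed(window_data: np.ndarray, tau: float, fs: float) -> np.ndarray:
    """Augment channels with copies delayed by round(tau * fs) samples.

    The delayed block is zero-padded at the left (window start) edge.
    Output shape: trials x 2*channels x samples.
    """
    d = int(round(tau * fs))
    n_samp = window_data.shape[-1]
    if d < 0 or d >= n_samp:
        raise ValueError("delay must be shorter than the window")
    delayed = np.zeros_like(window_data)
    if d == 0:
        delayed[:] = window_data
    else:
        delayed[..., d:] = window_data[..., :-d]
    return np.concatenate([window_data, delayed], axis=-2)


def _class_cov(trials: np.ndarray) -> np.ndarray:
    """Average of per-trial trace-normalized covariances."""
    n_ch = trials.shape[-2]
    acc = np.zeros((n_ch, n_ch))
    for x in trials:
        c = x @ x.T
        tr = np.trace(c)
        if tr > _VAR_FLOOR:
            acc += c / tr
    return acc / trials.shape[0]


def fit_csp(class_a: np.ndarray, class_b: np.ndarray, n_pairs: int = 3,
            reg: float = 1e-6, tau: float = 0.0) -> SpatialFilterBank:
    """Fit CSP filters from two sets of trials.

    Per-trial covariances are trace-normalized before averaging; filters are
    the generalized eigenvectors of (Sigma_a, Sigma_a + Sigma_b).  A
    rank-deficient composite covariance is ridge-regularized
    (``reg * trace/dim`` on the diagonal) with a warning.  The returned
    filters whiten the composite: W (Sa+Sb) W^T = I.
    """
    if class_a.shape[0] < 2 or class_b.shape[0] < 2:
        raise ValueError("need at least 2 trials per class")
    n_ch = class_a.shape[-2]
    if n_ch < 2 or class_b.shape[-2] != n_ch:
        raise ValueError("need >= 2 channels, identical across classes")
    if not 1 <= n_pairs <= n_ch // 2:
        raise ValueError("n_pairs must lie in [1, n_channels // 2]")
    cov_a = _class_cov(class_a)
    cov_b = _class_cov(class_b)
    composite = cov_a + cov_b
    eps = np.finfo(float).eps
    evs = linalg.eigvalsh(composite)
    if evs[0] < max(evs[-1], 1.0) * 1e-10:
        warnings.warn("rank-deficient composite covariance; applying ridge "
                      "regularization", RuntimeWarning, stacklevel=2)
        ridge = reg * max(np.trace(composite) / n_ch, eps)
        composite = composite + ridge * np.eye(n_ch)
    vals, vecs = linalg.eigh(cov_a, composite)
    vals = np.clip(vals, 0.0, 1.0)
    order = np.argsort(vals)[::-1]          # descending class-A variance
    vals, vecs = vals[order], vecs[:, order]
    sel = np.concatenate([np.arange(n_pairs),
                          np.arange(n_ch - n_pairs, n_ch)])
    return SpatialFilterBank(filters=vecs[:, sel].T.copy(),
                             eigenvalues=vals[sel].copy(),
                             all_filters=vecs.T.copy(),
                             all_eigenvalues=vals.copy(),
                             tau=tau, n_pairs=n_pairs)


def logvar_features(bank: SpatialFilterBank, window_data: np.ndarray,
                    normalize: bool = False) -> np.ndarray:
    """Log-variance of each filtered projection; trials x 2*n_pairs.

    With ``normalize=True`` variances are divided by their per-trial sum
    before the log (the classical normalized-CSP feature); the default is
    the plain log-variance.
    """
    if window_data.shape[-2] != bank.filters.shape[1]:
        raise ValueError("channel dimension does not match the filter bank")
    proj = np.einsum("fc,tcs->tfs", bank.filters, window_data)
    var = proj.var(axis=-1)
    if normalize:
        var = var / np.maximum(var.sum(axis=1, keepdims=True), _VAR_FLOOR)
    return np.log(np.maximum(var, _VAR_FLOOR))


def crossval_decode(epochs: EpochSet, scheme: WindowScheme | None = None,
                    tau: float = 0.012, n_pairs: int = 3, n_folds: int = 5,
                    seed: int = 0, C: float = 1.0,
                    use_kept: bool = True) -> AccuracyCurve:
    """Sliding-window CSSP + linear-SVM decoding, stratified K-fold CV.

    For every window, filters and classifier are fitted on the training
    folds only; test trials never influence the filters.  Band-pass the
    epochs (``butter_band``) and select channels before calling.
    """
    scheme = scheme or WindowScheme()
    mask = epochs.kept_mask if use_kept else np.ones(epochs.n_trials, bool)
    X_all = epochs.data[mask]
    y = (epochs.conditions[mask] == "go").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both conditions must be present")
    t_end = epochs.tmin + epochs.data.shape[-1] / epochs.fs
    starts = scheme.starts(epochs.tmin, t_end)
    n_len = int(round(scheme.length * epochs.fs))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(X_all, y))
    mean_acc = np.empty(len(starts))
    sd_acc = np.empty(len(starts))
    for w, t0 in enumerate(starts):
        i0 = int(round((t0 - epochs.tmin) * epochs.fs))
        Xw = delay_embed(X_all[..., i0:i0 + n_len], tau, epochs.fs)
        accs = []
        for train, test in folds:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                bank = fit_csp(Xw[train][y[train] == 1],
                               Xw[train][y[train] == 0],
                               n_pairs=n_pairs, tau=tau)
            clf = SVC(kernel="linear", C=C)
            clf.fit(logvar_features(bank, Xw[train]), y[train])
            accs.append(clf.score(logvar_features(bank, Xw[test]), y[test]))
        mean_acc[w] = np.mean(accs)
        sd_acc[w] = np.std(accs)
    return AccuracyCurve(window_starts=starts, mean_acc=mean_acc,
                         sd_acc=sd_acc, n_samples=len(y),
                         length=scheme.length)
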