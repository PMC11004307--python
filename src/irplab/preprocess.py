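"""Deterministic conditioning of continuous EEG into region-pooled epochs.

The pipeline order is fixed: polyphase resampling (1000 -> 250 Hz by
default), average re-referencing, zero-phase 1-45 Hz FIR band-pass,
epoching from 200 ms before to 800 ms after each event with baseline
correction over the pre-stimulus window, behavioral trial rejection, and
pooling of channels into the eight scalp regions.

Artifact handling is limited to :func:`ica_hook`, a pass-through placeholder:
the synthetic sessions this package analyses contain no ocular or muscular
artifacts, so no decomposition is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .montage import REGIONS, Montage
from .simulate import Recording

__all__ = [
    "EpochSet", "RegionEpochSet", "resample", "rereference_average",
    "bandpass_fir", "ica_hook", "epoch", "reject_trials", "rejection_report",
    "region_average", "preprocess_session",
]


@dataclass(frozen=True)
class EpochSet:
    """Baseline-corrected trials x channels x samples epochs.

    ``tmin`` is the (negative) time of the first sample relative to the
    event; the epoch window is half-open, ``[tmin, tmin + n/fs)``.
    ``kept_mask`` marks trials that survive behavioral rejection; rejection
    never alters ``data``.
    """

    data: np.ndarray
    fs: float
    tmin: float
    conditions: np.ndarray
    kept_mask: np.ndarray
    montage: Montage | None = field(default=None, hash=False)
    channel_labels: tuple[str, ...] | None = None
    behavior: pd.DataFrame | None = field(default=None, hash=False)

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[-1]) / self.fs

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def kept(self, condition: str | None = None) -> np.ndarray:
        """Data of kept trials, optionally restricted to one condition."""
        mask = self.kept_mask.copy()
        if condition is not None:
            mask &= self.conditions == condition
        return self.data[mask]

    def labels(self) -> tuple[str, ...]:
        if self.channel_labels is not None:
            return self.channel_labels
        if self.montage is not None:
            return self.montage.channel_labels
        return tuple(str(i) for i in range(self.data.shape[1]))


@dataclass(frozen=True)
class RegionEpochSet(EpochSet):
    """Epochs pooled to the eight regions, in the fixed order ``REGIONS``."""

    regions: tuple[str, ...] = REGIONS

    def labels(self) -> tuple[str, ...]:
        return self.regions


def resample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased polyphase resampling with event re-indexing."""
    if target_fs <= 0:
        raise ValueError("target_fs must be > 0")
    if target_fs > rec.fs:
        raise ValueError("upsampling is not supported")
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator,
                                axis=-1)
    events = tuple((int(round(s * target_fs / rec.fs)), c)
                   for s, c in rec.events)
    return Recording(data=data, fs=target_fs, montage=rec.montage,
                     events=events, behavior=rec.behavior)


def rereference_average(rec: Recording) -> Recording:
    """Re-reference to the common average: channel mean is 0 at each sample."""
    if rec.data.shape[0] < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return Recording(data=data, fs=rec.fs, montage=rec.montage,
                     events=rec.events, behavior=rec.behavior)


def bandpass_fir(rec: Recording, low: float = 1.0, high: float = 45.0,
                 transition: float = 1.0) -> Recording:
    """Zero-net-delay FIR band-pass (Hamming window design).

    A linear-phase type-I FIR filter is applied by FFT convolution with the
    group delay compensated exactly ('same'-mode centring), so the output is
    effectively zero-phase.  The transition band is ``transition`` Hz on each
    edge; passband ripple of the Hamming design is ~0.2%.
    """
    nyq = rec.fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"invalid band ({low}, {high}) at fs={rec.fs}")
    numtaps = int(round(3.3 * rec.fs / transition))
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay
    taps = signal.firwin(numtaps, [low, high], pass_zero=False, fs=rec.fs,
                         window="hamming")
    data = signal.oaconvolve(rec.data, taps[None, :], mode="same", axes=-1)
    return Recording(data=data, fs=rec.fs, montage=rec.montage,
                     events=rec.events, behavior=rec.behavior)


def ica_hook(rec: Recording) -> Recording:
    """Artifact-removal hook; identity for artifact-free synthetic data."""
    return rec


def epoch(rec: Recording, pre_s: float = 0.2, post_s: float = 0.8) -> EpochSet:
    """Cut ``[-pre_s, post_s)`` epochs and subtract the pre-stimulus mean.

    Trials whose window would run outside the recording are flagged
    (``kept_mask`` False, data zero) rather than silently dropped.
    """
    if pre_s < 0 or post_s <= 0:
        raise ValueError("invalid epoch window")
    n_pre = int(round(pre_s * rec.fs))
    n_len = int(round((pre_s + post_s) * rec.fs))
    n_ch, n_samp = rec.data.shape
    n_trials = len(rec.events)
    data = np.zeros((n_trials, n_ch, n_len))
    kept = np.ones(n_trials, dtype=bool)
    conditions = np.array([c for _, c in rec.events])
    for i, (s, _) in enumerate(rec.events):
        start = s - n_pre
        if start < 0 or start + n_len > n_samp:
            kept[i] = False
            continue
        seg = rec.data[:, start:start + n_len]
        baseline = seg[:, :n_pre].mean(axis=1, keepdims=True) if n_pre else 0.0
        data[i] = seg - baseline
    return EpochSet(data=data, fs=rec.fs, tmin=-pre_s, conditions=conditions,
                    kept_mask=kept, montage=rec.montage,
                    behavior=rec.behavior)


def reject_trials(epochs: EpochSet, behavior: pd.DataFrame | None = None,
                  rt_cutoff: float = 1.5) -> EpochSet:
    """Mask trials with incorrect responses or RT above the cutoff."""
    if behavior is None:
        behavior = epochs.behavior
    if behavior is None:
        raise ValueError("no behavioral log available")
    if len(behavior) != epochs.n_trials:
        raise ValueError("behavior rows do not match trials")
    ok = behavior["correct"].to_numpy(dtype=bool) & \
        (behavior["rt"].to_numpy(dtype=float) <= rt_cutoff)
    return replace(epochs, kept_mask=epochs.kept_mask & ok, behavior=behavior)


def rejection_report(epochs: EpochSet) -> pd.DataFrame:
    """Per-condition kept/rejected trial counts."""
    rows = []
    for cond in np.unique(epochs.conditions):
        m = epochs.conditions == cond
        rows.append({"condition": cond, "n_trials": int(m.sum()),
                     "n_kept": int((m & epochs.kept_mask).sum())})
    return pd.DataFrame(rows)


def region_average(epochs: EpochSet, montage: Montage | None = None
                   ) -> RegionEpochSet:
    """Pool channels to the 8 regions by arithmetic mean, fixed order."""
    montage = montage or epochs.montage
    if montage is None:
        raise ValueError("a montage is required for region pooling")
    out = np.empty((epochs.n_trials, len(REGIONS), epochs.data.shape[-1]))
    for r_idx, region in enumerate(REGIONS):
        idx = montage.indices_in(region)
        if not idx:
            raise ValueError(f"region {region} has no channels")
        out[:, r_idx] = epochs.data[:, idx].mean(axis=1)
    return RegionEpochSet(data=out, fs=epochs.fs, tmin=epochs.tmin,
                          conditions=epochs.conditions,
                          kept_mask=epochs.kept_mask, montage=montage,
                          behavior=epochs.behavior)


def preprocess_session(rec: Recording, target_fs: float | None = 250.0,
                       band: tuple[float, float] | None = (1.0, 45.0),
                       pre_s: float = 0.2, post_s: float = 0.8,
                       rt_cutoff: float = 1.5
                       ) -> tuple[EpochSet, RegionEpochSet]:
    """Run the full conditioning chain in its fixed order.

    ``target_fs=None`` skips resampling and ``band=None`` skips filtering
    (useful for noiseless algebra checks).  Returns the channel-level and
    the region-pooled epochs.
    """
    if target_fs is not None:
        rec = resample(rec, target_fs)
    rec = rereference_average(rec)
    if band is not None:
        rec = bandpass_fir(rec, band[0], band[1])
    rec = ica_hook(rec)
    epochs = epoch(rec, pre_s=pre_s, post_s=post_s)
    epochs = reject_trials(epochs, rt_cutoff=rt_cutoff)
    return epochs, region_average(epochs)
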