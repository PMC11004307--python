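"""ERP averaging, IRP difference waves, components, and effect sizes.

The information-related potential (IRP) is the difference wave
``IRP(t) = ERP_go(t) - ERP_nogo(t)``.  Under the additive evoked-potential
model, components evoked by the stimuli's physical and elemental attributes
are common to both conditions and cancel in the subtraction, leaving the
potentials evoked by the informational attributes of the Go stimuli
(plus residual background that shrinks as 1/sqrt(n_trials)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .montage import REGIONS
from .preprocess import EpochSet, region_average, rereference_average
from .simulate import GroundTruth, Recording

__all__ = [
    "Waveform", "TimeFreqMap", "EffectSizeResult",
    "compute_erp", "compute_irp", "detect_components", "time_frequency",
    "paired_effect", "effect_from_summary", "irp_template_correlation",
    "DEFAULT_COMPONENT_WINDOWS",
]

#: Default component search windows: label -> (t_lo s, t_hi s, polarity).
DEFAULT_COMPONENT_WINDOWS: dict[str, tuple[float, float, int]] = {
    "IN400": (0.35, 0.45, -1),
    "IP400": (0.35, 0.45, +1),
    "IN560": (0.50, 0.62, -1),
    "IP560": (0.50, 0.62, +1),
    "IN750": (0.70, 0.80, -1),
    "IP750": (0.70, 0.80, +1),
}


@dataclass(frozen=True)
class Waveform:
    """Average waveform: rows (regions or channels) x samples, microvolts."""

    data: np.ndarray
    fs: float
    tmin: float
    condition: str
    row_labels: tuple[str, ...]
    n_trials_go: int = 0
    n_trials_nogo: int = 0

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[-1]) / self.fs

    def to_frame(self) -> pd.DataFrame:
        """Tidy (row, time_s, value) representation."""
        t = self.times
        rows = [{"row": lab, "time_s": t[j], "value": self.data[i, j]}
                for i, lab in enumerate(self.row_labels)
                for j in range(len(t))]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TimeFreqMap:
    """Non-negative wavelet power: rows x frequencies x samples."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    row_labels: tuple[str, ...]


@dataclass(frozen=True)
class EffectSizeResult:
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    p_value: float
    cohens_d: float


def compute_erp(epochs: EpochSet, condition: str) -> Waveform:
    """Pointwise mean over kept trials of one condition."""
    data = epochs.kept(condition)
    if data.shape[0] == 0:
        raise ValueError(f"no kept trials of condition {condition!r}")
    counts = {"n_trials_go": 0, "n_trials_nogo": 0}
    counts[f"n_trials_{condition}"] = data.shape[0]
    return Waveform(data=data.mean(axis=0), fs=epochs.fs, tmin=epochs.tmin,
                    condition=condition, row_labels=tuple(epochs.labels()),
                    **counts)


def compute_irp(erp_go: Waveform, erp_nogo: Waveform) -> Waveform:
    """Difference wave ERP(Go) - ERP(Nogo)."""
    if (erp_go.fs != erp_nogo.fs or erp_go.tmin != erp_nogo.tmin
            or erp_go.data.shape != erp_nogo.data.shape
            or erp_go.row_labels != erp_nogo.row_labels):
        raise ValueError("ERP waveforms have mismatched axes or layout")
    return Waveform(data=erp_go.data - erp_nogo.data, fs=erp_go.fs,
                    tmin=erp_go.tmin, condition="irp",
                    row_labels=erp_go.row_labels,
                    n_trials_go=erp_go.n_trials_go,
                    n_trials_nogo=erp_nogo.n_trials_nogo)


def detect_components(irp: Waveform,
                      windows: dict[str, tuple[float, float, int]] | None = None,
                      regions: tuple[str, ...] | None = None,
                      k: float = 3.0) -> pd.DataFrame:
    """Locate polarity-specific extrema of the IRP in labelled windows.

    For each (window, region) pair the extremum of the window's polarity is
    reported; it is flagged ``present`` when its magnitude exceeds ``k``
    times the region's baseline-period (t < 0) standard deviation.
    Windows that do not fit inside the epoch are skipped.
    """
    if windows is None:
        windows = {lab: w for lab, w in DEFAULT_COMPONENT_WINDOWS.items()
                   if w[1] <= irp.times[-1] + 1e-9}
    rows = []
    t = irp.times
    baseline = irp.data[:, t < 0]
    base_sd = baseline.std(axis=1) if baseline.shape[1] else \
        np.full(irp.data.shape[0], np.nan)
    labels = regions or irp.row_labels
    for label, (t_lo, t_hi, polarity) in windows.items():
        sel = (t >= t_lo) & (t <= t_hi)
        if not sel.any():
            raise ValueError(f"window {label} is empty for this epoch")
        for region in labels:
            i = irp.row_labels.index(region)
            seg = irp.data[i, sel]
            j = int(np.argmax(polarity * seg))
            amp = float(seg[j])
            rows.append({
                "label": label, "region": region,
                "latency_s": float(t[sel][j]), "amplitude_uv": amp,
                "polarity": polarity,
                "present": bool(polarity * amp > 0
                                and abs(amp) > k * base_sd[i]),
                "t_lo": t_lo, "t_hi": t_hi,
            })
    return pd.DataFrame(rows)


def time_frequency(irp: Waveform, freqs, n_cycles: float = 3.0
                   ) -> TimeFreqMap:
    """Morlet-wavelet power of each row of the waveform.

    Uses a fixed ``n_cycles`` (default 3: the 1-6 Hz band needs short
    wavelets inside a one-second epoch, trading frequency resolution for
    temporal localization).
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= irp.fs / 2):
        raise ValueError("frequencies must be below Nyquist")
    # Zero-pad so the longest (lowest-frequency) wavelet fits the signal;
    # the pad is cropped from the output again.
    pad = int(math.ceil(3.0 * n_cycles / freqs.min() * irp.fs))
    padded = np.pad(irp.data, ((0, 0), (pad, pad)))[None]
    power = tfr_array_morlet(padded, sfreq=irp.fs, freqs=freqs,
                             n_cycles=n_cycles, output="power",
                             zero_mean=True)[0]
    power = power[:, :, pad:pad + irp.data.shape[-1]]
    return TimeFreqMap(power=power, freqs=freqs, times=irp.times,
                       row_labels=irp.row_labels)


def effect_from_summary(mean_a: float, sd_a: float, mean_b: float,
                        sd_b: float) -> float:
    """Cohen's d from group summaries, pooled-SD form.

    ``d = (mean_a - mean_b) / sqrt((sd_a^2 + sd_b^2) / 2)``.
    """
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be >= 0")
    pooled = math.sqrt((sd_a**2 + sd_b**2) / 2.0)
    if pooled == 0.0:
        if mean_a == mean_b:
            return 0.0
        raise ValueError("effect size undefined: zero pooled SD with "
                         "unequal means")
    return (mean_a - mean_b) / pooled


def paired_effect(values_a, values_b) -> EffectSizeResult:
    """Two-sided paired t-test plus Cohen's d (pooled-SD form)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    if np.allclose(a, b):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_rel(a, b)
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))
    return EffectSizeResult(
        mean_a=float(a.mean()), mean_b=float(b.mean()), sd_a=sd_a, sd_b=sd_b,
        t_statistic=float(t_stat), p_value=float(p),
        cohens_d=effect_from_summary(a.mean(), sd_a, b.mean(), sd_b))


def irp_template_correlation(irp: Waveform, gt: GroundTruth,
                             average_reference: bool = True) -> float:
    """Pearson correlation between a region-level IRP and the injected
    informational components.

    The expected waveform is the noiseless rendering of the ground-truth
    informational templates passed through the same deterministic spatial
    conditioning (average reference, region pooling) as the data, so a
    noiseless session yields exactly 1.
    """
    trace = gt.info_trace()
    rec = Recording(data=trace, fs=gt.fs, montage=gt.montage, events=(),
                    behavior=pd.DataFrame(columns=["condition", "rt",
                                                   "correct"]))
    if average_reference:
        rec = rereference_average(rec)
    expected = np.stack([rec.data[gt.montage.indices_in(r)].mean(axis=0)
                         for r in REGIONS])
    # Apply the same baseline correction as the epoching stage.
    t_full = gt.tmin + np.arange(expected.shape[-1]) / gt.fs
    pre = t_full < 0
    if pre.any():
        expected = expected - expected[:, pre].mean(axis=1, keepdims=True)
    if irp.fs != gt.fs:
        # Compare on the coarser time grid of the extracted IRP.
        step = int(round(gt.fs / irp.fs))
        expected = expected[:, ::step]
    n = min(expected.shape[-1], irp.data.shape[-1])
    return float(np.corrcoef(expected[:, :n].ravel(),
                             irp.data[:, :n].ravel())[0, 1])
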