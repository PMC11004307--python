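"""Synthetic Go/Nogo EEG sessions with known ground truth.

The generator follows the additive evoked-potential model that underlies
difference-wave analysis: every trial is the sum of (i) spontaneous
background activity that averages towards zero across trials, and (ii)
stimulus-locked evoked components that are identical across trials up to a
small latency jitter.  Go and Nogo trials share the components evoked by the
physical and elemental attributes of the stimulus; Go trials additionally
carry low-frequency "informational" components (the quantity the
information-related potential, IRP, is designed to isolate).  Because the
injected components are known exactly, every downstream stage — averaging,
subtraction, decoding, connectivity — can be validated against ground truth.

Components are modelled as Gabor atoms (Gaussian envelope x cosine carrier)
with per-region gains and small per-region latency offsets (~12 ms) that
mimic inter-region transmission delays.  The background is 1/f-shaped
Gaussian noise with an optional alpha (10 Hz) peak, built from a per-channel
independent part plus a component shared within each region so that
channels exhibit realistic spatial covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import REGIONS, Montage, make_montage

__all__ = [
    "ComponentTemplate",
    "BehaviorParams",
    "SessionConfig",
    "GroundTruth",
    "Recording",
    "make_montage",
    "simulate_background",
    "render_template",
    "simulate_session",
    "simulate_behavior",
    "vice_config",
    "aice_config",
]


@dataclass(frozen=True)
class ComponentTemplate:
    """One evoked component: a Gabor atom with regional topography.

    Parameters
    ----------
    label : str
        Name of the component (e.g. ``"IN400"``).
    latency : float
        Centre of the Gaussian envelope, seconds post-event.
    width : float
        Standard deviation of the Gaussian envelope, seconds.
    center_freq : float
        Carrier frequency in Hz (0 gives a pure Gaussian bump).
    amplitude : float
        Peak amplitude in microvolts; negative values model negative-going
        ("IN") waves, positive values positive-going ("IP") waves.
    region_weights : dict
        Region -> gain in [0, 1]; regions absent from the map get gain 0.
    region_lag : dict
        Region -> extra latency in seconds (inter-region transmission delay).
    """

    label: str
    latency: float
    width: float
    center_freq: float
    amplitude: float
    region_weights: dict[str, float] = field(hash=False)
    region_lag: dict[str, float] = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.center_freq < 0:
            raise ValueError("center_freq must be >= 0")
        for r, w in self.region_weights.items():
            if r not in REGIONS:
                raise ValueError(f"unknown region {r!r}")
            if abs(w) > 1:
                raise ValueError(f"|region weight| must be <= 1, got {w}")


@dataclass(frozen=True)
class BehaviorParams:
    """Reaction-time and accuracy model, per condition.

    RTs are lognormal with the stated mean and SD (in seconds, measured from
    stimulus onset); correctness is Bernoulli with the stated accuracy.
    """

    rt_mean_go: float = 0.91
    rt_sd_go: float = 0.15
    rt_mean_nogo: float = 0.69
    rt_sd_nogo: float = 0.12
    accuracy_go: float = 0.9456
    accuracy_nogo: float = 0.9823
    rt_cutoff: float = 1.5

    def __post_init__(self) -> None:
        for v in (self.rt_mean_go, self.rt_sd_go, self.rt_mean_nogo,
                  self.rt_sd_nogo):
            if v <= 0:
                raise ValueError("RT distribution parameters must be > 0")
        for a in (self.accuracy_go, self.accuracy_nogo):
            if not 0.0 <= a <= 1.0:
                raise ValueError("accuracy must lie in [0, 1]")


@dataclass(frozen=True)
class SessionConfig:
    """Full description of one simulated Go/Nogo session."""

    modality: str = "visual"
    n_go: int = 120
    n_nogo: int = 120
    fs: float = 1000.0
    tmin: float = -0.2
    tmax: float = 0.8
    iti: float = 1.5
    n_channels: int = 64
    shared_templates: tuple[ComponentTemplate, ...] = ()
    info_templates: tuple[ComponentTemplate, ...] = ()
    background_level: float = 2.5
    background_spectrum: dict = field(
        default_factory=lambda: {"one_over_f_exponent": 1.0,
                                 "alpha_peak_gain": 0.5,
                                 "shared_fraction": 0.5},
        hash=False)
    latency_jitter_sd: float = 0.010
    rng_seed: int = 0
    behavior_params: BehaviorParams = field(default_factory=BehaviorParams)

    def __post_init__(self) -> None:
        if self.modality not in ("visual", "auditory"):
            raise ValueError("modality must be 'visual' or 'auditory'")
        if self.n_go < 0 or self.n_nogo < 0:
            raise ValueError("trial counts must be non-negative")
        max_f = max((t.center_freq for t in
                     tuple(self.shared_templates) + tuple(self.info_templates)),
                    default=0.0)
        if self.fs <= 2 * max_f:
            raise ValueError("fs must exceed twice the highest template "
                             "carrier frequency")
        if self.iti < self.tmax - self.tmin:
            raise ValueError("inter-trial interval shorter than the epoch")


@dataclass(frozen=True)
class Recording:
    """Continuous multichannel EEG with event markers and behavior.

    ``data`` is channels x samples in microvolts; ``events`` is a list of
    ``(sample_index, condition)`` sorted by sample index; ``behavior`` has one
    row per event with columns ``condition``, ``rt`` (s) and ``correct``.
    """

    data: np.ndarray
    fs: float
    montage: Montage
    events: tuple[tuple[int, str], ...]
    behavior: pd.DataFrame = field(hash=False)

    def __post_init__(self) -> None:
        samples = [s for s, _ in self.events]
        if samples != sorted(samples):
            raise ValueError("events must be sorted by sample index")
        if samples and (samples[0] < 0 or samples[-1] >= self.data.shape[1]):
            raise ValueError("event outside the recording")


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to verify recovery of the injected signals.

    The noiseless evoked trace of any trial can be re-rendered exactly from
    the stored templates and per-trial jitters via :meth:`evoked_trace`, so
    the additivity identity (Go trace - Nogo trace = informational
    contribution) holds by construction.
    """

    conditions: tuple[str, ...]
    jitters: np.ndarray
    shared_templates: tuple[ComponentTemplate, ...]
    info_templates: tuple[ComponentTemplate, ...]
    montage: Montage = field(hash=False)
    fs: float = 1000.0
    tmin: float = -0.2
    tmax: float = 0.8
    behavior: pd.DataFrame | None = field(default=None, hash=False)

    def evoked_trace(self, trial: int) -> np.ndarray:
        """Noiseless channels x samples evoked trace of one trial."""
        tmpls = list(self.shared_templates)
        if self.conditions[trial] == "go":
            tmpls += list(self.info_templates)
        return sum(
            (render_template(t, self.fs, self.montage, self.tmin, self.tmax,
                             jitter=float(self.jitters[trial]))
             for t in tmpls),
            start=np.zeros(self._shape()),
        )

    def info_trace(self, jitter: float = 0.0) -> np.ndarray:
        """Channels x samples rendering of the informational components."""
        return sum(
            (render_template(t, self.fs, self.montage, self.tmin, self.tmax,
                             jitter=jitter) for t in self.info_templates),
            start=np.zeros(self._shape()),
        )

    def _shape(self) -> tuple[int, int]:
        n = int(round((self.tmax - self.tmin) * self.fs))
        return (self.montage.n_channels, n)


def _spectral_shape(freqs: np.ndarray, exponent: float,
                    alpha_peak_gain: float) -> np.ndarray:
    """Amplitude-shaping curve: 1/f^(exponent/2) with a 10 Hz bump."""
    shape = np.zeros_like(freqs)
    pos = freqs > 0
    shape[pos] = freqs[pos] ** (-exponent / 2.0)
    shape += alpha_peak_gain * np.exp(-((freqs - 10.0) ** 2) / (2 * 2.0**2))
    shape[0] = 0.0  # enforce zero mean
    return shape


def _shaped_noise(rng: np.random.Generator, n_signals: int, n_samples: int,
                  fs: float, exponent: float, alpha_peak_gain: float
                  ) -> np.ndarray:
    """Unit-RMS Gaussian noise with the requested power spectrum."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = _spectral_shape(freqs, exponent, alpha_peak_gain)
    # Variance of the shaped output for unit-variance white input.
    full = np.concatenate([shape, shape[-2 if n_samples % 2 == 0 else -1:0:-1]])
    scale = 1.0 / math.sqrt(np.mean(full**2))
    white = rng.standard_normal((n_signals, n_samples))
    spec = np.fft.rfft(white, axis=-1) * shape
    return np.fft.irfft(spec, n=n_samples, axis=-1) * scale


def simulate_background(fs: float, n_samples: int, montage: Montage,
                        spectrum_params: dict | None = None,
                        seed: int | np.random.SeedSequence = 0,
                        level: float = 1.0) -> np.ndarray:
    """Spontaneous background EEG: zero-mean 1/f-like Gaussian noise.

    Each channel is a mix of an independent component and a component shared
    by all channels of its region (mixing fraction ``shared_fraction``), so
    the spatial covariance is block-structured as in real recordings.  The
    per-channel RMS is ``level`` microvolts in expectation.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    p = {"one_over_f_exponent": 1.0, "alpha_peak_gain": 0.5,
         "shared_fraction": 0.5}
    if spectrum_params:
        p.update(spectrum_params)
    rho = float(p["shared_fraction"])
    if not 0.0 <= rho <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    own = _shaped_noise(rng, montage.n_channels, n_samples, fs,
                        p["one_over_f_exponent"], p["alpha_peak_gain"])
    shared = _shaped_noise(rng, len(REGIONS), n_samples, fs,
                           p["one_over_f_exponent"], p["alpha_peak_gain"])
    out = math.sqrt(1.0 - rho) * own
    for r_idx, region in enumerate(REGIONS):
        idx = montage.indices_in(region)
        if idx:
            out[idx] += math.sqrt(rho) * shared[r_idx]
    return level * out


def render_template(tmpl: ComponentTemplate, fs: float, montage: Montage,
                    tmin: float = -0.2, tmax: float = 0.8,
                    jitter: float = 0.0) -> np.ndarray:
    """Deterministic channels x samples rendering of one component.

    The waveform is ``amplitude * exp(-(t-c)^2 / (2 width^2)) *
    cos(2*pi*f*(t-c))`` with ``c = latency + region_lag``, scaled per channel
    by its region's weight.  The envelope (at +/-3 widths, ignoring jitter)
    must fit inside ``[tmin, tmax]``.
    """
    n = int(round((tmax - tmin) * fs))
    t = tmin + np.arange(n) / fs
    out = np.zeros((montage.n_channels, n))
    for region, weight in tmpl.region_weights.items():
        if weight == 0.0:
            continue
        c = tmpl.latency + tmpl.region_lag.get(region, 0.0)
        if c - 3 * tmpl.width < tmin or c + 3 * tmpl.width > tmax:
            raise ValueError(
                f"template {tmpl.label!r} extends past the trial span "
                f"[{tmin}, {tmax}] in region {region}")
        cj = c + jitter
        wave = (tmpl.amplitude * weight
                * np.exp(-((t - cj) ** 2) / (2 * tmpl.width**2))
                * np.cos(2 * np.pi * tmpl.center_freq * (t - cj)))
        out[montage.indices_in(region)] = wave
    return out


def simulate_behavior(cfg: SessionConfig, conditions, seed=None
                      ) -> pd.DataFrame:
    """Draw per-trial (RT, correct) under the lognormal/Bernoulli model."""
    bp = cfg.behavior_params
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    rt = np.empty(len(conditions))
    correct = np.empty(len(conditions), dtype=bool)
    for cond, mean, sd, acc in (
            ("go", bp.rt_mean_go, bp.rt_sd_go, bp.accuracy_go),
            ("nogo", bp.rt_mean_nogo, bp.rt_sd_nogo, bp.accuracy_nogo)):
        mask = np.asarray(conditions) == cond
        sigma2 = math.log(1.0 + (sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        rt[mask] = rng.lognormal(mu, math.sqrt(sigma2), size=mask.sum())
        correct[mask] = rng.random(mask.sum()) < acc
    return pd.DataFrame({"condition": list(conditions), "rt": rt,
                         "correct": correct})


def simulate_session(cfg: SessionConfig) -> tuple[Recording, GroundTruth]:
    """Generate one continuous session under the additive model.

    Every trial is background + shared components (+ informational
    components iff Go), with one latency jitter per trial applied to all of
    that trial's components.  The Go/Nogo order, background, jitters and
    behavioral draws are all reproducible from ``cfg.rng_seed``.
    """
    montage = make_montage(cfg.n_channels)
    ss = np.random.SeedSequence(cfg.rng_seed)
    s_bg, s_order, s_jit, s_beh = ss.spawn(4)

    n_trials = cfg.n_go + cfg.n_nogo
    conditions = np.array(["go"] * cfg.n_go + ["nogo"] * cfg.n_nogo)
    np.random.default_rng(s_order).shuffle(conditions)
    conditions = tuple(conditions)

    jitters = (np.random.default_rng(s_jit)
               .normal(0.0, cfg.latency_jitter_sd, size=n_trials)
               if cfg.latency_jitter_sd > 0 else np.zeros(n_trials))

    pad = 1.0
    onsets = np.round((pad + np.arange(n_trials) * cfg.iti - cfg.tmin)
                      * cfg.fs).astype(int)
    n_samples = int(math.ceil((pad + n_trials * cfg.iti + cfg.tmax + pad)
                              * cfg.fs))
    if cfg.background_level > 0:
        data = simulate_background(cfg.fs, n_samples, montage,
                                   cfg.background_spectrum, seed=s_bg,
                                   level=cfg.background_level)
    else:
        data = np.zeros((montage.n_channels, n_samples))

    n_epoch = int(round((cfg.tmax - cfg.tmin) * cfg.fs))
    i0 = int(round(-cfg.tmin * cfg.fs))  # epoch sample of the event
    for i, onset in enumerate(onsets):
        tmpls = list(cfg.shared_templates)
        if conditions[i] == "go":
            tmpls += list(cfg.info_templates)
        if not tmpls:
            continue
        evoked = sum(
            (render_template(t, cfg.fs, montage, cfg.tmin, cfg.tmax,
                             jitter=float(jitters[i])) for t in tmpls),
            start=np.zeros((montage.n_channels, n_epoch)),
        )
        data[:, onset - i0:onset - i0 + n_epoch] += evoked

    behavior = simulate_behavior(cfg, conditions, seed=s_beh)
    events = tuple((int(s), c) for s, c in zip(onsets, conditions))
    rec = Recording(data=data, fs=cfg.fs, montage=montage, events=events,
                    behavior=behavior)
    gt = GroundTruth(conditions=conditions, jitters=jitters,
                     shared_templates=tuple(cfg.shared_templates),
                     info_templates=tuple(cfg.info_templates),
                     montage=montage, fs=cfg.fs, tmin=cfg.tmin, tmax=cfg.tmax,
                     behavior=behavior)
    return rec, gt


# ---------------------------------------------------------------------------
# Default component sets and session presets
# ---------------------------------------------------------------------------

def _visual_shared() -> tuple[ComponentTemplate, ...]:
    return (
        ComponentTemplate("P1", 0.12, 0.030, 8.0, 6.0,
                          {"OL": 1.0, "OR": 1.0, "PL": 0.5, "PR": 0.5}),
        ComponentTemplate("N1", 0.20, 0.040, 6.0, -5.0,
                          {"OL": 0.8, "OR": 0.8, "TL": 0.6, "TR": 0.6,
                           "FL": 0.3, "FR": 0.3}),
        ComponentTemplate("P2", 0.30, 0.060, 4.0, 4.0,
                          {"PL": 0.8, "PR": 0.8, "FL": 0.5, "FR": 0.5}),
    )


def _visual_info() -> tuple[ComponentTemplate, ...]:
    # Negative wave in left frontal / left parietal / left occipital,
    # positive in right frontal, centred near 400 ms, 1-6 Hz band,
    # with ~12 ms inter-region transmission lags (occipital leads).
    return (
        ComponentTemplate("IN400", 0.40, 0.10, 4.0, -4.0,
                          {"FL": 1.0, "PL": 0.8, "OL": 0.8},
                          {"OL": 0.0, "FL": 0.012, "PL": 0.024}),
        ComponentTemplate("IP400", 0.40, 0.10, 4.0, 4.0,
                          {"FR": 1.0}, {"FR": 0.012}),
    )


def _auditory_shared() -> tuple[ComponentTemplate, ...]:
    return (
        ComponentTemplate("N1", 0.10, 0.030, 7.0, -5.0,
                          {"TL": 1.0, "TR": 1.0, "FL": 0.5, "FR": 0.5}),
        ComponentTemplate("P2", 0.25, 0.050, 5.0, 4.0,
                          {"FL": 0.7, "FR": 0.7, "TL": 0.6, "TR": 0.6}),
    )


def _auditory_info() -> tuple[ComponentTemplate, ...]:
    # Negative wave in both frontal regions near 750 ms, positive in the
    # parietal regions and right temporal region (temporal leads).
    return (
        ComponentTemplate("IN750", 0.75, 0.07, 3.0, -4.0,
                          {"FL": 1.0, "FR": 1.0},
                          {"FL": 0.012, "FR": 0.012}),
        ComponentTemplate("IP750", 0.75, 0.07, 3.0, 4.0,
                          {"PL": 0.8, "PR": 0.8, "TR": 0.6},
                          {"TR": 0.0, "PL": 0.024, "PR": 0.024}),
    )


def vice_config(seed: int = 0, fs: float = 1000.0, n_go: int = 120,
                n_nogo: int = 120, n_channels: int = 64,
                **overrides) -> SessionConfig:
    """Visual session preset: 240 balanced trials, I400-type components."""
    cfg = SessionConfig(
        modality="visual", n_go=n_go, n_nogo=n_nogo, fs=fs,
        n_channels=n_channels, tmin=-0.2, tmax=0.8,
        shared_templates=_visual_shared(), info_templates=_visual_info(),
        rng_seed=seed,
        behavior_params=BehaviorParams(rt_mean_go=0.91, rt_sd_go=0.15,
                                       rt_mean_nogo=0.69, rt_sd_nogo=0.12,
                                       accuracy_go=0.9456,
                                       accuracy_nogo=0.9823, rt_cutoff=1.5))
    return replace(cfg, **overrides) if overrides else cfg


def aice_config(seed: int = 0, fs: float = 1000.0, n_go: int = 120,
                n_nogo: int = 120, n_channels: int = 64,
                **overrides) -> SessionConfig:
    """Auditory session preset: 240 balanced trials, I750-type components.

    Epochs extend to 1.0 s post-event so the late informational component
    and the 650-900 ms connectivity window fit inside the trial.
    """
    cfg = SessionConfig(
        modality="auditory", n_go=n_go, n_nogo=n_nogo, fs=fs,
        n_channels=n_channels, tmin=-0.2, tmax=1.0,
        shared_templates=_auditory_shared(), info_templates=_auditory_info(),
        rng_seed=seed,
        behavior_params=BehaviorParams(rt_mean_go=1.57, rt_sd_go=0.20,
                                       rt_mean_nogo=1.29, rt_sd_nogo=0.18,
                                       accuracy_go=0.9333,
                                       accuracy_nogo=0.9916, rt_cutoff=3.0))
    return replace(cfg, **overrides) if overrides else cfg
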