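"""Config-driven end-to-end runs: simulate -> preprocess -> IRP -> decode
-> network, with seed control, archived configuration and a machine-readable
run report.

A single global seed is expanded deterministically (via
``numpy.random.SeedSequence.spawn``) into one child seed per simulated
subject plus one for the decoder's fold shuffling, so every stage is
individually reproducible and a full run is bit-reproducible from
``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decode as dec
from . import erp as erpmod
from . import io as iomod
from . import network as netmod
from . import preprocess as pre
from .montage import REGIONS
from .simulate import SessionConfig, aice_config, simulate_session, \
    vice_config

__all__ = ["RunConfig", "RunReport", "validate_config", "run_pipeline",
           "ALL_STAGES"]

logger = logging.getLogger("irplab")

ALL_STAGES = ("simulate", "preprocess", "erp", "decode", "network")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a full analysis run."""

    session: SessionConfig
    seed: int = 0
    out_dir: str = "irp_run"
    # preprocessing
    target_fs: float | None = 250.0
    band: tuple[float, float] | None = (1.0, 45.0)
    rt_cutoff: float | None = None      # None -> session behavior cutoff
    # component detection
    component_k: float = 3.0
    # decoding
    decode_band: tuple[float, float] = (1.0, 6.0)
    tau: float = 0.012
    n_pairs: int = 3
    n_folds: int = 5
    window_length: float = 0.2
    window_shift: float = 0.1
    # networks
    network_band: tuple[float, float] = (1.0, 6.0)
    network_q: float = 0.3
    network_order: int | None = None
    n_subjects: int = 4
    save_recording: bool = False

    @classmethod
    def from_preset(cls, preset: str, seed: int = 0, out_dir: str = "irp_run",
                    **session_overrides) -> "RunConfig":
        """Bundled presets: 'vice' (visual) or 'aice' (auditory) sessions."""
        if preset == "vice":
            session = vice_config(seed=seed, **session_overrides)
        elif preset == "aice":
            session = aice_config(seed=seed, **session_overrides)
        else:
            raise ValueError(f"unknown preset {preset!r}")
        return cls(session=session, seed=seed, out_dir=out_dir)

    def effective_rt_cutoff(self) -> float:
        return (self.rt_cutoff if self.rt_cutoff is not None
                else self.session.behavior_params.rt_cutoff)

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class RunReport:
    """Per-stage provenance, produced files (with checksums), checks."""

    stages: list[str] = field(default_factory=list)
    seeds: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)
    checks: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {"stages": self.stages, "seeds": self.seeds,
                   "files": self.files, "checks": self.checks,
                   "tables": self.tables}
        text = json.dumps(payload, indent=1, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def validate_config(config: RunConfig) -> list[str]:
    """Collect human-readable config problems; never raises."""
    problems: list[str] = []
    try:
        s = config.session
        fs = config.target_fs or s.fs
        for name, band in (("preprocess", config.band),
                           ("decode", config.decode_band),
                           ("network", config.network_band)):
            if band is not None and band[1] >= fs / 2:
                problems.append(
                    f"{name} band upper edge {band[1]} Hz violates the "
                    f"Nyquist limit at fs={fs} Hz")
            if band is not None and not 0 < band[0] < band[1]:
                problems.append(f"{name} band {band} is not increasing")
        epoch_len = s.tmax - s.tmin
        if config.window_length > epoch_len:
            problems.append("decoding window longer than the epoch")
        win = netmod.NETWORK_WINDOWS.get(s.modality)
        if win and win[1] > s.tmax + 1e-9:
            problems.append(
                f"network window {win} extends past the epoch end {s.tmax}")
        for t in tuple(s.shared_templates) + tuple(s.info_templates):
            c = t.latency + max([0.0, *t.region_lag.values()])
            if c + 3 * t.width > s.tmax or c - 3 * t.width < s.tmin:
                problems.append(
                    f"component {t.label!r} extends outside the epoch")
        if round(config.tau * fs) >= round(config.window_length * fs):
            problems.append("CSSP delay tau is not shorter than the window")
        if not 0 < config.network_q <= 1:
            problems.append("network edge density q must lie in (0, 1]")
        if config.n_subjects < 1:
            problems.append("n_subjects must be >= 1")
    except Exception as exc:  # malformed config objects
        problems.append(f"config could not be validated: {exc}")
    return problems


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _subject_metrics(repochs, modality, band, q, order):
    """Per-region clustering coefficients for Go and Nogo."""
    rows = {}
    for cond in ("go", "nogo"):
        net = netmod.window_networks(repochs, windows=modality, band=band,
                                     condition=cond, order=order)[0]
        net = netmod.threshold_adjacency(net, q=q)
        rows[cond] = netmod.clustering_coefficients(net.adjacency)
    return rows["go"], rows["nogo"]


def run_pipeline(config: RunConfig, stages=ALL_STAGES) -> RunReport:
    """Execute the requested stages in their fixed order and write outputs.

    Stage order is always simulate -> preprocess -> erp -> decode ->
    network; requesting a late stage runs its prerequisites.  Every output
    file is listed in the report with a SHA-256 checksum.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration:\n- " + "\n- ".join(problems))
    requested = [s for s in ALL_STAGES if s in stages]
    if not requested:
        raise ValueError(f"no known stage in {stages!r}")
    last = ALL_STAGES.index(requested[-1])
    todo = ALL_STAGES[:last + 1]

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    config.to_yaml(out / "config.yaml")

    s = config.session
    if s.n_go != s.n_nogo:
        logger.warning("n_go (%d) != n_nogo (%d): the balanced-design "
                       "assumption behind the IRP subtraction is relaxed",
                       s.n_go, s.n_nogo)

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects + 1)
    subj_seeds = [int(c.generate_state(1)[0] % 2**31) for c in
                  children[:config.n_subjects]]
    decode_seed = int(children[-1].generate_state(1)[0] % 2**31)
    report.seeds = {"global": config.seed, "subjects": subj_seeds,
                    "decode": decode_seed}

    def _session_for(seed):
        return simulate_session(dataclasses.replace(s, rng_seed=seed))

    def _preprocess(rec):
        return pre.preprocess_session(
            rec, target_fs=config.target_fs, band=config.band,
            pre_s=-s.tmin, post_s=s.tmax,
            rt_cutoff=config.effective_rt_cutoff())

    cur = None
    try:
        # --- simulate -----------------------------------------------------
        cur = "simulate"
        rec, gt = _session_for(subj_seeds[0])
        rec.behavior.to_csv(out / "behavior.csv", index=False)
        if config.save_recording:
            iomod.save_recording(rec, out / "recording")
        report.stages.append(cur)

        # --- preprocess ---------------------------------------------------
        if "preprocess" in todo:
            cur = "preprocess"
            epochs, repochs = _preprocess(rec)
            rej = pre.rejection_report(epochs)
            rej.to_csv(out / "rejection.csv", index=False)
            base = epochs.data[epochs.kept_mask][:, :, epochs.times < 0]
            report.checks["max_abs_baseline_mean"] = float(
                np.abs(base.mean(axis=-1)).max()) if base.size else 0.0
            report.stages.append(cur)

        # --- erp ----------------------------------------------------------
        if "erp" in todo:
            cur = "erp"
            erp_go = erpmod.compute_erp(repochs, "go")
            erp_nogo = erpmod.compute_erp(repochs, "nogo")
            irp = erpmod.compute_irp(erp_go, erp_nogo)
            wide = pd.DataFrame(
                {"time_s": irp.times,
                 **{f"go_{r}": erp_go.data[i] for i, r in enumerate(REGIONS)},
                 **{f"nogo_{r}": erp_nogo.data[i]
                    for i, r in enumerate(REGIONS)},
                 **{f"irp_{r}": irp.data[i] for i, r in enumerate(REGIONS)}})
            wide.to_csv(out / "waveforms.csv", index=False)
            comps = erpmod.detect_components(irp, k=config.component_k)
            comps.to_csv(out / "components.csv", index=False)
            report.tables["components_present"] = int(comps["present"].sum())
            report.checks["irp_template_correlation"] = \
                erpmod.irp_template_correlation(irp, gt)
            report.stages.append(cur)

        # --- decode -------------------------------------------------------
        if "decode" in todo:
            cur = "decode"
            dep = dec.select_channels(epochs, s.modality)
            dep = dec.butter_band(dep, *config.decode_band)
            curve = dec.crossval_decode(
                dep, scheme=dec.WindowScheme(config.window_length,
                                             config.window_shift),
                tau=config.tau, n_pairs=config.n_pairs,
                n_folds=config.n_folds, seed=decode_seed)
            curve.to_frame().to_csv(out / "accuracy_curve.csv", index=False)
            report.tables["peak_accuracy"] = float(curve.mean_acc.max())
            report.tables["peak_window"] = list(curve.peak_window)
            report.stages.append(cur)

        # --- network ------------------------------------------------------
        if "network" in todo:
            cur = "network"
            go_cc = np.empty((config.n_subjects, len(REGIONS)))
            nogo_cc = np.empty_like(go_cc)
            go_cc[0], nogo_cc[0] = _subject_metrics(
                repochs, s.modality, config.network_band, config.network_q,
                config.network_order)
            for i in range(1, config.n_subjects):
                rec_i, _ = _session_for(subj_seeds[i])
                _, rep_i = _preprocess(rec_i)
                go_cc[i], nogo_cc[i] = _subject_metrics(
                    rep_i, s.modality, config.network_band,
                    config.network_q, config.network_order)
            if config.n_subjects >= 2:
                table = netmod.compare_conditions(go_cc, nogo_cc)
            else:
                table = pd.DataFrame({"region": REGIONS,
                                      "go_mean": go_cc[0],
                                      "nogo_mean": nogo_cc[0]})
            table.to_csv(out / "network_table.csv", index=False)
            report.stages.append(cur)
    except Exception:
        logger.exception("pipeline failed during stage %r; partial outputs "
                         "remain under %s", cur, out)
        raise

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "report.json":
            report.files[f.name] = _sha256(f)
    report.to_json(out / "report.json")
    return report
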