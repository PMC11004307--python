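"""Disk layout for recordings, epochs and configuration files.

A :class:`~irplab.simulate.Recording` is stored as a directory holding the
raw array (``data.npy``, channels x samples, microvolts), a JSON sidecar
(``meta.json``: sampling rate, channel labels, region map, events) and the
behavioral log (``behavior.csv``).  Epoch sets use the same convention with
the trial axis first.  Session configurations round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .montage import Montage
from .preprocess import EpochSet
from .simulate import (BehaviorParams, ComponentTemplate, Recording,
                       SessionConfig)

__all__ = [
    "save_recording", "load_recording", "save_epochs", "load_epochs",
    "config_to_yaml", "config_from_yaml",
]


def save_recording(rec: Recording, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "data.npy", rec.data)
    meta = {
        "fs": rec.fs,
        "channel_labels": list(rec.montage.channel_labels),
        "region_of": dict(rec.montage.region_of),
        "events": [[int(s), c] for s, c in rec.events],
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    rec.behavior.to_csv(path / "behavior.csv", index=False)
    return path


def load_recording(path) -> Recording:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    montage = Montage(tuple(meta["channel_labels"]), meta["region_of"])
    behavior = pd.read_csv(path / "behavior.csv")
    return Recording(data=np.load(path / "data.npy"), fs=meta["fs"],
                     montage=montage,
                     events=tuple((s, c) for s, c in meta["events"]),
                     behavior=behavior)


def save_epochs(epochs: EpochSet, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "data.npy", epochs.data)
    meta = {
        "fs": epochs.fs,
        "tmin": epochs.tmin,
        "conditions": list(map(str, epochs.conditions)),
        "kept_mask": epochs.kept_mask.astype(int).tolist(),
        "channel_labels": list(epochs.labels()),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    if epochs.behavior is not None:
        epochs.behavior.to_csv(path / "behavior.csv", index=False)
    return path


def load_epochs(path) -> EpochSet:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    beh_file = path / "behavior.csv"
    return EpochSet(data=np.load(path / "data.npy"), fs=meta["fs"],
                    tmin=meta["tmin"],
                    conditions=np.array(meta["conditions"]),
                    kept_mask=np.array(meta["kept_mask"], dtype=bool),
                    channel_labels=tuple(meta["channel_labels"]),
                    behavior=pd.read_csv(beh_file) if beh_file.exists()
                    else None)


def _template_to_dict(t: ComponentTemplate) -> dict:
    return dataclasses.asdict(t)


def config_to_yaml(cfg: SessionConfig, path=None) -> str:
    """Serialize a SessionConfig to YAML (returned, optionally written)."""
    d = dataclasses.asdict(cfg)
    text = yaml.safe_dump(d, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_from_yaml(source) -> SessionConfig:
    """Load a SessionConfig from a YAML string or file path."""
    try:
        is_file = Path(source).is_file()
    except (OSError, ValueError):
        is_file = False
    text = Path(source).read_text() if is_file else str(source)
    d = yaml.safe_load(text)
    d["shared_templates"] = tuple(ComponentTemplate(**t)
                                  for t in d.get("shared_templates", ()))
    d["info_templates"] = tuple(ComponentTemplate(**t)
                                for t in d.get("info_templates", ()))
    if "behavior_params" in d and isinstance(d["behavior_params"], dict):
        d["behavior_params"] = BehaviorParams(**d["behavior_params"])
    return SessionConfig(**d)
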