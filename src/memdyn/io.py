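"""Serialization: behavioral tables as TSV, feature tensors as npz + JSON
sidecar, and YAML configuration round-trips."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import FeatureTensor
from .synthetic import BehaviorSession

__all__ = [
    "write_behavior",
    "read_behavior",
    "write_feature_tensor",
    "read_feature_tensor",
    "write_config",
    "read_config",
]


def write_behavior(session: BehaviorSession, directory: str | Path) -> None:
    """Write one session's presentation and recall tables as TSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{session.participant}_s{session.session:02d}"
    session.presentations.to_csv(
        directory / f"{stem}_presentations.tsv", sep="\t", index=False
    )
    session.recalls.to_csv(
        directory / f"{stem}_recalls.tsv", sep="\t", index=False
    )


def read_behavior(
    directory: str | Path, participant: str, session: int
) -> BehaviorSession:
    directory = Path(directory)
    stem = f"{participant}_s{session:02d}"
    presentations = pd.read_csv(
        directory / f"{stem}_presentations.tsv", sep="\t"
    )
    recalls = pd.read_csv(directory / f"{stem}_recalls.tsv", sep="\t")
    return BehaviorSession(
        participant=participant,
        session=session,
        presentations=presentations,
        recalls=recalls,
    )


def write_feature_tensor(tensor: FeatureTensor, path: str | Path) -> None:
    """Save a feature tensor as ``<path>.npz`` + ``<path>.json`` sidecar."""
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"), values=tensor.values, freqs=tensor.freqs
    )
    sidecar = {
        "session": tensor.session,
        "phase": tensor.phase,
        "channels": tensor.channels,
        "events": tensor.events.to_dict(orient="list"),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_feature_tensor(path: str | Path) -> FeatureTensor:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return FeatureTensor(
        values=arrays["values"],
        freqs=arrays["freqs"],
        channels=sidecar["channels"],
        events=pd.DataFrame(sidecar["events"]),
        session=sidecar["session"],
        phase=sidecar["phase"],
    )


def write_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
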