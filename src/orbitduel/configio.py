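"""Configuration and trajectory file handling.

Stimulus configurations are JSON or YAML; trajectories and eye traces
are CSV with a JSON sidecar carrying the frame label, anchor, dt and
provenance so a file round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fit import ObserverTrace
from .kinematics import StimulusConfig, Trajectory

__all__ = [
    "load_config", "save_config",
    "write_trajectory", "read_trajectory",
    "write_observer_trace", "read_observer_trace",
]


def load_config(path: str | Path) -> StimulusConfig:
    """Read a stimulus configuration from a .json/.yaml/.yml file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return StimulusConfig.from_dict(data)


def save_config(config: StimulusConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".csv" \
        else path.with_suffix(".json")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as `t,x,y` CSV plus a JSON sidecar."""
    path = Path(path)
    pd.DataFrame({"t": traj.t, "x": traj.xy[:, 0], "y": traj.xy[:, 1]}).to_csv(
        path, index=False)
    meta = {
        "frame": traj.frame,
        "anchor": [float(traj.anchor[0]), float(traj.anchor[1])],
        "dt": traj.dt,
        "provenance": traj.provenance,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path)
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
    else:
        meta = {"frame": "world", "anchor": [float(df["x"].mean()), float(df["y"].mean())],
                "provenance": {}}
    return Trajectory(frame=meta["frame"], anchor=np.asarray(meta["anchor"]),
                      t=df["t"].to_numpy(), xy=df[["x", "y"]].to_numpy(),
                      provenance=meta.get("provenance", {}))


def write_observer_trace(trace: ObserverTrace, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"t": trace.t, "x": trace.xy[:, 0], "y": trace.xy[:, 1]}).to_csv(
        path, index=False)
    _sidecar(path).write_text(json.dumps(trace.metadata, indent=2) + "\n")


def read_observer_trace(path: str | Path) -> ObserverTrace:
    path = Path(path)
    df = pd.read_csv(path)
    side = _sidecar(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    return ObserverTrace(t=df["t"].to_numpy(), xy=df[["x", "y"]].to_numpy(), metadata=meta)
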