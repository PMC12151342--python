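"""HDF5 / CSV / JSON / YAML persistence for experiments and analysis products.

Experiments are written as HDF5 with groups ``/tracking`` (x, y, heading,
tail_angle), ``/stimulus`` (power, temperature), ``/bouts`` (start/end frame
table plus kinematics) and ``/meta`` (condition, phase, frame rate, seeds).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .bouts import BoutEvent, bout_table
from .rf import ReceptiveField
from .simulate import Experiment, Trajectory


def save_experiment(path: str | Path, exp: Experiment, **meta) -> None:
    with h5py.File(path, "w") as f:
        tr = f.create_group("tracking")
        tr["x"] = exp.trajectory.x
        tr["y"] = exp.trajectory.y
        tr["heading"] = exp.trajectory.heading
        if exp.trajectory.tail_angle is not None:
            tr["tail_angle"] = exp.trajectory.tail_angle
        st = f.create_group("stimulus")
        st["temperature"] = exp.temperature
        if exp.power is not None:
            st["power"] = exp.power
        bt = f.create_group("bouts")
        bt["start_frame"] = np.array([b.start_frame for b in exp.true_bouts], dtype=np.int64)
        bt["end_frame"] = np.array([b.end_frame for b in exp.true_bouts], dtype=np.int64)
        bt["displacement_mm"] = np.array([b.displacement_mm for b in exp.true_bouts])
        bt["turn_angle_deg"] = np.array([b.turn_angle_deg for b in exp.true_bouts])
        mg = f.create_group("meta")
        mg.attrs["condition"] = exp.condition
        mg.attrs["exp_id"] = exp.exp_id
        mg.attrs["phase"] = exp.trajectory.phase
        mg.attrs["frame_rate"] = exp.trajectory.frame_rate
        for k, v in meta.items():
            mg.attrs[k] = v


def load_experiment(path: str | Path) -> Experiment:
    with h5py.File(path, "r") as f:
        tr = f["tracking"]
        traj = Trajectory(
            x=tr["x"][:],
            y=tr["y"][:],
            heading=tr["heading"][:],
            tail_angle=tr["tail_angle"][:] if "tail_angle" in tr else None,
            frame_rate=float(f["meta"].attrs["frame_rate"]),
            phase=str(f["meta"].attrs["phase"]),
        )
        bouts = [
            BoutEvent(int(s), int(e), displacement_mm=float(d),
                      turn_angle_deg=float(t), kinematics_valid=bool(np.isfinite(d)))
            for s, e, d, t in zip(
                f["bouts/start_frame"][:], f["bouts/end_frame"][:],
                f["bouts/displacement_mm"][:], f["bouts/turn_angle_deg"][:],
            )
        ]
        return Experiment(
            trajectory=traj,
            temperature=f["stimulus/temperature"][:],
            power=f["stimulus/power"][:] if "power" in f["stimulus"] else None,
            true_bouts=bouts,
            condition=str(f["meta"].attrs["condition"]),
            exp_id=str(f["meta"].attrs["exp_id"]),
        )


def save_bout_csv(path: str | Path, bouts: Sequence[BoutEvent], frame_rate: float = 250.0) -> None:
    bout_table(bouts, frame_rate).to_csv(path, index=False)


def load_bout_csv(path: str | Path, frame_rate: float = 250.0) -> pd.DataFrame:
    return pd.read_csv(path)


def save_receptive_field(path_csv: str | Path, rf: ReceptiveField, **meta) -> None:
    """RF as CSV (lag_s, temp_coeff, bout_coeff) plus a JSON sidecar."""
    pd.DataFrame(
        {"lag_s": rf.lags_s, "temp_coeff": rf.temp_coeffs, "bout_coeff": rf.bout_coeffs}
    ).to_csv(path_csv, index=False)
    sidecar = Path(path_csv).with_suffix(".json")
    payload = {"p_bar": rf.p_bar, "lp_bar": rf.lp_bar, "bin_rate_hz": rf.bin_rate_hz, **meta}
    sidecar.write_text(json.dumps(payload, indent=2))


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def save_config(path: str | Path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))
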