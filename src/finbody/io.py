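"""Delimited-text I/O for epochs, bout tables, presets and configs.

All on-disk formats are plain text: tracked epochs and bout tables as
comma-separated tables with headers, presets and run configurations as
YAML key/value documents.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .kinematics import TrackedEpoch
from .models import DoubleSigmoidParams, SigmoidParams
from .presets import (
    ConstantCoupling,
    DecoupledCoupling,
    DoubleSigmoidCoupling,
    FinBiasPreset,
    SigmoidCoupling,
    SimPreset,
)

__all__ = [
    "EPOCH_COLUMNS",
    "write_epochs",
    "read_epochs",
    "write_bouts",
    "read_bouts",
    "save_preset",
    "load_preset",
]

EPOCH_COLUMNS = ["epoch_id", "time_s", "x_mm", "z_mm", "posture_deg"]


def write_epochs(epochs, path) -> None:
    """Write one or more tracked epochs as a single delimited table."""
    if isinstance(epochs, TrackedEpoch):
        epochs = [epochs]
    frames = [
        pd.DataFrame({
            "epoch_id": e.epoch_id,
            "time_s": e.time,
            "x_mm": e.x,
            "z_mm": e.z,
            "posture_deg": e.posture,
        })
        for e in epochs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_epochs(path) -> list[TrackedEpoch]:
    """Read tracked epochs from delimited text (header required)."""
    df = pd.read_csv(path)
    missing = set(EPOCH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"epoch table missing columns: {sorted(missing)}")
    out = []
    for eid, g in df.groupby("epoch_id", sort=False):
        out.append(TrackedEpoch(
            epoch_id=str(eid),
            time=g["time_s"].to_numpy(),
            x=g["x_mm"].to_numpy(),
            z=g["z_mm"].to_numpy(),
            posture=g["posture_deg"].to_numpy(),
        ))
    return out


def write_bouts(bouts: pd.DataFrame, path) -> None:
    bouts.to_csv(path, index=False)


def read_bouts(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _coupling_to_dict(coupling) -> dict:
    if isinstance(coupling, SigmoidCoupling):
        p = coupling.params
        return {"type": "sigmoid", "k": p.k, "gamma0": p.gamma0,
                "gamma_max": p.gamma_max, "r_rise": p.r_rise}
    if isinstance(coupling, DoubleSigmoidCoupling):
        p = coupling.params
        return {"type": "double_sigmoid", "chi": p.chi, "k": p.k,
                "gamma0": p.gamma0, "r_rise": p.r_rise, "gamma_max": p.gamma_max}
    if isinstance(coupling, DecoupledCoupling):
        return {"type": "decoupled", "mean": coupling.mean}
    if isinstance(coupling, ConstantCoupling):
        return {"type": "constant_negative", "value": coupling.value}
    raise TypeError(f"cannot serialize coupling {coupling!r}")


def _coupling_from_dict(d: dict):
    kind = d["type"]
    rest = {k: v for k, v in d.items() if k != "type"}
    if kind == "sigmoid":
        return SigmoidCoupling(SigmoidParams(**rest))
    if kind == "double_sigmoid":
        return DoubleSigmoidCoupling(DoubleSigmoidParams(**rest))
    if kind == "decoupled":
        return DecoupledCoupling(**rest)
    if kind == "constant_negative":
        return ConstantCoupling(**rest)
    raise ValueError(f"unknown coupling type {kind!r}")


def save_preset(preset: SimPreset, path) -> None:
    """Write a preset as a human-readable YAML key/value document."""
    d = dataclasses.asdict(preset)
    d["coupling"] = _coupling_to_dict(preset.coupling)
    d["kind"] = "fin_bias" if isinstance(preset, FinBiasPreset) else "sim"
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_preset(path) -> SimPreset:
    d = yaml.safe_load(Path(path).read_text())
    kind = d.pop("kind", "sim")
    d["coupling"] = _coupling_from_dict(d["coupling"])
    cls = FinBiasPreset if kind == "fin_bias" else SimPreset
    return cls(**d)
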