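"""Plain-text readers and writers: signal CSVs with JSON sidecars,
event annotations, cohort tables and report files.

A signal is stored as a two-column CSV (``time_s``, ``acc_vertical``) with
a JSON sidecar of the same stem holding ``sampling_rate``, ``distance_m``,
``trial_id`` and ``first_side``.  Event annotations are a long CSV
(``event``, ``side``, ``time_s``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .types import GaitEventSeries, RawGaitSignal

__all__ = [
    "write_signal_csv",
    "read_signal_csv",
    "write_events_csv",
    "read_events_csv",
    "write_json",
    "read_json",
]


def write_signal_csv(signal: RawGaitSignal, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_s": signal.times, "acc_vertical": signal.samples})
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = {
        "sampling_rate": signal.sampling_rate,
        "distance_m": signal.walk_distance,
        "trial_id": signal.trial_id,
        "first_side": signal.first_side,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_signal_csv(path: str | Path) -> RawGaitSignal:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ConfigError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    df = pd.read_csv(path)
    return RawGaitSignal(
        samples=df["acc_vertical"].to_numpy(),
        sampling_rate=float(meta["sampling_rate"]),
        walk_distance=float(meta["distance_m"]),
        trial_id=str(meta.get("trial_id", path.stem)),
        first_side=str(meta.get("first_side", "left")),
    )


def write_events_csv(events: GaitEventSeries, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for kind, side, arr in (
        ("heel_strike", "left", events.left_heel_strikes),
        ("heel_strike", "right", events.right_heel_strikes),
        ("toe_off", "left", events.left_toe_offs),
        ("toe_off", "right", events.right_toe_offs),
    ):
        rows.extend({"event": kind, "side": side, "time_s": t} for t in arr)
    pd.DataFrame(rows).sort_values("time_s").to_csv(
        path, index=False, float_format="%.6f"
    )
    return path


def read_events_csv(path: str | Path) -> GaitEventSeries:
    df = pd.read_csv(path)

    def pick(kind: str, side: str) -> np.ndarray:
        sel = df[(df["event"] == kind) & (df["side"] == side)]["time_s"]
        return np.sort(sel.to_numpy(dtype=float))

    return GaitEventSeries(
        left_heel_strikes=pick("heel_strike", "left"),
        right_heel_strikes=pick("heel_strike", "right"),
        left_toe_offs=pick("toe_off", "left"),
        right_toe_offs=pick("toe_off", "right"),
    )


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=default))
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
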