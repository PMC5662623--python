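"""Serialization of traces, protocols and results.

Trace ensembles travel as tidy CSV (time_s, fluorescence_au, bouton_id,
coverslip_id, genotype); protocols as YAML (JSON is a YAML subset and is
accepted transparently); image stacks as standard TIFF.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .model import BoutonTrace, Epoch, Protocol

PathLike = Union[str, Path]

TRACE_COLUMNS = ["time_s", "fluorescence_au", "bouton_id", "coverslip_id", "genotype"]


def traces_to_frame(traces: Sequence[BoutonTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        rows.append(
            pd.DataFrame(
                {
                    "time_s": tr.time,
                    "fluorescence_au": tr.fluorescence,
                    "bouton_id": tr.bouton_id,
                    "coverslip_id": tr.coverslip_id,
                    "genotype": tr.genotype,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_traces(traces: Sequence[BoutonTrace], path: PathLike) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces(path: PathLike, protocol: Protocol) -> list[BoutonTrace]:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    out = []
    for (cs, bt), grp in df.groupby(["coverslip_id", "bouton_id"], sort=True):
        grp = grp.sort_values("time_s")
        out.append(
            BoutonTrace(
                time=grp["time_s"].to_numpy(),
                fluorescence=grp["fluorescence_au"].to_numpy(),
                protocol=protocol,
                bouton_id=int(bt),
                coverslip_id=int(cs),
                genotype=str(grp["genotype"].iloc[0]),
            )
        )
    return out


def protocol_to_dict(protocol: Protocol) -> dict:
    return {
        "name": protocol.name,
        "frame_interval_s": protocol.frame_interval,
        "n_frames": protocol.n_frames,
        "epochs": [
            {
                "start_s": e.start,
                "end_s": e.end,
                "kind": e.kind,
                "frequency_hz": e.frequency_hz,
            }
            for e in protocol.epochs
        ],
        "baths": dict(protocol.baths),
    }


def protocol_from_dict(d: dict) -> Protocol:
    return Protocol(
        frame_interval=d["frame_interval_s"],
        n_frames=int(d["n_frames"]),
        epochs=tuple(
            Epoch(e["start_s"], e["end_s"], e["kind"], e.get("frequency_hz"))
            for e in d.get("epochs", [])
        ),
        baths={k: float(v) for k, v in (d.get("baths") or {}).items()},
        name=d.get("name", "custom"),
    )


def write_protocol(protocol: Protocol, path: PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(protocol_to_dict(protocol), sort_keys=False))


def read_protocol(path: PathLike) -> Protocol:
    return protocol_from_dict(yaml.safe_load(Path(path).read_text()))


def write_quant_table(df: pd.DataFrame, path: PathLike) -> None:
    """Per-bouton results, one row per bouton, absent fields left empty."""
    df.to_csv(path, index=False, na_rep="")


def write_diagnostics(diagnostics: list[dict], path: PathLike) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(diagnostics, indent=2, default=default))


def write_rois(rois, path: PathLike) -> None:
    pd.DataFrame(
        {
            "x": [left for _, left in rois.boxes],
            "y": [top for top, _ in rois.boxes],
            "w": rois.size,
            "h": rois.size,
            "channel": rois.channel,
        }
    ).to_csv(path, index=False)


def read_rois(path: PathLike):
    from .imaging import RoiSet

    df = pd.read_csv(path)
    boxes = [(int(y), int(x)) for y, x in zip(df["y"], df["x"])]
    centers = np.asarray([(y + 1.5, x + 1.5) for y, x in boxes], dtype=float)
    channel = int(df["channel"].iloc[0]) if len(df) else 0
    return RoiSet(boxes, centers, channel)
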