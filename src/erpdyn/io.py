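"""On-disk epoch container, clinical table and ground-truth serialisation.

The epoch container stores one subject/condition per pair of files:
``<subject>_<condition>.f32`` — a little-endian 32-bit float array, C order,
channels x samples x trials — plus ``<subject>_<condition>.json`` with
shape and acquisition metadata.  The sidecar is authoritative: any mismatch
with the payload size raises FormatError.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .containers import EpochSet
from .errors import FormatError
from .synthetic import GroundTruth

_SIDECAR_KEYS = {"subject_id", "group", "condition", "channel_names", "fs",
                 "t0_offset_ms", "shape", "dtype"}


def _stem(subject_id: str, condition: str) -> str:
    safe = re.sub(r"[^A-Za-z0-9_-]", "-", subject_id)
    return f"{safe}_{condition}"


def write_epochset(directory: Union[str, Path], epochs: EpochSet) -> Path:
    """Write payload + sidecar; returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = _stem(epochs.subject_id, epochs.condition)
    payload = np.ascontiguousarray(epochs.data, dtype="<f4")
    (directory / f"{stem}.f32").write_bytes(payload.tobytes())
    sidecar = {
        "subject_id": epochs.subject_id,
        "group": epochs.group,
        "condition": epochs.condition,
        "channel_names": list(epochs.channel_names),
        "fs": epochs.fs,
        "t0_offset_ms": epochs.t0_offset_ms,
        "shape": list(epochs.data.shape),
        "dtype": "<f4",
        "provenance": "erpdyn epoch container v1",
    }
    path = directory / f"{stem}.json"
    path.write_text(json.dumps(sidecar, indent=1))
    return path


def read_epochset(sidecar_path: Union[str, Path]) -> EpochSet:
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"unreadable sidecar {sidecar_path}: {exc}") from exc
    missing = _SIDECAR_KEYS - set(meta)
    if missing:
        raise FormatError(f"sidecar {sidecar_path} missing keys {sorted(missing)}")
    payload_path = sidecar_path.with_suffix(".f32")
    if not payload_path.exists():
        raise FormatError(f"missing payload {payload_path}")
    raw = np.frombuffer(payload_path.read_bytes(), dtype=meta["dtype"])
    shape = tuple(int(s) for s in meta["shape"])
    if len(shape) != 3 or raw.size != int(np.prod(shape)):
        raise FormatError(
            f"payload {payload_path} has {raw.size} values, sidecar shape {shape}"
        )
    data = raw.reshape(shape).astype(float)
    if not np.all(np.isfinite(data)):
        raise FormatError(f"non-finite values in payload {payload_path}")
    return EpochSet(
        subject_id=meta["subject_id"],
        group=meta["group"],
        condition=meta["condition"],
        data=data,
        channel_names=tuple(meta["channel_names"]),
        fs=float(meta["fs"]),
        t0_offset_ms=float(meta["t0_offset_ms"]),
    )


def write_cohort(directory: Union[str, Path], epochsets: List[EpochSet]) -> None:
    for ep in epochsets:
        write_epochset(directory, ep)


def read_cohort(directory: Union[str, Path]) -> List[EpochSet]:
    """Read every epoch container in a directory, sorted by filename."""
    directory = Path(directory)
    sets = []
    for sidecar in sorted(directory.glob("*.json")):
        if sidecar.name in ("ground_truth.json", "summary.json"):
            continue
        sets.append(read_epochset(sidecar))
    return sets


def write_clinical(path: Union[str, Path], clinical: pd.DataFrame) -> None:
    clinical.to_csv(path, index=False)


def read_clinical(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth(path: Union[str, Path], truth: GroundTruth) -> None:
    doc = {
        "templates": truth.templates.tolist(),
        "activation": {
            f"{sid}|{cond}": arr.tolist()
            for (sid, cond), arr in truth.activation.items()
        },
        "separation": truth.separation,
        "amplitude": truth.amplitude,
        "clinical_loadings": truth.clinical_loadings,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_ground_truth(path: Union[str, Path]) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    activation = {}
    for key, arr in doc["activation"].items():
        sid, cond = key.split("|")
        activation[(sid, cond)] = np.asarray(arr)
    return GroundTruth(
        templates=np.asarray(doc["templates"]),
        activation=activation,
        separation=doc["separation"],
        amplitude=doc["amplitude"],
        clinical_loadings=doc["clinical_loadings"],
        seed=doc["seed"],
    )
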