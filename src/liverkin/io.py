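"""Delimited-text readers and writers for TAC tables and fit reports.

TAC table format: CSV with header ``frame_start_s,frame_duration_s``
followed by one column per ROI; all ROIs share the schedule.  Protocol
configs are YAML with frame groups as ``count x seconds`` strings, e.g.
``"12x5,4x60"``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tac import DomainError, FrameSchedule, TimeActivityCurve, ROI_KINDS

__all__ = [
    "read_tac_table",
    "write_tac_table",
    "read_schedule_config",
    "write_manifest",
]

_META_COLS = ("frame_start_s", "frame_duration_s")


def read_tac_table(path: str | Path) -> dict[str, TimeActivityCurve]:
    """Read one TAC per ROI column from a delimited text table.

    Raises a parse error naming the offending row for missing columns
    or non-monotone/overlapping frames.
    """
    df = pd.read_csv(path)
    for col in _META_COLS:
        if col not in df.columns:
            raise DomainError(f"{path}: missing required column {col!r}")
    start = df["frame_start_s"].to_numpy(dtype=float)
    dur = df["frame_duration_s"].to_numpy(dtype=float)
    for i in range(1, start.size):
        if start[i] <= start[i - 1]:
            raise DomainError(f"{path}: frames not sorted at row {i + 1}")
        if start[i] - (start[i - 1] + dur[i - 1]) < -1e-9:
            raise DomainError(f"{path}: overlapping frames at row {i + 1}")
    if np.any(dur <= 0):
        bad = int(np.nonzero(dur <= 0)[0][0])
        raise DomainError(f"{path}: non-positive duration at row {bad + 1}")
    schedule = FrameSchedule(start, dur, label=Path(path).stem)
    rois = [c for c in df.columns if c not in _META_COLS]
    if not rois:
        raise DomainError(f"{path}: no ROI columns found")
    out = {}
    for roi in rois:
        kind = roi if roi in ROI_KINDS else "tissue"
        out[roi] = TimeActivityCurve(
            schedule,
            df[roi].to_numpy(dtype=float),
            roi_kind=kind,
            allow_negative=True,
        )
    return out


def write_tac_table(tacs: dict[str, TimeActivityCurve], path: str | Path) -> None:
    """Write ROI TACs sharing one schedule to a delimited text table."""
    if not tacs:
        raise DomainError("no TACs to write")
    first = next(iter(tacs.values())).schedule
    for t in tacs.values():
        if not (
            np.array_equal(t.schedule.start_s, first.start_s)
            and np.array_equal(t.schedule.duration_s, first.duration_s)
        ):
            raise DomainError("all TACs in one table must share the schedule")
    df = pd.DataFrame(
        {"frame_start_s": first.start_s, "frame_duration_s": first.duration_s}
    )
    for name, t in tacs.items():
        df[name] = t.values
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_schedule_config(path: str | Path) -> dict[str, FrameSchedule]:
    """Read named protocols from a YAML config.

    Each entry maps a protocol name to either a ``"12x5,4x60"`` string
    or a mapping with ``groups`` and optional ``extra_frames``
    ``[[start_s, duration_s], ...]``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DomainError(f"{path}: expected a mapping of protocol -> frames")
    out = {}
    for name, spec in cfg.items():
        if isinstance(spec, str):
            out[name] = FrameSchedule.from_groups(spec, label=name)
        elif isinstance(spec, dict):
            out[name] = FrameSchedule.from_groups(
                spec["groups"],
                label=name,
                extra_frames=[tuple(f) for f in spec.get("extra_frames", [])],
            )
        else:
            raise DomainError(f"{path}: cannot parse protocol {name!r}")
    return out


def write_manifest(path: str | Path, config: dict) -> str:
    """Write a JSON run manifest carrying the config and its hash."""
    blob = json.dumps(config, sort_keys=True, default=str)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:16]
    doc = {"config": config, "config_hash": digest}
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(doc, indent=2, sort_keys=True, default=str) + "\n")
    return digest
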