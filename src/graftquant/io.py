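"""Readers and writers for the package's exchange formats.

Traces, events and tables travel as CSV; image stacks as multi-channel TIFF
(CZYX) with a YAML sidecar carrying channel roles and pixel sizes; every CLI
run writes a JSON manifest with all parameters and seeds so it can be
reproduced bit for bit.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .compartments import LabelStack
from .errors import InputError
from .traces import EVENT_COLUMNS, EventTable, TraceSet

SCHEMA_VERSION = 1

ROI_COLUMNS = ["roi_id", "roi_kind", "n_events", "active"]


def _sidecar(path: str | Path) -> Path:
    return Path(path).with_suffix(".yaml")


def write_trace_csv(traces: TraceSet, path: str | Path) -> None:
    """Trace CSV (roi_id, roi_kind, f000001...) plus a YAML sidecar with the
    frame rate, field id and schema version."""
    path = Path(path)
    n_frames = traces.n_frames
    frame_cols = [f"f{j:06d}" for j in range(n_frames)]
    df = pd.DataFrame(traces.fluorescence, columns=frame_cols)
    df.insert(0, "roi_kind", traces.roi_kind)
    df.insert(0, "roi_id", traces.roi_ids)
    df.to_csv(path, index=False)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "frame_rate_hz": float(1.0 / traces.frame_interval_s),
        "field_id": traces.field_id,
    }
    _sidecar(path).write_text(yaml.safe_dump(meta))


def read_trace_csv(path: str | Path, frame_rate_hz: float | None = None) -> TraceSet:
    """Read a trace CSV; the frame rate comes from the YAML sidecar unless
    given explicitly."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"trace file not found: {path}")
    meta_path = _sidecar(path)
    field_id = "field0"
    if frame_rate_hz is None:
        if not meta_path.exists():
            raise InputError(
                f"no frame rate given and no sidecar {meta_path.name} found"
            )
        meta = yaml.safe_load(meta_path.read_text())
        frame_rate_hz = float(meta["frame_rate_hz"])
        field_id = meta.get("field_id", field_id)
    df = pd.read_csv(path)
    if df.shape[1] < 3 or list(df.columns[:2]) != ["roi_id", "roi_kind"]:
        raise InputError(
            "trace CSV must start with roi_id and roi_kind columns followed "
            "by frame columns"
        )
    frame_part = df.iloc[:, 2:]
    try:
        fluor = frame_part.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for col in frame_part.columns:
            coerced = pd.to_numeric(frame_part[col], errors="coerce")
            bad = coerced.isna() & frame_part[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise InputError(
                    f"non-numeric value {frame_part[col].iloc[row]!r} at "
                    f"row {row}, column {col!r}"
                ) from None
        raise
    return TraceSet(
        fluorescence=fluor,
        frame_interval_s=1.0 / frame_rate_hz,
        roi_kind=df["roi_kind"].to_numpy(dtype=object),
        roi_ids=[str(r) for r in df["roi_id"]],
        field_id=field_id,
    )


def write_events_csv(table: EventTable, path: str | Path) -> None:
    """Events CSV in the canonical column order, plus a per-ROI CSV
    (``<stem>.rois.csv``) so activity proportions survive the round trip."""
    path = Path(path)
    table.events[EVENT_COLUMNS].to_csv(path, index=False)
    table.rois[ROI_COLUMNS].to_csv(
        path.with_suffix("").with_suffix(".rois.csv"), index=False
    )


def read_events_csv(path: str | Path) -> EventTable:
    path = Path(path)
    if not path.exists():
        raise InputError(f"events file not found: {path}")
    events = pd.read_csv(path)
    if list(events.columns) != EVENT_COLUMNS:
        raise InputError(
            f"events CSV columns {list(events.columns)} do not match the "
            f"schema {EVENT_COLUMNS}"
        )
    rois_path = path.with_suffix("").with_suffix(".rois.csv")
    if rois_path.exists():
        rois = pd.read_csv(rois_path)
        if list(rois.columns) != ROI_COLUMNS:
            raise InputError(f"ROI CSV columns do not match the schema {ROI_COLUMNS}")
    else:
        acc = events[~events["rejected"]]
        counts = acc.groupby("roi_id").size()
        kinds = events.drop_duplicates("roi_id").set_index("roi_id")["roi_kind"]
        rois = pd.DataFrame(
            {
                "roi_id": kinds.index,
                "roi_kind": kinds.to_numpy(),
                "n_events": [int(counts.get(r, 0)) for r in kinds.index],
            }
        )
        rois["active"] = rois["n_events"] > 0
    return EventTable(events=events, rois=rois)


def write_stack_tiff(stack: LabelStack, path: str | Path) -> None:
    """Multi-channel TIFF in CZYX order plus a YAML sidecar with channel
    roles and physical pixel sizes."""
    path = Path(path)
    tifffile.imwrite(
        path,
        np.asarray(stack.voxels),
        photometric="minisblack",
        metadata={"axes": "CZYX"},
    )
    meta = {
        "schema_version": SCHEMA_VERSION,
        "channel_roles": list(stack.channel_roles),
        "pixel_size_um": float(stack.pixel_size_um),
        "z_step_um": float(stack.z_step_um),
    }
    _sidecar(path).write_text(yaml.safe_dump(meta))


def read_stack_tiff(
    path: str | Path,
    roles: Sequence[str] | None = None,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> LabelStack:
    """Read a CZYX TIFF; roles and pixel sizes come from the sidecar unless
    overridden.  A role count that disagrees with the channel count is an
    error."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"stack file not found: {path}")
    voxels = tifffile.imread(path)
    if voxels.ndim == 3:  # single z plane stored as C,Y,X
        voxels = voxels[:, None]
    if voxels.ndim != 4:
        raise InputError(f"expected a CZYX stack, got shape {voxels.shape}")
    meta_path = _sidecar(path)
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
    roles = list(roles) if roles is not None else meta.get("channel_roles")
    if roles is None:
        raise InputError("channel roles must be given or present in the sidecar")
    if len(roles) != voxels.shape[0]:
        raise InputError(
            f"{len(roles)} roles declared for {voxels.shape[0]} channels"
        )
    return LabelStack(
        voxels=voxels,
        pixel_size_um=pixel_size_um or meta.get("pixel_size_um", 1.0),
        z_step_um=z_step_um or meta.get("z_step_um", 1.0),
        channel_roles=tuple(roles),
    )


def write_table_csv(table: pd.DataFrame, path: str | Path) -> None:
    pd.DataFrame(table).to_csv(path, index=False)


def read_table_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"table not found: {path}")
    return pd.read_csv(path)


def write_run_manifest(
    out_path: str | Path,
    command: str,
    params: Mapping,
    inputs: Sequence[str] = (),
    outputs: Sequence[str] = (),
) -> Path:
    """JSON manifest recording everything needed to reproduce a run."""
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "command": command,
        "params": {k: _jsonable(v) for k, v in params.items()},
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
    }
    mpath = Path(str(out_path) + ".manifest.json")
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, Path):
        return str(v)
    return v
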