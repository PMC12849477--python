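"""Readers and writers for every external format the pipeline touches.

CSV is the canonical interchange format; FCS support is read-only (a
small built-in parser for FCS 3.0/3.1 list-mode files, covering the
float/double/integer data types emitted by common acquisition software).
All writes are atomic: content goes to a temporary file in the target
directory and is renamed into place, so a crash never leaves a partial
output.  Times are decimal hours; pixel coordinates are 0-based.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import EventTable
from .image_quant import CellRecord
from .heterogeneity_stats import ShiftReport

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# atomic writes
# ---------------------------------------------------------------------------


def _atomic_write_bytes(path: Path, data: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(path: Path, text: str) -> None:
    _atomic_write_bytes(Path(path), text.encode())


# ---------------------------------------------------------------------------
# TIFF images
# ---------------------------------------------------------------------------


def read_image(path) -> np.ndarray:
    """Read a single-channel 8/16-bit TIFF as an integer grid, losslessly."""
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel 2D image, got shape {arr.shape} "
            "(multi-channel/RGB input is not supported)"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(
            f"{path}: expected integer pixel data, got {arr.dtype} "
            "(float images are not raw camera output)"
        )
    return arr


def write_image(path, image: np.ndarray) -> None:
    """Write an integer image (or label mask) as TIFF, atomically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tif")
    os.close(fd)
    try:
        tifffile.imwrite(tmp, image)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# FCS 3.x (read-only)
# ---------------------------------------------------------------------------


def _parse_fcs_text(segment: bytes) -> dict[str, str]:
    delim = segment[:1].decode("latin-1")
    parts = segment.decode("latin-1").split(delim)
    # parts[0] is empty (segment starts with the delimiter)
    kv = parts[1:]
    out = {}
    for key, val in zip(kv[0::2], kv[1::2]):
        out[key.strip().upper()] = val
    return out


def read_fcs(path, channel: str = "PE-A") -> EventTable:
    """Read one fluorescence channel from an FCS 3.0/3.1 list-mode file."""
    raw = Path(path).read_bytes()
    version = raw[:6].decode("latin-1")
    if not version.startswith("FCS3"):
        raise ValueError(f"{path}: unsupported FCS version {version!r}")
    text_begin = int(raw[10:18])
    text_end = int(raw[18:26])
    keywords = _parse_fcs_text(raw[text_begin : text_end + 1])
    data_begin = int(raw[26:34].strip() or 0) or int(keywords.get("$BEGINDATA", 0))
    data_end = int(raw[34:42].strip() or 0) or int(keywords.get("$ENDDATA", 0))
    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    datatype = keywords["$DATATYPE"].strip().upper()
    byteord = keywords["$BYTEORD"].strip()
    little = byteord.startswith("1")
    order = "<" if little else ">"
    names = [keywords.get(f"$P{i}N", f"P{i}").strip() for i in range(1, n_par + 1)]
    if channel not in names:
        raise ValueError(
            f"{path}: channel {channel!r} not present; available: {names}"
        )
    if keywords.get("$MODE", "L").strip().upper() != "L":
        raise ValueError(f"{path}: only list-mode ($MODE=L) FCS is supported")
    blob = raw[data_begin : data_end + 1]
    if datatype == "F":
        data = np.frombuffer(blob, dtype=f"{order}f4", count=n_par * n_tot)
    elif datatype == "D":
        data = np.frombuffer(blob, dtype=f"{order}f8", count=n_par * n_tot)
    elif datatype == "I":
        bits = {int(keywords[f"$P{i}B"]) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (16, 32):
            raise ValueError(f"{path}: only uniform 16/32-bit integer data supported")
        nbytes = (int(keywords["$P1B"])) // 8
        data = np.frombuffer(blob, dtype=f"{order}u{nbytes}", count=n_par * n_tot)
    else:
        raise ValueError(f"{path}: unsupported $DATATYPE {datatype!r}")
    matrix = data.reshape(n_tot, n_par).astype(float)
    values = matrix[:, names.index(channel)]
    return EventTable(
        strain=keywords.get("STRAIN", ""),
        timepoint_h=float(keywords.get("TIMEPOINT_H", "nan")),
        channel=channel,
        values=values,
        meta={"n_events": n_tot, "keywords": {k: v for k, v in keywords.items()}},
    )


FC_CSV_COLUMNS = ("sample_id", "strain", "timepoint_h", "value")


def read_event_tables(path, channel: str = "PE-A") -> list[EventTable]:
    """Read flow-cytometry events from a CSV (possibly several samples).

    The CSV must carry the columns sample_id, strain, timepoint_h,
    value; one :class:`EventTable` is returned per distinct sample_id.
    """
    df = pd.read_csv(path)
    missing = [c for c in FC_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    tables = []
    for sid, grp in df.groupby("sample_id", sort=True):
        tables.append(
            EventTable(
                strain=str(grp["strain"].iloc[0]),
                timepoint_h=float(grp["timepoint_h"].iloc[0]),
                channel=channel,
                values=grp["value"].to_numpy(dtype=float),
                meta={"sample_id": sid, "source": str(path)},
            )
        )
    return tables


def read_fc(path, channel: str = "PE-A") -> EventTable:
    """Read a single flow-cytometry sample from FCS 3.x or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".fcs":
        return read_fcs(path, channel)
    tables = read_event_tables(path, channel)
    if len(tables) != 1:
        raise ValueError(
            f"{path}: expected one sample, found {len(tables)}; "
            "use read_event_tables for combined files"
        )
    return tables[0]


def write_event_tables(path, tables: list[EventTable]) -> None:
    """Write event tables to the canonical combined CSV, atomically."""
    frames = [t.to_frame() for t in tables]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(FC_CSV_COLUMNS))
    )
    atomic_write_text(Path(path), df.to_csv(index=False))


# ---------------------------------------------------------------------------
# per-cell records and reports
# ---------------------------------------------------------------------------

CELL_CSV_COLUMNS = (
    "source_id",
    "strain",
    "timepoint_h",
    "label",
    "area_px",
    "centroid_x",
    "centroid_y",
    "mean_raw",
    "relative_pct",
)


def write_cell_records(path, records: list[CellRecord]) -> None:
    rows = [
        {
            "source_id": r.source_id,
            "strain": r.strain,
            "timepoint_h": r.timepoint_h,
            "label": r.label,
            "area_px": r.area,
            "centroid_x": r.centroid_x,
            "centroid_y": r.centroid_y,
            "mean_raw": r.mean_raw_intensity,
            "relative_pct": r.relative_intensity,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(CELL_CSV_COLUMNS))
    atomic_write_text(Path(path), df.to_csv(index=False))


def read_cell_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CELL_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_shift_report(out_dir, report: ShiftReport, stem: str = "shift_report") -> None:
    """Write a shift report as CSV (fractions, deltas) plus a JSON summary."""
    out_dir = Path(out_dir)
    atomic_write_text(out_dir / f"{stem}_fractions.csv", report.fractions.to_csv(index=False))
    atomic_write_text(out_dir / f"{stem}_deltas.csv", report.deltas.to_csv(index=False))
    payload = {
        "reference_timepoint_h": report.reference_timepoint,
        "late_timepoint_h": report.late_timepoint,
        "levels": list(report.levels),
        "thresholds": {
            strain: dict(zip(ts.quantile_levels, ts.thresholds))
            for strain, ts in report.thresholds.items()
        },
        "deltas_pp": report.deltas.to_dict(orient="records"),
    }
    atomic_write_text(out_dir / f"{stem}.json", json.dumps(payload, indent=2))


def write_json(path, payload) -> None:
    atomic_write_text(Path(path), json.dumps(payload, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to rerun a stage exactly."""

    config_hash: str
    seeds: dict[str, int] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    software_version: str = __version__
    stage_timings_s: dict[str, float] = field(default_factory=dict)
    started_at: float = field(default_factory=time.time)

    def add_input(self, path) -> None:
        self.inputs[str(path)] = sha256_file(path)

    def write(self, path) -> None:
        write_json(
            path,
            {
                "config_hash": self.config_hash,
                "seeds": self.seeds,
                "inputs": self.inputs,
                "software_version": self.software_version,
                "stage_timings_s": self.stage_timings_s,
            },
        )


def config_hash(config_obj) -> str:
    """Stable hash of a config mapping (canonical JSON serialization)."""
    blob = json.dumps(config_obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
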