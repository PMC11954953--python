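"""Readers and writers for the on-disk formats.

One delimited dialect everywhere: comma-separated, UTF-8, ``.`` decimal,
header row required. Large trace matrices can also travel in an HDF5
container (datasets ``values`` and ``cell_ids`` plus ``frame_rate`` /
``unit_tag`` attributes) which round-trips values bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Union

import h5py
import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .types import BoutInterval, BoutTrack, LongitudinalMap, TraceMatrix

__all__ = [
    "read_traces",
    "write_traces",
    "read_bouts",
    "write_bouts",
    "read_longitudinal_map",
    "write_longitudinal_map",
    "read_roi_table",
    "write_roi_table",
    "write_json_report",
    "read_json_report",
]

_PHASE_LABEL = "__phases__"

PathLike = Union[str, Path]


def _require_columns(df: pd.DataFrame, columns: List[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing columns {missing}")


# ---------------------------------------------------------------------------
# traces


def read_traces(
    path: PathLike,
    format: str = "delimited",
    frame_rate: Optional[float] = None,
    nan_policy: str = "strict",
) -> TraceMatrix:
    """Load a trace matrix.

    Parameters
    ----------
    format : {'delimited', 'columnar-binary'}
        Delimited files carry a ``frame`` index column plus one column per
        cell; the frame rate is not stored in the file and must be supplied
        (from configuration). The binary container stores it as an
        attribute.
    nan_policy : {'strict', 'interpolate'}
        ``strict`` rejects any NaN naming the offending (cell, frame);
        ``interpolate`` fills NaNs per cell by linear interpolation.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"trace file not found: {path}")
    if format == "delimited":
        if frame_rate is None:
            raise ConfigurationError(
                "frame_rate is required when reading delimited traces"
            )
        df = pd.read_csv(path)
        if df.columns[0] != "frame":
            raise ValidationError("delimited traces must start with a 'frame' column")
        cell_ids = [str(c) for c in df.columns[1:]]
        values = df.iloc[:, 1:].to_numpy(dtype=float).T
        unit_tag = "raw"
    elif format == "columnar-binary":
        with h5py.File(path, "r") as f:
            values = f["values"][()]
            cell_ids = [c.decode() for c in f["cell_ids"][()]]
            if "frame_rate" not in f.attrs:
                raise ConfigurationError(f"{path}: missing frame_rate attribute")
            frame_rate = float(f.attrs["frame_rate"])
            unit_tag = str(f.attrs.get("unit_tag", "raw"))
    else:
        raise ConfigurationError(f"unknown trace format {format!r}")

    bad = ~np.isfinite(values)
    if bad.any():
        if nan_policy == "strict":
            cell_idx, frame_idx = np.argwhere(bad)[0]
            raise ValidationError(
                f"{path}: non-finite value at cell {cell_ids[cell_idx]!r}, "
                f"frame {frame_idx} (nan_policy='strict')"
            )
        if nan_policy == "interpolate":
            for i in range(values.shape[0]):
                row = values[i]
                ok = np.isfinite(row)
                if not ok.all():
                    if not ok.any():
                        raise ValidationError(
                            f"{path}: cell {cell_ids[i]!r} is entirely non-finite"
                        )
                    row[~ok] = np.interp(
                        np.flatnonzero(~ok), np.flatnonzero(ok), row[ok]
                    )
        else:
            raise ConfigurationError(f"unknown nan_policy {nan_policy!r}")

    return TraceMatrix(
        cell_ids=cell_ids, frame_rate=frame_rate, values=values, unit_tag=unit_tag
    )


def write_traces(tm: TraceMatrix, path: PathLike, format: str = "delimited") -> None:
    """Write a trace matrix in the requested format (see :func:`read_traces`)."""
    path = Path(path)
    if format == "delimited":
        df = pd.DataFrame(tm.values.T, columns=tm.cell_ids)
        df.insert(0, "frame", np.arange(tm.n_frames))
        df.to_csv(path, index=False, float_format="%.9g")
    elif format == "columnar-binary":
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=tm.values, track_times=False)
            f.create_dataset(
                "cell_ids",
                data=np.array([c.encode() for c in tm.cell_ids]),
                track_times=False,
            )
            f.attrs["frame_rate"] = tm.frame_rate
            f.attrs["unit_tag"] = tm.unit_tag
    else:
        raise ConfigurationError(f"unknown trace format {format!r}")


# ---------------------------------------------------------------------------
# bouts


def read_bouts(path: PathLike) -> BoutTrack:
    """Load a bout table (columns start_s, end_s, label).

    The phase boundary travels in the same file as a single row with label
    ``__phases__`` whose start/end give (habituation_end, session_end).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"bout file not found: {path}")
    df = pd.read_csv(path)
    _require_columns(df, ["start_s", "end_s", "label"], "bout table")
    phase_rows = df[df["label"] == _PHASE_LABEL]
    if len(phase_rows) != 1:
        raise ValidationError(
            f"bout table must contain exactly one {_PHASE_LABEL!r} row, "
            f"found {len(phase_rows)}"
        )
    hab_end = float(phase_rows.iloc[0]["start_s"])
    sess_end = float(phase_rows.iloc[0]["end_s"])
    intervals = [
        BoutInterval(float(r.start_s), float(r.end_s), str(r.label))
        for r in df[df["label"] != _PHASE_LABEL].itertuples()
    ]
    return BoutTrack(intervals=intervals, phase_boundaries=(hab_end, sess_end))


def write_bouts(bouts: BoutTrack, path: PathLike) -> None:
    rows = [
        {"start_s": iv.start_s, "end_s": iv.end_s, "label": iv.label}
        for iv in bouts.intervals
    ]
    rows.append(
        {
            "start_s": bouts.habituation_end_s,
            "end_s": bouts.session_end_s,
            "label": _PHASE_LABEL,
        }
    )
    pd.DataFrame(rows, columns=["start_s", "end_s", "label"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# longitudinal maps, ROI tables, JSON reports


def read_longitudinal_map(path: PathLike) -> LongitudinalMap:
    df = pd.read_csv(path, dtype=str)
    _require_columns(
        df, ["session_id", "local_cell_id", "global_cell_id"], "longitudinal map"
    )
    lmap = LongitudinalMap()
    for r in df.itertuples():
        lmap.add(r.session_id, r.local_cell_id, r.global_cell_id)
    return lmap


def write_longitudinal_map(lmap: LongitudinalMap, path: PathLike) -> None:
    rows = [
        {"session_id": s, "local_cell_id": local, "global_cell_id": g}
        for (s, local), g in sorted(lmap.entries.items())
    ]
    pd.DataFrame(
        rows, columns=["session_id", "local_cell_id", "global_cell_id"]
    ).to_csv(path, index=False)


ROI_COLUMNS = [
    "region",
    "integrated_density",
    "roi_area",
    "background_mean",
    "is_injection_site",
]


def read_roi_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ROI_COLUMNS, "ROI table")
    df["is_injection_site"] = df["is_injection_site"].astype(bool)
    return df


def write_roi_table(df: pd.DataFrame, path: PathLike) -> None:
    _require_columns(df, ROI_COLUMNS, "ROI table")
    df.to_csv(path, index=False)


def write_json_report(report: Dict, path: PathLike) -> None:
    """Serialize a report dict deterministically (sorted keys)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_default) + "\n"
    )


def read_json_report(path: PathLike) -> Dict:
    return json.loads(Path(path).read_text())
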