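"""Z-scoring, event detection and phase/bout activity contrasts.

Z-scores are computed per cell against a baseline window — by default the
habituation phase of the same session, so that stimulus-phase activity is
expressed in units of spontaneous variability. Events are maximal
supra-threshold runs of the z-trace with a robust (MAD-based) threshold; a
cell counts as *active* in a phase if at least one event intersects it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .types import BoutTrack, Session, TraceMatrix

__all__ = [
    "zscore_traces",
    "detect_events",
    "summarize_activity",
    "phase_contrast",
]

logger = logging.getLogger(__name__)

_MAD_TO_SD = 0.6745  # Phi^-1(0.75): MAD/0.6745 estimates the SD for a Gaussian


def zscore_traces(
    traces: TraceMatrix,
    baseline_window: Optional[Tuple[float, float]] = None,
    bouts: Optional[BoutTrack] = None,
    sd_floor: float = 1e-12,
) -> Tuple[TraceMatrix, List[str]]:
    """Per-cell z-score against a baseline window.

    Parameters
    ----------
    baseline_window : (start_s, end_s), optional
        Explicit baseline. If omitted, ``bouts`` must be given and the
        habituation phase is used; if that phase is empty the whole
        session serves as baseline.

    Returns
    -------
    (zscored TraceMatrix, list of degenerate cell ids)
        Cells whose baseline SD vanishes are flagged degenerate; their
        z-row is set to zero and they should be excluded from downstream
        tests.
    """
    if baseline_window is None:
        if bouts is None:
            raise ParameterError("need baseline_window or bouts")
        hab_end = bouts.habituation_end_s
        baseline_window = (0.0, hab_end) if hab_end > 0 else (0.0, bouts.session_end_s)
    start_s, end_s = baseline_window
    t = traces.frame_times()
    base_mask = (t >= start_s) & (t < end_s)
    if not base_mask.any():
        raise ParameterError(f"baseline window {baseline_window} selects no frames")

    base = traces.values[:, base_mask]
    mean = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, ddof=0, keepdims=True)
    degenerate = sd[:, 0] <= sd_floor
    safe_sd = np.where(degenerate[:, None], 1.0, sd)
    z = (traces.values - mean) / safe_sd
    z[degenerate, :] = 0.0
    degenerate_ids = [c for c, d in zip(traces.cell_ids, degenerate) if d]
    if degenerate_ids:
        logger.warning(
            "%d cells with zero baseline SD flagged degenerate: %s",
            len(degenerate_ids),
            degenerate_ids[:5],
        )
    return (
        TraceMatrix(
            cell_ids=list(traces.cell_ids),
            frame_rate=traces.frame_rate,
            values=z,
            unit_tag="zscored",
        ),
        degenerate_ids,
    )


@dataclass
class EventDetection:
    """Detected supra-threshold events per cell."""

    raster: np.ndarray  # bool, cells x frames
    events: List[List[Tuple[int, int]]]  # per cell: half-open frame spans
    thresholds: np.ndarray  # per-cell z threshold actually applied


def detect_events(
    z_traces: TraceMatrix, k_mad: float = 3.0, min_duration_s: float = 0.3
) -> EventDetection:
    """Maximal runs of frames with z above a robust per-cell threshold.

    The threshold is ``k_mad * MAD(z) / 0.6745`` (a MAD-based SD estimate
    scaled by ``k_mad``); runs shorter than ``min_duration_s`` are
    discarded.
    """
    if not (k_mad > 0):
        raise ParameterError("k_mad must be positive")
    if min_duration_s * z_traces.frame_rate < 1.0:
        raise ParameterError(
            f"min_duration_s={min_duration_s} is shorter than one frame "
            f"at {z_traces.frame_rate} Hz"
        )
    min_frames = int(np.ceil(min_duration_s * z_traces.frame_rate))
    z = z_traces.values
    mad = np.median(np.abs(z - np.median(z, axis=1, keepdims=True)), axis=1)
    thresholds = k_mad * mad / _MAD_TO_SD
    above = z > thresholds[:, None]

    raster = np.zeros_like(above)
    events: List[List[Tuple[int, int]]] = []
    for i in range(z.shape[0]):
        spans: List[Tuple[int, int]] = []
        padded = np.diff(np.concatenate(([0], above[i].astype(int), [0])))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_frames:
                spans.append((int(s), int(e)))
                raster[i, s:e] = True
        events.append(spans)
    return EventDetection(raster=raster, events=events, thresholds=thresholds)


def _events_in_mask(spans: List[Tuple[int, int]], mask: np.ndarray) -> int:
    return sum(1 for s, e in spans if mask[s:e].any())


def summarize_activity(
    session: Session,
    z_traces: TraceMatrix,
    k_mad: float = 3.0,
    min_duration_s: float = 0.3,
) -> pd.DataFrame:
    """Per-cell activity summary across phases and bouts.

    Columns: mean z in habituation / stimulus phase, mean z inside /
    outside bouts (within the stimulus phase), event counts and active
    flags per phase.
    """
    bouts = session.bouts
    fr = z_traces.frame_rate
    n = z_traces.n_frames
    hab = bouts.phase_mask(fr, n, "habituation")
    stim = bouts.phase_mask(fr, n, "stimulus")
    in_bout = bouts.frame_mask(fr, n) & stim
    out_bout = stim & ~in_bout

    det = detect_events(z_traces, k_mad=k_mad, min_duration_s=min_duration_s)
    z = z_traces.values

    def _mean(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            return np.full(z.shape[0], np.nan)
        return z[:, mask].mean(axis=1)

    rows = []
    for i, cell in enumerate(z_traces.cell_ids):
        ev_hab = _events_in_mask(det.events[i], hab)
        ev_stim = _events_in_mask(det.events[i], stim)
        rows.append(
            {
                "animal": session.animal_id,
                "session": f"{session.animal_id}/{session.stimulus}",
                "cell": cell,
                "mean_z_habituation": _mean(hab)[i],
                "mean_z_stimulus": _mean(stim)[i],
                "mean_z_in_bout": _mean(in_bout)[i],
                "mean_z_out_bout": _mean(out_bout)[i],
                "events_habituation": ev_hab,
                "events_stimulus": ev_stim,
                "active_habituation": ev_hab >= 1,
                "active_stimulus": ev_stim >= 1,
            }
        )
    return pd.DataFrame(rows)


_PHASE_COLUMNS = {
    "habituation": ("mean_z_habituation", "active_habituation"),
    "stimulus": ("mean_z_stimulus", "active_stimulus"),
    "in_bout": ("mean_z_in_bout", "active_stimulus"),
    "out_bout": ("mean_z_out_bout", "active_stimulus"),
}


def phase_contrast(
    summary: pd.DataFrame,
    phase_a: str,
    phase_b: str,
    policy: str = "union",
) -> pd.DataFrame:
    """Paired per-cell means for two phases, restricted by activity policy.

    ``policy``: ``'union'`` keeps cells active in phase A or phase B,
    ``'either'`` is an alias of union, ``'all'`` keeps every cell.
    Returns a frame with columns cell, value_a, value_b, diff — the input
    for a paired group comparison.
    """
    for phase in (phase_a, phase_b):
        if phase not in _PHASE_COLUMNS:
            raise ParameterError(
                f"unknown phase {phase!r}; choose from {sorted(_PHASE_COLUMNS)}"
            )
    col_a, act_a = _PHASE_COLUMNS[phase_a]
    col_b, act_b = _PHASE_COLUMNS[phase_b]
    if summary[col_a].isna().all() or summary[col_b].isna().all():
        raise ValidationError(f"phase {phase_a!r} or {phase_b!r} is empty")

    if policy in ("union", "either"):
        keep = summary[act_a] | summary[act_b]
    elif policy == "all":
        keep = pd.Series(True, index=summary.index)
    else:
        raise ParameterError(f"unknown policy {policy!r}")
    sub = summary[keep]
    return pd.DataFrame(
        {
            "cell": sub["cell"].to_numpy(),
            "value_a": sub[col_a].to_numpy(),
            "value_b": sub[col_b].to_numpy(),
            "diff": (sub[col_a] - sub[col_b]).to_numpy(),
        }
    )
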