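"""Correlation-based classification of cells as positively, negatively or
neutrally coupled to consumption, with a circular-shift permutation null.

The null rotates each cell's trace by a uniformly drawn circular shift
(at least ``min_shift_s`` away from zero in either direction) before
recomputing the Pearson correlation with the bout regressor. Rotation
preserves the trace's autocorrelation — an i.i.d. frame shuffle would not,
and would overstate significance for slow calcium signals. The two-sided
permutation p-value uses the add-one estimator

    p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1),

so its support is {k/(n_perm+1), 1 <= k <= n_perm+1} and it is never 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError, ValidationError
from .rng import stage_rng
from .synth import CalciumKernel
from .types import LABELS, BoutTrack, Session, TraceMatrix

__all__ = [
    "bout_regressor",
    "correlate_cell",
    "permutation_null",
    "classify_cells",
    "ClassificationResult",
]

logger = logging.getLogger(__name__)


def bout_regressor(
    bouts: BoutTrack,
    frame_rate: float,
    n_frames: int,
    smoothing: str = "none",
    kernel: Optional[CalciumKernel] = None,
) -> np.ndarray:
    """Per-frame consumption indicator, optionally kernel-smoothed.

    ``smoothing='kernel'`` convolves the binary indicator with the same
    double-exponential calcium kernel the simulator uses, matching the
    temporal blurring the indicator imposes on the traces.
    """
    last_end = max((iv.end_s for iv in bouts.intervals), default=0.0)
    if last_end > n_frames / frame_rate + 1.0 / frame_rate:
        raise ValidationError(
            f"bout ending at {last_end}s lies outside the {n_frames}-frame trace"
        )
    reg = bouts.frame_mask(frame_rate, n_frames).astype(float)
    if smoothing == "none":
        return reg
    if smoothing == "kernel":
        h = (kernel or CalciumKernel()).sample(frame_rate)
        from scipy.signal import fftconvolve

        return fftconvolve(reg, h)[:n_frames]
    raise ParameterError(f"unknown smoothing {smoothing!r}")


def correlate_cell(z_trace: np.ndarray, regressor: np.ndarray) -> float:
    """Pearson correlation between one z-trace and the bout regressor."""
    z_trace = np.asarray(z_trace, dtype=float)
    regressor = np.asarray(regressor, dtype=float)
    if z_trace.shape != regressor.shape or z_trace.ndim != 1:
        raise ParameterError("trace and regressor must be 1-D of equal length")
    if z_trace.size < 3:
        raise ParameterError("need at least 3 frames")
    if np.ptp(regressor) == 0:
        raise ValidationError(
            "constant regressor (no bouts?) — classification should take the "
            "empty-bout path and label every cell neutral"
        )
    if np.ptp(z_trace) == 0:
        return 0.0
    return float(np.corrcoef(z_trace, regressor)[0, 1])


def _admissible_shifts(n_frames: int, min_shift_frames: int) -> np.ndarray:
    """Circular shifts at least ``min_shift_frames`` from identity in both
    rotation directions."""
    if 2 * min_shift_frames >= n_frames:
        raise ParameterError(
            f"trace of {n_frames} frames is shorter than twice the minimum "
            f"shift ({min_shift_frames} frames)"
        )
    return np.arange(min_shift_frames, n_frames - min_shift_frames + 1)


def _corr_all_shifts(z: np.ndarray, reg: np.ndarray) -> np.ndarray:
    """Pearson r between np.roll(z, s) and reg for every shift s, via FFT.

    corr(roll(z, s), reg) shares the marginal means/SDs of z and reg for
    every s; only the cross term sum_t z[(t - s) mod T] * reg[t] varies,
    and that is a circular cross-correlation computable in O(T log T).
    """
    T = z.size
    fz = np.fft.rfft(z)
    fr_ = np.fft.rfft(reg)
    cross = np.fft.irfft(fz * np.conj(fr_), n=T)  # index s = shift of z
    mz, mr = z.mean(), reg.mean()
    sz, sr = z.std(), reg.std()
    if sz == 0 or sr == 0:
        return np.zeros(T)
    return (cross / T - mz * mr) / (sz * sr)


def permutation_null(
    z_trace: np.ndarray,
    regressor: np.ndarray,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    min_shift_s: float = 10.0,
    frame_rate: float = 10.0,
    shifts: str = "random",
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Two-sided circular-shift permutation p-value for one cell.

    ``shifts='all'`` enumerates every admissible shift exactly once
    (exhaustive null); ``'random'`` draws ``n_perm`` shifts uniformly with
    replacement.
    """
    z_trace = np.asarray(z_trace, dtype=float)
    regressor = np.asarray(regressor, dtype=float)
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    min_shift_frames = int(round(min_shift_s * frame_rate))
    admissible = _admissible_shifts(z_trace.size, min_shift_frames)

    r_obs = correlate_cell(z_trace, regressor)
    r_all = _corr_all_shifts(z_trace, regressor)

    if shifts == "all":
        drawn = admissible
    elif shifts == "random":
        if rng is None:
            rng = np.random.default_rng(seed)
        drawn = rng.choice(admissible, size=n_perm, replace=True)
    else:
        raise ParameterError(f"unknown shifts mode {shifts!r}")

    r_perm = r_all[np.mod(drawn, z_trace.size)]
    n = drawn.size
    return float((1 + np.sum(np.abs(r_perm) >= abs(r_obs))) / (n + 1))


@dataclass
class ClassificationResult:
    """Per-cell classification table plus session-level label fractions."""

    table: pd.DataFrame  # animal, session, cell, r, p_perm, label, alpha, n_perm, seed
    fractions: Dict[str, float]
    params: Dict = field(default_factory=dict)

    def labels(self) -> pd.Series:
        return self.table.set_index("cell")["label"]


def classify_cells(
    session: Session,
    z_traces: TraceMatrix,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    min_shift_s: float = 10.0,
    smoothing: str = "none",
    kernel: Optional[CalciumKernel] = None,
    fdr: bool = False,
    exclude_cells: Sequence[str] = (),
) -> ClassificationResult:
    """Label every cell positive / negative / neutral against the bouts.

    A cell is non-neutral iff its permutation p-value is at or below
    ``alpha`` (after optional Benjamini–Hochberg adjustment across cells);
    the sign of r decides positive vs negative. With no bouts at all every
    cell is neutral and a warning is emitted.
    """
    if z_traces.unit_tag != "zscored":
        raise ParameterError("classify_cells expects z-scored traces")
    if not (0 <= alpha <= 1):
        raise ParameterError("alpha must lie in [0, 1]")
    fr = z_traces.frame_rate
    n_frames = z_traces.n_frames
    session_id = f"{session.animal_id}/{session.stimulus}"
    excluded = set(exclude_cells)

    empty_bouts = len(session.bouts.intervals) == 0
    if empty_bouts:
        warnings.warn(
            f"{session_id}: no bouts — all cells labeled neutral", stacklevel=2
        )
        reg = None
    else:
        reg = bout_regressor(session.bouts, fr, n_frames, smoothing, kernel)
        if np.ptp(reg) == 0:
            empty_bouts = True
            reg = None

    rng = stage_rng(seed, f"classify/{session_id}")
    rows = []
    pvals = []
    for i, cell in enumerate(z_traces.cell_ids):
        if empty_bouts or cell in excluded:
            r, p = 0.0, 1.0
        else:
            z = z_traces.values[i]
            if np.ptp(z) == 0:
                r, p = 0.0, 1.0
            else:
                r = correlate_cell(z, reg)
                p = permutation_null(
                    z, reg, n_perm=n_perm, min_shift_s=min_shift_s,
                    frame_rate=fr, rng=rng,
                )
        rows.append({"animal": session.animal_id, "session": session_id,
                     "cell": cell, "r": r, "p_perm": p})
        pvals.append(p)

    pvals = np.asarray(pvals)
    p_eff = sps.false_discovery_control(pvals, method="bh") if fdr else pvals
    for row, p_adj in zip(rows, p_eff):
        if p_adj <= alpha and row["r"] > 0:
            row["label"] = "positive"
        elif p_adj <= alpha and row["r"] < 0:
            row["label"] = "negative"
        else:
            row["label"] = "neutral"
        row["alpha"] = alpha
        row["n_perm"] = n_perm
        row["seed"] = seed

    table = pd.DataFrame(rows)
    fractions = {
        lab: float((table["label"] == lab).mean()) for lab in LABELS
    }
    params = {
        "alpha": alpha,
        "n_perm": n_perm,
        "seed": seed,
        "min_shift_s": min_shift_s,
        "smoothing": smoothing,
        "fdr": fdr,
        "null": "circular-shift",
    }
    return ClassificationResult(table=table, fractions=fractions, params=params)
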