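"""Core in-memory containers for the pipeline.

All time is expressed in seconds from session start. Bout intervals are
half-open ``[start, end)``; frame ``f`` at rate ``r`` covers the time span
``[f/r, (f+1)/r)``, so a frame belongs to a bout iff its start time falls
inside the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError

__all__ = ["TraceMatrix", "BoutInterval", "BoutTrack", "Session", "LongitudinalMap"]

#: Vocabulary for per-cell correlation categories.
LABELS = ("positive", "negative", "neutral")


@dataclass
class TraceMatrix:
    """Cells x frames fluorescence values plus sampling metadata.

    Parameters
    ----------
    cell_ids : list of str
        Stable identifiers, one per row; must be unique.
    frame_rate : float
        Acquisition rate in Hz, strictly positive.
    values : ndarray, shape (n_cells, n_frames)
        Fluorescence in arbitrary units (``unit_tag='raw'``) or z-units
        (``unit_tag='zscored'``). Must be finite.
    """

    cell_ids: List[str]
    frame_rate: float
    values: np.ndarray
    unit_tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValidationError("trace values must be 2-D (cells x frames)")
        if self.values.shape[0] != len(self.cell_ids):
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids but {self.values.shape[0]} trace rows"
            )
        if self.values.shape[1] < 2:
            raise ValidationError("trace matrix needs at least 2 frames")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("cell_ids must be unique")
        if not (self.frame_rate > 0):
            raise ValidationError("frame_rate must be positive")
        if self.unit_tag not in ("raw", "zscored"):
            raise ValidationError(f"unknown unit_tag {self.unit_tag!r}")
        bad = ~np.isfinite(self.values)
        if bad.any():
            cell_idx, frame_idx = np.argwhere(bad)[0]
            raise ValidationError(
                "non-finite trace value at cell "
                f"{self.cell_ids[cell_idx]!r}, frame {frame_idx}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def frame_times(self) -> np.ndarray:
        """Start time of each frame in seconds."""
        return np.arange(self.n_frames) / self.frame_rate

    def subset(self, cell_ids: Sequence[str]) -> "TraceMatrix":
        """Row-subset by cell id, preserving the requested order."""
        index = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in index]
        if missing:
            raise ValidationError(f"unknown cell ids: {missing[:5]}")
        rows = [index[c] for c in cell_ids]
        return TraceMatrix(
            cell_ids=list(cell_ids),
            frame_rate=self.frame_rate,
            values=self.values[rows],
            unit_tag=self.unit_tag,
        )


@dataclass(frozen=True)
class BoutInterval:
    start_s: float
    end_s: float
    label: str = "consume"

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValidationError(
                f"bout interval must satisfy 0 <= start < end, got "
                f"({self.start_s}, {self.end_s})"
            )


@dataclass
class BoutTrack:
    """Labeled consumption/administration intervals plus phase boundaries.

    ``phase_boundaries = (habituation_end_s, session_end_s)``: the
    habituation phase is ``[0, habituation_end_s)`` and the stimulus phase
    ``[habituation_end_s, session_end_s)``.
    """

    intervals: List[BoutInterval]
    phase_boundaries: Tuple[float, float]

    def __post_init__(self) -> None:
        hab_end, sess_end = self.phase_boundaries
        if not (0 <= hab_end <= sess_end):
            raise ValidationError(
                f"need 0 <= habituation_end <= session_end, got {self.phase_boundaries}"
            )
        self.intervals = sorted(self.intervals, key=lambda b: (b.start_s, b.end_s))
        by_label: Dict[str, List[BoutInterval]] = {}
        for iv in self.intervals:
            if iv.end_s > sess_end:
                raise ValidationError(
                    f"bout ({iv.start_s}, {iv.end_s}) extends past session end {sess_end}"
                )
            by_label.setdefault(iv.label, []).append(iv)
        for label, ivs in by_label.items():
            for a, b in zip(ivs, ivs[1:]):
                if b.start_s < a.end_s:
                    raise ValidationError(
                        f"overlapping {label!r} intervals "
                        f"({a.start_s},{a.end_s}) and ({b.start_s},{b.end_s})"
                    )

    @property
    def habituation_end_s(self) -> float:
        return self.phase_boundaries[0]

    @property
    def session_end_s(self) -> float:
        return self.phase_boundaries[1]

    def labels(self) -> List[str]:
        return sorted({iv.label for iv in self.intervals})

    def frame_mask(
        self,
        frame_rate: float,
        n_frames: int,
        labels: Optional[Sequence[str]] = None,
    ) -> np.ndarray:
        """Boolean per-frame bout indicator under the half-open convention."""
        t = np.arange(n_frames) / frame_rate
        mask = np.zeros(n_frames, dtype=bool)
        for iv in self.intervals:
            if labels is not None and iv.label not in labels:
                continue
            mask |= (t >= iv.start_s) & (t < iv.end_s)
        return mask

    def phase_mask(self, frame_rate: float, n_frames: int, phase: str) -> np.ndarray:
        """Per-frame mask for ``'habituation'`` or ``'stimulus'``."""
        t = np.arange(n_frames) / frame_rate
        hab_end, sess_end = self.phase_boundaries
        if phase == "habituation":
            return (t >= 0) & (t < hab_end)
        if phase == "stimulus":
            return (t >= hab_end) & (t < sess_end)
        raise ValidationError(f"unknown phase {phase!r}")


@dataclass
class Session:
    """One imaging session: traces plus its behavioral annotation."""

    animal_id: str
    stimulus: str
    traces: TraceMatrix
    bouts: BoutTrack

    def __post_init__(self) -> None:
        last_end = max((iv.end_s for iv in self.bouts.intervals), default=0.0)
        tol = 1.0 / self.traces.frame_rate
        if self.traces.duration_s + tol < last_end:
            raise ValidationError(
                f"trace duration {self.traces.duration_s:.2f}s shorter than "
                f"last bout end {last_end:.2f}s"
            )


@dataclass
class LongitudinalMap:
    """Cross-session cell identity: (session_id, local_cell_id) -> global id."""

    entries: Dict[Tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: Dict[Tuple[str, str], str] = {}
        for (session_id, _local), global_id in self.entries.items():
            key = (session_id, global_id)
            if key in seen:
                raise ValidationError(
                    f"global id {global_id!r} mapped twice within session {session_id!r}"
                )
            seen[key] = global_id

    def add(self, session_id: str, local_cell_id: str, global_cell_id: str) -> None:
        key = (session_id, local_cell_id)
        if key in self.entries and self.entries[key] != global_cell_id:
            raise ValidationError(f"{key} already mapped to {self.entries[key]!r}")
        if any(
            g == global_cell_id and s == session_id and l != local_cell_id
            for (s, l), g in self.entries.items()
        ):
            raise ValidationError(
                f"global id {global_cell_id!r} already present in session {session_id!r}"
            )
        self.entries[key] = global_cell_id

    def sessions(self) -> List[str]:
        return sorted({s for s, _ in self.entries})

    def globals_in(self, session_id: str) -> Dict[str, str]:
        """global_cell_id -> local_cell_id for one session."""
        return {
            g: local for (s, local), g in self.entries.items() if s == session_id
        }

    def shared_globals(self, session_a: str, session_b: str) -> List[str]:
        in_a = set(self.globals_in(session_a))
        in_b = set(self.globals_in(session_b))
        return sorted(in_a & in_b)
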