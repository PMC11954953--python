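"""Synthetic session generator with planted, recoverable ground truth.

The forward model mirrors what the downstream analyses assume about
miniscope recordings of consummatory behavior:

* each neuron fires as an inhomogeneous Poisson process whose rate is
  multiplied by a ``bout_gain`` inside consumption bouts (``>1`` for cells
  positively coupled to consumption, ``<1`` for suppressed cells, ``=1``
  for neutral ones — suppression is modelled as a gain rather than a
  negative rate so rates stay nonnegative);
* events are convolved with a double-exponential calcium-indicator kernel
  (GCaMP6m-like rise/decay defaults) and corrupted by additive Gaussian
  noise;
* sessions follow either a habituation-then-stimulus paradigm (10 min
  without reward, then 10 min with free consumption bouts) or a
  two-administration paradigm (1-min administrations starting at minutes
  1 and 6 of a 10-min session);
* longitudinal cohorts share a configurable fraction of cells between
  sessions, and shared cells switch their planted category with a
  configurable probability.

Every planted quantity is recorded in a :class:`GroundTruth` object so
recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .errors import ParameterError, ValidationError
from .rng import stage_rng
from .types import LABELS, BoutInterval, BoutTrack, LongitudinalMap, Session, TraceMatrix

__all__ = [
    "NeuronArchetype",
    "CalciumKernel",
    "BoutStatistics",
    "SessionConfig",
    "LongitudinalConfig",
    "GroundTruth",
    "simulate_events",
    "events_to_fluorescence",
    "sample_bouts",
    "make_paradigm_bouts",
    "simulate_session",
    "simulate_longitudinal",
    "simulate_roi_table",
]


@dataclass(frozen=True)
class NeuronArchetype:
    """Planted coupling of one neuron to consumption bouts."""

    label: str
    baseline_rate: float  # events/s
    bout_gain: float  # multiplicative rate factor inside bouts

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ParameterError(f"label must be one of {LABELS}, got {self.label!r}")
        if not (self.baseline_rate > 0):
            raise ParameterError("baseline_rate must be positive")
        if not (self.bout_gain > 0):
            raise ParameterError("bout_gain must be positive")


@dataclass(frozen=True)
class CalciumKernel:
    """Double-exponential indicator kernel, peak-normalized to ``amplitude``.

    h(t) = amplitude * (exp(-t/tau_decay) - exp(-t/tau_rise)) / peak

    Defaults approximate GCaMP6m kinetics (fast rise, ~1 s decay).
    """

    tau_rise_s: float = 0.07
    tau_decay_s: float = 1.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.tau_rise_s < self.tau_decay_s):
            raise ParameterError("need 0 < tau_rise < tau_decay")
        if not (self.amplitude > 0):
            raise ParameterError("amplitude must be positive")

    @property
    def peak_time_s(self) -> float:
        """Analytic argmax of the un-normalized double exponential."""
        tr, td = self.tau_rise_s, self.tau_decay_s
        return (tr * td) / (td - tr) * math.log(td / tr)

    def _raw(self, t: np.ndarray) -> np.ndarray:
        return np.exp(-t / self.tau_decay_s) - np.exp(-t / self.tau_rise_s)

    def sample(self, frame_rate: float, n_decay_constants: float = 8.0) -> np.ndarray:
        """Kernel evaluated at frame times, long enough to decay to ~0."""
        duration = self.peak_time_s + n_decay_constants * self.tau_decay_s
        t = np.arange(0.0, duration, 1.0 / frame_rate)
        raw = self._raw(t)
        peak = self._raw(np.array([self.peak_time_s]))[0]
        return self.amplitude * raw / peak


@dataclass(frozen=True)
class BoutStatistics:
    """Log-normal consume/rest alternation for free-consumption phases.

    Parameters are the log-normal *median* and log-space sigma of bout and
    inter-bout durations, chosen to give bouts of a few seconds separated
    by somewhat longer pauses (no quantitative bout statistics exist for
    the recordings being emulated; these are the fixture's declared
    defaults).
    """

    consume_median_s: float = 3.0
    consume_sigma: float = 0.5
    rest_median_s: float = 8.0
    rest_sigma: float = 0.6
    min_duration_s: float = 0.5


@dataclass
class SessionConfig:
    """Configuration of one simulated session."""

    n_cells: int = 150
    fractions: Tuple[float, float, float] = (0.4, 0.2, 0.4)  # pos, neg, neutral
    positive_gain: float = 2.5
    negative_gain: float = 0.2
    baseline_rate: float = 0.2  # events/s
    frame_rate: float = 10.0
    paradigm: str = "habituation_stimulus"  # or "two_administrations"
    habituation_s: float = 600.0
    stimulus_s: float = 600.0
    kernel: CalciumKernel = field(default_factory=CalciumKernel)
    noise_sd: float = 0.1
    bout_stats: BoutStatistics = field(default_factory=BoutStatistics)
    stimulus: str = "water"
    animal_id: str = "animal-01"
    simulate_traces: bool = True

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ParameterError(
                f"fractions must sum to 1, got {self.fractions} "
                f"(sum {sum(self.fractions)})"
            )
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Everything planted by a generator call, serializable as JSON."""

    labels: Dict[str, List[str]]  # session_id -> per-cell labels
    transitions: Dict[str, List[Tuple[str, str, str]]] = field(default_factory=dict)
    # animal -> [(global_id, label_a, label_b)] for cells shared between sessions
    kernel: Optional[CalciumKernel] = None
    noise_sd: Optional[float] = None
    seed: Optional[int] = None
    extra: Dict = field(default_factory=dict)

    def label_fractions(self, session_id: str) -> Dict[str, float]:
        labels = self.labels[session_id]
        n = len(labels)
        return {lab: labels.count(lab) / n for lab in LABELS}

    def to_dict(self) -> Dict:
        d = {
            "labels": self.labels,
            "transitions": {
                k: [list(t) for t in v] for k, v in self.transitions.items()
            },
            "kernel": asdict(self.kernel) if self.kernel else None,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "extra": self.extra,
        }
        return d


# ---------------------------------------------------------------------------
# event raster and fluorescence forward model


def simulate_events(
    archetypes: Sequence[NeuronArchetype],
    bouts: Optional[BoutTrack],
    duration_s: float,
    frame_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-frame Poisson event counts for each neuron.

    The rate of cell *i* at frame *f* is ``baseline_rate * bout_gain`` if
    frame *f* lies inside a bout and ``baseline_rate`` otherwise.
    """
    if not (duration_s > 0):
        raise ParameterError("duration_s must be positive")
    n_frames = int(round(duration_s * frame_rate))
    if bouts is not None:
        last_end = max((iv.end_s for iv in bouts.intervals), default=0.0)
        if last_end > duration_s + 1.0 / frame_rate:
            raise ParameterError("duration does not cover all bouts")
        mask = bouts.frame_mask(frame_rate, n_frames)
    else:
        mask = np.zeros(n_frames, dtype=bool)

    base = np.array([a.baseline_rate for a in archetypes])[:, None]
    gain = np.array([a.bout_gain for a in archetypes])[:, None]
    rate_hz = np.where(mask[None, :], base * gain, base)
    lam = rate_hz / frame_rate
    return rng.poisson(lam)


def events_to_fluorescence(
    raster: np.ndarray,
    kernel: CalciumKernel,
    noise_sd: float,
    frame_rate: float,
    rng: Optional[np.random.Generator] = None,
    cell_ids: Optional[Sequence[str]] = None,
    noise: Optional[np.ndarray] = None,
) -> TraceMatrix:
    """Convolve an event raster with the indicator kernel and add noise.

    ``noise`` may be passed explicitly (pre-drawn) so callers can keep
    noise streams independent of event streams; otherwise it is drawn from
    ``rng``.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    raster = np.asarray(raster, dtype=float)
    if raster.ndim != 2:
        raise ParameterError("raster must be 2-D (cells x frames)")
    h = kernel.sample(frame_rate)
    clean = fftconvolve(raster, h[None, :], axes=1)[:, : raster.shape[1]]
    if noise is None:
        if noise_sd > 0:
            if rng is None:
                raise ParameterError("rng required when noise_sd > 0")
            noise = rng.normal(0.0, noise_sd, size=raster.shape)
        else:
            noise = 0.0
    values = clean + noise
    # fftconvolve of an all-zero raster leaves ~1e-17 residue; snap it out
    values[np.abs(values) < 1e-12] = 0.0
    if cell_ids is None:
        cell_ids = [f"cell{i:04d}" for i in range(raster.shape[0])]
    return TraceMatrix(
        cell_ids=list(cell_ids), frame_rate=frame_rate, values=values, unit_tag="raw"
    )


# ---------------------------------------------------------------------------
# paradigms


def sample_bouts(
    window: Tuple[float, float],
    stats: BoutStatistics,
    rng: np.random.Generator,
    label: str = "consume",
) -> List[BoutInterval]:
    """Alternating rest/consume intervals with log-normal durations."""
    start, end = window
    out: List[BoutInterval] = []
    t = start
    while True:
        rest = max(
            stats.min_duration_s,
            rng.lognormal(math.log(stats.rest_median_s), stats.rest_sigma),
        )
        consume = max(
            stats.min_duration_s,
            rng.lognormal(math.log(stats.consume_median_s), stats.consume_sigma),
        )
        t += rest
        if t + consume > end:
            break
        out.append(BoutInterval(t, t + consume, label))
        t += consume
    return out


def make_paradigm_bouts(cfg: SessionConfig, rng: np.random.Generator) -> BoutTrack:
    """Bout track for the configured paradigm; habituation stays bout-free."""
    if cfg.paradigm == "habituation_stimulus":
        hab_end = cfg.habituation_s
        sess_end = cfg.habituation_s + cfg.stimulus_s
        bouts = sample_bouts((hab_end, sess_end), cfg.bout_stats, rng)
        return BoutTrack(intervals=bouts, phase_boundaries=(hab_end, sess_end))
    if cfg.paradigm == "two_administrations":
        # 1-min administrations starting at minutes 1 and 6 of a 10-min session;
        # minute 0-1 serves as the baseline window downstream.
        sess_end = cfg.stimulus_s if cfg.habituation_s == 0 else 600.0
        sess_end = max(sess_end, 600.0)
        intervals = [
            BoutInterval(60.0, 120.0, cfg.stimulus),
            BoutInterval(360.0, 420.0, cfg.stimulus),
        ]
        return BoutTrack(intervals=intervals, phase_boundaries=(60.0, sess_end))
    raise ParameterError(f"unknown paradigm {cfg.paradigm!r}")


def _draw_labels(
    n: int, fractions: Tuple[float, float, float], rng: np.random.Generator
) -> List[str]:
    """Deterministic counts per label (largest-remainder), shuffled order."""
    counts = [int(math.floor(f * n)) for f in fractions]
    remainders = [f * n - c for f, c in zip(fractions, counts)]
    while sum(counts) < n:
        i = int(np.argmax(remainders))
        counts[i] += 1
        remainders[i] = -1
    labels = [lab for lab, c in zip(LABELS, counts) for _ in range(c)]
    rng.shuffle(labels)
    return labels


def _archetype(label: str, cfg: SessionConfig) -> NeuronArchetype:
    gain = {
        "positive": cfg.positive_gain,
        "negative": cfg.negative_gain,
        "neutral": 1.0,
    }[label]
    return NeuronArchetype(label=label, baseline_rate=cfg.baseline_rate, bout_gain=gain)


def _simulate_session_traces(
    archetypes: List[NeuronArchetype],
    bouts: BoutTrack,
    cfg: SessionConfig,
    seed: int,
    stream_prefix: str,
) -> TraceMatrix:
    """Per-phase event and noise streams so the habituation segment is
    invariant to what happens in the stimulus phase under the same seed."""
    fr = cfg.frame_rate
    hab_end, sess_end = bouts.phase_boundaries
    n_frames = int(round(sess_end * fr))
    hab_frames = int(round(hab_end * fr))

    mask = bouts.frame_mask(fr, n_frames)
    base = np.array([a.baseline_rate for a in archetypes])[:, None]
    gain = np.array([a.bout_gain for a in archetypes])[:, None]
    lam = np.where(mask[None, :], base * gain, base) / fr

    rng_ev_hab = stage_rng(seed, f"{stream_prefix}/events/habituation")
    rng_ev_stim = stage_rng(seed, f"{stream_prefix}/events/stimulus")
    raster = np.empty((len(archetypes), n_frames))
    raster[:, :hab_frames] = rng_ev_hab.poisson(lam[:, :hab_frames])
    raster[:, hab_frames:] = rng_ev_stim.poisson(lam[:, hab_frames:])

    rng_nz_hab = stage_rng(seed, f"{stream_prefix}/noise/habituation")
    rng_nz_stim = stage_rng(seed, f"{stream_prefix}/noise/stimulus")
    noise = np.empty_like(raster)
    noise[:, :hab_frames] = rng_nz_hab.normal(
        0.0, cfg.noise_sd, size=(len(archetypes), hab_frames)
    )
    noise[:, hab_frames:] = rng_nz_stim.normal(
        0.0, cfg.noise_sd, size=(len(archetypes), n_frames - hab_frames)
    )

    # convolve each phase segment separately so the habituation part of the
    # trace depends only on habituation events (the causal kernel lets the
    # habituation tail bleed forward into the stimulus phase, never back)
    h = cfg.kernel.sample(fr)
    values = noise.copy()
    if hab_frames > 0:
        clean_hab = fftconvolve(raster[:, :hab_frames], h[None, :], axes=1)
        values[:, :hab_frames] += clean_hab[:, :hab_frames]
        tail = clean_hab[:, hab_frames:]
        stop = min(n_frames, hab_frames + tail.shape[1])
        values[:, hab_frames:stop] += tail[:, : stop - hab_frames]
    if n_frames > hab_frames:
        clean_stim = fftconvolve(raster[:, hab_frames:], h[None, :], axes=1)
        values[:, hab_frames:] += clean_stim[:, : n_frames - hab_frames]

    return TraceMatrix(
        cell_ids=[f"cell{i:04d}" for i in range(len(archetypes))],
        frame_rate=fr,
        values=values,
        unit_tag="raw",
    )


def simulate_session(
    cfg: SessionConfig, seed: int, _stream_prefix: str = "session"
) -> Tuple[Session, GroundTruth]:
    """Generate one session plus its planted ground truth."""
    rng_labels = stage_rng(seed, f"{_stream_prefix}/labels")
    labels = _draw_labels(cfg.n_cells, cfg.fractions, rng_labels)
    archetypes = [_archetype(lab, cfg) for lab in labels]

    rng_bouts = stage_rng(seed, f"{_stream_prefix}/bouts")
    bouts = make_paradigm_bouts(cfg, rng_bouts)

    session_id = f"{cfg.animal_id}/{cfg.stimulus}"
    if cfg.simulate_traces:
        traces = _simulate_session_traces(archetypes, bouts, cfg, seed, _stream_prefix)
    else:
        n_frames = int(round(bouts.session_end_s * cfg.frame_rate))
        traces = TraceMatrix(
            cell_ids=[f"cell{i:04d}" for i in range(cfg.n_cells)],
            frame_rate=cfg.frame_rate,
            values=np.zeros((cfg.n_cells, n_frames)),
        )

    session = Session(
        animal_id=cfg.animal_id, stimulus=cfg.stimulus, traces=traces, bouts=bouts
    )
    gt = GroundTruth(
        labels={session_id: labels},
        kernel=cfg.kernel,
        noise_sd=cfg.noise_sd,
        seed=seed,
    )
    return session, gt


# ---------------------------------------------------------------------------
# longitudinal cohorts


@dataclass
class LongitudinalConfig:
    n_animals: int = 1
    n_cells: int = 150
    overlap_rate: float = 0.5
    switch_prob: float = 0.2
    session_stimuli: Tuple[str, str] = ("water", "food")
    session_cfg: SessionConfig = field(default_factory=SessionConfig)

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_rate <= 1):
            raise ParameterError("overlap_rate must be in [0, 1]")
        if not (0 <= self.switch_prob <= 1):
            raise ParameterError("switch_prob must be in [0, 1]")


def simulate_longitudinal(
    cfg: LongitudinalConfig, seed: int
) -> Tuple[Dict[str, Session], LongitudinalMap, GroundTruth]:
    """Two-session cohorts with partial cell overlap and label switching.

    A fraction ``overlap_rate`` of each animal's cells appears in both
    sessions under a shared global id. A shared cell keeps its planted
    label with probability ``1 - switch_prob``; otherwise it is resampled
    uniformly from the two other labels. Non-shared cells draw fresh
    labels from the configured fractions.
    """
    sessions: Dict[str, Session] = {}
    lmap = LongitudinalMap()
    gt = GroundTruth(labels={}, kernel=cfg.session_cfg.kernel,
                     noise_sd=cfg.session_cfg.noise_sd, seed=seed)

    stim_a, stim_b = cfg.session_stimuli
    for a in range(cfg.n_animals):
        animal = f"animal-{a + 1:02d}"
        rng = stage_rng(seed, f"longitudinal/{animal}")
        n = cfg.n_cells
        n_shared = int(round(cfg.overlap_rate * n))
        shared_globals = [f"{animal}/g{j:04d}" for j in range(n_shared)]

        labels_a = _draw_labels(n, cfg.session_cfg.fractions, rng)
        # plant exactly round(switch_prob * n_shared) switchers (uniformly
        # chosen) so the planted switched fraction matches the configured
        # probability up to rounding, mirroring the deterministic label counts
        n_switch = int(round(cfg.switch_prob * n_shared))
        switchers = set(rng.choice(n_shared, size=n_switch, replace=False)) if n_shared else set()
        labels_b: List[str] = []
        transitions: List[Tuple[str, str, str]] = []
        for j in range(n):
            if j < n_shared:
                la = labels_a[j]
                if j in switchers:
                    others = [x for x in LABELS if x != la]
                    lb = others[rng.integers(len(others))]
                else:
                    lb = la
                labels_b.append(lb)
                transitions.append((shared_globals[j], la, lb))
            else:
                labels_b.append(_draw_labels(1, cfg.session_cfg.fractions, rng)[0])

        next_global = n_shared
        for s_idx, (stim, labels) in enumerate(
            [(stim_a, labels_a), (stim_b, labels_b)]
        ):
            session_id = f"{animal}/{stim}"
            sess_cfg = SessionConfig(
                **{
                    **asdict(cfg.session_cfg),
                    "n_cells": n,
                    "animal_id": animal,
                    "stimulus": stim,
                    "kernel": cfg.session_cfg.kernel,
                    "bout_stats": cfg.session_cfg.bout_stats,
                }
            )
            archetypes = [_archetype(lab, sess_cfg) for lab in labels]
            rng_bouts = stage_rng(seed, f"longitudinal/{session_id}/bouts")
            bouts = make_paradigm_bouts(sess_cfg, rng_bouts)
            if sess_cfg.simulate_traces:
                traces = _simulate_session_traces(
                    archetypes, bouts, sess_cfg, seed, f"longitudinal/{session_id}"
                )
            else:
                n_frames = int(round(bouts.session_end_s * sess_cfg.frame_rate))
                traces = TraceMatrix(
                    cell_ids=[f"cell{i:04d}" for i in range(n)],
                    frame_rate=sess_cfg.frame_rate,
                    values=np.zeros((n, n_frames)),
                )
            sessions[session_id] = Session(
                animal_id=animal, stimulus=stim, traces=traces, bouts=bouts
            )
            gt.labels[session_id] = list(labels)
            for j, local in enumerate(traces.cell_ids):
                if j < n_shared:
                    g = shared_globals[j]
                else:
                    g = f"{animal}/g{next_global:04d}"
                    next_global += 1
                lmap.add(session_id, local, g)
        gt.transitions[animal] = transitions

    gt.extra["config"] = {
        "n_animals": cfg.n_animals,
        "n_cells": cfg.n_cells,
        "overlap_rate": cfg.overlap_rate,
        "switch_prob": cfg.switch_prob,
    }
    return sessions, lmap, gt


# ---------------------------------------------------------------------------
# ROI tables


def simulate_roi_table(
    regions: Sequence[str],
    seed: int,
    injection_ctf: float = 2000.0,
    relative_intensities: Optional[Sequence[float]] = None,
    n_replicates: int = 3,
    background_mean: float = 5.0,
    roi_area: float = 100.0,
    noise_cv: float = 0.05,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """ROI intensity rows with a planted projection-strength ranking.

    Returns the table plus the planted normalized intensity per region
    (the recovery target for the quantification module).
    """
    rng = stage_rng(seed, "roi_table")
    if relative_intensities is None:
        # strictly decreasing planted ranking
        relative_intensities = np.linspace(0.9, 0.1, len(regions))
    if len(relative_intensities) != len(regions):
        raise ParameterError("one relative intensity per region required")

    rows = [
        {
            "region": "injection_site",
            "integrated_density": injection_ctf + roi_area * background_mean,
            "roi_area": roi_area,
            "background_mean": background_mean,
            "is_injection_site": True,
        }
    ]
    planted: Dict[str, float] = {}
    for region, rel in zip(regions, relative_intensities):
        planted[region] = float(rel)
        for _ in range(n_replicates):
            ctf = rel * injection_ctf * (1.0 + noise_cv * rng.standard_normal())
            rows.append(
                {
                    "region": region,
                    "integrated_density": ctf + roi_area * background_mean,
                    "roi_area": roi_area,
                    "background_mean": background_mean,
                    "is_injection_site": False,
                }
            )
    df = pd.DataFrame(rows)
    n_inj = int(df["is_injection_site"].sum())
    if n_inj != 1:
        raise ValidationError(f"expected exactly one injection-site row, got {n_inj}")
    return df, planted
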