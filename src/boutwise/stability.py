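"""Longitudinal matching of classified cells and stable/unstable fractions.

A cell followed across two sessions contributes one ordered label pair
(earlier session first). Pairs that keep a non-neutral category
(pos-pos, neg-neg) are *stable* (generalizers across stimuli of different
valence); the six switching categories (pos-neg, neg-pos, pos-neutral,
neg-neutral, neutral-pos, neutral-neg) are *unstable* (specializers).
Neutral-neutral pairs — cells coupled to consumption in neither session —
are excluded from both numerator and denominator, so the two fractions
are complementary on the declared denominator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .types import LABELS, LongitudinalMap

__all__ = [
    "match_labels",
    "transition_counts",
    "transition_fractions",
    "chord_export",
    "compare_fraction_groups",
    "FractionReport",
]

logger = logging.getLogger(__name__)

STABLE_PAIRS = {("positive", "positive"), ("negative", "negative")}
EXCLUDED_PAIR = ("neutral", "neutral")


def match_labels(
    class_a: pd.DataFrame,
    class_b: pd.DataFrame,
    lmap: LongitudinalMap,
    session_a: str,
    session_b: str,
) -> Tuple[List[Tuple[str, str]], Dict[str, int]]:
    """Ordered (label_earlier, label_later) pairs for cells seen in both
    sessions; cells detected in only one session are excluded and counted.

    Returns ``(pairs, bookkeeping)`` where bookkeeping counts matched
    cells and the per-session singletons.
    """
    labels_a = class_a.set_index("cell")["label"]
    labels_b = class_b.set_index("cell")["label"]
    local_a = lmap.globals_in(session_a)  # global -> local
    local_b = lmap.globals_in(session_b)

    for session, locals_, index in (
        (session_a, local_a, labels_a.index),
        (session_b, local_b, labels_b.index),
    ):
        unknown = [l for l in locals_.values() if l not in index]
        if unknown:
            raise ValidationError(
                f"longitudinal map references cells missing from the "
                f"{session!r} classification: {unknown[:5]}"
            )

    shared = sorted(set(local_a) & set(local_b))
    pairs = [
        (str(labels_a[local_a[g]]), str(labels_b[local_b[g]])) for g in shared
    ]
    bookkeeping = {
        "n_matched": len(shared),
        "only_in_a": len(set(local_a) - set(local_b)),
        "only_in_b": len(set(local_b) - set(local_a)),
    }
    if not pairs:
        logger.warning(
            "no cells shared between %s and %s", session_a, session_b
        )
    return pairs, bookkeeping


def transition_counts(pairs: Sequence[Tuple[str, str]]) -> pd.DataFrame:
    """3x3 label-pair counts (rows = earlier session, cols = later)."""
    counts = pd.DataFrame(0, index=list(LABELS), columns=list(LABELS), dtype=int)
    for a, b in pairs:
        if a not in LABELS or b not in LABELS:
            raise ValidationError(f"unknown label pair ({a!r}, {b!r})")
        counts.loc[a, b] += 1
    return counts


@dataclass
class FractionReport:
    """Stable/unstable split over matched cells, neutral-neutral excluded."""

    stable_fraction: Optional[float]
    unstable_fraction: Optional[float]
    denominator: int
    excluded_neutral_neutral: int
    n_matched: int
    counts: pd.DataFrame = field(repr=False, default=None)

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    def to_dict(self) -> Dict:
        return {
            "stable_fraction": self.stable_fraction,
            "unstable_fraction": self.unstable_fraction,
            "denominator": self.denominator,
            "excluded_neutral_neutral": self.excluded_neutral_neutral,
            "n_matched": self.n_matched,
            "neutral_neutral_policy": "excluded from numerator and denominator",
        }


def transition_fractions(pairs: Sequence[Tuple[str, str]]) -> FractionReport:
    """Stable vs unstable fractions from ordered label pairs.

    With every matched pair neutral-neutral the fractions are undefined
    and reported as ``None`` (sentinel) rather than a fabricated number.
    """
    if not pairs:
        raise ParameterError("no matched label pairs")
    counts = transition_counts(pairs)
    n_matched = int(counts.values.sum())
    excluded = int(counts.loc[EXCLUDED_PAIR])
    denominator = n_matched - excluded
    stable = sum(int(counts.loc[p]) for p in STABLE_PAIRS)
    if denominator == 0:
        logger.warning("all matched pairs neutral-neutral; fractions undefined")
        return FractionReport(None, None, 0, excluded, n_matched, counts)
    unstable = denominator - stable
    return FractionReport(
        stable_fraction=stable / denominator,
        unstable_fraction=unstable / denominator,
        denominator=denominator,
        excluded_neutral_neutral=excluded,
        n_matched=n_matched,
        counts=counts,
    )


def chord_export(counts: pd.DataFrame) -> Dict:
    """Serializable chord-diagram structure for a 3x3 transition table.

    Node order is fixed (positive, negative, neutral) on both sides;
    edges carry the 9 pair counts. Edge sums reproduce each session's
    marginal label counts.
    """
    if list(counts.index) != list(LABELS) or list(counts.columns) != list(LABELS):
        raise ValidationError("counts must be indexed by the 3 labels on both axes")
    edges = [
        {"source": a, "target": b, "count": int(counts.loc[a, b])}
        for a in LABELS
        for b in LABELS
    ]
    return {
        "nodes_earlier": list(LABELS),
        "nodes_later": list(LABELS),
        "edges": edges,
        "marginal_earlier": {a: int(counts.loc[a].sum()) for a in LABELS},
        "marginal_later": {b: int(counts[b].sum()) for b in LABELS},
    }


def compare_fraction_groups(
    fractions_a: Sequence[float],
    fractions_b: Sequence[float],
    design: str = "unpaired",
    alpha: float = 0.05,
):
    """Group comparison of per-animal fractions via the test-selection policy
    (Shapiro-Wilk gate, then t-test or rank test). See
    :func:`boutwise.quantify.stats_policy`."""
    from .quantify import stats_policy

    a = np.asarray(fractions_a, dtype=float)
    b = np.asarray(fractions_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("need at least 2 animals per group")
    return stats_policy(a, b, design=design, alpha=alpha)
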