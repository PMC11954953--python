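"""Closed-form quantifications and the test-selection policy.

Covers corrected total fluorescence (CTF) for projection-strength
ranking, the real-time place-preference and conditioned flavor-preference
indices, epoch-based consumption aggregation for alternating laser
OFF/ON designs, and a normality-gated two-group comparison that reports
Cohen's d alongside whichever test the gate selects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError, ValidationError

__all__ = [
    "ctf",
    "ctf_table",
    "normalize_ctf",
    "quantify_roi_table",
    "rtpp_index",
    "cfp_index",
    "epoch_consumption",
    "stats_policy",
    "cohens_d",
    "StatsReport",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# corrected total fluorescence


def ctf(integrated_density: float, roi_area: float, background_mean: float) -> float:
    """Corrected total fluorescence of one ROI measurement:

        CTF = integrated_density - roi_area * background_mean

    Negative values are legitimate (ROI dimmer than background) and are
    reported as-is; callers flag them rather than clipping, since clipping
    would bias region rankings.
    """
    if not (roi_area > 0):
        raise ValidationError("roi_area must be positive")
    if background_mean < 0:
        raise ValidationError("background_mean must be >= 0")
    return float(integrated_density - roi_area * background_mean)


def ctf_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`ctf` row-wise to an ROI table; adds ctf and negative flag."""
    out = df.copy()
    out["ctf"] = [
        ctf(r.integrated_density, r.roi_area, r.background_mean)
        for r in df.itertuples()
    ]
    out["ctf_negative"] = out["ctf"] < 0
    if out["ctf_negative"].any():
        logger.warning(
            "%d ROI rows have negative CTF (kept, flagged)",
            int(out["ctf_negative"].sum()),
        )
    return out


def normalize_ctf(
    ctf_roi: Sequence[float], ctf_injection_site: float
) -> float:
    """Replicate-averaged CTF of an ROI, normalized to the injection site."""
    if not (ctf_injection_site > 0):
        raise ParameterError(
            f"injection-site CTF must be positive to normalize, "
            f"got {ctf_injection_site}"
        )
    reps = np.asarray(list(ctf_roi), dtype=float)
    if reps.size == 0:
        raise ParameterError("need at least one CTF replicate")
    return float(reps.mean() / ctf_injection_site)


def quantify_roi_table(df: pd.DataFrame) -> pd.DataFrame:
    """Normalized intensity per region from a raw ROI table.

    Replicate CTFs of a region are averaged and divided by the
    injection-site CTF; exactly one injection-site row is required.
    """
    inj = df[df["is_injection_site"]]
    if len(inj) == 0:
        raise ValidationError("ROI table has no injection-site row")
    if len(inj) > 1:
        raise ValidationError(
            f"ROI table has {len(inj)} injection-site rows; exactly one required"
        )
    with_ctf = ctf_table(df)
    inj_ctf = float(with_ctf.loc[with_ctf["is_injection_site"], "ctf"].iloc[0])
    rows = []
    for region, grp in with_ctf[~with_ctf["is_injection_site"]].groupby(
        "region", sort=True
    ):
        rows.append(
            {
                "region": region,
                "n_replicates": len(grp),
                "mean_ctf": float(grp["ctf"].mean()),
                "normalized_intensity": normalize_ctf(grp["ctf"], inj_ctf),
                "any_negative_ctf": bool(grp["ctf_negative"].any()),
            }
        )
    return pd.DataFrame(rows).sort_values(
        "normalized_intensity", ascending=False, ignore_index=True
    )


# ---------------------------------------------------------------------------
# preference indices


def rtpp_index(time_in_stim_chamber_s: float, total_s: float) -> float:
    """Real-time place preference: percent time in the photostimulated
    chamber."""
    if not (total_s > 0):
        raise ParameterError("total_s must be positive")
    if not (0 <= time_in_stim_chamber_s <= total_s):
        raise ParameterError("time in chamber must lie in [0, total]")
    return 100.0 * time_in_stim_chamber_s / total_s


def cfp_index(amount_preferred: float, amount_least: float) -> Optional[float]:
    """Conditioned flavor preference: preferred / (preferred + least).

    Returns ``None`` (undefined sentinel) if both intakes are zero.
    """
    if amount_preferred < 0 or amount_least < 0:
        raise ParameterError("intake amounts must be >= 0")
    total = amount_preferred + amount_least
    if total == 0:
        logger.warning("both intakes zero; preference undefined")
        return None
    return amount_preferred / total


# ---------------------------------------------------------------------------
# epoch consumption


def epoch_consumption(table: pd.DataFrame) -> Dict:
    """Per-epoch amounts plus ON/OFF aggregates for alternating designs.

    ``table`` columns: start_min, end_min, light_state ('ON'/'OFF'),
    amount. Epochs must be contiguous and non-overlapping.
    """
    required = ["start_min", "end_min", "light_state", "amount"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"epoch table missing columns {missing}")
    df = table.sort_values("start_min", ignore_index=True)
    if (df["amount"] < 0).any():
        raise ValidationError("amounts must be >= 0")
    for prev, nxt in zip(df.itertuples(), df.iloc[1:].itertuples()):
        if nxt.start_min < prev.end_min:
            raise ValidationError(
                f"overlapping epochs at {prev.end_min} / {nxt.start_min} min"
            )
        if not math.isclose(nxt.start_min, prev.end_min):
            raise ValidationError(
                f"epochs not contiguous at {prev.end_min} / {nxt.start_min} min"
            )
    state = df["light_state"].str.upper()
    if not state.isin(["ON", "OFF"]).all():
        raise ValidationError("light_state must be 'ON' or 'OFF'")
    on = df[state == "ON"]["amount"]
    off = df[state == "OFF"]["amount"]
    return {
        "per_epoch": df[required].to_dict("records"),
        "on_sum": float(on.sum()),
        "off_sum": float(off.sum()),
        "on_amounts": on.tolist(),
        "off_amounts": off.tolist(),
    }


# ---------------------------------------------------------------------------
# test-selection policy


def cohens_d(x: np.ndarray, y: np.ndarray, design: str = "unpaired") -> float:
    """Cohen's d: pooled-SD form (unpaired) or SD-of-differences (paired)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if design == "paired":
        if x.size != y.size:
            raise ParameterError("paired design needs equal-length samples")
        diff = x - y
        sd = diff.std(ddof=1)
        return 0.0 if sd == 0 else float(diff.mean() / sd)
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (
        nx + ny - 2
    )
    sd = math.sqrt(pooled_var)
    return 0.0 if sd == 0 else float((x.mean() - y.mean()) / sd)


@dataclass
class StatsReport:
    test_name: str
    statistic: float
    p_value: float
    effect_size_d: float
    design: str
    normal_x: Optional[bool]
    normal_y: Optional[bool]
    degenerate: bool = False

    def to_dict(self) -> Dict:
        return self.__dict__.copy()


def _is_normal(sample: np.ndarray, alpha: float) -> Optional[bool]:
    if np.ptp(sample) == 0:
        return None  # Shapiro-Wilk undefined for constant data
    return bool(sps.shapiro(sample).pvalue > alpha)


def stats_policy(
    x: Sequence[float],
    y: Sequence[float],
    design: str = "unpaired",
    alpha: float = 0.05,
) -> StatsReport:
    """Normality-gated two-group comparison with effect size.

    Each sample is screened with the Shapiro-Wilk test at ``alpha``; if
    both pass, a two-tailed t-test (paired or unpaired per ``design``) is
    used, otherwise Mann-Whitney U (unpaired) or Wilcoxon signed-rank
    (paired). Cohen's d is reported regardless of the branch taken.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if design not in ("paired", "unpaired"):
        raise ParameterError(f"unknown design {design!r}")
    if x.size < 3 or y.size < 3:
        raise ParameterError("need n >= 3 per group")
    if design == "paired" and x.size != y.size:
        raise ParameterError("paired design needs equal-length samples")

    d = cohens_d(x, y, design)
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        # zero variance everywhere: no test is informative
        return StatsReport(
            test_name="degenerate",
            statistic=0.0,
            p_value=1.0 if x.mean() == y.mean() else 0.0,
            effect_size_d=d,
            design=design,
            normal_x=None,
            normal_y=None,
            degenerate=True,
        )
    if design == "paired" and np.ptp(x - y) == 0:
        # identical (or constant-offset-free) pairs: null exactly satisfied
        return StatsReport(
            test_name="degenerate-paired",
            statistic=0.0,
            p_value=1.0 if np.allclose(x, y) else 0.0,
            effect_size_d=d,
            design=design,
            normal_x=_is_normal(x, alpha),
            normal_y=_is_normal(y, alpha),
            degenerate=True,
        )

    normal_x = _is_normal(x, alpha)
    normal_y = _is_normal(y, alpha)
    gaussian = bool(normal_x) and bool(normal_y)

    if design == "unpaired":
        if gaussian:
            res = sps.ttest_ind(x, y)
            name = "unpaired t-test"
        else:
            res = sps.mannwhitneyu(x, y, alternative="two-sided")
            name = "Mann-Whitney U"
    else:
        if gaussian:
            res = sps.ttest_rel(x, y)
            name = "paired t-test"
        else:
            res = sps.wilcoxon(x, y, alternative="two-sided")
            name = "Wilcoxon signed-rank"
    return StatsReport(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size_d=d,
        design=design,
        normal_x=normal_x,
        normal_y=normal_y,
    )
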