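"""Per-item reduction statistics and the retention rule.

Statistics are computed on a pooled frame (community sample plus the clinic
subsample carrying the relevant diagnosis), separately per informant, with
pairwise deletion: each statistic uses exactly the persons complete on the
variables it involves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ResponseMatrix

__all__ = [
    "UndefinedCorrelationError",
    "GroupingError",
    "DegenerateCovariateError",
    "item_total_correlations",
    "point_biserial_discrimination",
    "partial_discrimination",
    "missing_fraction",
    "item_stats_table",
    "retain_items",
]


class UndefinedCorrelationError(ValueError):
    """A correlation is undefined (zero variance on the complete pairs)."""


class GroupingError(ValueError):
    """Cases or controls are absent after deletion."""


class DegenerateCovariateError(ValueError):
    """A partialling covariate is perfectly collinear with a variable."""


def _pearson(x: np.ndarray, y: np.ndarray, context: str) -> float:
    if len(x) < 3:
        raise UndefinedCorrelationError(f"{context}: fewer than 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(f"{context}: zero variance on complete pairs")
    return float(np.corrcoef(x, y)[0, 1])


def _complete(frame: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    return frame.dropna(subset=list(cols))


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the t approximation."""
    if n < 3:
        return float("nan")
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def item_total_correlations(
    data: ResponseMatrix,
    pool: Iterable[str],
    total_items: Sequence[str],
    *,
    case_flag: str = "anxiety",
    informant: str = "adolescent",
    corrected: bool = False,
) -> dict[str, float]:
    """Pearson correlation of each pool item with the scale total.

    The total is the sum over ``total_items`` on pairwise-complete persons of
    the pooled frame for ``case_flag``; by default the item stays in its own
    total (uncorrected item-total correlation).  ``corrected=True`` removes
    the item from the total first.
    """
    frame, _ = data.pooled_frame(case_flag, informant)
    total_items = list(total_items)
    if not total_items:
        raise ValueError("total_items is empty")
    out: dict[str, float] = {}
    for item in pool:
        cols = sorted(set(total_items) | {item})
        sub = _complete(frame, cols)
        totals = sub[total_items].sum(axis=1)
        if corrected and item in total_items:
            totals = totals - sub[item]
        out[item] = _pearson(sub[item].to_numpy(float), totals.to_numpy(float),
                             f"item-total for {item}")
    return out


def point_biserial_discrimination(
    data: ResponseMatrix,
    item: str,
    case_flag: str,
    *,
    informant: str = "adolescent",
) -> float:
    """Item-discrimination index: Pearson r of item score with the 0/1 case flag.

    Cases are clinic members with the diagnosis flag; controls are community
    members.  Clinic members lacking the flag are excluded from the frame.
    """
    frame, cases = data.pooled_frame(case_flag, informant)
    keep = frame[item].notna()
    x = frame.loc[keep, item].to_numpy(float)
    y = cases[keep].to_numpy(float)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise GroupingError(f"one group empty for item {item} after deletion")
    return _pearson(x, y, f"discrimination for {item}")


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial r_xy.z."""
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise DegenerateCovariateError(
            "covariate perfectly correlated with a variable (|r| = 1)")
    return (r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))


_COVARIATE_CODING = {
    "gender": ("gender", {"female": 1.0, "male": 0.0}),
    "age_group": ("age_group", {"older": 1.0, "younger": 0.0}),
    "age": ("age_group", {"older": 1.0, "younger": 0.0}),
}


def partial_discrimination(
    data: ResponseMatrix,
    item: str,
    case_flag: str,
    covariate: str,
    *,
    informant: str = "adolescent",
) -> float:
    """Item discrimination controlled for a binary covariate (one at a time)."""
    if covariate not in _COVARIATE_CODING:
        raise ValueError(f"unknown covariate {covariate!r}")
    col, coding = _COVARIATE_CODING[covariate]
    frame, cases = data.pooled_frame(case_flag, informant)
    keep = frame[item].notna()
    x = frame.loc[keep, item].to_numpy(float)
    y = cases[keep].to_numpy(float)
    z = frame.loc[keep, col].map(coding).to_numpy(float)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise GroupingError(f"one group empty for item {item} after deletion")
    r_xy = _pearson(x, y, f"discrimination for {item}")
    if np.ptp(z) == 0:
        # constant covariate carries no information; the partial collapses
        return r_xy
    r_xz = float(np.corrcoef(x, z)[0, 1])
    r_yz = float(np.corrcoef(y, z)[0, 1])
    return float(partial_correlation(r_xy, r_xz, r_yz))


def missing_fraction(
    data: ResponseMatrix,
    item: str,
    *,
    case_flag: str = "anxiety",
    informant: str = "adolescent",
) -> float:
    """Fraction of persons in the pooled frame with a missing response."""
    frame, _ = data.pooled_frame(case_flag, informant)
    return float(frame[item].isna().mean())


def item_stats_table(
    data: ResponseMatrix,
    pool: Sequence[str],
    total_items: Sequence[str],
    case_flag: str,
    *,
    informant: str = "adolescent",
    corrected_item_total: bool = False,
) -> pd.DataFrame:
    """One row per pool item: reduction statistics plus the retained flag."""
    it = item_total_correlations(
        data, pool, total_items, case_flag=case_flag, informant=informant,
        corrected=corrected_item_total)
    frame, _ = data.pooled_frame(case_flag, informant)
    rows = []
    for item in pool:
        rpb = point_biserial_discrimination(data, item, case_flag, informant=informant)
        n_pairs = int(frame[item].notna().sum())
        rows.append({
            "item_id": item,
            "item_total_r": it[item],
            "item_total_p": correlation_p_value(it[item], n_pairs),
            "discrimination_rpb": rpb,
            "discrimination_p": correlation_p_value(rpb, n_pairs),
            "discrimination_partial_gender": partial_discrimination(
                data, item, case_flag, "gender", informant=informant),
            "discrimination_partial_age": partial_discrimination(
                data, item, case_flag, "age_group", informant=informant),
            "missing_fraction": missing_fraction(
                data, item, case_flag=case_flag, informant=informant),
            "n_pairs_used": n_pairs,
        })
    table = pd.DataFrame(rows)
    table["retained"] = [
        item in retain_items(table) for item in table["item_id"]
    ]
    return table.sort_values("discrimination_rpb", ascending=False, kind="mergesort") \
        .reset_index(drop=True)


def retain_items(
    stats_table: pd.DataFrame,
    *,
    item_total_threshold: float = 0.70,
    discrimination_threshold: float = 0.30,
    missing_threshold: float = 0.10,
) -> set[str]:
    """Items with high item-total OR high discrimination, and low missingness.

    Thresholds are strict inequalities and default to the published rule
    (> 0.70 item-total or > 0.30 discrimination, < 10% missing).
    """
    keep = (
        (stats_table["item_total_r"] > item_total_threshold)
        | (stats_table["discrimination_rpb"] > discrimination_threshold)
    ) & (stats_table["missing_fraction"] < missing_threshold)
    return set(stats_table.loc[keep, "item_id"])
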