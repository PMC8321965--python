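"""Greedy nested subset construction and selection of the final screen items.

Candidate subsets are built by removing the eligible item with the lowest
discrimination index one at a time (after resolving user-supplied
content-overlap exclusion pairs), then evaluated with subgroup ROC analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .cohort import ResponseMatrix
from .roc import TIER_ORDER, subgroup_roc

__all__ = [
    "SubsetEvaluation",
    "SelectionFailure",
    "greedy_subset_sequence",
    "evaluate_subsets",
    "select_final_subset",
]


class SelectionFailure(RuntimeError):
    """No candidate subset met the selection criteria."""

    def __init__(self, message: str, best: "SubsetEvaluation | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class SubsetEvaluation:
    items: tuple[str, ...]
    informant: str
    strata: Mapping[str, dict]
    meets_criteria: bool

    @property
    def size(self) -> int:
        return len(self.items)

    @property
    def overall(self) -> dict:
        return self.strata["overall"]

    def row(self) -> dict:
        """Flat summary row (overall stratum) for tabular reports."""
        o = self.overall
        return {
            "informant": self.informant,
            "size": self.size,
            "items": " ".join(self.items),
            "auc": o["roc"].auc,
            "cutoff": o["cutoff"].cutoff,
            "sensitivity": o["cutoff"].sensitivity,
            "specificity": o["cutoff"].specificity,
            "tier": o["cutoff"].tier,
            "min_stratum_auc": min(s["roc"].auc for s in self.strata.values()),
            "meets_criteria": self.meets_criteria,
        }


def _rank_key(item: str, stats_table: pd.DataFrame) -> tuple:
    row = stats_table.loc[stats_table["item_id"] == item]
    if row.empty:
        raise KeyError(f"item {item} not in the stats table")
    r = row.iloc[0]
    # weakest first: lowest discrimination, then lower item-total, then id
    return (float(r["discrimination_rpb"]), float(r["item_total_r"]), item)


def greedy_subset_sequence(
    eligible: Sequence[str],
    stats_table: pd.DataFrame,
    exclusions: Sequence[tuple[str, str]] = (),
    *,
    min_size: int = 2,
) -> list[tuple[str, ...]]:
    """Nested subsets by one-at-a-time removal of the weakest item.

    Each exclusion pair (content-overlapping items) is resolved first by
    dropping its lower-discrimination member; ties fall back to lower
    item-total correlation then lexicographic id.  The returned list starts
    with the full (post-exclusion) set and shrinks to ``min_size`` items,
    every subset a strict superset of the next.
    """
    pool = sorted(set(eligible))
    for a, b in exclusions:
        if a not in pool or b not in pool:
            continue
        drop = min(a, b, key=lambda it: _rank_key(it, stats_table))
        pool.remove(drop)

    # strongest-last ordering; removal order is deterministic
    order = sorted(pool, key=lambda it: _rank_key(it, stats_table), reverse=True)
    sequence: list[tuple[str, ...]] = []
    while len(order) >= max(min_size, 1):
        sequence.append(tuple(order))
        order = order[:-1]
    return sequence


def evaluate_subsets(
    data: ResponseMatrix,
    subsets: Sequence[Sequence[str]],
    case_flag: str,
    *,
    informant: str = "adolescent",
    auc_threshold: float = 0.7,
) -> list[SubsetEvaluation]:
    """Subgroup ROC evaluation of each candidate subset's sum score.

    A subset meets criteria when its overall AUC is at least
    ``auc_threshold``, its overall tiered cut-off lands in T1-T3, and every
    non-empty stratum's AUC is at least the threshold.
    """
    if not subsets:
        raise ValueError("no subsets supplied")
    out = []
    for items in subsets:
        strata = subgroup_roc(data, list(items), case_flag, informant=informant)
        overall = strata["overall"]
        meets = (
            overall["roc"].auc >= auc_threshold
            and overall["cutoff"].tier != "NONE"
            and all(s["roc"].auc >= auc_threshold for s in strata.values())
        )
        out.append(SubsetEvaluation(
            items=tuple(items), informant=informant, strata=strata,
            meets_criteria=meets,
        ))
    return out


def _pick(evaluations: Sequence[SubsetEvaluation], rule: str) -> SubsetEvaluation:
    passing = [e for e in evaluations if e.meets_criteria]
    if not passing:
        best = min(
            evaluations,
            key=lambda e: (TIER_ORDER[e.overall["cutoff"].tier],
                           -(e.overall["cutoff"].sensitivity
                             + e.overall["cutoff"].specificity)),
        )
        raise SelectionFailure(
            f"no subset met the criteria; best achieved tier was "
            f"{best.overall['cutoff'].tier} at {best.size} items", best)
    if rule == "smallest":
        return min(passing, key=lambda e: (e.size, -e.overall["roc"].auc))
    if rule == "best":
        # sensitivity-prioritised: best tier first, then the subset-comparison
        # metric (overall AUC), then brevity.  AUC rather than sens+spec at
        # the selected cut-off: subsets are compared by their discriminative
        # ability, the tier ladder judges only the cut-off.
        return min(
            passing,
            key=lambda e: (
                TIER_ORDER[e.overall["cutoff"].tier],
                -e.overall["roc"].auc,
                e.size,
            ),
        )
    raise ValueError(f"unknown selection rule {rule!r}")


@dataclass(frozen=True)
class SubsetSelection:
    adolescent: SubsetEvaluation
    parent_same_items: SubsetEvaluation
    parent_optimal: SubsetEvaluation
    shared_set_retained: bool


def select_final_subset(
    evaluations: Sequence[SubsetEvaluation],
    parent_evaluations: Sequence[SubsetEvaluation],
    *,
    data: ResponseMatrix | None = None,
    case_flag: str | None = None,
    rule: str = "best",
) -> SubsetSelection:
    """Select the final item set from adolescent-report, verify on parent-report.

    The adolescent-report winner is chosen by ``rule`` ("best": best tier,
    then highest sensitivity+specificity, then fewest items; "smallest":
    fewest items meeting criteria).  The same items are then evaluated on
    parent-report (recomputed when ``data`` is given, otherwise looked up in
    ``parent_evaluations``); the parent-optimal subset is selected by the
    same rule, and the shared set is flagged as retained when it meets the
    criteria on parent-report too.
    """
    chosen = _pick(evaluations, rule)

    parent_same = next(
        (e for e in parent_evaluations if set(e.items) == set(chosen.items)), None)
    if parent_same is None:
        if data is None or case_flag is None:
            raise ValueError(
                "chosen items absent from parent evaluations; pass data and "
                "case_flag to evaluate them")
        parent_same = evaluate_subsets(
            data, [chosen.items], case_flag, informant="parent")[0]

    parent_optimal = _pick(parent_evaluations, rule)
    return SubsetSelection(
        adolescent=chosen,
        parent_same_items=parent_same,
        parent_optimal=parent_optimal,
        shared_set_retained=parent_same.meets_criteria,
    )
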