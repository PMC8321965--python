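"""End-to-end derivation of a brief screen from a response matrix.

Chains the reduction, subset-search and ROC stages for the anxiety and
depression pools separately, then assembles a scoreable screen definition
with informant- and gender-specific integer cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ResponseMatrix
from .reduction import item_stats_table, retain_items
from .roc import subgroup_roc
from .scoring import ScreenDefinition
from .subsets import (SelectionFailure, SubsetSelection, evaluate_subsets,
                      greedy_subset_sequence, select_final_subset)

__all__ = ["ScaleDerivation", "DerivationResult", "derive_screen", "derived_cutoff_table"]


@dataclass
class ScaleDerivation:
    case_flag: str
    stats: Mapping[str, pd.DataFrame]          # informant -> ItemStatsTable
    eligible: Mapping[str, set[str]]           # informant -> retained pool
    evaluations: Mapping[str, list]            # informant -> SubsetEvaluations
    selection: SubsetSelection | None
    failure: str | None = None

    @property
    def items(self) -> tuple[str, ...]:
        if self.selection is None:
            raise SelectionFailure(self.failure or "selection failed")
        return self.selection.adolescent.items


@dataclass
class DerivationResult:
    anxiety: ScaleDerivation
    depression: ScaleDerivation

    @property
    def screen_items(self) -> dict[str, tuple[str, ...]]:
        return {"anxiety": self.anxiety.items, "depression": self.depression.items}


def _derive_scale(
    data: ResponseMatrix,
    pool: Sequence[str],
    total_items: Sequence[str],
    case_flag: str,
    exclusions: Sequence[tuple[str, str]],
    rule: str,
) -> ScaleDerivation:
    stats = {}
    eligible = {}
    evaluations = {}
    for informant in ("adolescent", "parent"):
        stats[informant] = item_stats_table(
            data, pool, total_items, case_flag, informant=informant)
        eligible[informant] = retain_items(stats[informant])

    for informant in ("adolescent", "parent"):
        elig = eligible[informant]
        if len(elig) < 2:
            return ScaleDerivation(
                case_flag=case_flag, stats=stats, eligible=eligible,
                evaluations={}, selection=None,
                failure=f"fewer than 2 eligible {informant}-report items")
        seq = greedy_subset_sequence(sorted(elig), stats[informant], exclusions)
        evaluations[informant] = evaluate_subsets(
            data, seq, case_flag, informant=informant)

    try:
        selection = select_final_subset(
            evaluations["adolescent"], evaluations["parent"],
            data=data, case_flag=case_flag, rule=rule)
        failure = None
    except SelectionFailure as exc:
        selection, failure = None, str(exc)
    return ScaleDerivation(
        case_flag=case_flag, stats=stats, eligible=eligible,
        evaluations=evaluations, selection=selection, failure=failure)


def derive_screen(
    data: ResponseMatrix,
    *,
    exclusions: Sequence[tuple[str, str]] = (),
    rule: str = "best",
) -> DerivationResult:
    """Run the two-pool derivation on a cohort.

    Anxiety candidates are the 31 non-OCD RCADS anxiety items (item-total
    correlations against the conventional 37-item anxiety total), compared
    between community and the clinic anxiety subsample; depression
    candidates are the 10 RCADS depression items against the 10-item total
    and the clinic depression subsample.  ``exclusions`` lists
    content-overlapping item pairs supplied by the user.
    """
    bank = data.bank
    anxiety = _derive_scale(
        data,
        pool=bank.rcads_anxiety_items(include_ocd=False),
        total_items=bank.rcads_anxiety_items(include_ocd=True),
        case_flag="anxiety",
        exclusions=exclusions,
        rule=rule,
    )
    depression = _derive_scale(
        data,
        pool=bank.rcads_depression_items(),
        total_items=bank.rcads_depression_items(),
        case_flag="depression",
        exclusions=exclusions,
        rule=rule,
    )
    return DerivationResult(anxiety=anxiety, depression=depression)


def _integer_threshold(cutoff: float) -> int:
    """Integer >=-rule threshold equivalent to a midpoint 'score > c' cut-off."""
    return int(np.floor(cutoff)) + 1


def derived_cutoff_table(
    data: ResponseMatrix,
    anxiety_items: Sequence[str],
    depression_items: Sequence[str],
    impact_items: Sequence[str] = (),
) -> ScreenDefinition:
    """Assemble a scoreable screen with gender-specific derived cut-offs.

    For each (informant, gender, scale) cell the tiered cut-off is selected
    within the gender stratum; anxiety and depression scales are judged
    against their own diagnostic flags, total and total-plus-impact scales
    against any anxiety/depressive diagnosis.
    """
    scales: dict[str, tuple[Sequence[str], str]] = {
        "anxiety": (list(anxiety_items), "anxiety"),
        "depression": (list(depression_items), "depression"),
        "total": (list(anxiety_items) + list(depression_items), "any"),
    }
    if impact_items:
        scales["total_plus_impact"] = (
            list(anxiety_items) + list(depression_items) + list(impact_items), "any")

    cutoffs: dict[tuple[str, str, str], int] = {}
    for informant in ("adolescent", "parent"):
        for scale_name, (items, flag) in scales.items():
            per_gender = subgroup_roc(
                data, items, flag, informant=informant, strata=("female", "male"))
            for gender, res in per_gender.items():
                cutoffs[(informant, gender, scale_name)] = \
                    _integer_threshold(res["cutoff"].cutoff)
    return ScreenDefinition(
        name="derived",
        anxiety_items=tuple(anxiety_items),
        depression_items=tuple(depression_items),
        impact_items=tuple(impact_items),
        cutoffs=cutoffs,
    )
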