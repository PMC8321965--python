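"""Empirical ROC machinery with sensitivity-prioritised cut-off selection.

Positivity rule: a respondent screens positive when their score exceeds the
cut-off (score > threshold).  Thresholds are midpoints between consecutive
distinct observed scores plus the two extremes, so on integer sum scores the
selected cut-offs are half-integers and "score > k - 0.5" equals the integer
rule "score >= k".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ResponseMatrix, _flag_column

__all__ = [
    "RocResult",
    "CutoffResult",
    "roc_curve",
    "select_cutoff_tiered",
    "subgroup_roc",
    "required_n_per_group",
    "TIERS",
    "STRATA",
]

# sensitivity-prioritised tier ladder: (min sensitivity, min specificity),
# both strict inequalities
TIERS: list[tuple[str, float, float]] = [
    ("T1", 0.8, 0.7),
    ("T2", 0.7, 0.7),
    ("T3", 0.7, 0.6),
]

TIER_ORDER = {"T1": 0, "T2": 1, "T3": 2, "NONE": 3}

STRATA = ["overall", "female", "male", "younger", "older"]


class GroupingError(ValueError):
    pass


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivity_at: np.ndarray
    specificity_at: np.ndarray
    auc: float
    n_cases: int
    n_controls: int


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    tier: str


def roc_curve(case_scores: Sequence[float], control_scores: Sequence[float]) -> RocResult:
    """Empirical ROC for higher-score-is-more-pathological data.

    AUC is the Mann-Whitney probability that a random case outscores a
    random control, ties counted half; it equals the trapezoidal area under
    the empirical curve.
    """
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    cases = cases[~np.isnan(cases)]
    controls = controls[~np.isnan(controls)]
    if len(cases) == 0 or len(controls) == 0:
        raise GroupingError("roc_curve needs at least one case and one control score")

    pooled = np.concatenate([cases, controls])
    if np.ptp(pooled) == 0:
        warnings.warn("all scores identical across both groups; AUC = 0.5")

    # Mann-Whitney AUC via midranks (ties counted half)
    ranks = stats.rankdata(pooled)
    n1, n0 = len(cases), len(controls)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n0))

    uniq = np.unique(pooled)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[uniq[0] - 0.5], mids, [uniq[-1] + 0.5]])
    sens = (cases[None, :] > thresholds[:, None]).mean(axis=1)
    spec = (controls[None, :] <= thresholds[:, None]).mean(axis=1)
    return RocResult(
        thresholds=thresholds,
        sensitivity_at=sens,
        specificity_at=spec,
        auc=auc,
        n_cases=n1,
        n_controls=n0,
    )


def select_cutoff_tiered(roc: RocResult) -> CutoffResult:
    """Sensitivity-prioritised cut-off selection.

    Walk the tier ladder (sens > 0.8 & spec > 0.7, then > 0.7/0.7, then
    > 0.7/0.6); within the first non-empty tier pick the threshold
    maximising sensitivity + specificity, ties resolved toward the lower
    cut-off.  If no tier is attainable, return the global Youden optimum
    with tier NONE.
    """
    sens, spec, thr = roc.sensitivity_at, roc.specificity_at, roc.thresholds

    def best(mask: np.ndarray) -> CutoffResult | None:
        if not mask.any():
            return None
        idx = np.flatnonzero(mask)
        j = sens[idx] + spec[idx]
        # stable argmax then lowest threshold among ties
        top = idx[j == j.max()]
        k = top[np.argmin(thr[top])]
        return CutoffResult(float(thr[k]), float(sens[k]), float(spec[k]), "")

    for tier, s_min, p_min in TIERS:
        hit = best((sens > s_min) & (spec > p_min))
        if hit is not None:
            return CutoffResult(hit.cutoff, hit.sensitivity, hit.specificity, tier)
    fallback = best(np.ones_like(sens, dtype=bool))
    assert fallback is not None
    return CutoffResult(fallback.cutoff, fallback.sensitivity, fallback.specificity, "NONE")


def _stratum_mask(frame: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "overall":
        return pd.Series(True, index=frame.index)
    if stratum in ("female", "male"):
        return frame["gender"] == stratum
    if stratum in ("younger", "older"):
        return frame["age_group"] == stratum
    raise ValueError(f"unknown stratum {stratum!r}")


def subgroup_roc(
    data: ResponseMatrix,
    score_items: Sequence[str],
    case_flag: str,
    *,
    informant: str = "adolescent",
    strata: Sequence[str] = tuple(STRATA),
    min_group_n: int = 30,
) -> dict[str, dict]:
    """Per-stratum ROC and tiered cut-off for a sum score.

    Scores are sums over ``score_items``; persons missing any constituent
    item are dropped.  Empty strata are skipped with a warning, strata below
    ``min_group_n`` per group get a small-sample warning flag.
    """
    frame, cases = data.pooled_frame(case_flag, informant)
    scores = data.sum_score(score_items, frame)
    out: dict[str, dict] = {}
    for stratum in strata:
        mask = _stratum_mask(frame, stratum) & scores.notna()
        cs = scores[mask & (cases == 1)].to_numpy(float)
        ct = scores[mask & (cases == 0)].to_numpy(float)
        if len(cs) == 0 or len(ct) == 0:
            warnings.warn(f"stratum {stratum!r} skipped: empty case or control group")
            continue
        roc = roc_curve(cs, ct)
        cut = select_cutoff_tiered(roc)
        out[stratum] = {
            "roc": roc,
            "cutoff": cut,
            "n_pos": len(cs),
            "n_neg": len(ct),
            "underpowered": min(len(cs), len(ct)) < min_group_n,
        }
    return out


def _binormal_auc_variance(auc: float, n_per_group: float, kappa: float = 1.0) -> float:
    """Obuchowski's binormal variance approximation for an estimated AUC.

    ``kappa`` is the control/case size ratio; the binormal separation is
    a = sqrt(2) * Phi^-1(AUC) (unit variance ratio).
    """
    a = np.sqrt(2.0) * stats.norm.ppf(auc)
    v = 0.0099 * np.exp(-(a**2) / 2.0) * ((5.0 * a**2 + 8.0) + (a**2 + 8.0) / kappa)
    return float(v / n_per_group)


def required_n_per_group(
    auc_alt: float,
    power: float = 0.8,
    alpha: float = 0.05,
    two_sided: bool = True,
    *,
    rounding: str = "nearest",
) -> int:
    """A-priori per-group sample size for testing H0: AUC = 0.5.

    Solves the binormal power equation with Obuchowski's variance
    approximation and equal case/control groups:

        n = (z_{1-alpha[/2]} sqrt(V0) + z_{1-beta} sqrt(Va))^2 / (AUC - 0.5)^2

    with V0 the null (AUC = 0.5) and Va the alternative variance for one
    observation per group.  The continuous solution is reported to the
    nearest whole participant, matching how the requirement is
    conventionally printed (``rounding="ceil"`` gives the strict smallest
    integer n whose power reaches the target).
    """
    if not 0.5 < auc_alt < 1.0:
        raise ValueError(f"auc_alt must lie in (0.5, 1), got {auc_alt}")
    if not 0.0 < power < 1.0:
        raise ValueError(f"power must lie in (0, 1), got {power}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0) if two_sided else stats.norm.ppf(1.0 - alpha)
    z_b = stats.norm.ppf(power)
    v0 = _binormal_auc_variance(0.5, 1.0)
    va = _binormal_auc_variance(auc_alt, 1.0)
    n = ((z_a * np.sqrt(v0) + z_b * np.sqrt(va)) / (auc_alt - 0.5)) ** 2
    if rounding == "nearest":
        return int(np.rint(n))
    if rounding == "ceil":
        return int(np.ceil(n))
    if rounding == "none":
        return n  # type: ignore[return-value]
    raise ValueError(f"unknown rounding {rounding!r}")
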