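"""Add-on item evaluation and informant combination via nested logistic models.

Suicidal-ideation, symptom-impact and duration items are screened with the
same discrimination/missingness rule as the symptom items, then tested for
incremental validity by likelihood-ratio tests between nested logistic
regressions (case membership on sum scores).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import ResponseMatrix
from .reduction import missing_fraction, point_biserial_discrimination

__all__ = [
    "LogisticFit",
    "NestedTestResult",
    "SeparationError",
    "rescale_linear",
    "screen_addon_items",
    "fit_logistic",
    "nested_lr_test",
    "combine_informants",
]

ALPHA = 0.01  # conservative significance level used throughout


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation; the MLE does not exist."""


class GroupingError(ValueError):
    pass


def rescale_linear(
    score: float,
    from_range: tuple[float, float],
    to_range: tuple[float, float] = (0.0, 3.0),
) -> float:
    """Affine rescaling of an ordinal score between response ranges.

    The 0-2 MFQ scale maps onto the 0-3 RCADS scale as {0, 1.5, 3}.
    """
    lo, hi = from_range
    if hi <= lo:
        raise ValueError("from_range must be increasing")
    if not lo <= score <= hi:
        raise ValueError(f"score {score} outside range [{lo}, {hi}]")
    to_lo, to_hi = to_range
    return to_lo + (score - lo) * (to_hi - to_lo) / (hi - lo)


def screen_addon_items(
    data: ResponseMatrix,
    addon_pool: Sequence[str],
    case_flag: str,
    *,
    informant: str = "adolescent",
    discrimination_threshold: float = 0.30,
    missing_threshold: float = 0.10,
) -> pd.DataFrame:
    """Rank candidate add-on items by discrimination against the case flag.

    Items scored on a shorter raw range (e.g. 0-2 suicidal-ideation items)
    are linearly rescaled to 0-3 before the discrimination index is
    computed.  Returns all items with an ``eligible`` flag (> threshold
    discrimination and < threshold missingness), strongest first — which is
    also the greedy one-by-one removal order for candidate combinations.
    """
    work = data
    rescale = [i for i in addon_pool
               if (data.bank.get(i).min_score, data.bank.get(i).max_score) != (0, 3)]
    if rescale:
        df = data.data.copy()
        for item_id in rescale:
            it = data.bank.get(item_id)
            df[item_id] = df[item_id].map(
                lambda v: np.nan if pd.isna(v)
                else rescale_linear(v, (it.min_score, it.max_score)))
        work = ResponseMatrix(data=df, bank=data.bank)

    rows = []
    for item in addon_pool:
        rpb = point_biserial_discrimination(work, item, case_flag, informant=informant)
        miss = missing_fraction(work, item, case_flag=case_flag, informant=informant)
        rows.append({
            "item_id": item,
            "discrimination_rpb": rpb,
            "missing_fraction": miss,
            "eligible": rpb > discrimination_threshold and miss < missing_threshold,
        })
    out = pd.DataFrame(rows).sort_values(
        "discrimination_rpb", ascending=False, kind="mergesort").reset_index(drop=True)
    return out


@dataclass(frozen=True)
class LogisticFit:
    predictors: tuple[str, ...]
    coefficients: Mapping[str, float]  # log-odds per unit, incl. intercept
    odds_ratios: Mapping[str, float]
    deviance: float                    # -2 log-likelihood
    n_used: int
    converged: bool


@dataclass(frozen=True)
class NestedTestResult:
    chi_square: float
    df: int
    p_value: float
    significant: bool


def fit_logistic(outcome: Sequence[int], predictors: Mapping[str, Sequence[float]]
                 ) -> LogisticFit:
    """Unpenalised logistic regression of a 0/1 outcome on named predictors.

    Persons missing any involved variable are dropped listwise.  Complete
    separation (a diverging coefficient) raises ``SeparationError`` rather
    than returning a silent result.
    """
    if not predictors:
        raise ValueError("at least one predictor required")
    df = pd.DataFrame(dict(predictors))
    df["_y"] = np.asarray(outcome, dtype=float)
    df = df.dropna()
    y = df.pop("_y").to_numpy()
    if len(np.unique(y)) < 2:
        raise GroupingError("outcome has a single class after listwise deletion")
    names = tuple(df.columns)
    x = sm.add_constant(df.to_numpy(float), has_constant="add")
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("error", PerfectSeparationWarning)
            try:
                res = sm.Logit(y, x).fit(disp=0, maxiter=100, tol=1e-10)
            except np.linalg.LinAlgError:
                # singular design (constant or collinear predictors): the
                # deviance is still well defined along the flat direction, so
                # fall back to a gradient method instead of failing
                res = sm.Logit(y, x).fit(method="bfgs", disp=0, maxiter=500,
                                         gtol=1e-10)
    except (PerfectSeparationWarning, Exception) as exc:
        if isinstance(exc, PerfectSeparationWarning) or "eparation" in str(exc):
            raise SeparationError(f"complete separation: {exc}") from exc
        raise
    params = np.asarray(res.params, dtype=float)
    converged = bool(res.mle_retvals.get("converged", False))
    if np.any(np.abs(params[1:]) > 15.0) and not converged:
        raise SeparationError("coefficient diverging (|beta| > 15) without convergence")
    coef = {"intercept": float(params[0])}
    coef.update({name: float(b) for name, b in zip(names, params[1:])})
    ors = {k: float(np.exp(v)) for k, v in coef.items() if k != "intercept"}
    return LogisticFit(
        predictors=names,
        coefficients=coef,
        odds_ratios=ors,
        deviance=float(-2.0 * res.llf),
        n_used=int(len(y)),
        converged=converged,
    )


def nested_lr_test(reduced: LogisticFit, full: LogisticFit,
                   alpha: float = ALPHA) -> NestedTestResult:
    """Likelihood-ratio test between nested logistic fits on the same persons."""
    if not set(reduced.predictors) < set(full.predictors):
        raise ValueError("models are not nested (reduced predictors must be a "
                         "strict subset of the full model's)")
    if reduced.n_used != full.n_used:
        raise ValueError(
            f"fits used different persons ({reduced.n_used} vs {full.n_used}); "
            "fix the complete-case set before fitting")
    chi2 = reduced.deviance - full.deviance
    if chi2 < 0 and chi2 > -1e-8:
        chi2 = 0.0
    df = len(full.predictors) - len(reduced.predictors)
    p = float(stats.chi2.sf(chi2, df)) if chi2 >= 0 else float("nan")
    return NestedTestResult(chi_square=float(chi2), df=df, p_value=p,
                            significant=bool(p < alpha))


def incremental_test(
    data: ResponseMatrix,
    base_items: Sequence[str],
    addon_items: Sequence[str],
    case_flag: str,
    *,
    informant: str = "adolescent",
    addons_as_separate_predictors: bool = True,
) -> tuple[LogisticFit, LogisticFit, NestedTestResult]:
    """Does adding items improve prediction of case membership?

    Model 1: case ~ base sum score.  Model 2 adds each add-on item as its
    own predictor (or their sum when ``addons_as_separate_predictors`` is
    False).  The complete-case set is fixed across both fits so the
    likelihood-ratio test is valid.
    """
    frame, cases = data.pooled_frame(case_flag, informant)
    base = data.sum_score(base_items, frame)
    cols = {"base_score": base}
    if addons_as_separate_predictors:
        for item in addon_items:
            cols[item] = frame[item]
    else:
        cols["addon_score"] = data.sum_score(addon_items, frame)
    work = pd.DataFrame(cols)
    keep = work.notna().all(axis=1)
    outcome = cases[keep].to_numpy()
    work = work[keep]
    reduced = fit_logistic(outcome, {"base_score": work["base_score"]})
    full = fit_logistic(outcome, {c: work[c] for c in work.columns})
    return reduced, full, nested_lr_test(reduced, full)


def combine_informants(
    data: ResponseMatrix,
    score_items: Sequence[str],
    case_flag: str,
) -> tuple[LogisticFit, LogisticFit, NestedTestResult]:
    """Adolescent-report alone vs adolescent + parent report of the same score.

    Dyads missing either informant's complete sum score are dropped; the
    outcome is the diagnosis flag.  Model 1: adolescent sum score; model 2
    adds the parent sum score; per-unit odds ratios are reported for both.
    """
    adol_frame, adol_cases = data.pooled_frame(case_flag, "adolescent")
    par_frame, _ = data.pooled_frame(case_flag, "parent")
    adol = pd.DataFrame({
        "dyad_id": adol_frame["dyad_id"],
        "adolescent_score": data.sum_score(score_items, adol_frame),
        "case": adol_cases.to_numpy(),
    })
    par = pd.DataFrame({
        "dyad_id": par_frame["dyad_id"],
        "parent_score": data.sum_score(score_items, par_frame),
    })
    merged = adol.merge(par, on="dyad_id", how="inner").dropna()
    if merged.empty:
        raise GroupingError("no dyads with both informants' complete scores")
    outcome = merged["case"].to_numpy()
    reduced = fit_logistic(outcome, {"adolescent_score": merged["adolescent_score"]})
    full = fit_logistic(outcome, {
        "adolescent_score": merged["adolescent_score"],
        "parent_score": merged["parent_score"],
    })
    return reduced, full, nested_lr_test(reduced, full)
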