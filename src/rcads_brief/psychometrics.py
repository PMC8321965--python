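"""Reliability and validity evaluation of scale definitions.

McDonald's omega from a one-factor model fitted to the item covariance
matrix by minimum-residual (minres) least squares, with a seeded
nonparametric person-bootstrap percentile confidence interval; convergent
and divergent Pearson validity against the MFQ total; criterion-validity
ROC grids across scale definitions; and completer vs partial-completer
comparability checks for the missing-data assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import ResponseMatrix
from .reduction import correlation_p_value
from .roc import STRATA, subgroup_roc

__all__ = [
    "ScaleDefinition",
    "ReliabilityResult",
    "ReliabilityError",
    "mcdonald_omega",
    "omega_from_covariance",
    "convergent_divergent",
    "compare_scales_criterion",
    "missingness_comparability",
]

ALPHA = 0.01


class ReliabilityError(RuntimeError):
    """The one-factor model could not be fit (non-convergence or Heywood case)."""


@dataclass(frozen=True)
class ScaleDefinition:
    name: str
    item_ids: tuple[str, ...]
    informant: str = "adolescent"

    def __post_init__(self) -> None:
        if not self.item_ids:
            raise ValueError(f"scale {self.name!r} has no items")


@dataclass(frozen=True)
class ReliabilityResult:
    omega: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_persons: int
    sample_label: str
    loadings: tuple[float, ...]


def _minres_loadings(cov: np.ndarray) -> np.ndarray:
    """One-factor loadings minimising off-diagonal squared residuals.

    The matrix is normalised to unit average variance before optimisation
    (and the loadings rescaled back) so convergence tolerances are
    scale-free and omega is exactly scale-invariant.
    """
    scale = float(np.mean(np.diag(cov)))
    if scale <= 0:
        raise ReliabilityError("covariance matrix has non-positive variances")
    cov = cov / scale
    p = cov.shape[0]
    # principal-axis start from the largest eigenpair
    w, v = np.linalg.eigh(cov)
    lam0 = v[:, -1] * np.sqrt(max(w[-1], 1e-12))
    if lam0.sum() < 0:
        lam0 = -lam0
    off = ~np.eye(p, dtype=bool)

    def objective(lam: np.ndarray) -> float:
        resid = cov - np.outer(lam, lam)
        return float((resid[off] ** 2).sum())

    def grad(lam: np.ndarray) -> np.ndarray:
        resid = cov - np.outer(lam, lam)
        resid[np.diag_indices(p)] = 0.0
        return -4.0 * resid @ lam

    # communality bounds with a small uniqueness floor keep the
    # off-diagonal-only objective identified for near-diagonal matrices
    cap = np.sqrt(np.diag(cov) * 0.999)
    lam0 = np.clip(lam0, -cap, cap)
    res = optimize.minimize(objective, lam0, jac=grad, method="L-BFGS-B",
                            bounds=list(zip(-cap, cap)),
                            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10})
    if not res.success and res.status != 1:  # status 1 = maxiter
        raise ReliabilityError(f"minres factor fit did not converge: {res.message}")
    lam = res.x
    if lam.sum() < 0:
        lam = -lam
    return lam * np.sqrt(scale)


def omega_from_covariance(cov: np.ndarray) -> tuple[float, np.ndarray]:
    """McDonald's omega (sum lambda)^2 / ((sum lambda)^2 + sum theta).

    A Heywood case — the one-factor model demanding more common variance
    than an item has — shows up as a loading pinned at its communality bound
    together with gross off-diagonal misfit, and is raised as an error.
    """
    cov = np.asarray(cov, dtype=float)
    lam = _minres_loadings(cov)
    diag = np.diag(cov)
    pinned = lam**2 >= 0.99 * diag
    resid = cov - np.outer(lam, lam)
    resid[np.diag_indices(len(lam))] = 0.0
    if pinned.any() and np.abs(resid).max() > 0.1 * diag.max():
        bad = int(np.argmax(pinned))
        raise ReliabilityError(
            f"Heywood case: item index {bad} needs communality above its "
            f"variance (max residual {np.abs(resid).max():.3g})")
    theta = np.clip(diag - lam**2, 0.0, None)
    s = lam.sum()
    omega = s**2 / (s**2 + theta.sum())
    return float(omega), lam


def mcdonald_omega(
    data: ResponseMatrix,
    scale: ScaleDefinition,
    *,
    sample: str = "all",
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    min_persons: int | None = None,
) -> ReliabilityResult:
    """Omega reliability for a scale on complete-case persons.

    ``sample`` restricts the frame: "all", "community", "clinic",
    "clinic_anxiety" or "clinic_depression".  The confidence interval is a
    seeded nonparametric person-bootstrap percentile interval; resamples
    where the factor fit fails are discarded with a warning.  The default
    complete-case requirement (three persons per item) can be relaxed via
    ``min_persons`` for long scales in small subsamples, at the price of a
    noisier factor solution.
    """
    items = list(scale.item_ids)
    if len(items) < 3:
        raise ValueError("omega needs at least 3 items")
    frame = data.informant_frame(scale.informant)
    frame = _sample_frame(frame, sample)
    x = frame[items].dropna().to_numpy(float)
    required = 3 * len(items) if min_persons is None else max(min_persons, 10)
    if len(x) < required:
        raise ValueError(
            f"too few complete cases ({len(x)}) for a {len(items)}-item scale")
    omega, lam = omega_from_covariance(np.cov(x, rowvar=False))

    rng = np.random.default_rng(seed)
    boots = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(x), size=len(x))
        try:
            w, _ = omega_from_covariance(np.cov(x[idx], rowvar=False))
            boots.append(w)
        except ReliabilityError:
            failures += 1
    if failures:
        warnings.warn(f"{failures}/{n_boot} bootstrap resamples failed the factor fit")
    if boots:
        lo, hi = np.percentile(boots, [(1 - ci_level) / 2 * 100,
                                       (1 + ci_level) / 2 * 100])
    else:
        lo = hi = float("nan")
    return ReliabilityResult(
        omega=omega, ci_low=float(lo), ci_high=float(hi),
        n_boot=len(boots), n_persons=len(x), sample_label=sample,
        loadings=tuple(float(v) for v in lam),
    )


def _sample_frame(frame: pd.DataFrame, sample: str) -> pd.DataFrame:
    if sample == "all":
        return frame
    if sample == "community":
        return frame[frame["group"] == "community"]
    if sample == "clinic":
        return frame[frame["group"] == "clinic"]
    if sample == "clinic_anxiety":
        return frame[(frame["group"] == "clinic") & frame["anx_dx"]]
    if sample == "clinic_depression":
        return frame[(frame["group"] == "clinic") & frame["dep_dx"]]
    raise ValueError(f"unknown sample {sample!r}")


_VALIDITY_SAMPLES = ["community", "clinic", "clinic_anxiety", "clinic_depression"]


def convergent_divergent(
    data: ResponseMatrix,
    scales: Sequence[ScaleDefinition],
    criterion_items: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pearson validity of each scale score against the MFQ total.

    The criterion total is the sum of raw (0-2) MFQ responses; persons are
    pairwise-complete per (scale, sample) cell.  Correlations of depression
    scales with the MFQ read as convergent validity, of anxiety scales as
    divergent validity.
    """
    criterion_items = list(criterion_items) if criterion_items is not None \
        else data.bank.mfq_items()
    rows = []
    for scale in scales:
        frame = data.informant_frame(scale.informant)
        score = data.sum_score(scale.item_ids, frame)
        criterion = data.sum_score(criterion_items, frame)
        for sample in _VALIDITY_SAMPLES:
            sub = _sample_frame(frame, sample)
            s = score[sub.index]
            c = criterion[sub.index]
            ok = s.notna() & c.notna()
            n = int(ok.sum())
            if n < 3 or s[ok].std() == 0 or c[ok].std() == 0:
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(s[ok], c[ok])
            rows.append({
                "scale": scale.name, "informant": scale.informant,
                "sample": sample, "r": float(r), "p": float(p), "n": n,
                "significant": bool(p < ALPHA) if np.isfinite(p) else False,
            })
    return pd.DataFrame(rows)


def compare_scales_criterion(
    data: ResponseMatrix,
    scales: Sequence[ScaleDefinition],
    case_flag: str,
) -> pd.DataFrame:
    """Criterion-validity grid: per scale and stratum, AUC and tiered cut-off."""
    rows = []
    for scale in scales:
        result = subgroup_roc(data, list(scale.item_ids), case_flag,
                              informant=scale.informant)
        for stratum in STRATA:
            if stratum not in result:
                continue
            r = result[stratum]
            rows.append({
                "scale": scale.name, "informant": scale.informant,
                "stratum": stratum, "n_items": len(scale.item_ids),
                "n_pos": r["n_pos"], "n_neg": r["n_neg"],
                "auc": r["roc"].auc, "cutoff": r["cutoff"].cutoff,
                "sensitivity": r["cutoff"].sensitivity,
                "specificity": r["cutoff"].specificity,
                "tier": r["cutoff"].tier,
            })
    return pd.DataFrame(rows)


def missingness_comparability(
    data: ResponseMatrix,
    complete_flag: pd.Series | None = None,
    *,
    informant: str = "adolescent",
    scales: Mapping[str, Sequence[str]] | None = None,
    alpha: float = ALPHA,
) -> dict:
    """Compare full completers against partial completers.

    For each scale: pooled-variance independent-samples t-test of the mean
    score (computed on the items each person answered).  Additionally the
    anxiety-depression inter-scale correlation is compared between the two
    completion groups (Fisher z).  The data are flagged MCAR-consistent when
    no comparison is significant at ``alpha``.
    """
    frame = data.informant_frame(informant)
    if scales is None:
        scales = {
            "anxiety": data.bank.rcads_anxiety_items(),
            "depression": data.bank.rcads_depression_items(),
        }
    if complete_flag is None:
        complete_flag = frame[data.item_columns].notna().all(axis=1)
    complete_flag = complete_flag.reindex(frame.index).astype(bool)
    if complete_flag.all() or (~complete_flag).all():
        raise ValueError("both completion groups must be non-empty")

    tests = []
    means = {}
    for name, items in scales.items():
        # person mean over answered items, so partial completers contribute
        score = frame[list(items)].mean(axis=1)
        a = score[complete_flag].dropna()
        b = score[~complete_flag].dropna()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"completion group too small for scale {name!r}")
        t, p = stats.ttest_ind(a, b, equal_var=True)
        tests.append({
            "comparison": f"mean_{name}", "statistic": float(t),
            "df": len(a) + len(b) - 2, "p": float(p),
            "significant": bool(p < alpha),
        })
        means[name] = score

    names = list(scales)
    if len(names) >= 2:
        x, y = means[names[0]], means[names[1]]
        rs = {}
        for label, mask in (("complete", complete_flag), ("partial", ~complete_flag)):
            ok = mask & x.notna() & y.notna()
            rs[label] = float(np.corrcoef(x[ok], y[ok])[0, 1])
            tests.append({
                "comparison": f"r_{names[0]}_{names[1]}_{label}",
                "statistic": rs[label], "df": int(ok.sum()) - 2,
                "p": correlation_p_value(rs[label], int(ok.sum())),
                "significant": False,  # existence of correlation is not an MCAR test
            })
        n1 = int((complete_flag & x.notna() & y.notna()).sum())
        n2 = int((~complete_flag & x.notna() & y.notna()).sum())
        z1, z2 = np.arctanh(rs["complete"]), np.arctanh(rs["partial"])
        z = (z1 - z2) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
        p = float(2 * stats.norm.sf(abs(z)))
        tests.append({
            "comparison": f"r_diff_{names[0]}_{names[1]}", "statistic": float(z),
            "df": n1 + n2 - 6, "p": p, "significant": bool(p < alpha),
        })

    table = pd.DataFrame(tests)
    return {
        "tests": table,
        "mcar_consistent": bool(not table["significant"].any()),
    }
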