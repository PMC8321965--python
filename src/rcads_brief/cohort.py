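"""Seeded synthetic community and clinic-referred cohorts.

The generator emulates a two-sample screening-accuracy design: a community
sample and a clinic-referred sample in which every adolescent carries an
anxiety and/or depression diagnosis from a diagnostic interview.  Each
adolescent is reported on by two informants (the adolescent and a parent).

Mechanism (graded-response style): each person has latent anxiety and
depression traits, bivariate normal with correlation ``trait_correlation``.
A diagnosis shifts the corresponding trait by a standardized effect.  An
item's latent response is ``loading * trait + N(0, 1)`` and the ordinal
score is the number of item thresholds lying below it, which gives
closed-form category probabilities for test oracles.  Parent-report traits
equal ``informant_correlation * adolescent trait`` plus independent noise
rescaled back to unit variance.  Missingness is MCAR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bank import ItemBank, default_item_bank

__all__ = [
    "ConfigError",
    "SyntheticConfig",
    "ResponseMatrix",
    "default_config",
    "generate_cohort",
    "META_COLUMNS",
]

META_COLUMNS = [
    "person_id",
    "dyad_id",
    "informant",
    "group",
    "anx_dx",
    "dep_dx",
    "gender",
    "age_group",
]

COMMUNITY = "community"
CLINIC = "clinic"
ADOLESCENT = "adolescent"
PARENT = "parent"


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration; the message names the field."""


def _dimension(subscale: str) -> str:
    """Latent dimension an item loads on.

    Anxiety-disorder subscales (and OCD) load on the anxiety trait,
    depression and suicidal-ideation items on the depression trait, and
    impact/duration items on a general severity composite of the two.
    """
    if subscale in {"GAD", "PD", "SOC", "SEP", "OCD"}:
        return "anx"
    if subscale in {"MDD", "SUICIDE"}:
        return "dep"
    return "general"


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic two-sample, two-informant design."""

    n_community: int = 214
    n_clinic: int = 246
    p_clinic_anxiety: float = 0.935
    p_clinic_depression: float = 0.329
    trait_correlation: float = 0.65
    group_shift_anxiety: float = 1.4
    group_shift_depression: float = 1.8
    informant_correlation: float = 0.6
    item_loadings: Mapping[str, float] = field(default_factory=dict)
    item_thresholds: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    gender_effect: float = 0.35
    age_effect: float = 0.25
    p_female: float = 0.574
    p_older: float = 0.308
    missing_rate: float = 0.02
    seed: int = 0
    # group-specific demographic mixes (None -> use the community value)
    p_female_clinic: float | None = 0.768
    p_older_clinic: float | None = 0.52
    # extra shift of the general (impact/duration) latent in clinic members;
    # referral requires impairment, so impact items carry signal beyond the
    # symptom traits
    impact_extra_shift: float = 0.7

    def validate(self, bank: ItemBank) -> None:
        for name in ("n_community", "n_clinic"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive count")
        props = [
            "p_clinic_anxiety", "p_clinic_depression", "p_female", "p_older",
            "missing_rate",
        ]
        for name in props:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("p_female_clinic", "p_older_clinic"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("trait_correlation", "informant_correlation"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [-1, 1], got {v}")
        if self.p_clinic_anxiety == 0 and self.p_clinic_depression == 0:
            raise ConfigError(
                "p_clinic_anxiety/p_clinic_depression cannot both be zero: "
                "every clinic member needs at least one diagnosis"
            )
        for item_id, lam in self.item_loadings.items():
            if item_id not in bank:
                raise ConfigError(f"item_loadings references unknown item {item_id}")
            if lam < 0:
                raise ConfigError(f"item_loadings[{item_id}] must be >= 0, got {lam}")
        for item_id, taus in self.item_thresholds.items():
            if item_id not in bank:
                raise ConfigError(f"item_thresholds references unknown item {item_id}")
            taus = tuple(taus)
            item = bank.get(item_id)
            if len(taus) != item.max_score - item.min_score:
                raise ConfigError(
                    f"item_thresholds[{item_id}] needs "
                    f"{item.max_score - item.min_score} cut-points, got {len(taus)}"
                )
            if any(b <= a for a, b in zip(taus, taus[1:])):
                raise ConfigError(f"item_thresholds[{item_id}] must be strictly increasing")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


@dataclass
class ResponseMatrix:
    """Person x item ordinal scores (NaN = missing) plus person metadata.

    ``data`` holds one row per person per informant; metadata columns are
    listed in :data:`META_COLUMNS` and every other column is an item.
    """

    data: pd.DataFrame
    bank: ItemBank

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"ResponseMatrix missing metadata columns: {missing}")

    @property
    def item_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    def informant_frame(self, informant: str) -> pd.DataFrame:
        if informant not in (ADOLESCENT, PARENT):
            raise ValueError(f"unknown informant {informant!r}")
        return self.data[self.data["informant"] == informant]

    def sum_score(self, items: Sequence[str], frame: pd.DataFrame | None = None) -> pd.Series:
        """Sum of item responses; NaN when any constituent item is missing."""
        frame = self.data if frame is None else frame
        items = list(items)
        sub = frame[items]
        total = sub.sum(axis=1)
        total[sub.isna().any(axis=1)] = np.nan
        return total

    def pooled_frame(self, case_flag: str, informant: str) -> tuple[pd.DataFrame, pd.Series]:
        """Community + clinic-with-flag rows for one informant.

        Clinic members lacking the flag are excluded, mirroring the pooling
        of the community sample with the relevant diagnostic subsample.
        Returns the frame and a 0/1 case indicator.
        """
        flag = _flag_column(case_flag)
        frame = self.informant_frame(informant)
        if flag == "any":
            has_flag = frame["anx_dx"] | frame["dep_dx"]
        else:
            has_flag = frame[flag]
        keep = (frame["group"] == COMMUNITY) | ((frame["group"] == CLINIC) & has_flag)
        frame = frame[keep]
        cases = ((frame["group"] == CLINIC) & has_flag[keep]).astype(int)
        return frame, cases


def _flag_column(case_flag: str) -> str:
    aliases = {
        "anxiety": "anx_dx", "anx_dx": "anx_dx", "anx": "anx_dx",
        "depression": "dep_dx", "dep_dx": "dep_dx", "dep": "dep_dx",
        "any": "any", "any_dx": "any",
    }
    if case_flag not in aliases:
        raise ValueError(f"unknown case flag {case_flag!r}")
    return aliases[case_flag]


# ---------------------------------------------------------------------------
# default calibration
# ---------------------------------------------------------------------------

# Per-item discrimination weights for the default bank.  The six anxiety and
# five depression items that form the brief screen are planted with high
# loadings; remaining items fall into weaker tiers so that per-item
# discrimination spans the range observed for full-length item pools.
_PLANTED_ANXIETY = {
    "RCADS18": 1.30, "RCADS45": 1.10, "RCADS35": 1.05,
    "RCADS34": 1.00, "RCADS24": 0.95, "RCADS20": 0.95,
}
_PLANTED_DEPRESSION = {
    "RCADS19": 1.05, "RCADS6": 1.00, "RCADS29": 1.00,
    "RCADS2": 0.95, "RCADS21": 0.95,
}
_ANXIETY_TIERS = {
    0.55: ["RCADS28", "RCADS41", "RCADS1", "RCADS3", "RCADS33"],
    0.45: ["RCADS22", "RCADS43", "RCADS14", "RCADS27", "RCADS30", "RCADS12",
           "RCADS32", "RCADS7", "RCADS39", "RCADS26", "RCADS8", "RCADS46", "RCADS5"],
    0.35: ["RCADS4", "RCADS36", "RCADS38", "RCADS37", "RCADS17"],
    0.20: ["RCADS13", "RCADS9"],
}
_DEPRESSION_TIERS = {
    0.55: ["RCADS40", "RCADS47"],
    0.48: ["RCADS25", "RCADS15"],
    0.40: ["RCADS11"],
}
_OCD_LOADING = 0.45
_MFQ_LOADING = 0.90
_IMPACT_LOADING = 0.80
_DURATION_LOADING = 0.45

# Baseline (unshifted-trait) category probabilities by instrument/subscale,
# chosen to give realistic community endorsement rates.
_BASE_PROBS: dict[str, tuple[float, ...]] = {
    "rcads_anx": (0.45, 0.30, 0.15, 0.10),
    "rcads_dep": (0.50, 0.27, 0.13, 0.10),
    "mfq": (0.60, 0.25, 0.15),
    "impact": (0.50, 0.25, 0.15, 0.10),
    "duration": (0.45, 0.20, 0.17, 0.18),
}


def _default_loading(item) -> float:
    if item.item_id in _PLANTED_ANXIETY:
        return _PLANTED_ANXIETY[item.item_id]
    if item.item_id in _PLANTED_DEPRESSION:
        return _PLANTED_DEPRESSION[item.item_id]
    for lam, ids in _ANXIETY_TIERS.items():
        if item.item_id in ids:
            return lam
    for lam, ids in _DEPRESSION_TIERS.items():
        if item.item_id in ids:
            return lam
    if item.subscale == "OCD":
        return _OCD_LOADING
    if item.instrument == "MFQ":
        return _MFQ_LOADING
    if item.instrument == "IMPACT":
        return _IMPACT_LOADING
    if item.instrument == "DURATION":
        return _DURATION_LOADING
    raise AssertionError(f"no default loading for {item.item_id}")


def _base_probs(item) -> tuple[float, ...]:
    if item.instrument == "RCADS":
        return _BASE_PROBS["rcads_dep" if item.subscale == "MDD" else "rcads_anx"]
    if item.instrument == "MFQ":
        return _BASE_PROBS["mfq"]
    if item.instrument == "IMPACT":
        return _BASE_PROBS["impact"]
    return _BASE_PROBS["duration"]


def _thresholds_from_probs(probs: Sequence[float], loading: float) -> tuple[float, ...]:
    """Cut-points placing the stated category probabilities at trait = 0."""
    cum = np.cumsum(probs)[:-1]
    scale = float(np.sqrt(loading**2 + 1.0))
    return tuple(float(stats.norm.ppf(c) * scale) for c in cum)


def default_config(bank: ItemBank | None = None, seed: int = 0) -> SyntheticConfig:
    """Default configuration: Table-1-shaped samples with planted screen items."""
    bank = bank if bank is not None else default_item_bank()
    loadings = {it.item_id: _default_loading(it) for it in bank}
    thresholds = {
        it.item_id: _thresholds_from_probs(_base_probs(it), loadings[it.item_id])
        for it in bank
    }
    return SyntheticConfig(item_loadings=loadings, item_thresholds=thresholds, seed=seed)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _diagnosis_flags(rng: np.random.Generator, n: int, p_anx: float, p_dep: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Clinic diagnosis flags with at least one true per member.

    When p_anx + p_dep >= 1 the joint distribution matching both marginals
    exactly with P(neither) = 0 is used; otherwise independent draws are
    rejection-sampled until at least one flag is true.
    """
    if p_anx + p_dep >= 1.0:
        p_both = p_anx + p_dep - 1.0
        u = rng.uniform(size=n)
        anx = u < p_anx
        dep = u >= 1.0 - p_dep
        return anx, dep
    anx = np.zeros(n, dtype=bool)
    dep = np.zeros(n, dtype=bool)
    todo = np.ones(n, dtype=bool)
    while todo.any():
        m = int(todo.sum())
        a = rng.uniform(size=m) < p_anx
        d = rng.uniform(size=m) < p_dep
        ok = a | d
        idx = np.flatnonzero(todo)[ok]
        anx[idx] = a[ok]
        dep[idx] = d[ok]
        todo[idx] = False
    return anx, dep


def generate_cohort(config: SyntheticConfig, bank: ItemBank | None = None) -> ResponseMatrix:
    """Generate a two-sample, two-informant cohort under ``config``.

    Returns adolescent- and parent-report rows for every dyad; the same
    (seed, config) pair always yields an identical cohort.
    """
    bank = bank if bank is not None else default_item_bank()
    config.validate(bank)
    rng = np.random.default_rng(config.seed)

    n_com, n_cli = config.n_community, config.n_clinic
    n = n_com + n_cli
    group = np.array([COMMUNITY] * n_com + [CLINIC] * n_cli)

    p_f_cli = config.p_female if config.p_female_clinic is None else config.p_female_clinic
    p_o_cli = config.p_older if config.p_older_clinic is None else config.p_older_clinic
    female = np.concatenate([
        rng.uniform(size=n_com) < config.p_female,
        rng.uniform(size=n_cli) < p_f_cli,
    ])
    older = np.concatenate([
        rng.uniform(size=n_com) < config.p_older,
        rng.uniform(size=n_cli) < p_o_cli,
    ])

    anx_dx = np.zeros(n, dtype=bool)
    dep_dx = np.zeros(n, dtype=bool)
    anx_dx[n_com:], dep_dx[n_com:] = _diagnosis_flags(
        rng, n_cli, config.p_clinic_anxiety, config.p_clinic_depression)

    # adolescent latent traits
    rho = config.trait_correlation
    z = rng.standard_normal((n, 2))
    anx_t = z[:, 0]
    dep_t = rho * z[:, 0] + np.sqrt(max(0.0, 1.0 - rho**2)) * z[:, 1]
    demo = config.gender_effect * female + config.age_effect * older
    anx_t = anx_t + demo + config.group_shift_anxiety * anx_dx
    dep_t = dep_t + demo + config.group_shift_depression * dep_dx

    # Parent-report traits share the systematic (diagnosis/demographic) shift
    # and attenuate only the person-specific deviation: the informant
    # correlation acts on the trait given group membership, so two informants
    # disagree about the child, not about the design.
    ir = config.informant_correlation
    resid = np.sqrt(max(0.0, 1.0 - ir**2))
    anx_dev = anx_t - (demo + config.group_shift_anxiety * anx_dx)
    dep_dev = dep_t - (demo + config.group_shift_depression * dep_dx)
    anx_p = demo + config.group_shift_anxiety * anx_dx + ir * anx_dev + resid * rng.standard_normal(n)
    dep_p = demo + config.group_shift_depression * dep_dx + ir * dep_dev + resid * rng.standard_normal(n)

    clinic_member = group == CLINIC
    g_norm = np.sqrt(2.0 + 2.0 * rho)

    traits = {
        ADOLESCENT: {
            "anx": anx_t,
            "dep": dep_t,
            "general": (anx_t + dep_t) / g_norm + config.impact_extra_shift * clinic_member,
        },
        PARENT: {
            "anx": anx_p,
            "dep": dep_p,
            "general": (anx_p + dep_p) / g_norm + config.impact_extra_shift * clinic_member,
        },
    }

    dyad_ids = np.array([f"D{i + 1:04d}" for i in range(n)])
    frames = []
    for informant in (ADOLESCENT, PARENT):
        meta = pd.DataFrame({
            "person_id": [f"{d}-{informant[0].upper()}" for d in dyad_ids],
            "dyad_id": dyad_ids,
            "informant": informant,
            "group": group,
            "anx_dx": anx_dx,
            "dep_dx": dep_dx,
            "gender": np.where(female, "female", "male"),
            "age_group": np.where(older, "older", "younger"),
        })
        scores = {}
        for item in bank:
            lam = config.item_loadings.get(item.item_id, 1.0)
            taus = np.asarray(
                config.item_thresholds.get(
                    item.item_id,
                    _thresholds_from_probs(_base_probs(item), lam),
                ),
                dtype=float,
            )
            latent = lam * traits[informant][_dimension(item.subscale)] \
                + rng.standard_normal(n)
            scores[item.item_id] = (latent[:, None] > taus[None, :]).sum(axis=1) \
                .astype(float) + item.min_score
        frames.append(pd.concat([meta, pd.DataFrame(scores)], axis=1))

    data = pd.concat(frames, ignore_index=True)

    if config.missing_rate > 0:
        item_cols = [it.item_id for it in bank]
        mask = rng.uniform(size=(len(data), len(item_cols))) < config.missing_rate
        vals = data[item_cols].to_numpy(dtype=float)
        vals[mask] = np.nan
        data[item_cols] = vals

    return ResponseMatrix(data=data, bank=bank)
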