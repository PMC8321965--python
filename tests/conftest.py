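import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rcads_brief.bank import default_item_bank
from rcads_brief.cohort import META_COLUMNS, ResponseMatrix, default_config, generate_cohort

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bank():
    return default_item_bank()


@pytest.fixture(scope="session")
def cohort(bank):
    """One default-config cohort, shared across read-only tests."""
    return generate_cohort(default_config(bank, seed=11), bank)


@pytest.fixture(scope="session")
def quiet_cohort(bank):
    """A cohort with no missing data, for tests needing complete scores."""
    from dataclasses import replace
    cfg = replace(default_config(bank, seed=7), missing_rate=0.0)
    return generate_cohort(cfg, bank)


def toy_matrix(items: dict[str, list], *, group=None, anx=None, dep=None,
               gender=None, age=None, informant="adolescent", bank=None):
    """Hand-built ResponseMatrix for oracle examples.

    ``items`` maps item column -> list of scores; metadata defaults to a
    half community / half clinic split with anxiety+depression diagnoses.
    """
    n = len(next(iter(items.values())))
    if group is None:
        group = ["community"] * (n // 2) + ["clinic"] * (n - n // 2)
    if anx is None:
        anx = [g == "clinic" for g in group]
    if dep is None:
        dep = [g == "clinic" for g in group]
    if gender is None:
        gender = ["female", "male"] * (n // 2 + 1)
    if age is None:
        age = ["younger", "older"] * (n // 2 + 1)
    df = pd.DataFrame({
        "person_id": [f"P{i}" for i in range(n)],
        "dyad_id": [f"D{i}" for i in range(n)],
        "informant": informant,
        "group": group,
        "anx_dx": anx,
        "dep_dx": dep,
        "gender": gender[:n],
        "age_group": age[:n],
        **{k: pd.array(v, dtype="float64") for k, v in items.items()},
    })
    return ResponseMatrix(data=df, bank=bank if bank is not None else default_item_bank())
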