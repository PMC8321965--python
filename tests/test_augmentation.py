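import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from rcads_brief.augmentation import (GroupingError, SeparationError,
                                      combine_informants, fit_logistic,
                                      incremental_test, nested_lr_test,
                                      rescale_linear, screen_addon_items)

from conftest import toy_matrix


def bruteforce_logistic(y, X):
    """Independent ML fit: direct minimisation of the Bernoulli deviance."""
    X1 = np.column_stack([np.ones(len(y)), X])

    def nll(beta):
        eta = X1 @ beta
        return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)

    res = optimize.minimize(nll, np.zeros(X1.shape[1]), method="BFGS",
                            options={"gtol": 1e-12, "maxiter": 500})
    return res.x, 2.0 * res.fun


class TestRescale:
    @pytest.mark.parametrize("raw,expected", [(0, 0.0), (1, 1.5), (2, 3.0)])
    def test_mfq_image(self, raw, expected):
        assert rescale_linear(raw, (0, 2)) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rescale_linear(3, (0, 2))

    @given(st.floats(0, 5), st.floats(0, 5), st.integers(1, 10))
    def test_affine_preserves_midpoints(self, a, b, hi):
        a, b = min(a, hi), min(b, hi)
        mid = rescale_linear((a + b) / 2, (0, hi))
        assert mid == pytest.approx(
            (rescale_linear(a, (0, hi)) + rescale_linear(b, (0, hi))) / 2)


class TestAddonScreening:
    def test_flag_like_item_eligible_noise_item_excluded(self, bank):
        rng = np.random.default_rng(4)
        n = 80
        group = ["community"] * 40 + ["clinic"] * 40
        flagged = [0.0] * 40 + [3.0] * 40
        noise = list(rng.integers(0, 4, n).astype(float))
        m = toy_matrix({"IMP_DISTRESS": flagged, "IMP_SCHOOL": noise},
                       group=group, bank=bank)
        out = screen_addon_items(m, ["IMP_DISTRESS", "IMP_SCHOOL"], "any")
        ranked = out.set_index("item_id")
        assert ranked.loc["IMP_DISTRESS", "discrimination_rpb"] == pytest.approx(1.0)
        assert ranked.loc["IMP_DISTRESS", "eligible"]
        assert not ranked.loc["IMP_SCHOOL", "eligible"]
        assert out.iloc[0]["item_id"] == "IMP_DISTRESS"

    def test_mfq_items_rescaled_before_screening(self, bank):
        # raw 0-2 suicidal-ideation item perfectly tracking the flag
        group = ["community"] * 10 + ["clinic"] * 10
        raw = [0.0] * 10 + [2.0] * 10
        m = toy_matrix({"MFQ19": raw}, group=group, bank=bank)
        out = screen_addon_items(m, ["MFQ19"], "depression")
        assert out.iloc[0]["discrimination_rpb"] == pytest.approx(1.0)

    def test_impact_items_eligible_on_synthetic_cohorts(self, bank):
        from rcads_brief.cohort import default_config, generate_cohort
        hits = 0
        for seed in range(20):
            m = generate_cohort(default_config(bank, seed=seed), bank)
            out = screen_addon_items(m, ["IMP_DISTRESS", "IMP_SCHOOL"], "any")
            hits += bool(out["eligible"].all())
        assert hits >= 18


class TestLogisticFit:
    def test_matches_bruteforce_on_fixed_small_dataset(self):
        y = np.array([0, 1, 0, 1, 0, 0, 1, 1], float)
        x = np.array([1.0, 2.0, 2.0, 1.0, 3.0, 4.0, 3.0, 4.0])
        fit = fit_logistic(y, {"x": x})
        beta, dev = bruteforce_logistic(y, x[:, None])
        assert fit.coefficients["intercept"] == pytest.approx(beta[0], abs=1e-6)
        assert fit.coefficients["x"] == pytest.approx(beta[1], abs=1e-6)
        assert fit.deviance == pytest.approx(dev, abs=1e-6)
        assert fit.odds_ratios["x"] == pytest.approx(np.exp(beta[1]), rel=1e-6)

    def test_balanced_outcome_constant_predictor(self):
        y = [0, 1, 0, 1, 0, 1]
        fit = fit_logistic(y, {"c": [2.0] * 6})
        # flat likelihood in the redundant direction: slope stays at zero,
        # fitted probabilities are the base rate
        assert fit.deviance == pytest.approx(
            -2 * 6 * np.log(0.5), abs=1e-6)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(GroupingError):
            fit_logistic([1, 1, 1, 1], {"x": [1.0, 2.0, 3.0, 4.0]})

    def test_complete_separation_is_an_error(self):
        y = [0, 0, 0, 0, 1, 1, 1, 1]
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        with pytest.raises(SeparationError):
            fit_logistic(y, {"x": x})

    @given(st.data())
    @settings(max_examples=25)
    def test_property_matches_bruteforce(self, data):
        n = data.draw(st.integers(8, 20))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        x = rng.normal(size=(n, 2))
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(0.3 * x[:, 0])))).astype(float)
        if y.all() or not y.any():
            return
        try:
            fit = fit_logistic(y, {"a": x[:, 0], "b": x[:, 1]})
        except SeparationError:
            return
        beta, dev = bruteforce_logistic(y, x)
        got = [fit.coefficients["intercept"], fit.coefficients["a"],
               fit.coefficients["b"]]
        assert np.allclose(got, beta, atol=1e-5)
        assert fit.deviance == pytest.approx(dev, abs=1e-5)


class TestNestedTest:
    def _fits(self, rng_seed=0, n=120):
        rng = np.random.default_rng(rng_seed)
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-x))).astype(float)
        reduced = fit_logistic(y, {"x": x})
        full = fit_logistic(y, {"x": x, "z": z})
        return reduced, full

    def test_full_equals_reduced_gives_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        y = (rng.uniform(size=60) < 0.5).astype(float)
        reduced = fit_logistic(y, {"x": x})
        full = fit_logistic(y, {"x": x, "x_copy": x})
        out = nested_lr_test(reduced, full)
        assert out.chi_square == pytest.approx(0.0, abs=1e-6)
        assert out.p_value == pytest.approx(1.0, abs=1e-4)
        assert not out.significant

    def test_deviance_monotone_and_df(self):
        reduced, full = self._fits()
        assert full.deviance <= reduced.deviance + 1e-10
        out = nested_lr_test(reduced, full)
        assert out.df == 1
        assert out.chi_square >= 0

    def test_non_nested_rejected(self):
        reduced, full = self._fits()
        with pytest.raises(ValueError, match="nested"):
            nested_lr_test(full, reduced)

    def test_mismatched_persons_rejected(self):
        r1, _ = self._fits(n=100)
        _, f2 = self._fits(n=120)
        with pytest.raises(ValueError, match="persons"):
            nested_lr_test(r1, f2)


SCREEN_11 = ["RCADS18", "RCADS45", "RCADS35", "RCADS34", "RCADS24", "RCADS20",
             "RCADS19", "RCADS6", "RCADS29", "RCADS2", "RCADS21"]


class TestIncrementalAndInformants:
    def test_impact_items_add_signal_on_default_cohort(self, quiet_cohort):
        reduced, full, test = incremental_test(
            quiet_cohort, SCREEN_11, ["IMP_DISTRESS", "IMP_SCHOOL"], "any")
        assert full.deviance <= reduced.deviance
        assert test.df == 2
        assert test.significant

    def test_parent_report_adds_signal(self, quiet_cohort):
        reduced, full, test = combine_informants(quiet_cohort, SCREEN_11, "any")
        assert set(full.odds_ratios) == {"adolescent_score", "parent_score"}
        assert test.df == 1
        assert test.significant

    def test_parent_score_duplicating_adolescent_adds_nothing(self, bank):
        """Identical informant reports give a chi-square of ~0."""
        rng = np.random.default_rng(8)
        n = 60
        score = rng.integers(0, 19, n).astype(float)
        rows = {"RCADS18": score / 6, "RCADS45": score / 6, "RCADS35": score / 6,
                "RCADS34": score / 6, "RCADS24": score / 6, "RCADS20": score / 6,
                "RCADS19": score / 6, "RCADS6": score / 6, "RCADS29": score / 6,
                "RCADS2": score / 6, "RCADS21": score / 6}
        # same rows for both informants -> parent duplicates adolescent
        import pandas as pd
        from rcads_brief.cohort import ResponseMatrix
        group = ["community"] * 30 + ["clinic"] * 30
        base = {
            "dyad_id": [f"D{i}" for i in range(n)],
            "group": group,
            "anx_dx": [g == "clinic" for g in group],
            "dep_dx": [g == "clinic" for g in group],
            "gender": ["female"] * n,
            "age_group": ["younger"] * n,
        }
        frames = []
        for informant in ("adolescent", "parent"):
            df = pd.DataFrame({
                "person_id": [f"P{i}-{informant}" for i in range(n)],
                "informant": informant, **base, **rows})
            frames.append(df)
        m = ResponseMatrix(pd.concat(frames, ignore_index=True), bank)
        _, _, test = combine_informants(m, SCREEN_11, "any")
        assert test.chi_square == pytest.approx(0.0, abs=1e-5)
        assert not test.significant
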