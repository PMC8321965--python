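import numpy as np
import pandas as pd
import pytest

from rcads_brief.cohort import ResponseMatrix
from rcads_brief.psychometrics import (ReliabilityError, ScaleDefinition,
                                       compare_scales_criterion,
                                       convergent_divergent, mcdonald_omega,
                                       missingness_comparability,
                                       omega_from_covariance)

from conftest import toy_matrix


def parallel_item_matrix(n, k, loading, seed=0, scale=1.0):
    """Continuous parallel items: loading * trait + unit noise, times scale."""
    rng = np.random.default_rng(seed)
    t = rng.standard_normal(n)
    x = loading * t[:, None] + rng.standard_normal((n, k))
    return x * scale


class TestOmega:
    def test_parallel_items_closed_form(self):
        # 5 items, loadings 0.7, residual variances 0.51:
        # omega = 3.5^2 / (3.5^2 + 2.55) = 0.8277
        rng = np.random.default_rng(2)
        t = rng.standard_normal(2000)
        x = 0.7 * t[:, None] + np.sqrt(0.51) * rng.standard_normal((2000, 5))
        omega, lam = omega_from_covariance(np.cov(x, rowvar=False))
        assert omega == pytest.approx(12.25 / 14.80, abs=0.02)
        assert np.allclose(lam, 0.7, atol=0.06)

    def test_scale_invariance(self):
        x = parallel_item_matrix(400, 4, 0.8, seed=3)
        w1, _ = omega_from_covariance(np.cov(x, rowvar=False))
        w2, _ = omega_from_covariance(np.cov(7.3 * x, rowvar=False))
        assert w2 == pytest.approx(w1, abs=1e-7)

    def test_uncorrelated_items_low_omega(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((1500, 6))
        omega, _ = omega_from_covariance(np.cov(x, rowvar=False))
        assert omega < 0.25

    def test_heywood_case_is_an_error(self):
        # implied communality of the first variable exceeds its variance
        # (r12 * r13 / r23 = 0.9 * 0.9 / 0.3 = 2.7 > 1)
        s = np.array([[1.0, 0.9, 0.9],
                      [0.9, 1.0, 0.3],
                      [0.9, 0.3, 1.0]])
        with pytest.raises(ReliabilityError, match="Heywood"):
            omega_from_covariance(s)

    def test_lengthening_increases_omega(self):
        rng = np.random.default_rng(5)
        t = rng.standard_normal(1500)
        x = 0.6 * t[:, None] + rng.standard_normal((1500, 4))
        w_short, _ = omega_from_covariance(np.cov(x, rowvar=False))
        xx = np.hstack([x, 0.6 * t[:, None] + rng.standard_normal((1500, 4))])
        w_long, _ = omega_from_covariance(np.cov(xx, rowvar=False))
        assert w_long > w_short

    def test_bootstrap_ci_brackets_estimate(self, quiet_cohort):
        scale = ScaleDefinition("dep5", ("RCADS19", "RCADS6", "RCADS29",
                                        "RCADS2", "RCADS21"))
        res = mcdonald_omega(quiet_cohort, scale, sample="community",
                             n_boot=200, seed=3)
        assert res.ci_low <= res.omega <= res.ci_high
        assert 0.5 < res.omega <= 1.0
        assert res.n_boot > 150

    def test_bootstrap_is_seeded(self, quiet_cohort):
        scale = ScaleDefinition("anx", ("RCADS18", "RCADS45", "RCADS35"))
        a = mcdonald_omega(quiet_cohort, scale, n_boot=50, seed=9)
        b = mcdonald_omega(quiet_cohort, scale, n_boot=50, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_bootstrap_coverage_of_closed_form(self):
        """95% person-bootstrap CI covers the population omega most of the time."""
        true_omega = (4 * 0.6) ** 2 / ((4 * 0.6) ** 2 + 4 * 1.0)
        covered = 0
        reps = 60
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            t = rng.standard_normal(300)
            x = 0.6 * t[:, None] + rng.standard_normal((300, 4))
            boots = []
            for b in range(120):
                idx = rng.integers(0, 300, 300)
                try:
                    w, _ = omega_from_covariance(np.cov(x[idx], rowvar=False))
                    boots.append(w)
                except ReliabilityError:
                    continue
            lo, hi = np.percentile(boots, [2.5, 97.5])
            covered += lo <= true_omega <= hi
        assert covered >= 0.85 * reps


class TestValidity:
    def test_scale_identical_to_criterion(self, bank):
        rng = np.random.default_rng(6)
        vals = rng.integers(0, 3, 40).astype(float)
        m = toy_matrix({"MFQ19": vals, "MFQ21": vals * 0 + 1,
                        "MFQ15": vals * 0, "MFQ16": vals * 0}, bank=bank)
        scale = ScaleDefinition("self", ("MFQ19", "MFQ21", "MFQ15", "MFQ16"))
        out = convergent_divergent(m, [scale])
        com = out[(out["sample"] == "community")].iloc[0]
        assert com["r"] == pytest.approx(1.0)

    def test_noise_criterion_near_zero(self, bank):
        rng = np.random.default_rng(7)
        m = toy_matrix({
            "RCADS19": rng.integers(0, 4, 400).astype(float),
            "MFQ19": rng.integers(0, 3, 400).astype(float),
            "MFQ21": rng.integers(0, 3, 400).astype(float),
            "MFQ15": rng.integers(0, 3, 400).astype(float),
            "MFQ16": rng.integers(0, 3, 400).astype(float)}, bank=bank)
        scale = ScaleDefinition("dep1", ("RCADS19",))
        out = convergent_divergent(m, [scale])
        assert abs(out[out["sample"] == "community"].iloc[0]["r"]) < 0.2

    def test_depression_scale_converges_with_mfq_on_cohort(self, bank):
        """Shared depression trait drives scale-MFQ correlation above 0.6."""
        from rcads_brief.cohort import default_config, generate_cohort
        scale = ScaleDefinition("dep5", ("RCADS19", "RCADS6", "RCADS29",
                                        "RCADS2", "RCADS21"))
        hits = 0
        for seed in range(20):
            m = generate_cohort(default_config(bank, seed=seed), bank)
            out = convergent_divergent(m, [scale])
            r = out[out["sample"] == "community"].iloc[0]["r"]
            hits += r > 0.6
        assert hits >= 18


class TestCriterionGrid:
    def test_identical_scales_identical_rows(self, quiet_cohort):
        items = ("RCADS18", "RCADS45", "RCADS35", "RCADS34", "RCADS24", "RCADS20")
        scales = [ScaleDefinition("a", items), ScaleDefinition("b", items)]
        grid = compare_scales_criterion(quiet_cohort, scales, "anxiety")
        a = grid[grid["scale"] == "a"].drop(columns="scale").reset_index(drop=True)
        b = grid[grid["scale"] == "b"].drop(columns="scale").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_grid_shape_matches_reported_layout(self, quiet_cohort):
        scales = [
            ScaleDefinition("brief_total",
                            ("RCADS18", "RCADS45", "RCADS35", "RCADS34",
                             "RCADS24", "RCADS20", "RCADS19", "RCADS6",
                             "RCADS29", "RCADS2", "RCADS21")),
            ScaleDefinition("rcads_47", tuple(quiet_cohort.bank.rcads_total_items())),
        ]
        grid = compare_scales_criterion(quiet_cohort, scales, "any")
        assert set(grid["stratum"]) == {"overall", "female", "male",
                                       "younger", "older"}
        assert len(grid) == 10
        assert (grid["auc"] <= 1).all() and (grid["auc"] >= 0).all()

    def test_noise_padding_does_not_help(self, bank):
        """Adding no-signal items to a scale cannot raise its AUC much."""
        from dataclasses import replace
        from rcads_brief.cohort import default_config, generate_cohort
        core = ("RCADS18", "RCADS45", "RCADS35", "RCADS34", "RCADS24", "RCADS20")
        pads = ("RCADS13", "RCADS9", "RCADS17")
        diffs = []
        for seed in range(10):
            cfg = default_config(bank, seed=seed)
            zeroed = {k: (0.0 if k in pads else v)
                      for k, v in cfg.item_loadings.items()}
            m = generate_cohort(replace(cfg, item_loadings=zeroed,
                                        missing_rate=0.0), bank)
            scales = [ScaleDefinition("core", core),
                      ScaleDefinition("padded", core + pads)]
            grid = compare_scales_criterion(m, scales, "anxiety")
            overall = grid[grid["stratum"] == "overall"].set_index("scale")
            diffs.append(overall.loc["padded", "auc"] - overall.loc["core", "auc"])
        assert np.mean(diffs) < 0.05


class TestMissingness:
    def test_identical_groups_not_significant(self, bank):
        rng = np.random.default_rng(9)
        n = 200
        cols = {f"RCADS{i}": rng.integers(0, 4, n).astype(float)
                for i in range(1, 48)}
        m = toy_matrix(cols, bank=bank)
        flag = pd.Series([True, False] * (n // 2),
                         index=m.informant_frame("adolescent").index)
        out = missingness_comparability(m, flag)
        t_rows = out["tests"][out["tests"]["comparison"].str.startswith("mean")]
        assert not t_rows["significant"].any()

    def test_shifted_group_detected(self, bank):
        rng = np.random.default_rng(10)
        n = 200
        base = rng.normal(1.5, 0.2, n)
        base[:100] += 1.2  # "completers" score far higher
        cols = {f"RCADS{i}": np.clip(np.round(base + rng.normal(0, 0.1, n)), 0, 3)
                for i in range(1, 48)}
        m = toy_matrix(cols, bank=bank)
        flag = pd.Series([True] * 100 + [False] * 100,
                         index=m.informant_frame("adolescent").index)
        out = missingness_comparability(m, flag)
        assert not out["mcar_consistent"]

    def test_mcar_cohorts_flagged_consistent(self, bank):
        from rcads_brief.cohort import default_config, generate_cohort
        hits = 0
        for seed in range(20):
            m = generate_cohort(default_config(bank, seed=200 + seed), bank)
            out = missingness_comparability(m)
            hits += out["mcar_consistent"]
        assert hits >= 18
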