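"""Hypothesis-testing strategies: t-tests, Dunnett, closed testing, combination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from platformsim import (
    ALL_STRATEGIES,
    closed_test,
    combination_closed,
    dunnett_p,
    fisher_combination_reject,
    fit_model,
    make_scenario,
    mean_diff_t_test,
    model_based_tests,
    run_all_strategies,
    simulate_trial,
)
from platformsim.testing import (
    DegenerateDataError,
    EmptyCellError,
    fisher_threshold,
    max_t_sf,
)


class TestMeanDiffTTest:
    def test_hand_computed_example(self, manual_dataset_factory):
        # control {0, 2}, intervention {1, 3}: diff 1, pooled s^2 = 2,
        # t = 1/sqrt(2), df = 2
        df = manual_dataset_factory({("0", 1): [0, 2], ("A", 1): [1, 3]})
        r = mean_diff_t_test(df, "A")
        assert r.estimate == pytest.approx(1.0)
        assert r.t == pytest.approx(1 / np.sqrt(2))
        assert r.df == 2
        assert r.p == pytest.approx(stats.t.sf(1 / np.sqrt(2), 2), abs=1e-12)
        # closed form for df = 2: p = 1/2 - t / (2 sqrt(2 + t^2))
        t = 1 / np.sqrt(2)
        assert r.p == pytest.approx(0.5 - t / (2 * np.sqrt(2 + t**2)), abs=1e-12)

    def test_identical_groups_give_half(self, manual_dataset_factory):
        df = manual_dataset_factory({("0", 1): [1, 2, 3], ("A", 1): [1, 2, 3]})
        r = mean_diff_t_test(df, "A")
        assert r.t == 0 and r.p == pytest.approx(0.5)

    def test_concurrent_vs_all_control_for_c(self, null_dataset):
        conc = mean_diff_t_test(null_dataset, "C", "concurrent")
        allc = mean_diff_t_test(null_dataset, "C", "all")
        assert conc.df < allc.df  # stage-two controls only vs both stages
        # but for A the two policies coincide (A spans both stages anyway)
        a1 = mean_diff_t_test(null_dataset, "A", "concurrent")
        a2 = mean_diff_t_test(null_dataset, "A", "all")
        assert a1 == a2

    def test_policies_coincide_without_stage_one_controls(self, null_dataset):
        no_s1_ctrl = null_dataset[
            ~((null_dataset.arm == "0") & (null_dataset.stage == 1))
        ]
        conc = mean_diff_t_test(no_s1_ctrl, "C", "concurrent")
        allc = mean_diff_t_test(no_s1_ctrl, "C", "all")
        assert conc == allc

    def test_degenerate_and_empty_errors(self, manual_dataset_factory):
        flat = manual_dataset_factory({("0", 1): [1, 1], ("A", 1): [1, 1]})
        with pytest.raises(DegenerateDataError):
            mean_diff_t_test(flat, "A")
        with pytest.raises(EmptyCellError):
            mean_diff_t_test(flat, "B")


class TestDunnett:
    def test_singleton_reduces_to_t_test(self, null_dataset):
        for comparison in ("A", "C"):
            t = mean_diff_t_test(null_dataset, comparison)
            assert dunnett_p(null_dataset, [comparison]) == pytest.approx(
                t.p, abs=1e-12
            )

    def test_against_scipy_oracle(self):
        """Balanced two comparisons sharing all controls: correlation 1/2;
        our quadrature p must match scipy's QMC Dunnett p."""
        rng = np.random.default_rng(42)
        rows = []
        for arm, mu in [("0", 0.0), ("A", 0.35), ("B", 0.1)]:
            for v in rng.normal(mu, 1.0, 50):
                rows.append((len(rows) + 1, 1, "A" if arm == "0" else arm, arm, v))
        df = pd.DataFrame(
            rows, columns=["subject_id", "stage", "cohort", "arm", "y"]
        )
        ours = dunnett_p(df, ["A", "B"], stage_filter=1)
        res = stats.dunnett(
            df[df.arm == "A"].y.to_numpy(),
            df[df.arm == "B"].y.to_numpy(),
            control=df[df.arm == "0"].y.to_numpy(),
            alternative="greater",
            random_state=np.random.default_rng(0),
        )
        assert ours == pytest.approx(res.pvalue.min(), abs=2e-3)

    def test_adjusted_p_dominates_unadjusted(self, design_one):
        for seed in range(5):
            df = simulate_trial(
                design_one, make_scenario("S0", 2, -0.5), np.random.default_rng(seed)
            )
            for subset in (["A", "B"], ["A", "B", "C"]):
                padj = dunnett_p(df, subset)
                pmin = min(mean_diff_t_test(df, j).p for j in subset)
                assert padj >= pmin - 1e-12

    def test_stage_one_subset_ignores_comparison_c(self, null_dataset):
        p_ab = dunnett_p(null_dataset, ["A", "B"], stage_filter=1)
        # in stage one the triple intersection is the {A,B} intersection
        df1 = null_dataset[null_dataset.stage == 1]
        assert dunnett_p(df1, ["A", "B"]) == pytest.approx(p_ab, abs=1e-12)

    def test_max_t_quadrature_vs_monte_carlo(self):
        """P(max T >= t) for equicorrelated rho = 0.5 vs simulation."""
        rng = np.random.default_rng(2024)
        df, lam, t0 = 150, np.sqrt(0.5), 2.2
        n_mc = 400_000
        z0 = rng.standard_normal(n_mc)
        z = rng.standard_normal((n_mc, 3))
        u = np.sqrt(rng.chisquare(df, n_mc) / df)
        tj = (lam * z0[:, None] + np.sqrt(1 - lam**2) * z) / u[:, None]
        p_mc = (tj.max(axis=1) >= t0).mean()
        p_quad = max_t_sf(t0, np.full(3, lam), df)
        assert abs(p_quad - p_mc) < 3 * np.sqrt(p_mc * (1 - p_mc) / n_mc)


class TestClosedTesting:
    def test_all_small_p_rejects_everything(self):
        p = {s: 0.001 for s in _all_subsets()}
        d = closed_test(p, alpha=0.05)
        assert all(d.reject.values())

    def test_global_intersection_blocks(self):
        p = {s: 0.001 for s in _all_subsets()}
        p[frozenset("ABC")] = 0.2
        d = closed_test(p, alpha=0.05)
        assert not any(d.reject.values())

    def test_elementary_requires_all_containing_subsets(self):
        # H0A needs {A,B,C}, {A,B}, {A,C} and {A}; failing {A,C} blocks A only
        p = {s: 0.001 for s in _all_subsets()}
        p[frozenset("AC")] = 0.9
        d = closed_test(p, alpha=0.05)
        assert not d.reject["A"] and d.reject["B"] and not d.reject["C"]

    @settings(max_examples=50, deadline=None)
    @given(st.dictionaries(st.sampled_from(sorted(_s for _s in "ABC")), st.floats(0, 1), min_size=3, max_size=3))
    def test_monotone_in_p(self, elementary):
        """Lowering any intersection p never un-rejects a hypothesis."""
        base = {s: max(elementary[j] for j in s) for s in _all_subsets()}
        d1 = closed_test(base, alpha=0.05)
        lowered = {s: p * 0.5 for s, p in base.items()}
        d2 = closed_test(lowered, alpha=0.05)
        for j in "ABC":
            assert d2.reject[j] or not d1.reject[j]


class TestFisherCombination:
    def test_threshold_value(self):
        # exp(-chi2_4(0.95)/2) with chi2_4(0.95) ~ 9.488
        assert fisher_threshold(0.05) == pytest.approx(
            np.exp(-0.5 * stats.chi2.ppf(0.95, 4)), abs=1e-12
        )
        assert fisher_threshold(0.05) == pytest.approx(0.00870, abs=5e-6)

    def test_rejection_rule(self):
        assert fisher_combination_reject(1.0, 0.005, 0.05)
        assert not fisher_combination_reject(0.5, 0.05, 0.05)

    def test_exact_size_under_uniform_p_values(self):
        rng = np.random.default_rng(77)
        p1, p2 = rng.random((2, 200_000))
        rate = (p1 * p2 <= fisher_threshold(0.05)).mean()
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 200_000)


class TestStrategyBattery:
    def test_all_strategy_names(self, null_dataset):
        out = run_all_strategies(null_dataset)
        assert tuple(out) == ALL_STRATEGIES

    def test_bonferroni_consistent_with_t_tests(self, hetero_dataset):
        out = run_all_strategies(hetero_dataset)
        for j in "ABC":
            p = out["Bonferroni"].p_values[j]
            assert out["Bonferroni"].reject[j] == (p <= 0.05 / 3)
        assert out["Bonferroni"].p_values["C"] == out["T-test C"].p_values["C"]
        assert out["Bonferroni-nc"].p_values["C"] == out["T-test C-nc"].p_values["C"]

    def test_nc_variants_differ_only_in_comparison_c(self, hetero_dataset):
        out = run_all_strategies(hetero_dataset)
        for base in ("Bonferroni", "Dunnett.closed"):
            nc = out[f"{base}-nc"]
            assert out[base].p_values["A"] == nc.p_values["A"]
            assert out[base].p_values["B"] == nc.p_values["B"]

    def test_closed_dunnett_subset_of_unadjusted(self, design_one):
        for seed in range(8):
            df = simulate_trial(
                design_one, make_scenario("SA.b", 1, 0.0), np.random.default_rng(seed)
            )
            out = run_all_strategies(
                df, strategies=["T-test A", "T-test B", "T-test C", "Dunnett.closed"]
            )
            for name, j in [("T-test A", "A"), ("T-test B", "B"), ("T-test C", "C")]:
                if out["Dunnett.closed"].reject[j]:
                    assert out[name].reject[j]

    def test_unknown_strategy_raises(self, null_dataset):
        with pytest.raises(ValueError, match="unknown strategies"):
            run_all_strategies(null_dataset, strategies=["Sidak"])


class TestCombinationClosed:
    def test_decision_set_shape(self, null_dataset):
        d = combination_closed(null_dataset)
        assert set(d.reject) == {"A", "B", "C"}

    def test_elementary_c_uses_stage_two_only(self, design_one):
        """p1 = 1 for the {C} subset: rejection of H0C requires a stage-two
        Dunnett p below the Fisher threshold in every subset."""
        rng = np.random.default_rng(10)
        df = simulate_trial(design_one, make_scenario("S0", 1, 0.0), rng)
        # make arm C overwhelmingly effective in stage two
        df.loc[df.arm == "C", "y"] += 5.0
        d = combination_closed(df)
        assert d.reject["C"]
        # the elementary {C} decision is the product rule with p1 = 1
        p2 = dunnett_p(df, ["C"], stage_filter=2)
        assert fisher_combination_reject(1.0, p2, 0.05)
        # and stage-one p-values are blind to arm C: {A,B,C} reduces to {A,B}
        p1_ab = dunnett_p(df, ["A", "B"], stage_filter=1)
        assert p1_ab == dunnett_p(df[df.stage == 1], ["A", "B"])


class TestModelBasedTests:
    def test_m0_matches_pooled_control_t_tests(self, null_dataset):
        """M0's least-squares estimates are the sample mean differences, so
        model-based tests mirror the pooled-control (nc) battery."""
        est = fit_model(null_dataset, "M0")
        out_model = model_based_tests(est)
        out_data = run_all_strategies(null_dataset)
        for j, name in [("A", "T-test A"), ("B", "T-test B"), ("C", "T-test C-nc")]:
            r = mean_diff_t_test(null_dataset, j, control_policy="all")
            assert est.theta[j] == pytest.approx(r.estimate, abs=1e-10)
            # p differs only through the residual-variance convention
            assert out_model[f"T-test {j}"].p_values[j] == pytest.approx(
                out_data[name].p_values[j], abs=6e-3
            )

    def test_zero_statistic_never_rejects(self, manual_dataset_factory):
        from platformsim.estimation import EstimateResult

        est = EstimateResult(
            model_id="M0",
            theta={"A": 0.0, "B": 0.0, "C": 0.0},
            se={"A": 1.0, "B": 1.0, "C": 1.0},
            df_resid=100,
            vcov_theta=np.eye(3) * 1.0 + 0.5 - 0.5 * np.eye(3),
        )
        out = model_based_tests(est, alpha=0.2)
        for j in "ABC":
            assert out[f"T-test {j}"].p_values[j] == pytest.approx(0.5)
            assert not out[f"T-test {j}"].reject[j]

    def test_balanced_shared_control_correlation_half(self, design_one):
        df = simulate_trial(
            design_one, make_scenario("S0", 1, 0.0), np.random.default_rng(20)
        )
        est = fit_model(df, "M0")
        v = est.vcov_theta
        corr = v[0, 1] / np.sqrt(v[0, 0] * v[1, 1])
        # arms sharing one control pool: correlation ~ 1/2 at equal sizes
        n = df.groupby("arm").size()
        expect = (1 / n["0"]) / np.sqrt(
            (1 / n["A"] + 1 / n["0"]) * (1 / n["B"] + 1 / n["0"])
        )
        assert corr == pytest.approx(expect, abs=1e-10)
        assert corr == pytest.approx(0.5, abs=0.05)


def _all_subsets():
    from itertools import combinations

    return [
        frozenset(c) for r in (1, 2, 3) for c in combinations("ABC", r)
    ]
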