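import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from cqmark import (
    correlate,
    differential_expression,
    hemolysis_sweep,
    roc_with_age,
    signed_fold_change,
    stratified_comparisons,
    two_sample_ttest,
)
from cqmark.normalization import (
    ExpressionMatrix,
    SCHEME_PROFILING,
    SCHEME_VALIDATION,
)


def matrix_from(values: dict, groups: list, scheme=SCHEME_PROFILING):
    df = pd.DataFrame(values)
    df.index = [f"s{i}" for i in range(len(df))]
    g = pd.Series(groups, index=df.index)
    return ExpressionMatrix(values=df, scheme=scheme), g


class TestFoldChangeConvention:
    @pytest.mark.parametrize(
        "delta, expect",
        [
            (1.0, 2.0),
            (-1.0, -2.0),
            (0.0, 1.0),
            (np.log2(1.33), 1.33),   # the headline biomarker's printed ratio
            (np.log2(1.73), 1.73),
            (-np.log2(1.73), -1.73),
        ],
    )
    def test_signed_values(self, delta, expect):
        assert signed_fold_change(delta) == pytest.approx(expect, abs=1e-12)

    def test_sign_antisymmetry_and_magnitude(self):
        rng = np.random.default_rng(0)
        deltas = rng.normal(0, 2, 200)
        deltas = deltas[deltas != 0]
        fc_pos = signed_fold_change(deltas)
        fc_neg = signed_fold_change(-deltas)
        assert np.allclose(fc_pos * fc_neg, -(4.0 ** np.abs(deltas)))
        assert np.allclose(np.abs(fc_pos), 2.0 ** np.abs(deltas))
        assert (np.abs(fc_pos) >= 1.0).all()


class TestDifferentialExpression:
    def test_scheme_sign_convention(self):
        # same dCq numbers; abundance direction flips with the scheme
        vals = {"A": [1.0, 1.1, 0.9, 2.0, 2.1, 1.9]}
        groups = ["control"] * 3 + ["endometriosis"] * 3
        m_prof, g = matrix_from(vals, groups, SCHEME_PROFILING)
        m_val, _ = matrix_from(vals, groups, SCHEME_VALIDATION)
        de_prof = differential_expression(m_prof, g)
        de_val = differential_expression(m_val, g)
        assert de_prof.loc[0, "delta_log2"] == pytest.approx(1.0, abs=1e-9)
        assert de_val.loc[0, "delta_log2"] == pytest.approx(-1.0, abs=1e-9)
        assert de_prof.loc[0, "fold_change"] == pytest.approx(2.0, rel=1e-6)
        assert de_val.loc[0, "fold_change"] == pytest.approx(-2.0, rel=1e-6)
        assert de_prof.loc[0, "p_value"] == de_val.loc[0, "p_value"]

    def test_identical_groups_tie(self):
        m, g = matrix_from(
            {"A": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
            ["control"] * 3 + ["endometriosis"] * 3,
        )
        de = differential_expression(m, g)
        assert de.loc[0, "fold_change"] == 1.0
        assert de.loc[0, "p_value"] > 0.99
        assert not de.loc[0, "significant"]

    def test_degenerate_zero_variance_equal_means(self):
        m, g = matrix_from(
            {"A": [2.0, 2.0, 2.0, 2.0]}, ["control"] * 2 + ["endometriosis"] * 2
        )
        de = differential_expression(m, g)
        assert de.loc[0, "p_value"] == 1.0

    def test_insufficient_samples_gives_nan(self):
        m, g = matrix_from(
            {"A": [1.0, 2.0, np.nan, 3.0]},
            ["control", "control", "endometriosis", "endometriosis"],
        )
        de = differential_expression(m, g)
        assert np.isnan(de.loc[0, "p_value"])

    def test_bh_q_values_monotone_in_p(self):
        rng = np.random.default_rng(3)
        n_assay = 50
        vals = {f"A{i:02d}": rng.normal(0, 1, 20) for i in range(n_assay)}
        m, g = matrix_from(vals, ["control"] * 10 + ["endometriosis"] * 10)
        de = differential_expression(m, g)
        by_p = de.sort_values("p_value")
        assert by_p["q_value"].is_monotonic_increasing
        assert (de["q_value"] >= de["p_value"] - 1e-12).all()

    def test_welch_vs_pooled_flag(self):
        rng = np.random.default_rng(4)
        vals = {"A": np.r_[rng.normal(0, 0.1, 5), rng.normal(1, 2.0, 15)]}
        m, g = matrix_from(vals, ["control"] * 5 + ["endometriosis"] * 15)
        p_welch = differential_expression(m, g, equal_var=False).loc[0, "p_value"]
        p_pooled = differential_expression(m, g, equal_var=True).loc[0, "p_value"]
        assert p_welch != p_pooled


class TestRocWithAge:
    def test_uninformative_covariates_auc_half(self):
        rng = np.random.default_rng(5)
        n = 1000
        expr = pd.Series(rng.normal(0, 1, 2 * n))
        age = pd.Series(rng.normal(35, 6, 2 * n))
        groups = pd.Series(["control"] * n + ["endometriosis"] * n)
        res = roc_with_age(expr, age, groups)
        assert res.auc == pytest.approx(0.5, abs=0.04)

    def test_perfect_separation_auc_one(self):
        expr = pd.Series([0.0, 0.1, 0.2, 5.0, 5.1, 5.2])
        age = pd.Series([30, 31, 32, 33, 34, 35.0])
        groups = pd.Series(["control"] * 3 + ["endometriosis"] * 3)
        res = roc_with_age(expr, age, groups)
        assert res.auc == 1.0
        assert res.separation_warning
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_binormal_closed_form(self):
        # expression N(0,1) vs N(delta,1): AUC = Phi(delta / sqrt(2))
        rng = np.random.default_rng(6)
        n, delta = 2000, 1.0
        expr = pd.Series(np.r_[rng.normal(0, 1, n), rng.normal(delta, 1, n)])
        age = pd.Series(rng.normal(35, 6, 2 * n))  # uninformative
        groups = pd.Series(["control"] * n + ["endometriosis"] * n)
        res = roc_with_age(expr, age, groups)
        assert res.auc == pytest.approx(norm.cdf(delta / np.sqrt(2)), abs=0.02)

    def test_age_only_signal_matches_age_alone(self):
        rng = np.random.default_rng(7)
        n = 800
        expr = pd.Series(rng.normal(0, 1, 2 * n))  # no disease effect
        age = pd.Series(np.r_[rng.normal(31.7, 5.2, n), rng.normal(37.5, 7.0, n)])
        groups = pd.Series(["control"] * n + ["endometriosis"] * n)
        joint = roc_with_age(expr, age, groups)
        from sklearn.metrics import roc_auc_score

        age_alone = roc_auc_score((groups == "endometriosis").astype(int), age)
        assert joint.auc == pytest.approx(age_alone, abs=0.02)

    def test_auc_invariant_to_monotone_transform_of_expression(self):
        rng = np.random.default_rng(8)
        n = 300
        expr = pd.Series(np.r_[rng.normal(0, 1, n), rng.normal(1, 1, n)])
        age = pd.Series(rng.normal(35, 6, 2 * n))
        groups = pd.Series(["control"] * n + ["endometriosis"] * n)
        a = roc_with_age(expr, age, groups).auc
        b = roc_with_age(expr * 3.0 + 7.0, age, groups).auc
        assert a == pytest.approx(b, abs=0.01)

    def test_single_group_is_error(self):
        with pytest.raises(ValueError, match="nonempty"):
            roc_with_age(
                pd.Series([1.0, 2.0]),
                pd.Series([30.0, 31.0]),
                pd.Series(["control", "control"]),
            )


class TestCorrelate:
    def test_exact_linear(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x).r == pytest.approx(1.0, abs=1e-12)
        assert correlate(x, -x).r == pytest.approx(-1.0, abs=1e-12)

    def test_independent_noise_small_r(self):
        rng = np.random.default_rng(9)
        res = correlate(rng.normal(0, 1, 1000), rng.normal(0, 1, 1000))
        assert abs(res.r) < 0.1

    def test_constant_undefined(self):
        res = correlate(np.ones(5), np.arange(5.0))
        assert not res.defined and res.reason == "constant vector"

    def test_missing_pairs_dropped(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, np.nan])
        res = correlate(x, y)
        assert res.n == 3 and res.r == pytest.approx(1.0, abs=1e-12)


class TestStratifiedComparisons:
    def _samples(self, stages, phases):
        n_ctrl = len(phases)
        n_case = len(stages)
        return pd.DataFrame(
            {
                "sample_id": [f"c{i}" for i in range(n_ctrl)]
                + [f"e{i}" for i in range(n_case)],
                "group": ["control"] * n_ctrl + ["endometriosis"] * n_case,
                "phase": phases + ["unknown"] * n_case,
                "stage": ["not_applicable"] * n_ctrl + stages,
            }
        )

    def test_small_stage_skipped_named(self):
        rng = np.random.default_rng(10)
        samples = self._samples(
            stages=["I"] + ["III"] * 10 + ["IV"] * 10,
            phases=["proliferative"] * 10 + ["secretory"] * 5,
        )
        expr = pd.Series(
            rng.normal(0, 1, len(samples)), index=samples["sample_id"]
        )
        out = stratified_comparisons(expr, samples)
        row = out[out["comparison"] == "control_vs_stage_I"].iloc[0]
        assert np.isnan(row["p_value"]) and "stage I has 1" in row["skipped"]
        assert out[out["comparison"] == "control_vs_stage_III"]["p_value"].notna().all()

    def test_shifted_stage_iv_detected(self):
        rng = np.random.default_rng(21)
        samples = self._samples(
            stages=["III"] * 20 + ["IV"] * 20,
            phases=["proliferative"] * 20,
        )
        vals = np.r_[
            rng.normal(0, 0.5, 20),   # controls
            rng.normal(0, 0.5, 20),   # stage III: null
            rng.normal(1.0, 0.5, 20), # stage IV: shifted by 1 cycle
        ]
        expr = pd.Series(vals, index=samples["sample_id"])
        out = stratified_comparisons(expr, samples).set_index("comparison")
        assert out.loc["control_vs_stage_IV", "p_value"] < 0.001
        assert out.loc["control_vs_stage_III", "p_value"] > 0.05
        assert out.loc["stage_III_vs_IV", "p_value"] < 0.001

    def test_phase_anova_null_uniform_p(self):
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(300):
            samples = self._samples(
                stages=["III"] * 4,
                phases=["proliferative"] * 20 + ["secretory"] * 10 + ["unknown"] * 6,
            )
            expr = pd.Series(
                rng.normal(0, 1, len(samples)), index=samples["sample_id"]
            )
            out = stratified_comparisons(expr, samples).set_index("comparison")
            pvals.append(out.loc["phase_anova_controls", "p_value"])
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01


class TestHemolysisSweep:
    def _setup(self, contaminated=True, seed=13):
        rng = np.random.default_rng(seed)
        n = 60
        delta = rng.uniform(5, 12, 2 * n)
        effect = np.r_[np.zeros(n), np.full(n, -0.5)]
        load = 0.4 * delta if contaminated else 0.0
        dcq = effect + load + rng.normal(0, 0.4, 2 * n)
        ids = [f"s{i}" for i in range(2 * n)]
        expr = pd.Series(dcq, index=ids)
        reports = pd.DataFrame({"sample_id": ids, "delta_cq": delta})
        samples = pd.DataFrame(
            {
                "sample_id": ids,
                "group": ["control"] * n + ["endometriosis"] * n,
                "age": np.r_[rng.normal(31.7, 5.2, n), rng.normal(37.5, 7.0, n)],
            }
        )
        return expr, reports, samples

    def test_infinite_threshold_equals_unfiltered(self):
        expr, reports, samples = self._setup()
        sweep = hemolysis_sweep(expr, reports, samples, [np.inf, 9.0])
        # unfiltered analysis on the same (sorted) sample universe
        from cqmark import filter_by_hemolysis

        retained = filter_by_hemolysis(reports, np.inf)
        sub = expr.reindex(retained)
        grp = samples.set_index("sample_id").loc[retained, "group"]
        _, p_all = two_sample_ttest(sub[grp == "endometriosis"], sub[grp == "control"])
        row = sweep[sweep["threshold"] == np.inf].iloc[0]
        assert row["p_value"] == p_all  # bit-identical, not approx
        assert row["n_control"] + row["n_case"] == len(samples)

    def test_retained_counts_monotone(self):
        expr, reports, samples = self._setup()
        sweep = hemolysis_sweep(
            expr, reports, samples, [np.inf, 11, 10, 9, 8, 7, 6]
        )
        totals = (sweep["n_control"] + sweep["n_case"]).tolist()
        assert totals == sorted(totals, reverse=True)

    def test_filter_shrinks_contamination_correlation(self):
        expr_c, reports, samples = self._setup(contaminated=True)
        expr_0, _, _ = self._setup(contaminated=False)
        sweep_c = hemolysis_sweep(expr_c, reports, samples, [np.inf, 9.0])
        sweep_0 = hemolysis_sweep(expr_0, reports, samples, [np.inf, 9.0])
        r_unfiltered = abs(sweep_c.loc[0, "r"])
        r_filtered = abs(sweep_c.loc[1, "r"])
        r_clean = abs(sweep_0.loc[0, "r"])
        assert r_filtered < r_unfiltered
        assert abs(r_filtered - r_clean) < abs(r_unfiltered - r_clean)

    def test_too_few_samples_row_undefined(self):
        expr, reports, samples = self._setup()
        sweep = hemolysis_sweep(expr, reports, samples, [np.inf, 0.5])
        row = sweep[sweep["threshold"] == 0.5].iloc[0]
        assert not row["defined"] and np.isnan(row["auc"])

    def test_unsorted_thresholds_rejected(self):
        expr, reports, samples = self._setup()
        with pytest.raises(ValueError, match="descending"):
            hemolysis_sweep(expr, reports, samples, [8.0, 9.0])
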