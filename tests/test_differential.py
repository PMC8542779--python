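"""Differential expression and TE testing against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ribojoint import (
    call_degs,
    compute_te,
    differential_expression,
    dteg_test,
    estimate_common_dispersion,
    log2_fold_change,
    nb_exact_test,
    pooled_ttest,
)


class TestLog2FoldChange:
    def test_equal_means_are_zero(self):
        assert log2_fold_change(5.0, 5.0) == 0.0

    def test_fourfold_with_small_pseudocount(self):
        assert log2_fold_change(400.0, 100.0, pseudocount=1e-9) == pytest.approx(2.0)

    def test_zero_baseline_direct_evaluation(self):
        m = 7.0
        assert log2_fold_change(m, 0.0, pseudocount=1.0) == pytest.approx(np.log2(m + 1))

    def test_rejects_nonpositive_pseudocount(self):
        with pytest.raises(ValueError, match="pseudocount"):
            log2_fold_change(1.0, 1.0, pseudocount=0.0)


def binomial_minlik_pvalue(y_b: int, s: int, p: float) -> float:
    """Independent oracle: two-sided exact binomial by direct enumeration."""
    pmf = stats.binom.pmf(np.arange(s + 1), s, p)
    return float(min(1.0, pmf[pmf <= pmf[y_b] * (1 + 1e-9)].sum()))


class TestNBExactTest:
    def test_symmetric_counts_give_p_one(self):
        counts = np.array([10, 20, 10, 20])
        groups = np.array(["M", "M", "B", "B"])
        assert nb_exact_test(counts, groups, 0.1) == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(0, 300, 6)
            groups = np.array(["M", "M", "M", "B", "B", "B"])
            p1 = nb_exact_test(counts, groups, 0.07)
            swapped = np.where(groups == "M", "B", "M")
            p2 = nb_exact_test(counts, swapped, 0.07)
            assert p1 == pytest.approx(p2, abs=1e-12)
            assert 0.0 <= p1 <= 1.0

    def test_zero_dispersion_matches_binomial_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_m = int(rng.integers(2, 5))
            n_b = int(rng.integers(2, 5))
            counts = rng.integers(0, 200, n_m + n_b)
            groups = np.array(["M"] * n_m + ["B"] * n_b)
            if counts.sum() == 0:
                counts[0] = 1
            p_impl = nb_exact_test(counts, groups, 0.0)
            y_b = counts[groups == "B"].sum()
            p_oracle = binomial_minlik_pvalue(int(y_b), int(counts.sum()), n_b / (n_m + n_b))
            assert p_impl == pytest.approx(p_oracle, abs=1e-9)

    def test_extreme_difference_is_significant(self):
        counts = np.array([0, 0, 1000, 1000])
        groups = np.array(["M", "M", "B", "B"])
        assert nb_exact_test(counts, groups, 0.05) < 1e-6

    def test_all_zero_counts_p_one(self):
        assert nb_exact_test([0, 0, 0, 0], ["M", "M", "B", "B"], 0.05) == 1.0

    def test_rejects_empty_group_and_negative_dispersion(self):
        with pytest.raises(ValueError, match="non-empty"):
            nb_exact_test([1, 2], ["M", "M"], 0.1)
        with pytest.raises(ValueError, match="dispersion"):
            nb_exact_test([1, 2], ["M", "B"], -0.1)

    def test_library_size_equalization_restores_symmetry(self):
        # Sample 2 sequenced twice as deep: raw counts differ, but after
        # equalization the groups are exchangeable again.
        counts = np.array([100, 200, 100, 200])
        groups = np.array(["M", "M", "B", "B"])
        libs = np.array([1e6, 2e6, 1e6, 2e6])
        assert nb_exact_test(counts, groups, 0.05, lib_sizes=libs) == pytest.approx(1.0)

    def test_moment_dispersion_recovers_truth(self, default_scenario):
        _, _, truth, rna, _, _ = default_scenario
        null = truth.index[(truth["tx_log2fc"] == 0) & (truth["te_log2fc"] == 0)]
        groups = [c.split("_")[0] for c in rna.columns]
        est = estimate_common_dispersion(rna.loc[null], groups)
        assert 0.02 < est < 0.1  # truth is 0.05


class TestCallDegs:
    @pytest.fixture
    def records(self):
        return pd.DataFrame(
            {
                "log2fc": [2.0, 1.0, -3.0, 0.5],
                "p_value": [1e-4, 1e-9, 0.01, 1e-9],
            },
            index=["up_strong", "boundary", "down_loose", "small_fc"],
        )

    def test_transcriptome_thresholds(self, records):
        out = call_degs(records, "transcriptome")
        assert out.loc["up_strong", "direction"] == "up"
        assert out.loc["boundary", "direction"] == "ns"  # |lfc| = 1 exactly
        assert out.loc["down_loose", "direction"] == "ns"  # p = 0.01 >= 0.001
        assert out.loc["small_fc", "direction"] == "ns"

    def test_translatome_thresholds(self, records):
        out = call_degs(records, "translatome")
        assert out.loc["down_loose", "direction"] == "down"  # p < 0.05 suffices
        assert out.loc["boundary", "direction"] == "ns"

    def test_unknown_level_rejected(self, records):
        with pytest.raises(ValueError, match="level"):
            call_degs(records, "proteome")


class TestTE:
    def test_formula_identities(self):
        ribo = pd.DataFrame({"M_ribo_1": [20.0, 5.0]}, index=["a", "b"])
        rna = pd.DataFrame({"M_rna_1": [10.0, 5.0]}, index=["a", "b"])
        te = compute_te(ribo, rna)
        assert te.loc["a", "M_te_1"] == pytest.approx(2.0)
        assert te.loc["b", "M_te_1"] == pytest.approx(1.0)

    def test_zero_rna_is_masked(self):
        ribo = pd.DataFrame({"M_ribo_1": [20.0]}, index=["a"])
        rna = pd.DataFrame({"M_rna_1": [0.0]}, index=["a"])
        assert np.isnan(compute_te(ribo, rna).loc["a", "M_te_1"])

    def test_pairing_mismatch_rejected(self):
        ribo = pd.DataFrame({"M_ribo_1": [1.0]}, index=["a"])
        rna = pd.DataFrame({"M_rna_2": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="pairing"):
            compute_te(ribo, rna)


class TestPooledTTest:
    def test_identical_vectors(self):
        r = pooled_ttest(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert r.t_stat == 0.0 and r.p_value == 1.0

    def test_textbook_oracle_toy(self):
        # closed-form pooled-variance t on log2-scale toy values
        m = np.array([1.0, 1.2])
        b = np.array([3.9, 4.1])
        n_b, n_m = 2, 2
        sp2 = ((n_b - 1) * b.var(ddof=1) + (n_m - 1) * m.var(ddof=1)) / (n_b + n_m - 2)
        t_oracle = (b.mean() - m.mean()) / np.sqrt(sp2 * (1 / n_b + 1 / n_m))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), n_b + n_m - 2)
        r = pooled_ttest(b, m)
        assert r.t_stat == pytest.approx(t_oracle, abs=1e-12)
        assert r.p_value == pytest.approx(p_oracle, abs=1e-12)
        # and against scipy's independent implementation
        sc = stats.ttest_ind(b, m, equal_var=True)
        assert r.t_stat == pytest.approx(sc.statistic, abs=1e-12)
        assert r.p_value == pytest.approx(sc.pvalue, abs=1e-12)
        assert abs(b.mean() - m.mean()) > 2 and r.p_value < 0.05  # would be a DTEG

    def test_zero_variance_nonzero_difference(self):
        r = pooled_ttest(np.array([3.0, 3.0]), np.array([1.0, 1.0]))
        assert np.isinf(r.t_stat) and r.t_stat > 0
        assert 0 < r.p_value <= np.nextafter(0.0, 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        b=st.lists(st.floats(-5, 5), min_size=2, max_size=6),
        m=st.lists(st.floats(-5, 5), min_size=2, max_size=6),
        shift=st.floats(-10, 10),
    )
    def test_shift_invariance(self, b, m, shift):
        b, m = np.array(b), np.array(m)
        r1 = pooled_ttest(b, m)
        r2 = pooled_ttest(b + shift, m + shift)
        if np.isfinite(r1.t_stat):
            assert r2.t_stat == pytest.approx(r1.t_stat, rel=1e-6, abs=1e-9)


class TestDtegTest:
    def test_flags_and_untested_rules(self):
        te = pd.DataFrame(
            {
                "M_te_1": [2.0, 1.0, np.nan],
                "M_te_2": [2.3, 1.0, 1.0],
                "B_te_1": [16.0, 1.0, 1.0],
                "B_te_2": [18.0, 1.0, 1.0],
            },
            index=["shifted", "flat", "undefined"],
        )
        out = dteg_test(te)
        assert bool(out.loc["shifted", "is_dteg"])
        assert out.loc["shifted", "log2fc_te"] > 2
        assert not out.loc["flat", "is_dteg"]
        assert out.loc["flat", "p_value"] == 1.0
        # < 2 defined M values: untested, never flagged
        assert np.isnan(out.loc["undefined", "p_value"])
        assert not out.loc["undefined", "is_dteg"]

    def test_recovery_on_default_scenario(self, default_scenario):
        from ribojoint import compute_rpkm

        _, _, truth, rna, ribo, lengths = default_scenario
        te = compute_te(compute_rpkm(ribo, lengths), compute_rpkm(rna, lengths))
        out = dteg_test(te)
        is_te = truth["te_log2fc"] != 0
        sensitivity = out.loc[is_te, "is_dteg"].mean()
        fpr = out.loc[~is_te, "is_dteg"].mean()
        assert sensitivity >= 0.8
        assert fpr <= 0.01


class TestDifferentialExpression:
    def test_recovers_transcriptional_effects(self, default_scenario):
        _, _, truth, rna, _, lengths = default_scenario
        res = differential_expression(rna, lengths, "transcriptome")
        up = truth["tx_log2fc"] > 0
        down = truth["tx_log2fc"] < 0
        assert (res.loc[up, "direction"] == "up").mean() >= 0.9
        assert (res.loc[down, "direction"] == "down").mean() >= 0.9
        null = ~(up | down)
        assert (res.loc[null, "direction"] != "ns").mean() <= 0.01

    def test_q_values_reported_but_flagging_uses_raw_p(self, default_scenario):
        _, _, _, rna, _, lengths = default_scenario
        res = differential_expression(rna.iloc[:100], lengths, "translatome")
        assert "q_value" in res.columns
        expected = (res["log2fc"].abs() > 1) & (res["p_value"] < 0.05)
        assert (res["significant"] == expected).all()
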