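"""CPM filtering, dispersion estimation, the NB exact test, fold-change and
deregulation criteria, and delta-delta-Ct quantification."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from abscopal.mirna import (
    CountMatrix,
    classify_deregulated,
    cpm_filter,
    ddct_quantify,
    de_table,
    estimate_dispersion,
    nb_exact_test,
    signed_fold_change,
)
from abscopal.synthetic import CountSimConfig, simulate_mirna_counts


def matrix_from(counts: dict, groups: dict) -> CountMatrix:
    df = pd.DataFrame(counts)
    return CountMatrix(df, pd.Series(groups))


class TestCpmFilter:
    def test_hand_arithmetic_kept_and_removed(self):
        # pad feature brings each column to a 10^6 library size, so the
        # signal rows have CPM equal to their raw counts
        df = pd.DataFrame(
            {"s1": [2, 2, 10**6 - 4], "s2": [2, 0, 10**6 - 2],
             "s3": [0, 0, 10**6]},
            index=["kept", "removed", "pad"],
        )
        cm = CountMatrix(df, pd.Series({"s1": "a", "s2": "a", "s3": "b"}))
        out = cpm_filter(cm, min_cpm=1, min_samples=2)
        assert "kept" in out.counts.index      # CPM (2, 2, 0): two samples > 1
        assert "removed" not in out.counts.index  # CPM (2, 0, 0): only one

    def test_all_zero_feature_removed(self):
        cm = matrix_from({"s1": [0, 100], "s2": [0, 100]},
                         {"s1": "a", "s2": "b"})
        out = cpm_filter(cm)
        assert list(out.counts.index) == [1]

    def test_everything_removed_errors(self):
        cm = matrix_from({"s1": [1, 1], "s2": [1, 1]}, {"s1": "a", "s2": "b"})
        # CPM is 500k each, but with min_cpm above that nothing survives
        with pytest.raises(ValueError):
            cpm_filter(cm, min_cpm=10**6)


class TestEstimateDispersion:
    def test_identical_counts_give_zero(self):
        cm = matrix_from({"s1": [10], "s2": [10], "s3": [10]},
                         {"s1": "a", "s2": "a", "s3": "a"})
        assert estimate_dispersion(cm) == 0.0

    def test_poisson_matrix_near_zero(self):
        cfg = CountSimConfig(n_per_group=3, n_features=2000, dispersion=0.0,
                             library_size=300_000)
        counts, groups, _ = simulate_mirna_counts(cfg, seed=0)
        phi = estimate_dispersion(CountMatrix(counts, groups))
        assert phi <= 0.05

    def test_nb_dispersion_recovered(self):
        cfg = CountSimConfig(n_per_group=3, n_features=2000, dispersion=0.2,
                             library_size=300_000)
        counts, groups, _ = simulate_mirna_counts(cfg, seed=1)
        phi = estimate_dispersion(CountMatrix(counts, groups))
        assert 0.1 <= phi <= 0.3

    def test_no_replicated_group_errors(self):
        cm = matrix_from({"s1": [5]}, {"s1": "a"})
        with pytest.raises(ValueError):
            estimate_dispersion(cm)


def enumerate_binomial_p(a: int, t: int, p_success: float) -> float:
    """Full-enumeration two-sided exact p (minimum-likelihood convention)."""
    probs = stats.binom.pmf(np.arange(t + 1), t, p_success)
    return float(probs[probs <= probs[a] + 1e-12].sum())


def enumerate_nb_conditional_p(a: int, t: int, r_a: float, r_b: float) -> float:
    """Enumeration oracle for the NB conditional (negative hypergeometric)."""
    x = np.arange(t + 1)
    logw = (special.gammaln(x + r_a) - special.gammaln(x + 1)
            + special.gammaln(t - x + r_b) - special.gammaln(t - x + 1))
    w = np.exp(logw - logw.max())
    probs = w / w.sum()
    return float(probs[probs <= probs[a] * (1 + 1e-10)].sum())


class TestNbExactTest:
    def test_perfect_null_p_one(self):
        cm = matrix_from({"a1": [7, 100], "a2": [7, 100],
                          "b1": [7, 100], "b2": [7, 100]},
                         {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        p = nb_exact_test(cm, "A", "B", 0.0)
        assert p.iloc[0] == 1.0

    def test_poisson_split_matches_binomial_enumeration(self):
        # totals 10 vs 0 with equal library sizes; pad keeps libsizes equal
        cm = matrix_from({"a1": [10, 990], "b1": [0, 1000]},
                         {"a1": "A", "b1": "B"})
        p = nb_exact_test(cm, "A", "B", 0.0)
        assert p.iloc[0] == pytest.approx(enumerate_binomial_p(10, 10, 0.5),
                                          rel=1e-10)

    @pytest.mark.parametrize("a,b,na,nb", [(3, 9, 2, 2), (5, 5, 3, 3),
                                           (0, 12, 2, 4)])
    def test_unbalanced_poisson_matches_enumeration(self, a, b, na, nb):
        cols, groups, counts = [], {}, {}
        total = a + b
        for i in range(na):
            counts[f"a{i}"] = [a if i == 0 else 0, 1000 - (a if i == 0 else 0)]
            groups[f"a{i}"] = "A"
        for i in range(nb):
            counts[f"b{i}"] = [b if i == 0 else 0, 1000 - (b if i == 0 else 0)]
            groups[f"b{i}"] = "B"
        cm = matrix_from(counts, groups)
        p = nb_exact_test(cm, "A", "B", 0.0)
        assert p.iloc[0] == pytest.approx(
            enumerate_binomial_p(a, total, na / (na + nb)), rel=1e-9)

    def test_nb_dispersion_matches_enumeration(self):
        cm = matrix_from({"a1": [14, 986], "b1": [2, 998]},
                         {"a1": "A", "b1": "B"})
        phi = 0.4
        p = nb_exact_test(cm, "A", "B", phi)
        assert p.iloc[0] == pytest.approx(
            enumerate_nb_conditional_p(14, 16, 1 / phi, 1 / phi), rel=1e-9)

    def test_label_swap_symmetry(self):
        cm = matrix_from({"a1": [12, 988], "a2": [9, 991],
                          "b1": [2, 998], "b2": [4, 996]},
                         {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        p_ab = nb_exact_test(cm, "A", "B", 0.1)
        p_ba = nb_exact_test(cm, "B", "A", 0.1)
        assert np.allclose(p_ab.values, p_ba.values)

    def test_monotone_in_extremity(self):
        # for fixed total, p is non-increasing as the split grows extreme
        t = 12
        ps = [enumerate_binomial_p(a, t, 0.5) for a in range(t // 2, t + 1)]
        assert all(x >= y - 1e-12 for x, y in zip(ps, ps[1:]))
        cm_ps = []
        for a in range(t // 2, t + 1):
            cm = matrix_from({"a1": [a, 1000 - a], "b1": [t - a, 1000 - (t - a)]},
                             {"a1": "A", "b1": "B"})
            cm_ps.append(nb_exact_test(cm, "A", "B", 0.0).iloc[0])
        assert all(x >= y - 1e-12 for x, y in zip(cm_ps, cm_ps[1:]))

    def test_empty_group_errors(self):
        cm = matrix_from({"a1": [1]}, {"a1": "A"})
        with pytest.raises(ValueError):
            nb_exact_test(cm, "A", "B", 0.0)


class TestAgainstEdgeROracle:
    def test_exact_test_matches_edger_smallp(self, tmp_path):
        """Independent cross-check: p-values agree with edgeR's exact test
        (smallp rejection region, fixed common dispersion) on a simulated
        matrix with equalized library sizes."""
        import subprocess

        from abscopal.synthetic import simulate_mirna_counts

        cfg = CountSimConfig(n_per_group=3, n_features=40, dispersion=0.15,
                             library_size=100_000, de_features={0: 5.0})
        counts, groups, _ = simulate_mirna_counts(cfg, seed=7)
        cm = CountMatrix(counts, groups)
        p_mine = nb_exact_test(cm, "control", "treated", 0.15)
        counts_tsv = tmp_path / "counts.tsv"
        out_csv = tmp_path / "edger_p.csv"
        counts.to_csv(counts_tsv, sep="\t")
        rcode = f'''
        suppressMessages(library(edgeR))
        x <- read.delim("{counts_tsv}", row.names=1)
        group <- factor(c(rep("control", 3), rep("treated", 3)))
        y <- DGEList(counts=x, group=group)
        y$samples$norm.factors <- rep(1, 6)
        et <- exactTest(y, dispersion=0.15, rejection.region="smallp")
        write.csv(data.frame(feature=rownames(et$table), p=et$table$PValue),
                  "{out_csv}", row.names=FALSE)
        '''
        subprocess.run(["Rscript", "-e", rcode], check=True,
                       capture_output=True)
        p_edger = pd.read_csv(out_csv).set_index("feature")["p"]
        p_edger = p_edger.loc[p_mine.index]
        log_diff = np.abs(np.log(p_mine.values) - np.log(p_edger.values))
        assert log_diff.max() <= 0.05


class TestSignedFoldChange:
    def test_threefold_up_and_down_exact_without_offset(self):
        assert signed_fold_change(10, 30, eps=0.0) == pytest.approx(3.0)
        assert signed_fold_change(30, 10, eps=0.0) == pytest.approx(-3.0)

    def test_antisymmetry(self):
        assert signed_fold_change(7, 21, eps=0.5) == pytest.approx(
            -signed_fold_change(21, 7, eps=0.5))

    def test_equal_means_give_plus_one(self):
        assert signed_fold_change(5, 5) == 1.0

    def test_default_offset_negligible_at_large_means(self):
        assert signed_fold_change(1000, 3000) == pytest.approx(3.0, rel=1e-3)

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            signed_fold_change(0, 0)

    def test_zero_control_finite(self):
        assert signed_fold_change(0.0, 10.0) == pytest.approx(21.0)


class TestClassifyDeregulated:
    @pytest.mark.parametrize("fc,p,call", [
        (3.2, 0.05, "up"),
        (-3.5, 0.09, "down"),
        (5.0, 0.2, None),     # fails the p gate
        (2.0, 0.01, None),    # fails the FC gate
        (3.0, 0.1, "up"),     # thresholds are inclusive
        (-3.0, 0.1, "down"),
    ])
    def test_criteria(self, fc, p, call):
        res = pd.DataFrame({"feature": ["x"], "fc": [fc], "p": [p]})
        out = classify_deregulated(res, name="t")
        if call is None:
            assert len(out) == 0
        else:
            assert out.direction("x") == call

    def test_near_zero_calls_under_global_null(self):
        """Type-I error of the full classify pipeline at |FC| >= 3, p <= 0.1
        under the global null is <= 1% of features (the FC gate dominates
        at these counts)."""
        n_calls, n_features = 0, 0
        for seed in range(20):
            cfg = CountSimConfig(n_per_group=3, n_features=300,
                                 dispersion=0.05, library_size=300_000)
            counts, groups, _ = simulate_mirna_counts(cfg, seed=seed)
            cm = CountMatrix(counts, groups)
            tab = de_table(cm, "control", "treated", phi=0.05)
            out = classify_deregulated(tab, name="null")
            n_calls += len(out)
            n_features += len(tab)
        assert n_calls <= 0.01 * n_features

    def test_strong_signal_recovered(self):
        hits = 0
        for seed in range(25):
            cfg = CountSimConfig(n_per_group=3, n_features=100,
                                 dispersion=0.05, library_size=1_000_000,
                                 de_features={7: 8.0})
            counts, groups, _ = simulate_mirna_counts(cfg, seed=seed)
            tab = de_table(CountMatrix(counts, groups), "control", "treated",
                           phi=0.05)
            out = classify_deregulated(tab, name="sig")
            hits += "miR-7" in out and out.direction("miR-7") == "up"
        assert hits >= 0.9 * 25


class TestDdctQuantify:
    def make_ct(self, shift=0.0, sd=0.0, seed=0, n=3):
        rng = np.random.default_rng(seed)
        cols = [f"c{i}" for i in range(n)] + [f"t{i}" for i in range(n)]
        norm = pd.Series(15.0, index=cols)
        ctrl = 22.0 + rng.normal(0, sd, n)
        trt = 22.0 + shift + rng.normal(0, sd, n)
        ct = pd.DataFrame([np.concatenate([ctrl, trt]),
                           np.full(2 * n, 15.0)],
                          index=["miR-x", "ref"], columns=cols)
        groups = pd.Series(["control"] * n + ["treated"] * n, index=cols)
        return ct, groups, norm

    def test_no_shift_gives_unity_and_p_one(self):
        ct, groups, norm = self.make_ct()
        out = ddct_quantify(ct, groups, normalizer=norm)
        assert out.loc["miR-x", "relative_expression"] == pytest.approx(1.0)
        assert out.loc["miR-x", "p"] == 1.0

    def test_minus_one_cycle_doubles_expression(self):
        ct, groups, norm = self.make_ct(shift=-1.0, sd=1e-9, seed=1)
        out = ddct_quantify(ct, groups, normalizer=norm)
        assert out.loc["miR-x", "relative_expression"] == pytest.approx(2.0,
                                                                        rel=1e-6)

    def test_two_cycle_shift_detected_in_most_seeds(self):
        hits = 0
        for seed in range(100):
            ct, groups, norm = self.make_ct(shift=2.0, sd=0.3, seed=seed)
            out = ddct_quantify(ct, groups, normalizer=norm)
            hits += bool(out.loc["miR-x", "deregulated"])
        assert hits >= 95

    def test_missing_normalizer_errors(self):
        ct, groups, _ = self.make_ct()
        bad = pd.Series(15.0, index=["c0"])
        with pytest.raises(ValueError, match="normalizer"):
            ddct_quantify(ct, groups, normalizer=bad)

    def test_default_normalizer_is_per_sample_global_mean(self):
        ct, groups, _ = self.make_ct(shift=-1.0, sd=1e-9, seed=2)
        out = ddct_quantify(ct, groups)
        assert out.attrs["normalizer"] == "global_mean"
        # shared reference row cancels a constant per-sample offset
        out2 = ddct_quantify(ct + 3.0, groups)
        assert np.allclose(out["relative_expression"],
                           out2["relative_expression"])
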