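"""Signature activation scoring and stratified-resampling inference."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import tnbcprofiler as tp

from conftest import make_matrix


def _matrix_from_genes(gene_values: dict[str, list[float]]):
    genes = list(gene_values)
    vals = np.array([gene_values[g] for g in genes], dtype=float)
    return make_matrix(vals, probes=[f"pr_{g}" for g in genes],
                       genes=genes, is_log2=True)


class TestActivationScore:
    def test_profile_equal_to_weights_scores_one(self):
        sig = tp.GeneSignature("s", ("A", "B", "C", "D"),
                               (1.0, 2.0, 3.0, 4.0))
        m = _matrix_from_genes({"A": [1.0], "B": [2.0], "C": [3.0],
                                "D": [4.0]})
        res = tp.activation_score(m, sig)
        assert res.scores.iloc[0] == pytest.approx(1.0)

    def test_anticorrelated_profile(self):
        sig = tp.GeneSignature("s", ("A", "B", "C"), (1.0, -1.0, 1.0))
        m = _matrix_from_genes({"A": [0.0], "B": [5.0], "C": [0.0]})
        res = tp.activation_score(m, sig)
        assert res.scores.iloc[0] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        w = np.array([1.0, -1.0, 2.0, 0.5])
        x = np.array([3.0, 1.0, 4.0, 2.0])
        expected = (np.mean(w * x) - w.mean() * x.mean()) / (
            w.std() * x.std())
        sig = tp.GeneSignature("s", ("A", "B", "C", "D"), tuple(w))
        m = _matrix_from_genes({g: [v] for g, v in zip("ABCD", x)})
        res = tp.activation_score(m, sig)
        assert res.scores.iloc[0] == pytest.approx(expected)

    def test_multiple_probes_per_gene_averaged(self):
        sig = tp.GeneSignature("s", ("A", "B", "C"), (1.0, 2.0, 3.0))
        m = make_matrix([[0.5], [1.5], [2.0], [3.0]],
                        probes=["p1", "p2", "p3", "p4"],
                        genes=["A", "A", "B", "C"], is_log2=True)
        res = tp.activation_score(m, sig)  # A averages to 1.0
        assert res.scores.iloc[0] == pytest.approx(1.0)

    def test_too_few_genes_flagged_not_zeroed(self):
        sig = tp.GeneSignature("s", ("A", "B", "Z1"), (1.0, -1.0, 1.0))
        m = _matrix_from_genes({"A": [1.0], "B": [2.0]})
        res = tp.activation_score(m, sig)
        assert not res.scorable
        assert res.scores.isna().all()

    def test_zero_variance_sample_is_nan(self):
        sig = tp.GeneSignature("s", ("A", "B", "C"), (1.0, -1.0, 2.0))
        m = _matrix_from_genes({"A": [5.0, 1.0], "B": [5.0, 2.0],
                                "C": [5.0, 9.0]})
        res = tp.activation_score(m, sig)
        assert np.isnan(res.scores.iloc[0])
        assert np.isfinite(res.scores.iloc[1])

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_affine_weight_invariance(self, scale, shift):
        genes = ("A", "B", "C", "D", "E")
        w = np.array([1.0, -1.0, 0.5, 2.0, -0.3])
        m = _matrix_from_genes({
            "A": [3.1, 0.2], "B": [1.2, 4.4], "C": [2.0, 2.0],
            "D": [5.5, 1.1], "E": [0.7, 3.3]})
        base = tp.activation_score(m, tp.GeneSignature("s", genes, tuple(w)))
        moved = tp.activation_score(
            m, tp.GeneSignature("s", genes, tuple(scale * w + shift)))
        assert np.allclose(base.scores, moved.scores, atol=1e-9)


class TestDifferentialActivation:
    def test_identical_groups(self):
        s = pd.Series([0.1, 0.2, 0.3, 0.1, 0.2, 0.3],
                      index=list("abcdef"))
        g = pd.Series(["x"] * 3 + ["y"] * 3, index=list("abcdef"))
        t, p = tp.differential_activation(s, g)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        s = pd.Series([0.9, 0.8, 0.85, 0.1, 0.2, 0.15], index=list("abcdef"))
        g = pd.Series(["x"] * 3 + ["y"] * 3, index=list("abcdef"))
        t, p = tp.differential_activation(s, g)
        assert p < 0.01
        assert t > 0

    def test_label_swap_flips_sign(self):
        s = pd.Series([0.9, 0.8, 0.1, 0.2], index=list("abcd"))
        g1 = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        g2 = pd.Series(["y", "y", "x", "x"], index=list("abcd"))
        t1, p1 = tp.differential_activation(s, g1)
        t2, p2 = tp.differential_activation(s, g2)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_tiny_group_rejected(self):
        s = pd.Series([0.9, 0.1, 0.2], index=list("abc"))
        g = pd.Series(["x", "y", "y"], index=list("abc"))
        with pytest.raises(ValueError, match="at least 2"):
            tp.differential_activation(s, g)


class TestStageAdjustedP:
    def test_matches_exhaustive_permutation(self):
        # n=6 in one stratum: 20 distinct balanced label assignments
        scores = pd.Series([1.0, 3.0, 2.5, 0.5, 4.0, 1.5], index=list("abcdef"))
        groups = pd.Series(["x", "x", "x", "y", "y", "y"], index=list("abcdef"))
        strata = pd.Series(["1"] * 6, index=list("abcdef"))
        t_obs, _ = tp.differential_activation(scores, groups)
        vals = scores.to_numpy()
        exceed = total = 0
        for pos in itertools.combinations(range(6), 3):
            a = vals[list(pos)]
            b = vals[[i for i in range(6) if i not in pos]]
            se = np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
            t = (a.mean() - b.mean()) / se
            total += 1
            exceed += abs(t) >= abs(t_obs) - 1e-12
        exact = exceed / total
        R = 4000
        emp = tp.stage_adjusted_p(scores, groups, strata, n_resamples=R,
                                  seed=0)
        assert emp == pytest.approx(exact, abs=2 / np.sqrt(R))

    def test_single_stratum_equals_classical_permutation_test(self):
        # with one stratum the procedure is the ordinary two-sample
        # permutation test; check the empirical p is valid on a null draw
        rng = np.random.default_rng(7)
        scores = pd.Series(rng.normal(size=12),
                           index=[f"s{i}" for i in range(12)])
        groups = pd.Series(["x"] * 6 + ["y"] * 6, index=scores.index)
        strata = pd.Series(["1"] * 12, index=scores.index)
        p = tp.stage_adjusted_p(scores, groups, strata, n_resamples=500,
                                seed=1)
        assert 1 / 501 <= p <= 1.0

    def test_default_resample_depth(self):
        import inspect
        sig = inspect.signature(tp.stage_adjusted_p)
        assert sig.parameters["n_resamples"].default == 1000

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        scores = pd.Series(rng.normal(size=20),
                           index=[f"s{i}" for i in range(20)])
        groups = pd.Series(["x", "y"] * 10, index=scores.index)
        strata = pd.Series(["1", "1", "2", "2"] * 5, index=scores.index)
        p1 = tp.stage_adjusted_p(scores, groups, strata, 200, seed=3)
        p2 = tp.stage_adjusted_p(scores, groups, strata, 200, seed=3)
        assert p1 == p2

    def test_single_group_stratum_warns(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], index=list("abcdef"))
        groups = pd.Series(["x", "x", "y", "y", "x", "x"], index=list("abcdef"))
        strata = pd.Series(["1", "1", "1", "1", "2", "2"], index=list("abcdef"))
        with pytest.warns(UserWarning, match="single group"):
            tp.stage_adjusted_p(scores, groups, strata, 50, seed=0)

    def test_unknown_stage_excluded(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0, 100.0], index=list("abcde"))
        groups = pd.Series(["x", "y", "x", "y", "x"], index=list("abcde"))
        strata = pd.Series(["1", "1", "1", "1", "unknown"], index=list("abcde"))
        # the extreme unknown-stage sample must not influence the statistic
        p = tp.stage_adjusted_p(scores, groups, strata, 100, seed=0)
        assert 0 < p <= 1


class TestFdrAdjust:
    def bh_oracle(self, pvals):
        """Brute-force BH: min over larger p of n*p/rank, capped at 1."""
        p = np.asarray(pvals, float)
        n = len(p)
        order = np.argsort(p, kind="stable")
        adjusted = np.empty(n)
        sorted_p = p[order]
        for i in range(n):
            adjusted[i] = min(
                min(n * sorted_p[j] / (j + 1) for j in range(i, n)), 1.0)
        out = np.empty(n)
        out[order] = adjusted
        return out

    def test_single_p_unchanged(self):
        assert tp.fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_worked_example(self):
        assert np.allclose(tp.fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(tp.fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_empty(self):
        assert len(tp.fdr_adjust([])) == 0

    @given(st.lists(st.sampled_from([0.001, 0.01, 0.04, 0.2, 0.5, 0.9, 1.0]),
                    min_size=1, max_size=6))
    def test_matches_brute_force_definition(self, pvals):
        assert np.allclose(tp.fdr_adjust(pvals), self.bh_oracle(pvals),
                           atol=1e-12)


class TestLarCluster:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        n_low, n_high = 40, 6
        ar = pd.Series(np.concatenate([rng.normal(0, 1, n_low),
                                       rng.normal(6, 1, n_high)]),
                       index=[f"s{i}" for i in range(n_low + n_high)])
        lar = pd.Series(np.concatenate([rng.normal(-0.2, 0.1, n_low),
                                        rng.normal(0.6, 0.1, n_high)]),
                        index=ar.index)
        out = tp.lar_cluster(ar, lar, seed=0)
        assert set(out.index[out["lar_high"]]) == set(ar.index[n_low:])

    def test_restart_determinism(self):
        rng = np.random.default_rng(1)
        ar = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        lar = pd.Series(rng.normal(size=30), index=ar.index)
        a = tp.lar_cluster(ar, lar, seed=5)
        b = tp.lar_cluster(ar, lar, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_lar_high_labels_the_high_cluster(self):
        rng = np.random.default_rng(2)
        ar = pd.Series(np.r_[rng.normal(0, 0.1, 20), rng.normal(5, 0.1, 5)],
                       index=[f"s{i}" for i in range(25)])
        lar = pd.Series(np.r_[rng.normal(0, 0.1, 20), rng.normal(3, 0.1, 5)],
                        index=ar.index)
        out = tp.lar_cluster(ar, lar, seed=0)
        assert lar[out["lar_high"]].mean() > lar[~out["lar_high"]].mean()

    def test_too_few_samples(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError, match="at least 4"):
            tp.lar_cluster(s, s)


class TestSpearman:
    def test_identical(self):
        s = pd.Series([1.0, 3.0, 2.0, 5.0], index=list("abcd"))
        assert tp.spearman_pc_signature(s, s) == pytest.approx(1.0)

    def test_reversed(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        r = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        assert tp.spearman_pc_signature(s, r) == pytest.approx(-1.0)

    def test_hand_computed_with_tie(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        y = pd.Series([1.0, 2.0, 2.0, 4.0, 5.0], index=list("abcde"))
        # tie-averaged ranks of y: [1, 2.5, 2.5, 4, 5] -> rho = 9.5/sqrt(95)
        assert tp.spearman_pc_signature(x, y) == pytest.approx(
            9.5 / np.sqrt(95))

    def test_constant_vector_undefined(self):
        x = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        c = pd.Series([5.0, 5.0, 5.0], index=list("abc"))
        assert np.isnan(tp.spearman_pc_signature(x, c))


def test_signature_group_tests_end_to_end(small_cohort):
    m, ann, _ = small_cohort
    mm, _ = tp.qc_pipeline(m, ann)
    pool = sorted(set(mm.gene_symbols.dropna()))
    sigs = {f"sig{i}": tp.random_signature(f"sig{i}", pool, 30, seed=i)
            for i in range(3)}
    table = tp.activation_table(mm, sigs)
    results = tp.signature_group_tests(table, ann, n_resamples=200, seed=0)
    assert len(results) == 3
    for r in results:
        assert 1 / 201 <= r.stage_adjusted_p <= 1.0
        assert r.fdr >= min(x.stage_adjusted_p for x in results) - 1e-12
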