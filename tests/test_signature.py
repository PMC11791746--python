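"""Regularized t-test, FDR selection, signature build and sample scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from prolifmeta.signature import (
    GeneSignature,
    SignatureError,
    benjamini_hochberg,
    build_proliferation_signature,
    regularized_two_sample_t,
    score_samples,
    serum_differential_expression,
)
from prolifmeta.syndata import SimulationConfig, simulate_serum_experiment
from conftest import make_dataset


def two_group_matrix(a: np.ndarray, b: np.ndarray) -> tuple[pd.DataFrame, pd.Series]:
    """Stack genes x (arrays_a + arrays_b) with group labels."""
    mat = pd.DataFrame(
        np.hstack([a, b]),
        index=[f"G{i}" for i in range(a.shape[0])],
        columns=[f"a{i}" for i in range(a.shape[1])]
        + [f"b{i}" for i in range(b.shape[1])],
    )
    labels = pd.Series(["low_serum"] * a.shape[1] + ["high_serum"] * b.shape[1],
                       index=mat.columns)
    return mat, labels


def reference_regularized_t(mat, labels, nu0, window):
    """Independent loop-based evaluation of the regularized t formula."""
    a_cols = labels.index[labels == "low_serum"]
    b_cols = labels.index[labels == "high_serum"]
    out = {}
    for level, cols in (("a", a_cols), ("b", b_cols)):
        sub = mat[cols].to_numpy()
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        order = np.argsort(m, kind="stable")
        half = window // 2
        bg = np.empty_like(s2)
        for rank, gene_idx in enumerate(order):
            lo, hi = max(0, rank - half), min(len(order), rank + half + 1)
            bg[gene_idx] = s2[order[lo:hi]].mean()
        n = sub.shape[1]
        reg = (nu0 * bg + (n - 1) * s2) / (nu0 + n - 2)
        out[level] = (m, reg, n)
    ma, va, na = out["a"]
    mb, vb, nb = out["b"]
    t = (mb - ma) / np.sqrt(va / na + vb / nb)
    p = 2 * stats.t.sf(np.abs(t), nu0 + na + nb - 2)
    return t, p


class TestRegularizedT:
    def test_nu0_zero_matches_ordinary_t_up_to_df_convention(self, rng):
        # with nu0 = 0 the per-group variance is (n-1)/(n-2) * s^2, so for
        # equal group sizes the statistic is the ordinary equal-variance t
        # times the exact factor sqrt((n-2)/(n-1))
        n = 6
        a = rng.normal(8, 1, size=(40, n))
        b = rng.normal(8.3, 1, size=(40, n))
        mat, labels = two_group_matrix(a, b)
        de = regularized_two_sample_t(mat, labels, nu0=0.0, window=5)
        t_ref, _ = stats.ttest_ind(b, a, axis=1, equal_var=True)
        factor = np.sqrt((n - 2) / (n - 1))
        np.testing.assert_allclose(de["t_stat"], t_ref * factor, rtol=1e-10)

    def test_identical_groups_give_t_zero_p_one(self):
        block = np.array([[1.0, 2.0, 3.0], [4.0, 6.0, 8.0]])
        mat, labels = two_group_matrix(block, block.copy())
        de = regularized_two_sample_t(mat, labels, nu0=10, window=1)
        np.testing.assert_allclose(de["t_stat"], 0.0, atol=1e-14)
        np.testing.assert_allclose(de["p_value"], 1.0, atol=1e-14)

    def test_matches_hand_formula_on_small_example(self):
        a = np.array([[1.0, 1.5, 2.0], [5.0, 5.5, 4.5], [9.0, 8.0, 10.0]])
        b = np.array([[2.0, 2.5, 3.0], [5.2, 5.4, 5.0], [7.0, 8.5, 9.5]])
        mat, labels = two_group_matrix(a, b)
        de = regularized_two_sample_t(mat, labels, nu0=10, window=3)
        t_ref, p_ref = reference_regularized_t(mat, labels, nu0=10, window=3)
        np.testing.assert_allclose(de["t_stat"], t_ref, rtol=1e-12)
        np.testing.assert_allclose(de["p_value"], p_ref, rtol=1e-12)
        assert (de["log_fc"] == (de["mean_b"] - de["mean_a"])).all()

    def test_matches_hand_formula_on_random_data(self, rng):
        a = rng.normal(7, 1.2, size=(60, 4))
        b = rng.normal(7, 1.2, size=(60, 5))
        mat, labels = two_group_matrix(a, b)
        de = regularized_two_sample_t(mat, labels, nu0=4, window=11)
        t_ref, _ = reference_regularized_t(mat, labels, nu0=4, window=11)
        np.testing.assert_allclose(de["t_stat"], t_ref, rtol=1e-10)

    def test_regularized_t_approaches_ordinary_t_as_nu0_vanishes(self, rng):
        a = rng.normal(size=(30, 5))
        b = rng.normal(size=(30, 5))
        mat, labels = two_group_matrix(a, b)
        t_small = regularized_two_sample_t(mat, labels, nu0=1e-10, window=7)["t_stat"]
        t_zero = regularized_two_sample_t(mat, labels, nu0=0.0, window=7)["t_stat"]
        np.testing.assert_allclose(t_small, t_zero, rtol=1e-6)

    def test_group_with_single_array_rejected(self, rng):
        a = rng.normal(size=(5, 1))
        b = rng.normal(size=(5, 3))
        mat, labels = two_group_matrix(a, b)
        with pytest.raises(SignatureError, match="at least 2"):
            regularized_two_sample_t(mat, labels)

    def test_constant_matrix_with_no_regularization_rejected(self):
        mat, labels = two_group_matrix(np.ones((4, 3)), np.ones((4, 3)))
        with pytest.raises(SignatureError, match="variance"):
            regularized_two_sample_t(mat, labels, nu0=0.0, window=3)


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "p, q, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], 0.1, [True, True, True, True]),
            ([0.5, 0.6], 0.1, [False, False]),
            ([0.001, 0.9], 0.1, [True, False]),
        ],
    )
    def test_step_up_rule_hand_cases(self, p, q, expected):
        reject, p_adj = benjamini_hochberg(p, q)
        assert list(reject) == expected
        assert ((p_adj >= 0) & (p_adj <= 1)).all()

    def test_adjusted_p_matches_step_up_definition(self, rng):
        p = rng.random(200)
        _, p_adj = benjamini_hochberg(p, 0.1)
        m = len(p)
        order = np.argsort(p)
        ref = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        np.testing.assert_allclose(p_adj[order], np.minimum(ref, 1.0), rtol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(SignatureError):
            benjamini_hochberg([0.5, 1.2], 0.1)


class TestBuildSignature:
    def de_table(self, genes, p, log_fc):
        return pd.DataFrame(
            {"p_value": p, "log_fc": log_fc,
             "mean_a": 0.0, "mean_b": log_fc, "t_stat": 0.0},
            index=pd.Index(genes, name="gene"),
        )

    def test_disjoint_cycle_set_is_an_error(self):
        de = self.de_table(["A", "B"], [1e-6, 1e-6], [1.0, -1.0])
        with pytest.raises(SignatureError, match="intersection"):
            build_proliferation_signature(["C", "D"], de, q=0.1)

    def test_cycle_superset_keeps_all_significant_genes(self):
        de = self.de_table(["A", "B", "C"], [1e-6, 1e-6, 0.9], [1.0, -0.5, 2.0])
        sig = build_proliferation_signature(["A", "B", "C", "D"], de, q=0.1)
        assert set(sig.genes) == {"A", "B"}
        assert dict(zip(sig.genes, sig.weights)) == {"A": 1.0, "B": -0.5}

    def test_planted_recovery_in_one_replicate(self):
        cfg = SimulationConfig(seed=77)
        exp = simulate_serum_experiment(cfg, n_per_group=10, n_de=300)
        de = serum_differential_expression(exp, q=0.10)
        cycle = cfg.proliferation_genes() + cfg.filler_genes()[-150:]
        sig = build_proliferation_signature(cycle, de, q=0.10)
        planted = set(cfg.proliferation_genes())
        assert len(set(sig.genes) & planted) / len(planted) >= 0.8


class TestScoreSamples:
    def test_single_gene_unit_weight_is_centered_expression(self):
        values = pd.DataFrame([[3.0, 5.0, 7.0]], index=["A"],
                              columns=["s1", "s2", "s3"])
        ds = make_dataset(values)
        score = score_samples(ds, GeneSignature(genes=("A",), weights=(1.0,)))
        np.testing.assert_allclose(score, [-2.0, 0.0, 2.0])

    def test_hand_arithmetic_with_mixed_signs(self):
        # centered values for the first sample are {2, 1}: score = (2 - 1)/2
        values = pd.DataFrame([[2.0, -2.0], [1.0, -1.0]], index=["A", "B"],
                              columns=["s1", "s2"])
        ds = make_dataset(values)
        sig = GeneSignature(genes=("A", "B"), weights=(1.0, -1.0))
        score = score_samples(ds, sig)
        assert score["s1"] == pytest.approx(0.5)
        assert score["s2"] == pytest.approx(-0.5)

    def test_missing_all_signature_genes_is_an_error(self):
        values = pd.DataFrame([[1.0, 2.0]], index=["A"], columns=["s1", "s2"])
        ds = make_dataset(values)
        with pytest.raises(SignatureError, match="no signature genes"):
            score_samples(ds, GeneSignature(genes=("Z",), weights=(1.0,)))

    @given(shift=st.floats(-100, 100), scale=st.floats(0.01, 50))
    def test_invariances(self, shift, scale):
        values = pd.DataFrame(
            [[1.0, 4.0, 2.0], [0.5, 0.0, 2.5], [3.0, 1.0, 1.0]],
            index=["A", "B", "C"], columns=["s1", "s2", "s3"],
        )
        sig = GeneSignature(genes=("A", "B", "C"), weights=(1.5, -0.5, 0.7))
        base = score_samples(make_dataset(values), sig)
        # per-gene constants cancel through centering
        shifted = values.add(pd.Series({"A": shift, "B": -shift, "C": 2 * shift}),
                             axis=0)
        np.testing.assert_allclose(
            score_samples(make_dataset(shifted), sig), base, atol=1e-9
        )
        # weight scaling cancels through the |w| normalization
        scaled = GeneSignature(genes=sig.genes,
                               weights=tuple(scale * w for w in sig.weights))
        np.testing.assert_allclose(
            score_samples(make_dataset(values), scaled), base, atol=1e-9
        )

    def test_signature_round_trips_through_tsv(self, tmp_path):
        sig = GeneSignature(genes=("A", "B"), weights=(0.25, -1.5))
        sig.to_tsv(tmp_path / "sig.tsv")
        back = GeneSignature.from_tsv(tmp_path / "sig.tsv")
        assert back.genes == sig.genes
        assert back.weights == sig.weights

    def test_zero_weight_rejected(self):
        with pytest.raises(SignatureError, match="zero"):
            GeneSignature(genes=("A", "B"), weights=(1.0, 0.0))
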