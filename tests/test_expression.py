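"""Sample QC, size factors, the stand-in DE test, DEG filter, PCA and RQ."""

import numpy as np
import pandas as pd
import pytest

from fbrquant.expression import (
    compute_rq,
    de_test,
    deg_filter,
    filter_samples_by_rin,
    normalize_counts,
    pca_scores,
    size_factors,
    top_k_variable_genes,
)
from fbrquant.synthetic import generate_count_matrix


class TestRinFilter:
    def test_strictly_above_threshold(self):
        meta = pd.DataFrame({"RIN": [2.9, 3.0, 3.1, 7.0]},
                            index=["s1", "s2", "s3", "s4"])
        assert filter_samples_by_rin(meta) == ["s3", "s4"]

    def test_all_high_rin_retained(self):
        meta = pd.DataFrame({"RIN": [8.0] * 4}, index=list("abcd"))
        assert filter_samples_by_rin(meta) == list("abcd")

    def test_missing_rin_excluded_with_warning(self):
        meta = pd.DataFrame({"RIN": [7.0, None]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="without RIN"):
            assert filter_samples_by_rin(meta) == ["a"]


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([10, 20, 5, 80, 3])
        counts = pd.DataFrame({"a": col, "b": col, "c": col})
        np.testing.assert_allclose(size_factors(counts), 1.0)

    def test_doubled_column_ratio_exactly_two(self):
        col = np.array([10, 20, 5, 80, 3], dtype=float)
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0, rel=1e-12)

    def test_toy_matrix_matches_hand_computation(self):
        # medians of count/geomean per column, rescaled to geometric mean 1
        counts = pd.DataFrame(
            {"a": [4, 9, 10, 20, 7], "b": [8, 3, 30, 10, 7], "c": [2, 27, 10, 40, 7]}
        )
        geo = np.exp(np.log(counts.to_numpy()).mean(axis=1))
        expected = np.exp(np.median(np.log(counts.to_numpy() / geo[:, None]), axis=0))
        expected /= np.exp(np.mean(np.log(expected)))
        np.testing.assert_allclose(size_factors(counts), expected, rtol=1e-12)

    def test_idempotence_after_normalization(self):
        counts, _, _ = generate_count_matrix(n_genes=400, de_fraction=0.1,
                                             lfc_fixed=1.5, seed=3)
        norm = normalize_counts(counts)
        np.testing.assert_allclose(size_factors(norm), 1.0, atol=1e-9)

    def test_ratios_agree_with_deseq2_median_of_ratios(self):
        # pydeseq2 uses plain exp(median) without the geometric-mean
        # convention, so compare between-sample ratios, which are
        # convention-invariant
        from pydeseq2.preprocessing import deseq2_norm

        counts, _, _ = generate_count_matrix(n_genes=500, seed=8)
        ours = size_factors(counts).to_numpy()
        _, theirs = deseq2_norm(counts.T)  # pydeseq2 wants samples x genes
        theirs = np.asarray(theirs, dtype=float).ravel()
        np.testing.assert_allclose(ours / ours[0], theirs / theirs[0], rtol=1e-9)

    def test_no_universally_expressed_gene_is_error(self):
        counts = pd.DataFrame({"a": [5, 0], "b": [0, 7]})
        with pytest.raises(ValueError, match="size factors are undefined"):
            size_factors(counts)


class TestDeTest:
    @staticmethod
    def _norm(values: dict) -> pd.DataFrame:
        return pd.DataFrame(values)

    def test_identical_groups_zero_lfc(self):
        rng = np.random.default_rng(0)
        block = rng.uniform(1, 100, size=(50, 3))
        norm = pd.DataFrame(np.hstack([block, block]),
                            columns=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=norm.columns)
        rec = de_test(norm, groups, "A", "B")
        np.testing.assert_allclose(rec["log2_fold_change"], 0.0)

    def test_closed_form_lfc_on_constant_groups(self):
        norm = pd.DataFrame([[1.0, 1, 1, 4, 4, 4]],
                            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
                            index=["g"])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=norm.columns)
        rec = de_test(norm, groups, "A", "B")
        assert rec.loc["g", "log2_fold_change"] == pytest.approx(
            np.log2(5) - np.log2(2)
        )
        # zero variance in both groups: test undefined, p recorded as 1
        assert rec.loc["g", "p_value"] == 1.0

    def test_null_pvalues_roughly_uniform(self):
        counts, meta, _ = generate_count_matrix(n_genes=2000, de_fraction=0.0, seed=21)
        rec = de_test(normalize_counts(counts), meta["group"], "control", "treated")
        frac = (rec["p_value"] < 0.05).mean()
        assert 0.03 < frac < 0.07

    def test_sensitivity_and_fdr_on_spiked_truth(self):
        # 10% DE at |log2FC| = 2, n=6 per group, pooled over 20 seeds
        tp = fp = fn = 0
        for seed in range(20):
            counts, meta, truth = generate_count_matrix(
                n_genes=2000, de_fraction=0.1, lfc_fixed=2.0, seed=1000 + seed
            )
            rec = de_test(normalize_counts(counts), meta["group"], "control", "treated")
            called = set(deg_filter(rec))
            tp += len(called & truth.de_genes)
            fp += len(called - truth.de_genes)
            fn += len(truth.de_genes - called)
        sensitivity = tp / (tp + fn)
        fdr = fp / max(tp + fp, 1)
        assert sensitivity >= 0.7
        assert fdr <= 0.05


class TestDegFilter:
    @staticmethod
    def _records(rows):
        return pd.DataFrame(
            rows, columns=["base_mean", "log2_fold_change", "p_value", "adjusted_p"]
        ).rename_axis("gene")

    def test_passing_record_retained(self):
        rec = self._records([[10.0, 1.5, 0.0001, 0.001]])
        assert list(deg_filter(rec)) == [0]

    def test_zero_lfc_always_excluded(self):
        rec = self._records([[100.0, 0.0, 1e-12, 1e-12]])
        assert len(deg_filter(rec)) == 0

    def test_boundary_semantics(self):
        # |log2FC| = 1 inclusive; base = 3 and padj = 0.01 strict
        rec = self._records(
            [
                [10.0, 1.0, 0.001, 0.001],   # exactly twofold: retained
                [3.0, 2.0, 0.001, 0.001],    # base exactly 3: excluded
                [10.0, 2.0, 0.01, 0.01],     # padj exactly 0.01: excluded
                [10.0, -1.0, 0.001, 0.001],  # twofold down: retained
            ]
        )
        assert list(deg_filter(rec)) == [0, 3]

    def test_toy_table_matches_bruteforce_predicate(self):
        rng = np.random.default_rng(12)
        rec = self._records(
            np.column_stack(
                [
                    rng.uniform(0, 10, 8),
                    rng.normal(0, 1.5, 8),
                    rng.uniform(0, 1, 8),
                    rng.uniform(0, 1, 8),
                ]
            )
        )
        expected = [
            g
            for g, r in rec.iterrows()
            if abs(r["log2_fold_change"]) >= 1
            and r["base_mean"] > 3
            and r["adjusted_p"] < 0.01
        ]
        assert list(deg_filter(rec)) == expected


class TestTopKVariableGenes:
    def test_k_equals_n_returns_all(self):
        counts, _, _ = generate_count_matrix(n_genes=50, seed=2)
        norm = normalize_counts(counts)
        assert set(top_k_variable_genes(norm, k=50)) == set(norm.index)

    def test_single_variable_gene(self):
        norm = pd.DataFrame(
            {"s1": [5.0, 1.0], "s2": [5.0, 100.0], "s3": [5.0, 1.0]},
            index=["flat", "variable"],
        )
        assert list(top_k_variable_genes(norm, k=1)) == ["variable"]

    def test_matches_bruteforce_variance_sort(self):
        counts, _, _ = generate_count_matrix(n_genes=50, seed=13)
        norm = normalize_counts(counts)
        got = list(top_k_variable_genes(norm, k=10))
        var = np.log2(norm + 1).var(axis=1, ddof=1)
        expected = list(var.sort_index().sort_values(ascending=False, kind="stable").index[:10])
        assert got == expected

    def test_k_too_large_is_error(self):
        norm = pd.DataFrame({"s1": [1.0], "s2": [2.0]})
        with pytest.raises(ValueError, match="exceeds"):
            top_k_variable_genes(norm, k=5)


class TestPca:
    def test_collinear_samples_pc1_explains_all(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        direction = np.array([1.0, -2.0, 0.5])
        mat = pd.DataFrame((t[:, None] * direction).T,
                           columns=[f"s{i}" for i in range(4)])
        _, evf = pca_scores(mat, n_components=3)
        assert evf[0] == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(14)
        mat = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        mat["a2"] = mat["a"]
        scores, _ = pca_scores(mat, n_components=2)
        np.testing.assert_allclose(scores.loc["a"], scores.loc["a2"], atol=1e-9)

    def test_component_variances_match_eigendecomposition(self):
        rng = np.random.default_rng(15)
        mat = pd.DataFrame(rng.normal(size=(20, 8)))
        scores, evf = pca_scores(mat, n_components=7)
        X = mat.to_numpy().T
        Xc = X - X.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(np.cov(Xc, rowvar=False)))[::-1]
        np.testing.assert_allclose(
            scores.to_numpy().var(axis=0, ddof=1), eig[:7], rtol=1e-8
        )
        np.testing.assert_allclose(evf, eig[:7] / eig.sum(), rtol=1e-8)

    def test_constant_matrix_is_error(self):
        mat = pd.DataFrame(np.ones((5, 4)))
        with pytest.raises(ValueError, match="zero variance"):
            pca_scores(mat)


class TestComputeRq:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])

    def test_gene_tracking_housekeeping_gives_rq_one(self):
        rows = []
        for grp, base in (("WT", 18.0), ("KO", 20.0)):
            for i in range(3):
                rows += [
                    (f"{grp}{i}", grp, "Gapdh", base + i),
                    (f"{grp}{i}", grp, "Il1b", base + i + 2.0),
                ]
        rq = compute_rq(self._table(rows), "Gapdh", "WT")
        ko = rq[(rq["gene"] == "Il1b") & (rq["group"] == "KO")].iloc[0]
        assert ko["rq"] == pytest.approx(1.0)
        assert not ko["significant"]

    def test_rq_exactly_two_not_flagged(self):
        rows = [
            ("w0", "WT", "Gapdh", 18.0), ("w0", "WT", "g", 22.0),
            ("w1", "WT", "Gapdh", 18.0), ("w1", "WT", "g", 22.0),
            ("k0", "KO", "Gapdh", 18.0), ("k0", "KO", "g", 21.0),
            ("k1", "KO", "Gapdh", 18.0), ("k1", "KO", "g", 21.0),
        ]
        rq = compute_rq(self._table(rows), "Gapdh", "WT")
        ko = rq[(rq["gene"] == "g") & (rq["group"] == "KO")].iloc[0]
        assert ko["rq"] == pytest.approx(2.0)
        assert not ko["significant"]  # strict "more than 2"
        just_over = compute_rq(self._table(
            [r[:3] + ((20.9,) if r[0].startswith("k") and r[2] == "g" else (r[3],))
             for r in rows]), "Gapdh", "WT")
        assert just_over[(just_over["group"] == "KO")]["significant"].iloc[0]

    def test_hand_computed_two_gene_table(self):
        rows = [
            ("w0", "WT", "Gapdh", 18.0), ("w0", "WT", "g1", 21.0), ("w0", "WT", "g2", 24.0),
            ("k0", "KO", "Gapdh", 19.0), ("k0", "KO", "g1", 20.5), ("k0", "KO", "g2", 26.0),
        ]
        rq = compute_rq(self._table(rows), "Gapdh", "WT").set_index(["gene", "group"])
        # g1: dCt WT=3, KO=1.5 -> ddCt=-1.5 -> RQ=2^1.5
        assert rq.loc[("g1", "KO"), "rq"] == pytest.approx(2**1.5)
        # g2: dCt WT=6, KO=7 -> ddCt=1 -> RQ=0.5, not flagged (strict)
        assert rq.loc[("g2", "KO"), "rq"] == pytest.approx(0.5)
        assert not rq.loc[("g2", "KO"), "significant"]

    def test_invariant_to_per_sample_ct_offset(self):
        rows = [
            ("w0", "WT", "Gapdh", 18.0), ("w0", "WT", "g", 21.0),
            ("w1", "WT", "Gapdh", 17.5), ("w1", "WT", "g", 20.0),
            ("k0", "KO", "Gapdh", 19.0), ("k0", "KO", "g", 20.0),
            ("k1", "KO", "Gapdh", 18.2), ("k1", "KO", "g", 19.6),
        ]
        base = compute_rq(self._table(rows), "Gapdh", "WT")
        shifted_rows = [
            (s, g, gene, ct + (5.0 if s == "k0" else 0.0)) for s, g, gene, ct in rows
        ]
        shifted = compute_rq(self._table(shifted_rows), "Gapdh", "WT")
        np.testing.assert_allclose(base["rq"], shifted["rq"], rtol=1e-12)

    def test_sample_without_housekeeping_dropped(self):
        rows = [
            ("w0", "WT", "Gapdh", 18.0), ("w0", "WT", "g", 21.0),
            ("w1", "WT", "g", 19.0),  # no housekeeping Ct
            ("k0", "KO", "Gapdh", 18.0), ("k0", "KO", "g", 20.0),
        ]
        with pytest.warns(UserWarning, match="no housekeeping"):
            rq = compute_rq(self._table(rows), "Gapdh", "WT")
        assert rq.loc[(rq["gene"] == "g") & (rq["group"] == "KO"), "rq"].iloc[0] == (
            pytest.approx(2.0)
        )
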