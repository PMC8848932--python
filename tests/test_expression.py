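from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from mirtail import expression as ex
from mirtail import simulate

from _oracle import oracle_bh


class TestSizeFactors:
    def test_double_depth_sample(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = ex.size_factors(counts)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf["b"] == pytest.approx(np.sqrt(2))

    def test_identical_samples_are_unit(self):
        counts = pd.DataFrame({"a": [5, 9, 14], "b": [5, 9, 14]})
        assert np.allclose(ex.size_factors(counts), 1.0)

    def test_single_feature(self):
        counts = pd.DataFrame({"a": [4], "b": [16]})
        sf = ex.size_factors(counts)
        assert sf.tolist() == pytest.approx([0.5, 2.0])

    def test_depth_scaling_scales_factors(self):
        rng = np.random.default_rng(0)
        base = pd.DataFrame(rng.poisson(50, (100, 4)), columns=list("abcd")) + 1
        scaled = base * [1, 2, 4, 8]
        sf = ex.size_factors(scaled)
        ratios = sf / sf["a"]
        assert np.allclose(ratios, [1, 2, 4, 8], rtol=0.05)

    def test_no_all_nonzero_feature_is_error(self):
        counts = pd.DataFrame({"a": [0, 3], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudocount"):
            ex.size_factors(counts)


class TestBH:
    def test_worked_example(self):
        q = ex.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_p_unchanged(self):
        assert ex.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.allclose(ex.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ex.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_matches_textbook_oracle_and_is_monotone(self, pvals):
        q = ex.bh_adjust(pvals)
        assert np.allclose(q, oracle_bh(pvals))
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()
        assert (q <= 1.0).all() and (q >= np.asarray(pvals) - 1e-12).all()


def _nb_counts(seed, n_features=500, disp=0.1, effects=None, n_rep=4):
    cfg = simulate.SimConfig(
        seed=seed, n_genes=n_features, mrna_dispersion=disp,
        mrna_de_effects=effects or {},
        conditions=[simulate.ConditionSpec("A", n_replicates=n_rep, is_reference=True),
                    simulate.ConditionSpec("B", n_replicates=n_rep)])
    counts, truth = simulate.simulate_mrna_counts(cfg)
    cond = {c: c.rsplit("_", 1)[0] for c in counts.columns}
    return counts, cond, truth


class TestNBWald:
    def test_equal_means_zero_variance_feature(self):
        counts = pd.DataFrame(
            np.vstack([[50] * 8, np.random.default_rng(1).poisson(100, 8)]),
            columns=[f"s{i}" for i in range(8)])
        cond = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        unit_sf = pd.Series(1.0, index=counts.columns)
        res = ex.nb_wald_test(counts, cond, "A", "B", sf=unit_sf)
        assert res.loc[0, "log2fc"] == pytest.approx(0.0, abs=1e-9)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_label_swap_negates_log2fc_keeps_p(self):
        counts, cond, _ = _nb_counts(31, effects={"gene_0001": 1.0, "gene_0002": -1.0})
        ab = ex.nb_wald_test(counts, cond, "A", "B")
        ba = ex.nb_wald_test(counts, cond, "B", "A")
        assert np.allclose(ab["log2fc"], -ba["log2fc"])
        assert np.allclose(ab["p_value"], ba["p_value"])

    def test_planted_fourfold_recovered(self):
        effects = {f"gene_{i + 1:04d}": 2.0 for i in range(50)}
        counts, cond, _ = _nb_counts(32, n_features=1000, disp=0.05, effects=effects)
        res = ex.nb_wald_test(counts, cond, "A", "B")
        est = res.loc[list(effects), "log2fc"].median()
        assert est == pytest.approx(2.0, abs=0.3)

    def test_all_zero_features_excluded_and_reported(self):
        counts, cond, _ = _nb_counts(33, n_features=50)
        counts.iloc[0] = 0
        res = ex.nb_wald_test(counts, cond, "A", "B")
        assert res.attrs["n_all_zero"] == 1
        assert counts.index[0] not in res.index

    def test_too_few_replicates_rejected(self):
        counts, cond, _ = _nb_counts(34, n_rep=2)
        one_rep = {k: v for k, v in cond.items()}
        one_rep["A_2"] = "B"
        with pytest.raises(ValueError, match="replicates"):
            ex.nb_wald_test(counts, one_rep, "A", "B")

    def test_independent_deseq2_agrees_on_log2fc(self):
        """Cross-check against pydeseq2 (independent NB GLM implementation)
        on a small planted data set: estimated effects must correlate."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        effects = {f"gene_{i + 1:04d}": (2.0 if i % 2 else -2.0) for i in range(20)}
        counts, cond, _ = _nb_counts(35, n_features=200, disp=0.05, effects=effects)
        mine = ex.nb_wald_test(counts, cond, "A", "B")

        meta = pd.DataFrame({"condition": pd.Series(cond)})
        dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition", quiet=True)
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        stats.summary()
        theirs = stats.results_df["log2FoldChange"]
        joined = pd.concat([mine["log2fc"], theirs], axis=1).dropna()
        planted = joined.loc[list(effects)]
        assert np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1] > 0.95
        assert (planted.iloc[:, 0] - planted.iloc[:, 1]).abs().median() < 0.3


class TestKmeans:
    def _planted(self, seed=0, n_per=30, sep=5.0):
        rng = np.random.default_rng(seed)
        centers = np.array([[0, 0], [sep, 0], [0, sep]])
        rows, labels = [], []
        for ci, c in enumerate(centers):
            rows.append(rng.normal(c, 1.0, (n_per, 2)))
            labels += [ci] * n_per
        data = pd.DataFrame(np.vstack(rows), index=[f"m{i}" for i in range(3 * n_per)])
        return data, np.array(labels)

    def test_planted_clusters_recovered(self):
        data, truth = self._planted()
        out = ex.kmeans_profiles(data, k=3, seed=0)
        assert adjusted_rand_score(truth, out["cluster"]) >= 0.95

    def test_k_one_groups_everything(self):
        data, _ = self._planted()
        out = ex.kmeans_profiles(data, k=1, seed=0)
        assert (out["cluster"] == 0).all()
        centered = data - data.mean(axis=0)
        assert out.attrs["inertia"] == pytest.approx((centered ** 2).to_numpy().sum(), rel=1e-6)

    def test_duplicate_rows_share_cluster(self):
        data, _ = self._planted()
        data.loc["m0"] = data.loc["m1"]
        out = ex.kmeans_profiles(data, k=3, seed=0)
        assert out.loc["m0", "cluster"] == out.loc["m1", "cluster"]

    def test_k_exceeding_rows_rejected(self):
        data, _ = self._planted(n_per=2)
        with pytest.raises(ValueError):
            ex.kmeans_profiles(data, k=10)

    def test_fixed_seed_reproducible(self):
        data, _ = self._planted()
        a = ex.kmeans_profiles(data, k=3, seed=7)
        b = ex.kmeans_profiles(data, k=3, seed=7)
        assert a.equals(b)

    def test_excluded_families_are_dropped(self):
        data, _ = self._planted()
        out = ex.kmeans_profiles(data, k=3, seed=0, exclude=("m0", "m1"))
        assert "m0" not in out.index and len(out) == len(data) - 2


class TestPCA:
    def test_two_group_separation_on_pc1(self):
        counts = pd.DataFrame({
            "a1": [100, 10, 50], "a2": [100, 10, 50],
            "b1": [10, 100, 50], "b2": [10, 100, 50]})
        scores, var = ex.pca_qc(counts, log=True)
        assert var[0] == pytest.approx(1.0, abs=1e-9)
        assert np.sign(scores.loc["a1", "PC1"]) != np.sign(scores.loc["b1", "PC1"])

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(40, (30, 6)), columns=[f"s{i}" for i in range(6)])
        _, var = ex.pca_qc(counts)
        assert var.sum() == pytest.approx(1.0)

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.poisson(40, (30, 5)), columns=list("abcde"))
        scores, _ = ex.pca_qc(counts)
        perm = counts[["c", "a", "e", "b", "d"]]
        scores_p, _ = ex.pca_qc(perm)
        assert np.allclose(np.abs(scores.loc[list("abcde")].to_numpy()),
                           np.abs(scores_p.loc[list("abcde")].to_numpy()), atol=1e-8)
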