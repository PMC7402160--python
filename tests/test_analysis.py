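"""Rank ordering, pairwise matrices, clustering and PCA of element effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import combisort as cs


def additive_pair_matrix(n_rows=12, n_cols=10, noise_sd=0.0, seed=0,
                         row_sd=0.8, col_sd=0.4):
    """Ground-truth enhancer x promoter matrix with additive log10 effects
    and optional multiplicative log-normal noise."""
    rng = np.random.default_rng(seed)
    rows = rng.normal(0, row_sd, n_rows)
    cols = rng.normal(0, col_sd, n_cols)
    log10 = 3.0 + rows[:, None] + cols[None, :]
    values = 10.0 ** log10
    if noise_sd > 0:
        values = values * np.exp(rng.normal(0, noise_sd, values.shape))
    df = pd.DataFrame(
        values,
        index=[f"E{i:02d}" for i in range(n_rows)],
        columns=[f"P{j:02d}" for j in range(n_cols)],
    )
    return cs.PairMatrix(values=df, row_class="enhancer", col_class="promoter"), rows, cols


class TestStackedFractions:
    def test_fractions_sum_to_one_and_rank_is_permutation(self, pipeline, gates):
        enh = cs.counts_for_class(pipeline["counts"], "enhancer")
        prev = cs.normalize_prevalence(enh, gates)
        sf = cs.stacked_fractions(prev)
        np.testing.assert_allclose(sf.fractions.sum(axis=1).values, 1.0, atol=1e-9)
        assert sorted(sf.rank.values) == list(range(1, len(sf.rank) + 1))

    def test_inactive_element_ranks_last(self, gates):
        x = pd.DataFrame(
            [[0.5, 0.0, 0.0, 0.0], [0.1, 0.2, 0.1, 0.1], [0.0, 0.0, 0.1, 0.4]],
            index=["GAL1", "CYC1", "TDH3"],
            columns=list(cs.BIN_LABELS),
        )
        sf = cs.stacked_fractions(cs.Prevalence(x=x, gates=gates))
        np.testing.assert_allclose(sf.fractions.loc["GAL1"].values, [1, 0, 0, 0])
        assert sf.rank["GAL1"] == 3 and sf.rank["TDH3"] == 1

    def test_ties_broken_lexicographically(self, gates):
        x = pd.DataFrame(
            [[0.1, 0.1, 0.1, 0.1]] * 2, index=["B", "A"], columns=list(cs.BIN_LABELS)
        )
        sf = cs.stacked_fractions(cs.Prevalence(x=x, gates=gates))
        assert sf.rank["A"] == 1 and sf.rank["B"] == 2

    def test_zero_mass_element_excluded(self, gates):
        x = pd.DataFrame(
            [[0.2, 0.1, 0, 0], [0, 0, 0, 0]], index=["A", "Z"], columns=list(cs.BIN_LABELS)
        )
        with pytest.warns(UserWarning):
            sf = cs.stacked_fractions(cs.Prevalence(x=x, gates=gates))
        assert "Z" not in sf.fractions.index


class TestPairMatrix:
    def test_missing_pair_is_nan(self):
        pairs = pd.Series({("E1", "P1"): 100.0, ("E1", "P2"): 200.0, ("E2", "P2"): 50.0})
        pm = cs.pairwise_matrix(pairs)
        assert np.isnan(pm.values.loc["E2", "P1"])
        assert pm.n_missing == 1

    def test_native_pairs_flagged(self):
        pairs = pd.Series(
            {("TDH3_enhancer", "TDH3_promoter"): 5.0, ("TDH3_enhancer", "PGK1_promoter"): 2.0,
             ("PGK1_enhancer", "PGK1_promoter"): 3.0, ("PGK1_enhancer", "TDH3_promoter"): 1.0}
        )
        pm = cs.pairwise_matrix(pairs)
        assert pm.native_mask.loc["TDH3", "TDH3"]
        assert not pm.native_mask.loc["TDH3", "PGK1"]

    def test_additive_truth_is_rank_one_in_log(self):
        pm, rows, cols = additive_pair_matrix(noise_sd=0.0)
        log_m = np.log10(pm.values.values)
        centered = log_m - log_m.mean(axis=0, keepdims=True)
        s = np.linalg.svd(centered, compute_uv=False)
        assert s[1] / s[0] < 1e-10
        # and the row marginals reproduce the planted enhancer ordering
        marginal = pm.values.mean(axis=1)
        assert stats.spearmanr(marginal.values, rows).statistic == pytest.approx(1.0)


class TestClustering:
    def test_identical_rows_adjacent(self):
        pm, _, _ = additive_pair_matrix(n_rows=6)
        values = pm.values.copy()
        values.loc["E05"] = values.loc["E00"]
        res = cs.cluster_matrix(cs.PairMatrix(values, "enhancer", "promoter"))
        i, j = res.row_order.index("E00"), res.row_order.index("E05")
        assert abs(i - j) == 1

    def test_planted_groups_recovered(self):
        # three enhancer strata (strong / weak / inactive), promoter effects on
        # top; the dendrogram cut at k=3 must recover the planted partition
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(4)
        labels = np.repeat([0, 1, 2], 6)
        strength = np.array([2.0, 0.0, -2.5])[labels] + rng.normal(0, 0.1, 18)
        cols = rng.normal(0, 0.3, 8)
        values = 10.0 ** (2.5 + strength[:, None] + cols[None, :])
        df = pd.DataFrame(
            values, index=[f"E{i:02d}" for i in range(18)],
            columns=[f"P{j}" for j in range(8)],
        )
        res = cs.cluster_matrix(cs.PairMatrix(df, "enhancer", "promoter"))
        found = [res.row_clusters(3)[f"E{i:02d}"] for i in range(18)]
        assert adjusted_rand_score(labels, found) >= 0.9

    def test_row_permutation_invariance(self):
        pm, _, _ = additive_pair_matrix(seed=5)
        shuffled = cs.PairMatrix(
            pm.values.sample(frac=1.0, random_state=9), "enhancer", "promoter"
        )
        a = cs.cluster_matrix(pm)
        b = cs.cluster_matrix(shuffled)
        assert a.row_order == b.row_order
        assert a.col_order == b.col_order

    def test_too_small_matrix_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["E1"], columns=["P1", "P2"])
        with pytest.raises(ValueError):
            cs.cluster_matrix(cs.PairMatrix(df, "enhancer", "promoter"))


class TestPca:
    def test_exact_rank_one_gives_pc1_100pct(self):
        pm, _, _ = additive_pair_matrix(noise_sd=0.0, seed=6)
        res = cs.pca_elements(pm)
        assert res.explained_fraction[0] == pytest.approx(1.0, abs=1e-10)

    def test_additive_with_noise_keeps_dominant_pc1(self):
        pm, _, _ = additive_pair_matrix(n_rows=24, n_cols=25, noise_sd=0.05, seed=7)
        res = cs.pca_elements(pm)
        assert res.explained_fraction[0] >= 0.90
        assert res.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_pc1_share_decreases_with_noise(self):
        shares = []
        for noise in (0.01, 0.2, 0.8):
            pm, _, _ = additive_pair_matrix(n_rows=20, n_cols=15, noise_sd=noise, seed=8)
            shares.append(cs.pca_elements(pm).explained_fraction[0])
        assert shares[0] > shares[1] > shares[2]

    def test_transpose_duality_preserves_total_variance(self):
        pm, _, _ = additive_pair_matrix(n_rows=10, n_cols=10, noise_sd=0.1, seed=9)
        a = cs.pca_elements(pm, samples_axis="rows")
        b = cs.pca_elements(pm, samples_axis="cols")
        # same matrix, dual centering: both full-rank decompositions explain
        # their own total variance completely
        assert a.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert b.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_sample_permutation_equivariance(self):
        pm, _, _ = additive_pair_matrix(noise_sd=0.1, seed=10)
        res = cs.pca_elements(pm)
        perm = pm.values.sample(frac=1.0, random_state=11)
        res_p = cs.pca_elements(cs.PairMatrix(perm, "enhancer", "promoter"))
        np.testing.assert_allclose(res_p.explained_fraction, res.explained_fraction, atol=1e-9)
        pd.testing.assert_frame_equal(
            res_p.scores.sort_index(), res.scores.sort_index(), atol=1e-8
        )

    def test_missing_rows_dropped_not_imputed(self):
        pm, _, _ = additive_pair_matrix(seed=12)
        values = pm.values.copy()
        values.iloc[0, 0] = np.nan
        res = cs.pca_elements(cs.PairMatrix(values, "enhancer", "promoter"))
        assert values.index[0] not in res.scores.index
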