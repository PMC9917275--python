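"""Composition statistics against brute-force and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wrenprey.community import (
    UndefinedDistanceError,
    ZeroVarianceError,
    bray_curtis,
    dissimilarity_matrix,
    marginal_means,
    mixed_model_means,
    pca_composition,
    permanova,
    relative_composition,
)


class TestBrayCurtis:
    def test_identical_vectors_are_zero(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports_are_one(self):
        assert bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0

    def test_worked_example(self):
        assert bray_curtis([1, 2], [3, 0]) == pytest.approx(4 / 6)

    def test_both_zero_is_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            bray_curtis([0, 0], [0, 0])

    def test_matches_scipy_oracle(self):
        from scipy.spatial.distance import braycurtis as scipy_bc

        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.gamma(1.0, 2.0, size=6)
            y = rng.gamma(1.0, 2.0, size=6)
            assert bray_curtis(x, y) == pytest.approx(scipy_bc(x, y), abs=1e-12)

    @given(
        st.lists(st.floats(0, 50), min_size=2, max_size=8),
        st.lists(st.floats(0, 50), min_size=2, max_size=8),
    )
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_and_bounded(self, x, y):
        n = min(len(x), len(y))
        x, y = np.array(x[:n]), np.array(y[:n])
        if (x + y).sum() == 0:
            return
        d = bray_curtis(x, y)
        assert d == pytest.approx(bray_curtis(y, x))
        assert 0.0 <= d <= 1.0

    def test_matrix_agrees_with_pairwise_calls(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.gamma(1.0, 2.0, size=(7, 5)))
        dm = dissimilarity_matrix(m)
        for i in range(7):
            for j in range(7):
                if i != j:
                    assert dm.iloc[i, j] == pytest.approx(
                        bray_curtis(m.iloc[i], m.iloc[j]), abs=1e-12
                    )


class TestPermanova:
    def _clouds(self, rng, sep, n_per=16, p=4):
        a = rng.normal(0, 1, size=(n_per, p)) + 5
        b = rng.normal(0, 1, size=(n_per, p)) + 5 + sep
        x = np.abs(np.vstack([a, b]))
        groups = ["a"] * n_per + ["b"] * n_per
        return dissimilarity_matrix(pd.DataFrame(x)), groups

    def test_complete_separation_attains_minimal_p(self):
        rng = np.random.default_rng(0)
        dist, groups = self._clouds(rng, sep=400.0)
        res = permanova(dist, groups, n_permutations=999, seed=1)
        assert res.p_value == pytest.approx(0.001)

    def test_same_seed_reproduces_p(self):
        rng = np.random.default_rng(1)
        dist, groups = self._clouds(rng, sep=1.0, n_per=6)
        r1 = permanova(dist, groups, n_permutations=199, seed=9)
        r2 = permanova(dist, groups, n_permutations=199, seed=9)
        assert (r1.pseudo_f, r1.p_value) == (r2.pseudo_f, r2.p_value)
        assert 0 < r1.p_value <= 1

    def test_matches_skbio_pseudo_f(self):
        """Independent oracle: scikit-bio's PERMANOVA statistic on the same
        distance matrix."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(2)
        dist, groups = self._clouds(rng, sep=1.0, n_per=6)
        ours = permanova(dist, groups, n_permutations=99, seed=0)
        dm = skbio_distance.DistanceMatrix(dist.to_numpy())
        theirs = skbio_distance.permanova(dm, grouping=list(groups), permutations=99)
        assert ours.pseudo_f == pytest.approx(float(theirs["test statistic"]), rel=1e-10)

    def test_duplicating_every_point_scales_f_by_df_only(self):
        """Doubling both groups leaves the distance structure identical, so
        pseudo-F changes only through the among/within degrees of freedom."""
        rng = np.random.default_rng(5)
        x = np.abs(rng.normal(2, 1, size=(6, 4)))
        groups = ["a", "a", "a", "b", "b", "b"]
        f1 = permanova(dissimilarity_matrix(pd.DataFrame(x)), groups,
                       n_permutations=9, seed=0).pseudo_f
        x2 = np.vstack([x, x])
        g2 = groups + groups
        f2 = permanova(dissimilarity_matrix(pd.DataFrame(x2)), g2,
                       n_permutations=9, seed=0).pseudo_f

        # brute-force recomputation of both F values from first principles
        def brute_f(xmat, labels):
            n = len(labels)
            d2 = dissimilarity_matrix(pd.DataFrame(xmat)).to_numpy() ** 2
            uniq = sorted(set(labels))
            sst = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
            ssw = 0.0
            for g in uniq:
                idx = [i for i, l in enumerate(labels) if l == g]
                ssw += sum(
                    d2[i, j] for i in idx for j in idx if i < j
                ) / len(idx)
            ssa = sst - ssw
            return (ssa / (len(uniq) - 1)) / (ssw / (n - len(uniq)))

        assert f1 == pytest.approx(brute_f(x, groups), rel=1e-10)
        assert f2 == pytest.approx(brute_f(x2, g2), rel=1e-10)

    def test_single_group_is_design_error(self):
        d = dissimilarity_matrix(pd.DataFrame(np.ones((4, 2)) + np.eye(4, 2)))
        with pytest.raises(ValueError):
            permanova(d, ["a"] * 4, n_permutations=9)


class TestPCA:
    def test_two_column_tradeoff_loads_on_single_axis(self):
        x1 = np.array([0.1, 0.4, 0.7, 0.9])
        m = pd.DataFrame({"a": x1, "b": 1 - x1})
        res = pca_composition(m)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_identical_rows_raise_zero_variance(self):
        m = pd.DataFrame(np.tile([0.2, 0.8], (4, 1)))
        with pytest.raises(ZeroVarianceError):
            pca_composition(m)

    def test_reconstruction_and_eigen_oracle(self):
        """scores @ loadings.T rebuilds the centered matrix; variances match
        a direct eigendecomposition of the covariance."""
        rng = np.random.default_rng(8)
        raw = rng.dirichlet(np.ones(6), size=8)
        m = pd.DataFrame(raw)
        res = pca_composition(m)
        centered = raw - raw.mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, centered, atol=1e-10)
        evals = np.sort(np.linalg.eigvalsh(np.cov(centered.T, bias=True)))[::-1]
        got = res.variance_fraction * (centered**2).sum() / raw.shape[0]
        assert np.allclose(got[: len(evals)], np.clip(evals, 0, None), atol=1e-10)

    def test_variance_fractions_sum_to_one_and_scores_orthogonal(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.dirichlet(np.ones(5), size=10))
        res = pca_composition(m)
        assert res.variance_fraction.sum() == pytest.approx(1.0)
        gram = res.scores.to_numpy().T @ res.scores.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(10)
        m = pd.DataFrame(rng.dirichlet(np.ones(4), size=9))
        res = pca_composition(m)
        for axis in res.loadings.columns:
            col = res.loadings[axis].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_relative_composition_rows_sum_to_one(self):
        m = pd.DataFrame({"a": [1.0, 0.0], "b": [3.0, 0.0]})
        rel = relative_composition(m)
        assert rel.iloc[0].sum() == pytest.approx(1.0)
        assert rel.iloc[1].sum() == 0.0  # flagged empty row stays zero


class TestMarginalMeans:
    def _balanced(self, noise, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for terr in ["T1", "T2"]:
            for elem in ["ARCA", "ERFA"]:
                for block in [1, 2]:
                    for tb in [1, 2, 3]:
                        base = {"T1": 2.0, "T2": 5.0}[terr] + {"ARCA": 0.0, "ERFA": 1.5}[elem]
                        rows.append(
                            dict(site="S1", territory=terr, block=block,
                                 time_block=tb, habitat_element=elem,
                                 stratum="canopy", taxon="Araneae",
                                 biomass_mg=base + noise * rng.normal())
                        )
        return pd.DataFrame(rows)

    def test_noiseless_balanced_mean_is_log1p_of_cell_value(self):
        table = self._balanced(noise=0.0)
        mm = marginal_means(table)
        row = mm[(mm.territory == "T1") & (mm.habitat_element == "ARCA")]
        assert row["mean"].iloc[0] == pytest.approx(np.log1p(2.0))
        assert row["se"].iloc[0] == pytest.approx(0.0)

    def test_noisy_balanced_means_equal_cell_mean_oracle(self):
        table = self._balanced(noise=0.3, seed=4)
        mm = marginal_means(table).set_index(["territory", "habitat_element"])
        # brute-force oracle: mean of log1p over the 6 block x time replicates
        for (terr, elem), grp in table.groupby(["territory", "habitat_element"]):
            oracle = np.log1p(grp["biomass_mg"]).mean()
            assert mm.loc[(terr, elem), "mean"] == pytest.approx(oracle, abs=1e-8)

    def test_missing_block_mean_uses_remaining_blocks_with_larger_se(self):
        table = self._balanced(noise=0.3, seed=5)
        drop = (table.territory == "T1") & (table.habitat_element == "ARCA") & (table.block == 2)
        reduced = table[~drop]
        mm_full = marginal_means(table).set_index(["territory", "habitat_element"])
        mm_red = marginal_means(reduced).set_index(["territory", "habitat_element"])
        grp = reduced[(reduced.territory == "T1") & (reduced.habitat_element == "ARCA")]
        assert mm_red.loc[("T1", "ARCA"), "mean"] == pytest.approx(
            np.log1p(grp["biomass_mg"]).mean(), abs=1e-12
        )
        assert mm_red.loc[("T1", "ARCA"), "n_obs"] == 3
        assert mm_red.loc[("T1", "ARCA"), "n_obs"] < mm_full.loc[("T1", "ARCA"), "n_obs"]

    def test_mixed_model_refit_matches_cell_means_on_balanced_data(self):
        table = self._balanced(noise=0.2, seed=6)
        cell = marginal_means(table).set_index(["territory", "habitat_element"])["mean"]
        refit = mixed_model_means(table, "canopy", "Araneae").set_index(
            ["territory", "habitat_element"]
        )["mean"]
        for key in cell.index:
            assert refit.loc[key] == pytest.approx(cell.loc[key], abs=1e-6)

    def test_raw_scale_available(self):
        table = self._balanced(noise=0.0)
        mm = marginal_means(table, transform="raw")
        row = mm[(mm.territory == "T2") & (mm.habitat_element == "ERFA")]
        assert row["mean"].iloc[0] == pytest.approx(6.5)
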