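import numpy as np
import pandas as pd
import pytest

from ibrtox.ordination import (
    NMDS,
    StructuralError,
    classify_stress,
    euclidean_distances,
    impute_missing,
    zscore,
)


class TestZscore:
    def test_simple_column(self):
        out = zscore(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(out.ravel(), [-1, 0, 1])

    def test_constant_column_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out = zscore(np.array([[2.0, 1.0], [2.0, 2.0], [2.0, 3.0]]))
        assert np.allclose(out[:, 0], 0.0)

    def test_output_moments(self, rng):
        x = rng.normal(size=(30, 4)) * [1, 10, 100, 0.01]
        out = zscore(x)
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_missing_entries_ignored_and_preserved(self):
        x = np.array([[1.0, np.nan], [2.0, 1.0], [3.0, 3.0]])
        out = zscore(x)
        assert np.isnan(out[0, 1])
        assert np.allclose(out[:, 0], [-1, 0, 1])

    def test_underobserved_column_rejected(self):
        with pytest.raises(ValueError):
            zscore(np.array([[1.0], [np.nan], [np.nan]]))


class TestImpute:
    def test_no_missing_is_identity(self, rng):
        x = rng.normal(size=(10, 4))
        assert np.array_equal(impute_missing(x, 2), x)

    def test_rank_one_cell_recovered_exactly(self, rng):
        a, b = rng.lognormal(size=12), rng.lognormal(size=5)
        x = np.outer(a, b)
        truth = x[3, 2]
        x[3, 2] = np.nan
        out = impute_missing(x, n_components=1, tol=1e-12, max_iter=2000)
        assert out[3, 2] == pytest.approx(truth, abs=1e-8)

    def test_observed_cells_unchanged(self, rng):
        x = rng.normal(size=(12, 5))
        x[0, 0] = np.nan
        out = impute_missing(x, 2)
        mask = ~np.isnan(x)
        assert np.array_equal(out[mask], x[mask])

    def test_mcar_rmse_below_noise_sd(self, rng):
        """Imputed cells estimate the underlying signal better than raw noise.

        The error is measured against the noiseless low-rank truth: the
        noise on a held-out observation itself is irreducible, so beating
        the noise SD is only a meaningful bar for the signal estimate.
        """
        n, p, rank, noise_sd = 60, 8, 2, 0.3
        low_rank = rng.normal(size=(n, rank)) @ rng.normal(size=(rank, p))
        x = low_rank + rng.normal(0, noise_sd, size=(n, p))
        mask = rng.random((n, p)) < 0.10
        masked = x.copy()
        masked[mask] = np.nan
        out = impute_missing(masked, n_components=rank)
        rmse = np.sqrt(np.mean((out[mask] - low_rank[mask]) ** 2))
        assert rmse < noise_sd

    def test_all_missing_row_is_structural_error(self):
        x = np.array([[np.nan, np.nan], [1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(StructuralError):
            impute_missing(x, 1)

    def test_dataframe_round_trip(self, rng):
        df = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("abc"))
        df.iloc[2, 1] = np.nan
        out = impute_missing(df, 1)
        assert isinstance(out, pd.DataFrame)
        assert list(out.columns) == list("abc")


class TestDistances:
    def test_pythagorean(self):
        d = euclidean_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 0] == 0.0

    def test_identical_rows_distance_zero(self):
        d = euclidean_distances(np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]]))
        assert d[0, 1] == 0.0

    def test_metric_properties(self, rng):
        x = rng.normal(size=(15, 4))
        d = euclidean_distances(x)
        assert np.allclose(d, d.T)
        for i in range(15):
            for j in range(15):
                assert d[i, j] <= d[i].max() + d[j].max() + 1e-12
        # triangle inequality on random triples
        idx = rng.integers(0, 15, size=(30, 3))
        for i, j, k in idx:
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_missing_cells_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="impute"):
            euclidean_distances(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestNMDS:
    def test_planar_configuration_embeds_with_negligible_stress(self, rng):
        x = rng.normal(size=(10, 2))
        d = euclidean_distances(x)
        res = NMDS(d, n_starts=4, seed=0).fit()
        assert res.stress < 1e-3

    def test_collinear_points_embed_perfectly(self):
        x = np.arange(4.0)[:, None] * [1.0, 0.0]
        res = NMDS(euclidean_distances(x), n_starts=4, seed=0).fit()
        assert res.stress < 1e-3

    def test_never_worse_than_classical_start(self, rng):
        from scipy.spatial.distance import pdist

        from ibrtox.ordination import _classical_mds, _stress_and_disparities

        x = rng.normal(size=(20, 5))
        d = euclidean_distances(x)
        iu = np.triu_indices(20, k=1)
        x0 = _classical_mds(d, 2)
        d0 = pdist(x0)
        s0, _ = _stress_and_disparities(d0, np.lexsort((d0, d[iu])))
        res = NMDS(d, n_starts=6, seed=1).fit()
        assert res.stress <= s0 + 1e-12

    def test_more_starts_never_increase_stress(self, rng):
        x = rng.normal(size=(12, 6))
        d = euclidean_distances(x)
        s_few = NMDS(d, n_starts=3, seed=7).fit().stress
        s_many = NMDS(d, n_starts=8, seed=7).fit().stress
        assert s_many <= s_few + 1e-12

    def test_stress_invariant_under_rigid_transform_of_inputs(self, rng):
        x = rng.normal(size=(12, 3))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        a = NMDS(euclidean_distances(x), n_starts=3, seed=2).fit()
        b = NMDS(euclidean_distances(x @ rot + 5.0), n_starts=3, seed=2).fit()
        assert a.stress == pytest.approx(b.stress, abs=1e-9)

    def test_treatment_separation_on_strong_effects(self):
        from ibrtox import EffectConfig, generate_study
        from ibrtox.pipeline import build_feature_matrix
        from ibrtox import ViabilityConfig, generate_viability

        bio = generate_study(EffectConfig(dose_slope=0.6, cv=0.15, n_per_cell=4, seed=3))
        via = generate_viability(ViabilityConfig(n_per_cell=4), 3)
        fm = build_feature_matrix(bio, via)
        x = impute_missing(zscore(fm.drop(columns=["subject_id", "Matrix", "Treatment", "Day"])))
        res = NMDS(euclidean_distances(x), n_starts=5, seed=3).fit()
        coords = res.coordinates
        treat = fm["Treatment"].to_numpy()
        d = euclidean_distances(coords)
        same = np.equal.outer(treat, treat)
        iu = np.triu_indices_from(d, k=1)
        within = d[iu][same[iu]].mean()
        between = d[iu][~same[iu]].mean()
        assert between > within

    def test_degenerate_all_zero_distances_rejected(self):
        with pytest.raises(ValueError):
            NMDS(np.zeros((5, 5)))

    def test_agrees_with_sklearn_smacof_ballpark(self, rng):
        """Independent cross-check: both optimisers find comparable stress-1."""
        from sklearn.manifold import smacof

        x = rng.normal(size=(15, 8))
        d = euclidean_distances(x)
        ours = NMDS(d, n_starts=8, seed=0).fit().stress
        _, theirs = smacof(
            d, metric=False, n_components=2, n_init=8, normalized_stress=True, random_state=0
        )
        assert ours <= theirs * 1.25 + 0.01


class TestClassifyStress:
    @pytest.mark.parametrize(
        "stress,expected",
        [(0.1488, "acceptable"), (0.25, "poor"), (0.0, "acceptable"), (0.2, "poor")],
    )
    def test_rule(self, stress, expected):
        assert classify_stress(stress) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_stress(-0.1)
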