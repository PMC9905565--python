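import numpy as np
import pandas as pd
import pytest

from springtail_metrics import (
    EnsembleGridRegressor,
    ExtrapolationMask,
    default_model_grid,
    ensemble_predict,
    generate_covariate_grid,
    global_totals,
    metabolism_total_to_carbon,
    morans_i,
    pixel_area_m2,
    sample_training_sites,
    stratified_bootstrap_maps,
    summarize_bootstrap,
)


class TestModelGrid:
    def test_exactly_18_distinct_configs(self):
        grid = default_model_grid()
        assert len(grid) == len(set(grid)) == 18
        assert {c.variables_per_split for c in grid} == set(range(2, 8))
        assert {c.min_leaf_population for c in grid} == {3, 4, 5}


class TestEnsembleGridRegressor:
    def test_perfect_linear_signal_gives_cv_r2_near_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 3))
        y = 2.0 * X[:, 0] + 1.0
        est = EnsembleGridRegressor(engine="linear", random_state=0).fit(X, y)
        assert (est.cv_results_["cv_r2"] > 0.999).all()

    def test_pure_noise_gives_cv_r2_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 4))
        y = rng.normal(size=120)
        est = EnsembleGridRegressor(
            engine="random_forest", n_estimators=25, random_state=1
        ).fit(X, y)
        assert est.cv_results_["cv_r2"].max() < 0.2

    def test_constant_response_reported(self):
        X = np.random.default_rng(2).normal(size=(40, 3))
        with pytest.raises(ValueError, match="constant"):
            EnsembleGridRegressor(engine="linear").fit(X, np.ones(40))

    def test_config_ranking_stable_across_seeds(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(3)
        X = rng.uniform(-2, 2, size=(250, 4))
        y = np.sin(X[:, 0] * 2) + 0.5 * X[:, 1] ** 2 + rng.normal(0, 0.1, 250)
        r2s = []
        for seed in (10, 11):
            est = EnsembleGridRegressor(
                n_estimators=50, random_state=seed
            ).fit(X, y)
            d = dict(zip(est.cv_results_["config"], est.cv_results_["cv_r2"]))
            r2s.append([d[c] for c in default_model_grid()])
        assert spearmanr(r2s[0], r2s[1]).statistic > 0.8

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 3))
        y = X[:, 0] + rng.normal(0, 0.2, 60)
        p1 = EnsembleGridRegressor(n_estimators=15, random_state=7).fit(X, y).predict(X)
        p2 = EnsembleGridRegressor(n_estimators=15, random_state=7).fit(X, y).predict(X)
        assert np.array_equal(p1, p2)


class _Const:
    def __init__(self, v):
        self.v = v

    def predict(self, X):
        return np.full(len(X), self.v)


class TestEnsemblePredict:
    def test_mean_contract_over_constant_models(self):
        models = [_Const(v) for v in range(1, 11)]
        out = ensemble_predict(models, np.zeros((5, 2)))
        assert np.allclose(out, 5.5)

    def test_identical_models_equal_single_model(self):
        models = [_Const(3.0)] * 10
        assert np.allclose(ensemble_predict(models, np.zeros((4, 2))), 3.0)

    def test_ensemble_rmse_not_worse_than_median_model(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(-2, 2, size=(200, 3))
        y = np.sin(2 * X[:, 0]) + X[:, 1] + rng.normal(0, 0.2, 200)
        Xg = rng.uniform(-2, 2, size=(400, 3))
        truth = np.sin(2 * Xg[:, 0]) + Xg[:, 1]
        est = EnsembleGridRegressor(n_estimators=25, random_state=6).fit(X, y)
        rmses = [
            np.sqrt(np.mean((m.predict(Xg) - truth) ** 2)) for m in est.models_
        ]
        ens_rmse = np.sqrt(np.mean((est.predict(Xg) - truth) ** 2))
        assert ens_rmse <= np.median(rmses)


class TestExtrapolationMask:
    def test_training_points_are_inside(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 4))
        mask = ExtrapolationMask().fit(X)
        assert np.all(mask.outside_fraction(X) == 0.0)
        assert not mask.mask(X).any()

    def test_far_exterior_point_masked(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 4))
        mask = ExtrapolationMask().fit(X)
        far = np.full((1, 4), 50.0)
        assert mask.outside_fraction(far)[0] == 1.0
        assert mask.mask(far)[0]

    def test_triangle_edge_point_counts_inside(self):
        # 2 covariates -> a single PC pair; hull boundary is closed
        tri = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0], [1.0, 1.0]])
        mask = ExtrapolationMask(variance_target=0.99).fit(tri)
        frac = mask.outside_fraction(np.array([[2.0, 0.0]]))  # on an edge
        assert frac[0] == 0.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 5))
        grid = rng.normal(0, 3, size=(200, 5))
        m = ExtrapolationMask().fit(X)
        frac = m.outside_fraction(grid)
        for lo, hi in [(0.1, 0.5), (0.5, 0.9), (0.2, 0.95)]:
            assert not np.any((frac > hi) & ~(frac > lo))


class TestStratifiedBootstrap:
    def _sites(self, n=40):
        rng = np.random.default_rng(12)
        return pd.DataFrame(
            {
                "region": rng.choice(["a", "b", "c", "d"], size=n),
                "value": rng.normal(size=n),
            }
        )

    @staticmethod
    def _fit_predict(df, seed):
        # "map" = 3 pixels derived from the resample mean
        m = df["value"].mean()
        return np.array([m, 2 * m, -m])

    def test_summaries_match_brute_force(self):
        layers = stratified_bootstrap_maps(
            self._sites(), {"a": 0.25, "b": 0.25, "c": 0.25, "d": 0.25},
            self._fit_predict, n_boot=50, seed=3,
        )
        assert np.array_equal(layers.mean, layers.maps.mean(axis=0))
        assert np.array_equal(layers.sd, layers.maps.std(axis=0, ddof=1))
        assert np.array_equal(layers.ci_low, np.percentile(layers.maps, 2.5, axis=0))
        assert np.array_equal(layers.ci_high, np.percentile(layers.maps, 97.5, axis=0))
        nz = layers.mean != 0
        assert np.array_equal(layers.cv[nz], (layers.sd / layers.mean)[nz])

    def test_single_resample_degenerates(self):
        layers = stratified_bootstrap_maps(
            self._sites(), {"a": 0.25, "b": 0.25, "c": 0.25, "d": 0.25},
            self._fit_predict, n_boot=1, seed=0,
        )
        assert np.all(layers.sd == 0.0)
        assert np.array_equal(layers.ci_low, layers.maps[0])
        assert np.array_equal(layers.ci_high, layers.maps[0])

    def test_resample_composition_tracks_region_areas(self):
        sites = self._sites(200)
        counts = {r: [] for r in "abcd"}

        def record(df, seed):
            for r in "abcd":
                counts[r].append((df["region"] == r).sum())
            return np.zeros(1)

        stratified_bootstrap_maps(
            sites, {"a": 0.4, "b": 0.3, "c": 0.2, "d": 0.1}, record,
            n_boot=200, seed=1,
        )
        mean_share = {r: np.mean(v) / 200 for r, v in counts.items()}
        for r, area in zip("abcd", (0.4, 0.3, 0.2, 0.1)):
            assert mean_share[r] == pytest.approx(area, abs=0.02)

    def test_empty_region_with_area_rejected(self):
        sites = pd.DataFrame({"region": ["a"] * 5, "value": range(5)})
        with pytest.raises(ValueError, match="no sites"):
            stratified_bootstrap_maps(
                sites, {"a": 0.5, "b": 0.5}, self._fit_predict, n_boot=2, seed=0
            )


class TestTotalsAndArea:
    def test_uniform_total(self):
        assert global_totals(np.ones(10), np.full(10, 2.0)) == pytest.approx(20.0)

    def test_masking_half_halves_total(self):
        v, a = np.ones(10), np.full(10, 2.0)
        mask = np.arange(10) < 5
        assert global_totals(v, a, mask) == pytest.approx(10.0)

    def test_global_lattice_area_sums_to_sphere(self):
        lats = np.arange(-89.5, 90, 1.0)
        glat = np.repeat(lats, 360)
        total = pixel_area_m2(glat, 1.0, 1.0).sum()
        assert total == pytest.approx(4 * np.pi * 6_371_000.0**2, rel=1e-6)

    def test_metabolism_carbon_conversion_chain(self):
        # 1 pixel of 1 m2 at 7e6 J/h -> per month: 7e6*730.5 J -> kg C
        got = metabolism_total_to_carbon(np.array([7e6]), np.array([1.0]))
        assert got == pytest.approx(0.135 * 730.5)


class TestMoransI:
    def test_random_values_near_null_expectation(self):
        rng = np.random.default_rng(21)
        n = 80
        lat, lon = rng.uniform(-10, 10, n), rng.uniform(-10, 10, n)
        vals = [
            morans_i(rng.normal(size=n), lat, lon, (0, 2000)) for _ in range(40)
        ]
        assert np.mean(vals) == pytest.approx(-1 / (n - 1), abs=0.02)

    def test_linear_gradient_strongly_positive(self):
        n = 30
        lat = np.linspace(0, 29, n)
        lon = np.zeros(n)
        # neighbours-only band: ~111 km spacing
        val = morans_i(np.arange(n, dtype=float), lat, lon, (0, 120))
        assert val > 0.5

    def test_checkerboard_negative(self):
        xx, yy = np.meshgrid(np.arange(6), np.arange(6))
        vals = ((xx + yy) % 2).astype(float).ravel()
        val = morans_i(vals, yy.ravel() * 0.5, xx.ravel() * 0.5, (0, 60))
        assert val < 0

    def test_no_pairs_in_band_is_undefined(self):
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning, match="no site pairs"):
            out = morans_i(rng.normal(size=12), np.arange(12) * 10.0, np.zeros(12), (0, 1))
        assert np.isnan(out)


class TestGlobePipeline:
    def test_total_abundance_within_bootstrap_ci(self):
        grid = generate_covariate_grid(n_pixels=400, n_covariates=3, seed=30)
        train = sample_training_sites(grid, n_sites=100, noise_sd=0.25, seed=31)
        covs = grid.covariate_columns
        areas = grid.grid["area_m2"].to_numpy()

        from sklearn.linear_model import LinearRegression

        def fit_predict(df, seed):
            lm = LinearRegression().fit(df[covs], df["log10_response"])
            return lm.predict(grid.grid[covs])

        region_share = train["region"].value_counts(normalize=True).to_dict()
        layers = stratified_bootstrap_maps(train, region_share, fit_predict, 100, seed=32)
        totals = np.array([(10.0 ** m * areas).sum() for m in layers.maps])
        lo, hi = np.percentile(totals, [2.5, 97.5])
        assert lo <= grid.true_total <= hi
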