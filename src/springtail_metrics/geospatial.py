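"""Grid-based ensemble extrapolation of site metrics with uncertainty.

The mapping pipeline mirrors common practice in global soil-biodiversity
mapping: a grid of random-forest hyperparameter configurations (variables
per split 2-7 x minimum leaf population 3-5, 18 in total) is ranked by
10-fold cross-validated R2; the top 10 configurations, refit on all sites,
form an unweighted prediction ensemble on the log10 response scale.
Predictions are restricted to environmental conditions covered by the
training sites via a PCA convex-hull mask, and uncertainty is quantified by
a spatially stratified bootstrap (resampling sites in proportion to the
land area of four continental regions).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.spatial import QhullError
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold, cross_val_score
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .allometry import (
    DEFAULT_CARBON_CONSTANTS,
    HOURS_PER_MONTH,
    CarbonConversionConstants,
    energy_to_carbon,
)

EARTH_RADIUS_M = 6_371_000.0


class ModelConfig(NamedTuple):
    """One hyperparameter configuration of the regression engine."""

    variables_per_split: int
    min_leaf_population: int


def default_model_grid() -> list[ModelConfig]:
    """The 18 configurations: variables per split 2-7 x min leaf 3-5."""
    return [ModelConfig(v, l) for v, l in itertools.product(range(2, 8), range(3, 6))]


def _rf_factory(config: ModelConfig, n_estimators: int, seed: int):
    return RandomForestRegressor(
        n_estimators=n_estimators,
        max_features=config.variables_per_split,
        min_samples_leaf=config.min_leaf_population,
        random_state=seed,
    )


def _linear_factory(config: ModelConfig, n_estimators: int, seed: int):
    # hyperparameters have no effect; useful for fast harnesses and tests
    return LinearRegression()


_ENGINES: dict[str, Callable] = {
    "random_forest": _rf_factory,
    "linear": _linear_factory,
}


class EnsembleGridRegressor(BaseEstimator, RegressorMixin):
    """Top-k ensemble over a hyperparameter grid ranked by CV R2.

    Parameters
    ----------
    configs : sequence of ModelConfig, default the 18-config grid
    n_top : int, number of best configurations ensembled (default 10)
    cv : int, folds for the random K-fold used to rank configs (default 10)
    engine : "random_forest", "linear", or a callable
        ``(config, n_estimators, seed) -> estimator``
    n_estimators : trees per forest (ignored by non-forest engines)
    random_state : seed controlling fold assignment and the engine

    Attributes
    ----------
    cv_results_ : DataFrame with one row per config and its mean CV R2
    top_configs_ : the ``n_top`` best configs, best first
    models_ : fitted estimators for the top configs (refit on all data)

    The response is whatever scale ``y`` is given on; for skewed community
    metrics fit on log10 values and back-transform predictions explicitly.
    """

    def __init__(
        self,
        configs: Sequence[ModelConfig] | None = None,
        n_top: int = 10,
        cv: int = 10,
        engine="random_forest",
        n_estimators: int = 100,
        random_state: int | None = None,
    ) -> None:
        self.configs = configs
        self.n_top = n_top
        self.cv = cv
        self.engine = engine
        self.n_estimators = n_estimators
        self.random_state = random_state

    def _factory(self) -> Callable:
        if callable(self.engine):
            return self.engine
        try:
            return _ENGINES[self.engine]
        except KeyError:
            raise ValueError(
                f"unknown engine {self.engine!r}; choose from {sorted(_ENGINES)}"
            ) from None

    def fit(self, X, y) -> "EnsembleGridRegressor":
        X, y = check_X_y(X, y, ensure_min_samples=self.cv)
        if np.ptp(y) == 0:
            raise ValueError("response is constant; CV R2 is undefined")
        configs = list(self.configs) if self.configs is not None else default_model_grid()
        factory = self._factory()
        seed = 0 if self.random_state is None else int(self.random_state)
        folds = KFold(n_splits=self.cv, shuffle=True, random_state=seed)
        rows = []
        for i, cfg in enumerate(configs):
            est = factory(cfg, self.n_estimators, seed + i)
            scores = cross_val_score(est, X, y, cv=folds, scoring="r2")
            rows.append({"config": cfg, "cv_r2": float(np.mean(scores))})
        self.cv_results_ = pd.DataFrame(rows).sort_values(
            "cv_r2", ascending=False, kind="stable"
        ).reset_index(drop=True)
        n_top = min(self.n_top, len(configs))
        self.top_configs_ = list(self.cv_results_["config"].iloc[:n_top])
        self.models_ = []
        for j, cfg in enumerate(self.top_configs_):
            est = factory(cfg, self.n_estimators, seed + 1000 + j)
            self.models_.append(est.fit(X, y))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "models_")
        X = check_array(X)
        preds = np.stack([m.predict(X) for m in self.models_], axis=0)
        return preds.mean(axis=0)


def train_model_grid(
    X, y, configs=None, folds: int = 10, seed: int | None = None,
    engine="random_forest", n_estimators: int = 100,
) -> pd.DataFrame:
    """Per-config mean CV R2 (thin wrapper over EnsembleGridRegressor)."""
    est = EnsembleGridRegressor(
        configs=configs, cv=folds, engine=engine,
        n_estimators=n_estimators, random_state=seed,
    ).fit(X, y)
    return est.cv_results_


def ensemble_predict(models, X) -> np.ndarray:
    """Unweighted mean prediction over already-fitted models."""
    X = check_array(X)
    return np.stack([m.predict(X) for m in models], axis=0).mean(axis=0)


class ExtrapolationMask(BaseEstimator):
    """PCA convex-hull interpolation-vs-extrapolation mask.

    Fitted on training covariates only: standardize, project onto the first
    principal components that together explain ``variance_target`` of the
    variance, and build a convex hull over every pair of retained axes.
    A grid pixel's outside-fraction is the share of axis pairs whose hull
    excludes it; pixels with fraction > ``outside_threshold`` are masked.
    Hull membership is closed (boundary points count as inside).
    """

    def __init__(self, variance_target: float = 0.90, outside_threshold: float = 0.90):
        self.variance_target = variance_target
        self.outside_threshold = outside_threshold

    def fit(self, train_covariates) -> "ExtrapolationMask":
        X = check_array(np.asarray(train_covariates, dtype=float))
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)
        pca = PCA().fit(Z)
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_axes = int(np.searchsorted(cum, self.variance_target) + 1)
        n_axes = max(2, min(n_axes, Z.shape[1]))
        if Z.shape[1] < 2:
            raise ValueError("need at least 2 covariates to build axis-pair hulls")
        self.pca_ = pca
        self.n_axes_ = n_axes
        scores = pca.transform(Z)[:, :n_axes]
        self.hulls_: dict[tuple[int, int], np.ndarray] = {}
        for i, j in itertools.combinations(range(n_axes), 2):
            pts = scores[:, [i, j]]
            try:
                hull = ConvexHull(pts)
            except QhullError:
                warnings.warn(
                    f"degenerate (collinear) training cloud for PC pair ({i},{j}); "
                    "pair skipped"
                )
                continue
            self.hulls_[(i, j)] = hull.equations  # rows: [a, b, offset]
        if not self.hulls_:
            raise ValueError("no valid axis-pair hulls could be built")
        return self

    def outside_fraction(self, covariates, atol: float = 1e-9) -> np.ndarray:
        check_is_fitted(self, "hulls_")
        X = check_array(np.asarray(covariates, dtype=float))
        scores = self.pca_.transform(self.scaler_.transform(X))[:, : self.n_axes_]
        outside = np.zeros(len(X), dtype=float)
        for (i, j), eqs in self.hulls_.items():
            pts = scores[:, [i, j]]
            # inside a closed hull iff every facet equation <= 0 (within atol)
            vals = pts @ eqs[:, :2].T + eqs[:, 2]
            outside += (vals > atol).any(axis=1)
        return outside / len(self.hulls_)

    def mask(self, covariates) -> np.ndarray:
        """True where the pixel is environmental extrapolation (masked)."""
        return self.outside_fraction(covariates) > self.outside_threshold


def build_extrapolation_mask(
    train_covariates,
    grid_covariates,
    variance_target: float = 0.90,
    outside_threshold: float = 0.90,
) -> tuple[ExtrapolationMask, np.ndarray]:
    """Fit the mask on training sites and apply it to a pixel grid."""
    m = ExtrapolationMask(variance_target, outside_threshold).fit(train_covariates)
    return m, m.mask(grid_covariates)


@dataclass
class BootstrapLayers:
    """Pixelwise summaries of the bootstrap map stack."""

    maps: np.ndarray          # (B, n_pixels)
    mean: np.ndarray
    sd: np.ndarray
    ci_low: np.ndarray        # 2.5% empirical percentile
    ci_high: np.ndarray       # 97.5% empirical percentile
    cv: np.ndarray            # sd / mean


def summarize_bootstrap(maps: np.ndarray) -> BootstrapLayers:
    maps = np.asarray(maps, dtype=float)
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1) if maps.shape[0] > 1 else np.zeros(maps.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    return BootstrapLayers(
        maps=maps,
        mean=mean,
        sd=sd,
        ci_low=np.percentile(maps, 2.5, axis=0),
        ci_high=np.percentile(maps, 97.5, axis=0),
        cv=cv,
    )


def stratified_bootstrap_maps(
    sites: pd.DataFrame,
    region_areas: dict[str, float],
    fit_predict: Callable[[pd.DataFrame, int], np.ndarray],
    n_boot: int = 100,
    seed: int = 0,
) -> BootstrapLayers:
    """Spatially stratified bootstrap of the mapping pipeline.

    Each resample draws ``len(sites)`` sites with replacement; the number of
    draws per region is multinomial with probabilities proportional to the
    regions' relative land areas, so data-rich regions do not dominate the
    uncertainty estimate.  ``fit_predict(resampled_sites, seed)`` must
    return one prediction map (1-D pixel array); the B maps are reduced to
    mean, sd, 95% CI and coefficient-of-variation layers.
    """
    if "region" not in sites.columns:
        raise ValueError("sites need a 'region' column")
    regions = list(region_areas)
    areas = np.asarray([region_areas[r] for r in regions], dtype=float)
    if not np.isclose(areas.sum(), 1.0):
        areas = areas / areas.sum()
    groups = {r: sites[sites["region"] == r] for r in regions}
    for r, g in groups.items():
        if len(g) == 0 and region_areas[r] > 0:
            raise ValueError(f"region {r!r} has positive area but no sites")
    rng = np.random.default_rng(seed)
    n = len(sites)
    maps = []
    for b in range(n_boot):
        counts = rng.multinomial(n, areas)
        parts = []
        for r, c in zip(regions, counts):
            g = groups[r]
            if c == 0:
                continue
            idx = rng.integers(0, len(g), size=c)
            parts.append(g.iloc[idx])
        resample = pd.concat(parts, ignore_index=True)
        maps.append(np.asarray(fit_predict(resample, int(rng.integers(2**31)))))
    return summarize_bootstrap(np.stack(maps, axis=0))


def pixel_area_m2(lat_deg, dlat_deg: float, dlon_deg: float, radius: float = EARTH_RADIUS_M):
    """Spherical area [m2] of a lat/lon cell centred at ``lat_deg``."""
    lat = np.asarray(lat_deg, dtype=float)
    lo = np.radians(lat - dlat_deg / 2.0)
    hi = np.radians(lat + dlat_deg / 2.0)
    out = radius**2 * np.radians(dlon_deg) * (np.sin(hi) - np.sin(lo))
    return float(out) if out.ndim == 0 else out


def global_totals(prediction, areas_m2, mask=None) -> float:
    """Sum of a per-m2 prediction map over unmasked pixels: sum(v_i * A_i)."""
    v = np.asarray(prediction, dtype=float)
    a = np.asarray(areas_m2, dtype=float)
    if v.shape != a.shape:
        raise ValueError("prediction and area arrays must align")
    keep = np.ones(v.shape, dtype=bool) if mask is None else ~np.asarray(mask, bool)
    return float(np.sum(v[keep] * a[keep]))


def metabolism_total_to_carbon(
    metabolism_j_h_m2,
    areas_m2,
    mask=None,
    hours: float = HOURS_PER_MONTH,
    constants: CarbonConversionConstants = DEFAULT_CARBON_CONSTANTS,
) -> float:
    """Global community metabolism as carbon mass [kg C per ``hours``].

    Default 730.5 h converts J h-1 m-2 maps to kg C per month.
    """
    total_j_h = global_totals(metabolism_j_h_m2, areas_m2, mask)
    return energy_to_carbon(total_j_h * hours, constants)


def _haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * (EARTH_RADIUS_M / 1000.0) * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def morans_i(values, latitudes, longitudes, distance_band_km=(0.0, 150.0)) -> float:
    """Moran's I with binary great-circle distance-band weights.

    I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    with w_ij = 1 for site pairs whose distance falls in the band (i != j).
    Returns NaN (with a warning) when no pair falls in the band.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("Moran's I needs at least 10 sites")
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    d = _haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    lo, hi = distance_band_km
    w = (d > lo) & (d <= hi)
    np.fill_diagonal(w, False)
    W = w.sum()
    if W == 0:
        warnings.warn("no site pairs in the distance band; Moran's I undefined")
        return float("nan")
    z = x - x.mean()
    denom = float(np.sum(z**2))
    if denom == 0:
        warnings.warn("constant values; Moran's I undefined")
        return float("nan")
    num = float(z @ w.astype(float) @ z)
    return (n / W) * num / denom
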