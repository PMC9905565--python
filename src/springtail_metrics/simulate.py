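"""Synthetic community data with known ground truth.

The generator emulates the structure of global springtail compilation data:
sites spanning the latitudinal gradient with a strong polar-ward density
increase (log10 density linear in |latitude|), 1-20 soil samples per site,
genus-level taxon counts that are negative-binomially overdispersed, genus
body lengths of 0.2-5 mm, habitat classes conditional on climate band
(tundra = polar scrub/grassland), and a linear soil-temperature gradient
from warm tropics to sub-zero polar soils.  Every stochastic choice is
driven by one seed, and the generating coefficients are returned as ground
truth so parameter-recovery tests can close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import classify_climate_band, load_default_checklist
from .geospatial import pixel_area_m2

MORPHOGROUPS = ("entomobryomorpha", "poduromorpha", "symphypleona")

# band -> (habitats, probabilities); tundra shows up as polar scrub/grassland
_HABITAT_MIX = {
    "polar": (("scrub", "grassland", "woodland"), (0.5, 0.3, 0.2)),
    "temperate": (
        ("woodland", "grassland", "agriculture", "scrub"),
        (0.45, 0.25, 0.2, 0.1),
    ),
    "tropical": (("woodland", "agriculture", "grassland"), (0.5, 0.3, 0.2)),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition defaults for the synthetic dataset.

    log10 density [ind m-2] = beta0 + beta1 * |lat| + N(0, density_noise_sd);
    soil temperature [degC] falls linearly from ``temp_equator`` at the
    equator to ``temp_pole`` at 70 degrees.  Defaults give tropical site
    densities around 5e3 and polar around 1.3e5 ind m-2 (a ~25-fold
    latitudinal biomass contrast) and temperatures of about +27 to -10 degC.
    """

    n_sites: int = 300
    lat_range: tuple[float, float] = (-70.0, 70.0)
    beta0: float = 3.7                  # log10 density at the equator
    beta1: float = 0.02                 # log10 density per degree |lat|
    density_noise_sd: float = 0.5
    mean_samples_per_site: float = 6.0  # 1 + Poisson(mean - 1), capped at 20
    max_samples_per_site: int = 20
    sampling_area_m2: float = 0.002     # ~5 cm diameter soil core
    nb_dispersion: float = 2.0          # negative-binomial size parameter
    n_genera: int = 40
    species_per_genus: int = 8
    richness_mean: float = 20.0         # site species-pool size ~ 5 + Poisson
    richness_min: int = 5
    abundance_lognorm_sd: float = 1.0   # unevenness of relative abundances
    length_log_mean: float = np.log(0.8)  # genus body length [mm], lognormal
    length_log_sd: float = 0.45
    length_bounds: tuple[float, float] = (0.2, 5.0)
    temp_equator: float = 27.0
    temp_pole: float = -10.0            # at 70 degrees latitude
    temp_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genera < 1 or self.species_per_genus < 1:
            raise ValueError("need at least one genus and one species per genus")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for name in ("beta0", "beta1", "density_noise_sd", "nb_dispersion"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class GroundTruth:
    """Generator-side truth: recomputable exactly from config + seed."""

    config: GeneratorConfig
    true_density: pd.Series            # per-site density [ind m-2]
    true_richness: pd.Series           # per-site species-pool size
    occurrence_probs: dict = field(default_factory=dict)  # site -> per-species P(present in a sample)


@dataclass
class SyntheticDataset:
    samples: pd.DataFrame
    sites: pd.DataFrame
    traits: pd.DataFrame
    truth: GroundTruth

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(out / "samples.csv", index=False)
        self.sites.to_csv(out / "sites.csv", index=False)
        self.traits.to_csv(out / "traits.csv", index=False)


def _region_label(lat: float, lon: float) -> str:
    """Coarse four-region split used as bootstrap strata."""
    if lon < -30:
        return "americas"
    if lon < 60:
        return "europe_central_asia" if lat > 12 else "africa"
    return "asia_pacific"


def _genus_pool(n_genera: int) -> list[str]:
    names = load_default_checklist()
    if n_genera <= len(names):
        return names[:n_genera]
    # synthetic overflow names keep the generator usable for large pools
    return names + [f"Genus{i}" for i in range(n_genera - len(names))]


def generate_traits(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    genera = _genus_pool(config.n_genera)
    lengths = np.exp(
        rng.normal(config.length_log_mean, config.length_log_sd, size=len(genera))
    )
    lengths = np.clip(lengths, *config.length_bounds)
    return pd.DataFrame(
        {
            "genus": genera,
            "body_length_mm": lengths,
            "morphogroup": [MORPHOGROUPS[i % len(MORPHOGROUPS)] for i in range(len(genera))],
        }
    )


def generate_dataset(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Draw a full community dataset (samples + sites + traits + truth)."""
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    traits = generate_traits(config, rng)
    genera = traits["genus"].tolist()
    species = [
        f"{g} sp{k + 1}" for g in genera for k in range(config.species_per_genus)
    ]
    species = np.asarray(species)
    species_genus = np.asarray([s.split()[0] for s in species])

    lo, hi = config.lat_range
    lats = rng.uniform(lo, hi, size=config.n_sites)
    lons = rng.uniform(-180.0, 180.0, size=config.n_sites)
    bands = classify_climate_band(lats)
    habitats = np.empty(config.n_sites, dtype=object)
    for band in np.unique(bands):
        idx = np.where(bands == band)[0]
        habs, probs = _HABITAT_MIX[str(band)]
        habitats[idx] = rng.choice(habs, size=idx.size, p=probs)
    temps = (
        config.temp_equator
        + (config.temp_pole - config.temp_equator) * np.abs(lats) / 70.0
        + rng.normal(0.0, config.temp_noise_sd, size=config.n_sites)
    )
    log10_d = (
        config.beta0
        + config.beta1 * np.abs(lats)
        + rng.normal(0.0, config.density_noise_sd, size=config.n_sites)
    )
    true_density = 10.0 ** log10_d
    n_samples = 1 + rng.poisson(config.mean_samples_per_site - 1.0, size=config.n_sites)
    n_samples = np.minimum(n_samples, config.max_samples_per_site)

    site_ids = [f"site_{i:04d}" for i in range(config.n_sites)]
    sites = pd.DataFrame(
        {
            "site_id": site_ids,
            "latitude": lats,
            "longitude": lons,
            "habitat": habitats,
            "soil_temperature": temps,
            "layers": "litter+soil",
            "sampling_depth": 10.0,
            "region": [_region_label(la, lo_) for la, lo_ in zip(lats, lons)],
            "n_samples": n_samples,
        }
    )

    rows: list[dict] = []
    richness = np.empty(config.n_sites, dtype=int)
    occ_probs: dict[str, np.ndarray] = {}
    k = config.nb_dispersion
    for i, sid in enumerate(site_ids):
        s_true = config.richness_min + rng.poisson(
            max(config.richness_mean - config.richness_min, 0.0)
        )
        s_true = min(s_true, species.size)
        richness[i] = s_true
        pool_idx = rng.choice(species.size, size=s_true, replace=False)
        rel = np.exp(rng.normal(0.0, config.abundance_lognorm_sd, size=s_true))
        rel /= rel.sum()
        mu = true_density[i] * config.sampling_area_m2 * rel  # expected counts
        # negative binomial: P(count = 0) = (k / (k + mu))^k
        occ_probs[sid] = 1.0 - (k / (k + mu)) ** k
        for j in range(n_samples[i]):
            counts = rng.negative_binomial(k, k / (k + mu))
            present = counts > 0
            for sp_i, c in zip(pool_idx[present], counts[present]):
                rows.append(
                    {
                        "site_id": sid,
                        "sample_id": f"{sid}_s{j + 1:02d}",
                        "taxon": species[sp_i],
                        "genus": species_genus[sp_i],
                        "abundance": int(c),
                        "sampling_area": config.sampling_area_m2,
                    }
                )
            if not present.any():
                # keep empty samples on the books with an explicit zero row
                rows.append(
                    {
                        "site_id": sid,
                        "sample_id": f"{sid}_s{j + 1:02d}",
                        "taxon": species[pool_idx[0]],
                        "genus": species_genus[pool_idx[0]],
                        "abundance": 0,
                        "sampling_area": config.sampling_area_m2,
                    }
                )
    samples = pd.DataFrame(rows)
    truth = GroundTruth(
        config=config,
        true_density=pd.Series(true_density, index=site_ids, name="true_density"),
        true_richness=pd.Series(richness, index=site_ids, name="true_richness"),
        occurrence_probs=occ_probs,
    )
    return SyntheticDataset(samples=samples, sites=sites, traits=traits, truth=truth)


@dataclass
class SyntheticGrid:
    """Pixel table + generating surface for extrapolation experiments."""

    grid: pd.DataFrame                 # pixel_id, lat, lon, area_m2, cov_*
    coefficients: np.ndarray           # true linear coefficients on log10 scale
    true_log10: np.ndarray             # per-pixel true log10 response (per m2)
    true_total: float                  # sum(10**true_log10 * area)

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.grid.columns if c.startswith("cov_")]


def generate_covariate_grid(
    n_pixels: int = 1000,
    n_covariates: int = 5,
    coefficients=None,
    intercept: float = 3.7,
    lat_range: tuple[float, float] = (-60.0, 70.0),
    seed: int = 0,
) -> SyntheticGrid:
    """A lat/lon pixel lattice with latitude-correlated covariates and a
    known linear (log10-scale) response surface.

    The first covariate tracks |latitude| (temperature-like), the second is
    a greenness-like transform of latitude, the rest are independent noise
    channels.  The true per-m2 response is 10**(intercept + X @ coefficients)
    so the true masked/unmasked grid total is available exactly.
    """
    if n_pixels < 100:
        raise ValueError("use at least 100 pixels for a meaningful grid")
    rng = np.random.default_rng(seed)
    nx = int(np.ceil(np.sqrt(2 * n_pixels)))
    ny = int(np.ceil(n_pixels / nx))
    lons = np.linspace(-180 + 180 / nx, 180 - 180 / nx, nx)
    lats = np.linspace(lat_range[0], lat_range[1], ny)
    glon, glat = np.meshgrid(lons, lats)
    glon, glat = glon.ravel()[:n_pixels], glat.ravel()[:n_pixels]
    dlat = (lat_range[1] - lat_range[0]) / max(ny - 1, 1)
    dlon = 360.0 / nx
    area = pixel_area_m2(glat, dlat, dlon)

    cov = rng.normal(0.0, 0.3, size=(n_pixels, n_covariates))
    cov[:, 0] += (np.abs(glat) - 35.0) / 35.0          # temperature-like axis
    if n_covariates > 1:
        cov[:, 1] += np.cos(np.radians(glat))          # greenness-like axis
    if coefficients is None:
        coefficients = np.zeros(n_covariates)
        coefficients[0] = 0.6                          # density rises poleward
        if n_covariates > 1:
            coefficients[1] = -0.3
    coefficients = np.asarray(coefficients, dtype=float)
    true_log10 = intercept + cov @ coefficients
    grid = pd.DataFrame(
        {
            "pixel_id": np.arange(n_pixels),
            "lat": glat,
            "lon": glon,
            "area_m2": area,
        }
    )
    for c in range(n_covariates):
        grid[f"cov_{c}"] = cov[:, c]
    true_total = float(np.sum(10.0 ** true_log10 * area))
    return SyntheticGrid(grid, coefficients, true_log10, true_total)


def sample_training_sites(
    synthetic_grid: SyntheticGrid,
    n_sites: int = 150,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw training sites from grid pixels with observation noise on the
    log10 response; carries covariates, coordinates and a bootstrap region."""
    rng = np.random.default_rng(seed)
    g = synthetic_grid.grid
    idx = rng.choice(len(g), size=n_sites, replace=False)
    df = g.iloc[idx].reset_index(drop=True).copy()
    df["log10_response"] = synthetic_grid.true_log10[idx] + rng.normal(
        0.0, noise_sd, size=n_sites
    )
    df["region"] = [_region_label(la, lo) for la, lo in zip(df["lat"], df["lon"])]
    return df
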