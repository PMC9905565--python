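"""Length-mass allometry, metabolic rates, and site-level community metrics.

Individual dry mass is predicted from body length with group-specific
log10-log10 regressions (several regressions per morphogroup are averaged on
the arithmetic scale), converted to fresh mass with a group conversion
factor, and fed into the metabolic-theory equation

    ln I = ln(i0) + a * ln(M) - E / (k * T)

with I the individual metabolic rate [J h-1], M fresh body mass [mg],
T mean annual topsoil temperature [K], ln(i0) = 21.972, a = 0.759,
E = 0.657 eV and k the Boltzmann constant (8.617e-5 eV K-1) — the
insect-specific coefficient set of the metabolic theory of ecology.

Coefficient uncertainty is propagated by evaluating every regression with
its coefficients shifted by +/- one standard error ("min" / "max" variants);
the shift direction is chosen per coefficient so that the variants bound the
prediction, which keeps min <= mean <= max for all body lengths including
those below 1 mm where a larger slope lowers the predicted mass.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

Variant = Literal["min", "mean", "max"]
_VARIANT_SIGN = {"min": -1.0, "mean": 0.0, "max": 1.0}


@dataclass(frozen=True)
class Regression:
    """One log10(dry mass [ug]) = intercept + slope * log10(length [mm]) fit."""

    intercept: float
    slope: float
    intercept_se: float = 0.0
    slope_se: float = 0.0


@dataclass
class AllometrySet:
    """Group-specific length-mass regressions and dry->fresh factors."""

    regressions: dict[str, list[Regression]]
    dry_fresh: dict[str, tuple[float, float]]  # group -> (factor, se)

    def __post_init__(self) -> None:
        for group, regs in self.regressions.items():
            if not regs:
                raise ValueError(f"no regressions for group {group!r}")
            for r in regs:
                if r.slope <= 0:
                    raise ValueError(f"non-positive slope for group {group!r}")
        for group, (factor, _se) in self.dry_fresh.items():
            if factor <= 1:
                raise ValueError(
                    f"dry->fresh factor must exceed 1 (group {group!r}): "
                    "fresh mass includes water and cannot be below dry mass"
                )

    @property
    def groups(self) -> list[str]:
        return sorted(self.regressions)

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "AllometrySet":
        """Build from a table with columns group, intercept, intercept_se,
        slope, slope_se, dry_fresh_factor, dry_fresh_se (one row per
        regression; the dry-fresh columns may repeat within a group)."""
        regs: dict[str, list[Regression]] = {}
        d2f: dict[str, tuple[float, float]] = {}
        for _, row in df.iterrows():
            g = str(row["group"])
            regs.setdefault(g, []).append(
                Regression(
                    float(row["intercept"]),
                    float(row["slope"]),
                    float(row.get("intercept_se", 0.0)),
                    float(row.get("slope_se", 0.0)),
                )
            )
            d2f[g] = (float(row["dry_fresh_factor"]), float(row.get("dry_fresh_se", 0.0)))
        return cls(regs, d2f)

    @classmethod
    def load_default(cls) -> "AllometrySet":
        """Packaged synthetic coefficient table (realistic magnitudes; swap in
        measured regression tables with the same columns for real analyses)."""
        ref = importlib.resources.files("springtail_metrics.data").joinpath(
            "allometry_synthetic.tsv"
        )
        with ref.open() as fh:
            df = pd.read_csv(fh, sep="\t", comment="#")
        return cls.from_table(df)


@dataclass(frozen=True)
class MetabolicConstants:
    """Insect coefficients for the Boltzmann-Arrhenius mass scaling of
    individual metabolism; mass in mg fresh weight, rate in J h-1."""

    ln_i0: float = 21.972       # ln-scale normalization [J h-1]
    a: float = 0.759            # allometric exponent
    E: float = 0.657            # activation energy [eV]
    k: float = 8.617e-5         # Boltzmann constant [eV K-1]


@dataclass(frozen=True)
class CarbonConversionConstants:
    """Energy <-> carbon bookkeeping for community metabolism totals."""

    energy_density: float = 7e6       # J per kg fresh mass
    water_fraction: float = 0.70      # fresh mass that is water
    carbon_fraction_of_dry: float = 0.45

    def __post_init__(self) -> None:
        if not (0 < self.water_fraction < 1 and 0 < self.carbon_fraction_of_dry < 1):
            raise ValueError("fractions must lie in (0, 1)")


DEFAULT_METABOLIC_CONSTANTS = MetabolicConstants()
DEFAULT_CARBON_CONSTANTS = CarbonConversionConstants()

CELSIUS_OFFSET = 273.15
HOURS_PER_MONTH = 730.5


def _check_variant(variant: str) -> float:
    if variant not in _VARIANT_SIGN:
        raise ValueError(f"variant must be min/mean/max, got {variant!r}")
    return _VARIANT_SIGN[variant]


def length_to_dry_mass(
    length_mm,
    morphogroup: str,
    allometry: AllometrySet,
    variant: Variant = "mean",
):
    """Dry mass [ug] from body length [mm] for one morphogroup.

    Each applicable regression is evaluated on the log10 scale and
    back-transformed; the per-regression masses are then averaged
    arithmetically.  ``variant`` shifts every coefficient by one SE in the
    direction that bounds the prediction.
    """
    L = np.asarray(length_mm, dtype=float)
    if np.any(L <= 0):
        raise ValueError("body length must be positive")
    sign = _check_variant(variant)
    try:
        regs = allometry.regressions[morphogroup]
    except KeyError:
        raise KeyError(
            f"morphogroup {morphogroup!r} not in allometry set "
            f"(known: {allometry.groups})"
        ) from None
    logL = np.log10(L)
    masses = []
    for r in regs:
        # |logL| makes the slope shift bound the prediction for L < 1 mm too
        logm = (
            r.intercept
            + sign * r.intercept_se
            + r.slope * logL
            + sign * r.slope_se * np.abs(logL)
        )
        masses.append(10.0 ** logm)
    out = np.mean(masses, axis=0)
    return float(out) if out.ndim == 0 else out


def dry_to_fresh(
    dry_mass_ug,
    morphogroup: str,
    allometry: AllometrySet,
    variant: Variant = "mean",
):
    """Fresh mass [ug] from dry mass via the group conversion factor."""
    m = np.asarray(dry_mass_ug, dtype=float)
    if np.any(m < 0):
        raise ValueError("dry mass must be >= 0")
    sign = _check_variant(variant)
    try:
        factor, se = allometry.dry_fresh[morphogroup]
    except KeyError:
        raise KeyError(f"no dry->fresh factor for morphogroup {morphogroup!r}") from None
    out = m * (factor + sign * se)
    return float(out) if out.ndim == 0 else out


def individual_metabolic_rate(
    fresh_mass_mg,
    temperature_k,
    constants: MetabolicConstants = DEFAULT_METABOLIC_CONSTANTS,
):
    """Individual metabolic rate [J h-1] at fresh mass [mg] and T [K]."""
    M = np.asarray(fresh_mass_mg, dtype=float)
    T = np.asarray(temperature_k, dtype=float)
    if np.any(M <= 0):
        raise ValueError("fresh mass must be positive")
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    out = np.exp(constants.ln_i0 + constants.a * np.log(M) - constants.E / (constants.k * T))
    return float(out) if out.ndim == 0 else out


def trimmed_community_mean(values, trim_fraction: float = 0.10) -> float:
    """Mean after dropping floor(n*trim) largest and smallest values.

    With n < 1/trim nothing is dropped; an empty input raises (no data is not
    zero).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot average an empty collection (no data != 0)")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    return float(stats.trim_mean(v, trim_fraction))


def energy_to_carbon(
    energy_j,
    constants: CarbonConversionConstants = DEFAULT_CARBON_CONSTANTS,
):
    """Convert an energy flux [J per time] to carbon mass [kg C per time].

    Energy -> kg fresh-mass-equivalent -> dry fraction -> carbon fraction.
    """
    e = np.asarray(energy_j, dtype=float)
    if np.any(e < 0):
        raise ValueError("energy flux must be >= 0")
    out = (
        e
        / constants.energy_density
        * (1.0 - constants.water_fraction)
        * constants.carbon_fraction_of_dry
    )
    return float(out) if out.ndim == 0 else out


@dataclass
class SiteMetrics:
    """Per-site community metrics (one coefficient variant)."""

    site_id: object
    n_samples: int
    density: float                          # individuals m-2
    dry_biomass: float | None               # mg m-2
    fresh_biomass: float | None             # mg m-2
    mean_body_mass: float | None            # ug dry, CWM trimmed across samples
    mean_individual_metabolism: float | None  # mJ h-1
    community_metabolism: float | None      # J h-1 m-2
    note: str = ""


def site_metrics(
    samples: pd.DataFrame,
    site: pd.Series | dict,
    traits: pd.DataFrame,
    allometry: AllometrySet,
    constants: MetabolicConstants = DEFAULT_METABOLIC_CONSTANTS,
    variant: Variant = "mean",
    trim_fraction: float = 0.10,
    trim_level: str = "sample",
) -> SiteMetrics:
    """Aggregate one site's samples into community metrics.

    ``samples`` holds this site's rows (sample_id, genus, abundance,
    sampling_area); ``traits`` maps genus -> body_length_mm, morphogroup.
    Density uses all specimens; mass/metabolism use only genus-matched
    specimens (records without genus-level identification are excluded).
    Community-weighted means are computed per sample and then trim-averaged
    across samples (``trim_level="specimen"`` instead pools and trims the
    specimen-level values).
    """
    if samples.empty:
        raise ValueError("site has no samples")
    if (samples["sampling_area"] <= 0).any():
        raise ValueError("sampling_area must be positive")
    site = dict(site)
    soil_t = site.get("soil_temperature")
    temp_k = None if soil_t is None or pd.isna(soil_t) else float(soil_t) + CELSIUS_OFFSET

    trait_map = traits.set_index("genus")[["body_length_mm", "morphogroup"]]

    dens_per_sample: list[float] = []
    biom_dry: list[float] = []
    biom_fresh: list[float] = []
    metab_area: list[float] = []
    cwm_mass: list[float] = []
    cwm_rate: list[float] = []
    spec_mass: list[np.ndarray] = []
    spec_rate: list[np.ndarray] = []

    for _sid, g in samples.groupby("sample_id", sort=True):
        area = float(g["sampling_area"].iloc[0])
        total = float(g["abundance"].sum())
        dens_per_sample.append(total / area)

        known = g[g.get("genus").notna()] if "genus" in g else g.iloc[0:0]
        known = known[known["genus"].isin(trait_map.index) & (known["abundance"] > 0)]
        if known.empty:
            continue
        tr = trait_map.loc[known["genus"]]
        ab = known["abundance"].to_numpy(dtype=float)
        dry = np.array(
            [
                length_to_dry_mass(L, grp, allometry, variant)
                for L, grp in zip(tr["body_length_mm"], tr["morphogroup"])
            ]
        )
        fresh = np.array(
            [
                dry_to_fresh(d, grp, allometry, variant)
                for d, grp in zip(dry, tr["morphogroup"])
            ]
        )
        biom_dry.append(float((ab * dry).sum()) / area / 1e3)     # ug -> mg
        biom_fresh.append(float((ab * fresh).sum()) / area / 1e3)
        cwm_mass.append(float((ab * dry).sum() / ab.sum()))
        spec_mass.append(np.repeat(dry, np.maximum(ab, 0).astype(int)))
        if temp_k is not None:
            rate = individual_metabolic_rate(fresh / 1e3, temp_k, constants)  # ug->mg
            metab_area.append(float((ab * rate).sum()) / area)
            cwm_rate.append(float((ab * rate).sum() / ab.sum()))
            spec_rate.append(np.repeat(rate, np.maximum(ab, 0).astype(int)))

    density = float(np.mean(dens_per_sample))
    note = ""
    if not biom_dry:
        note = "no genus-level traits: mass/metabolism metrics unavailable"
        return SiteMetrics(site.get("site_id"), samples["sample_id"].nunique(),
                           density, None, None, None, None, None, note)

    if trim_level == "specimen":
        mass_pool = np.concatenate(spec_mass)
        mean_mass = trimmed_community_mean(mass_pool, trim_fraction)
        mean_rate = (
            trimmed_community_mean(np.concatenate(spec_rate), trim_fraction) * 1e3
            if spec_rate else None
        )
    else:
        mean_mass = trimmed_community_mean(cwm_mass, trim_fraction)
        mean_rate = (
            trimmed_community_mean(cwm_rate, trim_fraction) * 1e3 if cwm_rate else None
        )
    if temp_k is None:
        note = "no soil temperature: metabolism unavailable"

    return SiteMetrics(
        site_id=site.get("site_id"),
        n_samples=samples["sample_id"].nunique(),
        density=density,
        dry_biomass=float(np.mean(biom_dry)),
        fresh_biomass=float(np.mean(biom_fresh)),
        mean_body_mass=mean_mass,
        mean_individual_metabolism=mean_rate,
        community_metabolism=float(np.mean(metab_area)) if metab_area else None,
        note=note,
    )


def compute_site_metrics(
    samples: pd.DataFrame,
    sites: pd.DataFrame,
    traits: pd.DataFrame,
    allometry: AllometrySet | None = None,
    constants: MetabolicConstants = DEFAULT_METABOLIC_CONSTANTS,
    variant: Variant = "mean",
    trim_fraction: float = 0.10,
) -> pd.DataFrame:
    """Site-metric table for every site present in ``samples``."""
    if allometry is None:
        allometry = AllometrySet.load_default()
    site_index = sites.set_index("site_id")
    rows = []
    for sid, g in samples.groupby("site_id", sort=True):
        site = site_index.loc[sid].to_dict() if sid in site_index.index else {}
        site["site_id"] = sid
        m = site_metrics(g, site, traits, allometry, constants, variant, trim_fraction)
        row = vars(m)
        for passthrough in ("latitude", "longitude", "habitat"):
            if passthrough in site:
                row[passthrough] = site[passthrough]
        rows.append(row)
    return pd.DataFrame(rows)
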