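"""Technical selection rules excluding unreliable site-level estimates.

Three layer/protocol rules remove density (and hence biomass/metabolism)
estimates from protocols that systematically miss part of the community;
a low-density outlier rule flags implausibly low densities within each
ecosystem type; and a sampling-effort rule restricts richness
extrapolation to adequately sampled, species-resolved sites.  The outlier
step is flag-only: exclusion happens through an explicit deny list,
mirroring the study's manual check while keeping the pipeline reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAYER_RULES = ("woodland_single_layer", "scrub_ground_cover_only", "temperate_agri_shallow_soil")


@dataclass
class FilterReport:
    """Which sites each rule excluded/flagged, and what survives per metric."""

    excluded: dict[str, set] = field(default_factory=dict)
    unevaluated: set = field(default_factory=set)
    flagged_low_density: set = field(default_factory=set)
    retained_density: set = field(default_factory=set)
    retained_richness: set = field(default_factory=set)

    @property
    def excluded_union(self) -> set:
        out: set = set()
        for s in self.excluded.values():
            out |= s
        return out

    def counts(self) -> dict[str, int]:
        c = {rule: len(s) for rule, s in self.excluded.items()}
        c["flagged_low_density"] = len(self.flagged_low_density)
        c["unevaluated"] = len(self.unevaluated)
        return c


def _layers_as_set(val) -> set | None:
    if val is None or (isinstance(val, float) and np.isnan(val)):
        return None
    if isinstance(val, (set, frozenset)):
        return set(val)
    if isinstance(val, str):
        parts = {p.strip() for p in val.replace(";", "+").split("+") if p.strip()}
        return parts or None
    return set(val)


def apply_layer_rules(sites: pd.DataFrame) -> FilterReport:
    """Apply the three protocol rules to a site table.

    ``sites`` needs columns site_id, habitat, climate_band, layers
    (set-like or "+"-joined string of {litter, soil, other_cover}) and
    sampling_depth (cm; may be NaN).  Rules are independent; the exclusion
    is their union.  Sites with missing layer metadata are not excludable
    and are reported as unevaluated.
    """
    report = FilterReport(excluded={r: set() for r in LAYER_RULES})
    for _, row in sites.iterrows():
        sid = row["site_id"]
        layers = _layers_as_set(row.get("layers"))
        if layers is None:
            report.unevaluated.add(sid)
            continue
        habitat = row.get("habitat")
        band = row.get("climate_band")
        depth = row.get("sampling_depth")
        if habitat == "woodland" and (layers == {"soil"} or layers == {"litter"}):
            report.excluded["woodland_single_layer"].add(sid)
        if habitat == "scrub" and layers <= {"litter", "other_cover"}:
            report.excluded["scrub_ground_cover_only"].add(sid)
        if (
            habitat == "agriculture"
            and band == "temperate"
            and layers == {"soil"}
            and depth is not None
            and not pd.isna(depth)
            and float(depth) < 10.0
        ):
            report.excluded["temperate_agri_shallow_soil"].add(sid)
    all_ids = set(sites["site_id"])
    report.retained_density = all_ids - report.excluded_union
    return report


def low_density_outlier_flags(
    site_densities: pd.DataFrame,
    min_sites: int = 20,
    quantile_method: str = "linear",
) -> set:
    """Flag implausibly low densities within each ecosystem type.

    A site is flagged when it is BOTH within the lowest 10% of its ecosystem
    type AND below one third of the type's 1st percentile (linear-interpolation
    quantiles by default).  Types with fewer than ``min_sites`` sites give no
    flags (the percentile is not estimable) and raise a warning.
    """
    needed = {"site_id", "ecosystem_type", "density"}
    if not needed <= set(site_densities.columns):
        raise ValueError(f"need columns {sorted(needed)}")
    flagged: set = set()
    for eco, g in site_densities.groupby("ecosystem_type"):
        if len(g) < min_sites:
            warnings.warn(
                f"ecosystem type {eco!r} has {len(g)} sites (<{min_sites}); "
                "1% percentile not estimated, no outlier flags"
            )
            continue
        d = g["density"].to_numpy(dtype=float)
        p10 = np.quantile(d, 0.10, method=quantile_method)
        p1 = np.quantile(d, 0.01, method=quantile_method)
        mask = (d <= p10) & (d < p1 / 3.0)
        flagged |= set(g.loc[mask, "site_id"])
    return flagged


def richness_eligibility(
    sites: pd.DataFrame, min_samples: int = 3
) -> set:
    """Sites whose richness extrapolation is retained.

    Requires >= ``min_samples`` samples and (morpho)species-level
    identification; pooled-list sites are handled separately by the
    completeness model and are not returned here.  ``sites`` needs columns
    site_id, n_samples, species_level (bool); an optional ``pooled`` column
    marks pooled-list sites.
    """
    df = sites
    ok = (df["n_samples"] >= min_samples) & df["species_level"].astype(bool)
    if "pooled" in df.columns:
        ok &= ~df["pooled"].astype(bool)
    return set(df.loc[ok, "site_id"])


def apply_filters(
    sites: pd.DataFrame,
    site_densities: pd.DataFrame | None = None,
    richness_sites: pd.DataFrame | None = None,
    denylist: set | None = None,
    min_sites_per_type: int = 20,
) -> FilterReport:
    """Run all technical rules; order-independent by construction.

    ``denylist`` holds site ids confirmed for exclusion after manual review
    of the low-density flags; only flagged ids in the denylist are removed
    from the retained density set.
    """
    report = apply_layer_rules(sites)
    if site_densities is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report.flagged_low_density = low_density_outlier_flags(
                site_densities, min_sites=min_sites_per_type
            )
        confirmed = report.flagged_low_density & (denylist or set())
        report.retained_density -= confirmed
    if richness_sites is not None:
        report.retained_richness = richness_eligibility(richness_sites)
    return report
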