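"""Latitudinal-belt and ecosystem-type summaries of site metrics.

Sites are binned into 5-degree latitudinal belts (edges at multiples of the
belt width, half-open on the poleward side) and averaged with a symmetric
trim so each belt carries the same statistical weight regardless of how
densely it was sampled.  Skewed metrics (density, biomass, metabolism) are
averaged on the log10 scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .allometry import trimmed_community_mean
from .ingest import RETAINED_ECOSYSTEM_TYPES


def log10_metric(values):
    """Elementwise log10 for strictly positive metrics."""
    v = np.asarray(values, dtype=float)
    if np.any(~(v > 0)):
        raise ValueError(
            "log10 transform needs strictly positive values; "
            "filter zero/negative entries first (they are not missing data)"
        )
    out = np.log10(v)
    return float(out) if out.ndim == 0 else out


def belt_averages(
    site_metrics: pd.DataFrame,
    metric: str,
    belt_width: float = 5.0,
    trim_fraction: float = 0.10,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Trimmed per-belt averages of one site metric.

    Belt edges sit at multiples of ``belt_width``; a site at an edge joins
    the belt whose lower edge it equals ([lo, hi) convention).  With
    ``log_scale`` the trimmed mean is taken on log10 values and
    back-transformed (a trimmed geometric mean).  Empty belts are omitted.
    Returns columns belt_lo, belt_hi, belt_mid, mean, n_sites.
    """
    df = site_metrics.dropna(subset=["latitude", metric])
    if log_scale:
        log10_metric(df[metric].to_numpy())  # reject zero/negative up front
    lo = np.floor(df["latitude"].to_numpy() / belt_width) * belt_width
    rows = []
    for edge in sorted(set(lo)):
        vals = df.loc[lo == edge, metric].to_numpy(dtype=float)
        if log_scale:
            mean = 10.0 ** trimmed_community_mean(np.log10(vals), trim_fraction)
        else:
            mean = trimmed_community_mean(vals, trim_fraction)
        rows.append(
            {
                "belt_lo": edge,
                "belt_hi": edge + belt_width,
                "belt_mid": edge + belt_width / 2.0,
                "mean": mean,
                "n_sites": vals.size,
            }
        )
    return pd.DataFrame(rows)


def ecosystem_summary(
    site_metrics: pd.DataFrame,
    metric: str,
    retained_only: bool = True,
) -> pd.DataFrame:
    """Median, quartiles and n of one metric per ecosystem type."""
    df = site_metrics.dropna(subset=["ecosystem_type", metric])
    if retained_only:
        df = df[df["ecosystem_type"].isin(RETAINED_ECOSYSTEM_TYPES)]
    rows = []
    for eco, g in df.groupby("ecosystem_type", sort=True):
        v = g[metric].to_numpy(dtype=float)
        rows.append(
            {
                "ecosystem_type": eco,
                "median": float(np.median(v)),
                "q1": float(np.quantile(v, 0.25)),
                "q3": float(np.quantile(v, 0.75)),
                "n_sites": v.size,
            }
        )
    return pd.DataFrame(rows)


def quadratic_trend(belts: pd.DataFrame, log_scale: bool = True) -> np.ndarray:
    """Degree-2 OLS fit of belt means on belt midpoints (figure smoother).

    Returns polynomial coefficients (highest degree first, np.polyfit order).
    """
    y = belts["mean"].to_numpy(dtype=float)
    if log_scale:
        y = np.log10(y)
    return np.polyfit(belts["belt_mid"].to_numpy(dtype=float), y, deg=2)
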