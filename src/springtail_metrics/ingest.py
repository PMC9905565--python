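"""Reading, validation and harmonization of community tables.

The atomic input is one soil sample's taxon abundance record together with
site metadata (coordinates, habitat, mean annual topsoil temperature).
Taxon names are harmonized against a packaged genus checklist with
Levenshtein fuzzy matching; sites are classified into climate bands
(polar / temperate / tropical) and band x habitat ecosystem types.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

#: Columns a community table must provide (after schema renaming).
SAMPLE_COLUMNS = ("site_id", "sample_id", "taxon", "abundance", "sampling_area")

#: Optional per-sample metadata the pipeline can use when present.
SAMPLE_OPTIONAL = ("sampling_depth", "layers", "method", "year", "month")

#: Columns a site table must provide.
SITE_COLUMNS = ("site_id", "latitude", "longitude", "habitat")
SITE_OPTIONAL = ("soil_temperature", "air_temperature", "elevation")

HABITATS = ("woodland", "scrub", "grassland", "agriculture", "other")
CLIMATE_BANDS = ("polar", "temperate", "tropical")

#: The nine well-represented band x habitat combinations retained for
#: ecosystem-level comparisons ("tropical_woodland" is tropical forest).
RETAINED_ECOSYSTEM_TYPES = frozenset(
    {
        "polar_scrub",
        "polar_grassland",
        "polar_woodland",
        "temperate_woodland",
        "temperate_scrub",
        "temperate_grassland",
        "temperate_agriculture",
        "tropical_agriculture",
        "tropical_woodland",
    }
)


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


@dataclass(frozen=True)
class TaxonMatch:
    """Outcome of matching one raw taxon name against the checklist."""

    raw_name: str
    matched_name: str | None
    genus: str | None
    distance: int | None
    status: str  # "exact" | "fuzzy" | "unmatched"


@dataclass
class IngestResult:
    """Community samples + deduplicated sites + per-row rejection log."""

    samples: pd.DataFrame
    sites: pd.DataFrame
    rejections: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> dict:
        return {
            "n_rows": len(self.samples) + len(self.rejections),
            "n_samples_rows": len(self.samples),
            "n_sites": self.sites["site_id"].nunique() if len(self.sites) else 0,
            "n_rejected": len(self.rejections),
        }


def load_default_checklist() -> list[str]:
    """Packaged genus-level Collembola checklist (names only, offline)."""
    ref = importlib.resources.files("springtail_metrics.data").joinpath(
        "collembola_checklist.txt"
    )
    names = []
    for line in ref.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.append(line)
    return names


def levenshtein(a: str, b: str) -> int:
    """Case-insensitive Levenshtein edit distance (via edlib)."""
    a, b = a.lower(), b.lower()
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def harmonize_taxon(
    raw_name: str, checklist: Sequence[str], max_distance: int = 2
) -> TaxonMatch:
    """Match ``raw_name`` to the nearest checklist name within ``max_distance``.

    The comparison is genus-based: only the first whitespace token of the raw
    name is matched (species epithets are kept verbatim on the caller's side).
    Ties are broken by smallest distance, then alphabetically, so the result
    is deterministic.
    """
    if not checklist:
        raise ValueError("checklist must be non-empty")
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    raw = (raw_name or "").strip()
    if not raw:
        return TaxonMatch(raw_name, None, None, None, "unmatched")
    genus_token = raw.split()[0]
    best_name, best_dist = None, None
    for name in sorted(checklist):
        d = levenshtein(genus_token, name)
        if best_dist is None or d < best_dist:
            best_name, best_dist = name, d
        if best_dist == 0:
            break
    if best_dist is not None and best_dist <= max_distance:
        status = "exact" if best_dist == 0 else "fuzzy"
        return TaxonMatch(raw_name, best_name, best_name.split()[0], best_dist, status)
    return TaxonMatch(raw_name, None, None, best_dist, "unmatched")


def harmonize_table(
    samples: pd.DataFrame,
    checklist: Sequence[str] | None = None,
    max_distance: int = 2,
) -> pd.DataFrame:
    """Attach ``genus`` / ``match_status`` columns to a sample table."""
    if checklist is None:
        checklist = load_default_checklist()
    cache: dict[str, TaxonMatch] = {}
    out = samples.copy()
    genera, statuses = [], []
    for raw in out["taxon"].astype(str):
        m = cache.get(raw)
        if m is None:
            m = harmonize_taxon(raw, checklist, max_distance)
            cache[raw] = m
        genera.append(m.genus)
        statuses.append(m.status)
    out["genus"] = genera
    out["match_status"] = statuses
    return out


def classify_climate_band(latitude):
    """Climate band from latitude: |lat| > 66.5 polar, > 23.5 temperate,
    else tropical.  Boundaries are closed on the equatorward side
    (66.5 -> temperate, 23.5 -> tropical).  Accepts scalars or arrays.
    """
    lat = np.asarray(latitude, dtype=float)
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude outside [-90, 90]")
    a = np.abs(lat)
    out = np.where(a > 66.5, "polar", np.where(a > 23.5, "temperate", "tropical"))
    if np.isscalar(latitude) or np.ndim(latitude) == 0:
        return str(out)
    return out


def ecosystem_type(climate_band: str, habitat: str) -> tuple[str, bool]:
    """Combine band and habitat into an ecosystem-type label.

    Returns ``(label, retained)`` where ``retained`` flags the nine
    well-represented combinations used for ecosystem comparisons.
    """
    if climate_band not in CLIMATE_BANDS:
        raise ValueError(f"unknown climate band {climate_band!r}")
    if habitat not in HABITATS:
        raise ValueError(f"unknown habitat {habitat!r}")
    label = f"{climate_band}_{habitat}"
    return label, label in RETAINED_ECOSYSTEM_TYPES


def _rename(df: pd.DataFrame, schema: Mapping[str, str] | None) -> pd.DataFrame:
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    return df


def read_community_table(
    path,
    schema: Mapping[str, str] | None = None,
    site_path=None,
    sep: str | None = None,
) -> IngestResult:
    """Read a delimited community table into samples + sites.

    Parameters
    ----------
    path
        Delimited text (comma or tab; sniffed when ``sep`` is None), one row
        per sample x taxon.  May also carry the site columns, in which case
        sites are deduplicated from it; otherwise pass ``site_path``.
    schema
        Mapping from canonical column names (``site_id`` ...) to the file's
        column names, for files with non-standard headers.

    Rows with missing/negative/non-numeric abundance or non-positive sampling
    area are rejected individually and reported in ``result.rejections``;
    row count is conserved (kept + rejected = read).
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    df = _rename(df, schema)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    reasons = pd.Series("", index=df.index, dtype=object)
    abundance = pd.to_numeric(df["abundance"], errors="coerce")
    area = pd.to_numeric(df["sampling_area"], errors="coerce")
    reasons[abundance.isna()] = "non-numeric abundance"
    reasons[abundance < 0] = "negative abundance"
    reasons[(area.isna() | (area <= 0)) & (reasons == "")] = "invalid sampling_area"

    bad = reasons != ""
    rejections = df.loc[bad].copy()
    rejections["reason"] = reasons[bad]
    samples = df.loc[~bad].copy()
    samples["abundance"] = abundance[~bad]
    samples["sampling_area"] = area[~bad]

    if site_path is not None:
        sdf = _rename(pd.read_csv(site_path, sep=sep, engine="python"), schema)
    else:
        site_cols = [c for c in SITE_COLUMNS + SITE_OPTIONAL if c in samples.columns]
        sdf = samples[site_cols].drop_duplicates("site_id") if site_cols else pd.DataFrame()
    if len(sdf):
        missing_site = [c for c in SITE_COLUMNS if c not in sdf.columns]
        if missing_site:
            raise SchemaError(f"missing mandatory site column(s): {missing_site}")
        lat = pd.to_numeric(sdf["latitude"], errors="raise")
        lon = pd.to_numeric(sdf["longitude"], errors="raise")
        if (lat.abs() > 90).any() or (lon.abs() > 180).any():
            raise ValueError("site coordinates out of bounds")
        sdf = sdf.drop_duplicates("site_id").reset_index(drop=True)
    return IngestResult(samples.reset_index(drop=True), sdf, rejections.reset_index(drop=True))


def attach_climate(sites: pd.DataFrame) -> pd.DataFrame:
    """Add ``climate_band``, ``ecosystem_type`` and ``retained_type`` columns."""
    out = sites.copy()
    out["climate_band"] = classify_climate_band(out["latitude"].to_numpy())
    labels, retained = [], []
    for band, hab in zip(out["climate_band"], out["habitat"]):
        lab, ret = ecosystem_type(band, hab)
        labels.append(lab)
        retained.append(ret)
    out["ecosystem_type"] = labels
    out["retained_type"] = retained
    return out
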