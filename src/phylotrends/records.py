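"""Occurrence-record cleaning and assemblage construction.

Cleaning applies four rules in a fixed order, charging each removed row to
the first rule it fails so the accounting always balances:

1. missing species name (after whitespace normalization),
2. missing, malformed or out-of-bounds GPS coordinates,
3. missing or malformed collection year,
4. sequence length outside [length_min, length_max] bp (600 and 700 pass;
   removal is for strictly shorter/longer barcodes).

Assemblages are then the deduplicated species sets sharing one rounded
coordinate (2 decimal places, ~1 km) and collection year; assemblages with
fewer than ``min_species`` distinct species are dropped and counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._util import centideg, round_half_away

__all__ = [
    "FilterReport",
    "Assemblage",
    "RegionBox",
    "DEFAULT_REGION_BOXES",
    "read_occurrences",
    "apply_filters",
    "build_assemblages",
    "assign_region",
    "assign_regions",
    "join_covariates",
]

FILTER_RULES = ("missing_species", "invalid_coordinates", "missing_year", "length_out_of_range")


@dataclass
class FilterReport:
    """Sequential-rule removal accounting for one cleaning pass."""

    input_count: int
    removed: Dict[str, int]
    malformed: Dict[str, int]
    output_count: int
    extra: Dict[str, int] = field(default_factory=dict)

    def balances(self) -> bool:
        return self.input_count == self.output_count + sum(self.removed.values())

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "removed": dict(self.removed),
            "malformed_subcounts": dict(self.malformed),
            "output_count": self.output_count,
            **({"assemblage_stage": dict(self.extra)} if self.extra else {}),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def read_occurrences(path) -> pd.DataFrame:
    """Read an occurrence CSV/TSV as strings; empty cells stay empty strings."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _normalize_species(col: pd.Series) -> pd.Series:
    return col.fillna("").astype(str).str.strip().str.replace(r"\s+", " ", regex=True)


def _numeric(col: pd.Series) -> Tuple[pd.Series, pd.Series, pd.Series]:
    """Parse a possibly-string column → (values, missing mask, malformed mask)."""
    as_str = col.fillna("").astype(str).str.strip()
    missing = as_str == ""
    values = pd.to_numeric(as_str, errors="coerce")
    malformed = values.isna() & ~missing
    return values, missing, malformed


def apply_filters(
    records: pd.DataFrame, length_min: int = 600, length_max: int = 700
) -> Tuple[pd.DataFrame, FilterReport]:
    """Apply the four cleaning rules; return (clean typed table, report).

    Unparseable numeric fields count toward their rule's removal total and
    are also reported in a per-rule ``malformed`` subcount. The returned
    table has typed columns (float coordinates, int year and length) and
    whitespace-normalized species names.
    """
    df = records.reset_index(drop=True)
    n = len(df)
    species = _normalize_species(df.get("species", pd.Series([""] * n)))
    lat, lat_missing, lat_bad = _numeric(df["decimal_latitude"])
    lon, lon_missing, lon_bad = _numeric(df["decimal_longitude"])
    year, year_missing, year_bad = _numeric(df["year"])
    length, len_missing, len_bad = _numeric(df["seq_length_bp"])

    out_of_bounds = (lat.abs() > 90) | (lon.abs() > 180)
    fail_species = species == ""
    fail_coords = lat_missing | lon_missing | lat_bad | lon_bad | out_of_bounds
    fail_year = year_missing | year_bad
    fail_length = len_missing | len_bad | (length < length_min) | (length > length_max)

    charged = pd.Series("", index=df.index)
    for rule, mask in (
        ("missing_species", fail_species),
        ("invalid_coordinates", fail_coords),
        ("missing_year", fail_year),
        ("length_out_of_range", fail_length),
    ):
        charged = charged.mask((charged == "") & mask.astype(bool), rule)

    removed = {rule: int((charged == rule).sum()) for rule in FILTER_RULES}
    malformed = {
        "invalid_coordinates": int(((charged == "invalid_coordinates") & (lat_bad | lon_bad)).sum()),
        "missing_year": int(((charged == "missing_year") & year_bad).sum()),
        "length_out_of_range": int(((charged == "length_out_of_range") & len_bad).sum()),
    }
    keep = charged == ""
    clean = df.loc[keep].copy()
    clean["species"] = species[keep]
    clean["decimal_latitude"] = lat[keep].astype(float)
    clean["decimal_longitude"] = lon[keep].astype(float)
    clean["year"] = year[keep].astype(int)
    clean["seq_length_bp"] = length[keep].astype(int)
    report = FilterReport(
        input_count=n,
        removed=removed,
        malformed=malformed,
        output_count=int(keep.sum()),
    )
    return clean.reset_index(drop=True), report


@dataclass(frozen=True)
class Assemblage:
    """Deduplicated species set at one (lat_2dp, lon_2dp, year) key."""

    lat_2dp: float
    lon_2dp: float
    year: int
    species: frozenset
    region: str = "unassigned"

    @property
    def richness(self) -> int:
        return len(self.species)


def build_assemblages(
    records: pd.DataFrame, min_species: int = 10
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Bin filtered records into assemblages at 2-dp coordinates per year.

    Coordinates are rounded half-away-from-zero at 2 decimals; species are
    deduplicated within each (lat, lon, year) group; groups with fewer than
    ``min_species`` distinct species are dropped. Returns the assemblage
    frame (columns lat_2dp, lon_2dp, year, richness, species tuple) sorted
    by site key, plus an accounting addendum.
    """
    df = records.copy()
    df["lat_2dp"] = df["decimal_latitude"].map(round_half_away)
    df["lon_2dp"] = df["decimal_longitude"].map(round_half_away)
    grouped = df.groupby(["lat_2dp", "lon_2dp", "year"], sort=True)["species"]
    rows = []
    dup_removed = 0
    dropped_small = 0
    for (lat2, lon2, yr), sp in grouped:
        uniq = sorted(set(sp))
        dup_removed += len(sp) - len(uniq)
        if len(uniq) < min_species:
            dropped_small += 1
            continue
        rows.append(
            {
                "lat_2dp": lat2,
                "lon_2dp": lon2,
                "year": int(yr),
                "richness": len(uniq),
                "species": tuple(uniq),
            }
        )
    frame = pd.DataFrame(rows, columns=["lat_2dp", "lon_2dp", "year", "richness", "species"])
    addendum = {
        "input_records": int(len(df)),
        "duplicate_records_removed": int(dup_removed),
        "assemblages_dropped_small": int(dropped_small),
        "assemblages": int(len(frame)),
    }
    return frame, addendum


@dataclass(frozen=True)
class RegionBox:
    """Half-open lat/lon rectangle [lat_min, lat_max) × [lon_min, lon_max)."""

    label: str
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def contains(self, lat: float, lon: float) -> bool:
        return self.lat_min <= lat < self.lat_max and self.lon_min <= lon < self.lon_max


# Six continental regions as configurable rectangles (a region may own more
# than one box). Boxes are mutually disjoint; points outside every box
# (open ocean, Antarctica) stay "unassigned".
DEFAULT_REGION_BOXES: Tuple[RegionBox, ...] = (
    RegionBox("North America", 5.0, 85.0, -170.0, -30.0),
    RegionBox("South America", -60.0, 5.0, -95.0, -30.0),
    RegionBox("Europe", 35.0, 75.0, -30.0, 45.0),
    RegionBox("Africa/Arabia", -40.0, 35.0, -30.0, 60.0),
    RegionBox("Asia", 35.0, 80.0, 45.0, 180.0),
    RegionBox("Asia", -10.0, 35.0, 60.0, 180.0),
    RegionBox("Australasia", -50.0, -10.0, 90.0, 180.0),
)


def assign_region(lat: float, lon: float, region_boxes=DEFAULT_REGION_BOXES) -> str:
    """Label of the first box containing the point, else 'unassigned'."""
    for box in region_boxes:
        if box.contains(lat, lon):
            return box.label
    return "unassigned"


def assign_regions(assemblages: pd.DataFrame, region_boxes=DEFAULT_REGION_BOXES) -> pd.DataFrame:
    out = assemblages.copy()
    out["region"] = [
        assign_region(la, lo, region_boxes)
        for la, lo in zip(out["lat_2dp"], out["lon_2dp"])
    ]
    return out


COVARIATE_COLUMNS = ("temperature", "precipitation", "elevation", "land_cover")


def join_covariates(
    assemblages: pd.DataFrame, covariates: Optional[pd.DataFrame]
) -> pd.DataFrame:
    """Exact 2-dp key join of site covariates onto the assemblage table.

    Covariate rows are keyed by (lat_2dp, lon_2dp); duplicate keys raise.
    Assemblages without a covariate row keep missing covariate cells and
    get ``has_covariates = False`` (usable for latitude × year models,
    excluded from environmental models).
    """
    out = assemblages.copy()
    if covariates is None or len(covariates) == 0:
        for c in COVARIATE_COLUMNS:
            out[c] = np.nan
        out["has_covariates"] = False
        return out
    cov = covariates.copy()
    cov["_key"] = [
        (centideg(la), centideg(lo)) for la, lo in zip(cov["lat_2dp"], cov["lon_2dp"])
    ]
    if cov["_key"].duplicated().any():
        dups = cov.loc[cov["_key"].duplicated(), "_key"].tolist()
        raise ValueError(f"duplicate covariate keys: {dups[:5]}")
    cov = cov.set_index("_key")
    keys = [(centideg(la), centideg(lo)) for la, lo in zip(out["lat_2dp"], out["lon_2dp"])]
    matched = [k in cov.index for k in keys]
    for c in COVARIATE_COLUMNS:
        if c in cov.columns:
            out[c] = [cov.at[k, c] if ok else np.nan for k, ok in zip(keys, matched)]
        else:
            out[c] = np.nan
    out["has_covariates"] = matched
    return out
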