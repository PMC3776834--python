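"""Reading, validating, projecting and thinning occurrence records.

Occurrence tables are delimited text with at least a species identifier and
WGS84 longitude/latitude; the canonical in-memory container is a pandas
DataFrame with columns ``species_id, lon, lat, precision_m, source`` plus,
after projection, ``x, y`` in metres.  Management polygons (protected areas,
mining footprints, named geographic features) travel as GeoJSON
FeatureCollections whose features carry a ``role`` property.

Validation never silently drops rows: every rejected row is counted and the
reason recorded in the returned :class:`ValidationReport`.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.validation import make_valid

from .grids import GridSpec
from .projection import TransverseMercator

__all__ = [
    "CANONICAL_COLUMNS",
    "ValidationReport",
    "ManagementLayers",
    "read_occurrences",
    "write_occurrences",
    "project_records",
    "dedupe_for_model",
    "read_management_layers",
    "write_management_layers",
]

CANONICAL_COLUMNS = ("species_id", "lon", "lat", "precision_m", "source")

ROLES = ("protected", "mining", "named_feature")


@dataclass
class ValidationReport:
    """Counts of accepted and rejected rows, with per-reason tallies."""

    n_read: int = 0
    n_accepted: int = 0
    reasons: Counter = field(default_factory=Counter)

    @property
    def n_rejected(self) -> int:
        return self.n_read - self.n_accepted


def read_occurrences(
    path,
    dialect: dict | None = None,
    sep: str | None = None,
    study_extent: tuple[float, float, float, float] | None = None,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate an occurrence table.

    Parameters
    ----------
    path : str or file
        Delimited text file; comma or tab separated (sniffed unless ``sep``).
    dialect : dict, optional
        Mapping from canonical column names to the file's column names, e.g.
        ``{"species_id": "taxon", "lon": "longitude"}``.  Unmapped canonical
        names are looked up verbatim; ``precision_m`` and ``source`` are
        optional.
    study_extent : (lon_min, lat_min, lon_max, lat_max), optional
        Records outside this box are rejected (and counted).

    Returns
    -------
    records : DataFrame with the canonical columns.
    report : ValidationReport with rejection reasons.
    """
    dialect = dialect or {}
    raw = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    colmap = {canon: dialect.get(canon, canon) for canon in CANONICAL_COLUMNS}
    for canon in ("species_id", "lon", "lat"):
        if colmap[canon] not in raw.columns:
            raise KeyError(
                f"required column {colmap[canon]!r} (for {canon!r}) not in table; "
                f"available: {list(raw.columns)}"
            )

    report = ValidationReport(n_read=len(raw))
    species = raw[colmap["species_id"]].astype(str).str.strip()
    lon = pd.to_numeric(raw[colmap["lon"]], errors="coerce")
    lat = pd.to_numeric(raw[colmap["lat"]], errors="coerce")

    ok = pd.Series(True, index=raw.index)

    def reject(mask, reason):
        nonlocal ok
        mask = mask & ok
        report.reasons[reason] += int(mask.sum())
        ok &= ~mask

    reject(species.eq("") | species.str.lower().eq("nan"), "empty species_id")
    reject(lon.isna() | lat.isna(), "unparseable coordinate")
    reject(~lon.between(-180, 180) | ~lat.between(-90, 90), "coordinate out of bounds")
    if study_extent is not None:
        x0, y0, x1, y1 = study_extent
        reject(~(lon.between(x0, x1) & lat.between(y0, y1)), "outside study extent")

    out = pd.DataFrame(
        {
            "species_id": species[ok],
            "lon": lon[ok],
            "lat": lat[ok],
        }
    )
    if colmap["precision_m"] in raw.columns:
        prec = pd.to_numeric(raw[colmap["precision_m"]], errors="coerce")
        prec = prec.where(prec > 0)
        out["precision_m"] = prec[ok]
    else:
        out["precision_m"] = np.nan
    if colmap["source"] in raw.columns:
        out["source"] = raw[colmap["source"]][ok]
    else:
        out["source"] = ""
    out = out.reset_index(drop=True)
    report.n_accepted = len(out)
    return out, report


def write_occurrences(records: pd.DataFrame, path) -> None:
    """Write the canonical occurrence table (CSV with the canonical header)."""
    records.loc[:, list(CANONICAL_COLUMNS)].to_csv(path, index=False)


def project_records(records: pd.DataFrame, projection: TransverseMercator) -> pd.DataFrame:
    """Add projected metre coordinates ``x, y`` to a record table.

    Raises if any record lies outside the projection's validity band; the
    error lists offending row indices.
    """
    x, y = projection.forward(records["lon"].to_numpy(), records["lat"].to_numpy())
    out = records.copy()
    out["x"] = x
    out["y"] = y
    return out


def flag_imprecise(records: pd.DataFrame, cell_km: float) -> pd.DataFrame:
    """Flag records whose stated precision is worse than half the analysis cell.

    Flagged records stay in the table (``imprecise`` boolean column); callers
    that need precisely-located records only can filter on it.
    """
    out = records.copy()
    half_cell_m = cell_km * 1000.0 / 2.0
    prec = out.get("precision_m")
    out["imprecise"] = prec.notna() & (prec > half_cell_m) if prec is not None else False
    return out


def dedupe_for_model(records: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Keep at most one record per (species, grid cell).

    Duplicate records of the *same* species in a cell are collapsed to one;
    records of *different* species in the same cell are all retained, so
    cells rich in species keep their full species list.  Output is ordered
    by species_id, then cell row, then cell column (deterministic).
    """
    if not {"x", "y"}.issubset(records.columns):
        raise ValueError("records must be projected (x, y) before dedupe")
    ix, iy = grid.cell_index(records["x"].to_numpy(), records["y"].to_numpy())
    out = records.copy()
    out["_ix"] = ix
    out["_iy"] = iy
    out = (
        out.sort_values(["species_id", "_iy", "_ix"], kind="mergesort")
        .drop_duplicates(subset=["species_id", "_ix", "_iy"], keep="first")
        .drop(columns=["_ix", "_iy"])
        .reset_index(drop=True)
    )
    return out


@dataclass
class ManagementLayers:
    """Protected areas, mining footprints, named features and species lists.

    Polygons are shapely geometries on the analysis plane (metres).  Invalid
    polygons are repaired with ``make_valid`` on load; a polygon that cannot
    be repaired raises.
    """

    protected_areas: list = field(default_factory=list)
    mining_areas: list = field(default_factory=list)
    named_features: dict = field(default_factory=dict)
    protected_species: dict = field(default_factory=dict)  # jurisdiction -> set of species_id

    def all_polygons(self):
        yield from self.protected_areas
        yield from self.mining_areas
        yield from self.named_features.values()


def _repair(geom, label):
    if geom.is_valid:
        return geom
    fixed = make_valid(geom)
    if not fixed.is_valid or fixed.is_empty:
        raise ValueError(f"polygon {label!r} invalid and could not be repaired")
    return fixed


def read_management_layers(path) -> ManagementLayers:
    """Load a GeoJSON FeatureCollection with ``role`` properties.

    Roles: ``protected``, ``mining``, ``named_feature`` (the latter requires
    a ``name`` property).  A top-level ``protected_species`` member, if
    present, maps jurisdiction labels to species lists.
    """
    with open(path) as fh:
        doc = json.load(fh)
    layers = ManagementLayers()
    for i, feat in enumerate(doc.get("features", [])):
        role = feat.get("properties", {}).get("role")
        geom = _repair(shape(feat["geometry"]), feat.get("properties", {}).get("name", f"feature {i}"))
        if role == "protected":
            layers.protected_areas.append(geom)
        elif role == "mining":
            layers.mining_areas.append(geom)
        elif role == "named_feature":
            name = feat["properties"]["name"]
            layers.named_features[name] = geom
        else:
            raise ValueError(f"feature {i} has unknown role {role!r}; expected one of {ROLES}")
    for juris, splist in doc.get("protected_species", {}).items():
        layers.protected_species[juris] = set(splist)
    return layers


def write_management_layers(layers: ManagementLayers, path) -> None:
    features = []
    for geom in layers.protected_areas:
        features.append({"type": "Feature", "properties": {"role": "protected"}, "geometry": mapping(geom)})
    for geom in layers.mining_areas:
        features.append({"type": "Feature", "properties": {"role": "mining"}, "geometry": mapping(geom)})
    for name, geom in layers.named_features.items():
        features.append(
            {"type": "Feature", "properties": {"role": "named_feature", "name": name}, "geometry": mapping(geom)}
        )
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "protected_species": {j: sorted(s) for j, s in layers.protected_species.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
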