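"""Protection and mining-threat scoring for species and endemism hotspots.

Each narrow-endemic species is scored by the fraction of its records falling
inside protected areas and inside mining footprints (point-in-polygon with
boundary points counted as inside), and by whether it appears on a
jurisdiction's protected-species list.  Species whose entire recorded range
is mined, unlisted and unprotected are the highest-priority conservation
flags; a second tier covers species with at least half their records mined.

Hotspot cells are scored analogously: protected when the cell intersects a
protected polygon, mining-impacted when it intersects *or shares an edge
with* a mining polygon (corner-only contact does not count), and labelled
with the cell's modal substrate ('A/B' when two classes each cover at least
40% of the cell).

The module also ships a transcription of the published New Caledonian
hotspot table (36 cells with >7 NES each) used as a fixture for the tabular
summaries.
"""

from __future__ import annotations

import re
from importlib import resources

import numpy as np
import pandas as pd
from shapely.prepared import prep

from .grids import Raster
from .hotspot_grid import HotspotGrid
from .occurrence_io import ManagementLayers

__all__ = [
    "score_species",
    "score_hpne",
    "summarize_protection",
    "load_hpne_table",
    "summarize_hpne_table",
]

PRIORITY_FLAGS = ("all_mined_unprotected", "half_mined_unprotected", "none")

GEO_ORDER = ("U", "V", "L", "R")  # deterministic tie-break order for substrate modes


def _covered_fraction(xs, ys, polygons) -> np.ndarray:
    """Boolean per point: inside (or on the boundary of) any polygon."""
    hit = np.zeros(len(xs), dtype=bool)
    from shapely.geometry import Point

    prepared = [prep(p) for p in polygons]
    for i, (x, y) in enumerate(zip(xs, ys)):
        pt = Point(x, y)
        hit[i] = any(pp.covers(pt) for pp in prepared)
    return hit


def score_species(
    records: pd.DataFrame, profiles: pd.DataFrame, layers: ManagementLayers
) -> pd.DataFrame:
    """Per-species threat profile.

    Columns: species_id, n_records, n_protected, n_mined,
    prop_records_protected, prop_records_mined, species_listed (any
    jurisdiction), priority_flag.  Fractions are ratios of record counts.
    """
    for poly in layers.all_polygons():
        if not poly.is_valid:
            raise ValueError(f"invalid polygon in management layers: {poly.wkt[:60]}...")
    listed_any: set = set()
    for s in layers.protected_species.values():
        listed_any |= s
    rows = []
    nes_ids = set(profiles["species_id"])
    for sp, grp in records.groupby("species_id", sort=True):
        if sp not in nes_ids:
            continue
        xs = grp["x"].to_numpy()
        ys = grp["y"].to_numpy()
        in_prot = _covered_fraction(xs, ys, layers.protected_areas)
        in_mine = _covered_fraction(xs, ys, layers.mining_areas)
        n = len(grp)
        n_prot = int(in_prot.sum())
        n_mine = int(in_mine.sum())
        listed = sp in listed_any
        unprotected = (not listed) and n_prot == 0
        if unprotected and n_mine == n:
            flag = "all_mined_unprotected"
        elif unprotected and 2 * n_mine >= n:
            flag = "half_mined_unprotected"
        else:
            flag = "none"
        rows.append(
            {
                "species_id": sp,
                "n_records": n,
                "n_protected": n_prot,
                "n_mined": n_mine,
                "prop_records_protected": n_prot / n,
                "prop_records_mined": n_mine / n,
                "species_listed": listed,
                "priority_flag": flag,
            }
        )
    return pd.DataFrame(rows)


def substrate_label(fractions: dict[str, float], mixed_threshold: float = 0.40) -> str:
    """Modal substrate of a cell; 'A/B' when the top two classes each cover
    at least ``mixed_threshold`` of the cell.  Ties break in U < V < L < R order."""
    ordered = sorted(
        fractions.items(), key=lambda kv: (-kv[1], GEO_ORDER.index(kv[0]) if kv[0] in GEO_ORDER else 99)
    )
    if len(ordered) >= 2 and ordered[0][1] >= mixed_threshold and ordered[1][1] >= mixed_threshold:
        return f"{ordered[0][0]}/{ordered[1][0]}"
    return ordered[0][0]


def score_hpne(
    hg: HotspotGrid,
    layers: ManagementLayers,
    geology: Raster | None = None,
    geology_codes: dict[float, str] | None = None,
) -> pd.DataFrame:
    """Flags per hotspot cell: protected, mining-impacted, substrate label.

    Mining impact includes edge adjacency: a cell sharing an edge with a
    mining footprint is flagged even if their interiors do not overlap.
    Substrate fractions come from the fine geology raster cells whose
    centres fall inside the hotspot cell.
    """
    rows = []
    for ix, iy in hg.hpne_cells():
        cell = hg.grid.cell_polygon(ix, iy)
        protected = any(cell.intersects(p) for p in layers.protected_areas)
        mining = False
        for p in layers.mining_areas:
            inter = cell.intersection(p)
            if inter.area > 0 or (not inter.is_empty and inter.length > 0):
                mining = True
                break
        label = ""
        if geology is not None:
            g = geology.grid
            xs, ys = g.cell_centers()
            inside = (
                (xs >= cell.bounds[0]) & (xs < cell.bounds[2])
                & (ys >= cell.bounds[1]) & (ys < cell.bounds[3])
                & geology.mask_valid()
            )
            vals = geology.values[inside]
            if len(vals):
                fracs = {}
                for code in np.unique(vals):
                    name = geology_codes.get(float(code), str(code)) if geology_codes else str(code)
                    fracs[name] = float((vals == code).sum() / len(vals))
                label = substrate_label(fracs)
        rows.append(
            {
                "ix": ix,
                "iy": iy,
                "n_nes_total": int(hg.n_nes_total[iy, ix]),
                "protected": protected,
                "mining": mining,
                "substrate": label,
            }
        )
    return pd.DataFrame(rows, columns=["ix", "iy", "n_nes_total", "protected", "mining", "substrate"])


def summarize_protection(
    threat_profiles: pd.DataFrame,
    hpne_flags: pd.DataFrame | None = None,
    layers: ManagementLayers | None = None,
) -> dict:
    """Headline protection counts.

    Keys: n_nes, n_no_protected_records, n_majority_unprotected (>50% of
    records outside protected areas but at least one inside), n_listed (any
    jurisdiction), n_listed_by_jurisdiction, n_fully_unprotected (neither
    listed nor any record protected), n_priority_all_mined,
    n_priority_half_mined, and (when hotspot flags are given)
    n_hpne / n_hpne_protected / n_hpne_mining.
    """
    tp = threat_profiles
    out: dict = {"n_nes": int(len(tp))}
    if len(tp):
        none_prot = tp["n_protected"] == 0
        out["n_no_protected_records"] = int(none_prot.sum())
        out["n_majority_unprotected"] = int(
            ((tp["prop_records_protected"] < 0.5) & ~none_prot).sum()
        )
        out["n_listed"] = int(tp["species_listed"].sum())
        out["n_fully_unprotected"] = int((none_prot & ~tp["species_listed"]).sum())
        out["n_priority_all_mined"] = int((tp["priority_flag"] == "all_mined_unprotected").sum())
        out["n_priority_half_mined"] = int((tp["priority_flag"] == "half_mined_unprotected").sum())
        out["n_any_record_mined"] = int((tp["n_mined"] > 0).sum())
    else:
        out.update(
            n_no_protected_records=0, n_majority_unprotected=0, n_listed=0,
            n_fully_unprotected=0, n_priority_all_mined=0, n_priority_half_mined=0,
            n_any_record_mined=0,
        )
    if layers is not None and len(tp):
        out["n_listed_by_jurisdiction"] = {
            j: int(tp["species_id"].isin(s).sum()) for j, s in layers.protected_species.items()
        }
    if hpne_flags is not None:
        out["n_hpne"] = int(len(hpne_flags))
        out["n_hpne_protected"] = int(hpne_flags["protected"].sum()) if len(hpne_flags) else 0
        out["n_hpne_mining"] = int(hpne_flags["mining"].sum()) if len(hpne_flags) else 0
    return out


_DMS_RE = re.compile(r"(\d+)\s*°\s*(\d+)\s*[′']\s*(\d+(?:\.\d+)?)\s*[″\"]?")


def parse_dms(text: str) -> float:
    """Parse a degrees-minutes-seconds string like 164°46′55″ to decimal degrees."""
    m = _DMS_RE.match(str(text).strip())
    if not m:
        raise ValueError(f"cannot parse DMS coordinate {text!r}")
    d, mnt, s = float(m.group(1)), float(m.group(2)), float(m.group(3))
    return d + mnt / 60 + s / 3600


def load_hpne_table() -> pd.DataFrame:
    """Transcription of the published table of New Caledonian narrow-endemism
    hotspots (one row per 2 x 2 km cell with >7 NES).

    Columns: name, province ('N'/'S'), per-class and total NES counts,
    lon/lat in decimal degrees (latitudes southern, hence negative),
    protected and mining booleans, substrate label (U, V or mixed 'A/B').
    """
    with resources.files("nes_atlas.data").joinpath("hpne_table.csv").open() as fh:
        t = pd.read_csv(fh)
    t["lon"] = t["lon_dms"].map(parse_dms)
    t["lat"] = -t["lat_dms"].map(parse_dms)
    t["protected"] = t["protected"].astype(bool)
    t["mining"] = t["mining"].astype(bool)
    return t


def summarize_hpne_table(table: pd.DataFrame) -> dict:
    """Tabular summaries of a hotspot table: row count, province split,
    protection and mining counts, maximum per-cell NES count, and the
    substrate split (pure classes counted separately from mixed labels)."""
    def substrate_split(sub: pd.DataFrame) -> dict:
        split: dict[str, int] = {}
        for lab in sub["substrate"]:
            key = lab if "/" not in lab else "mixed"
            split[key] = split.get(key, 0) + 1
        return split

    cons = int((table["n_nes1"] + table["n_nes2"] + table["n_nes3"] != table["n_nes_total"]).sum())
    return {
        "n_rows": int(len(table)),
        "n_north": int((table["province"] == "N").sum()),
        "n_south": int((table["province"] == "S").sum()),
        "n_protected": int(table["protected"].sum()),
        "n_mining": int(table["mining"].sum()),
        "max_nes_per_cell": int(table["n_nes_total"].max()),
        "substrate_north": substrate_split(table[table["province"] == "N"]),
        "substrate_south": substrate_split(table[table["province"] == "S"]),
        "n_class_sum_mismatch": cons,
    }
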