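"""Gridded hotspots of plant narrow endemism (HPNE).

Narrow-endemic species are counted per cell of a regular metric grid
(default 2 x 2 km); a species counts once per cell however many records it
has there.  A cell is a *hotspot of plant narrow endemism* when strictly
more than ``threshold`` (default 7) distinct NES occur in it.  Because grid
placement can split a species cluster across a cell boundary, a shift
sensitivity scan re-counts hotspots under sub-cell origin offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point

from .grids import GridSpec
from .nes_classification import NES_CLASSES

__all__ = [
    "HotspotGrid",
    "count_nes_per_cell",
    "aggregate_named_features",
    "grid_shift_sensitivity",
    "bias_correlation",
]


@dataclass
class HotspotGrid:
    """Per-cell NES counts by class, with hotspot flags.

    ``cell_species[(ix, iy)]`` holds the set of distinct NES recorded in the
    cell; count rasters are (ny, nx) arrays with row 0 the southern row.
    """

    grid: GridSpec
    threshold: int
    n_nes1: np.ndarray
    n_nes2: np.ndarray
    n_nes3: np.ndarray
    n_nes_total: np.ndarray
    cell_species: dict = field(default_factory=dict)

    @property
    def hpne_flags(self) -> np.ndarray:
        return self.n_nes_total > self.threshold

    def hpne_cells(self) -> list[tuple[int, int]]:
        """(ix, iy) of flagged cells, row-major from the south-west."""
        iy, ix = np.nonzero(self.hpne_flags)
        order = np.lexsort((ix, iy))
        return list(zip(ix[order].tolist(), iy[order].tolist()))

    def hpne_table(self) -> pd.DataFrame:
        rows = []
        for ix, iy in self.hpne_cells():
            rows.append(
                {
                    "ix": ix,
                    "iy": iy,
                    "x_center": self.grid.x0 + (ix + 0.5) * self.grid.cell,
                    "y_center": self.grid.y0 + (iy + 0.5) * self.grid.cell,
                    "n_nes1": int(self.n_nes1[iy, ix]),
                    "n_nes2": int(self.n_nes2[iy, ix]),
                    "n_nes3": int(self.n_nes3[iy, ix]),
                    "n_nes_total": int(self.n_nes_total[iy, ix]),
                }
            )
        return pd.DataFrame(rows, columns=["ix", "iy", "x_center", "y_center",
                                           "n_nes1", "n_nes2", "n_nes3", "n_nes_total"])


def count_nes_per_cell(
    profiles: pd.DataFrame,
    records: pd.DataFrame,
    grid: GridSpec,
    threshold: int = 7,
) -> HotspotGrid:
    """Count distinct NES per grid cell, split by NES class.

    Only records of species classified NES1-3 in ``profiles`` contribute.
    Records outside the grid extent are ignored (they belong to no cell).
    """
    if grid.cell <= 0:
        raise ValueError("cell size must be positive")
    nes = profiles[profiles["nes_class"].isin(NES_CLASSES)]
    klass = dict(zip(nes["species_id"], nes["nes_class"]))
    recs = records[records["species_id"].isin(klass)]
    counts = {c: np.zeros(grid.shape, dtype=int) for c in NES_CLASSES}
    total = np.zeros(grid.shape, dtype=int)
    cell_species: dict[tuple[int, int], set] = {}
    if len(recs):
        x = recs["x"].to_numpy()
        y = recs["y"].to_numpy()
        inside = grid.contains(x, y)
        ix, iy = grid.cell_index(x, y)
        sp = recs["species_id"].to_numpy()
        seen = set()
        for i in np.nonzero(inside)[0]:
            key = (sp[i], int(ix[i]), int(iy[i]))
            if key in seen:
                continue
            seen.add(key)
            c = klass[sp[i]]
            counts[c][iy[i], ix[i]] += 1
            total[iy[i], ix[i]] += 1
            cell_species.setdefault((int(ix[i]), int(iy[i])), set()).add(sp[i])
    return HotspotGrid(
        grid=grid,
        threshold=threshold,
        n_nes1=counts["NES1"],
        n_nes2=counts["NES2"],
        n_nes3=counts["NES3"],
        n_nes_total=total,
        cell_species=cell_species,
    )


def aggregate_named_features(hg: HotspotGrid, named_features: dict) -> pd.DataFrame:
    """Species totals per named geographic feature (massif, valley, ...).

    A cell belongs to the feature polygon containing its centre; if several
    overlapping polygons contain it, the first feature in name order wins
    (with a warning).  A species counts once per feature — the union of the
    species sets of the feature's cells — so the totals are set-union
    counts, not sums over cells.
    """
    names = sorted(named_features)
    assignment: dict[tuple[int, int], str] = {}
    overlap = False
    for (ix, iy), species in hg.cell_species.items():
        cx = hg.grid.x0 + (ix + 0.5) * hg.grid.cell
        cy = hg.grid.y0 + (iy + 0.5) * hg.grid.cell
        p = Point(cx, cy)
        hits = [n for n in names if named_features[n].covers(p)]
        if len(hits) > 1:
            overlap = True
        if hits:
            assignment[(ix, iy)] = hits[0]
    if overlap:
        warnings.warn("overlapping named-feature polygons; cells assigned by feature name order")
    rows = []
    for name in names:
        cells = [c for c, n in assignment.items() if n == name]
        union: set = set()
        for c in cells:
            union |= hg.cell_species.get(c, set())
        rows.append({"feature": name, "n_cells_occupied": len(cells),
                     "n_nes_total": len(union), "species": sorted(union)})
    return pd.DataFrame(rows, columns=["feature", "n_cells_occupied", "n_nes_total", "species"])


def aggregate_named_features_by_class(
    hg: HotspotGrid, named_features: dict, profiles: pd.DataFrame
) -> pd.DataFrame:
    """Like :func:`aggregate_named_features` but also splits totals by class
    (the per-feature count of single-location species is the headline number
    for isolated massifs)."""
    base = aggregate_named_features(hg, named_features)
    klass = dict(zip(profiles["species_id"], profiles["nes_class"]))
    for c in NES_CLASSES:
        base[f"n_{c.lower()}"] = [
            sum(1 for s in species if klass.get(s) == c) for species in base["species"]
        ]
    return base.drop(columns=["species"])


def grid_shift_sensitivity(
    profiles: pd.DataFrame,
    records: pd.DataFrame,
    grid: GridSpec,
    offsets: list[tuple[float, float]],
    threshold: int = 7,
) -> tuple[pd.DataFrame, dict]:
    """Re-count hotspots under sub-cell origin offsets.

    Returns a per-offset table (number of hotspot cells, number of species
    captured by any hotspot) and a summary dict with min/max/median hotspot
    count over offsets.
    """
    for dx, dy in offsets:
        if abs(dx) >= grid.cell or abs(dy) >= grid.cell:
            raise ValueError("offsets must be smaller than one cell width")
    rows = []
    for dx, dy in offsets:
        hg = count_nes_per_cell(profiles, records, grid.shifted(dx, dy), threshold)
        species: set = set()
        for cell in hg.hpne_cells():
            species |= hg.cell_species.get(cell, set())
        rows.append({"dx": dx, "dy": dy, "n_hpne": int(hg.hpne_flags.sum()),
                     "n_species_captured": len(species)})
    table = pd.DataFrame(rows)
    summary = {
        "min_hpne": int(table["n_hpne"].min()),
        "max_hpne": int(table["n_hpne"].max()),
        "median_hpne": float(table["n_hpne"].median()),
    }
    return table, summary


def bias_correlation(
    effort_per_cell, richness_per_cell, exclude_zero_effort: bool = False
) -> tuple[float, float]:
    """Pearson correlation between sampling effort and NES richness per cell.

    A collector's documented number of sampling trips per cell against the
    number of NES recorded there; the correlation's weakness is the evidence
    that recorded hotspots are not mere artefacts of effort.  Returns
    ``(r, p)``; zero variance in either vector yields ``(nan, nan)``.
    """
    effort = np.asarray(effort_per_cell, dtype=float)
    rich = np.asarray(richness_per_cell, dtype=float)
    if effort.shape != rich.shape:
        raise ValueError("effort and richness must have equal length")
    if exclude_zero_effort:
        keep = effort > 0
        effort, rich = effort[keep], rich[keep]
    if len(effort) < 3:
        raise ValueError("need at least 3 cells")
    if effort.std() == 0 or rich.std() == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(effort, rich)
    return float(r), float(p)
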