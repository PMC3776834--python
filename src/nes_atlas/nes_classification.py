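"""Narrow-endemic species (NES) classification and range metrics.

A species' records are grouped into *locations*: connected components of the
graph that links any two records lying closer than a discontinuity threshold
(default 10 km, single linkage).  Chaining is deliberate — a continuous run
of records across a large area collapses into one location because no
discontinuity interrupts it.  Species with 1, 2 or 3 locations are NES 1,
NES 2 and NES 3 respectively; more than 3 locations is not narrow-endemic.

Range metrics follow the IUCN definitions: the area of occupancy (AOO) is
the summed area of occupied grid cells (default 2-km cells, 4 km^2 each) and
the extent of occurrence (EOO) is the area of the convex hull of the
records.  Degenerate hulls (one or two distinct points, or collinear
records) have EOO 0 and carry an explicit flag rather than a floor value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import MultiPoint

from .grids import GridSpec

__all__ = [
    "cluster_locations",
    "classify_nes",
    "compute_aoo",
    "compute_eoo",
    "build_species_profiles",
    "histogram_correlation",
    "endemism_rate",
    "HistogramComparison",
]

NES_CLASSES = ("NES1", "NES2", "NES3")


def cluster_locations(points: np.ndarray, threshold_km: float = 10.0) -> list[list[int]]:
    """Group records into locations by the distance-discontinuity rule.

    Parameters
    ----------
    points : (n, 2) array of projected metre coordinates.
    threshold_km : records strictly closer than this are linked.

    Returns
    -------
    Groups of record indices (connected components under single linkage),
    ordered by their smallest member index.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    if threshold_km <= 0:
        raise ValueError("threshold must be positive")
    n = len(points)
    if n == 1:
        return [[0]]
    d = squareform(pdist(points))
    adj = sparse.csr_matrix(d < threshold_km * 1000.0)
    n_comp, labels = connected_components(adj, directed=False)
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    return sorted(groups.values(), key=lambda g: g[0])


def nes_class_of(n_locations: int) -> str:
    return f"NES{n_locations}" if n_locations <= 3 else "not_NES"


def compute_aoo(points: np.ndarray, cell_km: float = 2.0, origin=(0.0, 0.0)) -> float:
    """Area of occupancy: number of distinct occupied cells x cell area (km^2).

    Cells are half-open squares anchored at ``origin`` (projected metres),
    the same convention as the hotspot grid.
    """
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise ValueError("need at least one point")
    cell_m = cell_km * 1000.0
    ix = np.floor((points[:, 0] - origin[0]) / cell_m).astype(int)
    iy = np.floor((points[:, 1] - origin[1]) / cell_m).astype(int)
    n_cells = len(set(zip(ix.tolist(), iy.tolist())))
    return n_cells * cell_km**2


def compute_eoo(points: np.ndarray) -> tuple[float, bool]:
    """Extent of occurrence: convex-hull area in km^2, with a degeneracy flag.

    Returns (area_km2, degenerate); degenerate hulls (fewer than 3 distinct
    points, or collinear points) have area 0.
    """
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise ValueError("need at least one point")
    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    area_m2 = getattr(hull, "area", 0.0)
    if area_m2 <= 0.0:
        return 0.0, True
    return area_m2 / 1e6, False


def build_species_profiles(
    records: pd.DataFrame,
    threshold_km: float = 10.0,
    aoo_cell_km: float = 2.0,
    grid_origin=(0.0, 0.0),
    iucn_status: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-species range profile table.

    Requires projected records (columns ``species_id, x, y``).  Columns of
    the result: species_id, n_records, n_locations, nes_class, aoo_km2,
    eoo_km2, eoo_degenerate, iucn_status.  IUCN statuses are consumed from a
    supplied mapping; species absent from it are 'not_assessed'.
    """
    iucn_status = iucn_status or {}
    rows = []
    for sp, grp in records.groupby("species_id", sort=True):
        pts = grp[["x", "y"]].to_numpy()
        groups = cluster_locations(pts, threshold_km)
        n_loc = len(groups)
        aoo = compute_aoo(pts, aoo_cell_km, grid_origin)
        eoo, degen = compute_eoo(pts)
        rows.append(
            {
                "species_id": sp,
                "n_records": len(pts),
                "n_locations": n_loc,
                "nes_class": nes_class_of(n_loc),
                "aoo_km2": aoo,
                "eoo_km2": eoo,
                "eoo_degenerate": degen,
                "iucn_status": iucn_status.get(sp, "not_assessed"),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class HistogramComparison:
    """Pearson correlation between two binned frequency distributions."""

    bin_edges: np.ndarray
    freq_a: np.ndarray
    freq_b: np.ndarray
    pearson_r: float
    p_value: float
    defined: bool


def default_area_bins(values, n_bins: int = 8, first_edge_km2: float = 50.0) -> np.ndarray:
    """Log-spaced area bins whose first interior edge is the smallest-area
    category boundary (default 50 km^2); values of 0 fall in the first bin."""
    top = float(np.max(values))
    top = max(top, first_edge_km2 * 2)
    inner = np.geomspace(first_edge_km2, top, n_bins - 1)
    return np.concatenate([[0.0], inner[:-1], [np.inf]])


def histogram_correlation(values_a, values_b, bin_edges) -> HistogramComparison:
    """Correlate the frequency distributions of two samples on shared bins.

    Both samples are binned with the identical edges; Pearson r and a
    two-sided t-test p-value (df = bins - 2) are computed on the binned
    counts.  Zero variance in either count vector yields an explicitly
    undefined result (``defined=False``) rather than NaNs.
    """
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if len(values_a) == 0 or len(values_b) == 0:
        raise ValueError("both samples must be non-empty")
    if len(bin_edges) < 4:
        raise ValueError("need at least 3 bins")
    fa, _ = np.histogram(values_a, bins=bin_edges)
    fb, _ = np.histogram(values_b, bins=bin_edges)
    if fa.std() == 0 or fb.std() == 0:
        return HistogramComparison(bin_edges, fa, fb, np.nan, np.nan, defined=False)
    r, p = stats.pearsonr(fa, fb)
    return HistogramComparison(bin_edges, fa, fb, float(r), float(p), defined=True)


def load_flora_summary() -> dict:
    """Published flora-level summary tallies for the New Caledonian
    narrow-endemism assessment (per-class NES counts, number of assessed
    species, ecological group sizes, number of precisely-located species)."""
    import json
    from importlib import resources

    with resources.files("nes_atlas.data").joinpath("flora_summary.json").open() as fh:
        return json.load(fh)


def endemism_rate(per_class_counts: dict[str, int], n_assessed: int) -> tuple[int, float]:
    """Total NES count across classes and its percentage of assessed species.

    Returns ``(total, percent)`` with percent rounded to one decimal, the
    convention used in published flora-level summaries.
    """
    total = sum(int(per_class_counts[c]) for c in NES_CLASSES)
    if n_assessed <= 0:
        raise ValueError("n_assessed must be positive")
    return total, round(100.0 * total / n_assessed, 1)
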