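"""Synthetic landscapes with known ground truth.

Every downstream stage of the pipeline is exercised against worlds built
here: a mountainous DEM (sum of smoothed random bumps, so massifs are
controllable), a Voronoi substrate mosaic over the four classes
(ultramafic U, volcano-sedimentary V, limestone L, riverbank/anthropic R,
with U covering about a third of the land), temperature as an exact lapse
of elevation, rainfall as a linear elevation trend plus a Gaussian random
field with exponential covariance (the structure the kriging stage
assumes), sparse weather stations, and species planted with known location
counts, substrate affinities and altitude niches.

Ground truth is constructed, not estimated: cluster spread and separation
margins guarantee that re-running the location-discontinuity rule at its
default threshold reproduces the planted location counts exactly, and
planted hotspot cells are guaranteed to exceed the hotspot threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from shapely.geometry import box

from .grids import GridSpec, Raster
from .occurrence_io import ManagementLayers
from .projection import TransverseMercator

__all__ = ["WorldConfig", "SyntheticWorld", "generate_world", "effort_field",
            "gaussian_random_field_sampler", "orographic_rainfall"]

GEO_CODES = {"U": 1.0, "V": 2.0, "L": 3.0, "R": 4.0}


@dataclass(frozen=True)
class WorldConfig:
    """Study conditions for a synthetic world.

    Distances in km, elevations in m, rainfall in mm/yr, temperature in
    deg C.  Defaults give a 100 x 100 km island at 1-km resolution with
    three planted ecological groups and a handful of planted hotspots.
    """

    size_km: float = 100.0
    cell_km: float = 1.0
    # terrain: smoothed random bumps -> controllable massifs
    n_bumps: int = 24
    bump_height_m: tuple[float, float] = (300.0, 1100.0)
    bump_sigma_km: tuple[float, float] = (4.0, 12.0)
    # overlapping bumps saturate smoothly at the island's maximum relief
    dem_max_m: float = 1650.0
    # substrate mosaic: Voronoi patches; U holds about 1/3 of the territory.
    # the mosaic is deliberately fine-grained — the real substrate map is a
    # patchwork of many isolated outcrops, so a group's species sample many
    # patches and within-group environment varies as a gradient
    n_patches: int = 150
    geology_shares: tuple[float, float, float, float] = (0.33, 0.45, 0.12, 0.10)  # U, V, L, R
    # climate
    t0_c: float = 24.0
    lapse_c_per_m: float = 0.0065
    rain_intercept_mm: float = 1500.0
    rain_per_m: float = 1.2
    rain_noise_sd_mm: float = 150.0
    rain_noise_range_km: float = 30.0
    n_stations: int = 60
    # species
    n_species: int = 200
    location_count_probs: dict = field(
        default_factory=lambda: {1: 0.30, 2: 0.20, 3: 0.15, "many": 0.35}
    )
    group_probs: tuple[float, float, float] = (0.15, 0.425, 0.425)  # G1 L/R, G2 V, G3 U
    # near-obligate edaphic specialism: ultramafic endemics essentially never
    # establish off their substrate; the residual 5% stands in for substrate
    # mapping error and misattributed localities
    substrate_affinity: float = 0.95
    niche_sd_m: float = 150.0
    intra_km: float = 5.0
    inter_km: float = 20.0
    # spatial footprint of one population; must not exceed intra_km / 2 so a
    # location's records can never be mistaken for two
    location_radius_km: float = 1.0
    mean_records_per_location: float = 4.0
    # hotspots
    n_planted_hotspots: int = 4
    species_per_hotspot: int = 10
    hotspot_cell_km: float = 2.0
    hpne_threshold: int = 7
    # management
    n_mined_species: int = 5
    n_protected_hotspots: int = 2
    strict_recovery: bool = True
    # geographic anchor (southern-hemisphere island, mirrors the study region)
    lon0: float = 165.5
    lat0: float = -21.0


@dataclass
class SyntheticWorld:
    config: WorldConfig
    seed: int
    grid: GridSpec
    dem: Raster
    geology: Raster
    temperature: Raster
    rainfall_true: Raster
    stations: pd.DataFrame
    records: pd.DataFrame
    species_truth: pd.DataFrame
    hotspot_truth: set
    layers: ManagementLayers
    projection: TransverseMercator

    def checksum(self) -> int:
        import zlib

        h = 0
        for arr in (self.dem.values, self.geology.values, self.rainfall_true.values):
            h = zlib.crc32(np.ascontiguousarray(arr).tobytes(), h)
        h = zlib.crc32(self.records.to_csv(index=False).encode(), h)
        h = zlib.crc32(self.species_truth.to_csv(index=False).encode(), h)
        return h


def gaussian_random_field_sampler(rng, sd: float, range_m: float, n_features: int = 300):
    """Stationary Gaussian random field with exponential covariance
    sd^2 * exp(-h / range), via random Fourier features.

    Returns a callable field(x, y) usable at arbitrary coordinates.  The
    2-D spectral measure of the exponential kernel has radial CDF
    F(w) = 1 - (1 + r^2 w^2)^(-1/2), inverted exactly for sampling.
    """
    u = rng.uniform(size=n_features)
    wmag = np.sqrt((1.0 - u) ** -2 - 1.0) / range_m
    theta = rng.uniform(0, 2 * np.pi, size=n_features)
    wx = wmag * np.cos(theta)
    wy = wmag * np.sin(theta)
    phase = rng.uniform(0, 2 * np.pi, size=n_features)
    amp = sd * np.sqrt(2.0 / n_features)

    def field(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        arg = x[..., None] * wx + y[..., None] * wy + phase
        return amp * np.cos(arg).sum(axis=-1)

    return field


def _make_dem(cfg: WorldConfig, grid: GridSpec, rng) -> np.ndarray:
    xs, ys = grid.cell_centers()
    z = np.zeros(grid.shape)
    for _ in range(cfg.n_bumps):
        cx = rng.uniform(0.1, 0.9) * cfg.size_km * 1000
        cy = rng.uniform(0.1, 0.9) * cfg.size_km * 1000
        h = rng.uniform(*cfg.bump_height_m)
        s = rng.uniform(*cfg.bump_sigma_km) * 1000
        z += h * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * s**2))
    return cfg.dem_max_m * np.tanh(z / cfg.dem_max_m)


def _make_geology(cfg: WorldConfig, grid: GridSpec, rng) -> np.ndarray:
    xs, ys = grid.cell_centers()
    px = rng.uniform(0, cfg.size_km * 1000, cfg.n_patches)
    py = rng.uniform(0, cfg.size_km * 1000, cfg.n_patches)
    codes = list(GEO_CODES.values())
    patch_class = rng.choice(codes, size=cfg.n_patches, p=cfg.geology_shares)
    d2 = (xs[..., None] - px) ** 2 + (ys[..., None] - py) ** 2
    return patch_class[np.argmin(d2, axis=-1)]


def _sample_cluster_centres(k, home_mask, alt_niche, dem_vals, grid, cfg, rng, all_mask):
    """Cluster centres separated by at least inter_km.

    Each centre is on the home substrate with probability
    ``substrate_affinity`` (faithful), biased toward the species' altitude
    niche.  When separation keeps failing, the niche bias is relaxed before
    the substrate constraint, and only as a last resort is a centre placed
    anywhere.  Returns (centres, faithful_flags).
    """
    iy_home, ix_home = np.nonzero(home_mask)
    iy_all, ix_all = np.nonzero(all_mask)
    centres: list[tuple[float, float]] = []
    flags: list[bool] = []
    min_sep2 = (cfg.inter_km * 1000) ** 2
    while len(centres) < k:
        placed = False
        faithful = bool(rng.uniform() < cfg.substrate_affinity) and len(iy_home) > 0
        iy, ix = (iy_home, ix_home) if faithful else (iy_all, ix_all)
        alt = dem_vals[iy, ix]
        w = np.exp(-((alt - alt_niche) ** 2) / (2 * cfg.niche_sd_m**2))
        for stage in range(3):  # niche-weighted -> substrate-only -> anywhere
            if stage == 1:
                w = None
            elif stage == 2:
                iy, ix = iy_all, ix_all
                faithful = False
            p = None
            if w is not None and w.sum() > 0:
                p = w / w.sum()
            for _ in range(60):
                j = int(rng.choice(len(iy), p=p))
                cx = grid.x0 + (ix[j] + 0.5) * grid.cell
                cy = grid.y0 + (iy[j] + 0.5) * grid.cell
                if all((cx - a) ** 2 + (cy - b) ** 2 >= min_sep2 for a, b in centres):
                    centres.append((cx, cy))
                    flags.append(faithful)
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise ValueError(
                "cannot place separated location clusters; reduce inter_km or location counts"
            )
    return centres, flags


def generate_world(config: WorldConfig = WorldConfig(), seed: int = 0) -> SyntheticWorld:
    """Generate a complete world from a single seed (bit-reproducible).

    Raises a configuration error when strict ground-truth recovery is
    requested but the cluster margins would make the planted location
    counts ambiguous under the 10-km rule.
    """
    cfg = config
    if cfg.strict_recovery and (cfg.inter_km <= 10.0 or cfg.intra_km >= 10.0):
        raise ValueError(
            "ambiguous ground truth: need inter_km > 10 and intra_km < 10 "
            "for strict recovery of planted location counts"
        )
    n = int(round(cfg.size_km / cfg.cell_km))
    if abs(n * cfg.cell_km - cfg.size_km) > 1e-9:
        raise ValueError("cell size must divide the extent")
    rng = np.random.default_rng(seed)
    grid = GridSpec(0.0, 0.0, cfg.cell_km * 1000, n, n)
    xs, ys = grid.cell_centers()

    dem_vals = _make_dem(cfg, grid, rng)
    geo_vals = _make_geology(cfg, grid, rng)
    temp_vals = cfg.t0_c - cfg.lapse_c_per_m * dem_vals
    noise = gaussian_random_field_sampler(rng, cfg.rain_noise_sd_mm, cfg.rain_noise_range_km * 1000)
    rain_vals = np.maximum(
        cfg.rain_intercept_mm + cfg.rain_per_m * dem_vals + noise(xs, ys), 100.0
    )

    dem = Raster(dem_vals, grid)
    geology = Raster(geo_vals, grid)
    temperature = Raster(temp_vals, grid)
    rainfall_true = Raster(rain_vals, grid)

    # stations sample the true rainfall field at their cells
    st_idx = rng.choice(n * n, size=cfg.n_stations, replace=False)
    st_iy, st_ix = np.unravel_index(np.sort(st_idx), (n, n))
    stations = pd.DataFrame(
        {
            "x": grid.x0 + (st_ix + 0.5) * grid.cell,
            "y": grid.y0 + (st_iy + 0.5) * grid.cell,
            "elevation": dem_vals[st_iy, st_ix],
            "rainfall": rain_vals[st_iy, st_ix],
        }
    )

    # --- species: three ecological groups with substrate affinity
    group_home = {1: ("L", "R"), 2: ("V",), 3: ("U",)}
    alt_lo, alt_hi = float(dem_vals.min()), float(dem_vals.max())
    rec_rows = []
    truth_rows = []
    kinds = list(cfg.location_count_probs)
    kprobs = np.array([cfg.location_count_probs[k] for k in kinds], dtype=float)
    kprobs /= kprobs.sum()
    all_mask = np.ones(grid.shape, dtype=bool)
    for s in range(cfg.n_species):
        gid = int(rng.choice([1, 2, 3], p=cfg.group_probs))
        home = group_home[gid]
        home_mask = np.isin(geo_vals, [GEO_CODES[h] for h in home])
        if gid == 1:
            # lowland group: limestone and riverbank/anthropic formations
            alt_niche = rng.uniform(alt_lo, alt_lo + 0.2 * (alt_hi - alt_lo))
        else:
            # montane-biased niches: narrow endemism concentrates at altitude,
            # but substrate remains the dominant constraint
            alt_niche = rng.uniform(alt_lo + 0.3 * (alt_hi - alt_lo), alt_hi)
        kind = kinds[int(rng.choice(len(kinds), p=kprobs))]
        k = int(kind) if kind != "many" else int(rng.integers(5, 9))
        centres, faith_flags = _sample_cluster_centres(
            k, home_mask, alt_niche, dem_vals, grid, cfg, rng, all_mask
        )
        sp = f"sp{s:04d}"
        radius = min(cfg.location_radius_km, cfg.intra_km / 2) * 1000
        home_codes = [GEO_CODES[h] for h in home]
        for (cx, cy), faithful in zip(centres, faith_flags):
            n_rec = 1 + rng.poisson(cfg.mean_records_per_location - 1)
            for _ in range(n_rec):
                # obligate specialists sit on their substrate at the record
                # level: resample the within-site position until it does
                for _try in range(30):
                    r = rng.uniform(0, radius)
                    a = rng.uniform(0, 2 * np.pi)
                    xx = float(np.clip(cx + r * np.cos(a), 0, cfg.size_km * 1000 - 1e-6))
                    yy = float(np.clip(cy + r * np.sin(a), 0, cfg.size_km * 1000 - 1e-6))
                    if not faithful:
                        break
                    ix0, iy0 = grid.cell_index(xx, yy)
                    if geo_vals[int(iy0), int(ix0)] in home_codes:
                        break
                rec_rows.append((sp, xx, yy))
        truth_rows.append(
            {
                "species_id": sp,
                "group_id": gid,
                "home_substrate": "/".join(home),
                "alt_niche_m": alt_niche,
                "n_locations_true": k,
                "planted_hotspot": False,
            }
        )

    # --- planted hotspots: extra single-location species packed into one
    # hotspot cell each, with a margin from the cell edges
    hcell = cfg.hotspot_cell_km * 1000
    n_hcells = int(cfg.size_km * 1000 // hcell)
    hotspot_truth: set[tuple[int, int]] = set()
    margin = 0.2 * hcell
    used = set()
    sidx = cfg.n_species
    for _ in range(cfg.n_planted_hotspots):
        for _try in range(100):
            hx = int(rng.integers(1, n_hcells - 1))
            hy = int(rng.integers(1, n_hcells - 1))
            far = all(abs(hx - a) + abs(hy - b) > 4 for a, b in used)
            if (hx, hy) not in used and far:
                break
        used.add((hx, hy))
        hotspot_truth.add((hx, hy))
        for _ in range(cfg.species_per_hotspot):
            sp = f"sp{sidx:04d}"
            sidx += 1
            n_rec = 1 + rng.poisson(2)
            px = rng.uniform(hx * hcell + margin, (hx + 1) * hcell - margin, size=n_rec)
            py = rng.uniform(hy * hcell + margin, (hy + 1) * hcell - margin, size=n_rec)
            for xx, yy in zip(px, py):
                rec_rows.append((sp, xx, yy))
            ix0, iy0 = grid.cell_index(np.mean(px), np.mean(py))
            gid = {"U": 3, "V": 2}.get(
                {v: k for k, v in GEO_CODES.items()}.get(float(geo_vals[int(iy0), int(ix0)]), "V"), 2
            )
            truth_rows.append(
                {
                    "species_id": sp,
                    "group_id": gid,
                    "home_substrate": "planted",
                    "alt_niche_m": float(dem_vals[int(iy0), int(ix0)]),
                    "n_locations_true": 1,
                    "planted_hotspot": True,
                }
            )
    if cfg.species_per_hotspot <= cfg.hpne_threshold:
        raise ValueError("species_per_hotspot must exceed the hotspot threshold")

    records = pd.DataFrame(rec_rows, columns=["species_id", "x", "y"])
    proj = TransverseMercator(cfg.lon0, cfg.lat0)
    # geographic anchor: the plane's origin maps to (lon0, lat0) offset so
    # the island sits around the anchor point
    half = cfg.size_km * 1000 / 2
    lon, lat = proj.inverse(records["x"].to_numpy() - half, records["y"].to_numpy() - half)
    records["lon"] = lon
    records["lat"] = lat
    records["precision_m"] = 10.0
    records["source"] = "synthetic"
    species_truth = pd.DataFrame(truth_rows)

    # --- management polygons
    layers = ManagementLayers()
    planted = sorted(hotspot_truth)
    for hx, hy in planted[: cfg.n_protected_hotspots]:
        layers.protected_areas.append(box(hx * hcell, hy * hcell, (hx + 1) * hcell, (hy + 1) * hcell))
    nes_candidates = species_truth[
        (species_truth["n_locations_true"] <= 3) & (~species_truth["planted_hotspot"])
    ]["species_id"].tolist()
    mined = list(rng.choice(nes_candidates, size=min(cfg.n_mined_species, len(nes_candidates)),
                            replace=False))
    for sp in mined:
        pts = records[records["species_id"] == sp]
        layers.mining_areas.append(
            box(pts["x"].min() - 500, pts["y"].min() - 500, pts["x"].max() + 500, pts["y"].max() + 500)
        )
    species_truth["mined_all_records"] = species_truth["species_id"].isin(mined)
    # a couple of named features over the first two planted hotspots
    for i, (hx, hy) in enumerate(planted[:2]):
        layers.named_features[f"massif_{i}"] = box(
            (hx - 1) * hcell, (hy - 1) * hcell, (hx + 2) * hcell, (hy + 2) * hcell
        )

    return SyntheticWorld(
        config=cfg,
        seed=seed,
        grid=grid,
        dem=dem,
        geology=geology,
        temperature=temperature,
        rainfall_true=rainfall_true,
        stations=stations,
        records=records,
        species_truth=species_truth,
        hotspot_truth=hotspot_truth,
        layers=layers,
        projection=proj,
    )


def effort_field(world: SyntheticWorld, mode: str = "uniform", strength: float = 1.0,
                 covariate: str = "elevation", seed: int = 0) -> Raster:
    """Sampling-intensity field for bias experiments.

    ``uniform`` is a constant field.  ``biased`` mixes a unit-scaled
    covariate with iid noise: intensity = strength * scaled_covariate +
    (1 - strength) * U(0, 1), so strength 0 is statistically uniform and
    strength 1 is perfectly covariate-driven.
    """
    grid = world.grid
    if mode == "uniform":
        return Raster(np.ones(grid.shape), grid)
    if mode != "biased":
        raise ValueError(f"unknown mode {mode!r}")
    layer = {"elevation": world.dem, "rainfall": world.rainfall_true,
             "temperature": world.temperature}[covariate]
    v = layer.values.astype(float)
    rngmax, rngmin = v.max(), v.min()
    scaled = (v - rngmin) / (rngmax - rngmin) if rngmax > rngmin else np.zeros_like(v)
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=grid.shape)
    return Raster(strength * scaled + (1.0 - strength) * u, grid)


def orographic_rainfall(world: SyntheticWorld, relief_scale_km: float = 5.0,
                        relief_mm_per_m: float = 3.0, seed: int = 1) -> pd.DataFrame:
    """Station table for a rainfall field with fine-scale topographic signal.

    On top of the linear elevation trend, rainfall gains a term proportional
    to the local relief (cell elevation minus the mean elevation within
    ``relief_scale_km``) — an orographic-exposure effect that a trivariate
    spline on (x, y, z) cannot represent but multi-scale topographic
    components can.  Returns a station table sampling this field at the
    world's station locations.
    """
    from scipy import ndimage

    cfg = world.config
    r = max(int(round(relief_scale_km / cfg.cell_km)), 1)
    z = world.dem.values
    zmean = ndimage.uniform_filter(z, size=2 * r + 1, mode="nearest")
    relief = z - zmean
    rng = np.random.default_rng(seed)
    noise = gaussian_random_field_sampler(rng, cfg.rain_noise_sd_mm / 3, cfg.rain_noise_range_km * 1000)
    xs, ys = world.grid.cell_centers()
    field = (
        cfg.rain_intercept_mm + cfg.rain_per_m * z + relief_mm_per_m * relief + noise(xs, ys)
    )
    st = world.stations.copy()
    ix, iy = world.grid.cell_index(st["x"].to_numpy(), st["y"].to_numpy())
    st["rainfall"] = field[iy, ix]
    return st
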