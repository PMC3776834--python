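"""Generate the study landscape and write it to disk.

Builds the default synthetic world — mountainous DEM, four-class substrate
mosaic (ultramafic near a third of the land), lapse-rate temperature,
elevation-driven rainfall with spatially correlated noise, 60 weather
stations, 200 species in three ecological groups plus four planted hotspot
cells, and protected/mining polygons — and writes the occurrence table,
station table, rasters, management polygons and the ground-truth sidecar.
"""

import json
from pathlib import Path

from nes_atlas.grids import write_ascii_grid
from nes_atlas.occurrence_io import write_management_layers, write_occurrences
from nes_atlas.synthetic_data import generate_world

WORLD_SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "world"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    world = generate_world(seed=WORLD_SEED)

    write_occurrences(world.records, OUT / "occurrences.csv")
    world.records.to_csv(OUT / "occurrences_projected.csv", index=False)
    world.stations.to_csv(OUT / "stations.csv", index=False)
    for name, raster in [("dem", world.dem), ("geology", world.geology),
                         ("temperature", world.temperature), ("rainfall_true", world.rainfall_true)]:
        write_ascii_grid(raster, OUT / f"{name}.asc")
    write_management_layers(world.layers, OUT / "management.geojson")
    world.species_truth.to_csv(OUT / "species_truth.csv", index=False)
    truth = {
        "seed": world.seed,
        "hotspot_cells": sorted(world.hotspot_truth),
        "n_species": int(world.species_truth.shape[0]),
        "n_records": int(len(world.records)),
        "checksum": world.checksum(),
    }
    with open(OUT / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)

    share_u = float((world.geology.values == 1.0).mean())
    print(f"world seed {WORLD_SEED}: {truth['n_species']} species, {truth['n_records']} records")
    print(f"ultramafic share of land: {share_u:.2f} (target ~1/3)")
    print(f"planted hotspot cells: {truth['hotspot_cells']}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
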