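# nes_atlas

Conservation prioritisation for narrow endemic plant species (NES) on
gridded landscapes — classification by distributional discontinuity,
endemism-hotspot mapping, protection/mining threat overlays, and
group-level habitat-suitability modelling, with a ground-truthed synthetic
landscape generator so the whole pipeline is testable end to end.

The design follows the analysis applied to the New Caledonian flora, a
global biodiversity hotspot where a fifth of the assessed species are
recorded from three or fewer locations and open-cast nickel mining
concentrates on the very substrate (ultramafic soils) that hosts the most
localised species.

## What it computes

- **NES classes.**  A species' *locations* are single-linkage connected
  components of its records at a 10-km discontinuity threshold; species
  with 1, 2 or 3 locations are NES 1/2/3.  IUCN-style range metrics are
  attached: area of occupancy AOO (occupied 2-km cells × 4 km²) and extent
  of occurrence EOO (convex-hull area).
- **Hotspots (HPNE).**  Cells of a 2 × 2 km grid holding more than 7
  distinct NES, with named-feature aggregation, grid-origin sensitivity,
  and an effort-vs-richness sampling-bias check.
- **Threats.**  Per-species fractions of records in protected areas and
  mining footprints, priority flags for unprotected species whose range is
  wholly or mostly mined, and per-hotspot protection/mining/substrate
  flags.  A transcription of the published table of 36 New Caledonian
  HPNE ships with the package.
- **Environment.**  Slope from the DEM (Horn stencil) and rainfall
  interpolated from stations by multi-scale topographic PCA + linear
  regression + ordinary kriging of residuals, truncated at 4900 mm, with a
  leave-one-station-out comparison against a trivariate thin-plate spline.
- **Ecological groups.**  Species-level environmental summaries, Gower
  distances, PAM / UPGMA / NMDS, and an isolation-filtered choice of the
  number of groups.
- **Habitat suitability.**  A presence-background maximum-entropy model
  (linear+quadratic+categorical features, L1 regularisation, coordinate
  ascent) fitted per ecological group:

      p(x) = exp(λ·f(x)) / Z,   λ = argmax  mean_pres(λ·f) − log Z(λ) − Σ β_j|λ_j|

  with logistic output `τ e^H p/(1−τ+τ e^H p)`, τ = 0.5, test AUC,
  percent contributions, permutation importances, marginal responses, and
  a cross-classification of hotspots against high-suitability (>0.75)
  habitat that flags candidate under-sampled sites.

`docs/methods.md` gives the full model descriptions, defaults and
numerical decisions.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on the
default synthetic island (100 × 100 km, 240 species, seed 1), writing
tables and rasters under `results/`:

```bash
python analysis/01_simulate_world.py
python analysis/02_classify_species.py
python analysis/03_map_hotspots.py
```

which prints, among other things:

```
world seed 1: 240 species, 2722 records
ultramafic share of land: 0.34 (target ~1/3)
species per class: {'NES1': 107, 'not_NES': 66, 'NES2': 37, 'NES3': 30}
planted-class recovery: 100.0%
4 hotspot cells (>7 NES per 4 km^2)
all 4 planted hotspots flagged: True
hotspot count over 16 grid origins: min 3, median 4, max 4
effort-richness correlation under uniform effort: r=-0.002 (p=0.91)
```

Every generated species' planted location count is recovered exactly by
the 10-km rule (the generator's separation margins guarantee it), all four
planted hotspot cells are flagged, shifting the grid origin can cost at
most one hotspot, and under a uniform collection effort the
effort–richness correlation is indistinguishable from zero — the
null-case behaviour the sampling-bias check must have.  Continuing,

```bash
python analysis/05_build_env_stack.py   # rainfall interpolation + jackknife
python analysis/06_group_species.py     # Gower/PAM/UPGMA/NMDS grouping
python analysis/07_model_habitat.py     # maxent per group
```

reports the two-step interpolation beating the thin-plate spline in the
jackknife (RMSE 89 vs 95 mm on the orographic test field), substrate-pure
ecological groups (ARI 0.975 against the planted groups once the
single-cell hotspot species are set aside), and per-group maxent test AUCs
of 0.86–0.91 with substrate the top-ranked covariate — the regime reported
for the real flora.

## Layout

```
src/nes_atlas/     library: occurrence_io, synthetic_data, nes_classification,
                   hotspot_grid, threat_overlay, environment, eco_grouping,
                   habitat_suitability, grids, projection
analysis/          numbered drivers over the library (01 simulate ... 07 model)
tests/             pytest suite (unit, property and end-to-end recovery tests)
scripts/           acceptance.py
docs/methods.md    models, defaults, numerical decisions, limitations
```
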