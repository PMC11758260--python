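# ednatrack

Where did sampled environmental DNA come from?

Environmental DNA (eDNA) metabarcoding detects species from water samples
without ever seeing the animal — invaluable for monitoring elusive,
threatened taxa such as sharks and rays in turbid coastal waters. But eDNA
drifts: tidal currents can carry it kilometres between shedding and
sampling, so a detection at a station is really a detection *somewhere in
the water that passed through that station* during the DNA's detectability
window. `ednatrack` couples the two halves of that problem:

1. **Detection filtering** — a conservative, auditable filter chain that
   turns a noisy ASV (amplicon sequence variant) read table into a boolean
   species × station × month detection matrix: paired negative-control
   subtraction, target-class restriction, per-sample singleton removal,
   genus-level/confidence taxonomy rules and contaminant removal.
2. **Lagrangian particle backtracking** — virtual particles released at
   each detection's station and sampling time are advected *backwards*
   through depth-averaged currents for a fixed decay window, mapping the
   plausible source area of the detected DNA.

It is aimed at marine ecologists and eDNA practitioners who have (or can
simulate) gridded 2-D current fields and a post-denoising metabarcoding
table, and want dispersal-aware interpretation of their detections.

## The model

**Backtracking.** A particle at position **x** is passively advected,
d**x**/dt = **u**(**x**, t), with no added diffusion. Backtracking solves
the same equation through the time-reversed field
**u**′(**x**, t′) = −**u**(**x**, T − t′), so integrating forward in t′ is
integration backwards in real time, and every particle arrives at the
station at the exact sampling time. Integration is fixed-step RK4 (default
dt = 60 s) on bilinear-in-space, linear-in-time interpolated velocities;
dry grid cells contribute zero velocity with interpolation weights
renormalised over wet corners. Particles hitting land or the open boundary
are frozen at their last valid position and keep contributing to counts.

**Release protocol.** Per station and sampling time: 1000 particles seeded
uniformly over a 200 m disc, tracked 3 days before sampling (a hard proxy
for eDNA decay: UK coastal eDNA is detectable for roughly 48 h), positions
recorded every 5 min (865 records per particle).

**Dispersal products.** On a regular 1 × 1 km analysis grid: the density
heatmap is the percentage of *all* particle-records in each cell
(100 · n_cell / (particles × records), so the grid sums to exactly 100 %);
the maximum straight-line distance is max over particles and records of
the distance from the station; the areal extent is (number of visited
cells) × 1 km²; connectivity[i, j] is the fraction of particles
backtracked from station i that ever pass within 1 km of station j —
non-zero entries flag stations whose samples may not be independent.

**Detection filtering.** In order: (1) any ASV with ≥ 1 read in a sample's
paired field control is zeroed in that sample; (2) ASVs outside the target
class (default Elasmobranchii) are dropped; (3) cells with exactly 1 read
(singletons) are zeroed; (4) ASVs not assigned to at least genus level at
≥ 40 % confidence, and known cross-project contaminants, are dropped —
genus-only ASVs are kept but excluded from species-level counts; (5) any
surviving positive cell is a detection. Every step logs rows/reads in and
out and cells zeroed.

## Worked example

```python
import numpy as np
from ednatrack import (
    GridSpec, ReleaseSpec, Station, backtrack, density_heatmap,
    make_bay_field, make_survey, max_straight_line_distance, areal_extent,
    run_filter_chain, summarize,
)

# 3-day backtracking release from a station in a synthetic tidal bay
field = make_bay_field(duration=340_000.0)          # 20 x 20 km, M2-like tide
station = Station("S01", 15_000.0, 10_000.0)
spec = ReleaseSpec(n_particles=1000, seed=42)       # 1000 particles, 200 m disc
traj = backtrack(field, station, sample_time=300_000.0, spec=spec)

grid = GridSpec(0.0, 0.0, n_x=20, n_y=20, cell_size=1000.0)
heat = density_heatmap([traj], grid)
print(f"max straight-line distance: {max_straight_line_distance(traj):.2f} km")
print(f"areal extent:               {areal_extent([traj], grid):.1f} km^2")
print(f"heatmap total:              {heat.total():.6f} %")
print(f"peak cell density:          {heat.density.max():.2f} %")

# metabarcoding survey -> filtered detection matrix
table, meta, truth = make_survey(seed=7, leakage_rate=0.05, singleton_rate=0.05)
filtered, matrix = run_filter_chain(table, meta, contaminant_list=truth.contaminant_list)
s = summarize(matrix, meta)
print(f"species detected:           {s['species_richness']}")
print(f"positive samples:           {s['n_samples_with_detection']} of "
      f"{s['n_samples_total']} ({s['pct_samples_with_detection']}%)")
```

Output:

```
max straight-line distance: 5.58 km
areal extent:               16.0 km^2
heatmap total:              100.000000 %
peak cell density:          22.17 %
species detected:           11
positive samples:           53 of 120 (44.2%)
```

The eDNA sampled at station S01 could have been shed up to ~5.6 km away,
anywhere in a 16 km² area; the densest cell held 22 % of all simulated
particle positions, so the most likely source is close to the station. Of
120 synthetic water samples, 53 (44.2 %) contained at least one of the 11
planted elasmobranch species after filtering.

## Command line

`ednatrack` installs a CLI mirroring the library: `ednatrack synth flow` /
`synth survey` generate inputs; `ednatrack backtrack --config run.yaml`
runs one release per station per sampling time and writes per-release
statistics, the pooled heatmap (netCDF + PNG), per-campaign connectivity
matrices and a JSON manifest; `ednatrack detect` runs the filter chain and
writes the detection matrix, attrition log and accumulation curve;
`ednatrack report` joins each detection to its release's dispersal
products and aggregates mean/sd over detection-coincident releases.

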