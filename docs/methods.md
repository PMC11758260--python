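# Methods

This note records the scientific and numerical choices behind
`ednatrack`: what is modelled, what the defaults mean, what the synthetic
generators do and do not emulate, and where the design was genuinely open.

## Transport model

Currents are depth-averaged (2-D), appropriate for shallow, well-mixed
coastal water in which eDNA is assumed neutrally buoyant. Particles are
passive tracers: d**x**/dt = **u**(**x**, t), with no behaviour, buoyancy
or settling. Sub-grid diffusion is off by default (`ReleaseSpec.diffusivity
= 0`); a random-walk term (step s.d. √(2K dt)) exists for sensitivity work
but is untested against any reference and deliberately not part of the
default protocol. Note that with diffusion enabled, backtracking is no
longer the deterministic inverse of forward advection.

Backtracking is implemented by time reversal: the reversed field has
times t′_k = T − t_{n−1−k} (re-anchored at 0) and velocities −u, −v
reversed along the time axis, so the tracker treats backtracking as
ordinary forward integration and the arrival constraint — particles at
the station at the exact sampling instant — holds by construction at
elapsed 0. Reversal preserves speed and the wet mask.

## Release protocol defaults

| parameter        | default          | meaning                                       |
|------------------|------------------|-----------------------------------------------|
| n_particles      | 1000             | particles per release                         |
| radius           | 200 m            | release disc about the station                |
| duration         | 259 200 s (3 d)  | decay-window proxy; trajectories stop here    |
| record_interval  | 300 s (5 min)    | position recording cadence (865 records)      |
| dt               | 60 s             | RK4 step                                      |

The 3-day window is a deliberately conservative envelope around the ~48 h
detectability of coastal eDNA (half-life roughly a day); decay is not
otherwise parameterised. The disc release absorbs station-position and
grid-resolution uncertainty; seeding uses the √U radial transform so
density is uniform per unit area.

## Numerics

* **Interpolation**: bilinear in space on the node grid, linear in time.
  Node values are recovered exactly; the scheme is continuous across cell
  interiors. Dry nodes contribute zero velocity and their weights are
  renormalised over the wet corners of the quad; an all-dry quad yields
  (0, 0). The underlying data model is a structured regular grid; an
  unstructured-mesh hindcast would be regridded before use.
* **Integrator**: fixed-step classical RK4. On the synthetic bay field a
  3-day integration changes by < 1 mm when dt is halved from 60 s to
  30 s, and a full backtrack → forward-advect round trip returns particles
  to their release positions to ~1e-7 m, so integration error is far below
  the 1 km analysis-grid scale.
* **Boundary policy**: a particle whose RK4 step lands on a dry cell is
  flagged `beached`; one leaving the bounding box is flagged
  `out_of_domain`. Both are frozen at their last valid position,
  irreversibly (status is monotone), and frozen particles keep
  contributing records so the heatmap normalisation (particles × records)
  is conserved and the density grid sums to exactly 100 %. No
  resuspension is modelled.
* **Grid convention**: analysis cells are half-open
  [origin + i·cell, origin + (i+1)·cell), anchored at the domain
  lower-left corner; the grid auto-expands on its own lattice so no
  record is dropped. Areal extent is the union of visited cells × cell
  area — a definition tied to the 1 km² tally grid rather than, e.g., a
  convex hull.
* **Distances** are measured from the station, not each particle's own
  release point (the difference is bounded by the 200 m release radius).
* **Coordinates** are local projected metres; `lonlat_to_xy` provides an
  equirectangular projection about a reference latitude, adequate at bay
  scale.

## Connectivity

`fraction[i, j]` is the share of particles backtracked from station i
with any record within 1 km of station j; `fraction > 0` is the
"potentially connected" view used to flag non-independent stations. The
diagonal is 1 by construction (release radius ≤ connectivity radius).
Fractions are invariant to particle relabelling and monotone in the
radius. The any-visit rule is a declared choice; a density-thresholded
variant could be stricter.

## Detection filter chain

Order: control subtraction → target-class filter → singleton removal →
taxonomy rules → detection matrix. Choices worth stating:

* Control subtraction runs **once, first**, using each sample's paired
  field control; a `second_control_pass` switch exists for sensitivity
  checks (after control columns are dropped it cannot remove anything
  further, and it is logged as such). Extraction/PCR blanks are screened —
  their target reads are reported in the attrition log — but not
  subtracted.
* Singletons are zeroed **per cell** (exactly 1 read in that sample), not
  row-dropped, so a taxon can survive via other samples.
* Taxonomy uses a single per-row assignment confidence compared to the
  40 % threshold; rows confident only to genus are retained as
  genus-level records but excluded from species-level detection counts.
  Unassigned-class rows are dropped at the target filter (they cannot be
  confirmed in-group) and counted in the log.
* After the chain, any positive cell implies ≥ 2 reads, which is the
  detection criterion.

Species accumulation curves are plain sample-based permutation curves
(mean cumulative richness over random sample orderings); no asymptotic
richness extrapolation is attempted.

## Synthetic generators

* **Flow fields.** `make_uniform_field` (closed-form oracle),
  `make_tidal_field` (spatially uniform single-constituent tide + steady
  residual; one M2-like constituent of period 44 712 s stands in for a
  full harmonic synthesis — it preserves the oscillatory-plus-residual
  structure that drives dispersal asymmetry, nothing more), and
  `make_bay_field` (square 20 × 20 km bay, 500 m nodes, land ring, gyre
  streamfunction ψ = Ψ sin(πx/L) sin(πy/L) modulated by the tide). The
  bay flow is divergence-free by construction and has no flow normal to
  the coast, so mid-gyre releases never beach — convenient for exact
  round-trip tests, and a known idealisation: no bathymetry, wind, river
  forcing, headlands or flow separation. Passing tests on these fields
  validates the *machinery* (integration, reversal, tallying), not any
  real circulation.
* **Surveys.** `make_survey` emulates a post-denoising ASV table for one
  survey: one water sample and one paired field control per
  station-month (10 stations × 12 months → 240 columns), an
  11-species elasmobranch pool, planted detections with log-normal read
  counts floored at 2, abundant human and teleost by-catch rows,
  cross-project contaminant rows (Indian Ocean elasmobranchs),
  family-only and genus-only rows. The default per-species
  detection probability (0.05) makes roughly 40–45 % of samples positive
  with ~0.5 detections per sample — the occupancy regime of a temperate
  coastal elasmobranch survey. Noise injection is bookkept exactly:
  leakage events are planted cells copied into the paired control (so
  control subtraction zeroes exactly those sample cells), and singleton
  events are 1-read cells injected into otherwise-empty target cells
  whose controls are clean (so singleton removal zeroes exactly those).
  Field controls carry no other reads; real controls can contain
  background contamination, which would make the leakage ledger an
  undercount in the field. Read depths, chimeras, index hopping and
  multi-ASV species are not modelled.

## Problem sizes

The shipped test suite and the acceptance script run at desk scale,
chosen so the full study remains a few minutes of single-core work: the
bay campaign uses 2 stations × 12 sampling campaigns × 1000 particles
(the 12 campaigns are spaced 2 days apart on one synthetic field — a
compressed stand-in for monthly sampling, which changes nothing in the
release arithmetic), and unit tests use 10–200 particles with shortened
windows except where a check is explicitly about the full 3-day window.

## Known limitations

2-D depth-averaged transport only; hard decay cutoff instead of
first-order decay kinetics; structured grids only; freeze-on-contact
boundary handling; single-confidence taxonomy; synthetic flows are
idealised analytic fields, not hindcasts. Dispersal statistics computed
on the synthetic bay characterise the pipeline, not any real coastline.
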