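# Methods

`trapchip` models a massively parallel single-cell phenotyping chip: a
silicon microfluidic device in which a binary flow-division tree feeds 128
parallel "streets", each a serial chain of 47 weir-trap/apartment unit
cells (6016 traps per chip). Single cells are captured in the trap
constrictions, transferred into culture apartments by a pressure pulse,
grown for days under perfusion, and imaged daily; per-apartment cell counts
yield clonal growth rates and drug-response statistics. The package
implements the hydraulic circuit model, a stochastic loading simulator, a
ground-truth-annotated synthetic imager, the image-quantification pipeline
and the clonal statistics, end to end.

## Hydraulic circuit model

Each street is an equivalent resistor network solved as a weighted graph
Laplacian with the inlet and outlet held at fixed pressures (the outlet is
the ground reference; sparse symmetric solve). Only resistance ratios
matter; hydraulic units are arbitrary.

The unit cell is wired as a hexagonal Wheatstone bridge. Flow arriving at
junction `J_i` splits along two short approach arms (resistance
`R_rung / 2` each) onto the apartment rail (trap-entrance node `T_i`, then
the trap + apartment chamber, resistance `kappa * R_A` when occupied,
`R_A` when empty) and the serpentine rail (node `B_i`, then the long
narrow bypass, `R_S`); a short bypass rung (`R_rung`) connects `B_i` to
`T_i`, and both rails rejoin at `J_{i+1}`.

This wiring was chosen deliberately. A plain aligned two-rail ladder with
uniform resistances carries *identically zero* rung flow regardless of the
`R_A : R_S` ratio (both rails interpolate the same linear pressure
profile), and staggered rungs have a flow direction fixed by the stagger
rather than by the resistances — neither reproduces the two flow regimes
the device exhibits. The bridge does: with equal approach arms, the rung
flow is exactly zero at `kappa * R_A = R_S` and flips sign across it, so

* `R_A < R_S` (empty trap): the rung joins flow *into* the trap entrance;
  the apartment edge is the only outflow at `T_i`, so the capture fraction
  (apartment outflow over total flow arriving at the entrance) is exactly
  1 — the "perfect trap" regime;
* `kappa * R_A > R_S` (occupied trap): the rung reverses, diverting
  arriving fluid around the trap, and the capture fraction drops well
  below the empty traps' — the self-limiting switch.

Note the switching condition: occupancy must satisfy `kappa > R_S / R_A`.
At `kappa * R_A = R_S` exactly, the bridge is balanced and no diversion
occurs. Defaults (`R_A = 1`, `R_S = 10`, `R_rung = R_A / 10`,
`kappa = 100`) put both regimes far from the boundary.

The capture fraction is defined at the trap-entrance node (the fraction of
impinging flow that sweeps through the apartment), not as the apartment
flow over the street throughflow: in a connected ladder whose serpentine
rail carries any flow, the latter can never reach 1 for every trap
(Kirchhoff cut argument), whereas the per-node fraction is exactly the
branch probability an advected cell experiences. Rungs with flow below
`1e-12` of the throughflow are labelled neutral, making the `R_A = R_S`
boundary reproducible.

## Loading simulator

Cells are introduced one at a time. Street assignment follows the binary
tree split (uniform multinomial by default; per-street weights
configurable). Within a street, a cell visits trap entrances in series and
enters each with probability equal to the current capture fraction at that
entrance; entry into a retaining (non-defective, non-full) trap is
capture. Flows are re-solved after every capture (only captures change the
resistances) with an O(n) banded solver that is property-tested equal to
the general graph solver. Degenerate branches (probability within `1e-12`
of 0 or 1) and rejections at full/defective traps consume no randomness,
so ideal loading is reproducible across seeds and fills the street exactly
in introduction order. Cells passing the last trap are washed out;
conservation holds as `introduced = captured + washed_out` (doublets count
as two cells; cells rejected by a defective trap continue downstream
rather than being destroyed).

Free parameters deliberately treated as emulation knobs, not measurements:
`defect_prob` (default 0 in the API; 0.07 in calibration runs) models
traps unable to retain a cell (fabrication defects, debris), and
`doublet_prob` (0.10 in calibration runs) models incompletely dissociated
pairs. With loads of 1.5 cells per trap these defaults reproduce the
target occupancy profile (~7% empty, ~83% singlet, ~10% multiple).
Pairing runs use 2.2% defects / 11.4% doublets and saturating loads
(3 cells per trap per round) to emulate a well-filled 320-apartment
section; trap-level defects persist across the two rounds, which raises
the 1:1 pair fraction slightly above the independence value `s^2`.
Transfer pulses move each trapped cell into its apartment independently
with `transfer_success_prob` (default 1); after transfer the constriction
is empty again, so a second load re-captures (`kappa` applies to cells in
the trap, not cells already in the apartment). Trap-geometry numbers
(3–6 um trap widths, 300–800 mbar pulses) are carried as metadata only.

## Clone populations

Each apartment founds a clone with division rate `lam` (divisions/day)
drawn per cohort: control `N(0.95, 0.2075^2)` (median 0.95, quartiles
0.81–1.09, matching the observed 0.84–1.12 up to normality), 0.5 nM drug
`N(0.55, 0.40^2)`, 1.5 nM `N(-0.20, 0.35^2)` (mostly dying). A
`resistant_fraction` (default 0.05%) of clones draws from the drug-free
distribution regardless of cohort. Clone median cell areas are lognormal
(137 um^2 control, 126 um^2 at 0.5 nM, sigma ~0.087 in log); a
`large_cell_fraction` (default 0.05%) of clones carries cells 2.5x the
median area. Eccentricities are Beta(2,3) scaled to [0, 0.75].

Counts follow `p(t) = p0 * 2**(lam * t)` integerized by
expectation-preserving stochastic rounding (`floor + Bernoulli(frac)`),
which emulates asynchronous division and keeps the mean fitted rate over a
clone population within 0.05 of the generating rate for `lam` in
[0.2, 1.5] over four daily timepoints. Deterministic rounding is available
(`integerize="round"`) but biases small-count trajectories (e.g.
`lam = 0.55` yields counts 1,1,2,3,5 and a fitted slope of 0.62); at very
low rates the integer resolution of counts limits any single trajectory
regardless. Counts are capped at the apartment carrying capacity (default
40; the renderer further caps at its 12 placement slots), emulating
under-counting in crowded apartments — fitted rates there are a lower
bound, which is property-tested. A clone whose count reaches zero stays at
zero (dead cells are washed out by the perfusion).

## Synthetic imaging and its limits

Fields of view tile 2 x 10 apartments at a 180 x 134 px pitch
(0.65 um/px, 16-bit grayscale). Each apartment crop carries an etched
cross fiducial, a 7-segment-style digit address (street + position; glyph
bitmaps shared between renderer and decoder), chamber outlines, and cells
as shaded ellipses — darker rim in brightfield, luminous nucleus
sub-ellipse in the nuclear channel, perimeter-weighted ring in the
surface-stain channel. Whole-image rigid rotation/translation jitter and
additive Gaussian noise are configurable; every rendered cell is recorded
in a ground-truth table.

Cells are placed on a jittered 28 px grid inside the apartment ROI so that
neighbouring cells remain separable by a classical segmenter; the pitch
was chosen so that the largest plausible cells (≈170 um^2) do not merge.
The imager does not model point-spread functions, z-stacks, focus quality,
uneven illumination, cell motion between frames, or realistic cell
texture. Passing round-trip tests therefore demonstrates the pipeline's
geometric and bookkeeping correctness — shared fixed offsets, rotation
inversion, registration, decoding, ROI filtering, count assembly — not
segmentation performance on real micrographs, where a trained instance
model would replace the watershed stand-in behind the same interface.

## Image quantification

Markers are found by normalized cross-correlation against the marker
template with non-maximum suppression at half the apartment pitch and 3x3
centroid subpixel refinement. Image rotation is estimated from
near-horizontal marker pairs in two passes (adjacent pairs for a coarse
median, then all baselines within 3 degrees of it), giving a mean error
well under 0.1 degrees on rotations in [-5, 5]; the image is rotated back
before cropping at fixed marker offsets, and each crop is registered to an
empty template rendering by integer-pixel phase correlation. Digits are
decoded by normalized correlation against the shared glyph bank;
confidence is the margin between the top two matches, and low-confidence
or out-of-layout addresses are flagged unreliable (apartments partially
rotated out of frame are the typical case).

Segmentation thresholds dark objects against the median background,
cleans small components, and splits touching cells by watershed seeded at
peaks of the Gaussian-smoothed distance transform (minimum separation 0.6
expected cell diameters). Detections are kept by centroid-in-ROI
(apartment or trap); centroids in the flow-channel exclusion zones are
asserted never to occur. Features are mask-moment based: area = pixel
count x `pixel_size^2`, eccentricity from second-order central moments
(mask-moment convention, documented since fitted-ellipse conventions
differ), mean intensity per channel over the mask. Live/dead
classification is intentionally absent — dead cells are removed by the
perfusion before imaging.

## Clonal statistics

Analyses keep apartments that start from exactly one cell and hold at
least one cell at every timepoint; the filter is idempotent and
order-independent, and zero counts are never patched with pseudo-counts.
`lam` is the OLS slope of `log2(count)` on time (>= 3 timepoints), `p0 =
2**intercept`; `R^2` is defined as 1 for a perfectly flat trajectory.
Time-averaged area/eccentricity weight timepoints equally (cell-number
weighting would be an equally defensible convention; equal weighting is
the simpler and is used throughout). Cohort summaries use
linear-interpolation quantiles, since quartile bounds depend on the
convention.

Cohorts are compared by subsampling up to 1000 growth rates per cohort
without replacement, taking the difference of subsample medians, and
permuting pooled labels (add-one p-value `(1 + #{|null| >= |obs|}) /
(n_perm + 1)`). This is one admissible reading of a subsample-based
resampling test; a bootstrap of medians would be another, and the choice
is documented rather than canonical. Calibration: the null rejection rate
at alpha = 0.05 is 0.05 +/- 0.02 over 500 replicates; a 0.4 divisions/day
median shift at n = 1000 per cohort is detected at p < 0.001.

Rare large-cell clones are flagged by a robust z-score on time-averaged
area, `0.6745 * (area - median) / MAD >= 5`. The threshold 5 is a free
parameter (there is no formula for "substantially larger"); at the default
population parameters it recovers the configured 0.05% frequency within
Poisson error with essentially no false positives. Heatmaps export raw
counts and `log10(count + 1)` so empty and single-cell apartments stay
distinguishable.

## Reproducibility and problem sizes

Every stage derives its stream from the global seed and stage name
(`numpy.random.SeedSequence`), so stages rerun independently and the demo
pipeline is byte-reproducible. Outputs are stamped with a hash of the
configuration. The bundled study sizes — full 6016-trap chips for
occupancy (3–5 seeds), a 320-apartment section for pairing, 3000-clone
cohorts for growth statistics, 20000-clone populations (8 replicates in
the acceptance script) for rare-phenotype frequency, and a 200-apartment,
5-day chip for the imaging round trip — were chosen as the smallest
populations whose Monte Carlo error is comfortably below the effects being
demonstrated.

## Known limitations

* The circuit is a 1-D ladder; 2-D mesh arrays, deformable-cell mechanics
  in the constriction, transit-time dynamics and cell–cell hydrodynamic
  interactions are out of scope.
* The exact channel dimensions and resistance formulas of the fabricated
  device are not modelled; only ratios are meaningful, and the defect and
  doublet rates are calibration knobs, not measurements.
* The imaging model is geometric, not photometric (see above); classical
  detectors stand in for trained models behind the same interfaces.
* Trajectories track per-apartment counts, not cell lineages; hysteresis
  in growth is ignored by the exponential model.
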