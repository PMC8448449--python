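# trapchip

Simulation and analysis toolkit for massively parallel single-cell
phenotyping on microfluidic weir-trap array chips.

These chips capture tens of thousands of single cells in an addressed
array of culture "apartments" — a binary flow-division tree feeds 128
parallel streets of 47 trap/apartment unit cells (6016 traps) — then grow
each captured cell into a clone under perfusion and image every apartment
daily. Per-apartment counts over time give clonal division rates, and the
sheer scale makes phenotypes at frequencies down to ~0.05% measurable:
rare drug-resistant clones, abnormally large cells. `trapchip` implements
the computational core of such a platform for people designing trap
arrays, building image-quantification pipelines for them, or studying
clonal drug-response statistics:

* **Hydraulic ladder model** (`trapchip.ladder`) — each street as a chain
  of Wheatstone-bridge unit cells (apartment rail `R_A`, serpentine bypass
  rail `R_S`, short-bypass rung). Solved via the weighted graph Laplacian.
  For `R_A < R_S` every empty trap is *perfect*: the short bypass joins
  flow into the trap entrance and the capture fraction is exactly 1; an
  occupied trap (`kappa * R_A > R_S`) flips its rung and diverts cells
  downstream — self-limiting, near-deterministic loading.
* **Loading simulator** (`trapchip.loading`) — sequential cell
  introduction with flow re-solves after every capture, trap defects,
  doublets, transfer pulses, two-step cell pairing, occupancy statistics.
* **Synthetic imager** (`trapchip.population`, `trapchip.render`) —
  seeded multi-channel, multi-day fields of view with fiducial markers,
  etched digit addresses, and cells growing as
  `p(t) = p0 * 2**(lambda * t)`; pixel-exact ground truth for every cell.
* **Image pipeline** (`trapchip.extract`, `trapchip.quantify`) — marker
  detection, rotation inference, template registration, digit decoding,
  watershed cell segmentation with ROI filtering, per-cell morphology and
  stain intensities.
* **Clonal statistics** (`trapchip.analysis`) — single-cell-start
  filtering, log2 growth fits, cohort medians/quartiles, subsampled
  permutation tests between drug cohorts, robust-z rare-phenotype
  detection, occupancy heatmaps.

## Worked example

Run the demo workflow (two 2-street chips, one DMSO control and one
0.5 nM FLT3-inhibitor cohort, five daily timepoints, full
simulate → render → extract → quantify → analyze loop):

```bash
trapchip run-all --outdir demo_run --seed 0
```

which prints

```json
{
  "config_hash": "fa2fcb52d1e1",
  "DMSO": {
    "occupancy": {"empty": 0.05, "singlet": 0.8, "doublet": 0.15, "multiplet": 0.0},
    "median_lam": 0.898,
    "n_clones": 16
  },
  "0.5nM": {
    "occupancy": {"empty": 0.0, "singlet": 0.85, "doublet": 0.15, "multiplet": 0.0},
    "median_lam": 0.561,
    "n_clones": 16
  },
  "p_values": {"0.5nM": 0.008}
}
```

Reading it: loading captured a single cell in 80–85% of apartments; the 16
control clones that passed the single-cell-start filter divide ~0.9
times/day as measured from the rendered-and-requantified images, the
drugged clones ~0.56 times/day, and a subsampled permutation test on the
cohort medians calls the shift significant (p = 0.008 at this small demo
size). `demo_run/` holds the TIFF images, the manifest, ground-truth and
detection tables, growth-fit CSVs, cohort summaries and heatmaps, all
stamped with the config hash; reruns with the same seed are
byte-identical.

The same stages are ordinary functions, e.g.:

```python
from trapchip import LadderSpec, build_ladder, solve_flows, classify_regime
net = build_ladder(LadderSpec(n_traps=47, R_A=1, R_S=10))
report = classify_regime(solve_flows(net), net)
report.regime            # 'high-efficiency'
report.capture_fraction  # [1.0, 1.0, ..., 1.0]
```

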