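# nodalgrad

Simulation and quantification of the zebrafish **Nodal** morphogen
signaling gradient.

During the ~2.5 hours before gastrulation, Nodal ligands secreted from
the yolk syncytial layer (YSL) spread into the blastoderm and establish
a signaling gradient — read out as nuclear phospho-Smad2 — that decays
exponentially over a few cell tiers from the embryonic margin. The
range of this gradient is set not by feedback relays but by the EGF-CFC
co-receptor Oep, whose abundance determines how fast target cells
capture diffusing ligand. `nodalgrad` packages the two computational
halves of that story for modellers and quantitative imaging people:

* **Reaction–diffusion models.** A 2D diffusion–capture model
  (pseudo-first-order: capture rate `k1 = k_on·R0`) with embedded
  sensor-cell discs whose parameters differ from the host tissue, and a
  1D model with explicit receptor production (`k3`) and consumption.
  At steady state the ligand gradient is exponential with length scale
  **λ = √(D / k1)**; with receptor replacement removed (`k3 = 0`, the
  zygotic *oep*-mutant condition) the stable gradient transforms into a
  travelling wave of signaling that detaches from the source.
* **Immunofluorescence quantification.** Nuclear segmentation of DAPI
  confocal stacks (background subtraction → adaptive threshold →
  morphological filtering → 2D-to-3D centroid linking), per-nucleus
  channel intensities, distance-transform margin distances, GFP⁺/GFP⁻
  sensor classification against a sliding-median baseline, per-embryo
  baseline normalization, pooled 20 μm sliding-window gradients, and
  single-exponential fits `A·e^{b·d} + c` with cluster-robust 95%
  confidence bounds, plus half-distances, stage kymographs and
  source-clone profiles.
* **Synthetic data with ground truth** for both inputs: per-nucleus
  tables with the sensor-assay's statistical structure, and 3D
  multi-channel phantom stacks of nuclei behind a curved margin.

## Worked example

The `demo` subcommand runs both pipelines end to end: it generates a
wild-type-like synthetic assay (8 embryos × 400 nuclei, true decay
b = −0.02 μm⁻¹), pushes it through classification → normalization →
windowing → fitting, and runs the 1D model with and without receptor
replacement:

```bash
$ nodalgrad demo --seed 1 --out runs/demo
{
  "A": 2.704643129708708,
  "b": -0.01974575035572374,
  "c": 0.9114168617035843,
  "ci_A": 0.46561734081513906,
  "ci_b": 0.0007881873444322858,
  "ci_c": 0.01889353198043876,
  "rss": 312.47371528732083,
  "n": 3200
}
wave speed (k3>0 vs k3=0): 0.00012 vs 0.01958 um/s
demo complete in 4.0s -> runs/demo
```

Reading the output: the fitted decay `b = −0.0197 ± 0.0008 μm⁻¹`
recovers the generating gradient from 3200 noisy nuclei pooled across
eight embryos with different staining brightness (the run's report,
`runs/demo/report.json`, additionally records the sliding-window
half-distance of 39.8 μm). The two wave
speeds contrast the model's regimes: with receptor replacement the
signaling front is effectively stationary (0.0001 μm/s — a stable
gradient), while the same embryo deprived of receptor replenishment
propagates its signaling maximum outward at ~0.02 μm/s, crossing some
200 μm of tissue in 2.5 h.

The same stages are available individually (`simulate-2d`,
`simulate-1d`, `kymo`, `wavefront`, `segment`, `quantify`, `fit`,
`synth`) and as library functions; see `docs/methods.md` for the model
equations, parameter defaults and the quantification conventions.

As a library:

```python
from nodalgrad import (RateParams, Geometry1D, simulate_receptor_dynamics_1d,
                       steady_state_length_scale)

p = RateParams()                      # D=4 um^2/s, k_on*R0=0.0025/s, ...
series = simulate_receptor_dynamics_1d(Geometry1D(), p, duration=9000)
print(steady_state_length_scale(p))   # 40.0 (um)
```

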