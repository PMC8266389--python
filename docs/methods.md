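# Methods

`nodalgrad` implements two linked pieces of machinery for studying how
the Nodal morphogen signaling gradient forms at the zebrafish embryonic
margin: reaction–diffusion models in which the EGF-CFC co-receptor (Oep)
sets the rate at which target cells capture diffusing ligand, and the
immunofluorescence quantification pipeline that turns confocal stacks of
α-pSmad2–stained embryos into per-nucleus gradient read-outs. A
synthetic-data module generates both kinds of raw input with known
ground truth so every stage can be validated end to end.

## Reaction–diffusion models

### 2D diffusion–capture (pseudo-first-order)

Nodal ligand `L` is secreted at constant rate density `s` in a 5 μm
source strip at one end of a 100 × 300 μm tissue slab (the yolk
syncytial layer margin), diffuses freely with coefficient `D`, and is
captured by cell-surface receptor complexes under pseudo-first-order
kinetics — the free-receptor level `R0(x, y)` is held constant per
region, giving an effective capture rate `k1 = k_on · R0`:

    ∂L/∂t = D ∇²L − k_on R0(x,y) L + s · 1_source(x,y)
    ∂C/∂t = k_on R0(x,y) L − k_int C
    ∂P/∂t = k_phos C

with no-flux boundaries and `L = C = P = 0` at the onset of secretion
(t = 0). Phospho-Smad2 `P` is a pure integrator of complex
concentration — no dephosphorylation term by default, since the
simulated quantity is accumulated signaling activity over the ~2.5 h of
gradient formation.

Sensor-cell assays are simulated as 6 μm circular sub-domains carrying
their own rate parameters (e.g. wild-type receptor levels inside a
receptor-free host). The discs are purely parameter heterogeneity:
`L` and `C` are continuous across their boundaries (permeable
interfaces, no interface resistance). Source-strip cells carry the
host's reaction parameters in addition to the production term.

### 1D receptor turnover

To ask what receptor replenishment contributes, the 1D variant makes
the free receptor `R` dynamic: produced at constant rate `k3`, removed
constitutively at rate `delta_R` and consumed by ligand binding:

    ∂L/∂t = D ∂²L/∂x² − k_on R L + s · 1_source
    ∂R/∂t = k3 − delta_R R − k_on R L
    ∂C/∂t = k_on R L − k_int C
    ∂P/∂t = k_phos C

`R` starts at its turnover steady state `k3/delta_R` when `k3 > 0`, or
at a finite maternal pool (default: the wild-type steady-state level)
when `k3 = 0` — the zygotic-mutant condition in which maternally
provided co-receptor is never replaced. A `fixed_receptor` switch
freezes `R`, reducing the model to the pseudo-first-order one; this is
the bridge used to cross-check the 2D solver (a y-invariant 2D problem
must reproduce the 1D solution, and does to ~1e-7 relative).

With turnover on, the system settles into a stable exponential gradient
with length scale `λ = sqrt(D / (k_on · k3/delta_R))`. With `k3 = 0`,
receptors near the source are progressively consumed, ligand penetrates
the depleted zone, and the signaling maximum (max of `C`) detaches from
the source and travels outward — a receptor-consumption wave requiring
no signaling feedback.

### Parameter defaults and why

The defaults (all overridable per config) are:

| parameter | default | units | rationale |
|---|---|---|---|
| `D` | 4 | μm²/s | measured range for GFP-tagged zebrafish Nodals (~0.5–5 μm²/s); upper end for the faster-spreading ligand |
| `k_on·R0` | 0.0025 | 1/s | sets λ = sqrt(D/k1) = 40 μm, matching the measured signaling range (half-distance ~37 μm) |
| `k_int` | 0.01 | 1/s | complex lifetime ~100 s, well inside the 2.5 h window so `C` tracks `L` |
| `k_phos` | 0.01 | 1/s per complex | scale factor only (linear readout) |
| `s` | 0.002 | conc/s | amplitude scale in the linear 2D model; in the 1D model, together with `R`, sets the consumption rate |
| `k3`, `delta_R` | 5e-4 | resp. units/s, 1/s | receptor turnover time 1/delta_R ≈ 2000 s; fast enough that replacement outpaces consumption (`k_on·L ≈ 2.5e-4`/s near the source), keeping the wild-type gradient pseudo-first-order and stable within 2.5 h, while the `k3 = 0` variant's wave (speed ≈ `s · source_depth / R_init` ≈ 0.02 μm/s) crosses >100 μm of tissue over the simulated window |

These constants are a calibrated, documented set — chosen from the
model's structure and the measured length scale, not copied from any
source — and the package's claims are about the model's qualitative
regimes (stable gradient vs travelling wave; gradient expansion and
contraction with receptor levels), which are robust across wide
parameter ranges.

### Numerics

Both solvers use method-of-lines finite differences: second-order
central Laplacian on a cell-centered grid (2 μm in 2D, 1 μm in 1D),
no-flux boundaries via mirror fluxes, explicit forward-Euler time
stepping with the step chosen automatically as 0.8× the tighter of the
diffusion CFL limit (`dx²/4D` in 2D, `dx²/2D` in 1D) and the fastest
reaction rate. The problems are non-stiff at these grids, so the
explicit scheme is the simplest convergent choice; halving the 1D grid
changes the fitted length scale by <0.1% (tested), and the fitted λ
matches the closed form `sqrt(D/k1)` to <1% across a 3×3 (D, k1) grid.
Divergence (NaN/Inf) raises immediately with a CFL/step failure
message. The solvers are fully deterministic; the only randomness in
the simulation module is sensor placement, which takes an explicit
seed.

Kymographs sample every species at 20 s columns starting at t = 0 to
capture the formation transients, source at row 0. The wavefront
tracker takes, per column, the largest position where the profile
crosses a fraction (default 0.5) of *that column's* maximum —
per-column normalization is what lets the tracker follow the
consumption wave while its amplitude decays — and estimates speed as
the slope of a least-squares line over the final third of columns.

## Image quantification pipeline

1. **Out-of-plane background subtraction.** The out-of-focus
   contribution to each DAPI slice is approximated by Gaussian-blurring
   (σ = 10 px) the mean of its two neighbouring slices and subtracting,
   clamped at zero. Edge slices (and slices at the user-supplied
   z-bounds, which in real data exclude internal YSL nuclei) use their
   single available neighbour rather than being dropped.
2. **2D segmentation.** Local-mean adaptive threshold (window 51 px,
   offset 2 intensity counts), binary opening with a 2 px disc, area
   filter at 50 px². The offset default is small but nonzero: with a
   zero offset, half of all background pixels in a noisy image exceed
   their local mean by definition; a few counts (about σ_noise/2 at
   typical acquisition settings) suppresses that while leaving nuclei —
   hundreds of counts above background — untouched.
3. **2D→3D linking.** A disc of radius 5 px is stamped at each 2D
   centroid into a sparse volume and labeled with 6-connectivity, so
   objects whose centroids on neighbouring slices are <10 px apart
   merge into one nucleus. Nuclei spanning <2 slices are discarded.
4. **Intensity measurement.** Per-nucleus mean pixel intensity of each
   channel over the union of the member 2D masks (not a filled hull).
5. **Margin distance.** The manually traced margin polyline is
   rasterized on the 2D projection, a Euclidean distance transform
   applied, and the map sampled at nucleus centroids (scaled by the
   pixel size). Coordinates are 0-based (z, y, x).

The pipeline is deterministic: identical stack and parameters give a
byte-identical table.

## Gradient quantification

- **Sensor/host classification**: the local GFP background is a sliding
  40 μm-window median of GFP vs margin distance (≥10 nuclei per window,
  nearest defined window otherwise). Nuclei >3× the local baseline are
  sensors (flag 1), ≤ baseline are hosts (flag 0), in between stays
  unclassified (−1) and is excluded downstream. The thresholds are
  deliberately stringent: some true sensors go unclassified, but no
  host should be called a sensor.
- **Normalization**: per embryo, raw pSmad2 intensity is divided by the
  mean over that embryo's nuclei 150–200 μm from the margin, putting
  the far-field baseline at 1 and making gradients comparable across
  embryos with different staining brightness.
- **Pooling and windowing**: nuclei are pooled across embryos at the
  point level and a centered, unweighted 20 μm sliding-window mean is
  evaluated every 2 μm (≥5 points per window).
- **Exponential fit**: `A·exp(b·d) + c` by nonlinear least squares on
  the pooled points, data-driven initialization (far-field mean for
  `c`, log-linear slope for `b`). For multi-embryo pools the 95% CIs
  use a cluster-robust (by-embryo sandwich) covariance with t(G−1)
  critical values: per-embryo amplitude variation correlates residuals
  within embryos and the iid covariance under-covers (~90% observed
  coverage vs ~95% cluster-robust in the recovery simulations).
  Wild-type-style hosts are fit on all cells; Nodal-insensitive hosts
  on sensor cells only, since sensors are the only reporters there.
- **Half-distance**: smallest distance at which the above-baseline
  window curve falls to half its value at the first defined grid point,
  linearly interpolated. Note this operational definition inherits the
  edge-window's one-sided average: on an exact exponential it sits a
  few μm above `ln 2/|b|`.
- **Stage kymographs**: per developmental stage (dome, 50% epiboly,
  shield), projection-image pixels are binned by margin distance
  (10 μm bins) and averaged across embryos, each embryo weighted
  equally.
- **Clone profiles**: intensity next to a transplanted source clone is
  background-subtracted (ungrafted controls), averaged in 1 μm bins
  over a 150 × 40 μm ROI, smoothed with a 5 μm sliding mean, sampled
  every 5 μm and normalized to the first sample adjacent to the source.

## Synthetic data

`make_nucleus_table` draws per-nucleus tables with the assay's
statistical structure: 8 embryos × 400 nuclei by default, margin
distances uniform on [0, 250] μm, normalized signal
`A_e·exp(b·d) + 1 + ε` with per-embryo log-normal amplitude factors
(σ = 0.2), additive Gaussian noise (σ = 0.3 normalized units, truncated
at 0 — chosen for simplicity and because the fits are least-squares),
log-normal GFP with sensor median 8× host, ~10% sensors, and per-embryo
staining-brightness factors converting normalized to raw intensities.
`decay_for_half_distance` deterministically inverts the operational
half-distance estimator on the noise-free windowed exponential, so a
table can be generated that embodies a stated half-distance read-out.

`make_phantom_stack` renders soft-edged ellipsoidal nuclei
(in-plane radius 9 ± 1.2 px at 0.5 μm/px, axial radius 1.8 slices at
2 μm z-step — the sampling regime of a confocal stack of ~9 μm
blastula nuclei) placed by rejection sampling without overlap behind a
curved margin polyline, plus out-of-focus haze (blurred
neighbouring-slice content), a constant background and Gaussian noise
at a stated SNR (nuclear amplitude / noise SD, default 8).

What the generators do **not** emulate: real PSF anisotropy and
spectral bleed-through, touching/dividing nuclei, chromatin texture,
depth-dependent attenuation, segmentation-relevant debris, or
biological covariation between signal level and nuclear morphology.
Passing the phantom benchmarks therefore demonstrates the pipeline's
correctness and calibration on well-posed inputs, not its robustness to
every pathology of real stacks; the stage most sensitive to those
pathologies (adaptive threshold + opening) exposes all of its
parameters for per-dataset adjustment.

Both generators are byte-stable under a fixed seed, and their
ground-truth sidecars (labels, noise-free values, per-embryo factors,
centroids, radii) are sufficient to score classification, fits and
segmentation without re-deriving anything.

## Problem sizes and determinism

The shipped tests and the acceptance script run the 1D model at 1 μm /
~0.1 s resolution for 9000 s (2.5 h of development), the 2D model at
2 μm / 0.8 s, recovery simulations over 100–200 seeded replicate
tables, and segmentation benchmarks on 60- and 200-nucleus phantoms at
SNR 8 — sizes chosen to exercise every claim at full fidelity while
keeping a complete run in the order of a minute. One global seed fans
out to per-stage substreams (CRC-derived), so any stage can be re-run
in isolation with an identical stream.

## Known limitations

- The pseudo-first-order 2D model has no receptor saturation or
  depletion; it is linear in `L` by construction, so absolute
  amplitudes are arbitrary and only shapes/ratios are meaningful.
- No Lefty inhibitor field, no Nodal autoregulation or relay, no cell
  movement or 3D embryo geometry — deliberately, since the point of the
  models is what diffusion + capture alone can do.
- The receptor-trafficking/recycling variant of the turnover model is
  not implemented.
- The half-distance estimator's edge-window bias (above) is inherent to
  its operational definition; compare half-distances only between
  curves computed with identical window settings.
- No parameter inference from experimental images is provided.
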