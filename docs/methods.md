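# Methods

This note documents the models, conventions, and design choices behind
`mhfocus`, in the order the pipeline uses them. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Phantom

The phantom is one axial slice of a heterogeneously dense breast on a
regular pixel grid (default 71 × 91 at 1 mm; row index increases with −y,
column with +x, coordinates in mm from the grid center, points map to
pixels under a half-open convention). The breast is an ellipse whose
semi-axes fill 92% / 90% of the grid half-extents, with:

- a 2 mm skin rim at ε_r = 38, σ = 1.5 S/m (values inside the printed
  in-breast conductivity range; the sources give no skin values for the
  central slice);
- a glandular interior drawn from a Gaussian random field (white noise
  smoothed with a Gaussian kernel of length `heterogeneity_mm`, default
  6 mm) and min–max rescaled so interior conductivity spans exactly
  1.00–1.88 S/m, with ε_r co-varying linearly on [10, 55];
- optionally a tumor disc (default radius 5 mm) at ε_r = 40,
  σ = 2.0 S/m — deliberately just above the densest glandular tissue.

In the infinitely-smooth limit the smoothed field is flat up to numerical
residue; rescaling would only amplify that residue, so a span below
10⁻⁶ of the raw-noise span is treated as constant and the interior is set
to the 1.44 S/m midpoint (the closed-form limit of the rescaling).

The generator stands in for an MRI-derived phantom: it reproduces the
dielectric *ranges* and the tumor contrast, not the anatomy. Frequency
dispersion (Debye/Cole–Cole) and tissue registration are out of scope.

## Field model

Each channel's unit-drive field is the coherent sum over its member
antennas of a cylindrical wave

```
s(r) = A · exp(−j k̄(r) d(r)) / sqrt(max(d(r), d_min)),
```

where `d` is the antenna–pixel distance, `d_min` is one pixel (guarding
the source singularity), and `k̄` is the complex wavenumber
`k = ω sqrt(μ₀ ε₀ (ε_r − j σ/(ω ε₀)))` averaged along the straight ray
from antenna to pixel (48 samples). The scalar is carried by the in-plane
unit vector transverse to the ray, giving two components per pixel. Time
convention is e^{+jωt}, so lossy media have Im(k) < 0 and the wave decays.
`A = 150 V·m⁻¹·√mm` per volt of drive fixes the absolute scale so that
P_av at 6 W lands in the tens of kW/m³; all Ω and Ψ metrics are invariant
to it.

This model reproduces the two physical features the optimizer exploits —
phase accumulation and lossy attenuation through heterogeneous tissue —
and ignores scattering, multipath, and antenna coupling. That is the main
fidelity limit: interference patterns are smoother than full-wave
solutions, so absolute Ω levels are lower and hotspots relatively larger
than in FEM-based studies. Consequences for testing: passing tests show
the *protocol* (corpus generation, two-stage regression, masked-target
inference, baselines, metrics) behaves correctly and that the planner
approaches the exhaustive-search optimum on this field model; they do not
certify focusing performance on real applicators. For that, externally
simulated fields can be loaded through the container contract below.

### Field container contract (HDF5)

Complex datasets `field_000 … field_{N−1}`, each shaped
`(components, n_rows, n_cols)` with 1–3 components, V/m per 1 V drive;
attributes `frequency_hz`, `port_resistance_ohm`, `pixel_mm`, `scheme`
(`linear` | `circular`); datasets `antenna_positions` (12 × 2, mm) and
`channel_index` (12, 0-based). Fields must be finite and follow the
e^{+jωt} convention. Downstream code depends only on this contract, never
on how fields were produced.

## Excitations and power accounting

Phases are stored in degrees wrapped to (−180°, 180°] (radians only
inside e^{jφ}). `φ₁ = 0` is the reference; the linear scheme has free
phases (φ₂, φ₃) with φ₄ = φ₂ + φ₃; the circular scheme has six free
even-antenna phases with each odd antenna the wrapped sum of its two
neighbours. The published running text mentions five independent circular
phases, but the published per-antenna tables are consistent with six free
even phases (every odd-antenna sum checks out and no even phase is
derivable from the others); the implementation follows the tables and
exposes the free-phase count per scheme.

Port power is `P = V²/R` at R = 50 Ω exactly as the sources use it (1 V
→ 0.02 W; no ½ factor). The 6 W reporting convention counts all 12
physical antennas: a linear channel's voltage feeds three antennas and
therefore enters the budget three times. Voltage scaling leaves phases
and all Ω ratios unchanged; P_av scales quadratically.

## Training corpora

- Phase stage: `m` samples (default 2000 linear / 50,000 circular) of
  integer free phases uniform on {0,…,359}°, unit voltages, superposed,
  converted to heating potential, min–max normalized to [0, 1]; labels
  are interleaved (sin, cos) pairs per free phase — a continuous encoding
  without the 360° wrap discontinuity (output sizes 4 and 12).
- Voltage stage: integer voltages uniform on {0,…,9} V per channel at the
  fixed stage-one phases; all-zero draws are re-drawn (a zero field has
  no normalizable map); labels are voltages / 9.
- Split: 80% train / 20% validation, seeded permutation, disjoint and
  exhaustive. Every corpus is reproducible from (field set, seed, scheme,
  m).

The masked-target input is 1 on the 10 mm square whose pixel centers fall
in the half-open box around the target center, 0 elsewhere; it is fed to
the networks as-is (it is already on the [0, 1] scale of the training
inputs).

## Networks and training

Both stages share one architecture: 3×3 convolutions with 16, 64, 128
filters ('same' padding, ReLU), each followed by 2×2 max pooling with
floor division (71 → 35 → 17 → 8; 91 → 45 → 22 → 11), then one batch
normalization over the conv output, flatten, and three dense layers.
Choices left open by the architecture description and fixed here:

- dense widths 256 → 64 → output (any monotone funnel is acceptable;
  recorded in the checkpoint sidecar);
- Glorot-uniform initialization, seeded; Adam (β₁ = 0.9, β₂ = 0.999,
  ε = 10⁻⁷) at learning rate 10⁻⁴; mean-absolute-error loss; batch size
  100 (linear) / 200 (circular);
- epochs configurable, default 100 with early stopping on validation
  loss (patience 10, best weights restored);
- batch-norm momentum 0.9: training runs here are a few hundred updates,
  and a 0.99 momentum leaves inference-mode running statistics stale
  relative to the batch statistics the network trained under;
- float32 arithmetic throughout; forward/backward passes are batched
  matrix products (a 3×3 'same' convolution as nine shifted GEMMs), so
  one CPU suffices at these problem sizes.

Inference decodes sin/cos pairs with atan2 (off-circle regression outputs
are projected radially; an exact (0, 0) pair raises), then expands the
free phases through the scheme constraint, so predicted vectors satisfy
it by construction. Voltage outputs are clipped to [0, 1], rescaled by
9 V, and renormalized to 6 W; an all-zero prediction raises rather than
silently producing a dead plan.

## Look-up-table baselines

Ω_target is a ratio of Hermitian quadratic forms in the channel
coefficients, so each region is reduced to an N × N Gram matrix
`M[i,j] = Σ_region σ conj(E_i)·E_j` once, after which every cell costs
O(N²). The phase table enumerates the integer-degree Cartesian grid
(129,600 cells for the linear scheme) in lexicographic order with
first-occurrence tie-breaking; the voltage table enumerates 41 levels per
channel (2,825,761 cells), skipping the all-zero cell, whose Ω is
undefined — whether the original search excluded it is unstated, and
exclusion is the only well-defined choice. Projected enumerations above
10⁷ cells are refused with a size estimate (the circular schemes' full
tables are deliberately out of reach, which is why the learning-based
planner exists). Blocked vectorized evaluation is verified against a
scalar per-pixel loop in the tests. Hotspots are deliberately absent from
the table's objective; that asymmetry versus the planner is the point of
the comparison.

## Metrics

`Ω_region = 100 · Σ_region q₀ / Σ_breast q₀` (the ½ cancels); pixels
outside the breast mask contribute to neither sum. The dominant hotspot
is operationalized as the best-scoring window congruent to the target
square, slid over every placement fully inside the grid, with any overlap
with the target square forbidden and ties broken toward the smallest row
then column — a window congruent to the target makes Ψ a like-for-like
energy ratio. On toy grids a centered target can leave no disjoint
window; that is reported as a geometry error rather than silently
shrinking the window.

P_av is implemented as the *mean heating potential* (with the ½) over the
target pixels, reported in kW/m³ at the 6 W convention, keeping its units
self-consistent with Q₀; the printed-formula variant without the ½ is
available via `include_half=False`. `evaluate()` always rescales to the
requested total power first because P_av is scale-dependent.

## Pipeline, determinism, problem sizes

`run_pipeline` chains phantom → fields → phase corpus → phase network →
masked-target phases → voltage corpus → voltage network → 6 W excitation
→ metrics, optionally adding both look-up baselines. Every stage artifact
is written under the run directory; a manifest records the configuration
hash, seed, and a content hash of each artifact (dataset/attribute
values, not raw bytes — HDF5 and NPZ containers embed timestamps), so
reruns with identical configuration produce identical manifests and
`resume=True` reuses verified artifacts. All randomness (phantom texture,
corpus draws, splits, weight initialization, batch shuffling) derives
from the configured seed.

The test suite exercises the full protocol at reduced sizes chosen to
keep a single-CPU run short while preserving the physics: unit tests use
coarse grids (16 × 16 to 24 × 32), and the parameter-recovery study runs
the linear applicator on a 36 × 46 grid at 2 mm — the same physical
breast as the 71 × 91 / 1 mm default — with the full 2000-sample corpus
and a 20-epoch fit. The library defaults remain at the full scale.

## Known limitations

- 2D single-slice planning; no 3D volumetric optimization.
- The synthetic field model omits scattering/multipath and antenna
  impedance effects (no S11 modeling, no matching-medium design).
- Heating potential is used as the temperature proxy; no bio-heat
  (Pennes) solve and no temperature-domain metrics (e.g. T90).
- The voltage look-up table is only tractable for the 4-channel scheme;
  circular baselines require a coarser phase step.
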