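# Methods

## The attack model

The attack treats an image channel as a function `f(x, y)` on the pixel
grid and expands it in the discrete Tchebichef polynomial basis. These
polynomials are orthogonal under plain summation over `x = 0..N-1`, so
the expansion is exactly invertible when complete: the moment set
`{M_pq}` up to orders `(N-1, M-1)` determines the image uniquely.
Truncating the set at order `K` and reconstructing projects the image
onto the span of the low-order basis — an optimal (least-squares)
low-order approximation. The residual energy is monotone in `K`, which
is why structural similarity to the original decreases monotonically as
`K` falls, and why attacking an already-attacked image at the same or
higher order is idempotent up to quantization: the image already lies in
the retained span.

Nothing in the attack reads labels, gradients, or model outputs; the
black-box property is structural, not assumed.

## Polynomial convention

We use the classical discrete Tchebichef polynomials
(`t_0 = 1`, `t_1(x) = 2x - N + 1`, three-term recurrence
`n t_n = (2n-1)(2x-N+1) t_{n-1} - (n-1)(N²-(n-1)²) t_{n-2}`), scaled by
`b(n, N) = N^n`. The closed form used by the reference evaluator is the
standard signed binomial sum

```
t̃_n(x) = n!/N^n · Σ_{i=0}^{n} (-1)^{n-i} C(N-1-i, n-i) C(n+i, n) C(x, i)
```

The alternating sign is essential — without it the family is not
orthogonal and the inverse transform does not exist. Squared norms
follow the closed form
`ρ(n,N) = Π_{i=1}^{n}(N²-i²) · N / ((2n+1) N^{2n})`, evaluated in log
space.

## Numerically stable construction

Tabulating the basis by recurring over the order `n` is unstable for
`n ≳ N/2`: there the wanted solution of the three-term recurrence is the
minimal one and rounding noise from the dominant solution takes over
(at `N = 64`, full-order Gram residuals reach order 1). We instead fix
the order and recur over the *position*:

1. `φ_n(0)` (orthonormal normalisation) via a ratio recurrence with
   O(1) factors;
2. `φ_n(1) = φ_n(0)(1 + n(n+1)/(1-N))`;
3. the second-order difference equation in `x` for `x = 2 .. ⌈N/2⌉-1`,
   where the wanted solution *grows* and the recursion is
   self-correcting;
4. the upper half by the parity symmetry
   `t̃_n(N-1-x) = (-1)^n t̃_n(x)` (the centre point of an odd-length
   axis is set to exactly 0 for odd orders);
5. rescaling to the `N^n` convention through log-space norms.

Measured quality: orthonormal Gram deviation ≤ 5e-14 and norm agreement
with the closed form ≤ 1e-12 (relative) up to `N = 512` at full order;
full-order forward-plus-inverse round trip ≤ 1e-13 max-abs on random
256×256 images. Bases are cached per `(N, K)` for the life of the
process.

One conditioning fact matters for interpreting orthogonality checks:
with the `N^n` scaling the norms span an enormous dynamic range
(`ρ(0,N) = N` down to `ρ(N-1,N) ≈ e^{-2(1-ln 2)N}`, about 8e-68 at
`N = 256`). Off-diagonal Gram entries computed in double precision are
eps-level *relative to `sqrt(ρ_p ρ_q)` of the pair involved* — that is
the strongest statement float64 arithmetic can certify, and it is the
form our stability tests assert for large `N`. A bound stated relative
to the *smallest* norm of a full-order basis is meaningful only while
`sqrt(ρ_max/ρ_min)` stays within the inverse of the certified pairwise
level — roughly `N ≤ 40` for a 1e-8 bound — because for the extreme row
pairs the cancellation floor `eps · sqrt(N ρ_min ρ_max)` exceeds
`1e-8 · ρ_min` beyond that. None of this affects the transform itself:
forward-plus-inverse accuracy depends only on the well-conditioned
orthonormal factorisation underneath.

## Attack semantics

- **Order cap.** A per-axis order can be at most the axis length minus
  one, so a shared order `K` is valid when `K ≤ min(N, M) - 1`.
  Single-image attacks reject an over-large order; batch and
  augmentation runs re-cap per image and record the applied order.
- **Non-square images** use the same `K` on both axes, each axis with
  its own basis; a per-axis override exists for experimentation.
- **Range policy and encoding.** Reconstructions are raw floats; the
  default policy clips to `[0, 1]` and re-quantises to the 8-bit grid
  (round half-to-even), so outputs are consumable by arbitrary image
  pipelines and byte-identical across reruns. A float policy/encoding
  is available for numerically exact pipelines. The fraction of clipped
  pixels is reported per attack.
- **Color** is handled per channel in the source color space, no
  conversion.
- **Reported SSIM** is computed against the original in the canonical
  unit range *before* quantisation, so it measures the attack, not the
  encoder.

## SSIM

`mean_ssim` implements the windowed product of the luminance, contrast
and structure terms with weights `α = β = γ = 1` by default. Defaults
follow the de-facto standard: 11×11 Gaussian window with σ = 1.5,
`C1 = (0.01 L)²`, `C2 = (0.03 L)²`, `C3 = C2/2`, dynamic range `L = 1`
for unit-interval images; under these settings the implementation
agrees with scikit-image's `structural_similarity` (Gaussian weights,
population covariance) to machine precision, which the test suite uses
as an independent cross-check. When `β = γ` and `C3 = C2/2` the
contrast–structure product collapses algebraically to
`(2σ_AB + C2)/(σ_A² + σ_B² + C2)`; the implementation uses that form,
which also makes `mean_ssim(x, x)` return exactly 1.0 in floating
point. A global-statistics window exists for closed-form verification
and is the automatic fallback for images smaller than the window.
Color SSIM is the arithmetic mean over channels. All public reports use
the percent convention (×100); the core returns the unit-interval
value.

IoU of two empty masks is defined as 1 (an empty prediction of an empty
truth is a correct segmentation), avoiding a NaN in sparse evaluation
sets.

## Augmentation and degradation protocol

`AugmentationPlan` emits one attacked copy per source per order on the
grid `order_min : order_max : order_step` (default step 20, the
granularity attack orders are usually reported at), inheriting the
source label or mask unchanged — label inheritance is the only policy,
since the attack is label-free. Manifest cardinality is exactly
`n_sources × (include_originals + n_orders)`, counting explicit skip
rows for orders above an image's cap. Filenames encode the order so a
directory-based training loader needs no changes.

`degradation_table` replays the evaluation protocol against any
callable predictor (image → label, or image → mask): one attack-free
baseline row (SSIM pinned at 100%) plus one row per order with mean
SSIM and accuracy or mean IoU. Predictor failures are isolated,
counted, and excluded from that row's means. Model training is out of
scope by design; the bundled Otsu `threshold_segmenter` is the simplest
predictor satisfying the contract.

## Synthetic fixtures

The generators emulate the *geometry* of the target imagery at reduced
scale, not its intensity statistics:

- `nuclei_like` — non-overlapping quasi-elliptical bright blobs
  (foreground 0.75) on a darker noisy background (0.15, Gaussian noise
  σ = 0.03), with the exact blob mask returned as ground truth. Blob
  semi-axes default to 5–12% of the shorter side so nuclei keep a
  realistic relative size at any resolution; placement is by rejection
  sampling and an infeasible packing raises an error. The contrast gap
  is deliberately wide so a correctly-tuned threshold segmenter scores
  IoU ≈ 1 on clean images — making any degradation attributable to the
  attack.
- `random_smooth` — random Tchebichef coefficients up to a cutoff
  order with `1/(1+p+q)` decay, mapped affinely into `[0.05, 0.95]`.
  Band-limited in the transform's own basis, so an attack at or above
  the cutoff preserves the image essentially exactly — the cleanest
  probe of the "keeps structure, removes detail" behaviour.
- `constant`, `gradient`, `checkerboard` — closed-form images for
  closure and determinism tests.

Every fixture is a pure function of its spec; the stream is a single
seeded PCG64 generator per spec, so counts (not bit streams) are
reproducible across NumPy-compatible reimplementations. Default sizes
are 64–256 px to keep the full suite fast. What passing tests on these
fixtures shows is that the *mechanism* behaves as the theory predicts
(monotone SSIM decay, task-score degradation, exact inversion); they do
not certify effect sizes on real clinical images, whose texture and
noise differ.

## Problem sizes and tolerances

The test suite and the acceptance script run at 64×64 (attack suites,
20-image degradation grids at orders {60, 45, 30, 20, 10}), 12×12
(brute-force double-sum oracle), and up to 512 (basis stability) —
sizes chosen so every property that is scale-free is exercised well
inside a laptop budget. Tolerances: oracle agreement 1e-10, round-trip
identity 1e-8, orthogonality 1e-8·ρ_min at small `N` and 1e-12
pairwise-relative at large `N`, SSIM cross-check 1e-12. Ties in Otsu
thresholds or quantisation are resolved by round-half-to-even
throughout.

## Known limitations

- Absolute SSIM/accuracy/IoU values on the original clinical datasets
  are not reproducible here: they depend on externally trained deep
  models and on a windowing choice those experiments did not publish.
- Per-image optimisation of the attack order is not implemented; the
  order is a user choice.
- Only the Tchebichef family is provided. The basis/transform seam is
  family-agnostic (any orthogonal table with norms would slot in), but
  Krawtchouk, dual Hahn and Racah tables are not implemented.
- Images with an axis shorter than 2 pixels support only order 0 on
  that axis; SSIM on images smaller than the window silently uses
  global statistics.
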