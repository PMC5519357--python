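# Methods

## Estimators

**Area expansion modulus.**  For a tensionless bilayer in the NPT
ensemble, the projected area is an equilibrium time series whose variance
is tied to the elastic modulus: `K_A = kB·T·A0/⟨δA²⟩`.  The estimator
discards an equilibration transient (default: the leading 25% of frames,
the fraction corresponding to a 50 ns discard on a 200 ns production run
when one stored frame is one ns), then uses the post-cut sample mean for
`A0` and the unbiased (n−1) sample variance for `⟨δA²⟩`.  At the frame
counts involved (10⁴–10⁵) the n vs n−1 difference is far below the
statistical error; the unbiased form is used and tested so the choice is
pinned down.  `A0` may be overridden with an externally supplied reference
area when the tensionless mean is known from a longer run.  A stride
option subsamples stored frames; the default uses every frame.

**Bilayer thickness.**  Phosphorus z coordinates are centered per frame at
their mean (removing bilayer drift without needing box geometry — the
alternative, centering at the box midplane, is available when box
information exists), histogrammed on uniform bins symmetric about zero,
padded with one empty bin per side, and averaged over frames
(center-then-average).  The density unit is atoms·nm⁻¹·frame⁻¹, so the
profile integrates exactly to the atoms-per-frame count — asserted to
1e-9 relative on every constructed profile.  The thickness is the distance
between the highest local maximum on each side of the midplane.  Each peak
is refined by a three-point parabola through the peak bin and its
neighbors (clipped to ±half a bin); the refinement is deterministic and is
tested against a no-interpolation argmax oracle.  Height ties are broken
toward the midplane, never randomly.  A profile without a local maximum on
each side has no defined thickness and is reported as an error, as is a
degenerate input with all coordinates equal.  Inputs are assumed already
unwrapped in z; the optional coordinate adapter inherits that assumption.

**Bending rigidity.**  `κ = K_A (d − d0)²/24` with `d0 = 1 nm`: the
mechanically active ("bending") thickness is the head-group peak-to-peak
distance minus a fixed 1 nm offset.  `d < d0` is reported as an
unphysical-input error, never clamped to zero.  κ is reported in kBT (the
headline unit for bilayer rigidities) and in joules, with the exact
Boltzmann constant 1.380649e-23 J/K; the two views are kept consistent to
1e-12 relative.  The standard error is first-order propagation:
`(σ_κ/κ)² = (σ_K/K_A)² + (2σ_d/(d−d0))²`.

**Block averaging.**  All error bars trace back to the block-average
method: block sizes double from 1 (from 2 for the variance statistic), the
series is cut into contiguous non-overlapping blocks with the trailing
`n mod b` points discarded, and the SE at each size is the standard
deviation of the block statistics over √(number of blocks).  The largest
size always leaves at least 8 blocks.  The plateau is the smallest block
size whose SE differs by less than 5% from each of the two preceding
doublings — i.e. the curve has already flattened when that size is
reached; if no such size exists the largest admissible size is reported
with a `converged=False` flag.  Reporting the converged end of the
flatness window, rather than its start, was chosen because the SE curve
approaches its plateau from below for positively correlated data.  Block
averaging is applied to the area variance (whose error propagates into
K_A and κ); the mean statistic is also supported, and is what the
calibration tests exercise directly.  The K_A error omits the `A0`
sampling-error term, which is O(1/n) relative against the O(1/√n)
variance term.

## Synthetic ensembles

The generator samples the stationary distribution the fluctuation relation
implies — Gaussian areas with mean `A0` and variance `kB·T·A0/K_A` —
rather than integrating any dynamical model, because the estimator sees
only stationary moments.  Serial correlation, the one dynamical feature
that matters (it inflates error bars), is modeled as an AR(1) process with
the same stationary variance and a chosen lag-1 autocorrelation; the first
frame is drawn from the stationary law so no burn-in is needed.
Phosphorus coordinates are a symmetric two-Gaussian mixture at ±d/2 with
width σ, leaflet chosen with probability ½ per draw (equal expected
membership for any atom count).

Defaults mirror a 400-lipid, fully hydrated PC patch at 30 °C: K_A =
240 mN/m, A0 = 130 nm² (≈0.65 nm² per lipid per leaflet), d = 3.8 nm,
σ = 0.35 nm, 400 phosphorus atoms, 2×10⁴ frames.  The bundled three-lipid
configurations assign the di-DHA species the smallest modulus and
thickness (230 mN/m / 3.35 nm vs 265 mN/m / 3.70 nm for di-oleoyl), values
in the range reported for fluid unsaturated PC bilayers, so the rigidity
ordering that falls out — di-DHA softest — is a consequence of realistic
inputs, not a hard-coded verdict.

What the generator does *not* emulate: undulation modes and their
finite-size coupling to the projected area, anharmonicity of the area
energy, head-group asymmetry, and any chemical detail of the acyl chains.
Passing recovery tests therefore demonstrates the correctness of the
estimators given the stated model, not the accuracy of any force field.

One integer seed drives everything through two spawned, independent
bit-generator streams (areas; coordinates), so generating one output never
perturbs the other and runs are bit-reproducible.

## Comparisons

The comparative report groups results by temperature (accepted in °C at
the configuration boundary, converted once to K), ranks species by κ and
attaches a verdict to each ordered pair: *lower*/*higher* when the κ
difference exceeds one combined standard error `√(σ_a²+σ_b²)`, otherwise
*indistinguishable*.  One combined SE — not a formal hypothesis test — is
used because the errors are purely statistical block-average bars; the
band is symmetric, so widening errors can only move verdicts toward
indistinguishable.  Across temperatures the per-temperature spread
(max κ − min κ, in kBT) summarizes the size of the unsaturation effect;
thermal softening shrinks it at higher temperature.  Comparisons never
cross temperatures; a temperature group with a single member is rejected.
Thickness is computed once per (post-cut) trajectory, not per block; a
per-block thickness would let the d uncertainty be block-averaged too, at
the cost of much noisier per-block profiles.

## Numerical choices and problem sizes

Degenerate inputs fail loudly: constant area series (zero variance),
single-frame series, cuts consuming the series or leaving fewer than 100
frames, monomodal profiles, `d < d0`.  Validation tolerances: density
conservation 1e-9 relative; unit round-trips 1e-12 relative; estimator vs
two-pass moment oracle 1e-12 relative.

Test and acceptance problem sizes — 2×10⁴-frame area series, 10⁶ mixture
draws, 5×10⁴-point AR(1) series, ensembles of 50–100 seeds — were chosen
so each stage's statistical error sits well below its tolerance while the
whole suite runs in a couple of minutes on one core.

## Known limitations

- The fluctuation estimator needs a genuinely tensionless ensemble; a net
  lateral tension biases both A0 and the variance, and nothing here can
  detect that from the area series alone.
- Parabolic peak refinement assumes locally quadratic peaks; for very
  coarse bins (comparable to the peak width) the half-bin uncertainty
  dominates and the refinement adds little.
- The AR(1) surrogate has a single relaxation time; real area series mix
  several, which the plateau rule absorbs but the generator cannot mimic.
- The block-average plateau SE is itself noisy (relative noise
  ≈ 1/√(2·n_blocks)); single-realization calibration against analytic
  errors scatters by ~10–15% at the sizes above, which is why ensemble
  means are quoted where precision matters.
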