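# Methods

`spiralmrf` implements self-calibrated k-space interpolation along the
partition-encoding (kz) direction of stack-of-spirals 3D magnetic resonance
fingerprinting (MRF), together with everything needed to exercise the
interpolators end to end on synthetic data: acquisition simulation, NUFFT-type
reconstruction, and dictionary-based T1/T2/PD quantification.  This note
records the models, the parameters that matter, and the design decisions taken
where the design was genuinely open.

## The interpolation problem

A stack-of-spirals MRF acquisition samples one spiral arm per time frame at
every Cartesian kz position ("partition"), rotating the arm by the golden
angle between frames.  Acceleration skips partitions: only every R-th
partition plus a centered block of `n_acs` auto-calibration (ACS) partitions
is acquired.  The idealized effective acceleration is

    N·R / (N + n_acs·(R−1)),

which for N = 144 partitions and 12 ACS partitions reproduces the factors
1.8, 2.6, 3.2, 3.8 and 4.2 at R = 2..6 after rounding half away from zero to
one decimal.  The realized acquired-set count (exposed as
`realized_acceleration`) can differ by ±1 partition when R does not divide N.

Three interpolators predict each group of R−1 skipped partitions from the two
flanking acquired partitions:

* **Spiral GRAPPA** — a linear kernel per readout location i, per offset
  m ∈ {1..R−1} and per target coil, over a 2×(2v+1)×C source neighborhood
  (two partitions, 2v+1 readout points, all coils; v = 1 by default).
  Because spiral samples are not equally spaced, the kernel varies with i.
  Kernels are fitted by least squares on the ACS block, pooling calibration
  instances across all time frames and all stride-1 ACS offsets; a relative
  Tikhonov term (`ridge`, default 1e-6 of the mean normal-matrix diagonal)
  keeps the pooled systems well posed.  A per-frame calibration mode exists
  behind a flag; pooled is the default since calibration data per kernel is
  scarce.
* **Cartesian CNN** — treats the readout as a straight line: blocks of one
  width-3 1D convolution followed by two width-1 convolutions with channel
  widths (512, 1024, 1024) by default, ReLU activations, and a residual
  connection per block (identity when channel counts match, learned pointwise
  projection otherwise); a final pointwise linear layer maps to the (R−1)·2·C
  output channels.  Inputs stack real and imaginary parts across coils.
* **GCN** — identical architecture except the width-3 aggregation is replaced
  by a graph convolution `P·H·W` whose propagation matrix
  `P = D̂^{-1/2}(A+I)D̂^{-1/2}` encodes the true spiral geometry through the
  Gaussian adjacency `A_ij = exp(−‖v_i−v_j‖²/d̄²)`, kNN-truncated to the K
  largest entries per row (K = 5 by default; ties break toward the smaller
  column index, with weights rounded to 10 decimals for ranking so that
  machine-precision distance ties resolve identically for every golden-angle
  rotation).  `d̄` is the mean over all unordered point pairs of one arm.
  The two width-1 layers remain pointwise (equivalently, graph convolutions
  with identity aggregation); this reading of "replacing the convolutional
  layers" preserves the CNN analogy and makes a K = 1 GCN exactly equal to an
  all-pointwise CNN with shared weights, which the tests assert.  The
  printed form of the normalization with a positive right-hand exponent is
  treated as typographical; the standard symmetric normalization is used.
  Row-wise truncation leaves A asymmetric and it is kept so (a symmetrized
  variant sits behind a flag).  Adding I to a matrix whose diagonal is
  already 1 doubles the self-weight; the constant is absorbed by the learned
  weights, and the formula is followed as printed.

Training is scan-specific ("self-calibrated"): pairs of ACS partitions p and
p+R form inputs, the partitions in between form targets, one pair per frame
and stride-1 start.  MSE loss, ADAM, batch size 1, initial learning rate
5e-4 decayed by 0.99 per epoch.  Epoch count is not part of the protocol
definition; the desk preset uses 100 epochs, at which the training loss has
plateaued (two decades below its initial value).  Each sample is normalized
by the RMS magnitude of its own input pair ("per-pair" normalization, the
default; a single global ACS scale is available behind
`normalization='global'`).  The per-pair choice matters: the ACS pairs all
come from the high-amplitude center of kz, while at inference the model
must predict partitions one to two orders of magnitude weaker; per-pair
normalization makes the learned relation scale-equivariant and measurably
changes whether the networks recover signal beyond the zero-filling floor
at desk scale (global: GCN NMSE 0.0145 vs zero-fill 0.0141; per-pair,
3 blocks: 0.0135).  One model is trained per acceleration factor R, since
the output width depends on R; the desk preset uses 3 blocks, the optimum
of the published block-count ablation.

The networks are implemented directly in numpy (layers, manual
backpropagation, ADAM): the interpolators are the heart of the package and
their numerics — parameter counts, K = 1 equivalence, determinism under a
fixed seed — are asserted against dense-matrix oracles in the tests.
Single-sample memorization checks ("overfit one pair") use a larger initial
learning rate (1e-2) than the production schedule: 500 single-sample ADAM
steps at 5e-4 move each parameter by at most ~0.25 in normalized units,
which is not enough to fit one sample to numerical precision, while the
production rate is appropriate for the hundreds-of-pairs training it was
specified for.

Skipped partitions beyond the last acquired multiple of R are predicted from
the wrapped pair (last multiple, partition 0): kz is a DFT axis, so the
shift-invariant kernel relation continues periodically across the boundary;
this replaces ad-hoc extrapolation for trailing partitions.

## Synthetic data generator

The generator emulates the study conditions of a 3T whole-brain protocol at
desk scale; the `paper-1mm` / `paper-0.8mm` presets record the full
geometries (matrix 256/320, 144/176 partitions, 768 frames, 32 coils,
Q = 2452/3300) as configuration, while `desk` (M = 64, P = 24, Q = 512,
C = 8, T = 48, R = 4, n_acs = 8) is the size used by the test suite.

* **Anatomy** — concentric ellipsoids of CSF / GM / WM with conventional 3T
  values (WM 800/70 ms, GM 1300/90 ms, CSF 4000/1800 ms; PD 0.7/0.8/1.0).
  Tissue boundaries carry partial-volume coverage fractions estimated on a
  2× supersampled grid, and a seed-controlled band-limited proton-density
  texture (Gaussian-filtered white noise, correlation length ~1 voxel,
  amplitude 0.35) stands in for within-tissue fine structure.  The texture
  matters: homogeneous shells have a kz spectrum that decays orders of
  magnitude faster than real brain images, in which regime *no* interpolator
  (including an oracle-calibrated GRAPPA) can beat zero-filling in global
  NMSE — a property of the featureless object, not of the methods.  With
  the texture the edge-partition energy is ~4e-3 of the center partition,
  the regime of high-resolution in-vivo data.
* **Coils** — localized surface-coil lobes (Gaussian magnitude, smooth linear
  phase) on a ring around the object with centers staggered along z.
  Parallel imaging along kz requires the modulation
  `s_c(r)·exp(−2πi·m·z/P)` to lie near the span of
  `{s_{c'}, s_{c'}·exp(−2πi·R·z/P)}`; globally smooth (e.g. low-order
  polynomial) sensitivities cannot represent these modulations and make
  partition-direction GRAPPA impossible at any calibration quality, so
  localization is essential, as it is for real receive arrays.
* **Fingerprints** — an explicit stand-in recursion, not a Bloch/EPG
  simulation: starting from Mz = −1 (inversion), each TR emits
  `s_t = Mz·sin(α_t)·exp(−TE/T2)`, then applies `Mz ← Mz·cos(α_t)` and T1
  recovery over TR; segment boundaries apply a longitudinal recovery gap
  (300 ms default) followed by a T2-preparation decay `exp(−TE_p/T2)` with
  TE_p cycling through (50, 90) ms.  Flip angles ramp sinusoidally within
  each segment between 5° and 12°.  The interpolators are agnostic to
  fingerprint fidelity; the recursion only needs distinct tissues to
  produce distinct, matchable time courses (the WM/GM normalized inner
  product stays below 1−1e-4, asserted).  Variable per-segment wait times
  of the real sequence are exposed as the recovery-gap parameter; no claim
  of quantitative equivalence to the scanned sequence is made.
* **Forward model** — per frame, image = PD·fingerprint·coil map; a centered
  DFT along z gives Cartesian kz; the in-plane transform evaluates the
  spiral samples of the golden-angle-rotated arm.  Complex Gaussian noise is
  added i.i.d. with σ = 1e-4 of the noiseless k-space peak (2e-4 for the
  tiny preset): for an object of N voxels, σ_k/peak ≈ (1/SNR)/√N, so 1e-4
  corresponds to a single-frame image SNR of roughly 30 at the desk matrix.
  (An early provisional value of 5e-3 implied per-sample noise ~50× any
  real scan and drowned the skipped-partition signal entirely.)
* **Undersampling** is retrospective and exact: acquired partitions are
  preserved bit-identically.

What the generator does **not** emulate: B0/B1 inhomogeneity, motion, partial
Fourier, variable-density spirals, physiological wait-time variation, and
Bloch-accurate transverse-state evolution.  Passing tests therefore show the
interpolators behave correctly under an idealized but physically structured
acquisition; they do not certify in-vivo image quality.

## Reconstruction and quantification

The in-plane transform is an exact direct non-uniform DFT evaluated as a
dense BLAS product (`DirectNUFFT`); at desk matrix sizes this is faster to
reason about and to test than a gridding approximation, and its adjoint is
exact, so the operator passes adjoint dot-tests at machine precision.
Density compensation for the adjoint reconstruction starts from the
geometric rule for constant-pitch spirals — (arc spacing) × (constant
winding gap), with a linear taper where the arms converge at the center —
and is refined by a few rounds of gridded-density correction (grid the
weighted sampling function, Fourier transform, divide each weight by the
density at its own location).  The common textbook rule w ∝ |k|·Δs is
wrong for uniform-parameter spirals (Δs already grows ∝ |k|) and measured a
radial transfer ramp of 0.12–1.45 before the change.  With refinement the
fully sampled round trip reaches NRMSE ≈ 0.03 on the desk phantom.  "Fully
sampled" reference reconstructions use all interleaves at Nyquist with
margin both radially and along the arm (Q = 1024, 5 turns, 8 arms for
M = 64); the undersampled interpolation benchmark keeps the coarser
single-arm readout of the desk preset, whose in-plane aliasing is the
MRF-typical regime.

Coils are combined by root-sum-of-squares (magnitude) or by a
phase-preserving combination against coil profiles estimated from the
time-averaged images.  Dictionary matching maximizes |⟨signal, entry⟩| over
unit-norm fingerprints simulated on a (T1, T2) grid with infeasible pairs
(T2 ≥ T1) excluded; PD is the winning inner-product magnitude, and voxels
below 5% of the peak time-course norm are masked as background.

Metrics: NMSE and Relative-L1 are global ratios over the whole array
(complex differences; aggregation is a single global ratio, not per-coil);
PSNR uses magnitudes with dynamic range max|ref| and reports an exact match
as +inf (serialized as the string "inf" in JSON); SSIM uses a Gaussian
window (σ = 1.5, standard stabilization constants, L = max|ref|) per 2D
slice, averaged over slices, with the window shrunk for images smaller than
11 pixels and a global (unwindowed) formula below 3 pixels.

## Problem sizes and runtime

The test suite runs the full desk benchmark — simulate, undersample at
R = 4, calibrate GRAPPA, train both networks (desk channels (64, 128, 128),
three blocks, 100 epochs over 192 pairs), interpolate, and compare k-space
NMSE — in roughly 10 minutes on one CPU; all other tests are seconds each.  The
desk network widths are a scaled-down preset of the published (512, 1024,
1024) architecture, which remains the default `InterpolatorConfig` and the
configuration recorded in the `paper-*` presets.

## Known limitations

* The fingerprint recursion is qualitative; dictionary values are exact for
  the recursion itself, so matching tests verify the matcher, not sequence
  physics.
* Adjoint-with-DCF reconstruction is approximate (no iterative data
  consistency).  Quantification-accuracy tests therefore run the matcher on
  noiseless voxel-level fingerprint series (recovery is exact); matching a
  *reconstructed* fully sampled series recovers the on-grid tissue values
  for only ~60% of object voxels at M = 64, because point-spread mixing
  and partial-volume boundaries pull boundary voxels to neighboring
  dictionary entries — a property of the reconstruction PSF, which the
  round-trip bound covers separately, not of the matcher.
* ACS-calibrated spiral GRAPPA lands above the zero-filling NMSE floor at
  the desk R = 4 benchmark (0.025 vs 0.014): its per-location kernels,
  fitted on the central ACS alone, mis-extrapolate across the kz amplitude
  decay (an oracle calibrated on all partitions reaches 0.009).  The
  published full-scale comparison reports the same regime — GRAPPA NMSE
  above 1 at high R while the learned interpolators stay below — so the
  benchmark asserts that the CNN and GCN beat both GRAPPA and
  zero-filling, and makes no claim that GRAPPA beats zero-filling.
* The desk problem is proportionally harder than the full-size protocol in
  one respect: R = 4 of P = 24 partitions spans 1/6 of the kz extent (vs
  1/36 at P = 144), so the coil-span feasibility of partition interpolation
  is stressed harder than in the original geometry; desk results should be
  read as property checks, not as quantitative reproductions of full-scale
  error levels.
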