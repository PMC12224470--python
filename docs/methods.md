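# Methods

## The model

`smikit` implements the multicompartment Standard Model (SM) of diffusion
in white matter.  A voxel is a collection of identical fiber fascicles
distributed over orientations according to an ODF P(n̂) (normalized to unit
mass over the sphere).  Each fascicle contributes a two-compartment kernel

    K(b, ξ) = s0 [ f e^{−b Da ξ²} + (1 − f) e^{−b De∥ ξ² − b De⊥ (1 − ξ²)} ],

ξ = ĝ·n̂, i.e. an intra-axonal "stick" of water fraction f with axial
diffusivity Da and zero radial diffusivity, plus an axially symmetric
Gaussian extra-axonal compartment (De∥, De⊥).  An optional isotropic
free-water term (fraction `fiso`, diffusivity D0 = 3 µm²/ms) is available
in the simulator; none of the estimators attempts to estimate it, because
two-shell protocols at realistic SNR do not constrain it.  Diffusivities
are in µm²/ms and b-values in ms/µm² throughout; conversion from the FSL
s/mm² convention happens only when reading bval files.

Model assumptions worth keeping in mind: no exchange between compartments,
zero axon radius (no transverse intra-axonal diffusion), and Gaussian
(time-independent) extra-axonal diffusion.  Time-dependent diffusion,
b-tensor encodings and compartmental T2 are out of scope.

## Spherical-harmonic factorization and rotational invariants

The convolution of kernel and ODF factorizes in the spherical-harmonic
basis: S_lm(b) = p_lm K_l(b), with K_l(b) = ∫₀¹ K(b, ξ) P_l(ξ) dξ the
Legendre projections of the kernel.  The basis is real, even-degree only
(antipodal symmetry), orthonormal with respect to the solid-angle measure,
and free of the Condon–Shortley phase; with the invariant normalization

    S_l(b)² = Σ_m S_lm(b)² / (4π(2l+1)),   p_l² = Σ_m p_lm² / (4π(2l+1)),

a fully aligned (delta) ODF gives p_l = 1 for every even l and an
isotropic ODF gives p_l = 0 for l ≥ 2, so 0 ≤ p_l ≤ 1 measures ODF
alignment.  The master identity S_l(b) = p_l |K_l(b)| (absolute value
because K_2, K_4 are negative for decaying kernels while invariants are
root-sum-square magnitudes) holds for *any* ODF and is enforced by a
property test over random non-zonal ODFs.

Numerical choices: K_l uses fixed-order Gauss–Legendre quadrature (order
64 on [0, 1]; doubling the order changes K_l by < 1e-10, which is tested).
Per-shell SH coefficients are obtained by linear least squares; a shell
with fewer directions than coefficients has its lmax lowered with a logged
warning, and a degenerate direction set raises a conditioning error.  ODF
positivity is deliberately not enforced when generating test ODFs —
invariant-based estimators only see (p2, p4).

## Synthetic data

The simulator is the package's definition of the study conditions, not a
tuning knob:

- **Benchmark test set** — ground truths {f, Da, De∥, De⊥, p2} uniform on
  [0.3, 1.5, 1.5, 0.4, 0.3] – [0.8, 2.5, 2.5, 1, 0.8] (n = 10,000), the
  most probable white-matter range; p4 = ρ·p2 with ρ ~ U(0.75, 0.85)
  (histology-motivated ODF shapes); De∥ ≥ De⊥ enforced by rejection (a
  no-op for this box); zonal ODFs realized exactly at (p2, p4) with
  uniformly random orientations; Gaussian noise at SNR 25 referenced to
  b=0 (σ = s0/SNR on every volume).  How full SH coefficient sets are
  realized from (p2, p4) is underdetermined; zonal-plus-random-rotation is
  the choice here, and rotational invariance makes the estimators blind to
  it.
- **Protocol** — 4 b=0 volumes, 20 directions at b=1 and 60 at b=2
  ms/µm², matching routine clinical two-shell scans; directions are
  spherical-Fibonacci layouts (deterministic per seed).  No published
  direction table is bundled; any quasi-uniform scheme is equivalent for
  rotational invariants, and the layout is recorded in the protocol
  metadata.
- **Noise realization sharing** — all estimators see the same noisy
  signals (paired design), so SSM differences between estimators are not
  noise-realization artifacts.

What the generator does *not* emulate: Rician noise floors (a Rician
option exists but Gaussian at SNR 25 is canonical), spatial correlations,
partial volume, fiber crossings beyond what (p2, p4) capture, and
time-dependent diffusion.  Passing benchmarks therefore demonstrates
estimator behavior under the model's own assumptions, not robustness to
real-data artifacts.

## Estimators

**SMI** (the machine-learning estimator).  Signals are compressed to six
b0-normalized rotational invariants {S0, S2, S4} × {b=1, b=2}; one
third-order polynomial regression per target parameter
{f, Da, De∥, De⊥, p2, p4} maps features to parameters.  Training data are
drawn from an independent Gaussian prior with mean [0.5, 2, 2, 0.7, 0.45]
and variance [0.06, 1, 1, 0.1, 0.06] (the vector is read literally as a
variance), truncated to the physical box by rejection with De⊥ ≤ De∥.
Training noise matches the benchmark SNR; the model records its protocol
hash, SNR and seed so mismatched use is an error.  OLS on all 84 monomials
of total degree ≤ 3, with a tiny ridge (1e-8) only if the design is rank
deficient; default training size 1e5 (large enough that coefficients
change < 1% on doubling).  Outputs are clipped to physical bounds; clip
events are counted.

**NODDI-style baseline.**  Constraints: Da = De∥ = 1.7 µm²/ms, tortuosity
De⊥ = De∥(1 − f), Watson ODF.  Because the fiber axis is a nuisance
parameter, the fit is performed in the rotational-invariant domain:
S_l(b) = p_l(κ) K_l(b; f) for l = 0, 2, 4 on both shells, two free
parameters (f and the Watson concentration, reported via p2).  This
removes the axis from the optimization entirely rather than profiling it
numerically; for quasi-uniform direction sets the invariants carry the
axis-independent information the directional likelihood would use.  Per
voxel: bounded nonlinear least squares with a vectorized coarse grid seed
plus four stratified restarts, on cubic-spline tables of K_l(b; f) and of
the Watson (p2, p4) curve.

**SMT baseline.**  Constraints: Da = De∥ = D and tortuosity.  Fits the
two per-shell spherical means with the closed form
m(b) = f h(bD) + (1−f) e^{−bDe⊥} h(bΔ), h(x) = √(π/4x) erf(√x) (series
branch below x = 1e-6), Δ = D − De⊥.  The spherical mean is taken as the
l=0 SH coefficient, not the raw direction average: on finite direction
sets the least-squares fit separates the isotropic component exactly,
whereas a plain average leaks l > 0 content.  Voxels with f pinned at the
box edge are flagged.

**WMTI baseline.**  A weighted linear least-squares DKI fit (log-signal
design in b and b², weights = squared signal) yields D and W tensors; the
two-compartment moment relations along each of 128 hemisphere directions
give f = max_n K(n)/(K(n)+3) and per-direction compartment diffusivities
via the square-root branch with Da ≤ De∥; tensors fitted to the
per-direction values give Da (trace of the intra tensor) and De∥, De⊥
(extra-tensor eigenvalues).  The inversion is exact for aligned fibers and
exact cumulants; at clinical b the O(b) cumulant-truncation bias of DKI is
part of what the benchmark measures, so the noise-free self-consistency
test runs at small b (0.11/0.22 ms/µm²) to isolate the inversion itself.

**Watson-WMTI (experimental).**  Same DKI front end, opposite branch
(Da ≥ De∥, enforced by parametrization) and a Watson ODF: the model-implied
directional moments D(θ), K(θ) at θ = 0°, 45°, 90° from the principal axis
(with Watson axis moments c2, c4 tied to p2) are matched by bounded least
squares, additionally yielding p2.

All baseline optimizers use tolerance 1e-10 and deterministic start lists,
so repeated runs are bit-identical.

## Sensitivity-Specificity Matrix

For each estimated parameter, an OLS regression (with intercept — the SSM
is a derivative statement and an intercept-free fit would bias the slopes)
of the estimates on all five ground truths; entries are slopes normalized
by ⟨θ_i⟩/⟨θ̂_j⟩.  The identity matrix is the ideal; off-diagonals are
spurious sensitivities.  Flagged voxels are dropped listwise per estimator
with counts reported.  p4 is not used as a regressor row: by construction
it is nearly collinear with p2 (ratio confined to [0.75, 0.85]); SMI's p4
*column* is still reported.  The prior-impact matrix repeats SMI training
over a 90–110% sweep (2.5% steps) of one prior mean at a time, with the
same training seed at every grid point so the sweep isolates the prior
dependence, and regresses mean estimates on the prior mean.

## Problem sizes and reproducibility

The acceptance script runs the full 10,000-voxel benchmark.  The test
suite runs a scaled-down 2,000-voxel version of the same benchmark with
the Monte-Carlo tolerance on reference SSM entries widened from ±0.15 to
±0.20, and a reduced prior-impact grid (5 points, diffusivity rows); these
sizes are the package's own testing choices.  Every random quantity is
driven by an explicit seed; two runs with the same seeds produce
byte-identical benchmark CSVs.

## ROI statistics

Outlier exclusion is two-pass and non-iterative: drop values outside the
parameter's physical bounds (fractions and invariants in [0, 1],
diffusivities in [0, 3] µm²/ms, the free-water ceiling), then drop values
outside ±2σ of the survivors' mean, with σ computed once after the
physical pass (the rule is ambiguous about iteration; single-pass is
chosen and documented).  White matter is masked by FA > 0.2 (strict).
Developmental trends are fit as A·e^{−t/τ} + B by multi-start nonlinear
least squares (τ starts {0.1, 0.5, 1, 2, 5} years); |τ| is reported, and
95% CIs come from the Jacobian covariance with Student-t quantiles —
Monte-Carlo coverage at these settings is ~94%, inside the tested
95% ± 3% band.  Flat data leave τ unidentifiable and are flagged rather
than reported.

## Known limitations

- The NODDI baseline's invariant-domain fit is not literally the
  directional maximum-likelihood estimator; at SNR 25 the rectified-noise
  bias of S2/S4 slightly inflates low-anisotropy estimates.  The
  benchmark entries it produces match the expected spurious-correlation
  pattern well within the stated tolerances.
- WMTI inherits DKI's finite-b cumulant truncation bias at clinical b;
  this is a property of the method, not of the implementation, and is
  deliberately visible in the benchmark.
- The polynomial SMI regression is a pointwise approximation of the
  posterior mean under the training prior; estimates regress toward the
  prior mean for weakly identified parameters (De∥ most of all), which is
  exactly the behavior the prior-impact matrix quantifies.
- FA of eigenvalues (2, 0.7, 0.7) is 0.5825 under the standard definition
  FA = √(3/2 · Σ(λᵢ−λ̄)²/Σλᵢ²); this value anchors the masking tests.
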