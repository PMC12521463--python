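# Methods

## The problem

Multi-echo BOLD fMRI acquires several gradient-echo images per repetition
time.  Under the monoexponential decay model

    e = S0 · exp(−TE / T2*)

the echo intensities at different echo times TE determine the effective
transverse relaxation time T2* (ms) and the initial intensity S0 of each
voxel at each frame, turning qualitative BOLD series into a quantitative,
time-unit-valued signal.  The obstacle is noise: the log-linear fit
amplifies echo noise (the variance of `ln e` scales as `σ²/e²`), so T2*
time courses fitted from raw echoes oscillate strongly, while invasive
measurements show the underlying physiological BOLD signal is smooth.

## TV–l2 restoration

Each voxel × echo time course `b` (length F) is restored by minimising

    G(u) = ‖D u‖₁ + (μ/2) ‖u − b‖₂²

where `D` is the forward-difference operator — the 1D analogue of the
Rudin–Osher–Fatemi image model.  The total-variation term removes
disturbances by their *value and temporal extent* rather than their
frequency content: an isolated spike has a flat spectrum and survives any
frequency filter or component-removal method, but it inflates the TV and
is removed by construction, while local signal means are preserved by the
fidelity term.

`D` is kept square (F × F) with an all-zero last row (Neumann boundary):
only F−1 forward differences exist and the endpoints of a non-periodic
physiological signal should not be wrapped.

### Solver

The minimiser is computed by a partially inexact ADMM on the splitting
`w = D u`:

1. *u-subproblem* (inexact): steepest-descent steps on
   `(β/2)‖Du − w − λ/β‖² + (μ/2)‖u − b‖²` with gradient
   `g = β·Dᵀ(Du − w − λ/β) + μ(u − b)` and the exact line-search step
   `α = gᵀg / gᵀAg`, `A = β·DᵀD + μI`, applied matrix-free.  Five
   gradient steps by default; optionally the relative-error stop
   `(2/β)|⟨r − u, g⟩| + ‖g‖² ≤ σ‖Du − w‖²` driven by the auxiliary
   iterate `r ← r − βg`.
2. *w-update* (exact): soft threshold
   `wᵢ = max(|Dᵢu − λᵢ/β| − 1/β, 0) · sgn(Dᵢu − λᵢ/β)`.
3. *multiplier update*: `λ ← λ − β(Du − w)`.  The sign is the one
   consistent with the `(Du − w − λ/β)` convention used in steps 1–2;
   with the opposite sign the iteration diverges geometrically, which we
   verified numerically.

Initialisation: `u⁰ = b`, `w⁰ = Db`, `λ⁰ = 0`, `r⁰ = 0` — a warm start at
the data so the first w-update acts directly on the measured differences.

### Parameters

| parameter | default | meaning |
|---|---|---|
| μ | 2⁻¹⁰ | data-fidelity weight, tuned to raw-magnitude BOLD values (~10⁴); equivalently a TV weight λ_TV = 1/μ = 1024 signal units |
| β | 2⁻⁴ | ADMM penalty weight |
| inner_iters | 5 | gradient steps per u-subproblem |
| outer_iters | 400 | outer ADMM iterations |
| σ | 0.5 | relative-error tolerance (only with the relative-stop flag) |

The outer iteration count matters more than commonly appreciated: each
outer pass can shrink any single forward difference by at most ~2/β
signal units (the soft-threshold step size), so removing a spike of
amplitude `s` needs at least ~`s·β/2` outer passes.  At BOLD magnitudes
a handful of outer iterations leaves spikes essentially intact.  The
default of 400 was chosen so that on raw-magnitude BOLD-like series the
achieved objective is within 1% (typically ~0.1%) of the exact TV–l2
minimum, verified against an independent exact solver (the dual
box-constrained least-squares formulation solved by BVLS, used only in
the test suite).  No signal rescaling is applied before denoising;
users working at other scales should retune μ (halving the scale is
equivalent to doubling λ_TV).

At these defaults the denoiser removes structures whose
contrast × duration is below ~2·λ_TV ≈ 2048 signal units: Gaussian noise
and most spikes vanish, while task blocks (contrast ≳ 1/(3μ) ≈ 340 units
over a ~12-frame block) survive, slightly shrunk.

## Dynamic T2* mapping

Per voxel and frame, `(S0, T2*)` are estimated by weighted least squares
of `ln e` on the echo times.  Weights default to the squared echo
amplitudes — the standard first-order variance compensation for
log-transformed Gaussian noise (`Var[ln e] ≈ σ²/e²`); `uniform` and
`amplitude` weightings are available.  In a Monte-Carlo check at SNR 50
the amplitude² weighting reduces the estimator's spread (SD 2.10 vs
2.35 ms at T2* = 40 ms) at the cost of a slightly larger mean bias; its
mean absolute error is lower.

Frames whose echoes are non-positive or do not strictly decrease with TE
violate the decay model and are marked invalid (NaN plus a boolean mask);
no clamping and no upper T2* bound are applied.  No Rician noise floor is
modelled: with three echoes the simultaneous estimation of three
dynamically changing parameters is not reliable.

## Quality metrics

- **tSNR** = mean / σ with σ the residual SD after least-squares removal
  of a 2nd-order polynomial trend (ordinary monomials on a normalised
  time axis, numerically adequate for F ≤ 10⁴; denominator F − 3).
  Computed on resting-state runs.
- **CNR** = ΔS / σ.  ΔS is the maximum over circular lags of the
  cross-correlation between the task series and a zero-sum *averaging
  boxcar* (+1/#ON on ON frames, −1/#OFF on OFF frames), i.e. the ON−OFF
  mean difference at the hemodynamic lag; σ comes from the tSNR of a
  matched resting-state run processed identically.
- **Similarity** = maximum magnitude over all F circular lags of the
  cross-correlation of the zero-mean, unit-energy-normalised series with
  the normalised theoretical response; lies in [0, 1] and is invariant
  to circular shifts and affine rescaling of either argument.
- Distribution comparisons use the Wilcoxon rank-sum test (exact for
  small untied samples, normal approximation with tie correction
  otherwise) on medians and IQRs.

## Task model

The block design alternates 30.025 s OFF and 21.35 s ON epochs for seven
cycles at TR = 1.8 s; a frame is ON iff its acquisition time `v·TR`
falls in the half-open ON interval.  The canonical HRF is the difference
of two Gamma densities (peak delay 6 s, undershoot delay 16 s, unit
dispersions, peak:undershoot 6:1, 32 s support), sampled on the TR grid
without microtime upsampling and normalised to unit sum; the theoretical
response is its linear convolution with the boxcar.

## ROI construction and FDR — a known limitation

The task ROI takes, per voxel, the lag-maximised similarity ρ of the raw
echo-2 series with the normalised response, converts it to
`t = ρ√(F−2)/√(1−ρ²)` (the standard correlation t-statistic; the
alternative `/(1−ρ)` form sometimes quoted appears to be a typographical
variant), then `p = 2(1−P(t))`, and applies Benjamini–Hochberg at
α = 0.05.

Because ρ is a *maximum over all circular lags*, its null distribution is
far from that of a single correlation: for F = 210 white-noise series the
best correlation concentrates around 0.15 (we verified this by
simulation), so the nominal p-values are strongly anticonservative and
the BH step declares a large fraction of pure-noise voxels significant.
On real data the procedure still yields plausible ROIs because truly
active voxels reach much higher correlations, but *nominal FDR control
should not be expected from this construction*, and the phantom-based
acceptance test documents the measured behaviour rather than asserting
control.  A lag-aware null (e.g. permutation of frames) would restore
control but is outside the present scope.

## The synthetic phantom

The generator emulates the target acquisition: TE = 15.00/32.64/50.28 ms,
TR = 1.8 s, 210 task or 312 resting frames, S0 uniform in
[25 000, 35 000], tissue-like baseline T2* = 40 ms.  Active voxels
(default 5%) follow `T2*(t) = 40 + 2·response(t)` with the response
scaled to peak 1, so the activation amplitude is 2 ms peak.  Noise is
additive Gaussian with SD defaulting to the mean echo-1 amplitude
divided by 50 (an "echo-1 SNR of 50"); spikes hit each sample
independently with probability 0.02 and N(0, (10·noise SD)²) amplitudes.
All randomness flows from a single integer seed.

What the phantom does *not* model: Rician magnitude bias (negligible at
tissue SNR and deliberately excluded from the fit), spatial noise
correlations, motion, physiological (cardiac/respiratory) noise, field
inhomogeneity and slice-timing effects.  Passing phantom tests therefore
demonstrates correctness of the algorithms under the stated noise model,
not performance on real scanner data.

Problem sizes in the test-suite acceptance checks: a 16×16×4 grid
(1 024 voxels) for the recovery and ordering checks, 8×8×2 / 12×12×3
grids for the FDR replicates — small enough for a desk run, large
enough for stable medians.

The package also reproduces two deterministic worked examples on why
spatial Gaussian smoothing must precede neither denoising nor T2*
fitting: a boundary voxel smoothed with the 1D kernel weights
[1.9835, 37.5354, 100, 37.5354, 1.9835] (%) drops to 0.7793 of its
value, and the corresponding first-echo drop (20200 → 15900 at
ΔTE = 17.64 ms) inflates the two-echo T2* estimate from 34.42 ms to
64.59 ms (+87.6%).  The kernel weights are consumed as given (they stem
from a pixel-integrated Gaussian at FWHM 5 mm on a 3 mm grid and are not
re-derived).

## Numerical choices and degenerate inputs

- Constant series: the denoiser returns them unchanged (tolerance
  1e-8 × magnitude); normalisation and similarity raise a
  degenerate-series error.
- `g = 0` in the line search: the step is skipped (A is positive
  definite, so `gᵀAg = 0` implies `g = 0`).
- Perfectly quadratic series report infinite tSNR (σ at rounding level)
  instead of overflowing.
- Rank-deficient nuisance designs (WM ∝ CSF) are solved by
  pseudo-inverse and flagged with a warning.
- The brain-mask histogram uses 256 bins, a 5-bin moving-average smooth,
  and requires the inter-peak valley to fall below half the smaller
  peak; otherwise it falls back to Otsu's threshold with a warning.
- Nuisance PCA uses covariance (not correlation) scaling of linearly
  detrended, mean-centred series; the component's sign is fixed against
  the mean in-mask series.
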