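# Methods

## Problem and model

A single-axis tilt series gives, for each reconstruction slice, one 1D
projection per tilt angle. By the central slice theorem the 1D Fourier
transform of the projection at angle θ equals the 2D Fourier transform of
the slice along the central line with direction (cos θ, sin θ). The slice
is modelled as a periodic trigonometric polynomial with coefficients on
the centred index set I_N = [−N/2, N/2)²; the acquisition operator A
evaluates that polynomial at the non-uniform points
x = (s/N)(cos θ, sin θ), s ∈ [−N/2, N/2), i.e. A is a 2D type-2 NUFFT and
Aᴴ its adjoint. θ = 0 samples the first Fourier axis (beam along the
second image axis); angles are degrees at all interfaces.

ICON reconstructs each slice by alternating

1. **fidelity preservation** — one steepest-descent step with exact line
   search on the quadratic q(x) = ½⟨x, AᴴWAx⟩ − Re⟨x, AᴴWf⟩:
   r = AᴴW(Ax − f), α = ‖r‖²/⟨Ar, W Ar⟩, y = x − αr;
2. **positivity restriction** — the hard threshold x = max(y, 0), the
   compressed-sensing sparsity prior for densities on a zero background.

The imaginary part of every adjoint application is discarded (x is a real
image); this is part of the operator definition. The exact line search
makes q non-increasing within every step (asserted on every trace); the
threshold may increase q, so the *sequence* of q values is not monotone
and is not asserted to be.

### Numerical safeguards

* If ‖r‖² falls below the machine floor (`tiny · N²` in the working
  precision) the step reports convergence instead of dividing.
* If the line-search denominator ⟨Ar, W Ar⟩ is non-positive within
  rounding, iteration stops and the event is recorded in the trace
  (`stop_reason = "degenerate_alpha"`) rather than dividing.
* The denominator is computed as Σ w|Ar|², which equals rᵀAᴴWAr exactly
  (adjointness) and saves one adjoint transform per iteration; the
  dense-matrix oracle test pins the identity numerically.
* NaN anywhere in an iterate aborts with a diagnostic.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_iter` | 200 | fixed iteration count, the published protocol |
| `stop_epsilon` | 0 | optional residual-norm floor; maps the ε of the constrained formulation onto early stopping. 0 = fixed iterations, since published runs use a fixed count and ε is described as empirical |
| `init_mode` | zeros | zeros makes the zero-data case exact and reproducible; `wbp` (thresholded weighted backprojection) is available |
| `weight_mode` | ramp | see below |
| `sigma` | 2 | NUFFT oversampling factor (fine grid n = σN) |
| `m` | 6 | window half-width in fine-grid pixels |
| `precision` | double | `single` runs the whole pipeline in float32/complex64 |

## Density-compensation weights W

The reference description of W defers to the INFR literature and the exact
recipe is not restated there, so both common choices are provided and the
choice is logged:

* **ramp** (default): w = |s|, the analytic analogue of WBP's ramp filter.
  The T duplicated DC samples (one per tilt; duplicates are kept so A stays
  a plain per-tilt sampling operator) each get 1/(4T), making the summed DC
  weight exactly 1/4 — the half-pixel-area rule — independent of T.
* **dc**: Pipe–Menon-style fixed point w ← w/(G w), where G grids the
  weighted samples through the Gaussian window and reads them back. Ten
  iterations suffice in practice. Note the converged weights follow the
  ramp only while neighbouring tilt lines are within kernel reach
  (|s| ≲ m/(σ·Δθ)); beyond that they saturate at the single-line density,
  which is the correct density estimate for widely separated lines —
  the analytic ramp is the dense-tilt limit.

## NUFFT implementation

Forward: divide coefficients by n²φ̂(k₀)φ̂(k₁), zero-pad to the n×n fine
grid, FFT with the e^{−2πi} sign, then for each sample point gather the
(2m+1)² fine-grid neighbours (per axis, centred on the nearest fine-grid
point, indices mod n — the model is periodic) with weights
φ(x − l/n). Adjoint: the exact transpose (spread, conjugate-sign FFT,
deconvolve, crop), with no 1/M factor. The dilated Gaussian pair

φ(x) = (πb)^(−1/2) e^(−(nx)²/b),  φ̂(k) = (1/n) e^(−b(πk/n)²),
b = 2σ/(2σ−1) · m/π

is evaluated in closed form; the precomputed per-sample tables store those
exact values, so tabled and on-the-fly paths are bit-identical. Because
forward and adjoint share the tables, they are exact adjoints: the dot
test passes at ~1e−15 in double precision.

**Accuracy.** With σ = 2, m = 6 the gridding transforms agree with the
direct-summation oracles to ~1–4e−6 relative max error for white random
inputs (worst over N ∈ {8…64}). This is the intrinsic accuracy of the
Gaussian window at these parameters — the classical worst-case bound is
4·e^(−mπ(1−1/(2σ−1))) = 4e^(−4π) ≈ 1.4e−5, dominated by aliasing of the
band-edge frequencies through the oversampled grid — and it cannot be
tightened by widening the truncation (measured: no change from support
13 to 19 taps) or by exact-DFT deconvolution (measured: worse). Unit
tests therefore assert 5e−6, the empirical envelope. Accuracy improves
monotonically as m grows at fixed σ (~8× per unit of m).

The direct-summation backend materialises the dense e^(−2πik·x) matrix
and refuses N > 128 unless forced (memory grows as 16·T·N³ bytes).

## Precision switch

`precision="single"` keeps images, samples, window tables and FFTs in
float32/complex64 end-to-end. Two deliberate exceptions: scalar reductions
(‖r‖², the line-search denominator, q) and the scatter accumulation inside
the adjoint are carried out in float64, mirroring the common practice of
double-width accumulators on accelerator hardware.

Comparing a single- against a double-precision run of the same 512²
reconstruction with the normalized RMSRE metric (c = 10⁻⁷) gives ~5e−4,
not the few-1e−6 one might expect from float32 rounding, and the reason is
structural: the positivity threshold leaves a population of pixels whose
converged value is a tiny positive number (~1e−7–1e−8 of the dynamic
range). Min-max normalization maps the slice minimum to c = 10⁻⁷ and the
RMSRE divides by it, so float32 rounding of those threshold-boundary
pixels turns into relative errors of 1–10% each, and a few hundred such
pixels dominate the metric — even though the two reconstructions are
globally identical (NCC = 1 − 1e−13) and their zero sets agree to 0–2
pixels. Exactly-zero pixels (most of the background) contribute nothing.
On data whose value distribution near the minimum is sparse the metric
stays at the few-1e−6 level; on sparse blob phantoms it cannot. The
acceptance suite states the published bound and reports this honestly.

## Synthetic data

Phantoms are sums of elliptical Gaussian blobs truncated at 3σ (so the
background is exactly zero, matching the positivity prior), placed inside
the central half of the field to avoid wrap-around in the periodic model,
deterministic given a seed. The simulator evaluates the phantom's Fourier
transform on each tilt line by direct summation (a phase-recurrence over
non-zero pixels — never the gridding NUFFT under test), inverse-transforms
to a real 1D projection, and adds a constant background and white Gaussian
noise. Noiseless data are therefore consistent with the reconstruction
model at every frequency except one: the unpaired −N/2 sample of each
line, where a real projection forces a real DFT coefficient but the true
line transform is complex. The residual of the true phantom is thus tiny
but not zero on simulated data; the exact fixed-point property is tested
with data constructed directly as f = Ax.

What the simulator does *not* emulate: CTF, dose damage, alignment error,
discrete ray-space integration (projections are Fourier-space samples by
construction), and 3D structure beyond independent stacked slices.
Passing tests show correctness of the operators and the iteration on data
matching the model's assumptions, not robustness to the full physics of a
microscope.

## Validation and filtering

Pseudo-missing-validation withholds one tilt (default: minimum |angle|,
the published choice), reconstructs from the remainder (the withheld
projection provably never enters: the reduced plan's angle set is
asserted), re-projects at the withheld angle (forward NUFFT on that line,
centred inverse DFT, real part), and scores the re-projection against the
withheld projection. For a single slice the FRC degenerates to a
per-conjugate-pair correlation of the two 1D spectra; the summary statistic
is the mean over rings with 0 < ρ < N/4 (below half-Nyquist, DC excluded).
2D FRC uses 1-Fourier-pixel half-open rings from the origin to Nyquist.

Verification filtering zeroes Fourier coefficients that lie inside the
missing-wedge sector AND beyond the first ring radius where the validation
FRC drops below the threshold (default 0.5). The measured sector — line
directions within [θ_min, θ_max] folded into (−90°, 90°] — is never
touched. The concrete wedge-sector + FRC-cutoff rule is this package's
choice; the original Step-4 criterion is only named, not specified, in the
available description.

RMSRE uses c = 10⁻⁷ exactly. Gray-value adjustment pools all micrographs
into one 256-bin histogram and subtracts the median of the fullest bin
(exact for discrete background levels; within half a bin width of the bin
centre otherwise). Pooled rather than per-micrograph adjustment is the
default; the published workflow does not specify which.

## Volume assembly and backends

Single-axis geometry makes slices perpendicular to the tilt axis
independent; `reconstruct_volume` gray-adjusts once globally, then
reconstructs row-sinograms independently (any processing order is
bit-identical — this independence contract is the package's stand-in for
the original GPU parallelization). All heavy steps are whole-array
operations (FFTs, gathers/scatters, reductions), so an accelerator array
backend could be substituted without algorithmic change.

## Problem sizes used in the automated checks

The shipped checks run at desk scale, chosen to exercise the published
protocol end-to-end on one CPU: backend-agreement and wedge-restoration
at N = 64 with the ±60°/2° scheme (61 tilts, 200 iterations), the
precision comparison at N = 512 with the ±68°/2° scheme (69 tilts),
oracle equivalence at N ∈ {8…64}, dense-matrix checks at N = 8, and
parameter recovery at N = 32 over 0°…179°.

## Known limitations

* No CTF correction or tilt alignment (upstream pre-processing).
* No dual-axis geometry, no 3D regularization across slices, no SIRT.
* The Gaussian gridding window caps oracle agreement at ~2e−6; Kaiser–
  Bessel windows would do better but are out of scope.
* The normalized RMSRE is ill-conditioned near its c constant for images
  with dense near-zero tails (see Precision switch above).
* MRC support covers modes 0/1/2/6 read, mode 2 write; extended headers
  are ignored.
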