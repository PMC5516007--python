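# iconet

Iterative compressed-sensing optimized NUFFT reconstruction (**ICON**) for
single-axis electron tomography, in pure scientific Python.

Electron tomography reconstructs a specimen in 3D from TEM projections
acquired over a limited tilt range (typically ±60°–±70°). The unsampled
region of Fourier space — the *missing wedge* — elongates densities and
smears ray artifacts across reconstructions made with single-pass methods
such as weighted back projection (WBP). ICON treats each 2D slice as a
compressed-sensing problem: it alternates a steepest-descent *fidelity*
step that keeps the slice consistent with the measured Fourier data, with a
*positivity hard threshold* that acts as the sparsity prior, and restores a
validated part of the missing-wedge information. A built-in
*pseudo-missing-validation* procedure withholds one projection,
reconstructs without it, and scores the re-projection against the withheld
"ground truth", so the restoration can be trusted quantitatively.

## The model

For one real N×N slice `x`, tilt angles θ₁…θ_T sample the slice's 2D
Fourier transform along central lines (central slice theorem). With

* `A` — the non-uniform Fourier sampling operator (a 2D type-2 NUFFT:
  `f_j = Σ_k x_k e^{−2πi k·x_j}` at points `x_j = (s/N)(cos θ, sin θ)`),
* `W` — diagonal density-compensation weights (the ramp `|s|` by default,
  or Pipe–Menon-style iterative weights),
* `f` — the 1D Fourier transforms of the measured projections,

ICON iterates, for k = 0, 1, …:

```
r      = AᴴWAxᵏ − AᴴWf                  (residual)
α      = rᵀr / (rᵀAᴴWAr)               (exact line search)
yᵏ⁺¹   = xᵏ − α r                       (fidelity preservation)
xᵏ⁺¹   = max(yᵏ⁺¹, 0)                   (positivity hard threshold)
```

for a fixed 200 iterations by default. `A`/`Aᴴ` are evaluated by
Gaussian-window gridding over a 2×-oversampled FFT (window half-width
m = 6), with brute-force direct-summation oracles available as a swappable
backend for verification. Validation metrics include the RMSRE between two
reconstructions (after min-max normalization into (c, 1+c], c = 10⁻⁷),
Pearson NCC, and Fourier ring correlation (FRC).

## Worked example

```python
import numpy as np
from iconet import (IconModel, PhantomSpec, make_phantom_slice,
                    make_tilt_scheme, simulate_sinogram, ncc)

phantom  = make_phantom_slice(PhantomSpec(N=64, n_blobs=8, seed=0))
scheme   = make_tilt_scheme(-60, 60, 2)        # 61 tilts, ±60° missing wedge
sinogram = simulate_sinogram(phantom, scheme, noise_sigma=0.05, seed=0)

results = IconModel(sinogram, scheme).fit(n_iter=200)
print(results.summary())
```

```
ICON reconstruction results
============================
slice side N         64
tilt angles          61
angular range (deg)  -60.00 .. +60.00
backend / precision  gridding / double
weights              ramp
iterations run       200
stop reason          n_iter
initial residual     2.64388e+06
final residual       4086.07
final step alpha     8.61704e-06
slice min / max      0 / 3.31535
```

The residual norm ‖r‖ drops by ~650× over the 200 fidelity steps and the
slice is non-negative by construction. Comparing against the ground truth
and the WBP baseline, and validating the restoration:

```python
model = IconModel(sinogram, scheme)
print(ncc(results.reconstruction, phantom), ncc(model.wbp(), phantom))
report = results.validate()                    # withholds the 0° projection
print(report.omitted_angle, report.ncc, report.mean_frc_half_nyquist)
```

```
NCC vs ground truth:  ICON 0.9972  WBP 0.8451
pseudo-missing-validation at +0.0 deg: NCC=1.0000, mean FRC below half-Nyquist=0.597
```

ICON recovers the phantom to NCC 0.997 despite the ±60° wedge (WBP: 0.845),
and the re-projection of the omit-reconstruction matches the withheld
projection almost perfectly at low frequency. `verification_filter` can
then remove wedge-region Fourier content beyond the radius where the
validation FRC drops below 0.5.

## Command line

```sh
iconet simulate    --size 64 --output ts.mrc --angles-out ts.tlt
iconet reconstruct --tilt-series ts.mrc --angles ts.tlt --row 0 \
                   --iterations 200 --output icon.mrc --trace trace.csv
iconet wbp         --tilt-series ts.mrc --angles ts.tlt --row 0 --output wbp.mrc
iconet validate    --tilt-series ts.mrc --angles ts.tlt --row 0 \
                   --report report.json --frc-csv frc.csv
iconet metrics     --ref icon.mrc --test wbp.mrc
```

Tilt series are MRC2014 stacks paired with plain-text `.tlt` angle files
(one degree value per line, stack order). The tilt axis is the image row
axis; each reconstructed slice is an (x, z) plane.

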