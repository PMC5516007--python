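"""The ICON iteration: fidelity preservation + positivity restriction.

ICON solves the missing-wedge-limited tomographic inverse problem

    argmin ‖P x‖_L0   subject to   ‖AᴴWAx − AᴴWf‖_L2 < ε,

where x is one real N×N reconstruction slice, A the non-uniform Fourier
sampling operator of the tilt scheme, W the density-compensation weights,
f the Fourier transform of the acquired projections, and P a diagonal
sparse transform whose action reduces to zeroing negative densities.  Each
iteration alternates

1. a steepest-descent fidelity step with exact line search,
       r = AᴴWAxᵏ − AᴴWf,   α = rᵀr / (rᵀAᴴWAr),   yᵏ⁺¹ = xᵏ − αr,
2. the positivity hard threshold  xᵏ⁺¹ = max(yᵏ⁺¹, 0).

The residual r is real (the imaginary part of every adjoint application is
discarded: x is a real image).  The exact line search makes the quadratic
fidelity functional q(x) = ½⟨x, AᴴWAx⟩ − Re⟨x, AᴴWf⟩ non-increasing within
every step; the hard threshold then projects onto the non-negative cone.

A weighted-backprojection baseline (one application of Re AᴴW f — direct
Fourier inversion with ramp-like weighting) is provided for comparison, and
single-axis geometry lets a 3D volume be assembled slice by slice
perpendicular to the tilt axis (tilt axis = image row axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as spfft

from .nufft import NufftOperator, WindowSpec, make_window
from .tilt_geometry import (
    SamplingPlan,
    TiltScheme,
    build_sampling_plan,
    density_compensation_weights,
    ramp_weights,
)

__all__ = [
    "ReconConfig",
    "IterationTrace",
    "gray_value_adjust",
    "sinogram_to_fourier",
    "fidelity_step",
    "positivity_threshold",
    "icon_reconstruct_slice",
    "wbp_reconstruct_slice",
    "reconstruct_volume",
]


@dataclass
class ReconConfig:
    """Reconstruction settings.

    n_iter : fixed iteration count (default 200, the published protocol).
    stop_epsilon : optional residual-norm floor mapping the ε of the
        constrained formulation onto an early-stopping rule; 0 disables it
        and runs the fixed n_iter iterations.
    init_mode : "zeros" (default) or "wbp" (thresholded weighted
        backprojection as the starting point).
    weight_mode : "ramp" (analytic |s| ramp, default) or "dc" (iterative
        density compensation).
    precision : "double" or "single" — end-to-end float width.
    backend : "gridding" (fast NUFFT) or "direct" (dense oracle).
    sigma, m : Gaussian window parameters.
    """

    n_iter: int = 200
    stop_epsilon: float = 0.0
    init_mode: str = "zeros"
    weight_mode: str = "ramp"
    precision: str = "double"
    backend: str = "gridding"
    sigma: float = 2.0
    m: int = 6
    dc_iters: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.stop_epsilon < 0:
            raise ValueError("stop_epsilon must be >= 0")
        if self.init_mode not in ("zeros", "wbp"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.weight_mode not in ("ramp", "dc"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")


@dataclass
class IterationTrace:
    """Per-iteration diagnostics of one ICON run.

    residual_norm[k] = ‖r‖ at iteration k; alpha[k] the line-search step;
    q_before/q_after the quadratic fidelity functional at xᵏ and at the
    intermediate yᵏ⁺¹ (exact line search guarantees q_after ≤ q_before).
    """

    residual_norm: list = field(default_factory=list)
    alpha: list = field(default_factory=list)
    q_before: list = field(default_factory=list)
    q_after: list = field(default_factory=list)
    converged: bool = False
    stop_reason: str = "n_iter"

    def __len__(self):
        return len(self.residual_norm)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(len(self)),
                "residual_norm": self.residual_norm,
                "alpha": self.alpha,
                "q": self.q_before,
                "q_after_step": self.q_after,
            }
        )


def gray_value_adjust(projections: np.ndarray, n_bins: int = 256):
    """Subtract the most frequent pixel value (the embedding background).

    The mode is estimated from the pooled histogram of all pixels of all
    micrographs, with ``n_bins`` equal-width bins over [min, max]; the
    median of the values inside the fullest bin (exact for a discrete
    background level, within half a bin width of the centre otherwise) is
    subtracted from every pixel.

    Returns ``(adjusted_stack, mode_value)``.  A constant-valued stack maps
    to all zeros (the constant is the mode).
    """
    projections = np.asarray(projections, dtype=float)
    if projections.size == 0:
        raise ValueError("empty projection stack")
    lo, hi = projections.min(), projections.max()
    if hi == lo:
        return projections - lo, float(lo)
    counts, edges = np.histogram(projections.ravel(), bins=n_bins, range=(lo, hi))
    i = int(np.argmax(counts))
    right = hi if i == n_bins - 1 else edges[i + 1]
    flat = projections.ravel()
    in_bin = (flat >= edges[i]) & (flat <= right)
    mode = float(np.median(flat[in_bin]))
    return projections - mode, mode


def sinogram_to_fourier(sinogram: np.ndarray, plan: SamplingPlan) -> np.ndarray:
    """Centred 1D DFT of every projection, laid out in plan order.

    Row t of the sinogram is the 1D projection at tilt t over centred pixel
    indices u ∈ [−N/2, N/2); its spectrum F(t, s) = Σ_u p[u] e^{−2πi su/N}
    is assigned to the plan sample with provenance (t, s).
    """
    sinogram = np.asarray(sinogram)
    T, N = sinogram.shape
    if N != plan.N or T != plan.n_tilts:
        raise ValueError(
            f"sinogram shape {sinogram.shape} does not match plan (T={plan.n_tilts}, N={plan.N})"
        )
    spectra = spfft.fftshift(spfft.fft(spfft.ifftshift(sinogram, axes=1), axis=1), axes=1)
    return spectra[plan.tilt_index, plan.freq_index + N // 2]


def positivity_threshold(y: np.ndarray) -> np.ndarray:
    """Hard threshold H(y): keep non-negative values, zero the rest."""
    y = np.asarray(y)
    return np.where(y >= 0, y, np.zeros((), dtype=y.dtype))


def fidelity_step(x, f, op: NufftOperator, weights, *, residual_floor=None):
    """One weighted steepest-descent step on the fidelity functional.

    Computes r = AᴴW(Ax − f) (real part), the exact line-search step
    α = ‖r‖² / ⟨Ar, W Ar⟩, and y = x − αr.

    Returns ``(y, alpha, info)`` where info carries the residual norm and
    the fidelity functional before/after the step.  If ‖r‖² falls below
    the machine floor the step returns y = x and flags convergence; a
    non-positive line-search denominator also stops the iteration (logged
    in info) rather than dividing.
    """
    x = np.asarray(x)
    w = np.asarray(weights, dtype=op.rdtype)
    Ax = op.forward(x)
    q_before = 0.5 * float(np.sum(w * np.abs(Ax) ** 2)) - float(
        np.real(np.sum(w * np.conj(Ax) * f))
    )
    r = op.adjoint(w * (Ax - f)).real.astype(op.rdtype)
    rn2 = float(np.sum(r.astype(np.float64) ** 2))
    if residual_floor is None:
        residual_floor = np.finfo(op.rdtype).tiny * r.size
    info = {
        "residual_norm": np.sqrt(rn2),
        "alpha": 0.0,
        "q_before": q_before,
        "q_after": q_before,
        "converged": False,
        "degenerate": False,
    }
    if not np.isfinite(rn2):
        raise FloatingPointError("non-finite residual in fidelity step")
    if rn2 <= residual_floor:
        info["converged"] = True
        return x, 0.0, info
    Ar = op.forward(r)
    denom = float(np.sum(w * np.abs(Ar.astype(np.complex128)) ** 2))  # = rᵀAᴴWAr
    if denom <= 0 or not np.isfinite(denom):
        info["degenerate"] = True
        return x, 0.0, info
    alpha = rn2 / denom
    if not np.isfinite(alpha):
        raise FloatingPointError("non-finite step size in fidelity step")
    y = x - op.rdtype(alpha) * r
    Ay = Ax - op.cdtype(alpha) * Ar
    info["alpha"] = alpha
    info["q_after"] = 0.5 * float(np.sum(w * np.abs(Ay) ** 2)) - float(
        np.real(np.sum(w * np.conj(Ay) * f))
    )
    return y, alpha, info


def _build_operator(scheme: TiltScheme, N: int, config: ReconConfig):
    """Plan + weights + operator for one slice, per the configuration."""
    plan = build_sampling_plan(scheme, N)
    spec = make_window(N, config.sigma, config.m)
    if config.weight_mode == "ramp":
        plan.weights = ramp_weights(plan)
    else:
        plan.weights = density_compensation_weights(plan, spec, config.dc_iters)
    op = NufftOperator(plan, spec, backend=config.backend, precision=config.precision)
    return plan, spec, op


def icon_reconstruct_slice(
    sinogram: np.ndarray,
    scheme: TiltScheme,
    config: ReconConfig | None = None,
):
    """Reconstruct one slice with the ICON iteration.

    Parameters
    ----------
    sinogram : (T, N) array
        One 1D projection per tilt, background already subtracted
        (see :func:`gray_value_adjust`).
    scheme : TiltScheme
    config : ReconConfig

    Returns
    -------
    (slice, trace) : the non-negative N×N reconstruction and the
    per-iteration :class:`IterationTrace`.
    """
    if config is None:
        config = ReconConfig()
    sinogram = np.asarray(sinogram, dtype=float)
    T, N = sinogram.shape
    plan, spec, op = _build_operator(scheme, N, config)
    f = sinogram_to_fourier(sinogram, plan).astype(op.cdtype)
    w = plan.weights.astype(op.rdtype)

    if config.init_mode == "zeros":
        x = np.zeros((N, N), dtype=op.rdtype)
    else:
        x = positivity_threshold(op.adjoint(w * f).real.astype(op.rdtype))

    trace = IterationTrace()
    for _ in range(config.n_iter):
        y, alpha, info = fidelity_step(x, f, op, w)
        trace.residual_norm.append(info["residual_norm"])
        trace.alpha.append(alpha)
        trace.q_before.append(info["q_before"])
        trace.q_after.append(info["q_after"])
        if info["converged"] or info["degenerate"]:
            trace.converged = info["converged"]
            trace.stop_reason = "converged" if info["converged"] else "degenerate_alpha"
            x = positivity_threshold(y)
            break
        x = positivity_threshold(y)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite values in reconstruction iterate")
        if config.stop_epsilon > 0 and info["residual_norm"] <= config.stop_epsilon:
            trace.converged = True
            trace.stop_reason = "stop_epsilon"
            break
    return x, trace


def wbp_reconstruct_slice(
    sinogram: np.ndarray,
    scheme: TiltScheme,
    config: ReconConfig | None = None,
) -> np.ndarray:
    """Weighted-backprojection baseline: one application of Re(AᴴWf).

    Direct Fourier inversion with density-compensation weighting — no
    iteration, no positivity constraint; output may be negative.
    """
    if config is None:
        config = ReconConfig()
    sinogram = np.asarray(sinogram, dtype=float)
    T, N = sinogram.shape
    plan, spec, op = _build_operator(scheme, N, config)
    f = sinogram_to_fourier(sinogram, plan).astype(op.cdtype)
    w = plan.weights.astype(op.rdtype)
    return op.adjoint(w * f).real.astype(op.rdtype)


def reconstruct_volume(
    tilt_series: np.ndarray,
    scheme: TiltScheme,
    config: ReconConfig | None = None,
    method: str = "icon",
    rows=None,
):
    """Reconstruct a 3D volume slice by slice.

    The tilt axis is the image row axis: row r of every projection forms
    the sinogram of the independent (x, z) slice r.  Gray-value adjustment
    is applied once, pooled over the whole stack, before slicing.  Slices
    are independent, so any processing order gives identical results.

    Parameters
    ----------
    tilt_series : (T, n_rows, N) array
    rows : optional iterable of row indices to reconstruct (default: all).

    Returns
    -------
    (volume, mode) : volume of shape (n_rows, N, N) (zero rows skipped if
    ``rows`` is given) and the subtracted background value.
    """
    if config is None:
        config = ReconConfig()
    tilt_series = np.asarray(tilt_series, dtype=float)
    if tilt_series.ndim != 3:
        raise ValueError("tilt series must be a (T, rows, N) stack")
    T, n_rows, N = tilt_series.shape
    if T != scheme.n_tilts:
        raise ValueError(
            f"stack depth {T} does not match tilt scheme ({scheme.n_tilts} angles)"
        )
    adjusted, mode = gray_value_adjust(tilt_series)
    volume = np.zeros((n_rows, N, N))
    for r in rows if rows is not None else range(n_rows):
        sinogram = adjusted[:, r, :]
        if method == "icon":
            volume[r], _ = icon_reconstruct_slice(sinogram, scheme, config)
        elif method == "wbp":
            volume[r] = wbp_reconstruct_slice(sinogram, scheme, config)
        else:
            raise ValueError(f"unknown method {method!r}")
    return volume, mode
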