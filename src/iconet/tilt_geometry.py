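"""Tilt geometry: from a tilt scheme to non-uniform Fourier sampling points.

Single-axis electron tomography acquires one projection per tilt angle. By
the central slice theorem, the 1D Fourier transform of the projection at
tilt angle θ equals the 2D Fourier transform of the slice along the line
through the origin with direction (cos θ, sin θ). A tilt scheme therefore
induces a set of non-uniform Fourier sampling points — one radial line per
tilt — together with density-compensation weights that account for the
radially non-uniform sampling (the analogue of the ramp filter in weighted
back projection).

Conventions (used consistently by the simulator, the reconstruction and the
re-projection code):

* θ = 0 is the untilted projection; it samples the first Fourier axis, so
  the beam at θ = 0 runs along the second image axis.
* Frequency indices s run over the half-open range [−N/2, N/2) (even N);
  the point for (θ, s) is x = (s/N)·(cos θ, sin θ) ∈ [−1/2, 1/2)².
* Angles are degrees at every interface and converted to radians once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TiltScheme",
    "SamplingPlan",
    "build_sampling_plan",
    "ramp_weights",
    "density_compensation_weights",
]


@dataclass(frozen=True)
class TiltScheme:
    """A single-axis tilt scheme.

    Parameters
    ----------
    angles : array-like of float
        Tilt angles in degrees, strictly increasing.  Physical single-axis
        schemes live in (−90, 90); angles in [90, 180) are also accepted
        for full-coverage sampling studies (θ samples the same central
        line as θ−180°), as long as all line directions are distinct
        modulo 180°.
    pixel_size : float
        Physical pixel size in nm. Metadata only; never enters the math.
    """

    angles: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        angles = np.asarray(self.angles, dtype=float).ravel()
        if angles.size == 0:
            raise ValueError("tilt scheme must contain at least one angle")
        if not np.all(np.isfinite(angles)):
            raise ValueError("tilt angles must be finite")
        if np.any(angles <= -90.0) or np.any(angles >= 180.0):
            raise ValueError("tilt angles must lie inside (-90, 180) degrees")
        if np.any(np.diff(angles) <= 0):
            raise ValueError("tilt angles must be strictly increasing (and distinct)")
        folded = np.sort(np.mod(angles, 180.0))
        if folded.size > 1 and np.min(np.diff(folded)) <= 1e-12:
            raise ValueError("tilt angles must have distinct directions modulo 180 degrees")
        object.__setattr__(self, "angles", angles)

    @property
    def n_tilts(self) -> int:
        return self.angles.size

    def without(self, angle: float, atol: float = 1e-9) -> "TiltScheme":
        """Return a new scheme with one angle removed (used by validation)."""
        mask = ~np.isclose(self.angles, angle, atol=atol)
        if mask.all():
            raise ValueError(f"angle {angle} not present in tilt scheme")
        return TiltScheme(self.angles[mask], self.pixel_size)


@dataclass
class SamplingPlan:
    """Non-uniform Fourier sampling points for one reconstruction slice.

    Attributes
    ----------
    N : int
        Slice side length in pixels (even).
    points : (M, 2) float array
        Sampling points in [−1/2, 1/2)², M = T·N.
    tilt_index : (M,) int array
        Tilt index t of each point.
    freq_index : (M,) int array
        Signed frequency index s ∈ [−N/2, N/2) of each point.
    weights : (M,) float array
        Diagonal of the density-compensation matrix W (non-negative).
    angles_deg : (T,) float array
        The tilt angles the plan was built from.
    """

    N: int
    points: np.ndarray
    tilt_index: np.ndarray
    freq_index: np.ndarray
    weights: np.ndarray
    angles_deg: np.ndarray = field(default=None)

    @property
    def M(self) -> int:
        return self.points.shape[0]

    @property
    def n_tilts(self) -> int:
        return self.angles_deg.size


def build_sampling_plan(scheme: TiltScheme, N: int) -> SamplingPlan:
    """Lay out the Fourier sampling points of a tilt scheme.

    For each tilt angle θ_t and each signed frequency index
    s ∈ {−N/2, …, N/2−1} the plan contains the point
    x = (s/N)·(cos θ_t, sin θ_t).  Points are ordered tilt-major, then by
    increasing s; duplicate DC samples (s = 0, one per tilt) are kept, with
    the weights absorbing the multiplicity.

    Weights are initialized with :func:`ramp_weights`.
    """
    if N % 2 != 0 or N < 4:
        raise ValueError(f"slice side N must be even and >= 4, got {N}")
    theta = np.deg2rad(scheme.angles)
    T = theta.size
    s = np.arange(-N // 2, N // 2)
    radius = s / N  # in [-1/2, 1/2)
    u = np.outer(np.cos(theta), radius)  # (T, N)
    v = np.outer(np.sin(theta), radius)
    points = np.stack([u.ravel(), v.ravel()], axis=1)
    plan = SamplingPlan(
        N=N,
        points=points,
        tilt_index=np.repeat(np.arange(T), N),
        freq_index=np.tile(s, T),
        weights=np.empty(T * N),
        angles_deg=scheme.angles.copy(),
    )
    plan.weights = ramp_weights(plan)
    return plan


def ramp_weights(plan: SamplingPlan) -> np.ndarray:
    """Analytic ramp-filter weights, w = |s|.

    The T duplicated DC samples each get 1/(4T) so their summed weight is
    exactly 1/4 — half the weight of the first non-zero frequency,
    mirroring the half-pixel-area rule of the ramp filter — independently
    of the number of tilts.
    """
    w = np.abs(plan.freq_index).astype(float)
    dc = plan.freq_index == 0
    w[dc] = 1.0 / (4.0 * plan.n_tilts)
    return w


def density_compensation_weights(
    plan: SamplingPlan,
    window=None,
    n_iter: int = 10,
) -> np.ndarray:
    """Iterative (Pipe–Menon style) density-compensation weights.

    Alternates ``w ← w / (G w)`` where ``G w`` grids the weighted samples
    onto the oversampled fine grid through the Gaussian window and reads
    them back at the sample points, i.e. convolves the sample cloud with
    the window autocorrelation.  The fixed point makes the re-gridded
    density approximately flat, which is the defining property of density
    compensation.  Returns strictly positive weights; the plan is not
    modified.

    Parameters
    ----------
    window : WindowSpec, optional
        Gridding window; defaults to the package default (σ=2, m=6).
    n_iter : int
        Number of fixed-point iterations (≥ 1).
    """
    from .nufft import make_window, precompute_window_tables, spread, gather

    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if window is None:
        window = make_window(plan.N)
    tables = precompute_window_tables(plan.points, window)
    w = np.ones(plan.M)
    for it in range(n_iter):
        grid = spread(w.astype(complex), tables, window)
        gw = gather(grid, tables).real
        if np.any(gw <= 0) or not np.all(np.isfinite(gw)):
            raise FloatingPointError(
                f"density compensation denominator vanished at iteration {it}"
            )
        w = w / gw
    return w
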