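"""2D non-uniform FFT (type 2) and its adjoint via Gaussian-window gridding.

The forward transform evaluates the trigonometric polynomial

    f_j = Σ_{k ∈ I_N} f̂_k · e^{−2πi k·x_j},      I_N = [−N/2, N/2)²,

at non-uniform points x_j ∈ [−1/2, 1/2)², and the adjoint spreads the
samples back,

    ĥ_k = Σ_j f_j · e^{+2πi k·x_j}.

Both are computed with the classic three-step gridding scheme over an
oversampled n×n grid, n = σN:

forward:  deconvolve  f̂_k / (n² φ̂(k₀) φ̂(k₁))  →  n×n FFT (e^{−2πi} sign)
          →  gather the (2m+1)² fine-grid neighbours of each x_j with
          window weights φ(x_j − l/n) per axis;
adjoint:  the exact transpose — spread, FFT with the conjugate sign,
          deconvolve, crop to N×N.  No 1/M factor anywhere.

The (dilated) Gaussian window pair is

    φ(x)  = (πb)^{−1/2} · exp(−(nx)²/b),    b = 2σ/(2σ−1) · m/π,
    φ̂(k)  = (1/n) · exp(−b (πk/n)²),

with defaults σ = 2 and m = 6.  The window support is applied periodically
(fine-grid indices mod n), matching the periodic polynomial model.  Because
forward and adjoint reuse the identical window tables, they are exact
adjoints of each other in exact arithmetic, and the adjoint dot test passes
at rounding level.

Direct-summation references (``ndft_forward`` / ``ndft_adjoint``) evaluate
the sums literally and serve as independent oracles for small N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as spfft

__all__ = [
    "WindowSpec",
    "WindowTables",
    "make_window",
    "window_phi",
    "window_phi_hat",
    "precompute_window_tables",
    "spread",
    "gather",
    "nufft_forward",
    "nufft_adjoint",
    "ndft_forward",
    "ndft_adjoint",
    "NufftOperator",
]

#: Largest side length the direct-summation oracles accept without force=True.
NDFT_SIZE_GUARD = 128


@dataclass(frozen=True)
class WindowSpec:
    """Gaussian gridding window parameters.

    N : image side (even); sigma : oversampling factor σ > 1;
    m : window half-width in fine-grid pixels; n : fine grid side σN;
    b : Gaussian shape parameter 2σ/(2σ−1) · m/π.
    """

    N: int
    sigma: float
    m: int
    n: int
    b: float


def make_window(N: int, sigma: float = 2.0, m: int = 6) -> WindowSpec:
    """Build a :class:`WindowSpec`; σ must exceed 1 and σN must be integral."""
    if sigma <= 1.0:
        raise ValueError(f"oversampling factor sigma must be > 1, got {sigma}")
    if m < 1:
        raise ValueError(f"window half-width m must be >= 1, got {m}")
    if N % 2 != 0:
        raise ValueError(f"image side N must be even, got {N}")
    n = sigma * N
    if abs(n - round(n)) > 1e-12:
        raise ValueError(f"sigma*N must be integral, got {n}")
    b = (2.0 * sigma / (2.0 * sigma - 1.0)) * (m / np.pi)
    return WindowSpec(N=N, sigma=float(sigma), m=int(m), n=int(round(n)), b=b)


def window_phi(x, spec: WindowSpec):
    """Real-space window φ(x) = (πb)^{−1/2} exp(−(nx)²/b); even, positive."""
    x = np.asarray(x, dtype=float)
    return (np.pi * spec.b) ** -0.5 * np.exp(-((spec.n * x) ** 2) / spec.b)


def window_phi_hat(k, spec: WindowSpec):
    """Fourier-space window φ̂(k) = (1/n) exp(−b(πk/n)²); even, positive."""
    k = np.asarray(k, dtype=float)
    return (1.0 / spec.n) * np.exp(-spec.b * (np.pi * k / spec.n) ** 2)


@dataclass(frozen=True)
class WindowTables:
    """Precomputed per-sample window values and fine-grid anchor indices.

    ``indices`` and ``values`` both have shape (M, 2, 2m+1): axis 1 selects
    the image axis, axis 2 the window tap.  Indices are already reduced
    mod n.  Using the tables is bit-identical to evaluating the window on
    the fly — they store the exact closed-form values.
    """

    indices: np.ndarray
    values: np.ndarray
    n: int

    @property
    def M(self) -> int:
        return self.indices.shape[0]


def precompute_window_tables(points: np.ndarray, spec: WindowSpec) -> WindowTables:
    """Tabulate window values/anchors for each sampling point.

    The window is truncated to the 2m+1 fine-grid points centred on the
    grid point nearest n·x, per axis.
    """
    points = np.asarray(points, dtype=float)
    anchors = np.rint(spec.n * points).astype(np.int64)  # (M, 2)
    taps = np.arange(-spec.m, spec.m + 1)
    grid_idx = anchors[:, :, None] + taps[None, None, :]  # (M, 2, 2m+1)
    offsets = points[:, :, None] - grid_idx / spec.n
    values = window_phi(offsets, spec)
    return WindowTables(indices=grid_idx % spec.n, values=values, n=spec.n)


def _deconvolution_factors(spec: WindowSpec, dtype) -> np.ndarray:
    """Per-axis factors 1/(n·φ̂(k)) for k ∈ [−N/2, N/2), as an outer product."""
    k = np.arange(-spec.N // 2, spec.N // 2)
    d = 1.0 / (spec.n * window_phi_hat(k, spec))
    return np.outer(d, d).astype(dtype)


def gather(fine_grid: np.ndarray, tables: WindowTables) -> np.ndarray:
    """Windowed interpolation of an n×n fine grid at the table's points."""
    ix = tables.indices[:, 0, :]
    iy = tables.indices[:, 1, :]
    sub = fine_grid[ix[:, :, None], iy[:, None, :]]  # (M, P, P)
    wx = tables.values[:, 0, :].astype(fine_grid.real.dtype)
    wy = tables.values[:, 1, :].astype(fine_grid.real.dtype)
    return np.einsum("jab,ja,jb->j", sub, wx, wy)


def spread(samples: np.ndarray, tables: WindowTables, spec: WindowSpec) -> np.ndarray:
    """Adjoint of :func:`gather`: scatter samples onto the n×n fine grid."""
    n = spec.n
    wx = tables.values[:, 0, :].astype(samples.real.dtype)
    wy = tables.values[:, 1, :].astype(samples.real.dtype)
    contrib = samples[:, None, None] * wx[:, :, None] * wy[:, None, :]
    flat_idx = (tables.indices[:, 0, :][:, :, None] * n
                + tables.indices[:, 1, :][:, None, :]).ravel()
    flat = contrib.ravel()
    grid = np.bincount(flat_idx, weights=flat.real, minlength=n * n).astype(flat.real.dtype)
    if np.iscomplexobj(samples):
        grid = grid + 1j * np.bincount(
            flat_idx, weights=flat.imag, minlength=n * n
        ).astype(flat.real.dtype)
    return grid.reshape(n, n).astype(samples.dtype)


def nufft_forward(
    coeffs: np.ndarray,
    points: np.ndarray,
    spec: WindowSpec,
    tables: WindowTables | None = None,
) -> np.ndarray:
    """Fast evaluation of f_j = Σ_k f̂_k e^{−2πi k·x_j} by gridding."""
    coeffs = np.asarray(coeffs)
    if coeffs.shape != (spec.N, spec.N):
        raise ValueError(f"coeffs must be {spec.N}x{spec.N}, got {coeffs.shape}")
    if tables is None:
        tables = precompute_window_tables(points, spec)
    cdtype = np.complex64 if coeffs.dtype in (np.float32, np.complex64) else np.complex128
    k = np.arange(-spec.N // 2, spec.N // 2)
    ghat = coeffs.astype(cdtype) * _deconvolution_factors(spec, cdtype)
    grid = np.zeros((spec.n, spec.n), dtype=cdtype)
    grid[np.ix_(k % spec.n, k % spec.n)] = ghat
    # fft2 realizes g_l = Σ_k ĝ_k e^{−2πi k·l/n} (indices mod n)
    g = spfft.fft2(grid)
    return gather(g, tables)


def nufft_adjoint(
    samples: np.ndarray,
    points: np.ndarray,
    spec: WindowSpec,
    tables: WindowTables | None = None,
) -> np.ndarray:
    """Fast evaluation of ĥ_k = Σ_j f_j e^{+2πi k·x_j} (no 1/M factor)."""
    samples = np.asarray(samples)
    if tables is None:
        tables = precompute_window_tables(points, spec)
    if samples.shape != (tables.M,):
        raise ValueError(f"samples must have length {tables.M}, got {samples.shape}")
    cdtype = np.complex64 if samples.dtype in (np.float32, np.complex64) else np.complex128
    grid = spread(samples.astype(cdtype), tables, spec)
    # n² · ifft2 realizes H_k = Σ_l G_l e^{+2πi k·l/n}
    H = spfft.ifft2(grid) * (spec.n * spec.n)
    k = np.arange(-spec.N // 2, spec.N // 2)
    cropped = H[np.ix_(k % spec.n, k % spec.n)]
    return cropped * _deconvolution_factors(spec, cdtype)


def ndft_forward(
    coeffs: np.ndarray, points: np.ndarray, force: bool = False
) -> np.ndarray:
    """Direct summation of f_j = Σ_k f̂_k e^{−2πi k·x_j} (oracle, small N)."""
    coeffs = np.asarray(coeffs)
    N = coeffs.shape[0]
    if coeffs.shape != (N, N):
        raise ValueError("coeffs must be square")
    if N > NDFT_SIZE_GUARD and not force:
        raise ValueError(f"ndft oracle refuses N={N} > {NDFT_SIZE_GUARD} without force=True")
    E = _ndft_matrix(points, N)
    return E @ coeffs.astype(complex).ravel()


def ndft_adjoint(
    samples: np.ndarray, points: np.ndarray, N: int, force: bool = False
) -> np.ndarray:
    """Direct summation of ĥ_k = Σ_j f_j e^{+2πi k·x_j} (oracle, small N)."""
    if N > NDFT_SIZE_GUARD and not force:
        raise ValueError(f"ndft oracle refuses N={N} > {NDFT_SIZE_GUARD} without force=True")
    E = _ndft_matrix(points, N)
    return (E.conj().T @ np.asarray(samples, dtype=complex)).reshape(N, N)


def _ndft_matrix(points: np.ndarray, N: int) -> np.ndarray:
    """Dense matrix E[j, k] = e^{−2πi k·x_j} over the centred index set I_N."""
    points = np.asarray(points, dtype=float)
    k = np.arange(-N // 2, N // 2)
    K0, K1 = np.meshgrid(k, k, indexing="ij")
    phase = np.outer(points[:, 0], K0.ravel()) + np.outer(points[:, 1], K1.ravel())
    return np.exp(-2j * np.pi * phase)


class NufftOperator:
    """The sampling operator A for one plan, with swappable backend.

    backend="gridding" uses the fast Gaussian-window NUFFT; backend="direct"
    uses the dense direct-summation matrix (the independent oracle — slow,
    guarded above N=128).  All heavy steps are whole-array operations so an
    accelerator array library could be substituted without algorithmic
    change.

    Parameters
    ----------
    plan : SamplingPlan
    spec : WindowSpec, optional (gridding backend only)
    backend : {"gridding", "direct"}
    precision : {"double", "single"}
        End-to-end floating point width of the transform pipeline.
    """

    def __init__(self, plan, spec: WindowSpec | None = None,
                 backend: str = "gridding", precision: str = "double",
                 force: bool = False):
        if backend not in ("gridding", "direct"):
            raise ValueError(f"unknown backend {backend!r}")
        if precision not in ("double", "single"):
            raise ValueError(f"unknown precision {precision!r}")
        self.plan = plan
        self.backend = backend
        self.precision = precision
        self.cdtype = np.complex64 if precision == "single" else np.complex128
        self.rdtype = np.float32 if precision == "single" else np.float64
        if backend == "gridding":
            self.spec = spec if spec is not None else make_window(plan.N)
            if self.spec.N != plan.N:
                raise ValueError("window spec N does not match plan N")
            self.tables = precompute_window_tables(plan.points, self.spec)
            self._matrix = None
        else:
            self.spec = spec
            if plan.N > NDFT_SIZE_GUARD and not force:
                raise ValueError(
                    f"direct backend refuses N={plan.N} > {NDFT_SIZE_GUARD} without force=True"
                )
            self._matrix = _ndft_matrix(plan.points, plan.N).astype(self.cdtype)
            self.tables = None

    def forward(self, image: np.ndarray) -> np.ndarray:
        """A x: transform an N×N (real or complex) array to plan samples."""
        if self.backend == "gridding":
            return nufft_forward(
                np.asarray(image).astype(self.cdtype), self.plan.points,
                self.spec, self.tables,
            )
        return self._matrix @ np.asarray(image).astype(self.cdtype).ravel()

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        """Aᴴ f: transform plan samples back to an N×N complex array."""
        samples = np.asarray(samples).astype(self.cdtype)
        if self.backend == "gridding":
            return nufft_adjoint(samples, self.plan.points, self.spec, self.tables)
        N = self.plan.N
        return (self._matrix.conj().T @ samples).reshape(N, N)
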