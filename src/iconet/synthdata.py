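"""Synthetic phantoms and simulated tilt series.

The simulator produces data with the structure the reconstruction model
assumes: non-negative density with compact support, a limited angular
range, a constant background offset from the embedding material, and
additive white Gaussian noise.  Projections are synthesized in Fourier
space — the phantom's 2D transform is evaluated on each tilt's central
line by *direct summation* (never by the fast gridding NUFFT under test)
and inverted to a real 1D projection — so noiseless simulated data are
exactly consistent with the reconstruction's periodic trigonometric
polynomial model, which the fixed-point tests require.  A real-space
ray-integration alternative is deliberately not provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as spfft

from .tilt_geometry import TiltScheme

__all__ = [
    "PhantomSpec",
    "make_phantom_slice",
    "simulate_sinogram",
    "make_tilt_scheme",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Blob-phantom parameters.

    N elliptical Gaussian blobs, truncated at 3 standard deviations (so the
    background is exactly zero), placed entirely inside the central half of
    the field to avoid wrap-around in the periodic model.  Intensities are
    drawn uniformly from ``intensity``.
    """

    N: int = 64
    n_blobs: int = 8
    intensity: tuple = (0.5, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.N % 2 != 0 or self.N < 4:
            raise ValueError("phantom side N must be even and >= 4")
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be >= 0")


def make_phantom_slice(spec: PhantomSpec) -> np.ndarray:
    """Deterministic (seeded) non-negative blob phantom with zero background."""
    rng = np.random.default_rng(spec.seed)
    N = spec.N
    img = np.zeros((N, N))
    yy, xx = np.mgrid[0:N, 0:N].astype(float)
    cut = 3.0
    for _ in range(spec.n_blobs):
        # blob fully inside the central half: centre and 3σ extent bounded
        sig = rng.uniform(N / 32.0, N / 12.0, size=2)
        margin = cut * sig.max()
        lo, hi = N / 4.0 + margin, 3.0 * N / 4.0 - margin
        if lo >= hi:  # tiny fields: fall back to the centre
            cx = cy = N / 2.0
        else:
            cy, cx = rng.uniform(lo, hi, size=2)
        theta = rng.uniform(0.0, np.pi)
        amp = rng.uniform(*spec.intensity)
        ct, st = np.cos(theta), np.sin(theta)
        u = (yy - cy) * ct + (xx - cx) * st
        v = -(yy - cy) * st + (xx - cx) * ct
        d2 = (u / sig[0]) ** 2 + (v / sig[1]) ** 2
        # truncated Gaussian: exactly zero beyond the 3σ ellipse
        blob = np.exp(-0.5 * d2) - np.exp(-0.5 * cut**2)
        img += amp * np.clip(blob, 0.0, None)
    return img


def _line_spectrum(phantom: np.ndarray, theta_rad: float) -> np.ndarray:
    """Direct-summation Fourier transform of the phantom on one central line.

    Evaluates F(s) = Σ_k x_k e^{−2πi s (k·d)/N}, d = (cos θ, sin θ), for all
    s ∈ [−N/2, N/2), using the phase recurrence e^{−2πi p s/N} =
    (e^{−2πi p/N})^s over the phantom's non-zero pixels only.  Independent
    of the gridding NUFFT code path.
    """
    N = phantom.shape[0]
    k = np.arange(-N // 2, N // 2)
    K0, K1 = np.meshgrid(k, k, indexing="ij")
    nz = phantom != 0.0
    vals = phantom[nz]
    proj = (K0[nz] * np.cos(theta_rad) + K1[nz] * np.sin(theta_rad)) / N
    z = np.exp(-2j * np.pi * proj)  # per-pixel unit phasor for one s step
    s0 = -N // 2
    cur = np.exp(-2j * np.pi * proj * s0) * vals
    out = np.empty(N, dtype=complex)
    for i in range(N):
        out[i] = cur.sum()
        cur *= z
    return out


def simulate_sinogram(
    phantom: np.ndarray,
    scheme: TiltScheme,
    noise_sigma: float = 0.0,
    background: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate the (T, N) sinogram of a phantom under a tilt scheme.

    Per tilt: sample the phantom's Fourier transform on the tilt's central
    line (direct summation), inverse-transform to a real 1D projection,
    then add the constant ``background`` and white Gaussian noise of the
    given sigma (absolute intensity units).  Deterministic given the seed.
    """
    phantom = np.asarray(phantom, dtype=float)
    N = phantom.shape[0]
    if phantom.shape != (N, N):
        raise ValueError("phantom must be square")
    rng = np.random.default_rng(seed)
    T = scheme.n_tilts
    sinogram = np.empty((T, N))
    for t, angle in enumerate(scheme.angles):
        line = _line_spectrum(phantom, np.deg2rad(angle))
        sinogram[t] = spfft.fftshift(spfft.ifft(spfft.ifftshift(line))).real
    sinogram += background
    if noise_sigma > 0:
        sinogram += rng.normal(0.0, noise_sigma, size=sinogram.shape)
    return sinogram


def make_tilt_scheme(
    min_deg: float, max_deg: float, step_deg: float, pixel_size: float = 1.0
) -> TiltScheme:
    """Inclusive arithmetic tilt sequence, e.g. (−68, 68, 2) → 69 angles."""
    if min_deg > max_deg:
        raise ValueError("min_deg must not exceed max_deg")
    if step_deg <= 0:
        raise ValueError("step_deg must be positive")
    count = int(np.floor((max_deg - min_deg) / step_deg + 1e-9)) + 1
    if count < 1:
        raise ValueError("tilt scheme would be empty")
    angles = min_deg + step_deg * np.arange(count)
    return TiltScheme(angles, pixel_size)
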