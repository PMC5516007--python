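"""Validation metrics: RMSRE, NCC, Fourier ring correlation, and the
pseudo-missing-validation / verification-filtering procedures.

Pseudo-missing-validation withholds one projection (by default the one at
the minimum |tilt|), reconstructs from the remainder, re-projects the
result at the withheld angle, and scores the re-projection against the
withheld "ground truth" — a self-contained measure of how faithfully the
algorithm restores information it never saw.  Verification filtering then
removes the missing-wedge Fourier content beyond the radius at which the
validation FRC falls below a threshold, i.e. the part of the restored
information that did not validate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as spfft

from .nufft import WindowSpec, make_window, nufft_forward, ndft_forward
from .reconstruction import (
    ReconConfig,
    icon_reconstruct_slice,
    wbp_reconstruct_slice,
)
from .tilt_geometry import TiltScheme, build_sampling_plan

__all__ = [
    "normalize01",
    "rmsre",
    "ncc",
    "frc",
    "projection_frc",
    "reproject_slice",
    "ValidationReport",
    "pseudo_missing_validate",
    "verification_filter",
]

#: Small constant added after min-max normalization to avoid zero divisors.
DEFAULT_NORM_C = 1e-7


def normalize01(P: np.ndarray, c: float = DEFAULT_NORM_C) -> np.ndarray:
    """Min-max normalize into (c, 1+c]:  (P − min P)/(max P − min P) + c.

    A constant array (degenerate range) maps to the all-c array.
    """
    P = np.asarray(P, dtype=float)
    lo, hi = P.min(), P.max()
    if hi == lo:
        return np.full_like(P, c)
    return (P - lo) / (hi - lo) + c


def rmsre(P: np.ndarray, C: np.ndarray, c: float = DEFAULT_NORM_C) -> float:
    """Root-mean-square relative error between two reconstructions.

    Both arrays are min-max normalized into (c, 1+c] first, so the metric
    is invariant under positive affine maps of either input; the result is

        ε = sqrt( Σ_i ((Pnorm_i − Cnorm_i)/Cnorm_i)² / N ),

    with N the element count.
    """
    P = np.asarray(P, dtype=float)
    C = np.asarray(C, dtype=float)
    if P.shape != C.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {C.shape}")
    Pn = normalize01(P, c)
    Cn = normalize01(C, c)
    return float(np.sqrt(np.mean(((Pn - Cn) / Cn) ** 2)))


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized (Pearson) cross-correlation over all elements, in [−1, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("NCC undefined for a constant-valued input")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def frc(a: np.ndarray, b: np.ndarray, ring_width: float = 1.0):
    """Fourier ring correlation of two equally shaped even square images.

    Rings are half-open in radius, ``ring_width`` Fourier pixels wide,
    from the origin out to Nyquist (radius N/2):

        FRC(ρ) = Re Σ_ρ F_a conj(F_b) / sqrt(Σ_ρ |F_a|² · Σ_ρ |F_b|²).

    Returns ``(radii, values)`` with radii the lower ring edges; rings
    without power in either image get value 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    N = a.shape[0]
    if a.ndim != 2 or a.shape[1] != N or N % 2 != 0:
        raise ValueError("frc requires even square images")
    Fa = spfft.fftshift(spfft.fft2(a))
    Fb = spfft.fftshift(spfft.fft2(b))
    k = np.arange(-N // 2, N // 2)
    K0, K1 = np.meshgrid(k, k, indexing="ij")
    radius = np.hypot(K0, K1)
    ring = np.floor(radius / ring_width).astype(int)
    n_rings = int(np.floor((N // 2) / ring_width)) + 1
    valid = ring < n_rings  # drop corners beyond Nyquist
    ring = ring[valid]
    cross = np.bincount(ring, weights=np.real(Fa * np.conj(Fb))[valid], minlength=n_rings)
    pa = np.bincount(ring, weights=(np.abs(Fa) ** 2)[valid], minlength=n_rings)
    pb = np.bincount(ring, weights=(np.abs(Fb) ** 2)[valid], minlength=n_rings)
    denom = np.sqrt(pa * pb)
    values = np.divide(cross, denom, out=np.zeros_like(cross), where=denom > 0)
    radii = np.arange(n_rings) * ring_width
    return radii, np.clip(values, -1.0, 1.0)


def projection_frc(p: np.ndarray, q: np.ndarray):
    """Per-frequency correlation of two 1D projections' spectra.

    The 1D analogue of the FRC for a single-slice validation: ring ρ is
    the conjugate frequency pair {+ρ, −ρ} of the centred spectra.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("projection_frc requires two equal-length 1D arrays")
    N = p.size
    Fp = spfft.fftshift(spfft.fft(spfft.ifftshift(p)))
    Fq = spfft.fftshift(spfft.fft(spfft.ifftshift(q)))
    s = np.arange(-N // 2, N // 2)
    rho = np.abs(s)
    n_rings = N // 2 + 1
    cross = np.bincount(rho, weights=np.real(Fp * np.conj(Fq)), minlength=n_rings)
    pp = np.bincount(rho, weights=np.abs(Fp) ** 2, minlength=n_rings)
    qq = np.bincount(rho, weights=np.abs(Fq) ** 2, minlength=n_rings)
    # the +N/2 member of the outermost pair is unrepresentable: keep as is
    denom = np.sqrt(pp * qq)
    values = np.divide(cross, denom, out=np.zeros_like(cross), where=denom > 0)
    return np.arange(n_rings, dtype=float), np.clip(values, -1.0, 1.0)


def reproject_slice(
    slice_image: np.ndarray,
    angle_deg: float,
    spec: WindowSpec | None = None,
    backend: str = "gridding",
) -> np.ndarray:
    """Re-project a reconstructed slice at one tilt angle.

    Samples the slice's Fourier transform on the central line of the given
    angle (forward NUFFT, or direct summation with backend="direct") and
    returns the centred inverse 1D DFT — the 1D projection the microscope
    would have recorded.
    """
    slice_image = np.asarray(slice_image, dtype=float)
    N = slice_image.shape[0]
    theta = np.deg2rad(angle_deg)
    s = np.arange(-N // 2, N // 2)
    points = np.stack(
        [s / N * np.cos(theta), s / N * np.sin(theta)], axis=1
    )
    if backend == "direct":
        line = ndft_forward(slice_image.astype(complex), points, force=True)
    else:
        if spec is None:
            spec = make_window(N)
        line = nufft_forward(slice_image.astype(complex), points, spec)
    return spfft.fftshift(spfft.ifft(spfft.ifftshift(line))).real


@dataclass
class ValidationReport:
    """Outcome of one pseudo-missing-validation run."""

    omitted_angle: float
    truth_projection: np.ndarray
    reprojection: np.ndarray
    frc_radii: np.ndarray
    frc_values: np.ndarray
    ncc: float
    mean_frc_half_nyquist: float
    method: str = "icon"

    def to_dict(self) -> dict:
        return {
            "omitted_angle": self.omitted_angle,
            "method": self.method,
            "ncc": self.ncc,
            "mean_frc_half_nyquist": self.mean_frc_half_nyquist,
            "frc_radii": self.frc_radii.tolist(),
            "frc_values": self.frc_values.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def frc_to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("radius_pixels,frc\n")
            for r, v in zip(self.frc_radii, self.frc_values):
                fh.write(f"{r},{v}\n")


def pseudo_missing_validate(
    sinogram: np.ndarray,
    scheme: TiltScheme,
    omit="min-abs",
    config: ReconConfig | None = None,
    method: str = "icon",
) -> ValidationReport:
    """Withhold one tilt, reconstruct without it, score the re-projection.

    Parameters
    ----------
    sinogram : (T, N) array of 1D projections, one per tilt.
    omit : "min-abs" (withhold the minimum-|angle| tilt, the published
        choice) or an angle in degrees that must be present in the scheme.
    method : "icon" or "wbp" — which reconstruction to validate.

    Returns a :class:`ValidationReport` whose FRC is the per-frequency
    correlation between the re-projected and the withheld 1D projection,
    and whose summary holds their NCC and the mean FRC over rings below
    half-Nyquist (ρ < N/4).
    """
    if config is None:
        config = ReconConfig()
    sinogram = np.asarray(sinogram, dtype=float)
    T, N = sinogram.shape
    if T != scheme.n_tilts:
        raise ValueError("sinogram depth does not match tilt scheme")
    if omit == "min-abs":
        idx = int(np.argmin(np.abs(scheme.angles)))
    else:
        matches = np.nonzero(np.isclose(scheme.angles, float(omit), atol=1e-9))[0]
        if matches.size == 0:
            raise ValueError(f"omit angle {omit} not present in tilt scheme")
        idx = int(matches[0])
    omitted_angle = float(scheme.angles[idx])
    truth = sinogram[idx]
    keep = np.arange(T) != idx
    reduced_scheme = TiltScheme(scheme.angles[keep], scheme.pixel_size)
    # the withheld projection never enters the reconstruction
    assert omitted_angle not in reduced_scheme.angles
    reduced_sinogram = sinogram[keep]
    if method == "icon":
        recon, _ = icon_reconstruct_slice(reduced_sinogram, reduced_scheme, config)
    elif method == "wbp":
        recon = wbp_reconstruct_slice(reduced_sinogram, reduced_scheme, config)
    else:
        raise ValueError(f"unknown method {method!r}")
    spec = make_window(N, config.sigma, config.m)
    reproj = reproject_slice(recon, omitted_angle, spec)
    radii, values = projection_frc(reproj, truth)
    half_ny = radii < N // 4
    # ring 0 is the DC term; keep it out of the summary statistic
    half_ny[0] = False
    return ValidationReport(
        omitted_angle=omitted_angle,
        truth_projection=truth,
        reprojection=reproj,
        frc_radii=radii,
        frc_values=values,
        ncc=ncc(reproj, truth),
        mean_frc_half_nyquist=float(values[half_ny].mean()),
        method=method,
    )


def missing_wedge_mask(N: int, scheme: TiltScheme, atol_deg: float = 1e-6) -> np.ndarray:
    """Boolean N×N mask (centred Fourier indices) of the missing wedge.

    A frequency (k₀, k₁) is *measured* when the direction of its central
    line, atan2(k₁, k₀) folded into (−90°, 90°], falls inside the closed
    angular range [θ_min, θ_max] of the tilt scheme; everything else is
    the missing wedge.  The origin is always measured.
    """
    k = np.arange(-N // 2, N // 2)
    K0, K1 = np.meshgrid(k, k, indexing="ij")
    phi = np.rad2deg(np.arctan2(K1, K0))
    phi = np.where(phi > 90.0, phi - 180.0, phi)
    phi = np.where(phi <= -90.0, phi + 180.0, phi)
    measured = (phi >= scheme.angles.min() - atol_deg) & (
        phi <= scheme.angles.max() + atol_deg
    )
    measured[N // 2, N // 2] = True
    return ~measured


def verification_filter(
    slice_image: np.ndarray,
    frc_radii: np.ndarray,
    frc_values: np.ndarray,
    scheme: TiltScheme,
    threshold: float = 0.5,
) -> np.ndarray:
    """Remove restored Fourier content that failed validation.

    Finds the smallest ring radius ρ* at which the validation FRC first
    drops below ``threshold`` and zeroes the slice's Fourier coefficients
    that lie inside the missing-wedge sector AND at radius ≥ ρ*.
    Coefficients in the measured sector are never touched.  If the FRC
    stays at or above the threshold everywhere the slice is returned
    unchanged (up to one FFT round trip).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    frc_radii = np.asarray(frc_radii, dtype=float)
    frc_values = np.asarray(frc_values, dtype=float)
    if frc_radii.size == 0:
        raise ValueError("empty FRC curve")
    slice_image = np.asarray(slice_image, dtype=float)
    N = slice_image.shape[0]
    below = frc_values < threshold
    if not below.any():
        return slice_image.copy()
    rho_star = float(frc_radii[np.argmax(below)])
    k = np.arange(-N // 2, N // 2)
    K0, K1 = np.meshgrid(k, k, indexing="ij")
    radius = np.hypot(K0, K1)
    kill = missing_wedge_mask(N, scheme) & (radius >= rho_star)
    F = spfft.fftshift(spfft.fft2(slice_image))
    F[kill] = 0.0
    return spfft.ifft2(spfft.ifftshift(F)).real
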