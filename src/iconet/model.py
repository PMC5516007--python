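"""Model/Results front end for slice reconstruction.

`IconModel` holds one sinogram and its tilt scheme; `fit()` runs the ICON
iteration and returns an `IconResults` carrying the reconstruction, the
iteration trace and validation helpers.  The functional API in
:mod:`iconet.reconstruction` and :mod:`iconet.metrics` does the work; this
layer only packages it the way fitted-model libraries do.
"""

from __future__ import annotations

import numpy as np

from .metrics import ValidationReport, ncc, pseudo_missing_validate, verification_filter
from .reconstruction import (
    IterationTrace,
    ReconConfig,
    gray_value_adjust,
    icon_reconstruct_slice,
    wbp_reconstruct_slice,
)
from .tilt_geometry import TiltScheme

__all__ = ["IconModel", "IconResults"]


class IconModel:
    """ICON reconstruction model for a single slice.

    Parameters
    ----------
    sinogram : (T, N) array
        One 1D projection per tilt angle.
    angles_deg : array-like
        Tilt angles in degrees, strictly increasing.
    pixel_size : float
        Pixel size in nm (metadata).
    adjust_gray : bool
        Subtract the pooled histogram mode (background gray value) before
        reconstructing.  Default False: single-slice sinograms are usually
        already background-subtracted; volume assembly does it globally.
    """

    def __init__(self, sinogram, angles_deg, pixel_size: float = 1.0,
                 adjust_gray: bool = False):
        sinogram = np.asarray(sinogram, dtype=float)
        if sinogram.ndim != 2:
            raise ValueError("sinogram must be a (T, N) array")
        self.scheme = (
            angles_deg
            if isinstance(angles_deg, TiltScheme)
            else TiltScheme(angles_deg, pixel_size)
        )
        if sinogram.shape[0] != self.scheme.n_tilts:
            raise ValueError(
                f"sinogram has {sinogram.shape[0]} rows but the scheme "
                f"has {self.scheme.n_tilts} angles"
            )
        self.gray_mode = 0.0
        if adjust_gray:
            sinogram, self.gray_mode = gray_value_adjust(sinogram)
        self.sinogram = sinogram

    @classmethod
    def from_files(cls, mrc_path, tlt_path, row: int, **kwargs) -> "IconModel":
        """Build the model for one slice (row) of an MRC tilt series."""
        from .io import check_pairing, read_mrc, read_tlt

        stack, voxel = read_mrc(mrc_path)
        scheme = read_tlt(tlt_path, pixel_size=voxel)
        check_pairing(stack, scheme)
        return cls(stack[:, row, :], scheme, **kwargs)

    @property
    def N(self) -> int:
        return self.sinogram.shape[1]

    def fit(self, config: ReconConfig | None = None, **config_kwargs) -> "IconResults":
        """Run the ICON iteration; returns an :class:`IconResults`."""
        if config is None:
            config = ReconConfig(**config_kwargs)
        elif config_kwargs:
            raise TypeError("pass either a ReconConfig or keyword overrides, not both")
        slice_image, trace = icon_reconstruct_slice(self.sinogram, self.scheme, config)
        return IconResults(self, config, slice_image, trace)

    def wbp(self, config: ReconConfig | None = None) -> np.ndarray:
        """Weighted-backprojection baseline reconstruction of the slice."""
        return wbp_reconstruct_slice(self.sinogram, self.scheme, config or ReconConfig())


class IconResults:
    """Results of one fitted ICON reconstruction."""

    def __init__(self, model: IconModel, config: ReconConfig,
                 reconstruction: np.ndarray, trace: IterationTrace):
        self.model = model
        self.config = config
        self.reconstruction = reconstruction
        self.trace = trace

    @property
    def n_iterations(self) -> int:
        return len(self.trace)

    @property
    def final_residual(self) -> float:
        return self.trace.residual_norm[-1] if len(self.trace) else float("nan")

    def validate(self, omit="min-abs", method: str = "icon") -> ValidationReport:
        """Pseudo-missing-validation of this model's data and settings."""
        return pseudo_missing_validate(
            self.model.sinogram, self.model.scheme, omit, self.config, method
        )

    def verification_filtered(self, report: ValidationReport,
                              threshold: float = 0.5) -> np.ndarray:
        """Apply verification filtering using a validation report's FRC."""
        return verification_filter(
            self.reconstruction, report.frc_radii, report.frc_values,
            self.model.scheme, threshold,
        )

    def ncc_against(self, reference: np.ndarray) -> float:
        return ncc(self.reconstruction, reference)

    def summary(self) -> str:
        """Plain-text summary table of the run."""
        t = self.trace
        rows = [
            ("slice side N", self.model.N),
            ("tilt angles", self.model.scheme.n_tilts),
            ("angular range (deg)",
             f"{self.model.scheme.angles.min():+.2f} .. {self.model.scheme.angles.max():+.2f}"),
            ("backend / precision", f"{self.config.backend} / {self.config.precision}"),
            ("weights", self.config.weight_mode),
            ("iterations run", self.n_iterations),
            ("stop reason", t.stop_reason),
            ("initial residual", f"{t.residual_norm[0]:.6g}" if len(t) else "n/a"),
            ("final residual", f"{self.final_residual:.6g}"),
            ("final step alpha", f"{t.alpha[-1]:.6g}" if len(t) else "n/a"),
            ("slice min / max",
             f"{self.reconstruction.min():.6g} / {self.reconstruction.max():.6g}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["ICON reconstruction results", "=" * 28]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Plot the residual-norm history (log scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(np.arange(self.n_iterations), self.trace.residual_norm)
        ax.set_xlabel("iteration")
        ax.set_ylabel(r"$\|r\|$")
        ax.set_title("ICON fidelity residual")
        return ax
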