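"""Hyperspectral image cube container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CANONICAL_AXES = "y,x,nu"


@dataclass
class HyperspectralCube:
    """A y * x * nu intensity cube with its wavenumber axis and pixel size.

    Parameters
    ----------
    data : ndarray, shape (ny, nx, n_nu)
        Intensity values; raw CARS intensity or Im[chi3] depending on ``mode``.
    axis_cm1 : ndarray, shape (n_nu,)
        Strictly increasing wavenumber axis in cm^-1.
    pixel_size_um : float
        Lateral sampling in micrometres per pixel (default 0.5).
    mode : str
        ``"im_domain"`` if data are Im[chi3] spectra, ``"chi3_domain"`` if raw
        CARS intensity that still needs phase retrieval.
    """

    data: np.ndarray
    axis_cm1: np.ndarray
    pixel_size_um: float = 0.5
    mode: str = "im_domain"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.axis_cm1 = np.asarray(self.axis_cm1, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (y, x, nu)")
        if self.axis_cm1.ndim != 1 or self.axis_cm1.size != self.data.shape[2]:
            raise ValueError(
                f"axis length {self.axis_cm1.size} does not match spectral "
                f"dimension {self.data.shape[2]}"
            )
        if np.any(np.diff(self.axis_cm1) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def channel_index(self, wavenumber: float) -> int:
        """Index of the spectral channel nearest to ``wavenumber`` (cm^-1)."""
        return int(np.argmin(np.abs(self.axis_cm1 - wavenumber)))

    def channel_image(self, wavenumber: float) -> np.ndarray:
        """2-D intensity image at the channel nearest to ``wavenumber``."""
        return self.data[:, :, self.channel_index(wavenumber)]

    def with_data(self, data: np.ndarray, mode: str | None = None) -> "HyperspectralCube":
        """Copy of this cube with replaced data (same axis and pixel size)."""
        return HyperspectralCube(
            data=data,
            axis_cm1=self.axis_cm1.copy(),
            pixel_size_um=self.pixel_size_um,
            mode=self.mode if mode is None else mode,
            meta=dict(self.meta),
        )
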