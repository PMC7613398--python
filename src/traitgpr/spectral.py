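"""Spectral grids, sensor band sets and RSR convolution.

Spectra live on a fine :func:`spectral_grid` (400–1020 nm, 1 nm default).
A :class:`BandSet` holds per-band relative spectral responses (RSR) sampled
on that grid; :func:`band_convolve` reduces a fine spectrum to band values.
The default band set models the 21 visible/NIR bands of a Sentinel-3 OLCI
style imager with Gaussian response shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["spectral_grid", "BandSet", "olci_band_set", "band_convolve"]

GRID_MIN_NM = 400.0
GRID_MAX_NM = 1020.0

# Center wavelength (nm) and width (nm) of the 21 OLCI VIS/NIR bands (Oa1–Oa21).
OLCI_BAND_CENTERS = np.array([
    400.0, 412.5, 442.5, 490.0, 510.0, 560.0, 620.0, 665.0, 673.75, 681.25,
    708.75, 753.75, 761.25, 764.375, 767.5, 778.75, 865.0, 885.0, 900.0,
    940.0, 1020.0,
])
OLCI_BAND_WIDTHS = np.array([
    15.0, 10.0, 10.0, 10.0, 10.0, 10.0, 10.0, 10.0, 7.5, 7.5,
    10.0, 7.5, 2.5, 3.75, 2.5, 15.0, 20.0, 10.0, 10.0, 20.0, 40.0,
])


def spectral_grid(step: float = 1.0) -> np.ndarray:
    """Fine wavelength grid in nm, covering 400–1020 inclusive."""
    if step <= 0:
        raise ValueError("step must be positive")
    return np.arange(GRID_MIN_NM, GRID_MAX_NM + 0.5 * step, step)


@dataclass
class BandSet:
    """A sensor's band definitions with RSRs sampled on a shared grid.

    Attributes
    ----------
    centers, widths : (B,) arrays, nm
    grid : (W,) array, nm — the fine grid the RSRs are sampled on
    rsr : (B, W) array — nonnegative, each row integrates to 1 on the grid
    """

    centers: np.ndarray
    widths: np.ndarray
    grid: np.ndarray
    rsr: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, float)
        self.widths = np.asarray(self.widths, float)
        self.grid = np.asarray(self.grid, float)
        self.rsr = np.asarray(self.rsr, float)
        if self.rsr.shape != (self.centers.size, self.grid.size):
            raise ValueError("rsr shape must be (n_bands, n_grid)")
        if (self.rsr < 0).any():
            raise ValueError("RSR values must be nonnegative")
        step = float(np.diff(self.grid).mean())
        integrals = self.rsr.sum(axis=1) * step
        if not np.allclose(integrals, 1.0, atol=1e-6):
            raise ValueError("each RSR must integrate to 1 on the grid")

    @property
    def n_bands(self) -> int:
        return self.centers.size

    @property
    def band_ids(self) -> list[str]:
        return [f"band_{i + 1:02d}" for i in range(self.n_bands)]

    def subset(self, indices) -> "BandSet":
        """Band set restricted to the given band indices."""
        idx = np.asarray(indices, int)
        if idx.size == 0:
            raise ValueError("band subset must be nonempty")
        return BandSet(self.centers[idx], self.widths[idx], self.grid, self.rsr[idx])


def _gaussian_rsr(centers, widths, grid) -> np.ndarray:
    # FWHM -> Gaussian sigma; renormalize numerically so truncation at the
    # grid edges cannot break the unit-integral invariant
    sigma = np.asarray(widths)[:, None] / 2.3548200450309493
    r = np.exp(-0.5 * ((grid[None, :] - np.asarray(centers)[:, None]) / sigma) ** 2)
    step = float(np.diff(grid).mean())
    return r / (r.sum(axis=1, keepdims=True) * step)


def olci_band_set(grid: np.ndarray | None = None) -> BandSet:
    """Default 21-band OLCI-style band set with Gaussian RSRs."""
    if grid is None:
        grid = spectral_grid()
    rsr = _gaussian_rsr(OLCI_BAND_CENTERS, OLCI_BAND_WIDTHS, grid)
    return BandSet(OLCI_BAND_CENTERS.copy(), OLCI_BAND_WIDTHS.copy(), grid, rsr)


def band_convolve(spectrum: np.ndarray, bands: BandSet) -> np.ndarray:
    """Convolve spectra with the band RSRs: value_b = Σ RSR_b·spectrum·Δλ.

    ``spectrum`` may be a single (W,) spectrum or an (n, W) stack; returns
    (B,) or (n, B) respectively.
    """
    spectrum = np.asarray(spectrum, float)
    if spectrum.shape[-1] != bands.grid.size:
        raise ValueError(
            f"spectrum has {spectrum.shape[-1]} samples but grid has {bands.grid.size}"
        )
    step = float(np.diff(bands.grid).mean())
    return spectrum @ (bands.rsr.T * step)
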