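"""Differential multi-frequency bi-focusing (MFBF) image reconstruction.

Differential imaging subtracts the scattering matrix of the state under test
from a reference ("healthy") state, ``dS = S_background - S_target``, which
cancels every static contribution (antenna coupling, phantom walls) and
isolates the change.  MFBF then focuses the differential data onto each pixel
(focal point) of the ROI grid:

    I(x, y) = sum_f sum_(Ti, Rj)  dS_TiRj(f) / k(f)^2
              * exp(+j k rho_Rj) * exp(+j k rho_Ti)

with ``k = 2 pi f sqrt(eps_r) / c`` the (real) background wavenumber and
``rho`` the Euclidean distances from the focal point to the transmit and
receive radiating points.  The positive exponents compensate the ``e^{-jk
rho}`` propagation phase of the physical channel, so contributions from the
true scatterer location add coherently across frequencies and channels — a
matched-filter back-propagation.  Only the six unique transmission channels
enter; reciprocal duplicates add no information, and reflection terms are
excluded.  Losses are deliberately left out of the focusing kernel: the image
is a qualitative contrast indicator, not a quantitative inversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.constants import c as C0

from dmwi.dielectrics import DebyeParameterization, debye_permittivity
from dmwi.errors import ComputationError, DataError
from dmwi.geometry import AntennaArray, ImagingGrid
from dmwi.synthetic import TRANSMISSION_CHANNELS, SParameterSet

__all__ = [
    "DifferentialSet",
    "ImageMap",
    "differential",
    "select_band",
    "wavenumber",
    "mfbf_image",
    "mfbf_image_series",
    "water_permittivity_fn",
]

log = logging.getLogger(__name__)

DEFAULT_BAND_HZ = (0.5e9, 2.0e9)


@dataclass
class DifferentialSet:
    """Per-frequency differential matrices with band mask and channel list."""

    frequencies_hz: np.ndarray
    delta_matrices: np.ndarray  # (n_f, 4, 4)
    band_mask: np.ndarray  # (n_f,) bool
    channels: tuple[tuple[int, int], ...] = TRANSMISSION_CHANNELS

    @property
    def n_band_points(self) -> int:
        return int(np.count_nonzero(self.band_mask))

    def channel_data(self) -> np.ndarray:
        """(n_f_masked, n_channels) differential transmission entries."""
        idx = np.flatnonzero(self.band_mask)
        return np.stack(
            [self.delta_matrices[idx, i, j] for (i, j) in self.channels], axis=1
        )


def differential(
    background: SParameterSet,
    target: SParameterSet,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    channels: Sequence[tuple[int, int]] = TRANSMISSION_CHANNELS,
) -> DifferentialSet:
    """Entry-wise ``S_background - S_target`` with the default usable band."""
    if background.frequencies_hz.shape != target.frequencies_hz.shape or not np.allclose(
        background.frequencies_hz, target.frequencies_hz
    ):
        raise DataError("background and target frequency grids differ")
    for i, j in channels:
        if i == j:
            raise DataError("channel list must contain off-diagonal pairs only")
    f = background.frequencies_hz
    mask = (f >= band_hz[0]) & (f <= band_hz[1])
    return DifferentialSet(
        frequencies_hz=f.copy(),
        delta_matrices=background.matrices - target.matrices,
        band_mask=mask,
        channels=tuple(tuple(c) for c in channels),
    )


def select_band(
    dset: DifferentialSet, f_low_hz: float, f_high_hz: float
) -> DifferentialSet:
    """Restrict the band mask to ``[f_low, f_high]`` (inclusive)."""
    if not f_low_hz < f_high_hz:
        raise ComputationError("band bounds are inverted")
    f = dset.frequencies_hz
    mask = (f >= f_low_hz) & (f <= f_high_hz)
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ComputationError(
            f"band {f_low_hz / 1e9:g}-{f_high_hz / 1e9:g} GHz selects no sweep points"
        )
    log.info(
        "band %.3g-%.3g GHz: %d of %d frequency points",
        f_low_hz / 1e9, f_high_hz / 1e9, n, len(f),
    )
    return replace(dset, band_mask=mask)


def wavenumber(frequency_hz: float | np.ndarray, eps_r: float) -> float | np.ndarray:
    """Real background wavenumber ``2 pi f sqrt(eps_r) / c`` in rad/m."""
    if eps_r <= 0:
        raise ComputationError("relative permittivity must be positive")
    k = 2.0 * np.pi * np.asarray(frequency_hz, dtype=float) * np.sqrt(eps_r) / C0
    if np.ndim(frequency_hz) == 0:
        return float(k)
    return k


def water_permittivity_fn(
    params: DebyeParameterization, temperature_c: float = 25.0
) -> Callable[[float], float]:
    """Background-medium dispersion for focusing: ``f -> real eps_r``."""

    def eps_r(frequency_hz: float) -> float:
        return float(np.real(debye_permittivity(frequency_hz, temperature_c, params)))

    return eps_r


@dataclass
class ImageMap:
    """Complex MFBF intensity over the ROI grid."""

    grid: ImagingGrid
    complex_intensity: np.ndarray  # (n_pix,)
    normalization: float = 1.0

    @property
    def display_intensity(self) -> np.ndarray:
        """|I|, divided by ``normalization`` (1 = raw magnitudes)."""
        return np.abs(self.complex_intensity) / self.normalization

    @property
    def peak_index(self) -> int:
        """Argmax of |I|; ``np.argmax`` breaks ties at the lowest linear index."""
        mag = np.abs(self.complex_intensity)
        idx = int(np.argmax(mag))
        if np.count_nonzero(mag == mag[idx]) > 1:
            log.info("image peak is tied; keeping lowest linear index %d", idx)
        return idx

    @property
    def peak_xy_mm(self) -> tuple[float, float]:
        x, y = self.grid.pixel_centers_mm[self.peak_index]
        return float(x), float(y)

    @property
    def peak_magnitude(self) -> float:
        return float(np.abs(self.complex_intensity[self.peak_index]))

    def normalized(self) -> "ImageMap":
        peak = self.peak_magnitude
        return ImageMap(
            grid=self.grid,
            complex_intensity=self.complex_intensity,
            normalization=peak if peak > 0 else 1.0,
        )


def _focusing_sum(
    stack: np.ndarray,  # (n_img, n_f_masked, n_ch)
    freqs: np.ndarray,
    channels: Sequence[tuple[int, int]],
    array: AntennaArray,
    grid: ImagingGrid,
    medium: Callable[[float], float],
    conjugate_focusing: bool,
) -> np.ndarray:
    pix_m = grid.pixel_centers_mm * 1e-3
    n_img = stack.shape[0]
    intensity = np.zeros((n_img, grid.n_pixels), dtype=complex)
    sign = -1.0 if conjugate_focusing else 1.0
    for fi, f in enumerate(freqs):
        k = wavenumber(f, medium(f))
        pos_m = array.positions(f) * 1e-3  # (4, 2)
        rho = np.hypot(
            pix_m[:, None, 0] - pos_m[None, :, 0],
            pix_m[:, None, 1] - pos_m[None, :, 1],
        )  # (n_pix, 4)
        e = np.exp(sign * 1j * k * rho)
        phase = np.stack([e[:, ti] * e[:, rj] for (ti, rj) in channels], axis=1)
        intensity += (stack[:, fi, :] / k**2) @ phase.T
    return intensity


def mfbf_image(
    dset: DifferentialSet,
    array: AntennaArray,
    grid: ImagingGrid,
    medium: Callable[[float], float],
    conjugate_focusing: bool = False,
) -> ImageMap:
    """Focus one differential set onto the ROI grid.

    ``medium`` maps frequency (Hz) to the real relative permittivity of the
    background used in the wavenumber; see :func:`water_permittivity_fn`.
    ``conjugate_focusing`` flips the sign of the focusing exponents (both
    conventions appear in the literature; the default is the
    matched-filter/back-propagation pairing with an ``e^{-jk rho}`` channel).
    """
    return mfbf_image_series([dset], array, grid, medium, conjugate_focusing)[0]


def mfbf_image_series(
    dsets: Sequence[DifferentialSet],
    array: AntennaArray,
    grid: ImagingGrid,
    medium: Callable[[float], float],
    conjugate_focusing: bool = False,
) -> list[ImageMap]:
    """Focus several differential sets sharing one sweep/band/channel layout.

    The per-frequency focusing exponentials are computed once and reused
    across the stack, which is what makes imaging a 46-acquisition cooling
    series cheap.
    """
    if not dsets:
        raise ComputationError("no differential sets supplied")
    first = dsets[0]
    if first.n_band_points == 0:
        raise ComputationError("band mask selects no frequency points")
    if not first.channels:
        raise ComputationError("channel list is empty")
    for d in dsets[1:]:
        if (
            not np.array_equal(d.band_mask, first.band_mask)
            or not np.allclose(d.frequencies_hz, first.frequencies_hz)
            or d.channels != first.channels
        ):
            raise DataError("differential sets in a series must share layout")
    stack = np.stack([d.channel_data() for d in dsets])
    freqs = first.frequencies_hz[first.band_mask]
    intensity = _focusing_sum(
        stack, freqs, first.channels, array, grid, medium, conjugate_focusing
    )
    return [ImageMap(grid=grid, complex_intensity=row) for row in intensity]
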