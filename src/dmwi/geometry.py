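"""Antenna-array layout, imaging grid, and path lengths.

Coordinates are millimeters in the transverse plane, origin at the common
center of the array, the region of interest (ROI), and the phantom; x points
right, y points up.  The four antennas form two pairs separated by 35 degrees
within a pair, with corresponding antennas of the two pairs 90 degrees apart,
all apertures on a circle of radius 100 mm.  The effective radiating point of
each antenna sits a frequency-dependent phase-center offset inward of its
aperture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dmwi.errors import ComputationError, DataError

__all__ = [
    "AntennaArray",
    "ImagingGrid",
    "build_array",
    "build_grid",
    "path_length",
    "phase_center_offset",
]

BAND_HZ = (0.5e9, 3.0e9)


def phase_center_offset(frequency_hz: float | np.ndarray, poly: np.ndarray) -> float | np.ndarray:
    """Phase-center offset in mm, measured from the aperture toward the ROI.

    ``poly`` holds polynomial coefficients in *ascending* powers of frequency
    expressed in GHz (degree <= 5).  Evaluation is restricted to the
    0.5-3 GHz design band; no extrapolation.
    """
    f = np.asarray(frequency_hz, dtype=float)
    if np.any(f < BAND_HZ[0]) or np.any(f > BAND_HZ[1]):
        raise ComputationError(
            f"frequency outside the {BAND_HZ[0] / 1e9:g}-{BAND_HZ[1] / 1e9:g} GHz "
            "band; the phase-center polynomial is not extrapolated"
        )
    coeffs = np.atleast_1d(np.asarray(poly, dtype=float))
    if coeffs.size > 6:
        raise ComputationError("phase-center polynomial degree must be <= 5")
    out = np.polynomial.polynomial.polyval(f / 1e9, coeffs)
    if np.ndim(frequency_hz) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class AntennaArray:
    """Four-antenna circular array with frequency-dependent radiating points."""

    aperture_radius_mm: float
    angular_positions_deg: np.ndarray
    phase_center_poly: np.ndarray = field(default_factory=lambda: np.zeros(1))

    @property
    def n_antennas(self) -> int:
        return len(self.angular_positions_deg)

    def aperture_positions(self) -> np.ndarray:
        """(n, 2) aperture coordinates in mm on the 100-mm circle."""
        ang = np.deg2rad(self.angular_positions_deg)
        return self.aperture_radius_mm * np.column_stack([np.cos(ang), np.sin(ang)])

    def positions(self, frequency_hz: float) -> np.ndarray:
        """(n, 2) radiating-point coordinates in mm at one frequency.

        The radiating point lies at radius ``aperture_radius - offset(f)``
        along each antenna boresight.
        """
        offset = phase_center_offset(frequency_hz, self.phase_center_poly)
        ang = np.deg2rad(self.angular_positions_deg)
        r = self.aperture_radius_mm - offset
        return r * np.column_stack([np.cos(ang), np.sin(ang)])


def build_array(
    aperture_radius_mm: float = 100.0,
    pair_separation_deg: float = 35.0,
    pair_offset_deg: float = 90.0,
    orientation_deg: float = 107.5,
    phase_center_poly: np.ndarray | None = None,
    min_separation_deg: float = 5.0,
) -> AntennaArray:
    """Construct the two-pair, four-antenna array.

    Antenna angles are ``{t0, t0 + sep, t0 + off, t0 + sep + off}`` with
    ``t0 = orientation_deg``; defaults give the 35/90-degree arrangement whose
    sensitivity axis bisects the pairs.  Raises if any two antennas end up
    closer than ``min_separation_deg``.
    """
    if aperture_radius_mm <= 0:
        raise ComputationError("aperture radius must be positive")
    if not 0 < pair_separation_deg < 90:
        raise ComputationError("pair separation must lie in (0, 90) degrees")
    angles = orientation_deg + np.array(
        [0.0, pair_separation_deg, pair_offset_deg, pair_offset_deg + pair_separation_deg]
    )
    wrapped = np.mod(angles, 360.0)
    for i in range(4):
        for j in range(i + 1, 4):
            d = abs(wrapped[i] - wrapped[j])
            d = min(d, 360.0 - d)
            if d < min_separation_deg:
                raise ComputationError(
                    f"antennas {i + 1} and {j + 1} are {d:.1f} deg apart, closer "
                    f"than the {min_separation_deg:g} deg minimum"
                )
    poly = np.zeros(1) if phase_center_poly is None else np.asarray(phase_center_poly, float)
    return AntennaArray(
        aperture_radius_mm=aperture_radius_mm,
        angular_positions_deg=angles,
        phase_center_poly=poly,
    )


def path_length(a_xy_mm, b_xy_mm) -> float | np.ndarray:
    """Euclidean distance in mm between two points (or arrays of points)."""
    a = np.asarray(a_xy_mm, dtype=float)
    b = np.asarray(b_xy_mm, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ComputationError("coordinates must be finite")
    d = np.hypot(a[..., 0] - b[..., 0], a[..., 1] - b[..., 1])
    if d.ndim == 0:
        return float(d)
    return d


@dataclass(frozen=True)
class ImagingGrid:
    """Square lattice of focal points clipped to a circular ROI."""

    roi_radius_mm: float
    pitch_mm: float
    pixel_centers_mm: np.ndarray  # (n_pix, 2)

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_centers_mm)

    def rasterize(self, values: np.ndarray, fill=np.nan) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Scatter a per-pixel vector onto a dense (ny, nx) array for export.

        Returns ``(x_axis_mm, y_axis_mm, image)`` with ``fill`` outside the ROI.
        """
        values = np.asarray(values)
        if values.shape[0] != self.n_pixels:
            raise DataError("value vector length does not match the grid")
        half = int(np.floor(self.roi_radius_mm / self.pitch_mm))
        axis = np.arange(-half, half + 1) * self.pitch_mm
        img = np.full((len(axis), len(axis)), fill, dtype=values.dtype)
        ix = np.rint(self.pixel_centers_mm[:, 0] / self.pitch_mm).astype(int) + half
        iy = np.rint(self.pixel_centers_mm[:, 1] / self.pitch_mm).astype(int) + half
        img[iy, ix] = values
        return axis, axis, img


def build_grid(roi_radius_mm: float = 100.0, pitch_mm: float = 1.0) -> ImagingGrid:
    """Build the ROI grid: lattice points with ``x^2 + y^2 <= R^2``.

    Pixel centers sit at integer multiples of the pitch, so the grid is
    symmetric under reflection about either axis and contains the origin.
    """
    if pitch_mm <= 0:
        raise ComputationError("pitch must be positive")
    if pitch_mm > roi_radius_mm:
        raise ComputationError("pitch larger than the ROI radius")
    half = int(np.floor(roi_radius_mm / pitch_mm))
    coords = np.arange(-half, half + 1) * pitch_mm
    xx, yy = np.meshgrid(coords, coords)
    keep = xx**2 + yy**2 <= roi_radius_mm**2
    centers = np.column_stack([xx[keep], yy[keep]])
    return ImagingGrid(
        roi_radius_mm=roi_radius_mm, pitch_mm=pitch_mm, pixel_centers_mm=centers
    )
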