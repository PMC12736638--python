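"""Synthetic S-parameter datasets for the cooling-inclusion experiment.

The measured scenario is a water-filled cylindrical phantom (inner radius
105 mm) at room temperature with an 8-mm-diameter water column at
``(-25, 10)`` mm whose temperature decays from 40.5 C to 36.0 C while a
four-port VNA records 4x4 scattering matrices over 0.5-3 GHz (201 points).
This module emulates that dataset with a physically structured surrogate:

* a first-order 2D Born forward model with line sources at the antenna
  radiating points.  The scattered contribution of the inclusion is
  ``k^2 * integral( dchi(r) G(tx, r) G(r, rx) dA )`` with
  ``dchi = (eps_inclusion - eps_background) / eps_background`` and ``G`` the
  outgoing 2D Green's function of the lossy background at complex wavenumber.
  The Born linearization is accurate for the thermal contrasts studied here
  (|dchi| of a few percent at most);
* a smooth deterministic baseline coupling between antenna pairs (line-source
  channel through the lossy background).  Its exact form is immaterial: it is
  identical in the background and target states and cancels exactly in the
  differential matrix;
* band-limited usable transmission: above the 2.3 GHz cutoff the transmission
  entries are forced below -80 dB with randomized (but per-sweep
  deterministic) phase, emulating the measured channel collapse;
* additive circular complex Gaussian noise at a configurable floor, the knob
  that creates a finite detection threshold;
* a two-phase acquisition-timing model (cooling slows as the target
  approaches room temperature).

Reflection (diagonal) entries carry a smooth placeholder model; they are never
used by the imaging chain.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.constants import c as C0
from scipy.special import hankel2

from dmwi.dielectrics import DEFAULT_WATER, DebyeParameterization, debye_permittivity
from dmwi.errors import ComputationError, DataError
from dmwi.geometry import AntennaArray

__all__ = [
    "PhantomScene",
    "AcquisitionSpec",
    "SParameterSet",
    "CoolingSeries",
    "air_permittivity",
    "born_transmission",
    "simulate_sparams",
    "cooling_series",
]

#: Tube geometry: 8 mm internal diameter, 1 mm wall.
TUBE_INNER_RADIUS_MM = 4.0
TUBE_OUTER_RADIUS_MM = 5.0

#: Two-phase timing model (seconds): the first 23 intervals are faster than
#: the remaining 22 because cooling slows near room temperature.
TIMING_FIRST = (4.78, 0.99)
TIMING_SECOND = (5.77, 0.68)
N_FIRST_INTERVALS = 23


def air_permittivity(frequency_hz: float | np.ndarray) -> complex | np.ndarray:
    """Lossless unit permittivity, for the air-filled validation target."""
    return np.ones_like(np.asarray(frequency_hz, dtype=float)) * (1.0 + 0.0j)


@dataclass(frozen=True)
class PhantomScene:
    """Cylindrical water background with one circular inclusion.

    ``inclusion_medium`` overrides the inclusion permittivity with an arbitrary
    function of frequency (e.g. :func:`air_permittivity`); when ``None`` the
    inclusion is water at ``inclusion_temperature_c``.
    """

    inclusion_temperature_c: float
    background_temperature_c: float = 25.0
    inclusion_center_mm: tuple[float, float] = (-25.0, 10.0)
    inclusion_radius_mm: float = TUBE_INNER_RADIUS_MM
    phantom_inner_radius_mm: float = 105.0
    params: DebyeParameterization = DEFAULT_WATER
    inclusion_medium: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.inclusion_radius_mm <= 0:
            raise ComputationError("inclusion radius must be positive")
        cx, cy = self.inclusion_center_mm
        if np.hypot(cx, cy) + self.inclusion_radius_mm > self.phantom_inner_radius_mm:
            raise ComputationError("inclusion does not fit inside the phantom")

    def background_permittivity(self, frequency_hz) -> np.ndarray:
        return debye_permittivity(
            frequency_hz, self.background_temperature_c, self.params
        )

    def inclusion_permittivity(self, frequency_hz) -> np.ndarray:
        if self.inclusion_medium is not None:
            return self.inclusion_medium(np.asarray(frequency_hz, dtype=float))
        return debye_permittivity(
            frequency_hz, self.inclusion_temperature_c, self.params
        )

    def contrast(self, frequency_hz) -> np.ndarray:
        """Born contrast ``dchi = (eps_inc - eps_bg) / eps_bg``."""
        eps_b = self.background_permittivity(frequency_hz)
        return (self.inclusion_permittivity(frequency_hz) - eps_b) / eps_b


@dataclass(frozen=True)
class AcquisitionSpec:
    """Frequency sweep and noise description of one VNA acquisition."""

    f_start_hz: float = 0.5e9
    f_stop_hz: float = 3.0e9
    n_points: int = 201
    noise_floor_db: float | None = -100.0
    highband_cutoff_hz: float = 2.3e9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ComputationError("sweep needs at least 2 frequency points")
        if not self.f_start_hz < self.f_stop_hz:
            raise ComputationError("f_start must be below f_stop")

    @property
    def frequencies_hz(self) -> np.ndarray:
        return np.linspace(self.f_start_hz, self.f_stop_hz, self.n_points)


@dataclass
class SParameterSet:
    """Per-frequency 4x4 complex scattering matrices with sweep metadata."""

    frequencies_hz: np.ndarray
    matrices: np.ndarray  # (n_f, 4, 4) complex
    temperature_c: float | None = None
    timestamp_s: float | None = None
    z0_ohm: float = 50.0
    comments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.matrices = np.asarray(self.matrices, dtype=complex)
        if self.matrices.shape != (len(self.frequencies_hz), 4, 4):
            raise DataError(
                f"expected (n_f, 4, 4) matrices, got {self.matrices.shape}"
            )

    @property
    def n_ports(self) -> int:
        return self.matrices.shape[1]


def background_wavenumber(scene: PhantomScene, frequency_hz) -> np.ndarray:
    """Complex wavenumber (rad/m) of the lossy background at 25 C.

    With ``eps = eps' - j eps''`` the principal square root gives
    ``Im k < 0``, so the outgoing Green's function decays with distance.
    """
    f = np.asarray(frequency_hz, dtype=float)
    return 2.0 * np.pi * f * np.sqrt(scene.background_permittivity(f)) / C0


def _green2d(k_per_m, r_m):
    """Outgoing 2D Green's function ``-j/4 H0^(2)(k r)`` (e^{+jwt} convention)."""
    return -0.25j * hankel2(0, np.asarray(k_per_m) * np.asarray(r_m))


def _inclusion_cells(scene: PhantomScene, cell_mm: float) -> tuple[np.ndarray, float]:
    """Sub-millimeter quadrature lattice covering the inclusion disk."""
    if cell_mm > scene.inclusion_radius_mm / 4.0:
        raise ComputationError(
            f"quadrature cell {cell_mm} mm exceeds inclusion_radius/4 "
            f"({scene.inclusion_radius_mm / 4.0:g} mm)"
        )
    r = scene.inclusion_radius_mm
    half = int(np.floor(r / cell_mm))
    ax = (np.arange(-half, half + 1)) * cell_mm
    xx, yy = np.meshgrid(ax, ax)
    keep = xx**2 + yy**2 <= r**2
    cx, cy = scene.inclusion_center_mm
    cells = np.column_stack([xx[keep] + cx, yy[keep] + cy])
    return cells, (cell_mm * 1e-3) ** 2


def born_transmission(
    scene: PhantomScene,
    tx_xy_mm: Sequence[float],
    rx_xy_mm: Sequence[float],
    frequency_hz: float,
    cell_mm: float = 0.25,
) -> complex:
    """First-order Born scattering contribution of the inclusion.

    Returns ``k^2 dchi sum_cells G(tx, r) G(r, rx) dA`` for a single
    transmit/receive pair at one frequency (line sources, 2D).  The
    contribution is exactly linear in the contrast, vanishes at zero contrast,
    and inherits the mirror symmetries of the geometry.
    """
    tx = np.asarray(tx_xy_mm, dtype=float)
    rx = np.asarray(rx_xy_mm, dtype=float)
    if np.allclose(tx, rx):
        raise ComputationError("transmit and receive points must differ")
    cells, da_m2 = _inclusion_cells(scene, cell_mm)
    k = background_wavenumber(scene, frequency_hz)
    d_tx = np.hypot(cells[:, 0] - tx[0], cells[:, 1] - tx[1]) * 1e-3
    d_rx = np.hypot(cells[:, 0] - rx[0], cells[:, 1] - rx[1]) * 1e-3
    chi = scene.contrast(frequency_hz)
    integral = np.sum(_green2d(k, d_tx) * _green2d(k, d_rx)) * da_m2
    return complex(k**2 * chi * integral)


#: Unordered transmission channels of the four-port system.
TRANSMISSION_CHANNELS: tuple[tuple[int, int], ...] = (
    (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3),
)


class _BornKernel:
    """Precomputed geometry factor ``k^2 sum G G dA`` per frequency/channel.

    The kernel depends only on the geometry and the background medium, so a
    cooling series (46 scenes differing only in inclusion temperature) reuses
    it; the scattered S-parameters are ``dchi(f, T) * kernel``.
    """

    def __init__(
        self,
        scene: PhantomScene,
        array: AntennaArray,
        acq: AcquisitionSpec,
        cell_mm: float = 0.25,
    ) -> None:
        freqs = acq.frequencies_hz
        cells, da_m2 = _inclusion_cells(scene, cell_mm)
        k = background_wavenumber(scene, freqs)  # (n_f,)
        n_ant = array.n_antennas
        # Radiating points per frequency; constant when the phase-center
        # polynomial is zero, in which case Green's functions are computed once
        # per antenna with frequency broadcast.
        pos0 = array.positions(freqs[0])
        frequency_dependent = bool(np.any(array.phase_center_poly[1:] != 0))
        g = np.empty((len(freqs), n_ant, len(cells)), dtype=complex)
        if not frequency_dependent:
            d = np.hypot(
                cells[None, :, 0] - pos0[:, None, 0],
                cells[None, :, 1] - pos0[:, None, 1],
            ) * 1e-3  # (n_ant, n_cells)
            g[:] = _green2d(k[:, None, None], d[None, :, :])
        else:
            for fi, f in enumerate(freqs):
                pos = array.positions(f)
                d = np.hypot(
                    cells[None, :, 0] - pos[:, None, 0],
                    cells[None, :, 1] - pos[:, None, 1],
                ) * 1e-3
                g[fi] = _green2d(k[fi], d)
        self.frequencies_hz = freqs
        self.kernel = np.empty((len(freqs), len(TRANSMISSION_CHANNELS)), complex)
        for ci, (ti, rj) in enumerate(TRANSMISSION_CHANNELS):
            self.kernel[:, ci] = k**2 * np.sum(g[:, ti, :] * g[:, rj, :], axis=1) * da_m2

    def scattered(self, scene: PhantomScene) -> np.ndarray:
        """(n_f, n_channels) scattered transmission for one inclusion state."""
        chi = scene.contrast(self.frequencies_hz)
        return chi[:, None] * self.kernel


def _baseline(
    scene: PhantomScene,
    array: AntennaArray,
    freqs: np.ndarray,
    coupling_scale: float,
) -> np.ndarray:
    """Smooth target-free coupling model, (n_f, 4, 4), reciprocal.

    Off-diagonal entries follow a line-source channel through the lossy
    background (propagation phase and attenuation over the inter-antenna
    path); diagonal entries are a smooth reflection placeholder, unused by the
    imaging chain.
    """
    k = background_wavenumber(scene, freqs)
    pos = array.positions(freqs[len(freqs) // 2])
    n = array.n_antennas
    s = np.zeros((len(freqs), n, n), dtype=complex)
    for i in range(n):
        for j in range(n):
            if i == j:
                # reflection placeholder: gentle ripple, flagged unused
                s[:, i, i] = 0.2 * np.exp(-1j * 2.0 * np.pi * freqs / 2.5e9)
            else:
                d = np.hypot(*(pos[i] - pos[j])) * 1e-3
                s[:, i, j] = coupling_scale * _green2d(k, d)
    return s


def simulate_sparams(
    scene: PhantomScene,
    array: AntennaArray,
    acq: AcquisitionSpec,
    rng: np.random.Generator | None = None,
    coupling_scale: float = 0.1,
    cell_mm: float = 0.25,
    kernel: _BornKernel | None = None,
    timestamp_s: float | None = None,
) -> SParameterSet:
    """Synthesize one 4-port acquisition of the scene.

    Total S = baseline coupling + Born scattering (off-diagonals, reciprocal
    by construction) + complex Gaussian noise at ``acq.noise_floor_db``
    (omitted when the floor is ``None``).  Above ``acq.highband_cutoff_hz``
    the transmission entries are replaced by sub--80 dB values with
    randomized phase; that replacement is seeded by ``acq.seed`` alone, so it
    is identical across acquisitions sharing an ``AcquisitionSpec`` and
    cancels in differential processing, as the measured high band effectively
    does.
    """
    freqs = acq.frequencies_hz
    if kernel is None:
        kernel = _BornKernel(scene, array, acq, cell_mm=cell_mm)
    s = _baseline(scene, array, freqs, coupling_scale)
    scat = kernel.scattered(scene)  # (n_f, n_ch)
    for ci, (i, j) in enumerate(TRANSMISSION_CHANNELS):
        s[:, i, j] += scat[:, ci]
        s[:, j, i] += scat[:, ci]

    high = freqs > acq.highband_cutoff_hz
    if np.any(high):
        rng_high = np.random.default_rng(acq.seed)
        for i, j in TRANSMISSION_CHANNELS:
            amp_db = -85.0 + 4.0 * rng_high.random(high.sum())
            phase = rng_high.uniform(0.0, 2.0 * np.pi, high.sum())
            val = 10.0 ** (amp_db / 20.0) * np.exp(1j * phase)
            s[high, i, j] = val
            s[high, j, i] = val

    if acq.noise_floor_db is not None:
        if rng is None:
            rng = np.random.default_rng(acq.seed)
        std = 10.0 ** (acq.noise_floor_db / 20.0)
        noise = (
            rng.standard_normal(s.shape) + 1j * rng.standard_normal(s.shape)
        ) * (std / np.sqrt(2.0))
        s = s + noise

    return SParameterSet(
        frequencies_hz=freqs,
        matrices=s,
        temperature_c=scene.inclusion_temperature_c,
        timestamp_s=timestamp_s,
    )


@dataclass
class CoolingSeries:
    """The 46-acquisition cooling experiment: 40.5 C down to 36.0 C."""

    temperatures_c: np.ndarray
    acquisition_times_s: np.ndarray
    s_sets: list[SParameterSet]

    @property
    def background(self) -> SParameterSet:
        """Reference ('healthy') acquisition: the hottest inclusion state."""
        return self.s_sets[0]

    @property
    def delta_t_c(self) -> np.ndarray:
        """Temperature drop of each acquisition relative to the reference."""
        return np.round(self.temperatures_c[0] - self.temperatures_c, 6)


def cooling_series(
    scene_template: PhantomScene,
    array: AntennaArray,
    acq: AcquisitionSpec,
    t_start_c: float = 40.5,
    t_stop_c: float = 36.0,
    t_step_c: float = 0.1,
    timing_noise: bool = True,
    coupling_scale: float = 0.1,
    cell_mm: float = 0.25,
) -> CoolingSeries:
    """Simulate the full cooling protocol.

    One acquisition per 0.1 C step (46 for the default range).  Acquisition
    timestamps follow the two-phase timing model; all randomness (timing,
    per-acquisition noise) derives from ``acq.seed`` through independent
    spawned streams, so a series is bit-reproducible.
    """
    n = int(round((t_start_c - t_stop_c) / t_step_c)) + 1
    temps = np.round(t_start_c - t_step_c * np.arange(n), 6)

    ss = np.random.SeedSequence(acq.seed)
    children = ss.spawn(n + 1)
    timing_rng = np.random.default_rng(children[0])
    intervals = np.empty(n - 1)
    for i in range(n - 1):
        mean, sd = TIMING_FIRST if i < N_FIRST_INTERVALS else TIMING_SECOND
        intervals[i] = mean + (sd * timing_rng.standard_normal() if timing_noise else 0.0)
    intervals = np.clip(intervals, 0.5, None)
    times = np.concatenate([[0.0], np.cumsum(intervals)])

    kernel = _BornKernel(scene_template, array, acq, cell_mm=cell_mm)
    sets = []
    for i, t in enumerate(temps):
        scene = dataclasses.replace(scene_template, inclusion_temperature_c=float(t))
        rng = np.random.default_rng(children[i + 1])
        sets.append(
            simulate_sparams(
                scene,
                array,
                acq,
                rng=rng,
                coupling_scale=coupling_scale,
                cell_mm=cell_mm,
                kernel=kernel,
                timestamp_s=float(times[i]),
            )
        )
    return CoolingSeries(
        temperatures_c=temps, acquisition_times_s=times, s_sets=sets
    )
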