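"""Temperature- and frequency-dependent dielectric properties of water.

Deionized water is the working liquid of the phantom: its complex relative
permittivity follows a single-pole Debye relaxation,

    eps(f, T) = eps_inf(T) + (eps_s(T) - eps_inf(T)) / (1 + j 2 pi f tau(T)),

with the convention ``eps = eps' - j eps''`` (``eps'' >= 0``), so that the
effective conductivity ``sigma = 2 pi f eps0 eps''`` is non-negative.  The
static permittivity ``eps_s``, high-frequency permittivity ``eps_inf`` and
relaxation time ``tau`` all decrease smoothly with temperature, which is what
turns a temperature step of the inclusion into a small, repeatable dielectric
contrast.

Two published pure-water parameterizations are bundled (``WATER_DEBYE``):
Stogryn's 1971 zero-salinity polynomial fits (the default) and Kaatze's 1989
log-linear/Arrhenius fits.  Printed two-significant-figure sensitivity tables
are reproduced by either to within a few percent; the residual spread between
published coefficient sets is the dominant uncertainty.

The per-0.1-degree *relative sensitivities* quantify how finely a temperature
protocol modulates the dielectric state.  For the permittivity the change is
normalized by the permittivity itself at the cold end (26 C).  For the
conductivity the change is normalized by the *relative permittivity* at 26 C,
not by sigma: deionized-water conductivity approaches zero at the low band
edge, so self-normalization diverges there, whereas referencing eps_r yields a
finite, frequency-comparable figure (and matches the convention of the
published sensitivity tables this module reproduces).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.constants import epsilon_0

from dmwi.errors import ComputationError

__all__ = [
    "DebyeParameterization",
    "DielectricSample",
    "SensitivityTable",
    "WATER_DEBYE",
    "debye_permittivity",
    "conductivity_from_permittivity",
    "dielectric_sample",
    "linearity_r2",
    "relative_sensitivity",
    "sensitivity_table",
]

#: Temperature protocol of the probe characterization: cooling from 36.5 C to
#: 26.0 C in 0.1 C steps, i.e. 105 increments.
PROTOCOL_T_LOW_C = 26.0
PROTOCOL_T_HIGH_C = 36.5
PROTOCOL_N_STEPS = 105


@dataclass(frozen=True)
class DebyeParameterization:
    """Temperature-dependent parameters of a single-Debye liquid.

    Attributes
    ----------
    static_permittivity_fn, inf_permittivity_fn :
        Map temperature in Celsius to the dimensionless static and
        high-frequency relative permittivity.
    relaxation_time_fn :
        Map temperature in Celsius to the relaxation time in seconds.
    valid_temperature_range :
        Inclusive (low, high) Celsius range over which the fits are trusted.
    label :
        Identifies the literature source of the coefficient set.
    """

    static_permittivity_fn: Callable[[float], float]
    inf_permittivity_fn: Callable[[float], float]
    relaxation_time_fn: Callable[[float], float]
    valid_temperature_range: tuple[float, float] = (0.0, 60.0)
    label: str = "unlabelled"

    def check_temperature(self, temperature_c: float | np.ndarray) -> None:
        lo, hi = self.valid_temperature_range
        t = np.asarray(temperature_c, dtype=float)
        if np.any(t < lo) or np.any(t > hi):
            raise ComputationError(
                f"temperature {temperature_c} C outside validity range "
                f"[{lo}, {hi}] C of parameterization {self.label!r}"
            )


def _stogryn_two_pi_tau(t: np.ndarray) -> np.ndarray:
    return 1.1109e-10 - 3.824e-12 * t + 6.938e-14 * t**2 - 5.096e-16 * t**3


#: Registry of bundled pure-water parameterizations.
WATER_DEBYE: dict[str, DebyeParameterization] = {
    "stogryn1971": DebyeParameterization(
        static_permittivity_fn=lambda t: 87.74
        - 0.40008 * t
        + 9.398e-4 * t**2
        + 1.410e-6 * t**3,
        inf_permittivity_fn=lambda t: 4.9 + 0.0 * np.asarray(t, dtype=float),
        relaxation_time_fn=lambda t: _stogryn_two_pi_tau(np.asarray(t, dtype=float))
        / (2.0 * np.pi),
        valid_temperature_range=(0.0, 60.0),
        label="stogryn1971",
    ),
    "kaatze1989": DebyeParameterization(
        static_permittivity_fn=lambda t: 10.0 ** (1.94404 - 1.991e-3 * t),
        inf_permittivity_fn=lambda t: 5.77 - 2.74e-2 * t,
        relaxation_time_fn=lambda t: 3.745e-15
        * np.exp(2.2957e3 / (np.asarray(t, dtype=float) + 273.15)),
        valid_temperature_range=(0.0, 60.0),
        label="kaatze1989",
    ),
}

DEFAULT_WATER = WATER_DEBYE["stogryn1971"]


@dataclass(frozen=True)
class DielectricSample:
    """Complex permittivity of a medium at one frequency and temperature."""

    frequency_hz: float
    temperature_c: float
    complex_permittivity: complex
    relative_permittivity: float = field(init=False)
    conductivity_s_per_m: float = field(init=False)

    def __post_init__(self) -> None:
        eps = complex(self.complex_permittivity)
        object.__setattr__(self, "relative_permittivity", eps.real)
        object.__setattr__(
            self,
            "conductivity_s_per_m",
            conductivity_from_permittivity(self.frequency_hz, -eps.imag),
        )


def debye_permittivity(
    frequency_hz: float | np.ndarray,
    temperature_c: float | np.ndarray,
    params: DebyeParameterization = DEFAULT_WATER,
) -> complex | np.ndarray:
    """Complex relative permittivity ``eps' - j eps''`` of a Debye liquid.

    Broadcasts over frequency and temperature.  Raises
    :class:`~dmwi.errors.ComputationError` if the temperature falls outside the
    validity range of ``params`` or the frequency is negative.
    """
    f = np.asarray(frequency_hz, dtype=float)
    if np.any(f < 0):
        raise ComputationError("frequency must be non-negative")
    params.check_temperature(temperature_c)
    t = np.asarray(temperature_c, dtype=float)
    eps_s = params.static_permittivity_fn(t)
    eps_inf = params.inf_permittivity_fn(t)
    tau = params.relaxation_time_fn(t)
    eps = eps_inf + (eps_s - eps_inf) / (1.0 + 1j * 2.0 * np.pi * f * tau)
    if eps.ndim == 0:
        return complex(eps)
    return eps


def conductivity_from_permittivity(
    frequency_hz: float | np.ndarray, eps_imag: float | np.ndarray
) -> float | np.ndarray:
    """Effective conductivity ``sigma = 2 pi f eps0 eps''`` in S/m.

    ``eps_imag`` is the magnitude of the imaginary part (``eps'' >= 0`` under
    the ``eps' - j eps''`` convention).  A negative result indicates a
    sign-convention misuse upstream and raises.
    """
    f = np.asarray(frequency_hz, dtype=float)
    if np.any(f < 0):
        raise ComputationError("frequency must be non-negative")
    sigma = 2.0 * np.pi * f * epsilon_0 * np.asarray(eps_imag, dtype=float)
    if np.any(np.asarray(sigma) < 0):
        raise ComputationError(
            "negative conductivity: eps'' must be passed as a non-negative "
            "magnitude (eps = eps' - j eps'' convention)"
        )
    if sigma.ndim == 0:
        return float(sigma)
    return sigma


def dielectric_sample(
    frequency_hz: float,
    temperature_c: float,
    params: DebyeParameterization = DEFAULT_WATER,
) -> DielectricSample:
    """Evaluate ``params`` into a :class:`DielectricSample`."""
    return DielectricSample(
        frequency_hz=frequency_hz,
        temperature_c=temperature_c,
        complex_permittivity=debye_permittivity(frequency_hz, temperature_c, params),
    )


def linearity_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Coefficient of determination of an ordinary least-squares line.

    ``R^2 = 1 - SS_res / SS_tot`` for the best-fit line of ``y`` on ``x``.
    Requires at least three points, non-constant ``x``, and non-constant ``y``
    (a flat ``y`` makes ``SS_tot = 0`` and the statistic undefined).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ComputationError("x and y must be 1-D sequences of equal length")
    if xa.size < 3:
        raise ComputationError("linearity_r2 requires at least 3 points")
    if np.ptp(xa) == 0:
        raise ComputationError("x values are all identical; no line can be fit")
    ss_tot = float(np.sum((ya - ya.mean()) ** 2))
    if ss_tot == 0.0:
        raise ComputationError(
            "y values are all identical (SS_tot = 0); R^2 is undefined"
        )
    slope, intercept = np.polyfit(xa, ya, 1)
    resid = ya - (slope * xa + intercept)
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def relative_sensitivity(
    value_low_t: float,
    value_high_t: float,
    n_steps: int,
    reference: float | None = None,
) -> float:
    """Per-step relative change of a property over a temperature protocol.

    Returns ``(value(T_low) - value(T_high)) / (n_steps * reference)`` in
    percent, where ``reference`` defaults to the low-temperature value.  The
    low-temperature (cold-end) value is the stable normalization choice because
    the dielectric properties of water decrease with temperature.
    """
    if n_steps < 1:
        raise ComputationError("n_steps must be >= 1")
    ref = value_low_t if reference is None else reference
    if ref == 0:
        raise ComputationError("zero reference value; relative sensitivity undefined")
    return 100.0 * (value_low_t - value_high_t) / (n_steps * ref)


@dataclass(frozen=True)
class SensitivityTable:
    """Per-frequency, per-0.1 C sensitivities of eps_r and sigma (percent)."""

    frequencies_hz: np.ndarray
    eta_eps_pct: np.ndarray
    eta_sigma_pct: np.ndarray
    n_steps: int = PROTOCOL_N_STEPS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_ghz": self.frequencies_hz / 1e9,
                "eta_eps_pct": self.eta_eps_pct,
                "eta_sigma_pct": self.eta_sigma_pct,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def sensitivity_table(
    params: DebyeParameterization = DEFAULT_WATER,
    frequencies_hz: Sequence[float] = (0.5e9, 1.0e9, 1.5e9, 2.0e9, 2.5e9, 3.0e9),
    t_low_c: float = PROTOCOL_T_LOW_C,
    t_high_c: float = PROTOCOL_T_HIGH_C,
    n_steps: int = PROTOCOL_N_STEPS,
) -> SensitivityTable:
    """Per-0.1 C sensitivity of eps_r and sigma at the given frequencies.

    The permittivity column normalizes by eps_r at the cold end; the
    conductivity column normalizes the conductivity change by eps_r at the cold
    end as well (see module docstring for why sigma is not self-normalized).
    """
    freqs = np.asarray(frequencies_hz, dtype=float)
    eta_eps = np.empty_like(freqs)
    eta_sigma = np.empty_like(freqs)
    for i, f in enumerate(freqs):
        cold = dielectric_sample(f, t_low_c, params)
        hot = dielectric_sample(f, t_high_c, params)
        eta_eps[i] = relative_sensitivity(
            cold.relative_permittivity, hot.relative_permittivity, n_steps
        )
        eta_sigma[i] = relative_sensitivity(
            cold.conductivity_s_per_m,
            hot.conductivity_s_per_m,
            n_steps,
            reference=cold.relative_permittivity,
        )
    return SensitivityTable(
        frequencies_hz=freqs,
        eta_eps_pct=eta_eps,
        eta_sigma_pct=eta_sigma,
        n_steps=n_steps,
    )
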