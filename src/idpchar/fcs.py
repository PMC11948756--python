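"""Fluorescence correlation spectroscopy: model fitting and calibration.

A one-component 3D-diffusion autocorrelation with a triplet term is used,

    G(τ) = (1/N) (1 + T/(1-T) e^{-τ/τ_T}) (1 + τ/τ_D)^{-1} (1 + τ/(s² τ_D))^{-1/2},

where N is the mean particle number in the confocal volume, T the triplet
fraction, τ_T the triplet lifetime, τ_D the diffusion time and s the axial/
lateral structure parameter (fixed per slide from a reference-dye
calibration).  Diffusion times are converted to hydrodynamic radii through
the reference dye (D_ref · τ_ref = D · τ at fixed calibration) and the
Stokes-Einstein relation, with first-order error propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .binding import TitrationSeries, QuadraticFit, fit_quadratic_binding
from .constants import BOLTZMANN, CELSIUS_OFFSET, water_viscosity_mpas
from .exceptions import FitError, ValidationError

__all__ = [
    "AutocorrelationCurve", "FcsFit", "CalibrationRef",
    "model_g", "fit_curve", "viscosity_correct", "viscosity_ratio_from_dye",
    "diffusion_from_tau", "rh_from_tau", "fit_fcs_titration",
]


@dataclass
class AutocorrelationCurve:
    """Measured (or synthetic) autocorrelation: lag times in µs."""

    lag_times: np.ndarray
    g_values: np.ndarray
    temperature: float = 23.0

    def __post_init__(self):
        self.lag_times = np.asarray(self.lag_times, dtype=float)
        self.g_values = np.asarray(self.g_values, dtype=float)
        if np.any(self.lag_times <= 0):
            raise ValidationError("lag times must be positive")
        if np.any(np.diff(self.lag_times) <= 0):
            raise ValidationError("lag times must be strictly increasing")
        if self.lag_times.size != self.g_values.size:
            raise ValidationError("lag/G length mismatch")


@dataclass
class FcsFit:
    n_particles: float
    triplet_fraction: float
    triplet_time: float  # µs
    tau_d: float  # µs
    structure_parameter: float
    tau_d_sd: float = float("nan")

    def __post_init__(self):
        if not (0 <= self.triplet_fraction < 1):
            raise ValidationError("triplet fraction must be in [0, 1)")
        if self.structure_parameter <= 1:
            raise ValidationError("structure parameter must exceed 1")
        if self.tau_d <= 0 or self.n_particles <= 0:
            raise ValidationError("tau_D and N must be positive")
        if self.triplet_time < 0 or self.triplet_time >= self.tau_d:
            raise ValidationError("triplet time must be in [0, tau_D)")


@dataclass
class CalibrationRef:
    """Reference-dye calibration of the confocal volume.

    ``d_ref`` µm²/s (AF 488 in water: 435), ``tau_ref`` µs measured on the
    same slide, droplet temperature in °C, and the solution/water viscosity
    ratio.
    """

    d_ref: float = 435.0
    tau_ref: float | None = None
    temperature: float = 23.0
    viscosity_ratio: float = 1.0

    def __post_init__(self):
        if self.d_ref <= 0 or self.viscosity_ratio <= 0:
            raise ValidationError("calibration values must be positive")
        if self.tau_ref is not None and self.tau_ref <= 0:
            raise ValidationError("tau_ref must be positive")


def model_g(tau, fit: FcsFit):
    """Triplet-corrected one-component 3D autocorrelation at lag ``tau`` µs."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValidationError("lag times must be positive")
    t = fit.triplet_fraction
    trip = 1.0 if t == 0 else 1.0 + t / (1.0 - t) * np.exp(-tau / fit.triplet_time)
    diff = (1.0 + tau / fit.tau_d) ** -1 * (1.0 + tau / (fit.structure_parameter ** 2 * fit.tau_d)) ** -0.5
    return trip * diff / fit.n_particles


def fit_curve(curve: AutocorrelationCurve, structure_parameter: float) -> FcsFit:
    """Least squares over (N, T, τ_T, τ_D) with the structure parameter fixed."""
    if curve.lag_times.size < 30:
        raise ValidationError("need at least 30 lag points")
    g = curve.g_values
    if g[-1] > 0.5 * g[0]:
        raise FitError("curve truncated before the diffusion decay; tau_D unidentifiable")
    n0 = 1.0 / max(g[0], 1e-12)
    # crude tau_D guess: lag at half the initial amplitude
    half_idx = int(np.argmin(np.abs(g - g[0] / 2)))
    tau_d0 = float(curve.lag_times[half_idx])

    def model(tau, n, t, tau_t, tau_d):
        trip = 1.0 + t / (1.0 - t) * np.exp(-tau / tau_t)
        diff = (1.0 + tau / tau_d) ** -1 * (1.0 + tau / (structure_parameter ** 2 * tau_d)) ** -0.5
        return trip * diff / n

    try:
        popt, pcov = optimize.curve_fit(
            model, curve.lag_times, g,
            p0=[n0, 0.05, min(2.0, tau_d0 / 10), tau_d0],
            bounds=([1e-9, 0.0, 1e-3, 1e-2], [np.inf, 0.9999, 1e3, 1e7]),
            maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"FCS fit did not converge: {exc}") from exc
    tau_d_sd = float(np.sqrt(max(pcov[3, 3], 0.0)))
    return FcsFit(n_particles=float(popt[0]), triplet_fraction=float(popt[1]),
                  triplet_time=float(popt[2]), tau_d=float(popt[3]),
                  structure_parameter=structure_parameter, tau_d_sd=tau_d_sd)


def viscosity_correct(tau_app, viscosity_ratio):
    """Remove the linear viscosity scaling from an apparent diffusion time."""
    if viscosity_ratio <= 0:
        raise ValidationError("viscosity ratio must be positive")
    return np.asarray(tau_app, dtype=float) / viscosity_ratio


def viscosity_ratio_from_dye(tau_solution, tau_water):
    """Solution/water viscosity ratio from reference-dye diffusion times."""
    if tau_solution <= 0 or tau_water <= 0:
        raise ValidationError("diffusion times must be positive")
    return tau_solution / tau_water


def diffusion_from_tau(tau, cal: CalibrationRef):
    """Diffusion coefficient (µm²/s) via the reference dye: D = D_ref τ_ref / τ."""
    if cal.tau_ref is None:
        raise ValidationError("tau_ref missing from calibration; it cannot be inferred")
    return cal.d_ref * cal.tau_ref / np.asarray(tau, dtype=float)


def _rh_angstrom(tau, tau_ref, d_ref, temperature_c, viscosity_ratio):
    d = d_ref * tau_ref / tau  # µm²/s
    eta = water_viscosity_mpas(temperature_c) * viscosity_ratio  # mPa*s
    t_abs = temperature_c + CELSIUS_OFFSET
    # Stokes-Einstein in SI, reported in Å
    r_m = BOLTZMANN * t_abs / (6 * np.pi * eta * 1e-3 * d * 1e-12)
    return r_m * 1e10


def rh_from_tau(tau, cal: CalibrationRef, tau_sd=0.0, tau_ref_sd=0.0,
                d_ref_sd=0.0, temperature_sd=0.0):
    """Hydrodynamic radius (Å) with first-order uncertainty propagation.

    Propagates relative errors of τ, τ_ref, D_ref and the absolute droplet
    temperature uncertainty through the Stokes-Einstein conversion
    (numerical derivative for the temperature channel, which enters both
    T_abs and the water viscosity).
    """
    if cal.tau_ref is None:
        raise ValidationError("tau_ref missing from calibration; it cannot be inferred")
    tau = float(tau)
    rh = _rh_angstrom(tau, cal.tau_ref, cal.d_ref, cal.temperature, cal.viscosity_ratio)
    rel_var = 0.0
    for val, sd in ((tau, tau_sd), (cal.tau_ref, tau_ref_sd), (cal.d_ref, d_ref_sd)):
        if sd:
            rel_var += (sd / val) ** 2
    if temperature_sd:
        dt = 0.05
        up = _rh_angstrom(tau, cal.tau_ref, cal.d_ref, cal.temperature + dt, cal.viscosity_ratio)
        dn = _rh_angstrom(tau, cal.tau_ref, cal.d_ref, cal.temperature - dt, cal.viscosity_ratio)
        rel_var += (((up - dn) / (2 * dt)) * temperature_sd / rh) ** 2
    return rh, rh * np.sqrt(rel_var)


def fit_fcs_titration(series: TitrationSeries, **kwargs) -> QuadraticFit:
    """Depletion-model fit of a viscosity-corrected τ_app titration."""
    if series.signal_kind != "tau_app":
        raise ValidationError("fit_fcs_titration expects signal_kind='tau_app'")
    return fit_quadratic_binding(series, **kwargs)
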