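"""Thermal-stability analysis: dye thermal shift and CD melts.

Dye (SYPRO-type) melts are first corrected for the exponential temperature
quenching of the free dye, fitted on a protein-free control; the melting
temperature is then the maximum of |dF/dT| of the corrected curve
(Savitzky-Golay smoothed derivative).  CD melts at 220 nm are converted to
mean-residue ellipticity and fitted with a Boltzmann sigmoid

    y(T) = bottom + (top - bottom) / (1 + exp((Tm - T)/width)).

A reversibility index compares the signal recovered after cooling with the
initial native signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, signal as sig

from .exceptions import FitError, ValidationError

__all__ = [
    "MeltCurve", "MeltResult", "DecayModel",
    "fit_probe_decay", "correct_fluorescence", "tm_derivative",
    "mre_convert", "fit_boltzmann", "boltzmann", "reversibility",
]


@dataclass
class MeltCurve:
    """Temperature-indexed signal trace (°C grid, >= 10 points)."""

    temperatures: np.ndarray
    signal: np.ndarray
    direction: str = "heating"  # heating | cooling
    channel: str = "dye"  # dye | cd220

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperatures.size < 10:
            raise ValidationError("melt grid shorter than 10 points; "
                                  "derivative analysis undefined")
        if self.temperatures.size != self.signal.size:
            raise ValidationError("temperature/signal length mismatch")
        diffs = np.diff(self.temperatures)
        if self.direction == "heating" and np.any(diffs <= 0):
            raise ValidationError("heating grid must be strictly increasing")
        if self.direction == "cooling" and np.any(diffs >= 0):
            raise ValidationError("cooling grid must be strictly decreasing")


@dataclass
class MeltResult:
    tm: float  # °C
    method: str  # derivative | boltzmann
    amplitude: float = float("nan")
    baseline_low: float = float("nan")
    baseline_high: float = float("nan")
    width: float = float("nan")
    tm_ci95: tuple[float, float] | None = None
    boundary_flag: bool = False
    reversibility_index: float | None = None


@dataclass
class DecayModel:
    """Exponential probe-quenching envelope F(T) = F0 exp(-k (T - T_ref))."""

    f0: float
    k_per_c: float
    t_ref: float
    no_decay_warning: bool = False

    def envelope(self, temperatures) -> np.ndarray:
        return self.f0 * np.exp(-self.k_per_c * (np.asarray(temperatures, float) - self.t_ref))

    def normalized_envelope(self, temperatures) -> np.ndarray:
        """Envelope scaled to 1 at the lowest temperature supplied."""
        env = self.envelope(temperatures)
        return env / env[int(np.argmin(np.asarray(temperatures)))]


def fit_probe_decay(control: MeltCurve) -> DecayModel:
    """Fit the dye-only quenching envelope; k is constrained >= 0."""
    if control.channel != "dye":
        raise ValidationError("probe-decay control must be a dye channel")
    t = control.temperatures
    y = control.signal
    if np.any(y <= 0):
        raise ValidationError("control fluorescence must be positive")
    t_ref = float(t.min())
    slope = np.polyfit(t - t_ref, np.log(y), 1)[0]
    warn = slope > 0
    k0 = max(-slope, 1e-6)

    def model(tt, f0, k):
        return f0 * np.exp(-k * (tt - t_ref))

    popt, _ = optimize.curve_fit(model, t, y, p0=[float(y[0]), k0],
                                 bounds=([1e-12, 0.0], [np.inf, 10.0]), maxfev=10000)
    return DecayModel(f0=float(popt[0]), k_per_c=float(popt[1]), t_ref=t_ref,
                      no_decay_warning=bool(warn))


def correct_fluorescence(curve: MeltCurve, decay: DecayModel) -> MeltCurve:
    """Divide out the normalized quenching envelope (anchored at low T)."""
    env = decay.normalized_envelope(curve.temperatures)
    if np.any(env <= 0):
        raise ValidationError("decay envelope non-positive over the curve span")
    return replace(curve, signal=curve.signal / env)


def _smooth_derivative(t, y, window, polyorder=2):
    window = min(window, y.size if y.size % 2 else y.size - 1)
    if window < polyorder + 2:
        raise ValidationError("melt curve too short for the smoothing window")
    if window % 2 == 0:
        window -= 1
    dt = float(np.mean(np.diff(t)))
    return sig.savgol_filter(y, window, polyorder, deriv=1, delta=dt)


def tm_derivative(curve: MeltCurve, window: int = 11) -> MeltResult:
    """Tm as the maximum |dF/dT| of a (corrected) melt curve.

    A maximum on the first or last grid point flags the absence of a
    transition inside the scanned span.
    """
    t, y = curve.temperatures, curve.signal
    deriv = _smooth_derivative(t, y, window)
    idx = int(np.argmax(np.abs(deriv)))
    boundary = idx in (0, t.size - 1)
    return MeltResult(tm=float(t[idx]), method="derivative",
                      amplitude=float(np.ptp(y)), boundary_flag=boundary)


def mre_convert(theta_mdeg, conc_mg_ml: float, path_cm: float, mrw_da: float):
    """Molar residue ellipticity, deg·cm²·dmol⁻¹: θ·MRW / (10·l·c)."""
    if conc_mg_ml <= 0 or path_cm <= 0 or mrw_da <= 0:
        raise ValidationError("concentration, path length and MRW must be positive")
    return np.asarray(theta_mdeg, dtype=float) * mrw_da / (10.0 * path_cm * conc_mg_ml)


def boltzmann(t, bottom, top, tm, width):
    """Two-state Boltzmann sigmoid in temperature."""
    return bottom + (top - bottom) / (1.0 + np.exp((tm - np.asarray(t, float)) / width))


def fit_boltzmann(curve: MeltCurve) -> MeltResult:
    """Least-squares Boltzmann fit of an ellipticity (or corrected) melt."""
    t, y = curve.temperatures, curve.signal
    if np.ptp(y) == 0:
        raise FitError("flat melt curve; no transition to fit")
    bottom0, top0 = float(y[0]), float(y[-1])
    half = (bottom0 + top0) / 2
    tm0 = float(t[int(np.argmin(np.abs(y - half)))])
    try:
        popt, pcov = optimize.curve_fit(
            boltzmann, t, y, p0=[bottom0, top0, tm0, 2.0],
            bounds=([-np.inf, -np.inf, t.min(), 1e-3], [np.inf, np.inf, t.max(), 100.0]),
            maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
    tm_sd = float(np.sqrt(max(pcov[2, 2], 0.0)))
    return MeltResult(tm=float(popt[2]), method="boltzmann",
                      amplitude=float(popt[1] - popt[0]),
                      baseline_low=float(popt[0]), baseline_high=float(popt[1]),
                      width=float(popt[3]),
                      tm_ci95=(float(popt[2]) - 1.96 * tm_sd, float(popt[2]) + 1.96 * tm_sd),
                      boundary_flag=bool(np.isclose(popt[2], t.min()) or np.isclose(popt[2], t.max())))


def reversibility(heating: MeltCurve, cooling: MeltCurve) -> float:
    """Fraction of the native signal recovered after a heat/cool cycle.

    recovery = (S_cool(T_low) - S_denatured) / (S_heat(T_low) - S_denatured),
    where S_denatured is the heating signal at the highest shared
    temperature.  ~1 for a fully reversible transition, ~0 for an
    irreversible one.
    """
    lo = max(heating.temperatures.min(), cooling.temperatures.min())
    hi = min(heating.temperatures.max(), cooling.temperatures.max())
    if lo >= hi:
        raise ValidationError("heating and cooling spans do not overlap")
    heat_lo = float(np.interp(lo, heating.temperatures, heating.signal))
    denat = float(np.interp(hi, heating.temperatures, heating.signal))
    ct = cooling.temperatures
    cs = cooling.signal
    if ct[0] > ct[-1]:
        ct, cs = ct[::-1], cs[::-1]
    cool_lo = float(np.interp(lo, ct, cs))
    if heat_lo == denat:
        raise ValidationError("no transition amplitude; reversibility undefined")
    return (cool_lo - denat) / (heat_lo - denat)
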