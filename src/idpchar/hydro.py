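"""SV-AUC post-analysis and hydrodynamic-radius inference.

Consumes species-level results (mass, partial specific volume, sedimentation
coefficient ranges) rather than raw boundary scans.  The frictional ratio
f/f0 relates the hydrodynamic radius to the anhydrous sphere of equal mass
and partial specific volume,

    R0 = (3 M vbar / (4 π N_A))^{1/3},     R_h = (f/f0) · R0,

and the Svedberg relation s = M (1 - vbar ρ) / (N_A · 6 π η R_h) links the
sedimentation coefficient to mass and shape.  ``refine_ff0`` reproduces the
iterative grid procedure used after a continuous c(f/f0) distribution
analysis: on each successively narrower f/f0 ladder, keep the rung whose
implied molecular weight at the peak-center s is closest to the known mass.
Also provides SEC calibration (K_av vs log R_h) and empirical R_h(N)
power-law scaling for folded, disordered and denatured chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import AVOGADRO
from .exceptions import ValidationError

__all__ = [
    "SolventModel", "HydroSpecies", "Ff0Grid", "SCALING_LAWS",
    "anhydrous_radius", "rh_from_ff0", "weighted_vbar", "s_from_species",
    "mw_from_s", "refine_ff0", "scaling_rh", "SecCalibration", "sec_calibrate",
    "DEFAULT_FF0_SCHEDULE",
]

log = logging.getLogger(__name__)

#: Published hydrodynamic scaling laws R_h = R0 * N^nu (Å, N residues).
SCALING_LAWS = {
    "folded": (4.75, 0.29),
    "idp": (2.49, 0.509),
    "denatured": (2.21, 0.57),
}


@dataclass
class SolventModel:
    """Solution density (g/ml), viscosity (mPa*s) and temperature (°C)."""

    density: float = 1.005
    viscosity: float = 1.0213
    temperature: float = 20.0

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ValidationError("density and viscosity must be positive")
        if self.viscosity < 0.05:
            # guard against the mPa*s / (Pa*s * 1e-2) mislabelling seen in
            # some software exports: 0.010213 "mPa*s" is water-like 1.0213
            log.warning("viscosity %.6g mPa*s is unphysically low; "
                        "interpreting as %.4f mPa*s", self.viscosity,
                        self.viscosity * 100)
            self.viscosity *= 100


@dataclass
class HydroSpecies:
    """A sedimenting entity: mass (kDa), vbar (ml/g), shape and size."""

    m_kda: float
    vbar: float
    ff0: float | None = None
    ff0_sd: float = 0.0
    rh: float | None = None  # Å
    rh_sd: float = 0.0
    s_svedberg: float | None = None

    def __post_init__(self):
        if self.m_kda <= 0 or self.vbar <= 0:
            raise ValidationError("mass and vbar must be positive")
        if self.ff0 is not None and self.ff0 < 1:
            raise ValidationError("frictional ratio must be >= 1")


@dataclass
class Ff0Grid:
    lower: float
    upper: float
    steps: int

    def __post_init__(self):
        if not (self.upper > self.lower >= 1):
            raise ValidationError("need upper > lower >= 1")
        if self.steps < 2:
            raise ValidationError("need at least 2 grid steps")

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.steps)

    @property
    def spacing(self) -> float:
        return (self.upper - self.lower) / (self.steps - 1)


#: Grid ladders used for the three refinement passes (the third is
#: re-centered ±0.09 around the running best value).
DEFAULT_FF0_SCHEDULE = (Ff0Grid(1.0, 3.5, 12), Ff0Grid(1.7, 3.5, 20), 0.09)


def anhydrous_radius(m_kda: float, vbar: float) -> float:
    """Radius (Å) of the anhydrous sphere of mass ``m_kda`` and given vbar."""
    if m_kda <= 0 or vbar <= 0:
        raise ValidationError("mass and vbar must be positive")
    vol_cm3 = m_kda * 1e3 * vbar / AVOGADRO  # per molecule
    return (3.0 * vol_cm3 / (4.0 * np.pi)) ** (1.0 / 3.0) * 1e8


def rh_from_ff0(m_kda: float, vbar: float, ff0: float, ff0_sd: float = 0.0):
    """Hydrodynamic radius R_h = (f/f0) · R0 in Å, with ΔR_h = ΔF/f0 · R0."""
    if ff0 < 1:
        raise ValidationError("frictional ratio must be >= 1")
    r0 = anhydrous_radius(m_kda, vbar)
    return ff0 * r0, ff0_sd * r0


def weighted_vbar(parts) -> float:
    """Mass-weighted partial specific volume of a complex, ml/g."""
    parts = list(parts)
    if not parts:
        raise ValidationError("empty component list")
    ms = np.array([p[0] for p in parts], dtype=float)
    vs = np.array([p[1] for p in parts], dtype=float)
    if np.any(ms <= 0) or np.any(vs <= 0):
        raise ValidationError("masses and vbars must be positive")
    return float(np.sum(ms * vs) / np.sum(ms))


def _buoyancy(vbar, solvent):
    b = 1.0 - vbar * solvent.density
    if b <= 0:
        raise ValidationError("vbar*density >= 1: species does not sediment")
    return b


def s_from_species(species: HydroSpecies, solvent: SolventModel) -> float:
    """Sedimentation coefficient (Svedberg) from mass, vbar and R_h."""
    if species.rh is None:
        raise ValidationError("species R_h required")
    b = _buoyancy(species.vbar, solvent)
    f = 6 * np.pi * solvent.viscosity * 1e-3 * species.rh * 1e-10  # kg/s
    s_seconds = species.m_kda * b / (AVOGADRO * f)  # kg/mol / (1/mol * kg/s)
    return s_seconds / 1e-13


def mw_from_s(s_svedberg: float, ff0: float, vbar: float, solvent: SolventModel) -> float:
    """Closed-form molecular weight (kDa) from s, f/f0 and vbar.

    Inverts the Svedberg relation with R_h = ff0 (3 M vbar / 4 π N_A)^{1/3}.
    """
    if s_svedberg < 0 or ff0 < 1:
        raise ValidationError("need s >= 0 and f/f0 >= 1")
    b = _buoyancy(vbar, solvent)
    s_sec = s_svedberg * 1e-13
    # SI: vbar m3/kg, eta Pa*s; M in kg/mol
    vbar_si = vbar * 1e-3
    eta = solvent.viscosity * 1e-3
    core = s_sec * AVOGADRO * 6 * np.pi * eta * ff0 * (3 * vbar_si / (4 * np.pi * AVOGADRO)) ** (1 / 3) / b
    return max(core, 0.0) ** 1.5


def refine_ff0(peak_s: float, target_m_kda: float, vbar: float,
               solvent: SolventModel, schedule=DEFAULT_FF0_SCHEDULE):
    """Iterative grid refinement of the frictional ratio.

    On each ladder the best rung minimizes |M(peak_s, ff0) - target_M|.
    The final pass spans ±width around the running best in 6 steps.
    Returns (ff0, Δff0, R_h Å, ΔR_h Å); Δ values are the neighbor-rung
    differences of the final grid.
    """
    if not schedule:
        raise ValidationError("empty grid schedule")
    best = None
    spacing = None
    boundary = False
    for item in schedule:
        if isinstance(item, Ff0Grid):
            grid = item
        else:  # re-centered final pass of half-width `item`
            lo = max(1.0, best - float(item))
            grid = Ff0Grid(lo, best + float(item), 6)
        vals = grid.values
        mws = np.array([mw_from_s(peak_s, f, vbar, solvent) for f in vals])
        idx = int(np.argmin(np.abs(mws - target_m_kda)))
        best = float(vals[idx])
        spacing = grid.spacing
        boundary = boundary or idx in (0, len(vals) - 1)
    rh, rh_sd = rh_from_ff0(target_m_kda, vbar, best, spacing)
    if boundary:
        log.warning("target mass at the edge of an f/f0 grid; result may be clipped")
    return best, spacing, rh, rh_sd


def scaling_rh(n_residues: int, chain_class: str, coefficients=None) -> float:
    """Empirical R_h(N) power law for a chain of ``n_residues``."""
    if n_residues < 1:
        raise ValidationError("need at least one residue")
    laws = dict(SCALING_LAWS)
    if coefficients:
        laws.update(coefficients)
    if chain_class not in laws:
        raise ValidationError(f"unknown chain class {chain_class!r}; "
                              f"choose from {sorted(laws)}")
    r0, nu = laws[chain_class]
    return r0 * n_residues ** nu


@dataclass
class SecCalibration:
    """Linear K_av vs log10(R_h) calibration of a size-exclusion column."""

    v0: float
    vt: float
    slope: float
    intercept: float
    residual_sd: float = 0.0
    n_standards: int = 0
    _fit: object = field(default=None, repr=False)

    def kav(self, ve: float) -> float:
        if not (self.v0 <= ve <= self.vt):
            raise ValidationError("elution volume outside column volume")
        return (ve - self.v0) / (self.vt - self.v0)

    def rh(self, ve: float) -> float:
        """Predicted hydrodynamic radius (Å) for elution volume ``ve``."""
        log_rh = (self.kav(ve) - self.intercept) / self.slope
        return 10.0 ** log_rh


def sec_calibrate(standards, v0: float, vt: float) -> SecCalibration:
    """Fit K_av = slope·log10(R_h) + intercept from (V_e, R_h) standards."""
    standards = list(standards)
    if len(standards) < 3:
        raise ValidationError("need at least 3 SEC standards")
    if not vt > v0 > 0:
        raise ValidationError("need V_t > V_0 > 0")
    ve = np.array([s[0] for s in standards], dtype=float)
    rh = np.array([s[1] for s in standards], dtype=float)
    if np.any((ve < v0) | (ve > vt)):
        raise ValidationError("standard elution volume outside column volume")
    kav = (ve - v0) / (vt - v0)
    res = stats.linregress(np.log10(rh), kav)
    pred = res.intercept + res.slope * np.log10(rh)
    rsd = float(np.std(kav - pred, ddof=min(2, len(standards) - 1)))
    return SecCalibration(v0=v0, vt=vt, slope=res.slope, intercept=res.intercept,
                          residual_sd=rsd, n_standards=len(standards), _fit=res)
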