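"""Synthetic-data generators emulating each assay's statistical structure.

Every generator draws additive Gaussian noise whose standard deviation is a
fixed fraction (default 3%) of the signal dynamic range, through a single
seeded entry point, so that identical (truth, design, seed) triples are
bit-reproducible.  Noiseless output equals the corresponding analysis
model exactly, which makes generator→fit round-trips the central pipeline
property.

Default ground-truth values are the study conditions of the TCF4 dimer
characterization: FP titrations of a 40 nM dsDNA probe over 0-1.5 µM dimer
at K_D = 0.12 µM, EMSA free-probe fractions from a modified Hill model at
K_D = 0.327 µM, FCS τ-titrations at K_D = 0.33 µM with a bound-state
diffusion time of 390 µs, dye melts with Tm = 68 °C under a 0.02 /°C
quenching envelope, CD melts with Tm = 66 °C, and HDX exposure series
(10 s ... 2.5 h, quadruplicate) with a bHLH-like segment that is protected
in the DNA-bound state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import TitrationSeries, quadratic_signal, hill_signal
from .constants import DEUTERIUM_MASS_INCREMENT_DA
from .exceptions import ValidationError
from .fcs import AutocorrelationCurve, FcsFit, model_g
from .seqfeat import SequenceRecord, chain_stats
from .thermal import MeltCurve, boltzmann

__all__ = [
    "NoiseSpec", "BindingTruth", "FcsTruth", "HdxTruth", "MeltTruth",
    "SequencePlan", "GroundTruth", "rng_from_seed",
    "gen_titration", "gen_fcs_curve", "gen_hdx_dataset", "gen_melt_curve",
    "gen_sequence", "HDX_EXPOSURES_S",
]

#: The study's HDX labelling times: 10 s, 1 min, 5 min, 30 min, 2.5 h.
HDX_EXPOSURES_S = (10.0, 60.0, 300.0, 1800.0, 9000.0)

_DISORDER_ALPHABET = "EEKKRRDDSSQQPPGGNNTTAH"  # charged/polar enriched
_ORDER_ALPHABET = "IILLVVFFAAMMWYCTG"  # hydrophobic enriched


def rng_from_seed(seed) -> np.random.Generator:
    """The single RNG entry point for every generator."""
    return np.random.default_rng(seed)


@dataclass
class NoiseSpec:
    """Additive Gaussian noise, sigma as a fraction of the dynamic range."""

    sigma: float = 0.03
    seed: int | None = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValidationError("noise sigma must be non-negative")

    def rng(self) -> np.random.Generator:
        return rng_from_seed(self.seed)


@dataclass
class BindingTruth:
    kd_um: float = 0.12
    y0: float = 60.0  # mP
    ymax: float = 230.0  # mP
    hill_kd_um: float = 0.327
    hill_a: float = 1.0
    hill_b: float = 0.0
    hill_n: float = 1.2
    fcs_kd_um: float = 0.33
    tau_free_us: float = 70.0
    tau_bound_us: float = 390.0

    def __post_init__(self):
        for name in ("kd_um", "hill_kd_um", "fcs_kd_um", "tau_free_us", "tau_bound_us"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass
class FcsTruth:
    tau_d_us: float = 390.0
    triplet_fraction: float = 0.15
    triplet_time_us: float = 2.0
    structure_parameter: float = 5.0
    n_particles: float = 1.0

    def as_fit(self) -> FcsFit:
        return FcsFit(n_particles=self.n_particles,
                      triplet_fraction=self.triplet_fraction,
                      triplet_time=self.triplet_time_us,
                      tau_d=self.tau_d_us,
                      structure_parameter=self.structure_parameter)


@dataclass
class HdxTruth:
    """Per-residue protection schedule for a synthetic protein.

    First-order exchange with intrinsic rate ``k_int`` (1 /s for every
    residue) slowed by state-specific protection factors; the bHLH-like
    ``protected_segment`` is ordered in both states and much more protected
    in the bound state.
    """

    sequence: str = ""
    protected_segment: tuple[int, int] = (41, 70)  # 1-based inclusive
    k_int_per_s: float = 1.0
    pf_background: float = 1.0
    pf_segment_apo: float = 30.0
    pf_segment_holo: float = 3000.0

    def __post_init__(self):
        if not self.sequence:
            self.sequence = gen_sequence(
                SequencePlan(segments=((40, "disordered"),
                                       (30, "ordered"),
                                       (50, "disordered"))), seed=2024).residues
        s, e = self.protected_segment
        if not (1 <= s <= e <= len(self.sequence)):
            raise ValidationError("protected segment outside the synthetic sequence")
        if min(self.k_int_per_s, self.pf_background,
               self.pf_segment_apo, self.pf_segment_holo) <= 0:
            raise ValidationError("rates and protection factors must be positive")

    def protection(self, state: str) -> np.ndarray:
        pf = np.full(len(self.sequence), self.pf_background)
        s, e = self.protected_segment
        pf[s - 1:e] = self.pf_segment_apo if state == "apo" else self.pf_segment_holo
        return pf


@dataclass
class MeltTruth:
    tm_c: float = 68.0
    width_c: float = 2.0
    baseline_low: float = 100.0
    baseline_high: float = 1000.0
    decay_k_per_c: float = 0.02
    cd_tm_c: float = 66.0
    cd_width_c: float = 3.0
    cd_low: float = -6000.0  # native MRE at 220 nm
    cd_high: float = -2000.0

    def __post_init__(self):
        if self.width_c <= 0 or self.cd_width_c <= 0 or self.decay_k_per_c < 0:
            raise ValidationError("widths must be positive and decay rate >= 0")


@dataclass
class SequencePlan:
    """Ordered/disordered segment layout: ((length, kind), ...)."""

    segments: tuple = ((100, "disordered"),)

    def __post_init__(self):
        if sum(l for l, _ in self.segments) < 1:
            raise ValidationError("sequence plan must cover at least one residue")
        for _, kind in self.segments:
            if kind not in ("ordered", "disordered"):
                raise ValidationError(f"unknown segment kind {kind!r}")


@dataclass
class GroundTruth:
    """All assay ground truths in one record."""

    binding: BindingTruth = field(default_factory=BindingTruth)
    fcs: FcsTruth = field(default_factory=FcsTruth)
    hdx: HdxTruth = field(default_factory=HdxTruth)
    melt: MeltTruth = field(default_factory=MeltTruth)
    sequence: SequencePlan = field(default_factory=SequencePlan)


# ---------------------------------------------------------------------------

def _default_ladder(top_um: float = 1.5, n: int = 12) -> np.ndarray:
    return np.linspace(0.0, top_um, n)


def gen_titration(truth: BindingTruth | None = None, kind: str = "fp",
                  ladder=None, probe_conc_um: float | None = None,
                  replicates: int = 3,
                  noise: NoiseSpec | None = None) -> TitrationSeries:
    """Synthetic titration for one assay.

    ``kind='fp'`` draws millipolarization from the exact depletion model,
    ``kind='fcs'`` apparent diffusion times from the same model with τ
    plateaus, and ``kind='emsa'`` free-probe fractions directly from the
    modified Hill model.  Noise SD = sigma × (signal dynamic range).
    """
    truth = truth or BindingTruth()
    noise = noise or NoiseSpec()
    if ladder is None:
        ladder = _default_ladder(2.5 if kind == "fcs" else 1.5)
    ladder = np.asarray(ladder, dtype=float)
    if ladder.size == 0:
        raise ValidationError("empty concentration ladder")
    if kind == "fp":
        probe = 0.04 if probe_conc_um is None else probe_conc_um
        clean = quadratic_signal(ladder, probe, truth.kd_um, truth.y0, truth.ymax)
        scale = abs(truth.ymax - truth.y0)
        signal_kind = "mP"
    elif kind == "fcs":
        probe = 0.1 if probe_conc_um is None else probe_conc_um
        clean = quadratic_signal(ladder, probe, truth.fcs_kd_um,
                                 truth.tau_free_us, truth.tau_bound_us)
        scale = abs(truth.tau_bound_us - truth.tau_free_us)
        signal_kind = "tau_app"
    elif kind == "emsa":
        probe = 0.04 if probe_conc_um is None else probe_conc_um
        clean = hill_signal(ladder, truth.hill_a, truth.hill_b,
                            truth.hill_kd_um, truth.hill_n)
        scale = abs(truth.hill_a)
        signal_kind = "free_probe_fraction"
    else:
        raise ValidationError(f"unknown titration kind {kind!r}")
    rng = noise.rng()
    signals = clean[:, None] + rng.normal(0.0, noise.sigma * scale,
                                          size=(ladder.size, replicates))
    return TitrationSeries(probe_conc=probe, ligand_concs=ladder,
                           signals=signals, signal_kind=signal_kind)


def gen_fcs_curve(truth: FcsTruth | None = None, lags=None,
                  noise: NoiseSpec | None = None,
                  temperature_c: float = 23.0) -> AutocorrelationCurve:
    """Synthetic autocorrelation on a log-spaced lag grid (µs)."""
    truth = truth or FcsTruth()
    noise = noise or NoiseSpec()
    if lags is None:
        lags = np.geomspace(0.2, 1e6, 120)
    lags = np.asarray(lags, dtype=float)
    clean = model_g(lags, truth.as_fit())
    scale = float(clean.max() - clean.min())
    g = clean + noise.rng().normal(0.0, noise.sigma * scale, size=lags.size)
    return AutocorrelationCurve(lag_times=lags, g_values=g,
                                temperature=temperature_c)


def gen_hdx_dataset(truth: HdxTruth | None = None, peptide_length: int = 10,
                    peptide_step: int = 8, exposures=HDX_EXPOSURES_S,
                    replicates: int = 4, noise: NoiseSpec | None = None,
                    states=("apo", "holo"),
                    protein: str = "synthetic") -> pd.DataFrame:
    """Flat uptake table for a tiled synthetic protein, controls included.

    Peptide centroid mass at exposure t is

        M(t) = M_min + ΔmD · Σ_r (1 - exp(-k_int t / PF_r)),

    summed over the peptide's exchangeable amides (length - 1; the
    N-terminal residue is excluded).  ``FD`` rows carry the full-deuteration
    control M_max = M_min + n_sites·ΔmD and ``T0`` rows the minimal-exchange
    control.  Gaussian noise scales with each peptide's M_max - M_min.
    """
    truth = truth or HdxTruth()
    noise = noise or NoiseSpec()
    exposures = [float(e) for e in exposures]
    if any(e <= 0 for e in exposures):
        raise ValidationError("exposures must be positive")
    seq = truth.sequence
    n = len(seq)
    if peptide_length > n:
        raise ValidationError("peptide length exceeds the synthetic sequence")
    starts = list(range(1, n - peptide_length + 2, peptide_step))
    if starts and starts[-1] + peptide_length - 1 < n:
        starts.append(n - peptide_length + 1)
    rng = noise.rng()
    rows = []
    for start in starts:
        end = start + peptide_length - 1
        if end > n:
            raise ValidationError("peptide extends past the synthetic sequence")
        pep_seq = seq[start - 1:end]
        n_sites = peptide_length - 1
        base = chain_stats(SequenceRecord(pep_seq)).mass_da
        m_max_clean = base + n_sites * DEUTERIUM_MASS_INCREMENT_DA
        sd = noise.sigma * (m_max_clean - base)

        def emit(state, exposure, mass_clean):
            for rep in range(1, replicates + 1):
                rows.append({"protein": protein, "start": start, "end": end,
                             "sequence": pep_seq, "state": state,
                             "exposure_s": exposure, "replicate": rep,
                             "centroid_mass_da": mass_clean + rng.normal(0.0, sd)})

        for state in states:
            pf = truth.protection(state)[start:end]  # amides of residues 2..L
            for t in exposures:
                frac = 1.0 - np.exp(-truth.k_int_per_s * t / pf)
                emit(state, t, base + DEUTERIUM_MASS_INCREMENT_DA * frac.sum())
        emit("T0", 0.0, base)
        emit("FD", 86400.0, m_max_clean)
    return pd.DataFrame(rows)


def gen_melt_curve(truth: MeltTruth | None = None, temperatures=None,
                   mode: str = "dye", noise: NoiseSpec | None = None):
    """Synthetic melt; dye mode returns (curve, dye-only control).

    Dye mode: two-state sigmoid × exponential quenching envelope
    (normalized to 1 at the grid start); the control is the pure envelope
    at the native baseline level.  Ellipticity mode: bare Boltzmann
    sigmoid; returns (curve, None).
    """
    truth = truth or MeltTruth()
    noise = noise or NoiseSpec()
    if temperatures is None:
        temperatures = (np.arange(25.0, 99.0 + 1e-9, 0.25) if mode == "dye"
                        else np.arange(20.0, 95.0 + 1e-9, 0.5))
    t = np.asarray(temperatures, dtype=float)
    if t.size < 10:
        raise ValidationError("melt grid shorter than 10 points")
    rng = noise.rng()
    if mode == "dye":
        sigmoid = boltzmann(t, truth.baseline_low, truth.baseline_high,
                            truth.tm_c, truth.width_c)
        env = np.exp(-truth.decay_k_per_c * (t - t[0]))
        amp = abs(truth.baseline_high - truth.baseline_low)
        curve = MeltCurve(t, sigmoid * env + rng.normal(0, noise.sigma * amp, t.size),
                          channel="dye")
        control = MeltCurve(t, truth.baseline_low * env
                            + rng.normal(0, noise.sigma * truth.baseline_low, t.size),
                            channel="dye")
        return curve, control
    if mode == "ellipticity":
        sigmoid = boltzmann(t, truth.cd_low, truth.cd_high,
                            truth.cd_tm_c, truth.cd_width_c)
        amp = abs(truth.cd_high - truth.cd_low)
        curve = MeltCurve(t, sigmoid + rng.normal(0, noise.sigma * amp, t.size),
                          channel="cd220")
        return curve, None
    raise ValidationError(f"unknown melt mode {mode!r}")


def gen_sequence(plan: SequencePlan | None = None, seed: int = 0) -> SequenceRecord:
    """Random sequence from segment-specific residue alphabets.

    Disordered segments draw from a charged/polar-enriched alphabet,
    ordered segments from a hydrophobic-enriched one; composition is
    reproducible under the seed.
    """
    plan = plan or SequencePlan()
    rng = rng_from_seed(seed)
    parts = []
    for length, kind in plan.segments:
        alphabet = _DISORDER_ALPHABET if kind == "disordered" else _ORDER_ALPHABET
        parts.append("".join(rng.choice(list(alphabet), size=length)))
    return SequenceRecord("".join(parts), accession=f"synthetic-{seed}")
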