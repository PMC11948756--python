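"""HDX-MS fractional-uptake and differential-exchange statistics.

Fractional deuterium uptake of a peptide normalizes the measured centroid
mass M between per-peptide controls: a minimal-exchange control (quench
before labelling, M_min) and a maximal-exchange control (24 h labelling,
M_max),

    D[%] = (M - M_min) / (M_max - M_min) × 100.

Differential analysis between two states subtracts mean fractional uptakes
per peptide and exposure; the error of the difference is the square root of
the summed state variances, and significance is a two-sided Welch t test
(unequal variances, Welch-Satterthwaite degrees of freedom) at a 98%
confidence level.  Values slightly outside [0, 100]% (back-exchange noise)
are retained and only flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "PeptideUptake", "ExchangeControls", "DifferentialResult",
    "fraction_exchanged", "uptake_profile", "differential",
    "classify_timecourse", "coverage_map", "SIGNIFICANCE_ALPHA",
]

#: Two-sided significance level implied by the 98% confidence interval.
SIGNIFICANCE_ALPHA = 0.02

#: |D%| overshoot beyond [0, 100] considered worth flagging.
EXCESS_FLAG_POINTS = 5.0


@dataclass
class PeptideUptake:
    """Per-peptide centroid masses: {exposure_s: replicate masses (Da)}."""

    sequence: str
    start: int
    end: int
    state: str
    observations: dict[float, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.end < self.start:
            raise ValidationError(f"peptide {self.sequence}: end < start")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValidationError(
                f"peptide {self.sequence}: length does not match coordinates "
                f"{self.start}-{self.end}")
        self.observations = {float(k): np.asarray(v, dtype=float)
                             for k, v in self.observations.items()}

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.sequence, self.start, self.end)

    @property
    def exposures(self) -> list[float]:
        return sorted(self.observations)


@dataclass
class ExchangeControls:
    """Replicate centroid masses of the min/max exchange controls (Da)."""

    m_min: np.ndarray
    m_max: np.ndarray

    def __post_init__(self):
        self.m_min = np.atleast_1d(np.asarray(self.m_min, dtype=float))
        self.m_max = np.atleast_1d(np.asarray(self.m_max, dtype=float))
        if self.m_max.mean() <= self.m_min.mean():
            raise ValidationError("degenerate controls: mean(M_max) <= mean(M_min)")


@dataclass
class DifferentialResult:
    peptide: tuple[str, int, int]
    exposure_s: float
    delta_fraction: float  # percent, state A - state B
    pooled_sd: float
    t_statistic: float
    p_value: float
    significant: bool
    n_a: int
    n_b: int


def fraction_exchanged(m, controls: ExchangeControls):
    """Control-normalized uptake in percent; not clamped to [0, 100]."""
    m_min = controls.m_min.mean()
    m_max = controls.m_max.mean()
    return (np.asarray(m, dtype=float) - m_min) / (m_max - m_min) * 100.0


def uptake_profile(peptide: PeptideUptake, controls: ExchangeControls) -> pd.DataFrame:
    """Mean ± SD fractional uptake per exposure.

    Replicate masses are converted individually, then averaged.  Rows with
    fewer than 3 replicates are reported but flagged (``stats_ok=False``);
    uptake outside [-5, 105]% sets ``excess_flag``.
    """
    rows = []
    for exposure in peptide.exposures:
        fr = fraction_exchanged(peptide.observations[exposure], controls)
        n = fr.size
        rows.append({
            "exposure_s": exposure,
            "mean_d_percent": float(fr.mean()),
            "sd_d_percent": float(fr.std(ddof=1)) if n > 1 else float("nan"),
            "n": n,
            "stats_ok": n >= 3,
            "excess_flag": bool(np.any(fr < -EXCESS_FLAG_POINTS) or
                                np.any(fr > 100 + EXCESS_FLAG_POINTS)),
        })
    return pd.DataFrame(rows)


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    import warnings
    with warnings.catch_warnings():
        # identical replicates (e.g. noiseless synthetic data) trip scipy's
        # catastrophic-cancellation warning; the nan result is handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def differential(state_a: dict, state_b: dict, controls: dict,
                 alpha: float = SIGNIFICANCE_ALPHA,
                 bh_correct: bool = False) -> list[DifferentialResult]:
    """Per-peptide, per-exposure differential uptake A - B.

    ``state_a``/``state_b`` map peptide keys to :class:`PeptideUptake`;
    ``controls`` maps the same keys to :class:`ExchangeControls`.  Exposure
    matching is exact (no interpolation).  With ``bh_correct`` the Welch
    p-values are Benjamini-Hochberg adjusted across all comparisons before
    thresholding.
    """
    orphans = set(state_a) ^ set(state_b)
    if orphans:
        raise ValidationError(f"unmatched peptides between states: {sorted(orphans)}")
    results = []
    for key in sorted(state_a):
        pa, pb = state_a[key], state_b[key]
        ctl = controls[key]
        shared = sorted(set(pa.observations) & set(pb.observations))
        for exposure in shared:
            fa = fraction_exchanged(pa.observations[exposure], ctl)
            fb = fraction_exchanged(pb.observations[exposure], ctl)
            tstat, pval = _welch(fa, fb)
            results.append(DifferentialResult(
                peptide=key, exposure_s=exposure,
                delta_fraction=float(fa.mean() - fb.mean()),
                pooled_sd=float(np.sqrt(fa.var(ddof=1) + fb.var(ddof=1))),
                t_statistic=tstat, p_value=pval,
                significant=bool(pval < alpha),
                n_a=fa.size, n_b=fb.size))
    if bh_correct and results:
        from statsmodels.stats.multitest import multipletests
        reject, _, _, _ = multipletests([r.p_value for r in results],
                                        alpha=alpha, method="fdr_bh")
        for r, rej in zip(results, reject):
            r.significant = bool(rej)
    return results


def classify_timecourse(results) -> pd.DataFrame:
    """Yes/No significance grid: peptides (rows) × exposures (columns).

    Rows are ordered by start coordinate; columns by exposure time.
    """
    results = list(results)
    exposures = sorted({r.exposure_s for r in results})
    if len(exposures) < 2:
        raise ValidationError("timecourse classification needs >= 2 exposures")
    peptides = sorted({r.peptide for r in results}, key=lambda k: (k[1], k[2], k[0]))
    cells = {p: {e: "No" for e in exposures} for p in peptides}
    for r in results:
        if r.significant:
            cells[r.peptide][r.exposure_s] = "Yes"
    return pd.DataFrame([cells[p] for p in peptides],
                        index=pd.MultiIndex.from_tuples(
                            peptides, names=["sequence", "start", "end"]),
                        columns=exposures)


def coverage_map(peptides, sequence_length: int):
    """Per-residue peptide coverage counts plus the uncovered residue list."""
    counts = np.zeros(sequence_length, dtype=int)
    for p in peptides:
        if p.start < 1 or p.end > sequence_length:
            raise ValidationError(
                f"peptide {p.sequence} ({p.start}-{p.end}) outside sequence "
                f"of length {sequence_length}")
        counts[p.start - 1:p.end] += 1
    uncovered = [i + 1 for i in range(sequence_length) if counts[i] == 0]
    return counts, uncovered
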