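"""Equilibrium binding: exact depletion solution, Hill model, diagnostics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import bisect

from idpchar import binding, synth
from idpchar.exceptions import FitError, ValidationError


def mass_balance_complex(p, l, kd, tol=1e-14):
    """Independent oracle: bisection on K_D = (P-cx)(L-cx)/cx."""
    if l == 0 or p == 0:
        return 0.0
    if kd == 0:
        return min(p, l)
    f = lambda cx: (p - cx) * (l - cx) - kd * cx
    hi = min(p, l)
    return bisect(f, 0.0, hi, xtol=tol * max(hi, 1.0))


class TestComplexConc:
    def test_hand_evaluated_example(self):
        assert binding.complex_conc(5, 10, 0.12) == pytest.approx(4.885, abs=5e-4)

    def test_stoichiometric_limit(self):
        assert binding.complex_conc(5, 10, 0.0) == pytest.approx(5.0)
        assert binding.complex_conc(10, 5, 0.0) == pytest.approx(5.0)

    def test_no_probe_no_complex(self):
        assert binding.complex_conc(5, 0, 0.12) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            binding.complex_conc(-1, 1, 0.1)
        with pytest.raises(ValidationError):
            binding.complex_conc(1, 1, -0.1)

    @settings(derandomize=True, max_examples=200)
    @given(p=st.floats(1e-4, 1e3), l=st.floats(1e-4, 1e3),
           kd=st.floats(1e-6, 1e3))
    def test_matches_bisection_oracle(self, p, l, kd):
        cx = float(binding.complex_conc(p, l, kd))
        oracle = mass_balance_complex(p, l, kd)
        assert cx == pytest.approx(oracle, rel=1e-10, abs=1e-12)
        assert 0 <= cx <= min(p, l) + 1e-12


class TestSignalModel:
    def test_endpoints_and_linearity(self):
        assert binding.signal_model(0.0, 1.0, 60, 230) == 60
        assert binding.signal_model(1.0, 1.0, 60, 230) == 230
        assert binding.signal_model(0.5, 1.0, 60, 230) == pytest.approx(145)

    def test_complex_exceeding_probe_rejected(self):
        with pytest.raises(ValidationError):
            binding.signal_model(2.0, 1.0, 60, 230)


class TestSaturation:
    def test_design_condition(self):
        assert binding.saturation(5, 10, 0.12) == pytest.approx(0.977, abs=1e-3)

    def test_asymptote(self):
        assert binding.saturation(5, 1e7, 0.12) == pytest.approx(1.0, abs=1e-5)

    def test_monotone_in_probe_and_kd(self):
        ls = np.linspace(0.1, 50, 40)
        sats = binding.saturation(5.0, ls, 0.12)
        assert np.all(np.diff(sats) >= -1e-12)
        kds = np.linspace(0.01, 10, 40)
        sats_kd = [binding.saturation(5.0, 10.0, kd) for kd in kds]
        assert np.all(np.diff(sats_kd) <= 1e-12)

    def test_inverse_query(self):
        l95 = binding.ligand_for_saturation(5.0, 0.12, 0.95)
        assert l95 == pytest.approx(7.03, abs=0.05)
        assert binding.saturation(5.0, l95, 0.12) == pytest.approx(0.95, abs=1e-9)

    def test_zero_protein_rejected(self):
        with pytest.raises(ValidationError):
            binding.saturation(0.0, 1.0, 0.1)


def brute_force_runs_p(signs):
    """Exact two-sided P by full enumeration of sign arrangements."""
    n1 = sum(1 for s in signs if s > 0)
    n2 = len(signs) - n1
    runs_of = lambda seq: 1 + sum(a != b for a, b in zip(seq, seq[1:]))
    obs = runs_of(signs)
    counts = {}
    for combo in itertools.combinations(range(len(signs)), n1):
        seq = [1 if i in combo else -1 for i in range(len(signs))]
        counts[runs_of(seq)] = counts.get(runs_of(seq), 0) + 1
    total = sum(counts.values())
    p_obs = counts[obs] / total
    return sum(c / total for c in counts.values() if c / total <= p_obs * (1 + 1e-12))


class TestRunsTest:
    def test_alternating_signs_small_p(self):
        assert binding.runs_test_p([1, -1, 1, -1, 1, -1, 1, -1]) < 0.1

    def test_two_blocks_small_p(self):
        assert binding.runs_test_p([1, 1, 1, 1, -1, -1, -1, -1]) < 0.1

    @pytest.mark.parametrize("signs", [
        (1, -1, 1, -1, 1, -1, 1, -1),
        (1, 1, 1, 1, -1, -1, -1, -1),
        (1, 1, -1, 1, -1, -1, 1, -1, 1, 1),
        (1, -1, -1, 1, 1, 1, -1),
    ])
    def test_exact_matches_enumeration_oracle(self, signs):
        assert binding.runs_test_p(list(signs)) == pytest.approx(
            brute_force_runs_p(list(signs)), rel=1e-12)

    def test_large_n_matches_statsmodels_normal_approx(self, rng):
        from statsmodels.sandbox.stats.runs import runstest_1samp
        x = rng.normal(size=60)
        p_pkg = binding.runs_test_p(np.sign(x))
        _, p_sm = runstest_1samp(x > 0, cutoff=0.5, correction=False)
        assert p_pkg == pytest.approx(p_sm, abs=1e-6)

    def test_single_sign_is_extreme(self):
        assert binding.runs_test_p([1.0] * 10) < 0.01

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            binding.runs_test_p([1.0])


class TestQuadraticFit:
    def test_zero_noise_recovery(self, zero_noise):
        series = synth.gen_titration(noise=zero_noise)
        fit = binding.fit_quadratic_binding(series)
        assert fit.kd == pytest.approx(0.12, rel=1e-3)
        assert fit.y0 == pytest.approx(60, rel=1e-3)
        assert fit.ymax == pytest.approx(230, rel=1e-3)
        assert fit.r_squared > 0.999999

    def test_constant_signal_degenerate(self):
        series = binding.TitrationSeries(
            probe_conc=0.04, ligand_concs=np.linspace(0, 1.5, 12),
            signals=np.full((12, 3), 100.0))
        with pytest.raises(FitError):
            binding.fit_quadratic_binding(series)

    def test_too_few_points_rejected(self):
        series = binding.TitrationSeries(
            probe_conc=0.04, ligand_concs=[0, 0.5, 1.0, 1.5],
            signals=np.arange(8.0).reshape(4, 2))
        with pytest.raises(ValidationError):
            binding.fit_quadratic_binding(series)

    def test_ci_bounds_bracket_estimate(self):
        series = synth.gen_titration(noise=synth.NoiseSpec(0.03, 11))
        fit = binding.fit_quadratic_binding(series)
        assert fit.kd_ci95[0] < fit.kd < fit.kd_ci95[1]

    def test_averaged_and_stacked_agree_at_zero_noise(self, zero_noise):
        series = synth.gen_titration(noise=zero_noise)
        stacked = binding.fit_quadratic_binding(series)
        averaged = binding.fit_quadratic_binding(series, average_replicates=True)
        assert stacked.kd == pytest.approx(averaged.kd, rel=1e-6)

    def test_ci_coverage_near_nominal(self):
        """Truth falls inside the 95% CI in ~95% of simulated fits."""
        hits = 0
        n_sim = 500
        for i in range(n_sim):
            series = synth.gen_titration(noise=synth.NoiseSpec(0.03, 10_000 + i))
            fit = binding.fit_quadratic_binding(series)
            hits += fit.kd_ci95[0] <= 0.12 <= fit.kd_ci95[1]
        assert hits / n_sim == pytest.approx(0.95, abs=0.05)


class TestHillFit:
    def test_zero_noise_recovery(self, zero_noise):
        series = synth.gen_titration(kind="emsa", noise=zero_noise)
        fit = binding.fit_hill(series)
        assert fit.kd == pytest.approx(0.327, rel=1e-3)
        assert fit.a == pytest.approx(1.0, rel=1e-3)
        assert abs(fit.b) < 1e-3
        assert fit.n == pytest.approx(1.2, rel=1e-2)

    def test_midpoint_identity(self):
        y = binding.hill_signal(0.327, a=1.0, b=0.1, kd=0.327, n=1.2)
        assert y == pytest.approx(1.0 / 2 + 0.1)

    def test_constant_signal_degenerate(self):
        series = binding.TitrationSeries(
            probe_conc=0.04, ligand_concs=np.linspace(0, 1.5, 12),
            signals=np.ones((12, 3)))
        with pytest.raises(FitError):
            binding.fit_hill(series)


class TestCrossModel:
    def test_quadratic_and_hill_kd_agree_when_n_near_one(self, zero_noise):
        """On depletion-model data with K_D >> probe the two models agree on K_D."""
        truth = synth.BindingTruth(kd_um=0.327, y0=1.0, ymax=0.0)
        series = synth.gen_titration(truth, kind="fp", probe_conc_um=0.01,
                                     noise=zero_noise)
        qfit = binding.fit_quadratic_binding(series)
        hseries = binding.TitrationSeries(
            probe_conc=series.probe_conc, ligand_concs=series.ligand_concs,
            signals=series.signals, signal_kind="free_probe_fraction")
        hfit = binding.fit_hill(hseries)
        assert hfit.kd == pytest.approx(qfit.kd, rel=0.05)


class TestMonomerBasis:
    def test_dilute_limit_doubles(self, zero_noise):
        truth = synth.BindingTruth(kd_um=5.0)
        series = synth.gen_titration(truth, ladder=np.linspace(0, 60, 12),
                                     probe_conc_um=0.04, noise=zero_noise)
        kd_mono = binding.kd_monomer_basis(series, method="refit")
        assert kd_mono == pytest.approx(10.0, rel=0.02)

    def test_scale_method_is_exact_doubling(self, zero_noise):
        series = synth.gen_titration(noise=zero_noise)
        fit = binding.fit_quadratic_binding(series)
        assert binding.kd_monomer_basis(series, method="scale") == pytest.approx(
            2 * fit.kd, rel=1e-9)

    def test_refit_near_paper_footnote_value(self, zero_noise):
        """FP truth 0.12 µM (dimer) refits to ~0.24-0.26 µM on the monomer axis."""
        series = synth.gen_titration(noise=zero_noise)
        kd_mono = binding.kd_monomer_basis(series, method="refit")
        assert 0.23 <= kd_mono <= 0.27

    def test_degenerate_ladder_rejected(self):
        with pytest.raises(ValidationError):
            binding.TitrationSeries(probe_conc=0.04, ligand_concs=[0.0, 0.0],
                                    signals=np.zeros((2, 1)))
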