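"""HDX-MS uptake normalization, differentials and significance calls."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idpchar import hdx, io as io_core, synth
from idpchar.exceptions import ValidationError


def controls(m_min=1000.0, m_max=1010.0, n=4):
    return hdx.ExchangeControls(m_min=np.full(n, m_min), m_max=np.full(n, m_max))


def peptide(state="apo", obs=None, start=1, end=8, seq="AAAAAAAA"):
    return hdx.PeptideUptake(sequence=seq, start=start, end=end, state=state,
                             observations=obs or {})


class TestFractionExchanged:
    def test_endpoints_and_midpoint(self):
        ctl = controls()
        assert hdx.fraction_exchanged(1010.0, ctl) == pytest.approx(100.0)
        assert hdx.fraction_exchanged(1000.0, ctl) == pytest.approx(0.0)
        assert hdx.fraction_exchanged(1005.0, ctl) == pytest.approx(50.0)

    def test_not_clamped(self):
        assert hdx.fraction_exchanged(1011.0, controls()) == pytest.approx(110.0)

    def test_degenerate_controls_rejected(self):
        with pytest.raises(ValidationError):
            hdx.ExchangeControls(m_min=[1010.0], m_max=[1000.0])

    @settings(derandomize=True, max_examples=100)
    @given(shift=st.floats(-1e4, 1e4), scale=st.floats(0.1, 100),
           frac=st.floats(-0.2, 1.2))
    def test_shift_and_scale_invariance(self, shift, scale, frac):
        m0, m1 = 1000.0, 1010.0
        m = m0 + frac * (m1 - m0)
        base = hdx.fraction_exchanged(m, controls(m0, m1))
        moved = hdx.fraction_exchanged(scale * (m + shift),
                                       controls(scale * (m0 + shift),
                                                scale * (m1 + shift)))
        assert moved == pytest.approx(base, rel=1e-6, abs=1e-6)


class TestUptakeProfile:
    def test_monotone_uptake_for_protected_peptide(self, tmp_path, hdx_table_clean):
        path = tmp_path / "hdx.csv"
        io_core.write_hdx_cluster_table(hdx_table_clean, path)
        states, ctls, _ = io_core.read_hdx_cluster_table(path)
        protected = [k for k in states["apo"] if 41 <= k[1] <= 70 or 41 <= k[2] <= 70]
        key = protected[0]
        prof = hdx.uptake_profile(states["apo"][key], ctls[key])
        assert np.all(np.diff(prof["mean_d_percent"]) >= -1e-9)

    def test_unprotected_peptide_fast_exchange(self, tmp_path, hdx_table_clean):
        path = tmp_path / "hdx.csv"
        io_core.write_hdx_cluster_table(hdx_table_clean, path)
        states, ctls, _ = io_core.read_hdx_cluster_table(path)
        key = next(k for k in sorted(states["apo"]) if k[2] < 41)
        prof = hdx.uptake_profile(states["apo"][key], ctls[key])
        assert prof["mean_d_percent"].iloc[0] > 99.0  # ~total exchange at 10 s

    def test_identical_replicates_zero_sd(self):
        pep = peptide(obs={10.0: [1005.0] * 4})
        prof = hdx.uptake_profile(pep, controls())
        assert prof["sd_d_percent"].iloc[0] == 0.0

    def test_few_replicates_flagged_not_fatal(self):
        pep = peptide(obs={10.0: [1005.0, 1006.0]})
        prof = hdx.uptake_profile(pep, controls())
        assert not prof["stats_ok"].iloc[0]
        assert np.isfinite(prof["mean_d_percent"].iloc[0])


class TestDifferential:
    def test_identical_states_null(self):
        obs = {10.0: [1004.0, 1005.0, 1006.0, 1005.0]}
        a = {("AAAAAAAA", 1, 8): peptide("apo", obs)}
        b = {("AAAAAAAA", 1, 8): peptide("holo", obs)}
        res = hdx.differential(a, b, {("AAAAAAAA", 1, 8): controls()})
        assert all(r.delta_fraction == 0 for r in res)
        assert not any(r.significant for r in res)

    def test_pooled_sd_formula(self, rng):
        xa = 1005 + rng.normal(0, 0.5, 4)
        xb = 1003 + rng.normal(0, 0.5, 4)
        a = {("AAAAAAAA", 1, 8): peptide("apo", {10.0: xa})}
        b = {("AAAAAAAA", 1, 8): peptide("holo", {10.0: xb})}
        res = hdx.differential(a, b, {("AAAAAAAA", 1, 8): controls()})[0]
        ctl = controls()
        fa = hdx.fraction_exchanged(xa, ctl)
        fb = hdx.fraction_exchanged(xb, ctl)
        assert res.pooled_sd == pytest.approx(
            np.sqrt(fa.var(ddof=1) + fb.var(ddof=1)))

    def test_equal_variances_give_sigma_root_two(self):
        xa = np.array([1004.0, 1005.0, 1006.0, 1005.0])
        xb = xa + 3.0
        a = {("AAAAAAAA", 1, 8): peptide("apo", {10.0: xa})}
        b = {("AAAAAAAA", 1, 8): peptide("holo", {10.0: xb})}
        res = hdx.differential(a, b, {("AAAAAAAA", 1, 8): controls()})[0]
        sigma = hdx.fraction_exchanged(xa, controls()).std(ddof=1)
        assert res.pooled_sd == pytest.approx(sigma * np.sqrt(2))

    def test_protection_detected_only_in_segment(self, tmp_path, hdx_table_noisy):
        path = tmp_path / "hdx.csv"
        io_core.write_hdx_cluster_table(hdx_table_noisy, path)
        states, ctls, _ = io_core.read_hdx_cluster_table(path)
        res = hdx.differential(states["apo"], states["holo"], ctls)
        early = [r for r in res if r.exposure_s == 10.0]
        seg = range(41, 71)
        for r in early:
            overlaps = bool(set(range(r.peptide[1], r.peptide[2] + 1)) & set(seg))
            if overlaps:
                assert r.significant and r.delta_fraction > 0
            else:
                assert not r.significant

    def test_orphan_peptides_rejected(self):
        a = {("AAAAAAAA", 1, 8): peptide("apo", {10.0: [1005.0] * 4})}
        with pytest.raises(ValidationError):
            hdx.differential(a, {}, {})

    def test_null_false_positive_rate_near_alpha(self):
        """Welch calls at the 98% CI flag ~2% of null comparisons."""
        rng = np.random.default_rng(42)
        ctl = controls()
        n_tests, n_sig = 0, 0
        for i in range(250):
            key = ("AAAAAAAA", 1, 8)
            xa = 1005 + rng.normal(0, 0.5, 4)
            xb = 1005 + rng.normal(0, 0.5, 4)
            a = {key: peptide("apo", {10.0: xa, 60.0: 1005 + rng.normal(0, 0.5, 4)})}
            b = {key: peptide("holo", {10.0: xb, 60.0: 1005 + rng.normal(0, 0.5, 4)})}
            for r in hdx.differential(a, b, {key: ctl}):
                n_tests += 1
                n_sig += r.significant
        assert n_sig / n_tests == pytest.approx(0.02, abs=0.015)

    def test_welch_agrees_with_permutation_oracle(self):
        """Exact permutation test and Welch t produce the same calls."""
        rng = np.random.default_rng(7)
        ctl = controls()
        cases = [(1005 + rng.normal(0, 0.4, 4), 1005 + rng.normal(0, 0.4, 4))
                 for _ in range(10)]
        cases += [(1008 + rng.normal(0, 0.3, 4), 1002 + rng.normal(0, 0.3, 4))
                  for _ in range(10)]
        for xa, xb in cases:
            key = ("AAAAAAAA", 1, 8)
            res = hdx.differential({key: peptide("apo", {10.0: xa})},
                                   {key: peptide("holo", {10.0: xb})},
                                   {key: ctl})[0]
            # exact permutation distribution of |mean difference|
            pooled = np.concatenate([xa, xb])
            obs = abs(xa.mean() - xb.mean())
            count = 0
            combos = list(itertools.combinations(range(8), 4))
            for idx in combos:
                mask = np.zeros(8, bool)
                mask[list(idx)] = True
                diff = abs(pooled[mask].mean() - pooled[~mask].mean())
                count += diff >= obs - 1e-12
            p_perm = count / len(combos)
            # with n=4 the permutation p floor is 1/35; compare calls only
            # where both tests are decisive
            if res.p_value < 0.005:
                assert p_perm <= 2 / 35
            elif res.p_value > 0.2:
                assert p_perm > 0.05

    def test_bh_correction_reduces_calls(self, tmp_path, hdx_table_noisy):
        path = tmp_path / "hdx.csv"
        io_core.write_hdx_cluster_table(hdx_table_noisy, path)
        states, ctls, _ = io_core.read_hdx_cluster_table(path)
        raw = hdx.differential(states["apo"], states["holo"], ctls)
        bh = hdx.differential(states["apo"], states["holo"], ctls, bh_correct=True)
        assert sum(r.significant for r in bh) <= sum(r.significant for r in raw)


class TestClassifyTimecourse:
    def test_early_only_protection(self):
        """A peptide protected only in the bound state early shows
        Yes at 10 s and No at the later exposures."""
        truth = synth.HdxTruth(pf_segment_apo=10.0, pf_segment_holo=100.0)
        table = synth.gen_hdx_dataset(truth, noise=synth.NoiseSpec(0.02, 3))
        import idpchar.io as io_mod
        import tempfile, os
        with tempfile.TemporaryDirectory() as d:
            path = os.path.join(d, "t.csv")
            io_mod.write_hdx_cluster_table(table, path)
            states, ctls, _ = io_mod.read_hdx_cluster_table(path)
        res = hdx.differential(states["apo"], states["holo"], ctls)
        grid = hdx.classify_timecourse(res)
        inner = [k for k in states["apo"] if k[1] >= 41 and k[2] <= 70]
        key = inner[0]
        assert grid.loc[key, 10.0] == "Yes"
        assert grid.loc[key, 9000.0] == "No"

    def test_null_grid_all_no(self):
        obs = {10.0: [1005.0, 1004.8, 1005.2, 1005.1],
               60.0: [1007.0, 1006.9, 1007.1, 1007.0]}
        key = ("AAAAAAAA", 1, 8)
        res = hdx.differential({key: peptide("apo", obs)},
                               {key: peptide("holo", obs)},
                               {key: controls()})
        grid = hdx.classify_timecourse(res)
        assert (grid == "No").all().all()

    def test_deterministic(self, tmp_path, hdx_table_noisy):
        path = tmp_path / "hdx.csv"
        io_core.write_hdx_cluster_table(hdx_table_noisy, path)
        states, ctls, _ = io_core.read_hdx_cluster_table(path)
        res = hdx.differential(states["apo"], states["holo"], ctls)
        g1 = hdx.classify_timecourse(res)
        g2 = hdx.classify_timecourse(res)
        assert g1.equals(g2)

    def test_single_exposure_rejected(self):
        key = ("AAAAAAAA", 1, 8)
        res = hdx.differential({key: peptide("apo", {10.0: [1005.0] * 4})},
                               {key: peptide("holo", {10.0: [1005.0] * 4})},
                               {key: controls()})
        with pytest.raises(ValidationError):
            hdx.classify_timecourse(res)


class TestCoverageMap:
    def test_overlap_counts(self):
        peps = [peptide(seq="AAAAAAAA", start=1, end=8),
                peptide(seq="AAAAAA", start=5, end=10)]
        counts, uncovered = hdx.coverage_map(peps, 12)
        assert list(counts[:4]) == [1, 1, 1, 1]
        assert list(counts[4:8]) == [2, 2, 2, 2]
        assert uncovered == [11, 12]

    def test_gap_free_tiling(self, hdx_table_clean):
        peps = [peptide(seq=s, start=a, end=b) for s, a, b in
                hdx_table_clean[["sequence", "start", "end"]]
                .drop_duplicates().itertuples(index=False)]
        n = max(p.end for p in peps)
        _, uncovered = hdx.coverage_map(peps, n)
        assert uncovered == []

    def test_matches_interval_stabbing_oracle(self, rng):
        n = 50
        peps = []
        for _ in range(20):
            start = int(rng.integers(1, n - 5))
            end = int(rng.integers(start, min(start + 12, n)))
            peps.append(peptide(seq="A" * (end - start + 1), start=start, end=end))
        counts, _ = hdx.coverage_map(peps, n)
        brute = [sum(p.start <= i <= p.end for p in peps) for i in range(1, n + 1)]
        assert list(counts) == brute

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            hdx.coverage_map([peptide(seq="AAAA", start=10, end=13)], 12)


class TestPeptideValidation:
    def test_end_before_start_rejected(self):
        with pytest.raises(ValidationError):
            hdx.PeptideUptake(sequence="AA", start=8, end=1, state="apo")

    def test_length_coordinate_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            hdx.PeptideUptake(sequence="AAA", start=1, end=8, state="apo")
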