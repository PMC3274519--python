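import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mitopop as mp
from mitopop import coalsim as cs, demography as dem


class TestMismatchHistogram:
    def test_two_sequences(self):
        aln = mp.Alignment(["a", "b"], ["AAAA", "ATTT"])
        h = dem.mismatch_histogram(aln)
        assert h[3] == 1.0 and h[:3].sum() == 0.0

    def test_three_sequences(self):
        aln = mp.Alignment(["a", "b", "c"], ["AAAA", "AAAT", "AATT"])
        h = dem.mismatch_histogram(aln)
        assert h[1] == pytest.approx(2 / 3)
        assert h[2] == pytest.approx(1 / 3)

    def test_constant_theta_matches_geometric_in_mean(self):
        """Mean simulated spectrum approximates F_i = theta^i/(theta+1)^(i+1)."""
        theta, reps = 3.0, 600
        rng = np.random.default_rng(14)
        model = cs.DemographyModel(kind="constant", theta0=theta)
        cfg = cs.SimConfig(n=2, L=1)
        counts = np.zeros(30)
        for _ in range(reps):
            mat = cs.mutate_infinite_sites(cs.simulate_genealogy(model, cfg, rng),
                                           cfg, rng)
            d = mat.shape[1]
            if d < 30:
                counts[d] += 1
        freqs = counts / reps
        expect = dem.equilibrium_mismatch(theta, 30)
        assert np.abs(freqs[:10] - expect[:10]).max() < 0.05


class TestExpectedMismatch:
    def test_tau_zero_reduces_to_equilibrium(self):
        F = dem.expected_mismatch(0.0, 1.0, 100.0, 8, fold_tail=False)
        assert np.allclose(F, dem.equilibrium_mismatch(1.0, 8))

    def test_closed_form_half_quarter_eighth(self):
        F = dem.expected_mismatch(0.0, 1.0, 50.0, 10, fold_tail=False)
        assert F[0] == pytest.approx(0.5)
        assert F[1] == pytest.approx(0.25)
        assert F[2] == pytest.approx(0.125)

    @settings(max_examples=150, deadline=None)
    @given(
        st.floats(0, 20), st.floats(0, 10), st.floats(0, 1000)
    )
    def test_nonnegative_and_sums_to_one(self, tau, theta0, theta1):
        F = dem.expected_mismatch(tau, theta0, theta1, 40, fold_tail=True)
        assert np.all(F >= 0)
        assert F.sum() == pytest.approx(1.0, abs=1e-9)


class TestFitSuddenExpansion:
    def test_recovers_tau_roughly(self):
        rng = np.random.default_rng(7)
        model = cs.DemographyModel(kind="sudden_expansion", theta0=1.0,
                                   theta1=100.0, tau=5.0)
        cfg = cs.SimConfig(n=50, L=1)
        mat = cs.mutate_infinite_sites(cs.simulate_genealogy(model, cfg, rng),
                                       cfg, rng)
        hist = dem._hist_from_diffs(dem._matrix_pairwise_diffs(mat))
        fit = dem.fit_sudden_expansion(hist, 50, seed=1, n_boot=100)
        assert fit.tau_CI[0] <= fit.tau <= fit.tau_CI[1]
        assert 1.0 < fit.tau < 12.0
        assert fit.theta0 <= fit.theta1

    def test_degenerate_single_class(self):
        fit = dem.fit_sudden_expansion(np.array([1.0]), 5, seed=0, n_boot=10)
        assert fit.degenerate

    def test_raggedness_hand_case(self):
        assert dem.raggedness([0.5, 0.3, 0.2]) == pytest.approx(0.04 + 0.01)


class TestFuFs:
    def test_pair_one_difference(self):
        # theta = 1, k_obs = 2: S' = 1/2, Fs = ln(1) = 0
        fs, sp, sat = dem.fs_statistic(2, 1.0, 2)
        assert fs == pytest.approx(0.0) and sp == pytest.approx(0.5)
        assert not sat

    def test_three_sequences_all_distinct(self):
        # |s(3,.)| = (2, 3, 1): S' = 1/6, Fs = ln(1/5)
        fs, sp, _ = dem.fs_statistic(3, 1.0, 3)
        assert sp == pytest.approx(1 / 6)
        assert fs == pytest.approx(math.log(0.2))

    @pytest.mark.parametrize("n,theta", [(5, 0.5), (20, 3.0), (100, 10.0), (200, 2.0)])
    def test_ewens_pmf_normalizes(self, n, theta):
        assert np.exp(dem.log_ewens_pmf(n, theta)).sum() == pytest.approx(1.0)

    def test_k_obs_one_saturates(self):
        fs, sp, sat = dem.fs_statistic(5, 1.0, 1)
        assert sat and fs == math.inf and sp == pytest.approx(1.0)

    def test_monomorphic_rejected(self):
        aln = mp.Alignment(["a", "b"], ["AAAA", "AAAA"])
        with pytest.raises(ValueError, match="k_bar = 0"):
            dem.fu_fs(aln, seed=1, n_sim=10)

    def test_expansion_sample_strongly_negative(self):
        model = cs.DemographyModel(kind="sudden_expansion", theta0=0.1,
                                   theta1=500.0, tau=6.0)
        aln = cs.simulate_alignment(model, cs.SimConfig(n=40, L=1000, seed=6))
        r = dem.fu_fs(aln, seed=2, n_sim=200)
        assert r.Fs < -5
        assert r.p_Fs < 0.05


class TestR2:
    def test_pair_single_difference_hand_value(self):
        # n=2, S=1, k_bar=1: U deviations from k_bar/2 are +-1/2 either way
        aln = mp.Alignment(["a", "b"], ["AAAA", "AAAT"])
        r = dem.r2_test(aln, seed=1, n_sim=10)
        assert r.R2 == pytest.approx(0.5)
        assert r.S == 1 and r.k_bar == 1.0

    def test_star_pattern_closed_form(self):
        # every sequence carries exactly one private mutation
        base = "A" * 6
        seqs = []
        for i in range(5):
            s = list(base)
            s[i] = "G"
            seqs.append("".join(s))
        aln = mp.Alignment([f"s{i}" for i in range(5)], seqs)
        U, S = dem._singletons_per_sequence(aln)
        assert list(U) == [1] * 5 and S == 5
        k_bar = float(np.mean(dem.pairwise_differences(aln)))
        expected = math.sqrt(np.mean((U - k_bar / 2) ** 2)) / S
        r = dem.r2_test(aln, seed=1, n_sim=10)
        assert r.R2 == pytest.approx(expected)

    def test_no_segregating_sites_rejected(self):
        aln = mp.Alignment(["a", "b"], ["AAAA", "AAAA"])
        with pytest.raises(ValueError, match="no segregating"):
            dem.r2_test(aln, seed=1, n_sim=10)

    def test_expansion_sample_small_r2(self):
        model = cs.DemographyModel(kind="sudden_expansion", theta0=0.1,
                                   theta1=500.0, tau=6.0)
        aln = cs.simulate_alignment(model, cs.SimConfig(n=40, L=1000, seed=6))
        r = dem.r2_test(aln, seed=2, n_sim=200)
        assert r.p_R2 < 0.05


class TestDating:
    CAL = dem.RateCalibration(clade_divergence_K2P=0.031, divergence_time=620_000,
                              L=1140, generation_time=1.0)

    def test_rate_algebra(self):
        assert self.CAL.mu == pytest.approx(2.5e-8)
        assert self.CAL.u == pytest.approx(5.7e-5)

    def test_zero_tau(self):
        t, _ = dem.date_expansion(0.0, self.CAL)
        assert t == 0.0

    @pytest.mark.parametrize("tau,mya", [(4.389, 0.039), (7.343, 0.064),
                                         (4.335, 0.038)])
    def test_point_estimates(self, tau, mya):
        t, _ = dem.date_expansion(tau, self.CAL)
        assert dem.years_to_mya(t) == pytest.approx(mya, abs=1e-3)

    @pytest.mark.parametrize("tau,mya", [(10.094, 0.089), (2.672, 0.023),
                                         (5.389, 0.047)])
    def test_interval_bounds(self, tau, mya):
        t, _ = dem.date_expansion(tau, self.CAL)
        assert dem.years_to_mya(t) == pytest.approx(mya, abs=1e-3)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 50), st.floats(0.1, 10))
    def test_linearity_in_tau(self, tau, a):
        t1, _ = dem.date_expansion(tau, self.CAL)
        t2, _ = dem.date_expansion(a * tau, self.CAL)
        assert t2 == pytest.approx(a * t1, rel=1e-9)

    def test_ci_transforms_identically(self):
        t, ci = dem.date_expansion(4.389, self.CAL, (3.172, 5.389))
        assert dem.years_to_mya(ci[0]) == pytest.approx(0.028, abs=1e-3)
        assert dem.years_to_mya(ci[1]) == pytest.approx(0.047, abs=1e-3)

    def test_bad_calibration_rejected(self):
        with pytest.raises(ValueError):
            dem.RateCalibration(0.0, 620_000, 1140, 1.0)
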