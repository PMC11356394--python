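"""Mismatch distributions, sudden-expansion fitting, Fu's Fs, expansion times."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

import sympy

from mitopop.demography import (MismatchDistribution, SuddenExpansionModel,
                                equilibrium_mismatch, ewens_log_pmf,
                                expansion_time, expected_mismatch,
                                fus_fs, harpending_raggedness,
                                mismatch_distribution, ssd)
from mitopop.errors import DomainError, InsufficientDataError
from mitopop.haplotypes import collapse_haplotypes
from mitopop.simulate import simulate_expansion_sample

from conftest import make_alignment


class TestMismatchDistribution:
    def test_identical_sequences_mass_at_zero(self):
        t = collapse_haplotypes(make_alignment(["ACGT", "ACGT"]))
        d = mismatch_distribution(t)
        assert d.freq[0] == 1.0
        assert d.n_pairs == 1

    def test_single_sample_rejected(self):
        t = collapse_haplotypes(make_alignment(["ACGT"]))
        with pytest.raises(InsufficientDataError):
            mismatch_distribution(t)

    def test_matches_brute_force_pair_enumeration(self):
        seqs = ["AAAA", "AAAC", "AACC", "GGGG"]
        t = collapse_haplotypes(make_alignment(seqs))
        d = mismatch_distribution(t)
        diffs = [sum(a != b for a, b in zip(s1, s2))
                 for s1, s2 in itertools.combinations(seqs, 2)]
        expected = np.bincount(diffs, minlength=len(d.freq)) / len(diffs)
        np.testing.assert_allclose(d.freq, expected)

    def test_two_clusters_second_mode_at_eleven(self):
        # two haplotypes separated by 11 sites, balanced counts: half of the
        # cross pairs differ by 11
        a = "A" * 11 + "C" * 9
        b = "G" * 11 + "C" * 9
        t = collapse_haplotypes(make_alignment([a] * 4 + [b] * 4))
        d = mismatch_distribution(t)
        assert d.d_max == 11
        assert d.freq[11] == pytest.approx((4 * 4) / 28)
        interior = d.freq[1:11]
        assert np.all(interior < d.freq[11])


class TestExpectedMismatch:
    def test_tau_zero_is_equilibrium(self):
        f = expected_mismatch(0.0, 1.5, d_max=60)
        i = np.arange(61)
        expect = equilibrium_mismatch(1.5, i)
        expect[-1] += 1 - expect.sum()
        np.testing.assert_allclose(f.freq, expect / expect.sum(), atol=1e-12)

    def test_theta0_zero_is_poisson(self):
        f = expected_mismatch(3.0, 0.0, d_max=60)
        np.testing.assert_allclose(f.freq[:40], stats.poisson.pmf(np.arange(40), 3.0),
                                   atol=1e-9)

    @pytest.mark.parametrize("tau,theta0", [(0.5, 0.2), (3.0, 1.0), (8.0, 4.0)])
    def test_normalizes_and_mean_is_tau_plus_theta0(self, tau, theta0):
        f = expected_mismatch(tau, theta0, d_max=200)
        assert f.freq.sum() == pytest.approx(1.0, abs=1e-12)
        assert f.mean == pytest.approx(tau + theta0, rel=1e-6)

    def test_finite_theta1_limits(self):
        # large theta1 approaches the theta1=inf model
        inf_model = expected_mismatch(2.0, 0.5, d_max=80)
        big = expected_mismatch(2.0, 0.5, theta1=1e7, d_max=80)
        np.testing.assert_allclose(big.freq, inf_model.freq, atol=1e-5)
        # tau = 0 puts the size change at the present: the whole pairwise
        # history sits in the ancestral epoch, so theta0 equilibrium results
        eq = expected_mismatch(0.0, 0.5, theta1=2.0, d_max=80)
        i = np.arange(81)
        expect = equilibrium_mismatch(0.5, i)
        expect[-1] += 1 - expect.sum()
        np.testing.assert_allclose(eq.freq, expect / expect.sum(), atol=1e-10)

    def test_negative_parameters_rejected(self):
        with pytest.raises(DomainError):
            expected_mismatch(-1.0, 0.5)


class TestRaggedness:
    def test_uniform_closed_form(self):
        for k in range(1, 6):
            freq = np.full(k + 1, 1.0 / (k + 1))
            d = MismatchDistribution(freq, 10, 5)
            assert harpending_raggedness(d) == pytest.approx(2.0 / (k + 1) ** 2)

    def test_point_mass_at_zero(self):
        d = MismatchDistribution(np.array([1.0]), 1, 2)
        assert harpending_raggedness(d) == pytest.approx(2.0)

    def test_matches_brute_force_sum(self, rng):
        x = rng.dirichlet(np.ones(9))
        padded = [0.0] + list(x) + [0.0]
        brute = sum((padded[i + 1] - padded[i]) ** 2 for i in range(len(padded) - 1))
        assert harpending_raggedness(np.array(x)) == pytest.approx(brute)


class TestSuddenExpansionFit:
    def test_recovers_exact_model_input(self):
        obs = expected_mismatch(3.0, 1.0, d_max=60)
        obs = MismatchDistribution(obs.freq, n_pairs=1225, n_samples=50)
        res = SuddenExpansionModel(obs).fit(n_boot=0)
        assert res.ssd < 1e-6
        assert res.tau == pytest.approx(3.0, abs=0.05)
        assert res.theta0 == pytest.approx(1.0, abs=0.05)

    def test_ssd_zero_when_obs_equals_expected(self):
        f = expected_mismatch(2.0, 0.5, d_max=40)
        assert ssd(f.freq, f.freq) == 0.0

    def test_degenerate_all_mass_at_zero(self):
        obs = MismatchDistribution(np.array([1.0]), 10, 5)
        res = SuddenExpansionModel(obs).fit(n_boot=0)
        assert res.tau == 0.0

    def test_bootstrap_reproducible_and_ci_contains_estimate(self):
        aln, _ = simulate_expansion_sample(30, L=274, tau=3.0, theta0=0.5, seed=11)
        t = collapse_haplotypes(aln)
        obs = mismatch_distribution(t)
        r1 = SuddenExpansionModel(obs).fit(n_boot=30, seed=5)
        r2 = SuddenExpansionModel(obs).fit(n_boot=30, seed=5)
        assert r1.tau == r2.tau
        assert r1.p_ssd == r2.p_ssd and r1.tau_ci == r2.tau_ci
        assert r1.tau_ci[0] <= r1.tau <= r1.tau_ci[1]
        assert 0 < r1.p_ssd <= 1 and 0 < r1.p_hri <= 1

    def test_fit_invariant_to_sequence_order(self, rng):
        aln, _ = simulate_expansion_sample(20, L=274, tau=2.0, theta0=0.5, seed=3)
        seqs = [r.bases for r in aln.records]
        perm = list(rng.permutation(len(seqs)))
        t1 = collapse_haplotypes(make_alignment(seqs))
        t2 = collapse_haplotypes(make_alignment([seqs[i] for i in perm]))
        f1 = SuddenExpansionModel(mismatch_distribution(t1)).fit(n_boot=0)
        f2 = SuddenExpansionModel(mismatch_distribution(t2)).fit(n_boot=0)
        assert f1.tau == pytest.approx(f2.tau)

    def test_summary_lists_parameters(self):
        obs = expected_mismatch(1.0, 0.3, d_max=30)
        obs = MismatchDistribution(obs.freq, 45, 10)
        res = SuddenExpansionModel(obs).fit(n_boot=0)
        s = res.summary()
        assert {"tau", "theta0", "SSD"} <= set(s["parameter"])


class TestFusFs:
    def test_ewens_normalizes_up_to_n50(self):
        for n in (4, 10, 25, 50):
            logp = ewens_log_pmf(n, 2.3)
            assert np.exp(logp).sum() == pytest.approx(1.0, rel=1e-10)

    def test_stirling_row_matches_sympy(self):
        # independent oracle for the Ewens weights at N=4, theta=1:
        # {|s(4,k)|} = {6, 11, 6, 1}, normalizer 4! = 24
        logp = ewens_log_pmf(4, 1.0)
        expected = np.array([0, 6, 11, 6, 1]) / 24
        np.testing.assert_allclose(np.exp(logp), expected, atol=1e-12)
        for n in range(2, 9):
            mine = np.exp(ewens_log_pmf(n, 0.7))
            oracle = np.array([
                float(sympy.functions.combinatorial.numbers.stirling(
                    n, k, kind=1, signed=False)) * 0.7 ** k
                for k in range(n + 1)
            ])
            oracle /= oracle.sum()
            np.testing.assert_allclose(mine, oracle, rtol=1e-10)

    def test_s_prime_matches_exhaustive_summation(self):
        for n in range(2, 9):
            theta = 1.7
            pmf = np.exp(ewens_log_pmf(n, theta))
            for k_obs in range(2, n + 1):
                res = fus_fs(n, k_obs, theta, n_sim=0)
                assert res.s_prime == pytest.approx(pmf[k_obs:].sum(), rel=1e-10)
                expect_fs = math.log(res.s_prime / (1 - res.s_prime))
                assert res.fs == pytest.approx(expect_fs, rel=1e-9)

    def test_undefined_cases(self):
        assert math.isnan(fus_fs(10, 1, 2.0, n_sim=0).fs)
        assert math.isnan(fus_fs(10, 5, 0.0, n_sim=0).fs)

    def test_star_like_expansion_gives_negative_fs(self):
        # strong expansion: many haplotypes, shallow pairwise differences
        aln, _ = simulate_expansion_sample(50, L=274, tau=3.0, theta0=0.1, seed=21)
        t = collapse_haplotypes(aln)
        obs = mismatch_distribution(t)
        res = fus_fs(50, t.n_haplotypes, obs.mean, n_sim=200, seed=9)
        assert res.fs < 0
        assert res.p < 0.05


class TestExpansionTime:
    def test_zero_tau(self):
        assert expansion_time(0.0).years == 0.0

    def test_linearity(self):
        assert expansion_time(2.0).years == pytest.approx(2 * expansion_time(1.0).years)

    def test_printed_conversion(self):
        # tau = 0.24034 with mu = 6.13e-8 /site/year over 274 sites
        est = expansion_time(0.24034)
        assert est.years == pytest.approx(0.24034 / (2 * 6.13e-8 * 274), rel=1e-12)
        assert est.years == pytest.approx(7154, abs=1.0)

    def test_years_independent_of_generation_interval(self):
        assert expansion_time(1.0, gen_years=8).years == pytest.approx(
            expansion_time(1.0, gen_years=5).years)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            expansion_time(-1.0)
        with pytest.raises(DomainError):
            expansion_time(1.0, mu_site_year=0.0)
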