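"""The alignment core: similarity, DP recursion, traceback, interpolation."""

import itertools
import math

import numpy as np
import pytest

import tickertape as tt
from tickertape.align import (
    InfeasibleAlignmentError,
    _accumulate_looped,
    accumulate,
    bin_errors,
    build_binned_similarity,
    build_similarity,
    decimate_template,
    interpolate_alignment,
    traceback,
)
from tickertape.dnap import LagPrior
from tickertape.traces import TimeTrace


def make_prior(log_pmf):
    lp = np.asarray(log_pmf, dtype=float)
    return LagPrior(lp - np.log(np.exp(lp).sum()), float(lp.size), 1.0)


def brute_force_best_path(A, log_pmf, omega):
    """Exhaustive enumeration over strictly increasing paths with bounded
    lags, applying the DP recursion to each path.  Continuous random inputs
    make score ties a measure-zero event, so a strict comparison suffices.
    """
    N, T = A.shape
    J = log_pmf.size
    best_score, best_path = -np.inf, None
    for path in itertools.combinations(range(T), N):
        if N > 1 and max(np.diff(path)) > J:
            continue
        s = A[0, path[0]]
        ok = True
        for n in range(1, N):
            lp = log_pmf[path[n] - path[n - 1] - 1]
            if lp == -np.inf:
                ok = False
                break
            s = A[n, path[n]] + (1 - omega) * s + omega * lp
        if ok and s > best_score + 1e-12:
            best_score, best_path = s, path
    return best_score, best_path


class TestBuildSimilarity:
    def test_entries_are_bernoulli_log_likelihoods(self):
        tpl = TimeTrace(np.zeros(4), 1.0)
        f = tt.ErrorFunction(0.5, 1.0, 0.0)  # f(0) = 0.25
        A = build_similarity(np.array([1, 0]), tpl, f)
        assert np.allclose(A[0], math.log(0.25))
        assert np.allclose(A[1], math.log(0.75))

    def test_constant_template_gives_constant_rows(self, rng):
        tpl = TimeTrace(np.full(7, 0.3), 1.0)
        A = build_similarity((rng.random(5) < 0.5).astype(int), tpl, tt.ErrorFunction(0.4, 2.0, 0.1))
        assert np.allclose(A, A[:, :1])

    def test_entries_nonpositive_and_finite(self, rng):
        tpl = TimeTrace(rng.normal(size=50), 1.0)
        A = build_similarity((rng.random(9) < 0.5).astype(int), tpl, tt.ErrorFunction(0.5, -1.0, 0.0))
        assert np.all(A <= 0) and np.all(np.isfinite(A))


class TestBinErrors:
    def test_hand_sums(self):
        counts, sizes = bin_errors(np.array([1, 0, 1, 1]), 2)
        assert counts.tolist() == [1, 2] and sizes.tolist() == [2, 2]

    def test_partial_last_bin(self):
        counts, sizes = bin_errors(np.array([1, 0, 1]), 2)
        assert counts.tolist() == [1, 1] and sizes.tolist() == [2, 1]

    def test_total_conserved(self, rng):
        d = (rng.random(137) < 0.3).astype(int)
        counts, sizes = bin_errors(d, 10)
        assert counts.sum() == d.sum() and sizes.sum() == 137


class TestBuildBinnedSimilarity:
    def test_reduces_to_bernoulli_at_unit_bins(self, rng):
        tpl = TimeTrace(rng.normal(size=20), 1.0)
        f = tt.ErrorFunction(0.5, -1.0, 0.0)
        d = (rng.random(6) < 0.5).astype(int)
        counts, sizes = bin_errors(d, 1)
        assert np.allclose(
            build_binned_similarity(counts, tpl, f, sizes), build_similarity(d, tpl, f)
        )

    def test_binomial_closed_form(self):
        tpl = TimeTrace(np.zeros(3), 1.0)
        f = tt.ErrorFunction(0.5, 1.0, 0.0)  # p = 0.25 everywhere
        A = build_binned_similarity(np.array([0]), tpl, f, np.array([4]))
        assert np.allclose(A, 4 * math.log(0.75))

    def test_extreme_count_floored_finite(self):
        tpl = TimeTrace(np.full(3, 1e4), 1.0)
        f = tt.ErrorFunction(0.5, -1.0, 0.0)  # f ~ 0.5 here; use opposite side
        A = build_binned_similarity(np.array([5]), TimeTrace(np.full(3, -1e4), 1.0), f, np.array([5]))
        assert np.all(np.isfinite(A))  # ln eps floor, never -inf

    def test_count_above_bin_size_rejected(self):
        tpl = TimeTrace(np.zeros(3), 1.0)
        with pytest.raises(ValueError):
            build_binned_similarity(np.array([3]), tpl, tt.ErrorFunction(0.5, 1, 0), np.array([2]))


class TestDecimateTemplate:
    def test_constant_trace_unchanged_values(self):
        out = decimate_template(TimeTrace(np.full(12, 2.5), 10.0), 40.0)
        assert np.allclose(out.values, 2.5) and len(out) == 3

    def test_identity_at_native_period(self):
        tpl = TimeTrace(np.arange(6, dtype=float), 10.0)
        out = decimate_template(tpl, 10.0)
        assert np.array_equal(out.values, tpl.values)

    def test_block_means_by_hand(self):
        out = decimate_template(TimeTrace(np.array([0.0, 2.0, 4.0, 6.0]), 1.0), 2.0)
        assert out.values.tolist() == [1.0, 5.0]
        assert out.t0_ms == pytest.approx(0.5)  # midpoints

    def test_non_divisible_period_rejected(self):
        with pytest.raises(ValueError):
            decimate_template(TimeTrace(np.zeros(10), 3.0), 10.0)


class TestAccumulateAndTraceback:
    def test_single_row_is_initialization(self, rng):
        A = rng.normal(size=(1, 8))
        S, bp = accumulate(A, make_prior(np.zeros(3)), 0.2)
        assert np.allclose(S, A) and np.all(bp == -1)
        aln = traceback(S, bp)
        assert aln.sample_indices[0] == np.argmax(A[0])

    def test_init_log_prior_hook(self, rng):
        A = rng.normal(size=(1, 5))
        init = rng.normal(size=5)
        S, _ = accumulate(A, make_prior(np.zeros(2)), 0.1, init_log_prior=init)
        assert np.allclose(S[0], A[0] + init)

    def test_matches_enumeration_oracle(self):
        """For all random instances with N <= 4, T <= 12, J <= 5 the DP and
        traceback reproduce the exhaustive-enumeration optimum exactly."""
        rng = np.random.default_rng(42)
        for _ in range(150):
            N = int(rng.integers(1, 5))
            T = int(rng.integers(N, 13))
            J = int(rng.integers(1, 6))
            omega = float(rng.uniform(0, 0.9))
            A = rng.normal(size=(N, T))
            lp = np.log(rng.dirichlet(np.ones(J)))
            S, bp = accumulate(A, make_prior(lp), omega)
            aln = traceback(S, bp)
            score, path = brute_force_best_path(A, make_prior(lp).log_pmf, omega)
            assert aln.log_likelihood == pytest.approx(score, abs=1e-9)
            assert tuple(aln.sample_indices) == path

    def test_row_parallel_contract(self):
        """Vectorized row computation equals the sequential loop to 1e-12
        on random 50 x 500 instances."""
        rng = np.random.default_rng(7)
        for trial in range(3):
            A = rng.normal(size=(50, 500))
            lp = np.log(rng.dirichlet(np.ones(25)))
            omega = float(rng.uniform(0, 0.5))
            prior = make_prior(lp)
            S_vec, bp_vec = accumulate(A, prior, omega, engine="vectorized")
            S_loop, bp_loop, _ = _accumulate_looped(A, prior.log_pmf, omega, None)
            finite = np.isfinite(S_vec)
            assert np.array_equal(finite, np.isfinite(S_loop))
            assert np.max(np.abs(S_vec[finite] - S_loop[finite])) <= 1e-12
            assert np.array_equal(bp_vec, bp_loop)

    def test_lag_evaluation_count_scales_as_ntk(self):
        """Operation count equals the number of admissible (cell, lag)
        pairs: O(N T k)."""
        rng = np.random.default_rng(0)
        for N, T, J in [(4, 30, 5), (8, 60, 10)]:
            A = rng.normal(size=(N, T))
            lp = np.log(rng.dirichlet(np.ones(J)))
            _, _, ops = _accumulate_looped(A, make_prior(lp).log_pmf, 0.1, None)
            expected = (N - 1) * sum(min(J, t) for t in range(T))
            assert ops == expected
            assert ops <= N * T * J

    def test_excluded_lags_never_used(self, rng):
        lp = np.array([-np.inf, math.log(0.5), math.log(0.5)])
        A = rng.normal(size=(4, 30))
        S, bp = accumulate(A, LagPrior(lp, 3.0, 1.0), 0.3)
        aln = traceback(S, bp)
        assert np.all(np.diff(aln.sample_indices) >= 2)  # lag 1 is banned

    def test_infeasible_shapes_raise(self, rng):
        with pytest.raises(InfeasibleAlignmentError):
            accumulate(rng.normal(size=(5, 3)), make_prior(np.zeros(2)), 0.1)

    def test_traceback_on_all_infeasible_row_raises(self):
        S = np.full((2, 4), -np.inf)
        bp = np.full((2, 4), -1)
        with pytest.raises(InfeasibleAlignmentError):
            traceback(S, bp)

    def test_strictly_increasing_paths(self, rng):
        for _ in range(10):
            A = rng.normal(size=(6, 40))
            lp = np.log(rng.dirichlet(np.ones(8)))
            S, bp = accumulate(A, make_prior(lp), 0.2)
            aln = traceback(S, bp)
            assert np.all(np.diff(aln.sample_indices) >= 1)
            assert aln.sample_indices.size == 6


class TestInterpolateAlignment:
    def test_unit_bins_identity(self):
        aln = tt.Alignment(np.array([10.0, 30.0, 70.0]), -1.0)
        out = interpolate_alignment(aln, 1, 3, sample_period_ms=10.0)
        assert np.allclose(out.times_ms, aln.times_ms)

    def test_two_bins_even_spacing(self):
        aln = tt.Alignment(np.array([0.0, 100.0]), -1.0)
        out = interpolate_alignment(aln, 2, 4, sample_period_ms=50.0)
        assert np.all(np.diff(out.times_ms) > 0)
        # anchors at nucleotide indices 0.5 and 2.5 -> slope 50 ms/nt
        assert np.allclose(out.times_ms, [-25.0, 25.0, 75.0, 125.0])

    def test_strictly_increasing_on_random_inputs(self, rng):
        for _ in range(20):
            n_bins = int(rng.integers(2, 9))
            times = np.sort(rng.uniform(0, 1e4, n_bins))
            times += np.arange(n_bins)  # ensure strict increase
            aln = tt.Alignment(times, -1.0)
            out = interpolate_alignment(aln, 5, 5 * n_bins, sample_period_ms=50.0)
            assert out.times_ms.size == 5 * n_bins
            assert np.all(np.diff(out.times_ms) > 0)


class TestAlignEndToEnd:
    def test_binned_unit_downsample_equals_full(self, rng):
        tpl = TimeTrace(rng.normal(size=300), 50.0)
        f = tt.ErrorFunction(0.5, -1.0, 0.0)
        kin = tt.KineticModel(0.001, 2000.0, 1.0, 10.0)
        cfg = tt.AlignmentConfig(omega=0.01, k_ms=2000.0, calcium_downsample_ms=50.0, dna_downsample=1)
        errors = (rng.random(40) < 0.3).astype(np.uint8)
        a_binned = tt.align(errors, tpl, f, kin, cfg, mode="binned")
        a_full = tt.align(errors, tpl, f, kin, cfg, mode="full")
        assert np.allclose(a_binned.times_ms, a_full.times_ms)
        assert a_binned.log_likelihood == pytest.approx(a_full.log_likelihood)

    def test_self_alignment_recovers_timing(self):
        """A strand simulated from a template with a sharp error sigmoid and
        no pausing aligns back with sub-feature timing error."""
        rng = np.random.default_rng(3)
        levels = rng.uniform(0, 1, 60)
        tpl_raw = TimeTrace(np.repeat(levels, 100), 50.0)  # 5 s features, 300 s
        tpl = tpl_raw.standardize()
        f = tt.ErrorFunction(0.5, -3.0, 0.0)
        kin = tt.KineticModel(0.0, 1.0, 1.0, 30.0)
        times = tt.sample_incorporation_times(
            kin, tpl.duration_ms, tt.StartPrior(0, tpl.duration_ms / 4), 2000, seed=4
        )
        rec = tt.sample_errors(tpl, times, f, seed=5)
        cfg = tt.AlignmentConfig(omega=0.01, k_ms=2000.0, calcium_downsample_ms=50.0, dna_downsample=20)
        aln = tt.align(rec.errors, tpl, f, kin, cfg)
        median_err_ms = np.median(np.abs(aln.times_ms - rec.true_times_ms))
        assert median_err_ms < 5000.0  # below the 5 s feature timescale

    def test_sensitive_to_template_block_shuffling(self):
        """Permuting template blocks changes the selected path."""
        rng = np.random.default_rng(9)
        levels = rng.uniform(0, 1, 40)
        tpl = TimeTrace(np.repeat(levels, 100), 50.0).standardize()
        perm = rng.permutation(40)
        tpl_shuf = TimeTrace(np.repeat(levels[perm], 100), 50.0).standardize()
        f = tt.ErrorFunction(0.5, -3.0, 0.0)
        kin = tt.KineticModel(0.0, 1.0, 1.0, 30.0)
        times = tt.sample_incorporation_times(
            kin, tpl.duration_ms, tt.StartPrior(0, tpl.duration_ms / 4), 1500, seed=1
        )
        rec = tt.sample_errors(tpl, times, f, seed=2)
        cfg = tt.AlignmentConfig(omega=0.01, k_ms=2000.0, calcium_downsample_ms=50.0, dna_downsample=20)
        a = tt.align(rec.errors, tpl, f, kin, cfg)
        b = tt.align(rec.errors, tpl_shuf, f, kin, cfg)
        assert not np.allclose(a.times_ms, b.times_ms)

    def test_deterministic(self, rng):
        tpl = TimeTrace(rng.normal(size=400), 50.0)
        f = tt.ErrorFunction(0.5, -1.0, 0.0)
        kin = tt.KineticModel(0.001, 2000.0, 1.0, 10.0)
        cfg = tt.AlignmentConfig(dna_downsample=10)
        errors = (rng.random(100) < 0.3).astype(np.uint8)
        a = tt.align(errors, tpl, f, kin, cfg)
        b = tt.align(errors, tpl, f, kin, cfg)
        assert np.array_equal(a.times_ms, b.times_ms)
        assert a.log_likelihood == b.log_likelihood


class TestGeneratingTemplatePreferred:
    def test_sign_test_generating_vs_phase_opposed(self):
        """Alignment log-likelihood of the generating template exceeds that
        of a phase-opposed template in most of >= 20 seeded records."""
        rng = np.random.default_rng(11)
        levels = rng.uniform(0, 1, 40)
        tpl = TimeTrace(np.repeat(levels, 100), 50.0).standardize()
        opposed = TimeTrace(-tpl.values, 50.0)
        f = tt.ErrorFunction(0.5, -1.0, 0.0)
        kin = tt.KineticModel(0.0, 1.0, 1.0, 30.0)
        cfg = tt.AlignmentConfig(omega=0.01, k_ms=2000.0, calcium_downsample_ms=50.0, dna_downsample=20)
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            times = tt.sample_incorporation_times(
                kin, tpl.duration_ms, tt.StartPrior(0, tpl.duration_ms / 4), 1200, seed=100 + seed
            )
            rec = tt.sample_errors(tpl, times, f, seed=200 + seed)
            ll_gen = tt.align(rec.errors, tpl, f, kin, cfg).log_likelihood
            ll_opp = tt.align(rec.errors, opposed, f, kin, cfg).log_likelihood
            wins += ll_gen > ll_opp
        from scipy import stats

        assert stats.binomtest(wins, n_seeds, alternative="greater").pvalue < 0.05
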