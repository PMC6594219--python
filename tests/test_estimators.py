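"""Estimator correctness against analytic harmonic ground truth."""

import numpy as np
import pytest
from scipy.optimize import minimize

import ionsolv as iv
from ionsolv.estimators import (
    CannotSplitError,
    NonOverlapError,
    ReducedEnergyMatrix,
    split_trials,
)


def reference_mbar(u, n_k):
    """Independent MBAR oracle: minimize the convex log-likelihood directly.

    A different algorithm (quasi-Newton on the objective) from the package
    solver (self-consistent iteration + Newton on the gradient).
    """
    n_k = np.asarray(n_k, dtype=float)
    sampled = n_k > 0

    def objective(f_free):
        f = np.concatenate([[0.0], f_free])
        a = np.log(n_k[sampled])[None, :] + f[sampled][None, :] - u[:, sampled]
        amax = a.max(axis=1, keepdims=True)
        logden = amax[:, 0] + np.log(np.exp(a - amax).sum(axis=1))
        return logden.sum() - (n_k * f).sum()

    res = minimize(objective, np.zeros(u.shape[1] - 1), method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 2000})
    return np.concatenate([[0.0], res.x])


def two_state_matrix(delta=0.0, n=50):
    """Two identical (or constant-shifted) states."""
    rng = np.random.default_rng(0)
    base = rng.normal(size=2 * n)
    u = np.column_stack([base, base + delta])
    return ReducedEnergyMatrix(u, np.array([n, n]), ["a", "b"])


class TestExpAveraging:
    def test_identical_states_give_zero(self):
        m = two_state_matrix()
        assert iv.exp_averaging(m, 0, 1) == pytest.approx(0.0, abs=1e-14)

    def test_constant_shift_recovered_exactly(self):
        m = two_state_matrix(delta=3.7)
        assert iv.exp_averaging(m, 0, 1) == pytest.approx(3.7, abs=1e-12)

    def test_harmonic_ladder_recovers_half_log_k_ratio(self, thermo):
        # forward EXP from the broad state; SE estimated across seeds
        errs = []
        for seed in range(6):
            spec = iv.HarmonicAlchemySpec(k=(1.0, 4.0), n_samples=100_000, seed=seed)
            m, analytic = iv.gen_harmonic_alchemy(spec, thermo)
            errs.append(iv.exp_averaging(m, 0, 1) - analytic[1])
        errs = np.array(errs)
        se = errs.std(ddof=1) / np.sqrt(len(errs))
        assert abs(errs.mean()) < 3 * se + 1e-3

    def test_empty_sample_set_errors(self):
        m = ReducedEnergyMatrix(np.zeros((4, 2)), np.array([0, 4]))
        with pytest.raises(iv.core.InvalidSpecError):
            iv.exp_averaging(m, 0, 1)


class TestBarPair:
    def test_identical_states_give_zero(self):
        m = two_state_matrix()
        assert iv.bar_pair(m, 0, 1) == pytest.approx(0.0, abs=1e-9)

    def test_harmonic_recovery_within_3se(self, thermo):
        errs = []
        for seed in range(6):
            spec = iv.HarmonicAlchemySpec(k=(1.0, 4.0), n_samples=20_000, seed=seed)
            m, analytic = iv.gen_harmonic_alchemy(spec, thermo)
            errs.append(iv.bar_pair(m, 0, 1) - analytic[1])
        errs = np.array(errs)
        se = errs.std(ddof=1) / np.sqrt(len(errs))
        assert abs(errs.mean()) < 3 * se + 1e-3

    def test_matches_two_state_mbar_to_1e6(self, thermo):
        spec = iv.HarmonicAlchemySpec(k=(1.0, 3.0), n_samples=5000, seed=5)
        m, _ = iv.gen_harmonic_alchemy(spec, thermo)
        bar = iv.bar_pair(m, 0, 1, tol=1e-12)
        mbar = iv.mbar_solve(m, tol=1e-12)
        assert bar == pytest.approx(mbar.f[1], abs=1e-6)

    def test_antisymmetric_under_state_swap(self, thermo):
        spec = iv.HarmonicAlchemySpec(k=(1.0, 2.5), n_samples=3000, seed=6)
        m, _ = iv.gen_harmonic_alchemy(spec, thermo)
        assert iv.bar_pair(m, 0, 1) == pytest.approx(-iv.bar_pair(m, 1, 0), abs=1e-8)

    def test_non_overlapping_states_error(self):
        rng = np.random.default_rng(1)
        n = 100
        # state b sits 200 reduced units above state a everywhere, and vice versa
        u = np.zeros((2 * n, 2))
        u[:n, 1] = 200.0 + rng.normal(size=n)
        u[n:, 0] = 200.0 + rng.normal(size=n)
        m = ReducedEnergyMatrix(u, np.array([n, n]))
        with pytest.raises(NonOverlapError):
            iv.bar_pair(m, 0, 1)


class TestMbar:
    def test_identical_states_give_zero_vector(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=90)
        u = np.column_stack([base, base, base])
        m = ReducedEnergyMatrix(u, np.array([30, 30, 30]))
        r = iv.mbar_solve(m)
        assert np.allclose(r.f, 0.0, atol=1e-10)

    def test_three_state_harmonic_within_3se(self, thermo):
        # per-state SE from the spread across 8 seeds
        ests = []
        for seed in range(8):
            spec = iv.HarmonicAlchemySpec(k=(1.0, 2.0, 4.0), n_samples=50_000,
                                          seed=100 + seed)
            m, analytic = iv.gen_harmonic_alchemy(spec, thermo)
            ests.append(iv.mbar_solve(m).f)
        ests = np.array(ests)
        se = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
        err = ests.mean(axis=0) - analytic
        assert abs(err[1]) < 3 * se[1] + 1e-3
        assert abs(err[2]) < 3 * se[2] + 1e-3

    def test_matches_independent_reference_to_1e6(self, harmonic_124):
        m, _ = harmonic_124
        ours = iv.mbar_solve(m, tol=1e-12)
        ref = reference_mbar(m.u, m.n_k)
        assert np.max(np.abs(ours.f - ref)) < 1e-6

    def test_gauge_invariance_column_shift(self, thermo):
        spec = iv.HarmonicAlchemySpec(k=(1.0, 2.0, 4.0), n_samples=2000, seed=9)
        m, _ = iv.gen_harmonic_alchemy(spec, thermo)
        f0 = iv.mbar_solve(m, tol=1e-10).f
        shifted = m.u.copy()
        shifted[:, 1] += 2.5
        m2 = ReducedEnergyMatrix(shifted, m.n_k, m.labels)
        f1 = iv.mbar_solve(m2, tol=1e-10).f
        assert f1[1] - f0[1] == pytest.approx(2.5, abs=1e-7)
        assert f1[2] == pytest.approx(f0[2], abs=1e-7)

    def test_state_order_independence(self, thermo):
        spec = iv.HarmonicAlchemySpec(k=(1.0, 2.0, 4.0), n_samples=2000, seed=12)
        m, _ = iv.gen_harmonic_alchemy(spec, thermo)
        f = iv.mbar_solve(m, tol=1e-10).f
        # permute states 1 and 2 (columns and sample blocks)
        blocks = [m.rows_from(k) for k in range(3)]
        perm = [0, 2, 1]
        u2 = np.vstack([blocks[k][:, perm] for k in perm])
        m2 = ReducedEnergyMatrix(u2, m.n_k[perm])
        f2 = iv.mbar_solve(m2, tol=1e-10).f
        assert f2[1] == pytest.approx(f[2], abs=1e-7)
        assert f2[2] == pytest.approx(f[1], abs=1e-7)

    def test_zero_sample_state_is_evaluation_only(self, thermo):
        spec = iv.HarmonicAlchemySpec(k=(1.0, 2.0, 4.0),
                                      n_samples=(4000, 4000, 1), seed=14)
        m, analytic = iv.gen_harmonic_alchemy(spec, thermo)
        # drop state 2's sample: becomes evaluation-only
        u = np.vstack([m.rows_from(0), m.rows_from(1), m.rows_from(2)[:0]])
        m2 = ReducedEnergyMatrix(u, np.array([4000, 4000, 0]), m.labels)
        r = iv.mbar_solve(m2)
        assert r.f[1] == pytest.approx(analytic[1], abs=0.05)
        assert np.isfinite(r.f[2])

    def test_path_independence_mbar_vs_adjacent_bar(self, harmonic_124):
        m, _ = harmonic_124
        mbar = iv.mbar_solve(m).delta_f
        bar_sum = iv.bar_pair(m, 0, 1) + iv.bar_pair(m, 1, 2)
        assert mbar == pytest.approx(bar_sum, abs=0.01)


class TestTrials:
    def test_even_split_preserves_order(self):
        u = np.arange(40, dtype=float).reshape(20, 2)
        m = ReducedEnergyMatrix(u, np.array([10, 10]))
        a, b = split_trials(m)
        assert list(a.n_k) == [5, 5] and list(b.n_k) == [5, 5]
        assert np.array_equal(a.rows_from(0), u[:5])
        assert np.array_equal(b.rows_from(0), u[5:10])

    def test_odd_split_uses_ceiling(self):
        u = np.zeros((22, 2))
        m = ReducedEnergyMatrix(u, np.array([11, 11]))
        a, b = split_trials(m)
        assert list(a.n_k) == [6, 6] and list(b.n_k) == [5, 5]

    def test_single_sample_state_cannot_split(self):
        m = ReducedEnergyMatrix(np.zeros((3, 2)), np.array([1, 2]))
        with pytest.raises(CannotSplitError):
            split_trials(m)

    def test_two_trial_mean_and_sd(self, thermo, harmonic_124):
        m, analytic = harmonic_124
        r = iv.estimate_with_uncertainty(m, thermo)
        g1, g2 = r.trial_delta_g
        assert r.delta_g == pytest.approx(0.5 * (g1 + g2), abs=1e-12)
        assert r.uncertainty == pytest.approx(abs(g1 - g2) / np.sqrt(2), rel=1e-10)
        # both trials and the mean should track the analytic value
        assert r.delta_g == pytest.approx(analytic[-1] / thermo.beta, abs=0.05)

    def test_equal_trials_give_zero_uncertainty(self):
        # duplicated halves: both trials see identical data
        rng = np.random.default_rng(3)
        half = rng.normal(size=(10, 2))
        u = np.vstack([half[:5], half[:5], half[5:], half[5:]])
        m = ReducedEnergyMatrix(u, np.array([10, 10]))
        r = iv.estimate_with_uncertainty(m, iv.ThermoState(300.0))
        assert r.uncertainty == pytest.approx(0.0, abs=1e-9)
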