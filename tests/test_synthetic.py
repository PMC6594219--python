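"""Generators: analytic invariants, sampler health, ground-truth recovery."""

import numpy as np
import pytest
from scipy import stats

import ionsolv as iv
from ionsolv.core import InvalidSpecError, LambdaSchedule, SoftCorePotentialSpec
from ionsolv.synthetic import (
    DegenerateDesignError,
    InvalidProfileError,
    consistent_counts,
)


class TestLambdaSchedule:
    def test_default_has_17_states(self):
        sched = LambdaSchedule.default()
        assert len(sched) == 17
        lj_only = [s for s in sched if s.lambda_elec == 0.0]
        assert len(lj_only) == 14
        assert all(s.lambda_lj == 1.0 for s in sched if s.lambda_elec > 0)

    def test_endpoints_and_uniqueness_enforced(self):
        with pytest.raises(InvalidSpecError):
            LambdaSchedule((iv.LambdaState(0.5, 0.0), iv.LambdaState(1.0, 1.0)))
        with pytest.raises(InvalidSpecError):
            LambdaSchedule(
                (iv.LambdaState(0.0, 0.0), iv.LambdaState(0.5, 0.5),
                 iv.LambdaState(1.0, 1.0))
            )


class TestHarmonicGenerator:
    def test_identical_states_have_zero_delta_f(self, thermo):
        spec = iv.HarmonicAlchemySpec(k=(1.0, 1.0), n_samples=10, seed=0)
        _, analytic = iv.gen_harmonic_alchemy(spec, thermo)
        assert analytic[1] == 0.0

    def test_analytic_value_is_half_log_ratio(self, thermo):
        spec = iv.HarmonicAlchemySpec(k=(1.0, 4.0), n_samples=10, seed=0)
        _, analytic = iv.gen_harmonic_alchemy(spec, thermo)
        assert analytic[1] == pytest.approx(0.5 * np.log(4), rel=1e-12)

    def test_telescoping_free_energies(self, thermo):
        spec = iv.HarmonicAlchemySpec(k=(1.0, 2.0, 4.0), n_samples=10, seed=0)
        _, f = iv.gen_harmonic_alchemy(spec, thermo)
        assert f[2] == pytest.approx((f[1] - f[0]) + (f[2] - f[1]), rel=1e-14)

    def test_sample_variance_matches_spring(self, thermo):
        n = 40_000
        spec = iv.HarmonicAlchemySpec(k=(2.0, 5.0), n_samples=n, seed=3)
        m, _ = iv.gen_harmonic_alchemy(spec, thermo)
        # u_i on own samples = beta k x^2/2 -> x^2 = 2u/(beta k); Var(x) = 1/(beta k)
        for i, ki in enumerate(spec.k):
            u_own = m.rows_from(i)[:, i]
            var = (2 * u_own / (thermo.beta * ki)).mean()
            expected = 1.0 / (thermo.beta * ki)
            se = (2 * u_own / (thermo.beta * ki)).std(ddof=1) / np.sqrt(n)
            assert abs(var - expected) < 3 * se

    def test_nonpositive_spring_rejected(self):
        with pytest.raises(InvalidSpecError):
            iv.HarmonicAlchemySpec(k=(1.0, -2.0))

    def test_seed_reproducibility(self, thermo):
        spec = iv.HarmonicAlchemySpec(k=(1.0, 2.0), n_samples=50, seed=42)
        m1, _ = iv.gen_harmonic_alchemy(spec, thermo)
        m2, _ = iv.gen_harmonic_alchemy(spec, thermo)
        assert np.array_equal(m1.u, m2.u)


class TestSoftCore:
    def test_full_coupling_equals_plain_lj(self):
        spec = SoftCorePotentialSpec(epsilon=0.8, sigma=0.3)
        r = np.linspace(0.05, 1.1, 50)
        plain = 4 * 0.8 * ((0.3 / r) ** 12 - (0.3 / r) ** 6)
        assert np.allclose(spec.lj_energy(r, 1.0), plain, rtol=1e-12)

    def test_zero_coupling_is_zero(self):
        spec = SoftCorePotentialSpec()
        r = np.linspace(0.01, 1.0, 20)
        assert np.all(spec.lj_energy(r, 0.0) == 0.0)

    def test_softcore_is_finite_at_origin(self):
        spec = SoftCorePotentialSpec()
        assert np.isfinite(spec.lj_energy(np.array([1e-9]), 0.5)).all()


class TestLJSampler:
    def test_decoupled_column_is_identically_zero(self, thermo):
        sched = LambdaSchedule.default()
        m = iv.gen_lj_alchemy(SoftCorePotentialSpec(), sched, n_solvent=10,
                              n_steps=600, thermo=thermo, seed=1, box_edge=2.0)
        assert np.all(m.u[:, 0] == 0.0)
        assert m.n_states == 17

    def test_histogram_invariant_under_longer_run(self, thermo):
        """Detailed-balance smoke test: the sampled energy distribution at a
        window should be the same whether the chain runs n or 2n steps."""
        sched = LambdaSchedule(
            (iv.LambdaState(0.0, 0.0), iv.LambdaState(1.0, 1.0))
        )
        spec = SoftCorePotentialSpec()
        # thin heavily (many sweeps between samples) so KS sees ~independent draws
        m1 = iv.gen_lj_alchemy(spec, sched, n_solvent=12, n_steps=25000,
                               thermo=thermo, seed=7, box_edge=2.0,
                               sample_every=200)
        m2 = iv.gen_lj_alchemy(spec, sched, n_solvent=12, n_steps=50000,
                               thermo=thermo, seed=8, box_edge=2.0,
                               sample_every=200)
        e1 = m1.rows_from(1)[:, 1]
        e2 = m2.rows_from(1)[:, 1]
        assert stats.ks_2samp(e1, e2).pvalue > 0.01

    def test_too_many_particles_rejected(self, thermo):
        with pytest.raises(InvalidSpecError):
            iv.gen_lj_alchemy(SoftCorePotentialSpec(), LambdaSchedule.default(),
                              n_solvent=101, n_steps=100, thermo=thermo, seed=0)


class TestMixtureGenerator:
    def test_totals_conserved_every_frame(self, enriched_frames):
        frames, n_w, n_c = enriched_frames
        for f in frames:
            assert (f.solvent_species == 0).sum() == n_w
            assert (f.solvent_species == 1).sum() == n_c

    def test_flat_profile_gamma_zero_within_ci(self):
        flat = iv.EnrichmentProfile.flat(0.5, radius=1.0)
        frames = iv.gen_mixture_trajectory(flat, 350, 350, box=5.0,
                                           n_frames=600, seed=5)
        g = iv.gamma(iv.count_domains(frames, 0.9))
        assert abs(g.gamma) < 3 * g.uncertainty + 0.05

    def test_no_cosolvent_means_zero_counts(self):
        pure = iv.EnrichmentProfile.flat(1.0, radius=1.0)
        frames = iv.gen_mixture_trajectory(pure, 300, 0, box=5.0,
                                           n_frames=5, seed=6)
        counts = iv.count_domains(frames, 1.2)
        assert np.all(counts.n_c_local == 0) and np.all(counts.n_c_bulk == 0)

    def test_enriched_profile_matches_integration_oracle(
        self, enriched_frames, enriched_profile
    ):
        frames, n_w, n_c = enriched_frames
        g = iv.gamma(iv.count_domains(frames, 1.2))
        expected = iv.expected_gamma(enriched_profile, n_w, n_c, 5.0, 1.2)
        # 95% CI from the 10-block standard error (t quantile, 9 dof)
        assert abs(g.gamma - expected) < 2.262 * g.uncertainty + 0.05

    def test_bulk_composition_matches_profile(self, enriched_frames):
        frames, n_w, n_c = enriched_frames
        counts = iv.count_domains(frames, 1.0)
        frac = counts.n_w_bulk.sum() / (counts.n_w_bulk.sum() + counts.n_c_bulk.sum())
        n = (counts.n_w_bulk + counts.n_c_bulk).sum()
        ci = 3 * np.sqrt(0.25 / n)
        assert abs(frac - 0.5) < ci + 0.01

    def test_infeasible_counts_rejected(self, enriched_profile):
        with pytest.raises(InvalidProfileError):
            iv.gen_mixture_trajectory(enriched_profile, 100, 600, box=5.0,
                                      n_frames=1, seed=0)

    def test_consistent_counts_feasible(self, enriched_profile):
        n_w, n_c = consistent_counts(enriched_profile, 5.0, 700)
        frames = iv.gen_mixture_trajectory(enriched_profile, n_w, n_c, 5.0,
                                           n_frames=2, seed=1)
        assert len(frames) == 2


class TestKineticGenerator:
    def design(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        return list(zip(rng.uniform(-2, 2, n), rng.uniform(1.0, 1.3, n)))

    def test_zero_noise_roundtrip_exact(self):
        ds = iv.gen_kinetic_dataset((0.33, 0.38, 0.1), self.design(), 0.0, seed=1)
        fit = iv.fit_multilinear(ds)
        assert fit.coefficients["gamma_prime"] == pytest.approx(0.33, abs=1e-12)
        assert fit.coefficients["dg_ratio"] == pytest.approx(0.38, abs=1e-12)
        assert fit.coefficients["intercept"] == pytest.approx(0.1, abs=1e-12)

    def test_noisy_replicates_have_small_bias(self):
        coefs = []
        for seed in range(200):
            ds = iv.gen_kinetic_dataset((0.33, 0.38, 0.1), self.design(), 0.1,
                                        seed=seed)
            fit = iv.fit_multilinear(ds)
            coefs.append([fit.coefficients["gamma_prime"],
                          fit.coefficients["dg_ratio"],
                          fit.coefficients["intercept"]])
        bias = np.mean(coefs, axis=0) - np.array([0.33, 0.38, 0.1])
        assert np.all(np.abs(bias) < 0.02)

    def test_nested_single_descriptor_agreement(self):
        # B = 0: the one-descriptor no-intercept fit on raw Gamma' should
        # recover the same slope the generator used on standardized Gamma'
        design = self.design(10, seed=3)
        ds = iv.gen_kinetic_dataset((0.5, 0.0, 0.0), design, 0.0, seed=2)
        gp = np.array([d[0] for d in design])
        z, mean, sd = iv.standardize(gp)
        # sigma = 0.5 * z = (0.5/sd) * (gp - mean); no-intercept fit of sigma
        # on raw gp recovers 0.5/sd only when mean = 0, so center the design
        design0 = [(g - mean, d) for g, d in design]
        ds0 = iv.gen_kinetic_dataset((0.5, 0.0, 0.0), design0, 0.0, seed=2)
        fit = iv.fit_single(ds0)
        assert fit.coefficients["gamma_prime"] == pytest.approx(0.5 / sd, rel=1e-10)

    def test_rates_consistent_with_sigma(self):
        ds = iv.gen_kinetic_dataset((0.3, 0.2, 0.0), self.design(), 0.0, seed=4)
        assert np.allclose(np.log(ds.k_org / ds.k_water), ds.sigma)

    def test_degenerate_design_rejected(self):
        design = [(1.0, 1.1), (1.0, 1.2), (1.0, 1.3), (1.0, 1.15)]
        with pytest.raises(DegenerateDesignError):
            iv.gen_kinetic_dataset((0.3, 0.2, 0.0), design, 0.0, seed=0)
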