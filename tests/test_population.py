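"""Population Monte Carlo: lognormal sampling, phenotype mixture, HK_AF."""

import math

import numpy as np
import pytest

from cpftk.pbk import Scenario
from cpftk.population import (
    DistributionSpec,
    enumerate_phenotype_combinations,
    hk_af,
    lognormal_spec,
    run_population,
    sample,
    summarize,
    truncated_moments,
    weighted_geometric_mean,
    weighted_quantile,
)


class TestDistributionSpec:
    def test_log_space_parameters_hand_arithmetic(self):
        spec = lognormal_spec(52.0, 0.67)
        assert spec.sigma_w == pytest.approx(math.sqrt(math.log(1.4489)), rel=1e-4)
        assert spec.mu_w == pytest.approx(math.log(52.0 / math.sqrt(1.4489)), rel=1e-4)
        assert spec.sigma_w == pytest.approx(0.609, abs=0.001)
        assert spec.mu_w == pytest.approx(3.766, abs=0.001)

    def test_identity_between_moments(self):
        for mu, cv in [(1.0, 0.1), (290.0, 0.33), (0.46, 0.73)]:
            spec = lognormal_spec(mu, cv)
            assert spec.sigma_w ** 2 == pytest.approx(math.log(1 + cv ** 2), abs=1e-12)
            assert spec.mu_w == pytest.approx(
                math.log(mu / math.sqrt(1 + cv ** 2)), abs=1e-12
            )

    def test_zero_cv_degenerates(self):
        spec = lognormal_spec(7.0, 0.0)
        assert spec.sigma_w == 0.0
        vals = sample(spec, 10, seed=0)
        np.testing.assert_allclose(vals, 7.0)

    def test_absorption_fraction_cap_tightens_upper_bound(self):
        spec = lognormal_spec(0.46, 0.73, cap=1.0)
        assert spec.upper_w == pytest.approx(0.0)  # ln(1)
        assert spec.upper_w < spec.mu_w + 3 * spec.sigma_w

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lognormal_spec(-1.0, 0.3)
        with pytest.raises(ValueError):
            lognormal_spec(1.0, -0.1)


class TestSampling:
    def test_moment_recovery_at_large_n(self):
        spec = lognormal_spec(52.0, 0.67)
        vals = sample(spec, 100_000, seed=42)
        mean_t, cv_t = truncated_moments(spec)
        assert abs(vals.mean() / 52.0 - 1) < 0.02
        assert abs(vals.mean() / mean_t - 1) < 0.01
        assert abs(vals.std(ddof=1) / vals.mean() / cv_t - 1) < 0.03

    def test_truncated_moments_sit_just_below_nominal(self):
        # clipping at +/-3 sigma shrinks the spread by a small, nearly
        # sigma-independent factor (~1.3%) and barely moves the mean
        mean_t, cv_t = truncated_moments(lognormal_spec(10.0, 0.05))
        assert mean_t == pytest.approx(10.0, rel=1e-3)
        assert 0.95 * 0.05 < cv_t < 0.05

    def test_truncation_acceptance_near_three_sigma_mass(self):
        spec = lognormal_spec(52.0, 0.67)
        vals = sample(spec, 200_000, seed=7)
        frac = vals.size / 200_000
        assert abs(frac - 0.9973) < 0.002

    def test_draws_respect_bounds(self):
        spec = lognormal_spec(0.46, 0.73, cap=1.0)
        vals = sample(spec, 50_000, seed=3)
        assert vals.max() <= 1.0
        assert np.log(vals).min() >= spec.lower_w - 1e-12


class TestPhenotypeCombinations:
    def test_reference_table_yields_six_weighted_combos(self):
        combos = enumerate_phenotype_combinations()
        assert len(combos) == 6
        weights = sorted(c.weight for c in combos)
        assert sum(weights) == pytest.approx(1.0, abs=1e-9)
        em_em = 0.890 * 0.590
        assert any(abs(c.weight - em_em) < 1e-9 for c in combos)

    def test_single_phenotype_table_gives_one_combo(self):
        from cpftk.params import PhenotypeEntry

        table = (
            PhenotypeEntry("CYP1A2", "EM", 52.0, 0.67, 1.0),
            PhenotypeEntry("CYP3A4", "EM", 137.0, 0.41, 1.0),
        )
        combos = enumerate_phenotype_combinations(table)
        assert len(combos) == 1 and combos[0].weight == pytest.approx(1.0)

    def test_bad_frequencies_rejected(self):
        from cpftk.params import PhenotypeEntry

        table = (PhenotypeEntry("CYP1A2", "EM", 52.0, 0.67, 0.8),)
        with pytest.raises(ValueError):
            enumerate_phenotype_combinations(table)


class TestWeightedStatistics:
    def test_quantile_matches_numpy_for_equal_weights(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 0.6, 5001)
        w = np.ones_like(x)
        for q in (0.01, 0.5, 0.95, 0.99):
            ours = weighted_quantile(x, w, q)
            ref = np.quantile(x, q, method="hazen")
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_percentile_ordering_invariant(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.lognormal(rng.normal(), rng.uniform(0.1, 1.0), 500)
            w = rng.uniform(0.5, 2.0, 500)
            p1 = weighted_quantile(x, w, 0.01)
            gm = weighted_geometric_mean(x, w)
            p95 = weighted_quantile(x, w, 0.95)
            p99 = weighted_quantile(x, w, 0.99)
            assert p1 <= gm <= p95 <= p99

    def test_identity_model_closed_form_hk_af(self):
        """A lognormal passed through an identity model: P95/GM and P99/GM
        equal exp(z_p * sigma_w) up to Monte Carlo error."""
        sigma = 0.6
        rng = np.random.default_rng(11)
        x = np.exp(rng.normal(0.0, sigma, 400_000))
        w = np.ones_like(x)
        r95 = weighted_quantile(x, w, 0.95) / weighted_geometric_mean(x, w)
        r99 = weighted_quantile(x, w, 0.99) / weighted_geometric_mean(x, w)
        assert r95 == pytest.approx(math.exp(1.6449 * sigma), rel=0.02)
        assert r99 == pytest.approx(math.exp(2.3263 * sigma), rel=0.02)
        assert math.exp(1.6449 * 0.6) == pytest.approx(2.68, abs=0.01)

    def test_constant_sample_has_unit_hk_af(self):
        res = summarize([2.0] * 50, [1.0] * 50, [("x", 50)], 50, 50, 0)
        assert hk_af(res, 95) == pytest.approx(1.0)
        assert hk_af(res, 99) == pytest.approx(1.0)

    def test_geometric_mean_requires_positive_values(self):
        with pytest.raises(ValueError):
            weighted_geometric_mean([1.0, 0.0], [1, 1])


class TestRunPopulation:
    def test_deterministic_under_fixed_seed(self, supersome_scenario):
        kw = dict(n_per_combo=20, seed=123, scope="kinetic_only")
        r1 = run_population(supersome_scenario, 0.47, **kw)
        r2 = run_population(supersome_scenario, 0.47, **kw)
        np.testing.assert_array_equal(r1.values, r2.values)
        assert r1.gm == r2.gm and r1.p99 == r2.p99

    def test_percentile_ordering_and_counts(self, supersome_scenario):
        r = run_population(supersome_scenario, 0.47, n_per_combo=40, seed=5)
        assert r.p1 <= r.gm <= r.p95 <= r.p99
        assert r.accepted_runs <= r.total_runs == 240
        assert r.hk_af_95 >= 1.0 and r.hk_af_99 >= r.hk_af_95

    def test_wider_scope_wider_spread(self, supersome_scenario):
        k = run_population(supersome_scenario, 0.47, n_per_combo=150, seed=9,
                           scope="kinetic_only")
        a = run_population(supersome_scenario, 0.47, n_per_combo=150, seed=9,
                           scope="all_influential")
        assert a.hk_af_99 > k.hk_af_99
        # the extended scope also rejects more runs (absorption cap at 1)
        assert a.accepted_runs < k.accepted_runs

    def test_nonbiphasic_mode_refused(self):
        with pytest.raises(ValueError):
            run_population(Scenario(mode="hlm_nonbiphasic"), 0.47, n_per_combo=5)

    def test_zero_dose_refused(self, supersome_scenario):
        with pytest.raises(ValueError):
            run_population(supersome_scenario, 0.0, n_per_combo=5)
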