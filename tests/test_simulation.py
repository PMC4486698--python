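import numpy as np
import pytest
from numpy.polynomial import polynomial as P

from survtg.simulation import (
    Scenario,
    apply_random_censoring,
    apply_type1_censoring,
    categorise_covariate,
    centile_times,
    contaminate,
    default_eval_times,
    draw_covariate,
    fleishman_coefficients,
    gen_exponential_ph,
    gen_two_arm_weibull,
    random_censoring_rate,
    run_experiment,
    simulate_replicate,
    type1_censoring_time,
    weibull_crossing_time,
)


def gaussian_poly_moments(coeffs):
    """Exact first four moments of a polynomial in a standard normal variate.

    Independent oracle: expand the polynomial powers symbolically and
    contract against the normal moments E[X^j] = (j-1)!! for even j.
    """
    def rm(k):
        pk = P.polypow(coeffs, k)
        return sum(
            cj * (np.prod(np.arange(j - 1, 0, -2)) if j > 0 else 1.0)
            for j, cj in enumerate(pk)
            if j % 2 == 0
        )

    m1 = rm(1)
    m2 = rm(2) - m1**2
    m3 = rm(3) - 3 * m1 * rm(2) + 2 * m1**3
    m4 = rm(4) - 4 * m1 * rm(3) + 6 * m1**2 * rm(2) - 3 * m1**4
    return m1, m2, m3 / m2**1.5, m4 / m2**2 - 3.0


class TestEventTimeGeneration:
    def test_baseline_centiles_match_canonical_times(self):
        """-ln(1-p)/0.02 reproduces T1=2.57 ... T6=34.66."""
        times = centile_times([0.05, 0.10, 0.15, 0.20, 0.25, 0.50])
        np.testing.assert_allclose(
            np.round(times, 2), [2.56, 5.27, 8.13, 11.16, 14.38, 34.66], atol=0.015
        )
        # the inversion formula at U=0.5 and U=0.95, beta=0
        assert -np.log(0.5) / 0.02 == pytest.approx(34.657, abs=1e-3)
        assert -np.log(0.95) / 0.02 == pytest.approx(2.565, abs=1e-3)
        # covariate effect scales time by exp(-beta z)
        assert -np.log(0.5) / 0.02 * np.exp(-np.log(2) * 1.0) == pytest.approx(17.329, abs=1e-3)

    def test_generator_is_deterministic_and_latent(self):
        sc = Scenario(name="x", n=50, seed=3)
        a = gen_exponential_ph(sc, 0)
        b = gen_exponential_ph(sc, 0)
        c = gen_exponential_ph(sc, 1)
        np.testing.assert_array_equal(a.times, b.times)
        assert not np.array_equal(a.times, c.times)
        assert a.n_events == 50
        np.testing.assert_array_equal(a.true_times, a.times)

    def test_marginal_median_at_t6(self):
        sc = Scenario(name="x", n=50_000, beta=0.0, seed=3)
        ds = gen_exponential_ph(sc, 0)
        frac = (ds.times <= default_eval_times()[-1]).mean()
        assert frac == pytest.approx(0.5, abs=0.01)

    @pytest.mark.parametrize("dist", ["normal", "pos_skew", "neg_skew"])
    def test_covariates_standardised(self, dist, rng):
        z = draw_covariate(dist, 200_000, rng)
        assert z.mean() == pytest.approx(0.0, abs=0.02)
        assert z.var() == pytest.approx(1.0, abs=0.03)
        from scipy.stats import skew

        expected_skew = {"normal": 0.0, "pos_skew": 2.8, "neg_skew": -2.8}[dist]
        assert skew(z) == pytest.approx(expected_skew, abs=0.15)


class TestFleishman:
    def test_identity_for_normal(self):
        assert fleishman_coefficients(0.0, 0.0) == (0.0, 1.0, 0.0, 0.0)

    def test_moment_oracle_for_target_pair(self):
        a, b, c, d = fleishman_coefficients(2.8, 13.2)
        assert a == -c
        mean, var, skewness, exkurt = gaussian_poly_moments([a, b, c, d])
        assert mean == pytest.approx(0.0, abs=1e-8)
        assert var == pytest.approx(1.0, abs=1e-8)
        assert skewness == pytest.approx(2.8, abs=1e-8)
        assert exkurt == pytest.approx(13.2, abs=1e-8)

    def test_negation_flips_skewness(self):
        a, b, c, d = fleishman_coefficients(2.8, 13.2)
        mean, var, skewness, exkurt = gaussian_poly_moments([-a, -b, -c, -d])
        assert skewness == pytest.approx(-2.8, abs=1e-8)
        assert exkurt == pytest.approx(13.2, abs=1e-8)

    def test_infeasible_pair_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            fleishman_coefficients(3.0, 0.0)


class TestRandomCensoring:
    def test_target_zero_is_noop(self, rng):
        sc = Scenario(name="x", n=30, seed=1)
        ds = gen_exponential_ph(sc, 0)
        out = apply_random_censoring(ds, 0.0, sc, rng)
        assert out.n_events == 30

    def test_null_effect_closed_form_rate(self):
        # beta=0: P(C<T) = theta/(theta+lam) => theta = lam * p/(1-p)
        sc = Scenario(name="x", beta=0.0)
        for p in (0.2, 0.5, 0.8):
            assert random_censoring_rate(sc, p) == pytest.approx(0.02 * p / (1 - p), rel=1e-8)

    @pytest.mark.parametrize(
        "dist,beta,target,tol",
        [("normal", 0.0, 0.5, 0.01), ("neg_skew", np.log(2), 0.8, 0.02)],
    )
    def test_realised_fraction_matches_target(self, dist, beta, target, tol, rng):
        sc = Scenario(name="x", n=100_000, beta=beta, covariate=dist, seed=2)
        ds = gen_exponential_ph(sc, 0)
        out = apply_random_censoring(ds, target, sc, rng)
        assert 1 - out.events.mean() == pytest.approx(target, abs=tol)


class TestType1Censoring:
    def test_null_effect_closed_form_tau(self):
        sc = Scenario(name="x", beta=0.0)
        assert type1_censoring_time(sc, 0.5) == pytest.approx(-np.log(0.5) / 0.02, rel=1e-8)

    def test_realised_fraction(self):
        sc = Scenario(name="x", n=100_000, beta=np.log(2), seed=2)
        ds = gen_exponential_ph(sc, 0)
        out = apply_type1_censoring(ds, 0.3, sc)
        assert 1 - out.events.mean() == pytest.approx(0.3, abs=0.01)
        # administrative: all censored subjects share the cut time
        assert np.unique(out.times[out.events == 0]).size == 1


class TestContamination:
    def test_sample_size_and_covariate_change(self, rng):
        sc = Scenario(name="x", n=40, seed=6)
        ds = gen_exponential_ph(sc, 0)
        out = contaminate(ds, "outlier", 5.0, sc, rng)
        assert out.n == ds.n
        changed = np.flatnonzero(out.covariates[:, 0] != ds.covariates[:, 0])
        assert len(changed) == 1
        assert out.covariates[changed[0], 0] == 5.0

    def test_outlier_keeps_time_extreme_regenerates(self):
        sc = Scenario(name="x", n=40, seed=6)
        ds = gen_exponential_ph(sc, 0)
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(1)
        out_keep = contaminate(ds, "outlier", 5.0, sc, rng1)
        out_regen = contaminate(ds, "extreme", 5.0, sc, rng2)
        i = int(np.flatnonzero(out_keep.covariates[:, 0] == 5.0)[0])
        assert out_keep.times[i] == ds.times[i]
        assert out_regen.times[i] != ds.times[i]

    def test_unknown_kind_rejected(self, rng):
        sc = Scenario(name="x", n=40, seed=6)
        ds = gen_exponential_ph(sc, 0)
        with pytest.raises(ValueError, match="extreme"):
            contaminate(ds, "typo", 5.0, sc, rng)


class TestTwoArmWeibull:
    def test_equal_allocation_and_truncation(self):
        sc = Scenario(name="t", n=1127, event_dist="two_arm_weibull", seed=4)
        ds = gen_two_arm_weibull(sc, 0)
        counts = dict(zip(*np.unique(ds.groups, return_counts=True)))
        assert sorted(counts.values()) == [563, 564]
        assert ds.times.max() <= 20.0
        np.testing.assert_array_equal(ds.events, (ds.true_times <= 20.0).astype(int))

    def test_per_arm_survival_at_one_month(self):
        sc = Scenario(name="t", n=40_000, event_dist="two_arm_weibull", seed=4)
        ds = gen_two_arm_weibull(sc, 0)
        from survtg.simulation import TWO_ARM_DEFAULTS

        for arm, (scale, shape) in TWO_ARM_DEFAULTS.items():
            frac = (ds.true_times[ds.groups == arm] > 1.0).mean()
            assert frac == pytest.approx(np.exp(-scale), abs=0.01)
            cens = 1 - ds.events[ds.groups == arm].mean()
            assert cens == pytest.approx(np.exp(-scale * 20.0**shape), abs=0.01)

    def test_shape_one_matches_exponential_inversion(self):
        sc = Scenario(
            name="t",
            n=50_000,
            event_dist="two_arm_weibull",
            arms={"a": (0.05, 1.0), "b": (0.05, 1.0)},
            truncation=1e9,
            seed=4,
        )
        ds = gen_two_arm_weibull(sc, 0)
        assert ds.times.mean() == pytest.approx(1 / 0.05, rel=0.02)

    def test_crossing_time_closed_form(self):
        assert weibull_crossing_time({"a": (0.035, 1.72), "b": (0.10, 1.08)}) == pytest.approx(
            (0.10 / 0.035) ** (1 / 0.64)
        )
        with pytest.raises(ValueError, match="proportional"):
            weibull_crossing_time({"a": (0.1, 1.0), "b": (0.2, 1.0)})


class TestCategorisation:
    def test_median_split(self):
        z = np.arange(10.0)
        design, names, codes = categorise_covariate(z, 2)
        assert design.shape == (10, 1)
        np.testing.assert_array_equal(design[:, 0], (z >= np.median(z)).astype(float))

    def test_ten_groups_use_decile_cut_points(self, rng):
        z = rng.standard_normal(5000)
        _, names, codes = categorise_covariate(z, 10)
        assert len(names) == 9
        sizes = np.bincount(codes, minlength=10)
        assert np.all(np.abs(sizes - 500) <= 1)

    def test_tied_cut_points_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            categorise_covariate(np.zeros(50), 4)


class TestRunExperiment:
    def test_identical_seed_identical_summaries(self):
        sc = Scenario(name="x", n=150, replicates=3, seed=0)
        a = run_experiment([sc], measures=["TG_STD"], seed=42).summary()
        b = run_experiment([sc], measures=["TG_STD"], seed=42).summary()
        assert a.equals(b)

    def test_paired_scenarios_share_latent_times(self):
        base = dict(n=100, replicates=1, beta=np.log(2), seed=7)
        unc = Scenario(name="u", **base)
        cen = Scenario(name="c", censoring="random", censoring_target=0.5, **base)
        du = simulate_replicate(unc, 0)
        dc = simulate_replicate(cen, 0)
        np.testing.assert_array_equal(du.true_times, dc.true_times)
        assert dc.n_events < du.n_events

    def test_unknown_measure_rejected(self):
        sc = Scenario(name="x", n=100, replicates=1, seed=0)
        with pytest.raises(RuntimeError):
            run_experiment([sc], measures=["nope"])
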