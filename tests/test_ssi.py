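import numpy as np
import pytest

from popinfo import (
    MCConfig,
    Population,
    TruncationConfig,
    TuningCurve,
    make_population,
    make_uniform_discrete,
    marginal_ssi,
    mutual_information,
    rsi,
    ssi_exact,
    ssi_mc,
)
from popinfo.ssi import EnumerationSizeError, enumerate_responses


def flat_population(n=1, level=5.0, tau=0.2):
    """Neurons whose rate barely depends on the stimulus."""
    tc = TuningCurve("unimodal", level, 1e-9, 0.2, 0.0)
    return make_population(n, tc, -0.5, 0.5, tau)


from tests_helpers import brute_force_mi_bits  # noqa: E402


class TestRSI:
    def test_flat_tuning_gives_zero(self, small_ens):
        pop = flat_population()
        for r in ([0], [1], [3]):
            assert rsi(r, pop, small_ens) == pytest.approx(0.0, abs=1e-7)

    def test_decisive_response_recovers_full_entropy(self):
        # two widely separated mean counts; r=0 pins the low-rate stimulus
        tc = TuningCurve("monotonic", 0.01, 60.0, 0.01, 0.5)
        pop = make_population(1, tc, 0, 1, tau=1.0)
        ens = make_uniform_discrete(2, 0.0, 1.0)
        assert rsi([0], pop, ens) == pytest.approx(1.0, abs=1e-3)

    def test_matches_direct_entropy_difference(self, small_pop, small_ens):
        # oracle: explicit Bayes posterior + entropies, computed independently
        from scipy.stats import poisson

        r = np.array([1, 2])
        lam = small_pop.expected_counts(small_ens.values)
        like = poisson.pmf(r[None, :], lam).prod(axis=1)
        post = like * small_ens.probabilities
        post /= post.sum()
        h_prior = -(small_ens.probabilities * np.log2(small_ens.probabilities)).sum()
        h_post = -(post[post > 0] * np.log2(post[post > 0])).sum()
        assert rsi(r, small_pop, small_ens) == pytest.approx(
            h_prior - h_post, abs=1e-10
        )


class TestSSIExact:
    def test_flat_tuning_curve_is_zero(self, small_ens):
        curve = ssi_exact(flat_population(), small_ens)
        assert np.allclose(curve.values, 0.0, atol=1e-7)

    def test_expectation_equals_mutual_information(self, small_pop, small_ens):
        curve = ssi_exact(small_pop, small_ens)
        mi_from_curve = mutual_information(curve, small_ens)
        assert mi_from_curve == pytest.approx(
            brute_force_mi_bits(small_pop, small_ens), abs=1e-10
        )

    def test_symmetric_about_peak_for_symmetric_model(self):
        tc = TuningCurve("unimodal", 1.0, 10.0, 0.2, 0.0)
        pop = make_population(1, tc, -1, 1, tau=0.3)
        ens = make_uniform_discrete(41, -1, 1)
        curve = ssi_exact(pop, ens)
        assert np.allclose(curve.values, curve.values[::-1], atol=1e-9)

    def test_enumeration_cap_raises_helpful_error(self, small_ens):
        tc = TuningCurve("unimodal", 10.0, 40.0, 0.1, 0.0)
        pop = make_population(8, tc, -0.5, 0.5, tau=1.0)
        with pytest.raises(EnumerationSizeError, match="ssi_mc"):
            ssi_exact(pop, small_ens)

    def test_zero_probability_stimulus_is_nan(self):
        from popinfo import make_custom_ensemble

        ens = make_custom_ensemble([-0.2, 0.0, 0.2], [1.0, 0.0, 1.0])
        curve = ssi_exact(flat_population(), ens)
        assert np.isnan(curve.values[1])
        assert np.isfinite(curve.values[[0, 2]]).all()

    def test_truncation_config_validation(self):
        with pytest.raises(ValueError):
            TruncationConfig(epsilon=1e-3)
        with pytest.raises(ValueError):
            TruncationConfig(epsilon=0.0)


class TestSSIMonteCarlo:
    def test_agrees_with_exact_within_three_se(self, small_pop, small_ens):
        exact = ssi_exact(small_pop, small_ens)
        mc = ssi_mc(small_pop, small_ens, MCConfig(2000, seed=5))
        z = np.abs(mc.values - exact.values) / mc.std_errors
        assert np.mean(z <= 3.0) >= 0.99

    def test_same_seed_is_deterministic(self, small_pop, small_ens, mc_fast):
        a = ssi_mc(small_pop, small_ens, mc_fast)
        b = ssi_mc(small_pop, small_ens, mc_fast)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.std_errors, b.std_errors)

    def test_se_shrinks_like_root_m(self, small_pop, small_ens):
        lo = ssi_mc(small_pop, small_ens, MCConfig(500, seed=2))
        hi = ssi_mc(small_pop, small_ens, MCConfig(2000, seed=2))
        ratio = np.median(lo.std_errors) / np.median(hi.std_errors)
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_saturation_warning(self):
        # near-noiseless two-stimulus code: MI -> H(S)
        tc = TuningCurve("monotonic", 0.01, 80.0, 0.01, 0.5)
        pop = make_population(1, tc, 0, 1, tau=2.0)
        ens = make_uniform_discrete(2, 0.0, 1.0)
        with pytest.warns(RuntimeWarning, match="saturates"):
            ssi_mc(pop, ens, MCConfig(200, seed=1))


class TestMarginalSSI:
    def test_identical_twin_makes_neuron_redundant(self):
        # long tau and pairwise-decisive stimuli: one twin alone pins the
        # stimulus, so the other contributes essentially nothing
        import warnings

        tc = TuningCurve("monotonic", 2.0, 20.0, 0.15, 0.0)
        pop = Population((tc, tc), tau=20.0)
        ens = make_uniform_discrete(3, -0.4, 0.4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            curve = marginal_ssi(pop, 0, ens, MCConfig(1500, seed=9))
        bound = np.maximum(3 * curve.std_errors, 1e-4)
        assert np.all(np.abs(curve.values) <= bound)

    def test_matches_exact_full_minus_reduced(self):
        tc = TuningCurve("monotonic", 2.0, 20.0, 0.15, 0.0)
        pop = Population((tc, tc), tau=20.0)
        ens = make_uniform_discrete(5, -0.5, 0.5)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            exact = ssi_exact(pop, ens).values - ssi_exact(
                Population((tc,), 20.0), ens
            ).values
            curve = marginal_ssi(pop, 0, ens, MCConfig(1500, seed=9))
        # allow a small absolute floor: at decisive stimuli the paired MC
        # difference is exactly 0 in nearly every draw, so its SE vanishes
        # while the exact difference retains a ~1e-4 truncation-level residue
        assert np.all(np.abs(curve.values - exact) <= 4 * curve.std_errors + 5e-4)

    def test_expectation_equals_mi_difference(self, small_ens):
        tc = TuningCurve("unimodal", 2.0, 8.0, 0.2, 0.0)
        pop = make_population(3, tc, -0.5, 0.5, tau=0.3)
        mc = MCConfig(3000, seed=13)
        curve = marginal_ssi(pop, 1, small_ens, mc)
        mi_marginal = mutual_information(curve, small_ens)
        mi_full = brute_force_mi_bits(pop, small_ens)
        mi_reduced = brute_force_mi_bits(pop.drop(1), small_ens)
        se = np.nanmean(curve.std_errors)
        assert mi_marginal == pytest.approx(mi_full - mi_reduced, abs=3 * se)

    def test_single_neuron_rejected(self, small_ens, mc_fast):
        pop = flat_population(n=1)
        with pytest.raises(ValueError):
            marginal_ssi(pop, 0, small_ens, mc_fast)

    def test_bounded_above_by_single_neuron_mi(self, small_ens):
        # redundant code: marginal MI contribution <= single-neuron MI
        tc = TuningCurve("unimodal", 2.0, 8.0, 0.2, 0.0)
        pop = make_population(3, tc, -0.5, 0.5, tau=0.3)
        mc = MCConfig(3000, seed=17)
        curve = marginal_ssi(pop, 1, small_ens, mc)
        single = Population((pop.neurons[1],), pop.tau)
        mi_single = mutual_information(ssi_exact(single, small_ens), small_ens)
        mi_marg = mutual_information(curve, small_ens)
        se = np.nanmean(curve.std_errors)
        assert mi_marg <= mi_single + 3 * se


class TestMutualInformation:
    def test_zero_curve_gives_zero(self, small_ens):
        curve = ssi_exact(flat_population(), small_ens)
        assert mutual_information(curve, small_ens) == pytest.approx(0.0, abs=1e-7)

    def test_two_discriminable_stimuli_saturate_one_bit(self):
        tc = TuningCurve("monotonic", 0.01, 60.0, 0.01, 0.5)
        pop = make_population(1, tc, 0, 1, tau=1.0)
        ens = make_uniform_discrete(2, 0.0, 1.0)
        with pytest.warns(RuntimeWarning):
            mi = mutual_information(ssi_exact(pop, ens), ens)
        assert mi == pytest.approx(1.0, abs=1e-3)

    def test_never_exceeds_stimulus_entropy(self, small_pop, small_ens):
        mi = mutual_information(ssi_exact(small_pop, small_ens), small_ens)
        assert 0.0 <= mi <= small_ens.entropy()

    def test_grid_mismatch_rejected(self, small_pop, small_ens):
        other = make_uniform_discrete(21, -1.0, 1.0)
        curve = ssi_exact(small_pop, small_ens)
        with pytest.raises(ValueError):
            mutual_information(curve, other)


def test_enumeration_covers_requested_mass(small_pop, small_ens):
    trunc = TruncationConfig(epsilon=1e-8)
    R = enumerate_responses(small_pop, small_ens, trunc)
    # worst-case stimulus: enumerated mass >= 1 - N * epsilon
    from scipy.stats import poisson

    lam = small_pop.expected_counts(small_ens.values)
    caps = R.max(axis=0)
    mass = poisson.cdf(caps[None, :], lam).prod(axis=1)
    assert mass.min() >= 1 - small_pop.N * trunc.epsilon


def test_exact_ssi_can_be_negative_under_peaked_prior():
    # unexpected stimuli at the tails of a concentrated prior
    from popinfo import make_custom_ensemble

    grid = np.linspace(-0.5, 0.5, 41)
    weights = np.exp(-(grid**2) / (2 * 0.1**2))
    ens = make_custom_ensemble(grid, weights)
    tc = TuningCurve("unimodal", 5.0, 40.0, 0.1, 0.0)
    pop = make_population(1, tc, -0.5, 0.5, tau=0.01)
    curve = ssi_exact(pop, ens)
    assert np.nanmin(curve.values) < 0
    assert mutual_information(curve, ens) >= 0
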