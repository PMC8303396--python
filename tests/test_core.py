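"""Unit and property tests for the LEUP steady-state distribution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leup.core import (
    ConeMosaicStats,
    LEUPModel,
    gaussian_leup_weights,
    gaussian_microenv_entropy,
    internal_energy,
    internal_entropy,
    leup_distribution,
    load_fixture,
    min_variance_weights,
)

from .conftest import CHICKEN_P, CHICKEN_SIGMA

positive_sd = st.lists(st.floats(0.2, 5.0), min_size=2, max_size=8)


class TestLeupDistribution:
    @pytest.mark.parametrize(
        "beta, mu, s, n, expected",
        [
            (0.0, 0.0, [0.3, 1.1, 0.2, 2.0, 0.7], [1, 2, 3, 4, 5], [0.2] * 5),
            (1.0, 0.0, [0.0, math.log(2)], [0.0, 0.0], [2 / 3, 1 / 3]),
            # weights exp(-0.5-1)=e^-1.5 and exp(-0.5-3)=e^-3.5, ratio e^2
            (1.0, 1.0, [0.5, 0.5], [1.0, 3.0], [np.e**2 / (np.e**2 + 1), 1 / (np.e**2 + 1)]),
        ],
    )
    def test_examples(self, beta, mu, s, n, expected):
        dist = leup_distribution(LEUPModel(beta=beta, mu=mu, microenv_entropy=s, neighbor_count=n))
        np.testing.assert_allclose(dist.probs, expected, atol=1e-12)

    def test_log_partition(self):
        model = LEUPModel(beta=1.0, mu=0.0, microenv_entropy=[0.0, math.log(2)], neighbor_count=[0, 0])
        dist = leup_distribution(model)
        assert dist.log_partition == pytest.approx(math.log(1.5), abs=1e-12)

    def test_empty_state_set_rejected(self):
        with pytest.raises(ValueError):
            LEUPModel(beta=1.0, mu=0.0, microenv_entropy=[], neighbor_count=[])

    def test_nonfinite_entropy_rejected(self):
        with pytest.raises(ValueError):
            LEUPModel(beta=1.0, mu=0.0, microenv_entropy=[np.inf, 0.0], neighbor_count=[0, 0])

    def test_large_beta_does_not_overflow(self):
        model = LEUPModel(beta=50.0, mu=0.0, microenv_entropy=[5.0, -5.0, 0.0], neighbor_count=[0, 0, 0])
        dist = leup_distribution(model)
        assert np.isfinite(dist.probs).all()
        assert dist.probs[1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_extended_precision_oracle(self, rng):
        """Random 5-state models agree with an mpmath brute-force evaluation."""
        import mpmath

        mpmath.mp.dps = 50
        for _ in range(100):
            s = rng.uniform(-2, 2, 5)
            n = rng.uniform(0, 5, 5)
            beta, mu = rng.uniform(-5, 5), rng.uniform(0, 2)
            dist = leup_distribution(LEUPModel(beta=beta, mu=mu, microenv_entropy=s, neighbor_count=n))
            weights = [mpmath.exp(-beta * si - mu * ni) for si, ni in zip(s, n)]
            z = sum(weights)
            expected = np.array([float(w / z) for w in weights])
            np.testing.assert_allclose(dist.probs, expected, atol=1e-12)


class TestGaussianWeights:
    @given(c=st.floats(0.1, 10.0), beta=st.floats(-10.0, 10.0), n=st.integers(2, 8))
    def test_equal_sigmas_give_uniform(self, c, beta, n):
        np.testing.assert_allclose(gaussian_leup_weights([c] * n, beta), np.full(n, 1 / n), atol=1e-12)

    def test_chicken_beta2(self):
        w = gaussian_leup_weights(CHICKEN_SIGMA, 2.0)
        # normalized sigma^-2, high-precision reference
        ref = CHICKEN_SIGMA**-2.0 / (CHICKEN_SIGMA**-2.0).sum()
        np.testing.assert_allclose(w, ref, atol=1e-14)
        np.testing.assert_allclose(w, [0.238, 0.155, 0.124, 0.071, 0.413], atol=5e-4)

    def test_fitted_beta_reproduces_observed_proportions(self):
        """At the fitted sensitivity the weights track the observed cone ratios."""
        w = gaussian_leup_weights(CHICKEN_SIGMA, 1.754)
        assert np.abs(w - CHICKEN_P).max() < 0.04

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_leup_weights([1.0, 0.0], 2.0)

    @given(sd=positive_sd, beta=st.floats(-20, 20))
    @settings(max_examples=60)
    def test_normalized_and_permutation_equivariant(self, sd, beta):
        w = gaussian_leup_weights(sd, beta)
        assert abs(w.sum() - 1.0) < 1e-12
        perm = np.argsort(sd)
        np.testing.assert_allclose(gaussian_leup_weights(np.asarray(sd)[perm], beta), w[perm], atol=1e-12)

    def test_smallest_sigma_dominates_as_beta_grows(self):
        sd = np.array([0.5, 1.0, 2.0])
        betas = np.array([0.0, 1.0, 5.0, 20.0, 80.0])
        probs = np.array([gaussian_leup_weights(sd, b)[0] for b in betas])
        assert np.all(np.diff(probs) > 0)
        assert probs[-1] == pytest.approx(1.0, abs=1e-6)

    def test_equals_leup_distribution_with_gaussian_entropies(self):
        beta = 1.3
        dist = leup_distribution(
            LEUPModel(
                beta=beta,
                mu=0.0,
                microenv_entropy=gaussian_microenv_entropy(CHICKEN_SIGMA),
                neighbor_count=np.zeros(5),
            )
        )
        np.testing.assert_allclose(dist.probs, gaussian_leup_weights(CHICKEN_SIGMA, beta), atol=1e-12)

    def test_min_variance_is_beta_two(self):
        got = min_variance_weights(CHICKEN_SIGMA)
        expected = gaussian_leup_weights(CHICKEN_SIGMA, 2.0)
        assert np.array_equal(got, expected)
        np.testing.assert_allclose(min_variance_weights([1.0, 2.0]), [0.8, 0.2], atol=1e-14)


class TestEntropyAndEnergy:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.2] * 5, math.log(5)),
            ([1.0, 0.0, 0.0, 0.0, 0.0], 0.0),
            (CHICKEN_P, 1.473),
        ],
    )
    def test_internal_entropy(self, p, expected):
        assert internal_entropy(p) == pytest.approx(expected, abs=1e-3)

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            internal_entropy([-0.1, 1.1])

    def test_energy_equals_mean_entropy_when_mu_zero(self, rng):
        s = rng.uniform(0, 3, 5)
        model = LEUPModel(beta=1.7, mu=0.0, microenv_entropy=s, neighbor_count=np.zeros(5))
        dist = leup_distribution(model)
        assert internal_energy(model, dist) == pytest.approx(float(dist.probs @ s), abs=1e-14)

    def test_energy_example(self):
        model = LEUPModel(beta=1.0, mu=1.0, microenv_entropy=[0.5, 0.5], neighbor_count=[1.0, 3.0])
        dist = leup_distribution(model)
        p0 = np.e**2 / (np.e**2 + 1)
        expected = 0.5 + (p0 * 1.0 + (1 - p0) * 3.0)
        assert internal_energy(model, dist) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(1.7384, abs=1e-4)

    def test_energy_undefined_for_beta_zero_with_mu(self):
        model = LEUPModel(beta=0.0, mu=1.0, microenv_entropy=[0.1, 0.2], neighbor_count=[1, 2])
        with pytest.raises(ValueError):
            internal_energy(model, leup_distribution(model))

    def test_entropy_identity_on_random_models(self, rng):
        """S(x) = beta <S> + mu <N> + ln Z holds for arbitrary discrete models."""
        for _ in range(100):
            s = rng.uniform(-1, 3, rng.integers(2, 7))
            n = rng.uniform(0, 4, s.size)
            beta, mu = rng.uniform(-3, 3), rng.uniform(0, 2)
            model = LEUPModel(beta=beta, mu=mu, microenv_entropy=s, neighbor_count=n)
            dist = leup_distribution(model)
            rhs = beta * float(dist.probs @ s) + mu * float(dist.probs @ n) + dist.log_partition
            assert internal_entropy(dist.probs) == pytest.approx(rhs, abs=1e-10)


class TestConeMosaicStats:
    def test_fixture_loads(self, chicken):
        assert chicken.labels == ("green", "red", "blue", "violet", "double")
        np.testing.assert_allclose(chicken.proportions, CHICKEN_P, atol=1e-12)
        np.testing.assert_allclose(chicken.nnd_sd, CHICKEN_SIGMA, atol=1e-12)

    def test_unknown_fixture(self):
        with pytest.raises(KeyError):
            load_fixture("nonexistent")

    def test_csv_round_trip(self, tmp_path, chicken):
        path = tmp_path / "stats.csv"
        chicken.to_csv(path)
        again = ConeMosaicStats.from_csv(path)
        assert again.labels == chicken.labels
        np.testing.assert_allclose(again.proportions, chicken.proportions, atol=1e-12)
        np.testing.assert_allclose(again.nnd_sd, chicken.nnd_sd, atol=1e-12)

    def test_rounded_proportions_renormalized(self):
        stats = ConeMosaicStats(labels=("a", "b"), proportions=[0.499, 0.499], nnd_sd=[1, 1])
        assert stats.proportions.sum() == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(labels=("a", "b"), proportions=[0.6, 0.6], nnd_sd=[1, 1]),  # sum 1.2
            dict(labels=("a", "b"), proportions=[0.5, 0.5], nnd_sd=[1, -1]),
            dict(labels=("a",), proportions=[0.5, 0.5], nnd_sd=[1, 1]),  # length mismatch
        ],
    )
    def test_invalid_tables_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ConeMosaicStats(**kwargs)
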