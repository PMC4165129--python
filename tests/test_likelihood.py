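import numpy as np
import pytest

from ripetime.bvn import mvn_rectangle_probability
from ripetime.likelihood import (
    QuadratureSpec,
    RipeningModelParams,
    plant_loglikelihood,
    total_loglikelihood,
)
from ripetime.stages import CensoredBivariateObservation


def _fruit(pid, lo, hi, genotype="mut", truss=1, fruit=1):
    return CensoredBivariateObservation(pid, genotype, truss, fruit, tuple(lo), tuple(hi))


def _mc_plant_oracle(fruits, params, n=10**5, seed=0):
    """Brute-force oracle: MC over the plant effect, exact rectangle probs."""
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0, 0], params.sigma0, size=n)
    vals = np.ones(n)
    for o in fruits:
        m = params.mean_for(o.genotype, o.truss, o.fruit)
        vals *= np.array(
            [mvn_rectangle_probability(m + zz, params.sigma, (o.lower, o.upper)) for zz in z]
        )
    mean = vals.mean()
    se = vals.std(ddof=1) / np.sqrt(n)
    return np.log(mean), 3 * se / mean  # 3 SE on the log scale (delta method)


def test_zero_random_effect_reduces_to_sum_of_rectangle_logs(two_genotype_params):
    p = RipeningModelParams(
        mu=two_genotype_params.mu,
        alpha=two_genotype_params.alpha,
        sigma0=np.zeros((2, 2)),
        sigma=two_genotype_params.sigma,
    )
    fruits = [
        _fruit("p1", (40, 51), (44, 54)),
        _fruit("p1", (44, 51), (47, 58), fruit=2),
        _fruit("p1", (40, 47), (44, 51), fruit=3),
    ]
    ll = plant_loglikelihood(fruits, p, QuadratureSpec(15))
    direct = sum(
        np.log(
            mvn_rectangle_probability(
                p.mean_for(o.genotype, o.truss, o.fruit), p.sigma, (o.lower, o.upper)
            )
        )
        for o in fruits
    )
    assert ll == pytest.approx(direct, abs=1e-12)


def test_certain_event_gives_zero_loglik(two_genotype_params):
    fruits = [_fruit("p1", (0, 0), (np.inf, np.inf))]
    assert plant_loglikelihood(fruits, two_genotype_params) == pytest.approx(0.0, abs=1e-12)


def test_plant_loglik_matches_monte_carlo_oracle(two_genotype_params):
    rng = np.random.default_rng(3)
    fruits = []
    for f in range(3):
        l1 = 42 + rng.uniform(0, 3)
        l2 = 51 + rng.uniform(0, 3)
        fruits.append(_fruit("p1", (l1, l2), (l1 + 3.5, l2 + 3.5), fruit=f + 1))
    ll = plant_loglikelihood(fruits, two_genotype_params, QuadratureSpec(15))
    oracle, tol = _mc_plant_oracle(fruits, two_genotype_params, seed=1)
    assert abs(ll - oracle) < tol


def test_total_is_additive_over_plants(two_genotype_params):
    a = [_fruit("p1", (40, 51), (44, 54))]
    b = [_fruit("p2", (44, 54), (47, 58))]
    t_all = total_loglikelihood(a + b, two_genotype_params)
    t_sep = total_loglikelihood(a, two_genotype_params) + total_loglikelihood(
        b, two_genotype_params
    )
    assert t_all == pytest.approx(t_sep, rel=1e-12)


def test_translation_equivariance(two_genotype_params):
    fruits = [
        _fruit("p1", (40, 51), (44, 54)),
        _fruit("p1", (44, 51), (47, np.inf), fruit=2),
    ]
    base = plant_loglikelihood(fruits, two_genotype_params)
    shift = 10.0
    shifted_fruits = [
        _fruit(o.plant_id, np.add(o.lower, shift), np.add(o.upper, shift), o.genotype, o.truss, o.fruit)
        for o in fruits
    ]
    shifted_params = RipeningModelParams(
        mu=two_genotype_params.mu + shift,
        alpha=two_genotype_params.alpha,
        sigma0=two_genotype_params.sigma0,
        sigma=two_genotype_params.sigma,
    )
    assert plant_loglikelihood(shifted_fruits, shifted_params) == pytest.approx(base, abs=1e-9)


def test_quadrature_convergence_well_conditioned():
    # unit-scale plant variance: 15 vs 25 nodes/dim agree below 1e-6
    p = RipeningModelParams(
        mu=[42, 52],
        alpha={"mut": [3, 4]},
        sigma0=[[1.0, 0.2], [0.2, 1.0]],
        sigma=[[2, 0.5], [0.5, 2]],
    )
    fruits = [_fruit("p1", (42 + f, 53 + f), (46 + f, 57 + f), fruit=f + 1) for f in range(3)]
    a = plant_loglikelihood(fruits, p, QuadratureSpec(15))
    b = plant_loglikelihood(fruits, p, QuadratureSpec(25))
    assert abs(a - b) < 1e-6


def test_sigma0_continuity_at_zero(two_genotype_params):
    fruits = [
        _fruit("p1", (40, 51), (44, 54)),
        _fruit("p1", (44, 51), (47, 58), fruit=2),
    ]
    p0 = RipeningModelParams(
        mu=two_genotype_params.mu, alpha=two_genotype_params.alpha,
        sigma0=np.zeros((2, 2)), sigma=two_genotype_params.sigma,
    )
    target = plant_loglikelihood(fruits, p0)
    vals = []
    for eps in [1e-2, 1e-4, 1e-6]:
        p_eps = RipeningModelParams(
            mu=two_genotype_params.mu, alpha=two_genotype_params.alpha,
            sigma0=eps * np.eye(2), sigma=two_genotype_params.sigma,
        )
        vals.append(plant_loglikelihood(fruits, p_eps))
    errs = [abs(v - target) for v in vals]
    assert errs[-1] < 1e-6 and errs[0] > errs[-1]


def test_unknown_level_rejected(two_genotype_params):
    fruits = [_fruit("p1", (40, 51), (44, 54), genotype="nope")]
    with pytest.raises(KeyError, match="nope"):
        total_loglikelihood(fruits, two_genotype_params)


def test_zero_likelihood_warns(two_genotype_params):
    # an empty rectangle far in the tail has numerically zero probability
    fruits = [_fruit("p1", (0, 0), (1e-9, 1e-9))]
    with pytest.warns(RuntimeWarning, match="zero likelihood"):
        ll = plant_loglikelihood(fruits, two_genotype_params)
    assert ll == -np.inf


def test_invalid_covariances_rejected():
    with pytest.raises(ValueError, match="sigma0"):
        RipeningModelParams(
            mu=[0, 0], alpha={}, sigma0=[[1, 2], [2, 1]], sigma=np.eye(2)
        )
    # a merely PSD residual covariance is fine to hold but not to evaluate
    p = RipeningModelParams(
        mu=[40, 50], alpha={"g": [0, 0]},
        sigma0=np.zeros((2, 2)), sigma=[[1, 1], [1, 1]],
    )
    with pytest.raises(ValueError, match="positive definite"):
        total_loglikelihood([_fruit("p1", (40, 50), (44, 54), genotype="g")], p)
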