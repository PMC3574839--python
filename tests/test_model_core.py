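"""Component covariance assembly, mixture likelihood and posteriors against
direct density oracles."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from tcmix import (
    ComponentParams,
    DesignSpec,
    MixtureModel,
    TimeCourseMatrix,
    component_covariance,
    mixture_loglik,
    n_free_parameters,
    posterior_probs,
)
from tcmix.ar1 import ar1_matrix
from tcmix.exceptions import InvalidParameterError, SingularCovarianceError


def comp(weight=1.0, beta=(0.0, 0.0, 0.0), theta2=0.0, rho=0.0, sigma2=1.0, d2=0.0, omega=10.0):
    return ComponentParams(
        weight_p=weight, beta=np.array(beta), theta2=theta2, rho=rho,
        sigma2=sigma2, d2=d2, period_omega=omega,
    )


def toy_model(weights=(0.4, 0.6)):
    times = np.arange(3.0)
    design = DesignSpec(kind="fourier", times=times, order_k=1)
    comps = [
        comp(weights[0], beta=(0.5, 1.0, -0.3), theta2=0.4, rho=0.5, sigma2=0.8, d2=0.2, omega=6.0),
        comp(weights[1], beta=(-0.2, 0.1, 0.7), theta2=0.9, rho=-0.3, sigma2=0.5, d2=0.1, omega=10.0),
    ]
    return MixtureModel(comps, design)


def toy_data(rng, n=4, m=3):
    return TimeCourseMatrix(values=rng.standard_normal((n, m)), times=np.arange(float(m)))


def test_component_covariance_values():
    assert np.allclose(component_covariance(comp(sigma2=1.0), 5), np.eye(5))
    c = comp(theta2=0.5, rho=0.6, sigma2=1.0, d2=0.4)
    cov = component_covariance(c, 3)
    assert np.allclose(cov, 0.5 * ar1_matrix(0.6, 3) + 1.4 * np.eye(3))
    assert cov[0, 0] == pytest.approx(0.5 / (1 - 0.36) + 1.4)  # 2.18125
    # AR(1)-residual regime: exactly theta2 * A(rho)
    k = comp(theta2=0.5, rho=0.6, sigma2=0.0, d2=0.0)
    assert np.allclose(component_covariance(k, 4), 0.5 * ar1_matrix(0.6, 4))
    with pytest.raises(SingularCovarianceError):
        component_covariance(comp(theta2=0.0, sigma2=0.0, d2=0.0), 3)


def test_covariance_monotone_in_sigma2():
    c = comp(theta2=0.5, rho=0.6, sigma2=1.0, d2=0.4)
    base = np.linalg.eigvalsh(component_covariance(c, 6))
    c2 = comp(theta2=0.5, rho=0.6, sigma2=1.5, d2=0.4)
    bumped = np.linalg.eigvalsh(component_covariance(c2, 6))
    assert np.allclose(bumped, base + 0.5)


def test_single_standard_normal_loglik():
    times = np.arange(2.0)
    design = DesignSpec(kind="fourier", times=times, order_k=1)
    model = MixtureModel([comp()], design)
    data = TimeCourseMatrix(values=np.zeros((1, 2)), times=times)
    assert mixture_loglik(model, data) == pytest.approx(-np.log(2 * np.pi))


def test_loglik_additivity_over_genes(rng):
    model = toy_model()
    data = toy_data(rng)
    doubled = TimeCourseMatrix(
        values=np.vstack([data.values, data.values]), times=data.times
    )
    assert mixture_loglik(model, doubled) == pytest.approx(2 * mixture_loglik(model, data))


def test_loglik_and_posteriors_match_density_sum_oracle(rng):
    model = toy_model()
    data = toy_data(rng)
    dens = np.zeros((data.n_genes, model.g))
    for h, c in enumerate(model.components):
        mvn = multivariate_normal(
            mean=model.design_matrix(h) @ c.beta, cov=component_covariance(c, data.n_times)
        )
        dens[:, h] = c.weight_p * mvn.pdf(data.values)
    assert mixture_loglik(model, data) == pytest.approx(np.log(dens.sum(axis=1)).sum(), abs=1e-10)
    tau = posterior_probs(model, data)
    assert np.allclose(tau, dens / dens.sum(axis=1, keepdims=True), atol=1e-12)
    assert np.allclose(tau.sum(axis=1), 1.0, atol=1e-10)


def test_posterior_degenerate_cases(rng):
    times = np.arange(3.0)
    design = DesignSpec(kind="fourier", times=times, order_k=1)
    data = toy_data(rng)
    single = MixtureModel([comp()], design)
    assert np.allclose(posterior_probs(single, data), 1.0)
    twin_params = dict(beta=(0.3, -0.2, 0.5), theta2=0.4, rho=0.2, sigma2=0.7, d2=0.1, omega=8.0)
    twins = MixtureModel([comp(0.3, **twin_params), comp(0.7, **twin_params)], design)
    tau = posterior_probs(twins, data)
    assert np.allclose(tau, [[0.3, 0.7]] * data.n_genes, atol=1e-12)


def test_serialization_round_trip_is_bit_exact():
    model = toy_model(weights=(1 / 3, 2 / 3))
    restored = MixtureModel.from_text(model.to_text())
    for a, b in zip(model.components, restored.components):
        assert a.weight_p == b.weight_p
        assert np.array_equal(a.beta, b.beta)
        assert (a.theta2, a.rho, a.sigma2, a.d2, a.period_omega) == (
            b.theta2, b.rho, b.sigma2, b.d2, b.period_omega,
        )
    assert np.array_equal(model.design.times, restored.design.times)


def test_parameter_counts():
    times = np.arange(5.0)
    design = DesignSpec(kind="fourier", times=times, order_k=1)
    single = MixtureModel([comp()], design)
    assert n_free_parameters(single) == 7  # 0 weights + 3 beta + 4 variance
    kim = MixtureModel(
        [comp(1 / 3), comp(1 / 3), comp(1 / 3)], design, variance_structure="ar1-only"
    )
    assert n_free_parameters(kim) == 2 + 9 + 6


def test_invalid_model_inputs():
    times = np.arange(3.0)
    design = DesignSpec(kind="fourier", times=times, order_k=1)
    with pytest.raises(InvalidParameterError):
        MixtureModel([comp(0.5), comp(0.2)], design)  # weights do not sum to 1
    with pytest.raises(InvalidParameterError):
        ComponentParams(weight_p=0.5, beta=np.zeros(3), theta2=-1.0, rho=0.0)
    with pytest.raises(InvalidParameterError):
        TimeCourseMatrix(values=np.array([[1.0, np.nan]]), times=np.arange(2.0))
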