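"""EM fitter: conditional-moment oracles, M-step grid oracles, limits and
convergence behaviour."""

import numpy as np
import pytest

from tcmix import (
    ComponentParams,
    DesignSpec,
    MixtureModel,
    TimeCourseMatrix,
    e_step,
    fit,
    fit_kim,
    initialize,
    m_step,
    map_labels,
    mixture_loglik,
    posterior_probs,
    preset,
    generate,
)
from tcmix.ar1 import ar1_logdet, ar1_matrix
from tcmix.em_fit import profile_ar1_update
from tcmix.exceptions import DegenerateComponentError, InvalidParameterError
from tcmix.simulate import replicate_seed


def single_component_model(theta2=0.4, rho=0.5, sigma2=0.3, d2=0.6, m=2):
    times = np.arange(float(m))
    design = DesignSpec(kind="fourier", times=times, order_k=1)
    c = ComponentParams(
        weight_p=1.0, beta=np.array([0.2, 0.1, -0.3]), theta2=theta2, rho=rho,
        sigma2=sigma2, d2=d2, period_omega=6.0,
    )
    return MixtureModel([c], design)


def test_e_step_matches_joint_gaussian_conditioning_oracle(rng):
    """g=1, m=2, n=2: conditional moments against brute-force conditioning of
    the stacked (2m + m)-dimensional Gaussian with a shared cluster effect."""
    m, n = 2, 2
    model = single_component_model(m=m)
    c = model.components[0]
    data = TimeCourseMatrix(values=rng.standard_normal((n, m)), times=np.arange(float(m)))

    B = c.theta2 * ar1_matrix(c.rho, m)
    sig = B + c.sigma2 * np.eye(m)
    mu = model.design_matrix(0) @ c.beta
    marg = np.block([
        [sig + c.d2 * np.eye(m), c.d2 * np.eye(m)],
        [c.d2 * np.eye(m), sig + c.d2 * np.eye(m)],
    ])
    resid = np.concatenate([data.values[0] - mu, data.values[1] - mu])
    solve = np.linalg.solve(marg, resid)

    # exact posterior of the shared effect v given both genes
    cov_vy = np.hstack([c.d2 * np.eye(m), c.d2 * np.eye(m)])
    v_exact = cov_vy @ solve
    v_var_exact = c.d2 * np.eye(m) - cov_vy @ np.linalg.solve(marg, cov_vy.T)
    # exact posterior mean of each gene-specific effect given both genes
    u_exact = [np.hstack([B, np.zeros((m, m))]) @ solve,
               np.hstack([np.zeros((m, m)), B]) @ solve]
    # conditional variance of u given (y, v)
    u_var_exact = B - B @ np.linalg.solve(sig, B)

    state = e_step(model, data)
    assert np.allclose(state.v_mean[0], v_exact, atol=1e-8)
    assert np.allclose(state.v_cond_var[0], v_var_exact, atol=1e-8)
    assert np.allclose(state.u_mean[0][0], u_exact[0], atol=1e-8)
    assert np.allclose(state.u_mean[0][1], u_exact[1], atol=1e-8)
    assert np.allclose(state.u_cond_var[0], u_var_exact, atol=1e-8)
    assert np.allclose(state.tau, 1.0)


def test_e_step_no_random_effects_limit(rng):
    model = single_component_model(theta2=0.0, d2=0.0, sigma2=1.0, m=4)
    data = TimeCourseMatrix(values=rng.standard_normal((3, 4)), times=np.arange(4.0))
    state = e_step(model, data)
    assert np.all(state.u_mean == 0.0)
    assert np.all(state.v_mean == 0.0)
    assert np.allclose(state.tau, posterior_probs(model, data))


def test_u_mean_shrinks_with_measurement_noise(rng):
    data = TimeCourseMatrix(values=rng.standard_normal((5, 4)), times=np.arange(4.0))
    norms = []
    for sigma2 in (0.1, 1.0, 10.0, 100.0):
        model = single_component_model(theta2=0.5, rho=0.4, sigma2=sigma2, d2=0.0, m=4)
        state = e_step(model, data)
        norms.append(np.linalg.norm(state.u_mean[0]))
    assert all(a > b for a, b in zip(norms, norms[1:]))


def test_profile_update_diagonal_matrix_gives_zero_rho():
    m, T, s = 6, 10.0, 1.7
    S = T * s * np.eye(m)
    theta2, rho = profile_ar1_update(S, T, m)
    assert abs(rho) < 1e-4
    assert theta2 == pytest.approx(s, rel=1e-4)


@pytest.mark.parametrize("seed", [0, 1])
def test_profile_update_matches_two_dim_grid_oracle(seed):
    rng = np.random.default_rng(seed)
    m, T = 3, 7.0
    X = rng.standard_normal((m, m + 2))
    S = T * (X @ X.T) / (m + 2)
    theta2, rho = profile_ar1_update(S, T, m)

    def expected_l3(th, r):
        quad = np.trace(np.linalg.solve(ar1_matrix(r, m), S))
        return -0.5 * (T * (m * np.log(2 * np.pi * th) + ar1_logdet(r)) + quad / th)

    rhos = np.linspace(-0.99, 0.99, 397)
    thetas = np.linspace(0.05, 5.0, 300)
    vals = np.array([[expected_l3(th, r) for th in thetas] for r in rhos])
    i, j = np.unravel_index(np.argmax(vals), vals.shape)
    assert rho == pytest.approx(rhos[i], abs=0.01)
    assert theta2 == pytest.approx(thetas[j], abs=0.05)
    assert expected_l3(theta2, rho) >= vals.max() - 1e-6


def test_m_step_reduces_to_ols_without_random_effects(rng):
    times = np.arange(12.0)
    design = DesignSpec(kind="fourier", times=times, order_k=1)
    X = design.matrix(8.0)
    model = MixtureModel(
        [ComponentParams(weight_p=1.0, beta=np.zeros(3), theta2=0.0, rho=0.0,
                         sigma2=1.0, d2=0.0, period_omega=8.0)], design,
    )
    data = TimeCourseMatrix(values=rng.standard_normal((20, 12)) + 1.5, times=times)
    new = m_step(e_step(model, data), data, model)
    ols, *_ = np.linalg.lstsq(X, data.values.mean(axis=0), rcond=None)
    assert np.allclose(new.components[0].beta, ols, atol=1e-10)


def test_m_step_degenerate_component_raises(rng):
    times = np.arange(6.0)
    design = DesignSpec(kind="fourier", times=times, order_k=1)
    near = ComponentParams(weight_p=0.5, beta=np.zeros(3), theta2=0.0, rho=0.0,
                           sigma2=1.0, d2=0.0, period_omega=6.0)
    far = ComponentParams(weight_p=0.5, beta=np.array([1e4, 0.0, 0.0]), theta2=0.0,
                          rho=0.0, sigma2=1.0, d2=0.0, period_omega=6.0)
    model = MixtureModel([near, far], design)
    data = TimeCourseMatrix(values=rng.standard_normal((8, 6)), times=times)
    with pytest.raises(DegenerateComponentError) as err:
        m_step(e_step(model, data), data, model)
    assert err.value.component == 1


def test_fit_single_component_parameter_recovery():
    cfg = preset("t5", n_genes=500, p=(1.0,), a0=(0.3,), a1=(1.03,), b1=(0.06,),
                 theta2=(0.5,), rho=(0.6,), sigma2=(0.0,), d2=(0.0,), periods=(6.0,), seed=11)
    ds = generate(cfg)
    res = fit(ds.data, 1, ds.true_model.design, init="true-partition",
              labels=ds.true_labels, periods=np.array(cfg.periods))
    c = res.model.components[0]
    truth = ds.true_model.components[0]
    # 3 Monte-Carlo standard errors at n=500 are on the order of a few percent
    assert np.all(np.abs(c.beta - truth.beta) < 0.06)
    assert abs(c.theta2 - truth.theta2) < 0.08
    assert abs(c.rho - truth.rho) < 0.06


def test_fit_infinite_tolerance_runs_single_iteration(t1_dataset):
    res = fit(t1_dataset.data, 3, t1_dataset.true_model.design, init="true-partition",
              labels=t1_dataset.true_labels, periods=np.array([6.0, 10.0, 16.0]),
              tol=np.inf, max_iter=1000)
    assert res.n_iter == 1
    assert res.loglik_trace.size == 2  # initial value + exactly one update


def test_objective_trace_monotone(t1_dataset):
    """Marginal mixture log-likelihood is non-decreasing along the fit: strictly
    for the AR(1)-residual baseline (a proper ECM), within a small relative
    slack for the full conditional scheme (a hybrid, not a strict EM)."""
    periods = np.array([6.0, 10.0, 16.0])
    res = fit(t1_dataset.data, 3, t1_dataset.true_model.design, init="true-partition",
              labels=t1_dataset.true_labels, periods=periods)
    diffs = np.diff(res.loglik_trace)
    assert diffs.min() >= -1e-4 * abs(res.loglik)
    kim = fit_kim(t1_dataset.data, 3, t1_dataset.true_model.design, init=t1_dataset.true_model)
    assert np.diff(kim.loglik_trace).min() >= -1e-6


def test_generative_parameters_are_near_fixed_point():
    cfg = preset("t5", n_genes=4000, seed=13)
    ds = generate(cfg)
    model = ds.true_model
    state = e_step(model, ds.data)
    new = m_step(state, ds.data, model)
    for c_new, c_old in zip(new.components, model.components):
        assert abs(c_new.weight_p - c_old.weight_p) < 0.03
        assert np.all(np.abs(c_new.beta - c_old.beta) < 0.05)
        assert abs(c_new.theta2 - c_old.theta2) / c_old.theta2 < 0.05
        assert abs(c_new.rho - c_old.rho) < 0.03


def test_reduction_to_mixture_of_regressions_matches_independent_em(rng):
    """With theta2 = d2 = 0 the fitter is a plain normal mixture of Fourier
    regressions; its objective must match an independently coded EM."""
    times = np.arange(12.0)
    design = DesignSpec(kind="fourier", times=times, order_k=1)
    X1, X2 = design.matrix(6.0), design.matrix(12.0)
    n = 60
    labels = rng.integers(0, 2, n)
    Y = np.where(labels[:, None] == 0, X1 @ [0.0, 2.0, 0.0], X2 @ [1.0, 0.0, 2.0])
    Y = Y + 0.7 * rng.standard_normal((n, 12))
    data = TimeCourseMatrix(values=Y, times=times)
    comps = [
        ComponentParams(weight_p=0.5, beta=np.array([0.1, 1.0, 0.1]), theta2=0.0,
                        rho=0.0, sigma2=1.0, d2=0.0, period_omega=6.0),
        ComponentParams(weight_p=0.5, beta=np.array([0.5, 0.1, 1.0]), theta2=0.0,
                        rho=0.0, sigma2=1.0, d2=0.0, period_omega=12.0),
    ]
    init = MixtureModel(comps, design)
    res = fit(data, 2, design, init=init, tol=1e-8, max_iter=500)

    # independent mixture-of-regressions EM with spherical noise
    p = np.array([0.5, 0.5])
    betas = [np.array([0.1, 1.0, 0.1]), np.array([0.5, 0.1, 1.0])]
    sig2 = np.array([1.0, 1.0])
    Xs = [X1, X2]
    ll_old = None
    for _ in range(500):
        logd = np.stack([
            np.log(p[h]) - 0.5 * (12 * np.log(2 * np.pi * sig2[h])
            + ((Y - Xs[h] @ betas[h]) ** 2).sum(1) / sig2[h])
            for h in range(2)
        ], axis=1)
        mx = logd.max(1, keepdims=True)
        w = np.exp(logd - mx)
        ll = float((mx.ravel() + np.log(w.sum(1))).sum())
        tau = w / w.sum(1, keepdims=True)
        T = tau.sum(0)
        p = T / n
        for h in range(2):
            target = (tau[:, h] @ Y) / T[h]
            betas[h], *_ = np.linalg.lstsq(Xs[h], target, rcond=None)
            r = Y - Xs[h] @ betas[h]
            sig2[h] = float(tau[:, h] @ (r * r).sum(1)) / (12 * T[h])
        if ll_old is not None and abs(ll - ll_old) < 1e-12:
            break
        ll_old = ll
    assert res.loglik == pytest.approx(ll, abs=1e-6)


def test_map_labels_rules():
    assert map_labels(np.array([[0.9, 0.1]])).tolist() == [0]
    assert map_labels(np.array([[0.5, 0.5]])).tolist() == [0]  # documented tie-break
    assert map_labels(np.eye(3)).tolist() == [0, 1, 2]


def test_initialize_strategies(t1_dataset):
    design = t1_dataset.true_model.design
    periods = np.array([6.0, 10.0, 16.0])
    with pytest.raises(InvalidParameterError):
        initialize(t1_dataset.data, 3, design, strategy="true-partition", periods=periods)
    m1 = initialize(t1_dataset.data, 3, design, strategy="kmeans", periods=periods, seed=4)
    m2 = initialize(t1_dataset.data, 3, design, strategy="kmeans", periods=periods, seed=4)
    for a, b in zip(m1.components, m2.components):
        assert np.array_equal(a.beta, b.beta) and a.theta2 == b.theta2
    one = initialize(t1_dataset.data, 3, design, strategy="random-starts",
                     periods=periods, n_starts=1, seed=9)
    five = initialize(t1_dataset.data, 3, design, strategy="random-starts",
                      periods=periods, n_starts=5, seed=9)
    assert mixture_loglik(five, t1_dataset.data) >= mixture_loglik(one, t1_dataset.data) - 1e-6


def test_initialize_true_partition_noiseless_equals_ols():
    cfg = preset("t1", n_genes=90, theta2=(0.0,) * 3, sigma2=(0.0,) * 3,
                 d2=(0.0,) * 3, seed=21)
    ds = generate(cfg)
    model = initialize(ds.data, 3, ds.true_model.design, strategy="true-partition",
                       labels_opt=ds.true_labels, periods=np.array(cfg.periods))
    for h, c in enumerate(model.components):
        X = ds.true_model.design_matrix(h)
        profile = ds.data.values[ds.true_labels == h].mean(axis=0)
        ols, *_ = np.linalg.lstsq(X, profile, rcond=None)
        assert np.allclose(c.beta, ols, atol=1e-10)
        assert np.allclose(c.beta, ds.true_model.components[h].beta, atol=1e-10)
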