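"""EM algorithm for the mixture of linear mixed models with AR(1) random
effects.

The complete data augment the profiles with the component labels z_jh, the
gene-specific effects u_jh and the shared cluster effects v_h.  The
complete-data log-likelihood separates into four blocks — label
probabilities, the conditional density of y, and the densities of u and v —
each maximised in closed form given the conditional moments from the E-step.

Following the EMMIX-WIRE scheme, the algorithm proceeds conditionally on the
current estimate of the shared effect: with B_h = theta2_h A(rho_h) and
S_uO = B_h + sigma2_h I,

    tau_jh    ∝ p_h phi(y_j ; X_h beta_h + v_hat_h, S_uO)
    v_hat_h   = (d2^-1 I + sum_j tau_jh S_uO^-1)^-1 sum_j tau_jh S_uO^-1 (y_j - X_h beta_h)
    E[u_jh|y] = B_h S_uO^-1 (y_j - X_h beta_h - v_hat_h)
    Var[u|y]  = B_h - B_h S_uO^-1 B_h

with v_hat_h = 0 in the d2 -> 0 limit.  The v_hat expression is the exact
posterior mean of the shared draw given all profiles of the component, and
E[u_jh|y] coincides with exact joint-Gaussian conditioning on all genes (the
shared-v uncertainty enters only the conditional variances).  Conditioning
the responsibilities on v_hat is essential, not cosmetic: when cluster
separation is carried by the realised shared effect, the marginal
(v-integrated) posteriors cannot recover the partition at all.  Each E-step
uses the v_hat carried over from the previous iteration (or from the
initial hard partition) for tau, then refreshes it.  The objective reported
in the per-iteration trace (and used for BIC and model comparison) is the
marginal mixture log-likelihood with component covariance
theta2 A(rho) + (d2 + sigma2) I; it is observed to be non-decreasing under
this scheme, whereas the v-conditional likelihood legitimately falls as d2
shrinks and is therefore not a useful convergence monitor.

The M-step updates mixing proportions, regression coefficients (ordinary
least squares on responsibility-weighted, random-effect-adjusted profiles),
sigma2 (expected residual sum of squares conditional on v_hat, including the
conditional-variance trace of u), d2 = tr E[v v^T | y] / m (the shared
effect is a single draw per component, so its density enters the objective
once; the posterior-variance trace keeps the update away from the
degenerate d2 = 0 fixed point of a pure plug-in update), and (theta2, rho) by
profiling: theta2_hat(rho) = tr(A(rho)^-1 S_h) / (m T_h) with the trace
expanded through the tridiagonal precision, and rho by bounded 1-D
maximisation of the profiled objective.

Iterations stop when the largest relative change across all scalar
parameters falls below ``tol`` (default 1e-5) or after ``max_iter``
iterations (default 1000).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.optimize import minimize_scalar
from sklearn.cluster import KMeans

from .ar1 import RHO_BOUND, ar1_logdet, ar1_matrix
from .designs import DesignSpec
from .exceptions import (
    DegenerateComponentError,
    InvalidParameterError,
    NumericalError,
    SingularCovarianceError,
)
from .model_core import (
    ComponentParams,
    MixtureModel,
    TimeCourseMatrix,
    _component_log_densities,
    n_free_parameters,
)

__all__ = [
    "EStepState",
    "FitResult",
    "e_step",
    "m_step",
    "fit",
    "initialize",
    "map_labels",
    "profile_ar1_update",
]

_EPS_MASS = 1e-8  # responsibility mass below which a component is degenerate

_logger = logging.getLogger("tcmix")


@dataclass
class EStepState:
    """Posterior membership probabilities and conditional random-effect moments.

    ``S`` accumulates, per component, sum_j tau_jh E[u_jh u_jh^T | y_j]; the
    conditional variance of u is identical across genes of a component, so it
    is stored once.  ``loglik`` is the objective the responsibilities were
    computed under: the v-conditional mixture log-likelihood when shared
    effects were carried in, the marginal one otherwise.
    """

    tau: np.ndarray  # (n, g)
    u_mean: np.ndarray  # (g, n, m)
    u_cond_var: np.ndarray  # (g, m, m)
    S: np.ndarray  # (g, m, m)
    v_mean: np.ndarray  # (g, m)
    v_cond_var: np.ndarray  # (g, m, m)
    v_second_moment: np.ndarray  # (g, m, m)
    component_mass: np.ndarray  # (g,)  T_h = sum_j tau_jh
    loglik: float


@dataclass
class FitResult:
    """Converged model with its objective trace and clustering."""

    model: MixtureModel
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    tau: np.ndarray
    labels: np.ndarray
    bic: float
    cluster_effects: np.ndarray | None = None  # (g, m) estimated v_hat

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def map_labels(tau: np.ndarray) -> np.ndarray:
    """MAP component assignment per gene; ties go to the lowest index."""
    return np.argmax(tau, axis=1)


def _posteriors_and_loglik(model: MixtureModel, data: TimeCourseMatrix):
    lw = _component_log_densities(model, data)
    mx = lw.max(axis=1, keepdims=True)
    p = np.exp(lw - mx)
    s = p.sum(axis=1, keepdims=True)
    tau = p / s
    loglik = float((mx.ravel() + np.log(s.ravel())).sum())
    return tau, loglik


def e_step(
    model: MixtureModel, data: TimeCourseMatrix, v_carry: np.ndarray | None = None
) -> EStepState:
    """Conditional moments of the random effects given the current model.

    ``v_carry`` holds the shared-effect estimates from the previous iteration
    (or the initial partition); when absent, the responsibilities fall back to
    the marginal posteriors of the v-integrated mixture.
    """
    n, m = data.values.shape
    g = model.g
    eye = np.eye(m)

    # pass 1: per-component factorisations and (conditional) responsibilities
    resid0 = np.empty((g, n, m))
    Bs = np.empty((g, m, m))
    sig_invs = np.empty((g, m, m))
    lw = np.empty((n, g))
    for h, c in enumerate(model.components):
        if c.theta2 <= 0 and c.sigma2 <= 0:
            raise SingularCovarianceError(
                f"component {h}: theta2 and sigma2 both zero, gene-level covariance singular"
            )
        resid0[h] = data.values - (model.design_matrix(h) @ c.beta)[None, :]
        Bs[h] = c.theta2 * ar1_matrix(c.rho, m) if c.theta2 > 0 else 0.0
        try:
            L = linalg.cholesky(Bs[h] + c.sigma2 * eye, lower=True)
            sig_invs[h] = linalg.cho_solve((L, True), eye)
        except linalg.LinAlgError as err:
            raise NumericalError(f"component {h}: singular gene-level covariance") from err
        if v_carry is not None:
            z = linalg.solve_triangular(L, (resid0[h] - v_carry[h][None, :]).T, lower=True)
            lw[:, h] = (
                np.log(c.weight_p)
                - np.log(np.diagonal(L)).sum()
                - 0.5 * (m * np.log(2.0 * np.pi) + (z * z).sum(axis=0))
            )
    if v_carry is None:
        tau, loglik = _posteriors_and_loglik(model, data)
    else:
        mx = lw.max(axis=1, keepdims=True)
        p = np.exp(lw - mx)
        s = p.sum(axis=1, keepdims=True)
        tau = p / s
        loglik = float((mx.ravel() + np.log(s.ravel())).sum())

    # pass 2: conditional moments of v and u
    u_mean = np.zeros((g, n, m))
    u_var = np.zeros((g, m, m))
    S = np.zeros((g, m, m))
    v_mean = np.zeros((g, m))
    v_var = np.zeros((g, m, m))
    v_second = np.zeros((g, m, m))
    mass = tau.sum(axis=0)
    for h, c in enumerate(model.components):
        T = mass[h]
        sig_inv = sig_invs[h]
        if c.d2 > 0:
            prec = eye / c.d2 + T * sig_inv
            try:
                v_var[h] = linalg.inv(prec)
            except linalg.LinAlgError as err:
                raise NumericalError(f"component {h}: singular shared-effect precision") from err
            v_mean[h] = v_var[h] @ sig_inv @ (tau[:, h] @ resid0[h])
        # else: v_hat = 0, Var[v|y] = 0 (no shared effect)
        v_second[h] = np.outer(v_mean[h], v_mean[h]) + v_var[h]

        if c.theta2 > 0:
            gain = Bs[h] @ sig_inv
            r = resid0[h] - v_mean[h][None, :]
            u_mean[h] = r @ gain.T
            u_var[h] = Bs[h] - gain @ Bs[h]
            u_var[h] = 0.5 * (u_var[h] + u_var[h].T)
            S[h] = (tau[:, h][:, None] * u_mean[h]).T @ u_mean[h] + T * u_var[h]
            S[h] = 0.5 * (S[h] + S[h].T)
        # else: u moments identically zero

    return EStepState(
        tau=tau,
        u_mean=u_mean,
        u_cond_var=u_var,
        S=S,
        v_mean=v_mean,
        v_cond_var=v_var,
        v_second_moment=v_second,
        component_mass=mass,
        loglik=loglik,
    )


def profile_ar1_update(S: np.ndarray, mass: float, m: int) -> tuple[float, float]:
    """Maximise the expected AR(1)-block objective over (theta2, rho).

    For fixed rho the optimal variance is theta2(rho) = tr(A(rho)^-1 S) /
    (m * mass); substituting back leaves a 1-D objective in rho,
    -mass * (m log theta2(rho) + log det A(rho)), maximised on the clipped
    interval |rho| <= 1 - 1e-6 by bounded scalar minimisation.
    """
    diag = np.diagonal(S)
    tr_S = float(diag.sum())
    if tr_S <= 1e-12:
        return 0.0, 0.0
    off = float(np.diagonal(S, 1).sum() + np.diagonal(S, -1).sum())
    corners = float(diag[0] + diag[-1])

    def theta2_of(rho: float) -> float:
        # tr(A(rho)^-1 S) / (m T) via the tridiagonal precision expansion
        return ((1.0 + rho * rho) * tr_S - rho * off - rho * rho * corners) / (m * mass)

    def neg_obj(rho: float) -> float:
        th = theta2_of(rho)
        if th <= 0 or not np.isfinite(th):
            return np.inf
        return mass * (m * np.log(th) + ar1_logdet(rho))

    res = minimize_scalar(
        neg_obj, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded", options={"xatol": 1e-8}
    )
    rho = float(res.x)
    return theta2_of(rho), rho


def m_step(state: EStepState, data: TimeCourseMatrix, model: MixtureModel) -> MixtureModel:
    """Closed-form parameter updates from the E-step moments.

    Takes the previous model for structural information (design kind,
    per-component periods, variance structure); all parameter values are
    recomputed.
    """
    n, m = data.values.shape
    new_components = []
    for h, c in enumerate(model.components):
        T = state.component_mass[h]
        if T < _EPS_MASS:
            raise DegenerateComponentError(h, float(T))
        w = state.tau[:, h]
        X = model.design_matrix(h)

        adj = data.values - state.u_mean[h] - state.v_mean[h][None, :]
        target = (w @ adj) / T
        beta, *_ = np.linalg.lstsq(X, target, rcond=None)

        # Residual variance conditional on v_hat (held fixed, in the spirit of
        # the conditional scheme): expected RSS adds only the conditional
        # variance of u.  Charging the v-posterior variance to every gene
        # would inflate sigma2 inversely with cluster size.
        e = adj - (X @ beta)[None, :]
        rss = float(w @ (e * e).sum(axis=1))
        rss += T * np.trace(state.u_cond_var[h])
        sigma2 = rss / (m * T)

        theta2, rho = profile_ar1_update(state.S[h], T, m)
        d2 = float(np.trace(state.v_second_moment[h])) / m

        new_components.append(
            ComponentParams(
                weight_p=T / n,
                beta=beta,
                theta2=theta2,
                rho=rho,
                sigma2=max(sigma2, 0.0),
                d2=max(d2, 0.0),
                period_omega=c.period_omega,
            )
        )
    return MixtureModel(new_components, model.design, model.variance_structure)


def _parameter_vector(model: MixtureModel) -> np.ndarray:
    full = model.variance_structure == "full"
    parts = [model.weights]
    parts += [np.asarray(c.free_parameters(full)) for c in model.components]
    return np.concatenate(parts)


def _relative_change(new: np.ndarray, old: np.ndarray) -> float:
    return float(np.max(np.abs(new - old) / (np.abs(old) + 1e-12)))


def run_em(
    data: TimeCourseMatrix,
    model: MixtureModel,
    e_step_fn,
    m_step_fn,
    tol: float = 1e-5,
    max_iter: int = 1000,
    v_init: np.ndarray | None = None,
) -> FitResult:
    """Generic EM driver shared by the full model and the AR(1)-residual
    baseline: alternates the supplied steps under the relative-change
    stopping rule, carrying the shared-effect estimates between iterations,
    and assembles the :class:`FitResult`."""
    from .model_core import mixture_loglik

    trace = [mixture_loglik(model, data)]
    prev_vec = _parameter_vector(model)
    converged = False
    n_iter = 0
    v_carry = v_init
    for n_iter in range(1, max_iter + 1):
        state = e_step_fn(model, data, v_carry)
        model = m_step_fn(state, data, model)
        v_carry = state.v_mean
        ll = mixture_loglik(model, data)
        trace.append(ll)
        _logger.debug("iteration %d: loglik %.6f", n_iter, ll)
        if not np.isfinite(ll):
            raise NumericalError(f"non-finite objective at iteration {n_iter}")
        vec = _parameter_vector(model)
        if _relative_change(vec, prev_vec) < tol:
            converged = True
            break
        prev_vec = vec
    final_state = e_step_fn(model, data, v_carry)
    tau = final_state.tau
    final_ll = trace[-1]
    bic = -2.0 * final_ll + n_free_parameters(model) * np.log(data.n_genes)
    return FitResult(
        model=model,
        loglik_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
        tau=tau,
        labels=map_labels(tau),
        bic=float(bic),
        cluster_effects=final_state.v_mean,
    )


def fit(
    data: TimeCourseMatrix,
    g: int,
    design: DesignSpec,
    init: str | MixtureModel = "kmeans",
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 1000,
    labels: np.ndarray | None = None,
    periods: np.ndarray | None = None,
    n_starts: int = 10,
) -> FitResult:
    """Fit the full AR(1)-random-effects mixture by EM.

    ``init`` is an initialisation strategy name (``"true-partition"``,
    ``"kmeans"``, ``"random-starts"``) or an explicit starting
    :class:`MixtureModel`.  Fourier designs require per-component ``periods``
    unless an explicit model is given.
    """
    if data.n_genes < g:
        raise InvalidParameterError(f"cannot fit {g} components to {data.n_genes} genes")
    if isinstance(init, MixtureModel):
        model, v0 = init, None
    else:
        model, v0 = _initialize_with_effects(
            data, g, design, strategy=init, labels_opt=labels, periods=periods,
            n_starts=n_starts, seed=seed,
        )
    return run_em(data, model, e_step, m_step, tol=tol, max_iter=max_iter, v_init=v0)


# ---------------------------------------------------------------------------
# initialisation


def _model_from_partition(
    data: TimeCourseMatrix,
    hard_labels: np.ndarray,
    g: int,
    design: DesignSpec,
    periods: np.ndarray | None,
    variance_structure: str = "full",
) -> MixtureModel:
    """Method-of-moments parameter estimates from a hard partition.

    Per cluster: OLS mean profile; the column mean of the residuals estimates
    the realised shared effect (giving d2); the de-meaned residual covariance
    yields rho from the lag-2/lag-1 autocovariance ratio, then theta2 and
    sigma2 from the stationary-variance split.
    """
    n, m = data.values.shape
    comps = []
    v0 = np.zeros((g, m))
    for h in range(g):
        members = data.values[hard_labels == h]
        n_h = members.shape[0]
        if n_h == 0:
            raise DegenerateComponentError(h, 0.0)
        omega = None if periods is None else float(periods[h])
        X = design.matrix(omega)
        profile = members.mean(axis=0)
        beta, *_ = np.linalg.lstsq(X, profile, rcond=None)
        resid = members - (X @ beta)[None, :]

        vbar = resid.mean(axis=0)
        if variance_structure == "full":
            v0[h] = vbar
        d2 = max(float(vbar @ vbar) / m, 1e-4)
        centred = resid - vbar[None, :]
        denom = max(n_h - 1, 1)
        c0 = float((centred * centred).sum()) / (denom * m)
        c1 = float((centred[:, :-1] * centred[:, 1:]).sum()) / (denom * (m - 1))
        c2 = float((centred[:, :-2] * centred[:, 2:]).sum()) / (denom * max(m - 2, 1))
        rho = float(np.clip(c2 / c1, -0.95, 0.95)) if abs(c1) > 1e-10 else 0.0
        gamma_u = c1 / rho if abs(rho) > 0.02 and 0.0 < c1 / rho < c0 else 0.5 * c0
        if variance_structure == "ar1-only":
            comps.append(
                ComponentParams(
                    weight_p=n_h / n,
                    beta=beta,
                    theta2=max(c0 * (1.0 - rho * rho), 1e-4),
                    rho=rho,
                    sigma2=0.0,
                    d2=0.0,
                    period_omega=omega,
                )
            )
        else:
            comps.append(
                ComponentParams(
                    weight_p=n_h / n,
                    beta=beta,
                    theta2=max(gamma_u * (1.0 - rho * rho), 1e-4),
                    rho=rho,
                    sigma2=max(c0 - gamma_u, 1e-4),
                    d2=d2,
                    period_omega=omega,
                )
            )
    return MixtureModel(comps, design, variance_structure), v0


def initialize(
    data: TimeCourseMatrix,
    g: int,
    design: DesignSpec,
    strategy: str = "kmeans",
    labels_opt: np.ndarray | None = None,
    periods: np.ndarray | None = None,
    n_starts: int = 10,
    seed: int = 0,
    variance_structure: str = "full",
) -> MixtureModel:
    """Initial model from a labelled partition, k-means, or random restarts."""
    model, _ = _initialize_with_effects(
        data, g, design, strategy, labels_opt, periods, n_starts, seed, variance_structure
    )
    return model


def _initialize_with_effects(
    data: TimeCourseMatrix,
    g: int,
    design: DesignSpec,
    strategy: str = "kmeans",
    labels_opt: np.ndarray | None = None,
    periods: np.ndarray | None = None,
    n_starts: int = 10,
    seed: int = 0,
    variance_structure: str = "full",
) -> tuple[MixtureModel, np.ndarray | None]:
    """As :func:`initialize`, also returning the initial shared-effect
    estimates (per-cluster mean residuals) used to seed the first E-step."""
    if strategy == "true-partition":
        if labels_opt is None:
            raise InvalidParameterError("true-partition initialisation requires labels")
        return _model_from_partition(
            data, np.asarray(labels_opt), g, design, periods, variance_structure
        )
    if strategy == "kmeans":
        km = KMeans(n_clusters=g, n_init=n_starts, random_state=seed)
        hard = km.fit_predict(data.values)
        return _model_from_partition(data, hard, g, design, periods, variance_structure)
    if strategy == "random-starts":
        rng = np.random.default_rng(seed)
        best, best_ll = None, -np.inf
        for _ in range(n_starts):
            while True:  # ensure every component receives at least one gene
                hard = rng.integers(0, g, size=data.n_genes)
                if len(np.unique(hard)) == g:
                    break
            model, v0 = _model_from_partition(data, hard, g, design, periods, variance_structure)
            try:
                short = run_em(data, model, e_step, m_step, tol=1e-3, max_iter=10, v_init=v0)
            except (DegenerateComponentError, NumericalError):
                continue
            if short.loglik > best_ll:
                best_ll, best = short.loglik, (short.model, short.cluster_effects)
        if best is None:
            raise NumericalError("all random starts failed")
        return best
    raise InvalidParameterError(f"unknown initialisation strategy {strategy!r}")
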