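"""Data model for the normal mixture of linear mixed models.

Conditional on membership of component h, the profile of gene j over the m
time points is

    y_j = X_h beta_h + u_jh + v_h + eps_jh,

with gene-specific AR(1) random effect u_jh ~ N(0, theta2_h A(rho_h)), a
cluster (coregulation) random effect v_h ~ N(0, d2_h I) shared by all genes of
the component, and measurement error eps_jh ~ N(0, sigma2_h I).  Marginally a
component is multivariate normal with mean X_h beta_h and covariance

    Sigma_h = theta2_h A(rho_h) + d2_h I + sigma2_h I.

Because v_h is shared within a component, genes are not marginally
independent; throughout the package "log-likelihood" denotes the working
objective sum_j log sum_h p_h phi(y_j; X_h beta_h, Sigma_h), the standard
EMMIX-WIRE convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .ar1 import ar1_matrix
from .designs import DesignSpec
from .exceptions import InvalidParameterError, SingularCovarianceError

__all__ = [
    "TimeCourseMatrix",
    "ComponentParams",
    "MixtureModel",
    "component_covariance",
    "mixture_loglik",
    "posterior_probs",
    "component_logpdf",
]


@dataclass
class TimeCourseMatrix:
    """n x m expression matrix with time coordinates and gene identifiers.

    Values are on an arbitrary (typically log) scale; missing values are not
    allowed — genes with incomplete profiles are dropped upstream.
    """

    values: np.ndarray
    times: np.ndarray
    gene_ids: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError("expression values must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("expression matrix contains missing/non-finite values")
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.times.size != self.values.shape[1]:
            raise InvalidParameterError("times length must match number of columns")
        if self.values.shape[1] < 2:
            raise InvalidParameterError("need at least two time points")
        if self.gene_ids is None:
            self.gene_ids = [f"g{i + 1:05d}" for i in range(self.values.shape[0])]
        elif len(self.gene_ids) != self.values.shape[0]:
            raise InvalidParameterError("gene_ids length must match number of rows")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]


@dataclass
class ComponentParams:
    """Parameters of one mixture component.

    beta follows the design-column order (for Fourier k=1: a0, a1, b1).
    theta2 is the AR(1) innovation-scale variance, rho the autocorrelation,
    sigma2 the measurement-error variance (Omega = sigma2 I) and d2 the
    cluster-effect variance (D = d2 I).  period_omega is the Fourier period
    (ignored for spline designs).
    """

    weight_p: float
    beta: np.ndarray
    theta2: float
    rho: float
    sigma2: float = 0.0
    d2: float = 0.0
    period_omega: float | None = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if not (0.0 < self.weight_p < 1.0 or np.isclose(self.weight_p, 1.0)):
            raise InvalidParameterError(f"mixing proportion must be in (0, 1], got {self.weight_p!r}")
        for name in ("theta2", "sigma2", "d2"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if abs(self.rho) >= 1.0:
            raise InvalidParameterError(f"rho must lie in (-1, 1), got {self.rho!r}")

    def free_parameters(self, full: bool = True) -> list[float]:
        """Flat list of this component's free scalars (excluding the weight)."""
        out = list(self.beta)
        out += [self.theta2, self.rho]
        if full:
            out += [self.sigma2, self.d2]
        return out


@dataclass
class MixtureModel:
    """A g-component mixture of linear mixed models.

    variance_structure is ``"full"`` (theta2, rho, sigma2, d2 free per
    component) or ``"ar1-only"`` (sigma2 = d2 = 0, the AR(1)-residual
    baseline).  Z1 and Z2 of the mixed-model formulation are identity
    matrices, so no incidence structure is stored.
    """

    components: list[ComponentParams]
    design: DesignSpec
    variance_structure: str = "full"

    def __post_init__(self):
        if self.variance_structure not in ("full", "ar1-only"):
            raise InvalidParameterError(
                f"unknown variance structure {self.variance_structure!r}"
            )
        w = sum(c.weight_p for c in self.components)
        if abs(w - 1.0) > 1e-8:
            raise InvalidParameterError(f"mixing proportions sum to {w}, expected 1")

    @property
    def g(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight_p for c in self.components])

    def design_matrix(self, h: int) -> np.ndarray:
        return self.design.matrix(self.components[h].period_omega)

    def means(self) -> np.ndarray:
        """g x m matrix of component mean profiles X_h beta_h."""
        return np.stack([self.design_matrix(h) @ c.beta for h, c in enumerate(self.components)])

    # --- serialization (exact float round trip via JSON repr) ---

    def to_text(self) -> str:
        doc = {
            "variance_structure": self.variance_structure,
            "design": {
                "kind": self.design.kind,
                "times": self.design.times.tolist(),
                "order_k": self.design.order_k,
                "spline_df": self.design.spline_df,
            },
            "components": [
                {
                    "weight": c.weight_p,
                    "beta": c.beta.tolist(),
                    "theta2": c.theta2,
                    "rho": c.rho,
                    "sigma2": c.sigma2,
                    "d2": c.d2,
                    "period": c.period_omega,
                }
                for c in self.components
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_text(cls, text: str) -> "MixtureModel":
        doc = json.loads(text)
        design = DesignSpec(
            kind=doc["design"]["kind"],
            times=np.array(doc["design"]["times"]),
            order_k=doc["design"]["order_k"],
            spline_df=doc["design"]["spline_df"],
        )
        comps = [
            ComponentParams(
                weight_p=c["weight"],
                beta=np.array(c["beta"]),
                theta2=c["theta2"],
                rho=c["rho"],
                sigma2=c["sigma2"],
                d2=c["d2"],
                period_omega=c["period"],
            )
            for c in doc["components"]
        ]
        return cls(comps, design, doc["variance_structure"])


def component_covariance(params: ComponentParams, m: int) -> np.ndarray:
    """Marginal covariance theta2 A(rho) + (d2 + sigma2) I of one component."""
    if params.theta2 == 0.0 and params.sigma2 == 0.0 and params.d2 == 0.0:
        raise SingularCovarianceError("all variance components are zero")
    cov = (params.d2 + params.sigma2) * np.eye(m)
    if params.theta2 > 0.0:
        cov += params.theta2 * ar1_matrix(params.rho, m)
    return cov


def _chol(cov: np.ndarray) -> np.ndarray:
    try:
        return linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as err:
        raise SingularCovarianceError(f"covariance not positive definite: {err}") from err


def component_logpdf(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Multivariate-normal log density of each row of y (n x m) via Cholesky."""
    L = _chol(cov)
    resid = y - mean[None, :]
    z = linalg.solve_triangular(L, resid.T, lower=True)
    logdet = 2.0 * np.log(np.diagonal(L)).sum()
    m = cov.shape[0]
    return -0.5 * (m * np.log(2.0 * np.pi) + logdet + (z * z).sum(axis=0))


def _component_log_densities(model: MixtureModel, data: TimeCourseMatrix) -> np.ndarray:
    """n x g matrix of log p_h + log phi_h(y_j)."""
    m = data.n_times
    out = np.empty((data.n_genes, model.g))
    for h, c in enumerate(model.components):
        mean = model.design_matrix(h) @ c.beta
        cov = component_covariance(c, m)
        out[:, h] = np.log(c.weight_p) + component_logpdf(data.values, mean, cov)
    return out


def mixture_loglik(model: MixtureModel, data: TimeCourseMatrix) -> float:
    """Working log-likelihood: sum_j log sum_h p_h phi(y_j; X_h beta_h, Sigma_h)."""
    lw = _component_log_densities(model, data)
    mx = lw.max(axis=1)
    return float((mx + np.log(np.exp(lw - mx[:, None]).sum(axis=1))).sum())


def posterior_probs(model: MixtureModel, data: TimeCourseMatrix) -> np.ndarray:
    """n x g posterior membership probabilities tau_jh, log-sum-exp stabilised."""
    lw = _component_log_densities(model, data)
    lw -= lw.max(axis=1, keepdims=True)
    tau = np.exp(lw)
    tau /= tau.sum(axis=1, keepdims=True)
    return tau


def n_free_parameters(model: MixtureModel) -> int:
    """Number of free parameters: (g-1) weights + regression coefficients +
    per-component variance-structure parameters (theta2, rho, sigma2, d2 for
    the full model; theta2, rho for the AR(1)-residual baseline)."""
    per_comp = 4 if model.variance_structure == "full" else 2
    return (model.g - 1) + sum(len(c.beta) for c in model.components) + model.g * per_comp
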