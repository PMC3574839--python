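"""Synthetic time-course generator for the three simulation regimes.

Three clusters of periodic genes with first-order Fourier mean profiles at
periods (6, 10, 16), observed at 24 time points 0..23.  The regimes are

* ``full`` — gene-specific AR(1) effects, a shared cluster effect and
  measurement error (the proposed model's own generative process);
* ``no-cluster-effect`` — d2 = 0, so gene profiles are independent within a
  cluster (the Qin–Self-type special case);
* ``ar1-residual`` — sigma2 = d2 = 0, so the component covariance is exactly
  theta2 A(rho) (the AR(1)-residual baseline's generative process).

``preset`` returns the exact parameter blocks of the six study tables;
``generate`` draws one labelled dataset.  The cluster effect v_h is drawn
once per component per dataset — this is what makes gene profiles within a
cluster correlated.  The number of genes per dataset is a study choice (the
default 400 gives expected cluster sizes of about 234/40/126).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg

from .ar1 import ar1_matrix
from .designs import DesignSpec
from .exceptions import ConfigurationError
from .model_core import ComponentParams, MixtureModel, TimeCourseMatrix

__all__ = ["SimulationConfig", "LabelledDataset", "preset", "generate", "generate_replicates"]

REGIMES = ("full", "no-cluster-effect", "ar1-residual")


@dataclass
class SimulationConfig:
    """Generative configuration for one batch of replicate datasets."""

    regime: str
    n_genes: int = 400
    times: np.ndarray = field(default_factory=lambda: np.arange(24.0))
    periods: tuple = (6.0, 10.0, 16.0)
    p: tuple = (0.585, 0.1, 0.315)
    a0: tuple = (0.3, 1.0, 0.2)
    a1: tuple = (1.03, 1.0, 0.02)
    b1: tuple = (0.06, 0.9, 0.01)
    theta2: tuple = (0.5, 0.5, 0.5)
    rho: tuple = (0.6, 0.6, 0.6)
    sigma2: tuple = (1.0, 1.0, 1.0)
    d2: tuple = (0.4, 0.2, 0.3)
    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ConfigurationError(f"unknown regime {self.regime!r}")
        if abs(sum(self.p) - 1.0) > 1e-10:
            raise ConfigurationError(f"mixing proportions sum to {sum(self.p)}")
        if self.regime in ("no-cluster-effect", "ar1-residual") and any(v != 0 for v in self.d2):
            raise ConfigurationError(f"regime {self.regime!r} requires d2 = 0")
        if self.regime == "ar1-residual" and any(v != 0 for v in self.sigma2):
            raise ConfigurationError("regime 'ar1-residual' requires sigma2 = 0")
        self.times = np.asarray(self.times, dtype=float)

    @property
    def g(self) -> int:
        return len(self.p)

    def true_model(self) -> MixtureModel:
        design = DesignSpec(kind="fourier", times=self.times, order_k=1)
        comps = [
            ComponentParams(
                weight_p=self.p[h],
                beta=np.array([self.a0[h], self.a1[h], self.b1[h]]),
                theta2=self.theta2[h],
                rho=self.rho[h],
                sigma2=self.sigma2[h],
                d2=self.d2[h],
                period_omega=self.periods[h],
            )
            for h in range(self.g)
        ]
        structure = "ar1-only" if self.regime == "ar1-residual" else "full"
        return MixtureModel(comps, design, structure)


@dataclass
class LabelledDataset:
    """A simulated dataset with its generating truth attached."""

    data: TimeCourseMatrix
    true_labels: np.ndarray
    true_model: MixtureModel
    cluster_effects: np.ndarray  # (g, m) realised v_h


_PRESETS = {
    "t1": dict(regime="full", theta2=(0.5,) * 3, sigma2=(1.0,) * 3, d2=(0.4, 0.2, 0.3)),
    "t2": dict(regime="full", theta2=(1.3,) * 3, sigma2=(1.0,) * 3, d2=(0.4, 0.2, 0.3)),
    "t3": dict(regime="no-cluster-effect", theta2=(0.5,) * 3, sigma2=(1.0,) * 3, d2=(0.0,) * 3),
    "t4": dict(regime="no-cluster-effect", theta2=(1.3,) * 3, sigma2=(1.0,) * 3, d2=(0.0,) * 3),
    "t5": dict(regime="ar1-residual", theta2=(0.5,) * 3, sigma2=(0.0,) * 3, d2=(0.0,) * 3),
    "t6": dict(regime="ar1-residual", theta2=(1.3,) * 3, sigma2=(0.0,) * 3, d2=(0.0,) * 3),
}


def preset(table_id: str, **overrides) -> SimulationConfig:
    """Parameter block of one of the six study tables (``"t1"`` .. ``"t6"``)."""
    if table_id not in _PRESETS:
        raise ConfigurationError(f"unknown preset {table_id!r}; choose from {sorted(_PRESETS)}")
    kwargs = dict(_PRESETS[table_id])
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def generate(config: SimulationConfig, seed: int | None = None) -> LabelledDataset:
    """Draw one labelled dataset from the configured generative model.

    Membership labels are categorical draws from p; v_h is drawn once per
    component, u_jh per gene from N(0, theta2 A(rho)), eps_jh per gene from
    N(0, sigma2 I).  Bit-reproducible for a given seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    model = config.true_model()
    m = config.times.size
    n = config.n_genes

    labels = rng.choice(config.g, size=n, p=np.asarray(config.p))
    v = np.zeros((config.g, m))
    values = np.empty((n, m))
    for h, comp in enumerate(model.components):
        if comp.d2 > 0:
            v[h] = rng.normal(0.0, np.sqrt(comp.d2), size=m)
        members = np.flatnonzero(labels == h)
        mean = model.design_matrix(h) @ comp.beta + v[h]
        profiles = np.tile(mean, (members.size, 1))
        if comp.theta2 > 0:
            L = linalg.cholesky(comp.theta2 * ar1_matrix(comp.rho, m), lower=True)
            profiles += rng.standard_normal((members.size, m)) @ L.T
        if comp.sigma2 > 0:
            profiles += rng.normal(0.0, np.sqrt(comp.sigma2), size=(members.size, m))
        values[members] = profiles

    data = TimeCourseMatrix(values=values, times=config.times)
    return LabelledDataset(data=data, true_labels=labels, true_model=model, cluster_effects=v)


def replicate_seed(master_seed: int, replicate: int) -> np.random.SeedSequence:
    """Seed-splitting rule: replicate r of master seed s uses SeedSequence((s, r)),
    so any single replicate can be regenerated in isolation."""
    return np.random.SeedSequence((master_seed, replicate))


def generate_replicates(config: SimulationConfig):
    """Yield ``config.n_replicates`` independent labelled datasets."""
    for r in range(config.n_replicates):
        yield generate(config, seed=replicate_seed(config.seed, r))
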