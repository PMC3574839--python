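"""Model selection: BIC over the number of components and the global grid
search over component periods.

BIC = -2 log L + nu log n, with n the number of genes (the mixture is over
genes) and nu the free-parameter count of the fitted model; lower is better.
The period search fits the model at every candidate period vector with the
periods held fixed and keeps the fit with the highest final log-likelihood —
the "global grid search" strategy, used because estimating periods inside the
M-step tends to stick at the initial value.  By default all components share
one period (the Cartesian product over per-component periods grows as
|grid|^g and is opt-in).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .designs import DesignSpec
from .em_fit import FitResult, fit
from .exceptions import InvalidParameterError
from .model_core import MixtureModel, TimeCourseMatrix, n_free_parameters

__all__ = ["PeriodGrid", "bic", "grid_search_periods", "sweep_components"]


@dataclass
class PeriodGrid:
    """Candidate periods; ``share_across_components`` restricts the search to
    a single common period (default) instead of the full product."""

    candidate_periods: np.ndarray
    share_across_components: bool = True

    def __post_init__(self):
        self.candidate_periods = np.asarray(self.candidate_periods, dtype=float).ravel()
        if self.candidate_periods.size == 0:
            raise InvalidParameterError("period grid is empty")
        if np.any(self.candidate_periods <= 0):
            raise InvalidParameterError("candidate periods must be positive")

    def vectors(self, g: int):
        if self.share_across_components:
            for w in self.candidate_periods:
                yield (w,) * g
        else:
            yield from itertools.product(self.candidate_periods, repeat=g)


def bic(fit_result: FitResult, n_genes: int) -> float:
    """-2 log L + nu log(n_genes) for a fitted model."""
    nu = n_free_parameters(fit_result.model)
    return -2.0 * fit_result.loglik + nu * np.log(n_genes)


def grid_search_periods(
    data: TimeCourseMatrix,
    g: int,
    grid: PeriodGrid,
    design: DesignSpec,
    fit_fn=fit,
    **fit_options,
) -> tuple[FitResult, tuple, list]:
    """Best fit over the period grid by final log-likelihood.

    Returns ``(best_fit, best_periods, log)`` where ``log`` holds one
    ``(periods, loglik)`` record per evaluated grid point.
    """
    best_fit, best_periods = None, None
    log = []
    for periods in grid.vectors(g):
        result = fit_fn(data, g, design, periods=np.asarray(periods), **fit_options)
        log.append((periods, result.loglik))
        if best_fit is None or result.loglik > best_fit.loglik:
            best_fit, best_periods = result, periods
    return best_fit, best_periods, log


def sweep_components(
    data: TimeCourseMatrix,
    g_values,
    design: DesignSpec,
    fit_fn=fit,
    **fit_options,
) -> list[dict]:
    """Fit each g and tabulate (g, loglik, nu, BIC) for BIC-based selection."""
    rows = []
    for g in g_values:
        result = fit_fn(data, int(g), design, **fit_options)
        rows.append(
            {
                "g": int(g),
                "loglik": result.loglik,
                "n_params": n_free_parameters(result.model),
                "bic": bic(result, data.n_genes),
                "fit": result,
            }
        )
    return rows
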