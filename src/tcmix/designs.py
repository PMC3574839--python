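"""Fixed-effects design matrices: Fourier bases for periodic mean profiles and
cubic B-spline bases for non-periodic ones.

A k-th order Fourier expansion of a periodic profile with period ``omega`` is

    g(t) = a0 + sum_{j=1..k} [ a_j cos(2 pi j t / omega) + b_j sin(2 pi j t / omega) ],

so the design row at time t is ``[1, cos(2 pi t/omega), sin(2 pi t/omega), ...,
cos(2 pi k t/omega), sin(2 pi k t/omega)]`` (harmonics interleaved cos/sin) and
the coefficient vector reads (a0, a1, b1, a2, b2, ...).  First order (k = 1) is
the default used throughout the experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .exceptions import InvalidParameterError

__all__ = ["DesignSpec", "fourier_design", "bspline_design"]


def fourier_design(times: np.ndarray, order_k: int = 1, period_omega: float = 1.0) -> np.ndarray:
    """m x (2k+1) Fourier design matrix at the given time coordinates."""
    if period_omega <= 0:
        raise InvalidParameterError(f"period must be positive, got {period_omega!r}")
    if order_k < 1:
        raise InvalidParameterError(f"Fourier order must be >= 1, got {order_k!r}")
    t = np.asarray(times, dtype=float).ravel()
    cols = [np.ones_like(t)]
    for j in range(1, order_k + 1):
        ang = 2.0 * np.pi * j * t / period_omega
        cols.append(np.cos(ang))
        cols.append(np.sin(ang))
    return np.column_stack(cols)


def bspline_design(times: np.ndarray, spline_df: int) -> np.ndarray:
    """Cubic B-spline basis (partition of unity), interior knots at quantiles.

    The basis has ``spline_df`` columns; every row sums to one, so the
    intercept is absorbed into the basis rather than prepended.  Requires more
    distinct time points than basis functions.
    """
    if spline_df < 4:
        raise InvalidParameterError(f"cubic spline basis needs df >= 4, got {spline_df!r}")
    t = np.asarray(times, dtype=float).ravel()
    if t.size <= spline_df:
        raise InvalidParameterError(
            f"need more time points ({t.size}) than basis functions ({spline_df})"
        )
    degree = 3
    n_interior = spline_df - (degree + 1)
    if n_interior > 0:
        qs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
        interior = np.quantile(t, qs)
    else:
        interior = np.array([])
    lo, hi = t.min(), t.max()
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    design = BSpline.design_matrix(t, knots, degree, extrapolate=True).toarray()
    return design


@dataclass
class DesignSpec:
    """Specification of the fixed-effects basis shared by all components.

    ``kind`` is ``"fourier"`` (periodic profiles; each component carries its
    own period in its parameter block) or ``"bspline"`` (non-periodic
    profiles).  ``times`` are the m observation time coordinates.
    """

    kind: str
    times: np.ndarray
    order_k: int = 1
    spline_df: int | None = None

    def __post_init__(self):
        if self.kind not in ("fourier", "bspline"):
            raise InvalidParameterError(f"unknown design kind {self.kind!r}")
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.kind == "bspline" and self.spline_df is None:
            raise InvalidParameterError("bspline design requires spline_df")

    @property
    def n_columns(self) -> int:
        return 2 * self.order_k + 1 if self.kind == "fourier" else int(self.spline_df)

    def matrix(self, period_omega: float | None = None) -> np.ndarray:
        """Design matrix for one component (Fourier needs its period).

        Matrices are cached per (times, period) since they are rebuilt every
        EM iteration but depend only on fixed quantities.
        """
        if self.kind == "fourier" and period_omega is None:
            raise InvalidParameterError("fourier design requires a period")
        key = (self.kind, self.times.tobytes(), self.order_k, self.spline_df, period_omega)
        cached = _matrix_cache.get(key)
        if cached is None:
            if self.kind == "fourier":
                cached = fourier_design(self.times, self.order_k, period_omega)
            else:
                cached = bspline_design(self.times, self.spline_df)
            if len(_matrix_cache) > 256:
                _matrix_cache.clear()
            _matrix_cache[key] = cached
        return cached


_matrix_cache: dict = {}
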