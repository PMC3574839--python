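"""Exact algebra for the scaled AR(1) covariance matrix A(rho).

The gene-specific random effect over ``m`` consecutive time points is modelled
as a stationary first-order autoregressive process with unit innovation scale,
so its covariance (up to the variance multiplier ``theta2``) is

    A(rho)[i, j] = rho**|i - j| / (1 - rho**2),

the stationary AR(1) autocovariance.  This scaling makes the precision matrix
tridiagonal with a closed form,

    A(rho)^{-1} = (1 + rho**2) I - rho J - rho**2 K,

where J has ones on the first sub- and super-diagonals and K is 1 at the two
diagonal corners.  (Stated with the sub-diagonal only, the formula would not be
symmetric; the symmetric reading is the one consistent with the dense inverse
and is what is implemented here.)  The log-determinant collapses to
``-log(1 - rho**2)`` independently of ``m``, and the trace identity

    trace( dA(rho)^{-1}/drho . A(rho) ) = -2 rho / (1 - rho**2)

supplies the score term for the profile update of ``rho`` in the M-step.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "RHO_BOUND",
    "ar1_matrix",
    "ar1_inverse",
    "ar1_logdet",
    "ar1_score_identity",
    "trace_inverse_product",
]

#: rho is kept strictly inside (-1, 1) in every optimisation to avoid the
#: boundary singularity of 1/(1 - rho**2).
RHO_BOUND: float = 1.0 - 1e-6


def _check(rho: float, m: int | None = None) -> None:
    if not np.isfinite(rho) or abs(rho) >= 1.0:
        raise InvalidParameterError(f"autocorrelation rho must satisfy |rho| < 1, got {rho!r}")
    if m is not None and (int(m) != m or m < 2):
        raise InvalidParameterError(f"number of time points m must be an integer >= 2, got {m!r}")


def ar1_matrix(rho: float, m: int) -> np.ndarray:
    """Scaled AR(1) covariance matrix, entry (i, j) = rho^|i-j| / (1 - rho^2)."""
    _check(rho, m)
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :]) / (1.0 - rho * rho)


def ar1_inverse(rho: float, m: int) -> np.ndarray:
    """Closed-form tridiagonal inverse of :func:`ar1_matrix`."""
    _check(rho, m)
    out = np.zeros((m, m))
    np.fill_diagonal(out, 1.0 + rho * rho)
    off = np.arange(m - 1)
    out[off, off + 1] = -rho
    out[off + 1, off] = -rho
    out[0, 0] -= rho * rho
    out[m - 1, m - 1] -= rho * rho
    return out


def ar1_logdet(rho: float, m: int | None = None) -> float:
    """log det A(rho) = -log(1 - rho^2); independent of m under this scaling."""
    _check(rho)
    return -float(np.log1p(-rho * rho))


def ar1_score_identity(rho: float, m: int | None = None) -> float:
    """trace( dA(rho)^{-1}/drho . A(rho) ), closed form -2 rho / (1 - rho^2)."""
    _check(rho)
    return -2.0 * rho / (1.0 - rho * rho)


def trace_inverse_product(S: np.ndarray, rho: float) -> float:
    """trace( A(rho)^{-1} S ) for symmetric S via the tridiagonal expansion.

    Equals ``(1 + rho^2) tr S - rho * (sum of both first off-diagonals of S)
    - rho^2 * (S[0,0] + S[-1,-1])``; O(m) instead of a dense product, used in
    the profiled variance update.
    """
    _check(rho)
    d = np.diagonal(S)
    off = np.diagonal(S, 1).sum() + np.diagonal(S, -1).sum()
    return float((1.0 + rho * rho) * d.sum() - rho * off - rho * rho * (d[0] + d[-1]))
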