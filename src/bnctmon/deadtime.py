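"""Fission-chamber dead-time model.

Counting losses (or gains) in a fission-chamber channel are modelled as a
quadratic distortion of the true counting rate,

    CR_meas = A * CR_correct + B * CR_correct**2,

where ``A`` is a dimensionless linear coefficient (unity for a perfectly
linear channel) and ``B`` (per counts/s) captures the rate-dependent
distortion; ``B < 0`` corresponds to counting losses.  The model is
inverted in closed form to restore true rates from measured ones, and the
pair ``(A, B)`` can be fitted by linear least squares from a sweep of
(true, measured) rate pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError, FittingError, RangeError, SaturationError

__all__ = [
    "DeadTimeParams",
    "distort",
    "correct",
    "fit_params",
    "fit_params_with_errors",
]


@dataclass(frozen=True)
class DeadTimeParams:
    """Coefficients of the quadratic dead-time distortion model.

    Parameters
    ----------
    a_lin
        Linear coefficient (dimensionless); must be positive.
    b_quad
        Quadratic coefficient, per (counts/s); either sign is allowed as
        long as the discriminant stays non-negative on the rates the
        parameters are applied to.
    """

    a_lin: float
    b_quad: float

    def __post_init__(self) -> None:
        if not (self.a_lin > 0):
            raise DomainError(f"a_lin must be positive, got {self.a_lin!r}")

    @property
    def max_true_rate(self) -> float:
        """Largest true rate with a non-negative measured rate.

        For ``b_quad < 0`` the forward parabola crosses zero at
        ``-a_lin / b_quad``; beyond that the model is unphysical.  For
        ``b_quad >= 0`` there is no upper bound.
        """
        if self.b_quad < 0:
            return -self.a_lin / self.b_quad
        return math.inf


def distort(cr_correct: float, params: DeadTimeParams) -> float:
    """Forward model: measured counting rate for a given true rate.

    Evaluates ``A*cr + B*cr**2`` (counts/s).  Raises :class:`RangeError`
    when the true rate lies beyond the physical branch (negative measured
    rate, only possible for ``B < 0``).
    """
    if cr_correct < 0:
        raise DomainError(f"true counting rate must be >= 0, got {cr_correct!r}")
    meas = params.a_lin * cr_correct + params.b_quad * cr_correct * cr_correct
    if meas < 0:
        raise RangeError(
            "true rate {:g} counts/s exceeds the physical range of the "
            "dead-time model (maximum admissible rate {:g} counts/s)".format(
                cr_correct, params.max_true_rate
            )
        )
    return meas


def correct(cr_meas: float, params: DeadTimeParams) -> float:
    """Invert the distortion: true counting rate for a measured rate.

    The physical root of the quadratic is ``(-A + sqrt(A^2 + 4*B*y)) / (2B)``;
    it is evaluated here in the equivalent conjugate form
    ``2*y / (A + sqrt(A^2 + 4*B*y))``, which is numerically stable for
    ``|B| -> 0`` and reduces to the analytic limit ``y / A`` at ``B = 0``
    without a separate branch.
    """
    if cr_meas < 0:
        raise DomainError(f"measured counting rate must be >= 0, got {cr_meas!r}")
    disc = params.a_lin * params.a_lin + 4.0 * params.b_quad * cr_meas
    if disc < 0:
        raise SaturationError(
            "measured rate {:g} counts/s exceeds the invertible range of the "
            "dead-time model (discriminant {:g} < 0)".format(cr_meas, disc)
        )
    return 2.0 * cr_meas / (params.a_lin + math.sqrt(disc))


def _design(cr_true: np.ndarray) -> np.ndarray:
    return np.column_stack([cr_true, cr_true * cr_true])


def fit_params(pairs: Sequence[tuple[float, float]]) -> DeadTimeParams:
    """Least-squares estimate of (A, B) from (true, measured) rate pairs.

    The model is linear in its coefficients, so the fit is an exact linear
    least-squares solve on the design ``[cr, cr**2]``.  On noiseless data
    generated by :func:`distort` the generating parameters are recovered to
    machine precision.
    """
    params, _ = fit_params_with_errors(pairs)
    return params


def fit_params_with_errors(
    pairs: Sequence[tuple[float, float]],
) -> tuple[DeadTimeParams, np.ndarray]:
    """As :func:`fit_params`, also returning the coefficient standard errors.

    Standard errors come from the usual residual-based covariance
    ``s^2 (X^T X)^{-1}``; with fewer than three points they are reported
    as zero (no residual degrees of freedom).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise FittingError("need at least two (true, measured) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.unique(x).size < 2:
        raise FittingError("degenerate design: all true rates are identical")
    design = _design(x)
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 2:
        raise FittingError("degenerate design: cannot separate A from B")
    a_lin, b_quad = float(coef[0]), float(coef[1])
    dof = x.size - 2
    if dof > 0:
        resid = y - design @ coef
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(design.T @ design)
        stderr = np.sqrt(np.diag(cov))
    else:
        stderr = np.zeros(2)
    return DeadTimeParams(a_lin=a_lin, b_quad=b_quad), stderr
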