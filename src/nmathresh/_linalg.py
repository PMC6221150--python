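"""Symmetric positive-definite solves with conditioning diagnostics."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg

#: Condition numbers above this trigger a warning on every SPD inversion.
COND_WARN = 1e10


class SingularSystemError(np.linalg.LinAlgError):
    """Raised when a precision system is singular; carries the null direction."""

    def __init__(self, message: str, null_direction: np.ndarray | None = None):
        super().__init__(message)
        self.null_direction = null_direction


def spd_inv(a: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Invert a symmetric positive-definite matrix via Cholesky.

    Raises :class:`SingularSystemError` naming the (approximate) null-space
    direction when the matrix is numerically singular.
    """
    a = np.asarray(a, dtype=float)
    a = 0.5 * (a + a.T)
    try:
        c, low = linalg.cho_factor(a, lower=True)
    except linalg.LinAlgError:
        w, v = np.linalg.eigh(a)
        null = v[:, int(np.argmin(np.abs(w)))]
        raise SingularSystemError(
            f"{name} is singular or not positive definite; "
            f"null-space direction approx {np.round(null, 4)}",
            null_direction=null,
        ) from None
    _check_condition(a, name)
    return linalg.cho_solve((c, low), np.eye(a.shape[0]))


def spd_solve(a: np.ndarray, b: np.ndarray, name: str = "matrix") -> np.ndarray:
    a = np.asarray(a, dtype=float)
    a = 0.5 * (a + a.T)
    try:
        c, low = linalg.cho_factor(a, lower=True)
    except linalg.LinAlgError:
        w, v = np.linalg.eigh(a)
        null = v[:, int(np.argmin(np.abs(w)))]
        raise SingularSystemError(
            f"{name} is singular or not positive definite; "
            f"null-space direction approx {np.round(null, 4)}",
            null_direction=null,
        ) from None
    _check_condition(a, name)
    return linalg.cho_solve((c, low), b)


def _check_condition(a: np.ndarray, name: str) -> None:
    if a.shape[0] == 0:
        return
    cond = np.linalg.cond(a)
    if cond > COND_WARN:
        warnings.warn(
            f"{name} is ill conditioned (cond ~ {cond:.2e}); "
            "results may be inaccurate",
            RuntimeWarning,
            stacklevel=3,
        )


def is_symmetric_pd(a: np.ndarray, tol: float = 1e-10) -> bool:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        return False
    if not np.allclose(a, a.T, atol=tol * max(1.0, np.abs(a).max())):
        return False
    try:
        linalg.cho_factor(0.5 * (a + a.T))
    except linalg.LinAlgError:
        return False
    return True
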