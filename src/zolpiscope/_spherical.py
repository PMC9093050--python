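"""Spherical-spline kernels on the unit sphere (Perrin-style).

Shared by bad-channel interpolation and the current-source-density surface
Laplacian. The spline order ``m``, Legendre truncation, and regularization
defaults follow the standard CSD-toolbox conventions: m=4, 50 Legendre
terms, lambda=1e-5.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre

DEFAULT_M = 4
DEFAULT_NTERMS = 50
DEFAULT_LAMBDA = 1e-5


def _legendre_series(cosang: np.ndarray, m: int, n_terms: int) -> np.ndarray:
    n = np.arange(1, n_terms + 1, dtype=float)
    coef = np.zeros(n_terms + 1)
    coef[1:] = (2.0 * n + 1.0) / (n * (n + 1.0)) ** m
    return legendre.legval(np.clip(cosang, -1.0, 1.0), coef) / (4.0 * np.pi)


def g_matrix(pos_a: np.ndarray, pos_b: np.ndarray, m: int = DEFAULT_M,
             n_terms: int = DEFAULT_NTERMS) -> np.ndarray:
    """Potential kernel g(cos angle) between two sets of unit vectors."""
    return _legendre_series(pos_a @ pos_b.T, m, n_terms)


def h_matrix(pos_a: np.ndarray, pos_b: np.ndarray, m: int = DEFAULT_M,
             n_terms: int = DEFAULT_NTERMS) -> np.ndarray:
    """Laplacian (CSD) kernel: one power of n(n+1) removed from g."""
    return _legendre_series(pos_a @ pos_b.T, m - 1, n_terms)


def _solve_spline(pos_from: np.ndarray, values: np.ndarray, m: int,
                  n_terms: int, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Fit spline coefficients c and constant c0 for each column of values.

    values has shape (n_from, n_samples); returns (c, c0) with c of shape
    (n_from, n_samples). The constraint sum(c) = 0 makes the interpolant
    reproduce constant fields exactly.
    """
    n = pos_from.shape[0]
    G = g_matrix(pos_from, pos_from, m, n_terms)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G + lam * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    rhs = np.vstack([values, np.zeros((1, values.shape[1]))])
    sol = np.linalg.solve(A, rhs)
    return sol[:n], sol[n]


def interpolation_matrix(pos_good: np.ndarray, pos_bad: np.ndarray,
                         m: int = DEFAULT_M, n_terms: int = DEFAULT_NTERMS,
                         lam: float = DEFAULT_LAMBDA) -> np.ndarray:
    """Matrix W with v_bad = W @ v_good under the spherical spline."""
    n = pos_good.shape[0]
    # Solve against the identity to get the linear operator directly.
    c, c0 = _solve_spline(pos_good, np.eye(n), m, n_terms, lam)
    return g_matrix(pos_bad, pos_good, m, n_terms) @ c + c0[None, :]


def csd_matrix(pos: np.ndarray, m: int = DEFAULT_M,
               n_terms: int = DEFAULT_NTERMS,
               lam: float = DEFAULT_LAMBDA) -> np.ndarray:
    """Matrix L with csd = L @ v (surface Laplacian at the electrodes).

    Constant fields map to ~0 because the spline constant term carries them
    and the h-kernel sees only the zero-sum coefficients.
    """
    n = pos.shape[0]
    c, _ = _solve_spline(pos, np.eye(n), m, n_terms, lam)
    return h_matrix(pos, pos, m, n_terms) @ c
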