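"""Exploratory model support: oblique geomin rotation by gradient projection.

The exploratory GRM is estimated with orthogonal factors and echelon
identification (see :func:`irtcal.estimation.model2_spec`); the resulting
standardized loading matrix is then rotated obliquely to minimise the geomin
criterion

    Q(L) = sum_i ( prod_k (L_ik^2 + eps) )^(1/m),

a regularised geometric mean of squared loadings per item that rewards
row-wise simple structure.  Minimisation uses the gradient projection
algorithm for oblique rotation (iterating over rotation matrices T with
unit-length columns, Lambda = A (T')^{-1}, Phi = T'T).  Geomin is multimodal,
so several seeded random starts are run and the best criterion value kept.

Rotation is a change of basis: the model-implied common covariance
Lambda Phi Lambda' and the communalities are invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_model import FitResult, ResponseMatrix, StandardizedLoadings
from .estimation import fit, model2_spec

logger = logging.getLogger("irtcal.rotation")

GEOMIN_EPSILON = 0.01
N_RANDOM_STARTS = 30


@dataclass
class RotationResult:
    """Obliquely rotated loadings with the factor correlation matrix."""

    loadings: StandardizedLoadings
    factor_correlations: np.ndarray
    criterion: float
    converged: bool
    rotation_matrix: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Geomin criterion
# ---------------------------------------------------------------------------

def geomin_criterion(L: np.ndarray, epsilon: float = GEOMIN_EPSILON) -> float:
    L2 = np.asarray(L) ** 2 + epsilon
    return float(np.sum(np.exp(np.mean(np.log(L2), axis=1))))

def _geomin_gradient(L: np.ndarray, epsilon: float) -> np.ndarray:
    L2 = L**2 + epsilon
    row = np.exp(np.mean(np.log(L2), axis=1))
    return (2.0 / L.shape[1]) * L / L2 * row[:, None]


# ---------------------------------------------------------------------------
# Gradient projection for oblique rotation
# ---------------------------------------------------------------------------

def _gpf_oblique(A: np.ndarray, T0: np.ndarray, epsilon: float,
                 max_iter: int = 1000, tol: float = 1e-7):
    """Oblique gradient-projection minimisation of the geomin criterion.

    Returns (L, T, f, converged); the criterion value is non-increasing
    across accepted iterations by construction of the line search.
    """
    T = T0.copy()
    L = A @ np.linalg.inv(T).T
    f = geomin_criterion(L, epsilon)
    G = -(L.T @ _geomin_gradient(L, epsilon) @ np.linalg.inv(T)).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0)        # project onto the constraint
        s = np.sqrt((Gp**2).sum())
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(30):
            X = T - al * Gp
            X = X / np.sqrt((X**2).sum(axis=0))
            Lt = A @ np.linalg.inv(X).T
            ft = geomin_criterion(Lt, epsilon)
            if f - ft > 0.5 * s**2 * al:
                break
            al /= 2.0
        else:                                    # no improving step found
            break
        T, L, f = X, Lt, ft
        G = -(L.T @ _geomin_gradient(L, epsilon) @ np.linalg.inv(T)).T
    return L, T, f, converged


def _canonical_order(L: np.ndarray, Phi: np.ndarray):
    """Sort factors by descending sum of squared loadings; make dominant
    loadings positive.  Purely presentational; the solution is otherwise
    defined up to column permutation and sign."""
    order = np.argsort(-np.sum(L**2, axis=0), kind="stable")
    L = L[:, order]
    Phi = Phi[np.ix_(order, order)]
    signs = np.where(L.sum(axis=0) < 0, -1.0, 1.0)
    L = L * signs
    Phi = Phi * np.outer(signs, signs)
    return L, Phi


def geomin_rotate(loadings: StandardizedLoadings | np.ndarray,
                  epsilon: float = GEOMIN_EPSILON,
                  n_starts: int = N_RANDOM_STARTS,
                  seed: int = 0) -> RotationResult:
    """Obliquely rotate an exploratory loading matrix by the geomin criterion.

    Runs the gradient-projection algorithm from the identity plus
    ``n_starts`` seeded random starts and keeps the lowest criterion value.
    Communalities and the model-implied common covariance are preserved.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if isinstance(loadings, StandardizedLoadings):
        A = loadings.loadings
        item_ids, factor_names = list(loadings.item_ids), list(loadings.factor_names)
    else:
        A = np.asarray(loadings, dtype=float)
        item_ids = [f"item{j + 1}" for j in range(A.shape[0])]
        factor_names = [f"f{k + 1}" for k in range(A.shape[1])]
    m = A.shape[1]
    rng = np.random.default_rng(seed)
    starts = [np.eye(m)]
    for _ in range(n_starts):
        X = rng.standard_normal((m, m))
        starts.append(X / np.sqrt((X**2).sum(axis=0)))
    best = None
    any_converged = False
    for T0 in starts:
        L, T, f, conv = _gpf_oblique(A, T0, epsilon)
        any_converged = any_converged or conv
        if best is None or f < best[2] - 1e-12:
            best = (L, T, f, conv)
    L, T, f, conv = best
    if not any_converged:
        logger.warning("geomin rotation: no start satisfied the gradient tolerance")
    Phi = T.T @ T
    L, Phi = _canonical_order(L, Phi)
    rotated = StandardizedLoadings(L, item_ids, factor_names)
    return RotationResult(rotated, Phi, f, any_converged, rotation_matrix=T)


# ---------------------------------------------------------------------------
# Exploratory fit
# ---------------------------------------------------------------------------

def fit_exploratory(data: ResponseMatrix, n_factors: int, **controls) -> FitResult:
    """Fit the exploratory GRM (full slope matrix, echelon identification,
    orthogonal factors).  Rotate the resulting ``loadings`` with
    :func:`geomin_rotate` to obtain the oblique solution."""
    if n_factors < 2:
        raise ValueError("exploratory estimation needs at least 2 factors")
    spec = model2_spec(data.codebook, n_factors=n_factors, **controls)
    return fit(data, spec)
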