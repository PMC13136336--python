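"""Regularized inverse solvers for epicardial potentials and volumetric sources.

Both problems are zero-order Tikhonov fits solved through one SVD reused
across all time samples, with the regularization weight chosen by the
L-curve criterion (maximum curvature of the log residual-norm vs log
solution-norm curve).  The volumetric problem additionally enforces the
source existence condition -- the volume-weighted sum of sources must
vanish at every instant -- as an exact equality constraint, imposed by
rotating the unknowns onto the null space of the weight row with a
Householder reflection and solving the unconstrained problem there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mesh import VolumeWeights

__all__ = [
    "RegularizationTrace",
    "EpicardialPotentials",
    "VolumetricSources",
    "solve_epicardial",
    "solve_volumetric",
    "lcurve_select",
    "default_lambda_grid",
]


@dataclass
class RegularizationTrace:
    """L-curve bookkeeping: residual and solution norms over the lambda grid."""

    lambdas: np.ndarray
    residual_norms: np.ndarray
    solution_norms: np.ndarray
    curvature: np.ndarray
    selected: float

    def check_monotone(self, rtol: float = 1e-9):
        r, s = self.residual_norms, self.solution_norms
        if np.any(np.diff(r) < -rtol * (r.max() + 1e-300)):
            raise RuntimeError("residual norms not non-decreasing in lambda")
        if np.any(np.diff(s) > rtol * (s.max() + 1e-300)):
            raise RuntimeError("solution norms not non-increasing in lambda")
        return self


@dataclass
class EpicardialPotentials:
    """Reconstructed heart-surface potentials, nodes x samples."""

    values: np.ndarray
    trace: RegularizationTrace


@dataclass
class VolumetricSources:
    """Reconstructed source density per heart node x sample.

    ``constraint_residual`` reports |w . f_t| per sample (machine-level by
    construction of the null-space solver).
    """

    values: np.ndarray
    trace: RegularizationTrace
    constraint_residual: np.ndarray


def default_lambda_grid(s1: float, n: int = 60) -> np.ndarray:
    """Log-spaced grid spanning [1e-8, 1e2] x (largest singular value)^2."""
    return np.logspace(-8, 2, n) * s1**2


def _tikhonov_path(U, s, g, lambdas):
    """Residual/solution norms and coefficients over the lambda grid.

    Uses the SVD filter factors; g may have many columns (time samples).
    Returns (rho, eta) aggregated over all samples (Frobenius norms) plus
    the projected data Utg for later solution assembly.
    """
    Utg = U.T @ g
    resid_perp = float(np.sum(g**2) - np.sum(Utg**2))
    resid_perp = max(resid_perp, 0.0)
    rho = np.empty(len(lambdas))
    eta = np.empty(len(lambdas))
    for i, lam in enumerate(lambdas):
        coef = (s / (s**2 + lam))[:, None] * Utg  # (r, T)
        eta[i] = np.sqrt(np.sum(coef**2))
        r = (lam / (s[:, None]**2 + lam)) * Utg
        rho[i] = np.sqrt(np.sum(r**2) + resid_perp)
    return rho, eta


def lcurve_select(trace: RegularizationTrace) -> float:
    """Corner of the L-curve by maximum finite-difference curvature.

    Curvature is computed on the (log rho, log eta) parametric curve with
    central differences over the log-lambda grid.  Degenerate (flat) curves
    fall back to the smallest lambda with a warning.
    """
    if len(trace.lambdas) < 3:
        raise ValueError("need at least 3 lambda samples for the L-curve")
    trace.check_monotone()
    with np.errstate(divide="ignore"):
        x = np.log(np.maximum(trace.residual_norms, 1e-300))
        y = np.log(np.maximum(trace.solution_norms, 1e-300))
    t = np.log(trace.lambdas)
    dx, dy = np.gradient(x, t), np.gradient(y, t)
    ddx, ddy = np.gradient(dx, t), np.gradient(dy, t)
    denom = (dx**2 + dy**2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (dx * ddy - dy * ddx) / denom
    kappa[~np.isfinite(kappa)] = -np.inf
    if not np.any(kappa > 0):
        warnings.warn(
            "degenerate (flat) L-curve: falling back to the smallest lambda",
            RuntimeWarning,
        )
        idx = 0
    else:
        idx = int(np.argmax(kappa))
    trace.curvature = kappa
    trace.selected = float(trace.lambdas[idx])
    return trace.selected


def _solve_tikhonov(Amat, g, lam, n_grid=60):
    """Shared SVD machinery; returns (solution_in_column_space, trace).

    Both the operator and the data are re-referenced to zero mean over the
    electrode axis before fitting: measured potentials only carry
    inter-electrode differences, so the common-mode component of the
    operator must not compete for data fit.
    """
    if Amat.size == 0 or not np.all(np.isfinite(Amat)):
        raise ValueError("transfer matrix empty or non-finite")
    Amat = Amat - Amat.mean(axis=0, keepdims=True)
    g = np.atleast_2d(g)
    g = g - g.mean(axis=0, keepdims=True)
    if g.shape[1] == 0:
        raise ValueError("empty signal matrix")
    U, s, Vt = np.linalg.svd(Amat, full_matrices=False)
    if s[0] == 0:
        raise ValueError("rank-0 transfer matrix")
    lambdas = default_lambda_grid(s[0], n_grid)
    rho, eta = _tikhonov_path(U, s, g, lambdas)
    trace = RegularizationTrace(lambdas, rho, eta, np.zeros_like(lambdas), np.nan)
    if lam == "auto" or lam is None:
        lam_val = lcurve_select(trace)
    else:
        lam_val = float(lam)
        trace.selected = lam_val
        trace.check_monotone()
    filt = s / (s**2 + lam_val)
    x = Vt.T @ (filt[:, None] * (U.T @ g))
    return x, trace


def solve_epicardial(A, g, lam="auto") -> EpicardialPotentials:
    """Zero-order Tikhonov reconstruction of epicardial potentials.

    One lambda is shared across all samples (single spatial operator); the
    minimizer is assembled from the SVD of A reused per sample.
    """
    Amat = A.matrix if hasattr(A, "matrix") else np.asarray(A)
    h, trace = _solve_tikhonov(Amat, g, lam)
    return EpicardialPotentials(h, trace)


def solve_volumetric(B, g, weights: VolumeWeights, lam="auto") -> VolumetricSources:
    """Equality-constrained Tikhonov reconstruction of volumetric sources.

    minimize ||B diag(w) f - g||^2 + lambda ||f||^2   s.t.  w . f = 0

    The constraint is exact: unknowns are rotated with the orthonormal
    Householder basis of null(w^T), the reduced problem is an ordinary
    Tikhonov fit, and the solution is rotated back.  Because the feasible
    set annihilates w, the result is invariant to adding arbitrary
    constants to the rows of B (the Neumann gauge cannot leak through).
    """
    Bmat = B.matrix if hasattr(B, "matrix") else np.asarray(B)
    g = np.atleast_2d(g)
    wh = weights.heart_weights if isinstance(weights, VolumeWeights) \
        else np.asarray(weights, dtype=float)
    if np.any(wh <= 0):
        raise ValueError("volume weights must be strictly positive")
    if Bmat.shape[1] != len(wh):
        raise ValueError("B column count does not match weight length")

    Bt = Bmat * wh[None, :]
    # Householder reflection H mapping w -> ||w|| e1; columns 2..P of H
    # form an orthonormal basis of null(w^T).
    v = wh.astype(float).copy()
    v[0] += np.linalg.norm(wh)
    vn2 = v @ v
    BH = Bt - np.outer(Bt @ v, v) * (2.0 / vn2)
    Br = BH[:, 1:]

    z, trace = _solve_tikhonov(Br, g, lam)
    y = np.vstack([np.zeros((1, z.shape[1])), z])
    f = y - np.outer(v, (v @ y)) * (2.0 / vn2)
    resid = np.abs(wh @ f)
    return VolumetricSources(f, trace, resid)
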