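"""Least-squares rigid-body superposition.

Covariance-based analyses (entropy, principal components, order parameters)
are only meaningful once overall translation and rotation have been removed.
:func:`kabsch_fit` solves the single-pair Procrustes problem;
:func:`fit_ensemble` iteratively superposes every model onto the mean of a
fit group (fit to current mean, recompute mean, repeat), which makes the
result independent of model order and of the choice of a reference model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble_io import Ensemble, Selection

__all__ = ["FitResult", "kabsch_fit", "apply_fit", "fit_ensemble"]

#: convergence threshold on the RMS change of the mean structure, Angstrom
MEAN_TOL = 1e-6
MAX_ITER = 100


@dataclass(frozen=True)
class FitResult:
    """Rotation + translation mapping mobile onto reference: x -> x @ R.T + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def kabsch_fit(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> FitResult:
    """Optimal proper rotation/translation of ``mobile`` onto ``reference``.

    Parameters
    ----------
    mobile, reference:
        ``(n, 3)`` coordinate sets, n >= 3, not all collinear.
    weights:
        Optional per-atom weights (e.g. masses) used in the least-squares
        objective; uniform when omitted.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both have shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        weights = np.asarray(weights, float)
        if weights.shape != (n,) or (weights < 0).any() or weights.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = weights / weights.sum()

    mob_c = mobile - (w[:, None] * mobile).sum(0)
    ref_c = reference - (w[:, None] * reference).sum(0)

    # Rank of the weighted reference configuration: collinear sets leave the
    # rotation about the line undetermined.
    if np.linalg.matrix_rank(ref_c * np.sqrt(w)[:, None], tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) configuration: rotation not defined")

    h = (mob_c * w[:, None]).T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    ref_mean = (w[:, None] * reference).sum(0)
    mob_mean = (w[:, None] * mobile).sum(0)
    trans = ref_mean - rot @ mob_mean
    fitted = mobile @ rot.T + trans
    rmsd = float(np.sqrt((w[:, None] * (fitted - reference) ** 2).sum()))
    return FitResult(rotation=rot, translation=trans, rmsd=rmsd)


def apply_fit(coords: np.ndarray, fit: FitResult) -> np.ndarray:
    """Apply a fit transform to an ``(..., 3)`` coordinate array."""
    return np.asarray(coords, float) @ fit.rotation.T + fit.translation


def fit_ensemble(
    e: Ensemble,
    fit_selection: Selection | None = None,
    mass_weighted: bool = False,
) -> Ensemble:
    """Superpose all models onto the iteratively refined mean of the fit group.

    The transformation found on the fit-group atoms is applied to *all*
    atoms of each model.  Iteration stops when the RMS change of the mean
    structure falls below ``1e-6`` Angstrom (or after 100 iterations, with a
    warning).  Per-model residual RMSDs are recorded on the returned
    ensemble's ``fit_residuals``.
    """
    if fit_selection is None:
        idx = np.arange(e.n_atoms)
    else:
        idx = fit_selection.indices(e.atoms)
        if idx.size == 0:
            raise ValueError("fit selection matched no atoms")
    if idx.size < 3:
        raise ValueError("fit group needs at least 3 atoms")
    weights = e.masses[idx] if mass_weighted else None

    coords = e.coords.copy()
    # Seed with the raw mean (keeps fitting idempotent: an already-fitted
    # ensemble converges in one pass without moving).  If the raw mean is
    # degenerate -- models carrying arbitrary rigid transforms can average
    # out to a near-point -- seed with the first model instead.
    mean = coords[:, idx, :].mean(axis=0)
    centered = mean - mean.mean(0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        mean = coords[0, idx, :].copy()
    residuals = np.zeros(e.n_models)
    converged = False
    for _ in range(MAX_ITER):
        for m in range(e.n_models):
            fit = kabsch_fit(coords[m, idx], mean, weights)
            coords[m] = apply_fit(coords[m], fit)
            residuals[m] = fit.rmsd
        new_mean = coords[:, idx, :].mean(axis=0)
        shift = float(np.sqrt(((new_mean - mean) ** 2).sum(1).mean()))
        mean = new_mean
        if shift < MEAN_TOL:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn("ensemble fit did not converge in 100 iterations; returning best")
    out = Ensemble(
        atoms=e.atoms, coords=coords, state_label=e.state_label,
        replica_ids=e.replica_ids, source=e.source,
    )
    out.fit_residuals = residuals
    return out
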