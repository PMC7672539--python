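"""Conformational entropy from the mass-weighted coordinate covariance.

Two estimators over the eigenvalues of M^(1/2) sigma M^(1/2) (sigma the
population covariance of the fitted coordinates, M the diagonal mass
matrix):

* Schlitter's determinant bound

      S = kB/2 * ln det[ 1 + (kB*T*e^2/hbar^2) * M^(1/2) sigma M^(1/2) ]

  evaluated as a log-sum over eigenvalues for numerical stability.  This is
  a per-mode upper bound on the quasi-harmonic value.

* The quasi-harmonic estimate, treating each eigenmode as a quantum
  harmonic oscillator with frequency omega_i = sqrt(kB*T / lambda_i):

      S = kB * sum_i [ x_i/(exp(x_i)-1) - ln(1 - exp(-x_i)) ],
      x_i = hbar*omega_i/(kB*T)

Eigenvalues below a documented floor (1e-12 amu*A^2) are skipped: they are
either numerical noise or rank deficiency of the sample covariance, and a
vanishing variance contributes no entropy in either estimator.

Values are reported per mole (J mol^-1 K^-1) by default; the covariance is
ingested in Angstrom^2 and converted to SI internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import constants

from .ensemble_io import Ensemble, Selection, select
from .superpose import fit_ensemble

__all__ = [
    "CovarianceModel",
    "EntropyResult",
    "BindingEntropyRatio",
    "covariance",
    "covariance_from_samples",
    "schlitter_entropy",
    "quasiharmonic_entropy",
    "entropy_result",
    "binding_entropy_ratio",
]

#: eigenvalue floor for mode inclusion, amu * Angstrom^2
EIGENVALUE_FLOOR = 1e-12
#: relative tolerance on negative eigenvalues before a covariance is
#: declared non-PSD
PSD_RTOL = 1e-8

_AMU_A2 = constants.atomic_mass * constants.angstrom**2  # amu*A^2 -> kg*m^2


@dataclass
class CovarianceModel:
    """Population (1/N) covariance of selected coordinates across models.

    ``matrix`` is 3N x 3N in Angstrom^2 (not mass weighted; the mass vector
    is carried separately and applied inside the entropy estimators).
    """

    matrix: np.ndarray
    masses: np.ndarray
    mean: np.ndarray
    n_models: int
    selection: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        self.masses = np.asarray(self.masses, float)
        n3 = self.matrix.shape[0]
        if self.matrix.shape != (n3, n3) or n3 != 3 * self.masses.size:
            raise ValueError("covariance must be 3N x 3N with N = len(masses)")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    def mass_weighted_eigenvalues(self) -> np.ndarray:
        """Eigenvalues of M^(1/2) sigma M^(1/2), amu*A^2, descending."""
        sqm = np.sqrt(np.repeat(self.masses, 3))
        a = sqm[:, None] * self.matrix * sqm[None, :]
        lam = np.linalg.eigvalsh(a)
        scale = max(lam.max(), 1.0)
        if lam.min() < -PSD_RTOL * scale:
            raise ValueError(
                f"covariance is not positive semidefinite "
                f"(min eigenvalue {lam.min():.3e} amu*A^2)"
            )
        return np.clip(lam, 0.0, None)[::-1]


@dataclass(frozen=True)
class EntropyResult:
    """Both entropy estimates for one covariance model."""

    s_quasiharmonic: float
    s_schlitter: float
    temperature: float
    n_models: int
    selection: str = ""


@dataclass
class BindingEntropyRatio:
    """Entropies of the four states and their binding-entropy ratio.

    States: ff = free full-length, fd = free truncated, cf = complex
    full-length, cd = complex truncated.  The ratio
    (S_cd - S_fd) / (S_cf - S_ff) compares the entropy change upon ligand
    binding in the truncated against the full-length domain; ``convergence``
    traces it over growing model-count prefixes.
    """

    s_ff: float
    s_fd: float
    s_cf: float
    s_cd: float
    ratio: float
    temperature: float
    estimator: str
    convergence: list[tuple[int, float]] = field(default_factory=list)


def covariance_from_samples(
    coords: np.ndarray,
    masses: np.ndarray,
    selection: str = "",
) -> CovarianceModel:
    """Population covariance of raw ``(n_models, n_atoms, 3)`` coordinates.

    No fitting is performed; use :func:`covariance` for the full
    fit-then-analyse convention.
    """
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("covariance undefined for a single model")
    flat = coords.reshape(n, -1)
    mean = flat.mean(0)
    dev = flat - mean
    mat = dev.T @ dev / n
    return CovarianceModel(
        matrix=mat, masses=np.asarray(masses, float),
        mean=mean.reshape(-1, 3), n_models=n, selection=selection,
    )


def covariance(
    e: Ensemble,
    fit_selection: Selection | None = None,
    analysis_selection: Selection | None = None,
    mass_weighted: bool = True,
    fitted: bool = False,
) -> CovarianceModel:
    """Fit an ensemble and return the covariance of the analysis selection.

    ``mass_weighted`` controls the weighting of the superposition fit (the
    quasi-harmonic/Schlitter convention); the stored covariance itself is
    plain coordinate covariance, with masses carried alongside.
    """
    if e.n_models < 2:
        raise ValueError("covariance undefined for a single model")
    work = e if fitted else fit_ensemble(e, fit_selection, mass_weighted=mass_weighted)
    sub = select(work, analysis_selection) if analysis_selection is not None else work
    desc = analysis_selection.describe() if analysis_selection is not None else "all atoms"
    return covariance_from_samples(sub.coords, sub.masses, selection=desc)


def _schlitter_alpha(temperature: float) -> float:
    """Dimensionless prefactor per (amu*A^2) of mass-weighted variance."""
    return constants.k * temperature * np.e**2 / constants.hbar**2 * _AMU_A2


def schlitter_entropy(
    c: CovarianceModel, temperature: float = 300.0, per_mole: bool = True
) -> float:
    """Schlitter entropy, J mol^-1 K^-1 (or J/K with ``per_mole=False``)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    lam = c.mass_weighted_eigenvalues()
    lam = lam[lam > EIGENVALUE_FLOOR]
    s = 0.5 * constants.k * float(np.log1p(_schlitter_alpha(temperature) * lam).sum())
    return s * constants.N_A if per_mole else s


def quasiharmonic_entropy(
    c: CovarianceModel, temperature: float = 300.0, per_mole: bool = True
) -> float:
    """Quasi-harmonic entropy, J mol^-1 K^-1 (or J/K with ``per_mole=False``)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    lam = c.mass_weighted_eigenvalues()
    lam = lam[lam > EIGENVALUE_FLOOR]
    if lam.size == 0:
        return 0.0
    # x = hbar * omega / kB T with omega = sqrt(kB T / lambda_SI)
    x = constants.hbar / np.sqrt(constants.k * temperature * lam * _AMU_A2)
    with np.errstate(over="ignore"):
        per_mode = x / np.expm1(x) - np.log(-np.expm1(-x))
    per_mode = np.where(np.isfinite(per_mode), per_mode, 0.0)  # x >> 1: mode frozen
    s = constants.k * float(per_mode.sum())
    return s * constants.N_A if per_mole else s


def entropy_result(
    c: CovarianceModel, temperature: float = 300.0, per_mole: bool = True
) -> EntropyResult:
    return EntropyResult(
        s_quasiharmonic=quasiharmonic_entropy(c, temperature, per_mole),
        s_schlitter=schlitter_entropy(c, temperature, per_mole),
        temperature=temperature,
        n_models=c.n_models,
        selection=c.selection,
    )


STATE_KEYS = ("ff", "fd", "cf", "cd")


def binding_entropy_ratio(
    ensembles: Mapping[str, Ensemble],
    fit_selection: Selection | None = None,
    analysis_selection: Selection | None = None,
    temperature: float = 300.0,
    estimator: str = "schlitter",
    prefix_fractions: Sequence[float] = tuple(f / 10 for f in range(1, 11)),
    denominator_tolerance: float = 1e-6,
) -> BindingEntropyRatio:
    """Binding-entropy ratio (S_cd - S_fd)/(S_cf - S_ff) with convergence trace.

    All four states must be present and share a common atom selection (the
    caller is responsible for excluding atoms absent from any state, e.g. a
    ligand or a C-terminal extension).  The trace evaluates the ratio on
    growing model-count prefixes (default 10%, 20%, ..., 100% of each
    state's models, in stored model order).
    """
    missing = [k for k in STATE_KEYS if k not in ensembles]
    if missing:
        raise ValueError(f"missing states for entropy ratio: {missing}")
    if estimator not in ("schlitter", "quasiharmonic"):
        raise ValueError(f"unknown estimator {estimator!r}")
    est = schlitter_entropy if estimator == "schlitter" else quasiharmonic_entropy

    def state_entropy(e: Ensemble, n_use: int) -> float:
        sub = e.with_models(np.arange(n_use))
        c = covariance(sub, fit_selection, analysis_selection, mass_weighted=True)
        return est(c, temperature)

    convergence: list[tuple[int, float]] = []
    full: dict[str, float] = {}
    for frac in prefix_fractions:
        counts = {k: max(2, round(frac * ensembles[k].n_models)) for k in STATE_KEYS}
        s = {k: state_entropy(ensembles[k], counts[k]) for k in STATE_KEYS}
        denom = s["cf"] - s["ff"]
        numer = s["cd"] - s["fd"]
        if abs(denom) < denominator_tolerance:
            if frac == prefix_fractions[-1]:
                raise ValueError(
                    f"denominator degenerate: |S_cf - S_ff| = {abs(denom):.3e} "
                    f"J/mol/K below tolerance {denominator_tolerance}"
                )
            ratio = float("nan")
        else:
            ratio = numer / denom
        convergence.append((counts["ff"], ratio))
        if frac == prefix_fractions[-1]:
            full = s
    return BindingEntropyRatio(
        s_ff=full["ff"], s_fd=full["fd"], s_cf=full["cf"], s_cd=full["cd"],
        ratio=convergence[-1][1], temperature=temperature, estimator=estimator,
        convergence=convergence,
    )
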