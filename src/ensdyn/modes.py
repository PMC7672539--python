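"""Combined-ensemble principal component analysis and state partitioning.

Several labelled ensembles are pooled, superposed onto their common mean,
and the population covariance of the selected coordinates (C-alpha by
convention) is diagonalized.  Every conformer keeps its source label and
replica id, so per-ensemble and per-replica statistics along the leading
modes fall out of the projection table.

Conformers are partitioned into binary states by the sign of their
projection along mode 1 (open/closed) and mode 2 (narrow/wide) relative to
a per-mode threshold (default 0).  A projection exactly at the threshold is
assigned to the negative side.

Sign convention: eigenvector signs are arbitrary, but occupancy semantics
are not, so each mode is oriented such that the reference ensembles
(default: the complex states, labels starting with "c") have non-positive
mean projection.  By default the positive side of mode 1 is called "open"
and the positive side of mode 2 "narrow".

Co-occurrence of the two binary states within one ensemble is summarised by
a symmetric two-way matching coefficient,

    co = max( P(open & narrow) + P(closed & wide),
              P(open & wide)  + P(closed & narrow) )

i.e. the probability mass on the better of the two diagonals of the joint
2x2 table; the full table is always reported alongside so any alternative
convention can be applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble_io import Ensemble, Selection, select
from .superpose import fit_ensemble, kabsch_fit, apply_fit

__all__ = [
    "ModeSpace",
    "StatePartition",
    "OverlapReport",
    "combined_pca",
    "variance_coverage",
    "partition_states",
    "project_external",
    "mode_overlap",
]

#: modes with eigenvalue below this (Angstrom^2) are dropped
EIGENVALUE_CUTOFF = 1e-9


@dataclass
class ModeSpace:
    """Eigenvectors/eigenvalues of a pooled-ensemble covariance plus projections.

    ``eigenvectors`` has one orthonormal column per retained mode, in
    descending eigenvalue order; ``projections`` has one row per conformer
    with columns ``ensemble``, ``replica``, ``model``, ``pc1`` ... ``pck``
    (Angstrom).
    """

    mean: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    total_variance: float
    projections: pd.DataFrame
    atom_layout: list[tuple[str, int, str]] = field(default_factory=list)
    selection: str = ""

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def variance_fractions(self) -> np.ndarray:
        return self.eigenvalues / self.total_variance

    def projection_matrix(self) -> np.ndarray:
        cols = [f"pc{i + 1}" for i in range(self.n_modes)]
        return self.projections[cols].to_numpy()


@dataclass
class StatePartition:
    """Binary open/closed and narrow/wide labels with per-ensemble statistics."""

    thresholds: tuple[float, float]
    labels: pd.DataFrame  # per conformer: ensemble, replica, model, mode1_state, mode2_state
    occupancy: pd.DataFrame  # per ensemble: open, closed, narrow, wide fractions
    joint: pd.DataFrame  # per ensemble: P(open&narrow), P(open&wide), P(closed&narrow), P(closed&wide)
    co_occurrence: dict[str, float]
    replica_occupancy: pd.DataFrame | None = None
    mode1_states: tuple[str, str] = ("open", "closed")
    mode2_states: tuple[str, str] = ("narrow", "wide")


@dataclass(frozen=True)
class OverlapReport:
    """Absolute inner products between two mode sets and their RMSIP."""

    overlap: np.ndarray  # O_ij = |u_i . v_j|, i,j <= k
    cumulative: np.ndarray  # per row i: sqrt(sum_j (u_i . v_j)^2)
    rmsip: float
    k: int


def _layout(atoms) -> list[tuple[str, int, str]]:
    return [(a.chain, a.residue_number, a.name) for a in atoms]


def combined_pca(
    ensembles: Sequence[Ensemble],
    selection: Selection | None = None,
    min_eigenvalue: float = EIGENVALUE_CUTOFF,
    max_modes: int | None = None,
    reference_labels: Sequence[str] | None = None,
) -> ModeSpace:
    """Pool ensembles, fit to the common mean, and diagonalize the covariance.

    All ensembles must share the selected atom layout (chain, residue
    number, atom name).  ``reference_labels`` name the ensembles used to
    orient eigenvector signs (default: state labels starting with "c", i.e.
    the complex states; if none match, the pooled mean projection is used).
    """
    if not ensembles:
        raise ValueError("no ensembles given")
    subs = [select(e, selection) if selection is not None else e for e in ensembles]
    ref_layout = _layout(subs[0].atoms)
    for e in subs[1:]:
        lay = _layout(e.atoms)
        if lay != ref_layout:
            for i, (a, b) in enumerate(zip(lay, ref_layout)):
                if a != b:
                    raise ValueError(
                        f"ensemble {e.state_label!r} atom layout mismatch at "
                        f"position {i}: {a} vs {b}"
                    )
            raise ValueError(
                f"ensemble {e.state_label!r} has {len(lay)} selected atoms, "
                f"expected {len(ref_layout)}"
            )
    total_models = sum(e.n_models for e in subs)
    if total_models < 2:
        raise ValueError("need at least 2 models in total")

    pooled_coords = np.concatenate([e.coords for e in subs], axis=0)
    labels = np.concatenate([[e.state_label or f"ens{i}"] * e.n_models
                             for i, e in enumerate(subs)])
    replicas = np.concatenate([
        e.replica_ids if e.replica_ids is not None else np.full(e.n_models, -1, dtype=int)
        for e in subs
    ])
    model_idx = np.concatenate([np.arange(e.n_models) for e in subs])

    pooled = Ensemble(atoms=subs[0].atoms, coords=pooled_coords, state_label="pooled")
    fitted = fit_ensemble(pooled, fit_selection=None, mass_weighted=False)

    flat = fitted.coords.reshape(total_models, -1)
    mean = flat.mean(0)
    dev = flat - mean
    cov = dev.T @ dev / total_models
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    keep = lam > min_eigenvalue
    lam, vec = lam[keep], vec[:, keep]
    if max_modes is not None:
        lam, vec = lam[:max_modes], vec[:, :max_modes]

    proj = dev @ vec

    if reference_labels is None:
        reference_labels = sorted({l for l in labels if str(l).startswith("c")})
    ref_mask = np.isin(labels, list(reference_labels))
    if not ref_mask.any():
        ref_mask = np.ones(total_models, bool)
    flip = proj[ref_mask].mean(0) > 0
    vec[:, flip] *= -1.0
    proj[:, flip] *= -1.0

    table = pd.DataFrame({"ensemble": labels, "replica": replicas, "model": model_idx,
                          **{f"pc{i + 1}": proj[:, i] for i in range(lam.size)}})

    return ModeSpace(
        mean=mean.reshape(-1, 3),
        eigenvectors=vec,
        eigenvalues=lam,
        total_variance=float(np.trace(cov)),
        projections=table,
        atom_layout=ref_layout,
        selection=selection.describe() if selection is not None else "all atoms",
    )


def variance_coverage(m: ModeSpace, k: int) -> dict[str, float]:
    """Mode 1's share of the first-k-mode variance, and the first-k share of the total."""
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, m.n_modes)  # fewer retained modes than requested: use them all
    top = m.eigenvalues[:k].sum()
    return {
        "pc1_share_of_first_k": float(m.eigenvalues[0] / top),
        "first_k_share_of_total": float(top / m.total_variance),
    }


def partition_states(
    m: ModeSpace,
    thresholds: tuple[float, float] = (0.0, 0.0),
    mode1_states: tuple[str, str] = ("open", "closed"),
    mode2_states: tuple[str, str] = ("narrow", "wide"),
) -> StatePartition:
    """Label every conformer by the sign of its first two mode projections.

    ``mode1_states``/``mode2_states`` name the (positive side, negative
    side) of each mode.  Projections exactly at the threshold go to the
    negative side.  Per-replica occupancies are tabulated whenever replica
    ids are present.
    """
    if m.n_modes < 2:
        raise ValueError("state partition needs at least 2 retained modes")
    pos1, neg1 = mode1_states
    pos2, neg2 = mode2_states
    p1 = m.projections["pc1"].to_numpy()
    p2 = m.projections["pc2"].to_numpy()
    s1 = np.where(p1 > thresholds[0], pos1, neg1)
    s2 = np.where(p2 > thresholds[1], pos2, neg2)
    labels = m.projections[["ensemble", "replica", "model"]].copy()
    labels["mode1_state"] = s1
    labels["mode2_state"] = s2

    occ_rows, joint_rows, co = [], [], {}
    for ens, grp in labels.groupby("ensemble", sort=False):
        n = len(grp)
        p_pos1 = float((grp["mode1_state"] == pos1).mean())
        p_pos2 = float((grp["mode2_state"] == pos2).mean())
        occ_rows.append({"ensemble": ens, pos1: p_pos1, neg1: 1 - p_pos1,
                         pos2: p_pos2, neg2: 1 - p_pos2, "n": n})
        jj = {
            f"{pos1}_{pos2}": float(((grp["mode1_state"] == pos1) & (grp["mode2_state"] == pos2)).mean()),
            f"{pos1}_{neg2}": float(((grp["mode1_state"] == pos1) & (grp["mode2_state"] == neg2)).mean()),
            f"{neg1}_{pos2}": float(((grp["mode1_state"] == neg1) & (grp["mode2_state"] == pos2)).mean()),
            f"{neg1}_{neg2}": float(((grp["mode1_state"] == neg1) & (grp["mode2_state"] == neg2)).mean()),
        }
        joint_rows.append({"ensemble": ens, **jj})
        co[ens] = max(jj[f"{pos1}_{pos2}"] + jj[f"{neg1}_{neg2}"],
                      jj[f"{pos1}_{neg2}"] + jj[f"{neg1}_{pos2}"])

    replica_occ = None
    if (labels["replica"] >= 0).any():
        rows = []
        for (ens, rep), grp in labels.groupby(["ensemble", "replica"], sort=False):
            rows.append({
                "ensemble": ens, "replica": rep, "n": len(grp),
                pos1: float((grp["mode1_state"] == pos1).mean()),
                pos2: float((grp["mode2_state"] == pos2).mean()),
            })
        replica_occ = pd.DataFrame(rows)

    return StatePartition(
        thresholds=thresholds,
        labels=labels,
        occupancy=pd.DataFrame(occ_rows),
        joint=pd.DataFrame(joint_rows),
        co_occurrence=co,
        replica_occupancy=replica_occ,
        mode1_states=mode1_states,
        mode2_states=mode2_states,
    )


def project_external(m: ModeSpace, structures: Ensemble) -> np.ndarray:
    """Project external conformers onto an existing mode space.

    Each model is superposed onto the mode-space mean before projection.
    Returns an ``(n_models, n_modes)`` array of projections in Angstrom.
    """
    if structures.n_atoms != m.mean.shape[0]:
        raise ValueError(
            f"external structures have {structures.n_atoms} atoms but the mode "
            f"space expects {m.mean.shape[0]}; map both through the same core "
            f"mapping (ensdyn.core_mapping) first"
        )
    out = np.empty((structures.n_models, m.n_modes))
    for i in range(structures.n_models):
        fit = kabsch_fit(structures.coords[i], m.mean)
        dev = (apply_fit(structures.coords[i], fit) - m.mean).ravel()
        out[i] = dev @ m.eigenvectors
    return out


def mode_overlap(a: ModeSpace, b: ModeSpace, k: int) -> OverlapReport:
    """Subspace overlap between the first k modes of two mode spaces.

    O_ij = |u_i . v_j| and RMSIP(k) = sqrt( (1/k) sum_{i,j<=k} (u_i.v_j)^2 ).
    """
    if a.eigenvectors.shape[0] != b.eigenvectors.shape[0]:
        raise ValueError(
            f"coordinate dimensionality differs: {a.eigenvectors.shape[0]} "
            f"vs {b.eigenvectors.shape[0]}"
        )
    if k < 1 or k > min(a.n_modes, b.n_modes):
        raise ValueError(f"k must be in [1, {min(a.n_modes, b.n_modes)}]")
    dots = a.eigenvectors[:, :k].T @ b.eigenvectors[:, :k]
    return OverlapReport(
        overlap=np.abs(dots),
        cumulative=np.sqrt((dots**2).sum(axis=1)),
        rmsip=float(np.sqrt((dots**2).sum() / k)),
        k=k,
    )
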