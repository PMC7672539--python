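"""Back-calculation of S2 order parameters from a coordinate ensemble.

The generalized order parameter of a bond vector reports on its
orientational restriction: with ``mu`` the unit internuclear vector and
angle brackets the ensemble average,

    S2 = 3/2 * ( <mux^2>^2 + <muy^2>^2 + <muz^2>^2
                 + 2<mux*muy>^2 + 2<mux*muz>^2 + 2<muy*muz>^2 ) - 1/2

so S2 = 1 for a rigid vector and tends to 0 for isotropic disorder.  The
expression is a second-moment average, hence invariant under mu -> -mu, but
*not* under per-model rotations: the ensemble must be superposed
(:func:`ensdyn.superpose.fit_ensemble`) before calling
:func:`back_calculate_s2`.

Backbone amide N-H vectors and side-chain methyl symmetry axes (the vector
from the methyl carbon's heavy-atom neighbour to the methyl carbon) are the
two vector classes handled here.  No proton-geometry scaling is applied to
methyl axes by default; pass ``methyl_axis_scale`` to compare against
proton-derived side-chain order parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble_io import Ensemble, read_table, write_table

__all__ = [
    "BACKBONE_NH",
    "METHYL_AXIS",
    "VectorDefinition",
    "OrderParameterTable",
    "default_nh_vectors",
    "back_calculate_s2",
    "correlate_s2",
]

BACKBONE_NH = "backbone_NH"
METHYL_AXIS = "methyl_axis"
_CLASSES = (BACKBONE_NH, METHYL_AXIS)


@dataclass(frozen=True)
class VectorDefinition:
    """An internuclear vector, resolved per model as atom_to - atom_from."""

    residue_number: int
    vector_class: str
    atom_from: str
    atom_to: str
    chain: str = "A"

    def __post_init__(self) -> None:
        if self.vector_class not in _CLASSES:
            raise ValueError(f"unknown vector class {self.vector_class!r}")


@dataclass
class OrderParameterTable:
    """Per-residue, per-vector-class S2 values.

    ``data`` has columns ``residue``, ``vector_class``, ``s2`` with unique
    (residue, vector_class) keys.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"residue", "vector_class", "s2"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"order parameter table needs columns {sorted(need)}")
        if self.data.duplicated(["residue", "vector_class"]).any():
            raise ValueError("duplicate (residue, vector_class) keys")

    @classmethod
    def from_records(cls, rows: Iterable[tuple[int, str, float]]) -> "OrderParameterTable":
        return cls(pd.DataFrame(rows, columns=["residue", "vector_class", "s2"]))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrderParameterTable":
        return cls(read_table(path)[["residue", "vector_class", "s2"]])

    def to_tsv(self, path: str | Path, comment: str = "") -> None:
        write_table(self.data, path, comment=comment or "S2 order parameters")

    def lookup(self) -> Mapping[tuple[int, str], float]:
        return {(int(r), c): float(s) for r, c, s in
                self.data[["residue", "vector_class", "s2"]].itertuples(index=False)}


def default_nh_vectors(e: Ensemble, h_name: str = "H") -> list[VectorDefinition]:
    """Backbone N-H vector definitions for every residue having both atoms.

    Residues without an amide proton (prolines, N-terminus) are simply
    absent, not errors.
    """
    have: dict[tuple[str, int], set[str]] = {}
    for a in e.atoms:
        have.setdefault((a.chain, a.residue_number), set()).add(a.name)
    defs = []
    for (chain, res), names in have.items():
        if "N" in names and h_name in names:
            defs.append(VectorDefinition(res, BACKBONE_NH, "N", h_name, chain=chain))
    return defs


def back_calculate_s2(
    e: Ensemble,
    vectors: Iterable[VectorDefinition],
    methyl_axis_scale: float = 1.0,
) -> OrderParameterTable:
    """Back-calculate one S2 per vector definition from a fitted ensemble.

    ``methyl_axis_scale`` multiplies methyl-axis values (e.g. 0.111 for the
    proton-geometry convention); the default 1.0 reports bare axis order
    parameters.
    """
    index = {a.key: i for i, a in enumerate(e.atoms)}
    rows = []
    for v in vectors:
        try:
            i_from = index[(v.chain, v.residue_number, v.atom_from)]
            i_to = index[(v.chain, v.residue_number, v.atom_to)]
        except KeyError as exc:
            raise ValueError(
                f"residue {v.chain}{v.residue_number}: atom {exc.args[0][2]!r} "
                f"not in the atom table"
            ) from None
        d = e.coords[:, i_to, :] - e.coords[:, i_from, :]
        norms = np.linalg.norm(d, axis=1)
        bad = np.nonzero(norms < 1e-12)[0]
        if bad.size:
            raise ValueError(
                f"zero-length {v.vector_class} vector in model {bad[0] + 1}, "
                f"residue {v.chain}{v.residue_number}"
            )
        mu = d / norms[:, None]
        x, y, z = mu[:, 0], mu[:, 1], mu[:, 2]
        s2 = 1.5 * (
            np.mean(x * x) ** 2 + np.mean(y * y) ** 2 + np.mean(z * z) ** 2
            + 2.0 * np.mean(x * y) ** 2 + 2.0 * np.mean(x * z) ** 2
            + 2.0 * np.mean(y * z) ** 2
        ) - 0.5
        if v.vector_class == METHYL_AXIS:
            s2 *= methyl_axis_scale
        s2 = float(min(max(s2, 0.0), 1.0))
        rows.append((v.residue_number, v.vector_class, s2))
    return OrderParameterTable.from_records(rows)


def correlate_s2(
    calculated: OrderParameterTable,
    experimental: OrderParameterTable,
) -> dict:
    """Compare back-calculated against experimental order parameters.

    Returns, separately for each vector class with at least 3 shared
    (residue, class) keys: Pearson r, RMS deviation, n, and per-residue
    residuals (calculated - experimental).  Raises if fewer than 3 keys are
    shared overall.
    """
    merged = calculated.data.merge(
        experimental.data, on=["residue", "vector_class"], suffixes=("_calc", "_exp")
    )
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} shared (residue, class) keys; need >= 3")
    report: dict = {}
    for vclass, grp in merged.groupby("vector_class"):
        if len(grp) < 3:
            continue
        calc = grp["s2_calc"].to_numpy()
        exp = grp["s2_exp"].to_numpy()
        resid = calc - exp
        if np.ptp(calc) == 0 or np.ptp(exp) == 0:
            r = 1.0 if np.allclose(resid, resid[0]) and np.ptp(resid) == 0 else float("nan")
        else:
            r = float(stats.pearsonr(calc, exp).statistic)
        report[vclass] = {
            "n": int(len(grp)),
            "pearson_r": r,
            "rmsd": float(np.sqrt(np.mean(resid**2))),
            "residuals": {int(res): float(d) for res, d in zip(grp["residue"], resid)},
        }
    return report
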