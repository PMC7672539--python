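"""Multi-model coordinate ensembles: the shared atom table, selections and PDB I/O.

An :class:`Ensemble` is an ordered list of :class:`AtomRecord` plus a stack of
coordinate sets (models), one 3-vector per atom per model, in Angstrom.  All
analyses in this package operate on this container.

PDB dialect notes
-----------------
* Models are delimited by ``MODEL``/``ENDMDL``; a file without ``MODEL``
  records is read as a single model.
* Alternate locations: the highest-occupancy conformer is kept; insertion
  codes are rejected with an error.
* Replica identifiers (which parallel-simulation trajectory a model came
  from) are carried in header lines ``REMARK 299 REPLICA MODEL <m> <r>``;
  when absent, a sidecar JSON file ``<path>.replicas.json`` holding a list of
  integers (one per model) is honoured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .elements import element_params, guess_element

__all__ = [
    "AtomRecord",
    "Ensemble",
    "Selection",
    "CALPHA",
    "BACKBONE",
    "HEAVY",
    "read_ensemble",
    "write_ensemble",
    "select",
]


@dataclass(frozen=True)
class AtomRecord:
    """One row of the shared atom table."""

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain: str
    mass: float
    vdw_radius: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.name}: mass must be > 0")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name}: vdw radius must be > 0")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_number, self.name)


@dataclass
class Ensemble:
    """An ordered set of conformers sharing one atom table.

    Attributes
    ----------
    atoms:
        The shared atom table.
    coords:
        Array of shape ``(n_models, n_atoms, 3)``, Angstrom.
    state_label:
        Free-text tag, e.g. ``"ff"`` (free full-length) or ``"cd"``
        (complex, C-terminally truncated).
    replica_ids:
        Optional integer per model identifying the source trajectory.
    fit_residuals:
        Per-model RMSD against the mean of the fit group, set by
        :func:`ensdyn.superpose.fit_ensemble`.
    """

    atoms: list[AtomRecord]
    coords: np.ndarray
    state_label: str = ""
    replica_ids: np.ndarray | None = None
    source: str = ""
    fit_residuals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("an ensemble needs at least one model")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coordinate sets have {self.coords.shape[1]} atoms, "
                f"atom table has {len(self.atoms)}"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates in ensemble")
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, int, str]] = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate atom (chain,residue,name)={k}")
                seen.add(k)
        if self.replica_ids is not None:
            self.replica_ids = np.asarray(self.replica_ids, dtype=int)
            if self.replica_ids.shape != (self.n_models,):
                raise ValueError("replica_ids must have one entry per model")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    def with_models(self, idx: Sequence[int] | np.ndarray) -> "Ensemble":
        """New ensemble restricted to the given model indices (order kept)."""
        idx = np.asarray(idx, dtype=int)
        return Ensemble(
            atoms=self.atoms,
            coords=self.coords[idx],
            state_label=self.state_label,
            replica_ids=None if self.replica_ids is None else self.replica_ids[idx],
            source=self.source,
        )


@dataclass(frozen=True)
class Selection:
    """Predicate on atoms; applying it preserves atom order and is idempotent."""

    residue_range: tuple[int, int] | None = None
    residues: frozenset[int] | None = None
    atom_names: frozenset[str] | None = None
    heavy_only: bool = False
    chain: str | None = None

    def matches(self, atom: AtomRecord) -> bool:
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if not (lo <= atom.residue_number <= hi):
                return False
        if self.residues is not None and atom.residue_number not in self.residues:
            return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        if self.heavy_only and atom.element == "H":
            return False
        if self.chain is not None and atom.chain != self.chain:
            return False
        return True

    def indices(self, atoms: Iterable[AtomRecord]) -> np.ndarray:
        return np.array([i for i, a in enumerate(atoms) if self.matches(a)], dtype=int)

    def describe(self) -> str:
        parts = []
        if self.residue_range:
            parts.append(f"residues {self.residue_range[0]}-{self.residue_range[1]}")
        if self.residues is not None:
            parts.append(f"residues {{{','.join(map(str, sorted(self.residues)))}}}")
        if self.atom_names is not None:
            parts.append(f"names {{{','.join(sorted(self.atom_names))}}}")
        if self.heavy_only:
            parts.append("heavy")
        if self.chain:
            parts.append(f"chain {self.chain}")
        return " & ".join(parts) if parts else "all atoms"


#: C-alpha trace (mode analysis convention)
CALPHA = Selection(atom_names=frozenset({"CA"}))
#: backbone fit group
BACKBONE = Selection(atom_names=frozenset({"N", "CA", "C", "O"}), heavy_only=True)
#: all non-hydrogen atoms (entropy / contact convention)
HEAVY = Selection(heavy_only=True)


def select(e: Ensemble, s: Selection) -> Ensemble:
    """Restrict an ensemble to the atoms matched by ``s`` (all models sliced identically)."""
    idx = s.indices(e.atoms)
    if idx.size == 0:
        raise ValueError(f"selection matched no atoms ({s.describe()})")
    return Ensemble(
        atoms=[e.atoms[i] for i in idx],
        coords=e.coords[:, idx, :],
        state_label=e.state_label,
        replica_ids=e.replica_ids,
        source=e.source,
    )


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> dict:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21]
        resseq = int(line[22:26])
        icode = line[26]
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed ATOM record at line {lineno}: {line.rstrip()!r}") from exc
    if icode not in (" ", ""):
        raise ValueError(
            f"insertion code {icode!r} at line {lineno} "
            f"(residue {chain}{resseq}): insertion codes are not supported"
        )
    if not element:
        element = guess_element(name)
    return dict(
        serial=serial, name=name, altloc=altloc, resname=resname, chain=chain,
        resseq=resseq, x=x, y=y, z=z, occupancy=occupancy, element=element,
    )


def _resolve_altlocs(raw: list[dict]) -> list[dict]:
    """Keep the highest-occupancy alternate location per (chain, residue, name)."""
    best: dict[tuple, dict] = {}
    order: list[tuple] = []
    for a in raw:
        key = (a["chain"], a["resseq"], a["name"])
        if key not in best:
            best[key] = a
            order.append(key)
        elif a["occupancy"] > best[key]["occupancy"]:
            best[key] = a
    return [best[k] for k in order]


def read_ensemble(path: str | Path, format: str = "pdb_multimodel") -> Ensemble:
    """Read a multi-model PDB file into an :class:`Ensemble`.

    Every model must contain the same atoms in the same order; a mismatch is
    a hard error naming the offending model.
    """
    if format != "pdb_multimodel":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    models: list[list[dict]] = []
    current: list[dict] | None = None
    saw_model_record = False
    state_label = ""
    replica_remarks: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model_record = True
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    models.append(_resolve_altlocs(current))
                current = None
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:
                    if saw_model_record:
                        raise ValueError(f"ATOM record outside MODEL block at line {lineno}")
                    current = []
                    models.append(None)  # type: ignore[arg-type]  # placeholder
                current.append(_parse_atom_line(line, lineno))
            elif rec == "REMARK":
                fields = line.split()
                if len(fields) >= 6 and fields[1] == "299" and fields[2] == "REPLICA" and fields[3] == "MODEL":
                    replica_remarks[int(fields[4])] = int(fields[5])
                elif len(fields) >= 4 and fields[1] == "299" and fields[2] == "STATE":
                    state_label = fields[3]
    if current is not None and not saw_model_record:
        models[0] = _resolve_altlocs(current)
    if not models or models[0] is None:
        raise ValueError(f"no coordinates found in {path}")

    ref = models[0]
    atoms: list[AtomRecord] = []
    for a in ref:
        mass, rvdw = element_params(a["element"])
        atoms.append(AtomRecord(
            serial=a["serial"], name=a["name"], element=a["element"].upper(),
            residue_number=a["resseq"], residue_name=a["resname"], chain=a["chain"],
            mass=mass, vdw_radius=rvdw,
        ))
    n_atoms = len(ref)
    coords = np.empty((len(models), n_atoms, 3))
    for m, model in enumerate(models):
        if len(model) != n_atoms:
            raise ValueError(f"model {m + 1} has {len(model)} atoms, expected {n_atoms}")
        for i, a in enumerate(model):
            if (a["chain"], a["resseq"], a["name"]) != atoms[i].key:
                raise ValueError(
                    f"model {m + 1}, atom {i + 1}: "
                    f"({a['chain']},{a['resseq']},{a['name']}) does not match "
                    f"model 1 atom {atoms[i].key}"
                )
            coords[m, i] = (a["x"], a["y"], a["z"])

    replica_ids: np.ndarray | None = None
    if replica_remarks:
        replica_ids = np.array([replica_remarks.get(m + 1, -1) for m in range(len(models))])
    else:
        sidecar = path.with_name(path.name + ".replicas.json")
        if sidecar.exists():
            ids = json.loads(sidecar.read_text())
            if len(ids) != len(models):
                raise ValueError(
                    f"replica sidecar {sidecar} has {len(ids)} entries for {len(models)} models"
                )
            replica_ids = np.asarray(ids, dtype=int)

    return Ensemble(atoms=atoms, coords=coords, state_label=state_label,
                    replica_ids=replica_ids, source=str(path))


def _format_atom_name(name: str, element: str) -> str:
    # PDB convention: 1-letter elements start in column 14 unless 4 chars long
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return name.ljust(4)
    return (" " + name).ljust(4)


def write_ensemble(e: Ensemble, path: str | Path) -> None:
    """Write a standard multi-model PDB file; model order is preserved.

    The state label and replica ids (if present) are recorded in
    ``REMARK 299`` header lines so a read/write round trip is lossless.
    """
    if e.n_models < 1:
        raise ValueError("refusing to write an ensemble with no models")
    path = Path(path)
    lines: list[str] = []
    if e.state_label:
        lines.append(f"REMARK 299 STATE {e.state_label}")
    if e.replica_ids is not None:
        for m, r in enumerate(e.replica_ids, start=1):
            lines.append(f"REMARK 299 REPLICA MODEL {m} {int(r)}")
    for m in range(e.n_models):
        lines.append(f"MODEL {m + 1:>8d}")
        for i, a in enumerate(e.atoms):
            x, y, z = e.coords[m, i]
            lines.append(
                "ATOM  {serial:>5d} {name}{alt}{res:>3s} {chain}{rnum:>4d}{icode}   "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}".format(
                    serial=(a.serial % 100000), name=_format_atom_name(a.name, a.element),
                    alt=" ", res=a.residue_name, chain=a.chain, rnum=a.residue_number,
                    icode=" ", x=x, y=y, z=z, occ=1.0, b=0.0, elem=a.element,
                )
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_table(df, path: str | Path, comment: str = "") -> None:
    """Write a DataFrame as TSV with a '#'-prefixed header line."""
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_table(path: str | Path):
    """Read a TSV written by :func:`write_table` (header line starts with '#')."""
    import pandas as pd

    path = Path(path)
    header: list[str] | None = None
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header = line[1:].strip().split("\t")
                skip += 1
            else:
                break
    if header is None:
        raise ValueError(f"{path}: no '#' header line")
    return pd.read_csv(path, sep="\t", skiprows=skip, names=header)
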