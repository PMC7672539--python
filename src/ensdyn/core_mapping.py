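"""Multiple-structure-alignment concatenation and common-core mapping.

Comparing conformational ensembles of homologous domains requires a common
set of residues.  Structural aligners can only handle limited batch sizes,
so several alignment blocks are produced and then *concatenated through a
pivot structure* present in every block: columns are reconciled by the
pivot's residue positions, and columns where the pivot is gapped in some
block are dropped (they cannot be reconciled; they are logged).

The *core* of an alignment is the set of columns ungapped in every
sequence, renumbered consecutively.  :func:`apply_core` rewrites a
structure or ensemble to core-only C-alpha atoms with this consensus
numbering, which makes ensembles of different domains directly poolable by
:func:`ensdyn.modes.combined_pca`.

Alignments are consumed, never computed: input is aligned FASTA (record id
``structure-id`` or ``structure-id|chain``) plus an optional sidecar TSV
giving the residue-number track; without a sidecar, non-gap positions are
numbered consecutively from 1 on chain "A".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .ensemble_io import AtomRecord, Ensemble, Selection, read_table, select

__all__ = ["AlignmentBlock", "CoreMapping", "read_alignment_fasta",
           "concatenate_alignments", "extract_core", "apply_core"]

logger = logging.getLogger(__name__)

ResidueRef = tuple[str, int]  # (chain, residue_number)
GAP = "-"


@dataclass
class AlignmentBlock:
    """One multiple alignment: aligned strings plus residue-number tracks.

    ``sequences`` maps structure-id to its aligned string (residue letters
    and ``-`` gaps, all the same length).  ``tracks`` maps structure-id to
    the (chain, residue_number) of each non-gap position, in order.
    """

    sequences: dict[str, str]
    tracks: dict[str, list[ResidueRef]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"aligned strings differ in length: {sorted(lengths)}")
        for sid, seq in self.sequences.items():
            n_res = sum(1 for ch in seq if ch != GAP)
            if sid not in self.tracks:
                self.tracks[sid] = [("A", i + 1) for i in range(n_res)]
            elif len(self.tracks[sid]) != n_res:
                raise ValueError(
                    f"{sid}: residue track has {len(self.tracks[sid])} entries "
                    f"for {n_res} non-gap positions"
                )

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def ungapped(self, sid: str) -> str:
        return self.sequences[sid].replace(GAP, "")

    def column_residues(self, sid: str) -> list[ResidueRef | None]:
        """Per column: the (chain, residue) of ``sid`` there, or None at gaps."""
        out: list[ResidueRef | None] = []
        it = iter(self.tracks[sid])
        for ch in self.sequences[sid]:
            out.append(None if ch == GAP else next(it))
        return out


@dataclass
class CoreMapping:
    """Consensus core indices 1..K and their residue in every structure."""

    mapping: dict[str, list[ResidueRef]]

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.mapping.values()}
        if len(lengths) != 1:
            raise ValueError("all structures must map every core index exactly once")
        for sid, refs in self.mapping.items():
            if len(set(refs)) != len(refs):
                raise ValueError(f"{sid}: core mapping is not injective")

    @property
    def core_length(self) -> int:
        return len(next(iter(self.mapping.values())))


def read_alignment_fasta(
    path: str | Path, track_tsv: str | Path | None = None
) -> AlignmentBlock:
    """Read an aligned FASTA (plus optional residue-number sidecar TSV).

    The sidecar has columns ``structure_id position chain residue`` where
    ``position`` is the 1-based index in the ungapped sequence.
    """
    sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not sequences:
        raise ValueError(f"no sequences in {path}")
    tracks: dict[str, list[ResidueRef]] = {}
    if track_tsv is not None:
        df = read_table(track_tsv)
        for sid, grp in df.groupby("structure_id"):
            grp = grp.sort_values("position")
            tracks[str(sid)] = [(str(c), int(r)) for c, r in zip(grp["chain"], grp["residue"])]
    return AlignmentBlock(sequences=sequences, tracks=tracks)


def concatenate_alignments(
    blocks: Sequence[AlignmentBlock], pivot: str
) -> AlignmentBlock:
    """Merge alignment blocks through a pivot structure present in all of them.

    The pivot's residues define the common column coordinate; each block's
    other sequences are re-expressed on those columns.  Alignment columns in
    which the pivot is gapped cannot be reconciled across blocks and are
    dropped (a warning reports how many per block).
    """
    if not blocks:
        raise ValueError("no alignment blocks given")
    for b, block in enumerate(blocks):
        if pivot not in block.sequences:
            raise ValueError(f"pivot {pivot!r} missing from block {b + 1}")
    ref = blocks[0].ungapped(pivot)
    for b, block in enumerate(blocks[1:], start=2):
        other = block.ungapped(pivot)
        if other != ref:
            for i, (x, y) in enumerate(zip(ref, other)):
                if x != y:
                    raise ValueError(
                        f"pivot sequences disagree at residue {i + 1}: "
                        f"{x!r} (block 1) vs {y!r} (block {b})"
                    )
            raise ValueError(
                f"pivot sequence length differs: {len(ref)} (block 1) vs "
                f"{len(other)} (block {b})"
            )

    n_piv = len(ref)
    merged_seqs: dict[str, list[str]] = {pivot: list(ref)}
    merged_tracks: dict[str, list[ResidueRef]] = {pivot: list(blocks[0].tracks[pivot])}
    for b, block in enumerate(blocks, start=1):
        # column index of the pivot's k-th residue in this block
        piv_cols = [c for c, ch in enumerate(block.sequences[pivot]) if ch != GAP]
        dropped = block.length - len(piv_cols)
        if dropped:
            logger.warning(
                "block %d: dropping %d column(s) not covered by pivot %r",
                b, dropped, pivot,
            )
        for sid in block.sequences:
            if sid == pivot:
                continue
            if sid in merged_seqs:
                raise ValueError(f"structure {sid!r} appears in more than one block")
            col_res = block.column_residues(sid)
            seq = block.sequences[sid]
            chars = [seq[c] for c in piv_cols]
            track = [col_res[c] for c in piv_cols if col_res[c] is not None]
            merged_seqs[sid] = chars
            merged_tracks[sid] = track  # type: ignore[assignment]
    return AlignmentBlock(
        sequences={sid: "".join(chars) for sid, chars in merged_seqs.items()},
        tracks=merged_tracks,
    )


def extract_core(block: AlignmentBlock) -> CoreMapping:
    """Columns ungapped in every sequence, renumbered 1..K in alignment order."""
    if len(block.sequences) < 2:
        raise ValueError("core extraction needs at least 2 structures")
    cols = [
        c for c in range(block.length)
        if all(seq[c] != GAP for seq in block.sequences.values())
    ]
    if not cols:
        raise ValueError("no common core: every column is gapped in some sequence")
    mapping: dict[str, list[ResidueRef]] = {}
    for sid in block.sequences:
        col_res = block.column_residues(sid)
        mapping[sid] = [col_res[c] for c in cols]  # type: ignore[misc]
    return CoreMapping(mapping=mapping)


def apply_core(e: Ensemble, m: CoreMapping, structure_id: str) -> Ensemble:
    """Rewrite an ensemble to core-only C-alpha atoms with consensus numbering.

    The output contains one CA atom per core index, in core order, residue
    numbers 1..K, for every model.  Missing residues or missing CA atoms
    are hard errors naming the residue.
    """
    if structure_id not in m.mapping:
        raise ValueError(f"structure {structure_id!r} not in core mapping")
    index = {a.key: i for i, a in enumerate(e.atoms)}
    picked: list[int] = []
    for k, (chain, res) in enumerate(m.mapping[structure_id], start=1):
        try:
            picked.append(index[(chain, res, "CA")])
        except KeyError:
            if any(a.chain == chain and a.residue_number == res for a in e.atoms):
                raise ValueError(
                    f"{structure_id}: residue {chain}{res} (core {k}) has no CA atom"
                ) from None
            raise ValueError(
                f"{structure_id}: residue {chain}{res} (core {k}) absent from ensemble"
            ) from None
    atoms = []
    for k, i in enumerate(picked, start=1):
        a = e.atoms[i]
        atoms.append(AtomRecord(
            serial=k, name="CA", element=a.element, residue_number=k,
            residue_name=a.residue_name, chain="A",
            mass=a.mass, vdw_radius=a.vdw_radius,
        ))
    return Ensemble(
        atoms=atoms,
        coords=e.coords[:, picked, :],
        state_label=e.state_label,
        replica_ids=e.replica_ids,
        source=f"{e.source}|core({structure_id})",
    )
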