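"""Residue-residue contact areas, discriminative contacts and the contact network.

Contact metric
--------------
The default ``soft_sphere`` metric is a solvent-probe-augmented overlap
proxy: for heavy atoms a in residue i and b in residue j,

    area(i, j) = sum_ab  pi * max(0, r_a + r_b + 2*r_w - d_ab)^2,   r_w = 1.4 A

summed per conformer, with sequence neighbours (|i - j| <= 1 on the same
chain) excluded.  It is monotone in atomic proximity but NOT numerically
comparable to Voronoi tessellation contact areas; the statistics below are
metric-agnostic, and ``precomputed`` ingests a per-model TSV from an
external tessellation tool instead.

Discriminative contacts
-----------------------
A residue pair discriminates two states when the difference of its mean
contact areas exceeds the sum of the two (population) standard deviations,

    |mean_A - mean_B| > sd_A + sd_B        (strict inequality),

for at least one of the examined state pairs.  Models where a pair is not
in contact contribute area 0 to its mean and SD.

The selected pairs form an undirected, unweighted residue graph whose
connected components and Brandes betweenness centralities (raw and
normalized) summarise the putative allosteric pathway.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .ensemble_io import Ensemble, read_table, select, HEAVY, write_table

__all__ = [
    "PROBE_RADIUS",
    "ContactAreas",
    "ContactStats",
    "ContactNetwork",
    "contact_areas",
    "read_precomputed_areas",
    "contact_statistics",
    "discriminative_contacts",
    "build_network",
]

PROBE_RADIUS = 1.4  # water probe, Angstrom
MIN_SEQ_SEP = 2  # |res_i - res_j| <= 1 excluded
#: distance margin (A) added to the maximal contact reach when prescreening
#: candidate atom pairs on the mean structure
PRESCREEN_MARGIN = 10.0

Pair = tuple[int, int]


@dataclass
class ContactAreas:
    """Per-conformer contact areas of one ensemble (sparse: zero rows omitted).

    ``data`` columns: ``model`` (0-based), ``res_i``, ``res_j`` (i < j),
    ``area`` (A^2).  ``n_models`` is required to average absent contacts
    as zeros.
    """

    data: pd.DataFrame
    n_models: int
    state_label: str = ""
    metric: str = "soft_sphere"

    def to_tsv(self, path: str | Path) -> None:
        write_table(self.data, path,
                    comment=f"per-model contact areas ({self.metric}), state={self.state_label}")


@dataclass
class ContactStats:
    """Per-state mean/SD of each contact; one row per residue pair.

    ``table`` columns: ``res_i``, ``res_j`` and ``mean_<state>``,
    ``sd_<state>`` for each state.
    """

    table: pd.DataFrame
    states: list[str]

    def pair_rows(self) -> Mapping[Pair, pd.Series]:
        return {(int(r.res_i), int(r.res_j)): r for r in self.table.itertuples()}


@dataclass
class ContactNetwork:
    graph: nx.Graph
    components: list[set[int]]  # sorted by size, descending
    betweenness_raw: dict[int, float]
    betweenness_normalized: dict[int, float]

    @property
    def n_nonzero_betweenness(self) -> int:
        return sum(1 for v in self.betweenness_raw.values() if v > 0)


def _candidate_pairs(e: Ensemble, min_seq_sep: int, margin: float):
    """Atom-pair index arrays worth evaluating, prescreened on the mean structure."""
    radii = e.vdw_radii
    resnum = np.array([a.residue_number for a in e.atoms])
    chains = np.array([a.chain for a in e.atoms])
    n = e.n_atoms
    ii, jj = np.triu_indices(n, k=1)
    same_res = (resnum[ii] == resnum[jj]) & (chains[ii] == chains[jj])
    near_seq = (np.abs(resnum[ii] - resnum[jj]) < min_seq_sep) & (chains[ii] == chains[jj])
    keep = ~(same_res | near_seq)
    ii, jj = ii[keep], jj[keep]
    reach = radii[ii] + radii[jj] + 2 * PROBE_RADIUS
    mean = e.coords.mean(axis=0)
    d_mean = np.linalg.norm(mean[ii] - mean[jj], axis=1)
    close = d_mean < reach + margin
    return ii[close], jj[close], reach[close], resnum, chains


def contact_areas(
    e: Ensemble,
    metric: str = "soft_sphere",
    min_seq_sep: int = MIN_SEQ_SEP,
    prescreen_margin: float = PRESCREEN_MARGIN,
) -> ContactAreas:
    """Per-conformer residue-pair contact areas over the heavy atoms of ``e``.

    ``prescreen_margin`` bounds how far atoms may fluctuate beyond their
    mean-structure separation and still be evaluated; it only matters for
    speed and must exceed the coordinate spread of the ensemble.
    """
    if metric != "soft_sphere":
        raise ValueError(
            f"unknown metric {metric!r}; use read_precomputed_areas() for "
            f"externally computed tessellation areas"
        )
    heavy = select(e, HEAVY)
    if (heavy.vdw_radii <= 0).any():
        raise ValueError("missing vdW radii")
    ii, jj, reach, resnum, chains = _candidate_pairs(heavy, min_seq_sep, prescreen_margin)

    # residue-pair id per candidate atom pair
    pair_keys = {}
    pair_of_atompair = np.empty(ii.size, dtype=int)
    for k in range(ii.size):
        ri, rj = int(resnum[ii[k]]), int(resnum[jj[k]])
        key = (min(ri, rj), max(ri, rj))
        pair_of_atompair[k] = pair_keys.setdefault(key, len(pair_keys))
    pairs = list(pair_keys)

    rows: list[tuple[int, int, int, float]] = []
    for m in range(e.n_models):
        d = np.linalg.norm(heavy.coords[m, ii] - heavy.coords[m, jj], axis=1)
        overlap = reach - d
        hit = overlap > 0
        if not hit.any():
            continue
        areas = np.zeros(len(pairs))
        np.add.at(areas, pair_of_atompair[hit], np.pi * overlap[hit] ** 2)
        for p in np.nonzero(areas)[0]:
            rows.append((m, pairs[p][0], pairs[p][1], float(areas[p])))
    data = pd.DataFrame(rows, columns=["model", "res_i", "res_j", "area"])
    return ContactAreas(data=data, n_models=e.n_models,
                        state_label=e.state_label, metric="soft_sphere")


def read_precomputed_areas(
    path: str | Path, n_models: int, state_label: str = ""
) -> ContactAreas:
    """Ingest per-model contact areas from an external tessellation tool.

    Expects a TSV with a '#'-prefixed header and columns
    ``model res_i res_j area`` (model 0-based, area in A^2).
    """
    df = read_table(path)[["model", "res_i", "res_j", "area"]]
    swap = df["res_i"] > df["res_j"]
    df.loc[swap, ["res_i", "res_j"]] = df.loc[swap, ["res_j", "res_i"]].to_numpy()
    return ContactAreas(data=df, n_models=n_models,
                        state_label=state_label, metric="precomputed")


def contact_statistics(per_state: Mapping[str, ContactAreas]) -> ContactStats:
    """Per-state mean and population SD of every contact seen in any state.

    The grouping keys may be ensemble labels or region labels from a state
    partition -- the statistics are agnostic.  Absent (model, pair)
    combinations count as zero area.
    """
    for state, ca in per_state.items():
        if ca.n_models < 2:
            raise ValueError(f"state {state!r} has {ca.n_models} conformers; need >= 2")
    all_pairs = sorted({
        (int(i), int(j))
        for ca in per_state.values()
        for i, j in zip(ca.data["res_i"], ca.data["res_j"])
    })
    index = {p: k for k, p in enumerate(all_pairs)}
    out = pd.DataFrame(all_pairs, columns=["res_i", "res_j"])
    states = list(per_state)
    for state in states:
        ca = per_state[state]
        total = np.zeros(len(all_pairs))
        total_sq = np.zeros(len(all_pairs))
        idx = np.array([index[(int(i), int(j))]
                        for i, j in zip(ca.data["res_i"], ca.data["res_j"])], dtype=int)
        a = ca.data["area"].to_numpy(float)
        np.add.at(total, idx, a)
        np.add.at(total_sq, idx, a * a)
        mean = total / ca.n_models
        var = np.clip(total_sq / ca.n_models - mean**2, 0.0, None)
        out[f"mean_{state}"] = mean
        out[f"sd_{state}"] = np.sqrt(var)
    return ContactStats(table=out, states=states)


def discriminative_contacts(
    stats: ContactStats,
    state_pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Residue pairs whose contact discriminates at least one state pair.

    Returns the selected rows of the statistics table with one boolean
    column ``disc_<A>_<B>`` per examined state pair and a ``selected``
    column; symmetric in state order.
    """
    if state_pairs is None:
        state_pairs = list(itertools.combinations(stats.states, 2))
    for a, b in state_pairs:
        for s in (a, b):
            if s not in stats.states:
                raise ValueError(f"unknown state {s!r}; have {stats.states}")
    out = stats.table.copy()
    selected = np.zeros(len(out), dtype=bool)
    for a, b in state_pairs:
        diff = np.abs(out[f"mean_{a}"] - out[f"mean_{b}"])
        flag = diff > (out[f"sd_{a}"] + out[f"sd_{b}"])
        out[f"disc_{a}_{b}"] = flag
        selected |= flag.to_numpy()
    out["selected"] = selected
    return out[out["selected"]].reset_index(drop=True)


def build_network(selected: pd.DataFrame | Sequence[Pair]) -> ContactNetwork:
    """Undirected unweighted graph over the selected contacts.

    Accepts the output of :func:`discriminative_contacts` or a plain list
    of residue pairs.  An empty selection yields an empty network.
    """
    if isinstance(selected, pd.DataFrame):
        edges = [(int(i), int(j)) for i, j in zip(selected["res_i"], selected["res_j"])]
    else:
        edges = [(int(i), int(j)) for i, j in selected]
    g = nx.Graph()
    g.add_edges_from(edges)
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    raw = nx.betweenness_centrality(g, normalized=False) if g.number_of_nodes() else {}
    norm = nx.betweenness_centrality(g, normalized=True) if g.number_of_nodes() else {}
    return ContactNetwork(
        graph=g, components=components,
        betweenness_raw=raw, betweenness_normalized=norm,
    )
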