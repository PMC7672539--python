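"""Contact areas, discriminative criterion and network metrics vs brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ensdyn.contacts_network import (PROBE_RADIUS, ContactAreas, build_network,
                                     contact_areas, contact_statistics,
                                     discriminative_contacts,
                                     read_precomputed_areas)

from conftest import make_ensemble


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_areas(e, min_seq_sep=2):
    """Triple-loop re-implementation of the soft-sphere contact metric."""
    out = []
    atoms = e.atoms
    for m in range(e.n_models):
        areas = {}
        for i, a in enumerate(atoms):
            for j in range(i + 1, len(atoms)):
                b = atoms[j]
                if a.element == "H" or b.element == "H":
                    continue
                if a.chain == b.chain and abs(a.residue_number - b.residue_number) < min_seq_sep:
                    continue
                d = float(np.linalg.norm(e.coords[m, i] - e.coords[m, j]))
                overlap = a.vdw_radius + b.vdw_radius + 2 * PROBE_RADIUS - d
                if overlap > 0:
                    key = tuple(sorted((a.residue_number, b.residue_number)))
                    areas[key] = areas.get(key, 0.0) + np.pi * overlap**2
        for (ri, rj), area in areas.items():
            out.append((m, ri, rj, area))
    return pd.DataFrame(out, columns=["model", "res_i", "res_j", "area"])


def brute_force_discriminative(stats, state_pairs):
    """Literal re-evaluation of the selection rule over every pair."""
    selected = set()
    for row in stats.table.itertuples():
        for a, b in state_pairs:
            diff = abs(getattr(row, f"mean_{a}") - getattr(row, f"mean_{b}"))
            if diff > getattr(row, f"sd_{a}") + getattr(row, f"sd_{b}"):
                selected.add((row.res_i, row.res_j))
                break
    return selected


def brute_force_betweenness(nodes, edges):
    """Betweenness by explicit shortest-path enumeration (raw convention)."""
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def bfs(src):
        dist, sigma = {src: 0}, {src: 1}
        frontier = [src]
        while frontier:
            nxt = []
            for v in frontier:
                for w in adj[v]:
                    if w not in dist:
                        dist[w] = dist[v] + 1
                        sigma[w] = 0
                        nxt.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
            frontier = nxt
        return dist, sigma

    bc = {v: 0.0 for v in nodes}
    info = {v: bfs(v) for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        dist_s, sigma_s = info[s]
        if t not in dist_s:
            continue
        dist_t, sigma_t = info[t]
        total = sigma_s[t]
        for v in nodes:
            if v in (s, t) or v not in dist_s or v not in dist_t:
                continue
            if dist_s[v] + dist_t[v] == dist_s[t]:
                bc[v] += sigma_s[v] * sigma_t[v] / total
    return bc


# ---------------------------------------------------------------------------
# contact areas
# ---------------------------------------------------------------------------

def two_residue_pair(d):
    """Two single-carbon residues 1 and 3 separated by distance d."""
    coords = np.array([[[0.0, 0, 0], [d, 0, 0]]])
    return make_ensemble(coords, resnums=[1, 3])


def test_hand_overlap_area():
    """r_a + r_b + 2 r_w - d = 1.7 + 1.7 + 2.8 - 5.2 = 1.0 -> area = pi."""
    ca = contact_areas(two_residue_pair(5.2))
    assert len(ca.data) == 1
    assert ca.data.area[0] == pytest.approx(np.pi, rel=1e-9)


def test_out_of_reach_is_zero():
    ca = contact_areas(two_residue_pair(6.3))  # reach is 6.2
    assert len(ca.data) == 0


def test_sequence_neighbours_excluded():
    coords = np.array([[[0.0, 0, 0], [4.0, 0, 0]]])
    e = make_ensemble(coords, resnums=[1, 2])
    assert len(contact_areas(e).data) == 0


def test_matches_brute_force_on_random_structures(rng):
    for _ in range(3):
        n_res = 6
        coords = rng.normal(scale=4.0, size=(4, 2 * n_res, 3))
        e = make_ensemble(coords,
                          names=["CA", "CB"] * n_res,
                          elements=["C", "O"] * n_res,
                          resnums=np.repeat(np.arange(1, n_res + 1), 2))
        got = contact_areas(e, prescreen_margin=1e6).data \
            .sort_values(["model", "res_i", "res_j"]).reset_index(drop=True)
        want = brute_force_areas(e).sort_values(["model", "res_i", "res_j"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, want, check_dtype=False, atol=1e-9)


def test_symmetry(rng):
    """area(i, j) is reported once per unordered pair with res_i < res_j."""
    coords = rng.normal(scale=3.0, size=(3, 8, 3))
    e = make_ensemble(coords, resnums=[1, 2, 3, 4, 5, 6, 7, 8])
    data = contact_areas(e).data
    assert (data.res_i < data.res_j).all()
    assert not data.duplicated(["model", "res_i", "res_j"]).any()


def test_precomputed_reader(tmp_path):
    from ensdyn.ensemble_io import write_table

    df = pd.DataFrame({"model": [0, 0, 1], "res_i": [1, 5, 3], "res_j": [3, 2, 1],
                       "area": [2.0, 1.0, 4.0]})
    path = tmp_path / "areas.tsv"
    write_table(df, path)
    ca = read_precomputed_areas(path, n_models=2, state_label="x")
    assert (ca.data.res_i < ca.data.res_j).all()
    assert ca.metric == "precomputed"


# ---------------------------------------------------------------------------
# statistics and the discriminative criterion
# ---------------------------------------------------------------------------

def areas_from_values(values, n_models, pair=(1, 3)):
    rows = [(m, pair[0], pair[1], v) for m, v in enumerate(values) if v != 0]
    return ContactAreas(
        data=pd.DataFrame(rows, columns=["model", "res_i", "res_j", "area"]),
        n_models=n_models)


def test_constant_area_stats():
    stats = contact_statistics({"a": areas_from_values([5.0] * 4, 4),
                                "b": areas_from_values([5.0] * 4, 4)})
    row = stats.table.iloc[0]
    assert row["mean_a"] == pytest.approx(5.0)
    assert row["sd_a"] == pytest.approx(0.0)


def test_population_sd():
    stats = contact_statistics({"a": areas_from_values([4.0, 6.0], 2)})
    row = stats.table.iloc[0]
    assert row["mean_a"] == pytest.approx(5.0)
    assert row["sd_a"] == pytest.approx(1.0)  # population, not sample


def test_absent_models_count_as_zero():
    stats = contact_statistics({"a": areas_from_values([8.0, 0.0], 2)})
    row = stats.table.iloc[0]
    assert row["mean_a"] == pytest.approx(4.0)
    assert row["sd_a"] == pytest.approx(4.0)


def test_single_conformer_state_rejected():
    with pytest.raises(ValueError, match="need >= 2"):
        contact_statistics({"a": areas_from_values([5.0], 1)})


def stats_from_design(design):
    """ContactStats with prescribed per-state (mean, sd) per pair."""
    pairs = sorted(design)
    table = pd.DataFrame(pairs, columns=["res_i", "res_j"])
    states = sorted({s for d in design.values() for s in d})
    for s in states:
        table[f"mean_{s}"] = [design[p][s][0] for p in pairs]
        table[f"sd_{s}"] = [design[p][s][1] for p in pairs]
    from ensdyn.contacts_network import ContactStats

    return ContactStats(table=table, states=states)


class TestDiscriminative:
    def test_direct_rule(self):
        stats = stats_from_design({(1, 3): {"A": (10.0, 1.0), "B": (20.0, 2.0)}})
        sel = discriminative_contacts(stats)
        assert len(sel) == 1 and sel.iloc[0]["disc_A_B"]

    def test_identical_distributions_not_selected(self):
        stats = stats_from_design({(1, 3): {"A": (10.0, 1.0), "B": (10.0, 1.0)}})
        assert len(discriminative_contacts(stats)) == 0

    def test_boundary_strictness(self):
        """|15 - 10| > 2 + 3 is false: the boundary case is NOT selected."""
        stats = stats_from_design({(1, 3): {"A": (10.0, 2.0), "B": (15.0, 3.0)}})
        assert len(discriminative_contacts(stats)) == 0

    def test_symmetric_in_state_order(self):
        stats = stats_from_design({(1, 3): {"A": (10.0, 1.0), "B": (20.0, 2.0)},
                                   (2, 5): {"A": (3.0, 2.0), "B": (4.0, 2.0)}})
        sel_ab = discriminative_contacts(stats, [("A", "B")])
        sel_ba = discriminative_contacts(stats, [("B", "A")])
        assert sel_ab[["res_i", "res_j"]].equals(sel_ba[["res_i", "res_j"]])

    def test_unknown_state(self):
        stats = stats_from_design({(1, 3): {"A": (1.0, 0.1), "B": (2.0, 0.1)}})
        with pytest.raises(ValueError, match="unknown state"):
            discriminative_contacts(stats, [("A", "Z")])

    def test_matches_brute_force(self, rng):
        design = {}
        for i in range(1, 15):
            for j in range(i + 2, 15):
                design[(i, j)] = {s: (float(rng.uniform(0, 20)), float(rng.uniform(0, 5)))
                                  for s in "ABCD"}
        stats = stats_from_design(design)
        pairs = list(itertools.combinations("ABCD", 2))
        sel = discriminative_contacts(stats, pairs)
        got = {(int(r.res_i), int(r.res_j)) for r in sel.itertuples()}
        assert got == brute_force_discriminative(stats, pairs)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class TestNetwork:
    def test_path_graph(self):
        net = build_network([(1, 2), (2, 3)])
        assert net.betweenness_raw[2] == pytest.approx(1.0)
        assert net.betweenness_raw[1] == net.betweenness_raw[3] == 0.0
        assert net.n_nonzero_betweenness == 1
        assert [len(c) for c in net.components] == [3]

    def test_disjoint_edges(self):
        net = build_network([(1, 2), (5, 8)])
        assert len(net.components) == 2
        assert all(v == 0.0 for v in net.betweenness_raw.values())

    def test_empty_selection(self):
        net = build_network([])
        assert net.components == [] and net.betweenness_raw == {}

    def test_normalized_scaling(self):
        net = build_network([(1, 2), (2, 3), (3, 4)])
        n = 4
        for v, raw in net.betweenness_raw.items():
            assert net.betweenness_normalized[v] == pytest.approx(
                raw * 2.0 / ((n - 1) * (n - 2)))

    def test_matches_exhaustive_oracle_on_random_graphs(self, rng):
        """50 random graphs with <= 12 nodes against shortest-path enumeration."""
        for _ in range(50):
            n = int(rng.integers(4, 13))
            p = rng.uniform(0.15, 0.6)
            nodes = list(range(n))
            edges = [(i, j) for i in nodes for j in nodes[i + 1:] if rng.random() < p]
            if not edges:
                continue
            net = build_network(edges)
            oracle = brute_force_betweenness(sorted(net.graph.nodes), edges)
            for v in net.graph.nodes:
                assert net.betweenness_raw[v] == pytest.approx(oracle[v], abs=1e-9)


def test_planted_contact_selected(default_study):
    """The displaced side-chain pair discriminates the designed states."""
    from ensdyn.contacts_network import contact_areas as areas

    per_state = {k: areas(e) for k, e in default_study.ensembles.items()}
    stats = contact_statistics(per_state)
    sel = discriminative_contacts(stats)
    i, j = default_study.manifest["contact_pair_residues"]
    assert ((sel.res_i == i) & (sel.res_j == j)).any()
    # and it discriminates specifically contact vs no-contact states
    row = sel[(sel.res_i == i) & (sel.res_j == j)].iloc[0]
    flags = [row[c] for c in sel.columns if c.startswith("disc_")
             and ("ff" in c or "fd" in c) and ("cf" in c or "cd" in c)]
    assert any(flags)
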