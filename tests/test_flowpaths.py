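"""Flow DAG construction and DA->AV path counting."""

import numpy as np
import pandas as pd
import pytest

from mvsim.flowpaths import (CycleError, FlowDAG, build_flow_dag, count_paths,
                             enumerate_paths, pair_analysis,
                             _penetrating_endpoints)
from mvsim.hemodynamics import BoundaryConditions, solve_pressure_flow
from mvsim.stroke import occlude
from mvsim.hemodynamics import fixed_point_flow_hematocrit

from conftest import simple_graph


def dag_from_edges(edges, da, av):
    """Build a FlowDAG directly from (vid, tail, head) triples."""
    e = {vid: (t, h) for vid, t, h in edges}
    out_e, in_e = {}, {}
    for vid, (t, h) in e.items():
        out_e.setdefault(t, []).append(vid)
        in_e.setdefault(h, []).append(vid)
    nodes = set(out_e) | set(in_e)
    import heapq
    indeg = {n: len(in_e.get(n, [])) for n in nodes}
    ready = [n for n in nodes if indeg[n] == 0]
    heapq.heapify(ready)
    topo = []
    while ready:
        n = heapq.heappop(ready)
        topo.append(n)
        for vid in out_e.get(n, []):
            indeg[e[vid][1]] -= 1
            if indeg[e[vid][1]] == 0:
                heapq.heappush(ready, e[vid][1])
    assert len(topo) == len(nodes)
    return FlowDAG(e, out_e, in_e, topo, set(da), set(av), 1e-8)


# ----------------------------------------------------------------- counting

def test_diamond_has_two_paths_one_per_middle_edge():
    dag = dag_from_edges([(0, 0, 1), (1, 0, 2), (2, 1, 3), (3, 2, 3)],
                         da={0}, av={3})
    idx = count_paths(dag)
    assert idx.total == 2
    assert idx.edge_counts == {0: 1, 1: 1, 2: 1, 3: 1}


def test_ladder_closed_form_path_count():
    # k+1 rungs between two directed rails -> k+1 distinct paths
    for k in (1, 3, 7, 12):
        edges = []
        vid = 0
        for i in range(k):
            edges.append((vid, ("a", i), ("a", i + 1))); vid += 1
            edges.append((vid, ("b", i), ("b", i + 1))); vid += 1
        for i in range(k + 1):
            edges.append((vid, ("a", i), ("b", i))); vid += 1
        dag = dag_from_edges(edges, da={("a", 0)}, av={("b", k)})
        assert count_paths(dag).total == k + 1


def _random_dag(rng):
    n = rng.integers(4, 12)
    edges = []
    vid = 0
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.35 and len(edges) < 30:
                edges.append((vid, int(i), int(j)))
                vid += 1
    if not edges:
        edges = [(0, 0, 1)]
    nodes = sorted({t for _, t, _ in edges} | {h for _, _, h in edges})
    head = nodes[:max(1, len(nodes) // 3)]
    tail = nodes[-max(1, len(nodes) // 3):]
    da = set(rng.choice(head, size=min(2, len(head)), replace=False).tolist())
    av = set(rng.choice(tail, size=min(2, len(tail)), replace=False).tolist())
    return dag_from_edges(edges, da=da, av=av - da)


def test_dp_counts_equal_exhaustive_enumeration_on_random_dags():
    rng = np.random.default_rng(23)
    for _ in range(500):
        dag = _random_dag(rng)
        idx = count_paths(dag)
        paths = enumerate_paths(dag)
        assert idx.total == len(paths)
        # per-edge identity U(tail) x W(head), checked against enumeration
        from collections import Counter
        per_edge = Counter(v for p in paths for v in set(p))
        for vid, (t, h) in dag.edges.items():
            assert idx.edge_counts[vid] == idx.u[t] * idx.w[h]
            assert idx.edge_counts[vid] == per_edge.get(vid, 0)
        # per-pair counts sum to the total
        assert sum(idx.pair_counts.values()) == idx.total


# ------------------------------------------------------------ DAG building

def _tree_graph():
    """DA main branch 0-1-2, offshoot to a branch point feeding two caps."""
    pos = {0: (0, 0, 0), 1: (0, 0, 80), 2: (0, 0, 160), 3: (50, 0, 170),
           4: (120, 0, 140), 5: (120, 40, 200)}
    g = simple_graph([(0, 1), (1, 2), (2, 3), (3, 4), (3, 5)], pos,
                     boundary=(0, 4, 5),
                     types=["DA", "DA", "DA", "C", "C"])
    g.vessels.loc[0, "main_branch"] = True
    g.vessels.loc[1, "main_branch"] = True
    return g


def test_penetrating_endpoint_is_first_branch_point_after_main():
    g = _tree_graph()
    assert _penetrating_endpoints(g, "DA") == {3}


def test_flow_dag_orientation_and_topological_order(lattice, lattice_baseline):
    g, _ = lattice
    dag = build_flow_dag(g, lattice_baseline)
    # topological order respects every edge
    order = {n: i for i, n in enumerate(dag.topo_order)}
    for t, h in dag.edges.values():
        assert order[t] < order[h]
    assert dag.da_endpoints and dag.av_endpoints


def test_large_eps_gives_empty_dag(motifs):
    g, _, _, field = motifs["2-2"]
    dag = build_flow_dag(g, field, q_eps=float(field.q.abs().max()) * 2,
                         da_endpoints=set(), av_endpoints=set())
    assert dag.edges == {}


def test_cyclic_orientation_is_detected():
    pos = {0: (0, 0, 0), 1: (50, 0, 0), 2: (25, 40, 0)}
    g = simple_graph([(0, 1), (1, 2), (2, 0)], pos)
    f = solve_pressure_flow(g, 0.0, BoundaryConditions({0: 10.0}))
    f.q = pd.Series({0: 1.0, 1: 1.0, 2: 1.0})   # artificial cyclic field
    with pytest.raises(CycleError):
        build_flow_dag(g, f, da_endpoints=set(), av_endpoints=set())


# ------------------------------------------------------------ pair analysis

def _motif_dags(motifs, mt="2-2"):
    g, bc, msc, field = motifs[mt]
    da, av = {1}, {8}     # node I (after the inlet stub) and node E
    dag_b = build_flow_dag(g, field, da_endpoints=da, av_endpoints=av)
    stroke = fixed_point_flow_hematocrit(occlude(g, [msc]), bc)
    dag_s = build_flow_dag(g, stroke, da_endpoints=da, av_endpoints=av)
    return g, msc, dag_b, dag_s


def test_cat1_ratio_matches_exhaustive_enumeration(motifs):
    g, msc, dag_b, dag_s = _motif_dags(motifs)
    pa = pair_analysis(dag_b, dag_s, msc)
    n_base = len(enumerate_paths(dag_b))
    n_stroke = len(enumerate_paths(dag_s))
    row = pa.pairs.iloc[0]
    assert len(pa.pairs) == 1
    assert row["category"] == "cat1"      # baseline paths traverse the MSC
    assert row["n_base"] == n_base
    assert row["n_stroke"] == n_stroke
    assert row["ratio"] == pytest.approx(n_stroke / n_base)


def test_occluding_the_only_bridge_loses_the_pair():
    #  da -> 0 -> 1 -> av ; single chain, occluding the middle drops the pair
    pos = {0: (0, 0, 0), 1: (50, 0, 0), 2: (100, 0, 0), 3: (150, 0, 0)}
    g = simple_graph([(0, 1), (1, 2), (2, 3)], pos, boundary=(0, 3))
    bc = BoundaryConditions({0: 100.0, 3: 0.0})
    base = solve_pressure_flow(g, 0.3, bc)
    stroke = solve_pressure_flow(occlude(g, [1]), 0.3, bc)
    dag_b = build_flow_dag(g, base, da_endpoints={1}, av_endpoints={2})
    dag_s = build_flow_dag(g, stroke, da_endpoints={1}, av_endpoints={2})
    pa = pair_analysis(dag_b, dag_s, 1)
    assert pa.n_pairs_lost == 1
    assert pa.total_base == 1 and pa.total_stroke == 0


def test_cat2_pair_untouched_by_rerouting_keeps_ratio_one():
    # two independent chains; occlusion in one leaves the other's pair at 1.0
    pos = {0: (0, 0, 0), 1: (50, 0, 0), 2: (100, 0, 0), 3: (150, 0, 0),
           4: (0, 100, 0), 5: (50, 100, 0), 6: (100, 100, 0), 7: (150, 100, 0)}
    g = simple_graph([(0, 1), (1, 2), (2, 3), (4, 5), (5, 6), (6, 7)], pos,
                     boundary=(0, 3, 4, 7))
    bc = BoundaryConditions({0: 100.0, 3: 0.0, 4: 100.0, 7: 0.0})
    base = solve_pressure_flow(g, 0.3, bc)
    stroke = solve_pressure_flow(occlude(g, [1]), 0.3, bc)
    da, av = {1, 5}, {2, 6}
    dag_b = build_flow_dag(g, base, da_endpoints=da, av_endpoints=av)
    dag_s = build_flow_dag(g, stroke, da_endpoints=da, av_endpoints=av)
    pa = pair_analysis(dag_b, dag_s, 1)
    cat2 = pa.pairs[pa.pairs["category"] == "cat2"]
    assert len(cat2) == 1
    assert cat2.iloc[0]["ratio"] == pytest.approx(1.0)
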