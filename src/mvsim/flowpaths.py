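"""Flow-direction DAG and DA -> AV flow-path counting.

The time-averaged flow field orients every perfused vessel; because the flow
follows the pressure potential the oriented graph is acyclic.  Paths are
counted between *DA endpoints* (the first branch point after the main branch
of a descending arteriole) and *AV endpoints* (mirrored for ascending
venules) by dynamic programming in topological order -- exact, big-integer
safe, and never materializing path lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import MVNGraph
from .hemodynamics import FlowField

Q_EPS_DEFAULT = 1e-8


class CycleError(RuntimeError):
    pass


@dataclass
class FlowDAG:
    """Directed view of the perfused network.

    ``edges`` maps vessel id -> (tail node, head node) following the flow;
    ``out_edges``/``in_edges`` index them per node; ``topo_order`` is a
    topological node order.
    """
    edges: dict[int, tuple[int, int]]
    out_edges: dict[int, list[int]]
    in_edges: dict[int, list[int]]
    topo_order: list[int]
    da_endpoints: set[int]
    av_endpoints: set[int]
    q_eps: float


def _penetrating_endpoints(g: MVNGraph, kind: str) -> set[int]:
    """Endpoints of penetrating trees: walk from every main-branch node along
    non-main vessels; the first node of degree >= 3 reached is an endpoint."""
    inc = g.incidence()
    main_vids = set(g.vessels.index[(g.vessels["type"] == kind)
                                    & g.vessels["main_branch"]])
    main_nodes: set[int] = set()
    for vid in main_vids:
        row = g.vessels.loc[vid]
        main_nodes.add(int(row["source"]))
        main_nodes.add(int(row["target"]))
    endpoints: set[int] = set()
    for node in sorted(main_nodes):
        for vid, other in inc[node]:
            if vid in main_vids:
                continue
            # walk away from the main branch until a branch point
            cur, cur_vid = other, vid
            for _ in range(g.n_vessels):
                if len(inc[cur]) >= 3:
                    endpoints.add(cur)
                    break
                nxt = [(v, o) for v, o in inc[cur] if v != cur_vid]
                if not nxt:
                    break
                cur_vid, cur = nxt[0]
    return endpoints


def build_flow_dag(g: MVNGraph, field: FlowField,
                   q_eps: float = Q_EPS_DEFAULT,
                   da_endpoints: set[int] | None = None,
                   av_endpoints: set[int] | None = None) -> FlowDAG:
    """Orient vessels by the sign of the (time-averaged) flow, dropping
    vessels with |q| <= q_eps, and verify acyclicity.

    Endpoints default to the first-branch-point definition applied to the
    main-branch flags; explicit sets override it (used on motif fixtures).
    """
    edges: dict[int, tuple[int, int]] = {}
    out_edges: dict[int, list[int]] = {}
    in_edges: dict[int, list[int]] = {}
    for vid in g.vessels.index:
        qv = float(field.q.loc[vid])
        if abs(qv) <= q_eps:
            continue
        row = g.vessels.loc[vid]
        s, t = int(row["source"]), int(row["target"])
        tail, head = (s, t) if qv > 0 else (t, s)
        edges[int(vid)] = (tail, head)
        out_edges.setdefault(tail, []).append(int(vid))
        in_edges.setdefault(head, []).append(int(vid))

    # Kahn topological sort
    nodes = set(out_edges) | set(in_edges)
    indeg = {n: len(in_edges.get(n, [])) for n in nodes}
    ready = sorted(n for n in nodes if indeg[n] == 0)
    topo: list[int] = []
    import heapq
    heapq.heapify(ready)
    while ready:
        n = heapq.heappop(ready)
        topo.append(n)
        for vid in out_edges.get(n, []):
            h = edges[vid][1]
            indeg[h] -= 1
            if indeg[h] == 0:
                heapq.heappush(ready, h)
    if len(topo) != len(nodes):
        cyc = sorted(n for n in nodes if indeg[n] > 0)
        raise CycleError(f"flow orientation contains a cycle through nodes {cyc[:10]}")

    if da_endpoints is None:
        da_endpoints = _penetrating_endpoints(g, "DA")
    if av_endpoints is None:
        av_endpoints = _penetrating_endpoints(g, "AV")
    return FlowDAG(edges, out_edges, in_edges, topo,
                   set(da_endpoints), set(av_endpoints), q_eps)


# ------------------------------------------------------------- path counting

@dataclass
class PathIndex:
    """Exact path counts on a flow DAG (Python integers, overflow-safe)."""
    u: dict[int, int]                    # paths from any DA endpoint to node
    w: dict[int, int]                    # paths from node to any AV endpoint
    edge_counts: dict[int, int]          # paths through each vessel
    total: int                           # total DA->AV path count
    pair_counts: dict[tuple[int, int], int]  # (da endpoint, av endpoint) -> n


def _forward_counts(dag: FlowDAG, sources: set[int]) -> dict[int, int]:
    u = {n: 0 for n in dag.topo_order}
    for n in dag.topo_order:
        if n in sources:
            u[n] += 1
        for vid in dag.out_edges.get(n, []):
            u[dag.edges[vid][1]] = u.get(dag.edges[vid][1], 0) + u[n]
    return u


def _backward_counts(dag: FlowDAG, sinks: set[int]) -> dict[int, int]:
    w = {n: 0 for n in dag.topo_order}
    for n in reversed(dag.topo_order):
        if n in sinks:
            w[n] += 1
        for vid in dag.in_edges.get(n, []):
            w[dag.edges[vid][0]] = w.get(dag.edges[vid][0], 0) + w[n]
    return w


def count_paths(dag: FlowDAG, per_pair: bool = True) -> PathIndex:
    """Count DA -> AV flow paths: per node (U, W), per edge (U x W), total,
    and per endpoint pair."""
    u = _forward_counts(dag, dag.da_endpoints)
    w = _backward_counts(dag, dag.av_endpoints)
    edge_counts = {vid: u[t] * w[h] for vid, (t, h) in dag.edges.items()}
    total = sum(u[a] for a in dag.av_endpoints if a in u)
    pair_counts: dict[tuple[int, int], int] = {}
    if per_pair:
        for d in sorted(dag.da_endpoints):
            ud = _forward_counts(dag, {d})
            for a in sorted(dag.av_endpoints):
                n = ud.get(a, 0)
                if n > 0:
                    pair_counts[(d, a)] = n
    return PathIndex(u, w, edge_counts, total, pair_counts)


def enumerate_paths(dag: FlowDAG, max_paths: int = 10 ** 6) -> list[list[int]]:
    """Explicit DFS enumeration of all DA -> AV paths (test oracle only)."""
    paths: list[list[int]] = []

    def dfs(node: int, acc: list[int]) -> None:
        if len(paths) >= max_paths:
            raise RuntimeError("path enumeration cap exceeded")
        if node in dag.av_endpoints and acc:
            paths.append(list(acc))
        for vid in sorted(dag.out_edges.get(node, [])):
            acc.append(vid)
            dfs(dag.edges[vid][1], acc)
            acc.pop()

    for d in sorted(dag.da_endpoints):
        dfs(d, [])
    return paths


# ------------------------------------------------------------- pair analysis

@dataclass
class PairAnalysis:
    """Per DA-AV-endpoint-pair comparison of baseline vs stroke path counts."""
    pairs: pd.DataFrame        # da, av, n_base, n_stroke, category, ratio
    n_pairs_gained: int
    n_pairs_lost: int
    total_base: int
    total_stroke: int


def _through_edge_pair_counts(dag: FlowDAG, msc: int) -> dict[tuple[int, int], int]:
    """Paths through a given edge per endpoint pair: U_d(tail) x W_a(head)."""
    if msc not in dag.edges:
        return {}
    tail, head = dag.edges[msc]
    wa_head = {a: _backward_counts(dag, {a}).get(head, 0)
               for a in sorted(dag.av_endpoints)}
    out: dict[tuple[int, int], int] = {}
    for d in sorted(dag.da_endpoints):
        ud_tail = _forward_counts(dag, {d}).get(tail, 0)
        if ud_tail == 0:
            continue
        for a, wh in wa_head.items():
            n = ud_tail * wh
            if n > 0:
                out[(d, a)] = n
    return out


def pair_analysis(dag_base: FlowDAG, dag_stroke: FlowDAG, msc: int) -> PairAnalysis:
    """Categorize endpoint pairs and compare path counts before/after stroke.

    Category 1: at least one baseline path between the pair traverses the
    MSC.  Category 2: no baseline path does.  Pairs that would be connected
    only through the (stagnant) MSC during stroke are excluded.
    """
    base_idx = count_paths(dag_base, per_pair=True)
    stroke_idx = count_paths(dag_stroke, per_pair=True)
    through = _through_edge_pair_counts(dag_base, msc)
    through_stroke = _through_edge_pair_counts(dag_stroke, msc)

    rows = []
    all_pairs = set(base_idx.pair_counts) | set(stroke_idx.pair_counts)
    gained = lost = 0
    for pair in sorted(all_pairs):
        n_base = base_idx.pair_counts.get(pair, 0)
        n_stroke = stroke_idx.pair_counts.get(pair, 0)
        if n_base == 0 and n_stroke > 0:
            gained += 1
        if n_base > 0 and n_stroke == 0:
            lost += 1
        n_stroke_off_msc = n_stroke - through_stroke.get(pair, 0)
        if n_stroke > 0 and n_stroke_off_msc == 0:
            category = "excluded"   # connected only through the MSC post-stroke
        elif through.get(pair, 0) > 0:
            category = "cat1"
        else:
            category = "cat2"
        ratio = n_stroke / n_base if n_base > 0 else np.nan
        rows.append((pair[0], pair[1], n_base, n_stroke, category, ratio))
    df = pd.DataFrame(rows, columns=["da", "av", "n_base", "n_stroke",
                                     "category", "ratio"])
    return PairAnalysis(df, gained, lost, base_idx.total, stroke_idx.total)
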