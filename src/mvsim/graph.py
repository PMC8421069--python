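"""Data model, validation, vessel-type labeling, depth layers and I/O for
microvascular network (MVN) graphs.

An MVN is an undirected geometric graph: nodes carry 3-D positions (um,
z = cortical depth, surface at z = 0) and vessels carry a diameter, a length
(which may exceed the straight source-target distance -- tortuosity), an
optional tortuous centerline polyline, a vessel-type label and, for
penetrating vessels, a main-branch flag.

Vessel types
------------
``PA`` pial artery, ``DA`` descending arteriole, ``C`` capillary,
``AV`` ascending venule, ``PV`` pial vein.
"""

from __future__ import annotations

import io
import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VESSEL_TYPES = ("PA", "DA", "C", "AV", "PV")

NODE_COLUMNS = ["x", "y", "z", "is_boundary"]
VESSEL_COLUMNS = ["source", "target", "diameter", "length", "type", "main_branch"]


@dataclass
class ValidationFinding:
    level: str  # "fatal" | "warning"
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.level}] {self.code}: {self.message}"


class MVNGraph:
    """Microvascular network graph.

    Parameters
    ----------
    nodes
        DataFrame indexed by integer node id with columns
        ``x, y, z`` (um) and ``is_boundary`` (bool).
    vessels
        DataFrame indexed by integer vessel id with columns
        ``source, target`` (node ids), ``diameter, length`` (um),
        ``type`` (one of :data:`VESSEL_TYPES`) and ``main_branch`` (bool).
        Extra columns are preserved as opaque attributes.
    centerlines
        Optional ``{vessel id: (k, 3) ndarray}``; vessels without an entry
        are treated as straight segments between their node positions.
    """

    def __init__(self, nodes: pd.DataFrame, vessels: pd.DataFrame,
                 centerlines: dict[int, np.ndarray] | None = None):
        nodes = nodes.copy()
        vessels = vessels.copy()
        for col, default in (("type", "C"), ("main_branch", False)):
            if col not in vessels.columns:
                vessels[col] = default
        if "is_boundary" not in nodes.columns:
            nodes["is_boundary"] = False
        nodes.index = nodes.index.astype(np.int64)
        vessels.index = vessels.index.astype(np.int64)
        nodes["is_boundary"] = nodes["is_boundary"].astype(bool)
        vessels["main_branch"] = vessels["main_branch"].astype(bool)
        missing = set(vessels["source"]).union(vessels["target"]) - set(nodes.index)
        if missing:
            bad = vessels[vessels["source"].isin(missing)
                          | vessels["target"].isin(missing)]
            raise ValueError(
                f"vessels {sorted(bad.index[:5].tolist())} reference missing "
                f"node ids {sorted(missing)[:5]}")
        self.nodes = nodes
        self.vessels = vessels
        self.centerlines: dict[int, np.ndarray] = {
            int(k): np.asarray(v, dtype=float) for k, v in (centerlines or {}).items()}
        self._incidence: dict[int, list[tuple[int, int]]] | None = None

    # ------------------------------------------------------------------ basics
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_vessels(self) -> int:
        return len(self.vessels)

    def node_position(self, nid: int) -> np.ndarray:
        return self.nodes.loc[nid, ["x", "y", "z"]].to_numpy(dtype=float)

    def positions(self) -> np.ndarray:
        return self.nodes[["x", "y", "z"]].to_numpy(dtype=float)

    def bounding_box(self) -> np.ndarray:
        """Axis-aligned bounds, shape (3, 2) [um]."""
        p = self.positions()
        return np.stack([p.min(axis=0), p.max(axis=0)], axis=1)

    def centerline(self, vid: int) -> np.ndarray:
        """Centerline polyline of a vessel, (k, 3); straight if none stored."""
        if vid in self.centerlines:
            return self.centerlines[vid]
        row = self.vessels.loc[vid]
        return np.stack([self.node_position(int(row["source"])),
                         self.node_position(int(row["target"]))])

    def incidence(self) -> dict[int, list[tuple[int, int]]]:
        """``{node id: [(vessel id, other node id), ...]}`` (cached)."""
        if self._incidence is None:
            inc: dict[int, list[tuple[int, int]]] = {int(n): [] for n in self.nodes.index}
            for vid, row in zip(self.vessels.index,
                                self.vessels[["source", "target"]].to_numpy()):
                s, t = int(row[0]), int(row[1])
                inc[s].append((int(vid), t))
                inc[t].append((int(vid), s))
            self._incidence = inc
        return self._incidence

    def degree(self, nid: int) -> int:
        return len(self.incidence()[nid])

    def invalidate_cache(self) -> None:
        self._incidence = None

    def copy(self) -> "MVNGraph":
        return MVNGraph(self.nodes, self.vessels,
                        {k: v.copy() for k, v in self.centerlines.items()})

    def chord_lengths(self) -> pd.Series:
        """Euclidean source-target distance per vessel [um]."""
        pos = self.nodes[["x", "y", "z"]]
        src = pos.loc[self.vessels["source"]].to_numpy()
        tgt = pos.loc[self.vessels["target"]].to_numpy()
        return pd.Series(np.linalg.norm(src - tgt, axis=1), index=self.vessels.index)

    def lumen_volumes(self) -> pd.Series:
        """Cylinder volume pi D^2/4 * L per vessel [um^3]."""
        d = self.vessels["diameter"].to_numpy(dtype=float)
        ln = self.vessels["length"].to_numpy(dtype=float)
        return pd.Series(np.pi * d * d / 4.0 * ln, index=self.vessels.index)

    def to_networkx(self):
        import networkx as nx
        g = nx.MultiGraph()
        for nid, row in self.nodes.iterrows():
            g.add_node(int(nid), x=row["x"], y=row["y"], z=row["z"],
                       is_boundary=bool(row["is_boundary"]))
        for vid, row in self.vessels.iterrows():
            g.add_edge(int(row["source"]), int(row["target"]), key=int(vid),
                       diameter=row["diameter"], length=row["length"],
                       type=row["type"], main_branch=bool(row["main_branch"]))
        return g


# ---------------------------------------------------------------- validation

def connected_components(g: MVNGraph) -> list[set[int]]:
    inc = g.incidence()
    seen: set[int] = set()
    comps = []
    for start in g.nodes.index:
        start = int(start)
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        seen.add(start)
        while queue:
            n = queue.popleft()
            for _, other in inc[n]:
                if other not in seen:
                    seen.add(other)
                    comp.add(other)
                    queue.append(other)
        comps.append(comp)
    return comps


def validate_graph(g: MVNGraph) -> list[ValidationFinding]:
    """Structural validation report; never raises."""
    findings: list[ValidationFinding] = []
    if g.nodes.index.has_duplicates:
        dup = g.nodes.index[g.nodes.index.duplicated()].tolist()
        findings.append(ValidationFinding("fatal", "duplicate-node-id",
                                          f"duplicate node ids {dup}"))
    if g.vessels.index.has_duplicates:
        dup = g.vessels.index[g.vessels.index.duplicated()].tolist()
        findings.append(ValidationFinding("fatal", "duplicate-vessel-id",
                                          f"duplicate vessel ids {dup}"))
    if not np.isfinite(g.positions()).all():
        findings.append(ValidationFinding("fatal", "non-finite-position",
                                          "node positions contain non-finite values"))
    for col in ("diameter", "length"):
        bad = g.vessels.index[~(g.vessels[col].to_numpy(dtype=float) > 0)]
        for vid in bad:
            findings.append(ValidationFinding(
                "fatal", f"nonpositive-{col}",
                f"vessel {int(vid)} has {col} = {g.vessels.loc[vid, col]}"))
    # tortuosity: length must not undercut the chord
    chord = g.chord_lengths()
    short = g.vessels.index[g.vessels["length"].to_numpy() < chord.to_numpy() * (1 - 1e-6)]
    for vid in short:
        findings.append(ValidationFinding(
            "warning", "length-below-chord",
            f"vessel {int(vid)} length {g.vessels.loc[vid, 'length']:.3g} um is below "
            f"its source-target distance {chord.loc[vid]:.3g} um"))
    # centerline consistency
    for vid, line in g.centerlines.items():
        if vid not in g.vessels.index:
            findings.append(ValidationFinding("warning", "orphan-centerline",
                                              f"centerline for unknown vessel {vid}"))
            continue
        arclen = float(np.linalg.norm(np.diff(line, axis=0), axis=1).sum())
        L = float(g.vessels.loc[vid, "length"])
        if L > 0 and abs(arclen - L) > 0.01 * L:
            findings.append(ValidationFinding(
                "warning", "centerline-length-mismatch",
                f"vessel {vid}: centerline arc length {arclen:.3g} deviates from "
                f"length attribute {L:.3g} by more than 1%"))
    inc = g.incidence()
    isolated = [n for n, lst in inc.items() if not lst]
    for n in isolated:
        findings.append(ValidationFinding("warning", "isolated-node",
                                          f"node {n} has no incident vessel"))
    comps = connected_components(g)
    nontrivial = [c for c in comps if len(c) > 1]
    if len(nontrivial) > 1:
        findings.append(ValidationFinding(
            "warning", "disconnected",
            f"graph has {len(nontrivial)} non-trivial connected components"))
    for nid, row in g.nodes.iterrows():
        if row["is_boundary"] and len(inc[int(nid)]) != 1:
            findings.append(ValidationFinding(
                "warning", "boundary-degree",
                f"boundary node {int(nid)} has degree {len(inc[int(nid)])} (expected 1)"))
    bad_type = g.vessels.index[~g.vessels["type"].isin(VESSEL_TYPES)]
    for vid in bad_type:
        findings.append(ValidationFinding(
            "fatal", "unknown-type",
            f"vessel {int(vid)} has unknown type {g.vessels.loc[vid, 'type']!r}"))
    mb_bad = g.vessels.index[g.vessels["main_branch"]
                             & ~g.vessels["type"].isin(["DA", "AV"])]
    for vid in mb_bad:
        findings.append(ValidationFinding(
            "warning", "main-branch-type",
            f"vessel {int(vid)} flagged main_branch but has type "
            f"{g.vessels.loc[vid, 'type']!r}"))
    return findings


# ------------------------------------------------------- vessel-type labeling

def _bfs_forest(g: MVNGraph, roots: list[int],
                skip_types: tuple[str, ...] = ()) -> tuple[dict[int, int], dict[int, int]]:
    """Deterministic BFS over vessels from root nodes.

    Returns ``(parent, dist)`` where ``parent[vid]`` is the vessel over which
    ``vid`` was first reached (-1 at a root) and ``dist[vid]`` its hop count.
    Ties between equal-distance discoveries are broken by vessel id, so the
    forest is independent of row order.
    """
    inc = g.incidence()
    vtypes = g.vessels["type"]
    parent: dict[int, int] = {}
    dist: dict[int, int] = {}
    node_frontier = {int(r): -1 for r in roots}  # node -> vessel that reached it
    visited_nodes = set(node_frontier)
    while node_frontier:
        # collect candidate (vid, via_vessel, far_node) from frontier, sorted by vid
        candidates: list[tuple[int, int, int]] = []
        for n, via in node_frontier.items():
            for vid, other in inc[n]:
                if vid in parent or vid == via:
                    continue
                candidates.append((vid, via, other))
        candidates.sort()
        next_frontier: dict[int, int] = {}
        for vid, via, other in candidates:
            if vid in parent:
                continue
            if str(vtypes.loc[vid]) in skip_types:
                continue
            parent[vid] = via
            dist[vid] = (dist[via] + 1) if via >= 0 else 1
            if other not in visited_nodes and other not in next_frontier:
                next_frontier[other] = vid
        visited_nodes.update(next_frontier)
        node_frontier = next_frontier
    return parent, dist


def assign_vessel_types(g: MVNGraph, da_roots: list[int], av_roots: list[int],
                        d_thresh: float = 6.0) -> MVNGraph:
    """Label vessels DA / AV / C by walking from the penetrating-tree roots.

    Walking away from each root, vessels keep the penetrating label until the
    first pair of *consecutive* vessels whose diameters are both below
    ``d_thresh``; the first vessel of that pair and everything beyond it is
    labeled capillary.  The identical rule is applied from the AV roots.
    Vessels of type PA/PV are left untouched; vessels unreachable from any
    root default to capillary.

    The walk order is a deterministic BFS (ties by vessel id), so the result
    is independent of vessel iteration order and idempotent.
    """
    out = g.copy()
    diam = out.vessels["diameter"]
    labels = pd.Series("C", index=out.vessels.index, dtype=object)
    pa_pv = out.vessels["type"].isin(["PA", "PV"])
    labels[pa_pv] = out.vessels.loc[pa_pv, "type"]
    claim_dist: dict[int, int] = {}

    for roots, label in ((da_roots, "DA"), (av_roots, "AV")):
        if not roots:
            continue
        parent, dist = _bfs_forest(out, list(roots), skip_types=())
        # children map of the BFS forest
        children: dict[int, list[int]] = {}
        for vid, par in parent.items():
            children.setdefault(par, []).append(vid)
        # find capillary-start vessels: first member of the first thin pair
        cap_start: set[int] = set()
        for vid, par in parent.items():
            if par >= 0 and diam.loc[vid] < d_thresh and diam.loc[par] < d_thresh:
                cap_start.add(par)
        # propagate: everything at/below a capillary start is C
        is_cap: dict[int, bool] = {}

        def mark(vid: int, inherited: bool) -> None:
            cap = inherited or vid in cap_start
            is_cap[vid] = cap
            for ch in children.get(vid, []):
                mark(ch, cap)

        for root_child in sorted(children.get(-1, [])):
            mark(root_child, False)
        for vid, cap in is_cap.items():
            if pa_pv.loc[vid]:
                continue
            new = "C" if cap else label
            if vid in claim_dist:
                # reached from both sides: closer root wins, tie -> capillary
                if dist[vid] < claim_dist[vid] and new != "C" and labels[vid] == "C":
                    labels[vid] = new
                    claim_dist[vid] = dist[vid]
                elif dist[vid] == claim_dist[vid] and labels[vid] != new:
                    labels[vid] = "C"
            else:
                labels[vid] = new
                claim_dist[vid] = dist[vid]
    out.vessels["type"] = labels
    # main_branch only meaningful on penetrating vessels
    out.vessels.loc[~out.vessels["type"].isin(["DA", "AV"]), "main_branch"] = False
    return out


# ----------------------------------------------------------- main-branch split

def split_main_branch(g: MVNGraph, da_roots: list[int], av_roots: list[int],
                      min_offshoot_length: float = 100.0) -> MVNGraph:
    """Flag the main branch of every penetrating (DA/AV) tree.

    At each bifurcation inside a penetrating tree exactly one child continues
    the main branch: the child minimizing the deviation angle from the parent
    direction, unless its downstream subtree path length is shorter than
    ``min_offshoot_length`` while a sibling's is not (then the longer child
    wins).  Ties break to the lowest vessel id.  This keeps short offshoots
    off the main branch.
    """
    out = g.copy()
    out.vessels["main_branch"] = False
    pos = {int(n): out.node_position(int(n)) for n in out.nodes.index}

    for roots, label in ((da_roots, "DA"), (av_roots, "AV")):
        for root in roots:
            # BFS restricted to this tree's own type (PA/PV lead into the root)
            parent, _ = _bfs_forest(out, [int(root)])
            tree = [vid for vid in parent if out.vessels.loc[vid, "type"] == label]
            tree_set = set(tree)
            children: dict[int, list[int]] = {}
            for vid in tree:
                par = parent[vid]
                children.setdefault(par if par in tree_set else -1, []).append(vid)

            # subtree max path length (within the tree)
            subtree_len: dict[int, float] = {}

            def slen(vid: int) -> float:
                if vid not in subtree_len:
                    L = float(out.vessels.loc[vid, "length"])
                    subtree_len[vid] = L + max((slen(c) for c in children.get(vid, [])),
                                               default=0.0)
                return subtree_len[vid]

            def direction(vid: int, from_node: int) -> np.ndarray:
                row = out.vessels.loc[vid]
                s, t = int(row["source"]), int(row["target"])
                far = t if s == from_node else s
                d = pos[far] - pos[from_node]
                n = np.linalg.norm(d)
                return d / n if n > 0 else d

            def far_node(vid: int, from_node: int) -> int:
                row = out.vessels.loc[vid]
                s, t = int(row["source"]), int(row["target"])
                return t if s == from_node else s

            # walk from the tree's entry vessel(s)
            entry = sorted(children.get(-1, []))
            if not entry:
                continue
            cur = entry[0]
            cur_node = int(root)
            # find which end of cur is attached toward the root side
            while True:
                out.vessels.loc[cur, "main_branch"] = True
                nxt_node = far_node(cur, cur_node)
                kids = children.get(cur, [])
                if not kids:
                    break
                if len(kids) == 1:
                    cur, cur_node = kids[0], nxt_node
                    continue
                par_dir = direction(cur, cur_node)
                lens = {k: slen(k) for k in kids}
                long_kids = [k for k in kids if lens[k] >= min_offshoot_length]
                pool = long_kids if long_kids else kids
                # smallest deviation angle; ties by vessel id
                best = min(pool, key=lambda k: (round(-float(np.dot(
                    par_dir, direction(k, nxt_node))), 9), k))
                cur, cur_node = best, nxt_node
    return out


# --------------------------------------------------------------- depth layers

@dataclass
class DepthLayerMap:
    """Vessel id -> analysis-layer index (1-based), plus bookkeeping."""
    layers: dict[int, int]
    thickness: float
    slack: float
    n_layers: int
    unassigned: list[int] = field(default_factory=list)


def assign_depth_layers(g: MVNGraph, thickness: float = 200.0,
                        slack: float = 50.0, n_layers: int = 5) -> DepthLayerMap:
    """Assign vessels to cortical analysis layers of ``thickness`` um.

    A vessel belongs to layer k if one endpoint depth lies in
    ``[(k-1)*thickness, k*thickness)`` and the other within the same bounds
    expanded by ``slack``.  Vessels qualifying for several layers get the
    shallowest one.
    """
    z = g.nodes["z"]
    layers: dict[int, int] = {}
    unassigned: list[int] = []
    src = g.vessels["source"].to_numpy()
    tgt = g.vessels["target"].to_numpy()
    z_s = z.loc[src].to_numpy(dtype=float)
    z_t = z.loc[tgt].to_numpy(dtype=float)
    for vid, zs, zt in zip(g.vessels.index, z_s, z_t):
        assigned = False
        for k in range(1, n_layers + 1):
            lo, hi = (k - 1) * thickness, k * thickness
            for za, zb in ((zs, zt), (zt, zs)):
                if lo <= za < hi and (lo - slack) <= zb <= (hi + slack):
                    layers[int(vid)] = k
                    assigned = True
                    break
            if assigned:
                break
        if not assigned:
            unassigned.append(int(vid))
    return DepthLayerMap(layers, thickness, slack, n_layers, unassigned)


# ------------------------------------------------------------------------ I/O

def _centerline_to_str(line: np.ndarray) -> str:
    return ";".join(":".join(repr(float(c)) for c in pt) for pt in line)


def _centerline_from_str(s: str) -> np.ndarray:
    pts = [[float(c) for c in pt.split(":")] for pt in s.split(";") if pt]
    return np.asarray(pts, dtype=float)


def write_network(g: MVNGraph, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``nodes.csv`` and ``edges.csv`` to ``out_dir`` (lossless)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    npath, epath = out_dir / "nodes.csv", out_dir / "edges.csv"
    npath.write_text(network_to_csv(g)[0])
    epath.write_text(network_to_csv(g)[1])
    return npath, epath


def network_to_csv(g: MVNGraph) -> tuple[str, str]:
    """Render the graph as (nodes csv, edges csv) strings."""
    nodes = g.nodes.copy()
    nodes.index.name = "id"
    vessels = g.vessels.copy()
    vessels.index.name = "id"
    vessels["centerline"] = [
        _centerline_to_str(g.centerlines[vid]) if vid in g.centerlines else ""
        for vid in vessels.index]
    nbuf, ebuf = io.StringIO(), io.StringIO()
    nodes.to_csv(nbuf, float_format=None)
    vessels.to_csv(ebuf)
    return nbuf.getvalue(), ebuf.getvalue()


def read_network(nodes_csv: str | Path, edges_csv: str | Path) -> MVNGraph:
    """Read a network from node/edge CSV tables (see ``write_network``).

    Raises ``ValueError`` naming the offending column/row on schema errors.
    """
    def _read(src):
        if isinstance(src, Path) or (isinstance(src, str) and "\n" not in src):
            return pd.read_csv(src, index_col="id")
        return pd.read_csv(io.StringIO(src), index_col="id")

    nodes = _read(nodes_csv)
    vessels = _read(edges_csv)
    for col in ("x", "y", "z"):
        if col not in nodes.columns:
            raise ValueError(f"nodes table is missing required column {col!r}")
    for col in ("source", "target", "diameter", "length"):
        if col not in vessels.columns:
            raise ValueError(f"edges table is missing required column {col!r}")
    for col in ("x", "y", "z"):
        if not np.issubdtype(np.asarray(nodes[col]).dtype, np.number):
            bad = nodes.index[pd.to_numeric(nodes[col], errors="coerce").isna()]
            raise ValueError(f"non-numeric {col!r} in nodes rows {bad.tolist()[:5]}")
    for col in ("diameter", "length"):
        if not np.issubdtype(np.asarray(vessels[col]).dtype, np.number):
            bad = vessels.index[pd.to_numeric(vessels[col], errors="coerce").isna()]
            raise ValueError(f"non-numeric {col!r} in edges rows {bad.tolist()[:5]}")
    centerlines = {}
    if "centerline" in vessels.columns:
        for vid, s in vessels["centerline"].items():
            if isinstance(s, str) and s:
                centerlines[int(vid)] = _centerline_from_str(s)
        vessels = vessels.drop(columns=["centerline"])
    return MVNGraph(nodes, vessels, centerlines)


def write_graphml(g: MVNGraph, path: str | Path) -> None:
    """GraphML export for external visualization tools."""
    import networkx as nx
    nxg = nx.Graph()
    for nid, row in g.nodes.iterrows():
        nxg.add_node(int(nid), x=float(row["x"]), y=float(row["y"]),
                     z=float(row["z"]), is_boundary=bool(row["is_boundary"]))
    for vid, row in g.vessels.iterrows():
        nxg.add_edge(int(row["source"]), int(row["target"]), id=int(vid),
                     diameter=float(row["diameter"]), length=float(row["length"]),
                     type=str(row["type"]), main_branch=bool(row["main_branch"]))
    nx.write_graphml(nxg, str(path))
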