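"""Local topology around a microstroke capillary (MSC).

MSC-type classification (2-in-2-out ... 1-in-1-out), signed generation maps
along the baseline flow directions, growing analysis boxes with perfusion
metrics, the upstream/downstream - parallel - distant vessel partition, and
the topological supplied-tissue-volume grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import deque

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .graph import MVNGraph
from .hemodynamics import FlowField
from .units import NL_TO_UM3

Q_EPS = 1e-8  # um^3/ms; below this a flow direction is numerically meaningless


# ------------------------------------------------------------ classification

def _signed_flow_at(g: MVNGraph, q: pd.Series, vid: int, node: int) -> float:
    """Flow signed positive when directed *into* ``node`` along vessel vid."""
    row = g.vessels.loc[vid]
    return float(q.loc[vid]) if int(row["target"]) == node else -float(q.loc[vid])


def classify_msc_type(g: MVNGraph, field: FlowField, vid: int,
                      q_eps: float = Q_EPS) -> str | None:
    """MSC type of a capillary: counts of baseline inflows at its upstream
    endpoint and outflows at its downstream endpoint.

    Returns ``"2-2" | "2-1" | "1-2" | "1-1"`` or ``None`` when the vessel is
    unclassifiable (an endpoint of degree != 3, or a stagnant incident
    vessel -- the flow direction in all five local vessels must be known).
    """
    q = field.q
    if abs(q.loc[vid]) <= q_eps:
        return None
    up = field.upstream_node(g, vid)
    down = field.downstream_node(g, vid)
    inc = g.incidence()
    if len(inc[up]) != 3 or len(inc[down]) != 3:
        return None
    n_in = 0
    for ovid, _ in inc[up]:
        if ovid == vid:
            continue
        f = _signed_flow_at(g, q, ovid, up)
        if abs(f) <= q_eps:
            return None
        if f > 0:
            n_in += 1
    n_out = 0
    for ovid, _ in inc[down]:
        if ovid == vid:
            continue
        f = _signed_flow_at(g, q, ovid, down)
        if abs(f) <= q_eps:
            return None
        if f < 0:
            n_out += 1
    if n_in not in (1, 2) or n_out not in (1, 2):
        return None
    return f"{n_in}-{n_out}"


# -------------------------------------------------------------- generations

@dataclass
class GenerationMap:
    """vessel id -> signed generation (-depth..-1, +1..+depth)."""
    generations: dict[int, int]
    msc: int
    depth: int

    def at(self, k: int) -> list[int]:
        return sorted(v for v, gg in self.generations.items() if gg == k)


def generations(g: MVNGraph, field: FlowField, msc: int, depth: int = 5,
                q_eps: float = Q_EPS) -> GenerationMap:
    """Signed generation map around the MSC on the baseline flow field.

    Generation -1 vessels carry flow *into* the MSC's upstream endpoint;
    generation -(k+1) vessels feed the upstream endpoints of generation -k
    vessels; mirrored downstream.  A vessel reachable at several depths keeps
    its first (smallest |generation|) assignment, upstream preferred on ties.
    """
    q = field.q
    inc = g.incidence()
    gen: dict[int, int] = {}
    up_frontier = {field.upstream_node(g, msc)}
    down_frontier = {field.downstream_node(g, msc)}
    for k in range(1, depth + 1):
        next_up: set[int] = set()
        for node in sorted(up_frontier):
            for vid, _ in inc[node]:
                if vid == msc or vid in gen:
                    continue
                f = _signed_flow_at(g, q, vid, node)
                if f > q_eps:  # feeds this node
                    gen[vid] = -k
                    next_up.add(field.upstream_node(g, vid))
        next_down: set[int] = set()
        for node in sorted(down_frontier):
            for vid, _ in inc[node]:
                if vid == msc or vid in gen:
                    continue
                f = _signed_flow_at(g, q, vid, node)
                if f < -q_eps:  # drains this node
                    gen[vid] = k
                    next_down.add(field.downstream_node(g, vid))
        up_frontier, down_frontier = next_up, next_down
    return GenerationMap(gen, msc, depth)


# ------------------------------------------------------------- analysis box

@dataclass
class AnalysisBox:
    """Axis-aligned box, bounds shape (3, 2) [um]."""
    bounds: np.ndarray

    @property
    def volume(self) -> float:
        side = self.bounds[:, 1] - self.bounds[:, 0]
        return float(np.prod(side))

    @property
    def volume_factor(self) -> float:
        return self.volume / (0.2 * NL_TO_UM3)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return np.all((pts >= lo) & (pts <= hi), axis=1)


def grow_box(initial_bounds: np.ndarray, target_volume: float,
             rtol: float = 1e-6) -> AnalysisBox:
    """Expand a box symmetrically by the same distance on all sides until its
    volume reaches ``target_volume`` [um^3].

    Solves ``(a + d)(b + d)(c + d) = V`` for ``d >= 0``.
    """
    b = np.asarray(initial_bounds, dtype=float).reshape(3, 2)
    sides = b[:, 1] - b[:, 0]
    v0 = float(np.prod(sides))
    if target_volume < v0 * (1 - 1e-9):
        raise ValueError(f"target volume {target_volume:.4g} um^3 is below the "
                         f"initial box volume {v0:.4g} um^3")
    if target_volume <= v0:
        return AnalysisBox(b.copy())

    def f(d: float) -> float:
        return float(np.prod(sides + d)) - target_volume

    hi = target_volume ** (1 / 3) + float(sides.max())
    d = brentq(f, 0.0, hi, rtol=rtol)
    out = b.copy()
    out[:, 0] -= d / 2.0
    out[:, 1] += d / 2.0
    return AnalysisBox(out)


def vessel_bounding_box(g: MVNGraph, vid: int) -> AnalysisBox:
    line = g.centerline(vid)
    return AnalysisBox(np.stack([line.min(axis=0), line.max(axis=0)], axis=1))


def msc_analysis_box(g: MVNGraph, msc: int, volume_nl: float = 0.2) -> AnalysisBox:
    """The analysis box around an MSC: its axis-aligned bounding box grown to
    the requested volume."""
    return grow_box(vessel_bounding_box(g, msc).bounds, volume_nl * NL_TO_UM3)


# -------------------------------------------------- centerline/box geometry

def _clip_segment(p0: np.ndarray, p1: np.ndarray,
                  lo: np.ndarray, hi: np.ndarray) -> tuple[float, float] | None:
    """Liang-Barsky: parameter interval [t0, t1] of p0->p1 inside the box."""
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        if abs(d[ax]) < 1e-300:
            if p0[ax] < lo[ax] or p0[ax] > hi[ax]:
                return None
            continue
        ta = (lo[ax] - p0[ax]) / d[ax]
        tb = (hi[ax] - p0[ax]) / d[ax]
        if ta > tb:
            ta, tb = tb, ta
        t0, t1 = max(t0, ta), min(t1, tb)
        if t0 > t1:
            return None
    return t0, t1


def clipped_centerline_length(g: MVNGraph, vid: int, box: AnalysisBox) -> float:
    """Arc length of the vessel centerline inside the box [um].

    The centerline is rescaled so that its full arc length equals the vessel's
    nominal length (tortuosity-consistent clipping).
    """
    line = g.centerline(vid)
    lo, hi = box.bounds[:, 0], box.bounds[:, 1]
    seg = np.diff(line, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = seg_len.sum()
    if total <= 0:
        return 0.0
    scale = float(g.vessels.loc[vid, "length"]) / total
    inside = 0.0
    for i in range(len(seg)):
        res = _clip_segment(line[i], line[i + 1], lo, hi)
        if res is not None:
            t0, t1 = res
            inside += (t1 - t0) * seg_len[i]
    return inside * scale


def vessels_in_box(g: MVNGraph, box: AnalysisBox,
                   types: tuple[str, ...] | None = None) -> list[int]:
    """Vessels whose centerline intersects the box."""
    out = []
    for vid in g.vessels.index:
        if types is not None and g.vessels.loc[vid, "type"] not in types:
            continue
        if clipped_centerline_length(g, int(vid), box) > 0:
            out.append(int(vid))
    return out


# --------------------------------------------------------- vessel categories

@dataclass
class VesselCategory:
    """Disjoint, exhaustive partition of the vessels inside a box."""
    updown: set[int]
    parallel: set[int]
    distant: set[int]

    def of(self, vid: int) -> str:
        if vid in self.updown:
            return "updown"
        if vid in self.parallel:
            return "parallel"
        return "distant"


def categorize_box_vessels(g: MVNGraph, field: FlowField, msc: int,
                           box: AnalysisBox, genmap: GenerationMap | None = None,
                           q_eps: float = Q_EPS) -> VesselCategory:
    """Partition the vessels inside the analysis box.

    ``updown``: the MSC and its generations +-1..+-5.  ``parallel``: vessels
    that branch off/into a generation 1 or 2 vessel, followed up to three
    segments along the flow (downstream on the upstream side, upstream on the
    downstream side).  ``distant``: everything else inside the box.
    """
    if genmap is None:
        genmap = generations(g, field, msc, depth=5, q_eps=q_eps)
    in_box = set(vessels_in_box(g, box))
    updown = ({msc} | set(genmap.generations)) & in_box

    q = field.q
    inc = g.incidence()
    core = {msc} | set(genmap.generations)
    parallel: set[int] = set()

    def follow(start_vid: int, direction: str) -> None:
        """Walk up to 3 segments down-/upstream of a branching vessel."""
        frontier = {start_vid}
        steps = 0
        while frontier and steps < 3:
            nxt: set[int] = set()
            for fv in frontier:
                node = (field.downstream_node(g, fv) if direction == "down"
                        else field.upstream_node(g, fv))
                for ovid, _ in inc[node]:
                    if ovid in core or ovid in parallel or ovid == fv:
                        continue
                    f = _signed_flow_at(g, q, ovid, node)
                    ok = (f < -q_eps) if direction == "down" else (f > q_eps)
                    if ok:
                        parallel.add(ovid)
                        nxt.add(ovid)
            frontier = nxt
            steps += 1

    for vid, gen in genmap.generations.items():
        if abs(gen) > 2:
            continue
        if gen < 0:
            # branches OFF an upstream vessel: outflows at its nodes other
            # than the path continuation, followed downstream
            for node in (field.upstream_node(g, vid), field.downstream_node(g, vid)):
                for ovid, _ in inc[node]:
                    if ovid in core or ovid == vid:
                        continue
                    f = _signed_flow_at(g, q, ovid, node)
                    if f < -q_eps:
                        parallel.add(ovid)
                        follow(ovid, "down")
        else:
            # branches INTO a downstream vessel: inflows, followed upstream
            for node in (field.upstream_node(g, vid), field.downstream_node(g, vid)):
                for ovid, _ in inc[node]:
                    if ovid in core or ovid == vid:
                        continue
                    f = _signed_flow_at(g, q, ovid, node)
                    if f > q_eps:
                        parallel.add(ovid)
                        follow(ovid, "up")

    parallel &= in_box
    parallel -= updown
    distant = in_box - updown - parallel
    return VesselCategory(updown, parallel, distant)


# ----------------------------------------------------------- box flow metrics

def box_inflow(g: MVNGraph, field: FlowField, box: AnalysisBox,
               q_eps: float = Q_EPS) -> float:
    """Total flow entering the box across its faces [um^3/ms].

    Every outside->inside crossing of a vessel centerline (walked in the
    direction of flow) contributes |q|; multi-crossing vessels contribute per
    crossing.
    """
    lo, hi = box.bounds[:, 0], box.bounds[:, 1]
    total = 0.0
    for vid in g.vessels.index:
        qv = float(field.q.loc[vid])
        if abs(qv) <= q_eps:
            continue
        line = g.centerline(int(vid))
        if qv < 0:
            line = line[::-1]
        prev_inside = bool(np.all(line[0] >= lo) and np.all(line[0] <= hi))
        for i in range(len(line) - 1):
            res = _clip_segment(line[i], line[i + 1], lo, hi)
            if res is None:
                prev_inside = False
                continue
            t0, t1 = res
            if not prev_inside and t0 >= 0.0 and t1 > t0:
                total += abs(qv)  # entering crossing
            prev_inside = t1 >= 1.0 - 1e-12
    return total


def box_inflow_difference(g: MVNGraph, base: FlowField, stroke: FlowField,
                          box: AnalysisBox) -> float | None:
    """Relative difference of total box inflow, stroke vs baseline.

    The sets of inflow crossings are recomputed independently for the two
    fields (reversals can change which vessels flow inward).  ``None`` when
    the baseline inflow is zero.
    """
    in_base = box_inflow(g, base, box)
    in_stroke = box_inflow(g, stroke, box)
    if in_base <= 0:
        return None
    return (in_stroke - in_base) / in_base


def box_total_flow(g: MVNGraph, field: FlowField, box: AnalysisBox) -> float:
    """Length-weighted total flow: sum |q| x (centerline length in box)."""
    total = 0.0
    for vid in g.vessels.index:
        ln = clipped_centerline_length(g, int(vid), box)
        if ln > 0:
            total += abs(float(field.q.loc[vid])) * ln
    return total


def box_total_flow_difference(g: MVNGraph, base: FlowField, stroke: FlowField,
                              box: AnalysisBox) -> float | None:
    tb = box_total_flow(g, base, box)
    ts = box_total_flow(g, stroke, box)
    if tb <= 0:
        return None
    return (ts - tb) / tb


def count_flow_decrease(g: MVNGraph, base: FlowField, stroke: FlowField,
                        box: AnalysisBox, exclude: set[int] | None = None,
                        tol: float = 1e-12) -> int:
    """Number of box vessels whose |q| decreased; occluded vessels excluded."""
    exclude = exclude or set()
    n = 0
    for vid in vessels_in_box(g, box):
        if vid in exclude:
            continue
        if abs(float(stroke.q.loc[vid])) < abs(float(base.q.loc[vid])) - tol:
            n += 1
    return n


# ------------------------------------------------------ supplied tissue grid

@dataclass
class TissueGrid:
    """4 um Cartesian tissue grid with nearest-vessel assignment."""
    cell_size: float
    shape: tuple[int, int, int]
    origin: np.ndarray
    nearest_vessel: np.ndarray            # flat array of vessel ids per cell
    supplied_volume: pd.Series            # um^3 per vessel

    @property
    def total_volume(self) -> float:
        return float(np.prod(self.shape)) * self.cell_size ** 3


def supplied_tissue_volume(g: MVNGraph, cell_size: float = 4.0,
                           bounds: np.ndarray | None = None,
                           point_spacing: float = 1.3) -> TissueGrid:
    """Topological supplied tissue volume per vessel.

    The tissue is discretized on a Cartesian grid (cells ``cell_size^3``);
    each cell center is assigned to the vessel with the nearest centerline
    point (ties -> lowest vessel id).  Summing cells per vessel gives its
    supplied volume; volumes partition the grid exactly.
    """
    from .avfactor import discretize
    pts, owner = discretize(g, spacing=point_spacing)
    # sort by (vessel id, point order) so the KD-tree prefers low ids on ties
    order = np.argsort(owner, kind="stable")
    pts, owner = pts[order], owner[order]
    tree = cKDTree(pts)
    if bounds is None:
        bounds = g.bounding_box()
    lo = bounds[:, 0]
    hi = bounds[:, 1]
    counts = np.maximum(np.ceil((hi - lo) / cell_size).astype(int), 1)
    axes = [lo[ax] + (np.arange(counts[ax]) + 0.5) * cell_size for ax in range(3)]
    centers = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    _, idx = tree.query(centers, workers=-1)
    nearest = owner[idx]
    vols = pd.Series(0.0, index=g.vessels.index)
    uniq, cnt = np.unique(nearest, return_counts=True)
    vols.loc[uniq] = cnt * cell_size ** 3
    return TissueGrid(cell_size, tuple(int(c) for c in counts), lo, nearest, vols)
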