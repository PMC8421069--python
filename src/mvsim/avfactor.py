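"""AV-factor and arteriole/venule proximity analyses.

The *AV-factor* of a capillary locates it along the arteriole -> venule
axis: the median length of all flow paths from DA endpoints to the capillary
divided by the sum of the upstream and downstream median path lengths.  It
is 0 near descending arterioles, 1 near ascending venules, and only defined
for capillaries lying on at least one complete DA -> AV flow path.

Three computation modes are provided:

``histogram`` (default)
    Exact weighted path-length distributions propagated through the flow
    DAG as fixed-bin histograms; medians read off the distribution.  Linear
    in (edges x bins) and exact up to the bin width.
``exact``
    Explicit DFS enumeration of all path lengths (combinatorially bounded;
    fixtures and tests).
``sample``
    Uniform path sampling weighted by DP path counts (unbiased; converges
    to the exhaustive medians).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .graph import MVNGraph
from .hemodynamics import FlowField
from .flowpaths import FlowDAG, build_flow_dag, _forward_counts, _backward_counts


# --------------------------------------------------------------- discretize

def discretize_vessel(g: MVNGraph, vid: int, spacing: float = 1.3) -> np.ndarray:
    """Arc-length-uniform resampling of one vessel centerline.

    ``n = ceil(L / spacing) + 1`` points including both endpoints, so
    consecutive spacing never exceeds the nominal value.
    """
    line = g.centerline(int(vid))
    L = float(g.vessels.loc[vid, "length"])
    n = int(np.ceil(L / spacing - 1e-9)) + 1
    seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        return np.repeat(line[:1], n, axis=0)
    targets = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for ax in range(3):
        out[:, ax] = np.interp(targets, cum, line[:, ax])
    return out


def discretize(g: MVNGraph, spacing: float = 1.3,
               vessels: list[int] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Discretization points for many vessels.

    Returns ``(points (N, 3), owner vessel id (N,))``.
    """
    vids = list(g.vessels.index) if vessels is None else list(vessels)
    pts_list, owner_list = [], []
    for vid in vids:
        p = discretize_vessel(g, int(vid), spacing)
        pts_list.append(p)
        owner_list.append(np.full(len(p), int(vid), dtype=np.int64))
    if not pts_list:
        return np.zeros((0, 3)), np.zeros(0, dtype=np.int64)
    return np.concatenate(pts_list), np.concatenate(owner_list)


# ---------------------------------------------------------------- AV-factor

@dataclass
class AVFactorMap:
    """Per-capillary AV-factor (NaN where unassigned) and median path lengths."""
    av_factor: pd.Series
    median_da: pd.Series
    median_av: pd.Series
    mode: str

    @property
    def assigned(self) -> pd.Series:
        return self.av_factor.notna()

    def fraction_assigned(self) -> float:
        return float(self.assigned.mean()) if len(self.av_factor) else 0.0


def _histogram_medians(dag: FlowDAG, lengths: dict[int, float],
                       sources: set[int], forward: bool,
                       bin_width: float) -> dict[int, float]:
    """Median path length from ``sources`` to every node (or from every node
    to ``sources`` when ``forward`` is False), via histogram DP."""
    counts = (_forward_counts(dag, sources) if forward
              else _backward_counts(dag, sources))
    hist: dict[int, tuple[int, np.ndarray]] = {}   # node -> (offset bin, weights)
    order = dag.topo_order if forward else list(reversed(dag.topo_order))
    medians: dict[int, float] = {}
    for n in order:
        if counts.get(n, 0) == 0:
            continue
        parts: list[tuple[int, np.ndarray, float]] = []  # (offset, normed hist, weight)
        if n in sources:
            parts.append((0, np.array([1.0]), 1.0))
        edge_iter = dag.in_edges.get(n, []) if forward else dag.out_edges.get(n, [])
        for vid in edge_iter:
            prev = dag.edges[vid][0] if forward else dag.edges[vid][1]
            if prev not in hist:
                continue
            off, h = hist[prev]
            shift = int(round(lengths[vid] / bin_width))
            parts.append((off + shift, h, float(counts[prev])))
        if not parts:
            continue
        lo = min(p[0] for p in parts)
        hi = max(p[0] + len(p[1]) for p in parts)
        acc = np.zeros(hi - lo)
        wsum = 0.0
        for off, h, wgt in parts:
            acc[off - lo: off - lo + len(h)] += h * wgt
            wsum += wgt
        acc /= acc.sum()
        hist[n] = (lo, acc)
        cum = np.cumsum(acc)
        k = int(np.searchsorted(cum, 0.5))
        medians[n] = (lo + k) * bin_width
    return medians


def _enumerate_lengths(dag: FlowDAG, lengths: dict[int, float], start: int,
                       targets: set[int], forward: bool,
                       cap: int) -> list[float]:
    """All path lengths between ``start`` and ``targets`` by DFS (oracle)."""
    out: list[float] = []

    def dfs(node: int, acc: float) -> None:
        if len(out) > cap:
            raise RuntimeError("enumeration cap exceeded")
        if node in targets:
            out.append(acc)
        edges = dag.out_edges.get(node, []) if forward else dag.in_edges.get(node, [])
        for vid in edges:
            nxt = dag.edges[vid][1] if forward else dag.edges[vid][0]
            dfs(nxt, acc + lengths[vid])

    dfs(start, 0.0)
    return out


def _sample_lengths(dag: FlowDAG, lengths: dict[int, float], start: int,
                    sources: set[int], forward_counts: dict[int, int],
                    n_samples: int, rng: np.random.Generator,
                    toward_sources_backward: bool) -> list[float]:
    """Uniformly sample path lengths between ``start`` and the sources using
    DP path-count weights (unbiased over all paths)."""
    out = []
    for _ in range(n_samples):
        node, acc = start, 0.0
        while True:
            total = float(forward_counts.get(node, 0))
            if total <= 0:
                break
            r = rng.random() * total
            if node in sources and r < 1.0:
                out.append(acc)
                break
            r -= 1.0 if node in sources else 0.0
            edges = (dag.in_edges.get(node, []) if toward_sources_backward
                     else dag.out_edges.get(node, []))
            chosen = None
            for vid in edges:
                prev = dag.edges[vid][0] if toward_sources_backward else dag.edges[vid][1]
                wgt = float(forward_counts.get(prev, 0))
                if r < wgt:
                    chosen = (vid, prev)
                    break
                r -= wgt
            if chosen is None and edges:
                vid = edges[-1]
                prev = dag.edges[vid][0] if toward_sources_backward else dag.edges[vid][1]
                chosen = (vid, prev)
            if chosen is None:
                break
            acc += lengths[chosen[0]]
            node = chosen[1]
    return out


def compute_av_factor(g: MVNGraph, field: FlowField, q_eps: float = 1e-8,
                      mode: str = "histogram", bin_width: float = 2.0,
                      enumeration_cap: int = 10 ** 5, n_samples: int = 10 ** 4,
                      seed: int = 0,
                      da_endpoints: set[int] | None = None,
                      av_endpoints: set[int] | None = None,
                      dag: FlowDAG | None = None) -> AVFactorMap:
    """AV-factor for every capillary on at least one DA -> AV flow path.

    The upstream median runs over the lengths of *all* flow paths from DA
    endpoints to the capillary's upstream node (plus half the capillary's own
    length); mirrored downstream.  AV-factor = medDA / (medDA + medAV).
    """
    if dag is None:
        dag = build_flow_dag(g, field, q_eps=q_eps,
                             da_endpoints=da_endpoints, av_endpoints=av_endpoints)
    lengths = {int(v): float(g.vessels.loc[v, "length"]) for v in dag.edges}
    caps = [int(v) for v in g.vessels.index if g.vessels.loc[v, "type"] == "C"]
    av_factor = pd.Series(np.nan, index=g.vessels.index, dtype=float)
    med_da = pd.Series(np.nan, index=g.vessels.index, dtype=float)
    med_av = pd.Series(np.nan, index=g.vessels.index, dtype=float)

    u = _forward_counts(dag, dag.da_endpoints)
    w = _backward_counts(dag, dag.av_endpoints)

    if mode == "histogram":
        med_up = _histogram_medians(dag, lengths, dag.da_endpoints, True, bin_width)
        med_down = _histogram_medians(dag, lengths, dag.av_endpoints, False, bin_width)
    rng = np.random.default_rng(seed)

    for vid in caps:
        if vid not in dag.edges:
            continue
        tail, head = dag.edges[vid]
        if u.get(tail, 0) == 0 or w.get(head, 0) == 0:
            continue
        half = lengths[vid] / 2.0
        if mode == "histogram":
            mda = med_up[tail] + half
            mav = med_down[head] + half
        elif mode == "exact":
            ups = _enumerate_lengths(dag, lengths, tail, dag.da_endpoints,
                                     forward=False, cap=enumeration_cap)
            downs = _enumerate_lengths(dag, lengths, head, dag.av_endpoints,
                                       forward=True, cap=enumeration_cap)
            mda = float(np.median(ups)) + half
            mav = float(np.median(downs)) + half
        elif mode == "sample":
            ups = _sample_lengths(dag, lengths, tail, dag.da_endpoints, u,
                                  n_samples, rng, toward_sources_backward=True)
            downs = _sample_lengths(dag, lengths, head, dag.av_endpoints, w,
                                    n_samples, rng, toward_sources_backward=False)
            mda = float(np.median(ups)) + half
            mav = float(np.median(downs)) + half
        else:
            raise ValueError(f"unknown mode {mode!r}")
        med_da.loc[vid] = mda
        med_av.loc[vid] = mav
        av_factor.loc[vid] = mda / (mda + mav)
    return AVFactorMap(av_factor, med_da, med_av, mode)


# ------------------------------------------------------------ distance maps

def distance_maps(g: MVNGraph, avmap: AVFactorMap, spacing: float = 1.3,
                  k_search: int = 24) -> pd.DataFrame:
    """Shortest distances around venule-sided capillary points.

    For every discretization point of a venule-sided capillary (AV-factor
    >= 0.5): the shortest distance to any vessel point excluding the point's
    own vessel, the shortest distance to an arteriole-sided capillary point
    (AV-factor < 0.5), and their ratio (the *distance factor*, >= 1 whenever
    the nearest vessel is not arteriole-sided).
    """
    pts, owner = discretize(g, spacing)
    tree_all = cKDTree(pts)
    factor = avmap.av_factor
    art_mask = np.array([factor.get(o, np.nan) < 0.5 for o in owner])
    ven_vessels = [int(v) for v in factor.index
                   if pd.notna(factor.loc[v]) and factor.loc[v] >= 0.5]
    if art_mask.any():
        tree_art = cKDTree(pts[art_mask])
    else:
        tree_art = None
    rows = []
    sel = np.isin(owner, ven_vessels)
    q_pts, q_owner = pts[sel], owner[sel]
    if len(q_pts):
        k = min(k_search, len(pts))
        dists, idxs = tree_all.query(q_pts, k=k, workers=-1)
        dists, idxs = np.atleast_2d(dists), np.atleast_2d(idxs)
        if tree_art is not None:
            d_art, _ = tree_art.query(q_pts, workers=-1)
        else:
            d_art = np.full(len(q_pts), np.nan)
        for i in range(len(q_pts)):
            d_any = np.nan
            for j in range(dists.shape[1]):
                if owner[idxs[i, j]] != q_owner[i]:
                    d_any = dists[i, j]
                    break
            if not np.isfinite(d_any):
                # all k nearest lie on the own vessel: fall back to a scan
                mask = owner != q_owner[i]
                if mask.any():
                    d_any = float(np.min(np.linalg.norm(
                        pts[mask] - q_pts[i], axis=1)))
            da = d_art[i]
            rows.append((int(q_owner[i]), *q_pts[i], d_any, da,
                         da / d_any if d_any and d_any > 0 else np.nan))
    return pd.DataFrame(rows, columns=["vessel", "x", "y", "z",
                                       "d_any", "d_arteriole", "distance_factor"])


# ------------------------------------------------------- sphere & cube scans

def sphere_scan(g: MVNGraph, avmap: AVFactorMap, radius: float = 50.0,
                spacing: float = 1.3, min_coverage: float = 0.5) -> pd.DataFrame:
    """Mean AV-factor in 50 um spheres moved along venule-sided capillaries.

    For each venule-sided capillary, all capillary points within ``radius``
    of any of its discretization points are collected; the sphere mean runs
    over points whose capillary has an AV-factor.  Capillaries where fewer
    than ``min_coverage`` of the in-sphere capillary points are assigned are
    flagged ineligible.
    """
    factor = avmap.av_factor
    cap_ids = [int(v) for v in g.vessels.index if g.vessels.loc[v, "type"] == "C"]
    pts, owner = discretize(g, spacing, vessels=cap_ids)
    tree = cKDTree(pts)
    pt_factor = np.array([factor.get(int(o), np.nan) for o in owner])
    rows = []
    for vid in cap_ids:
        f_own = factor.get(vid, np.nan)
        if pd.isna(f_own) or f_own < 0.5:
            continue
        own_pts = pts[owner == vid]
        hit: set[int] = set()
        for lst in tree.query_ball_point(own_pts, radius):
            hit.update(lst)
        hit_idx = np.fromiter(hit, dtype=np.int64)
        vals = pt_factor[hit_idx]
        n_tot = len(vals)
        n_ass = int(np.sum(~np.isnan(vals)))
        coverage = n_ass / n_tot if n_tot else 0.0
        mean = float(np.nanmean(vals)) if n_ass else np.nan
        rows.append((vid, f_own, mean, f_own - mean if n_ass else np.nan,
                     coverage, coverage >= min_coverage))
    return pd.DataFrame(rows, columns=["vessel", "av_factor", "sphere_mean",
                                       "difference", "coverage", "eligible"])


def cube_scan(g: MVNGraph, avmap: AVFactorMap, side: float,
              spacing: float = 1.3, min_capillaries: int = 4,
              min_coverage: float = 0.5) -> pd.DataFrame:
    """Mean AV-factor in an overlapping cube grid (overlap = half side).

    A cube is eligible if it holds at least ``min_capillaries`` capillaries
    with an AV-factor and at least ``min_coverage`` of its capillaries are
    assigned one.
    """
    factor = avmap.av_factor
    cap_ids = [int(v) for v in g.vessels.index if g.vessels.loc[v, "type"] == "C"]
    pts, owner = discretize(g, spacing, vessels=cap_ids)
    lo = g.bounding_box()[:, 0]
    stride = side / 2.0
    cube_caps: dict[tuple[int, int, int], set[int]] = {}
    rel = (pts - lo) / stride
    for p_rel, o in zip(rel, owner):
        # a point belongs to every cube whose [i*stride, i*stride + side) spans it
        idx_hi = np.floor(p_rel).astype(int)
        for di in (0, -1):
            for dj in (0, -1):
                for dk in (0, -1):
                    key = (idx_hi[0] + di, idx_hi[1] + dj, idx_hi[2] + dk)
                    if min(key) < 0:
                        continue
                    cube_caps.setdefault(key, set()).add(int(o))
    rows = []
    for key in sorted(cube_caps):
        caps = cube_caps[key]
        vals = [factor.get(v, np.nan) for v in caps]
        n_tot = len(vals)
        assigned = [v for v in vals if pd.notna(v)]
        coverage = len(assigned) / n_tot if n_tot else 0.0
        eligible = len(assigned) >= min_capillaries and coverage >= min_coverage
        center = lo + (np.array(key) * stride + side / 2.0)
        rows.append((*center, n_tot, len(assigned),
                     float(np.mean(assigned)) if assigned else np.nan,
                     coverage, eligible))
    return pd.DataFrame(rows, columns=["x", "y", "z", "n_capillaries",
                                       "n_assigned", "mean_av_factor",
                                       "coverage", "eligible"])
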