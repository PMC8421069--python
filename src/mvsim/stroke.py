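"""Microstroke protocol: occlusion, candidate selection, thresholded
relative change, single and sequential multi-capillary occlusion runs.

A microstroke is induced by constricting the microstroke capillary (MSC) to
a diameter of 0.01 um, which drives its flow below 1e-10 um^3/ms.  Flow
changes are compared through the *thresholded relative change*

    dq = (|q_stroke| - |q_base|) / |q_base|   if |Δ|q|| >= th_abs, else 0

with th_abs = 0.1 um^3/ms (0.2 RBC/s for RBC flux): absolute changes smaller
than the intrinsic fluctuations of the baseline field are treated as no
change.  Flow reversals are tracked separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .graph import MVNGraph
from .hemodynamics import (BoundaryConditions, FlowField,
                           fixed_point_flow_hematocrit)
from .rbc import RBCConfig, TimeAveragedField, run_and_average, steady_to_average
from .topology import (AnalysisBox, GenerationMap, Q_EPS, classify_msc_type,
                       generations, msc_analysis_box, vessel_bounding_box,
                       vessels_in_box)
from .units import NL_TO_UM3


@dataclass
class StrokeConfig:
    """Occlusion and MSC-selection parameters (units documented per field)."""
    occlusion_diameter: float = 0.01        # um
    th_abs: float = 0.1                     # um^3/ms
    th_rbc_flux: float = 0.2                # RBC/s
    cylinder_radius: float = 444.0          # um, criterion 1
    min_flow: float = 0.16                  # um^3/ms, criterion 2
    min_hematocrit: float = 0.02            # criterion 3 (tube hematocrit)
    dirchange_max_msc: float = 0.05         # criterion 4
    dirchange_max_gen1: float = 0.10
    dirchange_max_gen23: float = 0.30
    min_segments_from_main: int = 3         # criterion 5 (2 = relaxed variant)
    max_bounding_box_nl: float = 0.2        # criterion 6
    enabled_criteria: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    # optional case-specific filters (None = off)
    flow_range: tuple[float, float] | None = None
    q_eps: float = Q_EPS


@dataclass
class MSCCandidate:
    vessel: int
    msc_type: str
    baseline_flow: float
    baseline_hematocrit: float
    criteria: dict[int, bool]


@dataclass
class SelectionResult:
    candidates: list[MSCCandidate]
    surviving_counts: list[tuple[str, int]]   # cumulative "possible MSCs"


@dataclass
class StrokeResult:
    msc: int
    msc_type: str | None
    baseline: TimeAveragedField
    stroke: TimeAveragedField
    dq: pd.Series                  # thresholded relative flow change
    dq_flux: pd.Series             # thresholded relative RBC-flux change
    reversed_vessels: set[int]
    generations: GenerationMap
    occluded: tuple[int, ...]


# ------------------------------------------------------------------ occlude

def occlude(g: MVNGraph, vessel_ids: list[int] | tuple[int, ...],
            d_occ: float = 0.01) -> MVNGraph:
    """Return a copy of the graph with the given vessels constricted to
    ``d_occ`` um; everything else untouched."""
    if d_occ <= 0:
        raise ValueError("occlusion diameter must be positive")
    out = g.copy()
    for vid in vessel_ids:
        if vid not in out.vessels.index:
            raise KeyError(f"vessel {vid} does not exist")
    boundary_nodes = set(out.nodes.index[out.nodes["is_boundary"]])
    for vid in vessel_ids:
        row = out.vessels.loc[vid]
        if int(row["source"]) in boundary_nodes or int(row["target"]) in boundary_nodes:
            import warnings
            warnings.warn(f"occluding boundary vessel {vid}")
        out.vessels.loc[vid, "diameter"] = d_occ
    return out


# -------------------------------------------------- thresholded relative change

def thresholded_relative_change(q_base, q_stroke, th_abs: float = 0.1):
    """Relative change of |flow|, hard-zeroed below the absolute threshold.

    Vectorized; entries with ``q_base == 0`` are undefined and returned as
    NaN (excluded from aggregates).
    """
    qb = np.abs(np.asarray(q_base, dtype=float))
    qs = np.abs(np.asarray(q_stroke, dtype=float))
    delta = qs - qb
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(np.abs(delta) >= th_abs, delta / qb, 0.0)
    rel = np.where(qb == 0, np.nan, rel)
    if np.ndim(rel) == 0:
        return float(rel)
    if isinstance(q_base, pd.Series):
        return pd.Series(rel, index=q_base.index)
    return rel


# ---------------------------------------------------------------- selection

def segments_from_main_branch(g: MVNGraph, kind: str) -> pd.Series:
    """Per-vessel topological distance (in segments) to the nearest
    main-branch vessel of the given penetrating type (0 on the main branch)."""
    from collections import deque
    inc = g.incidence()
    dist = pd.Series(np.inf, index=g.vessels.index)
    start = g.vessels.index[(g.vessels["type"] == kind) & g.vessels["main_branch"]]
    dq = deque()
    for vid in start:
        dist.loc[vid] = 0
        dq.append(int(vid))
    while dq:
        vid = dq.popleft()
        row = g.vessels.loc[vid]
        for node in (int(row["source"]), int(row["target"])):
            for ovid, _ in inc[node]:
                if dist.loc[ovid] > dist.loc[vid] + 1:
                    dist.loc[ovid] = dist.loc[vid] + 1
                    dq.append(int(ovid))
    return dist


def select_msc_candidates(g: MVNGraph, baseline: TimeAveragedField,
                          cfg: StrokeConfig | None = None) -> SelectionResult:
    """Apply the six MSC selection criteria in order, reporting the count of
    surviving capillaries after each criterion.

    1. inside a cylinder of ``cylinder_radius`` around the x-y centroid;
    2. baseline mean flow > ``min_flow``;
    3. baseline mean hematocrit > ``min_hematocrit``;
    4. direction-change frequency <= 5% (MSC), 10% (generation +-1),
       30% (generations +-2, +-3);
    5. at least ``min_segments_from_main`` segments from both the DA and the
       AV main branch;
    6. vessel bounding box volume <= ``max_bounding_box_nl``.

    Criteria are conjunctive; disabled criteria pass everything.
    """
    cfg = cfg or StrokeConfig()
    caps = [int(v) for v in g.vessels.index if g.vessels.loc[v, "type"] == "C"]
    absq = baseline.mean_abs_q if baseline.mean_abs_q is not None else baseline.q.abs()
    freq = (baseline.dirchange_freq if baseline.dirchange_freq is not None
            else pd.Series(0.0, index=g.vessels.index))
    center = g.positions()[:, :2].mean(axis=0)
    d_da = segments_from_main_branch(g, "DA")
    d_av = segments_from_main_branch(g, "AV")

    def crit1(vid: int) -> bool:
        line = g.centerline(vid)
        mid = 0.5 * (line[0, :2] + line[-1, :2])
        return bool(np.linalg.norm(mid - center) <= cfg.cylinder_radius)

    def crit2(vid: int) -> bool:
        ok = absq.loc[vid] > cfg.min_flow
        if cfg.flow_range is not None:
            lo, hi = cfg.flow_range
            ok = ok and lo <= absq.loc[vid] <= hi
        return bool(ok)

    def crit3(vid: int) -> bool:
        return bool(baseline.ht.loc[vid] > cfg.min_hematocrit)

    def crit4(vid: int) -> bool:
        if freq.loc[vid] > cfg.dirchange_max_msc:
            return False
        gm = generations(g, baseline, vid, depth=3, q_eps=cfg.q_eps)
        for ovid, gen in gm.generations.items():
            cap = cfg.dirchange_max_gen1 if abs(gen) == 1 else cfg.dirchange_max_gen23
            if freq.loc[ovid] > cap:
                return False
        return True

    def crit5(vid: int) -> bool:
        return bool(d_da.loc[vid] >= cfg.min_segments_from_main
                    and d_av.loc[vid] >= cfg.min_segments_from_main)

    def crit6(vid: int) -> bool:
        return bool(vessel_bounding_box(g, vid).volume
                    <= cfg.max_bounding_box_nl * NL_TO_UM3)

    checks = {1: crit1, 2: crit2, 3: crit3, 4: crit4, 5: crit5, 6: crit6}
    surviving = list(caps)
    counts = [("capillaries", len(surviving))]
    results: dict[int, dict[int, bool]] = {v: {} for v in caps}
    for k in (1, 2, 3, 4, 5, 6):
        if k not in cfg.enabled_criteria:
            continue
        kept = []
        for vid in surviving:
            ok = checks[k](vid)
            results[vid][k] = ok
            if ok:
                kept.append(vid)
        surviving = kept
        counts.append((f"criterion {k}", len(surviving)))
    cands = []
    for vid in surviving:
        mt = classify_msc_type(g, baseline, vid, q_eps=cfg.q_eps)
        if mt is None:
            continue
        cands.append(MSCCandidate(vid, mt, float(absq.loc[vid]),
                                  float(baseline.ht.loc[vid]), results[vid]))
    return SelectionResult(cands, counts)


# ------------------------------------------------------------- stroke runs

def _compute_field(g: MVNGraph, bc: BoundaryConditions, mode: str, seed: int,
                   n_turnovers: int = 10,
                   rbc_cfg: RBCConfig | None = None) -> TimeAveragedField:
    if mode == "steady":
        return steady_to_average(fixed_point_flow_hematocrit(g, bc))
    if mode == "rbc":
        return run_and_average(g, bc, n_turnovers=n_turnovers, seed=seed,
                               cfg=rbc_cfg)
    raise ValueError(f"unknown mode {mode!r}")


def run_single_stroke(g: MVNGraph, msc: int, bc: BoundaryConditions,
                      mode: str = "steady", seed: int = 0,
                      cfg: StrokeConfig | None = None,
                      baseline: TimeAveragedField | None = None,
                      n_turnovers: int = 10,
                      rbc_cfg: RBCConfig | None = None) -> StrokeResult:
    """Occlude one capillary and compare the time-averaged fields.

    Pressure boundary conditions (and the seed, in RBC mode) are identical
    for the baseline and the stroke simulation.
    """
    cfg = cfg or StrokeConfig()
    if baseline is None:
        baseline = _compute_field(g, bc, mode, seed, n_turnovers, rbc_cfg)
    g_occ = occlude(g, [msc], cfg.occlusion_diameter)
    stroke = _compute_field(g_occ, bc, mode, seed, n_turnovers, rbc_cfg)

    qb = baseline.mean_abs_q if baseline.mean_abs_q is not None else baseline.q.abs()
    qs = stroke.mean_abs_q if stroke.mean_abs_q is not None else stroke.q.abs()
    dq = thresholded_relative_change(qb, qs, cfg.th_abs)
    dq = pd.Series(np.asarray(dq), index=g.vessels.index)
    dqf = thresholded_relative_change(baseline.rbc_flux, stroke.rbc_flux,
                                      cfg.th_rbc_flux)
    dqf = pd.Series(np.asarray(dqf), index=g.vessels.index)
    rev = {int(v) for v in g.vessels.index
           if abs(baseline.q.loc[v]) > cfg.q_eps
           and abs(stroke.q.loc[v]) > cfg.q_eps
           and np.sign(baseline.q.loc[v]) != np.sign(stroke.q.loc[v])}
    gm = generations(g, baseline, msc, depth=5, q_eps=cfg.q_eps)
    mt = classify_msc_type(g, baseline, msc, q_eps=cfg.q_eps)
    return StrokeResult(msc, mt, baseline, stroke, dq, dqf, rev, gm, (msc,))


def run_multi_occlusion(g: MVNGraph, msc: int, bc: BoundaryConditions,
                        mode: str = "steady", seed: int = 0,
                        cfg: StrokeConfig | None = None,
                        box_volume_nl: float = 0.3, n_target: int = 9,
                        baseline: TimeAveragedField | None = None,
                        min_box_capillaries: int = 12,
                        n_turnovers: int = 10,
                        rbc_cfg: RBCConfig | None = None
                        ) -> tuple[list[StrokeResult], AnalysisBox]:
    """Sequential multi-capillary occlusion (N = 1, 3, 5, 7, 9).

    After each stage the two non-occluded capillaries with the lowest
    time-averaged flow inside the 0.3 nl analysis box around the MSC are
    added to the occlusion set and the field is re-simulated.  Stops early
    (flagged by a shorter result list) when fewer than two candidates remain.
    """
    cfg = cfg or StrokeConfig()
    if baseline is None:
        baseline = _compute_field(g, bc, mode, seed, n_turnovers, rbc_cfg)
    box = msc_analysis_box(g, msc, volume_nl=box_volume_nl)
    box_caps = [v for v in vessels_in_box(g, box, types=("C",))]
    if len(box_caps) <= min_box_capillaries:
        raise ValueError(
            f"analysis box holds only {len(box_caps)} capillaries "
            f"(> {min_box_capillaries} required)")
    occluded: list[int] = [msc]
    results: list[StrokeResult] = []
    while True:
        g_occ = occlude(g, occluded, cfg.occlusion_diameter)
        stroke = _compute_field(g_occ, bc, mode, seed, n_turnovers, rbc_cfg)
        qb = baseline.mean_abs_q if baseline.mean_abs_q is not None else baseline.q.abs()
        qs = stroke.mean_abs_q if stroke.mean_abs_q is not None else stroke.q.abs()
        dq = pd.Series(np.asarray(thresholded_relative_change(qb, qs, cfg.th_abs)),
                       index=g.vessels.index)
        dqf = pd.Series(np.asarray(thresholded_relative_change(
            baseline.rbc_flux, stroke.rbc_flux, cfg.th_rbc_flux)),
            index=g.vessels.index)
        rev = {int(v) for v in g.vessels.index
               if abs(baseline.q.loc[v]) > cfg.q_eps
               and abs(stroke.q.loc[v]) > cfg.q_eps
               and np.sign(baseline.q.loc[v]) != np.sign(stroke.q.loc[v])}
        gm = generations(g, baseline, msc, depth=5, q_eps=cfg.q_eps)
        mt = classify_msc_type(g, baseline, msc, q_eps=cfg.q_eps)
        results.append(StrokeResult(msc, mt, baseline, stroke, dq, dqf, rev,
                                    gm, tuple(occluded)))
        if len(occluded) >= n_target:
            break
        # two lowest-|q| non-occluded capillaries in the box, from this stage
        pool = [(float(qs.loc[v]), v) for v in box_caps if v not in occluded]
        pool.sort()
        if len(pool) < 2:
            break
        occluded.extend([pool[0][1], pool[1][1]])
    return results, box
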