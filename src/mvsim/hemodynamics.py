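"""Steady pressure/flow solution of the vascular graph.

Poiseuille's law along every vessel and mass conservation at every node give
a sparse symmetric positive-definite linear system for the nodal pressures.
The presence of red blood cells enters through the empirical in-vitro
relative viscosity law (Pries formulation), the Fahraeus reduction of tube
hematocrit, and -- at divergent bifurcations -- the empirical phase
separation of RBC flux.

All three empirical relations were transcribed from the primary literature
and are exposed as plain vectorized functions.

Units: diameters/lengths um, pressures Pa, flows um^3/ms, viscosity Pa*s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph import MVNGraph, connected_components
from .units import MMHG_TO_PA, MU_PLASMA, RBC_VOLUME


# --------------------------------------------------------- empirical rheology

def relative_effective_viscosity(diameter, hd):
    """In-vitro relative effective viscosity mu_rel(D, H_d) (dimensionless).

    Empirical fit to glass-tube measurements: the relative apparent blood
    viscosity at 45% discharge hematocrit

        eta_45(D) = 220 exp(-1.3 D) + 3.2 - 2.44 exp(-0.06 D^0.645)

    is interpolated to other hematocrits through the shape exponent C(D).
    Equals 1 in the plasma limit ``hd = 0``.
    """
    d = np.asarray(diameter, dtype=float)
    h = np.asarray(hd, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    if np.any(h < 0) or np.any(h >= 1):
        raise ValueError("discharge hematocrit must be in [0, 1)")
    eta45 = 220.0 * np.exp(-1.3 * d) + 3.2 - 2.44 * np.exp(-0.06 * d ** 0.645)
    d12 = 1.0 / (1.0 + 1e-11 * d ** 12)
    c = (0.8 + np.exp(-0.075 * d)) * (-1.0 + d12) + d12
    num = (1.0 - h) ** c - 1.0
    den = (1.0 - 0.45) ** c - 1.0
    out = 1.0 + (eta45 - 1.0) * num / den
    return out if out.shape else float(out)


def fahraeus_ratio(diameter, hd):
    """Tube-to-discharge hematocrit ratio H_t/H_d (Fahraeus effect)."""
    d = np.asarray(diameter, dtype=float)
    h = np.asarray(hd, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    if np.any(h < 0) or np.any(h >= 1):
        raise ValueError("discharge hematocrit must be in [0, 1)")
    base = 1.0 + 1.7 * np.exp(-0.415 * d) - 0.6 * np.exp(-0.011 * d)
    out = h + (1.0 - h) * base
    return out if out.shape else float(out)


def fahraeus_tube_hematocrit(diameter, hd):
    """Tube hematocrit H_t from discharge hematocrit H_d; H_t <= H_d."""
    h = np.asarray(hd, dtype=float)
    out = h * np.asarray(fahraeus_ratio(diameter, np.maximum(h, 0.0)))
    return out if out.shape else float(out)


def discharge_from_tube_hematocrit(diameter, ht, n_iter: int = 40):
    """Invert the Fahraeus relation: H_d such that H_t(D, H_d) = ht.

    Fixed-point iteration; converges in a handful of steps over the
    microvascular range.
    """
    d = np.asarray(diameter, dtype=float)
    t = np.clip(np.asarray(ht, dtype=float), 0.0, 0.99)
    h = np.clip(t * 1.2, 0.0, 0.99)
    for _ in range(n_iter):
        r = fahraeus_ratio(d, np.clip(h, 0.0, 0.99))
        h_new = np.clip(t / np.maximum(r, 1e-9), 0.0, 0.99)
        if np.max(np.abs(h_new - h)) < 1e-12:
            h = h_new
            break
        h = h_new
    return h if h.shape else float(h)


def phase_separation_fraction(fqb, d_parent, d_d1, d_d2, hd):
    """Fraction of parent RBC flux entering daughter 1 (empirical law).

    ``fqb`` is the fractional bulk blood flow into daughter 1.  Valid for
    parent diameters above 10 um, where the empirical relation applies;
    smaller parents are in the single-file regime and must use the
    pressure-force rule instead.
    """
    if d_parent <= 10.0:
        raise ValueError("phase separation law applies to parent diameters > 10 um; "
                         "use the single-file rule below 10 um")
    if not 0.0 <= fqb <= 1.0:
        raise ValueError("fractional bulk flow must lie in [0, 1]")
    x0 = 0.964 * (1.0 - hd) / d_parent
    if fqb <= x0:
        return 0.0
    if fqb >= 1.0 - x0:
        return 1.0
    a = -13.29 * ((d_d1 ** 2 / d_d2 ** 2 - 1.0) / (d_d1 ** 2 / d_d2 ** 2 + 1.0)) \
        * (1.0 - hd) / d_parent
    b = 1.0 + 6.98 * (1.0 - hd) / d_parent
    x = (fqb - x0) / (1.0 - 2.0 * x0)
    logit = a + b * np.log(x / (1.0 - x))
    return float(1.0 / (1.0 + np.exp(-logit)))


# ------------------------------------------------------------ data containers

@dataclass
class BoundaryConditions:
    """Dirichlet pressure boundary conditions plus inflow hematocrit.

    ``pressures`` maps boundary node id -> pressure [Pa]; ``hd_inflow`` is the
    discharge hematocrit assigned to blood entering the domain.
    """
    pressures: dict[int, float]
    hd_inflow: float = 0.3

    @classmethod
    def from_mmhg(cls, pressures_mmhg: dict[int, float],
                  hd_inflow: float = 0.3) -> "BoundaryConditions":
        return cls({int(k): float(v) * MMHG_TO_PA for k, v in pressures_mmhg.items()},
                   hd_inflow)

    def copy(self) -> "BoundaryConditions":
        return BoundaryConditions(dict(self.pressures), self.hd_inflow)


@dataclass
class FlowField:
    """Steady solution: nodal pressures and per-vessel flow state.

    ``q`` is signed by the vessel's source -> target orientation.
    ``rbc_flux`` is in RBCs/s.
    """
    pressure: pd.Series
    q: pd.Series
    hd: pd.Series
    ht: pd.Series
    rbc_flux: pd.Series
    converged: bool = True
    n_iterations: int = 1

    def abs_q(self) -> pd.Series:
        return self.q.abs()

    def upstream_node(self, g: MVNGraph, vid: int) -> int:
        row = g.vessels.loc[vid]
        return int(row["source"]) if self.q.loc[vid] >= 0 else int(row["target"])

    def downstream_node(self, g: MVNGraph, vid: int) -> int:
        row = g.vessels.loc[vid]
        return int(row["target"]) if self.q.loc[vid] >= 0 else int(row["source"])


def conductances(g: MVNGraph, hd, mu: float = MU_PLASMA) -> pd.Series:
    """Vessel conductance G = pi D^4 / (128 L mu mu_rel) in um^3/(ms Pa)."""
    d = g.vessels["diameter"].to_numpy(dtype=float)
    ln = g.vessels["length"].to_numpy(dtype=float)
    h = np.asarray(hd, dtype=float)
    if h.ndim == 0:
        h = np.full(len(d), float(h))
    mu_rel = np.asarray(relative_effective_viscosity(d, h))
    g_si = np.pi * d ** 4 / (128.0 * ln * mu * mu_rel)  # um^3/(s Pa)
    return pd.Series(g_si * 1e-3, index=g.vessels.index)


class SingularSystemError(RuntimeError):
    pass


def solve_pressure_flow(g: MVNGraph, hd, bc: BoundaryConditions,
                        mu: float = MU_PLASMA,
                        rbc_volume: float = RBC_VOLUME) -> FlowField:
    """Solve the nodal continuity + Poiseuille system for pressures and flows.

    ``hd`` is a scalar or per-vessel Series of discharge hematocrits used for
    the effective viscosity.  Every connected component must contain at least
    one pressure boundary node, otherwise :class:`SingularSystemError` names
    the component.
    """
    node_ids = g.nodes.index.to_numpy()
    n = len(node_ids)
    pos_of = {int(nid): i for i, nid in enumerate(node_ids)}
    bset = {int(k) for k in bc.pressures}
    unknown_b = bset - set(pos_of)
    if unknown_b:
        raise ValueError(f"boundary pressures reference unknown nodes {sorted(unknown_b)[:5]}")
    for comp in connected_components(g):
        if len(comp) > 1 and not comp & bset:
            raise SingularSystemError(
                f"connected component of {len(comp)} nodes (e.g. node "
                f"{min(comp)}) has no pressure boundary condition")

    if isinstance(hd, pd.Series):
        hd = hd.reindex(g.vessels.index).to_numpy(dtype=float)
    cond = conductances(g, hd, mu=mu)
    src = np.array([pos_of[int(s)] for s in g.vessels["source"]])
    tgt = np.array([pos_of[int(t)] for t in g.vessels["target"]])
    gv = cond.to_numpy()

    rows = np.concatenate([src, tgt, src, tgt])
    cols = np.concatenate([src, tgt, tgt, src])
    vals = np.concatenate([gv, gv, -gv, -gv])
    lap = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    is_b = np.zeros(n, dtype=bool)
    pb = np.zeros(n)
    for nid, p in bc.pressures.items():
        is_b[pos_of[int(nid)]] = True
        pb[pos_of[int(nid)]] = float(p)
    interior = np.flatnonzero(~is_b)
    boundary = np.flatnonzero(is_b)

    p = np.array(pb)
    if interior.size:
        a_ii = lap[interior][:, interior]
        a_ib = lap[interior][:, boundary]
        rhs = -a_ib @ pb[boundary]
        if n > 1e5:
            sol, info = spla.cg(a_ii.tocsc(), rhs, rtol=1e-12, maxiter=20000)
            if info != 0:  # pragma: no cover - fallback path
                sol = spla.spsolve(a_ii.tocsc(), rhs)
        else:
            sol = spla.spsolve(a_ii.tocsc(), rhs)
        if not np.all(np.isfinite(sol)):
            raise SingularSystemError("pressure solve produced non-finite values")
        p[interior] = sol

    q = gv * (p[src] - p[tgt])
    pressure = pd.Series(p, index=node_ids)
    q_s = pd.Series(q, index=g.vessels.index)
    if np.isscalar(hd) or np.ndim(hd) == 0:
        hd_s = pd.Series(float(hd), index=g.vessels.index)
    else:
        hd_s = pd.Series(np.asarray(hd, dtype=float), index=g.vessels.index)
    ht_s = pd.Series(fahraeus_tube_hematocrit(
        g.vessels["diameter"].to_numpy(dtype=float), hd_s.to_numpy()),
        index=g.vessels.index)
    flux = hd_s * q_s.abs() * 1e3 / rbc_volume  # RBCs per second
    return FlowField(pressure, q_s, hd_s, ht_s, flux)


def continuity_residuals(g: MVNGraph, field: FlowField) -> pd.Series:
    """Net flow imbalance at every interior (non-boundary) node [um^3/ms]."""
    net = pd.Series(0.0, index=g.nodes.index)
    q = field.q
    for vid, row in zip(g.vessels.index, g.vessels[["source", "target"]].to_numpy()):
        net[int(row[0])] -= q.loc[vid]
        net[int(row[1])] += q.loc[vid]
    interior = ~g.nodes["is_boundary"].astype(bool)
    return net[interior]


def boundary_inflow(g: MVNGraph, field: FlowField) -> float:
    """Total flow entering the domain through boundary nodes [um^3/ms]."""
    total = 0.0
    inc = g.incidence()
    for nid, row in g.nodes.iterrows():
        if not row["is_boundary"]:
            continue
        for vid, _ in inc[int(nid)]:
            vrow = g.vessels.loc[vid]
            qv = field.q.loc[vid]
            # flow leaving the boundary node into the network counts as inflow
            s = int(vrow["source"])
            signed = qv if s == int(nid) else -qv
            if signed > 0:
                total += signed
    return total


def reynolds_numbers(g: MVNGraph, field: FlowField, rho: float = 1050.0,
                     mu: float = MU_PLASMA) -> pd.Series:
    """Diagnostic Reynolds number per vessel (should be < 1 in the
    microvasculature)."""
    d_um = g.vessels["diameter"].to_numpy(dtype=float)
    area_um2 = np.pi * d_um ** 2 / 4.0
    v_um_ms = field.q.abs().to_numpy() / area_um2      # um/ms == mm/s
    v_m_s = v_um_ms * 1e-3
    d_m = d_um * 1e-6
    return pd.Series(rho * v_m_s * d_m / mu, index=g.vessels.index)


# ----------------------------------------------------- fixed-point steady mode

def propagate_hematocrit(g: MVNGraph, field: FlowField, hd_inflow: float,
                         hd_prev: pd.Series, q_eps: float = 1e-8,
                         hd_max: float = 0.95) -> pd.Series:
    """Propagate discharge hematocrit downstream through the solved flow field.

    Nodes are processed in order of decreasing pressure (the flow field is a
    potential flow, hence acyclic).  RBC flux entering a node is distributed
    to its outflow vessels: by the empirical phase-separation law at divergent
    bifurcations with parent diameter > 10 um, otherwise proportionally to
    bulk flow (the time-average of the single-file regime).  Stagnant vessels
    (|q| <= q_eps) keep their previous hematocrit -- their RBCs are trapped.
    """
    node_ids = g.nodes.index.to_numpy()
    pos_of = {int(n): i for i, n in enumerate(node_ids)}
    src = np.array([pos_of[int(s)] for s in g.vessels["source"]])
    tgt = np.array([pos_of[int(t)] for t in g.vessels["target"]])
    qv = field.q.to_numpy()
    diam = g.vessels["diameter"].to_numpy(dtype=float)
    hd_new = hd_prev.to_numpy(dtype=float).copy()
    is_b = g.nodes["is_boundary"].to_numpy(dtype=bool)
    p = field.pressure.to_numpy()

    # per-node incidence as (vessel row, signed-out flow) lists
    n = len(node_ids)
    inc_v: list[list[int]] = [[] for _ in range(n)]
    for i in range(len(qv)):
        inc_v[src[i]].append(i)
        inc_v[tgt[i]].append(i)
    order = np.argsort(-p, kind="stable")
    flux_in = np.zeros(n)

    for ni in order:
        outs: list[tuple[int, float]] = []
        parents: list[tuple[int, float]] = []
        for i in inc_v[ni]:
            signed = qv[i] if src[i] == ni else -qv[i]
            if signed > q_eps:
                outs.append((i, signed))
            elif signed < -q_eps:
                parents.append((i, -signed))
        if not outs:
            continue
        total_out = sum(qq for _, qq in outs)
        f_in = hd_inflow * total_out if is_b[ni] else flux_in[ni]
        if len(outs) == 2 and parents:
            ip = max(parents, key=lambda t: t[1])[0]
            d_parent = diam[ip]
        else:
            ip, d_parent = -1, 0.0
        if len(outs) == 2 and d_parent > 10.0:
            (i1, q1), (i2, q2) = outs
            frac1 = phase_separation_fraction(q1 / total_out, d_parent,
                                              diam[i1], diam[i2], hd_new[ip])
            split = (f_in * frac1, f_in * (1.0 - frac1))
        else:
            split = tuple(f_in * qq / total_out for _, qq in outs)
        for (i, qq), s_flux in zip(outs, split):
            h = min(s_flux / qq, hd_max)
            hd_new[i] = h
            down = tgt[i] if src[i] == ni else src[i]
            flux_in[down] += min(s_flux, h * qq)
    return pd.Series(hd_new, index=g.vessels.index)


def fixed_point_flow_hematocrit(g: MVNGraph, bc: BoundaryConditions,
                                tol: float = 1e-6, max_iter: int = 50,
                                mu: float = MU_PLASMA, q_eps: float = 1e-8,
                                phase_separation: bool = True,
                                damping: float = 0.5) -> FlowField:
    """Steady flow/hematocrit fixed point.

    Alternates a pressure/flow solve with downstream hematocrit propagation
    until the maximum relative flow change drops below ``tol``.  With
    ``phase_separation=False`` the hematocrit is held uniform at the inflow
    value and the loop terminates after one iteration.
    """
    hd = pd.Series(bc.hd_inflow, index=g.vessels.index, dtype=float)
    field = solve_pressure_flow(g, hd, bc, mu=mu)
    if not phase_separation:
        field.converged = True
        field.n_iterations = 1
        return field
    prev_q = field.q.to_numpy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        hd_new = propagate_hematocrit(g, field, bc.hd_inflow, hd, q_eps=q_eps)
        hd = damping * hd + (1.0 - damping) * hd_new
        field = solve_pressure_flow(g, hd, bc, mu=mu)
        qn = field.q.to_numpy()
        # relative change, floored at 1% of the median perfused flow so that
        # numerically stagnant vessels cannot dominate the criterion
        absq = np.abs(prev_q)
        floor = max(0.01 * np.median(absq[absq > q_eps]) if (absq > q_eps).any()
                    else q_eps, q_eps)
        delta = np.max(np.abs(qn - prev_q) / np.maximum(absq, floor))
        prev_q = qn
        if delta < tol:
            converged = True
            break
    field.converged = converged
    field.n_iterations = it + 1
    return field
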