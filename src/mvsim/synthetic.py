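"""Synthetic microvascular networks.

Two families of generators:

* :func:`generate_lattice_mvn` -- a jittered, randomly diluted 3-D capillary
  lattice with penetrating arteriole/venule trees (main branch + offshoots),
  boundary stubs on the cut faces and pressure boundary conditions.  The
  defaults are calibrated to emulate the statistical structure of cortical
  capillary beds: diameters ~4-10 um, lengths ~40-80 um, tortuous
  centerlines, heterogeneous flow with a median of order 2 um^3/ms, and all
  four local bifurcation topologies (2-in-2-out ... 1-in-1-out) present.
* :func:`make_msc_motif` / :func:`special_gen1_fixture` -- minimal motif
  networks realizing each microstroke-capillary (MSC) type, used as exactly
  analyzable fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import MVNGraph
from .hemodynamics import BoundaryConditions
from .units import MMHG_TO_PA

MSC_TYPES = ("2-2", "2-1", "1-2", "1-1")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic lattice generator (lengths in um)."""
    nx: int = 10
    ny: int = 10
    nz: int = 10
    spacing: float = 34.0
    jitter: float = 0.06              # node jitter, fraction of spacing
    mean_degree: float = 3.0          # average interior node degree after dilution
    cap_diameter_mean: float = 5.0
    cap_diameter_cv: float = 0.2
    cap_length_mean: float = 62.0
    cap_length_cv: float = 0.2
    n_da_trees: int = 2
    n_av_trees: int = 2
    offshoots_per_trunk_node: int = 2
    stub_fraction: float = 0.4        # fraction of face nodes with boundary stubs
    p_da_root_mmhg: float = 60.0
    p_av_root_mmhg: float = 15.0
    # boundary stubs on the cut faces sit in the capillary pressure range;
    # interpolated between these by topological distance to the DA/AV trees
    p_stub_high_mmhg: float = 36.0
    p_stub_low_mmhg: float = 32.0
    stub_pressure_noise_mmhg: float = 0.5
    # pial feeding segment: lumped resistance standing in for the unresolved
    # upstream vasculature (the realistic hierarchical boundary pressures)
    feeder_diameter: float = 6.0
    feeder_length: float = 300.0
    hd_inflow: float = 0.3
    z_surface_gap: float = 40.0       # depth of the lattice top below the surface
    seed: int = 0

    def validate(self) -> None:
        if min(self.nx, self.ny, self.nz) < 3:
            raise ValueError("lattice must be at least 3 x 3 x 3")
        for name in ("spacing", "cap_diameter_mean", "cap_length_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.hd_inflow < 1.0:
            raise ValueError("hd_inflow must be in [0, 1)")


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log(1.0 + cv * cv)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def sample_capillary_diameters(cfg: GeneratorConfig, n: int,
                               rng: np.random.Generator) -> np.ndarray:
    mu, sigma = _lognormal_params(cfg.cap_diameter_mean, cfg.cap_diameter_cv)
    return rng.lognormal(mu, sigma, size=n)


def sample_capillary_lengths(cfg: GeneratorConfig, n: int,
                             rng: np.random.Generator) -> np.ndarray:
    mu, sigma = _lognormal_params(cfg.cap_length_mean, cfg.cap_length_cv)
    return rng.lognormal(mu, sigma, size=n)


def _tortuous_centerline(p0: np.ndarray, p1: np.ndarray, length: float,
                         n_pts: int = 9) -> np.ndarray:
    """Polyline from p0 to p1 whose arc length matches ``length``.

    A single perpendicular sine bump is scaled until the polyline arc length
    equals the requested length (bisection).
    """
    chord = p1 - p0
    c = float(np.linalg.norm(chord))
    t = np.linspace(0.0, 1.0, n_pts)
    base = p0[None, :] + t[:, None] * chord[None, :]
    if length <= c * (1 + 1e-9):
        return np.stack([p0, p1])
    # perpendicular unit vector (deterministic)
    ref = np.array([0.0, 0.0, 1.0]) if abs(chord[2]) < 0.9 * c \
        else np.array([1.0, 0.0, 0.0])
    perp = np.cross(chord, ref)
    perp /= np.linalg.norm(perp)
    bump = np.sin(np.pi * t)[:, None] * perp[None, :]

    def arclen(a: float) -> float:
        line = base + a * bump
        return float(np.linalg.norm(np.diff(line, axis=0), axis=1).sum())

    lo, hi = 0.0, c
    while arclen(hi) < length:
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if arclen(mid) < length:
            lo = mid
        else:
            hi = mid
    return base + 0.5 * (lo + hi) * bump


class _UnionFind:
    def __init__(self, n: int):
        self.p = list(range(n))

    def find(self, a: int) -> int:
        while self.p[a] != a:
            self.p[a] = self.p[self.p[a]]
            a = self.p[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.p[ra] = rb
        return True


class GenerationError(RuntimeError):
    pass


def generate_lattice_mvn(cfg: GeneratorConfig) -> tuple[MVNGraph, BoundaryConditions]:
    """Generate a synthetic MVN; the seed fully determines the output."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    s = cfg.spacing
    nx, ny, nz = cfg.nx, cfg.ny, cfg.nz

    # --- lattice nodes -----------------------------------------------------
    def nid(i: int, j: int, k: int) -> int:
        return (i * ny + j) * nz + k

    n_lat = nx * ny * nz
    coords = np.zeros((n_lat, 3))
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                coords[nid(i, j, k)] = (i * s, j * s, cfg.z_surface_gap + k * s)
    coords += rng.uniform(-cfg.jitter * s, cfg.jitter * s, size=coords.shape)

    # --- lattice edges: spanning tree + random fill to target degree -------
    all_edges: list[tuple[int, int]] = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                a = nid(i, j, k)
                if i + 1 < nx:
                    all_edges.append((a, nid(i + 1, j, k)))
                if j + 1 < ny:
                    all_edges.append((a, nid(i, j + 1, k)))
                if k + 1 < nz:
                    all_edges.append((a, nid(i, j, k + 1)))
    order = rng.permutation(len(all_edges))
    uf = _UnionFind(n_lat)
    tree_edges, rest = [], []
    for idx in order:
        e = all_edges[idx]
        (tree_edges if uf.union(*e) else rest).append(e)
    # fill toward degree-3 bifurcation nodes: a random spanning tree keeps the
    # bed connected; extra edges are added preferentially where the degree is
    # still below the target, capping it at mean_degree + 1
    deg = np.zeros(n_lat, dtype=int)
    for a, b in tree_edges:
        deg[a] += 1
        deg[b] += 1
    target = int(round(cfg.mean_degree))
    lattice_edges = list(tree_edges)
    remaining = []
    for e in rest:
        a, b = e
        if deg[a] < target and deg[b] < target:
            lattice_edges.append(e)
            deg[a] += 1
            deg[b] += 1
        else:
            remaining.append(e)
    for a, b in remaining:
        if (deg[a] < target or deg[b] < target) and max(deg[a], deg[b]) <= target:
            lattice_edges.append((a, b))
            deg[a] += 1
            deg[b] += 1
    lattice_edges.sort()

    nodes_rows: list[tuple[int, float, float, float, bool]] = [
        (i, coords[i, 0], coords[i, 1], coords[i, 2], False) for i in range(n_lat)]
    next_node = n_lat
    vessels_rows: list[dict] = []
    centerlines: dict[int, np.ndarray] = {}
    next_vid = 0

    def add_node(x: float, y: float, z: float, boundary: bool) -> int:
        nonlocal next_node
        nodes_rows.append((next_node, x, y, z, boundary))
        next_node += 1
        return next_node - 1

    def add_vessel(a: int, b: int, diameter: float, length: float | None,
                   vtype: str, main_branch: bool = False,
                   centerline: np.ndarray | None = None) -> int:
        nonlocal next_vid
        pa = np.array(nodes_rows[a][1:4])
        pb = np.array(nodes_rows[b][1:4])
        chord = float(np.linalg.norm(pb - pa))
        L = max(length if length is not None else chord, chord * (1 + 1e-9))
        vessels_rows.append(dict(id=next_vid, source=a, target=b, diameter=diameter,
                                 length=L, type=vtype, main_branch=main_branch))
        if centerline is not None:
            centerlines[next_vid] = centerline
        elif L > chord * 1.001:
            centerlines[next_vid] = _tortuous_centerline(pa, pb, L)
        next_vid += 1
        return next_vid - 1

    # --- capillaries -------------------------------------------------------
    diams = sample_capillary_diameters(cfg, len(lattice_edges), rng)
    lens = sample_capillary_lengths(cfg, len(lattice_edges), rng)
    for (a, b), d, L in zip(lattice_edges, diams, lens):
        add_vessel(a, b, float(d), float(L), "C")

    # --- boundary stubs on cut faces ---------------------------------------
    stub_len = 25.0
    face_nodes: list[tuple[int, np.ndarray]] = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                normal = None
                if i == 0:
                    normal = np.array([-1.0, 0.0, 0.0])
                elif i == nx - 1:
                    normal = np.array([1.0, 0.0, 0.0])
                elif j == 0:
                    normal = np.array([0.0, -1.0, 0.0])
                elif j == ny - 1:
                    normal = np.array([0.0, 1.0, 0.0])
                elif k == nz - 1:
                    normal = np.array([0.0, 0.0, 1.0])
                if normal is not None:
                    face_nodes.append((nid(i, j, k), normal))
    stub_nodes: list[int] = []
    for node, normal in face_nodes:
        if rng.random() >= cfg.stub_fraction:
            continue
        p = coords[node] + normal * stub_len
        b = add_node(p[0], p[1], p[2], True)
        d = float(sample_capillary_diameters(cfg, 1, rng)[0])
        add_vessel(node, b, d, None, "C")
        stub_nodes.append(b)

    # --- penetrating trees --------------------------------------------------
    def build_tree(kind: str, root_xy: np.ndarray,
                   d_top: float, d_bottom: float, d_off: tuple[float, float]):
        trunk_depth = cfg.z_surface_gap + 0.75 * (nz - 1) * s
        n_trunk = max(3, int(round(trunk_depth / s)))
        zs = np.linspace(0.0, trunk_depth, n_trunk + 1)
        trunk_nodes = []
        for z in zs:
            xy = root_xy + rng.uniform(-2.0, 2.0, size=2)
            trunk_nodes.append(add_node(xy[0], xy[1], float(z), False))
        # pial feeding segment + boundary root (lumped feeding resistance)
        broot = add_node(root_xy[0] + 60.0, root_xy[1], 0.0, True)
        add_vessel(broot, trunk_nodes[0], cfg.feeder_diameter,
                   cfg.feeder_length, "PA" if kind == "DA" else "PV")
        dtrunk = np.linspace(d_top, d_bottom, n_trunk)
        for t in range(n_trunk):
            add_vessel(trunk_nodes[t], trunk_nodes[t + 1], float(dtrunk[t]),
                       None, kind, main_branch=True)
        # offshoots from trunk nodes below the surface to nearby lattice nodes
        attach_nodes = []
        for t in range(1, n_trunk + 1):
            p = np.array(nodes_rows[trunk_nodes[t]][1:4])
            dist = np.linalg.norm(coords - p[None, :], axis=1)
            near = np.argsort(dist)
            n_off = 0
            for cand in near:
                if dist[cand] > 2.0 * s or n_off >= cfg.offshoots_per_trunk_node:
                    break
                if cand in used_attach:
                    continue
                d = float(rng.uniform(*d_off))
                add_vessel(trunk_nodes[t], int(cand), d, None, kind)
                used_attach.add(int(cand))
                attach_nodes.append(int(cand))
                n_off += 1
        return broot, attach_nodes

    used_attach: set[int] = set()
    span_x, span_y = (nx - 1) * s, (ny - 1) * s
    margin = min(1.5 * s, 0.3 * min(span_x, span_y))
    da_roots, av_roots = [], []
    da_attach: list[int] = []
    av_attach: list[int] = []
    for _ in range(cfg.n_da_trees):
        xy = rng.uniform([margin, margin], [span_x - margin, span_y - margin])
        root, attach = build_tree("DA", xy, 12.0, 7.0, (6.5, 7.5))
        da_roots.append(root)
        da_attach.extend(attach)
    for _ in range(cfg.n_av_trees):
        xy = rng.uniform([margin, margin], [span_x - margin, span_y - margin])
        root, attach = build_tree("AV", xy, 16.0, 9.0, (7.0, 8.5))
        av_roots.append(root)
        av_attach.extend(attach)
    if not da_attach or not av_attach:
        raise GenerationError("penetrating trees failed to attach to the lattice")

    # --- assemble graph -----------------------------------------------------
    nodes = pd.DataFrame(nodes_rows, columns=["id", "x", "y", "z", "is_boundary"]
                         ).set_index("id")
    vessels = pd.DataFrame(vessels_rows).set_index("id")
    g = MVNGraph(nodes, vessels, centerlines)

    # --- boundary pressures -------------------------------------------------
    from collections import deque
    inc = g.incidence()

    def hop_distances(sources: list[int]) -> dict[int, int]:
        dist = {int(v): 0 for v in sources}
        dq = deque(sources)
        while dq:
            n = dq.popleft()
            for _, other in inc[n]:
                if other not in dist:
                    dist[other] = dist[n] + 1
                    dq.append(other)
        return dist

    d_da = hop_distances(da_attach)
    d_av = hop_distances(av_attach)
    p_hi, p_lo = cfg.p_stub_high_mmhg, cfg.p_stub_low_mmhg
    pressures: dict[int, float] = {}
    for root in da_roots:
        pressures[root] = cfg.p_da_root_mmhg * MMHG_TO_PA
    for root in av_roots:
        pressures[root] = cfg.p_av_root_mmhg * MMHG_TO_PA
    for b in stub_nodes:
        dd = d_da.get(b, 50)
        da_ = d_av.get(b, 50)
        lam = da_ / max(dd + da_, 1)
        p = p_lo + (p_hi - p_lo) * lam
        p += rng.normal(0.0, cfg.stub_pressure_noise_mmhg)
        pressures[b] = float(np.clip(p, cfg.p_av_root_mmhg + 1.0,
                                     cfg.p_da_root_mmhg - 1.0)) * MMHG_TO_PA
    bc = BoundaryConditions(pressures, cfg.hd_inflow)
    return g, bc


# ------------------------------------------------------------------- motifs

@dataclass
class MotifSpec:
    """Request for a minimal MSC-motif network."""
    msc_type: str = "2-2"

    def validate(self) -> None:
        if self.msc_type not in MSC_TYPES:
            raise ValueError(f"msc_type must be one of {MSC_TYPES}")


def _motif_graph(nodes: dict[str, tuple[float, float, float, bool]],
                 edges: list[tuple[str, str, float, float]],
                 p_in_mmhg: float, p_out_mmhg: float, hd: float,
                 inlet: str, outlet: str,
                 msc_edge: tuple[str, str]) -> tuple[MVNGraph, BoundaryConditions, int]:
    names = list(nodes)
    idx = {nm: i for i, nm in enumerate(names)}
    ndf = pd.DataFrame(
        [(i, *nodes[nm]) for nm, i in idx.items()],
        columns=["id", "x", "y", "z", "is_boundary"]).set_index("id")
    rows = []
    msc_id = -1
    for vid, (a, b, d, L) in enumerate(edges):
        pa = np.array(nodes[a][:3])
        pb = np.array(nodes[b][:3])
        chord = float(np.linalg.norm(pb - pa))
        rows.append(dict(id=vid, source=idx[a], target=idx[b], diameter=d,
                         length=max(L, chord * (1 + 1e-9)), type="C",
                         main_branch=False))
        if (a, b) == msc_edge:
            msc_id = vid
    vdf = pd.DataFrame(rows).set_index("id")
    g = MVNGraph(ndf, vdf)
    bc = BoundaryConditions.from_mmhg({idx[inlet]: p_in_mmhg,
                                       idx[outlet]: p_out_mmhg}, hd)
    return g, bc, msc_id


def make_msc_motif(spec: MotifSpec, hd: float = 0.3
                   ) -> tuple[MVNGraph, BoundaryConditions, int]:
    """Build a <= 40-vessel network whose central capillary realizes the
    requested MSC type under the solved baseline flow.

    Every motif contains at least one path parallel to the central capillary,
    so occluding it never disconnects the bed.  Returns
    ``(graph, boundary conditions, msc vessel id)``.
    """
    spec.validate()
    z = 300.0
    D, Df, Dt = 5.0, 8.0, 4.0  # capillary / feeder / thin-bypass diameters
    L = 60.0

    if spec.msc_type == "2-2":
        nodes = {
            "I0": (-260.0, 0.0, z, True), "I": (-200.0, 0.0, z, False),
            "S1": (-140.0, 45.0, z, False), "S2": (-140.0, -45.0, z, False),
            "A": (-80.0, 0.0, z, False), "B": (-20.0, 0.0, z, False),
            "T1": (40.0, 45.0, z, False), "T2": (40.0, -45.0, z, False),
            "E": (100.0, 0.0, z, False), "O": (160.0, 0.0, z, True),
        }
        edges = [
            ("I0", "I", Df, 60.0), ("I", "S1", Df, 80.0), ("I", "S2", Df, 80.0),
            ("S1", "A", D, 80.0), ("S2", "A", D, 80.0),
            ("A", "B", D, L),
            ("B", "T1", D, 80.0), ("B", "T2", D, 80.0),
            ("T1", "E", D, 80.0), ("T2", "E", D, 80.0),
            ("E", "O", Df, 60.0),
            ("S1", "T1", Dt, 220.0),   # thin parallel path
        ]
        return _motif_graph(nodes, edges, 30.0, 25.0, hd, "I0", "O", ("A", "B"))

    if spec.msc_type == "2-1":
        nodes = {
            "I0": (-260.0, 0.0, z, True), "I": (-200.0, 0.0, z, False),
            "S1": (-140.0, 45.0, z, False), "S2": (-140.0, -45.0, z, False),
            "A": (-80.0, 0.0, z, False), "B": (-20.0, 0.0, z, False),
            "P2": (-80.0, -90.0, z, False),
            "T1": (40.0, 0.0, z, False), "O": (160.0, 0.0, z, True),
        }
        edges = [
            ("I0", "I", Df, 60.0), ("I", "S1", Df, 80.0), ("I", "S2", Df, 80.0),
            ("S1", "A", D, 80.0), ("S2", "A", D, 80.0),
            ("A", "B", D, L),
            ("S2", "P2", Dt, 140.0), ("P2", "B", D, 80.0),  # second inflow at B
            ("B", "T1", Df, 80.0), ("T1", "O", Df, 120.0),
        ]
        return _motif_graph(nodes, edges, 30.0, 25.0, hd, "I0", "O", ("A", "B"))

    if spec.msc_type == "1-2":
        nodes = {
            "I0": (-260.0, 0.0, z, True), "S1": (-140.0, 0.0, z, False),
            "A": (-80.0, 0.0, z, False), "B": (-20.0, 0.0, z, False),
            "P1": (-20.0, 90.0, z, False),
            "T1": (40.0, 45.0, z, False), "T2": (40.0, -45.0, z, False),
            "E": (100.0, 0.0, z, False), "O": (160.0, 0.0, z, True),
        }
        edges = [
            ("I0", "S1", Df, 120.0), ("S1", "A", Df, 80.0),
            ("A", "B", D, L),
            ("A", "P1", D, 110.0), ("P1", "T1", Dt, 140.0),  # divergent sibling
            ("B", "T1", D, 80.0), ("B", "T2", D, 80.0),
            ("T1", "E", D, 80.0), ("T2", "E", D, 80.0),
            ("E", "O", Df, 60.0),
        ]
        return _motif_graph(nodes, edges, 30.0, 25.0, hd, "I0", "O", ("A", "B"))

    # 1-1
    nodes = {
        "I0": (-260.0, 0.0, z, True), "S1": (-140.0, 0.0, z, False),
        "A": (-80.0, 0.0, z, False), "B": (-20.0, 0.0, z, False),
        "P1": (-80.0, 90.0, z, False), "P2": (-20.0, 90.0, z, False),
        "T1": (40.0, 0.0, z, False), "O": (160.0, 0.0, z, True),
    }
    edges = [
        ("I0", "S1", Df, 120.0), ("S1", "A", Df, 80.0),
        ("A", "B", D, L),
        ("A", "P1", D, 95.0), ("P1", "P2", D, 70.0), ("P2", "B", D, 95.0),
        ("B", "T1", Df, 80.0), ("T1", "O", Df, 120.0),
    ]
    return _motif_graph(nodes, edges, 30.0, 25.0, hd, "I0", "O", ("A", "B"))


def special_gen1_fixture(hd: float = 0.3) -> tuple[MVNGraph, BoundaryConditions, int]:
    """Degenerate 2-in-2-out topology whose occlusion causes *cessation*.

    Both generation -1 vessels spring from the same generation -2 node and
    both generation +1 vessels merge into the same generation +2 node, so
    after occlusion neither side can sustain a reversal: flow in all four
    generation +-1 vessels stops and the inflow re-routes through the
    parallel path.
    """
    z = 300.0
    D, Df, Dt = 5.0, 8.0, 4.0
    nodes = {
        "I0": (-260.0, 0.0, z, True), "S": (-150.0, 0.0, z, False),
        "A": (-80.0, 0.0, z, False), "B": (-20.0, 0.0, z, False),
        "T": (50.0, 0.0, z, False), "O": (160.0, 0.0, z, True),
    }
    edges = [
        ("I0", "S", Df, 110.0),
        ("S", "A", D, 90.0), ("S", "A", D, 100.0),   # shared generation -2 node
        ("A", "B", D, 60.0),
        ("B", "T", D, 90.0), ("B", "T", D, 100.0),   # shared generation +2 node
        ("T", "O", Df, 110.0),
        ("S", "T", Dt, 260.0),                       # parallel path
    ]
    names = list(nodes)
    idx = {nm: i for i, nm in enumerate(names)}
    ndf = pd.DataFrame([(i, *nodes[nm]) for nm, i in idx.items()],
                       columns=["id", "x", "y", "z", "is_boundary"]).set_index("id")
    rows = []
    msc_id = -1
    for vid, (a, b, d, L) in enumerate(edges):
        pa, pb = np.array(nodes[a][:3]), np.array(nodes[b][:3])
        chord = float(np.linalg.norm(pb - pa))
        rows.append(dict(id=vid, source=idx[a], target=idx[b], diameter=d,
                         length=max(L, chord * (1 + 1e-9)), type="C",
                         main_branch=False))
        if (a, b) == ("A", "B"):
            msc_id = vid
    vdf = pd.DataFrame(rows).set_index("id")
    g = MVNGraph(ndf, vdf)
    bc = BoundaryConditions.from_mmhg({idx["I0"]: 30.0, idx["O"]: 25.0}, hd)
    return g, bc, msc_id
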