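import numpy as np
import pandas as pd
import pytest

from mvsim.graph import MVNGraph
from mvsim.hemodynamics import fixed_point_flow_hematocrit
from mvsim.rbc import steady_to_average
from mvsim.synthetic import (GeneratorConfig, MotifSpec, generate_lattice_mvn,
                             make_msc_motif)


def simple_graph(edges, positions, boundary=(), diameters=None, lengths=None,
                 types=None):
    """Small-graph builder for hand-constructed fixtures.

    ``edges``: list of (source, target); ``positions``: {node: (x, y, z)}.
    """
    nids = sorted(positions)
    nodes = pd.DataFrame(
        [(n, *positions[n], n in set(boundary)) for n in nids],
        columns=["id", "x", "y", "z", "is_boundary"]).set_index("id")
    rows = []
    for i, (s, t) in enumerate(edges):
        d = diameters[i] if diameters is not None else 5.0
        p0, p1 = np.array(positions[s]), np.array(positions[t])
        chord = float(np.linalg.norm(p1 - p0))
        ln = lengths[i] if lengths is not None else max(chord, 1.0)
        rows.append(dict(id=i, source=s, target=t, diameter=d,
                         length=max(ln, chord * (1 + 1e-12)),
                         type=types[i] if types is not None else "C",
                         main_branch=False))
    vessels = pd.DataFrame(rows).set_index("id")
    return MVNGraph(nodes, vessels)


@pytest.fixture(scope="session")
def lattice():
    """Default 10x10x10 synthetic network with its boundary conditions."""
    return generate_lattice_mvn(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def lattice_baseline(lattice):
    g, bc = lattice
    return steady_to_average(fixed_point_flow_hematocrit(g, bc))


@pytest.fixture(scope="session")
def lattice_selection(lattice, lattice_baseline):
    from mvsim.stroke import select_msc_candidates
    g, _ = lattice
    return select_msc_candidates(g, lattice_baseline)


@pytest.fixture(scope="session")
def motifs():
    """All four MSC motifs with their solved steady baselines."""
    out = {}
    for t in ("2-2", "2-1", "1-2", "1-1"):
        g, bc, msc = make_msc_motif(MotifSpec(t))
        field = fixed_point_flow_hematocrit(g, bc)
        out[t] = (g, bc, msc, field)
    return out
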