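"""Local topology: classification, generations, boxes, categories, tissue grid."""

import numpy as np
import pandas as pd
import pytest

from mvsim.hemodynamics import (BoundaryConditions, boundary_inflow,
                                fixed_point_flow_hematocrit,
                                solve_pressure_flow)
from mvsim.stroke import occlude
from mvsim.synthetic import MotifSpec, make_msc_motif
from mvsim.topology import (AnalysisBox, box_inflow, box_inflow_difference,
                            box_total_flow, box_total_flow_difference,
                            categorize_box_vessels, classify_msc_type,
                            clipped_centerline_length, count_flow_decrease,
                            generations, grow_box, msc_analysis_box,
                            supplied_tissue_volume, vessels_in_box)
from mvsim.units import NL_TO_UM3

from conftest import simple_graph


# ------------------------------------------------------------ classification

def test_reversing_all_pressures_preserves_2in2out(motifs):
    g, bc, msc, field = motifs["2-2"]
    assert classify_msc_type(g, field, msc) == "2-2"
    swapped = BoundaryConditions(
        dict(zip(bc.pressures, reversed(list(bc.pressures.values())))),
        bc.hd_inflow)
    f2 = fixed_point_flow_hematocrit(g, swapped)
    assert classify_msc_type(g, f2, msc) == "2-2"


def test_degree_two_endpoint_is_unclassifiable():
    pos = {i: (i * 50.0, 0, 0) for i in range(4)}
    g = simple_graph([(0, 1), (1, 2), (2, 3)], pos, boundary=(0, 3))
    f = solve_pressure_flow(g, 0.3, BoundaryConditions({0: 100.0, 3: 0.0}))
    assert classify_msc_type(g, f, 1) is None


def test_stagnant_incident_vessel_is_unclassifiable(motifs):
    g, bc, msc, field = motifs["2-2"]
    f = field
    zeroed = f.q.copy()
    gm = generations(g, f, msc)
    zeroed.loc[gm.at(-1)[0]] = 0.0
    f2 = type(f)(f.pressure, zeroed, f.hd, f.ht, f.rbc_flux)
    assert classify_msc_type(g, f2, msc) is None


# --------------------------------------------------------------- generations

def test_chain_generations_minus5_to_plus5():
    n = 12
    pos = {i: (i * 50.0, 0, 0) for i in range(n)}
    g = simple_graph([(i, i + 1) for i in range(n - 1)], pos, boundary=(0, n - 1))
    f = solve_pressure_flow(g, 0.3, BoundaryConditions({0: 1000.0, n - 1: 0.0}))
    gm = generations(g, f, 5, depth=5)
    for k in range(1, 6):
        assert gm.at(-k) == [5 - k]
        assert gm.at(k) == [5 + k]


@pytest.mark.parametrize("mt,n1", [("2-2", 2), ("1-1", 1)])
def test_motif_generation_one_counts(mt, n1, motifs):
    g, bc, msc, field = motifs[mt]
    gm = generations(g, field, msc)
    assert len(gm.at(-1)) == n1
    assert len(gm.at(1)) == n1


# ----------------------------------------------------------------- grow box

def test_initial_02nl_box_is_a_5848um_cube():
    side = (0.2 * NL_TO_UM3) ** (1 / 3)
    assert side == pytest.approx(58.48, abs=0.005)
    b = np.array([[0.0, side]] * 3)
    grown = grow_box(b, 0.4 * NL_TO_UM3)
    new_side = grown.bounds[0, 1] - grown.bounds[0, 0]
    assert new_side == pytest.approx((0.4 * NL_TO_UM3) ** (1 / 3), rel=1e-6)
    assert new_side == pytest.approx(73.68, abs=0.005)


def test_grow_box_noop_when_target_equals_initial():
    b = np.array([[0, 50.0], [0, 100.0], [0, 40.0]])
    grown = grow_box(b, 50.0 * 100.0 * 40.0)
    np.testing.assert_allclose(grown.bounds, b)


def test_grow_box_rejects_shrinking():
    b = np.array([[0, 50.0], [0, 100.0], [0, 40.0]])
    with pytest.raises(ValueError):
        grow_box(b, 1000.0)


def _bisect_delta(sides, target):
    lo, hi = 0.0, target ** (1 / 3) + max(sides)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.prod(np.asarray(sides) + mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def test_grow_box_matches_bisection_oracle_on_random_draws():
    rng = np.random.default_rng(17)
    for _ in range(1000):
        sides = rng.uniform(10.0, 150.0, size=3)
        v0 = float(np.prod(sides))
        target = v0 * float(rng.uniform(1.0, 30.0))
        b = np.stack([np.zeros(3), sides], axis=1)
        grown = grow_box(b, target)
        delta = (grown.bounds[0, 1] - grown.bounds[0, 0]) - sides[0]
        assert delta == pytest.approx(_bisect_delta(sides, target),
                                      rel=1e-6, abs=1e-9)
        assert grown.volume == pytest.approx(target, rel=1e-6)


# ------------------------------------------------------------- box metrics

def test_clipped_length_of_half_inside_segment():
    g = simple_graph([(0, 1)], {0: (0, 0, 0), 1: (100, 0, 0)}, lengths=[100.0])
    box = AnalysisBox(np.array([[50.0, 200.0], [-10, 10], [-10, 10]]))
    assert clipped_centerline_length(g, 0, box) == pytest.approx(50.0)


def test_identical_fields_give_zero_differences(motifs):
    g, bc, msc, field = motifs["2-2"]
    box = msc_analysis_box(g, msc)
    assert box_inflow_difference(g, field, field, box) == pytest.approx(0.0)
    assert box_total_flow_difference(g, field, field, box) == pytest.approx(0.0)
    assert count_flow_decrease(g, field, field, box) == 0


def test_box_cutting_only_boundary_stubs_sees_total_inflow(motifs):
    g, bc, msc, field = motifs["2-2"]
    # every interior vessel is inside; only the two boundary stubs cross
    box = AnalysisBox(np.array([[-230.0, 130.0], [-200, 200], [100, 500.0]]))
    assert box_inflow(g, field, box) == pytest.approx(
        boundary_inflow(g, field), rel=1e-9)
    stroke = fixed_point_flow_hematocrit(occlude(g, [msc]), bc)
    expected = (boundary_inflow(g, stroke) - boundary_inflow(g, field)) \
        / boundary_inflow(g, field)
    assert box_inflow_difference(g, field, stroke, box) == pytest.approx(
        expected, rel=1e-9)


def test_occlusion_reduces_box_inflow_on_2in2out(motifs):
    g, bc, msc, field = motifs["2-2"]
    stroke = fixed_point_flow_hematocrit(occlude(g, [msc]), bc)
    box = msc_analysis_box(g, msc)
    diff = box_inflow_difference(g, field, stroke, box)
    assert diff is not None and diff < 0


def test_count_flow_decrease_matches_hand_tally(motifs):
    g, bc, msc, field = motifs["2-2"]
    stroke = fixed_point_flow_hematocrit(occlude(g, [msc]), bc)
    box = msc_analysis_box(g, msc, volume_nl=0.4)
    expected = sum(
        1 for v in vessels_in_box(g, box) if v != msc
        and abs(float(stroke.q.loc[v])) < abs(float(field.q.loc[v])) - 1e-12)
    assert count_flow_decrease(g, field, stroke, box, exclude={msc}) == expected


def test_box_translation_invariance(motifs):
    g, bc, msc, field = motifs["2-2"]
    box = msc_analysis_box(g, msc)
    shift = np.array([37.0, -12.0, 5.0])
    g2 = g.copy()
    g2.nodes[["x", "y", "z"]] += shift
    g2.centerlines = {k: v + shift for k, v in g.centerlines.items()}
    box2 = AnalysisBox(box.bounds + shift[:, None])
    assert box_inflow(g2, field, box2) == pytest.approx(
        box_inflow(g, field, box), rel=1e-9)


# ---------------------------------------------------------------- categories

def test_categories_partition_the_box(motifs):
    for mt, (g, bc, msc, field) in motifs.items():
        box = msc_analysis_box(g, msc, volume_nl=0.5)
        cats = categorize_box_vessels(g, field, msc, box)
        in_box = set(vessels_in_box(g, box))
        assert cats.updown | cats.parallel | cats.distant == in_box
        assert not (cats.updown & cats.parallel)
        assert not (cats.updown & cats.distant)
        assert not (cats.parallel & cats.distant)


def test_bypass_is_categorized_parallel(motifs):
    g, bc, msc, field = motifs["2-2"]
    box = AnalysisBox(np.stack([g.positions().min(0) - 50,
                                g.positions().max(0) + 50], axis=1))
    cats = categorize_box_vessels(g, field, msc, box)
    assert 11 in cats.parallel          # the thin S1 -> T1 bypass vessel


def test_tight_box_has_no_distant_vessels(motifs):
    g, bc, msc, field = motifs["2-2"]
    box = msc_analysis_box(g, msc, volume_nl=0.2)
    cats = categorize_box_vessels(g, field, msc, box)
    assert not cats.distant


# --------------------------------------------------------------- tissue grid

def test_tissue_grid_partitions_exactly(motifs):
    g, _, _, _ = motifs["1-1"]
    tg = supplied_tissue_volume(g, cell_size=8.0)
    assert tg.supplied_volume.sum() == pytest.approx(tg.total_volume)


def test_two_symmetric_vessels_split_the_slab_equally():
    pos = {0: (0, 30, 0), 1: (100, 30, 0), 2: (0, -30, 0), 3: (100, -30, 0)}
    g = simple_graph([(0, 1), (2, 3)], pos, lengths=[100.0, 100.0])
    tg = supplied_tissue_volume(g, cell_size=4.0,
                                bounds=np.array([[0, 100.0], [-60, 60.0],
                                                 [-20, 20.0]]))
    v = tg.supplied_volume
    assert v.loc[0] == v.loc[1]
    assert v.loc[0] > 0


def test_single_vessel_supplies_whole_grid():
    g = simple_graph([(0, 1)], {0: (0, 0, 0), 1: (100, 0, 0)}, lengths=[100.0])
    tg = supplied_tissue_volume(g, cell_size=4.0)
    assert tg.supplied_volume.loc[0] == pytest.approx(tg.total_volume)
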