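"""AV-factor computation and arteriole/venule proximity scans."""

import numpy as np
import pandas as pd
import pytest

from mvsim.avfactor import (AVFactorMap, compute_av_factor, cube_scan,
                            discretize, discretize_vessel, distance_maps,
                            sphere_scan)
from mvsim.hemodynamics import BoundaryConditions, solve_pressure_flow

from conftest import simple_graph


# ---------------------------------------------------------------- discretize

def test_straight_13um_vessel_gives_11_points():
    g = simple_graph([(0, 1)], {0: (0, 0, 0), 1: (13, 0, 0)}, lengths=[13.0])
    pts = discretize_vessel(g, 0, spacing=1.3)
    assert len(pts) == 11
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    np.testing.assert_allclose(d, 1.3, rtol=1e-9)


def test_resampled_polyline_length_close_to_vessel_length(lattice):
    g, _ = lattice
    rng = np.random.default_rng(2)
    for vid in rng.choice(list(g.centerlines), size=20, replace=False):
        pts = discretize_vessel(g, int(vid), spacing=1.3)
        arclen = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        assert arclen == pytest.approx(g.vessels.loc[vid, "length"], rel=0.01)
        # consecutive spacing never exceeds the nominal value
        assert np.linalg.norm(np.diff(pts, axis=0), axis=1).max() <= 1.3 + 1e-9


def test_point_count_scales_with_network_length(lattice):
    g, _ = lattice
    pts, owner = discretize(g, spacing=1.3)
    expected = sum(int(np.ceil(L / 1.3)) + 1 for L in g.vessels["length"])
    assert len(pts) == expected == len(owner)


# ----------------------------------------------------------------- AV-factor

def _ladder():
    """Mirror-symmetric series-parallel fixture; middle vessel id = 4."""
    pos = {10: (-60, 0, 0), 0: (0, 0, 0), 1: (40, 30, 0), 2: (40, -30, 0),
           3: (80, 0, 0), 4: (130, 0, 0), 5: (170, 30, 0), 6: (170, -30, 0),
           7: (210, 0, 0), 11: (270, 0, 0)}
    edges = [(10, 0), (0, 1), (1, 3), (0, 2), (2, 3), (3, 4),
             (4, 5), (5, 7), (4, 6), (6, 7), (7, 11)]
    lengths = [60.0, 50.0, 90.0, 110.0, 60.0, 50.0,
               90.0, 50.0, 60.0, 110.0, 60.0]
    g = simple_graph(edges, pos, boundary=(10, 11), lengths=lengths)
    bc = BoundaryConditions({10: 1000.0, 11: 0.0})
    f = solve_pressure_flow(g, 0.3, bc)
    return g, f


def test_mirror_symmetric_ladder_middle_is_half():
    g, f = _ladder()
    for mode in ("exact", "histogram"):
        avmap = compute_av_factor(g, f, mode=mode, bin_width=0.5,
                                  da_endpoints={0}, av_endpoints={7})
        assert avmap.av_factor.loc[5] == pytest.approx(0.5, abs=1e-6)


def test_medians_equal_brute_force_enumeration(motifs):
    g, bc, msc, field = motifs["2-2"]
    exact = compute_av_factor(g, field, mode="exact",
                              da_endpoints={1}, av_endpoints={8})
    hist = compute_av_factor(g, field, mode="histogram", bin_width=0.25,
                             da_endpoints={1}, av_endpoints={8})
    samp = compute_av_factor(g, field, mode="sample", n_samples=10_000, seed=1,
                             da_endpoints={1}, av_endpoints={8})
    mask = exact.assigned
    assert mask.sum() >= 5
    np.testing.assert_allclose(hist.av_factor[mask], exact.av_factor[mask],
                               atol=2e-3)
    np.testing.assert_allclose(samp.av_factor[mask], exact.av_factor[mask],
                               atol=2e-2)


def test_av_factor_in_unit_interval_and_assigned_only_on_paths(lattice,
                                                               lattice_baseline):
    g, _ = lattice
    avmap = compute_av_factor(g, lattice_baseline)
    vals = avmap.av_factor.dropna()
    assert len(vals) > 100
    assert ((vals >= 0) & (vals <= 1)).all()
    assert 0 < avmap.fraction_assigned() < 1


def test_monotone_increase_along_unbranched_chain():
    n = 8
    pos = {i: (i * 60.0, 0, 0) for i in range(n)}
    g = simple_graph([(i, i + 1) for i in range(n - 1)], pos,
                     boundary=(0, n - 1))
    f = solve_pressure_flow(g, 0.3, BoundaryConditions({0: 500.0, n - 1: 0.0}))
    avmap = compute_av_factor(g, f, mode="exact",
                              da_endpoints={1}, av_endpoints={n - 2})
    vals = avmap.av_factor.loc[1:n - 3].to_numpy()   # vessels between endpoints
    assert np.all(np.diff(vals) > 0)
    # capillary adjacent to the DA endpoint sits near 0
    assert vals[0] < 0.35


# ------------------------------------------------------------ distance maps

def _two_rails():
    pos = {0: (0, 0, 0), 1: (100, 0, 0), 2: (0, 20, 0), 3: (100, 20, 0)}
    g = simple_graph([(0, 1), (2, 3)], pos, lengths=[100.0, 100.0])
    factor = pd.Series([0.2, 0.7], index=[0, 1])
    avmap = AVFactorMap(factor, factor * 0, factor * 0, "manual")
    return g, avmap


def test_parallel_rails_distance_is_the_gap():
    g, avmap = _two_rails()
    df = distance_maps(g, avmap, spacing=1.0)
    # all points of the venule-sided rail are 20 um from the arteriole rail
    assert (df["vessel"] == 1).all()
    np.testing.assert_allclose(df["d_any"], 20.0)
    np.testing.assert_allclose(df["d_arteriole"], 20.0)
    np.testing.assert_allclose(df["distance_factor"], 1.0)


def test_distances_match_brute_force_scan(lattice, lattice_baseline):
    g, _ = lattice
    avmap = compute_av_factor(g, lattice_baseline)
    df = distance_maps(g, avmap, spacing=2.0).head(200)
    pts, owner = discretize(g, spacing=2.0)
    art = {int(v) for v in avmap.av_factor.index
           if pd.notna(avmap.av_factor.loc[v]) and avmap.av_factor.loc[v] < 0.5}
    art_mask = np.isin(owner, list(art))
    for _, row in df.iterrows():
        p = row[["x", "y", "z"]].to_numpy(dtype=float)
        d = np.linalg.norm(pts - p, axis=1)
        d_any = d[owner != int(row["vessel"])].min()
        d_art = d[art_mask].min()
        assert row["d_any"] == pytest.approx(d_any, abs=1e-9)
        assert row["d_arteriole"] == pytest.approx(d_art, abs=1e-9)
        if row["d_any"] > 0:
            assert (row["distance_factor"] >= 1.0
                    or row["d_any"] == row["d_arteriole"])
        else:
            assert np.isnan(row["distance_factor"])  # shared-node point


# ------------------------------------------------------- sphere & cube scans

def test_uniform_factor_gives_sphere_mean_half_and_zero_difference():
    g, avmap = _two_rails()
    uniform = AVFactorMap(pd.Series([0.5, 0.5], index=[0, 1]),
                          avmap.median_da, avmap.median_av, "manual")
    df = sphere_scan(g, uniform, radius=50.0)
    assert (df["sphere_mean"] == 0.5).all()
    np.testing.assert_allclose(df["difference"], 0.0)


def test_sphere_means_match_brute_force_average():
    g, avmap = _two_rails()
    df = sphere_scan(g, avmap, radius=30.0, spacing=1.0)
    pts, owner = discretize(g, spacing=1.0)
    own_pts = pts[owner == 1]
    hit = np.zeros(len(pts), dtype=bool)
    for p in own_pts:
        hit |= np.linalg.norm(pts - p, axis=1) <= 30.0
    factors = np.array([avmap.av_factor.loc[int(o)] for o in owner])
    expected = float(np.mean(factors[hit]))
    assert df.iloc[0]["sphere_mean"] == pytest.approx(expected)


def test_cube_with_fewer_than_four_capillaries_is_ineligible():
    pos = {0: (0, 0, 0), 1: (20, 0, 0), 2: (0, 10, 0), 3: (20, 10, 0),
           4: (0, 20, 0), 5: (20, 20, 0)}
    g = simple_graph([(0, 1), (2, 3), (4, 5)], pos, lengths=[20.0] * 3)
    factor = pd.Series([0.4, 0.6, 0.5], index=[0, 1, 2])
    avmap = AVFactorMap(factor, factor * 0, factor * 0, "manual")
    df = cube_scan(g, avmap, side=120.0)
    assert not df["eligible"].any()       # only three capillaries present


def test_cube_scan_eligibility_and_means(lattice, lattice_baseline):
    g, _ = lattice
    avmap = compute_av_factor(g, lattice_baseline)
    df = cube_scan(g, avmap, side=60.0)
    elig = df[df["eligible"]]
    assert len(elig) > 10
    assert (elig["n_assigned"] >= 4).all()
    assert (elig["coverage"] >= 0.5).all()
    assert elig["mean_av_factor"].between(0, 1).all()
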