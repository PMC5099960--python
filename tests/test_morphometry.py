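"""Morphometric analyses: generation assignment, bifurcation geometry,
plane-rotation series, piecewise regression, summaries, transition zones."""

import copy
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pigairway.generator import (DEFAULT_SEGMENTS, DiameterSeries,
                                 GeneratorParams, generate_diameter_series,
                                 generate_tree)
from pigairway.morphometry import (assign_generations, compute_bifurcations,
                                   fit_loglinear_segments,
                                   mainstem_pathway_series,
                                   plane_rotation_series,
                                   summarize_morphometry,
                                   transition_zone_fraction)
from pigairway.tree import AirwayTree, BifurcationRecord, transform_tree

from conftest import make_branch


def chain_tree(diameters):
    """A linear chain of branches with the given diameters (root first),
    padded with a sibling at each bifurcation so the tree stays binary."""
    branches = {}
    prev = None
    for k, d in enumerate(diameters):
        bid = f"c{k}"
        b = make_branch(bid, prev, [], [[0, 0, -20.0 * k], [0, 0, -20.0 * (k + 1)]],
                        d, role="trachea" if prev is None else "other")
        branches[bid] = b
        if prev is not None:
            branches[prev].child_ids.append(bid)
        prev = bid
    return AirwayTree(branches=branches, root_id="c0",
                      reference_plane={"normal": [0, 1, 0], "point": [0, 0, 0]})


# ---------------------------------------------------------------------------
# generation assignment
# ---------------------------------------------------------------------------

def test_generation_grouping_follows_tolerance_rule():
    """Diameters 20.4 (trachea), 14, 10.1, 9.9, 7 with 0.3 mm tolerance give
    generations 0, 1, 2, 2, 3 — 10.1 and 9.9 are indistinguishable."""
    t = chain_tree([20.4, 14.0, 10.1, 9.9, 7.0])
    out = assign_generations(t, tol_mm=0.3)
    gens = [out.branches[f"c{k}"].generation for k in range(5)]
    assert gens == [0, 1, 2, 2, 3]


def test_zero_tolerance_gives_strictly_increasing_generations():
    t = chain_tree([20.0, 15.0, 11.0, 8.0, 5.0])
    out = assign_generations(t, tol_mm=0.0)
    gens = [out.branches[f"c{k}"].generation for k in range(5)]
    assert gens == [0, 1, 2, 3, 4]


def test_daughter_within_tolerance_keeps_parent_generation():
    t = chain_tree([20.0, 10.0, 9.8, 5.0])
    out = assign_generations(t, tol_mm=0.3)
    assert out.branches["c2"].generation == out.branches["c1"].generation


def test_assignment_does_not_mutate_input(simple_tree):
    snapshot = copy.deepcopy(simple_tree)
    assign_generations(simple_tree)
    assert all(simple_tree.branches[k].generation ==
               snapshot.branches[k].generation for k in simple_tree.branches)


def test_unset_diameter_is_an_error(simple_tree):
    simple_tree.branches["a"].diameter_mm = -2.0
    with pytest.raises(ValueError, match="a"):
        assign_generations(simple_tree)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.lists(st.floats(1.0, 25.0), min_size=2, max_size=12),
       st.permutations(range(12)))
def test_assignment_invariant_to_branch_ordering(diams, perm):
    """Relabeling/reordering branches never changes assigned generations."""
    diams = sorted(diams, reverse=True)
    t1 = chain_tree(diams)
    out1 = assign_generations(t1)
    order = [p for p in perm if p < len(diams)]
    # rebuild the same chain but insert branches in permuted order
    t2 = chain_tree(diams)
    t2.branches = {f"c{k}": t2.branches[f"c{k}"] for k in order +
                   [i for i in range(len(diams)) if i not in order]}
    out2 = assign_generations(t2)
    for k in range(len(diams)):
        assert out1.branches[f"c{k}"].generation == \
            out2.branches[f"c{k}"].generation


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.lists(st.floats(1.0, 25.0), min_size=3, max_size=12))
def test_raising_tolerance_never_increases_generation_count(diams):
    diams = sorted(diams, reverse=True)
    t = chain_tree(diams)
    counts = []
    for tol in (0.0, 0.3, 0.6, 1.2):
        out = assign_generations(t, tol_mm=tol)
        counts.append(len({b.generation for b in out.branches.values()}))
    assert counts == sorted(counts, reverse=True)


def test_raising_tolerance_never_raises_the_maximum_generation(default_tree):
    """Raising the grouping tolerance from 0.3 to 0.4 mm can only merge
    diameter groups, so the maximum generation cannot increase."""
    g3 = assign_generations(default_tree, tol_mm=0.3)
    g4 = assign_generations(default_tree, tol_mm=0.4)
    m3 = max(b.generation for b in g3.branches.values())
    m4 = max(b.generation for b in g4.branches.values())
    assert m3 >= m4


# ---------------------------------------------------------------------------
# bifurcation geometry
# ---------------------------------------------------------------------------

def constructed_bifurcation(minor_rotation_deg=0.0):
    u = np.array([0.0, 0.0, -1.0])
    w = np.array([1.0, 0.0, 0.0])
    if minor_rotation_deg:
        from pigairway._geom import rotate_about_axis
        w = rotate_about_axis(w, u, minor_rotation_deg)
    j = np.array([0.0, 0.0, -30.0])
    vmin = np.cos(np.radians(41.44)) * u + np.sin(np.radians(41.44)) * w
    p = make_branch("p", None, ["a", "b"], [[0, 0, 0], j], 10.0, role="trachea")
    a = make_branch("a", "p", [], [j, j + u * 25], 8.8)
    b = make_branch("b", "p", [], [j, j + vmin * 25], 5.7)
    return AirwayTree(branches={"p": p, "a": a, "b": b}, root_id="p",
                      reference_plane={"normal": [0, 1, 0], "point": [0, 0, 0]})


def test_constructed_in_plane_bifurcation_measures_exactly():
    recs = compute_bifurcations(constructed_bifurcation())
    r = recs[0]
    assert r.angle1_deg == pytest.approx(0.0, abs=1e-9)
    assert r.angle2_deg == pytest.approx(41.44, abs=1e-9)
    assert r.planarity == "in_plane"
    assert r.d1_mm / r.D_mm == pytest.approx(0.88)
    assert r.d2_mm / r.D_mm == pytest.approx(0.57)


def test_minor_rotated_out_of_plane_is_classified_by_side():
    """A minor daughter leaving perpendicular to the reference plane is
    out-of-plane, signed by the side of the plane it grows toward (rotating
    +x by +90 deg about the caudal trachea axis -z lands on -y)."""
    recs = compute_bifurcations(constructed_bifurcation(90.0))
    assert recs[0].planarity == "out_of_plane_neg"
    assert recs[0].plane_rotation_deg == pytest.approx(-90.0, abs=1e-6)
    recs = compute_bifurcations(constructed_bifurcation(-90.0))
    assert recs[0].planarity == "out_of_plane_pos"
    assert recs[0].plane_rotation_deg == pytest.approx(90.0, abs=1e-6)


def test_nonbinary_internal_node_raises_in_strict_mode(simple_tree):
    extra = make_branch("c", "t", [], [[0, 0, -30], [0, 5, -50]], 4.0)
    simple_tree.branches["c"] = extra
    simple_tree.branches["t"].child_ids.append("c")
    with pytest.raises(ValueError, match="children"):
        compute_bifurcations(simple_tree)
    with pytest.warns(UserWarning, match="non-binary"):
        assert compute_bifurcations(simple_tree, strict=False) == []


def test_angles_and_ratios_invariant_under_rigid_motion_and_scale(default_tree):
    recs0 = compute_bifurcations(default_tree)
    th = np.deg2rad(33.0)
    R = np.array([[1, 0, 0],
                  [0, np.cos(th), -np.sin(th)],
                  [0, np.sin(th), np.cos(th)]])
    moved = transform_tree(default_tree, rotation=R,
                           translation=np.array([10.0, -4.0, 7.0]), scale=1.7)
    recs1 = compute_bifurcations(moved)
    for r0, r1 in zip(recs0, recs1):
        assert r1.angle1_deg == pytest.approx(r0.angle1_deg, abs=1e-6)
        assert r1.angle2_deg == pytest.approx(r0.angle2_deg, abs=1e-6)
        assert r1.plane_rotation_deg == pytest.approx(r0.plane_rotation_deg,
                                                      abs=1e-6)
        assert r1.d1_mm / r1.D_mm == pytest.approx(r0.d1_mm / r0.D_mm)


# ---------------------------------------------------------------------------
# plane-rotation series
# ---------------------------------------------------------------------------

def test_noise_free_mainstem_series_cycles_0_p90_m90(noise_free_tree):
    for side in ("right", "left"):
        series = mainstem_pathway_series(noise_free_tree, side)
        assert len(series) >= 6
        for k, rot in series:
            expected = (0.0, 90.0, -90.0)[(k - 1) % 3]
            assert rot == pytest.approx(expected, abs=1e-6)


def test_custom_schedule_is_reported_verbatim():
    p = replace(GeneratorParams().noise_free(), plane_schedule=(0.0, -90.0, 0.0))
    tree = generate_tree(p, seed=2)
    series = mainstem_pathway_series(tree, "right")
    for k, rot in series:
        assert rot == pytest.approx((0.0, -90.0, 0.0)[(k - 1) % 3], abs=1e-6)


def test_series_invariant_under_corotated_rigid_motion(noise_free_tree):
    th = np.deg2rad(30.0)
    R = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0],
                  [-np.sin(th), 0, np.cos(th)]])
    moved = transform_tree(noise_free_tree, rotation=R)
    s0 = mainstem_pathway_series(noise_free_tree, "right")
    s1 = mainstem_pathway_series(moved, "right")
    assert len(s0) == len(s1)
    for (k0, r0), (k1, r1) in zip(s0, s1):
        assert (k0, pytest.approx(r0, abs=1e-6)) == (k1, r1)


def test_leaf_pathway_gives_empty_series(simple_tree):
    assert plane_rotation_series(simple_tree, "a") == []


# ---------------------------------------------------------------------------
# piecewise log-linear regression
# ---------------------------------------------------------------------------

def test_printed_equations_recovered_exactly():
    series = generate_diameter_series(DEFAULT_SEGMENTS, 0.0, 3, seed=0)
    fits = fit_loglinear_segments(series)
    slopes = [f.slope for f in fits]
    intercepts = [f.intercept for f in fits]
    assert slopes == pytest.approx([-0.0438, -0.0228, -0.0418], abs=1e-9)
    assert intercepts == pytest.approx([1.3094, 1.0979, 1.488], abs=1e-9)


def test_constant_series_has_zero_slope():
    s = DiameterSeries(np.arange(6), np.full(6, 8.0))
    f = fit_loglinear_segments(s)[0]
    assert f.slope == pytest.approx(0.0, abs=1e-12)
    assert f.intercept == pytest.approx(np.log10(8.0))


def test_ols_matches_closed_form_oracle():
    """statsmodels fit equals the closed-form least-squares solution."""
    rng = np.random.default_rng(5)
    gens = np.repeat(np.arange(12), 3)
    diam = 10.0 ** (-0.05 * gens + 1.2 + rng.normal(0, 0.03, gens.size))
    f = fit_loglinear_segments(DiameterSeries(gens, diam))[0]
    x, y = gens.astype(float), np.log10(diam)
    sxx = ((x - x.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    assert f.slope == pytest.approx(slope, abs=1e-12)
    assert f.intercept == pytest.approx(intercept, abs=1e-12)
    # t-based 95% CI halfwidth from the residual variance
    resid = y - (intercept + slope * x)
    s2 = (resid ** 2).sum() / (len(x) - 2)
    from scipy import stats
    half = stats.t.ppf(0.975, len(x) - 2) * np.sqrt(s2 / sxx)
    assert f.ci_slope_halfwidth == pytest.approx(half, rel=1e-9)


def test_slope_cis_cover_truth_in_seeded_replicates():
    """With Normal(0, 0.02) log-noise and 6 subjects x 24 generations, the
    95% CI for the slope covers the true slope in >= 90% of replicates."""
    true_slope, true_int = -0.0438, 1.3094
    hits = 0
    n_rep = 200
    for rep in range(n_rep):
        s = generate_diameter_series([(true_slope, true_int, (0, 11))],
                                     noise_sd_log10=0.02, n_per_generation=6,
                                     seed=rep)
        f = fit_loglinear_segments(s)[0]
        if abs(f.slope - true_slope) <= f.ci_slope_halfwidth:
            hits += 1
    assert hits / n_rep >= 0.90


def test_partial_series_returns_only_covered_segments():
    s = generate_diameter_series([DEFAULT_SEGMENTS[1]], 0.0, 3)
    fits = fit_loglinear_segments(s)
    assert [f.segment_index for f in fits] == [2]
    assert fits[0].slope == pytest.approx(-0.0228, abs=1e-9)


def test_single_point_segment_is_an_error():
    s = DiameterSeries(np.array([5]), np.array([8.0]))
    with pytest.raises(ValueError):
        fit_loglinear_segments(s)


def test_two_point_segment_fits_without_ci_and_is_flagged():
    s = DiameterSeries(np.array([3, 7]), np.array([12.0, 9.0]))
    f = fit_loglinear_segments(s)[0]
    assert f.ci_flagged and f.ci_slope_halfwidth is None
    assert f.n == 2


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_identical_records_give_zero_ci_halfwidth():
    rec = BifurcationRecord("p", "a", "b", 10.0, 8.8, 5.7, 14.0, 41.0, 0.0,
                            "in_plane")
    summary = summarize_morphometry([rec, copy.copy(rec), copy.copy(rec)])
    stats = summary.per_class["in_plane"]
    assert stats["angle1_deg"]["ci95_halfwidth"] == pytest.approx(0.0)
    assert summary.counts == {"in_plane": 3}


def test_noise_free_class_means_are_exact(noise_free_tree):
    recs = compute_bifurcations(noise_free_tree)
    summary = summarize_morphometry(recs)
    assert summary.per_class["in_plane"]["d2_over_D"]["mean"] == \
        pytest.approx(0.57, abs=1e-9)
    assert summary.per_class["out_of_plane"]["d2_over_D"]["mean"] == \
        pytest.approx(0.35, abs=1e-9)
    assert summary.per_class["out_of_plane"]["angle2_deg"]["mean"] == \
        pytest.approx(41.37, abs=1e-9)


def test_pooled_ratio_matches_mixture_closed_form():
    """A 1:2 in:out mixture of exact 0.88 / 0.86 records pools to
    (0.88 + 2 * 0.86) / 3."""
    recs = []
    for k in range(20):
        recs.append(BifurcationRecord(f"p{k}", "a", "b", 10.0, 8.8, 5.7,
                                      14.0, 41.0, 0.0, "in_plane"))
    for k in range(40):
        recs.append(BifurcationRecord(f"q{k}", "a", "b", 10.0, 8.6, 3.5,
                                      0.0, 41.0, 90.0, "out_of_plane_pos"))
    summary = summarize_morphometry(recs)
    assert summary.pooled_d1_over_D["mean"] == \
        pytest.approx((0.88 + 2 * 0.86) / 3.0)


def test_empty_record_list_is_an_error():
    with pytest.raises(ValueError):
        summarize_morphometry([])


def test_per_generation_table_counts_every_branch(default_tree):
    tree = assign_generations(default_tree)
    recs = compute_bifurcations(tree)
    summary = summarize_morphometry(recs, tree)
    total = sum(v["n"] for v in summary.per_generation.values())
    assert total == tree.n_branches()


# ---------------------------------------------------------------------------
# transition zone
# ---------------------------------------------------------------------------

def make_profile(aspects, spacing=2.0):
    n = len(aspects)
    pos = np.arange(n) * spacing
    dmax = np.full(n, 10.0)
    return __import__("pigairway").extract.DiameterProfile(
        pos, dmax * np.asarray(aspects), dmax)


def test_cylindrical_profile_has_zero_transition_fraction():
    prof = make_profile([0.97] * 10)
    assert transition_zone_fraction(prof) == 0.0


def test_threshold_one_captures_any_discretized_profile():
    prof = make_profile([0.97, 0.96, 0.95, 0.94, 0.93])
    assert transition_zone_fraction(prof, aspect_threshold=1.0) == 1.0


def test_fraction_counts_only_the_contiguous_distal_run():
    aspects = [0.95, 0.85, 0.95, 0.95, 0.95, 0.85, 0.8, 0.7]
    prof = make_profile(aspects)
    # contiguous run below 0.9 from the distal end starts at sample 5 of 8:
    # arc from position 10 to 14 out of 14 (the isolated dip at sample 1
    # is not contiguous with the distal end and does not count)
    assert transition_zone_fraction(prof) == pytest.approx(4 / 14.0)


def test_short_profile_is_an_error():
    with pytest.raises(ValueError):
        transition_zone_fraction(make_profile([0.9, 0.8]))


def test_generated_transition_fraction_recovered_from_mask():
    """A parent with a 25% transition zone measures 0.25 +- 0.05."""
    from pigairway.extract import measure_diameter_profile
    from pigairway.voxelize import voxelize_tree

    meta = {"lumen": {"transition_zone_fraction": 0.25,
                      "aspect_ratio_outside": 0.95,
                      "transition_aspect_end": 0.6},
            "bifurcation": {"lateral": [1, 0, 0]}}
    b = make_branch("r", None, ["x", "y"], [[0, 0, 0], [0, 0, -40]], 10.0,
                    role="trachea", meta=meta)
    x = make_branch("x", "r", [], [[0, 0, -40], [5, 0, -55]], 8.0)
    y = make_branch("y", "r", [], [[0, 0, -40], [-5, 0, -55]], 5.0)
    t = AirwayTree(branches={"r": b, "x": x, "y": y}, root_id="r",
                   reference_plane={"normal": [0, 1, 0], "point": [0, 0, 0]})
    mask = voxelize_tree(t, spacing_mm=(0.4, 0.4, 0.4))
    path = np.array([[0.0, 0.0, -z] for z in np.linspace(1, 39, 20)])
    prof = measure_diameter_profile(mask, path)
    assert transition_zone_fraction(prof) == pytest.approx(0.25, abs=0.05)
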