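"""Synthetic tree generator: anatomy, determinism, noise-free exactness,
diameter series, tube phantoms."""

import collections
from dataclasses import replace

import numpy as np
import pytest

from pigairway.generator import (DEFAULT_SEGMENTS, GeneratorParams,
                                 generate_diameter_series, generate_tree,
                                 generate_tube_phantom)
from pigairway.morphometry import compute_bifurcations
from pigairway.tree import trees_equal, validate_tree


def test_default_tree_validates(default_tree):
    assert validate_tree(default_tree) == []


def test_tracheal_bronchus_precedes_the_main_carina(default_tree):
    """The first branching off the trachea is the (smaller) tracheal
    bronchus; the mainstem carina comes one segment later."""
    root = default_tree.root()
    assert root.role_tag == "trachea" and root.generation == 0
    kids = default_tree.children(root.id)
    assert len(kids) == 2
    minor = min(kids, key=lambda b: b.diameter_mm)
    major = max(kids, key=lambda b: b.diameter_mm)
    assert minor.role_tag == "tracheal_bronchus"
    assert major.role_tag == "trachea" and major.generation == 0
    grandkids = {b.role_tag for b in default_tree.children(major.id)}
    assert grandkids == {"right_mainstem", "left_mainstem"}


def test_same_seed_gives_bit_identical_trees():
    a = generate_tree(GeneratorParams(), seed=11)
    b = generate_tree(GeneratorParams(), seed=11)
    assert trees_equal(a, b)
    c = generate_tree(GeneratorParams(), seed=12)
    assert not trees_equal(a, c)


def test_noise_free_limit_reproduces_class_means_exactly(noise_free_tree):
    """With all spreads at zero, ordinary in-plane bifurcations emit exactly
    d1/D = 0.88 and angle 1 = 14.34 deg (the curved left mainstem and the
    special trachea events are the only exceptions)."""
    recs = compute_bifurcations(noise_free_tree)
    inp = [r for r in recs if r.planarity == "in_plane"]
    ratios = collections.Counter(round(r.d1_mm / r.D_mm, 6) for r in inp)
    angles = collections.Counter(round(r.angle1_deg, 4) for r in inp)
    assert ratios[0.88] >= len(inp) - 2
    assert angles[14.34] >= len(inp) - 2
    outp = [r for r in recs if r.planarity != "in_plane"]
    assert all(round(r.d2_mm / r.D_mm, 6) == 0.35 for r in outp)
    assert all(round(r.angle2_deg, 4) == 41.37 for r in outp)


def test_major_daughter_never_smaller_than_minor(default_tree):
    for r in compute_bifurcations(default_tree):
        assert r.d1_mm >= r.d2_mm > 0


def test_lumen_shape_parameters_within_configured_ranges(default_tree):
    p = GeneratorParams()
    for b in default_tree.branches.values():
        lum = b.meta["lumen"]
        lo, hi = p.transition_zone_fraction_range
        assert lo <= lum["transition_zone_fraction"] <= hi
        lo, hi = p.flow_divider_radius_range_mm
        assert lo <= lum["flow_divider_radius_mm"] <= hi
        lo, hi = p.aspect_ratio_range
        assert lo <= lum["aspect_ratio_outside"] <= hi


def test_same_generation_daughters_confined_to_deep_generations(default_tree):
    p = GeneratorParams()
    lo, hi = p.same_generation_range
    for b in default_tree.branches.values():
        parent = default_tree.parent(b.id)
        if parent is None or parent.role_tag == "trachea":
            continue
        if b.generation == parent.generation:
            assert lo <= parent.generation <= hi


def test_sample_means_converge_to_configured_means():
    """Pooled over >= 500 bifurcations the class means sit within 3 standard
    errors of the configured distribution means."""
    p = GeneratorParams()
    recs = []
    for seed in range(1, 7):
        recs.extend(compute_bifurcations(generate_tree(p, seed=seed)))
    assert len(recs) >= 500
    groups = {"in_plane": [], "out": []}
    for r in recs:
        groups["in_plane" if r.planarity == "in_plane" else "out"].append(r)
    checks = [
        ("in_plane", lambda r: r.d1_mm / r.D_mm, p.ratio_d1_in_mean, p.ratio_d1_sd),
        ("in_plane", lambda r: r.d2_mm / r.D_mm, p.ratio_d2_in_mean, p.ratio_d2_sd),
        ("out", lambda r: r.d2_mm / r.D_mm, p.ratio_d2_out_mean, p.ratio_d2_sd),
        ("in_plane", lambda r: r.angle2_deg, p.angle2_in_mean_deg, p.angle2_sd_deg),
        ("out", lambda r: r.angle2_deg, p.angle2_out_mean_deg, p.angle2_sd_deg),
    ]
    for cls, fn, mean, sd in checks:
        vals = np.array([fn(r) for r in groups[cls]])
        se = sd / np.sqrt(len(vals))
        # small allowance on top of 3 SE for the special trachea records
        assert abs(vals.mean() - mean) < 3 * se + 0.02 * abs(mean) + 0.005


def test_rejects_parameters_implying_nonterminating_growth():
    with pytest.raises(ValueError):
        GeneratorParams(min_diameter_mm=0.0).validate()
    with pytest.raises(ValueError):
        GeneratorParams(ratio_d1_in_mean=1.5).validate()
    with pytest.raises(ValueError):
        GeneratorParams(plane_schedule=(0.0, 45.0)).validate()


# ---------------------------------------------------------------------------
# diameter series
# ---------------------------------------------------------------------------

def test_noise_free_series_matches_closed_form():
    seg1 = [DEFAULT_SEGMENTS[0]]
    s = generate_diameter_series(seg1, noise_sd_log10=0.0, n_per_generation=1)
    d = dict(zip(s.generation.tolist(), s.diameter_mm.tolist()))
    assert d[0] == pytest.approx(10.0 ** 1.3094)          # 20.39 mm
    assert d[11] == pytest.approx(10.0 ** (1.3094 - 0.0438 * 11))  # 6.73 mm
    flat = generate_diameter_series([(0.0, 1.0, (0, 5))], 0.0, 2)
    assert np.allclose(flat.diameter_mm, 10.0)


def test_series_noise_is_seed_reproducible():
    a = generate_diameter_series(noise_sd_log10=0.05, seed=3)
    b = generate_diameter_series(noise_sd_log10=0.05, seed=3)
    c = generate_diameter_series(noise_sd_log10=0.05, seed=4)
    assert np.array_equal(a.diameter_mm, b.diameter_mm)
    assert not np.array_equal(a.diameter_mm, c.diameter_mm)


def test_overlapping_segment_ranges_rejected():
    with pytest.raises(ValueError, match="overlap"):
        generate_diameter_series([(-0.04, 1.3, (0, 11)), (-0.02, 1.1, (11, 20))])


# ---------------------------------------------------------------------------
# tube phantoms
# ---------------------------------------------------------------------------

def test_phantom_edt_diameter_matches_analytic_cylinder():
    from scipy import ndimage

    mask = generate_tube_phantom(20.0, 60.0, 0.4)
    edt = ndimage.distance_transform_edt(mask.data, sampling=mask.spacing_mm)
    assert 2.0 * edt.max() == pytest.approx(20.0, abs=0.4)


def test_phantom_is_translation_symmetric_along_axis():
    mask = generate_tube_phantom(3.0, 20.0, 0.4, axis=(0, 0, 1))
    counts = mask.data.sum(axis=(0, 1))
    interior = counts[counts > 0][2:-2]
    assert len(set(interior.tolist())) == 1


def test_phantom_rejects_subresolution_diameter():
    with pytest.raises(ValueError, match="resolvability"):
        generate_tube_phantom(0.5, 20.0, 0.4)
    with pytest.raises(ValueError, match="length"):
        generate_tube_phantom(5.0, 4.0, 0.4)


def test_phantom_padding_is_at_least_two_voxels():
    mask = generate_tube_phantom(7.0, 30.0, 0.4)
    assert not mask.data[:2].any() and not mask.data[-2:].any()
    assert not mask.data[:, :2].any() and not mask.data[:, -2:].any()
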