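"""Skeletonization, measured-tree reconstruction and cross-section profiling
validated on analytic phantoms."""

import warnings

import numpy as np
import pytest

from pigairway.extract import (build_measured_tree, measure_diameter_profile,
                               skeletonize_mask)
from pigairway.generator import generate_tube_phantom
from pigairway.tree import AirwayTree
from pigairway.voxelize import VoxelMask, voxelize_tree

from conftest import make_branch


@pytest.fixture(scope="module")
def tube_mask():
    return generate_tube_phantom(20.0, 60.0, 0.4)


def test_tube_skeleton_is_a_single_path(tube_mask):
    g = skeletonize_mask(tube_mask)
    degrees = [d for _, d in g.graph.degree]
    assert max(degrees) <= 2
    assert sum(1 for d in degrees if d == 1) == 2  # two endpoints, no junction


def test_tube_skeleton_lies_within_one_voxel_of_axis(tube_mask):
    g = skeletonize_mask(tube_mask)
    pts = g.node_points_mm(list(g.graph.nodes))
    interior = pts[(pts[:, 2] > 5) & (pts[:, 2] < 55)]
    radial = np.hypot(interior[:, 0], interior[:, 1])
    assert radial.max() <= 0.4 * np.sqrt(3) + 1e-9


def test_y_bifurcation_yields_one_junction():
    p = make_branch("p", None, ["a", "b"], [[0, 0, 0], [0, 0, -30]], 10.0,
                    role="trachea")
    a = make_branch("a", "p", [], [[0, 0, -30], [3, 0, -58]], 8.8)
    b = make_branch("b", "p", [], [[0, 0, -30], [18, 0, -51]], 5.7)
    t = AirwayTree(branches={"p": p, "a": a, "b": b}, root_id="p",
                   reference_plane={"normal": [0, 1, 0], "point": [0, 0, 0]})
    mask = voxelize_tree(t, spacing_mm=(0.4, 0.4, 0.4))
    g = skeletonize_mask(mask)
    mt = build_measured_tree(g, mask, (0, 0, -1.0))
    assert len(mt.branches) == 3
    assert len(mt.children(mt.root_id)) == 2


def test_disjoint_components_warn_and_use_largest(tube_mask):
    small = generate_tube_phantom(3.0, 20.0, 0.4)
    # embed both tubes in one array, far apart
    nx1, ny1, nz1 = tube_mask.data.shape
    nx2, ny2, nz2 = small.data.shape
    combo = np.zeros((nx1 + nx2 + 10, max(ny1, ny2), max(nz1, nz2)), bool)
    combo[:nx1, :ny1, :nz1] = tube_mask.data
    combo[nx1 + 10:nx1 + 10 + nx2, :ny2, :nz2] = small.data
    mask = VoxelMask(combo, tube_mask.spacing_mm, tube_mask.origin_mm)
    with pytest.warns(UserWarning, match="connected components"):
        g = skeletonize_mask(mask)
    # only the large tube's skeleton remains
    pts = g.node_points_mm(list(g.graph.nodes))
    assert pts[:, 0].max() < tube_mask.origin_mm[0] + nx1 * 0.4


def test_empty_foreground_is_an_error(tube_mask):
    empty = VoxelMask(np.zeros_like(tube_mask.data), tube_mask.spacing_mm,
                      tube_mask.origin_mm)
    with pytest.raises(ValueError, match="empty"):
        skeletonize_mask(empty)


def test_root_hint_outside_foreground_is_an_error(tube_mask):
    g = skeletonize_mask(tube_mask)
    with pytest.raises(ValueError, match="root_hint"):
        build_measured_tree(g, tube_mask, (50.0, 50.0, 50.0))


@pytest.mark.parametrize("diameter", [20.0, 12.0, 7.0, 3.0])
def test_phantom_diameter_recovered_within_segmentation_bound(diameter):
    """The segmentation-validation analog: tube phantoms at 0.4 mm voxels
    are measured to better than 0.3 mm."""
    mask = generate_tube_phantom(diameter, 60.0, 0.4)
    g = skeletonize_mask(mask)
    mt = build_measured_tree(g, mask, (0, 0, 1.0))
    main = max(mt.branches.values(), key=lambda b: b.length_mm)
    assert abs(main.diameter_mm - diameter) <= 0.3


def test_measured_tube_length_close_to_truth(tube_mask):
    g = skeletonize_mask(tube_mask)
    mt = build_measured_tree(g, tube_mask, (0, 0, 1.0))
    main = max(mt.branches.values(), key=lambda b: b.length_mm)
    # thinning retracts the skeleton by about one radius at each open end
    assert main.length_mm == pytest.approx(60.0, abs=2 * 10.0)
    assert main.length_mm > 35.0


# ---------------------------------------------------------------------------
# cross-section profiles
# ---------------------------------------------------------------------------

def test_circular_cylinder_profile_is_nearly_isotropic(tube_mask):
    path = np.array([[0.0, 0.0, z] for z in np.linspace(10, 50, 9)])
    prof = measure_diameter_profile(tube_mask, path)
    assert prof.aspect.min() >= 0.95
    assert np.median(prof.d_max_mm) == pytest.approx(20.0, abs=0.5)


def test_elliptical_section_aspect_recovered():
    """A lumen with axes 10 x 8 mm measures an aspect ratio near 0.8."""
    meta = {"lumen": {"transition_zone_fraction": 0.0,
                      "aspect_ratio_outside": 0.8,
                      "transition_aspect_end": 0.8},
            "bifurcation": {"lateral": [1, 0, 0]}}
    b = make_branch("r", None, ["x", "y"], [[0, 0, 0], [0, 0, -40]], 8.0,
                    role="trachea", meta=meta)
    x = make_branch("x", "r", [], [[0, 0, -40], [4, 0, -55]], 6.0)
    y = make_branch("y", "r", [], [[0, 0, -40], [-4, 0, -55]], 4.0)
    t = AirwayTree(branches={"r": b, "x": x, "y": y}, root_id="r",
                   reference_plane={"normal": [0, 1, 0], "point": [0, 0, 0]})
    mask = voxelize_tree(t, spacing_mm=(0.4, 0.4, 0.4))
    prof = measure_diameter_profile(
        mask, np.array([[0.0, 0.0, -z] for z in np.linspace(10, 30, 6)]))
    assert prof.aspect.mean() == pytest.approx(0.8, abs=0.05)


def test_duplicate_path_points_raise(tube_mask):
    path = np.array([[0, 0, 10.0], [0, 0, 10.0], [0, 0, 20.0]])
    with pytest.raises(ValueError, match="tangent"):
        measure_diameter_profile(tube_mask, path)
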