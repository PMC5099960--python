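"""Shared fixtures: small hand-built trees and a session-scoped recovery
ensemble (generate -> voxelize -> extract) reused by the pipeline and
acceptance tests to keep the suite fast."""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pytest

from pigairway.extract import build_measured_tree, skeletonize_mask
from pigairway.generator import GeneratorParams, generate_tree
from pigairway.tree import AirwayTree, BranchNode
from pigairway.voxelize import voxelize_tree


def make_branch(bid, parent, children, centerline, diameter, role="other",
                generation=None, meta=None):
    centerline = np.asarray(centerline, dtype=float)
    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1).sum()
    return BranchNode(id=bid, parent_id=parent, child_ids=list(children),
                      centerline=centerline, diameter_mm=diameter,
                      length_mm=float(seg), generation=generation,
                      role_tag=role, meta=meta or {})


@pytest.fixture
def simple_tree() -> AirwayTree:
    """Minimal valid tree: trachea bifurcating into two daughters."""
    t = make_branch("t", None, ["a", "b"], [[0, 0, 0], [0, 0, -30]], 18.0,
                    role="trachea", generation=0)
    a = make_branch("a", "t", [], [[0, 0, -30], [4, 0, -55]], 15.0)
    b = make_branch("b", "t", [], [[0, 0, -30], [-15, 0, -48]], 10.0)
    return AirwayTree(branches={"t": t, "a": a, "b": b}, root_id="t",
                      reference_plane={"normal": [0, 1, 0], "point": [0, 0, 0]})


@pytest.fixture(scope="session")
def default_tree() -> AirwayTree:
    return generate_tree(GeneratorParams(), seed=1)


@pytest.fixture(scope="session")
def noise_free_tree() -> AirwayTree:
    return generate_tree(GeneratorParams().noise_free(), seed=1)


#: reduced geometry for voxel-level recovery studies: shallow tree, branch
#: lengths above the local caliber so every junction is topologically
#: resolvable by medial-axis thinning (see docs/methods.md)
RECOVERY_PARAMS = replace(
    GeneratorParams(), max_generation=4, min_diameter_mm=3.0,
    trachea_length_mm=80.0, length_gen2_override_mm=24.0)

RECOVERY_SEEDS = (1, 2, 3, 4, 5, 6)
RECOVERY_SPACING = (0.4, 0.4, 0.4)


@pytest.fixture(scope="session")
def recovery_ensemble():
    """Six reduced trees pushed through voxelize(0.4 mm) -> extract."""
    out = []
    for seed in RECOVERY_SEEDS:
        true_tree = generate_tree(RECOVERY_PARAMS, seed=seed)
        mask = voxelize_tree(true_tree, spacing_mm=RECOVERY_SPACING)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            graph = skeletonize_mask(mask)
            measured = build_measured_tree(
                graph, mask,
                root_hint=true_tree.root().centerline[0] + np.array([0, 0, -1.0]),
                on_cycles="break", merge_factor=0.5)
        out.append((true_tree, measured))
    return out
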