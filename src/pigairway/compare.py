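"""Pair a measured tree against the generating ground truth.

Used by recovery studies: branches are matched top-down by direction, and a
structural-consistency gate separates measurement error (how well a
correctly recovered branch is measured) from topology error (branches whose
boundaries shifted because thinning fused or split junctions).
"""

from __future__ import annotations

import numpy as np

from ._geom import angle_between_deg
from .tree import AirwayTree, BranchNode

__all__ = ["match_branches", "pair_is_consistent", "collision_exclusion_ids"]


def _chord_direction(b: BranchNode) -> np.ndarray:
    v = b.centerline[-1] - b.centerline[0]
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError(f"branch {b.id} has zero extent")
    return v / n


def match_branches(true_tree: AirwayTree, measured_tree: AirwayTree,
                   max_angle_deg: float = 30.0) -> list[tuple[str, str]]:
    """Greedy top-down pairing of true and measured branches.

    Starting from the paired roots, each true child is matched to the
    unclaimed measured child whose chord direction is closest (within
    ``max_angle_deg``); matched pairs recurse.  Unmatched branches on either
    side are simply absent from the result.
    """
    pairs: list[tuple[str, str]] = []
    stack = [(true_tree.root_id, measured_tree.root_id)]
    while stack:
        a, b = stack.pop()
        pairs.append((a, b))
        true_kids = true_tree.children(a)
        meas_kids = measured_tree.children(b)
        used: set[str] = set()
        for tk in true_kids:
            best, best_ang = None, max_angle_deg
            td = _chord_direction(tk)
            for mk in meas_kids:
                if mk.id in used:
                    continue
                ang = angle_between_deg(td, _chord_direction(mk))
                if ang < best_ang:
                    best, best_ang = mk, ang
            if best is not None:
                used.add(best.id)
                stack.append((tk.id, best.id))
    return pairs


def pair_is_consistent(true_branch: BranchNode,
                       measured_branch: BranchNode) -> bool:
    """True when the measured branch plausibly spans the same anatomy.

    A measured branch whose length disagrees with the truth by more than a
    third of the branch (or one true diameter, whichever is larger) had its
    boundaries moved by a fused or split junction; its diameter samples then
    cover the wrong stretch of lumen and say nothing about measurement
    accuracy.
    """
    tol = max(0.35 * true_branch.length_mm, true_branch.diameter_mm)
    return abs(measured_branch.length_mm - true_branch.length_mm) <= tol


def collision_exclusion_ids(tree: AirwayTree) -> set[str]:
    """Branches touching a non-adjacent branch, plus immediate neighbours.

    Masks rasterized from a tree with touching branches contain fused lumens
    there; no segmentation could recover those regions, so recovery studies
    score them separately from cleanly separated anatomy.
    """
    from .generator import find_collisions

    excl: set[str] = set()
    for a, b in find_collisions(tree):
        for x in (a, b):
            excl.add(x)
            node = tree.branches[x]
            if node.parent_id is not None:
                excl.add(node.parent_id)
            excl.update(node.child_ids)
    return excl
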