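"""Airway-tree data model, validation and serialization.

The tree is a rooted binary spatial tree of lumen centerlines.  Each branch
carries a polyline centerline (mm), a representative lumen diameter, its arc
length and, once assigned, a Weibel-style generation number (trachea = 0).

Pig anatomy adds one wrinkle: a tracheal bronchus leaves the trachea *before*
the main carina.  To keep every branching event binary, the trachea is modeled
as two stacked segments — proximal trachea → {tracheal bronchus, distal
trachea} → {right mainstem, left mainstem} — with both segments labeled
generation 0 and role ``trachea``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from ._geom import polyline_length

SCHEMA_VERSION = 1

ROLE_TAGS = ("trachea", "tracheal_bronchus", "right_mainstem", "left_mainstem", "other")

#: Arc-length tolerance for the length/centerline consistency invariant (mm).
LENGTH_ATOL_MM = 1e-6


@dataclass
class BranchNode:
    """One airway branch: a centerline with a representative lumen diameter."""

    id: str
    parent_id: str | None
    child_ids: list[str]
    centerline: np.ndarray  # (N, 3) points, mm
    diameter_mm: float
    length_mm: float
    generation: int | None = None
    role_tag: str = "other"
    #: free-form per-branch metadata (generator ground truth, lumen shape, ...)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)


@dataclass
class BifurcationRecord:
    """Geometry of one bifurcation: parent D, daughters d1 >= d2, both angles,
    and the rotation of the bifurcating plane relative to the reference plane."""

    parent_id: str
    major_id: str
    minor_id: str
    D_mm: float
    d1_mm: float
    d2_mm: float
    angle1_deg: float
    angle2_deg: float
    plane_rotation_deg: float
    planarity: str  # in_plane | out_of_plane_pos | out_of_plane_neg


@dataclass
class AirwayTree:
    """Rooted tree of :class:`BranchNode` with a reference plane.

    The reference plane is the plane of the trachea and the two mainstem
    bronchi; bifurcating-plane rotations are measured against it.
    """

    branches: dict[str, BranchNode]
    root_id: str
    reference_plane: dict | None = None  # {"normal": [3], "point": [3]}
    frame: dict = field(default_factory=lambda: {
        "units": "mm", "handedness": "right", "trachea_axis": [0.0, 0.0, -1.0]})

    # -- navigation ---------------------------------------------------------
    def root(self) -> BranchNode:
        return self.branches[self.root_id]

    def children(self, branch_id: str) -> list[BranchNode]:
        return [self.branches[c] for c in self.branches[branch_id].child_ids]

    def parent(self, branch_id: str) -> BranchNode | None:
        pid = self.branches[branch_id].parent_id
        return self.branches[pid] if pid is not None else None

    def iter_branches(self) -> Iterator[BranchNode]:
        """Deterministic depth-first, pre-order, children in stored order."""
        stack = [self.root_id]
        seen = set()
        while stack:
            bid = stack.pop()
            if bid in seen:
                continue
            seen.add(bid)
            node = self.branches[bid]
            yield node
            stack.extend(reversed(node.child_ids))

    def reference_normal(self) -> np.ndarray:
        if self.reference_plane is None:
            raise ValueError("tree has no reference_plane set")
        return np.asarray(self.reference_plane["normal"], dtype=float)

    def n_branches(self) -> int:
        return len(self.branches)


@dataclass
class Diagnostic:
    branch_id: str | None
    rule: str
    message: str


def validate_tree(tree: AirwayTree) -> list[Diagnostic]:
    """Check every structural invariant; return one diagnostic per violation.

    Never raises and never mutates the tree — diagnostics, not exceptions.
    """
    out: list[Diagnostic] = []

    roots = [b.id for b in tree.branches.values() if b.parent_id is None]
    if len(roots) != 1:
        out.append(Diagnostic(None, "multiple_roots" if len(roots) > 1 else "no_root",
                              f"found {len(roots)} parentless branches: {sorted(roots)}"))
    if tree.root_id not in tree.branches:
        out.append(Diagnostic(tree.root_id, "missing_root", "root_id not in branches"))
        return out
    if tree.branches[tree.root_id].role_tag != "trachea":
        out.append(Diagnostic(tree.root_id, "root_role",
                              "root branch must carry role_tag 'trachea'"))

    for b in tree.branches.values():
        if b.role_tag not in ROLE_TAGS:
            out.append(Diagnostic(b.id, "role_tag", f"unknown role_tag {b.role_tag!r}"))
        if not (b.diameter_mm > 0):
            out.append(Diagnostic(b.id, "diameter_positive",
                                  f"diameter_mm = {b.diameter_mm}"))
        if not (b.length_mm > 0):
            out.append(Diagnostic(b.id, "length_positive", f"length_mm = {b.length_mm}"))
        if b.centerline.ndim != 2 or b.centerline.shape[0] < 2 or b.centerline.shape[1] != 3:
            out.append(Diagnostic(b.id, "centerline_shape",
                                  f"centerline shape {b.centerline.shape}"))
        else:
            arc = polyline_length(b.centerline)
            if abs(arc - b.length_mm) > LENGTH_ATOL_MM:
                out.append(Diagnostic(b.id, "length_consistency",
                                      f"length_mm {b.length_mm} vs arc {arc}"))
        for cid in b.child_ids:
            if cid not in tree.branches:
                out.append(Diagnostic(b.id, "dangling_child", f"child {cid} missing"))
            elif tree.branches[cid].parent_id != b.id:
                out.append(Diagnostic(cid, "parent_mismatch",
                                      f"child {cid} does not point back to {b.id}"))
        if b.parent_id is not None:
            p = tree.branches.get(b.parent_id)
            if p is None:
                out.append(Diagnostic(b.id, "dangling_parent",
                                      f"parent {b.parent_id} missing"))
            else:
                if b.generation is not None and p.generation is not None \
                        and b.generation < p.generation:
                    out.append(Diagnostic(b.id, "generation_order",
                                          f"generation {b.generation} < parent's "
                                          f"{p.generation}"))

    # connectivity / acyclicity from the root
    reachable: set[str] = set()
    stack = [tree.root_id] if tree.root_id in tree.branches else []
    while stack:
        bid = stack.pop()
        if bid in reachable:
            out.append(Diagnostic(bid, "cycle", "branch reachable twice from root"))
            continue
        reachable.add(bid)
        stack.extend(c for c in tree.branches[bid].child_ids if c in tree.branches)
    unreachable = set(tree.branches) - reachable
    for bid in sorted(unreachable):
        out.append(Diagnostic(bid, "disconnected", "branch not reachable from root"))

    # binary branching: internal branches have exactly two children; the two
    # trachea segments are themselves binary under the stacked-segment model.
    for b in tree.branches.values():
        if b.child_ids and len(b.child_ids) != 2:
            out.append(Diagnostic(b.id, "bifurcation_arity",
                                  f"internal branch has {len(b.child_ids)} children"))
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _branch_to_json(b: BranchNode) -> dict:
    return {
        "id": b.id,
        "parent_id": b.parent_id,
        "child_ids": list(b.child_ids),
        "centerline": [[float(x) for x in p] for p in b.centerline],
        "diameter_mm": float(b.diameter_mm),
        "length_mm": float(b.length_mm),
        "generation": b.generation,
        "role_tag": b.role_tag,
        "meta": _jsonable(b.meta),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_tree(tree: AirwayTree, path: str | Path) -> None:
    """Write the tree as schema-versioned JSON (lossless float round-trip)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "root_id": tree.root_id,
        "frame": tree.frame,
        "reference_plane": _jsonable(tree.reference_plane),
        "branches": [_branch_to_json(tree.branches[k]) for k in sorted(tree.branches)],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


class TreeParseError(ValueError):
    pass


def read_tree(path: str | Path) -> AirwayTree:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise TreeParseError(f"not valid JSON: {e}") from e
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise TreeParseError(f"schema_version {version!r} unsupported "
                             f"(expected {SCHEMA_VERSION})")
    for key in ("root_id", "branches"):
        if key not in doc:
            raise TreeParseError(f"missing required field {key!r}")
    branches: dict[str, BranchNode] = {}
    for raw in doc["branches"]:
        try:
            b = BranchNode(
                id=raw["id"],
                parent_id=raw["parent_id"],
                child_ids=list(raw["child_ids"]),
                centerline=np.asarray(raw["centerline"], dtype=float),
                diameter_mm=float(raw["diameter_mm"]),
                length_mm=float(raw["length_mm"]),
                generation=raw.get("generation"),
                role_tag=raw.get("role_tag", "other"),
                meta=raw.get("meta", {}),
            )
        except KeyError as e:
            raise TreeParseError(f"branch record missing field {e.args[0]!r}") from e
        branches[b.id] = b
    return AirwayTree(
        branches=branches,
        root_id=doc["root_id"],
        reference_plane=doc.get("reference_plane"),
        frame=doc.get("frame", {}),
    )


def branch_table(tree: AirwayTree) -> pd.DataFrame:
    """One row per branch: id, parent, generation, diameter_mm, length_mm."""
    rows = [
        {
            "id": b.id,
            "parent": b.parent_id,
            "generation": b.generation,
            "diameter_mm": b.diameter_mm,
            "length_mm": b.length_mm,
            "role_tag": b.role_tag,
        }
        for b in tree.iter_branches()
    ]
    return pd.DataFrame(rows)


def write_branch_table(tree: AirwayTree, path: str | Path) -> None:
    branch_table(tree).to_csv(path, index=False)


def transform_tree(tree: AirwayTree, rotation: np.ndarray | None = None,
                   translation: np.ndarray | None = None,
                   scale: float = 1.0) -> AirwayTree:
    """Similarity transform of the whole tree (rotation, translation, uniform
    scale), with the reference plane and direction metadata co-transformed."""
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    if scale <= 0:
        raise ValueError("scale must be positive")

    branches = {}
    for b in tree.branches.values():
        meta = json.loads(json.dumps(_jsonable(b.meta)))
        bif = meta.get("bifurcation")
        if bif and "lateral" in bif:
            bif["lateral"] = (R @ np.asarray(bif["lateral"])).tolist()
        branches[b.id] = BranchNode(
            id=b.id, parent_id=b.parent_id, child_ids=list(b.child_ids),
            centerline=(scale * b.centerline) @ R.T + t,
            diameter_mm=scale * b.diameter_mm,
            length_mm=scale * b.length_mm,
            generation=b.generation, role_tag=b.role_tag, meta=meta)
    ref = None
    if tree.reference_plane is not None:
        ref = {
            "normal": (R @ np.asarray(tree.reference_plane["normal"])).tolist(),
            "point": ((scale * R @ np.asarray(tree.reference_plane["point"])) + t).tolist(),
        }
    return AirwayTree(branches=branches, root_id=tree.root_id,
                      reference_plane=ref, frame=dict(tree.frame))


def trees_equal(a: AirwayTree, b: AirwayTree) -> bool:
    """Bit-identical comparison of coordinates and all scalar fields."""
    if a.root_id != b.root_id or set(a.branches) != set(b.branches):
        return False
    if _jsonable(a.reference_plane) != _jsonable(b.reference_plane):
        return False
    for bid, ba in a.branches.items():
        bb = b.branches[bid]
        if (ba.parent_id != bb.parent_id or ba.child_ids != bb.child_ids
                or ba.diameter_mm != bb.diameter_mm or ba.length_mm != bb.length_mm
                or ba.generation != bb.generation or ba.role_tag != bb.role_tag):
            return False
        if ba.centerline.shape != bb.centerline.shape or \
                not np.array_equal(ba.centerline, bb.centerline):
            return False
        if _jsonable(ba.meta) != _jsonable(bb.meta):
            return False
    return True
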