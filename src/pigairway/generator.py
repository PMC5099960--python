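"""Parametric generator of monopodial pig airway trees.

The model encodes the morphometry of the domestic-pig bronchial tree:

* a tracheal bronchus leaves the trachea *before* the main carina and feeds
  the right upper lung;
* the mainstem bronchi are monopodial — the major daughter continues close to
  the parent direction (angle 1, mean 14.34 degrees for in-plane bifurcations,
  near 0 for out-of-plane) while minor daughters leave laterally at angle 2
  (mean ~41 degrees);
* successive minor daughters along a pathway rotate their bifurcating plane in
  the repeating pattern 0, +90, -90 degrees relative to the plane of the
  trachea and mainstem bronchi;
* daughter/parent diameter ratios are class-conditional: d1/D 0.88 (in-plane)
  / 0.86 (out-of-plane), d2/D 0.57 / 0.35, making minor-daughter ratios
  bimodal;
* branch lengths decrease roughly linearly over generations 1-4 (with a short
  generation 2) and vary between 5 and 12 mm beyond generation 4;
* near each bifurcation the parent lumen has a transition zone covering
  15-40% of its length where the cross-section turns elliptical, and the flow
  divider is rounded with a 0.5-1.5 mm edge radius;
* the left mainstem bronchus is curved with a ~45 mm radius of curvature; all
  other branches are straight.

Each bifurcation's planarity class is determined from the rotation of the
plane it is actually built in, measured against the global reference plane
with the same 45-degree rule the measurement stage applies, so generator
ground truth and downstream classification agree by construction (see
docs/methods.md for why this matters on tilted sub-pathways).

Coordinates are mm, right-handed; the trachea initially points along -z and
the trachea/mainstem reference plane is the x-z plane (normal +y).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from ._geom import plane_rotation_deg, polyline_length, rotate_about_axis, unit
from .tree import AirwayTree, BranchNode

__all__ = [
    "GeneratorParams",
    "DiameterSeries",
    "DEFAULT_SEGMENTS",
    "generate_tree",
    "generate_diameter_series",
    "generate_tube_phantom",
]

_REF_NORMAL = np.array([0.0, 1.0, 0.0])
_TRACHEA_AXIS = np.array([0.0, 0.0, -1.0])


@dataclass(frozen=True)
class GeneratorParams:
    """Full parameter set of the pig airway morphology model.

    Defaults are published measured pig values wherever one exists; the
    remaining spreads and engineering constants are configurable and
    documented in docs/methods.md.
    """

    # trachea geometry (diameter = 10**1.3094, the generation-0 value of the
    # steep log-linear diameter segment; length is an engineering default —
    # no published trachea length exists)
    trachea_diameter_mm: float = 10.0 ** 1.3094
    trachea_length_mm: float = 120.0
    #: fraction of the trachea proximal to the tracheal-bronchus take-off
    tracheal_bronchus_fraction: float = 0.75
    #: take-off angle of the tracheal bronchus from the trachea axis; it
    #: feeds the top right lobe, so it leaves slightly cranial of
    #: perpendicular instead of at the ordinary minor-daughter angle
    tracheal_bronchus_angle_deg: float = 95.0

    # daughter/parent diameter-ratio model, per planarity class
    ratio_d1_in_mean: float = 0.88
    ratio_d1_out_mean: float = 0.86
    ratio_d2_in_mean: float = 0.57
    ratio_d2_out_mean: float = 0.35
    ratio_d1_sd: float = 0.03
    ratio_d2_sd: float = 0.05

    # bifurcation-angle model (degrees), per planarity class
    angle1_in_mean_deg: float = 14.34
    angle1_out_mean_deg: float = 0.0
    angle1_sd_deg: float = 5.0
    angle2_in_mean_deg: float = 41.44
    angle2_out_mean_deg: float = 41.37
    angle2_sd_deg: float = 7.0

    #: repeating bifurcating-plane rotation pattern along each pathway
    plane_schedule: tuple[float, ...] = (0.0, 90.0, -90.0)

    # branch-length model (mm): generations 1-4 linearly decreasing, with a
    # short generation 2 (the pre-branching right mainstem); uniform beyond
    length_gen1_mm: float = 40.0
    length_gen4_mm: float = 15.0
    length_gen2_override_mm: float = 12.0
    length_distal_range_mm: tuple[float, float] = (5.0, 12.0)

    # termination
    max_generation: int = 24
    min_diameter_mm: float = 1.0

    # lumen cross-section shape
    transition_zone_fraction_range: tuple[float, float] = (0.15, 0.40)
    flow_divider_radius_range_mm: tuple[float, float] = (0.5, 1.5)
    aspect_ratio_range: tuple[float, float] = (0.9, 0.98)
    #: aspect ratio the lumen reaches at the very distal end of the
    #: transition zone (noticeably noncircular near the flow divider)
    transition_aspect_end: float = 0.6

    left_mainstem_curvature_radius_mm: float = 45.0

    # occasional major daughter indistinguishable from its parent (same
    # generation), seen for generations 5-25
    same_generation_prob: float = 0.02
    same_generation_range: tuple[int, int] = (5, 25)
    generation_tol_mm: float = 0.3

    #: planarity classification threshold used for class-conditional draws
    planarity_threshold_deg: float = 45.0

    seed: int = 0

    def validate(self) -> None:
        for name in ("ratio_d1_in_mean", "ratio_d1_out_mean",
                     "ratio_d2_in_mean", "ratio_d2_out_mean"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("ratio_d1_sd", "ratio_d2_sd", "angle1_sd_deg",
                     "angle2_sd_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.trachea_diameter_mm <= 0 or self.trachea_length_mm <= 0:
            raise ValueError("trachea dimensions must be positive")
        if not 0.0 < self.tracheal_bronchus_angle_deg < 180.0:
            raise ValueError("tracheal_bronchus_angle_deg must be in (0, 180)")
        if not 0.0 < self.tracheal_bronchus_fraction < 1.0:
            raise ValueError("tracheal_bronchus_fraction must be in (0, 1)")
        if not all(r in (0.0, 90.0, -90.0) for r in self.plane_schedule):
            raise ValueError("plane_schedule entries must be in {0, +90, -90}")
        if self.min_diameter_mm <= 0 and self.max_generation is None:
            raise ValueError("non-terminating growth: set min_diameter_mm > 0 "
                             "or a finite max_generation")
        if self.min_diameter_mm <= 0:
            raise ValueError("min_diameter_mm must be positive")
        if self.max_generation < 1:
            raise ValueError("max_generation must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        d = dict(d)
        for key in ("plane_schedule", "length_distal_range_mm",
                    "transition_zone_fraction_range",
                    "flow_divider_radius_range_mm", "aspect_ratio_range",
                    "same_generation_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def noise_free(self) -> "GeneratorParams":
        """Copy with every stochastic spread collapsed to zero (the class
        means are emitted exactly; lengths distal of generation 4 and lumen
        shape collapse to their range midpoints)."""
        lo, hi = self.length_distal_range_mm
        tz = self.transition_zone_fraction_range
        fd = self.flow_divider_radius_range_mm
        ar = self.aspect_ratio_range
        mid = lambda r: (0.5 * (r[0] + r[1]),) * 2
        return replace(
            self, ratio_d1_sd=0.0, ratio_d2_sd=0.0, angle1_sd_deg=0.0,
            angle2_sd_deg=0.0, same_generation_prob=0.0,
            length_distal_range_mm=(0.5 * (lo + hi),) * 2,
            transition_zone_fraction_range=mid(tz),
            flow_divider_radius_range_mm=mid(fd),
            aspect_ratio_range=mid(ar),
        )


# ---------------------------------------------------------------------------
# random draws (single stream, documented order)
# ---------------------------------------------------------------------------

def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    """Truncated-normal draw by rejection; sd == 0 returns the clipped mean.

    One rejection loop per draw keeps the stream order documented: every
    accepted value consumes >= 1 normal variate.
    """
    if sd == 0.0:
        return float(np.clip(mean, lo, hi))
    for _ in range(10000):
        x = rng.normal(mean, sd)
        if lo < x < hi or (x == lo == hi):
            return float(x)
    return float(np.clip(mean, lo, hi))


def _uniform(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    if hi == lo:
        return float(lo)
    return float(rng.uniform(lo, hi))


# ---------------------------------------------------------------------------
# tree generation
# ---------------------------------------------------------------------------

@dataclass
class _Sprout:
    """A branch waiting to be expanded."""
    branch_id: str
    end_point: np.ndarray
    direction: np.ndarray
    diameter_mm: float
    generation: int
    schedule_index: int
    lateral_sign: float
    #: side of the next major-daughter deflection; alternates at in-plane
    #: bifurcations so the monopodial pathway zigzags slightly but keeps its
    #: general direction instead of drifting steadily off course
    major_side: float = 1.0


def _draw_length(rng: np.random.Generator, generation: int,
                 p: GeneratorParams) -> float:
    if generation <= 0:
        raise ValueError("generation-0 lengths are set by the trachea model")
    if generation == 2:
        return p.length_gen2_override_mm
    if generation <= 4:
        t = (generation - 1) / 3.0
        return p.length_gen1_mm + t * (p.length_gen4_mm - p.length_gen1_mm)
    return _uniform(rng, p.length_distal_range_mm)


def _draw_lumen(rng: np.random.Generator, p: GeneratorParams) -> dict:
    return {
        "transition_zone_fraction": _uniform(rng, p.transition_zone_fraction_range),
        "aspect_ratio_outside": _uniform(rng, p.aspect_ratio_range),
        "flow_divider_radius_mm": _uniform(rng, p.flow_divider_radius_range_mm),
        "transition_aspect_end": p.transition_aspect_end,
    }


def _lateral_frame(u: np.ndarray, lateral_sign: float,
                   rotation_deg: float) -> np.ndarray:
    """Unit vector, perpendicular to ``u``, along which the minor daughter
    tilts.  For an in-plane bifurcation (rotation 0) it lies in the reference
    plane on the pathway's lateral side; otherwise it is that vector rotated
    about the pathway by the scheduled plane rotation."""
    w0 = np.cross(_REF_NORMAL, u)
    n = np.linalg.norm(w0)
    if n < 1e-9:
        # pathway parallel to the reference normal: any perpendicular works
        w0 = np.cross(u, np.array([1.0, 0.0, 0.0]))
        n = np.linalg.norm(w0)
        if n < 1e-9:
            w0 = np.cross(u, np.array([0.0, 0.0, 1.0]))
            n = np.linalg.norm(w0)
    w0 = w0 / n
    if rotation_deg == 0.0:
        return lateral_sign * w0
    return rotate_about_axis(w0, u, rotation_deg)


def generate_tree(params: GeneratorParams | None = None,
                  seed: int | None = None) -> AirwayTree:
    """Grow one synthetic pig airway tree; deterministic given the seed.

    Per-branch ground truth (planarity class, drawn ratios and angles, lumen
    shape, schedule position) is stored in ``BranchNode.meta`` so recovery
    tests can compare measured against generated quantities.
    """
    p = params if params is not None else GeneratorParams()
    p.validate()
    if seed is not None:
        p = replace(p, seed=seed)
    rng = np.random.default_rng(p.seed)

    branches: dict[str, BranchNode] = {}
    counter = [0]

    def new_branch(parent_id, start, direction, length, diameter, generation,
                   role, meta, centerline=None) -> BranchNode:
        bid = f"b{counter[0]:04d}"
        counter[0] += 1
        if centerline is None:
            centerline = np.vstack([start, start + np.asarray(direction) * length])
        b = BranchNode(
            id=bid, parent_id=parent_id, child_ids=[],
            centerline=np.asarray(centerline, dtype=float),
            diameter_mm=float(diameter),
            length_mm=polyline_length(centerline),
            generation=int(generation), role_tag=role, meta=meta,
        )
        branches[bid] = b
        if parent_id is not None:
            branches[parent_id].child_ids.append(b.id)
        return b

    u0 = _TRACHEA_AXIS.copy()
    d0 = p.trachea_diameter_mm
    l_prox = p.tracheal_bronchus_fraction * p.trachea_length_mm
    l_dist = p.trachea_length_mm - l_prox

    # proximal trachea (generation 0)
    prox = new_branch(None, np.zeros(3), u0, l_prox, d0, 0, "trachea",
                      {"lumen": _draw_lumen(rng, p), "branch_kind": "root"})

    # --- tracheal-bronchus event (pre-carinal, in the reference plane) -----
    # the distal trachea continues undeflected at the parent diameter; the
    # tracheal bronchus is a minor daughter leaving toward the right (+x)
    w_tb = _lateral_frame(u0, -1.0, 0.0)
    a2_tb = _trunc_normal(rng, p.tracheal_bronchus_angle_deg, p.angle2_sd_deg,
                          0.0, 179.0)
    r2_tb = _trunc_normal(rng, p.ratio_d2_in_mean, p.ratio_d2_sd, 1e-6, 1.0)
    rot_tb = plane_rotation_deg(u0, w_tb, _REF_NORMAL)
    prox.meta["bifurcation"] = {
        "true_class": "in_plane", "schedule_rotation_deg": 0.0,
        "plane_rotation_deg": rot_tb, "true_d1_over_D": 1.0,
        "true_d2_over_D": r2_tb, "true_angle1_deg": 0.0,
        "true_angle2_deg": a2_tb, "lateral": w_tb.tolist(),
    }
    end_prox = prox.centerline[-1]
    dist = new_branch(prox.id, end_prox, u0, l_dist, d0, 0, "trachea",
                      {"lumen": _draw_lumen(rng, p), "branch_kind": "major",
                       "true_ratio": 1.0, "true_angle_deg": 0.0})
    tb_dir = unit(math.cos(math.radians(a2_tb)) * u0
                  + math.sin(math.radians(a2_tb)) * w_tb)
    tb_len = _draw_length(rng, 1, p)
    tb = new_branch(prox.id, end_prox, tb_dir, tb_len, r2_tb * d0, 1,
                    "tracheal_bronchus",
                    {"lumen": _draw_lumen(rng, p), "branch_kind": "minor",
                     "true_ratio": r2_tb, "true_angle_deg": a2_tb})

    # --- main carina (in the reference plane) ------------------------------
    # right mainstem = major daughter (deflects toward +x), left mainstem =
    # minor daughter (leaves toward -x on a ~45 mm arc)
    w_car = _lateral_frame(u0, +1.0, 0.0)  # points toward -x
    r1 = _trunc_normal(rng, p.ratio_d1_in_mean, p.ratio_d1_sd, 1e-6, 1.0)
    r2 = _trunc_normal(rng, p.ratio_d2_in_mean, p.ratio_d2_sd, 1e-6, r1)
    a1 = _trunc_normal(rng, p.angle1_in_mean_deg, p.angle1_sd_deg, 0.0, 90.0)
    a2 = _trunc_normal(rng, p.angle2_in_mean_deg, p.angle2_sd_deg, 0.0, 90.0)
    dist.meta["bifurcation"] = {
        "true_class": "in_plane", "schedule_rotation_deg": 0.0,
        "plane_rotation_deg": plane_rotation_deg(u0, w_car, _REF_NORMAL),
        "true_d1_over_D": r1, "true_d2_over_D": r2,
        "true_angle1_deg": a1, "true_angle2_deg": a2,
        "lateral": w_car.tolist(),
    }
    carina = dist.centerline[-1]
    rm_dir = unit(math.cos(math.radians(a1)) * u0
                  - math.sin(math.radians(a1)) * w_car)
    lm_dir = unit(math.cos(math.radians(a2)) * u0
                  + math.sin(math.radians(a2)) * w_car)
    rm_len = _draw_length(rng, 1, p)
    lm_len = _draw_length(rng, 1, p)
    rm = new_branch(dist.id, carina, rm_dir, rm_len, r1 * d0, 1,
                    "right_mainstem",
                    {"lumen": _draw_lumen(rng, p), "branch_kind": "major",
                     "true_ratio": r1, "true_angle_deg": a1})
    lm_line = _arc_centerline(carina, lm_dir, lm_len,
                              p.left_mainstem_curvature_radius_mm)
    lm = new_branch(dist.id, carina, lm_dir, lm_len, r2 * d0, 1,
                    "left_mainstem",
                    {"lumen": _draw_lumen(rng, p), "branch_kind": "minor",
                     "true_ratio": r2, "true_angle_deg": a2},
                    centerline=lm_line)
    lm_end_dir = unit(lm_line[-1] - lm_line[-2])

    queue: deque[_Sprout] = deque()
    queue.append(_Sprout(tb.id, tb.centerline[-1], tb_dir, tb.diameter_mm,
                         1, 0, -1.0))
    queue.append(_Sprout(rm.id, rm.centerline[-1], rm_dir, rm.diameter_mm,
                         1, 0, -1.0))
    queue.append(_Sprout(lm.id, lm.centerline[-1], lm_end_dir, lm.diameter_mm,
                         1, 0, +1.0))

    schedule = p.plane_schedule
    while queue:
        s = queue.popleft()
        if s.diameter_mm < p.min_diameter_mm or s.generation >= p.max_generation:
            continue
        theta = schedule[s.schedule_index % len(schedule)]
        w = _lateral_frame(s.direction, s.lateral_sign, theta)
        rot = plane_rotation_deg(s.direction, w, _REF_NORMAL)
        in_plane = abs(rot) < p.planarity_threshold_deg
        cls = "in_plane" if in_plane else "out_of_plane"

        # draw order per bifurcation: d1/D, d2/D, angle1, angle2,
        # [same-generation event], then per child: length, lumen shape
        m1 = p.ratio_d1_in_mean if in_plane else p.ratio_d1_out_mean
        m2 = p.ratio_d2_in_mean if in_plane else p.ratio_d2_out_mean
        r1 = _trunc_normal(rng, m1, p.ratio_d1_sd, 1e-6, 1.0)
        r2 = _trunc_normal(rng, m2, p.ratio_d2_sd, 1e-6, r1)
        ma1 = p.angle1_in_mean_deg if in_plane else p.angle1_out_mean_deg
        ma2 = p.angle2_in_mean_deg if in_plane else p.angle2_out_mean_deg
        a1 = _trunc_normal(rng, ma1, p.angle1_sd_deg, 0.0, 90.0)
        a2 = _trunc_normal(rng, ma2, p.angle2_sd_deg, 0.0, 90.0)

        g_major = s.generation + 1
        g_minor = s.generation + 1
        lo, hi = p.same_generation_range
        if lo <= s.generation <= hi and p.same_generation_prob > 0:
            if rng.random() < p.same_generation_prob:
                # major daughter indistinguishable from its parent
                g_major = s.generation
                r1 = (s.diameter_mm - rng.uniform(0.0, p.generation_tol_mm)) \
                    / s.diameter_mm
                r2 = min(r2, r1)

        u = s.direction
        maj_dir = unit(math.cos(math.radians(a1)) * u
                       - s.major_side * math.sin(math.radians(a1)) * w)
        min_dir = unit(math.cos(math.radians(a2)) * u
                       + math.sin(math.radians(a2)) * w)

        branches[s.branch_id].meta["bifurcation"] = {
            "true_class": cls, "schedule_rotation_deg": float(theta),
            "plane_rotation_deg": rot, "true_d1_over_D": r1,
            "true_d2_over_D": r2, "true_angle1_deg": a1, "true_angle2_deg": a2,
            "lateral": w.tolist(),
        }

        l_major = _draw_length(rng, g_major if g_major > 0 else 1, p)
        lum_major = _draw_lumen(rng, p)
        l_minor = _draw_length(rng, g_minor, p)
        lum_minor = _draw_lumen(rng, p)

        major = new_branch(
            s.branch_id, s.end_point, maj_dir, l_major, r1 * s.diameter_mm,
            g_major, "other",
            {"lumen": lum_major, "branch_kind": "major", "true_ratio": r1,
             "true_angle_deg": a1, "schedule_index": s.schedule_index})
        minor = new_branch(
            s.branch_id, s.end_point, min_dir, l_minor, r2 * s.diameter_mm,
            g_minor, "other",
            {"lumen": lum_minor, "branch_kind": "minor", "true_ratio": r2,
             "true_angle_deg": a2, "schedule_index": 0})

        next_side = -s.major_side if in_plane else s.major_side
        queue.append(_Sprout(major.id, major.centerline[-1], maj_dir,
                             major.diameter_mm, g_major,
                             (s.schedule_index + 1) % len(schedule),
                             s.lateral_sign, next_side))
        queue.append(_Sprout(minor.id, minor.centerline[-1], min_dir,
                             minor.diameter_mm, g_minor, 0, s.lateral_sign))

    tree = AirwayTree(
        branches=branches, root_id=prox.id,
        reference_plane={"normal": _REF_NORMAL.tolist(), "point": [0.0, 0.0, 0.0]},
    )
    tree.frame["seed"] = int(p.seed)
    return tree


def _arc_centerline(start: np.ndarray, tangent: np.ndarray, length: float,
                    radius: float, step_mm: float = 2.0) -> np.ndarray:
    """Circular arc in the reference (x-z) plane, bending the initial tangent
    back toward the caudal (-z) direction, sampled every ~2 mm."""
    n = max(2, int(math.ceil(length / step_mm)) + 1)
    svals = np.linspace(0.0, length, n)
    # center of curvature: 90 degrees from the tangent on the bending side
    center = start + radius * rotate_about_axis(tangent, _REF_NORMAL, -90.0)
    pts = np.empty((n, 3))
    for i, s in enumerate(svals):
        pts[i] = center + rotate_about_axis(start - center, _REF_NORMAL,
                                            -math.degrees(s / radius))
    return pts


def find_collisions(tree: AirwayTree, clearance_mm: float = 0.0,
                    step_mm: float = 2.0) -> list[tuple[str, str]]:
    """Pairs of non-adjacent branches whose lumens touch or overlap.

    The generator draws geometry without space-filling constraints, so
    sibling subtrees can occasionally intersect; masks rasterized from such
    trees contain fused lumens that no segmentation could separate.  This
    check lets callers screen specimens before measurement-fidelity studies.
    Branches sharing a junction (parent/child/sibling) are exempt.
    """
    from ._geom import resample_polyline

    ids = sorted(tree.branches)
    samples = {}
    radii = {}
    for bid in ids:
        b = tree.branches[bid]
        pts = resample_polyline(b.centerline, step_mm)
        samples[bid] = pts
        # local lumen half-width including the transition-zone widening
        r = b.diameter_mm / 2.0
        lumen = b.meta.get("lumen", {}) if isinstance(b.meta, dict) else {}
        tz = float(lumen.get("transition_zone_fraction", 0.0))
        a_end = float(lumen.get("transition_aspect_end", 1.0))
        s = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        total = s[-1] if s[-1] > 0 else 1.0
        rr = np.full(len(pts), r)
        if tz > 0 and b.child_ids:
            zone = s > total * (1.0 - tz)
            frac = (s[zone] - total * (1.0 - tz)) / (total * tz)
            rr[zone] = r / (1.0 + np.sqrt(frac) * (a_end - 1.0))
        radii[bid] = rr

    def grandparent(x: BranchNode):
        if x.parent_id is None:
            return None
        return tree.branches[x.parent_id].parent_id

    def adjacent(a: BranchNode, b: BranchNode) -> bool:
        return (a.parent_id == b.id or b.parent_id == a.id
                or (a.parent_id is not None and a.parent_id == b.parent_id)
                or grandparent(a) == b.id or grandparent(b) == a.id)

    hits = []
    for i, ai in enumerate(ids):
        a = tree.branches[ai]
        for bi in ids[i + 1:]:
            b = tree.branches[bi]
            if adjacent(a, b):
                continue
            pa, pb = samples[ai], samples[bi]
            dist = np.sqrt(np.sum(
                (pa[:, None, :] - pb[None, :, :]) ** 2, axis=-1))
            limit = radii[ai][:, None] + radii[bi][None, :] + clearance_mm
            if (dist < limit).any():
                hits.append((ai, bi))
    return hits


# ---------------------------------------------------------------------------
# log-linear diameter series
# ---------------------------------------------------------------------------

#: (slope, intercept, inclusive generation range) of the three log-linear
#: diameter segments: log10 D = slope * generation + intercept
DEFAULT_SEGMENTS: list[tuple[float, float, tuple[int, int]]] = [
    (-0.0438, 1.3094, (0, 11)),
    (-0.0228, 1.0979, (12, 20)),
    (-0.0418, 1.488, (21, 24)),
]


@dataclass
class DiameterSeries:
    """Per-branch (generation, diameter) observations."""

    generation: np.ndarray  # int
    diameter_mm: np.ndarray  # positive, mm

    def __post_init__(self) -> None:
        self.generation = np.asarray(self.generation, dtype=int)
        self.diameter_mm = np.asarray(self.diameter_mm, dtype=float)
        if self.generation.shape != self.diameter_mm.shape:
            raise ValueError("generation and diameter arrays must align")
        if (self.generation < 0).any():
            raise ValueError("generations must be non-negative")
        if (self.diameter_mm <= 0).any():
            raise ValueError("diameters must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"generation": self.generation,
                             "diameter_mm": self.diameter_mm})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DiameterSeries":
        return cls(df["generation"].to_numpy(), df["diameter_mm"].to_numpy())

    @classmethod
    def from_tree(cls, tree: AirwayTree) -> "DiameterSeries":
        gens, diams = [], []
        for b in tree.iter_branches():
            if b.generation is None:
                raise ValueError(f"branch {b.id} has no generation assigned")
            gens.append(b.generation)
            diams.append(b.diameter_mm)
        return cls(np.asarray(gens), np.asarray(diams))


def generate_diameter_series(
    segment_coeffs: list[tuple[float, float, tuple[int, int]]] | None = None,
    noise_sd_log10: float = 0.0,
    n_per_generation: int = 3,
    seed: int = 0,
) -> DiameterSeries:
    """Diameters drawn from piecewise log-linear models with log-normal noise.

    For each generation g inside each (slope, intercept, (g_lo, g_hi)) range,
    emits ``n_per_generation`` samples 10**(slope*g + intercept + eps) with
    eps ~ Normal(0, noise_sd_log10); zero noise gives exact model values.
    """
    if segment_coeffs is None:
        segment_coeffs = DEFAULT_SEGMENTS
    if noise_sd_log10 < 0:
        raise ValueError("noise_sd_log10 must be >= 0")
    if n_per_generation < 1:
        raise ValueError("n_per_generation must be >= 1")
    covered: set[int] = set()
    for _, _, (glo, ghi) in segment_coeffs:
        if ghi < glo:
            raise ValueError(f"invalid generation range ({glo}, {ghi})")
        rng_set = set(range(int(glo), int(ghi) + 1))
        if covered & rng_set:
            raise ValueError("segment generation ranges overlap")
        covered |= rng_set
    rng = np.random.default_rng(seed)
    gens, diams = [], []
    for slope, intercept, (glo, ghi) in segment_coeffs:
        for g in range(int(glo), int(ghi) + 1):
            for _ in range(n_per_generation):
                eps = rng.normal(0.0, noise_sd_log10) if noise_sd_log10 > 0 else 0.0
                gens.append(g)
                diams.append(10.0 ** (slope * g + intercept + eps))
    return DiameterSeries(np.asarray(gens), np.asarray(diams))


# ---------------------------------------------------------------------------
# tube phantoms
# ---------------------------------------------------------------------------

def generate_tube_phantom(diameter_mm: float, length_mm: float,
                          voxel_mm: float | tuple[float, float, float] = 0.4,
                          axis: tuple[float, float, float] = (0.0, 0.0, 1.0)):
    """Binary mask of a straight cylinder (the segmentation-validation tube).

    Voxel centers strictly inside the cylinder are foreground; the volume is
    padded by at least two background voxels on every side.
    """
    from .voxelize import VoxelMask  # local import: voxelize depends on tree only

    spacing = np.asarray(
        voxel_mm if np.ndim(voxel_mm) else (voxel_mm,) * 3, dtype=float)
    if (spacing <= 0).any():
        raise ValueError("voxel spacing must be positive")
    if diameter_mm < 2.0 * float(spacing.max()):
        raise ValueError(
            f"diameter {diameter_mm} mm is below the resolvability limit of "
            f"2 voxels ({2 * spacing.max():.2f} mm)")
    if length_mm <= diameter_mm:
        raise ValueError("length must exceed diameter")
    a = unit(np.asarray(axis, dtype=float))
    r = diameter_mm / 2.0

    p0 = np.zeros(3)
    p1 = a * length_mm
    # quarter-voxel grid offset: keeps the axis off the symmetric mid-grid
    # position where iterative thinning of an even-extent footprint is
    # degenerate (ties erode from both sides simultaneously)
    lo = np.minimum(p0, p1) - r - 2.0 * spacing - 0.25 * spacing
    hi = np.maximum(p0, p1) + r + 2.0 * spacing
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    origin = lo

    idx = [np.arange(n) for n in shape]
    xs = origin[0] + idx[0] * spacing[0]
    ys = origin[1] + idx[1] * spacing[1]
    zs = origin[2] + idx[2] * spacing[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    P = np.stack([X, Y, Z], axis=-1) - p0
    t = P @ a
    radial2 = np.maximum(np.einsum("...k,...k", P, P) - t * t, 0.0)
    mask = (radial2 <= r * r) & (t >= 0.0) & (t <= length_mm)
    return VoxelMask(data=mask, spacing_mm=spacing, origin_mm=origin)
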