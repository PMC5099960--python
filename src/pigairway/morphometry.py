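"""Morphometric analysis of airway trees.

Implements the measurement procedures used on the pig bronchial tree:

* **generation assignment** — branches sorted by diameter descending and
  grouped greedily with a 0.3 mm tolerance (the diameter-measurement
  uncertainty), so near-identical diameters share a generation even when the
  bifurcations are asymmetric; the trachea is generation 0;
* **bifurcation geometry** — for each bifurcation, parent diameter D, major
  and minor daughter diameters d1 >= d2, angle 1 (parent to major daughter),
  angle 2 (parent to minor daughter), and the signed rotation of the
  bifurcating plane relative to the trachea-mainstem reference plane, folded
  to [-90, +90] and thresholded at 45 degrees into in-plane and out-of-plane
  (positive/negative) classes;
* **plane-rotation series** — the rotation sequence along a monopodial
  pathway (follow major daughters from a mainstem), which in the pig cycles
  0, +90, -90;
* **piecewise log-linear regression** of log10 diameter on generation with
  fixed breakpoints at generations 11 and 20, fitted independently per
  segment by OLS with 95% t-based confidence intervals;
* **class-stratified summaries** of angles and diameter ratios;
* **transition-zone quantification** from a min/max diameter profile.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from ._geom import (angle_between_deg, fit_line_direction, plane_rotation_deg,
                    trim_polyline)
from .extract import DiameterProfile, _portion
from .generator import DiameterSeries
from .tree import AirwayTree, BifurcationRecord

__all__ = [
    "SegmentFit",
    "MorphometrySummary",
    "assign_generations",
    "compute_bifurcations",
    "plane_rotation_series",
    "mainstem_pathway_series",
    "fit_loglinear_segments",
    "summarize_morphometry",
    "transition_zone_fraction",
    "DEFAULT_BREAKPOINTS",
]

DEFAULT_BREAKPOINTS = (11, 20)
DEFAULT_GENERATION_TOL_MM = 0.3
DEFAULT_PLANARITY_THRESHOLD_DEG = 45.0


# ---------------------------------------------------------------------------
# generation assignment
# ---------------------------------------------------------------------------

def assign_generations(tree: AirwayTree,
                       tol_mm: float = DEFAULT_GENERATION_TOL_MM) -> AirwayTree:
    """Assign Weibel-style generations by descending-diameter grouping.

    The trachea is generation 0.  All other branches are sorted by diameter
    descending; a new group starts at the largest ungrouped branch and every
    branch within ``tol_mm`` of that group leader joins it; groups are
    numbered 1, 2, ... in order.  Finally each branch's generation is clamped
    to be >= its parent's (a daughter indistinguishable from its parent keeps
    the parent's generation, it can never become more proximal).

    Returns a new tree; the input is never mutated.  Deterministic and
    invariant to branch-id ordering.
    """
    if tol_mm < 0:
        raise ValueError("tol_mm must be >= 0")
    for b in tree.branches.values():
        if b.diameter_mm is None or not (b.diameter_mm > 0):
            raise ValueError(f"branch {b.id} has unset or nonpositive diameter")

    out = copy.deepcopy(tree)
    trachea = [b for b in out.branches.values() if b.role_tag == "trachea"]
    others = [b for b in out.branches.values() if b.role_tag != "trachea"]
    for b in trachea:
        b.generation = 0

    # greedy grouping on the diameter-sorted list (ties broken by id so the
    # result is independent of input ordering)
    others.sort(key=lambda b: (-b.diameter_mm, b.id))
    group = 0
    leader = None
    for b in others:
        if leader is None or (leader - b.diameter_mm) > tol_mm:
            group += 1
            leader = b.diameter_mm
        b.generation = group

    # clamp: child generation >= parent generation (top-down)
    for b in out.iter_branches():
        if b.parent_id is not None:
            pg = out.branches[b.parent_id].generation
            if pg is not None and b.generation < pg:
                b.generation = pg
    return out


# ---------------------------------------------------------------------------
# bifurcation geometry
# ---------------------------------------------------------------------------

def _classify(rotation_deg: float, threshold_deg: float) -> str:
    if abs(rotation_deg) < threshold_deg:
        return "in_plane"
    return "out_of_plane_pos" if rotation_deg >= 0 else "out_of_plane_neg"


def branch_direction(branch_centerline: np.ndarray, which: str,
                     junction_trim_mm: float = 0.0,
                     curvature_tol_mm: float = 1.5) -> np.ndarray:
    """Proximal or distal branch direction by line fit.

    ``junction_trim_mm`` removes the centerline portion inside the junction
    region first (for measured trees the medial axis bends across roughly
    one parent diameter while crossing from the parent axis into the
    daughter lumen); the trim is capped so short branches keep an interior.
    """
    cl = np.asarray(branch_centerline, dtype=float)
    if which == "proximal":
        pts = trim_polyline(cl, junction_trim_mm, 0.0)
    else:
        pts = trim_polyline(cl, 0.0, junction_trim_mm)
    along = cl[-1] - cl[0]
    # branches are predominantly straight: fit the whole trimmed centerline
    # (longest lever arm against staircase noise); genuinely curved branches
    # (e.g. the left mainstem) fall back to the local end portion
    if _chord_deviation(pts) > curvature_tol_mm:
        pts = _portion(pts, which)
    return fit_line_direction(pts, along=along)


def _chord_deviation(pts: np.ndarray) -> float:
    """Max perpendicular distance of polyline points from their chord."""
    if pts.shape[0] < 3:
        return 0.0
    chord = pts[-1] - pts[0]
    norm = np.linalg.norm(chord)
    if norm < 1e-12:
        return float("inf")
    chord = chord / norm
    rel = pts - pts[0]
    perp = rel - np.outer(rel @ chord, chord)
    return float(np.linalg.norm(perp, axis=1).max())


def compute_bifurcations(
    tree: AirwayTree,
    planarity_threshold_deg: float = DEFAULT_PLANARITY_THRESHOLD_DEG,
    strict: bool = True,
) -> list[BifurcationRecord]:
    """Per-bifurcation geometry for every internal branch of the tree.

    The major daughter is the larger-diameter one (ties broken toward the
    smaller branch id); angles are measured between the parent's distal
    direction and each daughter's proximal direction, estimated by line fits
    over the end 30% of the centerlines after trimming one parent diameter
    of junction region.  With ``strict=False`` internal branches that do not
    have exactly two children (possible in trees measured from masks with
    fused branches) are skipped with a warning instead of raising.
    """
    import warnings as _warnings

    n_ref = tree.reference_normal()
    records: list[BifurcationRecord] = []
    for parent in tree.iter_branches():
        children = tree.children(parent.id)
        if not children:
            continue
        if len(children) != 2:
            if strict:
                raise ValueError(
                    f"branch {parent.id} has {len(children)} children; the "
                    "tree must be binary (the trachea's two events are "
                    "modeled as stacked segments)")
            _warnings.warn(f"skipping non-binary junction at {parent.id} "
                           f"({len(children)} children)", stacklevel=2)
            continue
        major, minor = sorted(children, key=lambda c: (-c.diameter_mm, c.id))
        trim = parent.diameter_mm
        u = branch_direction(parent.centerline, "distal", trim)
        v_major = branch_direction(major.centerline, "proximal", trim)
        v_minor = branch_direction(minor.centerline, "proximal", trim)
        try:
            rot = plane_rotation_deg(u, v_minor, n_ref)
        except ValueError:
            if strict:
                raise
            _warnings.warn(f"skipping degenerate bifurcation at {parent.id} "
                           "(minor parallel to parent)", stacklevel=2)
            continue
        records.append(BifurcationRecord(
            parent_id=parent.id, major_id=major.id, minor_id=minor.id,
            D_mm=parent.diameter_mm, d1_mm=major.diameter_mm,
            d2_mm=minor.diameter_mm,
            angle1_deg=angle_between_deg(u, v_major),
            angle2_deg=angle_between_deg(u, v_minor),
            plane_rotation_deg=rot,
            planarity=_classify(rot, planarity_threshold_deg)))
    return records


def plane_rotation_series(tree: AirwayTree, pathway_id: str,
                          planarity_threshold_deg: float =
                          DEFAULT_PLANARITY_THRESHOLD_DEG,
                          strict: bool = True) -> list[tuple[int, float]]:
    """Bifurcating-plane rotations along the monopodial pathway that starts
    at ``pathway_id`` and follows major daughters, in order from the first
    bifurcation; empty if the pathway never bifurcates."""
    if pathway_id not in tree.branches:
        raise KeyError(f"no branch {pathway_id!r} in tree")
    by_parent = {r.parent_id: r for r in
                 compute_bifurcations(tree, planarity_threshold_deg,
                                      strict=strict)}
    series: list[tuple[int, float]] = []
    bid = pathway_id
    k = 1
    while bid in by_parent:
        rec = by_parent[bid]
        series.append((k, rec.plane_rotation_deg))
        bid = rec.major_id
        k += 1
    return series


def mainstem_pathway_series(tree: AirwayTree, side: str = "right",
                            **kw) -> list[tuple[int, float]]:
    """Convenience: the plane-rotation series of the right or left mainstem."""
    role = f"{side}_mainstem"
    for b in tree.branches.values():
        if b.role_tag == role:
            return plane_rotation_series(tree, b.id, **kw)
    raise KeyError(f"tree has no branch with role {role!r}")


# ---------------------------------------------------------------------------
# piecewise log-linear regression
# ---------------------------------------------------------------------------

@dataclass
class SegmentFit:
    """One log-linear segment: log10(D_mm) = slope * generation + intercept."""

    segment_index: int
    generation_range: tuple[int, int]
    slope: float
    intercept: float
    ci_slope_halfwidth: float | None
    ci_intercept_halfwidth: float | None
    r2: float
    n: int
    ci_flagged: bool = False  # True when n < 3 left no df for a CI

    def to_dict(self) -> dict:
        return {
            "segment_index": self.segment_index,
            "generation_range": list(self.generation_range),
            "slope": self.slope, "intercept": self.intercept,
            "ci_slope_halfwidth": self.ci_slope_halfwidth,
            "ci_intercept_halfwidth": self.ci_intercept_halfwidth,
            "r2": self.r2, "n": self.n, "ci_flagged": self.ci_flagged,
        }


def fit_loglinear_segments(series: DiameterSeries,
                           breakpoints=DEFAULT_BREAKPOINTS) -> list[SegmentFit]:
    """Independent per-segment OLS of log10 diameter on generation.

    Segments are [0, b1], [b1+1, b2], [b2+1, inf) with the default
    breakpoints 11 and 20 (the steep early drop runs up to generation 11,
    inclusive).  Segments the series does not reach are skipped; a non-empty
    segment with fewer than 2 points is an error; with exactly 2 points the
    fit is returned without confidence intervals and flagged.
    """
    b1, b2 = breakpoints
    if not (0 <= b1 < b2):
        raise ValueError("breakpoints must satisfy 0 <= b1 < b2")
    gen = np.asarray(series.generation)
    logd = np.log10(np.asarray(series.diameter_mm))
    bounds = [(0, b1), (b1 + 1, b2), (b2 + 1, int(gen.max()) if len(gen) else b2 + 1)]
    fits: list[SegmentFit] = []
    for k, (lo, hi) in enumerate(bounds, start=1):
        sel = (gen >= lo) & (gen <= hi)
        n = int(sel.sum())
        if n == 0:
            continue
        if n < 2:
            raise ValueError(f"segment {k} (generations {lo}-{hi}) has only "
                             f"{n} point(s); need >= 2")
        x, y = gen[sel].astype(float), logd[sel]
        if np.ptp(x) == 0:
            raise ValueError(f"segment {k} covers a single generation; the "
                             "slope is not identifiable")
        model = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = model.params
        if n >= 3:
            tcrit = stats.t.ppf(0.975, df=n - 2)
            se_int, se_slope = model.bse
            ci_slope = float(tcrit * se_slope)
            ci_int = float(tcrit * se_int)
            flagged = False
        else:
            ci_slope = ci_int = None
            flagged = True
        fits.append(SegmentFit(
            segment_index=k, generation_range=(lo, hi),
            slope=float(slope), intercept=float(intercept),
            ci_slope_halfwidth=ci_slope, ci_intercept_halfwidth=ci_int,
            r2=float(model.rsquared) if np.isfinite(model.rsquared) else 1.0,
            n=n, ci_flagged=flagged))
    return fits


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _mean_ci(values: np.ndarray) -> dict:
    """Mean with a symmetric 95% Student-t confidence-interval halfwidth."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    mean = float(v.mean()) if n else float("nan")
    if n >= 2:
        sd = float(v.std(ddof=1))
        half = float(stats.t.ppf(0.975, df=n - 1) * sd / np.sqrt(n))
    else:
        half = None
    return {"mean": mean, "ci95_halfwidth": half, "n": n}


@dataclass
class MorphometrySummary:
    """Class-stratified means/CIs of the bifurcation geometry plus per-
    generation length and diameter tables."""

    per_class: dict            # class -> quantity -> {mean, ci95_halfwidth, n}
    pooled_d1_over_D: dict     # {mean, ci95_halfwidth, n}
    counts: dict               # planarity label -> count
    per_generation: dict | None  # generation -> {n, length, diameter}

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "pooled_d1_over_D": self.pooled_d1_over_D,
            "counts": self.counts,
            "per_generation": self.per_generation,
        }


def summarize_morphometry(records: list[BifurcationRecord],
                          tree: AirwayTree | None = None) -> MorphometrySummary:
    """Stratify bifurcation records into in-plane and out-of-plane (both
    signs pooled) and summarize angles and diameter ratios with 95% t CIs."""
    if not records:
        raise ValueError("no bifurcation records to summarize")
    groups = {"in_plane": [], "out_of_plane": []}
    counts: dict[str, int] = {}
    for r in records:
        counts[r.planarity] = counts.get(r.planarity, 0) + 1
        key = "in_plane" if r.planarity == "in_plane" else "out_of_plane"
        groups[key].append(r)

    per_class = {}
    for cls, rs in groups.items():
        if not rs:
            continue
        per_class[cls] = {
            "angle1_deg": _mean_ci([r.angle1_deg for r in rs]),
            "angle2_deg": _mean_ci([r.angle2_deg for r in rs]),
            "d1_over_D": _mean_ci([r.d1_mm / r.D_mm for r in rs]),
            "d2_over_D": _mean_ci([r.d2_mm / r.D_mm for r in rs]),
        }
    pooled = _mean_ci([r.d1_mm / r.D_mm for r in records])

    per_generation = None
    if tree is not None:
        per_generation = {}
        gens: dict[int, list] = {}
        for b in tree.iter_branches():
            if b.generation is not None:
                gens.setdefault(b.generation, []).append(b)
        for g in sorted(gens):
            bs = gens[g]
            per_generation[int(g)] = {
                "n": len(bs),
                "length_mm": _mean_ci([b.length_mm for b in bs]),
                "diameter_mm": _mean_ci([b.diameter_mm for b in bs]),
            }
    return MorphometrySummary(per_class=per_class, pooled_d1_over_D=pooled,
                              counts=counts, per_generation=per_generation)


# ---------------------------------------------------------------------------
# transition zone
# ---------------------------------------------------------------------------

def transition_zone_fraction(profile: DiameterProfile,
                             aspect_threshold: float = 0.9) -> float:
    """Fraction of branch arc length, contiguous from the distal end, where
    the cross-section aspect ratio falls below the threshold."""
    if len(profile) < 3:
        raise ValueError("profile needs at least 3 samples")
    aspect = profile.aspect
    pos = profile.positions_mm
    total = pos[-1] - pos[0]
    if total <= 0:
        raise ValueError("profile has zero extent")
    k = len(aspect)
    while k > 0 and aspect[k - 1] < aspect_threshold:
        k -= 1
    if k == len(aspect):
        return 0.0
    return float((pos[-1] - pos[k]) / total)
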