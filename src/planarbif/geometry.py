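"""Bifurcation extraction and geometric statistics.

A *bifurcation* is a degree-3 internal vertex (the apex) together with the
three points it connects to: one parent and two daughters.  Its flatness is
quantified by the *cone angle*: the full aperture of the right circular cone
with apex at the branching point whose surface contains the three branch
directions.  A flat (planar) bifurcation has a cone angle of 180 degrees.

The cone angle is computed via the circumscribed circle of the three unit
branch directions: normalising each neighbour point to unit distance from the
apex places the three direction tips on the unit sphere; the circle through
them has circumradius rho, and the cone aperture is ``2*arcsin(rho)``.

The *bifurcation plane* is the plane through the three neighbour points (the
apex is deliberately excluded: the apex lies on that plane iff the bifurcation
is planar).  Orientation statistics between consecutive bifurcation planes use
the *fold angle* between plane normals, reduced to [0, 90] degrees since a
plane's normal sign is arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .tree_io import ReducedTree, SOMA_LABEL

#: Cone-angle window treated as "close to planar" (degrees).
PLANAR_WINDOW = (160.0, 180.0)
#: Branch-angle window treated as "close to the Steiner 120 degrees".
STEINER_WINDOW = (110.0, 130.0)

#: Unit-triangle area below which a direction triple is degenerate.
DEGENERATE_AREA = 1e-12

EndpointMode = Literal["reduced_node", "first_segment"]

__all__ = [
    "Bifurcation",
    "ConeAngleResult",
    "BifurcationPlane",
    "extract_bifurcations",
    "cone_angle",
    "cone_angles_from_units",
    "branch_angles",
    "bifurcation_plane",
    "consecutive_plane_pairs",
    "plane_fold_angle",
    "PLANAR_WINDOW",
    "STEINER_WINDOW",
]


@dataclass(frozen=True)
class Bifurcation:
    """Apex plus its parent and two daughter points, with provenance ids."""

    apex: np.ndarray
    parent_point: np.ndarray
    daughter1_point: np.ndarray
    daughter2_point: np.ndarray
    apex_id: int = -1
    parent_id: int = -1
    daughter1_id: int = -1
    daughter2_id: int = -1
    endpoint_mode: str = "reduced_node"

    def neighbour_points(self) -> np.ndarray:
        return np.array(
            [self.parent_point, self.daughter1_point, self.daughter2_point]
        )

    def unit_directions(self) -> np.ndarray:
        """Unit vectors from the apex towards parent, daughter1, daughter2."""
        d = self.neighbour_points() - self.apex
        norms = np.linalg.norm(d, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("neighbour point coincides with apex")
        return d / norms


@dataclass(frozen=True)
class ConeAngleResult:
    cone_angle_deg: float
    unit_directions: np.ndarray
    circumradius: float
    axis: np.ndarray
    degenerate: bool = False


@dataclass(frozen=True)
class BifurcationPlane:
    normal: np.ndarray
    points: np.ndarray
    degenerate: bool = False


# ---------------------------------------------------------------------------
# core angle computations (vectorised; used both per-bifurcation and by the
# Monte-Carlo null samplers)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def cone_angles_from_units(b1, b2, b3, return_parts: bool = False):
    """Cone angles (degrees) for batches of unit direction triples.

    Uses the circumradius of the 3-D triangle spanned by the direction tips:
    ``rho = abc / (4K)`` with side lengths a, b, c and area K, then aperture
    ``2*arcsin(min(rho, 1))``.  Clamping guards the near-flat case where rho
    exceeds 1 by floating error.  Triples with ``K < 1e-12`` are degenerate
    (NaN angle, flagged mask).
    """
    b1 = np.asarray(b1, float)
    b2 = np.asarray(b2, float)
    b3 = np.asarray(b3, float)
    cross = np.cross(b2 - b1, b3 - b1)
    area = 0.5 * np.linalg.norm(cross, axis=-1)
    a = np.linalg.norm(b2 - b3, axis=-1)
    b = np.linalg.norm(b1 - b3, axis=-1)
    c = np.linalg.norm(b1 - b2, axis=-1)
    degenerate = area < DEGENERATE_AREA
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(degenerate, np.nan, a * b * c / (4.0 * area))
    rho_c = np.clip(rho, 0.0, 1.0)
    angle = np.degrees(2.0 * np.arcsin(rho_c))
    angle = np.where(degenerate, np.nan, angle)
    if not return_parts:
        return angle
    with np.errstate(invalid="ignore"):
        axis = cross / np.linalg.norm(cross, axis=-1, keepdims=True)
    # sign the axis so the three directions have non-negative projection
    h = np.sum(axis * b1, axis=-1, keepdims=True)
    axis = np.where(h < 0, -axis, axis)
    return angle, rho_c, axis, degenerate


def cone_angle(bif: Bifurcation) -> ConeAngleResult:
    """Cone angle of one bifurcation via the circumscribed-circle method.

    The three neighbour points are normalised to unit distance from the apex;
    the aperture is twice the arcsine of the circumradius of the triangle they
    span.  The cone axis is the unit normal of that triangle's plane, signed
    so every direction has a non-negative projection onto it.
    """
    units = bif.unit_directions()
    angle, rho, axis, degen = cone_angles_from_units(
        units[0], units[1], units[2], return_parts=True
    )
    return ConeAngleResult(
        cone_angle_deg=float(angle),
        unit_directions=units,
        circumradius=float(rho),
        axis=np.asarray(axis, float),
        degenerate=bool(degen),
    )


def branch_angles(bif: Bifurcation) -> tuple[float, float, float]:
    """The three pairwise angles (degrees) between branch directions:
    parent-daughter1, parent-daughter2, daughter1-daughter2."""
    u = bif.unit_directions()
    pairs = [(0, 1), (0, 2), (1, 2)]
    out = []
    for i, j in pairs:
        c = float(np.clip(np.dot(u[i], u[j]), -1.0, 1.0))
        out.append(float(np.degrees(np.arccos(c))))
    return tuple(out)


def bifurcation_plane(bif: Bifurcation) -> BifurcationPlane:
    """Plane through the three neighbour points (parent and both daughters).

    The normal is the cross product of the two in-plane difference vectors,
    normalised; its sign is unspecified, so consumers must be sign-invariant.
    A collinear triple yields a degenerate flagged result.
    """
    pts = bif.neighbour_points()
    u = pts[1] - pts[0]
    v = pts[2] - pts[0]
    n = np.cross(u, v)
    nn = np.linalg.norm(n)
    scale = np.linalg.norm(u) * np.linalg.norm(v)
    if scale == 0 or nn < 1e-12 * scale:
        return BifurcationPlane(np.full(3, np.nan), pts, degenerate=True)
    return BifurcationPlane(n / nn, pts, degenerate=False)


def plane_fold_angle(n1, n2) -> float:
    """Angle between two plane normals folded to [0, 90] degrees.

    Normal signs are arbitrary, so the angle is ``arccos(|n1 . n2|)`` on the
    normalised vectors; angles above 90 degrees fold back symmetrically.
    """
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    l1, l2 = np.linalg.norm(n1), np.linalg.norm(n2)
    if l1 == 0 or l2 == 0:
        raise ValueError("zero-length normal vector")
    c = abs(float(np.dot(n1, n2))) / (l1 * l2)
    return float(np.degrees(np.arccos(min(c, 1.0))))


# ---------------------------------------------------------------------------
# extraction from reduced trees


def extract_bifurcations(
    reduced: ReducedTree,
    endpoint_mode: EndpointMode = "reduced_node",
    exclude_soma: bool = True,
) -> list[Bifurcation]:
    """One :class:`Bifurcation` per degree-3 internal node of the reduced tree.

    The apex must have exactly two children and a parent (the root is never an
    apex; it can serve as a parent point).  Multifurcations (>2 children) are
    skipped.  In ``reduced_node`` mode the neighbour points are the adjacent
    reduced nodes (branch points or terminals); in ``first_segment`` mode they
    are the original sample points closest to the apex along each incident
    chain, which is less sensitive to branch curvature.  With ``exclude_soma``
    (default) bifurcations whose apex or any neighbour sample is a soma
    (label 1) vertex are dropped.  Bifurcations with coincident points are
    dropped silently (they cannot define directions).
    """
    tree = reduced.tree
    out: list[Bifurcation] = []
    for node in reduced.nodes:
        if node not in reduced.parent:
            continue  # root
        kids = reduced.children_of(node)
        if len(kids) != 2:
            continue
        par = reduced.parent[node]
        if endpoint_mode == "reduced_node":
            ids = (par, kids[0], kids[1])
        elif endpoint_mode == "first_segment":
            # nearest original sample along each incident chain
            up_chain = reduced.chains.get(node, [])
            pid = up_chain[-1] if up_chain else par
            did = []
            for k in kids:
                ch = reduced.chains.get(k, [])
                did.append(ch[0] if ch else k)
            ids = (pid, did[0], did[1])
        else:
            raise ValueError(f"unknown endpoint mode: {endpoint_mode!r}")
        if exclude_soma:
            lab = [int(tree.labels[tree.index_of(i)]) for i in (node, *ids)]
            if SOMA_LABEL in lab:
                continue
        apex = tree.position_of(node)
        pts = [tree.position_of(i) for i in ids]
        all_pts = [apex] + pts
        coincident = any(
            np.array_equal(all_pts[i], all_pts[j])
            for i in range(4)
            for j in range(i + 1, 4)
        )
        if coincident:
            continue
        out.append(
            Bifurcation(
                apex=apex,
                parent_point=pts[0],
                daughter1_point=pts[1],
                daughter2_point=pts[2],
                apex_id=node,
                parent_id=ids[0],
                daughter1_id=ids[1],
                daughter2_id=ids[2],
                endpoint_mode=endpoint_mode,
            )
        )
    return out


def consecutive_plane_pairs(reduced: ReducedTree) -> list[tuple[int, int]]:
    """Pairs of apex ids (outer, inner) of consecutive bifurcations.

    Two bifurcations are consecutive when a daughter point of the outer one is
    the apex of the inner one, i.e. the inner apex is a reduced child of the
    outer apex and both are degree-3 internal nodes.
    """
    is_bif = {
        node
        for node in reduced.nodes
        if node in reduced.parent and len(reduced.children_of(node)) == 2
    }
    pairs = []
    for node in reduced.nodes:
        if node not in is_bif:
            continue
        par = reduced.parent[node]
        if par in is_bif:
            pairs.append((par, node))
    return pairs
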