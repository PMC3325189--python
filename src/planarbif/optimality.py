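"""Wiring-cost framework and the planarity test of optimality.

The wiring cost of an embedded tree is the sum over its edges of per-edge
costs, each a continuous, strictly increasing function of Euclidean edge
length.  Nothing else is assumed about the cost functions, which is what
makes the planarity property general: volume, surface area, conduction delay
and power-law compromises between them are all strictly increasing in length.

The central fact, turned into an executable audit here: if the apex of a
degree-3 bifurcation does not lie on the plane through its three neighbour
points, projecting it orthogonally onto that plane strictly shortens all
three incident edges at once (each original edge is the hypotenuse of a right
triangle whose leg is the projected edge), hence strictly decreases the total
cost under every strictly increasing per-edge cost.  A tree containing such a
*deformable* off-plane bifurcation therefore cannot be wiring-cost optimal.
The audit makes no claim in the other direction, and none about topology.

A small Fermat-point solver is included as the classical one-junction
benchmark: for Euclidean (identity-cost) Steiner trees, junction edges must
meet at 120 degrees whenever the junction is interior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .geometry import Bifurcation, BifurcationPlane, bifurcation_plane, cone_angle
from .tree_io import SpatialTree

__all__ = [
    "CostModel",
    "COST_MODELS",
    "make_cost_model",
    "total_wiring_cost",
    "project_point_to_plane",
    "flatten_bifurcation",
    "FlattenResult",
    "audit_planarity",
    "PlanarityAudit",
    "iterate_flatten",
    "fermat_point",
    "FermatResult",
]


@dataclass(frozen=True)
class CostModel:
    """A per-edge cost: a continuous, strictly increasing function of edge
    length, applied symmetrically to every edge of the tree."""

    name: str
    fn: Callable[[np.ndarray], np.ndarray]

    def __call__(self, length):
        return self.fn(np.asarray(length, float))


def make_cost_model(spec: str) -> CostModel:
    """Build a cost model from a name: ``identity``, ``power:k`` (length**k,
    k > 0) or ``affine:a,b`` (a + b*length, b > 0)."""
    if spec == "identity":
        return CostModel("identity", lambda l: l)
    if spec.startswith("power:"):
        k = float(spec.split(":", 1)[1])
        if k <= 0:
            raise ValueError("power-law exponent must be positive")
        return CostModel(spec, lambda l, k=k: l**k)
    if spec.startswith("affine:"):
        a, b = (float(x) for x in spec.split(":", 1)[1].split(","))
        if b <= 0:
            raise ValueError("affine slope must be positive")
        return CostModel(spec, lambda l, a=a, b=b: a + b * l)
    raise ValueError(f"unknown cost model: {spec!r}")


#: Default registry of strictly increasing per-edge cost models.
COST_MODELS: dict[str, CostModel] = {
    "identity": make_cost_model("identity"),
    "square": make_cost_model("power:2"),
    "cube": make_cost_model("power:3"),
    "affine": make_cost_model("affine:1,1"),
}


def total_wiring_cost(tree: SpatialTree, cost: CostModel) -> float:
    """Total wiring cost: the sum over edges of the per-edge cost of the
    Euclidean edge length.  A pure function of the vertex positions."""
    return float(np.sum(cost(tree.edge_lengths())))


# ---------------------------------------------------------------------------
# projection and flattening


def project_point_to_plane(p, plane: BifurcationPlane) -> np.ndarray:
    """Orthogonal projection of ``p`` onto the plane: the unique closest
    point; the residual ``p - result`` is parallel to the plane normal."""
    if plane.degenerate:
        raise ValueError("cannot project onto a degenerate plane")
    p = np.asarray(p, float)
    n = plane.normal
    d = float(np.dot(p - plane.points[0], n))
    return p - d * n


@dataclass(frozen=True)
class FlattenResult:
    """Outcome of projecting a bifurcation apex onto its bifurcation plane."""

    original_apex: np.ndarray
    projected_apex: np.ndarray
    edge_length_deltas: np.ndarray  # new - old, per (parent, d1, d2) edge
    cost_delta: float  # new - old total over the three edges
    degenerate: bool = False
    within_region: bool = True


def flatten_bifurcation(
    bif: Bifurcation,
    cost: CostModel = COST_MODELS["identity"],
    region_oracle: Optional[Callable[[np.ndarray], bool]] = None,
) -> FlattenResult:
    """Replace the apex by its orthogonal projection onto the bifurcation
    plane and report per-edge length changes and the change in cost.

    For an off-plane apex every one of the three edge lengths strictly
    decreases (hypotenuse vs. leg of a right triangle), so the cost delta is
    strictly negative under any strictly increasing cost model.  For an apex
    already on the plane the operation is the identity.  ``region_oracle``,
    when given, is a membership predicate for the apex's allowed region; the
    result's ``within_region`` records whether the projection is admissible.
    """
    plane = bifurcation_plane(bif)
    if plane.degenerate:
        return FlattenResult(
            np.asarray(bif.apex, float),
            np.asarray(bif.apex, float),
            np.zeros(3),
            0.0,
            degenerate=True,
        )
    new_apex = project_point_to_plane(bif.apex, plane)
    pts = bif.neighbour_points()
    old_len = np.linalg.norm(pts - bif.apex, axis=1)
    new_len = np.linalg.norm(pts - new_apex, axis=1)
    delta_cost = float(np.sum(cost(new_len)) - np.sum(cost(old_len)))
    within = True if region_oracle is None else bool(region_oracle(new_apex))
    return FlattenResult(
        np.asarray(bif.apex, float),
        new_apex,
        new_len - old_len,
        delta_cost,
        degenerate=False,
        within_region=within,
    )


# ---------------------------------------------------------------------------
# tree-level audit


@dataclass
class BifurcationAuditRow:
    apex_id: int
    cone_angle_deg: float
    apex_plane_distance: float
    planar: bool
    deformable: bool
    cost_reduction: float  # achievable reduction (>= 0) if flattened


@dataclass
class PlanarityAudit:
    rows: list[BifurcationAuditRow]
    cost_model: str
    tolerance_deg: float
    verdict: str  # "not optimal" | "no planarity-based improvement"
    n_bifurcations: int = 0
    n_nonplanar: int = 0
    n_flagged: int = 0
    total_achievable_reduction: float = 0.0

    def __post_init__(self):
        self.n_bifurcations = len(self.rows)
        self.n_nonplanar = sum(1 for r in self.rows if not r.planar)
        self.n_flagged = sum(
            1 for r in self.rows if r.deformable and not r.planar
        )
        self.total_achievable_reduction = float(
            sum(r.cost_reduction for r in self.rows if r.deformable)
        )


def _graph_bifurcations(tree: SpatialTree):
    """Degree-3 internal vertices of the original graph with their direct
    neighbours (the apex and the three points it is joined to)."""
    children = tree.children_map()
    root = tree.root_id
    for vid in tree.ids:
        vid = int(vid)
        if vid == root or len(children[vid]) != 2:
            continue
        par = int(tree.parents[tree.index_of(vid)])
        k1, k2 = children[vid]
        apex = tree.position_of(vid)
        pts = (tree.position_of(par), tree.position_of(k1), tree.position_of(k2))
        if any(np.array_equal(apex, p) for p in pts):
            continue
        yield Bifurcation(
            apex=apex,
            parent_point=pts[0],
            daughter1_point=pts[1],
            daughter2_point=pts[2],
            apex_id=vid,
            parent_id=par,
            daughter1_id=k1,
            daughter2_id=k2,
            endpoint_mode="first_segment",
        )


def audit_planarity(
    tree: SpatialTree,
    cost: CostModel = COST_MODELS["identity"],
    tolerance_deg: float = 1e-6,
    region_oracle: Optional[Callable[[int, np.ndarray], bool]] = None,
) -> PlanarityAudit:
    """Audit every degree-3 vertex of the tree for planarity-based
    improvability.

    A bifurcation is *planar* when its cone angle is within ``tolerance_deg``
    of 180 degrees or its apex lies within ``1e-9 x mean edge length`` of the
    bifurcation plane (scale-aware, so the test is meaningful for both
    micrometre-scale neurons and centimetre-scale corals).  It is *deformable*
    when the projection of its apex onto the plane lies inside the apex's
    allowed region; with no ``region_oracle`` every vertex is unrestricted
    and all bifurcations are deformable.  The verdict is ``"not optimal"``
    iff some deformable bifurcation is off-plane beyond tolerance, since then
    the projection strictly reduces the total wiring cost.
    """
    mean_edge = float(np.mean(tree.edge_lengths())) if tree.n_vertices > 1 else 0.0
    dist_tol = 1e-9 * mean_edge
    rows = []
    for bif in _graph_bifurcations(tree):
        res = cone_angle(bif)
        flat = flatten_bifurcation(bif, cost)
        if flat.degenerate:
            continue
        dist = float(np.linalg.norm(flat.original_apex - flat.projected_apex))
        planar = (
            (not res.degenerate and abs(res.cone_angle_deg - 180.0) < tolerance_deg)
            or dist < dist_tol
        )
        deformable = (
            True
            if region_oracle is None
            else bool(region_oracle(bif.apex_id, flat.projected_apex))
        )
        rows.append(
            BifurcationAuditRow(
                apex_id=bif.apex_id,
                cone_angle_deg=res.cone_angle_deg,
                apex_plane_distance=dist,
                planar=planar,
                deformable=deformable,
                cost_reduction=max(-flat.cost_delta, 0.0) if deformable else 0.0,
            )
        )
    flagged = any(r.deformable and not r.planar for r in rows)
    verdict = "not optimal" if flagged else "no planarity-based improvement"
    return PlanarityAudit(rows, cost.name, tolerance_deg, verdict)


def iterate_flatten(
    tree: SpatialTree, cost: CostModel = COST_MODELS["identity"], n_sweeps: int = 1
) -> tuple[SpatialTree, list[float]]:
    """Repeatedly project every degree-3 apex onto its current bifurcation
    plane, sweeping root-to-leaves, and return the flattened tree plus the
    total-cost sequence (one entry before and one after each sweep).

    Each projection weakly decreases the total cost, so the sequence is
    non-increasing; this is a local improvement pass, not a global optimiser.
    """
    out = tree.copy()
    costs = [total_wiring_cost(out, cost)]
    for _ in range(n_sweeps):
        for bif in _graph_bifurcations(out):
            flat = flatten_bifurcation(bif, cost)
            if not flat.degenerate:
                out.positions[out.index_of(bif.apex_id)] = flat.projected_apex
        costs.append(total_wiring_cost(out, cost))
    return out, costs


# ---------------------------------------------------------------------------
# Fermat point (one-junction Steiner benchmark)


@dataclass(frozen=True)
class FermatResult:
    junction: np.ndarray
    angles_deg: Optional[tuple[float, float, float]]  # None when at a vertex
    at_vertex: Optional[int]  # index of the capturing terminal, else None
    total_length: float


def fermat_point(t1, t2, t3, tol: float = 1e-10, max_iter: int = 100000) -> FermatResult:
    """The point minimising the summed Euclidean distances to three terminals.

    When every angle of the terminal triangle is below 120 degrees the
    junction is interior and its three edges meet pairwise at exactly 120
    degrees; when some angle is >= 120 degrees (including collinear
    terminals) the junction coincides with that terminal and the junction
    angles are undefined (reported as ``None``).  Solved by Weiszfeld
    fixed-point iteration on the distance-sum gradient, with the vertex
    capture case detected analytically beforehand.
    """
    T = np.array([t1, t2, t3], float)
    for i in range(3):
        for j in range(i + 1, 3):
            if np.linalg.norm(T[i] - T[j]) == 0:
                raise ValueError("terminals must be pairwise distinct")
    # Vertex capture: the Fermat point sits at terminal i iff the angle there
    # is >= 120 deg, i.e. the two unit vectors to the other terminals sum to
    # norm <= 1.
    for i in range(3):
        others = T[[j for j in range(3) if j != i]]
        u = others - T[i]
        u = u / np.linalg.norm(u, axis=1, keepdims=True)
        if np.linalg.norm(u.sum(axis=0)) <= 1.0 + 1e-12:
            total = float(np.sum(np.linalg.norm(others - T[i], axis=1)))
            return FermatResult(T[i].copy(), None, i, total)
    x = T.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(T - x, axis=1)
        w = 1.0 / d
        x_new = (T * w[:, None]).sum(axis=0) / w.sum()
        step = float(np.linalg.norm(x_new - x))
        x = x_new
        if step < tol:
            break
    d = T - x
    dn = np.linalg.norm(d, axis=1)
    u = d / dn[:, None]
    angles = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        c = float(np.clip(np.dot(u[i], u[j]), -1.0, 1.0))
        angles.append(float(np.degrees(np.arccos(c))))
    return FermatResult(x, tuple(angles), None, float(dn.sum()))
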