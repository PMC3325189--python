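"""Synthetic spatial trees with controlled bifurcation geometry.

The generators emulate the statistical structure the planarity analysis
assumes, so every pipeline stage is testable without reconstruction
downloads:

* :func:`generate_planar_tree` builds full binary trees whose bifurcations
  are exactly planar.  Each bifurcation plane contains the incoming parent
  direction, and consecutive planes are related by a rotation about the
  shared branch by an azimuth drawn per the configured rule.  With
  independent uniform azimuths, the fold angle between consecutive plane
  normals is exactly uniform on [0, 90] degrees --- the signature of
  direction-bias-free wiring optimisation the analysis looks for.
* :func:`perturb_off_plane` displaces each apex along its bifurcation-plane
  normal by Gaussian noise, creating the non-planar regime the optimality
  audit must detect.
* :func:`generate_random_bifurcation` draws the i.i.d.-uniform-direction
  bifurcations of the random null.
* :func:`generate_steiner_toy` emits the canonical three-terminal Fermat
  configurations with their known optima.

Default geometry: daughter deviation angles uniform on [20, 70] degrees
(pairwise branch angles then spread broadly over roughly (40, 160) degrees
rather than concentrating at the Steiner 120); branch lengths log-normal with
median 1 and sigma_log 0.3, positive and right-skewed like neurite segment
lengths.  All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Bifurcation, bifurcation_plane
from .tree_io import SpatialTree

__all__ = [
    "TreeGenConfig",
    "generate_planar_tree",
    "perturb_off_plane",
    "generate_random_bifurcation",
    "generate_steiner_toy",
]


@dataclass
class TreeGenConfig:
    """Configuration for the planar-tree generator.

    ``depth`` counts bifurcation levels: the tree carries ``2**depth - 1``
    bifurcations and ``2**depth - 2`` consecutive plane pairs.  ``azimuth_rule``
    is ``"independent_uniform"`` (each child plane rotated about the shared
    branch by an independent uniform azimuth) or ``"fixed"`` (constant azimuth
    ``fixed_azimuth_deg``; 0 keeps all bifurcations coplanar with the trunk
    plane).  ``off_plane_sigma`` is in the same distance units as branch
    lengths and is applied by :func:`perturb_off_plane`, never here.
    """

    depth: int = 5
    branch_length_median: float = 1.0
    branch_length_sigma: float = 0.3
    daughter_angle_range: tuple[float, float] = (20.0, 70.0)
    azimuth_rule: str = "independent_uniform"
    fixed_azimuth_deg: float = 0.0
    off_plane_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        lo, hi = self.daughter_angle_range
        if not (0.0 < lo <= hi < 90.0):
            raise ValueError("daughter angles must lie in (0, 90) degrees")
        if self.branch_length_median <= 0 or self.branch_length_sigma < 0:
            raise ValueError("invalid branch-length distribution")
        if self.azimuth_rule not in ("independent_uniform", "fixed"):
            raise ValueError(f"unknown azimuth rule: {self.azimuth_rule!r}")
        if self.off_plane_sigma < 0:
            raise ValueError("off-plane sigma must be >= 0")


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis``."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return (
        v * c
        + np.cross(axis, v) * s
        + axis * np.dot(axis, v) * (1.0 - c)
    )


def generate_planar_tree(config: TreeGenConfig) -> SpatialTree:
    """Full binary tree in which every bifurcation is exactly planar.

    At each apex the two daughter directions lie in the bifurcation plane on
    either side of the incoming direction, at deviation angles drawn from the
    configured range; the parent direction is contained in the plane by
    construction, so apex, parent point and both daughter points are exactly
    coplanar and every cone angle is 180 degrees.  Each child's plane shares
    the branch direction with its parent's plane and is rotated about it by
    the configured azimuth rule.
    """
    config.validate()
    if config.off_plane_sigma != 0.0:
        raise ValueError(
            "generate_planar_tree requires off_plane_sigma == 0; "
            "use perturb_off_plane for the noisy regime"
        )
    rng = np.random.default_rng(config.seed)
    lo, hi = np.radians(config.daughter_angle_range)
    mu = np.log(config.branch_length_median)

    def length() -> float:
        return float(rng.lognormal(mu, config.branch_length_sigma))

    ids = [1]
    pos = [np.zeros(3)]
    parents = [-1]

    def add_vertex(p: np.ndarray, parent_id: int) -> int:
        vid = len(ids) + 1
        ids.append(vid)
        pos.append(p)
        parents.append(parent_id)
        return vid

    # trunk from the root to the first apex, in a seed-dependent direction
    d0 = rng.standard_normal(3)
    d0 /= np.linalg.norm(d0)
    # in-plane unit vector orthogonal to the trunk
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(helper, d0)) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    u0 = np.cross(d0, helper)
    u0 /= np.linalg.norm(u0)

    apex0 = add_vertex(pos[0] + length() * d0, 1)
    # stack of (apex vertex id, incoming direction, in-plane unit, level)
    stack = [(apex0, d0, u0, 1)]
    while stack:
        vid, d, u, level = stack.pop()
        n = np.cross(d, u)
        a1, a2 = rng.uniform(lo, hi, size=2)
        for alpha, sign in ((a1, 1.0), (a2, -1.0)):
            w = np.cos(alpha) * d + sign * np.sin(alpha) * u
            child = add_vertex(pos[vid - 1] + length() * w, vid)
            if level < config.depth:
                if config.azimuth_rule == "independent_uniform":
                    psi = rng.uniform(0.0, 2.0 * np.pi)
                else:
                    psi = np.radians(config.fixed_azimuth_deg)
                u_child = np.cross(n, w)
                u_child /= np.linalg.norm(u_child)
                u_child = _rotate_about(u_child, w, psi)
                stack.append((child, w, u_child, level + 1))
    return SpatialTree(
        np.array(ids),
        np.array(pos),
        np.zeros(len(ids), dtype=int),
        np.zeros(len(ids)),
        np.array(parents),
    )


def perturb_off_plane(tree: SpatialTree, sigma: float, seed: int) -> SpatialTree:
    """Displace each bifurcation apex along its bifurcation-plane normal by
    zero-mean Gaussian noise of scale ``sigma``; ``sigma == 0`` is the
    identity.  Displacements are computed from the unperturbed geometry, so
    the result does not depend on traversal order."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = tree.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    children = tree.children_map()
    root = tree.root_id
    moves = []
    for vid in tree.ids:
        vid = int(vid)
        if vid == root or len(children[vid]) != 2:
            continue
        par = int(tree.parents[tree.index_of(vid)])
        k1, k2 = children[vid]
        bif = Bifurcation(
            apex=tree.position_of(vid),
            parent_point=tree.position_of(par),
            daughter1_point=tree.position_of(k1),
            daughter2_point=tree.position_of(k2),
            apex_id=vid,
        )
        plane = bifurcation_plane(bif)
        if plane.degenerate:
            continue
        moves.append((vid, plane.normal * rng.normal(0.0, sigma)))
    for vid, dv in moves:
        out.positions[out.index_of(vid)] += dv
    return out


def generate_random_bifurcation(seed: int) -> Bifurcation:
    """A random bifurcation of the null model: apex at the origin, three
    i.i.d. uniform unit-sphere neighbour points (all branch lengths 1)."""
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((3, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return Bifurcation(
        apex=np.zeros(3),
        parent_point=pts[0],
        daughter1_point=pts[1],
        daughter2_point=pts[2],
        apex_id=0,
        parent_id=1,
        daughter1_id=2,
        daughter2_id=3,
    )


def generate_steiner_toy(kind: str):
    """Canonical three-terminal configurations with known Fermat optima.

    Returns ``(terminals, expected)`` where ``terminals`` is a (3, 3) array
    and ``expected`` describes the analytically known junction: for
    ``"equilateral"`` the centroid with 120-degree junction angles; for
    ``"obtuse"`` (a 150-degree vertex angle) the obtuse vertex; for
    ``"collinear"`` the middle terminal.
    """
    if kind == "equilateral":
        T = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                      [0.5, np.sqrt(3.0) / 2.0, 0.0]])
        expected = {
            "junction": T.mean(axis=0),
            "angles_deg": (120.0, 120.0, 120.0),
            "at_vertex": None,
        }
    elif kind == "obtuse":
        # apex angle 150 degrees at the origin
        half = np.radians(75.0)
        T = np.array([[0.0, 0.0, 0.0],
                      [np.cos(half), np.sin(half), 0.0],
                      [np.cos(half), -np.sin(half), 0.0]])
        expected = {"junction": T[0], "angles_deg": None, "at_vertex": 0}
    elif kind == "collinear":
        T = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        expected = {"junction": T[1], "angles_deg": None, "at_vertex": 1}
    else:
        raise ValueError(f"unknown toy kind: {kind!r}")
    return T, expected
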