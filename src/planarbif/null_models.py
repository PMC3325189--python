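"""The random-bifurcation null model for cone angles.

When the three branch directions of a bifurcation are drawn i.i.d. uniformly
on the unit sphere (apex fixed at the centre), the cone angle theta has the
closed-form density

    p(theta) = (3/4) * sin^3(theta / 2),   theta in [0, pi] radians,

with CDF ``1 - (3/2)cos(theta/2) + (1/2)cos^3(theta/2)``.  The density is
increasing with a maximum at 180 degrees: even random bifurcations have a
tendency to be flat.  The tail probability above 160 degrees is ~0.2579
(26%), the reference point against which biological planarity fractions are
judged.

The derivation follows from the geometry of the circumscribed cone: for a
fixed axis, all three points must fall on the base circle of the cone, and
the offset h = cos(theta/2) of the base-circle plane from the sphere centre
has density proportional to 1 - h^2; a change of variables to theta gives the
sine-cubed law.  The Monte-Carlo samplers below provide the independent check.

Public interfaces use degrees; internal computation is in radians.
"""

from __future__ import annotations

import numpy as np

from .geometry import cone_angles_from_units

__all__ = [
    "NullDistribution",
    "random_cone_density",
    "random_cone_cdf",
    "random_cone_survival",
    "sample_random_bifurcation_cone_angles",
    "sample_four_point_cone_angles",
]


def _check_range(theta_deg: np.ndarray) -> np.ndarray:
    t = np.asarray(theta_deg, float)
    if np.any(t < 0) or np.any(t > 180):
        raise ValueError("cone angle must lie in [0, 180] degrees")
    return t


def random_cone_density(theta_deg) -> np.ndarray | float:
    """Density (per radian) of the random-bifurcation cone angle at
    ``theta_deg`` degrees: ``(3/4) sin^3(theta/2)`` with theta in radians."""
    t = np.radians(_check_range(theta_deg))
    out = 0.75 * np.sin(t / 2.0) ** 3
    return out if np.ndim(theta_deg) else float(out)


def random_cone_cdf(theta_deg) -> np.ndarray | float:
    """CDF of the random-bifurcation cone angle at ``theta_deg`` degrees."""
    t = np.radians(_check_range(theta_deg))
    c = np.cos(t / 2.0)
    out = 1.0 - 1.5 * c + 0.5 * c**3
    return out if np.ndim(theta_deg) else float(out)


def random_cone_survival(theta_deg) -> np.ndarray | float:
    """Tail probability P(cone angle > theta_deg) under the random null."""
    return 1.0 - random_cone_cdf(theta_deg)


class NullDistribution:
    """The analytic random-bifurcation cone-angle law as a distribution object
    (degrees at the interface; support [0, 180])."""

    support_deg = (0.0, 180.0)

    def density(self, theta_deg):
        return random_cone_density(theta_deg)

    def cdf(self, theta_deg):
        return random_cone_cdf(theta_deg)

    def survival(self, theta_deg):
        return random_cone_survival(theta_deg)

    def bin_probabilities(self, edges_deg: np.ndarray) -> np.ndarray:
        """Probability mass in each histogram bin given edges in degrees."""
        edges = np.asarray(edges_deg, float)
        cdf = random_cone_cdf(np.clip(edges, 0.0, 180.0))
        return np.diff(cdf)


# ---------------------------------------------------------------------------
# Monte-Carlo samplers


def _uniform_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform unit vectors via normalised i.i.d. standard Gaussians."""
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_random_bifurcation_cone_angles(n: int, seed: int) -> np.ndarray:
    """Cone angles (degrees) of ``n`` random bifurcations: apex at the sphere
    centre, three i.i.d. uniform unit directions each.  Degenerate triples
    (probability zero; possible only through floating-point coincidence) are
    resampled.  Reproducible for a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        m = todo.size
        ang = cone_angles_from_units(
            _uniform_directions(rng, m),
            _uniform_directions(rng, m),
            _uniform_directions(rng, m),
        )
        out[todo] = ang
        todo = todo[~np.isfinite(ang)]
    return out


def sample_four_point_cone_angles(
    n: int, seed: int, point_distribution: str = "gaussian"
) -> np.ndarray:
    """Cone angles (degrees) when a bifurcation is defined by 4 i.i.d. random
    points in space: the first is the apex, the other three give the branch
    directions.  ``point_distribution`` is ``"gaussian"`` (standard normal)
    or ``"uniform_ball"`` (uniform in the unit ball); both are rotationally
    symmetric.  Draws where a point coincides with the apex are resampled."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if point_distribution not in ("gaussian", "uniform_ball"):
        raise ValueError(f"unknown point distribution: {point_distribution!r}")
    rng = np.random.default_rng(seed)

    def draw(m: int) -> np.ndarray:
        if point_distribution == "gaussian":
            return rng.standard_normal((m, 4, 3))
        v = _uniform_directions(rng, 4 * m).reshape(m, 4, 3)
        r = rng.random((m, 4, 1)) ** (1.0 / 3.0)
        return v * r

    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        pts = draw(todo.size)
        d = pts[:, 1:, :] - pts[:, :1, :]
        norms = np.linalg.norm(d, axis=2, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            u = d / norms
        ang = cone_angles_from_units(u[:, 0], u[:, 1], u[:, 2])
        out[todo] = ang
        todo = todo[~np.isfinite(ang)]
    return out
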