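"""Histograms, window fractions, goodness-of-fit tests and divergences.

Angle samples are compared against two references: the analytic
random-bifurcation cone-angle law (one-sample Kolmogorov-Smirnov) and the
uniform law on [0, 90] degrees for fold angles between consecutive
bifurcation planes.  Histogram comparisons use the Jensen-Shannon divergence
with base-2 logarithms, so values lie in [0, 1] bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import jensenshannon

from .geometry import Bifurcation, bifurcation_plane, cone_angle, plane_fold_angle
from .null_models import NullDistribution, random_cone_cdf

__all__ = [
    "AngleHistogram",
    "GroupComparison",
    "fraction_in_window",
    "ks_vs_random_null",
    "ks_uniform_fold_test",
    "js_divergence",
    "z_plane_groups",
]


@dataclass
class AngleHistogram:
    """Binned angle distribution on fixed edges (degrees)."""

    edges: np.ndarray
    counts: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.edges = np.asarray(self.edges, float)
        self.counts = np.asarray(self.counts, float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.edges) - 1:
            raise ValueError("counts/edges length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @classmethod
    def from_samples(cls, angles, lo=0.0, hi=180.0, bin_width=10.0):
        angles = np.asarray(angles, float)
        angles = angles[np.isfinite(angles)]
        edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
        counts, _ = np.histogram(angles, bins=edges)
        return cls(edges, counts)

    def normalize(self) -> "AngleHistogram":
        total = self.counts.sum()
        if total == 0:
            raise ValueError("cannot normalize an empty histogram")
        return AngleHistogram(self.edges, self.counts / total, normalized=True)


def fraction_in_window(angles, lo: float, hi: float) -> float:
    """Fraction of finite angles lying in the closed window [lo, hi]."""
    if lo >= hi:
        raise ValueError("window must satisfy lo < hi")
    a = np.asarray(angles, float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValueError("no finite angles to window")
    return float(np.mean((a >= lo) & (a <= hi)))


def ks_vs_random_null(cone_angles_deg) -> tuple[float, float]:
    """One-sample KS test of cone angles against the analytic
    random-bifurcation law; returns (statistic, p-value)."""
    a = np.asarray(cone_angles_deg, float)
    a = a[np.isfinite(a)]
    if a.size < 1:
        raise ValueError("empty sample")
    res = sps.kstest(a, random_cone_cdf)
    return float(res.statistic), float(res.pvalue)


def ks_uniform_fold_test(fold_angles_deg) -> tuple[float, float]:
    """One-sample KS test of fold angles against Uniform(0, 90) degrees."""
    a = np.asarray(fold_angles_deg, float)
    a = a[np.isfinite(a)]
    if a.size < 1:
        raise ValueError("empty sample")
    res = sps.kstest(a, sps.uniform(loc=0.0, scale=90.0).cdf)
    return float(res.statistic), float(res.pvalue)


def js_divergence(h1: AngleHistogram, h2: AngleHistogram) -> float:
    """Jensen-Shannon divergence between two histograms in bits ([0, 1]).

    Histograms must share bin edges; each is normalised to a probability
    vector first.  Symmetric; zero iff the normalised histograms coincide.
    """
    if len(h1.edges) != len(h2.edges) or not np.allclose(h1.edges, h2.edges):
        raise ValueError("histograms must share bin edges")
    p = h1.normalize().counts
    q = h2.normalize().counts
    # scipy returns the JS *distance* (sqrt of the divergence)
    return float(jensenshannon(p, q, base=2) ** 2)


@dataclass
class GroupComparison:
    """Cone-angle comparison between two orientation groups of bifurcations."""

    labels: tuple[str, str]
    histograms: dict[str, AngleHistogram]
    group_sizes: dict[str, int]
    js_between: Optional[float]
    ks_pvalue_between: Optional[float]
    js_vs_null: dict[str, Optional[float]]
    empty_groups: list[str] = field(default_factory=list)


def z_plane_groups(
    bifurcations: list[Bifurcation],
    split_angle_deg: float = 45.0,
    bin_width: float = 10.0,
) -> GroupComparison:
    """Split bifurcations by the orientation of their plane relative to the
    z-plane and compare the two groups' cone-angle distributions.

    A bifurcation whose plane normal makes a (folded) angle below
    ``split_angle_deg`` with the z-axis has its plane near-parallel to the
    x-y slicing plane (group ``"near_parallel"``); the rest form
    ``"near_perpendicular"``.  Reports per-group histograms, the
    between-group Jensen-Shannon divergence (bits) and two-sample KS p-value,
    and each group's JS divergence against the analytic random null.
    Useful for detecting slice-compression (shrinkage) artifacts, which
    inflate planarity anisotropically.
    """
    if not 0.0 < split_angle_deg < 90.0:
        raise ValueError("split angle must lie in (0, 90) degrees")
    z = np.array([0.0, 0.0, 1.0])
    groups: dict[str, list[float]] = {"near_parallel": [], "near_perpendicular": []}
    for bif in bifurcations:
        plane = bifurcation_plane(bif)
        if plane.degenerate:
            continue
        res = cone_angle(bif)
        if res.degenerate:
            continue
        tilt = plane_fold_angle(plane.normal, z)
        key = "near_parallel" if tilt <= split_angle_deg else "near_perpendicular"
        groups[key].append(res.cone_angle_deg)

    labels = ("near_parallel", "near_perpendicular")
    hists = {
        k: AngleHistogram.from_samples(v, bin_width=bin_width)
        for k, v in groups.items()
    }
    empty = [k for k, v in groups.items() if len(v) == 0]
    null_hist = AngleHistogram(
        hists[labels[0]].edges,
        NullDistribution().bin_probabilities(hists[labels[0]].edges),
        normalized=True,
    )
    js_vs_null = {
        k: (js_divergence(hists[k], null_hist) if k not in empty else None)
        for k in labels
    }
    if empty:
        js_between, ks_p = None, None
    else:
        js_between = js_divergence(hists[labels[0]], hists[labels[1]])
        ks_p = float(
            sps.ks_2samp(groups[labels[0]], groups[labels[1]]).pvalue
        )
    return GroupComparison(
        labels=labels,
        histograms=hists,
        group_sizes={k: len(v) for k, v in groups.items()},
        js_between=js_between,
        ks_pvalue_between=ks_p,
        js_vs_null=js_vs_null,
        empty_groups=empty,
    )
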