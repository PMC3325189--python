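import numpy as np
import pytest

from planarbif import (
    Bifurcation,
    SpatialTree,
    TreeGenConfig,
    generate_planar_tree,
)


@pytest.fixture
def y_tree_swc(tmp_path):
    """Smallest bifurcating reconstruction: root, 2-sample trunk, branch
    point, one sample per daughter (7 samples)."""
    text = "\n".join(
        [
            "# minimal Y",
            "1 1 0 0 0 1 -1",
            "2 3 0 0 1 1 1",
            "3 3 0 0 2 1 2",
            "4 3 0 0 3 1 3",
            "5 3 1 0 4 1 4",
            "6 3 -1 0 4 1 4",
            "7 3 2 0 5 1 5",
        ]
    )
    path = tmp_path / "y.swc"
    path.write_text(text + "\n")
    return path


@pytest.fixture
def y_tree(y_tree_swc):
    from planarbif import read_swc

    return read_swc(y_tree_swc)


def build_tree(positions, parents, labels=None):
    """Construct a SpatialTree from positions (n,3) and parent ids (1-based
    ids assigned in order)."""
    n = len(positions)
    labels = labels if labels is not None else np.zeros(n, int)
    return SpatialTree(
        np.arange(1, n + 1),
        np.asarray(positions, float),
        np.asarray(labels, int),
        np.zeros(n),
        np.asarray(parents, int),
    )


def make_bif(apex, p, d1, d2):
    return Bifurcation(
        np.asarray(apex, float),
        np.asarray(p, float),
        np.asarray(d1, float),
        np.asarray(d2, float),
        apex_id=0, parent_id=1, daughter1_id=2, daughter2_id=3,
    )


def random_nonplanar_bifurcations(n, seed):
    """Random bifurcations with apex off the neighbour plane."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        pts = rng.standard_normal((4, 3))
        u = pts[2] - pts[1]
        v = pts[3] - pts[1]
        nrm = np.cross(u, v)
        norm = np.linalg.norm(nrm)
        if norm < 1e-8:
            continue
        dist = abs(np.dot(pts[0] - pts[1], nrm / norm))
        if dist < 1e-3:  # ensure genuinely off-plane
            continue
        out.append(make_bif(pts[0], pts[1], pts[2], pts[3]))
    return out


@pytest.fixture
def planar_tree():
    return generate_planar_tree(TreeGenConfig(depth=4, seed=11))
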