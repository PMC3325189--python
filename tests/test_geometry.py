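import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from planarbif import (
    TreeGenConfig,
    bifurcation_plane,
    branch_angles,
    cone_angle,
    consecutive_plane_pairs,
    extract_bifurcations,
    generate_planar_tree,
    plane_fold_angle,
    read_swc,
    reduce_topology,
)

from conftest import make_bif, random_nonplanar_bifurcations


def equal_projection_axis_oracle(bif):
    """Independent cone-angle oracle: the cone axis is the direction onto
    which the three unit branch vectors project equally; twice the arccos of
    that common projection is the aperture."""
    b1, b2, b3 = bif.unit_directions()
    n = np.cross(b1 - b2, b2 - b3)
    n = n / np.linalg.norm(n)
    h = np.dot(n, b1)
    if h < 0:
        n, h = -n, -h
    assert np.isclose(np.dot(n, b2), h)
    assert np.isclose(np.dot(n, b3), h)
    return 2.0 * np.degrees(np.arccos(np.clip(h, -1.0, 1.0)))


class TestConeAngle:
    def test_flat_bifurcation_is_180(self):
        bif = make_bif([0, 0, 0], [1, 0, 0], [0, 1, 0], [-1, -1, 0])
        assert cone_angle(bif).cone_angle_deg == pytest.approx(180.0, abs=1e-9)

    def test_symmetric_cone_at_60_degrees_polar(self):
        s, c = np.sin(np.radians(60)), np.cos(np.radians(60))
        pts = [
            [s * np.cos(a), s * np.sin(a), c]
            for a in np.radians([0.0, 120.0, 240.0])
        ]
        bif = make_bif([0, 0, 0], *pts)
        assert cone_angle(bif).cone_angle_deg == pytest.approx(120.0, abs=1e-9)

    def test_orthonormal_triple_closed_form(self):
        bif = make_bif([0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1])
        res = cone_angle(bif)
        assert res.circumradius == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-12)
        assert res.cone_angle_deg == pytest.approx(
            np.degrees(2 * np.arcsin(np.sqrt(2.0 / 3.0))), abs=1e-9
        )
        assert res.cone_angle_deg == pytest.approx(109.4712206, abs=1e-6)

    def test_axis_makes_equal_angles_with_directions(self):
        for bif in random_nonplanar_bifurcations(20, seed=5):
            res = cone_angle(bif)
            projs = res.unit_directions @ res.axis
            assert np.all(projs >= -1e-12)
            assert np.ptp(projs) < 1e-9
            # half-aperture consistency
            half = np.degrees(np.arccos(np.clip(projs[0], -1, 1)))
            assert res.cone_angle_deg == pytest.approx(2 * half, abs=1e-8)

    def test_oracle_equivalence_random_sample(self):
        for bif in random_nonplanar_bifurcations(200, seed=17):
            expected = equal_projection_axis_oracle(bif)
            assert cone_angle(bif).cone_angle_deg == pytest.approx(
                expected, abs=1e-9
            )

    def test_degenerate_collinear_directions_flagged(self):
        bif = make_bif([0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0])
        res = cone_angle(bif)
        assert res.degenerate
        assert np.isnan(res.cone_angle_deg)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariance_under_rigid_motion_and_rescaling(self, seed):
        rng = np.random.default_rng(seed)
        bif = random_nonplanar_bifurcations(1, seed=seed)[0]
        base = cone_angle(bif).cone_angle_deg
        # random rotation (QR of a Gaussian matrix), translation, and
        # independent positive rescaling of each branch about the apex
        q, r = np.linalg.qr(rng.standard_normal((3, 3)))
        q *= np.sign(np.diag(r))
        t = rng.standard_normal(3) * 10
        scales = rng.uniform(0.1, 10.0, size=3)
        apex = bif.apex
        pts = [
            apex + s * (p - apex)
            for s, p in zip(scales, bif.neighbour_points())
        ]
        moved = make_bif(q @ apex + t, *(q @ p + t for p in pts))
        assert cone_angle(moved).cone_angle_deg == pytest.approx(base, abs=1e-8)

    def test_planar_iff_branch_angles_sum_to_360(self):
        flat = make_bif([0, 0, 0], [1, 0, 0], [0, 1, 0], [-1, -1, 0])
        assert sum(branch_angles(flat)) == pytest.approx(360.0, abs=1e-9)
        bent = make_bif([0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1])
        assert sum(branch_angles(bent)) < 360.0 - 1e-6
        assert cone_angle(bent).cone_angle_deg < 180.0 - 1e-6


class TestBranchAngles:
    def test_orthonormal(self):
        bif = make_bif([0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1])
        assert branch_angles(bif) == pytest.approx((90.0, 90.0, 90.0))

    def test_planar_symmetric_tripod_all_120(self):
        pts = [
            [np.cos(a), np.sin(a), 0.0]
            for a in np.radians([90.0, 210.0, 330.0])
        ]
        bif = make_bif([0, 0, 0], *pts)
        assert branch_angles(bif) == pytest.approx((120.0, 120.0, 120.0))

    def test_near_antipodal_limit(self):
        bif = make_bif([0, 0, 0], [1, 0, 0], [-1, 1e-8, 0], [0, 1, 0])
        a = branch_angles(bif)
        assert a[0] == pytest.approx(180.0, abs=1e-4)
        assert a[1] == pytest.approx(90.0, abs=1e-6)
        assert a[2] == pytest.approx(90.0, abs=1e-4)

    def test_coincident_point_raises(self):
        bif = make_bif([0, 0, 0], [0, 0, 0], [0, 1, 0], [0, 0, 1])
        with pytest.raises(ValueError):
            branch_angles(bif)


class TestBifurcationPlane:
    def test_simple_plane_normal(self):
        bif = make_bif([5, 5, 5], [0, 0, 0], [1, 0, 0], [0, 1, 0])
        n = bifurcation_plane(bif).normal
        assert abs(n @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_normal_orthogonal_to_in_plane_vectors(self):
        bif = make_bif([9, 9, 9], [0, 0, 0], [1, 0, 0], [0, 0, 2])
        plane = bifurcation_plane(bif)
        assert abs(plane.normal @ [0, 1, 0]) == pytest.approx(1.0, abs=1e-12)
        pts = bif.neighbour_points()
        assert abs(plane.normal @ (pts[1] - pts[0])) < 1e-9
        assert abs(plane.normal @ (pts[2] - pts[0])) < 1e-9

    def test_collinear_triple_degenerate(self):
        bif = make_bif([0, 1, 0], [0, 0, 0], [1, 0, 0], [2, 0, 0])
        assert bifurcation_plane(bif).degenerate


class TestFoldAngle:
    @pytest.mark.parametrize(
        "n1,n2,expected",
        [
            ([0, 0, 1], [0, 0, 1], 0.0),
            ([0, 0, 1], [1, 0, 0], 90.0),
            ([0, 0, 1], [0, np.sin(np.radians(120)), np.cos(np.radians(120))], 60.0),
        ],
    )
    def test_examples(self, n1, n2, expected):
        assert plane_fold_angle(n1, n2) == pytest.approx(expected, abs=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_sign_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.standard_normal((2, 3))
        base = plane_fold_angle(n1, n2)
        for s1 in (1, -1):
            for s2 in (1, -1):
                assert plane_fold_angle(s1 * n1, s2 * n2) == pytest.approx(base)
        assert 0.0 <= base <= 90.0

    def test_zero_normal_rejected(self):
        with pytest.raises(ValueError):
            plane_fold_angle([0, 0, 0], [0, 0, 1])


class TestExtraction:
    def test_y_tree_single_bifurcation(self, y_tree):
        red = reduce_topology(y_tree)
        bifs = extract_bifurcations(red, exclude_soma=False)
        assert len(bifs) == 1
        assert bifs[0].apex_id == 4

    def test_full_binary_tree_counts(self, planar_tree):
        red = reduce_topology(planar_tree)
        bifs = extract_bifurcations(red)
        assert len(bifs) == 2**4 - 1  # depth-4 generator
        pairs = consecutive_plane_pairs(red)
        assert len(pairs) == 2**4 - 2
        bif_ids = {b.apex_id for b in bifs}
        for outer, inner in pairs:
            assert outer in bif_ids and inner in bif_ids

    def test_first_segment_mode_uses_adjacent_samples(self, y_tree):
        red = reduce_topology(y_tree)
        (bif,) = extract_bifurcations(
            red, endpoint_mode="first_segment", exclude_soma=False
        )
        # parent endpoint is sample 3 (adjacent on the trunk), not the root;
        # daughter 1 endpoint is sample 5 (the chain sample), not tip 7
        assert bif.parent_id == 3
        assert sorted([bif.daughter1_id, bif.daughter2_id]) == [5, 6]

    def test_soma_adjacent_bifurcation_excluded(self, tmp_path):
        text = (
            "1 1 0 0 0 1 -1\n"
            "2 3 1 0 0 1 1\n"
            "3 3 2 1 0 1 2\n"
            "4 3 2 -1 0 1 2\n"
        )
        p = tmp_path / "s.swc"
        p.write_text(text)
        red = reduce_topology(read_swc(p))
        assert extract_bifurcations(red, exclude_soma=True) == []
        assert len(extract_bifurcations(red, exclude_soma=False)) == 1

    def test_single_bifurcation_yields_no_pairs(self, y_tree):
        assert consecutive_plane_pairs(reduce_topology(y_tree)) == []

    def test_caterpillar_chain_of_bifurcations(self):
        from conftest import build_tree

        # trunk then 4 chained bifurcations, each with a terminal side branch
        pos, parents = [[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]], [-1, 1]
        pid = 2
        rng = np.random.default_rng(0)
        for k in range(4):
            first_child = len(pos) + 1
            for dp in (rng.standard_normal(3), rng.standard_normal(3)):
                pos.append(list(np.asarray(pos[pid - 1]) + dp))
                parents.append(pid)
            pid = first_child  # continue the chain along the first child
        red = reduce_topology(build_tree(pos, parents))
        assert len(consecutive_plane_pairs(red)) == 3
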