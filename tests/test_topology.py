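import itertools

import numpy as np
import pytest

import phylotda as pt
from phylotda.topology import Barcode, FilteredComplex

from conftest import random_cloud
from oracles import barcode_by_rank, gf2_rank, match_barcodes

SQRT2 = np.sqrt(2.0)
UNIT_SQUARE = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
REGULAR_TETRAHEDRON = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [0.5, np.sqrt(3) / 2, 0],
        [0.5, np.sqrt(3) / 6, np.sqrt(6) / 3],
    ]
)


class TestVietorisRips:
    def test_unit_square_edge_values(self):
        fc = pt.build_vietoris_rips(UNIT_SQUARE)
        values = {s: v for s, v in fc.simplices}
        edges = {s: v for s, v in values.items() if len(s) == 2}
        assert sum(1 for v in edges.values() if np.isclose(v, 1.0)) == 4
        assert sum(1 for v in edges.values() if np.isclose(v, SQRT2)) == 2
        triangles = [v for s, v in values.items() if len(s) == 3]
        assert len(triangles) == 4 and np.allclose(triangles, SQRT2)

    def test_triangle_enters_with_last_edge(self):
        # equilateral triangle of side 2 plus a far apex (n >= 4)
        s = 2.0
        pts = np.array(
            [[0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0], [0, 0, 50.0]]
        )
        fc = pt.build_vietoris_rips(pts)
        tri = dict(fc.simplices)[(0, 1, 2)]
        assert np.isclose(tri, s)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            pt.build_vietoris_rips(UNIT_SQUARE[:2])

    def test_point_cap_advises_alpha_complex(self):
        pts = np.random.default_rng(0).normal(size=(30, 3))
        with pytest.raises(ValueError, match="alpha"):
            pt.build_vietoris_rips(pts, max_points=25)

    def test_threshold_caps_unresolved_classes(self):
        fc = pt.build_vietoris_rips(UNIT_SQUARE, threshold=1.2)
        with pytest.warns(UserWarning, match="capped"):
            bars = pt.compute_persistence(fc)
        assert match_barcodes(bars[1].intervals, [(1.0, 1.2)])


class TestAlphaComplex:
    def test_regular_tetrahedron_filtration_values(self):
        fc = pt.build_alpha_complex(REGULAR_TETRAHEDRON)
        values = dict(fc.simplices)
        for s, v in values.items():
            if len(s) == 2:
                assert np.isclose(v, 0.25)
            elif len(s) == 3:
                assert np.isclose(v, 1.0 / 3.0)
            elif len(s) == 4:
                assert np.isclose(v, 3.0 / 8.0)

    def test_subcomplex_of_delaunay(self):
        from scipy.spatial import Delaunay

        pts = random_cloud(np.random.default_rng(3), 20)
        fc = pt.build_alpha_complex(pts)
        delaunay_tets = {tuple(sorted(t)) for t in Delaunay(pts).simplices}
        allowed = set()
        for tet in delaunay_tets:
            for d in range(1, 5):
                allowed.update(itertools.combinations(tet, d))
        assert {s for s, _ in fc.simplices} <= allowed

    def test_near_coplanar_points_handled(self):
        pts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 1e-9], [0.5, 0.5, 1e-9]]
        )
        fc = pt.build_alpha_complex(pts)
        fc.validate()
        bars = pt.compute_persistence(fc)
        assert set(bars) == {1, 2}

    def test_finite_intervals_only_in_dims_1_2(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            fc = pt.build_alpha_complex(random_cloud(rng, 15))
            bars = pt.compute_persistence(fc)
            for k in (1, 2):
                assert np.all(np.isfinite(bars[k].intervals))


class TestPersistence:
    def test_square_complex_hand_reduction(self):
        # the VR square: cycle born at 1, filled at sqrt(2)
        v = SQRT2
        simplices = [((i,), 0.0) for i in range(4)]
        simplices += [((0, 1), 1.0), ((1, 2), 1.0), ((2, 3), 1.0), ((0, 3), 1.0)]
        simplices += [((0, 2), v), ((1, 3), v)]
        simplices += [((0, 1, 2), v), ((0, 2, 3), v), ((0, 1, 3), v), ((1, 2, 3), v)]
        simplices += [((0, 1, 2, 3), v)]
        fc = FilteredComplex(simplices=simplices, kind="VR")
        bars = pt.compute_persistence(fc)
        assert match_barcodes(bars[1].intervals, [(1.0, v)])
        assert len(bars[2]) == 0

    def test_tetrahedron_betti_counting(self):
        fc = pt.build_alpha_complex(REGULAR_TETRAHEDRON)
        bars = pt.compute_persistence(fc)
        assert match_barcodes(bars[1].intervals, [(0.25, 1 / 3)] * 3)
        assert match_barcodes(bars[2].intervals, [(1 / 3, 3 / 8)])

    def test_deterministic(self):
        pts = random_cloud(np.random.default_rng(5), 12)
        fc = pt.build_vietoris_rips(pts)
        a = pt.compute_persistence(fc)
        b = pt.compute_persistence(fc)
        for k in (1, 2):
            np.testing.assert_array_equal(a[k].intervals, b[k].intervals)

    def test_face_violation_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            FilteredComplex([((0, 1), 1.0)], kind="VR").validate()
        bad = FilteredComplex(
            [((0,), 0.0), ((1,), 2.0), ((0, 1), 1.0)], kind="VR"
        )
        with pytest.raises(ValueError, match="enters after"):
            pt.compute_persistence(bad)

    @pytest.mark.parametrize("build", [pt.build_vietoris_rips, pt.build_alpha_complex])
    def test_matches_rank_oracle(self, build):
        """Barcodes agree with the persistent-Betti rank oracle (dims 0-2)."""
        rng = np.random.default_rng(21)
        for _ in range(4):
            fc = build(random_cloud(rng, int(rng.integers(8, 11))))
            mine = pt.compute_persistence(fc, include_dim0=True)
            oracle = barcode_by_rank(fc)
            for k in (0, 1, 2):
                assert match_barcodes(mine[k].intervals, np.array(oracle[k]).reshape(-1, 2))

    @pytest.mark.parametrize("build", [pt.build_vietoris_rips, pt.build_alpha_complex])
    def test_boundary_and_cohomology_routes_agree(self, build):
        rng = np.random.default_rng(8)
        for _ in range(3):
            fc = build(random_cloud(rng, int(rng.integers(10, 18))))
            a = pt.compute_persistence(fc, include_dim0=True, method="boundary")
            b = pt.compute_persistence(fc, include_dim0=True, method="coboundary")
            for k in (0, 1, 2):
                assert match_barcodes(a[k].intervals, b[k].intervals)

    @pytest.mark.parametrize("build", [pt.build_vietoris_rips, pt.build_alpha_complex])
    def test_euler_characteristic(self, build):
        """Alternating simplex counts equal alternating Betti numbers at the end."""
        rng = np.random.default_rng(13)
        fc = build(random_cloud(rng, 10))
        order = fc.sorted_simplices()
        index = {s: i for i, (s, _) in enumerate(order)}
        chi_simplices = sum((-1) ** (len(s) - 1) for s, _ in order)
        chi_betti = 0
        for k in range(4):
            k_simp = [s for s, _ in order if len(s) == k + 1]
            km1 = {s: i for i, (s, _) in enumerate(order) if len(s) == k}

            def bd(s):
                col = 0
                if k > 0:
                    for f in itertools.combinations(s, k):
                        col |= 1 << km1[f]
                return col

            kp1 = [s for s, _ in order if len(s) == k + 2]
            k_idx = {s: i for i, s in enumerate(k_simp)}

            def bd_up(s):
                col = 0
                for f in itertools.combinations(s, k + 1):
                    col |= 1 << k_idx[f]
                return col

            beta = len(k_simp) - gf2_rank([bd(s) for s in k_simp]) - gf2_rank(
                [bd_up(s) for s in kp1]
            )
            chi_betti += (-1) ** k * beta
        assert chi_simplices == chi_betti

    def test_vr_stability_under_perturbation(self):
        """Moving every point by <= delta moves VR barcodes by <= 2*delta."""
        rng = np.random.default_rng(17)
        pts = random_cloud(rng, 12)
        diam = np.max(np.linalg.norm(pts[:, None] - pts[None], axis=-1))
        delta = 0.01 * diam
        shift = rng.normal(size=pts.shape)
        shift *= delta / np.linalg.norm(shift, axis=1, keepdims=True)
        bars0 = pt.compute_persistence(pt.build_vietoris_rips(pts))
        bars1 = pt.compute_persistence(pt.build_vietoris_rips(pts + shift))
        for k in (1, 2):
            assert pt.bottleneck_distance(bars0[k], bars1[k]) <= 2 * delta + 1e-12


def test_complex_text_roundtrip():
    fc = pt.build_alpha_complex(REGULAR_TETRAHEDRON)
    back = FilteredComplex.from_text(fc.to_text())
    assert back.kind == fc.kind
    assert back.sorted_simplices() == fc.sorted_simplices()


def test_barcode_csv():
    bars = {1: Barcode(k=1, intervals=[(0.0, 1.0)]), 2: Barcode(k=2, intervals=np.zeros((0, 2)))}
    text = pt.topology.barcode_to_csv(bars)
    assert text.splitlines()[0] == "k,birth,death"
    assert "1,0.0,1.0" in text
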