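import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cabbagemorph as cm
from cabbagemorph.errors import EmptyPlantError, InvalidMeasureError
from cabbagemorph.leaf_morphometry import DEFAULT_SHAPE_FACTOR


def mask_of(pixels, shape=(10, 10), cls="leaf", iid=1):
    r = np.zeros(shape, dtype=bool)
    for row, col in pixels:
        r[row, col] = True
    return cm.InstanceMask(r, cls, iid)


def ap(x, y, z):
    return cm.AttachmentPoint(position=(x, y, z), support=1, dispersion=0.0)


class TestAssignLeaves:
    def test_fully_contained_leaf(self):
        leaf = mask_of([(0, 0), (0, 1)], iid=1)
        plant = mask_of([(r, c) for r in range(3) for c in range(3)], cls="plant", iid=7)
        assert cm.assign_leaves([leaf], [plant]) == {1: 7}

    def test_half_overlap_is_unassigned(self):
        # exactly 50 % inside: below the strict >80 % rule
        leaf = mask_of([(0, 0), (0, 1), (0, 2), (0, 3)], iid=1)
        plant = mask_of([(0, 0), (0, 1)], cls="plant", iid=2)
        assert cm.assign_leaves([leaf], [plant]) == {1: None}

    def test_exact_threshold_not_assigned(self):
        # exactly 80 % does not exceed the strict threshold
        leaf = mask_of([(0, c) for c in range(5)], iid=1)
        plant = mask_of([(0, c) for c in range(4)], cls="plant", iid=2)
        assert cm.assign_leaves([leaf], [plant]) == {1: None}

    def test_largest_fraction_wins_on_toy_grid(self):
        # 20-pixel leaf: 85 % inside plant A, 90 % inside plant B -> B
        leaf_px = [(r, c) for r in range(2) for c in range(10)]
        leaf = mask_of(leaf_px, iid=1)
        plant_a = mask_of(leaf_px[:17], cls="plant", iid=1)
        plant_b = mask_of(leaf_px[2:], cls="plant", iid=2)
        assert cm.assign_leaves([leaf], [plant_a, plant_b]) == {1: 2}

    def test_tie_goes_to_lower_plant_id(self):
        leaf_px = [(r, c) for r in range(2) for c in range(10)]
        leaf = mask_of(leaf_px, iid=5)
        plant_a = mask_of(leaf_px[:18], cls="plant", iid=9)
        plant_b = mask_of(leaf_px[:18], cls="plant", iid=3)
        assert cm.assign_leaves([leaf], [plant_a, plant_b]) == {5: 3}


class TestLeafEndpoint:
    def test_farthest_point_wins(self):
        cloud = cm.LeafPointCloud([[1, 0, 0], [3, 0, 0], [2, 0, 0]], leaf_id=1)
        q = cm.leaf_endpoint(cloud, ap(0, 0, 0))
        assert np.array_equal(q, [3, 0, 0])

    @pytest.mark.parametrize("n", [100, 10_000])
    def test_matches_exhaustive_scan(self, n):
        rng = np.random.default_rng(14)
        pts = rng.uniform(-500, 500, size=(n, 3))
        p = ap(10.0, -5.0, 30.0)
        q = cm.leaf_endpoint(cm.LeafPointCloud(pts, leaf_id=1), p)
        # brute-force python-loop oracle
        best, best_d = None, -1.0
        for row in pts:
            d = ((row[0] - 10.0) ** 2 + (row[1] + 5.0) ** 2 + (row[2] - 30.0) ** 2) ** 0.5
            if d > best_d:
                best, best_d = row, d
        assert np.array_equal(q, best)

    def test_tie_broken_by_scan_order(self):
        cloud = cm.LeafPointCloud([[1, 0, 0], [-1, 0, 0], [0, 1, 0]], leaf_id=1)
        q = cm.leaf_endpoint(cloud, ap(0, 0, 0))
        assert np.array_equal(q, [1, 0, 0])


class TestLeafLength:
    def test_3_4_5_triangle(self):
        assert cm.leaf_length(ap(0, 0, 0), np.array([3.0, 4.0, 0.0])) == pytest.approx(5.0)

    def test_coincident_points(self):
        assert cm.leaf_length(ap(1, 1, 1), np.array([1.0, 1.0, 1.0])) == 0.0

    def test_direct_formula(self):
        assert cm.leaf_length(ap(1, 1, 1), np.array([2.0, 3.0, 6.0])) == pytest.approx(np.sqrt(30))


class TestLeafAreas:
    def test_single_leaf_100mm(self):
        areas, total = cm.leaf_areas([100.0])
        assert areas[0] == pytest.approx(0.027)
        assert total == pytest.approx(0.027)

    def test_two_leaf_hand_evaluation(self):
        # L̄ = 300 mm: areas 300·200·2.7 and 300·400·2.7 mm² -> m²
        areas, total = cm.leaf_areas([200.0, 400.0])
        assert areas == pytest.approx([0.162, 0.324])
        assert total == pytest.approx(0.486)

    def test_equal_leaves_closed_form(self):
        n, L = 7, 250.0
        _, total = cm.leaf_areas([L] * n)
        assert total == pytest.approx(2.7 * n * (L / 1000.0) ** 2)

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(EmptyPlantError):
            cm.leaf_areas([])
        with pytest.raises(InvalidMeasureError):
            cm.leaf_areas([100.0, -5.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=10.0, max_value=1000.0), min_size=1, max_size=30)
    )
    def test_total_identity_on_random_inputs(self, lengths):
        # total LA = shape_factor · n · L̄² (mm² -> m²) on every input
        _, total = cm.leaf_areas(lengths)
        Lbar = np.mean(lengths)
        expected = DEFAULT_SHAPE_FACTOR * len(lengths) * (Lbar / 1000.0) ** 2
        assert total == pytest.approx(expected, rel=1e-12)

    def test_adding_mean_length_leaf(self):
        lengths = [150.0, 250.0, 350.0]
        Lbar = np.mean(lengths)
        _, t0 = cm.leaf_areas(lengths)
        _, t1 = cm.leaf_areas(lengths + [Lbar])
        assert t1 - t0 == pytest.approx(2.7 * (Lbar / 1000.0) ** 2)


class TestMeasurePlantLeaves:
    def test_known_lengths_recovered_noiseless(self, funnel_scene, funnel_render):
        depth, _ = funnel_render
        scene = funnel_scene
        clouds = [cm.backproject(m, depth, scene.camera) for m in scene.masks("leaf")]
        true_p = scene.plants[0].attachment
        attachment = cm.AttachmentPoint(position=tuple(true_p), support=1, dispersion=0.0)
        pm = cm.measure_plant_leaves(clouds, attachment, plant_id=1)
        truth = {lf.leaf_id: lf.length for lf in scene.plants[0].leaves}
        for leaf in pm.leaves:
            assert leaf.length == pytest.approx(truth[leaf.leaf_id], rel=0.02)

    def test_permutation_leaves_totals_unchanged(self, funnel_scene, funnel_render):
        depth, _ = funnel_render
        scene = funnel_scene
        clouds = [cm.backproject(m, depth, scene.camera) for m in scene.masks("leaf")]
        attachment = cm.AttachmentPoint(
            position=tuple(scene.plants[0].attachment), support=1, dispersion=0.0
        )
        a = cm.measure_plant_leaves(clouds, attachment)
        b = cm.measure_plant_leaves(clouds[::-1], attachment)
        assert a.total_leaf_area == pytest.approx(b.total_leaf_area, rel=1e-12)
        assert a.mean_leaf_length == pytest.approx(b.mean_leaf_length, rel=1e-12)

    def test_occluded_endpoint_underestimates(self):
        # hide the far half of a leaf: its measured length must drop
        rng = np.random.default_rng(15)
        s = rng.uniform(0, 300, 400)
        t = rng.uniform(-40, 40, 400)
        u = np.array([0.9, 0.0, 0.45])
        w = np.array([0.0, 1.0, 0.0])
        pts = np.outer(s, u) + np.outer(t, w)
        full = cm.LeafPointCloud(pts, leaf_id=1)
        visible = cm.LeafPointCloud(pts[s < 150], leaf_id=1)
        p = cm.AttachmentPoint(position=(0, 0, 0), support=1, dispersion=0.0)
        L_full = cm.leaf_length(p, cm.leaf_endpoint(full, p))
        L_vis = cm.leaf_length(p, cm.leaf_endpoint(visible, p))
        assert L_vis < L_full

    def test_scale_law(self):
        rng = np.random.default_rng(16)
        clouds = [
            cm.LeafPointCloud(rng.uniform(10, 300, (50, 3)), leaf_id=i) for i in range(1, 4)
        ]
        p = cm.AttachmentPoint(position=(0, 0, 0), support=1, dispersion=0.0)
        a = cm.measure_plant_leaves(clouds, p)
        s = 2.5
        scaled = [cm.LeafPointCloud(c.points * s, leaf_id=c.leaf_id) for c in clouds]
        b = cm.measure_plant_leaves(scaled, p)
        for la, lb in zip(a.leaves, b.leaves):
            assert lb.length == pytest.approx(s * la.length, rel=1e-12)
            assert lb.area == pytest.approx(s**2 * la.area, rel=1e-12)
        assert b.total_leaf_area == pytest.approx(s**2 * a.total_leaf_area, rel=1e-12)
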