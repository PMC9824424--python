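from itertools import permutations

import numpy as np
import pytest

import cabbagemorph as cm
from cabbagemorph.errors import InsufficientPlanesError, NoSupportError
from cabbagemorph.stem_locator import StemConfig


def plane(a, b, c):
    return cm.Plane(a=a, b=b, c=c)


def full_mask(shape=(512, 512)):
    return cm.InstanceMask(np.ones(shape, dtype=bool), "plant", 1)


class TestTripleIntersections:
    def test_three_planes_through_origin(self, camera):
        planes = [plane(1, 0, 0), plane(-1, 0, 0), plane(0, 1, 0)]
        pts = cm.triple_intersections(planes, full_mask(), None, camera)
        assert len(pts) == 1
        assert np.allclose(pts[0], [0, 0, 0], atol=1e-12)

    def test_parallel_planes_no_support(self, camera):
        planes = [plane(0, 0, 0), plane(0, 0, 10), plane(0, 0, 20)]
        with pytest.raises(NoSupportError):
            cm.triple_intersections(planes, full_mask(), None, camera)

    def test_four_planes_common_point_hand_oracle(self, camera):
        # four planes through (5, 5, 50) with distinct gradients; every
        # C(4,3) triple must solve to that point (hand 3x3 solve as oracle)
        target = np.array([5.0, 5.0, 50.0])
        grads = [(1, 0), (0, 1), (-1, 0.5), (0.3, -1)]
        planes = [
            plane(a, b, target[2] - a * target[0] - b * target[1]) for a, b in grads
        ]
        pts = cm.triple_intersections(planes, full_mask(), None, camera)
        assert len(pts) == 4
        from itertools import combinations

        for trio, pt in zip(combinations(planes, 3), pts):
            A = np.array([[p.a, p.b, -1.0] for p in trio])
            rhs = np.array([-p.c for p in trio])
            oracle = np.linalg.solve(A, rhs)
            assert np.allclose(pt, oracle, atol=1e-9)
            assert np.allclose(pt, target, atol=1e-9)

    def test_fewer_than_three_planes(self, camera):
        with pytest.raises(InsufficientPlanesError):
            cm.triple_intersections([plane(1, 0, 0)], None, None, camera)

    def test_mask_filter_rejects_outside_points(self, camera):
        # intersection at x = 2000 mm projects outside a small central mask
        target = np.array([2000.0, 0.0, 50.0])
        grads = [(1, 0), (0, 1), (-0.5, 0.5)]
        planes = [
            plane(a, b, target[2] - a * target[0] - b * target[1]) for a, b in grads
        ]
        raster = np.zeros((512, 512), dtype=bool)
        raster[250:260, 250:260] = True
        with pytest.raises(NoSupportError):
            cm.triple_intersections(
                planes, cm.InstanceMask(raster, "plant", 1), None, camera
            )

    def test_z_bounds_reject_below_ground(self, camera):
        target = np.array([0.0, 0.0, -100.0])
        grads = [(1, 0), (0, 1), (-0.5, 0.5)]
        planes = [
            plane(a, b, target[2] - a * target[0] - b * target[1]) for a, b in grads
        ]
        with pytest.raises(NoSupportError):
            cm.triple_intersections(planes, None, None, camera)


class TestAttachmentPoint:
    def test_mean_of_two_points(self):
        ap = cm.attachment_point([np.zeros(3), np.full(3, 2.0)])
        assert ap.position == pytest.approx((1.0, 1.0, 1.0))
        assert ap.support == 2

    def test_single_point_zero_dispersion(self):
        ap = cm.attachment_point([np.array([3.0, 4.0, 5.0])])
        assert ap.position == (3.0, 4.0, 5.0)
        assert ap.dispersion == 0.0

    def test_cube_corners_dispersion_sqrt3(self):
        # corners of a side-2 cube centered at (10,10,10): RMS distance √3
        corners = [
            np.array([10 + sx, 10 + sy, 10 + sz])
            for sx in (-1, 1)
            for sy in (-1, 1)
            for sz in (-1, 1)
        ]
        ap = cm.attachment_point(corners)
        assert ap.position == pytest.approx((10.0, 10.0, 10.0))
        assert ap.dispersion == pytest.approx(np.sqrt(3.0))

    def test_empty_list_rejected(self):
        with pytest.raises(NoSupportError):
            cm.attachment_point([])

    def test_median_aggregate_resists_one_wild_point(self):
        pts = [np.zeros(3)] * 5 + [np.array([1000.0, 0.0, 0.0])]
        med = cm.attachment_point(pts, aggregate="median")
        assert med.position == pytest.approx((0.0, 0.0, 0.0))


def clouds_from_scene(scene, depth):
    leaves = scene.masks("leaf")
    return [cm.backproject(m, depth, scene.camera) for m in leaves]


class TestLocateStem:
    def test_noiseless_funnel_recovery(self, funnel_scene, funnel_render):
        depth, _ = funnel_render
        clouds = clouds_from_scene(funnel_scene, depth)
        plant_mask = funnel_scene.masks("plant")[0]
        ap = cm.locate_stem(
            clouds, plant_mask, depth, funnel_scene.camera,
            cm.MsacConfig(rng_seed=1),
        )
        assert np.linalg.norm(ap.xyz - funnel_scene.plants[0].attachment) < 1.0

    def test_exact_planar_leaves_no_noise_solver_precision(self, camera):
        # synthetic planes through a common point, in-mask filter disabled:
        # recovery exact to solver precision
        p = np.array([10.0, -20.0, 60.0])
        rng = np.random.default_rng(9)
        clouds = []
        for k in range(6):
            az = 2 * np.pi * k / 6
            u = np.array([np.cos(az) * 0.9, np.sin(az) * 0.9, 0.45])
            w = np.array([-np.sin(az), np.cos(az), 0.0])
            s = rng.uniform(20, 200, 60)
            t = rng.uniform(-40, 40, 60)
            pts = p + np.outer(s, u) + np.outer(t, w)
            clouds.append(cm.LeafPointCloud(pts, leaf_id=k + 1))
        ap = cm.locate_stem(clouds, None, None, camera, cm.MsacConfig(rng_seed=2))
        assert np.linalg.norm(ap.xyz - p) < 1e-6

    def test_two_leaf_plant_rejected(self, camera):
        rng = np.random.default_rng(10)
        clouds = [
            cm.LeafPointCloud(rng.uniform(0, 10, (10, 3)), leaf_id=i) for i in (1, 2)
        ]
        with pytest.raises(InsufficientPlanesError):
            cm.locate_stem(clouds, None, None, camera)

    def test_translation_equivariance(self, camera):
        p = np.array([0.0, 0.0, 50.0])
        rng = np.random.default_rng(11)
        def make_clouds(offset):
            clouds = []
            for k in range(5):
                az = 2 * np.pi * k / 5
                u = np.array([np.cos(az) * 0.9, np.sin(az) * 0.9, 0.45])
                w = np.array([-np.sin(az), np.cos(az), 0.0])
                s = rng_k.uniform(20, 150, 40)
                t = rng_k.uniform(-30, 30, 40)
                clouds.append(
                    cm.LeafPointCloud(p + offset + np.outer(s, u) + np.outer(t, w), leaf_id=k + 1)
                )
            return clouds

        shift = np.array([120.0, -80.0, 30.0])
        rng_k = np.random.default_rng(12)
        ap0 = cm.locate_stem(make_clouds(np.zeros(3)), None, None, camera, cm.MsacConfig(rng_seed=3))
        rng_k = np.random.default_rng(12)  # identical cloud geometry
        ap1 = cm.locate_stem(make_clouds(shift), None, None, camera, cm.MsacConfig(rng_seed=3))
        assert np.allclose(ap1.xyz - ap0.xyz, shift, atol=1e-6)

    def test_leaf_order_permutation_invariant(self, camera):
        p = np.array([5.0, 5.0, 40.0])
        rng = np.random.default_rng(13)
        clouds = []
        for k in range(4):
            az = 2 * np.pi * k / 4 + 0.3
            u = np.array([np.cos(az) * 0.9, np.sin(az) * 0.9, 0.45])
            w = np.array([-np.sin(az), np.cos(az), 0.0])
            s = rng.uniform(20, 150, 30)
            t = rng.uniform(-30, 30, 30)
            clouds.append(cm.LeafPointCloud(p + np.outer(s, u) + np.outer(t, w), leaf_id=k + 1))
        results = set()
        for perm in list(permutations(range(4)))[:6]:
            ap = cm.locate_stem(
                [clouds[i] for i in perm], None, None, camera, cm.MsacConfig(rng_seed=4)
            )
            results.add(tuple(np.round(ap.xyz, 9)))
        assert len(results) == 1
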