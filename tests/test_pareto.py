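import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paretodose.errors import DegenerateDirectionError, ValidationError
from paretodose.grids import PriorityVector, VoxelGrid
from paretodose.pareto import (ParetoPoint, ParetoSurface, anpd, apd,
                               build_surface, compute_objectives,
                               dvh_dose_at_volume, grid_param_coords,
                               hausdorff, normalize_to_d95, pareto_rmse,
                               point_to_complex_distance, supersample_surface)


def _grid(vals):
    return VoxelGrid(values=np.asarray(vals, dtype=float), spacing=(1, 1, 1))


def _mask_like(vals, where=None):
    m = np.ones_like(np.asarray(vals, dtype=float)) if where is None else where
    return _grid(m)


class TestDvh:
    def test_uniform_dose(self):
        dose = _grid(np.full((2, 4, 4), 0.95))
        mask = _mask_like(dose.values)
        for x in (2, 25, 50, 95, 100):
            assert dvh_dose_at_volume(dose, mask, x) == pytest.approx(95.0)

    def test_sorting_rule_on_four_voxels(self):
        dose = _grid([[[0.1, 0.2], [0.3, 0.4]]])
        mask = _mask_like(dose.values)
        # descending [0.4, 0.3, 0.2, 0.1]; x=50 -> ceil(2) = 2nd hottest
        assert dvh_dose_at_volume(dose, mask, 50) == pytest.approx(30.0)

    def test_x_100_is_minimum(self):
        rng = np.random.default_rng(0)
        dose = _grid(rng.random((2, 5, 5)))
        mask = _mask_like(dose.values)
        assert dvh_dose_at_volume(dose, mask, 100) == \
            pytest.approx(100 * dose.values.min())

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sorting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((1, 6, 6))
        dose = _grid(vals)
        mask_arr = (rng.random((1, 6, 6)) < 0.6).astype(float)
        mask_arr[0, 0, 0] = 1
        mask = _grid(mask_arr)
        masked = sorted(vals[mask_arr.astype(bool)], reverse=True)
        for x in (1, 25, 33.3, 50, 95, 100):
            import math
            expected = 100 * masked[math.ceil(x / 100 * len(masked)) - 1]
            assert dvh_dose_at_volume(dose, mask, x) == pytest.approx(expected)

    def test_non_increasing_in_volume_fraction(self):
        rng = np.random.default_rng(2)
        dose = _grid(rng.random((2, 8, 8)))
        mask = _mask_like(dose.values)
        xs = np.linspace(1, 100, 34)
        ds = [dvh_dose_at_volume(dose, mask, x) for x in xs]
        assert all(a >= b for a, b in zip(ds, ds[1:]))

    def test_empty_mask_rejected(self):
        dose = _grid(np.ones((1, 2, 2)))
        with pytest.raises(ValidationError):
            dvh_dose_at_volume(dose, _grid(np.zeros((1, 2, 2))), 50)


class TestNormalization:
    def test_scales_to_exact_unity(self):
        rng = np.random.default_rng(1)
        dose = _grid(0.5 + 0.5 * rng.random((3, 6, 6)))
        ptv = _grid((rng.random((3, 6, 6)) < 0.4).astype(float))
        ptv.values[1, 3, 3] = 1
        normed = normalize_to_d95(dose, ptv)
        assert dvh_dose_at_volume(normed, ptv, 95) == pytest.approx(100.0,
                                                                    abs=1e-6)

    def test_idempotent_after_one_application(self):
        rng = np.random.default_rng(5)
        dose = _grid(0.2 + rng.random((2, 8, 8)))
        ptv = _grid(np.ones((2, 8, 8)))
        once = normalize_to_d95(dose, ptv)
        twice = normalize_to_d95(once, ptv)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-12)

    def test_prescaled_dose_unchanged(self):
        dose = _grid(np.full((1, 4, 4), 0.9))
        ptv = _grid(np.ones((1, 4, 4)))
        normed = normalize_to_d95(dose, ptv)
        np.testing.assert_allclose(normed.values, 1.0)
        again = normalize_to_d95(normed, ptv)
        np.testing.assert_array_equal(again.values, normed.values)


class TestObjectives:
    def test_uniform_dose_zero_hi(self, toy_structures):
        dose = toy_structures.grid.copy_with(
            np.full(toy_structures.grid.shape, 0.3))
        pt = compute_objectives(dose, toy_structures)
        assert pt.hi == pytest.approx(0.0)
        assert pt.bladder_d25 == pytest.approx(30.0)

    def test_hundred_voxel_ptv_order_statistics(self):
        # 98 voxels at 1.00, one at 1.10, one at 0.90 -> with the ceil rule
        # D2% is the 2nd hottest (1.00) and D98% the 98th hottest (1.00)
        shape = (1, 10, 10)
        vals = np.full(shape, 1.00)
        vals[0, 0, 0] = 1.10
        vals[0, 9, 9] = 0.90
        dose = _grid(vals)
        ptv = _grid(np.ones(shape))
        assert dvh_dose_at_volume(dose, ptv, 2) == pytest.approx(100.0)
        assert dvh_dose_at_volume(dose, ptv, 98) == pytest.approx(100.0)
        assert dvh_dose_at_volume(dose, ptv, 1) == pytest.approx(110.0)
        assert dvh_dose_at_volume(dose, ptv, 100) == pytest.approx(90.0)


def _square_surface(z=0.0, jitter=None):
    """A unit-square planar surface split into 2 triangles at height z."""
    verts = np.array([[0, 0, z], [1, 0, z], [0, 1, z], [1, 1, z]], float)
    if jitter is not None:
        verts = verts + jitter
    simplices = np.array([[0, 1, 3], [0, 3, 2]])
    params = verts[:, :2].copy()
    pts = [ParetoPoint(*v) for v in verts]
    return ParetoSurface(vertices=verts, simplices=simplices, params=params,
                         priorities=[PriorityVector(1, 1, 1)] * 4,
                         plan_ids=[str(i) for i in range(4)])


class TestSurfaceConstruction:
    def test_5x5_grid_yields_25_vertices_32_triangles(self):
        rng = np.random.default_rng(0)
        pts = [(PriorityVector(1, 1, 1), ParetoPoint(*rng.random(3)))
               for _ in range(25)]
        surf = build_surface(pts)
        assert len(surf.vertices) == 25
        assert len(surf.simplices) == 32

    def test_three_points_single_triangle(self):
        pts = [(PriorityVector(1, 1, 1), ParetoPoint(0, 0, 0)),
               (PriorityVector(1, 2, 1), ParetoPoint(1, 0, 0)),
               (PriorityVector(1, 1, 2), ParetoPoint(0, 1, 0))]
        surf = build_surface(pts)
        assert len(surf.simplices) == 1

    def test_every_vertex_in_a_simplex(self):
        rng = np.random.default_rng(3)
        pts = [(PriorityVector(1, 1, 1), ParetoPoint(*rng.random(3)))
               for _ in range(25)]
        surf = build_surface(pts)
        assert set(surf.simplices.ravel()) == set(range(25))

    def test_duplicate_param_coords_rejected(self):
        rng = np.random.default_rng(1)
        pts = [(PriorityVector(1, 1, 1), ParetoPoint(*rng.random(3)))
               for _ in range(4)]
        coords = np.array([[0, 0], [0, 1], [1, 0], [0, 0]], float)
        with pytest.raises(ValidationError):
            build_surface(pts, param_coords=coords)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            build_surface([(PriorityVector(1, 1, 1), ParetoPoint(0, 0, 0))] * 2)


class TestParetoRmse:
    def test_identical_surfaces_zero(self):
        pts = np.random.default_rng(0).random((25, 3))
        assert pareto_rmse(list(zip(pts, pts))) == 0.0

    def test_three_four_five(self):
        assert pareto_rmse([(np.array([3.0, 4.0, 0.0]),
                             np.zeros(3))]) == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random((25, 3)), rng.random((25, 3))
        acc = sum(np.sum((x - y) ** 2) for x, y in zip(a, b))
        expected = np.sqrt(acc / 25)
        assert pareto_rmse(list(zip(a, b))) == pytest.approx(expected, rel=1e-12)


class TestHausdorff:
    def test_singletons(self):
        assert hausdorff(np.array([[0.0]]), np.array([[3.0]])) == 3.0

    def test_asymmetric_directed_distances(self):
        A = np.array([[0.0], [1.0]])
        B = np.array([[0.0], [5.0]])
        # A->B sup inf = 1 (from 1 to 0); B->A = 4 (from 5 to 1)
        assert hausdorff(A, B) == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A, B = rng.random((8, 3)), rng.random((11, 3))
        d_ab = max(min(np.linalg.norm(a - b) for b in B) for a in A)
        d_ba = max(min(np.linalg.norm(a - b) for a in A) for b in B)
        assert hausdorff(A, B) == pytest.approx(max(d_ab, d_ba), rel=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_metric_axioms_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        A, B, C = (rng.random((4, 3)) for _ in range(3))
        assert hausdorff(A, A) == 0.0
        assert hausdorff(A, B) == pytest.approx(hausdorff(B, A))
        assert hausdorff(A, C) <= hausdorff(A, B) + hausdorff(B, C) + 1e-12


class TestApd:
    def test_parallel_displacements_give_common_magnitude(self):
        y = np.random.default_rng(0).random((6, 3))
        x = y + np.array([0.0, -1.0, 0.0])
        assert apd(list(zip(x, y))) == pytest.approx(1.0)

    def test_opposed_displacements_degenerate(self):
        pairs = [(np.array([0.0, 1.0, 0.0]), np.zeros(3)),
                 (np.array([0.0, -1.0, 0.0]), np.zeros(3))]
        with pytest.raises(DegenerateDirectionError):
            apd(pairs)

    def test_orthogonal_pair_projection(self):
        pairs = [(np.array([1.0, 0.0, 0.0]), np.zeros(3)),
                 (np.array([0.0, 1.0, 0.0]), np.zeros(3))]
        assert apd(pairs) == pytest.approx(1 / np.sqrt(2))

    def test_self_comparison_is_zero(self):
        pts = np.random.default_rng(1).random((10, 3))
        assert apd(list(zip(pts, pts))) == 0.0

    def test_rotation_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.random((8, 3)), rng.random((8, 3))
        base = apd(list(zip(x, y)))
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert apd(list(zip(x @ q.T, y @ q.T))) == pytest.approx(base, rel=1e-9)


class TestAnpd:
    def test_identical_surfaces_zero(self):
        s = _square_surface()
        assert anpd(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_parallel_planes_unit_apart(self):
        a, b = _square_surface(0.0), _square_surface(1.0)
        for density in (3, 105):
            assert anpd(a, b, density=density) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_sampling_oracle(self, seed):
        rng = np.random.default_rng(seed)

        def random_triangle_surface():
            v = rng.random((3, 3))
            return ParetoSurface(vertices=v, simplices=np.array([[0, 1, 2]]),
                                 params=np.array([[0, 0], [1, 0], [0, 1]], float),
                                 priorities=[PriorityVector(1, 1, 1)] * 3,
                                 plan_ids=["0", "1", "2"])

        A, B = random_triangle_surface(), random_triangle_surface()

        def dense_points(surface, n=10000):
            r1, r2 = rng.random(n), rng.random(n)
            u = np.sqrt(r1)
            bary = np.column_stack([1 - u, u * (1 - r2), u * r2])
            return bary @ surface.vertices

        pa, pb = dense_points(A), dense_points(B)
        d_ab = np.array([np.linalg.norm(pb - p, axis=1).min()
                         for p in supersample_surface(A, 105)]).mean()
        d_ba = np.array([np.linalg.norm(pa - p, axis=1).min()
                         for p in supersample_surface(B, 105)]).mean()
        oracle = 0.5 * (d_ab + d_ba)
        assert anpd(A, B, density=105) == pytest.approx(oracle, rel=0.02)

    def test_degenerate_triangles_handled(self):
        # all vertices identical: distance is point-to-point
        v = np.tile(np.array([1.0, 2.0, 3.0]), (3, 1))
        collapsed = ParetoSurface(vertices=v, simplices=np.array([[0, 1, 2]]),
                                  params=np.array([[0, 0], [1, 0], [0, 1]],
                                                  float),
                                  priorities=[PriorityVector(1, 1, 1)] * 3,
                                  plan_ids=["0", "1", "2"])
        d = point_to_complex_distance(np.array([[1.0, 2.0, 4.0]]), collapsed)
        assert d[0] == pytest.approx(1.0)

    def test_bounded_by_hausdorff_of_supersampled_clouds(self):
        rng = np.random.default_rng(9)
        a = _square_surface(0.0, jitter=0.1 * rng.random((4, 3)))
        b = _square_surface(0.5, jitter=0.1 * rng.random((4, 3)))
        pa, pb = supersample_surface(a, 105), supersample_surface(b, 105)
        assert anpd(a, b) <= hausdorff(pa, pb) + 1e-12

    def test_invalid_density_rejected(self):
        s = _square_surface()
        with pytest.raises(ValidationError):
            anpd(s, s, density=0)


class TestSurfaceExport:
    def test_json_and_csv_round_trip(self, tmp_path):
        import json
        from paretodose.pareto import surface_to_csv, surface_to_json
        s = _square_surface(0.5)
        blob = surface_to_json(s)
        json.dumps(blob)  # serializable
        assert len(blob["vertices"]) == 4 and len(blob["simplices"]) == 2
        surface_to_csv(s, tmp_path / "surf.csv")
        import pandas as pd
        df = pd.read_csv(tmp_path / "surf.csv")
        assert list(df.columns) == ["plan_id", "hi", "bladder_d25",
                                    "rectum_d25"]
        np.testing.assert_allclose(df[["hi", "bladder_d25", "rectum_d25"]],
                                   s.vertices)
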