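"""Ray traversal and the per-ray reduction of 3-D fields to the plane."""

import numpy as np
import pytest

import ifp
from ifp.bev import trace_ray_voxels

from conftest import sphere_mask


def ray_box_lengths_oracle(ray, grid):
    """Independent per-voxel chord lengths: slab-test the ray against every
    voxel's box (no traversal)."""
    src = np.asarray(ray.source)
    d = np.asarray(ray.direction)
    out = {}
    for idx in np.ndindex(grid.shape):
        lo = grid.index_to_world(idx) - 0.5 * np.asarray(grid.spacing)
        hi = lo + np.asarray(grid.spacing)
        t0, t1 = 0.0, np.inf
        ok = True
        for a in range(3):
            if abs(d[a]) < 1e-12:
                if not (lo[a] <= src[a] <= hi[a]):
                    ok = False
                    break
                continue
            ta, tb = sorted(((lo[a] - src[a]) / d[a], (hi[a] - src[a]) / d[a]))
            t0, t1 = max(t0, ta), min(t1, tb)
        if ok and t1 - t0 > 1e-9:
            out[idx] = t1 - t0
    return out


class TestTraceRayVoxels:
    def test_axis_aligned_ray_through_grid(self, unit_grid):
        ray = ifp.Ray(source=(-5.0, 2.0, 2.0), direction=(1.0, 0.0, 0.0))
        crossed = trace_ray_voxels(ray, unit_grid)
        assert [c[0] for c in crossed] == [(i, 2, 2) for i in range(5)]
        assert all(l == pytest.approx(1.0, abs=1e-12) for _, l in crossed)

    def test_miss_returns_empty(self, unit_grid):
        ray = ifp.Ray(source=(-5.0, 50.0, 2.0), direction=(1.0, 0.0, 0.0))
        assert trace_ray_voxels(ray, unit_grid) == []

    def test_oblique_rays_match_per_voxel_oracle(self, centered_grid8, rng):
        for _ in range(50):
            src = rng.uniform(-200, -100, 3)
            tgt = rng.uniform(-30, 30, 3)
            d = tgt - src
            d /= np.linalg.norm(d)
            ray = ifp.Ray(source=src, direction=d)
            got = dict(trace_ray_voxels(ray, centered_grid8))
            expected = ray_box_lengths_oracle(ray, centered_grid8)
            assert set(got) == set(expected)
            for idx, l in expected.items():
                assert got[idx] == pytest.approx(l, abs=1e-6)

    def test_chord_conservation(self, centered_grid8, rng):
        lo, hi = centered_grid8.bbox_min, centered_grid8.bbox_max
        for _ in range(200):
            src = rng.uniform(-300, -150, 3)
            tgt = rng.uniform(lo, hi)
            d = tgt - src
            d /= np.linalg.norm(d)
            crossed = trace_ray_voxels(ifp.Ray(source=src, direction=d),
                                       centered_grid8)
            total = sum(l for _, l in crossed)
            # chord oracle: slab method on the full box
            t0, t1 = 0.0, np.inf
            for a in range(3):
                ta, tb = sorted(((lo[a] - src[a]) / d[a], (hi[a] - src[a]) / d[a]))
                t0, t1 = max(t0, ta), min(t1, tb)
            assert total == pytest.approx(max(t1 - t0, 0.0), abs=1e-6)


def brute_force_bev(dvf, roi, beam, plane, length_weighted=False):
    """Reference reduction: enumerate ROI voxels, slab-test each pixel's ray
    against each voxel box, project and average.  No traversal involved."""
    vectors = np.zeros(plane.shape + (2,))
    coverage = np.zeros(plane.shape, dtype=int)
    centers = plane.pixel_centers()
    idxs = np.argwhere(roi.mask)
    for ip in range(plane.shape[0]):
        for jp in range(plane.shape[1]):
            ray = ifp.pixel_ray(centers[ip, jp], beam.sad, beam)
            lens = ray_box_lengths_oracle(ray, roi.grid)
            kept = [(tuple(i), lens.get(tuple(i), 0.0)) for i in idxs]
            kept = [(i, l) for i, l in kept if l > 1e-9]
            if not kept:
                continue
            projs = []
            for i, l in kept:
                start_w = roi.grid.index_to_world(i)
                end_w = start_w + dvf.vectors[i]
                projs.append(ifp.project_vector(
                    ifp.world_to_beam(start_w, beam),
                    ifp.world_to_beam(end_w, beam), beam.sad))
            projs = np.asarray(projs)
            if length_weighted:
                w = np.array([l for _, l in kept])
                vectors[ip, jp] = (projs * (w / w.sum())[:, None]).sum(axis=0)
            else:
                vectors[ip, jp] = projs.mean(axis=0)
            coverage[ip, jp] = len(kept)
    return vectors, coverage


class TestProjectDvfToBev:
    plane = ifp.PlaneGrid((10, 10), (6.0, 6.0), (-27.0, -27.0))

    def test_zero_dvf_gives_zero_vectors_with_coverage(self, centered_grid8):
        roi = sphere_mask(centered_grid8, (0, 0, 0), 25.0)
        beam = ifp.BeamGeometry(0.0, 1000.0, (0, 0, 0))
        d2 = ifp.project_dvf_to_bev(ifp.make_dvf("zero", {}, centered_grid8),
                                    roi, beam, self.plane)
        assert np.all(d2.vectors == 0.0)
        assert d2.coverage[5, 5] > 0

    def test_single_voxel_roi_mean_is_the_element(self, centered_grid8, rng):
        mask = np.zeros(centered_grid8.shape, bool)
        mask[4, 4, 4] = True
        roi = ifp.ROIMask(grid=centered_grid8, mask=mask)
        vec = rng.normal(size=centered_grid8.shape + (3,))
        dvf = ifp.DVF3D(grid=centered_grid8, vectors=vec)
        beam = ifp.BeamGeometry(0.0, 1000.0, (0, 0, 0))
        d2 = ifp.project_dvf_to_bev(dvf, roi, beam, self.plane)
        covered = np.argwhere(d2.coverage > 0)
        assert len(covered) >= 1
        ip, jp = covered[0]
        start_w = centered_grid8.index_to_world((4, 4, 4))
        expected = ifp.project_vector(
            ifp.world_to_beam(start_w, beam),
            ifp.world_to_beam(start_w + vec[4, 4, 4], beam), 1000.0)
        assert np.allclose(d2.vectors[ip, jp], expected, atol=1e-9)

    def test_two_voxels_on_one_ray_average(self, unit_grid):
        # vertical beam at gantry 0 travels along -y; stack two ROI voxels in y
        grid = ifp.Grid3D((5, 5, 5), (1.0, 1.0, 1.0), (-2.0, -2.0, -2.0))
        mask = np.zeros(grid.shape, bool)
        mask[2, 1, 2] = mask[2, 3, 2] = True
        vec = np.zeros(grid.shape + (3,))
        vec[2, 1, 2] = (-2.0, 0.0, 0.0)   # beam-frame x is -world x at gantry 0
        vec[2, 3, 2] = (-4.0, 0.0, 0.0)
        dvf = ifp.DVF3D(grid=grid, vectors=vec)
        beam = ifp.BeamGeometry(0.0, 1e7, (0, 0, 0))  # ~parallel: no magnification
        plane = ifp.PlaneGrid((5, 5), (1.0, 1.0), (-2.0, -2.0))
        d2 = ifp.project_dvf_to_bev(dvf, ifp.ROIMask(grid=grid, mask=mask),
                                    beam, plane)
        assert d2.coverage[2, 2] == 2
        assert np.allclose(d2.vectors[2, 2], (3.0, 0.0), atol=1e-4)

    def test_matches_brute_force_oracle(self, centered_grid8, rng):
        mask = rng.random(centered_grid8.shape) < 0.3
        mask[3:5, 3:5, 3:5] = True
        roi = ifp.ROIMask(grid=centered_grid8, mask=mask)
        dvf = ifp.DVF3D(grid=centered_grid8,
                        vectors=rng.normal(0, 3, centered_grid8.shape + (3,)))
        for gantry in (0.0, 72.0, 144.0):
            beam = ifp.BeamGeometry(gantry, 1000.0, (0, 0, 0))
            d2 = ifp.project_dvf_to_bev(dvf, roi, beam, self.plane)
            vec, cov = brute_force_bev(dvf, roi, beam, self.plane)
            assert np.array_equal(d2.coverage, cov)
            assert np.allclose(d2.vectors, vec, atol=1e-9)

    def test_empty_roi_rejected(self, centered_grid8):
        roi = ifp.ROIMask(grid=centered_grid8,
                          mask=np.zeros(centered_grid8.shape, bool))
        beam = ifp.BeamGeometry(0.0, 1000.0, (0, 0, 0))
        with pytest.raises(ValueError):
            ifp.project_dvf_to_bev(ifp.make_dvf("zero", {}, centered_grid8),
                                   roi, beam, self.plane)

    def test_frame_covariance_under_90_degree_rotation(self, rng):
        # rotating anatomy and beam together by 90 deg about the patient
        # axis leaves the plane field unchanged (centered square grid maps
        # onto itself)
        grid = ifp.Grid3D((8, 8, 8), (10.0,) * 3, (-35.0,) * 3)
        mask = rng.random(grid.shape) < 0.4
        mask[4, 4, 4] = True
        vec = rng.normal(0, 3, grid.shape + (3,))
        beam = ifp.BeamGeometry(40.0, 1000.0, (0, 0, 0))
        plane = ifp.PlaneGrid((10, 10), (6.0, 6.0), (-27.0, -27.0))
        d2 = ifp.project_dvf_to_bev(
            ifp.DVF3D(grid=grid, vectors=vec),
            ifp.ROIMask(grid=grid, mask=mask), beam, plane)
        # rotate: world (x,y,z) -> (-y,x,z); arrays: new[i,j,k]=old[j,n-1-i,k]
        rot_mask = np.rot90(mask, 1, axes=(0, 1))
        rot_vec = np.rot90(vec, 1, axes=(0, 1)).copy()
        rot_vec = np.stack([-rot_vec[..., 1], rot_vec[..., 0], rot_vec[..., 2]],
                           axis=-1)
        beam_rot = ifp.BeamGeometry((40.0 - 90.0) % 360.0, 1000.0, (0, 0, 0))
        d2_rot = ifp.project_dvf_to_bev(
            ifp.DVF3D(grid=grid, vectors=rot_vec),
            ifp.ROIMask(grid=grid, mask=rot_mask), beam_rot, plane)
        assert np.array_equal(d2.coverage, d2_rot.coverage)
        assert np.allclose(d2.vectors, d2_rot.vectors, atol=1e-9)


class TestFillUncovered:
    def _field(self):
        plane = ifp.PlaneGrid((5, 5), (1.0, 1.0), (0.0, 0.0))
        vec = np.zeros((5, 5, 2))
        cov = np.zeros((5, 5), int)
        vec[2, 2] = (5.0, 0.0)
        cov[2, 2] = 3
        return ifp.DVF2D(plane=plane, vectors=vec, coverage=cov)

    def test_zero_mode_is_identity(self):
        d = self._field()
        out = ifp.fill_uncovered(d, "zero")
        assert np.array_equal(out.vectors, d.vectors)

    def test_nearest_from_single_covered_pixel(self):
        out = ifp.fill_uncovered(self._field(), "nearest")
        assert np.all(out.vectors[..., 0] == 5.0)
        assert np.all(out.vectors[..., 1] == 0.0)

    def test_smooth_interpolates_between_boundary_values(self):
        plane = ifp.PlaneGrid((3, 5), (1.0, 1.0), (0.0, 0.0))
        vec = np.zeros((3, 5, 2))
        cov = np.zeros((3, 5), int)
        vec[:, 0, 0] = 0.0
        vec[:, 4, 0] = 4.0
        cov[:, 0] = cov[:, 4] = 1
        d = ifp.DVF2D(plane=plane, vectors=vec, coverage=cov)
        out = ifp.fill_uncovered(d, "smooth")
        assert np.allclose(out.vectors[:, 2, 0], 2.0, atol=1e-8)

    def test_all_covered_identity_and_no_covered_error(self):
        plane = ifp.PlaneGrid((3, 3), (1.0, 1.0), (0.0, 0.0))
        full = ifp.DVF2D(plane=plane, vectors=np.ones((3, 3, 2)),
                         coverage=np.ones((3, 3), int))
        for mode in ("zero", "nearest", "smooth"):
            assert np.array_equal(ifp.fill_uncovered(full, mode).vectors,
                                  full.vectors)
        empty = ifp.DVF2D(plane=plane, vectors=np.zeros((3, 3, 2)),
                          coverage=np.zeros((3, 3), int))
        with pytest.raises(ValueError):
            ifp.fill_uncovered(empty, "nearest")


class TestDepthMagnification:
    @pytest.mark.parametrize("z0", [-100.0, 0.0, 100.0, 250.0])
    def test_slab_translation_magnified_by_depth(self, z0):
        # gantry 0: beam axis = +world y, so a slab at beam depth z0 is a
        # single voxel layer at world y = z0
        grid = ifp.Grid3D((8, 8, 8), (10.0, 50.0, 10.0), (-35.0, -100.0, -35.0))
        iy = int((z0 + 100.0) / 50.0)
        assert grid.origin[1] + iy * 50.0 == z0
        mask = np.zeros(grid.shape, bool)
        mask[:, iy, :] = True
        t_world = np.array([3.0, 0.0, -2.0])  # no component along world y
        dvf = ifp.make_dvf("translation", {"translation": t_world}, grid)
        beam = ifp.BeamGeometry(0.0, 1000.0, (0, 0, 0))
        plane = ifp.PlaneGrid((10, 10), (5.0, 5.0), (-22.5, -22.5))
        d2 = ifp.project_dvf_to_bev(dvf, ifp.ROIMask(grid=grid, mask=mask),
                                    beam, plane)
        mag = 1000.0 / (1000.0 - z0)
        expected = np.array([-3.0, -2.0]) * mag  # beam frame: x=-xw, y=+zw
        covered = d2.coverage > 0
        assert covered.sum() > 10
        assert np.allclose(d2.vectors[covered], expected, atol=1e-6)
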