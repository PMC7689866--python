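"""3D segmentation: thresholds, flood fills, dilation, contact areas."""

import itertools
import math

import numpy as np
import pytest

from calyxsf.datatypes import ClusterSet, SomaMask, VolumeParams, VoxelVolume
from calyxsf.errors import EmptySomaError, ThresholdError
from calyxsf.seg3d import (
    contact_report,
    dilate_soma,
    floodfill_clusters,
    isodata_threshold,
    optimize_dilation,
    soma_surface_area,
    sphere_floodfill,
)
from calyxsf.synth import synth_volume

from conftest import make_cell

SIM_VS = (0.110, 0.041, 0.041)


def brute_force_label26(mask):
    """Independent 26-connected labelling by iterative min-label propagation."""
    lab = np.where(mask, np.arange(mask.size).reshape(mask.shape) + 1, 0)
    while True:
        new = lab.copy()
        for dz, dy, dx in itertools.product((-1, 0, 1), repeat=3):
            if dz == dy == dx == 0:
                continue
            shifted = np.full_like(lab, np.iinfo(lab.dtype).max)
            src = [slice(max(-d, 0), lab.shape[k] - max(d, 0)) for k, d in enumerate((dz, dy, dx))]
            dst = [slice(max(d, 0), lab.shape[k] - max(-d, 0)) for k, d in enumerate((dz, dy, dx))]
            shifted[tuple(dst)] = lab[tuple(src)]
            np.minimum(new, np.where(mask & (shifted > 0), shifted, new.dtype.type(np.iinfo(lab.dtype).max)), out=new, where=mask)
        if np.array_equal(new, lab):
            break
        lab = new
    return lab


def partitions_equal(lab_a, lab_b):
    """Same connected components regardless of label values."""
    fa = lab_a.ravel()
    fb = lab_b.ravel()
    fg = (fa > 0) | (fb > 0)
    if not np.array_equal(fa > 0, fb > 0):
        return False
    pairs = set(zip(fa[fg].tolist(), fb[fg].tolist()))
    return len(pairs) == len({a for a, _ in pairs}) == len({b for _, b in pairs})


class TestIsodata:
    def test_symmetric_two_level(self):
        vol = np.array([10.0, 90.0] * 50).reshape(10, 5, 2)
        assert isodata_threshold(VoxelVolume(vol, SIM_VS)) == pytest.approx(50.0)

    def test_constant_volume_error(self):
        with pytest.raises(ThresholdError):
            isodata_threshold(VoxelVolume(np.full((4, 4, 4), 7.0), SIM_VS))

    def test_fixed_point_of_intermeans_map(self, rng):
        for _ in range(20):
            vals = rng.normal(rng.uniform(10, 50), rng.uniform(1, 20), (16, 16, 16))
            t = isodata_threshold(VoxelVolume(vals, SIM_VS))
            m0 = vals[vals <= t].mean()
            m1 = vals[vals > t].mean()
            t_new = 0.5 * (m0 + m1)
            # fixed point: re-applying the map does not change the partition
            assert np.array_equal(vals <= t, vals <= t_new)

    def test_bimodal_mixture_between_modes(self, rng):
        vals = np.concatenate([rng.normal(20, 10, 2000), rng.normal(200, 10, 2000)])
        t = isodata_threshold(vals.reshape(20, 20, 10))
        assert 50 < t < 170

    def test_scale_invariance(self, rng):
        vals = rng.uniform(0, 100, (12, 12, 12))
        t1 = isodata_threshold(VoxelVolume(vals, SIM_VS))
        t2 = isodata_threshold(VoxelVolume(3.5 * vals, SIM_VS))
        assert t2 == pytest.approx(3.5 * t1, rel=1e-9)

    def test_agrees_with_reference_histogram_variant(self, rng):
        from skimage.filters import threshold_isodata

        vals = np.concatenate([rng.normal(30, 8, 3000), rng.normal(150, 15, 3000)])
        t = isodata_threshold(vals.reshape(30, 20, 10))
        t_ref = threshold_isodata(vals)
        assert t == pytest.approx(t_ref, abs=0.05 * np.ptp(vals))


class TestSphereFloodfill:
    def _ball_volume(self, radius_um=2.0, vs=(0.22, 0.082, 0.082), hi=100.0, lo=0.0):
        half = np.ceil((radius_um + 0.6) / np.array(vs)).astype(int)
        zz, yy, xx = np.meshgrid(*[np.arange(-h, h + 1) * v for h, v in zip(half, vs)], indexing="ij")
        r2 = zz**2 + yy**2 + xx**2
        vol = np.where(r2 <= radius_um**2, hi, lo).astype(np.float32)
        return VoxelVolume(vol, vs), r2

    def test_interior_of_solid_ball_in_mask(self):
        vol, r2 = self._ball_volume()
        soma = sphere_floodfill(vol, radius=0.4, threshold=50.0)
        interior = r2 <= (2.0 - 0.45) ** 2
        assert np.all(soma.mask[interior])

    def test_below_threshold_empty_error(self):
        vol, _ = self._ball_volume(hi=10.0)
        with pytest.raises(EmptySomaError):
            sphere_floodfill(vol, radius=0.4, threshold=50.0)

    def test_noisy_soma_volume_within_10pct(self):
        for seed in range(3):
            cell = make_cell([1.0], soma_radius=2.5)
            cell.true_contact_areas = np.zeros(0)
            cell.inputs = []
            vp = VolumeParams(
                voxel_size=(0.22, 0.082, 0.082), psf_sigma=(0.12, 0.05, 0.05),
                gaussian_sd=20.0, margin=2.4, seed=seed,
            )
            fill, _, _, extras = synth_volume(cell, vp, full_output=True)
            soma = sphere_floodfill(fill, radius=0.4)
            true_n = extras["soma_mask"].sum()
            assert soma.n_voxels == pytest.approx(true_n, rel=0.10)


class TestFloodfillClusters:
    def test_two_separated_blobs(self):
        vol = np.zeros((10, 20, 20), dtype=np.float32)
        vol[4:7, 2:6, 2:6] = 100
        vol[4:7, 10:14, 10:14] = 100
        cs = floodfill_clusters(VoxelVolume(vol, SIM_VS), threshold=50.0)
        assert cs.n_clusters == 2

    def test_diagonal_touch_is_one_cluster(self):
        vol = np.zeros((8, 8, 8), dtype=np.float32)
        vol[2:4, 2:4, 2:4] = 100
        vol[4:6, 4:6, 4:6] = 100  # corner-adjacent blocks
        cs = floodfill_clusters(VoxelVolume(vol, SIM_VS), threshold=50.0, min_size=1)
        assert cs.n_clusters == 1

    def test_min_size_filter(self, rng):
        vol = np.zeros((10, 10, 10), dtype=np.float32)
        vol[5, 5, 5] = 100  # single speck
        vol[1:4, 1:4, 1:4] = 100
        cs = floodfill_clusters(VoxelVolume(vol, SIM_VS), threshold=50.0, min_size=10)
        assert cs.n_clusters == 1

    def test_matches_bruteforce_labelling(self, rng):
        for _ in range(10):
            mask = rng.random((16, 16, 16)) < rng.uniform(0.1, 0.4)
            vol = VoxelVolume(np.where(mask, 100.0, 0.0), SIM_VS)
            cs = floodfill_clusters(vol, threshold=50.0, min_size=1)
            ref = brute_force_label26(mask)
            assert partitions_equal(cs.labels, ref)

    def test_labels_dense_and_disjoint(self, rng):
        mask = rng.random((20, 20, 20)) < 0.3
        cs = floodfill_clusters(VoxelVolume(np.where(mask, 9.0, 0.0), SIM_VS), threshold=5.0, min_size=1)
        labs = np.unique(cs.labels)
        assert labs[0] == 0
        assert np.array_equal(labs[1:], np.arange(1, cs.n_clusters + 1))


class TestDilateSoma:
    def _single_voxel(self):
        m = np.zeros((9, 9, 9), dtype=bool)
        m[4, 4, 4] = True
        return SomaMask(mask=m, voxel_size=SIM_VS)

    def test_distance_zero_identity(self):
        soma = self._single_voxel()
        assert np.array_equal(dilate_soma(soma, 0.0).mask, soma.mask)

    def test_inplane_neighbourhood_at_small_distance(self):
        # 0.06 um reaches only the in-plane 3x3 ring (lateral 41 nm,
        # diagonal 58 nm; axial 110 nm and 2-step 82 nm are beyond)
        out = dilate_soma(self._single_voxel(), 0.06).mask
        expect = np.zeros_like(out)
        expect[4, 3:6, 3:6] = True
        assert np.array_equal(out, expect)

    def test_matches_distance_enumeration(self):
        # oracle: every voxel within the physical distance, nothing else
        d = 0.12
        out = dilate_soma(self._single_voxel(), d).mask
        expect = np.zeros_like(out)
        for z, y, x in itertools.product(range(9), repeat=3):
            dist = math.sqrt(
                ((z - 4) * SIM_VS[0]) ** 2 + ((y - 4) * SIM_VS[1]) ** 2 + ((x - 4) * SIM_VS[2]) ** 2
            )
            expect[z, y, x] = dist <= d
        assert np.array_equal(out, expect)

    def test_monotone_in_distance(self):
        soma = self._single_voxel()
        m1 = dilate_soma(soma, 0.10).mask
        m2 = dilate_soma(soma, 0.20).mask
        assert np.all(m2[m1])


@pytest.fixture(scope="module")
def cap_scene():
    cell = make_cell([1.0], soma_radius=4.5)
    cell.true_contact_areas = np.array([0.4, 2.0, 10.0, 30.0, 60.0])
    cell.inputs = cell.inputs * 5
    vp = VolumeParams(psf_sigma=(0, 0, 0), gaussian_sd=0.0, cleft_offset=0.3, seed=3)
    fill, marker, report, extras = synth_volume(cell, vp, full_output=True)
    return cell, vp, report, extras


class TestContactAndDilation:
    def test_cap_areas_within_15pct_and_monotone(self, cap_scene):
        _, _, report, _ = cap_scene
        req = np.array([0.4, 2.0, 10.0, 30.0, 60.0])
        meas = np.sort(report.cluster_areas)
        assert np.all(np.diff(meas) > 0)
        assert np.allclose(meas, req, rtol=0.15)

    def test_cap_ratios_within_10pct(self, cap_scene):
        _, _, report, _ = cap_scene
        req = np.array([0.4, 2.0, 10.0, 30.0, 60.0])
        meas = np.sort(report.cluster_areas)
        assert np.allclose((meas / meas[-1]), (req / req[-1]), rtol=0.10)

    def test_fractions_bounded(self, cap_scene):
        _, _, report, _ = cap_scene
        assert 0.0 < report.contact_ratio <= 1.0
        assert 0.0 <= report.coverage_fraction <= 1.0

    def test_far_cluster_zero_contact(self):
        mask = np.zeros((20, 40, 40), dtype=bool)
        mask[8:12, 15:25, 15:25] = True
        soma = SomaMask(mask=mask, voxel_size=SIM_VS)
        labels = np.zeros_like(mask, dtype=np.int32)
        labels[0:2, 0:4, 0:4] = 1
        rep = contact_report(soma, ClusterSet(labels=labels, voxel_size=SIM_VS))
        assert rep.cluster_areas[0] == 0.0

    def test_full_coverage_unity(self):
        mask = np.zeros((16, 24, 24), dtype=bool)
        mask[6:10, 8:16, 8:16] = True
        soma = SomaMask(mask=mask, voxel_size=SIM_VS)
        labels = np.ones_like(mask, dtype=np.int32)
        labels[mask] = 1  # everywhere, including every surface voxel
        rep = contact_report(soma, ClusterSet(labels=labels, voxel_size=SIM_VS))
        assert rep.contact_ratio == pytest.approx(1.0)
        assert rep.coverage_fraction == pytest.approx(1.0)

    def test_sum_law(self, cap_scene):
        _, _, report, _ = cap_scene
        assert report.total_contact_area == pytest.approx(report.cluster_areas.sum())

    def test_dilation_recovers_cleft_offset(self):
        cell = make_cell([1.0, 1.0], soma_radius=3.0)
        cell.true_contact_areas = np.array([8.0, 3.0])
        vp = VolumeParams(
            psf_sigma=(0, 0, 0), gaussian_sd=0.0, cleft_offset=0.3, shell_thickness=0.12, seed=6
        )
        _, _, _, extras = synth_volume(cell, vp, full_output=True)
        soma = SomaMask(mask=extras["soma_mask"], voxel_size=vp.voxel_size)
        clus = ClusterSet(labels=extras["labels"], voxel_size=vp.voxel_size)
        d = optimize_dilation(soma, clus)
        assert abs(d - 0.3) <= 0.041 + 1e-9

    def test_touching_clusters_lower_bound(self):
        cell = make_cell([1.0], soma_radius=2.5)
        cell.true_contact_areas = np.array([6.0])
        vp = VolumeParams(psf_sigma=(0, 0, 0), gaussian_sd=0.0, cleft_offset=0.0,
                          shell_thickness=0.15, margin=1.3, seed=7)
        _, _, _, extras = synth_volume(cell, vp, full_output=True)
        soma = SomaMask(mask=extras["soma_mask"], voxel_size=vp.voxel_size)
        clus = ClusterSet(labels=extras["labels"], voxel_size=vp.voxel_size)
        assert optimize_dilation(soma, clus) == pytest.approx(0.16)

    def test_no_clusters_warns_lower_bound(self):
        mask = np.zeros((12, 20, 20), dtype=bool)
        mask[4:8, 6:14, 6:14] = True
        soma = SomaMask(mask=mask, voxel_size=SIM_VS)
        empty = ClusterSet(labels=np.zeros_like(mask, dtype=np.int32), voxel_size=SIM_VS)
        with pytest.warns(UserWarning):
            assert optimize_dilation(soma, empty) == 0.16

    def test_surface_estimator_near_analytic_sphere(self):
        vs = SIM_VS
        r = 3.0
        half = np.ceil((r + 0.3) / np.array(vs)).astype(int)
        zz, yy, xx = np.meshgrid(*[np.arange(-h, h + 1) * v for h, v in zip(half, vs)], indexing="ij")
        mask = zz**2 + yy**2 + xx**2 <= r**2
        a = soma_surface_area(SomaMask(mask=mask, voxel_size=vs))
        assert a == pytest.approx(4 * math.pi * r**2, rel=0.03)

    def test_threshold_invariance_of_masks(self, rng):
        # scaling intensities by a positive constant leaves the IsoData
        # segmentation unchanged
        vol = np.zeros((12, 24, 24), dtype=np.float32)
        vol[4:8, 8:16, 8:16] = 100
        vol += rng.normal(0, 5, vol.shape).astype(np.float32)
        a = floodfill_clusters(VoxelVolume(vol, SIM_VS))
        b = floodfill_clusters(VoxelVolume(vol * 2.7, SIM_VS))
        assert np.array_equal(a.labels, b.labels)
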