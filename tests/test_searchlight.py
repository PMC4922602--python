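"""Sphere geometry, searchlight maps and cluster inference."""

import numpy as np
import pandas as pd
import pytest

from glossmvpa.decoding import CONTRASTS
from glossmvpa.design import make_design
from glossmvpa.searchlight import (AccuracyMap, SearchlightParams, group_cluster_threshold,
                                   searchlight_map, sphere_neighborhoods)
from glossmvpa.simulate import EffectModel, ToyBrain, make_toy_brain, simulate_subject


def brute_force_sphere_count(voxel_size, radius):
    """Independent oracle: enumerate the integer lattice inside the sphere."""
    vs = np.asarray(voxel_size)
    reach = np.ceil(radius / vs).astype(int)
    count = 0
    for i in range(-reach[0], reach[0] + 1):
        for j in range(-reach[1], reach[1] + 1):
            for k in range(-reach[2], reach[2] + 1):
                if (i * vs[0]) ** 2 + (j * vs[1]) ** 2 + (k * vs[2]) ** 2 <= radius**2:
                    count += 1
    return count


def _box_brain(shape=(9, 9, 9), voxel_size=(2.5, 2.5, 3.0)):
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    ijk = np.stack([ii, jj, kk], -1).reshape(-1, 3)
    return ToyBrain(shape=shape, voxel_size=voxel_size, ijk=ijk,
                    roi=np.full(len(ijk), "", dtype=object))


class TestSphereNeighborhoods:
    def test_interior_sphere_matches_lattice_enumeration(self):
        """An interior 8-mm sphere on the anisotropic grid holds exactly the
        lattice-enumerated voxel count (113; center-to-center <= radius)."""
        brain = _box_brain()
        nbs = sphere_neighborhoods(brain, SearchlightParams(radius_mm=8.0))
        center = int(np.where((brain.ijk == 4).all(axis=1))[0][0])
        expected = brute_force_sphere_count((2.5, 2.5, 3.0), 8.0)
        assert len(nbs[center]) == expected == 113

    def test_single_voxel_mask(self):
        brain = ToyBrain(shape=(3, 3, 3), voxel_size=(2.5, 2.5, 3.0),
                         ijk=np.array([[1, 1, 1]]), roi=np.array([""], dtype=object))
        nbs = sphere_neighborhoods(brain)
        assert len(nbs) == 1 and list(nbs[0]) == [0]

    def test_edge_neighborhood_smaller_than_interior(self):
        brain = _box_brain()
        nbs = sphere_neighborhoods(brain)
        corner = int(np.where((brain.ijk == 0).all(axis=1))[0][0])
        center = int(np.where((brain.ijk == 4).all(axis=1))[0][0])
        assert len(nbs[corner]) < len(nbs[center])
        assert corner in nbs[corner]  # center voxel always included

    def test_radius_must_exceed_voxel_size(self):
        with pytest.raises(ValueError, match="radius"):
            sphere_neighborhoods(_box_brain(), SearchlightParams(radius_mm=2.0))


@pytest.fixture(scope="module")
def sl_brain():
    # one compact ROI inside a small mask: ~600 voxels total
    return make_toy_brain(n_rois=1, roi_radius_mm=7.0, background_voxels=350, seed=1)


class TestSearchlightMap:
    def test_localized_signal_peaks_inside_roi(self, sl_brain):
        m = EffectModel(f_structure=0.5, amp_structure=2.0, noise_sd=0.4)
        ds = simulate_subject(make_design("binocular", 6, 0), {"ROI1": m}, seed=3,
                              brain=sl_brain)
        amap = searchlight_map(ds, CONTRASTS["painted_vs_flat"])
        assert np.nanmin(amap.values) >= 0.0 and np.nanmax(amap.values) <= 1.0
        # the peak center must see the ROI: within one sphere radius of it
        peak_mm = (sl_brain.ijk[int(np.nanargmax(amap.values))]
                   * np.asarray(sl_brain.voxel_size))
        roi_mm = sl_brain.ijk[sl_brain.roi == "ROI1"] * np.asarray(sl_brain.voxel_size)
        assert np.min(np.linalg.norm(roi_mm - peak_mm, axis=1)) <= 8.0
        in_roi = amap.values[sl_brain.roi == "ROI1"].mean()
        outside = amap.values[sl_brain.roi == ""].mean()
        assert in_roi > outside + 0.1


class TestGroupClusterThreshold:
    def _maps(self, brain, values_list):
        return [AccuracyMap(values=v, brain=brain) for v in values_list]

    def test_chance_maps_give_empty_cluster_table(self, sl_brain):
        maps = self._maps(sl_brain, [np.full(sl_brain.n_voxels, 0.5)] * 4)
        t_vol, table = group_cluster_threshold(maps)
        assert len(table) == 0
        assert np.all(np.isnan(t_vol))

    def test_shared_blob_survives_as_single_cluster(self, sl_brain):
        rng = np.random.default_rng(0)
        roi_idx = sl_brain.roi_indices("ROI1")[:10]
        values_list = []
        for s in range(8):
            v = 0.5 + 0.02 * rng.standard_normal(sl_brain.n_voxels)
            v[roi_idx] = 0.7 + 0.02 * rng.standard_normal(10)
            values_list.append(v)
        t_vol, table = group_cluster_threshold(self._maps(sl_brain, values_list))
        assert len(table) == 1
        blob = set(map(tuple, sl_brain.ijk[roi_idx]))
        surviving = set(map(tuple, np.argwhere(np.isfinite(t_vol))))
        assert blob <= surviving

    def test_ceiling_blob_is_significant(self, sl_brain):
        """Accuracy 1.0 in every subject (zero variance) must survive, not
        vanish through an undefined t statistic."""
        roi_idx = sl_brain.roi_indices("ROI1")[:12]
        rng = np.random.default_rng(3)
        values_list = []
        for s in range(4):
            v = 0.5 + 0.01 * rng.standard_normal(sl_brain.n_voxels)
            v[roi_idx] = 1.0
            values_list.append(v)
        t_vol, table = group_cluster_threshold(self._maps(sl_brain, values_list))
        assert np.isinf(table.peak_t).any()
        blob_ijk = sl_brain.ijk[roi_idx]
        assert np.isinf(t_vol[blob_ijk[:, 0], blob_ijk[:, 1], blob_ijk[:, 2]]).all()

    def test_small_clusters_removed(self, sl_brain):
        rng = np.random.default_rng(1)
        # a supra-threshold blob of only 2 voxels: below the 4-voxel minimum
        roi_idx = sl_brain.roi_indices("ROI1")[:2]
        values_list = []
        for s in range(8):
            v = 0.5 + 0.01 * rng.standard_normal(sl_brain.n_voxels)
            v[roi_idx] = 0.8
            values_list.append(v)
        _, table = group_cluster_threshold(self._maps(sl_brain, values_list))
        assert len(table) == 0

    def test_grid_mismatch_rejected(self, sl_brain):
        other = _box_brain()
        maps = [AccuracyMap(values=np.full(sl_brain.n_voxels, 0.5), brain=sl_brain),
                AccuracyMap(values=np.full(other.n_voxels, 0.5), brain=other)]
        with pytest.raises(ValueError, match="grid"):
            group_cluster_threshold(maps)

    def test_needs_two_subjects(self, sl_brain):
        maps = self._maps(sl_brain, [np.full(sl_brain.n_voxels, 0.5)])
        with pytest.raises(ValueError, match="2 subjects"):
            group_cluster_threshold(maps)
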