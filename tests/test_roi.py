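"""ROI statistics, propagation, contusion volumetry, cohort-table joins."""

import numpy as np
import pandas as pd
import pytest

from tbiqmri.qmap import ParameterMap, interpolate_map
from tbiqmri.roi import (LesionConfig, ROISet, build_cohort_table, lesion_volume,
                         propagate_rois, roi_mean)


def _simple_roiset(n=16):
    lm = np.zeros((n, n), dtype=np.int16)
    lm[2:6, 2:6] = 1      # "core"-like, ipsi (left columns)
    lm[2:6, 10:14] = 2    # contralateral reference
    return ROISet(lm, {"core": 1, "contra_cortex": 2}, "file")


class TestROISet:
    def test_empty_roi_rejected(self):
        lm = np.zeros((8, 8), dtype=np.int16)
        lm[0, 0] = 1
        with pytest.raises(ValueError, match="empty"):
            ROISet(lm, {"core": 1, "missing": 5})

    def test_nearest_neighbor_scaling_quadruples_counts(self):
        rs = _simple_roiset()
        up = rs.scaled(2)
        for name in rs.names:
            assert up.mask(name).sum() == 4 * rs.mask(name).sum()


class TestPropagate:
    def test_matching_grid_passthrough(self):
        rs = _simple_roiset()
        pm = ParameterMap(np.ones((16, 16)), "ms", np.ones((16, 16), bool))
        pairs = propagate_rois(rs, [pm])
        assert pairs[0][1] is rs

    def test_double_grid_scaled(self):
        rs = _simple_roiset()
        pm = ParameterMap(np.ones((32, 32)), "ms", np.ones((32, 32), bool))
        (_, rs2), = propagate_rois(rs, [pm])
        assert rs2.shape == (32, 32)

    def test_mismatched_grid_rejected(self):
        rs = _simple_roiset()
        pm = ParameterMap(np.ones((24, 24)), "ms", np.ones((24, 24), bool))
        with pytest.raises(ValueError, match="coregistration"):
            propagate_rois(rs, [pm])


class TestRoiMean:
    def test_constant_map(self):
        rs = _simple_roiset()
        pm = ParameterMap(np.full((16, 16), 7.0), "ms", np.ones((16, 16), bool))
        s = roi_mean(pm, rs, "core", metric_name="t2")
        assert s.mean == 7.0 and s.sd == 0.0 and s.n_valid_voxels == 16

    def test_half_and_half(self):
        rs = _simple_roiset()
        vals = np.zeros((16, 16))
        vals[2:4, 2:6] = 10.0  # top half of the core ROI
        pm = ParameterMap(vals, "ms", np.ones((16, 16), bool))
        assert roi_mean(pm, rs, "core").mean == 5.0

    def test_invalid_voxels_excluded(self):
        rs = _simple_roiset()
        vals = np.full((16, 16), 3.0)
        valid = np.ones((16, 16), bool)
        valid[2:6, 2:4] = False
        pm = ParameterMap(vals, "ms", valid)
        s = roi_mean(pm, rs, "core")
        assert s.n_valid_voxels == 8

    def test_no_valid_voxels_is_an_error_naming_roi(self):
        rs = _simple_roiset()
        pm = ParameterMap(np.ones((16, 16)), "ms", np.zeros((16, 16), bool))
        with pytest.raises(ValueError, match="core"):
            roi_mean(pm, rs, "core", metric_name="t2")

    def test_phantom_roi_mean_equals_truth(self, severe_phantom):
        from tbiqmri.phantom import forward_sat
        from tbiqmri.qmap import compute_aptw
        truth, rois = severe_phantom
        sat = forward_sat(truth)
        pm = compute_aptw(sat.data[:, :, 2], sat.data[:, :, 1], sat.data[:, :, 0],
                          mask=truth.brain)
        for name in rois.names:
            s = roi_mean(pm, rois, name)
            assert s.mean == pytest.approx(truth.roi_truth[name]["aptw"], abs=1e-9)
            assert s.sd == pytest.approx(0.0, abs=1e-9)

    def test_roi_mean_stable_under_interpolation(self, severe_phantom):
        """Interpolating a smooth map moves ROI means by < 0.5%."""
        truth, rois = severe_phantom
        n = truth.label_map.shape[0]
        yy, xx = np.meshgrid(np.linspace(0, 1, n), np.linspace(0, 1, n), indexing="ij")
        smooth = 50.0 + 20.0 * yy + 10.0 * xx + 5.0 * yy * xx
        pm = ParameterMap(smooth, "a.u.", np.ones((n, n), bool))
        up = interpolate_map(pm, 2)
        for name in rois.names:
            m1 = roi_mean(pm, rois, name).mean
            m2 = roi_mean(up, rois.scaled(2), name).mean
            assert abs(m2 - m1) / abs(m1) < 0.005


class TestLesionVolume:
    def _phantom_t2w(self, n=192, fov=32.0, radius_mm=3.0, contrast_sd=5.0):
        """Disk lesion of known radius on a textured T2w-like slice.

        The background texture is a sinusoidal ripple whose maximum is
        sqrt(2) reference-SDs, safely below the k = 2 threshold, so the
        only hyperintense voxels are the lesion's.
        """
        c = (np.arange(n) + 0.5) * fov / n - fov / 2
        rows, cols = np.meshgrid(c, c, indexing="ij")
        base, amp = 60.0, 2.0  # ripple SD = amp/sqrt(2)
        sd_ref = amp / np.sqrt(2.0)
        img = base + amp * np.sin(2 * np.pi * cols / 2.1)
        lesion = (cols + 6.0) ** 2 + (rows + 5.0) ** 2 <= radius_mm**2
        img[lesion] += contrast_sd * sd_ref
        lm = np.zeros((n, n), dtype=np.int16)
        lm[(cols - 6.0) ** 2 + (rows + 5.0) ** 2 <= 9.0] = 2
        rs = ROISet(lm, {"contra_cortex": 2}, "file")
        return ParameterMap(img, "a.u.", np.ones((n, n), bool)), rs, lesion

    def test_disk_volume_matches_analytic(self):
        pm, rs, lesion = self._phantom_t2w()
        res = lesion_volume(pm, rs, 32.0 / 192, 1.5)
        analytic = np.pi * 3.0**2 * 1.5
        shell = 2 * np.pi * 3.0 * (32.0 / 192) * 1.5  # one-voxel perimeter ring
        assert abs(res.volume_mm3 - analytic) <= shell

    def test_no_hyperintensity_gives_zero(self):
        pm, rs, _ = self._phantom_t2w(contrast_sd=0.0)
        cfg = LesionConfig(k_sd=8.0)
        res = lesion_volume(pm, rs, 32.0 / 192, 1.5, cfg)
        assert res.volume_mm3 == 0.0 and res.n_voxels == 0

    def test_extreme_threshold_gives_zero(self):
        pm, rs, _ = self._phantom_t2w()
        res = lesion_volume(pm, rs, 32.0 / 192, 1.5, LesionConfig(k_sd=1e9))
        assert res.volume_mm3 == 0.0

    def test_volume_monotone_in_radius_and_contrast(self):
        vols_r = []
        for r in (1.5, 2.5, 3.5):
            pm, rs, _ = self._phantom_t2w(radius_mm=r)
            vols_r.append(lesion_volume(pm, rs, 32.0 / 192, 1.5).volume_mm3)
        assert vols_r == sorted(vols_r)
        vols_c = []
        for csd in (3.0, 5.0, 8.0):
            pm, rs, _ = self._phantom_t2w(contrast_sd=csd)
            vols_c.append(lesion_volume(pm, rs, 32.0 / 192, 1.5).volume_mm3)
        assert vols_c == sorted(vols_c)

    def test_contralateral_component_excluded(self):
        pm, rs, _ = self._phantom_t2w(contrast_sd=0.0)
        img = pm.values.copy()
        img[20:30, 150:160] += 50.0  # bright blob on the right (contra) side
        pm2 = ParameterMap(img, "a.u.", pm.valid_mask)
        res = lesion_volume(pm2, rs, 32.0 / 192, 1.5)
        assert res.volume_mm3 == 0.0

    def test_volume_formula_consistency(self):
        pm, rs, _ = self._phantom_t2w()
        res = lesion_volume(pm, rs, 32.0 / 192, 1.5)
        assert res.volume_mm3 == res.n_voxels * (32.0 / 192) ** 2 * 1.5

    def test_multislice_sums(self):
        pm, rs, lesion = self._phantom_t2w()
        stack = np.stack([pm.values, pm.values], axis=2)
        pm3 = ParameterMap(stack, "a.u.", np.ones(stack.shape, bool))
        res2 = lesion_volume(pm3, rs, 32.0 / 192, 1.5)
        res1 = lesion_volume(pm, rs, 32.0 / 192, 1.5)
        assert res2.n_voxels == 2 * res1.n_voxels


class TestCohortTable:
    def _stats(self, n_sub=2, tps=("1h", "1d", "3d"), rois=7, metrics=6):
        rows = []
        for s in range(n_sub):
            for tp in tps:
                for r in range(rois):
                    for m in range(metrics):
                        rows.append({"subject_id": f"S{s}", "timepoint": tp,
                                     "roi_name": f"roi{r}", "metric_name": f"m{m}",
                                     "mean": 1.0, "sd": 0.1, "n_valid_voxels": 10})
        return pd.DataFrame(rows)

    def test_cardinality(self):
        stats = self._stats()
        manifest = pd.DataFrame({"subject_id": ["S0", "S1"], "sex": ["M", "F"],
                                 "group": ["sham", "severe"]})
        table = build_cohort_table(stats, manifest)
        assert len(table) == 2 * 3 * 7 * 6 == 252

    def test_missing_outcomes_retained_as_nan(self):
        stats = self._stats()
        manifest = pd.DataFrame({"subject_id": ["S0", "S1"], "sex": ["M", "F"],
                                 "group": ["sham", "severe"]})
        outcomes = pd.DataFrame({"subject_id": ["S0"], "mnss": [3.0]})
        table = build_cohort_table(stats, manifest, outcomes)
        assert len(table) == 252
        assert table.loc[table.subject_id == "S1", "mnss"].isna().all()

    def test_duplicate_key_rejected(self):
        stats = self._stats()
        dup = pd.concat([stats, stats.iloc[[0]]], ignore_index=True)
        manifest = pd.DataFrame({"subject_id": ["S0", "S1"], "sex": ["M", "F"],
                                 "group": ["sham", "severe"]})
        with pytest.raises(ValueError, match="duplicate"):
            build_cohort_table(dup, manifest)
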