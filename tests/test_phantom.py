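"""Phantom construction and forward models: geometry contracts,
forward/inverse round trips, and the noise model."""

import numpy as np
import pytest

from tbiqmri.phantom import (LESION_RADIUS_MM, EffectTable, PhantomSpec,
                             add_noise, build_phantom, default_effect_table,
                             forward_asl, forward_dwi, forward_ir, forward_sat,
                             forward_t2, asl_delta_m_fraction)
from tbiqmri.protocol import AcquisitionProtocol, ROI_NAMES
from tbiqmri import qmap


class TestBuildPhantom:
    def test_sham_truth_equals_cortex_baseline(self, sham_phantom):
        truth, rois = sham_phantom
        core = rois.mask("core")
        assert core.any()
        assert truth.spec.lesion_radius_mm["sham"] == 0.0
        cc = truth.roi_truth["contra_cortex"]
        for p, v in truth.roi_truth["core"].items():
            assert v == cc[p]

    def test_same_spec_bit_identical(self, small_protocol):
        spec = PhantomSpec(protocol=small_protocol, severity="moderate", timepoint="1d")
        t1, r1 = build_phantom(spec)
        t2_, r2 = build_phantom(spec)
        for k in t1.maps:
            np.testing.assert_array_equal(t1.maps[k], t2_.maps[k])
        np.testing.assert_array_equal(r1.label_map, r2.label_map)

    def test_severe_perilesion_shift_read_back(self, severe_phantom):
        """IC APTw truth exceeds CC by exactly the configured 3-day shift."""
        truth, _ = severe_phantom
        shift = default_effect_table().get("severe", "3d", "ipsi_cortex")["aptw_truth_pct"]
        assert truth.roi_truth["ipsi_cortex"]["aptw"] == pytest.approx(
            truth.roi_truth["contra_cortex"]["aptw"] + shift)

    def test_rois_disjoint_nonempty_inside_brain(self, severe_phantom):
        truth, rois = severe_phantom
        total = 0
        for name in ROI_NAMES:
            m = rois.mask(name)
            assert m.any(), name
            assert (truth.label_map[m] > 0).all()
            total += m.sum()
        assert total == (rois.label_map > 0).sum()  # pairwise disjoint

    def test_lesion_radius_monotone_in_severity(self):
        radii = [LESION_RADIUS_MM[s] for s in ("sham", "mild", "moderate", "severe")]
        assert radii == sorted(radii)

    def test_lesion_outside_brain_rejected(self, small_protocol):
        spec = PhantomSpec(protocol=small_protocol, severity="severe",
                           lesion_center_vox=(2, 2))  # corner, outside the ellipse
        with pytest.raises(ValueError, match="outside the brain"):
            build_phantom(spec)

    def test_effect_table_validates_keys(self):
        with pytest.raises(ValueError):
            EffectTable({("severe", "1d", "not_a_roi"): {"t1_s": 0.1}})
        with pytest.raises(ValueError):
            EffectTable({("severe", "1d", "core"): {"bogus_field": 0.1}})


class TestForwardModels:
    def test_ir_asymptote_and_null_point(self, sham_phantom):
        truth, _ = sham_phantom
        prot = truth.spec.protocol
        t1 = truth.maps["t1"][truth.brain][0]
        # TI -> infinity recovers A = M0
        long_ti = AcquisitionProtocol(matrix=prot.matrix, ti_list_s=(1000.0,))
        stack = forward_ir(truth, long_ti)
        np.testing.assert_allclose(stack.data[truth.brain][:, 0],
                                   truth.maps["m0"][truth.brain], rtol=1e-12)
        # at TI = T1 ln 2 the signal nulls
        null_prot = AcquisitionProtocol(matrix=prot.matrix,
                                        ti_list_s=(float(t1 * np.log(2.0)),))
        stack = forward_ir(truth, null_prot)
        sel = truth.maps["t1"] == t1
        np.testing.assert_allclose(stack.data[sel][:, 0], 0.0, atol=1e-9)

    def test_t2_te0_extrapolates_to_i0_and_b0_equals_i0(self, sham_phantom):
        truth, _ = sham_phantom
        stack = forward_t2(truth)
        i0 = truth.maps["m0"]
        te0_ms = truth.spec.protocol.te_list_ms[0]
        extrap = stack.data[:, :, 0] * np.exp(
            te0_ms / np.where(truth.maps["t2"] > 0, truth.maps["t2"], np.inf))
        np.testing.assert_allclose(extrap[truth.brain], i0[truth.brain], rtol=1e-9)
        dwi = forward_dwi(truth)
        np.testing.assert_allclose(dwi.data[:, :, 0][truth.brain], i0[truth.brain])

    def test_asl_zero_cbf_means_no_label_difference(self, sham_phantom):
        truth, _ = sham_phantom
        t = truth.maps["cbf"].copy()
        truth.maps["cbf"][:] = 0.0
        try:
            stack = forward_asl(truth)
            np.testing.assert_array_equal(stack.data[:, :, 0], stack.data[:, :, 1])
        finally:
            truth.maps["cbf"][:] = t

    def test_asl_difference_linear_in_cbf(self):
        f1 = asl_delta_m_fraction(30.0, 1.5)
        f2 = asl_delta_m_fraction(60.0, 1.5)
        assert f2 == pytest.approx(2.0 * f1, rel=1e-12)

    def test_sat_symmetry_and_normal_brain_sign(self, sham_phantom):
        truth, _ = sham_phantom
        stack = forward_sat(truth)
        s0, s_pos, s_neg = stack.data[:, :, 0], stack.data[:, :, 1], stack.data[:, :, 2]
        brain = truth.brain
        # normal tissue has negative APTw -> S(+3.5) > S(-3.5)
        assert (s_pos[brain] > s_neg[brain]).all()
        # zero asymmetry would make them equal
        truth.maps["aptw"], saved = np.zeros_like(truth.maps["aptw"]), truth.maps["aptw"]
        try:
            st = forward_sat(truth)
            np.testing.assert_array_equal(st.data[:, :, 1], st.data[:, :, 2])
        finally:
            truth.maps["aptw"] = saved

    def test_sat_unrepresentable_truth_rejected(self, sham_phantom):
        truth, _ = sham_phantom
        saved = truth.maps["mtr"].copy()
        truth.maps["mtr"][truth.brain] = 120.0  # S_sat would be negative
        try:
            with pytest.raises(ValueError, match="outside"):
                forward_sat(truth)
        finally:
            truth.maps["mtr"] = saved


@pytest.mark.parametrize("severity,timepoint", [("sham", "1d"), ("severe", "1h"),
                                                ("severe", "3d"), ("moderate", "1d")])
def test_noiseless_round_trip_all_maps(small_protocol, severity, timepoint):
    """Every reconstruction inverts its forward model to < 1e-6 relative."""
    spec = PhantomSpec(protocol=small_protocol, severity=severity, timepoint=timepoint)
    truth, _ = build_phantom(spec)
    m = truth.brain

    pm = qmap.fit_t1_ir(forward_ir(truth), mask=m)
    assert np.nanmax(np.abs(pm.values[m] / truth.maps["t1"][m] - 1)) < 1e-6
    pm = qmap.fit_t2(forward_t2(truth), mask=m)
    assert np.nanmax(np.abs(pm.values[m] / truth.maps["t2"][m] - 1)) < 1e-6
    pm = qmap.fit_adc(forward_dwi(truth), mask=m)
    assert np.nanmax(np.abs(pm.values[m] / truth.maps["adc"][m] - 1)) < 1e-6

    asl = forward_asl(truth)
    t1map = qmap.ParameterMap(truth.maps["t1"], "s", m)
    cbf = qmap.compute_cbf(asl.data[:, :, 0], asl.data[:, :, 1], t1map, mask=m)
    denom = np.where(truth.maps["cbf"][m] > 0, truth.maps["cbf"][m], 1.0)
    assert np.nanmax(np.abs((cbf.values[m] - truth.maps["cbf"][m]) / denom)) < 1e-6

    sat = forward_sat(truth)
    aptw = qmap.compute_aptw(sat.data[:, :, 2], sat.data[:, :, 1], sat.data[:, :, 0], mask=m)
    assert np.nanmax(np.abs(aptw.values[m] - truth.maps["aptw"][m])) < 1e-9
    mtr = qmap.compute_mtr(sat.data[:, :, 3], sat.data[:, :, 0], mask=m)
    assert np.nanmax(np.abs(mtr.values[m] - truth.maps["mtr"][m])) < 1e-9


class TestAddNoise:
    def _stack(self, value=100.0, n=2000):
        from tbiqmri.qmap import RawStack
        return RawStack(np.full((n, 1, 1), value), np.array([0.0]), "t2")

    def test_infinite_snr_identity(self):
        st = self._stack()
        out = add_noise(st, snr=np.inf, na=4, seed=0)
        np.testing.assert_array_equal(out.data, st.data)

    def test_same_seed_identical(self):
        st = self._stack()
        a = add_noise(st, snr=40, na=4, seed=7)
        b = add_noise(st, snr=40, na=4, seed=7)
        np.testing.assert_array_equal(a.data, b.data)
        c = add_noise(st, snr=40, na=4, seed=8)
        assert not np.array_equal(a.data, c.data)

    def test_averaged_sd_matches_sigma_over_sqrt_na(self):
        """High-SNR regime: empirical SD ~ sigma/sqrt(na) within 5%."""
        st = self._stack(value=100.0, n=10000)
        snr, na = 50.0, 4
        out = add_noise(st, snr=snr, na=na, seed=3)
        sigma = 100.0 / snr
        sd = out.data.std()
        assert abs(sd - sigma / np.sqrt(na)) / (sigma / np.sqrt(na)) < 0.05

    def test_parameter_validation(self):
        st = self._stack(n=4)
        with pytest.raises(ValueError):
            add_noise(st, snr=-1.0)
        with pytest.raises(ValueError):
            add_noise(st, snr=40.0, na=0)
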