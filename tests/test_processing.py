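"""Voltage-to-load conversion, contact detection and QC rules."""

import numpy as np
import pytest

import gelmech as gm
from gelmech import processing


def _shifted(raw, dz):
    return gm.RawForceCurve(z=raw.z + dz, v=raw.v.copy(), segment=raw.segment.copy(),
                            metadata=dict(raw.metadata))


class TestConvertToLoad:
    def test_arithmetic(self, true_cal):
        # v = 0.01 V, sens = 20 nm/V, k = 0.1 N/m -> d = 0.2 nm, P = 2e-11 N
        n = 100
        z = np.linspace(0, 100e-9, n)
        v = np.full(n, 0.01)
        v[: n // 2] = 0.0  # baseline half so the offset fit sees zeros
        raw = gm.RawForceCurve(z=z, v=v, segment=np.array(["A"] * n))
        fd = gm.convert_to_load(raw, true_cal)
        assert fd.load.max() == pytest.approx(2e-11, rel=1e-6)

    def test_zero_voltage_zero_load(self, true_cal):
        z = np.linspace(0, 100e-9, 64)
        raw = gm.RawForceCurve(z=z, v=np.zeros(64), segment=np.array(["A"] * 64))
        fd = gm.convert_to_load(raw, true_cal)
        np.testing.assert_allclose(fd.load, 0.0, atol=1e-20)

    def test_roundtrip_recovers_simulated_load(self, noiseless_curve, true_cal, cantilever):
        fd = gm.convert_to_load(noiseless_curve, true_cal)
        expected = noiseless_curve.v * cantilever.sensitivity * cantilever.spring_constant
        np.testing.assert_allclose(fd.load, expected, rtol=5e-3, atol=1e-16)

    def test_sensitivity_scaling_scales_load(self, noiseless_curve, cantilever):
        cal1 = gm.Calibration(sensitivity=20e-9, spring_constant=0.1)
        cal2 = gm.Calibration(sensitivity=40e-9, spring_constant=0.1)
        f1 = gm.convert_to_load(noiseless_curve, cal1)
        f2 = gm.convert_to_load(noiseless_curve, cal2)
        np.testing.assert_allclose(f2.load, 2 * f1.load, rtol=1e-9, atol=1e-20)

    def test_missing_calibration_fails(self, noiseless_curve):
        with pytest.raises(ValueError):
            gm.convert_to_load(noiseless_curve, None)

    def test_baseline_tilt_removed(self, tip, cantilever, true_cal):
        acq = gm.AcquisitionSpec(deflection_noise_sd=0.0, baseline_tilt=0.02)
        cu = gm.simulate_force_curve(gm.GelSpec(young_modulus=1e6), acq, tip, cantilever)
        li = gm.preprocess_curve(cu, true_cal)
        assert li.ok
        # pre-peak baseline in P(h) space: load at h=0 within noise of zero
        assert abs(li.P[li.approach][0]) < 1e-13


class TestContactDetection:
    def test_noiseless_contact_within_sample_spacing(self, noiseless_curve, true_cal):
        fd = gm.convert_to_load(noiseless_curve, true_cal)
        fd.metadata["spring_constant"] = true_cal.spring_constant
        cp = gm.detect_contact_point(fd)
        dz = np.median(np.diff(fd.z[fd.approach]))
        assert cp.ok
        assert abs(cp.z0 - noiseless_curve.metadata["contact_z_true"]) < dz

    def test_noisy_contact_median_error_below_spacing(self, tip, cantilever, true_cal):
        """Median |z0 error| <= one sample spacing at 0.5 nm deflection noise."""
        acq = gm.AcquisitionSpec(deflection_noise_sd=0.5e-9)
        gel = gm.GelSpec(young_modulus=1e6)
        rng = np.random.default_rng(21)
        errs, dz = [], None
        for _ in range(40):
            cu = gm.simulate_force_curve(gel, acq, tip, cantilever, rng=rng)
            fd = gm.convert_to_load(cu, true_cal)
            fd.metadata["spring_constant"] = true_cal.spring_constant
            cp = gm.detect_contact_point(fd)
            assert cp.ok
            errs.append(abs(cp.z0 - cu.metadata["contact_z_true"]))
            dz = np.median(np.diff(fd.z[fd.approach]))
        assert np.median(errs) <= dz

    def test_pure_noise_flagged(self, true_cal):
        rng = np.random.default_rng(5)
        n = 400
        z = np.linspace(0, 300e-9, n)
        v = rng.normal(0, 0.5e-9 / true_cal.sensitivity, n)
        raw = gm.RawForceCurve(z=z, v=v, segment=np.array(["A"] * n))
        fd = gm.convert_to_load(raw, true_cal)
        cp = gm.detect_contact_point(fd)
        assert not cp.ok
        assert cp.reason == "no_contact"

    def test_translation_equivariance(self, noiseless_curve, true_cal):
        fd1 = gm.convert_to_load(noiseless_curve, true_cal)
        fd2 = gm.convert_to_load(_shifted(noiseless_curve, 55e-9), true_cal)
        for fd in (fd1, fd2):
            fd.metadata["spring_constant"] = true_cal.spring_constant
        z0_1 = gm.detect_contact_point(fd1).z0
        z0_2 = gm.detect_contact_point(fd2).z0
        assert z0_2 - z0_1 == pytest.approx(55e-9, abs=1e-12)


class TestLoadIndentation:
    def test_rigid_substrate_zero_indentation(self, cantilever, true_cal):
        acq = gm.AcquisitionSpec()
        cu = gm.simulate_hard_contact_curve(cantilever, acq)
        fd = gm.convert_to_load(cu, true_cal)
        li = gm.to_load_indentation(fd, cu.metadata["contact_z_true"], true_cal)
        in_contact = li.P > 1e-12
        assert np.all(li.h[in_contact] < 1e-12)
        assert li.quality_flag == "discarded:rigid_contact"

    def test_hmax_matches_simulated_indentation(self, noiseless_curve, true_cal):
        li = gm.preprocess_curve(noiseless_curve, true_cal)
        assert li.h.max() == pytest.approx(100e-9, rel=0.01)

    def test_load_zero_at_contact(self, noiseless_curve, true_cal):
        li = gm.preprocess_curve(noiseless_curve, true_cal)
        app = li.approach
        # first retained sample sits within one sample spacing of contact, so
        # its load is bounded by noise plus a sub-spacing contact load
        assert abs(li.P[app][0]) <= max(3 * li.metadata["baseline_sd_N"], 1e-4 * li.P.max())

    def test_requires_finite_contact(self, noiseless_curve, true_cal):
        fd = gm.convert_to_load(noiseless_curve, true_cal)
        with pytest.raises(ValueError):
            gm.to_load_indentation(fd, np.nan, true_cal)


class TestQCFilter:
    def _map_with_noise_curves(self, tip, cantilever, n_bad, seed=3):
        acq = gm.AcquisitionSpec(grid_nx=8, grid_ny=8, deflection_noise_sd=0.5e-9,
                                 samples_per_curve=300)
        return gm.simulate_force_volume(
            gm.GelSpec(young_modulus=1e6), acq, tip, cantilever,
            seed=seed, bad_curve_fraction=n_bad / 64,
        )

    def test_clean_map_nothing_discarded(self, tip, cantilever, true_cal):
        fv = self._map_with_noise_curves(tip, cantilever, n_bad=0)
        processed = [gm.preprocess_curve(c, true_cal) for c in fv.curves]
        retained, frac, _ = gm.qc_filter(processed)
        assert frac == 0.0
        assert len(retained) == 64

    def test_noise_curves_exactly_discarded(self, tip, cantilever, true_cal):
        fv = self._map_with_noise_curves(tip, cantilever, n_bad=7)
        processed = [gm.preprocess_curve(c, true_cal) for c in fv.curves]
        retained, frac, reasons = gm.qc_filter(processed)
        assert len(retained) == 64 - 7
        assert frac == pytest.approx(7 / 64)
        bad_ids = {c.metadata["index"] for c in fv.curves if c.metadata.get("corrupted")}
        kept_ids = {c.metadata["index"] for c in retained}
        assert bad_ids.isdisjoint(kept_ids)

    def test_idempotent(self, tip, cantilever, true_cal):
        fv = self._map_with_noise_curves(tip, cantilever, n_bad=7)
        processed = [gm.preprocess_curve(c, true_cal) for c in fv.curves]
        retained, _, _ = gm.qc_filter(processed)
        retained2, frac2, _ = gm.qc_filter(retained)
        assert frac2 == 0.0
        assert len(retained2) == len(retained)

    def test_all_discarded_is_error(self, true_cal):
        rng = np.random.default_rng(0)
        curves = []
        for _ in range(5):
            n = 300
            z = np.linspace(0, 300e-9, n)
            v = rng.normal(0, 0.5e-9 / true_cal.sensitivity, n)
            raw = gm.RawForceCurve(z=z, v=v, segment=np.array(["A"] * n))
            curves.append(gm.preprocess_curve(raw, true_cal))
        with pytest.raises(ValueError):
            gm.qc_filter(curves)
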