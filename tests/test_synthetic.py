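import numpy as np
import pytest

from myowork import (
    SyntheticCohortConfig,
    SyntheticPatientParams,
    analyze_patient,
    apply_knockout,
    cavity_volume,
    cohort_metric_values,
    compute_rsct,
    make_cohort,
    make_lv_mesh,
    make_motion,
    make_patient,
    make_pressure,
    segment_average_strain,
    stroke_work,
    total_myocardial_work,
    truth_work_map,
)
from myowork.synthetic import SyntheticError


class TestMesh:
    def test_sphere_mode_volume_matches_analytic(self):
        # axis length = 1.5 * equatorial radius -> spherical cap geometry
        p = SyntheticPatientParams(axis_length_mm=45.0, equatorial_radius_mm=30.0,
                                   n_phi=48, n_rings=32)
        mesh = make_lv_mesh(p)
        R = 30.0
        cap_h = 15.0  # truncated above z = 45 of the 60 mm tall sphere
        analytic = (4 / 3 * np.pi * R**3 - np.pi * cap_h**2 * (3 * R - cap_h) / 3) / 1000.0
        assert cavity_volume(mesh, 0) == pytest.approx(analytic, rel=0.01)

    def test_every_aha_segment_populated_at_default_resolution(self, lv_mesh):
        from myowork import assign_aha_segments
        segmap = assign_aha_segments(lv_mesh)
        assert set(np.unique(segmap.patch_segment)) == set(range(1, 18))

    def test_determinism(self):
        p = SyntheticPatientParams()
        m1, m2 = make_lv_mesh(p), make_lv_mesh(p)
        np.testing.assert_array_equal(m1.vertices, m2.vertices)
        np.testing.assert_array_equal(m1.triangles, m2.triangles)

    def test_too_coarse_resolution_rejected(self):
        with pytest.raises(SyntheticError, match="coarse"):
            make_lv_mesh(SyntheticPatientParams(n_phi=6, n_rings=5))


class TestMotion:
    def test_synchronous_limit_has_identical_segment_curves(self):
        params = SyntheticPatientParams(severity=0.0)
        mesh = make_lv_mesh(params)
        moving, truth = make_motion(mesh, params, "LBBB")
        seg = segment_average_strain(compute_rsct(moving), truth.segmap)
        spread = seg.values.max(axis=0) - seg.values.min(axis=0)
        assert np.max(spread) < 1e-9

    def test_severe_lbbb_septum_stretches_during_high_pressure(self, lbbb_patient):
        surf = lbbb_patient.surfaces["LBBB"]
        truth = lbbb_patient.truths["LBBB"]
        seg = segment_average_strain(compute_rsct(surf), truth.segmap)
        t = surf.frame_times / lbbb_patient.params.rr_ms
        window = (t > 0.35) & (t < 0.55)  # systolic ejection, pressure near peak
        mid_septal = np.isin(seg.unit_ids, [8, 9])
        rates = np.diff(seg.values[mid_septal], axis=1)[:, window[1:]]
        assert rates.mean() > 0  # net lengthening while pressure is high

    def test_crt_compresses_onset_dispersion_by_stated_factor(self, lbbb_patient):
        sd_lbbb = lbbb_patient.truths["LBBB"].onset_sd_ms
        sd_crt = lbbb_patient.truths["CRT"].onset_sd_ms
        assert sd_crt == pytest.approx(
            lbbb_patient.params.crt_dispersion_factor * sd_lbbb, rel=1e-9)

    def test_noise_free_motion_is_deterministic(self):
        params = SyntheticPatientParams(severity=0.5, seed=3)
        mesh = make_lv_mesh(params)
        s1, _ = make_motion(mesh, params, "LBBB")
        s2, _ = make_motion(mesh, params, "LBBB")
        np.testing.assert_array_equal(s1.vertices, s2.vertices)

    def test_patch_noise_perturbs_but_preserves_reference(self):
        params = SyntheticPatientParams(severity=0.5, patch_noise_sigma=0.02, seed=3)
        mesh = make_lv_mesh(params)
        s, _ = make_motion(mesh, params, "LBBB", rng=np.random.default_rng(7))
        clean, _ = make_motion(mesh, params, "LBBB")
        np.testing.assert_array_equal(s.vertices[0], clean.vertices[0])
        assert not np.allclose(s.vertices[1], clean.vertices[1])


class TestPressure:
    def test_peak_honored_exactly_without_noise(self):
        p = SyntheticPatientParams(peak_pressure_kpa=18.5)
        assert make_pressure(p).peak == pytest.approx(18.5)

    def test_zero_noise_equals_clean_waveform(self):
        p = SyntheticPatientParams()
        w1 = make_pressure(p, rng=np.random.default_rng(1))
        w2 = make_pressure(p)
        np.testing.assert_array_equal(w1.pressures, w2.pressures)

    def test_noise_realizations_differ_by_seed(self):
        p = SyntheticPatientParams(pressure_noise_kpa=0.3)
        w1 = make_pressure(p, rng=np.random.default_rng(1))
        w2 = make_pressure(p, rng=np.random.default_rng(2))
        assert not np.allclose(w1.pressures, w2.pressures)
        assert np.all(w1.pressures >= 0)


class TestEnergyConsistency:
    def test_stroke_work_not_exceeding_total_myocardial_work(self):
        """eta <= 1: the active-tension term makes wall work exceed PV work."""
        for seed, sev in [(1, 0.3), (2, 0.6), (3, 0.9)]:
            pat = make_patient(SyntheticPatientParams(severity=sev, seed=seed),
                               states=("LBBB",))
            surf = pat.surfaces["LBBB"]
            volumes = np.array([cavity_volume(surf, f) for f in range(surf.n_frames)])
            sw = stroke_work(pat.pressures["LBBB"], volumes, surf.frame_times)
            tm = truth_work_map(surf, pat.pressures["LBBB"], pat.params,
                                pat.truths["LBBB"])
            tw = total_myocardial_work(tm)
            assert 0 < sw <= tw


class TestCohort:
    def test_same_master_seed_reproduces_cohort_and_metrics(self):
        cfg = SyntheticCohortConfig(n_patients=3, states=("LBBB",), master_seed=9)
        c1, c2 = make_cohort(cfg), make_cohort(cfg)
        assert c1.ground_truth.equals(c2.ground_truth)
        v1 = cohort_metric_values(c1, "v_f_stnw", "P_LHC", "LBBB")
        v2 = cohort_metric_values(c2, "v_f_stnw", "P_LHC", "LBBB")
        np.testing.assert_array_equal(v1, v2)

    def test_small_cohort_recovers_positive_outcome_slope(self):
        from myowork import regress_outcome
        cfg = SyntheticCohortConfig(n_patients=8, states=("LBBB",), master_seed=4,
                                    sigma_eps=3.0)
        cohort = make_cohort(cfg)
        x = cohort_metric_values(cohort, "v_f_stnw", "P_LHC", "LBBB")
        y = np.array([p.outcome_desv for p in cohort.patients])
        assert regress_outcome(x, y).slope > 0

    def test_knockout_substitutes_only_named_parameter(self):
        cfg = SyntheticCohortConfig(n_patients=3, states=("LBBB",), master_seed=5)
        cohort = make_cohort(cfg)
        ko = apply_knockout(cohort, "pressure")
        peaks = {p.params.peak_pressure_kpa for p in ko.patients}
        assert len(peaks) == 1  # pressure collapsed to the cohort mean
        sev_orig = [p.params.severity for p in cohort.patients]
        sev_ko = [p.params.severity for p in ko.patients]
        assert sev_orig == sev_ko
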