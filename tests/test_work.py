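import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myowork import (
    GlobalWork,
    PressureWaveform,
    WorkMap,
    assign_aha_segments,
    compute_work_map,
    efficiency,
    loop_area,
    stroke_work,
    total_myocardial_work,
)
from myowork.strain import StrainField
from myowork.stress import StressField
from myowork.work import WorkError


def trapezoid_loop_integral(strain, stress):
    """Independent oracle: W = -closed trapezoid integral of sigma d(eps)."""
    e = np.concatenate([strain, strain[:1]])
    s = np.concatenate([stress, stress[:1]])
    return -float(np.sum(0.5 * (s[1:] + s[:-1]) * np.diff(e)))


class TestLoopArea:
    def test_ccw_ellipse_area(self):
        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        w = loop_area(0.1 * np.cos(th), 8.0 * np.sin(th))
        assert w == pytest.approx(np.pi * 0.1 * 8.0, rel=1e-3)

    def test_orientation_antisymmetry(self):
        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        e, s = 0.1 * np.cos(th), 8.0 * np.sin(th)
        assert loop_area(e[::-1], s[::-1]) == pytest.approx(-loop_area(e, s), rel=1e-12)

    def test_symmetric_figure_eight_cancels(self):
        th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        # lobes of equal, opposite signed area
        assert loop_area(0.1 * np.sin(2 * th), 8.0 * np.sin(th)) == pytest.approx(0.0, abs=1e-9)

    def test_matches_trapezoid_oracle_on_random_polygons(self, rng):
        for _ in range(200):
            n = rng.integers(3, 60)
            e = rng.normal(0, 0.2, n)
            s = rng.normal(5, 4, n)
            assert loop_area(e, s) == pytest.approx(trapezoid_loop_integral(e, s), abs=1e-9)

    def test_constant_stress_zero_work(self, rng):
        e = rng.normal(0, 0.2, 50)
        assert loop_area(e, np.full(50, 7.0)) == pytest.approx(0.0, abs=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(WorkError):
            loop_area([0.0, 1.0], [0.0, 1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(3, 40), st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
    def test_bilinearity_property(self, n, seed, c):
        r = np.random.default_rng(seed)
        e, s = r.normal(0, 0.2, n), r.normal(0, 5, n)
        w = loop_area(e, s)
        assert loop_area(e * c, s) == pytest.approx(c * w, rel=1e-9, abs=1e-12)
        assert loop_area(e, s * c) == pytest.approx(c * w, rel=1e-9, abs=1e-12)


def _fields(strain_curves, stress_curves, lv_mesh=None, segments=None):
    n_units, n_frames = strain_curves.shape
    times = np.arange(n_frames) * 40.0
    segs = np.arange(1, 18) if segments is None else segments
    strain = StrainField(values=strain_curves, unit_ids=segs[:n_units],
                         frame_times=times, resolution="segment",
                         reference_weights=np.ones(n_units))
    stress = StressField(method="P_LHC", segments=segs,
                         values=stress_curves, frame_times=times)
    return strain, stress


class TestComputeWorkMap:
    def test_shortening_at_high_stress_is_positive_work(self):
        t = np.linspace(0, 2 * np.pi, 30, endpoint=False)
        strain = np.where(t < np.pi, -0.2 * np.sin(t / 2) ** 2, 0.0)[None]
        strain[0, 0] = 0.0
        # stress high while shortening, low while re-lengthening
        stress = np.tile(np.where(t < np.pi, 12.0, 1.0), (17, 1))
        smap, sfield = _fields(np.repeat(strain, 1, 0), stress)
        wm = compute_work_map(smap, sfield)
        assert wm.work[0] > 0

    def test_early_activated_rebound_gives_negative_work(self, lbbb_patient):
        from myowork import compute_rsct, segment_average_strain
        from myowork.stress import build_stress_field
        surf = lbbb_patient.surfaces["LBBB"]
        segmap = lbbb_patient.truths["LBBB"].segmap
        seg_strain = segment_average_strain(compute_rsct(surf), segmap)
        sfield = build_stress_field("P_LHC", lbbb_patient.pressures["LBBB"],
                                    surf.frame_times)
        wm = compute_work_map(seg_strain, sfield, segmap=segmap)
        mid_septal = np.isin(wm.segment, [8, 9])
        assert np.all(wm.work[mid_septal] < 0)
        # and the late-activated lateral wall performs high positive work
        lateral = np.isin(wm.segment, [11, 12])
        assert np.all(wm.work[lateral] > 0)

    def test_stress_scaling_scales_work_linearly(self, rng):
        strain = np.zeros((17, 20))
        strain[:, 1:] = rng.normal(0, 0.1, (17, 19))
        stress = rng.uniform(0, 15, (17, 20))
        f1 = _fields(strain, stress)
        f2 = _fields(strain, stress * 3.0)
        w1 = compute_work_map(*f1).work
        w2 = compute_work_map(*f2).work
        np.testing.assert_allclose(w2, 3.0 * w1, rtol=1e-12)

    def test_mismatched_time_base_rejected(self):
        strain, stress = _fields(np.zeros((17, 5)), np.zeros((17, 5)))
        stress.frame_times = stress.frame_times + 1.0
        with pytest.raises(WorkError, match="time base"):
            compute_work_map(strain, stress)


class TestStrokeWork:
    def test_rectangular_pv_loop(self):
        wave = PressureWaveform(times=[0, 1, 2, 3], pressures=[1.0, 10.0, 10.0, 1.0])
        v = np.array([120.0, 120.0, 50.0, 50.0])
        sw = stroke_work(wave, v, np.array([0.0, 1.0, 2.0, 3.0]))
        assert sw == pytest.approx(0.63)

    def test_constant_volume_zero_work(self):
        wave = PressureWaveform(times=[0, 1, 2, 3], pressures=[1.0, 10.0, 10.0, 1.0])
        v = np.full(4, 80.0)
        assert stroke_work(wave, v, np.arange(4.0)) == 0.0

    def test_elliptical_loop_matches_trapezoid_oracle(self):
        th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        v = 85.0 + 35.0 * np.cos(th)
        p = 8.0 + 7.0 * np.sin(th)
        wave = PressureWaveform(times=np.arange(200.0), pressures=p)
        sw = stroke_work(wave, v, np.arange(200.0))
        # same signed-area rule as the stress-strain loops: -integral p dv
        assert sw == pytest.approx(trapezoid_loop_integral(v, p) / 1000.0, abs=1e-9)


def _volume_map(work, weights):
    n = len(work)
    return WorkMap(unit_ids=np.arange(n), work=work, weights=weights,
                   weight_kind="volume", segment=np.full(n, 9),
                   region=np.full(n, "septum", dtype=object))


class TestTotalWorkAndEfficiency:
    def test_uniform_density_times_wall_volume(self):
        wm = _volume_map(np.full(10, 5.0), np.full(10, 15000.0))  # 150 mL total
        assert total_myocardial_work(wm) == pytest.approx(0.75)

    def test_equal_opposite_halves_cancel(self):
        wm = _volume_map(np.array([2.0, -2.0] * 5), np.full(10, 1000.0))
        assert total_myocardial_work(wm) == pytest.approx(0.0)

    def test_matches_direct_summation(self, rng):
        work = rng.normal(0, 3, 40)
        weights = rng.uniform(100, 5000, 40)
        wm = _volume_map(work, weights)
        assert total_myocardial_work(wm) == pytest.approx(float(np.sum(work * weights)) * 1e-6)

    def test_surface_map_needs_thickness(self, rng):
        wm = _volume_map(rng.normal(0, 1, 5), np.ones(5))
        object.__setattr__(wm, "weight_kind", "area")
        with pytest.raises(WorkError, match="thickness"):
            total_myocardial_work(wm)
        assert total_myocardial_work(wm, thickness_mm=10.0) == pytest.approx(
            float(np.sum(wm.work * wm.weights * 10.0)) * 1e-6)

    def test_efficiency_ratio(self):
        assert efficiency(GlobalWork(0.63, 0.90)) == pytest.approx(0.70)
        assert efficiency(GlobalWork(0.5, 0.5)) == pytest.approx(1.0)

    def test_efficiency_undefined_for_nonpositive_total(self):
        assert np.isnan(efficiency(GlobalWork(0.5, 0.0)))
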