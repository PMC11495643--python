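"""Wall-stress surrogates for regional myocardial work estimation.

Five stress approximations of increasing simplification are supported, all
reported in kPa on the strain time base:

* ``P_LHC`` - the measured (catheter) LV pressure applied uniformly to all
  segments; patient-specific timing and magnitude, no shape information.
* ``WS_ED`` - Laplace wall stress sigma = P * r / (2 h) with segmental
  effective radius and wall thickness frozen at end-diastole: a constant
  per-segment scaling of the pressure trace.
* ``WS_TV`` - Laplace wall stress with time-varying segmental radius and
  thickness, so the scaling factor changes through the cycle.
* ``P_gen`` - a generic normal LV pressure waveform (parametric
  raised-cosine stand-in for a Wiggers-diagram trace), identical for all
  patients and segments.
* ``P_gen_scaled`` - the generic waveform scaled multiplicatively so its
  peak matches the patient-specific peak pressure.

Pressures may be ingested in mmHg (1 mmHg = 0.133322 kPa); everything
internal is kPa.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import SegmentGeometry

MMHG_TO_KPA = 0.133322

#: The five stress surrogate method names.
METHODS = ("P_LHC", "WS_ED", "WS_TV", "P_gen", "P_gen_scaled")

#: Methods that need segmental geometry.
SHAPE_METHODS = ("WS_ED", "WS_TV")


class StressError(ValueError):
    pass


@dataclass
class PressureWaveform:
    """One cardiac cycle of LV pressure, kPa, times in ms from the R wave."""

    times: np.ndarray
    pressures: np.ndarray
    label: str = "measured"  # measured | generic | generic_scaled

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.pressures.shape:
            raise StressError("times and pressures must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise StressError("pressure sample times must be strictly increasing")
        if np.any(self.pressures < 0):
            raise StressError("pressures must be non-negative")

    @property
    def peak(self) -> float:
        """Peak pressure (kPa)."""
        return float(self.pressures.max())

    @property
    def edp(self) -> float:
        """End-diastolic pressure (kPa): the value at t = 0."""
        return float(self.pressures[0])

    def resample(self, frame_times: np.ndarray) -> np.ndarray:
        """Linear interpolation onto ``frame_times`` (identity on own grid)."""
        return np.interp(np.asarray(frame_times, dtype=float), self.times, self.pressures)

    @classmethod
    def from_mmhg(cls, times, pressures_mmhg, label: str = "measured") -> "PressureWaveform":
        return cls(times=np.asarray(times, float),
                   pressures=np.asarray(pressures_mmhg, float) * MMHG_TO_KPA,
                   label=label)


def generic_waveform(
    peak_kpa: float = 16.0,
    edp_kpa: float = 1.07,
    onset_ms: float = 50.0,
    peak_time_ms: float = 300.0,
    relax_end_ms: float = 550.0,
    rr_ms: float = 800.0,
    diastolic_min_kpa: float = 0.5,
    dt_ms: float = 1.0,
) -> PressureWaveform:
    """Parametric generic LV pressure waveform (normal hemodynamics).

    Piecewise raised-cosine: baseline at the end-diastolic pressure until
    ``onset_ms``, systolic rise to exactly ``peak_kpa`` at ``peak_time_ms``,
    relaxation down to ``diastolic_min_kpa`` at ``relax_end_ms``, then slow
    diastolic refill back to the end-diastolic pressure at the end of the
    RR interval. Defaults: peak 16.0 kPa (120 mmHg), EDP 1.07 kPa (8 mmHg).
    """
    if not (peak_kpa > edp_kpa >= 0.0):
        raise StressError("require peak > EDP >= 0")
    if not (0.0 < onset_ms < peak_time_ms < relax_end_ms < rr_ms):
        raise StressError("require 0 < onset < peak time < relaxation end < RR")
    if not (0.0 <= diastolic_min_kpa <= edp_kpa):
        raise StressError("diastolic minimum must lie in [0, EDP]")
    t = np.arange(0.0, rr_ms + dt_ms / 2, dt_ms)
    p = np.full_like(t, edp_kpa)

    def _cos_ramp(t_seg, t0, t1, p0, p1):
        x = (t_seg - t0) / (t1 - t0)
        return p0 + (p1 - p0) * 0.5 * (1.0 - np.cos(np.pi * x))

    rise = (t >= onset_ms) & (t <= peak_time_ms)
    p[rise] = _cos_ramp(t[rise], onset_ms, peak_time_ms, edp_kpa, peak_kpa)
    fall = (t > peak_time_ms) & (t <= relax_end_ms)
    p[fall] = _cos_ramp(t[fall], peak_time_ms, relax_end_ms, peak_kpa, diastolic_min_kpa)
    refill = t > relax_end_ms
    p[refill] = _cos_ramp(t[refill], relax_end_ms, rr_ms, diastolic_min_kpa, edp_kpa)
    # guarantee the peak is met exactly even if the grid misses peak_time_ms
    p[np.argmin(np.abs(t - peak_time_ms))] = peak_kpa
    return PressureWaveform(times=t, pressures=p, label="generic")


def scale_waveform_to_peak(wave: PressureWaveform, target_peak_kpa: float) -> PressureWaveform:
    """Scale a waveform multiplicatively so its peak equals ``target_peak_kpa``."""
    if target_peak_kpa <= 0:
        raise StressError("target peak must be positive")
    if wave.peak <= 0:
        raise StressError("cannot scale a waveform with non-positive peak")
    return replace(
        wave,
        pressures=wave.pressures * (target_peak_kpa / wave.peak),
        label="generic_scaled",
    )


def laplace_stress(pressure_kpa, radius_mm, thickness_mm):
    """Thin-wall Laplace stress sigma = P * r / (2 h), in kPa.

    Radius and thickness are both in mm so their ratio is dimensionless and
    the stress carries the pressure unit.
    """
    r = np.asarray(radius_mm, dtype=float)
    h = np.asarray(thickness_mm, dtype=float)
    if np.any(r <= 0) or np.any(h <= 0):
        raise StressError("radius and thickness must be positive")
    out = np.asarray(pressure_kpa, dtype=float) * r / (2.0 * h)
    return float(out) if out.ndim == 0 else out


@dataclass
class StressField:
    """Per-segment stress time series (kPa) on the strain time base."""

    method: str
    segments: np.ndarray
    values: np.ndarray  # (n_segments, n_frames) kPa
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise StressError(f"unknown stress method {self.method!r}; expected one of {METHODS}")
        self.segments = np.asarray(self.segments)
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.shape != (len(self.segments), len(self.frame_times)):
            raise StressError("values shape must be (n_segments, n_frames)")


def build_stress_field(
    method: str,
    pressure: PressureWaveform,
    frame_times: np.ndarray,
    geometry: SegmentGeometry | None = None,
    segments: np.ndarray | None = None,
) -> StressField:
    """Assemble the per-segment stress field for one of the five methods.

    Pressure is linearly interpolated onto ``frame_times``. The pure
    pressure methods broadcast the same trace to every segment; the
    Laplace methods require ``geometry`` (``WS_ED`` uses end-diastolic
    radius/thickness as a constant factor, ``WS_TV`` per-frame values).
    """
    if method not in METHODS:
        raise StressError(f"unknown stress method {method!r}")
    frame_times = np.asarray(frame_times, dtype=float)
    p = pressure.resample(frame_times)
    if method in SHAPE_METHODS:
        if geometry is None:
            raise StressError(f"{method} requires segmental geometry")
        segs = geometry.segments
        if method == "WS_ED":
            factor = geometry.r_effective[:, :1] / (2.0 * geometry.wall_thickness[:, :1])
            values = factor * p[None, :]
        else:  # WS_TV
            if geometry.r_circ.shape[1] != len(frame_times):
                raise StressError("WS_TV needs per-frame geometry matching frame_times")
            values = p[None, :] * geometry.r_effective / (2.0 * geometry.wall_thickness)
    else:
        if segments is None:
            segments = geometry.segments if geometry is not None else np.arange(1, 18)
        segs = np.asarray(segments)
        values = np.tile(p, (len(segs), 1))
    return StressField(method=method, segments=segs, values=values, frame_times=frame_times)
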