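"""Synthetic dyssynchronous-ventricle data generator.

Generates time-resolved LV endocardial surfaces, pressure waveforms and
whole cohorts with planted metric-to-outcome structure, so every pipeline
stage can be exercised and validated without clinical data.

The motion model is phenomenological, built from raised-cosine basis
curves (onset ramp, systolic hold, release; a rebound bump; a pre-stretch
bump), with an activation-delay field that is earliest at the septum and
latest at the LV lateral free wall:

* LBBB pattern - early-activated septal myocardium shortens early (at low
  pressure) and rebound-stretches late in systole (at high pressure),
  producing figure-8 stress-strain loops with net negative work; the
  late-activated free wall pre-stretches, then shortens deeply at high
  pressure (elevated work).
* CRT pattern - the activation dispersion and all dyssynchrony-driven
  amplitudes are compressed by a fixed factor (default 0.3), so septal
  negative work shrinks for every patient.

Vertex motion is a spatially varying homothety about a point on the long
axis; per-frame, per-segment scale corrections are solved by fixed-point
iteration so the area-weighted segmental strain recovered by the analysis
pipeline matches the generator's target curves to machine precision.

Cohorts plant a linear outcome model
``dESV = beta0 + beta1 * V_f_STNW(LBBB) + eps`` whose noise scale can be
chosen to realize a target population R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (
    EndocardialSurface,
    SegmentMap,
    assign_aha_segments,
    patch_areas,
    _vertex_segments,
)
from .stress import PressureWaveform, generic_waveform
from .strain import compute_rsct
from .work import WorkMap, loop_area

logger = logging.getLogger(__name__)

#: Generator inputs the knock-out procedure can substitute.
KNOCKOUT_PARAMETERS = ("geometry", "dyssynchrony", "pressure", "thickness")


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticPatientParams:
    """Generator parameters for one synthetic patient.

    Geometry: a truncated prolate spheroid (apex at the pole, basal plane
    at 3/4 of the full long semi-axis height), dimensions typical of a
    dilated dyssynchronous-heart-failure LV. ``severity`` in [0, 1] scales
    the activation dispersion and every dyssynchrony-driven strain
    component; severity 0 reproduces a synchronous ventricle.
    """

    axis_length_mm: float = 90.0
    equatorial_radius_mm: float = 30.0
    wall_thickness_mm: float = 8.0
    n_phi: int = 24
    n_rings: int = 14
    n_frames: int = 25
    rr_ms: float = 800.0
    # dyssynchrony
    severity: float = 0.7
    activation_delay_ms: float = 120.0
    rebound_amplitude: float = 0.25
    prestretch_amplitude: float = 0.08
    hyperwork_gain: float = 0.5
    shortening_suppression: float = 0.6
    shortening_area_strain: float = 0.18
    crt_dispersion_factor: float = 0.3
    # pressure
    peak_pressure_kpa: float = 16.0
    edp_kpa: float = 1.4
    # noise
    patch_noise_sigma: float = 0.0
    pressure_noise_kpa: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise SyntheticError("severity must lie in [0, 1]")
        for name in ("axis_length_mm", "equatorial_radius_mm", "wall_thickness_mm"):
            if getattr(self, name) <= 0:
                raise SyntheticError(f"{name} must be positive")

    @property
    def thickness_table(self) -> dict[int, float]:
        return {s: self.wall_thickness_mm for s in range(1, 18)}


@dataclass
class MotionGroundTruth:
    """What the generator prescribed: per-segment strain targets etc."""

    segments: np.ndarray
    target_strain: np.ndarray  # (n_segments, n_frames)
    frame_times: np.ndarray
    vertex_delay_ms: np.ndarray
    onset_sd_ms: float
    segmap: SegmentMap


# ---------------------------------------------------------------------------
# mesh
# ---------------------------------------------------------------------------

_THETA_BASE = np.pi / 3.0  # basal truncation: z_base = 1.5 * b


def make_lv_mesh(params: SyntheticPatientParams) -> EndocardialSurface:
    """Reference (end-diastolic) truncated prolate-spheroid endocardium.

    Apex at the origin, long axis +z, base plane at z = axis_length. The
    basal ring is the single boundary loop.
    """
    a = params.equatorial_radius_mm
    L = params.axis_length_mm
    b = L / 1.5
    n_phi, n_rings = params.n_phi, params.n_rings
    n_tri = 2 * n_phi * (n_rings - 1) + n_phi
    if n_tri < 200:
        raise SyntheticError(
            f"resolution too coarse for 17 AHA segments ({n_tri} triangles < 200)")
    theta = np.linspace(_THETA_BASE, np.pi, n_rings + 1)[:-1]
    phi = np.arange(n_phi) * (2.0 * np.pi / n_phi)
    th, ph = np.meshgrid(theta, phi, indexing="ij")
    x = a * np.sin(th) * np.cos(ph)
    y = a * np.sin(th) * np.sin(ph)
    z = b * (1.0 + np.cos(th))
    verts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    apex_idx = len(verts)
    verts = np.vstack([verts, [0.0, 0.0, 0.0]])

    tris = []
    for i in range(n_rings - 1):
        for j in range(n_phi):
            v00 = i * n_phi + j
            v01 = i * n_phi + (j + 1) % n_phi
            v10 = (i + 1) * n_phi + j
            v11 = (i + 1) * n_phi + (j + 1) % n_phi
            tris.append((v00, v01, v10))
            tris.append((v01, v11, v10))
    last = (n_rings - 1) * n_phi
    for j in range(n_phi):
        tris.append((last + j, last + (j + 1) % n_phi, apex_idx))

    return EndocardialSurface(
        vertices=verts[None, :, :],
        triangles=np.asarray(tris, dtype=np.intp),
        frame_times=np.array([0.0]),
        apex_point=np.zeros(3),
        base_centroid=np.array([0.0, 0.0, L]),
    )


# ---------------------------------------------------------------------------
# strain basis curves
# ---------------------------------------------------------------------------


def _rise(t, onset, width):
    x = np.clip((t - onset) / width, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def _fall(t, start, width):
    x = np.clip((t - start) / width, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * x))


def _bump(t, t0, t1):
    """Raised-cosine bump: 0 outside [t0, t1], 1 at the midpoint."""
    inside = (t >= t0) & (t <= t1)
    x = (t - t0) / (t1 - t0)
    out = np.where(inside, 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(x, 0, 1))), 0.0)
    return out


def _activation_geometry(surface: EndocardialSurface):
    """Azimuthal earliness profile and longitudinal mid-wall weight.

    Returns (geo, fz, frac_from_base) per vertex: geo = 1 at the septal
    centre azimuth, 0 at the lateral centre; fz vanishes at base and apex.
    """
    rel = surface.vertices[0] - surface.apex_point
    axis = surface.long_axis
    t_apex = rel @ axis / surface.axis_length
    frac_from_base = 1.0 - t_apex
    n1 = np.array([1.0, 0.0, 0.0])
    n2 = np.cross(axis, n1)
    alpha = np.arctan2(rel @ n2, rel @ n1)
    delta = alpha - np.pi / 2.0  # septal centre sits a quarter-turn from anterior
    geo = 0.5 * (1.0 + np.cos(delta))
    fz = np.sin(np.pi * np.clip(frac_from_base, 0.0, 1.0)) ** 2
    return geo, fz, frac_from_base


def _vertex_strain_targets(
    surface: EndocardialSurface,
    params: SyntheticPatientParams,
    state: str,
    frame_times: np.ndarray,
):
    """Per-vertex target area-strain curves and activation delays."""
    if state not in ("LBBB", "CRT"):
        raise SyntheticError(f"state must be 'LBBB' or 'CRT', got {state!r}")
    rr = params.rr_ms
    sev = params.severity
    geo, fz, _ = _activation_geometry(surface)
    delay = sev * params.activation_delay_ms * (1.0 - geo)  # 0 at septum
    if state == "CRT":
        c = params.crt_dispersion_factor
        delay = delay.mean() + c * (delay - delay.mean())
        # rebound/pre-stretch amplitudes relax more slowly than the timing
        # dispersion (sqrt of the factor), leaving residual septal negative
        # work after resynchronization rather than abolishing it
        eff = sev * np.sqrt(c)
    else:
        eff = sev

    f_reb = geo**4 * fz          # rebound-stretch spatial profile (early wall)
    lateness = 1.0 - geo         # pre-stretch / hyperwork profile (late wall)

    onset0, t_rise = 0.06 * rr, 0.22 * rr
    t_rel, t_fall = 0.62 * rr, 0.22 * rr
    reb0, reb1 = 0.30 * rr, 0.70 * rr
    pre0, pre1 = 0.06 * rr, 0.30 * rr

    t = frame_times[None, :]
    amp = params.shortening_area_strain * (
        1.0 - params.shortening_suppression * eff * f_reb
    ) * (1.0 + params.hyperwork_gain * eff * lateness)
    contraction = _rise(t, (onset0 + delay)[:, None], t_rise) * _fall(t, t_rel, t_fall)
    eps = -amp[:, None] * contraction
    eps = eps + (eff * params.rebound_amplitude * f_reb)[:, None] * _bump(t, reb0, reb1)
    eps = eps + (eff * params.prestretch_amplitude * lateness * fz)[:, None] * _bump(t, pre0, pre1)
    eps[:, 0] = 0.0
    return eps, delay


# ---------------------------------------------------------------------------
# motion
# ---------------------------------------------------------------------------


def make_motion(
    mesh: EndocardialSurface,
    params: SyntheticPatientParams,
    state: str = "LBBB",
    rng: np.random.Generator | None = None,
    tol: float = 1e-12,
    max_iter: int = 80,
) -> tuple[EndocardialSurface, MotionGroundTruth]:
    """Time-resolved surface whose segmental strain hits prescribed targets.

    Vertices move by a spatially varying homothety about a point on the
    long axis; per-segment multiplicative corrections are iterated until
    the area-weighted mean patch strain of every AHA segment equals the
    target curve (essentially to machine precision for noise-free motion).
    Patch-level noise, when enabled, is applied afterwards as per-vertex
    log-normal radial scale jitter.
    """
    frame_times = np.linspace(0.0, params.rr_ms, params.n_frames + 1)[:-1]
    eps_v, delay = _vertex_strain_targets(mesh, params, state, frame_times)
    segmap = assign_aha_segments(mesh)
    vert_seg = _vertex_segments(mesh, segmap)
    segments = np.arange(1, 18)
    seg_index = np.searchsorted(segments, vert_seg)  # vert_seg in 1..17

    v0 = mesh.vertices[0]
    ref_areas = patch_areas(mesh, 0)
    tri_seg = segmap.patch_segment
    center = mesh.apex_point + 0.45 * mesh.axis_length * mesh.long_axis
    rel0 = v0 - center

    # segment targets = reference-area-weighted mean of per-patch targets
    eps_p = eps_v[mesh.triangles].mean(axis=1)  # (n_tri, n_frames)
    target = np.empty((17, len(frame_times)))
    seg_w = np.empty(17)
    for i, s in enumerate(segments):
        m = tri_seg == s
        if not np.any(m):
            raise SyntheticError(f"AHA segment {s} empty at this resolution")
        w = ref_areas[m]
        seg_w[i] = w.sum()
        target[i] = (eps_p[m] * w[:, None]).sum(axis=0) / w.sum()
    target[:, 0] = 0.0

    noise = None
    if rng is not None and params.patch_noise_sigma > 0:
        noise = np.exp(rng.normal(0.0, params.patch_noise_sigma,
                                  size=(len(frame_times), mesh.n_vertices)))
        noise[0] = 1.0

    frames = np.empty((len(frame_times), mesh.n_vertices, 3))
    frames[0] = v0
    lam_v = np.sqrt(np.maximum(1.0 + eps_v, 1e-6))
    for f in range(1, len(frame_times)):
        m = np.ones(17)
        lam = lam_v[:, f]
        for _ in range(max_iter):
            scale = lam * m[seg_index]
            verts = center + scale[:, None] * rel0
            p = verts[mesh.triangles]
            areas = 0.5 * np.linalg.norm(
                np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
            strain_p = areas / ref_areas - 1.0
            actual = np.array([
                (strain_p[tri_seg == s] * ref_areas[tri_seg == s]).sum() / seg_w[i]
                for i, s in enumerate(segments)
            ])
            err = np.max(np.abs(actual - target[:, f]))
            if err < tol:
                break
            m *= np.sqrt((1.0 + target[:, f]) / (1.0 + actual))
        else:
            logger.warning("segment strain solve stopped at err=%.2e (frame %d)", err, f)
        scale = lam * m[seg_index]
        if noise is not None:
            scale = scale * noise[f]
        frames[f] = center + scale[:, None] * rel0

    moving = EndocardialSurface(
        vertices=frames,
        triangles=mesh.triangles,
        frame_times=frame_times,
        apex_point=mesh.apex_point,
        base_centroid=mesh.base_centroid,
        long_axis=mesh.long_axis,
    )
    truth = MotionGroundTruth(
        segments=segments,
        target_strain=target,
        frame_times=frame_times,
        vertex_delay_ms=delay,
        onset_sd_ms=float(np.std(delay)),
        segmap=segmap,
    )
    return moving, truth


def make_pressure(
    params: SyntheticPatientParams,
    state: str = "LBBB",
    rng: np.random.Generator | None = None,
) -> PressureWaveform:
    """Patient pressure waveform (generic parametric shape, patient peak/EDP).

    Optional additive measurement noise (kPa, clipped at zero).
    """
    rr = params.rr_ms
    wave = generic_waveform(
        peak_kpa=params.peak_pressure_kpa,
        edp_kpa=params.edp_kpa,
        onset_ms=0.0625 * rr,
        peak_time_ms=0.375 * rr,
        relax_end_ms=0.6875 * rr,
        rr_ms=rr,
        diastolic_min_kpa=min(0.5, params.edp_kpa),
    )
    wave = replace(wave, label="measured")
    if rng is not None and params.pressure_noise_kpa > 0:
        noisy = wave.pressures + rng.normal(0.0, params.pressure_noise_kpa,
                                            size=wave.pressures.shape)
        wave = replace(wave, pressures=np.clip(noisy, 0.0, None))
    return wave


# ---------------------------------------------------------------------------
# energy-consistent ground-truth work map
# ---------------------------------------------------------------------------


def truth_work_map(
    surface: EndocardialSurface,
    pressure: PressureWaveform,
    params: SyntheticPatientParams,
    truth: MotionGroundTruth,
    state: str = "LBBB",
    active_stress_kpa: float = 10.0,
) -> WorkMap:
    """Generator-side ("model-truth") work-density map in kJ/m^3.

    Stress per patch is the local Laplace equilibrium stress (cavity
    pressure x local radius / 2h) plus a non-negative active-contraction
    component whose deactivation is faster than the strain release.
    Because the active tension is switched off before passive recoil
    re-lengthens the wall, part of the wall work never reaches the cavity,
    so total myocardial work exceeds stroke work and the mechanical
    efficiency eta stays below 1 (energy-consistent mode). Weights are
    wall volume (patch area x thickness), mm^3.
    """
    strain = compute_rsct(surface)
    t = surface.frame_times[None, :]
    rr = params.rr_ms
    center = surface.apex_point + 0.45 * surface.axis_length * surface.long_axis
    h = params.wall_thickness_mm
    p_t = pressure.resample(surface.frame_times)

    tri_delay = truth.vertex_delay_ms[surface.triangles].mean(axis=1)
    onset0, t_rise = 0.06 * rr, 0.22 * rr
    act_env = _rise(t, (onset0 + tri_delay)[:, None], t_rise) * _fall(
        t, 0.52 * rr, 0.13 * rr)  # deactivates earlier/faster than strain release

    work = np.empty(len(strain.unit_ids))
    for i, u in enumerate(strain.unit_ids):
        cent = surface.vertices[:, surface.triangles[u]].mean(axis=1)  # (n_frames, 3)
        r_local = np.linalg.norm(cent - center, axis=1)
        sigma = p_t * r_local / (2.0 * h) + active_stress_kpa * act_env[u]
        work[i] = loop_area(strain.values[i], sigma)

    segmap = truth.segmap
    seg = segmap.patch_segment[strain.unit_ids]
    region = np.array([segmap.segment_region(int(s)) for s in seg], dtype=object)
    return WorkMap(
        unit_ids=strain.unit_ids,
        work=work,
        weights=strain.reference_weights * h,
        weight_kind="volume",
        segment=seg,
        region=region,
        method="model_truth",
        state=state,
        resolution="patch",
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class SyntheticPatient:
    """One synthetic subject: params, per-state data and planted outcome."""

    patient_id: str
    params: SyntheticPatientParams
    surfaces: dict  # state -> EndocardialSurface
    pressures: dict  # state -> PressureWaveform
    truths: dict  # state -> MotionGroundTruth
    true_v_f_stnw: float = float("nan")  # pipeline value at LBBB, noise-free
    outcome_desv: float = float("nan")
    metrics_cache: dict = field(default_factory=dict)


@dataclass
class SyntheticCohortConfig:
    """Cohort-level generator configuration.

    The outcome model is dESV = beta0 + beta1 * V_f_STNW(LBBB) + eps with
    eps ~ N(0, sigma_eps); when ``sigma_eps`` is None it is derived from
    ``target_r2`` and the realized spread of the cohort's V_f_STNW values,
    sigma = |beta1| * SD(x) * sqrt((1 - R2) / R2).
    """

    n_patients: int = 8
    severity_range: tuple[float, float] = (0.3, 0.95)
    beta0: float = -20.0
    beta1: float = 150.0
    sigma_eps: float | None = None
    target_r2: float = 0.7
    states: tuple[str, ...] = ("LBBB", "CRT")
    master_seed: int = 0
    patch_noise_sigma: float = 0.0
    # inter-patient variability (SDs around the single-patient defaults)
    geometry_sd: float = 0.06  # relative, applied to axis length & radius
    thickness_sd_mm: float = 0.8
    pressure_sd_kpa: float = 1.5
    activation_sd_ms: float = 12.0


@dataclass
class SyntheticCohort:
    config: SyntheticCohortConfig
    patients: list
    ground_truth: pd.DataFrame


def _patient_params(cfg: SyntheticCohortConfig, rng: np.random.Generator,
                    seed: int) -> SyntheticPatientParams:
    lo, hi = cfg.severity_range
    return SyntheticPatientParams(
        axis_length_mm=90.0 * float(np.exp(rng.normal(0.0, cfg.geometry_sd))),
        equatorial_radius_mm=30.0 * float(np.exp(rng.normal(0.0, cfg.geometry_sd))),
        wall_thickness_mm=max(4.0, 8.0 + float(rng.normal(0.0, cfg.thickness_sd_mm))),
        severity=float(rng.uniform(lo, hi)),
        activation_delay_ms=max(60.0, 120.0 + float(rng.normal(0.0, cfg.activation_sd_ms))),
        peak_pressure_kpa=max(8.0, 16.0 + float(rng.normal(0.0, cfg.pressure_sd_kpa))),
        edp_kpa=float(np.clip(1.4 + rng.normal(0.0, 0.25), 0.5, 3.0)),
        patch_noise_sigma=cfg.patch_noise_sigma,
        seed=seed,
    )


def make_patient(
    params: SyntheticPatientParams,
    states: tuple[str, ...] = ("LBBB", "CRT"),
    patient_id: str = "SYN1",
) -> SyntheticPatient:
    """Generate one patient's mesh sequences and pressures for the states."""
    rng = np.random.default_rng(params.seed)
    mesh = make_lv_mesh(params)
    surfaces, pressures, truths = {}, {}, {}
    for state in states:
        surfaces[state], truths[state] = make_motion(mesh, params, state, rng=rng)
        pressures[state] = make_pressure(params, state, rng=rng)
    return SyntheticPatient(
        patient_id=patient_id, params=params,
        surfaces=surfaces, pressures=pressures, truths=truths,
    )


def make_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Cohort of synthetic patients with a planted metric-outcome relation.

    Every patient's LBBB data are analyzed at generation time (P_LHC
    pressure-strain work, patch resolution) to obtain the ground-truth
    V_f_STNW driving the planted linear outcome model. Fully reproducible
    from ``master_seed``; per-patient RNG streams are spawned from it.
    """
    from .pipeline import analyze_patient

    ss = np.random.SeedSequence(config.master_seed)
    patient_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_patients)]
    outcome_rng = np.random.default_rng(
        int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)))

    rng_params = np.random.default_rng(patient_seeds[0] ^ 0x5EED)
    patients = []
    for i in range(config.n_patients):
        params = _patient_params(config, rng_params, seed=patient_seeds[i])
        patients.append(make_patient(params, states=config.states, patient_id=f"SYN{i + 1}"))

    x = np.empty(config.n_patients)
    for i, p in enumerate(patients):
        res = analyze_patient(
            p.surfaces["LBBB"], p.pressures["LBBB"], p.params.thickness_table,
            methods=("P_LHC",), state="LBBB", compute_global=False)
        p.metrics_cache[("LBBB", "P_LHC")] = res.metrics["P_LHC"]
        x[i] = res.metrics["P_LHC"].v_f_stnw
        p.true_v_f_stnw = x[i]

    if config.sigma_eps is not None:
        sigma = config.sigma_eps
        eps = outcome_rng.normal(0.0, sigma, size=config.n_patients)
    else:
        # plant target_r2 exactly in-sample: draw noise, remove its chance
        # correlation with the metric, and rescale so the cohort's planted
        # coefficient of determination equals the target deterministically
        r2 = config.target_r2
        sigma = abs(config.beta1) * float(np.std(x)) * np.sqrt((1.0 - r2) / r2)
        eps = outcome_rng.normal(0.0, 1.0, size=config.n_patients)
        xc = x - x.mean()
        if np.ptp(x) > 0 and config.n_patients >= 3:
            eps = eps - xc * float(eps @ xc) / float(xc @ xc)
        eps = eps - eps.mean()
        sd = float(np.std(eps))
        if sd > 0:
            eps = eps * (sigma / sd)
    desv = config.beta0 + config.beta1 * x + eps
    for p, d in zip(patients, desv):
        p.outcome_desv = float(d)

    truth = pd.DataFrame({
        "patient_id": [p.patient_id for p in patients],
        "seed": patient_seeds,
        "severity": [p.params.severity for p in patients],
        "true_v_f_stnw_lbbb": x,
        "outcome_desv": desv,
        "beta0": config.beta0,
        "beta1": config.beta1,
        "sigma_eps": sigma,
    })
    return SyntheticCohort(config=config, patients=patients, ground_truth=truth)


def apply_knockout(cohort: SyntheticCohort, parameter: str) -> SyntheticCohort:
    """Replace one generator parameter by its cohort mean for every patient.

    Regenerates the per-patient data with the same seeds; planted outcomes
    are kept from the original cohort (the knock-out changes the model
    inputs, not the measured outcome).
    """
    if parameter not in KNOCKOUT_PARAMETERS:
        raise SyntheticError(f"unknown knock-out parameter {parameter!r}")
    ps = [p.params for p in cohort.patients]
    mean = {
        "axis_length_mm": float(np.mean([q.axis_length_mm for q in ps])),
        "equatorial_radius_mm": float(np.mean([q.equatorial_radius_mm for q in ps])),
        "wall_thickness_mm": float(np.mean([q.wall_thickness_mm for q in ps])),
        "severity": float(np.mean([q.severity for q in ps])),
        "activation_delay_ms": float(np.mean([q.activation_delay_ms for q in ps])),
        "peak_pressure_kpa": float(np.mean([q.peak_pressure_kpa for q in ps])),
        "edp_kpa": float(np.mean([q.edp_kpa for q in ps])),
    }
    new_patients = []
    for p in cohort.patients:
        q = p.params
        if parameter == "geometry":
            q = replace(q, axis_length_mm=mean["axis_length_mm"],
                        equatorial_radius_mm=mean["equatorial_radius_mm"])
        elif parameter == "dyssynchrony":
            q = replace(q, severity=mean["severity"],
                        activation_delay_ms=mean["activation_delay_ms"])
        elif parameter == "pressure":
            q = replace(q, peak_pressure_kpa=mean["peak_pressure_kpa"],
                        edp_kpa=mean["edp_kpa"])
        elif parameter == "thickness":
            q = replace(q, wall_thickness_mm=mean["wall_thickness_mm"])
        np_ = make_patient(q, states=cohort.config.states, patient_id=p.patient_id)
        np_.outcome_desv = p.outcome_desv
        np_.true_v_f_stnw = p.true_v_f_stnw
        new_patients.append(np_)
    return SyntheticCohort(config=cohort.config, patients=new_patients,
                           ground_truth=cohort.ground_truth)
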