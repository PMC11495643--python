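"""Signed stress-strain loop areas and global work quantities.

Regional myocardial work density is the signed area enclosed by the
stress-strain loop over one cardiac cycle, with strain on the abscissa and
stress on the ordinate. Counter-clockwise loops are positive (external work
performed by the myocardium); clockwise loops are negative (work done on
the myocardium), i.e.

    W = -closed-integral of sigma d(epsilon)

evaluated with the shoelace formula on the sampled loop, the end-diastolic
sample appended to close the cycle. Self-intersecting figure-8 loops -
typical of early-activated myocardium in LBBB - yield the net signed area
of their lobes.

Work densities from the pressure/Laplace surrogates carry kPa (identically
kJ/m^3); global quantities (stroke work, total myocardial work and their
ratio, the mechanical efficiency eta) are in joules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .geometry import SegmentMap
from .strain import StrainField
from .stress import PressureWaveform, StressField

logger = logging.getLogger(__name__)


class WorkError(ValueError):
    pass


def _shoelace(x: np.ndarray, y: np.ndarray) -> float:
    """Signed polygon area, CCW positive; closes the polygon itself."""
    x = np.concatenate([x, x[:1]])
    y = np.concatenate([y, y[:1]])
    return 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))


def loop_area(strain: np.ndarray, stress: np.ndarray) -> float:
    """Signed stress-strain loop area (kPa) over one closed cycle.

    ``strain`` and ``stress`` are equal-length series over one RR interval;
    the first sample is appended as the last to close the loop. Positive =
    counter-clockwise = work performed by the tissue.
    """
    strain = np.asarray(strain, dtype=float)
    stress = np.asarray(stress, dtype=float)
    if strain.shape != stress.shape or strain.ndim != 1:
        raise WorkError("strain and stress must be equal-length 1-D series")
    if len(strain) < 3:
        raise WorkError("need at least 3 samples to form a loop")
    return _shoelace(strain, stress)


@dataclass
class WorkMap:
    """Per-unit signed work densities with area or volume weights.

    work : kPa (== kJ/m^3) per unit (patch or AHA segment).
    weights : endocardial patch area mm^2 (``weight_kind='area'``) or wall
        volume mm^3 (``weight_kind='volume'``).
    """

    unit_ids: np.ndarray
    work: np.ndarray
    weights: np.ndarray
    weight_kind: str  # "area" | "volume"
    segment: np.ndarray
    region: np.ndarray  # "septum" | "lv_free_wall" | "apex"
    method: str = ""
    state: str = ""  # "LBBB" | "CRT" | ""
    resolution: str = "patch"

    def __post_init__(self) -> None:
        self.work = np.asarray(self.work, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.segment = np.asarray(self.segment)
        self.region = np.asarray(self.region)
        if self.weight_kind not in ("area", "volume"):
            raise WorkError("weight_kind must be 'area' or 'volume'")
        if np.any(self.weights <= 0):
            raise WorkError("weights must be positive")
        n = len(self.work)
        if not (len(self.weights) == len(self.segment) == len(self.region) == n):
            raise WorkError("work, weights, segment and region lengths must match")

    def with_volume_weights(self, thickness_mm: np.ndarray) -> "WorkMap":
        """Convert an area-weighted map to volume weights (area x thickness)."""
        if self.weight_kind != "area":
            raise WorkError("map already has volume weights")
        th = np.broadcast_to(np.asarray(thickness_mm, dtype=float), self.weights.shape)
        if np.any(th <= 0):
            raise WorkError("thickness must be positive")
        return replace(self, weights=self.weights * th, weight_kind="volume")

    def select(self, region: str) -> "WorkMap":
        """Sub-map for 'lv' (free wall + septum + apex), 'septum' or 'all'."""
        if region in ("all", "lv"):
            return self
        m = self.region == region
        if not np.any(m):
            raise WorkError(f"no units in region {region!r}")
        return replace(self, unit_ids=self.unit_ids[m], work=self.work[m],
                       weights=self.weights[m], segment=self.segment[m],
                       region=self.region[m])


def compute_work_map(
    strain: StrainField,
    stress: StressField,
    segmap: SegmentMap | None = None,
    weights: np.ndarray | None = None,
    weight_kind: str = "area",
    state: str = "",
) -> WorkMap:
    """Loop area per unit from matched strain and stress fields.

    Patch-resolution strain takes each patch's stress from its AHA segment
    (``segmap`` required); segment-resolution strain pairs curves by
    segment id. Default weights are the reference patch areas carried by
    the strain field.
    """
    if not np.allclose(strain.frame_times, stress.frame_times):
        raise WorkError("strain and stress are on different time bases")
    seg_row = {int(s): i for i, s in enumerate(stress.segments)}
    if strain.resolution == "patch":
        if segmap is None:
            raise WorkError("patch-resolution work maps need a SegmentMap")
        segment = segmap.patch_segment[strain.unit_ids]
    else:
        segment = strain.unit_ids
    missing = set(int(s) for s in np.unique(segment)) - set(seg_row)
    if missing:
        raise WorkError(f"stress field lacks segments {sorted(missing)}")
    rows = np.array([seg_row[int(s)] for s in segment])
    work = np.array([
        loop_area(strain.values[i], stress.values[rows[i]])
        for i in range(len(strain.unit_ids))
    ])
    if weights is None:
        weights = strain.reference_weights
    if segmap is not None:
        region = np.array([segmap.segment_region(int(s)) for s in segment], dtype=object)
    else:
        from .geometry import SEPTAL_SEGMENTS
        region = np.array(
            ["septum" if int(s) in SEPTAL_SEGMENTS else ("apex" if int(s) == 17 else "lv_free_wall")
             for s in segment], dtype=object)
    return WorkMap(unit_ids=np.asarray(strain.unit_ids), work=work,
                   weights=np.asarray(weights, float), weight_kind=weight_kind,
                   segment=np.asarray(segment), region=region,
                   method=stress.method, state=state, resolution=strain.resolution)


def stroke_work(
    pressure: PressureWaveform,
    volumes_ml: np.ndarray,
    frame_times: np.ndarray,
    closure_tol: float = 0.05,
) -> float:
    """Global LV stroke work (J): signed PV-loop area, CCW positive.

    Pressure is interpolated onto the volume frame times; the loop is
    closed back to the first sample. A cycle whose final volume differs
    from the first by more than ``closure_tol`` of the volume range is
    flagged and force-closed.
    """
    v = np.asarray(volumes_ml, dtype=float)
    t = np.asarray(frame_times, dtype=float)
    if v.shape != t.shape:
        raise WorkError("volumes and frame_times must match")
    vrange = float(np.ptp(v))
    if vrange > 0 and abs(v[-1] - v[0]) > closure_tol * vrange:
        logger.warning("PV loop open (|dV| = %.2f mL); forcing closure", abs(v[-1] - v[0]))
    p = pressure.resample(t)
    return _shoelace(v, p) / 1000.0  # kPa*mL = mJ


def total_myocardial_work(workmap: WorkMap, thickness_mm: np.ndarray | None = None) -> float:
    """Total LV myocardial work (J): sum of work density x wall volume.

    Needs volume weights (mm^3); an area-weighted map is converted with
    ``thickness_mm`` (per unit or scalar), a documented thin-wall
    approximation. kPa x mm^3 = uJ, returned in J.
    """
    if workmap.weight_kind == "area":
        if thickness_mm is None:
            raise WorkError("surface-mode map needs thickness to form volume weights")
        workmap = workmap.with_volume_weights(thickness_mm)
    return float(np.sum(workmap.work * workmap.weights)) * 1e-6


@dataclass
class GlobalWork:
    """Global energetics of one patient-state: stroke, total and eta."""

    stroke_work_j: float
    total_myocardial_work_j: float


def efficiency(global_work: GlobalWork) -> float:
    """Mechanical efficiency eta = stroke work / total myocardial work.

    Undefined (NaN, logged) when total work is not positive.
    """
    if global_work.total_myocardial_work_j <= 0:
        logger.warning("efficiency undefined: total myocardial work <= 0")
        return float("nan")
    return global_work.stroke_work_j / global_work.total_myocardial_work_j
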