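"""Endocardial area strain (RS_CT).

Regional strain is approximated from the fractional change of endocardial
patch area relative to end-diastole,

    RS_CT(v, t) = A(v, t) / A(v, 0) - 1,

where A(v, t) is the area of triangular patch v at time t in the RR
interval. Patch strains are averaged within AHA segments (area-weighted by
default) to give one strain curve per segment. Being built purely from
areas, RS_CT is invariant to rigid-body motion of the surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import EndocardialSurface, SegmentMap, patch_areas

logger = logging.getLogger(__name__)


class StrainError(ValueError):
    pass


@dataclass
class StrainField:
    """Unitless strain per unit (patch or AHA segment) per frame.

    values : ndarray, shape (n_units, n_frames); values[:, 0] == 0.
    unit_ids : patch indices or AHA segment ids.
    reference_weights : reference-frame patch areas (mm^2) used for
        averaging and surface-fraction weights; segment totals after
        averaging.
    """

    values: np.ndarray
    unit_ids: np.ndarray
    frame_times: np.ndarray
    resolution: str  # "patch" | "segment"
    reference_weights: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.unit_ids = np.asarray(self.unit_ids)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.reference_weights = np.asarray(self.reference_weights, dtype=float)
        if self.resolution not in ("patch", "segment"):
            raise StrainError("resolution must be 'patch' or 'segment'")
        if self.values.shape != (len(self.unit_ids), len(self.frame_times)):
            raise StrainError("values shape must be (n_units, n_frames)")
        if np.any(np.abs(self.values[:, 0]) > 1e-12):
            raise StrainError("strain must be exactly 0 at the reference frame")
        if np.any(self.values <= -1.0):
            raise StrainError("area strain cannot reach -1 (vanished patch)")


def compute_rsct(surface: EndocardialSurface) -> StrainField:
    """Patch-resolution RS_CT for every triangle with positive reference area.

    Patches whose end-diastolic area is zero are excluded from the field
    (logged); their indices simply do not appear in ``unit_ids``.
    """
    a0 = patch_areas(surface, 0)
    keep = a0 > 0.0
    if not np.all(keep):
        logger.warning("excluding %d zero-reference-area patch(es) from RS_CT",
                       int(np.sum(~keep)))
    areas = np.stack([patch_areas(surface, f) for f in range(surface.n_frames)], axis=1)
    values = areas[keep] / a0[keep, None] - 1.0
    values[:, 0] = 0.0  # exact by definition
    return StrainField(
        values=values,
        unit_ids=np.flatnonzero(keep),
        frame_times=surface.frame_times,
        resolution="patch",
        reference_weights=a0[keep],
    )


def segment_average_strain(
    field: StrainField,
    segmap: SegmentMap,
    area_weighted: bool = True,
) -> StrainField:
    """Average patch strains within AHA segments: one curve per segment.

    The default weights each patch by its reference (end-diastolic) area so
    the segmental curve is independent of mesh resolution; ``area_weighted=
    False`` gives the plain mean for sensitivity checks.
    """
    if field.resolution != "patch":
        raise StrainError("segment averaging expects a patch-resolution field")
    seg_of_unit = segmap.patch_segment[field.unit_ids]
    segments = np.unique(segmap.patch_segment)
    values = np.empty((len(segments), field.values.shape[1]))
    weights = np.empty(len(segments))
    for i, s in enumerate(segments):
        m = seg_of_unit == s
        if not np.any(m):
            raise StrainError(f"AHA segment {s} has no patches with valid strain")
        w = field.reference_weights[m] if area_weighted else np.ones(int(m.sum()))
        values[i] = (field.values[m] * w[:, None]).sum(axis=0) / w.sum()
        weights[i] = field.reference_weights[m].sum()
    values[:, 0] = 0.0
    return StrainField(
        values=values,
        unit_ids=segments,
        frame_times=field.frame_times,
        resolution="segment",
        reference_weights=weights,
    )
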