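"""Heterogeneity and regional-fraction metrics over work maps.

* COVW - coefficient of variation of regional work density (weighted SD /
  weighted |mean|), an index of work heterogeneity.
* Negative-work fractions - the fraction of the LV (or of the septum,
  AHA segments {2, 3, 8, 9, 14}) performing net negative work over the
  cycle; volume-weighted maps give V_f_LVNW / V_f_STNW, surface
  (area)-weighted maps give S_f_LVNW / S_f_STNW.
* High-work fraction - the weighted fraction of the LV above the upper
  quartile of its own work-density distribution (V_f_LVHW), computed per
  patient and state.
* delta_metric - baseline minus post-CRT changes, so a positive delta is a
  reduction after resynchronization.

All fractions lie in [0, 1]. These metrics are invariant under uniform
positive scaling of the work map, which is why the generic and
peak-scaled-generic pressure methods produce identical values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np

from .work import WorkMap

logger = logging.getLogger(__name__)


class MetricsError(ValueError):
    pass


def covw(workmap: WorkMap, region: str = "lv", weighted: bool = True) -> float:
    """Coefficient of variation of work density in a region.

    Weighted population standard deviation divided by the magnitude of the
    weighted mean; NaN (logged) when the mean is zero. ``weighted=False``
    ignores the area/volume weights for sensitivity checks.
    """
    sub = workmap.select(region)
    w = sub.weights if weighted else np.ones_like(sub.weights)
    mean = float(np.average(sub.work, weights=w))
    if mean == 0.0:
        logger.warning("COVW undefined: zero mean work in region %r", region)
        return float("nan")
    sd = float(np.sqrt(np.average((sub.work - mean) ** 2, weights=w)))
    return sd / abs(mean)


def negative_work_fraction(workmap: WorkMap, region: str = "lv") -> float:
    """Weighted fraction of a region with strictly negative work."""
    sub = workmap.select(region)
    return float(sub.weights[sub.work < 0.0].sum() / sub.weights.sum())


def _weighted_quantile_lower(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Lower-interpolation quantile of a weighted distribution.

    The smallest value at which the normalized cumulative weight reaches q.
    Deterministic; ties in value are merged by the sort.
    """
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w) / w.sum()
    idx = int(np.searchsorted(cum, q, side="left"))
    return float(v[min(idx, len(v) - 1)])


def high_work_fraction(workmap: WorkMap, region: str = "lv", quantile: float = 0.75) -> float:
    """Weighted fraction of a region strictly above its work quantile.

    The threshold is the weighted ``quantile`` of the same patient-state
    map (per-patient convention), so a uniform map yields 0.
    """
    sub = workmap.select(region)
    thr = _weighted_quantile_lower(sub.work, sub.weights, quantile)
    return float(sub.weights[sub.work > thr].sum() / sub.weights.sum())


@dataclass
class RegionalWorkMetrics:
    """Heterogeneity and regional-fraction metrics for one patient-state.

    Volume-fraction fields are NaN when only a surface-weighted map was
    available, and vice versa.
    """

    covw: float = float("nan")
    v_f_lvnw: float = float("nan")
    v_f_stnw: float = float("nan")
    s_f_lvnw: float = float("nan")
    s_f_stnw: float = float("nan")
    v_f_lvhw: float = float("nan")
    state: str = ""
    method: str = ""

    _METRIC_FIELDS = ("covw", "v_f_lvnw", "v_f_stnw", "s_f_lvnw", "s_f_stnw", "v_f_lvhw")

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in self._METRIC_FIELDS}


def compute_regional_metrics(
    surface_map: WorkMap | None = None,
    volume_map: WorkMap | None = None,
    high_work_quantile: float = 0.75,
) -> RegionalWorkMetrics:
    """All regional metrics from a surface- and/or volume-weighted work map.

    COVW (and the high-work fraction) are taken from the volume map when
    present, else from the surface map.
    """
    if surface_map is None and volume_map is None:
        raise MetricsError("need at least one work map")
    primary = volume_map if volume_map is not None else surface_map
    out = RegionalWorkMetrics(state=primary.state, method=primary.method)
    out.covw = covw(primary, "lv")
    if volume_map is not None:
        out.v_f_lvnw = negative_work_fraction(volume_map, "lv")
        out.v_f_stnw = negative_work_fraction(volume_map, "septum")
        out.v_f_lvhw = high_work_fraction(volume_map, "lv", high_work_quantile)
    if surface_map is not None:
        out.s_f_lvnw = negative_work_fraction(surface_map, "lv")
        out.s_f_stnw = negative_work_fraction(surface_map, "septum")
    return out


def delta_metric(baseline: RegionalWorkMetrics, post: RegionalWorkMetrics) -> RegionalWorkMetrics:
    """Baseline-minus-post change in each metric (positive = reduction).

    Both inputs must come from the same work-estimation method.
    """
    if baseline.method != post.method:
        raise MetricsError(
            f"method mismatch: {baseline.method!r} vs {post.method!r}")
    out = RegionalWorkMetrics(state=f"{baseline.state}-{post.state}", method=baseline.method)
    for f in RegionalWorkMetrics._METRIC_FIELDS:
        setattr(out, f, getattr(baseline, f) - getattr(post, f))
    return out
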