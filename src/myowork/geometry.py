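"""Left-ventricular endocardial surface geometry.

Time-resolved triangulated endocardial surfaces in an apex/base reference
frame, the AHA 17-segment parcellation, per-patch areas, cavity volume and
the segmental shape quantities (radii of curvature, wall thickness) that
feed the Laplace wall-stress surrogate.

Conventions
-----------
* Coordinates are millimetres. The canonical local frame has the long axis
  as +z with the apex at z = 0 and the base at z = L; arbitrary frames are
  accepted as long as ``apex_point``, ``base_centroid`` and ``long_axis``
  are populated.
* Frame 0 is end-diastole and is the reference configuration for strain.
* AHA segments 1-17: basal ring 1-6 and mid ring 7-12 in 60-degree sectors
  (anterior, anteroseptal, inferoseptal, inferior, inferolateral,
  anterolateral), apical ring 13-16 in 90-degree sectors (anterior, septal,
  inferior, lateral), segment 17 the apex cap. Septal segments are
  {2, 3, 8, 9, 14}.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: AHA segment ids belonging to the interventricular septum.
SEPTAL_SEGMENTS = frozenset({2, 3, 8, 9, 14})

#: All AHA segment ids.
ALL_SEGMENTS = tuple(range(1, 18))

#: Fractional position (measured base -> apex) above which a patch belongs
#: to the apex cap (segment 17).
APEX_CAP_FRACTION = 0.95


class GeometryError(ValueError):
    """Raised for invalid or degenerate geometric input."""


@dataclass
class EndocardialSurface:
    """Time-resolved triangulated LV endocardial surface.

    Parameters
    ----------
    vertices : ndarray, shape (n_frames, n_vertices, 3)
        Vertex coordinates in mm per frame. Frame 0 is end-diastole.
    triangles : ndarray, shape (n_triangles, 3)
        Vertex index triples; the triangulation is shared by all frames.
    frame_times : ndarray, shape (n_frames,)
        Milliseconds from the R wave; strictly increasing, frame_times[0]=0.
    apex_point, base_centroid : ndarray, shape (3,)
        Landmarks in the reference (frame 0) configuration.
    long_axis : ndarray, shape (3,), optional
        Unit vector apex -> base. Derived from the landmarks when omitted.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    frame_times: np.ndarray
    apex_point: np.ndarray
    base_centroid: np.ndarray
    long_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.intp)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.apex_point = np.asarray(self.apex_point, dtype=float)
        self.base_centroid = np.asarray(self.base_centroid, dtype=float)
        if self.vertices.ndim == 2:
            self.vertices = self.vertices[None, :, :]
        if self.vertices.ndim != 3 or self.vertices.shape[2] != 3:
            raise GeometryError("vertices must have shape (n_frames, n_vertices, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise GeometryError("triangles must have shape (n_triangles, 3)")
        n_v = self.vertices.shape[1]
        if self.triangles.min(initial=0) < 0 or self.triangles.max(initial=-1) >= n_v:
            raise GeometryError("triangle indices out of range")
        if len(self.frame_times) != self.vertices.shape[0]:
            raise GeometryError("frame_times length does not match vertex frames")
        if self.frame_times[0] != 0.0 or np.any(np.diff(self.frame_times) <= 0):
            raise GeometryError("frame_times must be strictly increasing from 0")
        axis = self.base_centroid - self.apex_point
        axis_len = float(np.linalg.norm(axis))
        if axis_len < 1e-6:
            raise GeometryError("degenerate long axis: apex coincides with base")
        if self.long_axis is None:
            self.long_axis = axis / axis_len
        else:
            self.long_axis = np.asarray(self.long_axis, dtype=float)
            self.long_axis = self.long_axis / np.linalg.norm(self.long_axis)

    # -- basic queries ---------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[1]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    @property
    def axis_length(self) -> float:
        """Apex-to-base distance (mm) in the reference frame."""
        return float(np.linalg.norm(self.base_centroid - self.apex_point))

    def triangle_centroids(self, frame: int = 0) -> np.ndarray:
        """Centroid of each triangle at ``frame``, shape (n_triangles, 3)."""
        v = self.vertices[frame]
        return v[self.triangles].mean(axis=1)

    def boundary_loops(self) -> list[np.ndarray]:
        """Connected loops of boundary edges (edges used by one triangle)."""
        edges = np.sort(
            np.concatenate(
                [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
            ),
            axis=1,
        )
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        boundary = uniq[counts == 1]
        if len(boundary) == 0:
            return []
        # chain edges into loops
        adj: dict[int, list[int]] = {}
        for a, b in boundary:
            adj.setdefault(int(a), []).append(int(b))
            adj.setdefault(int(b), []).append(int(a))
        unvisited = set(map(tuple, boundary.tolist()))
        loops = []
        while unvisited:
            a, b = next(iter(unvisited))
            loop = [a, b]
            unvisited.discard((a, b))
            while True:
                nxt = [n for n in adj[loop[-1]] if n != loop[-2]]
                nxt = [n for n in nxt if tuple(sorted((loop[-1], n))) in unvisited]
                if not nxt:
                    break
                loop.append(nxt[0])
                unvisited.discard(tuple(sorted((loop[-2], loop[-1]))))
            if loop[0] == loop[-1]:
                loop = loop[:-1]
            loops.append(np.asarray(loop, dtype=np.intp))
        return loops


@dataclass
class SegmentMap:
    """AHA 17-segment assignment for every triangle of a surface."""

    patch_segment: np.ndarray  # (n_triangles,) int, values 1..17
    septal_ids: frozenset = SEPTAL_SEGMENTS

    def __post_init__(self) -> None:
        self.patch_segment = np.asarray(self.patch_segment, dtype=np.intp)
        if self.patch_segment.min() < 1 or self.patch_segment.max() > 17:
            raise GeometryError("segment ids must lie in 1..17")

    def segment_region(self, segment: int) -> str:
        """Region label for an AHA segment: septum, apex or LV free wall."""
        if segment in self.septal_ids:
            return "septum"
        if segment == 17:
            return "apex"
        return "lv_free_wall"

    @property
    def patch_region(self) -> np.ndarray:
        """Region label per triangle."""
        out = np.full(len(self.patch_segment), "lv_free_wall", dtype=object)
        out[np.isin(self.patch_segment, list(self.septal_ids))] = "septum"
        out[self.patch_segment == 17] = "apex"
        return out

    def triangles_in(self, segment: int) -> np.ndarray:
        return np.flatnonzero(self.patch_segment == segment)


@dataclass
class SegmentGeometry:
    """Per-segment shape quantities driving the Laplace stress surrogate.

    Arrays are (n_segments, n_frames); ``segments`` gives the row order.
    ``r_effective`` combines circumferential and longitudinal curvature,
    r_eff = r_c * r_l / (r_c + r_l), and is therefore always below both.
    """

    segments: np.ndarray
    r_circ: np.ndarray
    r_long: np.ndarray
    wall_thickness: np.ndarray
    frame_times: np.ndarray
    sphere_fallback: np.ndarray = field(default=None)  # bool per segment

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=np.intp)
        for name in ("r_circ", "r_long", "wall_thickness"):
            arr = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            setattr(self, name, arr)
            if np.any(arr <= 0):
                raise GeometryError(f"{name} must be positive")
        if self.sphere_fallback is None:
            self.sphere_fallback = np.zeros(len(self.segments), dtype=bool)

    @property
    def r_effective(self) -> np.ndarray:
        return effective_radius(self.r_circ, self.r_long)

    def row(self, segment: int) -> int:
        idx = np.flatnonzero(self.segments == segment)
        if len(idx) == 0:
            raise GeometryError(f"segment {segment} missing from geometry table")
        return int(idx[0])


# ---------------------------------------------------------------------------
# AHA parcellation
# ---------------------------------------------------------------------------

_RING6 = {0: 0, 1: 1, 2: 2, 3: 3, 4: 4, 5: 5}  # sector index -> offset


def assign_aha_segments(
    surface: EndocardialSurface,
    anterior_reference: np.ndarray | None = None,
) -> SegmentMap:
    """Assign each triangle to an AHA segment (1-17).

    Longitudinal bands are defined by the fractional position of the
    triangle centroid measured from the base towards the apex: basal
    [0, 1/3), mid [1/3, 2/3), apical [2/3, 0.95), apex cap >= 0.95.
    Circumferential sectors start at ``anterior_reference`` (projected
    orthogonal to the long axis; default +x, or +y if the axis is x-like)
    and advance anterior -> anteroseptal -> inferoseptal -> ... so the
    septum sits a quarter turn from the anterior direction.
    """
    axis = surface.long_axis
    if anterior_reference is None:
        anterior_reference = np.array([1.0, 0.0, 0.0])
        if abs(float(np.dot(anterior_reference, axis))) > 0.9:
            anterior_reference = np.array([0.0, 1.0, 0.0])
    n1 = np.asarray(anterior_reference, dtype=float)
    n1 = n1 - np.dot(n1, axis) * axis
    nrm = np.linalg.norm(n1)
    if nrm < 1e-9:
        raise GeometryError("anterior reference is parallel to the long axis")
    n1 /= nrm
    n2 = np.cross(axis, n1)

    cent = surface.triangle_centroids(0)
    rel = cent - surface.apex_point
    t_apex = rel @ axis / surface.axis_length  # 0 at apex, 1 at base
    frac_from_base = 1.0 - t_apex
    alpha = np.degrees(np.arctan2(rel @ n2, rel @ n1))  # CCW from anterior

    seg = np.empty(len(cent), dtype=np.intp)
    cap = frac_from_base >= APEX_CAP_FRACTION
    seg[cap] = 17
    sector6 = (np.floor(((alpha + 30.0) % 360.0) / 60.0)).astype(np.intp)
    sector4 = (np.floor(((alpha + 45.0) % 360.0) / 90.0)).astype(np.intp)
    basal = (~cap) & (frac_from_base < 1.0 / 3.0)
    mid = (~cap) & (frac_from_base >= 1.0 / 3.0) & (frac_from_base < 2.0 / 3.0)
    apical = (~cap) & (frac_from_base >= 2.0 / 3.0)
    seg[basal] = 1 + sector6[basal]
    seg[mid] = 7 + sector6[mid]
    seg[apical] = 13 + sector4[apical]
    return SegmentMap(patch_segment=seg)


# ---------------------------------------------------------------------------
# Areas and volume
# ---------------------------------------------------------------------------


def patch_areas(surface: EndocardialSurface, frame: int) -> np.ndarray:
    """Area of each triangle (mm^2) at ``frame``; half cross-product norm.

    Degenerate triangles yield area 0 (kept, with a warning) so patch
    indexing stays stable across frames.
    """
    v = surface.vertices[frame]
    p0, p1, p2 = (v[surface.triangles[:, i]] for i in range(3))
    areas = 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)
    if np.any(areas == 0.0):
        logger.warning("%d degenerate zero-area triangle(s) at frame %d",
                       int(np.sum(areas == 0.0)), frame)
    return areas


def cavity_volume(surface: EndocardialSurface, frame: int) -> float:
    """Cavity volume in mL enclosed by the surface (plus planar basal cap).

    A closed surface is integrated directly with signed tetrahedra; an open
    surface must have exactly one boundary loop (the base), which is closed
    by a triangle fan to the loop centroid before integration.
    """
    loops = surface.boundary_loops()
    if len(loops) > 1:
        raise GeometryError(f"surface has {len(loops)} boundary loops; expected the basal loop only")
    v = surface.vertices[frame]
    tris = [surface.triangles]
    extra_pts = []
    if len(loops) == 1:
        # cap with a fan oriented consistently with the shell: each directed
        # boundary edge (a, b) of the shell is traversed reversed in the cap
        directed = np.concatenate(
            [surface.triangles[:, [0, 1]], surface.triangles[:, [1, 2]], surface.triangles[:, [2, 0]]]
        )
        und = np.sort(directed, axis=1)
        uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
        bedges = directed[counts[inv] == 1]
        cidx = len(v)
        cpt = v[np.unique(bedges)].mean(axis=0)
        fan = np.column_stack(
            [bedges[:, 1], bedges[:, 0], np.full(len(bedges), cidx, dtype=np.intp)]
        )
        tris.append(fan)
        extra_pts.append(cpt)
    allv = np.vstack([v] + extra_pts) if extra_pts else v
    alltri = np.vstack(tris)
    p0, p1, p2 = (allv[alltri[:, i]] for i in range(3))
    signed = np.einsum("ij,ij->i", p0, np.cross(p1, p2)) / 6.0
    return abs(float(signed.sum())) / 1000.0  # mm^3 -> mL


# ---------------------------------------------------------------------------
# Segmental radii and thickness
# ---------------------------------------------------------------------------


def fit_segment_radii(
    points: np.ndarray,
    long_axis: np.ndarray,
    axis_origin: np.ndarray,
) -> tuple[float, float, bool]:
    """Fit an axisymmetric ellipsoid to one segment's endocardial points.

    The ellipsoid is centred on the long axis (rho/a)^2 + ((z-z0)/b)^2 = 1,
    which linearises to rho^2 = c0 + c1 z + c2 z^2 and is solved by ordinary
    least squares. Returns (r_circ, r_long, sphere_fallback_used), where
    r_circ = a and r_long is the meridional radius of curvature
    (a^2 cos^2 th + b^2 sin^2 th)^{3/2} / (a b) at the points' mean polar
    angle th (b^2/a at the equator). Rank-deficient or non-elliptic fits
    fall back to a sphere centred on the axis (r_circ = r_long).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 9:
        raise GeometryError("need at least 9 points for a segment radius fit")
    axis = np.asarray(long_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rel = pts - np.asarray(axis_origin, dtype=float)
    z = rel @ axis
    rho2 = np.einsum("ij,ij->i", rel, rel) - z**2
    rho2 = np.maximum(rho2, 0.0)

    X = np.stack([np.ones_like(z), z, z * z], axis=1)
    fallback = False
    sol = None
    # guard against ill-conditioned quadratic term (e.g. equatorial bands)
    if np.ptp(z) > 1e-9:
        c, _, rank, _ = np.linalg.lstsq(X, rho2, rcond=None)
        if rank == 3 and c[2] < -1e-12:
            a2 = c[0] - c[1] ** 2 / (4.0 * c[2])
            b2 = -a2 / c[2]
            if a2 > 0 and b2 > 0:
                z0 = -c[1] / (2.0 * c[2])
                sol = (np.sqrt(a2), np.sqrt(b2), z0)
    if sol is None:
        fallback = True
        logger.info("segment ellipsoid fit rank-deficient; sphere fallback")
        # sphere centred on axis: rho^2 + z^2 = R^2 + 2 z z0 - z0^2
        Xs = np.stack([np.ones_like(z), z], axis=1)
        d, *_ = np.linalg.lstsq(Xs, rho2 + z * z, rcond=None)
        z0 = d[1] / 2.0
        R2 = d[0] + z0 * z0
        if R2 <= 0:
            raise GeometryError("sphere fallback failed: non-positive radius")
        R = float(np.sqrt(R2))
        return R, R, True

    a, b, z0 = sol
    # mean polar angle of the points on the fitted ellipsoid
    sin_th = np.clip(np.sqrt(np.maximum(rho2, 0.0)) / a, 0.0, 1.0)
    cos_th = np.clip((z - z0) / b, -1.0, 1.0)
    th = float(np.mean(np.arctan2(sin_th, cos_th)))
    r_long = (a**2 * np.cos(th) ** 2 + b**2 * np.sin(th) ** 2) ** 1.5 / (a * b)
    return float(a), float(r_long), fallback


def effective_radius(r_circ, r_long):
    """Effective radius r_c * r_l / (r_c + r_l) (mm).

    Harmonic-type mean arising from adding circumferential and longitudinal
    curvatures; tends to r_circ as r_long grows without bound.
    """
    r_circ = np.asarray(r_circ, dtype=float)
    r_long = np.asarray(r_long, dtype=float)
    if np.any(r_circ <= 0) or np.any(r_long <= 0):
        raise GeometryError("radii must be positive")
    out = r_circ * r_long / (r_circ + r_long)
    return float(out) if out.ndim == 0 else out


def segment_wall_thickness(
    table: dict[int, float],
    n_frames: int = 1,
    segment_area_ratio: np.ndarray | None = None,
    segments: tuple[int, ...] = ALL_SEGMENTS,
) -> np.ndarray:
    """Per-segment, per-frame wall thickness (mm) from an input table.

    ``table`` maps segment id -> end-diastolic thickness. With
    ``segment_area_ratio`` (n_segments, n_frames; A_s(t)/A_s(0)) thickness
    varies in time under wall incompressibility, h(t) = h(0) / ratio, so
    area x thickness is conserved per segment.
    """
    h0 = np.empty(len(segments), dtype=float)
    for i, s in enumerate(segments):
        if s not in table:
            raise GeometryError(f"missing wall thickness for segment {s}")
        h0[i] = float(table[s])
    if np.any(h0 <= 0):
        raise GeometryError("wall thickness must be positive")
    h = np.repeat(h0[:, None], n_frames, axis=1)
    if segment_area_ratio is not None:
        ratio = np.asarray(segment_area_ratio, dtype=float)
        if ratio.shape != h.shape:
            raise GeometryError("segment_area_ratio shape mismatch")
        h = h / ratio
    return h


def compute_segment_geometry(
    surface: EndocardialSurface,
    segmap: SegmentMap,
    thickness_table: dict[int, float],
    per_frame: bool = True,
    incompressible_thickness: bool = True,
    segments: tuple[int, ...] = ALL_SEGMENTS,
) -> SegmentGeometry:
    """Fit segmental radii (and thickness) for all frames of a surface.

    ``per_frame=False`` fits the end-diastolic frame only and holds the
    radii constant, matching the static end-diastolic stress surrogate.
    """
    n_frames = surface.n_frames if per_frame else 1
    n_seg = len(segments)
    r_c = np.empty((n_seg, n_frames))
    r_l = np.empty((n_seg, n_frames))
    fb = np.zeros(n_seg, dtype=bool)
    origin = surface.apex_point
    vert_seg = _vertex_segments(surface, segmap)
    for i, s in enumerate(segments):
        vidx = np.flatnonzero(vert_seg == s)
        if len(vidx) == 0:
            raise GeometryError(f"AHA segment {s} has no vertices")
        for f in range(n_frames):
            pts = surface.vertices[f][vidx]
            r_c[i, f], r_l[i, f], used_fb = fit_segment_radii(pts, surface.long_axis, origin)
            fb[i] |= used_fb
    # segment area ratios for incompressible thickness variation
    ratio = None
    if incompressible_thickness and surface.n_frames > 1:
        a0 = patch_areas(surface, 0)
        seg_a = np.empty((n_seg, surface.n_frames))
        for f in range(surface.n_frames):
            a = a0 if f == 0 else patch_areas(surface, f)
            for i, s in enumerate(segments):
                seg_a[i, f] = a[segmap.patch_segment == s].sum()
        ratio = seg_a / seg_a[:, :1]
        if not per_frame:
            ratio = ratio[:, :1]
    h = segment_wall_thickness(
        thickness_table,
        n_frames=n_frames if ratio is None else ratio.shape[1],
        segment_area_ratio=ratio,
        segments=segments,
    )
    times = surface.frame_times if per_frame else surface.frame_times[:1]
    return SegmentGeometry(
        segments=np.asarray(segments),
        r_circ=r_c,
        r_long=r_l,
        wall_thickness=h[:, : r_c.shape[1]] if h.shape[1] != r_c.shape[1] else h,
        frame_times=times,
        sphere_fallback=fb,
    )


def _vertex_segments(surface: EndocardialSurface, segmap: SegmentMap) -> np.ndarray:
    """Assign each vertex the segment of the majority of incident triangles."""
    votes = np.zeros((surface.n_vertices, 18), dtype=np.intp)
    for col in range(3):
        np.add.at(votes, (surface.triangles[:, col], segmap.patch_segment), 1)
    out = votes.argmax(axis=1)
    out[votes.sum(axis=1) == 0] = 0
    return out
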