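"""The eight acromial shape parameters for one shoulder.

All operators work in scapular-frame coordinates (x lateral, y superior,
z anterior).  Distances are mm, angles degrees.  Parameters:

* ``ahi``           acromiohumeral interval (outlet view, y-z projection)
* ``aap`` / ``aip`` anterior / inferior protrusion past the distal clavicle
* ``ac_angle``      angle at the most lateral point of the acromion (MLPA)
                    subtended by the AC joint-line margins in x-y
* ``a`` / ``b``     widths of the anterolateral protrusion (AALP) to the MLPA
* ``c``, ``c+d``    antero-posterior extents of the AALP and whole acromion
* ``ratio``         100 * c / (c + d)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .errors import DegenerateGeometryError
from .geometry import Plane, TriangleMesh, contour_curvature, contour_outward_normals, slice_mesh
from .model import ShoulderModel
from .scapular_frame import ScapularFrame, build_frame, normalize_side

PARAMETERS = ("ahi_mm", "aap_mm", "aip_mm", "ac_angle_deg",
              "a_mm", "b_mm", "c_mm", "ratio_percent")
"""Column order of the eight reported parameters."""


@dataclass
class AALPRegion:
    """Detected anterolateral protrusion.

    ``medial_border``: (n, 3) crease points in frame coordinates, ordered by
    y (one per axial slice).  ``member_points``: (m, 3) anterior-half surface
    points lateral/anterior of the border (border points included).
    """

    medial_border: np.ndarray
    member_points: np.ndarray
    slice_count: int
    empty: bool = False

    @classmethod
    def none(cls) -> "AALPRegion":
        z = np.zeros((0, 3))
        return cls(z, z, 0, empty=True)


@dataclass
class MeasurementSet:
    """The eight parameters for one shoulder (AALP entries absent => None)."""

    ahi_mm: float
    aap_mm: float
    aip_mm: float
    ac_angle_deg: float
    a_mm: float | None
    b_mm: float | None
    c_mm: float | None
    c_plus_d_mm: float
    ratio_percent: float | None
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("ahi_mm", "aap_mm", "aip_mm", "a_mm", "b_mm", "c_mm", "c_plus_d_mm"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.c_mm is not None:
            if self.c_mm > self.c_plus_d_mm + 1e-9:
                raise ValueError("c cannot exceed c + d")
            if not (0.0 < self.ratio_percent < 100.0):
                raise ValueError("ratio_percent must lie strictly in (0, 100)")

    def as_dict(self) -> dict:
        out = {name: getattr(self, name) for name in PARAMETERS}
        out["c_plus_d_mm"] = self.c_plus_d_mm
        out["flags"] = dict(self.flags)
        return out


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _frame_vertices(mesh: TriangleMesh, frame: ScapularFrame) -> np.ndarray:
    return frame.to_local(mesh.vertices)


def _frame_mesh(mesh: TriangleMesh, frame: ScapularFrame) -> TriangleMesh:
    return TriangleMesh(_frame_vertices(mesh, frame), mesh.faces, dict(mesh.labels))


def _extreme_vertex(coords: np.ndarray, axis: int, sign: float, tie_tol: float) -> int:
    """Index of the extreme vertex along *axis* with deterministic tie-breaks.

    Vertices within *tie_tol* of the extremum are tied; ties resolve to the
    smallest remaining coordinates in axis order (excluding *axis*).
    """
    key = sign * coords[:, axis]
    best = key.max()
    cand = np.flatnonzero(key >= best - tie_tol)
    others = [ax for ax in range(3) if ax != axis]
    # lexsort: last key is primary
    order = np.lexsort((coords[cand, others[1]], coords[cand, others[0]]))
    return int(cand[order[0]])


def _tls_line_2d(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through 2D points -> (point, unit direction)."""
    if len(points) < 2:
        raise DegenerateGeometryError("line fit needs at least 2 points")
    centroid = points.mean(axis=0)
    _, s, vt = np.linalg.svd(points - centroid, full_matrices=False)
    if s[0] < 1e-12:
        raise DegenerateGeometryError("line fit points are coincident")
    return centroid, vt[0]


def _bin_extremes(pts: np.ndarray, bin_mm: float, maximise: bool) -> np.ndarray:
    """Per-x-bin extreme points of (x, value) pairs.

    x is quantised to 1e-6 mm first so vertices sitting exactly on a bin
    boundary land in the same bin regardless of rigid-motion round-off.
    """
    x, v = pts[:, 0], pts[:, 1]
    x = np.round(x / 1e-6) * 1e-6
    bins = np.floor(x / bin_mm).astype(np.int64)
    out = []
    for b in np.unique(bins):
        sel = bins == b
        idx = np.argmax(v[sel]) if maximise else np.argmin(v[sel])
        out.append(pts[sel][idx])
    return np.asarray(out)


def _clavicle_distal_mask(model: ShoulderModel, frame: ScapularFrame) -> np.ndarray:
    """Distal-quarter mask: explicit label if present, else the quarter of the
    clavicle's principal-axis extent nearest the acromion centroid."""
    clav = model.clavicle_mesh
    if "distal_quarter" in clav.labels:
        return clav.label_mask("distal_quarter")
    cv = _frame_vertices(clav, frame)
    centroid = cv.mean(axis=0)
    _, _, vt = np.linalg.svd(cv - centroid, full_matrices=False)
    axis = vt[0]
    acr_centroid = _frame_vertices(model.acromion(), frame).mean(axis=0)
    if (acr_centroid - centroid) @ axis < 0:
        axis = -axis
    proj = (cv - centroid) @ axis
    return proj >= proj.min() + 0.75 * (proj.max() - proj.min())


def _line_offset_distance(points_line: np.ndarray, point: np.ndarray,
                          positive_toward: np.ndarray) -> float:
    """Signed perpendicular distance from *point* to the TLS line through
    *points_line*; positive on the side of *positive_toward*."""
    origin, direction = _tls_line_2d(points_line)
    normal = np.array([-direction[1], direction[0]])
    if normal @ positive_toward < 0:
        normal = -normal
    if abs(normal @ positive_toward) < 1e-9:
        raise DegenerateGeometryError("reference line is parallel to the protrusion axis")
    return float((point - origin) @ normal)


# ---------------------------------------------------------------------------
# individual operators
# ---------------------------------------------------------------------------

def find_MLPA(model: ShoulderModel, frame: ScapularFrame,
              config: RunConfig | None = None) -> np.ndarray:
    """Most lateral acromion vertex, in frame coordinates.

    Ties within the tie tolerance resolve to the smallest y, then smallest z.
    """
    config = config or RunConfig()
    acr = model.acromion()
    coords = _frame_vertices(acr, frame)
    idx = _extreme_vertex(coords, axis=0, sign=1.0, tie_tol=config.tie_tolerance)
    return coords[idx]


def measure_AHI(model: ShoulderModel, frame: ScapularFrame,
                config: RunConfig | None = None) -> tuple[float, dict]:
    """Acromiohumeral interval: outlet-view (y-z) distance from the most
    superior humeral vertex to the acromion undersurface vertex set."""
    config = config or RunConfig()
    hum = _frame_vertices(model.humerus_mesh, frame)
    h_idx = _extreme_vertex(hum, axis=1, sign=1.0, tie_tol=config.tie_tolerance)
    h = hum[h_idx]
    acr_frame = _frame_mesh(model.acromion(), frame)
    normals = acr_frame.vertex_normals()
    under = acr_frame.vertices[normals[:, 1] < config.undersurface_normal_y]
    flags = {}
    if len(under) == 0:
        raise DegenerateGeometryError("no acromial undersurface vertices found")
    if not (under[:, 2].min() <= h[2] <= under[:, 2].max()):
        flags["no_overhang"] = True
    d = np.hypot(under[:, 1] - h[1], under[:, 2] - h[2])
    return float(d.min()), flags


def measure_AAP(model: ShoulderModel, frame: ScapularFrame,
                config: RunConfig | None = None) -> tuple[float, dict]:
    """Anterior protrusion: x-z distance from the most anterior acromion
    point to the line along the anterior aspect of the distal clavicle.
    Negative (acromion behind the line) clamps to 0 with a flag."""
    config = config or RunConfig()
    mask = _clavicle_distal_mask(model, frame)
    clav = _frame_vertices(model.clavicle_mesh, frame)[mask]
    if len(clav) == 0:
        raise DegenerateGeometryError("distal clavicle selects no vertices")
    edge = _bin_extremes(clav[:, (0, 2)], config.clavicle_bin_mm, maximise=True)
    acr = _frame_vertices(model.acromion(), frame)
    p_idx = _extreme_vertex(acr, axis=2, sign=1.0, tie_tol=config.tie_tolerance)
    p = acr[p_idx][(0, 2),]
    value = _line_offset_distance(edge, p, positive_toward=np.array([0.0, 1.0]))
    flags = {}
    if value < 0:
        flags["aap_clamped"] = True
        value = 0.0
    return float(value), flags


def measure_AIP(model: ShoulderModel, frame: ScapularFrame,
                anterior_half: TriangleMesh, config: RunConfig | None = None
                ) -> tuple[float, dict]:
    """Inferior protrusion: x-y distance from the most inferior vertex of the
    anterior acromion to the line along the inferior aspect of the distal
    clavicle; positive below the line, clamped at 0 with a flag."""
    config = config or RunConfig()
    mask = _clavicle_distal_mask(model, frame)
    clav = _frame_vertices(model.clavicle_mesh, frame)[mask]
    if len(clav) == 0:
        raise DegenerateGeometryError("distal clavicle selects no vertices")
    edge = _bin_extremes(clav[:, (0, 1)], config.clavicle_bin_mm, maximise=False)
    ant = anterior_half.vertices  # anterior half is already in frame coordinates
    p_idx = _extreme_vertex(ant, axis=1, sign=-1.0, tie_tol=config.tie_tolerance)
    p = ant[p_idx][(0, 1),]
    value = _line_offset_distance(edge, p, positive_toward=np.array([0.0, -1.0]))
    flags = {}
    if value < 0:
        flags["aip_clamped"] = True
        value = 0.0
    return float(value), flags


def measure_AC_angle(model: ShoulderModel, frame: ScapularFrame,
                     mlpa: np.ndarray) -> float:
    """Angle (degrees) at the MLPA between the rays to the anterior and
    posterior AC joint-line margins, all projected to the x-y plane."""
    am = frame.to_local(model.landmarks.AM)[0, :2]
    pm = frame.to_local(model.landmarks.PM)[0, :2]
    apex = np.asarray(mlpa, dtype=float)[:2]
    v1, v2 = am - apex, pm - apex
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise DegenerateGeometryError("AC margin coincides with the MLPA in projection")
    angle = math.degrees(math.acos(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)))
    if not (0.0 < angle < 180.0):
        raise DegenerateGeometryError("AC angle is degenerate (0 or 180 degrees)")
    return angle


def split_acromion(model: ShoulderModel, frame: ScapularFrame,
                   mlpa: np.ndarray) -> tuple[TriangleMesh, TriangleMesh]:
    """Partition the acromion at the axial plane z = z(MLPA).

    Vertices with z >= z(MLPA) (boundary inclusive) form the anterior half.
    Faces straddling the cut belong to neither sub-mesh; vertex counts of the
    halves always sum to the acromion total.
    """
    acr = _frame_mesh(model.acromion(), frame)
    z_cut = float(np.asarray(mlpa)[2])
    mask = acr.vertices[:, 2] >= z_cut
    if not mask.any() or mask.sum() < 4:
        raise DegenerateGeometryError("anterior half of the acromion is empty")
    anterior = acr.submesh(mask)
    posterior = acr.submesh(~mask) if (~mask).sum() >= 4 else None
    return anterior, posterior


def localize_AALP(model: ShoulderModel, frame: ScapularFrame,
                  anterior_half: TriangleMesh,
                  config: RunConfig | None = None) -> AALPRegion:
    """Detect the anterolateral protrusion from axial slice curvature.

    The acromion is sliced with planes normal to y at ``slice_step``.  On
    each closed slice contour the candidate arc is the "inner edge": points
    anterior of the MLPA whose outward normal has a negative x component.
    The crease is the point of greatest concave curvature (the sharpest
    inward fold of the medial contour); it is kept when its magnitude
    exceeds ``curvature_min``.  Crease points across slices form the medial
    border; fewer than ``min_slices`` marked slices means no distinct
    protrusion.
    """
    config = config or RunConfig()
    acr = _frame_mesh(model.acromion(), frame)
    # anterior_half is already in frame coordinates (from split_acromion)
    ant_v = anterior_half.vertices
    z_cut = float(ant_v[:, 2].min())
    y_lo, y_hi = float(ant_v[:, 1].min()), float(ant_v[:, 1].max())
    border = []
    ys = np.arange(y_lo + config.slice_step / 2.0, y_hi, config.slice_step)
    for y in ys:
        plane = Plane(np.array([0.0, y, 0.0]), np.array([0.0, 1.0, 0.0]))
        best = None
        for contour in slice_mesh(acr, plane, config.min_contour_perimeter):
            if not contour.closed:
                continue
            try:
                prof = contour_curvature(contour, config.resample_step,
                                         config.smooth_window)
            except DegenerateGeometryError:
                continue
            pts3 = prof.contour.points3d()
            normals2d = contour_outward_normals(prof.contour.points2d,
                                                prof.contour.closed)
            u, v = plane.basis()
            normals3 = np.outer(normals2d[:, 0], u) + np.outer(normals2d[:, 1], v)
            candidate = (
                (pts3[:, 2] >= z_cut + config.anterior_margin)
                & (normals3[:, 0] < config.inner_edge_normal_x)
                & (prof.curvature <= -config.curvature_min)
            )
            if not candidate.any():
                continue
            kappa = np.where(candidate, prof.curvature, np.inf)
            i = int(np.argmin(kappa))  # most concave; first index wins ties
            point = _refine_peak(pts3, prof.curvature, i, prof.contour.closed)
            if best is None or prof.curvature[i] < best[0]:
                best = (prof.curvature[i], point)
        if best is not None:
            border.append(best[1])
    if len(border) < config.min_slices:
        return AALPRegion.none()
    border = np.asarray(border)
    border = border[np.argsort(border[:, 1])]
    xb = np.interp(ant_v[:, 1], border[:, 1], border[:, 0])
    zb = np.interp(ant_v[:, 1], border[:, 1], border[:, 2])
    member_mask = (ant_v[:, 2] >= zb - 1e-6) & (ant_v[:, 0] >= xb - 1e-6)
    members = np.vstack([ant_v[member_mask], border])
    return AALPRegion(medial_border=border, member_points=members,
                      slice_count=len(border))


def _refine_peak(pts3: np.ndarray, kappa: np.ndarray, i: int, closed: bool) -> np.ndarray:
    """Parabolic sub-sample refinement of a curvature extremum position."""
    n = len(pts3)
    if closed:
        im, ip = (i - 1) % n, (i + 1) % n
    else:
        if i == 0 or i == n - 1:
            return pts3[i]
        im, ip = i - 1, i + 1
    k0, k1, k2 = kappa[im], kappa[i], kappa[ip]
    denom = k0 - 2.0 * k1 + k2
    if abs(denom) < 1e-12:
        return pts3[i]
    delta = 0.5 * (k0 - k2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    if delta >= 0:
        return pts3[i] + delta * (pts3[ip] - pts3[i])
    return pts3[i] - delta * (pts3[im] - pts3[i])


def measure_AALP_params(region: AALPRegion, acromion: TriangleMesh,
                        mlpa: np.ndarray, frame: ScapularFrame | None = None,
                        config: RunConfig | None = None) -> dict:
    """AALP widths and antero-posterior extents.

    In the x-z projection: ``a`` is the distance from the most medial border
    point to the MLPA and ``b`` the distance from the most posteromedial
    border point (minimal x within the posterior ``posteromedial_fraction``
    of the border's z range).  In the y-z projection: ``c`` is the z extent
    of the region's member points and ``c_plus_d`` that of the whole
    acromion.  *acromion* must be in frame coordinates.
    """
    config = config or RunConfig()
    z_all = acromion.vertices[:, 2]
    c_plus_d = float(z_all.max() - z_all.min())
    if region.empty:
        return {"a_mm": None, "b_mm": None, "c_mm": None,
                "c_plus_d_mm": c_plus_d, "ratio_percent": None}
    mlpa_xz = np.asarray(mlpa, dtype=float)[(0, 2),]
    bxz = region.medial_border[:, (0, 2)]
    a_pt = bxz[int(np.argmin(bxz[:, 0]))]
    a_mm = float(np.linalg.norm(a_pt - mlpa_xz))
    z_lo, z_hi = bxz[:, 1].min(), bxz[:, 1].max()
    band = bxz[:, 1] <= z_lo + config.posteromedial_fraction * (z_hi - z_lo) + 1e-9
    band_pts = bxz[band]
    b_pt = band_pts[int(np.argmin(band_pts[:, 0]))]
    b_mm = float(np.linalg.norm(b_pt - mlpa_xz))
    zm = region.member_points[:, 2]
    c_mm = float(zm.max() - zm.min())
    ratio = 100.0 * c_mm / c_plus_d
    return {"a_mm": a_mm, "b_mm": b_mm, "c_mm": c_mm,
            "c_plus_d_mm": c_plus_d, "ratio_percent": ratio}


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def measure_all(model: ShoulderModel, config: RunConfig | None = None
                ) -> MeasurementSet:
    """Run the full measurement pipeline on one shoulder.

    Steps: side normalisation, scapular frame construction, then every
    parameter operator.  Flags raised along the way are collected in
    ``MeasurementSet.flags`` together with the mirrored-provenance marker.
    """
    config = config or RunConfig()
    model = normalize_side(model)
    frame = build_frame(model.landmarks)
    flags: dict = {}
    if model.provenance.get("mirrored"):
        flags["mirrored"] = True

    mlpa = find_MLPA(model, frame, config)
    ahi, f = measure_AHI(model, frame, config)
    flags.update(f)
    aap, f = measure_AAP(model, frame, config)
    flags.update(f)
    anterior, _posterior = split_acromion(model, frame, mlpa)
    aip, f = measure_AIP(model, frame, anterior, config)
    flags.update(f)
    ac_angle = measure_AC_angle(model, frame, mlpa)
    region = localize_AALP(model, frame, anterior, config)
    if region.empty:
        flags["no_distinct_protrusion"] = True
    acr_frame = _frame_mesh(model.acromion(), frame)
    aalp = measure_AALP_params(region, acr_frame, mlpa, frame, config)

    return MeasurementSet(
        ahi_mm=ahi, aap_mm=aap, aip_mm=aip, ac_angle_deg=ac_angle,
        a_mm=aalp["a_mm"], b_mm=aalp["b_mm"], c_mm=aalp["c_mm"],
        c_plus_d_mm=aalp["c_plus_d_mm"], ratio_percent=aalp["ratio_percent"],
        flags=flags,
    )
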