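"""Generic 3D/2D geometric primitives used by every downstream stage.

Conventions
-----------
* All coordinates are millimetres, float64.
* Planes are (point, unit normal); their 2D basis (u, v) is deterministic and
  satisfies ``u x v = normal``.
* Closed planar contours are stored counterclockwise in the plane basis;
  signed curvature is positive where the contour is convex with respect to
  that orientation (a CCW circle has curvature +1/r).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError

_EPS = 1e-12


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (n, 3) points, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite components")
    return pts


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < _EPS:
        raise DegenerateGeometryError("cannot normalise a zero-length vector")
    return v / n


# ---------------------------------------------------------------------------
# planes and frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Plane:
    """A plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", unit(self.normal))

    @property
    def offset(self) -> float:
        """Signed offset d in n.x = d."""
        return float(self.normal @ self.point)

    def signed_distance(self, points) -> np.ndarray:
        pts = _as_points(points)
        return (pts - self.point) @ self.normal

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic in-plane basis (u, v) with u x v = normal."""
        n = self.normal
        helper = np.zeros(3)
        helper[int(np.argmin(np.abs(n)))] = 1.0
        u = unit(np.cross(helper, n))
        v = np.cross(n, u)
        return u, v

    def to_2d(self, points) -> np.ndarray:
        u, v = self.basis()
        rel = _as_points(points) - self.point
        return np.column_stack([rel @ u, rel @ v])

    def to_3d(self, points2d) -> np.ndarray:
        u, v = self.basis()
        q = np.asarray(points2d, dtype=float)
        return self.point + np.outer(q[:, 0], u) + np.outer(q[:, 1], v)


@dataclass(frozen=True)
class OrthonormalFrame:
    """Right-handed orthonormal frame: origin plus axis rows (x, y, z)."""

    origin: np.ndarray
    axes: np.ndarray  # (3, 3), rows are the x, y, z axes

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float)
        axes = np.asarray(self.axes, dtype=float)
        if axes.shape != (3, 3):
            raise ValueError("axes must be a 3x3 matrix of row vectors")
        gram = axes @ axes.T
        if not np.allclose(gram, np.eye(3), atol=1e-9):
            raise ValueError("frame axes are not orthonormal within 1e-9")
        if np.linalg.det(axes) < 0:
            raise ValueError("frame is not right-handed")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)

    @classmethod
    def identity(cls) -> "OrthonormalFrame":
        return cls(np.zeros(3), np.eye(3))

    @property
    def x_axis(self) -> np.ndarray:
        return self.axes[0]

    @property
    def y_axis(self) -> np.ndarray:
        return self.axes[1]

    @property
    def z_axis(self) -> np.ndarray:
        return self.axes[2]

    def to_local(self, points) -> np.ndarray:
        return (_as_points(points) - self.origin) @ self.axes.T

    def to_world(self, points) -> np.ndarray:
        return _as_points(points) @ self.axes + self.origin


_PLANE_AXES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}


def _normalise_plane_name(name: str) -> tuple[int, int]:
    key = "".join(c for c in name.lower() if c in "xyz")
    if key not in _PLANE_AXES:
        raise ValueError(f"unknown projection plane {name!r}; use x-y, x-z or y-z")
    return _PLANE_AXES[key]


def project_to_plane(entity, frame: OrthonormalFrame, plane_name: str) -> np.ndarray:
    """Express *entity* in *frame* and keep the named coordinate pair.

    The first named axis becomes the abscissa.  Accepts a single point, an
    (n, 3) array, a polyline, or a :class:`TriangleMesh` (its vertices).
    """
    i, j = _normalise_plane_name(plane_name)
    if isinstance(entity, TriangleMesh):
        pts = entity.vertices
    else:
        pts = np.asarray(entity, dtype=float)
    single = pts.ndim == 1
    local = frame.to_local(pts)
    out = local[:, (i, j)]
    return out[0] if single else out


# ---------------------------------------------------------------------------
# triangle meshes
# ---------------------------------------------------------------------------

class TriangleMesh:
    """A triangle surface mesh with optional boolean per-vertex labels.

    Degenerate (zero-area) faces are dropped on construction; face indices
    are validated.  Vertex labels are name -> boolean mask over vertices.
    """

    def __init__(self, vertices, faces, labels: dict[str, np.ndarray] | None = None):
        self.vertices = _as_points(vertices)
        faces = np.asarray(faces, dtype=np.int64)
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3) vertex index triplets")
        if self.vertices.shape[0] < 4:
            raise ValueError("mesh must have at least 4 vertices")
        if faces.size and (faces.min() < 0 or faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        # drop degenerate faces (repeated indices or ~zero area)
        if faces.size:
            tri = self.vertices[faces]
            areas = 0.5 * np.linalg.norm(
                np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
            )
            distinct = (
                (faces[:, 0] != faces[:, 1])
                & (faces[:, 1] != faces[:, 2])
                & (faces[:, 0] != faces[:, 2])
            )
            faces = faces[distinct & (areas > 1e-10)]
        self.faces = faces
        self.labels: dict[str, np.ndarray] = {}
        for name, mask in (labels or {}).items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (len(self.vertices),):
                raise ValueError(f"label {name!r} has wrong length")
            self.labels[name] = mask

    # -- basic quantities ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array: row 0 = min corner, row 1 = max corner."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def face_normals(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norms = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.maximum(norms, _EPS)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals."""
        tri = self.vertices[self.faces]
        fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # area-weighted
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norms = np.linalg.norm(vn, axis=1, keepdims=True)
        return vn / np.maximum(norms, _EPS)

    def volume(self) -> float:
        """Signed volume (positive for outward-oriented closed meshes)."""
        tri = self.vertices[self.faces]
        return float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0)

    # -- derived meshes -----------------------------------------------------

    def label_mask(self, name: str) -> np.ndarray:
        if name not in self.labels:
            raise KeyError(f"mesh has no label {name!r}")
        return self.labels[name]

    def submesh(self, vertex_mask) -> "TriangleMesh":
        """Sub-mesh of the masked vertices and faces fully inside the mask."""
        vertex_mask = np.asarray(vertex_mask, dtype=bool)
        idx = np.flatnonzero(vertex_mask)
        if idx.size < 4:
            raise ValueError("sub-mesh would have fewer than 4 vertices")
        remap = -np.ones(len(self.vertices), dtype=np.int64)
        remap[idx] = np.arange(idx.size)
        keep = vertex_mask[self.faces].all(axis=1)
        labels = {k: v[idx] for k, v in self.labels.items()}
        return TriangleMesh(self.vertices[idx], remap[self.faces[keep]], labels)

    def transformed(self, rotation, translation) -> "TriangleMesh":
        rotation = _check_rotation(rotation)
        t = np.asarray(translation, dtype=float)
        return TriangleMesh(self.vertices @ rotation.T + t, self.faces, dict(self.labels))

    def mirrored(self, plane: Plane) -> "TriangleMesh":
        """Reflect across *plane*; face winding is flipped to keep normals outward."""
        n = plane.normal
        d = (self.vertices - plane.point) @ n
        verts = self.vertices - 2.0 * d[:, None] * n
        return TriangleMesh(verts, self.faces[:, ::-1], dict(self.labels))

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(),
                            {k: v.copy() for k, v in self.labels.items()})


def _check_rotation(rotation) -> np.ndarray:
    r = np.asarray(rotation, dtype=float)
    if r.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(r @ r.T, np.eye(3), atol=1e-8) or np.linalg.det(r) < 0:
        raise ValueError("rotation must be proper orthonormal (tolerance 1e-8)")
    return r


def rigid_transform(obj, rotation, translation):
    """Apply a proper rigid motion to points, a mesh, or any object exposing
    ``transformed(rotation, translation)``."""
    rotation = _check_rotation(rotation)
    t = np.asarray(translation, dtype=float)
    if hasattr(obj, "transformed"):
        return obj.transformed(rotation, t)
    pts = np.asarray(obj, dtype=float)
    return pts @ rotation.T + t


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_plane_lsq(points) -> Plane:
    """Total-least-squares plane through >= 3 non-collinear points."""
    pts = _as_points(points)
    if len(pts) < 3:
        raise DegenerateGeometryError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    scale = max(s[0], _EPS)
    if s[1] / scale < 1e-9:
        raise DegenerateGeometryError("points are collinear or coincident")
    return Plane(centroid, vt[2])


@dataclass(frozen=True)
class CircleFit:
    center: np.ndarray
    radius: float
    plane: Plane
    small_radius: bool = False  # warning flag: radius below configured minimum


def _kasa_circle(q: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kasa) circle fit in 2D."""
    a = np.column_stack([2.0 * q, np.ones(len(q))])
    b = (q ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:2]
    radius = float(np.sqrt(max(sol[2] + center @ center, 0.0)))
    return center, radius


def _gauss_newton_circle(q: np.ndarray, center: np.ndarray, radius: float):
    """One geometric Gauss-Newton refinement step of (cx, cy, r)."""
    rel = q - center
    dist = np.linalg.norm(rel, axis=1)
    dist = np.maximum(dist, _EPS)
    jac = np.column_stack([-rel[:, 0] / dist, -rel[:, 1] / dist, -np.ones(len(q))])
    res = dist - radius
    try:
        step, *_ = np.linalg.lstsq(jac, -res, rcond=None)
    except np.linalg.LinAlgError:  # pragma: no cover - extremely degenerate
        return center, radius
    return center + step[:2], radius + float(step[2])


def fit_circle_in_plane(points, min_radius: float = 1.0) -> CircleFit:
    """Least-squares circle through >= 3 points: TLS plane, then an in-plane
    Kasa fit refined by one Gauss-Newton step; the centre is lifted back to 3D.
    """
    pts = _as_points(points)
    if len(pts) < 3:
        raise DegenerateGeometryError("circle fit needs at least 3 points")
    plane = fit_plane_lsq(pts)  # raises on collinear input
    q = plane.to_2d(pts)
    center2d, radius = _kasa_circle(q)
    center2d, radius = _gauss_newton_circle(q, center2d, radius)
    center = plane.to_3d(center2d[None, :])[0]
    return CircleFit(center, float(radius), plane, small_radius=radius < min_radius)


# ---------------------------------------------------------------------------
# planar contours
# ---------------------------------------------------------------------------

@dataclass
class PlanarContour:
    """An ordered polyline/polygon in a named plane.

    ``points2d`` are coordinates in ``plane.basis()``; for closed contours the
    first point is not repeated at the end (the joint is topological).
    """

    points2d: np.ndarray
    plane: Plane
    closed: bool = False

    def __post_init__(self):
        pts = np.asarray(self.points2d, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points2d must be (n, 2)")
        self.points2d = pts

    def __len__(self) -> int:
        return len(self.points2d)

    def points3d(self) -> np.ndarray:
        return self.plane.to_3d(self.points2d)

    @property
    def perimeter(self) -> float:
        pts = self.points2d
        seg = np.diff(pts, axis=0)
        total = float(np.linalg.norm(seg, axis=1).sum())
        if self.closed and len(pts) > 1:
            total += float(np.linalg.norm(pts[0] - pts[-1]))
        return total

    @property
    def signed_area(self) -> float:
        if not self.closed:
            return 0.0
        x, y = self.points2d[:, 0], self.points2d[:, 1]
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def reversed(self) -> "PlanarContour":
        return PlanarContour(self.points2d[::-1].copy(), self.plane, self.closed)

    def resample(self, step: float) -> "PlanarContour":
        """Arc-length resampling at uniform *step*."""
        pts = self.points2d
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        if total < _EPS:
            raise DegenerateGeometryError("contour has zero length")
        if self.closed:
            n = max(int(round(total / step)), 3)
            targets = np.linspace(0.0, total, n, endpoint=False)
        else:
            n = max(int(np.floor(total / step)) + 1, 2)
            targets = np.linspace(0.0, total, n)
        out = np.column_stack([
            np.interp(targets, s, pts[:, 0]),
            np.interp(targets, s, pts[:, 1]),
        ])
        return PlanarContour(out, self.plane, self.closed)


# ---------------------------------------------------------------------------
# mesh slicing
# ---------------------------------------------------------------------------

_NEIGHBOUR_OFFSETS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)])


def _chain_segments(segments: list[tuple[np.ndarray, np.ndarray]], tol: float = 1e-6):
    """Chain unordered 3D segments into polylines; returns (points, closed) pairs.

    Endpoints are matched within *tol* using a hash grid; neighbouring cells
    are searched so coincident points straddling a cell boundary still join.
    """

    def key(p):
        return tuple(np.round(p / tol).astype(np.int64))

    adjacency: dict[tuple, list[int]] = {}
    for i, (a, b) in enumerate(segments):
        adjacency.setdefault(key(a), []).append(i)
        adjacency.setdefault(key(b), []).append(i)

    def matches(p, q) -> bool:
        return float(np.abs(p - q).max()) <= 2.0 * tol

    def next_unused(end, used):
        base = np.round(end / tol).astype(np.int64)
        for off in _NEIGHBOUR_OFFSETS:
            for j in adjacency.get(tuple(base + off), ()):
                if not used[j]:
                    c, d = segments[j]
                    if matches(c, end) or matches(d, end):
                        return j
        return None

    used = np.zeros(len(segments), dtype=bool)
    chains = []
    for start in range(len(segments)):
        if used[start]:
            continue
        used[start] = True
        a, b = segments[start]
        path = [a, b]
        for forward in (True, False):
            while True:
                end = path[-1] if forward else path[0]
                j = next_unused(end, used)
                if j is None:
                    break
                used[j] = True
                c, d = segments[j]
                nxt = d if matches(c, end) else c
                if forward:
                    path.append(nxt)
                else:
                    path.insert(0, nxt)
        closed = matches(path[0], path[-1]) and len(path) > 3
        pts = np.asarray(path[:-1] if closed else path)
        chains.append((pts, closed))
    return chains


def slice_mesh(mesh: TriangleMesh, plane: Plane,
               min_perimeter: float = 2.0) -> list[PlanarContour]:
    """Intersect *mesh* with *plane*.

    Returns contours ordered counterclockwise in the plane basis (closed
    contours only; open chains from non-watertight meshes keep their chained
    order).  Closed contours below *min_perimeter* are discarded.  A plane
    that misses the mesh yields an empty list.
    """
    d = plane.signed_distance(mesh.vertices)
    d = np.where(d == 0.0, 1e-12, d)  # nudge on-plane vertices deterministically
    tri_d = d[mesh.faces]
    crossing = ~(np.all(tri_d > 0, axis=1) | np.all(tri_d < 0, axis=1))
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    for face in mesh.faces[crossing]:
        pts = []
        for e0, e1 in ((0, 1), (1, 2), (2, 0)):
            a, b = face[e0], face[e1]
            da, db = d[a], d[b]
            if (da > 0) != (db > 0):
                t = da / (da - db)
                pts.append(mesh.vertices[a] + t * (mesh.vertices[b] - mesh.vertices[a]))
        if len(pts) == 2:
            segments.append((pts[0], pts[1]))
    if not segments:
        return []
    contours = []
    for pts3, closed in _chain_segments(segments):
        if len(pts3) < 2:
            continue
        contour = PlanarContour(plane.to_2d(pts3), plane, closed)
        if closed:
            if contour.perimeter < min_perimeter:
                continue
            if contour.signed_area < 0:
                contour = contour.reversed()
        contours.append(contour)
    return contours


# ---------------------------------------------------------------------------
# contour curvature
# ---------------------------------------------------------------------------

@dataclass
class CurvatureProfile:
    """Signed curvature sampled along an arc-length-resampled contour."""

    contour: PlanarContour          # the resampled contour
    curvature: np.ndarray           # 1/mm, one value per resampled point
    arclength: np.ndarray           # arc-length position of each sample


def _menger_curvature(p1, p2, p3) -> np.ndarray:
    """Signed inverse circumradius of point triples (vectorised, 2D)."""
    a = p2 - p1
    b = p3 - p2
    c = p3 - p1
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    la = np.linalg.norm(a, axis=1)
    lb = np.linalg.norm(b, axis=1)
    lc = np.linalg.norm(c, axis=1)
    denom = np.maximum(la * lb * lc, _EPS)
    return 2.0 * cross / denom


def contour_curvature(contour: PlanarContour, resample_step: float = 0.5,
                      smooth_window: int = 5) -> CurvatureProfile:
    """Signed curvature from the circumscribed circle of each resampled point
    and its neighbours at ``+/- smooth_window`` samples.

    Positive where the contour turns left (convex for CCW-oriented closed
    contours).  Raises for contours shorter than ``5 * resample_step``.
    """
    if contour.perimeter < 5.0 * resample_step:
        raise DegenerateGeometryError(
            f"contour of length {contour.perimeter:.3g} mm is shorter than "
            f"5 x resample_step = {5 * resample_step:.3g} mm")
    rs = contour.resample(resample_step)
    pts = rs.points2d
    n = len(pts)
    w = max(int(smooth_window), 1)
    kappa = np.zeros(n)
    if rs.closed:
        idx = np.arange(n)
        kappa = _menger_curvature(pts[(idx - w) % n], pts, pts[(idx + w) % n])
    else:
        w_eff = min(w, (n - 1) // 2)
        if w_eff < 1:
            raise DegenerateGeometryError("too few samples for curvature")
        idx = np.arange(w_eff, n - w_eff)
        inner = _menger_curvature(pts[idx - w_eff], pts[idx], pts[idx + w_eff])
        kappa[idx] = inner
        kappa[:w_eff] = inner[0]
        kappa[n - w_eff:] = inner[-1]
    arclength = np.arange(n) * resample_step
    return CurvatureProfile(rs, kappa, arclength)


def contour_outward_normals(profile_points: np.ndarray, closed: bool) -> np.ndarray:
    """Outward 2D normals of a CCW-oriented contour (rotate tangent by -90 deg)."""
    pts = profile_points
    if closed:
        nxt = np.roll(pts, -1, axis=0)
        prv = np.roll(pts, 1, axis=0)
    else:
        nxt = np.vstack([pts[1:], pts[-1]])
        prv = np.vstack([pts[0], pts[:-1]])
    tangent = nxt - prv
    norms = np.linalg.norm(tangent, axis=1, keepdims=True)
    tangent = tangent / np.maximum(norms, _EPS)
    return np.column_stack([tangent[:, 1], -tangent[:, 0]])


# ---------------------------------------------------------------------------
# polygon triangulation (used by the synthetic generator's end caps)
# ---------------------------------------------------------------------------

def triangulate_polygon(points2d: np.ndarray) -> np.ndarray:
    """Ear-clipping triangulation of a simple CCW polygon.

    Returns (m, 3) index triplets into *points2d*.  Handles collinear runs
    (zero-area ears are emitted and filtered out by the mesh constructor).
    """
    pts = np.asarray(points2d, dtype=float)
    n = len(pts)
    if n < 3:
        raise DegenerateGeometryError("polygon needs at least 3 vertices")
    indices = list(range(n))
    triangles = []
    guard = 0
    while len(indices) > 3 and guard < 10 * n * n:
        guard += 1
        m = len(indices)
        clipped = False
        for pos in range(m):
            i_prev = indices[(pos - 1) % m]
            i_cur = indices[pos]
            i_next = indices[(pos + 1) % m]
            a, b, c = pts[i_prev], pts[i_cur], pts[i_next]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross < -1e-12:
                continue  # reflex vertex
            # no other active vertex strictly inside the candidate ear
            others = [k for k in indices if k not in (i_prev, i_cur, i_next)]
            if others and cross > 1e-12:
                q = pts[others]
                if _any_point_in_triangle(q, a, b, c):
                    continue
            triangles.append((i_prev, i_cur, i_next))
            indices.pop(pos)
            clipped = True
            break
        if not clipped:
            # numerical fallback: clip the most convex remaining vertex
            m = len(indices)
            crosses = []
            for pos in range(m):
                a = pts[indices[(pos - 1) % m]]
                b = pts[indices[pos]]
                c = pts[indices[(pos + 1) % m]]
                crosses.append((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
            pos = int(np.argmax(crosses))
            triangles.append((indices[(pos - 1) % m], indices[pos], indices[(pos + 1) % m]))
            indices.pop(pos)
    triangles.append(tuple(indices))
    return np.asarray(triangles, dtype=np.int64)


def _any_point_in_triangle(q: np.ndarray, a, b, c) -> bool:
    # inside-or-on-boundary counts as blocking: a vertex lying exactly on the
    # candidate diagonal must not be sealed off by the ear
    eps = 1e-9
    d1 = (q[:, 0] - a[0]) * (b[1] - a[1]) - (q[:, 1] - a[1]) * (b[0] - a[0])
    d2 = (q[:, 0] - b[0]) * (c[1] - b[1]) - (q[:, 1] - b[1]) * (c[0] - b[0])
    d3 = (q[:, 0] - c[0]) * (a[1] - c[1]) - (q[:, 1] - c[1]) * (a[0] - c[0])
    blocking = (d1 < eps) & (d2 < eps) & (d3 < eps)
    return bool(blocking.any())
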