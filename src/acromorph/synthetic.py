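"""Parametric synthetic shoulders with analytic ground truth.

The generator builds three watertight labelled meshes (acromion-as-scapula,
clavicle, proximal humerus) in the canonical scapular frame (x lateral,
y superior, z anterior), plus the landmark set that reconstructs exactly
that frame, so every measurement has a closed-form expected value.

The acromion is a lofted prism: a planar x-z profile extruded in y.  The
profile is a main slab plus an anterolateral lobe whose medial border meets
the slab in a concave fillet crease; the crease corner drifts linearly with
y, which decouples the ``a`` and ``b`` ground truths.  Cohort and rater
simulations draw parameter values directly (no meshes) for speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InfeasibleGeometryError
from .geometry import Plane, TriangleMesh, triangulate_polygon, unit
from .measures import PARAMETERS
from .model import ShoulderModel
from .scapular_frame import ScapularLandmarks

_FILLET_MID = 1.0 - math.sqrt(0.5)  # fillet-arc midpoint offset factor


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass
class ShoulderSpec:
    """Full parameterisation of one synthetic shoulder (mm / degrees)."""

    # glenoid + scapular landmarks (canonical frame: A at the origin)
    glenoid_radius: float = 14.0
    n_rim_points: int = 12
    B: tuple = (-100.0, 0.0, 0.0)
    C: tuple = (-40.0, -120.0, 0.0)
    anterior_witness: tuple = (0.0, 0.0, 30.0)

    # acromion slab (prism extruded in y)
    acromion_x_medial: float = 5.0
    acromion_x_lateral: float = 30.0
    acromion_x_apex: float = 35.0
    acromion_z_posterior: float = -22.0
    acromion_z_anterior: float = 13.5
    acromion_z_mlpa: float = -5.0
    acromion_y_bottom: float = 26.0
    acromion_thickness: float = 8.0

    # anterolateral lobe (set has_lobe=False for a smooth slab)
    has_lobe: bool = True
    lobe_medial_x: float = 22.0        # crease-corner x at the inferior surface
    lobe_medial_dx: float = -2.5       # corner x drift, bottom -> top
    lobe_crease_z: float = 1.5         # crease-corner z at the inferior surface
    lobe_crease_dz: float = 3.0        # corner z drift, bottom -> top
    fillet_radius: float = 1.0

    # humeral head (sphere)
    humeral_head_radius: float = 24.0
    humeral_center_xz: tuple = (8.0, 0.0)
    ahi_gap: float = 8.1

    # clavicle box; reference-line offsets are the AAP / AIP ground truths
    aap_offset: float = 6.8
    aip_offset: float = 8.5
    clavicle_x_range: tuple = (-60.0, 18.0)
    clavicle_thickness: float = 6.0
    clavicle_depth: float = 10.0

    # AC joint margins: placed to realise this angle exactly at the MLPA
    ac_angle_deg: float = 41.0
    ac_margin_distance: float = 12.0

    side: str = "right"
    mesh_resolution: float = 0.7   # target edge length for subdivision
    seed: int = 0

    def validate(self) -> None:
        s = self
        if s.acromion_thickness <= 0 or s.mesh_resolution <= 0:
            raise InfeasibleGeometryError("extents and resolution must be positive")
        if s.ahi_gap < 0:
            raise InfeasibleGeometryError("ahi_gap must be non-negative")
        if not (s.acromion_x_medial < s.acromion_x_lateral < s.acromion_x_apex):
            raise InfeasibleGeometryError("acromion x extents must be increasing")
        if not (s.acromion_z_posterior < s.acromion_z_mlpa < s.acromion_z_anterior):
            raise InfeasibleGeometryError("MLPA z must lie inside the acromion z range")
        if s.has_lobe:
            f = s.fillet_radius
            xs = (s.lobe_medial_x, s.lobe_medial_x + s.lobe_medial_dx)
            zs = (s.lobe_crease_z, s.lobe_crease_z + s.lobe_crease_dz)
            if f <= 0:
                raise InfeasibleGeometryError("fillet radius must be positive")
            if min(xs) - f <= s.acromion_x_medial:
                raise InfeasibleGeometryError("lobe is wider than the acromion")
            if max(xs) >= s.acromion_x_lateral:
                raise InfeasibleGeometryError("lobe medial border exceeds the lateral edge")
            if min(zs) - f <= s.acromion_z_mlpa:
                raise InfeasibleGeometryError("crease reaches the posterior half")
            if max(zs) + f >= s.acromion_z_anterior:
                raise InfeasibleGeometryError("crease reaches the anterior edge")


@dataclass
class GroundTruth:
    """Closed-form expected measurements for a generated shoulder."""

    ahi_mm: float
    aap_mm: float
    aip_mm: float
    ac_angle_deg: float
    a_mm: float | None
    b_mm: float | None
    c_mm: float | None
    c_plus_d_mm: float
    ratio_percent: float | None
    glenoid_radius: float = 0.0
    mlpa: np.ndarray | None = None
    border_bottom: np.ndarray | None = None  # crease line endpoints (frame coords)
    border_top: np.ndarray | None = None

    def as_dict(self) -> dict:
        out = {k: getattr(self, k) for k in PARAMETERS}
        out["c_plus_d_mm"] = self.c_plus_d_mm
        out["glenoid_radius"] = self.glenoid_radius
        return out


# ---------------------------------------------------------------------------
# low-level mesh builders
# ---------------------------------------------------------------------------

def _merge_vertices(vertices: np.ndarray, faces: np.ndarray, tol: float = 1e-6):
    keys = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    return vertices[first], inverse[faces]


def _subdivide_edge(p0, p1, step: float) -> np.ndarray:
    """Points from p0 (inclusive) to p1 (exclusive) at roughly *step* spacing."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    n = max(int(np.ceil(np.linalg.norm(p1 - p0) / step)), 1)
    t = np.arange(n) / n
    return p0 + t[:, None] * (p1 - p0)


def _acromion_profile(spec: ShoulderSpec, t: float, counts: list[int] | None):
    """CCW x-z profile polygon at loft fraction *t* in [0, 1].

    When *counts* is given, each analytic edge is subdivided into exactly
    those point counts so profiles at different levels stay loft-compatible.
    """
    s = spec
    xc = s.lobe_medial_x + s.lobe_medial_dx * t
    zc = s.lobe_crease_z + s.lobe_crease_dz * t
    f = s.fillet_radius
    corners = [
        (s.acromion_x_medial, s.acromion_z_posterior),
        (s.acromion_x_lateral, s.acromion_z_posterior),
        (s.acromion_x_apex, s.acromion_z_mlpa),
        (s.acromion_x_lateral, s.acromion_z_anterior),
    ]
    if s.has_lobe:
        arc_pts = 16
        theta = np.linspace(0.0, -math.pi / 2.0, arc_pts + 1)
        center = np.array([xc - f, zc + f])
        arc = center + f * np.column_stack([np.cos(theta), np.sin(theta)])
        path = corners + [(xc, s.acromion_z_anterior)]
        path += [tuple(p) for p in arc]
        path += [(s.acromion_x_medial, zc)]
    else:
        path = corners + [(s.acromion_x_medial, s.acromion_z_anterior)]
    pts = []
    edge_counts = []
    m = len(path)
    for i in range(m):
        p0, p1 = np.asarray(path[i]), np.asarray(path[(i + 1) % m])
        if counts is None:
            seg = _subdivide_edge(p0, p1, s.mesh_resolution)
            edge_counts.append(len(seg))
        else:
            n = counts[i]
            tt = np.arange(n) / n
            seg = p0 + tt[:, None] * (p1 - p0)
        pts.append(seg)
    poly = np.vstack(pts)
    return (poly, edge_counts) if counts is None else (poly, None)


def _loft_prism(profiles: list[np.ndarray], ys: np.ndarray) -> TriangleMesh:
    """Watertight prism from CCW x-z profiles stacked at heights *ys*.

    Profiles must share a vertex count.  Winding follows the convention that
    CCW-in-(x, z) profiles produce outward wall normals with triangles
    (bottom_k, top_k, bottom_k+1) / (top_k, top_k+1, bottom_k+1); global
    orientation is verified by the signed volume and flipped if needed.
    """
    n = len(profiles[0])
    levels = len(profiles)
    verts = []
    for prof, y in zip(profiles, ys):
        verts.append(np.column_stack([prof[:, 0], np.full(n, y), prof[:, 1]]))
    verts = np.vstack(verts)
    faces = []
    for j in range(levels - 1):
        base0, base1 = j * n, (j + 1) * n
        for k in range(n):
            k1 = (k + 1) % n
            faces.append((base0 + k, base1 + k, base0 + k1))
            faces.append((base1 + k, base1 + k1, base0 + k1))
    tri = triangulate_polygon(profiles[0])
    faces.extend((a, b, c) for a, b, c in tri)                      # bottom cap
    top = (levels - 1) * n
    tri_top = triangulate_polygon(profiles[-1])
    faces.extend((top + a, top + c, top + b) for a, b, c in tri_top)  # top cap
    mesh = TriangleMesh(verts, np.asarray(faces, dtype=np.int64))
    if mesh.volume() < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


def box_mesh(lo, hi, step: float = 1.0) -> TriangleMesh:
    """Axis-aligned box with all six faces subdivided at roughly *step*."""
    lo, hi = np.asarray(lo, float), np.asarray(hi, float)
    counts = np.maximum(np.ceil((hi - lo) / step).astype(int), 1)
    verts, faces = [], []

    def add_face(axis: int, at: float, outward_sign: int):
        ax_u, ax_v = [a for a in range(3) if a != axis]
        nu, nv = counts[ax_u], counts[ax_v]
        us = np.linspace(lo[ax_u], hi[ax_u], nu + 1)
        vs = np.linspace(lo[ax_v], hi[ax_v], nv + 1)
        base = len(verts)
        for u in us:
            for v in vs:
                p = np.empty(3)
                p[axis], p[ax_u], p[ax_v] = at, u, v
                verts.append(p)
        # winding (a, c, b) yields normal +axis when (u, v, axis) is an even
        # permutation of (x, y, z), i.e. for axes 0 and 2; axis 1 is odd
        base_sign = -1 if axis == 1 else 1
        for i in range(nu):
            for j in range(nv):
                a = base + i * (nv + 1) + j
                b, c, d = a + 1, a + nv + 1, a + nv + 2
                if outward_sign == base_sign:
                    faces.extend([(a, c, b), (b, c, d)])
                else:
                    faces.extend([(a, b, c), (b, d, c)])
    for axis in range(3):
        add_face(axis, lo[axis], outward_sign=-1)
        add_face(axis, hi[axis], outward_sign=1)
    v, f = _merge_vertices(np.asarray(verts), np.asarray(faces, dtype=np.int64))
    mesh = TriangleMesh(v, f)
    if mesh.volume() < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


def uv_sphere(center, radius: float, stacks: int = 28, sectors: int = 56) -> TriangleMesh:
    """UV sphere with exact pole vertices (the north pole is the top point)."""
    center = np.asarray(center, float)
    verts = [center + [0.0, radius, 0.0]]
    for i in range(1, stacks):
        phi = math.pi * i / stacks
        y = radius * math.cos(phi)
        r = radius * math.sin(phi)
        for j in range(sectors):
            theta = 2.0 * math.pi * j / sectors
            verts.append(center + [r * math.cos(theta), y, r * math.sin(theta)])
    verts.append(center + [0.0, -radius, 0.0])
    south = len(verts) - 1
    faces = []
    ring = lambda i, j: 1 + (i - 1) * sectors + (j % sectors)
    for j in range(sectors):
        faces.append((0, ring(1, j + 1), ring(1, j)))
    for i in range(1, stacks - 1):
        for j in range(sectors):
            a, b = ring(i, j), ring(i, j + 1)
            c, d = ring(i + 1, j), ring(i + 1, j + 1)
            faces.extend([(a, b, c), (b, d, c)])
    for j in range(sectors):
        faces.append((south, ring(stacks - 1, j), ring(stacks - 1, j + 1)))
    mesh = TriangleMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64))
    if mesh.volume() < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


# ---------------------------------------------------------------------------
# shoulder generation
# ---------------------------------------------------------------------------

def _ground_truth(spec: ShoulderSpec) -> GroundTruth:
    s = spec
    mlpa = np.array([s.acromion_x_apex, s.acromion_y_bottom, s.acromion_z_mlpa])
    c_plus_d = s.acromion_z_anterior - s.acromion_z_posterior
    if not s.has_lobe:
        return GroundTruth(
            ahi_mm=s.ahi_gap, aap_mm=s.aap_offset, aip_mm=s.aip_offset,
            ac_angle_deg=s.ac_angle_deg, a_mm=None, b_mm=None, c_mm=None,
            c_plus_d_mm=c_plus_d, ratio_percent=None,
            glenoid_radius=s.glenoid_radius, mlpa=mlpa)
    off = _FILLET_MID * s.fillet_radius

    def border(t: float) -> np.ndarray:
        return np.array([
            s.lobe_medial_x + s.lobe_medial_dx * t - off,
            s.acromion_y_bottom + s.acromion_thickness * t,
            s.lobe_crease_z + s.lobe_crease_dz * t + off,
        ])

    b0, b1 = border(0.0), border(1.0)
    mlpa_xz = mlpa[(0, 2),]
    ends = np.array([b0[(0, 2),], b1[(0, 2),]])
    a_pt = ends[int(np.argmin(ends[:, 0]))]
    a_mm = float(np.linalg.norm(a_pt - mlpa_xz))
    # posterior band (lowest 20% of border z); minimal x within it.  The
    # border is linear in t, so the band minimum sits at one of two ends.
    if s.lobe_crease_dz == 0:
        t_candidates = (0.0, 1.0)
    elif s.lobe_crease_dz > 0:
        t_candidates = (0.0, 0.2)
    else:
        t_candidates = (1.0, 0.8)
    cand_xz = np.array([border(t)[(0, 2),] for t in t_candidates])
    b_pt = cand_xz[int(np.argmin(cand_xz[:, 0]))]
    b_mm = float(np.linalg.norm(b_pt - mlpa_xz))
    c_mm = float(s.acromion_z_anterior - min(b0[2], b1[2]))
    return GroundTruth(
        ahi_mm=s.ahi_gap, aap_mm=s.aap_offset, aip_mm=s.aip_offset,
        ac_angle_deg=s.ac_angle_deg, a_mm=a_mm, b_mm=b_mm, c_mm=c_mm,
        c_plus_d_mm=c_plus_d, ratio_percent=100.0 * c_mm / c_plus_d,
        glenoid_radius=s.glenoid_radius, mlpa=mlpa,
        border_bottom=b0, border_top=b1)


def generate_shoulder(spec: ShoulderSpec | None = None
                      ) -> tuple[ShoulderModel, GroundTruth]:
    """Build the labelled meshes, landmarks and ground truth for one shoulder.

    Deterministic: the same spec (including seed) always produces identical
    meshes.  ``side='left'`` emits the exact mirror image (across the
    scapular plane z = 0) of the right-handed construction; the ground truth
    is unchanged because measurement normalises the side first.
    """
    spec = spec or ShoulderSpec()
    spec.validate()
    s = spec
    truth = _ground_truth(s)

    # --- acromion prism -----------------------------------------------------
    prof0, counts = _acromion_profile(s, 0.0, None)
    levels = max(int(np.ceil(s.acromion_thickness / s.mesh_resolution)) + 1, 2)
    ts = np.linspace(0.0, 1.0, levels)
    profiles = [_acromion_profile(s, t, counts)[0] for t in ts]
    ys = s.acromion_y_bottom + s.acromion_thickness * ts
    acromion = _loft_prism(profiles, ys)
    scapula = TriangleMesh(acromion.vertices, acromion.faces,
                           {"acromion": np.ones(len(acromion), dtype=bool)})

    # --- clavicle box -------------------------------------------------------
    y_cl_lo = s.acromion_y_bottom + s.aip_offset
    z_cl_hi = s.acromion_z_anterior - s.aap_offset
    clav = box_mesh(
        [s.clavicle_x_range[0], y_cl_lo, z_cl_hi - s.clavicle_depth],
        [s.clavicle_x_range[1], y_cl_lo + s.clavicle_thickness, z_cl_hi],
        step=max(s.mesh_resolution, 0.5))
    x0, x1 = s.clavicle_x_range
    distal = clav.vertices[:, 0] >= x0 + 0.75 * (x1 - x0) - 1e-9
    clav = TriangleMesh(clav.vertices, clav.faces, {"distal_quarter": distal})

    # --- humeral head -------------------------------------------------------
    hc_y = s.acromion_y_bottom - s.ahi_gap - s.humeral_head_radius
    humerus = uv_sphere(
        [s.humeral_center_xz[0], hc_y, s.humeral_center_xz[1]],
        s.humeral_head_radius)

    # --- landmarks ----------------------------------------------------------
    theta = 2.0 * math.pi * np.arange(s.n_rim_points) / s.n_rim_points
    rim = np.column_stack([
        np.zeros_like(theta),
        s.glenoid_radius * np.cos(theta),
        s.glenoid_radius * np.sin(theta),
    ])
    half = math.radians(s.ac_angle_deg) / 2.0
    mlpa_xy = np.array([s.acromion_x_apex, s.acromion_y_bottom])
    d = s.ac_margin_distance
    am_xy = mlpa_xy + d * np.array([-math.cos(half), math.sin(half)])
    pm_xy = mlpa_xy + d * np.array([-math.cos(half), -math.sin(half)])
    am = np.array([am_xy[0], am_xy[1], s.acromion_z_mlpa + 2.0])
    pm = np.array([pm_xy[0], pm_xy[1], s.acromion_z_mlpa - 2.0])
    landmarks = ScapularLandmarks(
        glenoid_rim=rim, B=np.asarray(s.B, float), C=np.asarray(s.C, float),
        AM=am, PM=pm, anterior_witness=np.asarray(s.anterior_witness, float),
        side="right")

    model = ShoulderModel(scapula_mesh=scapula, clavicle_mesh=clav,
                          humerus_mesh=humerus, landmarks=landmarks,
                          provenance={"generator_seed": s.seed})
    if s.side == "left":
        plane = Plane(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        model = model.mirrored(plane)
        model.landmarks = replace(model.landmarks, side="left")
    return model, truth


# ---------------------------------------------------------------------------
# rater and cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class RaterNoiseModel:
    """Gaussian rater model: per-parameter replicate SD + per-rater bias SD."""

    within_rater_sd: dict | float = 0.2
    rater_bias_sd: dict | float = 0.1
    seed: int = 0

    def sd_for(self, attr: str, parameter: str) -> float:
        value = getattr(self, attr)
        if isinstance(value, dict):
            return float(value[parameter])
        return float(value)

    def __post_init__(self):
        for attr in ("within_rater_sd", "rater_bias_sd"):
            v = getattr(self, attr)
            vals = v.values() if isinstance(v, dict) else [v]
            if any(x < 0 for x in vals):
                raise ValueError(f"{attr} must be non-negative")


def simulate_rater_table(true_values: pd.DataFrame, noise: RaterNoiseModel,
                         n_raters: int = 2, n_replicates: int = 2,
                         seed: int | None = None) -> pd.DataFrame:
    """Long-format replicate readings for many subjects.

    *true_values*: rows = subjects, columns = parameters.  Each reading is
    ``truth + rater bias + replicate noise``; negative readings clamp to 0
    and are flagged.  Deterministic given *seed*.
    """
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    rows = []
    params = list(true_values.columns)
    biases = {
        (rater, p): rng.normal(0.0, noise.sd_for("rater_bias_sd", p))
        for rater in range(1, n_raters + 1) for p in params
    }
    for subject, row in true_values.iterrows():
        for rater in range(1, n_raters + 1):
            for rep in range(1, n_replicates + 1):
                for p in params:
                    sd = noise.sd_for("within_rater_sd", p)
                    val = row[p] + biases[(rater, p)] + (rng.normal(0.0, sd) if sd else 0.0)
                    clamped = val < 0
                    rows.append((subject, rater, rep, p, max(val, 0.0), clamped))
    return pd.DataFrame(rows, columns=["subject", "rater", "replicate",
                                       "parameter", "value", "clamped"])


def simulate_raters(model: ShoulderModel, noise: RaterNoiseModel,
                    n_raters: int = 2, n_replicates: int = 2,
                    seed: int | None = None) -> pd.DataFrame:
    """Replicate measurement table for one shoulder model."""
    from .measures import measure_all

    ms = measure_all(model)
    truth = pd.DataFrame(
        [{p: ms.as_dict()[p] for p in PARAMETERS if ms.as_dict()[p] is not None}],
        index=[0])
    return simulate_rater_table(truth, noise, n_raters, n_replicates, seed)


#: Reference per-group summary statistics (mean, SD) for the three cohorts:
#: healthy controls, non-impingement-injury (NII) and impingement-injury (II)
#: shoulders.  Units follow PARAMETERS (mm, degrees, percent).
DEFAULT_GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "control": {
        "ahi_mm": (8.6, 1.7), "aap_mm": (6.8, 3.5), "aip_mm": (8.5, 5.7),
        "ac_angle_deg": (41.2, 4.5), "a_mm": (12.9, 2.1), "b_mm": (9.7, 2.8),
        "c_mm": (10.0, 3.2), "ratio_percent": (28.1, 2.8),
    },
    "nii": {
        "ahi_mm": (8.4, 0.8), "aap_mm": (6.7, 3.4), "aip_mm": (8.9, 2.7),
        "ac_angle_deg": (40.8, 3.8), "a_mm": (13.8, 1.5), "b_mm": (10.1, 1.0),
        "c_mm": (10.3, 1.5), "ratio_percent": (29.0, 2.4),
    },
    "ii": {
        "ahi_mm": (8.1, 2.0), "aap_mm": (8.5, 4.7), "aip_mm": (9.0, 3.1),
        "ac_angle_deg": (40.8, 2.7), "a_mm": (14.8, 1.7), "b_mm": (11.0, 2.0),
        "c_mm": (11.3, 3.2), "ratio_percent": (31.6, 3.0),
    },
}

DEFAULT_GROUP_SIZES = {"control": 113, "nii": 98, "ii": 128}


@dataclass
class CohortSpec:
    """Per-group parameter distributions for cohort simulation."""

    group_stats: dict = field(default_factory=lambda: {
        g: dict(v) for g, v in DEFAULT_GROUP_STATS.items()})
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    seed: int = 0

    def __post_init__(self):
        for g, stats in self.group_stats.items():
            for p, (_, sd) in stats.items():
                if sd < 0:
                    raise ValueError(f"SD for {g}/{p} must be non-negative")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group size for {g} must be positive")


def simulate_cohort(spec: CohortSpec | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Independent truncated-Gaussian draws per parameter per group.

    Negative draws are resampled (truncation at 0) so distance parameters
    stay valid; the induced bias is negligible for the default ranges.
    Returns a wide table with ``subject``, ``group`` and parameter columns.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frames = []
    subject = 0
    for group, stats in spec.group_stats.items():
        n = spec.group_sizes[group]
        data = {"subject": np.arange(subject, subject + n), "group": group}
        subject += n
        for p, (mean, sd) in stats.items():
            draws = rng.normal(mean, sd, size=n)
            if sd > 0:
                bad = draws < 0
                while bad.any():
                    draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
                    bad = draws < 0
            data[p] = draws
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)
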