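"""Scapular coordinate frame from three landmark constructs.

The frame origin A is the centre of the best-fit circle of the inferior
glenoid rim.  The scapular plane passes through A, the spine/medial-border
junction B, and the inferior angle C.  Axes: x lateral (B toward A), z
anterior (plane normal, oriented by an annotated anterior witness point),
y = z x x superior.  Left shoulders are mirrored across the scapular plane
before measurement so a single right-handed convention applies throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateGeometryError, FrameOrientationError, SideError
from .geometry import (
    CircleFit,
    OrthonormalFrame,
    Plane,
    _check_rotation,
    fit_circle_in_plane,
    unit,
)

_SIDES = ("left", "right")


@dataclass
class ScapularLandmarks:
    """Landmark annotation for one shoulder (world coordinates, mm)."""

    glenoid_rim: np.ndarray       # (n >= 5, 3) points on the inferior glenoid rim
    B: np.ndarray                 # scapular spine / medial border junction
    C: np.ndarray                 # most inferior point of the inferior angle
    AM: np.ndarray                # anterior acromioclavicular joint-line margin
    PM: np.ndarray                # posterior acromioclavicular joint-line margin
    anterior_witness: np.ndarray  # any point strictly anterior to the scapular plane
    side: str = "right"

    def __post_init__(self):
        self.glenoid_rim = np.asarray(self.glenoid_rim, dtype=float)
        for name in ("B", "C", "AM", "PM", "anterior_witness"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        if self.glenoid_rim.ndim != 2 or self.glenoid_rim.shape[1] != 3:
            raise ValueError("glenoid_rim must be an (n, 3) array")
        if len(self.glenoid_rim) < 5:
            raise ValueError("at least 5 glenoid rim points are required")
        if len(np.unique(np.round(self.glenoid_rim, 9), axis=0)) < len(self.glenoid_rim):
            raise ValueError("glenoid rim points must be pairwise distinct")
        if np.allclose(self.B, self.C):
            raise ValueError("landmarks B and C must be distinct")
        if np.allclose(self.AM, self.PM):
            raise ValueError("landmarks AM and PM must be distinct")
        if self.side not in _SIDES:
            raise SideError(f"side must be one of {_SIDES}, got {self.side!r}")

    def transformed(self, rotation, translation) -> "ScapularLandmarks":
        r = _check_rotation(rotation)
        t = np.asarray(translation, dtype=float)
        return ScapularLandmarks(
            glenoid_rim=self.glenoid_rim @ r.T + t,
            B=r @ self.B + t, C=r @ self.C + t,
            AM=r @ self.AM + t, PM=r @ self.PM + t,
            anterior_witness=r @ self.anterior_witness + t,
            side=self.side,
        )

    def mirrored(self, plane: Plane, side: str | None = None) -> "ScapularLandmarks":
        def refl(p):
            p = np.atleast_2d(p)
            d = (p - plane.point) @ plane.normal
            out = p - 2.0 * d[:, None] * plane.normal
            return out if len(out) > 1 else out[0]

        return ScapularLandmarks(
            glenoid_rim=refl(self.glenoid_rim),
            B=refl(self.B), C=refl(self.C),
            AM=refl(self.AM), PM=refl(self.PM),
            anterior_witness=refl(self.anterior_witness),
            side=side if side is not None else self.side,
        )


@dataclass(frozen=True)
class ScapularFrame(OrthonormalFrame):
    """Orthonormal scapular frame plus the fitted glenoid circle radius."""

    glenoid_radius: float = 0.0


def fit_glenoid_circle(glenoid_rim_points, min_radius: float = 1.0) -> CircleFit:
    """Best-fit circle of the inferior glenoid rim (origin construct A)."""
    pts = np.asarray(glenoid_rim_points, dtype=float)
    if pts.ndim != 2 or len(pts) < 5:
        raise DegenerateGeometryError("glenoid circle fit needs at least 5 rim points")
    return fit_circle_in_plane(pts, min_radius=min_radius)


def build_frame(landmarks: ScapularLandmarks) -> ScapularFrame:
    """Construct the scapular frame from the landmark set.

    The scapular plane is the exact plane through A (fitted circle centre),
    B and C.  x = unit(A - B) (medial to lateral); z = plane normal oriented
    so the anterior witness has positive z; y = z x x.  C must come out with
    negative y (inferior angle below the origin) - if it does not, the
    shoulder side was not normalised first.
    """
    fit = fit_glenoid_circle(landmarks.glenoid_rim)
    a = fit.center
    ab = a - landmarks.B
    ac = landmarks.C - landmarks.B
    normal = np.cross(ab, ac)
    if np.linalg.norm(normal) < 1e-9 * max(np.linalg.norm(ab), 1.0):
        raise DegenerateGeometryError("A, B, C are collinear; scapular plane undefined")
    z = unit(normal)
    if (landmarks.anterior_witness - a) @ z < 0:
        z = -z
    x = unit(a - landmarks.B)
    x = unit(x - (x @ z) * z)  # re-orthogonalise (A, B numerically in-plane anyway)
    y = np.cross(z, x)
    if (landmarks.C - a) @ y > 0:
        raise FrameOrientationError(
            "inferior angle C lies above the frame origin; "
            "normalise the shoulder side before building the frame")
    return ScapularFrame(origin=a, axes=np.vstack([x, y, z]),
                         glenoid_radius=float(fit.radius))


def scapular_plane(landmarks: ScapularLandmarks) -> Plane:
    """Exact plane through A (fitted), B and C, normal oriented anterior."""
    fit = fit_glenoid_circle(landmarks.glenoid_rim)
    a = fit.center
    normal = np.cross(a - landmarks.B, landmarks.C - landmarks.B)
    if np.linalg.norm(normal) < 1e-9:
        raise DegenerateGeometryError("A, B, C are collinear")
    n = unit(normal)
    if (landmarks.anterior_witness - a) @ n < 0:
        n = -n
    return Plane(a, n)


def normalize_side(model):
    """Return a right-convention copy of *model*.

    Right shoulders pass through unchanged.  Left shoulders are reflected
    across the scapular plane (through A, B, C), which maps them onto their
    right-handed twin; meshes have their winding flipped so outward normals
    stay outward.  The returned model carries ``mirrored=True`` provenance.
    """
    side = model.landmarks.side
    if side == "right":
        return model
    if side != "left":
        raise SideError(f"unknown shoulder side {side!r}")
    plane = scapular_plane(model.landmarks)
    out = model.mirrored(plane)
    out.landmarks = replace_side(out.landmarks, "right")
    out.provenance["mirrored"] = True
    return out


def replace_side(landmarks: ScapularLandmarks, side: str) -> ScapularLandmarks:
    return replace(landmarks, side=side)
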