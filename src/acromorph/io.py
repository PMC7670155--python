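"""File formats: STL (ASCII/binary), OBJ, PLY meshes and JSON landmarks.

All interchange coordinates are raw world coordinates in millimetres; the
scapular frame is built inside the pipeline, never baked into files.
Duplicate vertices are merged at 1e-6 mm on load and degenerate faces
dropped (by the mesh constructor).
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

from .errors import MeshFormatError, MissingLandmarkError
from .geometry import TriangleMesh
from .scapular_frame import ScapularLandmarks

LANDMARK_SCHEMA_VERSION = 1
_REQUIRED_LANDMARKS = ("glenoid_rim", "B", "C", "AM", "PM", "anterior_witness")


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def read_mesh(path, label: str | None = None) -> TriangleMesh:
    """Read an STL/PLY/OBJ mesh; optionally attach *label* to all vertices.

    A sidecar ``<stem>.labels.json`` (mapping label name -> vertex index
    list) is applied when present.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise MeshFormatError(f"mesh file {path} is missing or empty")
    suffix = path.suffix.lower()
    if suffix == ".stl":
        verts, faces = _read_stl(path)
    elif suffix == ".obj":
        verts, faces = _read_obj(path)
    elif suffix == ".ply":
        verts, faces = _read_ply(path)
    else:
        raise MeshFormatError(f"unsupported mesh format {suffix!r} (use STL/OBJ/PLY)")
    verts, faces = _merge(verts, faces)
    labels = {}
    if label:
        labels[label] = np.ones(len(verts), dtype=bool)
    sidecar = path.with_suffix(path.suffix + ".labels.json")
    if sidecar.exists():
        with open(sidecar) as fh:
            for name, idx in json.load(fh).items():
                mask = np.zeros(len(verts), dtype=bool)
                mask[np.asarray(idx, dtype=int)] = True
                labels[name] = mask
    try:
        return TriangleMesh(verts, faces, labels)
    except ValueError as exc:
        raise MeshFormatError(f"{path}: {exc}") from exc


def write_mesh(mesh: TriangleMesh, path, binary: bool = False) -> None:
    """Write an ASCII (default) or binary STL plus a label sidecar if any."""
    path = Path(path)
    if path.suffix.lower() != ".stl":
        raise MeshFormatError("write_mesh emits STL only")
    tri = mesh.vertices[mesh.faces]
    normals = mesh.face_normals()
    if binary:
        with open(path, "wb") as fh:
            fh.write(b"\0" * 80)
            fh.write(struct.pack("<I", len(tri)))
            for n, t in zip(normals, tri):
                fh.write(struct.pack("<12fH", *n, *t[0], *t[1], *t[2], 0))
    else:
        with open(path, "w") as fh:
            fh.write("solid acromorph\n")
            for n, t in zip(normals, tri):
                fh.write(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n")
                fh.write("    outer loop\n")
                for v in t:
                    fh.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write("endsolid acromorph\n")
    if mesh.labels:
        # sidecar indices refer to the merged vertex order produced on re-read
        sidecar = path.with_suffix(path.suffix + ".labels.json")
        with open(sidecar, "w") as fh:
            json.dump(_stl_sidecar_labels(mesh), fh)


def _stl_sidecar_labels(mesh: TriangleMesh) -> dict:
    """Labels remapped to the vertex order an STL round-trip will produce.

    A re-read (merged) vertex inherits a label iff any coincident original
    face corner carried it.
    """
    corner_idx = mesh.faces.reshape(-1)
    corners = mesh.vertices[corner_idx]
    keys = np.round(corners / 1e-6).astype(np.int64)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    out = {}
    for name, mask in mesh.labels.items():
        lab = np.zeros(len(uniq), dtype=bool)
        np.logical_or.at(lab, inverse, mask[corner_idx])
        out[name] = np.flatnonzero(lab).tolist()
    return out


def _merge(verts: np.ndarray, faces: np.ndarray, tol: float = 1e-6):
    keys = np.round(verts / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    return verts[first], inverse[faces]


def _read_stl(path: Path):
    raw = path.read_bytes()
    is_ascii = raw.lstrip()[:5].lower() == b"solid" and b"facet" in raw[:1000]
    if is_ascii:
        verts = []
        for line in raw.decode("ascii", errors="replace").splitlines():
            parts = line.split()
            if parts[:1] == ["vertex"]:
                verts.append([float(x) for x in parts[1:4]])
        if not verts or len(verts) % 3:
            raise MeshFormatError(f"{path}: malformed ASCII STL")
        verts = np.asarray(verts)
    else:
        if len(raw) < 84:
            raise MeshFormatError(f"{path}: binary STL too short")
        (n_tri,) = struct.unpack_from("<I", raw, 80)
        expected = 84 + 50 * n_tri
        if len(raw) < expected:
            raise MeshFormatError(f"{path}: binary STL truncated")
        data = np.frombuffer(raw, dtype=np.uint8, count=50 * n_tri, offset=84)
        tri = data.reshape(n_tri, 50)[:, 12:48].copy().view("<f4").reshape(n_tri, 3, 3)
        verts = tri.reshape(-1, 3).astype(float)
    faces = np.arange(len(verts), dtype=np.int64).reshape(-1, 3)
    return verts, faces


def _read_obj(path: Path):
    verts, faces = [], []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            idx = [int(tok.split("/")[0]) - 1 for tok in parts[1:]]
            for k in range(1, len(idx) - 1):  # fan-triangulate polygons
                faces.append((idx[0], idx[k], idx[k + 1]))
    if not verts or not faces:
        raise MeshFormatError(f"{path}: no geometry found in OBJ")
    return np.asarray(verts, dtype=float), np.asarray(faces, dtype=np.int64)


def _read_ply(path: Path):
    text = path.read_text().splitlines()
    if not text or text[0].strip() != "ply":
        raise MeshFormatError(f"{path}: not a PLY file")
    n_verts = n_faces = None
    header_end = None
    for i, line in enumerate(text):
        parts = line.split()
        if parts[:2] == ["element", "vertex"]:
            n_verts = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            n_faces = int(parts[2])
        elif parts[:1] == ["format"] and parts[1] != "ascii":
            raise MeshFormatError(f"{path}: only ASCII PLY is supported")
        elif parts[:1] == ["end_header"]:
            header_end = i
            break
    if header_end is None or n_verts is None or n_faces is None:
        raise MeshFormatError(f"{path}: malformed PLY header")
    body = text[header_end + 1:]
    verts = np.asarray([[float(x) for x in body[i].split()[:3]]
                        for i in range(n_verts)])
    faces = []
    for i in range(n_verts, n_verts + n_faces):
        tokens = [int(x) for x in body[i].split()]
        idx = tokens[1:1 + tokens[0]]
        for k in range(1, len(idx) - 1):
            faces.append((idx[0], idx[k], idx[k + 1]))
    return verts, np.asarray(faces, dtype=np.int64)


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def read_landmarks(path) -> ScapularLandmarks:
    """Read and validate a versioned landmark JSON file."""
    path = Path(path)
    if not path.exists():
        raise MissingLandmarkError(f"landmark file {path} does not exist")
    with open(path) as fh:
        data = json.load(fh)
    if data.get("schema_version") != LANDMARK_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported landmark schema version {data.get('schema_version')!r}")
    if data.get("units", "mm") != "mm":
        raise ValueError("landmark coordinates must be in mm")
    marks = data.get("landmarks", {})
    missing = [name for name in _REQUIRED_LANDMARKS if name not in marks]
    if missing:
        raise MissingLandmarkError(f"missing landmark: {', '.join(missing)}")
    return ScapularLandmarks(
        glenoid_rim=np.asarray(marks["glenoid_rim"], dtype=float),
        B=marks["B"], C=marks["C"], AM=marks["AM"], PM=marks["PM"],
        anterior_witness=marks["anterior_witness"],
        side=data.get("side", "right"),
    )


def write_landmarks(landmarks: ScapularLandmarks, path) -> None:
    data = {
        "schema_version": LANDMARK_SCHEMA_VERSION,
        "units": "mm",
        "side": landmarks.side,
        "landmarks": {
            "glenoid_rim": landmarks.glenoid_rim.tolist(),
            "B": landmarks.B.tolist(), "C": landmarks.C.tolist(),
            "AM": landmarks.AM.tolist(), "PM": landmarks.PM.tolist(),
            "anterior_witness": landmarks.anterior_witness.tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
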