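"""The labelled bone-mesh + landmark bundle for one shoulder."""

from __future__ import annotations

from dataclasses import dataclass, field

from .geometry import Plane, TriangleMesh, _check_rotation
from .scapular_frame import ScapularLandmarks


@dataclass
class ShoulderModel:
    """Bone surfaces and landmarks for one shoulder, all in mm.

    ``scapula_mesh`` must carry an ``acromion`` vertex label (it may cover
    the whole mesh).  ``clavicle_mesh`` may carry a ``distal_quarter`` label;
    when absent the distal quarter is derived from the geometry.
    """

    scapula_mesh: TriangleMesh
    clavicle_mesh: TriangleMesh
    humerus_mesh: TriangleMesh
    landmarks: ScapularLandmarks
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("scapula_mesh", "clavicle_mesh", "humerus_mesh"):
            mesh = getattr(self, name)
            if len(mesh.faces) == 0:
                raise ValueError(f"{name} has no faces")
        if "acromion" not in self.scapula_mesh.labels:
            raise ValueError("scapula_mesh must carry an 'acromion' vertex label")
        if not self.scapula_mesh.labels["acromion"].any():
            raise ValueError("acromion label selects no vertices")

    @property
    def side(self) -> str:
        return self.landmarks.side

    def acromion(self) -> TriangleMesh:
        return self.scapula_mesh.submesh(self.scapula_mesh.label_mask("acromion"))

    def transformed(self, rotation, translation) -> "ShoulderModel":
        _check_rotation(rotation)
        return ShoulderModel(
            scapula_mesh=self.scapula_mesh.transformed(rotation, translation),
            clavicle_mesh=self.clavicle_mesh.transformed(rotation, translation),
            humerus_mesh=self.humerus_mesh.transformed(rotation, translation),
            landmarks=self.landmarks.transformed(rotation, translation),
            provenance=dict(self.provenance),
        )

    def mirrored(self, plane: Plane) -> "ShoulderModel":
        return ShoulderModel(
            scapula_mesh=self.scapula_mesh.mirrored(plane),
            clavicle_mesh=self.clavicle_mesh.mirrored(plane),
            humerus_mesh=self.humerus_mesh.mirrored(plane),
            landmarks=self.landmarks.mirrored(plane),
            provenance=dict(self.provenance),
        )
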