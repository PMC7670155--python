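"""Run configuration: every tunable default of the measurement pipeline.

All lengths are millimetres, angles degrees.  The defaults mirror the CT
acquisition the pipeline is designed around (0.625 mm axial slices) and are
deliberately below that resolution where resampling is involved.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


@dataclass
class RunConfig:
    # mesh slicing / protrusion localisation
    slice_step: float = 0.625          # axial slice spacing for AALP search
    resample_step: float = 0.5         # contour arc-length resampling
    smooth_window: int = 5             # curvature neighbourhood (+/- samples)
    curvature_min: float = 0.15        # 1/mm; minimum crease curvature magnitude
    min_slices: int = 3                # slices required for a detected region
    min_contour_perimeter: float = 2.0 # discard smaller slice contours
    inner_edge_normal_x: float = -0.05 # outward-normal x bound for "inner edge"
    anterior_margin: float = 0.5       # keep crease candidates this far anterior of MLPA

    # projections / extreme-point rules
    tie_tolerance: float = 1e-6        # coordinate tolerance for extreme-point ties
    undersurface_normal_y: float = -0.2
    clavicle_bin_mm: float = 1.0       # x-bin width for clavicle reference lines

    # circle fitting
    min_circle_radius: float = 1.0     # below this the fit is flagged

    # AALP parameter conventions
    posteromedial_fraction: float = 0.2  # posterior band used for parameter b

    # statistics
    pairwise_method: str = "welch"     # welch | pooled
    bonferroni: bool = False
    ci_method: str = "both"            # percentile | normal | both
    alpha: float = 0.05

    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def config_hash(self) -> str:
        """Stable hash used in run logs for reproducibility bookkeeping."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
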