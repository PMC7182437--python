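"""Shared domain containers."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from trimesh import Trimesh

from .angles import ClinicalAngles

__all__ = ["KneeSample"]


@dataclass
class KneeSample:
    """A femur + tibia surface pair with landmarks and (optionally) the
    clinical angles and the generative parameters that produced it.

    Meshes are in mm in the package coordinate convention; ``side`` is the
    anatomical side of the knee as generated/imaged.  Landmark names follow
    :data:`kneessm.angles.REQUIRED_LANDMARKS`.
    """

    sample_id: str
    side: str  # "left" | "right"
    femur: Trimesh | None
    tibia: Trimesh | None
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)
    angles: ClinicalAngles | None = None
    params: Any = None  # GenerativeParams for synthetic samples

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        self.landmarks = {k: np.asarray(v, dtype=float)
                          for k, v in self.landmarks.items()}

    def copy(self) -> "KneeSample":
        return replace(
            self,
            femur=None if self.femur is None else self.femur.copy(),
            tibia=None if self.tibia is None else self.tibia.copy(),
            landmarks={k: v.copy() for k, v in self.landmarks.items()},
        )

    @property
    def has_meshes(self) -> bool:
        return self.femur is not None and self.tibia is not None

    def to_right(self) -> "KneeSample":
        """Return the right-side-convention version of this sample (left knees
        are mirrored medio-laterally; right knees are returned unchanged)."""
        if self.side == "right":
            return self
        from .mesh import mirror_ml  # local import avoids a cycle
        out = self.copy()
        if out.femur is not None:
            out.femur = mirror_ml(out.femur)
        if out.tibia is not None:
            out.tibia = mirror_ml(out.tibia)
        flip = np.array([-1.0, 1.0, 1.0])
        out.landmarks = {k: v * flip for k, v in out.landmarks.items()}
        out.side = "right"
        return out
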