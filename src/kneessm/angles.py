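"""Clinical knee-alignment angles from landmarks, stability labels, and
corrected deviations.

Five signed angles (degrees) describe the 3D tibio-femoral alignment:

* ``hka`` (alpha) - hip-knee-ankle: frontal-plane angle between the femoral and
  tibial mechanical axes; varus positive.
* ``fvv`` (beta) - femoral varus-valgus: frontal-plane angle of the femoral
  mechanical axis to the normal of the femoral joint line; valgus negative.
* ``tvv`` (gamma) - tibial varus-valgus, analogous with the tibial joint line.
  With parallel joint lines, beta + gamma = alpha exactly.
* ``ier`` (theta) - internal-external femoral rotation: axial-plane angle
  between the femoral epicondylar axis and the tibial medio-lateral plateau
  axis; external positive.
* ``ts`` (omega) - tibial slope: sagittal-plane angle of the antero-posterior
  plateau line to the normal of the tibial mechanical axis; posterior slope
  positive (physiological ~7 deg).

All angles are computed in an anatomical frame rebuilt from the landmarks
themselves (z = tibial mechanical axis, x = medio-lateral plateau axis
orthogonalized against z), so they are exactly invariant to any global rigid
motion of the landmark set.  Right-side convention throughout: left knees are
mirrored upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ANGLE_NAMES",
    "REQUIRED_LANDMARKS",
    "ClinicalAngles",
    "StabilityThresholds",
    "compute_angles",
    "label_stability",
    "corrected_deviation",
]

ANGLE_NAMES = ("hka", "fvv", "tvv", "ier", "ts")

REQUIRED_LANDMARKS = (
    "hip_center",
    "knee_center_femur",
    "knee_center_tibia",
    "med_distal_condyle",
    "lat_distal_condyle",
    "med_epicondyle",
    "lat_epicondyle",
    "med_plateau",
    "lat_plateau",
    "ant_plateau",
    "post_plateau",
    "ankle_center",
)


@dataclass(frozen=True)
class ClinicalAngles:
    """The five alignment angles in degrees, signed."""

    hka: float
    fvv: float
    tvv: float
    ier: float
    ts: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ANGLE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in ANGLE_NAMES])


# physiological center +- half-width, degrees
_DEFAULT_RANGES = {
    "hka": (0.0, 3.0),
    "fvv": (-6.0, 2.0),
    "ier": (0.0, 5.0),
    "tvv": (0.0, 5.0),
    "ts": (7.0, 4.0),
}


@dataclass(frozen=True)
class StabilityThresholds:
    """Per-angle normality ranges (center, half_width) in degrees.

    Defaults: HKA 0+-3, FVV -6+-2 (physiological valgum), IER 0+-5, TVV 0+-5,
    TS 7+-4.  A value on the boundary counts as stable (closed interval).
    """

    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RANGES))

    def __post_init__(self):
        for name, (center, half) in self.ranges.items():
            if name not in ANGLE_NAMES:
                raise ValueError(f"unknown angle {name!r}")
            if not half > 0:
                raise ValueError(f"half_width for {name} must be > 0")

    def center(self, name: str) -> float:
        return self.ranges[name][0]


def _validate(lm: dict) -> dict[str, np.ndarray]:
    out = {}
    for name in REQUIRED_LANDMARKS:
        if name not in lm:
            raise ValueError(f"missing landmark {name!r}")
        p = np.asarray(lm[name], dtype=float)
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise ValueError(f"landmark {name!r} is not a finite 3D point")
        out[name] = p
    return out


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError(f"degenerate landmark geometry: {what} has zero length")
    return v / n


def compute_angles(lm: dict) -> ClinicalAngles:
    """Compute the five clinical angles from a complete landmark set.

    Raises ``ValueError`` if a required landmark is missing or a defining
    landmark pair coincides.
    """
    lm = _validate(lm)
    # anatomical frame from the landmarks (rigid-motion invariant)
    z = _unit(lm["knee_center_tibia"] - lm["ankle_center"],
              "tibial mechanical axis (knee_center_tibia/ankle_center)")
    jt = lm["lat_plateau"] - lm["med_plateau"]
    jt_perp = jt - (jt @ z) * z
    x = _unit(jt_perp, "plateau medio-lateral axis (med_plateau/lat_plateau)")
    y = np.cross(z, x)
    basis = np.stack([x, y, z])  # rows

    def coords(v):
        return basis @ v

    def frontal(v):  # angle from +z toward +x, degrees
        c = coords(v)
        return np.degrees(np.arctan2(c[0], c[2]))

    u_f = _unit(lm["hip_center"] - lm["knee_center_femur"],
                "femoral mechanical axis (hip_center/knee_center_femur)")
    j_f = _unit(lm["lat_distal_condyle"] - lm["med_distal_condyle"],
                "femoral joint line (distal condyles)")
    epi = _unit(lm["lat_epicondyle"] - lm["med_epicondyle"],
                "epicondylar axis")
    ap = _unit(lm["ant_plateau"] - lm["post_plateau"],
               "plateau antero-posterior axis")

    # frontal plane: tibial axis is the frame z, so its frontal angle is 0
    alpha = frontal(u_f)
    beta = alpha - frontal(j_f) + 90.0
    jt_c = coords(jt)
    gamma = np.degrees(np.arctan2(jt_c[0], jt_c[2])) - 90.0
    # axial plane: plateau ML axis is the frame x (axial angle 0)
    e_c = coords(epi)
    theta = np.degrees(np.arctan2(e_c[1], e_c[0]))
    # sagittal plane: tibial-axis normal is the frame y
    a_c = coords(ap)
    omega = np.degrees(np.arctan2(a_c[2], a_c[1]))

    def wrap(a):
        return (a + 180.0) % 360.0 - 180.0

    return ClinicalAngles(hka=float(wrap(alpha)), fvv=float(wrap(beta)),
                          tvv=float(wrap(gamma)), ier=float(wrap(theta)),
                          ts=float(wrap(omega)))


def label_stability(angles: ClinicalAngles,
                    thresholds: StabilityThresholds | None = None) -> dict[str, bool]:
    """Per-angle stability labels: ``True`` = stable.

    Stable iff ``|angle - center| <= half_width`` (boundary counts as stable).
    """
    thresholds = thresholds or StabilityThresholds()
    out = {}
    for name, (center, half) in thresholds.ranges.items():
        out[name] = bool(abs(getattr(angles, name) - center) <= half)
    return out


def corrected_deviation(x: float, center: float) -> float:
    """Corrected clinical variable: absolute deviation from the physiological
    mean, ``|x - center|``, so that drift in either direction reads as
    increasing instability."""
    if not (np.isfinite(x) and np.isfinite(center)):
        raise ValueError("angle and center must be finite")
    return float(abs(x - center))
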