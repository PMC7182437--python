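"""Parametric synthetic tibio-femoral cohorts with known ground truth.

The generator builds a canonical right-side knee from smooth primitives (a
bent elliptic-cylinder femoral shaft ending in two condylar lobes separated by
an intercondylar groove, and a flattened elliptic tibial plateau tapering into
a shaft), deforms it per sample (global scale, shaft elongation and diameter,
frontal bend, condyle/plateau sizes), poses the femur relative to the tibia,
and adds per-vertex noise.  Landmarks are transported through the same maps
and stay noise-free, so every sample carries exact ground-truth clinical
angles.

The five pose/tilt parameters *are* the ground-truth angles (degrees):
``rel_frontal_rot`` = HKA, ``femoral_jointline_tilt`` = FVV,
``tibial_jointline_tilt`` = TVV, ``rel_axial_rot`` = IER, ``plateau_slope`` =
TS.  Because plane-projection angles do not compose exactly under fixed-order
3D rotations, the generator calibrates its internal rotations (femur global
frontal + axial, condylar intrinsic tilt, plateau frontal + sagittal tilt)
against :func:`kneessm.angles.compute_angles` with a Newton solve, making the
recorded ground truth exact to well below 1e-6 degrees.

The template is primitive-based, not anatomically scanned: downstream
validation rests on statistical and geometric structure, not on realism.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import mesh as meshmod
from .angles import ANGLE_NAMES, ClinicalAngles, compute_angles
from .core import KneeSample

__all__ = [
    "GenerativeParams",
    "ParamDist",
    "CohortSpec",
    "build_template",
    "apply_params",
    "sample_cohort",
    "write_cohort",
    "read_cohort",
    "DEFAULT_DISTRIBUTIONS",
]

# ---------------------------------------------------------------------------
# Canonical template constants (mm / degrees, right side, knee center at origin)
# ---------------------------------------------------------------------------

_T = dict(
    global_scale=1.0,
    femur_shaft_len=30.0,
    tibia_shaft_len=25.0,
    femur_shaft_diam=28.0,
    tibia_shaft_diam=24.0,
    femur_bend_frontal=0.0,
    tibia_bend_frontal=0.0,
    condyle_ap=64.0,
    condyle_ml=80.0,
    plateau_ap=52.0,
    plateau_ml=72.0,
    rel_frontal_rot=0.0,
    rel_axial_rot=0.0,
    plateau_slope=7.0,        # physiological tibial slope
    femoral_jointline_tilt=-6.0,  # physiological valgum
    tibial_jointline_tilt=0.0,
    noise_sd=0.0,
)

# geometry layout
_F_RIM = 10.0        # bottom rim of femoral tube
_F_CONE = 37.0       # top of the condylar/metaphyseal zone = shaft start
_F_CAP = 6.0         # distal cap depth scale
_T_KNEE = -8.0       # tibial knee center z
_T_TOP = -9.0        # plateau top surface
_T_RIM = -12.0       # top rim of tibial tube
_T_SHAFT0 = -30.0    # shaft start (plateau zone above)
_HIP_Z = 400.0
_ANKLE_Z = -360.0

_CROP_RANGES = {"femur_shaft_len": (20.0, 40.0), "tibia_shaft_len": (20.0, 30.0)}


@dataclass(frozen=True)
class GenerativeParams:
    """Latent parameters of one synthetic knee (lengths mm, angles degrees)."""

    global_scale: float = _T["global_scale"]
    femur_shaft_len: float = _T["femur_shaft_len"]
    tibia_shaft_len: float = _T["tibia_shaft_len"]
    femur_shaft_diam: float = _T["femur_shaft_diam"]
    tibia_shaft_diam: float = _T["tibia_shaft_diam"]
    femur_bend_frontal: float = _T["femur_bend_frontal"]
    tibia_bend_frontal: float = _T["tibia_bend_frontal"]
    condyle_ap: float = _T["condyle_ap"]
    condyle_ml: float = _T["condyle_ml"]
    plateau_ap: float = _T["plateau_ap"]
    plateau_ml: float = _T["plateau_ml"]
    rel_frontal_rot: float = _T["rel_frontal_rot"]
    rel_axial_rot: float = _T["rel_axial_rot"]
    plateau_slope: float = _T["plateau_slope"]
    femoral_jointline_tilt: float = _T["femoral_jointline_tilt"]
    tibial_jointline_tilt: float = _T["tibial_jointline_tilt"]
    noise_sd: float = 0.0
    side: str = "right"

    def __post_init__(self):
        vals = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)
                if f.name != "side"}
        for name, v in vals.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite parameter {name}={v}")
        for name in ("global_scale", "femur_shaft_len", "tibia_shaft_len",
                     "femur_shaft_diam", "tibia_shaft_diam", "condyle_ap",
                     "condyle_ml", "plateau_ap", "plateau_ml"):
            if vals[name] <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, (lo, hi) in _CROP_RANGES.items():
            if not lo <= vals[name] <= hi:
                raise ValueError(f"{name}={vals[name]} outside crop range [{lo}, {hi}]")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    def target_angles(self) -> ClinicalAngles:
        return ClinicalAngles(hka=self.rel_frontal_rot,
                              fvv=self.femoral_jointline_tilt,
                              tvv=self.tibial_jointline_tilt,
                              ier=self.rel_axial_rot,
                              ts=self.plateau_slope)


NEUTRAL_PARAMS = GenerativeParams()

_PARAM_NAMES = [f.name for f in dataclasses.fields(GenerativeParams)
                if f.name != "side"]


# ---------------------------------------------------------------------------
# Template surfaces
# ---------------------------------------------------------------------------

def _smoothstep(z, z0, z1):
    """0 at z<=z0, 1 at z>=z1, C1 in between (z0 < z1 or reversed for decay)."""
    t = np.clip((z - z0) / (z1 - z0), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _close_grid(rings, bottom_point=None, top_point=None):
    """Triangulate stacked rings (list of (n,3) arrays, same n, bottom->top)
    into a closed surface with optional pole fans."""
    n = len(rings[0])
    V = [np.asarray(r) for r in rings]
    verts = np.concatenate(V)
    faces = []
    for i in range(len(rings) - 1):
        a0, b0 = i * n, (i + 1) * n
        for j in range(n):
            k = (j + 1) % n
            faces.append([a0 + j, a0 + k, b0 + j])
            faces.append([a0 + k, b0 + k, b0 + j])
    if bottom_point is not None:
        bi = len(verts)
        verts = np.concatenate([verts, [bottom_point]])
        for j in range(n):
            k = (j + 1) % n
            faces.append([j, bi, k])
    if top_point is not None:
        ti = len(verts)
        verts = np.concatenate([verts, [top_point]])
        base = (len(rings) - 1) * n
        for j in range(n):
            k = (j + 1) % n
            faces.append([base + j, base + k, ti])
    return meshmod._as_mesh(verts, np.array(faces))


def _femur_mesh(n_theta: int, n_axial: int):
    """Symmetric canonical distal femur: condylar block + elliptic shaft."""
    th = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    cos, sin = np.cos(th), np.sin(th)
    z_top = _F_CONE + _T["femur_shaft_len"]

    def semi_axes(z):
        w = _smoothstep(z, _F_CONE * 0.55, _F_CONE)  # 0 condyles -> 1 shaft
        a = (_T["condyle_ml"] / 2) * (1 - w) + (_T["femur_shaft_diam"] / 2) * w
        b = (_T["condyle_ap"] / 2) * (1 - w) + (_T["femur_shaft_diam"] / 2) * w
        return a, b

    # distal cap: two condylar lobes at +-x, intercondylar groove along y
    lobe = 1.0 + 0.35 * np.cos(2 * th)
    groove = 0.55 * np.exp(-(cos ** 2) / 0.18) * np.exp(-(sin ** 2) / 1.2)
    depth = _F_CAP * (lobe - groove)
    n_cap = max(3, n_axial // 4)
    a0, b0 = semi_axes(_F_RIM)
    rings = []  # bottom -> top
    for psi in np.linspace(np.pi / 2 * 0.92, 0.0, n_cap, endpoint=False):
        s = np.cos(psi)
        rings.append(np.column_stack([
            a0 * s * cos, b0 * s * sin, _F_RIM - depth * np.sin(psi)]))
    # tube rows
    for z in np.linspace(_F_RIM, z_top, n_axial):
        a, b = semi_axes(z)
        rings.append(np.column_stack([a * cos, b * sin, np.full(n_theta, z)]))
    pole = np.array([0.0, 0.0, float(rings[0][:, 2].mean()) - 0.5])
    top = np.array([0.0, 0.0, z_top])
    return _close_grid(rings, bottom_point=pole, top_point=top)


def _tibia_mesh(n_theta: int, n_axial: int):
    """Symmetric canonical proximal tibia: flat elliptic plateau + shaft."""
    th = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    cos, sin = np.cos(th), np.sin(th)
    z_bot = _T_SHAFT0 - _T["tibia_shaft_len"]

    def semi_axes(z):
        w = _smoothstep(-z, -(_T_RIM + 6.0), -_T_SHAFT0)  # 0 plateau -> 1 shaft
        a = (_T["plateau_ml"] / 2) * (1 - w) + (_T["tibia_shaft_diam"] / 2) * w
        b = (_T["plateau_ap"] / 2) * (1 - w) + (_T["tibia_shaft_diam"] / 2) * w
        return a, b

    rings = []  # bottom -> top
    for z in np.linspace(z_bot, _T_RIM, n_axial):
        a, b = semi_axes(z)
        rings.append(np.column_stack([a * cos, b * sin, np.full(n_theta, z)]))
    # slightly domed plateau top
    n_cap = max(2, n_axial // 5)
    a0, b0 = semi_axes(_T_RIM)
    for psi in np.linspace(0.0, np.pi / 2 * 0.85, n_cap + 1)[1:]:
        s = np.cos(psi)
        rings.append(np.column_stack([
            a0 * s * cos, b0 * s * sin,
            np.full(n_theta, _T_RIM + (_T_TOP - _T_RIM) * np.sin(psi))]))
    top = np.array([0.0, 0.0, _T_TOP + 0.3])
    bot = np.array([0.0, 0.0, z_bot])
    return _close_grid(rings, bottom_point=bot, top_point=top)


def _template_landmarks() -> dict[str, np.ndarray]:
    return {
        "hip_center": np.array([0.0, 0.0, _HIP_Z]),
        "knee_center_femur": np.array([0.0, 0.0, 0.0]),
        "knee_center_tibia": np.array([0.0, 0.0, _T_KNEE]),
        "med_distal_condyle": np.array([-22.0, 0.0, 6.0]),
        "lat_distal_condyle": np.array([22.0, 0.0, 6.0]),
        "med_epicondyle": np.array([-_T["condyle_ml"] / 2, 0.0, 18.0]),
        "lat_epicondyle": np.array([_T["condyle_ml"] / 2, 0.0, 18.0]),
        "med_plateau": np.array([-_T["plateau_ml"] / 2, 0.0, _T_TOP]),
        "lat_plateau": np.array([_T["plateau_ml"] / 2, 0.0, _T_TOP]),
        "ant_plateau": np.array([0.0, _T["plateau_ap"] / 2, _T_TOP]),
        "post_plateau": np.array([0.0, -_T["plateau_ap"] / 2, _T_TOP]),
        "ankle_center": np.array([0.0, 0.0, _ANKLE_Z]),
    }


_FEMUR_LANDMARKS = ("hip_center", "knee_center_femur", "med_distal_condyle",
                    "lat_distal_condyle", "med_epicondyle", "lat_epicondyle")
_TIBIA_LANDMARKS = ("knee_center_tibia", "med_plateau", "lat_plateau",
                    "ant_plateau", "post_plateau", "ankle_center")
_CONDYLE_LANDMARKS = ("med_distal_condyle", "lat_distal_condyle",
                      "med_epicondyle", "lat_epicondyle")
_PLATEAU_LANDMARKS = ("med_plateau", "lat_plateau", "ant_plateau", "post_plateau")


def _raw_template(resolution: float) -> KneeSample:
    n_theta = max(12, int(round(30 * np.sqrt(resolution))))
    n_axial = max(8, int(round(26 * np.sqrt(resolution))))
    return KneeSample(sample_id="template", side="right",
                      femur=_femur_mesh(n_theta, n_axial),
                      tibia=_tibia_mesh(n_theta, n_axial),
                      landmarks=_template_landmarks(),
                      params=NEUTRAL_PARAMS)


def build_template(resolution: float = 1.0) -> KneeSample:
    """Canonical right-side neutral knee (~1000 vertices/bone at resolution 1).

    All generative angles are zero except the physiological neutral offsets
    TS = 7 deg and FVV = -6 deg, so the computed HKA/TVV/IER on the template
    are 0 and TS/FVV sit at the physiological centers.
    """
    return apply_params(_raw_template(resolution), NEUTRAL_PARAMS)


# ---------------------------------------------------------------------------
# Deformation + calibrated pose
# ---------------------------------------------------------------------------

def _rot_y(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _condyle_weight(z):
    return 1.0 - _smoothstep(z, _F_CONE * 0.55, _F_CONE)


def _plateau_weight(z):
    return 1.0 - _smoothstep(-z, -(_T_RIM + 6.0), -_T_SHAFT0)


def _deform_femur(pts, p: GenerativeParams):
    """Region scalings, elongation and frontal bend in canonical coordinates."""
    pts = pts.copy()
    z = pts[:, 2].copy()
    wc = _condyle_weight(z)
    ws = 1.0 - wc
    sx = 1.0 + (p.condyle_ml / _T["condyle_ml"] - 1.0) * wc \
        + (p.femur_shaft_diam / _T["femur_shaft_diam"] - 1.0) * ws
    sy = 1.0 + (p.condyle_ap / _T["condyle_ap"] - 1.0) * wc \
        + (p.femur_shaft_diam / _T["femur_shaft_diam"] - 1.0) * ws
    pts[:, 0] *= sx
    pts[:, 1] *= sy
    ratio = p.femur_shaft_len / _T["femur_shaft_len"]
    above = z > _F_CONE
    pts[above, 2] = _F_CONE + (z[above] - _F_CONE) * ratio
    if p.femur_bend_frontal != 0.0:
        L = p.femur_shaft_len
        kappa = np.tan(np.radians(p.femur_bend_frontal)) / (2.0 * L)
        dz = np.maximum(pts[:, 2] - _F_CONE, 0.0)
        pts[:, 0] += kappa * dz ** 2
    return pts


def _deform_tibia(pts, p: GenerativeParams):
    pts = pts.copy()
    z = pts[:, 2].copy()
    wp = _plateau_weight(z)
    ws = 1.0 - wp
    sx = 1.0 + (p.plateau_ml / _T["plateau_ml"] - 1.0) * wp \
        + (p.tibia_shaft_diam / _T["tibia_shaft_diam"] - 1.0) * ws
    sy = 1.0 + (p.plateau_ap / _T["plateau_ap"] - 1.0) * wp \
        + (p.tibia_shaft_diam / _T["tibia_shaft_diam"] - 1.0) * ws
    pts[:, 0] *= sx
    pts[:, 1] *= sy
    ratio = p.tibia_shaft_len / _T["tibia_shaft_len"]
    below = z < _T_SHAFT0
    pts[below, 2] = _T_SHAFT0 + (z[below] - _T_SHAFT0) * ratio
    if p.tibia_bend_frontal != 0.0:
        L = p.tibia_shaft_len
        kappa = np.tan(np.radians(p.tibia_bend_frontal)) / (2.0 * L)
        dz = np.minimum(pts[:, 2] - _T_SHAFT0, 0.0)
        pts[:, 0] += kappa * dz ** 2
    return pts


def _weighted_rotation(pts, R_fn, angle, weight, center):
    """Rotate points about ``center`` by ``angle * weight`` (per-point)."""
    out = pts - center
    # group by unique weights is overkill; apply per-point via angle blending
    ang = angle * weight
    if np.isscalar(ang):
        return (R_fn(ang) @ out.T).T + center
    res = np.empty_like(out)
    for a in np.unique(np.round(ang, 12)):
        m = np.isclose(ang, a, rtol=0, atol=1e-12)
        res[m] = (R_fn(a) @ out[m].T).T
    return res + center


def _pose_landmarks(lm0, q, fem_center, tib_center):
    """Apply the five internal rotations to a landmark dict (exact weights)."""
    a_front, c_axial, d_cond, g_plat, w_slope = q
    lm = {k: v.copy() for k, v in lm0.items()}
    Rc = _rot_y(d_cond)
    for name in _CONDYLE_LANDMARKS:
        lm[name] = Rc @ (lm[name] - fem_center) + fem_center
    Rf = _rot_y(a_front) @ _rot_z(c_axial)
    for name in _FEMUR_LANDMARKS:
        lm[name] = Rf @ (lm[name] - fem_center) + fem_center
    Rp = _rot_x(w_slope) @ _rot_y(g_plat)
    for name in _PLATEAU_LANDMARKS:
        lm[name] = Rp @ (lm[name] - tib_center) + tib_center
    return lm


def _solve_pose(lm0, targets: ClinicalAngles, fem_center, tib_center):
    t = targets.as_array()

    def residual(q):
        ang = compute_angles(_pose_landmarks(lm0, q, fem_center, tib_center))
        return ang.as_array() - t

    cur = compute_angles(lm0).as_array()
    d = np.radians(t - cur)
    x0 = np.array([d[0], d[3], -d[1], d[2], d[4]])
    sol = optimize.root(residual, x0, method="hybr", tol=1e-13)
    err = np.max(np.abs(residual(sol.x)))
    if err > 1e-9:
        raise RuntimeError(f"pose calibration did not converge (residual {err:.2e} deg)")
    return sol.x


def apply_params(template: KneeSample, p: GenerativeParams,
                 rng: np.random.Generator | None = None,
                 sample_id: str = "sample") -> KneeSample:
    """Deform the template into a sample with exact ground-truth angles.

    Fixed order: region scalings -> shaft elongation -> frontal bend ->
    global scale -> calibrated pose rotations -> vertex noise -> mirroring for
    left sides.  Landmarks ride through every map except the noise, so the
    recorded angles are exact.
    """
    if not isinstance(p, GenerativeParams):
        p = GenerativeParams(**p)
    lm = {k: v.copy() for k, v in template.landmarks.items()}
    fem_v = None if template.femur is None else np.asarray(template.femur.vertices, float)
    tib_v = None if template.tibia is None else np.asarray(template.tibia.vertices, float)

    # smooth shape deformations (canonical coordinates)
    if fem_v is not None:
        fem_v = _deform_femur(fem_v, p)
        tib_v = _deform_tibia(tib_v, p)
    for name in _FEMUR_LANDMARKS:
        lm[name] = _deform_femur(lm[name][None], p)[0]
    for name in _TIBIA_LANDMARKS:
        lm[name] = _deform_tibia(lm[name][None], p)[0]

    # global scale
    s = p.global_scale
    if fem_v is not None:
        fem_v *= s
        tib_v *= s
    for name in lm:
        lm[name] = lm[name] * s

    # calibrated pose rotations
    fem_center = lm["knee_center_femur"].copy()
    tib_center = lm["knee_center_tibia"].copy()
    q = _solve_pose(lm, p.target_angles(), fem_center, tib_center)
    a_front, c_axial, d_cond, g_plat, w_slope = q
    lm = _pose_landmarks(lm, q, fem_center, tib_center)
    if fem_v is not None:
        zc = fem_v[:, 2] / s  # zone weights live in canonical coordinates
        wc = _condyle_weight(zc)
        fem_v = _weighted_rotation(fem_v, _rot_y, d_cond, wc, fem_center)
        Rf = _rot_y(a_front) @ _rot_z(c_axial)
        fem_v = (Rf @ (fem_v - fem_center).T).T + fem_center
        zt = tib_v[:, 2] / s
        wp = _plateau_weight(zt)
        tib_v = _weighted_rotation(tib_v, _rot_y, g_plat, wp, tib_center)
        tib_v = _weighted_rotation(tib_v, _rot_x, w_slope, wp, tib_center)

    # noise on mesh vertices only (landmark ground truth stays exact)
    if p.noise_sd > 0 and fem_v is not None:
        rng = rng or np.random.default_rng(0)
        fem_v = fem_v + rng.normal(0.0, p.noise_sd, fem_v.shape)
        tib_v = tib_v + rng.normal(0.0, p.noise_sd, tib_v.shape)

    fem_faces = None if template.femur is None else template.femur.faces
    tib_faces = None if template.tibia is None else template.tibia.faces
    # left side: mirror medio-laterally; medial/lateral labels follow anatomy
    if p.side == "left":
        if fem_v is not None:
            fem_v = fem_v.copy()
            fem_v[:, 0] *= -1.0
            tib_v = tib_v.copy()
            tib_v[:, 0] *= -1.0
            fem_faces = fem_faces[:, ::-1]
            tib_faces = tib_faces[:, ::-1]
        for name in lm:
            lm[name] = lm[name] * np.array([-1.0, 1.0, 1.0])

    femur = None if fem_v is None else meshmod._as_mesh(fem_v, fem_faces)
    tibia = None if tib_v is None else meshmod._as_mesh(tib_v, tib_faces)
    return KneeSample(sample_id=sample_id, side=p.side, femur=femur,
                      tibia=tibia, landmarks=lm, angles=p.target_angles(),
                      params=p)


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamDist:
    """Truncated-normal distribution of one generative parameter."""

    mean: float
    sd: float
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    def bounds(self) -> tuple[float, float]:
        lo = self.mean - 3.0 * self.sd if self.lower is None else self.lower
        hi = self.mean + 3.0 * self.sd if self.upper is None else self.upper
        return lo, hi

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        lo, hi = self.bounds()
        a, b = (lo - self.mean) / self.sd, (hi - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   size=n, random_state=rng)


# Defaults chosen so the stable/unstable class fractions under the printed
# normality ranges roughly echo a pathological surgical cohort; truncation at
# +-3 SD avoids self-intersecting meshes.
DEFAULT_DISTRIBUTIONS: dict[str, ParamDist] = {
    "global_scale": ParamDist(1.0, 0.04),
    "femur_shaft_len": ParamDist(30.0, 3.0, 20.0, 40.0),
    "tibia_shaft_len": ParamDist(25.0, 1.6, 20.0, 30.0),
    "femur_shaft_diam": ParamDist(28.0, 1.5),
    "tibia_shaft_diam": ParamDist(24.0, 1.3),
    "femur_bend_frontal": ParamDist(0.0, 1.5),
    "tibia_bend_frontal": ParamDist(0.0, 1.2),
    "condyle_ap": ParamDist(64.0, 3.0),
    "condyle_ml": ParamDist(80.0, 4.0),
    "plateau_ap": ParamDist(52.0, 3.0),
    "plateau_ml": ParamDist(72.0, 4.0),
    "rel_frontal_rot": ParamDist(0.0, 6.0, -15.0, 15.0),
    "rel_axial_rot": ParamDist(0.0, 3.5),
    "plateau_slope": ParamDist(7.0, 4.0),
    "femoral_jointline_tilt": ParamDist(-6.0, 4.0),
    "tibial_jointline_tilt": ParamDist(0.0, 4.0),
    "noise_sd": ParamDist(0.2, 0.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort draw."""

    n: int
    seed: int = 0
    distributions: dict[str, ParamDist] = field(
        default_factory=lambda: dict(DEFAULT_DISTRIBUTIONS))
    fraction_left: float = 0.5
    resolution: float = 1.0
    include_meshes: bool = True

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("n must be >= 3 (PCA needs at least 2 modes)")
        if not 0.0 <= self.fraction_left <= 1.0:
            raise ValueError("fraction_left must be in [0, 1]")
        unknown = set(self.distributions) - set(_PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")

    def with_overrides(self, **dists: ParamDist) -> "CohortSpec":
        d = dict(self.distributions)
        d.update(dists)
        return dataclasses.replace(self, distributions=d)


def draw_params(spec: CohortSpec) -> list[GenerativeParams]:
    """Draw the per-sample generative parameters (deterministic in the seed)."""
    rng = np.random.default_rng(spec.seed)
    dists = dict(DEFAULT_DISTRIBUTIONS)
    dists.update(spec.distributions)
    cols = {name: dists[name].draw(rng, spec.n) for name in _PARAM_NAMES}
    sides = np.where(rng.random(spec.n) < spec.fraction_left, "left", "right")
    out = []
    for i in range(spec.n):
        kw = {name: float(cols[name][i]) for name in _PARAM_NAMES}
        out.append(GenerativeParams(side=str(sides[i]), **kw))
    return out


def sample_cohort(spec: CohortSpec) -> list[KneeSample]:
    """Generate ``spec.n`` samples; identical seed => identical cohort.

    With ``include_meshes=False`` only landmarks/angles/parameters are
    produced (fast path for statistical checks on large n).
    """
    params = draw_params(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    template = _raw_template(spec.resolution) if spec.include_meshes else \
        KneeSample(sample_id="template", side="right", femur=None, tibia=None,
                   landmarks=_template_landmarks())
    out = []
    for i, p in enumerate(params):
        out.append(apply_params(template, p, rng=rng, sample_id=f"s{i:03d}"))
    return out


def latent_study_cohort(seed: int, n: int = 20, resolution: float = 1.0,
                        noise_sd: float = 0.2,
                        hka_mode: str = "continuous") -> list[KneeSample]:
    """The package's reference validation cohort: five latent parameters.

    Only global scale, femoral shaft length, frontal knee rotation, axial
    rotation and tibial slope vary; all other parameters are frozen at their
    canonical values.  Vertex noise defaults to 0.2 mm.  The frontal rotation
    (the HKA ground truth) is drawn either

    * ``hka_mode='continuous'``: from its default truncated normal
      (N(0, 6 deg), +-15 deg) — used for latent-recovery checks where rank
      resolution across the whole range matters; or
    * ``hka_mode='separated'``: bimodally, a stable class near 0 deg and an
      unstable class centered at +6 deg (twice the 3-deg normality
      half-width), so half the cohort is unstable by HKA with a clear
      geometric margin — used for classification checks.

    Samples are returned in right-side convention.
    """
    fixed = {name: ParamDist(d.mean, 0.0)
             for name, d in DEFAULT_DISTRIBUTIONS.items()}
    shared = dict(fixed)
    shared["global_scale"] = ParamDist(1.0, 0.04)
    shared["femur_shaft_len"] = ParamDist(30.0, 3.0, 20.0, 40.0)
    shared["rel_axial_rot"] = ParamDist(0.0, 3.5)
    shared["plateau_slope"] = ParamDist(7.0, 4.0)
    shared["noise_sd"] = ParamDist(noise_sd, 0.0)
    if hka_mode == "continuous":
        shared["rel_frontal_rot"] = DEFAULT_DISTRIBUTIONS["rel_frontal_rot"]
        specs = [CohortSpec(n=n, seed=seed * 2 + 1, distributions=shared,
                            resolution=resolution)]
    elif hka_mode == "separated":
        stable = dict(shared)
        stable["rel_frontal_rot"] = ParamDist(0.0, 1.0)
        unstable = dict(shared)
        unstable["rel_frontal_rot"] = ParamDist(6.0, 1.0)
        specs = [CohortSpec(n=n // 2, seed=seed * 2 + 1, distributions=stable,
                            resolution=resolution),
                 CohortSpec(n=n - n // 2, seed=seed * 2 + 2,
                            distributions=unstable, resolution=resolution)]
    else:
        raise ValueError("hka_mode must be 'continuous' or 'separated'")
    out = []
    i = 0
    for spec in specs:
        for s in sample_cohort(spec):
            s.sample_id = f"s{i:03d}"
            out.append(s.to_right())
            i += 1
    return out


# ---------------------------------------------------------------------------
# Cohort directory I/O
# ---------------------------------------------------------------------------

def write_cohort(samples: list[KneeSample], outdir) -> None:
    """Write one PLY per bone plus cohort.csv and landmarks.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows, lrows = [], []
    for s in samples:
        if s.has_meshes:
            meshmod.write_mesh(s.femur, outdir / f"{s.sample_id}_femur.ply")
            meshmod.write_mesh(s.tibia, outdir / f"{s.sample_id}_tibia.ply")
        row = {"id": s.sample_id, "side": s.side}
        if s.angles is not None:
            row.update({k: getattr(s.angles, k) for k in ANGLE_NAMES})
        if isinstance(s.params, GenerativeParams):
            row.update({n: getattr(s.params, n) for n in _PARAM_NAMES})
        rows.append(row)
        for name, pt in s.landmarks.items():
            lrows.append({"id": s.sample_id, "landmark_name": name,
                          "x": pt[0], "y": pt[1], "z": pt[2]})
    pd.DataFrame(rows).to_csv(outdir / "cohort.csv", index=False)
    pd.DataFrame(lrows).to_csv(outdir / "landmarks.csv", index=False)


def read_cohort(indir, load_meshes: bool = True) -> list[KneeSample]:
    """Read a cohort directory written by :func:`write_cohort` (or assembled
    by hand from per-subject meshes plus the two CSV tables)."""
    indir = Path(indir)
    tab = pd.read_csv(indir / "cohort.csv")
    lms = pd.read_csv(indir / "landmarks.csv")
    out = []
    for _, row in tab.iterrows():
        sid = str(row["id"])
        femur = tibia = None
        fp = indir / f"{sid}_femur.ply"
        if load_meshes and fp.exists():
            femur = meshmod.read_mesh(fp)
            tibia = meshmod.read_mesh(indir / f"{sid}_tibia.ply")
        sub = lms[lms["id"].astype(str) == sid]
        lm = {r["landmark_name"]: np.array([r["x"], r["y"], r["z"]])
              for _, r in sub.iterrows()}
        ang = None
        if all(k in row for k in ANGLE_NAMES) and np.isfinite(row["hka"]):
            ang = ClinicalAngles(**{k: float(row[k]) for k in ANGLE_NAMES})
        out.append(KneeSample(sample_id=sid, side=str(row["side"]),
                              femur=femur, tibia=tibia, landmarks=lm, angles=ang))
    return out
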