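"""Rigid pair alignment, coherent point drift, and dense correspondences.

Each femur+tibia pair is aligned to the reference pair with a single rigid
transform (rotation + translation, never scale), so the relative pose and the
joint space between the two bones of a sample are preserved.  Deformable
registration is then run separately per bone with coherent point drift (CPD):
a Gaussian-kernel motion field fitted by expectation-maximization moves the
reference vertices toward the sample, and each deformed reference vertex is
projected onto the sample surface.  Correspondences are therefore always
reference-indexed: every sample contributes exactly P = (reference femur
vertices + reference tibia vertices) corresponding points, in fixed order.

The CPD implementation follows the standard Gaussian-mixture formulation with
an optional uniform outlier component.  For large point sets the kernel is
replaced by its truncated eigendecomposition; the approximation is used
consistently in the E-step, the M-step and the regularization penalty, so the
EM objective remains monotone for the approximated model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .core import KneeSample
from .mesh import point_surface_distance

__all__ = [
    "RigidTransform",
    "CPDConfig",
    "CPDResult",
    "CorrespondenceSet",
    "rigid_align_pair",
    "cpd_register",
    "correspond",
    "build_correspondences",
    "select_reference",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: x -> R x + t (no scale)."""

    rotation: np.ndarray  # (3,3), det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with det +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class CPDConfig:
    """Coherent-point-drift settings.

    beta: Gaussian kernel width (mm) controlling motion-field smoothness;
    lam: regularization weight trading data fit against coherence;
    w: expected outlier fraction in [0, 1);
    low_rank: kernel eigenmodes kept for point sets above ``low_rank_min``
    points (the full kernel is used below that size).
    """

    beta: float = 2.0
    lam: float = 3.0
    w: float = 0.1
    max_iter: int = 150
    tol: float = 1e-5
    low_rank: int = 60
    low_rank_min: int = 500

    def __post_init__(self):
        if self.beta <= 0 or self.lam <= 0 or self.tol <= 0:
            raise ValueError("beta, lam and tol must be > 0")
        if not 0.0 <= self.w < 1.0:
            raise ValueError("w must be in [0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class CPDResult:
    points: np.ndarray          # deformed source, (M,3)
    log_likelihood: np.ndarray  # penalized log-likelihood trace per EM step
    sigma2: float
    converged: bool


# ---------------------------------------------------------------------------
# Rigid alignment
# ---------------------------------------------------------------------------

def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rotation+translation mapping src onto dst (no scale)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    S = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ S @ U.T
    return RigidTransform(R, cd - R @ cs)


def _principal_axes_init(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    def axes(pts):
        c = pts.mean(axis=0)
        _, _, Vt = np.linalg.svd(pts - c, full_matrices=False)
        # sign-fix axes by skewness along each axis for determinism
        proj = (pts - c) @ Vt.T
        sk = np.sign(np.sum(proj ** 3, axis=0))
        sk[sk == 0] = 1.0
        A = Vt * sk[:, None]
        if np.linalg.det(A) < 0:
            A[2] *= -1
        return c, A

    cs, As = axes(src)
    cd, Ad = axes(dst)
    R = Ad.T @ As
    return RigidTransform(R, cd - R @ cs)


def rigid_align_pair(sample: KneeSample, reference: KneeSample,
                     max_iter: int = 60, tol: float = 1e-10,
                     n_points: int = 1500) -> tuple[RigidTransform, KneeSample]:
    """Rigidly register a femur+tibia pair to the reference pair.

    One rotation+translation is fitted to the concatenated two-bone cloud
    (iterative closest point with a Procrustes inner step), so the femur-tibia
    relative pose of the sample is untouched.  Initialization uses landmark
    Procrustes when both samples carry landmarks, else centroid + principal
    axes.  Never fits scale.  Returns the transform and the transformed
    sample; ``converged`` failures still return the best transform found.
    """
    if not (sample.has_meshes and reference.has_meshes):
        raise ValueError("both samples must contain femur and tibia meshes")
    src = np.vstack([sample.femur.vertices, sample.tibia.vertices])
    dst = np.vstack([reference.femur.vertices, reference.tibia.vertices])

    common = sorted(set(sample.landmarks) & set(reference.landmarks))
    if len(common) >= 3:
        T = _kabsch(np.array([sample.landmarks[k] for k in common]),
                    np.array([reference.landmarks[k] for k in common]))
    else:
        T = _principal_axes_init(src, dst)

    if len(src) > n_points:
        step = len(src) // n_points
        src_icp = src[::step]
    else:
        src_icp = src
    tree = cKDTree(dst)
    prev = np.inf
    for _ in range(max_iter):
        moved = T.apply(src_icp)
        d, idx = tree.query(moved)
        T_new = _kabsch(moved, dst[idx])
        T = T_new.compose(T)
        res = float(np.mean(d ** 2))
        if abs(prev - res) <= tol * max(res, 1.0):
            break
        prev = res

    out = sample.copy()
    out.femur.vertices = T.apply(out.femur.vertices)
    out.tibia.vertices = T.apply(out.tibia.vertices)
    out.landmarks = {k: T.apply(v) for k, v in out.landmarks.items()}
    return T, out


# ---------------------------------------------------------------------------
# Coherent point drift
# ---------------------------------------------------------------------------

class CPDVarianceCollapse(RuntimeError):
    """The mixture variance collapsed to a non-finite value."""


def _gaussian_kernel(Y: np.ndarray, beta: float) -> np.ndarray:
    d2 = np.sum((Y[:, None, :] - Y[None, :, :]) ** 2, axis=2)
    return np.exp(-d2 / (2.0 * beta ** 2))


def cpd_register(source: np.ndarray, target: np.ndarray,
                 cfg: CPDConfig | None = None) -> CPDResult:
    """Non-rigid CPD: deform ``source`` toward ``target``.

    Returns the deformed source points and the penalized log-likelihood trace,
    which is monotone non-decreasing (to numerical tolerance) per EM step.
    """
    cfg = cfg or CPDConfig()
    Y = np.asarray(source, dtype=float)
    X = np.asarray(target, dtype=float)
    if Y.ndim != 2 or X.ndim != 2 or Y.shape[1] != 3 or X.shape[1] != 3:
        raise ValueError("source and target must be (n, 3) arrays")
    M, N, D = len(Y), len(X), 3
    if M < 10 or N < 10:
        raise ValueError("need at least 10 points in source and target")

    # work in a shared zero-mean, unit-RMS frame: beta is then expressed in
    # units of the cloud radius, as in the classic formulation
    center = np.vstack([X, Y]).mean(axis=0)
    scale = float(np.sqrt(np.mean(np.sum((np.vstack([X, Y]) - center) ** 2, axis=1))))
    scale = scale if scale > 0 else 1.0
    X = (X - center) / scale
    Y = (Y - center) / scale

    G = _gaussian_kernel(Y, cfg.beta)
    use_lowrank = M > cfg.low_rank_min and cfg.low_rank < M
    if use_lowrank:
        K = cfg.low_rank
        evals, evecs = np.linalg.eigh(G)
        Lam = np.maximum(evals[-K:], 1e-12)
        Qm = evecs[:, -K:]
        # the truncated kernel is used consistently everywhere below
        G = (Qm * Lam) @ Qm.T

    sigma2 = np.sum((X[None, :, :] - Y[:, None, :]) ** 2) / (D * M * N)
    span = X.max(axis=0) - X.min(axis=0)
    volume = float(np.prod(np.where(span > 0, span, 1.0)))
    W = np.zeros((M, D))
    trace = []
    converged = False
    for _ in range(cfg.max_iter):
        T = Y + G @ W
        d2 = np.sum((X[None, :, :] - T[:, None, :]) ** 2, axis=2)  # (M,N)
        gauss = np.exp(-d2 / (2.0 * sigma2)) * (2.0 * np.pi * sigma2) ** (-D / 2.0)
        mix = (1.0 - cfg.w) / M * np.sum(gauss, axis=0) + cfg.w / (N * volume)
        mix = np.maximum(mix, 1e-300)
        penalty = 0.5 * cfg.lam * float(np.sum(W * (G @ W)))
        ll = float(np.sum(np.log(mix))) - penalty
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < cfg.tol * abs(trace[-2] if trace[-2] != 0 else 1.0):
            converged = True
            break
        P = (1.0 - cfg.w) / M * gauss / mix[None, :]
        p1 = P.sum(axis=1)                      # (M,)
        pt1 = P.sum(axis=0)                     # (N,)
        Np = float(p1.sum())
        PX = P @ X
        rhs = PX - p1[:, None] * Y
        reg = cfg.lam * sigma2
        if use_lowrank:
            # Woodbury solve of (reg I + diag(p1) Q Lam Q^T) W = rhs
            dQ = p1[:, None] * Qm
            A = np.diag(reg / Lam) + Qm.T @ dQ
            W = (rhs - dQ @ np.linalg.solve(A, Qm.T @ rhs)) / reg
        else:
            A = G * p1[:, None] + reg * np.eye(M)
            W = np.linalg.solve(A, rhs)
        T = Y + G @ W
        xPx = float(pt1 @ np.sum(X ** 2, axis=1))
        trPXT = float(np.sum(PX * T))
        tTt = float(p1 @ np.sum(T ** 2, axis=1))
        sigma2 = (xPx - 2.0 * trPXT + tTt) / (Np * D)
        if not np.isfinite(sigma2):
            raise CPDVarianceCollapse("CPD mixture variance became non-finite")
        if sigma2 < 1e-10:
            sigma2 = 1e-10
            converged = True
            trace.append(ll)
            break
    return CPDResult(points=(Y + G @ W) * scale + center,
                     log_likelihood=np.array(trace),
                     sigma2=float(sigma2) * scale ** 2, converged=converged)


# ---------------------------------------------------------------------------
# Correspondences
# ---------------------------------------------------------------------------

def correspond(reference_bone, sample_bone, cfg: CPDConfig | None = None,
               gate_mm: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Reference-indexed corresponding points on a sample bone.

    CPD deforms the reference vertices toward the sample; each deformed vertex
    is then projected to its closest point on the sample surface.  Projections
    farther than ``gate_mm`` are flagged as outliers and keep the deformed
    position.  Returns ``(points, outlier_mask)`` with exactly one point per
    reference vertex, in reference order.
    """
    cfg = cfg or CPDConfig()
    res = cpd_register(np.asarray(reference_bone.vertices, float),
                       np.asarray(sample_bone.vertices, float), cfg)
    dists, proj = point_surface_distance(res.points, sample_bone,
                                         return_points=True)
    outliers = dists > gate_mm
    pts = proj.copy()
    pts[outliers] = res.points[outliers]
    return pts, outliers


@dataclass
class CorrespondenceSet:
    """Cohort of reference-indexed corresponding points.

    ``points`` is (n_samples, P, 3) in the common reference frame with the
    femur block first; ``n_femur`` marks the bone partition.
    """

    ids: list[str]
    points: np.ndarray
    n_femur: int
    reference_id: str
    transforms: list[RigidTransform] = field(default_factory=list)
    outlier_fraction: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 3:
            raise ValueError("points must be (n_samples, P, 3)")
        if len(self.ids) != len(self.points):
            raise ValueError("ids and points disagree in length")
        if not 0 <= self.n_femur <= self.points.shape[1]:
            raise ValueError("invalid bone partition")

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    @property
    def n_points(self) -> int:
        return self.points.shape[1]

    def as_matrix(self) -> np.ndarray:
        """(n_samples, 3P) flattened shape vectors."""
        return self.points.reshape(self.n_samples, -1)

    def save(self, prefix) -> None:
        """Matrix file (rows = samples, columns = 3P) + JSON sidecar."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        np.savetxt(prefix.with_suffix(".tsv"), self.as_matrix(), delimiter="\t")
        meta = {
            "ids": self.ids,
            "n_femur": int(self.n_femur),
            "n_points": int(self.n_points),
            "reference_id": self.reference_id,
            "transforms": [{"rotation": t.rotation.tolist(),
                            "translation": t.translation.tolist()}
                           for t in self.transforms],
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix) -> "CorrespondenceSet":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        mat = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
        pts = mat.reshape(len(meta["ids"]), meta["n_points"], 3)
        tf = [RigidTransform(np.array(t["rotation"]), np.array(t["translation"]))
              for t in meta["transforms"]]
        return cls(ids=meta["ids"], points=pts, n_femur=meta["n_femur"],
                   reference_id=meta["reference_id"], transforms=tf)


def select_reference(samples: list[KneeSample], thresholds=None,
                     reference_id: str | None = None) -> KneeSample:
    """Pick the reference pair: the sample whose five angles deviate least
    (summed absolute deviation) from the physiological centers — a
    deterministic analogue of randomly picking a low-deformity sample.
    Override by id."""
    from .angles import ANGLE_NAMES, StabilityThresholds, compute_angles
    if reference_id is not None:
        for s in samples:
            if s.sample_id == reference_id:
                return s
        raise ValueError(f"no sample with id {reference_id!r}")
    thresholds = thresholds or StabilityThresholds()
    best, best_score = None, np.inf
    for s in samples:
        ang = s.angles or compute_angles(s.landmarks)
        score = sum(abs(getattr(ang, n) - thresholds.center(n))
                    for n in ANGLE_NAMES)
        if score < best_score:
            best, best_score = s, score
    return best


def build_correspondences(cohort: list[KneeSample], reference: KneeSample,
                          cfg: CPDConfig | None = None, gate_mm: float = 5.0,
                          on_error: str = "report") -> CorrespondenceSet:
    """Rigid pair alignment then per-bone correspondence for every sample.

    All samples must already be in the right-side convention.  Deterministic
    given inputs and configuration.  A failing sample is reported (and
    skipped) unless ``on_error='raise'``.
    """
    cfg = cfg or CPDConfig()
    for s in cohort:
        if s.side != "right":
            raise ValueError(f"sample {s.sample_id} is not right-side; mirror first")
    n_femur = len(reference.femur.vertices)
    ids, rows, tfs, outfrac = [], [], [], []
    failures = []
    for s in cohort:
        try:
            T, aligned = rigid_align_pair(s, reference)
            fpts, fout = correspond(reference.femur, aligned.femur, cfg, gate_mm)
            tpts, tout = correspond(reference.tibia, aligned.tibia, cfg, gate_mm)
            rows.append(np.vstack([fpts, tpts]))
            tfs.append(T)
            outfrac.append((fout.sum() + tout.sum()) / (len(fout) + len(tout)))
            ids.append(s.sample_id)
        except Exception as exc:  # noqa: BLE001 - per-sample isolation
            if on_error == "raise":
                raise
            failures.append((s.sample_id, str(exc)))
    if failures:
        import warnings
        warnings.warn("correspondence failed for: "
                      + "; ".join(f"{i} ({m})" for i, m in failures))
    return CorrespondenceSet(ids=ids, points=np.array(rows), n_femur=n_femur,
                             reference_id=reference.sample_id, transforms=tfs,
                             outlier_fraction=np.array(outfrac))
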