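"""PCA shape space over dense correspondences.

A cohort of M samples, each represented by the same P reference-indexed
points, is stacked as M flat vectors of length 3P.  The model holds the mean
shape m, orthonormal modes of variation v_i, and mode standard deviations
sigma_i (mm), giving at most M-1 non-zero modes.  Conventions:

* explained variance of mode j:  EV_j = sigma_j^2 / sum_i sigma_i^2
* morphing (reconstruction):     s = m + sum_i lambda_i sigma_i v_i
* projection (weights):          lambda_i = v_i . (s - m) / sigma_i

so weights are unitless, in SD units; lambda = 0 is the mean shape.  The
eigendecomposition runs on the M x M Gram matrix (covariance divisor M-1),
which is exact and cheap even for P in the thousands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .registration import CorrespondenceSet

__all__ = [
    "SSMModel",
    "fit_ssm",
    "explained_variance",
    "n_modes_for",
    "morph",
    "project",
    "reconstruction_errors",
]


@dataclass
class SSMModel:
    """Statistical shape model: mean + orthonormal modes + mode SDs."""

    mean: np.ndarray            # (3P,)
    modes: np.ndarray           # (n_modes, 3P), orthonormal rows
    sigma: np.ndarray           # (n_modes,), mm, descending
    n_samples: int
    n_femur: int                # bone partition: first n_femur points = femur
    reference_id: str = ""

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.modes = np.asarray(self.modes, dtype=float).reshape(-1, self.mean.size)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if len(self.sigma) != len(self.modes):
            raise ValueError("sigma and modes disagree in count")
        if np.any(self.sigma < 0) or np.any(np.diff(self.sigma) > 1e-12):
            raise ValueError("sigma must be nonnegative and descending")

    @property
    def n_modes(self) -> int:
        return len(self.sigma)

    @property
    def explained_variance(self) -> np.ndarray:
        return explained_variance(self.sigma)

    def n_modes_for(self, threshold: float = 0.95) -> int:
        return n_modes_for(self.explained_variance, threshold)

    def mean_points(self) -> np.ndarray:
        return self.mean.reshape(-1, 3)

    def save(self, path) -> None:
        """Single .npz archive: mean, modes, sigma, partition, provenance."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path, mean=self.mean, modes=self.modes,
                            sigma=self.sigma,
                            meta=json.dumps({"n_samples": self.n_samples,
                                             "n_femur": self.n_femur,
                                             "reference_id": self.reference_id}))

    @classmethod
    def load(cls, path) -> "SSMModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            return cls(mean=z["mean"], modes=z["modes"], sigma=z["sigma"],
                       n_samples=meta["n_samples"], n_femur=meta["n_femur"],
                       reference_id=meta["reference_id"])


def fit_ssm(corr: CorrespondenceSet) -> SSMModel:
    """Fit the shape space: mean + eigendecomposition of the sample covariance.

    Uses the M x M Gram trick (equivalent to the dense 3P x 3P covariance
    eigendecomposition); rank-0 data yields a valid model with zero modes.
    Mode signs are fixed by making each mode's largest-magnitude component
    positive, so fits are deterministic.
    """
    X = corr.as_matrix()
    M = X.shape[0]
    if M < 3:
        raise ValueError("need at least 3 samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    gram = Xc @ Xc.T / (M - 1)
    evals, evecs = np.linalg.eigh(gram)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    # relative rank cut plus an absolute floor (sigma ~1e-8 mm is noise for
    # mm-scale geometry, e.g. byte-identical shapes after registration)
    tol = max(max(evals[0], 0.0) * 1e-10, 1e-16)
    keep = evals > tol
    evals, evecs = evals[keep], evecs[:, keep]
    sigma = np.sqrt(evals)
    if len(sigma):
        modes = (Xc.T @ evecs) / (sigma * np.sqrt(M - 1))
        modes = modes.T  # rows
        flip = np.sign(modes[np.arange(len(modes)),
                             np.argmax(np.abs(modes), axis=1)])
        modes *= flip[:, None]
    else:
        modes = np.zeros((0, X.shape[1]))
    return SSMModel(mean=mean, modes=modes, sigma=sigma, n_samples=M,
                    n_femur=corr.n_femur, reference_id=corr.reference_id)


def explained_variance(sigma) -> np.ndarray:
    """EV_j = sigma_j^2 / sum_i sigma_i^2 (proportions summing to 1)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be nonnegative")
    total = float(np.sum(sigma ** 2))
    if total == 0:
        raise ValueError("all mode SDs are zero")
    return sigma ** 2 / total


def n_modes_for(ev, threshold: float) -> int:
    """Smallest k whose cumulative explained variance reaches the threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    cum = np.cumsum(np.asarray(ev, dtype=float))
    idx = np.searchsorted(cum, threshold - 1e-12)
    return int(min(idx + 1, len(cum)))


def morph(model: SSMModel, weights) -> np.ndarray:
    """Shape vector m + sum_i lambda_i sigma_i v_i; lambda = 0 gives the mean."""
    lam = np.atleast_1d(np.asarray(weights, dtype=float))
    if len(lam) > model.n_modes:
        raise ValueError("more weights than modes")
    k = len(lam)
    return model.mean + (lam * model.sigma[:k]) @ model.modes[:k]


def project(model: SSMModel, shape_vector, n_modes: int | None = None) -> np.ndarray:
    """Weights lambda_i = v_i . (s - m) / sigma_i for the retained modes.

    Modes with sigma = 0 (none under the fit tolerance, but possible in
    hand-built models) get weight 0.
    """
    s = np.asarray(shape_vector, dtype=float).ravel()
    if s.size != model.mean.size:
        raise ValueError("shape vector has wrong length")
    k = model.n_modes if n_modes is None else min(n_modes, model.n_modes)
    coef = model.modes[:k] @ (s - model.mean)
    sig = model.sigma[:k]
    lam = np.zeros(k)
    nz = sig > 0
    lam[nz] = coef[nz] / sig[nz]
    return lam


def reconstruction_errors(model: SSMModel, corr: CorrespondenceSet,
                          k_modes: int | None = None) -> dict:
    """Project every sample, rebuild with k modes, compare to its points.

    Distances are point-to-point on the shared reference indexing: per sample
    the maximum (Hausdorff over corresponding points), mean, and rms of
    per-point deviations (mm), plus cohort mean +- SD of each.  The rms is the
    L2 reconstruction error and is guaranteed non-increasing in k.
    """
    k = model.n_modes if k_modes is None else k_modes
    if k > model.n_modes:
        raise ValueError("k_modes exceeds available modes")
    X = corr.as_matrix()
    per = {"hausdorff": [], "mean": [], "rms": []}
    for s in X:
        lam = project(model, s, n_modes=k)
        rec = morph(model, lam)
        d = np.linalg.norm((s - rec).reshape(-1, 3), axis=1)
        per["hausdorff"].append(float(d.max()))
        per["mean"].append(float(d.mean()))
        per["rms"].append(float(np.sqrt(np.mean(d ** 2))))
    out = {key: np.array(v) for key, v in per.items()}
    summary = {f"{key}_mean": float(v.mean()) for key, v in out.items()}
    summary.update({f"{key}_sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0
                    for key, v in out.items()})
    out["summary"] = summary
    return out
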