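"""Stability classification and mode-association statistics.

The shape-space weights of each knee (lambda, SD units) are used as
covariates to classify per-angle stability labels and to quantify which modes
of variation carry alignment information:

* LDA / QDA Gaussian discriminants with covariance shrinkage
  ``Sigma <- (1 - rho) Sigma + rho diag(Sigma)`` (high-dimensional weights vs
  small classes make the raw class covariances singular), evaluated with
  leave-one-out cross-validation and reported as accuracy / sensitivity /
  specificity with "unstable" as the positive class;
* logistic regression (maximum-likelihood IRLS) with per-mode Wald p-values,
  falling back to a lightly ridge-penalized fit when the classes are
  perfectly separable;
* greedy forward selection of small mode subsets by LOO accuracy;
* an unpaired two-sided rank-sum test between stable and unstable groups
  (exact enumeration of splits for small samples, tie-corrected normal
  approximation otherwise);
* Spearman rank correlation of each mode weight against the corrected
  clinical variables |X - X_mean|.

The shape model itself is fitted once on the full cohort; cross-validation
applies to the classifiers only.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .angles import ANGLE_NAMES, StabilityThresholds, corrected_deviation

__all__ = [
    "ClassifierSpec",
    "AnalysisReport",
    "loo_evaluate",
    "confusion_metrics",
    "fit_logreg",
    "select_modes",
    "ranksum_test",
    "spearman",
    "run_analysis",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to run and on which mode weights.

    kind: 'lda' | 'qda' | 'logreg'; features: column indices into the weight
    matrix or 'all'; shrinkage rho applies to lda/qda, ridge penalty to the
    logistic-regression fallback.
    """

    kind: str
    features: tuple | str = "all"
    shrinkage: float = 0.1
    ridge: float = 1e-4

    def __post_init__(self):
        if self.kind not in ("lda", "qda", "logreg"):
            raise ValueError("kind must be lda, qda or logreg")
        if not 0.0 <= self.shrinkage <= 1.0:
            raise ValueError("shrinkage must be in [0, 1]")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")

    def columns(self, n_features: int) -> np.ndarray:
        if isinstance(self.features, str):
            if self.features != "all":
                raise ValueError("features must be indices or 'all'")
            return np.arange(n_features)
        idx = np.asarray(self.features, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= n_features):
            raise ValueError("feature index out of range")
        return idx


# ---------------------------------------------------------------------------
# Gaussian discriminants
# ---------------------------------------------------------------------------

def _shrunk_cov(X: np.ndarray, rho: float) -> np.ndarray:
    n, p = X.shape
    if n < 2:
        C = np.zeros((p, p))
    else:
        C = np.cov(X, rowvar=False, ddof=1).reshape(p, p)
    d = np.diag(np.maximum(np.diag(C), 1e-12))
    return (1.0 - rho) * C + rho * d + 1e-10 * np.eye(p)


class _GaussianDA:
    """LDA (pooled covariance) / QDA (per-class) with diagonal shrinkage."""

    def __init__(self, kind: str, shrinkage: float):
        self.kind = kind
        self.rho = shrinkage

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need two classes")
        self.means_, covs, priors = [], [], []
        for c in self.classes_:
            Xi = X[y == c]
            self.means_.append(Xi.mean(axis=0))
            covs.append(_shrunk_cov(Xi, self.rho))
            priors.append(len(Xi) / len(X))
        self.log_priors_ = np.log(priors)
        if self.kind == "lda":
            pooled = np.zeros_like(covs[0])
            for c, C in zip(self.classes_, covs):
                pooled += (np.sum(y == c) - 1) * C
            pooled /= max(len(X) - len(self.classes_), 1)
            covs = [pooled for _ in self.classes_]
        self.chol_ = [np.linalg.cholesky(C) for C in covs]
        self.logdet_ = [2.0 * np.sum(np.log(np.diag(L))) for L in self.chol_]
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = np.empty((len(X), len(self.classes_)))
        from scipy.linalg import solve_triangular
        for i, (mu, L, ld, lp) in enumerate(zip(self.means_, self.chol_,
                                                self.logdet_, self.log_priors_)):
            z = solve_triangular(L, (X - mu).T, lower=True)
            scores[:, i] = -0.5 * np.sum(z ** 2, axis=0) - 0.5 * ld + lp
        return self.classes_[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

def _irls_logreg(X, y, ridge: float, tol: float = 1e-8, max_iter: int = 200):
    """Newton/IRLS for the binomial GLM with optional ridge on the slopes."""
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    pen = np.concatenate([[0.0], np.full(p, ridge)])
    for _ in range(max_iter):
        eta = np.clip(Xd @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        Wd = np.maximum(mu * (1 - mu), 1e-10)
        H = Xd.T @ (Wd[:, None] * Xd) + np.diag(pen)
        g = Xd.T @ (y - mu) - pen * beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(Xd @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    Wd = np.maximum(mu * (1 - mu), 1e-10)
    H = Xd.T @ (Wd[:, None] * Xd) + np.diag(pen)
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return beta, se


@dataclass
class LogregFit:
    coef: np.ndarray        # slopes (no intercept)
    intercept: float
    se: np.ndarray
    z: np.ndarray
    p_values: np.ndarray
    separable: bool

    def predict(self, X):
        eta = self.intercept + np.atleast_2d(X) @ self.coef
        return (eta > 0).astype(int)


def fit_logreg(X, y, tol: float = 1e-8, ridge_fallback: float = 1e-4) -> LogregFit:
    """Maximum-likelihood logistic regression with Wald z / p per coefficient.

    On (quasi-)complete separation or collinear columns the unpenalized MLE
    diverges; the fit is then redone with a small ridge penalty and flagged
    ``separable=True``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    beta, se = _irls_logreg(X, y, ridge=0.0, tol=tol)
    separable = bool(np.max(np.abs(beta)) > 1e2 or not np.all(np.isfinite(se))
                     or np.max(se) > 1e3)
    if separable:
        beta, se = _irls_logreg(X, y, ridge=ridge_fallback, tol=tol)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return LogregFit(coef=beta[1:], intercept=float(beta[0]), se=se[1:],
                     z=z[1:], p_values=p[1:], separable=separable)


# ---------------------------------------------------------------------------
# Metrics and LOO
# ---------------------------------------------------------------------------

def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """Accuracy, sensitivity, specificity.  Undefined ratios (empty class)
    come back as NaN with a warning."""
    for v in (tp, fn, tn, fp):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be nonnegative integers")
    n = tp + fn + tn + fp
    if n == 0:
        raise ValueError("empty confusion matrix")
    ac = (tp + tn) / n
    if tp + fn == 0:
        warnings.warn("no positive cases: sensitivity undefined (NaN)")
        se = float("nan")
    else:
        se = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative cases: specificity undefined (NaN)")
        sp = float("nan")
    else:
        sp = tn / (tn + fp)
    return float(ac), float(se), float(sp)


def _make_classifier(spec: ClassifierSpec):
    if spec.kind in ("lda", "qda"):
        return _GaussianDA(spec.kind, spec.shrinkage)

    class _LR:
        def fit(self, X, y):
            self.fit_ = fit_logreg(X, y)
            return self

        def predict(self, X):
            return self.fit_.predict(X)

    return _LR()


def loo_evaluate(weights, labels, spec: ClassifierSpec) -> dict:
    """Leave-one-out evaluation; positive class = unstable (label 1).

    Each sample is scored by a classifier fitted on the other n-1.  Folds
    whose training set loses an entire class are flagged and excluded from
    the confusion counts.
    """
    X = np.atleast_2d(np.asarray(weights, dtype=float))
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != len(y):
        raise ValueError("weights and labels disagree in length")
    if min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ValueError("need at least two samples per class")
    cols = spec.columns(X.shape[1])
    Xs = X[:, cols]
    preds = np.full(len(y), -1)
    skipped = []
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            skipped.append(i)
            continue
        clf = _make_classifier(spec).fit(Xs[mask], y[mask])
        preds[i] = int(np.asarray(clf.predict(Xs[i:i + 1]))[0])
    scored = preds >= 0
    tp = int(np.sum((preds == 1) & (y == 1) & scored))
    fn = int(np.sum((preds == 0) & (y == 1) & scored))
    tn = int(np.sum((preds == 0) & (y == 0) & scored))
    fp = int(np.sum((preds == 1) & (y == 0) & scored))
    ac, se, sp = confusion_metrics(tp, fn, tn, fp)
    return {"tp": tp, "fn": fn, "tn": tn, "fp": fp, "accuracy": ac,
            "sensitivity": se, "specificity": sp, "predictions": preds,
            "skipped_folds": skipped}


def select_modes(weights, labels, spec: ClassifierSpec, k: int) -> list[int]:
    """Greedy forward selection of k mode indices maximizing LOO accuracy;
    ties broken toward the lower mode index.  Deterministic."""
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.atleast_2d(np.asarray(weights, dtype=float))
    n_feat = X.shape[1]
    chosen: list[int] = []
    for _ in range(min(k, n_feat)):
        best_j, best_acc = None, -1.0
        for j in range(n_feat):
            if j in chosen:
                continue
            trial = ClassifierSpec(kind=spec.kind,
                                   features=tuple(chosen + [j]),
                                   shrinkage=spec.shrinkage, ridge=spec.ridge)
            acc = loo_evaluate(X, labels, trial)["accuracy"]
            if acc > best_acc + 1e-12:
                best_j, best_acc = j, acc
        chosen.append(best_j)
    return chosen


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------

def _rank_u(pooled_ranks, idx_a):
    na = len(idx_a)
    return float(np.sum(pooled_ranks[idx_a]) - na * (na + 1) / 2.0)


def ranksum_test(group_a, group_b) -> float:
    """Two-sided unpaired rank-sum (Mann-Whitney) p-value.

    Exact enumeration of all C(nA+nB, nA) group splits for nA+nB <= 12
    (valid with ties); tie-corrected normal approximation otherwise.
    Identical pooled values give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need at least 3 values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    na, nb = len(a), len(b)
    ranks = stats.rankdata(pooled)
    u_obs = _rank_u(ranks, np.arange(na))
    mu = na * nb / 2.0
    if na + nb <= 12:
        total = 0
        extreme = 0
        for comb in itertools.combinations(range(na + nb), na):
            u = _rank_u(ranks, np.array(comb))
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                extreme += 1
        return extreme / total
    # normal approximation with tie correction
    _, counts = np.unique(pooled, return_counts=True)
    n = na + nb
    tie = np.sum(counts ** 3 - counts) / (n * (n - 1))
    var = na * nb / 12.0 * (n + 1 - tie)
    if var <= 0:
        return 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)  # continuity-corrected
    return float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its p-value
    via the t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need at least 4 paired values")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Full analysis battery
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    """Classification metrics, per-mode statistics and correlations, by
    clinical variable."""

    classification: dict = field(default_factory=dict)  # var -> kind -> metrics
    logreg_pvalues: dict = field(default_factory=dict)  # var -> [p per mode]
    selected_subsets: dict = field(default_factory=dict)  # var -> {k: {...}}
    ranksum: dict = field(default_factory=dict)          # var -> {mode: p}
    correlations: dict = field(default_factory=dict)     # var -> [(c, p)]
    warnings: list = field(default_factory=list)
    n_modes: int = 0
    n_samples: int = 0

    def to_json(self) -> str:
        def clean(o):
            if isinstance(o, dict):
                return {str(k): clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [clean(v) for v in o]
            if isinstance(o, np.ndarray):
                return clean(o.tolist())
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating, float)):
                return None if not np.isfinite(o) else float(o)
            return o

        payload = {k: clean(getattr(self, k)) for k in
                   ("classification", "logreg_pvalues", "selected_subsets",
                    "ranksum", "correlations", "warnings", "n_modes",
                    "n_samples")}
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        d = json.loads(text)
        return cls(**d)


def run_analysis(weights, angle_table, thresholds: StabilityThresholds | None = None,
                 subset_sizes: tuple[int, ...] = (3, 4),
                 shrinkage: float = 0.1,
                 alpha: float = 0.05) -> AnalysisReport:
    """The full statistical battery over all clinical variables.

    ``weights``: (n_samples, n_modes) retained mode weights; ``angle_table``:
    mapping or DataFrame with one column per angle name (degrees), rows
    aligned with the weight rows.  For each variable: LDA/QDA/logistic LOO
    classification on all modes, greedy QDA subsets of the requested sizes,
    rank-sum tests on modes flagged significant by logistic regression, and
    Spearman correlation of every mode against the corrected variable.
    Variables with fewer than two samples in either class are skipped with a
    warning entry.
    """
    thresholds = thresholds or StabilityThresholds()
    X = np.atleast_2d(np.asarray(weights, dtype=float))
    report = AnalysisReport(n_modes=X.shape[1], n_samples=X.shape[0])
    for name in ANGLE_NAMES:
        try:
            vals = np.asarray(angle_table[name], dtype=float)
        except (KeyError, IndexError) as exc:
            raise KeyError(f"angle table lacks column {name!r}") from exc
        if len(vals) != len(X):
            raise ValueError("angle table and weights disagree in length")
        center, half = thresholds.ranges[name]
        y = (np.abs(vals - center) > half).astype(int)  # 1 = unstable
        # correlations are defined regardless of class balance
        xhat = np.array([corrected_deviation(v, center) for v in vals])
        if len(X) >= 4:
            report.correlations[name] = [spearman(X[:, j], xhat)
                                         for j in range(X.shape[1])]
        else:
            report.warnings.append(
                f"{name}: fewer than 4 samples; correlations skipped")
        if min(np.sum(y == 0), np.sum(y == 1)) < 2:
            report.warnings.append(
                f"{name}: fewer than 2 samples in one class; classification skipped")
            continue
        report.classification[name] = {}
        for kind in ("lda", "qda", "logreg"):
            spec = ClassifierSpec(kind=kind, shrinkage=shrinkage)
            res = loo_evaluate(X, y, spec)
            report.classification[name][kind] = {
                k: res[k] for k in ("tp", "fn", "tn", "fp", "accuracy",
                                    "sensitivity", "specificity")}
        lr = fit_logreg(X, y)
        report.logreg_pvalues[name] = lr.p_values.tolist()
        if lr.separable:
            report.warnings.append(f"{name}: separation; ridge fallback used")
        report.selected_subsets[name] = {}
        for k in subset_sizes:
            spec = ClassifierSpec(kind="qda", shrinkage=shrinkage)
            subset = select_modes(X, y, spec, k)
            res = loo_evaluate(X, y, ClassifierSpec(
                kind="qda", features=tuple(subset), shrinkage=shrinkage))
            report.selected_subsets[name][k] = {
                "modes": subset,
                "accuracy": res["accuracy"],
                "sensitivity": res["sensitivity"],
                "specificity": res["specificity"]}
        report.ranksum[name] = {}
        for j, p in enumerate(lr.p_values):
            if p < alpha:
                report.ranksum[name][j] = ranksum_test(X[y == 0, j], X[y == 1, j]) \
                    if min(np.sum(y == 0), np.sum(y == 1)) >= 3 else float("nan")
    return report
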