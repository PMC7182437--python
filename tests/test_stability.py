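"""Classification, rank statistics and the analysis battery."""

import itertools

import numpy as np
import pytest
from scipy import stats

from kneessm import stability as ST
from kneessm.angles import StabilityThresholds


def test_confusion_metrics_basic():
    assert ST.confusion_metrics(9, 1, 8, 2) == pytest.approx((0.85, 0.9, 0.8))
    with pytest.warns(UserWarning):
        ac, se, sp = ST.confusion_metrics(0, 0, 20, 0)
    assert ac == 1.0 and np.isnan(se) and sp == 1.0
    with pytest.warns(UserWarning):
        ac, se, sp = ST.confusion_metrics(20, 0, 0, 0)
    assert ac == 1.0 and se == 1.0 and np.isnan(sp)
    with pytest.raises(ValueError):
        ST.confusion_metrics(-1, 0, 0, 1)


@pytest.mark.parametrize("kind", ["lda", "qda", "logreg"])
def test_loo_separable_classes_are_perfect(kind, rng):
    X = np.concatenate([rng.normal(-10, 1, 10), rng.normal(10, 1, 10)])[:, None]
    y = np.array([0] * 10 + [1] * 10)
    res = ST.loo_evaluate(X, y, ST.ClassifierSpec(kind))
    assert res["accuracy"] == res["sensitivity"] == res["specificity"] == 1.0
    assert np.sum(res["predictions"] >= 0) == 20  # every sample scored


def test_loo_uninformative_features_score_at_chance(rng):
    X = rng.normal(size=(200, 3))
    y = rng.integers(0, 2, 200)
    res = ST.loo_evaluate(X, y, ST.ClassifierSpec("lda"))
    assert 0.4 <= res["accuracy"] <= 0.6


def test_qda_beats_lda_with_unequal_class_covariances(rng):
    """Stable class tight around 0, unstable spread on both sides: the class
    means coincide so LDA is blind, while QDA separates by covariance."""
    n = 60
    X0 = rng.normal(0, 0.5, (n, 2))
    X1 = rng.normal(0, 4.0, (n, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * n + [1] * n)
    lda = ST.loo_evaluate(X, y, ST.ClassifierSpec("lda"))["accuracy"]
    qda = ST.loo_evaluate(X, y, ST.ClassifierSpec("qda"))["accuracy"]
    assert qda > lda
    assert qda > 0.8


def test_qda_shrinkage_handles_wide_feature_matrices(rng):
    # more features than the smaller class: raw covariance would be singular
    X = rng.normal(size=(24, 10))
    y = np.array([0] * 6 + [1] * 18)
    X[y == 1, 0] += 3
    res = ST.loo_evaluate(X, y, ST.ClassifierSpec("qda", shrinkage=0.1))
    assert np.isfinite(res["accuracy"])


def test_logreg_coefficient_recovery(rng):
    x = rng.normal(size=2000)
    y = (rng.random(2000) < 1 / (1 + np.exp(-2 * x))).astype(int)
    fit = ST.fit_logreg(x[:, None], y)
    assert 1.6 <= fit.coef[0] <= 2.4
    assert fit.p_values[0] < 1e-6
    assert not fit.separable


def test_logreg_null_pvalues_are_uniformish():
    hits = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        x = r.normal(size=500)
        y = r.integers(0, 2, 500)
        if ST.fit_logreg(x[:, None], y).p_values[0] > 0.05:
            hits += 1
    assert hits >= 18  # >= 90% of seeds


def test_logreg_separation_and_collinearity(rng):
    x = np.concatenate([rng.normal(-5, 0.1, 10), rng.normal(5, 0.1, 10)])
    y = np.array([0] * 10 + [1] * 10)
    fit = ST.fit_logreg(x[:, None], y)
    assert fit.separable  # ridge fallback flagged
    assert np.all(np.isfinite(fit.p_values))
    # duplicated columns do not crash
    x2 = rng.normal(size=200)
    y2 = (x2 + rng.normal(0, 1, 200) > 0).astype(int)
    fit2 = ST.fit_logreg(np.column_stack([x2, x2]), y2)
    assert np.all(np.isfinite(fit2.coef))


def test_select_modes_matches_exhaustive_search(rng):
    X = rng.normal(size=(40, 5))
    y = ((X[:, 1] + 0.8 * X[:, 3] + 0.5 * rng.normal(size=40)) > 0).astype(int)
    spec = ST.ClassifierSpec("qda")
    greedy1 = ST.select_modes(X, y, spec, 1)
    accs = [ST.loo_evaluate(X, y, ST.ClassifierSpec(
        "qda", features=(j,)))["accuracy"] for j in range(5)]
    assert greedy1[0] == int(np.argmax(accs))  # argmax takes the lowest tie
    # greedy k=2 at least matches the best pair containing its first pick
    greedy2 = ST.select_modes(X, y, spec, 2)
    acc_greedy = ST.loo_evaluate(X, y, ST.ClassifierSpec(
        "qda", features=tuple(greedy2)))["accuracy"]
    best_with_first = max(
        ST.loo_evaluate(X, y, ST.ClassifierSpec(
            "qda", features=(greedy2[0], j)))["accuracy"]
        for j in range(5) if j != greedy2[0])
    assert acc_greedy == pytest.approx(best_with_first)
    assert ST.select_modes(X, y, spec, 2) == greedy2  # deterministic


def test_select_modes_finds_perfect_separator(rng):
    X = rng.normal(size=(30, 4))
    y = rng.integers(0, 2, 30)
    X[:, 2] = np.where(y == 1, 10.0, -10.0) + rng.normal(0, 0.1, 30)
    assert ST.select_modes(X, y, ST.ClassifierSpec("lda"), 1)[0] == 2


def test_ranksum_exact_enumeration_oracle():
    """Exact p equals full enumeration of rank splits (independent oracle)."""
    assert ST.ranksum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)
    assert ST.ranksum_test([2, 2, 2], [2, 2, 2, 2]) == 1.0
    rng = np.random.default_rng(0)
    for _ in range(3):
        a, b = rng.normal(size=5), rng.normal(0.8, 1, 6)
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        na = len(a)
        u_obs = ranks[:na].sum() - na * (na + 1) / 2
        mu = na * len(b) / 2
        us = [sum(ranks[list(c)]) - na * (na + 1) / 2
              for c in itertools.combinations(range(len(pooled)), na)]
        want = np.mean([abs(u - mu) >= abs(u_obs - mu) - 1e-12 for u in us])
        assert ST.ranksum_test(a, b) == pytest.approx(want)


def test_ranksum_exact_close_to_normal_approximation(rng):
    a = rng.normal(size=6)
    b = rng.normal(1.0, 1, 6)
    exact = ST.ranksum_test(a, b)
    approx = stats.mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic").pvalue
    assert abs(exact - approx) <= 0.05
    # large-sample branch agrees with scipy's tie-corrected asymptotics
    a2, b2 = rng.normal(size=15), rng.normal(0.5, 1, 15)
    ours = ST.ranksum_test(a2, b2)
    theirs = stats.mannwhitneyu(a2, b2, alternative="two-sided",
                                method="asymptotic", use_continuity=True).pvalue
    assert ours == pytest.approx(theirs, abs=1e-9)


def test_spearman_monotone_and_oracle(rng):
    c, _ = ST.spearman(np.arange(10), 2.0 * np.arange(10))
    assert c == pytest.approx(1.0, abs=1e-12)
    x = np.arange(1, 9, dtype=float)
    c, _ = ST.spearman(x, -x ** 3)
    assert c == pytest.approx(-1.0, abs=1e-12)
    # n=6 random pairs vs explicit rank-formula oracle (no ties)
    x = rng.permutation(6).astype(float)
    y = rng.normal(size=6)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    want = np.corrcoef(rx, ry)[0, 1]
    got, _ = ST.spearman(x, y)
    assert got == pytest.approx(want, abs=1e-12)


def test_run_analysis_finds_driving_mode(rng):
    """Labels driven by one latent rotation: its dominant mode is selected."""
    n = 60
    hka = rng.normal(0, 6, n)
    W = rng.normal(size=(n, 5))
    # mode 2 tracks the frontal deviation magnitude (instability direction)
    W[:, 2] = np.abs(hka) / 6 + rng.normal(0, 0.05, n)
    table = {"hka": hka, "fvv": np.full(n, -6.0) + rng.normal(0, 1, n),
             "tvv": rng.normal(0, 2, n), "ier": rng.normal(0, 2, n),
             "ts": rng.normal(7, 2, n)}
    rep = ST.run_analysis(W, table, subset_sizes=(3,))
    assert 2 in rep.selected_subsets["hka"][3]["modes"]
    c, p = rep.correlations["hka"][2]
    assert abs(c) > 0.8 and p < 1e-6


def test_run_analysis_degenerate_and_serialization(rng):
    n = 30
    W = rng.normal(size=(n, 3))
    table = {k: rng.normal(c, 0.1, n) for k, c in
             [("hka", 0), ("fvv", -6), ("tvv", 0), ("ier", 0), ("ts", 7)]}
    wide = StabilityThresholds(ranges={k: (c, 1e9) for k, (c, _) in
                                       StabilityThresholds().ranges.items()})
    rep = ST.run_analysis(W, table, thresholds=wide)
    assert rep.classification == {}  # all stable: classification skipped
    assert len(rep.warnings) == 5
    rep2 = ST.AnalysisReport.from_json(rep.to_json())
    assert rep2.to_json() == rep.to_json()  # lossless round trip
    with pytest.raises(KeyError):
        ST.run_analysis(W, {"hka": table["hka"]})
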