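"""LDA classification, feature selection and stability analysis.

The evaluation protocol mirrors common radiomics practice for small
two-class cohorts:

* an LDA classifier (Gaussian class-conditionals with pooled covariance)
  evaluated by repeated stratified 2-fold cross-validation (default 100
  repeats), reporting mean Az (ROC area), PPV and NPV with 95% percentile
  confidence intervals over the repeats;
* classifier stability quantified by the relative standard deviation of
  the per-repeat Az values, RSD = 100 * std(Az) / mean(Az);
* sequential floating forward selection (SFFS) wrapped around the
  cross-validated LDA Az as selection criterion;
* feature ranking: features whose Az exceeds the grand-mean Az while
  their RSD is below the grand-mean RSD are "stable";
* learning-curve analysis with the inverse power law
  err(n) = a * n**(-alpha) + eps, whose offset eps estimates the Bayes
  error of the problem.

Features are z-scored with train-fold statistics before every LDA fit, and
the pooled covariance carries a small ridge so subsets with more features
than samples stay solvable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares
from sklearn.metrics import roc_auc_score

from .core import ValidationError

POSITIVE_LABEL = 1  # high risk


@dataclass
class LdaModel:
    means: np.ndarray          # (2, p) class means (z-scored space)
    cov_inv: np.ndarray        # (p, p) inverse pooled covariance with ridge
    log_priors: np.ndarray     # (2,)
    scaler_mean: np.ndarray    # (p,) train-fold standardization
    scaler_std: np.ndarray

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Posterior probability of the positive (high-risk) class."""
        Z = (np.atleast_2d(X) - self.scaler_mean) / self.scaler_std
        logp = np.empty((Z.shape[0], 2))
        for c in range(2):
            d = Z - self.means[c]
            logp[:, c] = -0.5 * np.einsum("ij,jk,ik->i", d, self.cov_inv,
                                          d) + self.log_priors[c]
        m = logp.max(axis=1, keepdims=True)
        w = np.exp(logp - m)
        return w[:, 1] / w.sum(axis=1)


@dataclass
class EvalResult:
    name: str
    az_mean: float
    az_ci: tuple[float, float]
    ppv_mean: float
    ppv_ci: tuple[float, float]
    npv_mean: float
    npv_ci: tuple[float, float]
    rsd_percent: float
    err_mean: float
    az_values: np.ndarray = field(repr=False, default=None)


@dataclass
class PowerLawFit:
    a: float
    alpha: float
    eps: float
    residual: float
    flagged: bool = False

    def __call__(self, n):
        return self.a * np.asarray(n, dtype=float) ** (-self.alpha) + self.eps


def fit_lda(X, y, ridge_scale: float = 1e-6) -> LdaModel:
    """Fit a two-class LDA with pooled (ridge-stabilized) covariance.

    Features are z-scored internally with the training data's statistics;
    priors are empirical.  ``y`` holds 0 (low risk) / 1 (high risk).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y).astype(int)
    if X.shape[0] < 4:
        raise ValidationError("need at least 4 training samples")
    classes = np.unique(y)
    if set(classes) != {0, 1}:
        raise ValidationError("both classes (0 and 1) must be present")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    Z = (X - mu) / sd
    p = Z.shape[1]
    means = np.vstack([Z[y == c].mean(axis=0) for c in (0, 1)])
    pooled = np.zeros((p, p))
    for c in (0, 1):
        d = Z[y == c] - means[c]
        pooled += d.T @ d
    pooled /= max(len(y) - 2, 1)
    lam = ridge_scale * np.trace(pooled) / p
    pooled += max(lam, 1e-12) * np.eye(p)
    priors = np.array([(y == c).mean() for c in (0, 1)])
    return LdaModel(means=means, cov_inv=np.linalg.inv(pooled),
                    log_priors=np.log(priors), scaler_mean=mu, scaler_std=sd)


def roc_az(scores, y) -> float:
    """Area under the ROC curve (Mann-Whitney form; ties count one half)."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes required for ROC analysis")
    return float(roc_auc_score(y, np.asarray(scores, dtype=np.float64)))


def ppv_npv(scores, y, threshold: float = 0.5):
    """Positive / negative predictive value at a posterior threshold.

    An undefined ratio (no predicted positives or negatives) is returned
    as ``nan`` so callers can flag it rather than silently dropping it.
    """
    y = np.asarray(y).astype(int)
    pred = np.asarray(scores) >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    npv = tn / (tn + fn) if (tn + fn) > 0 else float("nan")
    return ppv, npv


def rsd(az_values) -> float:
    """Relative standard deviation in percent, 100 * std / mean.

    Computed with the sample (ddof=1) standard deviation; higher values
    mean a less stable classifier across CV repeats.
    """
    v = np.asarray(az_values, dtype=np.float64)
    if v.size == 0:
        raise ValidationError("rsd of empty input")
    m = v.mean()
    if m <= 0:
        raise ValidationError("rsd undefined for non-positive mean")
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    return float(100.0 * sd / m)


def _stratified_halves(y, rng, max_retries: int = 100):
    """Random stratified split into two folds, each containing both classes."""
    y = np.asarray(y).astype(int)
    for _ in range(max_retries):
        fold = np.empty(len(y), dtype=int)
        for c in np.unique(y):
            idx = np.where(y == c)[0]
            perm = rng.permutation(idx)
            half = len(idx) // 2
            fold[perm[:half]] = 0
            fold[perm[half:]] = 1
        ok = all(len(np.unique(y[fold == f])) == 2 for f in (0, 1))
        if ok:
            return fold
    raise ValidationError("could not build stratified folds with both classes")


def repeated_cv(X, y, repeats: int = 100, seed: int = 0,
                name: str = "features", threshold: float = 0.5) -> EvalResult:
    """Repeated stratified 2-fold cross-validation of LDA.

    Each repeat draws a fresh stratified random split into halves, trains
    on each half and scores the other; the pooled out-of-fold posteriors
    give that repeat's Az, PPV, NPV and error rate.  Means and 2.5/97.5
    percentile confidence intervals over the repeats are reported, and the
    per-repeat Az values are retained for stability (RSD) analysis.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.ndim == 2 and X.shape[0] == 1 and len(np.asarray(y)) > 1:
        X = X.T
    y = np.asarray(y).astype(int)
    if len(y) < 8:
        raise ValidationError("repeated CV needs at least 8 samples")
    rng = np.random.default_rng(seed)
    az = np.empty(repeats)
    ppv = np.empty(repeats)
    npv = np.empty(repeats)
    err = np.empty(repeats)
    for r in range(repeats):
        fold = _stratified_halves(y, rng)
        scores = np.empty(len(y))
        for f in (0, 1):
            model = fit_lda(X[fold == f], y[fold == f])
            scores[fold != f] = model.decision_scores(X[fold != f])
        az[r] = roc_az(scores, y)
        ppv[r], npv[r] = ppv_npv(scores, y, threshold)
        err[r] = float(np.mean((scores >= threshold).astype(int) != y))

    def ci(v):
        v = v[np.isfinite(v)]
        if v.size == 0:
            return (float("nan"), float("nan"))
        return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))

    return EvalResult(
        name=name,
        az_mean=float(az.mean()), az_ci=ci(az),
        ppv_mean=float(np.nanmean(ppv)), ppv_ci=ci(ppv),
        npv_mean=float(np.nanmean(npv)), npv_ci=ci(npv),
        rsd_percent=rsd(az), err_mean=float(err.mean()),
        az_values=az,
    )


def combine_features(X, subset):
    """Column-select a feature subset for joint (equal-weight) LDA use."""
    if len(subset) == 0:
        raise ValidationError("empty feature subset")
    return np.atleast_2d(np.asarray(X, dtype=np.float64))[:, list(subset)]


def _cv_az(X, y, subset, repeats, seed, cache):
    key = frozenset(subset)
    if key not in cache:
        res = repeated_cv(combine_features(X, sorted(subset)), y,
                          repeats=repeats, seed=seed)
        cache[key] = res.az_mean
    return cache[key]


def sffs_select(X, y, max_k: int = 10, repeats: int = 25, seed: int = 0):
    """Sequential floating forward selection with a CV-Az criterion.

    Classic SFFS: greedily add the feature that most improves the repeated
    cross-validated LDA Az, then conditionally remove features while that
    improves the criterion; the best subset of size <= max_k seen overall
    is returned (as a sorted list of column indices).  Ties break toward
    the lower feature index; the CV splits are fixed by ``seed`` so all
    subsets are compared on identical resamples.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    p = X.shape[1]
    if p < 1:
        raise ValidationError("no features to select from")
    cache: dict[frozenset, float] = {}
    current: list[int] = []
    best_by_size: dict[int, tuple[float, list[int]]] = {}

    while len(current) < max_k:
        # forward: best single addition
        best_j, best_score = None, -np.inf
        for j in range(p):
            if j in current:
                continue
            score = _cv_az(X, y, current + [j], repeats, seed, cache)
            if score > best_score + 1e-12:
                best_j, best_score = j, score
        if best_j is None:
            break
        current = sorted(current + [best_j])
        k = len(current)
        if k not in best_by_size or best_score > best_by_size[k][0] + 1e-12:
            best_by_size[k] = (best_score, list(current))

        # backward: conditionally drop while it improves on the best subset
        # of the smaller size
        while len(current) > 2:
            drop_j, drop_score = None, -np.inf
            for j in current:
                sub = [i for i in current if i != j]
                score = _cv_az(X, y, sub, repeats, seed, cache)
                if score > drop_score + 1e-12:
                    drop_j, drop_score = j, score
            k1 = len(current) - 1
            prev_best = best_by_size.get(k1, (-np.inf, None))[0]
            if drop_j is not None and drop_score > prev_best + 1e-12:
                current = [i for i in current if i != drop_j]
                best_by_size[len(current)] = (drop_score, list(current))
            else:
                break

    if not best_by_size:
        return []
    best_score, best_subset = max(best_by_size.values(),
                                  key=lambda t: (t[0], -len(t[1])))
    return sorted(best_subset)


def spearman_rho(values, labels):
    """Spearman rank correlation of a feature with the binary label.

    Returns (rho, p); rho is ``nan`` (flagged) when the feature is
    constant so no ranking exists.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if values.size < 5:
        raise ValidationError("Spearman correlation needs n >= 5")
    if np.ptp(values) == 0 or np.ptp(labels) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(values, labels)
    return float(rho), float(p)


def rank_stable_features(results: list[EvalResult]) -> list[EvalResult]:
    """Features both more accurate and more stable than the field.

    Keeps results whose mean Az is strictly above the grand-mean Az and
    whose RSD is strictly below the grand-mean RSD.
    """
    if len(results) < 2:
        raise ValidationError("need at least 2 results to rank")
    mean_az = np.mean([r.az_mean for r in results])
    mean_rsd = np.mean([r.rsd_percent for r in results])
    return [r for r in results
            if r.az_mean > mean_az and r.rsd_percent < mean_rsd]


ALPHA_BOUNDS = (1e-6, 2.0)
EPS_BOUNDS = (0.0, 0.5)
A_BOUNDS = (1e-12, 1e3)


def fit_power_law(sizes, errs, n_starts: int = 8) -> PowerLawFit:
    """Fit err(n) = a * n**(-alpha) + eps by constrained least squares.

    Multi-started from a log-grid of (a, alpha) pairs; the best-residual
    solution within the bounds a > 0, alpha in (0, 2], eps in [0, 0.5] is
    returned.  A constant error sequence is a degenerate ridge (a -> 0
    with eps = err, or alpha at its lower bound) and is returned flagged.
    """
    sizes = np.asarray(sizes, dtype=np.float64)
    errs = np.asarray(errs, dtype=np.float64)
    if len(np.unique(sizes)) < 4:
        raise ValidationError("need at least 4 distinct training sizes")
    if np.any((errs < 0) | (errs > 1)):
        raise ValidationError("error rates must lie in [0, 1]")

    def resid(p):
        return p[0] * sizes ** (-p[1]) + p[2] - errs

    lo = [A_BOUNDS[0], ALPHA_BOUNDS[0], EPS_BOUNDS[0]]
    hi = [A_BOUNDS[1], ALPHA_BOUNDS[1], EPS_BOUNDS[1]]
    eps0 = float(np.clip(errs.min(), *EPS_BOUNDS))
    starts = []
    for a0 in np.geomspace(0.05, 5.0, max(2, n_starts // 2)):
        for al0 in (0.3, 1.0):
            starts.append([a0, al0, eps0])
    best = None
    for x0 in starts[:max(1, n_starts)]:
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return PowerLawFit(float("nan"), float("nan"), float("nan"),
                           float("inf"), flagged=True)
    a, alpha, eps = map(float, best.x)
    residual = float(np.sqrt(2 * best.cost))
    flagged = (not best.success) or a <= 2 * A_BOUNDS[0] \
        or alpha <= 2 * ALPHA_BOUNDS[0]
    return PowerLawFit(a, alpha, eps, residual, flagged=flagged)


def learning_curve(X, y, sizes, reps: int = 50, seed: int = 0,
                   test_fraction: float = 0.25, threshold: float = 0.5):
    """Mean LDA test error as a function of training-set size.

    A fixed stratified test set (``test_fraction`` of the data) is held
    out; for each requested size, ``reps`` seeded stratified subsamples of
    the remaining pool are used for training and the test error averaged.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    # stratified train pool / test split
    test_idx = []
    for c in np.unique(y):
        idx = rng.permutation(np.where(y == c)[0])
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx.extend(idx[:n_test])
    test_mask = np.zeros(len(y), dtype=bool)
    test_mask[test_idx] = True
    pool = np.where(~test_mask)[0]
    sizes = [int(s) for s in sizes]
    if max(sizes) > len(pool):
        raise ValidationError(
            f"training size {max(sizes)} exceeds pool size {len(pool)}")
    errs = []
    for n in sizes:
        e = []
        for _ in range(reps):
            for _retry in range(100):
                sub = rng.choice(pool, size=n, replace=False)
                if len(np.unique(y[sub])) == 2 and n >= 4:
                    break
            else:
                raise ValidationError("cannot draw two-class training sample")
            model = fit_lda(X[sub], y[sub])
            scores = model.decision_scores(X[test_mask])
            pred = (scores >= threshold).astype(int)
            e.append(float(np.mean(pred != y[test_mask])))
        errs.append(float(np.mean(e)))
    return np.array(sizes), np.array(errs)
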