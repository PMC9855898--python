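"""Two-class linear discriminant analysis with leave-one-out cross-validation.

The classifier uses the pooled within-class covariance (n − g denominator)
and the linear discriminant scores

    g_k(x) = xᵀ Σ⁻¹ μ_k − ½ μ_kᵀ Σ⁻¹ μ_k + ln π_k .

Priors are equal by default (the chemometric convention for small grouped
studies); proportional priors are available.  A small ridge is added to the
covariance diagonal when it is ill-conditioned, which happens routinely when
the variable count approaches the size of the smaller class.

Leave-one-out cross-validation uses rank-one downdates of the class means and
pooled scatter rather than refitting from scratch; the result is identical to
the naive full-refit procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RIDGE_COND_LIMIT = 1e10
RIDGE_EPS = 1e-8


@dataclass
class LDAModel:
    classes: np.ndarray           # two labels, sorted
    class_means: np.ndarray       # (2, p)
    pooled_cov: np.ndarray        # (p, p), after any ridge
    cov_inv: np.ndarray
    priors: np.ndarray            # (2,), sum to 1
    ridge: float                  # ridge value actually applied

    @property
    def canonical_direction(self) -> np.ndarray:
        """Σ⁻¹(μ₁ − μ₂) for the two-class problem."""
        return self.cov_inv @ (self.class_means[0] - self.class_means[1])


@dataclass
class ClassificationReport:
    """Per-class rates with the underlying confusion counts.

    ``classification_pct`` holds the cross-validated (or training)
    recognition per class; ``external_pct`` the held-out test performance.
    ``total_rate_pct`` per class is the mean of the two, mirroring the usual
    summary layout; pooled totals weight by sample counts.
    """

    classes: list
    confusion_cv: dict            # class -> (n_correct, n_total)
    confusion_external: dict      # class -> (n_correct, n_total)
    misclassified_cv: list = field(default_factory=list)
    misclassified_external: list = field(default_factory=list)

    @staticmethod
    def _pct(pair) -> float:
        c, n = pair
        return 100.0 * c / n if n else float("nan")

    @property
    def classification_pct(self) -> dict:
        return {k: self._pct(v) for k, v in self.confusion_cv.items()}

    @property
    def external_pct(self) -> dict:
        return {k: self._pct(v) for k, v in self.confusion_external.items()}

    @property
    def total_rate_pct(self) -> dict:
        out = {}
        for k in self.classes:
            c1, n1 = self.confusion_cv.get(k, (0, 0))
            c2, n2 = self.confusion_external.get(k, (0, 0))
            out[k] = self._pct((c1 + c2, n1 + n2))
        return out

    def _pool(self, conf) -> float:
        c = sum(v[0] for v in conf.values())
        n = sum(v[1] for v in conf.values())
        return self._pct((c, n))

    @property
    def classification_total(self) -> float:
        return self._pool(self.confusion_cv)

    @property
    def external_total(self) -> float:
        return self._pool(self.confusion_external)

    @property
    def total_rate_total(self) -> float:
        c = sum(v[0] for d in (self.confusion_cv, self.confusion_external)
                for v in d.values())
        n = sum(v[1] for d in (self.confusion_cv, self.confusion_external)
                for v in d.values())
        return self._pct((c, n))


def _prepare(X, labels):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    return X, labels, classes


def fit_lda(X: np.ndarray, labels: np.ndarray, priors: str = "equal",
            ridge: float | None = None) -> LDAModel:
    """Fit the two-class LDA model.

    ``priors``: "equal" or "proportional".  ``ridge``: explicit diagonal
    ridge; by default a ridge of ``1e-8 · trace(Σ)/p`` is applied only when
    the pooled covariance condition number exceeds 1e10.
    """
    X, labels, classes = _prepare(X, labels)
    n, p = X.shape
    means = np.zeros((2, p))
    scatter = np.zeros((p, p))
    counts = np.zeros(2, dtype=int)
    for k, c in enumerate(classes):
        block = X[labels == c]
        if block.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        if block.shape[0] < p / 3:
            import warnings
            warnings.warn(f"class {c!r}: only {block.shape[0]} samples for "
                          f"{p} variables; fit may be unstable")
        counts[k] = block.shape[0]
        means[k] = block.mean(axis=0)
        centered = block - means[k]
        scatter += centered.T @ centered
    cov = scatter / (n - 2)
    applied = 0.0
    if ridge is not None:
        applied = ridge
    else:
        cond = np.linalg.cond(cov)
        if not np.isfinite(cond) or cond > RIDGE_COND_LIMIT:
            applied = RIDGE_EPS * np.trace(cov) / p
    if applied:
        cov = cov + applied * np.eye(p)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance singular even after ridge; reduce the number "
            "of variables") from exc
    pri = (np.array([0.5, 0.5]) if priors == "equal"
           else counts / counts.sum())
    return LDAModel(classes, means, cov, cov_inv, pri, applied)


def discriminant_scores(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """(n, 2) matrix of g_k(x)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.class_means.shape[1]:
        raise ValueError("variable count mismatch")
    G = np.zeros((X.shape[0], 2))
    for k in range(2):
        mu = model.class_means[k]
        w = model.cov_inv @ mu
        G[:, k] = X @ w - 0.5 * mu @ w + np.log(model.priors[k])
    return G


def predict(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Argmax-discriminant labels; ties go to the first class in sorted order."""
    G = discriminant_scores(model, X)
    return np.where(G[:, 0] >= G[:, 1], model.classes[0], model.classes[1])


def canonical_scores(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """One-dimensional canonical variable, shifted so the decision threshold
    sits at zero: positive scores are assigned to the first (sorted) class.

    Equal to g₁(x) − g₂(x), i.e. xᵀΣ⁻¹(μ₁−μ₂) − ½(μ₁+μ₂)ᵀΣ⁻¹(μ₁−μ₂) + ln(π₁/π₂).
    """
    G = discriminant_scores(model, X)
    return G[:, 0] - G[:, 1]


def loo_cv(X: np.ndarray, labels: np.ndarray, priors: str = "equal",
           ridge: float | None = None, sample_ids=None) -> ClassificationReport:
    """Leave-one-out cross-validation via rank-one scatter downdates.

    Each held-out sample is predicted from a model carrying the remaining
    n−1 samples' class means and pooled covariance; identical to a naive
    refit-per-fold loop.
    """
    X, labels, classes = _prepare(X, labels)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples for LOO")
    idx_by_class = {c: np.flatnonzero(labels == c) for c in classes}
    for c, idx in idx_by_class.items():
        if idx.size < 3:
            raise ValueError(
                f"class {c!r} needs >= 3 samples so every LOO fold keeps >= 2")
    means = {c: X[idx].mean(axis=0) for c, idx in idx_by_class.items()}
    scatter = np.zeros((p, p))
    for c, idx in idx_by_class.items():
        centered = X[idx] - means[c]
        scatter += centered.T @ centered
    counts = {c: idx.size for c, idx in idx_by_class.items()}

    ids = list(sample_ids) if sample_ids is not None else list(range(n))
    correct = {c: 0 for c in classes}
    missed = []
    for i in range(n):
        ci = labels[i]
        nk = counts[ci]
        mu_k = means[ci]
        d = X[i] - mu_k
        mu_loo = (nk * mu_k - X[i]) / (nk - 1)
        scatter_loo = scatter - (nk / (nk - 1)) * np.outer(d, d)
        cov = scatter_loo / (n - 1 - 2)
        applied = ridge if ridge is not None else 0.0
        if ridge is None:
            cond = np.linalg.cond(cov)
            if not np.isfinite(cond) or cond > RIDGE_COND_LIMIT:
                applied = RIDGE_EPS * np.trace(cov) / p
        if applied:
            cov = cov + applied * np.eye(p)
        cov_inv = np.linalg.inv(cov)
        fold_means = np.vstack([mu_loo if c == ci else means[c] for c in classes])
        fold_counts = np.array([counts[c] - (c == ci) for c in classes], dtype=float)
        pri = (np.array([0.5, 0.5]) if priors == "equal"
               else fold_counts / fold_counts.sum())
        fold = LDAModel(classes, fold_means, cov, cov_inv, pri, applied)
        pred = predict(fold, X[i][None, :])[0]
        if pred == ci:
            correct[ci] += 1
        else:
            missed.append(ids[i])
    conf = {c: (correct[c], counts[c]) for c in classes}
    return ClassificationReport(list(classes), conf, {c: (0, 0) for c in classes},
                                misclassified_cv=missed)


def loo_cv_naive(X: np.ndarray, labels: np.ndarray, priors: str = "equal",
                 ridge: float | None = None) -> np.ndarray:
    """Reference LOO: refit from scratch per fold.  Returns predicted labels."""
    X, labels, _ = _prepare(X, labels)
    n = X.shape[0]
    preds = np.empty(n, dtype=object)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_lda(X[mask], labels[mask], priors=priors, ridge=ridge)
        preds[i] = predict(model, X[i][None, :])[0]
    return preds


def evaluate(model: LDAModel, X_test: np.ndarray, y_test: np.ndarray,
             report: ClassificationReport | None = None,
             sample_ids=None) -> ClassificationReport:
    """External prediction rates; optionally merged into an LOO report."""
    preds = predict(model, X_test)
    y_test = np.asarray(y_test)
    ids = list(sample_ids) if sample_ids is not None else list(range(len(y_test)))
    conf = {}
    missed = []
    for c in model.classes:
        m = y_test == c
        conf[c] = (int((preds[m] == c).sum()), int(m.sum()))
    for i, (p_, t) in enumerate(zip(preds, y_test)):
        if p_ != t:
            missed.append(ids[i])
    if report is None:
        return ClassificationReport(list(model.classes),
                                    {c: (0, 0) for c in model.classes}, conf,
                                    misclassified_external=missed)
    return ClassificationReport(report.classes, report.confusion_cv, conf,
                                misclassified_cv=report.misclassified_cv,
                                misclassified_external=missed)
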