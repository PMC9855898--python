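"""SELECT — stepwise orthogonalization of predictors.

At each step the most class-discriminating variable (largest two-class
Fisher weight) is selected, then every remaining candidate column is replaced
by its residual after least-squares regression on the selected column, so
later selections carry no information already captured.  Selection stops at a
fixed ``k_max``, at the training-objects rule (at least ``min_ratio`` training
samples per selected variable, default 3), or when the best remaining weight
falls below ``weight_floor``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SelectResult:
    selected: list[int]            # column indices in selection order
    weights: list[float]           # Fisher weight at the moment of selection
    stop_reason: str               # "k_max" | "ratio_rule" | "weight_floor"
    X_ortho: np.ndarray            # working matrix after the final step

    @property
    def k(self) -> int:
        return len(self.selected)

    def selected_wavenumbers(self, grid: np.ndarray) -> np.ndarray:
        return np.asarray(grid)[self.selected]


def fisher_weight(x: np.ndarray, labels: np.ndarray) -> float:
    """Two-class Fisher weight w = (m₁ − m₂)² / (s₁² + s₂²).

    Per-class variances use the n−1 denominator.  Degenerate cases: equal
    means with zero pooled variance → 0; unequal means with zero variance →
    +inf (selected first).
    """
    x = np.asarray(x, dtype=float)
    classes = _two_classes(labels)
    g1, g2 = (x[labels == c] for c in classes)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each class needs at least 2 samples")
    num = (g1.mean() - g2.mean()) ** 2
    den = g1.var(ddof=1) + g2.var(ddof=1)
    if den == 0:
        return 0.0 if num == 0 else np.inf
    return num / den


def fisher_weights(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorised Fisher weights for every column of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    classes = _two_classes(labels)
    m1, m2 = (labels == classes[0]), (labels == classes[1])
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    num = (X[m1].mean(axis=0) - X[m2].mean(axis=0)) ** 2
    den = X[m1].var(axis=0, ddof=1) + X[m2].var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(den > 0, num / den, np.where(num > 0, np.inf, 0.0))
    return w


def _two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    return classes


def orthogonalize_against(X: np.ndarray, j: int) -> np.ndarray:
    """Residualize every column of X against column j (with intercept);
    column j itself is zeroed out of the candidate pool."""
    X = np.array(X, dtype=float)
    xj = X[:, j]
    if xj.var(ddof=1) == 0:
        raise ValueError(f"column {j} has zero variance; cannot orthogonalize")
    xc = xj - xj.mean()
    # slope of each column on xj, with intercept
    Xc = X - X.mean(axis=0)
    beta = Xc.T @ xc / (xc @ xc)
    resid = Xc - np.outer(xc, beta)
    # residuals keep their own means removed; reattach nothing (the Fisher
    # weight and later regressions are location-free)
    resid[:, j] = 0.0
    return resid


def run_select(X: np.ndarray, labels: np.ndarray, k_max: int = 20,
               min_ratio: float = 3.0, weight_floor: float = 0.0) -> SelectResult:
    """Run the full stepwise selection loop.

    Ties in the weight argmax break to the lowest column index, which on a
    descending-wavenumber grid is the highest wavenumber.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    n = X.shape[0]
    k_cap = int(np.floor(n / min_ratio)) if min_ratio > 0 else X.shape[1]
    if k_cap < 1:
        raise ValueError(f"training size {n} too small for min_ratio {min_ratio}")
    work = X.copy()
    selected: list[int] = []
    weights: list[float] = []
    limit = min(k_max, k_cap, X.shape[1])
    stop = "k_max" if limit == k_max else "ratio_rule"
    while len(selected) < limit:
        w = fisher_weights(work, labels)
        w[selected] = -np.inf
        j = int(np.argmax(w))            # first (lowest index) tie wins
        if w[j] < weight_floor:
            stop = "weight_floor"
            break
        selected.append(j)
        weights.append(float(w[j]))
        if work[:, j].var(ddof=1) > 0:
            work = orthogonalize_against(work, j)
    return SelectResult(selected, weights, stop, work)
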