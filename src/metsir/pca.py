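"""Principal component analysis by NIPALS (iterative sequential deflation).

NIPALS extracts components one at a time: pick a starting score vector,
alternate ``p = Xᵀt/tᵀt`` (normalised) and ``t = Xp`` until the scores
stabilise, then deflate ``X ← X − t pᵀ``.  It is the classic chemometric
PCA engine and the inner model of SIMCA; for well-conditioned data it agrees
with the eigendecomposition of the covariance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class PCAModel:
    center: np.ndarray
    scale: np.ndarray                 # per-variable SDs, or ones
    loadings: np.ndarray              # (p, A), orthonormal columns
    scores: np.ndarray                # (n, A) training scores
    explained_variance: np.ndarray    # fraction per component
    n_components: int
    n_train: int
    iterations: list[int] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)

    @property
    def n_variables(self) -> int:
        return self.center.size

    def standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_variables:
            raise ValueError(
                f"variable count {X.shape[1]} != model's {self.n_variables}")
        return (X - self.center) / self.scale

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "scores": self.scores.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "n_components": self.n_components,
            "n_train": self.n_train,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAModel":
        return cls(
            center=np.array(d["center"]),
            scale=np.array(d["scale"]),
            loadings=np.array(d["loadings"]),
            scores=np.array(d["scores"]),
            explained_variance=np.array(d["explained_variance"]),
            n_components=int(d["n_components"]),
            n_train=int(d["n_train"]),
        )


def fit_nipals(X: np.ndarray, n_components: int, tol: float = 1e-10,
               max_iter: int = 500, scale: bool = False) -> PCAModel:
    """Fit a PCA model with sequential NIPALS deflation.

    Parameters
    ----------
    X : (n, p) data matrix, n >= 2.
    n_components : number of components, <= min(n-1, p).
    tol : relative score-change convergence threshold per component.
    max_iter : iteration cap per component (warn and record on hit).
    scale : autoscale (unit-variance) the columns in addition to centering.

    Component signs are fixed so the largest-magnitude loading element of
    each component is positive.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not 0 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in [0, {min(n - 1, p)}]")
    center = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            j = int(np.flatnonzero(sd == 0)[0])
            raise ValueError(f"zero-variance column {j} cannot be autoscaled")
    else:
        sd = np.ones(p)
    Xw = (X - center) / sd
    total_var = np.sum(Xw ** 2) / (n - 1)

    loadings = np.zeros((p, n_components))
    scores = np.zeros((n, n_components))
    expl = np.zeros(n_components)
    iters, convs = [], []
    for a in range(n_components):
        t = Xw[:, int(np.argmax(Xw.var(axis=0)))].copy()
        if not np.any(t):
            t = Xw[:, 0].copy()
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            denom = t @ t
            if denom == 0:  # exhausted rank: leave component at zero
                break
            pvec = Xw.T @ t / denom
            norm = np.linalg.norm(pvec)
            if norm == 0:
                break
            pvec /= norm
            t_new = Xw @ pvec
            delta = np.linalg.norm(t_new - t) / (np.linalg.norm(t_new) or 1.0)
            t = t_new
            if delta < tol:
                converged = True
                break
        if not converged:
            warnings.warn(f"NIPALS component {a + 1} did not converge "
                          f"in {max_iter} iterations")
        # deterministic sign: largest |loading| element positive
        if np.any(pvec):
            jmax = int(np.argmax(np.abs(pvec)))
            if pvec[jmax] < 0:
                pvec = -pvec
                t = -t
        loadings[:, a] = pvec
        scores[:, a] = t
        expl[a] = (t @ t) / (n - 1) / total_var if total_var > 0 else 0.0
        Xw = Xw - np.outer(t, pvec)
        iters.append(it)
        convs.append(converged)
    return PCAModel(center, sd, loadings, scores, expl, n_components, n,
                    iterations=iters, converged=convs)


def project(model: PCAModel, X_new: np.ndarray) -> np.ndarray:
    """Scores of new samples: standardized(X) @ loadings."""
    return model.standardize(X_new) @ model.loadings


def residual_matrix(model: PCAModel, X: np.ndarray) -> np.ndarray:
    Z = model.standardize(X)
    T = Z @ model.loadings
    return Z - T @ model.loadings.T


def residual_stats(model: PCAModel, X: np.ndarray):
    """Per-sample and per-variable residual standard deviations.

    s_i = sqrt(Σ_j e_ij² / (p − A));  s_j = sqrt(Σ_i e_ij² / (n − A − 1)).
    """
    E = residual_matrix(model, X)
    n, p = E.shape
    A = model.n_components
    if p <= A:
        raise ValueError("need more variables than components")
    s_sample = np.sqrt((E ** 2).sum(axis=1) / (p - A))
    df_var = n - A - 1
    if df_var < 1:
        raise ValueError("need n > A + 1 for per-variable residual SDs")
    s_variable = np.sqrt((E ** 2).sum(axis=0) / df_var)
    return s_sample, s_variable


def outlier_flags(model: PCAModel, X: np.ndarray, alpha: float = 0.01,
                  leverage_factor: float = 3.0) -> np.ndarray:
    """Exploration-stage outlier screen on the data the model was fitted to.

    Flags samples whose reduced residual distance exceeds the F-limit at
    ``alpha`` or whose score-space leverage exceeds ``leverage_factor * A/n``.
    """
    from scipy import stats as sstats

    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, A = X.shape[0], model.n_components
    p = model.n_variables
    flags = np.zeros(n, dtype=bool)
    if n > A + 1 and p > A:
        E = residual_matrix(model, X)
        s_sample = np.sqrt((E ** 2).sum(axis=1) / (p - A))
        s0_sq = (E ** 2).sum() / ((n - A - 1) * (p - A))
        if s0_sq > 0:
            fcrit = sstats.f.ppf(1 - alpha, p - A, (n - A - 1) * (p - A))
            flags |= s_sample ** 2 / s0_sq > fcrit
    if A > 0:
        score_var = model.scores.var(axis=0, ddof=1)
        T = project(model, X)
        leverage = 1.0 / n + ((T ** 2) / (score_var * (model.n_train - 1))).sum(axis=1)
        flags |= leverage > leverage_factor * A / n
    return flags
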