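"""SIMCA — soft independent modelling by class analogy.

One PCA model (NIPALS, after within-class autoscaling) is fitted per class.
A sample is accepted by a class when its residual standard deviation around
that class model is not significantly larger than the class residual standard
deviation, by a one-sided F-test at significance ``alpha`` (default 5%):

    s(x)² = Σ_j e_j² / (p − A)
    s0²   = Σ_i Σ_j e_ij² / ((n − A − 1)(p − A))
    accept  iff  s(x)²/s0² ≤ F(1−α; p−A, (n−A−1)(p−A))

The reduced distance d = s(x)/s0 and the critical distance
sqrt(F(1−α)) give the axes and class boundaries of a Cooman's plot.
Diagnostics: per-variable modelling power (MP), per-variable discriminant
power (DP), the aggregate interclass distance, and the sensitivity /
specificity / efficiency summaries under leave-one-out and forced
(nearest-model) assignment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .pca import PCAModel, fit_nipals, project


@dataclass
class SIMCAClassModel:
    label: str
    pca: PCAModel
    s0: float                  # class residual SD (autoscaled units)
    alpha: float
    df1: int                   # p − A
    df2: int                   # (n − A − 1)(p − A)
    crit_distance: float       # sqrt of the F quantile

    @property
    def n_components(self) -> int:
        return self.pca.n_components

    def to_dict(self) -> dict:
        return {"label": self.label, "pca": self.pca.to_dict(), "s0": self.s0,
                "alpha": self.alpha, "df1": self.df1, "df2": self.df2,
                "crit_distance": self.crit_distance}

    @classmethod
    def from_dict(cls, d: dict) -> "SIMCAClassModel":
        return cls(label=d["label"], pca=PCAModel.from_dict(d["pca"]),
                   s0=float(d["s0"]), alpha=float(d["alpha"]),
                   df1=int(d["df1"]), df2=int(d["df2"]),
                   crit_distance=float(d["crit_distance"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "SIMCAClassModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SIMCAssignment:
    sample_ids: list
    distances: np.ndarray      # (n, n_models) reduced distances
    accepted: np.ndarray       # (n, n_models) bool
    membership: list           # per sample: label, "both", or "none"
    forced: np.ndarray         # per sample: nearest model's label


def fit_class_model(X_class: np.ndarray, n_components: int,
                    alpha: float = 0.05, label: str = "") -> SIMCAClassModel:
    """Fit one class model: autoscale, NIPALS, class residual SD, F limit."""
    X_class = np.atleast_2d(np.asarray(X_class, dtype=float))
    n, p = X_class.shape
    A = n_components
    if n < A + 2:
        raise ValueError(f"class {label!r}: need n >= A + 2 (n={n}, A={A})")
    sd = X_class.std(axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"class {label!r}: variable {j} has zero variance")
    pca = fit_nipals(X_class, A, scale=True)
    Z = pca.standardize(X_class)
    E = Z - (Z @ pca.loadings) @ pca.loadings.T
    df1 = p - A
    df2 = (n - A - 1) * (p - A)
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    s0 = float(np.sqrt((E ** 2).sum() / df2))
    crit = float(np.sqrt(stats.f.ppf(1 - alpha, df1, df2)))
    return SIMCAClassModel(label, pca, s0, alpha, df1, df2, crit)


def distance_to_model(model: SIMCAClassModel, X: np.ndarray) -> np.ndarray:
    """Reduced residual distance d = s(x)/s0 for each row of X."""
    Z = model.pca.standardize(X)
    E = Z - (Z @ model.pca.loadings) @ model.pca.loadings.T
    s = np.sqrt((E ** 2).sum(axis=1) / model.df1)
    return s / model.s0


def accepts(model: SIMCAClassModel, X: np.ndarray) -> np.ndarray:
    return distance_to_model(model, X) <= model.crit_distance


def score_distance(model: SIMCAClassModel, X: np.ndarray) -> np.ndarray:
    """Normalized score-space Mahalanobis distance.

    sqrt((m²/A) / F(1−α; A, n−A)), where m² uses the training score
    variances; equals 1 at its own acceptance limit.
    """
    A = model.n_components
    if A == 0:
        return np.zeros(np.atleast_2d(X).shape[0])
    T = project(model.pca, X)
    var = model.pca.scores.var(axis=0, ddof=1)
    m2 = ((T ** 2) / var).sum(axis=1)
    n = model.pca.n_train
    fcrit = stats.f.ppf(1 - model.alpha, A, max(n - A, 1))
    return np.sqrt(m2 / A / fcrit)


def augmented_distance(model: SIMCAClassModel, X: np.ndarray) -> np.ndarray:
    """Unweighted augmented distance: equal-weight quadrature combination of
    the residual distance and the score-space distance, each normalized by
    its own 1−α limit so the acceptance boundary sits at 1."""
    d_res = distance_to_model(model, X) / model.crit_distance
    d_sco = score_distance(model, X)
    return np.sqrt(0.5 * (d_res ** 2 + d_sco ** 2))


def assign(models, X: np.ndarray, sample_ids=None) -> SIMCAssignment:
    """Four-way membership (one class / both / none) plus forced assignment."""
    models = list(models)
    if len(models) < 2:
        raise ValueError("need at least 2 class models")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D = np.column_stack([distance_to_model(m, X) for m in models])
    acc = D <= np.array([m.crit_distance for m in models])
    labels = [m.label for m in models]
    membership = []
    for row in acc:
        hits = [labels[k] for k in np.flatnonzero(row)]
        membership.append(hits[0] if len(hits) == 1
                          else ("both" if len(hits) == len(labels) and len(labels) == 2
                                else ("none" if not hits else "+".join(hits))))
    forced = np.array([labels[int(k)] for k in np.argmin(D, axis=1)], dtype=object)
    ids = list(sample_ids) if sample_ids is not None else list(range(X.shape[0]))
    return SIMCAssignment(ids, D, acc, membership, forced)


def _pervar_sq_residuals(model: SIMCAClassModel, X: np.ndarray) -> np.ndarray:
    Z = model.pca.standardize(X)
    E = Z - (Z @ model.pca.loadings) @ model.pca.loadings.T
    return (E ** 2).sum(axis=0)


def modelling_power(model: SIMCAClassModel, X_class: np.ndarray) -> np.ndarray:
    """MP_j = 1 − s_j(residual)/s_j(total), clipped below at 0.

    In the autoscaled class space the total per-variable SD is 1 by
    construction; the residual SD uses the n − A − 1 denominator.
    """
    X_class = np.atleast_2d(np.asarray(X_class, dtype=float))
    n = X_class.shape[0]
    A = model.n_components
    sq = _pervar_sq_residuals(model, X_class)
    s_res = np.sqrt(sq / (n - A - 1))
    return np.clip(1.0 - s_res, 0.0, None)


def discriminant_power(model1: SIMCAClassModel, model2: SIMCAClassModel,
                       X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """DP_j = sqrt((Σe²_j(X2|M1) + Σe²_j(X1|M2)) / (Σe²_j(X1|M1) + Σe²_j(X2|M2))).

    ≈ 1 for a variable distributed identically in both classes; large values
    mark variables that discriminate.  Symmetric under swapping the classes.
    """
    cross = _pervar_sq_residuals(model1, X2) + _pervar_sq_residuals(model2, X1)
    own = _pervar_sq_residuals(model1, X1) + _pervar_sq_residuals(model2, X2)
    with np.errstate(divide="ignore", invalid="ignore"):
        dp = np.sqrt(np.where(own > 0, cross / own, np.inf))
    if np.any(own == 0):
        warnings.warn("zero self-residual for some variable; DP set to +inf")
    return dp


def class_distance(model1: SIMCAClassModel, model2: SIMCAClassModel,
                   X1: np.ndarray, X2: np.ndarray) -> float:
    """Aggregate interclass distance; 1.0 for a class against itself."""
    cross = (_pervar_sq_residuals(model1, X2).sum()
             + _pervar_sq_residuals(model2, X1).sum())
    own = (_pervar_sq_residuals(model1, X1).sum()
           + _pervar_sq_residuals(model2, X2).sum())
    if own == 0:
        warnings.warn("zero self-residual; class distance set to +inf")
        return float("inf")
    return float(np.sqrt(cross / own))


def coomans_coordinates(models, X: np.ndarray, augmented: bool = False):
    """Per-sample (d1, d2) distances to the two class models plus the two
    critical boundaries.  ``augmented=True`` uses the unweighted augmented
    distance (boundaries then both equal 1)."""
    models = list(models)
    if len(models) != 2:
        raise ValueError("Cooman coordinates need exactly 2 models")
    if augmented:
        d1, d2 = (augmented_distance(m, X) for m in models)
        crit = (1.0, 1.0)
    else:
        d1, d2 = (distance_to_model(m, X) for m in models)
        crit = (models[0].crit_distance, models[1].crit_distance)
    return d1, d2, crit


def sample_from_model(model: SIMCAClassModel, n: int, rng) -> np.ndarray:
    """Draw new samples consistent with a fitted class model: scores from
    the training score variances, residuals i.i.d. N(0, s0²), mapped back to
    the original variable units."""
    p = model.pca.n_variables
    A = model.n_components
    T = rng.normal(0.0, np.sqrt(model.pca.scores.var(axis=0, ddof=1)),
                   size=(n, A)) if A else np.zeros((n, 0))
    E = rng.normal(0.0, model.s0, size=(n, p))
    Z = T @ model.pca.loadings.T + E
    return Z * model.pca.scale + model.pca.center


@dataclass
class SIMCADiagnostics:
    name: str
    classification_pct: float      # training recognition (own-class acceptance)
    loo_pct: float                 # LOO own-class acceptance
    cv_efficiency_pct: float       # sqrt(sensitivity × specificity), LOO
    forced_efficiency_pct: float   # same under forced nearest-model assignment
    total_rate_pct: float          # external-test forced-assignment accuracy
    per_class: dict = field(default_factory=dict)


def fit_models(X: np.ndarray, labels: np.ndarray, n_components,
               alpha: float = 0.05):
    """Fit one class model per label.  ``n_components`` may be an int or a
    mapping label → A."""
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels))
    models = []
    for c in classes:
        A = n_components[c] if isinstance(n_components, dict) else n_components
        block = np.atleast_2d(np.asarray(X, dtype=float))[labels == c]
        A_eff = min(A, block.shape[0] - 2)
        if A_eff < A:
            warnings.warn(f"class {c!r}: A reduced from {A} to {A_eff} "
                          f"(only {block.shape[0]} samples)")
        models.append(fit_class_model(block, max(A_eff, 1), alpha, label=str(c)))
    return models


def simca_report(models, X_train, y_train, X_test=None, y_test=None,
                 name: str = "simca", alpha: float | None = None) -> tuple:
    """Full SIMCA performance summary.

    Returns ``(SIMCADiagnostics, SIMCAssignment)`` where the assignment holds
    the training-set distances.  LOO refits the left-out sample's own class
    model without it; the other class model is unchanged.
    """
    models = list(models)
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    y_train = np.asarray(y_train)
    labels = [m.label for m in models]
    lab_index = {lab: k for k, lab in enumerate(labels)}
    n = X_train.shape[0]

    assignment = assign(models, X_train)
    own_k = np.array([lab_index[str(c)] for c in y_train])

    # training recognition: acceptance by the own class model
    acc_own = assignment.accepted[np.arange(n), own_k]
    classification_pct = 100.0 * acc_own.mean()

    # LOO: refit the left-out sample's class model without it
    loo_acc = np.zeros(n, dtype=bool)
    loo_dist = np.zeros((n, len(models)))
    for i in range(n):
        k = own_k[i]
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        block = X_train[mask & (own_k == k)]
        m_loo = fit_class_model(block, min(models[k].n_components, block.shape[0] - 2),
                                models[k].alpha, label=labels[k])
        for j, m in enumerate(models):
            loo_dist[i, j] = (distance_to_model(m_loo, X_train[i][None])[0]
                              if j == k else assignment.distances[i, j])
        loo_acc[i] = loo_dist[i, k] <= m_loo.crit_distance
    loo_pct = 100.0 * loo_acc.mean()

    # sensitivity / specificity per model under LOO acceptance
    crit = np.array([m.crit_distance for m in models])
    loo_accept_matrix = loo_dist <= crit
    sens, spec = {}, {}
    for k, lab in enumerate(labels):
        own = own_k == k
        sens[lab] = loo_accept_matrix[own, k].mean() if own.any() else np.nan
        spec[lab] = (~loo_accept_matrix[~own, k]).mean() if (~own).any() else np.nan
    cv_eff = 100.0 * float(np.sqrt(np.nanmean(list(sens.values()))
                                   * np.nanmean(list(spec.values()))))

    # forced-model efficiency: nearest model under LOO distances
    forced_loo = np.argmin(loo_dist, axis=1)
    f_sens, f_spec = {}, {}
    for k, lab in enumerate(labels):
        own = own_k == k
        pred_k = forced_loo == k
        f_sens[lab] = pred_k[own].mean() if own.any() else np.nan
        f_spec[lab] = (~pred_k[~own]).mean() if (~own).any() else np.nan
    forced_eff = 100.0 * float(np.sqrt(np.nanmean(list(f_sens.values()))
                                       * np.nanmean(list(f_spec.values()))))

    # external test: forced nearest-model assignment accuracy
    total_rate = float("nan")
    if X_test is not None and y_test is not None and len(np.atleast_2d(X_test)):
        test_assign = assign(models, X_test)
        total_rate = 100.0 * float(
            (test_assign.forced == np.asarray(y_test, dtype=object)).mean())

    per_class = {lab: {"sensitivity": float(sens[lab]),
                       "specificity": float(spec[lab]),
                       "forced_sensitivity": float(f_sens[lab]),
                       "forced_specificity": float(f_spec[lab])}
                 for lab in labels}
    diag = SIMCADiagnostics(name, classification_pct, loo_pct, cv_eff,
                            forced_eff, total_rate, per_class)
    return diag, assignment
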