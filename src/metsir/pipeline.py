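"""End-to-end orchestration of the dual classification study.

Four branches share one stratified train/test split:

* clinical LDA (five measured parameters, LOO + external prediction),
* SELECT-LDA on preprocessed spectra (k ≤ 20 selected wavenumbers),
* SIMCA class modelling on clinical parameters,
* SELECT-SIMCA on spectra (the 20-variable SELECT ranking truncated to 10 by
  a recognition-guided greedy drop).

Plus exploration PCA on both blocks and NCEP-ATP-III rule labels.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io_formats, lda, mets_rules, preprocess, selection, simca
from .io_formats import ClinicalTable, SpectraSet
from .pca import fit_nipals, project
from .preprocess import PreprocessPlan, mean_center
from .synthetic import SyntheticDataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    n_test: int = 10
    stratified: bool = True
    seed: int = 0
    select_k_lda: int = 20
    select_k_simca: int = 10
    min_ratio: float = 3.0
    lda_priors: str = "equal"
    simca_components_clinical: int = 4
    simca_components_spectral: int = 3
    alpha: float = 0.05
    thresholds: mets_rules.CriteriaThresholds = field(
        default_factory=mets_rules.CriteriaThresholds)
    plan: PreprocessPlan = field(default_factory=PreprocessPlan)

    def digest(self) -> str:
        payload = {k: repr(v) for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def split_train_test(labels: np.ndarray, n_test: int, seed: int,
                     stratified: bool = True):
    """Random (optionally stratified) train/test row split.

    Stratification allocates test slots per class proportionally (largest
    remainder), keeping the class ratio within one sample.
    """
    labels = np.asarray(labels)
    n = labels.size
    if not 0 < n_test < n:
        raise ValueError(f"n_test must be in (0, {n})")
    rng = np.random.default_rng(seed)
    if not stratified:
        test_idx = rng.choice(n, size=n_test, replace=False)
    else:
        classes, counts = np.unique(labels, return_counts=True)
        exact = counts / n * n_test
        base = np.floor(exact).astype(int)
        rem = n_test - base.sum()
        order = np.argsort(-(exact - base))
        base[order[:rem]] += 1
        parts = []
        for c, k in zip(classes, base):
            idx = np.flatnonzero(labels == c)
            parts.append(rng.choice(idx, size=k, replace=False))
        test_idx = np.concatenate(parts)
    test_mask = np.zeros(n, dtype=bool)
    test_mask[test_idx] = True
    train_idx = np.flatnonzero(~test_mask)
    for c in np.unique(labels):
        if not np.any(labels[train_idx] == c):
            raise ValueError(f"class {c!r} absent from the training split")
    return train_idx, np.sort(test_idx)


def count_in_region(wavenumbers, region) -> int:
    """Number of listed wavenumbers ν with low ≤ ν ≤ high."""
    high, low = region
    nu = np.asarray(wavenumbers, dtype=float)
    return int(((nu >= low) & (nu <= high)).sum())


def truncate_for_simca(X_train, y_train, ranking, weights, target: int,
                       n_components, alpha: float = 0.05) -> list[int]:
    """Reduce a SELECT ranking to ``target`` variables for SIMCA.

    Greedy: at each step, drop the variable (among the current set) whose
    removal maximizes the SIMCA training recognition (own-class acceptance);
    ties resolve to the variable with the lowest selection weight.
    """
    current = list(ranking)
    w = {v: wt for v, wt in zip(ranking, weights)}
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    y_train = np.asarray(y_train)

    def recognition(cols):
        models = simca.fit_models(X_train[:, cols], y_train, n_components, alpha)
        acc = 0
        for m in models:
            block = X_train[np.asarray(y_train).astype(str) == m.label][:, cols]
            acc += int(simca.accepts(m, block).sum())
        return acc / X_train.shape[0]

    while len(current) > target:
        best = None
        for v in sorted(current, key=lambda v: w[v]):
            cols = [c for c in current if c != v]
            try:
                r = recognition(cols)
            except ValueError:
                continue
            if best is None or r > best[0] + 1e-12:
                best = (r, v)
        if best is None:
            raise ValueError("cannot reduce the variable set further")
        current.remove(best[1])
    return current


@dataclass
class DualClassificationResult:
    config_digest: str
    seed: int
    train_ids: list
    test_ids: list
    rule_labels: pd.Series
    lda_clinical: lda.ClassificationReport
    lda_spectral: lda.ClassificationReport
    selected_lda: list[float]          # wavenumbers used by SELECT-LDA
    selected_simca: list[float]        # wavenumbers used by SELECT-SIMCA
    simca_clinical: simca.SIMCADiagnostics
    simca_spectral: simca.SIMCADiagnostics
    powers_clinical: pd.DataFrame
    powers_spectral: pd.DataFrame
    coomans_clinical: pd.DataFrame
    coomans_spectral: pd.DataFrame
    pca_scores: dict

    def report_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "lda_clinical_rates": io_formats.rates_frame(self.lda_clinical),
            "lda_spectral_rates": io_formats.rates_frame(self.lda_spectral),
            "simca_summary": pd.concat([
                io_formats.simca_summary_frame(self.simca_clinical),
                io_formats.simca_summary_frame(self.simca_spectral)]),
            "powers_clinical": self.powers_clinical,
            "powers_spectral": self.powers_spectral,
            "coomans_clinical": self.coomans_clinical,
            "coomans_spectral": self.coomans_spectral,
        }


def _coomans_frame(models, X, ids, labels, augmented=False) -> pd.DataFrame:
    d1, d2, crit = simca.coomans_coordinates(models, X, augmented=augmented)
    df = pd.DataFrame({
        f"d_{models[0].label}": d1,
        f"d_{models[1].label}": d2,
        "label": np.asarray(labels, dtype=object),
    }, index=pd.Index(ids, name="sample_id"))
    df.attrs["crit"] = crit
    df[f"crit_{models[0].label}"] = crit[0]
    df[f"crit_{models[1].label}"] = crit[1]
    return df


def run_dual_classification(dataset: SyntheticDataset | None = None,
                            spectra: SpectraSet | None = None,
                            clinical: ClinicalTable | None = None,
                            config: PipelineConfig | None = None
                            ) -> DualClassificationResult:
    """Run all four classification branches on one shared split."""
    config = config or PipelineConfig()
    if dataset is not None:
        spectra, clinical = dataset.spectra, dataset.clinical
    if spectra is None or clinical is None:
        raise ValueError("need either a dataset or spectra + clinical table")

    # --- labels: provided if known, otherwise from the rule engine
    clinical.require_complete()
    rule_labels = mets_rules.label_table(clinical, config.thresholds)
    labels = clinical.data["label"].copy()
    unknown = labels == "unknown"
    labels[unknown] = rule_labels[unknown]

    # --- preprocess spectra (replicates averaged inside the plan)
    spec = config.plan.apply(spectra)
    # align spectra rows to the clinical table order
    order = [spec.sample_ids.index(sid) for sid in clinical.sample_ids]
    spec = spec.subset_rows(order)
    y = labels.to_numpy(dtype=object)
    ids = clinical.sample_ids

    # --- shared stratified split
    train_idx, test_idx = split_train_test(y, config.n_test, config.seed,
                                           config.stratified)
    tr, te = train_idx, test_idx
    train_ids = [ids[i] for i in tr]
    test_ids = [ids[i] for i in te]
    logger.info("split: %d train / %d test (config %s, seed %d)",
                len(tr), len(te), config.digest(), config.seed)

    Xc = clinical.values()
    Xs = spec.absorbance
    y_tr, y_te = y[tr], y[te]

    # --- exploration PCA (centering only) on both blocks
    pca_scores = {}
    for name, X in (("clinical", Xc), ("spectra", Xs)):
        m = fit_nipals(X[tr], min(2, len(tr) - 1), scale=False)
        pca_scores[name] = {
            "train": project(m, X[tr]),
            "test": project(m, X[te]),
            "explained_variance": m.explained_variance.tolist(),
        }

    # --- branch 1: LDA on the five clinical parameters
    rep = lda.loo_cv(Xc[tr], y_tr, priors=config.lda_priors, sample_ids=train_ids)
    model_c = lda.fit_lda(Xc[tr], y_tr, priors=config.lda_priors)
    lda_clinical = lda.evaluate(model_c, Xc[te], y_te, rep, sample_ids=test_ids)

    # --- centering of spectra with training means (spectral branches)
    Xs_tr, col_means = mean_center(Xs[tr])
    Xs_te, _ = mean_center(Xs[te], col_means)

    # --- branch 2: SELECT-LDA on spectra
    sel = selection.run_select(Xs_tr, y_tr, k_max=config.select_k_lda,
                               min_ratio=config.min_ratio)
    cols20 = sel.selected
    rep = lda.loo_cv(Xs_tr[:, cols20], y_tr, priors=config.lda_priors,
                     sample_ids=train_ids)
    model_s = lda.fit_lda(Xs_tr[:, cols20], y_tr, priors=config.lda_priors)
    lda_spectral = lda.evaluate(model_s, Xs_te[:, cols20], y_te, rep,
                                sample_ids=test_ids)

    # --- branch 3: SIMCA on clinical parameters
    models_c = simca.fit_models(Xc[tr], y_tr, config.simca_components_clinical,
                                config.alpha)
    simca_clinical, _ = simca.simca_report(
        models_c, Xc[tr], y_tr, Xc[te], y_te, name="clinical")
    blocks_c = [Xc[tr][y_tr == m.label] for m in models_c]
    powers_clinical = io_formats.power_frame(
        list(io_formats.CLINICAL_COLUMNS),
        simca.discriminant_power(models_c[0], models_c[1], *blocks_c),
        simca.modelling_power(models_c[0], blocks_c[0]),
        simca.modelling_power(models_c[1], blocks_c[1]),
        class_names=(models_c[0].label, models_c[1].label),
        var_name="parameter")
    coomans_clinical = _coomans_frame(models_c, Xc[np.concatenate([tr, te])],
                                      train_ids + test_ids,
                                      np.concatenate([y_tr, y_te]))

    # --- branch 4: SELECT-SIMCA on spectra (20 -> 10 recognition-guided)
    cols10 = truncate_for_simca(Xs_tr, y_tr, cols20, sel.weights,
                                config.select_k_simca,
                                config.simca_components_spectral, config.alpha)
    models_s = simca.fit_models(Xs_tr[:, cols10], y_tr,
                                config.simca_components_spectral, config.alpha)
    simca_spectral, _ = simca.simca_report(
        models_s, Xs_tr[:, cols10], y_tr, Xs_te[:, cols10], y_te, name="spectral")
    blocks_s = [Xs_tr[:, cols10][y_tr == m.label] for m in models_s]
    nu10 = spec.wavenumbers[cols10]
    powers_spectral = io_formats.power_frame(
        [f"{v:.2f}" for v in nu10],
        simca.discriminant_power(models_s[0], models_s[1], *blocks_s),
        simca.modelling_power(models_s[0], blocks_s[0]),
        simca.modelling_power(models_s[1], blocks_s[1]),
        class_names=(models_s[0].label, models_s[1].label))
    coomans_spectral = _coomans_frame(
        models_s, np.vstack([Xs_tr[:, cols10], Xs_te[:, cols10]]),
        train_ids + test_ids, np.concatenate([y_tr, y_te]))

    return DualClassificationResult(
        config_digest=config.digest(),
        seed=config.seed,
        train_ids=train_ids,
        test_ids=test_ids,
        rule_labels=rule_labels,
        lda_clinical=lda_clinical,
        lda_spectral=lda_spectral,
        selected_lda=spec.wavenumbers[cols20].tolist(),
        selected_simca=nu10.tolist(),
        simca_clinical=simca_clinical,
        simca_spectral=simca_spectral,
        powers_clinical=powers_clinical,
        powers_spectral=powers_spectral,
        coomans_clinical=coomans_clinical,
        coomans_spectral=coomans_spectral,
        pca_scores=pca_scores,
    )
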