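"""Fidelity battery: does synthetic data look like real data?

Three views, increasingly multivariate:

* per-ROI, age-adjusted group tests (real vs synthetic) with Bonferroni
  family-wise control at alpha/145;
* a real-vs-synthetic discriminator (linear-kernel max-margin classifier,
  5-fold cross-validated AUC; 0.5 means indistinguishable);
* covariate prediction (sex / race classification, age regression with
  gradient-boosted trees) contrasting models trained on real data (IND)
  against models trained on synthetic data (OOD), both evaluated on
  held-out real data — the train-synthetic-test-real pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    mean_absolute_error,
    roc_auc_score,
)
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier, XGBRegressor

from .features import (
    AGE_COLUMN,
    COGNITION_COLUMN,
    GROUP_COLUMN,
    ID_COLUMN,
    RACE_COLUMN,
    RACES,
    ROI_NAMES,
    SEX_COLUMN,
)

#: Fixed gradient-boosted-tree settings used across covariate tasks.
XGB_PARAMS = dict(n_estimators=300, max_depth=4, learning_rate=0.1, n_jobs=1)

_NON_ROI = {ID_COLUMN, SEX_COLUMN, RACE_COLUMN, AGE_COLUMN,
            GROUP_COLUMN, COGNITION_COLUMN}


def roi_columns(df: pd.DataFrame) -> list[str]:
    """The ROI volume columns of a cohort table (everything that is not an
    identifier/demographic column), in table order."""
    return [c for c in df.columns if c not in _NON_ROI]


def _roi(df: pd.DataFrame) -> np.ndarray:
    return df[roi_columns(df)].to_numpy(dtype=float)


def bonferroni_alpha(alpha: float = 0.05, n_tests: int = len(ROI_NAMES)) -> float:
    """Per-test threshold controlling family-wise error at ``alpha``."""
    return alpha / n_tests


def univariate_group_test(real: pd.DataFrame, synth: pd.DataFrame,
                          alpha: float = 0.05) -> tuple[pd.Series, int, float]:
    """OLS of each ROI volume on {intercept, group, age}; two-sided t-test
    on the group coefficient; significance counted at alpha / 145.

    Returns (per-ROI p-values, number significant, per-test threshold).
    All 145 regressions share one design matrix, so the fit is a single
    vectorized normal-equations solve.
    """
    shared = set(real[ID_COLUMN]) & set(synth[ID_COLUMN])
    if shared:
        raise ValueError(f"sample ids overlap between groups: {sorted(shared)[:5]}")
    group = np.r_[np.zeros(len(real)), np.ones(len(synth))]
    age = np.r_[real[AGE_COLUMN].to_numpy(float), synth[AGE_COLUMN].to_numpy(float)]
    Y = np.vstack([_roi(real), _roi(synth)])
    n = Y.shape[0]
    D = np.column_stack([np.ones(n), group, age])

    DtD_inv = np.linalg.inv(D.T @ D)
    B = DtD_inv @ D.T @ Y                      # 3 x 145 coefficients
    resid = Y - D @ B
    dof = n - 3
    s2 = (resid ** 2).sum(axis=0) / dof
    se_group = np.sqrt(s2 * DtD_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_group > 0, B[1] / se_group, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.where((se_group == 0) & (B[1] == 0), 1.0, p)  # identical groups
    cols = roi_columns(real)
    pvals = pd.Series(p, index=cols, name="p")
    thresh = bonferroni_alpha(alpha, len(cols))
    return pvals, int((pvals < thresh).sum()), thresh


def discriminator_auc(real: pd.DataFrame, synth: pd.DataFrame,
                      k_folds: int = 5, seed: int = 0,
                      include_age: bool = False,
                      return_folds: bool = False):
    """Stratified k-fold CV AUC of a linear max-margin classifier separating
    real from synthetic rows on the 145 ROI features (age excluded by
    default: the groups are age-matched by construction, so membership
    should be judged on ROI structure).  Features are standardized within
    training folds only.
    """
    if len(real) == 0 or len(synth) == 0:
        raise ValueError("both tables must be non-empty")
    cols = roi_columns(real) + ([AGE_COLUMN] if include_age else [])
    X = np.vstack([real[cols].to_numpy(float), synth[cols].to_numpy(float)])
    y = np.r_[np.zeros(len(real)), np.ones(len(synth))]
    if min(len(real), len(synth)) < k_folds:
        raise ValueError("each class needs at least k_folds rows")
    # canonical row order (class, then lexicographic features) so the fold
    # assignment — and hence the AUC — is invariant to input row order
    order = np.lexsort(np.vstack([X.T, y]))
    X, y = X[order], y[order]
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in cv.split(X, y):
        clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
        clf.fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[te], clf.decision_function(X[te])))
    mean = float(np.mean(aucs))
    return (mean, aucs) if return_folds else mean


def _task_arrays(df: pd.DataFrame, task: str):
    X = _roi(df)
    if task == "sex":
        y = (df[SEX_COLUMN] == "M").to_numpy(int)
    elif task == "race":
        y = df[RACE_COLUMN].map({r: i for i, r in enumerate(RACES)}).to_numpy(int)
    elif task == "age":
        y = df[AGE_COLUMN].to_numpy(float)
    else:
        raise ValueError(f"unknown task {task!r}")
    return X, y


def _make_learner(task: str, seed: int, **overrides):
    params = {**XGB_PARAMS, "random_state": seed, **overrides}
    if task == "age":
        return XGBRegressor(**params)
    return XGBClassifier(**params)


def covariate_prediction(train: pd.DataFrame, test: pd.DataFrame, task: str,
                         seed: int = 0, **learner_overrides) -> dict:
    """Train a gradient-boosted-tree model on ``train`` ROI features and
    score it on ``test``.

    Classification reports accuracy, balanced accuracy and AUC (macro
    one-vs-rest for the 3-class race task); age regression reports MAE
    (years) and the Pearson correlation between predicted and true age.
    """
    Xtr, ytr = _task_arrays(train, task)
    Xte, yte = _task_arrays(test, task)
    if task != "age" and len(np.unique(ytr)) < 2:
        raise ValueError("training labels contain a single class")
    model = _make_learner(task, seed, **learner_overrides)
    model.fit(Xtr, ytr)
    if task == "age":
        pred = model.predict(Xte)
        r, _ = stats.pearsonr(pred, yte)
        return {"mae": float(mean_absolute_error(yte, pred)),
                "pearson_r": float(r)}
    pred = model.predict(Xte)
    proba = model.predict_proba(Xte)
    if proba.shape[1] == 2:
        auc = roc_auc_score(yte, proba[:, 1])
    else:
        auc = roc_auc_score(yte, proba, multi_class="ovr", average="macro")
    return {"acc": float(accuracy_score(yte, pred)),
            "balanced_acc": float(balanced_accuracy_score(yte, pred)),
            "auc": float(auc)}


def ind_ood_comparison(real: pd.DataFrame, synth: pd.DataFrame,
                       tasks=("sex", "race", "age"), k_folds: int = 5,
                       seed: int = 0) -> dict:
    """IND vs OOD covariate-prediction contrast with k-fold evaluation.

    Real data is split into k folds.  Per fold, the IND model trains on
    the real training folds and the OOD model trains on the synthetic
    table; both are scored on the same held-out real fold, and metrics
    are averaged over folds.
    """
    out: dict = {}
    cv = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    splits = list(cv.split(real))
    for task in tasks:
        per_source: dict = {}
        for source in ("IND", "OOD"):
            fold_metrics = []
            for tr, te in splits:
                train = real.iloc[tr] if source == "IND" else synth
                fold_metrics.append(
                    covariate_prediction(train, real.iloc[te], task, seed=seed)
                )
            per_source[source] = {
                k: float(np.mean([m[k] for m in fold_metrics]))
                for k in fold_metrics[0]
            }
        out[task] = per_source
    return out


@dataclass
class FidelityReport:
    """Bundle of the full fidelity battery for one real/synthetic pair."""

    per_roi_p: dict
    n_significant: int
    bonferroni_alpha: float
    discriminator_auc: dict          # stratum label -> AUC
    covariate_metrics: dict | None   # task -> {IND, OOD} -> metrics

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def fidelity_report(real: pd.DataFrame, synth: pd.DataFrame,
                    per_stratum_discriminator: bool = True,
                    covariates: bool = True, seed: int = 0) -> FidelityReport:
    """Run the whole battery and assemble a :class:`FidelityReport`."""
    pvals, n_sig, thresh = univariate_group_test(real, synth)
    disc = {}
    if per_stratum_discriminator:
        for sex, race in sorted({(s, r) for s, r in
                                 zip(real[SEX_COLUMN], real[RACE_COLUMN])}):
            mask_r = (real[SEX_COLUMN] == sex) & (real[RACE_COLUMN] == race)
            mask_s = (synth[SEX_COLUMN] == sex) & (synth[RACE_COLUMN] == race)
            if mask_s.sum() >= 5 and mask_r.sum() >= 5:
                disc[f"{sex}/{race}"] = discriminator_auc(
                    real[mask_r], synth[mask_s], seed=seed
                )
    else:
        disc["all"] = discriminator_auc(real, synth, seed=seed)
    cov = ind_ood_comparison(real, synth, seed=seed) if covariates else None
    return FidelityReport(
        per_roi_p=pvals.to_dict(),
        n_significant=n_sig,
        bonferroni_alpha=thresh,
        discriminator_auc=disc,
        covariate_metrics=cov,
    )
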