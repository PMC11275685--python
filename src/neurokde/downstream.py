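"""Downstream utility experiments: CN augmentation and brain-age gap.

Two questions about practical value of the synthetic data:

* **Augmentation** — does topping up a small real cognitively-normal (CN)
  training pool with synthetic CN rows improve CN-vs-MCI / CN-vs-AD
  classification on purely real test data?  Each augmentation scheme
  "R+S" trains on R real + S synthetic controls; test sets never contain
  synthetic rows.

* **Brain-age gap** — train an age regressor on controls (real = IND,
  synthetic = OOD), apply the linear bias correction of Cole et al.
  (regress predicted on chronological age in the training controls; the
  corrected predicted age is (pred - beta) / alpha), and correlate the
  corrected gap (corrected predicted age minus chronological age, in
  years) with cognition scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBRegressor

from .features import AGE_COLUMN, COGNITION_COLUMN, GROUP_COLUMN
from .fidelity import XGB_PARAMS, roi_columns

# ---------------------------------------------------------------------------
# Augmentation curves


@dataclass(frozen=True)
class AugmentationScheme:
    """A training mixture of real and synthetic controls."""

    n_real_cn: int
    n_synth_cn: int

    def __post_init__(self):
        if self.n_real_cn + self.n_synth_cn < 2:
            raise ValueError("scheme needs at least 2 training controls")

    @property
    def label(self) -> str:
        return f"{self.n_real_cn}+{self.n_synth_cn}"

    @classmethod
    def parse(cls, text: str) -> "AugmentationScheme":
        real, _, synth = text.partition("+")
        return cls(int(real), int(synth or 0))


def _svm():
    return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))


def augmentation_experiment(real_cn: pd.DataFrame, synth_cn: pd.DataFrame,
                            cases: pd.DataFrame, schemes, n_repeats: int = 50,
                            seed: int = 0) -> pd.DataFrame:
    """AUC of CN-vs-case classification under each augmentation scheme.

    Per repeat, the real CN pool is freshly split into a training pool
    (large enough for the biggest scheme) and a test set, and the cases
    are split evenly between training and test.  Per scheme, a linear
    max-margin classifier is trained on the ROI features of the sampled
    real + synthetic controls plus the training cases, and scored by AUC
    on the held-out real-only test set.

    Returns a long DataFrame with columns (scheme, repeat, auc).
    """
    schemes = [AugmentationScheme.parse(s) if isinstance(s, str) else s
               for s in schemes]
    if GROUP_COLUMN not in cases.columns:
        raise ValueError("cases table must carry a Group column")
    max_real = max(s.n_real_cn for s in schemes)
    max_synth = max(s.n_synth_cn for s in schemes)
    if max_real >= len(real_cn):
        raise ValueError("largest scheme leaves no real CN rows for testing")
    if max_synth > len(synth_cn):
        raise ValueError("scheme requests more synthetic CN rows than available")
    cols = roi_columns(real_cn)
    Xr = real_cn[cols].to_numpy(float)
    Xs = synth_cn[cols].to_numpy(float)
    Xc = cases[cols].to_numpy(float)

    rng = np.random.default_rng(seed)
    records = []
    for rep in range(n_repeats):
        perm_r = rng.permutation(len(Xr))
        pool_r, test_r = perm_r[:max_real], perm_r[max_real:]
        perm_c = rng.permutation(len(Xc))
        half = len(Xc) // 2
        train_c, test_c = perm_c[:half], perm_c[half:]
        perm_s = rng.permutation(len(Xs))
        X_test = np.vstack([Xr[test_r], Xc[test_c]])
        y_test = np.r_[np.zeros(test_r.size), np.ones(test_c.size)]
        for scheme in schemes:
            ctrl = np.vstack([
                Xr[pool_r[:scheme.n_real_cn]],
                Xs[perm_s[:scheme.n_synth_cn]],
            ])
            X_train = np.vstack([ctrl, Xc[train_c]])
            y_train = np.r_[np.zeros(len(ctrl)), np.ones(train_c.size)]
            clf = _svm().fit(X_train, y_train)
            auc = roc_auc_score(y_test, clf.decision_function(X_test))
            records.append({"scheme": scheme.label, "repeat": rep,
                            "auc": float(auc)})
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Brain-age gap with Cole bias correction


class BrainAgeRegressor(BaseEstimator, RegressorMixin):
    """Gradient-boosted-tree brain-age predictor with Cole bias correction.

    ``fit`` trains the regressor on control subjects and estimates the
    correction coefficients (alpha, beta) by OLS of predicted age on
    chronological age within the training controls, using out-of-fold
    predictions (``cole_cv`` folds) so the coefficients reflect
    generalization rather than in-sample memorization.  The corrected
    predicted age of a new subject is ``(pred - beta) / alpha`` and the
    brain-age gap is the corrected prediction minus chronological age.

    Parameters mirror the fixed boosted-tree settings used elsewhere in
    the package; ``base_estimator`` swaps in any sklearn-style regressor
    (used for closed-form checks).
    """

    def __init__(self, n_estimators: int = XGB_PARAMS["n_estimators"],
                 max_depth: int = XGB_PARAMS["max_depth"],
                 learning_rate: float = XGB_PARAMS["learning_rate"],
                 random_state: int = 0, cole_cv: int = 5,
                 base_estimator=None):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.cole_cv = cole_cv
        self.base_estimator = base_estimator

    def _new_regressor(self):
        if self.base_estimator is not None:
            return clone(self.base_estimator)
        return XGBRegressor(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            random_state=self.random_state, n_jobs=1,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.std(y) == 0:
            raise ValueError("age column is constant; cannot fit")
        self.regressor_ = self._new_regressor().fit(X, y)
        if self.cole_cv and self.cole_cv >= 2:
            pred = np.empty_like(y)
            cv = KFold(n_splits=self.cole_cv, shuffle=True,
                       random_state=self.random_state)
            for tr, te in cv.split(X):
                pred[te] = self._new_regressor().fit(X[tr], y[tr]).predict(X[te])
        else:
            pred = self.regressor_.predict(X)
        alpha, beta = np.polyfit(y, pred, 1)
        if alpha == 0:
            raise ValueError("degenerate bias correction: alpha = 0")
        self.cole_alpha_ = float(alpha)
        self.cole_beta_ = float(beta)
        return self

    def predict(self, X) -> np.ndarray:
        """Raw (uncorrected) predicted age, years."""
        check_is_fitted(self, "regressor_")
        return np.asarray(self.regressor_.predict(np.asarray(X, float)), float)

    def corrected_age(self, X) -> np.ndarray:
        """Bias-corrected predicted age: (pred - beta) / alpha."""
        check_is_fitted(self, "cole_alpha_")
        return (self.predict(X) - self.cole_beta_) / self.cole_alpha_

    def gap(self, X, age) -> np.ndarray:
        """Corrected brain-age gap (years): corrected_age - chronological."""
        return self.corrected_age(X) - np.asarray(age, dtype=float)


def fit_brain_age(controls: pd.DataFrame, seed: int = 0,
                  **params) -> BrainAgeRegressor:
    """Fit a :class:`BrainAgeRegressor` on a control cohort table."""
    model = BrainAgeRegressor(random_state=seed, **params)
    return model.fit(controls[roi_columns(controls)].to_numpy(float),
                     controls[AGE_COLUMN].to_numpy(float))


def brain_age_gap(model: BrainAgeRegressor, subjects: pd.DataFrame) -> np.ndarray:
    """Per-subject corrected brain-age gap (years) for a cohort table."""
    return model.gap(subjects[roi_columns(subjects)].to_numpy(float),
                     subjects[AGE_COLUMN].to_numpy(float))


def gap_cognition_correlation(gaps, scores) -> tuple[float, float]:
    """Pearson correlation between brain-age gaps and cognition scores,
    with its two-sided t-test p-value."""
    gaps = np.asarray(gaps, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if gaps.shape != scores.shape or gaps.ndim != 1:
        raise ValueError("gaps and scores must be equal-length 1-d vectors")
    if gaps.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(gaps)) and np.all(np.isfinite(scores))):
        raise ValueError("inputs must be finite")
    if np.std(gaps) == 0 or np.std(scores) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    r, p = stats.pearsonr(gaps, scores)
    return float(r), float(p)


def gap_cognition_experiment(real_cn: pd.DataFrame, synth_cn: pd.DataFrame,
                             patients: pd.DataFrame, seed: int = 0) -> dict:
    """IND vs OOD brain-age-gap / cognition contrast on one patient table.

    Trains one age model on real controls (IND) and one on synthetic
    controls (OOD); reports, per source, the correlation of corrected
    gaps with cognition among the (pooled MCI/AD) patients.
    """
    if COGNITION_COLUMN not in patients.columns:
        raise ValueError("patients table must carry a Cognition column")
    out = {}
    for source, controls in (("IND", real_cn), ("OOD", synth_cn)):
        model = fit_brain_age(controls, seed=seed)
        gaps = brain_age_gap(model, patients)
        r, p = gap_cognition_correlation(
            gaps, patients[COGNITION_COLUMN].to_numpy(float))
        out[source] = {"pearson_r": r, "p_value": p,
                       "cole_alpha": model.cole_alpha_,
                       "cole_beta": model.cole_beta_}
    return out
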