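"""Stratified Gaussian-kernel density generative model.

One model per sex-by-race stratum.  Within a stratum, the 146-vector of
145 ROI volumes plus age is z-scored feature-wise (sample sd, ddof=1);
a product-Gaussian KDE with a single scalar bandwidth h in standardized
space delineates the joint density

    f(z) = (1/n) sum_i prod_d phi((z_d - Z_id) / h) / h,

and sampling draws a training row uniformly at random, perturbs every
dimension with independent Normal(0, h^2) noise, and back-transforms with
the retained means and sds.  The bandwidth is chosen on a grid within
[0.5, 1] by maximizing the k-fold cross-validated held-out log-likelihood
(ties broken toward the larger, smoother bandwidth); the grid is confined
to [0.5, 1] because the standardized features are approximately N(0, 1),
so smaller bandwidths overfit individual points and bandwidths near 1
oversmooth away the age-ROI correlation structure.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .features import (
    AGE_COLUMN,
    ID_COLUMN,
    N_ROI,
    RACE_COLUMN,
    ROI_NAMES,
    SEX_COLUMN,
    STRATA,
)

logger = logging.getLogger(__name__)

DEFAULT_GRID = tuple(np.round(np.arange(0.5, 1.0001, 0.05), 2))

#: Modeled feature order inside one stratum: the 145 ROIs then age.
MODEL_FEATURES = list(ROI_NAMES) + [AGE_COLUMN]


def gaussian_kde_logpdf(train: np.ndarray, query: np.ndarray, h: float,
                        block: int = 512) -> np.ndarray:
    """Log-density of a product-Gaussian KDE with scalar bandwidth ``h``.

    Evaluated with log-sum-exp over squared Euclidean distances, in blocks
    of query rows to bound memory; exact (no tree approximation).
    """
    train = np.atleast_2d(np.asarray(train, dtype=float))
    query = np.atleast_2d(np.asarray(query, dtype=float))
    n, d = train.shape
    if query.shape[1] != d:
        raise ValueError(f"query has {query.shape[1]} features, expected {d}")
    if h <= 0:
        raise ValueError("bandwidth must be > 0")
    const = -np.log(n) - d * np.log(h) - 0.5 * d * np.log(2.0 * np.pi)
    out = np.empty(query.shape[0])
    for start in range(0, query.shape[0], block):
        sq = cdist(query[start:start + block], train, "sqeuclidean")
        out[start:start + block] = logsumexp(-0.5 * sq / (h * h), axis=1)
    return out + const


def select_bandwidth(Z: np.ndarray, grid=DEFAULT_GRID, k_folds: int = 5,
                     seed: int = 0) -> tuple[float, pd.DataFrame]:
    """Grid-search the bandwidth by k-fold cross-validated log-likelihood.

    Returns the maximizing ``h`` (ties broken toward the larger value) and
    a table of every ``(h, score)`` pair, where score is the mean held-out
    log-likelihood per sample across folds.  Fold assignment is fixed by
    ``seed`` so selection is reproducible.
    """
    Z = np.asarray(Z, dtype=float)
    grid = [float(h) for h in grid]
    if len(grid) == 0:
        raise ValueError("bandwidth grid must be non-empty")
    if any(not 0.5 <= h <= 1.0 for h in grid):
        raise ValueError("bandwidth grid must lie within [0.5, 1.0]")
    if len(grid) == 1:
        return grid[0], pd.DataFrame({"h": grid, "score": [np.nan]})
    if Z.shape[0] < k_folds or k_folds < 2:
        raise ValueError("need n >= k_folds >= 2 for cross-validation")

    folds = list(KFold(n_splits=k_folds, shuffle=True, random_state=seed).split(Z))
    scores = []
    for h in grid:
        fold_means = [
            gaussian_kde_logpdf(Z[tr], Z[te], h).mean() for tr, te in folds
        ]
        scores.append(float(np.mean(fold_means)))
    table = pd.DataFrame({"h": grid, "score": scores})
    return grid[_argmax_prefer_larger(grid, scores)], table


def _argmax_prefer_larger(grid, scores) -> int:
    """Index of the maximal score; exact ties go to the larger bandwidth
    (smoother, less overfit)."""
    best = int(np.argsort(grid)[0])
    for i in np.argsort(grid):
        if scores[i] >= scores[best]:
            best = int(i)
    return best


class StratumKernelDensity(BaseEstimator):
    """Gaussian-kernel density estimator for one demographic stratum.

    Parameters
    ----------
    bandwidth : float or None
        Fixed kernel bandwidth in standardized space.  ``None`` selects it
        from ``bandwidth_grid`` by ``cv``-fold cross-validated
        log-likelihood.
    bandwidth_grid : sequence of float
        Candidate bandwidths, all within [0.5, 1.0].
    cv : int
        Folds for bandwidth selection.
    random_state : int
        Seeds the fold assignment of bandwidth selection.
    positive_columns : sequence of int or None
        Column indices whose sampled values must be strictly positive;
        offending draws are rejected and redrawn.  Defaults to every
        column except the last (the ROI block; age is never truncated)
        when the data has the full 146 modeled features, otherwise none.

    Attributes
    ----------
    mu_, sigma_ : per-feature mean and sd (ddof=1) in native units.
    Z_ : standardized training matrix.
    bandwidth_ : the bandwidth in effect after fitting.
    score_table_ : DataFrame of (h, CV score) pairs when selected by CV.
    """

    def __init__(self, bandwidth: float | None = None,
                 bandwidth_grid=DEFAULT_GRID, cv: int = 5,
                 random_state: int = 0, positive_columns=None,
                 feature_names=None, stratum=None):
        self.bandwidth = bandwidth
        self.bandwidth_grid = bandwidth_grid
        self.cv = cv
        self.random_state = random_state
        self.positive_columns = positive_columns
        self.feature_names = feature_names
        self.stratum = stratum

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit a stratum density")
        if not np.all(np.isfinite(X)):
            raise ValueError("training matrix contains non-finite values")
        self.n_features_in_ = X.shape[1]
        self.mu_ = X.mean(axis=0)
        self.sigma_ = X.std(axis=0, ddof=1)
        if np.any(self.sigma_ == 0):
            names = self.feature_names or [f"x{i}" for i in range(X.shape[1])]
            bad = [names[i] for i in np.flatnonzero(self.sigma_ == 0)]
            raise ValueError(f"constant feature(s) with zero sd: {bad}")
        self.Z_ = (X - self.mu_) / self.sigma_
        if self.bandwidth is not None:
            h = float(self.bandwidth)
            if h <= 0:
                raise ValueError("bandwidth must be > 0")
            self.bandwidth_ = h
            self.score_table_ = None
        else:
            self.bandwidth_, self.score_table_ = select_bandwidth(
                self.Z_, self.bandwidth_grid, self.cv, self.random_state
            )
        if self.positive_columns is None and X.shape[1] == N_ROI + 1:
            self.positive_columns_ = np.arange(N_ROI)
        elif self.positive_columns is None:
            self.positive_columns_ = np.array([], dtype=int)
        else:
            self.positive_columns_ = np.asarray(self.positive_columns, dtype=int)
        return self

    # -- density -----------------------------------------------------------

    def standardize(self, X):
        check_is_fitted(self, "mu_")
        return (np.asarray(X, dtype=float) - self.mu_) / self.sigma_

    def destandardize(self, Z):
        check_is_fitted(self, "mu_")
        return np.asarray(Z, dtype=float) * self.sigma_ + self.mu_

    def score_samples(self, X, native_units: bool = True) -> np.ndarray:
        """Per-row log-density; ``native_units=False`` takes pre-standardized
        coordinates."""
        check_is_fitted(self, "Z_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = self.standardize(X) if native_units else X
        return gaussian_kde_logpdf(self.Z_, Z, self.bandwidth_)

    def score(self, X, y=None) -> float:
        """Mean log-likelihood per sample (native units)."""
        return float(self.score_samples(X).mean())

    # -- sampling ----------------------------------------------------------

    def sample(self, n_samples: int, random_state: int | None = None,
               native_units: bool = True) -> np.ndarray:
        """Draw from the fitted mixture: uniformly chosen training row plus
        independent Normal(0, h^2) noise per dimension, back-transformed.

        Draws whose positive-support columns come out non-positive in
        native units are rejected and redrawn (count logged).
        """
        check_is_fitted(self, "Z_")
        if n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        rng = np.random.default_rng(
            self.random_state if random_state is None else random_state
        )
        n, d = self.Z_.shape
        h = self.bandwidth_

        def draw(m):
            comp = rng.integers(0, n, m)
            return self.Z_[comp] + h * rng.standard_normal((m, d))

        Z = draw(n_samples)
        X = self.destandardize(Z)
        pos = self.positive_columns_
        n_redrawn = 0
        if pos.size and n_samples:
            for _ in range(100):
                bad = np.flatnonzero((X[:, pos] <= 0).any(axis=1))
                if bad.size == 0:
                    break
                n_redrawn += bad.size
                X[bad] = self.destandardize(draw(bad.size))
            else:  # pragma: no cover
                raise RuntimeError("positivity rejection did not converge")
        if n_redrawn:
            logger.debug("sample(): redrew %d non-positive draws", n_redrawn)
        return X if native_units else self.standardize(X)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "Z_")
        return {
            "format_version": 1,
            "stratum": list(self.stratum) if self.stratum else None,
            "bandwidth": self.bandwidth_,
            "mu": self.mu_.tolist(),
            "sigma": self.sigma_.tolist(),
            "Z": self.Z_.tolist(),
            "feature_names": list(self.feature_names) if self.feature_names else None,
            "positive_columns": self.positive_columns_.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "StratumKernelDensity":
        if payload.get("format_version") != 1:
            raise ValueError("unsupported model format version")
        stratum = payload.get("stratum")
        model = cls(
            bandwidth=payload["bandwidth"],
            feature_names=payload.get("feature_names"),
            stratum=tuple(stratum) if stratum else None,
            positive_columns=payload.get("positive_columns"),
        )
        model.mu_ = np.asarray(payload["mu"], dtype=float)
        model.sigma_ = np.asarray(payload["sigma"], dtype=float)
        model.Z_ = np.asarray(payload["Z"], dtype=float)
        model.bandwidth_ = float(payload["bandwidth"])
        model.n_features_in_ = model.Z_.shape[1]
        model.positive_columns_ = np.asarray(payload["positive_columns"], dtype=int)
        model.score_table_ = None
        return model


# -- stratified wrapper ----------------------------------------------------


def _stratum_matrix(cohort: pd.DataFrame, sex: str, race: str) -> np.ndarray:
    mask = (cohort[SEX_COLUMN] == sex) & (cohort[RACE_COLUMN] == race)
    sub = cohort.loc[mask, MODEL_FEATURES]
    return sub.to_numpy(dtype=float)


def fit_stratum(cohort: pd.DataFrame, stratum: tuple[str, str],
                bandwidth: float | None = None, grid=DEFAULT_GRID,
                k_folds: int = 5, seed: int = 0) -> StratumKernelDensity:
    """Fit one stratum's standardizer + KDE from a cohort table."""
    sex, race = stratum[0].upper()[0], stratum[1].capitalize()
    X = _stratum_matrix(cohort, sex, race)
    if X.shape[0] == 0:
        raise ValueError(f"stratum {stratum!r} not present in cohort")
    model = StratumKernelDensity(
        bandwidth=bandwidth, bandwidth_grid=grid, cv=k_folds,
        random_state=seed, feature_names=MODEL_FEATURES, stratum=(sex, race),
    )
    return model.fit(X)


def fit_all_strata(cohort: pd.DataFrame, bandwidth: float | None = None,
                   grid=DEFAULT_GRID, k_folds: int = 5,
                   seed: int = 0) -> dict:
    """Fit all six stratum models; returns ``{(sex, race): model}``."""
    models = {}
    for i, stratum in enumerate(STRATA):
        models[stratum] = fit_stratum(
            cohort, stratum, bandwidth=bandwidth, grid=grid,
            k_folds=k_folds, seed=seed + i,
        )
        logger.info("fitted stratum %s: n=%d h=%.3g", stratum,
                    models[stratum].Z_.shape[0], models[stratum].bandwidth_)
    return models


def sample_stratum(model: StratumKernelDensity, n: int,
                   seed: int | None = None) -> pd.DataFrame:
    """Sample ``n`` rows from one stratum model as a cohort table
    (SampleID left blank; filled by :func:`generate_dataset`)."""
    X = model.sample(n, random_state=seed)
    sex, race = model.stratum if model.stratum else ("?", "?")
    df = pd.DataFrame({
        ID_COLUMN: ["" for _ in range(n)],
        SEX_COLUMN: np.full(n, sex),
        RACE_COLUMN: np.full(n, race),
        AGE_COLUMN: X[:, -1],
    })
    roi = pd.DataFrame(X[:, :-1], columns=ROI_NAMES, index=df.index)
    return pd.concat([df, roi], axis=1)


def generate_dataset(models: dict, n_per_stratum: int = 3000,
                     seed: int = 0) -> pd.DataFrame:
    """Emit the released-table dialect: ``n_per_stratum`` synthetic rows per
    stratum (default 3000, i.e. 18,000 rows total), each record holding 148
    fields (SampleID, Sex, Race, Age + 145 ROI volumes) with unique ids
    ``Synth1``, ``Synth2``, ...
    """
    missing = [s for s in STRATA if s not in models]
    if missing:
        raise ValueError(f"missing stratum model(s): {missing}")
    frames = []
    for i, stratum in enumerate(STRATA):
        frames.append(sample_stratum(models[stratum], n_per_stratum,
                                     seed=seed + i))
    out = pd.concat(frames, ignore_index=True)
    out[ID_COLUMN] = [f"Synth{i + 1}" for i in range(len(out))]
    return out
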