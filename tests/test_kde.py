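"""KDE core: standardization, log-density oracles, bandwidth CV, sampling laws."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp
from scipy.special import logsumexp
from scipy.stats import norm
from sklearn.model_selection import KFold
from sklearn.neighbors import KernelDensity

import neurokde as nk
from neurokde.kde import (
    MODEL_FEATURES,
    StratumKernelDensity,
    _argmax_prefer_larger,
    gaussian_kde_logpdf,
    select_bandwidth,
)

from conftest import make_tiny_config


def brute_force_logpdf(train, query, h):
    """Independent double-loop oracle for the product-Gaussian mixture."""
    out = []
    for x in query:
        dens = 0.0
        for row in train:
            dens += np.prod(norm.pdf((x - row) / h) / h)
        out.append(np.log(dens / len(train)))
    return np.array(out)


# -- standardization --------------------------------------------------------


def test_two_point_standardizer_moments():
    m = StratumKernelDensity(bandwidth=0.7, positive_columns=[]).fit(
        np.array([[1.0], [3.0]])
    )
    assert m.mu_[0] == pytest.approx(2.0)
    assert m.sigma_[0] == pytest.approx(np.sqrt(2.0))  # sample sd, ddof=1


def test_standardized_training_matrix_is_zscored():
    rng = np.random.default_rng(0)
    m = StratumKernelDensity(bandwidth=0.7, positive_columns=[]).fit(
        rng.normal(50, 5, (40, 3))
    )
    np.testing.assert_allclose(m.Z_.mean(axis=0), 0, atol=1e-12)
    np.testing.assert_allclose(m.Z_.std(axis=0, ddof=1), 1, rtol=1e-12)


@given(
    hnp.arrays(
        float, (7, 3),
        elements=st.floats(-1e3, 1e3, allow_nan=False, allow_infinity=False),
    )
)
def test_standardize_destandardize_round_trip(X):
    sd = X.std(axis=0, ddof=1)
    if np.any(sd <= 1e-6 * (1 + np.abs(X).max(axis=0))):
        return  # (near-)constant columns are rejected by fit / lose precision
    m = StratumKernelDensity(bandwidth=0.7, positive_columns=[]).fit(X)
    Z = np.linspace(-2, 2, X.size).reshape(X.shape)
    np.testing.assert_allclose(m.standardize(m.destandardize(Z)), Z, atol=1e-9)


def test_single_row_stratum_is_an_error():
    with pytest.raises(ValueError, match="at least 2 rows"):
        StratumKernelDensity(bandwidth=0.7).fit(np.ones((1, 4)))


def test_constant_feature_error_names_the_column():
    X = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
    with pytest.raises(ValueError, match="x1"):
        StratumKernelDensity(bandwidth=0.7, positive_columns=[]).fit(X)


# -- log-density ------------------------------------------------------------


def test_single_kernel_closed_form():
    # one training point at the origin, h=1, d=2: log f(0) = log(1/(2*pi))
    lp = gaussian_kde_logpdf(np.zeros((1, 2)), np.zeros((1, 2)), 1.0)
    assert lp[0] == pytest.approx(np.log(1.0 / (2.0 * np.pi)), abs=1e-12)


def test_logpdf_matches_brute_force_oracle_50_cases():
    rng = np.random.default_rng(42)
    for _ in range(50):
        n = int(rng.integers(2, 51))
        d = int(rng.integers(1, 11))
        h = float(rng.uniform(0.3, 1.2))
        train = rng.normal(0, 2, (n, d))
        query = rng.normal(0, 2, (5, d))
        fast = gaussian_kde_logpdf(train, query, h)
        np.testing.assert_allclose(fast, brute_force_logpdf(train, query, h),
                                   rtol=0, atol=1e-10)


def test_logpdf_matches_sklearn_kerneldensity():
    rng = np.random.default_rng(1)
    train = rng.normal(0, 1, (60, 4))
    query = rng.normal(0, 1, (10, 4))
    ours = gaussian_kde_logpdf(train, query, 0.7)
    ref = KernelDensity(bandwidth=0.7, kernel="gaussian").fit(train)
    np.testing.assert_allclose(ours, ref.score_samples(query), atol=1e-10)


def test_logpdf_decreases_into_the_tail():
    rng = np.random.default_rng(2)
    train = rng.normal(0, 1, (20, 3))
    radii = np.array([1.0, 5.0, 20.0, 100.0])
    direction = np.ones(3) / np.sqrt(3)
    lp = gaussian_kde_logpdf(train, np.outer(radii, direction), 0.8)
    assert np.all(np.diff(lp) < 0)
    assert np.all(np.isfinite(lp))


def test_dimension_mismatch_raises():
    with pytest.raises(ValueError, match="features"):
        gaussian_kde_logpdf(np.zeros((3, 4)), np.zeros((2, 5)), 0.7)


# -- bandwidth selection ----------------------------------------------------


def test_singleton_grid_short_circuits():
    h, table = select_bandwidth(np.zeros((3, 2)), grid=[0.7])
    assert h == 0.7
    assert list(table["h"]) == [0.7]


def test_tie_break_prefers_larger_bandwidth():
    assert _argmax_prefer_larger([0.5, 0.7, 0.9], [1.0, 2.0, 2.0]) == 2
    assert _argmax_prefer_larger([0.9, 0.5, 0.7], [3.0, 3.0, 3.0]) == 0
    assert _argmax_prefer_larger([0.5, 0.7], [5.0, 4.0]) == 0


def test_grid_validation():
    Z = np.random.default_rng(0).normal(size=(20, 2))
    with pytest.raises(ValueError, match="non-empty"):
        select_bandwidth(Z, grid=[])
    with pytest.raises(ValueError, match=r"\[0.5, 1.0\]"):
        select_bandwidth(Z, grid=[0.3, 0.7])


def test_cv_selection_matches_independent_oracle():
    """Selected h equals the argmax of a per-fold oracle built on sklearn's
    KernelDensity with the identical fold assignment."""
    rng = np.random.default_rng(3)
    Z = rng.standard_normal((300, 5))
    grid = [0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
    h_star, table = select_bandwidth(Z, grid=grid, k_folds=5, seed=11)

    folds = list(KFold(n_splits=5, shuffle=True, random_state=11).split(Z))
    oracle_scores = []
    for h in grid:
        per_fold = []
        for tr, te in folds:
            kd = KernelDensity(bandwidth=h, kernel="gaussian").fit(Z[tr])
            per_fold.append(kd.score_samples(Z[te]).mean())
        oracle_scores.append(np.mean(per_fold))
    assert h_star == grid[int(np.argmax(oracle_scores))]
    np.testing.assert_allclose(table["score"], oracle_scores, atol=1e-9)


def test_in_sample_likelihood_non_increasing_in_h():
    """Self-point kernels make in-sample likelihood favor the smallest h —
    the guard against accidentally selecting on in-sample score."""
    rng = np.random.default_rng(4)
    Z = rng.standard_normal((150, 4))
    grid = np.arange(0.5, 1.01, 0.1)
    in_sample = [gaussian_kde_logpdf(Z, Z, h).mean() for h in grid]
    assert np.all(np.diff(in_sample) < 0)


# -- sampling ---------------------------------------------------------------


def test_sampler_moments_match_mixture_closed_form():
    rng = np.random.default_rng(5)
    X = rng.normal(0, 1, (400, 4))
    m = StratumKernelDensity(bandwidth=0.7, positive_columns=[]).fit(X)
    S = m.sample(100_000, random_state=6, native_units=False)
    np.testing.assert_allclose(S.mean(axis=0), m.Z_.mean(axis=0), atol=0.02)
    expected_var = m.Z_.var(axis=0) + 0.7 ** 2
    np.testing.assert_allclose(S.var(axis=0), expected_var, rtol=0.03)
    # full covariance identity: Cov = S_train + h^2 I
    C = np.cov(S.T, ddof=0)
    expected_C = np.cov(m.Z_.T, ddof=0) + 0.49 * np.eye(4)
    np.testing.assert_allclose(C, expected_C, atol=0.03)


def test_correlation_attenuation_factor():
    """Kernel noise shrinks a standardized correlation rho to rho/(1+h^2):
    h=0.7 gives a factor of ~0.671."""
    rng = np.random.default_rng(7)
    z1 = rng.standard_normal(600)
    z2 = 0.8 * z1 + np.sqrt(1 - 0.64) * rng.standard_normal(600)
    m = StratumKernelDensity(bandwidth=0.7, positive_columns=[]).fit(
        np.column_stack([z1, z2])
    )
    S = m.sample(100_000, random_state=8, native_units=False)
    rho_train = np.corrcoef(m.Z_.T)[0, 1]
    rho_synth = np.corrcoef(S.T)[0, 1]
    assert rho_synth == pytest.approx(rho_train / 1.49, abs=0.02)
    assert 1 / 1.49 == pytest.approx(0.671, abs=0.001)


def test_vanishing_bandwidth_reproduces_training_rows():
    rng = np.random.default_rng(9)
    X = rng.normal(100, 10, (30, 3))
    m = StratumKernelDensity(bandwidth=1e-12, positive_columns=[]).fit(X)
    S = m.sample(200, random_state=10)
    dists = np.min(np.linalg.norm(S[:, None, :] - X[None], axis=2), axis=1)
    assert dists.max() < 1e-6


def test_sample_determinism_and_n_zero(small_models):
    m = small_models[("F", "White")]
    a = m.sample(50, random_state=3)
    b = m.sample(50, random_state=3)
    np.testing.assert_array_equal(a, b)
    empty = nk.sample_stratum(m, 0, seed=0)
    assert len(empty) == 0
    assert list(empty.columns) == ["SampleID", "Sex", "Race", "Age"] + nk.ROI_NAMES


def test_sampled_volumes_positive(small_models):
    m = small_models[("M", "Black")]
    tab = nk.sample_stratum(m, 500, seed=4)
    assert (tab[nk.ROI_NAMES].to_numpy() > 0).all()
    assert set(tab["Sex"]) == {"M"} and set(tab["Race"]) == {"Black"}


# -- stratified wrapper and dataset -----------------------------------------


def test_fit_all_strata_yields_six_models(small_models):
    assert len(small_models) == 6
    for (sex, race), m in small_models.items():
        assert m.stratum == (sex, race)
        assert m.Z_.shape[1] == 146
        assert np.isfinite(
            m.score_samples(m.destandardize(m.Z_), native_units=True)
        ).all()


def test_stratum_labels_case_insensitive(small_cohort):
    m = nk.fit_stratum(small_cohort, ("f", "WHITE"), bandwidth=0.7)
    assert m.stratum == ("F", "White")


def test_generate_dataset_minimal_ids(small_models):
    ds = nk.generate_dataset(small_models, n_per_stratum=1, seed=0)
    assert len(ds) == 6
    assert list(ds["SampleID"]) == [f"Synth{i}" for i in range(1, 7)]
    assert ds.shape[1] - 1 == 148  # 148 features per record beyond the id


def test_generate_dataset_missing_stratum_errors(small_models):
    partial = {k: v for k, v in small_models.items() if k != ("M", "Asian")}
    with pytest.raises(ValueError, match="missing stratum"):
        nk.generate_dataset(partial, n_per_stratum=1, seed=0)


def test_model_serialization_round_trip(small_models, tmp_path):
    m = small_models[("F", "Asian")]
    clone = StratumKernelDensity.from_dict(
        json.loads(json.dumps(m.to_dict()))
    )
    q = m.destandardize(m.Z_[:5] + 0.1)
    np.testing.assert_allclose(clone.score_samples(q), m.score_samples(q),
                               rtol=0, atol=1e-12)
    nk.save_models(small_models, tmp_path / "models")
    loaded = nk.load_models(tmp_path / "models")
    assert set(loaded) == set(small_models)
    np.testing.assert_allclose(
        loaded[("F", "Asian")].score_samples(q),
        m.score_samples(q), atol=1e-12,
    )
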