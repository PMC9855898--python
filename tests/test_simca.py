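import numpy as np
import pytest
from scipy import stats

from metsir.lda import fit_lda, predict
from metsir.simca import (SIMCAClassModel, assign, augmented_distance,
                          class_distance, coomans_coordinates,
                          discriminant_power, distance_to_model,
                          fit_class_model, fit_models, modelling_power,
                          sample_from_model, simca_report)


def _factor_data(rng, n=100, p=10, A=2, noise=0.1, shift=0.0):
    """Data from an A-component latent model plus isotropic noise."""
    sds = 3.0 * 2.0 ** (-0.5 * np.arange(A))
    T = rng.normal(size=(n, A)) * sds
    P = np.linalg.qr(rng.normal(size=(p, A)))[0]
    return T @ P.T + rng.normal(0, noise, size=(n, p)) + shift


def test_f_quantile_against_reference_table():
    """alpha=0.05 with 1 and 10 degrees of freedom: critical distance is
    sqrt(4.9646), the classic F-table value."""
    assert stats.f.ppf(0.95, 1, 10) == pytest.approx(4.9646, abs=2e-4)
    # a model engineered to those df: p - A = 1, (n - A - 1)(p - A) = 10
    rng = np.random.default_rng(0)
    X = _factor_data(rng, n=13, p=2, A=1, noise=0.3)
    m = fit_class_model(X, 1, alpha=0.05)
    assert (m.df1, m.df2) == (1, 11)  # n=13 -> df2 = 11; check formula instead
    m2 = fit_class_model(X[:12], 1, alpha=0.05)
    assert (m2.df1, m2.df2) == (1, 10)
    assert m2.crit_distance == pytest.approx(np.sqrt(4.9646), abs=1e-4)


def test_s0_is_one_with_zero_components(rng):
    """With A = 0 the autoscaled residual is the autoscaled data itself, so
    s0² = Σ z² / ((n−1)p) = 1 exactly (each column has SS = n−1 by
    construction of the ddof=1 scaling)."""
    X = rng.normal(0, 2.0, size=(50, 6))
    m = fit_class_model(X, 0)
    assert m.s0 == pytest.approx(1.0, abs=1e-12)


def test_s0_recovers_noise_scale(rng):
    """Data simulated from an A-component model: the class residual SD
    matches the injected noise expressed in autoscaled units."""
    noise, n, p, A = 0.1, 200, 10, 2
    X = _factor_data(rng, n=n, p=p, A=A, noise=noise)
    m = fit_class_model(X, A)
    # per-variable autoscaled noise variance is (noise/sd_j)²; the residual
    # pools n of each over (n−A−1)(p−A) degrees of freedom
    sd = X.std(axis=0, ddof=1)
    expected = noise * np.sqrt(n * np.sum(sd ** -2.0) / ((n - A - 1) * (p - A)))
    assert m.s0 == pytest.approx(expected, rel=0.2)


def test_centroid_has_zero_distance(rng):
    """The class centroid has zero residual to the class model exactly."""
    X = _factor_data(rng, n=60, p=8, A=2)
    m = fit_class_model(X, 2)
    centroid = X.mean(axis=0)[None, :]
    assert distance_to_model(m, centroid)[0] == pytest.approx(0.0, abs=1e-9)


def test_far_off_subspace_sample_rejected(rng):
    """A sample displaced orthogonally to the model plane by 10 residual SDs
    per variable falls far outside the acceptance boundary."""
    X = _factor_data(rng, n=60, p=8, A=2, noise=0.1)
    m = fit_class_model(X, 2)
    # standardized displacement orthogonal to the loadings, back-transformed
    v = np.ones(8) - m.pca.loadings @ (m.pca.loadings.T @ np.ones(8))
    v *= 10.0 * m.s0 / np.linalg.norm(v) * np.sqrt(8)
    off = X.mean(axis=0) + v * m.pca.scale
    d = distance_to_model(m, off[None, :])[0]
    assert d > m.crit_distance


def test_acceptance_coverage_95(rng):
    """Samples generated from a fitted class model are accepted at the 95%
    class-space confidence about 95% of the time (binomial 99% CI, n=500)."""
    X = _factor_data(rng, n=200, p=10, A=2, noise=0.15)
    m = fit_class_model(X, 2, alpha=0.05)
    new = sample_from_model(m, 500, np.random.default_rng(99))
    frac = (distance_to_model(m, new) <= m.crit_distance).mean()
    half = 2.576 * np.sqrt(0.05 * 0.95 / 500)
    assert abs(frac - 0.95) < half + 0.005


@pytest.mark.parametrize("alpha", [0.05, 0.01])
def test_acceptance_coverage_tracks_alpha(rng, alpha):
    X = _factor_data(rng, n=300, p=12, A=3, noise=0.2)
    m = fit_class_model(X, 3, alpha=alpha)
    new = sample_from_model(m, 1000, np.random.default_rng(7))
    frac = (distance_to_model(m, new) <= m.crit_distance).mean()
    half = 2.576 * np.sqrt(alpha * (1 - alpha) / 1000)
    assert abs(frac - (1 - alpha)) < half + 0.01


def test_assign_four_way_membership(rng):
    X1 = _factor_data(rng, n=50, p=6, A=2, noise=0.1)
    X2 = _factor_data(rng, n=50, p=6, A=2, noise=0.1, shift=50.0)
    m1 = fit_class_model(X1, 2, label="c1")
    m2 = fit_class_model(X2, 2, label="c2")
    a = assign([m1, m2], X1.mean(axis=0)[None, :])
    assert a.membership[0] == "c1"
    assert a.forced[0] == "c1"
    # a point far from both models
    nowhere = X1.mean(axis=0)[None, :] + 500.0
    assert assign([m1, m2], nowhere).membership[0] == "none"


def test_assign_overlapping_classes_both(rng):
    X1 = _factor_data(rng, n=80, p=6, A=2, noise=0.3)
    X2 = X1 + rng.normal(0, 0.01, size=X1.shape)  # nearly identical classes
    m1 = fit_class_model(X1, 2, label="c1")
    m2 = fit_class_model(X2, 2, label="c2")
    a = assign([m1, m2], X1.mean(axis=0)[None, :])
    assert a.membership[0] == "both"


def test_forced_assignment_concordant_with_lda(rng):
    """On well-separated isotropic classes the forced nearest-model rule
    agrees with LDA for at least 95% of samples."""
    n = 100
    X1 = rng.normal(size=(n, 5))
    X2 = rng.normal(size=(n, 5)) + 4.0
    X = np.vstack([X1, X2])
    y = np.array(["a"] * n + ["b"] * n, dtype=object)
    models = fit_models(X, y, 2)
    a = assign(models, X)
    lda_pred = predict(fit_lda(X, y), X)
    assert (a.forced == lda_pred).mean() >= 0.95


def test_modelling_power_fully_explained_variable(rng):
    """A variable lying exactly in the component plane reaches MP = 1."""
    T = rng.normal(size=(100, 2)) * [3.0, 1.5]
    P = np.linalg.qr(rng.normal(size=(5, 2)))[0]
    X = T @ P.T  # rank 2, no noise
    m = fit_class_model(X + rng.normal(0, 1e-8, size=X.shape), 2)
    mp = modelling_power(m, X)
    np.testing.assert_allclose(mp, 1.0, atol=1e-4)


def test_modelling_power_noise_variable_near_zero(rng):
    """A pure-noise variable appended to strongly structured ones gets
    MP near 0 while every structured variable stays near 1."""
    n, p = 500, 6
    T = rng.normal(size=(n, 2)) * [3.0, 1.5]
    # alternating mixing: columns load on t1+t2 and t1-t2, genuinely rank 2
    mix = np.vstack([np.ones(p), (-1.0) ** np.arange(p)])
    X = T @ mix + rng.normal(0, 0.05, size=(n, p))  # every column structured
    noise_col = rng.normal(size=(n, 1))  # unrelated to the structure
    Xn = np.hstack([X, noise_col])
    m = fit_class_model(Xn, 2)
    mp = modelling_power(m, Xn)
    assert mp[-1] < 0.15
    assert mp[:-1].min() > 0.8


def test_modelling_power_bounds(rng):
    X = rng.normal(size=(40, 8))
    m = fit_class_model(X, 3)
    mp = modelling_power(m, X)
    assert np.all(mp >= 0.0) and np.all(mp <= 1.0 + 1e-9)


def test_discriminant_power_null_near_one(rng):
    """Two classes drawn from the SAME latent distribution (shared loading
    subspace) have DP ~ 1 for every variable."""
    P = np.linalg.qr(rng.normal(size=(5, 2)))[0]

    def draw():
        T = rng.normal(size=(500, 2)) * [3.0, 1.5]
        return T @ P.T + rng.normal(0, 0.3, size=(500, 5))

    X1, X2 = draw(), draw()
    m1, m2 = fit_class_model(X1, 2), fit_class_model(X2, 2)
    dp = discriminant_power(m1, m2, X1, X2)
    assert np.all(dp > 0.8) and np.all(dp < 1.25)


def test_discriminant_power_shifted_variable_dominates(rng):
    X1 = rng.normal(size=(200, 6))
    X2 = rng.normal(size=(200, 6))
    X2[:, 3] += 5.0  # five within-class SDs
    m1, m2 = fit_class_model(X1, 2), fit_class_model(X2, 2)
    dp = discriminant_power(m1, m2, X1, X2)
    assert dp[3] > 2.0
    assert dp[3] == dp.max()


def test_discriminant_power_symmetric_under_swap(rng):
    X1 = rng.normal(size=(60, 5))
    X2 = rng.normal(size=(60, 5)) + 1.0
    m1, m2 = fit_class_model(X1, 2), fit_class_model(X2, 2)
    np.testing.assert_allclose(discriminant_power(m1, m2, X1, X2),
                               discriminant_power(m2, m1, X2, X1), atol=1e-12)


def test_class_distance_self_is_one(rng):
    X = rng.normal(size=(50, 6))
    m = fit_class_model(X, 2)
    assert class_distance(m, m, X, X) == pytest.approx(1.0, abs=1e-12)


def test_class_distance_monotone_in_shift(rng):
    dists = []
    for shift in (0.0, 1.0, 2.0, 4.0):
        X1 = rng.normal(size=(150, 6))
        X2 = rng.normal(size=(150, 6)) + shift
        m1, m2 = fit_class_model(X1, 2), fit_class_model(X2, 2)
        dists.append(class_distance(m1, m2, X1, X2))
    assert all(b > a for a, b in zip(dists, dists[1:]))


def test_class_distance_strong_separation_exceeds_three(rng):
    """Well-separated classes produce an interclass distance above 3, the
    order of magnitude reported for real clinical/spectral models."""
    X1 = rng.normal(size=(100, 10))
    X2 = rng.normal(size=(100, 10)) + 6.0
    m1, m2 = fit_class_model(X1, 3), fit_class_model(X2, 3)
    assert class_distance(m1, m2, X1, X2) > 3.0


def test_coomans_coordinates_consistency(rng):
    X1 = _factor_data(rng, n=60, p=6, A=2, noise=0.2)
    X2 = _factor_data(rng, n=60, p=6, A=2, noise=0.2, shift=8.0)
    m1 = fit_class_model(X1, 2, label="c1")
    m2 = fit_class_model(X2, 2, label="c2")
    X = np.vstack([X1, X2])
    d1, d2, crit = coomans_coordinates([m1, m2], X)
    a = assign([m1, m2], X)
    np.testing.assert_array_equal(d1 <= crit[0], a.accepted[:, 0])
    np.testing.assert_array_equal(d2 <= crit[1], a.accepted[:, 1])
    # centroid of class 1: close to model 1, far from model 2
    dc1, dc2, _ = coomans_coordinates([m1, m2], X1.mean(axis=0)[None, :])
    assert dc1[0] < 1.0 < dc2[0]
    with pytest.raises(ValueError):
        coomans_coordinates([m1], X)


def test_augmented_distance_exceeds_residual_part(rng):
    X = _factor_data(rng, n=60, p=6, A=2, noise=0.2)
    m = fit_class_model(X, 2, label="c")
    d_res = distance_to_model(m, X) / m.crit_distance
    d_aug = augmented_distance(m, X)
    assert np.all(d_aug >= d_res / np.sqrt(2) - 1e-12)


def test_simca_report_strong_signal_forced_rate_100(rng):
    """Ten informative variables at 6 within-class SDs, 95 train / 10 test:
    forced-model assignment classifies every sample correctly."""
    n1, n2 = 19, 76
    X = rng.normal(size=(n1 + n2 + 10, 10))
    X[:n1] += 6.0
    X[n1 + n2: n1 + n2 + 2] += 6.0  # 2 of the 10 test samples are positives
    y = np.array(["MetS"] * n1 + ["noMetS"] * n2, dtype=object)
    y_test = np.array(["MetS"] * 2 + ["noMetS"] * 8, dtype=object)
    models = fit_models(X[: n1 + n2], y, 3)
    diag, _ = simca_report(models, X[: n1 + n2], y, X[n1 + n2:], y_test)
    assert diag.forced_efficiency_pct == 100.0
    assert diag.total_rate_pct == 100.0


def test_simca_report_null_signal_near_chance(rng):
    """With no class signal the LOO efficiency collapses toward chance."""
    X = rng.normal(size=(60, 5))
    y = np.array(["a"] * 30 + ["b"] * 30, dtype=object)
    models = fit_models(X, y, 2)
    diag, _ = simca_report(models, X, y)
    assert diag.forced_efficiency_pct < 75.0


def test_model_serialization_roundtrip(tmp_path, rng):
    X = _factor_data(rng, n=50, p=7, A=2, noise=0.2)
    m = fit_class_model(X, 2, label="c1")
    path = tmp_path / "model.json"
    m.save(path)
    back = SIMCAClassModel.load(path)
    probe = rng.normal(size=(20, 7)) + X.mean(axis=0)
    np.testing.assert_allclose(distance_to_model(back, probe),
                               distance_to_model(m, probe), atol=1e-12)
    assert back.crit_distance == m.crit_distance
    assert back.s0 == m.s0


def test_fit_class_model_validation(rng):
    X = rng.normal(size=(5, 4))
    with pytest.raises(ValueError):
        fit_class_model(X, 4)  # n < A + 2
    X2 = rng.normal(size=(10, 3))
    X2[:, 1] = 7.0
    with pytest.raises(ValueError, match="zero variance"):
        fit_class_model(X2, 1)
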