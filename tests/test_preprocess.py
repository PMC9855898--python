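import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metsir.io_formats import SpectraSet
from metsir.preprocess import (PreprocessPlan, SavgolStep, average_replicates,
                               emsc, mean_center, restrict, savitzky_golay,
                               snv)
from metsir.synthetic import REPORTED_WAVENUMBERS, default_grid


def _spectra(matrix, grid=None, ids=None, replicate_of=None):
    matrix = np.atleast_2d(matrix)
    if grid is None:
        grid = np.arange(matrix.shape[1], dtype=float)[::-1] + 1000.0
    ids = ids or [f"s{i}" for i in range(matrix.shape[0])]
    return SpectraSet(grid, matrix, ids, replicate_of=replicate_of)


# ---------------------------------------------------------------- replicates

def test_average_identical_replicates_idempotent():
    row = np.linspace(0, 1, 8)
    spec = _spectra(np.vstack([row, row, row]),
                    ids=["a_rep1", "a_rep2", "a_rep3"],
                    replicate_of={"a_rep1": "a", "a_rep2": "a", "a_rep3": "a"})
    out = average_replicates(spec)
    assert out.sample_ids == ["a"]
    np.testing.assert_allclose(out.absorbance[0], row)


def test_average_two_replicates_arithmetic_mean():
    spec = _spectra(np.vstack([np.zeros(5), np.full(5, 2.0)]),
                    ids=["a_rep1", "a_rep2"],
                    replicate_of={"a_rep1": "a", "a_rep2": "a"})
    np.testing.assert_allclose(average_replicates(spec).absorbance[0],
                               np.ones(5))


def test_triplicates_collapse_to_one_row_per_sample(rng):
    n, p = 105, 20
    ids = [f"s{i}_rep{r}" for i in range(n) for r in (1, 2, 3)]
    rep = {i: i.rsplit("_rep", 1)[0] for i in ids}
    spec = _spectra(rng.normal(size=(n * 3, p)), ids=ids, replicate_of=rep)
    assert average_replicates(spec).n_samples == n


# ------------------------------------------------------------ Savitzky-Golay

def test_savgol_reproduces_quadratic():
    grid = np.linspace(1500, 1400, 101)
    poly = 3.0 + 0.5 * (grid - 1450) + 0.01 * (grid - 1450) ** 2
    out = savitzky_golay(_spectra(poly, grid), window=9, polyorder=2, deriv=0)
    np.testing.assert_allclose(out.absorbance[0], poly, atol=1e-10)


def test_savgol_first_derivative_of_linear_signal():
    """d/dν of a line with slope m per cm⁻¹ is m everywhere, including the
    boundary windows, despite the descending storage order."""
    m = 0.37
    grid = np.linspace(1500, 1400, 101)
    line = m * grid + 2.0
    out = savitzky_golay(_spectra(line, grid), window=9, polyorder=2, deriv=1)
    np.testing.assert_allclose(out.absorbance[0], np.full(101, m), atol=1e-10)


def test_savgol_second_derivative_of_quadratic():
    grid = np.linspace(1500, 1400, 101)
    c = 0.01
    sig = c * (grid - 1450) ** 2
    out = savitzky_golay(_spectra(sig, grid), window=11, polyorder=3, deriv=2)
    np.testing.assert_allclose(out.absorbance[0], np.full(101, 2 * c), atol=1e-8)


def test_savgol_parameter_validation():
    grid = np.linspace(1500, 1400, 50)
    spec = _spectra(np.zeros(50), grid)
    with pytest.raises(ValueError):
        savitzky_golay(spec, window=4)
    with pytest.raises(ValueError):
        savitzky_golay(spec, window=9, polyorder=2, deriv=3)


def test_savgol_rejects_nonuniform_segment():
    grid = np.array([1500.0, 1499.0, 1498.0, 1497.3, 1496.0, 1495.0, 1494.0,
                     1493.0, 1492.0, 1491.0])
    with pytest.raises(ValueError, match="non-uniform"):
        savitzky_golay(_spectra(np.zeros(10), grid), window=5)


def test_savgol_respects_segment_gap():
    """Filtering never convolves across the gap between the two analysed
    regions: a step between regions leaves each region's interior flat."""
    grid = default_grid()
    upper = grid >= 2000
    sig = np.where(upper, 1.0, 0.0)
    out = savitzky_golay(_spectra(sig, grid), window=9, polyorder=2)
    np.testing.assert_allclose(out.absorbance[0][upper], 1.0, atol=1e-10)
    np.testing.assert_allclose(out.absorbance[0][~upper], 0.0, atol=1e-10)


# ------------------------------------------------------------------------ SNV

def test_snv_small_example():
    out = snv(_spectra([[0.0, 1.0, 2.0]]))
    np.testing.assert_allclose(out.absorbance[0], [-1.0, 0.0, 1.0], atol=1e-12)


def test_snv_rows_standardized(rng):
    out = snv(_spectra(rng.normal(2.0, 3.0, size=(20, 50))))
    np.testing.assert_allclose(out.absorbance.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(out.absorbance.std(axis=1, ddof=1), 1.0,
                               atol=1e-12)


@settings(max_examples=25, deadline=None)
@given(scale=st.floats(0.1, 50.0), offset=st.floats(-100.0, 100.0),
       seed=st.integers(0, 2**16))
def test_snv_affine_invariance(scale, offset, seed):
    """SNV(a·x + b) == SNV(x): per-row affine transforms are removed."""
    x = np.random.default_rng(seed).normal(size=(3, 40))
    base = snv(_spectra(x)).absorbance
    transformed = snv(_spectra(scale * x + offset)).absorbance
    np.testing.assert_allclose(transformed, base, atol=1e-10)


def test_snv_constant_row_errors():
    with pytest.raises(ValueError, match="s1"):
        snv(_spectra(np.vstack([np.arange(5.0), np.full(5, 3.0)]),
                     ids=["s0", "s1"]))


# ----------------------------------------------------------------------- EMSC

def test_emsc_exact_model_case(rng):
    ref = np.abs(rng.normal(size=60)) + np.linspace(0, 1, 60)
    row = 2.0 * ref + 1.0
    out = emsc(_spectra(np.vstack([row]), grid=np.linspace(1500, 1400, 60)),
               reference=ref)
    np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-10)


def test_emsc_reference_unchanged(rng):
    ref = np.abs(rng.normal(size=60)) + 1.0
    out = emsc(_spectra(ref, grid=np.linspace(1500, 1400, 60)), reference=ref)
    np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-10)


def test_emsc_reduces_multiplicative_scatter(rng):
    base = np.exp(-0.5 * ((np.linspace(1500, 1400, 80) - 1450) / 10) ** 2)
    scales = 1.0 + rng.normal(0, 0.3, size=30)
    rows = scales[:, None] * base + rng.normal(0, 0.001, size=(30, 80))
    spec = _spectra(rows, grid=np.linspace(1500, 1400, 80))
    out = emsc(spec, reference=base)
    before = rows.std(axis=0).mean()
    after = out.absorbance.std(axis=0).mean()
    assert after < before / 5


# ------------------------------------------------------------------- restrict

def test_restrict_default_regions_keep_all_838():
    grid = default_grid()
    spec = _spectra(np.zeros(grid.size), grid)
    out = restrict(spec, ((2973.0, 2700.0), (1583.0, 1050.0)))
    assert out.wavenumbers.size == 838


def test_restrict_fingerprint_only():
    grid = default_grid()
    spec = _spectra(np.arange(grid.size, dtype=float), grid)
    out = restrict(spec, ((1500.0, 1050.0),))
    assert out.wavenumbers.size == int(((grid >= 1050) & (grid <= 1500)).sum())
    assert np.all(out.wavenumbers <= 1500)


def test_restrict_reported_wavenumbers_to_fingerprint_region():
    """Eight of the ten reported discriminating wavenumbers lie in the lower
    analysed range 1583-1050 cm⁻¹."""
    grid = np.array(sorted(REPORTED_WAVENUMBERS, reverse=True))
    spec = _spectra(np.zeros(10), grid)
    out = restrict(spec, ((1583.0, 1050.0),))
    assert out.wavenumbers.size == 8


def test_restrict_empty_errors():
    spec = _spectra(np.zeros(5), grid=np.linspace(1500, 1400, 5))
    with pytest.raises(ValueError):
        restrict(spec, ((3000.0, 2900.0),))


# --------------------------------------------------------------- mean center

def test_mean_center_idempotent_and_zero_mean(rng):
    X = rng.normal(3.0, 2.0, size=(15, 6))
    once, means = mean_center(X)
    np.testing.assert_allclose(once.mean(axis=0), 0.0, atol=1e-12)
    twice, _ = mean_center(once)
    np.testing.assert_allclose(twice, once, atol=1e-12)


def test_mean_center_test_rows_use_training_means(rng):
    train, test = rng.normal(size=(20, 4)), rng.normal(size=(5, 4)) + 10.0
    _, means = mean_center(train)
    centered_test, _ = mean_center(test, means)
    np.testing.assert_allclose(centered_test, test - train.mean(axis=0),
                               atol=1e-12)


# ------------------------------------------------------------------- pipeline

def test_plan_row_permutation_equivariance(rng):
    """Pipeline output follows row permutations exactly."""
    grid = default_grid()
    X = rng.normal(size=(12, grid.size)) + 2.0
    spec = _spectra(X, grid)
    plan = PreprocessPlan(steps=[SavgolStep(9, 2, 0), "snv", "restrict"])
    ref = plan.apply(spec).absorbance
    perm = rng.permutation(12)
    out = plan.apply(spec.subset_rows(perm)).absorbance
    np.testing.assert_allclose(out[np.argsort(perm)], ref, atol=1e-12)


def test_plan_validates_overlapping_regions():
    with pytest.raises(ValueError):
        PreprocessPlan(regions=((1583.0, 1050.0), (1200.0, 1100.0)))
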