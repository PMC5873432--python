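"""Sliding-window construction, series evaluation and AIC order selection."""

import numpy as np
import pandas as pd
import pytest

from covnet import (CohortConfig, DegenerateDataError, WindowSeries,
                    build_windows, fit_trajectory, generate_cohort,
                    sparsity_grid, window_property_series)


def _subjects(ages, ids=None):
    ids = ids or [f"s{i:03d}" for i in range(len(ages))]
    return pd.DataFrame({"subject_id": ids, "age": ages,
                         "sex": ["F", "M"] * (len(ages) // 2) +
                                ["F"] * (len(ages) % 2)})


def _series(ages, values, name="prop", w=10):
    return WindowSeries(property_name=name, window_ages=np.asarray(ages, float),
                        values=np.asarray(values, float), window_size=w)


def test_windows_enumeration_small():
    subjects = _subjects([1.0, 2.0, 3.0, 4.0, 5.0])
    windows, medians = build_windows(subjects, window_size=3)
    assert [sorted(w.tolist()) for w in windows] == [[0, 1, 2], [1, 2, 3], [2, 3, 4]]
    np.testing.assert_allclose(medians, [2.0, 3.0, 4.0])


def test_window_equal_to_cohort():
    subjects = _subjects([30.0, 20.0, 40.0, 50.0])
    windows, medians = build_windows(subjects, window_size=4)
    assert len(windows) == 1
    assert medians[0] == pytest.approx(np.median(subjects["age"]))


def test_full_scale_window_count(rng):
    ages = rng.uniform(48, 87, 437)
    subjects = _subjects(ages)
    windows, medians = build_windows(subjects, window_size=73)
    assert len(windows) == 437 - 73 + 1 == 365
    # contiguous windows differ by exactly one subject
    for a, b in zip(windows[:-1], windows[1:]):
        assert len(set(a) ^ set(b)) == 2
    assert np.all(np.diff(medians) >= 0)


def test_window_size_exceeds_cohort():
    with pytest.raises(DegenerateDataError, match="exceeds"):
        build_windows(_subjects([30.0, 40.0]), window_size=3)


def test_identical_consecutive_windows_identical_values(small_regions):
    """Two windows containing the same MT rows must yield identical values."""
    config = CohortConfig(n_subjects=30, age_range=(40, 60),
                          region_table=small_regions, seed=4)
    subjects, matrix, _ = generate_cohort(config)
    # duplicate one subject's row so two consecutive windows coincide in values
    grid = sparsity_grid(0.5, 0.9, 0.2)
    windows, _ = build_windows(subjects, window_size=20)
    series = window_property_series(matrix, subjects, small_regions,
                                    "global_connectivity", grid,
                                    windows=[windows[0], windows[0], windows[5]])
    assert series.values[0] == series.values[1]
    assert series.values[0] != series.values[2]


def test_flat_series_under_age_invariant_generator(small_regions):
    config = CohortConfig(n_subjects=120, age_range=(40, 80),
                          region_table=small_regions,
                          homologous_coupling=0.5, lobe_coupling=0.1, seed=6)
    subjects, matrix, _ = generate_cohort(config)
    grid = sparsity_grid(0.5, 0.9, 0.1)
    series = window_property_series(matrix, subjects, small_regions,
                                    "homologous_connectivity", grid,
                                    window_size=60)
    # no planted trend: the series stays inside a modest band around its mean
    assert series.values.std() < 0.05
    assert np.ptp(series.values) < 0.2


def test_planted_monotone_homologous_trend_recovered(small_regions):
    config = CohortConfig(n_subjects=160, age_range=(40, 80),
                          region_table=small_regions,
                          homologous_coupling=0.35, lobe_coupling=0.0,
                          homologous_coupling_slope=0.012, seed=10)
    subjects, matrix, _ = generate_cohort(config)
    grid = sparsity_grid(0.5, 0.9, 0.1)
    series = window_property_series(matrix, subjects, small_regions,
                                    "homologous_connectivity", grid,
                                    window_size=80)
    fit = fit_trajectory(series, max_order=1)
    assert fit.coefficients[1] > 0          # increasing trend
    assert fit.coef_pvalues[1] < 0.05


def test_exact_cubic_recovered_noise_free():
    ages = np.linspace(48, 75, 120)
    x = ages - ages.mean()
    coeffs = np.array([0.5, 0.02, -0.003, 0.0004])
    values = coeffs[0] + coeffs[1] * x + coeffs[2] * x ** 2 + coeffs[3] * x ** 3
    fit = fit_trajectory(_series(ages, values), max_order=6)
    assert fit.order == 3
    np.testing.assert_allclose(fit.coefficients, coeffs, atol=1e-6)
    assert np.all(fit.coef_pvalues < 1e-6)


def test_noise_free_line_selects_order_one():
    ages = np.linspace(48, 75, 60)
    fit = fit_trajectory(_series(ages, 1.0 + 0.01 * ages), max_order=6)
    assert fit.order == 1


def test_aic_selection_invariant_to_affine_value_rescaling(rng):
    ages = np.linspace(48, 75, 150)
    x = ages - ages.mean()
    values = 0.1 * x ** 2 - 0.05 * x + rng.normal(0, 1.0, len(x))
    f1 = fit_trajectory(_series(ages, values), max_order=5)
    f2 = fit_trajectory(_series(ages, 100.0 * values + 3.0), max_order=5)
    assert f1.order == f2.order


def test_consecutive_windows_change_continuously(small_regions):
    """Overlapping windows share all but one subject: consecutive values of a
    planted-structure series move in small steps, never wild jumps."""
    config = CohortConfig(n_subjects=80, age_range=(40, 80),
                          region_table=small_regions,
                          homologous_coupling=0.5, lobe_coupling=0.1, seed=12)
    subjects, matrix, _ = generate_cohort(config)
    series = window_property_series(matrix, subjects, small_regions,
                                    "homologous_connectivity",
                                    sparsity_grid(0.5, 0.9, 0.2),
                                    window_size=50)
    steps = np.abs(np.diff(series.values))
    assert steps.max() < 0.15


def test_too_few_windows_for_max_order():
    ages = np.linspace(48, 50, 5)
    with pytest.raises(DegenerateDataError):
        fit_trajectory(_series(ages, np.ones(5)), max_order=6)
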