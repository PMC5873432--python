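"""Pearson matrix construction and Fisher-pooled connectivity summaries."""

import numpy as np
import pandas as pd
import pytest

from covnet import (CohortConfig, DegenerateDataError, connectivity_summary,
                    fisher_mean_abs, generate_cohort, pearson_matrix,
                    regress_out_confounds, top_connected_regions)
from covnet.io import homologous_pairs

from conftest import random_corr_frame


def _frame(values, ids=None):
    ids = ids or [f"r{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, columns=ids)


def test_identical_and_negated_columns(rng):
    x = rng.normal(size=30)
    resid = _frame(np.column_stack([x, x, -x]))
    corr = pearson_matrix(resid).to_numpy()
    assert corr[0, 1] == pytest.approx(1.0, abs=1e-12)
    assert corr[0, 2] == pytest.approx(-1.0, abs=1e-12)
    assert np.all(np.diag(corr) == 0.0)


def test_matches_textbook_covariance_formula(rng):
    values = rng.normal(size=(10, 4))
    corr = pearson_matrix(_frame(values)).to_numpy()
    centered = values - values.mean(axis=0)
    cov = centered.T @ centered / len(values)
    sd = np.sqrt(np.diag(cov))
    expected = cov / np.outer(sd, sd)
    np.fill_diagonal(expected, 0.0)
    np.testing.assert_allclose(corr, expected, atol=1e-12)


def test_zero_variance_column_named(rng):
    values = rng.normal(size=(10, 3))
    values[:, 1] = 7.0
    with pytest.raises(DegenerateDataError, match="r1"):
        pearson_matrix(_frame(values))


@pytest.mark.parametrize("values, expected", [
    ([0.3, 0.3], 0.3),                       # mean of equal values
    ([0.5, -0.5], 0.5),                      # absolute value first
    ([0.2, 0.8], np.tanh((np.arctanh(0.2) + np.arctanh(0.8)) / 2)),  # 0.57245
])
def test_fisher_mean_abs_closed_form(values, expected):
    assert fisher_mean_abs(values) == pytest.approx(expected, abs=1e-12)


def test_fisher_mean_abs_contracts():
    with pytest.raises(DegenerateDataError):
        fisher_mean_abs([])
    with pytest.warns(UserWarning, match="clamped"):
        assert fisher_mean_abs([1.0]) < 1.0
    # lies between min and max |r|
    vals = [0.1, 0.4, 0.75]
    assert 0.1 < fisher_mean_abs(vals) < 0.75
    # first-order equal to the arithmetic mean as |r| -> 0
    tiny = [0.001, 0.002, 0.003]
    assert fisher_mean_abs(tiny) == pytest.approx(np.mean(tiny), rel=1e-4)


def test_global_summary_uniform_matrix(small_regions):
    n = len(small_regions)
    corr = np.full((n, n), 0.4)
    np.fill_diagonal(corr, 0.0)
    ids = list(small_regions["region_id"])
    frame = pd.DataFrame(corr, index=ids, columns=ids)
    summary = connectivity_summary(frame, small_regions, "global")
    assert summary.mean_abs_corr == pytest.approx(0.4, abs=1e-12)
    assert summary.n_pairs == n * (n - 1) // 2


def test_lobe_summary_two_regions_negative_r(small_regions):
    n = len(small_regions)
    ids = list(small_regions["region_id"])
    corr = np.zeros((n, n))
    insula = [i for i, l in enumerate(small_regions["lobe"]) if l == "insula"]
    assert len(insula) == 2
    i, j = insula
    corr[i, j] = corr[j, i] = -0.3
    # make the rest tiny nonzero to avoid an all-zero degenerate look
    frame = pd.DataFrame(corr, index=ids, columns=ids)
    summary = connectivity_summary(frame, small_regions, "lobe:insula")
    assert summary.mean_abs_corr == pytest.approx(0.3, abs=1e-12)
    assert summary.n_pairs == 1


def test_homologous_summary_recovers_planted_coupling(small_regions):
    config = CohortConfig(n_subjects=500, age_range=(20, 70),
                          region_table=small_regions,
                          homologous_coupling=0.64, lobe_coupling=0.0, seed=8)
    subjects, matrix, _ = generate_cohort(config)
    resid, _ = regress_out_confounds(matrix, subjects)
    corr = pearson_matrix(resid)
    summary = connectivity_summary(corr, small_regions, "homologous")
    assert summary.n_pairs == len(homologous_pairs(small_regions))
    assert 0.58 <= summary.mean_abs_corr <= 0.70


def test_unresolvable_scope(small_regions, rng):
    frame = random_corr_frame(len(small_regions), rng,
                              ids=list(small_regions["region_id"]))
    with pytest.raises(DegenerateDataError):
        connectivity_summary(frame, small_regions, "lobe:nowhere")
    with pytest.raises(DegenerateDataError):
        connectivity_summary(frame, small_regions, "region:missing")


def test_top_connected_regions_against_brute_force(small_regions, rng):
    frame = random_corr_frame(len(small_regions), rng,
                              ids=list(small_regions["region_id"]))
    ranking = top_connected_regions(frame, small_regions, k=len(small_regions))
    brute = []
    vals = frame.to_numpy()
    for k, rid in enumerate(small_regions["region_id"]):
        others = np.abs(np.delete(vals[k], k))
        brute.append((rid, float(np.tanh(np.mean(np.arctanh(others))))))
    brute.sort(key=lambda t: (-t[1], t[0]))
    assert [r for r, _ in ranking] == [r for r, _ in brute]
    np.testing.assert_allclose([v for _, v in ranking], [v for _, v in brute],
                               atol=1e-12)
    assert [r for r, _ in top_connected_regions(frame, small_regions, 3)] == \
        [r for r, _ in brute[:3]]


def test_dominant_region_ranked_first(small_regions):
    n = len(small_regions)
    ids = list(small_regions["region_id"])
    corr = np.full((n, n), 0.01)
    corr[3, :] = corr[:, 3] = 0.9
    np.fill_diagonal(corr, 0.0)
    frame = pd.DataFrame(corr, index=ids, columns=ids)
    assert top_connected_regions(frame, small_regions, 1)[0][0] == ids[3]


def test_summaries_equivariant_under_region_relabeling(small_regions, rng):
    ids = list(small_regions["region_id"])
    frame = random_corr_frame(len(ids), rng, ids=ids)
    perm = rng.permutation(len(ids))
    regions_p = small_regions.iloc[perm].reset_index(drop=True)
    frame_p = frame.iloc[perm, perm]
    for scope in ("global", "homologous", "lobe:frontal"):
        a = connectivity_summary(frame, small_regions, scope)
        b = connectivity_summary(frame_p, regions_p, scope)
        assert a.mean_abs_corr == pytest.approx(b.mean_abs_corr, abs=1e-12)
        assert a.n_pairs == b.n_pairs
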