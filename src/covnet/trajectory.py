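"""Sliding-window aging trajectories of network properties.

Subjects are ordered by age (ties broken by subject id) and grouped into
windows of a constant size (default 73 subjects) shifted one subject at a
time: window t covers age ranks [t, t + w).  Each window is detrended,
correlated and summarized exactly like a standalone group (no bootstrap),
yielding a series of property values against the window "age" — the median
age of its members.  The series is then fitted with polynomials of order
1..max_order and the minimum-AIC order is selected; coefficient significance
comes from t tests in the OLS fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariance import connectivity_summary, pearson_matrix
from .detrend import PolyFit, fit_polynomial, polynomial_aic, regress_out_confounds
from .errors import DegenerateDataError
from .graphs import betweenness, curve_auc, property_curves, threshold_at_sparsity
from .io import validate_subjects

DEFAULT_WINDOW_SIZE = 73
DEFAULT_MAX_ORDER = 6


@dataclass(frozen=True)
class WindowSeries:
    """One property value per sliding window, against median window age."""

    property_name: str
    window_ages: np.ndarray
    values: np.ndarray
    window_size: int

    def __post_init__(self):
        if len(self.window_ages) != len(self.values):
            raise DegenerateDataError("one value per window required")
        if (np.diff(self.window_ages) < 0).any():
            raise DegenerateDataError("window ages must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"window_age": self.window_ages,
                             "value": self.values})


def build_windows(subjects: pd.DataFrame, window_size: int = DEFAULT_WINDOW_SIZE
                  ) -> tuple[list[np.ndarray], np.ndarray]:
    """Age-ordered sliding windows of constant size, step one subject.

    Returns (window index arrays into the subject table's row order, median
    ages).  The number of windows is M - window_size + 1.
    """
    subjects = validate_subjects(subjects)
    m = len(subjects)
    if window_size < 2:
        raise DegenerateDataError("window_size must be at least 2")
    if window_size > m:
        raise DegenerateDataError(
            f"window_size {window_size} exceeds the {m} available subjects")
    order = subjects.sort_values(["age", "subject_id"], kind="mergesort").index.to_numpy()
    ages = subjects["age"].to_numpy(dtype=float)
    windows = [order[t:t + window_size] for t in range(m - window_size + 1)]
    medians = np.array([float(np.median(ages[w])) for w in windows])
    return windows, medians


def _window_statistic(matrix: pd.DataFrame, subjects: pd.DataFrame,
                      regions: pd.DataFrame, prop: str,
                      grid: np.ndarray) -> float:
    residuals, _ = regress_out_confounds(matrix, subjects)
    corr = pearson_matrix(residuals)
    if prop == "global_connectivity":
        return connectivity_summary(corr, regions, "global").mean_abs_corr
    if prop == "homologous_connectivity":
        return connectivity_summary(corr, regions, "homologous").mean_abs_corr
    if prop.startswith("nbc:"):
        rid = prop.split(":", 1)[1]
        ids = list(regions["region_id"])
        if rid not in ids:
            raise DegenerateDataError(f"unknown region {rid!r}")
        k = ids.index(rid)
        nbc = [betweenness(threshold_at_sparsity(corr, float(s))).nbc[k]
               for s in grid]
        return curve_auc(np.asarray(grid, dtype=float), np.array(nbc))
    curves = property_curves(corr, grid)
    if prop not in curves:
        raise DegenerateDataError(f"unknown property selector {prop!r}")
    return curves[prop].auc


def window_property_series(matrix: pd.DataFrame, subjects: pd.DataFrame,
                           regions: pd.DataFrame, prop: str,
                           grid: np.ndarray,
                           window_size: int = DEFAULT_WINDOW_SIZE,
                           windows: list[np.ndarray] | None = None
                           ) -> WindowSeries:
    """Evaluate one property per sliding window (detrended within window).

    ``prop`` is one of the four graph attributes (AUC over the grid):
    ``clustering``, ``path_length``, ``global_efficiency``,
    ``local_efficiency``; or ``global_connectivity``,
    ``homologous_connectivity``; or ``nbc:<region_id>`` (NBC AUC).
    """
    if windows is None:
        windows, medians = build_windows(subjects, window_size)
    else:
        ages = subjects["age"].to_numpy(dtype=float)
        medians = np.array([float(np.median(ages[w])) for w in windows])
        window_size = len(windows[0])
    values = np.empty(len(windows))
    for t, w in enumerate(windows):
        sub = subjects.iloc[w].reset_index(drop=True)
        mat = matrix.iloc[w]
        values[t] = _window_statistic(mat, sub, regions, prop, grid)
    return WindowSeries(property_name=prop, window_ages=medians,
                        values=values, window_size=window_size)


#: candidate orders within this AIC distance of the minimum are considered
#: statistically equivalent; the smallest such order is selected.
AIC_EQUIVALENCE = 2.0


def fit_trajectory(series: WindowSeries,
                   max_order: int = DEFAULT_MAX_ORDER) -> PolyFit:
    """AIC-based polynomial order selection over orders 1..max_order.

    Candidates are ranked by the regression AIC; following the usual
    parsimony convention for nested models, the selected order is the
    smallest one whose AIC lies within :data:`AIC_EQUIVALENCE` of the
    minimum (models closer than that are statistically indistinguishable,
    so the simplest wins).  Ages are mean-centered before building the
    design (orders up to 6 on a narrow age band are numerically singular in
    raw powers); the returned coefficients are in the centered variable, and
    the candidate AIC table is attached for reporting.
    """
    n = len(series.values)
    if n <= max_order + 1:
        raise DegenerateDataError(
            f"{n} windows cannot support fits up to order {max_order}")
    if np.ptp(series.window_ages) == 0:
        raise DegenerateDataError("constant window ages: trajectory fit undefined")
    scale = float(np.var(series.values))
    fits: dict[int, PolyFit] = {}
    for order in range(1, max_order + 1):
        fit = fit_polynomial(series.window_ages, series.values, order)
        fits[order] = fit
    aic_table = {order: polynomial_aic(n, fit.rss, order, scale=scale)
                 for order, fit in fits.items()}
    best_aic = min(aic_table.values())
    best_order = min(o for o, a in aic_table.items()
                     if a <= best_aic + AIC_EQUIVALENCE)
    best = fits[best_order]
    return PolyFit(order=best.order, coefficients=best.coefficients,
                   aic=aic_table[best_order], coef_pvalues=best.coef_pvalues,
                   rss=best.rss, age_center=best.age_center,
                   r_squared=best.r_squared, aic_table=aic_table)
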