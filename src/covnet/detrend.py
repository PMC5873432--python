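"""Confound detrending of regional MT values and global age-model fits.

Within each analysis unit (age group or sliding window) every region is
regressed, by ordinary least squares, on a shared five-column design:
intercept, age, age^2, sex, and the age x sex interaction.  The regression
residuals replace the raw values; only fluctuations around the mean aging
trajectory enter the covariance analysis.  The mean over regions ("global
MT") is deliberately NOT removed as a confound.

Age is mean-centered within the unit before squaring — purely numerical
hygiene that leaves residuals unchanged.  Sex is coded F=0, M=1.  In a
single-sex unit the sex and interaction columns are collinear with the
intercept and are dropped automatically (with a warning and a record).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateDataError, InvariantError
from .io import SEX_CODING

DESIGN_COLUMNS = ("intercept", "age", "age2", "sex", "age_sex")


@dataclass(frozen=True)
class DetrendInfo:
    """Bookkeeping from a detrending pass (for the JSON report)."""

    design_columns: tuple[str, ...]
    dropped_columns: tuple[str, ...]
    coefficients: pd.DataFrame  # design column x region
    sex_coding: dict = field(default_factory=lambda: dict(SEX_CODING))


@dataclass(frozen=True)
class PolyFit:
    """A polynomial OLS fit of a scalar series against age.

    ``coefficients`` are in ascending powers of the (centered) age variable;
    ``aic`` is the Gaussian-likelihood regression form n*ln(RSS/n) + 2(k+1).
    """

    order: int
    coefficients: np.ndarray
    aic: float
    coef_pvalues: np.ndarray
    rss: float
    age_center: float = 0.0
    r_squared: float = float("nan")
    aic_table: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.coefficients) != self.order + 1:
            raise InvariantError("coefficient count must equal order + 1")
        if self.rss < -1e-12:
            raise InvariantError("rss must be non-negative")

    def predict(self, ages: np.ndarray) -> np.ndarray:
        x = np.asarray(ages, dtype=float) - self.age_center
        return np.polynomial.polynomial.polyval(x, self.coefficients)

    @property
    def peak_age(self) -> float:
        """Vertex of a quadratic fit, in original age units (NaN otherwise)."""
        if self.order != 2 or self.coefficients[2] == 0:
            return float("nan")
        return float(self.age_center - self.coefficients[1] / (2 * self.coefficients[2]))

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "coefficients": self.coefficients.tolist(),
            "aic": self.aic,
            "coef_pvalues": self.coef_pvalues.tolist(),
            "rss": self.rss,
            "age_center": self.age_center,
            "r_squared": self.r_squared,
            "aic_table": {str(k): v for k, v in self.aic_table.items()},
        }


def _design_matrix(subjects: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    """Build the confound design, dropping collinear columns if needed."""
    ages = subjects["age"].to_numpy(dtype=float)
    sex = np.array([SEX_CODING[s] for s in subjects["sex"]], dtype=float)
    age_c = ages - ages.mean()
    columns = {
        "intercept": np.ones_like(ages),
        "age": age_c,
        "age2": age_c ** 2,
        "sex": sex,
        "age_sex": age_c * sex,
    }
    names = list(DESIGN_COLUMNS)
    dropped: list[str] = []
    if len(np.unique(sex)) < 2:
        dropped = ["sex", "age_sex"]
        names = [c for c in names if c not in dropped]
        warnings.warn(
            "single-sex unit: dropping 'sex' and 'age_sex' design columns",
            UserWarning, stacklevel=3)
    X = np.column_stack([columns[c] for c in names])
    # remaining rank deficiencies (e.g. all ages equal) are dropped greedily
    while np.linalg.matrix_rank(X) < X.shape[1]:
        for k in range(X.shape[1] - 1, 0, -1):
            reduced = np.delete(X, k, axis=1)
            if np.linalg.matrix_rank(reduced) == reduced.shape[1]:
                dropped.append(names.pop(k))
                warnings.warn(f"rank-deficient design: dropping column "
                              f"{dropped[-1]!r}", UserWarning, stacklevel=3)
                X = reduced
                break
        else:  # pragma: no cover - intercept alone is always full rank
            break
    return X, names, dropped


def regress_out_confounds(matrix: pd.DataFrame, subjects: pd.DataFrame
                          ) -> tuple[pd.DataFrame, DetrendInfo]:
    """Residualize every region on the shared confound design.

    Returns the residual matrix (same shape, index and units as the input)
    and a :class:`DetrendInfo` with fitted coefficients and dropped columns.
    """
    if list(matrix.index) != list(subjects["subject_id"]):
        raise InvariantError("matrix rows and subject table must be aligned")
    X, names, dropped = _design_matrix(subjects)
    m = len(subjects)
    if m <= X.shape[1]:
        raise DegenerateDataError(
            f"{m} subjects cannot support a {X.shape[1]}-column confound design")
    Y = matrix.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    residuals = pd.DataFrame(resid, index=matrix.index, columns=matrix.columns)
    info = DetrendInfo(
        design_columns=tuple(names),
        dropped_columns=tuple(dropped),
        coefficients=pd.DataFrame(beta, index=names, columns=matrix.columns),
    )
    return residuals, info


def polynomial_aic(n: int, rss: float, order: int,
                   scale: float | None = None) -> float:
    """Regression AIC: n*ln(RSS/n) + 2(k+1), k = order + 1 parameters.

    ``scale`` (the variance of the fitted values) floors RSS at the float
    rounding level, so exact fits compare by the parameter penalty rather
    than by the log of numerical noise.
    """
    floor = 1e-300 if scale is None else max(n * scale * 1e-18, 1e-300)
    rss = max(rss, floor)
    return float(n * np.log(rss / n) + 2 * (order + 2))


def fit_polynomial(ages: np.ndarray, values: np.ndarray, order: int) -> PolyFit:
    """OLS polynomial fit of values against centered age, with t-test p-values."""
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(ages) <= order + 1:
        raise DegenerateDataError(
            f"{len(ages)} points cannot support an order-{order} fit")
    if np.ptp(ages) == 0:
        raise DegenerateDataError("all ages identical: polynomial fit undefined")
    center = float(ages.mean())
    x = ages - center
    X = np.vander(x, order + 1, increasing=True)
    model = sm.OLS(values, X).fit()
    rss = float(np.sum(model.resid ** 2))
    return PolyFit(
        order=order,
        coefficients=np.asarray(model.params, dtype=float),
        aic=polynomial_aic(len(ages), rss, order, scale=float(np.var(values))),
        coef_pvalues=np.asarray(model.pvalues, dtype=float),
        rss=rss,
        age_center=center,
        r_squared=float(model.rsquared),
    )


def fit_global_age_model(matrix: pd.DataFrame, subjects: pd.DataFrame,
                         order: int = 2) -> PolyFit:
    """Fit mean-over-regions MT against age with a polynomial (default order 2).

    The global MT of a subject is the unweighted mean of its regional means.
    An order-2 fit captures the inverted-U lifespan trajectory; the vertex
    (``PolyFit.peak_age``) estimates the age of peak myelination.
    """
    if list(matrix.index) != list(subjects["subject_id"]):
        raise InvariantError("matrix rows and subject table must be aligned")
    global_mt = matrix.to_numpy(dtype=float).mean(axis=1)
    ages = subjects["age"].to_numpy(dtype=float)
    return fit_polynomial(ages, global_mt, order)
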