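"""Subject-level bootstrap of correlation statistics and BC percentile tests.

Each bootstrap draw resamples the M subjects with replacement (classical
Efron bootstrap, resample size = M), recomputes the Pearson matrix — by
default re-fitting the confound regression on the resample so detrending
uncertainty propagates — and evaluates one or more scalar statistics on it.
Group differences are tested with the bias-corrected (BC) percentile
bootstrap: the empirical distribution of differences is formed by
subtracting corresponding bootstrap samples between groups, and the 95% CI
endpoints are percentile points shifted by the bias term
z0 = Phi^-1(#{diff < point estimate} / Nboot).  A difference is significant
iff the CI excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError

DEFAULT_N_BOOT = 2000


@dataclass(frozen=True)
class BootstrapSet:
    """Bootstrap replicates of one or more named scalar statistics.

    ``values`` has shape (n_boot, n_statistics); ``names`` labels columns.
    """

    names: tuple[str, ...]
    values: np.ndarray
    n_boot: int
    seed: int | None
    n_redrawn: int = 0

    def __post_init__(self):
        if self.values.shape != (self.n_boot, len(self.names)):
            raise DegenerateDataError("bootstrap value array has wrong shape")
        if not np.isfinite(self.values).all():
            raise DegenerateDataError("non-finite bootstrap statistic")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


@dataclass(frozen=True)
class GroupDiff:
    """A two-group difference with its BC percentile bootstrap CI."""

    name: str
    point_estimate: float
    diff_distribution: np.ndarray
    ci_low: float
    ci_high: float
    significant: bool
    alpha: float
    z0: float

    def to_dict(self) -> dict:
        return {"name": self.name, "point_estimate": self.point_estimate,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "significant": self.significant, "alpha": self.alpha,
                "z0": self.z0}


def bootstrap_statistics(residuals: pd.DataFrame,
                         statistic: Callable[[pd.DataFrame], float | Sequence[float]],
                         n_boot: int = DEFAULT_N_BOOT,
                         seed: int | None = None,
                         names: Sequence[str] | None = None,
                         max_retries: int = 10,
                         subjects: pd.DataFrame | None = None) -> BootstrapSet:
    """Evaluate ``statistic`` on ``n_boot`` subject resamples.

    ``statistic`` maps a correlation matrix to a scalar or a fixed-length
    vector (``names`` labels the entries).  When ``subjects`` is given, the
    first argument is treated as the *raw* myelin matrix and the confound
    regression is re-fitted inside every resample, so the uncertainty of the
    detrending step propagates into the bootstrap distribution; otherwise
    precomputed residual rows are resampled directly.  A resample in which
    some region has zero variance is redrawn (at most ``max_retries`` times
    per draw) and the event counted in ``n_redrawn``.
    """
    from .covariance import correlation_values
    values = residuals.to_numpy(dtype=float)
    m = values.shape[0]
    if m < 10:
        raise DegenerateDataError("bootstrap needs at least 10 subjects")
    design = None
    if subjects is not None:
        from .detrend import _design_matrix
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)
            design, _, _ = _design_matrix(subjects)
    columns = list(residuals.columns)
    rng = np.random.default_rng(seed)
    rows = []
    n_redrawn = 0
    for _ in range(n_boot):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, m, size=m)
            sample = values[idx]
            if design is not None:
                xb = design[idx]
                beta, *_ = np.linalg.lstsq(xb, sample, rcond=None)
                sample = sample - xb @ beta
            try:
                corr = pd.DataFrame(correlation_values(sample, columns),
                                    index=columns, columns=columns)
            except DegenerateDataError:
                n_redrawn += 1
                if attempt == max_retries:
                    raise
                continue
            break
        rows.append(np.atleast_1d(np.asarray(statistic(corr), dtype=float)))
    arr = np.vstack(rows)
    if names is None:
        names = ("statistic",) if arr.shape[1] == 1 else tuple(
            f"statistic_{k}" for k in range(arr.shape[1]))
    return BootstrapSet(names=tuple(names), values=arr, n_boot=n_boot,
                        seed=seed, n_redrawn=n_redrawn)


def bc_percentile_ci(diffs: np.ndarray, point_estimate: float,
                     alpha: float = 0.05) -> tuple[float, float, float]:
    """Bias-corrected percentile CI bounds (low, high) and the bias term z0."""
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    if n < 2 or np.ptp(diffs) == 0:
        raise DegenerateDataError(
            "degenerate bootstrap difference distribution (all values equal)")
    prop = float(np.mean(diffs < point_estimate))
    if prop <= 0.0 or prop >= 1.0:
        warnings.warn(
            "bias-correction proportion at 0 or 1: clamping z0", UserWarning,
            stacklevel=2)
        prop = min(max(prop, 1.0 / (n + 1)), n / (n + 1.0))
    z0 = float(stats.norm.ppf(prop))
    z_lo, z_hi = stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)
    p_lo = float(stats.norm.cdf(2 * z0 + z_lo))
    p_hi = float(stats.norm.cdf(2 * z0 + z_hi))
    # conservative endpoint convention for a discrete bootstrap distribution:
    # round the order statistics outward instead of interpolating between them
    lo = np.quantile(diffs, p_lo, method="lower")
    hi = np.quantile(diffs, p_hi, method="higher")
    return float(lo), float(hi), z0


def group_difference(boot_a: BootstrapSet, boot_b: BootstrapSet,
                     point_a: float, point_b: float,
                     name: str = "statistic", alpha: float = 0.05) -> GroupDiff:
    """BC percentile bootstrap test of (group A - group B) for one statistic.

    Bootstrap samples are paired by index; since the two groups are resampled
    independently this is statistically equivalent to any other pairing.
    """
    if boot_a.n_boot != boot_b.n_boot:
        raise DegenerateDataError("bootstrap sets must have equal n_boot")
    diffs = boot_a.column(name) - boot_b.column(name)
    point = float(point_a - point_b)
    lo, hi, z0 = bc_percentile_ci(diffs, point, alpha)
    return GroupDiff(name=name, point_estimate=point, diff_distribution=diffs,
                     ci_low=lo, ci_high=hi,
                     significant=not (lo <= 0.0 <= hi), alpha=alpha, z0=z0)


def spawn_seeds(seed: int | None, n: int) -> list[int]:
    """Derive n independent child seeds (< 2**31) from one global seed."""
    seq = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in seq.spawn(n)]
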