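"""Pearson covariance matrix of detrended regional MT and its summaries.

An edge weight C_ij is the across-subject Pearson correlation between the
detrended MT fluctuations of regions i and j.  Self-connections are excluded
(zero diagonal).  Mean-correlation summaries (global, homologous pairs,
within-lobe, per-region) pool |r| values through Fisher's r-to-z transform:
z = atanh|r| are averaged and mapped back with tanh.  The raw arithmetic
mean of |r| is reported alongside for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InvariantError
from .io import homologous_pairs, validate_correlation_matrix

#: |r| at or above this is clamped before atanh to avoid infinities
_CLAMP = 1.0 - 1e-7


@dataclass(frozen=True)
class ConnectivitySummary:
    """Fisher-pooled mean |r| over a named set of region pairs."""

    scope: str
    mean_abs_corr: float
    n_pairs: int
    arithmetic_mean_abs: float

    def to_dict(self) -> dict:
        return {"scope": self.scope, "mean_abs_corr": self.mean_abs_corr,
                "n_pairs": self.n_pairs,
                "arithmetic_mean_abs": self.arithmetic_mean_abs}


def correlation_values(values: np.ndarray, names: Sequence[str]) -> np.ndarray:
    """Pearson matrix of columns as a bare array (zero diagonal, symmetric)."""
    if values.shape[0] < 3:
        raise DegenerateDataError("at least 3 subjects required for correlations")
    sd = values.std(axis=0)
    # columns at float rounding level (e.g. residuals of a noise-free model)
    # carry no signal: correlations on them would be numerically meaningless
    degenerate = sd <= 1e-10
    if degenerate.any():
        bad = names[int(np.argmax(degenerate))]
        raise DegenerateDataError(f"region {bad!r} has zero variance")
    corr = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(corr, 0.0)
    return np.clip((corr + corr.T) / 2.0, -1.0, 1.0)  # symmetrize fp noise


def pearson_matrix(residuals: pd.DataFrame) -> pd.DataFrame:
    """The N x N Pearson correlation matrix of region columns, zero diagonal."""
    corr = correlation_values(residuals.to_numpy(dtype=float),
                              list(residuals.columns))
    return pd.DataFrame(corr, index=residuals.columns, columns=residuals.columns)


def fisher_mean_abs(values: Iterable[float]) -> float:
    """tanh(mean(atanh|r|)) with |r| >= 1-1e-7 clamped."""
    arr = np.abs(np.asarray(list(values), dtype=float))
    if arr.size == 0:
        raise DegenerateDataError("fisher_mean_abs of an empty set of correlations")
    if (arr > 1 + 1e-12).any():
        raise InvariantError("correlations must lie in [-1, 1]")
    n_clamped = int((arr >= _CLAMP).sum())
    if n_clamped:
        warnings.warn(f"clamped {n_clamped} |r| value(s) at {_CLAMP}",
                      UserWarning, stacklevel=2)
    arr = np.minimum(arr, _CLAMP)
    return float(np.tanh(np.mean(np.arctanh(arr))))


def _pair_values(corr: pd.DataFrame, pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    values = corr.to_numpy(dtype=float)
    return np.array([values[i, j] for i, j in pairs], dtype=float)


def _scope_pairs(corr: pd.DataFrame, regions: pd.DataFrame,
                 scope: str) -> list[tuple[int, int]]:
    n = corr.shape[0]
    if scope == "global":
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    if scope == "homologous":
        pairs = homologous_pairs(regions)
        if not pairs:
            raise DegenerateDataError("no homologous pairs in the region table")
        return pairs
    if scope.startswith("lobe:"):
        lobe = scope.split(":", 1)[1]
        members = [i for i, l in enumerate(regions["lobe"]) if l == lobe]
        if len(members) < 2:
            raise DegenerateDataError(f"lobe {lobe!r} has fewer than 2 regions")
        return [(i, j) for a, i in enumerate(members) for j in members[a + 1:]]
    if scope.startswith("region:"):
        rid = scope.split(":", 1)[1]
        ids = list(regions["region_id"])
        if rid not in ids:
            raise DegenerateDataError(f"unknown region {rid!r}")
        k = ids.index(rid)
        return [(min(k, j), max(k, j)) for j in range(n) if j != k]
    raise DegenerateDataError(f"unresolvable scope {scope!r}")


def connectivity_summary(corr: pd.DataFrame, regions: pd.DataFrame,
                         scope: str) -> ConnectivitySummary:
    """Summary over a scope: ``global``, ``homologous``, ``lobe:<name>`` or
    ``region:<id>``.

    Global pools all N(N-1)/2 pairs; homologous pools the left/right pair
    diagonal; a lobe pools every within-lobe pair from both hemispheres; a
    region pools its N-1 incident pairs.
    """
    validate_correlation_matrix(corr)
    pairs = _scope_pairs(corr, regions, scope)
    vals = _pair_values(corr, pairs)
    return ConnectivitySummary(
        scope=scope,
        mean_abs_corr=fisher_mean_abs(vals),
        n_pairs=len(pairs),
        arithmetic_mean_abs=float(np.mean(np.abs(vals))),
    )


def top_connected_regions(corr: pd.DataFrame, regions: pd.DataFrame,
                          k: int) -> list[tuple[str, float]]:
    """The k regions with the strongest mean inter-regional covariation.

    Per-region strength is the Fisher-pooled mean |r| over that region's
    N-1 pairs; ties break lexicographically on region id.
    """
    if k < 1:
        raise DegenerateDataError("k must be at least 1")
    ids = list(regions["region_id"])
    if k > len(ids):
        raise DegenerateDataError(f"k={k} exceeds the {len(ids)} regions")
    strengths = [(rid, connectivity_summary(corr, regions, f"region:{rid}").mean_abs_corr)
                 for rid in ids]
    strengths.sort(key=lambda item: (-item[1], item[0]))
    return strengths[:k]
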