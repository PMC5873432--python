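"""Synthetic cohort generator with planted covariance structure.

The generator emulates the statistical features a regional-MT covariance
analysis relies on, with known ground truth:

* an inverted-U mean trajectory of MT with age (concave quadratic per region,
  peaking between 40 and 50 years by default);
* an additive sex effect and an optional age x sex interaction;
* residual covariance built from shared latent factors — one factor per
  homologous left/right pair and one per lobe — plus independent noise.

With pair loading sqrt(hc) and lobe loading sqrt(lc) on a unit-variance
residual, the planted Pearson correlation is ``hc + lc`` for a homologous
pair (the pair shares its lobe factor too), ``lc`` for same-lobe pairs and 0
across lobes.  The construction is positive semi-definite whenever
``hc + lc < 1``.  ``noise_sd`` scales the whole residual, so it never changes
planted correlations — only the size of fluctuations around the mean curve.

Couplings may optionally drift with the cohort's age (a linear slope on the
homologous coupling, an inverted-U profile on the lobe coupling) to plant
trends for the sliding-window trajectory analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import SEX_CODING, homologous_pairs, validate_regions
from .regions import default_region_table

_MAX_TOTAL_COUPLING = 0.98


@dataclass(frozen=True)
class CohortConfig:
    """Generative configuration for one cohort.

    Units: ages in years; MT values in semi-quantitative MT units (percent
    units, baseline ~1); couplings are planted correlations in [0, 1).
    """

    n_subjects: int
    age_range: tuple[float, float]
    region_table: pd.DataFrame
    female_fraction: float = 0.5
    baseline_mt: float = 1.0
    baseline_region_sd: float = 0.05
    peak_age_range: tuple[float, float] = (40.0, 50.0)
    quadratic_curvature: float = 8e-5  # MT units / year^2
    sex_effect: float = 0.01           # MT units, male minus female
    age_sex_effect: float = 0.0        # MT units / year
    homologous_coupling: float = 0.45
    lobe_coupling: float | Mapping[str, float] = 0.15
    noise_sd: float = 0.03             # MT units, total residual SD
    homologous_coupling_slope: float = 0.0   # per year, for planted trends
    lobe_coupling_peak_age: float | None = None
    lobe_coupling_curvature: float = 0.0     # per year^2 (inverted-U profile)
    subject_prefix: str = "sub"
    seed: int | None = None

    def lobe_coupling_for(self, lobe: str) -> float:
        if isinstance(self.lobe_coupling, Mapping):
            return float(self.lobe_coupling.get(lobe, 0.0))
        return float(self.lobe_coupling)

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ConfigError("n_subjects must be at least 4")
        lo, hi = self.age_range
        if not (0 < lo <= hi):
            raise ConfigError("age_range must satisfy 0 < lo <= hi")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        hc = self.homologous_coupling
        if hc < 0 or hc >= 1:
            raise ConfigError("homologous_coupling must lie in [0, 1)")
        lobes = set(self.region_table["lobe"])
        for lobe in lobes:
            lc = self.lobe_coupling_for(lobe)
            if lc < 0 or lc >= 1:
                raise ConfigError(f"lobe_coupling[{lobe}] must lie in [0, 1)")
            if hc + lc >= 1:
                raise ConfigError(
                    f"homologous_coupling + lobe_coupling[{lobe}] = {hc + lc:.3f} "
                    "implies a non-PSD residual covariance (must be < 1)")


def _effective_couplings(config: CohortConfig, ages: np.ndarray,
                         lobe: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject (hc, lc) after applying the optional age profiles."""
    mid = 0.5 * (config.age_range[0] + config.age_range[1])
    hc = config.homologous_coupling + config.homologous_coupling_slope * (ages - mid)
    lc0 = config.lobe_coupling_for(lobe)
    if config.lobe_coupling_peak_age is not None:
        lc = lc0 - config.lobe_coupling_curvature * (ages - config.lobe_coupling_peak_age) ** 2
    else:
        lc = np.full_like(ages, lc0, dtype=float)
    lc = np.clip(lc, 0.0, _MAX_TOTAL_COUPLING)
    hc = np.clip(hc, 0.0, _MAX_TOTAL_COUPLING - lc)
    return hc, lc


def planted_correlation(config: CohortConfig) -> pd.DataFrame:
    """The planted residual correlation matrix (age-profile-free baseline).

    Homologous pair: hc + lc of their lobe; same-lobe pair: lc; otherwise 0.
    Diagonal is zero, matching the pipeline's correlation-matrix convention.
    """
    regions = config.region_table
    ids = list(regions["region_id"])
    n = len(ids)
    lobes = list(regions["lobe"])
    truth = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if lobes[i] == lobes[j]:
                truth[i, j] = truth[j, i] = config.lobe_coupling_for(lobes[i])
    for i, j in homologous_pairs(regions):
        truth[i, j] = truth[j, i] = (config.homologous_coupling
                                     + config.lobe_coupling_for(lobes[i]))
    return pd.DataFrame(truth, index=ids, columns=ids)


def generate_cohort(config: CohortConfig, seed: int | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, Any]]:
    """Draw one cohort: (subjects, myelin matrix, ground-truth record).

    Deterministic given (config, seed); ``seed`` overrides ``config.seed``.
    """
    config.validate()
    regions = validate_regions(config.region_table)
    rng = np.random.default_rng(config.seed if seed is None else seed)

    m = config.n_subjects
    ids = [f"{config.subject_prefix}{i:04d}" for i in range(m)]
    ages = rng.uniform(config.age_range[0], config.age_range[1], size=m)
    n_female = int(round(config.female_fraction * m))
    sexes = np.array(["F"] * n_female + ["M"] * (m - n_female))
    rng.shuffle(sexes)
    subjects = pd.DataFrame({"subject_id": ids, "age": ages, "sex": sexes})

    region_ids = list(regions["region_id"])
    lobes = list(regions["lobe"])
    n = len(region_ids)
    mu = config.baseline_mt + rng.normal(0.0, config.baseline_region_sd, size=n)
    peaks = rng.uniform(*config.peak_age_range, size=n)

    sex_code = np.array([SEX_CODING[s] for s in sexes], dtype=float)
    mid_age = 0.5 * (config.age_range[0] + config.age_range[1])
    mean = (mu[None, :]
            - config.quadratic_curvature * (ages[:, None] - peaks[None, :]) ** 2
            + config.sex_effect * sex_code[:, None]
            + config.age_sex_effect * sex_code[:, None] * (ages[:, None] - mid_age))

    pairs = homologous_pairs(regions)
    pair_of = np.full(n, -1)
    for p, (i, j) in enumerate(pairs):
        pair_of[i] = pair_of[j] = p
    lobe_names = sorted(set(lobes))
    lobe_of = np.array([lobe_names.index(l) for l in lobes])

    pair_factors = rng.standard_normal((m, len(pairs)))
    lobe_factors = rng.standard_normal((m, len(lobe_names)))
    unique_noise = rng.standard_normal((m, n))

    resid = np.empty((m, n))
    for j in range(n):
        hc, lc = _effective_couplings(config, ages, lobes[j])
        if pair_of[j] < 0:
            hc = np.zeros_like(hc)
        load_pair = np.sqrt(hc)
        load_lobe = np.sqrt(lc)
        load_unique = np.sqrt(1.0 - hc - lc)
        col = load_lobe * lobe_factors[:, lobe_of[j]] + load_unique * unique_noise[:, j]
        if pair_of[j] >= 0:
            col = col + load_pair * pair_factors[:, pair_of[j]]
        resid[:, j] = col
    values = mean + config.noise_sd * resid

    matrix = pd.DataFrame(values, index=ids, columns=region_ids)
    matrix.index.name = "subject_id"
    truth = {
        "planted_correlation": planted_correlation(config),
        "peak_ages": pd.Series(peaks, index=region_ids),
        "region_baselines": pd.Series(mu, index=region_ids),
        "homologous_coupling": config.homologous_coupling,
        "lobe_coupling": (dict(config.lobe_coupling)
                          if isinstance(config.lobe_coupling, Mapping)
                          else config.lobe_coupling),
        "noise_sd": config.noise_sd,
        "seed": config.seed if seed is None else seed,
    }
    return subjects, matrix, truth


def make_two_group_fixture(config_young: CohortConfig, config_old: CohortConfig,
                           seed_young: int | None = None,
                           seed_old: int | None = None):
    """Two cohorts on the same parcellation (a young/old comparison fixture)."""
    if list(config_young.region_table["region_id"]) != list(config_old.region_table["region_id"]):
        raise ConfigError("the two cohorts must share the same region table")
    young = generate_cohort(config_young, seed=seed_young)
    old = generate_cohort(config_old, seed=seed_old)
    return young, old


def young_group_config(region_table: pd.DataFrame | None = None,
                       seed: int | None = None, **overrides) -> CohortConfig:
    """Study-matched young-adult cohort: 73 subjects (35 F), ages 20-31."""
    cfg = CohortConfig(
        n_subjects=73, age_range=(20.0, 31.0), female_fraction=35 / 73,
        region_table=default_region_table() if region_table is None else region_table,
        subject_prefix="Y", seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def old_group_config(region_table: pd.DataFrame | None = None,
                     seed: int | None = None, **overrides) -> CohortConfig:
    """Study-matched older cohort: 78 subjects (40 F), ages 60-71.

    Defaults plant the age pattern the analysis is designed to detect: a
    higher homologous coupling than the young group with the same lobe
    coupling, leaving global structure comparable.
    """
    cfg = CohortConfig(
        n_subjects=78, age_range=(60.0, 71.0), female_fraction=40 / 78,
        region_table=default_region_table() if region_table is None else region_table,
        homologous_coupling=0.6,
        subject_prefix="O", seed=seed)
    return replace(cfg, **overrides) if overrides else cfg
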