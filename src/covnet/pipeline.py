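"""End-to-end experiments: two-group comparison and aging trajectory.

``run_group_comparison`` executes, per group: confound detrending ->
Pearson matrix -> bootstrap distributions of every scalar statistic
(attribute AUCs over the sparsity grid, global/homologous/per-lobe
connectivity, per-region normalized betweenness AUC, targeted-attack
robustness) -> a bias-corrected percentile bootstrap test per statistic,
plus hub and most-connected-region tables.

``run_trajectory`` evaluates the same statistics over age-ordered sliding
windows (no bootstrap) and fits each series with an AIC-selected polynomial.

Everything is deterministic given (config, seed): one global seed spawns
per-group child seeds, and all outputs are written as sorted-key JSON/TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io
from .attack import targeted_attack
from .bootstrap import bootstrap_statistics, group_difference, spawn_seeds
from .covariance import connectivity_summary, pearson_matrix, top_connected_regions
from .detrend import regress_out_confounds
from .errors import ConfigError, DegenerateDataError
from .graphs import (GRAPH_PROPERTIES, NodeMetrics, betweenness_values,
                     clustering, curve_auc, local_efficiency,
                     pairwise_distances, shortest_path_counts, sparsity_grid,
                     threshold_at_sparsity, _efficiency_from_distances)
from .io import SEX_CODING
from .regions import default_region_table
from .simulate import CohortConfig, generate_cohort, young_group_config, old_group_config
from .trajectory import build_windows, fit_trajectory, WindowSeries

CONNECTIVITY_SCOPES = ("global", "homologous")


@dataclass
class PipelineConfig:
    """Aggregated defaults of the whole analysis (all overridable)."""

    mode: str = "simulate"                 # "simulate" or "files"
    matrix_path: str | None = None
    subjects_path: str | None = None
    regions_path: str | None = None
    young_age_range: tuple[float, float] = (20.0, 31.0)
    old_age_range: tuple[float, float] = (60.0, 71.0)
    group_column: str | None = None        # explicit label column alternative
    sparsity_lo: float = 0.50
    sparsity_hi: float = 0.90
    sparsity_step: float = 0.02
    n_boot: int = 2000
    alpha: float = 0.05
    hub_threshold: float = 1.5
    top_k: int = 15
    window_size: int = 73
    max_poly_order: int = 6
    trajectory_properties: tuple[str, ...] = (
        "clustering", "path_length", "global_efficiency", "local_efficiency",
        "global_connectivity", "homologous_connectivity")
    nbc_regions: tuple[str, ...] = ()
    include_attack: bool = True
    include_nbc: bool = True
    seed: int | None = None
    output_dir: str | None = None
    young: CohortConfig | None = None      # simulation-mode cohorts
    old: CohortConfig | None = None
    cohort: CohortConfig | None = None     # trajectory simulation cohort

    def validate(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.n_boot < 50:
            raise ConfigError("n_boot must be at least 50")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if len(self.grid()) < 2:
            raise ConfigError("sparsity grid must have at least 2 points")

    def grid(self) -> np.ndarray:
        return sparsity_grid(self.sparsity_lo, self.sparsity_hi, self.sparsity_step)

    def echo(self) -> dict[str, Any]:
        d = {k: v for k, v in asdict(self).items()
             if k not in ("young", "old", "cohort")}
        d["sex_coding"] = dict(SEX_CODING)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        for key in ("young_age_range", "old_age_range", "trajectory_properties",
                    "nbc_regions"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# the statistic sweep (shared by bootstrap, point estimates and windows)
# ---------------------------------------------------------------------------

def evaluate_statistics(corr: pd.DataFrame, regions: pd.DataFrame,
                        grid: np.ndarray, include_attack: bool = True,
                        include_nbc: bool = True,
                        hub_threshold: float = 1.5) -> dict[str, float]:
    """All scalar statistics of one correlation matrix, in one grid sweep.

    Distances and shortest-path counts are computed once per sparsity and
    shared between path length, efficiencies, betweenness and the attack.
    """
    stats: dict[str, float] = {}
    for scope in CONNECTIVITY_SCOPES:
        stats[f"{scope}_connectivity"] = connectivity_summary(
            corr, regions, scope).mean_abs_corr
    for lobe in sorted(set(regions["lobe"])):
        if (regions["lobe"] == lobe).sum() >= 2:
            stats[f"lobe_connectivity:{lobe}"] = connectivity_summary(
                corr, regions, f"lobe:{lobe}").mean_abs_corr

    grid = np.asarray(grid, dtype=float)
    n = corr.shape[0]
    curves: dict[str, list[float]] = {p: [] for p in GRAPH_PROPERTIES}
    attack_vals: list[float] = []
    nbc_mat = np.zeros((n, len(grid)))
    for k, s in enumerate(grid):
        graph = threshold_at_sparsity(corr, float(s))
        adj = graph.adjacency
        dist = pairwise_distances(adj)
        off = ~np.eye(n, dtype=bool)
        finite = np.isfinite(dist) & off
        ci, c = clustering(graph)
        curves["clustering"].append(c)
        curves["path_length"].append(float(dist[finite].mean()) if finite.any()
                                     else float("nan"))
        curves["global_efficiency"].append(_efficiency_from_distances(dist))
        curves["local_efficiency"].append(local_efficiency(graph))
        if include_nbc or include_attack:
            sigma = shortest_path_counts(adj, dist)
            b = betweenness_values(adj, dist, sigma)
            mean_b = float(b.mean())
            nbc = b / mean_b if mean_b > 0 else np.zeros_like(b)
            nbc_mat[:, k] = nbc
            if include_attack:
                metrics = NodeMetrics(
                    clustering=ci, betweenness=b, nbc=nbc,
                    degree=adj.sum(axis=1).astype(int),
                    mean_betweenness=mean_b, nbc_defined=mean_b > 0,
                    region_ids=graph.region_ids)
                attack_vals.append(targeted_attack(graph, metrics).robustness_auc)
    for prop in GRAPH_PROPERTIES:
        stats[f"{prop}_auc"] = curve_auc(grid, np.array(curves[prop]))
    if include_attack:
        stats["robustness_auc"] = curve_auc(grid, np.array(attack_vals))
    if include_nbc:
        for i, rid in enumerate(corr.columns):
            stats[f"nbc_auc:{rid}"] = curve_auc(grid, nbc_mat[i])
    return stats


def mean_nbc_over_grid(corr: pd.DataFrame, grid: np.ndarray) -> pd.Series:
    """Grid-averaged normalized betweenness per region (for hub tables)."""
    grid = np.asarray(grid, dtype=float)
    n = corr.shape[0]
    acc = np.zeros(n)
    for s in grid:
        graph = threshold_at_sparsity(corr, float(s))
        dist = pairwise_distances(graph.adjacency)
        b = betweenness_values(graph.adjacency, dist)
        mean_b = b.mean()
        acc += b / mean_b if mean_b > 0 else 0.0
    return pd.Series(acc / len(grid), index=corr.columns)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def _analyze_group(matrix: pd.DataFrame, subjects: pd.DataFrame,
                   regions: pd.DataFrame, config: PipelineConfig,
                   seed: int) -> dict[str, Any]:
    residuals, info = regress_out_confounds(matrix, subjects)
    corr = pearson_matrix(residuals)
    grid = config.grid()
    points = evaluate_statistics(corr, regions, grid,
                                 include_attack=config.include_attack,
                                 include_nbc=config.include_nbc,
                                 hub_threshold=config.hub_threshold)
    names = tuple(points.keys())
    boot = bootstrap_statistics(
        matrix,
        lambda c: np.array([v for v in evaluate_statistics(
            c, regions, grid, include_attack=config.include_attack,
            include_nbc=config.include_nbc,
            hub_threshold=config.hub_threshold).values()]),
        n_boot=config.n_boot, seed=seed, names=names, subjects=subjects)
    nbc_mean = mean_nbc_over_grid(corr, grid)
    hubs = [(rid, float(v)) for rid, v in
            nbc_mean.sort_values(ascending=False).items()
            if v > config.hub_threshold]
    summary = {
        "n_subjects": len(subjects),
        "detrend_dropped_columns": list(info.dropped_columns),
        "point_estimates": points,
        "hubs": [{"region_id": r, "nbc": v} for r, v in hubs],
        "top_connected": [
            {"region_id": r, "mean_abs_corr": v}
            for r, v in top_connected_regions(corr, regions,
                                              min(config.top_k, len(regions)))],
        "bootstrap_seed": seed,
        "n_redrawn": boot.n_redrawn,
    }
    return {"summary": summary, "boot": boot, "points": points, "corr": corr}


def _split_groups(config: PipelineConfig):
    """Resolve the two groups from files or from simulation configs."""
    if config.mode == "simulate":
        young_cfg = config.young or young_group_config()
        old_cfg = config.old or old_group_config()
        if list(young_cfg.region_table["region_id"]) != \
                list(old_cfg.region_table["region_id"]):
            raise ConfigError("the two cohorts must share a region table")
        seed_y, seed_o = spawn_seeds(config.seed, 2)
        subj_y, mat_y, _ = generate_cohort(young_cfg, seed=seed_y)
        subj_o, mat_o, _ = generate_cohort(old_cfg, seed=seed_o)
        return (mat_y, subj_y), (mat_o, subj_o), young_cfg.region_table
    matrix, subjects, regions = io.read_myelin_dataset(
        config.matrix_path, config.subjects_path, config.regions_path)
    if config.group_column:
        labels = subjects[config.group_column]
        names = sorted(labels.unique())
        if len(names) != 2:
            raise ConfigError("group column must define exactly 2 groups")
        mask_y = (labels == names[0]).to_numpy()
    else:
        ages = subjects["age"].to_numpy(dtype=float)
        lo_y, hi_y = config.young_age_range
        lo_o, hi_o = config.old_age_range
        mask_y = (ages >= lo_y) & (ages <= hi_y)
        mask_o = (ages >= lo_o) & (ages <= hi_o)
        subjects = subjects[mask_y | mask_o].reset_index(drop=True)
        matrix = matrix.loc[subjects["subject_id"]]
        ages = subjects["age"].to_numpy(dtype=float)
        mask_y = (ages >= lo_y) & (ages <= hi_y)
    subj_y = subjects[mask_y].reset_index(drop=True)
    subj_o = subjects[~mask_y].reset_index(drop=True)
    return ((matrix.loc[subj_y["subject_id"]], subj_y),
            (matrix.loc[subj_o["subject_id"]], subj_o), regions)


def run_group_comparison(config: PipelineConfig) -> dict[str, Any]:
    """The two-group experiment: per-group analysis + BC bootstrap contrasts."""
    config.validate()
    (mat_y, subj_y), (mat_o, subj_o), regions = _split_groups(config)
    seed_a, seed_b = spawn_seeds(None if config.seed is None else config.seed + 1, 2)
    group_a = _analyze_group(mat_y, subj_y, regions, config, seed_a)
    group_b = _analyze_group(mat_o, subj_o, regions, config, seed_b)
    diffs = {}
    for name in group_a["points"]:
        diff = group_difference(group_a["boot"], group_b["boot"],
                                group_a["points"][name], group_b["points"][name],
                                name=name, alpha=config.alpha)
        diffs[name] = diff.to_dict()
    report = {
        "config": config.echo(),
        "sparsity_grid": config.grid().tolist(),
        "n_sparsity_points": len(config.grid()),
        "groups": {"young": group_a["summary"], "old": group_b["summary"]},
        "differences": diffs,
    }
    if config.output_dir:
        out = Path(config.output_dir)
        io.write_report(report, out / "group_comparison.json")
        io.write_symmetric_matrix(group_a["corr"], out / "corr_young.tsv")
        io.write_symmetric_matrix(group_b["corr"], out / "corr_old.tsv")
        io.write_report({"files": ["group_comparison.json", "corr_young.tsv",
                                   "corr_old.tsv"],
                         "seed": config.seed}, out / "manifest.json")
    return report


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def run_trajectory(config: PipelineConfig) -> dict[str, Any]:
    """Sliding-window trajectory experiment with AIC-selected polynomial fits."""
    config.validate()
    if config.mode == "simulate":
        cohort_cfg = config.cohort
        if cohort_cfg is None:
            cohort_cfg = CohortConfig(
                n_subjects=437, age_range=(48.0, 87.0),
                region_table=default_region_table())
        seed, = spawn_seeds(config.seed, 1)
        subjects, matrix, _ = generate_cohort(cohort_cfg, seed=seed)
        regions = cohort_cfg.region_table
    else:
        matrix, subjects, regions = io.read_myelin_dataset(
            config.matrix_path, config.subjects_path, config.regions_path)
    if config.window_size > len(subjects):
        raise DegenerateDataError(
            f"window_size {config.window_size} exceeds cohort size {len(subjects)}")
    windows, medians = build_windows(subjects, config.window_size)
    grid = config.grid()

    wanted = list(config.trajectory_properties)
    nbc_wanted = [f"nbc:{r}" for r in config.nbc_regions]
    values: dict[str, np.ndarray] = {p: np.empty(len(windows))
                                     for p in wanted + nbc_wanted}
    for t, w in enumerate(windows):
        sub = subjects.iloc[w].reset_index(drop=True)
        residuals, _ = regress_out_confounds(matrix.iloc[w], sub)
        corr = pearson_matrix(residuals)
        stats = evaluate_statistics(
            corr, regions, grid, include_attack=False,
            include_nbc=bool(nbc_wanted))
        for p in wanted:
            key = f"{p}_auc" if p in GRAPH_PROPERTIES else p
            values[p][t] = stats[key]
        for p, rid in zip(nbc_wanted, config.nbc_regions):
            values[p][t] = stats[f"nbc_auc:{rid}"]

    series_out: dict[str, Any] = {}
    for prop, vals in values.items():
        series = WindowSeries(property_name=prop, window_ages=medians,
                              values=vals, window_size=config.window_size)
        max_order = min(config.max_poly_order, len(windows) - 2)
        fit = fit_trajectory(series, max_order=max_order)
        series_out[prop] = {
            "window_ages": medians.tolist(),
            "values": vals.tolist(),
            "fit": fit.to_dict(),
        }
    report = {
        "config": config.echo(),
        "n_windows": len(windows),
        "window_size": config.window_size,
        "series": series_out,
    }
    if config.output_dir:
        out = Path(config.output_dir)
        io.write_report(report, out / "trajectory.json")
        for prop, rec in series_out.items():
            frame = pd.DataFrame({"window_age": rec["window_ages"],
                                  "value": rec["values"]})
            io.write_table(frame, out / f"series_{prop.replace(':', '_')}.tsv")
        io.write_report({"files": sorted(["trajectory.json"] + [
            f"series_{p.replace(':', '_')}.tsv" for p in series_out]),
            "seed": config.seed}, out / "manifest.json")
    return report
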