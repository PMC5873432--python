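"""Typed tables, matrices and their plain-text (TSV / JSON) serialization.

The on-disk dialect is deliberately boring: UTF-8, tab-separated, header row,
decimal point, Unix newlines.  Three tables define a dataset:

* subject table  -- ``subject_id``, ``age`` (years), ``sex`` ({F, M});
* region table   -- ``region_id``, ``name``, ``hemisphere`` ({L, R, midline}),
  ``lobe`` (one of :data:`LOBES`), ``homologue_id`` (mirror region or empty);
* myelin matrix  -- M subjects x N regions of mean regional magnetization-
  transfer (MT) values, row index ``subject_id``, columns named by region.

The region-table row order is authoritative everywhere downstream: matrices,
graphs and reports all use it, so node indices are stable across the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import AlignmentError, InvariantError, ParseError

SEXES = ("F", "M")
HEMISPHERES = ("L", "R", "midline")
LOBES = ("frontal", "parietal", "temporal", "occipital", "limbic", "insula",
         "subcortical")

#: downstream numeric coding of sex; the choice is arbitrary and is echoed in
#: every report for reproducibility.
SEX_CODING = {"F": 0, "M": 1}


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_subjects(subjects: pd.DataFrame) -> pd.DataFrame:
    """Validate a subject table (unique ids, finite positive ages, F/M sex)."""
    required = {"subject_id", "age", "sex"}
    missing = required - set(subjects.columns)
    if missing:
        raise InvariantError(f"subject table missing columns: {sorted(missing)}")
    ids = subjects["subject_id"].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise InvariantError(f"duplicate subject_id: {dup.iloc[0]!r}")
    ages = pd.to_numeric(subjects["age"], errors="coerce")
    if not np.isfinite(ages.to_numpy(dtype=float)).all():
        bad = subjects.loc[~np.isfinite(ages.to_numpy(dtype=float)), "subject_id"]
        raise InvariantError(f"non-finite age for subject {bad.iloc[0]!r}")
    if (ages <= 0).any():
        bad = subjects.loc[(ages <= 0).to_numpy(), "subject_id"]
        raise InvariantError(f"non-positive age for subject {bad.iloc[0]!r}")
    bad_sex = ~subjects["sex"].isin(SEXES)
    if bad_sex.any():
        raise InvariantError(
            f"sex must be one of {SEXES}; offending subject "
            f"{subjects.loc[bad_sex, 'subject_id'].iloc[0]!r}")
    out = subjects.copy()
    out["subject_id"] = ids
    out["age"] = ages.astype(float)
    return out.reset_index(drop=True)


def validate_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Validate a region table (unique ids, valid lobes, symmetric homologues)."""
    required = {"region_id", "name", "hemisphere", "lobe", "homologue_id"}
    missing = required - set(regions.columns)
    if missing:
        raise InvariantError(f"region table missing columns: {sorted(missing)}")
    out = regions.copy().reset_index(drop=True)
    out["region_id"] = out["region_id"].astype(str)
    out["homologue_id"] = out["homologue_id"].fillna("").astype(str)
    ids = out["region_id"]
    dup = ids[ids.duplicated()]
    if len(dup):
        raise InvariantError(f"duplicate region_id: {dup.iloc[0]!r}")
    if (~out["hemisphere"].isin(HEMISPHERES)).any():
        raise InvariantError(f"hemisphere must be one of {HEMISPHERES}")
    if (~out["lobe"].isin(LOBES)).any():
        bad = out.loc[~out["lobe"].isin(LOBES), "lobe"].iloc[0]
        raise InvariantError(f"unknown lobe {bad!r}; expected one of {LOBES}")
    hemi = dict(zip(out["region_id"], out["hemisphere"]))
    homol = dict(zip(out["region_id"], out["homologue_id"]))
    for rid, mate in homol.items():
        if not mate:
            continue
        if mate not in homol:
            raise InvariantError(f"homologue_id {mate!r} of {rid!r} is unknown")
        if homol[mate] != rid:
            raise InvariantError(f"homologue relation not symmetric: {rid!r}/{mate!r}")
        if {hemi[rid], hemi[mate]} != {"L", "R"}:
            raise InvariantError(
                f"homologous pair {rid!r}/{mate!r} must span opposite hemispheres")
    return out


def validate_myelin_matrix(matrix: pd.DataFrame, subjects: pd.DataFrame,
                           regions: pd.DataFrame) -> pd.DataFrame:
    """Align a myelin matrix to the subject/region tables (their order wins)."""
    sub_ids = list(subjects["subject_id"])
    reg_ids = list(regions["region_id"])
    row_ids = [str(i) for i in matrix.index]
    col_ids = [str(c) for c in matrix.columns]
    for rid in reg_ids:
        if rid not in col_ids:
            raise AlignmentError(f"region {rid!r} missing from myelin matrix columns")
    for cid in col_ids:
        if cid not in reg_ids:
            raise AlignmentError(f"matrix column {cid!r} not in region table")
    for sid in sub_ids:
        if sid not in row_ids:
            raise AlignmentError(f"subject {sid!r} missing from myelin matrix rows")
    for sid in row_ids:
        if sid not in sub_ids:
            raise AlignmentError(f"matrix row {sid!r} not in subject table")
    aligned = matrix.copy()
    aligned.index = row_ids
    aligned.columns = col_ids
    aligned = aligned.loc[sub_ids, reg_ids]
    values = aligned.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ParseError(
            f"non-numeric/non-finite MT value for subject {sub_ids[i]!r}, "
            f"region {reg_ids[j]!r}")
    if len(sub_ids) < 4:
        raise InvariantError("myelin matrix needs at least 4 subjects")
    aligned = pd.DataFrame(values, index=sub_ids, columns=reg_ids)
    aligned.index.name = "subject_id"
    return aligned


def validate_correlation_matrix(corr: pd.DataFrame, atol: float = 1e-10) -> pd.DataFrame:
    """Check symmetry, zero diagonal and the [-1, 1] range of a Pearson matrix."""
    values = corr.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise InvariantError("correlation matrix must be square")
    if not np.allclose(values, values.T, atol=atol, equal_nan=False):
        i, j = np.argwhere(~np.isclose(values, values.T, atol=atol))[0]
        raise InvariantError(f"matrix not symmetric at ({corr.index[i]}, {corr.columns[j]})")
    if not np.allclose(np.diag(values), 0.0, atol=atol):
        raise InvariantError("correlation matrix diagonal must be exactly zero")
    off = values[~np.eye(len(values), dtype=bool)]
    if len(off) and (np.abs(off) > 1 + 1e-12).any():
        raise InvariantError("off-diagonal correlations must lie in [-1, 1]")
    return corr


# ---------------------------------------------------------------------------
# binary graph container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinaryGraph:
    """Undirected, unweighted graph from thresholding |Cij| at sparsity ``s``.

    ``adjacency`` is a symmetric boolean N x N matrix with a False diagonal;
    ``threshold`` is the retained-magnitude cutoff R_k.
    """

    adjacency: np.ndarray
    sparsity: float
    threshold: float
    region_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise InvariantError("adjacency must be a square matrix")
        if not np.array_equal(adj, adj.T):
            raise InvariantError("adjacency must be symmetric")
        if np.diag(adj).any():
            raise InvariantError("adjacency diagonal must be False (no self-loops)")
        if not 0.0 <= self.sparsity < 1.0:
            raise InvariantError("sparsity must lie in [0, 1)")
        if self.threshold < 0:
            raise InvariantError("threshold R_k must be >= 0")
        object.__setattr__(self, "adjacency", adj)
        if self.region_ids and len(self.region_ids) != adj.shape[0]:
            raise InvariantError("region_ids length must match adjacency size")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> list[tuple[str, str]]:
        ids = self.region_ids or tuple(str(i) for i in range(self.n_nodes))
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return [(ids[i], ids[j]) for i, j in zip(ii, jj)]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_myelin_dataset(matrix_path: str | Path, subjects_path: str | Path,
                        regions_path: str | Path
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and align the (matrix, subjects, regions) triple.

    Rows/columns of the matrix file may appear in any order; they are
    canonicalized to the subject- and region-table order.
    """
    subjects = validate_subjects(read_table(subjects_path))
    regions = validate_regions(read_table(regions_path))
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0)
    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna() if raw[col].dtype == object else coerced.isna()
        if bad.any():
            raise ParseError(
                f"non-numeric MT value for subject {raw.index[bad.argmax()]!r}, "
                f"region {col!r}")
        raw[col] = coerced
    matrix = validate_myelin_matrix(raw, subjects, regions)
    return matrix, subjects, regions


def write_myelin_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = matrix.copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t", lineterminator="\n", float_format="%.12g")


def write_symmetric_matrix(matrix: pd.DataFrame | BinaryGraph,
                           path: str | Path) -> None:
    """Write a correlation matrix or a binary graph's adjacency as TSV.

    The header row and first column carry region ids.  Asymmetric input is an
    invariant violation, not silently symmetrized.
    """
    if isinstance(matrix, BinaryGraph):
        ids = list(matrix.region_ids) or [str(i) for i in range(matrix.n_nodes)]
        frame = pd.DataFrame(matrix.adjacency.astype(int), index=ids, columns=ids)
    else:
        values = matrix.to_numpy(dtype=float)
        if not np.allclose(values, values.T, atol=1e-10):
            raise InvariantError("refusing to write an asymmetric matrix")
        frame = matrix
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame = frame.copy()
    frame.index.name = "region_id"
    frame.to_csv(path, sep="\t", lineterminator="\n", float_format="%.12g")


def read_symmetric_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_edge_list(graph: BinaryGraph, path: str | Path) -> None:
    """Write a binary graph as an undirected edge list, one pair per line."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, b in graph.edge_list():
            fh.write(f"{a}\t{b}\n")


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (Path,)):
        return str(obj)
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise ParseError(f"unserializable report field of type {type(obj).__name__}: {obj!r}")


def write_report(results: dict[str, Any], path: str | Path) -> None:
    """Write a results record as deterministic JSON (sorted keys, fixed floats).

    The record should carry its own config echo and seeds; this writer only
    guarantees that the same record always produces byte-identical files.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    text = json.dumps(results, indent=2, sort_keys=True, default=_json_default,
                      ensure_ascii=False)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text + "\n")


def homologous_pairs(regions: pd.DataFrame) -> list[tuple[int, int]]:
    """Index pairs (i < j) of homologous regions, in region-table order."""
    index = {rid: i for i, rid in enumerate(regions["region_id"])}
    pairs = []
    for rid, mate in zip(regions["region_id"], regions["homologue_id"]):
        if mate and index[rid] < index[mate]:
            pairs.append((index[rid], index[mate]))
    return pairs
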