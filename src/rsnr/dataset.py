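"""Data model and text I/O for multi-condition expression time courses.

The central container is :class:`ExpressionDataset`: a genes x samples
matrix together with a sample table that maps every column to an
experimental condition (a unique combination of experimental factors,
e.g. ``{"cold", "root"}``), a numeric time point and a 1-based replicate
index.  Values are taken as given (log scale is typical for microarray
data); nothing in this module rescales them.

File formats are plain tab-separated text:

* expression matrix — header row of sample ids, first column ``gene_id``;
* sample metadata — columns ``sample_id``, ``condition_id``, ``factors``
  (semicolon-separated labels), ``time_point`` (numeric), ``replicate``
  (integer, 1-based).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

__all__ = [
    "SampleKey",
    "ExperimentalCondition",
    "ExpressionDataset",
    "read_dataset",
    "write_dataset",
    "fold_change_filter",
    "quantile_normalize",
    "write_ranking",
    "read_ranking",
    "write_cv_result",
    "read_cv_result",
]

METADATA_COLUMNS = ("sample_id", "condition_id", "factors", "time_point", "replicate")


@dataclass(frozen=True)
class SampleKey:
    """Address of one expression-matrix column."""

    condition_id: str
    time_point: float
    replicate: int


@dataclass(frozen=True)
class ExperimentalCondition:
    """One experimental condition: a unique combination of factors
    measured over an ordered time grid with (possibly ragged) replication."""

    condition_id: str
    factors: frozenset
    time_points: tuple
    replicates_per_timepoint: tuple

    def __post_init__(self) -> None:
        if not self.factors:
            raise ConsistencyError(
                f"condition {self.condition_id!r} has an empty factor set"
            )
        tps = self.time_points
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ConsistencyError(
                f"condition {self.condition_id!r}: time points must be strictly increasing"
            )
        if len(self.replicates_per_timepoint) != len(tps):
            raise ConsistencyError(
                f"condition {self.condition_id!r}: replicate counts do not match time points"
            )
        if any(r < 0 for r in self.replicates_per_timepoint):
            raise ConsistencyError(
                f"condition {self.condition_id!r}: negative replicate count"
            )

    @property
    def n_timepoints(self) -> int:
        return len(self.time_points)

    def shares_factor(self, other: "ExperimentalCondition") -> bool:
        return bool(self.factors & other.factors)


class ExpressionDataset:
    """Expression values indexed by gene, condition, time point and replicate.

    Parameters
    ----------
    values:
        DataFrame, genes x samples; index holds gene ids, columns sample ids.
    samples:
        DataFrame indexed by sample id with columns ``condition_id``,
        ``factors`` (set of str), ``time_point`` (float), ``replicate`` (int).
    provenance:
        Free-text label describing where the data came from.
    """

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame, provenance: str = ""):
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if values.shape[1] < 1:
            raise ConsistencyError("dataset must have at least one sample")
        if samples.index.has_duplicates:
            dup = samples.index[samples.index.duplicated()][0]
            raise ConsistencyError(f"duplicate sample id {dup!r} in metadata")
        missing = set(values.columns) - set(samples.index)
        if missing:
            raise ConsistencyError(
                f"expression columns without metadata: {sorted(missing)[:5]}"
            )
        extra = set(samples.index) - set(values.columns)
        if extra:
            raise ConsistencyError(
                f"metadata rows without expression column: {sorted(extra)[:5]}"
            )
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric cells")
        if np.isnan(arr.astype(float)).any():
            raise FormatError("expression matrix contains missing cells")

        self.values = values.astype(float)
        self.samples = samples.loc[list(values.columns)].copy()
        self.samples["factors"] = self.samples["factors"].map(
            lambda f: _parse_factors(f) if isinstance(f, str) else frozenset(f))
        self.samples["time_point"] = self.samples["time_point"].astype(float)
        self.samples["replicate"] = self.samples["replicate"].astype(int)
        self.provenance = provenance

        self._array = self.values.to_numpy(dtype=float)
        self._col_pos = {s: i for i, s in enumerate(self.values.columns)}
        self._gene_pos = {g: i for i, g in enumerate(self.values.index)}
        self._conditions = self._derive_conditions()

    # -- derived metadata ------------------------------------------------

    def _derive_conditions(self) -> dict:
        conds: dict[str, ExperimentalCondition] = {}
        seen_keys: set[tuple] = set()
        for cid, grp in self.samples.groupby("condition_id", sort=True):
            fsets = set(grp["factors"])
            if len(fsets) != 1:
                raise ConsistencyError(
                    f"condition {cid!r} has inconsistent factor annotations"
                )
            for _, row in grp.iterrows():
                key = (cid, row["time_point"], row["replicate"])
                if key in seen_keys:
                    raise ConsistencyError(
                        f"duplicate sample address {key} in metadata"
                    )
                seen_keys.add(key)
            tps = tuple(sorted(grp["time_point"].unique()))
            reps = tuple(
                int((grp["time_point"] == t).sum()) for t in tps
            )
            conds[str(cid)] = ExperimentalCondition(
                condition_id=str(cid),
                factors=next(iter(fsets)),
                time_points=tps,
                replicates_per_timepoint=reps,
            )
        return conds

    # -- basic accessors -------------------------------------------------

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def conditions(self) -> dict:
        """Mapping condition_id -> :class:`ExperimentalCondition`."""
        return self._conditions

    @property
    def n_conditions(self) -> int:
        return len(self._conditions)

    @property
    def array(self) -> np.ndarray:
        """Genes x samples float array backing the dataset (do not mutate)."""
        return self._array

    def gene_positions(self, gene_ids: Iterable) -> np.ndarray:
        return np.array([self._gene_pos[g] for g in gene_ids], dtype=int)

    def col_positions(self, sample_ids: Iterable) -> np.ndarray:
        return np.array([self._col_pos[s] for s in sample_ids], dtype=int)

    def sample_key(self, sample_id: str) -> SampleKey:
        row = self.samples.loc[sample_id]
        return SampleKey(str(row["condition_id"]), float(row["time_point"]), int(row["replicate"]))

    def samples_of(self, condition_id: str, time_point: float | None = None,
                   within: Sequence | None = None) -> list:
        """Sample ids of one condition (optionally one time point), ordered by
        (time_point, replicate).  ``within`` restricts to a sample subset,
        e.g. a cross-validation training mask."""
        tab = self.samples
        mask = tab["condition_id"] == condition_id
        if time_point is not None:
            mask &= tab["time_point"] == float(time_point)
        if within is not None:
            mask &= tab.index.isin(set(within))
        sub = tab[mask].sort_values(["time_point", "replicate"])
        return list(sub.index)

    def matrix(self, sample_ids: Sequence) -> np.ndarray:
        """Genes x len(sample_ids) view of the expression values."""
        return self._array[:, self.col_positions(sample_ids)]

    # -- subsetting ------------------------------------------------------

    def subset_genes(self, gene_ids: Sequence) -> "ExpressionDataset":
        return ExpressionDataset(self.values.loc[list(gene_ids)], self.samples,
                                 provenance=self.provenance)

    def subset_samples(self, sample_ids: Sequence) -> "ExpressionDataset":
        ids = list(sample_ids)
        return ExpressionDataset(self.values[ids], self.samples.loc[ids],
                                 provenance=self.provenance)

    def with_values(self, new_array: np.ndarray, provenance: str | None = None) -> "ExpressionDataset":
        vals = pd.DataFrame(new_array, index=self.values.index, columns=self.values.columns)
        return ExpressionDataset(vals, self.samples,
                                 provenance=self.provenance if provenance is None else provenance)

    def equals(self, other: "ExpressionDataset") -> bool:
        return (
            self.genes == other.genes
            and self.sample_ids == other.sample_ids
            and np.array_equal(self._array, other._array)
            and all(
                self.sample_key(s) == other.sample_key(s)
                and self.samples.loc[s, "factors"] == other.samples.loc[s, "factors"]
                for s in self.sample_ids
            )
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<ExpressionDataset {self.n_genes} genes x {self.n_samples} samples, "
                f"{self.n_conditions} conditions ({self.provenance or 'unlabeled'})>")


# -- I/O -----------------------------------------------------------------


def _parse_factors(text: str) -> frozenset:
    labels = [f.strip() for f in str(text).split(";") if f.strip()]
    if not labels:
        raise FormatError(f"empty factor list: {text!r}")
    return frozenset(labels)


def read_dataset(expression_path, metadata_path, provenance: str | None = None) -> ExpressionDataset:
    """Load an expression matrix and its sample metadata from TSV files.

    Raises :class:`FormatError` for malformed files (duplicate gene ids,
    non-numeric or missing cells) and :class:`ConsistencyError` when the
    matrix columns and the metadata rows do not match one-to-one.
    """
    expr = pd.read_csv(expression_path, sep="\t", dtype={0: str},
                       float_precision="round_trip")
    if expr.columns[0] != "gene_id":
        raise FormatError(
            f"first column of {expression_path} must be 'gene_id', got {expr.columns[0]!r}"
        )
    expr = expr.set_index("gene_id")
    if expr.shape[0] < 1:
        raise FormatError(f"{expression_path} contains no genes")
    if expr.index.has_duplicates:
        dup = expr.index[expr.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r} in {expression_path}")
    for col in expr.columns:
        if not np.issubdtype(expr[col].dtype, np.number):
            raise FormatError(f"non-numeric cell in column {col!r} of {expression_path}")

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str, "condition_id": str})
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise FormatError(f"metadata {metadata_path} lacks columns {sorted(missing_cols)}")
    meta = meta.set_index("sample_id")
    meta["factors"] = meta["factors"].map(_parse_factors)

    if provenance is None:
        provenance = str(Path(expression_path).name)
    return ExpressionDataset(expr, meta, provenance=provenance)


def write_dataset(ds: ExpressionDataset, expression_path, metadata_path) -> None:
    """Write the dataset back to the two-file TSV layout (lossless round trip)."""
    out = ds.values.copy()
    out.index.name = "gene_id"
    out.to_csv(expression_path, sep="\t")
    meta = ds.samples.copy()
    meta["factors"] = meta["factors"].map(lambda fs: ";".join(sorted(fs)))
    meta.index.name = "sample_id"
    meta = meta[["condition_id", "factors", "time_point", "replicate"]]
    meta.to_csv(metadata_path, sep="\t")


# -- preprocessing filters ------------------------------------------------


def fold_change_filter(ds: ExpressionDataset, min_fold: float, log_scale: bool = False) -> ExpressionDataset:
    """Keep genes whose dynamic range over *all* samples reaches ``min_fold``.

    On a linear scale a gene is kept iff max/min >= min_fold (all values must
    be positive); with ``log_scale`` the criterion is max - min >= log2(min_fold),
    appropriate for log2-transformed values.  Gene order is preserved.
    """
    if not min_fold > 1:
        raise ValueError("min_fold must be > 1")
    arr = ds.array
    hi = arr.max(axis=1)
    lo = arr.min(axis=1)
    if log_scale:
        keep = (hi - lo) >= np.log2(min_fold)
    else:
        if (lo <= 0).any():
            raise ConsistencyError(
                "fold_change_filter on a linear scale requires strictly positive "
                "values; use log_scale=True for log-transformed data"
            )
        keep = hi / lo >= min_fold
    kept = [g for g, k in zip(ds.genes, keep) if k]
    if not kept:
        warnings.warn(f"fold_change_filter(min_fold={min_fold}) removed every gene")
    if len(kept) < ds.n_genes:
        return ds.subset_genes(kept)
    return ds


def quantile_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Force every sample column onto the mean order-statistic distribution.

    Ties within a column receive the mean of the reference values their
    rank span covers (the convention of limma's ``normalizeQuantiles``).
    """
    if ds.n_samples < 2:
        raise ConsistencyError("quantile normalization needs at least 2 samples")
    arr = ds.array
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        s = col[order]
        # average the reference values over runs of tied input values
        boundaries = np.flatnonzero(np.diff(s) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(s)]))
        for a, b in zip(starts, ends):
            if b - a > 1:
                assigned[order[a:b]] = ref[a:b].mean()
        out[:, j] = assigned
    return ds.with_values(out)


# -- rankings / CV tables --------------------------------------------------

RANKING_COLUMNS = ("condition_id", "rank", "gene_id", "score", "method")
CV_COLUMNS = ("repetition", "fold", "test_condition", "predicted_condition",
              "correct", "n_genes", "method")


def write_ranking(ranking, path) -> None:
    """Write one or several gene rankings as TSV (see RANKING_COLUMNS)."""
    rankings = ranking if isinstance(ranking, (list, tuple)) else [ranking]
    rows = []
    for r in rankings:
        for i, (g, s) in enumerate(zip(r.genes, r.scores), start=1):
            rows.append((r.condition_id, i, g, float(s), r.method))
    frame = pd.DataFrame(rows, columns=list(RANKING_COLUMNS))
    frame.to_csv(path, sep="\t", index=False)


def read_ranking(path):
    """Read rankings written by :func:`write_ranking`; returns a list of
    GeneRanking, one per (condition_id, method) block."""
    from .selection import GeneRanking

    frame = pd.read_csv(path, sep="\t")
    out = []
    for (cid, method), grp in frame.groupby(["condition_id", "method"], sort=False):
        grp = grp.sort_values("rank")
        out.append(GeneRanking(condition_id=str(cid), method=str(method),
                               genes=[str(g) for g in grp["gene_id"]],
                               scores=grp["score"].to_numpy(dtype=float)))
    return out


def write_cv_result(res, path) -> None:
    """Write per-fold cross-validation records as TSV (see CV_COLUMNS)."""
    frame = res.records[list(CV_COLUMNS)] if hasattr(res, "records") else res[list(CV_COLUMNS)]
    frame.to_csv(path, sep="\t", index=False)


def read_cv_result(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(CV_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"CV table {path} lacks columns {sorted(missing)}")
    return frame
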