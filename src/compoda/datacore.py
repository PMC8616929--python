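"""Count-matrix ingestion, validation, pseudocounting and covariate encoding.

The central container is :class:`CompositionalDataset`: an N x K matrix of
cell-type counts per sample, sample metadata, and an encoded N x M covariate
design matrix.  Counts are stored as floats because zero entries are replaced
by a 0.5 pseudocount before model fitting; integrality is enforced only when
reading raw tables from disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class DatasetError(ValueError):
    """Base class for dataset construction problems."""


class IdentityError(DatasetError):
    """Missing or duplicated sample / cell-type identifiers."""


class CountValidationError(DatasetError):
    """Non-numeric, negative or otherwise invalid count values."""


class AlignmentError(DatasetError):
    """Sample sets of counts and metadata do not match."""


@dataclass
class CompositionalDataset:
    """Samples x cell-types count table with covariates.

    Parameters
    ----------
    counts
        N x K nonnegative matrix (raw counts, possibly pseudocounted).
    sample_ids
        N unique sample labels.
    cell_types
        K unique cell-type labels.
    metadata
        Per-sample metadata table (indexed by sample id); columns are encoded
        into the design matrix on demand via :func:`encode_covariate`.
    covariates
        N x M design matrix X (starts empty, M = 0).
    covariate_names
        M labels for the columns of ``covariates``.
    """

    counts: np.ndarray
    sample_ids: list
    cell_types: list
    metadata: pd.DataFrame | None = None
    covariates: np.ndarray = None
    covariate_names: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise CountValidationError("counts must be a 2-D matrix")
        n, k = self.counts.shape
        if k < 2:
            raise CountValidationError(f"need at least 2 cell types, got {k}")
        if not np.all(np.isfinite(self.counts)):
            raise CountValidationError("counts contain non-finite values")
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise CountValidationError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"cell type {self.cell_types[bad[1]]!r}"
            )
        self.sample_ids = list(self.sample_ids)
        self.cell_types = list(self.cell_types)
        if len(self.sample_ids) != n:
            raise IdentityError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.cell_types) != k:
            raise IdentityError(f"{len(self.cell_types)} cell-type names for {k} columns")
        for name, labels in (("sample_ids", self.sample_ids), ("cell_types", self.cell_types)):
            dupes = pd.Index(labels)[pd.Index(labels).duplicated()].unique().tolist()
            if dupes:
                raise IdentityError(f"duplicated {name}: {dupes}")
        if self.covariates is None:
            self.covariates = np.empty((n, 0), dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.shape[0] != n:
            raise AlignmentError(
                f"covariates have {self.covariates.shape[0]} rows for {n} samples"
            )
        if self.covariates.shape[1] != len(self.covariate_names):
            raise AlignmentError("covariate_names length does not match design matrix")
        if self.metadata is not None:
            missing = [s for s in self.sample_ids if s not in self.metadata.index]
            extra = [s for s in self.metadata.index if s not in self.sample_ids]
            if missing or extra:
                raise AlignmentError(
                    f"metadata/count sample mismatch; missing from metadata: {missing}; "
                    f"extra in metadata: {extra}"
                )
            self.metadata = self.metadata.loc[self.sample_ids]

    # -- derived quantities -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cell_types(self) -> int:
        return self.counts.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    @property
    def totals(self) -> np.ndarray:
        """Per-sample total cell count (row sums), recomputed on access."""
        return self.counts.sum(axis=1)

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.totals[:, None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.cell_types)


def read_counts(counts_path, metadata_path=None, dialect: str | None = None) -> CompositionalDataset:
    """Read a delimited count table (and optional metadata table) from disk.

    The count table must have a header row of cell-type names and a first
    column of sample ids.  The metadata table keys on the same sample ids.
    ``dialect`` is the field delimiter; when ``None`` it is inferred from the
    file extension (``.csv`` -> comma, anything else -> tab).
    """
    sep = dialect if dialect is not None else ("," if str(counts_path).endswith(".csv") else "\t")
    raw = pd.read_csv(counts_path, sep=sep, index_col=0)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise IdentityError(f"duplicated sample ids in {counts_path}: {dupes}")
    try:
        counts = raw.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise CountValidationError(f"non-numeric counts in {counts_path}: {exc}") from None
    if np.any(~np.isfinite(counts)) or np.any(counts < 0):
        raise CountValidationError(f"negative or non-finite counts in {counts_path}")
    if np.any(counts != np.round(counts)):
        raise CountValidationError(f"non-integer counts in {counts_path}")
    metadata = None
    if metadata_path is not None:
        msep = dialect if dialect is not None else ("," if str(metadata_path).endswith(".csv") else "\t")
        metadata = pd.read_csv(metadata_path, sep=msep, index_col=0)
        if metadata.index.has_duplicates:
            dupes = metadata.index[metadata.index.duplicated()].unique().tolist()
            raise IdentityError(f"duplicated sample ids in {metadata_path}: {dupes}")
    return CompositionalDataset(
        counts=counts,
        sample_ids=raw.index.tolist(),
        cell_types=raw.columns.tolist(),
        metadata=metadata,
    )


def write_counts(ds: CompositionalDataset, counts_path, dialect: str = "\t") -> None:
    """Write the count table back to a delimited file (inverse of read_counts)."""
    frame = ds.to_frame()
    if np.all(frame.to_numpy() == np.round(frame.to_numpy())):
        frame = frame.astype(int)
    frame.to_csv(counts_path, sep=dialect)


def from_anndata(adata, sample_key: str, cell_type_key: str) -> CompositionalDataset:
    """Aggregate cell-level annotations to a sample x cell-type count table.

    ``sample_key`` and ``cell_type_key`` name two columns of ``adata.obs``;
    aggregation is a plain group-and-count of cells.
    """
    obs = adata.obs[[sample_key, cell_type_key]]
    table = pd.crosstab(obs[sample_key], obs[cell_type_key])
    return CompositionalDataset(
        counts=table.to_numpy(dtype=float),
        sample_ids=table.index.tolist(),
        cell_types=table.columns.tolist(),
        metadata=None,
    )


def apply_zero_pseudocount(ds: CompositionalDataset, pseudocount: float = 0.5) -> CompositionalDataset:
    """Replace every zero count with ``pseudocount`` (default 0.5).

    Nonzero entries are untouched, so the operation is idempotent.  The model
    likelihood requires strictly positive counts; this is the standard fix for
    cell types absent from some samples.
    """
    counts = ds.counts.copy()
    counts[counts == 0] = pseudocount
    return replace(ds, counts=counts)


def encode_covariate(ds: CompositionalDataset, column: str, case_level=None) -> CompositionalDataset:
    """Append a metadata column to the design matrix X.

    Binary categorical columns are encoded 0 (control) / 1 (``case_level``);
    numeric columns pass through unchanged.  Columns with more than two levels
    are rejected: compare conditions pairwise by subsetting samples first.
    """
    if ds.metadata is None or column not in ds.metadata.columns:
        raise KeyError(f"metadata column {column!r} not found")
    values = ds.metadata[column]
    if pd.api.types.is_numeric_dtype(values):
        encoded = values.to_numpy(dtype=float)
    else:
        levels = pd.unique(values)
        if len(levels) != 2:
            raise DatasetError(
                f"column {column!r} has {len(levels)} levels {list(levels)}; "
                "a binary covariate is required - subset the samples to one "
                "pairwise comparison at a time"
            )
        if case_level is None or case_level not in set(levels):
            raise DatasetError(
                f"case_level must be one of {list(levels)}, got {case_level!r}"
            )
        encoded = (values == case_level).to_numpy(dtype=float)
    covariates = np.column_stack([ds.covariates, encoded]) if ds.n_covariates else encoded[:, None]
    return replace(ds, covariates=covariates, covariate_names=ds.covariate_names + [column])
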