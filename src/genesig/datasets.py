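"""Expression matrices with per-sample annotations.

The in-memory container is :class:`ExpressionDataset`: a genes x samples
matrix of normalised log-scale intensities (e.g. RMA log2), plus a pandas
annotation table indexed by sample id carrying the binary outcome (distant
metastasis within five years) and an optional stratification label such as
estrogen-receptor status.

On disk the matrix is a tab-delimited table, genes as rows, first column the
gene identifier, header row the sample ids -- the layout of a GEO
series-matrix table after its ``!`` comment lines are stripped (the reader
skips them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OUTCOME_COL = "outcome"
STRATA_COL = "strata"


class ExpressionIOError(ValueError):
    """Raised for malformed expression or annotation inputs."""


@dataclass
class ExpressionDataset:
    """Genes x samples intensity matrix with sample annotations.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers (probe or gene ids).
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray, shape (n_genes, n_samples)
        Normalised log-scale intensities; no missing values.
    annotations : pandas.DataFrame
        Indexed by sample id, aligned with ``sample_ids``; must contain an
        ``outcome`` column in {0, 1} and may contain a ``strata`` column.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    annotations: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ExpressionIOError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ExpressionIOError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ExpressionIOError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ExpressionIOError("matrix contains missing or non-finite values")
        if OUTCOME_COL not in self.annotations.columns:
            raise ExpressionIOError(f"annotations lack an '{OUTCOME_COL}' column")
        self.annotations = self.annotations.loc[self.sample_ids]
        out = self.annotations[OUTCOME_COL]
        if not out.isin([0, 1]).all():
            raise ExpressionIOError("every sample outcome must be 0 or 1")
        self.annotations[OUTCOME_COL] = out.astype(int)

    # -- basic accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def outcome(self) -> np.ndarray:
        """Binary outcome per sample, aligned with ``sample_ids``."""
        return self.annotations[OUTCOME_COL].to_numpy()

    @property
    def strata(self) -> np.ndarray | None:
        """Stratification label per sample, or None when absent."""
        if STRATA_COL in self.annotations.columns:
            return self.annotations[STRATA_COL].to_numpy()
        return None

    def gene_index(self, gene_ids: list[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"unknown gene ids: {missing}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        """Matrix as a DataFrame (genes as rows, samples as columns)."""
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(
        cls, matrix: pd.DataFrame, annotations: pd.DataFrame
    ) -> "ExpressionDataset":
        """Build a dataset from a genes-x-samples DataFrame plus annotations."""
        return cls(
            gene_ids=list(matrix.index.astype(str)),
            sample_ids=list(matrix.columns.astype(str)),
            values=matrix.to_numpy(dtype=float),
            annotations=annotations.copy(),
        )

    # -- operations ------------------------------------------------------

    def subset(
        self, gene_ids: list[str] | None = None, sample_ids: list[str] | None = None
    ) -> "ExpressionDataset":
        """Restrict to the requested genes/samples, in the requested order."""
        gene_ids = list(self.gene_ids) if gene_ids is None else list(gene_ids)
        sample_ids = list(self.sample_ids) if sample_ids is None else list(sample_ids)
        gi = self.gene_index(gene_ids)
        slookup = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in slookup]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        sj = np.array([slookup[s] for s in sample_ids], dtype=int)
        return ExpressionDataset(
            gene_ids=gene_ids,
            sample_ids=sample_ids,
            values=self.values[np.ix_(gi, sj)],
            annotations=self.annotations.iloc[sj].copy(),
        )

    def zscore_by_gene(self) -> "ExpressionDataset":
        """Standardise every gene row to mean 0, sample sd 1 (ddof=1).

        Used to renormalise each dataset independently before cross-study
        validation, removing per-gene location/scale batch differences.
        Raises on zero-variance genes rather than dividing by zero.
        """
        mean = self.values.mean(axis=1, keepdims=True)
        sd = self.values.std(axis=1, ddof=1, keepdims=True)
        zero = np.flatnonzero(sd.ravel() == 0)
        if zero.size:
            names = [self.gene_ids[i] for i in zero[:5]]
            raise ExpressionIOError(f"zero-variance genes cannot be Z-scored: {names}")
        return ExpressionDataset(
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            values=(self.values - mean) / sd,
            annotations=self.annotations.copy(),
        )


def subset(
    ds: ExpressionDataset,
    gene_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> ExpressionDataset:
    return ds.subset(gene_ids, sample_ids)


def zscore_by_gene(ds: ExpressionDataset) -> ExpressionDataset:
    return ds.zscore_by_gene()


def _read_table(path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, comment="!", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_expression(
    matrix_path,
    annotation_path,
    sep: str = "\t",
    outcome_col: str = OUTCOME_COL,
    strata_col: str | None = STRATA_COL,
) -> ExpressionDataset:
    """Read a tab-delimited expression matrix and annotation table.

    The matrix has gene ids in the first column and sample ids in the header;
    lines beginning ``!`` (series-matrix metadata) are ignored.  The
    annotation table has sample ids in its first column, an outcome column
    (0/1), and optionally a strata column.  Samples are the intersection of
    both files in matrix column order; annotated samples missing an outcome
    are dropped with a warning.
    """
    raw = _read_table(matrix_path, sep)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][:5].tolist()
        raise ExpressionIOError(f"duplicate gene ids in matrix: {dup}")
    if pd.Index(raw.columns).duplicated().any():
        raise ExpressionIOError("duplicate sample ids in matrix header")
    try:
        values = raw.to_numpy(dtype=float)
    except ValueError as exc:
        raise ExpressionIOError(f"non-numeric cell in expression matrix: {exc}") from exc
    if not np.all(np.isfinite(values)):
        raise ExpressionIOError("expression matrix contains missing values")

    ann = pd.read_csv(annotation_path, sep=sep, index_col=0)
    ann.index = ann.index.astype(str)
    if ann.index.duplicated().any():
        raise ExpressionIOError("duplicate sample ids in annotation table")
    if outcome_col not in ann.columns:
        raise ExpressionIOError(f"annotation table lacks column '{outcome_col}'")

    with_outcome = ann[ann[outcome_col].notna()]
    dropped = len(ann) - len(with_outcome)
    if dropped:
        logger.warning("dropped %d annotated samples lacking an outcome", dropped)
    keep = [s for s in raw.columns if s in set(with_outcome.index)]
    n_unannotated = raw.shape[1] - len(keep)
    if n_unannotated:
        logger.warning("dropped %d matrix samples without annotation", n_unannotated)
    if not keep:
        raise ExpressionIOError("no samples shared between matrix and annotations")

    ann = with_outcome.loc[keep].copy()
    ann = ann.rename(columns={outcome_col: OUTCOME_COL})
    if strata_col and strata_col in ann.columns and strata_col != STRATA_COL:
        ann = ann.rename(columns={strata_col: STRATA_COL})
    cols = [raw.columns.get_loc(s) for s in keep]
    return ExpressionDataset(
        gene_ids=list(raw.index),
        sample_ids=keep,
        values=values[:, cols],
        annotations=ann,
    )


def write_expression(
    ds: ExpressionDataset, matrix_path, annotation_path, sep: str = "\t"
) -> None:
    """Write the dataset in the same tab-delimited dialect the reader accepts."""
    frame = ds.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(matrix_path, sep=sep)
    ann = ds.annotations.copy()
    ann.index.name = "sample_id"
    ann.to_csv(annotation_path, sep=sep)
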