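"""Expression containers, readers and paired-sample alignment.

The pipeline operates on paired genome-wide expression profiles of two
compartments of the same tissue specimen (e.g. adjacent-normal and tumour
epithelium from the same patients).  Matrices are genes x samples on a log
scale; missing values are rejected rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_DIALECT_SEP = {"tsv": "\t", "csv": ","}


class ExpressionParseError(ValueError):
    """Malformed expression input (location is reported where known)."""


class DegenerateInputError(ValueError):
    """Input too small or empty after validation/filtering."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of (log-scale) expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ExpressionParseError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def write(self, path: str | Path, dialect: str = "tsv") -> None:
        # %.17g keeps the full float64 precision through a round trip
        self.to_frame().to_csv(
            path, sep=_DIALECT_SEP[dialect], index_label="gene", float_format="%.17g"
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, cols])


@dataclass
class PairedExpressionDataset:
    """Two expression matrices over the same ordered patients."""

    normal: ExpressionMatrix
    tumour: ExpressionMatrix
    pairing: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.normal.gene_ids != self.tumour.gene_ids:
            raise ValueError("normal and tumour must share an identical gene list")
        if not self.pairing:
            self.pairing = list(self.normal.sample_ids)
        if len(self.pairing) != self.normal.n_samples or len(self.pairing) != self.tumour.n_samples:
            raise ValueError("pairing length must equal the sample count of both matrices")
        if self.n_pairs < 3:
            raise DegenerateInputError(f"need >= 3 sample pairs, got {self.n_pairs}")

    @property
    def gene_ids(self) -> list[str]:
        return self.normal.gene_ids

    @property
    def n_genes(self) -> int:
        return self.normal.n_genes

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)


def read_expression_matrix(
    path: str | Path,
    dialect: str = "tsv",
    duplicate_policy: str = "max_var",
) -> ExpressionMatrix:
    """Read a genes-in-rows expression table.

    First column holds gene ids, header row holds sample ids.  Duplicate
    gene ids are collapsed: ``max_var`` keeps the most variable row,
    ``mean`` averages the rows.  Non-numeric cells raise
    :class:`ExpressionParseError` naming the offending cell.
    """
    if dialect not in _DIALECT_SEP:
        raise ValueError(f"dialect must be one of {sorted(_DIALECT_SEP)}")
    sep = _DIALECT_SEP[dialect]
    # pandas mangles duplicate header names, so check the raw header first
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split(sep)
    samples = header[1:]
    if not samples:
        raise ExpressionParseError(f"{path}: no sample columns found")
    if len(set(samples)) != len(samples):
        dup = next(s for i, s in enumerate(samples) if s in samples[:i])
        raise ExpressionParseError(f"{path}: duplicate sample id {dup!r}")
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)

    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ExpressionParseError(
            f"{path}: non-numeric cell at gene {frame.index[i]!r}, "
            f"sample {frame.columns[j]!r}: {frame.iat[i, j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ExpressionParseError(
            f"{path}: missing value at gene {frame.index[i]!r}, "
            f"sample {frame.columns[j]!r}"
        )
    # to_numeric is only the validator; astype gives correctly rounded floats
    numeric = frame.astype(float)

    if numeric.index.duplicated().any():
        if duplicate_policy == "max_var":
            variances = numeric.var(axis=1, ddof=1)
            order = np.argsort(-variances.to_numpy(), kind="stable")
            numeric = numeric.iloc[order]
            keep = ~numeric.index.duplicated(keep="first")
            dropped = int((~keep).sum())
            numeric = numeric[keep]
            # restore the original first-occurrence gene order
            first = {g: k for k, g in enumerate(frame.index) if g not in frame.index[:k]}
            numeric = numeric.loc[sorted(numeric.index, key=first.__getitem__)]
        elif duplicate_policy == "mean":
            before = numeric.index.size
            numeric = numeric.groupby(level=0, sort=False).mean()
            dropped = before - numeric.index.size
        else:
            raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")
        logger.info("collapsed %d duplicate gene rows (%s)", dropped, duplicate_policy)

    return ExpressionMatrix.from_frame(numeric)


def read_pairing_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping sample_id -> patient_id."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise ExpressionParseError(f"{path}: pairing map needs two columns")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def align_paired_samples(
    normal: ExpressionMatrix,
    tumour: ExpressionMatrix,
    pairing: Mapping[str, str],
) -> PairedExpressionDataset:
    """Intersect genes and align columns of both matrices on shared patients.

    ``pairing`` maps sample ids (of either matrix) to patient ids.  Samples
    with no patient present in both matrices are dropped (and logged).  The
    result is ordered by sorted patient id so that it is invariant to the
    input column order.
    """
    genes = sorted(set(normal.gene_ids) & set(tumour.gene_ids))
    if not genes:
        raise DegenerateInputError("no shared genes between the two matrices")

    def patients_of(matrix: ExpressionMatrix) -> dict[str, str]:
        out: dict[str, str] = {}
        for sample in matrix.sample_ids:
            patient = pairing.get(sample)
            if patient is None:
                logger.info("sample %r has no pairing entry; dropped", sample)
                continue
            if patient in out:
                raise ValueError(f"patient {patient!r} mapped to multiple samples")
            out[patient] = sample
        return out

    normal_by_patient = patients_of(normal)
    tumour_by_patient = patients_of(tumour)
    shared = sorted(set(normal_by_patient) & set(tumour_by_patient))
    dropped = (set(normal_by_patient) | set(tumour_by_patient)) - set(shared)
    if dropped:
        logger.info("dropped %d unpaired patients: %s", len(dropped), sorted(dropped))
    if len(shared) < 3:
        raise DegenerateInputError(f"only {len(shared)} surviving pairs (< 3)")

    normal_aligned = normal.subset_genes(genes).subset_samples(
        [normal_by_patient[p] for p in shared]
    )
    tumour_aligned = tumour.subset_genes(genes).subset_samples(
        [tumour_by_patient[p] for p in shared]
    )
    # relabel columns by patient so both matrices carry the common order
    normal_aligned = ExpressionMatrix(genes, list(shared), normal_aligned.values)
    tumour_aligned = ExpressionMatrix(genes, list(shared), tumour_aligned.values)
    return PairedExpressionDataset(normal_aligned, tumour_aligned, list(shared))


@dataclass
class FilterReport:
    """Resolved absolute thresholds and removal counts of a gene filter."""

    min_expr_quantile: float
    min_var_quantile: float
    mean_thresholds: dict[str, float]
    var_thresholds: dict[str, float]
    n_before: int
    n_after: int

    @property
    def n_removed(self) -> int:
        return self.n_before - self.n_after


def _passes(matrix: ExpressionMatrix, mean_thr: float, var_thr: float) -> np.ndarray:
    means = matrix.values.mean(axis=1)
    variances = matrix.values.var(axis=1, ddof=1)
    return (means >= mean_thr) & (variances >= var_thr)


def filter_genes_abs(
    ds: PairedExpressionDataset,
    mean_thresholds: Mapping[str, float],
    var_thresholds: Mapping[str, float],
) -> PairedExpressionDataset:
    """Keep genes passing the absolute mean/variance thresholds in >= 1 tissue."""
    keep = _passes(ds.normal, mean_thresholds["normal"], var_thresholds["normal"]) | _passes(
        ds.tumour, mean_thresholds["tumour"], var_thresholds["tumour"]
    )
    if not keep.any():
        raise DegenerateInputError("gene filter removed every gene")
    genes = [g for g, k in zip(ds.gene_ids, keep) if k]
    return PairedExpressionDataset(
        ds.normal.subset_genes(genes), ds.tumour.subset_genes(genes), list(ds.pairing)
    )


def filter_genes(
    ds: PairedExpressionDataset,
    min_expr_quantile: float = 0.0,
    min_var_quantile: float = 0.0,
) -> tuple[PairedExpressionDataset, FilterReport]:
    """Remove low-expressed, low-variance genes.

    The quantiles are resolved per tissue to absolute thresholds on the
    per-gene mean and variance; a gene is kept iff it passes both
    thresholds in at least one tissue.  Re-applying the *resolved*
    thresholds (via :func:`filter_genes_abs`) is a no-op.
    """
    for q in (min_expr_quantile, min_var_quantile):
        if not 0.0 <= q < 1.0:
            raise ValueError("quantiles must be in [0, 1)")
    mean_thr = {}
    var_thr = {}
    for tissue, matrix in (("normal", ds.normal), ("tumour", ds.tumour)):
        mean_thr[tissue] = float(np.quantile(matrix.values.mean(axis=1), min_expr_quantile))
        var_thr[tissue] = float(np.quantile(matrix.values.var(axis=1, ddof=1), min_var_quantile))
    filtered = filter_genes_abs(ds, mean_thr, var_thr)
    report = FilterReport(
        min_expr_quantile=min_expr_quantile,
        min_var_quantile=min_var_quantile,
        mean_thresholds=mean_thr,
        var_thresholds=var_thr,
        n_before=ds.n_genes,
        n_after=filtered.n_genes,
    )
    logger.info("gene filter removed %d of %d genes", report.n_removed, report.n_before)
    return filtered, report
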