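"""Reading, writing and pre-processing of expression matrices and gene sets.

An expression matrix is a :class:`pandas.DataFrame` with unique gene
identifiers as the index (rows) and unique sample identifiers as columns.
All values are finite and non-negative; the unit depends on the processing
stage (raw counts, RPKM, or normalized intensities).  Because the
downstream statistics only consume within-sample orderings, any strictly
monotone per-sample transform (log2, RPKM with a shared length table, a
global scaling factor) leaves the results unchanged; the transforms here
exist so users can export values on conventional scales.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "validate_expression_matrix",
    "read_gene_lengths",
    "read_gmt",
    "write_gmt",
    "compute_rpkm",
    "quantile_normalize",
    "filter_low_expression",
]

_SEPARATORS = {"tsv": "\t", "csv": ","}


def _infer_fmt(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _SEPARATORS:
            raise ValueError(f"unsupported format {fmt!r}; expected 'tsv' or 'csv'")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    return suffix if suffix in _SEPARATORS else "tsv"


def validate_expression_matrix(matrix: pd.DataFrame, name: str = "matrix") -> pd.DataFrame:
    """Check the expression-matrix invariants, raising ``ValueError`` on violation."""
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"{name}: duplicate gene id(s): {dup}")
    if matrix.columns.duplicated().any():
        dup = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValueError(f"{name}: duplicate sample id(s): {dup}")
    values = matrix.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        bad = np.zeros(matrix.shape, dtype=bool)
        coerced = matrix.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna().to_numpy() & matrix.notna().to_numpy()
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"{name}: non-numeric value {matrix.iat[r, c]!r} at "
                f"gene {matrix.index[r]!r}, sample {matrix.columns[c]!r}"
            )
        matrix = coerced
        values = matrix.to_numpy()
    if values.size:
        finite = np.isfinite(values)
        if not finite.all():
            r, c = np.argwhere(~finite)[0]
            raise ValueError(
                f"{name}: non-finite value at gene {matrix.index[r]!r}, "
                f"sample {matrix.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"{name}: negative value {values[r, c]} at gene "
                f"{matrix.index[r]!r}, sample {matrix.columns[c]!r}"
            )
    return matrix


def read_expression_matrix(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a gene x sample expression table.

    The first column holds gene identifiers and the header row holds sample
    identifiers.  Duplicate identifiers, negative, non-numeric or non-finite
    cells are hard errors that name the offending entry.
    """
    path = Path(path)
    sep = _SEPARATORS[_infer_fmt(path, fmt)]
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dup = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample id(s): {dup}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = [str(c) for c in samples]
    return validate_expression_matrix(df, name=str(path))


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    """Write a matrix at full float precision so round trips are value-faithful."""
    path = Path(path)
    sep = _SEPARATORS[_infer_fmt(path, fmt)]
    # repr-based formatting: shortest string that round-trips the float
    matrix.to_csv(path, sep=sep, float_format=None)


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Read a two-column (gene_id, length_bp) TSV into a Series of positive ints."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "length"], dtype={0: str})
    lengths = pd.Series(df["length"].to_numpy(), index=df["gene_id"], name="length")
    if lengths.index.duplicated().any():
        dup = lengths.index[lengths.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s) in length table: {dup}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive transcript length for gene(s): {bad}")
    return lengths


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT gene-set file: set id, description, tab-separated members."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs id, description, >=1 member")
            set_id, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {set_id!r} has no members")
            if len(set(members)) != len(members):
                raise ValueError(f"{path}:{lineno}: duplicate members in set {set_id!r}")
            if set_id in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            sets[set_id] = (desc, members)
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, (desc, members) in sets.items():
            fh.write("\t".join([set_id, desc, *members]) + "\n")


def compute_rpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    log2_transform: bool = False,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Reads Per Kilobase per Million mapped reads.

    RPKM = count / ((column total / 1e6) * (length / 1e3)).  With
    ``log2_transform`` the result is ``log2(RPKM + pseudocount)``; because the
    map is strictly monotone for any pseudocount > 0, within-sample orderings
    (hence all REO-based results) are unchanged by it.
    """
    counts = validate_expression_matrix(counts, "counts")
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing transcript length for gene(s): {missing.tolist()}")
    col_totals = counts.sum(axis=0)
    zero_cols = col_totals.index[col_totals == 0].tolist()
    if zero_cols:
        raise ValueError(f"zero column total in sample(s): {zero_cols}")
    length_kb = lengths.reindex(counts.index).to_numpy(dtype=float) / 1e3
    per_million = col_totals.to_numpy(dtype=float) / 1e6
    rpkm = counts.to_numpy(dtype=float) / per_million[None, :] / length_kb[:, None]
    out = pd.DataFrame(rpkm, index=counts.index, columns=counts.columns)
    if log2_transform:
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0 for the log2 transform")
        out = np.log2(out + pseudocount)
    return out


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common per-rank cross-sample mean distribution.

    Tied values within a column receive the mean of the rank-values they span
    (the "average" tie dialect).  Idempotent.
    """
    matrix = validate_expression_matrix(matrix)
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for c in range(values.shape[1]):
        col = values[:, c]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(target)
        assigned[order] = target
        # average rank-values over tie groups
        s = pd.Series(assigned)
        out[:, c] = s.groupby(col, sort=False).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def filter_low_expression(counts: pd.DataFrame, max_zero_fraction: float = 0.75) -> pd.DataFrame:
    """Drop genes whose zero-count fraction strictly exceeds ``max_zero_fraction``.

    A gene that is zero in exactly the threshold fraction of samples is kept
    (removal applies to "more than" the threshold).  Row order is preserved.
    """
    counts = validate_expression_matrix(counts, "counts")
    zero_fraction = (counts.to_numpy() == 0).mean(axis=1)
    kept = counts.loc[zero_fraction <= max_zero_fraction]
    logger.info("filter_low_expression: kept %d of %d genes", kept.shape[0], counts.shape[0])
    return kept
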