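"""Reading, filtering and binarising taxon-abundance tables.

Tables are plain :class:`pandas.DataFrame` objects with **taxa on the rows
and samples on the columns** — the one orientation used everywhere in this
package. Values are non-negative abundances; whether they are raw counts or
relative abundances is the caller's business, but the default thresholds
elsewhere assume relative abundance (use :func:`normalize_relative` to close
columns to sum 1).

Supported on-disk formats:

* TSV — tab-separated, UTF-8, taxon label in column 1, header row = sample IDs.
* BIOM v2.1 — HDF5, observation-major CSR (read only).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AbundanceError, EmptyResultError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "read_abundance",
    "write_abundance",
    "validate_abundance",
    "to_presence_absence",
    "filter_by_mean_abundance",
    "top_n_by_abundance",
    "normalize_relative",
]


def validate_abundance(df: pd.DataFrame, *, min_shape: tuple[int, int] = (2, 2)) -> pd.DataFrame:
    """Check the abundance-matrix invariants, returning ``df`` unchanged.

    Raises :class:`AbundanceError` on duplicate taxon/sample labels, negative
    or non-finite entries, or a table smaller than ``min_shape``.
    """
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise AbundanceError(f"duplicate taxon labels: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise AbundanceError(f"duplicate sample labels: {dups}")
    values = df.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise AbundanceError("abundance table contains non-numeric entries")
    if values.size:
        if not np.isfinite(values).all():
            raise AbundanceError("abundance table contains NaN or infinite entries")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise AbundanceError(
                f"negative abundance {values[i, j]!r} for taxon "
                f"{df.index[i]!r} in sample {df.columns[j]!r}"
            )
    r_min, c_min = min_shape
    if df.shape[0] < r_min or df.shape[1] < c_min:
        raise AbundanceError(
            f"abundance matrix must be at least {r_min} taxa x {c_min} samples, "
            f"got {df.shape[0]} x {df.shape[1]}"
        )
    return df


def _read_tsv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # pandas names the offending line
        raise AbundanceError(f"malformed TSV {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise AbundanceError(f"non-numeric abundance in {path}: {exc}") from exc
    return df


def _read_biom(path: Path) -> pd.DataFrame:
    # Minimal BIOM v2.1 reader: observation-major CSR stored under
    # observation/matrix/{data,indices,indptr}, labels under */ids.
    import h5py
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as h5:
        try:
            taxa = [t.decode() if isinstance(t, bytes) else str(t) for t in h5["observation/ids"][:]]
            samples = [s.decode() if isinstance(s, bytes) else str(s) for s in h5["sample/ids"][:]]
            grp = h5["observation/matrix"]
            mat = csr_matrix(
                (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
                shape=(len(taxa), len(samples)),
            )
        except KeyError as exc:
            raise AbundanceError(f"{path} is not a BIOM v2.1 file: missing {exc}") from exc
    return pd.DataFrame(mat.toarray(), index=taxa, columns=samples)


def read_abundance(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a taxon-by-sample abundance table from TSV or BIOM v2.1.

    ``format`` is ``"tsv"``, ``"biom"`` or None (inferred from the suffix,
    defaulting to TSV). Labels are preserved in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "biom" if path.suffix.lower() == ".biom" else "tsv"
    if format == "tsv":
        df = _read_tsv(path)
    elif format == "biom":
        df = _read_biom(path)
    else:
        raise ParameterError(f"unknown abundance format {format!r} (expected tsv or biom)")
    return validate_abundance(df)


def write_abundance(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV (taxon label in column 1, header = sample IDs)."""
    df.to_csv(Path(path), sep="\t", index_label="taxon")


def to_presence_absence(df: pd.DataFrame, detection_limit: float = 0.0) -> pd.DataFrame:
    """Binarise: entry 1 iff abundance strictly exceeds ``detection_limit``.

    The default limit 0 encodes presence as any non-zero abundance. Labels
    and shape are preserved; the result is idempotent under re-binarisation.
    """
    if detection_limit < 0:
        raise ParameterError(f"detection_limit must be >= 0, got {detection_limit}")
    return (df > detection_limit).astype(np.int64)


def filter_by_mean_abundance(df: pd.DataFrame, min_mean_rel: float = 0.001) -> pd.DataFrame:
    """Retain taxa whose mean relative abundance across samples is >= ``min_mean_rel``.

    The boundary is inclusive (a taxon at exactly the threshold is kept).
    Assumes relative abundances; a warning is logged if columns clearly are
    not closed to <= 1.
    """
    if min_mean_rel < 0:
        raise ParameterError(f"min_mean_rel must be >= 0, got {min_mean_rel}")
    col_sums = df.sum(axis=0)
    if (col_sums > 1 + 1e-6).any():
        logger.warning(
            "filter_by_mean_abundance: some columns sum to > 1; "
            "input does not look like relative abundances"
        )
    means = df.mean(axis=1)
    keep = means >= min_mean_rel
    if min_mean_rel > 0 and not keep.any():
        raise EmptyResultError(
            f"no taxon has mean relative abundance >= {min_mean_rel}; "
            "lower the threshold or check normalisation"
        )
    return df.loc[keep]


def top_n_by_abundance(df: pd.DataFrame, n: int) -> pd.DataFrame:
    """Retain the ``n`` taxa with highest mean abundance.

    Ties in mean abundance are broken by lexicographic taxon label (the
    lexicographically first label wins). Original row order is preserved
    among the retained taxa.
    """
    if n < 1 or n > df.shape[0]:
        raise ParameterError(f"n must be in [1, {df.shape[0]}], got {n}")
    means = df.mean(axis=1)
    ranked = sorted(df.index, key=lambda t: (-means[t], str(t)))
    chosen = set(ranked[:n])
    return df.loc[[t for t in df.index if t in chosen]]


def normalize_relative(df: pd.DataFrame) -> pd.DataFrame:
    """Close each sample column to sum 1 (columns summing to 0 are left as zeros)."""
    sums = df.sum(axis=0)
    safe = sums.replace(0, 1.0)
    return df / safe
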