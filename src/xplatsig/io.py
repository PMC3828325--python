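"""Expression-matrix and phenotype-label input/output.

Expression matrices are plain :class:`pandas.DataFrame` objects with probe
ids on the index and sample ids on the columns, values on a log2 signal
scale.  Two on-disk dialects are supported: a headered TSV (first column =
probe id) and GCT 1.2.  Phenotype labels are a two-column TSV mapping
sample id to a binary class (0 = control, 1 = pathway-on).

Validation is strict: duplicate ids, non-numeric cells and missing values
are load errors, never silently repaired.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionFormatError",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "validate_expression",
]

#: tokens accepted in the class column of a label file
LABEL_TOKENS = {
    "0": 0,
    "1": 1,
    "control": 0,
    "ctrl": 0,
    "pathway": 1,
    "case": 1,
}


class ExpressionFormatError(ValueError):
    """Raised when an expression or label file violates the format contract."""


def _check_unique(ids, kind: str) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ExpressionFormatError(
            f"duplicate {kind} id(s): {', '.join(map(str, dups.index[:5]))}"
        )


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory expression matrix; returns it unchanged."""
    _check_unique(matrix.index, "probe")
    _check_unique(matrix.columns, "sample")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = matrix.columns[[
            not np.issubdtype(dt, np.number) for dt in matrix.dtypes
        ]]
        raise ExpressionFormatError(
            f"non-numeric expression values in column(s): {', '.join(map(str, bad[:5]))}"
        )
    if not np.isfinite(values).all():
        n_bad = int((~np.isfinite(values)).sum())
        raise ExpressionFormatError(
            f"{n_bad} missing/non-finite expression value(s); "
            "impute or filter upstream before loading"
        )
    return matrix


def _read_table(handle, path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(handle, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise ExpressionFormatError(f"cannot parse {path}: {exc}") from exc
    if frame.shape[1] == 0:
        raise ExpressionFormatError(f"{path}: no sample columns found")
    frame.index = frame.index.astype(str)
    frame.index.name = None  # header token ("probe_id"/"Name") is layout
    frame.columns = frame.columns.astype(str)
    return frame


def _as_float(frame: pd.DataFrame, path) -> pd.DataFrame:
    try:
        return frame.astype(float)
    except (TypeError, ValueError) as exc:
        raise ExpressionFormatError(
            f"{path}: non-numeric cell in expression table ({exc})"
        ) from exc


def read_expression(path, format: str = "tsv", log2: bool = False) -> pd.DataFrame:
    """Read an expression matrix from ``path``.

    Parameters
    ----------
    path : str or Path
        Input file.
    format : {"tsv", "gct"}
        ``tsv`` expects a header row of sample ids and probe ids in the
        first column.  ``gct`` expects the GCT 1.2 dialect (``#1.2`` line,
        dimension line, then a table with Name/Description columns).
    log2 : bool
        Apply ``log2(x + 1)`` after loading, for raw-scale inputs.
    """
    path = Path(path)
    if format == "tsv":
        with open(path) as handle:
            frame = _as_float(_read_table(handle, path), path)
    elif format == "gct":
        with open(path) as handle:
            version = handle.readline().strip()
            if not version.startswith("#1.2"):
                raise ExpressionFormatError(
                    f"{path}: not a GCT 1.2 file (first line {version!r})"
                )
            dims = handle.readline().split()
            if len(dims) < 2:
                raise ExpressionFormatError(f"{path}: malformed GCT dimension line")
            n_rows, n_cols = int(dims[0]), int(dims[1])
            body = _read_table(handle, path)
        # GCT carries a Description column after the probe id
        if body.shape[1] != n_cols + 1:
            raise ExpressionFormatError(
                f"{path}: GCT dimension line promises {n_cols} samples, "
                f"table has {body.shape[1] - 1}"
            )
        frame = body.drop(columns=body.columns[0])
        if frame.shape[0] != n_rows:
            raise ExpressionFormatError(
                f"{path}: GCT dimension line promises {n_rows} rows, table has {frame.shape[0]}"
            )
        frame = _as_float(frame, path)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    frame = validate_expression(frame)
    if log2:
        if (frame.to_numpy() < 0).any():
            raise ExpressionFormatError("negative values are incompatible with --log2")
        frame = np.log2(frame + 1.0)
    return frame


def write_expression(matrix: pd.DataFrame, path, format: str = "tsv",
                     header_comments=()) -> None:
    """Write a matrix as TSV or GCT 1.2; round-trips at 10+ significant digits."""
    path = Path(path)
    validate_expression(matrix)
    buf = _io.StringIO()
    for line in header_comments:
        buf.write(f"# {line}\n")
    if format == "tsv":
        out = matrix.copy()
        out.index.name = "probe_id"
        out.to_csv(buf, sep="\t", float_format="%.12g")
    elif format == "gct":
        buf.write("#1.2\n")
        buf.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
        out = matrix.copy()
        out.insert(0, "Description", "na")
        out.index.name = "Name"
        out.to_csv(buf, sep="\t", float_format="%.12g")
    else:
        raise ValueError(f"unknown expression format {format!r}")
    path.write_text(buf.getvalue())


def read_labels(path) -> pd.Series:
    """Read a two-column TSV of ``sample_id<TAB>class`` into an int Series.

    Accepted class tokens: ``0``/``control``/``ctrl`` and
    ``1``/``pathway``/``case`` (case-insensitive).  A header row with the
    literal first field ``sample_id`` is permitted and skipped.
    """
    path = Path(path)
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ExpressionFormatError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            if lineno == 1 and fields[0].lower() in {"sample_id", "sample"}:
                continue
            token = fields[1].strip().lower()
            if token not in LABEL_TOKENS:
                accepted = ", ".join(sorted(LABEL_TOKENS))
                raise ExpressionFormatError(
                    f"{path}:{lineno}: unknown class token {fields[1]!r} "
                    f"(accepted: {accepted})"
                )
            rows.append((fields[0], LABEL_TOKENS[token]))
    if not rows:
        raise ExpressionFormatError(f"{path}: no labels found")
    ids = [r[0] for r in rows]
    _check_unique(ids, "sample")
    return pd.Series([r[1] for r in rows], index=pd.Index(ids, name="sample_id"),
                     name="label", dtype=int)


def write_labels(labels: pd.Series, path) -> None:
    out = labels.rename("label").to_frame()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def check_labels_against_matrix(labels: pd.Series, matrix: pd.DataFrame,
                                require_both_classes: bool = True) -> pd.Series:
    """Subset/validate labels for a companion matrix (training contract)."""
    missing = labels.index.difference(matrix.columns)
    if len(missing):
        raise ExpressionFormatError(
            f"labeled sample(s) absent from matrix: {', '.join(missing[:5])}"
        )
    if require_both_classes and labels.nunique() < 2:
        raise ExpressionFormatError(
            "training labels contain a single class; need both control and pathway"
        )
    return labels
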