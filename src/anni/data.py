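"""Expression-matrix container, delimited-table IO and per-gene scaling.

Expression tables are plain delimited text (tab or comma, auto-detected)
with one header row of gene identifiers and a leading sample-identifier
column. Because every per-gene model predicts its target through a
sigmoid-bounded output node, targets must live in ``(0, 1)``; we map
every gene column into ``[0, 1]`` by per-gene min-max scaling before
training.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression_table",
    "write_expression_table",
    "minmax_scale",
    "deduplicate_ids",
]

#: column names recognised (case-insensitively) as per-sample class labels
LABEL_COLUMNS = ("class", "label", "group")


@dataclass
class ExpressionMatrix:
    """A samples x genes expression table.

    Attributes
    ----------
    values : pandas.DataFrame
        One row per sample, one column per gene. Arbitrary units before
        scaling, ``[0, 1]`` after.
    class_labels : pandas.Series, optional
        Per-sample categorical labels. Stored for benchmarking designs;
        the interaction inference itself never reads them.
    scaled : bool
        Whether per-gene min-max scaling has been applied.
    """

    values: pd.DataFrame
    class_labels: Optional[pd.Series] = None
    scaled: bool = False

    def __post_init__(self) -> None:
        ids = list(self.values.columns)
        if len(set(ids)) != len(ids):
            raise ValueError("gene_ids contain duplicates; deduplicate first")
        sids = list(self.values.index)
        if len(set(sids)) != len(sids):
            raise ValueError("sample_ids contain duplicates")
        if self.class_labels is not None:
            self.class_labels = self.class_labels.reindex(self.values.index)
        if self.scaled:
            vals = self.values.to_numpy(dtype=float)
            if vals.size and ((vals < -1e-12).any() or (vals > 1 + 1e-12).any()):
                raise ValueError("scaled matrix has values outside [0, 1]")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        labels = None if self.class_labels is None else self.class_labels.copy()
        return ExpressionMatrix(self.values.copy(), labels, self.scaled)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        state = "scaled" if self.scaled else "unscaled"
        return (
            f"<ExpressionMatrix {self.n_samples} samples x {self.n_genes} genes, {state}>"
        )


def deduplicate_ids(ids: Sequence[str]) -> List[str]:
    """Make identifiers unique by suffixing an occurrence index.

    The second occurrence of ``IGF2`` becomes ``IGF2.2``, the third
    ``IGF2.3`` and so on, mirroring how repeated clone identifiers on a
    microarray panel are kept as distinct network nodes.
    """
    seen: dict = {}
    out: List[str] = []
    for name in ids:
        name = str(name)
        n = seen.get(name, 0) + 1
        seen[name] = n
        out.append(name if n == 1 else f"{name}.{n}")
    return out


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text().splitlines()
    head = "\n".join(sample[:10])
    try:
        return csv.Sniffer().sniff(head, delimiters="\t,").delimiter
    except csv.Error:
        return "\t" if "\t" in head else ","


def read_expression_table(
    path: str | Path,
    orientation: str = "samples_by_genes",
    label_column: Optional[str] = None,
) -> ExpressionMatrix:
    """Read a delimited expression table.

    Parameters
    ----------
    path : path-like
        Tab- or comma-separated text with a header row and a leading
        identifier column.
    orientation : {"samples_by_genes", "genes_by_samples"}
        Layout of the file; ``genes_by_samples`` input is transposed so
        the returned matrix is always samples x genes.
    label_column : str, optional
        Name of a class-label column to split off. When omitted, a
        column named ``class``/``label``/``group`` (case-insensitive) is
        used if present.

    Returns
    -------
    ExpressionMatrix
        Unscaled matrix; duplicate gene identifiers are disambiguated by
        occurrence suffix.
    """
    path = Path(path)
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sniff_delimiter(path)
    # header parsed by hand: pandas would silently mangle repeated gene symbols
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str, skip_blank_lines=True)
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise ValueError(f"{path}: empty expression table")
    df = raw.iloc[1:, 1:].copy()
    df.columns = [str(c) for c in raw.iloc[0, 1:]]
    df.index = [str(i) for i in raw.iloc[1:, 0]]
    if orientation == "genes_by_samples":
        df = df.T

    labels: Optional[pd.Series] = None
    if label_column is None:
        for col in df.columns:
            if str(col).lower() in LABEL_COLUMNS:
                label_column = col
                break
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not in table")
        labels = df.pop(label_column).astype(str)
        labels.name = str(label_column)

    df.columns = deduplicate_ids(df.columns)
    df.index = [str(i) for i in df.index]

    try:  # numpy's strtod is correctly rounded, unlike pandas' fast parser
        numeric = df.astype(float)
    except (ValueError, TypeError):
        coerced = df.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & df.notna()
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at sample "
            f"{df.index[r]!r}, gene {df.columns[c]!r}"
        ) from None
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at sample {df.index[r]!r}, gene {df.columns[c]!r}"
        )
    return ExpressionMatrix(numeric, class_labels=labels)


def write_expression_table(
    m: ExpressionMatrix, path: str | Path, sep: str = "\t"
) -> None:
    """Write a matrix as delimited text at full float precision.

    Values are written with ``repr`` round-trip precision, so reading
    the file back reproduces them exactly. The class-label column, when
    present, is appended last.
    """
    df = m.values.copy()
    if m.class_labels is not None:
        df[m.class_labels.name or "class"] = m.class_labels
    df.to_csv(path, sep=sep, index_label="sample")


def minmax_scale(m: ExpressionMatrix) -> ExpressionMatrix:
    """Map every gene column onto ``[0, 1]`` by ``(x - min) / (max - min)``.

    Constant columns are mapped to 0.5 everywhere (the sigmoid midpoint):
    such genes carry no signal but must not break inference. The
    operation is idempotent — scaled columns span exactly ``[0, 1]``, so
    rescaling is the identity up to floating tolerance.
    """
    vals = m.values.to_numpy(dtype=float)
    lo = vals.min(axis=0)
    hi = vals.max(axis=0)
    span = hi - lo
    constant = span == 0
    span_safe = np.where(constant, 1.0, span)
    scaled = (vals - lo) / span_safe
    scaled[:, constant] = 0.5
    out = pd.DataFrame(scaled, index=m.values.index, columns=m.values.columns)
    labels = None if m.class_labels is None else m.class_labels.copy()
    return ExpressionMatrix(out, class_labels=labels, scaled=True)
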