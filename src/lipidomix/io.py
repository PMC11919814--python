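"""Tabular readers and writers.

Abundance tables are CSV or TSV with the lipid name in the first column
and one column per sample; metadata tables carry ``sample_id`` and a
group column.  The delimiter is sniffed from the header line, so comma
and tab dialects of the same data parse identically.  All writers emit
plain TSV with a fixed float format so that identical analyses produce
byte-identical files.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

__all__ = ["read_abundance_table", "read_table", "write_tsv"]

FLOAT_FORMAT = "%.10g"


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV with delimiter auto-detection."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=_sniff_sep(path))


def read_abundance_table(
    path: str | Path,
    metadata_path: str | Path,
    group_col: str = "group",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and cross-validate an abundance matrix and its metadata.

    Returns (raw matrix indexed by lipid name, metadata frame).  Rejects
    duplicate lipid names (with row numbers), duplicate sample ids,
    non-numeric abundance cells, and any mismatch between matrix samples
    and metadata samples — naming the offenders.
    """
    table = read_table(path)
    if table.shape[1] < 2:
        raise ValueError("abundance table needs a lipid column plus sample columns")
    lipid_col = table.columns[0]
    names = table[lipid_col].astype(str)
    dup = names.duplicated(keep=False)
    if dup.any():
        rows = [str(i + 2) for i in names.index[dup]]  # +2: header + 1-based
        raise ValueError(
            f"duplicated lipid names at file rows {', '.join(rows)}: "
            f"{sorted(set(names[dup]))}"
        )
    matrix = table.set_index(lipid_col)
    matrix.index.name = "lipid"
    try:
        matrix = matrix.apply(pd.to_numeric)
    except (ValueError, TypeError) as err:
        raise ValueError(f"non-numeric abundance cell: {err}") from err

    metadata = read_table(metadata_path)
    if "sample_id" not in metadata.columns or group_col not in metadata.columns:
        raise ValueError(f"metadata needs columns 'sample_id' and {group_col!r}")
    metadata["sample_id"] = metadata["sample_id"].astype(str)
    if metadata["sample_id"].duplicated().any():
        dups = sorted(set(metadata["sample_id"][metadata["sample_id"].duplicated()]))
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    matrix_samples = set(map(str, matrix.columns))
    meta_samples = set(metadata["sample_id"])
    only_meta = sorted(meta_samples - matrix_samples)
    only_matrix = sorted(matrix_samples - meta_samples)
    if only_meta or only_matrix:
        parts = []
        if only_meta:
            parts.append(f"samples only in metadata: {only_meta}")
        if only_matrix:
            parts.append(f"samples only in matrix: {only_matrix}")
        raise ValueError("; ".join(parts))
    return matrix, metadata


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a TSV with deterministic float formatting."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
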