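"""Summary-statistics tables: the GCTA-COJO ``.ma`` dialect and plain TSV.

A summary table is a pandas DataFrame with canonical columns
``snp, a1, a2, freq, b, se, p, n`` (allele columns optional in the tsv
dialect). Validation is row-wise with line numbers so a malformed upload
points at the offending record.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SummaryTable", "read_summary_table", "write_summary_table"]

_MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]
_CANON = {"SNP": "snp", "A1": "a1", "A2": "a2", "freq": "freq",
          "b": "b", "se": "se", "p": "p", "N": "n"}
_REQUIRED = ["snp", "b", "se", "p", "n"]


class SummaryTableError(ValueError):
    """Raised for unrecoverable summary-table problems (missing columns,
    duplicate SNP ids, invalid rows)."""


@dataclass
class SummaryTable:
    """Validated summary-statistics table."""

    data: pd.DataFrame
    dialect: str = "ma"

    def __len__(self) -> int:
        return len(self.data)

    def wald(self) -> np.ndarray:
        return (self.data["b"] / self.data["se"]).to_numpy() ** 2


def _fmt(v) -> str:
    if isinstance(v, float):
        if np.isnan(v):
            return "NA"
        if float(v).is_integer() and abs(v) < 1e15:
            return str(int(v))
        return repr(float(v))
    return str(v)


def read_summary_table(path, dialect: str = "ma") -> SummaryTable:
    """Read and validate a summary-statistics file.

    ``dialect="ma"`` expects the GCTA-COJO column order
    ``SNP A1 A2 freq b se p N`` (whitespace- or tab-delimited);
    ``dialect="tsv"`` accepts any tab-delimited header containing at least
    ``snp b se p n`` (case-insensitive).

    Rows failing validation (non-positive se, p outside (0, 1],
    non-numeric cells) are reported with their 1-based file line numbers.
    """
    if dialect not in ("ma", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    text = Path(path).read_text()
    sep = r"\s+" if dialect == "ma" else "\t"
    df = pd.read_csv(_io.StringIO(text), sep=sep, dtype=str)
    if dialect == "ma":
        missing = [c for c in _MA_COLUMNS if c not in df.columns]
        if missing:
            raise SummaryTableError(f"{path}: missing required column(s) {missing}")
        df = df[_MA_COLUMNS].rename(columns=_CANON)
    else:
        df = df.rename(columns={c: c.strip().lower() for c in df.columns})
        df = df.rename(columns={"snp_id": "snp", "beta": "b", "beta_hat": "b"})
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise SummaryTableError(f"{path}: missing required column(s) {missing}")

    errors = []
    numeric = {}
    for col in ("freq", "b", "se", "p", "n"):
        if col not in df.columns:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        for i in df.index[bad]:
            errors.append(f"line {i + 2}: non-numeric value {df.at[i, col]!r} in column {col}")
        numeric[col] = converted
    for col, vals in numeric.items():
        df[col] = vals
    if "n" in df.columns:
        df["n"] = df["n"].astype("Int64")

    if not errors:
        for i in df.index:
            se, p = df.at[i, "se"], df.at[i, "p"]
            if pd.notna(se) and se <= 0:
                errors.append(f"line {i + 2}: se must be positive, got {se}")
            if pd.notna(p) and not (0 < p <= 1):
                errors.append(f"line {i + 2}: p must be in (0, 1], got {p}")
    if errors:
        raise SummaryTableError(f"{path}: invalid rows:\n  " + "\n  ".join(errors))
    if df["snp"].duplicated().any():
        dups = df["snp"][df["snp"].duplicated()].tolist()
        raise SummaryTableError(f"{path}: duplicate SNP id(s) {dups}")
    return SummaryTable(df.reset_index(drop=True), dialect)


def write_summary_table(table: SummaryTable, path, dialect: str | None = None) -> None:
    """Serialize a summary table; floats use shortest round-trip repr so
    writing a just-read canonical file reproduces it byte for byte."""
    dialect = dialect or table.dialect
    df = table.data
    if dialect == "ma":
        cols = [c for c in ("snp", "a1", "a2", "freq", "b", "se", "p", "n") if c in df.columns]
        header = [k for k, v in _CANON.items() if v in cols]
    elif dialect == "tsv":
        cols = list(df.columns)
        header = cols
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = ["\t".join(header)]
    for _, row in df.iterrows():
        lines.append("\t".join(_fmt(row[c]) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")
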