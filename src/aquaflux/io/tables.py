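"""Tab-separated result tables: one header line, floats at 6 significant digits.

Censored / missing values are written as ``NA``.
"""

from __future__ import annotations

import math

import pandas as pd


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return f"{value:.6g}"
    return str(value)


def write_table(path, columns: dict) -> None:
    """Write named columns of equal length as TSV."""
    names = list(columns)
    cols = [list(columns[n]) for n in names]
    n_rows = len(cols[0]) if cols else 0
    if any(len(c) != n_rows for c in cols):
        raise ValueError("all columns must have equal length")
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        for i in range(n_rows):
            fh.write("\t".join(_fmt(c[i]) for c in cols) + "\n")


def write_dataframe(path, df: pd.DataFrame) -> None:
    write_table(path, {c: df[c].tolist() for c in df.columns})


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
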