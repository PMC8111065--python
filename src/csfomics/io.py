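"""Reading and writing the tabular interchange formats.

Matrices travel as delimited text (comma, semicolon or tab; the
delimiter is sniffed) with a header row, a sample-id first column, a
``label`` column in {0,1} and one column per feature.  The per-feature
block map is a two-column sidecar TSV (feature, block).  Missing cells
are a hard error with the offending row/column named: the cohorts this
pipeline targets have no missing data and imputation is out of scope.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import OmicsMatrix
from .errors import DataError, SchemaError


def _sniff_delimiter(path) -> str:
    """Pick the candidate delimiter most frequent in the header line."""
    with open(path, newline="") as fh:
        header = fh.readline()
    counts = {d: header.count(d) for d in (",", ";", "\t")}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else ","


def read_matrix(path, label_col: str = "label", block_path=None) -> OmicsMatrix:
    """Read a samples-by-features matrix with labels; strict validation."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if label_col not in df.columns:
        raise SchemaError(f"{path}: no label column {label_col!r}")
    if df.isna().any().any():
        stacked = df.isna().stack()
        row, col = stacked[stacked].index[0]
        # +2: header line and 1-based counting
        line = int(df.index.get_loc(row)) + 2
        raise DataError(f"{path}: missing value at line {line}, "
                        f"sample {row!r}, column {col!r}")
    labels = df[label_col]
    if not set(np.unique(labels)) <= {0, 1}:
        raise DataError(f"{path}: label column must contain only 0/1")
    values = df.drop(columns=[label_col]).astype(float)

    if block_path is not None:
        bmap = pd.read_csv(block_path, sep="\t", header=None,
                           names=["feature", "block"]).set_index("feature")["block"]
        missing = set(values.columns) - set(bmap.index)
        if missing:
            raise SchemaError(f"{block_path}: no block tag for {sorted(missing)[:5]}")
        block = bmap.loc[values.columns]
    else:
        block = pd.Series("metabolite", index=values.columns)
    return OmicsMatrix(values=values, labels=labels.astype(int), block=block)


def write_matrix(matrix: OmicsMatrix, path, block_path=None, sep: str = ",") -> None:
    df = matrix.values.copy()
    df.insert(0, "label", matrix.labels.to_numpy())
    df.to_csv(path, sep=sep)
    if block_path is not None:
        matrix.block.to_csv(block_path, sep="\t", header=False)


REPORT_COLUMNS = [
    "marker", "auc", "ci_low", "ci_high", "acc", "sens", "spec",
    "ppv", "npv", "threshold", "odds_ratio", "p_value",
]


def write_report(rows: list[dict], path, formatted_path=None) -> pd.DataFrame:
    """Write the marker-performance report.

    ``path`` receives full-precision CSV; ``formatted_path`` (optional)
    a 2-decimal presentation table in the conventional column order
    AUC [CI], Acc, Sens, Spec, PPV, NPV, threshold, OR, p.
    """
    df = pd.DataFrame(rows)
    for col in REPORT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[REPORT_COLUMNS]
    df.to_csv(path, index=False)
    if formatted_path is not None:
        fmt = pd.DataFrame(
            {
                "marker": df["marker"],
                "AUC [95% CI]": [
                    f"{a:.2f} [{lo:.2f}-{hi:.2f}]"
                    for a, lo, hi in zip(df["auc"], df["ci_low"], df["ci_high"])
                ],
                "Acc": df["acc"].round(2),
                "Sens": df["sens"].round(2),
                "Spec": df["spec"].round(2),
                "PPV": df["ppv"].round(2),
                "NPV": df["npv"].round(2),
                "ROC threshold": df["threshold"].round(2),
                "Odds ratio": df["odds_ratio"].round(2),
                "P-value": df["p_value"].map(
                    lambda p: "<0.001" if p < 0.001 else f"{p:.2g}"
                ),
            }
        )
        fmt.to_csv(formatted_path, index=False, sep="\t")
    return df
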