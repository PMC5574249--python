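"""Tab-separated and JSON I/O with round-trip fidelity.

TSV is the canonical tabular format (gene annotations commonly contain
commas); floats are written with ``repr`` precision so write-then-read
reproduces the in-memory object exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ValidationError

__all__ = [
    "write_expression",
    "read_expression",
    "write_annotation",
    "read_annotation",
    "write_trial",
    "read_trial",
    "write_report",
    "read_report",
]

_FLOAT_FMT = "%.17g"


def write_expression(m: ExpressionMatrix, path) -> None:
    """Genes-in-rows TSV: first column gene ID, header row sample IDs."""
    df = m.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_expression(path, batch: pd.Series | None = None, transpose: bool = False) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicated gene identifier {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"duplicated sample identifier {dup!r} in {path}")
    return ExpressionMatrix(values=df, batch=batch)


def write_annotation(label: pd.Series, batch: pd.Series | None, path) -> None:
    """Sample annotation TSV: sample_id, label, batch."""
    df = pd.DataFrame({"label": label})
    if batch is not None:
        df["batch"] = batch
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicated sample identifier {dup!r} in {path}")
    if "label" not in df.columns:
        raise ValidationError(f"annotation file {path} lacks a 'label' column")
    return df


def write_trial(table: pd.DataFrame, path) -> None:
    df = table.copy()
    df.index.name = "patient_id"
    df.to_csv(path, sep="\t")


def read_trial(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"tumor_size_cat": object})
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicated patient identifier {dup!r} in {path}")
    required = ["arm", "biomarker", "hr_status", "pcr"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"trial file {path} lacks columns {missing}")
    df["pcr"] = df["pcr"].astype(int)
    if "tumor_size_cat" in df.columns:
        df["tumor_size_cat"] = df["tumor_size_cat"].where(df["tumor_size_cat"].notna(), None)
    return df


class _JsonEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, cls=_JsonEncoder) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
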