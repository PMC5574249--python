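"""Core expression-data containers.

An :class:`ExpressionMatrix` is a genes-by-samples table of real-valued
(log2) intensities. Missing entries are encoded as NaN; the missing mask is
derived, never stored separately, so the two can't drift apart. An optional
per-sample batch label supports batch adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "LabeledCohort"]


class ValidationError(ValueError):
    """An input violated a documented precondition."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample identifiers
        as the columns. NaN marks a missing measurement.
    batch
        Optional per-sample batch label, indexed by sample identifier.
    """

    values: pd.DataFrame
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicated gene identifiers: {list(dupes)[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValidationError(f"duplicated sample identifiers: {list(dupes)[:5]}")
        if self.batch is not None:
            self.batch = pd.Series(self.batch)
            missing = self.values.columns.difference(self.batch.index)
            if len(missing):
                raise ValidationError(f"samples without batch label: {list(missing)[:5]}")
            self.batch = self.batch.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """New matrix with replaced values, carrying the batch labels over."""
        batch = None if self.batch is None else self.batch.copy()
        return ExpressionMatrix(values=values, batch=batch)


@dataclass
class LabeledCohort:
    """An expression matrix plus a per-sample binary reference label.

    The positive class (label == 1) is the copy-number "BRCA1-like" call;
    every sample in the expression matrix must carry a label and both
    classes must be represented.
    """

    expr: ExpressionMatrix
    label: pd.Series = field(default_factory=pd.Series)

    def __post_init__(self) -> None:
        self.label = pd.Series(self.label).astype(int)
        missing = self.expr.sample_ids.difference(self.label.index)
        if len(missing):
            raise ValidationError(f"samples without reference label: {list(missing)[:5]}")
        self.label = self.label.loc[self.expr.sample_ids]
        if not set(self.label.unique()) <= {0, 1}:
            raise ValidationError("labels must be binary (0/1)")
        if self.label.nunique() < 2:
            raise ValidationError("both label classes must be present")

    @property
    def positive_samples(self) -> pd.Index:
        return self.label.index[self.label == 1]

    @property
    def negative_samples(self) -> pd.Index:
        return self.label.index[self.label == 0]
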