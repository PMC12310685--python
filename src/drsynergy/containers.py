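"""Shared data containers: expression matrices and dose-response tables.

These are thin, validated wrappers around pandas objects. The expression
matrix is genes x samples with a per-sample metadata frame (drug, cell line,
condition, dose, time); the IC50 table is long-form (drug, cell_line, ic50).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UnknownDrugError, ValidationError

TREATED = "treated"
CONTROL = "control"

#: metadata columns every sample must carry
SAMPLE_FIELDS = ("drug", "cell_line", "condition", "dose", "time")


@dataclass
class ExpressionMatrix:
    """Normalized expression values (genes x samples) plus sample metadata.

    ``values`` is indexed by gene id with one column per sample id;
    ``samples`` is indexed by sample id with the columns in
    :data:`SAMPLE_FIELDS`. Control samples carry condition ``"control"`` and
    an empty drug field.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene ids in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in expression matrix")
        if list(self.values.columns) != list(self.samples.index):
            raise ValidationError("sample metadata does not align with expression columns")
        missing = [c for c in SAMPLE_FIELDS if c not in self.samples.columns]
        if missing:
            raise ValidationError(f"sample metadata missing fields: {missing}")
        if self.samples[list(SAMPLE_FIELDS)].isna().any().any():
            raise ValidationError("incomplete sample metadata (NaN entries)")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def treated_samples(self, drug: str | None = None) -> pd.DataFrame:
        mask = self.samples["condition"] == TREATED
        if drug is not None:
            mask &= self.samples["drug"] == drug
        return self.samples.loc[mask]

    def control_samples(self) -> pd.DataFrame:
        return self.samples.loc[self.samples["condition"] == CONTROL]

    def select_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(
            values=self.values.loc[:, sample_ids].copy(),
            samples=self.samples.loc[sample_ids].copy(),
        )


@dataclass
class IC50Table:
    """Long-form dose-response table with one positive IC50 per (drug, cell line)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"drug", "cell_line", "ic50"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"IC50 table missing columns: {sorted(missing)}")
        if not np.all(np.isfinite(self.table["ic50"])) or (self.table["ic50"] <= 0).any():
            raise ValidationError("ic50 values must be finite and > 0")
        if self.table.duplicated(subset=["drug", "cell_line"]).any():
            raise ValidationError("duplicate (drug, cell_line) rows in IC50 table")

    @property
    def drugs(self) -> list[str]:
        return sorted(self.table["drug"].unique())

    def for_drug(self, drug: str) -> pd.Series:
        """IC50 values of one drug, indexed by cell line."""
        sub = self.table.loc[self.table["drug"] == drug]
        if sub.empty:
            raise UnknownDrugError(f"drug {drug!r} not present in IC50 table")
        return sub.set_index("cell_line")["ic50"]
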