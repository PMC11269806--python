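"""Protein-by-sample intensity matrix container.

The matrix is the central object of the stratification pipeline: rows are
proteins (features), columns are patient samples, values are log2
intensities with NaN marking missing quantifications.  Each protein carries
the number of peptides supporting its identification, used later by the
differential shortlist filter.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd


class DegenerateMatrixError(ValueError):
    """Raised when a QC step would leave an unusable matrix."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


class IntensityMatrix:
    """Quantitative protein × sample table with missingness mask.

    Parameters
    ----------
    values : DataFrame
        Proteins as the index, samples as columns, log2 intensities as
        floats; NaN encodes a missing quantification.
    peptide_counts : Series
        Number of supporting peptides per protein (aligned to the index).
    qc_log : list of str, optional
        Ordered record of QC steps already applied.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        peptide_counts: pd.Series | None = None,
        qc_log: Sequence[str] | None = None,
    ):
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate protein id: {dup!r}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        self.values = values.astype(float)
        if peptide_counts is None:
            peptide_counts = pd.Series(1, index=values.index)
        peptide_counts = peptide_counts.reindex(values.index)
        if peptide_counts.isna().any() or (peptide_counts < 1).any():
            raise ValueError("peptide_counts must be >= 1 for every protein")
        self.peptide_counts = peptide_counts.astype(int)
        self.qc_log: list[str] = list(qc_log or [])

    # ------------------------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(), self.peptide_counts.copy(), list(self.qc_log)
        )

    def subset_rows(self, keep: np.ndarray | Sequence) -> "IntensityMatrix":
        """Return a row subset; `keep` is a boolean mask or index labels."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            vals = self.values.loc[keep]
        else:
            vals = self.values.loc[list(keep)]
        return IntensityMatrix(
            vals, self.peptide_counts.loc[vals.index], list(self.qc_log)
        )

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        p, s = self.shape
        return (
            f"<IntensityMatrix {p} proteins x {s} samples, "
            f"{self.n_missing} missing, qc={self.qc_log}>"
        )
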