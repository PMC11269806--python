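"""Five-step matrix adjustment applied before consensus partitioning.

The cleansing order is fixed and matters: (1) drop proteins quantified in
too few samples, (2) impute the remaining missing values from nearest
protein rows, (3) winsorize each row at its 5th/95th percentiles,
(4) drop zero-variance rows, (5) drop rows below the 5th percentile of row
variances (recomputed after step 4).  Winsorization precedes the variance
screen, so the variance cut acts on outlier-trimmed rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.impute import KNNImputer

from .matrix import IntensityMatrix, DegenerateMatrixError


@dataclass
class QCReport:
    """Per-step bookkeeping of the matrix adjustment."""

    rows_in: int = 0
    rows_removed_missing: int = 0
    values_imputed: int = 0
    values_winsorized: int = 0
    rows_removed_zero_variance: int = 0
    rows_removed_low_variance: int = 0
    variance_percentile_cut: float | None = None
    thresholds: dict = field(default_factory=dict)

    @property
    def rows_out(self) -> int:
        return (
            self.rows_in
            - self.rows_removed_missing
            - self.rows_removed_zero_variance
            - self.rows_removed_low_variance
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rows_out"] = self.rows_out
        return d


def filter_missing_rows(
    m: IntensityMatrix, max_missing_frac: float = 0.25
) -> tuple[IntensityMatrix, QCReport]:
    """Remove proteins whose missing fraction strictly exceeds the threshold.

    A row with exactly ``max_missing_frac`` missing is kept (strict ``>``
    removes).
    """
    if m.shape[0] == 0:
        raise DegenerateMatrixError("empty matrix")
    frac = m.values.isna().mean(axis=1).to_numpy()
    keep = frac <= max_missing_frac
    report = QCReport(
        rows_in=m.shape[0],
        rows_removed_missing=int((~keep).sum()),
        thresholds={"max_missing_frac": max_missing_frac},
    )
    if not keep.any():
        raise DegenerateMatrixError(
            "all rows exceed the missingness threshold", report
        )
    out = m.subset_rows(keep)
    out.qc_log.append(f"filter_missing_rows(max_missing_frac={max_missing_frac})")
    return out, report


def knn_impute(m: IntensityMatrix, k: int = 10) -> IntensityMatrix:
    """Impute missing entries from the k nearest protein rows.

    Distance between rows is Euclidean over mutually observed samples; a
    missing entry becomes the mean of that sample's values among the k
    nearest rows observed there.
    """
    n_rows = m.shape[0]
    if k >= n_rows:
        raise ValueError(f"k={k} must be smaller than the number of rows ({n_rows})")
    if m.n_missing == 0:
        out = m.copy()
        out.qc_log.append(f"knn_impute(k={k})")
        return out
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(m.to_array())
    out = m.copy()
    out.values.iloc[:, :] = filled
    out.qc_log.append(f"knn_impute(k={k})")
    return out


def winsorize_rows(
    m: IntensityMatrix, lower_pct: float = 5.0, upper_pct: float = 95.0
) -> tuple[IntensityMatrix, QCReport]:
    """Clamp each row to its [lower_pct, upper_pct] percentile interval.

    Percentiles use linear interpolation between order statistics.  The
    operation is idempotent: re-winsorizing a clamped row changes nothing,
    because the row extremes become the percentile values themselves.
    """
    if m.n_missing:
        raise ValueError("winsorize_rows requires a fully imputed matrix")
    arr = m.to_array()
    lo = np.percentile(arr, lower_pct, axis=1, keepdims=True)
    hi = np.percentile(arr, upper_pct, axis=1, keepdims=True)
    n_clipped = int(((arr < lo) | (arr > hi)).sum())
    clipped = np.clip(arr, lo, hi)
    out = m.copy()
    out.values.iloc[:, :] = clipped
    out.qc_log.append(f"winsorize_rows({lower_pct},{upper_pct})")
    report = QCReport(
        rows_in=m.shape[0],
        values_winsorized=n_clipped,
        thresholds={"lower_pct": lower_pct, "upper_pct": upper_pct,
                    "percentile_definition": "linear interpolation"},
    )
    return out, report


def variance_filter(m: IntensityMatrix) -> tuple[IntensityMatrix, QCReport]:
    """Drop zero-variance rows, then rows below the 5th variance percentile.

    The percentile is computed on the variances that remain after the
    zero-variance removal; removal uses a strict ``<``, so when all
    remaining variances are equal nothing is dropped.
    """
    if m.n_missing:
        raise ValueError("variance_filter requires a fully imputed matrix")
    arr = m.to_array()
    var = arr.var(axis=1, ddof=0)
    nonzero = var > 0.0
    report = QCReport(rows_in=m.shape[0],
                      rows_removed_zero_variance=int((~nonzero).sum()))
    if nonzero.sum() < 2:
        raise DegenerateMatrixError(
            "fewer than 2 rows with positive variance", report
        )
    cut = float(np.percentile(var[nonzero], 5.0))
    keep = nonzero & (var >= cut)
    report.rows_removed_low_variance = int(nonzero.sum() - keep.sum())
    report.variance_percentile_cut = cut
    if keep.sum() < 2:
        raise DegenerateMatrixError("fewer than 2 rows after variance filter", report)
    out = m.subset_rows(keep)
    out.qc_log.append(f"variance_filter(cut={cut:.6g})")
    return out, report


def adjust_matrix(
    m: IntensityMatrix,
    max_missing_frac: float = 0.25,
    k: int = 10,
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
) -> tuple[IntensityMatrix, QCReport]:
    """Full five-step adjustment in fixed order; aggregated report.

    Output has no missing values and no zero-variance rows; protein order
    is preserved among retained rows and no value is modified except by
    imputation or winsorization.
    """
    m1, r1 = filter_missing_rows(m, max_missing_frac)
    n_missing = m1.n_missing
    m2 = knn_impute(m1, k) if n_missing else m1
    m3, r3 = winsorize_rows(m2, lower_pct, upper_pct)
    m4, r4 = variance_filter(m3)
    report = QCReport(
        rows_in=m.shape[0],
        rows_removed_missing=r1.rows_removed_missing,
        values_imputed=n_missing,
        values_winsorized=r3.values_winsorized,
        rows_removed_zero_variance=r4.rows_removed_zero_variance,
        rows_removed_low_variance=r4.rows_removed_low_variance,
        variance_percentile_cut=r4.variance_percentile_cut,
        thresholds={
            "max_missing_frac": max_missing_frac,
            "knn_k": k,
            "lower_pct": lower_pct,
            "upper_pct": upper_pct,
            "percentile_definition": "linear interpolation",
        },
    )
    assert report.rows_out == m4.shape[0]
    return m4, report
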