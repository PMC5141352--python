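"""Elementary statistics of the screen: lRPKM transform, medians, ranking,
expression tiers and coefficient-of-variation variability.

The working scale throughout is lRPKM = log2(RPKM + 1); the +1 keeps very
small RPKM values from exploding under the log and maps RPKM 0 to lRPKM 0
exactly.  Tier cut points (1, 3.5, 6.7 lRPKM) are lower-inclusive: a median
of exactly 3.5 is "high".
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ExpressionMatrix,
    LogExpressionMatrix,
    Thresholds,
    Tier,
    ValidationError,
)

__all__ = [
    "log_transform",
    "inverse_log_transform",
    "median_by_group",
    "rank_by_median",
    "assign_tier",
    "tier_table",
    "variability",
    "gene_summary",
]


def log_transform(matrix: ExpressionMatrix) -> LogExpressionMatrix:
    """Elementwise lRPKM = log2(RPKM + 1); gene and sample axes preserved."""
    return LogExpressionMatrix(np.log2(matrix.values + 1.0))


def inverse_log_transform(lmatrix: LogExpressionMatrix) -> ExpressionMatrix:
    """Recover RPKM = 2**lRPKM - 1 (exact up to floating round-off)."""
    rpkm = np.exp2(lmatrix.values) - 1.0
    # round-off can leave tiny negatives where lRPKM ~ 0
    return ExpressionMatrix(rpkm.clip(lower=0.0))


def _subset(lmatrix: LogExpressionMatrix, sample_set: Iterable[str]) -> pd.DataFrame:
    ids = list(sample_set)
    if not ids:
        raise ValidationError("sample set must be non-empty")
    return lmatrix.subset(ids)


def median_by_group(
    lmatrix: LogExpressionMatrix, sample_set: Iterable[str]
) -> pd.Series:
    """Per-gene median lRPKM over ``sample_set``.

    Even-sized sets use the mean of the two central order statistics.
    """
    return _subset(lmatrix, sample_set).median(axis=1)


def rank_by_median(
    lmatrix: LogExpressionMatrix, sample_set: Iterable[str]
) -> list[str]:
    """Gene ids ordered by median lRPKM, highest first.

    Ties are broken lexicographically by gene id so the ranking is
    reproducible.
    """
    medians = median_by_group(lmatrix, sample_set)
    order = sorted(medians.index, key=lambda g: (-medians[g], g))
    return order


def assign_tier(median: float, thresholds: Thresholds = Thresholds()) -> Tier:
    """Expression tier of a median lRPKM value.

    <1 not_expressed; [1, 3.5) expressed; [3.5, 6.7) high; >=6.7 very_high
    under the default cut points.  Negative input is rejected (lRPKM of a
    non-negative RPKM is never negative).
    """
    if not np.isfinite(median) or median < 0:
        raise ValidationError(f"median lRPKM must be finite and >= 0, got {median}")
    if median < thresholds.expressed:
        return Tier.NOT_EXPRESSED
    if median < thresholds.high:
        return Tier.EXPRESSED
    if median < thresholds.very_high:
        return Tier.HIGH
    return Tier.VERY_HIGH


def tier_table(
    lmatrix: LogExpressionMatrix,
    sample_set: Iterable[str],
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Per-gene median and tier over ``sample_set``.

    Columns: gene_id, median, tier.
    """
    medians = median_by_group(lmatrix, sample_set)
    tiers = [assign_tier(m, thresholds).value for m in medians]
    return pd.DataFrame(
        {"gene_id": medians.index, "median": medians.to_numpy(), "tier": tiers}
    ).reset_index(drop=True)


def variability(
    lmatrix: LogExpressionMatrix,
    sample_set: Iterable[str],
    cv_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-gene mean, sample sd (n-1 denominator) and coefficient of variation.

    CV = sd / mean on the lRPKM scale.  When the mean is 0 the ratio is
    undefined: cv and low_variability are emitted as missing (pd.NA), never
    as a number.  Requires at least two samples.

    Columns: gene_id, mean, sd, cv, low_variability.
    """
    frame = _subset(lmatrix, sample_set)
    if frame.shape[1] < 2:
        raise ValidationError("variability needs at least 2 samples")
    mean = frame.mean(axis=1)
    sd = frame.std(axis=1, ddof=1)
    defined = mean > 0
    cv = pd.array(np.where(defined, sd / mean.where(defined, 1.0), np.nan),
                  dtype="Float64")
    cv[~defined.to_numpy()] = pd.NA
    low = pd.array([bool(c < cv_threshold) if c is not pd.NA else pd.NA
                    for c in cv], dtype="boolean")
    return pd.DataFrame(
        {
            "gene_id": frame.index,
            "mean": mean.to_numpy(),
            "sd": sd.to_numpy(),
            "cv": cv,
            "low_variability": low,
        }
    ).reset_index(drop=True)


def gene_summary(
    lmatrix: LogExpressionMatrix,
    aml_samples: Sequence[str],
    reference_samples: Sequence[str],
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Per-gene summary table combining medians, tier and AML variability.

    Columns: gene_id, median_aml, median_reference, tier, mean, sd, cv,
    low_variability.  Tier is assigned from the AML median.
    """
    med_aml = median_by_group(lmatrix, aml_samples)
    med_ref = median_by_group(lmatrix, reference_samples)
    var = variability(lmatrix, aml_samples, cv_threshold=thresholds.cv)
    out = var.copy()
    out.insert(1, "median_aml", med_aml.to_numpy())
    out.insert(2, "median_reference", med_ref.to_numpy())
    out.insert(3, "tier", [assign_tier(m, thresholds).value for m in med_aml])
    return out
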