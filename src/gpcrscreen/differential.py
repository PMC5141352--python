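"""Median-difference differential calls against the CD34+ reference and
receptor-subfamily enrichment of the up/down sets.

A gene is called up when median(case) - median(reference) > +1 lRPKM and
down when the difference is < -1 (thresholds configurable).  Enrichment of
each subfamily in a directional set is scored by a two-tailed Fisher exact
test against the background of all classified receptors excluding every
differentially expressed gene (both directions excluded).

The exact test sums hypergeometric point probabilities of all tables with
the observed margins whose probability is at most that of the observed
table; the comparison carries a 1e-7 relative tolerance so floating-point
representations of exactly tied tables are still counted as ties.  Terms
are accumulated from log factorials so tables with totals in the hundreds
stay finite.
"""

from __future__ import annotations

from math import exp, lgamma, log1p
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datamodel import (
    LogExpressionMatrix,
    SubfamilyClassification,
    ValidationError,
)
from .transform import median_by_group

__all__ = [
    "call_differential",
    "fisher_exact_two_tailed",
    "subfamily_enrichment",
    "STATUS_UP",
    "STATUS_DOWN",
    "STATUS_UNCHANGED",
]

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_UNCHANGED = "unchanged"

#: Relative tolerance on the "at most as probable" comparison.
_TIE_RTOL = 1e-7


def call_differential(
    lmatrix: LogExpressionMatrix,
    case_samples: Sequence[str],
    reference_samples: Sequence[str],
    delta_median: float = 1.0,
) -> pd.DataFrame:
    """Per-gene differential call from the median lRPKM difference.

    status is ``up`` when delta > +delta_median, ``down`` when
    delta < -delta_median, else ``unchanged``; the three sets partition the
    genes.  Case and reference sample sets must be non-empty and disjoint.

    Columns: gene_id, median_case, median_reference, delta_median, status.
    """
    case = list(case_samples)
    reference = list(reference_samples)
    overlap = set(case) & set(reference)
    if overlap:
        raise ValidationError(
            f"case and reference sample sets overlap: {sorted(overlap)}"
        )
    med_case = median_by_group(lmatrix, case)
    med_ref = median_by_group(lmatrix, reference)
    delta = med_case - med_ref
    status = np.where(
        delta > delta_median,
        STATUS_UP,
        np.where(delta < -delta_median, STATUS_DOWN, STATUS_UNCHANGED),
    )
    return pd.DataFrame(
        {
            "gene_id": med_case.index,
            "median_case": med_case.to_numpy(),
            "median_reference": med_ref.to_numpy(),
            "delta_median": delta.to_numpy(),
            "status": status,
        }
    ).reset_index(drop=True)


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities, with the table margins fixed, of
    every table whose point probability is <= that of the observed table
    (within 1e-7 relative tolerance).  The all-zero table returns 1 by
    convention; any negative count is rejected.  The result lies in (0, 1].
    """
    counts = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in counts):
        raise ValidationError(f"counts must be non-negative integers: {counts}")
    a, b, c, d = (int(x) for x in counts)
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    log_denom = _log_comb(n, col1)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)

    def log_point(x: int) -> float:
        return _log_comb(row1, x) + _log_comb(n - row1, col1 - x) - log_denom

    cutoff = log_point(a) + log1p(_TIE_RTOL)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_point(x)
        if lp <= cutoff:
            total += exp(lp)
    return min(total, 1.0)


def subfamily_enrichment(
    calls: pd.DataFrame,
    direction: str,
    classification: SubfamilyClassification,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Subfamily over/under-representation in a directional call set.

    For each subfamily F the 2x2 table is
        a = |direction-set  & F|    b = |direction-set  \\ F|
        c = |background     & F|    d = |background     \\ F|
    where background = universe minus every up or down gene, and the
    universe defaults to all classified receptors.  Subfamilies with a = 0
    are still reported.  A called gene missing from the classification (or
    from an explicit universe) raises ValidationError naming the gene.

    Columns: direction, subfamily, a, b, c, d, p_two_tailed, bh_q.  The
    bh_q column is a Benjamini-Hochberg adjusted value supplied as a
    labeled extension; the headline p carries no multiplicity correction.
    """
    if direction not in (STATUS_UP, STATUS_DOWN):
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
    universe_set = set(classification.genes if universe is None else universe)
    for gene in calls["gene_id"]:
        if gene not in classification:
            raise ValidationError(f"called gene {gene!r} missing from classification")
        if gene not in universe_set:
            raise ValidationError(f"called gene {gene!r} missing from universe")

    by_status = calls.set_index("gene_id")["status"]
    de_genes = set(by_status.index[by_status != STATUS_UNCHANGED]) & universe_set
    direction_set = set(by_status.index[by_status == direction]) & universe_set
    background = universe_set - de_genes

    rows = []
    for family in classification.subfamilies:
        members = set(classification.members(family))
        a = len(direction_set & members)
        b = len(direction_set - members)
        c = len(background & members)
        d = len(background - members)
        p = fisher_exact_two_tailed(a, b, c, d)
        rows.append((direction, family, a, b, c, d, p))
    out = pd.DataFrame(
        rows, columns=["direction", "subfamily", "a", "b", "c", "d", "p_two_tailed"]
    )
    out["bh_q"] = multipletests(out["p_two_tailed"], method="fdr_bh")[1]
    return out
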