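"""Genetic-subgroup expression fingerprints, cross-cohort validation and
nomination of subgroup-specific overexpressed receptors.

A fingerprint gene for a subgroup satisfies |mean(with) - mean(without)| >=
1.5 lRPKM with a significant two-sample Student t test (p < 0.05) inside
the comparison scope.  Mutation subgroups (FLT3-ITD, NPM1, DNMT3A) are
compared within normal-karyotype AML only; cytogenetic subgroups within all
AML samples.  A fingerprint is validated when the same (subgroup, gene)
pair is flagged with the same direction in a second cohort.  A validated
up-fingerprint is nominated as a candidate target when the subgroup's mean
expression significantly exceeds every normal blood/bone-marrow population
tested (delta > 0 and p < 0.05 for each).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import (
    MUTATION_SUBGROUPS,
    LogExpressionMatrix,
    SampleTable,
    ValidationError,
)
from .differential import STATUS_DOWN, STATUS_UP

__all__ = [
    "TTestResult",
    "student_t_two_sample",
    "default_scope",
    "fingerprint",
    "fingerprint_all",
    "cross_validate",
    "nominate_targets",
]


@dataclass(frozen=True)
class TTestResult:
    """Two-sample t outcome; degenerate=True flags zero pooled variance,
    in which case statistic and p_value are NaN, never numeric."""

    statistic: float
    p_value: float
    degenerate: bool


def _t_matrix(
    x: np.ndarray, y: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sample t over two gene x sample blocks.

    Returns (t, p, degenerate); degenerate rows (zero pooled variance, or a
    group smaller than 2) get NaN statistics.  equal_var selects classical
    Student pooling; False gives the Welch-Satterthwaite form.
    """
    nx, ny = x.shape[1], y.shape[1]
    if nx < 2 or ny < 2:
        raise ValidationError("t test needs at least 2 samples per group")
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    if equal_var:
        pooled = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se2 = pooled * (1.0 / nx + 1.0 / ny)
        df = np.full_like(se2, float(nx + ny - 2))
    else:
        se2 = vx / nx + vy / ny
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
            )
    degenerate = se2 <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(se2)
    t = np.where(degenerate, np.nan, t)
    p = np.where(
        degenerate, np.nan, 2.0 * stats.t.sf(np.abs(t), np.where(degenerate, 1, df))
    )
    return t, p, degenerate


def student_t_two_sample(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> TTestResult:
    """Classical two-sample Student t (pooled variance, nx+ny-2 df).

    Zero pooled variance yields a flagged degenerate result with NaN
    statistic and p — silently returning 0 would overstate significance.
    """
    xa = np.asarray(x, dtype=float).reshape(1, -1)
    ya = np.asarray(y, dtype=float).reshape(1, -1)
    t, p, degenerate = _t_matrix(xa, ya, equal_var=equal_var)
    return TTestResult(float(t[0]), float(p[0]), bool(degenerate[0]))


def default_scope(samples: SampleTable, subgroup: str) -> list[str]:
    """Comparison scope for a subgroup.

    Mutation subgroups are screened within normal-karyotype AML (where they
    define the published subgroups); cytogenetic subgroups within all AML.
    """
    if subgroup in MUTATION_SUBGROUPS:
        return samples.normal_karyotype_aml()
    return samples.aml_samples()


def fingerprint(
    lmatrix: LogExpressionMatrix,
    samples: SampleTable,
    subgroup: str,
    scope: Iterable[str] | None = None,
    delta_mean: float = 1.5,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Fingerprint records for one genetic subgroup.

    Within scope, each gene is tested with-flag vs without-flag; a record is
    emitted iff |delta_mean| >= delta_mean threshold AND p < alpha.
    Degenerate (zero-variance) genes never produce a record.  The
    "without" complement contains only scoped samples whose flag set is
    known — samples outside scope are simply absent.

    Columns: subgroup, gene_id, mean_with, mean_without, delta_mean,
    p_value, direction, bh_q, validated (initialized False; set by
    cross_validate).  bh_q is a Benjamini-Hochberg column over the genes
    tested for this subgroup, supplied as a labeled extension.
    """
    scope_ids = default_scope(samples, subgroup) if scope is None else list(scope)
    with_ids = samples.samples_with_flag(subgroup, within=scope_ids)
    without_ids = [s for s in scope_ids if s not in set(with_ids)]
    if len(with_ids) < 2 or len(without_ids) < 2:
        raise ValidationError(
            f"subgroup {subgroup!r}: needs >=2 samples with and without the "
            f"flag in scope (got {len(with_ids)} vs {len(without_ids)})"
        )
    x = lmatrix.subset(with_ids).to_numpy()
    y = lmatrix.subset(without_ids).to_numpy()
    t, p, degenerate = _t_matrix(x, y, equal_var=equal_var)
    delta = x.mean(axis=1) - y.mean(axis=1)

    tested = ~degenerate
    bh_q = np.full(p.shape, np.nan)
    if tested.any():
        bh_q[tested] = multipletests(p[tested], method="fdr_bh")[1]

    keep = tested & (np.abs(delta) >= delta_mean) & (p < alpha)
    genes = np.asarray(lmatrix.gene_ids)
    out = pd.DataFrame(
        {
            "subgroup": subgroup,
            "gene_id": genes[keep],
            "mean_with": x.mean(axis=1)[keep],
            "mean_without": y.mean(axis=1)[keep],
            "delta_mean": delta[keep],
            "p_value": p[keep],
            "direction": np.where(delta[keep] > 0, STATUS_UP, STATUS_DOWN),
            "bh_q": bh_q[keep],
            "validated": False,
        }
    )
    return out.reset_index(drop=True)


def fingerprint_all(
    lmatrix: LogExpressionMatrix,
    samples: SampleTable,
    subgroups: Iterable[str] | None = None,
    delta_mean: float = 1.5,
    alpha: float = 0.05,
    equal_var: bool = True,
    strict: bool = True,
) -> pd.DataFrame:
    """Concatenated fingerprints for several subgroups (defaults to every
    subgroup label present in the annotation, sorted).

    With strict=False a subgroup with fewer than 2 samples on either side
    of the split is skipped with a warning instead of raising — useful when
    subgroups are auto-detected from a small validation cohort.
    """
    import logging

    labels = sorted(subgroups) if subgroups is not None else samples.subgroup_labels()
    frames = []
    for label in labels:
        try:
            frames.append(
                fingerprint(
                    lmatrix, samples, label,
                    delta_mean=delta_mean, alpha=alpha, equal_var=equal_var,
                )
            )
        except ValidationError:
            if strict:
                raise
            logging.getLogger(__name__).warning(
                "skipping subgroup %r: too few samples in scope", label
            )
    if not frames:
        return pd.DataFrame(
            columns=[
                "subgroup", "gene_id", "mean_with", "mean_without",
                "delta_mean", "p_value", "direction", "bh_q", "validated",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def cross_validate(
    records_primary: pd.DataFrame, records_secondary: pd.DataFrame
) -> pd.DataFrame:
    """Flag primary records confirmed in a second cohort.

    validated = True iff the same (subgroup, gene) pair appears in both
    record sets with the same direction.  Symmetric in detection: swapping
    the cohorts yields the same validated triples.
    """
    secondary = {
        (r.subgroup, r.gene_id): r.direction
        for r in records_secondary.itertuples()
    }
    out = records_primary.copy()
    out["validated"] = [
        secondary.get((r.subgroup, r.gene_id)) == r.direction
        for r in records_primary.itertuples()
    ]
    return out


def nominate_targets(
    lmatrix: LogExpressionMatrix,
    samples: SampleTable,
    fingerprints: pd.DataFrame,
    populations: Iterable[str] | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Candidate targets: subgroup-overexpressed genes above every normal
    population.

    Only up-direction fingerprint records are candidates.  For each
    candidate and each normal population, the subgroup samples (in the
    subgroup's default scope) are t-tested against that population;
    nominated = True iff delta_mean > 0 and p < alpha for every population.
    Degenerate comparisons count as failures, never as passes.

    Columns: subgroup, gene_id, then delta_mean_<pop> and p_<pop> per
    population, then nominated.
    """
    pop_names = (
        sorted(populations) if populations is not None else samples.population_names()
    )
    for name in pop_names:
        samples.population_samples(name)  # raises on unknown label
    candidates = fingerprints[fingerprints["direction"] == STATUS_UP]

    columns = ["subgroup", "gene_id"]
    for name in pop_names:
        columns += [f"delta_mean_{name}", f"p_{name}"]
    columns.append("nominated")
    if candidates.empty:
        return pd.DataFrame(columns=columns)

    rows = []
    for record in candidates.itertuples():
        scope_ids = default_scope(samples, record.subgroup)
        with_ids = samples.samples_with_flag(record.subgroup, within=scope_ids)
        x = lmatrix.subset(with_ids).loc[record.gene_id].to_numpy()
        row: list[object] = [record.subgroup, record.gene_id]
        nominated = True
        for name in pop_names:
            pop_ids = samples.population_samples(name)
            y = lmatrix.subset(pop_ids).loc[record.gene_id].to_numpy()
            result = student_t_two_sample(x, y, equal_var=equal_var)
            delta = float(x.mean() - y.mean())
            row += [delta, result.p_value]
            ok = (
                not result.degenerate
                and delta > 0
                and result.p_value < alpha
            )
            nominated = nominated and ok
        row.append(nominated)
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)
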