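"""Domain types for the GPCR expression screen.

The screen works on a gene x sample expression matrix in RPKM (reads per
kilobase of transcript per million mapped reads), a per-sample annotation
table (cohort, genetic-subgroup flags, karyotype class) and a total
receptor -> subfamily classification.  All downstream statistics operate on
the lRPKM scale, lRPKM = log2(RPKM + 1).

Matrices are thin validated wrappers around a pandas DataFrame with genes as
rows and samples as columns; annotation and classification types wrap plain
frames/dicts and expose the sample-selection helpers the pipeline stages
need.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "LogExpressionMatrix",
    "SampleTable",
    "SubfamilyClassification",
    "Tier",
    "COHORT_AML",
    "COHORT_REFERENCE",
    "NORMAL_POPULATION_PREFIX",
    "KARYOTYPE_CLASSES",
    "CYTOGENETIC_SUBGROUPS",
    "MUTATION_SUBGROUPS",
]


class ValidationError(ValueError):
    """An input violates a structural invariant of a domain type."""


COHORT_AML = "AML"
COHORT_REFERENCE = "CD34_reference"
NORMAL_POPULATION_PREFIX = "normal_population:"

KARYOTYPE_CLASSES = frozenset(
    {"normal", "intermediate_abnormal", "complex", "other", "unknown"}
)

#: Mutually exclusive cytogenetic subgroup labels.
CYTOGENETIC_SUBGROUPS = frozenset({"t_8_21", "inv16", "MLL"})
#: Mutation subgroups; may co-occur (e.g. NPM1 with FLT3-ITD) and are
#: analyzed within normal-karyotype AML by default.
MUTATION_SUBGROUPS = frozenset({"FLT3_ITD", "NPM1", "DNMT3A"})


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} id(s): {dupes}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample RPKM matrix; every value finite and >= 0."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.values
        _check_unique(frame.index, "gene")
        _check_unique(frame.columns, "sample")
        arr = frame.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at gene {frame.index[bad[0]]!r}, "
                f"sample {frame.columns[bad[1]]!r}"
            )
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative RPKM at gene {frame.index[bad[0]]!r}, "
                f"sample {frame.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class LogExpressionMatrix:
    """Gene x sample matrix on the lRPKM = log2(RPKM+1) scale (all >= 0)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.values
        _check_unique(frame.index, "gene")
        _check_unique(frame.columns, "sample")
        arr = frame.to_numpy()
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValidationError("lRPKM values must be finite and >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, sample_ids: Iterable[str]) -> pd.DataFrame:
        """Columns for ``sample_ids``; unknown ids raise ValidationError."""
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown sample id(s): {missing}")
        return self.values[ids]


@dataclass(frozen=True)
class SampleTable:
    """Per-sample annotation: cohort, genetic-subgroup flags, karyotype.

    ``frame`` is indexed by sample_id with columns ``cohort`` (str),
    ``subgroup_flags`` (frozenset of labels) and ``karyotype`` (str).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.frame
        _check_unique(frame.index, "sample")
        required = {"cohort", "subgroup_flags", "karyotype"}
        if not required.issubset(frame.columns):
            raise ValidationError(
                f"annotation frame must have columns {sorted(required)}"
            )
        for sample, row in frame.iterrows():
            cohort = row["cohort"]
            if cohort not in (COHORT_AML, COHORT_REFERENCE) and not cohort.startswith(
                NORMAL_POPULATION_PREFIX
            ):
                raise ValidationError(
                    f"sample {sample!r}: unknown cohort label {cohort!r}"
                )
            if cohort != COHORT_AML and row["subgroup_flags"]:
                raise ValidationError(
                    f"sample {sample!r}: subgroup flags "
                    f"{sorted(row['subgroup_flags'])} on non-AML cohort {cohort!r}"
                )
            if row["karyotype"] not in KARYOTYPE_CLASSES:
                raise ValidationError(
                    f"sample {sample!r}: unknown karyotype {row['karyotype']!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.frame.index.tolist()

    def __len__(self) -> int:
        return len(self.frame)

    def aml_samples(self) -> list[str]:
        return self.frame.index[self.frame["cohort"] == COHORT_AML].tolist()

    def reference_samples(self) -> list[str]:
        return self.frame.index[self.frame["cohort"] == COHORT_REFERENCE].tolist()

    def normal_karyotype_aml(self) -> list[str]:
        mask = (self.frame["cohort"] == COHORT_AML) & (
            self.frame["karyotype"] == "normal"
        )
        return self.frame.index[mask].tolist()

    def population_names(self) -> list[str]:
        labels = self.frame["cohort"][
            self.frame["cohort"].str.startswith(NORMAL_POPULATION_PREFIX)
        ]
        names = sorted({c[len(NORMAL_POPULATION_PREFIX):] for c in labels})
        return names

    def population_samples(self, name: str) -> list[str]:
        label = NORMAL_POPULATION_PREFIX + name
        samples = self.frame.index[self.frame["cohort"] == label].tolist()
        if not samples:
            raise ValidationError(f"unknown normal population {name!r}")
        return samples

    def samples_with_flag(
        self, flag: str, within: Iterable[str] | None = None
    ) -> list[str]:
        pool = self.frame if within is None else self.frame.loc[list(within)]
        return pool.index[[flag in f for f in pool["subgroup_flags"]]].tolist()

    def subgroup_labels(self) -> list[str]:
        labels: set[str] = set()
        for flags in self.frame["subgroup_flags"]:
            labels.update(flags)
        return sorted(labels)


@dataclass(frozen=True)
class SubfamilyClassification:
    """Total, single-valued mapping receptor_id -> subfamily label."""

    mapping: Mapping[str, str]

    @property
    def genes(self) -> list[str]:
        return list(self.mapping)

    @property
    def subfamilies(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    @property
    def n_subfamilies(self) -> int:
        return len(set(self.mapping.values()))

    def members(self, subfamily: str) -> list[str]:
        return [g for g, f in self.mapping.items() if f == subfamily]

    def __contains__(self, gene: str) -> bool:
        return gene in self.mapping

    def __getitem__(self, gene: str) -> str:
        return self.mapping[gene]


class Tier(str, enum.Enum):
    """Median-expression tier with cut points at 1, 3.5 and 6.7 lRPKM."""

    NOT_EXPRESSED = "not_expressed"
    EXPRESSED = "expressed"
    HIGH = "high"
    VERY_HIGH = "very_high"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Thresholds:
    """All screen cut-offs in one place (defaults are the published ones).

    expressed/high/very_high: lRPKM tier cut points (lower-inclusive).
    cv: coefficient-of-variation bound below which a gene counts as stably
    expressed. delta_median: |median difference| beyond which a gene is
    called up/down vs the reference. delta_mean: minimum |mean difference|
    for a subgroup fingerprint. alpha: t-test significance level.
    """

    expressed: float = 1.0
    high: float = 3.5
    very_high: float = 6.7
    cv: float = 0.5
    delta_median: float = 1.0
    delta_mean: float = 1.5
    alpha: float = 0.05

    def as_dict(self) -> dict[str, float]:
        return {
            "expressed": self.expressed,
            "high": self.high,
            "very_high": self.very_high,
            "cv": self.cv,
            "delta_median": self.delta_median,
            "delta_mean": self.delta_mean,
            "alpha": self.alpha,
        }


# Backwards-friendly alias used throughout the pipeline code.
SampleAnnotation = SampleTable
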