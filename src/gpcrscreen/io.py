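"""Readers and writers for the three input tables and all result tables.

All files are tab-separated text with a header row.  TSV is used instead of
CSV because gene annotations routinely contain commas; decimal points only,
no thousands separators.  The expression matrix is genes-as-rows with the
first column holding gene ids — orientation is fixed, never auto-detected,
so parsing stays deterministic.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .datamodel import (
    ExpressionMatrix,
    SampleTable,
    SubfamilyClassification,
    ValidationError,
)

__all__ = [
    "read_expression_matrix",
    "read_classification",
    "read_sample_annotation",
    "read_synonym_table",
    "write_expression_matrix",
    "write_sample_annotation",
    "write_classification",
    "write_table",
    "write_run_metadata",
    "sha256_of",
]

#: Column order of every result table this package writes.
RESULT_COLUMNS = {
    "gene_summary": [
        "gene_id", "median_aml", "median_reference", "tier",
        "mean", "sd", "cv", "low_variability",
    ],
    "differential_calls": [
        "gene_id", "median_case", "median_reference", "delta_median", "status",
    ],
    "enrichment": [
        "direction", "subfamily", "a", "b", "c", "d", "p_two_tailed", "bh_q",
    ],
    "fingerprints": [
        "subgroup", "gene_id", "mean_with", "mean_without", "delta_mean",
        "p_value", "direction", "bh_q", "validated",
    ],
}


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Parse a genes-as-rows RPKM TSV into a validated ExpressionMatrix.

    The header row carries sample ids; the first column carries gene ids.
    Duplicate ids, negative or non-numeric cells raise ValidationError.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # malformed TSV
        raise ValidationError(f"cannot parse expression TSV {path}: {exc}") from exc
    if frame.empty:
        raise ValidationError(f"expression TSV {path} has no data rows")
    try:
        numeric = frame.astype(float)
    except ValueError as exc:
        raise ValidationError(
            f"non-numeric expression value in {path}: {exc}"
        ) from exc
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    numeric.index.name = "gene_id"
    return ExpressionMatrix(numeric)


def read_classification(path: str | Path) -> SubfamilyClassification:
    """Parse a two-column (receptor_id, subfamily) TSV into a partition.

    A receptor listed twice with conflicting subfamilies, or an empty file,
    raises ValidationError.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValidationError(
            f"classification TSV {path} needs two columns (receptor, subfamily)"
        )
    if frame.empty:
        raise ValidationError(f"classification TSV {path} is empty")
    receptors = frame.iloc[:, 0].astype(str)
    families = frame.iloc[:, 1].astype(str)
    mapping: dict[str, str] = {}
    for receptor, family in zip(receptors, families):
        if receptor in mapping and mapping[receptor] != family:
            raise ValidationError(
                f"receptor {receptor!r} assigned to both "
                f"{mapping[receptor]!r} and {family!r}"
            )
        mapping[receptor] = family
    return SubfamilyClassification(mapping)


def read_sample_annotation(path: str | Path) -> SampleTable:
    """Parse the sample annotation TSV.

    Expected columns: sample_id, cohort, subgroup_flags (semicolon-separated,
    may be empty), karyotype.  Structural violations (duplicate sample ids,
    unknown cohorts, flags on non-AML samples) raise ValidationError.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "cohort", "subgroup_flags", "karyotype"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(
            f"annotation TSV {path} missing column(s) {missing}"
        )
    flags = [
        frozenset(x for x in cell.split(";") if x)
        for cell in frame["subgroup_flags"]
    ]
    table = pd.DataFrame(
        {
            "cohort": frame["cohort"].tolist(),
            "subgroup_flags": flags,
            "karyotype": frame["karyotype"].tolist(),
        },
        index=pd.Index(frame["sample_id"].tolist(), name="sample_id"),
    )
    return SampleTable(table)


def read_synonym_table(path: str | Path) -> dict[str, str]:
    """Optional two-column alias -> canonical-id table; exact match only."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValidationError("synonym table needs two columns (alias, canonical)")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


# ---------------------------------------------------------------------------
# writers

_FLOAT_FORMAT = "%.10g"


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = matrix.values.copy()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT)


def write_sample_annotation(samples: SampleTable, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "sample_id": samples.frame.index,
            "cohort": samples.frame["cohort"].to_numpy(),
            "subgroup_flags": [
                ";".join(sorted(f)) for f in samples.frame["subgroup_flags"]
            ],
            "karyotype": samples.frame["karyotype"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_classification(cls: SubfamilyClassification, path: str | Path) -> None:
    out = pd.DataFrame(
        {"receptor_id": list(cls.mapping), "subfamily": list(cls.mapping.values())}
    )
    out.to_csv(path, sep="\t", index=False)


def write_table(frame: pd.DataFrame, path: str | Path, kind: str | None = None) -> None:
    """Write a result table with the fixed, documented column order."""
    if kind is not None:
        order = [c for c in RESULT_COLUMNS[kind] if c in frame.columns]
        extra = [c for c in frame.columns if c not in order]
        frame = frame[order + extra]
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def sha256_of(path: str | Path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()


def write_run_metadata(
    path: str | Path,
    thresholds: Mapping[str, float],
    inputs: Mapping[str, str | Path],
    seed: int | None = None,
    extra: Mapping[str, object] | None = None,
) -> None:
    """Record effective thresholds, seed and input checksums for a run.

    No timestamps: identical runs must produce byte-identical metadata.
    """
    payload: dict[str, object] = {
        "thresholds": dict(thresholds),
        # file name + checksum only: absolute paths would make otherwise
        # identical runs produce different manifests
        "inputs": {
            name: {"file": Path(p).name, "sha256": sha256_of(p)}
            for name, p in inputs.items()
        },
    }
    if seed is not None:
        payload["seed"] = seed
    if extra:
        payload["extra"] = dict(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
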