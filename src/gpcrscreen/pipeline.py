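"""End-to-end orchestration of the screen.

Runs transform -> tiers/variability -> differential calls -> subfamily
enrichment -> subgroup fingerprints -> (optional) cross-cohort validation
-> target nomination on one set of input tables, writing every result table
plus a run manifest (effective thresholds, seed, input checksums).  Each
stage logs its in/out counts so the filter funnel can be audited; a stage
failure aborts with the stage name attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import differential, fingerprint as fp, io, transform
from .datamodel import (
    LogExpressionMatrix,
    SubfamilyClassification,
    Thresholds,
    ValidationError,
)

__all__ = ["PipelineConfig", "PipelineError", "run_all"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds plus which subgroups/populations to analyze.

    None for subgroups or populations means "every label present in the
    annotation", resolved at run time and recorded in the manifest.
    """

    thresholds: Thresholds = field(default_factory=Thresholds)
    subgroups: tuple[str, ...] | None = None
    populations: tuple[str, ...] | None = None
    equal_var: bool = True
    enrichment_universe: str = "classified"  # or "expressed"


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return run
    return wrap


def _intersect_genes(
    lmatrix: LogExpressionMatrix, classification: SubfamilyClassification
) -> tuple[LogExpressionMatrix, list[str]]:
    """Restrict the matrix to classified genes; report the dropped set."""
    keep = [g for g in lmatrix.gene_ids if g in classification]
    dropped = [g for g in lmatrix.gene_ids if g not in classification]
    if not keep:
        raise ValidationError("no gene in the matrix is classified")
    if dropped:
        logger.warning(
            "dropping %d unclassified gene(s): %s%s",
            len(dropped), dropped[:5], "..." if len(dropped) > 5 else "",
        )
    return LogExpressionMatrix(lmatrix.values.loc[keep]), dropped


def run_all(
    matrix_path: str | Path,
    annotation_path: str | Path,
    classification_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
    secondary_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Run the whole screen and write all result tables under ``out_dir``.

    ``secondary_dir`` may hold a second cohort's matrix.tsv and
    annotation.tsv; when given, fingerprints are recomputed there and the
    primary records get their ``validated`` flags set.  Returns a name ->
    path map of everything written.  Running twice on identical inputs
    yields byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = config.thresholds

    load = _stage("load_inputs")(_load_inputs)
    matrix, samples, classification = load(
        matrix_path, annotation_path, classification_path
    )

    lmatrix = _stage("log_transform")(transform.log_transform)(matrix)
    lmatrix, dropped = _stage("intersect_classification")(_intersect_genes)(
        lmatrix, classification
    )

    aml = samples.aml_samples()
    reference = samples.reference_samples()
    logger.info("cohort: %d AML, %d reference, %d genes",
                len(aml), len(reference), len(lmatrix.gene_ids))

    summary = _stage("gene_summary")(transform.gene_summary)(
        lmatrix, aml, reference, thresholds
    )
    calls = _stage("differential_calls")(differential.call_differential)(
        lmatrix, aml, reference, thresholds.delta_median
    )
    n_up = int((calls["status"] == "up").sum())
    n_down = int((calls["status"] == "down").sum())
    logger.info("differential: %d up, %d down of %d genes",
                n_up, n_down, len(calls))

    if config.enrichment_universe == "expressed":
        expressed = summary.loc[summary["tier"] != "not_expressed", "gene_id"]
        universe: Iterable[str] | None = expressed.tolist()
    else:
        universe = None
    enrich = _stage("subfamily_enrichment")(_enrich_both)(
        calls, classification, universe
    )

    fingerprints = _stage("fingerprints")(fp.fingerprint_all)(
        lmatrix, samples,
        subgroups=config.subgroups,
        delta_mean=thresholds.delta_mean,
        alpha=thresholds.alpha,
        equal_var=config.equal_var,
    )
    logger.info("fingerprints: %d records over %d subgroup(s)",
                len(fingerprints), fingerprints["subgroup"].nunique())

    if secondary_dir is not None:
        fingerprints = _stage("cross_validate")(_validate_against)(
            fingerprints, Path(secondary_dir), classification, config
        )

    nominations = _stage("nominate_targets")(fp.nominate_targets)(
        lmatrix, samples, fingerprints,
        populations=config.populations,
        alpha=thresholds.alpha,
        equal_var=config.equal_var,
    )
    logger.info("nominations: %d candidate(s), %d nominated",
                len(nominations),
                int(nominations["nominated"].sum()) if len(nominations) else 0)

    paths: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame, kind: str | None = None) -> None:
        path = out / f"{name}.tsv"
        io.write_table(frame, path, kind=kind)
        paths[name] = path

    emit("gene_summary", summary, kind="gene_summary")
    emit("differential_calls", calls, kind="differential_calls")
    emit("enrichment", enrich, kind="enrichment")
    emit("fingerprints", fingerprints, kind="fingerprints")
    emit("nominations", nominations)
    if dropped:
        emit("dropped_genes", pd.DataFrame({"gene_id": dropped}))

    manifest = out / "run_manifest.json"
    io.write_run_metadata(
        manifest,
        thresholds.as_dict(),
        {
            "matrix": matrix_path,
            "annotation": annotation_path,
            "classification": classification_path,
        },
        seed=seed,
        extra={
            "subgroups": sorted(fingerprints["subgroup"].unique().tolist()),
            "populations": (
                sorted(config.populations)
                if config.populations is not None
                else samples.population_names()
            ),
            "equal_var": config.equal_var,
            "enrichment_universe": config.enrichment_universe,
            "n_genes": len(lmatrix.gene_ids),
            "n_dropped_genes": len(dropped),
            "counts": {"up": n_up, "down": n_down,
                       "fingerprints": len(fingerprints)},
        },
    )
    paths["run_manifest"] = manifest
    return paths


def _load_inputs(matrix_path, annotation_path, classification_path):
    matrix = io.read_expression_matrix(matrix_path)
    samples = io.read_sample_annotation(annotation_path)
    classification = io.read_classification(classification_path)
    unknown = [s for s in samples.sample_ids if s not in set(matrix.sample_ids)]
    if unknown:
        raise ValidationError(
            f"annotated sample(s) missing from the matrix: {unknown[:5]}"
        )
    return matrix, samples, classification


def _enrich_both(calls, classification, universe):
    frames = [
        differential.subfamily_enrichment(calls, "up", classification, universe),
        differential.subfamily_enrichment(calls, "down", classification, universe),
    ]
    return pd.concat(frames, ignore_index=True)


def _validate_against(
    fingerprints: pd.DataFrame,
    secondary_dir: Path,
    classification: SubfamilyClassification,
    config: PipelineConfig,
) -> pd.DataFrame:
    matrix = io.read_expression_matrix(secondary_dir / "matrix.tsv")
    samples = io.read_sample_annotation(secondary_dir / "annotation.tsv")
    lmatrix, _ = _intersect_genes(transform.log_transform(matrix), classification)
    secondary = fp.fingerprint_all(
        lmatrix, samples,
        subgroups=config.subgroups,
        delta_mean=config.thresholds.delta_mean,
        alpha=config.thresholds.alpha,
        equal_var=config.equal_var,
        strict=False,
    )
    return fp.cross_validate(fingerprints, secondary)
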