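"""Seeded generator of synthetic expression cohorts with planted truth.

The generator emulates the statistical structure the screen assumes: a
genetically annotated AML cohort (~148 samples), a small CD34+ reference
(~12 samples), several small normal blood/bone-marrow populations, per-gene
baselines on the lRPKM scale with per-gene Gaussian noise, and planted
effects — up/down median shifts vs the reference, a subfamily-concentrated
bias among the up genes, and subgroup-restricted mean shifts.

Effects are additive on the lRPKM scale, the scale every screen threshold
lives on, so a planted shift of D maps directly onto the screen's
delta-median / delta-mean cut-offs.  Draws below 0 lRPKM are truncated at 0
(RPKM cannot be negative); at the default baselines the induced bias is
negligible except for genes already silent.

All randomness flows from a single root seed through numpy SeedSequence
spawning (baseline stream, annotation stream, noise stream), so the same
config and seed reproduce the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    COHORT_AML,
    COHORT_REFERENCE,
    CYTOGENETIC_SUBGROUPS,
    MUTATION_SUBGROUPS,
    NORMAL_POPULATION_PREFIX,
    ExpressionMatrix,
    SampleTable,
    SubfamilyClassification,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_subfamily_sizes",
    "default_cohort_config",
    "generate",
    "gene_ids_for",
    "classification_for",
]


def default_subfamily_sizes() -> dict[str, int]:
    """An 18-subfamily partition of 772 receptors.

    Sizes mimic an IUPHAR/GRAFS-style split of the GPCR repertoire
    (large olfactory block, 23 chemokine receptors, 33 adhesion receptors,
    small frizzled/protease-activated families, ...).
    """
    sizes = {
        "olfactory": 370,
        "taste": 24,
        "vomeronasal": 4,
        "amine": 42,
        "peptide": 70,
        "glycoprotein_hormone": 8,
        "lipid": 38,
        "chemokine": 23,
        "purine": 22,
        "adhesion": 33,
        "frizzled": 11,
        "secretin": 15,
        "glutamate": 22,
        "protease_activated": 4,
        "melatonin": 3,
        "opsin": 9,
        "orphan": 60,
        "other": 14,
    }
    assert sum(sizes.values()) == 772 and len(sizes) == 18
    return sizes


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one synthetic cohort.

    planted_up / planted_down are (gene_id, delta-lRPKM) pairs applied to
    every AML sample; planted_subgroup_effects are (subgroup, gene_id,
    delta) triples applied only to AML samples carrying the flag.
    subgroup_prevalences: cytogenetic labels are fractions of all AML
    samples and mutually exclusive; mutation labels are independent
    fractions of normal-karyotype AML samples (so NPM1 and FLT3-ITD can
    co-occur).  baseline_overrides pins chosen genes' baseline means, e.g.
    to make a planted down-shift detectable above the truncation floor.
    """

    n_genes: int = 772
    subfamily_sizes: Mapping[str, int] = field(
        default_factory=default_subfamily_sizes
    )
    n_aml: int = 148
    n_reference: int = 12
    normal_populations: Mapping[str, int] = field(
        default_factory=lambda: {
            "granulocytes": 3,
            "b_cells": 3,
            "t_cells": 3,
            "monocytes": 3,
            "wbc": 3,
        }
    )
    subgroup_prevalences: Mapping[str, float] = field(
        default_factory=lambda: {
            "t_8_21": 0.08,
            "inv16": 0.08,
            "MLL": 0.10,
            "FLT3_ITD": 0.35,
            "NPM1": 0.45,
            "DNMT3A": 0.30,
        }
    )
    baseline_mean: float = 1.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.5
    planted_up: tuple[tuple[str, float], ...] = ()
    planted_down: tuple[tuple[str, float], ...] = ()
    planted_family_bias: Mapping[str, float] = field(default_factory=dict)
    planted_subgroup_effects: tuple[tuple[str, str, float], ...] = ()
    baseline_overrides: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if sum(self.subfamily_sizes.values()) != self.n_genes:
            raise ValidationError(
                f"subfamily sizes sum to {sum(self.subfamily_sizes.values())}, "
                f"expected n_genes={self.n_genes}"
            )
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        for label, prevalence in self.subgroup_prevalences.items():
            if not 0.0 <= prevalence <= 1.0:
                raise ValidationError(
                    f"prevalence of {label!r} out of [0,1]: {prevalence}"
                )
        cyto = sum(
            p for lab, p in self.subgroup_prevalences.items()
            if lab in CYTOGENETIC_SUBGROUPS
        )
        if cyto > 1.0:
            raise ValidationError(
                f"cytogenetic prevalences sum to {cyto} > 1 "
                "(labels are mutually exclusive)"
            )
        genes = set(gene_ids_for(self))
        for gene, _ in (*self.planted_up, *self.planted_down):
            if gene not in genes:
                raise ValidationError(f"planted gene {gene!r} not in gene universe")
        for _, gene, _ in self.planted_subgroup_effects:
            if gene not in genes:
                raise ValidationError(f"planted gene {gene!r} not in gene universe")
        for gene in self.baseline_overrides:
            if gene not in genes:
                raise ValidationError(f"override gene {gene!r} not in gene universe")


@dataclass(frozen=True)
class GroundTruth:
    """The planted structure the screen is expected to recover."""

    planted_up: dict[str, float]
    planted_down: dict[str, float]
    subgroup_effects: tuple[tuple[str, str, float], ...]
    biased_subfamilies: tuple[str, ...]

    def as_frame(self) -> pd.DataFrame:
        rows = [("up", "", g, d) for g, d in self.planted_up.items()]
        rows += [("down", "", g, d) for g, d in self.planted_down.items()]
        rows += [
            ("subgroup", sub, g, d) for sub, g, d in self.subgroup_effects
        ]
        return pd.DataFrame(
            rows, columns=["kind", "subgroup", "gene_id", "delta"]
        )


def gene_ids_for(config: SimulationConfig) -> list[str]:
    """Deterministic gene ids, grouped by subfamily in config order."""
    ids = []
    for family, size in config.subfamily_sizes.items():
        ids.extend(f"{family}_{i:03d}" for i in range(1, size + 1))
    return ids


def classification_for(config: SimulationConfig) -> SubfamilyClassification:
    mapping = {}
    for family, size in config.subfamily_sizes.items():
        for i in range(1, size + 1):
            mapping[f"{family}_{i:03d}"] = family
    return SubfamilyClassification(mapping)


def default_cohort_config(seed: int = 0, **overrides: object) -> SimulationConfig:
    """The default cohort-shaped configuration.

    148 AML + 12 CD34+ reference samples over 772 receptors in 18
    subfamilies, with 30 planted up and 19 planted down genes at +/-2
    lRPKM; 6 of the 30 up genes are drawn from the 23-member chemokine-like
    subfamily so a real subfamily enrichment exists to recover.  Planted
    down genes (and subgroup down-effects) receive high baselines so the
    shift is not hidden by truncation at 0 — mirroring how receptors lost
    in disease are ones well expressed in the normal reference.  Subgroup
    mean shifts of +/-2 lRPKM are planted for the cytogenetic and mutation
    subgroups to give the fingerprint stage a recoverable signal.

    Gene picks are deterministic in ``seed``; keyword overrides replace
    config fields after planting.
    """
    base = SimulationConfig(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([17, seed]))
    genes = np.array(gene_ids_for(base))
    chemokine = np.array([g for g in genes if g.startswith("chemokine_")])

    up_biased = rng.choice(chemokine, size=6, replace=False)
    pool = np.array([g for g in genes if g not in set(up_biased)
                     and not g.startswith("chemokine_")])
    up_rest = rng.choice(pool, size=24, replace=False)
    up_genes = [*up_biased, *up_rest]
    pool = np.array([g for g in pool if g not in set(up_rest)])
    down_genes = rng.choice(pool, size=19, replace=False).tolist()
    pool = np.array([g for g in pool if g not in set(down_genes)])

    subgroup_plan = [
        ("t_8_21", 5, 3), ("inv16", 8, 0), ("MLL", 1, 3),
        ("FLT3_ITD", 3, 0), ("NPM1", 1, 0), ("DNMT3A", 0, 0),
    ]
    subgroup_effects: list[tuple[str, str, float]] = []
    overrides_baseline: dict[str, float] = {}
    for subgroup, n_up, n_down in subgroup_plan:
        picked = rng.choice(pool, size=n_up + n_down, replace=False)
        pool = np.array([g for g in pool if g not in set(picked)])
        for gene in picked[:n_up]:
            subgroup_effects.append((subgroup, str(gene), 2.0))
            overrides_baseline[str(gene)] = float(rng.uniform(0.5, 2.0))
        for gene in picked[n_up:]:
            subgroup_effects.append((subgroup, str(gene), -2.0))
            overrides_baseline[str(gene)] = float(rng.uniform(3.5, 6.0))

    for gene in up_genes:
        overrides_baseline[str(gene)] = float(rng.uniform(0.5, 3.0))
    for gene in down_genes:
        overrides_baseline[str(gene)] = float(rng.uniform(3.5, 6.5))

    config = replace(
        base,
        planted_up=tuple((str(g), 2.0) for g in up_genes),
        planted_down=tuple((str(g), -2.0) for g in down_genes),
        planted_family_bias={"chemokine": 6 / 30},
        planted_subgroup_effects=tuple(subgroup_effects),
        baseline_overrides=overrides_baseline,
    )
    if overrides:
        config = replace(config, **overrides)  # type: ignore[arg-type]
    return config


def _assign_annotation(
    config: SimulationConfig, rng: np.random.Generator
) -> SampleTable:
    rows = []
    cyto_labels = sorted(
        lab for lab in config.subgroup_prevalences if lab in CYTOGENETIC_SUBGROUPS
    )
    mutation_labels = sorted(
        lab for lab in config.subgroup_prevalences if lab in MUTATION_SUBGROUPS
    )
    cyto_p = [config.subgroup_prevalences[lab] for lab in cyto_labels]
    for i in range(config.n_aml):
        sample = f"AML_{i + 1:03d}"
        flags: set[str] = set()
        u = rng.random()
        cumulative = 0.0
        cyto_hit = None
        for label, p in zip(cyto_labels, cyto_p):
            cumulative += p
            if u < cumulative:
                cyto_hit = label
                break
        if cyto_hit is not None:
            flags.add(cyto_hit)
            karyotype = "intermediate_abnormal" if cyto_hit == "MLL" else "other"
        else:
            karyotype = str(
                rng.choice(["normal", "complex", "other"], p=[0.65, 0.15, 0.20])
            )
            if karyotype == "normal":
                for label in mutation_labels:
                    if rng.random() < config.subgroup_prevalences[label]:
                        flags.add(label)
        rows.append((sample, COHORT_AML, frozenset(flags), karyotype))
    for i in range(config.n_reference):
        rows.append(
            (f"CD34_{i + 1:02d}", COHORT_REFERENCE, frozenset(), "normal")
        )
    for name, count in config.normal_populations.items():
        for i in range(count):
            rows.append(
                (
                    f"{name}_{i + 1:02d}",
                    NORMAL_POPULATION_PREFIX + name,
                    frozenset(),
                    "normal",
                )
            )
    frame = pd.DataFrame(
        [(cohort, flags, karyotype) for _, cohort, flags, karyotype in rows],
        columns=["cohort", "subgroup_flags", "karyotype"],
        index=pd.Index([r[0] for r in rows], name="sample_id"),
    )
    return SampleTable(frame)


def generate(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleTable, SubfamilyClassification, GroundTruth]:
    """Draw one cohort: (RPKM matrix, annotation, classification, truth).

    Per-gene baseline means come from Normal(baseline_mean, baseline_sd)
    truncated at 0 (overridable per gene); each sample value is
    Normal(baseline + applicable planted effects, noise_sd) truncated at 0
    on the lRPKM scale, emitted as RPKM = 2**lRPKM - 1.  Deterministic
    under ``config.seed``.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_baseline, rng_annotation, rng_noise = (
        np.random.default_rng(s) for s in root.spawn(3)
    )

    genes = gene_ids_for(config)
    gene_index = {g: i for i, g in enumerate(genes)}
    classification = classification_for(config)

    baseline = rng_baseline.normal(
        config.baseline_mean, config.baseline_sd, config.n_genes
    ).clip(min=0.0)
    for gene, mu in config.baseline_overrides.items():
        baseline[gene_index[gene]] = mu

    samples = _assign_annotation(config, rng_annotation)
    sample_ids = samples.sample_ids
    aml_mask = np.array(
        [samples.frame.loc[s, "cohort"] == COHORT_AML for s in sample_ids]
    )

    effects = np.zeros((config.n_genes, len(sample_ids)))
    for gene, delta in (*config.planted_up, *config.planted_down):
        effects[gene_index[gene], aml_mask] += delta
    for subgroup, gene, delta in config.planted_subgroup_effects:
        member = np.array(
            [
                subgroup in samples.frame.loc[s, "subgroup_flags"]
                for s in sample_ids
            ]
        )
        effects[gene_index[gene], member] += delta

    lvalues = (
        baseline[:, None]
        + effects
        + rng_noise.normal(0.0, config.noise_sd, effects.shape)
    ).clip(min=0.0)
    rpkm = (np.exp2(lvalues) - 1.0).clip(min=0.0)
    matrix = ExpressionMatrix(
        pd.DataFrame(rpkm, index=pd.Index(genes, name="gene_id"),
                     columns=sample_ids)
    )
    truth = GroundTruth(
        planted_up=dict(config.planted_up),
        planted_down=dict(config.planted_down),
        subgroup_effects=config.planted_subgroup_effects,
        biased_subfamilies=tuple(sorted(config.planted_family_bias)),
    )
    return matrix, samples, classification, truth


def config_from_dict(data: Mapping[str, object], seed: int | None = None) -> SimulationConfig:
    """Build a config from a flat key-value mapping (e.g. parsed YAML).

    Unknown keys raise; list-valued planted fields accept [gene, delta]
    pairs / [subgroup, gene, delta] triples.  ``seed`` overrides any seed in
    the mapping.
    """
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown simulation config key(s): {sorted(unknown)}")
    kwargs: dict[str, object] = dict(data)
    if "planted_up" in kwargs:
        kwargs["planted_up"] = tuple(
            (str(g), float(d)) for g, d in kwargs["planted_up"]  # type: ignore[union-attr]
        )
    if "planted_down" in kwargs:
        kwargs["planted_down"] = tuple(
            (str(g), float(d)) for g, d in kwargs["planted_down"]  # type: ignore[union-attr]
        )
    if "planted_subgroup_effects" in kwargs:
        kwargs["planted_subgroup_effects"] = tuple(
            (str(s), str(g), float(d))
            for s, g, d in kwargs["planted_subgroup_effects"]  # type: ignore[union-attr]
        )
    if seed is not None:
        kwargs["seed"] = seed
    return SimulationConfig(**kwargs)  # type: ignore[arg-type]
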