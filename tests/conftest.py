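"""Shared fixtures: tiny hand-built tables and one small simulated cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gpcrscreen import simulate, transform
from gpcrscreen.datamodel import (
    ExpressionMatrix,
    LogExpressionMatrix,
    SampleTable,
    SubfamilyClassification,
)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with easy-to-log RPKM values."""
    frame = pd.DataFrame(
        [[0.0, 1.0, 3.0, 7.0],
         [15.0, 15.0, 15.0, 15.0],
         [0.0, 0.0, 1.0, 3.0]],
        index=pd.Index(["GA", "GB", "GC"], name="gene_id"),
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(frame)


@pytest.fixture
def tiny_log(tiny_matrix) -> LogExpressionMatrix:
    return transform.log_transform(tiny_matrix)


@pytest.fixture
def tiny_samples() -> SampleTable:
    frame = pd.DataFrame(
        {
            "cohort": ["AML", "AML", "AML", "CD34_reference",
                       "CD34_reference", "normal_population:wbc",
                       "normal_population:wbc"],
            "subgroup_flags": [frozenset({"NPM1"}), frozenset({"NPM1"}),
                               frozenset(), frozenset(), frozenset(),
                               frozenset(), frozenset()],
            "karyotype": ["normal", "normal", "normal", "normal",
                          "normal", "normal", "normal"],
        },
        index=pd.Index(["a1", "a2", "a3", "r1", "r2", "w1", "w2"],
                       name="sample_id"),
    )
    return SampleTable(frame)


@pytest.fixture
def tiny_classification() -> SubfamilyClassification:
    return SubfamilyClassification(
        {"GA": "chemokine", "GB": "adhesion", "GC": "chemokine"}
    )


@pytest.fixture(scope="session")
def small_config() -> simulate.SimulationConfig:
    """A scaled-down cohort (60 genes over 3 subfamilies, 40 AML vs 8
    reference) that keeps every pipeline stage exercised but fast."""
    base = simulate.SimulationConfig(
        n_genes=60,
        subfamily_sizes={"chemokine": 20, "adhesion": 20, "orphan": 20},
        n_aml=40,
        n_reference=8,
        normal_populations={"wbc": 3, "t_cells": 3},
        subgroup_prevalences={"t_8_21": 0.25, "NPM1": 0.5},
        seed=11,
    )
    planted_up = tuple((f"chemokine_{i:03d}", 2.0) for i in (1, 2, 3))
    planted_down = (("adhesion_001", -2.0),)
    overrides = {"adhesion_001": 5.0, "orphan_005": 1.0, "adhesion_010": 5.0}
    return simulate.SimulationConfig(
        n_genes=60,
        subfamily_sizes=base.subfamily_sizes,
        n_aml=40,
        n_reference=8,
        normal_populations=base.normal_populations,
        subgroup_prevalences=base.subgroup_prevalences,
        planted_up=planted_up,
        planted_down=planted_down,
        planted_subgroup_effects=(
            ("t_8_21", "orphan_005", 2.5),
            ("NPM1", "adhesion_010", -2.5),
        ),
        baseline_overrides=overrides,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate.generate(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
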