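"""Subgroup fingerprints, t-test, cross-cohort validation and nomination."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gpcrscreen import fingerprint as fp
from gpcrscreen import simulate, transform
from gpcrscreen.datamodel import LogExpressionMatrix, SampleTable, ValidationError


def _lmatrix(rows, samples):
    return LogExpressionMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    )


class TestStudentT:
    def test_identical_samples_give_t0_p1(self):
        result = fp.student_t_two_sample([1, 2, 3], [1, 2, 3])
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)
        assert not result.degenerate

    def test_closed_form_separated_groups(self):
        """Means 5 vs 3, pooled sd 0.1581, n=5 each: t=20 with df=8."""
        result = fp.student_t_two_sample(
            [5.1, 4.9, 5.0, 5.2, 4.8], [3.1, 2.9, 3.0, 3.2, 2.8]
        )
        assert result.statistic == pytest.approx(20.0, rel=1e-9)
        assert result.p_value == pytest.approx(2 * stats.t.sf(20.0, 8), rel=1e-9)
        assert result.p_value < 1e-6

    def test_zero_pooled_variance_flagged_degenerate(self):
        result = fp.student_t_two_sample([1, 1, 1], [1, 1, 1])
        assert result.degenerate
        assert np.isnan(result.statistic) and np.isnan(result.p_value)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            fp.student_t_two_sample([1.0], [1.0, 2.0])

    @pytest.mark.parametrize("equal_var", [True, False])
    def test_matches_scipy_on_random_data(self, rng, equal_var):
        for _ in range(25):
            x = rng.normal(0, 1, rng.integers(2, 12))
            y = rng.normal(0.5, 1.6, rng.integers(2, 12))
            mine = fp.student_t_two_sample(x, y, equal_var=equal_var)
            ref = stats.ttest_ind(x, y, equal_var=equal_var)
            assert mine.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-10)


def _two_group_table(n_with: int, n_without: int) -> SampleTable:
    ids = [f"a{i}" for i in range(n_with + n_without)]
    flags = [frozenset({"NPM1"})] * n_with + [frozenset()] * n_without
    frame = pd.DataFrame(
        {
            "cohort": ["AML"] * len(ids),
            "subgroup_flags": flags,
            "karyotype": ["normal"] * len(ids),
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return SampleTable(frame)


class TestFingerprint:
    def test_planted_shift_flagged_up(self, rng):
        samples = _two_group_table(15, 100)
        base = rng.normal(3.0, 0.3, 115)
        shifted = base + np.r_[np.full(15, 2.0), np.zeros(100)]
        lm = _lmatrix({"hit": shifted, "nul": base}, samples.sample_ids)
        out = fp.fingerprint(lm, samples, "NPM1")
        assert out["gene_id"].tolist() == ["hit"]
        assert out.iloc[0]["direction"] == "up"
        assert out.iloc[0]["delta_mean"] == pytest.approx(2.0, abs=0.4)

    def test_significant_but_small_shift_gated_by_delta(self, rng):
        """p << 0.05 but delta < 1.5 lRPKM: the magnitude gate blocks it."""
        samples = _two_group_table(15, 100)
        base = rng.normal(3.0, 0.01, 115)
        shifted = base + np.r_[np.full(15, 1.0), np.zeros(100)]
        lm = _lmatrix({"small": shifted}, samples.sample_ids)
        assert fp.fingerprint(lm, samples, "NPM1").empty

    def test_threshold_endpoints_behave_as_limits(self, rng):
        samples = _two_group_table(10, 20)
        rows = {f"g{i}": rng.normal(2, 1, 30).clip(0) for i in range(8)}
        lm = _lmatrix(rows, samples.sample_ids)
        everything = fp.fingerprint(lm, samples, "NPM1", delta_mean=0.0, alpha=1.1)
        assert len(everything) == 8
        nothing = fp.fingerprint(lm, samples, "NPM1", delta_mean=np.inf)
        assert nothing.empty

    def test_small_subgroup_rejected_with_label(self, rng):
        samples = _two_group_table(1, 30)
        lm = _lmatrix({"g": rng.normal(2, 1, 31)}, samples.sample_ids)
        with pytest.raises(ValidationError, match="NPM1"):
            fp.fingerprint(lm, samples, "NPM1")

    def test_mutation_subgroup_scoped_to_normal_karyotype(self, small_cohort):
        matrix, samples, _, _ = small_cohort
        scope = fp.default_scope(samples, "NPM1")
        assert set(scope) == set(samples.normal_karyotype_aml())
        scope_cyto = fp.default_scope(samples, "t_8_21")
        assert set(scope_cyto) == set(samples.aml_samples())

    def test_recovery_monotone_in_planted_shift(self):
        """Recovery of planted genes never falls as the shift grows."""
        recovered = []
        for delta in (1.5, 2.0, 3.0):
            hits = 0
            for seed in range(6):
                rng = np.random.default_rng(seed)
                samples = _two_group_table(15, 100)
                base = rng.normal(3.0, 0.5, 115)
                shifted = base + np.r_[np.full(15, delta), np.zeros(100)]
                lm = _lmatrix({"hit": shifted}, samples.sample_ids)
                hits += not fp.fingerprint(lm, samples, "NPM1").empty
            recovered.append(hits)
        assert recovered[0] <= recovered[1] <= recovered[2]


class TestCrossValidate:
    @staticmethod
    def _records(rows):
        return pd.DataFrame(
            rows, columns=["subgroup", "gene_id", "direction"]
        ).assign(validated=False)

    def test_same_direction_validates(self):
        first = self._records([("inv16", "G1", "up")])
        second = self._records([("inv16", "G1", "up")])
        assert fp.cross_validate(first, second)["validated"].tolist() == [True]

    def test_opposite_direction_does_not_validate(self):
        first = self._records([("inv16", "G1", "up")])
        second = self._records([("inv16", "G1", "down")])
        assert fp.cross_validate(first, second)["validated"].tolist() == [False]

    def test_absent_from_secondary_does_not_validate(self):
        first = self._records([("inv16", "G1", "up"), ("MLL", "G2", "down")])
        second = self._records([("MLL", "G2", "down")])
        assert fp.cross_validate(first, second)["validated"].tolist() == [False, True]

    def test_symmetric_in_detection(self, small_cohort, small_config):
        """Swapping cohorts yields the same validated triples."""
        matrix, samples, _, _ = small_cohort
        lm = transform.log_transform(matrix)
        m2, s2, _, _ = simulate.generate(replace(small_config, seed=99))
        lm2 = transform.log_transform(m2)
        first = fp.fingerprint_all(lm, samples)
        second = fp.fingerprint_all(lm2, s2)

        def triples(validated):
            keep = validated[validated["validated"]]
            return {(r.subgroup, r.gene_id, r.direction) for r in keep.itertuples()}

        assert triples(fp.cross_validate(first, second)) == triples(
            fp.cross_validate(second, first)
        )


class TestNominate:
    def test_planted_candidate_above_every_population(self, small_cohort):
        matrix, samples, _, truth = small_cohort
        lm = transform.log_transform(matrix)
        records = fp.fingerprint_all(lm, samples)
        out = fp.nominate_targets(lm, samples, records)
        planted_up = {
            (s, g) for s, g, d in truth.subgroup_effects if d > 0
        }
        nominated = {
            (r.subgroup, r.gene_id) for r in out.itertuples() if r.nominated
        }
        assert planted_up <= nominated

    def test_candidate_level_with_population_not_nominated(self, rng):
        ids = [f"a{i}" for i in range(10)] + ["w1", "w2", "w3"]
        frame = pd.DataFrame(
            {
                "cohort": ["AML"] * 10 + ["normal_population:wbc"] * 3,
                "subgroup_flags": [frozenset({"NPM1"})] * 5
                + [frozenset()] * 8,
                "karyotype": ["normal"] * 13,
            },
            index=pd.Index(ids, name="sample_id"),
        )
        samples = SampleTable(frame)
        # subgroup mean ~5, complement ~2 (fingerprint fires), wbc also ~5
        values = np.r_[rng.normal(5, 0.2, 5), rng.normal(2, 0.2, 5),
                       rng.normal(5, 0.2, 3)]
        lm = _lmatrix({"g": values}, ids)
        records = fp.fingerprint(lm, samples, "NPM1")
        assert not records.empty
        out = fp.nominate_targets(lm, samples, records)
        assert out["nominated"].tolist() == [False]

    def test_empty_fingerprints_give_empty_output(self, small_cohort):
        matrix, samples, _, _ = small_cohort
        lm = transform.log_transform(matrix)
        empty = fp.fingerprint_all(lm, samples).iloc[0:0]
        out = fp.nominate_targets(lm, samples, empty)
        assert out.empty and "nominated" in out.columns

    def test_unknown_population_rejected(self, small_cohort):
        matrix, samples, _, _ = small_cohort
        lm = transform.log_transform(matrix)
        records = fp.fingerprint_all(lm, samples)
        with pytest.raises(ValidationError, match="erythroid"):
            fp.nominate_targets(lm, samples, records, populations=["erythroid"])


def test_null_cohort_produces_no_fingerprints():
    """With no planted subgroup effects the delta >= 1.5 gate keeps the
    flagged fraction essentially at zero."""
    flagged = 0
    total = 0
    for seed in range(3):
        config = simulate.SimulationConfig(seed=seed)
        matrix, samples, _, _ = simulate.generate(config)
        lm = transform.log_transform(matrix)
        records = fp.fingerprint_all(lm, samples)
        flagged += len(records)
        total += len(lm.gene_ids) * len(samples.subgroup_labels())
    assert flagged / total < 0.005
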