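"""Profiling, configuration combinatorics, categorisation and the
one-population-absence decision test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from evimpute.matrix_io import SampleDesign
from evimpute.missingness import (
    MnarDecision,
    VariableCategory,
    category_counts,
    classify_variables,
    enumerate_configurations,
    fisher_exact_two_sided,
    mnar_enrichment_test,
    profile_variable,
)

from conftest import make_matrix

NA = np.nan


def brute_force_configurations(k: int, p: int):
    """Oracle: enumerate all C(2p, k) placements explicitly."""
    total = one_pop = 0
    for pos in itertools.combinations(range(2 * p), k):
        total += 1
        if k >= 1 and (all(i < p for i in pos) or all(i >= p for i in pos)):
            one_pop += 1
    return total, one_pop


class TestProfileVariable:
    def test_one_population_missing(self, design3):
        m = make_matrix([[NA, NA, NA, 12, 9, 14]], design3)
        prof = profile_variable(m.data.iloc[0], design3)
        assert prof.n_missing_total == 3
        assert prof.n_missing_by_population == (3, 0)

    def test_complete_row(self, design3):
        m = make_matrix([[1, 2, 3, 4, 5, 6]], design3)
        prof = profile_variable(m.data.iloc[0], design3)
        assert prof.n_missing_total == 0
        assert prof.n_missing_by_population == (0, 0)

    def test_spread_four(self, design3):
        m = make_matrix([[NA, 2, NA, 3, NA, NA]], design3)
        prof = profile_variable(m.data.iloc[0], design3)
        assert prof.n_missing_total == 4
        assert prof.n_missing_by_population == (2, 2)

    def test_wrong_length_rejected(self, design3):
        with pytest.raises(ValueError):
            profile_variable(pd.Series([1.0, 2.0]), design3)


class TestEnumerateConfigurations:
    def test_three_of_six(self):
        cfg = enumerate_configurations(3, 3)
        assert (cfg.total, cfg.one_population) == (20, 2)
        assert cfg.one_population_fraction == pytest.approx(0.10)

    def test_single_missing_always_one_population(self):
        cfg = enumerate_configurations(1, 3)
        assert (cfg.total, cfg.one_population) == (6, 6)

    def test_four_of_eight(self):
        cfg = enumerate_configurations(4, 4)
        assert (cfg.total, cfg.one_population) == (70, 2)

    @pytest.mark.parametrize("p", range(1, 7))
    def test_matches_brute_force_all_k(self, p):
        for k in range(0, 2 * p + 1):
            cfg = enumerate_configurations(k, p)
            assert (cfg.total, cfg.one_population) == brute_force_configurations(k, p)

    @pytest.mark.parametrize("k,p", [(-1, 3), (7, 3), (1, 0)])
    def test_out_of_range(self, k, p):
        with pytest.raises(ValueError):
            enumerate_configurations(k, p)


class TestClassifyVariables:
    def test_paper_style_rows(self, design3):
        m = make_matrix(
            [
                [NA, NA, NA, 12, 9, 14],   # one population absent
                [NA, 2, NA, 3, NA, NA],    # k=4 -> excluded
                [1, 2, 3, 4, 5, 6],        # complete
                [NA, 2, 3, 4, 5, 6],       # k=1 -> imputable
            ],
            design3,
        )
        cats = classify_variables(m)
        assert cats["P0"] is VariableCategory.ONE_POP_ALL_MISSING
        assert cats["P1"] is VariableCategory.EXCLUDED
        assert cats["P2"] is VariableCategory.COMPLETE
        assert cats["P3"] is VariableCategory.IMPUTABLE

    def test_counts_sum_to_total(self, synthetic_standard):
        cats = classify_variables(synthetic_standard.matrix)
        assert sum(category_counts(cats).values()) == synthetic_standard.matrix.n_proteins

    def test_threshold_strictness_eight_samples(self):
        design4 = SampleDesign.from_populations(
            {"A": ["A1", "A2", "A3", "A4"], "B": ["B1", "B2", "B3", "B4"]}
        )
        retained = make_matrix([[NA, NA, NA, NA, 1, 2, 3, 4]], design4)  # k=4 of 8
        excluded = make_matrix([[NA, NA, NA, NA, NA, 2, 3, 4]], design4)  # k=5 of 8
        assert classify_variables(retained)["P0"] is VariableCategory.ONE_POP_ALL_MISSING
        assert classify_variables(excluded)["P0"] is VariableCategory.EXCLUDED

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_fraction(self, worked_example, bad):
        with pytest.raises(ValueError):
            classify_variables(worked_example, bad)

    def test_monotone_in_threshold(self, synthetic_standard):
        m = synthetic_standard.matrix
        retained_counts = []
        for f in (0.2, 0.35, 0.5, 0.65, 0.8):
            cats = classify_variables(m, f)
            retained_counts.append(
                sum(1 for c in cats.values() if c is not VariableCategory.EXCLUDED)
            )
        assert retained_counts == sorted(retained_counts)

    def test_within_population_permutation_invariance(self, design3):
        rng = np.random.RandomState(5)
        rows = np.where(rng.random((40, 6)) < 0.3, NA, rng.lognormal(2, 1, (40, 6)))
        m = make_matrix(rows.tolist(), design3)
        cats = classify_variables(m)
        # permute sample order inside each population
        perm = ["A3", "A1", "A2", "B2", "B3", "B1"]
        permuted = make_matrix(m.data[perm].to_numpy().tolist(), design3)
        assert classify_variables(permuted) == cats
        assert (
            mnar_enrichment_test(permuted).to_dict() == mnar_enrichment_test(m).to_dict()
        )


class TestFisherExact:
    def test_symmetric_table_is_one(self):
        assert fisher_exact_two_sided([[10, 90], [10, 90]]) == 1.0

    def test_extreme_table_tiny(self):
        assert fisher_exact_two_sided([[96, 4], [10, 90]]) < 1e-4

    def test_zero_table(self):
        assert fisher_exact_two_sided([[0, 0], [0, 0]]) == 1.0

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided([[-1, 2], [3, 4]])

    def test_oracle_agreement_small_tables(self):
        rng = np.random.RandomState(0)
        for _ in range(400):
            a, b, c, d = (int(x) for x in rng.randint(0, 100, size=4))
            mine = fisher_exact_two_sided([[a, b], [c, d]])
            ref = min(stats.fisher_exact([[a, b], [c, d]])[1], 1.0)
            assert mine == pytest.approx(ref, abs=1e-12)

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    @settings(max_examples=60, deadline=None)
    def test_oracle_agreement_property(self, a, b, c, d):
        mine = fisher_exact_two_sided([[a, b], [c, d]])
        assert 0 < mine <= 1
        ref = min(stats.fisher_exact([[a, b], [c, d]])[1], 1.0)
        assert mine == pytest.approx(ref, abs=1e-12)


class TestMnarEnrichmentTest:
    def _matrix_with_split(self, design3, n_one_pop, n_spread, n_complete=5):
        rows = []
        for i in range(n_one_pop):
            side_a = i % 2 == 0
            rows.append([NA] * 3 + [5.0, 6.0, 7.0] if side_a else [5.0, 6.0, 7.0] + [NA] * 3)
        for i in range(n_spread):
            rows.append([NA, 5.0, NA, 6.0, NA, 7.0])  # 2|1 split, k=3
        rows += [[4.0, 5.0, 6.0, 7.0, 8.0, 9.0]] * n_complete
        return make_matrix(rows, design3)

    def test_strong_excess_replaces(self, design3):
        m = self._matrix_with_split(design3, 96, 4)
        res = mnar_enrichment_test(m)
        assert (res.observed_one_pop, res.observed_spread) == (96, 4)
        assert res.p_value < 1e-4
        assert res.decision is MnarDecision.REPLACE

    def test_exactly_expected_imputes(self, design3):
        m = self._matrix_with_split(design3, 10, 90)
        res = mnar_enrichment_test(m)
        assert res.table == ((10, 90), (10, 90))
        assert res.p_value == 1.0
        assert res.decision is MnarDecision.IMPUTE

    def test_depletion_never_replaces(self, design3):
        m = self._matrix_with_split(design3, 0, 100)
        res = mnar_enrichment_test(m)
        assert res.observed_fraction < res.expected_probability
        assert res.decision is MnarDecision.IMPUTE

    def test_empty_returns_impute_with_warning(self, design3):
        m = make_matrix([[1, 2, 3, 4, 5, 6]], design3)
        res = mnar_enrichment_test(m)
        assert res.empty
        assert res.p_value == 1.0
        assert res.decision is MnarDecision.IMPUTE

    def test_expected_counts_round_half_up(self, design3):
        # N=15, q=0.1 -> 1.5 rounds up to 2
        m = self._matrix_with_split(design3, 5, 10)
        res = mnar_enrichment_test(m)
        assert res.table[1] == (2, 13)
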