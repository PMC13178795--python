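"""Per-protein missingness profiling, configuration combinatorics, variable
categorisation and the one-population-absence (MNAR) decision test.

The central question answered here: among retained proteins with exactly
``p`` missing values (one replicate count's worth), do significantly more
of them have all ``p`` missing cells confined to a single population than
the placement combinatorics predict?  If yes, those proteins are treated
as absent from that population and floor-replaced; otherwise they join the
random-forest imputation pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrix_io import AbundanceMatrix, SampleDesign

__all__ = [
    "VariableCategory",
    "MnarDecision",
    "MissingnessProfile",
    "ConfigurationCount",
    "MnarTestResult",
    "profile_variable",
    "profile_matrix",
    "enumerate_configurations",
    "classify_variables",
    "fisher_exact_two_sided",
    "mnar_enrichment_test",
]


class VariableCategory(str, Enum):
    """Mutually exclusive handling category of one protein (variable)."""

    COMPLETE = "complete"
    IMPUTABLE = "imputable"
    ONE_POP_ALL_MISSING = "one_pop_all_missing"
    EXCLUDED = "excluded"


class MnarDecision(str, Enum):
    REPLACE = "replace"
    IMPUTE = "impute"


@dataclass(frozen=True)
class MissingnessProfile:
    """Missing-value counts for one protein, total and per population."""

    protein_id: str
    n_missing_total: int
    n_missing_by_population: Tuple[int, int]

    def __post_init__(self) -> None:
        if self.n_missing_total != sum(self.n_missing_by_population):
            raise ValueError("per-population counts must sum to the total")


@dataclass(frozen=True)
class ConfigurationCount:
    """Counting of distinct placements of ``k`` missing cells over ``2p``
    labelled samples split into two populations of ``p``."""

    k: int
    p: int
    total: int
    one_population: int

    @property
    def one_population_fraction(self) -> float:
        return self.one_population / self.total


@dataclass(frozen=True)
class MnarTestResult:
    observed_one_pop: int
    observed_spread: int
    expected_probability: float
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    p_value: float
    decision: MnarDecision
    empty: bool = False

    @property
    def observed_fraction(self) -> float:
        n = self.observed_one_pop + self.observed_spread
        return self.observed_one_pop / n if n else float("nan")

    def to_dict(self) -> dict:
        return {
            "observed_one_pop": self.observed_one_pop,
            "observed_spread": self.observed_spread,
            "expected_probability": self.expected_probability,
            "table": [list(r) for r in self.table],
            "p_value": self.p_value,
            "decision": self.decision.value,
            "empty": self.empty,
        }


def profile_variable(row: pd.Series, design: SampleDesign, protein_id: str = "") -> MissingnessProfile:
    """Count missing cells of one protein row, split by population."""
    if len(row) != len(design.sample_ids):
        raise ValueError("row length does not match the design")
    pop_a, pop_b = design.populations
    k_a = int(row[list(design.samples_in(pop_a))].isna().sum())
    k_b = int(row[list(design.samples_in(pop_b))].isna().sum())
    pid = protein_id or str(row.name)
    return MissingnessProfile(pid, k_a + k_b, (k_a, k_b))


def profile_matrix(matrix: AbundanceMatrix) -> Dict[str, MissingnessProfile]:
    """Vectorised :func:`profile_variable` over all proteins."""
    design = matrix.design
    pop_a, pop_b = design.populations
    na = matrix.data.isna()
    k_a = na[list(design.samples_in(pop_a))].sum(axis=1).astype(int)
    k_b = na[list(design.samples_in(pop_b))].sum(axis=1).astype(int)
    return {
        str(pid): MissingnessProfile(str(pid), int(a + b), (int(a), int(b)))
        for pid, a, b in zip(matrix.data.index, k_a, k_b)
    }


def enumerate_configurations(k: int, p: int) -> ConfigurationCount:
    """Closed-form placement counts for ``k`` missing cells in ``2p`` samples.

    ``total`` counts all distinct placements, ``C(2p, k)``; ``one_population``
    counts placements with every missing cell inside a single population,
    ``2 * C(p, k)`` for ``1 <= k <= p`` and ``0`` otherwise.
    """
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    if not 0 <= k <= 2 * p:
        raise ValueError(f"k must be in [0, {2 * p}], got {k}")
    total = math.comb(2 * p, k)
    one_population = 2 * math.comb(p, k) if 1 <= k <= p else 0
    return ConfigurationCount(k=k, p=p, total=total, one_population=one_population)


def classify_variables(
    matrix: AbundanceMatrix,
    exclusion_fraction: float = 0.5,
) -> Dict[str, VariableCategory]:
    """Assign every protein its handling category.

    EXCLUDED iff the missing fraction strictly exceeds ``exclusion_fraction``
    (with 6 samples at the default 0.5 this removes proteins with >= 4
    missing cells).  Among retained proteins: COMPLETE when nothing is
    missing, ONE_POP_ALL_MISSING when one population is entirely missing
    and the other complete, IMPUTABLE otherwise.
    """
    if not 0 < exclusion_fraction < 1:
        raise ValueError("exclusion_fraction must lie strictly between 0 and 1")
    p = matrix.design.n_per_population
    n = 2 * p
    out: Dict[str, VariableCategory] = {}
    for pid, prof in profile_matrix(matrix).items():
        k_a, k_b = prof.n_missing_by_population
        k = prof.n_missing_total
        if k / n > exclusion_fraction:
            out[pid] = VariableCategory.EXCLUDED
        elif k == 0:
            out[pid] = VariableCategory.COMPLETE
        elif (k_a == p and k_b == 0) or (k_a == 0 and k_b == p):
            out[pid] = VariableCategory.ONE_POP_ALL_MISSING
        else:
            out[pid] = VariableCategory.IMPUTABLE
    return out


def category_counts(categories: Mapping[str, VariableCategory]) -> Dict[str, int]:
    counts = {c.value: 0 for c in VariableCategory}
    for cat in categories.values():
        counts[cat.value] += 1
    return counts


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value by direct hypergeometric summation.

    All tables with the observed margins whose point probability does not
    exceed the observed table's are summed.  Probabilities share the common
    denominator ``C(n, m)``, so the summation and the tie comparison are
    carried out in exact integer arithmetic.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0
    r = a + b          # first row margin
    m = a + c          # first column margin
    lo = max(0, m - (n - r))
    hi = min(r, m)
    numerators = [math.comb(r, x) * math.comb(n - r, m - x) for x in range(lo, hi + 1)]
    observed = numerators[a - lo]
    kept = sum(v for v in numerators if v <= observed)
    return float(min(Fraction(kept, math.comb(n, m)), Fraction(1)))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def mnar_enrichment_test(
    matrix: AbundanceMatrix,
    categories: Optional[Mapping[str, VariableCategory]] = None,
    alpha: float = 0.05,
    exclusion_fraction: float = 0.5,
) -> MnarTestResult:
    """Decide whether one-population-absent proteins are floor-replaced.

    Among retained proteins with exactly ``p`` missing values, the observed
    split (all-in-one-population vs spread) is compared against the chance
    expectation ``q = 2 / C(2p, p)`` via a 2x2 observed-vs-expected
    Fisher exact test.  Decision is REPLACE iff ``p_value < alpha`` *and*
    the observed one-population fraction exceeds ``q`` (so depletion never
    triggers replacement).
    """
    if categories is None:
        categories = classify_variables(matrix, exclusion_fraction)
    p = matrix.design.n_per_population
    config = enumerate_configurations(p, p)
    q = config.one_population_fraction
    profiles = profile_matrix(matrix)

    one_pop = spread = 0
    for pid, cat in categories.items():
        if cat is VariableCategory.EXCLUDED:
            continue
        if profiles[pid].n_missing_total == p:
            if cat is VariableCategory.ONE_POP_ALL_MISSING:
                one_pop += 1
            else:
                spread += 1

    n_total = one_pop + spread
    if n_total == 0:
        return MnarTestResult(
            observed_one_pop=0,
            observed_spread=0,
            expected_probability=q,
            table=((0, 0), (0, 0)),
            p_value=1.0,
            decision=MnarDecision.IMPUTE,
            empty=True,
        )

    expected_one = _round_half_up(q * n_total)
    table = ((one_pop, spread), (expected_one, n_total - expected_one))
    p_value = fisher_exact_two_sided(table)
    replace = p_value < alpha and (one_pop / n_total) > q
    return MnarTestResult(
        observed_one_pop=one_pop,
        observed_spread=spread,
        expected_probability=q,
        table=table,
        p_value=p_value,
        decision=MnarDecision.REPLACE if replace else MnarDecision.IMPUTE,
    )
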