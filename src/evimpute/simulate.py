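"""Synthetic two-population abundance matrices with controlled missingness.

Per-category protein counts are honoured exactly: complete rows, rows
with 1..p missing cells spread so that no population is entirely empty,
rows with one population fully censored (low-abundance dropout), and
heavily-missing rows destined for exclusion.  The pre-masking truth is
returned alongside, enabling imputation-error and recovery checks.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .matrix_io import AbundanceMatrix, SampleDesign
from .missingness import VariableCategory

__all__ = ["SyntheticSpec", "SyntheticData", "generate_matrix", "worked_example_matrix"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic matrix.

    Abundances are log-normal: a per-protein level ``mu + sigma*z`` plus
    per-cell noise ``noise_sigma*z`` on the natural-log scale, so smaller
    ``noise_sigma`` means stronger between-sample correlation.
    """

    n_complete: int = 100
    n_imputable: int = 60
    n_one_pop: int = 30
    n_excluded: int = 20
    p: int = 3
    mu: float = 8.0
    sigma: float = 1.2
    noise_sigma: float = 0.25
    n_differential: int = 0
    effect_log2: float = 2.0
    censor_threshold: float = 50.0
    mcar_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_complete", "n_imputable", "n_one_pop", "n_excluded"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.p < 2:
            raise ValueError("p must be >= 2")
        if not 0 <= self.mcar_rate < 1:
            raise ValueError("mcar_rate must lie in [0, 1)")
        if self.n_differential > self.n_complete:
            raise ValueError("n_differential cannot exceed n_complete")
        if self.censor_threshold <= 0:
            raise ValueError("censor_threshold must be positive")

    @property
    def n_total(self) -> int:
        return self.n_complete + self.n_imputable + self.n_one_pop + self.n_excluded

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticData:
    matrix: AbundanceMatrix
    truth: pd.DataFrame
    categories: Dict[str, VariableCategory]
    spec: SyntheticSpec


def _default_design(p: int) -> SampleDesign:
    return SampleDesign.from_populations(
        {"A": [f"A{i+1}" for i in range(p)], "B": [f"B{i+1}" for i in range(p)]}
    )


def _spread_positions(rng: np.random.RandomState, k: int, p: int) -> np.ndarray:
    """k cell positions over 2p samples, never a full single population."""
    while True:
        pos = rng.choice(2 * p, size=k, replace=False)
        if k == p and (np.all(pos < p) or np.all(pos >= p)):
            continue
        return np.sort(pos)


def generate_matrix(spec: SyntheticSpec) -> SyntheticData:
    """Draw abundances and plant the requested missingness structure."""
    rng = np.random.RandomState(spec.seed)
    design = _default_design(spec.p)
    p = spec.p
    n = spec.n_total
    if n == 0:
        raise ValueError("spec produces an empty matrix")

    ids = [f"P{i:05d}" for i in range(n)]
    level = spec.mu + spec.sigma * rng.standard_normal(n)
    noise = spec.noise_sigma * rng.standard_normal((n, 2 * p))
    truth = np.exp(level[:, None] + noise)

    planned: List[VariableCategory] = (
        [VariableCategory.COMPLETE] * spec.n_complete
        + [VariableCategory.IMPUTABLE] * spec.n_imputable
        + [VariableCategory.ONE_POP_ALL_MISSING] * spec.n_one_pop
        + [VariableCategory.EXCLUDED] * spec.n_excluded
    )

    # population effect on the first n_differential complete proteins
    for i in range(spec.n_differential):
        truth[i, p:] *= 2.0 ** spec.effect_log2

    mask = np.zeros((n, 2 * p), dtype=bool)
    for i, cat in enumerate(planned):
        if cat is VariableCategory.COMPLETE:
            continue
        if cat is VariableCategory.ONE_POP_ALL_MISSING:
            side = int(rng.randint(2))  # 0 -> first population censored
            cols = slice(0, p) if side == 0 else slice(p, 2 * p)
            # abundance-dependent dropout: the censored side truly sits low
            truth[i, cols] = rng.uniform(1.0, spec.censor_threshold, size=p)
            mask[i, cols] = True
        elif cat is VariableCategory.IMPUTABLE:
            k = 1 + int(rng.binomial(p - 1, spec.mcar_rate))
            mask[i, _spread_positions(rng, k, p)] = True
        else:  # EXCLUDED: more than half missing, at least one observed
            k = int(rng.randint(p + 1, 2 * p))
            mask[i, rng.choice(2 * p, size=k, replace=False)] = True

    order = rng.permutation(n)
    truth = truth[order]
    mask = mask[order]
    planned = [planned[i] for i in order]

    observed = truth.copy()
    observed[mask] = np.nan
    columns = list(design.sample_ids)
    index = pd.Index(ids, name="protein")
    matrix = AbundanceMatrix(pd.DataFrame(observed, index=index, columns=columns), design)
    truth_df = pd.DataFrame(truth, index=index, columns=columns)
    categories = dict(zip(ids, planned))
    return SyntheticData(matrix=matrix, truth=truth_df, categories=categories, spec=spec)


def worked_example_matrix() -> AbundanceMatrix:
    """Six-sample toy matrix covering every handling branch.

    Rows: a one-population-absent protein, a rescue-eligible excluded
    protein (3 missing in one population plus 1 in the other), an excluded
    protein with a 2|2 split, and three complete fillers.
    """
    design = _default_design(3)
    rows = {
        "EX_ONEPOP": [np.nan, np.nan, np.nan, 12.0, 9.0, 14.0],
        "EX_RESCUE": [np.nan, np.nan, np.nan, 3.0, 2.0, np.nan],
        "EX_SPREAD4": [np.nan, 2.0, np.nan, 3.0, np.nan, np.nan],
        "FILL_1": [10.0, 11.0, 12.0, 9.0, 10.0, 13.0],
        "FILL_2": [5.0, 6.0, 5.5, 5.2, 6.1, 5.8],
        "FILL_3": [100.0, 95.0, 110.0, 20.0, 22.0, 19.0],
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(design.sample_ids))
    df.index.name = "protein"
    return AbundanceMatrix(df, design)
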