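"""The two missing-value handling mechanisms: floor replacement by 1 for
proteins absent from one population, and iterative random-forest
imputation (missForest scheme) for everything else.

Orientation for the forest: proteins are the observations (rows) and
samples are the variables (columns) being imputed — with thousands of
proteins and a handful of samples this is the only direction with enough
rows to fit a regressor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .matrix_io import AbundanceMatrix, SampleDesign
from .missingness import VariableCategory, profile_matrix

__all__ = [
    "FLOOR_VALUE",
    "TAG_OBSERVED",
    "TAG_REPLACED",
    "TAG_IMPUTED",
    "ImputationConfig",
    "ProvenanceMatrix",
    "ImputationContractError",
    "replace_with_floor",
    "mean_initialize",
    "missforest_impute",
    "rescue_one_pop_plus_one",
]

#: Lowest possible count value, substituted for one-population-absent cells.
FLOOR_VALUE = 1.0

TAG_OBSERVED = "observed"
TAG_REPLACED = "replaced"
TAG_IMPUTED = "imputed"


class ImputationContractError(ValueError):
    pass


@dataclass(frozen=True)
class ImputationConfig:
    """Random-forest imputation settings (missForest defaults)."""

    n_trees: int = 100
    max_iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class ProvenanceMatrix:
    """Completed matrix with a per-cell origin tag.

    Tags are ``observed`` (value untouched from the input), ``replaced``
    (floor value 1) or ``imputed`` (random-forest estimate).
    """

    data: pd.DataFrame
    tags: pd.DataFrame
    design: SampleDesign
    seed: Optional[int] = None
    iterations: int = 0

    def __post_init__(self) -> None:
        if self.data.shape != self.tags.shape:
            raise ValueError("values and tags must have identical shape")
        if bool(self.data.isna().to_numpy().any()):
            raise ValueError("provenance matrix must be complete")

    def tag_counts(self) -> Dict[str, int]:
        flat = self.tags.to_numpy().ravel()
        return {t: int((flat == t).sum()) for t in (TAG_OBSERVED, TAG_REPLACED, TAG_IMPUTED)}

    def handling_class(self) -> Dict[str, str]:
        """Per-protein class: complete / replaced / imputed.

        ``replaced`` wins over ``imputed`` for proteins carrying both tag
        kinds (the rescued one-missing-plus-one-population rows).
        """
        out: Dict[str, str] = {}
        for pid in self.data.index:
            row = self.tags.loc[pid]
            if (row == TAG_REPLACED).any():
                out[str(pid)] = "replaced"
            elif (row == TAG_IMPUTED).any():
                out[str(pid)] = "imputed"
            else:
                out[str(pid)] = "complete"
        return out


def replace_with_floor(
    matrix: AbundanceMatrix,
    targets: Iterable[str],
) -> Tuple[AbundanceMatrix, pd.DataFrame]:
    """Replace every missing cell of the target proteins with the floor 1.

    Each target must be in the one-population-all-missing configuration
    (one population entirely missing, the other complete); anything else
    is a contract error.  Returns the updated matrix and the boolean mask
    of replaced cells.
    """
    targets = list(targets)
    p = matrix.design.n_per_population
    profiles = profile_matrix(matrix)
    for pid in targets:
        if pid not in profiles:
            raise ImputationContractError(f"unknown protein {pid!r}")
        k_a, k_b = profiles[pid].n_missing_by_population
        if sorted((k_a, k_b)) != [0, p]:
            raise ImputationContractError(
                f"protein {pid!r} is not all-missing in exactly one population "
                f"(per-population missing counts {k_a}|{k_b})"
            )
    out = matrix.data.copy()
    replaced = pd.DataFrame(False, index=out.index, columns=out.columns)
    for pid in targets:
        row_na = out.loc[pid].isna()
        out.loc[pid, row_na[row_na].index] = FLOOR_VALUE
        replaced.loc[pid, row_na[row_na].index] = True
    return AbundanceMatrix(out, matrix.design), replaced


def mean_initialize(data: pd.DataFrame) -> pd.DataFrame:
    """Fill every missing cell with its column mean over observed cells."""
    return data.fillna(data.mean(axis=0, skipna=True))


def _sweep_delta(new: np.ndarray, old: np.ndarray, mask: np.ndarray) -> float:
    num = float(((new - old)[mask] ** 2).sum())
    den = float((new[mask] ** 2).sum())
    return num / den if den > 0 else 0.0


def missforest_impute(
    matrix: AbundanceMatrix,
    config: Optional[ImputationConfig] = None,
    replaced_mask: Optional[pd.DataFrame] = None,
) -> ProvenanceMatrix:
    """Iterative random-forest imputation of the remaining missing cells.

    Algorithm: (1) mean-initialize all missing cells per column; (2) visit
    columns in ascending order of missing count (ties by column position);
    (3) for each such column fit a random-forest regressor on the rows
    observed in that column, predictors being all other columns in their
    current state, and overwrite the column's missing rows with the forest
    predictions; (4) after each full sweep compute
    ``delta = sum((new - old)^2) / sum(new^2)`` over imputed cells and
    return the *previous* sweep's values the first time delta increases,
    or stop at ``max_iterations``.  Deterministic for a fixed seed.

    ``replaced_mask`` marks cells already floor-replaced upstream; they
    are complete on entry, act as predictor context and keep their
    ``replaced`` tag in the output.
    """
    config = config or ImputationConfig()
    df = matrix.data
    mask = df.isna()
    tags = pd.DataFrame(TAG_OBSERVED, index=df.index, columns=df.columns)
    if replaced_mask is not None:
        tags = tags.mask(replaced_mask.astype(bool), TAG_REPLACED)

    if not bool(mask.to_numpy().any()):
        return ProvenanceMatrix(df.copy(), tags, matrix.design, seed=config.seed, iterations=0)

    tags = tags.mask(mask, TAG_IMPUTED)
    n_missing = mask.sum(axis=0)
    target_cols = [c for c in df.columns if n_missing[c] > 0]
    dead = [c for c in target_cols if n_missing[c] == len(df)]
    if dead:
        raise ImputationContractError(f"columns with zero observed values: {dead}")
    # ascending missing count, ties broken by original column position
    target_cols.sort(key=lambda c: (int(n_missing[c]), list(df.columns).index(c)))

    rng = np.random.RandomState(config.seed)
    current = mean_initialize(df)
    mask_arr = mask.to_numpy()
    prev_delta = np.inf
    kept = current
    iterations = 0

    for sweep in range(1, config.max_iterations + 1):
        previous = current.copy()
        for col in target_cols:
            obs = ~mask[col]
            predictors = current.drop(columns=[col])
            forest = RandomForestRegressor(
                n_estimators=config.n_trees,
                random_state=int(rng.randint(0, 2**31 - 1)),
                n_jobs=1,
            )
            forest.fit(predictors.loc[obs].to_numpy(), current.loc[obs, col].to_numpy())
            current.loc[mask[col], col] = forest.predict(predictors.loc[mask[col]].to_numpy())
        delta = _sweep_delta(current.to_numpy(), previous.to_numpy(), mask_arr)
        if delta > prev_delta:
            kept = previous
            break
        kept = current.copy()
        iterations = sweep
        prev_delta = delta

    return ProvenanceMatrix(kept, tags, matrix.design, seed=config.seed, iterations=iterations)


def rescue_one_pop_plus_one(
    matrix: AbundanceMatrix,
    categories: Dict[str, VariableCategory],
    enabled: bool = False,
) -> Tuple[AbundanceMatrix, Dict[str, VariableCategory], List[str], pd.DataFrame]:
    """Optionally rescue excluded proteins missing a full population plus one.

    A protein excluded with per-population missing counts ``(p, 1)`` (in
    either order) gets its all-missing side floor-replaced by 1 while the
    single remaining missing cell joins the random-forest imputation set;
    its category becomes IMPUTABLE.  Returns the updated matrix, updated
    categories, the rescued protein ids, and the floor-replacement mask.
    """
    replaced = pd.DataFrame(False, index=matrix.data.index, columns=matrix.data.columns)
    if not enabled:
        return matrix, dict(categories), [], replaced

    design = matrix.design
    p = design.n_per_population
    pop_a, pop_b = design.populations
    out = matrix.data.copy()
    cats = dict(categories)
    rescued: List[str] = []
    for pid, prof in profile_matrix(matrix).items():
        if cats.get(pid) is not VariableCategory.EXCLUDED:
            continue
        k_a, k_b = prof.n_missing_by_population
        if sorted((k_a, k_b)) != [1, p]:
            continue
        full_side = pop_a if k_a == p else pop_b
        cols = list(design.samples_in(full_side))
        out.loc[pid, cols] = FLOOR_VALUE
        replaced.loc[pid, cols] = True
        cats[pid] = VariableCategory.IMPUTABLE
        rescued.append(pid)
    return AbundanceMatrix(out, design), cats, rescued, replaced
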