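"""End-to-end orchestration: load -> classify/exclude -> normalize ->
one-population-absence test -> floor replacement -> random-forest
imputation -> final dataset -> differential table."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd

from .differential import build_volcano_table, significant_counts
from .imputation import (
    FLOOR_VALUE,
    ImputationConfig,
    ProvenanceMatrix,
    TAG_REPLACED,
    missforest_impute,
    replace_with_floor,
    rescue_one_pop_plus_one,
)
from .matrix_io import AbundanceMatrix, RunReport
from .missingness import (
    MnarDecision,
    MnarTestResult,
    VariableCategory,
    category_counts,
    classify_variables,
    mnar_enrichment_test,
)
from .normalization import NormalizationFactors, apply_factors, compute_factors

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("evimpute")


@dataclass(frozen=True)
class PipelineConfig:
    """User-tunable settings of one run."""

    exclusion_fraction: float = 0.5
    alpha: float = 0.05
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    rescue: bool = False
    normalize_on: str = "retained"  # factors from retained rows, or "raw"

    def __post_init__(self) -> None:
        if not 0 < self.exclusion_fraction < 1:
            raise ValueError("exclusion_fraction must lie strictly between 0 and 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if self.normalize_on not in {"retained", "raw"}:
            raise ValueError("normalize_on must be 'retained' or 'raw'")


@dataclass
class PipelineResult:
    provenance: ProvenanceMatrix
    report: RunReport
    volcano: pd.DataFrame
    categories: Dict[str, VariableCategory]
    mnar: MnarTestResult
    factors: NormalizationFactors
    rescued: List[str]


def run_pipeline(matrix: AbundanceMatrix, config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Run every stage on an in-memory matrix and return all artifacts.

    The final dataset contains the complete, floor-replaced and imputed
    proteins (raw minus excluded, plus any rescued rows).
    """
    config = config or PipelineConfig()
    design = matrix.design
    p = design.n_per_population

    # 1. categorise on the raw matrix
    categories = classify_variables(matrix, config.exclusion_fraction)
    counts = category_counts(categories)
    log.info("raw dataset: %d proteins (%s)", matrix.n_proteins, counts)

    # 2. decision test on raw missingness counts
    mnar = mnar_enrichment_test(matrix, categories, alpha=config.alpha)
    log.info(
        "one-population-absence test: %d|%d observed, q=%.4f, p=%.3g -> %s",
        mnar.observed_one_pop, mnar.observed_spread,
        mnar.expected_probability, mnar.p_value, mnar.decision.value,
    )

    # 3. optional rescue of (p|1)-split excluded proteins; replacement by 1
    #    is only justified when the absence test passed
    do_rescue = config.rescue and mnar.decision is MnarDecision.REPLACE
    matrix2, categories2, rescued, rescue_mask = rescue_one_pop_plus_one(
        matrix, categories, enabled=do_rescue
    )
    if config.rescue:
        log.info("rescue: %d proteins with a %d|1 missing split recovered", len(rescued), p)

    retained = [pid for pid, c in categories2.items() if c is not VariableCategory.EXCLUDED]
    # keep the original (still-missing) cells here; rescued cells get their
    # floor value only after normalization so that they stay exactly 1
    working = matrix.subset(retained)

    # 4. normalization (factors from the exclusion-filtered matrix by default)
    factor_source = (
        matrix.subset([pid for pid, c in categories.items() if c is not VariableCategory.EXCLUDED])
        if config.normalize_on == "retained"
        else matrix
    )
    factors = compute_factors(factor_source)
    working = apply_factors(working, factors)
    log.info("normalization: factors %s", {k: round(v, 4) for k, v in factors.factors.items()})

    # 5. floor replacement (only when the test justified it)
    replaced_mask = rescue_mask.loc[working.data.index]
    if rescued:
        working = AbundanceMatrix(
            working.data.mask(replaced_mask, FLOOR_VALUE), matrix.design
        )
    if mnar.decision is MnarDecision.REPLACE:
        targets = [pid for pid in retained if categories2[pid] is VariableCategory.ONE_POP_ALL_MISSING]
        working, floor_mask = replace_with_floor(working, targets)
        replaced_mask = replaced_mask | floor_mask
        log.info("floor replacement: %d proteins, %d cells set to 1", len(targets), int(floor_mask.to_numpy().sum()))
    else:
        log.info("floor replacement skipped; one-population rows pooled into imputation")

    # 6. random-forest imputation of everything still missing
    provenance = missforest_impute(working, config.imputation, replaced_mask=replaced_mask)
    log.info(
        "imputation: %d cells imputed in %d iteration(s), seed %s",
        provenance.tag_counts()["imputed"], provenance.iterations, config.imputation.seed,
    )

    # 7. differential analysis on the final dataset
    volcano = build_volcano_table(provenance, alpha=config.alpha)
    sig = significant_counts(volcano)
    log.info("final dataset: %d proteins; significant: %s", len(volcano), sig)

    report = RunReport(
        n_proteins_raw=matrix.n_proteins,
        category_counts=counts,
        thresholds={"exclusion_fraction": config.exclusion_fraction, "alpha": config.alpha},
        mnar=mnar.to_dict(),
        normalization={"on": config.normalize_on, "factors": factors.factors},
        imputation={
            "seed": config.imputation.seed,
            "n_trees": config.imputation.n_trees,
            "max_iterations": config.imputation.max_iterations,
            "iterations": provenance.iterations,
        },
        rescue={"enabled": config.rescue, "applied": do_rescue, "n_rescued": len(rescued)},
        stage_counts={
            "raw": matrix.n_proteins,
            "excluded": counts[VariableCategory.EXCLUDED.value] - len(rescued),
            "retained": len(retained),
            "replaced": counts[VariableCategory.ONE_POP_ALL_MISSING.value]
            if mnar.decision is MnarDecision.REPLACE
            else 0,
            "final": provenance.data.shape[0],
            "significant": sig["total"],
        },
    )
    report.validate()
    return PipelineResult(
        provenance=provenance,
        report=report,
        volcano=volcano,
        categories=categories,
        mnar=mnar,
        factors=factors,
        rescued=rescued,
    )
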