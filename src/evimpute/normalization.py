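"""Median-ratio sample normalization.

Each protein's reference is its median over observed values across
samples; each sample is scaled by the median of its value/reference
ratios, so that after scaling the median protein ratio of every sample
is exactly 1.  Missing cells are ignored when computing factors and stay
missing afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd

from .matrix_io import AbundanceMatrix

__all__ = ["NormalizationError", "NormalizationFactors", "median_ratio_normalize"]


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-sample scale factors and the per-protein reference used."""

    factors: Dict[str, float]
    reference: Dict[str, float]

    def to_dict(self) -> dict:
        return {"factors": dict(self.factors), "reference_size": len(self.reference)}


def compute_factors(matrix: AbundanceMatrix) -> NormalizationFactors:
    """Median-of-ratios scale factor per sample, on observed cells only."""
    df = matrix.data
    observed_per_sample = df.notna().sum(axis=0)
    empty = observed_per_sample[observed_per_sample == 0].index.tolist()
    if empty:
        raise NormalizationError(f"samples with zero observed values: {empty}")
    reference = df.median(axis=1, skipna=True)
    ratios = df.div(reference, axis=0)
    # rows with an undefined or zero reference give non-finite ratios and
    # are dropped from the factor computation
    ratios = ratios.where(np.isfinite(ratios))
    factors = ratios.median(axis=0, skipna=True)
    bad = factors[~(factors > 0)].index.tolist()
    if bad:
        raise NormalizationError(f"non-positive or undefined scale factor for samples: {bad}")
    ref = {str(k): float(v) for k, v in reference.items() if np.isfinite(v)}
    return NormalizationFactors(
        factors={str(k): float(v) for k, v in factors.items()},
        reference=ref,
    )


def apply_factors(matrix: AbundanceMatrix, factors: NormalizationFactors) -> AbundanceMatrix:
    scale = pd.Series(factors.factors)[list(matrix.design.sample_ids)]
    return AbundanceMatrix(matrix.data.div(scale, axis=1), matrix.design)


def median_ratio_normalize(matrix: AbundanceMatrix):
    """Normalize so every sample's median protein ratio equals 1.

    Returns ``(normalized_matrix, factors)``.  The missing mask is
    conserved bit-for-bit.
    """
    factors = compute_factors(matrix)
    return apply_factors(matrix, factors), factors
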