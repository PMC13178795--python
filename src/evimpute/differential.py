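"""Per-protein fold changes, unpaired t-tests and the volcano table."""

from __future__ import annotations

from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .imputation import ProvenanceMatrix

__all__ = [
    "compute_fold_changes",
    "t_test_per_protein",
    "build_volcano_table",
    "significant_counts",
]


def _population_arrays(pm: ProvenanceMatrix):
    design = pm.design
    pop_a, pop_b = design.populations
    a = pm.data[list(design.samples_in(pop_a))].to_numpy(dtype=float)
    b = pm.data[list(design.samples_in(pop_b))].to_numpy(dtype=float)
    return a, b, pop_a, pop_b


def compute_fold_changes(pm: ProvenanceMatrix) -> pd.DataFrame:
    """Arithmetic population means and the log2 ratio second/first.

    A zero mean leaves ``log2_fc`` as NaN with ``fc_defined`` False.
    """
    a, b, pop_a, pop_b = _population_arrays(pm)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    defined = (mean_a > 0) & (mean_b > 0)
    log2_fc = np.full(len(mean_a), np.nan)
    log2_fc[defined] = np.log2(mean_b[defined] / mean_a[defined])
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fc": log2_fc,
            "fc_defined": defined,
        },
        index=pm.data.index,
    )
    out.attrs["orientation"] = f"{pop_b}/{pop_a}"
    return out


def t_test_per_protein(pm: ProvenanceMatrix) -> pd.DataFrame:
    """Two-sided Student's (pooled-variance) unpaired t-test per protein.

    The statistic is oriented as second population minus first, matching
    the fold-change direction.  Proteins with zero variance in *both*
    populations cannot be assessed and come back with ``testable`` False
    and NaN statistics.
    """
    a, b, _, _ = _population_arrays(pm)
    n1, n2 = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    testable = ~((var_a == 0) & (var_b == 0))

    df_ = n1 + n2 - 2
    pooled = ((n1 - 1) * var_a + (n2 - 1) * var_b) / df_
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    t_stat = np.full(len(mean_a), np.nan)
    p_value = np.full(len(mean_a), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat[testable] = (mean_b[testable] - mean_a[testable]) / se[testable]
    p_value[testable] = 2.0 * stats.t.sf(np.abs(t_stat[testable]), df_)
    return pd.DataFrame(
        {"t_stat": t_stat, "p_value": p_value, "testable": testable},
        index=pm.data.index,
    )


def build_volcano_table(
    pm: ProvenanceMatrix,
    handling_class: Optional[Mapping[str, str]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assemble the differential table, sorted by p-value.

    Columns: population means, ``log2_fc``, ``t_stat``, ``p_value``, a
    Benjamini-Hochberg ``q_value`` (informational; the ``significant``
    flag uses the raw p-value), ``testable`` and ``handling_class``.
    """
    fc = compute_fold_changes(pm)
    tt = t_test_per_protein(pm)
    table = fc.join(tt)
    table["significant"] = table["testable"] & (table["p_value"] < alpha)

    q = np.full(len(table), np.nan)
    mask = table["testable"].to_numpy()
    if mask.any():
        q[mask] = multipletests(table.loc[mask, "p_value"], method="fdr_bh")[1]
    table["q_value"] = q

    if handling_class is None:
        handling_class = pm.handling_class()
    table["handling_class"] = [handling_class.get(str(i), "complete") for i in table.index]
    table = table.sort_values("p_value", na_position="last", kind="mergesort")
    table.attrs["orientation"] = fc.attrs.get("orientation", "")
    table.attrs["alpha"] = alpha
    return table


def significant_counts(table: pd.DataFrame) -> Dict[str, Dict[str, int]]:
    """Significant protein counts per handling class and per direction."""
    sig = table[table["significant"]]
    per_class = sig.groupby("handling_class").size().to_dict()
    return {
        "per_class": {str(k): int(v) for k, v in per_class.items()},
        "per_direction": {
            "up": int((sig["log2_fc"] > 0).sum()),
            "down": int((sig["log2_fc"] < 0).sum()),
        },
        "total": int(len(sig)),
    }
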