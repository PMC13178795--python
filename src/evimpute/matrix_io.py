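"""Readers/writers for abundance matrices, sample designs and run reports.

The canonical orientation everywhere in this package is proteins as rows
and samples as columns.  Missing cells are carried as ``NaN`` floats in a
:class:`pandas.DataFrame`; a missing cell is a distinct state and is never
encoded as ``0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "MatrixLoadError",
    "SampleDesign",
    "AbundanceMatrix",
    "RunReport",
    "MISSING_TOKENS",
    "read_design",
    "read_abundance_matrix",
    "write_abundance_matrix",
    "write_final_dataset",
    "read_final_dataset",
    "write_report",
    "read_report",
]


class DesignError(ValueError):
    """Raised for an invalid sample -> population design."""


class MatrixLoadError(ValueError):
    """Raised when an abundance matrix violates its load contract."""


def _case_variants(token: str) -> List[str]:
    """All upper/lower case spellings of ``token``."""
    variants = [""]
    for ch in token:
        variants = [v + c for v in variants for c in {ch.lower(), ch.upper()}]
    return variants


#: Tokens parsed as MISSING (besides the empty cell), case-insensitive.
MISSING_TOKENS: Tuple[str, ...] = tuple(
    sorted(set(_case_variants("na") + _case_variants("nan") + [""]))
)


@dataclass(frozen=True)
class SampleDesign:
    """Two-population design with equal replicate counts.

    Parameters
    ----------
    sample_ids
        Ordered sample labels (column order of the matrix).
    population_of
        Mapping ``sample_id -> population label``; exactly two distinct
        labels, each carrying the same number of samples (>= 2).
    """

    sample_ids: Tuple[str, ...]
    population_of: Mapping[str, str]

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.sample_ids)
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "population_of", dict(self.population_of))
        if len(set(ids)) != len(ids):
            raise DesignError("sample ids must be unique")
        missing = [s for s in ids if s not in self.population_of]
        if missing:
            raise DesignError(f"samples without a population: {missing}")
        pops = self.populations
        if len(pops) != 2:
            raise DesignError(
                f"exactly two populations required, got {sorted(set(self.population_of.values()))}"
            )
        sizes = [len(self.samples_in(p)) for p in pops]
        if sizes[0] != sizes[1]:
            raise DesignError(f"unequal population sizes {dict(zip(pops, sizes))}")
        if sizes[0] < 2:
            raise DesignError("each population needs at least 2 replicates")

    @property
    def populations(self) -> Tuple[str, ...]:
        """Population labels in order of first appearance."""
        seen: List[str] = []
        for s in self.sample_ids:
            p = self.population_of[s]
            if p not in seen:
                seen.append(p)
        return tuple(seen)

    @property
    def n_per_population(self) -> int:
        return len(self.sample_ids) // 2

    def samples_in(self, population: str) -> Tuple[str, ...]:
        return tuple(s for s in self.sample_ids if self.population_of[s] == population)

    def swapped(self) -> "SampleDesign":
        """Design with the population order reversed (second listed first),
        flipping the fold-change orientation."""
        a, b = self.populations
        return SampleDesign(self.samples_in(b) + self.samples_in(a), dict(self.population_of))

    @classmethod
    def from_populations(cls, groups: Mapping[str, Sequence[str]]) -> "SampleDesign":
        sample_ids: List[str] = []
        population_of: Dict[str, str] = {}
        for pop, samples in groups.items():
            for s in samples:
                sample_ids.append(str(s))
                population_of[str(s)] = str(pop)
        return cls(tuple(sample_ids), population_of)


@dataclass
class AbundanceMatrix:
    """Proteins x samples intensity table with missing cells.

    ``data`` is indexed by unique protein identifiers, columns follow
    ``design.sample_ids`` exactly, observed values are non-negative floats
    and missing cells are ``NaN``.
    """

    data: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        df = self.data.astype(float)
        if list(df.columns) != list(self.design.sample_ids):
            try:
                df = df[list(self.design.sample_ids)]
            except KeyError as exc:
                raise MatrixLoadError(f"matrix columns do not match design: {exc}") from exc
        dup = df.index[df.index.duplicated()].unique().tolist()
        if dup:
            raise MatrixLoadError(f"duplicate protein identifiers: {dup}")
        vals = df.to_numpy()
        if np.nanmin(vals, initial=np.inf) < 0:
            bad = df.index[(df < 0).any(axis=1)].tolist()
            raise MatrixLoadError(f"negative intensities for proteins: {bad}")
        self.data = df

    @property
    def proteins(self) -> List[str]:
        return list(self.data.index)

    @property
    def n_proteins(self) -> int:
        return len(self.data)

    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def subset(self, proteins: Iterable[str]) -> "AbundanceMatrix":
        keep = [p for p in self.proteins if p in set(proteins)]
        return AbundanceMatrix(self.data.loc[keep].copy(), self.design)

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.copy(), self.design)

    def population_values(self, population: str) -> pd.DataFrame:
        return self.data[list(self.design.samples_in(population))]


def read_design(path: str | Path) -> SampleDesign:
    """Read a 2-column ``sample,population`` CSV (header required)."""
    df = pd.read_csv(path, dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    if "sample" not in cols or "population" not in cols:
        raise DesignError(f"design file must have 'sample' and 'population' columns, got {list(df.columns)}")
    df.columns = cols
    return SampleDesign(
        tuple(df["sample"].astype(str)),
        dict(zip(df["sample"].astype(str), df["population"].astype(str))),
    )


def _read_table(path: Path, sheet: Optional[str]) -> pd.DataFrame:
    na = list(MISSING_TOKENS)
    if path.suffix.lower() in {".xlsx", ".xlsm", ".xls"}:
        return pd.read_excel(
            path, sheet_name=sheet if sheet is not None else 0,
            na_values=na, keep_default_na=False,
        )
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(
        path, sep=sep, na_values=na, keep_default_na=False, float_precision="round_trip"
    )


def read_abundance_matrix(
    path: str | Path,
    design: SampleDesign,
    sheet: Optional[str] = None,
) -> AbundanceMatrix:
    """Load a wide matrix (CSV/TSV/XLSX) into an :class:`AbundanceMatrix`.

    The first column holds protein identifiers; sample columns are picked
    by name from the design, so annotation columns between the identifier
    column and the sample block are tolerated and ignored.  Empty cells and
    the tokens ``NaN``/``NA`` (any case) parse as MISSING.
    """
    path = Path(path)
    raw = _read_table(path, sheet)
    if raw.shape[1] < 1 + len(design.sample_ids):
        raise MatrixLoadError(
            f"{path.name}: expected at least {1 + len(design.sample_ids)} columns, found {raw.shape[1]}"
        )
    id_col = raw.columns[0]
    absent = [s for s in design.sample_ids if s not in raw.columns]
    if absent:
        raise MatrixLoadError(f"{path.name}: design samples missing from file: {absent}")
    ids = raw[id_col].astype(str).str.strip()
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise MatrixLoadError(f"{path.name}: duplicate protein identifiers: {dup}")
    values = raw[list(design.sample_ids)].apply(pd.to_numeric, errors="raise")
    values.index = pd.Index(ids, name="protein")
    return AbundanceMatrix(values, design)


def write_abundance_matrix(matrix: AbundanceMatrix, path: str | Path) -> None:
    """Write a matrix (MISSING rendered as the token ``NaN``)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    # %.17g round-trips IEEE doubles exactly
    matrix.data.rename_axis("protein").to_csv(path, sep=sep, na_rep="NaN", float_format="%.17g")


def write_final_dataset(matrix, path: str | Path, provenance_path: str | Path | None = None) -> None:
    """Write a completed, provenance-tagged matrix.

    Values go to ``path`` as a TSV; per-cell provenance tags
    (``observed``/``replaced``/``imputed``) go to a parallel TSV at
    ``provenance_path`` (default: ``<path stem>.provenance.tsv``).
    A residual missing cell is a contract violation.
    """
    path = Path(path)
    if bool(matrix.data.isna().to_numpy().any()):
        raise ValueError("final dataset still contains missing cells")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    matrix.data.rename_axis("protein").to_csv(path, sep=sep, float_format="%.17g")
    if provenance_path is None:
        provenance_path = path.with_suffix(".provenance.tsv")
    matrix.tags.rename_axis("protein").to_csv(Path(provenance_path), sep="\t")


def read_final_dataset(path: str | Path, design: SampleDesign) -> AbundanceMatrix:
    """Re-read a final dataset written by :func:`write_final_dataset`."""
    return read_abundance_matrix(path, design)


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    n_proteins_raw: int
    category_counts: Dict[str, int]
    thresholds: Dict[str, float]
    mnar: Optional[dict] = None
    normalization: Optional[dict] = None
    imputation: Optional[dict] = None
    rescue: dict = field(default_factory=lambda: {"enabled": False, "n_rescued": 0})
    stage_counts: Dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        total = sum(self.category_counts.values())
        if total != self.n_proteins_raw:
            raise ValueError(
                f"category counts sum to {total}, expected {self.n_proteins_raw}"
            )

    def to_dict(self) -> dict:
        return {
            "n_proteins_raw": self.n_proteins_raw,
            "category_counts": dict(self.category_counts),
            "thresholds": dict(self.thresholds),
            "mnar": self.mnar,
            "normalization": self.normalization,
            "imputation": self.imputation,
            "rescue": self.rescue,
            "stage_counts": dict(self.stage_counts),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunReport":
        return cls(
            n_proteins_raw=int(d["n_proteins_raw"]),
            category_counts={k: int(v) for k, v in d["category_counts"].items()},
            thresholds=dict(d["thresholds"]),
            mnar=d.get("mnar"),
            normalization=d.get("normalization"),
            imputation=d.get("imputation"),
            rescue=d.get("rescue", {"enabled": False, "n_rescued": 0}),
            stage_counts=dict(d.get("stage_counts", {})),
        )


def write_report(report: RunReport, path: str | Path) -> None:
    report.validate()
    Path(path).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> RunReport:
    return RunReport.from_dict(json.loads(Path(path).read_text()))
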