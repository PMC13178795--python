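"""Marker-list over-representation: membership fractions and an
observed-vs-expected Fisher exact test against a stated universe."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import FrozenSet, Iterable, Tuple

from .missingness import _round_half_up, fisher_exact_two_sided

__all__ = [
    "MarkerUniverse",
    "MembershipResult",
    "EnrichmentResult",
    "load_marker_list",
    "membership_fraction",
    "enrichment_fisher",
]


def _normalize(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class MarkerUniverse:
    """Marker membership list with its database and search-universe sizes."""

    members: FrozenSet[str]
    n_db: int
    n_universe: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(_normalize(m) for m in self.members if m.strip()))
        if not len(self.members) <= self.n_db <= self.n_universe:
            raise ValueError(
                f"need |members| <= n_db <= n_universe, got "
                f"{len(self.members)} / {self.n_db} / {self.n_universe}"
            )

    @property
    def chance_fraction(self) -> float:
        """Fraction of the searchable universe present in the database."""
        return self.n_db / self.n_universe


@dataclass(frozen=True)
class MembershipResult:
    fraction: float
    n_in: int
    n_total: int


@dataclass(frozen=True)
class EnrichmentResult:
    p_value: float
    enriched: bool
    observed_fraction: float
    expected_fraction: float
    table: Tuple[Tuple[int, int], Tuple[int, int]]

    def to_dict(self) -> dict:
        return {
            "p_value": self.p_value,
            "enriched": self.enriched,
            "observed_fraction": self.observed_fraction,
            "expected_fraction": self.expected_fraction,
            "table": [list(r) for r in self.table],
        }


def load_marker_list(path: str | Path) -> FrozenSet[str]:
    """Read a one-symbol-per-line marker file (case-folded, trimmed)."""
    out = set()
    for line in Path(path).read_text().splitlines():
        sym = _normalize(line)
        if sym:
            out.add(sym)
    return frozenset(out)


def membership_fraction(proteins: Iterable[str], universe: MarkerUniverse) -> MembershipResult:
    """Fraction of the protein set found in the marker members."""
    normalized = {_normalize(p) for p in proteins if str(p).strip()}
    if not normalized:
        raise ValueError("empty protein set")
    n_in = len(normalized & universe.members)
    return MembershipResult(fraction=n_in / len(normalized), n_in=n_in, n_total=len(normalized))


def enrichment_fisher(
    observed_in: int,
    observed_out: int,
    universe: MarkerUniverse,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Observed in/out counts vs the chance expectation ``n_db/n_universe``.

    The expected row uses ``round(q * N)`` members (ties rounded half up);
    the p-value is the two-sided Fisher exact test on the resulting 2x2
    table.  ``enriched`` additionally requires the observed fraction to
    exceed the chance fraction.
    """
    if observed_in < 0 or observed_out < 0:
        raise ValueError("counts must be non-negative")
    n = observed_in + observed_out
    if n == 0:
        raise ValueError("counts must not both be zero")
    q = universe.chance_fraction
    expected_in = _round_half_up(q * n)
    table = ((observed_in, observed_out), (expected_in, n - expected_in))
    p_value = fisher_exact_two_sided(table)
    observed_fraction = observed_in / n
    return EnrichmentResult(
        p_value=p_value,
        enriched=p_value < alpha and observed_fraction > q,
        observed_fraction=observed_fraction,
        expected_fraction=q,
        table=table,
    )
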