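"""CDR3 length distributions, unique-CDR3 sets, shared-by-k tables, and
pairwise overlap percentages.

A CDR3 is handled as the full junction amino-acid string (anchors included)
for identity/sharing purposes; reported lengths subtract the two anchor
residues.  Only junctions from productive, motif-valid records enter these
analyses.  Sharing semantics: a CDR3 seen in several animals of one group
counts once for that group; the shared-by-k table tallies, over the union of
all group sets, how many group sets contain each unique sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    ContractError,
    Design,
    Repertoire,
    cdr3_is_valid,
    classify_functionality,
    is_class_switched,
)
from .usage import UsageTable, usage_percent

__all__ = [
    "CdrSet",
    "cdr3_length_distribution",
    "build_cdr3_sets",
    "sharing_table",
    "percent_from_counts",
    "variable_overlap",
    "OverlapRecord",
]


@dataclass(frozen=True)
class CdrSet:
    """Unique CDR3 amino-acid sequences of one group on one locus."""

    label: str
    locus: str
    sequences: frozenset[str]

    def __len__(self) -> int:
        return len(self.sequences)


def _valid_junctions(rep: Repertoire, class_switched_only: bool = False) -> list[str]:
    out = []
    for r in rep.records:
        if classify_functionality(r) != "productive" or not r.junction_aa:
            continue
        if not cdr3_is_valid(r):
            continue
        if class_switched_only and not is_class_switched(r):
            continue
        out.append(r.junction_aa)
    return out


def cdr3_length_distribution(
    reps: Iterable[Repertoire],
) -> tuple[UsageTable, pd.Series]:
    """Per-animal percent per CDR3 AA length, plus per-animal mean length.

    CDR3 length = junction length − 2 (the anchor C and W/F are excluded).
    """
    counts: dict[str, dict[int, float]] = {}
    means: dict[str, float] = {}
    for rep in reps:
        lengths = [len(j) - 2 for j in _valid_junctions(rep)]
        tally: dict[int, float] = {}
        for ln in lengths:
            tally[ln] = tally.get(ln, 0.0) + 1.0
        counts[rep.animal.animal_id] = tally
        if lengths:
            means[rep.animal.animal_id] = sum(lengths) / len(lengths)
    universe = sorted({ln for t in counts.values() for ln in t})
    table = usage_percent(counts, feature_universe=universe, axis="cdr3_length")
    return table, pd.Series(means, name="mean_cdr3_length")


def build_cdr3_sets(
    reps: Iterable[Repertoire],
    design: Design,
    grouping: str = "cell",
    class_switched_only: bool = False,
) -> list[CdrSet]:
    """Pool unique CDR3s per group.

    ``grouping`` is ``"cell"`` (8 treatment cells), ``"factor:AOS"`` (or TT,
    CpG; two pooled levels '-' and '+'), or a custom ``{animal_id: label}``
    mapping.  Deduplication happens after pooling a group's animals.
    """
    reps = list(reps)
    loci = {r.locus for rep in reps for r in rep.records}
    if len(loci) > 1:
        raise ContractError(f"records span multiple loci: {sorted(loci)}")
    locus = next(iter(loci)) if loci else "IGH"

    def label_of(animal_id: str) -> str:
        if isinstance(grouping, Mapping):
            return grouping[animal_id]
        if grouping == "cell":
            return design[animal_id].cell
        if grouping.startswith("factor:"):
            factor = grouping.split(":", 1)[1]
            return "+" if design.factor_level(animal_id, factor) else "-"
        raise ValueError(f"unknown grouping {grouping!r}")

    pools: dict[str, set[str]] = {}
    for rep in reps:
        label = label_of(rep.animal.animal_id)
        pools.setdefault(label, set()).update(
            _valid_junctions(rep, class_switched_only=class_switched_only)
        )
    return [
        CdrSet(label=label, locus=locus, sequences=frozenset(seqs))
        for label, seqs in sorted(pools.items())
    ]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.155 → 0.16), matching printed report tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent_from_counts(counts: Sequence[int]) -> list[float]:
    """Percent of total per count, rounded half-up to 2 decimals."""
    if any(c < 0 for c in counts):
        raise ValueError("counts must be >= 0")
    total = sum(counts)
    if total <= 0:
        raise ValueError("counts sum to zero")
    return [round_half_up(100.0 * c / total) for c in counts]


def sharing_table(sets: Sequence[CdrSet]) -> pd.DataFrame:
    """Shared-by-k table over G group sets.

    Rows k = 1..G: the number of unique CDR3s found in exactly k of the G
    sets, and that count as a percent of the union (2 decimals, half-up).
    """
    if len(sets) < 2:
        raise ValueError("sharing_table needs at least 2 sets")
    if len({s.locus for s in sets}) > 1:
        raise ContractError("sharing_table: sets from mixed loci")
    membership: dict[str, int] = {}
    for s in sets:
        for seq in s.sequences:
            membership[seq] = membership.get(seq, 0) + 1
    g = len(sets)
    counts = [0] * g
    for k in membership.values():
        counts[k - 1] += 1
    total = sum(counts)
    percents = percent_from_counts(counts) if total else [0.0] * g
    return pd.DataFrame(
        {"shared": range(1, g + 1), "count": counts, "percent": percents}
    ).set_index("shared")


@dataclass(frozen=True)
class OverlapRecord:
    """Pairwise set overlap with per-side shared-repertoire percentages."""

    label_a: str
    label_b: str
    size_a: int
    size_b: int
    shared: int
    percent_of_a: float
    percent_of_b: float


def variable_overlap(set_a: CdrSet, set_b: CdrSet) -> OverlapRecord:
    """Intersection size and the percent of each side's repertoire shared."""
    if set_a.locus != set_b.locus:
        raise ContractError("variable_overlap: sets from different loci")
    shared = len(set_a.sequences & set_b.sequences)
    if not set_a.sequences or not set_b.sequences:
        warnings.warn("variable_overlap: empty set; percents reported as 0")
    pct_a = 100.0 * shared / len(set_a) if len(set_a) else 0.0
    pct_b = 100.0 * shared / len(set_b) if len(set_b) else 0.0
    return OverlapRecord(
        label_a=set_a.label,
        label_b=set_b.label,
        size_a=len(set_a),
        size_b=len(set_b),
        shared=shared,
        percent_of_a=pct_a,
        percent_of_b=pct_b,
    )
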