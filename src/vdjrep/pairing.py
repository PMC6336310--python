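"""V/(D)/J combination resolution, pairing frequency tables, rankings, and
Circos link-file export.

A record enters pairing analysis only when it is functionally productive,
its junction motif is valid, and exactly one V gene was identified.  D and J
components that IMGT could not pin down — unreported, multi-candidate, or
(for D) aligned over fewer than six nucleotides — are reported as
undetermined ("U").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd

from .model import (
    Design,
    RearrangementRecord,
    Repertoire,
    cdr3_is_valid,
    classify_functionality,
    gene_family,
)

__all__ = [
    "VDJCombination",
    "PairingTable",
    "resolve_vdj",
    "pairing_table",
    "rank_top_combinations",
    "filter_low_frequency_pairs",
    "export_circos_links",
    "read_circos_links",
]


class VDJCombination(NamedTuple):
    """A resolved V/(D)/J combination; light chains carry no D (None)."""

    v: str
    d: Optional[str]  # gene, "U", or None for light chains
    j: str
    locus: str

    def label(self) -> str:
        parts = [self.v] + ([self.d] if self.d is not None else []) + [self.j]
        return "/".join(parts)


def resolve_vdj(
    r: RearrangementRecord, d_length_rule_on_j: bool = False
) -> Optional[VDJCombination]:
    """Resolve a record into a V/(D)/J combination, or None if ineligible.

    Eligibility: productive, motif-valid junction, single identified V gene.
    D is "U" when unreported, multi-candidate, or aligned < 6 nt; J is "U"
    when unreported or multi-candidate (the length rule optionally extends
    to J via ``d_length_rule_on_j`` — off by default, as the short-match
    concern targets the tiny D segment).
    """
    if classify_functionality(r) != "productive":
        return None
    if len(r.v_call) != 1:
        return None
    if not r.junction_aa or not cdr3_is_valid(r):
        return None
    v = r.v_call[0]
    if r.locus == "IGH":
        if len(r.d_call) != 1 or r.d_alignment_length < 6:
            d: Optional[str] = "U"
        else:
            d = r.d_call[0]
    else:
        d = None
    if len(r.j_call) != 1:
        j = "U"
    else:
        j = r.j_call[0]
    return VDJCombination(v=v, d=d, j=j, locus=r.locus)


@dataclass
class PairingTable:
    """Frequencies of resolved combinations.

    ``counts``/``percent`` are combination x animal DataFrames indexed by a
    MultiIndex (v, d, j); per-animal percents sum to 100 over all
    combinations, including those containing "U".
    """

    mode: str  # "VDJ" or "VJ"
    locus: str
    counts: pd.DataFrame
    percent: pd.DataFrame

    def group_means(self, design: Design) -> pd.DataFrame:
        """Combination x treatment-cell mean percent."""
        cell = pd.Series({a: design[a].cell for a in self.percent.columns})
        return self.percent.T.groupby(cell).mean().T

    def factor_level_means(self, design: Design, factor: str) -> pd.DataFrame:
        """Combination x {-,+} mean percent for one factor."""
        level = pd.Series(
            {a: ("+" if design.factor_level(a, factor) else "-") for a in self.percent.columns}
        )
        return self.percent.T.groupby(level).mean().T

    def to_long(self) -> pd.DataFrame:
        long = self.percent.stack().rename("percent").reset_index()
        long.columns = ["v", "d", "j", "animal_id", "percent"]
        return long


def pairing_table(
    reps: Iterable[Repertoire],
    mode: str = "VDJ",
    d_length_rule_on_j: bool = False,
) -> PairingTable:
    """Build a combination-frequency table over all animals.

    VJ mode marginalizes the D component.  Animals with zero resolvable
    records are excluded with a warning.
    """
    if mode not in ("VDJ", "VJ"):
        raise ValueError(f"mode must be VDJ or VJ, got {mode!r}")
    per_animal: dict[str, dict[tuple, int]] = {}
    locus = None
    for rep in reps:
        tally: dict[tuple, int] = {}
        for r in rep.records:
            combo = resolve_vdj(r, d_length_rule_on_j=d_length_rule_on_j)
            if combo is None:
                continue
            locus = locus or combo.locus
            if mode == "VJ" or combo.d is None:
                key = (combo.v, "", combo.j)
            else:
                key = (combo.v, combo.d, combo.j)
            tally[key] = tally.get(key, 0) + 1
        if not tally:
            warnings.warn(
                f"animal {rep.animal.animal_id} has no resolvable records; excluded"
            )
            continue
        per_animal[rep.animal.animal_id] = tally
    keys = sorted({k for t in per_animal.values() for k in t})
    index = pd.MultiIndex.from_tuples(keys, names=["v", "d", "j"]) if keys else pd.MultiIndex.from_tuples([], names=["v", "d", "j"])
    counts = pd.DataFrame(
        {a: [t.get(k, 0) for k in keys] for a, t in per_animal.items()},
        index=index,
        dtype=float,
    )
    percent = 100.0 * counts / counts.sum(axis=0)
    return PairingTable(mode=mode, locus=locus or "IGH", counts=counts, percent=percent)


def rank_top_combinations(
    table: PairingTable, design: Design, groups: Sequence[str], k: int = 5
) -> pd.DataFrame:
    """Rank matrix of the union of each group's top-k combinations.

    Rows: combinations in the union, columns: groups; cells hold the
    combination's rank (1 = most frequent by group-mean percent) within
    each group.  Ties break lexicographically by (v, d, j) so heat maps are
    reproducible; tied rows are flagged in the ``tied`` column.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    means = table.group_means(design)
    missing = set(groups) - set(means.columns)
    if missing:
        raise ValueError(f"unknown group(s): {sorted(missing)}")
    ranks = pd.DataFrame(index=means.index, columns=list(groups), dtype=float)
    tied = pd.Series(False, index=means.index)
    union: set = set()
    for g in groups:
        ordered = (
            means[[g]]
            .reset_index()
            .sort_values(by=[g, "v", "d", "j"], ascending=[False, True, True, True])
            .set_index(["v", "d", "j"])
        )
        rank_series = pd.Series(range(1, len(ordered) + 1), index=ordered.index, dtype=float)
        ranks[g] = rank_series.reindex(means.index)
        dup = ordered[g].duplicated(keep=False)
        tied |= dup.reindex(means.index).fillna(False)
        union |= set(ordered.index[: min(k, len(ordered))])
    out = ranks.loc[sorted(union)].copy()
    out["tied"] = tied.loc[out.index]
    return out


def filter_low_frequency_pairs(
    table: PairingTable,
    design: Design,
    factor: str,
    threshold: float = 0.1,
) -> PairingTable:
    """Drop combinations whose mean percent is below ``threshold`` in BOTH
    levels of the compared factor; a pair detected at or above threshold in
    at least one level is kept."""
    if table.percent.empty:
        return table
    means = table.factor_level_means(design, factor)
    keep = (means >= threshold).any(axis=1)
    return PairingTable(
        mode=table.mode,
        locus=table.locus,
        counts=table.counts.loc[keep],
        percent=table.percent.loc[keep],
    )


def export_circos_links(
    table: PairingTable, design: Design, group: str, path: str | Path
) -> None:
    """Write a whitespace-delimited chord-diagram link file for one group.

    One line per V-family/J-family pair: ``<segmentV> <segmentJ> <count>``,
    where counts are group-total resolved counts and segments are gene
    families ("V1", "J4", "U").
    """
    if table.mode != "VJ":
        raise ValueError("Circos export expects a VJ-mode table")
    animals = [a for a in table.counts.columns if design[a].cell == group]
    if not animals:
        raise ValueError(f"no animals in group {group!r}")
    totals = table.counts[animals].sum(axis=1)
    fam: dict[tuple[str, str], int] = {}
    for (v, _d, j), count in totals.items():
        key = (gene_family(v), gene_family(j))
        fam[key] = fam.get(key, 0) + int(count)
    with open(path, "w", encoding="utf-8") as fh:
        for (fv, fj), count in sorted(fam.items()):
            fh.write(f"{fv} {fj} {count}\n")


def read_circos_links(path: str | Path) -> dict[tuple[str, str], int]:
    """Parse a link file back into a {(segmentV, segmentJ): count} map."""
    out: dict[tuple[str, str], int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 3:
                continue
            out[(parts[0], parts[1])] = int(parts[2])
    return out
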