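"""Fractional gene-segment abundance and percent-of-repertoire tables.

Abundance follows the fractional assignment rule: a record whose call list
names exactly one gene contributes 1.0 to that gene; a two-gene partial
match contributes 0.5 to each; records with three or more candidates (or
none) are excluded from the axis entirely — numerator and denominator.
Percentages are per animal over the total assigned weight on the axis, so
rows sum to 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    ContractError,
    Design,
    IGG_SUBCLASSES,
    RearrangementRecord,
    Repertoire,
    classify_functionality,
    is_class_switched,
)

__all__ = [
    "UsageTable",
    "assign_abundance",
    "usage_counts_with_undetermined",
    "usage_percent",
    "usage_table",
    "constant_usage",
    "subset_class_switched",
    "exclude_lambda",
    "high_frequency_segments",
]

_AXIS_CALL = {"V": "v_call", "D": "d_call", "J": "j_call"}


@dataclass
class UsageTable:
    """Per-animal fractional counts and percent-of-repertoire on one axis.

    ``percent`` and ``counts`` are animal x feature DataFrames; percent rows
    sum to 100 over the included features (including "U" where present).
    """

    axis: str  # V | D | J | isotype | cdr3_length
    percent: pd.DataFrame
    counts: pd.DataFrame

    @property
    def animals(self) -> list[str]:
        return list(self.percent.index)

    @property
    def features(self) -> list:
        return list(self.percent.columns)

    def group_means(self, design: Design) -> pd.DataFrame:
        """Treatment-cell mean percent (cells x features)."""
        cell = pd.Series({a: design[a].cell for a in self.animals}, name="cell")
        return self.percent.groupby(cell).mean()

    def to_long(self) -> pd.DataFrame:
        long = (
            self.percent.stack()
            .rename("percent")
            .reset_index()
            .rename(columns={"level_0": "animal_id", "level_1": "feature"})
        )
        long.columns = ["animal_id", "feature", "percent"]
        long["count"] = [
            self.counts.at[a, f] for a, f in zip(long["animal_id"], long["feature"])
        ]
        return long[["animal_id", "feature", "count", "percent"]]

    def write_tsv(self, path: str | Path) -> None:
        self.percent.rename_axis("animal_id").to_csv(path, sep="\t", lineterminator="\n")


def _single_locus(records: Sequence[RearrangementRecord]) -> None:
    loci = {r.locus for r in records}
    if len(loci) > 1:
        raise ContractError(f"records span multiple loci: {sorted(loci)}")


def assign_abundance(
    records: Sequence[RearrangementRecord], axis: str
) -> dict[str, float]:
    """Fractional abundance per gene for one animal and one locus.

    One candidate gene → 1.0; two candidates → 0.5 each; zero or ≥3
    candidates → the record contributes nothing to this axis.
    """
    if axis not in _AXIS_CALL:
        raise ValueError(f"axis must be V, D or J, got {axis!r}")
    _single_locus(records)
    attr = _AXIS_CALL[axis]
    counts: dict[str, float] = {}
    for r in records:
        calls = getattr(r, attr)
        if len(calls) == 1:
            counts[calls[0]] = counts.get(calls[0], 0.0) + 1.0
        elif len(calls) == 2:
            for g in calls:
                counts[g] = counts.get(g, 0.0) + 0.5
    return counts


def usage_counts_with_undetermined(
    records: Sequence[RearrangementRecord], axis: str
) -> dict[str, float]:
    """D/J abundance with an explicit "U" (undetermined) category.

    A D segment is undetermined when it is unreported, aligned over fewer
    than six nucleotides, or carries multiple candidate genes; a J segment
    when unreported or multi-candidate.  Determined segments count 1.0.
    The V axis has no "U": records without a usable V call are excluded
    (the V call anchors the record), so this falls back to the fractional
    rule for axis="V".
    """
    if axis == "V":
        return assign_abundance(records, "V")
    if axis not in ("D", "J"):
        raise ValueError(f"axis must be V, D or J, got {axis!r}")
    _single_locus(records)
    counts: dict[str, float] = {}
    for r in records:
        calls = r.d_call if axis == "D" else r.j_call
        undetermined = len(calls) != 1 or (axis == "D" and r.d_alignment_length < 6)
        key = "U" if undetermined else calls[0]
        counts[key] = counts.get(key, 0.0) + 1.0
    return counts


def usage_percent(
    counts_per_animal: Mapping[str, Mapping[str, float]],
    feature_universe: Sequence[str] | None = None,
    axis: str = "V",
) -> UsageTable:
    """Percent-of-repertoire table from per-animal fractional counts.

    Cell = 100 x weight / total assigned weight for that animal; features
    absent from an animal report 0.  Animals with zero total weight are
    excluded with a warning.
    """
    if feature_universe is None:
        universe: list[str] = sorted({f for c in counts_per_animal.values() for f in c})
    else:
        universe = list(feature_universe)
    rows_counts, rows_pct, kept = [], [], []
    for animal, counts in counts_per_animal.items():
        total = sum(counts.values())
        if total <= 0:
            warnings.warn(f"animal {animal} has zero assigned weight on axis {axis}; excluded")
            continue
        kept.append(animal)
        row = [float(counts.get(f, 0.0)) for f in universe]
        rows_counts.append(row)
        rows_pct.append([100.0 * w / total for w in row])
    counts_df = pd.DataFrame(rows_counts, index=kept, columns=universe)
    pct_df = pd.DataFrame(rows_pct, index=kept, columns=universe)
    return UsageTable(axis=axis, percent=pct_df, counts=counts_df)


def _analysis_records(
    rep: Repertoire, productive_only: bool
) -> list[RearrangementRecord]:
    """Records entering usage: productive + unknown by default (as carried
    to total assessed reads), optionally productive-only."""
    out = []
    for r in rep.records:
        f = classify_functionality(r)
        if f == "unproductive":
            continue
        if productive_only and f != "productive":
            continue
        out.append(r)
    return out


def exclude_lambda(reps: Iterable[Repertoire]) -> list[Repertoire]:
    """Drop IGL records at analysis entry (lambda is ~5% of light chains)."""
    return [rep.subset(lambda r: r.locus != "IGL") for rep in reps]


def usage_table(
    reps: Iterable[Repertoire],
    axis: str,
    productive_only: bool = False,
    with_undetermined: bool | None = None,
) -> UsageTable:
    """Per-animal usage table on a V/D/J axis for a set of repertoires.

    ``with_undetermined`` defaults to True for D and J (explicit "U"
    column), False for V.
    """
    if with_undetermined is None:
        with_undetermined = axis in ("D", "J")
    counts: dict[str, dict[str, float]] = {}
    for rep in reps:
        records = _analysis_records(rep, productive_only)
        fn = usage_counts_with_undetermined if with_undetermined else assign_abundance
        counts[rep.animal.animal_id] = fn(records, axis)
    return usage_percent(counts, axis=axis)


def constant_usage(
    reps: Iterable[Repertoire],
    productive_only: bool = False,
    aggregate_igg: bool = True,
) -> UsageTable:
    """Isotype usage among heavy-chain records with an identifiable constant
    region; IgG subclasses aggregate to "IgG" for the report layer."""
    counts: dict[str, dict[str, float]] = {}
    any_known = False
    for rep in reps:
        tally: dict[str, float] = {}
        for r in _analysis_records(rep, productive_only):
            if r.locus != "IGH":
                raise ContractError("constant_usage expects IGH records only")
            if r.c_call == "unknown":
                continue
            label = "IgG" if (aggregate_igg and r.c_call in IGG_SUBCLASSES) else r.c_call
            tally[label] = tally.get(label, 0.0) + 1.0
        if tally:
            any_known = True
        counts[rep.animal.animal_id] = tally
    if not any_known:
        warnings.warn("no records with identifiable constant region; empty isotype table")
        return UsageTable(
            axis="isotype",
            percent=pd.DataFrame(index=list(counts), columns=[], dtype=float).iloc[0:0],
            counts=pd.DataFrame(index=list(counts), columns=[], dtype=float).iloc[0:0],
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return usage_percent(counts, axis="isotype")


def subset_class_switched(rep: Repertoire) -> Repertoire:
    """Retain heavy-chain records with a switched constant region (idempotent)."""
    return rep.subset(is_class_switched)


def high_frequency_segments(
    table: UsageTable,
    design: Design,
    groups: Sequence[str] | None = None,
    threshold: float = 5.0,
) -> set[str]:
    """Features whose group-mean percent strictly exceeds ``threshold`` in at
    least one named treatment cell (default: all cells present)."""
    if table.percent.empty:
        return set()
    means = table.group_means(design)
    if groups is None:
        groups = list(means.index)
    unknown = set(groups) - set(means.index)
    if unknown:
        raise ValueError(f"unknown group(s): {sorted(unknown)}")
    sub = means.loc[list(groups)]
    return set(sub.columns[(sub > threshold).any(axis=0)])
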