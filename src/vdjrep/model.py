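"""Core record types, AIRR TSV I/O, and record-level classification rules.

An immunoglobulin transcript is summarized by its germline gene-segment calls
(V, D, J at the gene level, alleles collapsed), its constant-region isotype,
and its junction — the CDR3 loop plus the two conserved anchor residues
(leading cysteine; trailing tryptophan for heavy chain, phenylalanine for
kappa).  Functionality follows the IMGT convention: a functional (productive)
sequence is in frame without a stop codon; sequences too short to decide are
"unknown".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

logger = logging.getLogger(__name__)

LOCI = ("IGH", "IGK", "IGL")

#: Isotype alphabet.  "unknown" marks records without an identifiable
#: constant region.
ISOTYPES = ("IgM", "IgD", "IgG1", "IgG2b", "IgG2c", "IgG3", "IgA", "IgE", "unknown")

#: Heavy-chain isotypes that indicate class switching (everything downstream
#: of IgM/IgD in the constant-region locus).
SWITCHED_ISOTYPES = frozenset({"IgG1", "IgG2b", "IgG2c", "IgG3", "IgA", "IgE"})

#: IgG subclasses, aggregated to "IgG" in report-layer isotype tables.
IGG_SUBCLASSES = frozenset({"IgG1", "IgG2b", "IgG2c", "IgG3"})

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

#: Fixed column order of the AIRR Rearrangement TSV dialect we read/write.
AIRR_COLUMNS = (
    "sequence_id",
    "locus",
    "v_call",
    "d_call",
    "j_call",
    "c_call",
    "junction_aa",
    "d_alignment_length",
    "vj_in_frame",
    "stop_codon",
)

MANDATORY_COLUMNS = ("sequence_id", "locus", "v_call", "d_call", "j_call", "junction_aa")


class AirrFormatError(ValueError):
    """Raised when an AIRR TSV is missing a mandatory column."""


class ContractError(ValueError):
    """Raised when an operation's input contract is violated (e.g. mixed loci)."""


def collapse_alleles(raw: str | float | None) -> tuple[str, ...]:
    """Parse a comma-separated gene-call cell into unique gene-level names.

    Allele suffixes (text after ``*``) are stripped; duplicates collapse,
    preserving first-appearance order.  Empty/NaN cells give an empty tuple.

    >>> collapse_alleles("IGHV1-26*01,IGHV1-26*02")
    ('IGHV1-26',)
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return ()
    text = str(raw).strip()
    if not text:
        return ()
    seen: dict[str, None] = {}
    for token in text.split(","):
        gene = token.strip().split("*", 1)[0]
        if gene:
            seen.setdefault(gene, None)
    return tuple(seen)


@dataclass(frozen=True)
class RearrangementRecord:
    """One annotated antibody transcript."""

    sequence_id: str
    locus: str
    v_call: tuple[str, ...] = ()
    d_call: tuple[str, ...] = ()
    j_call: tuple[str, ...] = ()
    c_call: str = "unknown"
    junction_aa: str = ""
    d_alignment_length: int = 0
    in_frame: Optional[bool] = None  # None = unknown
    has_stop: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise ValueError(f"unknown locus {self.locus!r}")
        if self.locus in ("IGK", "IGL") and (self.d_call or self.d_alignment_length):
            raise ValueError("light-chain record cannot carry a D segment")
        if self.c_call not in ISOTYPES:
            raise ValueError(f"unknown isotype {self.c_call!r}")


@dataclass(frozen=True)
class DesignRow:
    """One animal's treatment assignment in the 2x2x2 (AOS, TT, CpG) factorial."""

    animal_id: str
    aos: bool
    tt: bool
    cpg: bool
    trial: int = 1

    @property
    def cell(self) -> str:
        """Treatment-cell label in (AOS, TT, CpG) sign convention, e.g. ``-++``."""
        return "".join("+" if f else "-" for f in (self.aos, self.tt, self.cpg))


#: Named cells featured throughout the study-style reports.
SALINE, TT_CPG, AOS_TT_CPG = "---", "-++", "+++"
ALL_CELLS = tuple(
    "".join(s) for s in
    (("-+"[a] + "-+"[t] + "-+"[c]) for a in (0, 1) for t in (0, 1) for c in (0, 1))
)


class Design:
    """Animal → treatment-triple map for the factorial design."""

    def __init__(self, rows: Iterable[DesignRow]):
        self.rows: tuple[DesignRow, ...] = tuple(rows)
        ids = [r.animal_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate animal_id in design")
        self._by_id = {r.animal_id: r for r in self.rows}

    def __iter__(self) -> Iterator[DesignRow]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, animal_id: str) -> DesignRow:
        return self._by_id[animal_id]

    @property
    def animal_ids(self) -> list[str]:
        return [r.animal_id for r in self.rows]

    def cells(self) -> dict[str, list[str]]:
        """Map cell label → animal ids, in design order."""
        out: dict[str, list[str]] = {}
        for r in self.rows:
            out.setdefault(r.cell, []).append(r.animal_id)
        return out

    def factor_level(self, animal_id: str, factor: str) -> bool:
        return getattr(self._by_id[animal_id], factor.lower())

    def validate_full_factorial(self, n_min: int = 1) -> None:
        cells = self.cells()
        for cell in ALL_CELLS:
            if len(cells.get(cell, [])) < n_min:
                raise ValueError(f"design cell {cell} has fewer than {n_min} animals")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": [r.animal_id for r in self.rows],
                "aos": [r.aos for r in self.rows],
                "tt": [r.tt for r in self.rows],
                "cpg": [r.cpg for r in self.rows],
                "trial": [r.trial for r in self.rows],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        for col in ("aos", "tt", "cpg"):
            df[col] = df[col].map({True: "T", False: "F"})
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Design":
        df = pd.read_csv(path, sep="\t", dtype=str)
        rows = [
            DesignRow(
                animal_id=str(r.animal_id),
                aos=str(r.aos).strip() in ("T", "True", "true", "1"),
                tt=str(r.tt).strip() in ("T", "True", "true", "1"),
                cpg=str(r.cpg).strip() in ("T", "True", "true", "1"),
                trial=int(r.trial),
            )
            for r in df.itertuples()
        ]
        return cls(rows)


@dataclass
class Repertoire:
    """All annotated transcripts of one animal on one (or more) loci."""

    animal: DesignRow
    records: list[RearrangementRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[RearrangementRecord]:
        return iter(self.records)

    def subset(self, predicate) -> "Repertoire":
        return Repertoire(self.animal, [r for r in self.records if predicate(r)])

    def by_locus(self, locus: str) -> "Repertoire":
        return self.subset(lambda r: r.locus == locus)


# ---------------------------------------------------------------------------
# classification rules
# ---------------------------------------------------------------------------

def classify_functionality(r: RearrangementRecord) -> str:
    """Classify a record as ``productive``, ``unknown`` or ``unproductive``.

    Productive requires an in-frame junction without a stop codon; records
    lacking the evidence to decide (short sequences) are unknown.
    """
    if r.in_frame is None or r.has_stop is None or not r.junction_aa:
        return "unknown"
    if r.in_frame and not r.has_stop:
        return "productive"
    return "unproductive"


def is_class_switched(r: RearrangementRecord) -> bool:
    """True for heavy-chain records with a switched, identifiable constant region."""
    return r.locus == "IGH" and r.c_call in SWITCHED_ISOTYPES


def cdr3_is_valid(r: RearrangementRecord) -> bool:
    """Check the junction anchor motif required for a functional assignment.

    Heavy chain: C...W, or evidence of class switching (a switched constant
    region vouches for the transcript even with a non-canonical anchor).
    Kappa chain: C...F.
    """
    j = r.junction_aa
    if not j:
        raise ValueError("cdr3_is_valid requires a nonempty junction_aa")
    if r.locus == "IGH":
        return (j[0] == "C" and j[-1] == "W") or is_class_switched(r)
    # light chains
    return j[0] == "C" and j[-1] == "F"


# ---------------------------------------------------------------------------
# AIRR TSV I/O
# ---------------------------------------------------------------------------

def _tri(cell: str) -> Optional[bool]:
    if cell == "T":
        return True
    if cell == "F":
        return False
    return None


def _tri_str(value: Optional[bool]) -> str:
    return "" if value is None else ("T" if value else "F")


def read_airr(path: str | Path, animal: DesignRow) -> Repertoire:
    """Read an AIRR Rearrangement TSV into a :class:`Repertoire`.

    Comma-separated multi-gene calls split into lists, allele suffixes are
    stripped and duplicates collapsed; empty cells map to empty call lists or
    unknown tri-states.  Unparseable rows are skipped and counted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise AirrFormatError(f"missing mandatory AIRR column: {col}")
    records: list[RearrangementRecord] = []
    skipped = 0
    has = {c: c in df.columns for c in AIRR_COLUMNS}
    for row in df.itertuples(index=False):
        try:
            locus = row.locus.strip()
            d_len_raw = row.d_alignment_length.strip() if has["d_alignment_length"] else ""
            records.append(
                RearrangementRecord(
                    sequence_id=row.sequence_id,
                    locus=locus,
                    v_call=collapse_alleles(row.v_call),
                    d_call=collapse_alleles(row.d_call) if locus == "IGH" else (),
                    j_call=collapse_alleles(row.j_call),
                    c_call=(row.c_call.strip() or "unknown") if has["c_call"] else "unknown",
                    junction_aa=row.junction_aa.strip(),
                    d_alignment_length=(int(d_len_raw) if d_len_raw and locus == "IGH" else 0),
                    in_frame=_tri(row.vj_in_frame.strip()) if has["vj_in_frame"] else None,
                    has_stop=_tri(row.stop_codon.strip()) if has["stop_codon"] else None,
                )
            )
        except (ValueError, AttributeError):
            skipped += 1
    if skipped:
        logger.warning("read_airr(%s): skipped %d unreadable rows", path, skipped)
    return Repertoire(animal=animal, records=records)


def write_airr(rep: Repertoire, path: str | Path) -> None:
    """Write a repertoire as an AIRR Rearrangement TSV (fixed column order).

    Round-trips through :func:`read_airr`; byte-stable for a given repertoire.
    """
    rows = {
        "sequence_id": [r.sequence_id for r in rep.records],
        "locus": [r.locus for r in rep.records],
        "v_call": [",".join(r.v_call) for r in rep.records],
        "d_call": [",".join(r.d_call) for r in rep.records],
        "j_call": [",".join(r.j_call) for r in rep.records],
        "c_call": ["" if r.c_call == "unknown" else r.c_call for r in rep.records],
        "junction_aa": [r.junction_aa for r in rep.records],
        "d_alignment_length": [str(r.d_alignment_length) for r in rep.records],
        "vj_in_frame": [_tri_str(r.in_frame) for r in rep.records],
        "stop_codon": [_tri_str(r.has_stop) for r in rep.records],
    }
    pd.DataFrame(rows, columns=list(AIRR_COLUMNS)).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def short_gene_name(name: str) -> str:
    """Report-layer gene label: ``IGHV1-26`` → ``V1-26``; ``U`` unchanged."""
    if name == "U":
        return name
    for locus in LOCI:
        if name.startswith(locus):
            return name[len(locus):]
    return name


def gene_family(name: str) -> str:
    """Gene family label used for chord-diagram segments: ``IGHV1-26`` → ``V1``."""
    if name == "U":
        return "U"
    short = short_gene_name(name)
    return short.split("-", 1)[0]
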