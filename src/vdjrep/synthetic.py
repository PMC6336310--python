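"""Seeded generator of toy germline sets, per-animal repertoires, and TPM tables.

Emulates a 2x2x2 (AOS x TT x CpG) splenic bulk-RNA repertoire experiment:
each animal yields i.i.d. annotated rearrangement records whose gene-segment
and isotype sampling weights are the baseline weights multiplied by the
effect multipliers of every '+' factor of that animal, renormalized.
Junctions are built as ``C + core + anchor`` with cores drawn from a finite
shared ("public") pool with configured probability, else freshly random
("private").  Configured fractions of records carry ambiguous V calls,
missing or short D alignments, stop codons, or unknown frames.

Everything is reproducible from ``SimConfig.seed``: identical config, effects
and germline give byte-identical AIRR output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    AA_LETTERS,
    Design,
    DesignRow,
    ISOTYPES,
    RearrangementRecord,
    Repertoire,
)

__all__ = [
    "GermlineSet",
    "EffectSpec",
    "SimConfig",
    "default_design",
    "simulate_repertoires",
    "simulate_usage_counts",
    "simulate_tpm",
]


class ConfigurationError(ValueError):
    """Raised for impossible simulation configurations."""


# default heavy V genes: names drawn from commonly used C57BL/6 IGHV genes
_DEFAULT_IGHV = tuple(
    "IGHV" + g
    for g in (
        "1-18", "1-26", "1-31", "1-36", "1-53", "1-63", "1-69", "1-74", "1-76",
        "1-78", "1-80", "1-85", "3-6", "4-1", "5-16", "6-3", "8-8", "8-12",
        "9-3", "10-3",
    )
)
_DEFAULT_IGHD = ("IGHD1-1", "IGHD2-3", "IGHD3-1", "IGHD5-5")
_DEFAULT_IGHJ = ("IGHJ1", "IGHJ2", "IGHJ3", "IGHJ4")
_DEFAULT_IGKV = tuple(
    "IGKV" + g
    for g in (
        "1-132", "2-109", "3-4", "3-7", "4-55", "4-58", "4-63", "4-70", "4-71",
        "4-86", "4-91", "5-39", "5-48", "6-23", "6-25", "8-19", "8-30", "10-96",
        "12-46", "14-111",
    )
)
_DEFAULT_IGKJ = ("IGKJ1", "IGKJ2", "IGKJ4", "IGKJ5")
_DEFAULT_IGLV = ("IGLV1", "IGLV2", "IGLV3")
_DEFAULT_IGLJ = ("IGLJ1", "IGLJ2")


@dataclass(frozen=True)
class GermlineSet:
    """Per-locus germline gene lists (gene level; kappa/lambda have no D)."""

    ighv: tuple[str, ...] = _DEFAULT_IGHV
    ighd: tuple[str, ...] = _DEFAULT_IGHD
    ighj: tuple[str, ...] = _DEFAULT_IGHJ
    igkv: tuple[str, ...] = _DEFAULT_IGKV
    igkj: tuple[str, ...] = _DEFAULT_IGKJ
    iglv: tuple[str, ...] = _DEFAULT_IGLV
    iglj: tuple[str, ...] = _DEFAULT_IGLJ
    isotypes: tuple[str, ...] = tuple(i for i in ISOTYPES if i != "unknown")

    def __post_init__(self) -> None:
        for name in ("ighv", "ighd", "ighj", "igkv", "igkj", "iglv", "iglj"):
            genes = getattr(self, name)
            if len(set(genes)) != len(genes):
                raise ConfigurationError(f"duplicate gene names in {name}")

    def v_genes(self, locus: str) -> tuple[str, ...]:
        return {"IGH": self.ighv, "IGK": self.igkv, "IGL": self.iglv}[locus]

    def j_genes(self, locus: str) -> tuple[str, ...]:
        return {"IGH": self.ighj, "IGK": self.igkj, "IGL": self.iglj}[locus]


@dataclass(frozen=True)
class EffectSpec:
    """A multiplicative treatment effect on a sampling weight.

    When ``factor`` is '+' for an animal, the baseline weight of ``target``
    (a gene name, an isotype, or the special target ``"public_pool"`` scaling
    the public-CDR3 probability) is multiplied by ``multiplier``.
    ``multiplier == 1`` encodes no effect.
    """

    factor: str  # AOS | TT | CpG
    target: str
    multiplier: float

    def __post_init__(self) -> None:
        if self.factor not in ("AOS", "TT", "CpG"):
            raise ConfigurationError(f"unknown factor {self.factor!r}")
        if not self.multiplier > 0:
            raise ConfigurationError("effect multiplier must be > 0")


# baseline isotype mix: IgM-dominated, as in splenic bulk RNA
_DEFAULT_ISOTYPE_PROBS = {
    "IgM": 0.52,
    "IgD": 0.04,
    "IgG1": 0.12,
    "IgG2b": 0.08,
    "IgG2c": 0.06,
    "IgG3": 0.04,
    "IgA": 0.06,
    "IgE": 0.01,
    "unknown": 0.07,
}


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults state the emulated experiment.

    ``n_per_group=4`` matches the sequenced cohort (four animals in each of
    the eight treatment cells, two per suspension trial).  The default
    10^4 reads/animal is a desk-scale stand-in for the study's ~10^5
    assessed reads; scale is configurable, never asserted.
    """

    n_per_group: int = 4
    reads_per_animal: int = 10_000
    #: power-law exponent for baseline V weights (w_i ∝ 1/rank^a); with 20
    #: genes and a=1 a handful of genes exceed 5% of the repertoire
    v_weight_exponent: float = 1.0
    d_weight_exponent: float = 1.0
    j_weight_exponent: float = 0.5
    isotype_probs: tuple[tuple[str, float], ...] = tuple(_DEFAULT_ISOTYPE_PROBS.items())
    two_v_rate: float = 0.10
    multi_v_rate: float = 0.03
    d_missing_rate: float = 0.25
    d_short_rate: float = 0.15  # of reported Ds: alignment < 6 nt
    j_multi_rate: float = 0.02
    unknown_rate: float = 0.45  # IMGT 'unknown functionality' fraction
    unproductive_rate: float = 0.05
    invalid_motif_rate: float = 0.02
    mean_cdr3_length_igh: float = 12.0
    mean_cdr3_length_igk: float = 9.0
    public_pool_size: int = 500
    p_public: float = 0.20
    lambda_fraction: float = 0.05  # of light-chain reads; lambda excluded downstream
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "two_v_rate": self.two_v_rate,
            "multi_v_rate": self.multi_v_rate,
            "d_missing_rate": self.d_missing_rate,
            "d_short_rate": self.d_short_rate,
            "j_multi_rate": self.j_multi_rate,
            "unknown_rate": self.unknown_rate,
            "unproductive_rate": self.unproductive_rate,
            "invalid_motif_rate": self.invalid_motif_rate,
            "p_public": self.p_public,
            "lambda_fraction": self.lambda_fraction,
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.two_v_rate + self.multi_v_rate > 1:
            raise ConfigurationError("ambiguous-V rates sum above 1")
        if self.unknown_rate + self.unproductive_rate > 1:
            raise ConfigurationError("functionality rates sum above 1")
        if self.n_per_group < 2:
            raise ConfigurationError(
                "n_per_group must be >= 2 for the factorial ANOVA to be estimable"
            )
        if self.reads_per_animal < 0:
            raise ConfigurationError("reads_per_animal must be >= 0")
        total = sum(p for _, p in self.isotype_probs)
        if not total > 0:
            raise ConfigurationError("isotype probabilities sum to zero")


def default_design(n_per_group: int = 4) -> Design:
    """Full-factorial design: ``n_per_group`` animals in each of 8 cells.

    Animals split evenly across two suspension trials, as in the cohort.
    """
    rows = []
    idx = 1
    for a in (False, True):
        for t in (False, True):
            for c in (False, True):
                for i in range(n_per_group):
                    rows.append(
                        DesignRow(
                            animal_id=f"m{idx:03d}",
                            aos=a,
                            tt=t,
                            cpg=c,
                            trial=1 + (i % 2),
                        )
                    )
                    idx += 1
    return Design(rows)


def _power_law_weights(n: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1, dtype=float) ** exponent
    return w / w.sum()


def _apply_effects(
    base: np.ndarray,
    names: Sequence[str],
    effects: Sequence[EffectSpec],
    animal: DesignRow,
) -> np.ndarray:
    """Multiply baseline weights by every applicable effect, renormalize."""
    w = base.astype(float).copy()
    index = {n: i for i, n in enumerate(names)}
    on = {"AOS": animal.aos, "TT": animal.tt, "CpG": animal.cpg}
    for e in effects:
        if on[e.factor] and e.target in index:
            w[index[e.target]] *= e.multiplier
    total = w.sum()
    if not total > 0:
        raise ConfigurationError("all sampling weights zeroed by effects")
    return w / total


def _effective_p_public(cfg: SimConfig, effects: Sequence[EffectSpec], animal: DesignRow) -> float:
    p = cfg.p_public
    on = {"AOS": animal.aos, "TT": animal.tt, "CpG": animal.cpg}
    for e in effects:
        if e.target == "public_pool" and on[e.factor]:
            p *= e.multiplier
    return min(p, 1.0)


def effective_v_weights(
    cfg: SimConfig,
    germline: GermlineSet,
    effects: Sequence[EffectSpec],
    animal: DesignRow,
    locus: str = "IGH",
) -> pd.Series:
    """Effect-adjusted V-gene sampling weights for one animal (sums to 1)."""
    genes = germline.v_genes(locus)
    base = _power_law_weights(len(genes), cfg.v_weight_exponent)
    return pd.Series(_apply_effects(base, genes, effects, animal), index=list(genes))


def _public_pool(cfg: SimConfig, locus: str, mean_len: float) -> list[str]:
    """The shared core pool for a locus, fixed across animals for one seed."""
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 7919, sum(map(ord, locus))])
    )
    return _random_cores(rng, cfg.public_pool_size, mean_len)


def _random_cores(rng: np.random.Generator, n: int, mean_len: float) -> list[str]:
    if n == 0:
        return []
    lengths = np.maximum(rng.poisson(mean_len, size=n), 3)
    letters = rng.integers(0, len(AA_LETTERS), size=int(lengths.sum()))
    chars = np.frombuffer(AA_LETTERS.encode(), dtype="S1")[letters].astype("U1")
    out, pos = [], 0
    for ln in lengths:
        out.append("".join(chars[pos : pos + ln]))
        pos += ln
    return out


def _simulate_animal(
    cfg: SimConfig,
    germline: GermlineSet,
    effects: Sequence[EffectSpec],
    animal: DesignRow,
    locus: str,
    rng: np.random.Generator,
    pool: list[str],
) -> list[RearrangementRecord]:
    n = cfg.reads_per_animal
    if n == 0:
        return []
    light = locus != "IGH"
    v_genes = list(germline.v_genes(locus))
    j_genes = list(germline.j_genes(locus))
    mean_len = cfg.mean_cdr3_length_igh if locus == "IGH" else cfg.mean_cdr3_length_igk

    v_w = _apply_effects(
        _power_law_weights(len(v_genes), cfg.v_weight_exponent), v_genes, effects, animal
    )
    j_w = _apply_effects(
        _power_law_weights(len(j_genes), cfg.j_weight_exponent), j_genes, effects, animal
    )
    v_idx = rng.choice(len(v_genes), size=n, p=v_w)
    j_idx = rng.choice(len(j_genes), size=n, p=j_w)

    # ambiguous V calls: a second (or second+third) distinct gene, uniform
    u_v = rng.random(n)
    n_extra_v = np.where(u_v < cfg.multi_v_rate, 2, np.where(u_v < cfg.multi_v_rate + cfg.two_v_rate, 1, 0))
    extra_v = rng.integers(0, len(v_genes) - 1, size=(n, 2))
    u_j = rng.random(n) < cfg.j_multi_rate
    extra_j = rng.integers(0, max(len(j_genes) - 1, 1), size=n)

    if not light:
        d_genes = list(germline.ighd)
        d_w = _apply_effects(
            _power_law_weights(len(d_genes), cfg.d_weight_exponent), d_genes, effects, animal
        )
        d_idx = rng.choice(len(d_genes), size=n, p=d_w)
        d_missing = rng.random(n) < cfg.d_missing_rate
        d_short = rng.random(n) < cfg.d_short_rate
        d_len = np.where(d_short, rng.integers(1, 6, size=n), rng.integers(6, 17, size=n))
        d_len = np.where(d_missing, 0, d_len)
        iso_names = [k for k, _ in cfg.isotype_probs]
        iso_p = np.array([p for _, p in cfg.isotype_probs], dtype=float)
        iso_p = _apply_effects(iso_p, iso_names, effects, animal)
        iso_idx = rng.choice(len(iso_names), size=n, p=iso_p)

    # functionality classes
    u_f = rng.random(n)
    is_unknown = u_f < cfg.unknown_rate
    is_unprod = (~is_unknown) & (u_f < cfg.unknown_rate + cfg.unproductive_rate)

    # junction cores: public pool with probability p_public, else private
    p_pub = _effective_p_public(cfg, effects, animal)
    from_pool = (rng.random(n) < p_pub) & (len(pool) > 0)
    pool_idx = rng.integers(0, max(len(pool), 1), size=n)
    private = _random_cores(rng, n, mean_len)
    bad_anchor = rng.random(n) < cfg.invalid_motif_rate
    anchor_default = "W" if locus == "IGH" else "F"
    alt_anchor = rng.integers(0, len(AA_LETTERS), size=n)

    records: list[RearrangementRecord] = []
    for i in range(n):
        k_extra = int(n_extra_v[i])
        v_list = [v_genes[v_idx[i]]]
        for e in range(k_extra):
            alt = extra_v[i, e] + (extra_v[i, e] >= v_idx[i])  # skip the primary
            g = v_genes[alt % len(v_genes)]
            if g not in v_list:
                v_list.append(g)
        j_list = [j_genes[j_idx[i]]]
        if u_j[i] and len(j_genes) > 1:
            alt = extra_j[i] + (extra_j[i] >= j_idx[i])
            g = j_genes[alt % len(j_genes)]
            if g not in j_list:
                j_list.append(g)

        core = pool[pool_idx[i]] if from_pool[i] else private[i]
        anchor = anchor_default
        if bad_anchor[i]:
            anchor = AA_LETTERS[alt_anchor[i]]
        junction = "C" + core + anchor

        if is_unknown[i]:
            in_frame: Optional[bool] = None
            has_stop: Optional[bool] = None
        elif is_unprod[i]:
            in_frame, has_stop = True, True
        else:
            in_frame, has_stop = True, False

        if light:
            d_call: tuple[str, ...] = ()
            d_length = 0
            c_call = "unknown"
        else:
            d_call = () if d_missing[i] else (d_genes[d_idx[i]],)
            d_length = int(d_len[i])
            c_call = iso_names[iso_idx[i]]

        records.append(
            RearrangementRecord(
                sequence_id=f"{animal.animal_id}_{locus}_{i:06d}",
                locus=locus,
                v_call=tuple(v_list),
                d_call=d_call,
                j_call=tuple(j_list),
                c_call=c_call,
                junction_aa=junction,
                d_alignment_length=d_length,
                in_frame=in_frame,
                has_stop=has_stop,
            )
        )
    return records


def simulate_repertoire(
    cfg: SimConfig,
    germline: GermlineSet,
    effects: Sequence[EffectSpec],
    animal: DesignRow,
    locus: str = "IGH",
    animal_index: int = 0,
) -> Repertoire:
    """Simulate one animal's repertoire (no lambda admixture).

    ``animal_index`` selects the same per-animal stream that
    :func:`simulate_repertoires` would use at that design position.
    """
    pool = _public_pool(
        cfg, locus, cfg.mean_cdr3_length_igh if locus == "IGH" else cfg.mean_cdr3_length_igk
    )
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, sum(map(ord, locus)), animal_index])
    )
    return Repertoire(
        animal=animal,
        records=_simulate_animal(cfg, germline, effects, animal, locus, rng, pool),
    )


def simulate_repertoires(
    cfg: SimConfig,
    germline: GermlineSet,
    effects: Sequence[EffectSpec],
    design: Design,
    locus: str = "IGH",
) -> list[Repertoire]:
    """Simulate one repertoire per design animal for one chain.

    For the light chain (``locus="IGK"``), a ``lambda_fraction`` of reads is
    emitted as IGL records, mirroring the small lambda contingent that
    downstream analyses exclude.
    """
    if locus not in ("IGH", "IGK"):
        raise ConfigurationError(f"simulated locus must be IGH or IGK, got {locus!r}")
    design.validate_full_factorial(n_min=1)
    pool = _public_pool(cfg, locus, cfg.mean_cdr3_length_igh if locus == "IGH" else cfg.mean_cdr3_length_igk)
    out: list[Repertoire] = []
    locus_code = sum(map(ord, locus))
    for a_idx, animal in enumerate(design):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, locus_code, a_idx]))
        if locus == "IGK" and cfg.lambda_fraction > 0 and cfg.reads_per_animal > 0:
            n_lambda = int(round(cfg.reads_per_animal * cfg.lambda_fraction))
            cfg_k = _with_reads(cfg, cfg.reads_per_animal - n_lambda)
            cfg_l = _with_reads(cfg, n_lambda)
            records = _simulate_animal(cfg_k, germline, effects, animal, "IGK", rng, pool)
            records += _simulate_animal(cfg_l, germline, effects, animal, "IGL", rng, [])
        else:
            records = _simulate_animal(cfg, germline, effects, animal, locus, rng, pool)
        out.append(Repertoire(animal=animal, records=records))
    return out


def _with_reads(cfg: SimConfig, n: int) -> SimConfig:
    from dataclasses import replace

    return replace(cfg, reads_per_animal=n)


def simulate_usage_counts(
    cfg: SimConfig,
    germline: GermlineSet,
    effects: Sequence[EffectSpec],
    design: Design,
    locus: str = "IGH",
) -> pd.DataFrame:
    """Fast path: per-animal V-gene usage counts as direct multinomial draws.

    Because records are i.i.d., counting unambiguous single-V records is a
    multinomial sample from the effect-adjusted weights; this path draws the
    counts directly without materializing records.  It is the workhorse for
    many-replicate statistical calibration, where full record synthesis would
    be needlessly slow.  Ambiguous-call bookkeeping is not emulated here.
    """
    genes = list(germline.v_genes(locus))
    rows = {}
    locus_code = sum(map(ord, locus))
    for a_idx, animal in enumerate(design):
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, locus_code, a_idx, 11])
        )
        w = _apply_effects(
            _power_law_weights(len(genes), cfg.v_weight_exponent), genes, effects, animal
        )
        rows[animal.animal_id] = rng.multinomial(cfg.reads_per_animal, w)
    return pd.DataFrame.from_dict(rows, orient="index", columns=genes)


def simulate_tpm(
    genes: Sequence[str],
    design: Design,
    effects: Sequence[EffectSpec],
    seed: int,
    base_mean: float = 100.0,
    sigma: float = 0.35,
) -> pd.DataFrame:
    """Simulate a gene x animal TPM table with log-normal noise.

    Effect multipliers scale the expected TPM of '+' animals of the named
    factor; ``sigma`` is the log-scale SD.  Column normalization is upstream
    of this artifact and not emulated.
    """
    design.validate_full_factorial(n_min=2)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104729]))
    data = np.zeros((len(genes), len(design)))
    for gi, gene in enumerate(genes):
        for ai, animal in enumerate(design):
            mean = base_mean
            on = {"AOS": animal.aos, "TT": animal.tt, "CpG": animal.cpg}
            for e in effects:
                if e.target == gene and on[e.factor]:
                    mean *= e.multiplier
            data[gi, ai] = rng.lognormal(np.log(mean), sigma)
    return pd.DataFrame(data, index=list(genes), columns=design.animal_ids)
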