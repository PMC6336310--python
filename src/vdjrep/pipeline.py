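"""Simulate → analyze → report orchestration.

Each stage is a plain function over a configuration mapping so the CLI stays
a thin wrapper.  All outputs are TSV/JSON with fixed ordering; a manifest
declares every file written, the seed, and a hash of the configuration, so
identical (config, seed) runs produce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from . import cdr3 as cdr3mod
from . import pairing as pairingmod
from . import stats as statsmod
from . import usage as usagemod
from .model import (
    AOS_TT_CPG,
    Design,
    Repertoire,
    SALINE,
    TT_CPG,
    classify_functionality,
    read_airr,
    write_airr,
)
from .synthetic import (
    EffectSpec,
    GermlineSet,
    SimConfig,
    default_design,
    simulate_repertoires,
    simulate_tpm,
)

logger = logging.getLogger(__name__)

FACTORS = ("AOS", "TT", "CpG")
NAMED_GROUPS = (SALINE, TT_CPG, AOS_TT_CPG)

#: Default injected effects: directions mirror the study's observations
#: (AOS raises IgM and lowers IgG and a V1-family gene; CpG raises IgA).
DEFAULT_EFFECTS = (
    {"factor": "AOS", "target": "IgM", "multiplier": 1.25},
    {"factor": "AOS", "target": "IgG1", "multiplier": 0.75},
    {"factor": "AOS", "target": "IGHV1-63", "multiplier": 0.7},
    {"factor": "CpG", "target": "IgA", "multiplier": 1.5},
    {"factor": "TT", "target": "IGHD5-5", "multiplier": 0.8},
)

#: Default marker panel and effects for the TPM screen (plasma-cell marker
#: suppressed under unloading; memory marker reduced below the 2-fold line).
DEFAULT_MARKERS = ("B220", "CD62L", "CD44", "CD27", "CD19", "CD138", "CD80")
DEFAULT_TPM_EFFECTS = (
    {"factor": "AOS", "target": "CD138", "multiplier": 1 / 2.15},
    {"factor": "AOS", "target": "CD27", "multiplier": 1 / 1.40},
)


def config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def _parse_effects(raw: Sequence[Mapping[str, Any]]) -> list[EffectSpec]:
    return [
        EffectSpec(factor=str(e["factor"]), target=str(e["target"]), multiplier=float(e["multiplier"]))
        for e in raw
    ]


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _write_df(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n", float_format="%.6g")


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def run_simulate(config: Mapping[str, Any], out_dir: str | Path) -> dict:
    """Simulate heavy- and kappa-chain AIRR files, a design TSV and a TPM
    table; returns (and writes) the manifest."""
    out = Path(out_dir)
    (out / "airr").mkdir(parents=True, exist_ok=True)
    sim = dict(config.get("simulate", {}))
    seed = int(config.get("seed", 0))
    cfg = SimConfig(
        n_per_group=int(sim.get("n_per_group", 4)),
        reads_per_animal=int(sim.get("reads_per_animal", 10_000)),
        seed=seed,
        **{
            k: sim[k]
            for k in sim
            if k
            in {
                "two_v_rate", "multi_v_rate", "d_missing_rate", "d_short_rate",
                "j_multi_rate", "unknown_rate", "unproductive_rate",
                "invalid_motif_rate", "public_pool_size", "p_public",
                "lambda_fraction", "v_weight_exponent",
            }
        },
    )
    germline = GermlineSet()
    effects = _parse_effects(sim.get("effects", DEFAULT_EFFECTS))
    design = default_design(cfg.n_per_group)

    files: list[str] = []
    for locus in ("IGH", "IGK"):
        for rep in simulate_repertoires(cfg, germline, effects, design, locus=locus):
            rel = f"airr/{rep.animal.animal_id}_{locus}.tsv"
            write_airr(rep, out / rel)
            files.append(rel)

    design.write_tsv(out / "design.tsv")
    files.append("design.tsv")

    markers = list(sim.get("markers", DEFAULT_MARKERS))
    tpm_effects = _parse_effects(sim.get("tpm_effects", DEFAULT_TPM_EFFECTS))
    tpm = simulate_tpm(markers, design, tpm_effects, seed=seed)
    _write_df(tpm.rename_axis("gene"), out / "tpm.tsv")
    files.append("tpm.tsv")

    manifest = {
        "stage": "simulate",
        "seed": seed,
        "config_sha256": config_hash(config),
        "files": sorted(files),
    }
    _write_json(manifest, out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------

def _load_repertoires(
    airr_dir: Path, design: Design, locus: str
) -> list[Repertoire]:
    reps, missing = [], []
    for row in design:
        path = airr_dir / f"{row.animal_id}_{locus}.tsv"
        if not path.exists():
            missing.append(row.animal_id)
            continue
        reps.append(read_airr(path, row))
    if missing:
        raise FileNotFoundError(
            f"no {locus} AIRR file for animals: {', '.join(missing)}"
        )
    return reps


def _read_accounting(reps: Sequence[Repertoire]) -> pd.DataFrame:
    rows = []
    for rep in reps:
        tally = {"productive": 0, "unknown": 0, "unproductive": 0}
        for r in rep.records:
            tally[classify_functionality(r)] += 1
        rows.append(
            {
                "animal_id": rep.animal.animal_id,
                "cell": rep.animal.cell,
                **tally,
                "total_assessed": tally["productive"] + tally["unknown"],
            }
        )
    return pd.DataFrame(rows)


def _sharing_section(
    reps: Sequence[Repertoire], design: Design, class_switched_only: bool
) -> dict:
    sets = cdr3mod.build_cdr3_sets(
        reps, design, grouping="cell", class_switched_only=class_switched_only
    )
    nonempty = [s for s in sets if len(s)]
    section: dict[str, Any] = {
        "group_sizes": {s.label: len(s) for s in sets},
    }
    if len(nonempty) >= 2:
        table = cdr3mod.sharing_table(nonempty)
        section["shared_by_k"] = {
            str(k): {"count": int(row["count"]), "percent": float(row["percent"])}
            for k, row in table.iterrows()
        }
    overlaps = {}
    for factor in FACTORS:
        fsets = cdr3mod.build_cdr3_sets(
            reps, design, grouping=f"factor:{factor}",
            class_switched_only=class_switched_only,
        )
        if len(fsets) == 2:
            ov = cdr3mod.variable_overlap(fsets[0], fsets[1])
            overlaps[factor] = {
                "size_minus": ov.size_a,
                "size_plus": ov.size_b,
                "shared": ov.shared,
                "percent_of_minus": round(ov.percent_of_a, 2),
                "percent_of_plus": round(ov.percent_of_b, 2),
            }
    section["factor_overlaps"] = overlaps
    return section


def _analyze_chain(
    reps: list[Repertoire],
    design: Design,
    out: Path,
    prefix: str,
    options: Mapping[str, Any],
    files: list[str],
) -> dict:
    """Run the full analysis battery for one chain; returns summary JSON."""
    locus = "IGH" if prefix == "heavy" else "IGK"
    productive_only = bool(options.get("productive_only", False))
    hf_threshold = float(options.get("high_frequency_threshold", 5.0))
    pair_threshold = float(options.get("pair_exclusion_threshold", 0.1))
    d_rule_on_j = bool(options.get("d_length_rule_on_j", False))
    summary: dict[str, Any] = {}

    def save(df: pd.DataFrame, name: str, index: bool = True) -> None:
        _write_df(df, out / name, index=index)
        files.append(name)

    # read accounting (Table-1 shape)
    accounting = _read_accounting(reps)
    save(accounting, f"{prefix}_read_accounting.tsv", index=False)
    summary["read_accounting"] = {
        "mean_productive": float(accounting["productive"].mean()),
        "mean_unknown": float(accounting["unknown"].mean()),
        "mean_total_assessed": float(accounting["total_assessed"].mean()),
    }

    # usage tables + per-feature ANOVA + variance comparison
    axes = ("V", "D", "J") if locus == "IGH" else ("V", "J")
    anova_frames = []
    variance_rows = {}
    for axis in axes:
        table = usagemod.usage_table(reps, axis, productive_only=productive_only)
        save(table.percent.rename_axis("animal_id"), f"{prefix}_usage_{axis}.tsv")
        save(table.group_means(design).rename_axis("cell"), f"{prefix}_usage_{axis}_group_means.tsv")
        aov = statsmod.anova_by_feature(table, design)
        aov.insert(0, "axis", axis)
        anova_frames.append(aov)
        totals = statsmod.whole_animal_variation(table)
        variance_rows[axis] = totals
        comp = statsmod.compare_variance(totals, design)
        save(comp.contrasts, f"{prefix}_variance_contrasts_{axis}.tsv", index=False)
        summary.setdefault("variance_global_p", {})[axis] = comp.global_p
        if axis == "V":
            hf = usagemod.high_frequency_segments(
                table, design, groups=[g for g in NAMED_GROUPS], threshold=hf_threshold
            )
            summary["high_frequency_V"] = sorted(hf)
            means = table.group_means(design)
            regs = {}
            for a, b in ((SALINE, TT_CPG), (SALINE, AOS_TT_CPG), (TT_CPG, AOS_TT_CPG)):
                r2, p = statsmod.usage_regression(means.loc[a], means.loc[b])
                regs[f"{a} vs {b}"] = {"r2": round(r2, 4), "p": p}
            summary["usage_regression_V"] = regs

    # isotype usage (heavy only)
    if locus == "IGH":
        iso = usagemod.constant_usage(reps, productive_only=productive_only)
        if not iso.percent.empty:
            save(iso.percent.rename_axis("animal_id"), f"{prefix}_usage_isotype.tsv")
            aov = statsmod.anova_by_feature(iso, design)
            aov.insert(0, "axis", "isotype")
            anova_frames.append(aov)

        switched = [usagemod.subset_class_switched(rep) for rep in reps]
        sw_table = usagemod.usage_table(switched, "V", productive_only=productive_only)
        save(sw_table.percent.rename_axis("animal_id"), f"{prefix}_switched_usage_V.tsv")
        sw_hf = usagemod.high_frequency_segments(
            sw_table, design, groups=[g for g in NAMED_GROUPS], threshold=hf_threshold
        )
        summary["high_frequency_V_class_switched"] = sorted(sw_hf)

    # CDR3 lengths
    lengths, mean_lengths = cdr3mod.cdr3_length_distribution(reps)
    save(lengths.percent.rename_axis("animal_id"), f"{prefix}_cdr3_length.tsv")
    save(mean_lengths.rename("mean_cdr3_length").to_frame().rename_axis("animal_id"), f"{prefix}_cdr3_mean_length.tsv")
    aov = statsmod.anova_by_feature(lengths, design)
    aov.insert(0, "axis", "cdr3_length")
    anova_frames.append(aov)
    grand_mean = pd.Series(
        {design[a].cell: v for a, v in mean_lengths.items()}
    ).groupby(level=0).mean()
    summary["mean_cdr3_length_by_cell"] = {k: round(float(v), 2) for k, v in grand_mean.items()}

    save(pd.concat(anova_frames, ignore_index=True), f"{prefix}_anova.tsv", index=False)

    # pairing
    mode = "VDJ" if locus == "IGH" else "VJ"
    table = pairingmod.pairing_table(reps, mode=mode, d_length_rule_on_j=d_rule_on_j)
    save(table.percent, f"{prefix}_pairing_{mode}.tsv")
    ranks = pairingmod.rank_top_combinations(table, design, groups=list(NAMED_GROUPS), k=5)
    save(ranks, f"{prefix}_pairing_top5_ranks.tsv")
    summary["top_combination_union_size"] = int(len(ranks))

    vj = pairingmod.pairing_table(reps, mode="VJ", d_length_rule_on_j=d_rule_on_j)
    for factor in FACTORS:
        kept = pairingmod.filter_low_frequency_pairs(vj, design, factor, threshold=pair_threshold)
        save(kept.factor_level_means(design, factor), f"{prefix}_vj_{factor}_filtered_means.tsv")
    for group in NAMED_GROUPS:
        label = group.replace("+", "p").replace("-", "m")
        name = f"{prefix}_circos_{label}.txt"
        pairingmod.export_circos_links(vj, design, group, out / name)
        files.append(name)

    # CDR3 sharing and overlaps, whole and class-switched
    summary["sharing"] = _sharing_section(reps, design, class_switched_only=False)
    if locus == "IGH":
        summary["sharing_class_switched"] = _sharing_section(
            reps, design, class_switched_only=True
        )
    return summary


def run_analyze(
    config: Mapping[str, Any],
    airr_dir: str | Path,
    design_path: str | Path,
    out_dir: str | Path,
    tpm_path: str | Path | None = None,
) -> dict:
    """Execute the full analysis battery; writes tables and a summary JSON."""
    airr_dir, out = Path(airr_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not airr_dir.exists() or not any(airr_dir.glob("*.tsv")):
        raise FileNotFoundError(f"no AIRR files found under {airr_dir}")
    design = Design.read_tsv(design_path)
    options = dict(config.get("analysis", {}))
    files: list[str] = []

    heavy = _load_repertoires(airr_dir, design, "IGH")
    light = usagemod.exclude_lambda(_load_repertoires(airr_dir, design, "IGK"))

    summary = {
        "heavy": _analyze_chain(heavy, design, out, "heavy", options, files),
        "kappa": _analyze_chain(light, design, out, "kappa", options, files),
    }

    if tpm_path is not None and Path(tpm_path).exists():
        tpm = pd.read_csv(tpm_path, sep="\t", index_col=0)
        screen_rows = []
        for factor in FACTORS:
            for res in statsmod.marker_screen(tpm, design, factor):
                screen_rows.append(
                    {
                        "gene": res.gene,
                        "factor": factor,
                        "fold_change": round(res.fold_change, 2) if res.defined else "NA",
                        "p_value": res.p_value if res.defined else "NA",
                        "flagged": res.flagged,
                    }
                )
        screen = pd.DataFrame(screen_rows)
        _write_df(screen, out / "marker_screen.tsv", index=False)
        files.append("marker_screen.tsv")
        summary["marker_screen_flagged"] = sorted(
            {f"{r['gene']}:{r['factor']}" for r in screen_rows if r["flagged"]}
        )

    _write_json(summary, out / "summary.json")
    files.append("summary.json")
    manifest = {
        "stage": "analyze",
        "seed": int(config.get("seed", 0)),
        "config_sha256": config_hash(config),
        "files": sorted(files),
    }
    _write_json(manifest, out / "manifest.json")
    return summary


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def run_report(in_dir: str | Path) -> dict:
    """Condense an analysis bundle into report.json + report.md."""
    in_path = Path(in_dir)
    summary_path = in_path / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.json under {in_path}; run analyze first")
    summary = json.loads(summary_path.read_text())
    missing = [k for k in ("heavy", "kappa") if k not in summary]

    lines = ["# Repertoire analysis report", ""]
    if missing:
        lines.append(f"WARNING: missing sections: {', '.join(missing)}")
    for chain in ("heavy", "kappa"):
        if chain not in summary:
            continue
        sec = summary[chain]
        lines.append(f"## {chain.capitalize()} chain")
        acc = sec.get("read_accounting", {})
        lines.append(
            f"- mean assessed reads/animal: {acc.get('mean_total_assessed', 0):.0f} "
            f"(productive {acc.get('mean_productive', 0):.0f}, "
            f"unknown {acc.get('mean_unknown', 0):.0f})"
        )
        if "high_frequency_V" in sec:
            lines.append(f"- high-frequency V segments (>5% in a named group): {', '.join(sec['high_frequency_V']) or 'none'}")
        shared = sec.get("sharing", {}).get("shared_by_k", {})
        if shared:
            lines.append("- shared unique CDR3s by number of groups (count, percent):")
            for k in sorted(shared, key=int):
                row = shared[k]
                lines.append(f"    - {k}: {row['count']} ({row['percent']:.2f}%)")
        for factor, ov in sec.get("sharing", {}).get("factor_overlaps", {}).items():
            lines.append(
                f"- {factor} overlap: {ov['shared']} shared CDR3s "
                f"({ov['percent_of_minus']:.0f}% of '-', {ov['percent_of_plus']:.0f}% of '+')"
            )
        lines.append("")
    report_md = "\n".join(lines) + "\n"
    (in_path / "report.md").write_text(report_md, encoding="utf-8")
    report = {"sections": sorted(set(summary) - {"marker_screen_flagged"}), "missing": missing, "summary": summary}
    _write_json(report, in_path / "report.json")
    return report
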