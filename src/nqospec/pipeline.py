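"""End-to-end report: subtraction -> classification -> spectrum ->
spatial -> context -> saturation, with per-stage TSV outputs."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .context import build_context_matrix, context_bias_report, extract_context
from .io_formats import (
    AnnotationSet,
    GenomeSequence,
    StrainTable,
    VariantRecord,
    read_bed,
    read_fasta,
    read_gff,
    read_strain_table,
    read_vcf,
    subtract_parent_variants,
)
from .saturation import (
    DEFAULT_M,
    min_spores,
    saturation_probability,
    SaturationParams,
    spectrum_to_saturation_inputs,
)
from .spatial import (
    chromosome_distribution_test,
    inter_mutation_distances,
    ks_exponential_test,
    proximal_pairs,
)
from .spectrum import (
    A_CLASSES,
    G_CLASSES,
    SNV_CLASSES,
    classify_calls,
    flag_hypermutators,
    purine_ratio,
    region_classify,
    summarize_spectrum,
    transition_bias_test,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "dose_effect_test"]

log = logging.getLogger("nqospec")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs and thresholds for one pipeline run."""

    vcf_paths: dict[str, Path]  # strain id -> VCF
    fasta_path: Path
    gff_path: Path | None = None
    strain_table_path: Path | None = None
    exclusion_bed_path: Path | None = None
    parent_vcf_paths: Sequence[Path] = ()
    outdir: Path = Path("nqospec_out")
    proximal_window: int = 10
    saturation_threshold: float = 0.9
    saturation_grid: float = 1e7
    mean_load_m: float | None = None  # default: observed mean among kept strains
    seed: int = 0

    def __post_init__(self) -> None:
        for p in [self.fasta_path, *self.vcf_paths.values(), *self.parent_vcf_paths]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        for p in (self.gff_path, self.strain_table_path, self.exclusion_bed_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def dose_effect_test(strain_table: StrainTable) -> tuple[float, float]:
    """Welch two-sample t-test of per-strain loads grouped by kill fraction.

    Returns (t, p). Requires at least two strains in each of exactly
    the two largest dose groups; groups beyond two are rejected.
    """
    df = strain_table.frame
    groups = [g["n_mutations"].to_numpy(float) for _, g in df.groupby("kill")]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("need at least two dose groups with >= 2 strains each")
    a, b = sorted(groups, key=len, reverse=True)[:2]
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0  # identical constant groups: no evidence of any effect
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _stage(name: str):
    log.info("stage: %s", name)
    return name


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and emit per-stage TSVs plus a JSON summary.

    Returns the summary dict. Stage failures raise
    :class:`PipelineError` naming the stage; outputs written before the
    failure are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "proximal_window": config.proximal_window,
            "saturation_threshold": config.saturation_threshold,
            "saturation_grid": config.saturation_grid,
        },
    }

    stage = _stage("load_inputs")
    try:
        genome = read_fasta(config.fasta_path)
        annot = (
            read_gff(config.gff_path, chrom_lengths=genome.lengths)
            if config.gff_path
            else None
        )
        exclusions = (
            read_bed(config.exclusion_bed_path) if config.exclusion_bed_path else {}
        )
        parents: list[VariantRecord] = []
        for p in config.parent_vcf_paths:
            parents.extend(read_vcf(p, strain="parent"))
        per_strain = {
            strain: read_vcf(path, strain=strain)
            for strain, path in sorted(config.vcf_paths.items())
        }
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        raise PipelineError(stage, str(exc)) from exc

    stage = _stage("subtract")
    try:
        per_strain = {
            strain: subtract_parent_variants(recs, parents)
            for strain, recs in per_strain.items()
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = _stage("strain_filter")
    try:
        if config.strain_table_path:
            table = read_strain_table(config.strain_table_path)
            counts = {s: len(r) for s, r in per_strain.items()}
            table.frame["n_mutations"] = [
                counts.get(s, int(n))
                for s, n in zip(table.frame["strain"], table.frame["n_mutations"])
            ]
        else:
            table = StrainTable(
                pd.DataFrame(
                    {
                        "strain": list(per_strain),
                        "dose": "unknown",
                        "kill": 0.5,
                        "n_mutations": [len(r) for r in per_strain.values()],
                    }
                )
            )
        table = flag_hypermutators(table)
        kept = [s for s in table.kept_strains() if s in per_strain]
        if not kept:
            raise ValueError("no strains remain after hypermutator exclusion")
        records = [r for s in kept for r in per_strain[s]]
        summary["strains"] = {
            "total": len(per_strain),
            "kept": len(kept),
            "excluded": sorted(set(per_strain) - set(kept)),
        }
        table.frame.to_csv(outdir / "strains.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = _stage("classify")
    try:
        calls = classify_calls(records)
        spec_summary = summarize_spectrum(calls)
        if annot is not None:
            region_counts, region_labels = region_classify(calls, annot)
        else:
            region_counts, region_labels = {}, ["NA"] * len(calls)
        pd.DataFrame(
            {
                "chrom": [c.record.chrom for c in calls],
                "pos": [c.record.pos for c in calls],
                "ref": [c.record.ref for c in calls],
                "alt": [c.record.alt for c in calls],
                "strain": [c.record.strain for c in calls],
                "class": [c.klass.value for c in calls],
                "flipped": [c.flipped for c in calls],
                "transition": [c.klass.is_snv and c.is_transition for c in calls],
                "region": region_labels,
            }
        ).to_csv(outdir / "calls.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = _stage("spectrum")
    try:
        ratio, ratio_label = purine_ratio(spec_summary)
        chi_g = transition_bias_test(
            spec_summary.transitions_G, spec_summary.transversions_G
        )
        chi_a = (
            transition_bias_test(
                spec_summary.transitions_A, spec_summary.transversions_A
            )
            if spec_summary.adenine_total
            else None
        )
        summary["spectrum"] = {
            "counts": {k.value: spec_summary.counts[k] for k in SNV_CLASSES},
            "indels": spec_summary.indel_total,
            "total_snv": spec_summary.total_snv,
            "frequencies": {
                k.value: spec_summary.frequencies[k] for k in SNV_CLASSES
            },
            "guanine_total": spec_summary.guanine_total,
            "adenine_total": spec_summary.adenine_total,
            "guanine_share_pct": 100.0 * spec_summary.guanine_fraction,
            "purine_ratio": ratio,
            "purine_ratio_label": ratio_label,
            "transition_chi2_G": dataclasses.asdict(chi_g),
            "transition_chi2_A": dataclasses.asdict(chi_a) if chi_a else None,
            "regions": region_counts,
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = _stage("spatial")
    try:
        dist = inter_mutation_distances(calls, exclusions)
        per_chrom_counts = {
            c: int(sum(1 for call in calls if call.record.chrom == c))
            for c in genome.chrom_names
        }
        chrom_chi = chromosome_distribution_test(per_chrom_counts, genome.lengths)
        ks = ks_exponential_test(dist) if dist.n >= 5 else None
        pairs, n_proximal = proximal_pairs(calls, window=config.proximal_window)
        pd.DataFrame({"distance_bp": dist.distances}).to_csv(
            outdir / "distances.tsv", sep="\t", index=False
        )
        summary["spatial"] = {
            "n_distances": dist.n,
            "mean_distance_bp": dist.mean,
            "excluded_gaps": dist.excluded_gaps,
            "duplicates_collapsed": dist.duplicates_collapsed,
            "ks": dataclasses.asdict(ks) if ks else None,
            "ks_note": "p-value approximate: rate estimated from data",
            "per_chromosome_counts": per_chrom_counts,
            "chromosome_chi2": dataclasses.asdict(chrom_chi),
            "proximal_pairs": len(pairs),
            "proximal_calls": n_proximal,
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = _stage("context")
    try:
        snv_calls = [c for c in calls if c.klass.is_snv]
        windows = [extract_context(genome, c) for c in snv_calls]
        matrices = build_context_matrix(windows, by_class=True)
        verdicts = context_bias_report(matrices, seed=config.seed)
        pooled = build_context_matrix(windows)
        pd.DataFrame(
            pooled.counts,
            index=pooled.offsets,
            columns=list("ACGT"),
        ).rename_axis("offset").to_csv(outdir / "context_counts.tsv", sep="\t")
        summary["context"] = {
            k.value: {
                "verdict": v.verdict,
                "max_flanking_info_bits": v.max_flanking_info,
                "threshold_bits": v.threshold,
                "biased_offsets": list(v.biased_offsets),
            }
            for k, v in verdicts.items()
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = _stage("saturation")
    try:
        fs, bs = spectrum_to_saturation_inputs(spec_summary, genome)
        m = config.mean_load_m
        if m is None:
            kept_loads = [len(per_strain[s]) for s in kept]
            m = float(np.mean(kept_loads)) if kept_loads else DEFAULT_M
        sat_rows = []
        for kill in (0.5, 0.9):
            for label, classes in (
                ("guanine", G_CLASSES),
                ("adenine", A_CLASSES),
                ("all_six", SNV_CLASSES),
            ):
                class_fs = [fs[k] for k in classes if fs[k] > 0]
                b_vals = {bs[k.source_purine] for k in classes if fs[k] > 0}
                b_use = max(b_vals) if b_vals else bs["G"]
                try:
                    s_req = min_spores(
                        class_fs,
                        b_use,
                        m,
                        kill,
                        threshold=config.saturation_threshold,
                        grid_step=config.saturation_grid,
                    )
                except ValueError:
                    s_req = float("nan")
                sat_rows.append(
                    {
                        "target": label,
                        "kill": kill,
                        "m": m,
                        "b": b_use,
                        "threshold": config.saturation_threshold,
                        "min_spores": s_req,
                    }
                )
        sat_df = pd.DataFrame(sat_rows)
        sat_df.to_csv(outdir / "saturation.tsv", sep="\t", index=False)
        summary["saturation"] = sat_rows
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = _stage("dose_effect")
    try:
        if config.strain_table_path:
            kept_table = StrainTable(
                table.frame[~table.frame["excluded"]].reset_index(drop=True)
            )
            try:
                t, p = dose_effect_test(kept_table)
                summary["dose_effect"] = {"t": t, "p_value": p, "test": "welch"}
            except ValueError:
                summary["dose_effect"] = None
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    log.info("pipeline complete: %s", outdir / "summary.json")
    return summary
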