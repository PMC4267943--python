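"""Synthetic genomes, annotations and mutagenized strain cohorts.

The generator encodes the null model the analysis assumes: i.i.d. bases
at a chosen GC content, mutations placed uniformly over eligible purine
sites with fixed class frequencies, per-strain loads Poisson around a
mean (or uniform over a range), optional hypermutator strains with
multiplied loads, optional planted proximal pairs and a plantable
flanking motif for power testing. Everything is deterministic under a
seed, and a truth table records each simulated mutation so pipeline
recovery can be checked exactly.

Defaults emulate a desk-scale 4-NQO screen cohort: 38 strains, mean
load 105 (range roughly 23-240), class frequencies
G>A 0.53, G>T 0.276, G>C 0.14, A>G 0.03, A>C 0.01, A>T 0.01, a
~30.48 Mbp eight-chromosome genome at 50% GC, and one deletion per
4000 substitutions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    COMPLEMENT,
    AnnotationSet,
    GenomeSequence,
    StrainTable,
    VariantRecord,
    write_fasta,
    write_gff,
    write_strain_table,
    write_vcf,
)
from .spectrum import SNV_CLASSES, SubstitutionClass

__all__ = [
    "SimConfig",
    "simulate_genome",
    "simulate_mutagenesis",
    "monte_carlo_saturation",
    "write_simulation",
    "DEFAULT_CHROM_FRACTIONS",
]

#: Relative sizes of the eight chromosomes (normalized), so that
#: per-chromosome count tests are meaningful at any total size.
DEFAULT_CHROM_FRACTIONS: tuple[float, ...] = (
    0.1246,
    0.1342,
    0.1148,
    0.0953,
    0.1045,
    0.1122,
    0.1501,
    0.1643,
)

DEFAULT_TOTAL_LENGTH = 30_483_991

DEFAULT_CLASS_FREQS: dict[SubstitutionClass, float] = {
    SubstitutionClass.G_TO_A: 0.53,
    SubstitutionClass.G_TO_T: 0.276,
    SubstitutionClass.G_TO_C: 0.14,
    SubstitutionClass.A_TO_G: 0.03,
    SubstitutionClass.A_TO_C: 0.01,
    SubstitutionClass.A_TO_T: 0.01,
}

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Parameters of one synthetic screen cohort."""

    seed: int = 0
    total_length: int = DEFAULT_TOTAL_LENGTH
    chrom_fractions: Sequence[float] = DEFAULT_CHROM_FRACTIONS
    gc_content: float = 0.5
    n_strains: int = 38
    load_model: str = "poisson"  # "poisson" | "uniform"
    load_mean: float = 105.0
    load_range: tuple[int, int] = (23, 240)
    class_freqs: dict[SubstitutionClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FREQS)
    )
    n_hypermutators: int = 0
    hypermutator_multiplier: float = 9.0
    indel_rate: float = 1.0 / 4000.0  # deletions per substitution
    proximal_pair_rate: float = 0.0  # fraction of mutations planted <10 bp away
    context_motif: tuple[SubstitutionClass, str] | None = None
    transcribed_fraction: float = 0.5
    kill_fractions: tuple[float, ...] = (0.5, 0.9)

    def __post_init__(self) -> None:
        freqs = {k: float(v) for k, v in self.class_freqs.items()}
        if any(v < 0 for v in freqs.values()):
            raise ValueError("class frequencies must be non-negative")
        total = sum(freqs.values())
        if total <= 0:
            raise ValueError("class frequencies must not all be zero")
        self.class_freqs = {k: v / total for k, v in freqs.items()}
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0.0 <= self.transcribed_fraction <= 1.0:
            raise ValueError("transcribed_fraction must be in [0, 1]")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{_roman(i + 1)}" for i in range(len(self.chrom_fractions))]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        fracs = np.asarray(self.chrom_fractions, float)
        fracs = fracs / fracs.sum()
        lengths = np.floor(fracs * self.total_length).astype(int)
        lengths[-1] += self.total_length - lengths.sum()
        return dict(zip(self.chrom_names, lengths.tolist()))


def _roman(i: int) -> str:
    numerals = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    return numerals[i - 1]


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> tuple[GenomeSequence, AnnotationSet]:
    """Draw an i.i.d. genome and a block annotation at the configured coverage.

    Bases are i.i.d. with P(G) = P(C) = gc/2. "Transcribed" intervals
    are non-overlapping blocks of ~1.5 kb genes separated by spacers
    sized so coverage matches ``transcribed_fraction``.
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    names: list[str] = []
    seqs: dict[str, str] = {}
    transcribed: dict[str, list[tuple[int, int]]] = {}
    gene_len = 1500
    for name, length in config.chrom_lengths.items():
        codes = rng.choice(4, size=length, p=p).astype(np.uint8)
        seqs[name] = _BASE_BYTES[codes].tobytes().decode("ascii")
        names.append(name)
        ivs: list[tuple[int, int]] = []
        if config.transcribed_fraction > 0:
            period = max(int(round(gene_len / config.transcribed_fraction)), gene_len)
            start = 0
            while start < length:
                end = min(start + gene_len, length)
                ivs.append((start, end))
                start += period
        transcribed[name] = ivs
    genome = GenomeSequence(chrom_names=names, sequences=seqs)
    annot = AnnotationSet(transcribed=transcribed, chrom_lengths=genome.lengths)
    return genome, annot


# ---------------------------------------------------------------------------
# Mutagenesis
# ---------------------------------------------------------------------------

def _draw_load(config: SimConfig, rng: np.random.Generator) -> int:
    if config.load_model == "poisson":
        return int(rng.poisson(config.load_mean))
    if config.load_model == "uniform":
        lo, hi = config.load_range
        return int(rng.integers(lo, hi + 1))
    raise ValueError(f"unknown load model {config.load_model!r}")


def _eligible(base: str, klass: SubstitutionClass) -> bool:
    src = klass.source_purine
    if src == "G":
        return base in "GC"
    return base in "AT"


def _motif_matches(seq: str, pos0: int, base: str, motif: str, flank: int) -> bool:
    """Check the purine-strand context at pos0 against a centred motif."""
    half = len(motif) // 2
    lo, hi = pos0 - half, pos0 + half + 1
    if lo < 0 or hi > len(seq):
        return False
    window = seq[lo:hi]
    if base in "CT":  # purine is on the other strand
        window = window.translate(COMPLEMENT)[::-1]
    return all(m == "N" or m == w for m, w in zip(motif, window))


def _alt_for(base: str, klass: SubstitutionClass) -> str:
    """Alt allele on the reference strand for a class landing on ``base``."""
    target = klass.value[2]
    if base in "GA":
        return target
    return target.translate(COMPLEMENT)


def simulate_mutagenesis(
    genome: GenomeSequence, config: SimConfig
) -> tuple[dict[str, list[VariantRecord]], pd.DataFrame, StrainTable]:
    """Generate per-strain variant sets with known ground truth.

    Returns (records per strain, truth table, strain table). Sites are
    chosen uniformly over eligible bases by rejection sampling; a
    G-class mutation landing on a reference C is emitted as the
    complementary pyrimidine change, exercising strand normalization
    downstream. Hypermutator strains (the last ``n_hypermutators``)
    have their loads multiplied.
    """
    rng = np.random.default_rng(config.seed + 1)
    class_list = [k for k in SNV_CLASSES if config.class_freqs.get(k, 0) > 0]
    class_p = np.array([config.class_freqs[k] for k in class_list])
    for klass in class_list:
        src = klass.source_purine
        ok = any(
            b in seq for b in (("G", "C") if src == "G" else ("A", "T"))
            for seq in genome.sequences.values()
        )
        if not ok:
            raise ValueError(f"no eligible sites in genome for class {klass.value}")
    chrom_names = genome.chrom_names
    lengths = np.array([len(genome.sequences[c]) for c in chrom_names], float)
    chrom_p = lengths / lengths.sum()

    n_regular = config.n_strains
    n_total = n_regular + config.n_hypermutators
    kill_cycle = list(config.kill_fractions)

    per_strain: dict[str, list[VariantRecord]] = {}
    truth_rows: list[dict] = []
    strain_rows: list[dict] = []

    motif_klass, motif = (None, "")
    if config.context_motif is not None:
        motif_klass, motif = config.context_motif
        if len(motif) % 2 == 0:
            raise ValueError("context motif must have odd length (centred)")

    for s_idx in range(n_total):
        is_hyper = s_idx >= n_regular
        strain = f"{'hyper' if is_hyper else 'strain'}_{s_idx + 1:02d}"
        kill = kill_cycle[s_idx % len(kill_cycle)]
        load = _draw_load(config, rng)
        if is_hyper:
            load = int(round(load * config.hypermutator_multiplier))
        used: set[tuple[str, int]] = set()
        records: list[VariantRecord] = []

        def place(
            klass: SubstitutionClass, near: tuple[str, int] | None = None
        ) -> VariantRecord | None:
            for _ in range(10_000):
                if near is None:
                    ci = rng.choice(len(chrom_names), p=chrom_p)
                    chrom = chrom_names[ci]
                    pos = int(rng.integers(1, len(genome.sequences[chrom]) + 1))
                else:
                    chrom, anchor = near
                    off = int(rng.integers(1, 10))  # strictly < 10 bp away
                    pos = anchor + (off if rng.random() < 0.5 else -off)
                    if not 1 <= pos <= len(genome.sequences[chrom]):
                        continue
                base = genome.sequences[chrom][pos - 1]
                if not _eligible(base, klass) or (chrom, pos) in used:
                    continue
                if klass is motif_klass and not _motif_matches(
                    genome.sequences[chrom], pos - 1, base, motif, len(motif) // 2
                ):
                    continue
                used.add((chrom, pos))
                return VariantRecord(chrom, pos, base, _alt_for(base, klass), strain)
            return None

        n_indels = int(rng.binomial(load, min(config.indel_rate, 1.0))) if load else 0
        n_subs = load - n_indels
        classes = rng.choice(len(class_list), size=n_subs, p=class_p)
        for ki in classes:
            klass = class_list[int(ki)]
            near = None
            if (
                config.proximal_pair_rate > 0
                and records
                and rng.random() < config.proximal_pair_rate
            ):
                prev = records[-1]
                near = (prev.chrom, prev.pos)
            rec = place(klass, near=near)
            if rec is None and near is not None:
                rec = place(klass)
            if rec is None:
                raise RuntimeError(f"could not place a {klass.value} mutation")
            records.append(rec)
            truth_rows.append(
                {
                    "strain": strain,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alt,
                    "true_class": klass.value,
                    "hypermutator": is_hyper,
                }
            )
        for _ in range(n_indels):
            for _ in range(10_000):
                ci = rng.choice(len(chrom_names), p=chrom_p)
                chrom = chrom_names[ci]
                pos = int(rng.integers(1, len(genome.sequences[chrom])))
                if (chrom, pos) in used or (chrom, pos + 1) in used:
                    continue
                two = genome.sequences[chrom][pos - 1 : pos + 1]
                if "N" in two:
                    continue
                used.add((chrom, pos))
                rec = VariantRecord(chrom, pos, two, two[0], strain)
                records.append(rec)
                truth_rows.append(
                    {
                        "strain": strain,
                        "chrom": chrom,
                        "pos": pos,
                        "ref": two,
                        "alt": two[0],
                        "true_class": SubstitutionClass.DELETION.value,
                        "hypermutator": is_hyper,
                    }
                )
                break
        records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
        per_strain[strain] = records
        strain_rows.append(
            {
                "strain": strain,
                "dose": f"{int(kill * 100)}pct_kill",
                "kill": kill,
                "n_mutations": len(records),
                "excluded": False,
            }
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=["strain", "chrom", "pos", "ref", "alt", "true_class", "hypermutator"],
    )
    table = StrainTable(pd.DataFrame(strain_rows))
    return per_strain, truth, table


# ---------------------------------------------------------------------------
# Monte-Carlo occupancy oracle
# ---------------------------------------------------------------------------

def monte_carlo_saturation(
    f: float, b: int, n: int, reps: int = 100_000, seed: int = 0
) -> float:
    """Empirical saturation probability by direct occupancy simulation.

    Each of ``reps`` replicates draws ``n`` trials; a trial hits a
    uniformly chosen one of ``b`` sites with probability ``f``. Success
    means every site was hit at least once. Independent of the
    log-space closed form; usable as its oracle for small b.
    """
    if b > 10_000:
        raise ValueError("occupancy oracle is for small b (<= 1e4)")
    if reps < 1000:
        raise ValueError("need at least 1000 replicates")
    if f == 0.0 or n == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    successes = 0
    chunk = max(1, min(reps, 2_000_000 // max(n, 1)))
    done = 0
    while done < reps:
        r = min(chunk, reps - done)
        sites = rng.integers(0, b, size=(r, n))
        hit = rng.random((r, n)) < f
        covered = np.zeros((r, b), dtype=bool)
        rows = np.repeat(np.arange(r), n).reshape(r, n)
        covered[rows[hit], sites[hit]] = True
        successes += int(covered.all(axis=1).sum())
        done += r
    return successes / reps


# ---------------------------------------------------------------------------
# On-disk emission
# ---------------------------------------------------------------------------

def write_simulation(
    outdir: str | Path,
    config: SimConfig,
    genome: GenomeSequence,
    annot: AnnotationSet,
    per_strain: dict[str, list[VariantRecord]],
    truth: pd.DataFrame,
    table: StrainTable,
) -> dict[str, Path]:
    """Write FASTA, per-strain VCFs, GFF3, truth TSV, strain TSV, config JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["fasta"] = outdir / "genome.fa"
    write_fasta(genome, paths["fasta"])
    paths["gff"] = outdir / "annotation.gff3"
    write_gff(annot, paths["gff"])
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for strain in sorted(per_strain):
        p = vcf_dir / f"{strain}.vcf"
        write_vcf(per_strain[strain], p, contigs=genome.lengths)
        paths[f"vcf:{strain}"] = p
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["strains"] = outdir / "strains.tsv"
    write_strain_table(table, paths["strains"])
    paths["config"] = outdir / "sim_config.json"
    cfg = asdict(config)
    cfg["class_freqs"] = {k.value: v for k, v in config.class_freqs.items()}
    if config.context_motif is not None:
        cfg["context_motif"] = [config.context_motif[0].value, config.context_motif[1]]
    cfg["chrom_fractions"] = list(config.chrom_fractions)
    with open(paths["config"], "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
    return paths
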