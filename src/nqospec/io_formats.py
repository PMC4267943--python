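"""Readers, writers and the parent-vs-mutant variant subtraction.

On-disk dialects are the standard 1-based inclusive ones (VCF, GFF3);
BED exclusion intervals are 0-based half-open. Internally all interval
arithmetic is 0-based half-open; variant positions stay 1-based because
that is how every consumer reports them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

__all__ = [
    "FormatError",
    "GenomeSequence",
    "VariantRecord",
    "AnnotationSet",
    "StrainTable",
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "read_gff",
    "read_bed",
    "read_strain_table",
    "write_strain_table",
    "subtract_parent_variants",
]

_VALID_BASES = frozenset("ACGTN")
_ALLELE_RE = re.compile(r"^[ACGT]+$")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """An ordered collection of uppercase DNA sequences over {A,C,G,T,N}."""

    chrom_names: list[str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise FormatError("duplicate chromosome names")
        if self.total_length == 0:
            raise FormatError("genome has zero total length")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(self.sequences[name]) for name in self.chrom_names}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def base_counts(self) -> dict[str, int]:
        """Counts of A, C, G, T across all chromosomes; Ns excluded."""
        counts = {b: 0 for b in "ACGT"}
        for seq in self.sequences.values():
            for b in "ACGT":
                counts[b] += seq.count(b)
        return counts

    def gc_content(self) -> float:
        """GC fraction of the genome, ignoring N bases."""
        c = self.base_counts()
        acgt = sum(c.values())
        if acgt == 0:
            raise ValueError("genome contains no unambiguous bases")
        return (c["G"] + c["C"]) / acgt

    def base_at(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.sequences[chrom][pos - 1]


@dataclass(frozen=True, order=True)
class VariantRecord:
    """One called variant: substitution or small indel, 1-based position."""

    chrom: str
    pos: int
    ref: str
    alt: str
    strain: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        if not _ALLELE_RE.match(self.ref) or not _ALLELE_RE.match(self.alt):
            raise FormatError(
                f"alleles must be non-empty over ACGT: {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise FormatError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class AnnotationSet:
    """Two-way genome partition: transcribed vs everything else.

    ``transcribed`` holds, per chromosome, merged non-overlapping
    0-based half-open intervals. Positions outside them are "other"
    (intergenic).
    """

    transcribed: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, ivs in self.transcribed.items():
            self.transcribed[chrom] = merge_intervals(ivs)

    def is_transcribed(self, chrom: str, pos: int) -> bool:
        """Point lookup at a 1-based position (interval ends inclusive)."""
        import bisect

        ivs = self.transcribed.get(chrom)
        if not ivs:
            return False
        p0 = pos - 1
        idx = bisect.bisect_right([s for s, _ in ivs], p0) - 1
        return idx >= 0 and ivs[idx][0] <= p0 < ivs[idx][1]

    def transcribed_length(self, chrom: str) -> int:
        return sum(e - s for s, e in self.transcribed.get(chrom, []))

    def other_length(self, chrom: str) -> int:
        return self.chrom_lengths.get(chrom, 0) - self.transcribed_length(chrom)


@dataclass
class StrainTable:
    """Per-strain metadata: dose label, kill fraction, load, exclusion flag."""

    frame: pd.DataFrame  # columns: strain, dose, kill, n_mutations, excluded

    REQUIRED = ("strain", "dose", "kill", "n_mutations")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise FormatError(f"strain table missing columns: {missing}")
        if "excluded" not in self.frame.columns:
            self.frame = self.frame.assign(excluded=False)
        kills = self.frame["kill"].to_numpy(float)
        if ((kills < 0) | (kills >= 1)).any():
            raise FormatError("kill fractions must satisfy 0 <= k < 1")
        if (self.frame["n_mutations"].to_numpy(int) < 0).any():
            raise FormatError("mutation counts must be non-negative")

    @property
    def strains(self) -> list[str]:
        return list(self.frame["strain"])

    def loads(self, include_excluded: bool = True) -> dict[str, int]:
        df = self.frame if include_excluded else self.frame[~self.frame["excluded"]]
        return dict(zip(df["strain"], df["n_mutations"].astype(int)))

    def kept_strains(self) -> list[str]:
        return list(self.frame.loc[~self.frame["excluded"], "strain"])


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 0-based half-open intervals into a sorted disjoint set."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a multi-record FASTA into a :class:`GenomeSequence`.

    Sequences are uppercased; characters outside {A,C,G,T,N} are
    rejected with a :class:`FormatError` naming the record.
    """
    path = Path(path)
    names: list[str] = []
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains non-ACGTN characters {sorted(bad)}"
            )
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        names.append(rec.id)
        seqs[rec.id] = seq
    if not names:
        raise FormatError(f"{path}: no FASTA records found")
    return GenomeSequence(chrom_names=names, sequences=seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, strain: str | None = None) -> list[VariantRecord]:
    """Read a VCF into sorted :class:`VariantRecord` objects.

    Multi-allelic rows are split into one record per ALT allele. The
    strain id defaults to the file stem. Symbolic/structural alleles are
    rejected; the pipeline consumes small-variant calls only.
    """
    path = Path(path)
    if strain is None:
        strain = path.stem.removesuffix(".vcf")
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: not a parseable VCF ({exc})") from exc
    records: list[VariantRecord] = []
    with vf:
        for row in vf:
            for alt in row.alts or ():
                if not _ALLELE_RE.match(alt or ""):
                    raise FormatError(
                        f"{path}: unsupported ALT allele {alt!r} at "
                        f"{row.chrom}:{row.pos}"
                    )
                records.append(
                    VariantRecord(row.chrom, row.pos, row.ref, alt, strain)
                )
    records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write records as minimal VCF v4.2 with deterministic ordering."""
    recs = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in dict.fromkeys(r.chrom for r in recs):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in recs:
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

#: Feature types whose footprint counts as "transcribed" (UTRs, exons,
#: introns and whole-transcript spans all collapse into one union).
DEFAULT_TRANSCRIBED_TYPES = frozenset(
    {
        "mRNA",
        "transcript",
        "exon",
        "CDS",
        "five_prime_UTR",
        "three_prime_UTR",
        "intron",
    }
)


def read_gff(
    path: str | Path,
    transcribed_feature_types: frozenset[str] | set[str] = DEFAULT_TRANSCRIBED_TYPES,
    chrom_lengths: Mapping[str, int] | None = None,
) -> AnnotationSet:
    """Read GFF3 and build the transcribed/other partition.

    Transcribed intervals are the merged union of the selected feature
    types. Features whose coordinates fall outside a declared
    chromosome length are skipped with a warning.
    """
    import warnings

    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
            force=True,
        )
    except gffutils.exceptions.EmptyInputError:
        # no features at all: the whole genome is "other"
        return AnnotationSet(transcribed={}, chrom_lengths=dict(chrom_lengths or {}))
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for feat in db.all_features():
        if feat.featuretype not in transcribed_feature_types:
            continue
        if feat.start > feat.end:
            warnings.warn(
                f"{path}: feature {feat.id} has start > end; skipped", stacklevel=2
            )
            continue
        if chrom_lengths is not None:
            length = chrom_lengths.get(feat.seqid)
            if length is not None and (feat.start < 1 or feat.end > length):
                warnings.warn(
                    f"{path}: feature {feat.id} outside {feat.seqid} bounds; skipped",
                    stacklevel=2,
                )
                continue
        # GFF3 is 1-based inclusive -> 0-based half-open
        per_chrom.setdefault(feat.seqid, []).append((feat.start - 1, feat.end))
    return AnnotationSet(
        transcribed=per_chrom,
        chrom_lengths=dict(chrom_lengths or {}),
    )


def write_gff(annot: AnnotationSet, path: str | Path) -> None:
    """Write merged transcribed intervals as GFF3 ``mRNA`` features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annot.transcribed):
            for i, (s, e) in enumerate(annot.transcribed[chrom], 1):
                fh.write(
                    f"{chrom}\tnqospec\tmRNA\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"ID={chrom}.t{i}\n"
                )


# ---------------------------------------------------------------------------
# BED exclusion intervals, strain table TSV
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read BED (0-based half-open) intervals, merged per chromosome."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 0 or end < start:
                raise FormatError(f"{path}:{lineno}: bad interval {start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end))
    return {c: merge_intervals(ivs) for c, ivs in per_chrom.items()}


def read_strain_table(path: str | Path) -> StrainTable:
    df = pd.read_csv(path, sep="\t", dtype={"strain": str, "dose": str})
    return StrainTable(df)


def write_strain_table(table: StrainTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant subtraction
# ---------------------------------------------------------------------------

def subtract_parent_variants(
    mutant: Sequence[VariantRecord], parents: Sequence[VariantRecord]
) -> list[VariantRecord]:
    """Return mutant calls absent from the parent set.

    Matching is exact on (chrom, pos, ref, alt): a parent call at the
    same position with a different alt does not mask the mutant call.
    """
    parent_keys = {p.key for p in parents}
    return [m for m in mutant if m.key not in parent_keys]
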