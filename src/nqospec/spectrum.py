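"""Purine-normalized substitution classification and spectrum statistics.

Every base-pair substitution is reported on the strand whose reference
base is the purine (G or A): a C→T call becomes G→A on the opposite
strand. This yields six single-nucleotide classes (G→A, G→T, G→C,
A→G, A→C, A→T) plus insertion/deletion, the convention bulky-adduct
mutagen spectra are reported in.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import COMPLEMENT, AnnotationSet, StrainTable, VariantRecord

__all__ = [
    "SubstitutionClass",
    "SNV_CLASSES",
    "MutationCall",
    "SpectrumSummary",
    "Chi2Result",
    "classify_substitution",
    "classify_calls",
    "summarize_spectrum",
    "transition_bias_test",
    "purine_ratio",
    "flag_hypermutators",
    "compare_spectra",
    "region_classify",
]


class SubstitutionClass(str, Enum):
    G_TO_A = "G>A"
    G_TO_T = "G>T"
    G_TO_C = "G>C"
    A_TO_G = "A>G"
    A_TO_C = "A>C"
    A_TO_T = "A>T"
    INSERTION = "+N"
    DELETION = "dN"

    @property
    def is_snv(self) -> bool:
        return self not in (SubstitutionClass.INSERTION, SubstitutionClass.DELETION)

    @property
    def source_purine(self) -> str | None:
        return self.value[0] if self.is_snv else None

    @property
    def is_transition(self) -> bool:
        return self in (SubstitutionClass.G_TO_A, SubstitutionClass.A_TO_G)


#: The six SNV classes in conventional reporting order.
SNV_CLASSES: tuple[SubstitutionClass, ...] = (
    SubstitutionClass.G_TO_A,
    SubstitutionClass.G_TO_T,
    SubstitutionClass.G_TO_C,
    SubstitutionClass.A_TO_G,
    SubstitutionClass.A_TO_C,
    SubstitutionClass.A_TO_T,
)

G_CLASSES = tuple(k for k in SNV_CLASSES if k.source_purine == "G")
A_CLASSES = tuple(k for k in SNV_CLASSES if k.source_purine == "A")


@dataclass(frozen=True)
class MutationCall:
    """A variant with its strand-normalized class.

    ``flipped`` is True when the reference allele was a pyrimidine, i.e.
    the class is reported on the complementary strand.
    """

    record: VariantRecord
    klass: SubstitutionClass
    flipped: bool

    @property
    def is_transition(self) -> bool:
        return self.klass.is_transition


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float


def classify_substitution(ref: str, alt: str) -> tuple[SubstitutionClass, bool]:
    """Classify a single-base substitution into a purine-centric class.

    Returns (class, flipped). If ``ref`` is a pyrimidine both alleles
    are complemented first and flipped=True.
    """
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"alleles must be single bases in ACGT: {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref})")
    flipped = ref in "CT"
    if flipped:
        ref = ref.translate(COMPLEMENT)
        alt = alt.translate(COMPLEMENT)
    return SubstitutionClass(f"{ref}>{alt}"), flipped


def classify_record(record: VariantRecord) -> MutationCall:
    """Classify a variant record; indels map to +N / dN with flipped=False."""
    if record.is_snv:
        klass, flipped = classify_substitution(record.ref, record.alt)
        return MutationCall(record, klass, flipped)
    if len(record.alt) > len(record.ref):
        return MutationCall(record, SubstitutionClass.INSERTION, False)
    return MutationCall(record, SubstitutionClass.DELETION, False)


def classify_calls(records: Sequence[VariantRecord]) -> list[MutationCall]:
    return [classify_record(r) for r in records]


@dataclass
class SpectrumSummary:
    """Per-class counts and frequencies of a mutation spectrum.

    Frequencies ``f`` are per SNV class, counts/total_snv; indels are
    counted separately and excluded from the denominator.
    """

    counts: dict[SubstitutionClass, int]
    total_snv: int
    guanine_total: int
    adenine_total: int
    transitions_G: int
    transversions_G: int
    transitions_A: int
    transversions_A: int
    frequencies: dict[SubstitutionClass, float]

    @property
    def indel_total(self) -> int:
        return self.counts.get(SubstitutionClass.INSERTION, 0) + self.counts.get(
            SubstitutionClass.DELETION, 0
        )

    @property
    def guanine_fraction(self) -> float:
        return self.guanine_total / self.total_snv

    @property
    def transitions(self) -> int:
        return self.transitions_G + self.transitions_A

    @property
    def transversions(self) -> int:
        return self.transversions_G + self.transversions_A


def summarize_spectrum(calls: Sequence[MutationCall]) -> SpectrumSummary:
    """Tally calls into a :class:`SpectrumSummary`."""
    if not calls:
        raise ValueError("cannot summarize an empty call set")
    counts: Counter[SubstitutionClass] = Counter(c.klass for c in calls)
    g_total = sum(counts.get(k, 0) for k in G_CLASSES)
    a_total = sum(counts.get(k, 0) for k in A_CLASSES)
    total_snv = g_total + a_total
    freqs = {
        k: (counts.get(k, 0) / total_snv if total_snv else 0.0) for k in SNV_CLASSES
    }
    return SpectrumSummary(
        counts={k: counts.get(k, 0) for k in SubstitutionClass},
        total_snv=total_snv,
        guanine_total=g_total,
        adenine_total=a_total,
        transitions_G=counts.get(SubstitutionClass.G_TO_A, 0),
        transversions_G=counts.get(SubstitutionClass.G_TO_T, 0)
        + counts.get(SubstitutionClass.G_TO_C, 0),
        transitions_A=counts.get(SubstitutionClass.A_TO_G, 0),
        transversions_A=counts.get(SubstitutionClass.A_TO_C, 0)
        + counts.get(SubstitutionClass.A_TO_T, 0),
        frequencies=freqs,
    )


def transition_bias_test(n_transitions: int, n_transversions: int) -> Chi2Result:
    """Goodness-of-fit chi-square of transitions vs transversions against 50/50.

    df = 1, no continuity correction.
    """
    total = n_transitions + n_transversions
    if total <= 0:
        raise ValueError("need at least one observation")
    stat, p = stats.chisquare([n_transitions, n_transversions])
    return Chi2Result(float(stat), 1, float(p))


def purine_ratio(summary: SpectrumSummary) -> tuple[float, str]:
    """Guanine:adenine preference ratio and its rounded presentation.

    Returns (ratio, "R:1"); an adenine total of zero yields inf.
    """
    if summary.adenine_total == 0:
        return float("inf"), "inf:1"
    ratio = summary.guanine_total / summary.adenine_total
    return ratio, f"{round(ratio):d}:1"


def flag_hypermutators(
    strain_table: StrainTable,
    repair_gene_hits: Mapping[str, Sequence[str]] | None = None,
) -> StrainTable:
    """Flag strains whose mutation load is a boxplot outlier.

    A strain is flagged when its load exceeds Q3 + 1.5*IQR of all
    loads. If ``repair_gene_hits`` is given (strain -> list of
    non-silent DNA-repair gene hits), the flag additionally requires at
    least one hit, mirroring the corroboration used when excluding
    repair-defective hypermutators from spectrum estimates.
    """
    loads = strain_table.frame["n_mutations"].to_numpy(float)
    flags = np.zeros(len(loads), dtype=bool)
    if len(loads) < 4:
        warnings.warn(
            "fewer than 4 strains; hypermutator outlier rule not applied",
            stacklevel=2,
        )
    else:
        q1, q3 = np.percentile(loads, [25, 75])
        fence = q3 + 1.5 * (q3 - q1)
        flags = loads > fence
        if repair_gene_hits is not None:
            has_hit = np.array(
                [
                    bool(repair_gene_hits.get(s))
                    for s in strain_table.frame["strain"]
                ]
            )
            flags &= has_hit
    frame = strain_table.frame.assign(excluded=flags)
    return StrainTable(frame)


def compare_spectra(
    observed_counts: Mapping[SubstitutionClass, int] | Sequence[int],
    reference_freqs: Mapping[SubstitutionClass, float] | Sequence[float],
) -> Chi2Result:
    """One-way frequency chi-square of observed SNV class counts vs reference.

    Expected counts are total * freq with the reference frequencies
    renormalized to sum 1; df = (number of classes) - 1.
    """
    if isinstance(observed_counts, Mapping):
        obs = np.array([observed_counts.get(k, 0) for k in SNV_CLASSES], float)
    else:
        obs = np.asarray(observed_counts, float)
    if isinstance(reference_freqs, Mapping):
        ref = np.array([reference_freqs.get(k, 0.0) for k in SNV_CLASSES], float)
    else:
        ref = np.asarray(reference_freqs, float)
    if obs.shape != ref.shape:
        raise ValueError("observed and reference must cover the same classes")
    ref = ref / ref.sum()
    expected = obs.sum() * ref
    if (expected <= 0).any():
        raise ValueError(
            "zero expected count in at least one class; pool sparse classes "
            "before testing"
        )
    stat, p = stats.chisquare(obs, expected)
    return Chi2Result(float(stat), len(obs) - 1, float(p))


def region_classify(
    calls: Sequence[MutationCall], annot: AnnotationSet
) -> tuple[dict[str, int], list[str]]:
    """Assign each call to transcribed or intergenic by point lookup.

    Returns ({'transcribed': n, 'intergenic': m}, per-call labels).
    Calls on chromosomes absent from the annotation count as intergenic
    with a warning.
    """
    labels: list[str] = []
    unknown: set[str] = set()
    for call in calls:
        chrom, pos = call.record.chrom, call.record.pos
        if chrom not in annot.transcribed and chrom not in annot.chrom_lengths:
            unknown.add(chrom)
        labels.append(
            "transcribed" if annot.is_transcribed(chrom, pos) else "intergenic"
        )
    if unknown:
        warnings.warn(
            f"chromosomes absent from annotation counted intergenic: {sorted(unknown)}",
            stacklevel=2,
        )
    counts = {
        "transcribed": labels.count("transcribed"),
        "intergenic": labels.count("intergenic"),
    }
    return counts, labels
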