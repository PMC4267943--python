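"""Flanking-sequence context around mutated purines.

Windows of +/- flank bases are extracted around each mutated site and
strand-normalized so the central base is the mutated purine (G or A);
a call reported on the pyrimidine strand contributes the reverse
complement of its reference window. Position-wise base counts are
summarized by Shannon information content in bits, the quantity a
sequence-logo stack height displays. No small-sample correction is
applied; only relative comparisons against a matched-n multinomial
null are made.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import COMPLEMENT, GenomeSequence
from .spectrum import MutationCall, SubstitutionClass

__all__ = [
    "ContextWindow",
    "ContextMatrix",
    "extract_context",
    "build_context_matrix",
    "context_bias_report",
    "MIN_WINDOWS_FOR_VERDICT",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: Below this many windows the bias verdict is "insufficient data".
MIN_WINDOWS_FOR_VERDICT = 50


@dataclass(frozen=True)
class ContextWindow:
    """A (2*flank + 1)-base window centred on the mutated purine."""

    sequence: str
    klass: SubstitutionClass
    padded: bool  # True when truncated by a contig end and N-padded

    @property
    def flank(self) -> int:
        return (len(self.sequence) - 1) // 2

    @property
    def center(self) -> str:
        return self.sequence[self.flank]


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def extract_context(
    genome: GenomeSequence, call: MutationCall, flank: int = 10
) -> ContextWindow:
    """Extract the strand-normalized context window for one call.

    If the call was flipped (pyrimidine reference) the window is
    reverse-complemented so upstream/downstream are relative to the
    purine-bearing strand. Windows truncated by a contig end are padded
    with N and flagged.
    """
    chrom = call.record.chrom
    if chrom not in genome.sequences:
        raise KeyError(f"chromosome {chrom!r} absent from genome")
    seq = genome.sequences[chrom]
    center0 = call.record.pos - 1
    lo, hi = center0 - flank, center0 + flank + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(seq))
    window = "N" * left_pad + seq[max(lo, 0) : min(hi, len(seq))] + "N" * right_pad
    if call.flipped:
        window = reverse_complement(window)
    return ContextWindow(
        sequence=window, klass=call.klass, padded=bool(left_pad or right_pad)
    )


@dataclass
class ContextMatrix:
    """Position x base count matrix with per-position information content.

    Offsets run -flank..+flank; column j of ``counts`` sums to
    ``n_windows`` minus windows contributing an N at that offset.
    """

    counts: np.ndarray  # shape (2*flank + 1, 4), order A,C,G,T
    n_windows: int
    flank: int
    info_content: np.ndarray  # bits per position, in [0, 2]

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def frequencies(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, 0.0)

    def flanking_info(self) -> np.ndarray:
        """Information content with the central position removed."""
        return np.delete(self.info_content, self.flank)


def information_content(counts: np.ndarray) -> np.ndarray:
    """Per-position information 2 + sum_b p*log2(p), with 0*log(0) = 0."""
    counts = np.asarray(counts, float)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals > 0, counts / totals, 0.0)
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    info[totals[:, 0] == 0] = 0.0
    return np.clip(info, 0.0, 2.0)


def build_context_matrix(
    windows: Sequence[ContextWindow], by_class: bool = False
) -> ContextMatrix | dict[SubstitutionClass, ContextMatrix]:
    """Tally windows into count matrices (one per class if ``by_class``).

    N bases contribute nothing at their offset; all windows must share
    one flank size.
    """
    if not windows:
        raise ValueError("no context windows supplied")
    flanks = {w.flank for w in windows}
    if len(flanks) != 1:
        raise ValueError(f"mixed flank sizes: {sorted(flanks)}")
    if by_class:
        out: dict[SubstitutionClass, ContextMatrix] = {}
        for klass in {w.klass for w in windows}:
            out[klass] = build_context_matrix(
                [w for w in windows if w.klass == klass], by_class=False
            )
        return out
    flank = flanks.pop()
    width = 2 * flank + 1
    counts = np.zeros((width, 4), dtype=np.int64)
    for w in windows:
        for j, base in enumerate(w.sequence):
            if base != "N":
                counts[j, _BASE_INDEX[base]] += 1
    return ContextMatrix(
        counts=counts,
        n_windows=len(windows),
        flank=flank,
        info_content=information_content(counts),
    )


@dataclass(frozen=True)
class ContextVerdict:
    klass: SubstitutionClass
    verdict: str  # "no bias" | "bias" | "insufficient data"
    max_flanking_info: float
    threshold: float
    biased_offsets: tuple[int, ...]


def _null_info_quantile(
    n: int,
    n_positions: int,
    background: np.ndarray,
    q: float,
    n_sims: int,
    rng: np.random.Generator,
) -> float:
    """q-quantile of the max flanking information under the multinomial null.

    Each simulation draws ``n_positions`` independent multinomial(n, bg)
    columns (one per flanking position, matching how independent
    windows stack) and records the maximum per-position information, so
    the threshold is family-wise for the max statistic the verdict uses.
    """
    maxima = np.empty(n_sims)
    for i in range(n_sims):
        draws = rng.multinomial(n, background, size=n_positions)
        maxima[i] = information_content(draws.astype(float)).max()
    return float(np.quantile(maxima, q))


def context_bias_report(
    matrices: dict[SubstitutionClass, ContextMatrix],
    n_sims: int = 500,
    quantile: float = 0.99,
    seed: int | None = 0,
) -> dict[SubstitutionClass, ContextVerdict]:
    """Judge flanking-sequence bias per class against a multinomial null.

    For each class the threshold is the ``quantile`` of the maximum
    flanking-position information content under a multinomial null at
    the matched window count, with base probabilities taken from the
    class's own pooled flanking composition (family-wise over the
    2*flank positions). Verdict is "bias" when the observed max
    flanking information exceeds the threshold, "insufficient data"
    below :data:`MIN_WINDOWS_FOR_VERDICT` windows.
    """
    rng = np.random.default_rng(seed)
    report: dict[SubstitutionClass, ContextVerdict] = {}
    for klass, mat in sorted(matrices.items(), key=lambda kv: kv[0].value):
        flank_rows = np.delete(mat.counts, mat.flank, axis=0)
        if mat.n_windows < MIN_WINDOWS_FOR_VERDICT:
            report[klass] = ContextVerdict(
                klass, "insufficient data", float("nan"), float("nan"), ()
            )
            continue
        pooled = flank_rows.sum(axis=0).astype(float)
        background = pooled / pooled.sum()
        threshold = _null_info_quantile(
            mat.n_windows, flank_rows.shape[0], background, quantile, n_sims, rng
        )
        flank_info = mat.flanking_info()
        offsets = np.delete(mat.offsets, mat.flank)
        biased = tuple(int(o) for o in offsets[flank_info > threshold])
        report[klass] = ContextVerdict(
            klass,
            "bias" if biased else "no bias",
            float(flank_info.max()),
            threshold,
            biased,
        )
    return report
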