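"""Spatial randomness of mutations along the genome.

Under uniform random placement, gaps between consecutive pooled mutation
positions on a chromosome are approximately exponential with rate
lambda = 1/mean. This module computes those gaps (with exclusion
intervals for unmappable regions such as centromeres and rDNA repeats),
the exponential QQ pairing, a one-sample Kolmogorov-Smirnov
goodness-of-fit test against the fitted exponential, per-chromosome
count chi-square, and proximal same-strain pair detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import special, stats

from .spectrum import Chi2Result, MutationCall

__all__ = [
    "DistanceSet",
    "KSResult",
    "inter_mutation_distances",
    "exponential_qq",
    "ks_exponential_test",
    "chromosome_distribution_test",
    "proximal_pairs",
]


@dataclass
class DistanceSet:
    """Inter-mutation distances pooled across strains, per chromosome."""

    distances: np.ndarray  # positive gaps in bp, all chromosomes concatenated
    excluded_gaps: int  # gaps dropped because they span an exclusion interval
    chroms_with_positions: int  # chromosomes contributing >= 1 distinct position
    n_positions: int  # distinct positions after duplicate collapsing
    duplicates_collapsed: int  # positions shared by >1 strain, collapsed
    per_chrom: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return int(self.distances.size)

    @property
    def mean(self) -> float:
        return float(self.distances.mean()) if self.n else float("nan")


@dataclass(frozen=True)
class KSResult:
    D: float
    n: int
    p_value: float  # asymptotic; approximate when the rate is estimated
    mean: float


def _positions_by_chrom(
    calls: Sequence[MutationCall] | Sequence[tuple[str, int]],
) -> dict[str, np.ndarray]:
    per: dict[str, list[int]] = {}
    for c in calls:
        if isinstance(c, tuple):
            chrom, pos = c
        else:
            chrom, pos = c.record.chrom, c.record.pos
        per.setdefault(chrom, []).append(pos)
    return {chrom: np.asarray(sorted(p)) for chrom, p in per.items()}


def inter_mutation_distances(
    calls: Sequence[MutationCall] | Sequence[tuple[str, int]],
    exclusion_intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> DistanceSet:
    """Distances between consecutive pooled mutation positions per chromosome.

    All strains are pooled; duplicate positions (the same site mutated
    in more than one strain) are collapsed to a single position, since a
    zero gap is impossible under the continuous exponential model. A gap
    is dropped (and counted in ``excluded_gaps``) when the open interval
    between its two flanking positions overlaps any exclusion interval
    (0-based half-open BED coordinates). No inter-chromosome distances
    are formed.
    """
    per_chrom_pos = _positions_by_chrom(calls)
    exclusions = exclusion_intervals or {}

    all_d: list[np.ndarray] = []
    per_chrom_d: dict[str, np.ndarray] = {}
    excluded = 0
    duplicates = 0
    n_positions = 0
    chroms_with_positions = 0

    for chrom, pos in per_chrom_pos.items():
        uniq = np.unique(pos)
        duplicates += pos.size - uniq.size
        n_positions += uniq.size
        chroms_with_positions += 1
        if uniq.size < 2:
            per_chrom_d[chrom] = np.empty(0, dtype=np.int64)
            continue
        gaps = np.diff(uniq)
        keep = np.ones(gaps.size, dtype=bool)
        for ex_start, ex_end in exclusions.get(chrom, ()):
            # gap spans (p_i, p_{i+1}) exclusive, 1-based -> 0-based half-open
            gap_start = uniq[:-1]  # 0-based position right after p_i
            gap_end = uniq[1:] - 1  # 0-based end (half-open) just before p_{i+1}
            overlaps = (gap_start < ex_end) & (ex_start < gap_end)
            keep &= ~overlaps
        excluded += int((~keep).sum())
        kept = gaps[keep]
        per_chrom_d[chrom] = kept
        all_d.append(kept)

    distances = (
        np.concatenate(all_d) if all_d else np.empty(0, dtype=np.int64)
    )
    return DistanceSet(
        distances=distances,
        excluded_gaps=excluded,
        chroms_with_positions=chroms_with_positions,
        n_positions=n_positions,
        duplicates_collapsed=duplicates,
        per_chrom=per_chrom_d,
    )


def exponential_qq(dist: DistanceSet) -> list[tuple[float, float]]:
    """Pair observed order statistics with fitted exponential quantiles.

    Plotting positions p_i = (i - 0.5)/n; theoretical quantile
    -mean * ln(1 - p_i) with the mean estimated from the data.
    """
    if dist.n < 2:
        raise ValueError("need at least two distances for a QQ plot")
    x = np.sort(dist.distances.astype(float))
    n = x.size
    p = (np.arange(1, n + 1) - 0.5) / n
    theo = -dist.mean * np.log1p(-p)
    return list(zip(theo.tolist(), x.tolist()))


def ks_exponential_test(dist: DistanceSet, mean: float | None = None) -> KSResult:
    """One-sample KS goodness-of-fit against an exponential distribution.

    D = sup_i max(i/n - F(x_i), F(x_i) - (i-1)/n) over the sorted data,
    with F(x) = 1 - exp(-x/mean). By default the mean is the sample
    mean (rate estimated from the data, as in a sigma=est fit); pass
    ``mean`` to test against a fully specified exponential. The p-value
    is the asymptotic Kolmogorov distribution of sqrt(n)*D and is
    approximate (anti-conservative) when the rate is estimated.
    """
    if dist.n < 5:
        raise ValueError("need at least 5 distances for the KS test")
    x = np.sort(dist.distances.astype(float))
    if (x <= 0).any():
        raise ValueError("distances must be positive")
    scale = dist.mean if mean is None else float(mean)
    n = x.size
    cdf = -np.expm1(-x / scale)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max()
    d_minus = (cdf - (i - 1) / n).max()
    D = float(max(d_plus, d_minus))
    p = float(special.kolmogorov(math.sqrt(n) * D))
    return KSResult(D=D, n=n, p_value=p, mean=scale)


def chromosome_distribution_test(
    per_chrom_counts: Mapping[str, int], per_chrom_lengths: Mapping[str, int]
) -> Chi2Result:
    """Chi-square of per-chromosome counts against DNA-content expectation.

    Expected count for a chromosome is total * length/sum(lengths);
    df = number of chromosomes - 1.
    """
    chroms = sorted(per_chrom_lengths)
    if len(chroms) < 2:
        raise ValueError("need at least two chromosomes")
    lengths = np.array([per_chrom_lengths[c] for c in chroms], float)
    if (lengths <= 0).any():
        raise ValueError("zero-length chromosome")
    obs = np.array([per_chrom_counts.get(c, 0) for c in chroms], float)
    expected = obs.sum() * lengths / lengths.sum()
    stat, p = stats.chisquare(obs, expected)
    return Chi2Result(float(stat), len(chroms) - 1, float(p))


def proximal_pairs(
    calls: Sequence[MutationCall],
    window: int = 10,
    per_strain: bool = True,
) -> tuple[list[tuple[MutationCall, MutationCall]], int]:
    """Find calls lying strictly within ``window`` bp of another call.

    Pairs are same-chromosome and, by default, same-strain. Returns the
    pair list and the number of distinct calls involved in any pair.
    """
    groups: dict[tuple[str, str] | str, list[MutationCall]] = {}
    for call in calls:
        key = (
            (call.record.strain, call.record.chrom)
            if per_strain
            else call.record.chrom
        )
        groups.setdefault(key, []).append(call)

    pairs: list[tuple[MutationCall, MutationCall]] = []
    involved: set[int] = set()
    for members in groups.values():
        members = sorted(members, key=lambda c: c.record.pos)
        for i in range(len(members)):
            j = i + 1
            while (
                j < len(members)
                and members[j].record.pos - members[i].record.pos < window
            ):
                pairs.append((members[i], members[j]))
                involved.add(id(members[i]))
                involved.add(id(members[j]))
                j += 1
    return pairs, len(involved)
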