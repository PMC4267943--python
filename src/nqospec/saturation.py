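"""Screen-saturation probability under random mutagenesis.

A mutagenesis screen treats s spores, of which a fraction k is killed;
each survivor carries on average m mutations, so n = m*s*(1-k)
mutations are sampled with replacement across the genome. A target
substitution class arises with relative frequency f and can land on any
of b eligible base pairs. The chance a given site receives that
mutation at least once is

    p_site = 1 - (1 - f/b)^n

and the chance every eligible site has received it (saturation) is

    P_S = p_site ** b.

Both quantities involve (1 - tiny)^huge and are evaluated exclusively in
log space with log1p/expm1 primitives; the naive form collapses to 0 or
1 in double precision at realistic parameter values (b ~ 1.5e7,
n ~ 1e9). That log-space evaluation is the central numerical decision
of this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import GenomeSequence
from .spectrum import SNV_CLASSES, SpectrumSummary, SubstitutionClass

__all__ = [
    "SaturationParams",
    "SaturationResult",
    "site_hit_probability",
    "saturation_probability",
    "combined_saturation",
    "min_spores",
    "spontaneous_expectation",
    "spectrum_to_saturation_inputs",
    "YEAST_SPONTANEOUS_PER_STRAIN",
    "DEFAULT_B",
    "DEFAULT_M",
    "DEFAULT_CLASS_FREQS",
]

#: Eligible base pairs under the 50%-GC shortcut (half the 30,483,991 bp
#: nuclear genome of Aspergillus nidulans); fractional by construction.
DEFAULT_B = 15_241_995.5

#: Mean mutations per surviving spore observed at desk-standard doses.
DEFAULT_M = 105.0

#: Whole-genome relative frequencies of the six purine-normalized
#: substitution classes under 4-NQO.
DEFAULT_CLASS_FREQS: dict[SubstitutionClass, float] = {
    SubstitutionClass.G_TO_A: 0.53,
    SubstitutionClass.G_TO_T: 0.276,
    SubstitutionClass.G_TO_C: 0.14,
    SubstitutionClass.A_TO_G: 0.03,
    SubstitutionClass.A_TO_C: 0.01,
    SubstitutionClass.A_TO_T: 0.01,
}

#: Alternative spontaneous-load estimate per strain derived from yeast
#: whole-genome mutation-accumulation studies; shipped as a documented
#: constant because its derivation needs per-study generation counts
#: that are not part of this package's inputs.
YEAST_SPONTANEOUS_PER_STRAIN = 3.5

#: Hard cap for the minimum-spore search.
MAX_SPORES = 1e12


@dataclass(frozen=True)
class SaturationParams:
    """Parameters of the saturation equation.

    f: relative frequency of the target class (unitless, in [0, 1]);
    b: eligible base pairs (may be fractional under the GC shortcut);
    m: mean mutations per surviving spore; s: treated spores;
    k: kill fraction in [0, 1).
    """

    f: float
    b: float
    m: float
    s: float
    k: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must be in [0, 1], got {self.f}")
        if self.b < 1.0:
            raise ValueError(f"b must be >= 1, got {self.b}")
        if self.f > self.b:
            raise ValueError("f cannot exceed b")
        if self.m < 0 or self.s < 0:
            raise ValueError("m and s must be non-negative")
        if not 0.0 <= self.k < 1.0:
            raise ValueError(f"k must be in [0, 1), got {self.k}")

    @property
    def n(self) -> float:
        """Total mutations sampled: m * s * (1 - k)."""
        return self.m * self.s * (1.0 - self.k)


@dataclass(frozen=True)
class SaturationResult:
    p_site: float
    p_saturation: float
    log_p_site: float  # natural log, -inf when p_site == 0
    params: SaturationParams


def site_hit_probability(f: float, b: float, n: float) -> float:
    """P(a given eligible site receives the target mutation) = 1-(1-f/b)^n.

    Evaluated as -expm1(n * log1p(-f/b)); exact 0 for n = 0.
    """
    if f > b:
        raise ValueError("f cannot exceed b")
    if n == 0 or f == 0:
        return 0.0
    if f == b:
        return 1.0
    return -math.expm1(n * math.log1p(-f / b))


def _log1mexp(x: float) -> float:
    """log(1 - e^x) for x < 0, full precision on both branches."""
    if x > -math.log(2.0):
        return math.log(-math.expm1(x))
    return math.log1p(-math.exp(x))


def _log_p_site(f: float, b: float, n: float) -> float:
    """log of the site-hit probability, stable for p_site near 0 and 1."""
    if n == 0 or f == 0:
        return -math.inf
    if f == b:
        return 0.0
    log_miss = n * math.log1p(-f / b)  # log (1 - f/b)^n
    if log_miss < -745.0:  # exp underflows; p_site is 1 to full precision
        return 0.0
    return _log1mexp(log_miss)


def saturation_probability(params: SaturationParams) -> SaturationResult:
    """P_S = p_site^b, evaluated as exp(b * log(p_site))."""
    lp = _log_p_site(params.f, params.b, params.n)
    if lp == -math.inf:
        return SaturationResult(0.0, 0.0, lp, params)
    p_site = math.exp(lp)
    log_ps = params.b * lp
    p_sat = math.exp(log_ps) if log_ps > -745.0 else 0.0
    return SaturationResult(p_site, p_sat, lp, params)


def combined_saturation(
    class_fs: Sequence[float],
    b: float,
    m: float,
    s: float,
    k: float,
) -> float:
    """Probability all listed classes reach saturation simultaneously.

    The product of per-class P_S values, accumulated as a sum of logs.
    """
    if not class_fs:
        raise ValueError("need at least one class frequency")
    total_log = 0.0
    for f in class_fs:
        params = SaturationParams(f=f, b=b, m=m, s=s, k=k)
        lp = _log_p_site(f, b, params.n)
        if lp == -math.inf:
            return 0.0
        total_log += b * lp
    return math.exp(total_log) if total_log > -745.0 else 0.0


def min_spores(
    class_fs: Sequence[float],
    b: float,
    m: float,
    k: float,
    threshold: float = 0.9,
    grid_step: float = 1e7,
    cap: float = MAX_SPORES,
) -> float:
    """Smallest grid multiple of treated spores reaching the threshold.

    Searches s in {grid_step, 2*grid_step, ...} for the first value with
    combined_saturation >= threshold, exploiting monotonicity of P_S in
    s (binary search over grid indices after exponential bracketing).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")

    def ok(idx: int) -> bool:
        return combined_saturation(class_fs, b, m, idx * grid_step, k) >= threshold

    hi = 1
    lo = 0  # ok(0) is always False (no spores, P_S = 0)
    max_idx = int(cap // grid_step)
    while not ok(hi):
        lo = hi
        hi *= 2
        if hi > max_idx:
            if ok(max_idx):
                hi = max_idx
                break
            raise ValueError(
                f"saturation threshold {threshold} not reached below the "
                f"{cap:g}-spore cap"
            )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid
    return hi * grid_step


def spontaneous_expectation(
    rate_per_replication: float,
    growth_days: float,
    hours_per_division: float = 1.0,
) -> float:
    """Expected spontaneous mutations per strain over a growth period.

    rate * (growth_days * 24 / hours_per_division), i.e. one genome
    replication per nuclear division.
    """
    if rate_per_replication < 0 or growth_days < 0:
        raise ValueError("rate and growth period must be non-negative")
    if hours_per_division <= 0:
        raise ValueError("hours_per_division must be positive")
    return rate_per_replication * (growth_days * 24.0 / hours_per_division)


def spectrum_to_saturation_inputs(
    summary: SpectrumSummary,
    genome: GenomeSequence,
    gc_shortcut: bool = False,
) -> tuple[dict[SubstitutionClass, float], Mapping[str, float]]:
    """Derive per-class f and eligible-site counts from pipeline outputs.

    Returns (class frequencies, {"G": b_G, "A": b_A}) where b_G is the
    number of G:C pairs (G plus C bases on the reference strand) and
    b_A the number of A:T pairs, Ns excluded. With ``gc_shortcut`` both
    are total/2, the 50%-GC approximation.
    """
    counts = genome.base_counts()
    acgt = sum(counts.values())
    if acgt == 0:
        raise ValueError("genome has no eligible (non-N) sites")
    if gc_shortcut:
        b_g = b_a = acgt / 2.0
    else:
        b_g = float(counts["G"] + counts["C"])
        b_a = float(counts["A"] + counts["T"])
    fs = {k: summary.frequencies[k] for k in SNV_CLASSES}
    return fs, {"G": b_g, "A": b_a}
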