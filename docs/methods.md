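# Methods

## Scope and data model

`nqospec` analyses the substitution spectrum of a chemical mutagen from
whole-genome resequencing of mutagenized haploid strains, and converts
that spectrum into screen-design numbers. Its inputs are downstream of
alignment and variant calling: per-strain VCFs (one file per strain, or
mutant-minus-parent pairs), the reference FASTA, a GFF3 annotation and a
strain metadata table (`strain  dose  kill  n_mutations`). On-disk
coordinates follow the native dialects (VCF/GFF3 1-based inclusive, BED
0-based half-open); interval arithmetic is 0-based half-open internally
and every user-facing position is 1-based.

## Purine-normalized classification

Each single-nucleotide variant is reported on the strand whose
reference base is a purine: a C→T call is recorded as G→A with
`flipped=True`. This collapses the twelve directed substitutions into
six classes (G→A, G→T, G→C, A→G, A→C, A→T) — the natural frame for a
mutagen that adducts guanine and adenine — and makes spectra
strand-symmetric by construction (a property test asserts that
classifying a call and its complement yields the same class with
opposite flags). Indels are tallied separately (`+N`, `∆N`) and never
enter the SNV denominator.

Hypermutator exclusion uses the boxplot convention: a strain whose load
exceeds Q3 + 1.5·IQR of all per-strain loads is excluded from every
downstream spectrum statistic. When a per-strain list of non-silent
DNA-repair-gene hits is supplied, the flag additionally requires at
least one hit; the gene list is a user input because no canonical list
exists. With fewer than four strains the rule is skipped with a
warning. Quartiles are linearly interpolated (numpy default); with
small cohorts and several extreme strains Q3 itself can be dragged into
the outlier range, so the rule is reliable only when outliers are a
small minority — which is the regime it is meant for.

Categorical tests are plain goodness-of-fit χ² with no continuity
correction: transitions vs transversions against a 50/50 expectation
(df = 1), observed class counts against reference frequencies
renormalized to one (df = 5, error on zero expected cells suggesting
pooling), per-chromosome counts against DNA content (df = #chromosomes
− 1). p-values are the upper tail of the χ² distribution.

## Spatial randomness

Under uniform random placement, gaps between consecutive pooled
mutation positions on a chromosome are approximately exponential with
rate λ = 1/mean. Distances pool all strains; duplicate positions
(recurrent sites across strains) are collapsed before differencing
because a zero gap is impossible under the continuous model (the count
is logged). Gaps spanning user-supplied exclusion intervals (BED;
centromeres, rDNA repeats and other unmappable regions) are dropped and
counted, so the bookkeeping identity

    distances = positions − chromosomes-with-positions − excluded gaps

holds on any input and is asserted by a property test.

The QQ pairing uses plotting positions p_i = (i − 0.5)/n against
−mean·ln(1 − p_i). The one-sample KS statistic is
D = max_i max(i/n − F(x_i), F(x_i) − (i−1)/n) with F the exponential
CDF at the sample mean; the p-value is the asymptotic Kolmogorov
distribution of √n·D. Because the rate is estimated from the same data,
this p-value is approximate (anti-conservative in the Lilliefors
sense); the output labels it as such. Passing an explicit `mean` tests
against a fully specified exponential instead. Proximal-pair detection
reports calls strictly within a window (default 10 bp) of another call
of the same strain on the same chromosome; such pairs are reported but
deliberately kept as independent events in all other statistics, since
single-adduct and two-adduct origins cannot be distinguished.

## Flanking-sequence context

A ±10-base window is extracted around each mutated site and
reverse-complemented when the call was flipped, so upstream/downstream
are always relative to the purine-bearing strand; windows truncated by
a contig end are N-padded and flagged, and N bases contribute nothing
to their offset. Per-position information content is
2 + Σ_b p·log₂ p bits (0·log 0 = 0), the quantity a sequence-logo stack
displays, with no small-sample correction — only relative comparisons
are made. The bias verdict compares the maximum flanking-position
information against the 99th percentile of the same max statistic under
a multinomial null at the matched window count (simulated, 500 draws,
background = the class's own pooled flanking composition). Taking the
null distribution of the *max* rather than of a single position keeps
the family-wise false-positive rate at the nominal 1% across the 20
flanking positions. Classes with fewer than 50 windows return
"insufficient data".

## Saturation model

The probability that a specific substitution class (relative frequency
f) has occurred at a specific eligible base pair after n = m·s·(1−k)
sampled mutations is p_site = 1 − (1 − f/b)ⁿ, and the probability it
has occurred at *every* eligible base pair is P_S = p_site^b. Joint
saturation of several classes multiplies the per-class terms.
Assumptions inherited from the sampling-with-replacement frame:
mutations land independently and uniformly over eligible sites, classes
arise with fixed frequencies independent of position, and strains
contribute independently.

Parameters, defaults and units:

| symbol | meaning                         | default        |
|--------|---------------------------------|----------------|
| f      | class relative frequency        | spectrum-derived (0.53/0.276/0.14/0.03/0.01/0.01) |
| b      | eligible base pairs             | 15,241,995.5 (half a 30,483,991 bp genome at 50% GC) |
| m      | mutations per surviving spore   | 105            |
| s      | treated spores                  | variable       |
| k      | kill fraction                   | 0.5 or 0.9     |

b may be fractional (the 50%-GC shortcut); p_site^b is defined as
exp(b·log p_site), so no integrality is imposed. Per-purine b values
counted from an actual genome (G:C pairs for guanine classes, A:T for
adenine; Ns excluded) are available via
`spectrum_to_saturation_inputs`.

**Numerics.** Everything is evaluated in log space:
log p_site = log(1 − exp(n·log1p(−f/b))) via the two-branch log1mexp
(log(−expm1 x) for x > −ln 2, log1p(−eˣ) otherwise — the single-branch
form loses ~7 digits near x ≈ −18), and P_S = exp(b·log p_site) with
underflow clamped to 0. This agrees with 50-digit arbitrary-precision
direct evaluation to relative error < 10⁻¹⁰ across the realistic
parameter range, and with a Monte-Carlo occupancy simulation at small b
within sampling error; both checks are in the test suite as independent
oracles.

The minimum-spore solver returns the smallest multiple of a grid step
(defaults 10⁷–10⁸, matching how such numbers are quoted) with joint
P_S ≥ a threshold, default 0.9; monotonicity of P_S in s is exploited
by exponential bracketing plus binary search, with a 10¹² hard cap.
The threshold is a design choice: published spore requirements are read
off saturation curves without a stated cutoff, and 0.9 reproduces the
quoted guanine (4×10⁷ at 50% kill, 2×10⁸ at 90%) and all-six-class
(6×10⁸ at 50% kill) numbers. A caveat worth recording: evaluating the
printed equation with the printed parameters does *not* support the
claim that 2×10⁷ (50% kill) or 10⁸ (90% kill) treated spores reach
nucleotide saturation of adenine as well as guanine — at those values
P_S(A→B) = p_site^b with p_site ≈ 0.97 and b ≈ 1.5×10⁷ is
indistinguishable from zero. The package reports the formula's true
value; the likely explanation is a per-site vs all-sites slip in the
original curve reading, and the corresponding spore numbers are not
treated as reference points anywhere in the tests.

The spontaneous-mutation expectation is rate × divisions, with
divisions = growth_days × 24 / hours_per_division; at the literature
rate 0.0034 per replication, 30 days and hourly divisions this gives
2.448 per strain. An alternative yeast-derived estimate (3.5 per
strain) is shipped as a documented constant because its derivation
needs per-study generation counts not reproducible from this package's
inputs.

## Synthetic cohorts

The generator encodes the analysis's null model, so passing tests show
internal consistency — recovery of parameters the generator planted —
not fidelity to any real genome. Defaults describe a desk-scale screen
cohort: 8 chromosomes in fixed proportions summing to 30,483,991 bp
(scalable), i.i.d. bases at 50% GC, 38 strains with Poisson(105) loads
(uniform 23–240 as an alternative, since only the range and mean of
real loads are known), the six class frequencies above, one deletion
per 4000 substitutions, and alternating 50%/90% kill dose labels.
Mutations are placed uniformly over eligible sites by rejection
sampling; a G-class mutation landing on a reference C is emitted as the
complementary pyrimidine change, so the classifier's strand
normalization is exercised on roughly half of all records. Options
plant hypermutators (load multiplier, default ×9), proximal pairs
(re-drawn < 10 bp from the previous mutation) and a flanking motif for
one class (power testing of the context verdict). Everything is
deterministic under a seed and byte-identical on re-runs; a truth table
ties every emitted record to its class.

What the generator does not emulate: real base composition and repeat
structure, coverage-dependent callability, alignment artefacts,
selection on causative loci, and clustered damage beyond the simple
proximal-pair mechanism. Conclusions about real data rest on the
worked-example checks (exact published count tables through the same
code paths), not on the simulations.

## Test design for stochastic criteria

Statistical recovery checks run at the cohort scale the defaults
describe (38 strains, ~30.48 Mbp, ~4000 mutations). Per-class
frequency recovery is asserted within 99% binomial confidence
intervals, and context verdicts at their 1% family-wise level, on three
independently seeded cohorts with a majority rule: with six classes per
cohort a single seed fails by chance on a few percent of draws, while a
genuine miscalibration fails all three. Level checks (KS rejection
rate under the null, per-chromosome χ² below its 95% critical value,
Welch-test size) use 200–500 direct replicates of the position-sampling
step rather than full pipeline runs, which is the same distributional
question at a fraction of the cost.

## Known limitations

- The KS p-value is asymptotic and ignores rate estimation; it is
  suitable for the large-n pooled test it is used for, not for small
  per-chromosome samples.
- The hypermutator rule assumes outliers are a minority (see above).
- `compare_spectra` expects exact reference counts or frequencies;
  feeding it rounded published frequencies shifts χ² noticeably at
  n ≈ 200, which is why the pipeline always uses its own exact counts.
- Region classification is a two-way transcribed/other partition;
  codon-level consequences are out of scope.
- Saturation assumes spatial uniformity; it will overstate coverage of
  genuinely cold regions (e.g. unmappable or repair-shielded sequence).
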