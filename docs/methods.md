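# Methods

This note records the conventions, parameter choices and known
limitations behind each statistic, in the order a full analysis runs.

## Sequence handling

Coding sequences are extracted from GenBank flat files honouring
`join`, `complement` and `codon_start` (coordinates 1-based
inclusive); `codon_start > 1` trims leading bases before codonisation.
RNA input is normalised to DNA on read. Ambiguous IUPAC bases are kept
in the nucleotide string but any codon containing one is excluded from
every codon-level statistic — this avoids inventing fractional counts
at the cost of very slightly shortening the effective sequence.
Validation (`validate_cds`) is report-only: length divisibility,
internal stops (terminal codon exempt), ambiguity count.

The genetic code is the standard table (id 1): 61 sense codons, 3
stops, and degeneracy classes 1 (Met, Trp), 2 (nine amino acids),
3 (Ile), 4 (five), 6 (Leu, Ser, Arg). The six-codon amino acids are
treated as single six-fold families for RSCU and ENC, the CodonW
convention; their fourfold sub-boxes (CTN, TCN, CGN) — but not their
twofold partners — enter PR2.

## Composition

Whole-sequence base percentages run over unambiguous bases. Two
third-position conventions coexist in this literature and both are
emitted so either can be compared downstream:

- **GC3s** (CodonW): third positions of *synonymous* codons only —
  Met, Trp and stops excluded. Used for the NC plot and reported as
  A3s/T3s/G3s/C3s.
- **GC3** (Sueoka): third positions of all sense codons, stops
  excluded. Used as the abscissa of the neutrality plot.

GC12 is the exact mean of GC1 and GC2. Stop codons are excluded from
all positional statistics (coding sequences end in one; including it
would bias third-position AT upward).

## RSCU and group comparison

RSCU is computed per sequence over the 59 informative codons; a family
with zero usage contributes RSCU 0 for all members and is flagged.
Group-level vectors are arithmetic means of per-sequence RSCU vectors,
*not* RSCU of pooled counts — the two differ when sequence lengths
vary, and the mean-of-vectors form is what group-distance tables are
built from. Pairwise group distance at a codon is the absolute
difference of group means; the table's default codon set is every
codon whose group-mean RSCU reaches 1.6 (the over-representation
threshold) in at least one group, falling back to all 59 when no codon
qualifies (short synthetic regions). Representation classes: over at
RSCU ≥ 1.6, under at ≤ 0.6.

## ENC

Wright's estimator from class-averaged codon homozygosities. Amino
acids with usage n < 2 are skipped (F is undefined at n = 1). If the
single three-fold class (Ile) is missing, its average is imputed as
the mean of the two- and four-fold averages — Wright's published
recommendation; if any other class is empty the ENC is undefined and
flagged rather than guessed. Values are capped at 61. ENC < 35 is
surfaced as the conventional "significant bias" flag. Note the
estimator is only asymptotically scale-invariant: halving a sequence
shifts each F by O(1/n).

## CAI

Sharp & Li relative adaptiveness from a reference count table
(Kazusa text layout; per-1000 frequencies or raw counts both work).
Zero-count reference codons receive a 0.5 pseudo-count before
normalising, so log w is always finite (the CAIcal convention). The
geometric mean runs over all codons except ATG, TGG and stops. The
bundled human table is a transcription of the commonly republished
human reference frequencies; CAI values against other snapshots of the
human table differ in the second decimal at most, which is why
downstream comparisons to published CAI carry a ±0.02 band.

## PR2 and neutrality

PR2 coordinates use third-position counts inside the eight fourfold
boxes only; a zero denominator (no G+C or no A+T third positions)
leaves the coordinate undefined rather than forced to 0.5. The
neutrality fit is ordinary least squares of GC12 on GC3 with Pearson r
and the two-sided p from the t distribution (n−2 df); zero variance in
GC3 flags the slope undefined. The quantity (1 − slope)·100% is
reported as the selection contribution, matching standard usage.

## Correspondence analysis

Textbook CA of the nonnegative sequences × codons matrix (RSCU values
by default; a counts mode exists for comparison): proportions P, row
and column masses r and c, standardised residuals
S = D_r^{-1/2}(P − r cᵀ)D_c^{-1/2}, SVD, principal coordinates scaled
by singular values. Per-axis inertia is σ², and total inertia equals
the Pearson chi-square over the grand total (asserted in tests to
1e-8). SVD sign indeterminacy is fixed by making the
largest-magnitude column loading on each axis positive. Zero rows or
columns are dropped with a warning — short regions routinely leave
rare codons unused.

## Diversity and neutrality tests

All alignment statistics use complete deletion: any column
containing a gap or ambiguous base is removed before counting. S is
the number of polymorphic columns; η sums (alleles − 1) per column;
singletons are alleles carried by exactly one sequence (capped at
alleles − 1 per column so η_s ≤ η holds in degenerate two-sequence
cases); k comes from the column allele-frequency identity, which
equals the all-pairs Hamming average exactly; π = k / sites.

Tajima's D uses the standard a₁, a₂, b, c, e constants. Fu & Li's D*
and F* are the no-outgroup statistics with the corrected variance
constants (the c_n/d_n form of the later erratum lineage); because
published formulations disagree in detail, the implementation is
validated against its behavioural null rather than against another
closed form: across 4000 neutral coalescent replicates (m = 20,
θ = 5) the means of D, D* and F* must stay within ±0.15 of zero. The
replicate count is chosen so the Monte-Carlo standard error (≈0.014)
is small against that band — the exact null mean of Tajima's D is
itself slightly negative (≈ −0.09 at this sample size; tskit's
independent implementation reproduces this), and the band must absorb
that intrinsic offset, not sampling noise. Significance for the
pipeline output is reported as the conventional "ns" bands from the
published critical-value tables, not exact p-values.

## dN/dS

Nei–Gojobori (1986) counting. Synonymous site fractions per codon
position are taken among the changes that do not create a stop codon
(mutations to stops disregarded), each position contributing one site,
so every codon contributes exactly three sites. Codons with gaps,
ambiguity, or a stop in either sequence are skipped pairwise; site
totals are averaged between the two sequences. Multi-difference codons
average their synonymous/nonsynonymous step counts over all minimal
substitution pathways that avoid stop codons at intermediate steps
(all pathways, if every one passes through a stop — a rare corner
verified against exhaustive enumeration). Pairwise proportions are
Jukes–Cantor corrected, d = −(3/4)ln(1 − 4p/3); a pair with p ≥ 3/4 is
excluded with a warning. The group estimate is mean(dN)/mean(dS)
(ratio of averages, the convention of group-mean tools); a
mean-of-ratios variant sits behind a flag. Parameter recovery is
checked by evolving lineages under an accept–reject scheme with
ω = 0.2 and recovering the ratio within ±0.1.

## Synthetic data

`generate_codon_sequences` draws codons i.i.d.: amino acid from a
frequency vector (default uniform over the 20), then codon from
within-family preferences (default uniform — the no-selection null of
the NC plot). A GC3s target is met by exponentially tilting
third-position G/C with a single weight λ solved by bisection so the
*expected* GC3s equals the target; an infeasible target (outside the
reachable range of the given preferences) raises rather than clamps.
Measured GC3s at 50 000 codons sits within ±0.01 of the target.

`simulate_neutral_alignment` uses the standard coalescent (msprime,
haploid samples, time scaled so a pair coalesces at rate 1) with
finite-sites Jukes–Cantor mutation at total rate θ/2 per unit branch
length spread uniformly over the sites, so E[k] = θ and E[S] = θ·a₁
up to finite-site corrections. No recombination, no demography, no
selection — the generator exists to give the frequency-spectrum
statistics an exact null, not to mimic viral epidemiology. What the
synthetic tests therefore show is correctness of the estimators under
their own model assumptions; they say nothing about alignment quality,
recombination, or selection in real polyomavirus data.

All generators take an explicit integer seed; there is no global
random state, and identical seeds reproduce byte-identical output.

## Pipeline conventions

Five host groups {A, F, H, M, P} are the canonical stratification;
taxonomic genus is carried as metadata only. All tables are TSV with
fixed column order; floats are rendered at 5 significant digits so
reruns diff cleanly. Sequences are processed in sorted-id order, which
makes every stage independent of input file ordering. Missing inputs
skip their stage with a logged reason; the run manifest records
package and Python versions, the seed, and SHA-256 digests of file
inputs.

## Problem sizes used by the checks

The acceptance computations run at: 4000 coalescent replicates
(m = 20, θ = 5, 1000 sites) for the neutrality-test nulls and θ
recovery; 10 × 50 000 codons pooled for generator unbiasedness;
50 000 codons per GC3s target point; four lineages of 3000 codons for
ω recovery. These sizes put each Monte-Carlo standard error well
inside the corresponding tolerance band.

## Known limitations

- Alignments are consumed, never computed; population statistics on
  real data inherit the upstream aligner's choices (the fish helicase
  π check aligns with MAFFT, and published values from other aligners
  are matched only within a tolerance).
- Fu & Li significance is banded, not exact.
- The ENC missing-class imputation only covers Ile; exotic inputs
  missing an entire two-, four- or six-fold class yield an undefined
  ENC by design.
- CAI depends on the reference snapshot; see above.
- The published per-virus numbers require the RefSeq records, which
  must be fetched once (`scripts/fetch_refseq.py`) and are not
  redistributed with the package.
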