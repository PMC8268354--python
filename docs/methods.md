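# Methods

## Problem setting

In a female-heterogametic (WZ/ZZ) system, a candidate master sex determiner
can take the form of an extra, W-linked copy of a gene that is otherwise
present on the Z (and sometimes duplicated there). wzkit implements the
quantitative steps of establishing such a candidate: estimating how many
gene copies an individual carries and which chromosome each sits on, testing
how tightly markers in the region track phenotypic sex, testing which
inheritance model the genotype distribution supports, validating the
candidate's gene structure, and checking sex-restricted expression.

## Trace decomposition model

A Sanger chromatogram of a PCR product co-amplified from `n` near-identical
gene copies is modelled as a linear superposition: at window position `i`,
channel `c` carries expected height

    y[i, c] = gain * sum_h w_h * 1[base of haplotype h at i == c]

where `w_h` is the copy number of haplotype `h` and `gain` the signal per
template copy. Haplotypes are anchored at the window start, so an internal
deletion in one haplotype shifts its downstream bases and turns every
post-deletion position into a mixed peak. This is deliberate: the indel
makes hundreds of positions informative, which is what conditions the
decomposition well even when the haplotypes differ by only a few edits.

Estimation is non-negative least squares (`scipy.optimize.nnls`) of the
flattened (position × channel) heights on the binary signature matrix;
reported proportions are the weights normalised to sum to one, with
R² = 1 − SSR/SST as fit quality. Haplotypes identical over the window give
identical signature columns; they are merged into a single group before
fitting (their individual shares are unidentifiable in principle, only the
group share is reported). Forward and reverse sequencing orientations are
decomposed separately and combined by unweighted mean, with the smaller R²
kept — a deliberately symmetric rule, since neither orientation is more
trustworthy a priori.

The single-site peak-ratio estimator (height of each segregating channel
over their sum) is provided for the case where one informative SNP suffices,
e.g. resolving a Z-linked duplication from a C/T peak ratio of 0, 1/3 or
1/2.

## Integer copy models

An estimated minor fraction `f` is snapped to the integer pair
(major, minor) minimising |minor/(major+minor) − f| over totals ≤ 5 (two to
five copies per diploid genome is the observed range; `max_total` is a
parameter). Ties break toward the smaller total, then the smaller minor, so
returned ratios are in lowest terms. With at most 5 total copies the
feasible minor fractions are well separated (1/5, 1/4, 1/3, 2/5, ...), which
is what makes the snap robust at the simulated noise level.

Chromosome configurations are enumerated under the role constraints: the W
carries one or two W-specific copies (the variant itself, optionally a
second female-specific copy), each Z carries one copy or two when a Z
duplication is allowed. Consequently a WZ genotype can realise totals 2–4
but not 5; a five-copy individual is reported with its 4:1 ratio and an
empty configuration list (placement unresolved) rather than a forced model.
The concordance flag compares phenotypic sex against W-bearing status only
(threshold 0.10 on the W signal fraction — halfway between noise and the
smallest true fraction, 0.20); a phenotypic male with one-third W signal is
flagged discordant, the mechanism behind a near-perfect marker table's
single mismatch.

## Exact tests and inheritance models

Genotype-by-sex tables are tested with the exact conditional approach:
both margins fixed, two-sided p = sum of the probabilities of all tables
whose point probability does not exceed the observed one (relative tie
tolerance 1e-7). 2×2 tables go through `scipy.stats.fisher_exact`; r×2
tables use a hand-rolled Freeman–Halton enumeration in log space (scipy has
no r×c exact test), bounded at 8 rows, and cross-checked in the tests
against a brute-force rational-arithmetic enumeration.

Inheritance models for (ZZ, WZ, WW) counts at allele frequencies p, q:

- autosomal: n·(p², 2pq, q²);
- lethal WW homozygote: n·(p², 2pq, 0)/(1 − q²);
- obligate female-determining W: (0, n, 0).

Pearson goodness of fit sums (O−E)²/E over cells with E > 0; df = supported
cells − 1. An observation in a structural-zero cell rejects the model
outright (p = 0); a zero-df exact fit has p = 1. On the all-heterozygote
female distribution (0, 48, 0) this yields p ≈ 3.8e-11 against the
autosomal model, p ≈ 9.6e-7 (chi² = 24, df = 1) against lethal-WW, and p = 1
for the obligate-heterozygote model. Note that published analyses of this
comparison sometimes print a different lethal-WW value consistent with
using the ZZ cell alone (chi² = 16, df = 1); wzkit reports the full Pearson
statistic as defined above.

The Hardy–Weinberg deviation test estimates q from the data
(q = (WZ + 2·WW)/2N), costing one df (df = 3 − 1 − 1 = 1). On (48, 48, 0)
this gives chi² = 10.667, p ≈ 1.1e-3.

The association scan delimits the candidate interval as follows: the
maximally associated block is the set of markers with p within `top_factor`
(default 1e6) of the minimum, and the interval runs between the nearest
flanking weaker markers (or the outermost block marker where none flanks).
A single absolute p threshold cannot do this job — a moderately associated
marker megabases away can be far below any conventional threshold yet
clearly outside the candidate block — whereas the relative rule separates
p ≈ 1e-26 markers from p ≈ 1e-12 ones cleanly.

No multiple-testing correction is applied by default (raw per-marker
p-values are reported).

## Gene structure and divergence

Gene models are exon/intron length tables with optional sequence;
validation checks GT..AG intron boundaries. Translation enforces an ATG
start, triplet length, terminal stop and no internal stop (the offending
codon index is reported). Polyadenylation-signal search counts overlapping
AATAAA occurrences — overlap is allowed deliberately, since tandem signals
overlap in real 3'UTRs.

Windowed divergence on a pairwise alignment (1-based inclusive column
window) counts substitution columns plus maximal gap runs, each run one
event regardless of length; columns gapped in both sequences are alignment
padding and count nothing (they also terminate a run). Divergence is
events / window width. The utility global aligner (match +1, mismatch −1,
linear gap −2, via `Bio.Align.PairwiseAligner`) is plumbing; the divergence
operation itself expects supplied alignments. All substitution events in
the window are counted without attempting to classify sites as synonymous —
with a fixed, mostly coding window the distinction would require a codon
model that is out of scope.

## Expression quantification

"Fragments" are single-end reads; a read counts if it contains the probe
verbatim on either strand (strand-agnostic by default, matching how a
BLAST-style search behaves), and at most once. FPKM uses the probe length
(32 bp) as the feature length — the only length available under a
probe-counting design. This is documented prominently because absolute
values are not comparable with transcript-length FPKM; ratios and
detection calls are. Detection requires ≥ 3 reads; undetected probes report
FPKM 0.

## Synthetic data: what it emulates and what it does not

Defaults are the study conditions the pipeline assumes:

- cohort: 48 phenotypic females + 48 males sampled by sex (case-control
  style); sex-reversal rate default 0 (tests use ~1/96 where a near-perfect
  table with a single mismatch is wanted); per-marker recombination
  fractions in [0, 0.5].
- chromatogram noise: multiplicative Gaussian with CV 0.05, truncated at
  zero — peak heights are positive and roughly proportional to template
  amount, and 5 % is a realistic well-behaved capillary trace; no published
  noise magnitude exists for this setting, so the value is a package
  default and the recovery tolerances (±3 percentage points) are set to
  absorb it.
- gain 100 signal units per copy (arbitrary; decomposition is scale
  invariant and the tests assert it).
- haplotype family: identical Z copies plus a W variant with 2
  substitutions and a 3-base in-frame deletion within a 300 bp window, edits
  kept 10 bp clear of the window ends.
- reads: 32-mer probes planted exactly; background reads rejection-sampled
  to exclude every probe and its reverse complement, so planted counts are
  exact ground truth.

A single seeded generator drives each operation; identical configuration
gives byte-identical output. The generators do not emulate base-calling
artefacts, dye blobs, mobility shifts, read sequencing errors, quality
scores, or polymerase bias — so passing tests demonstrate correctness of
the inference chain under its model assumptions, not robustness to every
real-world artefact. Problem sizes used by the test suite and the
acceptance script (297-position windows, 200-replicate recovery runs,
cohorts up to 2000, libraries of a few thousand reads) are chosen to keep
runs fast while leaving Monte-Carlo error far below the asserted
tolerances.

## Numerical choices

- exact-test tie tolerance: relative 1e-7 on point probabilities.
- NNLS proportions must sum to 1 within 1e-9; R² clamped to [0, 1], defined
  as 1 when SST = 0 with zero residual.
- copy-ratio tie-break: smaller total, then smaller minor.
- W-bearing threshold 0.10; Z-duplication fractions snapped to the
  constrained set {0, 1/3, 1/2}.
- `top_factor` 1e6 for the association block.
- degenerate inputs: empty margins give p = 1 with a warning; all-zero
  traces, zero-height peak-ratio sites and all-constant ANOVA inputs raise.

## Limitations

- The decomposition assumes candidate haplotypes are known and complete; an
  unmodelled haplotype inflates residuals rather than being discovered.
- Group proportions, not per-copy proportions, are reported for haplotypes
  identical over the window; choose windows spanning discriminating sites.
- The Freeman–Halton implementation is exact but enumerative; it is bounded
  at 8 genotype rows by design.
- Exact conditional tests are conservative under discreteness; their null
  p-values are stochastically larger than uniform (the calibration tests
  assert type-I error ≤ nominal, not uniformity).
- FPKM values are probe-length normalised and not comparable to
  transcript-length FPKM from standard RNA-seq pipelines.
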