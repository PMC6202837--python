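# Methods

## Model and assumptions

The package treats an alignment of an ultra-short read to an artificially
mutated reference as a draw from one of two populations. A *true* alignment
derives from the reference lineage (possibly with ancient-DNA damage) and
shows the original base at a mutated site unless divergence or damage
intervenes. A *spurious* alignment is unrelated sequence accepted by the
aligner's mismatch allowance; conditional on acceptance we assume it carries
the maximum number of allowed mismatches, so at a mutated site it shows the
mutated reference state with probability 1 − M and each of the three other
bases with probability M/3, where M = m(l)/l is the maximum mismatch
proportion at read length l. This worst-case assumption makes the count
correction conservative: it can only over-estimate the spurious fraction.

m(l) is the smallest k whose Poisson upper tail P(X > k; λ = 0.02·l) falls
below 0.01, the edit-distance rule used by short-read aligners configured
with a 0.02 per-base error model and a 0.01 acceptance threshold. The gap
allowance of such aligners is deliberately not folded into m: m counts
substitutions only. This reproduces the ≈ 10% mismatch ceiling at the
dominant lengths (m = 2 at 20 bp, m = 3 at 30 bp).

Classification assumes single-stranded library chemistry: the sequenced
strand is the original molecule's strand, so deamination-induced errors
appear as C→T in read orientation (G→A in reference-forward coordinates for
reverse alignments). The strand guard therefore drops forward alignments at
sites whose original or mutated state is C, and reverse alignments where
either state is G; on a uniform-composition genome this discards a
predictable site/strand subset and removes essentially all damage-induced
misclassification at the site itself.

## Reference mutation

Sites are selected on a per-sequence grid with one candidate every
`spacing` bp (first at 0-based offset spacing − 1). A candidate inside an
exclusion track (or on an N) is relocated to the nearest included base,
leftward on ties; the relocated site is kept only if ≥ `min_adjacent` bp
from both the previously accepted site and the next grid candidate, and
dropped otherwise (one relocation attempt only — re-relocation would make
the site set depend on scan order in opaque ways). Defaults: spacing 100,
min_adjacent 75.

Two composition-preserving replacement schemes are provided. The default
*batch* scheme permutes the multiset of original bases across all selected
sites with no fixed points (shuffle with local repair), so the mutated
genome's base counts equal the input's exactly; when the multiset admits no
such permutation (e.g. a single site, or one base in the strict majority)
the scheme falls back to uniform replacement with a warning. The *matrix*
scheme fits a zero-diagonal flow matrix with row and column sums equal to
the genome composition by iterative proportional fitting (tolerance 1e−12)
and row-normalizes it, preserving composition in expectation; it requires
strictly positive base frequencies. Neither scheme is claimed to match any
particular production pipeline's construction; both satisfy the
composition-preservation contract, and batch is the default because its
guarantee is exact and directly testable.

## Mappability

A read is deemed uniquely mappable if, for the largest track length k not
exceeding the read length (default ladder 20, 23, 26, 29, 32, 35), some
position p in its alignment span [start, end − k] carries a k-mer that
occurs nowhere else in the genome — on either strand — within one mismatch.
The track builder is an exact brute-force search using a pigeonhole split of
each k-mer into max_mismatch + 1 exact-matching parts, bounded at 100 kb of
genome; production-scale genomes would use a dedicated external mappability
tool, and the tracks are interchangeable through the BED-per-k on-disk
format. A locus never conflicts with itself on the opposite strand (a
near-palindromic k-mer maps to the same position).

## Estimation and cutoffs

Counts are corrected per 1-bp length stratum with that stratum's M(l), then
summed for cumulative curves; stratum-exact correction dominates any single
pooled M because M varies by ~50% across 20–40 bp. The corrected true count
is clamped at zero (with a logged warning) only after aggregation decisions:
the pre-clamping identity N′_T + N′_¬T = N_T + N_¬T is what tests assert.
Binomial intervals are Wilson score intervals (95% for fraction estimates,
90% for lineage sharing), chosen for sane behaviour at extreme proportions.
L_τ is the smallest cutoff L ≥ 20 with cumulative corrected fraction < τ
among reads of length ≥ L; if the curve never drops below τ the cutoff is
reported as not reached rather than extrapolated. The deamination filter
accepts a terminal C→T at *either* read end; requiring both termini would
discard most genuinely damaged molecules at these lengths.

Mismatch counts subtract one mismatch per overlapped mutated site at which
the read does not match the mutated allele (such reads necessarily carry a
mismatch there by construction), floored at zero, for true and spurious
alignments alike; reads overlapping several sites (rare at ≤ 76 bp over a
≥ 75-bp grid) are classified at the 5′-most non-guarded site in read
orientation, deterministically.

## Lineage test

Informative sites require a primate-outgroup ancestral call with at least
four of five non-missing alleles agreeing, one randomly sampled allele per
diploid genotype (homozygous genotypes consume no randomness, keeping
streams comparable), and a biallelic carrier pattern mapping to exactly one
of Modern Human, Neandertal, Denisovan, or Neandertal-Denisovan; patterns
with modern-human-plus-one-archaic or all-three carriers are rejected as
uninformative about the archaic split. Read observations are dropped when
the read base is neither allele (treated as sequencing error) or when it is
a T within three positions of either read end in read orientation (the
deamination guard). The Neandertal-vs-Denisovan comparison is a two-sided
Fisher exact test; when several samples or cutoffs are tested the p-values
are adjusted with Benjamini–Hochberg by default (configurable), a standard
and conservative-enough choice for this small test family.

## Synthetic data

The generator emulates: endogenous reads as reference substrings diverged at
0.002 substitutions/bp with terminal C→T damage (probability p₀ = 0.3 at the
outermost base, geometric decay 0.5 per position, applied from both ends as
single-stranded libraries show), fragment lengths on a discrete distribution
over 20–76 bp concentrated in 20–40 bp; contaminants as i.i.d. or
unrelated-genome sequence with lengths uniform over 20–40 bp; and indel
events in 76% of spurious versus 0.05% of true alignments, matching the
contrast observed between bacterial and modern-human control alignments.
The damage parameters are a two-parameter stand-in for the empirically
U-shaped substitution spectrum; no published fit is implied.

The *direct* mixture mode bypasses alignment entirely and emits classified
records straight from the generative model above, with spurious carried
alleles at probabilities (1 − M, M/3, M/3, M/3) and mismatch counts pinned
at m(l). Under exactly these conditions the correction is calibrated, so
estimator-recovery tests are sharp. What direct mode does **not** exercise:
a real aligner's placement bias, soft-clipping, mapping-quality effects,
duplicate structure, base-quality errors, or reference bias in which reads
carrying non-reference alleles align less readily. Passing tests therefore
demonstrate the statistical machinery, not end-to-end behaviour on real
BAMs, which additionally depends on the upstream aligner configuration. The
read-level generators plus the SAM ingest path cover the formats involved;
an external-aligner round trip is possible with the emitted FASTQ/FASTA but
is not part of the test suite.

## Numerical choices and problem sizes

Poisson tails are exact cumulative sums (no normal approximation);
replacement-matrix fitting stops at an L∞ row-sum error of 1e−12; fractions
are clamped to [0, 1] after aggregation; empty strata propagate as missing
values rather than zeros. Simulation-based tests use 5·10⁴ records per seed
(20 seeds) for calibration, 6·10⁴ for filter effects, and ≤ 2.5-kb genomes
for the mappability cross-check — sizes at which the assertions' tolerances
are comfortably inside sampling noise while the whole suite stays fast.

## Known limitations

* The brute-force mappability builder is exact but bounded to small genomes
  by design.
* Spurious-fraction correction assumes every spurious alignment carries the
  maximum allowed mismatches; real chance alignments with fewer mismatches
  make the estimate conservative (biased high), never anti-conservative.
* The classifier assumes deduplicated, single-end, length-filtered input;
  duplicate removal and adapter trimming are upstream concerns.
* Genotype calling, primate whole-genome alignment, and the exclusion
  track's construction from population variant data are inputs, not
  implemented here.
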