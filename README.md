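# spuriometer

Quantify — and filter out — spurious alignments of ultra-short (20–45 bp)
ancient DNA sequences.

## The problem

The oldest and most degraded skeletal samples yield DNA fragments so short
that many microbial reads align to the human reference purely by chance:
an aligner that tolerates roughly 10% mismatches will accept a 25-bp
bacterial fragment somewhere in a 3-Gb genome surprisingly often. Standard
practice discards everything below 35 bp, throwing away a large share of the
genuinely endogenous molecules. `spuriometer` implements an
artificial-mutation strategy that measures the spurious fraction directly,
so the length threshold can be chosen per sample instead of by convention.

It is aimed at ancient-DNA practitioners working with single-stranded
libraries from highly degraded material (archaic hominins, very old or
thermally degraded samples) and at method developers who need a controlled
test bed for short-read authentication.

## The method

1. **Bait the reference.** Inject single-base changes into the reference
   every 100 bp at well-behaved positions (outside exclusion tracks, ≥ 75 bp
   apart), replacing bases with probabilities that keep the genome-wide
   nucleotide composition identical. A read truly derived from the reference
   lineage shows the *original* base at such a site; a chance alignment
   shows the *mutated* base with probability ≈ 1 − M, where M = m/l is the
   maximum mismatch proportion the aligner allows (≈ 10%: m = 2 at 20 bp,
   m = 3 at 30 bp under the Poisson-tail edit-distance rule with per-base
   error 0.02 and tail threshold 0.01).
2. **Classify and correct.** Reads overlapping mutated sites are classified
   true (reference base) or spurious (mutated or any other base), with a
   strand guard that skips C-involving sites on forward and G-involving
   sites on reverse alignments to stay robust to cytosine deamination.
   Because a spurious read still shows the reference base with probability
   M/3, the raw counts N_T, N_¬T are corrected:

       N′_T  = N_T − N_¬T · M/(3 − M)
       N′_¬T = N_¬T / (1 − M/3)

   and the spurious proportion reported as N′_¬T / (N′_¬T + N′_T). The
   correction conserves N_T + N_¬T exactly.
3. **Filter and cut.** Per-length estimates (with Wilson binomial CIs)
   quantify how indel and terminal-C→T ("deam") filters suppress the
   spurious fraction; cumulative curves yield the sample-specific cutoffs
   L_10% and L_1% — the shortest read length at which the spurious fraction
   among retained reads stays below 10% or 1% — plus the usable-base fold
   change relative to the conventional 35-bp threshold.
4. **Lineage test.** Derived-allele sharing with Modern-Human-, Neandertal-,
   Denisovan- and Neandertal+Denisovan-diagnostic sites (primate-outgroup
   ancestral calls, ≥ 4 of 5 agreeing) with 90% binomial intervals and a
   Fisher exact Neandertal-vs-Denisovan comparison, discarding terminal-T
   observations to stay robust to deamination.

A synthetic-data module generates references, damaged endogenous reads,
contaminants and pre-classified mixtures with known ground truth, so the
whole pipeline is testable without external data or an aligner.

## Worked example

```python
from spuriometer import SimConfig, cumulative_fraction, simulate_classified_mixture

config = SimConfig(p_spur=0.30, seed=11)          # 30% chance alignments
classified, truth = simulate_classified_mixture(config, 50_000)

uncorrected = (classified["class"] == "SPURIOUS").mean()
curve = cumulative_fraction(classified, filters="none", min_len=20)
print(uncorrected, curve[curve["L"] == 20]["frac"].iloc[0])
```

Running `python examples/02_quantify_spurious.py` prints:

```
true contaminant share:        0.3007
raw classified-spurious share: 0.2908
corrected estimate:            0.3018
```

The raw share is biased low by ≈ p·M/3 (spurious reads that show the
reference base by chance); the corrected estimator recovers the simulated
share. `examples/03_length_cutoffs.py` continues with cutoffs:

```
filters=none       tau= 10%  L=26 bp        fold-change vs 35 bp: 2.07
filters=none       tau=  1%  L=not reached  fold-change vs 35 bp: -
filters=deam+indel tau= 10%  L=20 bp        fold-change vs 35 bp: 2.34
filters=deam+indel tau=  1%  L=20 bp        fold-change vs 35 bp: 2.34
```

i.e. with both filters this simulated sample supports a 20-bp cutoff and
recovers 2.3× the true bases of a 35-bp threshold. The other examples cover
reference mutation (`01`) and the lineage test (`04`).

A thin CLI mirrors the library: `spuriometer mutate-ref | mappability |
classify | estimate | cutoff | lineage | simulate | estimate-pipeline`
(see `spuriometer --help`).

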