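"""Synthetic references, ancient-like reads, contaminants and mixtures.

The generator emulates the study conditions the estimator is meant for:

* endogenous reads are substrings of the reference diverged by about 0.002
  substitutions per bp, with elevated terminal C-to-T rates (probability p0
  at the outermost base, geometric decay d per position inward, applied from
  both ends as in single-stranded libraries) and short fragment lengths
  dominated by 20-40 bp;
* contaminant reads are unrelated sequence (i.i.d. bases or substrings of an
  independently simulated genome) with lengths uniform over 20-40 bp, the
  regime where chance alignments arise;
* the *direct* (alignment-free) mixture emits pre-classified records with
  known ground truth: spurious records carry the mutated allele with
  probability 1 - M(l) and each other base with probability M(l)/3, the
  maximum mismatch count m(l), and indel events at the bacterial-control
  rate, exactly the generative model under which the misclassification
  correction is calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import ReadAlignment, ReferenceGenome, revcomp
from .spurious_stats import DEFAULT_RULE, MaxDiffRule

BASES = "ACGT"
_BASE_TO_INT = {b: i for i, b in enumerate(BASES)}


def _default_fragment_probs() -> dict[int, float]:
    # geometric-ish decay from 20 bp: ~96% of mass in 20-40 bp
    lengths = np.arange(20, 77)
    w = np.exp(-(lengths - 20) / 6.0)
    w /= w.sum()
    return dict(zip(lengths.tolist(), w.tolist()))


@dataclass
class SimConfig:
    """Parameters of the synthetic read generator.

    Defaults describe the emulated study conditions: 0.002/bp endogenous
    divergence, fragments concentrated in 20-40 bp, terminal C-to-T
    probability 0.3 decaying geometrically (0.5/position) inward, contaminant
    lengths uniform over 20-40 bp, indel events in 76% of spurious and 0.05%
    of true alignments, and a 30% spurious share.
    """

    genome_length: int = 10_000
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    divergence: float = 0.002
    fragment_length_probs: dict[int, float] = field(default_factory=_default_fragment_probs)
    deam_p0: float = 0.3
    deam_decay: float = 0.5
    contaminant_length_range: tuple[int, int] = (20, 40)
    contaminant_mode: str = "iid"  # or "genome"
    p_spur: float | Mapping[int, float] = 0.3
    indel_prob_spurious: float = 0.76
    indel_prob_endogenous: float = 0.0005
    ct_prob_spurious: float = 0.01
    rule: MaxDiffRule = DEFAULT_RULE
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.array(list(self.fragment_length_probs.values()))
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("fragment length probabilities must be a distribution")
        if min(self.fragment_length_probs) < 20:
            raise ValueError("fragment lengths must be >= 20")
        for p in (self.divergence, self.deam_p0, self.deam_decay,
                  self.indel_prob_spurious, self.indel_prob_endogenous,
                  self.ct_prob_spurious):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")

    def p_spur_at(self, length: int) -> float:
        if isinstance(self.p_spur, Mapping):
            return float(self.p_spur[length])
        return float(self.p_spur)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimRead:
    """A simulated fragment with its ground-truth provenance.

    ``seq`` is in read orientation (the order bases were sequenced in); the
    reference-forward view is its reverse complement when ``is_reverse``.
    Contaminant reads have no genomic placement (chrom None).
    """

    name: str
    seq: str
    origin: str  # "endogenous" | "contaminant"
    chrom: str | None = None
    start: int | None = None
    is_reverse: bool = False

    @property
    def length(self) -> int:
        return len(self.seq)

    def to_alignment(self) -> ReadAlignment:
        """Perfect-placement alignment record (direct mode, no aligner)."""
        if self.chrom is None or self.start is None:
            raise ValueError("read has no genomic placement")
        seq_fwd = revcomp(self.seq) if self.is_reverse else self.seq
        return ReadAlignment(
            qname=self.name,
            ref_name=self.chrom,
            ref_start=self.start,
            seq=seq_fwd,
            cigar=((("M", self.length)),),
            is_reverse=self.is_reverse,
        )


def simulate_reference(
    length: int,
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    seed: int | np.random.Generator = 0,
    name: str = "sim1",
) -> ReferenceGenome:
    """An i.i.d. random genome at the stated base composition."""
    if length < 200:
        raise ValueError("simulated reference must be >= 200 bp")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = np.asarray(composition, dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("composition must sum to 1")
    idx = rng.choice(4, size=length, p=probs)
    seq = "".join(BASES[i] for i in idx)
    return ReferenceGenome({name: seq})


def _draw_lengths(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    lengths = np.array(list(config.fragment_length_probs))
    probs = np.array(list(config.fragment_length_probs.values()))
    return rng.choice(lengths, size=n, p=probs)


def _apply_deamination(seq: str, p0: float, d: float, rng: np.random.Generator) -> str:
    """C->T conversions decaying geometrically from both fragment ends."""
    if p0 == 0:
        return seq
    L = len(seq)
    out = list(seq)
    for i, b in enumerate(out):
        if b != "C":
            continue
        p = 1.0 - (1.0 - p0 * d**i) * (1.0 - p0 * d ** (L - 1 - i))
        if rng.random() < p:
            out[i] = "T"
    return "".join(out)


def simulate_endogenous(
    reference: ReferenceGenome,
    config: SimConfig,
    n_reads: int,
    rng: np.random.Generator | None = None,
) -> list[SimRead]:
    """Ancient-like fragments of the reference.

    Each read is a substring with divergence substitutions at the configured
    per-base rate (to a uniformly chosen other base), emitted in the
    orientation of a uniformly drawn strand, with terminal C-to-T damage
    applied in read orientation.
    """
    rng = rng if rng is not None else config.rng()
    names = list(reference.sequences)
    weights = np.array([len(reference.sequences[n]) for n in names], dtype=float)
    weights /= weights.sum()
    lengths = _draw_lengths(config, n_reads, rng)
    reads: list[SimRead] = []
    for i in range(n_reads):
        L = int(lengths[i])
        chrom = names[rng.choice(len(names), p=weights)]
        ref_seq = reference.sequences[chrom]
        if L > len(ref_seq):
            raise ValueError(f"fragment length {L} exceeds sequence {chrom}")
        start = int(rng.integers(0, len(ref_seq) - L + 1))
        frag = list(ref_seq[start : start + L])
        n_subs = rng.binomial(L, config.divergence)
        for pos in rng.choice(L, size=n_subs, replace=False):
            alternatives = [b for b in BASES if b != frag[pos]]
            frag[pos] = alternatives[rng.integers(0, 3)]
        is_reverse = bool(rng.random() < 0.5)
        seq = "".join(frag)
        if is_reverse:
            seq = revcomp(seq)
        seq = _apply_deamination(seq, config.deam_p0, config.deam_decay, rng)
        reads.append(
            SimRead(
                name=f"endo_{i}",
                seq=seq,
                origin="endogenous",
                chrom=chrom,
                start=start,
                is_reverse=is_reverse,
            )
        )
    return reads


def simulate_contaminant(
    config: SimConfig,
    n_reads: int,
    rng: np.random.Generator | None = None,
) -> list[SimRead]:
    """Unrelated reads that can align to the reference only by chance.

    Lengths are uniform over the configured range. ``iid`` mode draws bases
    independently at the configured composition; ``genome`` mode fragments an
    independently simulated genome (shared structure between reads, as real
    microbial contamination would have).
    """
    rng = rng if rng is not None else config.rng()
    lo, hi = config.contaminant_length_range
    lengths = rng.integers(lo, hi + 1, size=n_reads)
    probs = np.asarray(config.composition, dtype=float)
    reads: list[SimRead] = []
    if config.contaminant_mode == "genome":
        source = simulate_reference(
            max(1000, 10 * hi), config.composition, rng, name="contam_src"
        ).sequences["contam_src"]
        for i in range(n_reads):
            L = int(lengths[i])
            start = int(rng.integers(0, len(source) - L + 1))
            reads.append(SimRead(name=f"cont_{i}", seq=source[start : start + L], origin="contaminant"))
    elif config.contaminant_mode == "iid":
        for i in range(n_reads):
            L = int(lengths[i])
            idx = rng.choice(4, size=L, p=probs)
            reads.append(
                SimRead(name=f"cont_{i}", seq="".join(BASES[j] for j in idx), origin="contaminant")
            )
    else:
        raise ValueError(f"unknown contaminant mode {config.contaminant_mode!r}")
    return reads


def write_fastq(reads: Iterable[SimRead], path: str | Path, quality: str = "I") -> None:
    """Reads as FASTQ with constant quality (quality modelling is out of scope)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{quality * r.length}\n")


def write_ground_truth(reads: Iterable[SimRead], path: str | Path) -> None:
    pd.DataFrame(
        [(r.name, r.origin, r.chrom or "", -1 if r.start is None else r.start,
          "-" if r.is_reverse else "+", r.length) for r in reads],
        columns=["name", "origin", "chrom", "start", "strand", "len"],
    ).to_csv(path, sep="\t", index=False)


def simulate_classified_mixture(
    config: SimConfig,
    n_reads: int,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Alignment-free mixture of pre-classified records with ground truth.

    Bypasses mapping entirely: every record represents a mappable,
    non-strand-guarded alignment overlapping one mutated site. Endogenous
    records carry the original reference base unless a divergence
    substitution hit the site; contaminant (spurious) records carry the
    mutated allele with probability 1 - M(l) and each other base with
    probability M(l)/3, a mismatch count at the allowed maximum m(l), and
    indels at the configured rate. Classification then follows the site rule:
    a record is TRUE_HOMININ iff it shows the reference base.

    Returns (classified table, ground-truth labels); the labels share the
    qname key and must not feed the estimator under test.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(config.seed if seed is None else seed)
    )
    lengths = _draw_lengths(config, n_reads, rng).astype(int)
    p_spur = np.array([config.p_spur_at(int(l)) for l in lengths])
    is_spur = rng.random(n_reads) < p_spur
    M = np.array([config.rule.M(int(l)) for l in lengths])
    m = np.array([config.rule.m(int(l)) for l in lengths])

    # carried allele at the classifying site
    u = rng.random(n_reads)
    allele = np.empty(n_reads, dtype=object)
    # endogenous: reference unless divergence hit the site
    div = config.divergence
    endo = ~is_spur
    allele[endo & (u < 1 - div)] = "reference"
    allele[endo & (u >= 1 - div) & (u < 1 - 2 * div / 3)] = "mutated"
    allele[endo & (u >= 1 - 2 * div / 3)] = "other"
    # spurious: mutated w.p. 1-M, reference w.p. M/3, other w.p. 2M/3
    allele[is_spur & (u < 1 - M)] = "mutated"
    allele[is_spur & (u >= 1 - M) & (u < 1 - 2 * M / 3)] = "reference"
    allele[is_spur & (u >= 1 - 2 * M / 3)] = "other"

    cls = np.where(allele == "reference", "TRUE_HOMININ", "SPURIOUS")

    mm_raw = np.where(is_spur, m, rng.poisson(div * lengths))
    mm_corr = np.where(allele == "mutated", mm_raw, np.maximum(0, mm_raw - 1))
    indel_p = np.where(is_spur, config.indel_prob_spurious, config.indel_prob_endogenous)
    indels = (rng.random(n_reads) < indel_p).astype(int)

    # terminal C->T: per-end probability for endogenous reads is the chance
    # the terminal reference base is C times the damage probability p0
    f_c = config.composition[1]
    p_ct_endo = f_c * config.deam_p0
    p_ct = np.where(is_spur, config.ct_prob_spurious, p_ct_endo)
    ct5 = rng.random(n_reads) < p_ct
    ct3 = rng.random(n_reads) < p_ct

    strand = np.where(rng.random(n_reads) < 0.5, "+", "-")
    qnames = [f"mix_{i}" for i in range(n_reads)]
    classified = pd.DataFrame(
        {
            "qname": qnames,
            "chrom": "sim1",
            "pos0": -1,
            "len": lengths,
            "strand": strand,
            "class": cls,
            "allele": allele,
            "mm_corr": mm_corr,
            "mm_prop": mm_corr / lengths,
            "indels": indels,
            "ct5": ct5,
            "ct3": ct3,
        }
    )
    labels = pd.DataFrame(
        {
            "qname": qnames,
            "origin": np.where(is_spur, "contaminant", "endogenous"),
            "allele": allele,
        }
    )
    return classified, labels
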