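import numpy as np
import pytest

from spuriometer.io import ReadAlignment, ReferenceGenome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genome():
    return ReferenceGenome(
        {"chr1": "ACGT" * 300, "chr2": "TTGACCAGTC" * 50}
    )


def make_aln(
    seq: str,
    start: int = 0,
    cigar: str | None = None,
    reverse: bool = False,
    ref_name: str = "chr1",
    qname: str = "r1",
    md: str | None = None,
) -> ReadAlignment:
    """Shorthand for constructing alignment records in tests."""
    return ReadAlignment(
        qname=qname,
        ref_name=ref_name,
        ref_start=start,
        seq=seq,
        cigar=cigar or f"{len(seq)}M",
        is_reverse=reverse,
        md=md,
    )


def oracle_unique_flags(seq: str, k: int, max_mm: int = 1) -> np.ndarray:
    """All-pairs Hamming search: independent mappability oracle.

    Compares every k-mer against every other k-mer and every
    reverse-complement k-mer of a single-sequence genome with dense numpy
    broadcasting; a start is unique iff no other locus comes within max_mm
    mismatches on either strand.
    """
    comp = str.maketrans("ACGT", "TGCA")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    rc = np.frombuffer(seq.translate(comp).encode()[::-1], dtype=np.uint8)
    m = len(seq) - k + 1
    if m <= 0:
        return np.zeros(0, dtype=bool)
    W = np.lib.stride_tricks.sliding_window_view(arr, k)
    RCW = np.lib.stride_tricks.sliding_window_view(rc, k)
    # reverse-complement k-mer of the window starting at p is the rc-genome
    # window starting at len(seq) - k - p
    R = RCW[::-1]
    d_ff = (W[:, None, :] != W[None, :, :]).sum(-1)
    d_fr = (W[:, None, :] != R[None, :, :]).sum(-1)
    np.fill_diagonal(d_ff, k)  # same locus
    np.fill_diagonal(d_fr, k)  # same locus, opposite strand
    return (np.minimum(d_ff.min(1), d_fr.min(1)) > max_mm)


def fisher_oracle(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p by direct hypergeometric enumeration.

    Fixes all margins of the table [[k1, n1-k1], [k2, n2-k2]] and sums the
    point probabilities of every table no more probable than the observed
    one. Factorials only; independent of any library test routine.
    """
    from math import comb

    K = k1 + k2
    N = n1 + n2
    denom = comb(N, K)
    lo, hi = max(0, K - n2), min(K, n1)
    probs = {x: comb(n1, x) * comb(n2, K - x) / denom for x in range(lo, hi + 1)}
    p_obs = probs[k1]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))
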