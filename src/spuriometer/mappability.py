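"""Length-dependent unique-mappability tracks for small genomes.

A position is uniquely mappable at length k when its k-mer (or the k-mer's
reverse complement) occurs nowhere else in the genome within a given number
of mismatches. Tracks for a ladder of k values let a length-aware filter pick,
for each read, the largest k not exceeding the read length and keep the read
only if a uniquely mappable k-mer start falls within its alignment span.

The builder here is an exact brute-force search intended for genomes up to
roughly 100 kb (documented bound); it uses a pigeonhole split of each k-mer
into ``max_mismatch + 1`` exact-matching parts to prune candidate pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import ReadAlignment, ReferenceGenome, revcomp

DEFAULT_K_VALUES = (20, 23, 26, 29, 32, 35)
_BRUTE_FORCE_BOUND = 100_000


@dataclass
class MappabilityTrackSet:
    """Per-k boolean flags: True where a k-mer starting here maps uniquely.

    ``tracks[k][name]`` has one flag per start position 0 .. L-k.
    """

    k_values: tuple[int, ...]
    tracks: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)

    def largest_k_not_longer(self, read_length: int) -> int | None:
        eligible = [k for k in self.k_values if k <= read_length]
        return max(eligible) if eligible else None

    def to_dir(self, outdir: str | Path) -> None:
        """One BED of unique-start intervals per k, plus a JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lengths: dict[str, int] = {}
        for k in self.k_values:
            with open(outdir / f"mappability_k{k}.bed", "w") as fh:
                for name, flags in self.tracks[k].items():
                    lengths[name] = flags.size + k - 1
                    for start, end in _runs(flags):
                        fh.write(f"{name}\t{start}\t{end}\n")
        sidecar = {"k_values": list(self.k_values), "sequence_lengths": lengths}
        (outdir / "mappability.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_dir(cls, indir: str | Path) -> "MappabilityTrackSet":
        indir = Path(indir)
        sidecar = json.loads((indir / "mappability.json").read_text())
        k_values = tuple(sidecar["k_values"])
        lengths = sidecar["sequence_lengths"]
        tracks: dict[int, dict[str, np.ndarray]] = {}
        for k in k_values:
            per_seq = {
                name: np.zeros(max(0, L - k + 1), dtype=bool) for name, L in lengths.items()
            }
            with open(indir / f"mappability_k{k}.bed") as fh:
                for line in fh:
                    name, s, e = line.split("\t")[:3]
                    per_seq[name][int(s) : int(e)] = True
            tracks[k] = per_seq
        return cls(k_values=k_values, tracks=tracks)


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    if flags.size == 0:
        return []
    padded = np.concatenate(([False], flags, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def _hamming_leq(a: str, b: str, limit: int) -> bool:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return False
    return True


def build_mappability_tracks(
    genome: ReferenceGenome,
    k_values: tuple[int, ...] = DEFAULT_K_VALUES,
    max_mismatch: int = 1,
) -> MappabilityTrackSet:
    """Exact all-vs-all unique-mappability search for a small genome.

    A start position is flagged unique iff no other locus in the genome, on
    either strand, carries a k-mer within ``max_mismatch`` mismatches of the
    k-mer starting there. k-mers containing N are never unique. Sequences
    shorter than k contribute an empty track.
    """
    if genome.total_length > _BRUTE_FORCE_BOUND:
        raise ValueError(
            f"brute-force mappability is bounded at {_BRUTE_FORCE_BOUND} bp; "
            f"got {genome.total_length}"
        )
    tracks: dict[int, dict[str, np.ndarray]] = {}
    for k in sorted(set(k_values)):
        tracks[k] = _build_single_k(genome, k, max_mismatch)
    return MappabilityTrackSet(k_values=tuple(sorted(set(k_values))), tracks=tracks)


def _build_single_k(
    genome: ReferenceGenome, k: int, max_mismatch: int
) -> dict[str, np.ndarray]:
    # enumerate loci: (locus_id, forward k-mer); each locus also offers its
    # reverse complement as a target, since a read can map to either strand
    loci: list[tuple[int, str]] = []
    locus_coords: list[tuple[str, int]] = []
    for name, seq in genome.sequences.items():
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            loci.append((len(locus_coords), kmer))
            locus_coords.append((name, pos))

    parts = max_mismatch + 1
    bounds = [round(i * k / parts) for i in range(parts + 1)]
    # part index -> part string -> list of (locus_id, target k-mer)
    index: list[dict[str, list[tuple[int, str]]]] = [{} for _ in range(parts)]
    for locus_id, fwd in loci:
        if "N" in fwd:
            continue
        for target in (fwd, revcomp(fwd)):
            for pi in range(parts):
                part = target[bounds[pi] : bounds[pi + 1]]
                index[pi].setdefault(part, []).append((locus_id, target))

    per_seq = {
        name: np.zeros(max(0, len(seq) - k + 1), dtype=bool)
        for name, seq in genome.sequences.items()
    }
    for locus_id, fwd in loci:
        if "N" in fwd:
            continue
        unique = True
        seen_pairs: set[tuple[int, str]] = set()
        for pi in range(parts):
            part = fwd[bounds[pi] : bounds[pi + 1]]
            for tid, target in index[pi].get(part, ()):
                if tid == locus_id:
                    continue  # same genomic locus, either strand
                key = (tid, target)
                if key in seen_pairs:
                    continue
                seen_pairs.add(key)
                if _hamming_leq(fwd, target, max_mismatch):
                    unique = False
                    break
            if not unique:
                break
        name, pos = locus_coords[locus_id]
        per_seq[name][pos] = unique
    return per_seq


def is_uniquely_mappable(aln: ReadAlignment, tracks: MappabilityTrackSet) -> bool:
    """Length-aware unique-mappability decision for one alignment.

    Picks the largest track k not longer than the read, then accepts the read
    iff some uniquely mappable k-mer start p satisfies start <= p <= end - k
    within the alignment span. Reads shorter than every track length are
    rejected outright.
    """
    k = tracks.largest_k_not_longer(aln.read_length)
    if k is None:
        return False
    flags = tracks.tracks[k].get(aln.ref_name)
    if flags is None:
        return False
    lo = max(0, aln.ref_start)
    hi = min(flags.size, aln.ref_end - k + 1)
    if hi <= lo:
        return False
    return bool(flags[lo:hi].any())
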