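"""File formats and core containers.

Coordinates are 0-based, half-open everywhere inside the package; BED files
are read natively, SAM/BAM positions are converted on ingest.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class ReferenceGenome:
    """A small in-memory genome: sequence name -> uppercase string over ACGTN.

    Lowercase (soft-masked) input is uppercased on construction; repeat
    handling is expected to arrive through an exclusion track instead.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for name, seq in self.sequences.items():
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"sequence {name!r} contains invalid bases {sorted(bad)}")
            if len(seq) < 1:
                raise ValueError(f"sequence {name!r} is empty")
            clean[name] = seq
        self.sequences = clean

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def composition(self) -> dict[str, float]:
        """Genome-wide base frequencies over A,C,G,T (N excluded)."""
        counts = {b: 0 for b in "ACGT"}
        for seq in self.sequences.values():
            for b in "ACGT":
                counts[b] += seq.count(b)
        total = sum(counts.values())
        if total == 0:
            raise ValueError("genome contains no A/C/G/T bases")
        return {b: c / total for b, c in counts.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            raise ValueError(f"no sequences found in {path}")
        return cls(seqs)

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self.sequences.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)


@dataclass
class ExclusionTrack:
    """Per-sequence sorted, merged, in-bounds [start, end) intervals."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    @staticmethod
    def _normalize(iv: Iterable[tuple[int, int]]) -> np.ndarray:
        arr = np.asarray(sorted((int(s), int(e)) for s, e in iv if e > s), dtype=np.int64)
        if arr.size == 0:
            return arr.reshape(0, 2)
        merged = [list(arr[0])]
        for s, e in arr[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return np.asarray(merged, dtype=np.int64)

    @classmethod
    def from_intervals(cls, intervals: Mapping[str, Iterable[tuple[int, int]]]) -> "ExclusionTrack":
        return cls({name: cls._normalize(iv) for name, iv in intervals.items()})

    @classmethod
    def from_bed(cls, path: str | Path) -> "ExclusionTrack":
        per_seq: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: expected at least 3 BED columns")
                per_seq.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
        return cls.from_intervals(per_seq)

    def mask(self, name: str, length: int) -> np.ndarray:
        """Boolean array of `length`: True where the position is excluded."""
        m = np.zeros(length, dtype=bool)
        for s, e in self.intervals.get(name, ()):
            m[max(0, s) : min(length, e)] = True
        return m


@dataclass(frozen=True)
class MutatedSite:
    chrom: str
    pos0: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("original and mutated base must differ")
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError("site alleles must be A/C/G/T")


class MutatedSiteTable:
    """Ground-truth table of artificial reference changes.

    Positions are strictly increasing per sequence; the table is the key to
    classifying overlapping alignments and to reverting the mutated genome.
    """

    COLUMNS = ("chrom", "pos0", "ref", "alt")

    def __init__(self, sites: Iterable[MutatedSite]):
        self.sites: list[MutatedSite] = list(sites)
        self._by_chrom: dict[str, dict[int, MutatedSite]] = {}
        last: dict[str, int] = {}
        for s in self.sites:
            if s.chrom in last and s.pos0 <= last[s.chrom]:
                raise ValueError(f"positions not strictly increasing on {s.chrom}")
            last[s.chrom] = s.pos0
            self._by_chrom.setdefault(s.chrom, {})[s.pos0] = s

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[MutatedSite]:
        return iter(self.sites)

    def lookup(self, chrom: str, pos0: int) -> MutatedSite | None:
        return self._by_chrom.get(chrom, {}).get(pos0)

    def overlapping(self, chrom: str, start: int, end: int) -> list[MutatedSite]:
        """Sites with start <= pos0 < end, in position order."""
        positions = self._by_chrom.get(chrom)
        if not positions:
            return []
        return [positions[p] for p in sorted(positions) if start <= p < end]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.chrom, s.pos0, s.ref, s.alt) for s in self.sites], columns=list(self.COLUMNS)
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutatedSiteTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = set(cls.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        return cls(
            MutatedSite(r.chrom, int(r.pos0), r.ref, r.alt)
            for r in df.itertuples(index=False)
        )


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_MD_RE = re.compile(r"(\d+)|(\^[A-Z]+)|([A-Z])")


def parse_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    ops = tuple((op, int(n)) for n, op in _CIGAR_RE.findall(cigar))
    if not ops:
        raise ValueError(f"unparseable CIGAR {cigar!r}")
    return tuple(("M", n) if op in "=X" else (op, n) for op, n in ops)


@dataclass
class ReadAlignment:
    """A single-end alignment; `seq` is stored reference-forward as in SAM.

    The read-orientation view (the order bases were sequenced in, relevant for
    terminal deamination) is obtained by reverse-complementing when
    ``is_reverse`` is set.
    """

    qname: str
    ref_name: str
    ref_start: int
    seq: str
    cigar: tuple[tuple[str, int], ...]
    is_reverse: bool
    md: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.cigar, str):
            self.cigar = parse_cigar(self.cigar)
        self.seq = self.seq.upper()
        qlen = sum(n for op, n in self.cigar if op in "MIS")
        if qlen != len(self.seq):
            raise ValueError(
                f"{self.qname}: CIGAR query length {qlen} != sequence length {len(self.seq)}"
            )

    @property
    def read_length(self) -> int:
        return len(self.seq)

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.cigar if op in "MD")

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"

    def aligned_pairs(self) -> list[tuple[int | None, int | None]]:
        """(query_pos, ref_pos) pairs; None on the unaligned side of indels/clips."""
        pairs: list[tuple[int | None, int | None]] = []
        q, r = 0, self.ref_start
        for op, n in self.cigar:
            if op == "M":
                pairs.extend((q + i, r + i) for i in range(n))
                q += n
                r += n
            elif op in "IS":
                pairs.extend((q + i, None) for i in range(n))
                q += n
            elif op in "DN":
                pairs.extend((None, r + i) for i in range(n))
                r += n
        return pairs

    def query_pos_at(self, ref_pos: int) -> int | None:
        """Query index aligned to ref_pos, or None if a deletion spans it."""
        q, r = 0, self.ref_start
        for op, n in self.cigar:
            if op == "M":
                if r <= ref_pos < r + n:
                    return q + (ref_pos - r)
                q += n
                r += n
            elif op in "IS":
                q += n
            elif op in "DN":
                if r <= ref_pos < r + n:
                    return None
                r += n
        raise ValueError(f"ref position {ref_pos} outside alignment span")

    def base_at(self, ref_pos: int) -> str | None:
        qpos = self.query_pos_at(ref_pos)
        return None if qpos is None else self.seq[qpos]

    def read_orientation_seq(self) -> str:
        return revcomp(self.seq) if self.is_reverse else self.seq

    def md_mismatch_count(self) -> int | None:
        """Mismatches encoded in the MD tag, or None when no tag is carried."""
        if self.md is None:
            return None
        count = 0
        for num, deletion, sub in _MD_RE.findall(self.md):
            if sub:
                count += 1
        return count

    @classmethod
    def from_pysam(cls, rec) -> "ReadAlignment":
        md = rec.get_tag("MD") if rec.has_tag("MD") else None
        cigar = tuple(
            ("MIDNSHP=X"[op], n) for op, n in rec.cigartuples or ()
        )
        return cls(
            qname=rec.query_name,
            ref_name=rec.reference_name,
            ref_start=rec.reference_start,
            seq=rec.query_sequence,
            cigar=cigar,
            is_reverse=rec.is_reverse,
            md=md,
        )


def read_sam(path: str | Path, min_len: int = 20) -> Iterator[ReadAlignment]:
    """Iterate mapped single-end alignments from SAM/BAM.

    Paired-end records and reads shorter than ``min_len`` are discarded, as
    are unmapped and secondary/supplementary records.
    """
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_paired:
                continue
            if rec.query_sequence is None or len(rec.query_sequence) < min_len:
                continue
            yield ReadAlignment.from_pysam(rec)
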