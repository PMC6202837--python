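"""Classify alignments at artificially mutated sites and extract features.

A read overlapping a mutated site is *true* if it carries the original
reference base there, and *spurious* if it carries the mutated base or either
of the two other bases. Because post-mortem cytosine deamination converts C
to T (seen as G to A on the opposite strand), sites whose original or mutated
state is C are ignored for forward-strand alignments and sites whose original
or mutated state is G for reverse-strand alignments; the single-stranded
library protocol preserves strand, making this guard possible.

Feature extraction covers corrected mismatch counts (one mismatch subtracted
per overlapped site where the read does not match the mutated allele, since
such alignments necessarily carry a mismatch to the modified reference),
indel event counts from the CIGAR, terminal C-to-T flags in read orientation
against the unmodified reference, and the per-position substitution spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import MutatedSite, MutatedSiteTable, ReadAlignment, ReferenceGenome
from .mappability import (  # noqa: F401  (re-exported: part of this module's surface)
    MappabilityTrackSet,
    build_mappability_tracks,
    is_uniquely_mappable,
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SUBSTITUTION_TYPES = tuple(
    f"{x}>{y}" for x in "ACGT" for y in "ACGT" if x != y
)


class AlnClass(str, Enum):
    TRUE_HOMININ = "TRUE_HOMININ"
    SPURIOUS = "SPURIOUS"
    EXCLUDED_STRAND = "EXCLUDED_STRAND"
    NO_SITE = "NO_SITE"
    UNMAPPABLE = "UNMAPPABLE"


@dataclass
class ClassifiedAlignment:
    qname: str
    chrom: str
    pos0: int | None  # classifying site position, when one exists
    length: int
    strand: str
    cls: AlnClass
    allele: str | None  # "reference" | "mutated" | "other"
    mm_corr: int
    mm_prop: float
    indels: int
    ct5: bool
    ct3: bool


CLASSIFIED_COLUMNS = (
    "qname",
    "chrom",
    "pos0",
    "len",
    "strand",
    "class",
    "allele",
    "mm_corr",
    "mm_prop",
    "indels",
    "ct5",
    "ct3",
)


def classified_to_frame(records: Iterable[ClassifiedAlignment]) -> pd.DataFrame:
    rows = [
        (
            r.qname,
            r.chrom,
            -1 if r.pos0 is None else r.pos0,
            r.length,
            r.strand,
            r.cls.value,
            r.allele or "",
            r.mm_corr,
            r.mm_prop,
            r.indels,
            r.ct5,
            r.ct3,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(CLASSIFIED_COLUMNS))


def write_classified_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_classified_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(CLASSIFIED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def strand_guard(site: MutatedSite, is_reverse: bool) -> bool:
    """True when the deamination guard disqualifies this site/strand combination."""
    if not is_reverse:
        return site.ref == "C" or site.alt == "C"
    return site.ref == "G" or site.alt == "G"


def classify_at_site(aln: ReadAlignment, site: MutatedSite) -> tuple[AlnClass, str | None]:
    """Classify one alignment at one mutated site.

    Returns (class, carried allele). The strand guard fires regardless of the
    read base; a deletion spanning the site or an N base yields NO_SITE.
    """
    if not (aln.ref_start <= site.pos0 < aln.ref_end):
        raise ValueError(f"site {site.chrom}:{site.pos0} outside alignment span")
    if strand_guard(site, aln.is_reverse):
        return AlnClass.EXCLUDED_STRAND, None
    base = aln.base_at(site.pos0)
    if base is None or base == "N":
        return AlnClass.NO_SITE, None
    if base == site.ref:
        return AlnClass.TRUE_HOMININ, "reference"
    if base == site.alt:
        return AlnClass.SPURIOUS, "mutated"
    return AlnClass.SPURIOUS, "other"


def raw_mismatches(aln: ReadAlignment, reference: ReferenceGenome | None = None) -> int:
    """Mismatch count against the (mutated) reference the read was aligned to.

    Uses the MD tag when carried; otherwise compares the read to the provided
    reference over aligned positions. N on either side never counts.
    """
    md_count = aln.md_mismatch_count()
    if md_count is not None:
        return md_count
    if reference is None:
        raise ValueError("no MD tag and no reference supplied")
    ref_seq = reference.sequences[aln.ref_name]
    count = 0
    for qpos, rpos in aln.aligned_pairs():
        if qpos is None or rpos is None:
            continue
        q, r = aln.seq[qpos], ref_seq[rpos]
        if q != r and q != "N" and r != "N":
            count += 1
    return count


def corrected_mismatches(
    aln: ReadAlignment,
    overlapped_sites: Sequence[MutatedSite],
    reference: ReferenceGenome | None = None,
) -> tuple[int, float]:
    """Mismatch count with the artificial-site mismatch subtracted.

    One mismatch is removed for every overlapped mutated site where the read
    base differs from the mutated allele (those alignments necessarily carry
    a mismatch there by construction); the count is floored at zero. Returns
    (count, count / read length).
    """
    raw = raw_mismatches(aln, reference)
    subtract = 0
    for site in overlapped_sites:
        base = aln.base_at(site.pos0)
        if base is not None and base != "N" and base != site.alt:
            subtract += 1
    count = max(0, raw - subtract)
    return count, count / aln.read_length


def count_indels(aln: ReadAlignment) -> int:
    """Number of insertion plus deletion events (CIGAR runs, not bases)."""
    return sum(1 for op, _ in aln.cigar if op in "ID")


def _read_orientation_pairs(aln: ReadAlignment) -> list[tuple[int, int | None]]:
    """(read-orientation position, ref position) for every read base."""
    pairs = [(q, r) for q, r in aln.aligned_pairs() if q is not None]
    L = aln.read_length
    if aln.is_reverse:
        return [(L - 1 - q, r) for q, r in pairs]
    return list(pairs)


def _read_orientation_base(aln: ReadAlignment, sam_qpos: int) -> str:
    base = aln.seq[sam_qpos]
    return _COMPLEMENT[base] if aln.is_reverse else base


def terminal_ct_flags(
    aln: ReadAlignment, original: ReferenceGenome
) -> tuple[bool, bool]:
    """C-to-T at the first / last read base, in read orientation.

    Substitutions are called against the unmodified reference. For
    reverse-strand alignments both read and reference bases are complemented
    into read orientation first, so a reference-forward G-to-A at the
    alignment's right edge registers as a 5' C-to-T. A terminal base inside
    an insertion (no reference base) never flags.
    """
    ref_seq = original.sequences[aln.ref_name]
    L = aln.read_length
    flags = []
    for ro_pos in (0, L - 1):
        sam_qpos = (L - 1 - ro_pos) if aln.is_reverse else ro_pos
        rpos = _qpos_to_rpos(aln, sam_qpos)
        if rpos is None:
            flags.append(False)
            continue
        read_base = _read_orientation_base(aln, sam_qpos)
        ref_base = ref_seq[rpos]
        if aln.is_reverse:
            ref_base = _COMPLEMENT[ref_base]
        flags.append(ref_base == "C" and read_base == "T")
    return flags[0], flags[1]


def _qpos_to_rpos(aln: ReadAlignment, qpos: int) -> int | None:
    for q, r in aln.aligned_pairs():
        if q == qpos:
            return r
    return None


def substitution_spectrum(
    alns: Iterable[ReadAlignment], original: ReferenceGenome
) -> pd.DataFrame:
    """Per-read-position frequency of each of the 12 substitution types.

    Frequencies are conditional: reads showing X-to-Y at read position i over
    reads whose (unmodified) reference base at that position is X. Positions
    and bases are in read orientation. Cells with zero denominator are NaN.
    """
    sub_counts: dict[tuple[int, str], int] = {}
    ref_counts: dict[tuple[int, str], int] = {}
    max_pos = -1
    for aln in alns:
        ref_seq = original.sequences[aln.ref_name]
        for ro_pos, rpos in _read_orientation_pairs(aln):
            if rpos is None:
                continue
            sam_qpos = (aln.read_length - 1 - ro_pos) if aln.is_reverse else ro_pos
            read_base = _read_orientation_base(aln, sam_qpos)
            ref_base = ref_seq[rpos]
            if aln.is_reverse:
                ref_base = _COMPLEMENT[ref_base]
            if ref_base == "N" or read_base == "N":
                continue
            max_pos = max(max_pos, ro_pos)
            ref_counts[(ro_pos, ref_base)] = ref_counts.get((ro_pos, ref_base), 0) + 1
            if read_base != ref_base:
                key = (ro_pos, f"{ref_base}>{read_base}")
                sub_counts[key] = sub_counts.get(key, 0) + 1
    if max_pos < 0:
        raise ValueError("no aligned bases in input")
    data = np.full((max_pos + 1, len(SUBSTITUTION_TYPES)), np.nan)
    for j, sub in enumerate(SUBSTITUTION_TYPES):
        x = sub[0]
        for pos in range(max_pos + 1):
            denom = ref_counts.get((pos, x), 0)
            if denom:
                data[pos, j] = sub_counts.get((pos, sub), 0) / denom
    return pd.DataFrame(data, columns=list(SUBSTITUTION_TYPES))


def classify_alignment(
    aln: ReadAlignment,
    sites: MutatedSiteTable,
    mutated: ReferenceGenome | None,
    original: ReferenceGenome,
    tracks: MappabilityTrackSet | None = None,
) -> ClassifiedAlignment:
    """Full per-alignment record: class, allele and all filter features.

    Mappability (when tracks are given) is decided first; reads failing it
    are UNMAPPABLE. The classifying site is the 5'-most (in read orientation)
    overlapped site that the strand guard does not disqualify.
    """
    overlapped = sites.overlapping(aln.ref_name, aln.ref_start, aln.ref_end)
    mm_corr, mm_prop = corrected_mismatches(aln, overlapped, mutated)
    indels = count_indels(aln)
    ct5, ct3 = terminal_ct_flags(aln, original)

    def make(cls: AlnClass, allele: str | None, pos0: int | None) -> ClassifiedAlignment:
        return ClassifiedAlignment(
            qname=aln.qname,
            chrom=aln.ref_name,
            pos0=pos0,
            length=aln.read_length,
            strand=aln.strand,
            cls=cls,
            allele=allele,
            mm_corr=mm_corr,
            mm_prop=mm_prop,
            indels=indels,
            ct5=ct5,
            ct3=ct3,
        )

    if tracks is not None and not is_uniquely_mappable(aln, tracks):
        return make(AlnClass.UNMAPPABLE, None, None)
    if not overlapped:
        return make(AlnClass.NO_SITE, None, None)
    ordered = overlapped if not aln.is_reverse else list(reversed(overlapped))
    any_guarded = False
    for site in ordered:
        cls, allele = classify_at_site(aln, site)
        if cls in (AlnClass.TRUE_HOMININ, AlnClass.SPURIOUS):
            return make(cls, allele, site.pos0)
        if cls is AlnClass.EXCLUDED_STRAND:
            any_guarded = True
    if any_guarded:
        return make(AlnClass.EXCLUDED_STRAND, None, None)
    return make(AlnClass.NO_SITE, None, None)


def classify_alignments(
    alns: Iterable[ReadAlignment],
    sites: MutatedSiteTable,
    mutated: ReferenceGenome | None,
    original: ReferenceGenome,
    tracks: MappabilityTrackSet | None = None,
    min_len: int = 20,
) -> list[ClassifiedAlignment]:
    """Classify an alignment stream; reads shorter than ``min_len`` are dropped."""
    return [
        classify_alignment(a, sites, mutated, original, tracks)
        for a in alns
        if a.read_length >= min_len
    ]
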