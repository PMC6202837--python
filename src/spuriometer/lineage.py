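"""Derived-allele-sharing lineage assignment for ancient hominin samples.

Lineage-informative sites are positions where exactly one of four lineage
patterns carries a derived allele relative to the primate-outgroup ancestral
state: Modern Human only, Neandertal only, Denisovan only, or Neandertal and
Denisovan jointly. One random allele is sampled from each diploid genotype;
the ancestral call requires at least four of five primates to agree.

For a set of aligned reads, the percentage of informative sites of each
class at which the read carries the derived allele measures lineage
affinity. Read-base observations that are T within the three terminal
positions of either read end are discarded to limit the influence of
deamination-induced C-to-T changes. Neandertal-versus-Denisovan sharing is
compared with a two-sided Fisher exact test, adjusted for multiplicity
across samples and cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .io import ReadAlignment

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class Lineage(str, Enum):
    MODERN_HUMAN = "ModernHuman"
    NEANDERTAL = "Neandertal"
    DENISOVAN = "Denisovan"
    NEANDERTAL_DENISOVAN = "NeandertalDenisovan"


@dataclass(frozen=True)
class InformativeSite:
    chrom: str
    pos0: int
    ancestral: str
    derived: str
    lineage: Lineage

    def __post_init__(self) -> None:
        if self.ancestral == self.derived:
            raise ValueError("ancestral and derived alleles must differ")


def call_ancestral(column: Sequence[str | None]) -> str | None:
    """Ancestral allele supported by at least four non-missing primates."""
    alleles = [a for a in column if a not in (None, "", ".", "N")]
    if len(alleles) < 4:
        return None
    for allele in set(alleles):
        if alleles.count(allele) >= 4:
            return allele
    return None


def sample_allele(genotype: str | None, rng: np.random.Generator) -> str | None:
    """One random allele from a diploid genotype like "A/G"; missing -> None.

    Homozygous genotypes return their allele deterministically (no draw is
    consumed, keeping streams comparable across genotype mixes).
    """
    if genotype is None:
        return None
    parts = genotype.replace("|", "/").split("/")
    if len(parts) != 2:
        raise ValueError(f"expected a diploid genotype, got {genotype!r}")
    a, b = parts
    if a in (".", "", "N") or b in (".", "", "N"):
        return None
    if a == b:
        return a
    return a if rng.random() < 0.5 else b


def classify_informative_site(
    mh: str, nea: str, den: str, ancestral: str
) -> tuple[Lineage, str] | None:
    """Map sampled alleles to one of the four lineage classes.

    Returns (lineage, derived allele) or None. The derived allele is the
    single non-ancestral allele among the three samples; sites that are
    triallelic, carry no derived allele, or show a modern-human-plus-one-
    archaic or all-derived pattern are rejected.
    """
    alleles = {mh, nea, den}
    non_anc = alleles - {ancestral}
    if len(non_anc) != 1:
        return None  # no derived allele, or more than one (triallelic)
    derived = non_anc.pop()
    carriers = frozenset(
        name
        for name, allele in (("mh", mh), ("nea", nea), ("den", den))
        if allele == derived
    )
    mapping = {
        frozenset({"mh"}): Lineage.MODERN_HUMAN,
        frozenset({"nea"}): Lineage.NEANDERTAL,
        frozenset({"den"}): Lineage.DENISOVAN,
        frozenset({"nea", "den"}): Lineage.NEANDERTAL_DENISOVAN,
    }
    lineage = mapping.get(carriers)
    if lineage is None:
        return None
    return lineage, derived


def build_informative_sites(
    genotypes: pd.DataFrame,
    primate_columns: pd.DataFrame,
    seed: int | np.random.Generator = 0,
) -> list[InformativeSite]:
    """Join genotype and primate tables into lineage-informative sites.

    ``genotypes`` needs columns chrom, pos0, gt_mh, gt_nea, gt_den;
    ``primate_columns`` needs chrom, pos0 and five allele columns. Sites with
    missing genotypes, no ancestral call, or a non-informative carrier
    pattern are skipped.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    allele_cols = [c for c in primate_columns.columns if c not in ("chrom", "pos0")]
    if len(allele_cols) != 5:
        raise ValueError(f"expected 5 primate allele columns, got {allele_cols}")
    merged = genotypes.merge(primate_columns, on=["chrom", "pos0"], how="inner")
    sites: list[InformativeSite] = []
    for row in merged.itertuples(index=False):
        anc = call_ancestral([getattr(row, c) for c in allele_cols])
        if anc is None:
            continue
        sampled = [sample_allele(getattr(row, c), rng) for c in ("gt_mh", "gt_nea", "gt_den")]
        if any(a is None for a in sampled):
            continue
        result = classify_informative_site(*sampled, anc)
        if result is None:
            continue
        lineage, derived = result
        sites.append(InformativeSite(row.chrom, int(row.pos0), anc, derived, lineage))
    return sites


def write_informative_tsv(sites: Iterable[InformativeSite], path: str | Path) -> None:
    pd.DataFrame(
        [(s.chrom, s.pos0, s.ancestral, s.derived, s.lineage.value) for s in sites],
        columns=["chrom", "pos0", "anc", "der", "class"],
    ).to_csv(path, sep="\t", index=False)


def read_informative_tsv(path: str | Path) -> list[InformativeSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        InformativeSite(r.chrom, int(r.pos0), r.anc, r.der, Lineage(getattr(r, "_4")))
        if not hasattr(r, "class")
        else InformativeSite(r.chrom, int(r.pos0), r.anc, r.der, Lineage(getattr(r, "class")))
        for r in df.itertuples(index=False)
    ]


@dataclass
class ClassSharing:
    n: int = 0
    k: int = 0

    @property
    def pct(self) -> float:
        return 100.0 * self.k / self.n if self.n else float("nan")

    def ci(self, alpha: float = 0.10) -> tuple[float, float]:
        """Binomial confidence interval on the percentage (90% by default)."""
        if self.n == 0:
            return float("nan"), float("nan")
        lo, hi = proportion_confint(self.k, self.n, alpha=alpha, method="wilson")
        return 100.0 * float(lo), 100.0 * float(hi)


@dataclass
class SharingResult:
    classes: dict[Lineage, ClassSharing] = field(
        default_factory=lambda: {lin: ClassSharing() for lin in Lineage}
    )
    n_discarded_terminal_t: int = 0
    n_discarded_other_base: int = 0

    def to_dict(self, alpha: float = 0.10) -> dict:
        return {
            lin.value: {
                "n": cs.n,
                "k": cs.k,
                "pct": cs.pct,
                "ci": list(cs.ci(alpha)),
            }
            for lin, cs in self.classes.items()
        }


def derived_sharing(
    alns: Iterable[ReadAlignment],
    sites: Sequence[InformativeSite],
    min_len: int = 0,
) -> SharingResult:
    """Per-lineage derived-allele sharing over read/site overlaps.

    Only observations where the read base equals the ancestral or derived
    allele enter n (other bases are treated as sequencing error). Read bases
    that are T, in read orientation, within three positions of either read
    end are discarded to guard against deamination.
    """
    by_pos: dict[tuple[str, int], InformativeSite] = {
        (s.chrom, s.pos0): s for s in sites
    }
    result = SharingResult()
    for aln in alns:
        if aln.read_length < min_len:
            continue
        L = aln.read_length
        for qpos, rpos in aln.aligned_pairs():
            if qpos is None or rpos is None:
                continue
            site = by_pos.get((aln.ref_name, rpos))
            if site is None:
                continue
            base = aln.seq[qpos]  # reference orientation, like the site alleles
            if base == "N":
                continue
            ro_pos = (L - 1 - qpos) if aln.is_reverse else qpos
            ro_base = _COMPLEMENT[base] if aln.is_reverse else base
            if ro_base == "T" and (ro_pos < 3 or ro_pos >= L - 3):
                result.n_discarded_terminal_t += 1
                continue
            if base not in (site.ancestral, site.derived):
                result.n_discarded_other_base += 1
                continue
            cs = result.classes[site.lineage]
            cs.n += 1
            if base == site.derived:
                cs.k += 1
    return result


def lineage_test(sharing: SharingResult) -> float:
    """Two-sided Fisher exact p for Neandertal vs Denisovan derived sharing."""
    nea = sharing.classes[Lineage.NEANDERTAL]
    den = sharing.classes[Lineage.DENISOVAN]
    if nea.n == 0 or den.n == 0:
        raise ValueError("both Neandertal and Denisovan classes need observations")
    table = [[nea.k, nea.n - nea.k], [den.k, den.n - den.k]]
    return float(fisher_exact(table, alternative="two-sided")[1])


def adjust_pvalues(
    pvalues: Mapping[str, float], method: str = "fdr_bh"
) -> dict[str, float]:
    """Multiplicity adjustment across a family of sample/cutoff tests."""
    keys = list(pvalues)
    if not keys:
        return {}
    _, adj, _, _ = multipletests([pvalues[k] for k in keys], method=method)
    return dict(zip(keys, adj.tolist()))
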