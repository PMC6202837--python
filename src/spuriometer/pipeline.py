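"""Orchestration of the classify -> estimate -> cutoff and lineage analyses."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import aln_classify, lineage, spurious_stats
from .io import MutatedSiteTable, ReferenceGenome, read_sam
from .mappability import MappabilityTrackSet

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and seeds for one pipeline run."""

    bam: str | None = None
    classified: str | None = None
    sites: str | None = None
    fasta_mutated: str | None = None
    fasta_original: str | None = None
    mappability_dir: str | None = None
    sites_informative: str | None = None
    filters: str = "deam+indel"
    taus: tuple[float, ...] = (0.01, 0.10)
    baseline: int = 35
    min_len: int = 20
    seed: int = 0
    outdir: str = "."
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tau in self.taus:
            if not 0 < tau < 1:
                raise ValueError("tau must be in (0, 1)")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        extra = {k: v for k, v in data.items() if k not in known}
        kwargs = {k: v for k, v in data.items() if k in known}
        if "taus" in kwargs:
            kwargs["taus"] = tuple(kwargs["taus"])
        cfg = cls(**kwargs)
        cfg.extra.update(extra)
        return cfg


def _load_classified(config: RunConfig) -> pd.DataFrame:
    if config.classified:
        return aln_classify.read_classified_tsv(config.classified)
    if not (config.bam and config.sites and config.fasta_original):
        raise ValueError("need either a classified TSV or bam + sites + fasta-original")
    sites = MutatedSiteTable.from_tsv(config.sites)
    original = ReferenceGenome.from_fasta(config.fasta_original)
    mutated = (
        ReferenceGenome.from_fasta(config.fasta_mutated) if config.fasta_mutated else None
    )
    tracks = (
        MappabilityTrackSet.from_dir(config.mappability_dir)
        if config.mappability_dir
        else None
    )
    alns = list(read_sam(config.bam, min_len=config.min_len))
    if not alns:
        raise ValueError(f"no alignments >= {config.min_len} bp in {config.bam}")
    records = aln_classify.classify_alignments(
        alns, sites, mutated, original, tracks, min_len=config.min_len
    )
    return aln_classify.classified_to_frame(records)


def run_estimate_pipeline(config: RunConfig) -> dict:
    """Per-length estimates plus length cutoffs; writes TSV + JSON to outdir.

    Returns the report dictionary: per-filter estimate tables (as records)
    and one cutoff entry per (filter, tau).
    """
    classified = _load_classified(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    estimates = spurious_stats.fraction_by_length(classified, config.filters)
    estimates.to_csv(outdir / "estimates.tsv", sep="\t", index=False)
    cutoffs = []
    for tau in sorted(config.taus, reverse=True):
        res = spurious_stats.find_length_cutoff(
            classified,
            filters=config.filters,
            tau=tau,
            min_len=config.min_len,
            baseline=config.baseline,
        )
        cutoffs.append(res.to_dict())
        logger.info("tau=%s filters=%s -> L=%s", tau, config.filters, res.L)
    report = {
        "seed": config.seed,
        "filters": config.filters,
        "baseline": config.baseline,
        "n_alignments": int(len(classified)),
        "cutoffs": cutoffs,
    }
    (outdir / "cutoffs.json").write_text(json.dumps(report, indent=1))
    return report


def run_lineage_pipeline(config: RunConfig, cutoff: int | None = None) -> dict:
    """Derived-allele sharing per lineage class plus the Neandertal/Denisovan test.

    Applies the configured length cutoff before counting. When no informative
    site overlaps any read, all classes are reported undefined (with a
    warning) rather than failing.
    """
    if not (config.bam and config.sites_informative):
        raise ValueError("lineage pipeline needs bam + sites-informative")
    sites = lineage.read_informative_tsv(config.sites_informative)
    min_len = cutoff if cutoff is not None else config.min_len
    alns = list(read_sam(config.bam, min_len=20))
    sharing = lineage.derived_sharing(alns, sites, min_len=min_len)
    report: dict = {
        "seed": config.seed,
        "cutoff": min_len,
        "sharing": sharing.to_dict(),
        "discarded_terminal_T": sharing.n_discarded_terminal_t,
    }
    nea = sharing.classes[lineage.Lineage.NEANDERTAL]
    den = sharing.classes[lineage.Lineage.DENISOVAN]
    if nea.n == 0 or den.n == 0:
        logger.warning("no overlapping observations for Neandertal and/or Denisovan class")
        report["fisher_p"] = None
    else:
        report["fisher_p"] = lineage.lineage_test(sharing)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "lineage.json").write_text(json.dumps(report, indent=1))
    return report
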