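"""Misclassification-corrected spurious-alignment fractions and length cutoffs.

Raw counts of true (N_T) and spurious (N_S) classifications at mutated sites
undercount spurious alignments: a chance alignment allowed up to a mismatch
proportion M carries the mutated state with probability about 1 - M and each
of the three remaining bases — including the original reference base — with
probability about M/3. Assuming conservatively that every spurious alignment
carries the maximum allowed number of mismatches, the counts are corrected as

    N'_T = N_T - N_S * M / (3 - M)
    N'_S = N_S / (1 - M / 3)

and the spurious proportion reported as N'_S / (N'_S + N'_T). The correction
conserves the total count exactly and always shifts mass toward spurious.

M derives from the aligner's maximum-edit-distance rule: with a per-base
error rate of 0.02, the maximum mismatches m(l) at read length l is the
smallest k whose Poisson upper tail falls below 0.01 — about 10% of the read
length at the dominant ultra-short lengths (m=2 at 20 bp, m=3 at 30 bp).

Length cutoffs L_tau are the smallest read lengths at which the cumulative
corrected fraction among all retained reads of that length or longer drops
below tau (1% and 10% by convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .aln_classify import AlnClass

logger = logging.getLogger(__name__)

FILTERS = ("none", "indel", "deam", "deam+indel")


@dataclass(frozen=True)
class MaxDiffRule:
    """The aligner's Poisson-tail maximum-edit-distance rule.

    ``error`` is the assumed per-base error rate and ``threshold`` the tail
    probability below which a mismatch count is deemed implausible (the bwa
    ``-n 0.01`` convention with the 0.02 error model).
    """

    error: float = 0.02
    threshold: float = 0.01

    def m(self, length: int) -> int:
        return max_mismatches(length, self.error, self.threshold)

    def M(self, length: int) -> float:
        return self.m(length) / length


DEFAULT_RULE = MaxDiffRule()


@lru_cache(maxsize=4096)
def max_mismatches(length: int, error: float = 0.02, threshold: float = 0.01) -> int:
    """Smallest k with P(X > k) < threshold for X ~ Poisson(error * length).

    Computed by exact cumulative summation of Poisson terms.
    """
    if length < 1:
        raise ValueError("read length must be >= 1")
    lam = error * length
    term = math.exp(-lam)
    cdf = term
    k = 0
    while 1.0 - cdf >= threshold:
        k += 1
        term *= lam / k
        cdf += term
    return k


def expected_match_probs(M: float) -> tuple[float, float]:
    """(P(spurious read shows mutated state), P(it shows one given other base)).

    At a maximum mismatch proportion M, a chance alignment matches the
    mutated reference state with probability 1 - M and each of the three
    remaining states with probability M/3.
    """
    if not 0 <= M < 1:
        raise ValueError("M must be in [0, 1)")
    return 1.0 - M, M / 3.0


def correct_counts(
    n_true: float, n_spur: float, M: float, clamp: bool = True
) -> tuple[float, float]:
    """Misclassification-corrected (N'_T, N'_S).

    Pre-clamping the correction conserves N_T + N_S exactly; heavy
    contamination can push N'_T below zero, in which case it is clamped
    (with a logged warning) so the downstream fraction stays in [0, 1].
    """
    if n_true < 0 or n_spur < 0:
        raise ValueError("counts must be non-negative")
    if not 0 <= M < 1:
        raise ValueError("M must be in [0, 1)")
    n_true_c = n_true - n_spur * M / (3.0 - M)
    n_spur_c = n_spur / (1.0 - M / 3.0)
    if clamp and n_true_c < 0:
        logger.warning(
            "corrected true count negative (%.3f); clamped to 0", n_true_c
        )
        n_true_c = 0.0
    return n_true_c, n_spur_c


def spurious_fraction(
    n_true: float, n_spur: float, M: float, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Corrected spurious proportion with a Wilson binomial CI.

    The interval is evaluated at the effective sample size N_T + N_S.
    Undefined (NaN) when no alignments were observed.
    """
    n = n_true + n_spur
    if n == 0:
        return float("nan"), (float("nan"), float("nan"))
    n_true_c, n_spur_c = correct_counts(n_true, n_spur, M)
    frac = min(1.0, n_spur_c / (n_spur_c + n_true_c)) if (n_spur_c + n_true_c) > 0 else float("nan")
    lo, hi = proportion_confint(frac * n, n, alpha=alpha, method="wilson")
    return frac, (float(lo), float(hi))


def apply_filters(classified: pd.DataFrame, filters: str = "none") -> pd.DataFrame:
    """Subset a classified-alignment table by the standard filter combinations.

    ``indel`` drops alignments with any indel event; ``deam`` keeps only
    alignments with a terminal C-to-T at either end; ``deam+indel`` both.
    """
    if filters not in FILTERS:
        raise ValueError(f"unknown filter set {filters!r}; expected one of {FILTERS}")
    df = classified
    if "indel" in filters:
        df = df[df["indels"] == 0]
    if "deam" in filters:
        df = df[df["ct5"] | df["ct3"]]
    return df


def _counts_by_length(classified: pd.DataFrame) -> pd.DataFrame:
    """Per 1-bp length bin: n_true, n_spur (other classes ignored)."""
    df = classified[classified["class"].isin([AlnClass.TRUE_HOMININ.value, AlnClass.SPURIOUS.value])]
    if df.empty:
        return pd.DataFrame(columns=["len", "n_true", "n_spur"]).astype(int)
    tab = (
        df.groupby(["len", "class"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=[AlnClass.TRUE_HOMININ.value, AlnClass.SPURIOUS.value], fill_value=0)
        .rename(columns={AlnClass.TRUE_HOMININ.value: "n_true", AlnClass.SPURIOUS.value: "n_spur"})
        .reset_index()
    )
    return tab


def fraction_by_length(
    classified: pd.DataFrame,
    filters: str = "none",
    rule: MaxDiffRule = DEFAULT_RULE,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-length-bin corrected spurious-fraction estimates.

    Bins are single-bp read lengths; each bin is corrected with M(l) of its
    own length. Returns columns len, filter, n_true, n_spur, M, n_true_corr,
    n_spur_corr, frac, ci_lo, ci_hi. Empty bins are absent.
    """
    tab = _counts_by_length(apply_filters(classified, filters))
    rows = []
    for r in tab.itertuples(index=False):
        M = rule.M(int(r.len))
        nt_c, ns_c = correct_counts(r.n_true, r.n_spur, M)
        frac, (lo, hi) = spurious_fraction(r.n_true, r.n_spur, M, alpha=alpha)
        rows.append((int(r.len), filters, int(r.n_true), int(r.n_spur), M, nt_c, ns_c, frac, lo, hi))
    return pd.DataFrame(
        rows,
        columns=["len", "filter", "n_true", "n_spur", "M", "n_true_corr", "n_spur_corr", "frac", "ci_lo", "ci_hi"],
    )


def cumulative_fraction(
    classified: pd.DataFrame,
    filters: str = "none",
    min_len: int = 20,
    rule: MaxDiffRule = DEFAULT_RULE,
) -> pd.DataFrame:
    """Cumulative corrected spurious fraction for each candidate cutoff L.

    For each L, all alignments of length >= L are corrected per 1-bp length
    stratum (each with its own M), the corrected counts summed, and the
    pooled fraction formed. Returns columns L, n, frac.
    """
    tab = _counts_by_length(apply_filters(classified, filters))
    tab = tab[tab["len"] >= min_len]
    if tab.empty:
        return pd.DataFrame(columns=["L", "n", "frac"])
    lengths = tab["len"].to_numpy()
    Ms = np.array([rule.M(int(l)) for l in lengths])
    nt = tab["n_true"].to_numpy(dtype=float)
    ns = tab["n_spur"].to_numpy(dtype=float)
    nt_c = nt - ns * Ms / (3.0 - Ms)
    ns_c = ns / (1.0 - Ms / 3.0)
    rows = []
    for L in range(min_len, int(lengths.max()) + 1):
        sel = lengths >= L
        n = nt[sel].sum() + ns[sel].sum()
        if n == 0:
            continue
        total_c = nt_c[sel].sum() + ns_c[sel].sum()
        frac = float(np.clip(ns_c[sel].sum() / total_c, 0.0, 1.0)) if total_c > 0 else float("nan")
        rows.append((L, int(n), frac))
    return pd.DataFrame(rows, columns=["L", "n", "frac"])


@dataclass
class CutoffResult:
    """A sample-specific length cutoff and its data-yield consequences."""

    tau: float
    filters: str
    L: int | None  # None: the curve never drops below tau ("not reached")
    bases_at_cutoff: int | None
    bases_at_baseline: int
    fold: float | None

    def to_dict(self) -> dict:
        return {
            "filter": self.filters,
            "tau": self.tau,
            "L": self.L,
            "bases_L": self.bases_at_cutoff,
            "bases_35": self.bases_at_baseline,
            "fold": self.fold,
        }


def usable_bases(classified: pd.DataFrame, cutoff: int, filters: str = "none") -> int:
    """Total bases in true-classified, filter-passing alignments of length >= cutoff."""
    df = apply_filters(classified, filters)
    df = df[(df["class"] == AlnClass.TRUE_HOMININ.value) & (df["len"] >= cutoff)]
    return int(df["len"].sum())


def usable_bases_fold_change(
    classified: pd.DataFrame, cutoff: int, filters: str = "none", baseline: int = 35
) -> tuple[int, int, float | None]:
    """(bases at cutoff, bases at baseline, fold change) for true alignments."""
    at_cut = usable_bases(classified, cutoff, filters)
    at_base = usable_bases(classified, baseline, filters)
    fold = at_cut / at_base if at_base > 0 else None
    return at_cut, at_base, fold


def find_length_cutoff(
    classified: pd.DataFrame,
    filters: str = "deam+indel",
    tau: float = 0.01,
    min_len: int = 20,
    baseline: int = 35,
    rule: MaxDiffRule = DEFAULT_RULE,
) -> CutoffResult:
    """Smallest length cutoff whose cumulative corrected fraction is below tau.

    When no cutoff qualifies the limit is reported as not reached (L=None).
    """
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    curve = cumulative_fraction(classified, filters, min_len=min_len, rule=rule)
    at_base = usable_bases(classified, baseline, filters)
    if curve.empty:
        return CutoffResult(tau, filters, None, None, at_base, None)
    ok = curve[curve["frac"] < tau]
    if ok.empty:
        return CutoffResult(tau, filters, None, None, at_base, None)
    L = int(ok["L"].iloc[0])
    at_cut = usable_bases(classified, L, filters)
    fold = at_cut / at_base if at_base > 0 else None
    return CutoffResult(tau, filters, L, at_cut, at_base, fold)
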