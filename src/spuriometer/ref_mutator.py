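"""Inject composition-preserving single-base changes into a reference genome.

Artificial mutations at regularly spaced, well-behaved positions turn the
reference into a bait: a read genuinely derived from the reference lineage
should carry the original base at a changed site, whereas a read that aligns
only by chance matches the mutated state with high probability. Site
selection walks a fixed grid (one candidate every ``spacing`` bp), relocating
candidates that fall into excluded regions to the nearest included base, and
dropping relocations that would come closer than ``min_adjacent`` bp to a
neighbouring site.

Two replacement schemes are offered. ``batch`` permutes the multiset of
original bases across all sites with no fixed points, so the mutated genome
has exactly the same base counts as the input. ``matrix`` fits a zero-diagonal
replacement-probability matrix whose stationary flow preserves the expected
composition, via iterative proportional fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import ExclusionTrack, MutatedSite, MutatedSiteTable, ReferenceGenome

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def select_sites(
    genome: ReferenceGenome,
    exclusions: ExclusionTrack | None = None,
    spacing: int = 100,
    min_adjacent: int = 75,
) -> dict[str, list[int]]:
    """Pick mutation positions on a per-sequence grid.

    Grid candidates sit at 0-based offsets ``spacing-1, 2*spacing-1, ...``
    (i.e. every ``spacing`` bp counted from the sequence start). A candidate
    inside an excluded region (or on an N) is relocated to the nearest
    included position — ties broken leftward — and kept only if that position
    lies at least ``min_adjacent`` bp from both the previously accepted site
    and the next grid candidate; otherwise the site is dropped.
    """
    if not spacing > min_adjacent > 0:
        raise ValueError("require spacing > min_adjacent > 0")
    exclusions = exclusions or ExclusionTrack()
    result: dict[str, list[int]] = {}
    for name, seq in genome.sequences.items():
        length = len(seq)
        excluded = exclusions.mask(name, length)
        excluded |= np.frombuffer(seq.encode(), dtype=np.uint8) == ord("N")
        included_idx = np.flatnonzero(~excluded)
        accepted: list[int] = []
        for grid in range(spacing - 1, length, spacing):
            next_grid = grid + spacing if grid + spacing < length else None
            if not excluded[grid]:
                accepted.append(grid)
                continue
            pos = _nearest_included(included_idx, grid)
            if pos is None:
                continue
            if accepted and pos - accepted[-1] < min_adjacent:
                continue
            if next_grid is not None and abs(next_grid - pos) < min_adjacent:
                continue
            accepted.append(pos)
        result[name] = accepted
    return result


def _nearest_included(included_idx: np.ndarray, pos: int) -> int | None:
    """Nearest value in sorted included_idx to pos; leftward on ties."""
    if included_idx.size == 0:
        return None
    i = int(np.searchsorted(included_idx, pos))
    left = included_idx[i - 1] if i > 0 else None
    right = included_idx[i] if i < included_idx.size else None
    if left is None:
        return int(right)
    if right is None:
        return int(left)
    # leftward tie-break keeps the procedure deterministic
    if pos - left <= right - pos:
        return int(left)
    return int(right)


@dataclass
class ReplacementScheme:
    """How original bases at selected sites become mutated bases.

    ``batch`` assigns a fixed-point-free permutation of the original-base
    multiset (exact composition preservation). ``matrix`` holds a 4x4
    zero-diagonal row-stochastic matrix Q whose flow balances the genome
    composition f: sum_b f(b) Q(b->.) = f.
    """

    mode: str
    composition: dict[str, float] | None = None
    matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("batch", "matrix"):
            raise ValueError(f"unknown replacement mode {self.mode!r}")
        if self.mode == "matrix":
            if self.matrix is None or self.composition is None:
                raise ValueError("matrix mode requires matrix and composition")
            q = self.matrix
            if q.shape != (4, 4) or not np.allclose(np.diag(q), 0):
                raise ValueError("replacement matrix must be 4x4 with zero diagonal")
            if not np.allclose(q.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("replacement matrix rows must sum to 1")
            f = np.array([self.composition[b] for b in BASES])
            if np.max(np.abs(f @ q - f)) >= 1e-9:
                raise ValueError("replacement matrix violates flow balance")


def build_replacement_scheme(
    composition: dict[str, float], mode: str = "batch", tol: float = 1e-12, max_iter: int = 10_000
) -> ReplacementScheme:
    """Construct a composition-preserving replacement scheme.

    Matrix mode solves for a zero-diagonal flow matrix F with both row and
    column sums equal to the composition f by iterative proportional fitting,
    then row-normalizes F into the replacement probabilities Q.
    """
    f = np.array([composition.get(b, 0.0) for b in BASES], dtype=float)
    if not np.isclose(f.sum(), 1.0, atol=1e-6):
        raise ValueError("composition must sum to 1")
    if mode == "batch":
        return ReplacementScheme(mode="batch", composition=dict(composition))
    if mode != "matrix":
        raise ValueError(f"unknown replacement mode {mode!r}")
    if np.any(f <= 0):
        raise ValueError("matrix mode requires strictly positive base frequencies")
    F = np.outer(f, f)
    np.fill_diagonal(F, 0.0)
    for _ in range(max_iter):
        F *= (f / F.sum(axis=1))[:, None]
        F *= f / F.sum(axis=0)
        if np.max(np.abs(F.sum(axis=1) - f)) < tol:
            break
    Q = F / F.sum(axis=1, keepdims=True)
    return ReplacementScheme(mode="matrix", composition=dict(composition), matrix=Q)


def _derange_multiset(bases: list[str], rng: np.random.Generator, max_tries: int = 10_000) -> list[str]:
    """Permute a base multiset so no position keeps its original value.

    Shuffle-and-repair: after a shuffle, each fixed point is swapped with a
    position that resolves it without creating a new one. Raises if the
    multiset admits no such assignment (e.g. one base in the strict majority).
    """
    arr = np.array(bases)
    n = arr.size
    counts = {b: int((arr == b).sum()) for b in set(bases)}
    if max(counts.values()) > n - max(counts.values()):
        raise ValueError("multiset has a majority base; fixed-point-free permutation impossible")
    for _ in range(max_tries):
        perm = rng.permutation(n)
        out = arr[perm]
        fixed = np.flatnonzero(out == arr)
        ok = True
        for i in fixed:
            if out[i] != arr[i]:
                continue  # already repaired by an earlier swap
            candidates = np.flatnonzero((out != arr[i]) & (arr != out[i]))
            candidates = candidates[candidates != i]
            if candidates.size == 0:
                ok = False
                break
            j = int(rng.choice(candidates))
            out[i], out[j] = out[j], out[i]
        if ok and not np.any(out == arr):
            return out.tolist()
    raise RuntimeError("failed to build a fixed-point-free permutation")


def mutate_reference(
    genome: ReferenceGenome,
    sites: dict[str, list[int]],
    scheme: ReplacementScheme,
    seed: int | np.random.Generator = 0,
) -> tuple[ReferenceGenome, MutatedSiteTable]:
    """Apply the replacement scheme at the selected sites.

    Returns the mutated genome and the site table; applying the table in
    reverse (alt -> ref) restores the input exactly. Sites landing on N are
    skipped with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records: list[tuple[str, int, str]] = []  # (chrom, pos, original)
    for name in genome.sequences:
        for pos in sites.get(name, ()):
            base = genome.sequences[name][pos]
            if base == "N":
                warnings.warn(f"site {name}:{pos} is N; skipped", stacklevel=2)
                continue
            records.append((name, pos, base))

    originals = [b for _, _, b in records]
    if scheme.mode == "batch":
        if not originals:
            mutated = []
        else:
            try:
                mutated = _derange_multiset(originals, rng)
            except ValueError:
                # too few / too skewed sites for an exact permutation
                warnings.warn(
                    "site base multiset admits no fixed-point-free permutation; "
                    "falling back to uniform replacement (composition not preserved)",
                    stacklevel=2,
                )
                mutated = [
                    [b for b in BASES if b != orig][int(rng.integers(0, 3))]
                    for orig in originals
                ]
    else:
        mutated = []
        for b in originals:
            row = scheme.matrix[_BASE_INDEX[b]]
            mutated.append(BASES[rng.choice(4, p=row)])

    new_seqs = {name: bytearray(seq.encode()) for name, seq in genome.sequences.items()}
    table_records: list[MutatedSite] = []
    for (name, pos, ref), alt in zip(records, mutated):
        new_seqs[name][pos] = ord(alt)
        table_records.append(MutatedSite(name, pos, ref, alt))
    out = ReferenceGenome({name: bytes(s).decode() for name, s in new_seqs.items()})
    return out, MutatedSiteTable(table_records)


def revert_reference(genome: ReferenceGenome, table: MutatedSiteTable) -> ReferenceGenome:
    """Undo the artificial mutations (alt -> ref), recovering the input genome."""
    seqs = {name: bytearray(seq.encode()) for name, seq in genome.sequences.items()}
    for site in table:
        if seqs[site.chrom][site.pos0] != ord(site.alt):
            raise ValueError(f"{site.chrom}:{site.pos0} does not carry the recorded mutated base")
        seqs[site.chrom][site.pos0] = ord(site.ref)
    return ReferenceGenome({name: bytes(s).decode() for name, s in seqs.items()})
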