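"""Kane's contiguous-match (C15) filter and the GC-content filter.

An oligo cross-hybridizes if it shares a long perfect stretch with a
non-target (the classical rule of thumb: 15 or more contiguous matches), or
if its overall identity with a non-target window is too high (handled by
:mod:`bond.similarity`).  The GC filter keeps hybridization behaviour uniform
across the array.

"Occurs elsewhere" is interpreted as *occurs in a different gene* (forward or
reverse-complement): repeats confined to the target itself are not
cross-hybridization.  Both filters are idempotent and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kmers import contiguous_keys, revcomp_key
from .sequence_store import EncodedSequenceSet, ValidityMask

__all__ = ["FilterParams", "c15_filter", "gc_filter", "build_kmer_gene_map",
           "foreign_kmer_starts", "window_has_foreign_kmer"]


@dataclass(frozen=True)
class FilterParams:
    """Design parameters of a run.

    ``max_consec`` is the longest *allowed* contiguous match with a
    non-target; the eliminating stretch length is ``max_consec + 1`` (15 by
    default).  ``identity_threshold`` is the *bad* threshold: a window with
    ``ceil(identity_threshold * L)`` or more matching bases against a
    non-target window disqualifies the candidate.
    """

    L: int = 50
    max_consec: int = 14
    gc_min: float = 0.30
    gc_max: float = 0.70
    identity_threshold: float = 0.75
    check_revcomp: bool = True
    end_preference: str | None = None  # None | "3" | "5"

    def __post_init__(self) -> None:
        if not (0.0 < self.gc_min <= self.gc_max < 1.0):
            raise ValueError(f"need 0 < gc_min <= gc_max < 1, got {self.gc_min}, {self.gc_max}")
        if self.max_consec < 1:
            raise ValueError("max_consec must be >= 1")
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError("identity_threshold must lie in (0, 1]")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.end_preference not in (None, "3", "5"):
            raise ValueError("end_preference must be None, '3' or '5'")

    @property
    def kane_k(self) -> int:
        """Length of a disqualifying contiguous match (C15 stretch)."""
        return self.max_consec + 1

    @property
    def bad_matches(self) -> int:
        """Minimum matching bases making an L-window pair 'bad' (38 for 50/0.75)."""
        import math

        return math.ceil(self.identity_threshold * self.L)


def build_kmer_gene_map(seqs: EncodedSequenceSet, k: int) -> dict[int, set[int]]:
    """Map each contiguous k-mer key to the set of genes containing it (forward)."""
    occurs: dict[int, set[int]] = {}
    for g, (codes, amb) in enumerate(zip(seqs.codes, seqs.ambiguous)):
        _, keys = contiguous_keys(codes, amb, k)
        for key in np.unique(keys):
            occurs.setdefault(int(key), set()).add(g)
    return occurs


def foreign_kmer_starts(
    seqs: EncodedSequenceSet,
    gene: int,
    occurs: dict[int, set[int]],
    k: int,
    check_revcomp: bool,
) -> np.ndarray:
    """Start positions in ``gene`` of k-mers that also occur in another gene."""
    starts, keys = contiguous_keys(seqs.codes[gene], seqs.ambiguous[gene], k)
    bad = np.zeros(len(starts), dtype=bool)
    for i, key in enumerate(keys):
        genes = occurs.get(int(key), ())
        if any(g != gene for g in genes):
            bad[i] = True
            continue
        if check_revcomp:
            rc = occurs.get(revcomp_key(int(key), k), ())
            if any(g != gene for g in rc):
                bad[i] = True
    return starts[bad]


def window_has_foreign_kmer(
    seqs: EncodedSequenceSet,
    gene: int,
    start: int,
    occurs: dict[int, set[int]],
    params: FilterParams,
) -> bool:
    """Does the L-window at ``start`` contain a k-mer shared with another gene?"""
    k = params.kane_k
    bad = foreign_kmer_starts(seqs, gene, occurs, k, params.check_revcomp)
    if len(bad) == 0:
        return False
    return bool(((bad >= start) & (bad <= start + params.L - k)).any())


def window_covers_any(bad_starts, start: int, L: int, k: int) -> bool:
    """Does the L-window at ``start`` contain any of the given k-mer starts?"""
    return bool(((bad_starts >= start) & (bad_starts <= start + L - k)).any())


def c15_filter(
    seqs: EncodedSequenceSet,
    mask: ValidityMask,
    params: FilterParams,
    occurs: dict[int, set[int]] | None = None,
) -> int:
    """Eliminate L-mers containing a (max_consec+1)-mer that occurs in another gene.

    Hash-based: every k-mer key maps to the genes carrying it; no text index
    is needed because only elimination is performed.  Returns the number of
    newly eliminated starts.
    """
    k = params.kane_k
    if occurs is None:
        occurs = build_kmer_gene_map(seqs, k)
    L = params.L
    eliminated = 0
    for g in range(len(seqs)):
        n_starts = len(mask.eliminated[g])
        if n_starts == 0:
            continue
        bad = foreign_kmer_starts(seqs, g, occurs, k, params.check_revcomp)
        if len(bad) == 0:
            continue
        # L-window [s, s+L) contains k-mer start t iff s in [t-L+k, t]
        cover = np.zeros(n_starts + 1, dtype=np.int64)
        lo = np.maximum(bad - L + k, 0)
        hi = np.minimum(bad, n_starts - 1)
        keep = lo <= hi
        np.add.at(cover, lo[keep], 1)
        np.add.at(cover, hi[keep] + 1, -1)
        covered = np.cumsum(cover[:-1]) > 0
        eliminated += mask.eliminate(g, np.flatnonzero(covered))
    return eliminated


def gc_filter(seqs: EncodedSequenceSet, mask: ValidityMask, params: FilterParams) -> int:
    """Eliminate L-mers whose GC fraction falls outside [gc_min, gc_max] (inclusive).

    Returns the number of newly eliminated starts.
    """
    L = params.L
    eliminated = 0
    for g, codes in enumerate(seqs.codes):
        n_starts = len(mask.eliminated[g])
        if n_starts == 0:
            continue
        gc = (codes == 1) | (codes == 2)
        csum = np.concatenate([[0], np.cumsum(gc.astype(np.int64))])
        frac = (csum[L:] - csum[:-L]) / L
        bad = (frac < params.gc_min - 1e-12) | (frac > params.gc_max + 1e-12)
        eliminated += mask.eliminate(g, np.flatnonzero(bad))
    return eliminated
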