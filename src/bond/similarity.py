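"""Spaced-seed similarity search: the identity (C75) machinery.

Uniqueness of an oligo is decided in two phases.  Phase I screens the whole
input with the heavier ``w10s8`` seed set, examining only *consecutive* pairs
of positions within each hash bucket — linear in total bucket size — and
eliminating every L-mer start that an anchored window slide proves to be
within ``identity_threshold`` of a window in another gene.  Phase II takes one
candidate at a time (the midpoint of the longest surviving run) and spends the
full power of the more sensitive ``w9s8`` set on it: every seed placement
inside the candidate is looked up against the complete index and every
cross-gene partner is verified at the candidate's own alignment.

Same-gene similarities are never counted: cross-hybridization is by
definition against non-targets.  Reverse-complement similarity is checked by
indexing the reverse-complement view of the input alongside the forward view
(disable with ``check_revcomp=False``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kmers import spaced_keys
from .filters import FilterParams, foreign_kmer_starts, window_covers_any
from .sequence_store import EncodedSequenceSet, ValidityMask, reverse_complement_view
from .seeds import SeedSet, SpacedSeed

__all__ = [
    "SpacedKmerIndex",
    "Witness",
    "build_index",
    "verify_anchor",
    "phase1_eliminate",
    "Phase2Verifier",
    "pick_candidate",
]

FORWARD, REVCOMP = 0, 1


@dataclass(frozen=True)
class Witness:
    """Evidence that a window is non-unique: its best offending partner."""

    gene: int
    start: int          # forward-strand start of the offending window
    strand: int         # FORWARD or REVCOMP
    matches: int
    kind: str = "identity"  # "identity" (C75) or "contiguous" (C15)


class SpacedKmerIndex:
    """Hash index of one spaced seed over the input (and optionally its RC view).

    Spaced w-mer keys (2 bits per match position, <= 64 bits) map to the
    positions extracting them.  Entries are sorted by (key, strand, gene ID,
    position) — gene *ID*, not input order, so that bucket adjacency (and with
    it the whole screening phase) is invariant under permutations of the input
    records.  Bucket position lists are ascending within each (strand, gene).
    """

    def __init__(self, seed: SpacedSeed, stores: list[EncodedSequenceSet]):
        self.seed = seed
        self.stores = stores
        span = seed.length
        offs = seed.match_offsets
        id_rank = np.empty(len(stores[0].ids), dtype=np.int64)
        id_rank[np.argsort(np.array(stores[0].ids))] = np.arange(len(stores[0].ids))
        keys_parts, gene_parts, pos_parts, strand_parts = [], [], [], []
        for strand, store in enumerate(stores):
            for g, (codes, amb) in enumerate(zip(store.codes, store.ambiguous)):
                starts, keys = spaced_keys(codes, amb, offs, span)
                if len(starts) == 0:
                    continue
                keys_parts.append(keys)
                gene_parts.append(np.full(len(starts), g, dtype=np.int32))
                pos_parts.append(starts)
                strand_parts.append(np.full(len(starts), strand, dtype=np.int8))
        if keys_parts:
            keys = np.concatenate(keys_parts)
            gene = np.concatenate(gene_parts)
            pos = np.concatenate(pos_parts)
            strand = np.concatenate(strand_parts)
            order = np.lexsort((pos, id_rank[gene], strand, keys))
            self.keys = keys[order]
            self.gene = gene[order]
            self.pos = pos[order]
            self.strand = strand[order]
        else:
            self.keys = np.zeros(0, dtype=np.uint64)
            self.gene = np.zeros(0, dtype=np.int32)
            self.pos = np.zeros(0, dtype=np.int64)
            self.strand = np.zeros(0, dtype=np.int8)
        self.unique_keys, first = np.unique(self.keys, return_index=True)
        self.bucket_lo = first
        self.bucket_hi = np.append(first[1:], len(self.keys))

    def __len__(self) -> int:
        return len(self.keys)

    def n_buckets(self) -> int:
        return len(self.unique_keys)

    def lookup_many(self, query_keys: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Bucket slices for an array of keys: (found mask, lo, hi)."""
        idx = np.searchsorted(self.unique_keys, query_keys)
        idx = np.minimum(idx, max(len(self.unique_keys) - 1, 0))
        if len(self.unique_keys) == 0:
            found = np.zeros(len(query_keys), dtype=bool)
            return found, idx, idx
        found = self.unique_keys[idx] == query_keys
        return found, self.bucket_lo[idx], self.bucket_hi[idx]


def build_index(seqs: EncodedSequenceSet, seed: SpacedSeed) -> SpacedKmerIndex:
    """Index one seed over the forward view only (building block / testing surface)."""
    return SpacedKmerIndex(seed, [seqs])


def verify_anchor(
    store_a: EncodedSequenceSet,
    ga: int,
    ia: int,
    store_b: EncodedSequenceSet,
    gb: int,
    ib: int,
    span: int,
    params: FilterParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slide an L-window jointly over both sequences across every offset covering the hit.

    The hit at (ga, ia) / (gb, ib) fixes the relative alignment.  Returns the
    window start pairs (in the coordinates of the respective stores) whose
    match count reaches the bad threshold, with their counts.  Counts are
    maintained incrementally: the base-equality vector along the diagonal is
    computed once and window sums come from its cumulative sum.
    """
    L, T = params.L, params.bad_matches
    na = len(store_a.codes[ga])
    nb = len(store_b.codes[gb])
    lo_a = max(0, ia + span - L, ia - ib)
    hi_a = min(ia, na - L, ia + (nb - L - ib))
    if lo_a > hi_a:
        empty = np.zeros(0, dtype=np.int64)
        return empty, empty, empty
    d = ia - ib  # diagonal: sb = sa - d
    seg_lo_a, seg_hi_a = lo_a, hi_a + L
    a = store_a.codes[ga][seg_lo_a:seg_hi_a]
    b = store_b.codes[gb][seg_lo_a - d : seg_hi_a - d]
    eq = (a == b) & ~(
        store_a.ambiguous[ga][seg_lo_a:seg_hi_a]
        | store_b.ambiguous[gb][seg_lo_a - d : seg_hi_a - d]
    )
    csum = np.concatenate([[0], np.cumsum(eq.astype(np.int64))])
    counts = csum[L:] - csum[:-L]
    sa = np.arange(lo_a, hi_a + 1, dtype=np.int64)
    counts = counts[: len(sa)]
    bad = counts >= T
    return sa[bad], sa[bad] - d, counts[bad]


def _to_forward_start(store: EncodedSequenceSet, gene: int, start: int, L: int) -> int:
    """Map a window start in a (possibly reverse-complement) view to forward coordinates."""
    if not store.is_revcomp:
        return start
    return len(store.codes[gene]) - start - L


def phase1_eliminate(
    seqs: EncodedSequenceSet,
    mask: ValidityMask,
    screen_seeds: SeedSet,
    params: FilterParams,
    rc: EncodedSequenceSet | None = None,
) -> int:
    """Bulk repeat screening: adjacent hash-bucket pairs, anchored verification.

    For every seed, only *consecutive* entries of each sorted bucket are
    examined (the screen stays linear in total bucket size).  Every cross-gene
    pair is anchor-verified and all window starts proven non-unique are
    eliminated in both genes.  Returns the number of newly eliminated starts.
    """
    stores = [seqs]
    if params.check_revcomp:
        stores.append(rc if rc is not None else reverse_complement_view(seqs))
    L = params.L
    eliminated = 0
    for seed in screen_seeds:
        index = SpacedKmerIndex(seed, stores)
        if len(index) < 2:
            continue
        same_bucket = index.keys[1:] == index.keys[:-1]
        cross_gene = index.gene[1:] != index.gene[:-1]
        both_rc = (index.strand[1:] == REVCOMP) & (index.strand[:-1] == REVCOMP)
        for i in np.flatnonzero(same_bucket & cross_gene & ~both_rc):
            sa_store = stores[index.strand[i]]
            sb_store = stores[index.strand[i + 1]]
            ga, ia = int(index.gene[i]), int(index.pos[i])
            gb, ib = int(index.gene[i + 1]), int(index.pos[i + 1])
            sa, sb, _ = verify_anchor(sa_store, ga, ia, sb_store, gb, ib, seed.length, params)
            if len(sa) == 0:
                continue
            fa = [_to_forward_start(sa_store, ga, int(s), L) for s in sa]
            fb = [_to_forward_start(sb_store, gb, int(s), L) for s in sb]
            eliminated += mask.eliminate(ga, fa)
            eliminated += mask.eliminate(gb, fb)
    return eliminated


class Phase2Verifier:
    """Per-candidate verification with the full power of a sensitive seed set.

    Holds the complete indexes of every verification seed over the forward
    (and reverse-complement) views, plus the shared k-mer gene map for the
    contiguous-match re-check.  Per-gene spaced-key arrays are cached so the
    candidate loop touches each gene's keys once.
    """

    def __init__(
        self,
        seqs: EncodedSequenceSet,
        verify_seeds: SeedSet,
        params: FilterParams,
        kmer_gene_map: dict[int, set[int]],
        rc: EncodedSequenceSet | None = None,
    ):
        self.seqs = seqs
        self.params = params
        self.seeds = verify_seeds
        self.kmer_gene_map = kmer_gene_map
        self.stores = [seqs]
        if params.check_revcomp:
            self.stores.append(rc if rc is not None else reverse_complement_view(seqs))
        self.indexes = [SpacedKmerIndex(seed, self.stores) for seed in verify_seeds]
        self._key_cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        self._foreign_cache: dict[int, np.ndarray] = {}

    def _foreign_starts(self, gene: int) -> np.ndarray:
        bad = self._foreign_cache.get(gene)
        if bad is None:
            bad = foreign_kmer_starts(
                self.seqs, gene, self.kmer_gene_map,
                self.params.kane_k, self.params.check_revcomp,
            )
            self._foreign_cache[gene] = bad
        return bad

    def _gene_keys(self, seed_i: int, gene: int):
        ck = self._key_cache.get((seed_i, gene))
        if ck is None:
            seed = self.seeds.seeds[seed_i]
            ck = spaced_keys(
                self.seqs.codes[gene], self.seqs.ambiguous[gene],
                seed.match_offsets, seed.length,
            )
            self._key_cache[(seed_i, gene)] = ck
        return ck

    def verify(self, gene: int, start: int) -> Witness | None:
        """Return None if the candidate window is unique, else a witness.

        Every placement of every verification seed inside the window is looked
        up; each cross-gene partner fixes one alignment of the candidate
        window, which is checked exactly.  The contiguous-match condition is
        re-checked as well.
        """
        params = self.params
        L, T = params.L, params.bad_matches
        if window_covers_any(self._foreign_starts(gene), start, L, params.kane_k):
            return Witness(gene=-1, start=-1, strand=FORWARD, matches=params.kane_k,
                           kind="contiguous")
        cand_codes = self.seqs.codes[gene]
        for seed_i, index in enumerate(self.indexes):
            seed = self.seeds.seeds[seed_i]
            span = seed.length
            if span > L:
                continue
            starts, keys = self._gene_keys(seed_i, gene)
            sel = (starts >= start) & (starts <= start + L - span)
            if not sel.any():
                continue
            q_starts = starts[sel]
            found, lo, hi = index.lookup_many(keys[sel])
            for qi in np.flatnonzero(found):
                i = int(q_starts[qi])
                for e in range(int(lo[qi]), int(hi[qi])):
                    g2 = int(index.gene[e])
                    if g2 == gene:
                        continue
                    strand = int(index.strand[e])
                    store_b = self.stores[strand]
                    j = int(index.pos[e])
                    t = j - (i - start)
                    n2 = len(store_b.codes[g2])
                    if t < 0 or t > n2 - L:
                        continue
                    eq = (cand_codes[start : start + L] == store_b.codes[g2][t : t + L]) & ~(
                        self.seqs.ambiguous[gene][start : start + L]
                        | store_b.ambiguous[g2][t : t + L]
                    )
                    m = int(eq.sum())
                    if m >= T:
                        return Witness(
                            gene=g2,
                            start=_to_forward_start(store_b, g2, t, L),
                            strand=strand,
                            matches=m,
                        )
        return None


def pick_candidate(
    mask: ValidityMask, gene: int, end_preference: str | None = None
) -> int | None:
    """Midpoint of the longest run of valid starts; None if the gene is exhausted.

    Ties between equally long runs go to the leftmost run by default, to the
    rightmost with ``end_preference='3'`` (3'-most, reading genes 5'->3') and
    to the leftmost with ``end_preference='5'``.
    """
    arr = mask.eliminated[gene]
    if len(arr) == 0:
        return None
    valid = arr == 0
    if not valid.any():
        return None
    # run-length encode the validity array
    edges = np.flatnonzero(np.diff(np.concatenate([[0], valid.view(np.int8), [0]])))
    run_starts, run_ends = edges[::2], edges[1::2]
    run_lens = run_ends - run_starts
    best_len = run_lens.max()
    idx = np.flatnonzero(run_lens == best_len)
    chosen = idx[-1] if end_preference == "3" else idx[0]
    s = int(run_starts[chosen])
    return s + (int(best_len) - 1) // 2
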