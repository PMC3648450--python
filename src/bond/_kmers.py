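"""Internal helpers: integer keys for contiguous and spaced k-mers.

Keys pack one 2-bit code per (match) position, first position in the lowest
bits, so every key of weight w fits in 2w <= 64 bits.
"""

from __future__ import annotations

import numpy as np

from .sequence_store import EncodedSequenceSet


def contiguous_keys(codes: np.ndarray, ambiguous: np.ndarray, k: int):
    """(starts, keys) for every unambiguous k-window of one gene."""
    n = len(codes)
    if n < k:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.uint64)
    m = n - k + 1
    keys = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        keys |= codes[j : j + m].astype(np.uint64) << np.uint64(2 * j)
    csum = np.concatenate([[0], np.cumsum(ambiguous.astype(np.int64))])
    ok = (csum[k:] - csum[:-k]) == 0
    starts = np.flatnonzero(ok).astype(np.int64)
    return starts, keys[starts]


def spaced_keys(codes: np.ndarray, ambiguous: np.ndarray, match_offsets, span: int):
    """(starts, keys) for every placement of a spaced seed with an unambiguous span."""
    n = len(codes)
    if n < span:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.uint64)
    m = n - span + 1
    keys = np.zeros(m, dtype=np.uint64)
    for j, off in enumerate(match_offsets):
        keys |= codes[off : off + m].astype(np.uint64) << np.uint64(2 * j)
    csum = np.concatenate([[0], np.cumsum(ambiguous.astype(np.int64))])
    ok = (csum[span:] - csum[:-span]) == 0
    starts = np.flatnonzero(ok).astype(np.int64)
    return starts, keys[starts]


def revcomp_key(key: int, k: int) -> int:
    """Key of the reverse complement of a contiguous k-mer key."""
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (key & 3))
        key >>= 2
    return out


def all_contiguous_keys(seqs: EncodedSequenceSet, k: int):
    """Per-gene (starts, keys) lists over the whole set."""
    return [contiguous_keys(c, a, k) for c, a in zip(seqs.codes, seqs.ambiguous)]
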