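"""Encoded gene sequences: 2-bit packing, ambiguity tracking, window primitives.

All coordinates are 0-based half-open internally; an oligo candidate is the
window ``[start, start + L)`` of one gene.  Human-readable output uses 1-based
starts (stated in the output headers).

Bases are coded A=0, C=1, G=2, T=3 so that complementation is ``3 - code``.
Positions carrying any other IUPAC letter (N, R, Y, ...) are flagged in a
per-gene ambiguity mask and coded 0; every window primitive consults the mask
so an ambiguous position never counts as a match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

__all__ = [
    "EncodedSequenceSet",
    "ValidityMask",
    "FastaError",
    "read_fasta",
    "encode_sequences",
    "init_validity",
    "window_matches",
    "reverse_complement_view",
]

_CODE = np.full(256, -1, dtype=np.int16)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i
# RNA input: U reads as T
_CODE[ord("U")] = _CODE[ord("u")] = 3

_AMBIGUOUS = set("RYSWKMBDHVN")
_IUPAC = set("ACGTU") | _AMBIGUOUS

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


class FastaError(ValueError):
    """Raised for malformed FASTA input (empty, duplicate IDs, non-IUPAC letters)."""


@dataclass
class EncodedSequenceSet:
    """An ordered set of genes with 2-bit base codes and ambiguity masks.

    ``offsets[g]`` is the start of gene ``g`` in the concatenated global
    coordinate system (used by the spaced k-mer indexes); ``offsets[-1]`` is
    the total length.
    """

    ids: list[str]
    codes: list[np.ndarray]       # per gene, uint8 array of 2-bit codes
    ambiguous: list[np.ndarray]   # per gene, bool array, True = non-ACGT input
    is_revcomp: bool = False
    offsets: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        lengths = [len(c) for c in self.codes]
        self.offsets = np.concatenate([[0], np.cumsum(lengths)]).astype(np.int64)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def lengths(self) -> list[int]:
        return [len(c) for c in self.codes]

    @property
    def total_length(self) -> int:
        return int(self.offsets[-1])

    def sequence(self, gene: int, start: int = 0, end: int | None = None) -> str:
        """Decode a gene (or a slice of it) back to an ACGT/N string."""
        codes = self.codes[gene][start:end]
        amb = self.ambiguous[gene][start:end]
        out = _DECODE[codes].copy()
        out[amb] = ord("N")
        return out.tobytes().decode()

    def global_position(self, gene: int, pos: int) -> int:
        return int(self.offsets[gene]) + pos

    def locate(self, global_pos: np.ndarray | int) -> tuple[np.ndarray, np.ndarray]:
        """Map global positions back to (gene index, local position)."""
        gp = np.asarray(global_pos, dtype=np.int64)
        gene = np.searchsorted(self.offsets, gp, side="right") - 1
        return gene, gp - self.offsets[gene]


@dataclass
class ValidityMask:
    """Per-gene elimination state over L-mer start positions.

    ``0`` = still a valid candidate start, ``1`` = eliminated.  Pipeline steps
    only ever flip bits 0 -> 1 (monotone narrowing of the candidate set).
    """

    L: int
    eliminated: list[np.ndarray]  # per gene, uint8 array of length max(0, n-L+1)

    def valid_starts(self, gene: int) -> np.ndarray:
        return np.flatnonzero(self.eliminated[gene] == 0)

    def n_valid(self) -> int:
        return int(sum(int((e == 0).sum()) for e in self.eliminated))

    def eliminate(self, gene: int, starts: np.ndarray | Iterable[int]) -> int:
        """Mark starts eliminated; returns how many were newly eliminated."""
        arr = self.eliminated[gene]
        idx = np.asarray(list(starts) if not isinstance(starts, np.ndarray) else starts,
                         dtype=np.int64)
        idx = idx[(idx >= 0) & (idx < len(arr))]
        fresh = int((arr[idx] == 0).sum())
        arr[idx] = 1
        return fresh

    def eliminate_range(self, gene: int, lo: int, hi: int) -> int:
        """Eliminate starts in [lo, hi); returns newly eliminated count."""
        arr = self.eliminated[gene]
        lo = max(lo, 0)
        hi = min(hi, len(arr))
        if lo >= hi:
            return 0
        fresh = int((arr[lo:hi] == 0).sum())
        arr[lo:hi] = 1
        return fresh

    def copy(self) -> "ValidityMask":
        return ValidityMask(self.L, [e.copy() for e in self.eliminated])


def encode_sequences(records: Iterable[tuple[str, str]]) -> EncodedSequenceSet:
    """Encode (id, sequence) pairs; raises FastaError on invalid letters or IDs."""
    ids: list[str] = []
    codes: list[np.ndarray] = []
    ambiguous: list[np.ndarray] = []
    seen: set[str] = set()
    for rec_id, seq in records:
        if rec_id in seen:
            raise FastaError(f"duplicate record ID {rec_id!r}")
        seen.add(rec_id)
        raw = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        c = _CODE[raw]
        amb = c < 0
        if amb.any():
            letters = {chr(b) for b in raw[amb]}
            illegal = letters - _IUPAC
            if illegal:
                first = int(np.flatnonzero(amb)[0])
                raise FastaError(
                    f"record {rec_id!r}: non-IUPAC character(s) {sorted(illegal)!r} "
                    f"(first at position {first + 1})"
                )
        ids.append(rec_id)
        codes.append(np.where(amb, 0, c).astype(np.uint8))
        ambiguous.append(amb)
    if not ids:
        raise FastaError("no sequence records found")
    return EncodedSequenceSet(ids, codes, ambiguous)


def read_fasta(path: str | Path) -> EncodedSequenceSet:
    """Read a multi-record nucleotide FASTA into an encoded set."""
    path = Path(path)
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FastaError(f"{path}: empty or not FASTA")
    try:
        return encode_sequences(records)
    except FastaError as exc:
        raise FastaError(f"{path}: {exc}") from exc


def init_validity(seqs: EncodedSequenceSet, L: int) -> ValidityMask:
    """Start-position mask with every window containing an ambiguous base eliminated."""
    if L < 1:
        raise ValueError("oligo length L must be >= 1")
    eliminated = []
    for amb in seqs.ambiguous:
        n = len(amb)
        if n < L:
            eliminated.append(np.zeros(0, dtype=np.uint8))
            continue
        # window [s, s+L) contains an ambiguous base iff the windowed count > 0
        csum = np.concatenate([[0], np.cumsum(amb.astype(np.int64))])
        win = csum[L:] - csum[:-L]
        eliminated.append((win > 0).astype(np.uint8))
    return ValidityMask(L, eliminated)


# ---------------------------------------------------------------------------
# packed-window Hamming primitive

_SHIFTS = (2 * np.arange(32, dtype=np.uint64)).astype(np.uint64)
_LOW_BITS = np.uint64(0x5555555555555555)


def _pack_window(codes: np.ndarray, start: int, L: int) -> np.ndarray:
    """Pack L 2-bit codes into uint64 words, 32 bases per word, LSB first."""
    win = codes[start : start + L].astype(np.uint64)
    pad = (-len(win)) % 32
    if pad:
        win = np.concatenate([win, np.zeros(pad, dtype=np.uint64)])
    return (win.reshape(-1, 32) << _SHIFTS).sum(axis=1, dtype=np.uint64)


def window_matches(
    seqs_a: EncodedSequenceSet,
    g1: int,
    s1: int,
    seqs_b: EncodedSequenceSet | None,
    g2: int,
    s2: int,
    L: int,
) -> int:
    """Number of matching bases between two L-windows (packed XOR + popcount).

    ``seqs_b`` defaults to ``seqs_a``.  Ambiguous positions never match.
    """
    if seqs_b is None:
        seqs_b = seqs_a
    ca, cb = seqs_a.codes[g1], seqs_b.codes[g2]
    if not (0 <= s1 <= len(ca) - L) or not (0 <= s2 <= len(cb) - L):
        raise IndexError(
            f"window out of range: gene {g1}[{s1}:{s1+L}] vs gene {g2}[{s2}:{s2+L}]"
        )
    wa = _pack_window(ca, s1, L)
    wb = _pack_window(cb, s2, L)
    x = wa ^ wb
    mismatch_bits = (x | (x >> np.uint64(1))) & _LOW_BITS
    mismatches = int(np.bitwise_count(mismatch_bits).sum())
    matches = L - mismatches
    # ambiguous positions coded 0 can produce spurious equality; subtract them
    amb = seqs_a.ambiguous[g1][s1 : s1 + L] | seqs_b.ambiguous[g2][s2 : s2 + L]
    if amb.any():
        equal = ca[s1 : s1 + L] == cb[s2 : s2 + L]
        matches -= int((amb & equal).sum())
    return matches


def reverse_complement_view(seqs: EncodedSequenceSet) -> EncodedSequenceSet:
    """The reverse complement of every gene, ambiguity masks mirrored."""
    codes = [(3 - c[::-1]).astype(np.uint8) for c in seqs.codes]
    amb = [a[::-1].copy() for a in seqs.ambiguous]
    # complement of an ambiguous placeholder stays a placeholder (code 0)
    for c, a in zip(codes, amb):
        c[a] = 0
    return EncodedSequenceSet(list(seqs.ids), codes, amb, is_revcomp=not seqs.is_revcomp)
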