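"""Deterministic synthetic gene sets with planted, ground-truthed structure.

The generator emulates the one property of transcript sets that matters for
probe design — cross-gene similarity — while remaining fully controllable:
genes are i.i.d. with a configurable GC level, near-duplicate windows of
exact identity are planted between chosen gene pairs (forward or reverse
complement), and exact shared k-mers can be planted to exercise the
contiguous-match filter.  A planting of identity q and length n copies the
window and mutates exactly ``floor((1-q)*n)`` distinct positions, never back
to the original base, so the achieved identity is known, not sampled.

:func:`exhaustive_oracle` is the referee for every similarity decision in the
package: a naive all-windows scan (both strands) that returns, for every
L-start, the best cross-gene match count and its witness.  It shares no code
with the seed-based search it judges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .filters import FilterParams
from .sequence_store import EncodedSequenceSet, encode_sequences

__all__ = [
    "Planting",
    "SharedKmerPlanting",
    "FixtureSpec",
    "Fixture",
    "generate",
    "exhaustive_oracle",
    "exhaustive_good_starts",
    "exhaustive_max_coverage",
    "OracleResult",
]

ORACLE_MAX_TOTAL = 100_000  # bases; the oracle is quadratic


@dataclass(frozen=True)
class Planting:
    """Copy a window from one gene into another at a controlled identity."""

    source: int
    target: int
    length: int
    identity: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("planting identity must lie in [0, 1]")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.source == self.target:
            raise ValueError("planting must cross genes")


@dataclass(frozen=True)
class SharedKmerPlanting:
    """Plant ``count`` exact shared k-mers between a pair of genes."""

    gene_a: int
    gene_b: int
    count: int
    k: int = 15


@dataclass(frozen=True)
class FixtureSpec:
    n_genes: int
    gene_length: int
    gc: float = 0.5
    random_seed: int = 0
    plantings: tuple[Planting, ...] = ()
    shared_kmers: tuple[SharedKmerPlanting, ...] = ()

    def __post_init__(self) -> None:
        for p in self.plantings:
            if p.length > self.gene_length:
                raise ValueError("planted window longer than gene")
            if not (0 <= p.source < self.n_genes and 0 <= p.target < self.n_genes):
                raise ValueError("planting gene index out of range")


@dataclass
class PlantingRecord:
    source: int
    source_start: int
    target: int
    target_start: int
    length: int
    strand: str
    mutations: int
    achieved_identity: float


@dataclass
class Fixture:
    spec: FixtureSpec
    seqs: EncodedSequenceSet
    plantings: list[PlantingRecord]

    def fasta_text(self) -> str:
        lines = []
        for g, gid in enumerate(self.seqs.ids):
            lines.append(f">{gid}")
            lines.append(self.seqs.sequence(g))
        return "\n".join(lines) + "\n"

    def write(self, fasta_path: str | Path, manifest_path: str | Path | None = None,
              params: FilterParams | None = None) -> None:
        """Write the FASTA and, optionally, a ground-truth manifest TSV.

        The manifest lists every planted region (achieved identity included)
        and, when ``params`` is given, every L-start condemned by the
        exhaustive oracle at those parameters.
        """
        Path(fasta_path).write_text(self.fasta_text())
        if manifest_path is None:
            return
        lines = ["type\tgene\tstart\tother_gene\tother_start\tlength\tstrand\tvalue"]
        for p in self.plantings:
            lines.append(
                f"planting\t{p.target}\t{p.target_start}\t{p.source}\t{p.source_start}"
                f"\t{p.length}\t{p.strand}\t{p.achieved_identity:.4f}"
            )
        if params is not None:
            oracle = exhaustive_oracle(self.seqs, params)
            for g in range(len(self.seqs)):
                for s in np.flatnonzero(oracle.best_matches[g] >= params.bad_matches):
                    lines.append(
                        f"condemned\t{g}\t{s}\t{oracle.witness_gene[g][s]}"
                        f"\t{oracle.witness_start[g][s]}\t{params.L}"
                        f"\t{'+' if oracle.witness_strand[g][s] == 0 else '-'}"
                        f"\t{oracle.best_matches[g][s]}"
                    )
        Path(manifest_path).write_text("\n".join(lines) + "\n")


def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(4, size=n, p=probs).astype(np.uint8)


def _mutate(rng: np.random.Generator, window: np.ndarray, m: int) -> np.ndarray:
    out = window.copy()
    if m == 0:
        return out
    sites = rng.choice(len(window), size=m, replace=False)
    # shift by 1..3 mod 4: never restores the original base
    out[sites] = (out[sites] + rng.integers(1, 4, size=m)) % 4
    return out


def generate(spec: FixtureSpec) -> Fixture:
    """Generate the fixture; byte-identical output for identical specs."""
    rng = np.random.default_rng(spec.random_seed)
    codes = [_random_codes(rng, spec.gene_length, spec.gc) for _ in range(spec.n_genes)]
    occupied: dict[int, list[tuple[int, int]]] = {g: [] for g in range(spec.n_genes)}

    def _free_slot(gene: int, length: int) -> int:
        for _ in range(200):
            s = int(rng.integers(0, spec.gene_length - length + 1))
            if all(s + length <= lo or s >= hi for lo, hi in occupied[gene]):
                occupied[gene].append((s, s + length))
                return s
        raise ValueError(f"cannot place a {length}-base region in gene {gene}: too crowded")

    records: list[PlantingRecord] = []
    for p in spec.plantings:
        src_start = int(rng.integers(0, spec.gene_length - p.length + 1))
        tgt_start = _free_slot(p.target, p.length)
        window = codes[p.source][src_start : src_start + p.length]
        if p.strand == "-":
            window = (3 - window[::-1]).astype(np.uint8)
        m = int(np.floor((1.0 - p.identity) * p.length))
        codes[p.target][tgt_start : tgt_start + p.length] = _mutate(rng, window, m)
        records.append(
            PlantingRecord(
                source=p.source, source_start=src_start,
                target=p.target, target_start=tgt_start,
                length=p.length, strand=p.strand, mutations=m,
                achieved_identity=(p.length - m) / p.length,
            )
        )
    for sk in spec.shared_kmers:
        for _ in range(sk.count):
            kmer = _random_codes(rng, sk.k, spec.gc)
            for gene in (sk.gene_a, sk.gene_b):
                s = _free_slot(gene, sk.k)
                codes[gene][s : s + sk.k] = kmer

    decode = np.frombuffer(b"ACGT", dtype=np.uint8)
    n_digits = max(3, len(str(spec.n_genes)))
    recs = [
        (f"gene_{g:0{n_digits}d}", decode[c].tobytes().decode())
        for g, c in enumerate(codes)
    ]
    return Fixture(spec=spec, seqs=encode_sequences(recs), plantings=records)


@dataclass
class OracleResult:
    """Per-gene, per-L-start best cross-gene window match and its witness."""

    L: int
    best_matches: list[np.ndarray]   # int, -1 where no cross-gene window exists
    witness_gene: list[np.ndarray]
    witness_start: list[np.ndarray]  # forward-strand coordinates
    witness_strand: list[np.ndarray]  # 0 forward, 1 reverse complement


def _pair_counts(a: np.ndarray, b: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Match counts of every window pair of two code arrays.

    Returns (counts, s2_of_row): ``counts[r, s1]`` is the match count of
    a-window ``s1`` against b-window ``s2 = s1 + r - len(a)``; invalid pairs
    hold -1.
    """
    na, nb = len(a), len(b)
    pad = np.full(na, 255, dtype=np.int16)
    b_pad = np.concatenate([pad, b.astype(np.int16), pad])
    rows = sliding_window_view(b_pad, na)           # row r: b_pad[r : r+na]
    eq = rows == a.astype(np.int16)[None, :]
    cs = np.zeros((eq.shape[0], na + 1), dtype=np.int32)
    np.cumsum(eq, axis=1, dtype=np.int32, out=cs[:, 1:])
    counts = (cs[:, L:] - cs[:, :-L]).astype(np.int32)   # [r, s1]
    n1 = na - L + 1
    r = np.arange(counts.shape[0])[:, None]
    s1 = np.arange(n1)[None, :]
    s2 = s1 + r - na
    counts = counts[:, :n1]
    counts[(s2 < 0) | (s2 > nb - L)] = -1
    return counts, s2


def exhaustive_good_starts(
    seqs: EncodedSequenceSet,
    params: FilterParams,
    oracle: OracleResult | None = None,
) -> list[np.ndarray]:
    """Per gene, every L-start that truly satisfies all sequence conditions.

    Brute force, independent of the seed machinery: no ambiguity in the
    window, GC within bounds, no cross-gene shared (max_consec+1)-mer (string
    sets, both strands) and oracle best identity below the bad threshold.
    """
    if oracle is None:
        oracle = exhaustive_oracle(seqs, params)
    L, k = params.L, params.kane_k
    decoded = [seqs.sequence(g) for g in range(len(seqs))]
    rc_map = str.maketrans("ACGTN", "TGCAN")
    fwd_kmers = [
        {s[i : i + k] for i in range(len(s) - k + 1)} for s in decoded
    ]
    rc_kmers = [
        {s[i : i + k] for i in range(len(s) - k + 1)}
        for s in (d.translate(rc_map)[::-1] for d in decoded)
    ]
    out = []
    for g, seq in enumerate(decoded):
        n1 = max(0, len(seq) - L + 1)
        good = []
        others_f = set().union(*(fwd_kmers[h] for h in range(len(decoded)) if h != g)) \
            if len(decoded) > 1 else set()
        others_r = set().union(*(rc_kmers[h] for h in range(len(decoded)) if h != g)) \
            if (len(decoded) > 1 and params.check_revcomp) else set()
        for s in range(n1):
            window = seq[s : s + L]
            if "N" in window:
                continue
            gc = (window.count("G") + window.count("C")) / L
            if gc < params.gc_min - 1e-12 or gc > params.gc_max + 1e-12:
                continue
            if oracle.best_matches[g][s] >= params.bad_matches:
                continue
            kmers = {window[i : i + k] for i in range(L - k + 1)}
            if kmers & others_f or kmers & others_r:
                continue
            good.append(s)
        out.append(np.array(good, dtype=np.int64))
    return out


def exhaustive_max_coverage(
    seqs: EncodedSequenceSet,
    params: FilterParams,
    dtm: float = 10.0,
    conditions=None,
    oracle: OracleResult | None = None,
) -> int:
    """True optimum of genes-with-a-good-oligo over all ΔTm grid windows.

    The referee for the seed-based coverage estimator: candidate goodness by
    brute force, then the best closed ΔTm window on the centi-degree grid.
    """
    from .thermo import TmTable, sweep_gene_counts, tm_table
    from .sequence_store import init_validity, ValidityMask

    good = exhaustive_good_starts(seqs, params, oracle)
    if sum(len(s) for s in good) == 0:
        return 0
    # Tm of the good windows only
    mask = init_validity(seqs, params.L)
    full = tm_table(seqs, mask, conditions)
    starts, tms = [], []
    for g in range(len(seqs)):
        lookup = dict(zip(full.starts[g].tolist(), full.tms[g].tolist()))
        starts.append(good[g])
        tms.append(np.array([lookup[int(s)] for s in good[g]]))
    _, counts = sweep_gene_counts(TmTable(params.L, starts, tms), dtm)
    return int(counts.max())


def exhaustive_oracle(seqs: EncodedSequenceSet, params: FilterParams) -> OracleResult:
    """Naive all-window referee: best cross-gene match count per L-start.

    Every L-window of every gene is compared against every L-window of every
    *other* gene, forward and (when enabled) reverse complement.  Ambiguous
    positions never match (they are coded with per-strand sentinels).
    Refuses inputs above ~100 kb total: the scan is quadratic by design.
    """
    if seqs.total_length > ORACLE_MAX_TOTAL:
        raise ValueError(
            f"oracle refused: total length {seqs.total_length} > {ORACLE_MAX_TOTAL}"
        )
    L = params.L
    n_genes = len(seqs)
    # sentinel-code ambiguous positions so they can never match anything
    fwd = []
    for c, amb in zip(seqs.codes, seqs.ambiguous):
        x = c.astype(np.int16).copy()
        x[amb] = 100
        fwd.append(x)
    rc = []
    for c, amb in zip(seqs.codes, seqs.ambiguous):
        x = (3 - c[::-1]).astype(np.int16)
        x[amb[::-1]] = 120
        rc.append(x)

    best, wgene, wstart, wstrand = [], [], [], []
    for g in range(n_genes):
        n1 = max(0, len(seqs.codes[g]) - L + 1)
        best.append(np.full(n1, -1, dtype=np.int32))
        wgene.append(np.full(n1, -1, dtype=np.int32))
        wstart.append(np.full(n1, -1, dtype=np.int32))
        wstrand.append(np.full(n1, -1, dtype=np.int8))

    def _update(g, cnts, s2_of, other_gene, strand, map_self, map_other, n_other):
        col_best = cnts.max(axis=0)
        all_cols = np.arange(len(col_best))
        self_idx = all_cols if not map_self else len(best[g]) - 1 - all_cols
        improve = col_best > best[g][self_idx]
        if not improve.any():
            return
        rbest = cnts.argmax(axis=0)
        cols = np.flatnonzero(improve)
        s_self = self_idx[cols]
        s_oth = s2_of[rbest[cols], cols]
        if map_other:
            s_oth = n_other - s_oth - L
        best[g][s_self] = col_best[cols]
        wgene[g][s_self] = other_gene
        wstart[g][s_self] = s_oth
        wstrand[g][s_self] = strand

    for g1 in range(n_genes):
        if len(fwd[g1]) < L:
            continue
        na = len(fwd[g1])
        for g2 in range(g1 + 1, n_genes):
            if len(fwd[g2]) < L:
                continue
            nb = len(fwd[g2])
            strands = [(0, fwd[g2])] + ([(1, rc[g2])] if params.check_revcomp else [])
            for strand, other in strands:
                counts, s2 = _pair_counts(fwd[g1], other, L)
                # g1's windows vs g2 (strand): witness start in g2 forward coords
                _update(g1, counts, s2, g2, strand,
                        map_self=False, map_other=(strand == 1), n_other=nb)
                # the same matrix read for g2: row r pairs s2 = s1 + (r - na),
                # i.e. a per-row shift; gather the transposed view.
                n2 = nb - L + 1
                rr = np.arange(counts.shape[0])[:, None]
                s2g = np.arange(n2)[None, :]
                s1g = s2g - (rr - na)
                ok = (s1g >= 0) & (s1g <= na - L)
                ct = np.full((counts.shape[0], n2), -1, dtype=np.int32)
                ct[ok] = counts[rr.repeat(n2, 1)[ok], s1g[ok]]
                s1_of = s1g
                if strand == 0:
                    # g2 forward windows vs g1 forward
                    _update(g2, ct, s1_of, g1, 0,
                            map_self=False, map_other=False, n_other=na)
                else:
                    # g1-fwd vs g2-rc equals g2-fwd vs g1-rc after complementing
                    # both windows; g2-rc coords map to forward, while the g1
                    # witness window is the forward window s1 itself.
                    _update(g2, ct, s1_of, g1, 1,
                            map_self=True, map_other=False, n_other=na)
    return OracleResult(L, best, wgene, wstart, wstrand)
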