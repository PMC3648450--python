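"""Oligo-set evaluation: good/bad classification and maximum-coverage estimation.

A reported oligo is *good* if it satisfies both uniqueness conditions — no
cross-gene window at or above the identity threshold (either strand) and no
shared contiguous stretch of ``max_consec + 1`` bases — and *bad* otherwise.
Classification uses a near-exhaustive low-weight evaluation seed set (shipped
``w7s16``; average miss probability over the offending identity range below
1e-5), so that verdicts on programs' outputs are essentially exact.

*Coverage* relates the number of genes a program served to the maximum number
that could have been served under the same parameters.  That maximum is
approximated from above: after the cheap elimination steps, every ΔTm window
that could not beat the program's own count is discarded, the remaining span
is kept, all surviving candidates are verified individually, and the best
ΔTm window over verified-good candidates is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filters import FilterParams, build_kmer_gene_map, c15_filter, gc_filter
from .pipeline import OligoRecord, default_seed_set
from .seeds import SeedSet
from .sequence_store import EncodedSequenceSet, init_validity, reverse_complement_view
from .similarity import Phase2Verifier, Witness, phase1_eliminate
from .thermo import (
    ThermoConditions,
    TmInterval,
    TmTable,
    sweep_gene_counts,
    tm_filter,
    tm_table,
)

__all__ = ["OligoVerdict", "EvaluationReport", "evaluate_oligos", "estimate_max_coverage"]


@dataclass(frozen=True)
class OligoVerdict:
    oligo: OligoRecord
    good: bool
    witness: Witness | None


@dataclass
class EvaluationReport:
    verdicts: list[OligoVerdict]
    n_good: int
    n_bad: int
    specificity: float            # good / total
    estimated_max_genes: int | None = None
    coverage: float | None = None  # good / estimated max

    @property
    def n_total(self) -> int:
        return len(self.verdicts)


def _resolve_gene(seqs: EncodedSequenceSet, oligo: OligoRecord) -> int:
    if 0 <= oligo.gene_index < len(seqs) and seqs.ids[oligo.gene_index] == oligo.gene_id:
        g = oligo.gene_index
    else:
        try:
            g = seqs.ids.index(oligo.gene_id)
        except ValueError:
            raise ValueError(f"oligo gene {oligo.gene_id!r} not present in the input") from None
    window = seqs.sequence(g, oligo.start, oligo.start + len(oligo.sequence))
    if window.upper() != oligo.sequence.upper():
        raise ValueError(
            f"oligo for {oligo.gene_id!r} at start {oligo.start} does not match the gene "
            f"sequence ({oligo.sequence!r} vs {window!r})"
        )
    return g


def evaluate_oligos(
    oligos: list[OligoRecord],
    seqs: EncodedSequenceSet,
    eval_seeds: SeedSet | None = None,
    params: FilterParams | None = None,
) -> EvaluationReport:
    """Classify each oligo good/bad with the evaluation seed set.

    Every placement of every evaluation seed inside each oligo is looked up
    against a complete index of the input (both strands unless disabled);
    each cross-gene partner fixes one alignment which is checked exactly, and
    the contiguous-match condition is re-checked as well.
    """
    params = params or FilterParams()
    eval_seeds = eval_seeds or default_seed_set("evaluate")
    kmer_map = build_kmer_gene_map(seqs, params.kane_k)
    verifier = Phase2Verifier(seqs, eval_seeds, params, kmer_map)
    verdicts = []
    for oligo in oligos:
        g = _resolve_gene(seqs, oligo)
        witness = verifier.verify(g, oligo.start)
        verdicts.append(OligoVerdict(oligo=oligo, good=witness is None, witness=witness))
    n_good = sum(v.good for v in verdicts)
    n_bad = len(verdicts) - n_good
    specificity = n_good / len(verdicts) if verdicts else 1.0
    return EvaluationReport(verdicts=verdicts, n_good=n_good, n_bad=n_bad,
                            specificity=specificity)


def estimate_max_coverage(
    seqs: EncodedSequenceSet,
    params: FilterParams | None = None,
    verify_seeds: SeedSet | None = None,
    bond_count: int = 0,
    dtm: float = 10.0,
    conditions: ThermoConditions | None = None,
    screen_seeds: SeedSet | None = None,
) -> int:
    """Upper-bound estimate of how many genes can receive a good oligo.

    Runs the elimination steps up to the identity screen, discards every ΔTm
    window whose potential gene count is below ``bond_count`` (such windows
    cannot beat the design run that produced it), keeps the union span of the
    survivors, verifies **all** remaining valid L-mers with the verification
    seed set, and returns the highest distinct-gene count of any ΔTm window
    over the verified-good candidates.
    """
    params = params or FilterParams()
    verify_seeds = verify_seeds or default_seed_set("verify")
    screen_seeds = screen_seeds or default_seed_set("screen")
    conditions = conditions or ThermoConditions()

    rc = reverse_complement_view(seqs) if params.check_revcomp else None
    mask = init_validity(seqs, params.L)
    kmer_map = build_kmer_gene_map(seqs, params.kane_k)
    c15_filter(seqs, mask, params, kmer_map)
    gc_filter(seqs, mask, params)
    phase1_eliminate(seqs, mask, screen_seeds, params, rc=rc)

    table = tm_table(seqs, mask, conditions)
    if table.n_entries == 0:
        return 0
    lows, counts = sweep_gene_counts(table, dtm)
    survivors = counts >= max(bond_count, 1)
    if not survivors.any():
        return 0
    span = TmInterval(float(lows[survivors].min()), float(lows[survivors].max()) + dtm)
    tm_filter(mask, table, span)

    verifier = Phase2Verifier(seqs, verify_seeds, params, kmer_map, rc=rc)
    good_starts: list[np.ndarray] = []
    good_tms: list[np.ndarray] = []
    for g in range(len(seqs)):
        starts = mask.valid_starts(g)
        tm_lookup = dict(zip(table.starts[g].tolist(), table.tms[g].tolist()))
        keep, tms = [], []
        for s in starts:
            if verifier.verify(g, int(s)) is None:
                keep.append(int(s))
                tms.append(tm_lookup[int(s)])
        good_starts.append(np.array(keep, dtype=np.int64))
        good_tms.append(np.array(tms))
    verified = TmTable(table.L, good_starts, good_tms)
    if verified.n_entries == 0:
        return 0
    _, counts2 = sweep_gene_counts(verified, dtm)
    return int(counts2.max())
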