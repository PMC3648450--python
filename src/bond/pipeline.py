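"""End-to-end probe design: encode → filter → screen → Tm-select → verify → report.

One oligo of length L is sought per gene such that (i) no window of any other
gene (either strand) reaches the identity threshold against it, (ii) it shares
no contiguous stretch of ``max_consec + 1`` bases with another gene, (iii) its
GC fraction lies in the configured range and (iv) its melting temperature lies
in the common ΔTm-wide window chosen to serve the most genes.  Candidate
elimination is monotone: every step only shrinks the valid-start set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .filters import FilterParams, build_kmer_gene_map, c15_filter, gc_filter
from .seeds import SeedSet, read_seed_file
from .sequence_store import EncodedSequenceSet, init_validity, read_fasta, reverse_complement_view
from .similarity import Phase2Verifier, Witness, phase1_eliminate, pick_candidate
from .thermo import (
    NoIntervalError,
    ThermoConditions,
    TmInterval,
    select_tm_interval,
    tm_filter,
    tm_table,
)

__all__ = [
    "OligoRecord",
    "RunReport",
    "default_seed_set",
    "run_bond",
    "design_from_store",
    "write_outputs",
]

_DATA_DIR = Path(__file__).parent / "data"
_DEFAULT_SEED_FILES = {"screen": "w10s8.seeds", "verify": "w9s8.seeds", "evaluate": "w7s16.seeds"}


def default_seed_set(role: str) -> SeedSet:
    """The shipped designed seed set for a pipeline role: screen / verify / evaluate."""
    try:
        fname = _DEFAULT_SEED_FILES[role]
    except KeyError:
        raise ValueError(f"unknown seed role {role!r}") from None
    return read_seed_file(_DATA_DIR / fname)


@dataclass(frozen=True)
class OligoRecord:
    """One reported probe."""

    gene_id: str
    gene_index: int
    start: int          # 0-based
    sequence: str
    tm: float
    gc: float


@dataclass
class RunReport:
    """Auditable per-step account of a design run."""

    n_genes: int
    params: dict
    seed_labels: dict
    step_eliminations: dict = field(default_factory=dict)
    tm_interval: tuple[float, float] | None = None
    tm_interval_gene_count: int = 0
    phase2_rejections: int = 0
    genes_with_oligo: int = 0
    genes_without_oligo: int = 0
    rejects: list = field(default_factory=list)  # (gene, start, witness fields)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def design_from_store(
    seqs: EncodedSequenceSet,
    params: FilterParams | None = None,
    screen_seeds: SeedSet | None = None,
    verify_seeds: SeedSet | None = None,
    dtm: float = 10.0,
    conditions: ThermoConditions | None = None,
    collect_rejects: bool = False,
) -> tuple[list[OligoRecord], RunReport]:
    """Run the full design algorithm on an already-encoded sequence set."""
    params = params or FilterParams()
    screen_seeds = screen_seeds or default_seed_set("screen")
    verify_seeds = verify_seeds or default_seed_set("verify")
    conditions = conditions or ThermoConditions()

    report = RunReport(
        n_genes=len(seqs),
        params={**asdict(params), "dtm": dtm,
                "oligo_nM": conditions.oligo_nM, "na_mM": conditions.na_mM},
        seed_labels={"screen": screen_seeds.label, "verify": verify_seeds.label},
    )

    rc = reverse_complement_view(seqs) if params.check_revcomp else None

    # step 1: encode + eliminate ambiguous windows
    mask = init_validity(seqs, params.L)
    total_starts = sum(len(e) for e in mask.eliminated)
    report.step_eliminations["ambiguous"] = total_starts - mask.n_valid()

    # step 2: contiguous-match condition
    kmer_map = build_kmer_gene_map(seqs, params.kane_k)
    report.step_eliminations["contiguous_match"] = c15_filter(seqs, mask, params, kmer_map)

    # step 3: GC content
    report.step_eliminations["gc_content"] = gc_filter(seqs, mask, params)

    # step 4: identity screening (Phase I)
    report.step_eliminations["identity_phase1"] = phase1_eliminate(
        seqs, mask, screen_seeds, params, rc=rc
    )

    # steps 5-6: melting temperature interval
    table = tm_table(seqs, mask, conditions)
    try:
        interval, count = select_tm_interval(table, dtm)
    except NoIntervalError:
        report.genes_without_oligo = len(seqs)
        return [], report
    report.tm_interval = (interval.low, interval.high)
    report.tm_interval_gene_count = count
    report.step_eliminations["tm_window"] = tm_filter(mask, table, interval)

    # step 7: per-candidate verification (Phase II)
    verifier = Phase2Verifier(seqs, verify_seeds, params, kmer_map, rc=rc)
    tm_lookup = {
        (g, int(s)): float(t)
        for g, (starts, tms) in enumerate(zip(table.starts, table.tms))
        for s, t in zip(starts, tms)
    }
    records: list[OligoRecord] = []
    rejections = 0
    for g in range(len(seqs)):
        while True:
            start = pick_candidate(mask, g, params.end_preference)
            if start is None:
                break
            witness = verifier.verify(g, start)
            if witness is None:
                window = seqs.sequence(g, start, start + params.L)
                gc = (window.count("G") + window.count("C")) / params.L
                records.append(
                    OligoRecord(
                        gene_id=seqs.ids[g],
                        gene_index=g,
                        start=start,
                        sequence=window,
                        tm=tm_lookup[(g, start)],
                        gc=gc,
                    )
                )
                break
            rejections += 1
            mask.eliminate(g, [start])
            if collect_rejects:
                report.rejects.append(
                    (seqs.ids[g], start, witness.gene, witness.start, witness.matches,
                     witness.kind)
                )
    report.phase2_rejections = rejections
    report.genes_with_oligo = len(records)
    report.genes_without_oligo = len(seqs) - len(records)
    return records, report


def run_bond(
    fasta_path: str | Path,
    params: FilterParams | None = None,
    screen_seed_file: str | Path | None = None,
    verify_seed_file: str | Path | None = None,
    dtm: float = 10.0,
    conditions: ThermoConditions | None = None,
    collect_rejects: bool = False,
) -> tuple[list[OligoRecord], RunReport]:
    """Design one unique oligo per gene from a FASTA file."""
    seqs = read_fasta(fasta_path)
    screen = read_seed_file(screen_seed_file) if screen_seed_file else None
    verify = read_seed_file(verify_seed_file) if verify_seed_file else None
    return design_from_store(
        seqs, params=params, screen_seeds=screen, verify_seeds=verify,
        dtm=dtm, conditions=conditions, collect_rejects=collect_rejects,
    )


_TSV_COLUMNS = ("gene_id", "start_1based", "sequence", "tm_C", "gc_fraction")


def write_outputs(
    records: list[OligoRecord], report: RunReport, out_prefix: str | Path
) -> dict[str, Path]:
    """Write oligos as FASTA + TSV and the run report as JSON.

    FASTA headers and the TSV use 1-based inclusive starts (internal
    coordinates are 0-based half-open).
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    fasta = out_prefix.with_suffix(".oligos.fasta")
    tsv = out_prefix.with_suffix(".oligos.tsv")
    js = out_prefix.with_suffix(".report.json")

    with open(fasta, "w") as fh:
        for r in records:
            fh.write(f">{r.gene_id}|{r.start + 1}|{r.tm:.2f}|{r.gc:.3f}\n{r.sequence}\n")
    with open(tsv, "w") as fh:
        fh.write("# starts are 1-based, inclusive\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.start + 1}\t{r.sequence}\t{r.tm:.4f}\t{r.gc:.4f}\n"
            )
    js.write_text(report.to_json())
    return {"fasta": fasta, "tsv": tsv, "report": js}


def read_oligo_tsv(path: str | Path) -> list[OligoRecord]:
    """Re-read a TSV written by :func:`write_outputs` (gene_index left at -1)."""
    records = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#") or line.startswith(_TSV_COLUMNS[0]):
            continue
        gene_id, start1, seq, tm, gc = line.split("\t")
        records.append(
            OligoRecord(gene_id=gene_id, gene_index=-1, start=int(start1) - 1,
                        sequence=seq, tm=float(tm), gc=float(gc))
        )
    return records
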