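"""Melting temperatures and the common-temperature-interval optimisation.

Duplex Tm is computed with unified nearest-neighbor thermodynamics (the
Allawi & SantaLucia dimer parameters): enthalpy and entropy are summed over
stacked dimers plus terminal initiation terms, the entropy receives the
monovalent-salt correction 0.368·(L−1)·ln[Na+], and

    Tm(°C) = 1000·ΔH / (ΔS + R·ln C) − 273.15

with R = 1.987 cal/(mol·K) and C the excess-strand molar concentration.
Defaults model an array probe: 1 µM oligo, 50 mM Na+.  The model sits behind
:func:`melting_temperature` and the vectorised :func:`tm_table` so it can be
swapped without touching the pipeline.

All reported oligos must share one melting-temperature window of width ΔTm;
:func:`select_tm_interval` finds the window (on a 0.01 °C grid of interval
starts) containing valid candidates from the largest number of genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sequence_store import EncodedSequenceSet, ValidityMask

__all__ = [
    "ThermoConditions",
    "TmTable",
    "TmInterval",
    "melting_temperature",
    "tm_table",
    "sweep_gene_counts",
    "select_tm_interval",
    "tm_filter",
    "NoIntervalError",
]

R_GAS = 1.987  # cal / (mol K)

# Unified nearest-neighbor parameters (ΔH kcal/mol, ΔS cal/(mol·K)),
# 5'->3' top strand dimers; the complementary dimer shares the same values.
_NN_UNIFIED: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_INIT_AT = (2.3, 4.1)   # per A/T terminal pair
_INIT_GC = (0.1, -2.8)  # per G/C terminal pair

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _dimer_tables() -> tuple[np.ndarray, np.ndarray]:
    """(dH, dS) arrays indexed by 4*code(first)+code(second)."""
    dh = np.zeros(16)
    ds = np.zeros(16)
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    for a in "ACGT":
        for b in "ACGT":
            dimer = a + b
            rc = _COMP[b] + _COMP[a]
            vals = _NN_UNIFIED.get(dimer) or _NN_UNIFIED[rc]
            dh[4 * code[a] + code[b]] = vals[0]
            ds[4 * code[a] + code[b]] = vals[1]
    return dh, ds


_DIMER_DH, _DIMER_DS = _dimer_tables()
_TERM_DH = np.array([_INIT_AT[0], _INIT_GC[0], _INIT_GC[0], _INIT_AT[0]])
_TERM_DS = np.array([_INIT_AT[1], _INIT_GC[1], _INIT_GC[1], _INIT_AT[1]])


@dataclass(frozen=True)
class ThermoConditions:
    """Hybridization conditions: excess oligo concentration (nM) and Na+ (mM)."""

    oligo_nM: float = 1000.0
    na_mM: float = 50.0

    def __post_init__(self) -> None:
        if self.oligo_nM <= 0 or self.na_mM <= 0:
            raise ValueError("concentrations must be positive")


class NoIntervalError(ValueError):
    """Raised when no Tm interval can be selected (empty table)."""


def _tm_from_sums(dh: float, ds: float, length: int, cond: ThermoConditions) -> float:
    ds = ds + 0.368 * (length - 1) * math.log(cond.na_mM * 1e-3)
    conc = cond.oligo_nM * 1e-9
    return 1000.0 * dh / (ds + R_GAS * math.log(conc)) - 273.15


def melting_temperature(window: str, conditions: ThermoConditions | None = None) -> float:
    """Nearest-neighbor Tm (°C) of a pure-ACGT window against its perfect complement."""
    cond = conditions or ThermoConditions()
    window = window.upper()
    if set(window) - set("ACGT"):
        raise ValueError(f"ambiguous bases in window: {window!r}")
    if len(window) < 2:
        raise ValueError("window too short for nearest-neighbor Tm")
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    codes = np.array([code[c] for c in window])
    idx = 4 * codes[:-1] + codes[1:]
    dh = float(_DIMER_DH[idx].sum() + _TERM_DH[codes[0]] + _TERM_DH[codes[-1]])
    ds = float(_DIMER_DS[idx].sum() + _TERM_DS[codes[0]] + _TERM_DS[codes[-1]])
    return _tm_from_sums(dh, ds, len(window), cond)


@dataclass
class TmTable:
    """Per-gene (valid start, Tm) pairs for the current validity mask."""

    L: int
    starts: list[np.ndarray]  # per gene
    tms: list[np.ndarray]

    @property
    def n_entries(self) -> int:
        return int(sum(len(s) for s in self.starts))


@dataclass(frozen=True)
class TmInterval:
    """A closed melting-temperature window [low, high] with high - low == ΔTm."""

    low: float
    high: float

    @property
    def width(self) -> float:
        return self.high - self.low

    def contains(self, tm: float | np.ndarray):
        return (tm >= self.low - 1e-9) & (tm <= self.high + 1e-9)


def tm_table(
    seqs: EncodedSequenceSet,
    mask: ValidityMask,
    conditions: ThermoConditions | None = None,
) -> TmTable:
    """Tm of every currently valid L-mer, computed gene-wise from cumulative sums."""
    cond = conditions or ThermoConditions()
    L = mask.L
    salt = 0.368 * (L - 1) * math.log(cond.na_mM * 1e-3)
    rlnc = R_GAS * math.log(cond.oligo_nM * 1e-9)
    starts_out, tms_out = [], []
    for g, codes in enumerate(seqs.codes):
        starts = mask.valid_starts(g)
        if len(starts) == 0:
            starts_out.append(starts)
            tms_out.append(np.zeros(0))
            continue
        c = codes.astype(np.int64)
        idx = 4 * c[:-1] + c[1:]
        dh_c = np.concatenate([[0.0], np.cumsum(_DIMER_DH[idx])])
        ds_c = np.concatenate([[0.0], np.cumsum(_DIMER_DS[idx])])
        dh = dh_c[starts + L - 1] - dh_c[starts] + _TERM_DH[c[starts]] + _TERM_DH[c[starts + L - 1]]
        ds = ds_c[starts + L - 1] - ds_c[starts] + _TERM_DS[c[starts]] + _TERM_DS[c[starts + L - 1]]
        tms = 1000.0 * dh / (ds + salt + rlnc) - 273.15
        starts_out.append(starts)
        tms_out.append(tms)
    return TmTable(L, starts_out, tms_out)


def sweep_gene_counts(table: TmTable, dtm: float) -> tuple[np.ndarray, np.ndarray]:
    """Distinct-gene counts of every candidate ΔTm window on the 0.01 °C grid.

    Returns (window lows in °C, counts): for each grid start, how many genes
    own at least one valid L-mer with Tm inside the closed window.  Linear
    sweep: entries sorted by Tm enter and leave the window as its start
    advances, with a per-gene membership counter.
    """
    entries = [(float(t), g) for g, ts in enumerate(table.tms) for t in ts]
    if not entries:
        raise NoIntervalError("no valid L-mers: cannot select a Tm interval")
    n_genes = len(table.tms)
    tm_vals = np.array([e[0] for e in entries])
    genes = np.array([e[1] for e in entries], dtype=np.int64)
    order = np.argsort(tm_vals, kind="stable")
    tm_vals, genes = tm_vals[order], genes[order]

    lo_c = math.floor(round(tm_vals[0] * 100, 6))      # centi-degrees
    hi_c = math.ceil(round(tm_vals[-1] * 100, 6))
    width_c = round(dtm * 100)
    per_gene = np.zeros(n_genes, dtype=np.int64)
    inside = 0
    add_ptr = drop_ptr = 0
    n = len(tm_vals)
    lows = np.arange(lo_c, hi_c + 1) / 100.0
    counts = np.zeros(len(lows), dtype=np.int64)
    for i, low_c in enumerate(range(lo_c, hi_c + 1)):
        low = low_c / 100.0
        high = (low_c + width_c) / 100.0
        while add_ptr < n and tm_vals[add_ptr] <= high + 1e-9:
            g = genes[add_ptr]
            if per_gene[g] == 0:
                inside += 1
            per_gene[g] += 1
            add_ptr += 1
        while drop_ptr < n and tm_vals[drop_ptr] < low - 1e-9:
            g = genes[drop_ptr]
            per_gene[g] -= 1
            if per_gene[g] == 0:
                inside -= 1
            drop_ptr += 1
        counts[i] = inside
    return lows, counts


def select_tm_interval(table: TmTable, dtm: float) -> tuple[TmInterval, int]:
    """The ΔTm-wide closed interval holding valid L-mers from the most genes.

    Interval starts are evaluated on the 0.01 °C grid anchored at the lowest
    Tm rounded down; ties go to the lowest start.  Returns (interval, gene
    count).
    """
    lows, counts = sweep_gene_counts(table, dtm)
    best = int(np.argmax(counts))  # argmax takes the first (lowest) maximum
    low = float(lows[best])
    return TmInterval(low, low + dtm), int(counts[best])


def tm_filter(mask: ValidityMask, table: TmTable, interval: TmInterval) -> int:
    """Eliminate valid starts whose Tm falls outside the (closed) interval."""
    eliminated = 0
    for g, (starts, tms) in enumerate(zip(table.starts, table.tms)):
        if len(starts) == 0:
            continue
        outside = ~interval.contains(tms)
        eliminated += mask.eliminate(g, starts[outside])
    return eliminated
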