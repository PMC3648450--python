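# Methods

## Problem and model

Given a set of gene (transcript) sequences, the package reports at most one
probe (oligo) of length *L* per gene such that the probe hybridizes uniquely:
no window of any other gene — forward or reverse complement — reaches the
identity threshold against it, and no contiguous perfect match of
`max_consec + 1` bases is shared with another gene.  Identity is ungapped
Hamming identity between equal-length windows; gapped similarity is out of
scope, as is secondary-structure screening.

A candidate window pair is *bad* when its match count reaches
`ceil(identity_threshold * L)` — 38 of 50 at the defaults — encoding
"identity below 75%" as the good region, boundary inclusive on the bad side.
Intra-gene repeats are never disqualifying: specificity is defined against
non-targets only.  Reverse-complement similarity between different genes is
checked by default (`check_revcomp=False` disables it); whether unstranded
probes require it depends on the array protocol, so it is a switch.

## Seed sensitivity

An alignment between a probe and a non-target window is modelled as a
Bernoulli 0/1 sequence of length *N* with per-position match probability *p*.
A spaced seed hits if all its match positions align with 1s at some offset.
`bond.seeds.sensitivity` computes the exact hit probability of a seed set by
dynamic programming: the state is the joint distribution of the last
`max seed length` alignment bits; at each step the oldest bit is marginalised
out, the new bit is appended with probability *p*, and any state whose suffix
completes a seed moves to an absorbing hit state.  Left-padding with
mismatches is exact because seed patterns begin with a match.  The state
vector has `2**max_length` entries, which caps supported seed lengths at 24;
shipped sets stay at ≤ 24.  `brute_force_sensitivity` (full `2**N`
enumeration, *N* ≤ 20) is an independent reference kept under test.

`miss_area` reports the average of `1 − sensitivity(p)` over the identity
range `[p_min, 1]` — the fraction of above-threshold similarities a seed set
fails to flag.  Two averaging conventions are provided:

* `rule="trapezoid"` (default, step 0.001): the continuous uniform average —
  the mathematically natural definition;
* `rule="grid"` (step 0.01): the plain mean over whole-percent identity
  levels above the threshold (the threshold level itself excluded).  This is
  the convention under which the classical 16.98% miss fraction of the
  contiguous weight-11 seed at probe length 50 is obtained; the continuous
  average of the same curve is 18.17%.  The package computes both rather than
  privileging one; the whole-percent mean is used wherever published
  checkpoint values are being reproduced.

## Seed design

Sensitivity-optimal multiple seeds are hard to find, so the designer
minimises a proxy: the total **overlap complexity** of the set — for each
pair (self-pairs included), the sum over relative shifts of
`2**(aligned match–match positions)`.  Low overlap means the seeds' hit
events are closer to independent.  The search is steepest-descent
hill-climbing (move one interior match of one seed at a time), round-robin
over seeds, with a few random restarts; seed lengths are spread evenly over
the requested range.  Self-overlap terms are included in the score so that a
single-seed design is still meaningful.  The DP sensitivity of the winner is
verified afterwards, never used as the search objective (it would be far too
slow inside the loop).

Shipped sets (data files under `src/bond/data/`, regenerable with
`bond design-seeds`):

| set    | role            | design model      | quality (verified by DP)             |
|--------|-----------------|-------------------|--------------------------------------|
| w10s8  | Phase I screen  | N=50, p=0.85      | sensitivity 0.9995 at p=0.85         |
| w9s8   | Phase II verify | N=50, p=0.75      | sensitivity 0.9851 at p=0.75         |
| w7s16  | evaluation      | N=50, p=0.75      | trapezoid miss area 5.7e-6           |

The evaluation set uses weight 7: the target of ≤ 1e-5 average miss is not
reachable at weight 8 with 16 seeds (the class plateaus near 5e-5 across many
designs and length ranges), while weight 7 reaches it with an order of
magnitude to spare at a modest cost in hash-bucket density.  Lengths are
capped at 19 so the DP behind the miss-area check stays cheap.

## Sequence storage and primitives

Bases are coded 2 bits each (A=0, C=1, G=2, T=3; complement = 3 − code).
IUPAC ambiguity codes (N, R, Y, …) are accepted on input, flagged in a
per-position mask and coded 0; every window primitive consults the mask so an
ambiguous position never counts as a match, and every candidate window
containing one is eliminated up front.  `window_matches` packs both windows
into 64-bit words (32 bases/word) and counts mismatching 2-bit groups via
XOR + popcount.  Coordinates are 0-based half-open internally; all
human-readable output uses 1-based inclusive starts and says so in its
header.

## Filters and the two-phase identity search

* **Contiguous-match filter**: every (`max_consec`+1)-mer is hashed to the
  set of genes containing it (no text index is needed since only elimination
  is performed); a candidate dies iff one of its k-mers occurs in a different
  gene on either strand.
* **GC filter**: windowed GC fraction, inclusive bounds, computed on the
  probe window only.
* **Phase I** (screening, `w10s8`): per seed, the spaced w-mer keys of the
  forward and reverse-complement views are bucketed; only *adjacent* pairs of
  each sorted bucket are examined, keeping the pass linear in total bucket
  size.  Each cross-gene pair is verified by an anchored slide: the hit fixes
  the relative alignment, the base-equality vector along that diagonal is
  computed once, and every window offset covering the hit is scored from its
  cumulative sum.  All window starts at or above the bad threshold are
  eliminated in both genes.  Bucket entries are ordered by (strand, gene ID,
  position) — gene *ID*, not input order — which makes the screen invariant
  under permutations of the input records.  Reverse-complement-vs-
  reverse-complement pairs are skipped (they duplicate forward-forward).
* **Phase II** (per-candidate, `w9s8`): the candidate is the midpoint of the
  longest run of surviving starts (leftmost on ties; `--end 3|5` shifts the
  tie preference).  Every placement of every verification seed inside the
  candidate window is looked up against the full index; every cross-gene
  partner fixes one alignment of the candidate, which is checked exactly.
  The contiguous-match condition is re-checked at the same time.  On a bad
  verdict the start is eliminated and the next candidate is drawn until the
  gene is served or exhausted.  Per-gene verification is independent of gene
  order.

Phase I is a heuristic accelerator: it may miss repeats (consecutive-pair
hits only) but never mislabels — every elimination is verified at the exact
threshold.  Phase II carries the sensitivity guarantee, quantified by the
seed model above.

## Melting temperatures

Unified nearest-neighbor thermodynamics: ΔH/ΔS summed over stacked dimers
(Allawi–SantaLucia unified parameters) plus terminal initiation terms, the
monovalent-salt entropy correction `0.368·(L−1)·ln[Na+]`, and
`Tm = 1000·ΔH / (ΔS + R·ln C) − 273.15` with the excess-strand concentration
*C*.  Defaults model an array probe: 1 µM oligo, 50 mM Na⁺, both
configurable (`ThermoConditions`).  The model is isolated behind
`melting_temperature` / `tm_table` and can be swapped without touching the
pipeline; the implementation is verified against an independent
nearest-neighbor implementation to 0.1 °C.  Self-complementary probes are
not special-cased.

The common ΔTm window is chosen by evaluating every interval start on the
0.01 °C grid anchored at the lowest Tm rounded down, maximising the number of
distinct genes owning a valid candidate inside the closed interval; ties go
to the lowest start (a deliberate, possibly slightly suboptimal, fixed rule).
The evaluation's coverage estimator reuses the same grid, which is what makes
its result comparable to an exhaustive grid search.

## Evaluation and coverage

`evaluate_oligos` applies the Phase II machinery with the evaluation seeds to
an arbitrary probe set and reports specificity = good/total, with a witness
(gene, window, match count or shared-stretch flag) for every bad probe.

`estimate_max_coverage` approximates, from above, the maximum number of genes
that could have received a good probe: run the cheap eliminations (ambiguity,
C15, GC, Phase I), count per ΔTm grid window the genes holding a valid
candidate, discard windows that cannot beat the design run's own count, keep
the union span of the survivors, verify **all** remaining candidates
individually, and report the best ΔTm window over the verified-good
candidates.  On fixture-scale inputs this estimate equals the true optimum
computed by exhaustive search (asserted in tests); at scale it remains an
upper bound because seed misses can only keep candidates, never remove them.

## Synthetic data and what the tests show

The fixture generator emulates the single property of transcript sets that
drives probe design — controlled cross-gene similarity: i.i.d. background
with a configurable GC level, planted near-duplicate windows of *exact*
identity (copy then mutate exactly `floor((1−q)·n)` distinct positions, never
back to the original base, optionally reverse-complemented), and planted
exact shared k-mers.  It does not model real transcriptome features — shared
domains and gene families with non-uniform similarity profiles, splice
isoforms, low-complexity and repeat-element structure, biased base
composition along transcripts.  Passing tests therefore demonstrate the
correctness of the machinery (no bad probe survives; coverage estimates are
exact at desk scale) under the stated similarity model, not field performance
on any particular transcriptome.

The quadratic all-window referee (`exhaustive_oracle`) shares no code with
the seed-based search it judges; the test battery (default sizes 20–50 genes
of 0.5–1 kb, planted identities 70–90%) keeps the full suite within a few
minutes on one CPU while exercising every filter boundary (37 vs 38 matches,
shared runs of 14 vs 15, GC bounds inclusive, Tm interval closed).

## Numerical choices and degenerate inputs

* Elimination masks are monotone (bits only flip valid → eliminated); every
  step is idempotent and order-independent with respect to the others ahead
  of it.
* Genes shorter than *L* simply have no candidates; an input whose candidates
  are all eliminated yields a report listing the genes without probes — not
  an error.  An empty FASTA, duplicate record IDs or non-IUPAC characters are
  errors naming the record.
* Tm interval endpoints are closed on both sides; boundary Tm survives.
* Seeds longer than the alignment contribute zero sensitivity and are
  skipped silently; an all-don't-care or empty seed pattern is rejected at
  construction.
* The sensitivity DP caps seed length at 24 (state-vector memory); the
  brute-force reference refuses N > 20 (2^N enumeration).
* The exhaustive oracle refuses inputs over ~100 kb total (quadratic scan by
  design).

## Known limitations

* Ungapped identity only; a gapped 75% similarity spread over a longer region
  is outside the model (as is standard for this probe-design family).
* Phase I's "adjacent bucket pairs" rule is one concrete reading of
  consecutive-hit screening; other readings would change which eliminations
  happen early but not the final verdicts, which Phase II owns.
* One probe per gene; tiling or multi-probe designs are not supported.
* Thermodynamics ignores mismatch/dangling-end corrections and
  self-complementarity; Tm is used only to co-locate probes in one window,
  where a consistent model matters more than absolute accuracy.
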