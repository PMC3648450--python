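# bond — unique oligonucleotide (microarray probe) design with multiple spaced seeds

`bond` selects, for each gene (transcript) in a FASTA set, one DNA probe of
fixed length *L* (default 50) that hybridizes to its target and to nothing
else on the array.  A probe is considered cross-hybridizing — *bad* — if it
violates either of the classical empirical conditions:

* **C75** — its best ungapped identity with a window of any non-target gene
  (either strand) reaches 75% (≥ 38 of 50 matching bases), or
* **C15** — it shares a perfect contiguous stretch of 15 or more bases with a
  non-target.

Good probes must additionally have GC content within 30–70% and a melting
temperature inside one common window of width ΔTm = 10 °C chosen so that as
many genes as possible can be served.

## The method

Finding every ≥75%-identity window pair across hundreds of megabases is the
hard part.  `bond` detects similarities with **multiple spaced seeds**:
patterns of required matches (`1`) and don't-cares (`*`), e.g. the
verification set shipped with the package (`w9s8`: 8 seeds of weight 9).  For
a random ungapped alignment of length *N* whose positions match independently
with probability *p*, the *sensitivity* of a seed set — the probability that
some seed hits — is computed **exactly** by a dynamic program over the
distribution of recent match history, with hit states absorbed as they
appear.  Classical checkpoints, reproduced by `bond.seeds.sensitivity`:

| seed                     | N  | p    | sensitivity |
|--------------------------|----|------|-------------|
| `11111111111` (BLAST)    | 64 | 0.70 | 30%         |
| `111*1**1*1**11*111`     | 64 | 0.70 | 47%         |
| `11111111111`            | 50 | 0.75 | 40%         |

The contiguous 11-mer misses 16.98% of ≥75%-identity similarities at probe
scale (average miss over whole-percent identity levels 76–100%), which is why
hit-and-extend heuristics built on it are unsuitable for probe design.  The
shipped `w9s8` set reaches 98.5% sensitivity at the 75% threshold, and the
evaluation set (`w7s16`) has an average miss probability below 1e-5 over the
whole offending identity range.  Seed sets are designed by hill-climbing on
overlap complexity (`bond.seed_design`) and any user seed file can replace
the shipped ones.

The pipeline (per `bond design` run): encode sequences 2 bits/base →
eliminate candidate windows with ambiguous bases → C15 k-mer hashing → GC
filter → Phase I bulk screening with a heavier `w10s8` seed set (adjacent
hash-bucket pairs, anchored window verification) → nearest-neighbor Tm for
all surviving candidates and optimal ΔTm window selection → Phase II: one
candidate per gene at a time (midpoint of the longest surviving run), tested
with the full power of `w9s8` against the complete spaced-seed index, until a
unique probe is found or the gene is exhausted.

An evaluation mode (`bond evaluate`) classifies any probe set good/bad with
the near-exhaustive evaluation seeds and reports **specificity** (good /
total) and **coverage** (good / an upper-bound estimate of the maximum number
of genes that could have received a good probe under the same parameters).

## Worked example

Generate a synthetic 8-gene set with two planted cross-gene repeats (60 bases
at 80% identity; 55 bases at 90% identity on the reverse strand), design
probes, and evaluate them:

```
$ bond make-fixture --genes 8 --gene-length 600 --random-seed 7 \
      --plant 0:1:60:0.8 --plant 2:3:55:0.9:- --out genes.fasta
$ bond design --input genes.fasta --out demo
8/8 genes received an oligo; Tm window (64.11, 74.11); outputs:
demo.oligos.fasta, demo.oligos.tsv, demo.report.json

$ head -4 demo.oligos.tsv
# starts are 1-based, inclusive
gene_id  start_1based  sequence                                            tm_C     gc_fraction
gene_000 199           TGTGGAGATTTACCAGTCTTATTAGGGAGGTTCGTTAAGAGTCCCGACAG  70.0021  0.4600
gene_001 274           TCAGAATTGACAAAAGAATCCATGGGACGTTGGATAAGTTCAATTATCCG  67.7560  0.3800

$ bond evaluate --oligos demo.oligos.tsv --input genes.fasta --out demo_eval
{"total": 8, "good": 8, "bad": 0, "specificity": 1.0,
 "estimated_max_genes": 8, "coverage": 1.0}
```

Every gene received a probe inside the common 10 °C melting window; all eight
are good (specificity 100%), and since at most eight genes could have been
served, coverage is 100%.  The DP sensitivity of the shipped verification
set at the design threshold:

```
$ bond seed-sensitivity --seeds src/bond/data/w9s8.seeds -n 50 -p 0.75
0.985120
```

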