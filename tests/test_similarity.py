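"""Spaced-seed indexing, anchored verification, Phase I/II and candidate picking."""

import numpy as np
import pytest

from bond.filters import FilterParams, build_kmer_gene_map
from bond.fixtures import FixtureSpec, Planting, exhaustive_oracle, generate
from bond.pipeline import default_seed_set
from bond.seeds import SeedSet, SpacedSeed
from bond.sequence_store import ValidityMask, init_validity
from bond.similarity import (
    Phase2Verifier,
    build_index,
    phase1_eliminate,
    pick_candidate,
    verify_anchor,
)
from tests.conftest import make_store, random_dna


class TestBuildIndex:
    def test_hand_enumerated_buckets(self):
        # "ACACAC" with seed 1*1: keys (A,A),(C,C),(A,A),(C,C) -> 2 buckets of 2
        seqs = make_store(["ACACAC"])
        idx = build_index(seqs, SpacedSeed("1*1"))
        assert len(idx) == 4
        assert idx.n_buckets() == 2
        sizes = sorted(int(hi - lo) for lo, hi in zip(idx.bucket_lo, idx.bucket_hi))
        assert sizes == [2, 2]
        # positions ascending within buckets
        for lo, hi in zip(idx.bucket_lo, idx.bucket_hi):
            assert list(idx.pos[lo:hi]) == sorted(idx.pos[lo:hi])

    def test_single_position(self):
        seqs = make_store(["ACG"])
        idx = build_index(seqs, SpacedSeed("1*1"))
        assert len(idx) == 1 and idx.n_buckets() == 1

    def test_seed_longer_than_genes_gives_empty_index(self):
        seqs = make_store(["ACG"])
        idx = build_index(seqs, SpacedSeed("1" * 10))
        assert len(idx) == 0

    def test_ambiguous_span_excluded(self):
        seqs = make_store(["ACNAC"])
        idx = build_index(seqs, SpacedSeed("1*1"))
        # only placements not touching the N: none of starts 0,1,2 qualify
        # except start 0 spans ACN (touches), start 1 CNA, start 2 NAC -> all excluded
        assert len(idx) == 0


class TestVerifyAnchor:
    def test_identical_windows_report_every_covering_offset(self, rng):
        s = random_dna(rng, 150)
        seqs = make_store([s, s[20:110]])
        params = FilterParams()
        # a hit at positions (60, 40) with seed span 10 (same underlying bases)
        sa, sb, counts = verify_anchor(seqs, 0, 60, seqs, 1, 40, 10, params)
        assert (counts == 50).all()
        # covering offsets: sa in [max(0,60+10-50), min(60, 100)] intersect partner range
        assert sa.min() >= 20 and sa.max() <= 60
        assert len(sa) > 0 and np.array_equal(sb, sa - 20)

    @pytest.mark.parametrize("mutations,expected_bad", [(13, False), (12, True)])
    def test_identity_boundary_38_of_50(self, mutations, expected_bad):
        """38/50 matches condemns; 37/50 does not."""
        rng = np.random.default_rng(5)
        a = random_dna(rng, 120)
        window = list(a[30:80])
        for i in range(mutations):  # mutate a prefix, leaving a clean anchor region
            window[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[window[i]]
        b = random_dna(rng, 40) + "".join(window) + random_dna(rng, 30)
        seqs = make_store([a, b])
        params = FilterParams()
        anchor = mutations + 2  # inside the exactly-matching suffix
        sa, sb, counts = verify_anchor(
            seqs, 0, 30 + anchor, seqs, 1, 40 + anchor, 12, params
        )
        full = (sa == 30) & (sb == 40)
        assert full.any() == expected_bad


class TestPhase1:
    def test_exact_copy_eliminates_all_condemned_starts(self, params):
        rng = np.random.default_rng(7)
        fx = generate(FixtureSpec(n_genes=2, gene_length=150, random_seed=3,
                                  plantings=(Planting(0, 1, 60, 1.0),)))
        seqs = fx.seqs
        oracle = exhaustive_oracle(seqs, params)
        mask = init_validity(seqs, params.L)
        n = phase1_eliminate(seqs, mask, default_seed_set("screen"), params)
        assert n > 0
        for g in range(2):
            condemned = set(np.flatnonzero(oracle.best_matches[g] >= params.bad_matches))
            eliminated = set(range(len(mask.eliminated[g]))) - set(mask.valid_starts(g))
            # the exact 60-base copy is a long repeat: screening must find all of it
            assert condemned <= eliminated

    def test_never_eliminates_clearly_unique_starts(self, params):
        """Screening must not destroy candidates with best identity <= 0.70."""
        fx = generate(FixtureSpec(n_genes=6, gene_length=400, random_seed=11,
                                  plantings=(Planting(0, 1, 60, 0.85),
                                             Planting(2, 3, 60, 0.75, "-"))))
        seqs = fx.seqs
        oracle = exhaustive_oracle(seqs, params)
        mask = init_validity(seqs, params.L)
        phase1_eliminate(seqs, mask, default_seed_set("screen"), params)
        margin = int(np.floor(0.70 * params.L))
        for g in range(len(seqs)):
            eliminated = set(range(len(mask.eliminated[g]))) - set(mask.valid_starts(g))
            for s in eliminated:
                assert oracle.best_matches[g][s] > margin

    def test_unrelated_genes_unchanged(self, params):
        rng = np.random.default_rng(23)
        seqs = make_store([random_dna(rng, 200), random_dna(rng, 200)])
        oracle = exhaustive_oracle(seqs, params)
        # sanity: no window is actually bad
        assert all((bm < params.bad_matches).all() for bm in oracle.best_matches)
        mask = init_validity(seqs, params.L)
        phase1_eliminate(seqs, mask, default_seed_set("screen"), params)
        margin = int(np.floor(0.70 * params.L))
        for g in range(2):
            for s in set(range(len(mask.eliminated[g]))) - set(mask.valid_starts(g)):
                assert oracle.best_matches[g][s] > margin

    def test_single_gene_no_change(self, rng, params):
        seqs = make_store([random_dna(rng, 300)])
        mask = init_validity(seqs, params.L)
        assert phase1_eliminate(seqs, mask, default_seed_set("screen"), params) == 0


def make_verifier(seqs, params, seeds=None):
    kmer_map = build_kmer_gene_map(seqs, params.kane_k)
    return Phase2Verifier(seqs, seeds or default_seed_set("verify"), params, kmer_map)


class TestPhase2:
    def test_planted_80pct_copy_is_bad_with_witness(self, params):
        fx = generate(FixtureSpec(n_genes=2, gene_length=300, random_seed=19,
                                  plantings=(Planting(0, 1, 50, 0.80),)))
        seqs = fx.seqs
        p = fx.plantings[0]
        verifier = make_verifier(seqs, params)
        w = verifier.verify(p.target, p.target_start)
        assert w is not None
        if w.kind == "identity":
            assert w.matches >= params.bad_matches

    def test_unique_candidate_is_good(self, params):
        rng = np.random.default_rng(31)
        seqs = make_store([random_dna(rng, 300), random_dna(rng, 300)])
        oracle = exhaustive_oracle(seqs, params)
        verifier = make_verifier(seqs, params)
        mask = init_validity(seqs, params.L)
        s = pick_candidate(mask, 0)
        assert oracle.best_matches[0][s] < params.bad_matches
        assert verifier.verify(0, s) is None

    def test_single_gene_always_good(self, rng, params):
        seqs = make_store([random_dna(rng, 300)])
        verifier = make_verifier(seqs, params)
        assert verifier.verify(0, 100) is None

    def test_agrees_with_oracle_on_planted_fixture(self, params):
        """Zero false 'good' on every valid start of a mixed fixture."""
        fx = generate(FixtureSpec(n_genes=8, gene_length=300, random_seed=41,
                                  plantings=(Planting(0, 1, 70, 0.80),
                                             Planting(2, 3, 60, 0.90, "-"),
                                             Planting(4, 5, 55, 0.75))))
        seqs = fx.seqs
        oracle = exhaustive_oracle(seqs, params)
        verifier = make_verifier(seqs, params)
        for g in range(len(seqs)):
            for s in range(0, len(seqs.codes[g]) - params.L + 1, 7):
                verdict_good = verifier.verify(g, s) is None
                oracle_bad = oracle.best_matches[g][s] >= params.bad_matches
                if verdict_good:
                    assert not oracle_bad  # a missed bad window would be a false 'good'


class TestHitRate:
    def test_verify_seeds_detect_98pct_of_threshold_pairs(self):
        """w9s8 hits >= 98% of 1000 random window pairs with exactly 38/50 matches."""
        rng = np.random.default_rng(2718)
        seeds = default_seed_set("verify")
        offs = [np.array(s.match_offsets) for s in seeds]
        spans = [s.length for s in seeds]
        hits = 0
        for _ in range(1000):
            match = np.ones(50, dtype=bool)
            match[rng.choice(50, size=12, replace=False)] = False
            hit = any(
                match[i + o].all()
                for sp, o in zip(spans, offs)
                for i in range(50 - sp + 1)
            )
            hits += hit
        assert hits >= 980


class TestPickCandidate:
    def test_midpoint_of_longest_run(self):
        elim = np.ones(60, dtype=np.uint8)
        elim[10:13] = 0   # run of 3
        elim[40:45] = 0   # run of 5 -> midpoint 42
        mask = ValidityMask(50, [elim])
        assert pick_candidate(mask, 0) == 42

    def test_single_valid_start(self):
        elim = np.ones(20, dtype=np.uint8)
        elim[7] = 0
        mask = ValidityMask(50, [elim])
        assert pick_candidate(mask, 0) == 7

    def test_exhausted_gene(self):
        mask = ValidityMask(50, [np.ones(20, dtype=np.uint8)])
        assert pick_candidate(mask, 0) is None
        mask_empty = ValidityMask(50, [np.zeros(0, dtype=np.uint8)])
        assert pick_candidate(mask_empty, 0) is None

    def test_tie_preference(self):
        elim = np.ones(30, dtype=np.uint8)
        elim[2:5] = 0
        elim[20:23] = 0
        mask = ValidityMask(50, [elim])
        assert pick_candidate(mask, 0) == 3            # leftmost by default
        assert pick_candidate(mask, 0, "5") == 3
        assert pick_candidate(mask, 0, "3") == 21      # rightmost longest run


class TestOrderIndependence:
    def test_phase1_results_permute_with_genes(self, params):
        fx = generate(FixtureSpec(n_genes=6, gene_length=250, random_seed=4,
                                  plantings=(Planting(0, 1, 60, 0.85),)))
        seqs = fx.seqs
        mask = init_validity(seqs, params.L)
        phase1_eliminate(seqs, mask, default_seed_set("screen"), params)

        perm = [3, 1, 5, 0, 2, 4]
        from bond.sequence_store import EncodedSequenceSet

        permuted = EncodedSequenceSet(
            [seqs.ids[i] for i in perm],
            [seqs.codes[i] for i in perm],
            [seqs.ambiguous[i] for i in perm],
        )
        mask_p = init_validity(permuted, params.L)
        phase1_eliminate(permuted, mask_p, default_seed_set("screen"), params)
        for new_g, old_g in enumerate(perm):
            assert np.array_equal(mask_p.eliminated[new_g], mask.eliminated[old_g])
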