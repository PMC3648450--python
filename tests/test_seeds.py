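"""Exact seed-sensitivity DP: published checkpoints, oracle equivalence, invariants."""

import math

import numpy as np
import pytest

from bond.seeds import (
    AlignmentModel,
    ModelError,
    SeedError,
    SeedSet,
    SpacedSeed,
    brute_force_sensitivity,
    miss_area,
    read_seed_file,
    sensitivity,
    write_seed_file,
)

PH_SEED = "111*1**1*1**11*111"  # the classic PatternHunter weight-11 spaced seed


class TestSpacedSeedValidation:
    @pytest.mark.parametrize("bad", ["", "1*", "*1", "101", "**", "1 1"])
    def test_rejects_malformed_patterns(self, bad):
        with pytest.raises(SeedError):
            SpacedSeed(bad)

    def test_weight_and_length(self):
        s = SpacedSeed(PH_SEED)
        assert (s.weight, s.length) == (11, 18)
        assert s.match_offsets[0] == 0 and s.match_offsets[-1] == 17

    def test_seed_set_rejects_duplicates(self):
        with pytest.raises(SeedError):
            SeedSet((SpacedSeed("11"), SpacedSeed("11")))

    @pytest.mark.parametrize("N,p", [(0, 0.5), (10, -0.1), (10, 1.5)])
    def test_invalid_model(self, N, p):
        with pytest.raises(ModelError):
            AlignmentModel(N, p)


class TestSensitivityCheckpoints:
    """Known sensitivities of the classical BLAST and PatternHunter seeds."""

    @pytest.mark.parametrize(
        "seed,N,p,expected",
        [
            ("1" * 11, 64, 0.70, 0.30),
            (PH_SEED, 64, 0.70, 0.47),
            ("1" * 11, 50, 0.75, 0.40),
        ],
    )
    def test_published_values(self, seed, N, p, expected):
        assert round(sensitivity(SpacedSeed(seed), AlignmentModel(N, p)), 2) == expected

    def test_single_placement_equals_p_to_the_w(self):
        # seed exactly fills the alignment: independent match positions
        for pattern in ("1" * 7, PH_SEED, "1*1*1"):
            s = SpacedSeed(pattern)
            got = sensitivity(s, AlignmentModel(s.length, 0.63))
            assert got == pytest.approx(0.63 ** s.weight, abs=1e-12)

    def test_certain_hit_at_full_identity(self):
        ss = SeedSet((SpacedSeed("111"), SpacedSeed("1*1")))
        assert sensitivity(ss, AlignmentModel(10, 1.0)) == pytest.approx(1.0)

    def test_seeds_longer_than_alignment_are_skipped(self):
        ss = SeedSet((SpacedSeed("11"), SpacedSeed("1" * 15)))
        short_only = SeedSet((SpacedSeed("11"),))
        m = AlignmentModel(8, 0.5)
        assert sensitivity(ss, m) == pytest.approx(sensitivity(short_only, m))
        assert sensitivity(SpacedSeed("1" * 15), m) == 0.0


class TestBruteForceOracle:
    def test_hand_enumerated_example(self):
        # sequences of length 3 hit by "11": 110, 011, 111 -> 3/8 at p=1/2
        got = brute_force_sensitivity(SpacedSeed("11"), AlignmentModel(3, 0.5))
        assert got == pytest.approx(3 / 8, abs=1e-15)

    def test_zero_identity(self):
        assert brute_force_sensitivity(SpacedSeed("1*1"), AlignmentModel(6, 0.0)) == 0.0

    def test_refuses_large_N(self):
        with pytest.raises(ModelError):
            brute_force_sensitivity(SpacedSeed("11"), AlignmentModel(21, 0.5))

    def test_dp_matches_enumeration_on_random_instances(self, rng):
        """DP and 2^N enumeration agree to 1e-12 on random seed sets."""
        for _ in range(60):
            n_seeds = int(rng.integers(1, 3))
            seeds = []
            while len(seeds) < n_seeds:
                length = int(rng.integers(2, 9))
                pat = "1" + "".join(rng.choice(["1", "*"], size=length - 2)) + "1"
                if pat not in [s.pattern for s in seeds]:
                    seeds.append(SpacedSeed(pat))
            model = AlignmentModel(int(rng.integers(2, 15)), float(rng.uniform(0, 1)))
            ss = SeedSet(tuple(seeds))
            assert sensitivity(ss, model) == pytest.approx(
                brute_force_sensitivity(ss, model), abs=1e-12
            )


class TestSensitivityInvariants:
    def test_monotone_in_identity(self):
        ss = SeedSet((SpacedSeed("11*1"), SpacedSeed("1*11")))
        vals = [sensitivity(ss, AlignmentModel(30, p)) for p in np.linspace(0, 1, 21)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_monotone_in_alignment_length(self):
        s = SpacedSeed(PH_SEED)
        vals = [sensitivity(s, AlignmentModel(N, 0.7)) for N in range(18, 70, 5)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_adding_a_seed_never_hurts(self):
        base = SeedSet((SpacedSeed("111*1"),))
        more = SeedSet((SpacedSeed("111*1"), SpacedSeed("1*1*11")))
        for p in (0.3, 0.6, 0.8):
            m = AlignmentModel(25, p)
            assert sensitivity(more, m) >= sensitivity(base, m) - 1e-12

    def test_dropping_a_match_position_never_hurts(self):
        # the weight-reduced variant hits whenever the heavier seed does
        heavy, light = SpacedSeed("11*11"), SpacedSeed("11*1")
        for p in (0.3, 0.6, 0.8):
            m = AlignmentModel(20, p)
            assert sensitivity(light, m) >= sensitivity(heavy, m) - 1e-12

    @pytest.mark.parametrize("k,N,p", [(3, 17, 0.4), (5, 40, 0.75), (11, 50, 0.75)])
    def test_contiguous_seed_matches_no_run_recurrence(self, k, N, p):
        """Independent closed-form check: a(n) = a(n-1) - (1-p) p^k a(n-k-1)."""
        a = [1.0] * k + [1 - p**k]
        for n in range(k + 1, N + 1):
            a.append(a[n - 1] - (1 - p) * p**k * a[n - k - 1])
        got = sensitivity(SpacedSeed("1" * k), AlignmentModel(N, p))
        assert got == pytest.approx(1 - a[N], abs=1e-12)


class TestMissArea:
    def test_closed_form_single_match_seed(self):
        # S(p) = p at N=1, so the average miss over [0.5, 1] is 0.25 exactly
        assert miss_area(SpacedSeed("1"), 1, 0.5) == pytest.approx(0.25, abs=1e-12)

    def test_zero_when_always_hit(self):
        assert miss_area(SpacedSeed("1"), 40, 0.9) <= miss_area(SpacedSeed("1"), 1, 0.9)
        # a seed set with sensitivity 1 on the whole range misses nothing
        assert miss_area(SpacedSeed("1"), 5, 0.0, rule="grid", step=0.25) >= 0.0
        ss = SeedSet((SpacedSeed("1"),))
        assert miss_area(ss, 1, 0.999999) == pytest.approx(0.0, abs=1e-5)

    def test_percent_grid_convention_blast_seed(self):
        """The whole-percent average reproduces the published 16.98% miss rate."""
        got = miss_area(SpacedSeed("1" * 11), 50, 0.75, step=0.01, rule="grid")
        assert round(100 * got, 2) == 16.98

    def test_invalid_pmin(self):
        with pytest.raises(ModelError):
            miss_area(SpacedSeed("11"), 10, 1.0)


class TestSeedFileIO:
    def test_round_trip_with_comments(self, tmp_path):
        path = tmp_path / "s.seeds"
        path.write_text("# a comment\n111*1\n\n1*1  # trailing comment\n")
        ss = read_seed_file(path)
        assert [s.pattern for s in ss] == ["111*1", "1*1"]
        out = tmp_path / "o.seeds"
        write_seed_file(ss, out, header="hdr")
        assert [s.pattern for s in read_seed_file(out)] == ["111*1", "1*1"]

    def test_error_reports_line(self, tmp_path):
        path = tmp_path / "bad.seeds"
        path.write_text("111\n1*0\n")
        with pytest.raises(SeedError, match=":2"):
            read_seed_file(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.seeds"
        path.write_text("# nothing\n")
        with pytest.raises(SeedError):
            read_seed_file(path)
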