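"""Spaced seeds and their exact sensitivity under a Bernoulli alignment model.

A spaced seed is a pattern of required-match positions (``1``) and don't-care
positions (``*``).  An ungapped alignment of length *N* between an oligo and a
non-target is modelled as a random 0/1 sequence where each position is a match
independently with probability *p* (the sequence identity).  A seed *hits* the
alignment if, at some offset, every match position of the seed lines up with a
1.  The *sensitivity* of a (multiple) seed is the probability of at least one
hit; it is the quantity that decides whether a similarity-search filter will
notice a cross-hybridizing oligo.

Sensitivity is computed exactly by dynamic programming over the distribution
of the most recent alignment bits, with hit states absorbed as soon as they
appear.  ``brute_force_sensitivity`` enumerates all ``2**N`` alignments and is
kept as an independent exact reference for small *N*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "SpacedSeed",
    "SeedSet",
    "AlignmentModel",
    "SeedError",
    "ModelError",
    "sensitivity",
    "miss_area",
    "brute_force_sensitivity",
    "read_seed_file",
    "write_seed_file",
]

#: Hard cap on the DP state width (bits of match history kept).  The state
#: vector has 2**max_seed_length entries; 24 bits ≈ 134 MB of float64 which is
#: the largest we allow before demanding a shorter seed.
MAX_STATE_BITS = 24


class SeedError(ValueError):
    """Raised for syntactically or structurally invalid seed patterns."""


class ModelError(ValueError):
    """Raised for invalid alignment-model parameters (N < 1 or p outside [0,1])."""


@dataclass(frozen=True)
class SpacedSeed:
    """A single spaced seed, e.g. ``111*1**1*1**11*111`` (PatternHunter).

    The pattern must start and end with a match: leading or trailing don't-cares
    would describe the same detector with a longer nominal span.
    """

    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise SeedError("empty seed pattern")
        bad = set(self.pattern) - {"1", "*"}
        if bad:
            raise SeedError(f"seed pattern may contain only '1' and '*', got {sorted(bad)!r}")
        if self.pattern[0] != "1" or self.pattern[-1] != "1":
            raise SeedError(f"seed pattern must start and end with '1': {self.pattern!r}")

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def weight(self) -> int:
        return self.pattern.count("1")

    @property
    def match_offsets(self) -> tuple[int, ...]:
        """Offsets of the match positions, 0-based from the left end."""
        return tuple(i for i, c in enumerate(self.pattern) if c == "1")

    @classmethod
    def contiguous(cls, weight: int) -> "SpacedSeed":
        """The classical BLAST-style seed of ``weight`` consecutive matches."""
        if weight < 1:
            raise SeedError("contiguous seed weight must be >= 1")
        return cls("1" * weight)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.pattern


@dataclass(frozen=True)
class SeedSet:
    """A multiple spaced seed: a similarity is detected if any member hits.

    The conventional label is ``w{g}s{k}`` for k seeds of weight g.
    """

    seeds: tuple[SpacedSeed, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.seeds:
            raise SeedError("seed set must contain at least one seed")
        object.__setattr__(self, "seeds", tuple(self.seeds))
        patterns = [s.pattern for s in self.seeds]
        if len(set(patterns)) != len(patterns):
            raise SeedError("seed set contains duplicate patterns")

    def __iter__(self) -> Iterator[SpacedSeed]:
        return iter(self.seeds)

    def __len__(self) -> int:
        return len(self.seeds)

    @property
    def max_length(self) -> int:
        return max(s.length for s in self.seeds)

    @classmethod
    def single(cls, seed: SpacedSeed | str, label: str = "") -> "SeedSet":
        if isinstance(seed, str):
            seed = SpacedSeed(seed)
        return cls((seed,), label=label)


@dataclass(frozen=True)
class AlignmentModel:
    """Bernoulli alignment: N positions, each a match with probability p."""

    N: int
    p: float

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ModelError(f"alignment length must be >= 1, got {self.N}")
        if not (0.0 <= self.p <= 1.0):
            raise ModelError(f"identity p must lie in [0, 1], got {self.p}")


def _as_seed_set(seed_set: SeedSet | SpacedSeed | str) -> SeedSet:
    if isinstance(seed_set, SeedSet):
        return seed_set
    return SeedSet.single(seed_set)


def _right_aligned_mask(seed: SpacedSeed) -> int:
    """Bit mask of match positions with bit 0 = most recent alignment position."""
    req = 0
    for j, c in enumerate(reversed(seed.pattern)):
        if c == "1":
            req |= 1 << j
    return req


def sensitivity(seed_set: SeedSet | SpacedSeed | str, model: AlignmentModel) -> float:
    """Exact hit probability of a (multiple) spaced seed on a Bernoulli alignment.

    Seeds longer than the alignment cannot hit and are skipped.  The DP keeps
    the joint distribution of the last ``max_length`` alignment bits; mass is
    moved to an absorbing "hit" state as soon as the suffix completes any seed.
    Padding the left of the alignment with mismatches is sound because every
    seed begins with a match.
    """
    seed_set = _as_seed_set(seed_set)
    model = AlignmentModel(model.N, model.p)  # re-validate
    seeds = [s for s in seed_set if s.length <= model.N]
    if not seeds:
        return 0.0
    m = max(s.length for s in seeds)
    if m > MAX_STATE_BITS:
        raise SeedError(
            f"seed length {m} exceeds the supported DP state width ({MAX_STATE_BITS})"
        )
    size = 1 << m
    states = np.arange(size, dtype=np.int64)
    hit = np.zeros(size, dtype=bool)
    for s in seeds:
        req = _right_aligned_mask(s)
        hit |= (states & req) == req
    hit_idx = np.flatnonzero(hit)

    p = float(model.p)
    prob = np.zeros(size, dtype=np.float64)
    prob[0] = 1.0
    absorbed = 0.0
    half = size >> 1
    nxt = np.empty(size, dtype=np.float64)
    for _ in range(model.N):
        marg = prob[:half] + prob[half:]  # drop the oldest bit
        nxt[0::2] = (1.0 - p) * marg
        nxt[1::2] = p * marg
        hits = nxt[hit_idx]
        absorbed += float(hits.sum())
        nxt[hit_idx] = 0.0
        prob, nxt = nxt, prob
    return min(absorbed, 1.0)


def miss_area(
    seed_set: SeedSet | SpacedSeed | str,
    N: int,
    p_min: float,
    step: float = 0.001,
    rule: str = "trapezoid",
) -> float:
    """Average miss probability over identities in [p_min, 1].

    For an oligo filter this is the expected fraction of above-threshold
    similarities that the seed set fails to flag: the "area above the
    sensitivity curve", normalised by the width of the identity range.

    Two conventions are supported:

    ``rule="trapezoid"`` (default)
        Composite trapezoid approximation of the continuous uniform average of
        ``1 - sensitivity(p)`` over ``[p_min, 1]``, on a grid of the given
        ``step``.

    ``rule="grid"``
        The plain mean of ``1 - sensitivity(p)`` over the discrete identity
        levels ``p_min + step, p_min + 2*step, ..., 1.0`` — identity treated
        as a discrete variable binned at ``step`` resolution, each bin
        represented by its upper edge, the threshold level itself excluded.
        With ``step=0.01`` this is the whole-percent convention under which
        miss fractions of seed-sensitivity curves are customarily reported
        (e.g. 16.98% for the contiguous weight-11 seed at length 50 above 75%
        identity).
    """
    if not (0.0 <= p_min < 1.0):
        raise ModelError(f"p_min must lie in [0, 1), got {p_min}")
    n_steps = max(1, round((1.0 - p_min) / step))
    if rule == "trapezoid":
        ps = np.linspace(p_min, 1.0, n_steps + 1)
        misses = np.array([1.0 - sensitivity(seed_set, AlignmentModel(N, p)) for p in ps])
        return float(np.trapezoid(misses, ps) / (1.0 - p_min))
    if rule == "grid":
        ps = np.linspace(p_min, 1.0, n_steps + 1)[1:]
        misses = np.array([1.0 - sensitivity(seed_set, AlignmentModel(N, p)) for p in ps])
        return float(misses.mean())
    raise ValueError(f"unknown miss_area rule {rule!r}")


def brute_force_sensitivity(
    seed_set: SeedSet | SpacedSeed | str, model: AlignmentModel
) -> float:
    """Exact sensitivity by enumerating all 2**N alignments (N <= 20).

    Independent reference implementation: shares no machinery with the DP.
    """
    seed_set = _as_seed_set(seed_set)
    model = AlignmentModel(model.N, model.p)
    if model.N > 20:
        raise ModelError(f"brute force enumeration refused for N={model.N} > 20")
    N, p = model.N, float(model.p)
    vals = np.arange(1 << N, dtype=np.int64)
    hit = np.zeros(vals.shape, dtype=bool)
    for s in seed_set:
        if s.length > N:
            continue
        base = 0
        for j in s.match_offsets:
            base |= 1 << j
        for off in range(N - s.length + 1):
            req = base << off
            hit |= (vals & req) == req
    ones = np.bitwise_count(vals[hit]).astype(np.float64)
    if p == 0.0:
        # only the all-zero alignment has mass, and it is never hit
        return float(hit[0])
    if p == 1.0:
        return float(hit[-1])
    logw = ones * math.log(p) + (N - ones) * math.log1p(-p)
    return float(np.exp(logw).sum())


# ---------------------------------------------------------------------------
# seed file I/O: one pattern per line, '#' comments, blank lines ignored

def read_seed_file(path: str | Path, label: str = "") -> SeedSet:
    """Read a seed set from a plain-text file (one ``1``/``*`` pattern per line)."""
    path = Path(path)
    seeds: list[SpacedSeed] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            seeds.append(SpacedSeed(line))
        except SeedError as exc:
            raise SeedError(f"{path}:{lineno}: {exc}") from exc
    if not seeds:
        raise SeedError(f"{path}: no seed patterns found")
    return SeedSet(tuple(seeds), label=label or path.stem)


def write_seed_file(seed_set: SeedSet | Iterable[SpacedSeed], path: str | Path,
                    header: str | None = None) -> None:
    path = Path(path)
    lines = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    seeds: Sequence[SpacedSeed] = (
        seed_set.seeds if isinstance(seed_set, SeedSet) else tuple(seed_set)
    )
    lines.extend(s.pattern for s in seeds)
    path.write_text("\n".join(lines) + "\n")
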