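"""Design of multiple spaced seed sets by overlap-complexity minimisation.

Finding the most sensitive multiple spaced seed is hard, but the *overlap
complexity* of a seed pair — the sum over all relative shifts of
``2**(number of aligned match-match positions)`` — is a cheap proxy that
correlates strongly (inversely) with sensitivity: seed sets whose members
overlap little cover a random alignment's match positions more independently.
The designer here draws random seeds of the requested weight, then hill-climbs
by moving single match positions to minimise the total overlap complexity of
the set (all pairs, self-overlap included), with random restarts.  Sensitivity
of the winning set is then verified with the exact DP from :mod:`bond.seeds`.

The shipped default sets (``w10s8`` for screening, ``w9s8`` for verification,
``w8s16`` for evaluation) were produced by this designer with fixed RNG seeds;
they are data, and any user-supplied seed file can replace them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seeds import AlignmentModel, SeedError, SeedSet, SpacedSeed, sensitivity

__all__ = [
    "SeedDesignSpec",
    "DesignInfeasibleError",
    "overlap_complexity",
    "total_overlap_complexity",
    "design_seed_set",
]


class DesignInfeasibleError(ValueError):
    """Raised when the requested seed set cannot exist (e.g. too many distinct seeds)."""


@dataclass(frozen=True)
class SeedDesignSpec:
    """Parameters of one design run.

    ``length_range`` is inclusive; seed lengths are spread evenly across it,
    which keeps hit positions of different seeds from synchronising.
    """

    weight: int
    count: int
    length_range: tuple[int, int]
    model: AlignmentModel = field(default_factory=lambda: AlignmentModel(50, 0.75))
    random_seed: int = 0
    restarts: int = 3

    def __post_init__(self) -> None:
        if self.weight < 1:
            raise DesignInfeasibleError("seed weight must be >= 1")
        if self.count < 1:
            raise DesignInfeasibleError("seed count must be >= 1")
        lo, hi = self.length_range
        if not (self.weight <= lo <= hi <= 64):
            raise DesignInfeasibleError(
                f"length_range {self.length_range} must lie within [{self.weight}, 64]"
            )


def _ones_vector(seed: SpacedSeed) -> np.ndarray:
    return np.frombuffer(seed.pattern.encode(), dtype=np.uint8) == ord("1")


def overlap_complexity(a: SpacedSeed, b: SpacedSeed) -> int:
    """Sum over all relative shifts of ``2**(aligned match-match positions)``.

    Symmetric in its arguments; ``len(a) + len(b) - 1`` shifts contribute.
    """
    va = _ones_vector(a).astype(np.int64)
    vb = _ones_vector(b).astype(np.int64)
    counts = np.correlate(va, vb, mode="full")
    return int((1 << counts.astype(np.int64)).sum())


def total_overlap_complexity(seeds: list[SpacedSeed]) -> int:
    """Total score of a set: all unordered pairs plus each seed's self-overlap."""
    total = 0
    for i, a in enumerate(seeds):
        for b in seeds[i:]:
            total += overlap_complexity(a, b)
    return total


def _pattern_from_mask(mask: np.ndarray) -> str:
    return "".join("1" if m else "*" for m in mask)


def _random_seed_mask(rng: np.random.Generator, weight: int, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    mask[0] = mask[-1] = True
    if weight > 2:
        interior = rng.choice(np.arange(1, length - 1), size=weight - 2, replace=False)
        mask[interior] = True
    return mask


def _n_patterns(weight: int, length: int) -> int:
    """Distinct seed patterns of given weight/length with both ends matching."""
    from math import comb

    if weight == 1:
        return 1 if length == 1 else 0
    if length < 2:
        return 0
    return comb(length - 2, weight - 2)


def _seed_lengths(spec: SeedDesignSpec, rng: np.random.Generator) -> list[int]:
    lo, hi = spec.length_range
    if spec.weight == 1:
        return [1] * spec.count
    if spec.count == 1:
        return [hi]
    # deterministic even spread over the range, longest first
    return [round(hi - i * (hi - lo) / (spec.count - 1)) for i in range(spec.count)]


def _pair_score(mask: np.ndarray, others: list[np.ndarray]) -> int:
    """Overlap complexity of one seed against a set (self-term included)."""
    v = mask.astype(np.int64)
    total = int((1 << np.correlate(v, v, mode="full").astype(np.int64)).sum())
    for o in others:
        counts = np.correlate(v, o.astype(np.int64), mode="full")
        total += int((1 << counts.astype(np.int64)).sum())
    return total


def _climb(masks: list[np.ndarray], rng: np.random.Generator, max_sweeps: int = 60) -> None:
    """Steepest-descent moves of single interior match positions, in place."""
    k = len(masks)
    for _ in range(max_sweeps):
        improved = False
        for i in range(k):
            mask = masks[i]
            others = [masks[j] for j in range(k) if j != i]
            best = _pair_score(mask, others)
            best_move: tuple[int, int] | None = None
            ones = np.flatnonzero(mask[1:-1]) + 1
            stars = np.flatnonzero(~mask[1:-1]) + 1
            for o in ones:
                for s in stars:
                    mask[o] = False
                    mask[s] = True
                    score = _pair_score(mask, others)
                    mask[s] = False
                    mask[o] = True
                    if score < best:
                        best = score
                        best_move = (int(o), int(s))
            if best_move is not None:
                o, s = best_move
                mask[o] = False
                mask[s] = True
                improved = True
        if not improved:
            return


def design_seed_set(spec: SeedDesignSpec) -> SeedSet:
    """Design a multiple spaced seed set; deterministic for a fixed ``random_seed``.

    Raises :class:`DesignInfeasibleError` if ``count`` distinct seeds of the
    requested weight cannot exist within ``length_range``.
    """
    lo, hi = spec.length_range
    available = sum(_n_patterns(spec.weight, length) for length in range(lo, hi + 1))
    if spec.count > available:
        raise DesignInfeasibleError(
            f"{spec.count} distinct seeds of weight {spec.weight} do not exist "
            f"in length range {spec.length_range}"
        )

    best_masks: list[np.ndarray] | None = None
    best_score = None
    for restart in range(max(1, spec.restarts)):
        rng = np.random.default_rng(np.random.SeedSequence([spec.random_seed, restart]))
        lengths = _seed_lengths(spec, rng)
        masks = []
        seen: set[str] = set()
        for length in lengths:
            for _ in range(1000):
                m = (
                    np.ones(length, dtype=bool)
                    if spec.weight >= length
                    else _random_seed_mask(rng, spec.weight, length)
                )
                pat = _pattern_from_mask(m)
                if pat not in seen:
                    seen.add(pat)
                    masks.append(m)
                    break
            else:  # pragma: no cover - defensive
                raise DesignInfeasibleError("could not draw distinct starting seeds")
        _climb(masks, rng)
        if len({_pattern_from_mask(m) for m in masks}) != len(masks):
            continue  # climbing collapsed two seeds onto the same pattern
        score = total_overlap_complexity([SpacedSeed(_pattern_from_mask(m)) for m in masks])
        if best_score is None or score < best_score:
            best_score = score
            best_masks = [m.copy() for m in masks]
    if best_masks is None:
        raise DesignInfeasibleError("no restart produced a set of distinct seeds")
    seeds = tuple(SpacedSeed(_pattern_from_mask(m)) for m in best_masks)
    return SeedSet(seeds, label=f"w{spec.weight}s{spec.count}")
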