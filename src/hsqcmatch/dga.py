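"""Discrete genetic algorithm (DGA) over unique peak matchings.

The DGA searches the space of injective index vectors (see
:mod:`hsqcmatch.metric`) for the assignment minimizing the raw cost ε_S,
then scores the winner with the outlier-aware three-level metric. The
encoding and operators follow the travelling-salesman style of discrete
GA: value-exchange and small-derangement mutations (EXC, L3O, L4O, plus
EXON when spare target slots exist), and bit-mask crossovers (RX,
BURSTRAND, SINGLEBURST) combined with an order-based fill that preserves
validity.

Selection is greedy: a mutant replaces its parent, and a crossover child
replaces the current worst member, only when strictly cheaper — so the
best member is never lost (elitism) and the best cost is monotonically
non-increasing. The search is probabilistic; a fixed seed makes it
bit-reproducible. Named presets trade effort for symmetry of the
resulting similarity matrix: small (K=2, G_max=5·N_big), medium (K=5,
G_max=10·N_big), large (K=20, G_max=50·N_big), with N_big = max(N, M).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as _k
from .metric import (
    DEFAULT_S_FACTOR,
    MatchEvaluation,
    Matching,
    _distance_matrix,
    match_cost,
    refine_matching,
)
from .spectra import Spectrum

__all__ = [
    "GAConfig",
    "Population",
    "DGAResult",
    "OperatorInapplicableError",
    "MUTATION_KINDS",
    "MASK_KINDS",
    "PRESETS",
    "init_population",
    "mutate",
    "crossover_mask",
    "crossover_combine",
    "evolve",
    "dga_similarity",
]

MUTATION_KINDS = ("EXC", "L3O", "L4O", "EXON")
MASK_KINDS = ("RX", "BURSTRAND", "SINGLEBURST")

#: preset name -> (population size K, G_max multiplier)
PRESETS: dict[str, tuple[int, int]] = {
    "small": (2, 5),
    "medium": (5, 10),
    "large": (20, 50),
}


class OperatorInapplicableError(ValueError):
    """An operator's precondition is not met (caller picks another)."""


@dataclass
class GAConfig:
    """DGA parameters.

    ``preset`` (small/medium/large), when given, fixes ``k_population``
    and ``gmax_multiplier``. G_max = gmax_multiplier × max(N, M).
    ``s_factor`` is the outlier rejection multiple S of the three-level
    metric; ``mutation_sweeps`` is the number of full mutation passes
    over the population per generation.
    """

    k_population: int = 5
    gmax_multiplier: int = 10
    s_factor: float = DEFAULT_S_FACTOR
    mutation_sweeps: int = 5
    seed: int | None = None
    preset: str | None = None

    def __post_init__(self) -> None:
        if self.preset is not None:
            try:
                self.k_population, self.gmax_multiplier = PRESETS[self.preset]
            except KeyError:
                raise ValueError(
                    f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}"
                ) from None
        if self.k_population < 2:
            raise ValueError("k_population must be at least 2")
        if self.gmax_multiplier < 1:
            raise ValueError("gmax_multiplier must be at least 1")
        if self.mutation_sweeps < 1:
            raise ValueError("mutation_sweeps must be at least 1")

    def gmax(self, n_big: int) -> int:
        return self.gmax_multiplier * n_big


@dataclass
class Population:
    """A snapshot of the GA population with its evaluation bookkeeping."""

    members: list[Matching]
    costs: np.ndarray
    best: int  # index of the minimum-cost member
    nfe: int  # cumulative number of cost evaluations
    generations: int = 0  # generations actually run (early exit possible)

    @property
    def best_matching(self) -> Matching:
        return self.members[self.best]

    @property
    def best_cost(self) -> float:
        return float(self.costs[self.best])


@dataclass(frozen=True)
class DGAResult:
    """Outcome of a DGA similarity computation for one ordered pair."""

    final_score: float
    evaluation: MatchEvaluation
    nfe: int
    matching: Matching
    generations: int
    seed: int | None


def _wrap_members(p: Spectrum, q: Spectrum, pop: np.ndarray) -> list[Matching]:
    return [
        Matching(
            p_id=p.compound_id, q_id=q.compound_id, assignment=row.copy(),
            n_source=len(p), n_target=len(q),
        )
        for row in pop
    ]


def init_population(
    p: Spectrum, q: Spectrum, cfg: GAConfig
) -> Population:
    """K uniformly random valid matchings, evaluated, seeded by cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    universe = max(len(p), len(q))
    rows = np.stack(
        [_k.random_injection(len(p), universe, rng) for _ in range(cfg.k_population)]
    )
    members = _wrap_members(p, q, rows)
    costs = np.array([match_cost(p, q, m).epsilon_s for m in members])
    return Population(
        members=members, costs=costs, best=int(np.argmin(costs)),
        nfe=cfg.k_population,
    )


def mutate(m: Matching, kind: str, rng: np.random.Generator) -> Matching:
    """Apply one mutation of the given kind, returning a new Matching.

    EXC swaps two random positions; L3O/L4O derange three/four random
    positions; EXON (only when N < M) moves one position onto an unused
    target slot. Raises :class:`OperatorInapplicableError` when the
    kind's precondition fails, so a caller can pick another operator.
    """
    n, mt = m.n_source, m.n_target
    j = m.assignment.copy()
    if kind == "EXC":
        if n < 2:
            raise OperatorInapplicableError("EXC needs at least 2 positions")
        _k.mutate_exc(j, rng)
    elif kind == "L3O":
        if n < 3:
            raise OperatorInapplicableError("L3O needs at least 3 positions")
        _k.mutate_l3o(j, rng)
    elif kind == "L4O":
        if n < 4:
            raise OperatorInapplicableError("L4O needs at least 4 positions")
        _k.mutate_l4o(j, rng)
    elif kind == "EXON":
        if n >= mt:
            raise OperatorInapplicableError("EXON needs N < M (a spare target slot)")
        _k.mutate_exon(j, mt, rng)
    else:
        raise ValueError(f"unknown mutation kind {kind!r}; choose from {MUTATION_KINDS}")
    return Matching(
        p_id=m.p_id, q_id=m.q_id, assignment=j, n_source=n, n_target=mt
    )


def crossover_mask(kind: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Generate a crossover bit mask of length n (dtype uint8).

    RX: iid fair bits. BURSTRAND: first bit fair, then each bit disagrees
    with its predecessor with probability 2/n (bursty-channel noise).
    SINGLEBURST: a single cyclic block of ones of length uniform in
    [3, n] starting at a uniform position (requires n ≥ 3).
    """
    if n < 1:
        raise ValueError("mask length must be at least 1")
    if kind == "RX":
        return _k.mask_rx(n, rng)
    if kind == "BURSTRAND":
        return _k.mask_burstrand(n, rng)
    if kind == "SINGLEBURST":
        if n < 3:
            raise OperatorInapplicableError("SINGLEBURST needs mask length >= 3")
        return _k.mask_singleburst(n, rng)
    raise ValueError(f"unknown mask kind {kind!r}; choose from {MASK_KINDS}")


def crossover_combine(a: Matching, b: Matching, mask: np.ndarray) -> Matching:
    """Combine two parents under a bit mask with order-based fill.

    The child copies a's value where the mask is 1 and fills the
    remaining positions left-to-right from b's sequence, skipping values
    already present (falling back to unused slots in ascending order).
    Always yields a valid Matching.
    """
    if (a.n_source, a.n_target) != (b.n_source, b.n_target):
        raise ValueError("parents must encode matchings of the same spectra pair")
    mask = np.asarray(mask, dtype=np.uint8)
    if mask.shape != (a.n_source,):
        raise ValueError(f"mask must have length {a.n_source}")
    universe = max(a.n_source, a.n_target)
    child = _k.combine(a.assignment, b.assignment, mask, universe)
    return Matching(
        p_id=a.p_id, q_id=a.q_id, assignment=child,
        n_source=a.n_source, n_target=a.n_target,
    )


def evolve(p: Spectrum, q: Spectrum, cfg: GAConfig) -> tuple[Matching, Population]:
    """Run the full evolution loop; returns (best matching, population).

    Works for either orientation of the pair: when N > M the encoding
    parks |N−M| source peaks on dummy slots at zero cost. NFE counts
    every raw-cost evaluation: K at initialization plus, per generation,
    one per mutant (sweeps×K) and one per crossover child (K).
    """
    rng = np.random.default_rng(cfg.seed)
    d = _distance_matrix(p, q)
    gmax = cfg.gmax(max(len(p), len(q)))
    pop, costs, best, nfe, gens = _k.evolve_kernel(
        d, cfg.k_population, gmax, cfg.mutation_sweeps, rng
    )
    population = Population(
        members=_wrap_members(p, q, pop),
        costs=costs,
        best=best,
        nfe=int(nfe),
        generations=int(gens),
    )
    return population.best_matching, population


def dga_similarity(p: Spectrum, q: Spectrum, cfg: GAConfig | None = None) -> DGAResult:
    """Evolve a matching for (p, q) and score it with the three-level metric."""
    if cfg is None:
        cfg = GAConfig()
    best, population = evolve(p, q, cfg)
    ev = refine_matching(p, q, best, cfg.s_factor)
    return DGAResult(
        final_score=float(ev.final_score),
        evaluation=ev,
        nfe=population.nfe,
        matching=best,
        generations=population.generations,
        seed=cfg.seed,
    )
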