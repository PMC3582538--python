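"""Unique-matching cost, exact assignment oracle, and the three-level metric.

A *matching* between spectra p (N peaks) and q (M peaks) is an injective
index vector j of length N over slots 0..max(N,M)−1: peak n of p is
matched to peak j[n] of q when j[n] < M, and is unmatched otherwise (only
possible when N > M; exactly |N−M| peaks end up unmatched on the larger
side). The raw assignment cost ε_S is the sum of matched pair distances;
unmatched peaks cost nothing at this level.

The refined similarity score applies three levels:

1. matched-pair distances (ε_S contributions);
2. outlier rejection — pairs whose distance exceeds mean + S·σ of the
   matched distances are dropped and BOTH endpoint peaks are rematched to
   their nearest neighbour in the opposite spectrum (a single long
   cross-region match would otherwise dominate the mean);
3. unmatched-peak penalty — each of the |N−M| unmatched peaks contributes
   its nearest-neighbour distance to the opposite spectrum.

The final score is the mean over all contributions, i.e. a refined mean
distance per peak; the contribution count is
(#kept pairs) + 2·(#outlier pairs) + |N−M|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .spectra import Spectrum, _check_same_scheme

__all__ = [
    "Matching",
    "MatchEvaluation",
    "InvalidMatchingError",
    "match_cost",
    "optimal_assignment",
    "detect_outliers",
    "refine_matching",
]

DEFAULT_S_FACTOR = 2.5


class InvalidMatchingError(ValueError):
    """Raised when an index vector is not a valid unique matching."""


@dataclass(frozen=True)
class Matching:
    """An injective peak assignment between two spectra.

    ``assignment`` holds N pairwise-distinct 0-based integers. When
    N < M they lie in [0, M); when N ≥ M they lie in [0, N) and entries
    ≥ M mark unmatched peaks of p.
    """

    p_id: str
    q_id: str
    assignment: np.ndarray
    n_source: int  # N
    n_target: int  # M

    def __post_init__(self) -> None:
        j = np.asarray(self.assignment, dtype=np.int64)
        object.__setattr__(self, "assignment", j)
        validate_assignment(j, self.n_source, self.n_target)

    @property
    def matched(self) -> np.ndarray:
        """Boolean mask over source peaks: True where j[n] < M."""
        return self.assignment < self.n_target


def validate_assignment(j: np.ndarray, n: int, m: int) -> None:
    """Check uniqueness and range of an index vector; raise if invalid."""
    if j.shape != (n,):
        raise InvalidMatchingError(f"assignment must have length {n}, got {j.shape}")
    hi = max(n, m)
    if j.min(initial=0) < 0 or j.max(initial=-1) >= hi:
        raise InvalidMatchingError(
            f"assignment entries must lie in [0, {hi}), got range "
            f"[{j.min()}, {j.max()}]"
        )
    if len(np.unique(j)) != n:
        raise InvalidMatchingError("assignment entries must be pairwise distinct")


@dataclass(frozen=True)
class MatchEvaluation:
    """Per-pair distances and (optionally) the refined three-level score.

    ``pair_distances``/``epsilon_s`` are always present. The remaining
    fields are populated by :func:`refine_matching`; :func:`match_cost`
    leaves them None (cost-only evaluation).
    """

    p_id: str
    q_id: str
    pair_distances: np.ndarray  # distances of matched pairs, source order
    epsilon_s: float
    mean_d: float | None = None
    sigma_d: float | None = None
    outlier_flags: np.ndarray | None = None  # aligned with pair_distances
    final_score: float | None = None
    n_contributions: int | None = None


def _distance_matrix(p: Spectrum, q: Spectrum) -> np.ndarray:
    _check_same_scheme(p, q)
    return cdist(p.coords, q.coords)


def match_cost(p: Spectrum, q: Spectrum, m: Matching) -> MatchEvaluation:
    """Evaluate the raw assignment cost ε_S of a matching (level 1 only)."""
    if m.n_source != len(p) or m.n_target != len(q):
        raise InvalidMatchingError(
            f"matching shaped ({m.n_source},{m.n_target}) does not fit spectra "
            f"({len(p)},{len(q)})"
        )
    d = _distance_matrix(p, q)
    matched = m.matched
    dists = d[np.nonzero(matched)[0], m.assignment[matched]]
    return MatchEvaluation(
        p_id=p.compound_id,
        q_id=q.compound_id,
        pair_distances=dists,
        epsilon_s=float(dists.sum()),
    )


def optimal_assignment(p: Spectrum, q: Spectrum) -> tuple[Matching, float]:
    """Exact minimum-cost unique matching (rectangular assignment).

    Solves the linear assignment problem on the pairwise distance matrix.
    All peaks of the smaller spectrum are matched; unmatched peaks of the
    larger spectrum cost 0, consistent with the raw cost ε_S. Serves as
    the deterministic optimum the genetic algorithm is benchmarked
    against.
    """
    d = _distance_matrix(p, q)
    n, m = d.shape
    j = np.empty(n, dtype=np.int64)
    if n <= m:
        rows, cols = linear_sum_assignment(d)
        j[rows] = cols
    else:
        rows, cols = linear_sum_assignment(d)  # matches all m columns
        j.fill(-1)
        j[rows] = cols
        # park unmatched source peaks on distinct dummy slots in [m, n)
        j[j < 0] = np.arange(m, n)
    matching = Matching(
        p_id=p.compound_id, q_id=q.compound_id, assignment=j,
        n_source=n, n_target=m,
    )
    cost = float(d[rows, cols].sum())
    return matching, cost


def detect_outliers(
    pair_distances: np.ndarray | MatchEvaluation,
    s_factor: float = DEFAULT_S_FACTOR,
) -> np.ndarray:
    """Flag matched pairs whose distance exceeds mean + S·σ.

    σ is the population (divide-by-n) standard deviation over the matched
    pair distances — stable for the small pair counts involved. The
    criterion is one-sided (only unusually long matches are outliers) and
    applied in a single pass. With fewer than 3 matched pairs the
    statistics are meaningless and nothing is flagged.
    """
    if isinstance(pair_distances, MatchEvaluation):
        pair_distances = pair_distances.pair_distances
    d = np.asarray(pair_distances, dtype=np.float64)
    if d.size < 1:
        raise ValueError("need at least one matched pair")
    if s_factor <= 0:
        raise ValueError(f"s_factor must be positive, got {s_factor}")
    if d.size < 3:
        return np.zeros(d.size, dtype=bool)
    mean = d.mean()
    sigma = d.std()  # population standard deviation
    return d > mean + s_factor * sigma


def refine_matching(
    p: Spectrum,
    q: Spectrum,
    m: Matching,
    s_factor: float | None = DEFAULT_S_FACTOR,
) -> MatchEvaluation:
    """Apply the full three-level metric to a matching.

    Pass ``s_factor=None`` to disable outlier handling (level 2), in
    which case every matched pair is kept; levels 1 and 3 still apply.
    """
    if m.n_source != len(p) or m.n_target != len(q):
        raise InvalidMatchingError(
            f"matching shaped ({m.n_source},{m.n_target}) does not fit spectra "
            f"({len(p)},{len(q)})"
        )
    d = _distance_matrix(p, q)
    n, mm = d.shape
    matched_src = np.nonzero(m.matched)[0]
    matched_tgt = m.assignment[m.matched]
    dists = d[matched_src, matched_tgt]
    mean_d = float(dists.mean())
    sigma_d = float(dists.std())

    if s_factor is None:
        flags = np.zeros(dists.size, dtype=bool)
    else:
        flags = detect_outliers(dists, s_factor)

    nn_to_q = d.min(axis=1)  # per p-peak nearest distance into q
    nn_to_p = d.min(axis=0)  # per q-peak nearest distance into p

    contributions: list[float] = list(dists[~flags])
    # level 2: each dropped pair is replaced by two directed NN distances
    for src, tgt in zip(matched_src[flags], matched_tgt[flags]):
        contributions.append(float(nn_to_q[src]))
        contributions.append(float(nn_to_p[tgt]))
    # level 3: unmatched peaks of the larger spectrum pay their NN distance
    if n > mm:
        for src in np.nonzero(~m.matched)[0]:
            contributions.append(float(nn_to_q[src]))
    elif mm > n:
        unmatched_q = np.setdiff1d(np.arange(mm), matched_tgt, assume_unique=False)
        for tgt in unmatched_q:
            contributions.append(float(nn_to_p[tgt]))

    n_contrib = len(contributions)
    assert n_contrib == (dists.size - flags.sum()) + 2 * flags.sum() + abs(n - mm)
    return MatchEvaluation(
        p_id=p.compound_id,
        q_id=q.compound_id,
        pair_distances=dists,
        epsilon_s=float(dists.sum()),
        mean_d=mean_d,
        sigma_d=sigma_d,
        outlier_flags=flags,
        final_score=float(np.sum(contributions) / n_contrib),
        n_contributions=n_contrib,
    )
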