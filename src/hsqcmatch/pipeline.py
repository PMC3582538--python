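"""Library-scale comparison machinery for compound screening.

Given a compound library this module builds all-pairs similarity
matrices for the three comparators (MFP = Tanimoto fingerprints, NN =
nearest-neighbour spectral score, DGA = genetic-algorithm spectral
score), measures how symmetric a stochastic matrix is (the convergence
check for the DGA presets), bins scores into the six ranking categories,
selects top-k / thresholded hit lists, and intersects per-method hit
lists into a consensus (Venn) report.

Conventions: a C-compound library gives a C×C score grid whose entry
(r, c) is the score of matching compound r against compound c — the
upper triangle holds p→q matches and the lower triangle q→p. The
diagonal is self-similarity (0 for NN/DGA distances, 1 for MFP) and is
excluded from all statistics. The C·(C−1)/2 unordered pairs are the unit
of reporting; an unordered pair's score is by default the WORSE of its
two orientations (max for distance scores, min for MFP), a conservative
reduction that avoids crediting one lucky orientation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dga import GAConfig, dga_similarity
from .fingerprints import Fingerprint, tanimoto
from .nn import nn_similarity
from .spectra import Spectrum

__all__ = [
    "SimilarityMatrix",
    "CategoryScheme",
    "DEFAULT_SCHEMES",
    "build_matrix",
    "symmetry_error_rate",
    "categorize",
    "top_k_pairs",
    "mfp_threshold_pairs",
    "consensus",
    "ConsensusResult",
    "score_histogram",
]

METHODS = ("mfp", "nn", "dga")
#: methods where smaller scores mean more similar
_DISTANCE_LIKE = frozenset({"nn", "dga"})


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered-pair key (sorted id tuple)."""
    return (a, b) if a <= b else (b, a)


@dataclass
class SimilarityMatrix:
    """All ordered-pair scores of one method over a compound library."""

    method: str
    ids: list[str]
    scores: np.ndarray  # C×C; (r, c) = score of ids[r] -> ids[c]

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        self.scores = np.asarray(self.scores, dtype=np.float64)
        c = len(self.ids)
        if self.scores.shape != (c, c):
            raise ValueError(
                f"scores must be {c}×{c} to match {c} ids, got {self.scores.shape}"
            )

    @property
    def n_compounds(self) -> int:
        return len(self.ids)

    @property
    def n_unordered_pairs(self) -> int:
        c = self.n_compounds
        return c * (c - 1) // 2

    def pair_score(self, r: int, c: int, reduction: str = "worse") -> float:
        """Reduce the two orientation scores of an unordered pair to one.

        ``worse`` (default) keeps the less favourable orientation,
        ``better`` the more favourable, ``mean`` their average.
        """
        up, lo = self.scores[r, c], self.scores[c, r]
        if reduction == "mean":
            return float((up + lo) / 2.0)
        worse_is_max = self.method in _DISTANCE_LIKE
        if reduction == "worse":
            return float(max(up, lo) if worse_is_max else min(up, lo))
        if reduction == "better":
            return float(min(up, lo) if worse_is_max else max(up, lo))
        raise ValueError(f"unknown reduction {reduction!r}")

    def unordered_scores(self, reduction: str = "worse") -> pd.DataFrame:
        """One row per unordered pair: id_a, id_b, score."""
        rows = [
            (self.ids[r], self.ids[c], self.pair_score(r, c, reduction))
            for r, c in itertools.combinations(range(self.n_compounds), 2)
        ]
        return pd.DataFrame(rows, columns=["id_a", "id_b", "score"])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.scores, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, method: str) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(method=method, ids=[str(i) for i in df.index], scores=df.to_numpy())


def _pair_seed(master: int, r: int, c: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master) & 0x7FFFFFFF, r, c])


def build_matrix(
    items: Sequence[Spectrum] | Sequence[Fingerprint],
    method: str,
    cfg: GAConfig | None = None,
    master_seed: int = 0,
) -> SimilarityMatrix:
    """Score all C×(C−1) ordered pairs of a library with one method.

    Both orientations are computed even for symmetric methods — the
    upper/lower discrepancy of the stochastic DGA is exactly what the
    symmetry check measures. For the DGA each ordered pair gets its own
    seed derived deterministically from ``master_seed`` (or ``cfg.seed``
    when set) and the pair's position, so the matrix is reproducible and
    the two orientations are independent runs.
    """
    items = list(items)
    c = len(items)
    if c < 2:
        raise ValueError("need at least 2 compounds")
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    ids = [it.compound_id for it in items]
    if len(set(ids)) != c:
        raise ValueError("compound ids must be unique")
    scores = np.zeros((c, c), dtype=np.float64)

    if method == "mfp":
        np.fill_diagonal(scores, 1.0)
        for r, cc in itertools.permutations(range(c), 2):
            scores[r, cc] = tanimoto(items[r], items[cc])
        return SimilarityMatrix(method=method, ids=ids, scores=scores)

    schemes = {sp.scheme for sp in items}
    if len(schemes) != 1:
        raise ValueError("all spectra must share one normalization scheme")

    if method == "nn":
        for r, cc in itertools.permutations(range(c), 2):
            scores[r, cc] = nn_similarity(items[r], items[cc])
        return SimilarityMatrix(method=method, ids=ids, scores=scores)

    if cfg is None:
        cfg = GAConfig(preset="medium")
    master = cfg.seed if cfg.seed is not None else master_seed
    for r, cc in itertools.permutations(range(c), 2):
        seed = int(_pair_seed(master, r, cc).generate_state(1)[0] & 0x7FFFFFFF)
        pair_cfg = GAConfig(
            k_population=cfg.k_population,
            gmax_multiplier=cfg.gmax_multiplier,
            s_factor=cfg.s_factor,
            mutation_sweeps=cfg.mutation_sweeps,
            seed=seed,
        )
        scores[r, cc] = dga_similarity(items[r], items[cc], pair_cfg).final_score
    return SimilarityMatrix(method=method, ids=ids, scores=scores)


def symmetry_error_rate(
    m: SimilarityMatrix, tolerance: float = 1e-9
) -> tuple[int, float]:
    """Count unordered pairs whose two orientations disagree.

    A pair is discordant when |score(p→q) − score(q→p)| exceeds
    ``tolerance``. Returns (n_differences, rate in percent of the
    C·(C−1)/2 unordered pairs); callers report the rate to one decimal.
    """
    c = m.n_compounds
    upper = m.scores[np.triu_indices(c, k=1)]
    lower = m.scores.T[np.triu_indices(c, k=1)]
    n_diff = int(np.sum(np.abs(upper - lower) > tolerance))
    return n_diff, 100.0 * n_diff / m.n_unordered_pairs


@dataclass(frozen=True)
class CategoryScheme:
    """Six ranking categories per method; category 1 is the most similar.

    ``cutoffs`` holds the five boundaries between categories. For the
    distance scores (NN/DGA) they ascend and bins are half-open
    [lo, hi); for MFP they descend and the top bin is closed ([0.9, 1.0]).
    """

    method: str
    cutoffs: tuple[float, float, float, float, float]


DEFAULT_SCHEMES: dict[str, CategoryScheme] = {
    "mfp": CategoryScheme("mfp", (0.9, 0.8, 0.7, 0.6, 0.5)),
    "nn": CategoryScheme("nn", (0.0076, 0.0152, 0.0228, 0.0304, 0.0380)),
    "dga": CategoryScheme("dga", (0.0098, 0.0196, 0.0294, 0.0392, 0.0490)),
}


def categorize(score: float, method: str, scheme: CategoryScheme | None = None) -> int:
    """Bin a score into ranking categories 1 (most similar) to 6."""
    if scheme is None:
        try:
            scheme = DEFAULT_SCHEMES[method]
        except KeyError:
            raise ValueError(f"no default category scheme for method {method!r}") from None
    if method == "mfp":
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"MFP score must lie in [0, 1], got {score}")
        for cat, cut in enumerate(scheme.cutoffs, start=1):
            if score >= cut:
                return cat
        return 6
    if score < 0.0:
        raise ValueError(f"{method.upper()} score must be nonnegative, got {score}")
    return 1 + int(np.searchsorted(np.asarray(scheme.cutoffs), score, side="right"))


def top_k_pairs(
    m: SimilarityMatrix, k: int, reduction: str = "worse"
) -> tuple[list[tuple[str, str, float]], float]:
    """The k most similar unordered pairs and the k-th score as threshold.

    Ranking is ascending for the distance scores (NN/DGA) and descending
    for MFP. Pairs tied with the k-th score are all included, so the
    returned list can overrun k; callers can detect the overrun from its
    length.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > m.n_unordered_pairs:
        raise ValueError(
            f"k={k} exceeds the {m.n_unordered_pairs} unordered pairs"
        )
    df = m.unordered_scores(reduction)
    ascending = m.method in _DISTANCE_LIKE
    df = df.sort_values("score", ascending=ascending, kind="mergesort")
    threshold = float(df["score"].iloc[k - 1])
    if ascending:
        keep = df[df["score"] <= threshold]
    else:
        keep = df[df["score"] >= threshold]
    return (
        [(r.id_a, r.id_b, float(r.score)) for r in keep.itertuples()],
        threshold,
    )


def mfp_threshold_pairs(
    m: SimilarityMatrix, t_c: float = 0.7, reduction: str = "worse"
) -> list[tuple[str, str, float]]:
    """All unordered pairs with Tanimoto similarity ≥ t_c."""
    df = m.unordered_scores(reduction)
    keep = df[df["score"] >= t_c].sort_values("score", ascending=False)
    return [(r.id_a, r.id_b, float(r.score)) for r in keep.itertuples()]


@dataclass
class ConsensusResult:
    """Venn partition of per-method hit lists.

    ``regions`` maps each nonempty method subset (frozenset of method
    names) to the pairs found by exactly those methods; ``significant``
    are the pairs found by at least two methods.
    """

    regions: dict[frozenset, set]
    significant: set

    def region(self, *methods: str) -> set:
        return self.regions.get(frozenset(methods), set())


def consensus(sets: Mapping[str, Iterable]) -> ConsensusResult:
    """Intersect per-method hit lists into Venn regions.

    ``sets`` maps method name → iterable of unordered-pair keys (use
    :func:`pair_key` to canonicalize). Requires at least two methods;
    with three methods the partition has the usual 7 regions.
    """
    named = {name: {pair_key(*p) if isinstance(p, tuple) else p for p in pairs}
             for name, pairs in sets.items()}
    if len(named) < 2:
        raise ValueError("consensus needs at least two methods")
    all_pairs = set().union(*named.values())
    regions: dict[frozenset, set] = {
        frozenset(combo): set()
        for r in range(1, len(named) + 1)
        for combo in itertools.combinations(named, r)
    }
    significant: set = set()
    for pair in all_pairs:
        members = frozenset(name for name, s in named.items() if pair in s)
        regions[members].add(pair)
        if len(members) >= 2:
            significant.add(pair)
    return ConsensusResult(regions=regions, significant=significant)


def score_histogram(
    m: SimilarityMatrix,
    bins: int | Sequence[float] = 20,
    reduction: str = "worse",
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of the unordered-pair scores; counts sum to C·(C−1)/2."""
    scores = m.unordered_scores(reduction)["score"].to_numpy()
    return np.histogram(scores, bins=bins)
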