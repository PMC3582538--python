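"""Bidirectional nearest-neighbour (NN) matching of HSQC peak lists.

Each peak of spectrum p is matched to its nearest peak in q and vice
versa; the similarity score is the mean of all N+M directed nearest
distances. Matching is many-to-one (a popular peak may be the nearest
neighbour of several peaks), deterministic, and the score is symmetric
by construction. Smaller scores mean more similar spectra; identical
spectra score exactly 0.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .spectra import Spectrum, _check_same_scheme

__all__ = ["nn_directed", "nn_similarity"]


def nn_directed(
    source: Spectrum, target: Spectrum
) -> list[tuple[int, int, float]]:
    """Match every source peak to its nearest target peak.

    Returns one ``(source_index, target_index, distance)`` triple per
    source peak (0-based indices). Ties are broken toward the lowest
    target index, which keeps the output deterministic; the distance is
    unaffected by the tie-break.
    """
    _check_same_scheme(source, target)
    d = cdist(source.coords, target.coords)
    idx = np.argmin(d, axis=1)  # argmin returns the first (lowest) minimizer
    return [(i, int(j), float(d[i, j])) for i, j in enumerate(idx)]


def nn_similarity(p: Spectrum, q: Spectrum) -> float:
    """Average distance-per-peak over both matching directions.

    Concatenates the N directed matches p→q with the M matches q→p and
    averages all N+M distances, so every peak of both spectra contributes
    exactly once and the score is exactly symmetric in (p, q).
    """
    _check_same_scheme(p, q)
    d = cdist(p.coords, q.coords)
    total = d.min(axis=1).sum() + d.min(axis=0).sum()
    return float(total / (len(p) + len(q)))
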