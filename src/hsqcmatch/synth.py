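"""Seeded generator of HSQC-like compound libraries with known structure.

The generator emulates the situation a screening study faces: a library
of tens of small molecules in which some compounds belong to
combinatorial families — near-identical scaffolds whose spectra differ
only by small chemical-shift jitter and the occasional added or dropped
peak (e.g. a methoxy group swapped for an aromatic CH) — while the rest
are unrelated singletons. Chemical shifts are drawn from region boxes
(aromatic, aliphatic, methoxy) so that cross-region peak matches are
genuinely long in normalized coordinates.

Fabricated fingerprints mirror the family structure: members of a family
share a common bit core with a few per-member bit flips, so Tanimoto
similarity within families is much higher than between. A truth table
records family membership, giving tests a clustering ground truth
without any real chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fingerprints import Fingerprint
from .spectra import DEFAULT_SCHEME, NormalizationScheme, Spectrum

__all__ = [
    "LibraryConfig",
    "DEFAULT_REGIONS",
    "generate_library",
    "make_outlier_pair",
]

#: region name -> ((1H ppm lo, hi), (13C ppm lo, hi))
DEFAULT_REGIONS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "aromatic": ((6.0, 9.0), (110.0, 160.0)),
    "aliphatic": ((0.5, 4.5), (10.0, 80.0)),
    "methoxy": ((3.6, 4.0), (54.0, 57.0)),
}

_DEFAULT_REGION_WEIGHTS = {"aromatic": 0.45, "aliphatic": 0.45, "methoxy": 0.10}


@dataclass
class LibraryConfig:
    """Parameters of a synthetic compound library.

    Defaults produce a 51-compound library: 4 combinatorial families of
    6 members plus 27 unrelated singletons, 5–25 peaks per compound.
    ``jitter_sd`` is the (¹H, ¹³C) ppm standard deviation applied to
    every family-member peak; ``p_add``/``p_drop`` are the per-member
    probabilities of gaining/losing a peak relative to the scaffold.
    """

    n_compounds: int = 51
    peaks_range: tuple[int, int] = (5, 25)
    n_families: int = 4
    family_size: int = 6
    region_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_REGION_WEIGHTS)
    )
    jitter_sd: tuple[float, float] = (0.02, 0.2)  # (1H ppm, 13C ppm)
    p_add: float = 0.05
    p_drop: float = 0.05
    n_fingerprint_bits: int = 256
    seed: int | None = None
    scheme: NormalizationScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    def __post_init__(self) -> None:
        lo, hi = self.peaks_range
        if lo < 1 or hi < lo:
            raise ValueError(f"peaks_range must satisfy 1 <= min <= max, got {self.peaks_range}")
        if self.n_families * self.family_size > self.n_compounds:
            raise ValueError(
                f"{self.n_families} families of {self.family_size} exceed "
                f"{self.n_compounds} compounds"
            )
        if not self.region_weights:
            raise ValueError("region_weights must name at least one region")
        for name, w in self.region_weights.items():
            if name not in DEFAULT_REGIONS:
                raise ValueError(f"unknown region {name!r}")
            if w < 0:
                raise ValueError(f"region weight for {name!r} must be nonnegative")
        for p, nm in ((self.p_add, "p_add"), (self.p_drop, "p_drop")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{nm} must lie in [0, 1], got {p}")
        if self.n_fingerprint_bits % 4 != 0:
            raise ValueError("n_fingerprint_bits must be a multiple of 4")


def _draw_peaks(
    n: int, weights: dict[str, float], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n (h_ppm, c_ppm) peaks from the weighted region boxes."""
    names = list(weights)
    probs = np.array([weights[k] for k in names], dtype=float)
    probs = probs / probs.sum()
    h = np.empty(n)
    c = np.empty(n)
    regions = rng.choice(len(names), size=n, p=probs)
    for i, ridx in enumerate(regions):
        (h_lo, h_hi), (c_lo, c_hi) = DEFAULT_REGIONS[names[ridx]]
        h[i] = rng.uniform(h_lo, h_hi)
        c[i] = rng.uniform(c_lo, c_hi)
    return h, c


def _random_bits(n_bits: int, n_set: int, rng: np.random.Generator) -> set[int]:
    return set(rng.choice(n_bits, size=n_set, replace=False).tolist())


def generate_library(
    cfg: LibraryConfig,
) -> tuple[list[Spectrum], list[Fingerprint], pd.DataFrame]:
    """Generate (spectra, fingerprints, truth table) for one library.

    The truth table has one row per compound: ``compound_id``,
    ``family`` (family label, or ``singleton``), ``n_peaks``. Identical
    seeds give bit-identical libraries.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.peaks_range
    spectra: list[Spectrum] = []
    fps: list[Fingerprint] = []
    rows: list[tuple[str, str, int]] = []
    n_core_bits = max(4, cfg.n_fingerprint_bits // 3)
    n_flip = max(1, n_core_bits // 10)
    cid = 0

    for fam in range(cfg.n_families):
        n_scaffold = int(rng.integers(lo, hi + 1))
        h0, c0 = _draw_peaks(n_scaffold, cfg.region_weights, rng)
        core = _random_bits(cfg.n_fingerprint_bits, n_core_bits, rng)
        for _ in range(cfg.family_size):
            cid += 1
            name = f"C{cid:02d}"
            h = h0 + rng.normal(0.0, cfg.jitter_sd[0], n_scaffold)
            c = c0 + rng.normal(0.0, cfg.jitter_sd[1], n_scaffold)
            keep = np.ones(n_scaffold, dtype=bool)
            if n_scaffold > lo and rng.random() < cfg.p_drop:
                keep[rng.integers(0, n_scaffold)] = False
            h, c = h[keep], c[keep]
            if h.size < hi and rng.random() < cfg.p_add:
                ha, ca = _draw_peaks(1, cfg.region_weights, rng)
                h = np.append(h, ha)
                c = np.append(c, ca)
            spectra.append(Spectrum.from_shifts(name, h, c, cfg.scheme))
            bits = set(core)
            for b in rng.choice(cfg.n_fingerprint_bits, size=n_flip, replace=False):
                bits.symmetric_difference_update({int(b)})
            fps.append(
                Fingerprint(
                    compound_id=name, n_bits=cfg.n_fingerprint_bits,
                    set_bits=frozenset(bits),
                )
            )
            rows.append((name, f"F{fam + 1}", h.size))

    while cid < cfg.n_compounds:
        cid += 1
        name = f"C{cid:02d}"
        n = int(rng.integers(lo, hi + 1))
        h, c = _draw_peaks(n, cfg.region_weights, rng)
        spectra.append(Spectrum.from_shifts(name, h, c, cfg.scheme))
        fps.append(
            Fingerprint(
                compound_id=name, n_bits=cfg.n_fingerprint_bits,
                set_bits=frozenset(
                    _random_bits(cfg.n_fingerprint_bits, n_core_bits, rng)
                ),
            )
        )
        rows.append((name, "singleton", n))

    truth = pd.DataFrame(rows, columns=["compound_id", "family", "n_peaks"])
    return spectra, fps, truth


def make_outlier_pair(
    base_n: int = 11,
    far_offset: float = 80.0,
    seed: int | None = 0,
    scheme: NormalizationScheme = DEFAULT_SCHEME,
) -> tuple[Spectrum, Spectrum]:
    """Two equal-count spectra differing by one cross-region peak.

    Both spectra have ``base_n`` peaks; ``base_n − 1`` coincide exactly
    and the last peak of the second spectrum is displaced by
    ``far_offset`` ppm on the ¹³C axis (and proportionally on ¹H, so the
    displacement is diagonal in normalized coordinates). Any unique
    matching is therefore forced to contain exactly one long pair — the
    scenario where a single outlier match dominates a plain mean
    distance, used to exercise the outlier-aware metric.
    """
    if base_n < 2:
        raise ValueError("base_n must be at least 2")
    rng = np.random.default_rng(seed)
    # keep the base in the aliphatic box so a positive offset lands aromatic
    (h_lo, h_hi), (c_lo, c_hi) = DEFAULT_REGIONS["aliphatic"]
    h = rng.uniform(h_lo, h_hi, base_n)
    c = rng.uniform(c_lo, c_hi, base_n)
    h2 = h.copy()
    c2 = c.copy()
    c_span = scheme.c_range[1] - scheme.c_range[0]
    h_span = scheme.h_range[1] - scheme.h_range[0]
    c2[-1] += far_offset
    h2[-1] += far_offset * h_span / c_span
    p = Spectrum.from_shifts("base", h, c, scheme)
    q = Spectrum.from_shifts("displaced", h2, c2, scheme)
    return p, q
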