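"""Peak and spectrum data model for 2D HSQC peak lists.

An HSQC spectrum is represented as a set of (¹H ppm, ¹³C ppm) correlation
peaks. For matching, ppm coordinates are mapped onto dimensionless
Cartesian coordinates by min–max normalization over fixed, configurable
ppm windows (default ¹³C 0–200 ppm → x, ¹H 0–10 ppm → y). Fixed windows —
rather than per-spectrum scaling — keep distances comparable across a
whole compound library. Peak intensities are deliberately not modelled.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationScheme",
    "Peak",
    "Spectrum",
    "PeaklistFormatError",
    "normalize_peak",
    "peak_distance",
    "read_peaklist",
    "write_peaklist",
]


class PeaklistFormatError(ValueError):
    """Raised when a peak-list file violates the expected tabular dialect."""


@dataclass(frozen=True)
class NormalizationScheme:
    """Fixed ppm windows mapping chemical shifts to [0, 1] coordinates.

    Parameters
    ----------
    c_range : (float, float)
        (min, max) ppm window for the ¹³C axis. Default (0, 200).
    h_range : (float, float)
        (min, max) ppm window for the ¹H axis. Default (0, 10).
    """

    c_range: tuple[float, float] = (0.0, 200.0)
    h_range: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("c_range", self.c_range), ("h_range", self.h_range)):
            if not (math.isfinite(lo) and math.isfinite(hi)):
                raise ValueError(f"{name} bounds must be finite, got {(lo, hi)}")
            if not hi > lo:
                raise ValueError(f"{name} must satisfy max > min, got {(lo, hi)}")


DEFAULT_SCHEME = NormalizationScheme()


@dataclass(frozen=True)
class Peak:
    """A single HSQC correlation peak.

    ``h_shift``/``c_shift`` are the observed chemical shifts in ppm;
    ``x``/``y`` are the normalized ¹³C/¹H coordinates under the scheme
    the peak was normalized with.
    """

    h_shift: float
    c_shift: float
    x: float
    y: float


def normalize_peak(
    c_shift: float, h_shift: float, scheme: NormalizationScheme = DEFAULT_SCHEME
) -> Peak:
    """Map (¹³C ppm, ¹H ppm) onto normalized (x, y) coordinates.

    x = (c − c_min)/(c_max − c_min), and likewise y on the ¹H axis.
    Shifts outside the configured window yield coordinates outside [0, 1];
    this is allowed but logged, since it usually indicates a referencing
    problem or an unsuitable window.
    """
    if not (math.isfinite(c_shift) and math.isfinite(h_shift)):
        raise ValueError(f"chemical shifts must be finite, got ({h_shift}, {c_shift})")
    c_lo, c_hi = scheme.c_range
    h_lo, h_hi = scheme.h_range
    x = (c_shift - c_lo) / (c_hi - c_lo)
    y = (h_shift - h_lo) / (h_hi - h_lo)
    if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
        logger.warning(
            "peak (%g ppm 1H, %g ppm 13C) falls outside the normalization "
            "window; normalized coordinates (%g, %g)",
            h_shift, c_shift, x, y,
        )
    return Peak(h_shift=h_shift, c_shift=c_shift, x=x, y=y)


def peak_distance(a: Peak, b: Peak) -> float:
    """Euclidean distance between two peaks in normalized coordinates."""
    return math.hypot(a.x - b.x, a.y - b.y)


@dataclass(frozen=True)
class Spectrum:
    """An HSQC spectrum: a compound label plus an ordered set of peaks.

    Peak order is preserved from the source but carries no meaning; all
    matching operations are order-invariant. Duplicate coordinates are
    permitted (chemically equivalent CH groups).
    """

    compound_id: str
    peaks: tuple[Peak, ...]
    scheme: NormalizationScheme = DEFAULT_SCHEME
    _coords: np.ndarray | None = field(
        default=None, repr=False, compare=False, hash=False
    )

    def __post_init__(self) -> None:
        if len(self.peaks) < 1:
            raise ValueError(f"spectrum {self.compound_id!r} has no peaks")
        object.__setattr__(self, "peaks", tuple(self.peaks))

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def coords(self) -> np.ndarray:
        """(N, 2) array of normalized (x, y) coordinates (cached)."""
        if self._coords is None:
            arr = np.array([(p.x, p.y) for p in self.peaks], dtype=np.float64)
            object.__setattr__(self, "_coords", arr)
        return self._coords

    @classmethod
    def from_shifts(
        cls,
        compound_id: str,
        h_shifts: Sequence[float],
        c_shifts: Sequence[float],
        scheme: NormalizationScheme = DEFAULT_SCHEME,
    ) -> "Spectrum":
        """Build a spectrum from parallel ¹H/¹³C ppm sequences."""
        if len(h_shifts) != len(c_shifts):
            raise ValueError("h_shifts and c_shifts must have equal length")
        peaks = tuple(
            normalize_peak(c, h, scheme) for h, c in zip(h_shifts, c_shifts)
        )
        return cls(compound_id=compound_id, peaks=peaks, scheme=scheme)

    def with_scheme(self, scheme: NormalizationScheme) -> "Spectrum":
        """Re-normalize the stored ppm values under a different scheme."""
        return Spectrum.from_shifts(
            self.compound_id,
            [p.h_shift for p in self.peaks],
            [p.c_shift for p in self.peaks],
            scheme,
        )


def _check_same_scheme(p: Spectrum, q: Spectrum) -> None:
    if p.scheme != q.scheme:
        raise ValueError(
            f"spectra {p.compound_id!r} and {q.compound_id!r} use different "
            "normalization schemes; renormalize with Spectrum.with_scheme"
        )


_COLUMNS = ("compound_id", "h_ppm", "c_ppm")


def read_peaklist(
    path: str | Path, scheme: NormalizationScheme = DEFAULT_SCHEME
) -> list[Spectrum]:
    """Read a delimiter-separated peak list into spectra.

    The dialect is UTF-8 text, comma- or tab-delimited (autodetected from
    the header), with header ``compound_id,h_ppm,c_ppm``, one row per peak,
    rows grouped by compound. Lines starting with ``#`` are comments.
    Returns one :class:`Spectrum` per distinct compound_id, in order of
    first appearance, with normalization applied on read.
    """
    path = Path(path)
    groups: dict[str, list[tuple[float, float]]] = {}
    header: list[str] | None = None
    delim = ","
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if header is None:
                delim = "\t" if "\t" in line else ","
                header = [c.strip() for c in line.split(delim)]
                if tuple(header[:3]) != _COLUMNS:
                    raise PeaklistFormatError(
                        f"{path}:{lineno}: expected header "
                        f"{','.join(_COLUMNS)!r}, got {line!r}"
                    )
                continue
            fields = next(csv.reader([line], delimiter=delim))
            if len(fields) < 3:
                raise PeaklistFormatError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            cid = fields[0].strip()
            if not cid:
                raise PeaklistFormatError(f"{path}:{lineno}: empty compound_id")
            try:
                h = float(fields[1])
                c = float(fields[2])
            except ValueError as exc:
                raise PeaklistFormatError(
                    f"{path}:{lineno}: non-numeric chemical shift: {exc}"
                ) from None
            groups.setdefault(cid, []).append((h, c))
    if header is None:
        raise PeaklistFormatError(f"{path}: empty file (missing header)")
    return [
        Spectrum.from_shifts(cid, [h for h, _ in rows], [c for _, c in rows], scheme)
        for cid, rows in groups.items()
    ]


def write_peaklist(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra in the dialect read by :func:`read_peaklist`.

    ppm values (not normalized coordinates) are written, at 6 significant
    digits.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("cannot write an empty spectrum collection")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(_COLUMNS) + "\n")
        for sp in spectra:
            for pk in sp.peaks:
                fh.write(f"{sp.compound_id},{pk.h_shift:.6g},{pk.c_shift:.6g}\n")
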