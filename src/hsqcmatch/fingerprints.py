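"""Tanimoto similarity over externally supplied bit-string fingerprints.

Molecular fingerprints (e.g. Open Babel's path-based FP2) encode the
presence of structural fragments as fixed-length bit strings. This
module consumes them — it does not compute fingerprints from structures
— and scores pairs with the Tanimoto coefficient T_c = |A∩B|/|A∪B|,
ranging from 0 (no shared bits) to 1 (identical). The on-disk format is
FPS-like text: one ``compound_id<whitespace>hex`` line per compound, all
lines of equal hex length, hex decoded most-significant-bit first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "Fingerprint",
    "FingerprintFormatError",
    "tanimoto",
    "read_fingerprints",
    "write_fingerprints",
]


class FingerprintFormatError(ValueError):
    """Raised when a fingerprint file violates the FPS-like dialect."""


@dataclass(frozen=True)
class Fingerprint:
    compound_id: str
    n_bits: int
    set_bits: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "set_bits", frozenset(self.set_bits))
        if any(b < 0 or b >= self.n_bits for b in self.set_bits):
            raise ValueError(
                f"fingerprint {self.compound_id!r}: bit positions must lie in "
                f"[0, {self.n_bits})"
            )

    def to_hex(self) -> str:
        val = 0
        for b in self.set_bits:
            val |= 1 << (self.n_bits - 1 - b)  # bit 0 is the MSB
        return format(val, f"0{self.n_bits // 4}x")


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| of two equal-length fingerprints.

    Two identical all-zero strings are defined to have similarity 1.
    """
    if a.n_bits != b.n_bits:
        raise ValueError(
            f"fingerprint lengths differ: {a.n_bits} vs {b.n_bits}"
        )
    union = len(a.set_bits | b.set_bits)
    if union == 0:
        return 1.0
    return len(a.set_bits & b.set_bits) / union


def _hex_to_bits(hexstr: str) -> frozenset[int]:
    n_bits = 4 * len(hexstr)
    val = int(hexstr, 16)
    return frozenset(
        pos for pos in range(n_bits) if val >> (n_bits - 1 - pos) & 1
    )


def read_fingerprints(path: str | Path) -> list[Fingerprint]:
    """Read an FPS-like text file of ``id<whitespace>hex`` lines."""
    path = Path(path)
    fps: list[Fingerprint] = []
    hex_len: int | None = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FingerprintFormatError(
                    f"{path}:{lineno}: expected 'compound_id hex', got {line!r}"
                )
            cid, hexstr = parts
            if hex_len is None:
                hex_len = len(hexstr)
            elif len(hexstr) != hex_len:
                raise FingerprintFormatError(
                    f"{path}:{lineno}: hex length {len(hexstr)} differs from "
                    f"earlier lines ({hex_len})"
                )
            try:
                bits = _hex_to_bits(hexstr)
            except ValueError:
                raise FingerprintFormatError(
                    f"{path}:{lineno}: non-hex characters in {hexstr!r}"
                ) from None
            fps.append(
                Fingerprint(compound_id=cid, n_bits=4 * len(hexstr), set_bits=bits)
            )
    return fps


def write_fingerprints(fps: Iterable[Fingerprint], path: str | Path) -> None:
    """Write fingerprints in the dialect read by :func:`read_fingerprints`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for fp in fps:
            if fp.n_bits % 4 != 0:
                raise ValueError(
                    f"fingerprint {fp.compound_id!r}: n_bits must be a multiple "
                    "of 4 for hex serialization"
                )
            fh.write(f"{fp.compound_id}\t{fp.to_hex()}\n")
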