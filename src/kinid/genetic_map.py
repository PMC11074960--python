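"""Sex-averaged genetic map.

The bundled map carries one total genetic length per chromosome (cM) with
a monotone position scale in [0, length]; marker positions are expressed
directly in centimorgans.  One sex-averaged map is used for all meioses
and no minimum segment length is ever imposed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable

from .errors import KinidError

__all__ = ["GeneticMap", "AUTOSOMES", "MapError"]


class MapError(KinidError):
    """A chromosome required by the simulation is absent from the map."""


AUTOSOMES = [str(c) for c in range(1, 23)]

# Sex-averaged total genetic lengths in cM, magnitudes of the deCODE-style
# human linkage maps (autosomes 1-22 plus the female X scale).
_DEFAULT_LENGTHS_CM: Dict[str, float] = {
    "1": 286.3, "2": 268.6, "3": 223.4, "4": 214.6, "5": 204.1,
    "6": 192.0, "7": 187.2, "8": 168.0, "9": 166.4, "10": 181.0,
    "11": 158.4, "12": 174.7, "13": 125.9, "14": 119.5, "15": 141.7,
    "16": 134.8, "17": 128.5, "18": 117.2, "19": 107.9, "20": 108.3,
    "21": 62.8, "22": 74.1, "X": 180.8,
}


@dataclass(frozen=True)
class GeneticMap:
    """Per-chromosome total genetic lengths (cM)."""

    lengths: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LENGTHS_CM)
    )

    def __post_init__(self):
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom}: non-positive length")

    def length(self, chrom: str) -> float:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise MapError(f"chromosome {chrom!r} missing from genetic map") from None

    def total(self, chroms: Iterable[str] = AUTOSOMES) -> float:
        return sum(self.length(c) for c in chroms)

    @property
    def autosomes(self):
        return [c for c in AUTOSOMES if c in self.lengths]
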