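"""The sixteen S. cerevisiae chromosomes and their reference lengths.

Apparent (DNA-content) ploidy is a length-weighted mean copy number, so every
module that converts between karyotypes and ploidies needs the chromosome
lengths.  The bundled table carries the R64 (SGD/sacCer3) nuclear chromosome
lengths in base pairs; a user-supplied table with the same 16 identifiers may
be used instead everywhere a ``ChromosomeTable`` is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CHROMOSOMES",
    "ChromosomeTable",
    "R64_LENGTHS_BP",
    "default_table",
    "normalize_chromosome_id",
]

#: Canonical Roman-numeral identifiers, karyotype vector order.
CHROMOSOMES: tuple[str, ...] = (
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII",
    "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI",
)

#: R64 (SGD) nuclear chromosome lengths, base pairs.
R64_LENGTHS_BP: dict[str, int] = {
    "I": 230_218,
    "II": 813_184,
    "III": 316_620,
    "IV": 1_531_933,
    "V": 576_874,
    "VI": 270_161,
    "VII": 1_090_940,
    "VIII": 562_643,
    "IX": 439_888,
    "X": 745_751,
    "XI": 666_816,
    "XII": 1_078_177,
    "XIII": 924_431,
    "XIV": 784_333,
    "XV": 1_091_291,
    "XVI": 948_066,
}

_ROMAN = {numeral: i + 1 for i, numeral in enumerate(CHROMOSOMES)}
_ARABIC = {str(v): k for k, v in _ROMAN.items()}


def normalize_chromosome_id(label: str | int) -> str:
    """Map a chromosome label to its canonical Roman numeral.

    Accepts Roman numerals in any case, Arabic numbers 1-16, and optional
    ``chr`` prefixes (``chrIV``, ``Chr4``).
    """
    text = str(label).strip()
    if text.lower().startswith("chr"):
        text = text[3:]
    upper = text.upper()
    if upper in _ROMAN:
        return upper
    if text in _ARABIC:
        return _ARABIC[text]
    raise ValueError(f"unrecognized chromosome identifier: {label!r}")


@dataclass(frozen=True)
class ChromosomeTable:
    """The 16 chromosome identifiers with their lengths in base pairs."""

    lengths_bp: dict[str, int] = field(
        default_factory=lambda: dict(R64_LENGTHS_BP)
    )

    def __post_init__(self) -> None:
        normalized = {
            normalize_chromosome_id(k): int(v) for k, v in self.lengths_bp.items()
        }
        if len(normalized) != 16 or set(normalized) != set(CHROMOSOMES):
            missing = set(CHROMOSOMES) - set(normalized)
            raise ValueError(
                f"chromosome table must cover exactly chromosomes I-XVI; "
                f"missing {sorted(missing) or 'none'}, got {len(normalized)} entries"
            )
        if any(v <= 0 for v in normalized.values()):
            raise ValueError("all chromosome lengths must be positive")
        object.__setattr__(self, "lengths_bp", normalized)

    @property
    def lengths(self) -> np.ndarray:
        """Lengths as a float vector in canonical chromosome order."""
        return np.array([self.lengths_bp[c] for c in CHROMOSOMES], dtype=float)

    @property
    def total_bp(self) -> int:
        return int(sum(self.lengths_bp.values()))

    def weights(self) -> np.ndarray:
        """Length fractions L_i / sum(L), the apparent-ploidy weights."""
        lengths = self.lengths
        return lengths / lengths.sum()


def default_table() -> ChromosomeTable:
    """The bundled R64 reference length table."""
    return ChromosomeTable()
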