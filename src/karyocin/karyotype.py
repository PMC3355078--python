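"""Karyotype data model and per-strain aneuploidy metrics.

A karyotype is a length-16 vector of whole-chromosome copy numbers.  From it
we derive the quantities the downstream association analyses use: apparent
(length-weighted) ploidy, basal ploidy (the modal copy number), the set of
aneuploid chromosomes (copy number deviating from basal ploidy, gains and
losses treated symmetrically), and the genome content in chromosomes and
megabases.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .chromosomes import CHROMOSOMES, ChromosomeTable, default_table

__all__ = [
    "Karyotype",
    "AneuploidyMetrics",
    "BasalPloidyUndefined",
    "apparent_ploidy",
    "basal_ploidy",
    "aneuploid_chromosomes",
    "imbalance_ratio",
    "aneuploidy_metrics",
    "mean_copy_number",
]


class BasalPloidyUndefined(ValueError):
    """Raised when an operation needs a basal ploidy but the modal copy
    number is tied (e.g. eight chromosomes at 1 and eight at 2); such strains
    are excluded from single-chromosome analyses."""


@dataclass(frozen=True)
class Karyotype:
    """Whole-genome karyotype: one copy number per chromosome I-XVI."""

    copies: tuple[int, ...]

    def __post_init__(self) -> None:
        copies = tuple(int(c) for c in self.copies)
        if len(copies) != 16:
            raise ValueError(f"karyotype must have 16 entries, got {len(copies)}")
        if any(c < 0 for c in copies):
            raise ValueError("copy numbers must be non-negative")
        object.__setattr__(self, "copies", copies)

    @classmethod
    def from_iterable(cls, values: Iterable[int]) -> "Karyotype":
        return cls(tuple(int(v) for v in values))

    @classmethod
    def uniform(cls, copy_number: int) -> "Karyotype":
        return cls((int(copy_number),) * 16)

    def as_array(self) -> np.ndarray:
        return np.array(self.copies, dtype=int)

    def copy_number(self, chromosome: str) -> int:
        return self.copies[CHROMOSOMES.index(chromosome)]

    @property
    def is_live(self) -> bool:
        """A live cell retains at least one copy of every chromosome."""
        return all(c >= 1 for c in self.copies)

    @property
    def total_chromosomes(self) -> int:
        return sum(self.copies)

    def __str__(self) -> str:
        return "/".join(str(c) for c in self.copies)


@dataclass(frozen=True)
class AneuploidyMetrics:
    """Derived genome-level karyotype descriptors."""

    apparent_ploidy: float
    basal_ploidy: int | None
    n_aneuploid_chromosomes: int | None
    mb_aneuploid: float | None
    total_chromosomes: int
    total_mb: float


def _as_copies(karyotype: Karyotype | Sequence[int]) -> np.ndarray:
    if isinstance(karyotype, Karyotype):
        return karyotype.as_array()
    arr = np.asarray(karyotype, dtype=int)
    if arr.shape != (16,):
        raise ValueError("karyotype must have exactly 16 copy numbers")
    return arr


def apparent_ploidy(
    karyotype: Karyotype | Sequence[int], table: ChromosomeTable | None = None
) -> float:
    """Length-weighted mean copy number, sum(c_i L_i) / sum(L_i).

    Equals the DNA content relative to the haploid genome; 1.0 for a haploid,
    2.0 for a diploid, non-integer for aneuploids.
    """
    copies = _as_copies(karyotype)
    table = table or default_table()
    return float(copies @ table.weights())


def mean_copy_number(karyotype: Karyotype | Sequence[int]) -> float:
    """Unweighted alternative ploidy summary: total chromosomes / 16."""
    return float(_as_copies(karyotype).mean())


def basal_ploidy(karyotype: Karyotype | Sequence[int]) -> int | None:
    """Modal copy number of the karyotype; ``None`` when the mode is tied."""
    copies = _as_copies(karyotype)
    counts = Counter(int(c) for c in copies)
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    return ranked[0][0]


def aneuploid_chromosomes(karyotype: Karyotype | Sequence[int]) -> set[str]:
    """Chromosomes whose copy number deviates from the basal ploidy.

    Gains and losses both count.  Raises :class:`BasalPloidyUndefined` when
    the basal ploidy is tied, signalling that the strain must be excluded
    from single-chromosome analyses.
    """
    copies = _as_copies(karyotype)
    basal = basal_ploidy(copies)
    if basal is None:
        raise BasalPloidyUndefined(
            "modal copy number is tied; aneuploid chromosomes cannot be assigned"
        )
    return {CHROMOSOMES[i] for i in range(16) if copies[i] != basal}


def imbalance_ratio(
    karyotype: Karyotype | Sequence[int], chrom_a: str, chrom_b: str
) -> float:
    """Copy-number ratio c_a / c_b between two chromosomes.

    With copy numbers restricted to {1, 2} the ratio is one of {0.5, 1, 2};
    a pair is called imbalanced when the ratio differs from 1.
    """
    copies = _as_copies(karyotype)
    c_a = copies[CHROMOSOMES.index(chrom_a)]
    c_b = copies[CHROMOSOMES.index(chrom_b)]
    if c_a == 0 or c_b == 0:
        raise ValueError("imbalance ratio undefined for zero copy numbers")
    return c_a / c_b


def aneuploidy_metrics(
    karyotype: Karyotype | Sequence[int], table: ChromosomeTable | None = None
) -> AneuploidyMetrics:
    """All genome-level descriptors used by the CIN association analyses.

    When the basal ploidy is tied the aneuploid-chromosome counts are
    ``None`` (the strain is excluded from those analyses) while the
    ploidy and total-content fields remain defined.
    """
    copies = _as_copies(karyotype)
    table = table or default_table()
    lengths = table.lengths
    basal = basal_ploidy(copies)
    if basal is None:
        n_aneu: int | None = None
        mb_aneu: float | None = None
    else:
        aneu_mask = copies != basal
        n_aneu = int(aneu_mask.sum())
        mb_aneu = float(lengths[aneu_mask].sum() / 1e6)
    return AneuploidyMetrics(
        apparent_ploidy=float(copies @ (lengths / lengths.sum())),
        basal_ploidy=basal,
        n_aneuploid_chromosomes=n_aneu,
        mb_aneuploid=mb_aneu,
        total_chromosomes=int(copies.sum()),
        total_mb=float((copies * lengths).sum() / 1e6),
    )
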