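"""Branching-population simulator of karyotype divergence under CIN.

A colony starts from a single seed cell carrying a known karyotype.  Each
generation every live cell divides; during division each of the 16
chromosomes independently mis-segregates with probability ``p``.  In the
default ``"single_homolog"`` mode a mis-segregation sends one extra copy to a
uniformly chosen daughter (daughters receive ``c+1`` and ``c-1`` copies);
the ``"all_copies"`` mode sends every duplicated copy to one daughter
(``2c`` and ``0``).  Copy number is conserved at every division.  Daughters
that lose all copies of any chromosome are discarded as dead.  Whenever the
population exceeds the cap it is downsampled uniformly without replacement.

The simulator tracks the population as counts per distinct (karyotype,
lineage) group rather than as individual cells, which is exact in
distribution: faithful divisions simply double a group's count, the number
of mis-segregating divisions in a group is Binomial, and downsampling is
multivariate hypergeometric.  Lineage tracking (every mis-segregation event
opens a new lineage recorded with its generation and parent) gives sampled
colonies a ground-truth ancestry for event counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy import stats

from .karyotype import Karyotype

__all__ = [
    "MisSegConfig",
    "DeviantFractionResult",
    "LineageRecord",
    "ColonyPopulation",
    "divide_cell",
    "simulate_colony",
    "simulate_population",
]

Mode = Literal["single_homolog", "all_copies"]

ROOT_LINEAGE = 0


@dataclass(frozen=True)
class MisSegConfig:
    """Study conditions for a deviant-fraction simulation run."""

    seed_karyotype: Karyotype
    missegregation_rate: float
    generations: int
    population_cap: int = 100_000
    replicates: int = 30
    rng_seed: int | None = None
    mode: Mode = "single_homolog"

    def __post_init__(self) -> None:
        if not 0.0 <= self.missegregation_rate <= 1.0:
            raise ValueError("mis-segregation rate must be a probability")
        if self.generations < 1 or self.population_cap < 1 or self.replicates < 1:
            raise ValueError("generations, cap and replicates must be >= 1")
        if not self.seed_karyotype.is_live:
            raise ValueError("seed karyotype must be live (all copies >= 1)")


@dataclass(frozen=True)
class DeviantFractionResult:
    """Per-replicate fraction of live cells deviating from the seed."""

    fractions: tuple[float, ...]
    n_extinct: int
    generations: int
    missegregation_rate: float

    @property
    def median(self) -> float:
        return float(np.median(self.fractions))

    @property
    def iqr(self) -> tuple[float, float]:
        q1, q3 = np.percentile(self.fractions, [25, 75])
        return float(q1), float(q3)

    def summary(self) -> dict[str, float]:
        q1, q3 = self.iqr
        return {
            "median": self.median,
            "q1": q1,
            "q3": q3,
            "mean": float(np.mean(self.fractions)),
            "n_replicates": float(len(self.fractions)),
            "n_extinct": float(self.n_extinct),
        }


@dataclass(frozen=True)
class LineageRecord:
    """One mis-segregation lineage: opened by an event in ``generation``."""

    lineage_id: int
    parent_lineage: int
    generation: int
    karyotype: tuple[int, ...]


def divide_cell(
    karyotype: Karyotype,
    p: float,
    rng: np.random.Generator,
    mode: Mode = "single_homolog",
) -> tuple[Karyotype, Karyotype]:
    """Divide one cell; each chromosome mis-segregates with probability p.

    Copy number is conserved: per chromosome the daughters' copies sum to
    twice the parent's.  Dead daughters (a zero copy number) are returned
    as-is; discarding them is the population simulator's job.
    """
    parent = karyotype.as_array()
    d1 = parent.copy()
    d2 = parent.copy()
    events = rng.random(16) < p
    for i in np.flatnonzero(events):
        toward_first = rng.random() < 0.5
        if mode == "single_homolog":
            gain, loss = 1, -1
        else:  # all copies of the chromosome travel together
            gain, loss = parent[i], -parent[i]
        if toward_first:
            d1[i] += gain
            d2[i] += loss
        else:
            d1[i] += loss
            d2[i] += gain
    return Karyotype.from_iterable(d1), Karyotype.from_iterable(d2)


@dataclass
class ColonyPopulation:
    """Final state of one simulated colony."""

    groups: dict[tuple[tuple[int, ...], int], int]
    lineages: dict[int, LineageRecord]
    seed: tuple[int, ...]
    extinct: bool

    @property
    def size(self) -> int:
        return sum(self.groups.values())

    def deviant_fraction(self) -> float:
        total = self.size
        if total == 0:
            raise ValueError("population is extinct")
        deviant = sum(
            n for (karyo, _lin), n in self.groups.items() if karyo != self.seed
        )
        return deviant / total

    def modal_karyotype(self) -> Karyotype:
        """Most frequent karyotype in the final population."""
        by_karyo: dict[tuple[int, ...], int] = {}
        for (karyo, _lin), n in self.groups.items():
            by_karyo[karyo] = by_karyo.get(karyo, 0) + n
        best = max(sorted(by_karyo), key=lambda k: by_karyo[k])
        return Karyotype(best)

    def mean_copy_numbers(self) -> np.ndarray:
        """Population-average copy number per chromosome (qPCR sees this)."""
        total = self.size
        acc = np.zeros(16)
        for (karyo, _lin), n in self.groups.items():
            acc += n * np.asarray(karyo)
        return acc / total

    def sample_cells(
        self, n: int, rng: np.random.Generator
    ) -> list[tuple[Karyotype, int]]:
        """Draw n cells uniformly without replacement -> (karyotype, lineage)."""
        keys = sorted(self.groups)
        counts = np.array([self.groups[k] for k in keys], dtype=np.int64)
        if counts.sum() < n:
            raise ValueError("population smaller than requested sample")
        taken = rng.multivariate_hypergeometric(counts, n)
        out: list[tuple[Karyotype, int]] = []
        for (karyo, lin), k in zip(keys, taken):
            out.extend([(Karyotype(karyo), lin)] * int(k))
        rng.shuffle(out)  # type: ignore[arg-type]
        return out


def _conditional_event_count_dist(p: float) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the number of mis-segregating chromosomes, given >= 1."""
    ks = np.arange(1, 17)
    pmf = stats.binom.pmf(ks, 16, p)
    return ks, pmf / pmf.sum()


def simulate_colony(
    seed_karyotype: Karyotype,
    p: float,
    generations: int,
    *,
    population_cap: int = 100_000,
    rng: np.random.Generator,
    mode: Mode = "single_homolog",
    track_lineages: bool = False,
) -> ColonyPopulation:
    """Grow one colony from a single seed cell for ``generations`` divisions."""
    seed = tuple(seed_karyotype.copies)
    groups: dict[tuple[tuple[int, ...], int], int] = {(seed, ROOT_LINEAGE): 1}
    lineages: dict[int, LineageRecord] = {
        ROOT_LINEAGE: LineageRecord(ROOT_LINEAGE, ROOT_LINEAGE, 0, seed)
    }
    next_lineage = 1
    q_event = 1.0 - (1.0 - p) ** 16
    if p > 0:
        event_ks, event_pmf = _conditional_event_count_dist(p)

    for gen in range(1, generations + 1):
        new_groups: dict[tuple[tuple[int, ...], int], int] = {}

        def _add(karyo: tuple[int, ...], lin: int, n: int) -> None:
            if n:
                key = (karyo, lin)
                new_groups[key] = new_groups.get(key, 0) + n

        for (karyo, lin), n in groups.items():
            n_event = rng.binomial(n, q_event) if p > 0 else 0
            _add(karyo, lin, 2 * (n - n_event))
            if not n_event:
                continue
            parent = np.asarray(karyo)
            n_chrom_events = rng.choice(event_ks, size=n_event, p=event_pmf)
            for m in n_chrom_events:
                which = rng.choice(16, size=int(m), replace=False)
                d1 = parent.copy()
                d2 = parent.copy()
                for i in which:
                    step = 1 if mode == "single_homolog" else parent[i]
                    if rng.random() < 0.5:
                        d1[i] += step
                        d2[i] -= step
                    else:
                        d1[i] -= step
                        d2[i] += step
                for d in (d1, d2):
                    if d.min() < 1:
                        continue  # nullisomic daughter dies
                    if track_lineages:
                        child = next_lineage
                        next_lineage += 1
                        lineages[child] = LineageRecord(
                            child, lin, gen, tuple(int(x) for x in d)
                        )
                        _add(tuple(int(x) for x in d), child, 1)
                    else:
                        _add(tuple(int(x) for x in d), lin, 1)

        total = sum(new_groups.values())
        if total == 0:
            return ColonyPopulation({}, lineages, seed, extinct=True)
        if total > population_cap:
            keys = sorted(new_groups)
            counts = np.array([new_groups[k] for k in keys], dtype=np.int64)
            kept = rng.multivariate_hypergeometric(counts, population_cap)
            new_groups = {
                k: int(c) for k, c in zip(keys, kept) if c > 0
            }
        groups = new_groups

    return ColonyPopulation(groups, lineages, seed, extinct=False)


def simulate_population(config: MisSegConfig) -> DeviantFractionResult:
    """Run the configured number of independent colony replicates.

    Returns the per-replicate fraction of live cells whose karyotype differs
    from the seed at the final generation.  Extinct replicates are excluded
    from the fractions and counted separately.
    """
    rng = np.random.default_rng(config.rng_seed)
    fractions: list[float] = []
    n_extinct = 0
    for _ in range(config.replicates):
        colony = simulate_colony(
            config.seed_karyotype,
            config.missegregation_rate,
            config.generations,
            population_cap=config.population_cap,
            rng=rng,
            mode=config.mode,
        )
        if colony.extinct:
            n_extinct += 1
        else:
            fractions.append(colony.deviant_fraction())
    return DeviantFractionResult(
        fractions=tuple(fractions),
        n_extinct=n_extinct,
        generations=config.generations,
        missegregation_rate=config.missegregation_rate,
    )
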