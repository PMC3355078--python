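"""Random-spore karyotypes from triploid meiosis and their ploidy spectrum.

In a triploid, each chromosome has three homologs; meiosis I deals two to one
pole and one to the other, so (ignoring viability) every chromosome of a
spore independently ends up at copy number 1 or 2 with probability one half.
A spore karyotype is therefore a uniform draw from the 2^16 vectors over
{1, 2}, and its apparent ploidy is the length-weighted mean copy number,
symmetric about 1.5.  This module draws such spores, builds the expected
apparent-ploidy histogram/ECDF (with across-replicate standard deviations),
enumerates the exact 2^16 distribution, and compares an observed ploidy
sample against the expectation with a Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .chromosomes import ChromosomeTable, default_table
from .karyotype import Karyotype

__all__ = [
    "SporeSimConfig",
    "SporePloidyDistribution",
    "random_spore",
    "random_spore_ploidies",
    "spore_ploidy_distribution",
    "enumerate_spore_ploidies",
    "ks_compare",
    "expected_spores",
    "viability_percent",
]

DEFAULT_BIN_EDGES = np.round(np.arange(1.0, 2.0 + 1e-9, 0.1), 10)


@dataclass(frozen=True)
class SporeSimConfig:
    """Replicated random-spore draw mirroring the observed sample size."""

    n_spores_per_replicate: int = 41
    n_replicates: int = 10_000
    rng_seed: int | None = None
    bin_edges: tuple[float, ...] = tuple(DEFAULT_BIN_EDGES)

    def __post_init__(self) -> None:
        if self.n_spores_per_replicate < 1 or self.n_replicates < 1:
            raise ValueError("spore and replicate counts must be positive")


@dataclass(frozen=True)
class SporePloidyDistribution:
    """Binned expected frequencies with per-bin SDs, plus the pooled sample."""

    bin_edges: np.ndarray
    mean_counts: np.ndarray
    sd_counts: np.ndarray
    pooled_ploidies: np.ndarray

    def ecdf(self, x: float) -> float:
        return float(np.mean(self.pooled_ploidies <= x))


def random_spore(rng: np.random.Generator) -> Karyotype:
    """One random spore: every chromosome copy 1 or 2 with probability 1/2."""
    return Karyotype.from_iterable(rng.integers(1, 3, size=16))


def random_spore_ploidies(
    n: int, rng: np.random.Generator, table: ChromosomeTable | None = None
) -> np.ndarray:
    """Apparent ploidies of ``n`` independent random spores (vectorized)."""
    table = table or default_table()
    copies = rng.integers(1, 3, size=(n, 16))
    return copies @ table.weights()


def spore_ploidy_distribution(
    config: SporeSimConfig, table: ChromosomeTable | None = None
) -> SporePloidyDistribution:
    """Expected apparent-ploidy histogram from replicated spore draws.

    Each replicate draws ``n_spores_per_replicate`` spores and bins their
    apparent ploidies; the mean and SD of the per-bin counts across
    replicates estimate the expected histogram and its sampling error.
    """
    table = table or default_table()
    rng = np.random.default_rng(config.rng_seed)
    edges = np.asarray(config.bin_edges, dtype=float)
    weights = table.weights()
    counts = np.empty((config.n_replicates, edges.size - 1))
    pooled = np.empty(config.n_replicates * config.n_spores_per_replicate)
    n = config.n_spores_per_replicate
    for rep in range(config.n_replicates):
        ploidies = rng.integers(1, 3, size=(n, 16)) @ weights
        counts[rep], _ = np.histogram(ploidies, bins=edges)
        pooled[rep * n : (rep + 1) * n] = ploidies
    return SporePloidyDistribution(
        bin_edges=edges,
        mean_counts=counts.mean(axis=0),
        sd_counts=counts.std(axis=0, ddof=1),
        pooled_ploidies=pooled,
    )


def enumerate_spore_ploidies(table: ChromosomeTable | None = None) -> np.ndarray:
    """Apparent ploidies of all 2^16 equally likely spore karyotypes.

    The exact reference distribution: index bits select disomy per
    chromosome.
    """
    table = table or default_table()
    weights = table.weights()
    idx = np.arange(1 << 16, dtype=np.uint32)
    bits = (idx[:, None] >> np.arange(16)) & 1
    return 1.0 + bits @ weights


def ks_compare(
    observed: Sequence[float],
    expected_sample: Sequence[float],
) -> tuple[float, float]:
    """Two-sample KS test of observed ploidies against the expected pool.

    Returns (D, p).  ``expected_sample`` is typically a large simulated pool
    (or the exact 2^16 enumeration for a one-sample-like comparison).
    """
    observed = np.asarray(observed, dtype=float)
    if observed.size == 0:
        raise ValueError("observed sample is empty")
    result = stats.ks_2samp(observed, np.asarray(expected_sample, dtype=float))
    return float(result.statistic), float(result.pvalue)


def expected_spores(n_tetrads: int) -> int:
    """Expected number of spores from dissected tetrads (4 per tetrad)."""
    if n_tetrads < 0:
        raise ValueError("tetrad count must be non-negative")
    return 4 * n_tetrads


def viability_percent(n_viable: int, n_expected: int) -> float:
    """Spore viability as a percentage of expected spores."""
    if n_expected <= 0 or n_viable < 0 or n_viable > n_expected:
        raise ValueError("need 0 <= viable <= expected, expected > 0")
    return 100.0 * n_viable / n_expected
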