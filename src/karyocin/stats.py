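"""Association and comparison statistics over strain collections.

Covers the test families the CIN analyses rely on: Fisher's exact test
(2x2 via the minimum-likelihood two-sided convention; r x c by exact
enumeration over fixed-margin tables, falling back to seeded Monte Carlo),
upper-tail hypergeometric enrichment, the systematic pairwise
chromosome-imbalance scan, Welch's t-test, growth-rate estimation by
log-linear regression of cell counts, normalized Gaussian-kernel density
profiles, and per-chromosome gene-list enrichment against a uniform
expectation.  The conventional significance threshold alpha = 0.05 is
exposed as ``ALPHA``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .chromosomes import CHROMOSOMES, ChromosomeTable, default_table
from .karyotype import Karyotype, aneuploidy_metrics, imbalance_ratio
from .network import CinClassification

__all__ = [
    "ALPHA",
    "StrainRecord",
    "fisher_exact",
    "hypergeometric_enrichment",
    "pairwise_imbalance_scan",
    "welch_t",
    "growth_rate",
    "density_profile",
    "chromosome_gene_enrichment",
]

#: Results are considered significant below this two-sided p-value.
ALPHA = 0.05


@dataclass(frozen=True)
class StrainRecord:
    """Per-strain bundle feeding the association analyses."""

    strain_id: str
    karyotype: Karyotype
    cin_class: str | None = None  # "S" | "MU" | "HU"
    growth_rate: float | None = None

    def __post_init__(self) -> None:
        if self.cin_class is not None and self.cin_class not in {"S", "MU", "HU"}:
            raise ValueError("cin_class must be S, MU or HU")

    def metrics(self, table: ChromosomeTable | None = None):
        return aneuploidy_metrics(self.karyotype, table)


def _validate_table(table: np.ndarray) -> np.ndarray:
    arr = np.asarray(table, dtype=np.int64)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if arr.sum() == 0:
        raise ValueError("table must contain at least one positive count")
    return arr


def _log_table_probability(table: np.ndarray) -> float:
    """Log multivariate hypergeometric probability given both margins."""
    from scipy.special import gammaln

    def lf(x):
        return gammaln(np.asarray(x, dtype=float) + 1.0)

    return float(
        lf(table.sum(axis=1)).sum()
        + lf(table.sum(axis=0)).sum()
        - lf(table.sum())
        - lf(table).sum()
    )


def _enumerate_fixed_margin_tables(
    row_sums: np.ndarray, col_sums: np.ndarray
) -> Iterable[np.ndarray]:
    """All non-negative integer tables with the given margins (recursive)."""
    r, c = len(row_sums), len(col_sums)
    table = np.zeros((r, c), dtype=np.int64)

    def fill(row: int, remaining_cols: np.ndarray):
        if row == r - 1:
            table[row] = remaining_cols
            yield table
            return
        target = row_sums[row]

        def cells(col: int, left: int):
            if col == c - 1:
                if 0 <= left <= remaining_cols[col]:
                    table[row, col] = left
                    yield True
                return
            upper = min(left, remaining_cols[col])
            for v in range(upper + 1):
                table[row, col] = v
                yield from cells(col + 1, left - v)

        for _ in cells(0, int(target)):
            yield from fill(row + 1, remaining_cols - table[row])

    yield from fill(0, col_sums.copy())


def fisher_exact(
    table: Sequence[Sequence[int]],
    *,
    max_enumeration: int = 200_000,
    mc_samples: int = 100_000,
    mc_seed: int = 0,
) -> float:
    """Two-sided Fisher's exact test p-value for an r x c count table.

    Two-sided by the minimum-likelihood convention: the p-value sums the
    conditional probabilities of every fixed-margin table no more probable
    than the observed one.  2x2 tables are delegated to scipy; larger tables
    are enumerated exactly when the number of candidate tables is modest,
    otherwise estimated by Monte Carlo sampling from the margin-conditional
    null with a fixed seed.
    """
    arr = _validate_table(table)
    if arr.shape == (2, 2):
        return float(sps.fisher_exact(arr, alternative="two-sided")[1])

    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    log_p_obs = _log_table_probability(arr)
    tol = 1e-9

    # generous upper bound on the enumeration size
    bound = 1.0
    for rs in row_sums[:-1]:
        bound *= float(
            np.prod([(min(rs, cs) + 1) for cs in col_sums])
        )
        if bound > max_enumeration:
            break
    if bound <= max_enumeration:
        total = 0.0
        for cand in _enumerate_fixed_margin_tables(row_sums, col_sums):
            log_p = _log_table_probability(cand)
            if log_p <= log_p_obs + tol:
                total += np.exp(log_p)
        return float(min(total, 1.0))

    # Monte Carlo: resample category labels holding both margins fixed
    rng = np.random.default_rng(mc_seed)
    rows = np.repeat(np.arange(len(row_sums)), row_sums)
    cols = np.repeat(np.arange(len(col_sums)), col_sums)
    hits = 0
    for _ in range(mc_samples):
        perm = rng.permutation(cols)
        cand = np.zeros_like(arr)
        np.add.at(cand, (rows, perm), 1)
        if _log_table_probability(cand) <= log_p_obs + tol:
            hits += 1
    return (hits + 1) / (mc_samples + 1)


def hypergeometric_enrichment(
    hits_in_selection: int,
    selection_size: int,
    hits_total: int,
    population_size: int,
) -> float:
    """Upper-tail hypergeometric p-value P(X >= observed).

    ``X`` counts marked items in a uniform draw of ``selection_size`` items
    from a population containing ``hits_total`` marked items.
    """
    k, n, K, N = hits_in_selection, selection_size, hits_total, population_size
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError("inconsistent hypergeometric counts")
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def pairwise_imbalance_scan(
    strains: Sequence[StrainRecord],
    grouping: str = "hu-vs-rest",
) -> dict[tuple[str, str], float]:
    """Hypergeometric scan of chromosome-pair imbalance against CIN.

    For every unordered chromosome pair, strains whose copy-number ratio for
    the pair differs from 1 form the "imbalanced" selection; the test asks
    whether the unstable group (``"hu-vs-rest"``: HU vs S+MU;
    ``"s-vs-rest"``: MU+HU vs S) is enriched in that selection.  Returns the
    120-entry upper-triangle p-value map.
    """
    if grouping == "hu-vs-rest":
        unstable = {"HU"}
    elif grouping == "s-vs-rest":
        unstable = {"MU", "HU"}
    else:
        raise ValueError("grouping must be 'hu-vs-rest' or 's-vs-rest'")
    records = [s for s in strains if s.cin_class is not None]
    n_total = len(records)
    if n_total < 2:
        raise ValueError("need at least two classified strains")
    marked = sum(1 for s in records if s.cin_class in unstable)
    out: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(CHROMOSOMES, 2):
        imbalanced = [
            s for s in records if imbalance_ratio(s.karyotype, a, b) != 1
        ]
        hits = sum(1 for s in imbalanced if s.cin_class in unstable)
        out[(a, b)] = hypergeometric_enrichment(
            hits, len(imbalanced), marked, n_total
        )
    return out


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided unpaired Welch's t-test p-value."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 1.0
        raise ValueError("both groups are degenerate (zero variance)")
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def growth_rate(
    cell_counts: Sequence[float], times_h: Sequence[float]
) -> float:
    """Growth rate in generations per hour.

    Least-squares slope of log2(cell count) against time; a culture doubling
    every hour grows at 1 generation/h.
    """
    counts = np.asarray(cell_counts, dtype=float)
    times = np.asarray(times_h, dtype=float)
    if counts.size != times.size or counts.size < 2:
        raise ValueError("need matching counts and times, at least two points")
    if np.any(counts <= 0):
        raise ValueError("cell counts must be positive")
    slope, _ = np.polyfit(times, np.log2(counts), 1)
    return float(slope)


def density_profile(
    values: Sequence[float],
    class_weight: float = 1.0,
    grid: Sequence[float] | None = None,
    bandwidth: float | str = "silverman",
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density curve normalized to a peak of ``class_weight``.

    The curve's maximum equals ``class_weight`` exactly, so overlaying the
    per-class curves visualizes both shape and the relative share of strains
    per class.  Degenerate inputs (a single value or zero spread) return a
    Gaussian bump centred on the common value.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one value")
    if grid is None:
        span = vals.max() - vals.min()
        pad = 0.5 * span if span > 0 else max(abs(vals[0]), 1.0) * 0.25
        grid = np.linspace(vals.min() - pad, vals.max() + pad, 512)
    grid = np.asarray(grid, dtype=float)
    if vals.size == 1 or np.allclose(vals, vals[0]):
        width = (grid.max() - grid.min()) / 50 or 1.0
        curve = np.exp(-0.5 * ((grid - vals[0]) / width) ** 2)
    else:
        kde = sps.gaussian_kde(vals, bw_method=bandwidth)
        curve = kde(grid)
    curve = curve / curve.max() * class_weight
    return grid, curve


def chromosome_gene_enrichment(
    gene_to_chromosome: Mapping[str, str],
    gene_list: Iterable[str],
    table: ChromosomeTable | None = None,
) -> dict[str, dict[str, float]]:
    """Observed vs expected gene-list members per chromosome.

    Expected counts assume the list distributes across chromosomes in
    proportion to each chromosome's share of all mapped genes; a binomial
    upper-tail p accompanies each ratio.  Genes missing from the mapping are
    reported under the ``"unmapped"`` key.
    """
    genes = set(gene_list)
    unmapped = sorted(g for g in genes if g not in gene_to_chromosome)
    mapped = genes - set(unmapped)
    totals = {c: 0 for c in CHROMOSOMES}
    for chrom in gene_to_chromosome.values():
        totals[chrom] += 1
    n_genes = sum(totals.values())
    observed = {c: 0 for c in CHROMOSOMES}
    for g in mapped:
        observed[gene_to_chromosome[g]] += 1
    out: dict[str, dict[str, float]] = {}
    for c in CHROMOSOMES:
        expected = len(mapped) * totals[c] / n_genes if n_genes else 0.0
        p = (
            float(sps.binom.sf(observed[c] - 1, len(mapped), totals[c] / n_genes))
            if n_genes and mapped
            else 1.0
        )
        out[c] = {
            "observed": float(observed[c]),
            "expected": expected,
            "ratio": observed[c] / expected if expected > 0 else float("nan"),
            "p_binomial": p,
        }
    out["unmapped"] = {"n": float(len(unmapped))}
    return out
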