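"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementation paths they check:
the Steiner-tree oracle is a Dreyfus-Wagner dynamic program over the
hypercube of varying columns (the implementation enumerates Steiner
topologies), the Fisher oracle enumerates 2x2 tables directly, and the
population oracle simulates cells one by one.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def steiner_cost_oracle(terminals: list[tuple[int, ...]]) -> int:
    """Minimum Steiner tree cost over the grid of varying-column states.

    Dreyfus-Wagner DP: dp[S][v] = cost of an optimal tree spanning terminal
    subset S plus node v.  Exact for any number of terminals; practical for
    <= 6 terminals and <= 8 varying columns.
    """
    n_cols = len(terminals[0])
    cols = [i for i in range(n_cols) if len({t[i] for t in terminals}) > 1]
    if not cols:
        return 0
    states = [sorted({t[i] for t in terminals}) for i in cols]
    nodes = list(itertools.product(*states))
    proj = [tuple(t[i] for i in cols) for t in terminals]

    def dist(a, b):
        return sum(1 for x, y in zip(a, b) if x != y)

    idx = {v: i for i, v in enumerate(nodes)}
    n_v = len(nodes)
    dmat = [[dist(a, b) for b in nodes] for a in nodes]
    t = len(proj)
    INF = 10**9
    full = 1 << (t - 1)
    dp = [[INF] * n_v for _ in range(full)]
    for ti in range(1, t):
        row = dp[1 << (ti - 1)]
        src = dmat[idx[proj[ti]]]
        for i in range(n_v):
            row[i] = src[i]
    for S in range(1, full):
        row = dp[S]
        if S & (S - 1):  # merge strictly smaller subtrees
            sub = (S - 1) & S
            while sub:
                other = dp[sub]
                rest = dp[S ^ sub]
                for i in range(n_v):
                    c = other[i] + rest[i]
                    if c < row[i]:
                        row[i] = c
                sub = (sub - 1) & S
        # relax through the metric (distances are shortest paths already)
        for i in range(n_v):
            ri = row[i]
            if ri >= INF:
                continue
            di = dmat[i]
            for j in range(n_v):
                if ri + di[j] < row[j]:
                    row[j] = ri + di[j]
    root = idx[proj[0]]
    return min(dp[full - 1][i] + dmat[root][i] for i in range(n_v))


def fisher_2x2_oracle(table) -> float:
    """Two-sided Fisher p by direct enumeration of fixed-margin 2x2 tables."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # table [[x, r1-x], [c1-x, r2-(c1-x)]]
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def naive_population_sim(
    seed: tuple[int, ...],
    p: float,
    generations: int,
    rng: np.random.Generator,
) -> float:
    """Cell-by-cell population simulation, no cap, no grouping.

    Returns the deviant fraction at the final generation; raises if the
    population goes extinct.  Only usable at small generation counts.
    """
    cells = [tuple(seed)]
    for _ in range(generations):
        next_cells = []
        for cell in cells:
            d1 = list(cell)
            d2 = list(cell)
            for i in range(len(cell)):
                if rng.random() < p:
                    if rng.random() < 0.5:
                        d1[i] += 1
                        d2[i] -= 1
                    else:
                        d1[i] -= 1
                        d2[i] += 1
            for d in (d1, d2):
                if min(d) >= 1:
                    next_cells.append(tuple(d))
        cells = next_cells
        if not cells:
            raise RuntimeError("population extinct")
    return sum(1 for c in cells if c != tuple(seed)) / len(cells)


def permutation_test_oracle(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator, n_perm: int = 2000
) -> float:
    """Two-sided permutation p-value for a difference in means."""
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = abs(perm[: a.size].mean() - perm[a.size :].mean())
        if stat >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)
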