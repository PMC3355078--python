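"""Parsimony karyotype-network reconstruction and CIN classification.

Each strain contributes a matrix of 12 karyotypes (the population sample
that defines the founding karyotype plus 11 colonies).  Chromosomes act as
loci and copy numbers as alleles; the most likely karyotype network is the
graph connecting all observed karyotypes with the minimum total number of
copy-number change events, optionally routing through unobserved
intermediate ("median") karyotypes when that reduces the total — i.e. a
minimum Steiner tree in the Hamming graph over karyotype space.

For instances with at most five distinct observed karyotypes (the typical
case for 12-row matrices) the optimum is found exactly by enumerating
Steiner topologies - trees over the terminals plus up to t-2 internal nodes
of degree >= 3 - and solving per-chromosome unit-cost small parsimony
(Sankoff) on each topology; all co-optimal topologies are kept.  Larger
instances fall back to a median-joining style heuristic: a minimum spanning
tree over observed karyotypes, augmented by greedily inserting per-column
majority vectors of node triples whenever doing so strictly lowers the
spanning cost.

Chromosome instability is then read off the network: every edge incident to
the founding (population) karyotype is one CIN event, regardless of how many
chromosomes changed on it; changes that the network attributes to a deviant
karyotype's own progeny are not charged to the founder.  Strains are
classed stable (S, 0 events), mildly unstable (MU, 1) or highly unstable
(HU, >= 2).
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .chromosomes import CHROMOSOMES
from .karyotype import Karyotype

__all__ = [
    "KaryotypeMatrix",
    "KaryotypeNetwork",
    "CinClassification",
    "infer_modal_karyotype",
    "build_network",
    "count_root_events",
    "classify_cin",
]

Vec = tuple[int, ...]


@dataclass(frozen=True)
class KaryotypeMatrix:
    """Karyotype rows of one strain (population sample + colonies)."""

    rows: tuple[Vec, ...]
    root_row: int
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        rows = tuple(tuple(int(c) for c in r) for r in self.rows)
        if not rows:
            raise ValueError("matrix needs at least one row")
        if any(len(r) != 16 for r in rows):
            raise ValueError("every row must have 16 chromosome columns")
        if not 0 <= self.root_row < len(rows):
            raise ValueError("root_row out of range")
        object.__setattr__(self, "rows", rows)

    @property
    def root_karyotype(self) -> Karyotype:
        return Karyotype(self.rows[self.root_row])


@dataclass(frozen=True)
class CinClassification:
    """Root-linked event count and the derived CIN class."""

    n_root_events: int
    cin_class: str  # "S" | "MU" | "HU"

    @staticmethod
    def from_events(n: int) -> "CinClassification":
        cls = "S" if n == 0 else ("MU" if n == 1 else "HU")
        return CinClassification(n, cls)


class KaryotypeNetwork:
    """A reconstructed karyotype network.

    Nodes are karyotype vectors carrying observation frequency (0 for
    inferred median nodes); edges carry the set of changed chromosomes
    signed by direction away from the root.
    """

    def __init__(
        self,
        graph: nx.Graph,
        root: Vec,
        frequencies: dict[Vec, int],
    ) -> None:
        if root not in graph:
            raise ValueError("root karyotype absent from network")
        if graph.number_of_nodes() > 1 and not nx.is_connected(graph):
            raise ValueError("network must be connected")
        self.graph = graph
        self.root = root
        for node in graph.nodes:
            graph.nodes[node]["frequency"] = frequencies.get(node, 0)
            graph.nodes[node]["is_root"] = node == root
        self._label_edges()

    def _label_edges(self) -> None:
        """Orient edges away from the root and label chromosome changes."""
        for parent, child in nx.bfs_edges(self.graph, self.root):
            changes = []
            for i in range(16):
                delta = child[i] - parent[i]
                if delta:
                    sign = "+" if delta > 0 else "-"
                    changes.append(f"{sign}{CHROMOSOMES[i]}")
            self.graph.edges[parent, child]["changes"] = tuple(changes)
            self.graph.edges[parent, child]["label"] = ",".join(changes)

    @property
    def total_cost(self) -> int:
        """Total copy-number change count over all edges."""
        return sum(
            sum(1 for a, b in zip(u, v) if a != b) for u, v in self.graph.edges
        )

    def root_edges(self) -> list[tuple[Vec, Vec]]:
        return [(self.root, nbr) for nbr in self.graph.neighbors(self.root)]

    def signature(self) -> frozenset[frozenset[Vec]]:
        return frozenset(frozenset((u, v)) for u, v in self.graph.edges)


def infer_modal_karyotype(
    colonies: Sequence[Karyotype],
    population: Karyotype | None = None,
) -> tuple[Karyotype, tuple[str, ...]]:
    """Per-chromosome modal copy number across colonies.

    Ties are resolved toward the population-sample copy number when one is
    provided; otherwise the lowest tied value is taken and the chromosome is
    reported in the unresolved-ties tuple.
    """
    if not colonies:
        raise ValueError("need at least one colony karyotype")
    arr = np.array([k.copies for k in colonies], dtype=int)
    modal = np.empty(16, dtype=int)
    unresolved: list[str] = []
    for i in range(16):
        values, counts = np.unique(arr[:, i], return_counts=True)
        winners = values[counts == counts.max()]
        if winners.size == 1:
            modal[i] = winners[0]
        elif population is not None and population.copies[i] in winners:
            modal[i] = population.copies[i]
        else:
            modal[i] = winners.min()
            unresolved.append(CHROMOSOMES[i])
    return Karyotype.from_iterable(modal), tuple(unresolved)


# ---------------------------------------------------------------------------
# exact search: Steiner topology enumeration + per-column Sankoff labelling


def _prufer_trees(n: int) -> Iterable[list[tuple[int, int]]]:
    """All labeled trees on nodes 0..n-1, decoded from Prüfer sequences."""
    if n == 1:
        yield []
        return
    if n == 2:
        yield [(0, 1)]
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in seq:
            degree[v] += 1
        edges: list[tuple[int, int]] = []
        deg = degree[:]
        heap = [i for i in range(n) if deg[i] == 1]
        heapq.heapify(heap)
        for v in seq:
            leaf = heapq.heappop(heap)
            edges.append((leaf, v))
            deg[v] -= 1
            if deg[v] == 1:
                heapq.heappush(heap, v)
        u, w = heapq.heappop(heap), heapq.heappop(heap)
        edges.append((u, w))
        yield edges


@lru_cache(maxsize=None)
def _steiner_topologies(n_terminals: int) -> tuple[tuple[tuple[int, int], ...], ...]:
    """All Steiner topologies for ``n_terminals`` labelled terminals.

    Nodes 0..t-1 are terminals, t.. are Steiner nodes (degree >= 3, up to
    t-2 of them); topologies are deduplicated under Steiner relabelling.
    """
    t = n_terminals
    if t == 1:
        return ((),)
    seen: set[tuple[tuple[int, int], ...]] = set()
    out: list[tuple[tuple[int, int], ...]] = []
    max_steiner = max(0, t - 2)
    for s in range(max_steiner + 1):
        n = t + s
        steiner = list(range(t, n))
        for edges in _prufer_trees(n):
            degree = [0] * n
            for u, v in edges:
                degree[u] += 1
                degree[v] += 1
            if any(degree[v] < 3 for v in steiner):
                continue
            canonical = None
            for perm in itertools.permutations(steiner):
                relabel = {old: new for old, new in zip(steiner, perm)}
                mapped = tuple(
                    sorted(
                        tuple(
                            sorted(
                                (relabel.get(u, u), relabel.get(v, v))
                            )
                        )
                        for u, v in edges
                    )
                )
                if canonical is None or mapped < canonical:
                    canonical = mapped
            if canonical not in seen:
                seen.add(canonical)
                out.append(canonical)
    return tuple(out)


def _root_topology(
    edges: Sequence[tuple[int, int]], n_nodes: int, root: int
) -> list[list[int]]:
    """Children lists of the topology rooted at ``root`` (parent order)."""
    adj: list[list[int]] = [[] for _ in range(n_nodes)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    seen = {root}
    stack = [root]
    order = [root]
    while stack:
        node = stack.pop()
        for nbr in adj[node]:
            if nbr not in seen:
                seen.add(nbr)
                children[node].append(nbr)
                stack.append(nbr)
                order.append(nbr)
    return children, order  # type: ignore[return-value]


def _sankoff_column(
    children: list[list[int]],
    order: list[int],
    terminal_states: dict[int, int],
    states: Sequence[int],
    root: int,
) -> tuple[int, dict[int, int]]:
    """Unit-cost small parsimony for one column on a rooted topology.

    Terminal states are fixed; Steiner nodes range over ``states``.  Returns
    the minimum change count and one optimal assignment (ties broken toward
    the parent's state, so labellings are deterministic and parsimonious
    near the root).
    """
    INF = 10**9
    k = len(states)
    state_index = {s: j for j, s in enumerate(states)}
    cost = {v: [0] * k for v in order}
    for v in reversed(order):
        if v in terminal_states:
            fixed = state_index[terminal_states[v]]
            base = [0 if j == fixed else INF for j in range(k)]
        else:
            base = [0] * k
        for j in range(k):
            total = base[j]
            for child in children[v]:
                total += min(
                    cost[child][m] + (0 if m == j else 1) for m in range(k)
                )
            cost[v][j] = min(total, INF)

    assignment: dict[int, int] = {}
    root_j = min(range(k), key=lambda j: cost[root][j])
    best_cost = cost[root][root_j]
    assignment[root] = root_j
    for v in order:
        if v == root:
            continue
        parent_j = assignment[_parent_of(children, v, order)]
        # prefer keeping the parent's state on ties
        best = min(
            range(k),
            key=lambda j: (cost[v][j] + (0 if j == parent_j else 1), j != parent_j, j),
        )
        assignment[v] = best
    return best_cost, {v: states[j] for v, j in assignment.items()}


def _parent_of(children: list[list[int]], node: int, order: list[int]) -> int:
    for v in order:
        if node in children[v]:
            return v
    raise RuntimeError("node has no parent")  # pragma: no cover


def _exact_networks(
    terminals: list[Vec],
    root_vec: Vec,
    frequencies: dict[Vec, int],
) -> list[KaryotypeNetwork]:
    t = len(terminals)
    root_idx = terminals.index(root_vec)
    varying = [i for i in range(16) if len({v[i] for v in terminals}) > 1]
    col_states = {i: sorted({v[i] for v in terminals}) for i in varying}

    best_cost: int | None = None
    solutions: list[tuple[tuple[tuple[int, int], ...], dict[int, Vec]]] = []
    for edges in _steiner_topologies(t):
        n = t + (max(max(e) for e in edges) - t + 1 if edges else 0)
        n = max(n, t)
        children, order = _root_topology(edges, n, root_idx)
        total = 0
        assignments: dict[int, list[int]] = {v: list(terminals[root_idx]) for v in range(n)}
        feasible = True
        for col in varying:
            term_states = {j: terminals[j][col] for j in range(t)}
            col_cost, assign = _sankoff_column(
                children, order, term_states, col_states[col], root_idx
            )
            if col_cost >= 10**9:
                feasible = False
                break
            total += col_cost
            for v in range(n):
                assignments[v][col] = assign[v]
        if not feasible:
            continue
        if best_cost is None or total < best_cost:
            best_cost = total
            solutions = []
        if total == best_cost:
            vectors = {v: tuple(assignments[v]) for v in range(n)}
            solutions.append((edges, vectors))

    networks: list[KaryotypeNetwork] = []
    seen: set[frozenset[frozenset[Vec]]] = set()
    for edges, vectors in solutions:
        graph = nx.Graph()
        graph.add_nodes_from(terminals)
        for u, v in edges if edges else []:
            a, b = vectors[u], vectors[v]
            if a != b:
                graph.add_edge(a, b)
        if not edges:
            graph.add_node(root_vec)
        # drop inferred nodes left isolated by zero-length contraction
        for node in list(graph.nodes):
            if node not in frequencies and graph.degree(node) == 0:
                graph.remove_node(node)
        net = KaryotypeNetwork(graph, root_vec, frequencies)
        sig = net.signature()
        if sig not in seen:
            seen.add(sig)
            networks.append(net)
    return networks


# ---------------------------------------------------------------------------
# heuristic: minimum spanning network with median-vector augmentation


def _hamming(a: Vec, b: Vec) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _mst_cost(nodes: list[Vec]) -> int:
    graph = nx.Graph()
    graph.add_nodes_from(range(len(nodes)))
    for i, j in itertools.combinations(range(len(nodes)), 2):
        graph.add_edge(i, j, weight=_hamming(nodes[i], nodes[j]))
    return int(
        sum(
            d["weight"]
            for _, _, d in nx.minimum_spanning_edges(graph, algorithm="kruskal")
        )
    )


def _median_vector(a: Vec, b: Vec, c: Vec) -> Vec:
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:  # three-way tie: deterministic, keep the first
            out.append(x)
    return tuple(out)


def _heuristic_network(
    terminals: list[Vec],
    root_vec: Vec,
    frequencies: dict[Vec, int],
    max_medians: int = 16,
) -> list[KaryotypeNetwork]:
    nodes = list(terminals)
    cost = _mst_cost(nodes)
    for _ in range(max_medians):
        candidates = {
            _median_vector(a, b, c)
            for a, b, c in itertools.combinations(nodes, 3)
        } - set(nodes)
        best_gain = 0
        best_node: Vec | None = None
        for cand in sorted(candidates):
            new_cost = _mst_cost(nodes + [cand])
            gain = cost - new_cost
            if gain > best_gain:
                best_gain, best_node = gain, cand
        if best_node is None:
            break
        nodes.append(best_node)
        cost -= best_gain

    graph = nx.Graph()
    graph.add_nodes_from(range(len(nodes)))
    for i, j in itertools.combinations(range(len(nodes)), 2):
        graph.add_edge(i, j, weight=_hamming(nodes[i], nodes[j]))
    mst = nx.minimum_spanning_tree(graph, algorithm="kruskal")

    # splice out unobserved pass-through nodes that add no parsimony value
    changed = True
    while changed:
        changed = False
        for i in list(mst.nodes):
            if nodes[i] in frequencies or mst.degree(i) != 2:
                continue
            a, b = list(mst.neighbors(i))
            through = mst.edges[a, i]["weight"] + mst.edges[i, b]["weight"]
            if _hamming(nodes[a], nodes[b]) == through:
                mst.remove_node(i)
                mst.add_edge(a, b, weight=through)
                changed = True

    out = nx.Graph()
    out.add_nodes_from(nodes[i] for i in mst.nodes)
    out.add_edges_from((nodes[i], nodes[j]) for i, j in mst.edges)
    return [KaryotypeNetwork(out, root_vec, frequencies)]


def build_network(
    matrix: KaryotypeMatrix, *, max_exact_terminals: int = 5
) -> list[KaryotypeNetwork]:
    """Reconstruct the most parsimonious karyotype network(s).

    Duplicate rows collapse into frequency-weighted nodes.  Returns every
    co-optimal network found (exact enumeration when the number of distinct
    karyotypes is at most ``max_exact_terminals``, heuristic single solution
    beyond that).
    """
    frequencies: dict[Vec, int] = {}
    for row in matrix.rows:
        frequencies[row] = frequencies.get(row, 0) + 1
    root_vec = matrix.rows[matrix.root_row]
    terminals = sorted(frequencies)
    if len(terminals) == 1:
        graph = nx.Graph()
        graph.add_node(root_vec)
        return [KaryotypeNetwork(graph, root_vec, frequencies)]
    if len(terminals) <= max_exact_terminals:
        return _exact_networks(terminals, root_vec, frequencies)
    return _heuristic_network(terminals, root_vec, frequencies)


def count_root_events(network: KaryotypeNetwork) -> CinClassification:
    """CIN events chargeable to the founding karyotype.

    Each network edge incident to the root counts as exactly one event, no
    matter how many chromosomes changed on it; edges deeper in the network
    belong to deviant progeny and contribute nothing.
    """
    return CinClassification.from_events(network.graph.degree(network.root))


def classify_cin(
    networks: Sequence[KaryotypeNetwork],
) -> tuple[list[CinClassification], str | None]:
    """Classification per co-optimal network plus the consensus class.

    The consensus is the shared class when all co-optimal networks agree
    (the usual case) and ``None`` otherwise.
    """
    if not networks:
        raise ValueError("no networks to classify")
    calls = [count_root_events(net) for net in networks]
    classes = {c.cin_class for c in calls}
    return calls, (classes.pop() if len(classes) == 1 else None)
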