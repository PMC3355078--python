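import itertools

import numpy as np
import pytest

from karyocin.karyotype import Karyotype
from karyocin.network import (
    CinClassification,
    KaryotypeMatrix,
    KaryotypeNetwork,
    build_network,
    classify_cin,
    count_root_events,
    infer_modal_karyotype,
)

from .oracles import steiner_cost_oracle

HAPLOID = (1,) * 16


def vec(*disomic: int) -> tuple[int, ...]:
    """Haploid background with the given chromosome indices disomic."""
    return tuple(2 if i in disomic else 1 for i in range(16))


def matrix(rows, root=0):
    padded = list(rows) + [rows[root]] * max(0, 12 - len(rows))
    return KaryotypeMatrix(rows=tuple(padded), root_row=root)


class TestInferModalKaryotype:
    def test_identical_colonies(self):
        k = Karyotype(vec(3))
        modal, ties = infer_modal_karyotype([k] * 11)
        assert modal == k and ties == ()

    def test_majority_wins(self):
        nine = [Karyotype(vec(3))] * 9
        two = [Karyotype(HAPLOID)] * 2
        modal, ties = infer_modal_karyotype(nine + two)
        assert modal == Karyotype(vec(3))
        assert ties == ()

    def test_tie_resolved_by_population_evidence(self):
        half_a = [Karyotype(vec(0))] * 5
        half_b = [Karyotype(HAPLOID)] * 5
        modal, ties = infer_modal_karyotype(
            half_a + half_b, population=Karyotype(vec(0))
        )
        assert modal == Karyotype(vec(0))
        assert ties == ()

    def test_unresolved_tie_flagged(self):
        modal, ties = infer_modal_karyotype(
            [Karyotype(vec(0))] * 5 + [Karyotype(HAPLOID)] * 5
        )
        assert ties == ("I",)

    def test_recovers_seed_from_synthetic_colonies(self):
        from karyocin.missegregation import simulate_colony

        rng = np.random.default_rng(17)
        seed = Karyotype(vec(1, 4, 9))
        colony = simulate_colony(seed, 1e-3, 25, population_cap=5000, rng=rng)
        cells = colony.sample_cells(11, rng)
        modal, _ = infer_modal_karyotype([k for k, _ in cells])
        assert modal == seed


class TestBuildNetworkBasics:
    def test_all_identical_single_node(self):
        nets = build_network(matrix([HAPLOID] * 12))
        assert len(nets) == 1
        net = nets[0]
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0
        assert net.graph.nodes[HAPLOID]["frequency"] == 12

    def test_single_deviant_one_edge(self):
        nets = build_network(matrix([HAPLOID] * 11 + [vec(15)]))
        net = nets[0]
        assert net.graph.number_of_edges() == 1
        assert net.graph.edges[HAPLOID, vec(15)]["label"] == "+XVI"

    def test_multichromosome_deviant_single_edge(self):
        nets = build_network(matrix([HAPLOID] * 10 + [vec(6, 9)] * 2))
        net = nets[0]
        assert net.total_cost == 2
        assert net.graph.number_of_edges() == 1
        assert net.graph.edges[HAPLOID, vec(6, 9)]["label"] == "+VII,+X"

    def test_chain_beats_star(self):
        # deviant B = A plus one more change: route B through A
        rows = [HAPLOID, vec(0), vec(0, 1)]
        nets = build_network(matrix(rows))
        for net in nets:
            assert net.total_cost == 2
            assert net.graph.degree(HAPLOID) == 1

    def test_duplicate_rows_change_frequencies_only(self):
        rows_a = [HAPLOID] * 10 + [vec(3)] * 2
        rows_b = [HAPLOID] * 8 + [vec(3)] * 4
        sig_a = build_network(matrix(rows_a))[0].signature()
        sig_b = build_network(matrix(rows_b))[0].signature()
        assert sig_a == sig_b

    def test_cooptimal_ties_enumerated(self):
        # square: root, two single-step deviants, and their combination;
        # every spanning tree dropping one unit edge of the 4-cycle ties at 3
        rows = [HAPLOID, vec(0), vec(1), vec(0, 1)]
        nets = build_network(matrix(rows))
        assert {net.total_cost for net in nets} == {3}
        assert len(nets) == 4
        calls, consensus = classify_cin(nets)
        # chains give MU, the two stars give HU: genuinely ambiguous
        assert consensus is None
        assert {c.cin_class for c in calls} == {"MU", "HU"}


class TestOptimalityAgainstOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_dreyfus_wagner_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            n_distinct = int(rng.integers(2, 6))
            rows = {HAPLOID}
            while len(rows) < n_distinct:
                changed = rng.choice(16, size=int(rng.integers(1, 5)), replace=False)
                rows.add(tuple(2 if i in changed else 1 for i in range(16)))
            rows = sorted(rows)
            nets = build_network(matrix(rows))
            oracle = steiner_cost_oracle(rows)
            assert nets[0].total_cost == oracle
            assert all(net.total_cost == oracle for net in nets)

    def test_median_node_used_when_it_saves_changes(self):
        # three deviants pairwise distance 2 around an unobserved center
        rows = [vec(0, 1), vec(1, 2), vec(0, 2)]
        nets = build_network(matrix(rows, root=0))
        oracle = steiner_cost_oracle(rows)
        assert nets[0].total_cost == oracle == 3
        for net in nets:
            inferred = [
                n for n, d in net.graph.nodes(data=True) if d["frequency"] == 0
            ]
            assert len(inferred) == 1  # the median vector (+I,+II,+III all at 1...)

    def test_row_and_column_permutation_invariance(self):
        rng = np.random.default_rng(42)
        rows = [HAPLOID, vec(2), vec(2, 5), vec(11)]
        base_cost = build_network(matrix(rows))[0].total_cost
        base_degree = build_network(matrix(rows))[0].graph.degree(HAPLOID)
        for _ in range(5):
            perm = rng.permutation(16)
            permuted = [tuple(r[i] for i in perm) for r in rows]
            order = rng.permutation(len(rows))
            shuffled = [permuted[i] for i in order]
            root = int(np.argwhere(order == 0)[0][0])
            nets = build_network(matrix(shuffled, root=root))
            assert nets[0].total_cost == base_cost
            assert nets[0].graph.degree(tuple(HAPLOID[i] for i in perm)) == base_degree

    def test_heuristic_path_on_star_instance(self):
        # 7 distinct karyotypes forces the heuristic; star from root is optimal
        rows = [HAPLOID] + [vec(i) for i in range(6)]
        nets = build_network(matrix(rows))
        assert nets[0].total_cost == steiner_cost_oracle(rows) == 6
        assert nets[0].graph.degree(HAPLOID) == 6


class TestCinClassification:
    def test_single_node_is_stable(self):
        nets = build_network(matrix([HAPLOID] * 12))
        assert count_root_events(nets[0]) == CinClassification(0, "S")

    def test_multichromosome_edge_is_one_event(self):
        nets = build_network(matrix([HAPLOID] * 11 + [vec(6, 9)]))
        assert count_root_events(nets[0]) == CinClassification(1, "MU")

    def test_secondary_events_not_charged_to_root(self):
        # two direct deviants, one of which spawned its own deviant
        rows = [HAPLOID] * 6 + [vec(0)] * 3 + [vec(0, 1)] * 2 + [vec(11)]
        nets = build_network(matrix(rows))
        oracle = steiner_cost_oracle(sorted(set(rows)))
        assert nets[0].total_cost == oracle
        calls, consensus = classify_cin(nets)
        assert consensus == "HU"
        assert all(c.n_root_events == 2 for c in calls)

    def test_class_boundaries(self):
        assert CinClassification.from_events(0).cin_class == "S"
        assert CinClassification.from_events(1).cin_class == "MU"
        assert CinClassification.from_events(2).cin_class == "HU"
        assert CinClassification.from_events(5).cin_class == "HU"

    def test_root_must_be_in_network(self):
        import networkx as nx

        g = nx.Graph()
        g.add_node(vec(0))
        with pytest.raises(ValueError):
            KaryotypeNetwork(g, HAPLOID, {vec(0): 1})
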