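"""Network construction, classification, lineages, ancestrality."""

import random
from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapcol import (InputError, UnsupportedOperationError, ancestrality_rank,
                    build_network, classify_nodes, lineages,
                    pairwise_distances, read_incidence)
from hapcol.network import write_edgelist

from conftest import (bf_hamming, make_table, oracle_msn_connections,
                      oracle_on_cycle, replica_network_table)


def network_connections(net):
    """Retained observed-pair connections as {(a, b, steps)} with a < b."""
    return {(min(c.a, c.b), max(c.a, c.b), c.steps)
            for c in net.connections}


class TestPairwiseDistances:
    def test_identity_and_single_difference(self):
        table = make_table(["ACGT", "ACGA"])
        d = pairwise_distances(table)
        assert d.loc["x1", "x1"] == 0
        assert d.loc["x1", "x2"] == d.loc["x2", "x1"] == 1

    def test_ambiguous_positions_do_not_count(self):
        table = make_table(["ACGT", "ANGA"])
        d = pairwise_distances(table)
        assert d.loc["x1", "x2"] == 1  # only the final site differs

    def test_matches_double_loop_oracle(self):
        rng = random.Random(7)
        seqs = ["".join(rng.choice("ACGT") for _ in range(30))
                for _ in range(8)]
        table = make_table(seqs)
        d = pairwise_distances(table)
        ids = table.haplotype_ids
        for i, j in combinations(range(8), 2):
            assert d.iloc[i, j] == bf_hamming(seqs[i], seqs[j])

    def test_sequence_free_table_refused(self, tmp_path):
        p = tmp_path / "i.tsv"
        p.write_text("haplotype\tA\nh1\t1\nh2\t2\n")
        with pytest.raises(UnsupportedOperationError):
            pairwise_distances(read_incidence(p))


class TestBuildNetwork:
    def test_two_haplotypes_one_step(self):
        net = build_network(make_table(["ACGT", "ACGA"]))
        assert network_connections(net) == {("x1", "x2", 1)}
        assert net.inferred == ()

    def test_three_step_pair_gets_two_missing_intermediates(self):
        net = build_network(make_table(["AAAA", "TTTA"]))
        assert len(net.inferred) == 2
        (conn,) = net.connections
        assert conn.steps == 3 and len(conn.intermediates) == 2
        # expanded path: x1 - m - m - x2, all single-step edges
        assert net.graph.number_of_edges() == 3

    def test_chain_prefers_short_edges_over_long(self):
        # d(A,B)=d(B,C)=1, d(A,C)=2: unique minimal network is the chain
        net = build_network(make_table(["ACGT", "ACGA", "ACTA"]))
        assert network_connections(net) == {("x1", "x2", 1),
                                            ("x2", "x3", 1)}
        cls = classify_nodes(net)
        assert cls["x2"] == "interior"
        assert cls["x1"] == cls["x3"] == "tip"

    def test_equal_distance_alternatives_retained_as_loop(self):
        # square over two sites: every neighbouring pair differs by one
        net = build_network(make_table(["AA", "AT", "TT", "TA"]))
        assert len(net.connections) == 4  # the 2-step diagonals lose
        flags = net.loop_flags()
        assert all(flags[n] for n in net.observed)

    def test_max_steps_disconnects_distant_groups(self):
        table = make_table(["AAAAAAAA", "AAAAAAAT", "TTTTAAAA", "TTTTAAAT"])
        net = build_network(table, max_steps=1)
        assert sorted(net.components) == [["x1", "x2"], ["x3", "x4"]]

    def test_empty_table_rejected(self):
        with pytest.raises(InputError):
            build_network(make_table([]))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_threshold_graph_oracle(self, seed):
        rng = random.Random(seed)
        n = rng.randint(2, 6)
        length = rng.randint(4, 12)
        alphabet = rng.choice(["AT", "ACGT"])
        seqs = []
        while len(seqs) < n:
            s = "".join(rng.choice(alphabet) for _ in range(length))
            if s not in seqs:
                seqs.append(s)
        table = make_table(seqs)
        net = build_network(table)
        want = oracle_msn_connections(
            dict(zip(table.haplotype_ids, seqs)))
        assert network_connections(net) == want

    def test_invariant_to_input_order(self):
        rng = random.Random(3)
        seqs = ["".join(rng.choice("AT") for _ in range(6))
                for _ in range(5)]
        seqs = list(dict.fromkeys(seqs))
        ids = [f"x{i + 1}" for i in range(len(seqs))]
        net1 = build_network(make_table(seqs, ids=ids))
        order = list(range(len(seqs)))
        rng.shuffle(order)
        net2 = build_network(make_table([seqs[i] for i in order],
                                        ids=[ids[i] for i in order]))
        assert network_connections(net1) == network_connections(net2)

    def test_connected_with_tree_edge_count_when_no_ties(self):
        rng = random.Random(11)
        # unique mutation sites -> perfect tree, n-1 connections
        base = "A" * 20
        seqs = [base]
        for i in range(6):
            parent = rng.choice(seqs)
            child = parent[:i * 2] + "T" + parent[i * 2 + 1:]
            if child not in seqs:
                seqs.append(child)
        net = build_network(make_table(seqs))
        assert len(net.components) == 1
        assert len(net.connections) == len(seqs) - 1
        total_inferred = sum(c.steps - 1 for c in net.connections)
        assert len(net.inferred) == total_inferred

    def test_loop_flags_match_brute_force_cycle_search(self):
        rng = random.Random(5)
        for _ in range(10):
            n = rng.randint(3, 6)
            seqs = []
            while len(seqs) < n:
                s = "".join(rng.choice("AT") for _ in range(5))
                if s not in seqs:
                    seqs.append(s)
            net = build_network(make_table(seqs))
            if net.graph.number_of_nodes() > 10:
                continue
            flags = net.loop_flags()
            edges = list(net.graph.edges)
            for node in net.graph.nodes:
                assert flags[node] == oracle_on_cycle(edges, node), node


class TestClassifyAndLineages:
    def test_star_centre_is_interior(self):
        base = "AAAAAA"
        tips = [base[:i] + "T" + base[i + 1:] for i in range(6)]
        net = build_network(make_table([base] + tips))
        cls = classify_nodes(net)
        assert cls["x1"] == "interior"
        assert [cls[f"x{i}"] for i in range(2, 8)] == ["tip"] * 6

    def test_single_node_isolated(self):
        net = build_network(make_table(["ACGT"]))
        assert classify_nodes(net) == {"x1": "isolated"}

    def test_replica_structure_two_interior_seven_tips(self):
        table = replica_network_table()
        net = build_network(table)
        cls = classify_nodes(net)
        observed = [cls[h] for h in table.haplotype_ids]
        assert observed.count("interior") == 2
        assert observed.count("tip") == 7

    def test_disconnected_pairs_are_two_lineages(self):
        table = make_table(["AAAAAAAA", "AAAAAAAT", "TTTTAAAA", "TTTTAAAT"])
        net = build_network(table, max_steps=1)
        assert lineages(net) == [["x1", "x2"], ["x3", "x4"]]

    def test_cut_middle_edge_splits_four_and_four(self):
        # path of 8 single-step haplotypes; cutting the middle edge
        # yields two lineages of four haplotypes each
        seqs = []
        cur = "AAAAAAA"
        seqs.append(cur)
        for i in range(7):
            cur = cur[:i] + "T" + cur[i + 1:]
            seqs.append(cur)
        net = build_network(make_table(seqs))
        parts = lineages(net, cut=[("x4", "x5")])
        assert sorted(len(p) for p in parts) == [4, 4]

    def test_cut_edge_must_exist(self):
        net = build_network(make_table(["ACGT", "ACGA"]))
        with pytest.raises(InputError):
            lineages(net, cut=[("x1", "nope")])

    def test_random_tree_single_lineage(self):
        rng = random.Random(9)
        base = "A" * 15
        seqs = [base]
        for i in range(5):
            parent = rng.choice(seqs)
            child = parent[:i * 3] + "G" + parent[i * 3 + 1:]
            if child not in seqs:
                seqs.append(child)
        net = build_network(make_table(seqs))
        assert len(lineages(net)) == 1


class TestAncestrality:
    def test_dominated_winner_ranks_first(self):
        table = replica_network_table()
        net = build_network(table)
        report = ancestrality_rank(net, table)
        assert report.rank1() == "x1"
        row = report.frame.loc["x1"]
        assert row["steps_to_outgroup"] == 3
        assert row["degree"] == 6
        assert row["n_islands"] == 6
        assert row["n_samples"] == 53
        assert not report.no_outgroup

    def test_identical_profiles_tie_broken_by_id(self):
        table = make_table(["ACGT", "ACGA"])
        net = build_network(table)
        report = ancestrality_rank(net, table)
        assert list(report.frame.index) == ["x1", "x2"]
        assert report.frame["tied"].all()
        assert list(report.frame["rank"]) == [1, 2]

    def test_single_haplotype_rank_one(self):
        table = make_table(["ACGT"])
        report = ancestrality_rank(build_network(table), table)
        assert report.frame.loc["x1", "rank"] == 1

    def test_no_outgroup_mode_flags_and_omits_steps(self):
        table = make_table(["ACGT", "ACGA", "ACTA"])
        report = ancestrality_rank(build_network(table), table)
        assert report.no_outgroup
        assert report.frame["steps_to_outgroup"].isna().all()

    def test_steps_use_raw_distance_not_graph_path(self):
        # outgroup far beyond max_steps still gets a defined step count
        table = make_table(["AAAAAAAA", "AAAAAAAT"],
                           outgroups=["TTTTTTTT"])
        net = build_network(table, max_steps=1)
        report = ancestrality_rank(net, table)
        assert report.frame.loc["x1", "steps_to_outgroup"] == 8
        assert report.frame.loc["x2", "steps_to_outgroup"] == 7


class TestExports:
    def test_edgelist_marks_inferred_nodes(self, tmp_path):
        net = build_network(make_table(["AAAA", "TTAA"]))
        p = tmp_path / "edges.tsv"
        write_edgelist(net, p)
        lines = p.read_text().strip().splitlines()
        assert lines[0] == "node_a\tnode_b\tinferred_a\tinferred_b"
        assert len(lines) == 3  # 2-step connection -> 2 expanded edges
        assert any("\t1" in line for line in lines[1:])
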