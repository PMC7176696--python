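import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ibdnet import (
    PopulationTable,
    SegmentSimConfig,
    SharingSummary,
    build_network,
    components_and_isolated,
    export_network,
    import_network,
    population_pair_matrix,
    possible_pair_counts,
    regional_subnetwork,
    sharing_rates,
    simulate_segments,
)

from conftest import make_segment


class TestBuildNetwork:
    def test_edges_follow_segments(self, toy_table):
        segs = [make_segment(a="A1", b="A2"), make_segment(a="A2", b="A3")]
        g = build_network(segs, toy_table)
        assert set(g.nodes) == {"A1", "A2", "A3"}
        assert set(map(frozenset, g.edges)) == {frozenset({"A1", "A2"}), frozenset({"A2", "A3"})}
        assert nx.number_connected_components(g) == 1

    def test_multi_segment_pair_is_one_weighted_edge(self, toy_table):
        segs = [
            make_segment(a="A1", b="B1", length=7.0),
            make_segment(a="B1", b="A1", chrom="2", length=9.0),
        ]
        g = build_network(segs, toy_table)
        assert g.number_of_edges() == 1
        assert g["A1"]["B1"]["count"] == 2
        assert g["A1"]["B1"]["total_cM"] == pytest.approx(16.0)

    def test_include_isolated_adds_degree_zero_nodes(self, toy_table):
        g = build_network([], toy_table, include_isolated=True)
        assert g.number_of_nodes() == 5 and g.number_of_edges() == 0

    def test_unknown_sample_strict_raises(self, toy_table):
        with pytest.raises(KeyError, match="ZZ"):
            build_network([make_segment(a="ZZ", b="A1")], toy_table)

    def test_degree_counts_partners_not_segments(self, toy_table):
        segs = [
            make_segment(a="A1", b="A2"),
            make_segment(a="A1", b="A2", chrom="2"),
            make_segment(a="A1", b="B1"),
        ]
        g = build_network(segs, toy_table)
        assert g.degree["A1"] == 2


class TestPairCounts:
    def test_small_table_matches_enumeration(self, toy_table):
        intra, inter = possible_pair_counts(toy_table)
        # brute-force enumeration of all 10 unordered pairs
        inds = toy_table.individuals
        pairs = list(itertools.combinations(inds, 2))
        intra_brute = sum(1 for a, b in pairs if toy_table[a] == toy_table[b])
        assert (intra, inter) == (intra_brute, len(pairs) - intra_brute)
        assert (intra, inter) == (4, 6)

    def test_single_population_has_no_inter_pairs(self):
        table = PopulationTable.from_mapping({f"i{k}": "A" for k in range(6)})
        assert possible_pair_counts(table) == (15, 0)

    def test_singleton_populations_have_no_intra_pairs(self):
        table = PopulationTable.from_mapping({f"i{k}": f"P{k}" for k in range(5)})
        assert possible_pair_counts(table) == (0, 10)

    def test_fewer_than_two_individuals_errors(self):
        with pytest.raises(ValueError):
            possible_pair_counts(PopulationTable.from_mapping({"i": "A"}))

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(st.integers(1, 30), min_size=1, max_size=10).filter(lambda s: sum(s) >= 2)
    )
    def test_intra_plus_inter_is_all_pairs(self, sizes):
        labels = {}
        for p, n in enumerate(sizes):
            for k in range(n):
                labels[f"p{p}_i{k}"] = f"P{p}"
        table = PopulationTable.from_mapping(labels)
        intra, inter = possible_pair_counts(table)
        n = table.n_individuals
        assert intra + inter == n * (n - 1) // 2


class TestSharingRates:
    def test_reference_count_regime(self):
        # 235 segments over 86,403 possible inter pairs -> 0.0027 per pair
        summary = SharingSummary.from_counts(
            intra_segments=1014, inter_segments=235, intra_pairs=5403, inter_pairs=86403
        )
        assert round(summary.inter_rate, 4) == 0.0027

    def test_no_segments_means_zero_rates(self, toy_table):
        summary = sharing_rates([], toy_table)
        assert summary.intra_rate == 0.0 and summary.inter_rate == 0.0
        assert summary.ratio is None

    def test_toy_rates_and_ratio_by_hand(self, toy_table):
        segs = [
            make_segment(a="A1", b="A2"),
            make_segment(a="A1", b="A3"),
            make_segment(a="A1", b="B1"),
        ]
        summary = sharing_rates(segs, toy_table)
        assert summary.intra_rate == pytest.approx(2 / 4)
        assert summary.inter_rate == pytest.approx(1 / 6)
        assert summary.ratio == pytest.approx(3.0)

    def test_planted_rate_ratio_recovered(self):
        # lambda_intra / lambda_inter = 10; estimate over pooled replicates
        lam_i, lam_x = 0.2, 0.02
        intra_seg = inter_seg = intra_pairs = inter_pairs = 0
        for seed in range(30):
            cfg = SegmentSimConfig(
                populations={"A": 12, "B": 12},
                lambda_intra=lam_i,
                lambda_inter=lam_x,
                seed=seed,
            )
            segs, table, _ = simulate_segments(cfg)
            s = sharing_rates(segs, table)
            intra_seg += s.intra_segment_count
            inter_seg += s.inter_segment_count
            intra_pairs += s.intra_pair_count
            inter_pairs += s.inter_pair_count
        ratio = (intra_seg / intra_pairs) / (inter_seg / inter_pairs)
        # delta-method MC standard error of the ratio of two Poisson rates
        se = ratio * np.sqrt(1 / intra_seg + 1 / inter_seg)
        assert abs(ratio - lam_i / lam_x) < 3 * se


class TestPopulationMatrix:
    def test_toy_entries_by_hand(self):
        table = PopulationTable.from_mapping({"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
        segs = [make_segment(a="A1", b="A2"), make_segment(a="A1", b="B1")]
        m = population_pair_matrix(segs, table)
        assert m.loc["A", "A"] == pytest.approx(1.0)
        assert m.loc["A", "B"] == pytest.approx(0.25)
        assert m.loc["B", "B"] == 0.0

    def test_no_segments_gives_zero_matrix(self, toy_table):
        m = population_pair_matrix([], toy_table)
        assert (m.fillna(0).to_numpy() == 0).all()

    def test_singleton_population_diagonal_is_missing(self):
        table = PopulationTable.from_mapping({"A1": "A", "B1": "B", "B2": "B"})
        m = population_pair_matrix([], table)
        assert np.isnan(m.loc["A", "A"])

    def test_reconstruction_identity(self):
        cfg = SegmentSimConfig(populations={"A": 8, "B": 6, "C": 5}, seed=9)
        segs, table, _ = simulate_segments(cfg)
        m = population_pair_matrix(segs, table)
        sizes = table.sizes
        total = 0.0
        for i, p in enumerate(m.index):
            for j, q in enumerate(m.columns):
                if j < i:
                    continue
                pairs = (
                    sizes[p] * (sizes[p] - 1) / 2 if p == q else sizes[p] * sizes[q]
                )
                if pairs:
                    total += m.loc[p, q] * pairs
        assert total == pytest.approx(len(segs))


class TestComponents:
    def test_two_components_and_disconnected_set(self, toy_table):
        segs = [
            make_segment(a="A1", b="A2"),
            make_segment(a="A2", b="A3"),
            make_segment(a="B1", b="B2"),
        ]
        comps, disconnected = components_and_isolated(build_network(segs, toy_table))
        assert comps[0] == {"A1", "A2", "A3"}
        assert disconnected == {"B1", "B2"}

    def test_fully_connected_has_no_disconnected(self, toy_table):
        segs = [make_segment(a=a, b=b) for a, b in itertools.combinations(toy_table.individuals, 2)]
        _, disconnected = components_and_isolated(build_network(segs, toy_table))
        assert disconnected == set()

    def test_empty_network(self):
        assert components_and_isolated(nx.Graph()) == ([], set())

    def test_partition_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(17)
        g = nx.Graph()
        g.add_nodes_from(range(100))
        for _ in range(80):
            a, b = rng.integers(0, 100, size=2)
            if a != b:
                g.add_edge(int(a), int(b))
        comps, _ = components_and_isolated(g)

        # flood-fill oracle
        seen, oracle = set(), []
        for start in g.nodes:
            if start in seen:
                continue
            stack, comp = [start], set()
            while stack:
                v = stack.pop()
                if v in comp:
                    continue
                comp.add(v)
                stack.extend(g.neighbors(v))
            seen |= comp
            oracle.append(comp)
        assert sorted(map(len, comps), reverse=True) == sorted(map(len, oracle), reverse=True)
        assert {frozenset(c) for c in comps} == {frozenset(c) for c in oracle}


class TestModularityCommunities:
    def test_two_dense_blocks_recovered(self):
        from ibdnet import modularity_communities

        cfg = SegmentSimConfig(
            populations={"A": 10, "B": 10}, lambda_intra=0.8, lambda_inter=0.0, seed=21
        )
        segs, table, _ = simulate_segments(cfg)
        g = build_network(segs, table)
        comms = modularity_communities(g)
        # with no inter-population sharing, no community mixes populations
        for c in comms:
            assert len({table[n] for n in c}) == 1

    def test_empty_network(self):
        from ibdnet import modularity_communities

        assert modularity_communities(nx.Graph()) == []


class TestRegionalSubnetwork:
    def test_one_hop_rule(self, toy_table):
        # chain A1(A) - B1 - B2: B2 is a neighbor-of-neighbor, excluded
        segs = [make_segment(a="A1", b="B1"), make_segment(a="B1", b="B2")]
        g = build_network(segs, toy_table)
        sub = regional_subnetwork(g, toy_table, ["A"])
        assert set(sub.nodes) == {"A1", "B1"}
        assert list(map(frozenset, sub.edges)) == [frozenset({"A1", "B1"})]

    def test_focal_population_without_segments(self, toy_table):
        g = build_network([make_segment(a="B1", b="B2")], toy_table, include_isolated=True)
        sub = regional_subnetwork(g, toy_table, ["A"])
        assert set(sub.nodes) == {"A1", "A2", "A3"} and sub.number_of_edges() == 0

    def test_unknown_population_errors(self, toy_table):
        g = build_network([], toy_table, include_isolated=True)
        with pytest.raises(KeyError, match="Z"):
            regional_subnetwork(g, toy_table, ["Z"])


class TestExport:
    @pytest.fixture
    def toy_net(self, toy_table):
        segs = [make_segment(a="A1", b="A2", length=7.5), make_segment(a="A1", b="B1", length=6.25)]
        return build_network(segs, toy_table)

    @pytest.mark.parametrize("fmt", ["graphml", "tsv"])
    def test_round_trip(self, toy_net, tmp_path, fmt):
        path = tmp_path / f"net.{fmt}"
        export_network(toy_net, path, fmt)
        back = import_network(path, fmt)
        assert set(back.nodes) == set(toy_net.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, toy_net.edges))
        for a, b, data in toy_net.edges(data=True):
            assert back[a][b]["count"] == data["count"]
            assert back[a][b]["total_cM"] == pytest.approx(data["total_cM"])
        for n in toy_net.nodes:
            assert back.nodes[n]["population"] == toy_net.nodes[n]["population"]

    def test_empty_network_writes_valid_file(self, tmp_path):
        export_network(nx.Graph(), tmp_path / "empty.graphml", "graphml")
        assert import_network(tmp_path / "empty.graphml").number_of_nodes() == 0
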