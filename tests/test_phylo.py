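import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fawkit import phylo, synthdata
from fawkit.phylo import (
    DistanceMatrix,
    HaploNode,
    TN93SaturationError,
    build_network,
    collapse_haplotypes,
    haversine_km,
    min_separation,
    mutational_steps,
    nj_tree,
    tn93_distance,
)

from _oracles import (
    random_additive_matrix as _random_additive_matrix_impl,
    random_sequence_pair as _random_pair,
    tn93_oracle,
)


class TestTN93:
    def test_identical_sequences_zero(self):
        assert tn93_distance("ACGT" * 64, "ACGT" * 64) == 0.0

    def test_single_transition_matches_oracle(self):
        rng = np.random.default_rng(3)
        a, b = _random_pair(rng, n_subs=0)
        # force one A<->G transition
        i = a.index("A")
        b = b[:i] + "G" + b[i + 1 :]
        assert tn93_distance(a, b) == pytest.approx(tn93_oracle(a, b), abs=1e-12)

    def test_matches_independent_closed_form_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            a, b = _random_pair(rng, n_subs=int(rng.integers(1, 40)))
            assert tn93_distance(a, b) == pytest.approx(
                tn93_oracle(a, b), abs=1e-12
            )

    def test_symmetric(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b = _random_pair(rng, n_subs=15)
            assert tn93_distance(a, b) == tn93_distance(b, a)

    def test_ambiguous_sites_excluded_pairwise(self):
        a = "AAAAACGTACGT"
        b = "AAAAACGTACGT"
        # a difference only at a site masked by N must not count
        assert tn93_distance(a[:-1] + "N", b[:-1] + "T") == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            tn93_distance("ACGT", "ACG")

    def test_saturation_raises(self):
        a = "AG" * 100
        b = "GA" * 100  # every site a purine transition
        with pytest.raises(TN93SaturationError):
            tn93_distance(a, b)

    def test_positive_for_non_identical(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a, b = _random_pair(rng, n_subs=5)
            assert tn93_distance(a, b) > 0.0


# ---------------------------------------------------------------------------
# neighbor joining


def _random_additive_matrix(rng, n_taxa):
    return _random_additive_matrix_impl(rng, n_taxa)


def _ls_fit_quartet(d):
    """Least-squares oracle for 4 taxa: fit branch lengths for each of
    the 3 unrooted topologies, return the best (topology, fitted path
    matrix)."""
    splits = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
    best = None
    for (a, b), (c, e) in splits:
        # params: la, lb, lc, le, internal m
        rows, rhs = [], []
        for i, j in itertools.combinations(range(4), 2):
            coef = np.zeros(5)
            pend = {a: 0, b: 1, c: 2, e: 3}
            coef[pend[i]] += 1
            coef[pend[j]] += 1
            same_side = {i, j} in ({a, b}, {c, e})
            if not same_side:
                coef[4] = 1
            rows.append(coef)
            rhs.append(d[i, j])
        A, y = np.array(rows), np.array(rhs)
        x, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        fitted = A @ x
        sse = ((fitted - y) ** 2).sum()
        if best is None or sse < best[0]:
            best = (sse, ((a, b), (c, e)), A, x)
    return best


class TestNeighborJoining:
    def test_quartet_recovery_against_least_squares_oracle(self):
        """A quartet with branch lengths 1..5 must be recovered exactly;
        the oracle enumerates all 3 topologies with least-squares fits."""
        # tree: (t0:1, t1:2):5, (t2:3, t3:4)
        labels = ["t0", "t1", "t2", "t3"]
        la, lb, lc, le, m = 1.0, 2.0, 3.0, 4.0, 5.0
        d = np.array(
            [
                [0, la + lb, la + m + lc, la + m + le],
                [la + lb, 0, lb + m + lc, lb + m + le],
                [la + m + lc, lb + m + lc, 0, lc + le],
                [la + m + le, lb + m + le, lc + le, 0],
            ]
        )
        sse, split, *_ = _ls_fit_quartet(d)
        assert sse == pytest.approx(0.0, abs=1e-18)
        assert split == ((0, 1), (2, 3))  # oracle confirms the generating split

        tree = nj_tree(DistanceMatrix(labels, d))
        recovered = tree.path_length_matrix()
        np.testing.assert_allclose(recovered.d, d, atol=1e-9)

    def test_reproduces_random_additive_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            dm = _random_additive_matrix(rng, 5)
            tree = nj_tree(dm)
            np.testing.assert_allclose(
                tree.path_length_matrix().d, dm.d, atol=1e-9
            )

    def test_equal_distance_matrix_gives_equal_pendant_branches(self):
        labels = list("abcd")
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = nj_tree(DistanceMatrix(labels, d))
        pend = [tree.graph[l][next(iter(tree.graph[l]))]["length"] for l in labels]
        assert all(p == pytest.approx(1.0) for p in pend)

    def test_requires_three_taxa(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]])))

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = 6
            # perturbed additive matrix can induce negative NJ estimates
            dm = _random_additive_matrix(rng, n)
            noise = rng.uniform(0, 0.2, size=(n, n))
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0.0)
            tree = nj_tree(DistanceMatrix(dm.labels, dm.d + noise))
            for _, _, data in tree.graph.edges(data=True):
                assert data["length"] >= 0.0

    def test_strain_consensus_pair_clusters_within_panel(self, refs):
        dm = DistanceMatrix.from_sequences(refs.panel.entries)
        tree = nj_tree(dm)
        cs, rs = "S_frugiperda_CS_consensus", "S_frugiperda_RS_consensus"
        plm = tree.path_length_matrix()
        i, j = plm.labels.index(cs), plm.labels.index(rs)
        others = [k for k in range(len(plm.labels)) if k not in (i, j)]
        assert plm.d[i, j] < min(plm.d[i, k] for k in others)

    def test_newick_round_trips_leaf_set(self):
        rng = np.random.default_rng(9)
        dm = _random_additive_matrix(rng, 5)
        nwk = nj_tree(dm).to_newick()
        assert nwk.endswith(";")
        for lab in dm.labels:
            assert lab in nwk


# ---------------------------------------------------------------------------
# haplotype collapsing and networks


class TestMutationalSteps:
    @pytest.mark.parametrize(
        "a,b,steps",
        [
            ("ACGT", "ACGT", 0),
            ("ACGT", "ACGA", 1),
            ("AC--T", "ACGGT", 1),  # one gap run = one step
            ("A----T", "AGGGGT", 1),
            ("A--G--T", "AGGGGGT", 2),  # two separate runs
            ("AC-T", "AGGT", 2),  # substitution + gap run
        ],
    )
    def test_step_counting(self, a, b, steps):
        assert mutational_steps(a, b) == steps
        assert mutational_steps(b, a) == steps

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            mutational_steps("AC", "A")


class TestCollapse:
    def test_counts_partitioned_by_site(self):
        seqs = {f"s{i}": "AAAA" for i in range(5)} | {f"t{i}": "AAAT" for i in range(2)}
        sites = {k: ("X" if k.startswith("s") else "Y") for k in seqs}
        nodes = collapse_haplotypes(seqs, sites)
        assert [(n.sequence, n.count) for n in nodes] == [("AAAA", 5), ("AAAT", 2)]
        assert nodes[0].site_counts == {"X": 5}

    def test_all_identical_single_node(self):
        nodes = collapse_haplotypes({"a": "ACGT", "b": "acgt"}, {"a": "X", "b": "X"})
        assert len(nodes) == 1 and nodes[0].count == 2

    def test_count_conservation(self):
        rng = np.random.default_rng(10)
        seqs = {
            f"s{i}": "".join("ACGT"[j] for j in rng.integers(0, 4, 6))
            for i in range(40)
        }
        sites = {k: "X" for k in seqs}
        nodes = collapse_haplotypes(seqs, sites)
        assert sum(n.count for n in nodes) == 40


class TestNetwork:
    def test_two_haplotypes_single_edge(self):
        nodes = [HaploNode("AAAA", 3, {"X": 3}), HaploNode("AAAT", 1, {"X": 1})]
        net = build_network(nodes)
        assert net.edges() == [(0, 1, 1)]

    def test_tied_triangle_retained(self):
        nodes = [
            HaploNode("AA", 1, {"X": 1}),
            HaploNode("AT", 1, {"X": 1}),
            HaploNode("TA", 1, {"X": 1}),
        ]
        net = build_network(nodes)
        # pairwise: AA-AT=1, AA-TA=1, AT-TA=2; the two 1-step edges tie
        assert (0, 1, 1) in net.edges() and (0, 2, 1) in net.edges()

    def test_all_pairwise_one_step_triangle(self):
        # three haplotypes mutually 1 step apart at the same column
        nodes = [HaploNode(s, 1, {"X": 1}) for s in ("AA", "CA", "GA")]
        net = build_network(nodes)
        assert len(net.edges()) == 3  # full triangle kept

    def test_connected_and_contains_spanning_tree(self):
        import networkx as nx

        rng = np.random.default_rng(11)
        seqs = ["".join("ACGT"[j] for j in rng.integers(0, 4, 8)) for _ in range(12)]
        nodes = [HaploNode(s, 1, {"X": 1}) for s in dict.fromkeys(seqs)]
        net = build_network(nodes)
        assert nx.is_connected(net.graph)
        mst_only = net.graph.edge_subgraph(
            [(u, v) for u, v, d in net.graph.edges(data=True) if d["in_mst"]]
        )
        assert mst_only.number_of_edges() == len(nodes) - 1
        assert nx.is_connected(mst_only)

    def test_single_node_network(self):
        net = build_network([HaploNode("ACGT", 4, {"X": 4})])
        assert len(net.nodes) == 1 and net.graph.number_of_edges() == 0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            build_network([])


class TestMinSeparation:
    def _net(self):
        nodes = [
            HaploNode("AAAA", 2, {"X": 1, "Y": 1}),  # shared
            HaploNode("AAAT", 1, {"X": 1}),
            HaploNode("TTTT", 1, {"Z": 1}),
        ]
        return build_network(nodes)

    def test_shared_haplotype_gives_zero(self):
        assert min_separation(self._net(), {"X"}, {"Y"}) == 0

    def test_private_separation(self):
        # TTTT vs AAAT differs at 3 positions; TTTT vs AAAA at 4
        assert min_separation(self._net(), {"Z"}, {"X", "Y"}) == 3

    def test_identical_partitions_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            min_separation(self._net(), {"X"}, {"X"})

    def test_empty_partition_raises(self):
        with pytest.raises(ValueError):
            min_separation(self._net(), set(), {"X"})

    def test_programmed_isolation_recovered(self, refs):
        records, _ = synthdata.simulate_isolated_site(
            synthdata.IsolationSpec(site_id="isl", divergence_steps=8, seed=3), refs
        )
        mainland, _ = synthdata.simulate_population(
            synthdata.PopulationSpec(
                site_id="main", n_specimens=25, seed=4,
                tpi_R_allele_freq=0.0, male_fraction=0.0,
            ),
            refs,
        )
        lo, hi = refs.offsets.tpie4i4_window
        seqs = {
            r.specimen_id: r.sequences["TPI"][lo:hi] for r in records + mainland
        }
        sites = {r.specimen_id: r.site_id for r in records + mainland}
        net = build_network(collapse_haplotypes(seqs, sites))
        assert min_separation(net, {"isl"}, {"main"}) == 8


class TestExports:
    def test_edgelist_frame(self):
        nodes = [HaploNode("AA", 1, {"X": 1}), HaploNode("AT", 1, {"Y": 1})]
        df = phylo.network_to_edgelist_frame(build_network(nodes))
        assert df.loc[0, "steps"] == 1 and bool(df.loc[0, "in_mst"])

    def test_nexus_contains_traits_block(self):
        nodes = [HaploNode("AA", 2, {"X": 2}), HaploNode("AT", 1, {"Y": 1})]
        nexus = phylo.network_to_nexus(build_network(nodes))
        assert nexus.startswith("#NEXUS")
        assert "BEGIN TRAITS;" in nexus and "Hap_0 2,0" in nexus


# ---------------------------------------------------------------------------
# great-circle distances


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine_km((10.0, 20.0), (10.0, 20.0)) == 0.0

    def test_antipodal(self):
        d = haversine_km((0.0, 0.0), (0.0, 180.0))
        assert d == pytest.approx(math.pi * 6371.0, abs=0.1)

    def test_portoviejo_to_port_of_spain_matches_law_of_cosines(self):
        a, b = (-1.07, -80.46), (10.65, -61.43)
        # independent spherical-law-of-cosines evaluation
        p1, p2 = math.radians(a[0]), math.radians(b[0])
        dl = math.radians(b[1] - a[1])
        slc = 6371.0 * math.acos(
            math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
        )
        d = haversine_km(a, b)
        assert d == pytest.approx(slc, abs=1e-6)
        assert d == pytest.approx(2476, abs=25)

    def test_accepts_collection_sites(self):
        from fawkit.seqio import CollectionSite

        pv = CollectionSite("Ecu-Pv", "Portoviejo", "Ecuador", -1.07, -80.46)
        to = CollectionSite("Ecu-To", "Tosagua", "Ecuador", -0.78, -80.22)
        assert 0 < haversine_km(pv, to) < 60

    @given(
        st.tuples(st.floats(-90, 90), st.floats(-180, 180)),
        st.tuples(st.floats(-90, 90), st.floats(-180, 180)),
        st.tuples(st.floats(-90, 90), st.floats(-180, 180)),
    )
    @settings(max_examples=100)
    def test_metric_properties(self, a, b, c):
        dab = haversine_km(a, b)
        assert dab >= 0
        assert dab == pytest.approx(haversine_km(b, a), abs=1e-9)
        assert dab <= haversine_km(a, c) + haversine_km(c, b) + 1e-6
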