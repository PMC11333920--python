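"""Network construction, complexity, connectivity and the cohesion statistic."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phyllonet.network import (
    NetworkError,
    build_network,
    cohesion,
    cohesion_env_correlation,
    complexity_env_correlation,
    connectivity_values,
    inherited_nodes,
    network_complexity,
)
from phyllonet.sparcc import SparCCResults


def make_result(rho, pval, ids=None):
    ids = ids or [f"Otu{i + 1}" for i in range(len(rho))]
    rho = np.asarray(rho, dtype=float)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    pval = np.asarray(pval, dtype=float)
    np.fill_diagonal(pval, 1.0)
    return SparCCResults(
        pd.DataFrame(rho, index=ids, columns=ids),
        pd.DataFrame(pval, index=ids, columns=ids),
        [],
        1000,
        0,
    )


@pytest.fixture
def three_otu_result():
    # one significant pair (Otu1, Otu2); Otu3 isolated
    rho = [[1, 0.5, 0.2], [0.5, 1, -0.1], [0.2, -0.1, 1]]
    p = [[1, 1e-3, 0.5], [1e-3, 1, 0.9], [0.5, 0.9, 1]]
    return make_result(rho, p)


class TestBuildNetwork:
    def test_single_significant_pair(self, three_otu_result):
        net = build_network(three_otu_result, p_max=0.001)
        assert net.n_nodes == 2 and net.n_edges == 1
        assert "Otu3" not in net.graph  # isolated OTUs dropped
        edge = net.graph["Otu1"]["Otu2"]
        assert edge["weight"] == pytest.approx(0.5)
        assert edge["sign"] == "+"

    def test_all_insignificant_empty(self):
        rho = np.full((3, 3), 0.9)
        p = np.ones((3, 3))
        net = build_network(make_result(rho, p))
        assert network_complexity(net)[:2] == (0, 0)

    def test_edge_count_bounded(self, rng):
        D = 6
        rho = rng.uniform(-1, 1, (D, D))
        rho = (rho + rho.T) / 2
        p = np.full((D, D), 1e-4)
        net = build_network(make_result(rho, p))
        assert net.n_edges <= D * (D - 1) // 2

    def test_mismatched_ids_rejected(self, three_otu_result):
        bad = SparCCResults(
            three_otu_result.rho,
            three_otu_result.pvalues.set_axis(["a", "b", "c"], axis=0),
            [],
            1000,
            0,
        )
        with pytest.raises(NetworkError, match="mismatch"):
            build_network(bad)

    def test_graphml_round_trip(self, three_otu_result, tmp_path):
        net = build_network(three_otu_result)
        path = tmp_path / "net.graphml"
        net.write_graphml(path)
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(net.graph.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, net.graph.edges))
        for u, v in net.graph.edges:
            assert back[u][v]["weight"] == pytest.approx(net.graph[u][v]["weight"])


class TestComplexityAndInheritance:
    def test_triangle_all_positive(self):
        rho = np.array([[1, 0.4, 0.4], [0.4, 1, 0.4], [0.4, 0.4, 1]])
        p = np.full((3, 3), 1e-4)
        net = build_network(make_result(rho, p))
        assert network_complexity(net) == (3, 3, 1.0)

    def test_inherited_nodes_cases(self, three_otu_result):
        net = build_network(three_otu_result)
        assert inherited_nodes(net, net) == {"Otu1", "Otu2"}
        other = build_network(
            make_result(
                [[1, 0.8], [0.8, 1]], [[1, 1e-3], [1e-3, 1]], ids=["X", "Y"]
            )
        )
        assert inherited_nodes(net, other) == set()
        assert len(inherited_nodes(net, other)) <= min(net.n_nodes, other.n_nodes)


class TestConnectivity:
    def test_mean_of_significant_positive_partners(self):
        # Otu1 has significant partners +0.4 and +0.6 -> positive conn 0.5
        rho = np.array(
            [
                [1.0, 0.4, 0.6, -0.3],
                [0.4, 1.0, 0.0, 0.0],
                [0.6, 0.0, 1.0, 0.0],
                [-0.3, 0.0, 0.0, 1.0],
            ]
        )
        p = np.where(np.abs(rho) > 0.2, 1e-3, 1.0)
        conn = connectivity_values(make_result(rho, p))
        assert conn.loc["Otu1", "positive"] == pytest.approx(0.5)
        assert conn.loc["Otu1", "negative"] == pytest.approx(-0.3)
        # Otu4's only significant partner is negative -> positive conn 0
        assert conn.loc["Otu4", "positive"] == 0.0

    def test_no_partners_zero(self):
        rho = np.eye(3)
        p = np.ones((3, 3))
        conn = connectivity_values(make_result(rho, p))
        assert (conn.to_numpy() == 0).all()


class TestCohesion:
    def test_two_otu_worked_example(self):
        # RA (0.6, 0.4), one significant edge rho = +0.5:
        # both OTUs have positive connectivity 0.5, so positive cohesion
        # = 0.6*0.5 + 0.4*0.5 = 0.5; negative = 0; total = 0.5
        res = make_result([[1, 0.5], [0.5, 1]], [[1, 1e-3], [1e-3, 1]])
        conn = connectivity_values(res)
        ra = pd.DataFrame({"s1": [0.6, 0.4]}, index=["Otu1", "Otu2"])
        out = cohesion(ra, conn)
        assert out.samples.loc["s1", "positive"] == pytest.approx(0.5)
        assert out.samples.loc["s1", "negative"] == 0.0
        assert out.samples.loc["s1", "total"] == pytest.approx(0.5)

    def test_no_significant_correlations_zero_everywhere(self, rng):
        res = make_result(rng.uniform(-1, 1, (4, 4)), np.ones((4, 4)))
        conn = connectivity_values(res)
        ra = pd.DataFrame(
            rng.dirichlet(np.ones(4), size=5).T,
            index=res.otu_ids,
            columns=[f"s{i}" for i in range(5)],
        )
        out = cohesion(ra, conn)
        assert (out.samples["total"] == 0).all()

    def test_zero_ra_otus_do_not_contribute(self):
        res = make_result(
            [[1, 0.5, 0.0], [0.5, 1, 0.0], [0.0, 0.0, 1]],
            [[1, 1e-3, 1], [1e-3, 1, 1], [1, 1, 1]],
        )
        conn = connectivity_values(res)
        ra_full = pd.DataFrame({"s1": [0.6, 0.4, 0.0]}, index=res.otu_ids)
        ra_trimmed = ra_full.iloc[:2]
        full = cohesion(ra_full, conn)
        trimmed = cohesion(ra_trimmed, conn.iloc[:2])
        assert full.samples.loc["s1", "total"] == pytest.approx(
            trimmed.samples.loc["s1", "total"]
        )

    def test_otu_mismatch_rejected(self, rng):
        res = make_result(np.eye(3), np.ones((3, 3)))
        conn = connectivity_values(res)
        ra = pd.DataFrame({"s1": [0.5, 0.5]}, index=["Other1", "Other2"])
        with pytest.raises(NetworkError, match="different OTUs"):
            cohesion(ra, conn)

    def test_ra_sums_above_one_rejected(self):
        res = make_result(np.eye(2), np.ones((2, 2)))
        conn = connectivity_values(res)
        ra = pd.DataFrame({"s1": [0.8, 0.8]}, index=res.otu_ids)
        with pytest.raises(NetworkError, match="sum to <= 1"):
            cohesion(ra, conn)

    def test_bounds_on_random_instances(self, rng):
        # positive in [0,1], negative in [-1,0], total in [0,2] for any
        # valid RA/connectivity combination
        for _ in range(200):
            D = rng.integers(2, 8)
            n = rng.integers(1, 6)
            conn = pd.DataFrame(
                {
                    "positive": rng.uniform(0, 1, D),
                    "negative": -rng.uniform(0, 1, D),
                },
                index=[f"Otu{i}" for i in range(D)],
            )
            ra = pd.DataFrame(
                rng.dirichlet(np.ones(D), size=n).T,
                index=conn.index,
                columns=[f"s{j}" for j in range(n)],
            )
            out = cohesion(ra, conn)  # internal asserts check the bounds
            assert ((out.samples["total"] >= 0) & (out.samples["total"] <= 2)).all()


class TestEnvCorrelations:
    def test_nodes_track_env_exactly(self):
        comp = pd.DataFrame({"n_nodes": [10, 20, 30, 40]}, index=range(4))
        env = pd.DataFrame(
            {"ppt": [1.0, 2.0, 3.0, 4.0], "flat": [1.0, 1.0, 1.0, 1.0]},
            index=range(4),
        )
        out = complexity_env_correlation(comp, env)
        assert out.loc["ppt", "r"] == pytest.approx(1.0)
        assert np.isnan(out.loc["flat", "r"])  # constant env -> NA

    def test_cohesion_spearman_monotone_and_shuffled(self, rng):
        total = pd.Series(np.linspace(0.1, 1.0, 40), index=[f"s{i}" for i in range(40)])
        env = pd.DataFrame(
            {
                "mono": np.exp(total.to_numpy()),  # monotone transform
                "noise": rng.permutation(total.to_numpy()),
            },
            index=total.index,
        )
        out = cohesion_env_correlation(total, env)
        assert out.loc["mono", "rho"] == pytest.approx(1.0)
        assert abs(out.loc["noise", "rho"]) < 0.35
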