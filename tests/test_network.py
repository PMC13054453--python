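import itertools

import numpy as np
import pytest

from icsignal import vocab
from icsignal.disproportionality import AnalysisOptions
from icsignal.network import (
    CaseTermMatrix,
    EventNetwork,
    build_matrix,
    compare_partitions,
    compute_ppmi,
    detect_communities,
    edge_jaccard,
    fit_ising,
    select_terms,
    simulate_ising,
    two_cluster_ising,
)
from icsignal.store import apply_exclusion, select_cases


def _matrix(data):
    data = np.asarray(data)
    return CaseTermMatrix(data, [f"V{i}" for i in range(data.shape[1])],
                          list(range(data.shape[0])))


class TestPpmi:
    def test_perfect_cooccurrence_closed_form(self):
        # p(a)=p(b)=0.5, always together: pmi = log2(0.5/0.25) = 1
        n = 10_000
        col = np.tile([1, 0], n // 2)
        net = compute_ppmi(_matrix(np.column_stack([col, col, 1 - col])))
        assert net.weights[0, 1] == pytest.approx(1.0, abs=0.01)

    def test_independence_limit(self):
        rng = np.random.default_rng(1)
        data = (rng.random((10_000, 3)) < 0.5).astype(int)
        net = compute_ppmi(_matrix(data))
        assert np.abs(net.weights).max() < 0.05

    def test_zero_joint_count_clipped_finite(self):
        col = np.tile([1, 0], 50)
        net = compute_ppmi(_matrix(np.column_stack([col, 1 - col, col])))
        assert np.isfinite(net.weights).all()
        assert net.weights[0, 1] == 0.0  # never co-occur -> clipped at 0

    def test_symmetric_nonnegative_zero_diagonal(self):
        rng = np.random.default_rng(2)
        data = (rng.random((500, 6)) < 0.3).astype(int)
        net = compute_ppmi(_matrix(data))
        assert np.allclose(net.weights, net.weights.T)
        assert (net.weights >= 0).all()
        assert np.diagonal(net.weights).sum() == 0

    def test_needs_two_columns(self):
        with pytest.raises(ValueError):
            compute_ppmi(_matrix(np.ones((50, 1))))


class TestIsingFit:
    def test_independent_columns_give_no_edge(self):
        rng = np.random.default_rng(3)
        data = (rng.random((500, 3)) < 0.5).astype(int)
        net = fit_ising(_matrix(data))
        assert (net.weights == 0).all()

    def test_coupled_pair_recovered(self):
        rng = np.random.default_rng(4)
        a = (rng.random(500) < 0.5).astype(int)
        b = np.where(rng.random(500) < 0.05, 1 - a, a)  # a with 5% flips
        c = (rng.random(500) < 0.5).astype(int)
        net = fit_ising(_matrix(np.column_stack([a, b, c])))
        assert net.weights[0, 1] > 0
        assert net.weights[0, 2] == 0 and net.weights[1, 2] == 0

    def test_small_matrix_refused(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            fit_ising(_matrix((rng.random((10, 5)) < 0.5).astype(int)))
        with pytest.raises(ValueError):
            fit_ising(_matrix((rng.random((100, 2)) < 0.5).astype(int)))

    def test_collinear_column_dropped(self):
        rng = np.random.default_rng(6)
        a = (rng.random(200) < 0.5).astype(int)
        b = (rng.random(200) < 0.5).astype(int)
        c = (rng.random(200) < 0.4).astype(int)
        net = fit_ising(_matrix(np.column_stack([a, b, a, c])))
        assert net.nodes == ["V0", "V1", "V3"]

    def test_and_rule_subgraph_of_or_rule(self):
        h, J, _ = two_cluster_ising(3, coupling=0.8)
        X = simulate_ising(h, J, 600, np.random.default_rng(7))
        m = _matrix(X)
        and_net = fit_ising(m, rule="and")
        or_net = fit_ising(m, rule="or")
        and_edges = {(a, b) for a, b, _ in and_net.edges()}
        or_edges = {(a, b) for a, b, _ in or_net.edges()}
        assert and_edges <= or_edges

    def test_estimated_signs_match_planted_signs(self):
        """Positive planted couplings yield positive recovered weights."""
        h, J, _ = two_cluster_ising(5, coupling=1.0)
        for seed in range(3):
            X = simulate_ising(h, J, 1000, np.random.default_rng(30 + seed))
            net = fit_ising(_matrix(X))
            ij = np.nonzero(np.triu(net.weights, 1))
            for i, j in zip(*ij):
                if J[i, j] != 0:
                    assert net.weights[i, j] > 0


class TestCommunities:
    def test_two_disconnected_cliques(self):
        w = np.zeros((6, 6))
        for i, j in itertools.combinations(range(3), 2):
            w[i, j] = w[j, i] = 1.0
            w[i + 3, j + 3] = w[j + 3, i + 3] = 1.0
        net = EventNetwork(nodes=[f"V{i}" for i in range(6)], weights=w, method="ising")
        part = detect_communities(net)
        assert len(set(part.values())) == 2
        assert part["V0"] == part["V1"] == part["V2"]
        assert part["V3"] == part["V4"] == part["V5"]

    def test_single_node_single_community(self):
        net = EventNetwork(nodes=["V0"], weights=np.zeros((1, 1)), method="ppmi")
        assert detect_communities(net) == {"V0": 0}

    def test_edgeless_network_gives_singletons(self):
        net = EventNetwork(nodes=["A", "B", "C"], weights=np.zeros((3, 3)), method="ppmi")
        part = detect_communities(net)
        assert len(set(part.values())) == 3


class TestPartitionComparison:
    def test_identical_partitions_score_one(self):
        p = {"A": 0, "B": 0, "C": 1, "D": 1}
        assert compare_partitions(p, p) == 1.0

    def test_singletons_vs_one_block_scores_zero(self):
        nodes = list("ABCDE")
        singles = {v: i for i, v in enumerate(nodes)}
        block = {v: 0 for v in nodes}
        assert compare_partitions(singles, block) == 0.0

    def test_random_relabelling_near_zero_in_expectation(self):
        rng = np.random.default_rng(8)
        nodes = [f"V{i}" for i in range(40)]
        truth = {v: i % 4 for i, v in enumerate(nodes)}
        scores = []
        for _ in range(50):
            labels = rng.permutation([truth[v] for v in nodes])
            scores.append(compare_partitions(truth, dict(zip(nodes, labels))))
        assert abs(np.mean(scores)) < 0.05

    def test_node_set_mismatch_fatal(self):
        with pytest.raises(ValueError):
            compare_partitions({"A": 0}, {"B": 0})

    def test_edge_jaccard(self):
        w1 = np.zeros((3, 3)); w1[0, 1] = w1[1, 0] = 1.0
        w2 = np.zeros((3, 3)); w2[0, 1] = w2[1, 0] = 0.5; w2[1, 2] = w2[2, 1] = 0.5
        n1 = EventNetwork(["A", "B", "C"], w1, "ppmi")
        n2 = EventNetwork(["A", "B", "C"], w2, "ppmi")
        assert edge_jaccard(n1, n2) == pytest.approx(0.5)
        assert edge_jaccard(n1, n1) == 1.0


class TestTermSelection:
    def test_planted_cluster_terms_recovered(self, demo_db):
        db, truth = demo_db
        opts = AnalysisOptions()
        included = apply_exclusion(db, select_cases(db, opts.rp_pt_codes))
        cluster = next(c for c in truth.clusters if c.class_tag == "beta_blocker")
        terms = select_terms(db, "beta_blocker", included,
                             exclude_pts=opts.rp_pt_codes)
        assert set(cluster.pt_codes) - {vocab.RAYNAUDS_PT} <= set(terms)
        assert vocab.RAYNAUDS_PT not in terms

    def test_unknown_class_fatal(self, demo_db):
        db, _ = demo_db
        with pytest.raises(KeyError):
            select_terms(db, "no_such_class", {"R0000001"})

    def test_class_without_cases_warns_empty(self, demo_db, caplog):
        db, _ = demo_db
        assert select_terms(db, "tki", set()) == []


class TestBuildMatrix:
    def test_membership_binary_and_shapes(self, demo_db):
        db, truth = demo_db
        included = apply_exclusion(db, select_cases(db, (vocab.RAYNAUDS_PT,)))
        cluster = truth.clusters[0]
        m = build_matrix(db, cluster.class_tag, included, list(cluster.pt_codes))
        assert set(np.unique(m.data)) <= {0, 1}
        assert m.data.shape == (len(m.report_ids), len(m.pt_codes))
        # marginals agree with the raw event table
        ev = db.report_events
        for j, pt in enumerate(m.pt_codes):
            expected = ev[(ev.pt_code == pt) & ev.report_id.isin(m.report_ids)][
                "report_id"].nunique()
            assert m.data[:, j].sum() == expected

    def test_empty_pt_list_rejected(self, demo_db):
        db, _ = demo_db
        with pytest.raises(ValueError):
            build_matrix(db, "beta_blocker", {"R0000001"}, [])
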