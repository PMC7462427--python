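"""Multilayer modularity, greedy optimization, consensus, partition similarity."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from netreconf import (
    DegenerateLayerError,
    ModularityParams,
    MultilayerLouvain,
    MultilayerPartition,
    PartitionEnsemble,
    build_multilayer,
    consensus_partition,
    louvain_multilayer,
    match_labels,
    partition_ensemble,
    static_communities,
    zrand,
)
from oracles import exhaustive_max_q, mean_pairwise_similarity


def two_triangles() -> np.ndarray:
    a = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        a[i, j] = a[j, i] = 1.0
    return a


def planted_two_block_layers(n_layers=3) -> np.ndarray:
    layers = []
    for _ in range(n_layers):
        b = np.zeros((4, 4))
        b[0, 1] = b[1, 0] = 1.0
        b[2, 3] = b[3, 2] = 1.0
        b[0, 2] = b[2, 0] = 0.1
        layers.append(b)
    return np.array(layers)


class TestModularityValue:
    def test_two_triangles_closed_form(self):
        # two equal components of a 6-edge graph: Q = 2 * (1/2 - 1/4) = 1/2
        net = build_multilayer(two_triangles()[None], ModularityParams(1.0, 0.0))
        labels = np.array([[1, 1, 1, 2, 2, 2]])
        assert np.isclose(net.q(labels), 0.5)

    def test_all_in_one_single_layer_zero(self):
        net = build_multilayer(two_triangles()[None], ModularityParams(1.0, 0.0))
        assert np.isclose(net.q(np.ones((1, 6), dtype=int)), 0.0)

    def test_omega_zero_decomposes_into_layer_modularities(self):
        rng = np.random.default_rng(0)
        layers = rng.uniform(0.1, 1.0, size=(3, 5, 5))
        layers = 0.5 * (layers + layers.transpose(0, 2, 1))
        net = build_multilayer(layers, ModularityParams(1.2, 0.0))
        labels = rng.integers(1, 3, size=(3, 5))
        per_layer = []
        for s in range(3):
            single = build_multilayer(layers[s][None], ModularityParams(1.2, 0.0))
            per_layer.append(single.q(labels[s][None]) * single.two_mu)
        assert np.isclose(net.q(labels), sum(per_layer) / net.two_mu)

    def test_relabeling_invariance(self):
        net = build_multilayer(planted_two_block_layers(), ModularityParams(1.0, 1.0))
        labels = np.array([[1, 1, 2, 2]] * 3)
        swapped = np.array([[7, 7, 3, 3]] * 3)
        assert np.isclose(net.q(labels), net.q(swapped))

    def test_node_reordering_invariance(self):
        rng = np.random.default_rng(1)
        layers = rng.uniform(0.1, 1.0, size=(2, 6, 6))
        layers = 0.5 * (layers + layers.transpose(0, 2, 1))
        labels = rng.integers(1, 4, size=(2, 6))
        net = build_multilayer(layers, ModularityParams(1.0, 0.5))
        perm = rng.permutation(6)
        net_p = build_multilayer(layers[:, perm][:, :, perm], ModularityParams(1.0, 0.5))
        assert np.isclose(net.q(labels), net_p.q(labels[:, perm]))

    def test_degenerate_layer_raises(self):
        layers = np.array([two_triangles(), np.zeros((6, 6))])
        with pytest.raises(DegenerateLayerError):
            build_multilayer(layers, ModularityParams(1.0, 1.0))

    def test_negative_edges_clipped_and_counted(self):
        a = two_triangles()
        a[0, 3] = a[3, 0] = -0.5
        net = build_multilayer(a[None], ModularityParams(1.0, 0.0))
        assert net.n_clipped == 1
        assert net.layers.min() >= 0.0


class TestLouvain:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_two_triangles_any_seed(self, seed):
        net = build_multilayer(two_triangles()[None], ModularityParams(1.0, 0.0))
        p = louvain_multilayer(net, seed=seed)
        assert p.n_communities == 2
        assert np.isclose(p.q, 0.5)
        assert len(set(p.labels[0, :3])) == 1 and len(set(p.labels[0, 3:])) == 1

    def test_high_gamma_all_singletons(self):
        # equal weights, gamma large: every merge has negative gain
        a = np.ones((6, 6)) - np.eye(6)
        net = build_multilayer(a[None], ModularityParams(3.0, 0.0))
        p = louvain_multilayer(net, seed=0)
        assert p.n_communities == 6

    def test_planted_multilayer_recovered(self):
        net = build_multilayer(planted_two_block_layers(), ModularityParams(1.0, 1.0))
        p = louvain_multilayer(net, seed=3)
        expected = np.array([[1, 1, 2, 2]] * 3)
        assert np.array_equal(p.labels, expected)
        q_max, _ = exhaustive_max_q(net.modularity_matrix(), net.two_mu, max_blocks=4)
        assert np.isclose(p.q, q_max)

    @pytest.mark.parametrize("seed", range(6))
    def test_never_beats_exhaustive_on_random_nets(self, seed):
        rng = np.random.default_rng(seed)
        layers = rng.uniform(0.0, 1.0, size=(2, 4, 4))
        layers = 0.5 * (layers + layers.transpose(0, 2, 1))
        net = build_multilayer(layers, ModularityParams(1.0, 0.3))
        p = louvain_multilayer(net, seed=seed)
        q_max, _ = exhaustive_max_q(net.modularity_matrix(), net.two_mu)
        assert p.q <= q_max + 1e-10

    def test_result_is_local_maximum(self):
        rng = np.random.default_rng(7)
        layers = rng.uniform(0.0, 1.0, size=(2, 5, 5))
        layers = 0.5 * (layers + layers.transpose(0, 2, 1))
        net = build_multilayer(layers, ModularityParams(1.0, 0.5))
        p = louvain_multilayer(net, seed=1)
        b = net.modularity_matrix()
        flat = p.labels.ravel()
        q0 = float(b[flat[:, None] == flat[None, :]].sum())
        for u in range(len(flat)):
            for target in set(flat) | {flat.max() + 1}:
                if target == flat[u]:
                    continue
                trial = flat.copy()
                trial[u] = target
                q1 = float(b[trial[:, None] == trial[None, :]].sum())
                assert q1 <= q0 + 1e-9

    def test_deterministic_given_seed(self):
        net = build_multilayer(planted_two_block_layers(), ModularityParams(1.0, 1.0))
        a = louvain_multilayer(net, seed=5)
        b = louvain_multilayer(net, seed=5)
        assert np.array_equal(a.labels, b.labels) and a.q == b.q

    def test_gamma_increases_community_count_monotonically(self):
        layers = planted_two_block_layers(4)
        counts = []
        for gamma in (0.8, 1.0, 1.6, 3.0):
            est = MultilayerLouvain(gamma=gamma, omega=0.5, n_iter=10,
                                    random_state=0).fit(layers)
            counts.append(est.n_communities_)
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestEnsembleAndConsensus:
    def test_easy_network_full_agreement(self):
        net = build_multilayer(two_triangles()[None], ModularityParams(1.0, 0.0))
        ens = partition_ensemble(net, n_iter=20, base_seed=0)
        assert ens.agreement == 1.0

    def test_single_member_agreement_one(self):
        net = build_multilayer(two_triangles()[None], ModularityParams(1.0, 0.0))
        ens = partition_ensemble(net, n_iter=1, base_seed=0)
        assert ens.agreement == 1.0

    def test_planted_network_high_agreement(self):
        net = build_multilayer(planted_two_block_layers(5), ModularityParams(1.0, 1.0))
        ens = partition_ensemble(net, n_iter=100, base_seed=0)
        assert ens.agreement >= 0.98

    def test_seed_ladder_recorded(self):
        net = build_multilayer(two_triangles()[None], ModularityParams(1.0, 0.0))
        ens = partition_ensemble(net, n_iter=5, base_seed=17)
        assert [p.seed for p in ens.partitions] == [17, 18, 19, 20, 21]

    def _fake_ensemble(self, labelings, qs=None):
        parts = [
            MultilayerPartition(labels=np.asarray(lab), q=(qs[i] if qs else 0.5),
                                seed=i)
            for i, lab in enumerate(labelings)
        ]
        return PartitionEnsemble(partitions=parts, agreement=0.0)

    def test_all_identical_returns_that_partition(self):
        lab = [[1, 1, 2, 2, 3, 3]]
        ens = self._fake_ensemble([lab] * 5)
        cons = consensus_partition(ens)
        assert np.array_equal(cons.labels, np.asarray(lab))

    def test_majority_beats_single_deviant(self):
        majority = [[1, 1, 2, 2, 3, 3]]
        deviant = [[1, 2, 3, 4, 5, 6]]
        ens = self._fake_ensemble([majority] * 9 + [deviant])
        cons = consensus_partition(ens)
        assert np.array_equal(cons.labels, np.asarray(majority))

    def test_mixed_ensemble_matches_similarity_oracle(self):
        rng = np.random.default_rng(0)
        labelings = [rng.integers(1, 4, size=(1, 8)).tolist() for _ in range(7)]
        ens = self._fake_ensemble(labelings)
        cons = consensus_partition(ens)
        sims = mean_pairwise_similarity(
            [np.asarray(l).ravel() for l in labelings],
            lambda a, b: zrand(a, b),
        )
        best = np.asarray(labelings[int(np.argmax(sims))])
        assert np.array_equal(cons.labels, best)


class TestZrand:
    def test_identical_nontrivial_positive(self):
        labels = np.array([1, 1, 1, 2, 2, 3, 3, 3])
        assert zrand(labels, labels) > 2.0

    def test_mean_over_permutations_near_zero(self):
        rng = np.random.default_rng(0)
        a = np.repeat([1, 2, 3], [8, 6, 6])
        b = np.repeat([1, 2], [10, 10])
        zs = [zrand(a, rng.permutation(b)) for _ in range(300)]
        assert abs(np.mean(zs)) < 0.2

    def test_degenerate_all_one_returns_zero(self):
        assert zrand(np.ones(6), np.ones(6)) == 0.0


class TestStaticCommunities:
    def _series(self, layers):
        from netreconf import ConnectivitySeries

        n_layer = len(layers)
        centers = -0.1 * np.arange(n_layer)[::-1] - 0.1
        return ConnectivitySeries(
            band=(8.0, 12.0), layers=np.asarray(layers, float), centers=centers,
            tags=np.array(["pre"] * n_layer, dtype="U5"),
        )

    def test_constant_labels_collapse_to_same(self):
        conn = self._series(planted_two_block_layers(3))
        labels = static_communities(conn, ModularityParams(1.0, 1.0), n_iter=5)
        assert adjusted_rand_score(labels, [1, 1, 2, 2]) == 1.0

    def test_single_layer_identity_collapse(self):
        conn = self._series(two_triangles()[None])
        labels = static_communities(conn, ModularityParams(1.0, 0.0), n_iter=5)
        assert adjusted_rand_score(labels, [1, 1, 1, 2, 2, 2]) == 1.0

    def test_recovers_plant_from_synthetic_data(self):
        from netreconf import (
            SlidingWindowDWPLI,
            generate_trials,
            make_study_config,
            planted_partition,
        )

        cfg = make_study_config(n_regions=8, n_communities=2, perturb=False,
                                n_trials=48, n_subjects=1, seed=2)
        ens = generate_trials(cfg)
        conn = SlidingWindowDWPLI(band=(8.0, 12.0)).fit(ens).transform(ens)
        labels = static_communities(conn, ModularityParams(1.0, 1.0), n_iter=10)
        plant = planted_partition(cfg, (8.0, 12.0), "pre")
        assert adjusted_rand_score(labels, plant) >= 0.9


def test_match_labels_hungarian():
    reference = np.array([1, 1, 2, 2, 3, 3])
    shuffled = np.array([5, 5, 9, 9, 7, 7])
    assert np.array_equal(match_labels(shuffled, reference), reference)


def test_estimator_api():
    est = MultilayerLouvain(gamma=1.0, omega=0.0, n_iter=8, random_state=0)
    labels = est.fit_predict(two_triangles()[None])
    assert labels.shape == (1, 6)
    assert est.q_ == pytest.approx(0.5)
    assert est.agreement_ == 1.0
    assert est.n_communities_ == 2
    assert est.get_params()["gamma"] == 1.0
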