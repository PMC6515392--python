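import numpy as np
import pytest

from spikenose import (
    CapacityError,
    FeatureVector,
    Network,
    NetworkConfig,
    StateError,
    StructuralError,
    manhattan_distance,
)


def vec(components, mask=None):
    return FeatureVector(np.asarray(components), mask)


def random_vec(rng, n=16):
    return vec(rng.integers(0, 256, n))


class TestManhattanDistance:
    def test_identical_vectors_distance_zero(self):
        v = vec([1, 2, 3])
        assert manhattan_distance(v, v) == 0

    def test_hand_sum(self):
        assert manhattan_distance(vec([0, 3]), vec([3, 0])) == 6

    def test_mask_restricts_the_sum(self):
        v = vec([0, 3], mask=[True, False])
        assert manhattan_distance(v, vec([3, 0])) == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(StructuralError):
            manhattan_distance(vec([0, 1]), vec([0, 1, 2]))

    def test_matches_elementwise_loop_on_random_masked_pairs(self, rng):
        for _ in range(500):
            a = rng.integers(0, 256, 16)
            b = rng.integers(0, 256, 16)
            mask = rng.random(16) < rng.random()
            expected = sum(
                abs(int(a[i]) - int(b[i])) for i in range(16) if mask[i]
            )
            assert manhattan_distance(vec(a, mask), vec(b)) == expected


class TestLearning:
    def test_first_commit_gets_max_if(self):
        net = Network(NetworkConfig(max_if=1000, min_if=2))
        report = net.learn(vec([0] * 16), "A")
        assert report.committed and report.new_aif == 1000
        assert net.neurons[0].category == "A"

    def test_second_category_shrinks_first_and_commits_at_distance(self):
        net = Network(NetworkConfig(max_if=1000, min_if=2))
        v1, v2 = vec([0] * 16), vec([10] * 16)  # distance 160 < max_if
        net.learn(v1, "A")
        report = net.learn(v2, "B")
        assert report.committed and report.new_aif == 160
        assert net.neurons[0].aif == 160  # shrunk to broadcast distance
        assert report.shrunk == ((0, 1000, 160),)

    def test_same_vector_same_category_twice_commits_once(self):
        net = Network()
        v = vec([5] * 16)
        net.learn(v, "A")
        report = net.learn(v, "A")
        assert not report.committed and len(net) == 1

    def test_correct_category_firing_neuron_is_never_shrunk(self):
        net = Network(NetworkConfig(max_if=1000, min_if=2))
        net.learn(vec([0] * 16), "A")
        net.learn(vec([1] * 16), "A")  # fires on neuron 0, same category
        assert net.neurons[0].aif == 1000

    def test_shrink_clamps_at_min_if_and_flags_degenerate(self):
        net = Network(NetworkConfig(max_if=1000, min_if=50))
        net.learn(vec([0] * 16), "A")
        net.learn(vec([1] * 16), "B")  # distance 16 < min_if 50
        assert net.neurons[0].aif == 50 and net.neurons[0].degenerate
        assert net.neurons[1].aif == 50 and net.neurons[1].degenerate

    def test_capacity_exhaustion_raises(self):
        net = Network(NetworkConfig(capacity=1, max_if=10, min_if=1))
        net.learn(vec([0] * 16), "A")
        with pytest.raises(CapacityError):
            net.learn(vec([200] * 16), "B")  # distance 3200, nothing fires

    def test_learning_requires_full_mask(self):
        net = Network()
        with pytest.raises(StructuralError):
            net.learn(vec([0] * 16, mask=[True] * 8 + [False] * 8), "A")

    def test_aif_trajectories_non_increasing_within_bounds(self, rng):
        cfg = NetworkConfig(max_if=3840, min_if=16)
        net = Network(cfg)
        history: dict[int, list[int]] = {}
        for _ in range(300):
            net.learn(random_vec(rng), str(rng.integers(4)))
            for n in net.neurons:
                history.setdefault(n.id, []).append(n.aif)
        for traj in history.values():
            assert all(a >= b for a, b in zip(traj, traj[1:]))
            assert all(cfg.min_if <= a <= cfg.max_if for a in traj)


class TestClassification:
    def _trained(self, rng, n_patterns=40, n_categories=4):
        net = Network(NetworkConfig(k=3))
        vectors = []
        for _ in range(n_patterns):
            v = random_vec(rng)
            net.learn(v, str(rng.integers(n_categories)))
            vectors.append(v)
        return net, vectors

    def test_empty_network_raises(self):
        with pytest.raises(StateError):
            Network().classify(vec([0] * 16))

    def test_stored_prototype_recalled_at_distance_zero(self, rng):
        net, _ = self._trained(rng)
        for neuron in net.neurons:
            res = net.classify(vec(neuron.prototype))
            assert res.hits[0].distance == 0
            assert res.hits[0].category == neuron.category

    def test_far_vector_is_unknown_in_rbf_mode(self):
        net = Network(NetworkConfig(max_if=100, min_if=1))
        net.learn(vec([0] * 16), "A")
        res = net.classify(vec([200] * 16))
        assert res.status == "unknown" and res.hits == ()

    def test_hits_match_exhaustive_scan_oracle(self, rng):
        net, _ = self._trained(rng, n_patterns=64)
        for _ in range(100):
            v = random_vec(rng)
            res = net.classify(v)
            scored = sorted(
                (
                    (int(np.abs(n.prototype - v.components).sum()), n.id, n.category)
                    for n in net.neurons
                ),
            )
            firing = [(d, i, c) for d, i, c in scored if d < net.neurons[i].aif]
            expected = firing[: net.config.k]
            assert [(h.distance, h.neuron_id, h.category) for h in res.hits] == [
                (d, i, c) for d, i, c in expected
            ]
            if not firing:
                assert res.status == "unknown"
            elif len({c for _, _, c in firing}) == 1:
                assert res.status == "identified"
            else:
                assert res.status == "uncertain"

    def test_knn_mode_never_unknown_and_rbf_firing_is_subset(self, rng):
        net, _ = self._trained(rng, n_patterns=20)
        knn = Network.from_json(net.to_json())
        knn.config.mode = "knn"
        knn.config.k = len(knn.neurons)
        net.config.k = len(net.neurons)
        for _ in range(100):
            v = vec(rng.integers(0, 256, 16))
            rbf_res, knn_res = net.classify(v), knn.classify(v)
            assert knn_res.status != "unknown"
            assert len(knn_res.hits) == len(knn.neurons)
            rbf_ids = {h.neuron_id for h in rbf_res.hits}
            assert rbf_ids <= {h.neuron_id for h in knn_res.hits}

    def test_classification_invariant_to_commit_order(self, rng):
        # learning is order-dependent, so fix (prototype, category, aif)
        # triples and install them in two different orders
        triples = [
            (rng.integers(0, 256, 16), str(c % 3), int(rng.integers(200, 2000)))
            for c in range(12)
        ]

        def build(order):
            from spikenose.network import Neuron

            net = Network(NetworkConfig(k=12))
            for i, idx in enumerate(order):
                proto, cat, aif = triples[idx]
                net.neurons.append(
                    Neuron(id=i, prototype=np.asarray(proto), category=cat, aif=aif)
                )
            return net

        a = build(range(12))
        b = build(reversed(range(12)))
        for _ in range(50):
            v = random_vec(rng)
            ra, rb = a.classify(v), b.classify(v)
            assert ra.status == rb.status
            assert sorted((h.distance, h.category) for h in ra.hits) == sorted(
                (h.distance, h.category) for h in rb.hits
            )


class TestTrainingSetConsistency:
    def test_distinct_category_vectors_recalled_exactly(self, rng):
        # one distinct vector per category, repeated in random order: every
        # training vector ends up stored, recalled at distance 0, and no
        # wrong-category neuron can fire on it
        for trial in range(10):
            n_cat = int(rng.integers(2, 7))
            protos = {str(c): random_vec(rng) for c in range(n_cat)}
            net = Network()
            for _ in range(100):
                c = str(rng.integers(n_cat))
                net.learn(protos[c], c)
            assert len(net) == n_cat
            for c, v in protos.items():
                res = net.classify(v)
                assert res.status == "identified"
                assert res.hits[0].category == c and res.hits[0].distance == 0

    def test_random_distinct_vectors_recall_exactly_when_committed(self, rng):
        # fully random sequences: every vector the learning rule actually
        # committed is recalled by its own category at distance 0 (a vector
        # skipped because a same-category neuron already fired carries no
        # such guarantee — a later commit with a fresh max_if field may
        # capture it)
        net = Network()
        committed = []
        for _ in range(200):
            v, c = random_vec(rng), str(rng.integers(5))
            if net.learn(v, c).committed:
                committed.append((v, c))
        assert committed
        for v, c in committed:
            res = net.classify(v)
            assert res.hits[0].category == c and res.hits[0].distance == 0


class TestSerialization:
    def test_json_round_trip_is_bit_exact(self, rng):
        net = Network(NetworkConfig(capacity=64, max_if=2000, min_if=8, k=5))
        for _ in range(30):
            net.learn(random_vec(rng), str(rng.integers(4)))
        clone = Network.from_json(net.to_json())
        assert clone.to_json() == net.to_json()
        assert len(clone) == len(net)
        for a, b in zip(net.neurons, clone.neurons):
            assert np.array_equal(a.prototype, b.prototype)
            assert (a.category, a.aif, a.degenerate) == (b.category, b.aif, b.degenerate)
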