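import numpy as np
import pytest

from spikenose import (
    FrameError,
    Network,
    NetworkConfig,
    RankOrderPattern,
    StreamingClassifier,
    anomaly_template,
    default_templates,
    latch_decision,
    log_anomaly,
    rank_order_to_vector,
    stream_events,
    train_on_references,
)
from spikenose.network import ClassificationResult, Hit
from spikenose.streaming import StreamTrace, SpikeEvent


@pytest.fixture
def trained_net():
    return train_on_references(default_templates(0))


def perm(seq):
    return RankOrderPattern(np.asarray(seq))


class TestPushSpike:
    def test_duplicate_sensor_in_frame_rejected(self, trained_net):
        clf = StreamingClassifier(trained_net)
        clf.start_frame()
        clf.push_spike(3)
        with pytest.raises(FrameError):
            clf.push_spike(3)

    def test_more_than_sixteen_spikes_rejected(self, trained_net):
        clf = StreamingClassifier(trained_net)
        clf.start_frame()
        for s in range(16):
            clf.push_spike(s)
        with pytest.raises(FrameError):
            clf.push_spike(0)

    def test_first_spike_classifies_on_one_component_window(self, trained_net):
        clf = StreamingClassifier(trained_net)
        clf.start_frame()
        res = clf.push_spike(5)
        assert res.hits  # tiny window: distances small, neurons fire
        # the masked distance can involve only sensor 5's component
        ref = trained_net.neurons[res.hits[0].neuron_id].prototype
        assert res.hits[0].distance == abs(int(ref[5]) - 0)

    def test_streaming_a_stored_reference_ends_identified_at_zero(self, trained_net):
        refs = default_templates(0)
        clf = StreamingClassifier(trained_net)
        for analyte, pattern in refs.items():
            trace = clf.classify_frame(pattern, analyte)
            final = trace.final
            assert final.status in ("identified", "uncertain")
            assert final.hits[0].distance == 0
            assert final.hits[0].category == analyte

    def test_per_spike_results_equal_batch_masked_classification(self, trained_net, rng):
        # stream/batch equivalence: window m of a streamed frame is the
        # batch classification of the full vector masked to its first m sensors
        for _ in range(50):
            pattern = perm(rng.permutation(16))
            clf = StreamingClassifier(trained_net)
            trace = clf.classify_frame(pattern)
            order = pattern.firing_order
            for m, res in enumerate(trace.results, start=1):
                batch = trained_net.classify(
                    rank_order_to_vector(pattern, received=order[:m])
                )
                assert [(h.category, h.distance, h.neuron_id) for h in res.hits] == [
                    (h.category, h.distance, h.neuron_id) for h in batch.hits
                ]
                assert res.status == batch.status

    def test_window_distances_non_decreasing_per_neuron(self, trained_net, rng):
        knn = Network.from_json(trained_net.to_json())
        knn.config.mode = "knn"
        knn.config.k = len(knn.neurons)
        for _ in range(50):
            pattern = perm(rng.permutation(16))
            clf = StreamingClassifier(knn)
            trace = clf.classify_frame(pattern)
            per_neuron: dict[int, list[int]] = {}
            for res in trace.results:
                for h in res.hits:
                    per_neuron.setdefault(h.neuron_id, []).append(h.distance)
            for dists in per_neuron.values():
                assert all(a <= b for a, b in zip(dists, dists[1:]))


def _fake_trace(categories, frame_id=0):
    """Build a trace whose window-m top-1 category is categories[m-1]
    (None marks an unknown window)."""
    trace = StreamTrace(frame_id)
    for m, cat in enumerate(categories):
        trace.events.append(SpikeEvent(m, m))
        if cat is None:
            trace.results.append(ClassificationResult((), "unknown"))
        else:
            trace.results.append(
                ClassificationResult((Hit(cat, m, 0),), "identified")
            )
    return trace


class TestLatchDecision:
    def test_constant_top1_latches_at_first_spike(self):
        trace = _fake_trace(["gas"] * 16)
        dec = latch_decision(trace)
        assert dec.category == "gas"
        assert dec.spikes_to_decision == 1
        assert dec.frame_fraction == pytest.approx(6.25)

    def test_flip_at_spike_five_latches_at_five(self):
        trace = _fake_trace(["other"] * 4 + ["gas"] * 12)
        assert latch_decision(trace).spikes_to_decision == 5

    def test_unknown_final_window_never_latches(self):
        trace = _fake_trace(["gas"] * 15 + [None])
        assert latch_decision(trace) is None

    def test_first_identified_policy_latches_on_first_identified_window(self):
        trace = _fake_trace([None, "a", "b", "b"])
        dec = latch_decision(trace, policy="first-identified")
        assert dec.category == "a" and dec.spikes_to_decision == 2

    def test_matches_suffix_scan_oracle_on_random_traces(self, rng):
        cats = ["a", "b", "c", None]
        for _ in range(300):
            seq = [cats[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 17)))]
            trace = _fake_trace(seq)
            dec = latch_decision(trace)
            # oracle: smallest m whose suffix is constant and defined
            expected = None
            for m in range(1, len(seq) + 1):
                suffix = seq[m - 1 :]
                if all(c is not None and c == suffix[0] for c in suffix):
                    expected = (suffix[0], m)
                    break
            if expected is None:
                assert dec is None
            else:
                assert (dec.category, dec.spikes_to_decision) == expected


class TestAnomalies:
    def test_stored_reference_is_never_logged(self, trained_net):
        refs = default_templates(0)
        clf = StreamingClassifier(trained_net)
        for analyte, pattern in refs.items():
            clf.classify_frame(pattern, analyte)
        assert clf.anomalies == []

    def test_distant_frame_is_logged_with_full_signature(self, trained_net):
        far = anomaly_template(default_templates(0), seed=3)
        clf = StreamingClassifier(trained_net)
        trace = clf.classify_frame(far, "f0")
        assert trace.final.status == "unknown"
        assert len(clf.anomalies) == 1
        rec = clf.anomalies[0]
        assert rec.category == "unknown" and rec.frame_id == "f0"
        assert rec.rank_order().footrule(far) == 0

    def test_incomplete_frame_not_eligible_for_anomaly_logging(self, trained_net):
        clf = StreamingClassifier(trained_net)
        clf.start_frame("partial")
        clf.push_spike(0)
        trace = clf.finish_frame()
        assert not trace.complete
        assert log_anomaly(trace) is None and clf.anomalies == []


class TestStreamEvents:
    def test_frames_grouped_by_contiguous_frame_id(self, trained_net, rng):
        p1, p2 = perm(rng.permutation(16)), perm(rng.permutation(16))
        events = [("f1", int(s)) for s in p1.firing_order] + [
            ("f2", int(s)) for s in p2.firing_order
        ]
        clf = StreamingClassifier(trained_net)
        traces = stream_events(clf, events)
        assert [t.frame_id for t in traces] == ["f1", "f2"]
        assert all(t.complete for t in traces)
        assert traces[0].rank_order().footrule(p1) == 0
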