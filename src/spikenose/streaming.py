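"""Continuous per-spike classification with a growing pattern-matching window.

Sensors fire one at a time; each arriving spike extends the set of received
sensors, the partial rank order (arrival position = rank) is re-encoded
with the received set as mask, and the network is queried again.  Because
the masked Manhattan distance only accumulates terms, distances grow
monotonically with the window, and a decision can usually be latched long
before the 16th spike — the source of the classifier's low decision
latency.

A full frame whose final restricted-Coulomb (RBF) status is *unknown* is
logged as an anomaly: the complete signature is stored with the "unknown"
category for later inspection and relabelling, the hook through which
sensor drift shows up as a stream of unmatched signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from .encoder import (
    DEFAULT_SCALE,
    N_SENSORS,
    RankOrderPattern,
    rank_order_to_vector,
)
from .errors import FrameError, StructuralError
from .network import ClassificationResult, Network


@dataclass(frozen=True)
class SpikeEvent:
    """Arrival of one sensor's spike within a frame."""

    sensor_index: int
    order: int  # rank implied by arrival position, 0 = first

    def __post_init__(self) -> None:
        if not 0 <= self.sensor_index < N_SENSORS:
            raise FrameError(f"sensor_index {self.sensor_index} outside array")
        if not 0 <= self.order < N_SENSORS:
            raise FrameError(f"order {self.order} outside frame")


@dataclass(frozen=True)
class Decision:
    """A latched streaming decision."""

    category: str
    spikes_to_decision: int  # 1..16
    policy: str

    @property
    def frame_fraction(self) -> float:
        """Percent of the 16-element pattern frame consumed."""
        return 100.0 * self.spikes_to_decision / N_SENSORS


@dataclass
class StreamTrace:
    """Per-spike classification results for one frame."""

    frame_id: int | str
    events: list[SpikeEvent] = field(default_factory=list)
    results: list[ClassificationResult] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return len(self.events) == N_SENSORS

    @property
    def final(self) -> ClassificationResult | None:
        return self.results[-1] if self.results else None

    def rank_order(self) -> RankOrderPattern:
        """The received signature; only defined for a complete frame."""
        if not self.complete:
            raise FrameError("frame incomplete; partial signature has no permutation")
        return RankOrderPattern.from_firing_order(
            [e.sensor_index for e in self.events]
        )


@dataclass(frozen=True)
class AnomalyRecord:
    """A full frame whose signature matched no learned reference."""

    frame_id: int | str
    firing_order: tuple[int, ...]
    category: str = "unknown"

    def rank_order(self) -> RankOrderPattern:
        return RankOrderPattern.from_firing_order(list(self.firing_order))


class StreamingClassifier:
    """Drives a trained network one spike at a time.

    Typical use::

        clf = StreamingClassifier(net)
        clf.start_frame("frame-0")
        for sensor in firing_order:
            result = clf.push_spike(sensor)
        trace = clf.finish_frame()          # may append to clf.anomalies
        decision = latch_decision(trace)
    """

    def __init__(self, net: Network, scale: int = DEFAULT_SCALE) -> None:
        self.net = net
        self.scale = scale
        self.anomalies: list[AnomalyRecord] = []
        self._trace: StreamTrace | None = None
        self._ranks = [0] * N_SENSORS
        self._received: set[int] = set()

    def start_frame(self, frame_id: int | str = 0) -> None:
        self._trace = StreamTrace(frame_id)
        self._ranks = [0] * N_SENSORS
        self._received = set()

    def push_spike(self, sensor_index: int) -> ClassificationResult:
        """Receive one spike, widen the window and reclassify.

        The arriving sensor's rank is its arrival position; the partial
        pattern is encoded with mask = received sensors and broadcast.
        """
        if self._trace is None:
            self.start_frame()
        trace = self._trace
        assert trace is not None
        if sensor_index in self._received:
            raise FrameError(
                f"sensor {sensor_index} already fired in frame {trace.frame_id}"
            )
        if len(self._received) >= N_SENSORS:
            raise FrameError(f"frame {trace.frame_id} already holds 16 spikes")
        order = len(self._received)
        event = SpikeEvent(sensor_index, order)
        self._ranks[sensor_index] = order
        self._received.add(sensor_index)
        result = self.net.classify(self._partial_vector())
        trace.events.append(event)
        trace.results.append(result)
        return result

    def _partial_vector(self):
        # Received sensors hold ranks 0..m-1; unreceived components are
        # masked out, so their placeholder values never enter a distance.
        pattern = list(self._ranks)
        for s in range(N_SENSORS):
            if s not in self._received:
                pattern[s] = -1
        # Build a valid permutation by parking unreceived sensors on the
        # unused high ranks (deterministic: ascending sensor index).
        free = iter(range(len(self._received), N_SENSORS))
        for s in range(N_SENSORS):
            if pattern[s] == -1:
                pattern[s] = next(free)
        return rank_order_to_vector(
            RankOrderPattern(pattern), received=self._received, scale=self.scale
        )

    def finish_frame(self) -> StreamTrace:
        """Close the current frame, logging it if its final status is unknown.

        Incomplete frames (sensor dead, stream truncated) are returned
        as-is — classified on the available mask — but are not eligible
        for anomaly logging, which requires the full signature.
        """
        trace = self._trace
        if trace is None:
            raise FrameError("no frame in progress")
        record = log_anomaly(trace)
        if record is not None:
            self.anomalies.append(record)
        self._trace = None
        return trace

    def classify_frame(
        self, pattern: RankOrderPattern, frame_id: int | str = 0
    ) -> StreamTrace:
        """Stream a complete signature spike-by-spike in its firing order."""
        self.start_frame(frame_id)
        for sensor in pattern.firing_order:
            self.push_spike(int(sensor))
        return self.finish_frame()


def log_anomaly(trace: StreamTrace) -> AnomalyRecord | None:
    """Create an anomaly record iff a complete frame ended unknown."""
    if not trace.complete:
        return None
    final = trace.final
    if final is None or final.status != "unknown":
        return None
    return AnomalyRecord(
        trace.frame_id,
        tuple(int(e.sensor_index) for e in trace.events),
    )


def latch_decision(
    trace: StreamTrace,
    policy: Literal["stable", "first-identified"] = "stable",
) -> Decision | None:
    """Extract the streaming decision and its spike count from a trace.

    ``stable`` (default, used for reported spikes-to-decision metrics):
    the smallest window m whose top-1 category is defined and identical
    for every window m..end — a retrospective criterion matching averaged
    continuous-classification statistics.  ``first-identified``: the
    smallest m whose status is *identified*, usable online.  Returns None
    when the trace never latches.
    """
    if not trace.results:
        return None
    if policy == "first-identified":
        for m, res in enumerate(trace.results, start=1):
            if res.status == "identified":
                return Decision(res.hits[0].category, m, policy)
        return None
    if policy != "stable":
        raise ValueError(f"unknown latch policy {policy!r}")
    final_cat = trace.results[-1].category
    if final_cat is None:
        return None
    latch = None
    # scan backwards over the suffix of windows agreeing with the final call
    for m in range(len(trace.results), 0, -1):
        cat = trace.results[m - 1].category
        if cat == final_cat:
            latch = m
        else:
            break
    assert latch is not None
    return Decision(final_cat, latch, policy)


def stream_events(
    clf: StreamingClassifier,
    events: Sequence[tuple[int | str, int]],
) -> list[StreamTrace]:
    """Replay a (frame_id, sensor_index) event list grouped by frame.

    Events of one frame must be contiguous; frame boundaries are detected
    by a change of frame id.
    """
    traces: list[StreamTrace] = []
    current: int | str | None = None
    for frame_id, sensor in events:
        if frame_id != current:
            if current is not None:
                traces.append(clf.finish_frame())
            clf.start_frame(frame_id)
            current = frame_id
        clf.push_spike(int(sensor))
    if current is not None:
        traces.append(clf.finish_frame())
    return traces
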