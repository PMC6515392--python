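"""Metrics and end-to-end experiment orchestration.

The evaluation protocol mirrors the streaming study: the learning set is
exactly one reference rank-order signature per class (derived by
probabilistic rank-score coding, or supplied directly), the network is
trained offline on those references alone, and every test frame is
streamed spike-by-spike.  Reported metrics are classification accuracy, a
confusion matrix with an explicit *unknown* column, and early-decision
statistics: spikes-to-decision and the corresponding percentage of the
16-element pattern frame, overall and per analyte.

A frame that never latches a decision (or whose full-frame status is
unknown) has no predicted class; it lands in the unknown column and counts
against accuracy — the conservative treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .encoder import (
    DEFAULT_SCALE,
    N_SENSORS,
    RankOrderPattern,
    SensorCharacteristics,
    encode_exposure,
    SteadyStateFeature,
    to_rank_order,
)
from .errors import DomainError, StructuralError
from .network import Network, NetworkConfig, train_on_references
from .reference import derive_references
from .streaming import Decision, StreamingClassifier, StreamTrace, latch_decision
from .synthetic import (
    FEATURE_COLUMNS,
    GeneratorConfig,
    SyntheticDataset,
    sample_dataset,
)

UNKNOWN = "unknown"


def frame_fraction(spikes: float, frame_size: int = N_SENSORS) -> float:
    """Percent of the pattern frame consumed by a given spike count.

    E.g. 3 of 16 spikes -> 18.75; accepts fractional spike counts so that
    averaged spikes-to-decision values convert directly.
    """
    if frame_size < 1:
        raise DomainError(f"frame_size must be >= 1, got {frame_size}")
    if not 0 < spikes <= frame_size:
        raise DomainError(
            f"spikes must lie in (0, {frame_size}], got {spikes!r}"
        )
    return 100.0 * spikes / frame_size


@dataclass(frozen=True)
class EvaluationReport:
    """Aggregate streaming-classification metrics.

    confusion : DataFrame, rows = true analytes, columns = predicted
        analytes plus an ``unknown`` column for unlatched/unmatched frames.
        Row sums equal per-class test counts.
    accuracy : percent of frames whose latched decision matches the truth;
        unknown frames count as errors.
    mean_spikes_to_decision / mean_frame_fraction : averages over latched
        frames only.
    per_analyte : DataFrame indexed by analyte with n, n_correct,
        mean_spikes, mean_frame_fraction, var_frame_fraction.
    """

    confusion: pd.DataFrame
    accuracy: float
    mean_spikes_to_decision: float
    mean_frame_fraction: float
    per_analyte: pd.DataFrame
    n_frames: int
    n_unknown: int
    policy: str

    def round(self, ndigits: int = 2) -> dict:
        """Plain-dict summary with reporting precision (percentages and
        spike counts to two decimals by default)."""
        return {
            "accuracy_pct": round(self.accuracy, ndigits),
            "mean_spikes_to_decision": round(self.mean_spikes_to_decision, ndigits),
            "mean_frame_fraction_pct": round(self.mean_frame_fraction, ndigits),
            "n_frames": self.n_frames,
            "n_unknown": self.n_unknown,
            "policy": self.policy,
        }


def evaluate(
    traces: Sequence[StreamTrace],
    truth: Sequence[str],
    classes: Sequence[str] | None = None,
    policy: Literal["stable", "first-identified"] = "stable",
) -> EvaluationReport:
    """Score streamed frames against ground-truth labels."""
    if len(traces) != len(truth):
        raise StructuralError(
            f"{len(traces)} traces but {len(truth)} truth labels"
        )
    truth = [str(t) for t in truth]
    if classes is None:
        classes = list(dict.fromkeys(truth))
    classes = [str(c) for c in classes]
    unseen = set(truth) - set(classes)
    if unseen:
        raise StructuralError(f"truth labels outside class list: {sorted(unseen)}")

    columns = classes + [UNKNOWN]
    confusion = pd.DataFrame(
        np.zeros((len(classes), len(columns)), dtype=int),
        index=pd.Index(classes, name="true"),
        columns=pd.Index(columns, name="predicted"),
    )
    decisions: list[Decision | None] = [latch_decision(t, policy) for t in traces]
    spikes, fractions, rows = [], [], []
    for dec, true_label in zip(decisions, truth):
        pred = dec.category if dec is not None else UNKNOWN
        if pred not in confusion.columns:  # decision for an untrained label
            pred = UNKNOWN
        confusion.loc[true_label, pred] += 1
        if dec is not None:
            spikes.append(dec.spikes_to_decision)
            fractions.append(dec.frame_fraction)
            rows.append((true_label, pred, dec.spikes_to_decision))
        else:
            rows.append((true_label, UNKNOWN, np.nan))

    n = len(traces)
    correct = int(np.diag(confusion.values[:, : len(classes)]).sum())
    accuracy = 100.0 * correct / n if n else float("nan")
    per = pd.DataFrame(rows, columns=["true", "pred", "spikes"])
    grouped = per.groupby("true", sort=False)
    per_analyte = pd.DataFrame(
        {
            "n": grouped.size(),
            "n_correct": per.assign(ok=per["true"] == per["pred"])
            .groupby("true", sort=False)["ok"]
            .sum()
            .astype(int),
            "mean_spikes": grouped["spikes"].mean(),
            "mean_frame_fraction": grouped["spikes"].mean() * 100.0 / N_SENSORS,
            "var_frame_fraction": grouped["spikes"]
            .apply(lambda s: np.var(s.dropna() * 100.0 / N_SENSORS)),
        }
    ).reindex(classes)
    return EvaluationReport(
        confusion=confusion,
        accuracy=accuracy,
        mean_spikes_to_decision=float(np.mean(spikes)) if spikes else float("nan"),
        mean_frame_fraction=float(np.mean(fractions)) if fractions else float("nan"),
        per_analyte=per_analyte,
        n_frames=n,
        n_unknown=int(confusion[UNKNOWN].sum()),
        policy=policy,
    )


# ---------------------------------------------------------------------------
# Pipeline helpers
# ---------------------------------------------------------------------------


def encode_table(
    features: pd.DataFrame,
    chars: SensorCharacteristics | None = None,
) -> list[RankOrderPattern]:
    """Encode a feature table (sample_id, analyte, concentration_ppmv,
    S0..S15) into rank-order signatures, one per row."""
    missing = [c for c in ("analyte", *FEATURE_COLUMNS) if c not in features.columns]
    if missing:
        raise StructuralError(f"feature table lacks columns {missing}")
    patterns = []
    for _, row in features.iterrows():
        feats = [
            SteadyStateFeature(
                sensor_index=i,
                resistance=float(row[f"S{i}"]),
                analyte=str(row["analyte"]),
                concentration=float(row.get("concentration_ppmv", 1.0)),
            )
            for i in range(N_SENSORS)
        ]
        patterns.append(to_rank_order(encode_exposure(feats, chars)))
    return patterns


@dataclass(frozen=True)
class ExperimentResult:
    """Everything the end-to-end synthetic experiment produces."""

    report: EvaluationReport
    references: dict[str, RankOrderPattern]
    net: Network
    traces: list[StreamTrace]
    patterns: list[RankOrderPattern]
    dataset: SyntheticDataset


def run_experiment(
    gen_config: GeneratorConfig | None = None,
    net_config: NetworkConfig | None = None,
    policy: Literal["stable", "first-identified"] = "stable",
    scale: int = DEFAULT_SCALE,
    reference_method: Literal["greedy", "optimal"] = "greedy",
) -> ExperimentResult:
    """Full synthetic pipeline: generate, encode, derive references, train,
    stream every frame, and score.

    The learning set is the per-class rank-score reference signatures —
    derived summaries, disjoint from the individual test frames streamed
    for evaluation.
    """
    gen_config = gen_config or GeneratorConfig()
    dataset = sample_dataset(gen_config)
    patterns = encode_table(dataset.features)
    truth = dataset.features["analyte"].tolist()
    references = derive_references(
        patterns, truth, class_order=gen_config.analytes, method=reference_method
    )
    net = train_on_references(references, net_config, scale=scale)
    clf = StreamingClassifier(net, scale=scale)
    traces = [
        clf.classify_frame(p, frame_id=int(sid))
        for sid, p in zip(dataset.features["sample_id"], patterns)
    ]
    report = evaluate(traces, truth, classes=list(gen_config.analytes), policy=policy)
    return ExperimentResult(report, references, net, traces, patterns, dataset)
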