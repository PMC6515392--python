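"""Probabilistic rank-score coding of per-gas reference signatures.

Given a set of rank-order signatures recorded for one target gas *k*, the
rank-score matrix tallies how often sensor *i* spiked at rank *j*:

    P_ij(k) = N_ij(k) / N(k)

where N(k) is the number of patterns and N_ij(k) the count of patterns in
which sensor *i* held rank *j*.  Each complete pattern contributes exactly
one sensor per rank, so every rank column of P sums to one.  A single
reference rank-order signature per gas — the network's entire learning set
— is then extracted by assigning each rank its most probable sensor.

The extraction is a constrained assignment (each sensor and each rank used
exactly once).  The default resolves conflicts greedily: cells are visited
in decreasing probability, ties broken by lower rank then lower sensor
index, and a cell is taken whenever both its sensor and rank are still
free.  An optimal (Hungarian) assignment maximising total probability is
available via ``method="optimal"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .encoder import N_SENSORS, RankOrderPattern
from .errors import StructuralError


@dataclass(frozen=True)
class RankScoreMatrix:
    """Per-gas sensor-by-rank spike-probability matrix.

    ``counts[i, j]`` = number of patterns in which sensor *i* spiked at
    rank *j*; ``n_patterns`` = N(k); ``probs`` = counts / N(k).
    """

    counts: np.ndarray
    n_patterns: int
    analyte: str | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (N_SENSORS, N_SENSORS):
            raise StructuralError(
                f"counts must be {N_SENSORS}x{N_SENSORS}, got {counts.shape}"
            )
        if self.n_patterns < 1:
            raise StructuralError("n_patterns must be positive")
        if np.any(counts < 0) or np.any(counts.sum(axis=0) != self.n_patterns):
            raise StructuralError(
                "each rank column must tally exactly n_patterns sensors"
            )
        object.__setattr__(self, "counts", counts)

    @property
    def probs(self) -> np.ndarray:
        """P_ij(k): probability of sensor i spiking at rank j."""
        return self.counts / self.n_patterns


def rank_score_matrix(
    patterns: Iterable[RankOrderPattern], analyte: str | None = None
) -> RankScoreMatrix:
    """Tally N_ij(k) over complete rank-order patterns of one gas."""
    counts = np.zeros((N_SENSORS, N_SENSORS), dtype=int)
    n = 0
    for p in patterns:
        counts[np.arange(N_SENSORS), p.rank_of_sensor] += 1
        n += 1
        if analyte is None:
            analyte = p.analyte
    if n == 0:
        raise ValueError("need at least one rank-order pattern")
    return RankScoreMatrix(counts, n, analyte=analyte)


def reference_signature(
    matrix: RankScoreMatrix,
    method: Literal["greedy", "optimal"] = "greedy",
) -> RankOrderPattern:
    """Extract one reference rank-order signature from a rank-score matrix.

    ``greedy`` (default) assigns cells in decreasing probability with
    deterministic tie-breaking (lower rank, then lower sensor index);
    ``optimal`` maximises the total assigned probability with the
    Hungarian algorithm.  Either way the output is a permutation.
    """
    probs = matrix.probs
    if method == "optimal":
        sensors, ranks = linear_sum_assignment(-probs)
        rank_of_sensor = np.empty(N_SENSORS, dtype=int)
        rank_of_sensor[sensors] = ranks
        return RankOrderPattern(rank_of_sensor, analyte=matrix.analyte)
    if method != "greedy":
        raise ValueError(f"unknown method {method!r}")
    return RankOrderPattern(greedy_assignment(probs), analyte=matrix.analyte)


def greedy_assignment(probs: np.ndarray) -> np.ndarray:
    """Greedy one-to-one sensor->rank assignment on a square score matrix.

    Visits cells in decreasing score, ties broken by lower rank then lower
    sensor index, taking a cell whenever its sensor and rank are both
    free.  Returns rank_of_sensor.
    """
    probs = np.asarray(probs, dtype=float)
    n = probs.shape[0]
    if probs.shape != (n, n):
        raise StructuralError("assignment needs a square matrix")
    cells = [(-probs[i, j], j, i) for i in range(n) for j in range(n)]
    cells.sort()
    rank_of_sensor = np.full(n, -1, dtype=int)
    rank_taken = np.zeros(n, dtype=bool)
    assigned = 0
    for _neg_p, j, i in cells:
        if rank_of_sensor[i] == -1 and not rank_taken[j]:
            rank_of_sensor[i] = j
            rank_taken[j] = True
            assigned += 1
            if assigned == n:
                break
    return rank_of_sensor


def derive_references(
    patterns: Sequence[RankOrderPattern],
    labels: Sequence[str] | None = None,
    class_order: Sequence[str] | None = None,
    method: Literal["greedy", "optimal"] = "greedy",
) -> dict[str, RankOrderPattern]:
    """Group patterns by analyte and derive one reference signature each.

    Labels default to each pattern's own ``analyte`` metadata.  The result
    preserves ``class_order`` when given, else first-appearance order —
    this fixes the neuron commit order downstream.
    """
    if labels is None:
        labels = [p.analyte for p in patterns]
        if any(lbl is None for lbl in labels):
            raise StructuralError(
                "patterns lack analyte metadata; pass labels explicitly"
            )
    if len(labels) != len(patterns):
        raise StructuralError("labels and patterns must have equal length")
    groups: dict[str, list[RankOrderPattern]] = {}
    for lbl, p in zip(labels, patterns):
        groups.setdefault(str(lbl), []).append(p)
    order = [str(c) for c in class_order] if class_order is not None else list(groups)
    missing = [c for c in order if c not in groups]
    if missing:
        raise StructuralError(f"no patterns for classes {missing}")
    return {
        c: reference_signature(rank_score_matrix(groups[c], analyte=c), method=method)
        for c in order
    }
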