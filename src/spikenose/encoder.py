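"""Rank-order encoding of steady-state gas-sensor-array responses.

A metal-oxide (MOX) sensor array read out through a resistance-to-time
converter emits one spike per sensor, with firing latency

    t_i = ln(R_ij) / gamma_ij

where ``R_ij`` is the steady-state resistance feature of sensor *i* under
analyte *j* and ``gamma_ij`` is a sensor/analyte characteristic constant.
The analog multivariate response is thereby compressed into the *order* in
which the 16 sensors fire — a rank-order signature — discarding absolute
timing.  This module converts steady-state feature rows into latency
patterns, latency patterns into rank-order permutations, and permutations
into byte-valued vectors suitable for broadcast to an associative
nearest-neighbor network.

The byte layout is rank-by-sensor: component *i* holds ``scale * rank_i``
where ``rank_i`` is the rank (0 = earliest) at which sensor *i* fired.
Under a full mask, the Manhattan distance between two such vectors equals
``scale`` times the Spearman footrule distance between the underlying
permutations, so mild spike shuffles produce proportionally small
distances, and a partial mask implements the growing pattern-matching
window used for streaming classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DomainError, RangeError, StructuralError

#: Number of sensors in the emulated 4 x 4 MOX array.
N_SENSORS = 16

#: Largest value storable in one byte of neuron memory.
BYTE_MAX = 255

#: Default rank-to-byte scale; 16 rank levels then span 0..240.
DEFAULT_SCALE = 16


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SteadyStateFeature:
    """One sensor's steady-state response for one exposure.

    Parameters
    ----------
    sensor_index : int
        Position of the sensor in the array, 0..15.
    resistance : float
        Steady-state resistance-derived feature R_ij; must be positive so
        its logarithm is defined.
    analyte : str, optional
        Label of the exposed gas.
    concentration : float, optional
        Exposure concentration in ppmv; positive when given.
    """

    sensor_index: int
    resistance: float
    analyte: str | None = None
    concentration: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.sensor_index < N_SENSORS:
            raise StructuralError(
                f"sensor_index {self.sensor_index} outside 0..{N_SENSORS - 1}"
            )
        if not (self.resistance > 0 and math.isfinite(self.resistance)):
            raise DomainError(
                f"sensor {self.sensor_index}: non-positive or non-finite "
                f"resistance {self.resistance!r} (log undefined)"
            )
        if self.concentration is not None and not self.concentration > 0:
            raise DomainError(
                f"sensor {self.sensor_index}: concentration must be positive, "
                f"got {self.concentration!r}"
            )


class SensorCharacteristics:
    """Per-sensor (optionally per-analyte) latency constants gamma_ij.

    ``gamma`` may be a scalar applied to every sensor, a length-16 sequence
    indexed by sensor, or a mapping ``analyte -> length-16 sequence`` for
    analyte-dependent characteristics.  All values must be positive and
    finite.  The default, ``gamma = 1`` everywhere, makes the firing order
    identical to the order of ln R (equivalently of R), which is the minimal
    assumption when sensor/gas characteristics are unavailable.
    """

    def __init__(
        self,
        gamma: float | Sequence[float] | Mapping[str, Sequence[float]] = 1.0,
    ) -> None:
        if isinstance(gamma, Mapping):
            self._table = {
                str(k): self._validate_vector(v, label=str(k))
                for k, v in gamma.items()
            }
            self._default = None
        else:
            self._table = {}
            self._default = self._validate_vector(gamma, label="gamma")

    @staticmethod
    def _validate_vector(gamma, label: str) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(gamma, dtype=float), (N_SENSORS,)).copy()
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise DomainError(f"{label}: gamma values must be positive and finite")
        return arr

    @classmethod
    def unit(cls) -> "SensorCharacteristics":
        """Characteristics with gamma = 1 for every sensor."""
        return cls(1.0)

    @classmethod
    def calibrate(
        cls,
        resistances: Sequence[float],
        target_latencies: Sequence[float],
        analyte: str | None = None,
    ) -> "SensorCharacteristics":
        """Estimate gamma_i = ln(R_i) / t_i from one reference exposure.

        A convenience for users who know what latency each sensor should
        produce on a designated calibration exposure; every target latency
        must be nonzero and share the sign of ln R_i so the resulting gamma
        is positive.
        """
        r = np.asarray(resistances, dtype=float)
        t = np.asarray(target_latencies, dtype=float)
        if r.shape != (N_SENSORS,) or t.shape != (N_SENSORS,):
            raise StructuralError(
                f"calibration needs {N_SENSORS} resistances and latencies"
            )
        if np.any(r <= 0):
            raise DomainError("calibration resistances must be positive")
        if np.any(t == 0):
            raise DomainError("target latencies must be nonzero")
        gamma = np.log(r) / t
        if np.any(gamma <= 0):
            raise DomainError(
                "calibration produced non-positive gamma; target latencies "
                "must share the sign of ln(R)"
            )
        if analyte is not None:
            return cls({analyte: gamma})
        return cls(gamma)

    def gamma_for(self, sensor_index: int, analyte: str | None = None) -> float:
        if analyte is not None and analyte in self._table:
            return float(self._table[analyte][sensor_index])
        if self._default is not None:
            return float(self._default[sensor_index])
        raise StructuralError(
            f"no gamma registered for analyte {analyte!r} and no default"
        )

    def gamma_vector(self, analyte: str | None = None) -> np.ndarray:
        return np.array(
            [self.gamma_for(i, analyte) for i in range(N_SENSORS)], dtype=float
        )


@dataclass(frozen=True)
class SpikeLatencyPattern:
    """Vector of 16 firing latencies t_i plus exposure metadata."""

    latencies: np.ndarray
    analyte: str | None = None
    concentration: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.latencies, dtype=float)
        if arr.shape != (N_SENSORS,):
            raise StructuralError(
                f"latency vector must have length {N_SENSORS}, got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise DomainError("latencies must all be finite")
        object.__setattr__(self, "latencies", arr)


@dataclass(frozen=True)
class RankOrderPattern:
    """Permutation of the 16 sensors by firing order.

    ``rank_of_sensor[i]`` is the rank (0 = earliest) at which sensor *i*
    fired.  Always a permutation of {0..15}.
    """

    rank_of_sensor: np.ndarray
    analyte: str | None = None
    concentration: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.rank_of_sensor, dtype=int)
        if arr.shape != (N_SENSORS,) or sorted(arr.tolist()) != list(range(N_SENSORS)):
            raise StructuralError(
                f"rank_of_sensor must be a permutation of 0..{N_SENSORS - 1}"
            )
        object.__setattr__(self, "rank_of_sensor", arr)

    @classmethod
    def from_firing_order(
        cls, firing_order: Sequence[int], **metadata
    ) -> "RankOrderPattern":
        """Build from the sensor indices listed in firing order."""
        order = np.asarray(firing_order, dtype=int)
        ranks = np.empty(N_SENSORS, dtype=int)
        ranks[order] = np.arange(N_SENSORS)
        return cls(ranks, **metadata)

    @property
    def firing_order(self) -> np.ndarray:
        """Sensor indices sorted by firing rank (earliest first)."""
        return np.argsort(self.rank_of_sensor, kind="stable")

    def footrule(self, other: "RankOrderPattern") -> int:
        """Spearman footrule distance: sum over sensors of |rank difference|."""
        return int(np.abs(self.rank_of_sensor - other.rank_of_sensor).sum())


@dataclass(frozen=True)
class FeatureVector:
    """Byte-valued vector broadcast to the network, with a validity mask.

    ``mask[i]`` marks component *i* as received; distance evaluation runs
    over masked components only, which is how the streaming pattern-matching
    window is realised.  Components must fit the 256-byte neuron memory.
    """

    components: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        comp = np.asarray(self.components, dtype=int)
        if comp.ndim != 1 or comp.size > 256:
            raise StructuralError(
                f"feature vector must be 1-D with at most 256 components, "
                f"got shape {comp.shape}"
            )
        mask = self.mask
        if mask is None:
            mask = np.ones(comp.size, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != comp.shape:
            raise StructuralError("mask shape must match components")
        if np.any(comp[mask] < 0) or np.any(comp[mask] > BYTE_MAX):
            raise RangeError(
                f"unmasked components must lie in [0, {BYTE_MAX}]"
            )
        object.__setattr__(self, "components", comp)
        object.__setattr__(self, "mask", mask)

    @property
    def full_mask(self) -> bool:
        return bool(self.mask.all())


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def spike_latency(
    resistance: float, gamma: float, sensor_index: int | None = None
) -> float:
    """Firing latency t = ln(resistance) / gamma of one sensor.

    Raises :class:`DomainError` naming the sensor when resistance or gamma
    is non-positive.
    """
    label = "" if sensor_index is None else f"sensor {sensor_index}: "
    if not resistance > 0:
        raise DomainError(f"{label}resistance must be positive, got {resistance!r}")
    if not gamma > 0:
        raise DomainError(f"{label}gamma must be positive, got {gamma!r}")
    return math.log(resistance) / gamma


def encode_exposure(
    features: Iterable[SteadyStateFeature],
    chars: SensorCharacteristics | None = None,
) -> SpikeLatencyPattern:
    """Convert the 16 steady-state features of one exposure to latencies.

    Requires exactly one feature per sensor index 0..15; analyte and
    concentration metadata (taken from the features, which must agree) are
    copied onto the output pattern.
    """
    chars = chars or SensorCharacteristics.unit()
    feats = list(features)
    seen = [f.sensor_index for f in feats]
    if sorted(seen) != list(range(N_SENSORS)):
        missing = set(range(N_SENSORS)) - set(seen)
        dupes = {s for s in seen if seen.count(s) > 1}
        raise StructuralError(
            f"exposure must contain each sensor exactly once "
            f"(missing {sorted(missing)}, duplicated {sorted(dupes)})"
        )
    analytes = {f.analyte for f in feats}
    concs = {f.concentration for f in feats}
    if len(analytes) > 1 or len(concs) > 1:
        raise StructuralError("features of one exposure must share metadata")
    analyte = analytes.pop()
    latencies = np.empty(N_SENSORS, dtype=float)
    for f in feats:
        latencies[f.sensor_index] = spike_latency(
            f.resistance, chars.gamma_for(f.sensor_index, analyte), f.sensor_index
        )
    return SpikeLatencyPattern(latencies, analyte=analyte, concentration=concs.pop())


def to_rank_order(pattern: SpikeLatencyPattern) -> RankOrderPattern:
    """Rank the sensors by firing latency (rank 0 = earliest spike).

    Ties are broken deterministically in favour of the lower sensor index,
    so equal latencies yield sensor-index order.
    """
    order = np.argsort(pattern.latencies, kind="stable")
    ranks = np.empty(N_SENSORS, dtype=int)
    ranks[order] = np.arange(N_SENSORS)
    return RankOrderPattern(
        ranks, analyte=pattern.analyte, concentration=pattern.concentration
    )


def rank_order_to_vector(
    pattern: RankOrderPattern,
    received: Iterable[int] | None = None,
    scale: int = DEFAULT_SCALE,
) -> FeatureVector:
    """Encode a (possibly partially received) rank order as a byte vector.

    Component *i* is ``scale * rank_of_sensor[i]``; the mask marks the
    sensors in ``received`` (all 16 when omitted).  ``scale`` must keep the
    largest rank inside the byte range, i.e. ``scale * 15 <= 255``.
    """
    if scale <= 0:
        raise RangeError(f"scale must be a positive integer, got {scale!r}")
    if scale * (N_SENSORS - 1) > BYTE_MAX:
        raise RangeError(
            f"scale {scale} drives rank {N_SENSORS - 1} to "
            f"{scale * (N_SENSORS - 1)} > {BYTE_MAX}"
        )
    components = scale * pattern.rank_of_sensor
    if received is None:
        mask = np.ones(N_SENSORS, dtype=bool)
    else:
        idx = list(received)
        if any(not 0 <= i < N_SENSORS for i in idx):
            raise StructuralError(f"received sensors must lie in 0..{N_SENSORS - 1}")
        mask = np.zeros(N_SENSORS, dtype=bool)
        mask[idx] = True
    return FeatureVector(components, mask)


def vector_to_rank_order(vector: FeatureVector, scale: int = DEFAULT_SCALE) -> RankOrderPattern:
    """Invert :func:`rank_order_to_vector` for a fully masked vector."""
    if not vector.full_mask:
        raise StructuralError("only fully masked vectors encode a complete permutation")
    ranks, rem = np.divmod(vector.components, scale)
    if np.any(rem != 0):
        raise StructuralError(f"components are not multiples of scale {scale}")
    return RankOrderPattern(ranks)


def footrule_distance(a: RankOrderPattern, b: RankOrderPattern) -> int:
    """Spearman footrule distance between two rank-order signatures."""
    return a.footrule(b)
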