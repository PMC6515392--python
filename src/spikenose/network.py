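"""Software simulator of a daisy-chain nearest-neighbor spiking network.

Models a bank of up to 1024 trainable neurons, each holding a prototype
byte vector, a category, and an *active influence field* (AIF) — a
Manhattan-distance radius within which the neuron fires on a broadcast
pattern.  Two readout modes are supported:

* ``rbf`` — restricted-Coulomb-energy behaviour: a neuron fires only when
  the broadcast pattern falls strictly inside its AIF, so patterns far
  from every prototype yield an *unknown* (open-set) result;
* ``knn`` — every committed neuron answers regardless of AIF, so the k
  closest prototypes are always returned.

Supervised learning commits new neurons and shrinks the AIF of
wrong-category firing neurons to exactly their distance from the broadcast
vector, carving the decision space so that each learned pattern is excluded
from competing categories.  AIFs only ever shrink after commit; a shrink
clamped at the minimum influence field flags the neuron as degenerate but
keeps it active.

Distances are evaluated over the broadcast vector's mask only, so a
partially received pattern (a growing pattern-matching window) naturally
yields smaller distances and fires more neurons — the mechanism behind
per-spike streaming classification.  This is intentional and is not
rescaled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .encoder import FeatureVector
from .errors import CapacityError, StateError, StructuralError
from . import encoder

#: Default maximum influence field: the worst-case full-frame distance at
#: the default byte scale (16 components x 240) is 2048; 3840 is a
#: conservative register ceiling with headroom for custom encodings.
DEFAULT_MAX_IF = 3840

#: Default minimum influence field: one rank step at the default scale.
DEFAULT_MIN_IF = 16


def manhattan_distance(v: FeatureVector, p: FeatureVector) -> int:
    """Masked Manhattan distance  D = sum_{i in mask(v)} |V_i - P_i|.

    Only the broadcast vector ``v``'s mask is honoured — the stored
    prototype is always complete.  Raises on length mismatch.
    """
    if v.components.shape != p.components.shape:
        raise StructuralError(
            f"length mismatch: {v.components.shape} vs {p.components.shape}"
        )
    m = v.mask
    return int(np.abs(v.components[m] - p.components[m]).sum())


@dataclass
class NetworkConfig:
    """Network-wide registers and readout mode.

    capacity : number of neurons available (hardware bank size).
    max_if   : value loaded into a newly committed neuron's AIF when no
               neuron fired on the learning broadcast.
    min_if   : floor below which an AIF cannot shrink; hitting it marks the
               neuron degenerate.
    mode     : ``"rbf"`` (open-set, AIF-gated firing) or ``"knn"``.
    k        : number of winner-takes-all hits returned.
    """

    capacity: int = 1024
    max_if: int = DEFAULT_MAX_IF
    min_if: int = DEFAULT_MIN_IF
    mode: Literal["rbf", "knn"] = "rbf"
    k: int = 2

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise StructuralError("capacity must be >= 1")
        if not 0 < self.min_if <= self.max_if:
            raise StructuralError("need 0 < min_if <= max_if")
        if self.k < 1:
            raise StructuralError("k must be >= 1")
        if self.mode not in ("rbf", "knn"):
            raise StructuralError(f"unknown mode {self.mode!r}")


@dataclass
class Neuron:
    """One committed prototype with its category and influence field."""

    id: int
    prototype: np.ndarray
    category: str
    aif: int
    degenerate: bool = False

    def fires(self, distance: int) -> bool:
        """Strict RBF firing condition: distance strictly below the AIF."""
        return distance < self.aif


@dataclass(frozen=True)
class Hit:
    """One winner-takes-all response line."""

    category: str
    distance: int
    neuron_id: int


@dataclass(frozen=True)
class ClassificationResult:
    """WTA-ordered responses plus an aggregate status.

    ``status`` is ``"unknown"`` when no neuron fired (RBF only),
    ``"identified"`` when every firing neuron agrees on one category, and
    ``"uncertain"`` otherwise.  ``hits`` holds at most k responses ordered
    by increasing distance (ties: lower neuron id).
    """

    hits: tuple[Hit, ...]
    status: Literal["identified", "uncertain", "unknown"]

    @property
    def category(self) -> str | None:
        """Top-1 category, or None when unknown."""
        return self.hits[0].category if self.hits else None

    @property
    def distance(self) -> int | None:
        return self.hits[0].distance if self.hits else None


@dataclass(frozen=True)
class LearnReport:
    """Outcome of one learning broadcast."""

    committed: bool
    neuron_id: int | None
    new_aif: int | None
    shrunk: tuple[tuple[int, int, int], ...]  # (neuron_id, old_aif, new_aif)


class Network:
    """Simulated daisy-chain bank of influence-field neurons."""

    def __init__(self, config: NetworkConfig | None = None) -> None:
        self.config = config or NetworkConfig()
        self.neurons: list[Neuron] = []

    # -- introspection ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.neurons)

    @property
    def categories(self) -> list[str]:
        seen: dict[str, None] = {}
        for n in self.neurons:
            seen.setdefault(n.category, None)
        return list(seen)

    def _distances(self, vector: FeatureVector) -> np.ndarray:
        protos = np.stack([n.prototype for n in self.neurons])
        m = vector.mask
        return np.abs(protos[:, m] - vector.components[m]).sum(axis=1)

    # -- learning ---------------------------------------------------------

    def learn(self, vector: FeatureVector, category: str) -> LearnReport:
        """Supervised learning broadcast of ``vector`` under ``category``.

        * No neuron fires: commit a new neuron with AIF = max_if.
        * Neurons fire but none carries ``category``: commit with AIF set
          to the distance of the closest firing neuron, and shrink every
          firing neuron (all necessarily of other categories) to its own
          distance from the broadcast, clamped at min_if.
        * A firing neuron already identifies ``category``: no commit;
          wrong-category firing neurons still shrink.

        Learning requires a complete (fully masked) vector.
        """
        if not vector.full_mask:
            raise StructuralError("learning requires a fully masked vector")
        category = str(category)
        if not self.neurons:
            return self._commit(vector, category, self.config.max_if)

        dist = self._distances(vector)
        firing = [
            (int(d), n) for d, n in zip(dist, self.neurons) if n.fires(int(d))
        ]
        firing.sort(key=lambda t: (t[0], t[1].id))

        shrunk: list[tuple[int, int, int]] = []
        for d, n in firing:
            if n.category != category:
                old = n.aif
                n.aif = max(self.config.min_if, d)
                if n.aif == self.config.min_if and d <= self.config.min_if:
                    n.degenerate = True
                shrunk.append((n.id, old, n.aif))

        if not firing:
            return self._commit(vector, category, self.config.max_if)
        if any(n.category == category for _, n in firing):
            return LearnReport(False, None, None, tuple(shrunk))
        closest_distance = firing[0][0]
        aif = min(self.config.max_if, max(self.config.min_if, closest_distance))
        report = self._commit(vector, category, aif, shrunk=shrunk)
        if closest_distance <= self.config.min_if:
            self.neurons[-1].degenerate = True
        return report

    def _commit(
        self,
        vector: FeatureVector,
        category: str,
        aif: int,
        shrunk: list[tuple[int, int, int]] | None = None,
    ) -> LearnReport:
        if len(self.neurons) >= self.config.capacity:
            raise CapacityError(
                f"all {self.config.capacity} neurons committed; cannot learn"
            )
        neuron = Neuron(
            id=len(self.neurons),
            prototype=vector.components.copy(),
            category=category,
            aif=int(aif),
        )
        self.neurons.append(neuron)
        return LearnReport(True, neuron.id, neuron.aif, tuple(shrunk or ()))

    # -- classification ---------------------------------------------------

    def classify(self, vector: FeatureVector) -> ClassificationResult:
        """Winner-takes-all classification of a broadcast vector.

        In RBF mode only neurons with distance strictly inside their AIF
        fire; an empty firing set yields status ``unknown``.  In KNN mode
        every committed neuron responds and ``unknown`` cannot occur.
        """
        if not self.neurons:
            raise StateError("cannot classify with no committed neurons")
        dist = self._distances(vector)
        if self.config.mode == "rbf":
            firing = [
                (int(d), n) for d, n in zip(dist, self.neurons) if n.fires(int(d))
            ]
        else:
            firing = [(int(d), n) for d, n in zip(dist, self.neurons)]
        firing.sort(key=lambda t: (t[0], t[1].id))
        hits = tuple(
            Hit(n.category, d, n.id) for d, n in firing[: self.config.k]
        )
        if not firing:
            status = "unknown"
        elif len({n.category for _, n in firing}) == 1:
            status = "identified"
        else:
            status = "uncertain"
        return ClassificationResult(hits, status)

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        """Serialize configuration and neuron state; bit-exact round-trip."""
        payload = {
            "config": {
                "capacity": self.config.capacity,
                "max_if": self.config.max_if,
                "min_if": self.config.min_if,
                "mode": self.config.mode,
                "k": self.config.k,
            },
            "neurons": [
                {
                    "id": n.id,
                    "prototype": n.prototype.tolist(),
                    "category": n.category,
                    "aif": n.aif,
                    "degenerate": n.degenerate,
                }
                for n in self.neurons
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Network":
        payload = json.loads(text)
        net = cls(NetworkConfig(**payload["config"]))
        for rec in payload["neurons"]:
            net.neurons.append(
                Neuron(
                    id=int(rec["id"]),
                    prototype=np.asarray(rec["prototype"], dtype=int),
                    category=str(rec["category"]),
                    aif=int(rec["aif"]),
                    degenerate=bool(rec["degenerate"]),
                )
            )
        return net

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        return cls.from_json(Path(path).read_text())


def train_on_references(
    references: dict[str, "encoder.RankOrderPattern"],
    config: NetworkConfig | None = None,
    scale: int = encoder.DEFAULT_SCALE,
) -> Network:
    """Commit one reference rank-order signature per category.

    Categories are learned in the mapping's iteration order, mirroring the
    offline learning protocol in which the unique learning set is one
    derived reference signature per target gas.
    """
    net = Network(config)
    for category, pattern in references.items():
        net.learn(encoder.rank_order_to_vector(pattern, scale=scale), category)
    return net
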