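"""Seeded generator of synthetic e-nose exposures with known rank structure.

Emulates a 4 x 4 metal-oxide sensor array exposed to six analytes over
concentration ranges typical of an e-nose bench study (tens to hundreds of
ppmv).  The log steady-state response of sensor *i* to class *k* follows a
power law in concentration plus Gaussian noise:

    ln R_i = beta_i(k) - alpha_i(k) * ln(C / C0) + b * delta * d_i + eps_i

* ``beta_i(k)`` — baseline log-response, laid out so the noiseless firing
  order reproduces the class's template rank-order signature with one
  *rank spacing* of log-response between consecutive ranks;
* ``alpha_i(k)`` — concentration sensitivity.  When alpha is constant
  across sensors within a class, changing C shifts all log-responses
  equally and the rank order is concentration-invariant; heterogeneous
  alpha lets latency curves cross so the signature changes with C;
* ``b * delta * d_i`` — optional monotone drift: batch index times drift
  rate along a fixed unit-norm per-sensor direction d (a uniform shift
  could never alter a rank order, so drift must differ across sensors to
  perturb signatures the way ageing arrays do);
* ``eps_i ~ N(0, sigma^2)`` — i.i.d. latency jitter (noise on the
  log-response is noise on the spike latency at gamma = 1), whose size
  relative to the rank spacing sets the expected number of adjacent rank
  swaps per frame.

Class templates default to six well-separated random permutations, except
for one deliberately confusable pair (ethylene/ethanol) that shares its
early firing ranks and differs only by three adjacent swaps in mid-frame —
mimicking odors with similar rank-order signatures that need extra spikes
to tell apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .encoder import N_SENSORS, RankOrderPattern, SteadyStateFeature
from .errors import DomainError, StructuralError

#: Analytes, concentration grids (ppmv) and per-class sample counts of the
#: emulated bench study.
BENCH_DESIGN: dict[str, dict] = {
    "ammonia": {
        "concentrations": (50, 75, 100, 125, 150, 175, 200, 225, 250, 275),
        "samples": 55,
    },
    "acetaldehyde": {
        "concentrations": (50, 75, 100, 125, 150, 175, 200, 225, 250, 275, 300),
        "samples": 23,
    },
    "acetone": {
        "concentrations": (150, 200, 250, 300, 350, 400, 450, 500),
        "samples": 40,
    },
    "ethylene": {
        "concentrations": (50, 75, 100, 125, 150, 175, 200, 225, 250, 275),
        "samples": 64,
    },
    "ethanol": {
        "concentrations": (50, 75, 100, 125, 150, 175, 200, 225, 250, 275, 300),
        "samples": 46,
    },
    "toluene": {
        "concentrations": (20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75),
        "samples": 57,
    },
}

#: The deliberately confusable analyte pair in the default templates.
CONFUSABLE_PAIR = ("ethylene", "ethanol")

#: Ranks at which the confusable pair's adjacent swaps sit (mid-frame, so
#: the two signatures agree on all earlier spikes).
_CONFUSABLE_SWAP_RANKS = (8, 10, 12)

FEATURE_COLUMNS = [f"S{i}" for i in range(N_SENSORS)]
TABLE_COLUMNS = ["sample_id", "analyte", "concentration_ppmv", *FEATURE_COLUMNS]


def expected_adjacent_swaps(shuffle_sd: float, rank_spacing: float = 1.0) -> float:
    """Expected adjacent-rank swaps per frame for a given latency jitter.

    Consecutive ranks sit one rank spacing apart in log-response; the two
    independent N(0, sd^2) jitters swap them with probability
    Phi(-spacing / (sd * sqrt(2))), summed over the 15 adjacent pairs.
    (Pairs are treated independently — accurate for mild jitter.)
    """
    if shuffle_sd <= 0:
        return 0.0
    return (N_SENSORS - 1) * float(
        norm.cdf(-rank_spacing / (shuffle_sd * np.sqrt(2.0)))
    )


def jitter_for_mean_swaps(mean_swaps: float, rank_spacing: float = 1.0) -> float:
    """Latency jitter sd producing a given expected adjacent-swap count."""
    if not 0 < mean_swaps < N_SENSORS - 1:
        raise DomainError(
            f"mean_swaps must lie in (0, {N_SENSORS - 1}), got {mean_swaps}"
        )
    return float(
        rank_spacing / (np.sqrt(2.0) * norm.ppf(1.0 - mean_swaps / (N_SENSORS - 1)))
    )


def _random_permutation(rng: np.random.Generator) -> RankOrderPattern:
    return RankOrderPattern(rng.permutation(N_SENSORS))


def _swap_adjacent_ranks(
    pattern: RankOrderPattern, ranks: Sequence[int]
) -> RankOrderPattern:
    """Exchange the sensors holding rank r and r+1 for each r in ranks."""
    new = pattern.rank_of_sensor.copy()
    order = pattern.firing_order
    for r in ranks:
        a, b = order[r], order[r + 1]
        new[a], new[b] = new[b], new[a]
    return RankOrderPattern(new)


def default_templates(
    seed: int = 0,
    analytes: Sequence[str] | None = None,
    min_separation: int = 40,
    confusable_swap_ranks: Sequence[int] = _CONFUSABLE_SWAP_RANKS,
) -> dict[str, RankOrderPattern]:
    """Template signatures: well-separated except one confusable pair.

    All templates except the second member of the confusable pair are
    random permutations with pairwise Spearman footrule >= min_separation;
    the confusable partner is its mate with three adjacent swaps applied
    (footrule 6), giving the dataset one genuinely hard class pair.
    """
    analytes = list(analytes or BENCH_DESIGN)
    rng = np.random.default_rng(seed)
    base, partner = CONFUSABLE_PAIR
    templates: dict[str, RankOrderPattern] = {}
    for name in analytes:
        if name == partner and base in templates:
            continue
        for _ in range(100_000):
            cand = _random_permutation(rng)
            if all(cand.footrule(t) >= min_separation for t in templates.values()):
                templates[name] = cand
                break
        else:  # pragma: no cover - rejection sampling effectively never fails
            raise RuntimeError("could not place a separated template")
    if partner in analytes and base in templates:
        templates[partner] = _swap_adjacent_ranks(
            templates[base], confusable_swap_ranks
        )
    return {name: templates[name] for name in analytes}


def anomaly_template(
    templates: Mapping[str, RankOrderPattern],
    seed: int = 0,
    n_candidates: int = 4000,
) -> RankOrderPattern:
    """A signature far (max-min footrule) from every given template.

    Random search over permutations; used to emulate an untrained gas
    whose frames should be rejected as anomalies.
    """
    rng = np.random.default_rng(seed)
    best, best_d = None, -1
    for _ in range(n_candidates):
        cand = _random_permutation(rng)
        d = min(cand.footrule(t) for t in templates.values())
        if d > best_d:
            best, best_d = cand, d
    assert best is not None
    return best


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic bench dataset.

    Defaults reproduce the emulated study: six analytes with the
    concentration grids and per-class sample counts of ``BENCH_DESIGN``,
    one rank spacing of log-response between consecutive template ranks,
    latency jitter calibrated to one expected adjacent swap per frame,
    no drift, single batch.
    """

    analytes: tuple[str, ...] = tuple(BENCH_DESIGN)
    templates: dict[str, RankOrderPattern] | None = None
    concentrations: Mapping[str, Sequence[float]] | None = None
    samples_per_class: Mapping[str, int] | None = None
    rank_spacing: float = 1.0
    base_log_response: float = 4.0
    #: concentration sensitivity alpha; scalar (sensor-constant, so the rank
    #: order is concentration-invariant) or per-analyte length-16 vectors.
    sensitivity: float | Mapping[str, Sequence[float]] = 0.8
    reference_concentration: float = 50.0
    noise_sd: float = 0.0
    shuffle_sd: float = field(default_factory=lambda: jitter_for_mean_swaps(1.0))
    drift_rate: float = 0.0
    n_batches: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.templates is None:
            self.templates = default_templates(0, self.analytes)
        if self.concentrations is None:
            self.concentrations = {
                a: BENCH_DESIGN[a]["concentrations"] for a in self.analytes
            }
        if self.samples_per_class is None:
            self.samples_per_class = {
                a: BENCH_DESIGN[a]["samples"] for a in self.analytes
            }
        if set(self.templates) < set(self.analytes):
            raise StructuralError("every analyte needs a template")
        if self.noise_sd < 0 or self.shuffle_sd < 0 or self.drift_rate < 0:
            raise DomainError("noise_sd, shuffle_sd and drift_rate must be >= 0")
        if self.rank_spacing <= 0 or self.reference_concentration <= 0:
            raise DomainError("rank_spacing and reference_concentration must be > 0")
        if self.n_batches < 1:
            raise StructuralError("n_batches must be >= 1")
        # Fixed per-sensor drift direction, drawn once from the seed so the
        # whole dataset remains a pure function of the config.
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xD81F]))
        d = rng.standard_normal(N_SENSORS)
        self.drift_direction = d / np.linalg.norm(d)

    def sensitivity_vector(self, analyte: str) -> np.ndarray:
        if isinstance(self.sensitivity, Mapping):
            vec = np.asarray(self.sensitivity[analyte], dtype=float)
            if vec.shape != (N_SENSORS,):
                raise StructuralError("per-analyte sensitivity must have length 16")
            return vec
        return np.full(N_SENSORS, float(self.sensitivity))

    def beta(self, analyte: str) -> np.ndarray:
        """Baseline log-responses realising the analyte's template ranks."""
        template = self.templates[analyte]
        return (
            self.base_log_response
            + self.rank_spacing * template.rank_of_sensor.astype(float)
        )


def sample_log_response(
    config: GeneratorConfig,
    analyte: str,
    concentration: float,
    batch: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One exposure's 16 log-responses (equivalently latencies at gamma=1)."""
    if concentration <= 0:
        raise DomainError(f"concentration must be positive, got {concentration!r}")
    sigma = float(np.hypot(config.noise_sd, config.shuffle_sd))
    eps = rng.normal(0.0, sigma, N_SENSORS) if sigma > 0 else np.zeros(N_SENSORS)
    return (
        config.beta(analyte)
        - config.sensitivity_vector(analyte)
        * np.log(concentration / config.reference_concentration)
        + batch * config.drift_rate * config.drift_direction
        + eps
    )


def sample_exposure(
    config: GeneratorConfig,
    analyte: str,
    concentration: float,
    batch: int = 0,
    rng: np.random.Generator | None = None,
) -> list[SteadyStateFeature]:
    """Draw one exposure as 16 steady-state features (R = exp log-response)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    log_r = sample_log_response(config, analyte, concentration, batch, rng)
    return [
        SteadyStateFeature(
            sensor_index=i,
            resistance=float(np.exp(log_r[i])),
            analyte=analyte,
            concentration=float(concentration),
        )
        for i in range(N_SENSORS)
    ]


@dataclass(frozen=True)
class SyntheticDataset:
    """Feature table plus ground truth returned by :func:`sample_dataset`."""

    features: pd.DataFrame  # columns: sample_id, analyte, concentration_ppmv, S0..S15
    labels: pd.Series  # sample_id -> analyte
    templates: dict[str, RankOrderPattern]


def sample_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate the full bench dataset as a feature table with ground truth.

    Concentrations cycle through each analyte's grid; batches (when
    ``n_batches > 1``) split each class's samples evenly for drift studies.
    Fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    sample_id = 0
    for analyte in config.analytes:
        grid = list(config.concentrations[analyte])
        n = int(config.samples_per_class[analyte])
        for s in range(n):
            conc = grid[s % len(grid)]
            batch = (s * config.n_batches) // max(n, 1)
            log_r = sample_log_response(config, analyte, conc, batch, rng)
            rows.append(
                {
                    "sample_id": sample_id,
                    "analyte": analyte,
                    "concentration_ppmv": float(conc),
                    **{
                        f"S{i}": float(np.exp(log_r[i])) for i in range(N_SENSORS)
                    },
                }
            )
            sample_id += 1
    features = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    labels = (
        features.set_index("sample_id")["analyte"]
        if rows
        else pd.Series(dtype=object, name="analyte")
    )
    return SyntheticDataset(features, labels, dict(config.templates))
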