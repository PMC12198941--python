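"""Synthetic device cohorts with a known ground truth.

The generator emulates the structure the concordance analysis assumes:
across a cohort, real prices and value-based prices are linked by a linear
law ``VBP = true_slope * real_price + true_intercept`` with additive
Gaussian scatter, and a configurable fraction of devices cannot be priced
at all (missing comparative data, no adequate comparator, or an
unvaluable benefit) or carry an externally published full-CEA price.

Construction per priced device: a standard-of-care price, a relative
improvement and an optional saving are drawn; the noiseless real price is
the inverse linear law of the resulting structural VBP (truncated at 0);
the Gaussian scatter is then absorbed into the health-care cost delta, so
that the device's *computed* VBP equals ``slope * price + intercept +
noise`` exactly. Putting the scatter on the VBP side of the regression
keeps ordinary least squares consistent for the generating slope, and the
cost delta is the ingredient of the model that is least precisely measured
in practice. Endpoint rates are derived from the drawn improvement, so
re-deriving the improvement from the rates is exact.

With ``price_noise_sd = 0`` the full pipeline (generate -> evaluate ->
concordance) returns r = 1 and recovers the slope and intercept to
numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .engine import (
    FAILURE_STATUSES,
    DeviceStatus,
)
from .model import (
    Cohort,
    CostProfile,
    DeviceRecord,
    EndpointDirection,
    EndpointEvidence,
)

__all__ = ["ScenarioConfig", "GenerationTruth", "generate_cohort", "tuscany_like_scenario"]


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic cohort scenario.

    ``improvement_distribution`` is ``("uniform", low, high)`` or
    ``("constant", value)``, in percent. ``failure_probability`` is split
    across the three failure kinds by ``failure_kind_weights`` (order:
    no comparative data, no comparator, unvaluable benefit).
    ``true_slope``/``true_intercept`` define the linear law
    ``VBP = true_slope * real_price + true_intercept``; the generator
    inverts it to place each device's real price.
    """

    n_devices: int = 17
    soc_price_range: tuple[float, float] = (300.0, 22_000.0)
    improvement_distribution: tuple = ("uniform", 0.0, 90.0)
    saving_probability: float = 0.15
    saving_range: tuple[float, float] = (800.0, 1_800.0)
    failure_probability: float = 0.0
    failure_kind_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    external_cea_probability: float = 0.0
    price_noise_sd: float = 0.0
    true_slope: float = 1.0
    true_intercept: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_devices < 1:
            raise ValueError("n_devices must be >= 1")
        for name in ("saving_probability", "failure_probability",
                     "external_cea_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.failure_probability + self.external_cea_probability > 1.0:
            raise ValueError("failure and external-CEA probabilities sum above 1")
        for name in ("soc_price_range", "saving_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name}=({lo}, {hi}) must be ordered and non-negative")
        family = self.improvement_distribution[0]
        if family == "uniform":
            _, lo, hi = self.improvement_distribution
            if lo > hi or hi >= 100.0:
                raise ValueError("uniform improvement bounds must be ordered and < 100")
        elif family == "constant":
            if not -100.0 < self.improvement_distribution[1] < 100.0:
                raise ValueError("constant improvement must lie in (-100, 100)")
        else:
            raise ValueError(f"unknown improvement distribution family {family!r}")
        if any(w < 0 for w in self.failure_kind_weights) or sum(self.failure_kind_weights) == 0:
            raise ValueError("failure_kind_weights must be non-negative, not all zero")
        if self.price_noise_sd < 0:
            raise ValueError("price_noise_sd must be >= 0")
        if self.true_slope <= 0:
            raise ValueError("true_slope must be positive")


@dataclass
class GenerationTruth:
    """Ground truth attached to a generated cohort."""

    config: ScenarioConfig
    true_status: dict[str, DeviceStatus] = field(default_factory=dict)
    true_vbp: dict[str, float | None] = field(default_factory=dict)


def _draw_improvement(cfg: ScenarioConfig, rng: np.random.Generator) -> float:
    dist = cfg.improvement_distribution
    if dist[0] == "uniform":
        return float(rng.uniform(dist[1], dist[2]))
    return float(dist[1])


def _rates_for(improvement: float, rng: np.random.Generator
               ) -> tuple[EndpointDirection, float, float]:
    """Draw a comparator rate and derive the new-device rate.

    The derived rate is kept in [0, 100] by bounding the comparator rate;
    by construction ``relative_improvement`` returns exactly the drawn
    improvement.
    """
    factor = 1.0 + improvement / 100.0
    if improvement < 0 or rng.random() < 0.5:  # higher-is-better arm
        hi = min(100.0, 100.0 / factor) if factor > 1 else 100.0
        rate_comp = float(rng.uniform(0.5, hi))
        return (EndpointDirection.HIGHER_BETTER, rate_comp * factor, rate_comp)
    rate_comp = float(rng.uniform(0.5, 100.0))
    return (EndpointDirection.LOWER_BETTER, rate_comp * (1.0 - improvement / 100.0), rate_comp)


def generate_cohort(config: ScenarioConfig) -> tuple[Cohort, GenerationTruth]:
    """Generate a synthetic cohort; deterministic for a given config.

    Returns the cohort together with a :class:`GenerationTruth` carrying
    each device's intended status and, for priced devices, the VBP the
    pipeline should reproduce.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    a, b = config.true_slope, config.true_intercept
    records: list[DeviceRecord] = []
    truth = GenerationTruth(config=replace(config))

    kinds = np.asarray(config.failure_kind_weights, dtype=float)
    kinds = kinds / kinds.sum()

    for i in range(config.n_devices):
        code = f"S{i + 1:03d}"
        soc = float(rng.uniform(*config.soc_price_range))
        improvement = _draw_improvement(config, rng)
        direction, rate_new, rate_comp = _rates_for(improvement, rng)
        saving = float(rng.uniform(*config.saving_range)) \
            if rng.random() < config.saving_probability else 0.0
        structural_vbp = soc * (1.0 + improvement / 100.0) + saving
        price = max(0.0, (structural_vbp - b) / a)
        noise = float(rng.normal(0.0, config.price_noise_sd)) if config.price_noise_sd else 0.0
        target_vbp = a * price + b + noise
        # the scatter lands in the cost delta so the computed VBP hits target_vbp
        delta = target_vbp - soc * (1.0 + improvement / 100.0)

        u = rng.random()
        evidence = EndpointEvidence(
            endpoint_name=f"synthetic endpoint {code}",
            direction=direction, rate_new=rate_new, rate_comparator=rate_comp,
            has_comparative_study=True,
        )
        costs = CostProfile(device_price=price, comparator_prices=[soc],
                            delta_healthcare_cost=delta)
        record = DeviceRecord(code=code, name=f"Synthetic device {code}",
                              evidence=evidence, costs=costs)

        if u < config.failure_probability:
            kind = FAILURE_STATUSES[int(rng.choice(3, p=kinds))]
            if kind is DeviceStatus.FAILED_NO_COMPARATIVE_DATA:
                record.evidence = EndpointEvidence(
                    endpoint_name=evidence.endpoint_name, has_comparative_study=False)
                record.supportive_evidence = False
            elif kind is DeviceStatus.FAILED_NO_COMPARATOR:
                record.has_adequate_comparator = False
                record.costs.comparator_prices = []
            else:
                record.benefit_valuable = False
            truth.true_status[code] = kind
            truth.true_vbp[code] = None
        elif u < config.failure_probability + config.external_cea_probability:
            record.external_cea_vbp = target_vbp
            record.evidence = EndpointEvidence(endpoint_name=evidence.endpoint_name)
            record.costs.delta_healthcare_cost = None
            truth.true_status[code] = DeviceStatus.EXTERNAL_CEA
            truth.true_vbp[code] = target_vbp
        else:
            truth.true_status[code] = DeviceStatus.COMPUTED
            truth.true_vbp[code] = target_vbp
        records.append(record)

    cohort = Cohort(records=records, label=f"synthetic-seed{config.seed}")
    cohort.validate()
    return cohort, truth


def tuscany_like_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """Preset emulating the 17-device regional cohort.

    Sized and weighted like the study conditions: 17 devices, a 4/17
    failure probability split 2:1:1 across the failure kinds as observed,
    one external full-CEA device in 17, standard-of-care prices spanning
    roughly 300-22000 EUR/patient, occasional savings of 800-1800
    EUR/patient, and price scatter of 3000 EUR around the printed linear
    relation (slope 0.9653, intercept -552.9477).
    """
    cfg = ScenarioConfig(
        n_devices=17,
        soc_price_range=(300.0, 22_000.0),
        improvement_distribution=("uniform", 0.0, 90.0),
        saving_probability=2.0 / 13.0,
        saving_range=(800.0, 1_800.0),
        failure_probability=4.0 / 17.0,
        failure_kind_weights=(2.0, 1.0, 1.0),
        external_cea_probability=1.0 / 17.0,
        price_noise_sd=3_000.0,
        true_slope=0.9653,
        true_intercept=-552.9477,
        seed=seed,
    )
    cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg
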