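"""Simplified value-based pricing: the equation and the decision algorithm.

The value-based price (VBP) of a new device is anchored on the per-patient
price of the current standard of care (SOC), scaled by the relative
clinical improvement of the new device, and adjusted by the per-patient
health-care cost delta::

    VBP = SOC_price * (1 + improvement_pct / 100) + delta_cost

Improvement is positive when the new device improves the clinical outcome
and negative when it worsens it; the cost delta is positive when the new
device produces a saving. When the benefit is expressed as a QALY gain it
is monetised at a willingness-to-pay threshold (60 000 EUR/QALY by
regional convention) and enters additively — this is the only place a
willingness-to-pay threshold appears in the model.

The decision algorithm classifies each device before pricing it. In order:

1. a published full cost-effectiveness analysis supplies the VBP directly
   (status ``EXTERNAL_CEA``);
2. no adequate comparator -> failure;
3. a claimed benefit that no data allow valuing -> failure;
4. no comparative study and no quantified benefit: with committee-accepted
   supportive evidence the device is priced at the SOC price plus the cost
   delta (the 0%-improvement rule), otherwise -> failure;
5. otherwise the equation applies, a stated improvement percentage taking
   precedence over the rate-derived one (with a logged warning when the
   two disagree).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

from .errors import (
    NoComparatorPriceError,
    RecordValidationError,
    UndefinedImprovementError,
)
from .model import Cohort, DeviceRecord, EndpointDirection

__all__ = [
    "Rounding",
    "PricingConfig",
    "DeviceStatus",
    "VBPResult",
    "CohortResult",
    "relative_improvement",
    "monetise_qaly",
    "aggregate_comparator_price",
    "compute_vbp",
    "evaluate_device",
    "evaluate_cohort",
]

logger = logging.getLogger(__name__)

#: percentage points; stated vs rate-derived improvements differing by more
#: than this trigger a warning (printed values are given to 1 dp).
STATED_IMPROVEMENT_WARN_TOL = 0.1


class Rounding(str, Enum):
    """How the reported VBP is rounded (internals stay at full precision)."""

    NONE = "none"
    NEAREST_EURO = "nearest_euro"
    TWO_DECIMALS = "two_decimals"

    def apply(self, value: float) -> float:
        if self is Rounding.NEAREST_EURO:
            return float(round(value))
        if self is Rounding.TWO_DECIMALS:
            return round(value, 2)
        return value


@dataclass
class PricingConfig:
    """Tunables of the pricing engine.

    ``wtp_threshold`` is the willingness-to-pay per QALY (EUR/QALY) used to
    monetise QALY gains; 60 000 EUR/QALY is the threshold formally
    recognised by the region for innovative devices.
    """

    wtp_threshold: float = 60_000.0
    rounding: Rounding = Rounding.TWO_DECIMALS

    def __post_init__(self) -> None:
        if not self.wtp_threshold > 0:
            raise ValueError(f"wtp_threshold must be positive, got {self.wtp_threshold}")
        self.rounding = Rounding(self.rounding)


class DeviceStatus(str, Enum):
    """Outcome of the decision algorithm for one device."""

    COMPUTED = "computed"
    EXTERNAL_CEA = "external_cea"
    FAILED_NO_COMPARATIVE_DATA = "failed_no_comparative_data"
    FAILED_NO_COMPARATOR = "failed_no_comparator"
    FAILED_UNVALUABLE_BENEFIT = "failed_unvaluable_benefit"

    @property
    def priced(self) -> bool:
        return self in (DeviceStatus.COMPUTED, DeviceStatus.EXTERNAL_CEA)


#: the three failure statuses, in a stable order (used by the generator).
FAILURE_STATUSES = (
    DeviceStatus.FAILED_NO_COMPARATIVE_DATA,
    DeviceStatus.FAILED_NO_COMPARATOR,
    DeviceStatus.FAILED_UNVALUABLE_BENEFIT,
)


@dataclass
class VBPResult:
    """Per-device outcome: status, the VBP (EUR/patient) and its components.

    ``vbp`` is present exactly when the status is priced (``COMPUTED`` or
    ``EXTERNAL_CEA``); ``monetised_benefit`` is the euro value of a QALY
    gain (absent when the benefit entered as a percentage)."""

    code: str
    status: DeviceStatus
    vbp: float | None = None
    soc_price_used: float | None = None
    improvement_pct_used: float | None = None
    delta_cost_used: float | None = None
    monetised_benefit: float | None = None
    notes: str = ""


@dataclass
class CohortResult:
    """Cohort-level tally of the decision algorithm."""

    results: list[VBPResult] = field(default_factory=list)
    n_total: int = 0
    n_computed: int = 0
    n_failed: int = 0
    failure_rate_pct: float = 0.0

    @classmethod
    def from_results(cls, results: list[VBPResult]) -> "CohortResult":
        n_total = len(results)
        n_computed = sum(1 for r in results if r.status.priced)
        n_failed = n_total - n_computed
        rate = 100.0 * n_failed / n_total if n_total else 0.0
        return cls(results=results, n_total=n_total, n_computed=n_computed,
                   n_failed=n_failed, failure_rate_pct=rate)

    def by_code(self) -> dict[str, VBPResult]:
        return {r.code: r for r in self.results}


def relative_improvement(rate_new: float, rate_comparator: float,
                         direction: EndpointDirection) -> float:
    """Percent relative improvement of the new device over the comparator.

    For a higher-is-better endpoint this is the relative increase
    ``100 * (rate_new - rate_comparator) / rate_comparator``; for a
    lower-is-better endpoint the relative reduction
    ``100 * (rate_comparator - rate_new) / rate_comparator``. Either way
    the sign is positive when the new device improves the outcome and
    negative when it worsens it.

    Raises
    ------
    UndefinedImprovementError
        If ``rate_comparator`` is zero (a stated improvement percentage
        must be supplied instead).
    """
    for label, rate in (("rate_new", rate_new), ("rate_comparator", rate_comparator)):
        if not (0.0 <= rate <= 100.0):
            raise RecordValidationError(f"{label}={rate} outside [0, 100]")
    if rate_comparator == 0:
        raise UndefinedImprovementError(
            "relative improvement undefined for a zero comparator rate; "
            "supply stated_improvement_pct instead"
        )
    direction = EndpointDirection(direction)
    if direction is EndpointDirection.HIGHER_BETTER:
        return 100.0 * (rate_new - rate_comparator) / rate_comparator
    return 100.0 * (rate_comparator - rate_new) / rate_comparator


def monetise_qaly(qaly_gain: float, config: PricingConfig | None = None) -> float:
    """Euro value of a per-patient QALY gain at the willingness-to-pay threshold."""
    config = config or PricingConfig()
    if not math.isfinite(qaly_gain):
        raise RecordValidationError(f"qaly_gain must be finite, got {qaly_gain}")
    return qaly_gain * config.wtp_threshold


def aggregate_comparator_price(prices: list[float],
                               override: float | None = None) -> float:
    """SOC price for the equation: the override if stated, else the mean.

    Several alternative comparators may each have a per-patient price; the
    simplified model uses their arithmetic mean unless the committee
    worksheet documents the exact value used.
    """
    if override is not None:
        return override
    if not prices:
        raise NoComparatorPriceError("no comparator price available (empty list, no override)")
    return sum(prices) / len(prices)


def compute_vbp(soc_price: float, improvement_pct: float, delta_cost: float,
                additive_benefit: float = 0.0) -> float:
    """Evaluate the pricing equation at full precision.

    ``additive_benefit`` is the monetised QALY term (0 when the benefit is
    expressed as a percentage). The result may legitimately fall below the
    manufacturer's asked price; no floor is applied.
    """
    if soc_price < 0:
        raise RecordValidationError(f"soc_price={soc_price} is negative")
    return soc_price * (1.0 + improvement_pct / 100.0) + delta_cost + additive_benefit


def _benefit_claimed(record: DeviceRecord) -> bool:
    ev = record.evidence
    return bool(ev.endpoint_name) or ev.rate_new is not None \
        or ev.stated_improvement_pct is not None or ev.qaly_gain is not None


def evaluate_device(record: DeviceRecord,
                    config: PricingConfig | None = None) -> VBPResult:
    """Run the decision algorithm and, where possible, price one device.

    Returns exactly one of the five statuses (see module docstring for the
    branch order). Raises :class:`RecordValidationError` for records that
    violate domain invariants (e.g. endpoint rates together with a QALY
    gain).
    """
    config = config or PricingConfig()
    record.validate()
    ev, costs = record.evidence, record.costs

    # 1. an external full cost-effectiveness analysis takes precedence
    if record.external_cea_vbp is not None:
        logger.info("device %s: VBP taken from published full economic analysis", record.code)
        return VBPResult(code=record.code, status=DeviceStatus.EXTERNAL_CEA,
                         vbp=config.rounding.apply(record.external_cea_vbp),
                         notes="VBP from published full cost-effectiveness analysis")

    # 2. data-availability failures come before any computation
    if not record.has_adequate_comparator:
        logger.info("device %s: failed, no adequate comparator", record.code)
        return VBPResult(code=record.code, status=DeviceStatus.FAILED_NO_COMPARATOR,
                         notes="no adequate comparator identified")

    # 3. a claimed benefit that no data allow valuing
    if _benefit_claimed(record) and not record.benefit_valuable:
        logger.info("device %s: failed, benefit cannot be valued", record.code)
        return VBPResult(code=record.code, status=DeviceStatus.FAILED_UNVALUABLE_BENEFIT,
                         notes="no data allow valuing the claimed benefit")

    delta_cost = costs.stated_delta_cost_override
    if delta_cost is None:
        delta_cost = costs.delta_healthcare_cost
    if delta_cost is None:
        delta_cost = 0.0

    # 4. no comparative study and no quantified benefit
    no_quantified = (ev.stated_improvement_pct is None and ev.qaly_gain is None
                     and ev.rate_new is None)
    if not ev.has_comparative_study and no_quantified:
        if not record.supportive_evidence:
            logger.info("device %s: failed, no comparative data", record.code)
            return VBPResult(code=record.code,
                             status=DeviceStatus.FAILED_NO_COMPARATIVE_DATA,
                             notes="no comparative study and no supportive evidence")
        # 0%-improvement rule: purchasable at the SOC price plus the cost delta
        soc = aggregate_comparator_price(costs.comparator_prices,
                                         costs.stated_comparator_price_override)
        vbp = compute_vbp(soc, 0.0, delta_cost)
        logger.info("device %s: 0%%-improvement rule, VBP=%.2f", record.code, vbp)
        return VBPResult(code=record.code, status=DeviceStatus.COMPUTED,
                         vbp=config.rounding.apply(vbp), soc_price_used=soc,
                         improvement_pct_used=0.0, delta_cost_used=delta_cost,
                         notes="0%-improvement rule (supportive evidence only)")

    # 5. the equation proper
    soc = aggregate_comparator_price(costs.comparator_prices,
                                     costs.stated_comparator_price_override)
    notes: list[str] = []
    monetised: float | None = None
    if ev.qaly_gain is not None:
        monetised = monetise_qaly(ev.qaly_gain, config)
        improvement = ev.stated_improvement_pct if ev.stated_improvement_pct is not None else 0.0
        notes.append(f"QALY gain {ev.qaly_gain:g} monetised at "
                     f"{config.wtp_threshold:g} EUR/QALY")
    elif ev.stated_improvement_pct is not None:
        improvement = ev.stated_improvement_pct
        if ev.rate_new is not None and ev.rate_comparator is not None \
                and ev.rate_comparator > 0:
            derived = relative_improvement(ev.rate_new, ev.rate_comparator, ev.direction)
            if abs(derived - improvement) > STATED_IMPROVEMENT_WARN_TOL:
                msg = (f"stated improvement {improvement:g}% differs from rate-derived "
                       f"{derived:.1f}%; stated value used")
                logger.warning("device %s: %s", record.code, msg)
                notes.append(msg)
    elif ev.rate_new is not None:
        improvement = relative_improvement(ev.rate_new, ev.rate_comparator, ev.direction)
    else:
        # a comparative study exists but quantifies no usable benefit
        improvement = 0.0
        notes.append("comparative study without a quantified improvement; 0% used")

    vbp = compute_vbp(soc, improvement, delta_cost, monetised or 0.0)
    logger.info("device %s: computed VBP=%.2f (SOC=%.2f, improvement=%.2f%%, "
                "delta=%.2f, monetised=%.2f)", record.code, vbp, soc, improvement,
                delta_cost, monetised or 0.0)
    return VBPResult(code=record.code, status=DeviceStatus.COMPUTED,
                     vbp=config.rounding.apply(vbp), soc_price_used=soc,
                     improvement_pct_used=improvement, delta_cost_used=delta_cost,
                     monetised_benefit=monetised, notes="; ".join(notes))


def evaluate_cohort(cohort: Cohort,
                    config: PricingConfig | None = None) -> CohortResult:
    """Evaluate every device in input order and tally successes/failures."""
    config = config or PricingConfig()
    cohort.validate()
    results = []
    for record in cohort.records:
        try:
            results.append(evaluate_device(record, config))
        except RecordValidationError as exc:
            raise RecordValidationError(f"device {record.code}: {exc}") from exc
    return CohortResult.from_results(results)
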