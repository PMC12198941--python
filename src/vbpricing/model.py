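"""Domain model for device cohorts: record types, validation, and CSV I/O.

A cohort is a table with one row per high-tech medical device. Each row
carries the three ingredients of the simplified value-based price (VBP):
the per-patient price of the standard of care (SOC), the relative clinical
improvement of the new device over the SOC (as endpoint rates, a stated
percentage, or a QALY gain), and the per-patient health-care cost delta.
Evidence-availability flags feed the failure branches of the decision
algorithm.

CSV dialect is fixed: UTF-8, comma separator, dot decimal mark, mandatory
header. An empty cell means "not available" and is distinct from an
explicit 0, which means a measured zero; the decision algorithm treats the
two differently.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .errors import (
    EmptyCohortError,
    ParseError,
    RecordValidationError,
    SchemaError,
)

__all__ = [
    "EndpointDirection",
    "EndpointEvidence",
    "CostProfile",
    "DeviceRecord",
    "Cohort",
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "write_results",
    "read_results",
    "fixture_path",
    "load_tuscany17",
]


class EndpointDirection(str, Enum):
    """Whether larger endpoint rates are clinically better or worse."""

    HIGHER_BETTER = "higher_better"
    LOWER_BETTER = "lower_better"


@dataclass
class EndpointEvidence:
    """Clinical-benefit evidence for one device.

    Exactly one of three representations drives pricing: a pair of endpoint
    rates (new vs comparator, percentages), a pre-stated percent
    improvement, or a QALY gain per patient. Rates may accompany a stated
    percentage (the stated value takes precedence, with a warning when they
    disagree), but a QALY gain is exclusive of both.
    """

    endpoint_name: str = ""
    direction: EndpointDirection | None = None
    rate_new: float | None = None
    rate_comparator: float | None = None
    stated_improvement_pct: float | None = None
    qaly_gain: float | None = None
    has_comparative_study: bool = False

    def validate(self) -> None:
        if (self.rate_new is None) != (self.rate_comparator is None):
            raise RecordValidationError(
                "endpoint rates must be given as a pair (rate_new with rate_comparator)"
            )
        for label, rate in (("rate_new", self.rate_new),
                            ("rate_comparator", self.rate_comparator)):
            if rate is not None and not (0.0 <= rate <= 100.0):
                raise RecordValidationError(f"{label}={rate} outside [0, 100]")
        if self.rate_new is not None and self.direction is None:
            raise RecordValidationError(
                "endpoint_direction is required when endpoint rates are given"
            )
        if self.rate_new is not None and not self.has_comparative_study:
            raise RecordValidationError(
                "endpoint rates imply a comparative study but has_comparative_study is 0"
            )
        if self.qaly_gain is not None:
            if self.rate_new is not None or self.stated_improvement_pct is not None:
                raise RecordValidationError(
                    "qaly_gain is exclusive: remove endpoint rates / stated improvement"
                )
            if not math.isfinite(self.qaly_gain):
                raise RecordValidationError("qaly_gain must be finite")


@dataclass
class CostProfile:
    """Per-patient prices and the health-care cost delta for one device.

    ``delta_healthcare_cost`` uses the model's sign convention: positive
    when the new device produces a saving, negative when it adds cost.
    Overrides, when present, take precedence over the aggregated values
    (they mirror committee worksheets that document the exact number used).
    """

    device_price: float = 0.0
    comparator_prices: list[float] = field(default_factory=list)
    delta_healthcare_cost: float | None = None
    stated_comparator_price_override: float | None = None
    stated_delta_cost_override: float | None = None

    def validate(self) -> None:
        if self.device_price < 0:
            raise RecordValidationError(f"device_price={self.device_price} is negative")
        for p in self.comparator_prices:
            if p < 0:
                raise RecordValidationError(f"comparator price {p} is negative")
        if (self.stated_comparator_price_override is not None
                and self.stated_comparator_price_override < 0):
            raise RecordValidationError("comparator price override is negative")


@dataclass
class DeviceRecord:
    """One device: identity, evidence, costs, and evidence-availability flags.

    ``benefit_valuable`` is False when no data allow putting a value on the
    claimed benefit; ``supportive_evidence`` records the committee judgment
    that non-comparative evidence supports the device, enabling the
    0%-improvement pricing rule; ``external_cea_vbp`` carries a VBP from a
    published full cost-effectiveness analysis, which takes precedence over
    the simplified model.
    """

    code: str
    name: str = ""
    evidence: EndpointEvidence = field(default_factory=EndpointEvidence)
    costs: CostProfile = field(default_factory=CostProfile)
    has_adequate_comparator: bool = True
    benefit_valuable: bool = True
    supportive_evidence: bool = False
    external_cea_vbp: float | None = None
    procurement_approved: bool = True

    def validate(self) -> None:
        if not self.code:
            raise RecordValidationError("device code must be non-empty")
        self.evidence.validate()
        self.costs.validate()


@dataclass
class Cohort:
    """An ordered, code-unique collection of device records."""

    records: list[DeviceRecord] = field(default_factory=list)
    label: str = ""

    def validate(self) -> None:
        if not self.records:
            raise EmptyCohortError(f"empty cohort {self.label!r}")
        seen: dict[str, int] = {}
        for rec in self.records:
            seen[rec.code] = seen.get(rec.code, 0) + 1
        dupes = sorted(code for code, k in seen.items() if k > 1)
        if dupes:
            raise RecordValidationError(f"duplicate device codes: {', '.join(dupes)}")
        for rec in self.records:
            try:
                rec.validate()
            except RecordValidationError as exc:
                raise RecordValidationError(f"device {rec.code}: {exc}") from exc

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


# Documented input schema, in column order. `supportive_evidence` is optional
# (absent column => False for every device); all others are mandatory.
COHORT_COLUMNS = [
    "code",
    "name",
    "device_price_eur",
    "comparator_name",
    "comparator_prices_eur",
    "comparator_price_override_eur",
    "endpoint_name",
    "endpoint_direction",
    "rate_new_pct",
    "rate_comparator_pct",
    "stated_improvement_pct",
    "qaly_gain",
    "delta_cost_eur",
    "delta_cost_override_eur",
    "has_comparative_study",
    "has_adequate_comparator",
    "benefit_valuable",
    "external_cea_vbp_eur",
    "procurement_approved",
]
OPTIONAL_COLUMNS = ["supportive_evidence"]


def _blank(cell: object) -> bool:
    return cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == ""


def _opt_float(cell: object, column: str, row: int) -> float | None:
    if _blank(cell):
        return None
    try:
        return float(str(cell).strip())
    except ValueError:
        raise ParseError(f"non-numeric value {cell!r} in column {column!r}", row=row) from None


def _req_float(cell: object, column: str, row: int) -> float:
    value = _opt_float(cell, column, row)
    if value is None:
        raise ParseError(f"missing mandatory value in column {column!r}", row=row)
    return value


def _flag(cell: object, column: str, row: int, default: bool | None = None) -> bool:
    if _blank(cell):
        if default is None:
            raise ParseError(f"missing 0/1 flag in column {column!r}", row=row)
        return default
    text = str(cell).strip()
    if text not in {"0", "1"}:
        raise ParseError(f"flag column {column!r} must be 0 or 1, got {text!r}", row=row)
    return text == "1"


def _price_list(cell: object, column: str, row: int) -> list[float]:
    if _blank(cell):
        return []
    parts = [p for p in str(cell).split(";") if p.strip() != ""]
    return [_req_float(p, column, row) for p in parts]


def _record_from_row(row: pd.Series, rownum: int) -> DeviceRecord:
    direction_cell = row.get("endpoint_direction")
    if _blank(direction_cell):
        direction = None
    else:
        text = str(direction_cell).strip()
        try:
            direction = EndpointDirection(text)
        except ValueError:
            raise ParseError(
                f"endpoint_direction must be 'higher_better' or 'lower_better', got {text!r}",
                row=rownum,
            ) from None

    evidence = EndpointEvidence(
        endpoint_name="" if _blank(row.get("endpoint_name")) else str(row["endpoint_name"]).strip(),
        direction=direction,
        rate_new=_opt_float(row.get("rate_new_pct"), "rate_new_pct", rownum),
        rate_comparator=_opt_float(row.get("rate_comparator_pct"), "rate_comparator_pct", rownum),
        stated_improvement_pct=_opt_float(
            row.get("stated_improvement_pct"), "stated_improvement_pct", rownum),
        qaly_gain=_opt_float(row.get("qaly_gain"), "qaly_gain", rownum),
        has_comparative_study=_flag(
            row.get("has_comparative_study"), "has_comparative_study", rownum),
    )
    costs = CostProfile(
        device_price=_req_float(row.get("device_price_eur"), "device_price_eur", rownum),
        comparator_prices=_price_list(
            row.get("comparator_prices_eur"), "comparator_prices_eur", rownum),
        delta_healthcare_cost=_opt_float(row.get("delta_cost_eur"), "delta_cost_eur", rownum),
        stated_comparator_price_override=_opt_float(
            row.get("comparator_price_override_eur"), "comparator_price_override_eur", rownum),
        stated_delta_cost_override=_opt_float(
            row.get("delta_cost_override_eur"), "delta_cost_override_eur", rownum),
    )
    if _blank(row.get("code")):
        raise ParseError("missing device code", row=rownum)
    return DeviceRecord(
        code=str(row["code"]).strip(),
        name="" if _blank(row.get("name")) else str(row["name"]).strip(),
        evidence=evidence,
        costs=costs,
        has_adequate_comparator=_flag(
            row.get("has_adequate_comparator"), "has_adequate_comparator", rownum),
        benefit_valuable=_flag(row.get("benefit_valuable"), "benefit_valuable", rownum),
        supportive_evidence=_flag(
            row.get("supportive_evidence"), "supportive_evidence", rownum, default=False),
        external_cea_vbp=_opt_float(
            row.get("external_cea_vbp_eur"), "external_cea_vbp_eur", rownum),
        procurement_approved=_flag(
            row.get("procurement_approved"), "procurement_approved", rownum, default=True),
    )


def read_cohort(path: str | Path, delimiter: str = ",") -> Cohort:
    """Read and validate a device cohort from CSV.

    Parameters
    ----------
    path
        CSV file following the documented schema (see ``COHORT_COLUMNS``).
        Lines starting with ``#`` are treated as comments.
    delimiter
        Field separator; the documented dialect uses a comma.

    Returns
    -------
    Cohort
        One validated :class:`DeviceRecord` per data row, in file order.
        Absent cells become absent (None) fields, never zeros.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=delimiter, dtype=str, comment="#",
                        keep_default_na=False, encoding="utf-8")
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    if frame.empty:
        raise EmptyCohortError(f"empty cohort: {path.name} has a header but no device rows")
    records = [_record_from_row(row, rownum) for rownum, (_, row)
               in enumerate(frame.iterrows(), start=1)]
    cohort = Cohort(records=records, label=path.stem)
    cohort.validate()
    return cohort


def _record_to_row(rec: DeviceRecord) -> dict[str, str]:
    def fmt(value: object) -> str:
        if value is None:
            return ""
        if isinstance(value, bool):
            return "1" if value else "0"
        if isinstance(value, float) and value == int(value) and abs(value) < 1e15:
            return str(int(value))
        return str(value)

    ev, co = rec.evidence, rec.costs
    return {
        "code": rec.code,
        "name": rec.name,
        "device_price_eur": fmt(co.device_price),
        "comparator_name": "",
        "comparator_prices_eur": ";".join(fmt(p) for p in co.comparator_prices),
        "comparator_price_override_eur": fmt(co.stated_comparator_price_override),
        "endpoint_name": ev.endpoint_name,
        "endpoint_direction": "" if ev.direction is None else ev.direction.value,
        "rate_new_pct": fmt(ev.rate_new),
        "rate_comparator_pct": fmt(ev.rate_comparator),
        "stated_improvement_pct": fmt(ev.stated_improvement_pct),
        "qaly_gain": fmt(ev.qaly_gain),
        "delta_cost_eur": fmt(co.delta_healthcare_cost),
        "delta_cost_override_eur": fmt(co.stated_delta_cost_override),
        "has_comparative_study": fmt(ev.has_comparative_study),
        "has_adequate_comparator": fmt(rec.has_adequate_comparator),
        "benefit_valuable": fmt(rec.benefit_valuable),
        "external_cea_vbp_eur": fmt(rec.external_cea_vbp),
        "procurement_approved": fmt(rec.procurement_approved),
        "supportive_evidence": fmt(rec.supportive_evidence),
    }


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Serialise a cohort to the documented CSV schema (UTF-8, comma)."""
    frame = pd.DataFrame([_record_to_row(rec) for rec in cohort.records],
                         columns=COHORT_COLUMNS + OPTIONAL_COLUMNS)
    frame.to_csv(path, index=False, encoding="utf-8")


RESULT_COLUMNS = [
    "code", "status", "vbp_eur", "soc_price_used_eur", "improvement_pct_used",
    "delta_cost_used_eur", "monetised_benefit_eur", "notes",
]


def write_results(cohort_result, path: str | Path) -> None:
    """Write evaluation results: a per-device CSV plus a JSON summary sidecar.

    The CSV has one row per device (code, status, VBP and its components,
    rounded to euro cents); the sidecar ``<path stem>.json`` carries cohort
    counts and the failure rate.
    """
    path = Path(path)

    def fmt(value: float | None) -> str:
        return "" if value is None else f"{value:.2f}"

    rows = [{
        "code": res.code,
        "status": res.status.value,
        "vbp_eur": fmt(res.vbp),
        "soc_price_used_eur": fmt(res.soc_price_used),
        "improvement_pct_used": (
            "" if res.improvement_pct_used is None else f"{res.improvement_pct_used:g}"),
        "delta_cost_used_eur": fmt(res.delta_cost_used),
        "monetised_benefit_eur": fmt(res.monetised_benefit),
        "notes": res.notes,
    } for res in cohort_result.results]
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, index=False, encoding="utf-8")

    sidecar = {
        "n_total": cohort_result.n_total,
        "n_computed": cohort_result.n_computed,
        "n_failed": cohort_result.n_failed,
        "failure_rate_pct": cohort_result.failure_rate_pct,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2), encoding="utf-8")


def read_results(path: str | Path):
    """Re-read a results CSV written by :func:`write_results`."""
    from .engine import CohortResult, DeviceStatus, VBPResult  # avoid import cycle

    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"results file missing column(s): {', '.join(missing)}")
    results = []
    for rownum, (_, row) in enumerate(frame.iterrows(), start=1):
        results.append(VBPResult(
            code=str(row["code"]).strip(),
            status=DeviceStatus(str(row["status"]).strip()),
            vbp=_opt_float(row["vbp_eur"], "vbp_eur", rownum),
            soc_price_used=_opt_float(row["soc_price_used_eur"], "soc_price_used_eur", rownum),
            improvement_pct_used=_opt_float(
                row["improvement_pct_used"], "improvement_pct_used", rownum),
            delta_cost_used=_opt_float(row["delta_cost_used_eur"], "delta_cost_used_eur", rownum),
            monetised_benefit=_opt_float(
                row["monetised_benefit_eur"], "monetised_benefit_eur", rownum),
            notes=str(row["notes"]),
        ))
    return CohortResult.from_results(results)


def fixture_path() -> Path:
    """Path to the bundled 17-device Tuscany cohort fixture."""
    return Path(importlib.resources.files("vbpricing") / "data" / "tuscany17.csv")


def load_tuscany17() -> Cohort:
    """Load the bundled 17-device cohort (Tuscany, first semester 2024)."""
    return read_cohort(fixture_path())


def record_as_dict(rec: DeviceRecord) -> dict:
    """Flat dict view of a record (for reports and debugging)."""
    return dataclasses.asdict(rec)
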