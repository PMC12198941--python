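"""End-to-end pipeline and human/machine-readable run reports.

``run_full_pipeline`` executes read -> evaluate -> concordance and collects
everything a committee-facing report needs: the per-device table, the
cohort tally, the concordance summary (skipped with a warning when fewer
than three devices were priced), and the warnings raised along the way.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .concordance import analyse_concordance, pair_for_concordance
from .engine import CohortResult, PricingConfig, Rounding, evaluate_cohort
from .errors import InputError, InsufficientDataError
from .model import Cohort, read_cohort

__all__ = ["RunReport", "load_config", "run_full_pipeline", "build_report"]

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Structured summary of one full pipeline run."""

    cohort_label: str
    config: dict
    devices: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)
    concordance: dict | None = None
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "cohort_label": self.cohort_label,
            "config": self.config,
            "devices": self.devices,
            "summary": self.summary,
            "concordance": self.concordance,
            "warnings": self.warnings,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2), encoding="utf-8")

    def render_text(self) -> str:
        lines = [f"Cohort: {self.cohort_label}", ""]
        header = f"{'code':>6}  {'name':<44}  {'real price':>10}  {'status':<26}  {'VBP':>10}"
        lines += [header, "-" * len(header)]
        for dev in self.devices:
            vbp = "" if dev["vbp_eur"] is None else f"{dev['vbp_eur']:.2f}"
            lines.append(f"{dev['code']:>6}  {dev['name'][:44]:<44}  "
                         f"{dev['real_price_eur']:>10.2f}  {dev['status']:<26}  {vbp:>10}")
        s = self.summary
        lines += ["", f"Priced {s['n_computed']}/{s['n_total']} devices "
                      f"({s['n_failed']} failures, {s['failure_rate_pct']:.1f}% failure rate)"]
        if self.concordance:
            c = self.concordance
            lines += [f"Concordance over n={c['n']} priced devices: r={c['r']:.3f} "
                      f"({c['ci_level']:.0%} CI {c['ci_low']:.4f} to {c['ci_high']:.4f}, "
                      f"p={c['p_value']:.2e}); VBP = {c['slope']:.4f} x real price "
                      f"{c['intercept']:+.4f}"]
        for warning in self.warnings:
            lines.append(f"WARNING: {warning}")
        return "\n".join(lines) + "\n"


def load_config(path: str | Path | None) -> tuple[PricingConfig, float]:
    """Read a pricing config from JSON or key=value lines.

    Recognised keys: ``wtp_threshold_eur_per_qaly``, ``rounding``
    (none | nearest_euro | two_decimals), ``ci_level``. Returns the
    pricing config plus the confidence level for the concordance stage.
    """
    if path is None:
        return PricingConfig(), 0.95
    text = Path(path).read_text(encoding="utf-8")
    try:
        raw = json.loads(text)
    except json.JSONDecodeError:
        raw = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise InputError(f"config line is neither JSON nor key=value: {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            raw[key] = value
    known = {"wtp_threshold_eur_per_qaly", "rounding", "ci_level"}
    unknown = set(raw) - known
    if unknown:
        raise InputError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    try:
        config = PricingConfig(
            wtp_threshold=float(raw.get("wtp_threshold_eur_per_qaly", 60_000)),
            rounding=Rounding(raw.get("rounding", Rounding.TWO_DECIMALS)),
        )
        ci_level = float(raw.get("ci_level", 0.95))
    except ValueError as exc:
        raise InputError(f"invalid config value: {exc}") from exc
    if not 0 < ci_level < 1:
        raise InputError(f"ci_level must be in (0, 1), got {ci_level}")
    return config, ci_level


def build_report(cohort: Cohort, cohort_result: CohortResult, config: PricingConfig,
                 ci_level: float = 0.95) -> RunReport:
    """Assemble a :class:`RunReport` from an evaluated cohort."""
    by_code = {rec.code: rec for rec in cohort.records}
    devices = []
    warnings = []
    for res in cohort_result.results:
        rec = by_code[res.code]
        devices.append({
            "code": res.code,
            "name": rec.name,
            "real_price_eur": rec.costs.device_price,
            "status": res.status.value,
            "vbp_eur": res.vbp,
            "soc_price_used_eur": res.soc_price_used,
            "improvement_pct_used": res.improvement_pct_used,
            "delta_cost_used_eur": res.delta_cost_used,
            "monetised_benefit_eur": res.monetised_benefit,
            "notes": res.notes,
        })
        if "differs" in res.notes:
            warnings.append(f"device {res.code}: {res.notes}")

    concordance = None
    try:
        pairs = pair_for_concordance(cohort_result, cohort)
        concordance = analyse_concordance(pairs, level=ci_level).as_dict()
    except InsufficientDataError as exc:
        warnings.append(f"concordance: skipped ({exc})")
        logger.warning("concordance skipped: %s", exc)

    return RunReport(
        cohort_label=cohort.label,
        config={"wtp_threshold_eur_per_qaly": config.wtp_threshold,
                "rounding": config.rounding.value, "ci_level": ci_level},
        devices=devices,
        summary={"n_total": cohort_result.n_total,
                 "n_computed": cohort_result.n_computed,
                 "n_failed": cohort_result.n_failed,
                 "failure_rate_pct": cohort_result.failure_rate_pct},
        concordance=concordance,
        warnings=warnings,
    )


def run_full_pipeline(cohort_path: str | Path,
                      config_path: str | Path | None = None) -> RunReport:
    """Read a cohort CSV, evaluate every device, and analyse concordance."""
    config, ci_level = load_config(config_path)
    cohort = read_cohort(cohort_path)
    cohort_result = evaluate_cohort(cohort, config)
    return build_report(cohort, cohort_result, config, ci_level)
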