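"""Pricing equation, its helper operations, and the decision algorithm."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vbpricing import (
    Cohort,
    CostProfile,
    DeviceRecord,
    DeviceStatus,
    EndpointDirection,
    EndpointEvidence,
    PricingConfig,
    Rounding,
    aggregate_comparator_price,
    compute_vbp,
    evaluate_cohort,
    evaluate_device,
    monetise_qaly,
    relative_improvement,
)
from vbpricing.errors import (
    NoComparatorPriceError,
    RecordValidationError,
    UndefinedImprovementError,
)

NO_ROUND = PricingConfig(rounding=Rounding.NONE)


@pytest.mark.parametrize(
    ("rate_new", "rate_comp", "direction", "expected"),
    [
        (1.5, 6.8, EndpointDirection.LOWER_BETTER, 77.9),
        (91.4, 85.2, EndpointDirection.HIGHER_BETTER, 7.3),
        (17.0, 63.9, EndpointDirection.LOWER_BETTER, 73.4),
        (42.0, 42.0, EndpointDirection.HIGHER_BETTER, 0.0),
        (42.0, 42.0, EndpointDirection.LOWER_BETTER, 0.0),
    ],
)
def test_relative_improvement_matches_published_rows(rate_new, rate_comp, direction, expected):
    assert relative_improvement(rate_new, rate_comp, direction) == pytest.approx(expected, abs=0.05)


def test_relative_improvement_sign_flips_with_direction():
    # the new device does worse on a higher-is-better endpoint
    assert relative_improvement(40.0, 50.0, EndpointDirection.HIGHER_BETTER) == pytest.approx(-20.0)
    assert relative_improvement(40.0, 50.0, EndpointDirection.LOWER_BETTER) == pytest.approx(20.0)


def test_relative_improvement_undefined_for_zero_comparator_rate():
    with pytest.raises(UndefinedImprovementError):
        relative_improvement(10.0, 0.0, EndpointDirection.HIGHER_BETTER)


@pytest.mark.parametrize(
    ("qaly", "threshold", "expected"),
    [(0.05, 60_000.0, 3000.0), (0.0, 60_000.0, 0.0), (0.1908, 60_000.0, 11_448.0)],
)
def test_monetise_qaly_is_the_wtp_product(qaly, threshold, expected):
    config = PricingConfig(wtp_threshold=threshold)
    assert monetise_qaly(qaly, config) == pytest.approx(expected)


@pytest.mark.parametrize(
    ("prices", "override", "expected"),
    [([3090.0, 4090.0], None, 3590.0), ([777.0], None, 777.0), ([850.0, 1301.0], 1075.0, 1075.0)],
)
def test_comparator_price_aggregation_and_override(prices, override, expected):
    assert aggregate_comparator_price(prices, override) == pytest.approx(expected)


def test_no_comparator_price_at_all_is_an_error():
    with pytest.raises(NoComparatorPriceError):
        aggregate_comparator_price([], None)


@pytest.mark.parametrize(
    ("soc", "imp", "delta", "benefit", "expected"),
    [
        (6000.0, 77.9, 0.0, 0.0, 10_674.0),
        (1234.5, 0.0, 0.0, 0.0, 1234.5),
        (3590.0, 0.0, 1075.0, 0.0, 4665.0),
        (0.0, 0.0, 0.0, 3000.0, 3000.0),
        (809.0, 73.4, 0.0, 0.0, 1402.806),
    ],
)
def test_vbp_equation(soc, imp, delta, benefit, expected):
    assert compute_vbp(soc, imp, delta, benefit) == pytest.approx(expected)


def _record(**kwargs) -> DeviceRecord:
    base = dict(
        code="X1",
        evidence=EndpointEvidence(endpoint_name="e", direction=EndpointDirection.HIGHER_BETTER,
                                  rate_new=60.0, rate_comparator=50.0,
                                  has_comparative_study=True),
        costs=CostProfile(device_price=1000.0, comparator_prices=[800.0]),
    )
    base.update(kwargs)
    return DeviceRecord(**base)


class TestDecisionAlgorithm:
    def test_external_cea_takes_precedence(self):
        res = evaluate_device(_record(external_cea_vbp=8475.0), NO_ROUND)
        assert res.status is DeviceStatus.EXTERNAL_CEA
        assert res.vbp == 8475.0

    def test_missing_comparator_fails(self):
        res = evaluate_device(_record(has_adequate_comparator=False), NO_ROUND)
        assert res.status is DeviceStatus.FAILED_NO_COMPARATOR
        assert res.vbp is None

    def test_unvaluable_benefit_fails(self):
        res = evaluate_device(_record(benefit_valuable=False), NO_ROUND)
        assert res.status is DeviceStatus.FAILED_UNVALUABLE_BENEFIT

    def test_no_comparative_data_without_support_fails(self):
        rec = _record(evidence=EndpointEvidence(endpoint_name="e"),
                      supportive_evidence=False)
        res = evaluate_device(rec, NO_ROUND)
        assert res.status is DeviceStatus.FAILED_NO_COMPARATIVE_DATA

    def test_supportive_evidence_prices_at_soc_plus_delta(self):
        rec = _record(evidence=EndpointEvidence(endpoint_name="e"),
                      costs=CostProfile(device_price=950.0, comparator_prices=[472.5]),
                      supportive_evidence=True)
        res = evaluate_device(rec, NO_ROUND)
        assert res.status is DeviceStatus.COMPUTED
        assert res.vbp == pytest.approx(472.5)
        assert res.improvement_pct_used == 0.0

    def test_rate_derived_pricing(self):
        res = evaluate_device(_record(), NO_ROUND)
        assert res.status is DeviceStatus.COMPUTED
        # 800 * (1 + 20%) with no cost delta
        assert res.vbp == pytest.approx(960.0)

    def test_stated_improvement_overrides_rates_with_note(self):
        ev = EndpointEvidence(endpoint_name="e", direction=EndpointDirection.HIGHER_BETTER,
                              rate_new=82.0, rate_comparator=53.0,
                              stated_improvement_pct=57.6, has_comparative_study=True)
        res = evaluate_device(_record(evidence=ev,
                                      costs=CostProfile(device_price=1575.0,
                                                        comparator_prices=[1351.0])), NO_ROUND)
        assert res.vbp == pytest.approx(1351.0 * 1.576)
        assert "differs" in res.notes

    def test_qaly_gain_with_zero_priced_comparator(self):
        ev = EndpointEvidence(endpoint_name="QALYs", qaly_gain=0.05,
                              has_comparative_study=True)
        rec = _record(evidence=ev, costs=CostProfile(device_price=6350.0,
                                                     comparator_prices=[0.0]))
        res = evaluate_device(rec, NO_ROUND)
        assert res.status is DeviceStatus.COMPUTED
        assert res.monetised_benefit == pytest.approx(3000.0)
        assert res.vbp == pytest.approx(3000.0)

    def test_inconsistent_record_raises(self):
        ev = EndpointEvidence(direction=EndpointDirection.HIGHER_BETTER,
                              rate_new=60.0, rate_comparator=50.0, qaly_gain=0.1,
                              has_comparative_study=True)
        with pytest.raises(RecordValidationError):
            evaluate_device(_record(evidence=ev), NO_ROUND)


# --- properties -----------------------------------------------------------

prices = st.floats(min_value=0.0, max_value=1e6, allow_nan=False)
improvements = st.floats(min_value=-99.0, max_value=500.0, allow_nan=False)
deltas = st.floats(min_value=-1e5, max_value=1e5, allow_nan=False)


@given(soc=prices)
@settings(max_examples=200, derandomize=True)
def test_identity_no_improvement_no_delta(soc):
    assert compute_vbp(soc, 0.0, 0.0, 0.0) == soc


@given(soc=st.floats(min_value=1e-3, max_value=1e6), imp=improvements,
       bump=st.floats(min_value=1e-3, max_value=100.0))
@settings(max_examples=200, derandomize=True)
def test_vbp_monotone_in_improvement(soc, imp, bump):
    assert compute_vbp(soc, imp + bump, 0.0) > compute_vbp(soc, imp, 0.0)


@given(soc=prices, imp=improvements, delta=deltas,
       bump=st.floats(min_value=1e-3, max_value=1e5))
@settings(max_examples=200, derandomize=True)
def test_vbp_monotone_in_delta_and_benefit(soc, imp, delta, bump):
    base = compute_vbp(soc, imp, delta, 0.0)
    assert compute_vbp(soc, imp, delta + bump, 0.0) > base
    assert compute_vbp(soc, imp, delta, bump) > base


@given(soc=st.floats(min_value=1e-3, max_value=1e6),
       imp=st.floats(min_value=-99.0, max_value=-0.01))
@settings(max_examples=200, derandomize=True)
def test_worsened_endpoint_prices_below_soc(soc, imp):
    assert compute_vbp(soc, imp, 0.0) < soc


@st.composite
def device_records(draw):
    """Syntactically valid records spanning every decision branch."""
    has_study = draw(st.booleans())
    kind = draw(st.sampled_from(["rates", "stated", "qaly", "none"]))
    rate_comp = draw(st.floats(min_value=0.5, max_value=100.0))
    evidence = EndpointEvidence(
        endpoint_name=draw(st.sampled_from(["", "endpoint"])),
        direction=draw(st.sampled_from(list(EndpointDirection))),
        rate_new=draw(st.floats(min_value=0.0, max_value=100.0))
        if kind == "rates" and has_study else None,
        rate_comparator=rate_comp if kind == "rates" and has_study else None,
        stated_improvement_pct=draw(st.floats(min_value=-50.0, max_value=200.0))
        if kind == "stated" else None,
        qaly_gain=draw(st.floats(min_value=0.0, max_value=1.0)) if kind == "qaly" else None,
        has_comparative_study=has_study,
    )
    n_comp = draw(st.integers(min_value=0, max_value=3))
    costs = CostProfile(
        device_price=draw(st.floats(min_value=0.0, max_value=50_000.0)),
        comparator_prices=[draw(st.floats(min_value=0.0, max_value=50_000.0))
                           for _ in range(n_comp)],
        delta_healthcare_cost=draw(st.one_of(
            st.none(), st.floats(min_value=-5000.0, max_value=5000.0))),
        stated_comparator_price_override=draw(st.one_of(
            st.none(), st.floats(min_value=0.0, max_value=50_000.0))),
    )
    return DeviceRecord(
        code=draw(st.text(alphabet="0123456789", min_size=1, max_size=4)),
        evidence=evidence,
        costs=costs,
        has_adequate_comparator=draw(st.booleans()),
        benefit_valuable=draw(st.booleans()),
        supportive_evidence=draw(st.booleans()),
        external_cea_vbp=draw(st.one_of(st.none(),
                                        st.floats(min_value=0.0, max_value=50_000.0))),
    )


@given(record=device_records())
@settings(max_examples=300, derandomize=True)
def test_every_valid_record_gets_exactly_one_status(record):
    """The algorithm is exhaustive: one of five statuses, VBP iff priced."""
    try:
        res = evaluate_device(record, NO_ROUND)
    except (NoComparatorPriceError, UndefinedImprovementError):
        return  # refused for a stated, specific reason — not a misclassification
    assert res.status in DeviceStatus
    assert (res.vbp is not None) == res.status.priced


@given(records=st.lists(device_records(), min_size=1, max_size=12, unique_by=lambda r: r.code))
@settings(max_examples=100, derandomize=True, deadline=None)
def test_cohort_counts_are_conserved(records):
    for rec in records:
        # guarantee a comparator price so evaluation cannot be refused
        if not rec.costs.comparator_prices and rec.costs.stated_comparator_price_override is None:
            rec.costs.comparator_prices = [100.0]
        if rec.evidence.rate_comparator == 0:
            rec.evidence.rate_comparator = 1.0
    result = evaluate_cohort(Cohort(records=records), NO_ROUND)
    assert result.n_total == result.n_computed + result.n_failed == len(records)
    assert result.failure_rate_pct == pytest.approx(100.0 * result.n_failed / result.n_total)


def test_single_priced_device_has_zero_failure_rate():
    result = evaluate_cohort(Cohort(records=[_record()]), NO_ROUND)
    assert result.failure_rate_pct == 0.0
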