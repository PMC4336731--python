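"""Two-test cascade routing and the closed-form effectiveness estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stentstrat as ss
from stentstrat.effectiveness import ConditionalEstimates, conditional_adverse_estimates
from stentstrat.trees import ConfusionMatrix

probs = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


# ---------------------------------------------------------------------------
# Routing
# ---------------------------------------------------------------------------


def test_suggestion_routing(trained_cascade, catalog):
    cascade, _, test = trained_cascade
    suggestions = ss.suggest_treatments(test, cascade, catalog)
    assert len(suggestions) == len(test)
    for s in suggestions:
        assert s.suggestion in ("sBMS", "sDES", "sCABG")
        if s.fallback:
            assert s.suggestion == "sDES"
        else:
            # routing invariant: sBMS iff P_R < theta_R; sDES iff second test negative
            if s.p_r < s.theta_r:
                assert s.suggestion == "sBMS"
            elif s.p_h is not None and s.p_h < s.theta_h:
                assert s.suggestion == "sDES"
            else:
                assert s.suggestion == "sCABG"


def test_single_record_routing_matches_thresholds(trained_cascade, catalog):
    cascade, _, test = trained_cascade
    records = ss.frame_to_cohort(test.iloc[:5], catalog)
    batch = ss.suggest_treatments(test.iloc[:5], cascade, catalog)
    for record, expected in zip(records, batch):
        got = ss.suggest_treatment(record, cascade, catalog)
        assert got.suggestion == expected.suggestion


def test_unscoreable_record_defaults_to_sdes(trained_cascade, catalog):
    cascade, _, test = trained_cascade
    record = ss.frame_to_cohort(test.iloc[:1], catalog)[0]
    record.clinical = {k: None for k in record.clinical}
    record.biomarkers = {k: None for k in record.biomarkers}
    out = ss.suggest_treatment(record, cascade, catalog)
    assert out.suggestion == "sDES"
    assert out.fallback


# ---------------------------------------------------------------------------
# Closed-form estimators
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "prev,sens,spec,expected",
    [
        (0.0, 0.3, 1.0, 1.0),
        (1.0, 1.0, 0.2, 0.0),
        # 40-record toy population: 10 events (2 below threshold), 30 non-events
        # (18 below): negatives = 20/40
        (0.25, 0.8, 0.6, 0.5),
    ],
)
def test_est_p_sbms(prev, sens, spec, expected):
    assert ss.est_p_sbms(prev, sens, spec) == pytest.approx(expected)


def test_est_p_sbms_rejects_out_of_range():
    with pytest.raises(ValueError):
        ss.est_p_sbms(1.2, 0.5, 0.5)


def test_est_p_sdes_hand_arithmetic():
    assert ss.est_p_sdes(1.0, 0.2, 0.7, 0.5) == 0.0
    assert ss.est_p_sdes(0.0, 0.0, 0.5, 1.0) == pytest.approx(1.0)
    assert ss.est_p_sdes(0.5, 0.2, 0.75, 0.5) == pytest.approx(0.225)


def test_est_p_scabg_complement():
    assert ss.est_p_scabg(0.2, 0.7) == pytest.approx(0.1)
    assert ss.est_p_scabg(1.0, 0.0) == pytest.approx(0.0)
    assert ss.est_p_scabg(0.097, 0.818) == pytest.approx(0.085)
    with pytest.raises(ValueError):
        ss.est_p_scabg(0.8, 0.4)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(prev=probs, sens=probs, spec=probs, prev_h=probs, sens_h=probs, spec_h=probs)
def test_treatment_probabilities_sum_to_one(prev, sens, spec, prev_h, sens_h, spec_h):
    p_bms = ss.est_p_sbms(prev, sens, spec)
    p_des = ss.est_p_sdes(p_bms, prev_h, sens_h, spec_h)
    p_cabg = ss.est_p_scabg(p_bms, p_des)
    assert 0 <= p_bms <= 1 and 0 <= p_des <= 1 and 0 <= p_cabg <= 1
    assert p_bms + p_des + p_cabg == pytest.approx(1.0, abs=1e-12)


def test_est_p_sbms_monotonicity():
    base = ss.est_p_sbms(0.3, 0.7, 0.6)
    assert ss.est_p_sbms(0.3, 0.7, 0.7) > base  # increasing in spec
    assert ss.est_p_sbms(0.3, 0.8, 0.6) < base  # decreasing in sens (prev > 0)


def test_formula_probabilities_match_counted_fractions(trained_cascade, catalog):
    """Computed on the same evaluation set, the closed-form P(sBMS) and
    P(sDES) must equal the directly counted negative-prediction fractions."""
    cascade, _, test = trained_cascade
    ev = ss.evaluate_cascade(test, cascade, catalog=catalog)
    assert ev.proposed.p_sbms == pytest.approx(ev.counted_frac_r_negative, abs=1e-12)
    assert ev.proposed.p_sdes == pytest.approx(
        (1 - ev.counted_frac_r_negative) * ev.counted_frac_h_negative, abs=1e-12
    )


# ---------------------------------------------------------------------------
# Conditionals and totals
# ---------------------------------------------------------------------------


def test_conditionals_from_confusion_and_counts():
    cm_r = ConfusionMatrix(tp=5, fp=5, fn=0, tn=40)  # NPV = 1
    cm_h = ConfusionMatrix(tp=4, fp=2, fn=2, tn=22)  # NPV = 22/24
    cond = conditional_adverse_estimates(cm_r, cm_h, np.array([0, 0, 0, 0]), np.array([1] + [0] * 9))
    assert cond.p_rest_sbms == pytest.approx(0.0)  # NPV 1 -> zero restenosis
    assert cond.p_haz_sdes == pytest.approx(1 - 22 / 24)
    assert cond.p_haz_sbms == pytest.approx(0.0)
    assert cond.p_rest_sdes == pytest.approx(0.1)  # 1 event among 10 suggested sDES


def test_empty_denominator_is_flagged_not_raised():
    cm = ConfusionMatrix(tp=5, fp=5, fn=1, tn=40)
    cond = conditional_adverse_estimates(cm, cm, np.array([]), np.array([0, 1]))
    assert math.isnan(cond.p_haz_sbms)
    assert "P(Hazard|sBMS)" in cond.undefined


def test_total_adverse_weighted_sums():
    cond = ConditionalEstimates(p_rest_sbms=0.1, p_haz_sdes=0.0, p_haz_sbms=0.0, p_rest_sdes=0.2)
    est = ss.total_adverse(0.5, 0.5, 0.0, cond)
    assert est.p_restenosis == pytest.approx(0.15)
    assert est.p_hazard == pytest.approx(0.0)
    assert est.p_adverse == est.p_restenosis + est.p_hazard
    zero = ss.total_adverse(0.5, 0.5, 0.0, ConditionalEstimates(0, 0, 0, 0))
    assert zero.p_adverse == 0.0


def test_total_adverse_uses_literature_cabg_constants():
    cond = ConditionalEstimates(p_rest_sbms=0.0, p_haz_sdes=0.0, p_haz_sbms=0.0, p_rest_sdes=0.0)
    est = ss.total_adverse(0.0, 0.0, 1.0, cond)
    assert est.p_hazard == pytest.approx(0.0856)
    assert est.p_restenosis == pytest.approx(0.019)


def test_total_adverse_rejects_undefined_conditional_with_weight():
    cond = ConditionalEstimates(p_rest_sbms=math.nan, p_haz_sdes=0.0, p_haz_sbms=0.0, p_rest_sdes=0.0, undefined=["P(Restenosis|sBMS)"])
    with pytest.raises(ValueError):
        ss.total_adverse(0.5, 0.5, 0.0, cond)
    # zero weight on the undefined arm is fine
    est = ss.total_adverse(0.0, 1.0, 0.0, cond)
    assert est.p_adverse == 0.0


# ---------------------------------------------------------------------------
# Baseline
# ---------------------------------------------------------------------------


def test_baseline_no_grey_zone_equals_pure_des():
    constants = ss.LiteratureConstants(lambda_grey=0.0)
    est = ss.baseline_effectiveness(0.08, 0.05, 0.5, constants)
    assert est.p_restenosis == pytest.approx(0.08)
    assert est.p_hazard == pytest.approx(0.05)


def test_baseline_grey_zone_weighting():
    # omega = 0.21 * 0.5 = 0.105
    constants = ss.LiteratureConstants()
    est = ss.baseline_effectiveness(0.08, 0.05, 0.5, constants)
    omega = 0.21 * 0.5
    assert est.p_scabg == pytest.approx(omega / 2)
    expected_rest = (1 - omega) * 0.08 + 0.5 * omega * (0.08 + 0.019)
    assert est.p_restenosis == pytest.approx(expected_rest)


def test_baseline_hand_arithmetic():
    constants = ss.LiteratureConstants(lambda_grey=0.2)
    est = ss.baseline_effectiveness(0.08, 0.0, 1.0, constants)  # omega = 0.2
    assert est.p_restenosis == pytest.approx(0.8 * 0.08 + 0.1 * (0.08 + 0.019))
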