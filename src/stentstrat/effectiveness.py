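"""Treatment suggestion by the two-test cascade and closed-form estimators of
treatment probabilities, adverse-effect rates, and the baseline workflow.

The cascade first applies the restenosis test T_R: a negative result
(P_R < theta_R) suggests a bare-metal stent (sBMS). Otherwise the hazard test
T_H is applied: a negative result suggests a drug-eluting stent (sDES), a
positive one bypass surgery (sCABG). Treatment probabilities follow from the
tests' sensitivity/specificity and the arm prevalences, assuming the two
tests are independent (restenosis and stent thrombosis have different
pathophysiologies and are treated as competing, independent risks).

Estimates carry a provenance: "hat" quantities derive from classifier
performance, "tilde" quantities are counted directly from follow-up labels
or taken from literature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import FeatureCatalog
from .cohort import EVENT, PatientRecord, cohort_to_frame
from .logistic import roc_auc
from .trees import ClassifierPerformance, ConfusionMatrix, FittedCascade, confusion_at_threshold

logger = logging.getLogger(__name__)

SUGGESTIONS = ("sBMS", "sDES", "sCABG")


@dataclass(frozen=True)
class LiteratureConstants:
    """Adverse-effect rates under CABG (from surgical literature) and the
    grey-zone fraction lambda of 3-vessel-disease patients with low lesion
    complexity, for whom stenting and surgery perform comparably."""

    p_hazard_scabg: float = 0.0856
    p_restenosis_scabg: float = 0.019
    lambda_grey: float = 0.21

    def __post_init__(self) -> None:
        for name in ("p_hazard_scabg", "p_restenosis_scabg", "lambda_grey"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class TreatmentSuggestion:
    record_id: str
    suggestion: str  # "sBMS" | "sDES" | "sCABG"
    p_r: float | None
    theta_r: float | None
    p_h: float | None = None
    theta_h: float | None = None
    fallback: bool = False  # record unscoreable; defaulted to sDES


@dataclass
class EffectivenessEstimates:
    p_sbms: float
    p_sdes: float
    p_scabg: float
    p_rest_given: dict[str, float] = field(default_factory=dict)
    p_haz_given: dict[str, float] = field(default_factory=dict)
    p_restenosis: float = math.nan
    p_hazard: float = math.nan
    p_adverse: float = math.nan
    provenance: dict[str, str] = field(default_factory=dict)  # "hat" | "tilde" | "literature"
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "P(sBMS)": self.p_sbms,
            "P(sDES)": self.p_sdes,
            "P(sCABG)": self.p_scabg,
            "P(Restenosis|sBMS)": self.p_rest_given.get("sBMS", math.nan),
            "P(Restenosis|sDES)": self.p_rest_given.get("sDES", math.nan),
            "P(Hazard|sBMS)": self.p_haz_given.get("sBMS", math.nan),
            "P(Hazard|sDES)": self.p_haz_given.get("sDES", math.nan),
            "P(Restenosis)": self.p_restenosis,
            "P(Hazard)": self.p_hazard,
            "P(Adverse)": self.p_adverse,
        }


# ---------------------------------------------------------------------------
# Suggestion
# ---------------------------------------------------------------------------


def suggest_treatment(
    record: PatientRecord, cascade: FittedCascade, catalog: FeatureCatalog | None = None
) -> TreatmentSuggestion:
    """Route one record through the cascade.

    An unscoreable record (missing features for its leaf's models) is flagged
    and routed to sDES — the workflow's default treatment — with a warning.
    """
    catalog = catalog or FeatureCatalog.default()
    frame = cohort_to_frame([record], catalog)
    res = suggest_treatments(frame, cascade, catalog)
    return res[0]


def suggest_treatments(
    cohort, cascade: FittedCascade, catalog: FeatureCatalog | None = None
) -> list[TreatmentSuggestion]:
    """Vectorized routing of a whole cohort through the cascade."""
    catalog = catalog or FeatureCatalog.default()
    frame = cohort_to_frame(cohort, catalog)
    n = len(frame)
    suggestion = np.array(["sDES"] * n, dtype=object)
    p_r = np.full(n, np.nan)
    p_h = np.full(n, np.nan)
    th_r = np.full(n, np.nan)
    th_h = np.full(n, np.nan)
    fallback = np.zeros(n, dtype=bool)
    for leaf in cascade.tree.leaves:
        pair = cascade.leaf_pairs[leaf]
        mask = leaf.mask(frame)
        if not mask.any():
            continue
        sub = frame[mask]
        idx = np.flatnonzero(mask)
        th_r[idx] = pair.test_r.threshold
        th_h[idx] = pair.test_h.threshold
        ok_r = pair.test_r.model.scoreable_mask(sub)
        ok_h = pair.test_h.model.scoreable_mask(sub)
        scores_r = np.full(len(sub), np.nan)
        scores_h = np.full(len(sub), np.nan)
        if ok_r.any():
            scores_r[ok_r] = pair.test_r.model.predict_frame(sub[ok_r])
        if ok_h.any():
            scores_h[ok_h] = pair.test_h.model.predict_frame(sub[ok_h])
        p_r[idx] = scores_r
        p_h[idx] = scores_h
        neg_r = ok_r & (scores_r < pair.test_r.threshold)
        pos_r = ok_r & ~neg_r
        suggestion[idx[neg_r]] = "sBMS"
        # positive first test: second test decides between sDES and sCABG
        pos_and_ok = pos_r & ok_h
        suggestion[idx[pos_and_ok & (scores_h >= pair.test_h.threshold)]] = "sCABG"
        suggestion[idx[pos_and_ok & (scores_h < pair.test_h.threshold)]] = "sDES"
        bad = ~ok_r | (pos_r & ~ok_h)
        if bad.any():
            fallback[idx[bad]] = True
            suggestion[idx[~ok_r]] = "sDES"
            suggestion[idx[pos_r & ~ok_h]] = "sDES"
            logger.warning(
                "%d unscoreable record(s) in leaf %s routed to sDES", int(bad.sum()), leaf.label
            )
    ids = frame["record_id"].astype(str).to_numpy()
    return [
        TreatmentSuggestion(
            record_id=ids[i],
            suggestion=suggestion[i],
            p_r=None if math.isnan(p_r[i]) else float(p_r[i]),
            theta_r=None if math.isnan(th_r[i]) else float(th_r[i]),
            p_h=None if math.isnan(p_h[i]) else float(p_h[i]),
            theta_h=None if math.isnan(th_h[i]) else float(th_h[i]),
            fallback=bool(fallback[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Closed-form treatment-probability estimators
# ---------------------------------------------------------------------------


def _check_prob(name: str, value: float) -> None:
    if not 0 <= value <= 1:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def est_p_sbms(prev: float, sens: float, spec: float) -> float:
    """P(first test negative) = prev*(1 - sens) + (1 - prev)*spec."""
    for nm, v in (("prev", prev), ("sens", sens), ("spec", spec)):
        _check_prob(nm, v)
    return prev * (1 - sens) + (1 - prev) * spec


def est_p_sdes(p_sbms: float, prev_h: float, sens_h: float, spec_h: float) -> float:
    """P(first positive, second negative) under test independence."""
    for nm, v in (("p_sbms", p_sbms), ("prev_h", prev_h), ("sens_h", sens_h), ("spec_h", spec_h)):
        _check_prob(nm, v)
    return (1 - p_sbms) * (prev_h * (1 - sens_h) + (1 - prev_h) * spec_h)


def est_p_scabg(p_sbms: float, p_sdes: float) -> float:
    """Probability of the remaining treatment: 1 - P(sBMS) - P(sDES)."""
    _check_prob("p_sbms", p_sbms)
    _check_prob("p_sdes", p_sdes)
    if p_sbms + p_sdes > 1 + 1e-12:
        raise ValueError("p_sbms + p_sdes must not exceed 1")
    return 1 - p_sbms - p_sdes


# ---------------------------------------------------------------------------
# Conditional adverse-effect estimates and totals
# ---------------------------------------------------------------------------


@dataclass
class ConditionalEstimates:
    """The four data-driven conditionals feeding the adverse-effect totals."""

    p_rest_sbms: float  # hat: 1 - NPV(T_R)
    p_haz_sdes: float  # hat: 1 - NPV(T_H)
    p_haz_sbms: float  # tilde: counted hazard rate among T_R-negative records
    p_rest_sdes: float  # tilde: counted restenosis rate among sDES-suggested records
    undefined: list[str] = field(default_factory=list)


def conditional_adverse_estimates(
    perf_r: ClassifierPerformance | ConfusionMatrix,
    perf_h: ClassifierPerformance | ConfusionMatrix,
    haz_labels_sbms: np.ndarray | None,
    rest_labels_sdes: np.ndarray | None,
) -> ConditionalEstimates:
    """Combine performance-based ("hat") and counted ("tilde") conditionals.

    ``haz_labels_sbms``: binary hazard labels of records the restenosis test
    classified negative; ``rest_labels_sdes``: binary restenosis labels of
    records the cascade suggested sDES for. Empty label sets yield a flagged
    NaN instead of an error.
    """
    npv_r = perf_r.npv
    npv_h = perf_h.npv
    undefined = []
    if math.isnan(npv_r):
        undefined.append("P(Restenosis|sBMS)")
    if math.isnan(npv_h):
        undefined.append("P(Hazard|sDES)")

    def _rate(labels, name):
        if labels is None or len(labels) == 0:
            undefined.append(name)
            return math.nan
        return float(np.mean(labels))

    return ConditionalEstimates(
        p_rest_sbms=1 - npv_r,
        p_haz_sdes=1 - npv_h,
        p_haz_sbms=_rate(haz_labels_sbms, "P(Hazard|sBMS)"),
        p_rest_sdes=_rate(rest_labels_sdes, "P(Restenosis|sDES)"),
        undefined=undefined,
    )


def total_adverse(
    p_sbms: float,
    p_sdes: float,
    p_scabg: float,
    conditionals: ConditionalEstimates,
    constants: LiteratureConstants = LiteratureConstants(),
) -> EffectivenessEstimates:
    """Adverse-effect decomposition: probability-weighted sums over the three
    suggested treatments, with CABG conditionals from literature constants.

    Raises if a conditional is undefined but carries nonzero weight.
    """
    weights = {"sBMS": p_sbms, "sDES": p_sdes, "sCABG": p_scabg}
    rest = {
        "sBMS": conditionals.p_rest_sbms,
        "sDES": conditionals.p_rest_sdes,
        "sCABG": constants.p_restenosis_scabg,
    }
    haz = {
        "sBMS": conditionals.p_haz_sbms,
        "sDES": conditionals.p_haz_sdes,
        "sCABG": constants.p_hazard_scabg,
    }
    for t in SUGGESTIONS:
        if weights[t] > 0 and (math.isnan(rest[t]) or math.isnan(haz[t])):
            raise ValueError(f"undefined conditional for {t} with nonzero weight {weights[t]}")
    p_restenosis = sum(weights[t] * rest[t] for t in SUGGESTIONS if weights[t] > 0)
    p_hazard = sum(weights[t] * haz[t] for t in SUGGESTIONS if weights[t] > 0)
    return EffectivenessEstimates(
        p_sbms=p_sbms,
        p_sdes=p_sdes,
        p_scabg=p_scabg,
        p_rest_given=rest,
        p_haz_given=haz,
        p_restenosis=p_restenosis,
        p_hazard=p_hazard,
        p_adverse=p_restenosis + p_hazard,
        provenance={
            "P(Restenosis|sBMS)": "hat",
            "P(Hazard|sDES)": "hat",
            "P(Hazard|sBMS)": "tilde",
            "P(Restenosis|sDES)": "tilde",
            "P(.|sCABG)": "literature",
        },
        undefined=list(conditionals.undefined),
    )


def baseline_effectiveness(
    p_rest_des: float,
    p_haz_des: float,
    three_vessel_rate: float,
    constants: LiteratureConstants = LiteratureConstants(),
) -> EffectivenessEstimates:
    """The predominant-DES baseline: everyone gets DES except the grey zone
    omega = lambda * P(3-vessel disease), which is split half DES / half CABG.

    ``p_rest_des`` and ``p_haz_des`` are empirical DES-arm rates counted from
    follow-up (tilde provenance).
    """
    for nm, v in (("p_rest_des", p_rest_des), ("p_haz_des", p_haz_des), ("three_vessel_rate", three_vessel_rate)):
        _check_prob(nm, v)
    omega = constants.lambda_grey * three_vessel_rate
    p_rest = (1 - omega) * p_rest_des + 0.5 * omega * (p_rest_des + constants.p_restenosis_scabg)
    p_haz = (1 - omega) * p_haz_des + 0.5 * omega * (p_haz_des + constants.p_hazard_scabg)
    return EffectivenessEstimates(
        p_sbms=0.0,
        p_sdes=1 - 0.5 * omega,
        p_scabg=0.5 * omega,
        p_rest_given={"sDES": p_rest_des, "sCABG": constants.p_restenosis_scabg},
        p_haz_given={"sDES": p_haz_des, "sCABG": constants.p_hazard_scabg},
        p_restenosis=p_rest,
        p_hazard=p_haz,
        p_adverse=p_rest + p_haz,
        provenance={"P(Restenosis|sDES)": "tilde", "P(Hazard|sDES)": "tilde", "P(.|sCABG)": "literature"},
    )


# ---------------------------------------------------------------------------
# Evaluation of a fitted cascade on a held-out population
# ---------------------------------------------------------------------------


@dataclass
class CascadeEvaluation:
    """Everything measured when applying a fitted cascade to an evaluation set."""

    confusion_r: ConfusionMatrix
    confusion_h: ConfusionMatrix
    prevalence_r: float
    prevalence_h: float
    proposed: EffectivenessEstimates
    baseline: EffectivenessEstimates
    auc_r: float
    auc_h: float
    counted_frac_r_negative: float
    counted_frac_h_negative: float
    n_scored_r: int
    n_scored_h: int
    scores_r: np.ndarray | None = None
    labels_r: np.ndarray | None = None
    scores_h: np.ndarray | None = None
    labels_h: np.ndarray | None = None


def _scored_arm(frame, cascade, endpoint, which, catalog):
    """Scores, thresholds-applied predictions and labels for one test over
    its treatment arm in the evaluation population."""
    arm = "BMS" if which == "r" else "DES"
    mask = (frame["treatment"] == arm).to_numpy() & frame[endpoint].notna().to_numpy()
    scores, preds, labels, other = [], [], [], []
    other_ep = cascade.endpoint_pair[1] if which == "r" else cascade.endpoint_pair[0]
    for leaf in cascade.tree.leaves:
        pair = cascade.leaf_pairs[leaf]
        test = pair.test_r if which == "r" else pair.test_h
        m = mask & leaf.mask(frame)
        if not m.any():
            continue
        sub = frame[m]
        ok = test.model.scoreable_mask(sub)
        if not ok.any():
            continue
        sub = sub[ok]
        s = test.model.predict_frame(sub)
        scores.append(s)
        preds.append(s >= test.threshold)
        labels.append((sub[endpoint] == EVENT).to_numpy().astype(int))
        oth = sub[other_ep]
        other.append(np.where(oth.notna(), (oth == EVENT).astype(float), np.nan))
    if not scores:
        return (np.zeros(0),) * 4
    return (
        np.concatenate(scores),
        np.concatenate(preds),
        np.concatenate(labels),
        np.concatenate(other),
    )


def evaluate_cascade(
    cohort,
    cascade: FittedCascade,
    constants: LiteratureConstants = LiteratureConstants(),
    catalog: FeatureCatalog | None = None,
    keep_scores: bool = False,
) -> CascadeEvaluation:
    """Apply a fitted cascade to an evaluation population and compute the full
    effectiveness report: test performances, treatment probabilities (both by
    formula and by direct counting), conditionals, totals, and the baseline.
    """
    catalog = catalog or FeatureCatalog.default()
    frame = cohort_to_frame(cohort, catalog)
    rest_ep, haz_ep = cascade.endpoint_pair

    scores_r, preds_r, labels_r, haz_of_r = _scored_arm(frame, cascade, rest_ep, "r", catalog)
    scores_h, preds_h, labels_h, rest_of_h = _scored_arm(frame, cascade, haz_ep, "h", catalog)
    cm_r = ConfusionMatrix(
        tp=int(np.sum(preds_r & (labels_r == 1))),
        fp=int(np.sum(preds_r & (labels_r == 0))),
        fn=int(np.sum(~preds_r & (labels_r == 1))),
        tn=int(np.sum(~preds_r & (labels_r == 0))),
    )
    cm_h = ConfusionMatrix(
        tp=int(np.sum(preds_h & (labels_h == 1))),
        fp=int(np.sum(preds_h & (labels_h == 0))),
        fn=int(np.sum(~preds_h & (labels_h == 1))),
        tn=int(np.sum(~preds_h & (labels_h == 0))),
    )
    prev_r, prev_h = cm_r.prevalence, cm_h.prevalence
    p_sbms = est_p_sbms(prev_r, cm_r.sens, cm_r.spec) if cm_r.total else math.nan
    p_sdes = est_p_sdes(p_sbms, prev_h, cm_h.sens, cm_h.spec) if cm_h.total else math.nan
    p_scabg = est_p_scabg(p_sbms, p_sdes)

    # tilde conditionals: labels of the complementary endpoint along each route
    haz_sbms = haz_of_r[~preds_r]
    haz_sbms = haz_sbms[~np.isnan(haz_sbms)]
    rest_sdes = rest_of_h[~preds_h]
    rest_sdes = rest_sdes[~np.isnan(rest_sdes)]
    conditionals = conditional_adverse_estimates(cm_r, cm_h, haz_sbms, rest_sdes)
    proposed = total_adverse(p_sbms, p_sdes, p_scabg, conditionals, constants)

    # baseline from the evaluation DES arm, counted directly from follow-up
    des = frame[(frame["treatment"] == "DES")]
    rest_lab = des[rest_ep].dropna()
    haz_lab = des[haz_ep].dropna()
    p_rest_des = float((rest_lab == EVENT).mean()) if len(rest_lab) else math.nan
    p_haz_des = float((haz_lab == EVENT).mean()) if len(haz_lab) else math.nan
    tv = frame["three_vessel"].dropna()
    three_vessel_rate = float((tv == "yes").mean()) if len(tv) else 0.0
    baseline = baseline_effectiveness(p_rest_des, p_haz_des, three_vessel_rate, constants)

    def _auc(s, l):
        if len(s) == 0 or len(np.unique(l)) < 2:
            return math.nan
        return roc_auc(s, l)

    return CascadeEvaluation(
        confusion_r=cm_r,
        confusion_h=cm_h,
        prevalence_r=prev_r,
        prevalence_h=prev_h,
        proposed=proposed,
        baseline=baseline,
        auc_r=_auc(scores_r, labels_r),
        auc_h=_auc(scores_h, labels_h),
        counted_frac_r_negative=float(np.mean(~preds_r)) if cm_r.total else math.nan,
        counted_frac_h_negative=float(np.mean(~preds_h)) if cm_h.total else math.nan,
        n_scored_r=cm_r.total,
        n_scored_h=cm_h.total,
        scores_r=scores_r if keep_scores else None,
        labels_r=labels_r if keep_scores else None,
        scores_h=scores_h if keep_scores else None,
        labels_h=labels_h if keep_scores else None,
    )
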