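"""Repeated k-fold cross-validation of the full pipeline, percentile
confidence intervals, and comparison of the proposed workflow against the
predominant-DES baseline.

Each repetition draws a fresh random k-fold split, stratified by endpoint
label within treatment arm so small subgroups keep both classes in every
fold. All training decisions — leaf fitting, feature/operating-point
selection, tree selection — use the training folds only; evaluation pools
held-out per-record predictions across folds within a repetition
(micro-pooling) before performance, effectiveness and costs are computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import FeatureCatalog
from .cohort import ENDPOINTS, EVENT, cohort_to_frame
from .costs import CostEstimates, CostTable, cost_report
from .effectiveness import (
    CascadeEvaluation,
    EffectivenessEstimates,
    LiteratureConstants,
    baseline_effectiveness,
    conditional_adverse_estimates,
    est_p_sbms,
    est_p_scabg,
    est_p_sdes,
    total_adverse,
)
from .logistic import DEFAULT_PENALTY, roc_auc
from .trees import ConfusionMatrix, train_cascade

logger = logging.getLogger(__name__)

ENDPOINT_PAIRS = (
    ("angio_restenosis_6m", "hazard_1y"),
    ("angio_restenosis_6m", "hazard_3y"),
    ("clin_restenosis_1y", "hazard_1y"),
    ("clin_restenosis_3y", "hazard_3y"),
)


@dataclass
class AnalysisConfig:
    endpoint_pair: tuple[str, str] = ("angio_restenosis_6m", "hazard_1y")
    k: int = 10
    repetitions: int = 10  # 300 for CI-quality runs; 10 is the test-scale default
    seed: int = 0
    penalty: float = DEFAULT_PENALTY
    global_mode: bool = False
    constants: LiteratureConstants = field(default_factory=LiteratureConstants)
    cost_table: CostTable | None = None
    min_samples: int = 100
    min_positives: int = 10

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be at least 1")
        if self.endpoint_pair not in ENDPOINT_PAIRS:
            raise ValueError(f"endpoint pair must be one of {ENDPOINT_PAIRS}")


@dataclass
class CVResult:
    per_repetition: list[dict]
    summary: dict  # metric -> {"median": ..., "ci": (lo, hi)}
    config: AnalysisConfig


def percentile_ci(values: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Empirical percentile interval (linear-interpolation convention)."""
    values = np.asarray(list(values), dtype=float)
    if len(values) < 2:
        raise ValueError("at least two values are required for a percentile CI")
    alpha = 100 * (1 - level) / 2
    lo, hi = np.percentile(values, [alpha, 100 - alpha], method="linear")
    return float(lo), float(hi)


def stratified_folds(frame: pd.DataFrame, endpoint_pair: tuple[str, str], k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment stratified by (treatment arm, endpoint labels)."""
    rest_ep, haz_ep = endpoint_pair
    keys = (
        frame["treatment"].astype(str)
        + "|" + frame[rest_ep].astype(str)
        + "|" + frame[haz_ep].astype(str)
    ).to_numpy()
    folds = np.empty(len(frame), dtype=int)
    start = rng.integers(0, k)
    for key in np.unique(keys):
        idx = np.flatnonzero(keys == key)
        rng.shuffle(idx)
        folds[idx] = (np.arange(len(idx)) + start) % k
    return folds


def _pooled_evaluation(
    frame: pd.DataFrame,
    folds: np.ndarray,
    config: AnalysisConfig,
    catalog: FeatureCatalog,
) -> dict:
    """One repetition: train per fold, pool held-out predictions, evaluate."""
    rest_ep, haz_ep = config.endpoint_pair
    pooled = {
        "r": {"scores": [], "preds": [], "labels": [], "other": []},
        "h": {"scores": [], "preds": [], "labels": [], "other": []},
    }
    tree_ids = []
    n_eval_records = 0
    for f in range(config.k):
        train = frame[folds != f]
        test = frame[folds == f]
        n_eval_records += len(test)
        cascade = train_cascade(
            train,
            endpoint_pair=config.endpoint_pair,
            catalog=catalog,
            penalty=config.penalty,
            global_mode=config.global_mode,
            min_samples=config.min_samples,
            min_positives=config.min_positives,
        )
        tree_ids.append(cascade.tree.describe())
        from .effectiveness import _scored_arm  # shared arm-scoring helper

        for which, ep in (("r", rest_ep), ("h", haz_ep)):
            s, p, l, o = _scored_arm(test, cascade, ep, which, catalog)
            pooled[which]["scores"].append(s)
            pooled[which]["preds"].append(p)
            pooled[which]["labels"].append(l)
            pooled[which]["other"].append(o)

    out: dict = {"chosen_trees": tree_ids, "n_eval_records": n_eval_records}
    cms = {}
    for which in ("r", "h"):
        s = np.concatenate(pooled[which]["scores"])
        p = np.concatenate(pooled[which]["preds"]).astype(bool)
        l = np.concatenate(pooled[which]["labels"])
        cms[which] = ConfusionMatrix(
            tp=int(np.sum(p & (l == 1))),
            fp=int(np.sum(p & (l == 0))),
            fn=int(np.sum(~p & (l == 1))),
            tn=int(np.sum(~p & (l == 0))),
        )
        out[f"auc_{which}"] = (
            roc_auc(s, l) if len(s) and len(np.unique(l)) == 2 else math.nan
        )
        out[f"n_scored_{which}"] = len(s)
    cm_r, cm_h = cms["r"], cms["h"]
    preds_r = np.concatenate(pooled["r"]["preds"]).astype(bool)
    preds_h = np.concatenate(pooled["h"]["preds"]).astype(bool)
    haz_of_r = np.concatenate(pooled["r"]["other"])
    rest_of_h = np.concatenate(pooled["h"]["other"])

    p_sbms = est_p_sbms(cm_r.prevalence, cm_r.sens, cm_r.spec)
    p_sdes = est_p_sdes(p_sbms, cm_h.prevalence, cm_h.sens, cm_h.spec)
    p_scabg = est_p_scabg(p_sbms, p_sdes)
    haz_sbms = haz_of_r[~preds_r]
    haz_sbms = haz_sbms[~np.isnan(haz_sbms)]
    rest_sdes = rest_of_h[~preds_h]
    rest_sdes = rest_sdes[~np.isnan(rest_sdes)]
    conditionals = conditional_adverse_estimates(cm_r, cm_h, haz_sbms, rest_sdes)
    try:
        proposed = total_adverse(p_sbms, p_sdes, p_scabg, conditionals, config.constants)
    except ValueError:
        proposed = None

    des = frame[frame["treatment"] == "DES"]
    rest_lab = des[rest_ep].dropna()
    haz_lab = des[haz_ep].dropna()
    tv = frame["three_vessel"].dropna()
    three_vessel_rate = float((tv == "yes").mean()) if len(tv) else 0.0
    baseline = baseline_effectiveness(
        float((rest_lab == EVENT).mean()),
        float((haz_lab == EVENT).mean()),
        three_vessel_rate,
        config.constants,
    )
    out["p_sbms"] = p_sbms
    out["p_sdes"] = p_sdes
    out["p_scabg"] = p_scabg
    out["baseline_adverse"] = baseline.p_adverse
    if proposed is not None:
        out["proposed_adverse"] = proposed.p_adverse
        deltas = compare_workflows(proposed, baseline)
        out["delta_adverse"] = deltas["delta_adverse"]
        out["relative_reduction"] = deltas["relative_reduction"]
        if config.cost_table is not None:
            costs = cost_report(
                proposed, baseline, three_vessel_rate, config.cost_table, config.constants.lambda_grey
            )
            out["total_savings"] = costs.total_savings
            out["savings_pct"] = costs.savings_pct
    return out


def repeated_cv(cohort, config: AnalysisConfig, catalog: FeatureCatalog | None = None) -> CVResult:
    """Repeated k-fold cross-validation of the whole pipeline.

    Deterministic given ``config.seed``. Per-repetition metrics are summarized
    by medians and 95% percentile intervals across repetitions.
    """
    catalog = catalog or FeatureCatalog.default()
    frame = cohort_to_frame(cohort, catalog)
    if len(frame) == 0:
        raise ValueError("cohort is empty")
    rng = np.random.default_rng(config.seed)
    per_rep = []
    for rep in range(config.repetitions):
        folds = stratified_folds(frame, config.endpoint_pair, config.k, rng)
        per_rep.append(_pooled_evaluation(frame, folds, config, catalog))
    summary = {}
    scalar_keys = sorted(
        {
            k
            for rep in per_rep
            for k, v in rep.items()
            if isinstance(v, (int, float)) and not isinstance(v, bool)
        }
    )
    for key in scalar_keys:
        vals = [rep[key] for rep in per_rep if key in rep and not math.isnan(rep[key])]
        if not vals:
            continue
        entry = {"median": float(np.median(vals))}
        if len(vals) >= 2:
            entry["ci"] = percentile_ci(vals)
        summary[key] = entry
    return CVResult(per_repetition=per_rep, summary=summary, config=config)


def summary_table(result: CVResult) -> pd.DataFrame:
    """Report frame (one row per estimated quantity: median, CI bounds)."""
    rows = []
    for key, entry in result.summary.items():
        lo, hi = entry.get("ci", (math.nan, math.nan))
        rows.append({"quantity": key, "median": entry["median"], "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def compare_workflows(proposed: EffectivenessEstimates, baseline: EffectivenessEstimates) -> dict:
    """Deltas between baseline and proposed adverse-effect estimates.

    Relative reduction is flagged undefined (NaN) when the baseline rate is 0.
    """
    delta = baseline.p_adverse - proposed.p_adverse
    if baseline.p_adverse == 0:
        rel = math.nan if delta != 0 else 0.0
    else:
        rel = delta / baseline.p_adverse
    return {
        "delta_adverse": delta,
        "relative_reduction": rel,
        "baseline_adverse": baseline.p_adverse,
        "proposed_adverse": proposed.p_adverse,
    }
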