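"""Subgroup and classification-tree enumeration, operating-point selection,
and aggregation of leaf classifiers into a population-wide cascade.

The cohort is partitioned by binary splits on age (<=60 / >60), sex and
diabetes, each variable used at most once per root-to-leaf path (so trees
have at most four levels). Every distinct partition of the population
induced by such a tree competes; leaves are the 27 possible constraint
triples. At each leaf a pair of ridge-logistic classifiers is selected by an
exhaustive search over feature-set combinations and specificity-indexed
thresholds, maximizing NPV of the restenosis test plus PPV of the hazard
test. Leaf confusion matrices are summed to score whole trees, and the tree
with the best aggregated objective wins.

Sign convention: a *positive* prediction is score >= threshold (high risk);
a negative prediction routes the patient to the less aggressive treatment.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import BIOMARKER_OPTIONS, CLINICAL_OPTIONS, NONE_SET, FeatureCatalog
from .cohort import (
    ENDPOINTS,
    CohortIndex,
    EligibleSample,
    SubgroupSpec,
    cohort_to_frame,
    filter_eligible,
)
from .logistic import DEFAULT_PENALTY, LogisticModel, ScoreSet, fit_l2_logistic

logger = logging.getLogger(__name__)

SPLIT_VARIABLES = ("age", "sex", "diabetes")

_SPLIT_LEVELS = {
    "age": ("LE60", "GT60"),
    "sex": ("FEMALE", "MALE"),
    "diabetes": ("NO", "YES"),
}

#: Specificity grid for operating-point selection: 5% to 95% in 5% steps
#: (19 levels; the trivial 0% and 100% operating points are excluded).
SPECIFICITY_GRID = tuple(p / 100 for p in range(5, 100, 5))

#: Preference order used in tie-breaking on set indices (no-feature first).
_SET_INDEX = {NONE_SET: 0, "C1": 1, "C2": 2, "C3": 3, "B1": 1, "B2": 2, "B3": 3}


def enumerate_subgroups() -> list[SubgroupSpec]:
    """All 27 constraint triples over {unconstrained, level1, level2}^3."""
    return [
        SubgroupSpec(a, s, d)
        for a, s, d in product(("ALL", "LE60", "GT60"), ("ALL", "FEMALE", "MALE"), ("ALL", "NO", "YES"))
    ]


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeNode:
    """Either a leaf (subgroup set) or a binary split on one variable."""

    subgroup: SubgroupSpec | None = None
    var: str | None = None
    low: "TreeNode | None" = None
    high: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.subgroup is not None

    def depth(self) -> int:
        if self.is_leaf:
            return 1
        return 1 + max(self.low.depth(), self.high.depth())


@dataclass(frozen=True)
class ClassificationTreeSpec:
    """A tree whose leaves partition the cohort into subgroups.

    ``root`` may be ``None`` for trees reconstructed from serialized
    cascades; routing and evaluation only need the leaf partition.
    """

    root: TreeNode | None
    leaves: tuple[SubgroupSpec, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def leaf_masks(self, frame: pd.DataFrame) -> dict[SubgroupSpec, np.ndarray]:
        return {leaf: leaf.mask(frame) for leaf in self.leaves}

    def route(self, age: float, sex: str, diabetes: str) -> SubgroupSpec:
        """The unique leaf whose constraints the record satisfies."""
        for leaf in self.leaves:
            if leaf.matches(age, sex, diabetes):
                return leaf
        raise RuntimeError("leaves do not cover the record; tree is malformed")

    def describe(self) -> str:
        return " | ".join(leaf.label for leaf in self.leaves)


def _build_trees(avail: tuple[str, ...], constraints: dict[str, str]) -> Iterable[TreeNode]:
    yield TreeNode(subgroup=SubgroupSpec(**{**{"age": "ALL", "sex": "ALL", "diabetes": "ALL"}, **constraints}))
    for v in avail:
        rest = tuple(x for x in avail if x != v)
        lo_lvl, hi_lvl = _SPLIT_LEVELS[v]
        for low in _build_trees(rest, {**constraints, v: lo_lvl}):
            for high in _build_trees(rest, {**constraints, v: hi_lvl}):
                yield TreeNode(var=v, low=low, high=high)


def _collect_leaves(node: TreeNode) -> tuple[SubgroupSpec, ...]:
    if node.is_leaf:
        return (node.subgroup,)
    return _collect_leaves(node.low) + _collect_leaves(node.high)


def enumerate_trees(variables: Sequence[str] = SPLIT_VARIABLES) -> list[ClassificationTreeSpec]:
    """All classification trees over the split variables, deduplicated by the
    partition their leaves induce; deterministic order (coarse to fine)."""
    seen: dict[frozenset, ClassificationTreeSpec] = {}
    for root in _build_trees(tuple(variables), {}):
        leaves = _collect_leaves(root)
        key = frozenset(leaves)
        if key not in seen:
            seen[key] = ClassificationTreeSpec(root=root, leaves=tuple(sorted(leaves)))
    return sorted(seen.values(), key=lambda t: (t.n_leaves, tuple(l.label for l in t.leaves)))


def single_leaf_tree() -> ClassificationTreeSpec:
    all_spec = SubgroupSpec("ALL", "ALL", "ALL")
    return ClassificationTreeSpec(root=TreeNode(subgroup=all_spec), leaves=(all_spec,))


# ---------------------------------------------------------------------------
# Confusion matrices and performance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sens(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else math.nan

    @property
    def spec(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else math.nan

    @property
    def ppv(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else math.nan

    @property
    def npv(self) -> float:
        d = self.tn + self.fn
        return self.tn / d if d else math.nan

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.total if self.total else math.nan


@dataclass(frozen=True)
class ClassifierPerformance:
    sens: float
    spec: float
    ppv: float
    npv: float
    prevalence: float
    n: int

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix) -> "ClassifierPerformance":
        return cls(cm.sens, cm.spec, cm.ppv, cm.npv, cm.prevalence, cm.total)


def confusion_at_threshold(scores: ScoreSet | np.ndarray, threshold: float, labels: np.ndarray | None = None) -> ConfusionMatrix:
    """Tabulate predictions (positive iff score >= threshold) against labels."""
    if isinstance(scores, ScoreSet):
        s, y = scores.scores, scores.labels
    else:
        s, y = np.asarray(scores, float), np.asarray(labels, int)
    pred = s >= threshold
    pos = y == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
    )


def thresholds_at_specificity(
    scores: ScoreSet | np.ndarray,
    labels: np.ndarray | None = None,
    grid: Sequence[float] = SPECIFICITY_GRID,
) -> dict[float, tuple[float, float]]:
    """For each grid level, the smallest threshold whose achieved specificity
    on the given scores is >= that level.

    Returns ``{level: (threshold, achieved_specificity)}``. Requires at least
    one negative sample. Thresholds are non-decreasing in the level.
    """
    if isinstance(scores, ScoreSet):
        s, y = scores.scores, scores.labels
    else:
        s, y = np.asarray(scores, float), np.asarray(labels, int)
    neg = np.sort(s[y == 0])
    n_neg = len(neg)
    if n_neg == 0:
        raise ValueError("at least one negative sample is required")
    candidates = np.unique(s)
    below = np.searchsorted(neg, candidates, side="left")  # negatives strictly below
    fallback = float(np.nextafter(candidates[-1], np.inf))
    out: dict[float, tuple[float, float]] = {}
    for level in grid:
        k = int(math.ceil(level * n_neg - 1e-9))
        ok = np.flatnonzero(below >= k)
        if len(ok):
            i = ok[0]
            out[level] = (float(candidates[i]), below[i] / n_neg)
        else:
            out[level] = (fallback, 1.0)
    return out


def selection_search_size(n_candidates_r: int, n_candidates_h: int, n_thresholds: int = len(SPECIFICITY_GRID)) -> int:
    """Number of (candidate, threshold) cells scanned by the per-subgroup
    selection: the NPV and PPV terms decompose, so the search is
    ``n_thresholds * n_candidates`` per test, summed over the two tests
    (38 cells with one candidate per test, 608 with the full 16 per test)."""
    return n_thresholds * n_candidates_r + n_thresholds * n_candidates_h


# ---------------------------------------------------------------------------
# Per-subgroup selection (feature sets x thresholds)
# ---------------------------------------------------------------------------


@dataclass
class SelectedTest:
    model: LogisticModel
    threshold: float
    spec_level: float
    achieved_spec: float
    confusion: ConfusionMatrix  # training confusion at the chosen threshold
    metric: float  # NPV for the restenosis test, PPV for the hazard test


@dataclass
class LeafPair:
    """The selected (restenosis test, hazard test) pair for one subgroup."""

    subgroup: SubgroupSpec
    test_r: SelectedTest
    test_h: SelectedTest
    objective: float  # training NPV(T_R) + PPV(T_H)
    n_evaluations: int  # (candidate, threshold) cells scanned
    n_candidates_r: int
    n_candidates_h: int


def _select_test(
    index,
    subgroup: SubgroupSpec,
    treatment_arm: str,
    endpoint: str,
    metric_name: str,
    catalog: FeatureCatalog,
    penalty: float,
    endpoint_kind: str,
    min_samples: int,
    min_positives: int,
) -> tuple[SelectedTest | None, int, int]:
    """Exhaustive scan over feature-set pairs and grid thresholds for one test.

    Ties are broken by higher metric, then fewer total features, then lower
    set indices, then lower specificity level; candidates whose metric
    denominator is zero are excluded.
    """
    best_key = None
    best: SelectedTest | None = None
    n_candidates = 0
    n_evals = 0
    for ci in CLINICAL_OPTIONS:
        for bj in BIOMARKER_OPTIONS:
            sample = filter_eligible(
                index.frame, subgroup, (ci, bj), treatment_arm, endpoint, catalog,
                min_samples=min_samples, min_positives=min_positives, index=index,
            )
            if sample is None:
                continue
            n_candidates += 1
            model = fit_l2_logistic(sample, penalty, catalog, endpoint_kind=endpoint_kind)
            scores = model.predict_frame(sample.features)
            thr_map = thresholds_at_specificity(scores, sample.y)
            n_features = len(sample.features.columns)
            for level in SPECIFICITY_GRID:
                threshold, achieved = thr_map[level]
                cm = confusion_at_threshold(scores, threshold, sample.y)
                n_evals += 1
                value = cm.npv if metric_name == "npv" else cm.ppv
                if math.isnan(value):
                    continue
                key = (-value, n_features, _SET_INDEX[ci], _SET_INDEX[bj], level)
                if best_key is None or key < best_key:
                    best_key = key
                    best = SelectedTest(
                        model=model,
                        threshold=threshold,
                        spec_level=level,
                        achieved_spec=achieved,
                        confusion=cm,
                        metric=value,
                    )
    return best, n_candidates, n_evals


def select_pair_for_subgroup(
    cohort,
    subgroup: SubgroupSpec,
    endpoint_pair: tuple[str, str] = ("angio_restenosis_6m", "hazard_1y"),
    catalog: FeatureCatalog | None = None,
    penalty: float = DEFAULT_PENALTY,
    min_samples: int = 100,
    min_positives: int = 10,
    index: CohortIndex | None = None,
) -> LeafPair | None:
    """Jointly select feature sets and thresholds for a subgroup's test pair.

    The restenosis test is trained on the subgroup's BMS arm, the hazard test
    on its DES arm; the returned pair maximizes training NPV + PPV. Returns
    ``None`` (ineligible) if no eligible candidate exists for either test.
    """
    catalog = catalog or FeatureCatalog.default()
    if index is None:
        index = CohortIndex(cohort_to_frame(cohort, catalog), catalog)
    rest_ep, haz_ep = endpoint_pair
    test_r, n_r, evals_r = _select_test(
        index, subgroup, "BMS", rest_ep, "npv", catalog, penalty, "R", min_samples, min_positives
    )
    test_h, n_h, evals_h = _select_test(
        index, subgroup, "DES", haz_ep, "ppv", catalog, penalty, "H", min_samples, min_positives
    )
    if test_r is None or test_h is None:
        return None
    return LeafPair(
        subgroup=subgroup,
        test_r=test_r,
        test_h=test_h,
        objective=test_r.metric + test_h.metric,
        n_evaluations=evals_r + evals_h,
        n_candidates_r=n_r,
        n_candidates_h=n_h,
    )


# ---------------------------------------------------------------------------
# Tree aggregation and selection
# ---------------------------------------------------------------------------


def aggregate_tree(
    tree: ClassificationTreeSpec, leaf_pairs: dict[SubgroupSpec, LeafPair]
) -> tuple[ConfusionMatrix, ConfusionMatrix, float] | None:
    """Element-wise sums of leaf training confusion matrices and the
    aggregated objective NPV + PPV; ``None`` if any leaf lacks a pair or an
    aggregated metric is undefined (tree discarded from competition)."""
    cm_r = ConfusionMatrix()
    cm_h = ConfusionMatrix()
    for leaf in tree.leaves:
        pair = leaf_pairs.get(leaf)
        if pair is None:
            return None
        cm_r = cm_r + pair.test_r.confusion
        cm_h = cm_h + pair.test_h.confusion
    if math.isnan(cm_r.npv) or math.isnan(cm_h.ppv):
        return None
    return cm_r, cm_h, cm_r.npv + cm_h.ppv


@dataclass
class FittedCascade:
    """The winning partition with a fitted test pair at every leaf."""

    tree: ClassificationTreeSpec
    leaf_pairs: dict[SubgroupSpec, LeafPair]
    confusion_r: ConfusionMatrix
    confusion_h: ConfusionMatrix
    objective: float
    endpoint_pair: tuple[str, str]

    @property
    def performance_r(self) -> ClassifierPerformance:
        return ClassifierPerformance.from_confusion(self.confusion_r)

    @property
    def performance_h(self) -> ClassifierPerformance:
        return ClassifierPerformance.from_confusion(self.confusion_h)

    def to_jsonable(self) -> dict:
        return {
            "endpoint_pair": list(self.endpoint_pair),
            "objective": self.objective,
            "leaves": [
                {
                    "subgroup": [l.age, l.sex, l.diabetes],
                    "model_r": p.test_r.model.to_jsonable(),
                    "theta_r": p.test_r.threshold,
                    "spec_level_r": p.test_r.spec_level,
                    "confusion_r": vars(p.test_r.confusion),
                    "model_h": p.test_h.model.to_jsonable(),
                    "theta_h": p.test_h.threshold,
                    "spec_level_h": p.test_h.spec_level,
                    "confusion_h": vars(p.test_h.confusion),
                }
                for l, p in ((leaf, self.leaf_pairs[leaf]) for leaf in self.tree.leaves)
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_jsonable()))

    @classmethod
    def from_jsonable(cls, d: dict) -> "FittedCascade":
        leaf_pairs: dict[SubgroupSpec, LeafPair] = {}
        leaves = []
        for entry in d["leaves"]:
            sg = SubgroupSpec(*entry["subgroup"])
            leaves.append(sg)
            cm_r = ConfusionMatrix(**entry["confusion_r"])
            cm_h = ConfusionMatrix(**entry["confusion_h"])
            test_r = SelectedTest(
                model=LogisticModel.from_jsonable(entry["model_r"]),
                threshold=float(entry["theta_r"]),
                spec_level=float(entry["spec_level_r"]),
                achieved_spec=cm_r.spec,
                confusion=cm_r,
                metric=cm_r.npv,
            )
            test_h = SelectedTest(
                model=LogisticModel.from_jsonable(entry["model_h"]),
                threshold=float(entry["theta_h"]),
                spec_level=float(entry["spec_level_h"]),
                achieved_spec=cm_h.spec,
                confusion=cm_h,
                metric=cm_h.ppv,
            )
            leaf_pairs[sg] = LeafPair(
                subgroup=sg,
                test_r=test_r,
                test_h=test_h,
                objective=test_r.metric + test_h.metric,
                n_evaluations=0,
                n_candidates_r=0,
                n_candidates_h=0,
            )
        tree = ClassificationTreeSpec(root=None, leaves=tuple(sorted(leaves)))
        agg_r = ConfusionMatrix()
        agg_h = ConfusionMatrix()
        for p in leaf_pairs.values():
            agg_r = agg_r + p.test_r.confusion
            agg_h = agg_h + p.test_h.confusion
        return cls(
            tree=tree,
            leaf_pairs=leaf_pairs,
            confusion_r=agg_r,
            confusion_h=agg_h,
            objective=float(d["objective"]),
            endpoint_pair=tuple(d["endpoint_pair"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FittedCascade":
        return cls.from_jsonable(json.loads(Path(path).read_text()))


def select_best_tree(
    trees: Sequence[ClassificationTreeSpec],
    leaf_pairs: dict[SubgroupSpec, LeafPair],
    endpoint_pair: tuple[str, str],
) -> FittedCascade:
    """The tree with maximal aggregated objective; ties broken by fewer
    leaves, then enumeration order. Raises if no tree has all leaves fitted."""
    best = None
    for order, tree in enumerate(trees):
        agg = aggregate_tree(tree, leaf_pairs)
        if agg is None:
            continue
        cm_r, cm_h, obj = agg
        key = (-obj, tree.n_leaves, order)
        if best is None or key < best[0]:
            best = (key, tree, cm_r, cm_h, obj)
    if best is None:
        raise RuntimeError("no valid classification tree (even the single-leaf tree is ineligible)")
    _, tree, cm_r, cm_h, obj = best
    return FittedCascade(
        tree=tree,
        leaf_pairs={leaf: leaf_pairs[leaf] for leaf in tree.leaves},
        confusion_r=cm_r,
        confusion_h=cm_h,
        objective=obj,
        endpoint_pair=endpoint_pair,
    )


def train_cascade(
    cohort,
    endpoint_pair: tuple[str, str] = ("angio_restenosis_6m", "hazard_1y"),
    catalog: FeatureCatalog | None = None,
    penalty: float = DEFAULT_PENALTY,
    global_mode: bool = False,
    min_samples: int = 100,
    min_positives: int = 10,
) -> FittedCascade:
    """Full training stage: fit and select test pairs for every subgroup,
    aggregate over all candidate trees and return the winning cascade.

    ``global_mode`` restricts to the single-leaf (unpartitioned) tree, i.e. a
    conventional population-wide classifier pair with the same feature and
    operating-point selection.
    """
    catalog = catalog or FeatureCatalog.default()
    frame = cohort_to_frame(cohort, catalog)
    index = CohortIndex(frame, catalog)
    subgroups = [SubgroupSpec()] if global_mode else enumerate_subgroups()
    leaf_pairs: dict[SubgroupSpec, LeafPair] = {}
    for sg in subgroups:
        pair = select_pair_for_subgroup(
            frame, sg, endpoint_pair, catalog, penalty, min_samples, min_positives, index=index
        )
        if pair is not None:
            leaf_pairs[sg] = pair
        else:
            logger.debug("subgroup %s ineligible, excluded", sg.label)
    trees = [single_leaf_tree()] if global_mode else enumerate_trees()
    return select_best_tree(trees, leaf_pairs, endpoint_pair)
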