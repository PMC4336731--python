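"""Subgroup/tree enumeration, operating-point grid, confusion matrices and
tree aggregation/selection."""

from itertools import product

import numpy as np
import pytest

import stentstrat as ss
from stentstrat.trees import (
    LeafPair,
    SelectedTest,
    _collect_leaves,
)


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------


def test_27_subgroups_distinct_and_universal_included():
    subgroups = ss.enumerate_subgroups()
    assert len(subgroups) == 27
    assert len(set(subgroups)) == 27
    assert ss.SubgroupSpec("ALL", "ALL", "ALL") in subgroups


def test_tree_enumeration_includes_extremes():
    trees = ss.enumerate_trees()
    sizes = [t.n_leaves for t in trees]
    assert 1 in sizes  # the unpartitioned tree
    assert 8 in sizes  # full split on all three variables
    assert max(t.root.depth() for t in trees) <= 4


def test_two_variable_restriction_gives_8_partitions():
    assert len(ss.enumerate_trees(("age", "sex"))) == 8


def _brute_force_guillotine_partitions():
    """Independent oracle: partitions of the 2x2x2 subgroup cube realizable by
    recursive axis-aligned cuts."""
    cells = frozenset(product([0, 1], repeat=3))

    def guillotine(cellset):
        out = {frozenset([cellset])}
        for ax in range(3):
            lo = frozenset(c for c in cellset if c[ax] == 0)
            hi = frozenset(c for c in cellset if c[ax] == 1)
            if lo and hi:
                for pl in guillotine(lo):
                    for ph in guillotine(hi):
                        out.add(pl | ph)
        return out

    return guillotine(cells)


def test_tree_count_matches_brute_force_partition_oracle():
    trees = ss.enumerate_trees()
    oracle = _brute_force_guillotine_partitions()
    assert len(trees) == len(oracle)

    # map each tree's leaves onto cube cells and check set equality
    axes = {"age": ("LE60", "GT60"), "sex": ("FEMALE", "MALE"), "diabetes": ("NO", "YES")}

    def cells_of(leaf):
        opts = []
        for var in ("age", "sex", "diabetes"):
            c = getattr(leaf, var if var != "age" else "age")
            if c == "ALL":
                opts.append((0, 1))
            else:
                opts.append((axes[var].index(c),))
        return frozenset(product(*opts))

    tree_partitions = {frozenset(cells_of(l) for l in t.leaves) for t in trees}
    assert tree_partitions == oracle


def test_leaf_subgroups_are_among_the_27_and_partition():
    allowed = set(ss.enumerate_subgroups())
    for tree in ss.enumerate_trees():
        assert set(tree.leaves) <= allowed
        cells = set()
        for leaf in tree.leaves:
            ages = ("LE60", "GT60") if leaf.age == "ALL" else (leaf.age,)
            sexes = ("FEMALE", "MALE") if leaf.sex == "ALL" else (leaf.sex,)
            diab = ("NO", "YES") if leaf.diabetes == "ALL" else (leaf.diabetes,)
            for cell in product(ages, sexes, diab):
                assert cell not in cells
                cells.add(cell)
        assert len(cells) == 8


# ---------------------------------------------------------------------------
# Operating points
# ---------------------------------------------------------------------------


def test_specificity_grid_has_19_levels():
    assert len(ss.SPECIFICITY_GRID) == 19
    assert ss.SPECIFICITY_GRID[0] == pytest.approx(0.05)
    assert ss.SPECIFICITY_GRID[-1] == pytest.approx(0.95)


def test_thresholds_from_20_distinct_negative_scores():
    rng = np.random.default_rng(0)
    neg = np.sort(rng.permutation(np.linspace(0.01, 0.95, 20)))
    pos = np.array([0.97, 0.98])
    scores = np.concatenate([neg, pos])
    labels = np.concatenate([np.zeros(20, int), np.ones(2, int)])
    out = ss.thresholds_at_specificity(scores, labels)
    thr, achieved = out[0.5]
    # smallest threshold with >= 10 negatives strictly below: the 11th negative
    assert thr == pytest.approx(np.sort(neg)[10])
    assert achieved == pytest.approx(0.5)
    # thresholds non-decreasing and achieved specificity >= level
    levels = sorted(out)
    ths = [out[l][0] for l in levels]
    assert all(a <= b for a, b in zip(ths, ths[1:]))
    assert all(out[l][1] >= l - 1e-12 for l in levels)


def test_thresholds_all_negatives_tied_collapse_to_full_specificity():
    scores = np.array([0.3] * 10 + [0.9])
    labels = np.array([0] * 10 + [1])
    out = ss.thresholds_at_specificity(scores, labels)
    values = set(out.values())
    assert values == {(0.9, 1.0)}


def test_thresholds_require_a_negative():
    with pytest.raises(ValueError):
        ss.thresholds_at_specificity(np.array([0.5]), np.array([1]))


# ---------------------------------------------------------------------------
# Confusion matrices
# ---------------------------------------------------------------------------


def test_confusion_at_threshold_tabulation():
    scores = np.array([0.2, 0.6, 0.7])
    labels = np.array([0, 1, 0])
    cm = ss.confusion_at_threshold(scores, 0.5, labels)
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 0, 1)
    all_pos = ss.confusion_at_threshold(scores, 0.0, labels)
    assert all_pos.fn == all_pos.tn == 0
    all_neg = ss.confusion_at_threshold(scores, 0.8, labels)
    assert all_neg.tp == all_neg.fp == 0


def test_performance_derivations():
    cm = ss.ConfusionMatrix(tp=8, fp=3, fn=3, tn=18)
    perf = ss.ClassifierPerformance.from_confusion(cm)
    assert perf.sens == pytest.approx(8 / 11)
    assert perf.spec == pytest.approx(18 / 21)
    assert perf.ppv == pytest.approx(8 / 11)
    assert perf.npv == pytest.approx(18 / 21)
    assert perf.prevalence == pytest.approx(11 / 32)
    assert perf.n == 32


# ---------------------------------------------------------------------------
# Aggregation and tree selection
# ---------------------------------------------------------------------------


def _pair(subgroup, cm_r, cm_h):
    dummy = None
    tr = SelectedTest(model=dummy, threshold=0.5, spec_level=0.5, achieved_spec=0.5, confusion=cm_r, metric=cm_r.npv)
    th = SelectedTest(model=dummy, threshold=0.5, spec_level=0.5, achieved_spec=0.5, confusion=cm_h, metric=cm_h.ppv)
    return LeafPair(subgroup=subgroup, test_r=tr, test_h=th, objective=tr.metric + th.metric, n_evaluations=38, n_candidates_r=1, n_candidates_h=1)


def test_aggregate_tree_sums_matrices_elementwise():
    trees = {t.n_leaves: t for t in ss.enumerate_trees(("diabetes",))}
    two_leaf = trees[2]
    pairs = {
        two_leaf.leaves[0]: _pair(two_leaf.leaves[0], ss.ConfusionMatrix(5, 1, 2, 10), ss.ConfusionMatrix(5, 1, 2, 10)),
        two_leaf.leaves[1]: _pair(two_leaf.leaves[1], ss.ConfusionMatrix(3, 2, 1, 8), ss.ConfusionMatrix(3, 2, 1, 8)),
    }
    cm_r, cm_h, obj = ss.aggregate_tree(two_leaf, pairs)
    assert (cm_r.tp, cm_r.fp, cm_r.fn, cm_r.tn) == (8, 3, 3, 18)
    assert cm_r.total == sum(p.test_r.confusion.total for p in pairs.values())
    assert obj == pytest.approx(cm_r.npv + cm_h.ppv)


def test_single_leaf_aggregate_equals_leaf_matrix():
    tree = ss.single_leaf_tree()
    cm = ss.ConfusionMatrix(4, 2, 1, 9)
    pairs = {tree.leaves[0]: _pair(tree.leaves[0], cm, cm)}
    cm_r, cm_h, obj = ss.aggregate_tree(tree, pairs)
    assert cm_r == cm and cm_h == cm


def test_tree_with_missing_leaf_is_discarded_not_raised():
    trees = {t.n_leaves: t for t in ss.enumerate_trees(("diabetes",))}
    two_leaf = trees[2]
    pairs = {two_leaf.leaves[0]: _pair(two_leaf.leaves[0], ss.ConfusionMatrix(5, 1, 2, 10), ss.ConfusionMatrix(5, 1, 2, 10))}
    assert ss.aggregate_tree(two_leaf, pairs) is None


def test_select_best_tree_argmax_and_ties():
    single = ss.single_leaf_tree()
    trees = ss.enumerate_trees(("diabetes",))
    two_leaf = next(t for t in trees if t.n_leaves == 2)
    good = ss.ConfusionMatrix(9, 1, 1, 9)  # npv = ppv = 0.9
    poor = ss.ConfusionMatrix(5, 5, 5, 5)  # npv = ppv = 0.5
    pairs = {
        single.leaves[0]: _pair(single.leaves[0], poor, poor),
        two_leaf.leaves[0]: _pair(two_leaf.leaves[0], good, good),
        two_leaf.leaves[1]: _pair(two_leaf.leaves[1], good, good),
    }
    best = ss.select_best_tree([single, two_leaf], pairs, ("angio_restenosis_6m", "hazard_1y"))
    assert best.tree is two_leaf
    assert best.objective == pytest.approx(1.8)
    # exact tie: fewer leaves wins
    pairs[single.leaves[0]] = _pair(single.leaves[0], good, good)
    best = ss.select_best_tree([two_leaf, single], pairs, ("angio_restenosis_6m", "hazard_1y"))
    assert best.tree is single


def test_select_best_tree_errors_with_no_valid_tree():
    with pytest.raises(RuntimeError):
        ss.select_best_tree([ss.single_leaf_tree()], {}, ("angio_restenosis_6m", "hazard_1y"))


def test_select_best_matches_brute_force_objective_scan(trained_cascade):
    cascade, train, _ = trained_cascade
    # independent re-scan: recompute every tree's aggregated objective from
    # the leaf pairs the cascade was selected from
    pairs = {}
    for sg in ss.enumerate_subgroups():
        p = ss.select_pair_for_subgroup(train, sg, ("angio_restenosis_6m", "hazard_1y"))
        if p is not None:
            pairs[sg] = p
    objectives = []
    for t in ss.enumerate_trees():
        agg = ss.aggregate_tree(t, pairs)
        if agg is not None:
            objectives.append(agg[2])
    assert cascade.objective == pytest.approx(max(objectives))
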