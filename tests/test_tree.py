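"""Unit and oracle tests for the surrogate-split regression tree."""

import numpy as np
import pytest

import oracle
from ertmap import (
    RegressionTree,
    TreeParams,
    find_surrogates,
    fit_tree,
    predict_tree,
    predictor_importance,
)


def kernel_nodes(tree):
    """(feature, threshold) of each branch node in assignment order, plus
    surrogate tuples, matched against the oracle's recursive layout."""
    out = {}
    for nid in tree.branch_ids:
        node = tree.node(int(nid))
        out[int(nid)] = node
    return out


def compare_with_oracle(X, y, min_leaf=1, max_surr=10):
    tree = fit_tree(X, y, TreeParams(min_leaf=min_leaf, max_surrogates=max_surr, mtry="all"))
    root = oracle.grow(X, y, min_leaf=min_leaf, max_surr=max_surr)

    def recurse(onode, nid):
        node = tree.node(nid)
        assert node.n_samples == onode["n"]
        assert node.prediction == pytest.approx(onode["prediction"], abs=1e-12)
        if "split" not in onode:
            assert node.is_leaf
            return
        assert not node.is_leaf
        assert node.primary_split.feature_index == onode["split"]["feature"]
        assert node.primary_split.threshold == pytest.approx(onode["split"]["threshold"])
        assert node.primary_split.risk_reduction == pytest.approx(onode["split"]["rr"], rel=1e-9)
        osur = onode["surrogates"]
        assert len(node.surrogates) == len(osur)
        for got, want in zip(node.surrogates, osur):
            assert got.feature_index == want["feature"]
            assert got.threshold == pytest.approx(want["threshold"])
            assert got.association == pytest.approx(want["lambda"], rel=1e-9)
            assert got.risk_reduction == pytest.approx(want["rr"], rel=1e-9, abs=1e-12)
        recurse(onode["left"], node.children[0])
        recurse(onode["right"], node.children[1])

    recurse(root, 0)
    np.testing.assert_allclose(
        predictor_importance(tree), oracle.importance(root, X.shape[1]), rtol=1e-9, atol=1e-12
    )
    return tree, root


def test_step_function_split():
    """A perfectly separable step puts the root threshold between the steps
    and converts the whole root risk (var y = 25) into risk reduction."""
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array([0.0, 0.0, 10.0, 10.0])
    tree = fit_tree(X, y, TreeParams(min_leaf=1))
    root = tree.node(0)
    assert 1.0 < root.primary_split.threshold < 2.0
    assert root.primary_split.risk_reduction == pytest.approx(25.0)
    assert tree.node_rr.sum() == pytest.approx(25.0)
    np.testing.assert_array_equal(predict_tree(tree, X), y)
    assert predict_tree(tree, np.array([[1.5]]))[0] == (0.0 if tree.node(0).primary_split.threshold > 1.5 else 10.0)


def test_constant_target_single_leaf():
    X = np.arange(8.0).reshape(4, 2)
    y = np.full(4, 5.0)
    tree = fit_tree(X, y, TreeParams(min_leaf=1))
    assert tree.n_branch_nodes == 0
    root = tree.node(0)
    assert root.is_leaf and root.prediction == 5.0 and root.risk == 0.0
    np.testing.assert_array_equal(predictor_importance(tree), np.zeros(2))
    np.testing.assert_array_equal(predict_tree(tree, X), np.full(4, 5.0))


def test_length_mismatch_raises():
    with pytest.raises(ValueError, match="rows"):
        fit_tree(np.zeros((4, 2)), np.zeros(3))
    tree = fit_tree(np.zeros((4, 2)) + np.arange(4)[:, None], np.arange(4.0), TreeParams(min_leaf=1))
    with pytest.raises(ValueError, match="columns"):
        predict_tree(tree, np.zeros((2, 3)))


@pytest.mark.parametrize("case", range(8))
@pytest.mark.parametrize("min_leaf", [1, 2])
def test_oracle_equivalence_random_tiny(case, min_leaf):
    """Fitted splits, surrogate ordering, and importance equal exhaustive
    enumeration on random tiny problems (n <= 12, p <= 3)."""
    from conftest import tiny_datasets

    X, y = tiny_datasets()[case]
    compare_with_oracle(X, y, min_leaf=min_leaf)


def test_oracle_equivalence_tiny_fixture(tiny_cohort):
    """Same equivalence on the simulated tiny cohort (first 3 regions)."""
    from ertmap import select_group

    X, y, _ = select_group(tiny_cohort, "HC_MCI_AD", "SYN_A", "MMSE")
    compare_with_oracle(X[:, :3], y, min_leaf=1)
    compare_with_oracle(X[:, :3], y, min_leaf=2)


def test_duplicate_column_perfect_surrogate():
    """An identical column yields a surrogate with association 1 and the
    same risk reduction as the primary split."""
    rng = np.random.default_rng(5)
    x = rng.normal(size=10)
    X = np.column_stack([x, x])
    y = x * 2 + rng.normal(0, 0.1, size=10)
    tree = fit_tree(X, y, TreeParams(min_leaf=2))
    root = tree.node(0)
    assert root.primary_split.feature_index == 0
    sur = root.surrogates[0]
    assert sur.feature_index == 1
    assert sur.association == pytest.approx(1.0)
    assert sur.risk_reduction == pytest.approx(root.primary_split.risk_reduction, rel=1e-12)
    # both copies receive positive importance through the surrogate channel
    imp = predictor_importance(tree)
    assert imp[0] > 0 and imp[1] > 0


def test_anticorrelated_column_excluded():
    """With left-if-less routing only, a sign-flipped copy mimics the primary
    partition no better than majority routing and is dropped (lambda <= 0)."""
    x = np.array([-2.5, -1.5, -0.5, 0.5, 1.5, 2.5])
    X = np.column_stack([x, -x])
    y = np.array([0.0, 0.0, 0.0, 4.0, 4.0, 4.0])
    tree = fit_tree(X, y, TreeParams(min_leaf=1))
    root = tree.node(0)
    assert root.primary_split.feature_index == 0
    assert all(s.feature_index != 1 for s in root.surrogates)


def test_risk_conservation():
    """Sum of primary risk reductions equals root risk minus summed leaf
    risks, exactly to floating tolerance."""
    rng = np.random.default_rng(11)
    for n, p, min_leaf in [(30, 3, 1), (100, 5, 5), (57, 4, 2)]:
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        tree = fit_tree(X, y, TreeParams(min_leaf=min_leaf))
        root_risk = tree.node_sse[0] / n
        leaf_risk = tree.node_sse[tree.leaf_ids].sum() / n
        assert tree.node_rr.sum() == pytest.approx(root_risk - leaf_risk, rel=1e-9)


def test_importance_nonnegative_and_permutation_equivariant():
    """Permuting feature columns permutes importance identically.

    Uses well-populated nodes (min_leaf=10): at very small nodes two distinct
    partitions can tie exactly in risk reduction, and the deterministic
    lowest-feature-index tie-break is then order-dependent by design.
    """
    rng = np.random.default_rng(21)
    X = rng.normal(size=(100, 4))
    y = X[:, 2] + 0.3 * rng.normal(size=100)
    params = TreeParams(min_leaf=10, mtry="all")
    imp = predictor_importance(fit_tree(X, y, params))
    assert np.all(imp >= 0)
    perm = np.array([2, 0, 3, 1])
    imp_p = predictor_importance(fit_tree(X[:, perm], y, params))
    np.testing.assert_allclose(imp_p, imp[perm], rtol=1e-9)


def test_affine_feature_rescaling_preserves_partition():
    rng = np.random.default_rng(31)
    X = rng.normal(size=(50, 3))
    y = X[:, 0] - X[:, 1] + 0.2 * rng.normal(size=50)
    t1 = fit_tree(X, y, TreeParams(min_leaf=4))
    X2 = X.copy()
    X2[:, 1] = 2.5 * X2[:, 1] + 7.0
    t2 = fit_tree(X2, y, TreeParams(min_leaf=4))
    np.testing.assert_array_equal(t1.node_feature, t2.node_feature)
    np.testing.assert_array_equal(t1.node_n, t2.node_n)
    np.testing.assert_allclose(predict_tree(t1, X), predict_tree(t2, X2))


def test_memorization_with_min_leaf_one():
    rng = np.random.default_rng(41)
    X = rng.normal(size=(25, 3))
    y = rng.normal(size=25)
    tree = fit_tree(X, y, TreeParams(min_leaf=1))
    np.testing.assert_allclose(predict_tree(tree, X), y, atol=1e-9)


def test_find_surrogates_matches_kernel(rng):
    """The pure-Python surrogate reference reproduces the kernel's surrogate
    tables at every branch node."""
    X = rng.normal(size=(60, 5))
    X[:, 3] = X[:, 1] + 0.05 * rng.normal(size=60)
    y = X[:, 1] + 0.5 * rng.normal(size=60)
    params = TreeParams(min_leaf=5, max_surrogates=4)
    tree = fit_tree(X, y, params)
    members = tree.assign_samples(X)
    for nid in tree.branch_ids:
        node = tree.node(int(nid))
        ref = find_surrogates(node, X, y, members[int(nid)], params)
        assert [s.feature_index for s in ref] == [s.feature_index for s in node.surrogates]
        for a, b in zip(ref, node.surrogates):
            assert a.threshold == pytest.approx(b.threshold)
            assert a.association == pytest.approx(b.association, rel=1e-9)
            assert a.risk_reduction == pytest.approx(b.risk_reduction, rel=1e-9, abs=1e-12)


def test_tree_invariants_property():
    """Risk conservation and non-negative importance hold for arbitrary
    small regression problems (property-based)."""
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra import numpy as hnp

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        X=hnp.arrays(
            float,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=4, max_side=20),
            elements=st.floats(-50, 50, allow_nan=False),
        ),
        y_seed=st.integers(0, 2**16),
        min_leaf=st.integers(1, 3),
    )
    def check(X, y_seed, min_leaf):
        y = np.random.default_rng(y_seed).normal(size=X.shape[0])
        tree = fit_tree(X, y, TreeParams(min_leaf=min_leaf))
        n = tree.n_samples
        root_risk = tree.node_sse[0] / n
        leaf_risk = tree.node_sse[tree.leaf_ids].sum() / n
        assert tree.node_rr.sum() == pytest.approx(
            root_risk - leaf_risk, rel=1e-9, abs=1e-12
        )
        imp = predictor_importance(tree)
        assert np.all(imp >= 0)
        if tree.n_branch_nodes == 0:
            assert np.all(imp == 0)
        # children partition the parent's samples
        for nid in tree.branch_ids:
            l, r = tree.node_left[nid], tree.node_right[nid]
            assert tree.node_n[l] + tree.node_n[r] == tree.node_n[nid]

    check()


def test_json_round_trip(rng):
    X = rng.normal(size=(30, 3))
    y = X[:, 0] + rng.normal(size=30)
    tree = fit_tree(X, y, TreeParams(min_leaf=3))
    clone = RegressionTree.from_dict(tree.to_dict())
    np.testing.assert_allclose(predict_tree(clone, X), predict_tree(tree, X))
    np.testing.assert_allclose(predictor_importance(clone), predictor_importance(tree))
    assert clone.n_branch_nodes == tree.n_branch_nodes
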