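import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import balanced_accuracy_score

from maskshaker import (
    ValidationError,
    assign_phenotypes,
    balanced_accuracy,
    confusion_percentages,
    fit_gate_model,
    fit_marker_gmm,
    gate_positive,
    phenotype_error_breakdown,
    wu_palmer_distance,
)
from maskshaker.phenotype import GatingTree, ROOT, UNASSIGNED

from .conftest import make_table


class TestGatingTreeStructure:
    def test_root_depth_zero(self, tree):
        assert tree.depth(ROOT) == 0

    def test_child_requirements_extend_parent(self, tree):
        req_cd8 = tree.requirements["CD8 T"]
        req_parent = tree.requirements["T cell"]
        assert set(req_parent.items()) <= set(req_cd8.items())

    def test_every_leaf_reachable_by_consistent_path(self, tree):
        for leaf in tree.leaves():
            path = list(reversed(tree.ancestors(leaf)))  # root ... leaf
            for parent, child in zip(path, path[1:]):
                assert set(tree.requirements[parent].items()) <= set(
                    tree.requirements[child].items()
                )

    def test_inconsistent_child_rejected(self):
        with pytest.raises(ValidationError):
            GatingTree(
                parents={ROOT: None, "A": ROOT, "B": "A"},
                requirements={ROOT: {}, "A": {"CD45": True}, "B": {"CD45": False}},
            )

    def test_yaml_round_trip(self, tree, tmp_path):
        tree.to_yaml(tmp_path / "tree.yaml")
        back = GatingTree.from_yaml(tmp_path / "tree.yaml")
        assert back.parents == tree.parents
        assert back.requirements == tree.requirements


class TestMarkerGMM:
    def test_recovers_component_means(self, rng):
        data = np.concatenate([
            rng.normal(0.0, 0.15, 1000),
            rng.normal(1.0, 0.15, 1000),
            rng.normal(5.0, 0.3, 1000),
        ])
        gate = fit_marker_gmm(data, seed=0)
        np.testing.assert_allclose(gate.means, [0.0, 1.0, 5.0], atol=0.1)

    def test_seeded_determinism(self, rng):
        data = rng.normal(0, 1, 200)
        a = fit_marker_gmm(data, seed=4)
        b = fit_marker_gmm(data, seed=4)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_constant_column_rejected(self):
        with pytest.raises(ValidationError):
            fit_marker_gmm(np.ones(100))

    def test_too_few_cells_rejected(self, rng):
        with pytest.raises(ValidationError):
            fit_marker_gmm(rng.normal(0, 1, 10))


class TestGatePositive:
    @pytest.fixture
    def trimodal_gate(self, rng):
        data = np.concatenate([
            rng.normal(0.0, 0.2, 1500),
            rng.normal(1.0, 0.2, 1000),
            rng.normal(6.0, 0.3, 500),
        ])
        return fit_marker_gmm(data, seed=0)

    def test_extreme_values(self, trimodal_gate):
        assert gate_positive(trimodal_gate, np.array([20.0]))[0]
        assert not gate_positive(trimodal_gate, np.array([0.0]))[0]

    def test_planted_top_component_recovered(self, rng, trimodal_gate):
        low = rng.normal(0.0, 0.2, 500)
        high = rng.normal(6.0, 0.3, 500)  # ~20 sigma from the mid component
        values = np.concatenate([low, high])
        calls = gate_positive(trimodal_gate, values)
        planted = np.concatenate([np.zeros(500, bool), np.ones(500, bool)])
        assert (calls == planted).mean() >= 0.99


class TestAssignPhenotypes:
    def test_cd8_t_cell_combination(self, tree, clean_tissue):
        """A cell positive for CD45, CD3 and CD8 (and nothing else) lands on
        the CD8 T leaf."""
        from maskshaker import NUCLEUS_CHANNEL, drop_nucleus, extract_features

        image, mask, pheno = clean_tissue
        ft = drop_nucleus(extract_features(image, mask), NUCLEUS_CHANNEL)
        gates = fit_gate_model(ft, tree, seed=0)
        assigned = assign_phenotypes(ft, tree, gates)
        cd8_cells = pheno[pheno == "CD8 T"].index
        assert (assigned.loc[cd8_cells] == "CD8 T").all()

    def test_all_negative_cell_unassigned(self, tree, rng):
        markers = tree.markers()
        # 99 background cells + 1 clear positive population per marker so
        # every gate is well defined
        n = 400
        data = {}
        for m in markers:
            col = rng.lognormal(np.log(2), 0.4, n)
            col[:80] = rng.lognormal(np.log(60), 0.2, 80)
            data[m] = col
        df = pd.DataFrame(data, index=pd.RangeIndex(1, n + 1, name="cell_id"))
        from maskshaker import FeatureTable

        ft = FeatureTable(df, markers=markers)
        gates = fit_gate_model(ft, tree, seed=0)
        assigned = assign_phenotypes(ft, tree, gates)
        low_rows = assigned.iloc[200:]  # far from any positive population
        assert (low_rows == UNASSIGNED).all()

    def test_missing_marker_rejected(self, tree, rng):
        ft = make_table({i: {"CD45": float(rng.random())} for i in range(1, 40)})
        with pytest.raises(ValidationError):
            fit_gate_model(ft, tree, seed=0)


class TestWuPalmer:
    def test_identical_node_zero(self, tree):
        assert wu_palmer_distance(tree, "CD8 T", "CD8 T") == 0.0

    def test_depth2_siblings_half(self, tree):
        # Hepatocyte and LSEC share the depth-1 parent Parenchymal
        assert wu_palmer_distance(tree, "Hepatocyte", "LSEC") == 0.5

    def test_cross_lineage_one(self, tree):
        assert wu_palmer_distance(tree, "CD8 T", "Hepatocyte") == 1.0

    def test_symmetry(self, tree):
        nodes = [n for n in tree.nodes if n != ROOT]
        for x in nodes:
            for y in nodes:
                assert wu_palmer_distance(tree, x, y) == wu_palmer_distance(tree, y, x)

    def test_root_and_unknown_rejected(self, tree):
        with pytest.raises(ValidationError):
            wu_palmer_distance(tree, ROOT, "CD8 T")
        with pytest.raises(KeyError):
            wu_palmer_distance(tree, "CD8 T", "nope")


class TestBalancedAccuracy:
    def test_perfect(self):
        y = ["a", "b", "a", "b"]
        assert balanced_accuracy(y, y) == 1.0

    def test_binary_half(self):
        # tp=1, fn=1, tn=1, fp=1 -> (0.5 + 0.5)/2
        y_true = ["pos", "pos", "neg", "neg"]
        y_pred = ["pos", "neg", "neg", "pos"]
        assert balanced_accuracy(y_true, y_pred) == 0.5

    def test_three_class_macro_recall(self):
        y_true = ["a", "a", "b", "b", "c", "c"]
        y_pred = ["a", "a", "b", "c", "a", "b"]  # recalls 1.0, 0.5, 0.0
        assert balanced_accuracy(y_true, y_pred) == 0.5

    def test_matches_sklearn(self, rng):
        y_true = rng.integers(0, 3, 100).astype(str)
        y_pred = rng.integers(0, 3, 100).astype(str)
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(
            balanced_accuracy_score(y_true, y_pred)
        )

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            balanced_accuracy([], [])


class TestConfusionPercentages:
    def test_perfect_prediction_identity(self):
        y = ["a", "b", "a"]
        mat = confusion_percentages(y, y, ["a", "b"])
        np.testing.assert_allclose(np.diag(mat), [100.0, 100.0])

    def test_rows_sum_to_100(self, rng):
        y_true = rng.integers(0, 3, 60).astype(str)
        y_pred = rng.integers(0, 3, 60).astype(str)
        mat = confusion_percentages(y_true, y_pred, ["0", "1", "2"])
        np.testing.assert_allclose(mat.sum(axis=1), 100.0)

    def test_single_error_split(self):
        y_true = ["a", "a", "a", "a"]
        y_pred = ["a", "a", "a", "b"]
        mat = confusion_percentages(y_true, y_pred, ["a", "b"])
        assert mat.loc["a", "a"] == 75.0
        assert mat.loc["a", "b"] == 25.0


class TestErrorBreakdown:
    def test_all_correct(self, tree):
        y = ["CD8 T", "Hepatocyte"]
        assert phenotype_error_breakdown(tree, y, y) == {
            "correct": 1.0, "subtype": 0.0, "granularity": 0.0, "lineage": 0.0,
        }

    def test_sibling_swap_is_subtype_change(self, tree):
        out = phenotype_error_breakdown(tree, ["CD4 T"], ["Treg"])
        assert out["subtype"] == 1.0

    def test_cross_lineage_change(self, tree):
        out = phenotype_error_breakdown(tree, ["T cell"], ["Hepatocyte"])
        assert out["lineage"] == 1.0

    def test_ancestor_move_is_granularity_change(self, tree):
        out = phenotype_error_breakdown(tree, ["LSEC"], ["Parenchymal"])
        assert out["granularity"] == 1.0

    def test_fractions_sum_to_one(self, tree, rng):
        nodes = [n for n in tree.nodes if n != ROOT] + [UNASSIGNED]
        y_true = rng.choice(nodes, 50)
        y_pred = rng.choice(nodes, 50)
        out = phenotype_error_breakdown(tree, y_true, y_pred)
        assert sum(out.values()) == pytest.approx(1.0)
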