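"""Backward weight-propagation attribution."""

import numpy as np
import pytest

from braintopo.attribution import (
    backward_propagate_contributions,
    format_report,
    layer_contributions,
    select_over_half,
)
from braintopo.features import feature_names
from braintopo.sae import SaeModel


def model_from_weights(weights):
    return SaeModel(
        weights=[np.asarray(w, dtype=float) for w in weights],
        biases=[np.zeros(np.asarray(w).shape[0]) for w in weights],
        label_weight=np.ones((2, np.asarray(weights[-1]).shape[0])),
        label_bias=np.zeros(2),
    )


class TestLayerContributions:
    def test_identity_weights_give_indicator(self):
        c = layer_contributions(np.eye(4), [2])
        np.testing.assert_allclose(c, [0, 0, 1, 0])

    def test_zero_column_scores_zero(self):
        w = np.array([[1.0, 0.0, 2.0], [3.0, 0.0, 1.0]])
        c = layer_contributions(w, [0, 1])
        assert c[1] == 0
        assert c.sum() == pytest.approx(1.0)

    def test_three_by_three_hand_computed(self):
        w = np.array([[1.0, -2.0, 0.5],
                      [0.0, 1.0, -1.0],
                      [2.0, 0.0, 3.0]])
        # kept rows {0, 2}: |col| sums = (3, 2, 3.5), total 8.5
        c = layer_contributions(w, [0, 2])
        np.testing.assert_allclose(c, np.array([3.0, 2.0, 3.5]) / 8.5)

    def test_squared_mode(self):
        w = np.array([[1.0, 2.0], [2.0, 1.0]])
        c = layer_contributions(w, [0, 1], mode="sq")
        np.testing.assert_allclose(c, [0.5, 0.5])

    def test_all_zero_restriction_rejected(self):
        w = np.array([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="degenerate"):
            layer_contributions(w, [0])


class TestSelectOverHalf:
    def test_dominant_node_selected_alone(self):
        assert select_over_half(np.array([0.6, 0.3, 0.1])) == [0]

    def test_uniform_four_nodes_takes_three(self):
        # 0.5 is not > 0.5, so a third node is required
        assert select_over_half(np.full(4, 0.25)) == [0, 1, 2]

    def test_single_node(self):
        assert select_over_half(np.array([1.0])) == [0]

    def test_kept_sum_exceeds_half_and_is_minimal(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = rng.dirichlet(np.ones(12))
            kept = select_over_half(c)
            assert c[kept].sum() > 0.5
            dropped_best = c[sorted(kept, key=lambda i: c[i])[0]]
            assert c[kept].sum() - dropped_best <= 0.5 + 1e-12


class TestBackwardPass:
    def test_dominant_path_attributes_to_single_feature(self):
        w1 = np.full((6, 8), 1e-6)
        w1[0, 3] = 5.0  # feature 3 dominates the only relevant hidden node
        w2 = np.full((3, 6), 1e-6)
        w2[1, 0] = 4.0
        model = model_from_weights([w1, w2])
        names = [f"f{i}" for i in range(8)]
        report = backward_propagate_contributions(model, names, top_k=3)
        assert report.top_features[0][0] == "f3"
        assert report.top_features[0][1] > 0.99

    def test_three_layer_network_matches_hand_computation(self):
        w1 = np.array([[1.0, 0.0, 2.0, 0.0],
                       [0.0, 3.0, 0.0, 1.0],
                       [1.0, 1.0, 1.0, 1.0]])
        w2 = np.array([[2.0, 0.0, 1.0],
                       [0.0, 1.0, 1.0]])
        model = model_from_weights([w1, w2])
        # l3 = output layer of the stack: kept = all {0, 1}
        # l2 contributions via w2: |cols| = (2, 1, 2) / 5
        # select > 0.5: sorted (0:0.4, 2:0.4, 1:0.2) -> kept {0, 2} (0.8)
        # l1 contributions via w1 rows {0, 2}: cols = (2, 1, 3, 1) / 7
        report = backward_propagate_contributions(
            model, ["a", "b", "c", "d"], top_k=4
        )
        assert report.kept_nodes["l2"] == [0, 2]
        np.testing.assert_allclose(
            report.feature_contributions, np.array([2.0, 1.0, 3.0, 1.0]) / 7.0
        )
        assert report.top_features[0] == ("c", pytest.approx(3 / 7))

    def test_scale_invariance_of_ranking(self):
        rng = np.random.default_rng(1)
        w1 = rng.standard_normal((10, 20))
        w2 = rng.standard_normal((4, 10))
        names = [f"f{i}" for i in range(20)]
        r1 = backward_propagate_contributions(model_from_weights([w1, w2]), names)
        r2 = backward_propagate_contributions(
            model_from_weights([w1 * 7.3, w2 * 0.2]), names
        )
        assert [f for f, _ in r1.top_features] == [f for f, _ in r2.top_features]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        w1 = rng.standard_normal((8, 12))
        w2 = rng.standard_normal((3, 8))
        names = [f"f{i}" for i in range(12)]
        perm = rng.permutation(12)
        r1 = backward_propagate_contributions(model_from_weights([w1, w2]), names)
        r2 = backward_propagate_contributions(
            model_from_weights([w1[:, perm], w2]), [names[i] for i in perm]
        )
        assert dict(r1.top_features) == pytest.approx(dict(r2.top_features))

    def test_report_length_and_descending_order(self):
        rng = np.random.default_rng(3)
        w1 = rng.standard_normal((10, 30))
        w2 = rng.standard_normal((4, 10))
        report = backward_propagate_contributions(
            model_from_weights([w1, w2]), [f"f{i}" for i in range(30)]
        )
        assert len(report.top_features) == 10
        values = [v for _, v in report.top_features]
        assert values == sorted(values, reverse=True)
        assert report.feature_contributions.sum() == pytest.approx(1.0)


class TestFormatReport:
    def make_report(self, names_values):
        n = len(names_values)
        from braintopo.attribution import ContributionReport

        contributions = np.array([v for _, v in names_values])
        full = contributions / contributions.sum()
        return ContributionReport(
            kept_nodes={"l2": [0]},
            feature_contributions=full,
            feature_names=[f for f, _ in names_values],
            top_features=[(f, v) for f, v in names_values],
        )

    def test_nodal_feature_row_uses_full_region_name(self):
        report = self.make_report([("betweenness:MFG.R", 0.6), ("degree:AMYG.L", 0.4)])
        table = format_report(report)
        assert list(table.iloc[0]) == ["Nodal betweenness", "Middle frontal gyrus R", 0.6]
        assert list(table.iloc[1]) == ["Nodal degree", "Amygdala L", 0.4]

    def test_global_feature_row(self):
        report = self.make_report([("global:Cp", 1.0)])
        table = format_report(report)
        assert table.iloc[0]["topological_property"] == "Global"
        assert table.iloc[0]["brain_region"] == "—"

    def test_contribution_rounded_to_four_decimals(self):
        report = self.make_report([("degree:MFG.R", 0.00791)])
        assert format_report(report).iloc[0]["contribution"] == 0.0079
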