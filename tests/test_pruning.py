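"""Omission-based pruning, significance ranking and mirror symmetry."""

import numpy as np
import pandas as pd
import pytest

from dynedge.edgenet import EdgeNetwork, TrainConfig, forward, init_network, train
from dynedge.pruning import (
    PruneTrace,
    _drop_input_positions,
    mirror_component,
    prune_full,
    prune_step,
    significance_scores,
    symmetry_report,
)


def _separable(seed=0, n=200, p=4):
    """y depends only on input 0; the rest is noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, p))
    y = (X[:, 0] > 0).astype(float)
    X[:, 0] += np.where(y > 0, 2.0, -2.0)
    return X, y


def _trained_net(X, y, seed=0, hidden=6):
    cfg = TrainConfig(epochs=150, n_starts=2, start_epochs=20, seed=seed)
    net, _ = train(None, X, y, cfg, n_hidden=hidden)
    return net


class TestPruneStep:
    def test_zero_weight_input_removed_first_with_zero_increment(self):
        """An input with all-zero outgoing weights costs exactly nothing to
        omit; informative inputs cost strictly more."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 3))
        y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(float)
        net = EdgeNetwork(np.array([[2.0, 1.0, 0.0]]), np.zeros(1), np.array([4.0]), -2.0)
        cands = {f"in{i}": [i] for i in range(3)}
        best, inc = prune_step(net, X, y, cands, "input")
        assert best == "in2"
        assert inc["in2"] == pytest.approx(0.0, abs=1e-15)
        assert inc["in0"] > inc["in1"] > 0

    def test_increments_essentially_nonnegative_on_trained_net(self):
        """At a trained optimum, zeroing a component cannot meaningfully
        reduce the training SSE: any negative increment is tiny relative
        to the informative component's cost (finite-sample / table
        quantization slack)."""
        X, y = _separable(2, n=400)
        net = _trained_net(X, y, 2)
        _, inc = prune_step(net, X, y, {f"in{i}": [i] for i in range(4)}, "input")
        values = inc.to_numpy()
        assert values.max() > 1.0  # the informative input is expensive
        assert np.all(values >= -1e-4 * values.max())

    def test_duplicated_redundant_input_cheap_to_remove(self):
        """With a duplicated informative column, dropping one copy costs
        far less than dropping the unique informative signal."""
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (300, 3))
        X[:, 1] = X[:, 0]
        y = (X[:, 0] > 0).astype(float)
        net = _trained_net(X, y, 3)
        _, inc = prune_step(net, X, y, {f"in{i}": [i] for i in range(3)}, "input")
        cheapest_dup = min(inc["in0"], inc["in1"])
        # removing either duplicate alone must be far cheaper than the
        # total information loss from removing both
        both = prune_step(net, X, y, {"pair": [0, 1], "noise": [2]}, "input")[1]["pair"]
        assert cheapest_dup < 0.2 * both

    def test_tie_breaks_to_first_listed(self):
        """Two inputs with identical (zero) increments: the one listed
        first in the candidate order is removed."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] > 0).astype(float)
        net = EdgeNetwork(np.array([[3.0, 0.0, 0.0, 0.0]]), np.zeros(1), np.array([4.0]), -2.0)
        best, inc = prune_step(net, X, y, {f"in{i}": [i] for i in range(4)}, "input")
        assert inc["in1"] == inc["in3"] == 0.0
        assert best == "in1"

    def test_hidden_mode(self):
        """A hidden unit with zero output weight is free to remove."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] > 0).astype(float)
        W1 = np.array([[3.0, 0.0], [1.0, 1.0], [1.0, 0.0]])
        net = EdgeNetwork(W1, np.zeros(3), np.array([4.0, 0.0, 1.0]), -2.5)
        best, inc = prune_step(net, X, y, {f"H{j}": j for j in range(3)}, "hidden")
        assert best == "H1"
        assert inc["H1"] == pytest.approx(0.0, abs=1e-15)
        assert inc["H0"] > 0

    def test_fewer_than_two_candidates_rejected(self):
        net = init_network(2, 2)
        with pytest.raises(ValueError):
            prune_step(net, np.zeros((4, 2)), np.zeros(4), {"a": [0]}, "input")


class TestDropEquivalence:
    def test_dropping_equals_zeroing(self):
        """Forward outputs after physically removing a column equal those
        of the intact network with that input forced silent."""
        net = init_network(5, 4, seed=6)
        net.feature_names = [f"f{i}" for i in range(5)]
        X = np.random.default_rng(6).normal(size=(20, 5))
        dropped = _drop_input_positions(net, [2])
        Xz = X.copy()
        Xz[:, 2] = 0.0
        assert np.allclose(forward(dropped, np.delete(X, 2, axis=1)), forward(net, Xz))
        assert dropped.feature_names == ["f0", "f1", "f3", "f4"]


class TestPruneFull:
    def test_trace_covers_all_but_survivor(self):
        X, y = _separable(7, n=240, p=5)
        net = _trained_net(X, y, 7)
        net.feature_names = [f"f{i}" for i in range(5)]
        trace = prune_full(net, X, y, mode="input", retrain_epochs=20,
                           cfg=TrainConfig(seed=7))
        assert len(trace.removal_order) == 4
        assert set(trace.removal_order + [trace.survivor]) == set(trace.component_names)
        assert all(0.0 <= s <= 1.0 for s in trace.scores)
        assert trace.n_remaining == [4, 3, 2, 1]
        frame = trace.as_frame()
        assert list(frame.columns) == [
            "removed", "loss_increment", "score_after_retrain", "n_remaining",
        ]

    def test_hidden_pruning_runs_to_one_unit(self):
        X, y = _separable(8, n=240, p=3)
        net = _trained_net(X, y, 8, hidden=5)
        trace = prune_full(net, X, y, mode="hidden", retrain_epochs=20,
                           cfg=TrainConfig(seed=8))
        assert len(trace.removal_order) == 4

    def test_grouped_input_pruning(self):
        X, y = _separable(9, n=240, p=6)
        net = _trained_net(X, y, 9)
        net.feature_names = [f"f{i}" for i in range(6)]
        groups = {"g0": [0, 1], "g1": [2, 3], "g2": [4, 5]}
        trace = prune_full(net, X, y, mode="input", groups=groups,
                           retrain_epochs=20, cfg=TrainConfig(seed=9))
        assert len(trace.removal_order) == 2
        assert set(trace.removal_order) < set(groups)

    def test_untrained_net_rejected(self):
        """A chance-level network (constant output 0.5 -> score exactly
        0.5 on a balanced set) must not enter the pruning loop."""
        X = np.random.default_rng(10).normal(size=(100, 4))
        y = np.r_[np.ones(50), np.zeros(50)]
        net = EdgeNetwork(np.zeros((4, 4)), np.zeros(4), np.zeros(4), 0.0)
        with pytest.raises(ValueError):
            prune_full(net, X, y)


def _trace(universe, order):
    t = PruneTrace("input", list(universe))
    t.removal_order = list(order)
    t.loss_increments = [0.0] * len(order)
    t.scores = [1.0] * len(order)
    t.n_remaining = list(range(len(universe) - 1, len(universe) - 1 - len(order), -1))
    return t


class TestSignificance:
    UNIVERSE = [f"c{i:02d}" for i in range(12)]

    def test_survivor_scores_ten_everywhere(self):
        order = self.UNIVERSE[1:]  # c00 survives
        traces = [_trace(self.UNIVERSE, order) for _ in range(5)]
        ranking = significance_scores(traces)
        top = ranking.iloc[0]
        assert top["component"] == "c00"
        assert top["score"] == 10.0 and top["occurrences"] == 5

    def test_component_outside_final_ten_scores_zero(self):
        order = self.UNIVERSE[1:]
        ranking = significance_scores([_trace(self.UNIVERSE, order)] * 5)
        row = ranking[ranking["component"] == self.UNIVERSE[1]].iloc[0]
        assert row["score"] == 0.0 and row["occurrences"] == 0

    def test_mean_of_mixed_depths(self):
        """Component scoring (10, 9, 8, 9, 7) across five traces -> 8.6."""
        traces = []
        for depth in (10, 9, 8, 9, 7):
            # 'cXX' removed so that it scores `depth`: it is at position
            # depth in the final sequence of 10
            others = [c for c in self.UNIVERSE if c != "c05"]
            seq = others[:2] + []  # first two removed, outside final ten
            rest = [c for c in others if c not in seq]
            final = rest + []
            final.insert(depth - 1, "c05")  # final ten, survivor last
            order = seq + final[:-1]
            traces.append(_trace(self.UNIVERSE, order))
        ranking = significance_scores(traces)
        row = ranking[ranking["component"] == "c05"].iloc[0]
        assert row["score"] == pytest.approx(8.6)
        assert row["occurrences"] == 5

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError):
            significance_scores(
                [_trace(self.UNIVERSE, self.UNIVERSE[1:]),
                 _trace(self.UNIVERSE[:6], self.UNIVERSE[1:6])]
            )


class TestSymmetry:
    def test_raw_signal_mirror_pairs(self):
        assert mirror_component("SUS_ON_D-Left", 4) == "SUS_ON_D-Right"
        assert mirror_component("TRN_OFF_U-LeftMid", 4) == "TRN_OFF_U-RightMid"
        assert mirror_component("SUS_ON_D-Left", 2) == "SUS_ON_D-Right"

    def test_inter_product_self_mirror(self):
        name = "SUS_ON_D-Left*SUS_ON_D-Right"
        assert mirror_component(name, 2) == name

    def test_intra_product_mirror(self):
        assert (
            mirror_component("SUS_ON_U*SUS_ON_D-LeftMid", 4)
            == "SUS_ON_U*SUS_ON_D-RightMid"
        )

    def test_mirror_is_involution(self):
        for name in ("SUS_OFF_D-RightMid", "TRN_ON_U-Left*SUS_OFF_D-LeftMid"):
            assert mirror_component(mirror_component(name, 4), 4) == name

    def test_undefined_mirror_raises(self):
        with pytest.raises(ValueError):
            mirror_component("H3", 4)

    def test_symmetric_ranking_has_zero_defects(self):
        ranking = pd.DataFrame(
            dict(
                component=["SUS_ON_D-Left", "SUS_ON_D-Right"],
                score=[7.4, 7.4],
                occurrences=[5, 5],
            )
        )
        report = symmetry_report(ranking, 2)
        assert np.all(report["defect"] == 0.0)
        assert not report["self_mirror"].any()

    def test_asymmetric_ranking_defect(self):
        ranking = pd.DataFrame(
            dict(component=["SUS_ON_D-Left", "SUS_ON_D-Right"], score=[8.6, 7.4],
                 occurrences=[5, 4])
        )
        report = symmetry_report(ranking, 2)
        assert np.allclose(report["defect"], 1.2)
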