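import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import random_digraph
from spanet.blockmodel import (
    ConcorBlockModel,
    block_density_matrix,
    block_flow_summary,
    classify_roles,
    concor_partition,
    image_matrix,
)
from spanet.containers import DirectedNetwork
from spanet.synthetic import generate_block_network
from spanet.whole import density


def _partition_sets(part):
    return {frozenset(part.members(k)) for k in range(part.n_blocks)}


class TestConcor:
    def test_recovers_separable_planted_blocks(self):
        net = generate_block_network([5, 5], p_in=1.0, p_out=0.0, seed=0)
        part = concor_partition(net, depth=1)
        assert _partition_sets(part) == {
            frozenset(net.labels[:5]), frozenset(net.labels[5:])
        }

    def test_depth_bounds_block_count(self):
        for seed in range(5):
            net = random_digraph(12, 0.35, seed=seed)
            part = concor_partition(net, depth=2)
            assert part.n_blocks <= 4
            assert sorted(part.assignment) == sorted(net.labels)

    def test_mirrored_star_components_separate(self):
        # star A: center sends to its leaves; star B: leaves send to center
        a = np.zeros((8, 8), int)
        a[0, [1, 2, 3]] = 1
        a[[5, 6, 7], 4] = 1
        net = DirectedNetwork([f"n{i}" for i in range(8)], a)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            part = concor_partition(net, depth=1)
        assert _partition_sets(part) == {
            frozenset(net.labels[:4]), frozenset(net.labels[4:])
        }

    def test_constant_profile_warns_not_raises(self):
        a = np.zeros((5, 5), int)
        a[0, 1] = a[1, 0] = a[1, 2] = 1  # nodes 3, 4 fully isolated
        net = DirectedNetwork(list("abcde"), a)
        with pytest.warns(RuntimeWarning, match="constant"):
            concor_partition(net, depth=1)

    def test_invariant_under_relabeling(self):
        net = generate_block_network([6, 6], 0.9, 0.1, seed=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(net.n)
        net2 = DirectedNetwork(
            [net.labels[i] for i in perm], net.a[np.ix_(perm, perm)]
        )
        p1 = concor_partition(net, depth=1)
        p2 = concor_partition(net2, depth=1)
        assert _partition_sets(p1) == _partition_sets(p2)

    def test_small_network_rejected(self):
        with pytest.raises(ValueError):
            concor_partition(random_digraph(3, 0.5, seed=0), depth=1)

    def test_sklearn_estimator_surface(self):
        net = generate_block_network([5, 5], 0.9, 0.05, seed=1)
        model = ConcorBlockModel(depth=1)
        labels = model.fit_predict(net.a)
        assert set(model.get_params()) >= {"depth", "conv_tol", "max_iter"}
        assert labels.shape == (10,)
        assert model.n_blocks_ == 2
        clone = ConcorBlockModel(**model.get_params())
        np.testing.assert_array_equal(clone.fit_predict(net.a), labels)


class TestBlockFlows:
    def test_arc_conservation_and_internal_symmetry(self):
        net = random_digraph(12, 0.3, seed=7)
        part = concor_partition(net, depth=2)
        flows = block_flow_summary(net, part)
        assert (flows["inside_received"] == flows["inside_sent"]).all()
        assert flows["outside_sent"].sum() == flows["outside_received"].sum()
        total = flows["inside_sent"].sum() + flows["outside_sent"].sum()
        assert total == net.n_arcs

    def test_internal_ratio_arithmetic(self):
        # inside 50 of 66 sent -> 76%; a 6-of-31 block expects 5/30 -> 17%
        assert round(100 * 50 / 66) == 76
        net = generate_block_network([6, 25], 0.5, 0.2, seed=1)
        part = concor_partition(net, depth=1)
        flows = block_flow_summary(net, part)
        for blk in flows.index:
            row = flows.loc[blk]
            expect = 100 * (row["n_members"] - 1) / (net.n - 1)
            assert row["expected_internal_ratio"] == pytest.approx(expect)
            if row["inside_sent"] + row["outside_sent"] > 0:
                assert row["actual_internal_ratio"] == pytest.approx(
                    100 * row["inside_sent"]
                    / (row["inside_sent"] + row["outside_sent"])
                )

    def test_single_block_partition_all_internal(self):
        net = generate_block_network([6], 0.8, 0.0, seed=2)
        part = concor_partition(net, depth=1, conv_tol=0.9)
        if part.n_blocks == 1:
            flows = block_flow_summary(net, part)
            assert flows["outside_sent"].iloc[0] == 0
            assert flows["actual_internal_ratio"].iloc[0] == 100.0


class TestDensityAndImage:
    def test_block_density_cells(self):
        # 26 internal arcs in a 6-node block -> 26/30; empty net -> zeros
        net = generate_block_network([6, 6], 1.0, 0.0, seed=0)
        part = concor_partition(net, depth=1)
        dm = block_density_matrix(net, part)
        assert np.diag(dm.to_numpy()) == pytest.approx([1.0, 1.0])
        empty = DirectedNetwork(net.labels, np.zeros_like(net.a))
        assert (block_density_matrix(empty, part).to_numpy() == 0).all()

    def test_size_weighted_average_equals_overall_density(self):
        for seed in range(5):
            net = random_digraph(13, 0.35, seed=seed)
            part = concor_partition(net, depth=2)
            dm = block_density_matrix(net, part).to_numpy()
            sizes = part.sizes().astype(float)
            w = np.outer(sizes, sizes)
            np.fill_diagonal(w, sizes * (sizes - 1))
            avg = (dm * w).sum() / (net.n * (net.n - 1))
            assert avg == pytest.approx(density(net), abs=1e-12)

    def test_image_matrix_thresholding(self):
        dm = pd.DataFrame(
            [[0.364, 0.018, 0.444, 0.355], [0.867, 0.250, 0.178, 0.055]],
            index=["IV", "II"], columns=["I", "II", "III", "IV"],
        )
        img = image_matrix(dm, 0.2688)
        assert img.loc["IV"].tolist() == [1, 0, 1, 1]
        assert img.loc["II"].tolist() == [1, 0, 0, 0]
        every = image_matrix(dm, 0.0)
        assert (every.to_numpy() == 1).all()


class TestRoles:
    @pytest.mark.parametrize(
        "received,sent,role",
        [
            (90, 34, "net_benefit"),
            (6, 42, "net_spillover"),
            (108, 66, "two_way_spillover"),
            (46, 108, "broker"),
        ],
    )
    def test_worked_example_assignments(self, received, sent, role):
        assert classify_roles([received], [sent]) == [role]

    def test_zero_sent_unclassifiable(self):
        assert classify_roles([5], [0]) == ["unclassifiable"]

    def test_custom_thresholds(self):
        assert classify_roles([3], [2], thresholds=(1.4, 1.0, 0.25)) == [
            "net_benefit"
        ]
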