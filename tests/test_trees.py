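"""Tree-ensemble inference: importances, thresholding, consensus, signs."""

import numpy as np
import pandas as pd
import pytest

from seedgrn.containers import PROMOTING, REGULATING, REPRESSING, ExpressionMatrix
from seedgrn.simulate import sample_ground_truth_network, simulate_time_course
from seedgrn.trees import (
    assign_signs,
    consensus_edges,
    infer_rtp_star,
    threshold_edges,
    tree_importance_matrix,
)


def expr_from_array(arr: np.ndarray, genes: list[str]) -> ExpressionMatrix:
    n = arr.shape[1]
    ids = [f"s{i}" for i in range(n)]
    times = [float(i // 2) for i in range(n)]
    reps = [i % 2 + 1 for i in range(n)]
    return ExpressionMatrix(
        values=pd.DataFrame(arr, index=pd.Index(genes, name="gene"), columns=ids),
        samples=pd.DataFrame({"sample_id": ids, "time_dap": times, "replicate": reps}),
    )


class TestImportanceMatrix:
    def test_single_regulator_gets_full_importance(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 5, size=12)
        y = 2 * x + rng.normal(0, 0.01, size=12)
        expr = expr_from_array(np.vstack([x, y]), ["r", "t"])
        imp = tree_importance_matrix(expr, ["r"], ensemble_size=50, seed=1)
        assert imp.at["r", "t"] == pytest.approx(1.0)
        assert imp.at["r", "r"] == 0.0

    def test_constant_target_column_is_zero(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 10)
        const = np.full(10, 3.0)
        expr = expr_from_array(np.vstack([x, const]), ["r", "c"])
        imp = tree_importance_matrix(expr, ["r"], ensemble_size=20, seed=0)
        assert (imp["c"] == 0).all()

    def test_informative_feature_dominates(self):
        rng = np.random.default_rng(2)
        x1 = rng.uniform(0, 4, 60)
        x2 = rng.uniform(0, 4, 60)
        y = 2 * x1 + rng.normal(0, 0.1, 60)
        expr = expr_from_array(np.vstack([x1, x2, y]), ["x1", "x2", "y"])
        imp = tree_importance_matrix(expr, ["x1", "x2"], ensemble_size=100, seed=3)
        assert imp.at["x1", "y"] > 5 * imp.at["x2", "y"]

    def test_columns_normalized(self):
        rng = np.random.default_rng(3)
        expr = expr_from_array(rng.uniform(0, 5, size=(5, 12)), list("abcde"))
        imp = tree_importance_matrix(expr, list("abc"), ensemble_size=30, seed=4)
        sums = imp.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_determinism(self):
        rng = np.random.default_rng(4)
        expr = expr_from_array(rng.uniform(0, 5, size=(6, 10)), list("abcdef"))
        a = tree_importance_matrix(expr, list("abcd"), 30, seed=7)
        b = tree_importance_matrix(expr, list("abcd"), 30, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestThresholdEdges:
    def mat(self, values: np.ndarray, regs, targets) -> pd.DataFrame:
        return pd.DataFrame(values, index=regs, columns=targets)

    def test_full_fraction_keeps_all_nonzero(self):
        rng = np.random.default_rng(5)
        regs = [f"r{i}" for i in range(4)]
        m = self.mat(rng.uniform(0.1, 1, size=(4, 4)), regs, regs)
        for r in regs:
            m.at[r, r] = 0.0
        m.at["r0", "r1"] = 0.0
        kept = threshold_edges(m, top_fraction=1.0)
        assert kept == {(r, t) for r in regs for t in regs if r != t and m.at[r, t] > 0}

    def test_all_equal_importances_all_retained(self):
        regs = ["a", "b", "c"]
        m = self.mat(np.full((3, 3), 0.5), regs, regs)
        for r in regs:
            m.at[r, r] = 0.0
        assert len(threshold_edges(m, top_fraction=0.1)) == 6

    def test_distinct_values_keep_exact_top(self):
        rng = np.random.default_rng(6)
        regs = [f"g{i}" for i in range(10)]
        vals = rng.permutation(np.linspace(0.01, 1, 90))
        m = pd.DataFrame(0.0, index=regs, columns=regs)
        k = 0
        for r in regs:
            for t in regs:
                if r != t:
                    m.at[r, t] = vals[k]
                    k += 1
        kept = threshold_edges(m, top_fraction=0.1)
        # brute force: the 10% largest of the 90 off-diagonal entries
        ranked = sorted(
            ((m.at[r, t], r, t) for r in regs for t in regs if r != t), reverse=True
        )
        expected = {(r, t) for _, r, t in ranked[:len(kept)]}
        assert kept == expected
        assert 9 <= len(kept) <= 10

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            threshold_edges(pd.DataFrame(), top_fraction=0.1)


class TestConsensus:
    def test_single_iteration_is_identity(self):
        s = {("a", "b"), ("c", "d")}
        assert set(consensus_edges([s], min_support=1)) == s

    def test_majority_counting(self):
        sets = [
            {("a", "b"), ("c", "d")},
            {("a", "b"), ("e", "f")},
            {("a", "b"), ("c", "d")},
            {("x", "y")},
            {("c", "d")},
        ]
        kept = consensus_edges(sets, min_support=3)
        assert set(kept) == {("a", "b"), ("c", "d")}
        assert kept[("a", "b")] == 3 and kept[("c", "d")] == 3

    def test_matches_brute_force_counts(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(8)]
        sets = []
        for _ in range(6):
            pairs = {
                (genes[int(a)], genes[int(b)])
                for a, b in rng.integers(0, 8, size=(12, 2))
                if a != b
            }
            sets.append(pairs)
        kept = consensus_edges(sets, min_support=2)
        for e in set().union(*sets):
            count = sum(e in s for s in sets)
            assert (e in kept) == (count >= 2)

    def test_monotone_in_support(self):
        rng = np.random.default_rng(8)
        sets = [
            {(f"g{int(a)}", f"t{int(b)}") for a, b in rng.integers(0, 6, size=(10, 2))}
            for _ in range(5)
        ]
        strict = set(consensus_edges(sets, min_support=5))
        majority = set(consensus_edges(sets, min_support=3))
        assert strict <= majority

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consensus_edges([])


class TestAssignSigns:
    def means(self, **profiles) -> pd.DataFrame:
        return pd.DataFrame({g: v for g, v in profiles.items()}).T

    def test_sign_categories(self):
        m = self.means(
            up=[1, 2, 3, 4, 5, 6],
            double=[2, 4, 6, 8, 10, 12],
            down=[12, 10, 8, 6, 4, 2],
            flat=[3, 3, 3, 3, 3, 3],
        )
        net = assign_signs(
            [("up", "double"), ("up", "down"), ("up", "flat")], m, tau=0.3
        )
        signs = {(e.source, e.target): e.sign for e in net.edges}
        assert signs[("up", "double")] == PROMOTING
        assert signs[("up", "down")] == REPRESSING
        assert signs[("up", "flat")] == REGULATING

    def test_antisymmetry_under_reflection(self):
        rng = np.random.default_rng(9)
        src = rng.uniform(0, 5, 6)
        tgt = src * 1.3 + rng.normal(0, 0.2, 6)
        reflected = 2 * tgt.mean() - tgt
        m = self.means(s=src, t=tgt, tr=reflected)
        net = assign_signs([("s", "t"), ("s", "tr")], m)
        signs = {e.target: e.sign for e in net.edges}
        assert {signs["t"], signs["tr"]} == {PROMOTING, REPRESSING}

    def test_missing_profile_rejected(self):
        m = self.means(a=[1, 2, 3])
        with pytest.raises(ValueError):
            assign_signs([("a", "missing")], m)


class TestInferEndToEnd:
    def test_noise_free_single_edge_recovered(self):
        net = sample_ground_truth_network(6, 1, 1.2, 0.0, seed=13)
        assert len(net.edges) >= 1
        expr = simulate_time_course(net, noise_sd=0.0, seed=2)
        inferred = infer_rtp_star(
            expr, regulators=net.regulators, iterations=3, ensemble_size=60,
            top_fraction=0.2, seed=5,
        )
        assert net.edge_pairs & inferred.edge_pair_set()

    def test_same_seed_same_network(self):
        net = sample_ground_truth_network(15, 4, 2, 0.3, seed=1)
        expr = simulate_time_course(net, seed=3)
        a = infer_rtp_star(expr, net.regulators, iterations=2, ensemble_size=40, seed=9)
        b = infer_rtp_star(expr, net.regulators, iterations=2, ensemble_size=40, seed=9)
        assert a.edges == b.edges
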