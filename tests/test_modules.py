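"""Module discovery: adjacency, TOM, eigenvectors, Wilcoxon, coherence, grid."""

import itertools
import math

import numpy as np
import pytest

from pathstack import (
    ModuleGridConfig,
    cluster_modules,
    explanatory_fraction,
    grid_select,
    make_pathway_scores,
    module_eigenvector,
    module_phenotype_test,
    significant_modules,
    soft_adjacency,
    topological_overlap,
)


def tom_by_triple_sum(A):
    """Independent oracle: direct evaluation of the overlap formula."""
    n = A.shape[0]
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = sum(A0[i, u] * A0[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (num + A0[i, j]) / (min(k[i], k[j]) + 1 - A0[i, j])
    return out


def power_iteration_first_left_singular(Z, iters=2000):
    """Independent oracle for the dominant left singular vector."""
    G = Z @ Z.T
    v = np.ones(G.shape[0]) / math.sqrt(G.shape[0])
    for _ in range(iters):
        v = G @ v
        v = v / np.linalg.norm(v)
    return v


class TestSoftAdjacency:
    def test_identical_columns_and_exponent(self, rng):
        y = rng.standard_normal(50)
        S = np.column_stack([y, y, rng.standard_normal(50)])
        A, keep = soft_adjacency(S, beta=1.0)
        assert A[0, 1] == pytest.approx(1.0)
        assert 0.5 ** 6 == pytest.approx(0.015625)

    def test_independent_columns_near_zero(self, rng):
        S = rng.standard_normal((2000, 3))
        A, _ = soft_adjacency(S, beta=6.0)
        off = A[~np.eye(3, dtype=bool)]
        assert (off < 0.01).all()

    def test_constant_columns_removed_with_warning(self, rng):
        S = np.column_stack([rng.standard_normal(20), np.full(20, 0.5),
                             rng.standard_normal(20)])
        with pytest.warns(UserWarning, match="constant"):
            A, keep = soft_adjacency(S)
        assert keep.tolist() == [0, 2]

    def test_invalid_beta(self, rng):
        with pytest.raises(ValueError):
            soft_adjacency(rng.standard_normal((10, 2)), beta=0)


class TestTopologicalOverlap:
    def test_complete_graph_overlap_is_one(self):
        A = np.ones((3, 3))
        tom = topological_overlap(A)
        # (1 + 1) / (2 + 1 - 1) = 1 for every off-diagonal pair
        assert tom == pytest.approx(np.ones((3, 3)))

    def test_empty_graph_zero_off_diagonal(self):
        tom = topological_overlap(np.eye(4))
        assert tom == pytest.approx(np.eye(4))

    def test_matches_triple_sum_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 7))
            A = rng.random((n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            assert topological_overlap(A) == pytest.approx(tom_by_triple_sum(A),
                                                           abs=1e-12)

    def test_range_and_symmetry(self, rng):
        A = rng.random((8, 8))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        tom = topological_overlap(A)
        assert (tom >= 0).all() and (tom <= 1).all()
        assert tom == pytest.approx(tom.T)

    def test_asymmetric_input_rejected(self, rng):
        A = rng.random((4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(A)


class TestEigenvector:
    def test_rank_one_module_recovers_column(self, rng):
        v = rng.standard_normal(30)
        S = np.column_stack([2 * v + 1, -3 * v, 0.5 * v])
        e = module_eigenvector(S, [0, 1, 2])
        z = (v - v.mean()) / v.std()
        r = np.corrcoef(e, z)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-10

    def test_sign_equivariant_under_column_flip(self, rng):
        """Flipping every column flips the alignment reference, hence the
        eigenvector: the convention is equivariant, and deterministic."""
        S = rng.standard_normal((40, 3))
        e1 = module_eigenvector(S, [0, 1, 2])
        e2 = module_eigenvector(-S, [0, 1, 2])
        assert e1 == pytest.approx(-e2, abs=1e-10)

    def test_matches_power_iteration(self, rng):
        S = rng.standard_normal((25, 3))
        e = module_eigenvector(S, [0, 1, 2])
        Z = (S - S.mean(axis=0)) / S.std(axis=0)
        v = power_iteration_first_left_singular(Z)
        if np.dot(v, e) < 0:
            v = -v
        assert e == pytest.approx(v, abs=1e-8)

    def test_constant_column_errors(self, rng):
        S = np.column_stack([np.full(10, 1.0), rng.standard_normal(10)])
        with pytest.raises(ValueError, match="constant"):
            module_eigenvector(S, [0, 1])


def wilcoxon_exact_by_enumeration(cases, controls):
    """Enumerate all assignments of ranks to the case group (no ties)."""
    pooled = np.concatenate([cases, controls])
    n, m = len(cases), len(controls)
    ranks = stats_rankdata(pooled)
    observed = ranks[:n].sum()
    null = [sum(comb) for comb in itertools.combinations(ranks, n)]
    null = np.array(null)
    mean = null.mean()
    p = np.mean(np.abs(null - mean) >= np.abs(observed - mean) - 1e-9)
    return p


def stats_rankdata(x):
    from scipy.stats import rankdata

    return rankdata(x)


class TestWilcoxon:
    def test_complete_separation_5v5(self):
        cases = np.array([6.0, 7, 8, 9, 10])
        controls = np.array([1.0, 2, 3, 4, 5])
        y = np.array([0] * 5 + [1] * 5)
        e = np.concatenate([controls, cases])
        p = module_phenotype_test(e, y)
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_matches_enumeration_for_small_groups(self, rng):
        for n, m in [(3, 3), (4, 5), (5, 4), (6, 6), (7, 7), (2, 7)]:
            cases = rng.standard_normal(n)
            controls = rng.standard_normal(m)
            y = np.array([1] * n + [0] * m)
            e = np.concatenate([cases, controls])
            p = module_phenotype_test(e, y)
            p_oracle = wilcoxon_exact_by_enumeration(cases, controls)
            assert p == pytest.approx(p_oracle, rel=1e-9)

    def test_symmetric_interleaving_gives_p_one(self):
        e = np.array([1.0, 2, 3, 4])
        y = np.array([0, 1, 1, 0])
        assert module_phenotype_test(e, y) == pytest.approx(1.0)

    def test_null_calibration(self):
        rng = np.random.default_rng(55)
        y = np.array([0, 1] * 15)
        hits = 0
        runs = 500
        for _ in range(runs):
            e = rng.standard_normal(30)
            hits += module_phenotype_test(e, y) < 0.05
        assert 0.01 <= hits / runs <= 0.10

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            module_phenotype_test(np.arange(4.0), np.ones(4, dtype=int))


class TestExplanatoryFraction:
    ANC = {
        "P1": frozenset({"A"}), "P2": frozenset({"A", "B"}),
        "P3": frozenset({"A"}), "P4": frozenset({"B"}),
    }

    def test_toy_dag_three_quarters(self):
        frac, anc = explanatory_fraction(["P1", "P2", "P3", "P4"], self.ANC)
        assert frac == 0.75 and anc == "A"

    def test_full_and_zero_coverage(self):
        frac, anc = explanatory_fraction(["P1", "P2", "P3"], self.ANC)
        assert frac == 1.0 and anc == "A"
        frac, anc = explanatory_fraction(["X"], {"X": frozenset()})
        assert frac == 0.0 and anc is None

    def test_member_missing_from_map_counts_in_denominator(self):
        with pytest.warns(UserWarning, match="absent"):
            frac, anc = explanatory_fraction(["P1", "P3", "ZZ"], self.ANC)
        assert frac == pytest.approx(2 / 3) and anc == "A"

    def test_adding_member_sharing_dominant_ancestor_never_decreases(self):
        base, anc = explanatory_fraction(["P1", "P4"], self.ANC)
        grown, _ = explanatory_fraction(["P1", "P4", "P3"], self.ANC)
        assert grown >= base

    def test_tie_broken_by_smallest_ancestor_id(self):
        anc_map = {"Q1": frozenset({"B", "A"}), "Q2": frozenset({"A", "B"})}
        frac, anc = explanatory_fraction(["Q1", "Q2"], anc_map)
        assert frac == 1.0 and anc == "A"


def _planted_block_matrix(seed=5):
    blocks = [(10, 0.85, 1.0), (10, 0.85, 1.0)]
    S, y, members = make_pathway_scores(n_samples=120, blocks=blocks,
                                        n_noise=0, seed=seed)
    return S, y, members


class TestClustering:
    def test_recovers_two_planted_blocks(self):
        S, y, members = _planted_block_matrix()
        controls = S[y == 0]
        A, keep = soft_adjacency(controls, beta=6.0)
        tom = topological_overlap(A)
        ids = [f"P{i}" for i in range(S.shape[1])]
        asg = cluster_modules(tom, controls, ids, min_module_size=5,
                              merge_cut_height=0.15)
        assert asg.n_modules == 2
        found = {frozenset(m) for m in asg.modules.values()}
        expect = {frozenset(f"P{i}" for i in blk) for blk in members}
        assert found == expect

    def test_merge_height_near_one_merges_everything(self):
        S, y, members = _planted_block_matrix()
        controls = S[y == 0]
        A, _ = soft_adjacency(controls, beta=6.0)
        tom = topological_overlap(A)
        ids = [f"P{i}" for i in range(S.shape[1])]
        asg = cluster_modules(tom, controls, ids, min_module_size=5,
                              merge_cut_height=0.999)
        assert asg.n_modules == 1

    def test_min_size_larger_than_n_leaves_all_unassigned(self, rng):
        S = rng.standard_normal((30, 4))
        A, _ = soft_adjacency(S, beta=6.0)
        tom = topological_overlap(A)
        with pytest.warns(UserWarning):
            asg = cluster_modules(tom, S, list("abcd"), min_module_size=10,
                                  merge_cut_height=0.2)
        assert asg.n_modules == 0 and len(asg.unassigned) == 4

    def test_permutation_equivariance(self):
        S, y, members = _planted_block_matrix()
        controls = S[y == 0]
        perm = np.random.default_rng(2).permutation(S.shape[1])
        ids = [f"P{i}" for i in range(S.shape[1])]
        A1, _ = soft_adjacency(controls, beta=6.0)
        asg1 = cluster_modules(topological_overlap(A1), controls, ids, 5, 0.15)
        A2, _ = soft_adjacency(controls[:, perm], beta=6.0)
        asg2 = cluster_modules(topological_overlap(A2), controls[:, perm],
                               [ids[i] for i in perm], 5, 0.15)
        assert ({frozenset(m) for m in asg1.modules.values()}
                == {frozenset(m) for m in asg2.modules.values()})


class TestGridSelect:
    def _planted(self, seed=9):
        blocks = [(8, 0.85, 1.2), (8, 0.85, 1.2), (8, 0.85, 1.2), (8, 0.85, 1.2)]
        S, y, members = make_pathway_scores(n_samples=160, blocks=blocks,
                                            n_noise=20, seed=seed)
        ids = [f"GO:P{i:02d}" for i in range(S.shape[1])]
        ancestors = {}
        for b, blk in enumerate(members):
            for i in blk:
                ancestors[ids[i]] = frozenset({f"GO:ANC{b}"})
        for i in range(len(members) * 8, S.shape[1]):
            ancestors[ids[i]] = frozenset()
        return S, y, ids, members, ancestors

    def test_planted_blocks_selected_and_reported(self):
        S, y, ids, members, ancestors = self._planted()
        cfg = ModuleGridConfig(min_module_sizes=(5, 8), merge_cut_heights=(0.1, 0.2))
        report = grid_select(S[y == 0], S, y, ids, cfg, ancestors)
        # at least 3 of the 4 planted blocks recovered coherently
        recovered = 0
        for blk in members:
            blk_ids = {ids[i] for i in blk}
            for mid, mem in report.assignment.modules.items():
                if len(blk_ids & set(mem)) / len(mem) >= 0.8:
                    row = report.table.set_index("module_id").loc[mid]
                    if (row["explanatory_fraction"] >= 0.8
                            and row["wilcoxon_p"] < 0.05):
                        recovered += 1
                    break
        assert recovered >= 3
        assert report.mean_fraction > 0.5

    def test_single_grid_point_trivially_selected(self):
        S, y, ids, members, ancestors = self._planted()
        cfg = ModuleGridConfig(min_module_sizes=(5,), merge_cut_heights=(0.2,))
        report = grid_select(S[y == 0], S, y, ids, cfg, ancestors)
        assert report.chosen_min_module_size == 5
        assert report.chosen_merge_cut_height == 0.2
        assert set(report.table.columns) >= {"module_id", "size", "wilcoxon_p",
                                             "explanatory_fraction",
                                             "dominant_ancestor"}

    def test_permuted_ancestry_lowers_mean_fraction(self):
        S, y, ids, members, ancestors = self._planted()
        cfg = ModuleGridConfig(min_module_sizes=(5, 8), merge_cut_heights=(0.1, 0.2))
        aligned = grid_select(S[y == 0], S, y, ids, cfg, ancestors)
        rng = np.random.default_rng(17)
        vals = list(ancestors.values())
        shuffled = {k: vals[i] for k, i in
                    zip(ancestors, rng.permutation(len(vals)))}
        permuted = grid_select(S[y == 0], S, y, ids, cfg, shuffled)
        assert permuted.mean_fraction < aligned.mean_fraction

    def test_all_grid_points_empty_errors(self, rng):
        S = rng.standard_normal((40, 4))
        y = np.array([0, 1] * 20)
        cfg = ModuleGridConfig(min_module_sizes=(10,), merge_cut_heights=(0.2,))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="zero modules"):
                grid_select(S[y == 0], S, y, list("abcd"), cfg, {})


class TestSignificantModules:
    def test_threshold_filtering_and_order(self):
        import pandas as pd

        from pathstack.modules import ModuleAssignment, ModuleReport

        table = pd.DataFrame({
            "module_id": ["ME1", "ME2", "ME3"],
            "size": [10, 8, 6],
            "wilcoxon_p": [0.001, 0.2, 0.0005],
            "explanatory_fraction": [0.9, 0.95, 0.6],
            "dominant_ancestor": ["A", "B", "C"],
        })
        report = ModuleReport(assignment=ModuleAssignment({}, []), table=table,
                              eigenvectors=pd.DataFrame(), mean_fraction=0.8,
                              chosen_min_module_size=5, chosen_merge_cut_height=0.2)
        out = significant_modules(report, alpha=0.05, min_fraction=0.5)
        assert out["module_id"].tolist() == ["ME3", "ME1"]
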