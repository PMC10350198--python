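import numpy as np
import pytest
from scipy.optimize import linprog

from lesionsubtype.errors import (ArgumentError, SelectionError,
                                  UndefinedSimilarityError)
from lesionsubtype.subtyping import (ConsensusMatrix,
                                     affinity_propagation_consensus,
                                     cluster_similarity_summary,
                                     consensus_matrix, dip_statistic,
                                     dip_test, eta_squared_similarity,
                                     kmeans_eta, pac_score, select_solution)


class TestEtaSquared:
    def test_identical_maps_score_one(self):
        a = np.random.default_rng(0).normal(size=100)
        assert eta_squared_similarity(a, a) == pytest.approx(1.0)

    def test_anticorrelated_two_voxel_maps_score_zero(self):
        assert eta_squared_similarity([0.0, 1.0], [1.0, 0.0]) == \
            pytest.approx(0.0)

    def test_offset_breaks_similarity_unlike_pearson(self):
        a = np.random.default_rng(1).normal(size=50)
        assert eta_squared_similarity(a, a + 2.0) < 1.0
        assert np.corrcoef(a, a + 2.0)[0, 1] == pytest.approx(1.0)

    def test_both_constant_undefined(self):
        with pytest.raises(UndefinedSimilarityError):
            eta_squared_similarity(np.ones(10), np.ones(10))


def _blob_maps(rng, n_per_group, centers, n_vox=120, noise=0.05):
    maps, labels = [], []
    for g, c in enumerate(centers):
        template = np.zeros(n_vox)
        template[c:c + 15] = 1.0
        for _ in range(n_per_group):
            maps.append(template + rng.normal(0, noise, n_vox))
            labels.append(g)
    return np.array(maps), np.array(labels)


class TestKMeansEta:
    def test_identical_duplicate_groups_recovered_exactly(self):
        base = np.random.default_rng(0).normal(size=(2, 50))
        maps = np.repeat(base, 5, axis=0)
        labels, total, _ = kmeans_eta(maps, 2, n_replicates=5, seed=0)
        assert total == pytest.approx(0.0, abs=1e-9)
        assert len(np.unique(labels[:5])) == 1
        assert labels[0] != labels[5]

    def test_k_one_single_cluster(self):
        maps = np.random.default_rng(1).normal(size=(8, 30))
        labels, _, _ = kmeans_eta(maps, 1, n_replicates=3, seed=0)
        assert (labels == labels[0]).all()

    def test_best_replicate_no_worse_than_any(self):
        rng = np.random.default_rng(2)
        maps, _ = _blob_maps(rng, 6, [0, 40, 80], noise=0.3)
        _, best, totals = kmeans_eta(maps, 3, n_replicates=10, seed=3)
        assert best <= min(totals) + 1e-12

    def test_invalid_k_raises(self):
        with pytest.raises(ArgumentError):
            kmeans_eta(np.zeros((4, 10)), 0)


class TestConsensusMatrix:
    def test_duplicated_pair_always_coclusters(self):
        rng = np.random.default_rng(0)
        maps, _ = _blob_maps(rng, 4, [0, 60])
        maps[1] = maps[0]  # exact duplicate
        cm = consensus_matrix(maps, 2, n_runs=25, seed=1, kmeans_replicates=3)
        assert cm.values[0, 1] == pytest.approx(1.0)

    def test_block_structure_for_separated_groups(self):
        rng = np.random.default_rng(1)
        maps, labels = _blob_maps(rng, 6, [0, 60])
        cm = consensus_matrix(maps, 2, n_runs=40, seed=2, kmeans_replicates=5)
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(maps), dtype=bool)
        assert cm.values[same & off].min() >= 0.95
        assert cm.values[~same].max() <= 0.05

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(2)
        maps, _ = _blob_maps(rng, 4, [0, 50], noise=0.4)
        cm = consensus_matrix(maps, 2, n_runs=10, seed=0, kmeans_replicates=2)
        assert np.allclose(cm.values, cm.values.T)
        assert np.allclose(np.diag(cm.values), 1.0)
        assert cm.values.min() >= 0 and cm.values.max() <= 1

    def test_invalid_parameters_raise(self):
        maps = np.zeros((4, 10))
        with pytest.raises(ArgumentError):
            consensus_matrix(maps, 2, n_runs=0)
        with pytest.raises(ArgumentError):
            consensus_matrix(maps, 2, subsample_fraction=1.5)


def _dip_lp_oracle(x, n_grid=240):
    """Independent dip computation: minimax fit of a unimodal CDF on a fine
    grid (convex second differences before the mode, concave after, jump
    allowed at the mode only) solved as one LP per candidate mode cell."""
    x = np.sort(np.asarray(x, float))
    n = x.size
    lo_x, hi_x = x[0], x[-1]
    span = max(hi_x - lo_x, 1e-12)
    grid = np.linspace(lo_x - 0.02 * span, hi_x + 0.02 * span, n_grid)
    cell = np.clip(np.searchsorted(grid, x, side="left"), 1, n_grid - 1)
    bottoms, tops = np.arange(n) / n, (np.arange(n) + 1) / n
    val_lo = np.full(n_grid, -np.inf)
    val_hi = np.full(n_grid, np.inf)
    for i in range(n):
        c = cell[i]
        val_lo[c] = max(val_lo[c], tops[i])
        val_hi[c] = min(val_hi[c], bottoms[i])
        val_lo[c - 1] = max(val_lo[c - 1], bottoms[i])
        val_hi[c - 1] = min(val_hi[c - 1], bottoms[i])
    best = np.inf
    for mode in range(1, n_grid, 4):  # stride keeps the oracle affordable
        A_ub, b_ub = [], []
        for c in range(n_grid - 1):
            row = np.zeros(n_grid + 1)
            row[c], row[c + 1] = 1, -1
            A_ub.append(row)
            b_ub.append(0.0)
        for c in range(n_grid - 2):
            row = np.zeros(n_grid + 1)
            row[c], row[c + 1], row[c + 2] = 1, -2, 1
            if c + 2 <= mode - 1:
                A_ub.append(-row)
                b_ub.append(0.0)
            if c >= mode:
                A_ub.append(row)
                b_ub.append(0.0)
        for c in range(n_grid):
            if np.isfinite(val_lo[c]):
                row = np.zeros(n_grid + 1)
                row[c], row[-1] = -1, -1
                A_ub.append(row)
                b_ub.append(-val_lo[c])
            if np.isfinite(val_hi[c]):
                row = np.zeros(n_grid + 1)
                row[c], row[-1] = 1, -1
                A_ub.append(row)
                b_ub.append(val_hi[c])
        cost = np.zeros(n_grid + 1)
        cost[-1] = 1
        res = linprog(cost, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                      bounds=[(0, 1)] * n_grid + [(0, None)], method="highs")
        if res.success:
            best = min(best, res.fun)
    return best


class TestDip:
    def test_equally_spaced_data_minimum_dip(self):
        assert dip_statistic(np.linspace(0, 1, 10)) == pytest.approx(1 / 20)

    def test_two_equal_point_masses_quarter(self):
        assert dip_statistic([0.0] * 50 + [1.0] * 50) == pytest.approx(0.25)

    def test_nonnegative_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = dip_statistic(rng.normal(size=int(rng.integers(5, 60))))
            assert 0.0 <= d <= 0.25 + 1e-12

    @pytest.mark.parametrize("case", range(4))
    def test_matches_minimax_lp_oracle(self, case):
        rng = np.random.default_rng(40 + case)
        if case < 2:
            x = rng.uniform(size=12 + case)
        else:
            x = np.concatenate([rng.normal(-3, 0.2, 7),
                                rng.normal(3, 0.2, 7)])
        assert dip_statistic(x) == pytest.approx(_dip_lp_oracle(x), abs=7e-3)

    def test_bimodal_rejects_unimodality(self):
        x = np.array([0.0] * 100 + [1.0] * 100)
        _, p = dip_test(x, n_boot=200, seed=0)
        assert p < 0.01

    def test_gaussian_mostly_consistent_with_unimodality(self):
        rng = np.random.default_rng(1)
        hits = 0
        n_seeds = 10
        for _ in range(n_seeds):
            _, p = dip_test(rng.normal(size=200), n_boot=200, seed=0)
            hits += p > 0.05
        assert hits >= int(0.9 * n_seeds)

    def test_constant_values_dip_zero_p_one(self):
        assert dip_test(np.ones(10)) == (0.0, 1.0)


class TestPAC:
    def test_crisp_consensus_zero(self):
        vals = np.array([[1, 0, 1.0], [0, 1, 0], [1, 0, 1]])
        assert pac_score(vals) == 0.0

    def test_fully_ambiguous_one(self):
        vals = np.full((4, 4), 0.5)
        np.fill_diagonal(vals, 1.0)
        assert pac_score(vals) == 1.0

    def test_counting_example(self):
        entries = [0.05, 0.5, 0.95, 0.95, 0.08, 0.91]
        # embed in a 4x4 matrix's upper triangle
        m = np.eye(4)
        m[np.triu_indices(4, k=1)] = entries
        m = np.maximum(m, m.T)
        assert pac_score(m) == pytest.approx(1 / 6)

    def test_invalid_bounds_raise(self):
        with pytest.raises(ArgumentError):
            pac_score(np.eye(3), lower=0.9, upper=0.1)


def _synthetic_consensus(k_true, k, n_per=6, seed=0):
    """Consensus matrix as produced by subsampling data with k_true groups
    clustered at candidate k: crisp for k <= k_true, ambiguous above."""
    rng = np.random.default_rng(seed)
    n = k_true * n_per
    labels = np.repeat(np.arange(k_true), n_per)
    same = labels[:, None] == labels[None, :]
    if k <= k_true:
        vals = np.where(same, 1.0, 0.0)
        # merge groups consistently when k < k_true
        merged = labels % k
        vals = np.where(merged[:, None] == merged[None, :], 1.0, 0.0)
    else:
        vals = np.where(same, 0.5 + 0.1 * rng.random((n, n)), 0.0)
    vals = np.maximum(vals, vals.T)
    np.fill_diagonal(vals, 1.0)
    return ConsensusMatrix(values=vals, k=k, n_runs=100, subsample_fraction=0.6)


class TestSelectSolution:
    def test_largest_reliable_k_selected(self):
        consensus = {k: _synthetic_consensus(4, k, seed=k) for k in range(2, 7)}
        out = select_solution(consensus, n_boot=200, seed=0)
        assert out["k_selected"] == 4
        assert not out["fallback"]

    def test_single_surviving_candidate_selected(self):
        out = select_solution({3: _synthetic_consensus(3, 3)}, n_boot=200,
                              seed=0)
        assert out["k_selected"] == 3

    def test_all_unimodal_falls_back_with_warning(self, caplog):
        rng = np.random.default_rng(0)
        consensus = {}
        for k in (2, 3):
            vals = rng.uniform(0.45, 0.55, size=(20, 20))
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 1.0)
            consensus[k] = ConsensusMatrix(vals, k, 100, 0.6)
        import logging
        with caplog.at_level(logging.WARNING, logger="lesionsubtype.subtyping"):
            out = select_solution(consensus, n_boot=200, seed=0)
        assert out["fallback"]
        assert any("PAC" in r.message or "unimodal" in r.message
                   for r in caplog.records)

    def test_empty_candidates_raise(self):
        with pytest.raises(SelectionError):
            select_solution({})


class TestAffinityPropagation:
    def test_perfect_two_block_consensus(self):
        cm = _synthetic_consensus(2, 2, n_per=8)
        sol = affinity_propagation_consensus(cm, 2)
        assert sol.k_selected == 2
        labels = sol.assignments
        assert len(np.unique(labels[:8])) == 1
        assert labels[0] != labels[8]
        for c, ex in enumerate(sol.exemplars):
            assert labels[ex] == c

    def test_single_subject_self_exemplar(self):
        cm = ConsensusMatrix(np.ones((1, 1)), 1, 10, 0.6)
        sol = affinity_propagation_consensus(cm, 1)
        assert sol.assignments.tolist() == [0]
        assert sol.exemplars.tolist() == [0]

    def test_permutation_equivariance(self):
        cm = _synthetic_consensus(3, 3, n_per=5, seed=1)
        sol = affinity_propagation_consensus(cm, 3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(cm.values))
        cm2 = ConsensusMatrix(cm.values[np.ix_(perm, perm)], 3, 100, 0.6)
        sol2 = affinity_propagation_consensus(cm2, 3)
        # partitions agree modulo relabeling
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(sol.assignments[perm], sol2.assignments) == 1.0
        # exemplar membership: each reordered exemplar sits in the cluster of
        # the corresponding original exemplar (identity may differ on ties)
        for ex2 in perm[sol2.exemplars]:
            assert any(sol.assignments[ex2] == sol.assignments[ex1]
                       for ex1 in sol.exemplars)


class TestClusterSummary:
    def test_planted_groups_within_exceeds_between(self):
        rng = np.random.default_rng(0)
        maps, labels = _blob_maps(rng, 6, [0, 60])
        out = cluster_similarity_summary(maps, labels)
        assert out["mean_within"] > out["mean_between"]
        assert np.nanmin(out["per_subject_contrast"]) > 0

    def test_identical_maps_within_equals_between(self):
        maps = np.tile(np.arange(10.0), (6, 1))
        out = cluster_similarity_summary(maps, [0, 0, 0, 1, 1, 1])
        assert out["mean_within"] == pytest.approx(1.0)
        assert out["mean_between"] == pytest.approx(1.0)

    def test_singletons_flagged(self):
        rng = np.random.default_rng(1)
        maps = rng.normal(size=(5, 20))
        out = cluster_similarity_summary(maps, [0, 0, 0, 0, 1])
        assert out["singletons"] == [4]


class TestConsensusConvergence:
    def test_pac_stable_when_doubling_runs(self):
        """Doubling the number of consensus runs moves PAC by < 0.02 on a
        structured fixture."""
        rng = np.random.default_rng(5)
        maps, _ = _blob_maps(rng, 6, [0, 60], noise=0.3)
        pacs = []
        for n_runs in (40, 80):
            cm = consensus_matrix(maps, 2, n_runs=n_runs, seed=3,
                                  kmeans_replicates=4)
            pacs.append(pac_score(cm))
        assert abs(pacs[1] - pacs[0]) < 0.02
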