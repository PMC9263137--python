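import numpy as np
import pytest

from kcselect import (
    LabelVector,
    LatentProjection,
    RunConfig,
    SimulationSpec,
    evaluate_subset,
    find_k1,
    make_k_grid,
    nmi,
    simulate_classes,
    strategy_a,
)
from kcselect.strategy import SubsetEvaluation, _scan_k2


def _ev(k, pillai):
    return SubsetEvaluation(
        k=k, mode="G", Z=LatentProjection(np.zeros((5, 2))),
        labels=LabelVector(np.ones(5, dtype=int), 1), pillai=pillai,
    )


class TestFindK1:
    def test_argmax_over_grid(self):
        assert find_k1([_ev(10, 0.1), _ev(100, 0.9), _ev(1000, 0.4)]) == 100

    def test_tie_prefers_smaller_k(self):
        assert find_k1([_ev(5, 0.9), _ev(50, 0.9)]) == 5

    def test_all_zero_warns_and_returns_smallest(self):
        with pytest.warns(UserWarning):
            assert find_k1([_ev(3, 0.0), _ev(7, 0.0)]) == 3


class TestScanK2:
    def test_stated_nmi_sequence(self):
        # NMI at k = k1-1, k1-2, k1-3, ... = 0.99, 0.97, 0.80 -> k2 = k1 - 2
        k1 = 10
        seq = {9: 0.99, 8: 0.97, 7: 0.80}
        k2, flags = _scan_k2(lambda k: seq.get(k, 0.5), k1)
        assert k2 == k1 - 2 and not flags["boundary"]

    def test_all_above_threshold_boundary_convention(self):
        k2, flags = _scan_k2(lambda k: 0.99, 10)
        assert k2 == 1 and flags["boundary"]

    def test_immediate_drop_returns_k1(self):
        k2, _ = _scan_k2(lambda k: 0.2, 10)
        assert k2 == 10

    def test_grid_localization_matches_direct_scan(self):
        # k1 above the scan cap: grid localization + integer refinement must
        # find the same k2 as the unbounded downward scan
        k1 = 800
        drop_at = 613  # largest k with NMI < threshold

        def nmi_at(k):
            return 0.5 if k <= drop_at else 0.99

        grid = make_k_grid(1000)
        k2_direct, _ = _scan_k2(nmi_at, k1, cap=10**6)
        k2_grid, flags = _scan_k2(nmi_at, k1, cap=500, grid=grid)
        assert k2_direct == drop_at + 1
        assert k2_grid == k2_direct and not flags["budget_exhausted"]

    def test_budget_exhaustion_flagged(self):
        k2, flags = _scan_k2(lambda k: 0.99, 2000, cap=10, grid=range(2, 2000, 7))
        assert flags["budget_exhausted"] and k2 >= 1


class TestKGrid:
    def test_dense_plus_log_points(self):
        grid = make_k_grid(5000)
        assert grid[0] == 2 and grid[-1] == 5000
        assert list(grid[:49]) == list(range(2, 51))
        assert all(grid[i] < grid[i + 1] for i in range(len(grid) - 1))

    def test_small_p_is_dense(self):
        assert make_k_grid(7) == (2, 3, 4, 5, 6, 7)


@pytest.fixture(scope="module")
def planted():
    X, y = simulate_classes(
        SimulationSpec(n=75, p=60, n_informative=9, effect_size=3.0, seed=5)
    )
    cfg = RunConfig(n_clusters=3, seed=13, dense_k_max=15, n_log_grid=8)
    return X, y, cfg


class TestEvaluateSubset:
    def test_cache_returns_identical_object(self, planted):
        X, _, cfg = planted
        cache = {}
        order = np.arange(X.p)
        e1 = evaluate_subset(X, order, 5, "G", 3, cfg, cache)
        e2 = evaluate_subset(X, order, 5, "G", 3, cfg, cache)
        assert e1 is e2

    def test_full_subset_reproduces_all_feature_evaluation(self, planted):
        """k = p with the identity ordering equals running the embedding and
        clustering directly on the full matrix."""
        from kcselect import (
            kmeans_cluster,
            pillai_trace,
            similarity_to_affinities,
            single_kernel_similarity,
            tsne_embed,
        )
        from kcselect.data import child_seed

        X, _, cfg = planted
        e = evaluate_subset(X, np.arange(X.p), X.p, "G", 3, cfg, {})
        S = single_kernel_similarity(X.values, k=cfg.single_k, sigma=cfg.single_sigma)
        Z = tsne_embed(
            similarity_to_affinities(S), d=cfg.latent_dim,
            seed=child_seed(cfg.seed, "tsne", "G", X.p),
            n_iter=cfg.tsne_iters, learning_rate=cfg.tsne_learning_rate,
            early_exaggeration=cfg.tsne_early_exaggeration,
        )
        y = kmeans_cluster(Z, 3, restarts=cfg.kmeans_restarts,
                           seed=child_seed(cfg.seed, "kmeans", "G", X.p))
        np.testing.assert_array_equal(e.Z.coords, Z.coords)
        np.testing.assert_array_equal(e.labels.labels, y.labels)
        assert e.pillai == pytest.approx(pillai_trace(Z, y))

    def test_degenerate_subset_rejected(self, planted):
        _, _, cfg = planted
        from kcselect import ExpressionMatrix
        from kcselect.strategy import DegenerateSubsetError

        Xc = ExpressionMatrix(
            np.ones((10, 3)), [f"c{i}" for i in range(10)], ["a", "b", "c"]
        )
        with pytest.raises(DegenerateSubsetError, match="2"):
            evaluate_subset(Xc, np.arange(3), 2, "G", 2, cfg, {})


class TestStrategyPipeline:
    @pytest.fixture(scope="class")
    def runs(self, planted):
        X, y, cfg = planted
        out = []
        for s in range(10):
            # strong structure: clean (dropout-free) marker genes
            Xs, ys = simulate_classes(
                SimulationSpec(n=120, p=60, n_informative=12, effect_size=3.0,
                               informative_dropout=(0.0, 0.0, 0.0), seed=50 + s)
            )
            cfg_s = RunConfig(n_clusters=3, seed=s, dense_k_max=15, n_log_grid=8)
            out.append((strategy_a(Xs, 3, "kc", cfg_s), ys))
        return out

    def test_strong_structure_accepts_single_kernel_mode(self, runs):
        modes = [r.mode_used for r, _ in runs]
        finals = [nmi(r.labels, y) for r, y in runs]
        assert modes.count("G") >= 8
        assert np.median(finals) >= 0.9

    def test_selection_does_not_hurt_clustering(self, runs):
        """Final NMI vs truth within 0.05 of the all-features multi-kernel
        clustering in at least 8 of 10 seeds."""
        ok = sum(
            nmi(r.labels, y) >= nmi(r.reference_labels, y) - 0.05
            for r, y in runs
        )
        assert ok >= 8

    def test_structural_invariants(self, runs):
        from kcselect import rank_features

        for r, _ in runs:
            assert 1 <= r.k2 <= r.k1
            # the selected genes are exactly the top-k2 of the score ordering
            expected = rank_features(r.scores, max(r.k2, 1)).indices
            np.testing.assert_array_equal(r.subset.indices, expected)
            assert len(r.selected_gene_ids) == max(r.k2, 1)
            assert 0.0 <= r.adequacy_nmi <= 1.0

    def test_laplacian_method_contract(self, planted):
        X, _, cfg = planted
        r = strategy_a(X, 3, "laplacian", cfg)
        assert r.score_method == "laplacian"
        assert r.k2 >= 1
        assert np.unique(r.labels.labels).size <= 3

    def test_adequacy_failure_switches_to_multi_kernel(self):
        """When the single-kernel clustering cannot reproduce the
        multi-kernel view (driven here via a strict adequacy threshold on
        weakly structured data), the pipeline reruns in mode M and says so."""
        X, _ = simulate_classes(
            SimulationSpec(n=60, p=80, n_informative=8, effect_size=1.0,
                           dispersion=0.8, seed=3)
        )
        cfg = RunConfig(n_clusters=3, seed=11, adequacy_nmi=0.99,
                        dense_k_max=10, n_log_grid=6)
        r = strategy_a(X, 3, "kc", cfg)
        assert r.adequacy_nmi <= 0.99
        assert r.mode_used == "M"
        assert 1 <= r.k2 <= r.k1
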