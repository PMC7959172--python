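import numpy as np
import pytest

from proteosect import (
    PipelineConfig,
    SyntheticSpec,
    benchmark_methods,
    census,
    classify_missing,
    compute_threshold1,
    evaluate_rmse,
    impute_downshift,
    impute_knn,
    sectionalized_impute,
    simulate,
)
from proteosect.missingness import DISCARD, FLAG_ONE_GROUP, RETAIN
from conftest import make_matrix


def matrix_with_miss_counts(counts, n_per_group=20):
    """One protein per (miss_A, miss_B) pair, groups of `n_per_group`."""
    n = len(counts)
    values = np.random.default_rng(0).normal(size=(n, 2 * n_per_group)) + 10
    mask = np.zeros_like(values, dtype=bool)
    for i, (a, b) in enumerate(counts):
        mask[i, :a] = True
        mask[i, n_per_group : n_per_group + b] = True
    return make_matrix(values, mask, n_a=n_per_group)


class TestCensus:
    # strict-inequality boundaries around the discard (16,16) and
    # one-group (18,8) rules
    COMBOS = [
        ((17, 17), DISCARD),
        ((16, 16), RETAIN),
        ((16, 17), RETAIN),
        ((17, 16), RETAIN),
        ((16, 20), RETAIN),
        ((19, 5), FLAG_ONE_GROUP),
        ((5, 19), FLAG_ONE_GROUP),
        ((18, 7), RETAIN),   # 18 is not > 18
        ((19, 8), RETAIN),   # 8 is not < 8
    ]

    @pytest.mark.parametrize("counts,expected", COMBOS)
    def test_filter_rule_boundaries(self, counts, expected, config):
        m = matrix_with_miss_counts([counts])
        report = census(m, config)
        assert report.verdicts().iloc[0] == expected

    def test_counts_and_totals(self, config):
        m = matrix_with_miss_counts([(3, 5), (0, 0)])
        report = census(m, config)
        assert report.table.loc["P001", "miss_A"] == 3
        assert report.table.loc["P001", "miss_B"] == 5
        assert report.totals == {"A": 3, "B": 5}

    def test_invariant_to_sample_permutation_within_groups(self, rng, config):
        m, _ = simulate(SyntheticSpec(n_proteins=150, seed=4))
        base = census(m, config).verdicts()
        perm = np.concatenate([rng.permutation(20), 20 + rng.permutation(20)])
        shuffled = make_matrix(m.values[:, perm], m.missing_mask[:, perm], n_a=20)
        assert (census(shuffled, config).verdicts().values == base.values).all()


class TestThreshold1:
    def test_constant_cells_give_the_constant(self):
        m = make_matrix(np.full((2, 4), 7.0))
        assert compute_threshold1(m) == 7.0

    def test_hand_computed_value(self):
        # observed cells {0,0,2,2}: mean 1, sample sd 2/sqrt(3)
        m = make_matrix(np.array([[0.0, 0.0, 2.0, 2.0]]))
        expected = 1.0 + 2.0 * (2.0 / np.sqrt(3.0))
        assert compute_threshold1(m) == pytest.approx(expected, abs=1e-12)
        assert compute_threshold1(m) == pytest.approx(3.3094, abs=1e-4)

    def test_all_missing_is_error(self):
        m = make_matrix(np.full((2, 4), np.nan))
        with pytest.raises(ValueError):
            compute_threshold1(m)


class TestClassifyMissing:
    def test_boundary_mean_routes_downshift(self, config):
        # protein P002's observed mean equals threshold1 exactly -> not strictly above
        values = np.array([[0.0, 0.0, 0.0, np.nan], [1.0, 1.0, 1.0, np.nan]])
        m = make_matrix(values)
        report = census(m, config)
        t1 = float(np.nanmean(values[1]))
        routes = classify_missing(m, report, t1, config)
        assert routes[1, 3] == 1  # downshift

    def test_degenerate_low_threshold_routes_all_knn(self, config):
        values = np.array([[0.0, 1.0, 2.0, np.nan], [1.0, 1.0, 1.0, 2.0]])
        m = make_matrix(values)
        report = census(m, config)
        routes = classify_missing(m, report, -np.inf, config)
        assert routes[0, 3] == 2  # knn

    def test_high_abundance_protein_routes_knn(self, config):
        rngv = np.random.default_rng(0).normal(0, 1, size=(50, 4))
        rngv[0] = 100.0
        mask = np.zeros_like(rngv, dtype=bool)
        mask[0, 1] = True
        m = make_matrix(rngv, mask)
        report = census(m, config)
        t1 = compute_threshold1(m)
        routes = classify_missing(m, report, t1, config)
        assert routes[0, 1] == 2

    def test_flagged_protein_near_empty_group_forced_downshift(self):
        cfg = PipelineConfig()
        m = matrix_with_miss_counts([(19, 5)])
        extra = make_matrix(
            np.vstack([np.where(m.missing_mask, np.nan, m.values + 100),
                       np.random.default_rng(1).normal(size=(3, 40))]),
            n_a=20,
        )
        report = census(extra, cfg)
        assert report.verdicts().iloc[0] == FLAG_ONE_GROUP
        t1 = -np.inf  # would otherwise route everything to knn
        routes = classify_missing(extra, report, t1, cfg)
        assert (routes[0, :19] == 1).all()   # near-empty group cells: downshift
        assert (routes[0, 20:] != 1).all()


class TestDownshift:
    def test_zero_shrink_gives_exact_shifted_mean(self):
        cfg = PipelineConfig(shrink_factor=0.0)
        values = np.random.default_rng(2).normal(3, 2, size=(50, 4))
        mask = np.zeros_like(values, dtype=bool)
        mask[:5, 0] = True
        m = make_matrix(values, mask)
        fills, params = impute_downshift(m, mask, cfg, seed=0)
        s0 = m.sample_ids[0]
        expected = params.loc[s0, "mean"] - 1.8 * params.loc[s0, "sd"]
        assert all(v == pytest.approx(expected) for v in fills.values())

    def test_same_seed_identical_fills(self, config):
        values = np.random.default_rng(3).normal(size=(30, 4))
        mask = np.zeros_like(values, dtype=bool)
        mask[::3, 1] = True
        m = make_matrix(values, mask)
        f1, _ = impute_downshift(m, mask, config, seed=9)
        f2, _ = impute_downshift(m, mask, config, seed=9)
        assert f1 == f2

    def test_sparse_sample_is_error(self, config):
        values = np.array([[1.0, np.nan, 1.0, 1.0], [np.nan, np.nan, 2.0, 2.0]])
        m = make_matrix(values)
        cells = np.isnan(values)
        with pytest.raises(ValueError, match="fewer than 2 observed"):
            impute_downshift(m, cells, config, seed=0)

    def test_fill_moments_match_shifted_gaussian(self, config):
        """Empirical fill mean/sd converge to (Mean_s - 1.8 Sd_s, 0.3 Sd_s)."""
        rng = np.random.default_rng(4)
        obs = rng.normal(5.0, 2.0, size=3000)
        obs = (obs - obs.mean()) / obs.std(ddof=1) * 2.0 + 5.0  # exact moments
        col0 = np.concatenate([obs, np.full(2000, np.nan)])
        values = np.column_stack([col0] + [rng.normal(size=5000) for _ in range(3)])
        m = make_matrix(values)
        cells = np.zeros_like(values, dtype=bool)
        cells[3000:, 0] = True
        fills, _ = impute_downshift(m, cells, config, seed=1)
        draws = np.array(list(fills.values()))
        assert draws.mean() == pytest.approx(5.0 - 1.8 * 2.0, abs=0.05)
        assert draws.std(ddof=1) == pytest.approx(0.3 * 2.0, abs=0.05)


def knn_oracle(values, cells, k):
    """All-pairs brute-force reimplementation of the KNN fill convention."""
    values = np.asarray(values, float)
    n, m = values.shape
    fills, fallback = {}, []
    for i in range(n):
        for j in range(m):
            if not cells[i, j]:
                continue
            dists = []
            for u in range(n):
                if u == i:
                    continue
                shared = [
                    s for s in range(m)
                    if np.isfinite(values[i, s]) and np.isfinite(values[u, s])
                ]
                if not shared:
                    continue
                d = np.sqrt(
                    sum((values[i, s] - values[u, s]) ** 2 for s in shared)
                    / len(shared)
                )
                if np.isfinite(values[u, j]):
                    dists.append((d, u))
            if not dists:
                fallback.append((i, j))
                continue
            dists.sort(key=lambda t: (t[0], t[1]))
            nearest = dists[:k]
            zeros = [u for d, u in nearest if d == 0]
            if zeros:
                fills[(i, j)] = float(np.mean([values[u, j] for u in zeros]))
            else:
                w = np.array([1.0 / d for d, _ in nearest])
                v = np.array([values[u, j] for _, u in nearest])
                fills[(i, j)] = float((w * v).sum() / w.sum())
    return fills, fallback


class TestKnn:
    def test_identical_neighbor_copies_value(self):
        values = np.array([[1.0, 2.0, 3.0, np.nan], [1.0, 2.0, 3.0, 9.0],
                           [50.0, 60.0, 70.0, 80.0]])
        cells = np.isnan(values)
        fills, fb = impute_knn(values, cells, k=1)
        assert not fb
        assert fills[(0, 3)] == 9.0

    def test_equidistant_neighbors_average(self):
        values = np.array(
            [[0.0, 0.0, np.nan],
             [1.0, 1.0, 1.0],
             [-1.0, -1.0, 3.0]]
        )
        cells = np.isnan(values)
        fills, _ = impute_knn(values, cells, k=2)
        assert fills[(0, 2)] == pytest.approx(2.0)

    def test_single_protein_falls_back(self):
        values = np.array([[1.0, np.nan, 2.0, 4.0]])
        fills, fb = impute_knn(values, np.isnan(values), k=3)
        assert fills == {}
        assert fb == [(0, 1)]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(5, 31), rng.integers(4, 11)
        values = rng.normal(size=(n, m))
        values[rng.random((n, m)) < 0.25] = np.nan
        cells = np.isnan(values)
        k = int(rng.integers(1, 8))
        fills, fb = impute_knn(values, cells, k)
        ofills, ofb = knn_oracle(values, cells, k)
        assert set(fills) == set(ofills) and fb == ofb
        for key in fills:
            assert fills[key] == pytest.approx(ofills[key], abs=1e-10)


class TestSectionalized:
    def test_complete_matrix_is_identity(self, config):
        values = np.random.default_rng(5).normal(size=(30, 40))
        m = make_matrix(values, n_a=20)
        res = sectionalized_impute(m, config, seed=0)
        assert np.array_equal(res.matrix.values, values)
        assert (res.provenance == "observed").all()

    def test_output_complete_with_partitioned_provenance(self, config):
        m, _ = simulate(SyntheticSpec(n_proteins=400, seed=6))
        res = sectionalized_impute(m, config, seed=0)
        assert np.isfinite(res.matrix.values).all()
        kept = set(res.matrix.protein_ids)
        idx = [i for i, p in enumerate(m.protein_ids) if p in kept]
        sub_mask = m.missing_mask[idx]
        prov = res.provenance
        assert ((prov == "observed") == ~sub_mask).all()
        assert set(np.unique(prov)) <= {"observed", "downshift", "knn"}

    def test_high_abundance_missing_avoids_downshift(self, config):
        rng = np.random.default_rng(7)
        values = rng.normal(0, 0.5, size=(60, 40))
        values[:3] = rng.normal(100, 0.5, size=(3, 40))
        mask = np.zeros_like(values, dtype=bool)
        mask[0, 5], mask[1, 12], mask[2, 33] = True, True, True
        m = make_matrix(values, mask, n_a=20)
        res = sectionalized_impute(m, config, seed=0)
        assert "downshift" not in res.provenance

    def test_discarded_proteins_are_dropped(self, config):
        counts = [(17, 17), (0, 0), (1, 2), (3, 1)] + [(0, 0)] * 10
        m = matrix_with_miss_counts(counts)
        res = sectionalized_impute(m, config, seed=0)
        assert "P001" not in res.matrix.protein_ids
        assert res.matrix.n_proteins == 13


class TestRmse:
    def test_perfect_imputation_is_zero(self):
        x = np.arange(6.0).reshape(2, 3)
        assert evaluate_rmse(x, x, np.ones_like(x, bool)) == 0.0

    def test_single_cell_definition(self):
        t = np.array([[0.0]])
        i = np.array([[3.0]])
        assert evaluate_rmse(t, i, np.array([[True]])) == 3.0

    def test_hand_formula(self):
        t = np.array([[0.0, 0.0]])
        i = np.array([[1.0, -1.0]])
        assert evaluate_rmse(t, i, np.ones((1, 2), bool)) == 1.0

    def test_empty_mask_is_error(self):
        x = np.zeros((2, 2))
        with pytest.raises(ValueError):
            evaluate_rmse(x, x, np.zeros((2, 2), bool))


class TestBenchmark:
    def test_no_missing_all_methods_tie_at_zero(self, config):
        m, truth = simulate(SyntheticSpec(n_proteins=50, mcar_rate=0, mnar_rate=0, seed=8))
        tab = benchmark_methods(m, truth, config, seeds=[0, 1])
        assert (tab["rmse"] == 0).all()

    def test_pure_mnar_sectionalized_beats_knn_only(self, config):
        """Full left-censoring removes every donor below the cutoff, so KNN
        cannot reach the censored truth while the down-shift can."""
        m, truth = simulate(
            SyntheticSpec(n_proteins=800, mcar_rate=0.0, mnar_rate=1.0, seed=9)
        )
        tab = benchmark_methods(m, truth, config, seeds=[0]).set_index("method")
        assert tab.loc["sectionalized", "rmse"] < tab.loc["knn_only", "rmse"]

    def test_pure_mcar_high_abundance_coincides_with_knn(self, config):
        """When every missing cell routes to KNN the two methods are identical."""
        rng = np.random.default_rng(10)
        values = rng.normal(0, 1, size=(220, 40))
        values[:20] = rng.normal(60, 1, size=(20, 40))
        mask = np.zeros_like(values, dtype=bool)
        for i in range(20):
            mask[i, rng.integers(0, 40, size=2)] = True
        from proteosect import SyntheticTruth

        truth = SyntheticTruth(values.copy(), np.zeros(220, bool))
        m = make_matrix(values.copy(), mask, n_a=20)
        tab = benchmark_methods(m, truth, config, seeds=[0]).set_index("method")
        assert tab.loc["sectionalized", "rmse"] == pytest.approx(
            tab.loc["knn_only", "rmse"], abs=1e-12
        )
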