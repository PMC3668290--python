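"""MB-MDR engine: partition, labeling, step-2, maxT, oracle equivalence."""

import numpy as np
import pytest
from helpers_naive import naive_mbmdr, naive_single_step_top_p

from mbmdr_robust import (
    AnalysisConfig,
    GenotypeMatrix,
    SimulationConfig,
    analyze_all_pairs,
    label_cells,
    m170_high_indicator,
    maxt_adjust,
    pair_index,
    partition_pair,
    run_mbmdr,
    simulate_replicate,
    step2_statistic,
    stepdown_maxt,
)
from mbmdr_robust.core import _permutation_matrix


class TestPartition:
    def test_counts_partition_n(self, small_dataset):
        G, _ = small_dataset
        cells = partition_pair(G, 0, 3)
        assert cells.counts.sum() == G.n_individuals
        flat = np.concatenate([cells.indices[a][b] for a in range(3) for b in range(3)])
        assert np.array_equal(np.sort(flat), np.arange(G.n_individuals))

    def test_degenerate_single_cell(self):
        G = GenotypeMatrix(np.zeros((40, 2), dtype=int))
        cells = partition_pair(G, 0, 1)
        assert cells.counts[0, 0] == 40
        assert cells.counts.sum() == 40

    def test_hwe_expected_center_cell(self, rng):
        from mbmdr_robust import simulate_genotypes

        G = simulate_genotypes(5000, np.array([0.5, 0.5]), rng)
        cells = partition_pair(G, 0, 1)
        assert cells.counts[1, 1] == pytest.approx(5000 * 0.25, rel=0.1)

    def test_same_snp_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            partition_pair(small_dataset[0], 2, 2)


class TestLabeling:
    def test_small_cells_are_other(self, rng):
        # a cell with 9 individuals is O regardless of its trait values
        g1 = np.array([0] * 9 + [1] * 50 + [2] * 41)
        g2 = np.array([0] * 9 + [0] * 50 + [1] * 41)
        G = GenotypeMatrix(np.column_stack([g1, g2]))
        t = rng.normal(size=100)
        t[:9] += 100.0
        grid = label_cells(partition_pair(G, 0, 1), t, AnalysisConfig())
        assert grid.labels[0, 0] == "O"

    def test_constant_trait_all_other(self, small_dataset):
        G, _ = small_dataset
        cfg = AnalysisConfig(min_cell=2)
        grid = label_cells(partition_pair(G, 0, 1), np.ones(G.n_individuals), cfg)
        assert (grid.labels == "O").all()

    def test_shifted_cell_labeled_high_and_low(self, rng):
        g1 = np.array([0] * 50 + [1] * 250 + [2] * 200)
        g2 = np.array([0] * 50 + [1] * 250 + [0] * 200)
        G = GenotypeMatrix(np.column_stack([g1, g2]))
        t = rng.normal(size=500)
        t[:50] += 10.0  # cell (0,0) far above the rest
        t[300:] -= 10.0  # cell (2,0) far below
        grid = label_cells(partition_pair(G, 0, 1), t, AnalysisConfig())
        assert grid.labels[0, 0] == "H"
        assert grid.labels[2, 0] == "L"
        # empty cells fail the size rule and stay O
        assert grid.labels[0, 1] == "O"


class TestStep2:
    def test_all_other_is_zero(self, small_dataset):
        G, t = small_dataset
        cells = partition_pair(G, 0, 1)
        grid = label_cells(cells, np.ones(G.n_individuals), AnalysisConfig(min_cell=2))
        assert step2_statistic(grid, cells, np.ones(G.n_individuals),
                               AnalysisConfig(min_cell=2)) == 0.0

    def test_matches_two_group_test_on_pooling(self, rng):
        from mbmdr_robust import student_t

        g1 = np.array([0] * 100 + [1] * 250 + [2] * 150)
        g2 = np.array([1] * 100 + [1] * 250 + [0] * 150)
        G = GenotypeMatrix(np.column_stack([g1, g2]))
        t = rng.normal(size=500)
        t[:100] += 5.0
        cfg = AnalysisConfig()
        cells = partition_pair(G, 0, 1)
        grid = label_cells(cells, t, cfg)
        assert grid.labels[0, 1] == "H"
        f = step2_statistic(grid, cells, t, cfg)
        h_mask = np.zeros(500, dtype=bool)
        for a in range(3):
            for b in range(3):
                if grid.labels[a, b] == "H":
                    h_mask[cells.indices[a][b]] = True
        f_ref = student_t(t[h_mask], t[~h_mask]).f_value
        assert f == pytest.approx(max(f_ref, f))  # F_H is a candidate
        assert f >= f_ref - 1e-9


class TestAllPairs:
    def test_pair_count_and_order(self, small_dataset):
        G, t = small_dataset
        F = analyze_all_pairs(G, t, AnalysisConfig(min_cell=5))
        assert F.shape == (10,)
        ii, jj = pair_index(5)
        assert (ii < jj).all()

    def test_row_permutation_invariance(self, small_dataset):
        G, t = small_dataset
        cfg = AnalysisConfig(min_cell=5)
        F0 = analyze_all_pairs(G, t, cfg)
        perm = np.random.default_rng(1).permutation(G.n_individuals)
        F1 = analyze_all_pairs(GenotypeMatrix(G.values[perm]), t[perm], cfg)
        assert np.allclose(F0, F1)

    @pytest.mark.parametrize("test_kind", ["student", "welch"])
    def test_engine_matches_reference_ops(self, small_dataset, test_kind):
        G, t = small_dataset
        cfg = AnalysisConfig(test_kind=test_kind, min_cell=5)
        F = analyze_all_pairs(G, t, cfg)
        ii, jj = pair_index(G.n_snps)
        for k, (i, j) in enumerate(zip(ii, jj)):
            cells = partition_pair(G, i, j)
            grid = label_cells(cells, t, cfg)
            assert F[k] == pytest.approx(step2_statistic(grid, cells, t, cfg))


class TestStepdownMaxT:
    def test_floor_and_monotonicity(self, rng):
        obs = np.array([10.0, 3.0, 1.0, 0.5])
        perm = rng.chisquare(1, size=(4, 199))
        adj = stepdown_maxt(obs, perm)
        assert adj[0] == pytest.approx(1 / 200)  # observed max beats every max
        order = np.argsort(-obs)
        assert (np.diff(adj[order]) >= 0).all()
        assert ((adj >= 1 / 200) & (adj <= 1.0)).all()

    def test_top_rank_equals_single_step_maxt(self, rng):
        obs = rng.chisquare(1, size=6) * 3
        perm = rng.chisquare(1, size=(6, 199))
        adj = stepdown_maxt(obs, perm)
        assert adj[np.argmax(obs)] == pytest.approx(
            naive_single_step_top_p(list(obs), perm))


@pytest.mark.parametrize("test_kind", ["student", "welch"])
def test_naive_oracle_equivalence(test_kind, rng):
    """A loop-based re-implementation reproduces every statistic and adjusted p
    on a 4-SNP, n=60 instance with B=199 permutations."""
    from mbmdr_robust import simulate_genotypes

    G = simulate_genotypes(60, np.array([0.5, 0.5, 0.4, 0.3]), rng)
    t = rng.normal(size=60) + 1.5 * m170_high_indicator(G.values[:, 0], G.values[:, 1])
    cfg = AnalysisConfig(test_kind=test_kind, n_permutations=199, seed=17)
    table = run_mbmdr(G, t, cfg)
    perms = _permutation_matrix(t, cfg.n_permutations,
                                np.random.default_rng(cfg.seed))
    obs_ref, _, adj_ref = naive_mbmdr(G.values, t, perms, cfg)
    assert np.allclose(table["step2_F"], obs_ref, rtol=1e-9, atol=1e-12)
    assert np.array_equal(table["adjusted_p"].to_numpy(), adj_ref)

    # the spec'd maxt_adjust entry point agrees as well
    adj2 = maxt_adjust(G, t, table["step2_F"].to_numpy(), cfg,
                       np.random.default_rng(cfg.seed))
    assert np.array_equal(adj2, adj_ref)


class TestRunMbmdr:
    def test_constant_trait_no_findings(self, small_dataset):
        G, _ = small_dataset
        cfg = AnalysisConfig(min_cell=5, n_permutations=49)
        table = run_mbmdr(G, np.ones(G.n_individuals), cfg)
        assert (table["step2_F"] == 0.0).all()
        assert not table["significant"].any()

    def test_deterministic(self, small_dataset):
        G, t = small_dataset
        cfg = AnalysisConfig(min_cell=5, n_permutations=49, seed=9)
        t1 = run_mbmdr(G, t, cfg)
        t2 = run_mbmdr(G, t, cfg)
        assert t1.equals(t2)

    def test_affine_invariance(self, small_dataset):
        G, t = small_dataset
        cfg = AnalysisConfig(min_cell=5, n_permutations=99, seed=9)
        t1 = run_mbmdr(G, t, cfg)
        t2 = run_mbmdr(G, 2.5 * t - 7.0, cfg)
        assert np.array_equal(t1["adjusted_p"], t2["adjusted_p"])
        assert np.allclose(t1["step2_F"], t2["step2_F"])

    def test_planted_signal_attains_maximum(self):
        # strong checkerboard signal, m=10, n=500: the causal pair wins
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(n_individuals=500, n_noise_snps=8, g2=0.1,
                                   scenario="normal", seed=seed)
            G, t, _ = simulate_replicate(cfg, 0)
            F = analyze_all_pairs(G, t, AnalysisConfig())
            hits += int(np.argmax(F) == 0)  # pair (SNP1, SNP2) is row 0
        assert hits >= 18

    def test_rank_pipeline_monotone_invariance(self, small_dataset):
        from mbmdr_robust import apply_transform

        G, t = small_dataset
        cfg = AnalysisConfig(min_cell=5, n_permutations=99, seed=3)
        r1 = run_mbmdr(G, apply_transform("rank", t), cfg)
        r2 = run_mbmdr(G, apply_transform("rank", np.exp(t / 3.0)), cfg)
        assert r1.equals(r2)


class TestNullExport:
    def test_step2_dominates_cell_branch(self, rng):
        from mbmdr_robust import export_null_statistics, simulate_genotypes

        G = simulate_genotypes(300, np.full(6, 0.5), rng)
        t = rng.normal(size=300)
        cfg = AnalysisConfig(n_permutations=30, seed=5)
        f_cell = export_null_statistics(G, t, cfg, which="cell", cell=(0, 0))
        f_step2 = export_null_statistics(G, t, cfg, which="step2")
        assert f_cell.shape == f_step2.shape == (15 * 30,)
        # in the upper tail the step-2 max over labeled pools is larger
        assert np.quantile(f_step2, 0.95) >= np.quantile(f_cell, 0.95)

    def test_invalid_which(self, small_dataset):
        from mbmdr_robust import export_null_statistics

        G, t = small_dataset
        with pytest.raises(ValueError):
            export_null_statistics(G, t, AnalysisConfig(), which="bogus")
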