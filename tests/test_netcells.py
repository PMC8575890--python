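"""Network-cell statistics, consensus maps, drop-one-network sensitivity."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from gcaconn._utils import triu_index
from gcaconn.blocks import build_blocks
from gcaconn.factors import BifactorModel
from gcaconn.netcells import (
    cell_mean_abs_beta,
    cell_permutation_test,
    cell_table,
    consensus_map,
    drop_network,
    edge_betas,
    edge_cell_ids,
    num_cells,
    rerun_loso_per_drop,
)
from gcaconn.synth import CohortConfig, make_atlas, simulate_dataset


class TestCellGeometry:
    @pytest.mark.parametrize("n,expected", [(15, 120), (1, 1), (2, 3), (5, 15)])
    def test_num_cells(self, n, expected):
        assert num_cells(n) == expected

    def test_partition_is_exhaustive_and_exclusive(self):
        atlas = make_atlas(60, 15)
        ids = edge_cell_ids(atlas)
        assert ids.shape == (60 * 59 // 2,)
        assert ids.min() == 0 and ids.max() == num_cells(15) - 1
        cells = cell_table(atlas)
        assert len(cells) == 120
        # every edge in exactly one cell; totals add up
        counts = np.bincount(ids, minlength=120)
        assert counts.sum() == 1770
        assert (counts > 0).all()

    def test_edge_network_membership_consistent(self):
        atlas = make_atlas(12, 3)
        ids = edge_cell_ids(atlas)
        cells = cell_table(atlas)
        nets = atlas["network"].to_numpy()
        i, j = triu_index(12)
        for e in range(len(ids)):
            row = cells.iloc[ids[e]]
            assert {nets[i[e]], nets[j[e]]} <= {row["network_a"], row["network_b"]}


class TestEdgeBetas:
    def test_matches_per_edge_ols_oracle(self, rng):
        feats = rng.standard_normal((100, 20))
        y = rng.standard_normal(100)
        x_cov = rng.standard_normal((100, 3))
        betas = edge_betas(feats, y, x_cov)
        # brute force: residualize y, then per-edge standardized simple OLS
        x1 = np.column_stack([np.ones(100), x_cov])
        resid = y - x1 @ np.linalg.lstsq(x1, y, rcond=None)[0]
        rz = (resid - resid.mean()) / resid.std()
        for e in range(20):
            fz = (feats[:, e] - feats[:, e].mean()) / feats[:, e].std()
            b = np.linalg.lstsq(fz[:, None], rz, rcond=None)[0][0]
            assert abs(betas[e] - b) < 1e-10

    def test_pure_noise_betas_small(self, rng):
        betas = edge_betas(rng.standard_normal((5000, 10)), rng.standard_normal(5000))
        assert np.abs(betas).max() < 0.06

    def test_y_equal_to_edge_gives_unit_beta(self, rng):
        feats = rng.standard_normal((200, 5))
        betas = edge_betas(feats, feats[:, 2].copy())
        assert betas[2] == pytest.approx(1.0)

    def test_zero_variance_edge_warns_and_zeroes(self, rng):
        feats = rng.standard_normal((50, 4))
        feats[:, 1] = 7.0
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            betas = edge_betas(feats, rng.standard_normal(50))
        assert betas[1] == 0.0


class TestCellMeans:
    def test_constant_betas_give_constant_cell_means(self):
        atlas = make_atlas(12, 3)
        betas = np.full(66, -0.42)
        cells = cell_mean_abs_beta(betas, atlas)
        np.testing.assert_allclose(cells["mean_abs_beta"], 0.42)
        assert cells["n_edges"].sum() == 66

    def test_planted_cell_is_maximal(self, rng):
        atlas = make_atlas(12, 3)
        ids = edge_cell_ids(atlas)
        betas = rng.normal(0, 0.01, 66)
        betas[ids == 2] += 0.5
        cells = cell_mean_abs_beta(betas, atlas)
        assert cells["mean_abs_beta"].idxmax() == 2


class TestBenjaminiHochberg:
    def test_textbook_step_up_example(self):
        # hand computation: m=4, q=.05, thresholds .0125/.025/.0375/.05;
        # p(4)=.045 <= .05 so the step-up rule rejects all four
        p = np.array([0.001, 0.013, 0.04, 0.045])
        reject, q, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert reject.all()
        np.testing.assert_allclose(q, [0.004, 0.026, 0.045, 0.045], atol=1e-12)

    def test_step_up_partial_rejection(self):
        p = np.array([0.001, 0.013, 0.04, 0.9])
        reject, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert list(reject) == [True, True, False, False]


class TestCellPermutation:
    @pytest.fixture(scope="class")
    def planted_cells_dataset(self):
        cfg = CohortConfig(
            n_sites=4, subjects_per_site=(80, 90), n_parcels=20, n_networks=5,
            signal_cells=[("NET01", "NET02"), ("NET03", "NET03")],
            n_components=1, seed=77,
        )
        return simulate_dataset(cfg)

    def test_planted_cells_detected_others_mostly_not(self, planted_cells_dataset):
        ds = planted_cells_dataset
        y = BifactorModel(ds.task_table).fit().score(ds.task_table)
        blocks = build_blocks(ds.phenotypes)
        stats = cell_permutation_test(
            ds.features, y, None, ds.atlas, n_perm=200, seed=0, blocks=blocks
        )
        planted = {("NET01", "NET02"), ("NET03", "NET03")}
        flagged = {
            (r["network_a"], r["network_b"])
            for _, r in stats[stats["significant"]].iterrows()
        }
        assert planted <= flagged
        assert len(flagged - planted) <= 2

    def test_null_data_controls_fdr(self):
        cfg = CohortConfig(n_sites=3, subjects_per_site=(60, 70), n_parcels=20,
                           n_networks=5, brain_gca_corr=0.0,
                           proportion_mediated=0.0, seed=55)
        ds = simulate_dataset(cfg)
        y = BifactorModel(ds.task_table).fit().score(ds.task_table)
        stats = cell_permutation_test(
            ds.features, y, None, ds.atlas, n_perm=200, seed=1,
            blocks=build_blocks(ds.phenotypes),
        )
        assert stats["significant"].sum() <= 2  # 15 null cells at q=.05

    def test_zero_permutations_rejected(self, planted_cells_dataset):
        ds = planted_cells_dataset
        with pytest.raises(ValueError):
            cell_permutation_test(
                ds.features, np.zeros(ds.n_subjects), None, ds.atlas,
                n_perm=0, seed=0, blocks=build_blocks(ds.phenotypes),
            )


class TestConsensusMap:
    def test_single_component_identity(self, rng, small_dataset):
        # fixed-effects path against the OLS oracle on a tiny instance
        ds = small_dataset
        y = rng.standard_normal(ds.n_subjects)
        edge_map, info = consensus_map(ds, y, k=3, use_mixed=False)
        import statsmodels.api as sm
        from gcaconn.pcr import CovariateSpec, covariate_design, fit_pca

        spec = CovariateSpec.from_frame(ds.phenotypes)
        x_cov = covariate_design(ds.phenotypes, spec)
        _, comps, scores = fit_pca(ds.features)
        exog = np.column_stack([np.ones(ds.n_subjects), x_cov, scores[:, :3]])
        ols = sm.OLS(y, exog).fit()
        expected = comps[:, :3] @ ols.params[-3:]
        np.testing.assert_allclose(edge_map, expected, atol=1e-8)

    def test_weighted_sum_of_orthogonal_components(self, rng):
        # directly check map = sum_j coef_j * component_j
        from gcaconn.pcr import fit_pca

        cfg = CohortConfig(n_sites=3, subjects_per_site=(50, 60), n_parcels=12,
                           n_networks=3, seed=2)
        ds = simulate_dataset(cfg)
        y = rng.standard_normal(ds.n_subjects)
        edge_map, info = consensus_map(ds, y, k=2, use_mixed=False)
        _, comps, _ = fit_pca(ds.features)
        manual = info["coef"].to_numpy() @ comps[:, :2].T
        np.testing.assert_allclose(edge_map, manual, atol=1e-10)

    def test_recovers_planted_signal_map_at_default_scale(self):
        cfg = CohortConfig(n_sites=6, subjects_per_site=(100, 100), seed=19)
        ds = simulate_dataset(cfg)
        y = BifactorModel(ds.task_table).fit().score(ds.task_table)
        edge_map, _ = consensus_map(ds, y, k=10, use_mixed=False)
        truth_map = ds.ground_truth.signal_map
        r = np.corrcoef(edge_map, truth_map)[0, 1]
        assert abs(r) > 0.8

    def test_mixed_effects_path_close_to_fixed_effects(self, rng):
        cfg = CohortConfig(n_sites=3, subjects_per_site=(50, 60), n_parcels=12,
                           n_networks=3, seed=29)
        ds = simulate_dataset(cfg)
        y = BifactorModel(ds.task_table).fit().score(ds.task_table)
        mixed_map, _ = consensus_map(ds, y, k=3, use_mixed=True)
        ols_map, _ = consensus_map(ds, y, k=3, use_mixed=False)
        assert np.corrcoef(mixed_map, ols_map)[0, 1] > 0.95


class TestDropNetwork:
    def test_feature_count_combinatorics(self, small_dataset):
        # dropping m parcels of R leaves C(R - m, 2) edges
        ds = small_dataset
        reduced = drop_network(ds, "NET03")
        r, m = 20, 4
        assert reduced.n_features == (r - m) * (r - m - 1) // 2
        assert "NET03" not in set(reduced.atlas["network"])

    def test_unknown_network_raises(self, small_dataset):
        with pytest.raises(ValueError, match="not in atlas"):
            drop_network(small_dataset, "XXX")

    def test_cannot_drop_last_network(self, small_dataset):
        ds = small_dataset
        for net in ["NET01", "NET02", "NET03", "NET04"]:
            ds = drop_network(ds, net)
        with pytest.raises(ValueError, match="only network"):
            drop_network(ds, "NET05")

    def test_distributed_signal_gives_flat_profile(self):
        # the planted signal spans all networks, so no single drop collapses r
        cfg = CohortConfig(n_sites=3, subjects_per_site=(60, 70), n_parcels=15,
                           n_networks=5, seed=23)
        ds = simulate_dataset(cfg)
        table = rerun_loso_per_drop(ds, min_site_n=10, seed=4, k_grid=[5, 10])
        assert len(table) == 5
        full = run_r = None
        from gcaconn.loso import run_loso

        full = run_loso(ds, min_site_n=10, seed=4, k_grid=[5, 10]).mean_r
        assert (table["mean_r"] > full - 0.2).all()
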