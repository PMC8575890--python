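"""End-to-end orchestration: simulate/load -> connectomes -> factors -> LOSO
-> permutations -> network cells -> mediation, with one JSON report."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .blocks import build_blocks
from .config import RunConfig
from .dataset import StudyData
from .factors import BifactorModel, OneFactorModel
from .io import (load_atlas, load_features, load_phenotypes, save_atlas,
                 save_features, save_json, save_phenotypes)
from .loso import freedman_lane_null, low_motion_subset, perm_pvalue, run_loso
from .mediation import run_split_half_mediation
from .netcells import cell_permutation_test, num_cells
from .pcr import CovariateSpec, covariate_design
from .synth import simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["build_dataset", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def build_dataset(config: RunConfig) -> StudyData:
    if config.simulate:
        return simulate_dataset(config.cohort, mode=config.simulate_mode,
                                metric=config.metric)
    pheno = load_phenotypes(config.phenotypes_path)
    atlas = load_atlas(config.atlas_path)
    if config.features_path:
        features, subject_ids, metric = load_features(config.features_path)
        order = pd.Index(subject_ids).get_indexer(pheno["subject_id"])
        if (order < 0).any():
            raise ValueError("feature manifest does not cover every subject")
        return StudyData(pheno, features[order], atlas, metric=metric)
    if config.timeseries_path:
        from .connectome import subject_connectome
        from .io import load_timeseries

        runs = load_timeseries(config.timeseries_path)
        feats, keep = [], []
        for i, sid in enumerate(pheno["subject_id"]):
            try:
                conn = subject_connectome(
                    runs[sid], metric=config.metric,
                    censor_threshold=config.censor_threshold_mm,
                )
            except Exception as exc:  # noqa: BLE001
                logger.info("excluding subject %s: %s", sid, exc)
                continue
            feats.append(conn.features)
            keep.append(i)
            pheno.loc[pheno.index[i], "mean_fd"] = conn.mean_fd
        return StudyData(
            pheno.iloc[keep].reset_index(drop=True), np.asarray(feats), atlas,
            metric=config.metric,
        )
    raise ValueError("need features_path or timeseries_path when not simulating")


def _stage(report: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            report.setdefault("timings_s", {})[name] = round(dt, 2)
            if exc is not None:
                raise StageError(name, exc) from exc
            logger.info("stage %s: done in %.1fs", name, dt)

    return _Timer()


def run_all(config: RunConfig, write_outputs: bool = True) -> dict:
    """Run every enabled stage and aggregate headline outputs into one report."""
    out = Path(config.output_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "seed": config.seed,
            "config_hash": config.hash,
            "gcaconn_version": __version__,
            "numpy_version": np.__version__,
        }
    }

    with _stage(report, "dataset"):
        dataset = build_dataset(config)
        report["n_subjects"] = dataset.n_subjects
        report["n_features"] = dataset.n_features
        if write_outputs:
            save_phenotypes(dataset.phenotypes, out / "phenotypes.csv")
            save_atlas(out / "atlas.tsv", dataset.atlas)
            save_features(out / "features.h5", dataset.features,
                          dataset.phenotypes["subject_id"], dataset.metric)

    with _stage(report, "factors"):
        gca = BifactorModel(dataset.task_table).fit()
        ses = OneFactorModel(dataset.ses_table).fit()
        report["omega_h"] = gca.omega_h
        report["ses_variance_explained"] = ses.variance_explained
        gca_scores = gca.score(dataset.task_table)
        ses_scores = ses.score(dataset.ses_table)
        beta = float(np.corrcoef(
            (ses_scores - ses_scores.mean()) / ses_scores.std(),
            (gca_scores - gca_scores.mean()) / gca_scores.std(),
        )[0, 1])
        report["ses_gca_beta_standardized"] = beta

    with _stage(report, "loso"):
        loso = run_loso(
            dataset, covariates=config.covariates, k_grid=config.k_grid,
            min_site_n=config.min_site_n, seed=config.seed,
        )
        report["loso_mean_r_cv"] = loso.mean_r
        report["loso_mean_partial_eta2_cv"] = loso.mean_partial_eta2
        report["loso_per_site"] = loso.per_site

    if config.run_permutations:
        with _stage(report, "permutations"):
            blocks = build_blocks(dataset.phenotypes)
            null = freedman_lane_null(
                dataset, loso, n_perm=config.n_perm, seed=config.seed,
                blocks=blocks, covariates=config.covariates,
            )
            loso.p_perm = perm_pvalue(loso.mean_r, null)
            report["loso_p_perm"] = loso.p_perm
            if write_outputs:
                pd.DataFrame({"null_mean_r": null}).to_csv(
                    out / "null_distribution.csv", index=False
                )

    if config.run_low_motion:
        with _stage(report, "low_motion"):
            try:
                lm = low_motion_subset(dataset, config.low_motion_fd_mm,
                                       config.min_site_n)
                lm_loso = run_loso(
                    lm, covariates=config.covariates, k_grid=config.k_grid,
                    min_site_n=config.min_site_n, seed=config.seed,
                )
                report["low_motion_n"] = lm.n_subjects
                report["low_motion_mean_r_cv"] = lm_loso.mean_r
            except ValueError as exc:
                logger.warning("low-motion analysis skipped: %s", exc)
                report["low_motion_mean_r_cv"] = None

    if config.run_cells:
        with _stage(report, "cells"):
            spec = CovariateSpec.from_frame(dataset.phenotypes, config.covariates)
            x_cov = covariate_design(dataset.phenotypes, spec)
            blocks = build_blocks(dataset.phenotypes)
            cells = cell_permutation_test(
                dataset.features, gca_scores, x_cov, dataset.atlas,
                n_perm=config.n_perm_cells, seed=config.seed, blocks=blocks,
            )
            report["n_cells"] = num_cells(dataset.atlas["network"].nunique())
            report["n_significant_cells"] = int(cells["significant"].sum())
            report["n_elevated_cells"] = int(cells["elevated"].sum())
            if write_outputs:
                cells.to_csv(out / "cell_stats.csv", index=False)

    if config.run_mediation:
        with _stage(report, "mediation"):
            table, summary = run_split_half_mediation(
                dataset, n_splits=config.n_splits, seed=config.seed,
                covariates=config.covariates, k_grid=config.k_grid,
                n_sims=config.n_sims,
            )
            report["mean_proportion_mediated"] = summary["mean_proportion_mediated"]
            report["mediation_iqr"] = summary["iqr"]
            rep = summary["representative"]
            report["representative_mediation"] = {
                "a": rep.a, "b": rep.b, "c_prime": rep.c_prime,
                "total": rep.total,
                "proportion_mediated": rep.proportion_mediated,
            }
            if write_outputs:
                table.to_csv(out / "mediation_splits.csv", index=False)

    if write_outputs:
        save_json(out / "report.json", report)
    return report
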