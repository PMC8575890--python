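"""Spatial characterization of phenotype-related connectivity by network cell.

A *cell* is the set of edges linking one pair of large-scale networks
(including a network with itself): N networks give N(N+1)/2 cells — 120 for
the 15-network atlas.  Each edge's relationship with the phenotype is a
standardized simple-regression beta of the z-scored edge predicting the
covariate-residualized, z-scored phenotype; cell-level summaries average the
absolute betas, with significance from Freedman-Lane permutations and
Benjamini-Hochberg FDR across cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._utils import triu_index
from . import pcr as _pcr
from .blocks import ExchangeabilityBlocks, sample_permutations
from .dataset import StudyData

logger = logging.getLogger(__name__)

__all__ = [
    "num_cells",
    "cell_table",
    "edge_cell_ids",
    "edge_betas",
    "cell_mean_abs_beta",
    "cell_permutation_test",
    "consensus_map",
    "drop_network",
    "rerun_loso_per_drop",
    "ELEVATED_BETA_THRESHOLD",
]

#: annotation threshold for "elevated" mean |beta| cells
ELEVATED_BETA_THRESHOLD = 0.03


def num_cells(n_networks: int) -> int:
    """Between-network pairs plus within-network cells: N(N+1)/2."""
    if n_networks < 1:
        raise ValueError("need at least one network")
    return n_networks * (n_networks + 1) // 2


def cell_table(atlas: pd.DataFrame) -> pd.DataFrame:
    """All unordered network pairs in a canonical order (by atlas appearance)."""
    names = list(dict.fromkeys(atlas["network"]))
    rows = [
        {"cell_id": k, "network_a": names[i], "network_b": names[j]}
        for k, (i, j) in enumerate(
            (i, j) for i in range(len(names)) for j in range(i, len(names))
        )
    ]
    return pd.DataFrame(rows)


def edge_cell_ids(atlas: pd.DataFrame) -> np.ndarray:
    """Cell id of every edge in the canonical upper-triangle ordering."""
    names = list(dict.fromkeys(atlas["network"]))
    net_idx = {n: i for i, n in enumerate(names)}
    parcel_net = atlas["network"].map(net_idx).to_numpy()
    i, j = triu_index(len(atlas))
    a = np.minimum(parcel_net[i], parcel_net[j])
    b = np.maximum(parcel_net[i], parcel_net[j])
    n = len(names)
    # id of unordered pair (a, b), a <= b, in the cell_table ordering
    return (a * (2 * n - a + 1)) // 2 + (b - a)


def edge_betas(
    features: np.ndarray, y: np.ndarray, x_cov: Optional[np.ndarray] = None
) -> np.ndarray:
    """Per-edge standardized beta of each edge predicting residualized y.

    With both sides z-scored, the simple-regression beta is the Pearson
    correlation.  Zero-variance edges get beta 0 with a warning.
    """
    features = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    if x_cov is not None and np.size(x_cov):
        y, _ = _pcr.fit_covariates(y, x_cov)
    yz = (y - y.mean()) / y.std()
    fc = features - features.mean(axis=0)
    sd = features.std(axis=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance edges; betas set to 0",
            RuntimeWarning, stacklevel=2,
        )
        sd[dead] = 1.0
    betas = (fc / sd).T @ yz / len(y)
    betas[dead] = 0.0
    return betas


def cell_mean_abs_beta(betas: np.ndarray, atlas: pd.DataFrame) -> pd.DataFrame:
    """Mean |beta| per cell (the cell-level connectivity-association statistic)."""
    cells = cell_table(atlas)
    ids = edge_cell_ids(atlas)
    n_cells = len(cells)
    sums = np.bincount(ids, weights=np.abs(betas), minlength=n_cells)
    counts = np.bincount(ids, minlength=n_cells)
    cells = cells.copy()
    cells["n_edges"] = counts
    with np.errstate(invalid="ignore"):
        cells["mean_abs_beta"] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    cells["elevated"] = cells["mean_abs_beta"] > ELEVATED_BETA_THRESHOLD
    return cells


def cell_permutation_test(
    features: np.ndarray,
    y: np.ndarray,
    x_cov: Optional[np.ndarray],
    atlas: pd.DataFrame,
    n_perm: int,
    seed: int,
    blocks: ExchangeabilityBlocks,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Per-cell permutation test of elevated mean |beta|, BH-FDR corrected.

    The null recomputes every cell mean under Freedman-Lane permutations of
    the phenotype with the same exchangeability blocks as the main analysis;
    per-cell p-values use the add-one rule and are corrected across the
    N(N+1)/2 cells.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    if x_cov is not None and np.size(x_cov):
        resid, betas_cov = _pcr.fit_covariates(y, x_cov)
        fitted = y - resid
        x1 = np.column_stack([np.ones(len(y)), x_cov])
        hat = np.linalg.pinv(x1)
    else:
        resid, fitted = y - y.mean(), np.full(len(y), y.mean())
        x1, hat = np.ones((len(y), 1)), np.full((1, len(y)), 1.0 / len(y))

    obs = cell_mean_abs_beta(edge_betas(features, y, x_cov), atlas)
    ids = edge_cell_ids(atlas)
    n_cells = obs.shape[0]

    # z-scored features once; per permutation the betas are one matrix product
    sd = features.std(axis=0)
    sd[sd == 0] = 1.0
    fz = (features - features.mean(axis=0)) / sd

    perms = sample_permutations(blocks, n_perm, seed)
    y_star = fitted[:, None] + resid[perms].T           # n x n_perm
    resid_star = y_star - x1 @ (hat @ y_star)           # re-residualized
    resid_star = (resid_star - resid_star.mean(axis=0)) / resid_star.std(axis=0)
    null_betas = np.abs(fz.T @ resid_star / len(y))     # p x n_perm

    null_cell = np.zeros((n_cells, n_perm))
    np.add.at(null_cell, ids, null_betas)
    counts = np.bincount(ids, minlength=n_cells).astype(float)
    null_cell /= np.maximum(counts, 1.0)[:, None]

    obs_vals = obs["mean_abs_beta"].to_numpy()
    p = (1.0 + (null_cell >= obs_vals[:, None]).sum(axis=1)) / (1.0 + n_perm)
    reject, q, *_ = multipletests(p, alpha=fdr_q, method="fdr_bh")
    out = obs.copy()
    out["p_perm"] = p
    out["q_fdr"] = q
    out["significant"] = reject
    return out


# ---------------------------------------------------------------------------
# consensus maps
# ---------------------------------------------------------------------------

def consensus_map(
    dataset: StudyData,
    y: np.ndarray,
    k: Optional[int] = None,
    covariates: Optional[Sequence[str]] = None,
    use_mixed: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Edge-space consensus of phenotype-related connectivity components.

    A single whole-sample PCA yields component expression scores; the
    phenotype is regressed on all k scores with fixed covariates and random
    intercepts for family nested within site; each component map is weighted
    by its coefficient and the weighted maps are summed into one edge-space
    map.  If the mixed model fails to converge the fit falls back, loudly, to
    OLS with family-cluster-robust standard errors (identical coefficients).
    """
    pheno = dataset.phenotypes
    spec = _pcr.CovariateSpec.from_frame(pheno, covariates)
    x_cov = _pcr.covariate_design(pheno, spec)
    means, comps, scores = _pcr.fit_pca(dataset.features)
    if k is None:
        resid, _ = _pcr.fit_covariates(np.asarray(y, float), x_cov)
        k, _ = _pcr.select_k(
            dataset.features, resid, _pcr.default_k_grid(len(pheno)),
            pheno["family_id"].to_numpy(),
        )
    k = int(min(k, comps.shape[1]))
    scores = scores[:, :k]

    exog = np.column_stack([np.ones(len(pheno)), x_cov, scores])
    coefs = None
    if use_mixed:
        import statsmodels.api as sm

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = sm.MixedLM(
                    np.asarray(y, float), exog, groups=pheno["site"],
                    exog_vc=_family_vc(pheno),
                )
                fit = md.fit(reml=True, method="lbfgs", maxiter=200)
            if not fit.converged:
                raise RuntimeError("mixed model did not converge")
            coefs = np.asarray(fit.fe_params)
        except Exception as exc:  # noqa: BLE001 - fall back on any fit failure
            logger.warning(
                "mixed-effects consensus fit failed (%s); "
                "falling back to family-cluster-robust OLS", exc,
            )
            coefs = None
    if coefs is None:
        import statsmodels.api as sm

        ols = sm.OLS(np.asarray(y, float), exog).fit(
            cov_type="cluster", cov_kwds={"groups": pheno["family_id"]}
        )
        coefs = np.asarray(ols.params)

    comp_coefs = coefs[-k:]
    edge_map = comps[:, :k] @ comp_coefs
    info = pd.DataFrame({"component": np.arange(1, k + 1), "coef": comp_coefs})
    return edge_map, info


def _family_vc(pheno: pd.DataFrame):
    """Variance-component design: one indicator column per family."""
    fams = pd.get_dummies(pheno["family_id"], dtype=float)
    return {"family": {"fam": np.asarray(fams)}}


# ---------------------------------------------------------------------------
# drop-one-network sensitivity
# ---------------------------------------------------------------------------

def drop_network(dataset: StudyData, network_name: str) -> StudyData:
    """Remove every edge with either endpoint in the named network."""
    atlas = dataset.atlas
    if network_name not in set(atlas["network"]):
        raise ValueError(f"network {network_name!r} not in atlas")
    if atlas["network"].nunique() <= 1:
        raise ValueError("cannot drop the only network")
    in_net = (atlas["network"] == network_name).to_numpy()
    i, j = triu_index(len(atlas))
    edge_keep = ~(in_net[i] | in_net[j])
    new_atlas = atlas.loc[~in_net].reset_index(drop=True)
    return dataset.select_edges(edge_keep, atlas=new_atlas)


def rerun_loso_per_drop(dataset: StudyData, **loso_kwargs) -> pd.DataFrame:
    """Drop one network at a time, redoing the entire LOSO stream each time."""
    from .loso import run_loso

    rows = []
    for net in dict.fromkeys(dataset.atlas["network"]):
        res = run_loso(drop_network(dataset, net), **loso_kwargs)
        rows.append(
            {"dropped_network": net, "mean_r": res.mean_r,
             "mean_partial_eta2": res.mean_partial_eta2,
             "n_features": drop_network(dataset, net).n_features}
        )
    return pd.DataFrame(rows)
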