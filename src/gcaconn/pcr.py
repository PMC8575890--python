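"""Principal component regression (PCR) predictive modeling.

The predictive model that carries the whole pipeline: PCA on the training
connectivity-feature matrix, component count ``k`` chosen by family-blocked
five-fold cross-validation within the training data, ordinary least squares of
the covariate-residualized phenotype on the top-``k`` component expression
scores, and strictly out-of-sample application — test features are centered
with training means, projected onto training components, and covariate
coefficients learned on train are applied (never refitted) to test.

Out-of-sample performance is summarized by the cross-validated Pearson
correlation and a cross-validated partial eta squared defined as the variance
explained beyond covariates on test data,
``max(0, 1 - SSE_full / SSE_cov)`` with
``SSE_cov = sum(resid^2)`` and ``SSE_full = sum((resid - pred)^2)``, which
makes partial eta^2 track r^2 whenever predictions are well-scaled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_COVARIATES",
    "CovariateSpec",
    "PCRModel",
    "CVMetrics",
    "PCR",
    "PCRResults",
    "covariate_design",
    "fit_covariates",
    "apply_covariates",
    "fit_pca",
    "select_k",
    "fit_pcr",
    "predict",
    "cv_metrics",
    "default_k_grid",
]

DEFAULT_COVARIATES = ["sex", "race", "age", "age_sq", "mean_fd", "mean_fd_sq"]

_CATEGORICAL = {"sex", "race", "site"}
_SQUARES = {"age_sq": "age", "mean_fd_sq": "mean_fd"}


@dataclass
class CovariateSpec:
    """Ordered covariate list plus everything needed to rebuild the design.

    Categorical levels and centering constants are learned from the training
    sample so a test design is reproducible without refitting.
    """

    names: list
    cat_levels: dict = field(default_factory=dict)
    centers: dict = field(default_factory=dict)
    columns: list = field(default_factory=list)

    @classmethod
    def from_frame(cls, pheno: pd.DataFrame, names: Optional[Sequence[str]] = None) -> "CovariateSpec":
        names = list(DEFAULT_COVARIATES if names is None else names)
        spec = cls(names=names)
        for name in names:
            base = _SQUARES.get(name, name)
            if base not in pheno.columns:
                raise ValueError(f"covariate column {base!r} missing from phenotypes")
            if base in _CATEGORICAL:
                spec.cat_levels[base] = sorted(pheno[base].astype(str).unique())
            elif base not in spec.centers:
                spec.centers[base] = float(pheno[base].mean())
        return spec


def covariate_design(pheno: pd.DataFrame, spec: CovariateSpec) -> np.ndarray:
    """Build the (no-intercept) covariate matrix per the spec's train statistics.

    Continuous covariates are centered at training means before squaring, so
    quadratic terms stay well-conditioned; categoricals are one-hot with the
    first training level dropped.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name in spec.names:
        base = _SQUARES.get(name, name)
        if base in _CATEGORICAL:
            levels = spec.cat_levels[base]
            vals = pheno[base].astype(str)
            for lev in levels[1:]:
                cols.append((vals == lev).to_numpy(dtype=float))
                names.append(f"{name}[{lev}]")
        else:
            centered = pheno[base].to_numpy(dtype=float) - spec.centers[base]
            if name in _SQUARES:
                cols.append(centered**2)
            else:
                cols.append(centered)
            names.append(name)
    spec.columns = names
    if not cols:
        return np.empty((len(pheno), 0))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# covariate regression
# ---------------------------------------------------------------------------

def _collinear_columns(x: np.ndarray) -> list[int]:
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps * 1e3
    return np.flatnonzero(diag < tol).tolist()


def fit_covariates(y: np.ndarray, x_cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS of y on an intercept plus the covariates; returns (residuals, betas).

    ``betas[0]`` is the intercept.  A rank-deficient design raises with the
    offending column indices named.
    """
    y = np.asarray(y, dtype=float)
    x = np.column_stack([np.ones(len(y)), np.asarray(x_cov, dtype=float)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _collinear_columns(x)
        raise np.linalg.LinAlgError(
            f"covariate design is rank-deficient; collinear design columns "
            f"(0 = intercept): {bad}"
        )
    betas, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ betas, betas


def apply_covariates(
    y_test: np.ndarray, x_cov_test: np.ndarray, covariate_betas: np.ndarray
) -> np.ndarray:
    """Residualize test phenotypes with *train-fitted* covariate coefficients."""
    x = np.column_stack([np.ones(len(y_test)), np.asarray(x_cov_test, dtype=float)])
    return np.asarray(y_test, dtype=float) - x @ np.asarray(covariate_betas)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca(features: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-centered SVD; returns (means, components p x m, scores n x m).

    Components are ordered by decreasing variance with a deterministic sign
    convention: the largest-magnitude loading of each component is positive.
    """
    features = np.asarray(features, dtype=float)
    means = features.mean(axis=0)
    u, s, vt = np.linalg.svd(features - means, full_matrices=False)
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    return means, vt.T, u * s


def default_k_grid(n_train: int) -> list[int]:
    grid = [5, 10, 25, 50, 100, 250, 500]
    return [k for k in grid if 1 <= k <= n_train - 1] or [min(5, n_train - 1)]


def _family_folds(
    family_ids: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Row indices per fold; all members of a family land in one fold."""
    fams = np.unique(family_ids)
    rng.shuffle(fams)
    fold_of_fam = {f: i % n_folds for i, f in enumerate(fams)}
    assign = np.array([fold_of_fam[f] for f in family_ids])
    return [np.flatnonzero(assign == i) for i in range(n_folds)]


def select_k(
    features_train: np.ndarray,
    y_resid_train: np.ndarray,
    k_grid: Sequence[int],
    family_ids: Optional[np.ndarray] = None,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Pick k by family-blocked five-fold CV inside the training sample.

    Returns the k maximizing the mean held-out correlation (ties break toward
    the smallest k) plus the per-k path.  PCA is refitted inside every inner
    fold; because PCA scores are orthogonal, the nested-k regressions are a
    single projection swept cumulatively across components.
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("k grid is empty")
    n = len(y_resid_train)
    k_grid = [k for k in k_grid if k <= n - 1] or [n - 1]
    if family_ids is None:
        family_ids = np.arange(n)
    rng = np.random.default_rng(seed)
    folds = _family_folds(np.asarray(family_ids), n_folds, rng)
    kmax = max(k_grid)
    corrs = np.full((n_folds, len(k_grid)), np.nan)
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if len(test_idx) < 3 or len(train_idx) < 3:
            continue
        means, comps, scores = fit_pca(features_train[train_idx])
        m = min(kmax, scores.shape[1])
        scores = scores[:, :m]
        y_tr = y_resid_train[train_idx]
        y_te = y_resid_train[test_idx]
        denom = (scores**2).sum(axis=0)
        denom[denom == 0] = 1.0
        betas = scores.T @ (y_tr - y_tr.mean()) / denom
        proj = (features_train[test_idx] - means) @ comps[:, :m]
        contrib = np.cumsum(proj * betas[None, :], axis=1) + y_tr.mean()
        for ki, k in enumerate(k_grid):
            pred = contrib[:, min(k, m) - 1]
            if pred.std() == 0 or y_te.std() == 0:
                continue
            corrs[fi, ki] = np.corrcoef(pred, y_te)[0, 1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_r = np.nanmean(corrs, axis=0)
    path = pd.DataFrame({"k": k_grid, "mean_inner_r": mean_r})
    if np.all(np.isnan(mean_r)):
        return k_grid[0], path
    best = int(np.nanargmax(mean_r))  # first max -> smallest k on ties
    return k_grid[best], path


# ---------------------------------------------------------------------------
# the transferable model object
# ---------------------------------------------------------------------------

@dataclass
class PCRModel:
    """Everything needed to apply a train-fitted PCR model out of sample."""

    feature_means: np.ndarray
    components: np.ndarray  # p x k, orthonormal
    k: int
    phenotype_betas: np.ndarray  # intercept followed by k score coefficients
    covariate_betas: np.ndarray
    covariate_spec: Optional[CovariateSpec] = None

    def __post_init__(self) -> None:
        if self.components.shape[1] != self.k:
            raise ValueError("component basis width must equal k")


@dataclass
class CVMetrics:
    r_cv: float
    partial_eta2_cv: float
    n: int
    p_perm: float = np.nan


def fit_pcr(
    features_train: np.ndarray,
    y_train: np.ndarray,
    x_cov_train: np.ndarray,
    k: int,
    covariate_spec: Optional[CovariateSpec] = None,
) -> PCRModel:
    """Residualize on covariates, PCA, regress residuals on top-k scores."""
    resid, cov_betas = fit_covariates(y_train, x_cov_train)
    means, comps, scores = fit_pca(features_train)
    k = int(min(k, comps.shape[1]))
    scores = scores[:, :k]
    denom = (scores**2).sum(axis=0)
    denom[denom == 0] = 1.0
    betas = scores.T @ (resid - resid.mean()) / denom
    return PCRModel(
        feature_means=means,
        components=comps[:, :k],
        k=k,
        phenotype_betas=np.concatenate([[resid.mean()], betas]),
        covariate_betas=cov_betas,
        covariate_spec=covariate_spec,
    )


def predict(model: PCRModel, features_test: np.ndarray, x_cov_test=None) -> np.ndarray:
    """Out-of-sample expression scores (predicted residualized phenotype).

    Test features are centered with *training* means and projected onto the
    training component basis; covariates play no role in the brain-based
    prediction itself (they define what is being predicted).
    """
    scores = (np.asarray(features_test, dtype=float) - model.feature_means) @ model.components
    return model.phenotype_betas[0] + scores @ model.phenotype_betas[1:]


def cv_metrics(
    pred: np.ndarray,
    y_test: np.ndarray,
    x_cov_test: np.ndarray,
    covariate_betas: np.ndarray,
) -> CVMetrics:
    """Cross-validated r and partial eta^2 against train-residualized test y."""
    resid = apply_covariates(y_test, x_cov_test, covariate_betas)
    pred = np.asarray(pred, dtype=float)
    if pred.std() == 0 or resid.std() == 0:
        warnings.warn(
            "constant predictions or residuals; r_cv undefined", RuntimeWarning,
            stacklevel=2,
        )
        r = np.nan
    else:
        r = float(np.corrcoef(pred, resid)[0, 1])
    sse_cov = float(np.sum(resid**2))
    sse_full = float(np.sum((resid - pred) ** 2))
    eta2 = max(0.0, 1.0 - sse_full / sse_cov) if sse_cov > 0 else 0.0
    return CVMetrics(r_cv=r, partial_eta2_cv=eta2, n=len(resid))


# ---------------------------------------------------------------------------
# model-class front end
# ---------------------------------------------------------------------------

class PCR:
    """Statsmodels-style front end over the functional PCR pipeline.

    Parameters
    ----------
    y : phenotype vector (n,)
    features : connectivity feature matrix (n x p)
    covariates : covariate design (n x c), built by :func:`covariate_design`
    family_ids : optional family labels used to block the inner CV folds
    k_grid : candidate component counts; default depends on n
    """

    def __init__(
        self,
        y: np.ndarray,
        features: np.ndarray,
        covariates: np.ndarray,
        family_ids: Optional[np.ndarray] = None,
        k_grid: Optional[Sequence[int]] = None,
        seed: int = 0,
        covariate_spec: Optional[CovariateSpec] = None,
    ):
        self.y = np.asarray(y, dtype=float)
        self.features = np.asarray(features, dtype=float)
        self.covariates = np.asarray(covariates, dtype=float)
        self.family_ids = None if family_ids is None else np.asarray(family_ids)
        self.k_grid = list(k_grid) if k_grid is not None else default_k_grid(len(self.y))
        self.seed = seed
        self.covariate_spec = covariate_spec

    def fit(self, k: Optional[int] = None) -> "PCRResults":
        k_path = None
        if k is None:
            resid, _ = fit_covariates(self.y, self.covariates)
            k, k_path = select_k(
                self.features, resid, self.k_grid, self.family_ids, seed=self.seed
            )
        model = fit_pcr(self.features, self.y, self.covariates, k, self.covariate_spec)
        return PCRResults(model=model, k_path=k_path, n_train=len(self.y))


@dataclass
class PCRResults:
    model: PCRModel
    n_train: int
    k_path: Optional[pd.DataFrame] = None

    @property
    def k(self) -> int:
        return self.model.k

    def predict(self, features, covariates=None) -> np.ndarray:
        return predict(self.model, features, covariates)

    def evaluate(self, features, y, covariates) -> CVMetrics:
        pred = self.predict(features)
        return cv_metrics(pred, y, covariates, self.model.covariate_betas)

    def summary(self) -> str:
        lines = [
            "Principal component regression",
            f"  n_train = {self.n_train}, p = {self.model.components.shape[0]}, "
            f"k = {self.model.k}",
            f"  |beta| range over components: "
            f"[{np.abs(self.model.phenotype_betas[1:]).min():.4g}, "
            f"{np.abs(self.model.phenotype_betas[1:]).max():.4g}]",
        ]
        if self.k_path is not None:
            lines.append("  inner-CV path:")
            for _, row in self.k_path.iterrows():
                lines.append(f"    k={int(row['k']):>4d}  mean r={row['mean_inner_r']:.3f}")
        return "\n".join(lines)
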