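"""Cross-validated split-half mediation: SES -> brain signature -> GCA.

The cohort is split into demographically matched halves many times.  For
each pair, the connectome-based predictive model (PCR) is trained in split
*a* only; applying it to split *b* yields each subject's expression score of
the ability-related connectivity signature.  A mediation model is then
estimated entirely in split *b* — socioeconomic status as treatment, the
transferred expression score as mediator, general cognitive ability as
outcome, with the usual covariates plus site fixed effects — so the indirect
effect is never quantified in the sample where the signature was discovered.

Uncertainty uses the quasi-Bayesian simulation familiar from causal-mediation
software: coefficient vectors are drawn from each fitted regression's
asymptotic normal, and indirect/direct/total effects and the proportion
mediated are summarized over draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import pcr as _pcr
from .dataset import StudyData
from .factors import BifactorModel, OneFactorModel

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPair",
    "MediationResult",
    "Mediation",
    "matched_splits",
    "mediate_fit",
    "split_half_mediation",
    "run_split_half_mediation",
    "aggregate",
]

DEFAULT_MATCHING_VARS = [
    "gca_proxy", "income", "education", "neighborhood_disadvantage",
    "age", "sex", "race",
]


@dataclass
class SplitPair:
    """Two disjoint halves covering the analysis sample, families kept whole."""

    split_a: np.ndarray
    split_b: np.ndarray
    balance: pd.DataFrame

    def __post_init__(self) -> None:
        if np.intersect1d(self.split_a, self.split_b).size:
            raise ValueError("split halves overlap")


@dataclass
class MediationResult:
    a: float                 # treatment -> mediator (standardized)
    b: float                 # mediator -> outcome | treatment (standardized)
    c_prime: float           # direct effect
    total: float
    indirect: float          # mean of simulation draws
    proportion_mediated: float       # point estimate a*b / (a*b + c')
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_sims: int
    n_discordant: int = 0
    proportion_mediated_sim: float = np.nan  # mean of concordant clipped draws
    prop_ci_low: float = np.nan
    prop_ci_high: float = np.nan

    def summary(self) -> str:
        return (
            "Mediation (quasi-Bayesian simulation)\n"
            f"  a (treatment->mediator)        = {self.a:.3f}\n"
            f"  b (mediator->outcome | treat)  = {self.b:.3f}\n"
            f"  c' (direct)                    = {self.c_prime:.3f}\n"
            f"  total                          = {self.total:.3f}\n"
            f"  indirect (sim mean)            = {self.indirect:.3f} "
            f"[{self.ci_low:.3f}, {self.ci_high:.3f}], p = {self.p:.4g}\n"
            f"  proportion mediated            = {self.proportion_mediated:.3f} "
            f"[{self.prop_ci_low:.3f}, {self.prop_ci_high:.3f}]\n"
            f"  n = {self.n}, sims = {self.n_sims}, "
            f"sign-discordant draws dropped = {self.n_discordant}"
        )


# ---------------------------------------------------------------------------
# matched halving
# ---------------------------------------------------------------------------

def _matching_matrix(pheno: pd.DataFrame, matching_vars: Sequence[str]) -> np.ndarray:
    cols = []
    for var in matching_vars:
        if var not in pheno.columns:
            raise ValueError(f"matching variable {var!r} missing")
        col = pheno[var]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, dtype=float)
            cols.append(dummies.to_numpy())
        else:
            cols.append(col.to_numpy(dtype=float)[:, None])
    return np.column_stack(cols)


def _smd(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ma, mb = x[a].mean(axis=0), x[b].mean(axis=0)
    va, vb = x[a].var(axis=0, ddof=1), x[b].var(axis=0, ddof=1)
    pooled = np.sqrt((va + vb) / 2.0)
    pooled[pooled == 0] = 1.0
    return np.abs(ma - mb) / pooled


def matched_splits(
    phenotypes: pd.DataFrame,
    matching_vars: Optional[Sequence[str]] = None,
    n_splits: int = 100,
    seed: int = 0,
    smd_threshold: float = 0.1,
    max_redraws: int = 50,
) -> list[SplitPair]:
    """Repeated matched halving with families assigned as whole units.

    Family units are paired greedily by Mahalanobis distance over the
    family-averaged matching variables (family size included so units pair
    like-for-like); one member of each pair goes to each half at random.  A
    draw is accepted only if every matching variable's absolute standardized
    mean difference between halves is below ``smd_threshold``.
    """
    matching_vars = list(DEFAULT_MATCHING_VARS if matching_vars is None else matching_vars)
    matching_vars = [v for v in matching_vars if v in phenotypes.columns]
    x = _matching_matrix(phenotypes, matching_vars)

    fam_ids, fam_inverse = np.unique(phenotypes["family_id"], return_inverse=True)
    n_fam = len(fam_ids)
    fam_x = np.zeros((n_fam, x.shape[1] + 1))
    counts = np.bincount(fam_inverse).astype(float)
    for j in range(x.shape[1]):
        fam_x[:, j] = np.bincount(fam_inverse, weights=x[:, j]) / counts
    fam_x[:, -1] = counts  # family size as a matching dimension

    # Mahalanobis whitening of family aggregates
    cov = np.cov(fam_x, rowvar=False)
    white = fam_x @ np.linalg.cholesky(
        np.linalg.pinv(cov + 1e-8 * np.eye(cov.shape[0]))
    )
    sq = (white**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (white @ white.T)
    np.fill_diagonal(d2, np.inf)

    members = [np.flatnonzero(fam_inverse == i) for i in range(n_fam)]
    rng = np.random.default_rng(seed)
    pairs: list[SplitPair] = []
    for _ in range(n_splits):
        for attempt in range(max_redraws):
            order = rng.permutation(n_fam)
            unmatched = np.ones(n_fam, dtype=bool)
            side_a: list[int] = []
            side_b: list[int] = []
            for u in order:
                if not unmatched[u]:
                    continue
                unmatched[u] = False
                dists = np.where(unmatched, d2[u], np.inf)
                if np.isinf(dists).all():
                    (side_a if rng.random() < 0.5 else side_b).append(u)
                    continue
                v = int(dists.argmin())
                unmatched[v] = False
                if rng.random() < 0.5:
                    side_a.append(u); side_b.append(v)
                else:
                    side_a.append(v); side_b.append(u)
            idx_a = np.sort(np.concatenate([members[f] for f in side_a]))
            idx_b = np.sort(np.concatenate([members[f] for f in side_b]))
            smd = _smd(x, idx_a, idx_b)
            if (smd < smd_threshold).all():
                balance = pd.DataFrame({"smd": smd})
                pairs.append(SplitPair(idx_a, idx_b, balance))
                break
        else:
            raise RuntimeError(
                f"could not balance halves in {max_redraws} redraws; "
                f"worst |SMD| = {smd.max():.3f}"
            )
    return pairs


# ---------------------------------------------------------------------------
# the mediation model itself
# ---------------------------------------------------------------------------

class Mediation:
    """Two-regression mediation model with quasi-Bayesian uncertainty.

    mediator ~ treatment + covariates; outcome ~ treatment + mediator +
    covariates.  Treatment, mediator and outcome are z-scored so all paths
    are standardized coefficients.  With nested OLS fits the total effect
    decomposes exactly as c = c' + a*b.
    """

    def __init__(self, outcome, treatment, mediator, covariates=None):
        self.y = _z(outcome)
        self.t = _z(treatment)
        self.m = _z(mediator)
        n = len(self.y)
        self.x_cov = (
            np.empty((n, 0)) if covariates is None
            else np.asarray(covariates, dtype=float)
        )

    def fit(self, n_sims: int = 1000, seed: int = 0) -> MediationResult:
        n = len(self.y)
        x_med = np.column_stack([np.ones(n), self.t, self.x_cov])
        x_out = np.column_stack([np.ones(n), self.t, self.m, self.x_cov])
        fit_m = sm.OLS(self.m, x_med).fit()
        fit_y = sm.OLS(self.y, x_out).fit()
        a_hat, b_hat, c_hat = fit_m.params[1], fit_y.params[2], fit_y.params[1]

        rng = np.random.default_rng(seed)
        draws_m = rng.multivariate_normal(fit_m.params, fit_m.cov_params(), n_sims)
        draws_y = rng.multivariate_normal(fit_y.params, fit_y.cov_params(), n_sims)
        a_d, b_d, cp_d = draws_m[:, 1], draws_y[:, 2], draws_y[:, 1]
        indirect = a_d * b_d
        total = cp_d + indirect
        concord = np.sign(indirect) == np.sign(total)
        n_disc = int((~concord).sum())
        if n_disc:
            logger.debug("%d sign-discordant mediation draws dropped", n_disc)
        props = np.clip(indirect[concord] / total[concord], 0.0, 1.0)
        if props.size == 0:
            props = np.array([0.0])
        ci = np.percentile(indirect, [2.5, 97.5])
        p_ci = np.percentile(props, [2.5, 97.5])
        p_pos = (1 + np.sum(indirect <= 0)) / (1 + n_sims)
        p_neg = (1 + np.sum(indirect >= 0)) / (1 + n_sims)
        total_hat = c_hat + a_hat * b_hat
        prop_point = a_hat * b_hat / total_hat if total_hat != 0 else 0.0
        if np.sign(a_hat * b_hat) == np.sign(total_hat):
            prop_point = float(np.clip(prop_point, 0.0, 1.0))
        else:
            prop_point = 0.0
        return MediationResult(
            a=float(a_hat), b=float(b_hat), c_prime=float(c_hat),
            total=float(total_hat),
            indirect=float(indirect.mean()),
            proportion_mediated=prop_point,
            proportion_mediated_sim=float(props.mean()),
            ci_low=float(ci[0]), ci_high=float(ci[1]),
            p=float(min(1.0, 2 * min(p_pos, p_neg))),
            n=n, n_sims=n_sims, n_discordant=n_disc,
            prop_ci_low=float(p_ci[0]), prop_ci_high=float(p_ci[1]),
        )


def _z(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def mediate_fit(
    treatment, mediator, outcome, covariates=None, n_sims: int = 1000, seed: int = 0
) -> MediationResult:
    return Mediation(outcome, treatment, mediator, covariates).fit(n_sims, seed)


# ---------------------------------------------------------------------------
# the split-half stream
# ---------------------------------------------------------------------------

def split_half_mediation(
    pair: SplitPair,
    dataset: StudyData,
    covariates: Optional[Sequence[str]] = None,
    k_grid: Optional[Sequence[int]] = None,
    n_sims: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Signature trained in split a; mediation estimated in split b.

    GCA and SES factor models are also fitted in split a and transferred, so
    nothing about split b informs any trained component.  Covariates plus
    site fixed effects adjust both mediation regressions inside split b.
    """
    pheno = dataset.phenotypes
    a_idx, b_idx = pair.split_a, pair.split_b

    gca_model = BifactorModel(dataset.task_table.iloc[a_idx]).fit()
    ses_model = OneFactorModel(dataset.ses_table.iloc[a_idx]).fit()
    y_a = gca_model.score(dataset.task_table.iloc[a_idx])
    y_b = gca_model.score(dataset.task_table.iloc[b_idx])
    ses_b = ses_model.score(dataset.ses_table.iloc[b_idx])

    spec = _pcr.CovariateSpec.from_frame(pheno.iloc[a_idx], covariates)
    x_a = _pcr.covariate_design(pheno.iloc[a_idx], spec)
    grid = list(k_grid) if k_grid is not None else _pcr.default_k_grid(len(a_idx))
    grid_ok = [k for k in grid if k <= len(a_idx) - 1]
    if len(grid_ok) < len(grid):
        logger.info("k grid truncated to %s for split of size %d", grid_ok, len(a_idx))
    model = _pcr.PCR(
        y_a, dataset.features[a_idx], x_a,
        family_ids=pheno["family_id"].to_numpy()[a_idx],
        k_grid=grid_ok, seed=seed, covariate_spec=spec,
    ).fit()
    expression_b = model.predict(dataset.features[b_idx])

    x_b = _pcr.covariate_design(pheno.iloc[b_idx], spec)
    site_dummies = pd.get_dummies(pheno["site"].iloc[b_idx], drop_first=True, dtype=float)
    x_med = np.column_stack([x_b, site_dummies.to_numpy()]) if len(site_dummies.columns) else x_b
    return mediate_fit(ses_b, expression_b, y_b, x_med, n_sims=n_sims, seed=seed)


def run_split_half_mediation(
    dataset: StudyData,
    n_splits: int = 100,
    seed: int = 0,
    matching_vars: Optional[Sequence[str]] = None,
    covariates: Optional[Sequence[str]] = None,
    k_grid: Optional[Sequence[int]] = None,
    n_sims: int = 1000,
) -> tuple[pd.DataFrame, dict]:
    """Matched splits -> per-split mediation -> aggregate summary."""
    pheno = dataset.phenotypes.copy()
    if "gca_proxy" not in pheno.columns:
        # matching proxy: whole-sample general-factor score (design step only)
        pheno["gca_proxy"] = BifactorModel(dataset.task_table).fit().score(
            dataset.task_table
        )
    pairs = matched_splits(pheno, matching_vars, n_splits, seed)
    results = []
    for i, pair in enumerate(pairs):
        results.append(
            split_half_mediation(
                pair, dataset, covariates=covariates, k_grid=k_grid,
                n_sims=n_sims, seed=seed * 10007 + i,
            )
        )
    table = pd.DataFrame(
        {
            "split": np.arange(len(results)),
            "a": [r.a for r in results],
            "b": [r.b for r in results],
            "c_prime": [r.c_prime for r in results],
            "total": [r.total for r in results],
            "indirect": [r.indirect for r in results],
            "proportion_mediated": [r.proportion_mediated for r in results],
            "p": [r.p for r in results],
        }
    )
    return table, aggregate(results)


def aggregate(results: Sequence[MediationResult]) -> dict:
    """Mean / median / IQR of the proportion mediated + representative model."""
    props = np.array([r.proportion_mediated for r in results])
    mean = float(props.mean())
    rep = int(np.argmin(np.abs(props - mean)))
    q1, q3 = np.percentile(props, [25, 75])
    return {
        "mean_proportion_mediated": mean,
        "median_proportion_mediated": float(np.median(props)),
        "iqr": (float(q1), float(q3)),
        "representative_index": rep,
        "representative": results[rep],
        "n_splits": len(results),
    }
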