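"""Latent-factor models for the cognitive battery and the SES composite.

Two confirmatory models are fitted by maximum likelihood on the sample
correlation matrix:

* a **bifactor model** for the 11-task cognitive battery — every task loads
  on an orthogonal general factor (general cognitive ability, GCA) and on at
  most one of three orthogonal domain-specific factors;
* a **one-factor model** for the three socioeconomic indicators (household
  income, parental education, neighborhood disadvantage).

Both expose regression-method (Thurstone) factor scores that transfer a
train-fitted model to new subjects: test tasks are standardized with the
training means/SDs and projected through the train-fitted weights, with no
refitting on test data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "BifactorModel",
    "BifactorResults",
    "OneFactorModel",
    "OneFactorResults",
    "omega_from_loadings",
    "omega_hierarchical",
    "triad_loadings",
    "fit_bifactor",
    "fit_onefactor",
    "score_subjects",
    "HeywoodError",
    "ConvergenceError",
]

_PSI_FLOOR = 1e-3


class HeywoodError(RuntimeError):
    """An estimated uniqueness collapsed to (or below) zero."""


class ConvergenceError(RuntimeError):
    """The ML optimizer failed to converge."""


def omega_from_loadings(
    general: np.ndarray,
    specific: np.ndarray,
    assignment: np.ndarray,
    uniquenesses: np.ndarray,
) -> float:
    """Coefficient omega-hierarchical.

    omega_h = (sum lg)^2 / [ (sum lg)^2 + sum_f (sum_{j in f} ls_j)^2 + sum psi ]
    i.e. the share of total-score variance carried by the general factor.
    """
    general = np.asarray(general, dtype=float)
    specific = np.asarray(specific, dtype=float)
    assignment = np.asarray(assignment, dtype=int)
    gen_var = general.sum() ** 2
    spec_var = sum(
        specific[assignment == f].sum() ** 2 for f in np.unique(assignment)
    )
    total = gen_var + spec_var + float(np.sum(uniquenesses))
    return float(gen_var / total)


def triad_loadings(corr3: np.ndarray) -> np.ndarray:
    """Closed-form one-factor loadings for exactly three indicators.

    lambda_1^2 = r12*r13/r23 (and cyclic); the solution is exact because the
    3-indicator model is just-identified.
    """
    r12, r13, r23 = corr3[0, 1], corr3[0, 2], corr3[1, 2]
    l1 = np.sqrt(abs(r12 * r13 / r23))
    l2 = np.sign(r12) * np.sqrt(abs(r12 * r23 / r13))
    l3 = np.sign(r13) * np.sqrt(abs(r13 * r23 / r12))
    return np.array([l1, l2, l3])


# ---------------------------------------------------------------------------
# shared ML machinery
# ---------------------------------------------------------------------------

def _ml_discrepancy_and_grad(
    params: np.ndarray,
    sample_corr: np.ndarray,
    assignment: Optional[np.ndarray],
) -> tuple[float, np.ndarray]:
    """F_ML = log|Sigma| + tr(S Sigma^-1) - log|S| - t, with analytic gradient.

    ``assignment`` of None means a plain one-factor model (no specifics).
    """
    t = sample_corr.shape[0]
    lg = params[:t]
    if assignment is None:
        ls = None
        psi = params[t:]
    else:
        ls = params[t : 2 * t]
        psi = params[2 * t :]
    sigma = np.outer(lg, lg) + np.diag(psi)
    if assignment is not None:
        for f in np.unique(assignment):
            v = np.where(assignment == f, ls, 0.0)
            sigma += np.outer(v, v)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf, np.zeros_like(params)
    inv = np.linalg.inv(sigma)
    _, logdet_s = np.linalg.slogdet(sample_corr)
    f_val = logdet + float(np.sum(inv * sample_corr)) - logdet_s - t
    # dF/dSigma = inv (Sigma - S) inv
    g_mat = inv @ (sigma - sample_corr) @ inv
    grad_lg = 2.0 * g_mat @ lg
    grad_psi = np.diag(g_mat).copy()
    if assignment is None:
        return f_val, np.concatenate([grad_lg, grad_psi])
    grad_ls = np.zeros(t)
    for f in np.unique(assignment):
        mask = assignment == f
        v = np.where(mask, ls, 0.0)
        grad_ls[mask] = 2.0 * (g_mat @ v)[mask]
    return f_val, np.concatenate([grad_lg, grad_ls, grad_psi])


def _fit_ml(
    sample_corr: np.ndarray,
    assignment: Optional[np.ndarray],
    columns: Sequence[str],
    maxiter: int = 2000,
    heywood: str = "warn",
) -> tuple[np.ndarray, Optional[np.ndarray], np.ndarray, float]:
    t = sample_corr.shape[0]
    # principal-component start: robust to sign-mixed indicators
    vals, vecs = np.linalg.eigh(sample_corr)
    lg0 = vecs[:, -1] * np.sqrt(max(vals[-1], 0.1))
    if lg0.sum() < 0:
        lg0 = -lg0
    lg0 = np.clip(lg0, -0.95, 0.95)
    x0 = [lg0]
    bounds: list[tuple] = [(-2.0, 2.0)] * t
    if assignment is not None:
        x0.append(np.full(t, 0.3))
        bounds += [(-2.0, 2.0)] * t
    x0.append(np.clip(1.0 - lg0**2, 0.2, 1.0))
    bounds += [(_PSI_FLOOR, 10.0)] * t
    res = minimize(
        _ml_discrepancy_and_grad,
        np.concatenate(x0),
        args=(sample_corr, assignment),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
    )
    if not res.success and "ROUND" not in str(res.message).upper():
        raise ConvergenceError(
            f"factor-model ML fit failed: {res.message} "
            f"(nit={res.nit}, final F={res.fun:.6g}, |grad|={np.abs(res.jac).max():.3g})"
        )
    lg = res.x[:t]
    ls = None if assignment is None else res.x[t : 2 * t]
    psi = res.x[-t:]
    at_floor = psi <= _PSI_FLOOR * 1.5
    if at_floor.any():
        bad = [columns[i] for i in np.flatnonzero(at_floor)]
        msg = (
            f"uniqueness collapsed to zero for indicator(s) {bad}; "
            "the model is misspecified or the sample is degenerate"
        )
        if heywood == "raise":
            raise HeywoodError(msg)
        # boundary-constrained ML solution: the standard applied remedy is to
        # hold the variance at a small positive floor and proceed
        warnings.warn(msg + " (returning the boundary-constrained solution)",
                      RuntimeWarning, stacklevel=3)
    # canonical signs: each factor's loading sum is positive
    if lg.sum() < 0:
        lg = -lg
    if ls is not None:
        for f in np.unique(assignment):
            mask = assignment == f
            if ls[mask].sum() < 0:
                ls[mask] = -ls[mask]
    return lg, ls, psi, float(res.fun)


def _fit_indices(f_min: float, sample_corr: np.ndarray, n_obs: int, n_params: int) -> dict:
    t = sample_corr.shape[0]
    df = t * (t + 1) // 2 - n_params
    chi2 = (n_obs - 1) * f_min
    _, logdet_s = np.linalg.slogdet(sample_corr)
    chi2_null = (n_obs - 1) * (-logdet_s)
    df_null = t * (t - 1) // 2
    rmsea = float(np.sqrt(max(chi2 / max(df, 1) - 1.0, 0.0) / (n_obs - 1)))
    cfi_den = max(chi2_null - df_null, chi2 - df, 0.0)
    cfi = 1.0 if cfi_den == 0 else float(1.0 - max(chi2 - df, 0.0) / cfi_den)
    return {"chi2": float(chi2), "df": int(df), "rmsea": rmsea, "cfi": cfi}


def _srmr(sample_corr: np.ndarray, implied: np.ndarray) -> float:
    t = sample_corr.shape[0]
    i, j = np.tril_indices(t)
    res = (sample_corr - implied)[i, j]
    return float(np.sqrt(np.mean(res**2)))


# ---------------------------------------------------------------------------
# bifactor model
# ---------------------------------------------------------------------------

class BifactorModel:
    """Confirmatory bifactor model of a task battery.

    Parameters
    ----------
    task_table : DataFrame (n subjects x t tasks)
    assignment : sequence of int, task -> specific-factor index.  Defaults to
        the generator's 4/4/3 split over three domains.
    """

    def __init__(self, task_table: pd.DataFrame, assignment: Optional[Sequence[int]] = None):
        self.task_table = pd.DataFrame(task_table)
        t = self.task_table.shape[1]
        if assignment is None:
            base, rem = divmod(t, 3)
            sizes = [base + 1] * rem + [base] * (3 - rem)
            assignment = np.repeat(np.arange(3), sizes)
        self.assignment = np.asarray(assignment, dtype=int)
        if len(self.assignment) != t:
            raise ValueError("assignment must give one specific factor per task")
        if len(self.task_table) < 10 * t:
            warnings.warn(
                f"only {len(self.task_table)} observations for {t} tasks; "
                "ML estimates may be unstable",
                RuntimeWarning,
                stacklevel=2,
            )

    def fit(self, maxiter: int = 2000, heywood: str = "warn") -> "BifactorResults":
        data = self.task_table.to_numpy(dtype=float)
        means, sds = data.mean(axis=0), data.std(axis=0, ddof=1)
        if (sds == 0).any():
            bad = self.task_table.columns[sds == 0].tolist()
            raise ValueError(f"constant task column(s): {bad}")
        corr = np.corrcoef(data, rowvar=False)
        lg, ls, psi, f_min = _fit_ml(
            corr, self.assignment, list(self.task_table.columns), maxiter, heywood
        )
        implied = np.outer(lg, lg) + np.diag(psi)
        for f in np.unique(self.assignment):
            v = np.where(self.assignment == f, ls, 0.0)
            implied += np.outer(v, v)
        indices = _fit_indices(f_min, corr, len(self.task_table), 3 * len(lg))
        indices["srmr"] = _srmr(corr, implied)
        return BifactorResults(
            general_loadings=lg,
            specific_loadings=ls,
            assignment=self.assignment,
            uniquenesses=psi,
            implied_corr=implied,
            fit_indices=indices,
            train_means=means,
            train_sds=sds,
            columns=list(self.task_table.columns),
            n_obs=len(self.task_table),
        )


@dataclass
class BifactorResults:
    general_loadings: np.ndarray
    specific_loadings: np.ndarray
    assignment: np.ndarray
    uniquenesses: np.ndarray
    implied_corr: np.ndarray
    fit_indices: dict
    train_means: np.ndarray
    train_sds: np.ndarray
    columns: list
    n_obs: int

    @property
    def omega_h(self) -> float:
        return omega_from_loadings(
            self.general_loadings, self.specific_loadings,
            self.assignment, self.uniquenesses,
        )

    def score(self, task_table: pd.DataFrame) -> np.ndarray:
        """Regression-method general-factor scores with train-fitted weights."""
        missing = [c for c in self.columns if c not in task_table.columns]
        if missing:
            raise ValueError(f"task column(s) missing from scoring table: {missing}")
        z = (task_table[self.columns].to_numpy(dtype=float) - self.train_means) / self.train_sds
        weights = np.linalg.solve(self.implied_corr, self.general_loadings)
        return z @ weights

    def summary(self) -> str:
        lines = ["Bifactor model (ML on correlations)", "-" * 38]
        lines.append(f"{'task':<10}{'general':>9}{'specific':>9}{'psi':>8}  domain")
        for j, c in enumerate(self.columns):
            lines.append(
                f"{c:<10}{self.general_loadings[j]:>9.3f}"
                f"{self.specific_loadings[j]:>9.3f}{self.uniquenesses[j]:>8.3f}"
                f"  {self.assignment[j]}"
            )
        fi = self.fit_indices
        lines.append(
            f"omega_h = {self.omega_h:.3f} | chi2({fi['df']}) = {fi['chi2']:.2f}, "
            f"RMSEA = {fi['rmsea']:.3f}, CFI = {fi['cfi']:.3f}, SRMR = {fi['srmr']:.3f}"
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# one-factor model
# ---------------------------------------------------------------------------

class OneFactorModel:
    """Single-factor confirmatory model (used for the 3-indicator SES composite)."""

    def __init__(self, indicator_table: pd.DataFrame, require_three: bool = True):
        self.table = pd.DataFrame(indicator_table)
        if require_three and self.table.shape[1] != 3:
            raise ValueError(
                f"the SES measurement model is fixed at 3 indicators, "
                f"got {self.table.shape[1]}"
            )

    def fit(self, maxiter: int = 2000, heywood: str = "warn") -> "OneFactorResults":
        data = self.table.to_numpy(dtype=float)
        means, sds = data.mean(axis=0), data.std(axis=0, ddof=1)
        corr = np.corrcoef(data, rowvar=False)
        lam, _, psi, f_min = _fit_ml(corr, None, list(self.table.columns), maxiter, heywood)
        implied = np.outer(lam, lam) + np.diag(psi)
        indices = _fit_indices(f_min, corr, len(self.table), 2 * len(lam))
        indices["srmr"] = _srmr(corr, implied)
        return OneFactorResults(
            loadings=lam,
            uniquenesses=psi,
            implied_corr=implied,
            fit_indices=indices,
            train_means=means,
            train_sds=sds,
            columns=list(self.table.columns),
            n_obs=len(self.table),
        )


@dataclass
class OneFactorResults:
    loadings: np.ndarray
    uniquenesses: np.ndarray
    implied_corr: np.ndarray
    fit_indices: dict
    train_means: np.ndarray
    train_sds: np.ndarray
    columns: list
    n_obs: int

    @property
    def variance_explained(self) -> float:
        return float(np.mean(self.loadings**2))

    def score(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.columns if c not in table.columns]
        if missing:
            raise ValueError(f"indicator column(s) missing: {missing}")
        z = (table[self.columns].to_numpy(dtype=float) - self.train_means) / self.train_sds
        return z @ np.linalg.solve(self.implied_corr, self.loadings)

    def summary(self) -> str:
        rows = "\n".join(
            f"{c:<28}{l:>8.3f}{p:>8.3f}"
            for c, l, p in zip(self.columns, self.loadings, self.uniquenesses)
        )
        return (
            "One-factor model (ML on correlations)\n"
            f"{'indicator':<28}{'lambda':>8}{'psi':>8}\n{rows}\n"
            f"variance explained = {self.variance_explained:.3f}"
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_bifactor(task_table: pd.DataFrame, assignment=None) -> BifactorResults:
    return BifactorModel(task_table, assignment).fit()


def fit_onefactor(ses_table: pd.DataFrame) -> OneFactorResults:
    return OneFactorModel(ses_table).fit()


def omega_hierarchical(model: BifactorResults) -> float:
    return model.omega_h


def score_subjects(model: BifactorResults, task_table: pd.DataFrame) -> np.ndarray:
    return model.score(task_table)
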