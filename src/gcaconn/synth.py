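"""Synthetic multi-site cohort generator with planted, recoverable structure.

Every downstream stage of the package (connectome construction, factor
models, principal component regression, leave-one-site-out validation,
network-cell statistics, mediation) is exercised against cohorts produced
here, where the generative truth is known exactly:

* a family/twin structure nested in acquisition sites,
* a latent socioeconomic factor (``ses``) measured by three indicators,
* a latent general cognitive ability (``gca``) measured by 11 task scores
  under a bifactor structure (dominant general factor),
* connectomes whose component expressions carry the gca and ses signal, and
* per-frame head-motion (framewise displacement) traces.

The standardized ses -> gca path, the population brain-gca correlation, and
the population proportion of the ses -> gca effect mediated by the brain
signal are all direct configuration inputs; :func:`solve_brain_weights` maps
them onto generative coefficients in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from ._utils import child_rngs, devectorize, fisher_z, n_edges, triu_index
from .connectome import RunTimeSeries, subject_connectome
from .dataset import SES_COLUMNS, StudyData, task_columns

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "default_task_loadings",
    "default_ses_loadings",
    "solve_brain_weights",
    "planted_proportion_mediated",
    "make_atlas",
    "generate_cohort",
    "generate_task_scores",
    "generate_ses_indicators",
    "generate_features",
    "generate_timeseries",
    "simulate_dataset",
    "NETWORK_NAMES_15",
]

#: the 15 large-scale network labels used for the desk-scale atlas
NETWORK_NAMES_15 = [
    "SMH", "SMM", "CO", "AUD", "DMN", "VIS", "FPN", "SAL",
    "SC", "VAN", "DAN", "CER", "NONE", "CP", "RST",
]

#: demographic margins emulated by the covariate draws
RACE_LEVELS = ["White", "Black", "Hispanic", "Asian", "Other"]
RACE_PROBS = [0.586, 0.123, 0.182, 0.017, 0.092]
AGE_MEAN, AGE_SD = 9.96, 0.62


class InfeasibleConfigError(ValueError):
    """Raised when a cohort configuration cannot be realized."""


@dataclass
class CohortConfig:
    """All knobs of the generator; defaults are the desk-scale study conditions.

    Desk scale keeps 60 parcels in 15 networks (4 per network), preserving the
    15-network cell grid while holding the edge count at 1770, and 10 sites of
    80-120 subjects.
    """

    n_sites: int = 10
    subjects_per_site: tuple[int, int] = (80, 120)
    family_size_dist: tuple[float, float, float] = (0.85, 0.12, 0.03)
    twin_fraction: float = 0.3
    n_tasks: int = 11
    n_parcels: int = 60
    n_networks: int = 15
    frames_per_run: int = 150
    n_runs: int = 4
    seed: int = 0

    # planted effect structure
    ses_gca_path: float = 0.32
    brain_gca_corr: float = 0.42
    proportion_mediated: float = 0.155
    n_components: int = 3
    component_norm: float = 0.6
    nuisance_component_sd: float = 1.0
    signal_cells: Optional[Sequence[tuple[str, str]]] = None

    # observation model
    edge_noise_sd: float = 0.05
    site_effect_sd: float = 0.02
    base_within_corr: float = 0.30
    base_between_corr: float = 0.05
    task_specific_sizes: tuple[int, int, int] = (4, 4, 3)
    omega_h_target: float = 0.75
    specific_share_target: float = 0.13
    ses_variance_explained: float = 0.58

    # motion model
    fd_mean: float = 0.21
    fd_sd: float = 0.09
    spike_fraction: float = 0.05
    motion_noise_coupling: float = 0.0
    confound_covariates: bool = False

    def __post_init__(self) -> None:
        probs = np.asarray(self.family_size_dist, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise InfeasibleConfigError(
                "family_size_dist must be 3 non-negative probabilities summing to 1"
            )
        for name in ("n_sites", "n_tasks", "n_parcels", "n_networks",
                     "frames_per_run", "n_runs", "n_components"):
            if getattr(self, name) < 1:
                raise InfeasibleConfigError(f"{name} must be >= 1")
        lo, hi = self.subjects_per_site
        if lo < 1 or hi < lo:
            raise InfeasibleConfigError("subjects_per_site range is empty")
        max_family = max(s for s, p in zip((1, 2, 3), probs) if p > 0)
        if max_family > lo:
            raise InfeasibleConfigError(
                f"family size {max_family} exceeds smallest site size {lo}"
            )
        if not 0 <= self.twin_fraction <= 1:
            raise InfeasibleConfigError("twin_fraction must be in [0, 1]")
        if self.n_parcels % self.n_networks:
            raise InfeasibleConfigError(
                "n_parcels must be a multiple of n_networks for the uniform atlas"
            )
        if sum(self.task_specific_sizes) != self.n_tasks:
            raise InfeasibleConfigError(
                "task_specific_sizes must partition the n_tasks tasks"
            )

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_parcels)


@dataclass
class GroundTruth:
    """Per-subject latents and the generative parameters, for recovery tests."""

    gca_latent: np.ndarray
    ses_latent: np.ndarray
    path_ses_to_gca_total: float
    component_maps: np.ndarray  # q x p, edge space, symmetric by construction
    component_expression_betas_on_gca: np.ndarray
    planted_proportion_mediated: float
    planted_brain_gca_corr: float
    general_loadings: np.ndarray
    specific_loadings: np.ndarray
    specific_assignment: np.ndarray
    uniquenesses: np.ndarray
    ses_loadings: np.ndarray
    brain_weight_on_gca: float
    brain_weight_on_ses: float
    brain_noise_sd: float
    component_weights: Optional[np.ndarray] = None  # n x q, filled at feature time
    base_edges: Optional[np.ndarray] = None
    site_offsets: Optional[np.ndarray] = None

    @property
    def signal_map(self) -> np.ndarray:
        """The GCA-related edge-space direction (first component map)."""
        return self.component_maps[0]

    def subset(self, mask: np.ndarray) -> "GroundTruth":
        w = self.component_weights[mask] if self.component_weights is not None else None
        return replace(
            self,
            gca_latent=self.gca_latent[mask],
            ses_latent=self.ses_latent[mask],
            component_weights=w,
        )


# ---------------------------------------------------------------------------
# loadings and effect-size calibration
# ---------------------------------------------------------------------------

def default_task_loadings(
    n_tasks: int = 11,
    sizes: Sequence[int] = (4, 4, 3),
    omega_h: float = 0.75,
    specific_share: float = 0.13,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Equal-loading bifactor parameters hitting target variance shares.

    With equal general loadings ``lg``, equal specific loadings ``ls`` and
    unit task variances, the hierarchical omega is
    ``(n lg)^2 / [(n lg)^2 + sum_f (n_f ls)^2 + sum psi]``; solving the three
    variance shares (general, specific, unique) for ``lg``, ``ls`` is linear
    in the squared loadings.
    """
    sizes = np.asarray(sizes, dtype=int)
    if sizes.sum() != n_tasks:
        raise ValueError("specific-factor sizes must partition the tasks")
    unique_share = 1.0 - omega_h - specific_share
    if unique_share <= 0:
        raise ValueError("omega_h + specific share must be < 1")
    a_coef = float(n_tasks**2)          # (sum lg)^2 = a_coef * lg^2
    b_coef = float((sizes**2).sum())    # sum_f (sum ls_f)^2 = b_coef * ls^2
    # shares: a : b : c = omega_h : specific : unique with c = n(1 - lg^2 - ls^2)
    lg2_per_c = omega_h / (unique_share * a_coef)
    ls2_per_c = specific_share / (unique_share * b_coef)
    c = n_tasks / (1.0 + n_tasks * (lg2_per_c + ls2_per_c))
    lg = np.sqrt(lg2_per_c * c)
    ls = np.sqrt(ls2_per_c * c)
    general = np.full(n_tasks, lg)
    specific = np.full(n_tasks, ls)
    assignment = np.repeat(np.arange(len(sizes)), sizes)
    psi = 1.0 - general**2 - specific**2
    return general, specific, assignment, psi


def default_ses_loadings(variance_explained: float = 0.58) -> np.ndarray:
    """Equal standardized loadings; variance explained is the squared loading.

    Neighborhood disadvantage loads negatively (it is a deprivation index).
    """
    lam = float(np.sqrt(variance_explained))
    return np.array([lam, lam, -lam])


def score_validity(loadings: np.ndarray, implied_corr: np.ndarray) -> float:
    """Correlation between a regression-method factor score and its factor.

    For orthogonal factors the squared validity is ``lambda' Sigma^-1 lambda``.
    """
    lam = np.asarray(loadings, dtype=float)
    return float(np.sqrt(lam @ np.linalg.solve(implied_corr, lam)))


def _generator_validities(
    general, specific, assignment, psi, ses_loadings
) -> tuple[float, float]:
    sigma = np.outer(general, general) + np.diag(psi)
    for f in np.unique(assignment):
        v = np.where(assignment == f, specific, 0.0)
        sigma += np.outer(v, v)
    v_g = score_validity(general, sigma)
    lam = np.asarray(ses_loadings, dtype=float)
    v_s = score_validity(lam, np.outer(lam, lam) + np.diag(1 - lam**2))
    return v_g, v_s


def planted_proportion_mediated(
    beta_g: float,
    beta_s: float,
    c: float,
    validity_g: float = 1.0,
    validity_s: float = 1.0,
) -> tuple[float, float]:
    """Population proportion mediated and brain-GCA correlation, *measured* scale.

    The brain signal is ``m = beta_g*g + beta_s*s + noise`` over the latents
    ``g = c*s + sqrt(1-c^2)*u``.  Reported effect sizes in this field live on
    the scale of the measured factor scores, which correlate with their
    latents at the score validities; the implied measured-scale covariances
    of (ses score, m, gca score) give the mediation paths in closed form.
    """
    a = validity_s * (beta_g * c + beta_s)          # cov(ses score, m)
    r = validity_g * (beta_g + beta_s * c)          # cov(gca score, m)
    c_meas = validity_g * validity_s * c            # cov(ses score, gca score)
    b = (r - a * c_meas) / (1.0 - a**2)
    return a * b / c_meas, r


def solve_brain_weights(
    brain_gca_corr: float,
    proportion: float,
    ses_gca_path: float,
    validity_g: float = 1.0,
    validity_s: float = 1.0,
) -> tuple[float, float, float]:
    """Solve (beta_g, beta_s, noise_sd) planting both measured-scale targets.

    ``brain_gca_corr`` and ``proportion`` are anchored on the measured
    factor-score scale (where the field reports them); ``ses_gca_path`` is the
    latent standardized path.  Var(m) = 1.
    """
    c_meas = ses_gca_path * validity_g * validity_s
    r = brain_gca_corr
    if r == 0.0:
        if proportion != 0.0:
            raise InfeasibleConfigError(
                "a brain signal uncorrelated with GCA cannot mediate"
            )
        return 0.0, 0.0, 1.0

    def prop_given_a(a: float) -> float:
        return a * (r - a * c_meas) / ((1.0 - a**2) * c_meas) - proportion

    a_meas = brentq(prop_given_a, -0.95, 0.95, xtol=1e-12)
    r_lat, a_lat = r / validity_g, a_meas / validity_s
    c = ses_gca_path
    beta_g = (r_lat - c * a_lat) / (1.0 - c**2)
    beta_s = (a_lat - c * r_lat) / (1.0 - c**2)
    var_sig = 1.0 - (beta_g**2 + beta_s**2 + 2 * beta_g * beta_s * c)
    if var_sig <= 0:
        raise InfeasibleConfigError(
            f"brain_gca_corr={r}, proportion={proportion}, ses_gca_path={c} "
            "imply a brain-signal variance above 1; targets are incompatible"
        )
    return float(beta_g), float(beta_s), float(np.sqrt(var_sig))


# ---------------------------------------------------------------------------
# atlas and cohort
# ---------------------------------------------------------------------------

def make_atlas(n_parcels: int = 60, n_networks: int = 15) -> pd.DataFrame:
    """Uniform parcel -> network table; 15-network runs use the field's labels."""
    if n_parcels % n_networks:
        raise ValueError("n_parcels must divide evenly into networks")
    if n_networks == 15:
        names = NETWORK_NAMES_15
    else:
        names = [f"NET{i + 1:02d}" for i in range(n_networks)]
    per = n_parcels // n_networks
    return pd.DataFrame(
        {
            "parcel_id": np.arange(n_parcels),
            "network": np.repeat(names, per),
        }
    )


def _sample_fd_means(n: int, cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    lo = (0.03 - cfg.fd_mean) / cfg.fd_sd
    return truncnorm.rvs(lo, np.inf, loc=cfg.fd_mean, scale=cfg.fd_sd,
                         size=n, random_state=rng)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the subject table (sites, families, latents, covariates).

    Socioeconomic status is a family-level latent (siblings share it); general
    cognitive ability is ``c * ses + sqrt(1-c^2) * individual noise`` so the
    standardized ses -> gca regression equals the configured path in
    expectation.  Deterministic given ``config.seed``.
    """
    rng_cohort, rng_latent, rng_cov, rng_maps = child_rngs(config.seed, 4)
    sizes = np.array([1, 2, 3])
    probs = np.asarray(config.family_size_dist)

    rows: list[dict] = []
    fam_counter = 0
    for s in range(config.n_sites):
        site = f"site{s + 1:02d}"
        target = int(rng_cohort.integers(config.subjects_per_site[0],
                                         config.subjects_per_site[1] + 1))
        filled = 0
        while filled < target:
            size = int(rng_cohort.choice(sizes, p=probs))
            size = min(size, target - filled)
            fam_counter += 1
            fam = f"fam{fam_counter:05d}"
            twin = bool(size == 2 and rng_cohort.random() < config.twin_fraction)
            for m in range(size):
                rows.append(
                    {"subject_id": f"sub{len(rows) + 1:05d}", "site": site,
                     "family_id": fam, "twin": twin}
                )
            filled += size
    pheno = pd.DataFrame(rows)
    n = len(pheno)

    # family-level ses, individual gca
    fam_ids, fam_index = np.unique(pheno["family_id"], return_inverse=True)
    ses_fam = rng_latent.standard_normal(len(fam_ids))
    ses = ses_fam[fam_index]
    c = config.ses_gca_path
    gca = c * ses + np.sqrt(1 - c**2) * rng_latent.standard_normal(n)

    # covariates, independent of the latents unless confounding is requested
    pheno["age"] = np.clip(rng_cov.normal(AGE_MEAN, AGE_SD, n), 8.5, 11.5)
    pheno["sex"] = rng_cov.choice(["F", "M"], size=n, p=[0.504, 0.496])
    pheno["race"] = rng_cov.choice(RACE_LEVELS, size=n, p=RACE_PROBS)
    mean_fd = _sample_fd_means(n, config, rng_cov)
    if config.confound_covariates:
        # mild motion-ability and age-ability coupling to exercise adjustment
        mean_fd = np.clip(mean_fd - 0.02 * gca, 0.03, None)
        gca = gca + 0.1 * (pheno["age"].to_numpy() - AGE_MEAN) / AGE_SD
    pheno["mean_fd"] = mean_fd

    general, specific, assignment, psi = default_task_loadings(
        config.n_tasks, config.task_specific_sizes,
        config.omega_h_target, config.specific_share_target,
    )
    ses_loadings = default_ses_loadings(config.ses_variance_explained)
    v_g, v_s = _generator_validities(general, specific, assignment, psi, ses_loadings)
    beta_g, beta_s, sig = solve_brain_weights(
        config.brain_gca_corr, config.proportion_mediated, config.ses_gca_path,
        v_g, v_s,
    )
    prop, corr = planted_proportion_mediated(
        beta_g, beta_s, config.ses_gca_path, v_g, v_s
    )

    maps = _component_maps(config, rng_maps)
    betas_on_gca = np.zeros(config.n_components)
    betas_on_gca[0] = beta_g

    truth = GroundTruth(
        gca_latent=gca,
        ses_latent=ses,
        path_ses_to_gca_total=c,
        component_maps=maps,
        component_expression_betas_on_gca=betas_on_gca,
        planted_proportion_mediated=prop,
        planted_brain_gca_corr=corr,
        general_loadings=general,
        specific_loadings=specific,
        specific_assignment=assignment,
        uniquenesses=psi,
        ses_loadings=ses_loadings,
        brain_weight_on_gca=beta_g,
        brain_weight_on_ses=beta_s,
        brain_noise_sd=sig,
    )
    return pheno, truth


def _component_maps(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Edge-space component maps, unit structure scaled to ``component_norm``.

    The first map carries the planted gca/ses signal; the rest are nuisance
    directions of inter-individual connectivity variation.  If
    ``signal_cells`` is set, the signal map's support is restricted to edges
    whose endpoint networks match one of the listed (unordered) pairs.
    """
    p = config.n_edges
    maps = rng.standard_normal((config.n_components, p))
    if config.signal_cells is not None:
        atlas = make_atlas(config.n_parcels, config.n_networks)
        nets = atlas["network"].to_numpy()
        i, j = triu_index(config.n_parcels)
        wanted = {frozenset(pair) for pair in config.signal_cells}
        mask = np.array(
            [frozenset((a, b)) in wanted for a, b in zip(nets[i], nets[j])]
        )
        if not mask.any():
            raise InfeasibleConfigError("signal_cells matched no edges in the atlas")
        maps[0, ~mask] = 0.0
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    return maps * config.component_norm


# ---------------------------------------------------------------------------
# measured phenotypes
# ---------------------------------------------------------------------------

def generate_task_scores(
    cohort: pd.DataFrame,
    truth: GroundTruth,
    noise_sd: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Bifactor task battery: task_j = lg_j*g + ls_j*s_dom(j) + sqrt(psi_j)*e."""
    if rng is None:
        rng = np.random.default_rng(0)
    n = len(cohort)
    n_tasks = len(truth.general_loadings)
    if len(truth.specific_loadings) != n_tasks or len(truth.uniquenesses) != n_tasks:
        raise ValueError("loading vectors must all have one entry per task")
    n_spec = int(truth.specific_assignment.max()) + 1
    spec_factors = rng.standard_normal((n, n_spec))
    eps = rng.standard_normal((n, n_tasks))
    scores = (
        np.outer(truth.gca_latent, truth.general_loadings)
        + spec_factors[:, truth.specific_assignment] * truth.specific_loadings
        + eps * np.sqrt(truth.uniquenesses) * noise_sd
    )
    return pd.DataFrame(scores, columns=task_columns(n_tasks), index=cohort.index)


def generate_ses_indicators(
    cohort: pd.DataFrame,
    truth: GroundTruth,
    noise_sd: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Three indicators (income, education, neighborhood disadvantage).

    One-factor structure over the family-level ses latent; the deprivation
    index loads negatively.  The measurement model is fixed at 3 indicators.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    lam = np.asarray(truth.ses_loadings, dtype=float)
    if lam.shape != (3,):
        raise ValueError("the SES measurement model has exactly 3 indicators")
    n = len(cohort)
    eps = rng.standard_normal((n, 3))
    vals = np.outer(truth.ses_latent, lam) + eps * np.sqrt(1 - lam**2) * noise_sd
    return pd.DataFrame(vals, columns=SES_COLUMNS, index=cohort.index)


# ---------------------------------------------------------------------------
# connectomes: edge-space fast path and full time-series path
# ---------------------------------------------------------------------------

def _component_weights(
    cohort: pd.DataFrame, truth: GroundTruth, config: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(cohort)
    w = rng.standard_normal((n, config.n_components)) * config.nuisance_component_sd
    w[:, 0] = (
        truth.brain_weight_on_gca * truth.gca_latent
        + truth.brain_weight_on_ses * truth.ses_latent
        + truth.brain_noise_sd * rng.standard_normal(n)
    )
    return w


def _base_and_sites(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline connectivity (z-space edges) and per-site edge offsets."""
    atlas = make_atlas(config.n_parcels, config.n_networks)
    nets = atlas["network"].to_numpy()
    i, j = triu_index(config.n_parcels)
    within = nets[i] == nets[j]
    base_r = np.where(within, config.base_within_corr, config.base_between_corr)
    base_z = fisher_z(base_r)
    offsets = rng.standard_normal((config.n_sites, config.n_edges)) * config.site_effect_sd
    return base_z, offsets


def _motion_scale(cohort: pd.DataFrame, config: CohortConfig) -> np.ndarray:
    if config.motion_noise_coupling == 0:
        return np.ones(len(cohort))
    z = (cohort["mean_fd"].to_numpy() - config.fd_mean) / config.fd_sd
    return np.clip(1.0 + config.motion_noise_coupling * z, 0.2, None)


def generate_features(
    cohort: pd.DataFrame,
    truth: GroundTruth,
    config: CohortConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Edge-space observation model (fast path).

    Features are Fisher-z edge values: baseline + site offset + planted
    component mixture + Gaussian noise whose default scale (0.05) matches the
    finite-scan variability of ~4 runs of correlation estimates.  Subjects
    with high mean FD optionally receive inflated noise
    (``motion_noise_coupling``).
    """
    if rng is None:
        rng = child_rngs(config.seed, 6)[4]
    base_z, offsets = _base_and_sites(config, child_rngs(config.seed, 6)[5])
    w = _component_weights(cohort, truth, config, rng)
    site_idx = pd.Categorical(
        cohort["site"], categories=sorted(cohort["site"].unique())
    ).codes
    # small sites lists reuse the first offsets rows deterministically
    scale = _motion_scale(cohort, config)
    noise = rng.standard_normal((len(cohort), config.n_edges))
    features = (
        base_z[None, :]
        + offsets[site_idx % offsets.shape[0]]
        + w @ truth.component_maps
        + noise * (config.edge_noise_sd * scale[:, None])
    )
    truth = replace(truth, component_weights=w, base_edges=base_z, site_offsets=offsets)
    return features, truth


def _spd_correlation(mat: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Nearest-by-eigenvalue-clipping SPD repair, rescaled to unit diagonal."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    if np.linalg.eigvalsh(fixed).min() <= 0:
        raise ValueError("connectivity target is not positive definite after repair")
    return fixed


def _fd_trace(
    mean_fd: float, n_frames: int, spike_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame FD with a controllable high-motion (>0.5 mm) spike fraction."""
    spikes = rng.random(n_frames) < spike_fraction
    spike_fd = 0.5 + rng.exponential(0.25, size=int(spikes.sum()))
    spike_mass = spike_fd.sum()
    n_quiet = n_frames - int(spikes.sum())
    quiet_target = (mean_fd * n_frames - spike_mass) / max(n_quiet, 1)
    if quiet_target < 0.015:
        # subject too still to carry spikes at this rate; drop them
        spikes[:] = False
        spike_fd = np.array([])
        n_quiet, quiet_target = n_frames, mean_fd
    quiet = rng.gamma(8.0, quiet_target / 8.0, size=n_quiet)
    fd = np.empty(n_frames)
    fd[spikes] = spike_fd
    fd[~spikes] = np.clip(quiet, 0.005, None)
    return fd, spikes


def generate_timeseries(
    cohort: pd.DataFrame,
    truth: GroundTruth,
    config: CohortConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, list[RunTimeSeries]], GroundTruth]:
    """Full observation model: frames drawn from each subject's target covariance.

    The subject's target correlation matrix is the back-transformed edge-space
    mixture (baseline + site offset + component weights), repaired to the
    nearest symmetric positive-definite correlation matrix by eigenvalue
    clipping.  High-motion spike frames get doubled amplitude so that the
    0.5 mm censoring stage has real work to do.
    """
    if rng is None:
        rng = child_rngs(config.seed, 6)[4]
    base_z, offsets = _base_and_sites(config, child_rngs(config.seed, 6)[5])
    w = _component_weights(cohort, truth, config, rng)
    site_idx = pd.Categorical(
        cohort["site"], categories=sorted(cohort["site"].unique())
    ).codes
    scale = _motion_scale(cohort, config)

    runs: dict[str, list[RunTimeSeries]] = {}
    mean_fd = cohort["mean_fd"].to_numpy()
    for idx, (_, row) in enumerate(cohort.iterrows()):
        z_edges = base_z + offsets[site_idx[idx] % offsets.shape[0]] + w[idx] @ truth.component_maps
        target = _spd_correlation(
            devectorize(np.tanh(z_edges), config.n_parcels, diag=1.0)
        )
        chol = np.linalg.cholesky(target)
        subject_runs = []
        for r in range(config.n_runs):
            frames = rng.standard_normal(
                (config.frames_per_run, config.n_parcels)
            ) @ chol.T
            if scale[idx] != 1.0:
                frames += (scale[idx] - 1.0) * rng.standard_normal(frames.shape)
            fd, spikes = _fd_trace(
                mean_fd[idx], config.frames_per_run, config.spike_fraction, rng
            )
            frames[spikes] *= 2.0  # motion artifact on censored frames
            subject_runs.append(
                RunTimeSeries(frames, fd, run_id=r, subject_id=row["subject_id"])
            )
        runs[row["subject_id"]] = subject_runs
    truth = replace(truth, component_weights=w, base_edges=base_z, site_offsets=offsets)
    return runs, truth


# ---------------------------------------------------------------------------
# one-call simulation
# ---------------------------------------------------------------------------

def simulate_dataset(
    config: Optional[CohortConfig] = None,
    mode: str = "edges",
    metric: str = "pearson",
) -> StudyData:
    """Generate a complete study: phenotypes, features, atlas, ground truth.

    ``mode='edges'`` uses the fast edge-space observation model;
    ``mode='timeseries'`` draws frames and runs them through the full
    censoring/correlation/Fisher-z/averaging stream of
    :mod:`gcaconn.connectome`.
    """
    if config is None:
        config = CohortConfig()
    cohort, truth = generate_cohort(config)
    rngs = child_rngs(config.seed, 6)
    tasks = generate_task_scores(cohort, truth, rng=rngs[1])
    ses = generate_ses_indicators(cohort, truth, rng=rngs[2])
    if mode == "edges":
        features, truth = generate_features(cohort, truth, config, rngs[4])
    elif mode == "timeseries":
        runs, truth = generate_timeseries(cohort, truth, config, rngs[4])
        feats = []
        for sid in cohort["subject_id"]:
            conn = subject_connectome(runs[sid], metric=metric)
            feats.append(conn.features)
            cohort.loc[cohort["subject_id"] == sid, "mean_fd"] = conn.mean_fd
        features = np.asarray(feats)
    else:
        raise ValueError(f"unknown simulation mode {mode!r}")
    pheno = pd.concat([cohort.reset_index(drop=True), tasks.reset_index(drop=True),
                       ses.reset_index(drop=True)], axis=1)
    return StudyData(
        phenotypes=pheno,
        features=features,
        atlas=make_atlas(config.n_parcels, config.n_networks),
        ground_truth=truth,
        metric=metric,
    )
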