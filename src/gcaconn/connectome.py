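"""Run-level ROI time series -> subject-level connectome feature vectors.

A subject contributes four resting-state runs; each run is motion-censored
(framewise displacement threshold, default 0.5 mm), turned into a parcel x
parcel connectivity matrix (Pearson or Ledoit-Wolf partial correlation),
Fisher z-transformed, and averaged across usable runs.  The averaged matrix's
upper triangle is the subject's feature vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import LedoitWolf

from ._utils import fisher_z, triu_index, vectorize_matrix

__all__ = [
    "RunTimeSeries",
    "ConnectomeFeatures",
    "UnusableRunError",
    "censor_frames",
    "pearson_connectome",
    "partial_connectome",
    "subject_connectome",
]

#: minimum frames a run must retain after censoring to be usable
DEFAULT_MIN_FRAMES = 10
FD_CENSOR_MM = 0.5


class UnusableRunError(ValueError):
    """Raised when a run retains too few frames after motion censoring."""


@dataclass
class RunTimeSeries:
    """One run: ``frames`` is T x R (frames by parcels), ``fd`` per-frame mm."""

    frames: np.ndarray
    fd: np.ndarray
    run_id: int = 0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.fd = np.asarray(self.fd, dtype=float)
        if self.frames.ndim != 2:
            raise ValueError("frames must be a T x R matrix")
        if self.fd.shape != (self.frames.shape[0],):
            raise ValueError("fd must have one value per frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.frames.shape[1]


@dataclass
class ConnectomeFeatures:
    """Subject-level connectivity matrix plus its edge feature vector."""

    matrix: np.ndarray
    features: np.ndarray
    metric: str
    mean_fd: float
    subject_id: str = ""
    n_usable_runs: int = 0


def censor_frames(
    run: RunTimeSeries,
    threshold_mm: float = FD_CENSOR_MM,
    min_frames: int = DEFAULT_MIN_FRAMES,
) -> RunTimeSeries:
    """Drop frames at or above the FD threshold, preserving temporal order."""
    if threshold_mm <= 0:
        raise ValueError("censoring threshold must be positive")
    keep = run.fd < threshold_mm
    if int(keep.sum()) < min_frames:
        raise UnusableRunError(
            f"run {run.run_id} of subject {run.subject_id!r}: "
            f"{int(keep.sum())} frames survive {threshold_mm} mm censoring "
            f"(minimum {min_frames})"
        )
    return RunTimeSeries(run.frames[keep], run.fd[keep], run.run_id, run.subject_id)


def _check_variance(frames: np.ndarray, subject_id: str) -> np.ndarray:
    sd = frames.std(axis=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(
            f"subject {subject_id!r}: {int(dead.sum())} zero-variance parcels; "
            "their correlations are set to NaN",
            RuntimeWarning,
            stacklevel=3,
        )
    return dead


def pearson_connectome(run: RunTimeSeries) -> np.ndarray:
    """Full Pearson correlation matrix of the run's parcel time series."""
    dead = _check_variance(run.frames, run.subject_id)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(run.frames, rowvar=False)
    if dead.any():
        mat[dead, :] = np.nan
        mat[:, dead] = np.nan
    np.fill_diagonal(mat, 1.0)
    return mat


def partial_connectome(run: RunTimeSeries) -> np.ndarray:
    """Partial correlation matrix via the Ledoit-Wolf shrinkage estimator.

    The shrunk covariance S is inverted to the precision matrix P and
    rescaled: partial_ij = -P_ij / sqrt(P_ii P_jj), diagonal set to 1.
    """
    _check_variance(run.frames, run.subject_id)
    cov = LedoitWolf(assume_centered=False).fit(run.frames).covariance_
    try:
        precision = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - shrinkage prevents this
        raise np.linalg.LinAlgError(
            "shrunk covariance is singular; cannot form partial correlations"
        ) from exc
    d = np.sqrt(np.diag(precision))
    mat = -precision / np.outer(d, d)
    np.fill_diagonal(mat, 1.0)
    return mat


_METRICS = {"pearson": pearson_connectome, "partial": partial_connectome}


def subject_connectome(
    runs: list[RunTimeSeries],
    metric: str = "pearson",
    censor_threshold: float = FD_CENSOR_MM,
    min_frames: int = DEFAULT_MIN_FRAMES,
) -> ConnectomeFeatures:
    """Aggregate runs into one subject-level connectome.

    Per-run matrices are Fisher z-transformed then averaged over usable runs;
    features stay in z-space.  ``mean_fd`` summarizes all frames before
    censoring (it is used later as a nuisance covariate, which should reflect
    the subject's overall motion, not the surviving frames).
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown connectivity metric {metric!r}")
    if not runs:
        raise UnusableRunError("subject has no runs")
    all_fd = np.concatenate([r.fd for r in runs])
    mats = []
    for run in runs:
        try:
            censored = censor_frames(run, censor_threshold, min_frames)
        except UnusableRunError:
            continue
        mats.append(fisher_z(_METRICS[metric](censored)))
    if not mats:
        raise UnusableRunError(
            f"subject {runs[0].subject_id!r}: no usable runs after censoring"
        )
    mean_z = np.mean(mats, axis=0)
    return ConnectomeFeatures(
        matrix=mean_z,
        features=vectorize_matrix(mean_z),
        metric=metric,
        mean_fd=float(all_fd.mean()),
        subject_id=runs[0].subject_id,
        n_usable_runs=len(mats),
    )
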