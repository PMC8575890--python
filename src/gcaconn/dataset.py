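"""The in-memory study container shared by every analysis stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

#: canonical phenotype columns every stage may rely on
ID_COLUMNS = ["subject_id", "site", "family_id", "twin"]
COVARIATE_COLUMNS = ["age", "sex", "race", "mean_fd"]
SES_COLUMNS = ["income", "education", "neighborhood_disadvantage"]


def task_columns(n_tasks: int) -> list[str]:
    return [f"task_{i + 1:02d}" for i in range(n_tasks)]


@dataclass
class StudyData:
    """Phenotypes, edge-space connectome features, and the parcel atlas.

    ``features`` rows align with ``phenotypes`` rows; columns follow the
    canonical upper-triangle edge ordering of :mod:`gcaconn._utils`.
    """

    phenotypes: pd.DataFrame
    features: np.ndarray
    atlas: pd.DataFrame
    ground_truth: Optional[object] = None
    metric: str = "pearson"

    def __post_init__(self) -> None:
        if len(self.phenotypes) != self.features.shape[0]:
            raise ValueError(
                f"{len(self.phenotypes)} phenotype rows but "
                f"{self.features.shape[0]} feature rows"
            )
        if self.phenotypes["subject_id"].duplicated().any():
            raise ValueError("duplicate subject_id in phenotype table")

    # -- convenience views -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.phenotypes)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_parcels(self) -> int:
        return len(self.atlas)

    @property
    def sites(self) -> list:
        return sorted(self.phenotypes["site"].unique().tolist())

    @property
    def task_table(self) -> pd.DataFrame:
        cols = [c for c in self.phenotypes.columns if c.startswith("task_")]
        return self.phenotypes[cols]

    @property
    def ses_table(self) -> pd.DataFrame:
        return self.phenotypes[SES_COLUMNS]

    def subset(self, mask: np.ndarray) -> "StudyData":
        """Row-subset phenotypes and features together (boolean or index mask)."""
        mask = np.asarray(mask)
        gt = self.ground_truth.subset(mask) if hasattr(self.ground_truth, "subset") else self.ground_truth
        return replace(
            self,
            phenotypes=self.phenotypes.iloc[mask].reset_index(drop=True)
            if mask.dtype != bool
            else self.phenotypes.loc[mask].reset_index(drop=True),
            features=self.features[mask],
            ground_truth=gt,
        )

    def select_edges(self, edge_mask: np.ndarray, atlas: Optional[pd.DataFrame] = None) -> "StudyData":
        """Column-subset the edge features (used by drop-one-network)."""
        return replace(
            self,
            features=self.features[:, edge_mask],
            atlas=self.atlas if atlas is None else atlas,
        )
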