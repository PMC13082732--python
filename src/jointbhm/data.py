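"""Long-format repeated-measures dataset container.

One row per (patient, leg, side, occasion) measurement carrying both the
continuous severity score and the binary health status, plus the two
continuous predictors.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError

#: canonical column order of the long-format schema
SCHEMA = (
    "patient_id",
    "leg",
    "side",
    "occasion",
    "score_y1",
    "status_y2",
    "ultrasound_x1",
    "rcp_x2",
)

#: optional column holding the simulated latent normal behind status_y2
LATENT_COLUMN = "latent_y2star"

#: names usable as fixed/random covariates, mapped to dataframe columns
COVARIATE_COLUMNS = {
    "intercept": None,
    "leg": "leg",
    "side": "side",
    "ultrasound": "ultrasound_x1",
    "rcp": "rcp_x2",
}


@dataclass
class LongTableDataset:
    """A validated long-format table plus generation/processing metadata."""

    df: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SCHEMA if c not in self.df.columns]
        if missing:
            raise InvalidArgumentError(f"dataset missing columns: {missing}")
        core = self.df[list(SCHEMA)]
        if core.isna().any().any():
            bad = sorted(core[core.isna().any(axis=1)].index.tolist())
            raise InvalidArgumentError(
                f"dataset must be fully observed; missing values in rows {bad}"
            )
        status = self.df["status_y2"].to_numpy()
        if not np.isin(status, [0, 1]).all():
            raise InvalidArgumentError("status_y2 must be coded 0/1")
        if len(self.df) > 0 and self.n_patients < 1:
            raise InvalidArgumentError("dataset needs at least one patient")

    # -- basic accessors -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def n_patients(self) -> int:
        return self.df["patient_id"].nunique()

    @property
    def patient_ids(self) -> np.ndarray:
        return np.unique(self.df["patient_id"].to_numpy())

    def patient_codes(self) -> np.ndarray:
        """0-based dense patient index per row (order of sorted ids)."""
        return np.searchsorted(self.patient_ids, self.df["patient_id"].to_numpy())

    @property
    def y1(self) -> np.ndarray:
        return self.df["score_y1"].to_numpy(dtype=float)

    @property
    def y2(self) -> np.ndarray:
        return self.df["status_y2"].to_numpy(dtype=int)

    @property
    def has_latent(self) -> bool:
        return LATENT_COLUMN in self.df.columns

    def covariate_column(self, name: str) -> np.ndarray:
        """Value vector for a named covariate ('intercept' -> ones)."""
        if name not in COVARIATE_COLUMNS:
            raise InvalidArgumentError(f"unknown covariate {name!r}")
        col = COVARIATE_COLUMNS[name]
        if col is None:
            return np.ones(self.n_rows)
        return self.df[col].to_numpy(dtype=float)

    def design_matrix(self, covariates: tuple[str, ...]) -> np.ndarray:
        return np.column_stack([self.covariate_column(c) for c in covariates])

    # -- manipulation ----------------------------------------------------
    def subset(self, row_mask: np.ndarray) -> "LongTableDataset":
        """Row subset (used by K-fold CV); metadata carried over."""
        return LongTableDataset(
            self.df.loc[np.asarray(row_mask)].reset_index(drop=True),
            dict(self.metadata),
        )

    def copy(self) -> "LongTableDataset":
        return LongTableDataset(self.df.copy(), dict(self.metadata))

    def digest(self) -> str:
        """Stable content hash of the core columns (schema order, repr to 12 dp)."""
        h = hashlib.sha256()
        core = self.df[list(SCHEMA)]
        h.update(",".join(SCHEMA).encode())
        for row in core.itertuples(index=False):
            h.update(
                ("|".join(f"{v:.12g}" if isinstance(v, float) else str(v) for v in row)).encode()
            )
        return h.hexdigest()
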