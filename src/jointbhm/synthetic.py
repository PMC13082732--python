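"""Synthetic balanced repeated-measures data generator.

Emulates the arterial-occlusive-disease study layout: ``n_patients`` subjects,
each measured on every (leg, side, occasion) cell, with a continuous severity
score (normal errors), a probit-linked binary status driven by a latent normal
with unit residual variance, and patient-level random effects that are
correlated across the two responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import LATENT_COLUMN, LongTableDataset
from .exceptions import DegenerateInputError, InvalidArgumentError

#: order of fixed-effect coefficients in TrueParameters.beta_*
FIXED_ORDER = ("intercept", "leg", "ultrasound", "rcp")


@dataclass
class DesignTable:
    """Balanced crossing of patients x legs x sides x occasions."""

    df: pd.DataFrame

    @property
    def n_rows(self) -> int:
        return len(self.df)


@dataclass
class TrueParameters:
    """Ground-truth parameters for the simulator.

    ``Sigma_u`` is the joint random-effect covariance over
    ``random_covariates`` for y1 followed by the same set for y2
    (dimension ``2 * len(random_covariates)``).
    """

    beta_y1: np.ndarray
    beta_y2: np.ndarray
    sigma2_y1: float
    Sigma_u: np.ndarray
    random_covariates: tuple[str, ...] = ("intercept",)
    predictor_means: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0]))
    predictor_sds: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0]))
    #: predictors are normal truncated at +/- this many sd (None: unbounded).
    #: Clinical scores are bounded; unbounded tails also create high-leverage
    #: rows that destabilize leave-one-out diagnostics on small designs.
    predictor_truncation: float | None = 2.0

    def __post_init__(self) -> None:
        self.beta_y1 = np.atleast_1d(np.asarray(self.beta_y1, dtype=float))
        self.beta_y2 = np.atleast_1d(np.asarray(self.beta_y2, dtype=float))
        self.Sigma_u = np.atleast_2d(np.asarray(self.Sigma_u, dtype=float))
        self.predictor_means = np.asarray(self.predictor_means, dtype=float)
        self.predictor_sds = np.asarray(self.predictor_sds, dtype=float)
        if self.sigma2_y1 < 0:
            raise InvalidArgumentError("sigma2_y1 must be non-negative")
        q = 2 * len(self.random_covariates)
        if self.Sigma_u.shape != (q, q):
            raise InvalidArgumentError(
                f"Sigma_u must be {q}x{q} for random covariates {self.random_covariates}"
            )
        if not np.allclose(self.Sigma_u, self.Sigma_u.T):
            raise InvalidArgumentError("Sigma_u must be symmetric")
        eig = np.linalg.eigvalsh(self.Sigma_u)
        if np.any(eig < -1e-12):
            raise InvalidArgumentError("Sigma_u must be positive semi-definite")


def aod_like_truth() -> TrueParameters:
    """Default preset with moderate fixed effects mirroring the study's sign
    pattern (ultrasound positive and dominant on the binary status) and
    modest subject-level heterogeneity in line with the small random-effect
    scales the study reports.  Values are presets for simulation, not
    estimates."""
    rc = ("intercept", "ultrasound")
    sds = np.array([0.7, 0.4, 0.7, 0.4])
    corr = np.eye(4)
    corr[0, 2] = corr[2, 0] = 0.3
    corr[1, 3] = corr[3, 1] = 0.2
    sigma = np.outer(sds, sds) * corr
    return TrueParameters(
        beta_y1=np.array([0.5, 0.3, 0.8, 0.2]),
        beta_y2=np.array([0.3, 0.2, 1.0, 0.3]),
        sigma2_y1=0.5,
        Sigma_u=sigma,
        random_covariates=rc,
    )


def make_design(
    n_patients: int, n_legs: int = 2, n_sides: int = 2, n_occasions: int = 4
) -> DesignTable:
    """Fully crossed balanced design, sorted by (patient, leg, side, occasion)."""
    for name, v in (
        ("n_patients", n_patients),
        ("n_legs", n_legs),
        ("n_sides", n_sides),
        ("n_occasions", n_occasions),
    ):
        if int(v) != v or v < 1:
            raise InvalidArgumentError(f"{name} must be a positive integer, got {v!r}")
    grid = np.array(
        np.meshgrid(
            np.arange(1, n_patients + 1),
            np.arange(n_legs),
            np.arange(n_sides),
            np.arange(1, n_occasions + 1),
            indexing="ij",
        )
    ).reshape(4, -1)
    df = pd.DataFrame(
        {
            "patient_id": grid[0],
            "leg": grid[1],
            "side": grid[2],
            "occasion": grid[3],
        }
    )
    return DesignTable(df)


def simulate_dataset(
    design: DesignTable,
    truth: TrueParameters,
    seed: int,
    keep_latent: bool = False,
) -> LongTableDataset:
    """Draw predictors, random effects and both responses under the model.

    Predictors are i.i.d. normal with the preset means/sds.  The latent normal
    behind the binary status is retained in ``latent_y2star`` when
    ``keep_latent`` is set (test-oracle mode; the column is flagged
    non-observable in metadata).
    """
    if design.n_rows == 0:
        raise InvalidArgumentError("design is empty")
    rng = np.random.default_rng(seed)
    df = design.df.copy()
    n = len(df)

    def draw_predictor(mean: float, sd: float) -> np.ndarray:
        if truth.predictor_truncation is None:
            return mean + sd * rng.standard_normal(n)
        a = truth.predictor_truncation
        raw = stats.truncnorm.rvs(-a, a, size=n, random_state=rng)
        return mean + sd * raw

    x1 = draw_predictor(truth.predictor_means[0], truth.predictor_sds[0])
    x2 = draw_predictor(truth.predictor_means[1], truth.predictor_sds[1])
    df["ultrasound_x1"] = x1
    df["rcp_x2"] = x2

    def covcol(name: str) -> np.ndarray:
        if name == "intercept":
            return np.ones(n)
        if name == "leg":
            return df["leg"].to_numpy(dtype=float)
        if name == "side":
            return df["side"].to_numpy(dtype=float)
        if name == "ultrasound":
            return x1
        if name == "rcp":
            return x2
        raise InvalidArgumentError(f"unknown covariate {name!r}")

    X = np.column_stack([covcol(c) for c in FIXED_ORDER])
    Z = np.column_stack([covcol(c) for c in truth.random_covariates])
    k = Z.shape[1]

    patient_ids = np.unique(df["patient_id"].to_numpy())
    codes = np.searchsorted(patient_ids, df["patient_id"].to_numpy())
    n_pat = len(patient_ids)

    q = 2 * k
    eigval, eigvec = np.linalg.eigh(truth.Sigma_u)
    root = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))
    U = rng.standard_normal((n_pat, q)) @ root.T

    eta1 = X @ truth.beta_y1 + np.einsum("ij,ij->i", Z, U[codes, :k])
    eta2 = X @ truth.beta_y2 + np.einsum("ij,ij->i", Z, U[codes, k:])
    y1 = eta1 + np.sqrt(truth.sigma2_y1) * rng.standard_normal(n)
    y2star = eta2 + rng.standard_normal(n)
    df["score_y1"] = y1
    df["status_y2"] = (y2star > 0).astype(int)
    if keep_latent:
        df[LATENT_COLUMN] = y2star

    meta: dict = {
        "seed": int(seed),
        "coding": {"leg": {"left": 0, "right": 1}, "side": {"upper": 0, "lower": 1}},
        "random_covariates": list(truth.random_covariates),
        "latent_observable": False,
        "true_parameters": {
            "beta_y1": truth.beta_y1.tolist(),
            "beta_y2": truth.beta_y2.tolist(),
            "sigma2_y1": float(truth.sigma2_y1),
            "Sigma_u": truth.Sigma_u.tolist(),
        },
    }
    if keep_latent:  # oracle mode: in-memory only, never written to CSV
        meta["true_U"] = U
    return LongTableDataset(df, meta)


@dataclass
class Standardization:
    """Centering/scaling constants applied to continuous predictors."""

    means: dict[str, float]
    sds: dict[str, float]

    def invert(self, column: str, values: np.ndarray) -> np.ndarray:
        return values * self.sds[column] + self.means[column]


def standardize_predictors(
    data: LongTableDataset,
    columns: tuple[str, ...] = ("ultrasound_x1", "rcp_x2"),
) -> tuple[LongTableDataset, Standardization]:
    """Z-score the continuous predictor columns (sample sd, ddof=1).

    Binary/categorical columns are untouched.  Returns the transformed data
    and the constants needed to invert the transform.
    """
    out = data.copy()
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for col in columns:
        v = out.df[col].to_numpy(dtype=float)
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        if sd == 0.0:
            raise DegenerateInputError(f"predictor column {col!r} is constant")
        m = float(np.mean(v))
        out.df[col] = (v - m) / sd
        means[col] = m
        sds[col] = sd
    out.metadata["standardized"] = {"means": means, "sds": sds}
    return out, Standardization(means, sds)
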