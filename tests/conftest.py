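import numpy as np
import pandas as pd
import pytest

import jointbhm as j
from jointbhm.data import SCHEMA, LongTableDataset
from jointbhm.priors import PriorConfig


@pytest.fixture(scope="session")
def tiny_data() -> LongTableDataset:
    """4 patients x 2 x 2 x 2 = 32 rows, standardized predictors."""
    data = j.simulate_dataset(j.make_design(4, 2, 2, 2), j.aod_like_truth(), seed=11)
    data, _ = j.standardize_predictors(data)
    return data


@pytest.fixture(scope="session")
def small_data() -> LongTableDataset:
    """8 patients x 2 x 2 x 4 = 128 rows, standardized predictors."""
    data = j.simulate_dataset(j.make_design(8, 2, 2, 4), j.aod_like_truth(), seed=21)
    data, _ = j.standardize_predictors(data)
    return data


@pytest.fixture(scope="session")
def ri_spec() -> j.ModelSpec:
    """Random-intercept joint model with the conjugate prior family."""
    return j.ModelSpec.from_structure("random_intercept", prior=j.preset("mcmcglmm_like"))


def make_empty_dataset() -> LongTableDataset:
    int_cols = {"patient_id", "leg", "side", "occasion", "status_y2"}
    df = pd.DataFrame(
        {c: pd.Series(dtype="int64" if c in int_cols else "float64") for c in SCHEMA}
    )
    return LongTableDataset(df)


def single_row_dataset(y1: float = 0.0, y2: int = 0, x1: float = 0.0, x2: float = 0.0):
    df = pd.DataFrame(
        {
            "patient_id": [1],
            "leg": [0],
            "side": [0],
            "occasion": [1],
            "score_y1": [y1],
            "status_y2": [y2],
            "ultrasound_x1": [x1],
            "rcp_x2": [x2],
        }
    )
    return LongTableDataset(df)


def conjugate_gaussian_spec(
    beta_scale: float = 1.0, covs: tuple = ("intercept",), sigma2: float = 1.0
) -> j.ModelSpec:
    """Continuous-only, no random effects, fixed sigma^2: the posterior for
    beta is exactly Normal (closed form used as the sampler oracle)."""
    return j.ModelSpec(
        structure="full",
        fixed_y1=covs,
        fixed_y2=("intercept",),
        random_covariates=(),
        responses=("y1",),
        prior=PriorConfig(beta_scale=beta_scale),
        fix_sigma2=sigma2,
    )


def conjugate_posterior(data, covs, beta_scale, sigma2):
    """Closed-form N(mean, cov) posterior of beta for the spec above."""
    X = data.design_matrix(covs)
    P = X.T @ X / sigma2 + np.eye(X.shape[1]) / beta_scale**2
    cov = np.linalg.inv(P)
    mean = cov @ (X.T @ data.y1 / sigma2)
    return mean, cov


def mcse_mean(x: np.ndarray) -> float:
    """Monte Carlo standard error of a posterior mean via bulk ESS."""
    from jointbhm.diagnostics import ess_bulk

    x = np.atleast_2d(x)
    return float(np.std(x, ddof=1) / np.sqrt(max(ess_bulk(x), 1.0)))
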