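"""Prior/posterior predictive checks, HPD intervals, and the prior
sensitivity harness."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .chains import ChainDraws, RunConfig
from .data import LongTableDataset
from .exceptions import InvalidArgumentError, UnsupportedPriorError
from .model import ModelFrame, ModelSpec
from .priors import PriorConfig


# ---------------------------------------------------------------------------
# HPD interval
# ---------------------------------------------------------------------------
def hpd_interval(draws_1d: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws."""
    if not (0.0 < mass < 1.0):
        raise InvalidArgumentError("mass must be in (0, 1)")
    x = np.sort(np.asarray(draws_1d, dtype=float).ravel())
    n = len(x)
    if n < 2:
        return (float(x[0]), float(x[0])) if n else (np.nan, np.nan)
    m = int(np.ceil(mass * n))
    m = min(max(m, 1), n)
    widths = x[m - 1 :] - x[: n - m + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m - 1])


# ---------------------------------------------------------------------------
# predictive simulation helpers
# ---------------------------------------------------------------------------
def _simulate_responses(
    frame: ModelFrame,
    beta1: np.ndarray,
    beta2: np.ndarray,
    sigma2: float,
    U: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One replicated (y1, y2) at the observed covariates."""
    y1 = np.zeros(frame.n)
    y2 = np.zeros(frame.n, dtype=int)
    if frame.has_y1:
        eta1 = frame.X1 @ beta1
        if frame.q:
            eta1 = eta1 + np.einsum("ij,ij->i", frame.Z, U[frame.codes, frame.u_cols["y1"]])
        y1 = eta1 + np.sqrt(sigma2) * rng.standard_normal(frame.n)
    if frame.has_y2:
        eta2 = frame.X2 @ beta2
        if frame.q:
            eta2 = eta2 + np.einsum("ij,ij->i", frame.Z, U[frame.codes, frame.u_cols["y2"]])
        y2 = ((eta2 + rng.standard_normal(frame.n)) > 0).astype(int)
    return y1, y2


def _summaries(y1: np.ndarray, y2: np.ndarray, has_y1: bool, has_y2: bool) -> dict:
    out: dict[str, float] = {}
    if has_y1:
        out["y1_mean"] = float(np.mean(y1))
        out["y1_sd"] = float(np.std(y1, ddof=1)) if len(y1) > 1 else 0.0
    if has_y2:
        out["y2_rate"] = float(np.mean(y2))
    return out


@dataclass
class PredictiveCheck:
    """Replicated responses plus per-replicate summary statistics."""

    y1_rep: np.ndarray  # (n_rep, n)
    y2_rep: np.ndarray
    summaries: pd.DataFrame
    observed: dict | None = None

    def coverage(self, stat: str, central: float = 0.95) -> bool:
        """Is the observed statistic inside the central interval of the
        replicated distribution?"""
        if self.observed is None or stat not in self.observed:
            raise InvalidArgumentError(f"no observed statistic {stat!r}")
        lo, hi = np.quantile(
            self.summaries[stat], [(1 - central) / 2, 1 - (1 - central) / 2]
        )
        return bool(lo <= self.observed[stat] <= hi)


def prior_predictive(
    spec: ModelSpec,
    data: LongTableDataset,
    n_draws: int = 200,
    seed: int = 0,
) -> PredictiveCheck:
    """Simulate datasets from the prior at the observed covariates.

    Proper priors required: a flat fixed-effect prior is rejected.
    """
    prior = spec.prior
    if not prior.is_proper:
        raise UnsupportedPriorError("prior predictive needs proper priors (flat beta)")
    frame = ModelFrame(data, spec)
    rng = np.random.default_rng(seed)
    y1_rep = np.zeros((n_draws, frame.n))
    y2_rep = np.zeros((n_draws, frame.n), dtype=int)
    rows = []
    for r in range(n_draws):
        beta1 = prior.beta_scale * rng.standard_normal(frame.p1)
        beta2 = prior.beta_scale * rng.standard_normal(frame.p2)
        sigma2 = prior.sigma2.sample(rng) if frame.free_sigma2 else (
            spec.fix_sigma2 or 1.0
        )
        if frame.q:
            Sigma = prior.sigma_u.sample(frame.q, rng)
            L = np.linalg.cholesky(Sigma)
            U = rng.standard_normal((frame.N, frame.q)) @ L.T
        else:
            U = np.zeros((frame.N, 0))
        y1, y2 = _simulate_responses(frame, beta1, beta2, sigma2, U, rng)
        y1_rep[r], y2_rep[r] = y1, y2
        rows.append(_summaries(y1, y2, frame.has_y1, frame.has_y2))
    obs = _summaries(frame.y1, frame.y2, frame.has_y1, frame.has_y2)
    return PredictiveCheck(y1_rep, y2_rep, pd.DataFrame(rows), obs)


def posterior_predictive(
    draws: ChainDraws,
    data: LongTableDataset,
    spec: ModelSpec,
    n_rep: int = 200,
    seed: int = 0,
) -> PredictiveCheck:
    """Simulate replicated responses from ``n_rep`` sampled posterior draws
    at the observed covariates (using each draw's random effects)."""
    frame = ModelFrame(data, spec)
    rng = np.random.default_rng(seed)
    S = draws.n_total
    pick = rng.choice(S, size=n_rep, replace=n_rep > S)
    stacked = draws.stacked
    y1_rep = np.zeros((n_rep, frame.n))
    y2_rep = np.zeros((n_rep, frame.n), dtype=int)
    rows = []
    for j, s in enumerate(pick):
        st = frame.row_to_state(stacked[s])
        y1, y2 = _simulate_responses(
            frame, st.beta_y1, st.beta_y2, st.sigma2_y1, st.U, rng
        )
        y1_rep[j], y2_rep[j] = y1, y2
        rows.append(_summaries(y1, y2, frame.has_y1, frame.has_y2))
    obs = _summaries(frame.y1, frame.y2, frame.has_y1, frame.has_y2)
    return PredictiveCheck(y1_rep, y2_rep, pd.DataFrame(rows), obs)


def plot_predictive_overlay(check: PredictiveCheck, path: str, max_rep: int = 50) -> None:
    """Optional PNG artifact: observed-vs-replicated density overlay for y1
    and the replicated y2-rate histogram.  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    from scipy.stats import gaussian_kde

    pooled = check.y1_rep[:max_rep]
    grid = np.linspace(pooled.min(), pooled.max(), 200)
    for rep in pooled:
        axes[0].plot(grid, gaussian_kde(rep)(grid), color="C0", alpha=0.15, lw=0.8)
    if check.observed is not None and "y1_mean" in check.observed:
        axes[0].axvline(check.observed["y1_mean"], color="C3", lw=1.5)
    axes[0].set_title("replicated y1 densities")
    axes[1].hist(check.summaries["y2_rate"], bins=20, color="C0", alpha=0.7)
    if check.observed is not None and "y2_rate" in check.observed:
        axes[1].axvline(check.observed["y2_rate"], color="C3", lw=1.5)
    axes[1].set_title("replicated P(Y2=1)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def density_grid(values: np.ndarray, n_points: int = 101) -> pd.DataFrame:
    """Pooled gaussian-KDE density grid for overlay plots (numeric output
    first; plotting is an optional artifact)."""
    from scipy.stats import gaussian_kde

    v = np.asarray(values, dtype=float).ravel()
    grid = np.linspace(v.min(), v.max(), n_points)
    return pd.DataFrame({"x": grid, "density": gaussian_kde(v)(grid)})


# ---------------------------------------------------------------------------
# prior sensitivity
# ---------------------------------------------------------------------------
@dataclass
class SensitivityTable:
    table: pd.DataFrame

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path)


def sensitivity_priors() -> list[tuple[str, PriorConfig]]:
    """Built-in trio: half-Student-t(3) reference, half-Cauchy(0,1), and a
    very informative positive-truncated Normal(5, 0.01)."""
    from .priors import (
        HalfCauchy,
        HalfStudentT,
        LKJWithScales,
        ScaleSigma2,
        TruncatedNormalScale,
    )

    def cfg(sp) -> PriorConfig:
        return PriorConfig(
            beta_scale=10.0, sigma2=ScaleSigma2(sp), sigma_u=LKJWithScales(2.0, sp)
        )

    return [
        ("half_student_t(3)", cfg(HalfStudentT(3.0, 0.0, 10.0))),
        ("half_cauchy(0,1)", cfg(HalfCauchy(1.0))),
        ("truncated_normal(5,0.01)", cfg(TruncatedNormalScale(5.0, 0.01))),
    ]


def sensitivity_analysis(
    data: LongTableDataset,
    spec: ModelSpec,
    priors: list[tuple[str, PriorConfig]] | None = None,
    reference: int = 0,
    sampler: str = "hmc",
    run: RunConfig | None = None,
    use_mean: bool = False,
    near_zero: float = 0.05,
) -> SensitivityTable:
    """Refit under each prior; report posterior medians (or means), 95% HPD
    intervals, and percent deviation from the reference prior.

    Parameters whose reference median is below ``near_zero`` in absolute
    value are flagged numerically sensitive (tiny denominators make the
    percentages unstable)."""
    from .samplers import run_sampler

    priors = priors if priors is not None else sensitivity_priors()
    if len(priors) < 2:
        raise InvalidArgumentError("sensitivity analysis needs >= 2 priors")
    if not (0 <= reference < len(priors)):
        raise InvalidArgumentError("reference prior index out of range")
    run = run if run is not None else RunConfig(
        n_chains=2, n_iterations=1500, burn_in=500, thinning=1
    )
    results: dict[str, dict[str, tuple[float, float, float]]] = {}
    for label, prior in priors:
        fitted_spec = ModelSpec(
            structure=spec.structure,
            fixed_y1=spec.fixed_y1,
            fixed_y2=spec.fixed_y2,
            random_covariates=spec.random_covariates,
            responses=spec.responses,
            prior=prior,
            fix_sigma2=spec.fix_sigma2,
        )
        fit = run_sampler(sampler, data, fitted_spec, run=run)
        per_param = {}
        for nm in fit.param_names:
            if nm.startswith("u["):
                continue
            x = fit.get(nm).ravel()
            center = float(np.mean(x)) if use_mean else float(np.median(x))
            lo, hi = hpd_interval(x, 0.95)
            per_param[nm] = (center, lo, hi)
        results[label] = per_param
    ref_label = priors[reference][0]
    ref = results[ref_label]
    rows = []
    for nm in ref:
        row: dict[str, float | str] = {"parameter": nm}
        ref_med = ref[nm][0]
        for label, _ in priors:
            med, lo, hi = results[label][nm]
            row[f"{label}:median"] = med
            row[f"{label}:hpd_lo"] = lo
            row[f"{label}:hpd_hi"] = hi
            if label == ref_label:
                row[f"{label}:pct_dev"] = 0.0
            else:
                row[f"{label}:pct_dev"] = (
                    100.0 * (med - ref_med) / abs(ref_med) if ref_med != 0 else np.inf
                )
        row["flag"] = "numerically sensitive" if abs(ref_med) < near_zero else ""
        rows.append(row)
    return SensitivityTable(pd.DataFrame(rows).set_index("parameter"))


def probit_marginal_rate(eta_fixed: np.ndarray, z_var: float) -> np.ndarray:
    """Closed-form marginal P(Y2=1 | x) = Phi(eta / sqrt(1 + z' Sigma z))
    used as a test oracle for the simulator."""
    return ndtr(eta_fixed / np.sqrt(1.0 + z_var))
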