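"""Predictive model-comparison criteria: DIC, WAIC, PSIS-LOO, K-fold CV and
an information-complexity (ICOMP) criterion.

The pointwise log-likelihood is conditional on the drawn random effects,
matching how hierarchical-model WAIC/LOO is conventionally computed; a
marginal (quadrature) variant is available for K-fold scoring behind a flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .chains import ChainDraws, RunConfig
from .data import LongTableDataset
from .exceptions import DegenerateInputError, InvalidArgumentError
from .model import LOG2PI, ModelFrame, ModelSpec


# ---------------------------------------------------------------------------
# pointwise conditional log-likelihood
# ---------------------------------------------------------------------------
def pointwise_loglik(
    draws: ChainDraws, data: LongTableDataset, spec: ModelSpec
) -> np.ndarray:
    """S x n matrix with entry (s, i) = log p(y1_i | theta_s) + log p(y2_i |
    theta_s), conditional on the drawn random effects."""
    from scipy.special import log_ndtr

    frame = ModelFrame(data, spec)
    S = draws.n_total
    stacked = draws.stacked
    names = draws.param_names
    out = np.zeros((S, frame.n))

    def block(prefix: str, expected: list[str]) -> np.ndarray:
        idx = [names.index(nm) for nm in expected]
        return stacked[:, idx]

    if frame.has_y1:
        b1 = block("beta_y1", [f"beta_y1[{c}]" for c in spec.fixed_y1])
        eta1 = b1 @ frame.X1.T  # (S, n)
    if frame.has_y2:
        b2 = block("beta_y2", [f"beta_y2[{c}]" for c in spec.fixed_y2])
        eta2 = b2 @ frame.X2.T
    if frame.q:
        u_names = [
            f"u[{i + 1},{c}]" for i in range(frame.N) for c in frame.component_names
        ]
        U = block("u", u_names).reshape(S, frame.N, frame.q)
        if frame.has_y1:
            eta1 = eta1 + np.einsum(
                "nk,snk->sn", frame.Z, U[:, frame.codes, frame.u_cols["y1"]]
            )
        if frame.has_y2:
            eta2 = eta2 + np.einsum(
                "nk,snk->sn", frame.Z, U[:, frame.codes, frame.u_cols["y2"]]
            )
    if frame.has_y1:
        if frame.free_sigma2:
            s2 = stacked[:, names.index("sigma2_y1")][:, None]
        else:
            s2 = np.full((S, 1), spec.fix_sigma2 if spec.fix_sigma2 is not None else 1.0)
        r = frame.y1[None, :] - eta1
        out += -0.5 * (LOG2PI + np.log(s2)) - 0.5 * r * r / s2
    if frame.has_y2:
        out += log_ndtr(frame.sign2[None, :] * eta2)
    if out.shape[1] != frame.n:
        raise InvalidArgumentError("shape mismatch between draws and data")
    return out


def pointwise_loglik_marginal(
    draws: ChainDraws,
    data: LongTableDataset,
    spec: ModelSpec,
    n_nodes: int = 9,
    max_draws: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """S' x N_patients matrix of *marginal* (random effects integrated out by
    adaptive Gauss-Hermite quadrature) per-subject log-likelihoods.

    Sensitivity tool for subject-level LOO; quadrature is expensive, so at
    most ``max_draws`` posterior draws are subsampled.
    """
    from .model import integrated_loglik_subject

    frame = ModelFrame(data, spec)
    rng = np.random.default_rng(seed)
    S = draws.n_total
    pick = np.sort(rng.choice(S, size=min(max_draws, S), replace=False))
    stacked = draws.stacked
    out = np.zeros((len(pick), frame.N))
    for row_i, s in enumerate(pick):
        state = frame.row_to_state(stacked[s])
        for pc in range(frame.N):
            out[row_i, pc] = integrated_loglik_subject(state, frame, pc, n_nodes)
    return out


# ---------------------------------------------------------------------------
# WAIC
# ---------------------------------------------------------------------------
def waic(pw: np.ndarray) -> tuple[float, float, float]:
    """Return (lppd, p_waic, waic) with the S-1 variance denominator."""
    pw = np.asarray(pw, dtype=float)
    S = pw.shape[0]
    if S < 2:
        raise InvalidArgumentError("waic needs at least 2 draws")
    lppd = float(np.sum(logsumexp(pw, axis=0) - math.log(S)))
    p_waic = float(np.sum(np.var(pw, axis=0, ddof=1)))
    return lppd, p_waic, -2.0 * (lppd - p_waic)


# ---------------------------------------------------------------------------
# generalized Pareto fit (profile/empirical-Bayes method)
# ---------------------------------------------------------------------------
def gpd_fit(tail_sample: np.ndarray) -> tuple[float, float]:
    """Fit exceedances to a generalized Pareto distribution.

    Uses the Zhang-Stephens profile-posterior quadrature with the weak
    prior regularization of the shape toward 0.5 that is standard in the
    PSIS literature.  Returns (k, sigma).
    """
    x = np.sort(np.asarray(tail_sample, dtype=float))
    n = len(x)
    if n < 5:
        raise InvalidArgumentError("gpd_fit needs at least 5 tail points")
    if x[-1] - x[0] < 1e-14 * max(abs(x[-1]), 1.0):
        raise DegenerateInputError("gpd_fit: tail sample has no spread")
    m = 30 + int(math.sqrt(n))
    prior_bs = 3.0
    x_quart = x[int(n / 4.0 + 0.5) - 1]
    if x_quart <= 0 or x[-1] <= 0:
        raise DegenerateInputError("gpd_fit: non-positive exceedances in tail")
    j = np.arange(1, m + 1)
    b = 1.0 / x[-1] + (1.0 - np.sqrt(m / (j - 0.5))) / (prior_bs * x_quart)
    k_b = -np.mean(np.log1p(-b[:, None] * x[None, :]), axis=1)
    log_lik = n * (np.log(b / k_b) + k_b - 1.0)
    with np.errstate(over="ignore"):  # overflow -> weight 0, which is correct
        w = 1.0 / np.sum(np.exp(log_lik[None, :] - log_lik[:, None]), axis=1)
    b_hat = float(np.sum(b * w))
    k_hat = float(np.mean(np.log1p(-b_hat * x)))
    sigma = -k_hat / b_hat
    # weak prior: pull k toward 0.5 with 10 pseudo-observations
    k_hat = k_hat * n / (n + 10.0) + 0.5 * 10.0 / (n + 10.0)
    return k_hat, float(sigma)


def _gpd_quantiles(p: np.ndarray, k: float, sigma: float) -> np.ndarray:
    if abs(k) < 1e-12:
        return -sigma * np.log1p(-p)
    return sigma / k * (np.power(1.0 - p, -k) - 1.0)


# ---------------------------------------------------------------------------
# PSIS-LOO
# ---------------------------------------------------------------------------
@dataclass
class LooResult:
    elpd_loo: float
    p_loo: float
    loo_ic: float
    pareto_k: np.ndarray
    elpd_i: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_bad(self) -> int:
        return int(np.sum(self.pareto_k > 0.7))


def psis_loo(pw: np.ndarray) -> LooResult:
    """Pareto-smoothed importance-sampling LOO.

    Raw ratios are exp(-pw); the largest M = min(ceil(0.2 S), ceil(3 sqrt S))
    log-weights are replaced by fitted-GPD order-statistic quantiles and all
    weights truncated at the raw maximum.  Observations with k > 0.7 are
    unreliable (flagged by the caller via ``pareto_k``).
    """
    pw = np.asarray(pw, dtype=float)
    S, n = pw.shape
    if S < 100:
        warnings.warn(f"psis_loo: only {S} draws; results may be unstable", stacklevel=2)
    lppd_i = logsumexp(pw, axis=0) - math.log(S)
    elpd_i = np.zeros(n)
    ks = np.zeros(n)
    M = int(min(math.ceil(0.2 * S), math.ceil(3.0 * math.sqrt(S))))
    for i in range(n):
        lr = -pw[:, i]
        lr = lr - lr.max()
        order = np.argsort(lr)
        tail_idx = order[S - M :]
        cutoff_log = lr[order[S - M - 1]]
        exceed = np.exp(lr[tail_idx]) - math.exp(cutoff_log)
        lw = lr.copy()
        try:
            k, sigma = gpd_fit(exceed)
            p = (np.arange(1, M + 1) - 0.5) / M
            smoothed = math.exp(cutoff_log) + _gpd_quantiles(p, k, sigma)
            # assign smoothed quantiles to tail members in ascending order
            asc = tail_idx[np.argsort(lr[tail_idx], kind="stable")]
            lw[asc] = np.log(smoothed)
            lw = np.minimum(lw, 0.0)  # truncate at max raw weight (=0 after shift)
        except DegenerateInputError:
            k = -np.inf  # zero-spread tail: weights effectively uniform
        ks[i] = k
        elpd_i[i] = logsumexp(pw[:, i] + lw) - logsumexp(lw)
    elpd = float(np.sum(elpd_i))
    p_loo = float(np.sum(lppd_i) - elpd)
    return LooResult(elpd, p_loo, -2.0 * elpd, ks, elpd_i)


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------
def _plugin_state(draws: ChainDraws, frame: ModelFrame):
    """Posterior-mean state on the constrained scale; Sigma_u is projected to
    the nearest SPD matrix if element-wise averaging left the cone."""
    mean_row = draws.stacked.mean(axis=0)
    state = frame.row_to_state(mean_row)
    if frame.q:
        eig = np.linalg.eigvalsh(state.Sigma_u)
        if np.any(eig <= 0):
            warnings.warn("posterior-mean Sigma_u not SPD; projecting", stacklevel=2)
            val, vec = np.linalg.eigh(state.Sigma_u)
            state.Sigma_u = (vec * np.clip(val, 1e-10, None)) @ vec.T
    return state


def dic(
    draws: ChainDraws,
    data: LongTableDataset,
    spec: ModelSpec,
    pw: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Deviance information criterion: returns (Dbar, pD, DIC) with the
    plug-in deviance evaluated at constrained-scale posterior means."""
    frame = ModelFrame(data, spec)
    if pw is None:
        pw = pointwise_loglik(draws, data, spec)
    deviances = -2.0 * pw.sum(axis=1)
    dbar = float(np.mean(deviances))
    from .model import pointwise_loglik_state

    d_hat = -2.0 * float(np.sum(pointwise_loglik_state(_plugin_state(draws, frame), frame)))
    p_d = dbar - d_hat
    return dbar, p_d, dbar + p_d


# ---------------------------------------------------------------------------
# ICOMP
# ---------------------------------------------------------------------------
def c1_complexity(cov: np.ndarray) -> float:
    """Maximal-information complexity C1(S) = (s/2) log(tr S / s) - (1/2) log det S."""
    cov = np.atleast_2d(cov)
    s = cov.shape[0]
    eig = np.linalg.eigvalsh(cov)
    if eig.min() <= 0:
        ridge = 1e-8 * np.trace(cov) / s
        warnings.warn("singular draw covariance; adding ridge", stacklevel=2)
        eig = eig + ridge
    return float(0.5 * s * math.log(np.sum(eig) / s) - 0.5 * np.sum(np.log(eig)))


def icomp(
    draws: ChainDraws,
    data: LongTableDataset,
    spec: ModelSpec,
    pw: np.ndarray | None = None,
) -> float:
    """ICOMP = D(theta_bar) + 2 C1(cov of unconstrained draws).

    The C1-penalized form is an implementation choice (the criterion family
    has several variants); documented as such.
    """
    frame = ModelFrame(data, spec)
    if draws.n_total < 2:
        raise InvalidArgumentError("icomp needs at least 2 draws")
    vecs = np.array(
        [frame.to_unconstrained(st) for st in draws.states(frame)]
    )
    cov = np.cov(vecs, rowvar=False)
    from .model import pointwise_loglik_state

    d_hat = -2.0 * float(np.sum(pointwise_loglik_state(_plugin_state(draws, frame), frame)))
    return d_hat + 2.0 * c1_complexity(np.atleast_2d(cov))


# ---------------------------------------------------------------------------
# K-fold cross-validation
# ---------------------------------------------------------------------------
def make_folds(
    data: LongTableDataset, K: int, seed: int = 0
) -> np.ndarray:
    """Fold labels per row: cyclic assignment within the patient-sorted row
    order (so every patient keeps rows in every training set where
    possible), with a seeded random fold-label rotation/permutation."""
    n = data.n_rows
    if K < 2 or K > n:
        raise InvalidArgumentError("require 2 <= K <= n")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(K)
    order = np.argsort(data.df["patient_id"].to_numpy(), kind="stable")
    labels = np.empty(n, dtype=int)
    labels[order] = perm[np.arange(n) % K]
    return labels


def kfold_cv(
    data: LongTableDataset,
    spec: ModelSpec,
    sampler: str = "gibbs",
    K: int = 10,
    run: RunConfig | None = None,
    seed: int = 0,
) -> tuple[float, list[dict]]:
    """K-fold expected log predictive density.

    Per fold: refit on the training rows, then score each held-out row by
    log mean_s p(y_i | theta_s, u_s) over the training posterior draws
    (conditional predictive density).  Returns (elpd_kfold, per_fold).
    """
    from .samplers import run_sampler

    run = run if run is not None else RunConfig(
        n_chains=2, n_iterations=1500, burn_in=500, thinning=2, seed=seed
    )
    labels = make_folds(data, K, seed)
    per_fold = []
    total = 0.0
    for fold in range(K):
        test_mask = labels == fold
        train = data.subset(~test_mask)
        test = data.subset(test_mask)
        fold_run = RunConfig(
            n_chains=run.n_chains,
            n_iterations=run.n_iterations,
            burn_in=run.burn_in,
            thinning=run.thinning,
            seed=run.seed + 1000 * fold,
        )
        fit = run_sampler(sampler, train, spec, run=fold_run)
        # score: align test patients with the training random effects
        elpd_fold = _score_heldout(fit, train, test, spec)
        total += elpd_fold
        per_fold.append({"fold": fold, "n_test": int(test_mask.sum()), "elpd": elpd_fold})
    return total, per_fold


def _score_heldout(
    fit: ChainDraws,
    train: LongTableDataset,
    test: LongTableDataset,
    spec: ModelSpec,
) -> float:
    from scipy.special import log_ndtr

    train_frame = ModelFrame(train, spec)
    test_frame = ModelFrame(test, spec)
    S = fit.n_total
    stacked = fit.stacked
    names = fit.param_names
    train_ids = train_frame.data.patient_ids
    # map test rows -> training patient slots (patients always present by
    # construction of the folds; unseen patients would get u = 0)
    test_pids = test.df["patient_id"].to_numpy()
    slot = np.searchsorted(train_ids, test_pids)
    known = (slot < len(train_ids)) & (train_ids[np.clip(slot, 0, len(train_ids) - 1)] == test_pids)
    pw = np.zeros((S, test_frame.n))
    if test_frame.has_y1:
        b1 = stacked[:, [names.index(f"beta_y1[{c}]") for c in spec.fixed_y1]]
        eta1 = b1 @ test_frame.X1.T
    if test_frame.has_y2:
        b2 = stacked[:, [names.index(f"beta_y2[{c}]") for c in spec.fixed_y2]]
        eta2 = b2 @ test_frame.X2.T
    if train_frame.q:
        u_names = [
            f"u[{i + 1},{c}]"
            for i in range(train_frame.N)
            for c in train_frame.component_names
        ]
        U = stacked[:, [names.index(nm) for nm in u_names]].reshape(
            S, train_frame.N, train_frame.q
        )
        u_rows = np.where(known[:, None], U[:, np.clip(slot, 0, train_frame.N - 1), :], 0.0)
        if test_frame.has_y1:
            eta1 = eta1 + np.einsum(
                "nk,snk->sn", test_frame.Z, u_rows[:, :, train_frame.u_cols["y1"]]
            )
        if test_frame.has_y2:
            eta2 = eta2 + np.einsum(
                "nk,snk->sn", test_frame.Z, u_rows[:, :, train_frame.u_cols["y2"]]
            )
    if test_frame.has_y1:
        if train_frame.free_sigma2:
            s2 = stacked[:, names.index("sigma2_y1")][:, None]
        else:
            s2 = np.full((S, 1), spec.fix_sigma2 if spec.fix_sigma2 is not None else 1.0)
        r = test_frame.y1[None, :] - eta1
        pw += -0.5 * (LOG2PI + np.log(s2)) - 0.5 * r * r / s2
    if test_frame.has_y2:
        pw += log_ndtr(test_frame.sign2[None, :] * eta2)
    return float(np.sum(logsumexp(pw, axis=0) - math.log(S)))


# ---------------------------------------------------------------------------
# combined report
# ---------------------------------------------------------------------------
@dataclass
class CriteriaReport:
    dic: tuple[float, float, float]
    waic: tuple[float, float, float]
    loo: LooResult
    icomp: float
    kfold: tuple[float, list[dict]] | None = None

    def row(self) -> dict[str, float]:
        out = {
            "DIC": self.dic[2],
            "ICOMP": self.icomp,
            "WAIC": self.waic[2],
            "LOO_IC": self.loo.loo_ic,
        }
        out["K-fold"] = -2.0 * self.kfold[0] if self.kfold is not None else float("nan")
        return out


def evaluate_criteria(
    draws: ChainDraws,
    data: LongTableDataset,
    spec: ModelSpec,
    kfold_K: int | None = None,
    kfold_sampler: str = "gibbs",
    kfold_run: RunConfig | None = None,
    seed: int = 0,
) -> CriteriaReport:
    pw = pointwise_loglik(draws, data, spec)
    report = CriteriaReport(
        dic=dic(draws, data, spec, pw=pw),
        waic=waic(pw),
        loo=psis_loo(pw),
        icomp=icomp(draws, data, spec, pw=pw),
    )
    if kfold_K:
        report.kfold = kfold_cv(
            data, spec, sampler=kfold_sampler, K=kfold_K, run=kfold_run, seed=seed
        )
    return report
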