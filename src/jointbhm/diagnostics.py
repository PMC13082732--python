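"""Convergence and efficiency diagnostics.

Implements rank-normalized split R-hat and Bulk/Tail effective sample sizes
(autocorrelation sums with Geyer's initial-monotone truncation), plus a
posterior summary table.  Plain (non-rank) split R-hat is available behind a
flag for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .chains import ChainDraws
from .exceptions import InsufficientChainsError, InvalidArgumentError

_EPS = 1e-10


def _as_chain_matrix(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2:
        raise InvalidArgumentError("expected (chains, draws) matrix")
    return x


def _split_chains(x: np.ndarray) -> np.ndarray:
    m, n = x.shape
    half = n // 2
    return np.vstack([x[:, :half], x[:, half : 2 * half]])


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    """Pooled fractional ranks mapped through the normal quantile function."""
    shape = x.shape
    flat = x.ravel()
    ranks = np.argsort(np.argsort(flat, kind="stable"), kind="stable") + 1.0
    # average ties for stability on discrete inputs
    order = np.argsort(flat, kind="stable")
    sorted_vals = flat[order]
    avg = np.empty_like(ranks)
    i = 0
    n = len(flat)
    rr = np.empty(n)
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        rr[i : j + 1] = 0.5 * (i + j) + 1.0
        i = j + 1
    avg[order] = rr
    z = ndtri((avg - 3.0 / 8.0) / (n + 0.25))
    return z.reshape(shape)


def _rhat_basic(x: np.ndarray) -> float:
    m, n = x.shape
    means = x.mean(axis=1)
    w = float(np.mean(np.var(x, axis=1, ddof=1)))
    b = float(n * np.var(means, ddof=1))
    if w < _EPS:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def split_rhat(x: np.ndarray, rank_normalized: bool = True) -> float:
    """Split R-hat; with ``rank_normalized`` the max of the bulk (rank) and
    folded-rank variants is returned.  Constant input returns 1.0."""
    x = _as_chain_matrix(x)
    if x.shape[0] < 2:
        raise InsufficientChainsError("split_rhat needs at least 2 chains")
    if x.shape[1] < 4:
        raise InvalidArgumentError("split_rhat needs at least 4 draws per chain")
    if np.ptp(x) < _EPS:
        return 1.0
    xs = _split_chains(x)
    if not rank_normalized:
        return max(_rhat_basic(xs), 1.0)
    bulk = _rhat_basic(_rank_normalize(xs))
    folded = _rhat_basic(_rank_normalize(np.abs(xs - np.median(xs))))
    # the estimator can dip below 1 in finite samples; floor for reporting
    return max(bulk, folded, 1.0)


def _autocovariance(x: np.ndarray) -> np.ndarray:
    """Per-chain autocovariance (biased, FFT) for each lag."""
    m, n = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), size, axis=1)[:, :n].real
    return acov / n


def _ess_from_matrix(x: np.ndarray) -> float:
    """Combined-chain ESS with Geyer initial-monotone positive truncation."""
    m, n = x.shape
    if n < 4:
        raise InvalidArgumentError("ess needs at least 4 draws per chain")
    if np.ptp(x) < _EPS:
        return float(m * n)  # degenerate: no information, report total by convention
    acov = _autocovariance(x)
    chain_var = acov[:, 0] * n / (n - 1.0)
    w = float(np.mean(chain_var))
    mean_acov = acov.mean(axis=0)
    if m > 1:
        var_plus = (n - 1.0) / n * w + float(np.var(x.mean(axis=1), ddof=1))
    else:
        var_plus = (n - 1.0) / n * w + w / n
    if var_plus < _EPS:
        return float(m * n)
    rho = 1.0 - (w - mean_acov) / var_plus
    rho[0] = 1.0
    # Geyer: sums of adjacent-lag pairs (rho_0+rho_1), (rho_2+rho_3), ...
    # kept while positive and forced monotone non-increasing.
    pair_sums = []
    for t in range(0, n - 1, 2):
        s = rho[t] + (rho[t + 1] if t + 1 < n else 0.0)
        if s <= 0:
            break
        pair_sums.append(s)
    mono = np.minimum.accumulate(pair_sums) if pair_sums else np.zeros(0)
    tau = -1.0 + 2.0 * float(np.sum(mono))
    tau = max(tau, 1.0 / np.log10(m * n + 10.0))
    ess = m * n / tau
    return float(min(ess, 1.5 * m * n))


def ess_bulk(x: np.ndarray) -> float:
    """Bulk ESS: ESS of the rank-normalized split chains."""
    x = _as_chain_matrix(x)
    if np.ptp(x) < _EPS:
        return float(x.size)
    return _ess_from_matrix(_rank_normalize(_split_chains(x)))


def ess_tail(x: np.ndarray) -> float:
    """Tail ESS: minimum ESS of the 5% and 95% quantile indicators."""
    x = _as_chain_matrix(x)
    if np.ptp(x) < _EPS:
        return float(x.size)
    out = []
    for prob in (0.05, 0.95):
        q = np.quantile(x, prob)
        ind = (x <= q).astype(float)
        if np.ptp(ind) < _EPS:
            out.append(float(x.size))
        else:
            out.append(_ess_from_matrix(_rank_normalize(_split_chains(ind))))
    return float(min(out))


@dataclass
class DiagnosticsReport:
    """Per-parameter summary plus global convergence indicators."""

    table: pd.DataFrame
    max_rhat: float
    min_ess: float

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path)

    def to_json(self, path: str) -> None:
        payload = self.table.to_dict(orient="index")
        out = {
            "parameters": payload,
            "max_rhat": self.max_rhat,
            "min_ess": self.min_ess,
        }
        import json

        with open(path, "w") as fh:
            json.dump(out, fh, indent=1)

    def pretty(self) -> str:
        with pd.option_context("display.width", 160, "display.max_rows", 500):
            return self.table.to_string(float_format=lambda v: f"{v:9.4f}")


def mcmc_summary(
    draws: ChainDraws, include_random_effects: bool = False
) -> DiagnosticsReport:
    """One row per parameter: mean, sd, 2.5%/97.5% quantiles, split R-hat,
    Bulk-ESS, Tail-ESS, and threshold flags at all the conventional levels
    (R-hat 1.01 / 1.1; ESS 100 per chain / 400 / 1000)."""
    names = [
        nm
        for nm in draws.param_names
        if include_random_effects or not nm.startswith("u[")
    ]
    n_chains = draws.n_chains
    rows = []
    for nm in names:
        x = draws.get(nm)
        pooled = x.ravel()
        degenerate = np.ptp(pooled) < _EPS
        rhat = split_rhat(x) if n_chains >= 2 else np.nan
        eb = ess_bulk(x)
        et = ess_tail(x)
        flags = []
        if degenerate:
            flags.append("degenerate")
        else:
            if n_chains >= 2 and rhat > 1.1:
                flags.append("rhat>1.1")
            elif n_chains >= 2 and rhat > 1.01:
                flags.append("rhat>1.01")
            if min(eb, et) < 100 * n_chains:
                flags.append(f"ess<{100 * n_chains}")
            if min(eb, et) < 400:
                flags.append("ess<400")
            if min(eb, et) < 1000:
                flags.append("ess<1000")
        rows.append(
            {
                "mean": float(pooled.mean()),
                "sd": float(pooled.std(ddof=1)) if len(pooled) > 1 else 0.0,
                "q2.5": float(np.quantile(pooled, 0.025)),
                "q97.5": float(np.quantile(pooled, 0.975)),
                "split_rhat": float(rhat),
                "bulk_ess": float(eb),
                "tail_ess": float(et),
                "flags": ",".join(flags),
            }
        )
    table = pd.DataFrame(rows, index=names)
    non_deg = table[~table["flags"].str.contains("degenerate")]
    max_rhat = float(non_deg["split_rhat"].max()) if len(non_deg) else 1.0
    min_ess = (
        float(min(non_deg["bulk_ess"].min(), non_deg["tail_ess"].min()))
        if len(non_deg)
        else float(draws.n_total)
    )
    return DiagnosticsReport(table=table, max_rhat=max_rhat, min_ess=min_ess)
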