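"""Three self-contained MCMC engines for the joint posterior.

* blockwise random-walk Metropolis / general Metropolis-Hastings on the
  unconstrained scale,
* a systematic-scan Gibbs sampler using latent-normal (Albert-Chib style)
  augmentation for the probit sub-model, requiring the conjugate prior
  family (normal beta, inverse-gamma sigma^2, inverse-Wishart Sigma_u),
* fixed-trajectory Hamiltonian Monte Carlo with a leapfrog integrator,
  diagonal mass matrix and dual-averaging step-size adaptation.

All samplers are single-threaded and bit-reproducible given a seed; chains
derive their streams from the master seed via ``SeedSequence.spawn``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .chains import ChainDraws, RunConfig
from .data import LongTableDataset
from .exceptions import (
    InitializationError,
    InvalidArgumentError,
    TuningFailureError,
)
from .model import (
    ModelFrame,
    ModelSpec,
    ParameterState,
    linear_predictor,
    logpost_and_grad_unconstrained,
)

__all__ = [
    "ProposalConfig",
    "HMCConfig",
    "run_metropolis_hastings",
    "run_gibbs",
    "run_hmc",
    "draw_latent_y2star",
    "leapfrog",
    "metropolis_hastings_kernel",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------
@dataclass
class ProposalConfig:
    """Per-block random-walk scales, or a custom full-vector proposal Q.

    A custom ``q_sample(rng, x) -> x'`` with ``q_logpdf(x_from, x_to)``
    switches the kernel to general (possibly asymmetric) MH.
    """

    scales: dict[str, float] = field(
        default_factory=lambda: {"beta_y1": 0.1, "beta_y2": 0.1, "variance": 0.1, "u": 0.1}
    )
    adapt: bool = True
    target_accept: float = 0.35
    q_sample: Callable[[np.random.Generator, np.ndarray], np.ndarray] | None = None
    q_logpdf: Callable[[np.ndarray, np.ndarray], float] | None = None

    def __post_init__(self) -> None:
        for k, v in self.scales.items():
            if v <= 0:
                raise InvalidArgumentError(f"proposal scale for {k!r} must be > 0")


@dataclass
class HMCConfig:
    step_size: float | None = None  # None -> auto heuristic + adaptation
    n_leapfrog: int = 32
    mass: np.ndarray | None = None  # diagonal, None -> identity (maybe adapted)
    target_accept: float = 0.9
    adapt: bool = True
    adapt_mass: bool = True
    divergence_threshold: float = 1000.0
    jitter: float = 0.1  # relative step-size jitter per iteration
    #: trajectory lengths are drawn uniformly in [ceil(0.5 L), floor(1.5 L)]
    #: each iteration; randomized path lengths break leapfrog resonances that
    #: otherwise leave individual coordinates mixing by random walk
    jitter_length: bool = True

    def __post_init__(self) -> None:
        if self.step_size is not None and self.step_size <= 0:
            raise InvalidArgumentError("step_size must be > 0")
        if self.n_leapfrog < 1:
            raise InvalidArgumentError("n_leapfrog must be >= 1")
        if not (0.0 < self.target_accept < 1.0):
            raise InvalidArgumentError("target_accept must be in (0, 1)")


# ---------------------------------------------------------------------------
# generic Metropolis-Hastings kernel (also used by fixture-target tests)
# ---------------------------------------------------------------------------
def metropolis_hastings_kernel(
    log_target: Callable[[np.ndarray], float],
    x0: np.ndarray,
    rng: np.random.Generator,
    n_iterations: int,
    burn_in: int = 0,
    thinning: int = 1,
    blocks: list[np.ndarray] | None = None,
    scales: list[float] | None = None,
    q_sample: Callable[[np.random.Generator, np.ndarray], np.ndarray] | None = None,
    q_logpdf: Callable[[np.ndarray, np.ndarray], float] | None = None,
    adapt: bool = False,
    target_accept: float = 0.35,
) -> tuple[np.ndarray, dict[str, Any]]:
    """Random-walk (blockwise) or general MH on an arbitrary target.

    Acceptance p = min{1, P(x*) Q(x*, x) / (P(x) Q(x, x*))}, reducing to the
    Metropolis ratio for symmetric Q.
    """
    x = np.array(x0, dtype=float)
    lp = log_target(x)
    if not np.isfinite(lp):
        raise InitializationError("log target not finite at the initial state")
    dim = len(x)
    if q_sample is None:
        if blocks is None:
            blocks = [np.arange(dim)]
        if scales is None:
            scales = [0.1] * len(blocks)
        log_scales = [math.log(s) for s in scales]
    kept = []
    n_blocks = 1 if q_sample is not None else len(blocks)
    acc_post = np.zeros(n_blocks)
    n_post = 0
    for it in range(n_iterations):
        if q_sample is not None:
            prop = np.asarray(q_sample(rng, x), dtype=float)
            lp_prop = log_target(prop)
            log_ratio = (lp_prop + q_logpdf(prop, x)) - (lp + q_logpdf(x, prop))
            if math.log(rng.random()) <= min(0.0, log_ratio):
                x, lp = prop, lp_prop
                if it >= burn_in:
                    acc_post[0] += 1
        else:
            for b, idx in enumerate(blocks):
                prop = x.copy()
                prop[idx] = prop[idx] + math.exp(log_scales[b]) * rng.standard_normal(len(idx))
                lp_prop = log_target(prop)
                log_ratio = lp_prop - lp
                alpha = math.exp(min(0.0, log_ratio)) if np.isfinite(log_ratio) else 0.0
                if rng.random() <= alpha:
                    x, lp = prop, lp_prop
                if adapt and it < burn_in:
                    log_scales[b] += (alpha - target_accept) * min(0.1, 3.0 / math.sqrt(it + 1.0))
                elif it >= burn_in:
                    acc_post[b] += alpha
        if it >= burn_in and (it - burn_in) % thinning == 0:
            kept.append(x.copy())
        if it >= burn_in:
            n_post += 1
    stats_out: dict[str, Any] = {
        "acceptance": (acc_post / max(n_post, 1)).tolist(),
    }
    if q_sample is None:
        stats_out["scales"] = [math.exp(s) for s in log_scales]
    return np.array(kept), stats_out


def _initial_unconstrained(
    frame: ModelFrame, rng: np.random.Generator, jitter: float = 0.1
) -> np.ndarray:
    """Jittered start near the origin of the unconstrained scale
    (beta = 0, sigma^2 = 1, Sigma_u = I, U = 0)."""
    for _ in range(50):
        v = jitter * rng.standard_normal(frame.dim)
        lp, _ = logpost_and_grad_unconstrained(v, frame)
        if np.isfinite(lp):
            return v
    raise InitializationError("could not find a starting state with finite posterior")


def _frame_blocks(frame: ModelFrame) -> tuple[list[np.ndarray], list[str]]:
    blocks, names = [], []
    if frame.p1:
        blocks.append(np.arange(frame.dim)[frame.sl_b1]); names.append("beta_y1")
    if frame.p2:
        blocks.append(np.arange(frame.dim)[frame.sl_b2]); names.append("beta_y2")
    var_idx = np.concatenate(
        [np.arange(frame.dim)[frame.sl_t], np.arange(frame.dim)[frame.sl_c]]
    )
    if len(var_idx):
        blocks.append(var_idx); names.append("variance")
    if frame.q:
        blocks.append(np.arange(frame.dim)[frame.sl_u]); names.append("u")
    return blocks, names


def run_metropolis_hastings(
    data: LongTableDataset,
    spec: ModelSpec,
    proposal: ProposalConfig | None = None,
    run: RunConfig | None = None,
) -> ChainDraws:
    """Blockwise random-walk Metropolis(-Hastings) on the unconstrained scale."""
    proposal = proposal if proposal is not None else ProposalConfig()
    run = run if run is not None else RunConfig(n_iterations=11000, burn_in=1000, thinning=10)
    frame = ModelFrame(data, spec)
    blocks, names = _frame_blocks(frame)
    scales = [proposal.scales.get(nm, 0.1) for nm in names]

    all_draws = []
    chain_stats = []
    for ss in run.chain_seeds():
        rng = np.random.default_rng(ss)
        x0 = _initial_unconstrained(frame, rng)
        kept, st = metropolis_hastings_kernel(
            lambda v: logpost_and_grad_unconstrained(v, frame)[0],
            x0,
            rng,
            run.n_iterations,
            run.burn_in,
            run.thinning,
            blocks=blocks,
            scales=scales,
            q_sample=proposal.q_sample,
            q_logpdf=proposal.q_logpdf,
            adapt=proposal.adapt and proposal.q_sample is None,
            target_accept=proposal.target_accept,
        )
        rows = np.array([frame.state_to_row(frame.from_unconstrained(v)) for v in kept])
        all_draws.append(rows)
        st["blocks"] = names
        chain_stats.append(st)
    return ChainDraws(
        draws=np.stack(all_draws),
        param_names=frame.constrained_names,
        sampler="mh",
        run=run,
        stats={"chains": chain_stats},
        spec_dict=spec.to_dict(),
        data_digest=data.digest(),
    )


# ---------------------------------------------------------------------------
# Gibbs with probit data augmentation
# ---------------------------------------------------------------------------
def draw_latent_y2star(
    state: ParameterState,
    data: LongTableDataset,
    spec: ModelSpec,
    rng: np.random.Generator,
    frame: ModelFrame | None = None,
) -> np.ndarray:
    """Draw the latent normals behind the binary status from their truncated
    full conditionals: (0, inf) where y = 1, (-inf, 0] where y = 0."""
    fr = frame if frame is not None else ModelFrame(data, spec)
    eta = linear_predictor(state, data, spec, "y2", fr)
    y = fr.y2
    lo = np.where(y == 1, -eta, -np.inf)
    hi = np.where(y == 1, np.inf, -eta)
    return eta + stats.truncnorm.rvs(lo, hi, random_state=rng)


def _sample_mvn_from_precision(
    P: np.ndarray, rhs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw from N(P^{-1} rhs, P^{-1}) via the Cholesky of the precision."""
    c, low = cho_factor(P, lower=True)
    mean = cho_solve((c, low), rhs)
    # solving L' x = z yields covariance P^{-1}
    z = rng.standard_normal(len(rhs))
    return mean + solve_triangular(c, z, lower=True, trans="T")


def run_gibbs(
    data: LongTableDataset,
    spec: ModelSpec,
    run: RunConfig | None = None,
) -> ChainDraws:
    """Systematic-scan Gibbs: latent y2*, beta blocks, sigma^2, each u_i,
    Sigma_u, all from standard full conditionals.

    Requires the conjugate prior family (checked up front).  An empty
    dataset degenerates to exact prior sampling, which is used as a
    correctness oracle.
    """
    run = run if run is not None else RunConfig(n_iterations=3000, burn_in=1000, thinning=2)
    spec.prior.require_conjugate()
    frame = ModelFrame(data, spec)
    prior = spec.prior
    beta_prec1 = (
        np.eye(frame.p1) / prior.beta_scale**2 if frame.p1 else np.zeros((0, 0))
    )
    beta_prec2 = (
        np.eye(frame.p2) / prior.beta_scale**2 if frame.p2 else np.zeros((0, 0))
    )
    iw = prior.sigma_u.resolved(frame.q) if frame.q else None
    k = frame.k

    all_draws = []
    for ss in run.chain_seeds():
        rng = np.random.default_rng(ss)
        beta1 = np.zeros(frame.p1)
        beta2 = np.zeros(frame.p2)
        sigma2 = spec.fix_sigma2 if spec.fix_sigma2 is not None else 1.0
        U = np.zeros((frame.N, frame.q))
        Sigma = np.eye(frame.q)
        kept = []
        for it in range(run.n_iterations):
            state = ParameterState(beta1, beta2, sigma2, U, Sigma)
            # (1) latent y2*
            if frame.has_y2 and frame.n:
                ystar = draw_latent_y2star(state, data, spec, rng, frame)
            else:
                ystar = np.zeros(0)
            # (2) beta blocks
            if frame.has_y1 and frame.p1:
                off = (
                    np.einsum("ij,ij->i", frame.Z, U[frame.codes, frame.u_cols["y1"]])
                    if frame.q and frame.n
                    else 0.0
                )
                e1 = frame.y1 - off
                P = frame.X1.T @ frame.X1 / sigma2 + beta_prec1
                beta1 = _sample_mvn_from_precision(P, frame.X1.T @ e1 / sigma2, rng)
            if frame.has_y2 and frame.p2:
                off = (
                    np.einsum("ij,ij->i", frame.Z, U[frame.codes, frame.u_cols["y2"]])
                    if frame.q and frame.n
                    else 0.0
                )
                e2 = ystar - off
                P = frame.X2.T @ frame.X2 + beta_prec2
                beta2 = _sample_mvn_from_precision(P, frame.X2.T @ e2, rng)
            # (3) sigma^2
            if frame.free_sigma2 and prior.sigma2.kind == "inverse_gamma":
                if frame.n:
                    off = (
                        np.einsum("ij,ij->i", frame.Z, U[frame.codes, frame.u_cols["y1"]])
                        if frame.q
                        else 0.0
                    )
                    r = frame.y1 - frame.X1 @ beta1 - off
                    ssr = float(np.sum(r * r))
                else:
                    ssr = 0.0
                sigma2 = float(
                    stats.invgamma.rvs(
                        prior.sigma2.a + 0.5 * frame.n,
                        scale=prior.sigma2.b + 0.5 * ssr,
                        random_state=rng,
                    )
                )
            # (4) random effects
            if frame.q and frame.N:
                Sinv = np.linalg.inv(Sigma)
                r1 = frame.y1 - frame.X1 @ beta1 if frame.has_y1 else None
                r2 = ystar - frame.X2 @ beta2 if frame.has_y2 else None
                lin1 = np.zeros((frame.N, k))
                lin2 = np.zeros((frame.N, k))
                if frame.has_y1:
                    np.add.at(lin1, frame.codes, frame.Z * (r1 / sigma2)[:, None])
                if frame.has_y2:
                    np.add.at(lin2, frame.codes, frame.Z * r2[:, None])
                for i in range(frame.N):
                    P = Sinv.copy()
                    rhs = np.zeros(frame.q)
                    if frame.has_y1:
                        sl = frame.u_cols["y1"]
                        P[sl, sl] += frame.ZZt_by_patient[i] / sigma2
                        rhs[sl] += lin1[i]
                    if frame.has_y2:
                        sl = frame.u_cols["y2"]
                        P[sl, sl] += frame.ZZt_by_patient[i]
                        rhs[sl] += lin2[i]
                    U[i] = _sample_mvn_from_precision(P, rhs, rng)
            # (5) Sigma_u
            if frame.q:
                scale_post = iw.S + U.T @ U
                Sigma = np.atleast_2d(
                    stats.invwishart.rvs(
                        df=iw.nu + frame.N, scale=scale_post, random_state=rng
                    )
                )
            if it >= run.burn_in and (it - run.burn_in) % run.thinning == 0:
                kept.append(
                    frame.state_to_row(ParameterState(beta1, beta2, sigma2, U, Sigma))
                )
        all_draws.append(np.array(kept))
    return ChainDraws(
        draws=np.stack(all_draws),
        param_names=frame.constrained_names,
        sampler="gibbs",
        run=run,
        stats={},
        spec_dict=spec.to_dict(),
        data_digest=data.digest() if frame.n else None,
    )


# ---------------------------------------------------------------------------
# Hamiltonian Monte Carlo
# ---------------------------------------------------------------------------
def leapfrog(
    position: np.ndarray,
    momentum: np.ndarray,
    eps: float,
    n_steps: int,
    grad_fn: Callable[[np.ndarray], np.ndarray],
    inv_mass: np.ndarray | float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Half-kick / drift / half-kick composition, ``n_steps`` times.

    ``grad_fn`` returns the gradient of the log target (so the potential is
    its negation).  n_steps = 0 is the identity map.
    """
    if eps <= 0:
        raise InvalidArgumentError("eps must be > 0")
    if n_steps < 0:
        raise InvalidArgumentError("n_steps must be >= 0")
    x = np.array(position, dtype=float)
    p = np.array(momentum, dtype=float)
    if n_steps == 0:
        return x, p
    g = grad_fn(x)
    for _ in range(n_steps):
        p = p + 0.5 * eps * g
        x = x + eps * inv_mass * p
        g = grad_fn(x)
        if not np.all(np.isfinite(g)):
            return x, np.full_like(p, np.nan)
        p = p + 0.5 * eps * g
    return x, p


def _find_reasonable_epsilon(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x: np.ndarray,
    rng: np.random.Generator,
    inv_mass: np.ndarray,
) -> float:
    """Double/halve eps until the one-step acceptance crosses 1/2."""
    eps = 1.0
    lp0, g0 = logp_grad(x)
    p0 = rng.standard_normal(len(x)) / np.sqrt(inv_mass)
    h0 = -lp0 + 0.5 * float(np.sum(p0 * p0 * inv_mass))

    def delta(eps_try: float) -> float:
        p = p0 + 0.5 * eps_try * g0
        x1 = x + eps_try * inv_mass * p
        lp1, g1 = logp_grad(x1)
        if not np.isfinite(lp1):
            return -np.inf
        p = p + 0.5 * eps_try * g1
        h1 = -lp1 + 0.5 * float(np.sum(p * p * inv_mass))
        return h0 - h1

    d = delta(eps)
    direction = 1 if d > math.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        d = delta(eps)
        if (direction == 1 and d <= math.log(0.5)) or (
            direction == -1 and d >= math.log(0.5)
        ):
            break
    return eps


def run_hmc(
    data: LongTableDataset,
    spec: ModelSpec,
    hmc: HMCConfig | None = None,
    run: RunConfig | None = None,
) -> ChainDraws:
    """Fixed-trajectory HMC with leapfrog integration.

    Momentum is refreshed from N(0, M) every iteration; proposals are
    accepted with min{1, exp(-dH)}.  Dual-averaging tunes the step size
    during burn-in (frozen afterwards); the diagonal mass matrix is
    optionally adapted to warm-up variances in one window.  Trajectories
    with |dH| above the divergence threshold are rejected and counted.
    """
    hmc = hmc if hmc is not None else HMCConfig()
    run = run if run is not None else RunConfig(n_iterations=3000, burn_in=1000, thinning=1)
    frame = ModelFrame(data, spec)
    dim = frame.dim

    def logp_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        return logpost_and_grad_unconstrained(x, frame)

    # warm-up schedule: an initial fast interval (step size only), a span of
    # expanding "slow" windows after each of which the diagonal mass matrix
    # is re-estimated and dual averaging restarted, then a final fast
    # interval that settles the step size under the final metric.
    warm = run.burn_in

    def _mass_update_points() -> list[int]:
        if not hmc.adapt_mass or warm < 200:
            return []
        slow_start = int(0.15 * warm)
        slow_end = int(0.75 * warm)  # leave a long final interval for step size
        pts = []
        w = max(25, (slow_end - slow_start) // 15)
        pos = slow_start + w
        while pos < slow_end:
            pts.append(pos)
            w *= 2
            pos += w
        pts.append(slow_end)
        return pts

    all_draws = []
    chain_stats = []
    for ss in run.chain_seeds():
        rng = np.random.default_rng(ss)
        x = _initial_unconstrained(frame, rng)
        inv_mass = (
            1.0 / np.asarray(hmc.mass, dtype=float)
            if hmc.mass is not None
            else np.ones(dim)
        )
        eps = (
            hmc.step_size
            if hmc.step_size is not None
            else _find_reasonable_epsilon(logp_grad, x, rng, inv_mass)
        )
        # dual-averaging state; log eps is clamped to a window around the
        # coarse heuristic value because the raw recursion can overshoot by
        # orders of magnitude under plain HMC's noisy accept statistic
        gamma, t0, kappa = 0.05, 10.0, 0.75
        eps_ref = eps
        mu = math.log(10.0 * eps)
        log_eps_bar, h_bar, da_t = math.log(eps), 0.0, 0

        lp, _ = logp_grad(x)
        kept = []
        divergences = 0
        warm_divergences = 0
        acc_sum, acc_n = 0.0, 0
        mass_points = _mass_update_points()
        window: list[np.ndarray] = []
        collecting_from = int(0.15 * warm) if mass_points else warm
        # final warm-up interval: step size is tuned by direct acceptance
        # feedback at frozen eps ("rungs"), which is far more robust for
        # plain HMC than letting dual averaging run to the very end
        rung_start = mass_points[-1] + 1 if mass_points else int(0.75 * warm)
        n_rungs = 5
        rung_len = max(20, (warm - rung_start) // n_rungs)
        rung_acc, rung_n = 0.0, 0
        for it in range(run.n_iterations):
            eps_it = eps
            if hmc.jitter > 0:
                eps_it = eps * (1.0 + hmc.jitter * (2.0 * rng.random() - 1.0))
            n_steps = hmc.n_leapfrog
            if hmc.jitter_length:
                lo = max(1, math.ceil(0.5 * hmc.n_leapfrog))
                hi = max(lo, math.floor(1.5 * hmc.n_leapfrog))
                n_steps = int(rng.integers(lo, hi + 1))
            p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
            h0 = -lp + 0.5 * float(np.sum(p0 * p0 * inv_mass))
            x1, p1 = leapfrog(
                x, p0, eps_it, n_steps, lambda z: logp_grad(z)[1], inv_mass
            )
            if np.all(np.isfinite(p1)):
                lp1, _ = logp_grad(x1)
                with np.errstate(over="ignore"):  # overflow -> divergence
                    h1 = -lp1 + 0.5 * float(np.sum(p1 * p1 * inv_mass))
                d_h = h1 - h0
            else:
                lp1, d_h = -np.inf, np.inf
            diverged = (not np.isfinite(d_h)) or abs(d_h) > hmc.divergence_threshold
            alpha = 0.0 if diverged else math.exp(min(0.0, -d_h))
            if diverged:
                if it < warm:
                    warm_divergences += 1
                else:
                    divergences += 1
            elif rng.random() <= alpha:
                x, lp = x1, lp1
            if it < warm:
                tuning = hmc.adapt and hmc.step_size is None
                if tuning and it < rung_start:
                    da_t += 1
                    eta_t = 1.0 / (da_t + t0)
                    h_bar = (1.0 - eta_t) * h_bar + eta_t * (hmc.target_accept - alpha)
                    log_eps = mu - math.sqrt(da_t) / gamma * h_bar
                    log_eps = min(
                        max(log_eps, math.log(eps_ref) - 2.0),
                        math.log(eps_ref) + 1.5,
                    )
                    w = da_t**-kappa
                    log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
                    eps = math.exp(log_eps)
                elif tuning:
                    if it == rung_start:
                        eps = math.exp(log_eps_bar)
                        rung_acc, rung_n = 0.0, 0
                    rung_acc += alpha
                    rung_n += 1
                    if rung_n >= rung_len and it < warm - 1:
                        mean_a = rung_acc / rung_n
                        factor = math.exp(2.5 * (mean_a - hmc.target_accept))
                        eps *= min(max(factor, 0.5), 2.0)
                        rung_acc, rung_n = 0.0, 0
                if it >= collecting_from:
                    window.append(x.copy())
                if mass_points and it == mass_points[0]:
                    mass_points.pop(0)
                    if len(window) > 10:
                        var = np.var(np.array(window), axis=0)
                        nw = len(window)
                        # shrink toward unit metric (few-sample robustness)
                        var = var * nw / (nw + 5.0) + 1e-3 * 5.0 / (nw + 5.0)
                        med = float(np.median(var))
                        if med > 1e-8:
                            # floor each coordinate relative to the median so
                            # a temporarily stuck coordinate cannot freeze the
                            # chain through a near-zero mass entry
                            inv_mass = np.clip(var, 1e-3 * med, None)
                        window = []
                        if hmc.adapt and hmc.step_size is None:
                            eps = _find_reasonable_epsilon(logp_grad, x, rng, inv_mass)
                            eps_ref = eps
                            mu = math.log(10.0 * eps)
                            log_eps_bar, h_bar, da_t = math.log(eps), 0.0, 0
                if it == warm - 1 and warm_divergences >= warm:
                    raise TuningFailureError(
                        f"all {warm} warm-up iterations diverged "
                        f"(eps={eps:.3g}); the model may be misparameterized"
                    )
            else:
                acc_sum += alpha
                acc_n += 1
                if (it - warm) % run.thinning == 0:
                    kept.append(frame.state_to_row(frame.from_unconstrained(x)))
        all_draws.append(np.array(kept))
        chain_stats.append(
            {
                "acceptance": acc_sum / max(acc_n, 1),
                "step_size": eps,
                "divergences": divergences,
                "warmup_divergences": warm_divergences,
                "n_leapfrog": hmc.n_leapfrog,
            }
        )
    return ChainDraws(
        draws=np.stack(all_draws),
        param_names=frame.constrained_names,
        sampler="hmc",
        run=run,
        stats={"chains": chain_stats},
        spec_dict=spec.to_dict(),
        data_digest=data.digest(),
    )


def run_sampler(
    name: str,
    data: LongTableDataset,
    spec: ModelSpec,
    run: RunConfig | None = None,
    **kwargs: Any,
) -> ChainDraws:
    """Dispatch by sampler name: 'mh', 'gibbs' or 'hmc'."""
    if name == "mh":
        return run_metropolis_hastings(data, spec, run=run, **kwargs)
    if name == "gibbs":
        return run_gibbs(data, spec, run=run, **kwargs)
    if name == "hmc":
        return run_hmc(data, spec, run=run, **kwargs)
    raise InvalidArgumentError(f"unknown sampler {name!r} (expected mh|gibbs|hmc)")
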