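"""Joint model core: parameters, likelihoods, priors, posterior, gradients.

The model couples a normal sub-model for the continuous severity score with a
latent-probit sub-model (unit residual variance) for the binary status.
Patient-level random effects for the two responses are stacked into one
vector with a joint covariance ``Sigma_u``, which is what makes the
cross-response correlation estimable.

The unconstrained parameterization used by the gradient-based and
random-walk samplers is ``(beta_y1, beta_y2, log sigma^2, log-Cholesky of
Sigma_u, U)`` with the change-of-variables Jacobian accumulated explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy.special import log_ndtr, logsumexp
from scipy.stats import multivariate_normal

from .data import COVARIATE_COLUMNS, LongTableDataset
from .exceptions import InvalidArgumentError, SpecError
from .priors import (
    LOG2PI,
    PriorConfig,
    chol_from_unconstrained,
    chol_log_jacobian,
    chol_log_jacobian_grad,
    preset,
    unconstrained_from_chol,
)

ALL_COVARIATES = ("intercept", "leg", "ultrasound", "rcp")
STRUCTURES = ("null", "random_intercept", "full")


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------
@dataclass
class ModelSpec:
    """Which covariates enter fixed/random parts, the link, and the priors.

    ``responses`` may drop ``"y2"`` (or ``"y1"``) to fit a single-response
    sub-model, which is how the conjugate closed-form oracles are exercised.
    ``fix_sigma2`` freezes the residual variance (it then leaves the
    parameter vector entirely).
    """

    structure: str = "full"
    fixed_y1: tuple[str, ...] = ALL_COVARIATES
    fixed_y2: tuple[str, ...] = ALL_COVARIATES
    random_covariates: tuple[str, ...] = ("intercept", "ultrasound")
    responses: tuple[str, ...] = ("y1", "y2")
    link: str = "probit"
    prior: PriorConfig = field(default_factory=PriorConfig)
    fix_sigma2: float | None = None

    def __post_init__(self) -> None:
        if self.link != "probit":
            raise SpecError("only the probit link is supported")
        for r in self.responses:
            if r not in ("y1", "y2"):
                raise SpecError(f"unknown response {r!r}")
        for c in (*self.fixed_y1, *self.fixed_y2, *self.random_covariates):
            if c not in COVARIATE_COLUMNS:
                raise SpecError(f"unknown covariate {c!r}")
        if self.structure == "null":
            if self.fixed_y1 != ("intercept",) or self.random_covariates != ("intercept",):
                raise SpecError("null structure implies intercept-only fixed and random parts")
        elif self.structure == "random_intercept":
            if self.random_covariates != ("intercept",):
                raise SpecError("random_intercept structure implies random = (intercept,)")
        elif self.structure == "full":
            if self.random_covariates and "intercept" not in self.random_covariates:
                raise SpecError("full structure requires a random intercept")
        else:
            raise SpecError(f"unknown structure {self.structure!r}")

    @classmethod
    def from_structure(
        cls,
        structure: str,
        prior: PriorConfig | None = None,
        random_slopes: tuple[str, ...] = ("ultrasound",),
        **kwargs: Any,
    ) -> "ModelSpec":
        """Presets: null / random_intercept / full (intercept + declared slopes)."""
        prior = prior if prior is not None else PriorConfig()
        if structure == "null":
            return cls(structure, ("intercept",), ("intercept",), ("intercept",),
                       prior=prior, **kwargs)
        if structure == "random_intercept":
            return cls(structure, ALL_COVARIATES, ALL_COVARIATES, ("intercept",),
                       prior=prior, **kwargs)
        if structure == "full":
            return cls(structure, ALL_COVARIATES, ALL_COVARIATES,
                       ("intercept", *random_slopes), prior=prior, **kwargs)
        raise SpecError(f"unknown structure {structure!r}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "structure": self.structure,
            "fixed_y1": list(self.fixed_y1),
            "fixed_y2": list(self.fixed_y2),
            "random_covariates": list(self.random_covariates),
            "responses": list(self.responses),
            "link": self.link,
            "prior": self.prior.to_dict(),
            "fix_sigma2": self.fix_sigma2,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelSpec":
        prior = d.get("prior")
        if isinstance(prior, str):
            prior_cfg = preset(prior)
        elif prior is None:
            prior_cfg = PriorConfig()
        else:
            prior_cfg = PriorConfig.from_dict(prior)
        return cls(
            structure=d.get("structure", "full"),
            fixed_y1=tuple(d.get("fixed_y1", ALL_COVARIATES)),
            fixed_y2=tuple(d.get("fixed_y2", ALL_COVARIATES)),
            random_covariates=tuple(d.get("random_covariates", ("intercept", "ultrasound"))),
            responses=tuple(d.get("responses", ("y1", "y2"))),
            link=d.get("link", "probit"),
            prior=prior_cfg,
            fix_sigma2=d.get("fix_sigma2"),
        )


# ---------------------------------------------------------------------------
# parameter state
# ---------------------------------------------------------------------------
@dataclass
class ParameterState:
    """All unknowns on the constrained scale.

    ``U`` is N_patients x q with the first ``k`` columns belonging to y1 and
    the rest to y2 (k = number of random covariates per response present).
    ``latent_y2star`` is only populated inside the Gibbs sweep.
    """

    beta_y1: np.ndarray
    beta_y2: np.ndarray
    sigma2_y1: float
    U: np.ndarray
    Sigma_u: np.ndarray
    latent_y2star: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta_y1 = np.atleast_1d(np.asarray(self.beta_y1, dtype=float))
        self.beta_y2 = np.atleast_1d(np.asarray(self.beta_y2, dtype=float))
        self.U = np.asarray(self.U, dtype=float)
        self.Sigma_u = np.atleast_2d(np.asarray(self.Sigma_u, dtype=float))
        if self.U.ndim == 1:
            self.U = self.U.reshape(-1, self.Sigma_u.shape[0] or 1)


# ---------------------------------------------------------------------------
# model frame: everything precomputable from (data, spec)
# ---------------------------------------------------------------------------
class ModelFrame:
    """Design matrices, patient indexing, and the unconstrained layout."""

    def __init__(self, data: LongTableDataset, spec: ModelSpec):
        self.data = data
        self.spec = spec
        self.n = data.n_rows
        self.has_y1 = "y1" in spec.responses
        self.has_y2 = "y2" in spec.responses
        self.X1 = data.design_matrix(spec.fixed_y1) if self.has_y1 else np.zeros((self.n, 0))
        self.X2 = data.design_matrix(spec.fixed_y2) if self.has_y2 else np.zeros((self.n, 0))
        self.k = len(spec.random_covariates)
        self.Z = (
            data.design_matrix(spec.random_covariates) if self.k else np.zeros((self.n, 0))
        )
        self.codes = data.patient_codes() if self.n else np.zeros(0, dtype=int)
        self.N = data.n_patients if self.n else 0
        self.n_resp = len(spec.responses)
        self.q = self.k * self.n_resp
        self.y1 = data.y1 if self.has_y1 else np.zeros(0)
        self.y2 = data.y2 if self.has_y2 else np.zeros(0, dtype=int)
        self.sign2 = 2.0 * self.y2 - 1.0 if self.has_y2 else np.zeros(0)
        self.free_sigma2 = self.has_y1 and spec.fix_sigma2 is None

        # column blocks of u per response
        off = 0
        self.u_cols: dict[str, slice] = {}
        for r in spec.responses:
            self.u_cols[r] = slice(off, off + self.k)
            off += self.k

        # per-patient scatter of Z z' (constant across iterations)
        if self.q:
            zz = np.einsum("ni,nj->nij", self.Z, self.Z)
            self.ZZt_by_patient = np.zeros((self.N, self.k, self.k))
            np.add.at(self.ZZt_by_patient, self.codes, zz)

        # unconstrained layout ------------------------------------------------
        self.p1 = self.X1.shape[1]
        self.p2 = self.X2.shape[1]
        self.n_chol = self.q * (self.q + 1) // 2 if self.q else 0
        pos = 0
        self.sl_b1 = slice(pos, pos + self.p1); pos += self.p1
        self.sl_b2 = slice(pos, pos + self.p2); pos += self.p2
        self.sl_t = slice(pos, pos + (1 if self.free_sigma2 else 0))
        pos += 1 if self.free_sigma2 else 0
        self.sl_c = slice(pos, pos + self.n_chol); pos += self.n_chol
        self.sl_u = slice(pos, pos + self.N * self.q); pos += self.N * self.q
        self.dim = pos

        # names of the reported constrained parameters
        comp_names = [f"{r}_{c}" for r in spec.responses for c in spec.random_covariates]
        self.component_names = comp_names
        names: list[str] = []
        names += [f"beta_y1[{c}]" for c in spec.fixed_y1] if self.has_y1 else []
        names += [f"beta_y2[{c}]" for c in spec.fixed_y2] if self.has_y2 else []
        if self.free_sigma2:
            names.append("sigma2_y1")
        names += [f"sd_u[{c}]" for c in comp_names]
        names += [
            f"cor_u[{comp_names[a]},{comp_names[b]}]"
            for a in range(self.q)
            for b in range(a + 1, self.q)
        ]
        names += [f"u[{i + 1},{c}]" for i in range(self.N) for c in comp_names]
        self.constrained_names = names

        if self.q:
            self.tril = np.tril_indices(self.q)
            self.triu1 = np.triu_indices(self.q, 1)

    # -- constrained <-> named row --------------------------------------
    def state_to_row(self, state: ParameterState) -> np.ndarray:
        parts = []
        if self.has_y1:
            parts.append(state.beta_y1)
        if self.has_y2:
            parts.append(state.beta_y2)
        if self.free_sigma2:
            parts.append([state.sigma2_y1])
        if self.q:
            sds = np.sqrt(np.diag(state.Sigma_u))
            parts.append(sds)
            corr = state.Sigma_u / np.outer(sds, sds)
            parts.append(corr[np.triu_indices(self.q, 1)])
            parts.append(state.U.ravel())
        return np.concatenate([np.asarray(p, dtype=float).ravel() for p in parts]) if parts else np.zeros(0)

    def row_to_state(self, row: np.ndarray) -> ParameterState:
        pos = 0

        def take(m: int) -> np.ndarray:
            nonlocal pos
            out = row[pos : pos + m]
            pos += m
            return np.asarray(out, dtype=float)

        b1 = take(self.p1)
        b2 = take(self.p2)
        s2 = float(take(1)[0]) if self.free_sigma2 else (
            self.spec.fix_sigma2 if self.spec.fix_sigma2 is not None else 1.0
        )
        if self.q:
            sds = take(self.q)
            corr = np.eye(self.q)
            iu = np.triu_indices(self.q, 1)
            vals = take(len(iu[0]))
            corr[iu] = vals
            corr[(iu[1], iu[0])] = vals
            Sigma = corr * np.outer(sds, sds)
            U = take(self.N * self.q).reshape(self.N, self.q)
        else:
            Sigma = np.zeros((0, 0))
            U = np.zeros((self.N, 0))
        return ParameterState(b1, b2, s2, U, Sigma)

    # -- unconstrained transform ----------------------------------------
    # Random effects are carried non-centered: the vector stores
    # standardized effects z with U = z L' (L the Cholesky factor of
    # Sigma_u), which removes the scale/location funnel from the HMC and
    # random-walk geometry while leaving the posterior over (U, Sigma_u)
    # unchanged.
    def to_unconstrained(self, state: ParameterState) -> np.ndarray:
        v = np.zeros(self.dim)
        v[self.sl_b1] = state.beta_y1
        v[self.sl_b2] = state.beta_y2
        if self.free_sigma2:
            if state.sigma2_y1 <= 0:
                raise InvalidArgumentError("sigma2_y1 must be > 0")
            v[self.sl_t] = math.log(state.sigma2_y1)
        if self.q:
            L = np.linalg.cholesky(state.Sigma_u)
            v[self.sl_c] = unconstrained_from_chol(L)
            z = np.linalg.solve(L, state.U.T).T  # z = U L^{-T}
            v[self.sl_u] = z.ravel()
        return v

    def from_unconstrained(self, v: np.ndarray) -> ParameterState:
        v = np.asarray(v, dtype=float)
        if v.shape != (self.dim,):
            raise InvalidArgumentError(f"expected vector of length {self.dim}, got {v.shape}")
        b1 = v[self.sl_b1].copy()
        b2 = v[self.sl_b2].copy()
        if self.free_sigma2:
            s2 = float(np.exp(np.clip(float(v[self.sl_t][0]), -745.0, 709.0)))
        else:
            s2 = self.spec.fix_sigma2 if self.spec.fix_sigma2 is not None else 1.0
        if self.q:
            L = chol_from_unconstrained(v[self.sl_c], self.q)
            Sigma = L @ L.T
            U = v[self.sl_u].reshape(self.N, self.q) @ L.T
        else:
            Sigma = np.zeros((0, 0))
            U = np.zeros((self.N, 0))
        return ParameterState(b1, b2, s2, U, Sigma)

    def log_jacobian(self, v: np.ndarray) -> float:
        """Total log-Jacobian of the constrained -> unconstrained map.

        The sigma^2 component depends on the prior's natural measure
        (variance for inverse-gamma, sd otherwise); the Sigma_u component is
        the log-Cholesky Jacobian whenever the prior is a density in Sigma,
        composed with the (sd, R) factorization for LKJ-type priors.  Those
        measure conversions live inside the prior objects; here we only add
        the pieces that are pure reparameterization, so this function is used
        together with ``log_prior_unconstrained`` below.
        """
        total = 0.0
        if self.free_sigma2:
            total += float(v[self.sl_t][0])  # d sigma^2 / d t  (IG measure)
        if self.q:
            total += chol_log_jacobian(v[self.sl_c], self.q)
        return total


def build_frame(data: LongTableDataset, spec: ModelSpec) -> ModelFrame:
    return ModelFrame(data, spec)


# ---------------------------------------------------------------------------
# likelihoods (constrained scale)
# ---------------------------------------------------------------------------
def linear_predictor(
    state: ParameterState, data: LongTableDataset, spec: ModelSpec, response: str,
    frame: ModelFrame | None = None,
) -> np.ndarray:
    """eta_ij = x_ij' beta_r + z_ij' u_i for the requested response."""
    fr = frame if frame is not None else ModelFrame(data, spec)
    if response == "y1":
        if not fr.has_y1:
            raise SpecError("y1 not in model responses")
        eta = fr.X1 @ state.beta_y1
        cols = fr.u_cols["y1"]
    elif response == "y2":
        if not fr.has_y2:
            raise SpecError("y2 not in model responses")
        eta = fr.X2 @ state.beta_y2
        cols = fr.u_cols["y2"]
    else:
        raise SpecError(f"unknown response {response!r}")
    if fr.q and fr.n:
        eta = eta + np.einsum("ij,ij->i", fr.Z, state.U[fr.codes, cols])
    return eta


def loglik_continuous(
    state: ParameterState, data: LongTableDataset, spec: ModelSpec,
    frame: ModelFrame | None = None,
) -> float:
    fr = frame if frame is not None else ModelFrame(data, spec)
    if state.sigma2_y1 <= 0:
        raise InvalidArgumentError("sigma2_y1 must be > 0")
    if not fr.has_y1 or fr.n == 0:
        return 0.0
    eta = linear_predictor(state, data, spec, "y1", fr)
    r = fr.y1 - eta
    return float(-0.5 * fr.n * (LOG2PI + math.log(state.sigma2_y1))
                 - 0.5 * np.sum(r * r) / state.sigma2_y1)


def loglik_binary_probit(
    state: ParameterState, data: LongTableDataset, spec: ModelSpec,
    frame: ModelFrame | None = None,
) -> float:
    """Latent-integrated probit log-likelihood: sum log Phi((2y-1) eta)."""
    fr = frame if frame is not None else ModelFrame(data, spec)
    if not fr.has_y2 or fr.n == 0:
        return 0.0
    eta = linear_predictor(state, data, spec, "y2", fr)
    return float(np.sum(log_ndtr(fr.sign2 * eta)))


def pointwise_loglik_state(
    state: ParameterState, frame: ModelFrame
) -> np.ndarray:
    """Per-row conditional log-likelihood (sum of the two sub-models)."""
    out = np.zeros(frame.n)
    if frame.has_y1:
        eta = frame.X1 @ state.beta_y1
        if frame.q:
            eta = eta + np.einsum(
                "ij,ij->i", frame.Z, state.U[frame.codes, frame.u_cols["y1"]]
            )
        r = frame.y1 - eta
        out += -0.5 * (LOG2PI + math.log(state.sigma2_y1)) - 0.5 * r * r / state.sigma2_y1
    if frame.has_y2:
        eta = frame.X2 @ state.beta_y2
        if frame.q:
            eta = eta + np.einsum(
                "ij,ij->i", frame.Z, state.U[frame.codes, frame.u_cols["y2"]]
            )
        out += log_ndtr(frame.sign2 * eta)
    return out


# ---------------------------------------------------------------------------
# priors and posterior (constrained scale)
# ---------------------------------------------------------------------------
def log_prior(state: ParameterState, prior: PriorConfig, frame: ModelFrame) -> float:
    """Sum of log prior densities on the natural scales plus the
    random-effect term log N(U | 0, Sigma_u).  Returns -inf off support."""
    total = 0.0
    if frame.has_y1:
        total += prior.beta_logpdf(state.beta_y1)
    if frame.has_y2:
        total += prior.beta_logpdf(state.beta_y2)
    if frame.free_sigma2:
        if state.sigma2_y1 <= 0:
            return -np.inf
        total += prior.sigma2.logpdf(state.sigma2_y1)
    if frame.q:
        try:
            L = np.linalg.cholesky(state.Sigma_u)
        except np.linalg.LinAlgError:
            return -np.inf
        total += prior.sigma_u.logpdf(state.Sigma_u)
        # MVN(U | 0, Sigma_u)
        sol = np.linalg.solve(L, state.U.T)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        total += float(
            -0.5 * frame.N * (frame.q * LOG2PI + logdet) - 0.5 * np.sum(sol * sol)
        )
    return float(total)


def log_posterior_unnormalized(
    state: ParameterState, data: LongTableDataset, spec: ModelSpec,
    frame: ModelFrame | None = None,
) -> float:
    """Eq-7-style unnormalized posterior on the constrained scale."""
    fr = frame if frame is not None else ModelFrame(data, spec)
    if fr.free_sigma2 and state.sigma2_y1 <= 0:
        return -np.inf
    lp = log_prior(state, spec.prior, fr)
    if not np.isfinite(lp):
        return -np.inf
    ll = 0.0
    if fr.has_y1:
        ll += loglik_continuous(state, data, spec, fr)
    if fr.has_y2:
        ll += loglik_binary_probit(state, data, spec, fr)
    return float(ll + lp)


# ---------------------------------------------------------------------------
# unconstrained target with analytic gradient (used by HMC and MH)
# ---------------------------------------------------------------------------
def _probit_lambda(a: np.ndarray) -> np.ndarray:
    """phi(a) / Phi(a), computed stably for very negative a."""
    return np.exp(-0.5 * a * a - 0.5 * LOG2PI - log_ndtr(a))


def _scatter_by_patient(frame: "ModelFrame", w: np.ndarray) -> np.ndarray:
    """Per-patient sums of Z-weighted row values: (N, k)."""
    return np.column_stack(
        [
            np.bincount(frame.codes, weights=frame.Z[:, i] * w, minlength=frame.N)
            for i in range(frame.k)
        ]
    )


def logpost_and_grad_unconstrained(
    v: np.ndarray, frame: ModelFrame
) -> tuple[float, np.ndarray]:
    """Log posterior density of the unconstrained vector and its gradient.

    Includes all change-of-variables Jacobians so that the returned value is
    a proper density in v.
    """
    spec = frame.spec
    prior = spec.prior
    g = np.zeros(frame.dim)
    if not np.all(np.isfinite(v)):
        return -np.inf, g
    if frame.free_sigma2 and abs(float(v[frame.sl_t][0])) > 500.0:
        return -np.inf, g
    if frame.q and np.max(np.abs(v[frame.sl_c])) > 300.0:
        return -np.inf, g
    total = 0.0
    beta1 = v[frame.sl_b1]
    beta2 = v[frame.sl_b2]
    if frame.free_sigma2:
        s2 = math.exp(float(v[frame.sl_t][0]))
    else:
        s2 = frame.spec.fix_sigma2 if frame.spec.fix_sigma2 is not None else 1.0
    if not (np.isfinite(s2) and s2 > 0):
        return -np.inf, g
    if frame.q:
        L = chol_from_unconstrained(v[frame.sl_c], frame.q)
        Sigma = L @ L.T
        if not np.all(np.isfinite(Sigma)):
            return -np.inf, g
        Zm = v[frame.sl_u].reshape(frame.N, frame.q)  # standardized effects
        U = Zm @ L.T
    else:
        U = np.zeros((frame.N, 0))
    gU = np.zeros_like(U)

    # continuous likelihood ------------------------------------------------
    if frame.has_y1 and frame.n:
        eta1 = frame.X1 @ beta1
        if frame.q:
            eta1 = eta1 + np.einsum("ij,ij->i", frame.Z, U[frame.codes, frame.u_cols["y1"]])
        r = frame.y1 - eta1
        if not np.all(np.isfinite(r)):
            return -np.inf, g
        ssr = float(np.sum(r * r))
        total += -0.5 * frame.n * (LOG2PI + math.log(s2)) - 0.5 * ssr / s2
        g[frame.sl_b1] += frame.X1.T @ r / s2
        if frame.q:
            gU[:, frame.u_cols["y1"]] += _scatter_by_patient(frame, r / s2)
        if frame.free_sigma2:
            g[frame.sl_t] += -0.5 * frame.n + 0.5 * ssr / s2

    # probit likelihood ----------------------------------------------------
    if frame.has_y2 and frame.n:
        eta2 = frame.X2 @ beta2
        if frame.q:
            eta2 = eta2 + np.einsum("ij,ij->i", frame.Z, U[frame.codes, frame.u_cols["y2"]])
        a = frame.sign2 * eta2
        if not np.all(np.isfinite(a)) or np.max(np.abs(a)) > 1e8:
            return -np.inf, g
        total += float(np.sum(log_ndtr(a)))
        lam = frame.sign2 * _probit_lambda(a)  # d loglik / d eta
        g[frame.sl_b2] += frame.X2.T @ lam
        if frame.q:
            gU[:, frame.u_cols["y2"]] += _scatter_by_patient(frame, lam)

    # beta priors ----------------------------------------------------------
    if frame.has_y1:
        total += prior.beta_logpdf(beta1)
        g[frame.sl_b1] += prior.beta_grad(beta1)
    if frame.has_y2:
        total += prior.beta_logpdf(beta2)
        g[frame.sl_b2] += prior.beta_grad(beta2)

    # sigma^2 prior (includes its own Jacobian onto t) ---------------------
    if frame.free_sigma2:
        t = float(v[frame.sl_t][0])
        total += prior.sigma2.logpdf_unconstrained(t)
        g[frame.sl_t] += prior.sigma2.dlogpdf_unconstrained(t)

    # random effects (non-centered) + Sigma_u prior ------------------------
    if frame.q:
        # N(z | 0, I) replaces MVN(U | 0, Sigma) under U = z L'
        total += -0.5 * frame.N * frame.q * LOG2PI - 0.5 * float(np.sum(Zm * Zm))
        g_z = gU @ L - Zm

        lp_sigma = prior.sigma_u.logpdf_dsigma(Sigma, chol=L)
        if not np.isfinite(lp_sigma):
            return -np.inf, g
        total += lp_sigma
        total += chol_log_jacobian(v[frame.sl_c], frame.q)

        G_sigma = prior.sigma_u.grad_dsigma(Sigma, chol=L)
        dL = (G_sigma + G_sigma.T) @ L
        dL += gU.T @ Zm  # likelihood flows into L through U = z L'
        dL[frame.triu1] = 0.0
        dL[np.diag_indices(frame.q)] *= np.diag(L)
        g[frame.sl_c] += dL[frame.tril]
        g[frame.sl_c] += chol_log_jacobian_grad(v[frame.sl_c], frame.q)
        g[frame.sl_u] += g_z.ravel()

    if not np.isfinite(total):
        return -np.inf, g
    return float(total), g


def log_posterior_unconstrained(v: np.ndarray, frame: ModelFrame) -> float:
    return logpost_and_grad_unconstrained(v, frame)[0]


def grad_log_posterior(v: np.ndarray, frame: ModelFrame) -> np.ndarray:
    """Analytic gradient of the unconstrained log posterior."""
    return logpost_and_grad_unconstrained(v, frame)[1]


# ---------------------------------------------------------------------------
# integrated (marginal) per-subject likelihood via adaptive Gauss-Hermite
# ---------------------------------------------------------------------------
def _subject_conditional(frame: ModelFrame, state: ParameterState, rows: np.ndarray):
    """Return f(u), grad f(u), hess f(u) of the subject's conditional
    log-likelihood as a function of its random-effect vector u."""
    X1 = frame.X1[rows] if frame.has_y1 else None
    X2 = frame.X2[rows] if frame.has_y2 else None
    Z = frame.Z[rows]
    y1 = frame.y1[rows] if frame.has_y1 else None
    s = frame.sign2[rows] if frame.has_y2 else None
    s2 = state.sigma2_y1
    k = frame.k

    def f(u: np.ndarray) -> float:
        val = 0.0
        if frame.has_y1:
            r = y1 - X1 @ state.beta_y1 - Z @ u[:k] if k else y1 - X1 @ state.beta_y1
            val += float(np.sum(-0.5 * (LOG2PI + math.log(s2)) - 0.5 * r * r / s2))
        if frame.has_y2:
            off = k if frame.has_y1 else 0
            eta = X2 @ state.beta_y2 + (Z @ u[off : off + k] if k else 0.0)
            val += float(np.sum(log_ndtr(s * eta)))
        return val

    def grad_hess(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        q = frame.q
        gr = np.zeros(q)
        H = np.zeros((q, q))
        if frame.has_y1 and k:
            r = y1 - X1 @ state.beta_y1 - Z @ u[:k]
            gr[:k] = Z.T @ r / s2
            H[:k, :k] = -(Z.T @ Z) / s2
        if frame.has_y2 and k:
            off = k if frame.has_y1 else 0
            eta = X2 @ state.beta_y2 + Z @ u[off : off + k]
            a = s * eta
            lam = _probit_lambda(a)
            gr[off : off + k] = Z.T @ (s * lam)
            w = lam * (lam + a)  # -d^2/d eta^2 of log Phi(s eta)
            H[off : off + k, off : off + k] = -(Z.T * w) @ Z
        return gr, H

    return f, grad_hess


def integrated_loglik_subject(
    state: ParameterState,
    frame: ModelFrame,
    patient_code: int,
    n_nodes: int = 20,
) -> float:
    """Adaptive Gauss-Hermite approximation of the subject's marginal
    log-likelihood, integrating the random effects against N(0, Sigma_u).

    With no random effects (or Sigma_u -> 0) this degenerates to the
    conditional log-likelihood at u = 0.
    """
    if n_nodes < 1:
        raise InvalidArgumentError("n_nodes must be >= 1")
    rows = np.flatnonzero(frame.codes == patient_code)
    if frame.q == 0:
        f, _ = _subject_conditional(frame, state, rows)
        return f(np.zeros(0))
    Sigma = state.Sigma_u
    eig = np.linalg.eigvalsh(Sigma)
    if np.any(eig <= 0):
        if np.all(np.abs(Sigma) < 1e-12):  # point-mass random effect
            f, _ = _subject_conditional(frame, state, rows)
            return f(np.zeros(frame.q))
        raise InvalidArgumentError("Sigma_u must be positive definite")
    q = frame.q
    Sinv = np.linalg.inv(Sigma)
    _, logdet = np.linalg.slogdet(Sigma)
    f, grad_hess = _subject_conditional(frame, state, rows)

    def log_integrand(u: np.ndarray) -> float:
        return f(u) - 0.5 * (q * LOG2PI + logdet) - 0.5 * float(u @ Sinv @ u)

    # Newton iterations to the conditional mode
    u = np.zeros(q)
    for _ in range(100):
        gr, H = grad_hess(u)
        gr = gr - Sinv @ u
        H = H - Sinv
        step = np.linalg.solve(H, -gr)
        # simple backtracking
        t0 = log_integrand(u)
        alpha = 1.0
        for _ in range(30):
            if log_integrand(u + alpha * step) >= t0 - 1e-12:
                break
            alpha *= 0.5
        u = u + alpha * step
        if np.linalg.norm(gr) < 1e-10:
            break
    _, H = grad_hess(u)
    H = H - Sinv
    C = np.linalg.cholesky(np.linalg.inv(-H))

    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    grids = np.meshgrid(*([nodes] * q), indexing="ij")
    T = np.stack([gd.ravel() for gd in grids], axis=1)  # (m, q)
    W = np.prod(
        np.stack(np.meshgrid(*([weights] * q), indexing="ij"), axis=0).reshape(q, -1),
        axis=0,
    )
    pts = u[None, :] + math.sqrt(2.0) * (T @ C.T)
    vals = np.array([log_integrand(p) for p in pts])
    log_terms = np.log(W) + vals + np.sum(T * T, axis=1)
    _, logdet_c = np.linalg.slogdet(C)
    return float(0.5 * q * math.log(2.0) + logdet_c + logsumexp(log_terms))


def marginal_loglik_continuous_subject(
    state: ParameterState, frame: ModelFrame, patient_code: int
) -> float:
    """Closed-form marginal for a continuous-only subject (test oracle):
    y ~ N(X beta, sigma^2 I + Z Sigma Z')."""
    rows = np.flatnonzero(frame.codes == patient_code)
    X1 = frame.X1[rows]
    Z = frame.Z[rows, : frame.k]
    cov = state.sigma2_y1 * np.eye(len(rows))
    if frame.k:
        cov = cov + Z @ state.Sigma_u[: frame.k, : frame.k] @ Z.T
    return float(
        multivariate_normal.logpdf(frame.y1[rows], mean=X1 @ state.beta_y1, cov=cov)
    )


# convenience: finite-difference gradient (testing / debugging) -------------
def finite_difference_grad(
    fn: Callable[[np.ndarray], float], v: np.ndarray, h: float = 1e-5
) -> np.ndarray:
    g = np.zeros_like(v)
    for i in range(len(v)):
        vp = v.copy(); vp[i] += h
        vm = v.copy(); vm[i] -= h
        g[i] = (fn(vp) - fn(vm)) / (2.0 * h)
    return g
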