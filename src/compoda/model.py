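"""Generative model: Dirichlet-Multinomial regression with spike-and-slab effects.

The hierarchy, for N samples, K cell types and M covariates:

    Y_n        ~ DirMult(phi_n, ybar_n)          (counts; ybar_n = row total)
    log(phi)   = alpha + X beta                  (log-link regression)
    alpha_k    ~ Normal(0, 5)                    (intercepts)
    beta       = tau * beta_tilde                (spike-and-slab product)
    tau_{m,k}  = logistic(t_{m,k})               (continuous inclusion weight)
    t_{m,k}/50 ~ Normal(0, 1)                    (near-flat prior on tau)
    beta_tilde = sigma2_m * gamma_{m,k}          (scaled raw effect)
    sigma2_m   ~ HalfCauchy(1)                   (covariate-level scale)
    gamma_{m,k} ~ Normal(0, 1)

One cell type is the *reference*: its column of beta is pinned to zero so the
remaining effects are identifiable.  All changes are interpreted relative to
the reference.

The sampler works on an unconstrained flat vector
``theta = [alpha (K), gamma (M*K), log sigma2 (M), t (M*K)]``; sigma2 is
log-transformed with the corresponding Jacobian term added to the joint.
Normal scale parameters denote standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, digamma, expit

__all__ = [
    "ModelConfig",
    "ModelParameters",
    "constrain_parameters",
    "compute_concentrations",
    "dirmult_log_pmf",
    "log_joint",
    "log_joint_grad",
    "make_log_joint_and_grad",
    "unconstrained_dim",
]

_LOG_2_OVER_PI = np.log(2.0 / np.pi)


@dataclass(frozen=True)
class ModelConfig:
    """Fixed model settings.

    ``reference_index`` pins one cell-type column of beta to zero.  The prior
    scales are standard deviations (half-Cauchy scale for ``sigma2``).
    ``beta_zero_threshold`` is the magnitude below which a posterior draw of
    beta counts as excluded from the model.
    """

    n_cell_types: int
    n_covariates: int
    reference_index: int
    alpha_prior_scale: float = 5.0
    t_prior_scale: float = 50.0
    sigma2_cauchy_scale: float = 1.0
    beta_zero_threshold: float = 1e-3

    def __post_init__(self):
        if not (0 <= self.reference_index < self.n_cell_types):
            raise ValueError(
                f"reference_index {self.reference_index} out of range for K={self.n_cell_types}"
            )
        for name in ("alpha_prior_scale", "t_prior_scale", "sigma2_cauchy_scale", "beta_zero_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ModelParameters:
    """Constrained parameter bundle derived from one unconstrained vector."""

    alpha: np.ndarray        # (K,)
    gamma: np.ndarray        # (M, K)
    sigma2: np.ndarray       # (M,)
    t_raw: np.ndarray        # (M, K)
    tau: np.ndarray          # (M, K), logistic(t) in (0, 1)
    beta_tilde: np.ndarray   # (M, K), sigma2 * gamma
    beta: np.ndarray         # (M, K), tau * beta_tilde, reference column == 0


def unconstrained_dim(config: ModelConfig) -> int:
    k, m = config.n_cell_types, config.n_covariates
    return k + m * k + m + m * k


def _split(theta: np.ndarray, config: ModelConfig):
    k, m = config.n_cell_types, config.n_covariates
    alpha = theta[:k]
    gamma = theta[k:k + m * k].reshape(m, k)
    log_sigma2 = theta[k + m * k:k + m * k + m]
    t_raw = theta[k + m * k + m:].reshape(m, k)
    return alpha, gamma, log_sigma2, t_raw


def constrain_parameters(theta: np.ndarray, config: ModelConfig) -> ModelParameters:
    """Map the flat unconstrained vector to the constrained parameter bundle.

    The reference column of beta is zeroed *after* the tau * sigma2 * gamma
    product, so it is exactly zero regardless of the raw parameter values.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (unconstrained_dim(config),):
        raise ValueError(
            f"expected vector of length {unconstrained_dim(config)}, got {theta.shape}"
        )
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite entries in unconstrained parameter vector")
    alpha, gamma, log_sigma2, t_raw = _split(theta, config)
    sigma2 = np.exp(log_sigma2)
    tau = expit(t_raw)
    beta_tilde = sigma2[:, None] * gamma
    beta = tau * beta_tilde
    beta = beta.copy()
    beta[:, config.reference_index] = 0.0
    return ModelParameters(alpha=alpha.copy(), gamma=gamma.copy(), sigma2=sigma2,
                           t_raw=t_raw.copy(), tau=tau, beta_tilde=beta_tilde, beta=beta)


def compute_concentrations(params: ModelParameters, X: np.ndarray) -> np.ndarray:
    """Dirichlet concentrations phi = exp(alpha + X beta), one row per sample."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    eta = params.alpha[None, :] + X @ params.beta
    with np.errstate(over="ignore"):
        phi = np.exp(eta)
    bad = ~np.all(np.isfinite(phi), axis=1)
    if np.any(bad):
        raise FloatingPointError(
            f"concentration overflow for sample index {int(np.flatnonzero(bad)[0])}"
        )
    return phi


def dirmult_log_pmf(y: np.ndarray, phi: np.ndarray) -> float:
    """Exact log pmf of the Dirichlet-Multinomial.

    ``y`` are the per-category counts (possibly non-integer after
    pseudocounting; factorials become gamma functions), ``phi`` the positive
    concentration parameters.  The trial count is ``sum(y)``.
    """
    y = np.asarray(y, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0):
        raise ValueError("all concentrations must be strictly positive")
    if np.any(y < 0) or y.sum() <= 0:
        raise ValueError("counts must be nonnegative with positive sum")
    n = y.sum()
    a = phi.sum()
    return float(
        gammaln(n + 1) - gammaln(y + 1).sum()
        + gammaln(a) - gammaln(n + a)
        + (gammaln(y + phi) - gammaln(phi)).sum()
    )


def _dm_loglik_terms(counts: np.ndarray, phi: np.ndarray) -> float:
    """Dirichlet-Multinomial log likelihood summed over sample rows."""
    totals = counts.sum(axis=1)
    a = phi.sum(axis=1)
    return float(
        (gammaln(totals + 1) - gammaln(counts + 1).sum(axis=1)
         + gammaln(a) - gammaln(totals + a)
         + (gammaln(counts + phi) - gammaln(phi)).sum(axis=1)).sum()
    )


def log_joint(theta: np.ndarray, counts: np.ndarray, X: np.ndarray,
              config: ModelConfig, on_invalid: str = "raise") -> float:
    """Unnormalized log posterior density on the unconstrained scale.

    Sum of the Dirichlet-Multinomial log likelihood, the log prior densities
    of alpha, gamma, t and sigma2, and the log-Jacobian of the log transform
    of sigma2.  ``on_invalid='neginf'`` returns ``-inf`` instead of raising
    when the density overflows (the sampler rejects such proposals).
    """
    value, _ = _log_joint_impl(theta, counts, X, config, want_grad=False, on_invalid=on_invalid)
    return value


def log_joint_grad(theta: np.ndarray, counts: np.ndarray, X: np.ndarray,
                   config: ModelConfig, on_invalid: str = "raise"):
    """Value and analytic gradient of :func:`log_joint` w.r.t. theta."""
    return _log_joint_impl(theta, counts, X, config, want_grad=True, on_invalid=on_invalid)


def _log_joint_impl(theta, counts, X, config, want_grad, on_invalid):
    theta = np.asarray(theta, dtype=float)
    counts = np.asarray(counts, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k, m = config.n_cell_types, config.n_covariates
    alpha, gamma, log_sigma2, t_raw = _split(theta, config)
    sigma2 = np.exp(log_sigma2)
    tau = expit(t_raw)
    beta = tau * sigma2[:, None] * gamma
    beta[:, config.reference_index] = 0.0

    with np.errstate(over="ignore"):
        eta = alpha[None, :] + X @ beta
        phi = np.exp(eta)
    if not np.all(np.isfinite(phi)):
        return _invalid("likelihood (concentration overflow)", theta, on_invalid)

    totals = counts.sum(axis=1)
    a = phi.sum(axis=1)
    loglik = (
        gammaln(totals + 1) - gammaln(counts + 1).sum(axis=1)
        + gammaln(a) - gammaln(totals + a)
        + (gammaln(counts + phi) - gammaln(phi)).sum(axis=1)
    ).sum()

    sa, st, sc = config.alpha_prior_scale, config.t_prior_scale, config.sigma2_cauchy_scale
    lp_alpha = -0.5 * np.sum(alpha ** 2) / sa ** 2 - k * (0.5 * np.log(2 * np.pi) + np.log(sa))
    lp_gamma = -0.5 * np.sum(gamma ** 2) - m * k * 0.5 * np.log(2 * np.pi)
    lp_t = -0.5 * np.sum(t_raw ** 2) / st ** 2 - m * k * (0.5 * np.log(2 * np.pi) + np.log(st))
    # half-Cauchy(scale sc) density of sigma2, plus Jacobian sigma2 = exp(s)
    lp_sigma2 = np.sum(
        _LOG_2_OVER_PI - np.log(sc) - np.log1p((sigma2 / sc) ** 2) + log_sigma2
    )

    value = float(loglik + lp_alpha + lp_gamma + lp_t + lp_sigma2)
    if not np.isfinite(value):
        terms = {"likelihood": loglik, "alpha prior": lp_alpha, "gamma prior": lp_gamma,
                 "t prior": lp_t, "sigma2 prior": lp_sigma2}
        bad = [name for name, v in terms.items() if not np.isfinite(v)]
        return _invalid(" + ".join(bad), theta, on_invalid)
    if not want_grad:
        return value, None

    # dLL/d eta_{n,k} = phi * (digamma(a) - digamma(ybar + a) + digamma(y + phi) - digamma(phi))
    g_eta = phi * (
        (digamma(a) - digamma(totals + a))[:, None]
        + digamma(counts + phi) - digamma(phi)
    )
    grad_alpha = g_eta.sum(axis=0) - alpha / sa ** 2
    d_beta = X.T @ g_eta                     # (M, K) dLL/d beta
    d_beta[:, config.reference_index] = 0.0
    grad_gamma = d_beta * tau * sigma2[:, None] - gamma
    grad_log_sigma2 = (d_beta * tau * gamma).sum(axis=1) * sigma2 \
        - 2.0 * (sigma2 / sc) ** 2 / (1.0 + (sigma2 / sc) ** 2) + 1.0
    grad_t = d_beta * sigma2[:, None] * gamma * tau * (1.0 - tau) - t_raw / st ** 2
    grad = np.concatenate([grad_alpha, grad_gamma.ravel(), grad_log_sigma2, grad_t.ravel()])
    return value, grad


def _invalid(which: str, theta, on_invalid: str):
    if on_invalid == "neginf":
        return -np.inf, np.zeros_like(theta)
    raise FloatingPointError(f"log joint diverged in term(s): {which}")


def make_log_joint_and_grad(counts: np.ndarray, X: np.ndarray, config: ModelConfig):
    """Build a fast ``theta -> (log_joint, grad)`` closure for the sampler.

    Precomputes every data-dependent constant (row totals, multinomial
    coefficients, prior normalizers, index splits) so the per-call cost is
    dominated by the gamma-function evaluations.  Returns ``(-inf, 0)`` on
    overflow instead of raising, which the sampler treats as a rejected
    proposal.  Matches :func:`log_joint` / :func:`log_joint_grad` exactly on
    finite inputs.
    """
    counts = np.asarray(counts, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k, m = config.n_cell_types, config.n_covariates
    n = counts.shape[0]
    ref = config.reference_index
    totals = counts.sum(axis=1)
    sa2 = config.alpha_prior_scale ** 2
    st2 = config.t_prior_scale ** 2
    sc = config.sigma2_cauchy_scale
    const = float(
        (gammaln(totals + 1) - gammaln(counts + 1).sum(axis=1)).sum()
        - k * (0.5 * np.log(2 * np.pi) + np.log(config.alpha_prior_scale))
        - m * k * 0.5 * np.log(2 * np.pi)
        - m * k * (0.5 * np.log(2 * np.pi) + np.log(config.t_prior_scale))
        + m * (_LOG_2_OVER_PI - np.log(sc))
    )
    i_gamma, i_s, i_t = k, k + m * k, k + m * k + m
    nk = n * k

    def value_and_grad(theta):
        alpha = theta[:i_gamma]
        gamma = theta[i_gamma:i_s].reshape(m, k)
        log_sigma2 = theta[i_s:i_t]
        t_raw = theta[i_t:].reshape(m, k)
        if log_sigma2.max() > 700.0:  # exp would overflow; reject the proposal
            return -np.inf, np.zeros_like(theta)
        sigma2 = np.exp(log_sigma2)
        tau = expit(t_raw)
        beta = tau * sigma2[:, None] * gamma
        beta[:, ref] = 0.0
        eta = alpha[None, :] + X @ beta
        eta_max = eta.max()
        if not (np.isfinite(eta_max) and eta_max <= 700.0):
            return -np.inf, np.zeros_like(theta)
        phi = np.exp(eta)
        a = phi.sum(axis=1)
        big = np.concatenate([phi.ravel(), (counts + phi).ravel(), a, totals + a])
        gl = gammaln(big)
        dg = digamma(big)
        loglik = (gl[nk:2 * nk] - gl[:nk]).sum() + (gl[2 * nk:2 * nk + n] - gl[2 * nk + n:]).sum()
        sig_ratio2 = (sigma2 / sc) ** 2
        value = (
            const + loglik
            - 0.5 * (alpha @ alpha) / sa2
            - 0.5 * (gamma.ravel() @ gamma.ravel())
            - 0.5 * (t_raw.ravel() @ t_raw.ravel()) / st2
            - np.log1p(sig_ratio2).sum() + log_sigma2.sum()
        )
        if not np.isfinite(value):
            return -np.inf, np.zeros_like(theta)
        g_eta = phi * (
            (dg[2 * nk:2 * nk + n] - dg[2 * nk + n:])[:, None]
            + (dg[nk:2 * nk] - dg[:nk]).reshape(n, k)
        )
        d_beta = X.T @ g_eta
        d_beta[:, ref] = 0.0
        grad_alpha = g_eta.sum(axis=0) - alpha / sa2
        grad_gamma = d_beta * tau * sigma2[:, None] - gamma
        grad_log_sigma2 = (d_beta * tau * gamma).sum(axis=1) * sigma2 \
            - 2.0 * sig_ratio2 / (1.0 + sig_ratio2) + 1.0
        grad_t = d_beta * sigma2[:, None] * gamma * tau * (1.0 - tau) - t_raw / st2
        return float(value), np.concatenate(
            [grad_alpha, grad_gamma.ravel(), grad_log_sigma2, grad_t.ravel()]
        )

    return value_and_grad
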