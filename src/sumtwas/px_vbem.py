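"""Parameter-expanded variational Bayes EM for the summary-statistic model.

The marginal log-likelihood decomposes as ELBO + KL(q || posterior); with a
fully factorized Gaussian ``q(gamma) = prod_k N(mu_k, s2_k)`` the ELBO has
closed-form coordinate maximizers in both the variational factors (E-step)
and the model parameters (M-step), so the fit is a monotone coordinate
ascent.  The redundant expansion parameter ``tau`` multiplies the eQTL-arm
mean; maximizing over it as well accelerates convergence on LD-correlated
instances, and the fit is mapped back to the ``tau = 1`` parameterization
at the end (the mapping leaves the marginal — and the ELBO, once the
posterior is rescaled accordingly — unchanged).

All ELBO values follow the constant-dropping convention of
:mod:`sumtwas.model_core`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kernels import gauss_seidel_sweep
from .model_core import SIGMA2_FLOOR, GeneSummaryData, ModelParams

logger = logging.getLogger(__name__)

#: Default initialization and convergence settings.
INIT_SIGMA2 = 0.01
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 1000

#: Denominators below this are treated as degenerate in the M-step.
_DENOM_EPS = 1e-300


@dataclass
class VariationalPosterior:
    """Mean-field Gaussian posterior factors over the latent effects."""

    mu: np.ndarray
    s2: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.s2 = np.asarray(self.s2, dtype=float)
        if self.mu.shape != self.s2.shape or self.mu.ndim != 1:
            raise ValueError("mu and s2 must be 1-d vectors of equal length")
        if np.any(self.s2 <= 0):
            raise ValueError("posterior variances must be strictly positive")

    def copy(self) -> "VariationalPosterior":
        return VariationalPosterior(self.mu.copy(), self.s2.copy())


@dataclass
class FitResult:
    """Converged parameters, posterior, and the ELBO ascent trace.

    ``elbo_trace`` records the ELBO after every half-step (E and M
    alternating), so monotonicity of the ascent is directly inspectable.
    """

    params: ModelParams
    posterior: VariationalPosterior
    elbo: float
    elbo_trace: np.ndarray
    n_iter: int
    converged: bool
    degenerate: bool = False


def elbo(
    data: GeneSummaryData, params: ModelParams, q: VariationalPosterior
) -> float:
    """Evidence lower bound E_q[loglik_kernel] + entropy(q).

    Expectations of quadratic forms use
    ``E[g' A g] = mu' A mu + sum_k A_kk s2_k``.
    """
    if np.any(q.s2 <= 0):
        raise ValueError("posterior variances must be strictly positive")
    mu, s2 = q.mu, q.s2
    tau, a, sg2 = params.tau, params.alpha_prime, params.sigma2_gamma
    R1, R2 = data.ld_eqtl, data.ld_gwas
    m = data.m
    quad1 = mu @ R1 @ mu + np.diag(R1) @ s2
    quad2 = mu @ R2 @ mu + np.diag(R2) @ s2
    e_kernel = (
        tau * data.eqtl_z @ mu
        - 0.5 * tau**2 * quad1
        + a * data.gwas_z @ mu
        - 0.5 * a**2 * quad2
        - 0.5 * (mu @ mu + s2.sum()) / sg2
        - 0.5 * m * np.log(2.0 * np.pi * sg2)
    )
    entropy = 0.5 * np.sum(np.log(2.0 * np.pi * np.e * s2))
    return float(e_kernel + entropy)


def update_posterior(
    data: GeneSummaryData, params: ModelParams, q: VariationalPosterior
) -> VariationalPosterior:
    """One full ascending Gauss-Seidel sweep of coordinate updates.

    Each coordinate update is the exact full conditional of ``gamma_k``
    given the freshest means of the other coordinates, so the ELBO cannot
    decrease.
    """
    tau, a, sg2 = params.tau, params.alpha_prime, params.sigma2_gamma
    R1, R2 = data.ld_eqtl, data.ld_gwas
    s2 = 1.0 / (tau**2 * np.diag(R1) + a**2 * np.diag(R2) + 1.0 / sg2)
    mu = q.mu.copy()
    r1 = R1 @ mu
    r2 = R2 @ mu
    gauss_seidel_sweep(
        mu, s2, data.eqtl_z, data.gwas_z, R1, R2, tau, tau**2, a, a**2, r1, r2
    )
    return VariationalPosterior(mu, s2)


def update_parameters(
    data: GeneSummaryData, params: ModelParams, q: VariationalPosterior
) -> ModelParams:
    """Closed-form M-step maximizers of the ELBO given the posterior.

    The ELBO separates in (sigma2_gamma, alpha', tau) for fixed ``q``, so
    the three one-dimensional maximizers can be applied simultaneously.  A
    degenerate (zero) denominator keeps the previous value and logs a
    warning.
    """
    mu, s2 = q.mu, q.s2
    m = data.m
    sg2 = max(float((mu @ mu + s2.sum()) / m), SIGMA2_FLOOR)

    alpha = params.alpha_prime
    if not params.null_model:
        denom = mu @ data.ld_gwas @ mu + np.diag(data.ld_gwas) @ s2
        if denom > _DENOM_EPS:
            alpha = float(data.gwas_z @ mu / denom)
        else:
            logger.warning(
                "gene %s: degenerate alpha' denominator; keeping %.3g",
                data.gene_id,
                alpha,
            )
    denom1 = mu @ data.ld_eqtl @ mu + np.diag(data.ld_eqtl) @ s2
    if denom1 > _DENOM_EPS:
        tau = float(data.eqtl_z @ mu / denom1)
    else:
        tau = params.tau
        logger.warning(
            "gene %s: degenerate tau denominator; keeping %.3g",
            data.gene_id,
            tau,
        )
    return ModelParams(
        sigma2_gamma=sg2,
        alpha_prime=alpha,
        tau=tau,
        null_model=params.null_model,
    )


def reduce_expansion(params: ModelParams) -> ModelParams:
    """Map expanded parameters back to the ``tau = 1`` model.

    ``sigma2_gamma <- tau^2 sigma2_gamma`` and ``alpha' <- alpha' / tau``
    leave the marginal distribution of the z-scores unchanged.  A fit that
    collapsed to ``tau = 0`` carries no eQTL signal; it is returned with the
    variance floored and flagged degenerate by :func:`fit`.
    """
    if params.tau == 0.0:
        return ModelParams(
            sigma2_gamma=SIGMA2_FLOOR,
            alpha_prime=params.alpha_prime,
            tau=1.0,
            null_model=params.null_model,
        )
    return ModelParams(
        sigma2_gamma=max(params.tau**2 * params.sigma2_gamma, SIGMA2_FLOOR),
        alpha_prime=params.alpha_prime / params.tau,
        tau=1.0,
        null_model=params.null_model,
    )


def _reduce_posterior(params: ModelParams, q: VariationalPosterior) -> VariationalPosterior:
    """Rescale the posterior consistently with :func:`reduce_expansion`."""
    if params.tau == 0.0:
        return q
    return VariationalPosterior(params.tau * q.mu, params.tau**2 * q.s2)


def fit(
    data: GeneSummaryData,
    null_model: bool = False,
    init: ModelParams | None = None,
    q_init: VariationalPosterior | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    use_px: bool = True,
) -> FitResult:
    """Fit the model by PX-VBEM coordinate ascent.

    Alternates :func:`update_posterior` and :func:`update_parameters` until
    the relative ELBO change per iteration drops below ``tol`` or
    ``max_iter`` is reached, then reduces the expansion.  Deterministic
    given the data and initialization.  ``use_px=False`` freezes ``tau`` at
    1 (plain VBEM); it exists for benchmarking the expansion, not for
    production use.
    """
    if init is None:
        params = ModelParams(
            sigma2_gamma=INIT_SIGMA2,
            alpha_prime=0.0,
            tau=1.0,
            null_model=null_model,
        )
    else:
        params = ModelParams(
            sigma2_gamma=init.sigma2_gamma,
            alpha_prime=0.0 if null_model else init.alpha_prime,
            tau=init.tau,
            null_model=null_model,
        )
    if q_init is None:
        q = VariationalPosterior(
            np.zeros(data.m), np.full(data.m, params.sigma2_gamma)
        )
    else:
        q = q_init.copy()

    trace: list[float] = []
    prev = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        q = update_posterior(data, params, q)
        trace.append(elbo(data, params, q))
        new_params = update_parameters(data, params, q)
        if not use_px:
            new_params = ModelParams(
                sigma2_gamma=new_params.sigma2_gamma,
                alpha_prime=new_params.alpha_prime,
                tau=1.0,
                null_model=null_model,
            )
        params = new_params
        current = elbo(data, params, q)
        trace.append(current)
        if np.isfinite(prev):
            denom = max(abs(prev), 1e-3)
            if abs(current - prev) / denom < tol:
                converged = True
                break
        prev = current

    if not converged:
        logger.warning(
            "gene %s: PX-VBEM did not converge in %d iterations",
            data.gene_id,
            max_iter,
        )
    degenerate = params.tau == 0.0
    q = _reduce_posterior(params, q)
    params = reduce_expansion(params)
    return FitResult(
        params=params,
        posterior=q,
        elbo=elbo(data, params, q),
        elbo_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
        degenerate=degenerate,
    )
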