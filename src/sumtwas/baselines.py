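"""Comparator methods for the simulation study.

Two families:

* :func:`comm_s2_lrt` — the same latent-effect model as the main test but
  with the eQTL arm replaced by the exact individual-level Gaussian
  likelihood ``y | W1 ~ N(W1 S1 gamma, sigma_e^2 I)`` (the latent vector
  stays on the z-score scale via the simple-regression SE scaling ``S1``),
  fitted with the same PX-VBEM machinery and tested with the same
  chi-square(1) LRT.  It is the individual-level-eQTL reference the
  summary-statistic test is benchmarked against.

* :func:`two_stage_twas` — predict-then-associate: a cross-validated
  penalized regression (ridge or elastic net) learns expression weights,
  which are combined with GWAS z-scores through the standard weighted
  summary-statistic formula ``z = sum_k w_k s_k zhat2_k / sqrt(w' D R2 D w)``
  with ``D = diag(s_k)`` the reference-panel genotype SDs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import ElasticNetCV, RidgeCV

from . import px_vbem
from .model_core import SIGMA2_FLOOR, GeneSummaryData, ModelParams, _check_ld_matrix
from .px_vbem import FitResult, VariationalPosterior
from ._kernels import gauss_seidel_sweep
from .association import TestResult

logger = logging.getLogger(__name__)


@dataclass
class IndividualEqtlData:
    """Individual-level eQTL data plus summary-level GWAS inputs."""

    y: np.ndarray
    W1: np.ndarray
    gwas_z: np.ndarray
    ld_gwas: np.ndarray
    gene_id: str = "gene"

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.W1 = np.asarray(self.W1, dtype=float)
        self.gwas_z = np.asarray(self.gwas_z, dtype=float)
        if self.W1.ndim != 2 or self.y.shape[0] != self.W1.shape[0]:
            raise ValueError("y and W1 must share the sample dimension")
        m = self.W1.shape[1]
        if self.gwas_z.shape != (m,):
            raise ValueError("gwas_z length must match W1 columns")
        self.ld_gwas = _check_ld_matrix(self.ld_gwas, m, "ld_gwas")
        if np.any(self.W1.std(axis=0) == 0):
            raise ValueError("W1 contains a constant column")

    @property
    def m(self) -> int:
        return self.W1.shape[1]

    @property
    def n(self) -> int:
        return self.W1.shape[0]


class _S2Workspace:
    """Precomputed sufficient statistics for the individual-level arm.

    ``X = centered(W1) @ S1`` where ``S1 = diag(sd(y) / (sqrt(n) sd(w_k)))``
    approximates the simple-regression SEs, so the latent effects live on
    the same z-score scale as in the summary-statistic model.
    """

    def __init__(self, data: IndividualEqtlData):
        Wc = data.W1 - data.W1.mean(axis=0)
        sd_w = data.W1.std(axis=0)
        sd_y = float(np.std(data.y, ddof=1))
        self.s1 = sd_y / (math.sqrt(data.n) * sd_w)
        X = Wc * self.s1
        yc = data.y - data.y.mean()
        self.XtX = X.T @ X
        self.Xty = X.T @ yc
        self.yty = float(yc @ yc)
        self.n = data.n
        self.m = data.m
        self.z2 = data.gwas_z
        self.R2 = data.ld_gwas
        self.d1 = np.diag(self.XtX).copy()
        self.d2 = np.diag(self.R2).copy()


def _s2_elbo(ws: _S2Workspace, sg2, alpha, tau, sig_e2, mu, s2) -> float:
    quadX = mu @ ws.XtX @ mu + ws.d1 @ s2
    quad2 = mu @ ws.R2 @ mu + ws.d2 @ s2
    e_y = -0.5 * ws.n * math.log(2.0 * math.pi * sig_e2) - 0.5 / sig_e2 * (
        ws.yty - 2.0 * tau * ws.Xty @ mu + tau**2 * quadX
    )
    e_gwas = alpha * ws.z2 @ mu - 0.5 * alpha**2 * quad2
    e_prior = -0.5 * (mu @ mu + s2.sum()) / sg2 - 0.5 * ws.m * math.log(
        2.0 * math.pi * sg2
    )
    entropy = 0.5 * np.sum(np.log(2.0 * math.pi * math.e * s2))
    return float(e_y + e_gwas + e_prior + entropy)


def _s2_fit(
    ws: _S2Workspace,
    null_model: bool,
    init=None,
    tol: float = px_vbem.DEFAULT_TOL,
    max_iter: int = px_vbem.DEFAULT_MAX_ITER,
) -> FitResult:
    """PX-VBEM for the individual-level-eQTL arm.

    The coordinate updates reuse the generic Gauss-Seidel kernel with
    coefficients ``(b1, a1) = (tau, tau^2)/sigma_e^2`` on the Gram matrix
    and ``(b2, a2) = (alpha, alpha^2)`` on the GWAS LD matrix.
    """
    if init is None:
        sg2, alpha, tau = px_vbem.INIT_SIGMA2, 0.0, 1.0
        sig_e2 = ws.yty / ws.n
        mu = np.zeros(ws.m)
        s2 = np.full(ws.m, sg2)
    else:
        sg2, alpha, tau, sig_e2, mu, s2 = init
        alpha = 0.0 if null_model else alpha
        mu, s2 = mu.copy(), s2.copy()

    trace = []
    prev = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        b1, a1 = tau / sig_e2, tau**2 / sig_e2
        b2, a2 = alpha, alpha**2
        s2 = 1.0 / (a1 * ws.d1 + a2 * ws.d2 + 1.0 / sg2)
        r1 = ws.XtX @ mu
        r2 = ws.R2 @ mu
        gauss_seidel_sweep(
            mu, s2, ws.Xty, ws.z2, ws.XtX, ws.R2, b1, a1, b2, a2, r1, r2
        )
        trace.append(_s2_elbo(ws, sg2, alpha, tau, sig_e2, mu, s2))

        sg2 = max(float((mu @ mu + s2.sum()) / ws.m), SIGMA2_FLOOR)
        if not null_model:
            denom = mu @ ws.R2 @ mu + ws.d2 @ s2
            if denom > 0:
                alpha = float(ws.z2 @ mu / denom)
        quadX = mu @ ws.XtX @ mu + ws.d1 @ s2
        if quadX > 0:
            tau = float(ws.Xty @ mu / quadX)
        sig_e2 = max(
            (ws.yty - 2.0 * tau * ws.Xty @ mu + tau**2 * quadX) / ws.n,
            1e-12,
        )
        current = _s2_elbo(ws, sg2, alpha, tau, sig_e2, mu, s2)
        trace.append(current)
        if np.isfinite(prev) and abs(current - prev) / max(abs(prev), 1e-3) < tol:
            converged = True
            break
        prev = current

    # reduce the expansion: fold tau into sigma2_gamma / alpha and rescale q
    if tau != 0.0:
        sg2 = max(tau**2 * sg2, SIGMA2_FLOOR)
        alpha = alpha / tau
        mu, s2 = tau * mu, tau**2 * s2
    else:
        sg2 = SIGMA2_FLOOR
    params = ModelParams(
        sigma2_gamma=sg2, alpha_prime=alpha, tau=1.0, null_model=null_model
    )
    q = VariationalPosterior(mu, s2)
    final = _s2_elbo(ws, sg2, alpha, 1.0, sig_e2, mu, s2)
    result = FitResult(
        params=params,
        posterior=q,
        elbo=final,
        elbo_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
    )
    result.sigma_e2 = sig_e2  # residual variance of the expression arm
    return result


def _s2_marginal_loglik(ws: _S2Workspace, sg2, alpha, sig_e2) -> float:
    """Exact marginal log-likelihood of (y, zhat2) for the reduced model.

    The joint covariance is ``D + sg2 U U'`` with ``D = blockdiag(sig_e2 I,
    R2)`` and ``U = [X; alpha R2]``, so the Woodbury identity and the
    matrix determinant lemma reduce everything to m x m algebra on the
    precomputed sufficient statistics (the n x n block is never formed).
    """
    m = ws.m
    M = np.eye(m) + sg2 * (ws.XtX / sig_e2 + alpha**2 * ws.R2)
    sign, logdet_M = np.linalg.slogdet(M)
    if sign <= 0:
        raise np.linalg.LinAlgError("marginal covariance is singular")
    sign2, logdet_R2 = np.linalg.slogdet(ws.R2)
    if sign2 <= 0:
        raise np.linalg.LinAlgError("GWAS LD matrix is singular")
    v = ws.Xty / sig_e2 + alpha * ws.z2
    quad_base = ws.yty / sig_e2 + ws.z2 @ np.linalg.solve(ws.R2, ws.z2)
    quad = quad_base - sg2 * v @ np.linalg.solve(M, v)
    logdet = ws.n * math.log(sig_e2) + logdet_R2 + logdet_M
    return float(
        -0.5 * ((ws.n + m) * math.log(2.0 * math.pi) + logdet + quad)
    )


def comm_s2_lrt(
    data: IndividualEqtlData,
    tol: float = px_vbem.DEFAULT_TOL,
    max_iter: int = px_vbem.DEFAULT_MAX_ITER,
) -> TestResult:
    """Likelihood-ratio test using individual-level eQTL data.

    Same null/alternative structure, warm start, clamping, and chi-square(1)
    reference as the summary-statistic test; only the eQTL arm of the
    likelihood differs.  As in the summary-statistic test, the statistic
    evaluates the exact marginal at the variational parameter estimates.
    """
    ws = _S2Workspace(data)
    fit_null = _s2_fit(ws, null_model=True, tol=tol, max_iter=max_iter)
    warm = (
        fit_null.params.sigma2_gamma,
        0.0,
        1.0,
        fit_null.sigma_e2,
        fit_null.posterior.mu,
        fit_null.posterior.s2,
    )
    fit_alt = _s2_fit(ws, null_model=False, init=warm, tol=tol, max_iter=max_iter)
    stat = 2.0 * (
        _s2_marginal_loglik(
            ws,
            fit_alt.params.sigma2_gamma,
            fit_alt.params.alpha_prime,
            fit_alt.sigma_e2,
        )
        - _s2_marginal_loglik(
            ws,
            fit_null.params.sigma2_gamma,
            fit_null.params.alpha_prime,
            fit_null.sigma_e2,
        )
    )
    clamped = stat < 0.0
    stat = max(stat, 0.0)
    return TestResult(
        gene_id=data.gene_id,
        lrt_stat=float(stat),
        p_value=float(stats.chi2.sf(stat, df=1)),
        alpha_prime_hat=fit_alt.params.alpha_prime,
        sigma2_hat=fit_alt.params.sigma2_gamma,
        fit_null=fit_null,
        fit_alt=fit_alt,
        clamped=clamped,
    )


#: Ridge penalty grid for the two-stage predictor.
_RIDGE_ALPHAS = np.logspace(-2, 5, 30)


def two_stage_twas(
    data: IndividualEqtlData,
    predictor: str = "ridge",
    ref_sd: np.ndarray | None = None,
    cv: int = 5,
) -> TestResult:
    """Predict-then-associate TWAS with a penalized expression model.

    Stage 1 fits ridge or elastic net (mixing 0.5) regression of expression
    on standardized genotype columns, tuning the penalty by ``cv``-fold
    cross-validation; weights are mapped back to the per-dosage scale.
    Stage 2 forms the weighted summary-statistic z-score using the GWAS
    z-scores, the reference LD matrix, and reference genotype SDs ``ref_sd``
    (defaulting to the eQTL genotype SDs).  The squared z-score is reported
    through the same result shape as the likelihood-ratio methods.

    An all-zero weight vector (elastic net can select nothing) yields p = 1.
    """
    Wstd = data.W1 - data.W1.mean(axis=0)
    sd_w = data.W1.std(axis=0)
    Wstd = Wstd / sd_w
    yc = data.y - data.y.mean()
    if predictor == "ridge":
        model = RidgeCV(alphas=_RIDGE_ALPHAS, cv=cv)
    elif predictor == "elastic_net":
        model = ElasticNetCV(l1_ratio=0.5, cv=cv, alphas=50, max_iter=5000)
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    model.fit(Wstd, yc)
    w = np.asarray(model.coef_, dtype=float) / sd_w  # per-dosage weights

    sk = (
        np.asarray(ref_sd, dtype=float)
        if ref_sd is not None
        else data.W1.std(axis=0, ddof=1)
    )
    denom2 = float((w * sk) @ data.ld_gwas @ (w * sk))
    if denom2 <= 0 or not np.any(w):
        logger.info("gene %s: empty prediction model, p = 1", data.gene_id)
        z = 0.0
        p = 1.0
    else:
        z = float((w * sk) @ data.gwas_z / math.sqrt(denom2))
        p = float(2.0 * stats.norm.sf(abs(z)))
    return TestResult(
        gene_id=data.gene_id,
        lrt_stat=z**2,
        p_value=p,
        alpha_prime_hat=z,
        sigma2_hat=max(float(np.var(w)), SIGMA2_FLOOR),
        fit_null=None,
        fit_alt=None,
    )
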