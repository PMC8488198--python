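"""Core model types and likelihood surfaces for summary-statistic TWAS.

The model links per-SNP eQTL z-scores ``zhat1`` and GWAS z-scores ``zhat2``
for one gene to a shared latent vector ``gamma`` of standardized cis-eQTL
effects through an RSS (regression-with-summary-statistics) likelihood:

    zhat1 | gamma ~ N(tau * R1 @ gamma,    R1)
    zhat2 | gamma ~ N(alpha' * R2 @ gamma, R2)
    gamma        ~ N(0, sigma2_gamma * I)

``R1`` and ``R2`` are SNP correlation (LD) matrices estimated from reference
panels matching the eQTL and GWAS populations.  ``alpha'`` is the effect of
genetically regulated expression on the trait, on the z-score scale; the
raw-scale effect is ``alpha = alpha' / c`` with the positive constant ``c``
from :func:`compute_cj`, so testing ``alpha' = 0`` is equivalent to testing
``alpha = 0``.  ``tau`` is a redundant expansion parameter used to speed up
EM-style fitting; it equals 1 in the reduced model.

Every likelihood surface in this package drops the terms that do not depend
on ``gamma`` or the parameters (the ones involving ``R^{-1}`` and ``log|R|``):
they cancel in the likelihood-ratio statistic, and avoiding them is what
makes the variational fit cheap (no LD-matrix inversion).
:func:`exact_marginal_loglik` exposes the closed-form Gaussian marginal of
the same model and serves as an independent oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Lower bound enforced on sigma2_gamma; prevents degenerate null fits for
#: genes with no eQTL signal.
SIGMA2_FLOOR = 1e-8

#: Symmetry / unit-diagonal tolerance for LD matrix validation.
_LD_ATOL = 1e-8


def _as_float_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be a 1-d vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} contains non-finite values")
    return v


def _check_ld_matrix(R, m: int, name: str) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (m, m):
        raise ValueError(f"{name} must be {m}x{m}, got {R.shape}")
    if not np.all(np.isfinite(R)):
        raise ValueError(f"{name} contains non-finite values")
    if not np.allclose(R, R.T, atol=_LD_ATOL):
        raise ValueError(f"{name} is not symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise ValueError(f"{name} does not have a unit diagonal")
    return R


@dataclass
class GeneSummaryData:
    """Per-gene bundle of eQTL/GWAS z-scores and the two LD matrices.

    All vectors and matrices are indexed in the order of ``snp_ids``; both
    LD matrices must be supplied in that same order (harmonization across
    sources is the job of :mod:`sumtwas.ld_reference`).
    """

    gene_id: str
    eqtl_z: np.ndarray
    gwas_z: np.ndarray
    ld_eqtl: np.ndarray
    ld_gwas: np.ndarray
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.eqtl_z = _as_float_vector(self.eqtl_z, "eqtl_z")
        self.gwas_z = _as_float_vector(self.gwas_z, "gwas_z")
        m = self.eqtl_z.shape[0]
        if m < 1:
            raise ValueError("need at least one SNP")
        if self.gwas_z.shape[0] != m:
            raise ValueError(
                f"eqtl_z has {m} SNPs but gwas_z has {self.gwas_z.shape[0]}"
            )
        self.ld_eqtl = _check_ld_matrix(self.ld_eqtl, m, "ld_eqtl")
        self.ld_gwas = _check_ld_matrix(self.ld_gwas, m, "ld_gwas")
        if not self.snp_ids:
            self.snp_ids = [f"snp{k + 1}" for k in range(m)]
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids length does not match z-score length")

    @property
    def m(self) -> int:
        """Number of cis-SNPs for this gene."""
        return self.eqtl_z.shape[0]


@dataclass
class ModelParams:
    """Model parameters (sigma2_gamma, alpha', tau) with the expansion flag.

    ``tau`` is 1 in the reduced model; ``null_model=True`` pins ``alpha'``
    at exactly 0 (the no-association null).
    """

    sigma2_gamma: float
    alpha_prime: float = 0.0
    tau: float = 1.0
    null_model: bool = False

    def __post_init__(self):
        if not np.isfinite(self.sigma2_gamma) or self.sigma2_gamma <= 0:
            raise ValueError("sigma2_gamma must be positive and finite")
        self.sigma2_gamma = max(float(self.sigma2_gamma), SIGMA2_FLOOR)
        if self.null_model and self.alpha_prime != 0.0:
            raise ValueError("null_model requires alpha_prime == 0")


@dataclass
class GeneScale:
    """Sample scales needed to map alpha' back to the raw-effect alpha."""

    sd_expression: float
    sd_trait: float
    n_eqtl: int
    n_gwas: int

    def __post_init__(self):
        for name in ("sd_expression", "sd_trait", "n_eqtl", "n_gwas"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class LatentEffects:
    """Latent standardized eQTL effects gamma (z-score scale)."""

    gamma: np.ndarray

    def __post_init__(self):
        self.gamma = _as_float_vector(self.gamma, "gamma")


def compute_cj(scale: GeneScale) -> float:
    """Positive constant linking alpha' to alpha for simple-regression stats.

    ``c = (sd_expression / sd_trait) * sqrt(n_gwas / n_eqtl)``.  Used only to
    report the raw-scale effect ``alpha = alpha' / c``; it never affects the
    association test because c > 0.
    """
    return (scale.sd_expression / scale.sd_trait) * np.sqrt(
        scale.n_gwas / scale.n_eqtl
    )


def loglik_kernel(
    data: GeneSummaryData, gamma: LatentEffects, params: ModelParams
) -> float:
    """Gamma-and-parameter-dependent part of the complete-data log-likelihood.

    Returns::

        tau * zhat1'g - tau^2/2 * g'R1 g
        + alpha' * zhat2'g - alpha'^2/2 * g'R2 g
        - g'g / (2 sigma2) - m/2 * log(2 pi sigma2)

    with ``g = gamma``.  Terms free of gamma and the parameters (those with
    ``R^{-1}`` and ``log|R|``) are deliberately dropped; they cancel in the
    likelihood-ratio statistic.
    """
    g = gamma.gamma
    if g.shape[0] != data.m:
        raise ValueError(
            f"gamma has length {g.shape[0]} but data has {data.m} SNPs"
        )
    tau, a, s2 = params.tau, params.alpha_prime, params.sigma2_gamma
    out = (
        tau * data.eqtl_z @ g
        - 0.5 * tau**2 * g @ data.ld_eqtl @ g
        + a * data.gwas_z @ g
        - 0.5 * a**2 * g @ data.ld_gwas @ g
        - 0.5 * (g @ g) / s2
        - 0.5 * data.m * np.log(2.0 * np.pi * s2)
    )
    return float(out)


def marginal_covariance(data: GeneSummaryData, params: ModelParams) -> np.ndarray:
    """Joint covariance of (zhat1, zhat2) after integrating out gamma.

    The model is linear-Gaussian, so the marginal of the stacked z-scores is
    a zero-mean 2m-variate normal with blocks::

        Cov(zhat1)        = R1 + tau^2   sigma2 R1 R1
        Cov(zhat2)        = R2 + alpha'^2 sigma2 R2 R2
        Cov(zhat1, zhat2) = tau alpha' sigma2 R1 R2
    """
    R1, R2 = data.ld_eqtl, data.ld_gwas
    tau, a, s2 = params.tau, params.alpha_prime, params.sigma2_gamma
    m = data.m
    cov = np.empty((2 * m, 2 * m))
    cov[:m, :m] = R1 + tau**2 * s2 * R1 @ R1
    cov[m:, m:] = R2 + a**2 * s2 * R2 @ R2
    cross = tau * a * s2 * R1 @ R2
    cov[:m, m:] = cross
    cov[m:, :m] = cross.T
    return cov


def dropped_constant(data: GeneSummaryData) -> float:
    """Parameter-free terms excluded from every likelihood surface.

    Equals ``-1/2 zhat1'R1^{-1}zhat1 - 1/2 log|2 pi R1|`` plus the analogous
    GWAS terms.  Adding it to a constant-dropped surface recovers the full
    log-density; it requires inverting the LD matrices, which is exactly what
    the working surfaces avoid.
    """
    out = 0.0
    for z, R in ((data.eqtl_z, data.ld_eqtl), (data.gwas_z, data.ld_gwas)):
        sign, logdet = np.linalg.slogdet(R)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                "LD matrix is singular; increase shrinkage"
            )
        out += (
            -0.5 * z @ np.linalg.solve(R, z)
            - 0.5 * logdet
            - 0.5 * data.m * np.log(2.0 * np.pi)
        )
    return float(out)


def exact_marginal_loglik(
    data: GeneSummaryData, params: ModelParams, drop_constant: bool = False
) -> float:
    """Closed-form marginal log-likelihood of the stacked z-scores.

    Evaluates the exact zero-mean Gaussian marginal implied by the model
    (see :func:`marginal_covariance`).  With ``drop_constant=True`` the
    parameter-free constant of :func:`loglik_kernel` is subtracted, making
    the value directly comparable to the variational ELBO.

    This is an oracle for testing: the fitting code never calls it, because
    it inverts a 2m x 2m covariance.

    Raises
    ------
    numpy.linalg.LinAlgError
        If the covariance is singular.  Remediation: increase LD shrinkage.
    """
    m = data.m
    cov = marginal_covariance(data, params)
    x = np.concatenate([data.eqtl_z, data.gwas_z])
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError(
            "marginal covariance is singular; increase LD shrinkage"
        )
    try:
        sol = np.linalg.solve(cov, x)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise np.linalg.LinAlgError(
            "marginal covariance is singular; increase LD shrinkage"
        ) from exc
    ll = -0.5 * (2 * m * np.log(2.0 * np.pi) + logdet + x @ sol)
    if drop_constant:
        ll -= dropped_constant(data)
    return float(ll)
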