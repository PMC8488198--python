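"""Synthetic linked eQTL/GWAS worlds and the power/concordance harnesses.

Genotypes are produced by thresholding a latent AR(1) Gaussian: each row is
drawn from ``N(0, Sigma)`` with ``Sigma_kl = rho^|k-l|`` and cut at the
Hardy-Weinberg quantiles implied by a per-SNP minor allele frequency drawn
from ``U(0.05, 0.5)``, giving 0/1/2 genotype counts with HWE frequencies
and LD decaying with SNP distance.  Gene expression is ``y = W1 @ gamma +
e1`` with spike-and-slab effects (sparsity ``pi``); the trait is
``z = alpha * W2 @ gamma + e2``.  Noise scales are calibrated per replicate
against the realized genetic variance so the cellular heritability (of
expression) and trait heritability are controlled exactly at finite n.
Per-SNP summary statistics come from simple linear regression, and LD
matrices from small reference panels drawn from the same genotype law.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import cholesky

from .association import lrt
from .ld_reference import SIM_SHRINKAGE, GenotypePanel, estimate_ld
from .model_core import GeneScale, GeneSummaryData

logger = logging.getLogger(__name__)

LD_SCENARIOS = ("shared", "distinct_ld", "distinct_ld_and_architecture")
RHO_CHOICES = (0.2, 0.5, 0.8)

#: Heritability grids of the simulation study.
H_CELL_GRID = (0.01, 0.03, 0.05, 0.07, 0.09)
H_TRAIT_GRID = (0.001, 0.002, 0.003)
SPARSITY_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 1.0)


@dataclass
class ScenarioConfig:
    """One cell of the simulation design.

    Defaults are the power-study conditions: eQTL study of 500 samples,
    GWAS of 10000, reference panels of 400 each, 100 cis-SNPs with AR(1)
    correlation 0.5, sparsity 0.1, cellular heritability 0.01 and trait
    heritability 0.003, tested at nominal level 0.05.
    """

    n_eqtl: int = 500
    n_gwas: int = 10000
    n_ref_eqtl: int = 400
    n_ref_gwas: int = 400
    m: int = 100
    rho: float = 0.5
    sparsity: float = 0.1
    h_cell: float = 0.01
    h_trait: float = 0.003
    ld_scenario: str = "shared"
    gwas_rho: float | None = None
    overlap_fraction: float = 0.5
    n_reps: int = 500
    seed: int = 0
    alpha_level: float = 0.05
    shrinkage: float = SIM_SHRINKAGE

    def __post_init__(self):
        if not 0.0 <= self.h_cell < 1.0 or not 0.0 <= self.h_trait < 1.0:
            raise ValueError("heritabilities must lie in [0, 1)")
        if not 0.0 < self.sparsity <= 1.0:
            raise ValueError("sparsity must lie in (0, 1]")
        if self.m < 1:
            raise ValueError("need at least one SNP")
        for name in ("n_eqtl", "n_gwas", "n_ref_eqtl", "n_ref_gwas"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be at least 2")
        if self.ld_scenario not in LD_SCENARIOS:
            raise ValueError(f"unknown ld_scenario {self.ld_scenario!r}")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")


@dataclass
class SimulatedWorld:
    """One replicate: individual-level data plus derived summary inputs."""

    W1: np.ndarray
    W2: np.ndarray
    panel1: GenotypePanel
    panel2: GenotypePanel
    gamma_true: np.ndarray
    gamma_gwas: np.ndarray
    y: np.ndarray
    z: np.ndarray
    alpha_true: float
    sigma_e1: float
    sigma_e2: float
    summary: GeneSummaryData
    scale: GeneScale


_CHOL_CACHE: dict[tuple[int, float], np.ndarray] = {}


def _ar1_cholesky(m: int, rho: float) -> np.ndarray:
    key = (m, round(float(rho), 12))
    if key not in _CHOL_CACHE:
        idx = np.arange(m)
        sigma = rho ** np.abs(idx[:, None] - idx[None, :])
        _CHOL_CACHE[key] = cholesky(sigma, lower=True)
    return _CHOL_CACHE[key]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def draw_maf(m: int, seed) -> np.ndarray:
    """Per-SNP minor allele frequencies from U(0.05, 0.5)."""
    return _rng(seed).uniform(0.05, 0.5, size=m)


def simulate_genotypes(
    n: int, m: int, rho: float, seed, maf: np.ndarray | None = None
) -> np.ndarray:
    """Genotype matrix from a thresholded latent AR(1) Gaussian.

    Latent rows are N(0, Sigma) with ``Sigma_kl = rho^|k-l|``; each SNP's
    latent values are cut at the ``(1-f)^2`` and ``(1-f)^2 + 2f(1-f)``
    standard-normal quantiles so that 0/1/2 minor-allele counts occur with
    Hardy-Weinberg probabilities for its MAF ``f``.  Passing ``maf`` pins
    the frequencies (used to share one genotype law across the matrices of
    a world); otherwise they are drawn fresh.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive")
    if not abs(rho) < 1.0:
        raise ValueError("|rho| must be < 1")
    rng = _rng(seed)
    if maf is None:
        maf = draw_maf(m, rng)
    maf = np.asarray(maf, dtype=float)
    latent = rng.standard_normal((n, m)) @ _ar1_cholesky(m, rho).T
    p0 = (1.0 - maf) ** 2
    t0 = sps.norm.ppf(p0)
    t1 = sps.norm.ppf(p0 + 2.0 * maf * (1.0 - maf))
    geno = (latent >= t0).astype(np.float64) + (latent >= t1)
    return geno


def simulate_effects(m: int, sparsity: float, seed) -> np.ndarray:
    """Spike-and-slab standardized effect draw with at least one slab hit.

    Each entry is N(0, 1) with probability ``sparsity`` and exactly 0
    otherwise; an all-zero mask is redrawn (heritability would be
    undefined).  The overall effect scale is immaterial because the noise
    variances are calibrated to the realized genetic variance downstream.
    """
    if not 0.0 < sparsity <= 1.0:
        raise ValueError("sparsity must lie in (0, 1]")
    rng = _rng(seed)
    while True:
        mask = rng.random(m) < sparsity
        if mask.any():
            break
    gamma = np.zeros(m)
    gamma[mask] = rng.standard_normal(mask.sum())
    return gamma


def simulate_expression(
    W1: np.ndarray, gamma: np.ndarray, h_cell: float, seed
) -> tuple[np.ndarray, float]:
    """Expression vector with realized cis-heritability ``h_cell``.

    The noise SD solves ``var(W1 @ gamma) / (var + sigma^2) = h_cell`` with
    the empirical variance of the genetic component, so the target is met
    exactly per replicate.  ``h_cell = 0`` returns pure unit noise.
    """
    if not 0.0 <= h_cell < 1.0:
        raise ValueError("h_cell must lie in [0, 1)")
    rng = _rng(seed)
    n = W1.shape[0]
    if h_cell == 0.0:
        return rng.standard_normal(n), 1.0
    g = W1 @ gamma
    var_g = float(np.var(g))
    if var_g == 0.0:
        raise ValueError("genetic component has zero variance but h_cell > 0")
    sigma_e1 = math.sqrt(var_g * (1.0 - h_cell) / h_cell)
    return g + sigma_e1 * rng.standard_normal(n), sigma_e1


def simulate_trait(
    W2: np.ndarray, gamma: np.ndarray, alpha: float, h_trait: float, seed
) -> tuple[np.ndarray, float, float]:
    """Trait vector with realized trait-level heritability ``h_trait``.

    With unit noise variance, ``alpha`` is rescaled (keeping its sign) so
    that ``var(alpha W2 gamma) / (var + 1) = h_trait``; under the null
    (``h_trait = 0``) the trait is pure noise and ``alpha = 0``.
    Returns ``(z, alpha_scaled, sigma_e2)``.
    """
    if not 0.0 <= h_trait < 1.0:
        raise ValueError("h_trait must lie in [0, 1)")
    rng = _rng(seed)
    n = W2.shape[0]
    noise = rng.standard_normal(n)
    if h_trait == 0.0:
        return noise, 0.0, 1.0
    g = W2 @ gamma
    var_g = float(np.var(g))
    if var_g == 0.0:
        raise ValueError("genetic component has zero variance but h_trait > 0")
    alpha_scaled = math.copysign(
        math.sqrt(h_trait / ((1.0 - h_trait) * var_g)), alpha if alpha else 1.0
    )
    return alpha_scaled * g + noise, alpha_scaled, 1.0


def summary_stats(
    outcome: np.ndarray, W: np.ndarray, on_perfect_fit: str = "error"
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-SNP simple-linear-regression z-scores.

    Regresses the outcome on each mean-centered genotype column separately;
    the standard error uses the usual OLS residual variance with n - 2
    degrees of freedom.  Returns ``(z, se, sd_outcome)``.

    A column that fits the outcome perfectly (zero residual variance)
    either raises or, with ``on_perfect_fit='sentinel'``, yields a signed
    |z| = 1e6 sentinel.
    """
    y = np.asarray(outcome, dtype=float)
    n = y.shape[0]
    if n <= 2:
        raise ValueError("need more than 2 samples")
    Wc = W - W.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Wc, Wc)
    if np.any(sxx == 0):
        raise ValueError("zero-variance SNP column in genotype matrix")
    yc = y - y.mean()
    beta = (Wc.T @ yc) / sxx
    ssy = float(yc @ yc)
    rss = ssy - beta**2 * sxx
    rss = np.maximum(rss, 0.0)
    se = np.sqrt(rss / ((n - 2) * sxx))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    perfect = se == 0
    if perfect.any():
        if on_perfect_fit == "sentinel":
            z[perfect] = np.sign(beta[perfect]) * 1e6
            se[perfect] = np.abs(beta[perfect]) / 1e6
        else:
            raise ValueError("perfect fit: zero residual variance for a SNP")
    return z, se, float(np.std(y, ddof=1))


def _gwas_side_law(config: ScenarioConfig, rng: np.random.Generator) -> float:
    if config.gwas_rho is not None:
        return config.gwas_rho
    remaining = [r for r in RHO_CHOICES if not np.isclose(r, config.rho)]
    return float(rng.choice(remaining)) if remaining else config.rho


def _perturb_architecture(
    gamma: np.ndarray, overlap_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """GWAS-side effects sharing only a fraction of the eQTL causal set.

    Keeps a random ``overlap_fraction`` of the causal SNPs and moves the
    rest to previously non-causal positions, drawing replacement effects
    from a normal whose variance matches the original nonzero effects.
    """
    nz = np.flatnonzero(gamma)
    n_keep = int(round(overlap_fraction * nz.size))
    keep = rng.choice(nz, size=n_keep, replace=False) if n_keep else np.array([], int)
    dropped = np.setdiff1d(nz, keep)
    gamma2 = np.zeros_like(gamma)
    gamma2[keep] = gamma[keep]
    if dropped.size:
        zeros = np.setdiff1d(np.arange(gamma.size), nz)
        n_new = min(dropped.size, zeros.size)
        new_pos = rng.choice(zeros, size=n_new, replace=False)
        scale = math.sqrt(float(np.mean(gamma[nz] ** 2)))
        gamma2[new_pos] = scale * rng.standard_normal(n_new)
    if not gamma2.any():
        gamma2 = gamma.copy()
    return gamma2


def build_world(config: ScenarioConfig, rep_seed) -> SimulatedWorld:
    """Generate one full replicate of the linked eQTL/GWAS design.

    ``shared``: a single genotype law (one rho, one MAF vector) underlies
    the eQTL matrix, GWAS matrix, and both reference panels.
    ``distinct_ld``: the eQTL side (W1 and its panel) and GWAS side (W2 and
    its panel) use independent laws with different rho.
    ``distinct_ld_and_architecture``: additionally, the GWAS-side causal
    set retains only ``overlap_fraction`` of the eQTL causal SNPs.
    """
    rng = _rng(rep_seed)
    m = config.m
    ids = [f"snp{k + 1}" for k in range(m)]

    maf1 = draw_maf(m, rng)
    if config.ld_scenario == "shared":
        rho2, maf2 = config.rho, maf1
    else:
        rho2 = _gwas_side_law(config, rng)
        maf2 = draw_maf(m, rng)

    W1 = simulate_genotypes(config.n_eqtl, m, config.rho, rng, maf=maf1)
    W2 = simulate_genotypes(config.n_gwas, m, rho2, rng, maf=maf2)
    P1 = simulate_genotypes(config.n_ref_eqtl, m, config.rho, rng, maf=maf1)
    P2 = simulate_genotypes(config.n_ref_gwas, m, rho2, rng, maf=maf2)
    panel1 = GenotypePanel(P1, ids)
    panel2 = GenotypePanel(P2, ids)

    gamma = simulate_effects(m, config.sparsity, rng)
    if config.ld_scenario == "distinct_ld_and_architecture":
        gamma_gwas = _perturb_architecture(gamma, config.overlap_fraction, rng)
    else:
        gamma_gwas = gamma

    y, sigma_e1 = simulate_expression(W1, gamma, config.h_cell, rng)
    z, alpha, sigma_e2 = simulate_trait(W2, gamma_gwas, 1.0, config.h_trait, rng)

    eqtl_z, _, sd_y = summary_stats(y, W1)
    gwas_z, _, sd_z = summary_stats(z, W2)
    summary = GeneSummaryData(
        gene_id="sim_gene",
        eqtl_z=eqtl_z,
        gwas_z=gwas_z,
        ld_eqtl=estimate_ld(panel1, config.shrinkage),
        ld_gwas=estimate_ld(panel2, config.shrinkage),
        snp_ids=ids,
    )
    scale = GeneScale(
        sd_expression=sd_y,
        sd_trait=sd_z,
        n_eqtl=config.n_eqtl,
        n_gwas=config.n_gwas,
    )
    return SimulatedWorld(
        W1=W1,
        W2=W2,
        panel1=panel1,
        panel2=panel2,
        gamma_true=gamma,
        gamma_gwas=gamma_gwas,
        y=y,
        z=z,
        alpha_true=alpha,
        sigma_e1=sigma_e1,
        sigma_e2=sigma_e2,
        summary=summary,
        scale=scale,
    )


def _run_method(method: str, world: SimulatedWorld, rng: np.random.Generator):
    # imported lazily to avoid a circular import at module load
    from .baselines import IndividualEqtlData, comm_s2_lrt, two_stage_twas

    if method == "comm_s4":
        return lrt(world.summary, scale=world.scale)
    data = IndividualEqtlData(
        y=world.y,
        W1=world.W1,
        gwas_z=world.summary.gwas_z,
        ld_gwas=world.summary.ld_gwas,
    )
    if method == "comm_s2":
        return comm_s2_lrt(data)
    ref_sd = world.panel2.genotypes.std(axis=0, ddof=1)
    if method == "ridge_twoStage":
        return two_stage_twas(data, predictor="ridge", ref_sd=ref_sd)
    if method == "enet_twoStage":
        return two_stage_twas(data, predictor="elastic_net", ref_sd=ref_sd)
    raise ValueError(f"unknown method {method!r}")


def power_experiment(
    config: ScenarioConfig,
    methods=("comm_s4",),
    h_cell_grid=None,
    sparsity_grid=None,
    h_trait_grid=None,
    progress: bool = False,
) -> pd.DataFrame:
    """Empirical rejection rates over a (h_cell x sparsity x h_trait) grid.

    Each cell runs ``config.n_reps`` independent replicates; a replicate on
    which a method fails counts as a non-rejection and is logged.  Returns
    one row per (cell, method) with the rejection fraction and its binomial
    Monte-Carlo standard error.
    """
    if config.n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    h_cells = list(h_cell_grid) if h_cell_grid is not None else [config.h_cell]
    sparsities = (
        list(sparsity_grid) if sparsity_grid is not None else [config.sparsity]
    )
    h_traits = (
        list(h_trait_grid) if h_trait_grid is not None else [config.h_trait]
    )
    rows = []
    root = np.random.SeedSequence(config.seed)
    cells = [(hc, pi, ht) for hc in h_cells for pi in sparsities for ht in h_traits]
    cell_seeds = root.spawn(len(cells))
    for (h_cell, sparsity, h_trait), cell_seed in zip(cells, cell_seeds):
        cell_cfg = replace(
            config, h_cell=h_cell, sparsity=sparsity, h_trait=h_trait
        )
        rejects = {meth: 0 for meth in methods}
        rep_seeds = cell_seed.spawn(config.n_reps)
        for r, rep_seed in enumerate(rep_seeds):
            rng = np.random.default_rng(rep_seed)
            world = build_world(cell_cfg, rng)
            for meth in methods:
                try:
                    res = _run_method(meth, world, rng)
                    if res.p_value < config.alpha_level:
                        rejects[meth] += 1
                except Exception as exc:  # noqa: BLE001 - rep isolation
                    logger.warning(
                        "rep %d method %s failed: %s", r, meth, exc
                    )
            if progress and (r + 1) % 50 == 0:
                logger.info(
                    "cell (%g, %g, %g): %d/%d reps",
                    h_cell, sparsity, h_trait, r + 1, config.n_reps,
                )
        for meth in methods:
            p = rejects[meth] / config.n_reps
            rows.append(
                {
                    "scenario": config.ld_scenario,
                    "h_cell": h_cell,
                    "sparsity": sparsity,
                    "h_trait": h_trait,
                    "method": meth,
                    "n_reps": config.n_reps,
                    "power": p,
                    "mc_se": math.sqrt(p * (1.0 - p) / config.n_reps),
                }
            )
    return pd.DataFrame(rows)


def concordance_experiment(
    config: ScenarioConfig,
    h_cell_grid=H_CELL_GRID,
    h_trait_grid=H_TRAIT_GRID,
) -> tuple[float, float, pd.DataFrame]:
    """Paired summary-statistic vs individual-level-eQTL LRT statistics.

    On each simulated world both the summary-level test (comm_s4) and the
    individual-level-eQTL test (comm_s2) are run; pairs are pooled over the
    heritability grid with ``config.n_reps`` total pairs spread evenly over
    the cells.  Returns ``(r_squared, slope, pairs)`` where slope and R^2
    come from the OLS regression of the individual-level statistic on the
    summary-level one.
    """
    from .baselines import IndividualEqtlData, comm_s2_lrt

    if config.n_reps < 2:
        raise ValueError("need at least 2 replicates")
    cells = [(hc, ht) for hc in h_cell_grid for ht in h_trait_grid]
    reps_per_cell = max(1, math.ceil(config.n_reps / len(cells)))
    root = np.random.SeedSequence(config.seed)
    cell_seeds = root.spawn(len(cells))
    rows = []
    for (h_cell, h_trait), cell_seed in zip(cells, cell_seeds):
        cell_cfg = replace(config, h_cell=h_cell, h_trait=h_trait)
        for rep_seed in cell_seed.spawn(reps_per_cell):
            rng = np.random.default_rng(rep_seed)
            world = build_world(cell_cfg, rng)
            res4 = lrt(world.summary)
            res2 = comm_s2_lrt(
                IndividualEqtlData(
                    y=world.y,
                    W1=world.W1,
                    gwas_z=world.summary.gwas_z,
                    ld_gwas=world.summary.ld_gwas,
                )
            )
            rows.append(
                {
                    "h_cell": h_cell,
                    "h_trait": h_trait,
                    "lrt_s4": res4.lrt_stat,
                    "lrt_s2": res2.lrt_stat,
                }
            )
    pairs = pd.DataFrame(rows)
    fit = sps.linregress(pairs["lrt_s4"], pairs["lrt_s2"])
    return float(fit.rvalue**2), float(fit.slope), pairs
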