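"""LD estimation from reference panels and cross-source SNP harmonization.

Reference panels are small relative to the number of cis-SNPs (a few
hundred samples against ~100 SNPs), so the sample correlation matrix is
shrunk toward the identity, ``R = (1 - s) P + s I``, which guarantees
positive definiteness for any ``s > 0`` (all eigenvalues are at least
``s``).  Harmonization intersects the SNPs present in the eQTL stats, GWAS
stats, and both panels, aligns effect alleles by flipping z-score signs
and dosage orientation, and drops strand-ambiguous (A/T, C/G) variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import GeneSummaryData

logger = logging.getLogger(__name__)

#: Default shrinkage for real reference panels.
DEFAULT_SHRINKAGE = 0.1
#: Default shrinkage used throughout the simulation suite.
SIM_SHRINKAGE = 0.05

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class GenotypePanel:
    """Reference-panel dosage matrix (samples x SNPs) with allele labels."""

    genotypes: np.ndarray
    snp_ids: list[str]
    a1: list[str] = field(default_factory=list)
    a2: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-d samples x SNPs matrix")
        n, m = self.genotypes.shape
        if n < 2:
            raise ValueError("need at least 2 reference samples")
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids length does not match genotype columns")
        if np.any(self.genotypes < 0) or np.any(self.genotypes > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if not self.a1:
            self.a1 = ["A"] * m
        if not self.a2:
            self.a2 = ["G"] * m
        if len(self.a1) != m or len(self.a2) != m:
            raise ValueError("allele vectors must match genotype columns")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]


def estimate_ld(
    panel: GenotypePanel, shrinkage: float = DEFAULT_SHRINKAGE
) -> np.ndarray:
    """Shrunk SNP correlation matrix ``(1 - s) P + s I`` from a panel.

    ``P`` is the sample Pearson correlation of the (mean-centered) genotype
    columns.  The result is symmetric with unit diagonal and positive
    definite for ``s > 0``.

    Raises
    ------
    ValueError
        If a genotype column has zero variance (the offending SNP is
        named) or ``shrinkage`` is outside [0, 1].
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    G = panel.genotypes
    sd = G.std(axis=0)
    if np.any(sd == 0):
        bad = [panel.snp_ids[k] for k in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance SNP(s) in panel: {', '.join(bad)}")
    if panel.m == 1:
        return np.ones((1, 1))
    P = np.corrcoef(G, rowvar=False)
    R = (1.0 - shrinkage) * P + shrinkage * np.eye(panel.m)
    # enforce exact symmetry / unit diagonal against rounding
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    return R


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def _orient(a1: str, a2: str, ref_a1: str, ref_a2: str) -> int | None:
    """+1 if alleles match the reference orientation, -1 if swapped.

    Allele pairs that match neither orientation (also after strand
    complement) are unresolvable and return None.
    """
    a1, a2 = a1.upper(), a2.upper()
    ref_a1, ref_a2 = ref_a1.upper(), ref_a2.upper()
    if (a1, a2) == (ref_a1, ref_a2):
        return 1
    if (a1, a2) == (ref_a2, ref_a1):
        return -1
    c1, c2 = _COMPLEMENT.get(a1), _COMPLEMENT.get(a2)
    if (c1, c2) == (ref_a1, ref_a2):
        return 1
    if (c1, c2) == (ref_a2, ref_a1):
        return -1
    return None


def _stats_frame(stats, name: str) -> pd.DataFrame:
    df = pd.DataFrame(stats).copy()
    required = {"snp", "a1", "a2", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{name} is missing columns: {sorted(missing)}")
    if df["snp"].duplicated().any():
        raise ValueError(f"{name} contains duplicate SNP ids")
    return df


def harmonize(
    eqtl_stats,
    gwas_stats,
    panel_eqtl: GenotypePanel,
    panel_gwas: GenotypePanel,
    gene_id: str = "gene",
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> GeneSummaryData:
    """Intersect and allele-align the four per-gene sources.

    The GWAS panel's allele orientation is the reference frame: z-scores
    whose allele pair is swapped relative to it have their signs flipped,
    and eQTL-panel dosage columns are flipped to ``2 - g``.  SNPs absent
    from any source, strand-ambiguous SNPs, and SNPs with unresolvable
    allele pairs are dropped (with logged counts).  Output SNP order is the
    GWAS panel's order restricted to the intersection.  The returned bundle
    carries shrunk LD matrices estimated from the aligned panels, so
    harmonize is idempotent on its own output.
    """
    eqtl = _stats_frame(eqtl_stats, "eqtl_stats").set_index("snp")
    gwas = _stats_frame(gwas_stats, "gwas_stats").set_index("snp")

    ref = {
        sid: (panel_gwas.a1[k], panel_gwas.a2[k])
        for k, sid in enumerate(panel_gwas.snp_ids)
    }
    eqtl_panel_idx = {sid: k for k, sid in enumerate(panel_eqtl.snp_ids)}

    common = [
        sid
        for sid in panel_gwas.snp_ids
        if sid in eqtl.index and sid in gwas.index and sid in eqtl_panel_idx
    ]
    if not common:
        raise ValueError("no SNPs shared by all four sources")

    keep: list[str] = []
    eqtl_z: list[float] = []
    gwas_z: list[float] = []
    eqtl_cols: list[np.ndarray] = []
    gwas_cols: list[np.ndarray] = []
    n_ambiguous = n_unresolved = 0
    for sid in common:
        ra1, ra2 = ref[sid]
        if _is_ambiguous(ra1, ra2):
            n_ambiguous += 1
            continue
        flips = [
            _orient(eqtl.loc[sid, "a1"], eqtl.loc[sid, "a2"], ra1, ra2),
            _orient(gwas.loc[sid, "a1"], gwas.loc[sid, "a2"], ra1, ra2),
            _orient(
                panel_eqtl.a1[eqtl_panel_idx[sid]],
                panel_eqtl.a2[eqtl_panel_idx[sid]],
                ra1,
                ra2,
            ),
        ]
        if any(f is None for f in flips):
            n_unresolved += 1
            continue
        keep.append(sid)
        eqtl_z.append(flips[0] * float(eqtl.loc[sid, "z"]))
        gwas_z.append(flips[1] * float(gwas.loc[sid, "z"]))
        col = panel_eqtl.genotypes[:, eqtl_panel_idx[sid]]
        eqtl_cols.append(2.0 - col if flips[2] == -1 else col)
        gwas_cols.append(panel_gwas.genotypes[:, panel_gwas.snp_ids.index(sid)])
    if n_ambiguous:
        logger.info("dropped %d strand-ambiguous SNPs", n_ambiguous)
    if n_unresolved:
        logger.info("dropped %d SNPs with unresolvable alleles", n_unresolved)
    if not keep:
        raise ValueError("no SNPs survived allele harmonization")

    alleles_a1 = [ref[sid][0] for sid in keep]
    alleles_a2 = [ref[sid][1] for sid in keep]
    aligned_eqtl = GenotypePanel(
        np.column_stack(eqtl_cols), list(keep), alleles_a1, alleles_a2
    )
    aligned_gwas = GenotypePanel(
        np.column_stack(gwas_cols), list(keep), alleles_a1, alleles_a2
    )
    return GeneSummaryData(
        gene_id=gene_id,
        eqtl_z=np.asarray(eqtl_z),
        gwas_z=np.asarray(gwas_z),
        ld_eqtl=estimate_ld(aligned_eqtl, shrinkage),
        ld_gwas=estimate_ld(aligned_gwas, shrinkage),
        snp_ids=list(keep),
    )
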