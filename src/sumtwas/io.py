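"""Delimited-text readers and writers.

All formats are plain tab-delimited text (configurable delimiter) with a
header row; run metadata travels in '#'-prefixed comment lines.  Summary
statistics carry the columns ``gene, snp, a1, a2, z`` plus optional ``se``
and ``n``; genotype panels are samples x SNPs matrices with SNP ids in the
header and a two-column allele sidecar.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .ld_reference import GenotypePanel

REQUIRED_STAT_COLUMNS = ("gene", "snp", "a1", "a2", "z")


def read_summary_stats(path, sep: str = "\t") -> dict[str, pd.DataFrame]:
    """Per-gene summary statistics grouped by the ``gene`` column.

    Returns an ordered mapping gene -> DataFrame (row order preserved
    within each gene).  Malformed rows and structural problems raise with
    the offending line or column named.
    """
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    missing = [c for c in REQUIRED_STAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("z", "se", "n"):
        if col not in df.columns:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: non-numeric {col!r} on line {bad[0] + 2}"
            )
        df[col] = converted
    dup = df.duplicated(subset=["gene", "snp"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["gene", "snp"]].tolist()
        raise ValueError(f"{path}: duplicate (gene, snp) pair {tuple(pair)}")
    return {
        gene: grp.drop(columns="gene").reset_index(drop=True)
        for gene, grp in df.groupby("gene", sort=False)
    }


def write_summary_stats(groups: dict[str, pd.DataFrame], path, sep: str = "\t"):
    """Inverse of :func:`read_summary_stats` (round-trip identity)."""
    frames = []
    for gene, grp in groups.items():
        out = grp.copy()
        out.insert(0, "gene", gene)
        frames.append(out)
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def read_genotype_panel(path, allele_path=None, sep: str = "\t") -> GenotypePanel:
    """Samples x SNPs dosage matrix with SNP ids in the header.

    ``allele_path`` points to a sidecar table with columns ``snp, a1, a2``;
    without it, placeholder alleles are assigned (sufficient when the panel
    is already harmonized).
    """
    df = pd.read_csv(path, sep=sep, comment="#")
    snp_ids = [str(c) for c in df.columns]
    a1 = a2 = []
    if allele_path is not None:
        al = pd.read_csv(allele_path, sep=sep, comment="#", dtype=str)
        for col in ("snp", "a1", "a2"):
            if col not in al.columns:
                raise ValueError(f"{allele_path}: missing column {col!r}")
        al = al.set_index("snp")
        try:
            a1 = [al.loc[s, "a1"] for s in snp_ids]
            a2 = [al.loc[s, "a2"] for s in snp_ids]
        except KeyError as exc:
            raise ValueError(f"{allele_path}: no alleles for SNP {exc}") from exc
    return GenotypePanel(df.to_numpy(dtype=float), snp_ids, list(a1), list(a2))


def read_ld_matrix(path, sep: str = "\t") -> np.ndarray:
    """Pre-computed square SNP correlation matrix (header = SNP ids)."""
    df = pd.read_csv(path, sep=sep, comment="#")
    R = df.to_numpy(dtype=float)
    if R.shape[0] != R.shape[1]:
        raise ValueError(f"{path}: LD matrix is not square ({R.shape})")
    return R


def write_ld_matrix(R: np.ndarray, snp_ids, path, sep: str = "\t"):
    pd.DataFrame(R, columns=list(snp_ids)).to_csv(path, sep=sep, index=False)


#: Default cis-window half-width in base pairs.
DEFAULT_CIS_WINDOW = 500_000


def group_by_window(
    stats: pd.DataFrame, genes: pd.DataFrame, window: int = DEFAULT_CIS_WINDOW
) -> dict[str, pd.DataFrame]:
    """Assign positionally keyed SNP statistics to genes by cis-window.

    ``stats`` needs columns ``chrom, pos, snp, a1, a2, z`` (no gene
    column); ``genes`` needs ``gene, chrom, start, end`` with half-open
    0-based intervals.  A SNP is assigned to every gene whose interval,
    extended by ``window`` bp on each side, contains its position.
    Returns the same grouped mapping as :func:`read_summary_stats`.
    """
    for col in ("chrom", "pos", "snp", "a1", "a2", "z"):
        if col not in stats.columns:
            raise ValueError(f"stats is missing column {col!r}")
    for col in ("gene", "chrom", "start", "end"):
        if col not in genes.columns:
            raise ValueError(f"genes is missing column {col!r}")
    groups: dict[str, pd.DataFrame] = {}
    for row in genes.itertuples(index=False):
        lo, hi = row.start - window, row.end + window
        hit = stats[
            (stats["chrom"] == row.chrom)
            & (stats["pos"] >= lo)
            & (stats["pos"] < hi)
        ]
        if len(hit):
            groups[row.gene] = hit.drop(columns=["chrom", "pos"]).reset_index(
                drop=True
            )
    return groups


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping, for run metadata."""
    blob = repr(sorted(config.items())).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


RESULT_COLUMNS = (
    "gene",
    "m_snps",
    "alpha_prime_hat",
    "sigma2_hat",
    "lrt",
    "pvalue",
    "converged_null",
    "converged_alt",
)


def write_results(results, path, seed=None, cfg_hash=None, sep: str = "\t"):
    """Deterministically ordered per-gene result table with a metadata line.

    Results are sorted by gene id; the first line is a '#'-prefixed header
    carrying the package version, seed, and configuration hash.
    """
    from . import __version__

    rows = []
    for r in sorted(results, key=lambda r: r.gene_id):
        rows.append(
            {
                "gene": r.gene_id,
                "m_snps": len(r.fit_alt.posterior.mu) if r.fit_alt else "",
                "alpha_prime_hat": r.alpha_prime_hat,
                "sigma2_hat": r.sigma2_hat,
                "lrt": r.lrt_stat,
                "pvalue": r.p_value,
                "converged_null": r.fit_null.converged if r.fit_null else "",
                "converged_alt": r.fit_alt.converged if r.fit_alt else "",
            }
        )
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"# sumtwas {__version__} seed={seed} config={cfg_hash}\n"
        )
        pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(
            fh, sep=sep, index=False
        )


def write_power_table(table: pd.DataFrame, path, sep: str = "\t"):
    table.to_csv(path, sep=sep, index=False)
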