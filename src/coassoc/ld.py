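"""Linkage disequilibrium summaries among candidate SNPs.

LD is the squared Pearson correlation (r^2) of genotype dosage codes across
individuals with complete data at both SNPs. Gene-pair means aggregate r^2
over all SNP pairs annotated to two contigs, excluding SNPs genotyped in
too few individuals (default 250, matching the empirical study; synthetic
panels use a smaller threshold).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data_io import MISSING, SnpTable

__all__ = [
    "pairwise_r2",
    "r2_matrix",
    "gene_pair_mean_ld",
    "module_ld_summary",
]


def pairwise_r2(snps: SnpTable, snp_a: str, snp_b: str) -> float:
    """r^2 between two SNPs over individuals genotyped at both.

    NaN (with a warning) when fewer than 2 complete individuals remain or
    either SNP is monomorphic among them.
    """
    ids = list(snps.snp_ids)
    ga = snps.genotypes[:, ids.index(snp_a)].astype(float)
    gb = snps.genotypes[:, ids.index(snp_b)].astype(float)
    ok = (ga != MISSING) & (gb != MISSING)
    ga, gb = ga[ok], gb[ok]
    if len(ga) < 2 or np.ptp(ga) == 0 or np.ptp(gb) == 0:
        warnings.warn(f"r^2 undefined for pair ({snp_a}, {snp_b}): "
                      "monomorphic or insufficient overlap")
        return float("nan")
    r = np.corrcoef(ga, gb)[0, 1]
    return float(r * r)


def r2_matrix(snps: SnpTable, snp_ids=None) -> pd.DataFrame:
    """Symmetric r^2 matrix (unit diagonal) over a SNP subset."""
    if snp_ids is None:
        snp_ids = list(snps.snp_ids)
    idx = [list(snps.snp_ids).index(s) for s in snp_ids]
    G = snps.genotypes[:, idx].astype(float)
    G[G == MISSING] = np.nan
    n = len(snp_ids)
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(G[:, i]) & ~np.isnan(G[:, j])
            if ok.sum() < 2:
                continue
            a, b = G[ok, i], G[ok, j]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            out[i, j] = out[j, i] = r * r
    return pd.DataFrame(out, index=snp_ids, columns=snp_ids)


def _eligible_snps(snps: SnpTable, min_genotyped: int) -> np.ndarray:
    n_obs = (snps.genotypes != MISSING).sum(axis=0)
    return n_obs >= min_genotyped


def gene_pair_mean_ld(snps: SnpTable, min_genotyped: int = 250,
                      snp_subset=None) -> pd.DataFrame:
    """Mean r^2 for every pair of contigs.

    SNPs genotyped in fewer than ``min_genotyped`` individuals are excluded
    from all means. The diagonal is the within-gene mean excluding
    self-pairs; gene pairs with no eligible SNP pair are NaN.
    """
    if min_genotyped < 2:
        raise ValueError("min_genotyped must be >= 2")
    keep = _eligible_snps(snps, min_genotyped)
    if snp_subset is not None:
        wanted = np.isin(snps.snp_ids, list(snp_subset))
        keep = keep & wanted
    sub = snps.subset_snps(keep)
    if sub.n_snps == 0:
        raise ValueError("no SNPs pass the genotyping threshold")
    r2 = r2_matrix(sub)
    contig = pd.Series(sub.contig_ids, index=sub.snp_ids)
    genes = sorted(set(contig))
    out = pd.DataFrame(np.nan, index=genes, columns=genes)
    members = {g: list(contig.index[contig == g]) for g in genes}
    for gi, ga in enumerate(genes):
        for gb in genes[gi:]:
            vals = r2.loc[members[ga], members[gb]].to_numpy(dtype=float)
            if ga == gb:
                iu = np.triu_indices(len(members[ga]), k=1)
                vals = vals[iu]
            m = np.nanmean(vals) if vals.size and not np.isnan(vals).all() else np.nan
            out.loc[ga, gb] = out.loc[gb, ga] = m
    return out


def module_ld_summary(r2: pd.DataFrame, modules: dict) -> pd.DataFrame:
    """Mean r^2 within and between modules (self-pairs excluded within)."""
    mods = sorted(set(modules.values()), key=str)
    out = pd.DataFrame(np.nan, index=mods, columns=mods)
    members = {m: [s for s in r2.index if modules.get(s) == m] for m in mods}
    for i, ma in enumerate(mods):
        for mb in mods[i:]:
            vals = r2.loc[members[ma], members[mb]].to_numpy(dtype=float)
            if ma == mb:
                iu = np.triu_indices(len(members[ma]), k=1)
                vals = vals[iu]
            m = np.nanmean(vals) if vals.size and not np.isnan(vals).all() else np.nan
            out.loc[ma, mb] = out.loc[mb, ma] = m
    return out
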