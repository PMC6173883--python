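"""Top candidate genes and SNPs.

A *top candidate gene* is a contig carrying more outlier-association SNPs
than expected by chance: with k of its n SNPs flagged as outliers and a
genome-wide outlier fraction pbar, the binomial tail P(X >= k | n, pbar)
falls below a very restrictive cutoff (default 1e-9). Because SNPs within
a contig are not independent this P is an index for ranking, not an exact
probability.

A *top candidate SNP* lies inside a top candidate gene and, for at least
one environment, passes BOTH criteria: (i) uncorrected Spearman P below the
Bonferroni cutoff and (ii) log10 Bayes factor > 2 (default) for the
structure-corrected layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .associations import AssociationMatrix, bonferroni_threshold

__all__ = [
    "CandidateSet",
    "flag_outlier_snps",
    "top_candidate_genes",
    "top_candidate_snps",
]


@dataclass
class CandidateSet:
    """Gene-level and SNP-level candidate tables."""

    genes: pd.DataFrame  # index contig_id; n_snps, n_outlier_snps, binomial_tail_p, candidate
    snps: Optional[pd.DataFrame] = None  # index snp_id; contig_id, environments

    @property
    def candidate_contigs(self) -> list:
        return list(self.genes.index[self.genes["candidate"]])

    @property
    def candidate_snp_ids(self) -> list:
        return [] if self.snps is None else list(self.snps.index)


def flag_outlier_snps(assoc: AssociationMatrix, quantile: float = 0.99) -> pd.DataFrame:
    """Flag cells whose |rho| strictly exceeds the per-environment
    genome-wide empirical quantile."""
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    r = assoc.rho.abs()
    thresh = r.quantile(quantile, axis=0)
    flags = r.gt(thresh, axis=1) & r.notna()
    return flags


def top_candidate_genes(flags: pd.DataFrame, contig_of_snp: pd.Series,
                        p_cutoff: float = 1e-9) -> CandidateSet:
    """Binomial-tail enrichment of outlier SNPs per contig.

    A SNP flagged in any environment counts once; pbar is the genome-wide
    fraction of flagged SNPs across all contigs.
    """
    unmapped = [s for s in flags.index if s not in contig_of_snp.index]
    if unmapped:
        raise ValueError(f"SNPs without a contig: {unmapped[:5]}")
    snp_flag = flags.any(axis=1)
    contig = contig_of_snp.loc[flags.index]
    grp = snp_flag.groupby(contig)
    n = grp.size()
    k = grp.sum()
    if (n == 0).any():
        warnings.warn("contigs with zero SNPs excluded")
        keep = n > 0
        n, k = n[keep], k[keep]
    pbar = float(snp_flag.mean())
    tail_p = stats.binom.sf(k - 1, n, pbar)  # P(X >= k)
    genes = pd.DataFrame({
        "n_snps": n.astype(int),
        "n_outlier_snps": k.astype(int),
        "binomial_tail_p": tail_p,
    })
    genes["candidate"] = genes["binomial_tail_p"] < p_cutoff
    genes.index.name = "contig_id"
    return CandidateSet(genes.sort_values("binomial_tail_p"))


def top_candidate_snps(assoc_raw: AssociationMatrix,
                       assoc_corrected: AssociationMatrix,
                       genes: CandidateSet,
                       contig_of_snp: pd.Series,
                       alpha: float = 0.05,
                       bf_min: float = 2.0) -> CandidateSet:
    """SNPs inside top candidate genes passing the dual criteria.

    For at least one environment the SNP must have (i) uncorrected P below
    the Bonferroni threshold ``alpha / (n_snps * n_envs)`` and (ii)
    structure-corrected log10 BF > ``bf_min``. The passing environments are
    recorded.
    """
    if assoc_corrected.log10_bf is None:
        raise ValueError(
            "corrected association layer has no Bayes factors; compute them "
            "with log10_bf_matrix or load external ones with read_bayes_factors"
        )
    if list(assoc_raw.snp_ids) != list(assoc_corrected.snp_ids):
        raise ValueError("raw and corrected layers are not aligned on SNP ids")
    n_snps = len(assoc_raw.snp_ids)
    n_envs = len(assoc_raw.environments)
    cutoff = bonferroni_threshold(n_snps, n_envs, alpha)
    pass_p = assoc_raw.pvalue < cutoff
    pass_bf = assoc_corrected.log10_bf > bf_min
    both = pass_p & pass_bf.loc[pass_p.index, pass_p.columns]
    cand_contigs = set(genes.candidate_contigs)
    rows = []
    for snp in assoc_raw.snp_ids:
        contig = contig_of_snp.get(snp)
        if contig not in cand_contigs:
            continue
        envs = [e for e in assoc_raw.environments if bool(both.loc[snp, e])]
        if envs:
            rows.append((snp, contig, ",".join(envs)))
    snps = pd.DataFrame(rows, columns=["snp_id", "contig_id", "environments"])
    snps = snps.set_index("snp_id")
    return CandidateSet(genes.genes, snps)
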