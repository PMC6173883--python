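"""SNP x environment association statistics.

Two layers are produced for each SNP/environment pair:

* an uncorrected nonparametric association — Spearman's rho between the
  per-population derived-allele frequency and the environmental variable,
  with a two-sided P value;
* a structure-corrected analog — the population covariance of standardized
  allele frequencies is estimated from putatively neutral SNPs, frequencies
  are whitened by its Cholesky factor, and a conjugate normal linear model
  on the whitened frequencies yields a Bayes factor for a linear
  frequency-environment relationship after shared history is removed.

The Bayes factor here is a deterministic closed-form approximation to the
MCMC-based statistic used in the empirical study; externally computed Bayes
factors can be ingested from TSV instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats, linalg

from .data_io import EnvMatrix, FreqMatrix

__all__ = [
    "AssociationMatrix",
    "PopCovariance",
    "spearman_matrix",
    "bonferroni_threshold",
    "estimate_pop_covariance",
    "whiten_frequencies",
    "approx_log10_bf",
    "log10_bf_matrix",
    "read_bayes_factors",
    "write_association_matrix",
]

EXACT_PERM_MAX_N = 9  # exact permutation P values below this sample size


@dataclass
class AssociationMatrix:
    """SNP x environment statistics (rho, P, optionally log10 BF)."""

    rho: pd.DataFrame        # SNPs x environments, signed, in [-1, 1]
    pvalue: pd.DataFrame     # two-sided P values
    log10_bf: Optional[pd.DataFrame] = None
    corrected: bool = False

    def __post_init__(self):
        r = self.rho.to_numpy(dtype=float)
        if np.nanmax(np.abs(r), initial=0.0) > 1 + 1e-9:
            raise ValueError("|rho| must be <= 1")
        if self.pvalue.shape != self.rho.shape:
            raise ValueError("rho and pvalue shapes differ")
        if self.log10_bf is not None and self.log10_bf.shape != self.rho.shape:
            raise ValueError("log10_bf shape differs from rho")

    @property
    def snp_ids(self) -> list:
        return list(self.rho.index)

    @property
    def environments(self) -> list:
        return list(self.rho.columns)


@dataclass
class PopCovariance:
    """Population covariance of standardized allele frequencies.

    Estimated from putatively neutral SNPs; a ridge term keeps it positive
    definite so it admits a Cholesky factorization.
    """

    matrix: pd.DataFrame  # populations x populations
    n_snps: int = 0

    def __post_init__(self):
        m = self.matrix.to_numpy(dtype=float)
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    def cholesky(self) -> np.ndarray:
        try:
            return np.linalg.cholesky(self.matrix.to_numpy(dtype=float))
        except np.linalg.LinAlgError as e:
            raise ValueError(
                "covariance is not positive definite; increase the ridge "
                "regularization in estimate_pop_covariance"
            ) from e


def _rankdata_cols(a: np.ndarray) -> np.ndarray:
    """Average ranks column-wise (ties get mean rank)."""
    return stats.rankdata(a, axis=0)


def _spearman_exact_pvalue(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation P value for Spearman's rho (small n)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = np.array(list(itertools.permutations(range(n))))
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    rhos = (ry_c[perms] @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def _spearman_pair(f: np.ndarray, e: np.ndarray):
    """rho and two-sided P for one SNP/environment pair (complete cases)."""
    n = len(f)
    if n < 3 or np.ptp(f) == 0 or np.ptp(e) == 0:
        return np.nan, np.nan
    rho, _ = stats.spearmanr(f, e)
    if np.isnan(rho):
        return np.nan, np.nan
    if n < max(EXACT_PERM_MAX_N + 1, 10):
        p = _spearman_exact_pvalue(f, e, rho)
    else:
        p = _t_approx_pvalue(np.array([rho]), n)[0]
    return float(rho), float(p)


def _t_approx_pvalue(rho: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    # perfect monotone relation: P underflows to the smallest representable
    p = np.where(np.abs(rho) >= 1 - 1e-12, np.finfo(float).tiny, p)
    return p


def spearman_matrix(freqs: FreqMatrix, envs: EnvMatrix,
                    corrected: bool = False) -> AssociationMatrix:
    """Spearman's rho and two-sided P for every SNP/environment pair.

    Pairs with fewer than 3 populations of complete data, or with a
    constant frequency or environment, are NaN. P values use the
    t approximation for n >= 10 and exact rank permutation below that.
    """
    F = freqs.freq.to_numpy(dtype=float)           # pops x snps
    E = envs.values.loc[freqs.pop_ids].to_numpy(dtype=float)  # pops x envs
    n_pops, n_snps = F.shape
    n_envs = E.shape[1]
    if not np.isnan(F).any() and n_pops >= 10:
        # fast path: rank-transform then Pearson via matrix products
        rf = _rankdata_cols(F)
        re = _rankdata_cols(E)
        rf = rf - rf.mean(axis=0)
        re = re - re.mean(axis=0)
        sf = np.sqrt((rf ** 2).sum(axis=0))
        se = np.sqrt((re ** 2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (rf.T @ re) / np.outer(sf, se)
        rho[np.abs(rho) > 1] = np.sign(rho[np.abs(rho) > 1])  # fp round-off
        pv = _t_approx_pvalue(rho, n_pops)
        const = (sf == 0)[:, None] | (se == 0)[None, :]
        rho = np.where(const, np.nan, rho)
        pv = np.where(const, np.nan, pv)
    else:
        rho = np.full((n_snps, n_envs), np.nan)
        pv = np.full((n_snps, n_envs), np.nan)
        for j in range(n_envs):
            e = E[:, j]
            for i in range(n_snps):
                f = F[:, i]
                ok = ~np.isnan(f) & ~np.isnan(e)
                if ok.sum() < 3:
                    continue
                rho[i, j], pv[i, j] = _spearman_pair(f[ok], e[ok])
    idx = pd.Index(freqs.snp_ids, name="snp_id")
    cols = pd.Index(envs.variables, name="environment")
    return AssociationMatrix(
        pd.DataFrame(rho, index=idx, columns=cols),
        pd.DataFrame(pv, index=idx, columns=cols),
        corrected=corrected,
    )


def bonferroni_threshold(n_snps: int, n_envs: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / (n_snps * n_envs) over all tests."""
    if n_snps < 1 or n_envs < 1:
        raise ValueError("n_snps and n_envs must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / (n_snps * n_envs)


def estimate_pop_covariance(neutral_freqs: FreqMatrix,
                            regularization: float = 1e-6) -> PopCovariance:
    """Population covariance of standardized frequencies from neutral SNPs.

    Each SNP is centered by its across-population mean and scaled by
    sqrt(pbar (1 - pbar)); the covariance across SNPs is then regularized
    with a ridge ``regularization * trace / n_pops`` to guarantee positive
    definiteness.
    """
    F = neutral_freqs.freq.to_numpy(dtype=float)
    if F.shape[0] < 2:
        raise ValueError("need >= 2 populations")
    pbar = np.nanmean(F, axis=0)
    poly = (pbar > 0) & (pbar < 1)
    if not poly.any():
        raise ValueError("all neutral SNPs are monomorphic")
    F = F[:, poly]
    pbar = pbar[poly]
    S = (F - pbar) / np.sqrt(pbar * (1 - pbar))
    S = np.where(np.isnan(S), 0.0, S)
    cov = (S @ S.T) / S.shape[1]
    ridge = regularization * np.trace(cov) / cov.shape[0]
    cov = cov + ridge * np.eye(cov.shape[0])
    idx = pd.Index(neutral_freqs.pop_ids, name="pop_id")
    return PopCovariance(pd.DataFrame(cov, index=idx, columns=idx),
                         n_snps=int(poly.sum()))


def whiten_frequencies(freqs: FreqMatrix, cov: PopCovariance) -> pd.DataFrame:
    """Decorrelate populations: L^-1 (f - fbar) per SNP, cov = L L^T.

    For SNPs drawn under the estimated covariance the output has
    near-identity population covariance, so ordinary linear-model statistics
    on it are free of shared-history confounding.
    """
    F = freqs.freq.to_numpy(dtype=float)
    if cov.matrix.shape[0] != F.shape[0]:
        raise ValueError("covariance dimension does not match populations")
    L = cov.cholesky()
    centered = F - np.nanmean(F, axis=0)
    centered = np.where(np.isnan(centered), 0.0, centered)
    W = linalg.solve_triangular(L, centered, lower=True)
    return pd.DataFrame(W, index=freqs.freq.index, columns=freqs.freq.columns)


def _prepare_env(env: np.ndarray) -> np.ndarray:
    sd = env.std()
    if sd == 0:
        raise ValueError("environment is constant")
    return (env - env.mean()) / sd


def approx_log10_bf(whitened_freq: np.ndarray, env: np.ndarray,
                    prior_scale: float = 1.0) -> float:
    """Closed-form log10 Bayes factor for a linear frequency-environment
    relationship on whitened frequencies.

    Model: y ~ N(b x, s^2 I) with x the standardized environment, null
    b = 0, slope prior b ~ N(0, (prior_scale * s)^2) where s^2 is the null
    variance estimate mean(y^2). The marginal likelihood ratio is exact
    under this prior (matrix determinant lemma), deterministic, and
    invariant to affine rescaling of the environment.
    """
    y = np.asarray(whitened_freq, dtype=float)
    x = np.asarray(env, dtype=float)
    if y.shape != x.shape:
        raise ValueError("env length must match frequency vector length")
    n = len(y)
    if n < 3:
        raise ValueError("need >= 3 populations")
    x = _prepare_env(x)
    y = y - y.mean()
    s2 = float(np.mean(y ** 2))
    if s2 == 0:
        return 0.0
    q = prior_scale ** 2
    xx = float(x @ x)          # = n for a standardized environment
    xy = float(x @ y)
    log_bf = -0.5 * math.log1p(q * xx) + (q * xy ** 2) / (2 * s2 * (1 + q * xx))
    return log_bf / math.log(10)


def log10_bf_matrix(whitened: pd.DataFrame, envs: EnvMatrix,
                    prior_scale: float = 1.0) -> pd.DataFrame:
    """Vectorized ``approx_log10_bf`` over all SNP/environment pairs."""
    Y = whitened.to_numpy(dtype=float)          # pops x snps
    Y = Y - Y.mean(axis=0)
    s2 = np.mean(Y ** 2, axis=0)                # per SNP
    E = envs.values.loc[list(whitened.index)].to_numpy(dtype=float)
    E = (E - E.mean(axis=0)) / E.std(axis=0)
    n = Y.shape[0]
    q = prior_scale ** 2
    xy = Y.T @ E                                 # snps x envs
    with np.errstate(invalid="ignore", divide="ignore"):
        log_bf = (-0.5 * np.log1p(q * n)
                  + (q * xy ** 2) / (2 * s2[:, None] * (1 + q * n)))
    log_bf = np.where(s2[:, None] == 0, 0.0, log_bf) / np.log(10)
    return pd.DataFrame(log_bf, index=whitened.columns,
                        columns=envs.variables)


def read_bayes_factors(paths) -> pd.DataFrame:
    """Load externally computed Bayes factors (one TSV per replicate chain,
    SNPs x environments of log10 BF) and average across chains."""
    if isinstance(paths, (str, bytes)) or not hasattr(paths, "__iter__"):
        paths = [paths]
    frames = [pd.read_csv(p, sep="\t", index_col=0) for p in paths]
    out = frames[0].copy()
    for f in frames[1:]:
        out = out + f.loc[out.index, out.columns]
    return out / len(frames)


def write_association_matrix(assoc: AssociationMatrix, prefix) -> None:
    """Write rho/P(/BF) as TSVs with SNPs as rows and environments as columns."""
    assoc.rho.to_csv(f"{prefix}rho.tsv", sep="\t")
    assoc.pvalue.to_csv(f"{prefix}pvalue.tsv", sep="\t")
    if assoc.log10_bf is not None:
        assoc.log10_bf.to_csv(f"{prefix}log10_bf.tsv", sep="\t")
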