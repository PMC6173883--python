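"""Genotype, population and environment input handling.

Genotypes are stored as derived-allele dosage codes: for diploids 0/1/2
copies of the derived allele, for haploids 0/1. Ancestral state comes from
an outgroup comparison (the ``AA`` INFO tag in a VCF); SNPs whose ancestral
state is unknown keep the reference polarity and are flagged
``derived_known=False`` so downstream views that depend on polarity (galaxy
biplots) can drop them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "SnpTable",
    "PopulationFrame",
    "EnvMatrix",
    "FreqMatrix",
    "filter_snps",
    "population_frequencies",
    "read_vcf",
    "read_genotype_tsv",
    "read_population_table",
    "read_env_matrix",
    "write_freq_matrix",
    "read_freq_matrix",
]


@dataclass
class SnpTable:
    """Individual-level SNP genotypes with per-SNP annotation.

    Parameters
    ----------
    snp_ids, contig_ids, positions, derived_known
        Per-SNP annotation. ``contig_ids`` maps each SNP to the gene/contig
        it is annotated to; ``derived_known`` marks SNPs whose ancestral
        state could be determined.
    genotypes
        ``(n_individuals, n_snps)`` integer array of derived-allele counts,
        ``MISSING`` (-1) for no-calls.
    individual_ids
        Row labels for ``genotypes``.
    pop_of_individual
        Maps each individual id to exactly one population id.
    ploidy
        2 for diploid 0/1/2 coding, 1 for haploid 0/1 coding.
    """

    snp_ids: np.ndarray
    contig_ids: np.ndarray
    positions: np.ndarray
    derived_known: np.ndarray
    genotypes: np.ndarray
    individual_ids: list
    pop_of_individual: dict
    ploidy: int = 2

    def __post_init__(self):
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.contig_ids = np.asarray(self.contig_ids, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.derived_known = np.asarray(self.derived_known, dtype=bool)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        n_ind, n_snp = self.genotypes.shape
        if len(self.individual_ids) != n_ind:
            raise ValueError("individual_ids length does not match genotype rows")
        for arr, name in (
            (self.snp_ids, "snp_ids"),
            (self.contig_ids, "contig_ids"),
            (self.positions, "positions"),
            (self.derived_known, "derived_known"),
        ):
            if len(arr) != n_snp:
                raise ValueError(f"{name} length does not match genotype columns")
        if len(set(self.snp_ids)) != n_snp:
            raise ValueError("snp_ids must be unique")
        if np.any(self.positions < 0):
            raise ValueError("positions must be >= 0")
        valid = set(range(self.ploidy + 1)) | {MISSING}
        if not set(np.unique(self.genotypes)).issubset(valid):
            raise ValueError(
                f"genotype codes must be in 0..{self.ploidy} or {MISSING} (missing)"
            )
        missing_pop = [i for i in self.individual_ids if i not in self.pop_of_individual]
        if missing_pop:
            raise ValueError(f"individuals without a population: {missing_pop[:5]}")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def contig_of_snp(self) -> pd.Series:
        return pd.Series(self.contig_ids, index=self.snp_ids)

    def recode(self, snp_indices=None) -> "SnpTable":
        """Swap ancestral/derived polarity (dosage g -> ploidy - g)."""
        idx = np.arange(self.n_snps) if snp_indices is None else np.asarray(snp_indices)
        geno = self.genotypes.copy()
        sub = geno[:, idx]
        obs = sub != MISSING
        sub[obs] = self.ploidy - sub[obs]
        geno[:, idx] = sub
        return SnpTable(
            self.snp_ids, self.contig_ids, self.positions, self.derived_known,
            geno, self.individual_ids, self.pop_of_individual, self.ploidy,
        )

    def subset_snps(self, mask) -> "SnpTable":
        mask = np.asarray(mask)
        return SnpTable(
            self.snp_ids[mask], self.contig_ids[mask], self.positions[mask],
            self.derived_known[mask], self.genotypes[:, mask],
            self.individual_ids, self.pop_of_individual, self.ploidy,
        )


@dataclass
class PopulationFrame:
    """Sampling locations: id, coordinates and sample size."""

    table: pd.DataFrame  # index pop_id; columns latitude, longitude, elevation, n_individuals

    def __post_init__(self):
        required = {"latitude", "longitude", "elevation", "n_individuals"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"population table missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise ValueError("pop_id must be unique")
        if (self.table["n_individuals"] < 1).any():
            raise ValueError("n_individuals must be >= 1")

    @property
    def pop_ids(self) -> list:
        return list(self.table.index)

    def validate_against(self, snps: SnpTable) -> None:
        """Check n_individuals equals the count of mapped individuals."""
        counts = pd.Series(list(snps.pop_of_individual.values())).value_counts()
        for pop in self.pop_ids:
            n = int(counts.get(pop, 0))
            if n != int(self.table.loc[pop, "n_individuals"]):
                raise ValueError(
                    f"population {pop}: table says {self.table.loc[pop, 'n_individuals']}"
                    f" individuals but {n} are mapped"
                )


@dataclass
class EnvMatrix:
    """Population x environmental-variable matrix with category tags.

    Categories follow the empirical study's grouping of climate and
    geography variables (e.g. Aridity, Freezing, Geography); untagged
    variables default to "other".
    """

    values: pd.DataFrame  # index pop_id, columns variable names
    categories: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("environment matrix contains missing cells")
        self.categories = {
            v: self.categories.get(v, "other") for v in self.values.columns
        }

    @property
    def variables(self) -> list:
        return list(self.values.columns)

    @property
    def pop_ids(self) -> list:
        return list(self.values.index)


@dataclass
class FreqMatrix:
    """Per-population derived-allele frequencies plus genotyped counts.

    ``freq`` holds f = (derived allele count) / (ploidy x genotyped
    individuals) per (population, SNP) cell, NaN where no individual was
    genotyped; ``n_genotyped`` the per-cell diploid (or haploid) counts.
    """

    freq: pd.DataFrame  # index pop_id, columns snp_id
    n_genotyped: pd.DataFrame

    def __post_init__(self):
        vals = self.freq.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
        if not ok.all():
            raise ValueError("frequencies must lie in [0, 1]")
        if self.freq.shape != self.n_genotyped.shape:
            raise ValueError("freq and n_genotyped shapes differ")

    @property
    def pop_ids(self) -> list:
        return list(self.freq.index)

    @property
    def snp_ids(self) -> list:
        return list(self.freq.columns)


def _maf_and_callrate(snps: SnpTable):
    geno = snps.genotypes
    obs = geno != MISSING
    n_obs = obs.sum(axis=0)
    derived = np.where(obs, geno, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = derived / (snps.ploidy * n_obs)
    maf = np.minimum(f, 1.0 - f)
    callrate = n_obs / snps.n_individuals
    return maf, callrate, n_obs


def filter_snps(snps: SnpTable, maf_min: float = 0.05,
                callrate_min: float = 0.10) -> SnpTable:
    """Apply the study's SNP quality filters.

    Keeps SNPs with pooled minor allele frequency strictly greater than
    ``maf_min`` and genotyping rate strictly greater than ``callrate_min``;
    SNP order is preserved. MAF is computed across all genotyped
    individuals pooled.
    """
    if snps.n_snps == 0:
        raise ValueError("empty SNP table")
    for name, t in (("maf_min", maf_min), ("callrate_min", callrate_min)):
        if not 0 <= t <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    maf, callrate, n_obs = _maf_and_callrate(snps)
    keep = (n_obs > 0) & (maf > maf_min) & (callrate > callrate_min)
    return snps.subset_snps(keep)


def population_frequencies(snps: SnpTable, pops: PopulationFrame) -> FreqMatrix:
    """Derived-allele frequency per population.

    Missing genotypes are excluded from both the numerator and the
    denominator; a (population, SNP) cell with zero genotyped individuals
    is NaN.
    """
    pop_ids = pops.pop_ids
    known = set(pop_ids)
    for ind in snps.individual_ids:
        p = snps.pop_of_individual[ind]
        if p not in known:
            raise ValueError(f"individual {ind} maps to unknown population {p}")
    geno = snps.genotypes
    obs = geno != MISSING
    freq = np.full((len(pop_ids), snps.n_snps), np.nan)
    counts = np.zeros((len(pop_ids), snps.n_snps), dtype=np.int64)
    ind_pop = np.asarray([snps.pop_of_individual[i] for i in snps.individual_ids],
                         dtype=object)
    for pi, pop in enumerate(pop_ids):
        rows = ind_pop == pop
        n_obs = obs[rows].sum(axis=0)
        derived = np.where(obs[rows], geno[rows], 0).sum(axis=0)
        counts[pi] = n_obs
        nz = n_obs > 0
        freq[pi, nz] = derived[nz] / (snps.ploidy * n_obs[nz])
    idx = pd.Index(pop_ids, name="pop_id")
    cols = pd.Index(snps.snp_ids, name="snp_id")
    return FreqMatrix(pd.DataFrame(freq, index=idx, columns=cols),
                      pd.DataFrame(counts, index=idx, columns=cols))


# ---------------------------------------------------------------------------
# readers / writers

def read_vcf(path, pop_of_individual: dict, ancestral_tag: str = "AA") -> SnpTable:
    """Read biallelic SNPs from a VCF into derived-allele dosage codes.

    If the ``AA`` INFO tag matches REF the ALT dosage is already the derived
    dosage; if it matches ALT the dosage is flipped; otherwise the SNP keeps
    reference polarity with ``derived_known=False``. Multi-allelic records
    are skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    snp_ids, contigs, positions, known, rows = [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        # gts012: 0/1/2 = ALT dosage, 3 = unknown
        dosage = np.asarray(var.gt_types, dtype=np.int16)
        dosage[dosage == 3] = MISSING
        aa = var.INFO.get(ancestral_tag)
        if aa is not None:
            aa = str(aa).upper()
        if aa == var.REF.upper():
            derived_known = True
        elif aa == var.ALT[0].upper():
            derived_known = True
            obs = dosage != MISSING
            dosage[obs] = 2 - dosage[obs]
        else:
            derived_known = False
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        snp_ids.append(vid)
        contigs.append(var.CHROM)
        positions.append(var.POS)
        known.append(derived_known)
        rows.append(dosage)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic records")
    if not rows:
        raise ValueError("no biallelic SNPs in VCF")
    return SnpTable(
        snp_ids, contigs, positions, known,
        np.stack(rows, axis=1), individuals, pop_of_individual,
    )


def read_genotype_tsv(path, pop_of_individual: dict, annotation=None,
                      ploidy: int = 2) -> SnpTable:
    """Read a TSV genotype matrix (rows = individuals, columns = SNPs).

    ``annotation`` is an optional TSV/DataFrame with columns ``snp_id``,
    ``contig_id``, ``position`` and optionally ``derived_known``. Without
    it, the contig defaults to the SNP id up to the last underscore.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    geno = df.fillna(MISSING).to_numpy()
    snp_ids = list(df.columns)
    if annotation is not None:
        ann = annotation if isinstance(annotation, pd.DataFrame) else pd.read_csv(
            annotation, sep="\t")
        ann = ann.set_index("snp_id").loc[snp_ids]
        contigs = list(ann["contig_id"])
        positions = list(ann["position"])
        known = list(ann.get("derived_known", pd.Series(True, index=ann.index)))
    else:
        contigs = [s.rsplit("_", 1)[0] if "_" in s else s for s in snp_ids]
        positions = [0] * len(snp_ids)
        known = [True] * len(snp_ids)
    return SnpTable(snp_ids, contigs, positions, known, geno,
                    list(df.index), pop_of_individual, ploidy)


def read_population_table(path) -> tuple[PopulationFrame, dict]:
    """Read a population TSV; returns the frame and, if an ``individuals``
    column (comma-separated ids) is present, the individual->population map."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    pop_of_individual = {}
    if "individuals" in df.columns:
        for pop, cell in df["individuals"].items():
            for ind in str(cell).split(","):
                pop_of_individual[ind.strip()] = pop
        df = df.drop(columns=["individuals"])
    return PopulationFrame(df), pop_of_individual


def read_env_matrix(path, categories=None) -> EnvMatrix:
    """Read a population x environment TSV; ``categories`` may be a YAML
    path or a dict mapping variable -> category."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    cats = {}
    if categories is not None:
        if isinstance(categories, dict):
            cats = categories
        else:
            import yaml

            with open(categories) as fh:
                cats = yaml.safe_load(fh)
    return EnvMatrix(df, cats)


def write_freq_matrix(freqs: FreqMatrix, path) -> None:
    freqs.freq.to_csv(path, sep="\t")


def read_freq_matrix(path, counts_path=None) -> FreqMatrix:
    freq = pd.read_csv(path, sep="\t", index_col=0)
    if counts_path is not None:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    else:
        counts = pd.DataFrame(np.where(freq.isna(), 0, 1),
                              index=freq.index, columns=freq.columns)
    return FreqMatrix(freq, counts)
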