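# Methods

`coassoc` implements a co-association network framework for interpreting
multivariate genotype–environment association (GEA) signals, together with
the forward-time landscape simulator used to validate its candidate-SNP
criteria. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data do and do not emulate.

## Association layers

For each SNP, the per-population derived-allele frequency
f = (derived count) / (ploidy × genotyped individuals) is associated with
each environmental variable in two ways.

**Uncorrected layer.** Spearman's ρ between f and the variable across
populations, with a two-sided P value. P values use the t approximation
t = ρ√((n−2)/(1−ρ²)) for n ≥ 10 populations and an exact rank-permutation
distribution below that (all n! permutations; ties get average ranks).
Pairs with fewer than three complete populations, or a constant frequency
or variable, are reported missing rather than propagating NaNs.

**Structure-corrected layer.** Shared demographic history makes population
frequencies covary, which inflates uncorrected associations. We estimate
the population covariance Ω from putatively neutral SNPs: each SNP is
centered by its across-population mean p̄ and scaled by √(p̄(1−p̄)), and Ω
is the covariance of these standardized frequencies across SNPs, plus a
ridge `regularization × trace/n` (default regularization 10⁻⁶) to keep it
positive definite. Frequencies are then whitened, W = L⁻¹(f − f̄) with
Ω = LLᵀ, and a conjugate normal linear model on W yields a Bayes factor
for a linear frequency–environment relationship:

y ~ N(bx, s²I) with x the standardized variable, s² = mean(y²) the null
variance estimate, and slope prior b ~ N(0, (c·s)²) with prior scale c = 1
by default. The marginal-likelihood ratio has the closed form

log BF = −½ log(1 + c²n) + c²(xᵀy)² / (2 s²(1 + c²n)),

which is deterministic and invariant to affine rescaling of the
environment. This replaces the MCMC-based Bayes factor of the original
analysis stack; the two are not numerically interchangeable, and externally
computed Bayes factors (replicate chains averaged) can be loaded from TSV
instead. Because the whitening uses a per-SNP centering step, the whitened
covariance of neutral data converges to the centering-projected identity,
not the identity itself; the distortion is O(1/n populations).

## Candidate detection

A SNP is an *outlier* for a variable when its |ρ| strictly exceeds the
per-variable genome-wide empirical quantile (default 0.99; the original
outlier definition combines several association tests that are not
restated here, so the quantile is a configurable stand-in). A *top
candidate gene* is a contig whose outlier count k among its n SNPs has
binomial tail P(X ≥ k | n, p̄) below 10⁻⁹, where p̄ is the genome-wide
outlier fraction; SNPs flagged in any variable count once. Because SNPs
within a contig are linked, this P is an enrichment index, not a calibrated
probability, and is labelled as such. A *top candidate SNP* lies in a top
candidate gene and, for at least one variable, has (i) uncorrected P below
the Bonferroni threshold α/(SNPs × variables) and (ii) structure-corrected
log₁₀ BF > 2.

## Co-association networks

Each candidate SNP is represented by its vector of associations across all
variables (signed ρ by default; |ρ| is used for heatmap ordering). Pairwise
Euclidean distances between these profiles feed (a) Ward hierarchical
clustering (Ward.D2 criterion, as `scipy.cluster.hierarchy.linkage`
implements for Euclidean input) cut into k groups — k = 4 by default and
explicitly a visualization choice — and (b) a threshold graph joining SNP
pairs with distance strictly below 0.1. Connected components of that graph
are the co-association modules, read as sets of loci responding to one
distinct environmental factor. `threshold_stability` reports how the
module count reacts to halving or raising the threshold by 0.05, since the
0.1 default is an empirical convention, not a derived constant. The graph
is built globally; groups are used for rendering, so group membership and
module membership are independent labels.

Per-gene module proportions (the pleiotropy table) quantify *environmental
pleiotropy*: a contig whose SNPs fall in several modules is associated with
several distinct aspects of the multivariate environment.

## Galaxy biplots and prediction ellipses

A galaxy biplot places each SNP at (ρ with variable 1, ρ with variable 2).
With alleles coded against the ancestral state the point shows the
bivariate environment in which the derived allele is at elevated frequency;
recoding reflects the point through the origin, so SNPs with unknown
ancestral state are excluded from this view. The genome-wide null backdrop
is the (1−α) prediction ellipse of the fitted bivariate normal: center at
the sample means, semi-axes l_j = √(λ_j q) from the eigenvalues λ_j of the
2×2 sample covariance (n−1 denominator) and the χ²(df = 2) quantile q at
probability 1−α (α = 0.05 → q = 5.991, and for df 2 the closed form
q = −2 ln α). Orientation is the leading eigenvector's angle, normalized to
(−π/2, π/2]. A point is inside when its covariance quadratic form is ≤ q.
The ellipse is a meaningful null only for many unlinked SNPs; a runtime
warning fires below 200 points.

## Linkage disequilibrium

r² is the squared Pearson correlation of genotype dosage codes across
individuals with complete data at both SNPs (genotype-code LD; phased
haplotypes are not assumed). Gene-pair means aggregate r² over all SNP
pairs of two contigs after excluding SNPs genotyped in fewer than 250
individuals (configurable; synthetic panels are smaller); within-gene means
exclude self-pairs. Even unlinked loci have E[r²] ≈ 1/(n−1) from sampling,
which the module-level summaries inherit.

## Landscape simulator

Independent haploid SNPs evolve on a grid of demes by the recurrence
migration → selection → drift:

* **Migration.** A Gaussian dispersal kernel (σ in deme units, truncated at
  3σ, separable in x and y, renormalized over occupied demes) averages
  neighbour frequencies. Boundaries reflect by default; a torus is
  available and used for calibration runs.
* **Selection.** Haploid viability selection against a fixed surface:
  p′ = p(1+s_d)/(p(1+s_d)+(1−p)) with s_d = s × surface(deme). The surface
  mixes a north–south cline (weight 0.3 by default, i.e. a weak cline) with
  a Gaussian-smoothed white-noise field (autocorrelation length 5 demes),
  min–max rescaled to [−1, 1]. Selected loci draw s from the classes
  {0.001, 0.005, 0.01, 0.05, 0.1} and make up ~1% of loci by default.
* **Drift.** p″ = Binomial(K, p′)/K with carrying capacity K haploids per
  deme; K = None switches drift off for exact deterministic tests.

Demographies: IBD (whole grid occupied), 1R (expansion from a mid-south
refugium), 2R (expansion from the SW and SE corners). The colonization
front advances one ring of demes per generation; new demes are founded from
the kernel-weighted frequencies of adjacent occupied demes. Each refugium
founds the expansion with independently drawn initial frequencies
(uniform on [0.1, 0.9] per locus), standing in for drift during glacial
isolation — with two refugia this seeds the secondary-contact structure
that widens the per-locus F_ST distribution, giving the characteristic
ordering Var(F_ST): 2R > 1R > IBD at matched mean F_ST.

F_ST is the unweighted variance ratio Var_demes(p)/(p̄(1−p̄)) per locus
(equal K per deme makes sample-size weighting unnecessary); globally
monomorphic loci are excluded from the mean. `calibrate_capacity` bisects
over K on a log scale (common random numbers across evaluations, three
replicate seeds per evaluation by default) until the mean neutral F_ST hits
a target, 0.05 by default, mirroring the original design in which each
demography was calibrated to the same mean neutral differentiation.

**Problem sizes.** Defaults are desk scale: 32 × 32 demes, hundreds to a
thousand loci, 200 generations for IBD and 150 for expansions, with 250
sampled demes as "populations". Mean F_ST on this grid is flat from about
generation 100 onward, so the 200-generation IBD run is at
quasi-equilibrium; the shorter expansion runs deliberately retain
non-equilibrium founder structure. `SimulationConfig.full_scale()` restores
the study-scale 360 × 360 grid with 10,000 (IBD) or 1,000 (expansion)
generations. The default K = 25 is the desk-scale IBD value calibrated to
F_ST ≈ 0.05; per-scenario recalibration is one function call.

## Synthetic environments

The generator emulates the structure of a real climate dataset: 22
observed variables with strong within-category correlations (a pine-like
default correlation matrix built from a three-factor model — aridity,
freezing, geography — and therefore positive semi-definite by
construction), plus one *hidden* selective variable whose absolute
correlation with every observed variable lies in [0, 0.2]. Target
correlations for the hidden variable are drawn uniformly from the band
with random signs, and the observed variables are assembled as
X_j = r_j h + √(1−r_j²) B_j with B_j residual factors made exactly
sample-uncorrelated with h, so the band holds in-sample by construction,
not merely in expectation.

When sampling coordinates are supplied (the overlay path used with the
simulator), the residual factors are spatially autocorrelated Gaussian
fields (squared-exponential correlation, length scale a quarter of the
landscape extent, nugget 0.1) rather than white noise. This matters: with
white-noise environments a clinal selected locus can never reach
Bonferroni-level significance against variables correlated at most 0.2
with the true driver, and spurious spatial associations of neutral loci
vanish too, making validation trivially empty. Spatially smooth variables
reproduce both phenomena — neutral false positives under the relaxed
(Bonferroni-only) criterion and detectable true positives — which is the
regime the co-association framework is meant to operate in.

What the synthetic data do *not* emulate: linked loci (all simulated SNPs
are unlinked, so LD module summaries on simulated data reflect sampling
noise only), diploid dominance, missing genotypes, ascertainment of SNP
panels, and real climate gradients (the overlay fields are stationary
random fields, not climate rasters). Passing validation here shows the
criteria behave correctly under the stated model, not that they are robust
to these additional features of real data.

## Evaluation of the criteria

`apply_candidate_criteria` scores loci against simulation truth. The
strict dual mode requires, in the same environment, an uncorrected P below
the Bonferroni cutoff AND whitened log₁₀ BF > 2; the relaxed mode —
operationalizing the original study's "less stringent" simulation analysis
— drops the BF requirement, which deliberately admits neutral false
positives whose network behaviour is the object of study. The edge
threshold for simulated networks is chosen by a sweep (0.02–0.5, step
0.02) maximizing mean degree(selected) − mean degree(neutral), the same
enrichment logic the original analysis describes. The PCA comparator runs
principal components on standardized variables and flags SNPs on an axis
by whitened BF > 2 (or Bonferroni P without a BF layer); per-group "missed
fractions" count candidate SNPs not flagged on any of the first 10 axes.

## Numerical and degenerate-input conventions

Strict inequalities follow the source conventions throughout: MAF > 5%,
call rate > 10%, edge distance < 0.1, quantile exceedance, BF > 2.
Frequencies use NaN for no-data cells. Ward clustering on a permuted
distance matrix yields the same partition up to relabeling. Binomial tail
probabilities come from `scipy.stats.binom.sf`. Constant environments,
singular covariances, non-PSD correlation targets, empty SNP tables, and
misaligned truth tables raise errors rather than returning silent NaNs.
The Spearman fast path (no missing data, n ≥ 10) computes ranks once and
uses matrix products; results match the per-pair path to floating-point
round-off.
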