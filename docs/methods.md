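# Methods

`mitoconcord` re-implements, as a tested pipeline, the statistical workflow
used to detect mitonuclear coadaptation in a hybrid zone between two bird
lineages: a coastal population ("parental A", mtDNA clade 0) and an inland
population ("parental B", clade 1) that hybridized along a broad front,
leaving admixed demes polymorphic for both mtDNA clades. The question the
workflow answers is whether a nuclear candidate block co-varies with mtDNA
clade more than neutral admixture would allow.

## Statistical components

**Variant filtering.** Genotypes with GQ ≤ 20 are masked first, so masked
calls count toward site missingness; sites are then removed if they are
indels, not biallelic, > 30% missing, or have minor allele frequency below
0.05 (the boundary is inclusive: MAF = 0.05 survives). Masking-then-filter
is the only order in which the genotype-quality rule can influence the
missingness rule; the alternative reading (site-mean GQ) is not used.

**Differentiation.** Per-site Weir & Cockerham (1984) variance components
(a, b, c) for the two-population diploid biallelic case, with the weighted
estimate Σa/Σ(a+b+c) over any site subset. Negative per-site ratios are
reported as computed (VCFtools semantics). Sites with fewer than two
genotyped individuals in either population are undefined (NaN), as is the
ratio at monomorphic sites.

**Diversity.** Windowed nucleotide diversity uses the ratio-of-sums
estimator on all-sites data: per site, differences = 2·n_ref·n_alt and
comparisons = n(n−1) over genotyped alleles; a window's π is total
differences over total comparisons, so invariant and partially missing
sites contribute correctly to the denominator. Windows are anchored at
position 1 ([1,1000], [1001,2000], ...). Variant-only input is rejected
because the estimator is upward-biased without invariant sites.

**LD.** Genotype r² is the squared Pearson correlation of dosage vectors
with pairwise-complete deletion; pairs monomorphic after deletion are
skipped.

**Ancestry.** A marker panel is the set of SNPs with parental F_ST strictly
above a threshold (0.6 default, 0.3 as robustness panel). Polarity comes
from parental allele frequencies, not ref/alt labels, so ancestry
semantics survive allele relabeling. Per-individual ancestry is the mean
0/0.5/1 score over non-missing panel loci and interspecific heterozygosity
the fraction of heterozygous panel loci; with complete data the triangle
constraint het ≤ 2·min(a, 1−a) holds exactly. Candidate-block ancestry θ
averages the scores of panel loci inside the block interval; mitonuclear
ancestry is the unweighted mean of the mtDNA clade score and θ.

**Association scan.** The mtDNA clade score (0/1) is tested against each
SNP after regressing the top k eigenvectors (default k = 3) of the
identity-by-state kinship matrix out of both phenotype and dosages;
the statistic is n_eff·r² with n_eff = n − k − 1, referred to χ²₁.
Genomic control then sets λ = median(χ²)/0.4549 and divides the statistics
by λ; significance uses p < 10⁻⁶. The n − k − 1 convention and k = 3 were
validated by the null-calibration battery (neutral simulations give
3–7% of corrected p < 0.05 and essentially no genome-wide hits); larger k
removes more structure but lets strongly differentiated neutral loci reach
genome-wide significance under selection, so k = 3 is the default.

**Sweep contrast.** Percentile bootstrap (default 10,000 iterations) of the
mean of per-window π (resampling unit: 1-kb windows, respecting
within-window dependence) or per-pair r² (unit: site pairs), comparing the
candidate block against its flanking super-region (or rest of chromosome
for π). Windows join the block by midpoint; LD pairs must have both ends
on one side — straddling pairs are excluded. The disjoint-CI flag records
direction (depletion/elevation).

**Genomic cline.** θ(h) = h + 2(h − h²)(α + β(2h − 1)); α shifts the cline
center (biased introgression), β steepens it (divergent selection), and
θ(0) = 0, θ(1) = 1 for any parameters. The printed form of this function
in the source literature admits a parenthesization under which θ ≠ h at
α = β = 0, contradicting the stated neutral expectation; the standard
quadratic-cline reading used here restores θ = h. The model is linear in
(α, β) given h, so the damped Gauss–Newton fit (start (0,0)) agrees with
the closed-form weighted regression to numerical precision; both are
exposed and cross-checked. For iid errors the CIs use the exact t(n−2)
reference (the model is linear, so this is the exact small-sample
distribution under Gaussian noise); an optional cluster-robust sandwich
covariance keyed by sampling site is provided and used by the pipeline,
because a fully linked block drifts as a single locus and leaves
within-deme correlated residuals that iid intervals understate. Weights
default to 1 (the source describes weighted least squares without stating
weights); binomial-variance weights are available.

**Hybrid index.** `hybrid_index_from_axis` implements the min–max transform
of the first genotype-PCA eigenvector. In the simulation pipeline the
index is instead the panel ancestry over markers *outside* the candidate
block: min–max EV1 anchors on the most extreme individuals, and at
desk-scale drift admixed individuals overshoot the parental EV1 range,
pushing parentals to interior h with extreme θ and biasing β upward even
under neutrality; excluding the block also keeps the index independent of
the θ it is regressed on.

**Spatial tests.** Great-circle (haversine, R = 6371 km) site distances;
Mantel tests correlate vectorized upper triangles with simultaneous
row/column permutation of the first matrix and one-sided
p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1) (exhaustive enumeration available
for small n); the partial test correlates residuals of A~C and B~C. A
matrix fully explained by the control yields r = 0 by construction.
Climate PCA standardizes variables and decomposes the correlation matrix.
Group differences use tie-corrected Kruskal–Wallis plus pairwise Wilcoxon
rank-sum tests (exact for small tie-free samples) with Benjamini–Hochberg
adjustment across the pairwise family.

**mtDNA.** Haplotype distances are Hamming counts ignoring N/gap columns.
The minimum spanning network collapses identical sequences and applies
Kruskal's algorithm with deterministic (weight, lexicographic) edge order.
Clades are the two components left after removing the unique
maximum-weight tree edge; a tie for that edge raises rather than choosing
silently, and polarity follows a designated reference sample. Fixed
differences are sites with disjoint observed allele sets between groups;
d_xy averages pairwise mismatch fractions over comparable sites. Amino
acid comparison translates each group's majority consensus (ties → N,
codon skipped) with the vertebrate mitochondrial code (table 2: TGA→W,
AGA/AGG→stop, ATA→M), reporting fixed substitutions as e.g. N150D.

**Wright–Fisher arithmetic.** Ne from mitochondrial diversity supports two
conventions, π/μ (default) and π/(4μ). The default reproduces the
headline arithmetic this workflow is known for — π = 0.0015 and
μ = 4.42×10⁻⁹ give Ne ≈ 3.4×10⁵, and the diffusion mean absorption time
T(p) = −4Ne(p ln p + (1−p) ln(1−p)) at p = 0.5 gives ≈ 9.4×10⁵
generations — whereas π/(4μ) gives 8.5×10⁴; both are exposed because the
two conventions are genuinely in tension in the source material. A
forward binomial simulator (2N allele copies, resampled each generation)
serves as the independent Monte-Carlo check of the diffusion formula.

## The synthetic-data generator

The generator emulates the study scenario, not any particular dataset:

- **Genome.** 2,000 unlinked background loci on chr1–chr5 with parental
  frequencies drawn by Balding–Nichols sampling around a shared ancestral
  frequency (q ~ U(0.1, 0.9)) with F = 0.02, so realized weighted
  background F_ST ≈ 0.02; 25 island loci plus a 15-SNP candidate block
  near-fixed for alternative alleles (0.01/0.99). chr5 is desk-scaled to
  300 kb with the block at 100,001–160,000 and flanking super-region
  50,001–250,000; background loci are kept out of the block interval
  because they are unlinked and would otherwise plant unswept variation
  inside a region modeled as one haplotype. Invariant chr5 sites (5 per
  kb) are appended for all-sites diversity estimation.
- **Demography.** 60 individuals per parental population over six sites
  each; seven admixed demes of 50 along the contact front, founded as
  parental mixtures and evolved for 25 non-overlapping Wright–Fisher
  generations with migration (5% per generation, drawn at the founding
  mixture proportions) and maternal mtDNA transmission. Background loci
  assort independently; the block is transmitted as intact haplotypes.
- **Selection.** Viability (1 − s)^m where m is the dosage of block
  alleles mismatched to the individual's mtDNA clade (s = 0.5 default;
  s = 0 gives the neutral control). Offspring are accepted by rejection
  sampling at constant deme size; total reproductive failure raises an
  explicit extinction error.
- **Space and climate.** Founding parental-A fractions follow a
  climate-suitability axis combining latitude and coastal distance
  (0.3/0.7), so site-level ancestry tracks climate beyond raw geographic
  distance — the contrast the partial Mantel tests probe. Thirteen
  temperature-like variables load mainly on latitude and thirteen
  precipitation-like variables mainly on coastal distance, with
  cross-loadings and 5% relative noise, giving a dominant climate PC1
  aligned with the suitability axis.
- **mtDNA.** Two clade haplotype clusters separated by 8 fixed
  differences over 800 bp (≈ 1% divergence) with a few within-clade
  variants, so the network splits cleanly at its deepest edge.
- **Truth.** Pedigree-tracked individual ancestry, island/block locus
  indices, the block interval and the selection regime are recorded for
  recovery tests.

What the generator does **not** emulate: recombination maps and linked
background selection, coalescent ancestry, sequencing-read error
structure, unequal deme sizes through time, or climate data beyond a
rank-two-plus-noise structure. Passing tests therefore show that the
statistics behave correctly under the assumed admixture-with-selection
model, not that the pipeline is robust to every property of real GBS data.

## Problem sizes and numerical choices

Simulation batteries use 20 replicate seeds; the default cohort is 260
individuals × ~2,040 variant loci (plus 1,500 invariant sites), sizes at
which the full pipeline runs in a few seconds per seed. Bootstrap
contrasts default to 10,000 iterations, Mantel tests to 10,000
permutations (199 in the repeated type-I-error batteries), cline recovery
checks to 200 individuals per replicate. Gauss–Newton iterations are
damped by step-halving with a 200-iteration cap (the linear model
converges in one step). Per-stage seeds derive from the master seed by
fixed offsets, keeping every randomized stage independently reproducible.

## Known limitations

- At desk-scale deme sizes, drift of the fully linked block is large, so
  the cline fit's iid CIs are anticalibrated for deme-structured data;
  the cluster-robust option is the supported remedy and the pipeline
  default. Even so, roughly one selected replicate in ten realizes an
  evolutionary outcome whose β CI touches zero — detecting divergent
  selection from a single block is genuinely noisy at these sizes.
- The pooled-admixed π contrast is uninformative in this scenario because
  demes sweep *opposite* block haplotypes (matching their local mtDNA
  majority), which preserves pooled block diversity; the pipeline runs
  the π contrast within the focal deme (the one with the clearest mtDNA
  majority — an observable choice mirroring the per-cluster variant of
  the analysis) and the r² contrast on pooled admixed samples.
- The asymptotic Kruskal–Wallis χ² reference is slightly anticonservative
  below ~15 observations per group; calibration holds from ~n = 20.
- The association scan treats the mtDNA clade as a binary phenotype in a
  linear score test; logistic alternatives are out of scope.
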