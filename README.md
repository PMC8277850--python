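# mitoconcord

Mitonuclear-concordance analysis for hybrid zones, as a tested, reusable
Python pipeline. Given diploid genotypes (VCF), sample metadata, mtDNA
alignments and site-level climate data, it answers the question: *does a
nuclear genomic block co-vary with mitochondrial ancestry more strongly
than neutral admixture allows — i.e., is there selection maintaining
matched mitonuclear combinations?*

The package is aimed at population geneticists working on hybrid zones and
cytonuclear interactions. It covers:

- **Filtering** — GQ masking and indel/biallelic/missingness/MAF site
  filters (`variant_io`).
- **Differentiation and diversity** — per-site and weighted Weir–Cockerham
  F_ST, missing-data-aware windowed π on all-sites data, genotype-r² LD,
  genotype PCA (`popgen`).
- **Admixture diagnostics** — ancestry-informative marker panels
  (F_ST > 0.6 / 0.3), triangle plots (ancestry vs interspecific
  heterozygosity), candidate-block ancestry θ, mitonuclear ancestry,
  hybrid index h (`ancestry`).
- **Association** — mtDNA-clade GWAS with identity-by-state kinship
  eigenvector adjustment and genomic control λ = median(χ²)/0.4549,
  cutoff p < 10⁻⁶ (`mitoassoc`).
- **Sweep signatures** — 10,000-iteration bootstrap contrasts of π and r²
  between a candidate block and its flank, with disjoint-CI calls
  (`sweep`).
- **Genomic clines** — θ(h) = h + 2(h−h²)(α + β(2h−1)); weighted
  least-squares estimation of the cline-center deviation α and steepness β,
  with closed-form cross-check, optional cluster-robust CIs, and
  interpretation (β CI > 0 ⇒ divergent selection; α CI below/above 0 ⇒
  biased introgression) (`cline`).
- **Spatial & climate tests** — haversine distances, Mantel and partial
  Mantel permutation tests, climate PCA, Kruskal–Wallis + pairwise
  Wilcoxon with Benjamini–Hochberg (`spatial`).
- **mtDNA** — minimum spanning haplotype networks, 0/1 clade scoring by
  deepest-edge bipartition, fixed differences and d_xy, amino-acid
  comparison under the vertebrate mitochondrial code, and Wright–Fisher
  lineage-sorting arithmetic with a forward-simulation oracle
  (`mito_genome`).
- **Synthetic data** — a Wright–Fisher admixture generator with divergence
  islands, a fully linked candidate block, maternal mtDNA, viability
  selection against mitonuclear mismatch, and a spatial climate gradient,
  plus ground truth for recovery tests (`simdata`).
- **Orchestration** — a single-config pipeline with per-stage seeds and a
  run manifest (`pipeline`, CLI `mitoconcord`).

See `docs/methods.md` for the statistical details and modeling choices.

## Worked example

Lineage-sorting arithmetic from mitochondrial diversity (π = 0.0015,
μ = 4.42 × 10⁻⁹ per generation):

```sh
$ mitoconcord drift --pi 0.0015 --mu 4.42e-9 --p0 0.5
{
 "ne": 339366.51583710406,
 "t_absorption": 940923.7745157628,
 "t_loss": 940923.7745157628
}
```

Ne = π/μ ≈ 3.4 × 10⁵, and from a 50% starting frequency the expected
Wright–Fisher time to lose (or fix) a haplotype is 4·Ne·ln 2 ≈ 9.4 × 10⁵
generations — far longer than plausible since contact, which is the
argument that mixed mtDNA clades in the hybrid populations reflect
hybridization rather than incomplete lineage sorting.

A full run on a simulated hybrid zone with selection against mitonuclear
mismatch (s = 0.5 per mismatched block allele):

```python
from mitoconcord.pipeline import RunConfig, run_pipeline
from mitoconcord.simdata import SimConfig

res = run_pipeline(RunConfig(sim=SimConfig(s_mismatch=0.5), seed=1))
```

prints (via the summaries in `res`):

```text
weighted parental FST (all filtered SNPs): 0.065
marker panel size (FST>0.6): 40
association: lambda = 3.42, hits at p<1e-6 = 11
pi block mean 0.0012 vs flank 0.0374 -> depletion
r2 block mean 0.966 vs flank 0.007 -> elevation
cline: alpha=-0.033 beta=0.934 CI_beta=(0.721, 1.147) ['divergent selection']
partial Mantel mito r=0.999 p=0.0001; climate r=0.612 p=0.0001
```

Reading the output: parental differentiation is shallow genome-wide but
the 40-marker panel captures the divergence islands; all genome-wide
significant mtDNA-association hits fall in the candidate block; the block
shows the sweep signature (π depleted, r² elevated, disjoint bootstrap
CIs); the genomic cline for block ancestry is significantly steeper than
neutral (β > 0, divergent selection); and site-level mitonuclear ancestry
tracks both the nuclear block and climate PC1 after controlling for
geographic distance. Under `s_mismatch=0` the same pipeline produces a
calibrated null: no association hits and a β CI covering zero.

The same run is available from the shell:

```sh
mitoconcord run --out runs/demo --seed 1
mitoconcord simulate --out data/sim --seed 7
mitoconcord fst --vcf data/sim/variants.vcf --samples data/sim/samples.tsv \
    --pops parentA,parentB --out fst.tsv
```

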