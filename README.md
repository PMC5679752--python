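# molarmap

Genome-wide association of 3D tooth-shape phenotypes in mice, built for
studies that map subtle, polygenic shape variation — for example the first
upper molar of wild-derived house mice — with a sample of related animals
and a dense SNP panel.

The package covers the whole analysis chain:

- **Semi-landmark surface phenotyping.** A template crown surface carrying
  an ordered set of semi-landmarks is warped onto each specimen through a
  thin-plate spline (TPS) anchored at a few manually placed landmarks;
  semi-landmarks slide in their tangent planes to minimise TPS bending
  energy toward the Procrustes consensus; a full generalized Procrustes
  analysis (GPA) yields shape coordinates and centroid size (CS); a PCA
  provides the mapping phenotypes (axes carrying > 1% of variance).
  A *wear-free* template — cusp tips truncated at a fixed height — removes
  tooth-wear variation, the dominant non-heritable signal.
- **Mixed-model association.** Each retained PC (and CS) is scanned against
  every SNP under the linear mixed model
  `y = Wα + xβ + u + ε`, `u ~ N(0, σ²_g K)` with `K = X_c X_cᵀ / p` the
  centered kinship matrix; λ = σ²_g/σ²_e is estimated by REML on the
  eigen-rotated data and each SNP gets a generalized-least-squares Wald
  test.  Genome-wide significance per phenotype comes from permutations of
  the phenotype (10,000 by default, X chromosome separate): the threshold
  is the 5% point of the permuted minimum-p distribution.
- **QTL regions and effect sizes.** Significant SNPs are extended into
  regions by LD (r² > 0.8 in the full, pre-pruning panel), with a 500 kb
  fallback window for isolated SNPs; a region's effect size is the
  fraction of total retained shape variance explained by the best SNP.
- **Shape heritability.** Per-PC mixed-model `pve` values are aggregated
  as `H = Σᵢ wᵢ hᵢ` with weights wᵢ the percentage of total shape variance
  per PC; per-chromosome variance is partitioned by single-chromosome
  REML fits with kinship-eigenvector covariates, and the relative shares
  are correlated with chromosome length.
- **Effect signatures across superimpositions.** Effects measured in
  different Procrustes superimpositions (a SNP in the mapping sample, a
  mutant line, a PC axis) are compared through per-vertex distance
  profiles between pairs of reconstructed surfaces; the distribution of
  pairwise PC-vs-PC profile correlations calibrates what "orthogonal
  directions of change" look like.
- **Mutant-line validation.** Each mutant group is tested against wild
  type with a Hotelling T² on the first two PCs of a pooled
  superimposition, Holm-corrected, plus Procrustes-distance spectra
  relative to the wild-type consensus.
- **Synthetic data.** A first-class generator produces sibship-structured
  genotypes (Mendelian drop from small founder pools, hemizygous-doubled
  male X), tooth-like crown surfaces, an additive shape architecture
  (QTL fields + polygenic background + noise) with age-dependent cusp
  wear, and mutant-line groups — so the whole pipeline is testable
  without any external data.

## Worked example

```python
import numpy as np
from molarmap import simdata, morpho, lmm, herit, regions, geno

# 1. simulate a mapping study: 120 sib-structured mice, 1500 SNPs,
#    one QTL at 6% of shape variance on a polygenic background of 0.5
template = simdata.make_tooth_template(seed=0)
cfg = simdata.SimConfig(
    n_individuals=120, n_families=18, n_snps=1500,
    n_qtl=1, qtl_effect_fractions=(0.06,), polygenic_h2=0.5,
    chromosomes=(("1", 100_000_000), ("2", 100_000_000), ("X", 80_000_000)),
    seed=7,
)
panel = simdata.simulate_genotypes(cfg)
configs, ages, truth = simdata.simulate_shapes(panel, cfg, template)

# 2. wear-free phenotyping: truncate, align, decompose
cut = morpho.suggest_cut_height(configs)
wf = morpho.build_wear_free_template(template, cut)
pheno = np.stack([morpho.phenotype_config(wf, c) for c in configs])
model = morpho.compute_pca(morpho.gpa_align(pheno))

# 3. mixed-model scan with the centered kinship
K = lmm.centered_kinship(panel)
assoc, fits = lmm.association_scan(model.retained_scores[:, :3], panel, K)
best = assoc.loc[assoc["p"].idxmin()]

# 4. region delimitation and effect size; 5. aggregate heritability
region = regions.delimit_region(best.snp_id, panel,
                                chromosome_length=100_000_000)
es = regions.effect_size(
    model.retained_scores,
    geno.mean_impute(panel)[:, panel.snp_index(best.snp_id)],
)
w = model.retained_variance_pct
h = np.array([lmm.fit_lmm_null(model.retained_scores[:, i], K).pve
              for i in range(model.n_retained)])
H = herit.weighted_shape_heritability(w, h)
```

Output:

```
retained PCs: 29 (53.3% of shape variance)
top SNP: s1_46480161 (chr1:46480161), p = 9.67e-86  [simulated QTL: s1_46480161]
region Mo.1: 46,230,161-46,730,161 (500 kb), effect size 13.3% [simulated: 6%]
weighted shape heritability: 52.0%
```

The scan recovers the planted QTL as the top association; with no SNP in
LD nearby, the region falls back to the 500 kb window around it.  The
measured effect size (13.3%) exceeds the planted 6% for two reasons the
method itself documents: it is expressed relative to the *retained* shape
subspace (here 53.3% of total variance), and sibship structure inflates
genotype–phenotype correlations.  The aggregate heritability (52.0%) is
bounded by the retained-variance total and reflects that PCA concentrates
the heritable, high-variance directions into the retained axes.

A command-line interface wraps the same stages
(`molarmap simulate | phenotype | map | heritability | run`); `molarmap
run --config cfg.yaml` executes everything from one YAML file and writes a
manifest with input hashes and the seed.

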