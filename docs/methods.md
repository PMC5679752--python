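# Methods

This note documents the models, numerical choices and deliberate design
decisions behind `molarmap`, and what the synthetic-data tests do and do
not establish about real data.

## Shape phenotyping

**Semi-landmarks and the template.** A specimen's shape is an ordered set
of 3D points in one-to-one correspondence with a template's
semi-landmarks.  The template is a crown surface mesh; its semi-landmark
scheme is fixed once (an equal-area sampler with a requested count is
provided; such samplers overshoot the request, and the realised count —
not the requested one — becomes the scheme).  Anchor landmarks (cusp
apices and margin points) drive a thin-plate-spline warp of the template
onto each specimen; warped semi-landmarks are projected to the nearest
point of the specimen surface.  Point-to-surface projection is an exact,
exhaustive point-to-triangle computation (barycentric clamping) — robust
and fast at template scale.

**TPS and bending energy.** The 3D TPS uses the biharmonic kernel
`U(r) = -r` (the sign making the kernel conditionally positive definite,
hence the bending-energy quadratic form positive semi-definite).  The
bending-energy matrix `B` is the upper-left block of the inverse of the
bordered kernel system; it annihilates affine maps, so rigid motions of a
configuration cost nothing.

**Sliding.** Semi-landmarks slide to minimise the bending energy of each
specimen relative to the current consensus.  The slide is solved in
closed form: displacements are restricted to per-point tangent planes and
the joint quadratic programme over all 2k tangent coefficients is solved
by least squares; a slide is accepted only if it does not increase the
energy.  Tangent planes come from per-specimen surface normals when
meshes are available and from the template's vertex normals otherwise;
re-projection onto the specimen surface is applied when a mesh is
supplied.  Three outer iterations (slide → GPA → new consensus) with a
1e-6 RMS tolerance on the consensus are the default; the energy descent
property is what the tests pin down, not an iteration count.

**Occlusal axis and wear.** The height axis is the third coordinate of
the template frame; the anchoring warp brings specimens into that frame.
The wear-free template truncates every vertex above a cut plane straight
down onto it (flat caps, topology preserved).  The cut height is a
required analysis parameter; a helper computes the minimal valid cut from
a specimen set (lowest specimen apex minus a 5% crown-height margin).
For corresponded configurations, wear-free phenotyping is exactly this
truncation, which makes the wear-invariance property provable: two copies
of one tooth worn to different depths, both above the cut, become
identical.  This is a deliberate modelling decision — wear is represented
as plane truncation both in the generator and in the template — so the
wear tests certify the *protocol's* invariance, not the fidelity of plane
truncation to real enamel loss.

**GPA.** Full Procrustes: centering, unit-centroid-size scaling, and
iterative Kabsch rotation (reflections disallowed) to the running mean.
The consensus is defined only up to rotation, so the result is
canonicalised: configurations are first rotated to their own principal
axes (making initialisation independent of specimen order), and the
converged consensus is re-oriented to its principal axes with signs fixed
from the projected coordinates.  Centroid sizes are recorded before
scaling and analysed separately from shape.

**PCA phenotypes.** Eigendecomposition of the covariance of the flattened
aligned coordinates (via SVD of the centered data).  Axes with strictly
more than the retention threshold (default 1%) of total variance become
the mapping phenotypes.  The multivariate age regression reports, per PC
and in aggregate, the variance-weighted fraction of score variance
explained by the covariate, with permutation p-values (the distributional
form of the classical multivariate test is deliberately avoided; the
pipeline's permutation machinery serves instead).

## Association model

Per phenotype `y` (a PC score or CS):
`y = Wα + xβ + u + ε`, `u ~ N(0, σ²_g K)`, `ε ~ N(0, σ²_e I)`, where
`K = X_c X_cᵀ / p` is the centered kinship from mean-imputed dosages
(mean imputation is used only at association time; LD always uses
observed genotypes).  REML estimation of λ = σ²_g/σ²_e works in the
eigenbasis of K: an 80-point grid on log10 λ over [-5, 5] brackets the
optimum and Brent refines it; estimates pinned at a bracket end carry a
boundary flag.  `pve = λτ/(λτ+1)` with `τ = tr(K)/n`; its standard error
comes from the numerical observed information in log10 λ via the delta
method.

SNPs are scored by GLS of `y` on `[1, x]` in the rotated frame with the
null-model λ held fixed (the classic approximation that re-uses the null
variance components per phenotype; exact per-SNP re-optimisation is
available behind a flag and makes a negligible difference at small effect
sizes).  Wald p-values use a t reference with n-2 degrees of freedom.
Monomorphic SNPs return β = 0, p = 1 with a degenerate flag.  Males on X
are coded {0, 2} so one additive dosage column works genome-wide.

**Permutation thresholds.** Phenotype values are permuted across
individuals with genotypes and kinship jointly fixed — this severs the
phenotype-genotype and phenotype-kinship links together.  Every permuted
phenotype is scanned exactly as a real one, *including REML re-estimation
of λ*; re-using the observed phenotype's λ breaks the exchangeability
between permuted scans and fresh data and measurably mis-calibrates the
threshold.  The threshold is the Weibull (type-6) empirical quantile of
the minimum-p distribution at level 1-q: its expected exceedance over a
fresh null scan equals 1-q exactly, whereas the default interpolated
quantile is slightly anti-conservative at a few hundred permutations.
Autosomes and X get separate thresholds; a chromosome class with fewer
than two SNPs yields a warning and no threshold.

## Genotype QC and LD

Filters (in attribution order): heterozygosity > 0.9, missingness > 5%,
minor allele frequency < 5%; a SNP failing several is counted once under
the first.  Heterozygosity is the fraction of non-missing calls equal to
1; MAF uses non-missing calls.  LD is the squared Pearson correlation of
dosages over pairwise-complete observations.  Perfect-LD pruning scans
each chromosome left to right and collapses any SNP with r² = 1 (within
1e-12) to its left-most representative — deterministic and
order-independent — while the full panel stays available for region
delimitation.

## Regions and effect sizes

A significant SNP's region spans the maximal interval of same-chromosome
SNPs individually in LD (r² > 0.8) with it; interior SNPs below threshold
do not split the span (this span rule is what lets a handful of
significant SNPs delimit one long high-LD region).  With no linked
neighbour the region is the 250 kb window to each side (500 kb span),
clipped to the chromosome.  Overlapping regions merge, keeping the
lowest-p SNP; names are `Mo.<chr>` with `.1`, `.2` suffixes by ascending
start when a chromosome holds several.

Effect size: with retained PC scores `S` and dosage `g`,
`effect = Σ_k Var(S_k) r²_k / Σ_k Var(S_k)` — the fraction of total
retained shape variance explained by the SNP, invariant to orthogonal
rotations of the score block.  The sentence defining this estimator in
the source protocol admits a second reading (the R² of regressing `g` on
all retained scores jointly), which is implemented behind
`mode="multivariate"`; the variance-weighted form is the default and the
two are not claimed to agree numerically.  Both are inflated by sibship
structure, and both are relative to the retained subspace, not to total
variance including discarded axes.

## Heritability

The aggregate shape heritability is `H = Σ wᵢhᵢ` with wᵢ the per-PC
percentages of *total* variance — not renormalised to the retained
subspace — so `H` is bounded by the retained-variance total (86.7% for
the reference spectrum shipped with the package, which aggregates to
65.5%).  The aggregate standard error propagates as
`sqrt(Σ wᵢ² seᵢ²)`.

Per-chromosome partitioning fits one single-component REML per
chromosome (kinship from that chromosome's SNPs only) with the top 10
eigenvectors of the genome-wide kinship as fixed covariates.  Separate
fits inflate the per-chromosome pve relative to a joint fit, so only
relative shares are reported and correlated (Pearson) with chromosome
length.  When several PCs are analysed, per-chromosome profiles are
combined with the same wᵢ weights before the correlation — the
aggregation rule was an open choice and per-PC output is also emitted.

## Effect signatures

Effects from independent superimpositions are compared through
per-vertex distance profiles between pairs of reconstructed surfaces
(template mesh warped by the TPS from template semi-landmarks to the
target configuration; when the semi-landmarks are the full vertex set the
warp reduces to the configuration itself).  Profiles are unsigned
Euclidean distances — the signed, outward-normal displacement exists only
for heat-map export.  Profile comparison is Pearson correlation
(Spearman behind a flag; whether the source protocol rank-transformed is
unknowable from its text, and Pearson is the documented default).  The
baseline for "orthogonal directions of change" is the distribution of all
pairwise correlations among retained-PC signatures; the profile length is
a property of the template, not a constant.

## Mutant-line statistics

Each mutant group is tested against wild type on its own pooled GPA +
PCA (scores are deliberately not shared across tests, so the tests are
not nested); the first two PC scores enter a two-sample Hotelling T² with
pooled covariance and the exact F transform.  A group smaller than
n_pcs + 1 cannot support the F approximation and is excluded with a
reason (a 5,000-permutation label test is available as a fallback).
Across-group p-values are Holm-adjusted.  Procrustes distances to a
consensus use the grand mean for a mapping sample and the wild-type mean
for mutant panels.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes: 183
male mice aged 9-12 weeks in sibships (per family a founder pool of 2
dams and 2 sires; offspring draw parents at random, yielding full- and
half-sibs; male X descends from the dam and is coded {0, 2}); ~145k
post-QC-like SNPs allocated to 19 autosomes + X proportionally to
chromosome length, founder allele frequencies uniform on [0.05, 0.5]; a
shape architecture of five QTL at 1.1-3.2% of total variance plus a
polygenic background of 0.65 realised as 200 SNP-attached random fields
rescaled to the target fraction exactly (using realised genotype
variances); isotropic Gaussian vertex noise (0.004 mm per coordinate)
sized so the variance fractions sum to one; wear as per-individual plane
truncation at (crown apex - 0.012 mm/week x age), ages uniform on
[9, 12] weeks.  The mutant module mirrors a validation panel of 36 mice
(groups of 5, 5, 10, 2, 4, 5 mutants + 5 wild types) as template mean +
fixed offset + noise.

What it does **not** emulate: LD decay and recombination maps (SNPs are
transmitted independently, so LD arises only from family structure or
explicit construction), genotype errors, ancestry gradients (a
two-population divergence knob exists conceptually but is not calibrated
to any real hybrid-zone geometry), non-plane wear, or measurement error
correlated along the surface.  Passing tests therefore certify the
statistical machinery under the stated additive model — not robustness to
realistic LD or to segmentation artefacts.

## Problem sizes and tolerances

Test and acceptance runs use deliberately small instances chosen to keep
the full suite in the minutes range while leaving the statistical
assertions well-powered: templates of ~100-250 semi-landmarks, panels of
100-400 individuals and 300-2000 SNPs, 100-200 permutations in tests
(10,000 remains the analysis default), 25-50 replicates for recovery
properties.  The threshold-calibration experiment follows its prescribed
design exactly (n = 100, 2000 autosomal SNPs, 200 permutations, 400
fresh null replicates, ±2 percentage points).  Numerical tolerances:
kinship PSD check at 1e-8; REML Brent tolerance 1e-8 on log10 λ;
perfect-LD tolerance 1e-12; GPA consensus tolerance 1e-12 with
order-invariance asserted at 1e-10; PCA reconstruction exact to 1e-10.

## Known limitations

- The REML search is bounded on log10 λ ∈ [-5, 5]; phenotypes that are
  almost purely genetic pin λ at the upper bracket (flagged, pve ≈ 1).
- The per-vertex signature comparison assumes both effects were measured
  against the same template; cross-template comparison is not supported.
- Sliding without specimen meshes keeps points in the tangent planes of
  the aligned configurations and does not re-project; with strongly bent
  surfaces this slightly under-constrains the slide.
- The mutant Hotelling test's F approximation is exact under bivariate
  normality of the pooled PC scores; for very small groups the
  permutation fallback is the safer choice.
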