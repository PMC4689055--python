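# Methods

## What the pipeline studies

Genomic prediction exploits linkage disequilibrium (LD) between genotyped
SNPs and the causal loci (QTL) behind a trait.  If prediction really works
through tight LD, then the SNPs immediately flanking a QTL should carry most
of the predictive signal, and training on those SNPs alone ("local
training") should do at least as well as training genome-wide.  The pipeline
makes this comparison measurable under fully controlled conditions: the
phenotype is *defined* as a QTL genotype (or a sum of QTL genotypes), so
heritability is exactly 1 and prediction accuracy — corr(y, DGV) — measures
recovery of genetic merit with no residual noise floor.

Two designed phenotypes are used.  *Single-QTL*: y equals the dosage column
of one designated QTL (multiplying by an effect size would only rescale y,
so the raw dosage is used).  *Summed-QTL*: y is the integer sum of dosages
over all designated QTL, a polygenic trait in which every QTL has the same
effect and each one's variance contribution depends only on its allele
frequency.  No residual is ever added; lower heritabilities are out of
scope.

## Synthetic population

The generator emulates the statistical structure of a commercial beef-cattle
dataset — family structure from a multi-generation pedigree, LD decaying
with physical distance, and two SNP densities over one genome — without
claiming to reproduce any real breed's allele-frequency spectrum.

**Genome and panels.** Default layout: 10 chromosomes × 500 markers at
50 kb spacing (a 50 K-array-like density), with an optional dense panel at
`density_ratio` (14 by default when enabled) times that density over the
same physical genome; the sparse panel is the every-14th-marker thinning of
the dense one, so the two densities share marker coordinates and QTL.  The
14:1 ratio mirrors the ratio between high-density (~770 K) and standard
(~54 K) bovine arrays.

**Founder haplotypes (LD model).** Allele-1 frequencies are uniform on
[`maf_low`, `maf_high`] = [0.01, 0.5] (mean 0.255, matching the mid-0.2s
average MAF typical of array SNP sets).  Along each chromosome a latent
standard-normal AR(1) with per-interval correlation
`ld_rho ** (d_bp / reference_distance)` is thresholded at each marker's
frequency quantile (a Gaussian copula).  Marginal frequencies are therefore
exact, allele correlation decays monotonically with distance, and
chromosomes are independent.  Defaults `ld_rho = 0.9` at
`reference_distance = 50 kb` give adjacent sparse-panel markers a latent
correlation of 0.9 (realized dosage r² a few tenths, in the range reported
for dense cattle panels) and negligible LD beyond a few hundred kb.  A
first-order Markov process was chosen over a coalescent simulator because it
is cheap, exactly seed-reproducible, and sufficient to create the
distance-decaying LD the design needs.

**Pedigree and gene drop.** Founders (200 by default) carry the simulated
haplotypes; each later generation pairs the previous one into random
sire × dam matings with 2 offspring each (4 generations → 1000 animals).
Every non-founder inherits one recombinant gamete per parent; crossover
between adjacent markers follows Haldane's map function
c = ½(1 − e^(−2d)) with d in Morgans at 1 cM/Mb, the standard cattle-scale
assumption.  Transmission is Mendelian by construction, and property tests
verify that every transmitted allele exists in the parent.

**QTL and phenotypes.** QTL are every m-th ordered SNP of the sparse panel
(m = 250 by default → 20 QTL); candidates that happen to be monomorphic in
the generated population are dropped rather than re-drawn, mirroring how a
fixed selection rule plus polymorphism filter plays out on real data.  QTL
columns are *never* used as predictors.

## Inference

The Bayesian-alphabet sampler (`localqtl.bayes`, numba kernel in
`localqtl._gibbs`) is a single-site Gibbs sampler for

y_i = μ + Σ_j z_ij β_j δ_j + e_i.

Numerical and design choices:

- **Centering.** Dosages are centered before fitting and the intercept
  absorbs the mean — algebraically equivalent to fitting raw 0/1/2 codes for
  prediction correlations, and better conditioned.  The training column
  means are stored in the posterior summary so DGV for validation animals is
  centered consistently.
- **Inclusion sampling.** δ_j is drawn from its Bernoulli full conditional
  with β_j integrated out (ratio of the two marginal likelihoods of the
  partial residual); log-odds are clamped at ±35 to avoid overflow when the
  residual variance collapses at h² = 1.
- **Variances.** Per-marker effect variances (BayesA/B) or one common
  variance (BayesC family) follow scaled inverse-χ² full conditionals; an
  excluded locus in BayesB draws its variance from the prior.  The residual
  variance is sampled even though h² = 1 — it converges near zero and is
  floored at 1e−8; in practice the prior keeps it near ν_e S_e / (ν_e + n)
  so the floor rarely binds.
- **Hyperparameters.** ν_β = 4.2, ν_e = 4.  The effect-variance scale is
  derived from an assumed genetic variance V (default var(y)):
  S_β = V(ν_β − 2) / (ν_β (1 − π) p · mean 2p_j q_j), which makes the
  prior-implied genetic variance match V.  The residual scale corresponds to
  a nominal residual variance of 0.01 var(y); with noiseless phenotypes the
  posterior is insensitive to it.
- **Update order.** Fixed ascending marker index each iteration, for exact
  reproducibility; a permutation property test confirms the posterior means
  are equivariant to marker order up to Monte-Carlo error.
- **Degenerate inputs.** Constant phenotypes are refused; π = 1 is refused;
  monomorphic predictor columns carry no information, get a zero effect, and
  their indicator is drawn from the prior (so π = 0 methods report inclusion
  frequency exactly 1 for every marker).
- **Chain lengths.** Defaults are 4000 iterations with 500 burn-in; the
  orchestrated whole-genome chains use 800/200.  The convergence monitor
  (running posterior-mean effects → training correlation at checkpoints)
  shows the training correlation plateauing within a few hundred post-burn-in
  iterations on h² = 1 traits, which is what makes the shorter whole-genome
  chains adequate; all lengths are configurable.

`expected_markers_per_iteration(π, p) = (1 − π)p` gives the average number
of SNPs fitted per iteration (2500 at π = 0.95 and 200 at π = 0.996 on a
50,000-marker panel), and an inclusion-calibration test checks the sampler
reproduces it on null data.

## Prediction strategies and experiments

For each QTL, `flank_indices` returns up to k markers on each side,
restricted to the QTL's chromosome and truncated at its ends (boundary QTL
simply get one-sided windows).  *Local training* fits only that window;
*whole-genome training* fits all non-QTL markers once per (method, panel,
phenotype) and every window size re-uses the same fit, predicting from the
window's estimated effects only.  For the summed trait the prediction window
at size k is the union of the per-QTL windows with each marker counted once.
QTL-averaged accuracies are unweighted means over QTL.

Cross-validation clusters animals into K = 6 groups by K-means on the rows
of the pedigree relationship matrix A (tabular method; exact against a
rational-arithmetic oracle).  Raw rows of A with Euclidean distance and 10
restarts are used — the simplest faithful construction, since fancier
feature scalings change little when A is close to block-diagonal.  Each
group is predicted once from a whole-genome fit on the other five.

Per-chain seeds are derived from the master seed and the grid-cell
coordinates by a blake2s hash, so any cell can be re-run independently and
a full experiment is bit-reproducible.

## Problem sizes

The shipped study conditions are desk-scale: main replicate 1000 animals ×
5000 sparse markers with 20 QTL; density comparison 402 animals with a
2800-marker dense / 200-marker sparse pair and 10 QTL; cross-validation 180
animals in six unrelated families.  These sizes keep a full pipeline run in
the minutes range while preserving the structure the questions need
(p ≫ number of QTL, multiple QTL per MAF bin, non-trivial family
structure).

## What the generator does and does not emulate — limitations

- Allele frequencies are drawn independently per marker.  Real tightly
  linked SNPs share a genealogy, so their frequencies are correlated; under
  the copula an adjacent marker with a very different frequency has a capped
  attainable allele correlation.  Local LD is therefore noisier marker-to-
  marker than on a real dense panel, which mainly inflates the variance of
  ±1-SNP-window results for small QTL sets.
- No selection, migration, or mutation: LD comes only from the founder
  process and limited recombination, so there is no long-range or
  cross-chromosome LD of the kind selection can create.
- The pedigree is regular (constant family size, discrete generations,
  no inbreeding loops by design of the mating scheme, though the machinery
  handles inbred pedigrees exactly).
- h² = 1 by construction.  Passing tests show the machinery recovers QTL
  genotypes through LD; they say nothing about low-heritability traits,
  imputation error, or real allele-frequency spectra.
- Accuracy is reported as NaN (with a warning) when a DGV has zero variance
  — e.g. when every flank effect shrinks to zero — rather than silently
  dropped.
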