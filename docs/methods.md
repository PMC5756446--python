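# Methods

This note documents the models implemented in `fstprior`, the choices made
where the design was genuinely open, and what the desk-scale simulations
do and do not demonstrate.

## Forward simulation

**Genome.** `n_chromosomes` chromosomes of `chrom_length_cM` each (default
10 × 100 cM). Markers are evenly spaced; QTL candidate positions are
uniform random and nudged off marker positions so the two sets never
coincide. Positions are genetic distances; recombination is Haldane
(Poisson crossover count with mean = map length in Morgans, uniform
positions, no interference, random starting strand). Mutation is a
recurrent allele flip at `1e-4` per locus per gamete per generation — the
stated rate; the flip model is our reading, since only the rate is given.

**Historical phase.** All loci start at frequency 0.5 in linkage
equilibrium; LD accrues purely through drift in a finite random-mating
population (default 8,000 animals for 300 generations, then a linear
expansion from 12,000 to 17,000 over 15 generations). Only the final
generation is kept. Starting at 0.5 plus hundreds of generations of drift
and mutation yields a realistic U-shaped frequency spectrum at founding.

**Founders and selection phase.** G0 draws 1,500 males and 15,000 females
without replacement from the last historical generation; G0 mates at
random. G1–G4 are produced with one progeny per dam, a random sire per
mating, and a 50 % sex ratio. Before G2, G3 and G4, the breeding
population is refreshed by truncation on EBV: 50 % of sires and 20 % of
dams are culled (lowest EBV first) and replaced by the top-EBV candidates
of the latest generation.

**EBV engine.** The source design selects on "EBVs" without defining the
estimator; we use single-trait pedigree animal-model BLUP with the true
variance ratio λ = σ²e/σ²g, the standard reading. The inverse numerator
relationship matrix is built with Henderson's rules ignoring inbreeding (a
small-bias, large-speed approximation for shallow pedigrees of 4
generations), and the mixed-model equations are solved by Jacobi-
preconditioned conjugate gradients to relative tolerance 1e-8. A
`selection: phenotypic` engine is available for speed.

**Trait.** 100 QTL (desk scale: 40) receive additive effects either
(a) *gamma*: |a| ~ Gamma(shape 0.4), random sign, all effects rescaled so
the Hardy–Weinberg variance Σ 2·p·q·a² equals σ²g = 0.4 exactly; or
(b) *predefined*: per-QTL variance fractions ~ Uniform(0.005, 0.015),
renormalized to sum to 1 and converted via a = sqrt(f σ²g / 2pq), so every
QTL explains ≥ ~0.5 % of the genetic variance and none dominates.
Monomorphic loci get zero effect. QTL are drawn at G0 from candidates with
MAF ≥ 0.05; panel markers require MAF ≥ 0.01 (the source is silent; a QTL
must segregate to carry variance).

**Phenotypes.** y = TBV + e, e ~ N(0, σ²e). Under the default `rescale`
policy σ²e = Var(TBV)·(1−h²)/h² is recomputed from each generation's
realized TBV variance, so that the realized heritability stays at 0.4 even
as truncation selection erodes genetic variance (Bulmer effect); this is
our reading of "residual variance adjusted to maintain heritability
constant". A `nominal` policy (σ²e = 0.6 throughout) is also provided.
BLUP uses the nominal ratio λ = 1.5 in all generations; per-generation
residual rescaling makes phenotypic variances mildly heterogeneous across
generations, which the animal model ignores — a deliberate simplification.

**Determinism.** One master seed spawns named child streams (genome,
historical, founders, QTL, mating, phenotype), all recorded in the run
manifest; identical configurations are bit-identical.

## F_ST scoring and preselection

Nei's global estimator between the bottom- and top-5 % phenotype tails of
the genotyped training generation:
F_ST = (H_T − H_S)/H_T with H_T = 2pq on the size-weighted pooled
frequency of the two tails (the middle 90 % is excluded, matching the
estimator's use of S1/S2 only) and H_S the size-weighted mean of tail
heterozygosities. Conventions: tails are taken by rank so the two groups
are exactly equal; loci monomorphic across both tails score 0 (no
differentiation signal, avoids NaN in the quantile step); scores are
clipped to [0,1] against round-off; the preselection threshold is the
empirical quantile over *all* loci, ties included (≥), so selected counts
can exceed (1−q)·n. A within-stratum mode scores each stratum (e.g.
breed) separately for admixed populations; combining per-stratum panels is
left to the user. In real-data mode, missing genotypes are mean-imputed
per locus and loci with > 10 % missingness are dropped.

## Bayesian whole-genome regression

Single-site Gibbs sampler for y = μ + Σ X β γ + e on training-centered
dosages (centering by twice the training allele frequency; validation
reuses the training centers). Variants:

* `fst_preselect` — every design SNP stays in the model (γ ≡ 1),
  locus-specific effect variances (BayesA-like on the reduced panel);
* `bayesB` — γ sampled per locus from its full conditional with the effect
  integrated out (no Metropolis step), locus-specific variances; excluded
  loci refresh their variance from the prior;
* `bayesC` — γ as above with a single effect variance shared by included
  SNPs.

Priors are scaled-inverse-χ² with scales tied to the true simulation
variances (σ²g = 0.4, σ²e = 0.6) and degrees of freedom 1 (effects) and 4
(residual). The total-variance scale is partitioned per locus as
σ²g / (m · mean(2pq)) for m design SNPs, so the implied total genetic
variance matches the prior scale; BayesC divides additionally by (1 − π)
because only that fraction of SNPs is in the model at a time. The
partition is an interpretation — the reference software's internal
parameterization is not published. `pi_zero` (= π) is the prior
*exclusion* probability; the study's table columns map to
π ∈ {0.90, 0.95, 0.98, 0.99}.

Chain defaults are 3,000 iterations, 500 burn-in, thinning 5 — sized for
desk-scale designs of up to a few thousand SNPs, where posterior means of
effects stabilize well before that; for production analyses on larger
panels we recommend 11,000/1,000/10. The kernel is numba-compiled and
deterministic given the seed.

**Sampler validation.** (i) In the known-variance limit (df → ∞) the
one-SNP preselect model reproduces the conjugate ridge posterior mean to
< 1 %. (ii) Prior-predictive calibration: on data simulated from the
BayesC prior itself, the mean posterior inclusion frequency recovers
1 − π. Note that on data whose effects are *exactly* zero the posterior
inclusion falls below the prior — correct behavior, since such data carry
evidence against inclusion — so calibration must be checked against
prior-predictive draws, not against literal null data. (iii) Permutation
exchangeability, seed determinism, monotone shrinkage in π, and recovery
of large effects against an OLS oracle are covered in the test suite.

## Evaluation

`Acc_G` = Pearson(TBV, GEBV) and `Acc_P` = Pearson(GEBV, y − μ̂) on the
validation generation. A QTL is *tagged* when its dosage vector has
squared correlation > 0.7 with at least one selected SNP; r² is computed
from dosages (composite LD — the convention in this literature, and it
needs no phasing), with the training animals as the LD reference
population. The % of genetic variance explained sums single-locus
Hardy–Weinberg variances 2pqa² of tagged QTL over all polymorphic QTL,
ignoring QTL–QTL LD covariance (an approximation; with linked QTL under
selection the single-locus sum understates negative-covariance effects).

## Desk-scale study conditions

`SimConfig.desk_scale()` preserves the design's structure on one CPU:
2 chromosomes × 100 cM, 4,000 evenly spaced markers, 40 QTL, founder
population of 300 sires and 3,000 dams (so each selected generation holds
3,000 animals and a 2,000-animal training set is two thirds of G3, the
full design's training fraction), validation on 1,000 G4 animals, 5 %
phenotype tails of 150 animals each.

The historical bottleneck is the one full-scale knob that cannot be
shrunk proportionally. At 0.05 cM marker spacing, the `high` LD regime
(200 generations at N = 60) realizes mean adjacent-marker r² ≈ 0.56–0.60 —
the strongest attainable at this density before fixation erodes the panel
faster than drift builds LD — and the `low` regime (120 at N = 150)
realizes ≈ 0.3, mirroring the dense/sparse contrast of the full design
(≈ 0.65–0.70 vs ≈ 0.3).

**What the desk scale shows and does not show.** The scaled runs reproduce
the mechanism of the method: realized heritability holds at 0.40 ± 0.05
under the rescale policy; truncation selection raises mean TBV generation
over generation; and the F_ST-selected panel is strongly enriched for the
large QTL — at the 99.5 % quantile it tags more top-decile QTL than an
equal-sized random panel in essentially every replicate while covering the
majority of the genetic variance with < 3 % of SNPs. What the desk scale
does *not* reproduce is the headline accuracy inversion (preselected panel
beating the all-SNP regression): that inversion is a property of the
severely over-parametrized regime — 200 K SNPs against 10 K records
(20 : 1) — whereas a 4,000-marker desk panel against 2,000 records leaves
the all-SNP model with roughly one parameter per record, a regime in which
including all markers costs little and captures the untagged variance. In
the suite's five desk replicates the all-SNP model is therefore usually
the more accurate one. Scaling the marker count up while holding records
fixed restores the full design's ratio but not its runtime; the full
configuration remains the documented default of `SimConfig`.

Other simplifications of the generator relative to real data: no
genotyping error or missingness (real-data mode handles missingness at
input instead), purely additive single-trait architecture, no pedigree
errors, discrete generations, and an idealized bottleneck demography.
Passing tests demonstrate internal correctness of the estimators and the
direction of the method's enrichment signal, not field performance on any
real population.

## Numerical choices

- BLUP: CG with Jacobi preconditioner, rtol 1e-8, hard iteration cap
  20,000 (raises on non-convergence).
- F_ST: degenerate loci (H_T = 0) score 0; scores clipped to [0, 1].
- Gibbs: zero-variance design columns are skipped (effect pinned at 0);
  the Bayes-factor exponent is capped at 50 before exponentiation to
  avoid overflow; per-locus prior scale as above.
- Tag r²: columns with zero variance are excluded; monomorphic QTL are
  dropped from numerator and denominator with a reported count.
- Quantile thresholds use `numpy.quantile` (linear interpolation), with
  ties included by ≥ comparison.
- Renormalization in the predefined-effects scheme means realized minimum
  GV fractions can undershoot 0.5 % by the ratio of the fraction sum to 1
  (≤ ~20 % for 40–100 QTL).
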