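# Methods

## The problem

In genomic selection (GS), breeding candidates are ranked on genomically
estimated breeding values (GEBVs) predicted by GBLUP: a mixed linear model
whose random genetic effect has covariance proportional to a genomic
relationship matrix (GRM) computed from SNP dosages.  Beyond a moderate
marker density the unweighted GRM stops improving — realized additive
relationships are already estimated accurately — so prediction accuracy
plateaus even as panels grow.  The idea implemented here is to make the GRM
less a measure of average relatedness and more a measure of *genetic
similarity at trait-relevant loci*: markers are prioritized by a fixation
index (F_ST) contrast between the phenotypic tails of the training
population, and their contribution to the GRM is up-weighted.

## Model and procedure

1. **Tail subpopulations.** Training phenotypes are split at the empirical
   5% and 95% quantiles into a low tail S1, middle S0, and high tail S2.
   Tie handling is deterministic: individuals are ordered by (phenotype,
   position) and exactly ⌊0.05·n⌋ taken from each end, so a population of
   15,000 yields exactly 1,500 tail animals.

2. **Per-locus F_ST (Nei).** With tail allele frequencies p_S1, p_S2 and
   census sizes n_S1, n_S2:

       H_Si = 2 p_Si (1 − p_Si)
       H_S  = (n_S1 H_S1 + n_S2 H_S2) / (n_S1 + n_S2)
       H_T  = 2 p (1 − p),   p = (n_S1 p_S1 + n_S2 p_S2) / (n_S1 + n_S2)
       F_ST = (H_T − H_S) / H_T,   0 when H_T = 0

   The total-population frequency p is taken from the pooled tails
   (consistent with the census-weighted H_S; S0 never enters the scores).
   An `total="all"` option uses the whole training generation instead.
   Monomorphic loci score 0 by definition, so they can never enter the
   top-k set.  F_ST ∈ [0, 1] follows from concavity of 2pq.

3. **Relative weights.** Score-proportional weights are
   w_i = F_ST,i / Σ_j F_ST,j · N (mean weight 1 over N loci).  Budget
   scenarios assign x% of the total weight N to the top-k set and
   (100−x)% to the remainder — the study grid is
   (100,0), (90,10), (75,25), (50,50), (25,75), score-proportional ("PS"),
   and equal weights — spread equally within each group by default
   (`within="fst"` spreads a group's budget score-proportionally instead).
   The paper states only the group budgets; equal-within-group is the
   simplest reading consistent with "PS" being singled out as the
   proportional case, and the alternative is one flag away.  Two top-only
   panels (equal / score-proportional over the top-k set alone) complete
   the scenario set.

4. **Weighted GRM (VanRaden).** Z = M − 2P over the panel loci;

       G = Z diag(w) Zᵀ / (2 Σ_i w_i p_i (1 − p_i)).

   With w ≡ 1 this is exactly VanRaden's first method.  The *weighted*
   normalization keeps E[diag G] ≈ 1 under any budget and makes G invariant
   to rescaling all weights by a positive constant (the unweighted
   denominator is available as an option).  Centering frequencies default
   to the combined train+validation genotyped set.  Loci monomorphic in the
   frequency reference contribute nothing to numerator or denominator and
   are dropped with a logged count.  Before any inverse is taken the matrix
   is blended, G* = 0.99·G + 0.01·I; the study applies the same G* in the
   REML fit so that variance components and predictions refer to one
   covariance model.

5. **GBLUP / REML.** y = Xb + u + e on the training animals (X an intercept;
   the simulation has only an overall mean), u ~ N(0, G σ_u²) over
   train+validation, e ~ N(0, I σ_e²).  Variance components maximize the
   restricted likelihood by average-information (AI) updates with EM-REML
   fallback whenever an AI proposal leaves the parameter space; one
   eigendecomposition of the training block makes each iteration O(n).
   Starting values are σ_u² = σ_e² = var(y)/2; components are floored at
   1e−8·var(y); convergence requires relative parameter change < 1e−8 and
   gradient norm < 1e−6 (max 50 iterations; non-convergence is flagged,
   not raised).  The reported deviance is
   −2logL_R = log|V| + log|XᵀV⁻¹X| + yᵀPy + (n−p)·log 2π — constant
   conventions differ between REML programs, so only differences between
   scenarios are meaningful.  GEBVs solve the joint mixed-model equations
   over train+validation with phenotypes only on training rows (a
   covariance back-solve that never inverts G is provided and tested equal).
   Validation accuracy is the Pearson correlation of GEBV with true
   breeding value; bias is the OLS regression of GEBV on TBV.

## The simulator

The generator stands in for a full-scale forward simulation and defines the
study conditions.

* **Historical phase.** Loci start in linkage equilibrium at frequency 0.5;
  discrete generations of random mating (Poisson-count crossovers with
  uniform placement and no interference; recurrent biallelic mutation,
  default 2.5e−5 per locus per gamete, during this phase only) let drift
  build linkage disequilibrium.  The default schedule — 198 generations of
  250, then an expansion to 1,600 and 6,400 — was chosen once to bring mean
  adjacent-marker r² near 0.3 at the default marker spacing (realized
  ≈ 0.26–0.28) while remaining seconds-scale; exact matching is not
  enforced.  The schedule list is right-aligned: earlier generations reuse
  the first entry.

* **Trait.** 100 (default; 200 at full scale) QTL are drawn uniformly among
  loci polymorphic in the base population, never coinciding with a panel
  SNP and never genotyped.  Effect magnitudes are i.i.d. Gamma(0.4, 0.15),
  signs ±1 with probability ½.  Effects are rescaled by one common factor
  so the variance of base-generation TBVs equals h²·V_P exactly
  (defaults 0.3·1.0), then σ_e = √((1−h²)·V_P): the base generation
  realizes h² = 0.3 and V_P = 1 up to phenotype sampling noise.

* **Selection phase.** A base population of 200 sires and 3,000 dams breeds
  3,000 offspring per generation for 7 generations (one progeny per mating,
  offspring sex Bernoulli(½)).  Each generation, 50% of the sire pool and
  20% of the dam pool are replaced by the top-ranked young candidates;
  retained parents are the top-ranked of the existing pool.  Ranking uses a
  pedigree-index EBV, h²·(y − ȳ_gen) + ½(EBV_sire + EBV_dam) — a cheap
  surrogate for a per-generation BLUP that preserves directional selection
  pressure; pure phenotypic or random ranking are config options.
  Generation 6 is the training population, generation 7 the validation
  population.

* **Scale.** The default is a 1:5 shadow of the full design: 2 chromosomes
  × 100 cM carrying 20,000 SNPs (vs 10 × 100 cM with 400,000), 100 QTL
  (vs 200), 3,000 animals per generation (vs 15,000), 2,000 training and
  1,000 validation animals sampled (vs 10,000/5,000), top-k = 1,000 (5% of
  the panel, the same ratio as 20K/400K), 5%/95% tails taken from the full
  training generation *before* analysis sampling, 5 replicates.  These
  sizes keep the full nine-scenario study at roughly ten minutes on one
  CPU.  Full-scale sizes are reachable through the config.

### What the generator does and does not emulate

It reproduces drift-generated LD, a Gamma effect-size spectrum dominated by
tiny effects, truncation selection on pedigree-index EBVs with partial
parent replacement, and exact base-generation calibration of h² and V_P.
It does **not** model mutation–drift equilibrium (history starts at
frequency 0.5, so the allele-frequency spectrum is unimodal rather than
U-shaped), sex chromosomes, dominance or epistasis, overlapping-generation
age structure, genotyping error, or a bottleneck–expansion demography.
Passing tests therefore demonstrate the method's behaviour under clean
additive architecture and drift LD — not its performance on real livestock
data, where LD structure, minor-allele-frequency spectra and
genotype–environment effects differ.

## Numerical choices

* Tail ties: deterministic (phenotype, position) ordering; exact
  ⌊q·n⌋ tail counts.
* Top-k ties: broken by genome order (chromosome, position).
* F_ST at monomorphic pooled loci: 0, not NaN; scores clipped to [0, 1]
  against rounding at the boundaries.
* GRM symmetry enforced as (G + Gᵀ)/2 after the product; equal-within-group
  budget scenarios are assembled from two per-group cross-products, which
  is algebraically identical to the direct weighted product (tested to
  1e−10).
* Histogram bins: lower-inclusive half-open intervals over the ordered
  thresholds (−0.05, −0.03, −0.01, 0.01, 0.03, 0.05), covering the line.
* Degenerate inputs raise: empty tails, all-zero score vectors, zero
  phenotypic variance, non-positive GRM normalization, singular
  mixed-model equations (with a hint to blend).

## Known limitations

* The QTL-architecture summary ("share of QTL explaining < 0.1% of genetic
  variance") is ≈ 66–68% under the stated Gamma(0.4) magnitude distribution
  for any allele-frequency spectrum — the share statistic is invariant to
  the Gamma scale, so this is a hard property of the shape parameter.
  Reported values near 55% in the genomic-selection literature are not
  reproducible from that distribution alone.
* At 1/5 scale the replicate-to-replicate spread of validation accuracy is
  large (tails of 150 animals make F_ST scores noisy); the *direction* of
  the weighting effect is stable across replicates, its magnitude varies.
* AI-REML is implemented for the single-random-effect model only; no
  multi-trait, repeated-records or single-step extensions.
* The simulator's historical phase is a drift process, not a coalescent;
  very long histories are proportionally expensive.
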