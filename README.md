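# fstgrm

Fixation-index (F_ST) prioritized SNP weighting for genomic relationship
matrices, with a forward-in-time breeding simulator and a GBLUP/REML
evaluation harness.

Dense marker panels have not delivered the accuracy gains genomic selection
was promised: beyond a moderate density, the unweighted genomic relationship
matrix (GRM) stops changing, because average realized relationships are
already well estimated.  `fstgrm` implements a prioritization strategy for
animal-breeding research: score every SNP by the allele-frequency
differentiation (Nei's F_ST) between the low and high phenotypic tails of the
training population, then let the top-scoring markers carry a larger share of
the weight when the GRM is built.  The package is aimed at quantitative
geneticists who want to study marker-weighting schemes on simulated breeding
populations or apply them to their own genotype/phenotype tables.

## The method

For each locus, with tail allele frequencies `p_S1`, `p_S2` and tail sizes
`n_S1`, `n_S2`:

```
H_Si = 2 p_Si (1 - p_Si)
H_S  = (n_S1 H_S1 + n_S2 H_S2) / (n_S1 + n_S2)
H_T  = 2 p (1 - p),  p = pooled-tail frequency
F_ST = (H_T - H_S) / H_T
```

Relative weights over N panel SNPs are `w_i = F_STi / Σ_j F_STj × N`
(mean weight 1), or group budgets that give the top-k set x% of the total
weight and the remaining SNPs (100−x)%.  The weighted VanRaden GRM is

```
G = Z diag(w) Z' / (2 Σ_i w_i p_i (1 - p_i)),   Z = M - 2P
```

which reduces to the ordinary VanRaden matrix when all weights are 1.  GBLUP
breeding values and REML variance components come from the single-random-
effect mixed model `y = Xb + u + e`, `u ~ N(0, G σ_u²)`, fitted by
average-information REML with EM fallback.

The built-in simulator produces the full study substrate — a drift-generated
LD structure, Gamma(0.4, 0.15) QTL effects on non-genotyped loci, base
heritability 0.3 and phenotypic variance 1.0 exactly, and seven generations
of truncation selection on pedigree-index EBVs — so the whole experiment runs
from a single seed with no external data.  See `docs/methods.md` for the
model, defaults, and what the simulator does and does not emulate.

## Worked example

The default `ExperimentPlan` is a 1:5-scale scenario study: 20,000 SNPs on
2 chromosomes, 100 QTL, 3,000 animals per generation, 2,000 training /
1,000 validation animals, top-k = 1,000 SNPs by F_ST, 5 replicates.

```python
from fstgrm import ExperimentPlan, run_experiment

report = run_experiment(ExperimentPlan(base_seed=1))   # ~10 min on one CPU
print(report.summary_accuracy().round(3))
```

```
 scenario  accuracy_mean  accuracy_sd
    100:0          0.808        0.032
    90:10          0.821        0.031
    75:25          0.827        0.029
    50:50          0.828        0.028
    25:75          0.817        0.028
       PS          0.830        0.024
    equal          0.774        0.036
top-equal          0.808        0.032
  top-fst          0.813        0.031
```

Every F_ST-weighted scenario beats the equal-weight baseline (`equal`,
accuracy 0.774): shifting 25–100% of the weight budget onto the prioritized
top 5% of SNPs — or using the prioritized subset alone (`top-fst`, 0.813) —
raises the correlation between predicted and true breeding values of the
validation generation by 4–7% relative.  `report.summary_varcomps()`,
`report.summary_fit_bias()` and `report.summary_histograms()` give the
variance components, the GEBV-on-TBV bias regression (slope < 1 everywhere:
shrinkage), and the train×validation relationship distribution, whose mass
above 0.03 grows with the top-set weight share.  The realized base-generation
calibration sits in `report.base_stats` (h² 0.294–0.314, V_P 0.956–1.020,
adjacent-marker r² ≈ 0.27 across the five replicates above).

The same study runs from the shell, with per-table CSV output:

```
fstgrm run-all --out study/ --seed 1
fstgrm simulate config.yaml --out simdata/ --generations 6,7
fstgrm fst simdata/gen6.raw g6_phenotypes.csv --top-k 1000 --out scores.csv
fstgrm weights scores.csv scores.topk.txt --scenario 75:25 --out w.csv
fstgrm grm simdata/gen6.raw --weights w.csv --blend 0.01 --out grm.csv
fstgrm fit g6_phenotypes.csv grm.csv --out-prefix fit
```

A YAML plan file (see `docs/methods.md` for every field) looks like:

```yaml
sim:
  n_snp: 20000
  n_qtl: 100
  n_chromosomes: 2
  seed: 1
scenarios: ["equal", "100:0", "75:25", "ps", "top-fst"]
n_replicates: 5
train_sample: 2000
val_sample: 1000
top_k: 1000
```

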