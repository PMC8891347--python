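# hybridpanel

Tools for designing, evaluating and deploying high-differentiation SNP
panels that assign individuals to **intra-specific hybrid classes** — the
six generation-2 genotype-frequency classes: the two pure parental forms,
F1, F2, and the two first backcrosses (F1 × pure). The motivating setting
is monitoring introgressive hybridization between the anadromous (sockeye)
and freshwater-resident (kokanee) forms of *Oncorhynchus nerka* with a
GT-seq amplicon panel, but the workflow applies to any two-population
system with reference samples for both forms.

The package covers the whole workflow:

1. **Synthetic reference data** (`hybridpanel.synthetic`) — two parental
   populations genotyped at thousands of RAD-like biallelic SNPs under a
   Balding–Nichols divergence model with a tail of highly differentiated
   outlier loci, missing calls, near-duplicate (linked) locus pairs and
   homeolog-like loci with forced excess heterozygosity.
2. **Per-locus statistics** (`hybridpanel.popgen`) — call rate, minor
   allele frequency, observed heterozygosity, F_is, the exact conditional
   Hardy–Weinberg test, the two-population Weir & Cockerham (1984) θ
   estimator of F_st, and a genotypic linkage-disequilibrium G-test with a
   permutation null.
3. **Panel design** (`hybridpanel.design`) — the filter chain: call rate ≥
   60% in both populations and pooled MAF > 0.05 → homeolog filter (F_is <
   0 or H_obs > 0.5 in *both* populations) → Hardy–Weinberg filter → SNP
   position within base pairs 40–70 of the RAD tag → top 650 loci by θ →
   LD pruning to 600 candidates → modelled primer dropout to the deployed
   panel (default 342 SNPs).
4. **Hybrid-class simulation** (`hybridpanel.crosses`) — Mendelian pedigree
   crossing of unlinked loci. Each class is characterised by
   φ = (φ00, φ01, φ11), the probability that a locus's two gene copies
   derive from (pop0, pop0), (pop0, pop1) or (pop1, pop1):
   pure0 = (1,0,0), pure1 = (0,0,1), F1 = (0,1,0), F2 = (¼,½,¼),
   BC0 = (½,½,0), BC1 = (0,½,½).
5. **Bayesian class assignment** (`hybridpanel.assign`) — per-locus
   genotype probabilities are a φ-weighted mixture over gene-copy origins,
   e.g. P(g=2) = φ00·p0² + φ01·p0·p1 + φ11·p1²; loci multiply
   independently, and posteriors follow from a uniform class prior. A
   deterministic plug-in mode uses smoothed reference allele-frequency
   estimates; a Gibbs mode (default 10,000 burn-in + 50,000 sweeps)
   additionally integrates over reference-frequency uncertainty and the
   cohort mixture proportions, with the references acting as
   known-genotype frequency informers.
6. **Performance evaluation** (`hybridpanel.evaluate`) — confusion
   matrices and, per class c at posterior threshold t: accuracy (correct
   assignments to c / all assignments to c), efficiency (correct
   assignments to c / true class size) and power (their product), plus the
   Type I (pure → hybrid) and Type II (hybrid → pure) error rates.
7. **Cohort analysis** (`hybridpanel.cohort`) — per-individual
   missing-data filtering (> 25% removed), per-year stock-composition
   tables with hybrid summaries, within-year and across-year chi-square
   tests on class proportions, and fork-length ANOVA with Tukey HSD.

## Worked example

The `run` pipeline ties every stage together on synthetic data:

```python
from hybridpanel import RunConfig, run_pipeline

artifacts = run_pipeline(RunConfig(seed=1, outdir="demo"))
```

With the default configuration (3,000 loci, reference sample sizes 20 and
35, background F = 0.15 with 5% outlier loci at F = 0.8) the filter chain
reports:

```
                stage  n_entered  n_removed  n_survived
              quality       3000        176        2824
             homeolog       2824       1067        1757
                  hwe       1757         97        1660
             position       1660       1072         588
         rank_top_fst        588          0         588
             ld_prune        588          1         587
  truncate_candidates        587        245         342
```

i.e. 176 loci fail call-rate/MAF, 1,067 look like collapsed homeologs
(excess heterozygosity or negative F_is in both populations — the forced
homeolog-like loci plus small-sample noise), 97 deviate from
Hardy–Weinberg, 1,072 sit too close to a tag edge for primer design, one
planted near-duplicate is removed as linked, and a random 342-SNP subset
models primer dropout. Assigning 1,000 simulated individuals per class
with the plug-in posterior gives the confusion matrix

```
       pure0  pure1     F1     F2    BC0    BC1
pure0  1.000  0.000  0.000  0.000  0.000  0.000
pure1  0.000  1.000  0.000  0.000  0.000  0.000
F1     0.000  0.000  0.996  0.004  0.000  0.000
F2     0.000  0.000  0.004  0.983  0.006  0.007
BC0    0.001  0.000  0.001  0.007  0.991  0.000
BC1    0.000  0.002  0.004  0.006  0.000  0.988
```

(rows = true class, columns = assigned class, row-normalised): every class
is recovered with ≥ 98% of individuals on the diagonal, and the residual
confusion sits where it should — between F1/F2 and between F2 and the
backcrosses. On an independent 100-per-class cohort the power
(accuracy × efficiency) at the 50% posterior threshold is ≥ 0.95 for every
class, with Type I error 0.0 and Type II error 0.0025.

A command-line surface mirrors the library
(`hybridpanel design | simulate | assign | evaluate | cohort | run`); every
stochastic subcommand takes `--seed`, and all outputs are stamped with the
seed and a configuration hash.

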