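# Methods

This note documents the models, parameter choices and numerical
conventions behind `hybridpanel`, and what the synthetic experiments do
and do not demonstrate about real data.

## The genotype-frequency-class model

An individual belongs to one of six generation-2 classes: pure0, pure1,
F1, F2, BC0 (first backcross to pop0) and BC1 (first backcross to pop1).
A class is fully characterised, for unlinked loci, by the distribution
φ = (φ00, φ01, φ11) of the two gene-copy origins at a locus — both copies
from population 0, one from each, or both from population 1. The stored φ
triples are the Mendelian expectations and are equal to the outer product
of the parental gamete-origin laws (pure gametes carry their own
population's copy; an F1 gamete carries either with probability ½). The
package deliberately stops at generation 2: later backcrosses (B3+)
converge on the pure classes and are not identifiable at these panel
sizes, and per-locus ancestry proportions (admixture coefficients) are a
different estimand than class membership.

Given reference alternate-allele frequencies p0 and p1 at a locus, the
genotype law of a class is the φ-mixture over origins with
Hardy–Weinberg sampling of each copy:

    P(g=2) = φ00 p0² + φ01 p0 p1 + φ11 p1²
    P(g=1) = φ00 2p0q0 + φ01 (p0 q1 + p1 q0) + φ11 2p1q1
    P(g=0) = φ00 q0² + φ01 q0 q1 + φ11 q1²

Unlinked loci multiply; missing genotypes contribute a likelihood factor
of 1 (marginalisation by omission). Class posteriors use a uniform prior
by default.

### Assignment modes

*Plug-in* (deterministic): reference frequencies are point estimates
smoothed with a pseudocount (default 0.5, a Jeffreys-style prior):
`(alt + 0.5) / (2 n_called + 1)`. Smoothing keeps frequencies strictly
inside (0,1) so a single discordant genotype at a locus fixed in a
reference sample cannot annihilate a class likelihood. Log-likelihoods
are normalised with log-sum-exp; ties in the maximum posterior (within
1e-12) are flagged and broken by the fixed class order pure0, pure1, F1,
F2, BC0, BC1. An individual with zero called loci receives the prior and
a tie flag.

*Gibbs* (stochastic, defaults 10,000 burn-in + 50,000 sweeps): per sweep,
reference allele frequencies are drawn from their Beta posteriors given
the reference genotype counts (symmetric pseudocount prior); latent class
labels are drawn categorically given the mixture weights and genotype
likelihoods; mixture weights are drawn from a Dirichlet(1,…,1) posterior
updated from the *test* individuals only — reference individuals inform
frequencies but are not mixture members, mirroring the known-genotype
("z"/"s") reference semantics of class-assignment software. The reported
posterior is the occupancy fraction of post-burn-in sweeps; runs are
reproducible given a seed. On well-separated panels the two modes agree
essentially always; the plug-in mode is the test surface because it is
exactly reproducible and admits closed-form oracles.

## Synthetic reference data

The generator emulates the statistical shape of a two-population RAD
dataset used for panel design, with defaults chosen once to mirror a
realistic monitoring setting:

* sample sizes 20 (pop0) and 35 (pop1) — small legacy reference
  collections;
* 3,000 biallelic SNPs; ancestral frequencies uniform on [0.1, 0.9]
  (degenerate monomorphic loci are redrawn);
* Balding–Nichols divergence: each population's frequency is a
  Beta(p(1−F)/F, q(1−F)/F) draw around the ancestral frequency. The
  per-locus F is two-component: a genome-wide background of F = 0.15 and
  a 5% fraction of divergence-outlier loci at F = 0.8 shared by both
  populations. The outlier component represents the near-diagnostic
  markers that differentiation scans of ecotype pairs consistently
  report and that high-differentiation panels are built from; a single
  genome-wide F produces a unimodal θ distribution whose upper tail is
  too weak to support a panel of several hundred strongly informative
  SNPs from a few thousand candidates. The calibration (fraction 0.05,
  F 0.8) was chosen as the smallest outlier component under which the
  designed 342-SNP panel reaches the published performance regime of
  such panels, and is fixed; both parameters are exposed on
  `PopulationModel` for sensitivity analyses.
* missing genotype calls inserted uniformly at 5%;
* 10 near-duplicate locus pairs (a copy with ~3% of genotypes redrawn,
  ≥95% identity) to exercise LD pruning;
* 50 homeolog-like loci forced to all-heterozygote in both populations —
  the signature of collapsed salmonid paralogs;
* SNP positions uniform on a 90 bp RAD tag (classic single-end tag
  length), so roughly a third of loci fall in the 40–70 bp
  primer-design window.

What this does **not** model: read-level error, allelic dropout or depth
structure (genotypes are sampled directly), genuine chromosomal linkage
(only near-duplicates), null alleles, and any demographic history beyond
symmetric divergence from a shared ancestor. Passing performance on this
generator therefore demonstrates that the *pipeline* — filters, ranking,
simulation and the assignment model — behaves correctly and that panels
of this size and differentiation profile carry enough information for
six-class assignment; it does not by itself certify any particular
empirical marker set.

Cohorts are simulated by explicit pedigree crossing at the smoothed
reference-frequency estimates — the same frequencies the assigner uses —
so simulation and assignment share one frequency model, as they do in
reference-genotype-driven simulation tools.

## Panel-design conventions

* Call-rate threshold 0.60 is inclusive ("at least 60%"); the MAF
  threshold 0.05 is strict ("greater than").
* The homeolog filter removes a locus only when (F_is < 0 or H_obs > 0.5)
  holds in *both* populations. An undefined F_is (monomorphic sample)
  counts as not satisfying the condition — a conservative keep, flagged.
  Note that a locus whose minor alleles occur only in heterozygotes has
  F_is < 0 mechanically, so with small reference samples this filter also
  removes a substantial fraction of ordinary loci, including near-fixed
  highly differentiated ones; fully fixed reference samples (F_is
  undefined) escape it.
* The Hardy–Weinberg filter removes loci with exact-test p below α = 0.05
  in *either* population. The exact test enumerates heterozygote counts
  conditional on the allele counts and sums configurations no more
  probable than the observed one (two-sided); α and the either/both
  convention are configurable since source pipelines rarely state them.
* The tag-position window 40–70 is inclusive on both ends (ordinal base
  pairs, 1-based).
* θ ranking uses the two-population Weir–Cockerham variance-components
  ratio a/(a+b+c) per locus (ranking is per locus, so no multi-locus
  averaging is needed); ties are broken lexicographically by locus id for
  determinism, and float overshoot beyond [−1, 1] (exactly fixed
  differences) is truncated.
* LD pruning tests genotypic association *within* each reference
  population and sums the per-pair G statistics and degrees of freedom
  over populations. Testing on the pooled sample would read population
  structure itself as association and preferentially strip the
  highest-θ loci. The default significance rule is the asymptotic
  chi-square p of the summed G with Bonferroni correction across tested
  pairs: with hundreds of candidates there are ~10⁵ pairs, and an
  uncorrected per-pair α of 0.05 would flag thousands of null pairs and
  gut the panel. The seeded permutation G-test remains available as the
  single-pair primitive (`popgen.ld_genotypic_test`), with
  p = (1 + #{G_perm ≥ G_obs}) / (1 + n_perm). Removal is iterative:
  significant pairs in order of increasing p, dropping the lower-θ
  member (never the higher), until no significant pair remains.
* Primer dropout during multiplex optimisation is modelled abstractly in
  three modes — a seeded random subset, an explicit drop list, and
  removal of loci whose raw-read share exceeds 2% (strict) — since
  amplification chemistry is out of scope.

## Evaluation conventions

Accuracy at a threshold excludes unassigned individuals from its
denominator; a class receiving no assignments at a high threshold has
undefined (missing, not zero) accuracy. Efficiency keeps the full true
class size in the denominator and is therefore non-increasing in the
threshold. Power = accuracy × efficiency holds as an exact identity at
every grid point. The default threshold grid is 0.50 to 0.95 in steps of
0.05. Evaluation cohorts default to 100 individuals per class; the
design-stage informativeness check uses 1,000 per class.

## Cohort analyses

Individuals with strictly more than 25% missing genotypes are removed
before assignment. Stock-composition proportions are exact internally and
rounded only for presentation. The within-year test is a Pearson
goodness-of-fit of the six class counts against equal proportions
(df = 5); the across-year test for one class is a chi-square on the
years × (class, not-class) table (df = years − 1). Both offer seeded
Monte-Carlo exact p-values; the chi-square is the default report. Source
analyses of this kind sometimes label such tests "Fisher's exact" while
reporting chi-square statistics; printed statistics assembled under
unknown conventions may therefore differ from the Pearson value computed
here, and this package always reports the standard statistic. Fork-length
comparisons use one-way ANOVA plus Tukey HSD (statsmodels).

## Reproducibility

Every stochastic stage takes an explicit seed; the pipeline derives all
stage seeds from one global seed via `SeedSequence`, stamps every output
with the seed and a configuration hash, and reruns are byte-identical.
The acceptance script scales its problem exactly as the design workflow
does (3,000 candidate loci; 1,000 simulated individuals per class for the
confusion matrix, 100 per class for power curves), which completes in
seconds on one CPU.

## Known limitations

* Six classes only; a B2 backcross individual and a B3 backcross are not
  distinguished (the latter is absorbed mostly into pure/backcross).
* The Gibbs sampler treats reference frequencies as informed by the
  references alone; test individuals do not update frequencies, which is
  slightly more conservative than a full joint sampler when cohorts are
  large and references tiny.
* The LD permutation test and the HWE exact test assume diploid,
  biallelic, autosomal markers; there is no multi-allelic or sex-linked
  support.
* VCF support covers biallelic SNP records with GT fields; other records
  are skipped with a warning.
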