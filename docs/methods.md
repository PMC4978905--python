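# Methods

## Study system and scope

The package analyzes multiparental introgression populations: several
families of near-isogenic lines (NILs), each derived from a different wild
donor accession crossed into a common recurrent inbred, genotyped with a
shared SNP panel and phenotyped in replicated multi-environment trials. The
implementation covers simulation of such populations, genotype preparation,
phenotype reduction, composite-trait construction, joint linkage QTL mapping,
and pleiotropy inference. It does not implement HMM ancestry inference,
REML/BLUP mixed models, composite interval mapping, dominance or epistasis
scans, or GWAS.

## Simulator

Each line descends from a single F1 by `n_backcross` backcrosses to the
recurrent parent (default 4) and `n_self` selfing generations (default 2),
tracked at the gamete level per chromosome: crossovers fall as a Poisson
process with rate 1 per 100 cM and no interference, so recombination between
loci follows the Haldane map function r(d) = (1 − e^(−2d/100))/2 (d in cM).
Marker alleles are read off the crossover mosaic exactly, with no per-locus
frequency approximation. Expected per-locus frequencies at BC₄S₂ are
1/32 donor-allele frequency, 1/64 heterozygotes and 3/128 donor homozygotes;
the test suite verifies these against an independent Markov-chain enumeration
of the breeding scheme.

Per population, a configurable fraction of markers (default 24%) is forced
monomorphic by fixing the donor founder allele to the recurrent state. This
emulates SNP panels ascertained across many donors — a given family
segregates at only ~3/4 of markers — and produces the "no introgression /
n.d." cases the mapper must handle. An optional `missing_rate` masks random
cells to NA to exercise imputation.

Planted QTL carry per-population donor-allele substitution effects (trait
units per allele); a line's genotypic value adds `effect × dosage` at the
marker nearest the planted position (positions are snapped to the map at
simulation time so the causal genotype is exact). Plot values add a
population offset (drawn once per population), an environment effect, a
line×environment interaction, a replicate-within-environment effect and a
residual, all Gaussian with configurable SDs; one record per
line × environment × replicate. The default study design is 10 populations ×
86 lines, 728 markers on 10 chromosomes, 2 environments with 3+2 replicates,
and six kernel traits (50-kernel weight, area, width, length, roundness,
perimeter) at realistic means and noise levels, with pleiotropic size/weight
QTL clusters, shape QTL of opposing sign through width, and one allelic-series
locus (mixed-sign population effects).

What the simulator does not emulate: selection during backcrossing,
segregation distortion, crossover interference, genotyping error, shared
pedigree between lines of one family (lines are simulated as independent
lineages from the F1), and non-Gaussian trait distributions. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to these real-data features.

## Genotype preparation

Dosages count donor alleles (0/1/2; heterozygotes are retained since BC₄S₂
lines keep residual heterozygosity). Missing calls are filled from the
nearest non-missing flanking markers on the same chromosome: agreeing flanks
copy through (exact in the dominant case of long introgression blocks);
disagreeing flanks get the conditional expectation of dosage under a
two-state Markov model of donor ancestry with Haldane transition
probabilities, treating the two gametes as independent with per-gamete donor
probability g/2 at each flank; chromosome ends copy the nearest value. Every
imputed cell is flagged and written to an audit table with the rule used, so
downstream users can filter expectation-imputed (fractional) dosages.
Fractional dosages are deliberately left unrounded — the mapping model treats
dosage as a covariate. The same conditional-expectation rule, evaluated at an
arbitrary cM position, provides pseudomarker dosages for the support-interval
scan; at an observed marker position it returns the observed column exactly.

## Phenotype reduction and heritability

Line means are best linear unbiased estimates from the fixed-effects model
`value ~ line + environment + replicate-within-environment`, with
environment and replicate effects under sum-to-zero constraints so line
coefficients sit on the original trait scale; with balanced data this equals
the per-line arithmetic mean. The line×environment interaction is absorbed
into the residual for mean estimation. A full REML/BLUP engine was
deliberately avoided: the fixed-effect solution is deterministic,
closed-form, and reproduces the balanced-data answer exactly.

Variance components come from the method of moments: σ²_err is the pooled
within-cell (line×environment) variance; the line×environment cell-mean ANOVA
gives σ²_GE = MS'_GE − σ²_err/R̃ and σ²_G = (MS'_G − MS'_GE)/E, with R̃ the
harmonic mean of replicates per environment (handles the 3+2 default design;
balanced data reproduce the textbook expected-mean-squares solution).
Negative estimates are truncated to zero and flagged. Entry-mean broad-sense
heritability is H² = σ²_G / (σ²_G + σ²_GE/E + σ²_err/(E·R̃)); with a single
environment σ²_GE is undefined and reported as zero with a flag.

Derived traits: factor form density FFD = (Wt50k/50 × 1000)/area in mg/mm²
(mean single-kernel weight over projected area — the maize-appropriate
variant of the wheat weight/(length×width) definition), and L/W =
length/width. Zero denominators yield missing values.

## Composite PC traits

PCA is performed on the Pearson correlation matrix of the line-mean traits
(standardized with ddof = 1), so eigenvalues sum to the trait count and the
Kaiser rule (retain eigenvalue ≥ 1, boundary included) applies. Eigenvector
sign is arbitrary; it is fixed so each component's largest-magnitude loading
is positive, making loadings and scores deterministic. The 50-kernel weight
is included among the PCA inputs by default alongside the size/shape traits.
Retained component scores are appended to the line means and mapped exactly
like measured traits.

## Joint linkage mapping

The design for one trait holds the response, a forced population block
(intercept + P−1 indicators, never subject to selection), and one candidate
group per marker with a dosage column for each population in which the marker
segregates ("markers nested within population"). Populations without dosage
variation at a marker are excluded from that marker's group — no test is run
where there is no introgression.

*Threshold.* The entry/exit p-value is calibrated by permutation: the trait
is shuffled among lines within each population (preserving the forced
population term; a global shuffle would inflate the null when populations
differ in mean), every candidate group is F-tested against the
population-only model, and the genome-wide minimum p is recorded; the
threshold is the empirical α-quantile (inverted-CDF, so 20 permutations at
α = 0.05 give the smallest minimum) of those minima. One calibrated
threshold serves as both entry and exit level.

*Selection.* Forward steps add the group with the smallest joint-F p-value if
below threshold (ties broken by chromosome, then position, then marker name);
after each addition, backward steps drop any included group whose p-value in
the current model rises to or above the exit threshold, worst first, to
convergence. Groups aliased with the current model (post-residualization rank
zero, judged relative to the group's own scale) are skipped. All F-tests run
via orthonormal-basis projections; the permutation scan residualizes every
group against the base model once and reduces each permutation to one matrix
product.

*Final model and effects.* The selected model is refit by OLS (aliased
columns dropped and logged). Each per-population dosage coefficient is the
additive effect of the donor allele relative to the recurrent parent, with SE
and two-sided t-test; non-segregating populations report "n.d.". Per-QTL
group p-values are drop-one F-tests; partial R² is the drop in explained sum
of squares as a fraction of the total.

*Support intervals.* From the peak outward in 0.1 cM steps, a pseudomarker
group (expected dosages nested in population) is added to the full model; the
boundary on each side is the first position where that group is significant
at P = 0.05 — territory the fitted QTL model does not explain — bounded by
chromosome ends. The peak pseudomarker is perfectly aliased with the fitted
peak and thus always inside. The inclusion rule is isolated behind a single
predicate so the opposite convention is a one-line change.

## Pleiotropy

For each trait pair, QTL on the same chromosome with intersecting closed
support intervals are tested by Pearson-correlating the two traits'
per-population effect estimates (all estimates, not only individually
significant ones) across populations where both are determined; pairs with
fewer than 3 shared populations are reported untestable rather than given a
meaningless p. Benjamini–Hochberg step-up at q = 0.05 is applied jointly
across all tested QTL pairs; the realized raw-p cutoff is data dependent and
reported in the output metadata, never hard-coded. Significant pairs are
aggregated into a trait-level network with edge weight = mean |r| and the
sign of the mean r.

## Numerical choices and degenerate inputs

Rank decisions use SVD with tolerance 1e−8 relative to the tested group's
norm; polymorphism uses a dosage-range tolerance of 1e−9; the BH cutoff with
no rejection is 0 (no flags); constant traits abort PCA with the trait named;
single-plot lines pass their value through with a warning; a line with an
entirely missing chromosome is left missing with a warning. One global seed
is expanded into per-stage substreams (map, genotypes, phenotypes,
permutations per trait) so stages are individually rerunnable and identical
seeds give byte-identical output files.

## Validation studies and problem sizes

`nilqtl.studies` packages the simulation studies used by the test suite and
the acceptance script, at sizes chosen to run in minutes on one core:
genome-wide type-I error (200 null runs, 2 populations × 100 lines, one
40-marker chromosome, 100 permutations each); additive-effect recovery and
support-interval coverage (100 runs, 5 populations × 100 lines, one QTL sized
from the BC₄S₂ dosage variance — Var(d) = 27/256 — to explain 10% of
line-mean variance); heritability recovery at planted H² ∈ {0.3, 0.7, 0.9}
(500 lines, 2 environments × 2 replicates; variance components averaged over
20 draws before forming the ratio, since a single draw's H² estimate has
Monte-Carlo sd ≈ 0.04 and a small downward Jensen bias, and the planted
GxE/residual split is 30/70 so zero-truncation stays inactive); pleiotropy
power (100 runs, 10 populations × 60 lines, proportional effect vectors) and
an FDR null (200 runs of overlapping QTL with independently drawn effects —
QTL with literally disjoint intervals produce no tested pairs at all, so the
null of interest is overlap without effect correlation). The acceptance
script runs the full pipeline at 10 populations × 40 lines with 300 markers
and 100 permutations per trait.

## Known limitations

Stepwise selection inherits the usual winner's-curse bias for marginal QTL;
effect estimates are unbiased only for well-powered loci. The
expectation-based imputation ignores phase ambiguity of double-heterozygous
flanks (gametes treated independently). Support intervals can span most of a
chromosome when introgressions are sparse, because distant pseudomarkers are
informative only through the few recombinant lines. The moment estimator of
variance components can be noticeably noisy below ~500 lines, and the
permutation threshold becomes conservative when a very strong QTL dominates
the trait variance (the shuffled trait then has heavy-tailed structure).
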