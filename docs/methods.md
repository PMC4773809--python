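# Methods

This note documents the models, estimators, numerical conventions and
deliberate design choices behind `ptc_popgen`, and what the synthetic
cohorts do and do not establish about real exome data.

## Synthetic cohort model

Genotypes are simulated under the Balding–Nichols (BN) model. Each locus
draws an ancestral derived-allele frequency *p* ~ Uniform(lo, hi)
(default 0.01–0.5; a stand-in for an unknown discovery-set frequency
spectrum, not a claim about one). Each of K populations draws its own
frequency p_i ~ Beta(p(1−F)/F, (1−p)(1−F)/F); at F=0 the Beta degenerates
and p_i = p exactly. Individuals are diploid with genotype ~
Binomial(2, p_i), so Hardy–Weinberg equilibrium holds within populations
by construction. BN was chosen because its differentiation parameter F is
precisely the quantity the Weir–Cockerham θ estimator targets, making
parameter recovery a meaningful end-to-end test of simulator + counting +
estimator together.

Defaults describe the reference study conditions used throughout the
tests: 4 populations × 100 diploids × 2,000 loci at F = 0.10. A fraction
of loci (default 10%) put the derived allele into the VCF REF column,
exercising the polarization flip (the reference genome is itself a
sample). Outgroup species carry the true ancestral allele independently
with probability `outgroup_concordance` (default 0.98 — primate
outgroups occasionally carry lineage-specific or recurrent mutations, so
perfect concordance would be unrealistically easy on the consensus rule).
The archaic carrier fraction defaults to 0.219, the fraction observed for
real PTC sets against Neanderthal/Denisovan genomes. Site-quality INFO
metrics (depth ~ Poisson(80), covered individuals ~ Binomial(n, 0.97),
mean read position ~ N(0.5, 0.08) clipped to [0,1]) emulate exome calling
metadata and pass the default filters at almost all sites; filter logic is
tested with adversarially constructed records instead.

A hierarchical variant (`simulate_grouped_populations`) nests BN twice:
group frequencies around the global ancestral frequency (F_between,
default 0.3), population frequencies around their group (F_within,
default 0.02). With F_between ≫ F_within the groups form well-separated
clusters in frequency space — the planted-partition design used to
validate PCA/HCA structure recovery.

Transcripts are fully coding: ATG, random sense codons, a single terminal
stop; 1–5 exons with random intron/intergenic filler; strands alternate
so both orientations are always exercised. Injected stop-gain SNVs mutate
a sense codon upstream of the native stop into TAA/TAG/TGA by one
substitution (strand-aware placement back onto the genome); decoy SNVs
(default 1:1) are substitutions verified *not* to create stops, giving
the classifier true negatives.

What the simulator does **not** emulate: linkage disequilibrium and
recombination, demographic history (bottlenecks, admixture, growth),
sequencing reads and genotyping error, indels and splice variants,
overlapping genes and UTRs. Passing tests therefore establish estimator
and pipeline correctness under idealized sampling, not robustness to
real-data artefacts; the site filters address the latter only at the
semantic level.

## Estimators and numerical conventions

**DAF.** 100·n_a/(n_A+n_a); missing genotypes reduce the denominator
(no imputation). Zero called alleles is an error, not 0. Selection
thresholds are strict inequalities (total DAF > 1% by default), applied
at variant level; gene-level selection uses the *sum* of a gene's
variant DAFs (uncapped — a gene with two 0.7% PTCs passes 1% at gene
level), which is why variant-level and gene-level gene lists differ.

**Ancestral inference.** Majority vote among available outgroup calls
(chimpanzee, gorilla, orangutan, human reference, equal weights), ≥2
informative calls required; ties, insufficient calls, or a consensus
matching neither VCF allele → unresolved, and unresolved sites are
excluded downstream with a logged count. Weighting the human reference
equally is a decision (the alternative — primates only — is obtainable by
dropping the column from the table).

**HWE.** Exact test conditional on allele counts: the heterozygote count
follows the Levene/Haldane distribution; the p-value sums probabilities
of tables as or less probable than the observed one (probability
ordering, two-sided), computed in log space with a ≤(1+1e−12) relative
guard on the "as probable" comparison. The test is conservative; its
type-I rate at α=0.05 is verified ≤0.06 over 5,000 simulated loci.

**Weir–Cockerham θ.** The published moment estimator for diploid
biallelic data from per-population (n_i, p_i, h_i): components a, b, c
with n̄, n_c, p̄, s², h̄ as defined there; θ = a/(a+b+c). Negative
estimates are reported, not truncated; globally monomorphic loci are NaN.
For sets of loci the package reports the ratio of summed components
Σa/Σ(a+b+c) (`multilocus_theta`): the per-locus ratio mean is biased
toward zero (Jensen), measurably so at F=0.3, while the ratio of sums
recovers the BN F to ~1% under the reference conditions.

**G family.** H_S = unweighted mean of 2p_i(1−p_i), H_T = 2p̄(1−p̄) from
the unweighted mean frequency — plain Nei gene diversities, chosen so the
closed-form anchors hold exactly (identical populations → G_ST=G'_ST=D=0;
two populations fixed for alternate alleles → H_S=0, H_T=0.5, all three
statistics 1). The small-sample-corrected within-population estimator
(2n/(2n−1))·2p̂q̂ is kept in `heterozygosity()` for reporting H_obs/H_exp;
Chao-type corrections used by some published software are deliberately
not replicated. Undefined cases are NaN: G_ST at H_T=0; G'_ST and D at
H_S=1.

**Bootstrap.** Percentile intervals from B resamples (default 1000,
level 0.95) of individuals with replacement *within* populations,
preserving sample sizes; seeded `numpy.random.Generator`, bit-reproducible.
Replicates with undefined statistics are dropped; >50% undefined reports
the interval as missing with a warning.

**Cohort comparison.** Two-sided Wilcoxon signed-rank on paired
per-variant DAFs; exact null for ≤25 non-zero differences, normal
approximation with tie correction beyond; all-tied input returns p=1
with a warning.

**Outliers.** OLS of per-locus F_ST on the predictor (total DAF or
heterozygosity; H_T is the default heterozygosity regressor, pooled
rather than mean-within-population — both are emitted). Residuals are
internally studentized (leverage-corrected); flag iff residual > +2,
one-sided — only unexpectedly *high* differentiation is of interest. An
independent flag marks raw F_ST strictly above the 95th percentile
(linear interpolation); it survives a degenerate regression.

**Structure.** PCA on populations-as-observations of the column-centered
DAF matrix via SVD, no unit-variance scaling (DAFs share units); sign
convention: each component's largest-|loading| entry is positive. HCA on
Euclidean distances with average linkage; the dendrogram is exported as
Newick with branch lengths from merge-height differences. Category DAF
totals are uncapped sums over member genes (they may exceed 100% — e.g. a
category of several near-fixed genes), with unmapped genes pooled under
"unclustered".

**Consequence.** Truncation measured against the ancestral ORF length L
(codons, including the native stop): PTC at codon k retains k−1 residues;
position% = 100(k−1)/L so a PTC at codon 1 sits at 0%. NMD: ≥2 exons and
the first base of the premature stop strictly more than 50 nt (mRNA
coordinates) upstream of the last exon–exon junction; the threshold is a
named parameter and outputs record the rule used. A PTC exactly 50 nt
upstream is predicted to escape.

**Filters.** The three site filters (total depth, covered individuals,
mean read-position band) have configurable thresholds with defaults
min_depth=10, min_covered=0.8×samples, band [0.1, 0.9] — conventional
exome QC values; the contract is the semantics, not the numbers. A
variant failing several filters is tallied once per failed filter;
retained+removed = input always. Missing metrics fail their filter in
strict mode (default) and pass in permissive mode.

**Coordinates.** VCF positions 1-based; BED12 0-based half-open; CDS
offsets 0-based in transcript orientation; codon indices 1-based.
Multi-allelic VCF records are split into biallelic records, each ALT
counted against everything else. Only SNV stop-gains are in scope
(indels/frameshifts and splice-site consequences are not).

## Problem sizes

The test-suite and acceptance script run everything at desk scale, chosen
as the smallest sizes at which the statistical properties are sharp:
F-recovery at 4×100×2,000 loci; HWE calibration at 5,000 loci × 200
diploids; truncation geometry at 10,000 ORFs; outlier recovery at 100
replicates of 501 loci × 14 populations × 50 diploids (14 matching the
population division differentiation scans conventionally use); structure
recovery at 16 populations × 300 loci. Cohort-scale discovery numbers
from consortium exomes are not reproducible from synthetic data and are
not targeted.

## Known limitations

- One transcript per locus is assumed when classifying (overlapping genes
  untested); the synthetic genome never produces overlaps.
- The NMD rule is the canonical last-junction heuristic; real NMD
  efficiency varies and single-exon escape is an approximation.
- G'_ST/D here are the per-locus closed forms; harmonic-mean multi-locus
  variants are not implemented.
- The archaic interface is a precomputed allele table; read-level
  filtering of ancient DNA (damage, contamination) is out of scope.
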