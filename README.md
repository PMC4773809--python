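# ptc-popgen

Population-genetic analysis of **premature termination codons (PTCs)** —
stop-gain variants that truncate proteins and, at high enough frequency,
mark candidate "human knockout" loci under recent selection. The package
implements the full analysis as a tested, reusable library: stop-gain
identification and site-quality filtering, primate-outgroup polarization
and derived allele frequencies, truncation/NMD consequence annotation,
multi-population differentiation statistics with bootstrap confidence
intervals, outlier and structure analyses, and archaic-genome overlap —
all exercisable end-to-end on synthetic cohorts with known truth.

## The statistics at the core

**Derived allele frequency.** With *n*<sub>A</sub> ancestral and
*n*<sub>a</sub> derived allele counts (missing genotypes excluded),
DAF(%) = 100·*n*<sub>a</sub>/(*n*<sub>A</sub>+*n*<sub>a</sub>). The
ancestral state is the majority vote of chimpanzee, gorilla, orangutan and
human-reference alleles (≥2 informative calls required; ties unresolved).

**Hardy–Weinberg.** Exact test conditional on allele counts (the
chi-square approximation fails at the rare nonsense-homozygote counts
typical of PTCs); expected genotype frequencies (p², 2pq, q²).

**Differentiation.** Weir–Cockerham variance components *a* (among
populations), *b* (among individuals within populations), *c* (within
individuals), with θ = a/(a+b+c) per locus and the multi-locus estimator
Σa/Σ(a+b+c). The G family uses Nei gene diversities H_S (mean within-
population 2p_iq_i) and H_T (2p̄q̄): G_ST = (H_T−H_S)/H_T, Hedrick's
G'_ST = G_ST(k−1+H_S)/((k−1)(1−H_S)), Jost's D = (k/(k−1))(H_T−H_S)/(1−H_S).
Percentile bootstrap CIs resample individuals within populations (B=1000
by default).

**Consequence.** A PTC at codon *k* of an *L*-codon ORF retains *k*−1
residues (truncation = 100·(L−(k−1))/L). NMD prediction follows the 50-nt
rule: ≥2 exons and the stop more than 50 nt upstream of the last
exon–exon junction.

**Synthetic cohorts.** The Balding–Nichols model: per-locus ancestral
frequency *p*, population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F),
genotypes Binomial(2, p_i). Its F parameter is exactly the quantity θ
estimates, so parameter recovery is an end-to-end correctness check.

## Worked example

```python
import ptc_popgen as pp
from ptc_popgen.stats import multilocus_theta

cfg = pp.SimulationConfig(n_populations=4, samples_per_population=100,
                          n_loci=2000, differentiation_F=0.10, seed=11)
ds = pp.simulate_populations(cfg)
n, p, h = pp.pop_allele_stats(ds.derived_dosages(), ds.pop_indices())
print(multilocus_theta(n, p, h))   # 0.1007 — recovers the simulated F = 0.10
```

Running the narrative scripts in `examples/` prints, among others:

```
stop-gains: 20 of 140 retained variants
  GENE2 codon 14/214 TCA->TAA  total DAF 4.25%
pooled genotypes (246, 87, 67): HWE exact p = 1.126e-18   # Wahlund effect
POP1 genotypes (91,9,0): HWE exact p = 1.000              # HWE within pops
theta = 0.487, 95% bootstrap CI = (0.412, 0.565), B=1000
planted locus flagged: True (studentized residual 16.2, threshold +2)
overlap fraction: 23.6% of 500 sites (simulated carrier rate 21.9%)
```

i.e. every injected stop-gain is recovered with its codon index, pooling
differentiated populations shows the expected heterozygote deficit while
each population is in HWE, and the planted high-F_ST locus stands out of
the F_ST ~ DAF regression.

A thin CLI wraps the pipeline: `ptc-popgen simulate --config sim.yaml
--out DIR --seed N` and `ptc-popgen all --config run.yaml` (stages:
simulate → call → polarize → annotate → stats → structure → archaic, with
TSV intermediates and a JSON manifest).

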