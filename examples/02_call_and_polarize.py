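"""Call stop-gains from a VCF, polarize against primate outgroups and
compute derived allele frequencies (run 01_simulate_cohort.py first).

DAF(%) = 100 * n_a / (n_A + n_a): the share of chromosomes carrying the
derived (mutated) allele, pooled and per population.
"""

from pathlib import Path

import ptc_popgen as pp

d = Path("scratch/example_cohort")
variants, panel = pp.load_variants(d / "genotypes.vcf", d / "panel.tsv")
retained, report = pp.apply_quality_filters(variants)
print("site filters:", dict(report.to_rows()))

transcripts = pp.read_bed12(d / "transcripts.bed")
genome = pp.read_fasta(d / "reference.fa")
calls = pp.classify_all(retained, transcripts, genome)
print(f"stop-gains: {len(calls)} of {len(retained)} retained variants")

outgroup = pp.OutgroupTable.read_tsv(d / "outgroup.tsv")
samples = panel.samples
polarized, unresolved = pp.polarize_calls(calls, outgroup, samples, panel)
print(f"polarized: {len(polarized)} (ancestral state unresolved: {unresolved})")

over_1pct = pp.select_by_threshold(polarized, min_total_daf=1.0)
print(f"total DAF > 1%: {len(over_1pct)} variants")
for p in over_1pct[:5]:
    print(f"  {p.gene_id} codon {p.codon_index}/{p.orf_codons} "
          f"{p.ref_codon}->{p.alt_codon}  total DAF {p.total_daf:.2f}%")
# Gene-level totals: a gene with several sub-threshold PTCs can still pass
# the 1% cut on its summed DAF.
genes = pp.aggregate_gene_daf(polarized)
print(f"genes over 1% by summed DAF: {(genes['total_daf'] > 1).sum()}")
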