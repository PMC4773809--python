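"""Synthetic-data generator: model contracts and reproducibility."""

import numpy as np
import pytest
from scipy.stats import binom

import ptc_popgen as pp
from ptc_popgen.simulate import ConfigurationError, PlacementError, stop_substitutions
from ptc_popgen.transcripts import STOP_CODONS


class TestBaldingNichols:
    def test_zero_F_degenerates_to_ancestral_frequency(self):
        cfg = pp.SimulationConfig(n_populations=3, samples_per_population=5,
                                  n_loci=20, differentiation_F=0.0, seed=1)
        ds = pp.simulate_populations(cfg)
        for pop in ds.panel.populations[1:]:
            np.testing.assert_array_equal(
                ds.truth[f"p_{pop}"], ds.truth[f"p_{ds.panel.populations[0]}"])

    def test_seeded_runs_identical(self):
        cfg = pp.SimulationConfig(n_populations=2, samples_per_population=10,
                                  n_loci=30, seed=7)
        a, b = pp.simulate_populations(cfg), pp.simulate_populations(cfg)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        assert a.loci.equals(b.loci) and a.truth.equals(b.truth)

    def test_sample_frequencies_converge_to_truth(self):
        # n=500 diploids: sample frequency within 3 binomial SEs of truth p_i
        cfg = pp.SimulationConfig(n_populations=2, samples_per_population=500,
                                  n_loci=100, differentiation_F=0.1, seed=3,
                                  derived_ref_fraction=0.0)
        ds = pp.simulate_populations(cfg)
        n, p, _ = pp.pop_allele_stats(ds.derived_dosages(), ds.pop_indices())
        for k, pop in enumerate(ds.panel.populations):
            truth = ds.truth[f"p_{pop}"].to_numpy()
            se = np.sqrt(truth * (1 - truth) / (2 * 500))
            assert (np.abs(p[k] - truth) <= 3 * se + 1e-12).mean() > 0.95

    def test_within_population_hwe_calibration(self):
        # genotype counts pass the exact HWE test at ~(1-alpha) of loci
        cfg = pp.SimulationConfig(n_populations=1, samples_per_population=100,
                                  n_loci=2000, differentiation_F=0.2, seed=5,
                                  ancestral_freq_range=(0.1, 0.5))
        ds = pp.simulate_populations(cfg)
        g = ds.derived_dosages()
        rej = 0
        tested = 0
        for j in range(ds.n_loci):
            d = g[:, j]
            counts = int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())
            if counts[1] + counts[2] == 0:
                continue
            tested += 1
            rej += pp.hwe_test(*counts).p_value < 0.05
        assert tested > 1500
        assert rej / tested <= 0.06  # exact test is conservative

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            pp.SimulationConfig(n_populations=0)
        with pytest.raises(ConfigurationError):
            pp.SimulationConfig(differentiation_F=1.0)
        with pytest.raises(ConfigurationError):
            pp.SimulationConfig(ancestral_freq_range=(0.5, 0.1))

    def test_missing_rate_and_dosage_domain(self):
        cfg = pp.SimulationConfig(n_populations=2, samples_per_population=50,
                                  n_loci=200, missing_rate=0.1, seed=9)
        ds = pp.simulate_populations(cfg)
        assert set(np.unique(ds.genotypes)) <= {-1, 0, 1, 2}
        miss = (ds.genotypes == -1).mean()
        assert 0.05 < miss < 0.15


class TestTranscripts:
    def test_minimal_single_exon_transcript(self):
        txs, genome = pp.simulate_transcripts(1, exons_per_gene=(1, 1),
                                              cds_codons=(10, 10), seed=2)
        (t,) = txs
        assert t.cds_length == 30 and t.n_exons == 1
        t.validate_orf(genome)

    def test_orf_has_exactly_one_terminal_stop(self):
        txs, genome = pp.simulate_transcripts(12, seed=4)
        for t in txs:
            cds = t.spliced_cds(genome)
            codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
            stops = [c for c in codons if c in STOP_CODONS]
            assert stops == [codons[-1]]

    def test_reverse_strand_extraction_oracle(self):
        # spliced CDS equals the reverse complement of the genomic pieces,
        # extracted independently of TranscriptModel
        txs, genome = pp.simulate_transcripts(6, exons_per_gene=(2, 4), seed=6)
        minus = [t for t in txs if t.strand == "-"]
        assert minus
        for t in minus:
            raw = "".join(genome[t.chrom][a:b] for a, b in t.exons)
            comp = raw.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            assert t.spliced_cds(genome) == comp

    def test_both_strands_represented(self):
        txs, _ = pp.simulate_transcripts(5, seed=8)
        assert {t.strand for t in txs} == {"+", "-"}

    def test_infeasible_constraints_rejected(self):
        with pytest.raises(ConfigurationError):
            pp.simulate_transcripts(1, cds_codons=(5, 5))

    def test_cds_coordinate_round_trip(self):
        txs, _ = pp.simulate_transcripts(4, exons_per_gene=(2, 5), seed=10)
        for t in txs:
            for cds_pos in (0, 1, t.cds_length // 2, t.cds_length - 1):
                assert t.genomic_to_cds(t.cds_to_genomic(cds_pos)) == cds_pos


class TestInjection:
    def test_trp_codon_mutable_to_two_stops(self):
        stops = {s for _, _, s in stop_substitutions("TGG")}
        assert stops == {"TGA", "TAG"}

    def test_sense_codon_far_from_stop_rejected(self):
        txs, genome = pp.simulate_transcripts(1, exons_per_gene=(1, 1),
                                              cds_codons=(30, 30), seed=1)
        cds = txs[0].spliced_cds(genome)
        hard = next(k for k in range(2, 30)
                    if not stop_substitutions(cds[3 * (k - 1):3 * k]))
        cfg = pp.SimulationConfig(n_populations=2, samples_per_population=5,
                                  n_loci=5, seed=2)
        ds = pp.simulate_populations(cfg)
        with pytest.raises(PlacementError):
            pp.inject_ptc_variants(txs, genome, ds,
                                   placement={txs[0].transcript_id: [hard]})

    def test_injected_variants_are_genuine_stop_gains(self, bundle):
        truth = bundle["truth"]
        genome = bundle["genome"]
        by_tx = {t.transcript_id: t for t in bundle["transcripts"]}
        for row in truth[truth.is_ptc].itertuples():
            t = by_tx[row.transcript_id]
            cds = t.spliced_cds(genome)
            cds_pos = t.genomic_to_cds(row.pos - 1)
            k = cds_pos // 3 + 1
            assert k == row.codon_index
            alt_t = row.alt if t.strand == "+" else row.alt.translate(
                str.maketrans("ACGT", "TGCA"))
            codon = list(cds[3 * (k - 1):3 * k])
            codon[cds_pos % 3] = alt_t
            assert "".join(codon) in STOP_CODONS

    def test_decoys_are_not_stop_gains(self, bundle, polarized_calls):
        truth = bundle["truth"]
        called = {(c.chrom, c.pos) for c in polarized_calls}
        decoys = {(r.chrom, r.pos) for r in truth[~truth.is_ptc].itertuples()}
        assert called.isdisjoint(decoys)


class TestOutgroupAndArchaic:
    def test_full_concordance_recovers_truth(self, bundle, polarized_calls):
        ds = bundle["dataset"]
        truth_anc = dict(zip(ds.loci["pos"], ds.truth["ancestral"]))
        for c in polarized_calls:
            assert c.ancestral == truth_anc[c.pos]

    def test_zero_carrier_fraction_gives_zero_overlap(self, polarized_calls, bundle):
        ds = bundle["dataset"]
        table = pp.simulate_archaic_calls(ds, 0.0, seed=21)
        tmp = bundle["paths"]["archaic"].parent / "arch0.tsv"
        table.to_csv(tmp, sep="\t", index=False)
        res = pp.overlap_fraction(polarized_calls, pp.ArchaicTable.read_tsv(tmp))
        assert res.fraction == 0.0 and res.union_detected == 0

    def test_carrier_fraction_within_binomial_bounds(self):
        cfg = pp.SimulationConfig(n_populations=2, samples_per_population=5,
                                  n_loci=400, seed=17)
        ds = pp.simulate_populations(cfg)
        pp.simulate_archaic_calls(ds, 0.25, seed=18)
        k = int(ds.truth["archaic_carrier"].sum())
        lo, hi = binom.ppf([0.005, 0.995], 400, 0.25)
        assert lo <= k <= hi


class TestRoundTrip:
    def test_vcf_round_trip_reproduces_genotypes(self, bundle):
        ds = bundle["dataset"]
        variants, _ = pp.load_variants(bundle["paths"]["vcf"], bundle["paths"]["panel"])
        assert len(variants) == ds.n_loci
        mat = np.stack([v.dosages for v in variants], axis=1)
        np.testing.assert_array_equal(mat, ds.genotypes)

    def test_panel_round_trip(self, bundle):
        panel = pp.PanelMap.read_tsv(bundle["paths"]["panel"])
        ds = bundle["dataset"]
        assert panel.samples == ds.samples
        assert len(panel.populations) == 3

    def test_bed12_round_trip(self, bundle, tmp_path):
        txs = bundle["transcripts"]
        back = pp.read_bed12(bundle["paths"]["bed"])
        assert len(back) == len(txs)
        for t0, t1 in zip(txs, back):
            assert (t0.exons, t0.strand, t0.gene_id) == (t1.exons, t1.strand, t1.gene_id)

    def test_fasta_round_trip(self, bundle):
        genome = pp.read_fasta(bundle["paths"]["fasta"])
        assert genome == bundle["genome"]
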