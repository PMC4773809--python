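import numpy as np
import pytest
from hypothesis import settings

import ptc_popgen as pp

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A complete small synthetic cohort written to disk and reloaded.

    20 genes (both strands), 3 populations x 20 diploids, 40 intergenic
    background loci plus one injected stop-gain and one decoy SNV per
    gene; fully concordant outgroups, 25% archaic carriers.
    """
    out = tmp_path_factory.mktemp("bundle")
    transcripts, genome = pp.simulate_transcripts(20, exons_per_gene=(1, 5), seed=11)
    cfg = pp.SimulationConfig(
        n_populations=3, samples_per_population=20, n_loci=40,
        differentiation_F=0.1, outgroup_concordance=1.0,
        archaic_carrier_fraction=0.25, seed=12,
    )
    dataset = pp.simulate_populations(cfg)
    dataset, truth = pp.inject_ptc_variants(transcripts, genome, dataset,
                                            decoy_ratio=1.0, seed=13)
    outgroup = pp.simulate_outgroup_alleles(dataset, 1.0, seed=14)
    archaic = pp.simulate_archaic_calls(dataset, 0.25, seed=15)
    paths = pp.write_dataset(dataset, out, transcripts, genome, outgroup, archaic)
    return {
        "transcripts": transcripts, "genome": genome, "dataset": dataset,
        "truth": truth, "outgroup": outgroup, "archaic": archaic, "paths": paths,
    }


@pytest.fixture(scope="session")
def polarized_calls(bundle):
    """Stop-gain calls classified from the bundle VCF and truth-polarized."""
    variants, panel = pp.load_variants(bundle["paths"]["vcf"], bundle["paths"]["panel"])
    retained, _ = pp.apply_quality_filters(variants, 0, 0, (0.0, 1.0))
    calls = pp.classify_all(retained, bundle["transcripts"], bundle["genome"])
    outgroup = pp.OutgroupTable.read_tsv(bundle["paths"]["outgroup"])
    polarized, unresolved = pp.polarize_calls(
        calls, outgroup, bundle["dataset"].samples, panel)
    assert unresolved == 0
    return polarized


def make_counts(rng, n_pops=3, n_max=60):
    """Random valid per-population genotype counts."""
    out = {}
    for k in range(n_pops):
        n = int(rng.integers(2, n_max))
        naa = int(rng.integers(0, n + 1))
        nab = int(rng.integers(0, n - naa + 1))
        out[f"POP{k+1}"] = pp.PopAlleleCounts(
            n_AA=n - naa - nab, n_Aa=nab, n_aa=naa)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(42)
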