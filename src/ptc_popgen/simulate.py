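"""Synthetic cohort generator for the PTC population analysis.

Emulates the inputs the pipeline consumes in production -- a multi-sample
VCF of exome genotypes, transcript models with reference sequence, a
population panel, a primate-outgroup allele table and an archaic allele
table -- with full truth tracking, so every downstream stage can be tested
against known answers.

The allele-frequency model is Balding-Nichols: each locus has an ancestral
derived-allele frequency ``p`` and each population draws its own frequency
from ``Beta(p(1-F)/F, (1-p)(1-F)/F)``. The differentiation parameter ``F``
of this model is exactly the quantity the Weir-Cockerham theta estimator
targets, which makes parameter recovery a meaningful end-to-end check.
Genotypes are binomial(2, p_i) within populations, i.e. Hardy-Weinberg
equilibrium holds within each population by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import PanelMap
from .transcripts import (
    STOP_CODONS,
    TranscriptModel,
    reverse_complement,
    write_bed12,
    write_fasta,
)

BASES = "ACGT"
SENSE_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class ConfigurationError(ValueError):
    """Invalid simulation parameters."""


class PlacementError(ValueError):
    """A requested codon cannot be mutated to a stop by one substitution."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the reference study conditions used throughout the
    test-suite: 4 populations of 100 diploids, 2,000 biallelic loci,
    Balding-Nichols differentiation F = 0.10, ancestral derived-allele
    frequencies uniform on (0.01, 0.5), primate outgroups concordant with
    the true ancestral state at 98% of draws, and 21.9% of loci carried by
    at least one archaic genome.
    """

    n_populations: int = 4
    samples_per_population: int = 100
    n_loci: int = 2000
    differentiation_F: float = 0.10
    ancestral_freq_range: tuple[float, float] = (0.01, 0.5)
    outgroup_concordance: float = 0.98
    archaic_carrier_fraction: float = 0.219
    derived_ref_fraction: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1 or self.samples_per_population < 1 or self.n_loci < 1:
            raise ConfigurationError("counts must be >= 1")
        if not 0.0 <= self.differentiation_F < 1.0:
            raise ConfigurationError("differentiation_F must lie in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError("ancestral_freq_range must be well-ordered within (0,1)")
        for name in ("outgroup_concordance", "archaic_carrier_fraction", "missing_rate",
                     "derived_ref_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")


@dataclass
class GenotypeDataset:
    """Genotypes plus truth for a synthetic cohort.

    ``genotypes`` holds ALT-allele dosages (samples x loci, int8; -1 =
    missing). ``loci`` is one row per site (VCF-style 1-based ``pos``) with
    the site-quality INFO metrics. ``truth`` parallels ``loci`` and records
    the ancestral/derived alleles, per-population true derived frequencies
    (columns ``p_<pop>``) and archaic carrier status.
    """

    samples: list[str]
    panel: PanelMap
    loci: pd.DataFrame
    genotypes: np.ndarray
    truth: pd.DataFrame
    config: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.samples), len(self.loci)):
            raise ValueError("genotype matrix does not match samples x loci")
        if len(self.truth) != len(self.loci):
            raise ValueError("truth table does not match loci")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def derived_dosages(self) -> np.ndarray:
        """Dosage matrix of the *derived* allele (truth polarization)."""
        flip = (self.truth["ancestral"].to_numpy() == self.loci["alt"].to_numpy())
        g = self.genotypes.astype(np.int8).copy()
        flipped = np.where(g[:, flip] >= 0, 2 - g[:, flip], -1).astype(np.int8)
        g[:, flip] = flipped
        return g

    def pop_indices(self) -> dict[str, list[int]]:
        return self.panel.sample_indices_by_population(self.samples)


def balding_nichols_freqs(
    p: np.ndarray, F: float, n_populations: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-population derived-allele frequencies under Balding-Nichols.

    Returns an (n_populations, n_loci) array. For F = 0 the Beta
    degenerates and every population's frequency equals the ancestral one.
    Loci with ancestral frequency exactly 0 or 1 stay fixed.
    """
    p = np.asarray(p, dtype=float)
    if F == 0.0:
        return np.broadcast_to(p, (n_populations, p.size)).copy()
    scale = (1.0 - F) / F
    out = np.empty((n_populations, p.size))
    interior = (p > 0.0) & (p < 1.0)
    a = p[interior] * scale
    b = (1.0 - p[interior]) * scale
    out[:, interior] = rng.beta(a, b, size=(n_populations, interior.sum()))
    out[:, ~interior] = p[~interior]
    return out


def _site_metrics(n_loci: int, n_samples: int, rng: np.random.Generator) -> pd.DataFrame:
    """Site-quality INFO fields emulating exome calling metadata: total
    read depth, count of individuals with coverage, and the mean fractional
    position of variant-supporting bases along their reads."""
    depth = rng.poisson(80, size=n_loci)
    covered = rng.binomial(n_samples, 0.97, size=n_loci)
    read_pos = np.clip(rng.normal(0.5, 0.08, size=n_loci), 0.0, 1.0)
    return pd.DataFrame({"depth": depth, "covered": covered, "read_pos": read_pos.round(4)})


def _draw_snp_alleles(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    anc = rng.integers(0, 4, size=n)
    der = (anc + rng.integers(1, 4, size=n)) % 4
    bases = np.array(list(BASES))
    return bases[anc], bases[der]


def _make_panel(pop_names: list[str], samples_per_pop: int,
                groups: dict[str, str] | None = None) -> tuple[list[str], PanelMap]:
    samples: list[str] = []
    population_of: dict[str, str] = {}
    for pop in pop_names:
        for i in range(samples_per_pop):
            s = f"{pop}_S{i:04d}"
            samples.append(s)
            population_of[s] = pop
    super_group_of = dict(groups) if groups else {p: p for p in pop_names}
    return samples, PanelMap(population_of, super_group_of)


def simulate_populations(config: SimulationConfig,
                         groups: dict[str, str] | None = None) -> GenotypeDataset:
    """Simulate genotypes for K populations under Balding-Nichols.

    Per locus: ancestral derived frequency p ~ Uniform(ancestral_freq_range);
    population frequencies p_i ~ BN(p, F); genotypes ~ Binomial(2, p_i) per
    diploid. A ``derived_ref_fraction`` of loci put the derived allele into
    the VCF REF column (the reference genome is itself a sample), which
    exercises the polarization flip downstream. Fully reproducible given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    pop_names = [f"POP{i + 1}" for i in range(config.n_populations)]
    samples, panel = _make_panel(pop_names, config.samples_per_population, groups)

    lo, hi = config.ancestral_freq_range
    p = rng.uniform(lo, hi, size=config.n_loci)
    pop_freqs = balding_nichols_freqs(p, config.differentiation_F,
                                      config.n_populations, rng)

    n_samples = len(samples)
    derived = np.empty((n_samples, config.n_loci), dtype=np.int8)
    for k in range(config.n_populations):
        block = slice(k * config.samples_per_population,
                      (k + 1) * config.samples_per_population)
        derived[block] = rng.binomial(
            2, pop_freqs[k], size=(config.samples_per_population, config.n_loci)
        ).astype(np.int8)

    anc_base, der_base = _draw_snp_alleles(config.n_loci, rng)
    ref_is_derived = rng.random(config.n_loci) < config.derived_ref_fraction
    ref = np.where(ref_is_derived, der_base, anc_base)
    alt = np.where(ref_is_derived, anc_base, der_base)
    genotypes = derived.copy()
    genotypes[:, ref_is_derived] = 2 - genotypes[:, ref_is_derived]

    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes[mask] = -1

    pos = 1_000_000 + 10 * np.arange(config.n_loci)  # 1-based, intergenic region
    loci = pd.DataFrame({"chrom": "chr1", "pos": pos, "ref": ref, "alt": alt})
    loci = pd.concat([loci, _site_metrics(config.n_loci, n_samples, rng)], axis=1)

    truth = pd.DataFrame({
        "ancestral": anc_base,
        "derived": der_base,
        "archaic_carrier": False,
        "is_ptc": False,
        "transcript_id": "",
        "gene_id": "",
        "codon_index": 0,
    })
    for k, popname in enumerate(pop_names):
        truth[f"p_{popname}"] = pop_freqs[k]

    return GenotypeDataset(samples, panel, loci, genotypes, truth, config)


def simulate_grouped_populations(
    n_groups: int = 4,
    pops_per_group: int = 4,
    samples_per_population: int = 30,
    n_loci: int = 300,
    F_between: float = 0.3,
    F_within: float = 0.02,
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95),
    seed: int = 0,
) -> GenotypeDataset:
    """Hierarchical variant of :func:`simulate_populations`.

    Group-level frequencies are Balding-Nichols draws around the global
    ancestral frequency (parameter ``F_between``); populations then draw
    around their group frequency (``F_within``). With F_between >> F_within
    the groups form well-separated clusters in allele-frequency space --
    the planted-partition design used to validate structure recovery.
    """
    rng = np.random.default_rng(seed)
    pop_names: list[str] = []
    group_of: dict[str, str] = {}
    for g in range(n_groups):
        for j in range(pops_per_group):
            name = f"G{g + 1}P{j + 1}"
            pop_names.append(name)
            group_of[name] = f"GRP{g + 1}"
    samples, panel = _make_panel(pop_names, samples_per_population, group_of)

    lo, hi = ancestral_freq_range
    p = rng.uniform(lo, hi, size=n_loci)
    group_freqs = balding_nichols_freqs(p, F_between, n_groups, rng)
    # keep Beta parameters finite when a group drifts to fixation
    group_freqs = np.clip(group_freqs, 1e-4, 1 - 1e-4)

    pop_freqs = np.empty((len(pop_names), n_loci))
    for g in range(n_groups):
        pop_freqs[g * pops_per_group:(g + 1) * pops_per_group] = (
            balding_nichols_freqs(group_freqs[g], F_within, pops_per_group, rng)
        )

    derived = np.empty((len(samples), n_loci), dtype=np.int8)
    for k in range(len(pop_names)):
        block = slice(k * samples_per_population, (k + 1) * samples_per_population)
        derived[block] = rng.binomial(
            2, pop_freqs[k], size=(samples_per_population, n_loci)
        ).astype(np.int8)

    anc_base, der_base = _draw_snp_alleles(n_loci, rng)
    pos = 1_000_000 + 10 * np.arange(n_loci)
    loci = pd.DataFrame({"chrom": "chr1", "pos": pos, "ref": anc_base, "alt": der_base})
    loci = pd.concat([loci, _site_metrics(n_loci, len(samples), rng)], axis=1)
    truth = pd.DataFrame({
        "ancestral": anc_base, "derived": der_base, "archaic_carrier": False,
        "is_ptc": False, "transcript_id": "", "gene_id": "", "codon_index": 0,
    })
    for k, popname in enumerate(pop_names):
        truth[f"p_{popname}"] = pop_freqs[k]
    return GenotypeDataset(samples, panel, loci, derived, truth, None)


# -- transcripts ----------------------------------------------------------

def simulate_transcripts(
    n_genes: int,
    exons_per_gene: tuple[int, int] = (1, 5),
    cds_codons: tuple[int, int] = (50, 300),
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[list[TranscriptModel], dict[str, str]]:
    """Generate transcripts with in-frame ORFs plus the reference genome.

    Each CDS starts with ATG, ends with a single stop codon and contains no
    internal stop. Strands alternate so both orientations are always
    represented. Returns (transcripts, genome) where the genome contains
    intronic and intergenic filler sequence around the exons.
    """
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    if cds_codons[0] < 10 or cds_codons[0] > cds_codons[1]:
        raise ConfigurationError("cds_codons lower bound must be >= 10 and <= upper")
    if exons_per_gene[0] < 1 or exons_per_gene[0] > exons_per_gene[1]:
        raise ConfigurationError("exons_per_gene interval ill-formed")

    rng = np.random.default_rng(seed)
    pieces: list[str] = []
    cursor = 0

    def emit(seq: str) -> None:
        nonlocal cursor
        pieces.append(seq)
        cursor += len(seq)

    def filler(n: int) -> str:
        return "".join(rng.choice(list(BASES), size=n))

    transcripts: list[TranscriptModel] = []
    emit(filler(100))
    for i in range(n_genes):
        n_codons = int(rng.integers(cds_codons[0], cds_codons[1] + 1))
        body = rng.choice(SENSE_CODONS, size=n_codons - 2)
        cds = "ATG" + "".join(body) + str(rng.choice(STOP_CODONS))
        strand = "+" if i % 2 == 0 else "-"
        m_max = min(exons_per_gene[1], len(cds))
        m = int(rng.integers(exons_per_gene[0], m_max + 1))
        if m > 1:
            cuts = np.sort(rng.choice(np.arange(1, len(cds)), size=m - 1, replace=False))
            t_lengths = np.diff(np.concatenate([[0], cuts, [len(cds)]])).tolist()
        else:
            t_lengths = [len(cds)]
        g_lengths = t_lengths[::-1] if strand == "-" else t_lengths
        genomic_cds = reverse_complement(cds) if strand == "-" else cds

        exons: list[tuple[int, int]] = []
        offset = 0
        for j, L in enumerate(g_lengths):
            exons.append((cursor, cursor + L))
            emit(genomic_cds[offset:offset + L])
            offset += L
            if j < len(g_lengths) - 1:
                emit(filler(int(rng.integers(30, 101))))
        transcripts.append(
            TranscriptModel(f"GENE{i + 1}", f"TX{i + 1}", chrom, strand, exons)
        )
        emit(filler(int(rng.integers(150, 251))))

    genome = {chrom: "".join(pieces)}
    for t in transcripts:
        t.validate_orf(genome)
    return transcripts, genome


def stop_substitutions(codon: str) -> list[tuple[int, str, str]]:
    """All (offset, alt_base, stop_codon) single substitutions turning
    ``codon`` into a stop. Empty if the codon is not one step from a stop."""
    out = []
    for off in range(3):
        for base in BASES:
            if base == codon[off]:
                continue
            mutated = codon[:off] + base + codon[off + 1:]
            if mutated in STOP_CODONS:
                out.append((off, base, mutated))
    return out


def inject_ptc_variants(
    transcripts: list[TranscriptModel],
    genome: dict[str, str],
    dataset: GenotypeDataset,
    placement: dict[str, list[int]] | None = None,
    decoy_ratio: float = 1.0,
    seed: int = 0,
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Add stop-gain SNVs (and non-PTC decoys) inside transcript CDSs.

    ``placement`` maps transcript_id -> 1-based codon indices; when None,
    one random mutable codon upstream of the native stop is chosen per
    transcript. Decoy SNVs (missense/synonymous, never stop-creating) are
    added at ``decoy_ratio`` per injected PTC so the stop-gain classifier
    sees true negatives. Injected sites always have REF = the (ancestral)
    genome base; population frequencies are fresh Balding-Nichols draws
    under the dataset's config. Returns the extended dataset plus a truth
    table of the injected sites.
    """
    cfg = dataset.config or SimulationConfig(
        n_populations=len(dataset.panel.populations),
        samples_per_population=max(
            len(v) for v in dataset.pop_indices().values()
        ),
    )
    rng = np.random.default_rng(seed)
    by_id = {t.transcript_id: t for t in transcripts}
    if placement is None:
        placement = {}
        for t in transcripts:
            cds = t.spliced_cds(genome)
            candidates = [
                k for k in range(1, t.orf_codons)
                if stop_substitutions(cds[3 * (k - 1):3 * k])
            ]
            placement[t.transcript_id] = [int(rng.choice(candidates))]

    rows = []
    for tid, codons in placement.items():
        t = by_id[tid]
        cds = t.spliced_cds(genome)
        for k in codons:
            if not 1 <= k < t.orf_codons:
                raise PlacementError(f"{tid}: codon {k} not upstream of the native stop")
            codon = cds[3 * (k - 1):3 * k]
            subs = stop_substitutions(codon)
            if not subs:
                raise PlacementError(
                    f"{tid}: codon {k} ({codon}) not mutable to a stop by one substitution"
                )
            off, alt_base, _stop = subs[rng.integers(len(subs))]
            rows.append(_cds_snv_row(t, cds, 3 * (k - 1) + off, alt_base, genome,
                                     is_ptc=True, codon_index=k))

    n_decoys = int(round(decoy_ratio * len(rows)))
    decoy_rows = []
    attempts = 0
    while len(decoy_rows) < n_decoys and attempts < 100 * max(n_decoys, 1):
        attempts += 1
        t = by_id[str(rng.choice(list(by_id)))]
        cds = t.spliced_cds(genome)
        cds_pos = int(rng.integers(0, 3 * (t.orf_codons - 1)))  # upstream of native stop
        codon_i = cds_pos // 3
        codon = cds[3 * codon_i:3 * codon_i + 3]
        alt_base = str(rng.choice([b for b in BASES if b != cds[cds_pos]]))
        off = cds_pos % 3
        if codon[:off] + alt_base + codon[off + 1:] in STOP_CODONS:
            continue  # would be a stop-gain; decoys must be negatives
        row = _cds_snv_row(t, cds, cds_pos, alt_base, genome,
                           is_ptc=False, codon_index=codon_i + 1)
        if any(r["pos"] == row["pos"] for r in rows + decoy_rows):
            continue
        decoy_rows.append(row)
    rows += decoy_rows

    truth_table = pd.DataFrame(rows)
    new_ds = _append_sites(dataset, truth_table, cfg, rng)
    return new_ds, truth_table


def _cds_snv_row(t: TranscriptModel, cds: str, cds_pos: int, alt_base: str,
                 genome: dict[str, str], is_ptc: bool, codon_index: int) -> dict:
    pos0 = t.cds_to_genomic(cds_pos)
    ref_g = genome[t.chrom][pos0]
    alt_g = alt_base if t.strand == "+" else alt_base.translate(_COMPLEMENT)
    return {
        "chrom": t.chrom, "pos": pos0 + 1, "ref": ref_g, "alt": alt_g,
        "transcript_id": t.transcript_id, "gene_id": t.gene_id,
        "codon_index": codon_index, "is_ptc": is_ptc,
    }


def _append_sites(dataset: GenotypeDataset, sites: pd.DataFrame,
                  cfg: SimulationConfig, rng: np.random.Generator) -> GenotypeDataset:
    """Append new biallelic sites with fresh Balding-Nichols genotypes."""
    n_new = len(sites)
    pops = dataset.panel.populations
    idx = dataset.pop_indices()
    lo, hi = cfg.ancestral_freq_range
    p = rng.uniform(lo, hi, size=n_new)
    pop_freqs = balding_nichols_freqs(p, cfg.differentiation_F, len(pops), rng)
    geno = np.empty((dataset.n_samples, n_new), dtype=np.int8)
    for k, pop in enumerate(pops):
        rows = idx[pop]
        geno[rows] = rng.binomial(2, pop_freqs[k], size=(len(rows), n_new)).astype(np.int8)

    loci_new = sites[["chrom", "pos", "ref", "alt"]].copy()
    metrics = _site_metrics(n_new, dataset.n_samples, rng)
    loci_new = pd.concat([loci_new.reset_index(drop=True), metrics], axis=1)

    truth_new = pd.DataFrame({
        "ancestral": sites["ref"].to_numpy(),  # injected REF is the ancestral base
        "derived": sites["alt"].to_numpy(),
        "archaic_carrier": False,
        "is_ptc": sites["is_ptc"].to_numpy(),
        "transcript_id": sites["transcript_id"].to_numpy(),
        "gene_id": sites["gene_id"].to_numpy(),
        "codon_index": sites["codon_index"].to_numpy(),
    })
    for k, pop in enumerate(pops):
        truth_new[f"p_{pop}"] = pop_freqs[k]

    loci = pd.concat([dataset.loci, loci_new], ignore_index=True)
    truth = pd.concat([dataset.truth, truth_new], ignore_index=True)
    genotypes = np.concatenate([dataset.genotypes, geno], axis=1)
    order = np.argsort(loci["pos"].to_numpy(), kind="stable")
    return GenotypeDataset(
        dataset.samples, dataset.panel,
        loci.iloc[order].reset_index(drop=True),
        genotypes[:, order],
        truth.iloc[order].reset_index(drop=True),
        cfg,
    )


# -- outgroup and archaic tables ------------------------------------------

def simulate_outgroup_alleles(dataset: GenotypeDataset, concordance: float,
                              seed: int = 0, dropout: float = 0.0) -> pd.DataFrame:
    """Primate outgroup table: chimp/gorilla/orangutan each carry the true
    ancestral allele with probability ``concordance`` (else the derived
    allele) independently; ``human_ref`` is the VCF REF allele. ``dropout``
    is the per-species probability of a missing call ('.')."""
    rng = np.random.default_rng(seed)
    n = dataset.n_loci
    anc = dataset.truth["ancestral"].to_numpy()
    der = dataset.truth["derived"].to_numpy()
    cols = {}
    for species in ("chimp", "gorilla", "orangutan"):
        allele = np.where(rng.random(n) < concordance, anc, der)
        if dropout > 0:
            allele = np.where(rng.random(n) < dropout, ".", allele)
        cols[species] = allele
    return pd.DataFrame({
        "chrom": dataset.loci["chrom"],
        "pos": dataset.loci["pos"],
        "ref": dataset.loci["ref"],
        "alt": dataset.loci["alt"],
        **cols,
        "human_ref": dataset.loci["ref"],
    })


def simulate_archaic_calls(dataset: GenotypeDataset, carrier_fraction: float,
                           seed: int = 0) -> pd.DataFrame:
    """Archaic allele table: a ``carrier_fraction`` of loci carry the derived
    allele in at least one archaic genome (Neanderthal/Denisovan or both);
    the rest show only the ancestral allele. Updates
    ``dataset.truth['archaic_carrier']`` in place."""
    rng = np.random.default_rng(seed)
    n = dataset.n_loci
    carrier = rng.random(n) < carrier_fraction
    anc = dataset.truth["ancestral"].to_numpy()
    der = dataset.truth["derived"].to_numpy()
    which = rng.integers(0, 3, size=n)  # 0: Nea only, 1: Den only, 2: both
    nea = np.where(carrier & (which != 1), der, anc)
    den = np.where(carrier & (which != 0), der, anc)
    dataset.truth["archaic_carrier"] = carrier
    return pd.DataFrame({
        "chrom": dataset.loci["chrom"],
        "pos": dataset.loci["pos"],
        "alleles_neanderthal": nea,
        "alleles_denisovan": den,
    })


# -- serialization --------------------------------------------------------

def write_vcf(dataset: GenotypeDataset, path: str | Path) -> None:
    """Write genotypes as plain VCF 4.2 with DP / NC / ARP INFO fields
    (site depth, covered-individual count, mean fractional read position)."""
    gt_str = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(dataset.loci["chrom"]):
            length = int(dataset.loci.loc[dataset.loci["chrom"] == chrom, "pos"].max()) + 1000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##INFO=<ID=NC,Number=1,Type=Integer,'
                 'Description="Individuals with coverage at the site">\n')
        fh.write('##INFO=<ID=ARP,Number=1,Type=Float,'
                 'Description="Mean fractional position of variant alleles along reads">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(dataset.samples) + "\n")
        G = dataset.genotypes
        for j, row in enumerate(dataset.loci.itertuples(index=False)):
            info = f"DP={row.depth};NC={row.covered};ARP={row.read_pos:g}"
            gts = "\t".join(gt_str[int(g)] for g in G[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                     f"{info}\tGT\t{gts}\n")


def write_dataset(
    dataset: GenotypeDataset,
    out_dir: str | Path,
    transcripts: list[TranscriptModel] | None = None,
    genome: dict[str, str] | None = None,
    outgroup: pd.DataFrame | None = None,
    archaic: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the complete input bundle (VCF, panel TSV, optional BED12 +
    FASTA + outgroup/archaic TSVs + truth TSV) and return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["vcf"] = out / "genotypes.vcf"
    write_vcf(dataset, paths["vcf"])
    paths["panel"] = out / "panel.tsv"
    dataset.panel.write_tsv(paths["panel"])
    paths["truth"] = out / "truth.tsv"
    dataset.truth.assign(chrom=dataset.loci["chrom"], pos=dataset.loci["pos"]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    if transcripts is not None:
        paths["bed"] = out / "transcripts.bed"
        write_bed12(transcripts, paths["bed"])
    if genome is not None:
        paths["fasta"] = out / "reference.fa"
        write_fasta(genome, paths["fasta"])
    if outgroup is not None:
        paths["outgroup"] = out / "outgroup.tsv"
        outgroup.to_csv(paths["outgroup"], sep="\t", index=False)
    if archaic is not None:
        paths["archaic"] = out / "archaic.tsv"
        archaic.to_csv(paths["archaic"], sep="\t", index=False)
    return paths
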