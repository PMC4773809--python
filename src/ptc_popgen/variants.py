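"""Variant loading, site-quality filtering and stop-gain classification.

The filters mirror standard exome QC on the site level: total read depth,
number of individuals with coverage at the site, and the mean fractional
position of variant-supporting alleles along their reads (variants called
only near read ends are enriched for artefacts). Thresholds are
configurable; the contract is the filter semantics, not the numbers.

Stop-gain (PTC) classification substitutes the ALT base into the spliced
CDS (strand-aware) and asks whether an in-frame sense codon upstream of
the native stop becomes TAA/TAG/TGA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .panel import PanelMap
from .transcripts import STOP_CODONS, TranscriptModel

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class DataIntegrityError(ValueError):
    """Inputs contradict each other (e.g. VCF REF != reference genome base)."""


@dataclass
class VariantRecord:
    """One biallelic SNV with per-sample ALT dosages and site metrics."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    dosages: np.ndarray  # int8 per sample; -1 = missing
    depth: float | None = None
    covered: int | None = None
    read_pos: float | None = None  # mean fractional position in [0,1]

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: REF == ALT")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"{self.chrom}:{self.pos}: only SNVs are supported")

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class FilterReport:
    """Per-filter removal tallies. A variant failing several filters is
    counted once per failed filter; retained + removed = input."""

    n_input: int = 0
    n_retained: int = 0
    failed_depth: int = 0
    failed_covered: int = 0
    failed_read_pos: int = 0

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    def to_rows(self) -> list[tuple[str, int]]:
        return [
            ("input", self.n_input),
            ("failed_depth", self.failed_depth),
            ("failed_covered_individuals", self.failed_covered),
            ("failed_read_position", self.failed_read_pos),
            ("removed", self.n_removed),
            ("retained", self.n_retained),
        ]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("filter\tcount\n")
            for name, count in self.to_rows():
                fh.write(f"{name}\t{count}\n")


@dataclass
class PtcCall:
    """A classified stop-gain variant.

    Polarization (ancestral/derived, per-population counts, DAF) is filled
    in by the :mod:`~ptc_popgen.polarize` stage.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    transcript_id: str
    strand: str
    codon_index: int          # 1-based PTC codon k
    orf_codons: int           # ORF length L (incl. native stop)
    ref_codon: str
    alt_codon: str
    junction_distance_nt: int | None  # PTC (first base of stop codon) to last junction; None if single exon
    dosages: np.ndarray = field(repr=False, default=None)
    # polarization results
    ancestral: str | None = None
    derived: str | None = None
    pop_counts: dict | None = None   # population -> PopAlleleCounts
    pop_daf: dict | None = None      # population -> DAF (%)
    total_daf: float | None = None


def load_variants(
    vcf_path: str | Path,
    panel: str | Path | PanelMap,
    info_keys: tuple[str, str, str] = ("DP", "NC", "ARP"),
) -> tuple[list[VariantRecord], PanelMap]:
    """Read a multi-sample VCF plus panel into VariantRecords.

    Multi-allelic sites are split into one biallelic record per ALT (each
    ALT's dosage counted independently against everything else). Every VCF
    sample must appear in the panel.
    """
    from cyvcf2 import VCF

    if not isinstance(panel, PanelMap):
        panel = PanelMap.read_tsv(panel)
    vcf = VCF(str(vcf_path), gts012=False)
    for s in vcf.samples:
        if s not in panel.population_of:
            raise KeyError(f"VCF sample {s!r} absent from panel")

    dp_key, nc_key, arp_key = info_keys
    records: list[VariantRecord] = []
    for v in vcf:
        gt = np.asarray(v.genotypes, dtype=np.int16)[:, :2]  # allele indices per sample
        depth = v.INFO.get(dp_key)
        covered = v.INFO.get(nc_key)
        read_pos = v.INFO.get(arp_key)
        for ai, alt in enumerate(v.ALT, start=1):
            if len(v.REF) != 1 or len(alt) != 1:
                continue  # SNVs only
            missing = (gt < 0).any(axis=1)
            dos = (gt == ai).sum(axis=1).astype(np.int8)
            dos[missing] = -1
            records.append(
                VariantRecord(v.CHROM, v.POS, v.REF, alt, dos,
                              depth=depth, covered=covered, read_pos=read_pos)
            )
    return records, panel


def apply_quality_filters(
    variants: Iterable[VariantRecord],
    min_depth: float = 10,
    min_covered_individuals: float = 0.8,
    read_pos_band: tuple[float, float] = (0.1, 0.9),
    strict_missing: bool = True,
) -> tuple[list[VariantRecord], FilterReport]:
    """Retain variants passing all three site filters.

    ``min_covered_individuals`` < 1 is interpreted as a fraction of the
    sample count; >= 1 as an absolute count. Variants lacking a metric fail
    the corresponding filter in strict mode and pass it otherwise.
    """
    lo, hi = read_pos_band
    if lo > hi:
        raise ValueError("read_pos_band lower bound exceeds upper bound")
    variants = list(variants)
    report = FilterReport(n_input=len(variants))
    retained: list[VariantRecord] = []
    for v in variants:
        n_samples = len(v.dosages)
        min_cov = (min_covered_individuals * n_samples
                   if 0 < min_covered_individuals < 1 else min_covered_individuals)
        missing_fail = strict_missing
        ok_depth = v.depth >= min_depth if v.depth is not None else not missing_fail
        ok_cov = v.covered >= min_cov if v.covered is not None else not missing_fail
        ok_pos = (lo <= v.read_pos <= hi) if v.read_pos is not None else not missing_fail
        if not ok_depth:
            report.failed_depth += 1
        if not ok_cov:
            report.failed_covered += 1
        if not ok_pos:
            report.failed_read_pos += 1
        if ok_depth and ok_cov and ok_pos:
            retained.append(v)
    report.n_retained = len(retained)
    return retained, report


def classify_stop_gain(
    variant: VariantRecord,
    transcript: TranscriptModel,
    genome: Mapping[str, str],
) -> PtcCall | None:
    """Classify a variant as a premature stop-gain against one transcript.

    Returns a :class:`PtcCall` iff substituting ALT for REF converts an
    in-frame sense codon strictly upstream of the native stop into a stop
    codon. Variants outside the CDS, at the native stop, or whose
    substitution is not stop-creating return None. A REF base inconsistent
    with the reference genome raises :class:`DataIntegrityError`.
    """
    if variant.chrom != transcript.chrom:
        return None
    pos0 = variant.pos - 1
    cds_pos = transcript.genomic_to_cds(pos0)
    if cds_pos is None:
        return None
    genome_base = genome[transcript.chrom][pos0].upper()
    if genome_base != variant.ref:
        raise DataIntegrityError(
            f"{variant.chrom}:{variant.pos}: VCF REF {variant.ref} != genome {genome_base}"
        )
    cds = transcript.spliced_cds(genome)
    alt_t = variant.alt if transcript.strand == "+" else variant.alt.translate(_COMPLEMENT)
    k = cds_pos // 3 + 1  # 1-based codon index
    if k >= transcript.orf_codons:
        return None  # native stop codon itself: not premature
    codon = cds[3 * (k - 1):3 * k]
    off = cds_pos % 3
    alt_codon = codon[:off] + alt_t + codon[off + 1:]
    if codon in STOP_CODONS or alt_codon not in STOP_CODONS:
        return None

    junction = transcript.last_junction_mrna()
    jdist = None if junction is None else junction - 3 * (k - 1)
    return PtcCall(
        chrom=variant.chrom, pos=variant.pos, ref=variant.ref, alt=variant.alt,
        gene_id=transcript.gene_id, transcript_id=transcript.transcript_id,
        strand=transcript.strand, codon_index=k, orf_codons=transcript.orf_codons,
        ref_codon=codon, alt_codon=alt_codon, junction_distance_nt=jdist,
        dosages=variant.dosages,
    )


def classify_all(
    variants: Iterable[VariantRecord],
    transcripts: Iterable[TranscriptModel],
    genome: Mapping[str, str],
) -> list[PtcCall]:
    """Run :func:`classify_stop_gain` for every variant against every
    transcript whose span contains it (simple interval scan; the synthetic
    genomes here have non-overlapping genes)."""
    transcripts = list(transcripts)
    calls: list[PtcCall] = []
    for v in variants:
        for t in transcripts:
            if t.chrom == v.chrom and t.start <= v.pos - 1 < t.end:
                call = classify_stop_gain(v, t, genome)
                if call is not None:
                    calls.append(call)
    return calls
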