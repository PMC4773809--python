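"""Transcript models: exon/CDS structure against which stop-gains are judged.

A :class:`TranscriptModel` holds the genomic exon structure (0-based
half-open, as in BED12) and knows how to splice its coding sequence out of
a reference genome, map a genomic position into CDS coordinates
(strand-aware) and locate the last exon-exon junction in mRNA coordinates
-- the anchor of the 50-nt nonsense-mediated-decay rule.

The transcripts used throughout this package are fully coding (the CDS
spans the whole transcript); untranslated regions are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from Bio.Seq import Seq

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class TranscriptModel:
    """One transcript: ordered exons and a fully coding CDS.

    ``exons`` are 0-based half-open genomic intervals, sorted by start and
    non-overlapping regardless of strand. The spliced CDS is read 5'->3'
    in transcript orientation: for minus-strand transcripts that is the
    reverse complement of the genomic concatenation.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = -1
        for a, b in self.exons:
            if b <= a:
                raise ValueError(f"empty exon ({a},{b}) in {self.transcript_id}")
            if a < prev_end:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
            prev_end = b

    # -- geometry ---------------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def orf_codons(self) -> int:
        """ORF length L in codons, including the native stop."""
        return self.cds_length // 3

    def spliced_cds(self, genome: Mapping[str, str]) -> str:
        """Extract the spliced CDS (transcript orientation) from a genome dict."""
        chrom_seq = genome[self.chrom]
        s = "".join(chrom_seq[a:b] for a, b in self.exons)
        return reverse_complement(s) if self.strand == "-" else s.upper()

    def genomic_to_cds(self, pos0: int) -> int | None:
        """Map a 0-based genomic position to a 0-based CDS offset, or None.

        The offset counts nucleotides 5'->3' along the spliced transcript,
        so on the minus strand genomic coordinates run opposite to CDS
        coordinates.
        """
        offset = 0
        plus = None
        for a, b in self.exons:
            if a <= pos0 < b:
                plus = offset + (pos0 - a)
                break
            offset += b - a
        if plus is None:
            return None
        return plus if self.strand == "+" else self.cds_length - 1 - plus

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Inverse of :meth:`genomic_to_cds` (0-based both sides)."""
        if not 0 <= cds_pos < self.cds_length:
            raise IndexError(cds_pos)
        plus = cds_pos if self.strand == "+" else self.cds_length - 1 - cds_pos
        for a, b in self.exons:
            if plus < b - a:
                return a + plus
            plus -= b - a
        raise AssertionError("unreachable")

    def last_junction_mrna(self) -> int | None:
        """mRNA coordinate (0-based, transcript orientation) of the last
        exon-exon junction: the offset of the first base of the last exon.
        None for single-exon transcripts."""
        if self.n_exons < 2:
            return None
        lengths = [b - a for a, b in self.exons]
        if self.strand == "-":
            lengths = lengths[::-1]
        return sum(lengths[:-1])

    def validate_orf(self, genome: Mapping[str, str]) -> None:
        """Check the in-frame ORF contract: ATG start, single terminal stop."""
        cds = self.spliced_cds(genome)
        if len(cds) % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length not a multiple of 3")
        if not cds.startswith(START_CODON):
            raise ValueError(f"{self.transcript_id}: CDS does not start with ATG")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons[-1] not in STOP_CODONS:
            raise ValueError(f"{self.transcript_id}: CDS lacks terminal stop")
        for k, codon in enumerate(codons[:-1], 1):
            if codon in STOP_CODONS:
                raise ValueError(f"{self.transcript_id}: internal stop at codon {k}")


# -- BED12 I/O ------------------------------------------------------------
# BED12 columns: chrom start end name score strand thickStart thickEnd
# itemRgb blockCount blockSizes blockStarts. Transcripts here are fully
# coding, so thickStart/thickEnd equal the transcript span. The name field
# encodes "transcript_id|gene_id".


def read_bed12(path: str | Path) -> list[TranscriptModel]:
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns, got {len(f)}")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}:{lineno}: blockCount mismatch")
            exons = [(start + s, start + s + z) for s, z in zip(starts, sizes)]
            tid, _, gid = name.partition("|")
            out.append(TranscriptModel(gid or tid, tid, chrom, strand, exons))
    return out


def write_bed12(transcripts: list[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            sizes = ",".join(str(b - a) for a, b in t.exons)
            starts = ",".join(str(a - t.start) for a, _ in t.exons)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        t.chrom, t.start, t.end, f"{t.transcript_id}|{t.gene_id}",
                        0, t.strand, t.start, t.end, "0,0,0", t.n_exons,
                        sizes, starts,
                    )
                )
                + "\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) FASTA into a chrom -> uppercase sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
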