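"""Virtual genotyping of PTC sites against archaic genomes.

A modern derived allele is "detected" in an archaic genome (Neanderthal or
Denisovan) when it is among the alleles observed at the orthologous
position in that genome's sequence; the union fraction over both genomes
measures how much of the modern PTC repertoire predates the split from
archaic humans. Read-level processing of archaic data is out of scope: the
interface is a precomputed per-site allele table ('.' = no coverage).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .variants import PtcCall

GENOMES = ("neanderthal", "denisovan")


@dataclass
class ArchaicTable:
    """Site -> alleles observed per archaic genome.

    Alleles are stored as frozensets; None (no coverage) is distinct from
    an empty set.
    """

    alleles: dict[tuple[str, int], dict[str, frozenset[str] | None]]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ArchaicTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
        out: dict[tuple[str, int], dict[str, frozenset[str] | None]] = {}
        for row in df.itertuples(index=False):
            out[(row.chrom, int(row.pos))] = {
                "neanderthal": _parse(row.alleles_neanderthal),
                "denisovan": _parse(row.alleles_denisovan),
            }
        return cls(out)

    def at(self, chrom: str, pos: int) -> dict[str, frozenset[str] | None]:
        return self.alleles.get((chrom, pos), {g: None for g in GENOMES})


def _parse(field: str) -> frozenset[str] | None:
    field = str(field).strip()
    if field in (".", "", "nan"):
        return None
    return frozenset(a for a in field.split(",") if a)


@dataclass(frozen=True)
class ArchaicOverlapResult:
    n_ptcs: int
    n_assayable: int               # covered by at least one archaic genome
    detected: dict[str, int]       # per genome
    union_detected: int
    denominator: str               # "total" or "assayable"
    fraction: float                # union / denominator (0 if denominator empty)


def overlap_fraction(ptcs: list[PtcCall], archaic: ArchaicTable,
                     denominator: str = "total") -> ArchaicOverlapResult:
    """Fraction of PTC derived alleles observed in either archaic genome.

    ``denominator`` chooses between the full PTC set ("total") and only
    sites with archaic coverage ("assayable").
    """
    if denominator not in ("total", "assayable"):
        raise ValueError("denominator must be 'total' or 'assayable'")
    detected = {g: 0 for g in GENOMES}
    union = 0
    assayable = 0
    for ptc in ptcs:
        calls = archaic.at(ptc.chrom, ptc.pos)
        covered = any(calls[g] is not None for g in GENOMES)
        assayable += covered
        hit = False
        for g in GENOMES:
            alleles = calls[g]
            if alleles is not None and ptc.derived in alleles:
                detected[g] += 1
                hit = True
        union += hit
    denom = len(ptcs) if denominator == "total" else assayable
    return ArchaicOverlapResult(
        n_ptcs=len(ptcs), n_assayable=assayable, detected=detected,
        union_detected=union, denominator=denominator,
        fraction=union / denom if denom else 0.0,
    )
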