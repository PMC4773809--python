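"""Ancestral-allele polarization and derived allele frequencies (DAF).

The ancestral state of each variant is re-determined from primate
outgroups (chimpanzee, gorilla, orangutan) plus the human reference
allele, by majority vote over the available calls; ties or a consensus
matching neither VCF allele leave the site unresolved, and unresolved
sites are excluded downstream with a logged count.

DAF is the percentage of derived (mutated) chromosomes,

    DAF(%) = 100 * n_a / (n_A + n_a),

with ``n_A`` and ``n_a`` the ancestral and derived allele counts; missing
genotypes are excluded from both counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import PanelMap
from .variants import PtcCall

OUTGROUP_SPECIES = ("chimp", "gorilla", "orangutan", "human_ref")


class UndefinedValueError(ValueError):
    """Requested statistic has an empty denominator."""


@dataclass(frozen=True)
class PopAlleleCounts:
    """Genotype and allele counts for one population at one site.

    ``n_AA``/``n_Aa``/``n_aa`` count ancestral homozygotes, heterozygotes
    and derived homozygotes; missing genotypes are tallied separately and
    enter neither allele count.
    """

    n_AA: int
    n_Aa: int
    n_aa: int
    missing: int = 0

    @property
    def n_A(self) -> int:
        return 2 * self.n_AA + self.n_Aa

    @property
    def n_a(self) -> int:
        return 2 * self.n_aa + self.n_Aa

    @property
    def n_genotyped(self) -> int:
        return self.n_AA + self.n_Aa + self.n_aa


@dataclass
class OutgroupTable:
    """Per-site outgroup alleles; '.' or NaN marks an absent call."""

    table: pd.DataFrame  # columns: chrom pos ref alt chimp gorilla orangutan human_ref

    def __post_init__(self) -> None:
        self.table = self.table.set_index(["chrom", "pos"], drop=False) \
            if not isinstance(self.table.index, pd.MultiIndex) else self.table

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OutgroupTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        self.table.reset_index(drop=True).to_csv(path, sep="\t", index=False)

    def alleles_at(self, chrom: str, pos: int) -> dict[str, str | None]:
        try:
            row = self.table.loc[(chrom, pos)]
        except KeyError:
            return {s: None for s in OUTGROUP_SPECIES}
        if isinstance(row, pd.DataFrame):
            row = row.iloc[0]
        out = {}
        for s in OUTGROUP_SPECIES:
            a = row.get(s)
            out[s] = None if (a is None or a in (".", "", "N") or pd.isna(a)) else str(a)
        return out


def infer_ancestral(
    ref: str,
    alt: str,
    outgroup_alleles: dict[str, str | None],
    min_informative: int = 2,
) -> str | None:
    """Majority-vote ancestral allele over available outgroup calls.

    Returns the ancestral *base* (must equal ref or alt) or None when
    unresolved: fewer than ``min_informative`` calls, a tied vote, or a
    consensus matching neither allele. The human reference allele votes
    with the same weight as the non-human primates.
    """
    votes = [a for a in outgroup_alleles.values() if a is not None]
    if len(votes) < min_informative:
        return None
    counts: dict[str, int] = {}
    for a in votes:
        counts[a] = counts.get(a, 0) + 1
    best = max(counts.values())
    winners = [a for a, c in counts.items() if c == best]
    if len(winners) != 1 or winners[0] not in (ref, alt):
        return None
    return winners[0]


def compute_daf(n_A: int | np.ndarray, n_a: int | np.ndarray) -> float | np.ndarray:
    """DAF(%) = 100 * n_a / (n_A + n_a). Raises on an empty denominator."""
    total = np.asarray(n_A) + np.asarray(n_a)
    if np.any(total <= 0):
        raise UndefinedValueError("DAF undefined: zero called alleles")
    return 100.0 * np.asarray(n_a) / total


def count_by_population(derived_dosages: np.ndarray, samples: list[str],
                        panel: PanelMap) -> dict[str, PopAlleleCounts]:
    """Per-population genotype counts from a derived-dosage vector
    (one entry per sample; -1 = missing)."""
    idx = panel.sample_indices_by_population(samples)
    out: dict[str, PopAlleleCounts] = {}
    for pop, rows in idx.items():
        d = derived_dosages[rows]
        out[pop] = PopAlleleCounts(
            n_AA=int((d == 0).sum()), n_Aa=int((d == 1).sum()),
            n_aa=int((d == 2).sum()), missing=int((d < 0).sum()),
        )
    return out


def polarize_calls(
    ptcs: list[PtcCall],
    outgroup: OutgroupTable,
    samples: list[str],
    panel: PanelMap,
) -> tuple[list[PtcCall], int]:
    """Fill ancestral/derived alleles, per-population counts and DAFs.

    PTCs whose ancestral state cannot be resolved are dropped; the second
    return value is the count of unresolved sites.
    """
    kept: list[PtcCall] = []
    unresolved = 0
    for ptc in ptcs:
        anc = infer_ancestral(ptc.ref, ptc.alt, outgroup.alleles_at(ptc.chrom, ptc.pos))
        if anc is None:
            unresolved += 1
            continue
        ptc.ancestral = anc
        ptc.derived = ptc.alt if anc == ptc.ref else ptc.ref
        dos = ptc.dosages.astype(np.int8)
        derived_dos = dos if anc == ptc.ref else np.where(dos >= 0, 2 - dos, -1).astype(np.int8)
        ptc.pop_counts = count_by_population(derived_dos, samples, panel)
        ptc.pop_daf = {}
        for pop, c in ptc.pop_counts.items():
            ptc.pop_daf[pop] = (float(compute_daf(c.n_A, c.n_a))
                                if c.n_genotyped > 0 else float("nan"))
        n_A = sum(c.n_A for c in ptc.pop_counts.values())
        n_a = sum(c.n_a for c in ptc.pop_counts.values())
        ptc.total_daf = float(compute_daf(n_A, n_a)) if n_A + n_a > 0 else float("nan")
        kept.append(ptc)
    return kept, unresolved


def select_by_threshold(ptcs: list[PtcCall], min_total_daf: float = 1.0) -> list[PtcCall]:
    """Variant-level selection: total DAF strictly above ``min_total_daf`` (%)."""
    return [p for p in ptcs if p.total_daf is not None
            and not np.isnan(p.total_daf) and p.total_daf > min_total_daf]


def aggregate_gene_daf(ptcs: list[PtcCall]) -> pd.DataFrame:
    """Per-gene total DAF: the sum of the gene's variant DAFs, overall and
    per population. A gene whose individual PTCs each sit below a frequency
    threshold can still pass it on the summed, gene-level DAF, which is why
    variant-level and gene-level selections differ. Raw sums are returned
    (they may exceed 100); reporting may cap for display."""
    if not ptcs:
        return pd.DataFrame(columns=["gene_id", "n_ptcs", "total_daf"])
    pops = list(ptcs[0].pop_daf) if ptcs[0].pop_daf else []
    rows: dict[str, dict] = {}
    for p in ptcs:
        r = rows.setdefault(p.gene_id, {"gene_id": p.gene_id, "n_ptcs": 0,
                                        "total_daf": 0.0,
                                        **{f"daf_{q}": 0.0 for q in pops}})
        r["n_ptcs"] += 1
        r["total_daf"] += p.total_daf
        for q in pops:
            v = p.pop_daf.get(q, float("nan"))
            if not np.isnan(v):
                r[f"daf_{q}"] += v
    return pd.DataFrame(list(rows.values()))


def calls_to_frame(ptcs: list[PtcCall]) -> pd.DataFrame:
    """Flatten polarized calls to the per-variant TSV layout."""
    rows = []
    for p in ptcs:
        row = {
            "chrom": p.chrom, "pos": p.pos, "ref": p.ref, "alt": p.alt,
            "gene_id": p.gene_id, "transcript_id": p.transcript_id,
            "strand": p.strand, "codon_index": p.codon_index,
            "orf_codons": p.orf_codons, "ancestral": p.ancestral,
            "derived": p.derived,
            "total_daf": round(p.total_daf, 3) if p.total_daf is not None else None,
        }
        if p.pop_counts:
            for pop, c in p.pop_counts.items():
                row[f"nA_{pop}"] = c.n_A
                row[f"na_{pop}"] = c.n_a
                row[f"daf_{pop}"] = round(p.pop_daf[pop], 3)
        rows.append(row)
    return pd.DataFrame(rows)
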