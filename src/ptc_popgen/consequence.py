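"""Truncation geometry and nonsense-mediated decay (NMD) prediction.

A premature stop at codon ``k`` of an ORF of ``L`` codons retains ``k-1``
residues; the truncation percentage is measured against the ancestral ORF
length. NMD susceptibility follows the canonical 50-nt rule: a transcript
is a predicted NMD target when the premature stop lies more than 50 nt
upstream (in mRNA coordinates) of the last exon-exon junction;
intron-less transcripts escape NMD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .transcripts import TranscriptModel
from .variants import DataIntegrityError, PtcCall


@dataclass(frozen=True)
class TruncationMetrics:
    orf_codons: int          # L
    codon_index: int         # k, 1-based
    retained_residues: int   # k - 1
    position_pct: float      # 100*(k-1)/L
    truncation_pct: float    # 100*(L-(k-1))/L
    junction_distance_nt: int | None
    nmd: bool


def predict_nmd(ptc: PtcCall, transcript: TranscriptModel,
                rule_threshold_nt: int = 50) -> bool:
    """50-nt last-junction rule, strict inequality.

    The PTC position is the first base of the new stop codon in mRNA
    coordinates; single-exon transcripts are never NMD targets.
    """
    junction = transcript.last_junction_mrna()
    if junction is None:
        return False
    distance = junction - 3 * (ptc.codon_index - 1)
    return distance > rule_threshold_nt


def truncation_metrics(ptc: PtcCall, transcript: TranscriptModel,
                       nmd_threshold_nt: int = 50) -> TruncationMetrics:
    """Truncation geometry of one PTC against its transcript."""
    L, k = transcript.orf_codons, ptc.codon_index
    if not 1 <= k <= L:
        raise DataIntegrityError(f"codon index {k} outside ORF of {L} codons")
    retained = k - 1
    return TruncationMetrics(
        orf_codons=L,
        codon_index=k,
        retained_residues=retained,
        position_pct=100.0 * retained / L,
        truncation_pct=100.0 * (L - retained) / L,
        junction_distance_nt=ptc.junction_distance_nt,
        nmd=predict_nmd(ptc, transcript, nmd_threshold_nt),
    )


def deletion_fraction_summary(
    truncation_pcts: Sequence[float],
    thresholds: Sequence[float] = (20.0,),
) -> dict:
    """Distribution summary of truncation percentages.

    Returns the median and, for each threshold x, the fraction of PTCs
    deleting more than x% of the protein. Exact order statistics.
    """
    vals = np.asarray(truncation_pcts, dtype=float)
    if vals.size == 0:
        raise ValueError("no truncation values supplied")
    out = {"n": int(vals.size), "median": float(np.median(vals))}
    for x in thresholds:
        out[f"fraction_gt_{x:g}"] = float((vals > x).mean())
    return out
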