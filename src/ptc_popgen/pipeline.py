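"""End-to-end orchestration: simulate -> call -> polarize -> annotate ->
stats -> structure -> archaic, with plain-TSV intermediates and a JSON run
manifest (input checksums, seeds, per-stage row counts, version).

Intermediates are never mutated by later stages; re-running with an
identical config reproduces identical outputs (bit-exact for the
deterministic stages, seed-exact for the stochastic ones).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .archaic import ArchaicTable, overlap_fraction
from .consequence import deletion_fraction_summary, truncation_metrics
from .panel import PanelMap
from .polarize import (
    OutgroupTable,
    aggregate_gene_daf,
    calls_to_frame,
    polarize_calls,
    select_by_threshold,
)
from .simulate import (
    ConfigurationError,
    SimulationConfig,
    inject_ptc_variants,
    simulate_archaic_calls,
    simulate_outgroup_alleles,
    simulate_populations,
    simulate_transcripts,
    write_dataset,
)
from .stats import (
    bootstrap_ci,
    differentiation,
    hwe_test,
    theta_statistic,
)
from .structure import (
    daf_matrix,
    group_summaries,
    hca_structure,
    pca_structure,
    regress_outliers,
)
from .transcripts import read_bed12, read_fasta
from .variants import apply_quality_filters, classify_all, load_variants

log = logging.getLogger("ptc_popgen")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    ``genome_wide_ptc_rate`` is a reporting constant (the approximate
    average per-gene PTC frequency across the genome, in percent) used as
    a reference line in summaries; it is never estimated here.
    """

    out_dir: str = "ptc_run"
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    min_depth: float = 10
    min_covered_individuals: float = 0.8
    read_pos_band: tuple[float, float] = (0.1, 0.9)
    daf_threshold: float = 1.0
    nmd_threshold_nt: int = 50
    bootstrap_B: int = 1000
    bootstrap_level: float = 0.95
    outlier_threshold: float = 2.0
    genome_wide_ptc_rate: float = 0.16
    categories: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "read_pos_band" in raw:
            raw["read_pos_band"] = tuple(raw["read_pos_band"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["read_pos_band"] = list(self.read_pos_band)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": config.to_dict(), "stages": {}}
    (out / "config.resolved.json").write_text(json.dumps(config.to_dict(), indent=2))

    # -- stage: simulate (or locate inputs) -------------------------------
    if config.inputs:
        paths = {k: Path(v) for k, v in config.inputs.items()}
    else:
        paths = stage_simulate(config, out / "input")
    manifest["inputs"] = {k: {"path": str(v), "sha256": _sha256(v)}
                          for k, v in paths.items()}

    transcripts = read_bed12(paths["bed"])
    genome = read_fasta(paths["fasta"])
    outgroup = OutgroupTable.read_tsv(paths["outgroup"])
    archaic = ArchaicTable.read_tsv(paths["archaic"])

    # -- stage: call ------------------------------------------------------
    variants, panel = load_variants(paths["vcf"], paths["panel"])
    retained, report = apply_quality_filters(
        variants, config.min_depth, config.min_covered_individuals,
        config.read_pos_band,
    )
    report.write_tsv(out / "filter_report.tsv")
    samples = PanelMap.read_tsv(paths["panel"]).samples
    calls = classify_all(retained, transcripts, genome)
    log.info("call: %d variants in, %d retained, %d stop-gains",
             report.n_input, report.n_retained, len(calls))
    manifest["stages"]["call"] = {
        "n_variants": report.n_input, "n_retained": report.n_retained,
        "n_removed": report.n_removed, "n_stop_gains": len(calls),
    }

    # -- stage: polarize --------------------------------------------------
    polarized, unresolved = polarize_calls(calls, outgroup, samples, panel)
    selected = select_by_threshold(polarized, config.daf_threshold)
    gene_daf = aggregate_gene_daf(polarized)
    gene_daf.to_csv(out / "gene_daf.tsv", sep="\t", index=False)
    genes_over = gene_daf[gene_daf["total_daf"] > config.daf_threshold]
    manifest["stages"]["polarize"] = {
        "n_polarized": len(polarized), "n_unresolved": unresolved,
        "n_selected": len(selected),
        "n_genes": int(gene_daf["gene_id"].nunique()) if len(gene_daf) else 0,
        "n_genes_over_threshold": len(genes_over),
    }

    # -- stage: annotate --------------------------------------------------
    by_tx = {t.transcript_id: t for t in transcripts}
    frame = calls_to_frame(polarized)
    metrics = [truncation_metrics(p, by_tx[p.transcript_id], config.nmd_threshold_nt)
               for p in polarized]
    if metrics:
        frame["truncation_pct"] = [round(m.truncation_pct, 3) for m in metrics]
        frame["position_pct"] = [round(m.position_pct, 3) for m in metrics]
        frame["nmd"] = [m.nmd for m in metrics]
    frame.to_csv(out / "ptc_calls.tsv", sep="\t", index=False)
    summary = (deletion_fraction_summary([m.truncation_pct for m in metrics])
               if metrics else {"n": 0})
    manifest["stages"]["annotate"] = {
        "n_annotated": len(metrics),
        "n_nmd": int(sum(m.nmd for m in metrics)),
        "median_truncation_pct": summary.get("median"),
    }

    # -- stage: stats -----------------------------------------------------
    rows = []
    pop_indices = panel.sample_indices_by_population(samples)
    for p in polarized:
        locus = f"{p.chrom}:{p.pos}"
        diff = differentiation(p.pop_counts, locus=locus)
        pooled = tuple(sum(getattr(c, a) for c in p.pop_counts.values())
                       for a in ("n_AA", "n_Aa", "n_aa"))
        hwe = hwe_test(*pooled)
        derived_dos = np.asarray(p.dosages, dtype=np.int8)
        if p.ancestral == p.alt:
            derived_dos = np.where(derived_dos >= 0, 2 - derived_dos, -1).astype(np.int8)
        per_pop_dos = {pop: derived_dos[idx] for pop, idx in pop_indices.items()}
        ci = bootstrap_ci(theta_statistic, per_pop_dos, B=config.bootstrap_B,
                          level=config.bootstrap_level, seed=config.seed)
        rows.append({
            "locus": locus, "gene_id": p.gene_id, "total_daf": p.total_daf,
            "theta": diff.theta, "a": diff.a, "b": diff.b, "c": diff.c,
            "G_ST": diff.G_ST, "G_prime_ST": diff.G_prime_ST, "D": diff.D,
            "H_S": diff.H_S, "H_T": diff.H_T,
            "theta_ci_lo": ci[0] if ci else None,
            "theta_ci_hi": ci[1] if ci else None,
            "hwe_p": hwe.p_value,
        })
    stats_df = pd.DataFrame(rows)
    stats_df.to_csv(out / "locus_stats.tsv", sep="\t", index=False)
    manifest["stages"]["stats"] = {"n_loci": len(stats_df),
                                   "bootstrap_B": config.bootstrap_B}

    # -- stage: structure -------------------------------------------------
    structure_info: dict = {}
    if len(polarized) >= 2 and len(panel.populations) >= 2:
        M, mask, pops, ids = daf_matrix(polarized, panel)
        pd.DataFrame(M, index=pops, columns=ids).to_csv(out / "daf_matrix.tsv", sep="\t")
        try:
            scores, loadings, explained = pca_structure(M)
            pd.DataFrame(scores, index=pops,
                         columns=[f"PC{i+1}" for i in range(scores.shape[1])]
                         ).to_csv(out / "pca_scores.tsv", sep="\t")
            structure_info["pca_variance_explained"] = explained.round(6).tolist()
        except ValueError as e:
            structure_info["pca_skipped"] = str(e)
        Z, newick = hca_structure(M, pops)
        (out / "populations.nwk").write_text(newick + "\n")
        gs = group_summaries(M, pops, panel.super_group_of)
        gs.to_csv(out / "group_summaries.tsv", sep="\t", index=False)

        theta = stats_df["theta"].to_numpy()
        daf = stats_df["total_daf"].to_numpy()
        het = stats_df["H_T"].to_numpy()
        if np.isfinite(theta).sum() >= 3:
            out_rows = []
            for name, x in (("daf", daf), ("heterozygosity", het)):
                rep = regress_outliers(x, theta, predictor=name,
                                       threshold=config.outlier_threshold)
                out_rows.append(pd.DataFrame({
                    "locus": stats_df["locus"], "predictor": name,
                    "studentized_residual": rep.studentized,
                    "outlier": rep.outlier, "above_95th": rep.above_95th,
                }))
                structure_info[f"n_outliers_{name}"] = int(rep.outlier.sum())
            pd.concat(out_rows).to_csv(out / "outliers.tsv", sep="\t", index=False)
        if config.categories:
            cat = pd.read_csv(config.categories, sep="\t",
                              names=["gene_id", "category"], header=None)
            from .structure import category_daf

            cd = category_daf(gene_daf, dict(zip(cat["gene_id"], cat["category"])))
            cd.to_csv(out / "category_daf.tsv", sep="\t", index=False)
    manifest["stages"]["structure"] = structure_info

    # -- stage: archaic ---------------------------------------------------
    res = overlap_fraction(polarized, archaic, denominator="total")
    manifest["stages"]["archaic"] = {
        "n_ptcs": res.n_ptcs, "n_assayable": res.n_assayable,
        "union_detected": res.union_detected,
        "fraction_pct": round(100 * res.fraction, 3),
    }
    with open(out / "archaic_overlap.tsv", "w") as fh:
        fh.write("n_ptcs\tn_assayable\tneanderthal\tdenisovan\tunion\tfraction_pct\n")
        fh.write(f"{res.n_ptcs}\t{res.n_assayable}\t{res.detected['neanderthal']}\t"
                 f"{res.detected['denisovan']}\t{res.union_detected}\t"
                 f"{100 * res.fraction:.3f}\n")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def stage_simulate(config: PipelineConfig, out_dir: Path) -> dict[str, Path]:
    """Generate the full synthetic input bundle under ``out_dir``."""
    sim = dict(config.simulate)
    n_genes = int(sim.pop("n_genes", 30))
    decoy_ratio = float(sim.pop("decoy_ratio", 1.0))
    concordance = float(sim.pop("outgroup_concordance", 0.98))
    carrier = float(sim.pop("archaic_carrier_fraction", 0.219))
    sim.setdefault("seed", config.seed)
    if "ancestral_freq_range" in sim:
        sim["ancestral_freq_range"] = tuple(sim["ancestral_freq_range"])
    sc = SimulationConfig(outgroup_concordance=concordance,
                          archaic_carrier_fraction=carrier, **sim)
    dataset = simulate_populations(sc)
    transcripts, genome = simulate_transcripts(n_genes, seed=sc.seed + 1)
    dataset, _truth = inject_ptc_variants(transcripts, genome, dataset,
                                          decoy_ratio=decoy_ratio, seed=sc.seed + 2)
    outgroup = simulate_outgroup_alleles(dataset, concordance, seed=sc.seed + 3)
    archaic = simulate_archaic_calls(dataset, carrier, seed=sc.seed + 4)
    return write_dataset(dataset, out_dir, transcripts, genome, outgroup, archaic)
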