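"""End-to-end orchestration of the analysis stages on synthetic inputs.

A single configured run generates (or loads) two-condition chromatin and
enhancer read sets, calls dynamic sites for both marks, integrates them
with paired expression, identifies super-enhancers per condition, runs the
locus permutation and peak-shift enrichment tests, scores the packaged
allele sequences against the packaged motifs, and writes per-stage outputs
plus a machine-readable summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import integration, motifs, super_enhancers
from .core_io import (
    GenomicInterval,
    coverage_from_reads,
    write_bed,
)
from .differential import DynamicSite, call_peaks_simple, hotspot_clusters, run_differential
from .enrichment import permute_enrichment, shift_enrichment
from .synthetic import (
    SimulationConfig,
    simulate_annotation,
    simulate_chromatin,
    simulate_expression,
    simulate_genes,
    simulate_locus_catalog,
)

logger = logging.getLogger(__name__)

# fixed offsets deriving per-stage seeds from the master seed
STAGE_SEED_OFFSETS = {
    "chromatin": 11, "enhancer": 23, "expression": 37, "loci": 41,
    "snp_enrich": 53, "shift_enrich": 67,
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str | Path = "chromadelta_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    fdr: float = 0.025
    pad: int = 300
    expression_fdr: float = 0.05
    stitch_gap: int = 12_500
    peak_threshold_fold: float = 2.0       # peaks called at this fold over the
                                           # genome-average reads-per-million
    n_permutations: int = 10_000
    n_shift_permutations: int = 100
    stages: tuple[str, ...] = (
        "simulate", "differential", "integration", "super", "enrichment",
        "allele_scan",
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(simulation=sim, **raw)


_DEPENDENCIES = {
    "differential": "simulate",
    "integration": "differential",
    "super": "differential",
    "enrichment": "differential",
}


def _sites_to_bed(sites: list[DynamicSite]) -> list[GenomicInterval]:
    return [
        GenomicInterval(
            s.interval.chrom, s.interval.start, s.interval.end,
            strand=".",
            score=float(-np.log10(max(s.best_q, 1e-300))),
            name="up" if s.direction > 0 else "down",
        )
        for s in sites
    ]


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the summary
    dict (also written to ``summary.json`` in the output directory)."""
    for stage, dep in _DEPENDENCIES.items():
        if stage in config.stages and dep not in config.stages:
            raise ValueError(f"stage {stage!r} requires stage {dep!r}")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    seeds = {k: seed + off for k, off in STAGE_SEED_OFFSETS.items()}
    logger.info("run seed=%d out=%s stages=%s", seed, out_dir, config.stages)

    summary: dict = {"seed": seed, "parameters": {
        "fdr": config.fdr, "pad": config.pad,
        "n_permutations": config.n_permutations,
        "simulation": dataclasses.asdict(config.simulation),
    }}
    sim = config.simulation
    genome = sim.genome

    chromatin_sites: list[DynamicSite] = []
    enhancer_sites: list[DynamicSite] = []
    genes = None

    if "simulate" in config.stages:
        rng_c = np.random.default_rng(seeds["chromatin"])
        chrom_reads, truth = simulate_chromatin(sim, rng_c)
        # enhancer mark re-uses the chromatin truth's planted intervals and
        # directions so that the two marks are concordant by construction
        rng_e = np.random.default_rng(seeds["enhancer"])
        enh_reads, _ = _resimulate_with_truth(sim, truth, rng_e)
        genes = simulate_genes(sim)
        expression = simulate_expression(
            sim, truth, genes, np.random.default_rng(seeds["expression"]))
        summary["simulate"] = {
            "n_planted_sites": len(truth.planted_sites),
            "n_genes": len(genes),
            "library_sizes": {
                f"{rs.condition}/{rs.replicate}": rs.library_size
                for rs in chrom_reads
            },
        }

    if "differential" in config.stages:
        chrom_stats, chromatin_sites = run_differential(
            chrom_reads, genome, mode="chromatin", q_threshold=config.fdr)
        enh_stats, enhancer_sites = run_differential(
            enh_reads, genome, mode="enhancer", q_threshold=config.fdr)
        write_bed(out_dir / "dynamic_chromatin.bed", _sites_to_bed(chromatin_sites))
        write_bed(out_dir / "dynamic_enhancer.bed", _sites_to_bed(enhancer_sites))
        chrom_stats[chrom_stats["tested"]].to_csv(
            out_dir / "chromatin_windows.tsv", sep="\t", index=False)
        hotspots = hotspot_clusters(chromatin_sites, genome) if chromatin_sites else []
        summary["differential"] = {
            "n_chromatin_sites": len(chromatin_sites),
            "n_chromatin_up": sum(1 for s in chromatin_sites if s.direction > 0),
            "n_enhancer_sites": len(enhancer_sites),
            "n_hotspots": len(hotspots),
        }

    if "integration" in config.stages:
        promoter, distal, pcts = integration.classify_promoter(
            chromatin_sites, genes)
        pairs, report = integration.intersect_dynamic(
            chromatin_sites, enhancer_sites, pad=config.pad)
        pairs.to_csv(out_dir / "dynamic_pairs.tsv", sep="\t", index=False)
        de = integration.paired_de(expression, config.expression_fdr)
        de.to_csv(out_dir / "paired_de.tsv", sep="\t")
        de_sig = de[de["significant"]]
        couplings, r, r2 = integration.couple_genes(enhancer_sites, de_sig, genes)
        try:
            quart = integration.quartile_concordance(de_sig, enhancer_sites, genes)
            quart.to_csv(out_dir / "quartile_concordance.tsv", sep="\t",
                         index=False)
        except ValueError:
            logger.info("too few DE genes per direction for quartile split")
        summary["integration"] = {
            "n_promoter_sites": len(promoter),
            "n_distal_sites": len(distal),
            **pcts,
            "concordance": {
                "n_chromatin_sites_overlapping": report.n_chromatin_sites_overlapping,
                "n_enhancer_sites_overlapped": report.n_enhancer_sites_overlapped,
                "n_concordant": report.n_concordant,
                "pct_concordant": report.pct_concordant,
            },
            "n_de_genes": int(de["significant"].sum()),
            "coupling": {"n_genes": len(couplings), "pearson_r": r, "r2": r2},
        }

    if "super" in config.stages:
        super_summary = {}
        per_condition: dict[str, list] = {}
        bin_bp = 50
        mean_rpm = 1e6 * bin_bp / genome.total_length
        for cond in dict.fromkeys(rs.condition for rs in enh_reads):
            reads_c = [rs for rs in enh_reads if rs.condition == cond]
            coverage = coverage_from_reads(reads_c, genome, bin_bp=bin_bp)
            peaks = call_peaks_simple(coverage,
                                      config.peak_threshold_fold * mean_rpm,
                                      max_bp=50_000)
            stitched = super_enhancers.stitch(peaks, config.stitch_gap)
            try:
                _, ranked = super_enhancers.super_cutoff(stitched)
            except ValueError:
                ranked = []
            per_condition[cond] = ranked
            super_enhancers.stitched_table(ranked).to_csv(
                out_dir / f"stitched_{cond}.tsv", sep="\t", index=False)
            super_summary[cond] = {
                "n_stitched": len(ranked),
                "n_super": sum(1 for e in ranked if e.is_super),
            }
        conds = list(per_condition)
        if len(conds) == 2 and all(per_condition.values()):
            specific = super_enhancers.condition_specific(
                per_condition[conds[1]], per_condition[conds[0]])
            super_summary["n_condition2_specific"] = len(specific)
        summary["super"] = super_summary

    if "enrichment" in config.stages:
        annotation = [s.interval for s in chromatin_sites] or \
            simulate_annotation(sim)
        targets, background, locus_truth = simulate_locus_catalog(
            sim, annotation, np.random.default_rng(seeds["loci"]))
        enr = permute_enrichment(
            targets, background, annotation,
            n_permutations=config.n_permutations, seed=seeds["snp_enrich"])
        shift_annotation = simulate_annotation(
            sim, np.random.default_rng(seeds["loci"] + 1), n_features=300)
        shift = shift_enrichment(
            [s.interval for s in chromatin_sites] or annotation,
            shift_annotation, genome,
            n_permutations=config.n_shift_permutations,
            seed=seeds["shift_enrich"])
        summary["enrichment"] = {
            "locus": dataclasses.asdict(enr),
            "shift": dataclasses.asdict(shift),
        }

    if "allele_scan" in config.stages:
        table = allele_scan_packaged()
        table.to_csv(out_dir / "allele_affinity.tsv", sep="\t", index=False)
        summary["allele_scan"] = {
            "top_motif": str(table.iloc[0]["motif_id"]),
            "top_diff_logp": float(table.iloc[0]["diff_logp"]),
        }

    with open(out_dir / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, default=float)
    return summary


def _resimulate_with_truth(sim: SimulationConfig, truth, rng):
    """Simulate a second mark re-using the planted intervals and effects."""
    from .synthetic import GroundTruth, _segment_reads
    from .core_io import ReadSet

    readsets = []
    planted = truth.planted_sites
    effects = truth.effects
    for ci, condition in enumerate(("macrophage", "foam_cell")):
        for rep in range(sim.n_replicates):
            positions = {}
            for chrom, length in sim.chrom_lengths.items():
                sites = [(iv, eff) for iv, eff in zip(planted, effects)
                         if iv.chrom == chrom]
                chunks = []
                cursor = 0
                for iv, eff in sites:
                    if iv.start > cursor:
                        chunks.append(_segment_reads(
                            rng, cursor, iv.start, sim.background_rate,
                            sim.nb_dispersion))
                    rate = sim.background_rate
                    if ci == 1:
                        rate *= 2.0 ** eff
                    chunks.append(_segment_reads(rng, iv.start, iv.end, rate,
                                                 sim.nb_dispersion))
                    cursor = iv.end
                if cursor < length:
                    chunks.append(_segment_reads(
                        rng, cursor, length, sim.background_rate,
                        sim.nb_dispersion))
                positions[chrom] = np.concatenate(chunks)
            readsets.append(ReadSet(condition, f"rep{rep + 1}", positions))
    return readsets, truth


def allele_scan_packaged(eps: float = 0.01):
    """Affinity table for the packaged allele probes and synthetic motifs."""
    data = resources.files("chromadelta.data")
    with resources.as_file(data / "motifs_synthetic.jaspar") as p:
        pwms = motifs.read_jaspar(p)
    with resources.as_file(data / "rs72664324_alleles.fa") as p:
        seqs = motifs.read_fasta(p)
    return motifs.allele_affinity_table(
        pwms, seqs["rs72664324_A"], seqs["rs72664324_G"], eps)
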