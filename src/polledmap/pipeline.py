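"""End-to-end orchestration: simulate -> map -> filter -> cnv -> rank -> associate.

``RunConfig`` holds every stage toggle, parameter and seed and round-trips
losslessly through YAML.  ``run_pipeline`` executes the enabled stages in
order on synthetic inputs, writes per-stage text outputs under the configured
output directory and returns (and writes) a JSON-able summary; identical
config and seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from . import association, catalog, cnv, conservation, filtering, io, mapping, simulate
from .intervals import interval_length


@dataclass
class RunConfig:
    """Serialisable configuration of a full pipeline run."""

    seed: int = 0
    outdir: str = "results/pipeline"
    stages: Dict[str, bool] = field(default_factory=lambda: {
        "map": True, "filter": True, "cnv": True, "rank": True, "associate": True})
    # mapping
    n_perm: int = 500
    alpha: float = 0.01
    panel_cases: int = 20
    panel_controls: int = 20
    panel_chromosomes: int = 5
    panel_markers_per_chromosome: int = 100
    shared_haplotype_markers: int = 9
    # filtering
    pp_band: tuple = (0.95, 1.00)
    het_band: tuple = (0.40, 0.60)
    min_depth: int = 20
    # cnv
    bin_reads: int = 400
    read_rate_per_bp: float = 0.2
    copy_ratio: float = 2.0
    min_log2: float = 0.4
    min_span_bp: int = 10_000
    cbs_alpha: float = 0.01
    # ranking
    tau_hi: float = 0.8
    tau_lo: float = 0.3
    # association
    n_required: int = 12

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["pp_band"] = list(self.pp_band)
        d["het_band"] = list(self.het_band)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["pp_band"] = tuple(d["pp_band"])
        d["het_band"] = tuple(d["het_band"])
        return cls(**d)


def demo_conservation_profiles() -> Dict[str, Optional[conservation.ConservationProfile]]:
    """Synthetic conservation profiles encoding the published qualitative
    descriptions of the Friesian candidates (the real phastCons tracks are
    inputs the pipeline consumes, not artifacts it computes)."""
    n = 25
    high = np.full(n, 1.0)
    low = np.full(n, 0.1)
    mid = np.full(n, 0.5)
    return {
        # repeat-masked, no score computable
        "P_5ID": conservation.ConservationProfile(repeat_masked=True),
        "P_G1654405A": conservation.ConservationProfile(repeat_masked=True),
        # flanking sequence weakly conserved; goat carries the variant base
        "P_C1655463T": conservation.ConservationProfile(
            scores={"bovid": low, "unhorned": low, "all": low},
            cross_species_allele="T"),
        # centre of a block identical in all bovids, unconserved elsewhere
        "P_C1768587A": conservation.ConservationProfile(
            scores={"bovid": high, "unhorned": low, "all": low}),
        "P_T1671849G": conservation.ConservationProfile(
            scores={"bovid": mid, "unhorned": mid, "all": mid}),
        "P_T1680646C": conservation.ConservationProfile(
            scores={"bovid": mid, "unhorned": mid, "all": mid}),
        # junction variants conserved among bovids only sit inside the event
        "P_80kbID": None,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in order and write a JSON run summary.

    Stage seeds are derived deterministically from ``config.seed``; every
    stage writes its own text outputs under ``config.outdir`` and contributes
    a section to the summary.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    stage_seed = {name: int(s.generate_state(1)[0] % (2 ** 31))
                  for name, s in zip(["panel", "perm", "reseq", "tracks", "cbs",
                                      "population"], root.spawn(6))}
    summary: dict = {"config": {"seed": config.seed}, "stages": {}}
    config.to_yaml(out / "config.yaml")

    if config.stages.get("map", False):
        spec = simulate.PanelSpec(
            seed=stage_seed["panel"], n_chromosomes=config.panel_chromosomes,
            markers_per_chromosome=config.panel_markers_per_chromosome,
            n_cases=config.panel_cases, n_controls=config.panel_controls,
            shared_haplotype_markers=config.shared_haplotype_markers)
        panel = simulate.generate_genotype_panel(spec)
        io.write_ped_map(panel, out / "panel")
        result = mapping.map_locus(panel, n_perm=config.n_perm,
                                   alpha=config.alpha, seed=stage_seed["perm"])
        report = mapping.extract_candidate_interval(result, panel)
        io.write_stats_tsv(panel, result.stats, result.pvalues, out / "asshom.tsv")
        io.write_intervals_bed(result.significant_intervals, out / "significant.bed")
        ci = report.candidate_interval
        summary["stages"]["map"] = {
            "threshold": result.threshold,
            "n_significant_markers": int((result.stats > result.threshold).sum()),
            "core_marker_count": report.core_marker_count,
            "core_interval": [ci and report.core_interval.start,
                              ci and report.core_interval.end],
            "candidate_interval": None if ci is None else [ci.start, ci.end],
            "candidate_interval_kb": None if ci is None else round(
                (ci.end - ci.start) / 1000),
            "degenerate": report.degenerate,
        }

    if config.stages.get("filter", False):
        table = simulate.generate_variant_tables(simulate.ReseqSpec(
            seed=stage_seed["reseq"]))
        io.write_variant_table(table, out / "variants.tsv", out / "samples.tsv")
        cfg = filtering.FilterConfig(pp_band=config.pp_band,
                                     het_band=config.het_band,
                                     min_depth=config.min_depth)
        partitions = {g: list(table.samples[table.samples["group"] == g]["id"])
                      for g in table.samples["group"].unique()}
        het = filtering.subgroup_heterogeneity_scan(table, partitions, cfg)
        het.combined_survivors.to_csv(out / "survivors_combined.tsv", sep="\t",
                                      index=False)
        for name, df in het.partition_survivors.items():
            df.to_csv(out / f"survivors_{name}.tsv", sep="\t", index=False)
        summary["stages"]["filter"] = {
            "combined_survivors": len(het.combined_survivors),
            "partition_survivors": {k: len(v)
                                    for k, v in het.partition_survivors.items()},
            "heterogeneity": het.heterogeneity,
            "exclusivity": het.exclusivity,
        }

    if config.stages.get("cnv", False):
        ref, tgt = simulate.generate_read_tracks(
            catalog.P_80KBID_INTERVAL, catalog.TARGET_REGION,
            rate_per_bp=config.read_rate_per_bp, copy_ratio=config.copy_ratio,
            seed=stage_seed["tracks"])
        bins = cnv.dynamic_bins(ref, n_reads=config.bin_reads)
        track = cnv.log2_ratio_track(bins, tgt)
        io.write_bedgraph(catalog.CHROM, track["start"], track["end"],
                          track["log2_ratio"], out / "log2_ratios.bedgraph")
        segments = cnv.segment_ratios(track, alpha=config.cbs_alpha,
                                      seed=stage_seed["cbs"])
        calls = cnv.call_duplication(segments, catalog.CHROM,
                                     min_log2=config.min_log2,
                                     min_span_bp=config.min_span_bp)
        io.write_intervals_bed([c.interval for c in calls], out / "dup_calls.bed",
                               names=[c.id for c in calls])
        summary["stages"]["cnv"] = {
            "n_segments": len(segments),
            "n_duplication_calls": len(calls),
            "calls": [{"start": c.interval.start, "end": c.interval.end,
                       "length_bp": interval_length(c.interval)} for c in calls],
            "dup_segment_mean_log2": max((s.mean for s in segments), default=None),
        }

    if config.stages.get("rank", False):
        ranked = conservation.rank_candidates(
            list(catalog.FRIESIAN_BLOCK.members), demo_conservation_profiles(),
            tau_hi=config.tau_hi, tau_lo=config.tau_lo)
        ranked.to_csv(out / "ranked_candidates.tsv", sep="\t", index=False)
        summary["stages"]["rank"] = {
            "order": ranked[ranked["rankable"]]["id"].tolist(),
            "categories": dict(zip(ranked["id"], ranked["category"].astype(str))),
        }

    if config.stages.get("associate", False):
        table, pedigree = simulate.generate_population_table(
            seed=stage_seed["population"])
        table.to_csv(out / "allele_calls.tsv", sep="\t", index=False)
        pedigree.to_csv(out / "pedigree.tsv", sep="\t", index=False)
        report = association.perfect_association_test(table)
        compounds = association.compound_heterozygote_scan(table)
        recomb = association.block_recombination_check(table, catalog.FRIESIAN_BLOCK)
        dist = association.genotype_distribution_summary(table)
        dist["counts"].to_csv(out / "genotype_counts.tsv", sep="\t")
        summary["stages"]["associate"] = {
            "perfect_association": report.holds,
            "n_violations": len(report.violations),
            "n_compound_heterozygotes": len(compounds),
            "n_recombinants": len(recomb),
            "pct_wildtype_homozygous": float(dist["percent"].loc[0, 0]),
        }

    io.write_json(summary, out / "summary.json")
    return summary
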