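"""Pipeline orchestration: configuration, stage chaining, result bundle.

Every threshold the analysis uses is a named field of
:class:`PipelineConfig` with the conservative defaults the method was built
around (GQ 999, TP 60, 400-kb pair/end exclusions, 100-kb validation windows
with 0.1/0.9 thresholds, 250-kb GC flanks, 2-kb promoters, 10,000
permutations), so sensitivity to any filter can be probed from the config
alone.  Outputs embed the seed and thresholds used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, enrichment, maps, phasing, simulate, spatial
from .io import meta_dict, read_chrom_meta, read_vcf_quartet, write_chrom_meta, \
    write_quartet_vcf, read_annotations, read_fst_windows

logger = logging.getLogger("xomap")


@dataclass
class PipelineConfig:
    """Declarative configuration for a full run."""

    out_dir: str = "results"
    seed: int = 0

    # inputs: either simulate or provide VCFs
    simulate: bool = True
    n_quartets: int = 15
    n_female_used: int = 12
    snp_spacing_mean: float = 2500.0
    informative_fraction: float = 1.0
    error_rate: float = 1e-3
    missing_rate: float = 0.0
    vcf_paths: list = field(default_factory=list)     # one per quartet
    quartet_samples: list = field(default_factory=list)  # 4 names per quartet
    chrom_meta_path: str | None = None
    annotations_path: str | None = None
    fasta_path: str | None = None
    fst_windows_path: str | None = None

    # filtering / calling thresholds
    min_gq: int = 999
    min_tp: int = 60
    changepoint_beta: float = 3.0
    validation_window_bp: int = 100_000
    validation_lo: float = 0.1
    validation_hi: float = 0.9
    min_separation: int = 400_000
    end_buffer: int = 400_000

    # statistics
    n_segments_model: int = 10
    hotspot_windows_bp: tuple = (100_000, 10_000)
    n_sims: int = 10_000
    gc_flank_bp: int = 250_000
    promoter_bp: int = 2_000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hotspot_windows_bp"] = list(self.hotspot_windows_bp)
        return d


def _phase_and_call(cfg: PipelineConfig, tables, metas, use_mother):
    md = meta_dict(metas)
    all_pairs = []
    for i, table in enumerate(tables):
        pairs, _ = phasing.phase_quartet(
            table, cfg.min_gq, cfg.min_tp,
            parent_ids=(table.samples[0], table.samples[1]),
            pair_id=f"pair{i}")
        if not use_mother[i]:
            pairs = [p for p in pairs if p.parent_sex != "female"]
        all_pairs += pairs
    co = calling.call_crossovers(
        all_pairs, md, beta=cfg.changepoint_beta,
        window_bp=cfg.validation_window_bp, lo=cfg.validation_lo,
        hi=cfg.validation_hi, min_separation=cfg.min_separation,
        end_buffer=cfg.end_buffer)
    return co


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; write the result bundle; return summary.

    With ``simulate=True`` the quartets come from the meiosis simulator and
    recovery against ground truth is reported.  Statistical outputs are
    deterministic given the seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"seed": config.seed, "config": config.to_dict()}

    truth = None
    if config.simulate:
        ds = simulate.simulate_dataset(
            meta=(read_chrom_meta(config.chrom_meta_path)
                  if config.chrom_meta_path else None),
            n_quartets=config.n_quartets, n_female_used=config.n_female_used,
            snp_spacing_mean=config.snp_spacing_mean,
            informative_fraction=config.informative_fraction,
            error_rate=config.error_rate, missing_rate=config.missing_rate,
            min_separation=config.min_separation, end_buffer=config.end_buffer,
            seed=config.seed)
        metas, tables, truth, use_mother = ds.meta, ds.tables, ds.truth, ds.use_mother
        meioses = ds.meioses_by_sex
        write_chrom_meta(metas, out / "chrom_meta.tsv")
        simulate.write_truth_tsv(truth, out / "truth_transitions.tsv",
                                 out / "truth_chiasmata.tsv")
    else:
        if not config.vcf_paths or config.chrom_meta_path is None:
            raise ValueError("need vcf_paths and chrom_meta_path when not simulating")
        metas = read_chrom_meta(config.chrom_meta_path)
        tables = [read_vcf_quartet(p, s)
                  for p, s in zip(config.vcf_paths, config.quartet_samples)]
        use_mother = [True] * len(tables)
        meioses = {"male": 2 * len(tables), "female": 2 * len(tables)}

    if not tables:
        (out / "co_table.tsv").write_text(
            "\t".join(calling.CO_COLUMNS) + "\n")
        summary["n_crossovers"] = 0
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        return summary

    md = meta_dict(metas)
    co = _phase_and_call(config, tables, metas, use_mother)
    co.to_csv(out / "co_table.tsv", sep="\t", index=False)
    kept = calling.retained(co)
    summary["n_crossovers"] = int(len(kept))
    summary["n_crossovers_by_sex"] = (
        kept.parent_sex.value_counts().to_dict() if len(kept) else {})

    chrom_names = [m.name for m in metas]
    table, stats_ = maps.per_chromosome_table(kept, meioses, chrom_names)
    table.to_csv(out / "map_table.tsv", sep="\t", index=False)
    summary["map_stats"] = stats_
    totals = table[table.chromosome == "Total"].iloc[0]
    summary["total_map_cM"] = {"female": float(totals.female_cM),
                               "male": float(totals.male_cM),
                               "ratio": float(totals.ratio)}

    if len(kept):
        maps.segment_correlation_scan(kept, md).to_csv(
            out / "segment_correlations.tsv", sep="\t", index=False)
        if any(m.centromere_pos_bp is not None for m in metas):
            arms, arm_tests = maps.arm_rates(kept, md)
            arms.to_csv(out / "arm_rates.tsv", sep="\t", index=False)
            summary["arm_tests"] = arm_tests
            for sex in ("male", "female"):
                cov = spatial.build_covariates(md, config.n_segments_model)
                cov = spatial.count_cos_in_segments(kept, cov, sex=sex)
                ledger = spatial.fit_model_ledger(cov, "n_co")
                ledger.to_csv(out / f"model_ledger_{sex}.tsv", sep="\t",
                              index=False)
                summary[f"best_model_{sex}"] = spatial.best_model(ledger)

        hotspots = {}
        for w in config.hotspot_windows_bp:
            res = enrichment.hotspot_permutation(
                kept, md, w, n_sims=config.n_sims, seed=config.seed)
            hotspots[f"{w}bp"] = {
                "observed": res.observed, "null_median": res.null_median,
                "p_enrichment": res.p_enrichment}
        summary["hotspots"] = hotspots

        if config.annotations_path:
            ann = read_annotations(config.annotations_path)
            lengths = {m.name: m.length_bp for m in metas}
            features = {
                "gene": ann.genes[["chrom", "start", "end"]],
                "exon": ann.exons[["chrom", "start", "end"]],
                "intron": ann.introns()[["chrom", "start", "end"]],
                "promoter": ann.promoters(lengths, config.promoter_bp)[
                    ["chrom", "start", "end"]],
            }
            overlaps = {}
            for name, feats in features.items():
                if not len(feats):
                    continue
                res = enrichment.feature_overlap_permutation(
                    kept, feats, md, n_sims=config.n_sims, seed=config.seed,
                    statistic=f"{name}_overlap")
                overlaps[name] = {"observed": res.observed,
                                  "null_median": res.null_median,
                                  "p_two_sided": res.p_two_sided}
            summary["feature_overlap"] = overlaps

        if config.fasta_path:
            gc_table, gc_tests = enrichment.gc_analysis(
                kept, config.fasta_path, md, config.gc_flank_bp)
            gc_table.to_csv(out / "gc_intervals.tsv", sep="\t", index=False)
            summary["gc_tests"] = gc_tests

        if config.fst_windows_path:
            fst = spatial.fst_star(read_fst_windows(config.fst_windows_path))
            fst.to_csv(out / "fst_star.tsv", sep="\t", index=False)
            segs = maps.fold_and_bin(kept, md, config.n_segments_model)
            rec = spatial.mean_rel_length_by_segment(segs, config.n_segments_model)
            fseg = spatial.fst_star_by_folded_segment(fst, md,
                                                      config.n_segments_model)
            r, p = spatial.recomb_differentiation_correlation(rec, fseg)
            summary["fst_recomb_correlation"] = {"r": r, "p": p}

    if truth is not None and len(kept):
        summary["recovery"] = simulate.evaluate_recovery(co, truth)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
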