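"""Config-driven orchestration of the full selection-signature analysis.

Given phased input (or a simulation block), the pipeline runs, per focal /
comparison population pair, the windowed FST + diversity-ratio cross
analysis with Mann-Whitney validation, the within-population iHS scan, the
cross-population xpEHH scan, merges outlier windows into candidate regions,
annotates them with gene/QTL intervals, intersects the per-comparison gene
lists, and profiles LD decay — writing every table as TSV plus BED exports
and a run log that records each realized threshold.

All stages call the public library functions; the pipeline adds no
computation of its own, so every reported number can be re-derived directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, haplotype, ld, outliers
from .core import HaplotypeMatrix, PopulationMap
from .io import (
    make_windows,
    read_intervals,
    read_phased_vcf,
    read_population_map,
    write_intervals_bed,
)
from .outliers import regions_to_frame, regions_to_intervals
from .simulate import BottleneckConfig, SimConfig, SweepConfig, emit_truth_bundle, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative run description with the study defaults pre-filled.

    Windows are 10 kb; the FST/diversity windows tile the genome
    (step = size) while the haplotype-scan windows overlap by 1 kb
    (step = size - overlap = 9 kb). Thresholds: joint-tail quantile 0.95,
    iHS p < 1e-6 with >= 2 outlier SNPs per window, xpEHH p < 1e-4 with
    >= 5.
    """

    focal: str
    comparisons: list[str]
    out_dir: str = "sweepscan_out"
    seed: int = 1
    # input: either a VCF + sample map, or a simulate block
    vcf: str | None = None
    popmap: str | None = None
    simulate: dict | None = None
    genes: str | None = None
    qtls: str | None = None
    # analysis parameters (study defaults)
    fst_window: int = 10_000
    fst_step: int = 10_000
    hap_window: int = 10_000
    hap_overlap: int = 1_000
    tail_quantile: float = 0.95
    ihs_p: float = 1e-6
    ihs_min_snps: int = 2
    xpehh_p: float = 1e-4
    xpehh_min_snps: int = 5
    maf_min: float = 0.05
    ehh_cutoff: float = 0.05
    maxgap: int = 200_000
    max_gap_merge: int = 0
    ld_bin: int = 10_000
    ld_max_distance: int = 250_000
    n_boot: int = 100
    threads: int = 1  # accepted for interface parity; computation is
    # single-threaded and results never depend on it

    def __post_init__(self) -> None:
        for name in ("tail_quantile", "ihs_p", "xpehh_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.vcf is None and self.simulate is None:
            raise ValueError("config needs either a vcf/popmap pair or a simulate block")

    @property
    def hap_step(self) -> int:
        return self.hap_window - self.hap_overlap

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _sim_config(block: dict, seed: int) -> SimConfig:
    block = dict(block)
    if "sweep" in block and block["sweep"] is not None:
        block["sweep"] = SweepConfig(**block["sweep"])
    if "bottleneck" in block and block["bottleneck"] is not None:
        block["bottleneck"] = BottleneckConfig(**block["bottleneck"])
    block.setdefault("seed", seed)
    return SimConfig(**block)


def _load_input(
    config: RunConfig, out: Path
) -> tuple[dict[str, dict[str, HaplotypeMatrix]], PopulationMap]:
    """Returns {chrom: {pop: matrix}} plus the population map."""
    if config.simulate is not None:
        sim_cfg = _sim_config(config.simulate, config.seed)
        matrices, truth = simulate(sim_cfg)
        emit_truth_bundle(matrices, truth, sim_cfg, out / "simulated")
        popmap = PopulationMap(
            {s: pop for pop, m in matrices.items() for s in m.sample_ids}
        )
        chrom = next(iter(matrices.values())).chrom
        return {chrom: matrices}, popmap
    popmap = read_population_map(config.popmap)
    per_chrom = read_phased_vcf(config.vcf, popmap)
    split: dict[str, dict[str, HaplotypeMatrix]] = {}
    for chrom, matrix in per_chrom.items():
        split[chrom] = {
            pop: matrix.subset_samples(popmap.samples_in(pop))
            for pop in popmap.populations
        }
    return split, popmap


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the result tables and writes the
    report bundle under ``config.out_dir``. Deterministic given the seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed={config.seed}"]

    def stage(name: str):
        logger.info("stage: %s", name)
        log.append(f"stage {name}")

    try:
        stage("load")
        per_chrom, popmap = _load_input(config, out)
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc
    pops = popmap.populations
    if config.focal not in pops:
        raise ValueError(f"focal population {config.focal!r} not in sample map {pops}")
    for c in config.comparisons:
        if c not in pops:
            raise ValueError(f"comparison population {c!r} not in sample map")

    genes = read_intervals(config.genes) if config.genes else None
    qtls = read_intervals(config.qtls) if config.qtls else None
    if config.simulate is not None and genes is None:
        genes = read_intervals(out / "simulated" / "genes.bed", format="BED")
        qtls = read_intervals(out / "simulated" / "qtls.bed", format="BED")

    results: dict = {"log": log}
    table1_rows = []
    table2_rows = []
    fstpi_gene_sets: dict[str, set[str]] = {}
    xpehh_gene_sets: dict[str, set[str]] = {}
    all_regions = []

    chrom_lengths = {
        chrom: int(max(m.positions[-1] for m in mats.values() if m.n_variants))
        for chrom, mats in per_chrom.items()
    }

    # ---------------- xpFST/theta-pi cross analysis -----------------------
    stage("scan-fstpi")
    for comp in config.comparisons:
        tables = []
        for chrom, mats in per_chrom.items():
            merged = _merged_genotypes(mats, [comp, config.focal])
            windows = make_windows(
                chrom_lengths[chrom], config.fst_window, config.fst_step, chrom=chrom
            )
            tables.append(
                diversity.fst_pi_window_table(
                    merged, popmap, comp, config.focal, windows
                )
            )
        wtab = pd.concat(tables, ignore_index=True)
        wtab["window_id"] = np.arange(len(wtab))  # genome-wide unique ids
        wtab.to_csv(out / f"fstpi_windows_{comp}.tsv", sep="\t", index=False)

        sel_fst, sel_ratio, joint = outliers.joint_tail_outliers(
            wtab, quantile=config.tail_quantile
        )
        log.append(
            f"{comp}: fst_threshold={sel_fst.threshold:.6g} "
            f"ratio_threshold={sel_ratio.threshold:.6g} joint_windows={len(joint)}"
        )
        defined = np.isfinite(wtab["fst"]) & np.isfinite(wtab["theta_pi_ratio"])
        joint_mask = wtab["window_id"].isin(joint)
        mw_fst = mw_ratio = None
        if (joint_mask & defined).any():
            mw_fst = outliers.mann_whitney_u(
                wtab.loc[joint_mask & defined, "fst"].to_numpy(),
                wtab.loc[defined, "fst"].to_numpy(),
            )
            mw_ratio = outliers.mann_whitney_u(
                wtab.loc[joint_mask & defined, "theta_pi_ratio"].to_numpy(),
                wtab.loc[defined, "theta_pi_ratio"].to_numpy(),
            )

        regions = outliers.merge_windows_to_regions(
            wtab.loc[joint_mask], source="xpFstPi", max_gap=config.max_gap_merge
        )
        regions, gene_universe, _ = outliers.annotate_regions(regions, genes, qtls)
        fstpi_gene_sets[comp] = gene_universe
        all_regions.extend(regions)
        table1_rows.append(
            {
                "comparison": f"{config.focal}_vs_{comp}",
                "threshold_fst": sel_fst.threshold,
                "W_fst": mw_fst.w if mw_fst else float("nan"),
                "p_fst": outliers.format_p(mw_fst.p_two_sided) if mw_fst else "NA",
                "threshold_ratio": sel_ratio.threshold,
                "W_ratio": mw_ratio.w if mw_ratio else float("nan"),
                "p_ratio": outliers.format_p(mw_ratio.p_two_sided) if mw_ratio else "NA",
                "n_outlier_regions": len(regions),
                "outlier_extent_kb": sum(r.span for r in regions) / 1e3,
            }
        )

    # ---------------- iHS (focal population) ------------------------------
    stage("scan-ihs")
    ihs_tables = []
    for chrom, mats in per_chrom.items():
        raw = haplotype.ihs_scan(
            mats[config.focal],
            maf_min=config.maf_min,
            cutoff=config.ehh_cutoff,
            maxgap=config.maxgap,
        )
        raw.insert(0, "chrom", chrom)
        ihs_tables.append(raw)
    ihs_raw = pd.concat(ihs_tables, ignore_index=True)
    ihs_scores = haplotype.standardize_ihs(ihs_raw)
    ihs_scores.to_csv(out / f"ihs_{config.focal}.tsv", sep="\t", index=False)
    ihs_regions = _hap_regions(
        ihs_scores, per_chrom, chrom_lengths, config, "iHS",
        config.ihs_p, config.ihs_min_snps,
    )
    ihs_regions, ihs_genes, _ = outliers.annotate_regions(ihs_regions, genes, qtls)
    all_regions.extend(ihs_regions)
    table2_rows.append(_table2_row("iHS", config.focal, ihs_scores, ihs_regions, config.ihs_p))

    # ---------------- xpEHH (focal vs each comparison) --------------------
    stage("scan-xpehh")
    for comp in config.comparisons:
        xp_tables = []
        for chrom, mats in per_chrom.items():
            raw = haplotype.xpehh_scan(
                mats[config.focal],
                mats[comp],
                cutoff=config.ehh_cutoff,
                maxgap=config.maxgap,
            )
            raw.insert(0, "chrom", chrom)
            xp_tables.append(raw)
        xp = pd.concat(xp_tables, ignore_index=True)
        xp.to_csv(out / f"xpehh_{config.focal}_vs_{comp}.tsv", sep="\t", index=False)
        xp_regions = _hap_regions(
            xp, per_chrom, chrom_lengths, config, "xpEHH",
            config.xpehh_p, config.xpehh_min_snps,
        )
        xp_regions, xp_genes, _ = outliers.annotate_regions(xp_regions, genes, qtls)
        xpehh_gene_sets[comp] = xp_genes
        all_regions.extend(xp_regions)
        table2_rows.append(_table2_row(f"xpEHH_{comp}", config.focal, xp, xp_regions, config.xpehh_p))

    # ---------------- summaries, intersections, LD ------------------------
    stage("summaries")
    table1 = pd.DataFrame.from_records(table1_rows)
    table1.to_csv(out / "cross_analysis_summary.tsv", sep="\t", index=False)
    table2 = pd.DataFrame.from_records(table2_rows)
    table2.to_csv(out / "haplotype_scan_summary.tsv", sep="\t", index=False)
    region_frame = regions_to_frame(all_regions)
    region_frame.to_csv(out / "candidate_regions.tsv", sep="\t", index=False)
    write_intervals_bed(regions_to_intervals(all_regions), out / "candidate_regions.bed")

    intersections = {}
    for label, sets in (("xpFstPi", fstpi_gene_sets), ("xpEHH", xpehh_gene_sets)):
        if len(sets) >= 2:
            tab = outliers.intersect_gene_lists(sets)
            tab.to_csv(out / f"gene_intersections_{label}.tsv", sep="\t", index=False)
            intersections[label] = tab

    stage("ld")
    ld_profiles = {}
    for pop in pops:
        profiles = []
        for chrom, mats in per_chrom.items():
            profiles.append(
                ld.ld_decay_profile(
                    mats[pop],
                    bin_size=config.ld_bin,
                    max_distance=config.ld_max_distance,
                    seed=config.seed,
                )
            )
        prof = profiles[0] if len(profiles) == 1 else _combine_ld(profiles)
        prof.to_csv(out / f"ld_decay_{pop}.tsv", sep="\t", index=False)
        ld_profiles[pop] = prof

    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    results.update(
        {
            "table1": table1,
            "table2": table2,
            "regions": region_frame,
            "region_objects": all_regions,
            "ihs": ihs_scores,
            "intersections": intersections,
            "ld": ld_profiles,
            "popmap": popmap,
        }
    )
    return results


def _merged_genotypes(mats: dict[str, HaplotypeMatrix], pops: list[str]):
    from .simulate import merge_populations

    return merge_populations({p: mats[p] for p in pops}).to_genotypes()


def _hap_regions(scores, per_chrom, chrom_lengths, config, source, p_thr, min_snps):
    regions = []
    for chrom in per_chrom:
        windows = make_windows(
            chrom_lengths[chrom], config.hap_window, config.hap_step, chrom=chrom
        )
        sub = scores[scores["chrom"] == chrom] if "chrom" in scores else scores
        calls = haplotype.call_outlier_windows(sub, windows, p_thr, min_snps)
        cand = calls[calls["is_candidate"]]
        regions.extend(
            outliers.merge_windows_to_regions(
                cand,
                source=source,
                max_gap=config.max_gap_merge,
                snp_positions=sub["position"].to_numpy(),
                outlier_positions=sub.loc[sub["p"] < p_thr, "position"].to_numpy(),
            )
        )
    return regions


def _table2_row(method, focal, scores, regions, p_thr):
    return {
        "method": method,
        "population": focal,
        "n_snps_scored": int(len(scores)),
        "n_outlier_snps": int((scores["p"] < p_thr).sum()) if len(scores) else 0,
        "n_regions": len(regions),
        "regions_extent_kb": sum(r.span for r in regions) / 1e3,
        "gene_count": len({g for r in regions for g in r.genes}),
    }


def _combine_ld(profiles: list[pd.DataFrame]) -> pd.DataFrame:
    out = profiles[0].copy()
    n = sum(p["n_pairs"] for p in profiles)
    weighted = sum(
        np.where(p["n_pairs"] > 0, p["mean_r2"].fillna(0) * p["n_pairs"], 0.0)
        for p in profiles
    )
    out["mean_r2"] = np.where(n > 0, weighted / np.maximum(n, 1), np.nan)
    out["n_pairs"] = n
    return out


def save_config(config: RunConfig, path: str | Path) -> None:
    data = {k: v for k, v in vars(config).items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_truth(out_dir: str | Path) -> dict | None:
    p = Path(out_dir) / "simulated" / "truth.json"
    if not p.exists():
        return None
    return json.loads(p.read_text())
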