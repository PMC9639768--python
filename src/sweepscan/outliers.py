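"""Joint FST / diversity-ratio tail selection, Mann-Whitney validation,
candidate-region assembly, interval annotation and gene-list intersection.

The cross analysis selects windows lying simultaneously in the right
``1 - quantile`` tails of windowed FST and of the log2 diversity ratio, then
checks that outlier windows differ from the genomic background with a
Mann-Whitney U test. Candidate windows (from this cross analysis or from the
haplotype scans) are merged into non-overlapping regions and annotated with
any gene / QTL intervals sharing at least one bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .core import Interval, IntervalSet


@dataclass
class TailSelection:
    statistic: str
    quantile: float
    threshold: float
    window_ids: set[int]


def joint_tail_outliers(
    window_stats: pd.DataFrame,
    quantile: float = 0.95,
    fst_col: str = "fst",
    ratio_col: str = "theta_pi_ratio",
) -> tuple[TailSelection, TailSelection, set[int]]:
    """Windows in the right tails of both FST and the diversity ratio.

    Thresholds are the empirical linear-interpolation quantiles of each
    statistic over its defined (finite) windows; a window is selected when
    its value is >= the threshold, and the joint set is the intersection of
    the two tails. Requires >= 20 defined windows per statistic.

    Returns (fst_selection, ratio_selection, joint_window_ids).
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    selections = []
    for col in (fst_col, ratio_col):
        vals = window_stats[col].to_numpy(dtype=float)
        defined = np.isfinite(vals)
        if defined.sum() < 20:
            raise ValueError(
                f"only {int(defined.sum())} defined windows for {col}; "
                "need >= 20 for a meaningful quantile"
            )
        thr = float(np.quantile(vals[defined], quantile))
        ids = set(
            window_stats.loc[defined & (vals >= thr), "window_id"].astype(int)
        )
        selections.append(
            TailSelection(statistic=col, quantile=quantile, threshold=thr, window_ids=ids)
        )
    joint = selections[0].window_ids & selections[1].window_ids
    return selections[0], selections[1], joint


@dataclass
class MannWhitneyResult:
    """R wilcox.test convention: W = #{pairs with x > y} + 0.5 #{ties}."""

    w: float
    p_two_sided: float
    n_outlier: int
    n_background: int
    method: str  # "exact" or "normal"


def mann_whitney_u(
    outlier_values: np.ndarray, background_values: np.ndarray
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of outlier vs background values.

    Uses the exact null distribution when n_x * n_y <= 10,000 and the data
    carry no ties, otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(outlier_values, dtype=float)
    y = np.asarray(background_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact_ok = (x.size * y.size <= 10_000) and not has_ties
    method = "exact" if exact_ok else "asymptotic"
    res = mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return MannWhitneyResult(
        w=float(res.statistic),
        p_two_sided=float(res.pvalue),
        n_outlier=int(x.size),
        n_background=int(y.size),
        method="exact" if exact_ok else "normal",
    )


def format_p(p: float, floor: float = 2.2e-16) -> str:
    """Report a p-value, bounding tiny values as '< 2.2e-16'."""
    return f"< {floor:g}" if p < floor else f"{p:.4g}"


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    source: str  # xpFstPi | iHS | xpEHH
    n_windows: int
    n_snps: int = 0
    n_outlier_snps: int = 0
    genes: list[str] = field(default_factory=list)
    qtls: list[str] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def merge_windows_to_regions(
    candidate_windows: pd.DataFrame,
    source: str,
    max_gap: int = 0,
    snp_positions: np.ndarray | None = None,
    outlier_positions: np.ndarray | None = None,
) -> list[CandidateRegion]:
    """Union overlapping / bookended candidate windows into regions.

    Windows whose gap is <= ``max_gap`` bp are merged (gap 0 = bookended).
    SNPs are counted once per region via the optional position arrays.
    Merging is idempotent: merging the resulting regions changes nothing.
    """
    if candidate_windows.empty:
        return []
    df = candidate_windows.sort_values(["chrom", "start", "end"])
    snp_positions = (
        np.asarray(snp_positions) if snp_positions is not None else np.empty(0, int)
    )
    outlier_positions = (
        np.asarray(outlier_positions)
        if outlier_positions is not None
        else np.empty(0, int)
    )
    regions: list[CandidateRegion] = []
    cur: dict | None = None
    for row in df.itertuples(index=False):
        if (
            cur is not None
            and row.chrom == cur["chrom"]
            and row.start - cur["end"] - 1 <= max_gap
        ):
            cur["end"] = max(cur["end"], row.end)
            cur["n"] += 1
        else:
            if cur is not None:
                regions.append(_finish_region(cur, source, snp_positions, outlier_positions))
            cur = {"chrom": row.chrom, "start": int(row.start), "end": int(row.end), "n": 1}
    if cur is not None:
        regions.append(_finish_region(cur, source, snp_positions, outlier_positions))
    return regions


def _finish_region(
    cur: dict, source: str, snp_positions: np.ndarray, outlier_positions: np.ndarray
) -> CandidateRegion:
    in_r = (snp_positions >= cur["start"]) & (snp_positions <= cur["end"])
    in_o = (outlier_positions >= cur["start"]) & (outlier_positions <= cur["end"])
    return CandidateRegion(
        chrom=cur["chrom"],
        start=cur["start"],
        end=cur["end"],
        source=source,
        n_windows=cur["n"],
        n_snps=int(in_r.sum()),
        n_outlier_snps=int(in_o.sum()),
    )


def annotate_regions(
    regions: list[CandidateRegion],
    genes: IntervalSet | None = None,
    qtls: IntervalSet | None = None,
) -> tuple[list[CandidateRegion], set[str], set[str]]:
    """Attach overlapping gene / QTL names to each region.

    Any shared bp counts as overlap (abutting intervals without shared bp do
    not). Returns the regions plus the per-source gene and QTL universes
    (each name once, however many regions it overlaps).
    """
    gene_universe: set[str] = set()
    qtl_universe: set[str] = set()
    for r in regions:
        if genes is not None:
            hits = genes.overlapping(r.chrom, r.start, r.end)
            r.genes = sorted({h.name for h in hits})
            gene_universe.update(r.genes)
        if qtls is not None:
            hits = qtls.overlapping(r.chrom, r.start, r.end)
            r.qtls = sorted({h.name for h in hits})
            qtl_universe.update(r.qtls)
    return regions, gene_universe, qtl_universe


def regions_to_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "span": r.span,
                "source": r.source,
                "n_windows": r.n_windows,
                "n_snps": r.n_snps,
                "n_outlier_snps": r.n_outlier_snps,
                "genes": ",".join(r.genes),
                "qtls": ",".join(r.qtls),
            }
            for r in regions
        ],
        columns=[
            "chrom", "start", "end", "span", "source", "n_windows",
            "n_snps", "n_outlier_snps", "genes", "qtls",
        ],
    )


def regions_to_intervals(regions: list[CandidateRegion]) -> IntervalSet:
    out = IntervalSet()
    for i, r in enumerate(regions):
        out.add(
            Interval(
                chrom=r.chrom, start=r.start, end=r.end,
                name=f"{r.source}_region{i}", kind="other",
            )
        )
    return out


def intersect_gene_lists(named_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Venn-style intersection-class counts for 2-5 named gene sets.

    Each class is an exclusive membership pattern (present in exactly the
    listed sets); all 2^n - 1 classes are reported, plus a ``full`` row with
    the members shared by every set. With more than 5 sets only pairwise
    intersections and the full intersection are reported.

    Columns: sets (sorted '+'-joined names), n, members (';'-joined, only for
    the full intersection to keep output compact).
    """
    if len(named_sets) < 2:
        raise ValueError("need >= 2 gene sets")
    names = list(named_sets)
    records = []
    full = set.intersection(*(set(named_sets[n]) for n in names))
    if len(named_sets) <= 5:
        for k in range(1, len(names) + 1):
            for combo in combinations(names, k):
                inside = set.intersection(*(set(named_sets[n]) for n in combo))
                outside = set().union(
                    *(set(named_sets[n]) for n in names if n not in combo)
                )
                exclusive = inside - outside
                records.append(
                    {"sets": "+".join(combo), "n": len(exclusive), "members": ""}
                )
    else:
        for a, b in combinations(names, 2):
            records.append(
                {
                    "sets": f"{a}+{b}",
                    "n": len(set(named_sets[a]) & set(named_sets[b])),
                    "members": "",
                }
            )
    records.append({"sets": "full", "n": len(full), "members": ";".join(sorted(full))})
    return pd.DataFrame.from_records(records)
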