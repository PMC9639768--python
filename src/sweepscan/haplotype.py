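"""Extended haplotype homozygosity scans: EHH, iHH, iHS and xpEHH.

Definitions
-----------
EHH at a marker x, for a set of n carrier haplotypes of a core allele, is the
probability that two carriers drawn at random are identical over the interval
from the core SNP to x:

    EHH(x) = sum_h C(n_h, 2) / C(n, 2)

where n_h counts carriers sharing the h-th distinct extended haplotype.
EHH(core) = 1 and EHH is monotone non-increasing outward (partitions are
nested).

iHH is the trapezoidal integral of EHH over physical distance, in both
directions from the core, truncated by linear interpolation at the point
where EHH first drops below a cutoff (default 0.05). If the last marker on a
side is reached with EHH still >= cutoff the score is border-flagged and, by
default, discarded; inter-marker gaps larger than ``maxgap`` truncate the
integral at the last marker before the gap.

iHS is ln(iHH_ancestral / iHH_derived), standardized to zero mean and unit
variance within derived-allele-frequency bins; xpEHH is
ln(iHH_pop1 / iHH_pop2) over allele-agnostic per-population EHH, standardized
genome-wide. Both are assigned the two-sided normal p-value 2(1 - Phi(|z|)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import _kernels
from .core import GenomicWindow, HaplotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.05
DEFAULT_MAXGAP = 200_000


@dataclass
class EhhProfile:
    """EHH values walking outward from a core marker on one side.

    ``positions[0]`` is the core position with ``ehh[0] = 1``; subsequent
    entries move away from the core. ``reached_end`` is True when the walk
    consumed the last marker on this side (no early stop below the cutoff).
    """

    positions: np.ndarray
    ehh: np.ndarray
    reached_end: bool


def _walk_side(
    alleles: np.ndarray,
    positions: np.ndarray,
    core_index: int,
    carriers: np.ndarray,
    step: int,
    stop_below: float | None,
    stop_beyond: float | None = None,
) -> EhhProfile:
    """Walk outward from the core refining the haplotype partition.

    Missing alleles are treated as a distinct state (conservative: they break
    homozygosity). With ``stop_below`` set, the walk stops at the first marker
    whose EHH falls below it (that marker is included so callers can
    interpolate the crossing); with ``stop_beyond`` it stops at the first
    marker at or past that physical distance from the core.
    """
    m = positions.size
    out_pos = np.empty(m + 1, dtype=np.int64)
    out_ehh = np.empty(m + 1, dtype=np.float64)
    k, reached_end = _kernels.ehh_walk(
        alleles,
        np.ascontiguousarray(positions, dtype=np.int64),
        core_index,
        np.ascontiguousarray(carriers, dtype=np.int64),
        step,
        -1.0 if stop_below is None else float(stop_below),
        -1.0 if stop_beyond is None else float(stop_beyond),
        out_pos,
        out_ehh,
    )
    return EhhProfile(out_pos[:k].copy(), out_ehh[:k].copy(), reached_end=reached_end)


def ehh_profile(
    matrix: HaplotypeMatrix,
    core_index: int,
    carriers: np.ndarray,
    side: str = "both",
    stop_below: float | None = None,
) -> EhhProfile | tuple[EhhProfile, EhhProfile]:
    """EHH outward from ``core_index`` among the given carrier haplotype rows.

    ``side`` is "left", "right" or "both" (returns a (left, right) tuple).
    Requires at least two carriers.
    """
    carriers = np.asarray(carriers)
    if carriers.size < 2:
        raise ValueError("EHH needs >= 2 carrier haplotypes")
    args = (matrix.alleles, matrix.positions, core_index, carriers)
    if side == "left":
        return _walk_side(*args, step=-1, stop_below=stop_below)
    if side == "right":
        return _walk_side(*args, step=+1, stop_below=stop_below)
    if side == "both":
        return (
            _walk_side(*args, step=-1, stop_below=stop_below),
            _walk_side(*args, step=+1, stop_below=stop_below),
        )
    raise ValueError(f"side must be left/right/both, got {side!r}")


def integrate_ihh(
    profile: EhhProfile,
    cutoff: float = DEFAULT_CUTOFF,
    maxgap: int = DEFAULT_MAXGAP,
) -> tuple[float, bool]:
    """Trapezoidal integral of one side's EHH profile over physical distance.

    Truncated by linear interpolation where EHH first crosses ``cutoff``.
    Returns (ihh, border_flag); border_flag is True when the profile ends
    (chromosome end) with EHH still >= cutoff. Gaps > ``maxgap`` truncate the
    integral without setting the border flag.
    """
    pos, ehh = profile.positions, profile.ehh
    ihh = 0.0
    for i in range(1, pos.size):
        gap = abs(int(pos[i]) - int(pos[i - 1]))
        if gap > maxgap:
            return ihh, False
        if ehh[i] >= cutoff:
            ihh += gap * (ehh[i - 1] + ehh[i]) / 2.0
        else:
            frac = (ehh[i - 1] - cutoff) / (ehh[i - 1] - ehh[i])
            d = gap * frac
            ihh += d * (ehh[i - 1] + cutoff) / 2.0
            return ihh, False
    # profile exhausted without crossing the cutoff
    return ihh, bool(profile.reached_end and ehh[-1] >= cutoff)


def _integrate_to_extent(
    profile: EhhProfile, extent: float, maxgap: int
) -> tuple[float, bool]:
    """Integrate a side's EHH out to a fixed physical distance from the core.

    The boundary EHH is linearly interpolated between the bracketing markers.
    Returns (ihh, hit_end) where hit_end is True if the profile ran out
    before the extent (chromosome end reached).
    """
    pos, ehh = profile.positions, profile.ehh
    core = int(pos[0])
    ihh = 0.0
    for i in range(1, pos.size):
        gap = abs(int(pos[i]) - int(pos[i - 1]))
        if gap > maxgap:
            return ihh, False
        d_prev = abs(int(pos[i - 1]) - core)
        d_here = abs(int(pos[i]) - core)
        if d_here <= extent:
            ihh += gap * (ehh[i - 1] + ehh[i]) / 2.0
            if d_here == extent:
                return ihh, False
        else:
            frac = (extent - d_prev) / (d_here - d_prev)
            e_at = ehh[i - 1] + frac * (ehh[i] - ehh[i - 1])
            ihh += (extent - d_prev) * (ehh[i - 1] + e_at) / 2.0
            return ihh, False
    return ihh, bool(profile.reached_end)


def _cutoff_extent(profile: EhhProfile, cutoff: float) -> float | None:
    """Physical distance from the core to the interpolated cutoff crossing,
    or None if the profile never crosses (border)."""
    pos, ehh = profile.positions, profile.ehh
    core = int(pos[0])
    for i in range(1, pos.size):
        if ehh[i] < cutoff:
            frac = (ehh[i - 1] - cutoff) / (ehh[i - 1] - ehh[i])
            d_prev = abs(int(pos[i - 1]) - core)
            d_here = abs(int(pos[i]) - core)
            return d_prev + frac * (d_here - d_prev)
    return None


# ---------------------------------------------------------------------------
# iHS
# ---------------------------------------------------------------------------

def ihs_scan(
    matrix: HaplotypeMatrix,
    maf_min: float = 0.05,
    cutoff: float = DEFAULT_CUTOFF,
    maxgap: int = DEFAULT_MAXGAP,
    keep_border: bool = False,
) -> pd.DataFrame:
    """Unstandardized iHS at every qualifying SNP of one population.

    Alleles are polarized to ancestral/derived (REF assumed ancestral when
    the matrix carries no annotation). SNPs pass when minor allele frequency
    >= ``maf_min`` among called alleles and both allele classes have >= 2
    carriers. SNPs with a zero iHH on either allele are skipped; border SNPs
    are discarded unless ``keep_border``.

    Columns: position, derived_freq, ihh_a, ihh_d, unihs, border.
    """
    derived = matrix.derived_alleles()
    records = []
    n_border = 0
    for j in range(matrix.n_variants):
        col = derived[:, j]
        anc = np.flatnonzero(col == 0)
        der = np.flatnonzero(col == 1)
        n_called = anc.size + der.size
        if n_called < 4 or anc.size < 2 or der.size < 2:
            continue
        freq = der.size / n_called
        if min(freq, 1.0 - freq) < maf_min:
            continue
        border = False
        ihh = {}
        for key, carriers in (("a", anc), ("d", der)):
            left, right = ehh_profile(
                matrix, j, carriers, side="both", stop_below=cutoff
            )
            il, bl = integrate_ihh(left, cutoff=cutoff, maxgap=maxgap)
            ir, br = integrate_ihh(right, cutoff=cutoff, maxgap=maxgap)
            ihh[key] = il + ir
            border = border or bl or br
        if border and not keep_border:
            n_border += 1
            continue
        if ihh["a"] <= 0.0 or ihh["d"] <= 0.0:
            continue
        records.append(
            {
                "position": int(matrix.positions[j]),
                "derived_freq": freq,
                "ihh_a": ihh["a"],
                "ihh_d": ihh["d"],
                "unihs": float(np.log(ihh["a"] / ihh["d"])),
                "border": border,
            }
        )
    if n_border:
        logger.info("ihs_scan: discarded %d border SNPs", n_border)
    if not records:
        logger.warning("ihs_scan: no qualifying SNPs")
        return pd.DataFrame(
            columns=["position", "derived_freq", "ihh_a", "ihh_d", "unihs", "border"]
        )
    return pd.DataFrame.from_records(records)


def _merge_sparse_bins(bin_idx: np.ndarray, n_bins: int, min_count: int) -> np.ndarray:
    """Group frequency bins left to right so every group holds >= min_count
    SNPs; a sparse trailing group is folded into its predecessor."""
    counts = np.bincount(bin_idx, minlength=n_bins)
    group_of = np.zeros(n_bins, dtype=np.int64)
    g = 0
    acc = 0
    for b in range(n_bins):
        group_of[b] = g
        acc += counts[b]
        if acc >= min_count:
            g += 1
            acc = 0
    if acc > 0 and g > 0:
        # fold the sparse tail into the previous group
        group_of[group_of == g] = g - 1
    return group_of[bin_idx]


def standardize_ihs(
    scores: pd.DataFrame,
    bin_width: float = 0.025,
    min_bin_count: int = 10,
) -> pd.DataFrame:
    """Standardize unihs within derived-allele-frequency bins and attach
    two-sided normal p-values.

    Bins of ``bin_width`` on derived frequency are merged with neighbors
    until each holds >= ``min_bin_count`` SNPs. Within each merged bin the
    mean is subtracted and the standard deviation divided out, so the output
    has mean 0 / sd 1 per bin by construction. p = 2(1 - Phi(|ihs|)).
    """
    out = scores.copy()
    if out.empty:
        out["ihs"] = pd.Series(dtype=float)
        out["p"] = pd.Series(dtype=float)
        out["log10p"] = pd.Series(dtype=float)
        return out
    freq = out["derived_freq"].to_numpy()
    n_bins = int(np.ceil(1.0 / bin_width))
    bin_idx = np.minimum((freq / bin_width).astype(np.int64), n_bins - 1)
    groups = _merge_sparse_bins(bin_idx, n_bins, min_bin_count)
    unihs = out["unihs"].to_numpy()
    z = np.full(unihs.size, np.nan)
    for g in np.unique(groups):
        sel = groups == g
        sd = unihs[sel].std(ddof=0)
        if sd == 0.0:
            logger.warning("standardize_ihs: zero variance in a frequency bin")
            continue
        z[sel] = (unihs[sel] - unihs[sel].mean()) / sd
    out["ihs"] = z
    out["p"] = np.clip(2.0 * norm.sf(np.abs(z)), 1e-300, 1.0)
    out["log10p"] = -np.log10(out["p"])
    return out


# ---------------------------------------------------------------------------
# xpEHH
# ---------------------------------------------------------------------------

def xpehh_scan(
    pop1: HaplotypeMatrix,
    pop2: HaplotypeMatrix,
    cutoff: float = DEFAULT_CUTOFF,
    maxgap: int = DEFAULT_MAXGAP,
    keep_border: bool = False,
) -> pd.DataFrame:
    """Standardized xpEHH at every SNP shared by two populations.

    Both matrices must carry the identical variant grid. EHH is
    allele-agnostic (all haplotypes of a population are the carrier set) and
    both populations are integrated to a shared stopping extent per side:
    the farther of the two interpolated cutoff crossings, each population's
    integral evaluated on its own profile out to that extent. Positive
    xpehh means longer haplotypes (selection) in ``pop1``.

    Columns: position, ihh_pop1, ihh_pop2, unxpehh, xpehh, p, log10p, border.
    """
    if not np.array_equal(pop1.positions, pop2.positions):
        raise ValueError("xpehh_scan requires the same variant grid in both pops")
    c1 = np.arange(pop1.n_haplotypes)
    c2 = np.arange(pop2.n_haplotypes)
    records = []
    n_border = 0
    for j in range(pop1.n_variants):
        pooled = np.concatenate([pop1.alleles[:, j], pop2.alleles[:, j]])
        called = pooled[pooled >= 0]
        if called.size < 4 or len(np.unique(called)) < 2:
            continue
        border = False
        ihh = [0.0, 0.0]
        for step in (-1, +1):
            profs = [
                _walk_side(m.alleles, m.positions, j, c, step=step, stop_below=cutoff)
                for m, c in ((pop1, c1), (pop2, c2))
            ]
            extents = [_cutoff_extent(p, cutoff) for p in profs]
            if any(e is None for e in extents):
                border = True
                break
            shared = max(extents)
            # the population that crossed first must be walked further out
            for k in range(2):
                prof = profs[k]
                dmax = abs(int(prof.positions[-1]) - int(prof.positions[0]))
                if dmax < shared:
                    m, c = ((pop1, c1), (pop2, c2))[k]
                    prof = _walk_side(
                        m.alleles, m.positions, j, c, step=step,
                        stop_below=None, stop_beyond=shared,
                    )
                val, hit_end = _integrate_to_extent(prof, shared, maxgap)
                if hit_end:
                    border = True
                ihh[k] += val
            if border:
                break
        if border and not keep_border:
            n_border += 1
            continue
        if ihh[0] <= 0.0 or ihh[1] <= 0.0:
            continue
        records.append(
            {
                "position": int(pop1.positions[j]),
                "ihh_pop1": ihh[0],
                "ihh_pop2": ihh[1],
                "unxpehh": float(np.log(ihh[0] / ihh[1])),
                "border": border,
            }
        )
    if n_border:
        logger.info("xpehh_scan: discarded %d border SNPs", n_border)
    if not records:
        logger.warning("xpehh_scan: no qualifying SNPs")
        return pd.DataFrame(
            columns=[
                "position", "ihh_pop1", "ihh_pop2", "unxpehh",
                "xpehh", "p", "log10p", "border",
            ]
        )
    out = pd.DataFrame.from_records(records)
    un = out["unxpehh"].to_numpy()
    sd = un.std(ddof=0)
    if sd == 0.0:
        out["xpehh"] = 0.0 if un.size == 1 else np.nan
        out["p"] = 1.0
    else:
        out["xpehh"] = (un - un.mean()) / sd
        out["p"] = np.clip(2.0 * norm.sf(np.abs(out["xpehh"])), 1e-300, 1.0)
    out["log10p"] = -np.log10(out["p"])
    return out


# ---------------------------------------------------------------------------
# Windowed outlier calling
# ---------------------------------------------------------------------------

def call_outlier_windows(
    scores: pd.DataFrame,
    windows: list[GenomicWindow],
    p_threshold: float,
    min_snps: int,
) -> pd.DataFrame:
    """Flag windows holding >= ``min_snps`` SNPs with p < ``p_threshold``.

    SNPs falling in several overlapping windows count in each; deduplication
    happens later when candidate windows are merged into regions.

    Columns: chrom, start, end, window_id, n_snps_total, n_snps_outlier,
    is_candidate.
    """
    pos = scores["position"].to_numpy() if len(scores) else np.empty(0, dtype=np.int64)
    pvals = scores["p"].to_numpy() if len(scores) else np.empty(0)
    records = []
    for w in windows:
        in_w = (pos >= w.start) & (pos <= w.end)
        n_out = int(((pvals < p_threshold) & in_w).sum())
        records.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "window_id": w.window_id,
                "n_snps_total": int(in_w.sum()),
                "n_snps_outlier": n_out,
                "is_candidate": n_out >= min_snps,
            }
        )
    return pd.DataFrame.from_records(records)
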