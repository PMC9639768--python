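"""Nucleotide diversity, the log2 diversity ratio, and Weir-Cockerham FST.

Windowed statistics follow the VCFtools conventions the field uses:

* per-window pi is the sum of per-site pi over variant sites divided by the
  full window span in bp (invariant bp contribute zero to the numerator);
* windowed FST is the ratio of sums of the Weir & Cockerham (1984) variance
  components, a / (a + b + c), not a mean of per-site ratios;
* missing genotypes are excluded pairwise per site.

The log2 ratio ``theta_pi_ratio = log2(pi_pop / pi_focal)`` is oriented so
that large positive values flag diversity loss in the focal population
relative to the comparison population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenomicWindow, GenotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def site_pi(genotype_column: np.ndarray) -> float:
    """Per-site nucleotide diversity among the non-missing alleles.

    pi = (# differing unordered allele pairs) / C(n, 2)
       = 2 j (n - j) / (n (n - 1))

    for j ALT copies among n non-missing alleles. Sites with fewer than two
    non-missing alleles are undefined and raise ValueError (callers skip and
    log them).
    """
    col = np.asarray(genotype_column)
    called = col[col != MISSING]
    n = called.size
    if n < 2:
        raise ValueError("site needs >= 2 non-missing alleles for pi")
    j = int(np.sum(called == 1))
    return 2.0 * j * (n - j) / (n * (n - 1))


def _sites_pi_vector(alleles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-site pi over all columns of a (rows x sites) matrix.

    Returns (pi, defined) where ``defined`` marks sites with >= 2 called
    alleles.
    """
    called = alleles != MISSING
    n = called.sum(axis=0).astype(np.float64)
    j = np.logical_and(called, alleles == 1).sum(axis=0).astype(np.float64)
    defined = n >= 2
    pi = np.zeros(alleles.shape[1], dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = 2.0 * j * (n - j) / (n * (n - 1.0))
    pi[defined] = vals[defined]
    return pi, defined


def window_pi(
    genotypes: GenotypeMatrix,
    population_map: PopulationMap,
    population: str,
    windows: list[GenomicWindow],
) -> pd.DataFrame:
    """Per-window per-bp nucleotide diversity for one population.

    Output columns: chrom, start, end, window_id, n_variants, pi.
    Monomorphic and unsampled bp contribute 0 to the numerator but the full
    window span to the denominator.
    """
    samples = population_map.samples_in(population)
    if not samples:
        raise ValueError(f"no samples for population {population!r}")
    rows = genotypes.sample_rows(samples)
    sub = genotypes.alleles[rows]
    pi, defined = _sites_pi_vector(sub)
    n_skipped = int((~defined).sum())
    if n_skipped:
        logger.info(
            "pi(%s): skipped %d sites with < 2 called alleles", population, n_skipped
        )
    pos = genotypes.positions
    records = []
    for w in windows:
        in_w = (pos >= w.start) & (pos <= w.end)
        use = in_w & defined
        records.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "window_id": w.window_id,
                "n_variants": int(use.sum()),
                "pi": float(pi[use].sum()) / w.span,
            }
        )
    return pd.DataFrame.from_records(records)


def theta_pi_ratio(pi_pop: float, pi_ref: float) -> float:
    """log2(pi_pop / pi_ref); the focal (reference) population is the
    denominator so sweeps in it push the ratio up.

    Edge cases: pi_ref = 0 with pi_pop > 0 -> +inf sentinel; pi_pop = 0 with
    pi_ref > 0 -> -inf sentinel; both zero -> NaN (undefined, excluded from
    tail selection).
    """
    if pi_pop < 0 or pi_ref < 0:
        raise ValueError("pi values must be >= 0")
    if pi_pop == 0.0 and pi_ref == 0.0:
        return float("nan")
    if pi_ref == 0.0:
        return float("inf")
    if pi_pop == 0.0:
        return float("-inf")
    return float(np.log2(pi_pop / pi_ref))


# ---------------------------------------------------------------------------
# Weir & Cockerham FST
# ---------------------------------------------------------------------------

@dataclass
class SiteComponents:
    """Per-site Weir-Cockerham variance components for r=2 populations."""

    a: np.ndarray  # among populations
    b: np.ndarray  # among individuals within populations
    c: np.ndarray  # within individuals
    defined: np.ndarray  # sites usable (>= 2 individuals per pop, polymorphic)


def _pop_site_summaries(alleles: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n_individuals, alt freq, observed het freq) for one
    population given its (2n x sites) allele rows; individuals with any
    missing allele at a site are excluded there."""
    a0 = alleles[0::2]
    a1 = alleles[1::2]
    called = (a0 != MISSING) & (a1 != MISSING)
    n = called.sum(axis=0).astype(np.float64)
    dose = np.where(called, (a0 == 1).astype(np.int32) + (a1 == 1).astype(np.int32), 0)
    het = np.where(called, (a0 != a1).astype(np.int32), 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dose.sum(axis=0) / (2.0 * n)
        h = het.sum(axis=0) / n
    return n, p, h


def wc_fst_site(
    alleles_pop1: np.ndarray, alleles_pop2: np.ndarray
) -> SiteComponents:
    """Weir & Cockerham (1984) variance components for two populations.

    Inputs are (2n x sites) allele matrices (two rows per diploid). Sites
    where either population has fewer than 2 genotyped individuals, or that
    are monomorphic across both populations, are flagged undefined with
    components (0, 0, 0).
    """
    n1, p1, h1 = _pop_site_summaries(np.atleast_2d(alleles_pop1))
    n2, p2, h2 = _pop_site_summaries(np.atleast_2d(alleles_pop2))
    r = 2.0
    defined = (n1 >= 2) & (n2 >= 2)

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0

    mono = (pbar == 0.0) | (pbar == 1.0)
    defined = defined & ~mono & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    zero = ~defined
    a = np.where(zero, 0.0, a)
    b = np.where(zero, 0.0, b)
    c = np.where(zero, 0.0, c)
    return SiteComponents(a=a, b=b, c=c, defined=defined)


def site_components(
    genotypes: GenotypeMatrix,
    population_map: PopulationMap,
    pop1: str,
    pop2: str,
) -> SiteComponents:
    """Convenience: per-site components for two labelled populations."""
    s1 = population_map.samples_in(pop1)
    s2 = population_map.samples_in(pop2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError(f"need >= 2 samples per population ({pop1}, {pop2})")
    return wc_fst_site(
        genotypes.alleles[genotypes.sample_rows(s1)],
        genotypes.alleles[genotypes.sample_rows(s2)],
    )


def ratio_of_sums_fst(components: SiteComponents, mask: np.ndarray | None = None) -> float:
    """Weighted FST = sum(a) / sum(a+b+c) over the (masked) usable sites.

    NaN when the denominator is zero (no usable variation).
    """
    use = components.defined if mask is None else (components.defined & mask)
    denom = float((components.a + components.b + components.c)[use].sum())
    if denom == 0.0:
        return float("nan")
    return float(components.a[use].sum()) / denom


def window_fst(
    components: SiteComponents,
    positions: np.ndarray,
    windows: list[GenomicWindow],
) -> pd.DataFrame:
    """Per-window ratio-of-sums FST.

    Output columns: chrom, start, end, window_id, n_variants, fst. Windows
    with zero denominator have fst = NaN (flagged undefined).
    """
    pos = np.asarray(positions)
    records = []
    for w in windows:
        in_w = (pos >= w.start) & (pos <= w.end)
        records.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "window_id": w.window_id,
                "n_variants": int((in_w & components.defined).sum()),
                "fst": ratio_of_sums_fst(components, mask=in_w),
            }
        )
    return pd.DataFrame.from_records(records)


def fst_pi_window_table(
    genotypes: GenotypeMatrix,
    population_map: PopulationMap,
    pop: str,
    focal: str,
    windows: list[GenomicWindow],
) -> pd.DataFrame:
    """Joint per-window table: FST, pi for both populations, and the log2
    diversity ratio (comparison over focal). Columns: chrom, start, end,
    window_id, n_variants, fst, pi_pop, pi_ref, theta_pi_ratio.
    """
    comp = site_components(genotypes, population_map, pop, focal)
    fst = window_fst(comp, genotypes.positions, windows)
    pi_pop = window_pi(genotypes, population_map, pop, windows)
    pi_ref = window_pi(genotypes, population_map, focal, windows)
    out = fst.copy()
    out["pi_pop"] = pi_pop["pi"].to_numpy()
    out["pi_ref"] = pi_ref["pi"].to_numpy()
    out["theta_pi_ratio"] = [
        theta_pi_ratio(p, q) for p, q in zip(out["pi_pop"], out["pi_ref"])
    ]
    return out


# ---------------------------------------------------------------------------
# Global pairwise FST and bootstrap
# ---------------------------------------------------------------------------

def global_pairwise_fst(
    genotypes: GenotypeMatrix,
    population_map: PopulationMap,
    snp_mask: np.ndarray | None = None,
    populations: list[str] | None = None,
) -> pd.DataFrame:
    """Ratio-of-sums FST for every population pair over the masked sites.

    ``snp_mask`` is any caller-provided boolean variant mask (e.g. a
    synonymous-site subset); None means all sites. Pairs where either
    population has < 2 samples, or with no usable sites, get NaN.
    Output columns: pop1, pop2, fst, n_sites.
    """
    pops = populations if populations is not None else population_map.populations
    records = []
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1 :]:
            try:
                comp = site_components(genotypes, population_map, p1, p2)
            except ValueError:
                records.append({"pop1": p1, "pop2": p2, "fst": float("nan"), "n_sites": 0})
                continue
            use = comp.defined if snp_mask is None else comp.defined & snp_mask
            records.append(
                {
                    "pop1": p1,
                    "pop2": p2,
                    "fst": ratio_of_sums_fst(comp, mask=snp_mask),
                    "n_sites": int(use.sum()),
                }
            )
    return pd.DataFrame.from_records(records)


def bootstrap_fst(
    genotypes: GenotypeMatrix,
    population_map: PopulationMap,
    pop1: str,
    pop2: str,
    n_boot: int = 100,
    seed: int | None = None,
    snp_mask: np.ndarray | None = None,
) -> dict:
    """Bootstrap over sites for one population pair.

    Sites are resampled with replacement ``n_boot`` times and the
    ratio-of-sums FST recomputed. The p-value tests FST > 0:
    p = (1 + #{replicates <= 0}) / (n_boot + 1), the standard small-B
    correction. A percentile 95% CI is reported alongside.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    comp = site_components(genotypes, population_map, pop1, pop2)
    use = comp.defined if snp_mask is None else comp.defined & np.asarray(snp_mask)
    idx = np.flatnonzero(use)
    if idx.size < 2:
        raise ValueError("need >= 2 usable sites for bootstrap")
    a = comp.a[idx]
    total = (comp.a + comp.b + comp.c)[idx]
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot, dtype=np.float64)
    for k in range(n_boot):
        take = rng.integers(0, idx.size, size=idx.size)
        denom = total[take].sum()
        reps[k] = a[take].sum() / denom if denom != 0.0 else np.nan
    finite = reps[np.isfinite(reps)]
    n_le0 = int((finite <= 0.0).sum())
    return {
        "fst": ratio_of_sums_fst(comp, mask=snp_mask),
        "p": (1.0 + n_le0) / (n_boot + 1.0),
        "ci_low": float(np.percentile(finite, 2.5)),
        "ci_high": float(np.percentile(finite, 97.5)),
        "n_boot": n_boot,
        "n_sites": int(idx.size),
    }
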