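"""Linkage disequilibrium: haplotype r-squared, LD-decay profiles and
greedy LD pruning.

r-squared is computed from phased haplotype frequencies,
``r2 = D^2 / (p_i (1 - p_i) p_j (1 - p_j))`` with ``D = p_ij - p_i p_j``,
over haplotypes called at both sites (pairwise-complete).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MISSING, HaplotypeMatrix, PopulationMap


def haplotype_r2(matrix: HaplotypeMatrix, i: int, j: int) -> float:
    """Pairwise r^2 between variants ``i`` and ``j``.

    NaN if either variant is monomorphic after missing-data exclusion.
    """
    a = matrix.alleles[:, i]
    b = matrix.alleles[:, j]
    ok = (a != MISSING) & (b != MISSING)
    n = int(ok.sum())
    if n < 2:
        return float("nan")
    x = a[ok].astype(np.float64)
    y = b[ok].astype(np.float64)
    pi = x.mean()
    pj = y.mean()
    if pi in (0.0, 1.0) or pj in (0.0, 1.0):
        return float("nan")
    d = (x * y).mean() - pi * pj
    return float(d * d / (pi * (1 - pi) * pj * (1 - pj)))


def _pair_r2_vector(
    alleles: np.ndarray, ii: np.ndarray, jj: np.ndarray, chunk: int = 100_000
) -> np.ndarray:
    """Vectorized r^2 for the listed variant-index pairs (NaN where
    monomorphic after pairwise deletion). Evaluated in chunks to bound the
    (n_haplotypes x n_pairs) intermediates."""
    out = np.full(ii.size, np.nan)
    for lo in range(0, ii.size, chunk):
        hi = min(lo + chunk, ii.size)
        a = alleles[:, ii[lo:hi]]
        b = alleles[:, jj[lo:hi]]
        ok = (a != MISSING) & (b != MISSING)
        n = ok.sum(axis=0).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            ax = np.where(ok, a, 0).astype(np.float64)
            bx = np.where(ok, b, 0).astype(np.float64)
            pi = ax.sum(axis=0) / n
            pj = bx.sum(axis=0) / n
            pij = (ax * bx).sum(axis=0) / n
            d = pij - pi * pj
            denom = pi * (1 - pi) * pj * (1 - pj)
            vals = d * d / denom
        good = (n >= 2) & (denom > 0)
        sub = out[lo:hi]
        sub[good] = vals[good]
    return out


def ld_decay_profile(
    matrix: HaplotypeMatrix,
    population_map: PopulationMap | None = None,
    population: str | None = None,
    bin_size: int = 10_000,
    max_distance: int = 250_000,
    pair_budget: int = 500_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean r^2 binned by physical distance, out to ``max_distance``.

    All intra-chromosomal variant pairs closer than ``max_distance`` are
    binned by |pos_i - pos_j|; when the pair count exceeds ``pair_budget``
    a seeded uniform subsample is used. Bins with no pairs are flagged
    empty (mean NaN), not zero.

    Columns: bin_start, bin_end, mean_r2, n_pairs.
    """
    if population is not None:
        if population_map is None:
            raise ValueError("population given without a population map")
        matrix = matrix.subset_samples(population_map.samples_in(population))
    if matrix.n_haplotypes < 4:
        raise ValueError("LD decay needs >= 4 haplotypes")
    pos = matrix.positions
    m = pos.size
    pairs_i: list[np.ndarray] = []
    pairs_j: list[np.ndarray] = []
    hi = np.searchsorted(pos, pos + max_distance, side="right")
    for i in range(m):
        if hi[i] > i + 1:
            pairs_j.append(np.arange(i + 1, hi[i]))
            pairs_i.append(np.full(hi[i] - i - 1, i))
    if pairs_i:
        ii = np.concatenate(pairs_i)
        jj = np.concatenate(pairs_j)
    else:
        ii = jj = np.empty(0, dtype=np.int64)
    if ii.size > pair_budget:
        rng = np.random.default_rng(seed)
        take = rng.choice(ii.size, size=pair_budget, replace=False)
        ii, jj = ii[take], jj[take]
    r2 = _pair_r2_vector(matrix.alleles, ii, jj)
    dist = np.abs(pos[jj] - pos[ii])
    good = np.isfinite(r2)
    r2, dist = r2[good], dist[good]
    n_bins = int(np.ceil(max_distance / bin_size))
    bin_idx = np.minimum(dist // bin_size, n_bins - 1)
    records = []
    for b in range(n_bins):
        sel = bin_idx == b
        n_pairs = int(sel.sum())
        records.append(
            {
                "bin_start": b * bin_size,
                "bin_end": min((b + 1) * bin_size, max_distance),
                "mean_r2": float(r2[sel].mean()) if n_pairs else float("nan"),
                "n_pairs": n_pairs,
            }
        )
    return pd.DataFrame.from_records(records)


def ld_prune(
    matrix: HaplotypeMatrix,
    window: int = 50_000,
    step: int = 5,
    r2_max: float = 0.5,
) -> np.ndarray:
    """Greedy left-to-right LD pruning; returns the kept variant indices.

    Within each window (``window`` bp wide, advancing by ``step`` variants),
    every pair of kept variants with r^2 > ``r2_max`` loses the member with
    the lower minor allele frequency (tie: the later position). The result
    is deterministic and contains no within-window pair above the threshold.
    """
    pos = matrix.positions
    m = pos.size
    keep = np.ones(m, dtype=bool)
    called = matrix.alleles != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called, matrix.alleles, 0).sum(axis=0) / called.sum(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    start = 0
    while start < m:
        end = int(np.searchsorted(pos, pos[start] + window, side="right"))
        idx = [k for k in range(start, end) if keep[k]]
        changed = True
        while changed:
            changed = False
            for x in range(len(idx)):
                if not keep[idx[x]]:
                    continue
                for y in range(x + 1, len(idx)):
                    if not keep[idx[y]]:
                        continue
                    r2 = haplotype_r2(matrix, idx[x], idx[y])
                    if np.isfinite(r2) and r2 > r2_max:
                        a, b = idx[x], idx[y]
                        # drop the lower-MAF member; tie -> later position
                        drop = b if (maf[b] < maf[a] or maf[a] == maf[b]) else a
                        keep[drop] = False
                        changed = True
        start += step
    return np.flatnonzero(keep)
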