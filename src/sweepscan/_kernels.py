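"""Numba kernels for the inner loops: the EHH partition-refinement walk and
the per-gamete crossover application in the simulator.

Pure implementation details; the public semantics live in
:mod:`sweepscan.haplotype` and :mod:`sweepscan.simulate`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def ehh_walk(
    alleles: np.ndarray,  # (n_hap, M) int8, -1 = missing
    positions: np.ndarray,  # (M,) int64
    core: int,
    carriers: np.ndarray,  # (n_carriers,) int64
    step: int,
    stop_below: float,  # walk stops once EHH < this (-1.0 disables)
    stop_beyond: float,  # ... or once |pos - core| >= this (-1.0 disables)
    out_pos: np.ndarray,  # (M+1,) int64 scratch
    out_ehh: np.ndarray,  # (M+1,) float64 scratch
):
    """Refine the carrier haplotype partition marker by marker outward.

    Returns (k, reached_end): k entries were written to the scratch arrays
    (entry 0 is the core with EHH = 1) and reached_end is True when the walk
    consumed the chromosome end on this side.
    """
    n = carriers.size
    m = alleles.shape[1]
    npairs = n * (n - 1)
    codes = np.zeros(n, dtype=np.int64)
    counts = np.zeros(3 * n + 3, dtype=np.int64)
    relabel = np.empty(3 * n + 3, dtype=np.int64)
    out_pos[0] = positions[core]
    out_ehh[0] = 1.0
    k = 1
    j = core
    while True:
        j += step
        if j < 0 or j >= m:
            return k, True
        # refine: key = old_code * 3 + allele state in {0,1,2}
        max_key = 0
        for t in range(n):
            key = codes[t] * 3 + alleles[carriers[t], j] + 1
            codes[t] = key
            if key > max_key:
                max_key = key
        for key in range(max_key + 1):
            counts[key] = 0
        for t in range(n):
            counts[codes[t]] += 1
        pairs = 0
        next_id = 0
        for key in range(max_key + 1):
            c = counts[key]
            if c > 0:
                pairs += c * (c - 1)
                relabel[key] = next_id
                next_id += 1
        for t in range(n):
            codes[t] = relabel[codes[t]]
        ehh = pairs / npairs
        out_pos[k] = positions[j]
        out_ehh[k] = ehh
        k += 1
        if stop_below >= 0.0 and ehh < stop_below:
            return k, False
        if ehh == 0.0:
            return k, False
        if stop_beyond >= 0.0:
            d = out_pos[k - 1] - out_pos[0]
            if d < 0:
                d = -d
            if d >= stop_beyond:
                return k, False


@njit(cache=True)
def apply_crossovers(
    mat: np.ndarray,  # parent haplotypes (2N, S) uint8
    children: np.ndarray,  # (n_gam, S) uint8, pre-filled with the start hap
    positions: np.ndarray,  # (S,) int64, any order
    other_hap: np.ndarray,  # (k,) parent row holding the other haplotype
    gamete_idx: np.ndarray,  # (k,) rows of `children` to recombine
    bp_flat: np.ndarray,  # sorted breakpoints, concatenated per gamete
    bp_off: np.ndarray,  # (k+1,) offsets into bp_flat
):
    """Switch each recombining gamete to the other parental haplotype at
    sites lying an odd number of breakpoints from the left end."""
    s = positions.size
    for t in range(gamete_idx.size):
        g = gamete_idx[t]
        oh = other_hap[t]
        b0, b1 = bp_off[t], bp_off[t + 1]
        nb = b1 - b0
        for c in range(s):
            v = positions[c]
            lo, hi = 0, nb
            while lo < hi:
                mid = (lo + hi) >> 1
                if bp_flat[b0 + mid] <= v:
                    lo = mid + 1
                else:
                    hi = mid
            if lo & 1:
                children[g, c] = mat[oh, c]
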