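"""Replicated validation studies: drift calibration, sweep recovery,
neutral-tail calibration and the bottleneck LD contrast.

These compose the library's public operations into the standard experiments
used to validate the pipeline on simulated data with known truth. Study
conditions (population sizes, divergence times, rates, selection parameters)
are fixed here as the package's reference validation settings; see
docs/methods.md for the reasoning behind each value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import diversity, haplotype, outliers
from .core import PopulationMap
from .io import make_windows
from .simulate import BottleneckConfig, SimConfig, SweepConfig, merge_populations, simulate

# Reference sweep-study conditions: two populations of N=300 diploids split
# 150 generations before sampling (background FST ~ 1 - exp(-t/2N) ~ 0.22),
# scaled rates keeping 4N*mu = 1e-3 and 4N*rec = 3.6e-4 per bp, and one hard
# sweep (s=0.1, h=0.7) arising in the focal population at the split,
# conditioned to reach frequency >= 0.9 by sampling (a sweep near fixation).
SWEEP_STUDY = dict(
    chrom_length=800_000,
    n_pops=2,
    pop_size=300,
    split_time=150,
    mu=8.33e-7,
    rec=3e-7,
    sample_sizes=(50, 50),
)
SWEEP_PARAMS = dict(s=0.1, h=0.7, introduction_time=150, min_final_freq=0.9)

# Drift calibration: N=100 per population, split 40 generations before
# sampling, neutral; expected genome FST is 1 - exp(-t/2N) and expected
# per-bp diversity is 4N*mu.
DRIFT_STUDY = dict(
    chrom_length=500_000,
    n_pops=2,
    pop_size=100,
    split_time=40,
    mu=2.5e-6,
    rec=1.0e-6,
    sample_sizes=(20, 20),
)

# Bottleneck LD contrast: a moderate bottleneck (40 -> 10 diploids for 10
# generations) ending just before sampling elevates LD at all distances.
BOTTLENECK_STUDY = dict(
    chrom_length=150_000,
    n_pops=2,
    pop_size=40,
    split_time=60,
    mu=6.25e-6,
    rec=2.5e-6,
    sample_sizes=(12, 12),
)
BOTTLENECK_PARAMS = dict(start=12, duration=10, reduced_n=10)


def _child_seed(seed: int, *path: int) -> int:
    """Deterministic sub-seed below 2**31."""
    return int(np.random.SeedSequence([seed, *path]).generate_state(1)[0] % 2**31)


def _popmap(matrices) -> PopulationMap:
    return PopulationMap({s: p for p, m in matrices.items() for s in m.sample_ids})


@dataclass
class SweepRecoveryResult:
    n_replicates: int
    hits_fstpi: int = 0
    hits_ihs: int = 0
    hits_xpehh: int = 0
    fp_fraction_max: float = 0.0
    final_freqs: list = field(default_factory=list)
    details: list = field(default_factory=list)


def sweep_recovery_study(
    seed: int,
    n_replicates: int = 10,
    fp_margin: int = 50_000,
) -> SweepRecoveryResult:
    """Run replicated two-population sweep simulations and score recovery by
    the three detection routes at the study thresholds:

    * joint 5%-right-tail of windowed FST and the log2 diversity ratio
      containing a window that overlaps the sweep position;
    * iHS candidate regions (p < 1e-6, >= 2 SNPs per 10 kb window,
      windows overlapping by 1 kb) overlapping the sweep position;
    * xpEHH candidate regions (p < 1e-4, >= 5 SNPs) likewise.

    False-positive span per replicate = total extent of haplotype-scan
    candidate regions farther than ``fp_margin`` from the sweep, as a
    fraction of the chromosome.
    """
    L = SWEEP_STUDY["chrom_length"]
    pos = L // 2
    res = SweepRecoveryResult(n_replicates=n_replicates)
    for r in range(n_replicates):
        cfg = SimConfig(
            seed=_child_seed(seed, 4, r),
            sweep=SweepConfig(pop=0, position=pos, **SWEEP_PARAMS),
            **SWEEP_STUDY,
        )
        matrices, truth = simulate(cfg)
        m1, m2 = matrices["pop1"], matrices["pop2"]
        pm = _popmap(matrices)
        geno = merge_populations(matrices).to_genotypes()

        wtab = diversity.fst_pi_window_table(
            geno, pm, "pop2", "pop1", make_windows(L, 10_000, 10_000)
        )
        _, _, joint = outliers.joint_tail_outliers(wtab, quantile=0.95)
        jw = wtab[wtab.window_id.isin(joint)]
        hit_a = bool(any(w.start <= pos <= w.end for w in jw.itertuples()))

        hap_windows = make_windows(L, 10_000, 9_000)
        ihs = haplotype.standardize_ihs(haplotype.ihs_scan(m1))
        calls = haplotype.call_outlier_windows(ihs, hap_windows, 1e-6, 2)
        regs_b = outliers.merge_windows_to_regions(calls[calls.is_candidate], "iHS")
        hit_b = any(reg.start <= pos <= reg.end for reg in regs_b)

        xp = haplotype.xpehh_scan(m1, m2)
        xcalls = haplotype.call_outlier_windows(xp, hap_windows, 1e-4, 5)
        regs_c = outliers.merge_windows_to_regions(xcalls[xcalls.is_candidate], "xpEHH")
        hit_c = any(reg.start <= pos <= reg.end for reg in regs_c)

        fp = sum(
            reg.span
            for reg in regs_b + regs_c
            if not (reg.start <= pos + fp_margin and reg.end >= pos - fp_margin)
        )
        res.hits_fstpi += hit_a
        res.hits_ihs += hit_b
        res.hits_xpehh += hit_c
        res.fp_fraction_max = max(res.fp_fraction_max, fp / L)
        res.final_freqs.append(truth.final_freq["pop1"])
        res.details.append(
            dict(seed=cfg.seed, hit_fstpi=hit_a, hit_ihs=hit_b, hit_xpehh=hit_c,
                 fp_fraction=fp / L, restarts=truth.restarts,
                 final_freq=truth.final_freq["pop1"])
        )
    return res


@dataclass
class DriftCalibrationResult:
    n_replicates: int
    fst_mean: float
    fst_se: float
    fst_expected: float
    pi_mean: float
    pi_expected: float
    per_rep_fst: list
    per_rep_pi: list


def drift_calibration_study(seed: int, n_replicates: int = 10) -> DriftCalibrationResult:
    """Neutral two-population divergence: genome ratio-of-sums FST against
    the pure-drift expectation 1 - exp(-t/2N), and per-bp diversity against
    4N*mu."""
    cfgs = [
        SimConfig(seed=_child_seed(seed, 3, r), **DRIFT_STUDY)
        for r in range(n_replicates)
    ]
    fsts, pis = [], []
    L = DRIFT_STUDY["chrom_length"]
    for cfg in cfgs:
        matrices, _ = simulate(cfg)
        pm = _popmap(matrices)
        geno = merge_populations(matrices).to_genotypes()
        comp = diversity.site_components(geno, pm, "pop1", "pop2")
        fsts.append(diversity.ratio_of_sums_fst(comp))
        pi = diversity.window_pi(geno, pm, "pop1", make_windows(L, L))
        pis.append(float(pi["pi"].iloc[0]))
    fsts = np.asarray(fsts)
    return DriftCalibrationResult(
        n_replicates=n_replicates,
        fst_mean=float(fsts.mean()),
        fst_se=float(fsts.std(ddof=1) / np.sqrt(n_replicates)),
        fst_expected=float(
            1.0 - np.exp(-DRIFT_STUDY["split_time"] / (2 * DRIFT_STUDY["pop_size"]))
        ),
        pi_mean=float(np.mean(pis)),
        pi_expected=4 * DRIFT_STUDY["pop_size"] * DRIFT_STUDY["mu"],
        per_rep_fst=[float(x) for x in fsts],
        per_rep_pi=pis,
    )


@dataclass
class NeutralTailResult:
    n_snps: int
    fractions: dict  # alpha -> observed fraction of p < alpha
    bin_mean_max: float  # max |mean| of standardized iHS over merged bins
    bin_sd_err_max: float  # max |sd - 1| over merged bins
    xpehh_mean: float
    xpehh_sd: float


def neutral_tail_study(
    seed: int, n_replicates: int = 3, alphas=(1e-2, 1e-3)
) -> NeutralTailResult:
    """Standardization sanity on neutral simulations: per-bin mean/sd of
    standardized iHS, genome mean/sd of xpEHH, and the fraction of SNPs
    reaching p < alpha (should not exceed 2*alpha under neutrality)."""
    from .haplotype import _merge_sparse_bins

    all_scores = []
    bin_mean_max = bin_sd_err_max = 0.0
    xp_mean = xp_sd = np.nan
    for r in range(n_replicates):
        cfg = SimConfig(seed=_child_seed(seed, 5, r), **DRIFT_STUDY)
        matrices, _ = simulate(cfg)
        scores = haplotype.standardize_ihs(haplotype.ihs_scan(matrices["pop1"]))
        scored = scores.dropna(subset=["ihs"])
        all_scores.append(scored)
        freq = scored["derived_freq"].to_numpy()
        bins = np.minimum((freq / 0.025).astype(np.int64), 39)
        groups = _merge_sparse_bins(bins, 40, 10)
        for g in np.unique(groups):
            z = scored["ihs"].to_numpy()[groups == g]
            bin_mean_max = max(bin_mean_max, abs(float(z.mean())))
            bin_sd_err_max = max(bin_sd_err_max, abs(float(z.std(ddof=0)) - 1.0))
        if r == 0:
            xp = haplotype.xpehh_scan(matrices["pop1"], matrices["pop2"])
            xp_mean = float(xp["xpehh"].mean())
            xp_sd = float(xp["xpehh"].std(ddof=0))
    import pandas as pd

    pooled = pd.concat(all_scores, ignore_index=True)
    fractions = {
        alpha: float((pooled["p"] < alpha).mean()) for alpha in alphas
    }
    return NeutralTailResult(
        n_snps=len(pooled),
        fractions=fractions,
        bin_mean_max=bin_mean_max,
        bin_sd_err_max=bin_sd_err_max,
        xpehh_mean=xp_mean,
        xpehh_sd=xp_sd,
    )


def bottleneck_ld_study(seed: int, bin_size: int = 15_000, max_distance: int = 60_000):
    """One bottlenecked vs one constant-size population: per-bin mean r^2 for
    each and the bottleneck/constant uplift ratio."""
    from .ld import ld_decay_profile

    cfg = SimConfig(
        seed=_child_seed(seed, 8, 0),
        bottleneck=BottleneckConfig(pop=0, **BOTTLENECK_PARAMS),
        **BOTTLENECK_STUDY,
    )
    matrices, _ = simulate(cfg)
    prof_b = ld_decay_profile(matrices["pop1"], bin_size=bin_size, max_distance=max_distance)
    prof_n = ld_decay_profile(matrices["pop2"], bin_size=bin_size, max_distance=max_distance)
    ratio = (prof_b["mean_r2"] / prof_n["mean_r2"]).to_numpy()
    return prof_b, prof_n, ratio
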