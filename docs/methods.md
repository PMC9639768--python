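# Methods

`sweepscan` detects signatures of recent positive selection in phased
diploid population data by three complementary routes, and validates all of
them end-to-end against a bundled forward-time Wright–Fisher simulator with
known ground truth. This note documents the statistical models, the default
parameters and why they hold their values, what the simulator does and does
not emulate, and the numerical conventions.

## Statistics

### Windowed nucleotide diversity (π)

Per-site diversity among the `n` non-missing alleles with `j` ALT copies is
the average pairwise difference `π = 2j(n−j)/(n(n−1))`. Window diversity is
the sum of per-site π over variant sites divided by the *full window span in
bp* — invariant positions contribute zero to the numerator and their length
to the denominator, the convention used by VCFtools, so values are per-bp
and comparable across window sizes. Sites with fewer than two called alleles
are skipped and logged. Missing genotypes are excluded pairwise per site
throughout.

### The diversity log-ratio

For a focal population (the one screened for selection) and a comparison
population,

    θπ_ratio = log2(π_comparison / π_focal)

per window. Large positive values flag diversity loss in the focal
population. Windows where the focal π is exactly 0 give an infinite
sentinel and windows with both π = 0 are undefined; both are *excluded from
tail selection rather than imputed*, since a quantile over a mixture of
finite values and sentinels is not meaningful.

### Weir–Cockerham FST

Per site we compute the Weir & Cockerham (1984) variance components for
r = 2 populations from diploid genotypes — among populations (a), among
individuals within populations (b), within individuals (c) — including the
observed-heterozygosity term, matching the VCFtools estimator. Windowed and
global FST are the *ratio of sums* `Σa / Σ(a+b+c)`, not a mean of per-site
ratios; sites monomorphic across both populations or with fewer than two
genotyped individuals in either population are excluded. Negative windowed
values are retained unclamped: clamping would bias the genome-wide
Mann-Whitney background, and the right-tail selection ignores them anyway.

Global pairwise FST accepts an arbitrary caller-provided variant mask (the
analysis this reproduces used a synonymous-SNP subset; effect classification
is out of scope, so the mask is an input). Bootstrap p-values resample sites
with replacement (default B = 100) and test FST > 0 with the small-B
correction `p = (1 + #{replicates ≤ 0})/(B + 1)`, avoiding p = 0 at small B;
a percentile 95% CI is reported alongside.

### The joint tail cross analysis

Windows simultaneously in the right 5% tails of windowed FST *and* of the
diversity log-ratio are the between-population candidates. Thresholds are
empirical linear-interpolation quantiles over all defined windows pooled
across chromosomes (one genome-wide threshold per population pair, which is
how the realized thresholds are reported per comparison). A Mann-Whitney U
test (R `wilcox.test` convention, `W = #{x>y} + ½·ties`) compares the
selected windows against the genomic background — by default including the
outliers in the background, with a flag to exclude them. The exact null
distribution is used when `n_x·n_y ≤ 10,000` with no ties, otherwise the
normal approximation with tie and continuity corrections. p-values below
2.2e-16 are reported as "< 2.2e-16" in the summary tables.

### EHH, iHH, iHS

EHH at marker x for a carrier set of size n is the probability that two
random carriers are identical at all markers strictly between the core and
x, inclusive of x: `EHH(x) = Σ_h C(n_h,2)/C(n,2)` over the distinct extended
haplotypes. EHH(core) = 1 and the profile is monotone non-increasing
(partitions are nested). Missing alleles are treated as a private state:
they break homozygosity, which is conservative.

iHH integrates EHH over physical distance with trapezoids on both sides of
the core, truncating by linear interpolation at the point where EHH first
crosses the cutoff (default 0.05). If a chromosome end is reached with EHH
still at or above the cutoff the SNP is border-flagged and discarded by
default (a flag keeps truncated scores); inter-marker gaps above `maxgap`
(default 200 kb) truncate the integral without the border flag. Physical
distance is used because no genetic map is assumed; cutoff, gap and border
handling follow the defaults of the standard R implementation of these
scans.

iHS is `ln(iHH_ancestral / iHH_derived)`, standardized to mean 0 / sd 1
within derived-allele-frequency bins of width 0.025; sparse bins (< 10
SNPs) are merged left-to-right with a sparse tail folded into its
predecessor, deterministically. SNPs need minor allele frequency ≥ 0.05 and
at least two carriers of each allele. Ancestral state comes from the `AA`
INFO field when present, otherwise REF is assumed ancestral — exact for
simulator output, configurable for real data. The two-sided p-value is
`2(1 − Φ(|z|))`; the raw log-ratio is *not* centered at zero under
neutrality (young, low-frequency derived alleles carry longer haplotypes),
which is exactly what the frequency-bin standardization removes.

### xpEHH

Per SNP, EHH is computed allele-agnostically over all haplotypes of each
population on the same variant grid. Both populations integrate to a shared
stopping extent per side — the farther of the two interpolated cutoff
crossings, each integral evaluated on its own profile out to that extent —
so the two iHH values cover the same physical span and their ratio is
comparable. `ln(iHH_pop1/iHH_pop2)` is standardized genome-wide (single
mean/sd); positive scores mean longer haplotypes, hence selection, in the
first (focal) population.

### Outlier windows and candidate regions

Haplotype-scan scores are assessed in 10 kb windows overlapping by 1 kb
(step 9 kb; the step is configurable because the overlap phrasing admits a
1 kb-step reading). A window is a candidate when it holds at least
`min_snps` SNPs with p below the threshold — defaults p < 1e-6 with ≥ 2
SNPs for iHS and p < 1e-4 with ≥ 5 SNPs for xpEHH. Candidate windows from
one source are merged into regions when overlapping or bookended
(`max_gap = 0` by default, configurable since no merge rule is mandated);
merging is idempotent and SNPs are counted once per region. Regions are
annotated with any gene/QTL interval sharing ≥ 1 bp (BED input is converted
from 0-based half-open to the internal 1-based inclusive convention), and
per-source gene universes feed the Venn-style intersection table across
comparisons (all 2ⁿ−1 exclusive classes for up to five sets, pairwise plus
full intersection beyond that).

### LD tools

r² comes from phased haplotype frequencies, `r² = D²/(p_i q_i p_j q_j)`
with pairwise-complete haplotypes; a genotype-based composite estimator is
out of scope since inputs are phased. The decay profile bins all
intra-chromosomal pairs within 250 kb into 10 kb distance bins (a single
uniform bin size; the dual-resolution binning of PopLDdecay is simplified
because the profile is used for qualitative comparison), with seeded
subsampling above a pair budget. Greedy pruning slides a 50 kb window in
5-variant steps; within a window, each pair with r² > 0.5 loses the
lower-MAF member (tie: later position). The rule is declared, deterministic
and leaves no surviving within-window pair above the threshold; it is not
claimed to replicate PLINK's implementation-defined removal choice
bit-for-bit.

## The simulator

Forward-time Wright–Fisher with discrete non-overlapping generations of N
diploids per population: fitness-weighted parent sampling, one recombined
gamete per offspring (Poisson crossovers, uniform breakpoints), Poisson
infinite-sites mutation on integer bp with collision re-draw (guaranteeing
biallelic sites). A single ancestral population burns in for 8N generations
from a monomorphic start (pairwise coalescent equilibration to within
e⁻⁴ ≈ 2% of 4Nμ), then splits into daughter populations of size N that
drift independently for `split_time` generations. Options: a bottleneck
(one population at reduced size for a span of generations), a stepwise
ancestral expansion (`ancient_n` until `expansion_time` generations before
sampling), and a hard sweep — a new mutation with fitness 1, 1+hs, 1+s
injected on one random haplotype at its introduction time. If the allele is
lost, or (with `min_final_freq` set) falls short of that frequency at
sampling, the sweep phase restarts from the saved pre-introduction state on
a fresh child seed stream, and restarts are counted in the ground truth.
Everything is reproducible from the config seed, including restarts.

Populations are desk-scaled: N of order 100 with μ and r scaled up so
4Nμ = 1e-3/bp and 4Nr of a few 1e-4/bp remain realistic for livestock
genomes. Emitted VCFs use REF = true ancestral allele, so downstream
polarization is exact. The simulator does **not** emulate migration or
admixture, recombination maps, selection on standing variation, gene
conversion, or realistic chromosome counts — so passing tests demonstrate
the *statistical machinery* is correct and calibrated, not that power on
real livestock data matches these numbers.

### Reference validation studies (`sweepscan.studies`)

* **Drift calibration** — two populations, N = 100, split 40 generations,
  500 kb, neutral, 10 replicates: genome ratio-of-sums FST is compared with
  drift expectations, and per-bp π with 4Nμ within 25%. Two FST
  expectations exist and differ measurably here: the moment formula
  1 − exp(−t/2N) ≈ 0.181 describes allele-frequency variance of *standing*
  variation, while for the full set of segregating sites (which includes
  post-split mutations, and is what the pipeline — like VCFtools — actually
  measures) the coalescent expectation is
  FST = 1 − T_W/T_B = t/(t + 2N) ≈ 0.167,
  with T_W = 2N the within-population and T_B = t + 2N the
  between-population pairwise coalescent times. The measured means land on
  the latter (≈ 0.16, within its Monte-Carlo error) and consistently below
  the former, so the suite asserts both: the coalescent expectation as the
  correctness check, and the moment formula as the looser historical
  benchmark, which can sit ~2–4 Monte-Carlo SE away at this replicate
  precision.
* **Sweep recovery** — two populations of N = 300, split 150 generations
  (background FST ≈ 0.22, inside the 0.14–0.26 range typical of diverged
  pig breeds), 800 kb, 4Nμ = 1e-3, 4Nr = 3.6e-4, 50 diploids sampled per
  population; one hard sweep (s = 0.1, h = 0.7) arising in the focal
  population at the split, conditioned to reach frequency ≥ 0.9 by
  sampling. Ten replicates score whether each detection route recovers the
  sweep position and how much candidate span lands away from it.
* **Neutral tails** — three neutral replicates: per-bin standardized iHS
  and genome-wide xpEHH must have mean 0 / sd 1 to 1e-6 by construction,
  and the fraction of SNPs reaching p < α must stay ≤ 2α.
* **Bottleneck LD** — N 40 → 10 for 10 generations ending just before
  sampling versus a constant-size population: the bottlenecked profile sits
  uniformly above the constant one. (A *long, extreme* scaled bottleneck
  does the opposite: it resets variation and the surviving polymorphism is
  young, rare and unlinked — worth knowing when designing such tests.)

### Known power ceiling at desk scale

The standardized contrast a sweep can achieve over the neutral background —
for iHS, xpEHH, *and* the diversity ratio — is bounded by roughly
`ln(T_bg / T_sweep)`, where T_bg ≈ 2N generations is the background
pairwise coalescent time and T_sweep the sweep age. With s ≤ 0.1 the
heterozygote growth rate caps T_sweep at ≥ ~100 generations, and the 8N
burn-in makes N ≫ 400 impractically slow, so the contrast tops out near 2
(in ln units) ≈ z of 3–4 against the measured score dispersions. The
joint-tail route uses *relative* (quantile) thresholds and recovers the
sweep in most replicates; the absolute haplotype-scan thresholds
(p < 1e-6 for iHS, i.e. |z| > 4.89) are calibrated for million-SNP,
N_e ≈ 10⁴ datasets, where ln(T_bg/T_sweep) reaches 4–6, and are generally
out of reach at this scale. The thresholds are kept at their published
values rather than rescaled: the validation suite reports recovery rates
honestly instead of moving the bar.

## Numerical conventions and edge cases

* Coordinates are 1-based inclusive internally (VCF convention); BED
  converts at the boundary, and window tiling starts at position 1
  (window/variant alignment is configurable in principle via the window
  list, which is an explicit argument everywhere).
* Quantiles: NumPy's default linear interpolation.
* Windows with an empty FST denominator or zero covered bp are NaN-flagged,
  never zero-filled.
* Bootstrap and pair-subsampling RNGs are seeded explicitly; the pipeline
  derives all of them from the single run seed.
* `--threads` is accepted for interface parity and ignored: all computation
  is single-threaded, so thread count trivially cannot change results.
* Two numba kernels (the EHH partition walk and per-gamete crossover
  application) carry the inner loops; they are exact reimplementations of
  the straightforward NumPy versions they replaced and are covered by the
  same brute-force oracles.
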