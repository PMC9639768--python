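"""Forward-time Wright-Fisher simulator with divergence, bottlenecks and
hard sweeps, emitting phased haplotypes with known ground truth.

Model
-----
Discrete non-overlapping generations of N diploids per population. Each
offspring draws a parent (fitness-weighted under selection), receives one
recombined gamete (Poisson number of crossovers, uniform breakpoints) and
Poisson new mutations under infinite sites on integer bp (collisions
re-drawn). A single ancestral population is burned in for >= 8N generations
from a monomorphic start, then split into ``n_pops`` daughter populations of
size N that drift independently for ``split_time`` generations before
sampling. An optional bottleneck reduces one population's size for a span of
generations; an optional hard sweep injects a beneficial allele (fitness
1, 1+hs, 1+s) on one haplotype at its introduction time and restarts the
sweep phase from the pre-introduction state (fresh seed stream, counted)
whenever the allele is lost - or, when ``min_final_freq`` is set, whenever
it falls short of that frequency at sampling.

Population sizes are desk-scaled (N of order 100) with mutation and
recombination rates scaled up so that 4*N*mu and 4*N*r per bp stay realistic.
The emitted VCF uses REF = true ancestral allele, so ancestral polarization
downstream is exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels
from .core import HaplotypeMatrix
from .io import write_vcf

_HARMONIC_CACHE: dict[int, float] = {}


def _harmonic(n: int) -> float:
    if n not in _HARMONIC_CACHE:
        _HARMONIC_CACHE[n] = float(np.sum(1.0 / np.arange(1, n + 1)))
    return _HARMONIC_CACHE[n]


@dataclass
class BottleneckConfig:
    """Temporary size reduction of one population.

    ``start`` is in generations before sampling; the population runs at
    ``reduced_n`` diploids for ``duration`` generations from that point.
    """

    pop: int
    start: int
    duration: int
    reduced_n: int


@dataclass
class SweepConfig:
    """A hard sweep from a new mutation.

    ``introduction_time`` is in generations before sampling and must not
    precede the population split. ``min_final_freq``, when set, makes the
    simulator condition on the beneficial allele reaching at least that
    frequency at sampling (restarting the sweep phase otherwise), i.e. a
    sweep sampled near fixation.
    """

    pop: int
    position: int
    s: float
    h: float = 0.5
    introduction_time: int = 0
    min_final_freq: float | None = None


@dataclass
class SimConfig:
    seed: int
    chrom_length: int = 1_000_000
    n_pops: int = 2
    pop_size: int = 100
    split_time: int = 60
    mu: float = 2.5e-6
    rec: float = 1.0e-6
    sample_sizes: tuple[int, ...] | list[int] = (20, 20)
    bottleneck: BottleneckConfig | None = None
    sweep: SweepConfig | None = None
    # optional stepwise expansion: the ancestral population runs at
    # ``ancient_n`` diploids until ``expansion_time`` generations before
    # sampling, then grows instantaneously to ``pop_size``
    ancient_n: int | None = None
    expansion_time: int = 0
    burn_in: int | None = None  # default 8 * pop_size
    chrom: str = "1"
    max_restarts: int = 2000
    max_expected_sites: int = 100_000

    def __post_init__(self) -> None:
        if self.mu < 0 or self.rec < 0:
            raise ValueError("rates must be >= 0")
        if self.split_time < 0:
            raise ValueError("split_time must be >= 0")
        if len(self.sample_sizes) != self.n_pops:
            raise ValueError("one sample size per population required")
        if any(s > self.pop_size for s in self.sample_sizes):
            raise ValueError("sample size exceeds population size")
        if self.ancient_n is not None:
            if self.ancient_n < 2:
                raise ValueError("ancient_n must be >= 2")
            if self.expansion_time < self.split_time:
                raise ValueError("expansion must happen at or before the split")
        if self.bottleneck is not None:
            b = self.bottleneck
            if not 0 <= b.pop < self.n_pops:
                raise ValueError("bottleneck population index out of range")
            if b.reduced_n < 2 or b.duration < 1:
                raise ValueError("bottleneck needs reduced_n >= 2 and duration >= 1")
            if b.start > self.split_time:
                raise ValueError("bottleneck must start at or after the split")
        if self.sweep is not None:
            sw = self.sweep
            if not 1 <= sw.position <= self.chrom_length:
                raise ValueError("sweep position outside chromosome")
            if not 0 <= sw.pop < self.n_pops:
                raise ValueError("sweep population index out of range")
            if self.n_pops > 1 and sw.introduction_time > self.split_time:
                raise ValueError(
                    "sweep must be introduced at or after the population split"
                )
        # desk-scale guard on expected segregating sites (Watterson)
        n_hap = 2 * self.pop_size
        expected = 4 * self.pop_size * self.mu * self.chrom_length * _harmonic(n_hap - 1)
        if expected > self.max_expected_sites:
            raise ValueError(
                f"expected ~{expected:.0f} segregating sites exceeds the "
                f"desk-scale guard of {self.max_expected_sites}; reduce "
                "pop_size, chrom_length or mu"
            )

    @property
    def burn_in_generations(self) -> int:
        return 8 * self.pop_size if self.burn_in is None else self.burn_in


@dataclass
class SweepTruth:
    position: int
    s: float
    h: float
    pop: int
    final_freq: dict[str, float] = field(default_factory=dict)
    fixed: bool = False
    restarts: int = 0
    neutral_control: bool = False


class _State:
    """Mutable simulator state: per-pop allele matrices over a shared,
    unsorted column grid of segregating positions."""

    def __init__(self, n_pops: int, chrom_length: int):
        self.mats: list[np.ndarray] = [
            np.empty((0, 0), dtype=np.uint8) for _ in range(n_pops)
        ]
        self.positions = np.empty(0, dtype=np.int64)
        self.used: set[int] = set()
        self.chrom_length = chrom_length
        self.gens_since_prune = 0

    def copy(self) -> "_State":
        other = _State(len(self.mats), self.chrom_length)
        other.mats = [m.copy() for m in self.mats]
        other.positions = self.positions.copy()
        other.used = set(self.used)
        other.gens_since_prune = self.gens_since_prune
        return other

    def add_columns(self, new_positions, per_pop_rows) -> None:
        """Append one column per new mutation; per_pop_rows[p] lists, aligned
        with new_positions, the carrier row in pop p (or -1)."""
        k = len(new_positions)
        if k == 0:
            return
        self.positions = np.concatenate(
            [self.positions, np.asarray(new_positions, dtype=np.int64)]
        )
        self.used.update(int(x) for x in new_positions)
        for p, mat in enumerate(self.mats):
            block = np.zeros((mat.shape[0], k), dtype=np.uint8)
            rows = np.asarray(per_pop_rows[p], dtype=np.int64)
            hit = np.flatnonzero(rows >= 0)
            block[rows[hit], hit] = 1
            self.mats[p] = np.concatenate([mat, block], axis=1)

    def prune(self, protect: int | None = None) -> None:
        """Drop columns lost everywhere or fixed everywhere."""
        if self.positions.size == 0:
            return
        total = np.zeros(self.positions.size, dtype=np.int64)
        capacity = 0
        for mat in self.mats:
            if mat.shape[1]:
                total += mat.sum(axis=0, dtype=np.int64)
            capacity += mat.shape[0]
        keep = (total > 0) & (total < capacity)
        if protect is not None:
            keep |= self.positions == protect
        if keep.all():
            return
        dropped = self.positions[~keep]
        self.used.difference_update(int(x) for x in dropped)
        self.positions = self.positions[keep]
        self.mats = [m[:, keep] for m in self.mats]

    def column_of(self, position: int) -> int:
        hits = np.flatnonzero(self.positions == position)
        return int(hits[0]) if hits.size else -1


def _offspring(
    mat: np.ndarray,
    positions: np.ndarray,
    n_children: int,
    rng: np.random.Generator,
    chrom_length: int,
    rec: float,
    fitness: np.ndarray | None,
) -> np.ndarray:
    """One WF generation for one population: returns the 2*n_children x S
    child haplotype matrix."""
    n_parents = mat.shape[0] // 2
    n_gam = 2 * n_children
    if fitness is None:
        parents = rng.integers(0, n_parents, size=n_gam)
    else:
        parents = rng.choice(n_parents, size=n_gam, p=fitness / fitness.sum())
    start = rng.integers(0, 2, size=n_gam)
    children = mat[2 * parents + start]  # fancy indexing already copies
    if rec > 0.0 and positions.size:
        n_cross = rng.poisson(chrom_length * rec, size=n_gam)
        recomb = np.flatnonzero(n_cross)
        if recomb.size:
            bp_off = np.zeros(recomb.size + 1, dtype=np.int64)
            np.cumsum(n_cross[recomb], out=bp_off[1:])
            bp_flat = rng.integers(1, chrom_length + 1, size=int(bp_off[-1]))
            for t in range(recomb.size):
                bp_flat[bp_off[t] : bp_off[t + 1]].sort()
            _kernels.apply_crossovers(
                np.ascontiguousarray(mat),
                children,
                np.ascontiguousarray(positions, dtype=np.int64),
                (2 * parents[recomb] + 1 - start[recomb]).astype(np.int64),
                recomb.astype(np.int64),
                bp_flat.astype(np.int64),
                bp_off,
            )
    return children


def _mutate(
    state: _State,
    pop_children: list[np.ndarray],
    rng: np.random.Generator,
    mu: float,
    reserved: int | None,
) -> None:
    """Add Poisson new mutations to this generation's children, one column
    per mutation (infinite sites; colliding positions re-drawn)."""
    if mu <= 0.0:
        state.mats = pop_children
        return
    n_pops = len(pop_children)
    new_positions: list[int] = []
    pop_of: list[int] = []
    row_of: list[int] = []
    taken: set[int] = set()
    for p, children in enumerate(pop_children):
        n_gam = children.shape[0]
        n_new = int(rng.poisson(n_gam * state.chrom_length * mu))
        placed = 0
        while placed < n_new:
            # batch draws; infinite-sites collisions are rare and re-drawn
            batch = rng.integers(1, state.chrom_length + 1, size=n_new - placed)
            rows = rng.integers(0, n_gam, size=batch.size)
            for pos, row in zip(batch, rows):
                pos = int(pos)
                if pos in state.used or pos == reserved or pos in taken:
                    continue
                taken.add(pos)
                new_positions.append(pos)
                pop_of.append(p)
                row_of.append(int(row))
                placed += 1
    per_pop_rows = []
    pop_arr = np.asarray(pop_of, dtype=np.int64)
    row_arr = np.asarray(row_of, dtype=np.int64)
    for q in range(n_pops):
        per_pop_rows.append(np.where(pop_arr == q, row_arr, -1))
    state.mats = pop_children
    state.add_columns(new_positions, per_pop_rows)


def _sweep_fitness(
    mat: np.ndarray, col: int, s: float, h: float
) -> np.ndarray | None:
    if col < 0:
        return None
    dose = mat[0::2, col].astype(np.int64) + mat[1::2, col].astype(np.int64)
    w = np.ones(dose.size)
    w[dose == 1] = 1.0 + h * s
    w[dose == 2] = 1.0 + s
    return w


def _step(
    state: _State,
    sizes: list[int],
    rng: np.random.Generator,
    cfg: SimConfig,
    sweep_col_pop: tuple[int, int] | None,
) -> None:
    """Advance every population by one generation."""
    children = []
    for p, mat in enumerate(state.mats):
        fitness = None
        if sweep_col_pop is not None and sweep_col_pop[1] == p and cfg.sweep is not None:
            fitness = _sweep_fitness(mat, sweep_col_pop[0], cfg.sweep.s, cfg.sweep.h)
        children.append(
            _offspring(
                mat, state.positions, sizes[p], rng,
                cfg.chrom_length, cfg.rec, fitness,
            )
        )
    reserved = cfg.sweep.position if cfg.sweep is not None else None
    _mutate(state, children, rng, cfg.mu, reserved)
    # pruning lost/fixed columns is bookkeeping only; amortize it
    state.gens_since_prune += 1
    if state.gens_since_prune >= 4:
        protect = reserved if sweep_col_pop is not None else None
        state.prune(protect=protect)
        state.gens_since_prune = 0


def _pop_sizes_at(cfg: SimConfig, gens_before_sampling: int) -> list[int]:
    sizes = [cfg.pop_size] * cfg.n_pops
    b = cfg.bottleneck
    if b is not None and b.start >= gens_before_sampling > b.start - b.duration:
        sizes[b.pop] = b.reduced_n
    return sizes


def simulate(cfg: SimConfig) -> tuple[dict[str, HaplotypeMatrix], SweepTruth | None]:
    """Run the simulation; returns one phased matrix per population plus the
    sweep ground truth (None for neutral runs).

    Fully reproducible from ``cfg.seed``: the burn-in and divergence phases
    consume one deterministic stream, and each sweep-phase attempt uses its
    own child stream so restarts are reproducible too.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    burn = cfg.burn_in_generations
    total = burn + cfg.split_time
    sweep = cfg.sweep

    # --- burn-in: single ancestral population -----------------------------
    def ancestral_size(gens_before_sampling: int) -> int:
        if cfg.ancient_n is not None and gens_before_sampling > cfg.expansion_time:
            return cfg.ancient_n
        return cfg.pop_size

    one_pop = _State(1, cfg.chrom_length)
    one_pop.mats[0] = np.zeros(
        (2 * ancestral_size(burn + cfg.split_time), 0), dtype=np.uint8
    )
    for g in range(burn):
        _step(
            one_pop,
            [ancestral_size(burn + cfg.split_time - g - 1)],
            rng, cfg, sweep_col_pop=None,
        )

    # --- split: daughters start as copies of the ancestral pool -----------
    state = _State(cfg.n_pops, cfg.chrom_length)
    state.positions = one_pop.positions
    state.used = one_pop.used
    state.mats = [one_pop.mats[0].copy() for _ in range(cfg.n_pops)]

    intro_gen = None if sweep is None else total - sweep.introduction_time

    def run_divergence(
        st: _State, start_gen: int, end_gen: int, gen_rng: np.random.Generator,
        sweep_active: bool,
    ) -> bool:
        """Advance from start_gen to end_gen; returns False if an active
        sweep allele was lost."""
        def sweep_count() -> int:
            col = st.column_of(sweep.position)
            return 0 if col < 0 else int(st.mats[sweep.pop][:, col].sum())

        col_pop = None
        for g in range(start_gen, end_gen):
            if sweep_active:
                if sweep_count() == 0:
                    return False
                col_pop = (st.column_of(sweep.position), sweep.pop)
            _step(st, _pop_sizes_at(cfg, total - g), gen_rng, cfg, col_pop)
        if sweep_active:
            return sweep_count() > 0
        return True

    truth = None
    if sweep is None:
        run_divergence(state, burn, total, rng, sweep_active=False)
        restarts = 0
    else:
        run_divergence(state, burn, intro_gen, rng, sweep_active=False)
        snapshot = state.copy()
        restarts = 0
        attempt = 0
        while True:
            if attempt > cfg.max_restarts:
                raise RuntimeError(
                    f"sweep allele lost in {cfg.max_restarts} consecutive attempts"
                )
            attempt_rng = np.random.default_rng([cfg.seed, 1, attempt])
            state = snapshot.copy()
            # inject the beneficial allele on one random haplotype
            row = int(attempt_rng.integers(0, state.mats[sweep.pop].shape[0]))
            state.add_columns(
                [sweep.position],
                [[row if p == sweep.pop else -1] for p in range(cfg.n_pops)],
            )
            ok = run_divergence(state, intro_gen, total, attempt_rng, sweep_active=True)
            if ok and sweep.min_final_freq is not None:
                col = state.column_of(sweep.position)
                freq = float(state.mats[sweep.pop][:, col].mean())
                ok = freq >= sweep.min_final_freq
            if ok:
                rng = attempt_rng  # sampling continues on the final stream
                break
            restarts += 1
            attempt += 1

    # --- sampling ----------------------------------------------------------
    order = np.argsort(state.positions, kind="stable")
    positions = state.positions[order]
    matrices: dict[str, HaplotypeMatrix] = {}
    pop_names = [f"pop{p + 1}" for p in range(cfg.n_pops)]
    sampled_rows_per_pop = []
    for p in range(cfg.n_pops):
        chosen = rng.choice(state.mats[p].shape[0] // 2, size=cfg.sample_sizes[p], replace=False)
        rows = np.sort(np.concatenate([2 * chosen, 2 * chosen + 1]))
        sampled_rows_per_pop.append(rows)
    # keep the variant grid = sites segregating in the pooled sample
    pooled = np.concatenate(
        [state.mats[p][sampled_rows_per_pop[p]][:, order] for p in range(cfg.n_pops)],
        axis=0,
    )
    totals = pooled.sum(axis=0, dtype=np.int64)
    seg = (totals > 0) & (totals < pooled.shape[0])
    if sweep is not None:
        seg |= positions == sweep.position
    positions_out = positions[seg]
    row_offset = 0
    for p in range(cfg.n_pops):
        n_rows = sampled_rows_per_pop[p].size
        alleles = pooled[row_offset : row_offset + n_rows][:, seg].astype(np.int8)
        row_offset += n_rows
        sample_ids = [f"{pop_names[p]}_s{i}" for i in range(cfg.sample_sizes[p])]
        matrices[pop_names[p]] = HaplotypeMatrix(
            chrom=cfg.chrom,
            positions=positions_out.copy(),
            alleles=alleles,
            sample_ids=sample_ids,
            ancestral_is_ref=np.ones(positions_out.size, dtype=bool),
        )

    if sweep is not None:
        col = state.column_of(sweep.position)
        final_freq = {
            pop_names[p]: (float(state.mats[p][:, col].mean()) if col >= 0 else 0.0)
            for p in range(cfg.n_pops)
        }
        truth = SweepTruth(
            position=sweep.position,
            s=sweep.s,
            h=sweep.h,
            pop=sweep.pop,
            final_freq=final_freq,
            fixed=final_freq[pop_names[sweep.pop]] >= 1.0,
            restarts=restarts,
            neutral_control=sweep.s == 0.0,
        )
    return matrices, truth


def merge_populations(matrices: dict[str, HaplotypeMatrix]) -> HaplotypeMatrix:
    """Stack per-population matrices (shared variant grid) into one matrix."""
    mats = list(matrices.values())
    first = mats[0]
    for m in mats[1:]:
        if not np.array_equal(m.positions, first.positions):
            raise ValueError("populations do not share a variant grid")
    return HaplotypeMatrix(
        chrom=first.chrom,
        positions=first.positions.copy(),
        alleles=np.concatenate([m.alleles for m in mats], axis=0),
        sample_ids=[s for m in mats for s in m.sample_ids],
        ancestral_is_ref=first.ancestral_is_ref,
    )


def emit_truth_bundle(
    matrices: dict[str, HaplotypeMatrix],
    truth: SweepTruth | None,
    cfg: SimConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the simulation as a ready-to-analyze bundle.

    Produces a merged phased VCF (REF = ancestral allele), a sample->population
    map TSV, a truth/config JSON, and toy gene/QTL BED files placing one
    'gene' over the sweep site (or mid-chromosome for neutral runs) so the
    annotation path is exercised end-to-end.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    merged = merge_populations(matrices)
    paths = {
        "vcf": out / "simulated.vcf",
        "popmap": out / "popmap.tsv",
        "truth": out / "truth.json",
        "genes": out / "genes.bed",
        "qtls": out / "qtls.bed",
    }
    write_vcf(merged, paths["vcf"])
    lines = []
    for pop, m in matrices.items():
        for s in m.sample_ids:
            lines.append(f"{s}\t{pop}")
    paths["popmap"].write_text("\n".join(lines) + "\n")

    payload = {
        "config": _config_dict(cfg),
        "seed": cfg.seed,
        "sweep_truth": None if truth is None else asdict(truth),
    }
    paths["truth"].write_text(json.dumps(payload, indent=2) + "\n")

    center = truth.position if truth is not None else cfg.chrom_length // 2
    half = 10_000
    g_start = max(0, center - half - 1)
    g_end = min(cfg.chrom_length, center + half)
    decoy_start = max(0, cfg.chrom_length // 10)
    paths["genes"].write_text(
        f"{cfg.chrom}\t{g_start}\t{g_end}\tsweepGene\n"
        f"{cfg.chrom}\t{decoy_start}\t{decoy_start + 5000}\tdecoyGene\n"
    )
    paths["qtls"].write_text(f"{cfg.chrom}\t{g_start}\t{g_end}\tsweepQTL\n")
    return paths


def _config_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["sample_sizes"] = list(cfg.sample_sizes)
    return d
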