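"""Core data model: phased haplotypes, genotypes, populations, windows, intervals.

Conventions
-----------
* All genomic coordinates are 1-based inclusive (VCF convention). BED input is
  converted at the I/O boundary.
* Allele matrices are coded 0 (REF), 1 (ALT), ``MISSING`` (= -1).
* For diploid samples the haplotype matrix has ``2 * n_samples`` rows; row
  ``2*i`` and ``2*i + 1`` are the two phased haplotypes of sample ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING: int = -1


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 allele matrix over (haplotype x variant).

    Attributes
    ----------
    chrom : str
        Chromosome name.
    positions : np.ndarray
        1-based physical positions (bp), strictly increasing.
    alleles : np.ndarray
        int8 matrix of shape (n_haplotypes, n_variants); 0 = REF, 1 = ALT,
        -1 = missing.
    sample_ids : list of str
        One entry per diploid sample; haplotype rows 2i and 2i+1 belong to
        sample i.
    ancestral_is_ref : np.ndarray or None
        Per-variant boolean: True if the ancestral allele is REF. ``None``
        means unknown, in which case analyses that need polarization assume
        REF is ancestral.
    ref : np.ndarray or None
        Optional REF base per variant (kept for VCF round-trips).
    alt : np.ndarray or None
        Optional ALT base per variant.
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    sample_ids: list[str]
    ancestral_is_ref: np.ndarray | None = None
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[1] != self.positions.size:
            raise ValueError(
                f"{self.alleles.shape[1]} allele columns vs "
                f"{self.positions.size} positions"
            )
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError(
                f"{self.alleles.shape[0]} haplotype rows but "
                f"{len(self.sample_ids)} samples (expected 2 per sample)"
            )
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.ancestral_is_ref is not None:
            self.ancestral_is_ref = np.asarray(self.ancestral_is_ref, dtype=bool)
            if self.ancestral_is_ref.size != self.positions.size:
                raise ValueError("ancestral_is_ref length mismatch")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    @property
    def haplotype_ids(self) -> list[str]:
        """Sample name + phase index, e.g. ``s1_hap0``, ``s1_hap1``."""
        return [f"{s}_hap{k}" for s in self.sample_ids for k in (0, 1)]

    def derived_alleles(self) -> np.ndarray:
        """Alleles recoded so that 1 = derived (ancestral polarization).

        REF is assumed ancestral where ``ancestral_is_ref`` is None.
        Missing entries stay -1.
        """
        out = self.alleles.copy()
        if self.ancestral_is_ref is not None:
            flip = ~self.ancestral_is_ref
            cols = out[:, flip]
            swapped = np.where(cols == MISSING, MISSING, 1 - cols)
            out[:, flip] = swapped.astype(np.int8)
        return out

    def subset_samples(self, sample_ids: Sequence[str]) -> "HaplotypeMatrix":
        """Restrict to the given samples (order preserved as given)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows: list[int] = []
        for s in sample_ids:
            if s not in index:
                raise KeyError(f"sample {s!r} not in matrix")
            rows.extend((2 * index[s], 2 * index[s] + 1))
        return HaplotypeMatrix(
            chrom=self.chrom,
            positions=self.positions.copy(),
            alleles=self.alleles[rows],
            sample_ids=list(sample_ids),
            ancestral_is_ref=None
            if self.ancestral_is_ref is None
            else self.ancestral_is_ref.copy(),
            ref=self.ref,
            alt=self.alt,
        )

    def to_genotypes(self) -> "GenotypeMatrix":
        """Forget phase; allele counts are conserved."""
        return GenotypeMatrix(
            chrom=self.chrom,
            positions=self.positions.copy(),
            alleles=self.alleles.copy(),
            sample_ids=list(self.sample_ids),
        )


@dataclass
class GenotypeMatrix:
    """Unphased diploid genotypes as unordered allele pairs.

    Stored internally as the same (2N x M) allele matrix as
    :class:`HaplotypeMatrix`, but row order within a sample carries no phase
    meaning and no analysis may rely on it.
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("need 2 allele rows per diploid sample")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    def sample_rows(self, sample_ids: Sequence[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows: list[int] = []
        for s in sample_ids:
            if s not in index:
                raise KeyError(f"sample {s!r} not in matrix")
            rows.extend((2 * index[s], 2 * index[s] + 1))
        return np.asarray(rows, dtype=np.intp)


class PopulationMap:
    """Mapping sample -> population label."""

    def __init__(self, mapping: Mapping[str, str]):
        self._map = dict(mapping)
        if not self._map:
            raise ValueError("empty population map")

    def __getitem__(self, sample: str) -> str:
        return self._map[sample]

    def __contains__(self, sample: str) -> bool:
        return sample in self._map

    def __len__(self) -> int:
        return len(self._map)

    @property
    def samples(self) -> list[str]:
        return list(self._map)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self._map.values():
            seen.setdefault(p)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self._map.items() if p == population]

    def validate_against(self, sample_ids: Iterable[str]) -> None:
        missing = [s for s in sample_ids if s not in self._map]
        if missing:
            raise ValueError(f"samples without population label: {missing}")

    def items(self):
        return self._map.items()


@dataclass(frozen=True)
class GenomicWindow:
    """1-based inclusive genomic window."""

    chrom: str
    start: int
    end: int
    window_id: int = 0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"window end {self.end} < start {self.start}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass(frozen=True)
class Interval:
    """Named annotation interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    name: str
    kind: str = "other"  # gene | QTL | other


@dataclass
class IntervalSet:
    """Collection of annotation intervals with overlap queries."""

    records: list[Interval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def add(self, interval: Interval) -> None:
        self.records.append(interval)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Interval]:
        """Intervals sharing >= 1 bp with [start, end] on chrom."""
        return [
            r
            for r in self.records
            if r.chrom == chrom and r.start <= end and start <= r.end
        ]

    def names(self) -> list[str]:
        return [r.name for r in self.records]
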