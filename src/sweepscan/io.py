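"""Readers/writers for VCF, BED/GFF3/TSV intervals and population maps,
plus sliding-window construction.

Only biallelic SNPs are kept when reading VCF; multi-allelic records and
indels are dropped with a logged count. Haplotype use requires the phased
``|`` separator in every non-missing genotype.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from .core import (
    MISSING,
    GenomicWindow,
    HaplotypeMatrix,
    Interval,
    IntervalSet,
    PopulationMap,
)

logger = logging.getLogger(__name__)


def read_population_map(path: str | Path) -> PopulationMap:
    """Read a two-column ``sample<TAB>population`` table."""
    mapping: dict[str, str] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{line_no}: expected sample<TAB>population")
        sample, pop = fields[0], fields[1]
        if sample in mapping:
            raise ValueError(f"{path}:{line_no}: duplicate sample {sample!r}")
        mapping[sample] = pop
    return PopulationMap(mapping)


def read_phased_vcf(
    path: str | Path,
    population_map: PopulationMap | None = None,
    require_phased: bool = True,
) -> dict[str, HaplotypeMatrix]:
    """Read a phased VCF into one :class:`HaplotypeMatrix` per chromosome.

    Multi-allelic records and non-SNP records are excluded (count logged).
    Missing alleles are preserved as missing. With ``require_phased`` (the
    default) any unphased non-missing genotype raises, naming the record.
    Ancestral polarity is taken from an ``AA`` INFO field when present,
    otherwise left unknown (downstream defaults to REF = ancestral).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if population_map is not None:
        population_map.validate_against(samples)

    per_chrom: dict[str, dict[str, list]] = {}
    n_dropped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_dropped += 1
            continue
        ref, alt = variant.REF, variant.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or alt in ("*", "."):
            n_dropped += 1
            continue
        chrom = variant.CHROM
        store = per_chrom.setdefault(
            chrom,
            {"pos": [], "alleles": [], "aa": [], "ref": [], "alt": []},
        )
        if store["pos"] and store["pos"][-1] == variant.POS:
            raise ValueError(f"duplicate position {chrom}:{variant.POS}")

        row = np.full(2 * len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            a0, a1, phased = gt[0], gt[1], bool(gt[-1])
            if require_phased and not phased and (a0 >= 0 or a1 >= 0):
                raise ValueError(
                    f"unphased genotype for sample {samples[i]!r} at "
                    f"{chrom}:{variant.POS}; phased '|' separator required"
                )
            row[2 * i] = a0 if a0 >= 0 else MISSING
            row[2 * i + 1] = a1 if a1 >= 0 else MISSING
        store["pos"].append(variant.POS)
        store["alleles"].append(row)
        aa = variant.INFO.get("AA")
        store["aa"].append(None if aa is None else str(aa).upper() == ref.upper())
        store["ref"].append(ref)
        store["alt"].append(alt)
    vcf.close()

    if n_dropped:
        logger.info("dropped %d multi-allelic/non-SNP records from %s", n_dropped, path)

    result: dict[str, HaplotypeMatrix] = {}
    for chrom, store in per_chrom.items():
        pos = np.asarray(store["pos"], dtype=np.int64)
        if np.any(np.diff(pos) <= 0):
            bad = int(pos[np.argmin(np.diff(pos))])
            raise ValueError(f"positions not strictly increasing near {chrom}:{bad}")
        aa_vals = store["aa"]
        anc = None
        if any(v is not None for v in aa_vals):
            anc = np.array([True if v is None else v for v in aa_vals], dtype=bool)
        result[chrom] = HaplotypeMatrix(
            chrom=chrom,
            positions=pos,
            alleles=np.column_stack(store["alleles"])
            if store["alleles"]
            else np.empty((2 * len(samples), 0), dtype=np.int8),
            sample_ids=samples,
            ancestral_is_ref=anc,
            ref=np.asarray(store["ref"], dtype=object),
            alt=np.asarray(store["alt"], dtype=object),
        )
    return result


def write_vcf(matrices: HaplotypeMatrix | list[HaplotypeMatrix], path: str | Path) -> None:
    """Write phased matrices to a VCF 4.2 text file.

    Round-trips exactly through :func:`read_phased_vcf`: alleles, positions
    and sample order are preserved. Missing alleles are emitted as ``.``.
    When ``ancestral_is_ref`` is set, the ancestral allele is recorded in the
    ``AA`` INFO field.
    """
    if isinstance(matrices, HaplotypeMatrix):
        matrices = [matrices]
    if not matrices:
        raise ValueError("nothing to write")
    samples = matrices[0].sample_ids
    for m in matrices[1:]:
        if m.sample_ids != samples:
            raise ValueError("all matrices must share the same samples")

    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for m in matrices:
        length = int(m.positions[-1]) if m.n_variants else 1
        lines.append(f"##contig=<ID={m.chrom},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )

    def _code(a: int) -> str:
        return "." if a == MISSING else str(int(a))

    for m in matrices:
        ref = m.ref if m.ref is not None else np.full(m.n_variants, "A", dtype=object)
        alt = m.alt if m.alt is not None else np.full(m.n_variants, "C", dtype=object)
        for j in range(m.n_variants):
            if m.ancestral_is_ref is None:
                info = "."
            else:
                info = f"AA={ref[j] if m.ancestral_is_ref[j] else alt[j]}"
            gts = "\t".join(
                f"{_code(m.alleles[2 * i, j])}|{_code(m.alleles[2 * i + 1, j])}"
                for i in range(m.n_samples)
            )
            lines.append(
                f"{m.chrom}\t{int(m.positions[j])}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t"
                f"{info}\tGT\t{gts}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_intervals(path: str | Path, format: str | None = None) -> IntervalSet:
    """Read annotation intervals from BED, GFF3 or a simple TSV.

    BED half-open 0-based coordinates are converted to 1-based inclusive;
    GFF3 and TSV are taken as 1-based inclusive. The TSV layout is
    ``chrom<TAB>start<TAB>end<TAB>name[<TAB>kind]``.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"bed": "BED", ".bed": "BED", ".gff": "GFF3", ".gff3": "GFF3"}.get(
            suffix, "TSV"
        )
    format = format.upper()
    if format not in ("BED", "GFF3", "TSV"):
        raise ValueError(f"unrecognized interval format {format!r}")

    out = IntervalSet()
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split("\t")
        if len(fields) == 1:
            fields = stripped.split()
        try:
            if format == "BED":
                chrom = fields[0]
                start = int(fields[1]) + 1  # 0-based half-open -> 1-based inclusive
                end = int(fields[2])
                name = fields[3] if len(fields) > 3 else f"interval{line_no}"
                kind = fields[4] if len(fields) > 4 else "other"
            elif format == "GFF3":
                if len(fields) < 9:
                    raise IndexError("GFF3 needs 9 columns")
                chrom, start, end = fields[0], int(fields[3]), int(fields[4])
                kind = fields[2] if fields[2] in ("gene", "QTL") else "other"
                name = f"interval{line_no}"
                for item in fields[8].split(";"):
                    if "=" in item:
                        key, value = item.split("=", 1)
                        if key in ("Name", "ID", "gene_name"):
                            name = value
                            if key == "Name":
                                break
            else:  # TSV
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else f"interval{line_no}"
                kind = fields[4] if len(fields) > 4 else "other"
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{line_no}: malformed {format} line: {exc}") from exc
        if end < start:
            raise ValueError(f"{path}:{line_no}: start > end after normalization")
        out.add(Interval(chrom=chrom, start=start, end=end, name=name, kind=kind))
    return out


def write_intervals_bed(intervals: IntervalSet | list, path: str | Path) -> None:
    """Export intervals as BED (1-based inclusive -> 0-based half-open)."""
    lines = []
    for r in intervals:
        lines.append(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.name}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def make_windows(
    chrom_length: int, size: int, step: int | None = None, chrom: str = "1"
) -> list[GenomicWindow]:
    """Tile [1, chrom_length] with windows of ``size`` advancing by ``step``.

    The first window starts at 1; the last is truncated at ``chrom_length``.
    With ``step == size`` the windows partition the chromosome exactly; with
    ``step < size`` adjacent windows overlap by ``size - step`` bp.
    """
    if step is None:
        step = size
    if size < 1 or step < 1:
        raise ValueError("window size and step must be >= 1")
    if step > size:
        raise ValueError("step must not exceed window size (gaps would appear)")
    if chrom_length < 1:
        raise ValueError("chrom_length must be >= 1")
    windows = []
    wid = 0
    start = 1
    while start <= chrom_length:
        end = min(start + size - 1, chrom_length)
        windows.append(GenomicWindow(chrom=chrom, start=start, end=end, window_id=wid))
        wid += 1
        if end == chrom_length:
            break
        start += step
    return windows
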