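"""Domain types, file readers/writers and variant filtering.

Containers used throughout the pipeline: sample metadata (:class:`Specimen`),
per-position read-depth tables (:class:`DepthMatrix`, the ``samtools depth -aa``
convention of one row per position with one column per individual), a variant
table backed by numpy arrays (:class:`VariantTable`), and tiling window grids.

Coordinate conventions: depth tables are 1-based and cover every position of a
chromosome; windows and BED exports are 0-based half-open.
"""

from __future__ import annotations

import csv
import gzip
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

MALE = "male"
FEMALE = "female"

_SEX_TOKENS = {
    "m": MALE, "male": MALE, "males": MALE, "1": MALE,
    "f": FEMALE, "female": FEMALE, "females": FEMALE, "2": FEMALE,
}


@dataclass(frozen=True)
class Specimen:
    """One sequenced individual with known phenotypic sex."""

    id: str
    sex: str
    population: str = "pop"

    def __post_init__(self) -> None:
        if self.sex not in (MALE, FEMALE):
            raise ValueError(f"specimen {self.id!r}: sex must be male/female, got {self.sex!r}")


def normalize_sex(token: str) -> str:
    try:
        return _SEX_TOKENS[token.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown sex token {token!r}") from None


class GenomeIndex:
    """Ordered chromosome names and lengths (bp)."""

    def __init__(self, entries: Iterable[tuple[str, int]]):
        self.names: list[str] = []
        self.lengths: dict[str, int] = {}
        for name, length in entries:
            if name in self.lengths:
                raise ValueError(f"duplicate chromosome name {name!r}")
            if length < 1:
                raise ValueError(f"chromosome {name!r}: length must be >= 1, got {length}")
            self.names.append(name)
            self.lengths[name] = int(length)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return ((n, self.lengths[n]) for n in self.names)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeIndex) and list(self) == list(other)

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())


@dataclass(frozen=True)
class Window:
    """Half-open genomic interval [start, end) on a chromosome (0-based)."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window {self.chromosome}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


class DepthMatrix:
    """Per-position sequencing depth for a panel of specimens.

    ``depth[chrom]`` is an ``(n_positions, n_specimens)`` integer array whose
    row i holds depths at 1-based position i+1; every position of each
    chromosome is present (all-positions contract).
    """

    def __init__(self, depth: dict[str, np.ndarray], specimens: Sequence[Specimen]):
        self.specimens = list(specimens)
        ids = [s.id for s in self.specimens]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate specimen ids in depth matrix")
        self.depth: dict[str, np.ndarray] = {}
        for chrom, arr in depth.items():
            arr = np.asarray(arr)
            if arr.ndim != 2 or arr.shape[1] != len(self.specimens):
                raise ValueError(
                    f"{chrom}: depth array must be (n_positions, {len(self.specimens)})"
                )
            if arr.size and arr.min() < 0:
                raise ValueError(f"{chrom}: negative depth")
            self.depth[chrom] = arr

    @property
    def chromosomes(self) -> list[str]:
        return list(self.depth)

    def genome_index(self) -> GenomeIndex:
        return GenomeIndex((c, a.shape[0]) for c, a in self.depth.items())

    def sex_columns(self, sex: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.specimens) if s.sex == sex], dtype=int)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DepthMatrix):
            return NotImplemented
        return (
            self.specimens == other.specimens
            and self.chromosomes == other.chromosomes
            and all(np.array_equal(self.depth[c], other.depth[c]) for c in self.depth)
        )


class VariantTable:
    """Biallelic-or-multiallelic variant sites with per-specimen genotypes.

    Genotypes are stored as an ``(n_sites, n_specimens, 2)`` int8 array of
    allele indices, -1 for a missing call. Site annotations (QD, FS, ...) are
    float arrays with NaN where the annotation is absent.
    """

    def __init__(
        self,
        chrom: np.ndarray,
        pos: np.ndarray,
        ref: np.ndarray,
        alts: list[tuple[str, ...]],
        genotypes: np.ndarray,
        specimens: Sequence[Specimen],
        annotations: dict[str, np.ndarray] | None = None,
    ):
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alts = list(alts)
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        self.specimens = list(specimens)
        self.annotations = {k: np.asarray(v, dtype=float) for k, v in (annotations or {}).items()}
        n = len(self.pos)
        if not (len(self.chrom) == len(self.ref) == len(self.alts) == n):
            raise ValueError("inconsistent site array lengths")
        if self.genotypes.shape != (n, len(self.specimens), 2):
            raise ValueError("genotype array shape mismatch")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"{c}: positions not strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def take(self, mask: np.ndarray) -> "VariantTable":
        idx = np.flatnonzero(mask)
        return VariantTable(
            self.chrom[idx],
            self.pos[idx],
            self.ref[idx],
            [self.alts[i] for i in idx],
            self.genotypes[idx],
            self.specimens,
            {k: v[idx] for k, v in self.annotations.items()},
        )

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of specimens with a missing genotype call."""
        miss = np.any(self.genotypes < 0, axis=2)
        return miss.mean(axis=1)


@dataclass
class FilterConfig:
    """Hard-filter thresholds for SNP sites plus cohort-level site filters.

    Defaults are the conventional GATK-style SNP thresholds; a predicate with
    a missing annotation at a site never triggers removal of that site.
    ``max_missing`` removes sites with *more than* that fraction of missing
    genotypes; ``biallelic_snps_only`` keeps sites with exactly two single-base
    alleles.
    """

    # annotation -> (operator, threshold); "lt" removes when value < threshold
    snp_rules: dict[str, tuple[str, float]] = field(default_factory=lambda: {
        "MQ": ("lt", 40.0),
        "FS": ("gt", 60.0),
        "QD": ("lt", 2.0),
        "SOR": ("gt", 7.5),
        "MQRankSum": ("lt", -12.5),
        "ReadPosRankSum": ("lt", -10.0),
    })
    # indel rules accepted for completeness; the default pipeline keeps SNPs only
    indel_rules: dict[str, tuple[str, float]] = field(default_factory=lambda: {
        "QD": ("lt", 2.0),
        "FS": ("gt", 200.0),
        "ReadPosRankSum": ("lt", -20.0),
        "SOR": ("gt", 10.0),
    })
    max_missing: float = 0.2
    biallelic_snps_only: bool = True


def read_sample_sheet(path: str | os.PathLike) -> list[Specimen]:
    """Read a CSV/TSV sample sheet with header columns id, sex, population."""
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if sample.count("\t") >= sample.count(",") else ","
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or not {"id", "sex"} <= set(reader.fieldnames):
            raise ValueError("sample sheet must have header columns id, sex[, population]")
        specimens, seen = [], set()
        for i, row in enumerate(reader, start=2):
            sid = row["id"].strip()
            if sid in seen:
                raise ValueError(f"duplicate specimen id {sid!r} (line {i})")
            seen.add(sid)
            try:
                sex = normalize_sex(row["sex"])
            except ValueError as e:
                raise ValueError(f"line {i} (id {sid!r}): {e}") from None
            specimens.append(Specimen(sid, sex, (row.get("population") or "pop").strip()))
    return specimens


def write_sample_sheet(specimens: Sequence[Specimen], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "sex", "population"])
        for s in specimens:
            w.writerow([s.id, s.sex, s.population])


def _open_text(path, mode="rt"):
    p = os.fspath(path)
    return gzip.open(p, mode) if p.endswith(".gz") else open(p, mode)


def parse_depth(source, sample_order: Sequence[Specimen]) -> DepthMatrix:
    """Parse a depth table (chrom, pos, one depth column per specimen).

    ``source`` is a path (gzip-transparent) or an open text stream. Positions
    must run 1..length consecutively within each chromosome.
    """
    close = False
    if isinstance(source, (str, os.PathLike)):
        fh, close = _open_text(source), True
    else:
        fh = source
    n = len(sample_order)
    per_chrom: dict[str, list[np.ndarray]] = {}
    order: list[str] = []
    try:
        cur, rows, expect = None, None, 1
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != n + 2:
                raise ValueError(
                    f"line {lineno}: expected {n + 2} columns ({n} specimens), got {len(parts)}"
                )
            chrom, pos = parts[0], int(parts[1])
            if chrom != cur:
                if chrom in per_chrom:
                    raise ValueError(f"line {lineno}: chromosome {chrom!r} rows are not contiguous")
                cur, expect = chrom, 1
                rows = per_chrom.setdefault(chrom, [])
                order.append(chrom)
            if pos != expect:
                raise ValueError(
                    f"line {lineno}: {chrom} position {pos}, expected {expect} "
                    "(gap or non-monotone positions)"
                )
            expect += 1
            rows.append(np.array(parts[2:], dtype=np.int32))
    finally:
        if close:
            fh.close()
    depth = {c: (np.vstack(v) if v else np.empty((0, n), np.int32)) for c, v in per_chrom.items()}
    return DepthMatrix({c: depth[c] for c in order}, sample_order)


def write_depth(d: DepthMatrix, path: str | os.PathLike) -> None:
    """Write a DepthMatrix in the depth-scan TSV convention (gzip by suffix)."""
    with _open_text(path, "wt") as fh:
        for chrom, arr in d.depth.items():
            buf = io.StringIO()
            for i in range(arr.shape[0]):
                buf.write(chrom)
                buf.write(f"\t{i + 1}\t")
                buf.write("\t".join(map(str, arr[i])))
                buf.write("\n")
            fh.write(buf.getvalue())


def make_windows(genome: GenomeIndex, size_bp: int) -> list[Window]:
    """Tile each chromosome with consecutive [k*size, (k+1)*size) windows.

    A shorter terminal window is emitted when the length is not a multiple of
    the window size, so every base is covered exactly once.
    """
    if size_bp < 1:
        raise ValueError(f"window size must be >= 1, got {size_bp}")
    windows = []
    for chrom, length in genome:
        for start in range(0, length, size_bp):
            windows.append(Window(chrom, start, min(start + size_bp, length)))
    return windows


def windows_to_bed(windows: Iterable[Window], path: str | os.PathLike, extra=None) -> None:
    """Write windows as BED3(+) lines; ``extra`` maps a window to extra columns."""
    with open(path, "w") as fh:
        for w in windows:
            cols = [w.chromosome, str(w.start), str(w.end)]
            if extra is not None:
                cols += [str(x) for x in extra(w)]
            fh.write("\t".join(cols) + "\n")


def _violates(values: np.ndarray, op: str, threshold: float) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        if op == "lt":
            bad = values < threshold
        elif op == "gt":
            bad = values > threshold
        else:
            raise ValueError(f"unknown operator {op!r}")
    bad[np.isnan(values)] = False  # missing annotation never triggers removal
    return bad


def apply_variant_filters(v: VariantTable, rules: FilterConfig | None = None) -> VariantTable:
    """Apply hard-filter predicates plus missingness/biallelic-SNP site filters.

    A site is removed if any annotation predicate fires (missing annotations
    never fire), if more than ``max_missing`` of its genotypes are missing, or
    (by default) if it is not a biallelic single-nucleotide variant.
    Idempotent: a filtered table passes unchanged through a second application.
    """
    rules = rules or FilterConfig()
    keep = np.ones(v.n_sites, dtype=bool)
    for ann, (op, thr) in rules.snp_rules.items():
        if ann in v.annotations:
            keep &= ~_violates(v.annotations[ann], op, thr)
    keep &= v.missing_fraction() <= rules.max_missing
    if rules.biallelic_snps_only:
        bial = np.array(
            [len(a) == 1 and len(a[0]) == 1 and len(r) == 1 for a, r in zip(v.alts, v.ref)]
        )
        keep &= bial
    return v.take(keep)


def read_vcf(path: str | os.PathLike, specimens: Sequence[Specimen] | None = None) -> VariantTable:
    """Read a VCF (v4.x) into a VariantTable using cyvcf2.

    If ``specimens`` is given, its ids must match the VCF sample columns; sex
    and population metadata are attached from it. Otherwise specimens are
    created with unknown metadata defaults (all female, population "pop"),
    which is only suitable for genotype-free operations.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    samples = list(vcf.samples)
    if specimens is not None:
        by_id = {s.id: s for s in specimens}
        missing = [s for s in samples if s not in by_id]
        if missing:
            raise ValueError(f"VCF samples absent from sample sheet: {missing}")
        spec = [by_id[s] for s in samples]
    else:
        spec = [Specimen(s, FEMALE) for s in samples]
    ann_keys = ("QD", "FS", "SOR", "DP", "MQ", "MQRankSum", "ReadPosRankSum")
    chrom, pos, ref, alts, gts = [], [], [], [], []
    ann: dict[str, list[float]] = {k: [] for k in ann_keys}
    for rec in vcf:
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alts.append(tuple(rec.ALT))
        g = np.asarray(rec.genotype.array())[:, :2]
        gts.append(np.where(g < 0, -1, g).astype(np.int8))
        for k in ann_keys:
            val = rec.INFO.get(k)
            ann[k].append(float(val) if val is not None else np.nan)
    n = len(pos)
    genotypes = (
        np.stack(gts) if n else np.empty((0, len(spec), 2), np.int8)
    )
    return VariantTable(
        np.array(chrom, dtype=object), np.array(pos, dtype=np.int64),
        np.array(ref, dtype=object), alts, genotypes, spec,
        {k: np.array(v) for k, v in ann.items()},
    )


def write_vcf(v: VariantTable, path: str | os.PathLike) -> None:
    """Write a VariantTable as a minimal plain-text VCF v4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for k in v.annotations:
            fh.write(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        lengths: dict[str, int] = {}
        for c, p in zip(v.chrom, v.pos):
            lengths[c] = max(lengths.get(c, 0), int(p))
        for c, ln in lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(s.id for s in v.specimens) + "\n"
        )
        for i in range(v.n_sites):
            info = ";".join(
                f"{k}={v.annotations[k][i]:g}" for k in v.annotations
                if not np.isnan(v.annotations[k][i])
            ) or "."
            gt_strs = []
            for a, b in v.genotypes[i]:
                gt_strs.append("./." if a < 0 or b < 0 else f"{a}/{b}")
            fh.write(
                f"{v.chrom[i]}\t{v.pos[i]}\t.\t{v.ref[i]}\t{','.join(v.alts[i]) or '.'}"
                f"\t.\tPASS\t{info}\tGT\t" + "\t".join(gt_strs) + "\n"
            )
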