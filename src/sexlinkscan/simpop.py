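"""Synthetic population generator with planted sex-determination architectures.

Emulates the inputs of the downstream scans — genotype tables, per-position
depth tables (an "all reads" and a strict mismatch-free-mapping flavor),
per-sex assembly FASTA and per-specimen reads — for a population of known-sex
diploid individuals, under a configurable architecture:

``none``
    no sex linkage anywhere (null model).
``xy_region`` / ``zw_region``
    a contiguous region where X/Y (Z/W) gametologs have diverged: sex-linked
    SNPs are heterozygous in every heterogametic individual, and under strict
    mismatch-free mapping the heterogametic sex loses the reads originating
    from the diverged gametolog, reducing its mapped depth over the region.
``y_insertion`` / ``w_insertion``
    sequence present only on the Y (W): emitted as extra scaffolds of the
    heterogametic-sex assembly, covered at hemizygous depth in that sex and at
    zero depth in the other.
``polygenic``
    several unlinked loci with partial-penetrance sex association.

Every planted feature is recorded in a :class:`SimTruth` ledger so recovery can
be scored exactly. All randomness derives from the single config seed;
identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    FEMALE,
    MALE,
    DepthMatrix,
    GenomeIndex,
    Specimen,
    VariantTable,
    write_depth,
    write_sample_sheet,
    write_vcf,
)

ARCHITECTURES = ("none", "xy_region", "zw_region", "y_insertion", "w_insertion", "polygenic")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for one synthetic population.

    Defaults mirror the per-population design of the study this pipeline
    supports: six individuals per sex sequenced to ~20x, scanned in a genome
    of ten 1-Mb chromosomes, with a 200-kb sex-differentiated region (for
    region architectures) or a 2-kb sex-limited insertion (for insertion
    architectures).
    """

    seed: int = 0
    n_chromosomes: int = 10
    chromosome_length_bp: int = 1_000_000
    n_males: int = 6
    n_females: int = 6
    mean_depth: float = 20.0
    architecture: str = "none"
    sd_region: tuple[str, int, int] | None = None  # default: middle 20% of chromosome 1
    gametolog_divergence: float = 0.01
    insertion_length_bp: int = 2_000
    n_insertions: int = 1
    snp_density: float = 0.001
    allele_frequency_prior: tuple[float, float] = (0.5, 0.5)
    read_length_bp: int = 100
    read_error_rate: float = 0.001
    strict_mapping_mode: bool = True
    depth_tracks: tuple[str, ...] = ("all", "strict")
    polygenic_loci: int = 10
    polygenic_penetrance: float = 0.8
    population: str = "pop1"
    with_sequences: bool = True  # generate genome sequences, assemblies and reads

    def validate(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.n_males < 2 or self.n_females < 2:
            raise ValueError("need at least 2 individuals per sex")
        for p in (self.gametolog_divergence, self.snp_density, self.read_error_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.architecture in ("xy_region", "zw_region"):
            c, s, e = self.resolved_region()
            if c not in self.chromosome_names():
                raise ValueError(f"sd_region chromosome {c!r} not in genome")
            if not (0 <= s < e <= self.chromosome_length_bp):
                raise ValueError("sd_region outside chromosome bounds")
        if self.sd_region is not None and self.architecture not in ("xy_region", "zw_region"):
            raise ValueError(f"sd_region is not meaningful for architecture={self.architecture!r}")

    def chromosome_names(self) -> list[str]:
        return [f"LG{i + 1:02d}" for i in range(self.n_chromosomes)]

    def genome_index(self) -> GenomeIndex:
        return GenomeIndex((c, self.chromosome_length_bp) for c in self.chromosome_names())

    def resolved_region(self) -> tuple[str, int, int]:
        """The sex-differentiated region (0-based half-open)."""
        if self.sd_region is not None:
            return self.sd_region
        length = self.chromosome_length_bp
        return (self.chromosome_names()[0], int(length * 0.4), int(length * 0.6))

    @property
    def heterogametic_sex(self) -> str | None:
        if self.architecture in ("xy_region", "y_insertion"):
            return MALE
        if self.architecture in ("zw_region", "w_insertion"):
            return FEMALE
        return None


@dataclass
class SimTruth:
    """Ledger of planted sex-linked features, sufficient to score recovery."""

    architecture: str
    region: tuple[str, int, int] | None = None
    sex_linked_snps: list[tuple[str, int, str]] = field(default_factory=list)  # (chrom, pos1, pattern)
    insertions: list[dict] = field(default_factory=list)  # {scaffold, length, carrier_sex, sequence}
    polygenic: list[tuple[str, int]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        d["region"] = tuple(d["region"]) if d["region"] else None
        d["sex_linked_snps"] = [tuple(x) for x in d["sex_linked_snps"]]
        d["polygenic"] = [tuple(x) for x in d["polygenic"]]
        return cls(**d)


@dataclass
class SimResult:
    specimens: list[Specimen]
    genotypes: VariantTable
    depth_all: DepthMatrix | None
    depth_strict: DepthMatrix | None
    assemblies: dict[str, list[tuple[str, str]]]  # sex -> [(scaffold, sequence)]
    reads: dict[str, list[str]]  # specimen id -> read sequences
    truth: SimTruth
    config: SimConfig


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _random_genome(cfg: SimConfig) -> dict[str, np.ndarray]:
    rng = _rng(cfg, 1)
    return {
        c: _BASES[rng.integers(0, 4, size=cfg.chromosome_length_bp)]
        for c in cfg.chromosome_names()
    }


def _simulate_variants(cfg: SimConfig, specimens, genome):
    """Background SNPs (Hardy-Weinberg, sex-independent) plus planted sex-linked SNPs."""
    rng = _rng(cfg, 2)
    n_ind = len(specimens)
    male_idx = np.array([i for i, s in enumerate(specimens) if s.sex == MALE])
    female_idx = np.array([i for i, s in enumerate(specimens) if s.sex == FEMALE])
    a, b = cfg.allele_frequency_prior
    truth = SimTruth(architecture=cfg.architecture)

    sex_linked: dict[str, np.ndarray] = {}
    if cfg.architecture in ("xy_region", "zw_region"):
        chrom, start, end = cfg.resolved_region()
        truth.region = (chrom, start, end)
        hits = np.flatnonzero(rng.random(end - start) < cfg.gametolog_divergence)
        sex_linked[chrom] = start + hits  # 0-based
        pattern = "XY" if cfg.architecture == "xy_region" else "ZW"
        truth.sex_linked_snps = [(chrom, int(p) + 1, pattern) for p in sex_linked[chrom]]

    poly: dict[str, list[int]] = {}
    if cfg.architecture == "polygenic":
        chroms = cfg.chromosome_names()
        for _ in range(cfg.polygenic_loci):
            c = chroms[rng.integers(0, len(chroms))]
            p = int(rng.integers(0, cfg.chromosome_length_bp))
            poly.setdefault(c, []).append(p)
            truth.polygenic.append((c, p + 1))

    chrom_arr, pos_arr, ref_codes, alt_codes, gt_blocks = [], [], [], [], []
    het_idx = male_idx if cfg.heterogametic_sex == MALE else female_idx
    for c in cfg.chromosome_names():
        bg = np.flatnonzero(rng.random(cfg.chromosome_length_bp) < cfg.snp_density)
        planted_sl = np.asarray(sex_linked.get(c, []), dtype=np.int64)
        planted_poly = np.asarray(sorted(poly.get(c, ())), dtype=np.int64)
        planted = set(planted_sl.tolist()) | set(planted_poly.tolist())
        bg = bg[~np.isin(bg, list(planted))] if planted else bg

        kinds = np.concatenate([
            np.zeros(len(bg), np.int8),
            np.ones(len(planted_sl), np.int8),
            np.full(len(planted_poly), 2, np.int8),
        ])
        pos0 = np.concatenate([bg, planted_sl, planted_poly])
        order = np.argsort(pos0, kind="stable")
        pos0, kinds = pos0[order], kinds[order]
        m = len(pos0)
        if m == 0:
            continue

        g = np.zeros((m, n_ind, 2), dtype=np.int8)
        is_bg = kinds == 0
        n_bg = int(is_bg.sum())
        if n_bg:
            freq = rng.beta(a, b, size=n_bg)
            g[is_bg] = (rng.random((n_bg, n_ind, 2)) < freq[:, None, None]).astype(np.int8)
        is_sl = kinds == 1
        if is_sl.any() and len(het_idx):
            # heterogametic sex heterozygous, other sex homozygous reference
            g[np.ix_(np.flatnonzero(is_sl), het_idx, [1])] = 1
        is_poly = kinds == 2
        if is_poly.any():
            pen = cfg.polygenic_penetrance
            rows = np.flatnonzero(is_poly)
            het_m = rng.random((len(rows), len(male_idx))) < pen
            het_f = rng.random((len(rows), len(female_idx))) < (1 - pen)
            for r, hm, hf in zip(rows, het_m, het_f):
                g[r, male_idx[hm], 1] = 1
                g[r, female_idx[hf], 1] = 1

        ref = (
            genome[c][pos0].copy() if genome is not None
            else _BASES[rng.integers(0, 4, size=m)]
        )
        base_idx = np.searchsorted(_BASES, ref)
        alt = _BASES[(base_idx + rng.integers(1, 4, size=m)) % 4]
        chrom_arr.append(np.full(m, c, dtype=object))
        pos_arr.append(pos0 + 1)
        ref_codes.append(ref)
        alt_codes.append(alt)
        gt_blocks.append(g)

    if chrom_arr:
        chroms = np.concatenate(chrom_arr)
        positions = np.concatenate(pos_arr)
        refs = np.array([chr(x) for x in np.concatenate(ref_codes)], dtype=object)
        alts = [(chr(x),) for x in np.concatenate(alt_codes)]
        genotypes = np.concatenate(gt_blocks)
    else:
        chroms = np.array([], dtype=object)
        positions = np.array([], dtype=np.int64)
        refs = np.array([], dtype=object)
        alts = []
        genotypes = np.empty((0, n_ind, 2), np.int8)
    table = VariantTable(chroms, positions, refs, alts, genotypes, specimens)
    return table, truth, sex_linked


def _insertion_scaffolds(cfg: SimConfig, truth: SimTruth) -> list[tuple[str, np.ndarray]]:
    rng = _rng(cfg, 3)
    carrier = cfg.heterogametic_sex
    tag = "Yins" if carrier == MALE else "Wins"
    scaffolds = []
    for i in range(cfg.n_insertions):
        seq = _BASES[rng.integers(0, 4, size=cfg.insertion_length_bp)]
        name = f"{tag}_{i + 1}"
        scaffolds.append((name, seq))
        truth.insertions.append({
            "scaffold": name,
            "length": cfg.insertion_length_bp,
            "carrier_sex": carrier,
            "sequence": seq.tobytes().decode(),
        })
    return scaffolds


def _simulate_depth(cfg: SimConfig, specimens, sex_linked, insertions):
    """Two depth matrices: all-reads and strict mismatch-free mapping.

    Strict mode models the loss of heterogametic-sex reads over a diverged
    region: a read from the diverged gametolog survives mismatch-free mapping
    only if its whole span carries no divergent site, so the per-site mean for
    the heterogametic sex becomes mean*(1+(1-d)^L)/2 across the region and
    exactly mean/2 at the divergent sites themselves.
    """
    n_ind = len(specimens)
    het_cols = np.array([i for i, s in enumerate(specimens) if s.sex == cfg.heterogametic_sex]) \
        if cfg.heterogametic_sex else np.array([], dtype=int)
    opp_cols = np.array([i for i in range(n_ind) if i not in set(het_cols.tolist())])

    region = cfg.resolved_region() if cfg.architecture in ("xy_region", "zw_region") else None
    survival = (1.0 - cfg.gametolog_divergence) ** cfg.read_length_bp

    def one_track(rng: np.random.Generator, strict: bool) -> DepthMatrix:
        depth: dict[str, np.ndarray] = {}
        for c in cfg.chromosome_names():
            L = cfg.chromosome_length_bp
            arr = rng.poisson(cfg.mean_depth, size=(L, n_ind)).astype(np.int16)
            if strict and region is not None and region[0] == c and len(het_cols):
                _, s, e = region
                reduced = cfg.mean_depth * (1.0 + survival) / 2.0
                block = np.ix_(np.arange(s, e), het_cols)
                arr[block] = rng.poisson(reduced, size=(e - s, len(het_cols)))
                div = sex_linked.get(c, np.array([], dtype=int))
                if len(div):
                    arr[np.ix_(div, het_cols)] = rng.poisson(
                        cfg.mean_depth / 2.0, size=(len(div), len(het_cols))
                    )
            depth[c] = arr
        for name, seq in insertions:
            L = len(seq)
            ins = np.zeros((L, n_ind), dtype=np.int16)
            if len(het_cols):
                # hemizygous: reads come from one haplotype only
                ins[:, het_cols] = rng.poisson(cfg.mean_depth / 2.0, size=(L, len(het_cols)))
            depth[name] = ins
        return DepthMatrix(depth, specimens)

    depth_all = one_track(_rng(cfg, 4), strict=False) if "all" in cfg.depth_tracks else None
    strict_on = cfg.strict_mapping_mode
    depth_strict = (
        one_track(_rng(cfg, 5), strict=strict_on) if "strict" in cfg.depth_tracks else None
    )
    return depth_all, depth_strict


_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for x, y in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[x] = y


def _haplotypes(cfg, specimen_index, specimen, genome, genotypes, sex_linked, insertions):
    """The two haplotype sequences of one individual, as uint8 arrays."""
    v = genotypes
    col = v.genotypes[:, specimen_index, :]
    haps = []
    for h in (0, 1):
        hap_chroms = {}
        for c in cfg.chromosome_names():
            seq = genome[c].copy()
            on_c = np.flatnonzero((v.chrom == c) & (col[:, h] == 1))
            for i in on_c:
                alt = v.alts[i][0]
                seq[v.pos[i] - 1] = ord(alt)
            hap_chroms[c] = seq
        haps.append(hap_chroms)
    extra = []
    if specimen.sex == cfg.heterogametic_sex and insertions:
        extra = [(name, seq) for name, seq in insertions]
    return haps, extra


def _reads_for_specimen(cfg, rng, haps, extra):
    L = cfg.read_length_bp
    reads: list[str] = []
    sources = []
    for h, hap_chroms in enumerate(haps):
        for c, seq in hap_chroms.items():
            sources.append(seq)
        if h == 1:  # insertions ride on the second (Y/W) haplotype
            for _, seq in extra:
                sources.append(seq)
    for seq in sources:
        if len(seq) < L:
            continue
        n_reads = rng.poisson(cfg.mean_depth / 2.0 * len(seq) / L)
        starts = rng.integers(0, len(seq) - L + 1, size=n_reads)
        n_err = rng.binomial(L, cfg.read_error_rate, size=n_reads)
        for s, ne in zip(starts, n_err):
            r = seq[s:s + L]
            if ne:
                r = r.copy()
                pos = rng.integers(0, L, size=ne)
                r[pos] = _BASES[(rng.integers(1, 4, size=ne) +
                                 np.searchsorted(_BASES, r[pos])) % 4]
            reads.append(r.tobytes().decode())
    return reads


def simulate_population(cfg: SimConfig) -> SimResult:
    """Generate one synthetic population under the configured architecture."""
    cfg.validate()
    specimens = (
        [Specimen(f"m{i + 1}", MALE, cfg.population) for i in range(cfg.n_males)]
        + [Specimen(f"f{i + 1}", FEMALE, cfg.population) for i in range(cfg.n_females)]
    )
    genome = _random_genome(cfg) if cfg.with_sequences else None
    genotypes, truth, sex_linked = _simulate_variants(cfg, specimens, genome)

    insertions: list[tuple[str, np.ndarray]] = []
    if cfg.architecture in ("y_insertion", "w_insertion"):
        insertions = _insertion_scaffolds(cfg, truth)

    depth_all, depth_strict = _simulate_depth(cfg, specimens, sex_linked, insertions)

    assemblies: dict[str, list[tuple[str, str]]] = {}
    reads: dict[str, list[str]] = {}
    if cfg.with_sequences:
        base = [(c, genome[c].tobytes().decode()) for c in cfg.chromosome_names()]
        assemblies = {MALE: list(base), FEMALE: list(base)}
        carrier = cfg.heterogametic_sex
        if insertions and carrier:
            assemblies[carrier] = base + [(n, s.tobytes().decode()) for n, s in insertions]
        for idx, s in enumerate(specimens):
            rng = _rng(cfg, 100 + idx)
            haps, extra = _haplotypes(cfg, idx, s, genome, genotypes, sex_linked, insertions)
            reads[s.id] = _reads_for_specimen(cfg, rng, haps, extra)

    return SimResult(specimens, genotypes, depth_all, depth_strict, assemblies, reads, truth, cfg)


def write_sim_bundle(result: SimResult, directory: str | os.PathLike) -> dict:
    """Write all simulated files and return a manifest of paths plus the seed."""
    d = os.fspath(directory)
    os.makedirs(d, exist_ok=True)
    paths = {
        "samples": os.path.join(d, "samples.csv"),
        "vcf": os.path.join(d, "variants.vcf"),
        "truth": os.path.join(d, "truth.json"),
    }
    write_sample_sheet(result.specimens, paths["samples"])
    for name, mat in (("depth_all", result.depth_all), ("depth_strict", result.depth_strict)):
        if mat is not None:
            paths[name] = os.path.join(d, f"{name}.tsv.gz")
            write_depth(mat, paths[name])
    write_vcf(result.genotypes, paths["vcf"])
    with open(paths["truth"], "w") as fh:
        fh.write(result.truth.to_json())
    for sex, scaffolds in result.assemblies.items():
        p = os.path.join(d, f"assembly_{sex}.fasta")
        with open(p, "w") as fh:
            for name, seq in scaffolds:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        paths[f"assembly_{sex}"] = p
    if result.reads:
        rd = os.path.join(d, "reads")
        os.makedirs(rd, exist_ok=True)
        for sid, rr in result.reads.items():
            p = os.path.join(rd, f"{sid}.fastq")
            with open(p, "w") as fh:
                for i, r in enumerate(rr):
                    fh.write(f"@{sid}.{i}\n{r}\n+\n{'I' * len(r)}\n")
            paths[f"reads_{sid}"] = p
    manifest = {"seed": result.config.seed, "architecture": result.config.architecture,
                "paths": paths}
    with open(os.path.join(d, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
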