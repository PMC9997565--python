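"""Reference-free heterogamety detection from prefix-sampled k-mer catalogs.

Per population, every AG-prefixed 37-mer of each specimen's reads (both
strands, no canonical collapsing — the prefix samples 1/16 of k-mer space) is
counted; k-mers seen in fewer than five specimens are dropped. An ordinary
least-squares regression of the female total count on the male total count
identifies outlier k-mers by externally studentized (jack-knifed) residual
|r| ≥ 3; outliers are categorized as Y (male-specific), W (female-specific),
X (female-biased beyond a ratio threshold) or Z (male-biased). A rank-sum test
on the per-k-mer coverage of the Y versus W sets calls the heterogametic
system, and catalogs can be intersected across populations.
"""

from __future__ import annotations

import itertools
import os
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import FEMALE, MALE, Specimen


@dataclass
class KmerCatalog:
    """AG-prefixed fixed-length k-mer counts per specimen."""

    k: int
    prefix: str
    kmers: list[str]
    counts: np.ndarray  # (n_kmers, n_specimens)
    specimens: list[Specimen]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.kmers), len(self.specimens)):
            raise ValueError("count matrix shape mismatch")

    @property
    def n_kmers(self) -> int:
        return len(self.kmers)

    @property
    def n_specimens_present(self) -> np.ndarray:
        return (self.counts > 0).sum(axis=1)

    def _sex_cols(self, sex: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.specimens) if s.sex == sex], dtype=int)

    @property
    def sum_m(self) -> np.ndarray:
        return self.counts[:, self._sex_cols(MALE)].sum(axis=1)

    @property
    def sum_f(self) -> np.ndarray:
        return self.counts[:, self._sex_cols(FEMALE)].sum(axis=1)


@dataclass
class KmerCalls:
    """Regression residuals and Y/W/X/Z category labels for a catalog."""

    catalog: KmerCatalog
    studentized_residual: np.ndarray
    outlier: np.ndarray
    category: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.category is None:
            self.category = np.full(self.catalog.n_kmers, "none", dtype=object)

    def kmers_in_category(self, cat: str) -> set[str]:
        return {k for k, c in zip(self.catalog.kmers, self.category) if c == cat}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "kmer": self.catalog.kmers,
            "sum_m": self.catalog.sum_m,
            "sum_f": self.catalog.sum_f,
            "studentized_residual": self.studentized_residual,
            "outlier": self.outlier,
            "category": self.category,
        })


_RC_TABLE = bytes.maketrans(b"ACGTN", b"TGCAN")


def _scan_sequences(seqs, k: int, prefix: str) -> Counter:
    """Count prefix-anchored k-length windows of sequences and their reverse
    complements; windows containing N are skipped."""
    counts: Counter = Counter()
    pb = prefix.encode()
    plen = len(pb)
    for seq in seqs:
        b = seq.upper().encode() if isinstance(seq, str) else seq.upper()
        for strand in (b, b[::-1].translate(_RC_TABLE)):
            start = strand.find(pb)
            while start != -1:
                if start + k <= len(strand):
                    window = strand[start:start + k]
                    if b"N" not in window:
                        counts[window] += 1
                start = strand.find(pb, start + 1)
    return counts


def build_kmer_catalog(
    reads_by_specimen: dict[str, "list[str]"],
    specimens: list[Specimen],
    k: int = 37,
    prefix: str = "AG",
    min_specimens: int = 5,
) -> KmerCatalog:
    """Count AG-prefixed k-mers per specimen and drop rare entries.

    ``reads_by_specimen`` maps specimen id to an iterable of read sequences
    (use :func:`read_fastq_sequences` for files). Both strands are scanned;
    entries present in fewer than ``min_specimens`` specimens are removed.
    """
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    if len(prefix) > k:
        raise ValueError("prefix longer than k")
    if len(specimens) < min_specimens:
        raise ValueError(
            f"need at least {min_specimens} specimens, got {len(specimens)}"
        )
    index: dict[bytes, int] = {}
    per_specimen: list[Counter] = []
    for s in specimens:
        c = _scan_sequences(reads_by_specimen.get(s.id, ()), k, prefix)
        per_specimen.append(c)
        for km in c:
            index.setdefault(km, len(index))
    counts = np.zeros((len(index), len(specimens)), dtype=np.int64)
    for j, c in enumerate(per_specimen):
        for km, n in c.items():
            counts[index[km], j] = n
    kmers = [km.decode() for km in index]
    present = (counts > 0).sum(axis=1)
    keep = present >= min_specimens
    order = np.flatnonzero(keep)
    return KmerCatalog(k, prefix, [kmers[i] for i in order], counts[order], list(specimens))


def read_fastq_sequences(path: str | os.PathLike) -> list[str]:
    """Sequences from a FASTA/FASTQ file (format by extension)."""
    from Bio import SeqIO

    p = os.fspath(path)
    fmt = "fastq" if p.endswith((".fastq", ".fq")) else "fasta"
    return [str(rec.seq) for rec in SeqIO.parse(p, fmt)]


def regression_outliers(
    catalog: KmerCatalog, residual_threshold: float = 3.0, log_counts: bool = False
) -> KmerCalls:
    """Externally studentized residuals of sum_f regressed on sum_m.

    An entry is an outlier when its leave-one-out (jack-knifed) studentized
    residual has absolute value at or above ``residual_threshold``.
    """
    import statsmodels.api as sm

    if catalog.n_kmers < 10:
        raise ValueError("need at least 10 catalog entries for the regression")
    x = catalog.sum_m.astype(float)
    y = catalog.sum_f.astype(float)
    if log_counts:
        x, y = np.log1p(x), np.log1p(y)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in male counts; regression undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid = model.get_influence().resid_studentized_external
    resid = np.nan_to_num(resid, nan=0.0)
    return KmerCalls(catalog, resid, np.abs(resid) >= residual_threshold)


def categorize_kmers(
    calls: KmerCalls,
    ratio_threshold: float = 4.0,
    z_ratio_threshold: float | None = None,
) -> KmerCalls:
    """Assign Y/W/X/Z categories among regression outliers.

    Y: female total zero, male positive; W: mirrored. X: female/male ratio
    above ``ratio_threshold`` (both positive); Z: male/female ratio above
    ``z_ratio_threshold`` (defaults to ``ratio_threshold``; a stricter value
    compensates for an unbalanced sex ratio in the sample, as with the 12×
    threshold used for a female-poor population). Categories are mutually
    exclusive; non-outliers stay "none".
    """
    zt = ratio_threshold if z_ratio_threshold is None else z_ratio_threshold
    sm_, sf = calls.catalog.sum_m, calls.catalog.sum_f
    cat = np.full(calls.catalog.n_kmers, "none", dtype=object)
    out = calls.outlier
    y_mask = out & (sf == 0) & (sm_ > 0)
    w_mask = out & (sm_ == 0) & (sf > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_mask = out & (sm_ > 0) & (sf > 0) & (sf / sm_ > ratio_threshold)
        z_mask = out & (sm_ > 0) & (sf > 0) & (sm_ / sf > zt) & ~x_mask
    cat[z_mask] = "Z"
    cat[x_mask] = "X"
    cat[w_mask] = "W"
    cat[y_mask] = "Y"
    return KmerCalls(calls.catalog, calls.studentized_residual, calls.outlier, cat)


def heterogamety_test(calls: KmerCalls, alpha: float = 0.05, min_one_sided: int = 20) -> dict:
    """Call the heterogametic system from Y- vs W-k-mer coverage.

    Coverage of a sex-specific k-mer is its total count in the sex that
    carries it (sum_m for Y, sum_f for W). A two-sided rank-sum test compares
    the two coverage sets; the verdict is XY when Y coverage is significantly
    higher (median), ZW when W wins, undetermined otherwise. With one empty
    set the verdict goes to the nonempty set if it holds at least
    ``min_one_sided`` k-mers (no p-value).
    """
    cov_y = calls.catalog.sum_m[calls.category == "Y"]
    cov_w = calls.catalog.sum_f[calls.category == "W"]
    n_y, n_w = len(cov_y), len(cov_w)
    if n_y + n_w == 0:
        raise ValueError("no sex-specific k-mers; heterogamety test undefined")
    med_y = float(np.median(cov_y)) if n_y else np.nan
    med_w = float(np.median(cov_w)) if n_w else np.nan
    result = {
        "n_Y": n_y, "n_W": n_w,
        "median_cov_Y": med_y, "median_cov_W": med_w,
        "p_value": None, "verdict": "undetermined",
    }
    if n_y == 0 or n_w == 0:
        if n_y >= min_one_sided:
            result["verdict"] = "XY"
        elif n_w >= min_one_sided:
            result["verdict"] = "ZW"
        return result
    exact = min(n_y, n_w) <= 20 and len(np.intersect1d(cov_y, cov_w)) == 0
    method = "exact" if exact else "asymptotic"
    p = float(stats.mannwhitneyu(cov_y, cov_w, alternative="two-sided", method=method).pvalue)
    result["p_value"] = p
    if p < alpha:
        result["verdict"] = "XY" if med_y > med_w else "ZW" if med_w > med_y else "undetermined"
    return result


def kmer_intersections(
    calls_by_population: dict[str, KmerCalls],
    categories: tuple[str, ...] = ("Y", "W", "X", "Z"),
) -> dict:
    """Cross-population k-mer set intersections, UpSet style.

    Returns per-category population sets' sizes, exclusive intersection
    cardinalities for every population combination, pairwise overlap counts,
    and cross-category pairwise overlaps (e.g. Y in one population vs W in
    another).
    """
    if len(calls_by_population) < 2:
        raise ValueError("need at least 2 populations to intersect")
    pops = sorted(calls_by_population)
    sets = {
        cat: {p: calls_by_population[p].kmers_in_category(cat) for p in pops}
        for cat in categories
    }
    result: dict = {"set_sizes": {}, "exclusive": {}, "pairwise": {}, "cross_category": {}}
    for cat in categories:
        result["set_sizes"][cat] = {p: len(sets[cat][p]) for p in pops}
        exclusive = {}
        for r in range(1, len(pops) + 1):
            for combo in itertools.combinations(pops, r):
                inter = set.intersection(*(sets[cat][p] for p in combo))
                for other in pops:
                    if other not in combo:
                        inter = inter - sets[cat][other]
                if inter:
                    exclusive[combo] = len(inter)
        result["exclusive"][cat] = exclusive
        result["pairwise"][cat] = {
            (a, b): len(sets[cat][a] & sets[cat][b])
            for a, b in itertools.combinations(pops, 2)
        }
    for ca, cb in itertools.combinations(categories, 2):
        for a in pops:
            for b in pops:
                if a != b:
                    n = len(sets[ca][a] & sets[cb][b])
                    if n:
                        result["cross_category"][(ca, a, cb, b)] = n
    return result
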