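"""Sex-limited region (SSR) calling from read depth over per-sex assemblies.

A sex-limited region is a maximal run of assembly positions where every
individual of the sex opposite to the assembly has zero mapped depth, at most
one individual of the assembly's own sex is entirely uncovered across the run,
and the run is at least ``min_length`` bp long. Region calls are summarized per
(assembly sex, population) with exact (Garwood) Poisson confidence intervals on
the number of scaffolds carrying at least one region, and candidate marker
sequences can be screened against assemblies by exact two-strand substring
search.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .core_io import FEMALE, MALE, DepthMatrix


@dataclass
class SexLimitedRegion:
    """Maximal opposite-sex-zero run on an assembly scaffold (0-based, half-open)."""

    scaffold: str
    start: int
    end: int
    assembly_sex: str
    n_same_sex_zero: int
    flank_sequence: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def _zero_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean vector, as (start, end) half-open."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def call_sex_limited_regions(
    d: DepthMatrix,
    assembly_sex: str,
    min_length: int = 500,
    max_same_sex_zero: int = 1,
) -> list[SexLimitedRegion]:
    """Call maximal runs with zero opposite-sex depth in every individual.

    Runs shorter than ``min_length`` are discarded, as are runs where more
    than ``max_same_sex_zero`` assembly-sex individuals have zero depth over
    the whole run (assembly-sex dropout tolerance). Output is sorted by
    (scaffold, start); each region is maximal by construction.
    """
    if assembly_sex not in (MALE, FEMALE):
        raise ValueError(f"assembly_sex must be male/female, got {assembly_sex!r}")
    opposite = FEMALE if assembly_sex == MALE else MALE
    opp_cols = d.sex_columns(opposite)
    same_cols = d.sex_columns(assembly_sex)
    if len(opp_cols) == 0:
        raise ValueError(f"no {opposite} individuals in depth matrix")
    regions = []
    for scaffold in d.chromosomes:
        arr = d.depth[scaffold]
        opp_zero = (arr[:, opp_cols] == 0).all(axis=1)
        for s, e in _zero_runs(opp_zero):
            if e - s < min_length:
                continue
            n_zero = int((arr[s:e][:, same_cols] == 0).all(axis=0).sum())
            if n_zero > max_same_sex_zero:
                continue
            regions.append(SexLimitedRegion(scaffold, s, e, assembly_sex, n_zero))
    regions.sort(key=lambda r: (r.scaffold, r.start))
    return regions


def extract_flank(
    region: SexLimitedRegion, scaffold_sequences: dict[str, str], total_length: int = 5000
) -> str:
    """Extend a region symmetrically into its flanks to ``total_length`` bp.

    Truncation at a scaffold end shifts the remaining extension to the other
    side, so the full target length is reached whenever the scaffold permits;
    a scaffold shorter than the target is returned whole. Regions already at
    or above the target length are returned unextended.
    """
    try:
        seq = scaffold_sequences[region.scaffold]
    except KeyError:
        raise ValueError(f"scaffold {region.scaffold!r} absent from assembly") from None
    L = len(seq)
    if L <= total_length:
        return seq
    if region.length >= total_length:
        return seq[region.start:region.end]
    extra = total_length - region.length
    left = region.start - extra // 2
    right = region.end + (extra - extra // 2)
    if left < 0:
        right = min(L, right - left)
        left = 0
    if right > L:
        left = max(0, left - (right - L))
        right = L
    return seq[left:right]


def load_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Scaffold name -> uppercase sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def poisson_exact_ci(k: int, confidence: float = 0.95) -> tuple[float, float]:
    """Garwood exact Poisson CI from chi-square quantiles.

    low = χ²(α/2; 2k)/2 (0 for k = 0), high = χ²(1−α/2; 2k+2)/2.
    """
    if k < 0:
        raise ValueError(f"count must be non-negative, got {k}")
    alpha = 1.0 - confidence
    low = 0.0 if k == 0 else 0.5 * chi2.ppf(alpha / 2.0, 2 * k)
    high = 0.5 * chi2.ppf(1.0 - alpha / 2.0, 2 * k + 2)
    return float(low), float(high)


def summarize_ssr(
    regions_by_group: dict[tuple[str, str], list[SexLimitedRegion]],
    assembly_scaffold_counts: dict[tuple[str, str], int] | None = None,
    confidence: float = 0.95,
) -> tuple[pd.DataFrame, float]:
    """Per-(assembly sex, population) SSR counts with exact Poisson CIs.

    ``regions_by_group`` maps (assembly_sex, population) to called regions.
    Returns the summary table plus the grand mean of per-group region counts
    (1 decimal), the headline sharing statistic of the scan.
    """
    rows = []
    for (sex, population), regions in regions_by_group.items():
        n_ssr = len(regions)
        n_scaf = len({r.scaffold for r in regions})
        lo, hi = poisson_exact_ci(n_scaf, confidence)
        rows.append({
            "assembly_sex": sex,
            "population": population,
            "n_scaffolds_in_assembly": (assembly_scaffold_counts or {}).get((sex, population)),
            "n_ssr": n_ssr,
            "n_scaffolds_with_ssr": n_scaf,
            "ci_low": round(lo, 2),
            "ci_high": round(hi, 2),
        })
    table = pd.DataFrame(rows)
    grand_mean = round(float(table["n_ssr"].mean()), 1) if len(table) else 0.0
    return table, grand_mean


_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], haystack.find(needle)
    while start != -1:
        hits.append(start)
        start = haystack.find(needle, start + 1)
    return hits


def screen_markers(
    markers: dict[str, str], assembly: dict[str, str]
) -> pd.DataFrame:
    """Exact two-strand substring search of markers against assembly scaffolds.

    Returns one row per marker with presence and all match locations
    (scaffold, 0-based start, strand); multiple matches are reported.
    """
    rows = []
    for name, seq in markers.items():
        if not seq:
            raise ValueError(f"marker {name!r} is empty")
        seq = seq.upper()
        rc = reverse_complement(seq)
        locations = []
        for scaffold, s in assembly.items():
            for start in _find_all(s, seq):
                locations.append((scaffold, start, "+"))
            for start in _find_all(s, rc):
                locations.append((scaffold, start, "-"))
        rows.append({
            "marker": name,
            "present": bool(locations),
            "n_matches": len(locations),
            "locations": locations,
        })
    return pd.DataFrame(rows)


def group_flank_sequences(flanks: dict[str, str]) -> list[list[str]]:
    """Group flank sequences by exact duplication or containment (either strand).

    A lightweight stand-in for cross-population redundancy collapsing: two
    sequences share a group when one contains the other exactly on either
    strand. Groups are returned as lists of flank names.
    """
    names = sorted(flanks, key=lambda n: -len(flanks[n]))
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(names):
        sa = flanks[a]
        sa_rc = reverse_complement(sa)
        for b in names[i + 1:]:
            sb = flanks[b]
            if sb in sa or sb in sa_rc:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    groups: dict[str, list[str]] = {}
    for n in names:
        groups.setdefault(find(n), []).append(n)
    return sorted(groups.values(), key=lambda g: (-len(g), g[0]))
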