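"""Intersex coverage-differential scan.

The scan works on per-position depth over an assembly: per-site per-sex median
depth is normalized by that sex's genome-wide median, windows summarize the
male:female normalized-coverage ratio and difference, windows in the extreme
tails of the genome-wide ratio distribution with a difference above a floor are
flagged, flagged windows receive a paired two-sided Wilcoxon signed-rank test
(exact for small windows) with a Hodges–Lehmann 95% confidence interval, and a
per-chromosome one-sided Fisher exact test with Bonferroni correction measures
enrichment of significant windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import FEMALE, MALE, DepthMatrix, GenomeIndex, Window


@dataclass
class NormalizedTracks:
    """Per-sex per-site median depth, normalized within each sex.

    ``med_m/med_f`` are medians of raw depth across specimens of each sex;
    ``norm_m/norm_f`` divide them by the sex's genome-wide median of site
    medians, so a global sequencing-effort difference between sexes cancels.
    """

    med_m: dict[str, np.ndarray]
    med_f: dict[str, np.ndarray]
    norm_m: dict[str, np.ndarray]
    norm_f: dict[str, np.ndarray]
    genome_median_m: float
    genome_median_f: float

    @property
    def chromosomes(self) -> list[str]:
        return list(self.norm_m)

    def log2(self, sex: str, chrom: str) -> np.ndarray:
        """log2 normalized track for plotting; zero coverage maps to NaN."""
        norm = (self.norm_m if sex == MALE else self.norm_f)[chrom]
        out = np.full(norm.shape, np.nan)
        nz = norm > 0
        out[nz] = np.log2(norm[nz])
        return out


def normalize_depth(d: DepthMatrix) -> NormalizedTracks:
    """Per-site per-sex median depth divided by the sex's genome-wide median."""
    mcols, fcols = d.sex_columns(MALE), d.sex_columns(FEMALE)
    if len(mcols) < 2 or len(fcols) < 2:
        raise ValueError("need at least 2 specimens per sex")
    med_m, med_f = {}, {}
    for c, arr in d.depth.items():
        med_m[c] = np.median(arr[:, mcols], axis=1).astype(np.float32)
        med_f[c] = np.median(arr[:, fcols], axis=1).astype(np.float32)
    gm = float(np.median(np.concatenate(list(med_m.values()))))
    gf = float(np.median(np.concatenate(list(med_f.values()))))
    if gm <= 0 or gf <= 0:
        raise ValueError("genome-wide median depth is zero for one sex")
    norm_m = {c: v / gm for c, v in med_m.items()}
    norm_f = {c: v / gf for c, v in med_f.items()}
    return NormalizedTracks(med_m, med_f, norm_m, norm_f, gm, gf)


def window_coverage_stats(
    tracks: NormalizedTracks,
    windows: list[Window],
    epsilon: float = 0.01,
    site_ratio: bool = True,
) -> pd.DataFrame:
    """Per-window median male:female coverage ratio and difference.

    ``ratio`` is the median over sites of (norm_m+eps)/(norm_f+eps) with sites
    where both norms are zero excluded (``site_ratio=False`` uses the ratio of
    window medians instead); ``diff`` is the median over all sites of
    norm_m − norm_f. Windows without a usable site get NaN statistics.
    """
    rows = []
    for w in windows:
        nm = tracks.norm_m[w.chromosome][w.start:w.end]
        nf = tracks.norm_f[w.chromosome][w.start:w.end]
        usable = ~((nm == 0) & (nf == 0))
        n_sites = int(usable.sum())
        if n_sites == 0:
            ratio = np.nan
        elif site_ratio:
            ratio = float(np.median((nm[usable] + epsilon) / (nf[usable] + epsilon)))
        else:
            ratio = float(
                (np.median(nm[usable]) + epsilon) / (np.median(nf[usable]) + epsilon)
            )
        diff = float(np.median(nm - nf)) if len(nm) else np.nan
        rows.append((w.chromosome, w.start, w.end, n_sites, ratio, diff))
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "n_sites", "ratio", "diff"])
    df["outlier"] = False
    df["p_value"] = np.nan
    df["ci_low"] = np.nan
    df["ci_high"] = np.nan
    df["significant"] = False
    return df


def detect_outlier_windows(
    ws: pd.DataFrame, quantile: float = 0.99, min_diff: float = 0.25
) -> pd.DataFrame:
    """Flag windows whose ratio is outside the central ``quantile`` interval
    of the genome-wide window-ratio distribution AND whose |diff| > min_diff.

    Both tails are flagged: reduced heterogametic-sex coverage (X-like) and
    reduced homogametic-sex coverage (Z-like) windows.
    """
    ws = ws.copy()
    ratios = ws["ratio"].dropna().to_numpy()
    if len(ratios) == 0:
        return ws
    tail = (1.0 - quantile) / 2.0 * 100.0
    lo, hi = np.percentile(ratios, [tail, 100.0 - tail])
    # inclusive bounds: a block of tied extreme ratios sitting exactly on the
    # percentile still counts as outside; the diff floor keeps nulls quiet
    flag = (
        ws["ratio"].notna()
        & ((ws["ratio"] <= lo) | (ws["ratio"] >= hi))
        & (ws["diff"].abs() > min_diff)
    )
    ws["outlier"] = flag.to_numpy()
    return ws


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with an exact (tie-aware) small-sample null


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of sign assignments per positive-rank-sum, for doubled ranks.

    Midranks are half-integers, so doubling makes them integers; the null
    assigns each rank a + or − sign independently with probability 1/2.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def _midranks(absd: np.ndarray) -> np.ndarray:
    return stats.rankdata(absd)


def signed_rank_exact_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p over all 2^n sign assignments.

    Zero differences must already be removed; ties are handled with midranks
    (the permutation null conditions on the observed |differences|).
    """
    d = np.asarray(diffs, dtype=float)
    ranks2 = np.round(2.0 * _midranks(np.abs(d))).astype(int)
    w_pos = int(ranks2[d > 0].sum())
    dist = _signed_rank_distribution(ranks2)
    total = dist.sum()
    cdf = dist[: w_pos + 1].sum() / total
    sf = dist[w_pos:].sum() / total
    return float(min(1.0, 2.0 * min(cdf, sf)))


def _signed_rank_normal_p(diffs: np.ndarray) -> float:
    """Normal approximation with tie correction (no continuity correction)."""
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    ranks = _midranks(np.abs(d))
    w_pos = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    _, t = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (t**3 - t).sum() / 48.0
    if var <= 0:
        return 1.0
    z = (w_pos - mu) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wilcoxon_signed_rank_p(diffs: np.ndarray, max_exact: int = 25) -> float:
    """Two-sided paired Wilcoxon p, exact for n ≤ max_exact nonzero pairs."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        return np.nan
    if len(d) <= max_exact:
        return signed_rank_exact_p(d)
    return _signed_rank_normal_p(d)


def _count_walsh_le(ds: np.ndarray, t: float) -> int:
    """Number of Walsh averages (d_i+d_j)/2, i<=j, at most t (ds sorted)."""
    # j-range per i via searchsorted: pairs i<=j<idx[i] satisfy d_i+d_j <= 2t
    idx = np.searchsorted(ds, 2.0 * t - ds, side="right")
    return int(np.maximum(idx - np.arange(len(ds)), 0).sum())


def _kth_walsh(ds: np.ndarray, k: int) -> float:
    """k-th smallest Walsh average (1-based) via value-space bisection."""
    n = len(ds)
    m = n * (n + 1) // 2
    k = min(max(k, 1), m)
    if m <= 500_000:
        i, j = np.triu_indices(n)
        avgs = np.sort((ds[i] + ds[j]) / 2.0)
        return float(avgs[k - 1])
    lo, hi = float(ds[0]), float(ds[-1])
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _count_walsh_le(ds, mid) >= k:
            hi = mid
        else:
            lo = mid
    return hi


def hodges_lehmann_ci(
    diffs: np.ndarray, alpha: float = 0.05, max_exact: int = 25
) -> tuple[float, float, float]:
    """Hodges–Lehmann estimate and (1-alpha) CI of the paired location shift.

    The CI trims k Walsh averages from each end, k from the exact signed-rank
    null for small n and from its normal approximation otherwise.
    """
    d = np.sort(np.asarray(diffs, dtype=float))
    n = len(d)
    m = n * (n + 1) // 2
    if n == 0:
        return np.nan, np.nan, np.nan
    if n <= max_exact:
        ranks2 = 2 * np.arange(1, n + 1)
        dist = _signed_rank_distribution(ranks2)
        cdf = np.cumsum(dist) / dist.sum()
        qualifying = np.flatnonzero(cdf <= alpha / 2.0)
        # doubled-scale sum -> rank-sum scale
        k = int(qualifying.max() // 2) if len(qualifying) else -1
    else:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        k = int(np.floor(m / 2.0 - z * np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)))
    k = int(np.clip(k, -1, m // 2 - 1))
    est = _kth_walsh(d, (m + 1) // 2) if m % 2 else 0.5 * (
        _kth_walsh(d, m // 2) + _kth_walsh(d, m // 2 + 1)
    )
    # CI = (A_(k+1), A_(m-k)) with P(W+ <= k) <= alpha/2
    low = _kth_walsh(d, max(k + 1, 1))
    high = _kth_walsh(d, min(m - k, m))
    return float(est), float(low), float(high)


def test_windows(
    ws: pd.DataFrame,
    tracks: NormalizedTracks,
    alpha: float = 0.05,
    min_pairs: int = 6,
    max_exact: int = 25,
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank test of norm_m vs norm_f for flagged windows.

    Pairs are the per-site (norm_m, norm_f) values; zero differences are
    discarded for the test. Windows with fewer than ``min_pairs`` nonzero
    differences get no p-value and are never significant. A Hodges–Lehmann
    95% CI of the median paired difference is attached to tested windows.
    """
    ws = ws.copy()
    for idx in ws.index[ws["outlier"]]:
        chrom = ws.at[idx, "chromosome"]
        s, e = int(ws.at[idx, "start"]), int(ws.at[idx, "end"])
        d = (tracks.norm_m[chrom][s:e] - tracks.norm_f[chrom][s:e]).astype(float)
        nz = d[d != 0]
        if len(nz) < min_pairs:
            continue
        p = wilcoxon_signed_rank_p(nz, max_exact=max_exact)
        _, lo, hi = hodges_lehmann_ci(d, alpha=alpha, max_exact=max_exact)
        ws.at[idx, "p_value"] = p
        ws.at[idx, "ci_low"] = lo
        ws.at[idx, "ci_high"] = hi
        ws.at[idx, "significant"] = bool(p < alpha)
    return ws


def chromosome_enrichment(ws: pd.DataFrame, genome: GenomeIndex) -> pd.DataFrame:
    """One-sided Fisher enrichment of significant windows per chromosome.

    For each chromosome the 2×2 table [[sig_c, nonsig_c], [sig_rest,
    nonsig_rest]] is tested for enrichment (alternative='greater'); p-values
    are Bonferroni-corrected across chromosomes, and counts are normalized by
    chromosome length in Mb.
    """
    n_chrom = len(genome)
    sig_total = int(ws["significant"].sum())
    n_total = len(ws)
    rows = []
    for chrom, length in genome:
        sub = ws[ws["chromosome"] == chrom]
        n_c, sig_c = len(sub), int(sub["significant"].sum())
        table = [[sig_c, n_c - sig_c], [sig_total - sig_c, (n_total - n_c) - (sig_total - sig_c)]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append({
            "chromosome": chrom,
            "n_windows": n_c,
            "n_sig": sig_c,
            "odds_ratio": float(odds),
            "p_raw": float(p),
            "p_bonferroni": float(min(1.0, p * n_chrom)),
            "sig_per_mb": sig_c / (length / 1e6),
        })
    return pd.DataFrame(rows)


def coverage_scan(
    d: DepthMatrix,
    windows: list[Window],
    quantile: float = 0.99,
    min_diff: float = 0.25,
    alpha: float = 0.05,
    epsilon: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame, NormalizedTracks]:
    """Full scan: normalize, window stats, outliers, tests, enrichment."""
    tracks = normalize_depth(d)
    ws = window_coverage_stats(tracks, windows, epsilon=epsilon)
    ws = detect_outlier_windows(ws, quantile=quantile, min_diff=min_diff)
    ws = test_windows(ws, tracks, alpha=alpha)
    enrich = chromosome_enrichment(ws, d.genome_index())
    return ws, enrich, tracks
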