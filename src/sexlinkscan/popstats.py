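"""Intersex Fst, per-sex nucleotide diversity, and an XY/ZW genotype pattern scan.

Fst treats the males and the females of one population as two groups and uses
the Weir & Cockerham (1984) two-population θ estimator: per biallelic site the
variance components are, with per-group sample sizes nᵢ, alternate-allele
frequencies pᵢ and observed heterozygote fractions hᵢ, n̄ the mean size,
n_c = 2n̄ − Σnᵢ²/(2n̄), p̄ = Σnᵢpᵢ/(2n̄), s² = Σnᵢ(pᵢ−p̄)²/n̄ and
h̄ = Σnᵢhᵢ/(2n̄):

    a = (n̄/n_c)·[s² − (p̄(1−p̄) − s²/2 − h̄/4)/(n̄−1)]
    b = (n̄/(n̄−1))·[p̄(1−p̄) − s²/2 − ((2n̄−1)/(4n̄))·h̄]
    c = h̄/2

Per-site Fst = a/(a+b+c); the window estimate is the ratio of sums Σa/Σ(a+b+c).
At a fully sex-linked site (every heterogametic individual heterozygous, the
other sex homozygous reference, equal sample sizes) this gives exactly 0.5 —
the hallmark of a differentiated sex chromosome. Negative per-site estimates
are reported as-is.

Nucleotide diversity per window is Σ_sites 2·n_A·n_a/(n(n−1)) divided by the
full window length in bp (invariant sites included), the convention of
windowed-π tools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import FEMALE, MALE, VariantTable, Window


def _sex_indices(v: VariantTable, sex: str) -> np.ndarray:
    return np.array([i for i, s in enumerate(v.specimens) if s.sex == sex], dtype=int)


def _per_sex_site_stats(gt: np.ndarray, cols: np.ndarray):
    """(n called individuals, alt-allele frequency, het fraction) per site."""
    g = gt[:, cols, :]
    called = ~np.any(g < 0, axis=2)
    n = called.sum(axis=1).astype(float)
    alt = np.where(called, (g == 1).sum(axis=2), 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n)
        het = np.where(called, g[:, :, 0] != g[:, :, 1], False).sum(axis=1) / n
    return n, p, het


def weir_cockerham_components(v: VariantTable) -> pd.DataFrame:
    """Per-site Weir–Cockerham (1984) a, b, c components for males vs females.

    Sites with fewer than 2 genotyped individuals in either sex are skipped.
    Monomorphic sites yield all-zero components and an undefined (NaN) Fst.
    """
    mcols, fcols = _sex_indices(v, MALE), _sex_indices(v, FEMALE)
    n1, p1, h1 = _per_sex_site_stats(v.genotypes, mcols)
    n2, p2, h2 = _per_sex_site_stats(v.genotypes, fcols)
    ok = (n1 >= 2) & (n2 >= 2)

    nbar = (n1 + n2) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = 2.0 * nbar - (n1**2 + n2**2) / (2.0 * nbar)
        pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)
        inner = pbar * (1.0 - pbar) - s2 / 2.0 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - s2 / 2.0 - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
    a, b, c = (np.where(ok, x, np.nan) for x in (a, b, c))
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom != 0, a / denom, np.nan)
    return pd.DataFrame({
        "chromosome": v.chrom,
        "position": v.pos,
        "a": a, "b": b, "c": c,
        "fst": fst,
        "usable": ok,
    })


def intersex_fst(
    v: VariantTable, windows: list[Window] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-site components plus (optionally) per-window ratio-of-sums Fst."""
    site = weir_cockerham_components(v)
    if windows is None:
        return site, None
    rows = []
    for w in windows:
        sel = site[
            (site["chromosome"] == w.chromosome)
            & (site["position"] > w.start)
            & (site["position"] <= w.end)
            & site["usable"]
        ]
        num = sel["a"].sum()
        den = (sel["a"] + sel["b"] + sel["c"]).sum()
        rows.append({
            "chromosome": w.chromosome, "start": w.start, "end": w.end,
            "n_sites": len(sel),
            "fst": float(num / den) if den != 0 else np.nan,
        })
    return site, pd.DataFrame(rows)


def nucleotide_diversity(
    v: VariantTable, sex: str, windows: list[Window]
) -> pd.DataFrame:
    """Per-window π for the specimens of one sex.

    Per site π = 2·n_A·n_a/(n(n−1)) over called haplotypes; the window value
    divides the site sum by the full window length (invariant sites count as
    zero difference). Windows without genotyped sites get π = 0.
    """
    cols = _sex_indices(v, sex)
    g = v.genotypes[:, cols, :]
    called = ~np.any(g < 0, axis=2)
    n_hap = 2.0 * called.sum(axis=1)
    alt = np.where(called, (g == 1).sum(axis=2), 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = 2.0 * alt * (n_hap - alt) / (n_hap * (n_hap - 1.0))
    pi_site = np.where(n_hap >= 2, pi_site, 0.0)
    rows = []
    for w in windows:
        sel = (v.chrom == w.chromosome) & (v.pos > w.start) & (v.pos <= w.end)
        rows.append({
            "chromosome": w.chromosome, "start": w.start, "end": w.end,
            "n_sites": int(sel.sum()),
            "pi": float(pi_site[sel].sum() / w.length),
        })
    return pd.DataFrame(rows)


def sex_pattern_scan(v: VariantTable) -> pd.DataFrame:
    """Descriptive XY/ZW genotype-pattern fractions per site.

    xy_score = (heterozygous males + homozygous females) / genotyped
    individuals; zw_score mirrors it. A score of 1.0 means the site's
    genotypes perfectly follow the heterogametic pattern. This is a
    descriptive screen, not a significance test.
    """
    mcols, fcols = _sex_indices(v, MALE), _sex_indices(v, FEMALE)
    g = v.genotypes
    called = ~np.any(g < 0, axis=2)
    het = (g[:, :, 0] != g[:, :, 1]) & called
    hom = (g[:, :, 0] == g[:, :, 1]) & called
    n_called = called.sum(axis=1).astype(float)
    xy = het[:, mcols].sum(axis=1) + hom[:, fcols].sum(axis=1)
    zw = het[:, fcols].sum(axis=1) + hom[:, mcols].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xy_score = np.where(n_called > 0, xy / n_called, np.nan)
        zw_score = np.where(n_called > 0, zw / n_called, np.nan)
    return pd.DataFrame({
        "chromosome": v.chrom,
        "position": v.pos,
        "xy_score": xy_score,
        "zw_score": zw_score,
    })
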