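"""Window and gene statistics from pooled allele counts.

Allele frequencies are estimated per site as alt_count / depth after coverage
filters; nucleotide diversity uses the unbiased per-site heterozygosity
2*p*(1-p)*n/(n-1) at the group's chromosome count n, and Tajima's D is the
classic normalized difference between pi and the Watterson estimator S/a1.
The haploid sample size for a pool group is taken as twice the number of
diploid individuals contributing to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TajimaConstants:
    """Coefficients of the D statistic for haploid sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n_chrom: int) -> TajimaConstants:
    if n_chrom < 2:
        raise ValueError("n_chrom must be >= 2")
    n = n_chrom
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass(frozen=True)
class Window:
    """Genomic window; 0-based half-open internally, 1-based in reports."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError("window must have positive width")


@dataclass
class FilterTally:
    """Site-filter bookkeeping in the style of a pool summary table."""

    n_input: int
    n_variant: int          # depth > min_depth and alt_count > 0
    n_alt_ge_threshold: int  # of those, alt frequency >= min_alt_freq
    mean_depth_variant: float


def site_pi(ref_count, alt_count, n_chrom: int):
    """Unbiased per-site heterozygosity 2*p*(1-p) * n/(n-1).

    ``p`` is the read-frequency estimate alt/(ref+alt). Accepts scalars or
    arrays; zero-depth sites are an error (filter first).
    """
    ref = np.asarray(ref_count, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    if n_chrom < 2:
        raise ValueError("n_chrom must be >= 2")
    depth = ref + alt
    if np.any(depth <= 0):
        raise ValueError("site_pi requires depth > 0")
    p = alt / depth
    out = 2.0 * p * (1.0 - p) * n_chrom / (n_chrom - 1.0)
    return float(out) if np.isscalar(ref_count) else out


def filter_sites(
    sites: pd.DataFrame,
    min_depth: int = 6,
    min_alt_freq: float = 0.2,
    coverage_floor: int = 8,
) -> tuple[pd.DataFrame, FilterTally]:
    """Apply the variant-site filters and tally the summary counts.

    A *variant site* has read depth strictly above ``min_depth`` and at least
    one alternate read; the tally also counts variant sites whose alternate
    frequency is at least ``min_alt_freq`` and reports mean depth at variant
    sites. The returned table — used by all downstream statistics — keeps
    variant sites that additionally meet the stricter ``coverage_floor``
    (depth >= 8 by default, applied identically to every group to avoid
    coverage-driven bias).
    """
    if not 0.0 <= min_alt_freq <= 1.0:
        raise ValueError("min_alt_freq must be in [0, 1]")
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    if len(sites) == 0:
        return sites.copy(), FilterTally(0, 0, 0, 0.0)
    ref = sites["ref_count"].to_numpy()
    alt = sites["alt_count"].to_numpy()
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("negative read counts")
    depth = ref + alt
    variant = (depth > min_depth) & (alt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        altfreq = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    tally = FilterTally(
        n_input=len(sites),
        n_variant=int(variant.sum()),
        n_alt_ge_threshold=int((variant & (altfreq >= min_alt_freq)).sum()),
        mean_depth_variant=float(depth[variant].mean()) if variant.any() else 0.0,
    )
    keep = variant & (depth >= coverage_floor)
    return sites[keep].reset_index(drop=True), tally


def combine_group_counts(sites: pd.DataFrame, group_map: dict[str, str]) -> pd.DataFrame:
    """Sum read counts across a group's pools, site-wise.

    ``group_map`` maps pool_id -> group label. Frequencies downstream are
    estimated from the summed counts, mirroring group-level pileups.
    Returns columns chrom, pos, ref_allele, alt_allele, ref_count, alt_count,
    group.
    """
    df = sites.copy()
    unknown = set(df["pool_id"]) - set(group_map)
    if unknown:
        raise ValueError(f"pools missing from group map: {sorted(unknown)}")
    df["group"] = df["pool_id"].map(group_map)
    keys = ["chrom", "pos", "ref_allele", "alt_allele", "group"]
    out = (
        df.groupby(keys, as_index=False, sort=False)[["ref_count", "alt_count"]]
        .sum()
        .sort_values(["group", "chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    return out


def tajima_d_from_pi_s(pi: float, s: int, const: TajimaConstants) -> float:
    """D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)); NaN when S == 0."""
    if s == 0:
        return math.nan
    denom = math.sqrt(const.e1 * s + const.e2 * s * (s - 1))
    return (pi - s / const.a1) / denom


@dataclass
class WindowStats:
    window: Window
    group: str
    S: int
    pi: float
    D: float
    n_sites_covered: int

    @property
    def pi_per_bp(self) -> float:
        return self.pi / (self.window.end - self.window.start)


def window_stats(
    sites: pd.DataFrame, window: Window, n_chrom: int, group: str = ""
) -> WindowStats:
    """Segregating sites, pi and Tajima's D for one window.

    ``sites`` must already be filtered; segregating means 0 < p-hat < 1.
    """
    if n_chrom < 4:
        raise ValueError("n_chrom must be >= 4 for window statistics")
    pos = sites["pos"].to_numpy()
    in_win = (sites["chrom"].to_numpy() == window.chrom) & \
        (pos > window.start) & (pos <= window.end)
    sub = sites[in_win]
    n_cov = len(sub)
    if n_cov == 0:
        return WindowStats(window, group, 0, 0.0, math.nan, 0)
    ref = sub["ref_count"].to_numpy(dtype=float)
    alt = sub["alt_count"].to_numpy(dtype=float)
    p = alt / (ref + alt)
    seg = (p > 0) & (p < 1)
    s = int(seg.sum())
    pi = float(np.sum(site_pi(ref[seg], alt[seg], n_chrom))) if s else 0.0
    const = tajima_constants(n_chrom)
    return WindowStats(window, group, s, pi, tajima_d_from_pi_s(pi, s, const), n_cov)


def windowed_stats(
    sites: pd.DataFrame,
    chrom_lengths: dict[str, int],
    n_chrom: int,
    window_size: int = 10_000,
    group: str = "",
) -> pd.DataFrame:
    """Window statistics over a full genome grid (vectorized).

    Trailing partial windows are dropped. Returns a frame with columns
    chrom, start, end (0-based half-open), group, S, pi, pi_per_bp, D,
    n_sites — one row per grid window, in genome order.
    """
    if n_chrom < 4:
        raise ValueError("n_chrom must be >= 4 for window statistics")
    const = tajima_constants(n_chrom)
    frames = []
    for chrom, length in chrom_lengths.items():
        n_win = length // window_size
        starts = np.arange(n_win, dtype=np.int64) * window_size
        sub = sites[sites["chrom"] == chrom]
        ref = sub["ref_count"].to_numpy(dtype=float)
        alt = sub["alt_count"].to_numpy(dtype=float)
        pos = sub["pos"].to_numpy(dtype=np.int64)
        depth = ref + alt
        with np.errstate(invalid="ignore"):
            p = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
        widx_all = (pos - 1) // window_size
        in_grid = widx_all < n_win
        widx = widx_all[in_grid]
        p_g, ref_g, alt_g = p[in_grid], ref[in_grid], alt[in_grid]
        seg = (p_g > 0) & (p_g < 1)
        S = np.bincount(widx[seg], minlength=n_win)
        pis = site_pi(ref_g[seg], alt_g[seg], n_chrom) if seg.any() else np.zeros(0)
        pi = np.bincount(widx[seg], weights=pis, minlength=n_win)
        n_sites = np.bincount(widx, minlength=n_win)
        with np.errstate(invalid="ignore", divide="ignore"):
            D = (pi - S / const.a1) / np.sqrt(const.e1 * S + const.e2 * S * (S - 1))
        D = np.where(S == 0, np.nan, D)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": starts + window_size,
            "group": group,
            "S": S.astype(np.int64),
            "pi": pi,
            "pi_per_bp": pi / window_size,
            "D": D,
            "n_sites": n_sites.astype(np.int64),
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class GeneFreqStat:
    gene_id: str
    group: str
    mean_major_freq: float  # NaN when n_snps == 0
    n_snps: int


def gene_major_allele_freq(
    sites: pd.DataFrame, gene, group: str = ""
) -> GeneFreqStat:
    """Mean major-allele frequency max(p, 1-p) over SNPs inside one gene.

    ``sites`` must hold group-combined, filtered counts. ``gene`` is any
    object with gene_id, chrom, start, end (0-based half-open). Genes with no
    SNPs yield NaN and are excluded from downstream scans.
    """
    if gene.end <= gene.start:
        raise ValueError(f"malformed gene interval {gene.gene_id}")
    pos = sites["pos"].to_numpy()
    mask = (sites["chrom"].to_numpy() == gene.chrom) & \
        (pos > gene.start) & (pos <= gene.end)
    sub = sites[mask]
    ref = sub["ref_count"].to_numpy(dtype=float)
    alt = sub["alt_count"].to_numpy(dtype=float)
    depth = ref + alt
    ok = depth > 0
    p = alt[ok] / depth[ok]
    seg = (p > 0) & (p < 1)
    p = p[seg]
    if len(p) == 0:
        return GeneFreqStat(gene.gene_id, group, math.nan, 0)
    return GeneFreqStat(gene.gene_id, group, float(np.mean(np.maximum(p, 1 - p))), len(p))


def gene_freq_table(sites: pd.DataFrame, genes: pd.DataFrame, group: str = "") -> pd.DataFrame:
    """Per-gene major-allele-frequency statistics for a gene table."""
    rows = []
    for g in genes.itertuples():
        st = gene_major_allele_freq(sites, g, group)
        rows.append({
            "gene_id": st.gene_id, "chrom": g.chrom, "start": g.start,
            "end": g.end, "annotated": bool(g.annotated), "group": group,
            "mean_major_freq": st.mean_major_freq, "n_snps": st.n_snps,
        })
    return pd.DataFrame(rows)
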