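"""Per-gene diversity statistics from individual genotypes.

Used to validate pooled-scan candidates against independently sequenced
individuals: within-group Tajima's D, nucleotide diversity per bp, mean
individual heterozygosity, the Weir & Cockerham (1984) two-population F_ST,
and the between-species pi ratio. Negative D with bottom-quartile pi and
heterozygosity in the putatively selected group counts as support for a
sweep candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .poolstats import tajima_constants, tajima_d_from_pi_s

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Diploid genotypes: individuals x sites, alt-allele dosage 0/1/2, -1 missing."""

    genotypes: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray  # 1-based
    samples: list[str]
    groups: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.genotypes.shape != (len(self.samples), len(self.pos)):
            raise ValueError("genotype matrix shape does not match samples x sites")
        if len(self.groups) != len(self.samples):
            raise ValueError("one group label per sample required")

    def group_rows(self, group: str) -> np.ndarray:
        rows = np.array([i for i, g in enumerate(self.groups) if g == group])
        if rows.size == 0:
            raise ValueError(f"no individuals in group {group!r}")
        return rows

    def gene_cols(self, gene) -> np.ndarray:
        return np.where(
            (self.chrom == gene.chrom)
            & (self.pos > gene.start)
            & (self.pos <= gene.end)
        )[0]


@dataclass
class GeneDiversityStats:
    gene_id: str
    group: str
    pi_per_bp: float
    S: int
    tajima_d: float
    het_mean: float
    n_sites: int


def gene_diversity(gm: GenotypeMatrix, gene, group: str) -> GeneDiversityStats:
    """Within-group pi/bp, S, Tajima's D and mean heterozygosity for one gene.

    Per site, pi = 2*p*q * 2N/(2N-1) with 2N the called chromosomes;
    pi_per_bp divides the site sum by the gene interval length (monomorphic
    positions count in the denominator). D uses Tajima constants at the
    median called-chromosome count over the gene's sites. het_mean averages,
    over individuals, the fraction of that individual's called in-gene sites
    that are heterozygous.
    """
    rows = gm.group_rows(group)
    cols = gm.gene_cols(gene)
    length = gene.end - gene.start
    gt = gm.genotypes[np.ix_(rows, cols)]
    called = gt != MISSING
    if cols.size == 0 or not called.any():
        return GeneDiversityStats(gene.gene_id, group, math.nan, 0, math.nan,
                                  math.nan, 0)
    n2 = 2 * called.sum(axis=0)          # called chromosomes per site
    alt = np.where(called, gt, 0).sum(axis=0)
    ok = n2 >= 2
    p = np.zeros(cols.size)
    p[ok] = alt[ok] / n2[ok]
    seg = ok & (p > 0) & (p < 1)
    pi_sites = 2.0 * p[seg] * (1 - p[seg]) * n2[seg] / (n2[seg] - 1)
    s = int(seg.sum())
    pi = float(pi_sites.sum())
    if s > 0:
        n_med = int(np.median(n2[seg]))
        d = tajima_d_from_pi_s(pi, s, tajima_constants(max(n_med, 2)))
    else:
        d = math.nan
    per_ind_called = called.sum(axis=1)
    per_ind_het = (gt == 1).sum(axis=1)
    has = per_ind_called > 0
    het_mean = float(np.mean(per_ind_het[has] / per_ind_called[has])) if has.any() \
        else math.nan
    return GeneDiversityStats(gene.gene_id, group, pi / length, s, d, het_mean,
                              int(cols.size))


@dataclass
class FstResult:
    gene_id: str
    fst_gene: float    # ratio of sums; may be negative, reported raw
    sum_a: float
    sum_b: float
    sum_c: float
    n_sites_used: int


def _wc84_site(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components for one biallelic site.

    ``n``: individuals per population; ``p``: alt frequencies; ``h``:
    observed heterozygote proportions. Returns (a, b, c): among-population,
    among-individual-within-population, and within-individual components.
    """
    r = len(n)
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def gene_fst(gm: GenotypeMatrix, gene, group_1: str, group_2: str) -> FstResult:
    """Two-population Weir & Cockerham F_ST over a gene's sites.

    Per-site components are summed over polymorphic sites with at least two
    called individuals in each group ("ratio of sums"); monomorphic sites are
    skipped. Negative estimates are reported raw.
    """
    rows1, rows2 = gm.group_rows(group_1), gm.group_rows(group_2)
    cols = gm.gene_cols(gene)
    sa = sb = sc = 0.0
    used = 0
    for j in cols:
        stats = []
        for rows in (rows1, rows2):
            g = gm.genotypes[rows, j]
            g = g[g != MISSING]
            if len(g) < 2:
                break
            stats.append((len(g), g.sum() / (2 * len(g)), (g == 1).mean()))
        if len(stats) < 2:
            continue
        n = np.array([s[0] for s in stats], dtype=float)
        p = np.array([s[1] for s in stats])
        h = np.array([s[2] for s in stats])
        pbar = (n * p).sum() / n.sum()
        if pbar <= 0 or pbar >= 1:
            continue  # monomorphic overall
        a, b, c = _wc84_site(n, p, h)
        sa, sb, sc = sa + a, sb + b, sc + c
        used += 1
    denom = sa + sb + sc
    fst = sa / denom if used and denom != 0 else math.nan
    return FstResult(gene.gene_id, fst, sa, sb, sc, used)


def pi_ratio(pi_wild_species: float, pi_domesticated: float) -> float:
    """Factor by which the wild species' pi exceeds the domesticated one's.

    A zero denominator returns +inf (flagged infinite, not an error), so a
    completely swept gene still yields a reportable value.
    """
    if pi_wild_species < 0 or pi_domesticated < 0:
        raise ValueError("pi values must be non-negative")
    if pi_domesticated == 0:
        return math.inf
    return pi_wild_species / pi_domesticated


def candidate_support(
    all_stats: pd.DataFrame,
    candidate_ids: list[str],
    d_threshold: float = 0.0,
    pi_quantile: float = 0.25,
    het_quantile: float = 0.25,
) -> pd.DataFrame:
    """Verdict per candidate gene: is the individual-genome evidence consistent
    with a sweep?

    ``all_stats`` holds one row per gene (columns gene_id, tajima_d,
    pi_per_bp, het_mean) for the whole genome; the pi and heterozygosity
    cutoffs are genome-wide lower quantiles computed from it. A candidate is
    "supported" iff D < d_threshold AND pi and het_mean both fall below their
    cutoffs; genes with missing statistics get "insufficient_data".
    """
    pi_cut = float(all_stats["pi_per_bp"].quantile(pi_quantile))
    het_cut = float(all_stats["het_mean"].quantile(het_quantile))
    stats = all_stats.set_index("gene_id")
    rows = []
    for gid in candidate_ids:
        if gid not in stats.index:
            rows.append({"gene_id": gid, "verdict": "insufficient_data"})
            continue
        g = stats.loc[gid]
        if any(pd.isna(g[k]) for k in ("tajima_d", "pi_per_bp", "het_mean")):
            rows.append({"gene_id": gid, "verdict": "insufficient_data"})
            continue
        ok = (g["tajima_d"] < d_threshold) and (g["pi_per_bp"] <= pi_cut) \
            and (g["het_mean"] <= het_cut)
        rows.append({"gene_id": gid, "verdict": "supported" if ok else "not_supported"})
    return pd.DataFrame(rows)
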