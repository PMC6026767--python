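"""Candidate-sweep detection from between-group Tajima's D differences.

Two scans are provided:

* a permutation test on the per-window difference in Tajima's D between two
  pool groups (wild minus orchard by convention, so a sweep in the orchard
  group pushes the difference positive), with consecutive-window and
  strict-single-window candidate rules plus a histogram-based local false
  discovery rate;
* a major-allele-fixation outlier scan on 10-gene intervals, flagging
  intervals whose between-group difference in mean major-allele frequency
  exceeds the genome-wide mean by a configurable number of standard
  deviations (3 for the domestication contrast, 2 for regional contrasts).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_GRID_COLS = ["chrom", "start", "end"]


def observed_difference(stats_a: pd.DataFrame, stats_b: pd.DataFrame) -> pd.DataFrame:
    """Per-window difference track: delta_i = D_A,i - D_B,i.

    Both inputs are window-stats frames on identical grids (chrom/start/end in
    the same order). With A = wild and B = orchard, positive delta is the
    sweep-like signal (depressed D in the orchard group). Missing D on either
    side propagates to a missing delta.
    """
    if len(stats_a) != len(stats_b):
        raise ValueError(
            f"window grids differ in length: {len(stats_a)} vs {len(stats_b)}"
        )
    ga = stats_a[_GRID_COLS].reset_index(drop=True)
    gb = stats_b[_GRID_COLS].reset_index(drop=True)
    neq = (ga != gb).any(axis=1)
    if neq.any():
        i = int(neq.idxmax())
        raise ValueError(
            f"window grids differ first at row {i}: "
            f"{tuple(ga.iloc[i])} vs {tuple(gb.iloc[i])}"
        )
    out = ga.copy()
    out["D_a"] = stats_a["D"].to_numpy()
    out["D_b"] = stats_b["D"].to_numpy()
    out["delta"] = out["D_a"] - out["D_b"]
    return out


@dataclass
class PermutationResult:
    """Per-window permutation p-values for the observed difference track."""

    table: pd.DataFrame  # chrom, start, end, delta, exceed_count, n_permutations, p_value
    mode: str            # "per-window" | "pooled-null" | "exhaustive"
    seed: int | None
    n_perm: int


def exhaustive_pvalues(d_a: np.ndarray, d_b: np.ndarray) -> np.ndarray:
    """Exact per-window one-sided p over all joint permutations of both tracks.

    Under the uniform joint group of (perm_A, perm_B) pairs the value placed
    at window i is a uniformly random pair (a_j, b_k), so the exceedance
    probability reduces to counting the m^2 value pairs with
    a_j - b_k >= delta_i. This equals full enumeration of all (m!)^2 joint
    permutations, at m^2 cost.
    """
    d_a = np.asarray(d_a, dtype=float)
    d_b = np.asarray(d_b, dtype=float)
    delta = d_a - d_b
    pairs = (d_a[:, None] - d_b[None, :]).ravel()
    # tiny tolerance so exact ties survive float subtraction
    counts = np.array([(pairs >= d - 1e-12).sum() for d in delta])
    return counts / (len(d_a) ** 2)


def permutation_test(
    track_a: pd.DataFrame | np.ndarray,
    track_b: pd.DataFrame | np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    mode: str = "per-window",
) -> PermutationResult:
    """Permutation null for the between-group Tajima's D difference.

    Each permutation independently reassigns both groups' observed D values
    to random window positions and recomputes the difference. One-sided:
    permuted differences >= the observed difference count as exceedances.

    ``per-window`` (default): p_i = (1 + #{delta_perm_i >= delta_i}) /
    (1 + n_perm). ``pooled-null``: delta_i is compared against the shuffled
    differences of all windows and permutations combined. Windows with a
    missing D on either side are excluded from shuffling and get missing p.
    Exhaustive enumeration replaces sampling automatically when the joint
    permutation count (m!)^2 is at most 10,000.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("per-window", "pooled-null"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(track_a, pd.DataFrame):
        grid = track_a[_GRID_COLS].reset_index(drop=True)
        d_a = track_a["D"].to_numpy(dtype=float)
        d_b = track_b["D"].to_numpy(dtype=float)
    else:
        d_a = np.asarray(track_a, dtype=float)
        d_b = np.asarray(track_b, dtype=float)
        grid = pd.DataFrame({
            "chrom": "chr0",
            "start": np.arange(len(d_a)) * 1,
            "end": np.arange(len(d_a)) + 1,
        })
    ok = ~(np.isnan(d_a) | np.isnan(d_b))
    m = int(ok.sum())
    if m < 2:
        raise ValueError("need >= 2 windows with non-missing D in both tracks")
    a, b = d_a[ok], d_b[ok]
    delta = a - b

    p = np.full(len(d_a), np.nan)
    exceed = np.full(len(d_a), -1, dtype=np.int64)
    if mode == "per-window" and math.factorial(m) ** 2 <= 10_000:
        p[ok] = exhaustive_pvalues(a, b)
        exceed[ok] = np.round(p[ok] * m * m).astype(np.int64)
        used_mode, used_n = "exhaustive", m * m
    else:
        rng = np.random.default_rng(seed)
        perm_a = rng.permuted(np.broadcast_to(a, (n_perm, m)).copy(), axis=1)
        perm_b = rng.permuted(np.broadcast_to(b, (n_perm, m)).copy(), axis=1)
        perm_delta = perm_a - perm_b
        if mode == "per-window":
            cnt = (perm_delta >= delta[None, :] - 1e-12).sum(axis=0)
            p[ok] = (1 + cnt) / (1 + n_perm)
            exceed[ok] = cnt
            used_mode, used_n = mode, n_perm
        else:
            pool = np.sort(perm_delta.ravel())
            cnt = len(pool) - np.searchsorted(pool, delta - 1e-12, side="left")
            p[ok] = (1 + cnt) / (1 + len(pool))
            exceed[ok] = cnt
            used_mode, used_n = mode, len(pool)

    table = grid.copy()
    table["delta"] = d_a - d_b
    table["exceed_count"] = exceed
    table["n_permutations"] = used_n
    table["p_value"] = p
    return PermutationResult(table, used_mode, seed, n_perm)


@dataclass
class SweepCall:
    chrom: str
    start: int
    end: int
    min_p: float
    run_length: int
    rule: str  # "consecutive_p01" | "single_p001"


def call_candidates(
    perm_table: pd.DataFrame,
    alpha_run: float = 0.01,
    alpha_single: float = 0.001,
    min_run: int = 2,
) -> list[SweepCall]:
    """Merge significant windows into candidate sweep calls.

    Maximal runs of >= ``min_run`` adjacent windows (same chromosome,
    touching coordinates) with p <= ``alpha_run`` become one merged call;
    windows with p <= ``alpha_single`` that are not in such a run become
    singleton calls. Overlapping calls are merged; the resulting intervals
    are disjoint. Missing p breaks runs.
    """
    calls: list[SweepCall] = []
    df = perm_table.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    chroms = df["chrom"].to_numpy()
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    p = df["p_value"].to_numpy(dtype=float)

    sig = np.where(np.isnan(p), False, p <= alpha_run)
    adjacent = np.zeros(len(df), dtype=bool)
    if len(df) > 1:
        adjacent[1:] = (chroms[1:] == chroms[:-1]) & (starts[1:] == ends[:-1])
    run_id = np.cumsum(~(sig & adjacent))  # breaks where not (sig and touching)
    in_run = np.zeros(len(df), dtype=bool)
    for rid in np.unique(run_id[sig]):
        idx = np.where((run_id == rid) & sig)[0]
        if len(idx) >= min_run:
            in_run[idx] = True
            calls.append(SweepCall(
                chrom=str(chroms[idx[0]]),
                start=int(starts[idx[0]]),
                end=int(ends[idx[-1]]),
                min_p=float(np.nanmin(p[idx])),
                run_length=len(idx),
                rule="consecutive_p01",
            ))
    singles = np.where(np.isnan(p), False, p <= alpha_single) & ~in_run
    for i in np.where(singles)[0]:
        calls.append(SweepCall(str(chroms[i]), int(starts[i]), int(ends[i]),
                               float(p[i]), 1, "single_p001"))
    return _merge_calls(calls)


def _merge_calls(calls: list[SweepCall]) -> list[SweepCall]:
    calls = sorted(calls, key=lambda c: (c.chrom, c.start))
    merged: list[SweepCall] = []
    for c in calls:
        if merged and merged[-1].chrom == c.chrom and c.start < merged[-1].end:
            last = merged.pop()
            merged.append(SweepCall(
                last.chrom, last.start, max(last.end, c.end),
                min(last.min_p, c.min_p),
                last.run_length + c.run_length,
                last.rule if last.rule == c.rule else "consecutive_p01",
            ))
        else:
            merged.append(c)
    return merged


@dataclass
class LfdrResult:
    lfdr: np.ndarray
    pi0_hat: float
    bin_edges: np.ndarray
    bin_lfdr: np.ndarray


def local_fdr(p_values: np.ndarray, n_bins: int = 20) -> LfdrResult:
    """Histogram-based local false discovery rate.

    pi0 is Storey's estimator at lambda = 0.5: min(1, #{p > 0.5} / (0.5 m)).
    lfdr(p) = pi0 / f(p) with f a ``n_bins``-bin histogram density on [0, 1],
    clipped to [0, 1] and regularized to be monotone non-decreasing in p by a
    cumulative maximum across bins. Empty bins get lfdr 1.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m < 50:
        raise ValueError("need >= 50 p-values for density estimation")
    pi0 = min(1.0, (p > 0.5).sum() / (0.5 * m))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(p, bins=edges)
    dens = counts / (m * (1.0 / n_bins))
    with np.errstate(divide="ignore"):
        bin_lfdr = np.where(dens > 0, pi0 / np.maximum(dens, 1e-300), np.inf)
    bin_lfdr = np.clip(bin_lfdr, 0.0, 1.0)
    bin_lfdr = np.maximum.accumulate(bin_lfdr)
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, n_bins - 1)
    return LfdrResult(bin_lfdr[idx], float(pi0), edges, bin_lfdr)


@dataclass
class FixationOutlier:
    chrom: str
    start: int
    end: int
    gene_ids: list[str] = field(default_factory=list)
    delta: float = math.nan
    z_sd: float = math.nan
    flagged: bool = False
    contrast: str = "domestication"


DEFAULT_SD_MULTIPLIER = {"domestication": 3.0, "regional": 2.0}


def fixation_scan(
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    interval_size: int = 10,
    sd_multiplier: float | None = None,
    contrast: str = "domestication",
) -> list[FixationOutlier]:
    """Major-allele-fixation outliers over consecutive gene intervals.

    Genes (restricted to annotated ones with at least one SNP in both groups)
    are grouped, in genome order, into non-overlapping runs of
    ``interval_size`` per chromosome (trailing remainders dropped). Per
    interval, delta = mean_A - mean_B of the interval-averaged per-gene mean
    major-allele frequency; an interval is flagged when delta exceeds the
    genome-wide mean of delta by ``sd_multiplier`` population standard
    deviations (default 3 for the domestication contrast, 2 for regional).
    """
    if sd_multiplier is None:
        sd_multiplier = DEFAULT_SD_MULTIPLIER.get(contrast, 3.0)
    a = genes_a.set_index("gene_id")
    b = genes_b.set_index("gene_id")
    if set(a.index) != set(b.index):
        raise ValueError("the two gene tables must cover the same gene set")
    b = b.loc[a.index]
    usable = (
        a["annotated"].to_numpy(bool)
        & (a["n_snps"].to_numpy() > 0)
        & (b["n_snps"].to_numpy() > 0)
    )
    a = a[usable].sort_values(["chrom", "start"], kind="stable")
    b = b.loc[a.index]

    intervals: list[FixationOutlier] = []
    for chrom, sub_a in a.groupby("chrom", sort=False):
        sub_b = b.loc[sub_a.index]
        n_full = len(sub_a) // interval_size
        if len(sub_a) % interval_size:
            logger.info("fixation_scan: dropping %d trailing genes on %s",
                        len(sub_a) % interval_size, chrom)
        for k in range(n_full):
            block_a = sub_a.iloc[k * interval_size:(k + 1) * interval_size]
            block_b = sub_b.iloc[k * interval_size:(k + 1) * interval_size]
            intervals.append(FixationOutlier(
                chrom=str(chrom),
                start=int(block_a["start"].min()),
                end=int(block_a["end"].max()),
                gene_ids=list(block_a.index),
                delta=float(block_a["mean_major_freq"].mean()
                            - block_b["mean_major_freq"].mean()),
                contrast=contrast,
            ))
    if not intervals:
        return intervals
    deltas = np.array([iv.delta for iv in intervals])
    mu = float(deltas.mean())
    sigma = float(deltas.std())  # population SD
    if sigma == 0.0:
        logger.warning("fixation_scan: all interval deltas identical; no outliers")
        for iv in intervals:
            iv.z_sd = 0.0
        return intervals
    for iv in intervals:
        iv.z_sd = (iv.delta - mu) / sigma
        iv.flagged = iv.z_sd > sd_multiplier
    return intervals
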