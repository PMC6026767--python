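"""Pooled chloroplast haplotype deconvolution.

A chloroplast haplotype carried by a fraction f of the copies in a pool
leaves its private SNPs at alternate-allele frequency ~f, so the haplotype
composition of a pool shows up as peaks in a histogram of SNP counts over
allele-frequency bins: the bin center estimates the haplotype frequency, the
SNP count in the bin estimates its divergence from the reference, and the
member SNP sets let peaks be matched across pools. Shared SNPs between
co-occurring haplotypes inflate intermediate bins; no deconvolution of
shared sites is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass
class FreqHistogram:
    pool_id: str
    bin_width: float
    centers: np.ndarray            # 0.1, 0.2, ..., 1.0 at default width
    counts: np.ndarray
    members: list[np.ndarray]      # SNP positions per bin

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pool_id": self.pool_id,
            "bin_center": self.centers,
            "snp_count": self.counts,
        })


@dataclass
class HaplotypePeak:
    pool_id: str
    freq_estimate: float
    snp_count: int
    snp_set: frozenset[int]


@dataclass
class HaplotypeMatch:
    peak_i: HaplotypePeak
    peak_j: HaplotypePeak
    jaccard: float
    same_haplotype: bool


@dataclass
class HaplotypeGroup:
    """A connected component of matched peaks: one inferred haplotype."""

    peaks: list[HaplotypePeak] = field(default_factory=list)

    @property
    def mean_snp_count(self) -> float:
        return float(np.mean([p.snp_count for p in self.peaks]))

    @property
    def pool_frequencies(self) -> dict[str, float]:
        return {p.pool_id: p.freq_estimate for p in self.peaks}


def bin_frequencies(
    snps: pd.DataFrame, bin_width: float = 0.10, pool_id: str | None = None
) -> FreqHistogram:
    """Tally SNPs into allele-frequency bins spanning (0.05, 1.05) by default.

    Bins are half-open [c - w/2, c + w/2) with lower edge inclusive and the
    top bin closed at 1.0; SNPs below the lowest edge are dropped. Centers
    are the multiples of ``bin_width`` from w to 1.0, so the span must divide
    evenly into bins.
    """
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide (w/2, 1+w/2] evenly")
    if pool_id is None:
        ids = snps["pool_id"].unique() if "pool_id" in snps.columns else [""]
        if len(ids) > 1:
            raise ValueError("multiple pools in input; pass pool_id")
        pool_id = str(ids[0]) if len(ids) else ""
    f = snps["alt_freq"].to_numpy(dtype=float)
    pos = snps["pos"].to_numpy()
    if np.any((f <= 0) | (f > 1)):
        raise ValueError("alt_freq must lie in (0, 1]")
    # index via lower-edge-inclusive rule; guard float edges
    idx = np.floor((f + bin_width / 2) / bin_width + 1e-9).astype(int) - 1
    keep = idx >= 0
    idx = np.clip(idx, 0, n_bins - 1)  # top bin closed at 1.0
    centers = np.round(bin_width * np.arange(1, n_bins + 1), 10)
    counts = np.bincount(idx[keep], minlength=n_bins)
    members = [np.sort(pos[keep & (idx == k)]) for k in range(n_bins)]
    return FreqHistogram(pool_id, bin_width, centers, counts, members)


def detect_peaks(hist: FreqHistogram, min_snps: int = 30) -> list[HaplotypePeak]:
    """Peaks = bins with >= min_snps SNPs strictly exceeding both neighbors.

    Missing neighbors count as 0. The 1.0 bin (a haplotype fixed in the
    pool) is always reported when it meets the support threshold, local
    maximum or not. Returned sorted by SNP count, descending.
    """
    counts = hist.counts
    n = len(counts)
    peaks = []
    for k in range(n):
        left = counts[k - 1] if k > 0 else 0
        right = counts[k + 1] if k < n - 1 else 0
        is_top_bin = k == n - 1 and np.isclose(hist.centers[k], 1.0)
        if counts[k] >= min_snps and (counts[k] > left and counts[k] > right or is_top_bin):
            peaks.append(HaplotypePeak(
                pool_id=hist.pool_id,
                freq_estimate=float(hist.centers[k]),
                snp_count=int(counts[k]),
                snp_set=frozenset(int(p) for p in hist.members[k]),
            ))
    return sorted(peaks, key=lambda p: -p.snp_count)


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a or not b:
        raise ValueError("empty SNP set")
    return len(a & b) / len(a | b)


def match_peaks(
    peaks: list[HaplotypePeak], jaccard_threshold: float = 0.5
) -> tuple[list[HaplotypeMatch], list[HaplotypeGroup]]:
    """Match peaks across pools by SNP-set Jaccard similarity.

    Peaks from different pools with Jaccard >= threshold are declared the
    same haplotype; haplotype groups are the connected components of the
    match graph (singleton peaks form their own group).
    """
    matches = []
    parent = list(range(len(peaks)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(len(peaks)), 2):
        if peaks[i].pool_id == peaks[j].pool_id:
            continue
        jac = jaccard(peaks[i].snp_set, peaks[j].snp_set)
        same = jac >= jaccard_threshold
        matches.append(HaplotypeMatch(peaks[i], peaks[j], jac, same))
        if same:
            parent[find(i)] = find(j)

    groups: dict[int, HaplotypeGroup] = {}
    for i, pk in enumerate(peaks):
        groups.setdefault(find(i), HaplotypeGroup()).peaks.append(pk)
    return matches, list(groups.values())
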