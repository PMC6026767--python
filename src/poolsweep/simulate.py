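"""Synthetic pool-seq data with known truth.

The generator is a deliberately simple, coalescent-free stand-in for two
diverged gene pools of a partially domesticated tree: ancestral alternate-allele
frequencies are drawn from a Beta law shared by all groups, selective sweeps
perturb the target group's frequencies inside fixed genomic intervals, and
pooled sequencing is emulated by binomial chromosome sampling followed by
Poisson read depth and binomial read sampling with a symmetric error rate.
Downstream window statistics respond only to the site-frequency spectrum, so
no linkage or haplotype structure is simulated.

Default pool structure mirrors a published pool-seq design for Chinese
chestnut: ten pools of 9–13 diploid trees at roughly 4–15x expected depth,
split into orchard and wild (northern/southern) groups.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("orchard", "wild_north", "wild_south")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PoolSpec:
    """One sequencing pool: several diploid individuals sequenced together."""

    pool_id: str
    group: str
    n_individuals: int
    mean_depth: float

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError(f"pool {self.pool_id}: n_individuals must be >= 2")
        if self.mean_depth <= 0:
            raise ValueError(f"pool {self.pool_id}: mean_depth must be > 0")
        if self.group not in GROUPS:
            raise ValueError(f"pool {self.pool_id}: unknown group {self.group!r}")


@dataclass(frozen=True)
class SweepSpec:
    """A localized sweep: reduced diversity / elevated fixation in one group.

    ``fixation_shift`` moves the target group's alternate frequency toward the
    nearer boundary: p' = p*(1-s) if p < 0.5 else p + (1-p)*s.
    ``diversity_reduction`` then scales expected heterozygosity by (1-d),
    moving p' further toward its boundary so that 2p''(1-p'') = (1-d)*2p'(1-p').
    """

    lg: str
    start_bp: int
    end_bp: int
    target_group: str
    diversity_reduction: float = 0.9
    fixation_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError(f"sweep on {self.lg}: start_bp must be < end_bp")
        for name in ("diversity_reduction", "fixation_shift"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"sweep on {self.lg}: {name} must be in [0, 1]")
        if self.target_group not in GROUPS:
            raise ValueError(f"sweep on {self.lg}: unknown group {self.target_group!r}")


def default_pools() -> list[PoolSpec]:
    """The ten-pool design the simulator emulates by default.

    Numbers of individuals and expected depths follow the published pool
    table (wild forest pools from Yunnan/Guizhou in the south and Shaanxi in
    the north; orchard pools from Shaanxi, Hebei, Beijing and a US orchard
    derived from northern Chinese cultivars).
    """
    return [
        PoolSpec("Y1", "wild_south", 9, 9.46),
        PoolSpec("Y2", "wild_south", 10, 14.89),
        PoolSpec("S1", "wild_north", 13, 9.42),
        PoolSpec("S2", "wild_north", 10, 11.06),
        PoolSpec("S3", "wild_north", 10, 7.19),
        PoolSpec("S4", "orchard", 10, 12.68),
        PoolSpec("GZ", "wild_south", 10, 11.02),
        PoolSpec("HB", "orchard", 10, 7.92),
        PoolSpec("BY", "orchard", 10, 6.72),
        PoolSpec("ECC", "orchard", 12, 4.49),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_linkage_groups: int = 2
    lg_length_bp: int = 1_000_000
    snp_density: float = 0.005
    window_size_bp: int = 10_000
    n_genes: int = 200
    gene_length_bp: int = 2_000
    pools: list[PoolSpec] = field(default_factory=default_pools)
    sweeps: list[SweepSpec] = field(default_factory=list)
    base_freq_alpha: float = 0.8
    base_freq_beta: float = 0.8
    seq_error_rate: float = 0.001

    def __post_init__(self) -> None:
        for name in ("n_linkage_groups", "lg_length_bp", "window_size_bp",
                     "n_genes", "gene_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be positive")
        if not 0.0 <= self.seq_error_rate <= 0.1:
            raise ValueError("seq_error_rate must be in [0, 0.1]")
        if self.base_freq_alpha <= 0 or self.base_freq_beta <= 0:
            raise ValueError("Beta shape parameters must be positive")
        self._check_sweep_overlap()

    def _check_sweep_overlap(self) -> None:
        by_key: dict[tuple[str, str], list[SweepSpec]] = {}
        for sw in self.sweeps:
            by_key.setdefault((sw.lg, sw.target_group), []).append(sw)
        for (lg, group), sweeps in by_key.items():
            sweeps = sorted(sweeps, key=lambda s: s.start_bp)
            for a, b in zip(sweeps, sweeps[1:]):
                if b.start_bp < a.end_bp:
                    raise ValueError(
                        f"overlapping sweeps for group {group} on {lg}: "
                        f"[{a.start_bp}, {a.end_bp}) and [{b.start_bp}, {b.end_bp})"
                    )

    @property
    def lg_names(self) -> list[str]:
        return [f"lg{i + 1}" for i in range(self.n_linkage_groups)]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for p in self.pools:
            if p.group not in seen:
                seen.append(p.group)
        return seen


def _pool_seed(config: SimulationConfig, tag: str) -> int:
    # stable per-pool/per-purpose substream, below 2^31
    return (config.seed * 1_000_003 + zlib.crc32(tag.encode())) % (2**31 - 1)


def shift_toward_boundary(p: np.ndarray, shift: float) -> np.ndarray:
    """Move frequencies toward the nearer of {0, 1} by fraction ``shift``."""
    p = np.asarray(p, dtype=float)
    return np.where(p < 0.5, p * (1.0 - shift), p + (1.0 - p) * shift)


def compress_heterozygosity(p: np.ndarray, reduction: float) -> np.ndarray:
    """Rescale p so expected heterozygosity 2p(1-p) shrinks by ``reduction``.

    The root on the same side of 0.5 as the input is taken, so the transform
    is a pure compression toward the nearer boundary and is exact:
    2p'(1-p') = (1-reduction) * 2p(1-p).
    """
    p = np.asarray(p, dtype=float)
    h = (1.0 - reduction) * p * (1.0 - p)
    root = np.sqrt(np.maximum(0.0, 1.0 - 4.0 * h))
    return np.where(p <= 0.5, (1.0 - root) / 2.0, (1.0 + root) / 2.0)


def simulate_group_frequencies(config: SimulationConfig) -> pd.DataFrame:
    """True per-site alternate-allele frequencies per group.

    Sites are placed uniformly at the expected SNP density on each linkage
    group; the base frequency is Beta(alpha, beta) and shared across groups
    outside sweeps. Within a sweep the target group's frequency is shifted
    toward the nearer boundary (``fixation_shift``) and its heterozygosity
    compressed (``diversity_reduction``).

    Returns a frame with columns chrom, pos (1-based), ref_allele, alt_allele
    and one frequency column per group (``freq_<group>``).
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    for lg in config.lg_names:
        n_sites = rng.poisson(config.snp_density * config.lg_length_bp)
        pos = np.sort(rng.choice(config.lg_length_bp, size=n_sites, replace=False)) + 1
        base = rng.beta(config.base_freq_alpha, config.base_freq_beta, size=n_sites)
        ref_idx = rng.integers(0, 4, size=n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
        df = pd.DataFrame({
            "chrom": lg,
            "pos": pos.astype(np.int64),
            "ref_allele": _BASES[ref_idx],
            "alt_allele": _BASES[alt_idx],
        })
        for group in config.groups:
            df[f"freq_{group}"] = base
        frames.append(df)
    freqs = pd.concat(frames, ignore_index=True)

    for sw in config.sweeps:
        col = f"freq_{sw.target_group}"
        if col not in freqs.columns:
            raise ValueError(f"sweep targets unknown group {sw.target_group!r}")
        mask = (
            (freqs["chrom"] == sw.lg)
            & (freqs["pos"] > sw.start_bp)
            & (freqs["pos"] <= sw.end_bp)
        )
        p = freqs.loc[mask, col].to_numpy()
        p = shift_toward_boundary(p, sw.fixation_shift)
        p = compress_heterozygosity(p, sw.diversity_reduction)
        freqs.loc[mask, col] = p
    return freqs


def simulate_pool_readcounts(
    freqs: pd.DataFrame,
    pool: PoolSpec,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pooled read counts for one pool.

    Per site: 2*n_individuals chromosomes are drawn from the group frequency,
    a read depth is drawn Poisson(mean_depth), and alternate reads are drawn
    binomially from the realized pool frequency with symmetric per-read error.
    Deterministic given the config seed (or an explicit ``seed``).
    """
    col = f"freq_{pool.group}"
    if col not in freqs.columns:
        raise ValueError(f"group {pool.group!r} not present in frequency table")
    if pool.mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = np.random.default_rng(
        _pool_seed(config, f"pool:{pool.pool_id}") if seed is None else seed
    )
    p = freqs[col].to_numpy()
    n_chrom = 2 * pool.n_individuals
    alt_chrom = rng.binomial(n_chrom, p)
    q = alt_chrom / n_chrom
    depth = rng.poisson(pool.mean_depth, size=len(p))
    e = config.seq_error_rate
    read_p = q * (1.0 - e) + (1.0 - q) * e
    alt_count = rng.binomial(depth, read_p)
    return pd.DataFrame({
        "chrom": freqs["chrom"].to_numpy(),
        "pos": freqs["pos"].to_numpy(),
        "ref_allele": freqs["ref_allele"].to_numpy(),
        "alt_allele": freqs["alt_allele"].to_numpy(),
        "ref_count": (depth - alt_count).astype(np.int64),
        "alt_count": alt_count.astype(np.int64),
        "pool_id": pool.pool_id,
    })


def simulate_individual_genotypes(
    freqs: pd.DataFrame, group: str, n_individuals: int, seed: int
) -> np.ndarray:
    """Hardy–Weinberg diploid genotypes (individuals x sites, values 0/1/2)."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    col = f"freq_{group}"
    if col not in freqs.columns:
        raise ValueError(f"group {group!r} not present in frequency table")
    rng = np.random.default_rng(seed)
    p = freqs[col].to_numpy()
    return rng.binomial(2, p, size=(n_individuals, len(p))).astype(np.int8)


def simulate_chloroplast_pool(
    haplotypes: list[tuple[set[int], float]],
    n_copies: int,
    depth: int | None = None,
    error: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-site alternate-allele frequencies for a pooled organelle sample.

    Each haplotype is a set of variant positions (vs the reference) plus a
    population frequency; the remainder of the pool carries the reference.
    Copies are assigned by largest-remainder rounding of frequency*n_copies,
    so a haplotype at 0.30 in a 10-copy pool contributes exactly 3 carriers.
    When ``depth`` is given, frequencies are re-estimated from binomially
    sampled reads with symmetric error.

    Returns a frame with columns pos, alt_freq (only sites with alt_freq > 0).
    """
    total = sum(f for _, f in haplotypes)
    if total > 1.0 + 1e-9:
        raise ValueError(f"haplotype frequencies sum to {total:.4f} > 1")
    quotas = [f * n_copies for _, f in haplotypes] + [(1.0 - total) * n_copies]
    copies = [int(np.floor(q + 1e-9)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, copies)]
    for i in sorted(range(len(quotas)), key=lambda i: -remainders[i]):
        if sum(copies) >= n_copies:
            break
        copies[i] += 1

    carrier: dict[int, int] = {}
    for (sites, _), c in zip(haplotypes, copies):
        for pos in sites:
            carrier[pos] = carrier.get(pos, 0) + c
    pos = np.array(sorted(carrier), dtype=np.int64)
    freq = np.array([carrier[p] / n_copies for p in pos])

    if depth is not None:
        rng = np.random.default_rng(seed)
        read_p = freq * (1.0 - error) + (1.0 - freq) * error
        alt = rng.binomial(depth, read_p)
        freq = alt / depth
    out = pd.DataFrame({"pos": pos, "alt_freq": freq})
    return out[out["alt_freq"] > 0].reset_index(drop=True)


def make_genes(config: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced non-overlapping gene intervals across the linkage groups.

    Coordinates are 0-based half-open. All genes are flagged annotated; tests
    and the fixation scan may flip the flag on a subset.
    """
    per_lg = config.n_genes // config.n_linkage_groups
    extra = config.n_genes % config.n_linkage_groups
    rows = []
    gid = 0
    for i, lg in enumerate(config.lg_names):
        n = per_lg + (1 if i < extra else 0)
        if n == 0:
            continue
        spacing = config.lg_length_bp // n
        if spacing < config.gene_length_bp:
            raise ValueError("genes do not fit: reduce n_genes or gene_length_bp")
        for j in range(n):
            start = j * spacing
            rows.append({
                "gene_id": f"{lg}_g{gid}",
                "chrom": lg,
                "start": start,
                "end": start + config.gene_length_bp,
                "annotated": True,
            })
            gid += 1
    return pd.DataFrame(rows)


def _overlaps(start: int, end: int, sweeps: list[SweepSpec], lg: str) -> tuple[bool, str]:
    for sw in sweeps:
        if sw.lg == lg and start < sw.end_bp and sw.start_bp < end:
            return True, sw.target_group
    return False, ""


def build_truth_table(config: SimulationConfig, genes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Ground-truth labels: every window and gene exactly once, with sweep flags."""
    rows = []
    n_windows = config.lg_length_bp // config.window_size_bp
    for lg in config.lg_names:
        for w in range(n_windows):
            start = w * config.window_size_bp
            end = start + config.window_size_bp
            swept, grp = _overlaps(start, end, config.sweeps, lg)
            rows.append({
                "record_type": "window", "record_id": f"{lg}:{start}-{end}",
                "chrom": lg, "start": start, "end": end,
                "swept": swept, "target_group": grp,
            })
    if genes is None:
        genes = make_genes(config)
    for g in genes.itertuples():
        swept, grp = _overlaps(g.start, g.end, config.sweeps, g.chrom)
        rows.append({
            "record_type": "gene", "record_id": g.gene_id,
            "chrom": g.chrom, "start": g.start, "end": g.end,
            "swept": swept, "target_group": grp,
        })
    return pd.DataFrame(rows)
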