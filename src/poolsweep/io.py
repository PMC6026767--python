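"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions: all in-memory tables are 0-based half-open for
intervals and 1-based for point positions (matching VCF/pileup); TSV reports
are written with explicit headers and 1-based inclusive interval columns
where noted. PoPoolation2 sync lines carry per-pool A:T:C:G:N:del count
strings; biallelic collapse keeps the two highest summed-count bases (ties
broken A<C<G<T), orients ref to the file's reference column, and excludes
N/del from depth.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .validation import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_BASE_ORDER = "ATCG"  # column order in sync count strings
_TIE_ORDER = {b: i for i, b in enumerate("ACGT")}


# ---------------------------------------------------------------- sync

def read_sync(path: str | Path, pool_ids: list[str]) -> pd.DataFrame:
    """Parse a PoPoolation2 sync file into a long per-pool SiteCounts table.

    Collapse to two alleles: the two bases with the highest counts summed
    across pools (ties by A<C<G<T); ref is the file's reference base, alt the
    highest-count base other than ref.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 + len(pool_ids):
                raise ValueError(
                    f"{path}: line {ln}: expected {3 + len(pool_ids)} fields "
                    f"({len(pool_ids)} pools), found {len(fields)}"
                )
            chrom, pos_s, ref = fields[:3]
            counts = np.zeros((len(pool_ids), 4), dtype=np.int64)
            for i, f in enumerate(fields[3:]):
                parts = f.split(":")
                if len(parts) != 6:
                    raise ValueError(f"{path}: line {ln}: malformed count string {f!r}")
                try:
                    counts[i] = [int(x) for x in parts[:4]]  # A,T,C,G; drop N/del
                except ValueError as exc:
                    raise ValueError(f"{path}: line {ln}: malformed count string {f!r}") from exc
            total = counts.sum(axis=0)
            order = sorted(range(4), key=lambda k: (-total[k], _TIE_ORDER[_BASE_ORDER[k]]))
            top2 = [_BASE_ORDER[k] for k in order[:2]]
            ref = ref.upper()
            if ref in top2:
                alt = top2[0] if top2[1] == ref else top2[1]
            else:
                alt = top2[0]
            ri = _BASE_ORDER.index(ref) if ref in _BASE_ORDER else None
            ai = _BASE_ORDER.index(alt)
            for i, pid in enumerate(pool_ids):
                rows.append((chrom, int(pos_s), ref, alt,
                             int(counts[i, ri]) if ri is not None else 0,
                             int(counts[i, ai]), pid))
    return pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref_allele", "alt_allele", "ref_count", "alt_count", "pool_id",
    ])


def write_sync(sites: pd.DataFrame, path: str | Path, pool_ids: list[str] | None = None) -> None:
    """Write a long per-pool SiteCounts table as PoPoolation2 sync."""
    if pool_ids is None:
        pool_ids = list(dict.fromkeys(sites["pool_id"]))
    wide = sites.pivot_table(
        index=["chrom", "pos", "ref_allele", "alt_allele"],
        columns="pool_id", values=["ref_count", "alt_count"], fill_value=0,
        aggfunc="sum",
    )
    with open(path, "w") as fh:
        for (chrom, pos, ref, alt), row in wide.sort_index().iterrows():
            cols = []
            for pid in pool_ids:
                c = dict.fromkeys(_BASE_ORDER, 0)
                c[ref] = int(row[("ref_count", pid)])
                c[alt] = c.get(alt, 0) + int(row[("alt_count", pid)])
                cols.append(":".join(str(c[b]) for b in _BASE_ORDER) + ":0:0")
            fh.write("\t".join([chrom, str(pos), ref, *cols]) + "\n")


# ---------------------------------------------------------------- pileup

def read_pileup(path: str | Path, pool_id: str = "") -> pd.DataFrame:
    """Parse 6-column samtools pileup into a SiteCounts table.

    '.'/',' count as reference reads; ACGT characters as alternate reads
    (alt allele = the most common non-reference base). ^X, $, * and +n/-n
    indel notations are consumed; base qualities are ignored.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}: line {ln}: expected >= 5 pileup columns")
            chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
            bases = fields[4]
            ref_n = 0
            alt_counts: dict[str, int] = {}
            i = 0
            while i < len(bases):
                ch = bases[i]
                if ch == "^":
                    i += 2
                    continue
                if ch in "$*<>":
                    i += 1
                    continue
                if ch in "+-":
                    j = i + 1
                    while j < len(bases) and bases[j].isdigit():
                        j += 1
                    i = j + int(bases[i + 1:j])
                    continue
                if ch in ".,":
                    ref_n += 1
                else:
                    b = ch.upper()
                    if b in "ACGT":
                        alt_counts[b] = alt_counts.get(b, 0) + 1
                i += 1
            if alt_counts:
                alt = min(alt_counts, key=lambda b: (-alt_counts[b], _TIE_ORDER[b]))
                alt_n = alt_counts[alt]
            else:
                alt, alt_n = "N", 0
            rows.append((chrom, int(pos_s), ref, alt, ref_n, alt_n, pool_id))
    return pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref_allele", "alt_allele", "ref_count", "alt_count", "pool_id",
    ])


def write_pileup(sites: pd.DataFrame, path: str | Path) -> None:
    """Write one pool's SiteCounts as minimal 6-column pileup."""
    with open(path, "w") as fh:
        for r in sites.itertuples():
            bases = "." * int(r.ref_count) + r.alt_allele * int(r.alt_count)
            quals = "I" * (int(r.ref_count) + int(r.alt_count))
            fh.write(f"{r.chrom}\t{r.pos}\t{r.ref_allele}\t"
                     f"{r.ref_count + r.alt_count}\t{bases}\t{quals}\n")


# ---------------------------------------------------------------- VCF

def write_vcf(
    genotypes: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    ref: np.ndarray,
    alt: np.ndarray,
    samples: list[str],
    path: str | Path,
) -> None:
    """Write a diploid genotype matrix (individuals x sites, 0/1/2/-1) as VCFv4.2."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j in range(len(pos)):
            gts = "\t".join(gt_str[int(g)] for g in genotypes[:, j])
            fh.write(f"{chrom[j]}\t{pos[j]}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf_genotypes(path: str | Path, group_map: dict[str, str]) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF into a GenotypeMatrix.

    ``group_map`` maps sample name -> group label; every mapped sample must
    be present in the header. Non-biallelic or non-SNP records are skipped
    (tallied in the log); phased and unphased genotypes are equivalent.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    missing = set(group_map) - set(samples)
    if missing:
        raise ValueError(f"samples in group map absent from VCF header: {sorted(missing)}")
    keep = [i for i, s in enumerate(samples) if s in group_map]
    kept_samples = [samples[i] for i in keep]
    chroms, positions, gts = [], [], []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        g = rec.gt_types[keep].astype(np.int8)  # 0/1/2, 3 = unknown
        g[g == 3] = MISSING
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        gts.append(g)
    if skipped:
        logger.info("read_vcf_genotypes: skipped %d non-biallelic-SNP records", skipped)
    genotypes = np.array(gts, dtype=np.int8).T if gts else \
        np.zeros((len(keep), 0), dtype=np.int8)
    return GenotypeMatrix(
        genotypes=genotypes,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        samples=kept_samples,
        groups=[group_map[s] for s in kept_samples],
    )


# ---------------------------------------------------------------- intervals

def read_intervals(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read gene intervals from BED6 or GFF3 into 0-based half-open records.

    BED is 0-based half-open (name column = gene id; score > 0 marks the gene
    as annotated). GFF3 is 1-based inclusive; ``gene`` features are taken,
    with the id from the ID attribute and annotated unless attribute
    annotated=0. Output is sorted by (chrom, start), stable.
    """
    path = Path(path)
    if dialect is None:
        dialect = "GFF3" if path.suffix.lower() in {".gff", ".gff3"} else "BED"
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if dialect == "BED":
                start, end = int(f[1]), int(f[2])
                gene_id = f[3] if len(f) > 3 else f"{f[0]}:{start}-{end}"
                annotated = True if len(f) <= 4 else float(f[4]) > 0
                chrom = f[0]
            else:
                if len(f) < 9 or f[2] != "gene":
                    continue
                chrom = f[0]
                start, end = int(f[3]) - 1, int(f[4])
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gene_id = attrs.get("ID", f"{chrom}:{start}-{end}")
                annotated = attrs.get("annotated", "1") != "0"
            if start >= end:
                raise ValueError(f"{path}: line {ln}: start >= end after conversion")
            rows.append({"gene_id": gene_id, "chrom": chrom, "start": start,
                         "end": end, "annotated": annotated})
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "annotated"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene intervals as BED6 (score column = annotated flag)."""
    with open(path, "w") as fh:
        for g in genes.itertuples():
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t"
                     f"{1 if g.annotated else 0}\t+\n")


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            ann = "" if g.annotated else ";annotated=0"
            fh.write(f"{g.chrom}\tpoolsweep\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t"
                     f"ID={g.gene_id}{ann}\n")


# ---------------------------------------------------------------- TSV reports

def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_window_stats(stats: pd.DataFrame, path: str | Path) -> None:
    """Window stats TSV: chrom, start_1based, end, group, S, pi, pi_per_bp, D, n_sites."""
    out = stats.copy()
    out.insert(1, "start_1based", out.pop("start") + 1)
    write_tsv(out, path)


def read_window_stats(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    df.insert(1, "start", df.pop("start_1based") - 1)
    return df
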