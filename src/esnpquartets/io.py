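"""Readers, writers and genotype quality filters.

Genotypes come from a VCF (GT field, biallelic records only) or a TSV
dosage matrix (first three columns ``snp_id``, ``chrom``, ``pos``; the
remaining header fields are sample IDs).  Expression is a TSV of genes
x samples (orientation auto-detected when the genotype sample IDs are
supplied).  Interval annotations are BED, 0-based half-open on disk,
converted to 1-based inclusive internally.

Quality filters applied to genotypes, iterated to a fixed point:

* minor allele frequency > 0.05 (strict),
* per-SNP missingness < 0.1,
* per-sample missingness < 0.1.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .datatypes import (
    ExpressionMatrix,
    GeneRecord,
    GenotypeMatrix,
    SnpRecord,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

MAF_MIN = 0.05          # strict: a SNP at exactly 0.05 is removed
SNP_MISS_MAX = 0.1      # strict: per-SNP missingness must be < 0.1
SAMPLE_MISS_MAX = 0.1   # strict: per-sample missingness must be < 0.1


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


class EmptyDatasetError(ValueError):
    """No SNPs (or samples) survive filtering."""


# ---------------------------------------------------------------------------
# BED intervals

def read_bed(path: str | Path) -> dict[str, IntervalTree]:
    """Read a 3+ column BED file into per-chromosome interval trees.

    BED is 0-based half-open; intervals are stored 1-based inclusive,
    so a BED line ``chr1  99  200`` covers positions 100..200.
    """
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has <3 columns")
            chrom = normalize_chrom(parts[0])
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if end0 <= start0:
                continue
            # 1-based inclusive: [start0+1, end0]; IntervalTree is half-open
            trees.setdefault(chrom, IntervalTree()).addi(start0 + 1, end0 + 1)
    return trees


def _in_intervals(trees: dict[str, IntervalTree], chrom: str, pos: int) -> bool:
    tree = trees.get(normalize_chrom(chrom))
    return bool(tree is not None and tree.overlaps_point(pos))


def categorize_snp(
    chrom: str,
    pos: int,
    exon_trees: dict[str, IntervalTree],
    tf_trees: dict[str, IntervalTree],
) -> str:
    """Annotation category: exon / tf / both / other by span containment."""
    in_exon = _in_intervals(exon_trees, chrom, pos)
    in_tf = _in_intervals(tf_trees, chrom, pos)
    if in_exon and in_tf:
        return "both"
    if in_exon:
        return "exon"
    if in_tf:
        return "tf"
    return "other"


# ---------------------------------------------------------------------------
# Genotypes

def _read_genotype_tsv(path: Path) -> tuple[list[str], list[tuple[str, str, int]], np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 4:
        raise FormatError(f"{path}: dosage TSV needs snp_id, chrom, pos + >=1 sample")
    expected = ["snp_id", "chrom", "pos"]
    if [c.lower() for c in df.columns[:3]] != expected:
        raise FormatError(
            f"{path}:1: first three columns must be {expected}, got {list(df.columns[:3])}"
        )
    samples = [str(c) for c in df.columns[3:]]
    meta = []
    for i, row in enumerate(df.itertuples(index=False), 2):
        try:
            meta.append((str(row[0]), str(row[1]), int(row[2])))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}:{i}: bad snp metadata") from exc
    counts = df.iloc[:, 3:].to_numpy(dtype=float).T  # samples x snps
    bad = counts[~np.isnan(counts)]
    if bad.size and (np.any(bad < 0) or np.any(bad > 2)):
        raise FormatError(f"{path}: dosage values must lie in [0, 2] or be NA")
    ids = [m[0] for m in meta]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate SNP identifiers")
    return samples, meta, counts


def _read_genotype_vcf(path: Path) -> tuple[list[str], list[tuple[str, str, int]], np.ndarray]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    meta: list[tuple[str, str, int]] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = var.gt_types.astype(float)
        alt_count = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        # cohort-relative minor allele; tie at 0.5 -> alphabetically first allele
        with np.errstate(invalid="ignore"):
            alt_freq = np.nanmean(alt_count) / 2.0
        flip = alt_freq > 0.5 or (
            np.isclose(alt_freq, 0.5) and sorted([var.REF, var.ALT[0]])[0] == var.REF
        )
        meta.append((vid, str(var.CHROM), int(var.POS)))
        rows.append(2.0 - alt_count if flip else alt_count)
    if n_multi:
        logger.warning("%s: skipped %d multiallelic records", path, n_multi)
    if not rows:
        raise EmptyDatasetError(f"{path}: no biallelic records")
    return samples, meta, np.vstack(rows).T


def _nanmean_cols(counts: np.ndarray) -> np.ndarray:
    """Column nanmean that returns NaN (silently) for all-missing columns."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(counts, axis=0)


def _orient_minor(counts: np.ndarray) -> np.ndarray:
    """Flip count columns so the stored allele is the cohort minor allele."""
    freq = _nanmean_cols(counts) / 2.0
    flip = freq > 0.5
    out = counts.copy()
    out[:, flip] = 2.0 - out[:, flip]
    return out


def compute_maf(counts: np.ndarray) -> np.ndarray:
    """Per-SNP minor-allele frequency from a (samples x snps) count matrix."""
    freq = _nanmean_cols(counts) / 2.0
    return np.minimum(freq, 1.0 - freq)


def apply_quality_filters(
    samples: list[str], counts: np.ndarray
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Iterate MAF / SNP-missingness / sample-missingness filters to a fixed point.

    Returns (kept samples, kept counts, boolean mask over original SNPs).
    The iteration makes the result independent of filter application
    order: dropping samples changes per-SNP MAF and missingness, so the
    checks are repeated until nothing more is removed.
    """
    sample_mask = np.ones(counts.shape[0], dtype=bool)
    snp_mask = np.ones(counts.shape[1], dtype=bool)
    while True:
        sub = counts[np.ix_(sample_mask, snp_mask)]
        if sub.size == 0:
            break
        snp_miss = np.mean(np.isnan(sub), axis=0)
        maf = compute_maf(sub)
        with np.errstate(invalid="ignore"):
            drop_snp = (snp_miss >= SNP_MISS_MAX) | ~(maf > MAF_MIN)
        sample_miss = np.mean(np.isnan(sub[:, ~drop_snp]), axis=1) if (~drop_snp).any() else np.zeros(sub.shape[0])
        drop_sample = sample_miss >= SAMPLE_MISS_MAX
        if not drop_snp.any() and not drop_sample.any():
            break
        snp_idx = np.flatnonzero(snp_mask)
        snp_mask[snp_idx[drop_snp]] = False
        sample_idx = np.flatnonzero(sample_mask)
        sample_mask[sample_idx[drop_sample]] = False
    kept_samples = [s for s, keep in zip(samples, sample_mask) if keep]
    return kept_samples, counts[np.ix_(sample_mask, snp_mask)], snp_mask


def load_genotypes(
    path: str | Path,
    exon_bed_path: str | Path | None = None,
    tf_bed_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Load, quality-filter and annotate a genotype matrix.

    ``path`` may be a VCF (``.vcf``/``.vcf.gz``) or a dosage TSV.  SNPs
    outside all exon/TF spans are labeled "other" and retained; they are
    excluded from association-source candidacy downstream but can still
    serve as intermediate-SNP candidates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        samples, meta, counts = _read_genotype_vcf(path)
    else:
        samples, meta, counts = _read_genotype_tsv(path)
    counts = _orient_minor(counts)
    samples, counts, snp_mask = apply_quality_filters(samples, counts)
    kept_meta = [m for m, keep in zip(meta, snp_mask) if keep]
    if not kept_meta:
        raise EmptyDatasetError(f"{path}: zero SNPs survive quality filters")
    n_dropped = len(meta) - len(kept_meta)
    if n_dropped:
        logger.info("%s: %d SNPs removed by quality filters", path, n_dropped)

    exon_trees = read_bed(exon_bed_path) if exon_bed_path else {}
    tf_trees = read_bed(tf_bed_path) if tf_bed_path else {}
    maf = compute_maf(counts)
    snps = [
        SnpRecord(
            snp_id=sid,
            chrom=chrom,
            pos=pos,
            maf=float(m),
            category=categorize_snp(chrom, pos, exon_trees, tf_trees),
        )
        for (sid, chrom, pos), m in zip(kept_meta, maf)
    ]
    return GenotypeMatrix(samples=samples, snps=snps, counts=counts)


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a dosage TSV that :func:`load_genotypes` re-loads identically."""
    df = pd.DataFrame(
        geno.counts.T,
        columns=geno.samples,
    )
    df.insert(0, "pos", [s.pos for s in geno.snps])
    df.insert(0, "chrom", [s.chrom for s in geno.snps])
    df.insert(0, "snp_id", [s.snp_id for s in geno.snps])
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Expression

def read_gene_bed(path: str | Path) -> dict[str, GeneRecord]:
    """Gene spans from a BED file whose 4th column is the gene ID."""
    records: dict[str, GeneRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: gene BED needs 4 columns (incl. name)")
            chrom, start0, end0, gene_id = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if gene_id in records:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            records[gene_id] = GeneRecord(
                gene_id=gene_id, chrom=normalize_chrom(chrom), start=start0 + 1, end=end0
            )
    return records


def load_expression(
    tsv_path: str | Path,
    gene_bed_path: str | Path,
    sample_ids: list[str] | None = None,
) -> ExpressionMatrix:
    """Load an expression TSV (genes x samples or transposed).

    Orientation is auto-detected by matching row/column labels against
    ``sample_ids`` (typically the genotype samples); ambiguity (labels
    matching on both axes, or neither) is an error.  With
    ``sample_ids=None`` rows are assumed to be genes.  Genes without a
    span in ``gene_bed_path``, or with missing values, are dropped with
    a logged count.
    """
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if sample_ids is not None:
        wanted = set(sample_ids)
        cols_match = len(wanted & set(df.columns))
        rows_match = len(wanted & set(df.index))
        if rows_match > cols_match:
            df = df.T
        elif rows_match == cols_match:
            if cols_match == 0:
                raise ValueError(
                    f"{tsv_path}: no overlapping sample IDs with the genotype matrix"
                )
            raise ValueError(f"{tsv_path}: ambiguous orientation (sample IDs on both axes)")
    # now rows = genes, columns = samples
    gene_spans = read_gene_bed(gene_bed_path)
    present = [g for g in df.index if g in gene_spans]
    n_no_span = df.shape[0] - len(present)
    if n_no_span:
        logger.warning("%s: dropped %d genes without a span in the gene BED", tsv_path, n_no_span)
    df = df.loc[present]
    has_missing = df.isna().any(axis=1)
    if has_missing.any():
        logger.warning("%s: dropped %d genes with missing values", tsv_path, int(has_missing.sum()))
        df = df.loc[~has_missing]
    genes = [gene_spans[g] for g in df.index]
    return ExpressionMatrix(
        samples=[str(c) for c in df.columns],
        genes=genes,
        values=df.to_numpy(dtype=float).T,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        expr.values.T,
        index=[g.gene_id for g in expr.genes],
        columns=expr.samples,
    )
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sample intersection

MIN_SHARED_SAMPLES = 10


def intersect_samples(
    geno: GenotypeMatrix, expr: ExpressionMatrix
) -> tuple[GenotypeMatrix, ExpressionMatrix]:
    """Restrict both matrices to shared samples in one canonical order.

    The canonical order is the genotype matrix's sample order filtered
    to the intersection.  The minor allele and MAF are recomputed on the
    intersected cohort.  Fewer than 10 shared samples is an error: the
    conditional regressions downstream need residual degrees of freedom.
    """
    shared = [s for s in geno.samples if s in set(expr.samples)]
    if len(shared) < MIN_SHARED_SAMPLES:
        raise ValueError(
            f"only {len(shared)} shared samples; need >= {MIN_SHARED_SAMPLES}"
        )
    g = geno.subset_samples(shared)
    e = expr.subset_samples(shared)
    counts = _orient_minor(g.counts)
    maf = compute_maf(counts)
    snps = [
        SnpRecord(s.snp_id, s.chrom, s.pos, float(m), s.category)
        for s, m in zip(g.snps, maf)
    ]
    return GenotypeMatrix(samples=shared, snps=snps, counts=counts), e


def check_id_collisions(geno: GenotypeMatrix, expr: ExpressionMatrix) -> None:
    """SNP/gene identifier collisions across input files are a hard error."""
    snp_ids = {s.snp_id for s in geno.snps}
    gene_ids = {g.gene_id for g in expr.genes}
    clash = snp_ids & gene_ids
    if clash:
        raise ValueError(f"identifiers used for both SNPs and genes: {sorted(clash)[:5]}")
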