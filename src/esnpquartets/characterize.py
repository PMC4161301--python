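"""Descriptive characterization of quartets.

Covers the direction-of-effect algebra (16 sign configurations, parity
consistency, four symmetry categories), genomic properties (annotation
bins, cis/trans classes, chromosome co-location), dependency
structures, target co-expression, and the real-vs-permuted categorical
comparisons (Fisher's exact test) including shared functional
annotation and GWAS-gene overlap.

Sign algebra
------------
Each of the four source->target edges of a quartet is oriented by the
sign of its marginal regression slope: "+1" (up) means the minor allele
count correlates positively with expression.  Of the 2^4 = 16 possible
configurations a quartet is *consistent* iff the number of up edges is
even — equivalently the product of the four signs is +1.  The 8
consistent configurations split into 4 two-member categories by two
binary criteria: whether the two sources act on gene 2 in the same
directions as on gene 1 (genes axis), and whether source 2 acts on the
two targets in the same directions as source 1 (snps axis).
"""

from __future__ import annotations

import logging
from itertools import product

import numpy as np
from scipy import stats

from .datatypes import (
    ExpressionMatrix,
    GeneRecord,
    GenotypeMatrix,
    Quartet,
    SnpRecord,
    normalize_chrom,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Sign-configuration algebra

#: Edge order of a sign configuration: (s1->g1, s1->g2, s2->g1, s2->g2).
EDGE_ORDER = (("s1", "g1"), ("s1", "g2"), ("s2", "g1"), ("s2", "g2"))

SignConfiguration = tuple[int, int, int, int]


def all_sign_configurations() -> list[SignConfiguration]:
    """Enumerate all 16 possible up/down edge configurations."""
    return [tuple(c) for c in product((+1, -1), repeat=4)]


def classify_consistency(config: SignConfiguration) -> bool:
    """Consistent iff the number of up edges is even (sign product +1)."""
    _validate_config(config)
    return config[0] * config[1] * config[2] * config[3] == +1


def classify_category(config: SignConfiguration) -> tuple[str, str]:
    """(genes_axis, snps_axis) symmetry category of a consistent configuration.

    genes_axis = "same" iff the pair of source effects on g1 equals the
    pair on g2; snps_axis = "same" iff s1's effects on the two targets
    equal s2's.  Only defined for consistent configurations.
    """
    _validate_config(config)
    if not classify_consistency(config):
        raise ValueError(f"category undefined for inconsistent configuration {config}")
    s1g1, s1g2, s2g1, s2g2 = config
    genes_axis = "same" if (s1g1, s2g1) == (s1g2, s2g2) else "opposite"
    snps_axis = "same" if (s1g1, s1g2) == (s2g1, s2g2) else "opposite"
    return (genes_axis, snps_axis)


def _validate_config(config: SignConfiguration) -> None:
    if len(config) != 4 or any(e not in (+1, -1) for e in config):
        raise ValueError(f"sign configuration must be four entries of +-1, got {config}")


def orient_edges(q: Quartet, assoc_index: dict[tuple[str, str], float]) -> SignConfiguration:
    """Sign per edge = sign of the marginal regression slope.

    ``assoc_index`` maps (snp_id, gene_id) to the marginal beta.  Also
    stores the configuration, its consistency and (when consistent) its
    category on the quartet.
    """
    config = []
    for snp_id, gene_id in (
        (q.snp1_id, q.gene1_id),
        (q.snp1_id, q.gene2_id),
        (q.snp2_id, q.gene1_id),
        (q.snp2_id, q.gene2_id),
    ):
        beta = assoc_index[(snp_id, gene_id)]
        if beta == 0:
            raise ValueError(f"zero slope for edge ({snp_id}, {gene_id})")
        config.append(+1 if beta > 0 else -1)
    config = tuple(config)
    q.sign_config = config
    q.consistent = classify_consistency(config)
    q.category = classify_category(config) if q.consistent else None
    return config


# ---------------------------------------------------------------------------
# Genomic properties

def classify_cis_trans(q: Quartet, geno: GenotypeMatrix, expr: ExpressionMatrix) -> str:
    """Bin a quartet by how many of its 4 source-target pairs are cis.

    A source is cis to a target iff it resides within the target's span
    (same chromosome).  Count 2 -> "two_cis", 1 -> "one_cis",
    0 -> "two_trans".  Counts above 2 (a source inside both targets'
    spans) are reported as-is with a warning.
    """
    n_cis = cis_count(q, geno, expr)
    if n_cis > 2:
        logger.warning("quartet %s has %d cis pairs", q.key(), n_cis)
        return f"{n_cis}_cis"
    return {2: "two_cis", 1: "one_cis", 0: "two_trans"}[n_cis]


def cis_count(q: Quartet, geno: GenotypeMatrix, expr: ExpressionMatrix) -> int:
    n = 0
    for snp_id in q.snp_pair:
        snp = geno.snp(snp_id)
        for gene_id in q.gene_pair:
            if expr.gene(gene_id).contains(snp.chrom, snp.pos):
                n += 1
    return n


def sources_on_different_chromosomes(q: Quartet, geno: GenotypeMatrix) -> bool:
    return normalize_chrom(geno.snp(q.snp1_id).chrom) != normalize_chrom(
        geno.snp(q.snp2_id).chrom
    )


def targets_on_different_chromosomes(q: Quartet, expr: ExpressionMatrix) -> bool:
    return normalize_chrom(expr.gene(q.gene1_id).chrom) != normalize_chrom(
        expr.gene(q.gene2_id).chrom
    )


def source_annotation_bin(q: Quartet, geno: GenotypeMatrix) -> str:
    """Unordered pair of source categories binned as exon+exon / exon+tf / tf+tf.

    A SNP in both an exon and a TF span counts as exon (documented
    precedence).  "other" sources (possible only with non-default source
    categories) yield an "other" bin.
    """
    def collapse(cat: str) -> str:
        return "exon" if cat in ("exon", "both") else cat

    cats = sorted(
        collapse(geno.snp(s).category) for s in q.snp_pair
    )
    if "other" in cats:
        return "other"
    return "+".join(cats)


def dependency_structure(q: Quartet) -> str:
    """mutual_mutual / mixed / directional_directional from triplet kinds."""
    return q.dependency_class


def target_coexpression(q: Quartet, expr: ExpressionMatrix) -> tuple[float, float]:
    """Pearson r of the two targets across samples, and |r|."""
    g1 = expr.gene_values(q.gene1_id)
    g2 = expr.gene_values(q.gene2_id)
    if np.std(g1) == 0 or np.std(g2) == 0:
        raise ValueError("constant gene expression: correlation undefined")
    r = float(np.corrcoef(g1, g2)[0, 1])
    return r, abs(r)


# ---------------------------------------------------------------------------
# Real-vs-permuted comparisons

def compare_categorical(table: list[list[int]] | np.ndarray) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table."""
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ValueError("need a 2x2 table of non-negative integers")
    if arr.sum() == 0:
        raise ValueError("all-zero table")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def _share_terms(pair: tuple[str, str], gene2terms: dict[str, set[str]]) -> bool:
    a = gene2terms.get(pair[0], set())
    b = gene2terms.get(pair[1], set())
    return len(a & b) > 0


def shared_annotation_test(
    quartets: list[Quartet],
    permuted: list[Quartet],
    gene2terms: dict[str, set[str]],
) -> dict[str, float | None]:
    """Do real target pairs share a functional term more than permuted ones?

    For every quartet the target pair is scored as sharing >= 1 term
    (genes missing from the table count as term-free); the real and
    permuted indicator counts form a 2x2 Fisher table.  Returns the p
    and the two sharing fractions; p is None when a margin is empty.
    """
    real_share = sum(_share_terms(q.gene_pair, gene2terms) for q in quartets)
    perm_share = sum(_share_terms(q.gene_pair, gene2terms) for q in permuted)
    table = [
        [real_share, len(quartets) - real_share],
        [perm_share, len(permuted) - perm_share],
    ]
    p = compare_categorical(table) if (len(quartets) and len(permuted)) else None
    return {
        "fisher_p": p,
        "real_sharing_fraction": real_share / len(quartets) if quartets else None,
        "permuted_sharing_fraction": perm_share / len(permuted) if permuted else None,
    }


def _has_gwas_source(
    q: Quartet, geno: GenotypeMatrix, gwas_gene_spans: list[GeneRecord]
) -> bool:
    for snp_id in q.snp_pair:
        snp = geno.snp(snp_id)
        if any(g.contains(snp.chrom, snp.pos) for g in gwas_gene_spans):
            return True
    return False


def gwas_overlap_test(
    quartets: list[Quartet],
    permuted: list[Quartet],
    geno: GenotypeMatrix,
    gwas_genes: set[str],
    gene_spans: dict[str, GeneRecord],
) -> dict[str, float | None]:
    """Do real quartets harbor a source SNP inside a GWAS-listed gene more often?

    A quartet scores true when >= 1 source SNP resides within the span
    of a listed gene.  Real-vs-permuted indicators form a 2x2 Fisher
    table.  With an empty gene list all indicators are false and p = 1.
    """
    spans = [gene_spans[g] for g in sorted(gwas_genes) if g in gene_spans]
    real_hit = sum(_has_gwas_source(q, geno, spans) for q in quartets)
    perm_hit = sum(_has_gwas_source(q, geno, spans) for q in permuted)
    if not quartets or not permuted:
        return {"fisher_p": None, "real_fraction": None, "permuted_fraction": None}
    if not spans:
        return {
            "fisher_p": 1.0,
            "real_fraction": 0.0,
            "permuted_fraction": 0.0,
        }
    table = [
        [real_hit, len(quartets) - real_hit],
        [perm_hit, len(permuted) - perm_hit],
    ]
    return {
        "fisher_p": compare_categorical(table),
        "real_fraction": real_hit / len(quartets),
        "permuted_fraction": perm_hit / len(permuted),
    }


# ---------------------------------------------------------------------------
# Full per-quartet characterization

def characterize_quartets(
    quartets: list[Quartet],
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    assoc_betas: dict[tuple[str, str], float],
) -> list[dict]:
    """Per-quartet descriptive record covering every reported property."""
    rows = []
    for q in quartets:
        config = orient_edges(q, assoc_betas)
        r, abs_r = target_coexpression(q, expr)
        rows.append(
            {
                "snp1_id": q.snp1_id,
                "snp2_id": q.snp2_id,
                "gene1_id": q.gene1_id,
                "gene2_id": q.gene2_id,
                "dependency_class": q.dependency_class,
                "sign_config": "".join("+" if e > 0 else "-" for e in config),
                "consistent": q.consistent,
                "category_genes_axis": q.category[0] if q.category else None,
                "category_snps_axis": q.category[1] if q.category else None,
                "cis_trans": classify_cis_trans(q, geno, expr),
                "sources_diff_chrom": sources_on_different_chromosomes(q, geno),
                "targets_diff_chrom": targets_on_different_chromosomes(q, expr),
                "annotation_bin": source_annotation_bin(q, geno),
                "target_r": r,
                "target_abs_r": abs_r,
            }
        )
    return rows


def coexpression_comparison(
    real_abs_r: list[float], permuted_abs_r: list[float]
) -> float:
    """Two-sample rank test (Mann-Whitney U) on |r|, real vs permuted."""
    if not real_abs_r or not permuted_abs_r:
        raise ValueError("both samples must be non-empty")
    return float(
        stats.mannwhitneyu(real_abs_r, permuted_abs_r, alternative="two-sided")[1]
    )
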