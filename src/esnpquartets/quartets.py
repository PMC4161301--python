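"""Quartet assembly and the three-stage filter chain.

Two triplets that share the same (unordered) pair of target genes
define a quartet: two source SNPs jointly associated with two genes —
the bi-fan arrangement.  The raw set is filtered in order:

1. cooperating sources — in the joint model
   ``g_i ~ intercept + b1*s1 + b2*s2`` (i = 1, 2) all four SNP
   coefficients are significant: each source carries independent
   information about each target;
2. no better intermediate SNP — no third SNP s3, co-chromosomal with a
   source and itself forming a triplet with the two genes, explains
   both targets better than that source (a conditional-significance
   exchange test);
3. unique gene targets — at most one quartet per unordered gene pair,
   keeping the quartet minimizing the max of its four marginal
   association p-values.

Counts are monotonically non-increasing through the chain.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from itertools import combinations

import numpy as np

from .datatypes import (
    ExpressionMatrix,
    GenotypeMatrix,
    Quartet,
    Triplet,
    canonical_pair,
    normalize_chrom,
)
from .triplets import DegenerateModelError, ols_coefficient_pvalues

logger = logging.getLogger(__name__)

COOP_ALPHA = 0.05
INTERMEDIATE_ALPHA = 0.05


def assemble_quartets(triplets: list[Triplet]) -> list[Quartet]:
    """One quartet per unordered SNP pair sharing an identical gene pair.

    With k triplets on the same gene pair the output contains
    k*(k-1)/2 quartets.  Marginal p-values and triplet kinds are carried
    over from the triplets.  Output order is deterministic.
    """
    by_pair: dict[tuple[str, str], list[Triplet]] = defaultdict(list)
    for t in triplets:
        by_pair[t.gene_pair].append(t)
    out: list[Quartet] = []
    for gene_pair in sorted(by_pair):
        members = sorted(by_pair[gene_pair], key=lambda t: t.snp_id)
        for t1, t2 in combinations(members, 2):
            if t1.snp_id == t2.snp_id:
                continue
            a, b = (t1, t2) if t1.snp_id < t2.snp_id else (t2, t1)
            g1, g2 = gene_pair
            out.append(
                Quartet(
                    snp1_id=a.snp_id,
                    snp2_id=b.snp_id,
                    gene1_id=g1,
                    gene2_id=g2,
                    triplet1_kind=a.kind,
                    triplet2_kind=b.kind,
                    marginal_p={
                        (a.snp_id, g1): a.p1,
                        (a.snp_id, g2): a.p2,
                        (b.snp_id, g1): b.p1,
                        (b.snp_id, g2): b.p2,
                    },
                )
            )
    out.sort(key=lambda q: q.key())
    return out


def cooperating_filter(
    q: Quartet,
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    alpha: float = COOP_ALPHA,
) -> bool:
    """Do both sources carry independent information about both targets?

    Fits the joint two-SNP model for each target gene and requires all
    four coefficient p-values < alpha.  Perfectly collinear sources
    (LD r^2 = 1) fail with the ``collinear`` flag set: the coefficients
    are not identifiable.  Fills ``q.coop_p`` and
    ``q.passed_cooperating`` as a side effect.
    """
    s1 = geno.snp_counts(q.snp1_id)
    s2 = geno.snp_counts(q.snp2_id)
    ok = ~np.isnan(s1) & ~np.isnan(s2)
    X = np.column_stack([s1[ok], s2[ok]])
    coop_p: dict[tuple[str, str], float] = {}
    for gene_id in q.gene_pair:
        y = expr.gene_values(gene_id)[ok]
        try:
            _, p = ols_coefficient_pvalues(X, y)
        except DegenerateModelError:
            q.collinear = True
            q.passed_cooperating = False
            return False
        coop_p[(q.snp1_id, gene_id)] = float(p[0])
        coop_p[(q.snp2_id, gene_id)] = float(p[1])
    q.coop_p = coop_p
    q.passed_cooperating = all(p < alpha for p in coop_p.values())
    return q.passed_cooperating


def _exchange_test(
    s_src: np.ndarray,
    s3: np.ndarray,
    targets: list[np.ndarray],
    alpha: float,
) -> bool:
    """True if s3 explains every target better than the source SNP.

    "Better" means: conditioning on s3 renders the source coefficient
    non-significant while s3's coefficient conditioned on the source
    stays significant, for both genes.
    """
    ok = ~np.isnan(s_src) & ~np.isnan(s3)
    X = np.column_stack([s_src[ok], s3[ok]])
    for y in targets:
        try:
            _, p = ols_coefficient_pvalues(X, y[ok])
        except DegenerateModelError:
            return False
        p_src_given_s3, p_s3_given_src = float(p[0]), float(p[1])
        if not (p_src_given_s3 >= alpha and p_s3_given_src < alpha):
            return False
    return True


def intermediate_snp_filter(
    q: Quartet,
    all_triplets: list[Triplet],
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    alpha: float = INTERMEDIATE_ALPHA,
) -> bool:
    """Reject the quartet if a third SNP explains the expression better.

    A candidate s3 must (a) lie on the same chromosome as a source SNP
    (an intermediate explanation via linkage requires co-localization),
    (b) itself form a triplet with the two target genes, and (c) win the
    exchange test against that co-chromosomal source on both genes.
    Sets ``q.passed_intermediate``.
    """
    gene_pair = q.gene_pair
    candidates = sorted(
        {t.snp_id for t in all_triplets if t.gene_pair == gene_pair}
        - {q.snp1_id, q.snp2_id}
    )
    if not candidates:
        q.passed_intermediate = True
        return True
    targets = [expr.gene_values(g) for g in gene_pair]
    src_chroms = {
        q.snp1_id: normalize_chrom(geno.snp(q.snp1_id).chrom),
        q.snp2_id: normalize_chrom(geno.snp(q.snp2_id).chrom),
    }
    for s3_id in candidates:
        s3_chrom = normalize_chrom(geno.snp(s3_id).chrom)
        s3 = geno.snp_counts(s3_id)
        for src_id, src_chrom in src_chroms.items():
            if s3_chrom != src_chrom:
                continue
            if _exchange_test(geno.snp_counts(src_id), s3, targets, alpha):
                q.passed_intermediate = False
                return False
    q.passed_intermediate = True
    return True


def unique_targets_filter(quartets: list[Quartet]) -> list[Quartet]:
    """Keep at most one quartet per unordered gene pair.

    The survivor minimizes the max of its four marginal association
    p-values; ties break lexicographically by SNP IDs.
    """
    best: dict[tuple[str, str], Quartet] = {}
    for q in quartets:
        cur = best.get(q.gene_pair)
        if cur is None or (q.worst_marginal_p, q.snp_pair) < (
            cur.worst_marginal_p,
            cur.snp_pair,
        ):
            best[q.gene_pair] = q
    return [best[k] for k in sorted(best)]


def filter_quartets(
    quartets: list[Quartet],
    triplets: list[Triplet],
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    alpha: float = COOP_ALPHA,
) -> tuple[list[Quartet], dict[str, int]]:
    """Run the full filter chain; returns survivors and per-stage counts."""
    counts = {"assembled": len(quartets)}
    coop = [q for q in quartets if cooperating_filter(q, geno, expr, alpha)]
    counts["cooperating"] = len(coop)
    no_mid = [
        q for q in coop if intermediate_snp_filter(q, triplets, geno, expr, alpha)
    ]
    counts["no_intermediate"] = len(no_mid)
    unique = unique_targets_filter(no_mid)
    counts["unique_targets"] = len(unique)
    return unique, counts
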