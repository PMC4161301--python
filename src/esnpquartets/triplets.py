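"""SNP-gene-gene triplets and their conditional-independence classification.

A triplet is one eSNP associated (marginally, at the association
threshold) with two genes.  Conditioning each association on the other
gene's expression splits the triplets:

* mutual      — both SNP coefficients stay nominally significant given
                the respective other gene (mutually independent effects),
* directional — exactly one survives (a mediation-like chain: the SNP's
                effect on one gene is explained by the other gene).

Candidates where neither conditional signal survives are dropped, never
stored.  Conditioning uses the SNP coefficient's t-test in the joint
two-predictor OLS ``target ~ intercept + snp + covariate`` for exact
finite-sample degrees of freedom.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
from scipy import stats

from .datatypes import (
    AssociationRecord,
    ExpressionMatrix,
    GenotypeMatrix,
    Triplet,
    canonical_pair,
)

logger = logging.getLogger(__name__)

NOMINAL_ALPHA = 0.05  # "nominally significant", two-sided

MIN_COMPLETE_COND = 5


class DegenerateModelError(ValueError):
    """Collinear predictors or zero residual variance."""


def ols_coefficient_pvalues(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient estimates and two-sided p-values for OLS with intercept.

    ``X`` is (n x k) without the intercept column.  Solved via the
    normal equations with a rank check; raises
    :class:`DegenerateModelError` for collinear designs or a saturated
    fit with zero residual degrees of freedom.
    """
    n, k = X.shape
    A = np.column_stack([np.ones(n), X])
    df = n - (k + 1)
    if df < 1:
        raise DegenerateModelError(f"no residual degrees of freedom (n={n}, k={k})")
    gram = A.T @ A
    if np.linalg.matrix_rank(gram) < k + 1:
        raise DegenerateModelError("collinear predictors")
    gram_inv = np.linalg.inv(gram)
    coef = gram_inv @ (A.T @ y)
    resid = y - A @ coef
    rss = float(resid @ resid)
    tss = float((y - y.mean()) @ (y - y.mean()))
    if tss > 0 and rss <= np.finfo(float).eps * tss * n:
        raise DegenerateModelError("zero residual variance (saturated fit)")
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2 * np.diag(gram_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return coef[1:], p[1:]


def conditional_p(
    snp_counts: np.ndarray, target_expr: np.ndarray, covariate_expr: np.ndarray
) -> float:
    """p-value of the SNP coefficient given the covariate gene.

    Fits ``target ~ intercept + snp + covariate`` on pairwise-complete
    samples and returns the SNP coefficient's two-sided p.
    """
    s = np.asarray(snp_counts, dtype=float)
    y = np.asarray(target_expr, dtype=float)
    z = np.asarray(covariate_expr, dtype=float)
    ok = ~np.isnan(s) & ~np.isnan(y) & ~np.isnan(z)
    if ok.sum() < MIN_COMPLETE_COND:
        raise ValueError(f"only {int(ok.sum())} complete samples; need >= {MIN_COMPLETE_COND}")
    _, p = ols_coefficient_pvalues(np.column_stack([s[ok], z[ok]]), y[ok])
    return float(p[0])


def build_triplets(
    assocs: list[AssociationRecord],
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    alpha: float = NOMINAL_ALPHA,
) -> list[Triplet]:
    """Classify every SNP with >= 2 associated genes over all gene pairs.

    Output triplets carry canonical gene order (gene1 < gene2) and are
    sorted by (snp_id, gene1_id, gene2_id); degenerate pairs (collinear
    designs) are skipped with a log message.  The labeling is exhaustive
    and mutually exclusive: each candidate lands in exactly one of
    {mutual, directional, excluded}, and excluded candidates are not
    returned.
    """
    by_snp: dict[str, list[AssociationRecord]] = defaultdict(list)
    for rec in assocs:
        by_snp[rec.snp_id].append(rec)

    out: list[Triplet] = []
    n_skipped = 0
    for snp_id in sorted(by_snp):
        recs = sorted(by_snp[snp_id], key=lambda r: r.gene_id)
        if len(recs) < 2:
            continue
        s = geno.snp_counts(snp_id)
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                r1, r2 = recs[i], recs[j]  # gene IDs already sorted
                g1 = expr.gene_values(r1.gene_id)
                g2 = expr.gene_values(r2.gene_id)
                try:
                    p1_c = conditional_p(s, g1, g2)
                    p2_c = conditional_p(s, g2, g1)
                except (DegenerateModelError, ValueError):
                    n_skipped += 1
                    continue
                sig1, sig2 = p1_c < alpha, p2_c < alpha
                if sig1 and sig2:
                    kind, target = "mutual", None
                elif sig1 or sig2:
                    kind = "directional"
                    target = r1.gene_id if sig1 else r2.gene_id
                else:
                    continue  # excluded: neither conditional signal survives
                out.append(
                    Triplet(
                        snp_id=snp_id,
                        gene1_id=r1.gene_id,
                        gene2_id=r2.gene_id,
                        p1=r1.p_value,
                        p2=r2.p_value,
                        p1_given_g2=p1_c,
                        p2_given_g1=p2_c,
                        kind=kind,
                        directional_target=target,
                    )
                )
    if n_skipped:
        logger.info("skipped %d degenerate gene pairs in triplet building", n_skipped)
    out.sort(key=lambda t: (t.snp_id, t.gene1_id, t.gene2_id))
    return out


def match_threshold_to_permutations(
    real_triplets: list[Triplet],
    permuted_triplet_counts: list[int],
    base_threshold: float,
) -> float:
    """Tighten the p-value cutoff so real and permuted triplet sets are comparable.

    Ranks the real triplets by their worse (larger) marginal p and keeps
    the top ``round(mean(permuted counts))``; the returned cutoff is the
    worse marginal p of the last retained triplet.  If real data has no
    more triplets than the permutation mean, the base threshold is
    returned unchanged with a warning.
    """
    if not permuted_triplet_counts:
        raise ValueError("permuted_triplet_counts is empty")
    target = int(round(float(np.mean(permuted_triplet_counts))))
    if len(real_triplets) <= target:
        if len(real_triplets) < target:
            logger.warning(
                "real data has %d triplets, fewer than the permutation mean %d; "
                "keeping base threshold",
                len(real_triplets),
                target,
            )
        return base_threshold
    ranked = sorted(
        real_triplets, key=lambda t: (t.worse_p, t.snp_id, t.gene1_id, t.gene2_id)
    )
    return ranked[target - 1].worse_p if target > 0 else base_threshold


def filter_triplets_at(triplets: list[Triplet], threshold: float) -> list[Triplet]:
    """Triplets whose worse marginal p is <= the (matched) threshold."""
    return [t for t in triplets if t.worse_p <= threshold]
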