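"""Single-SNP single-gene additive linear regression and the genome-wide scan.

The model is ordinary least squares of expression on minor-allele count
with an intercept — the additive eQTL model.  The slope t-statistic is
referred to a t distribution with n - 2 degrees of freedom and the
p-value is two-sided; no asymptotic normal approximation is used, since
cohorts of ~50 samples are the intended regime.

Missing genotypes are handled pairwise-complete: each regression uses
the samples with an observed call for that SNP (expression carries no
missing values by construction).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .datatypes import AssociationRecord, ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

ASSOC_THRESHOLD = 1e-4          # association-pair retention threshold
DEFAULT_SOURCE_CATEGORIES = frozenset({"exon", "tf", "both"})

#: p-value reported for a numerically perfect fit (zero residuals);
#: the smallest positive normal double, flagged ``perfect_fit``.
PERFECT_FIT_P = float(np.finfo(float).tiny)

MIN_COMPLETE = 4  # minimum pairwise-complete samples for a marginal test


class DegeneratePredictorError(ValueError):
    """The genotype vector is constant on the complete samples."""


def ols_slope_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, bool]:
    """Slope, t and two-sided p for OLS of y on x with intercept.

    Closed form via the Pearson correlation: t = r * sqrt(n-2) / sqrt(1-r^2).
    Returns (beta, t, p, perfect_fit).
    """
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    if sxx == 0.0:
        raise DegeneratePredictorError("constant predictor")
    beta = sxy / sxx
    if syy == 0.0:
        # constant response: slope 0, no evidence
        return 0.0, 0.0, 1.0, False
    r2 = sxy * sxy / (sxx * syy)
    df = n - 2
    resid = syy - beta * sxy
    if resid <= 0 or np.isclose(r2, 1.0):
        return beta, np.sign(beta) * np.inf, PERFECT_FIT_P, True
    t = beta * np.sqrt(df * sxx / resid)
    p = 2.0 * stats.t.sf(abs(t), df)
    return beta, float(t), float(max(p, PERFECT_FIT_P)), False


def associate(
    snp_counts: np.ndarray, expr: np.ndarray, snp_id: str = "", gene_id: str = ""
) -> AssociationRecord:
    """Test one SNP against one gene.

    Drops samples with a missing genotype, then regresses expression on
    minor-allele count.  Requires >= 4 complete samples and a
    non-constant genotype on the complete set.
    """
    snp_counts = np.asarray(snp_counts, dtype=float)
    expr = np.asarray(expr, dtype=float)
    ok = ~np.isnan(snp_counts) & ~np.isnan(expr)
    x, y = snp_counts[ok], expr[ok]
    if x.size < MIN_COMPLETE:
        raise ValueError(f"only {x.size} pairwise-complete samples; need >= {MIN_COMPLETE}")
    beta, t, p, perfect = ols_slope_test(x, y)
    return AssociationRecord(
        snp_id=snp_id,
        gene_id=gene_id,
        n_used=int(x.size),
        beta=beta,
        t_stat=t,
        p_value=p,
        direction="up" if beta > 0 else "down",
        perfect_fit=perfect,
    )


def _scan_one_snp(
    x: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int] | None:
    """Vectorized regression of one SNP against every gene.

    ``values`` is (samples x genes).  Returns (beta, t, p, n_used) or
    None if the SNP is degenerate on its complete samples.
    """
    ok = ~np.isnan(x)
    n = int(ok.sum())
    if n < MIN_COMPLETE:
        return None
    xs = x[ok]
    ys = values[ok, :]
    xc = xs - xs.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        return None
    yc = ys - ys.mean(axis=0)
    sxy = xc @ yc
    syy = np.einsum("ij,ij->j", yc, yc)
    beta = sxy / sxx
    df = n - 2
    resid = syy - beta * sxy
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta * np.sqrt(df * sxx / resid)
    p = np.where(
        resid <= np.finfo(float).eps * syy,
        PERFECT_FIT_P,
        2.0 * stats.t.sf(np.abs(t), df),
    )
    # constant-expression genes: slope 0, p 1
    const = syy == 0.0
    beta[const], p[const] = 0.0, 1.0
    t = np.where(const, 0.0, t)
    return beta, t, np.maximum(p, PERFECT_FIT_P), n


def associate_all(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    p_threshold: float = ASSOC_THRESHOLD,
    source_categories: frozenset[str] | set[str] = DEFAULT_SOURCE_CATEGORIES,
) -> list[AssociationRecord]:
    """Scan every candidate-source SNP against every gene.

    Only SNPs whose annotation category is in ``source_categories``
    (default exon / tf / both) are tested.  Records with
    p < ``p_threshold`` are returned sorted by p ascending, ties broken
    by (snp_id, gene_id) for determinism.
    """
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError(f"p_threshold {p_threshold} outside (0, 1]")
    if geno.samples != expr.samples:
        raise ValueError("matrices are not sample-aligned; call intersect_samples first")
    out: list[AssociationRecord] = []
    n_degenerate = 0
    for j, snp in enumerate(geno.snps):
        if snp.category not in source_categories:
            continue
        res = _scan_one_snp(geno.counts[:, j], expr.values)
        if res is None:
            n_degenerate += 1
            continue
        beta, t, p, n = res
        hits = np.flatnonzero(p < p_threshold)
        for k in hits:
            out.append(
                AssociationRecord(
                    snp_id=snp.snp_id,
                    gene_id=expr.genes[k].gene_id,
                    n_used=n,
                    beta=float(beta[k]),
                    t_stat=float(t[k]),
                    p_value=float(p[k]),
                    direction="up" if beta[k] > 0 else "down",
                    perfect_fit=bool(p[k] == PERFECT_FIT_P),
                )
            )
    if n_degenerate:
        logger.info("skipped %d degenerate SNPs in association scan", n_degenerate)
    out.sort(key=lambda r: (r.p_value, r.snp_id, r.gene_id))
    return out


def is_cis(snp, gene) -> bool:
    """Span-based cis definition: the SNP lies inside the target's span."""
    return gene.contains(snp.chrom, snp.pos)
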