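"""Genotype/expression simulator with planted motif structure.

The generator emulates the statistical structure the discovery pipeline
assumes: biallelic SNPs in Hardy-Weinberg proportions at MAF above the
quality filter, approximately Gaussian per-gene expression, additive
per-allele linear effects, and three planted building blocks —

* bi-fans: two source SNPs each affecting the same two target genes
  with configurable 2x2 slope matrices (the quartet ground truth),
* mediation chains: SNP -> gene1 -> gene2 (ground truth for
  directional triplets),
* LD pairs: two SNPs with a target allele-count correlation, generated
  through a Gaussian copula on latent variables.

Every non-planted gene is pure noise, so null calibration and
false-discovery behavior are measurable on the same dataset.  Output is
fully reproducible from ``master_seed``.

Defaults mirror a small sequencing cohort: 50 samples, unit noise
standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .characterize import classify_category, classify_consistency
from .datatypes import ExpressionMatrix, GeneRecord, GenotypeMatrix, SnpRecord
from . import io as qio


@dataclass(frozen=True)
class PlantedBifan:
    """Two sources x two targets with a 2x2 slope matrix.

    ``effects[i][j]`` is the slope of source i on target j (per
    minor-allele copy).  Source/target chromosomes default to four
    distinct chromosomes so the planted motif is a trans structure.
    """

    effects: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 1.0), (1.0, 1.0))
    source_chroms: tuple[str, str] = ("1", "2")
    target_chroms: tuple[str, str] = ("3", "4")


@dataclass(frozen=True)
class PlantedMediation:
    """A SNP -> gene1 -> gene2 chain (directional-triplet ground truth)."""

    snp_to_g1: float = 1.0
    g1_to_g2: float = 1.0
    chrom: str = "5"


@dataclass(frozen=True)
class LdPair:
    """Two SNP indices with a target allele-count correlation."""

    snp_a: int
    snp_b: int
    r: float


@dataclass
class SimulationConfig:
    n_samples: int = 50
    n_snps: int = 100
    n_genes: int = 50
    maf_range: tuple[float, float] = (0.1, 0.5)
    planted_bifans: list[PlantedBifan] = field(default_factory=list)
    planted_mediations: list[PlantedMediation] = field(default_factory=list)
    ld_pairs: list[LdPair] = field(default_factory=list)
    noise_sd: float = 1.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.05 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} must lie within (0.05, 0.5]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for lp in self.ld_pairs:
            if not (abs(lp.r) < 1):
                raise ValueError(f"LD target |r| must be < 1, got {lp.r}")
        needed_snps = 2 * len(self.planted_bifans) + len(self.planted_mediations)
        needed_genes = 2 * (len(self.planted_bifans) + len(self.planted_mediations))
        if needed_snps > self.n_snps:
            raise ValueError("planted structures need more SNPs than n_snps")
        if needed_genes > self.n_genes:
            raise ValueError("planted structures need more genes than n_genes")
        for lp in self.ld_pairs:
            if not (0 <= lp.snp_a < self.n_snps and 0 <= lp.snp_b < self.n_snps):
                raise ValueError("LD pair index out of range")


@dataclass
class GroundTruth:
    """What was planted, and what the pipeline should recover."""

    bifans: list[dict] = field(default_factory=list)
    mediations: list[dict] = field(default_factory=list)
    null_genes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "bifans": self.bifans,
                    "mediations": self.mediations,
                    "null_genes": self.null_genes,
                },
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# Gaussian-copula LD

def _hw_thresholds(maf: float) -> tuple[float, float]:
    """Latent-normal cut points giving Hardy-Weinberg genotype proportions."""
    p0 = (1 - maf) ** 2
    p01 = p0 + 2 * maf * (1 - maf)
    return stats.norm.ppf(p0), stats.norm.ppf(p01)


def _count_corr_at_latent_rho(rho: float, maf_a: float, maf_b: float) -> float:
    """Allele-count correlation induced by latent correlation ``rho``."""
    ta = (-np.inf,) + _hw_thresholds(maf_a) + (np.inf,)
    tb = (-np.inf,) + _hw_thresholds(maf_b) + (np.inf,)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    mvn = stats.multivariate_normal(mean=[0, 0], cov=cov, allow_singular=True)

    def rect(xlo, xhi, ylo, yhi):
        def cdf(x, y):
            if np.isinf(x) and x < 0 or np.isinf(y) and y < 0:
                return 0.0
            return float(mvn.cdf([min(x, 8.0), min(y, 8.0)]))

        return cdf(xhi, yhi) - cdf(xlo, yhi) - cdf(xhi, ylo) + cdf(xlo, ylo)

    probs = np.array(
        [[rect(ta[i], ta[i + 1], tb[j], tb[j + 1]) for j in range(3)] for i in range(3)]
    )
    probs = np.clip(probs, 0, None)
    probs /= probs.sum()
    counts = np.arange(3.0)
    ea = probs.sum(axis=1) @ counts
    eb = probs.sum(axis=0) @ counts
    eab = counts @ probs @ counts
    va = probs.sum(axis=1) @ counts**2 - ea**2
    vb = probs.sum(axis=0) @ counts**2 - eb**2
    if va <= 0 or vb <= 0:
        return 0.0
    return float((eab - ea * eb) / np.sqrt(va * vb))


def solve_latent_rho(target_r: float, maf_a: float, maf_b: float) -> float:
    """Bisect the latent correlation achieving a target count correlation.

    Raises a ValueError naming the attainable bound when the target
    exceeds what the two binomial margins allow.
    """
    if target_r == 0:
        return 0.0
    hi = 0.999
    bound = _count_corr_at_latent_rho(np.sign(target_r) * hi, maf_a, maf_b)
    if abs(target_r) > abs(bound):
        raise ValueError(
            f"LD target r={target_r} unattainable for MAFs ({maf_a}, {maf_b}); "
            f"bound is {bound:+.4f}"
        )
    lo_rho, hi_rho = 0.0, np.sign(target_r) * hi
    for _ in range(40):
        mid = (lo_rho + hi_rho) / 2
        if abs(_count_corr_at_latent_rho(mid, maf_a, maf_b)) < abs(target_r):
            lo_rho = mid
        else:
            hi_rho = mid
    return (lo_rho + hi_rho) / 2


def _counts_from_latent(z: np.ndarray, maf: float) -> np.ndarray:
    t1, t2 = _hw_thresholds(maf)
    return np.where(z < t1, 0.0, np.where(z < t2, 1.0, 2.0))


# ---------------------------------------------------------------------------
# Simulation

def _snp_id(i: int) -> str:
    return f"snp{i:04d}"


def _gene_id(j: int) -> str:
    return f"gene{j:04d}"


def simulate(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, ExpressionMatrix, GroundTruth]:
    """Draw one dataset under the configured generative model.

    Planted structures consume the lowest SNP/gene indices in order
    (bi-fans first, then mediations); everything else is pure noise.
    SNP annotation category is "exon" throughout, so all SNPs are
    association-source candidates.
    """
    rng = np.random.default_rng(config.master_seed)
    n, m, g = config.n_samples, config.n_snps, config.n_genes

    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    # latent normals; LD pairs share correlated latents
    z = rng.standard_normal((n, m))
    for lp in config.ld_pairs:
        rho = solve_latent_rho(lp.r, float(mafs[lp.snp_a]), float(mafs[lp.snp_b]))
        za = z[:, lp.snp_a]
        z[:, lp.snp_b] = rho * za + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    counts = np.empty((n, m))
    for j in range(m):
        counts[:, j] = _counts_from_latent(z[:, j], float(mafs[j]))

    # orient to the realized cohort minor allele
    freq = counts.mean(axis=0) / 2.0
    flip = freq > 0.5
    counts[:, flip] = 2.0 - counts[:, flip]
    realized_maf = counts.mean(axis=0) / 2.0

    # genomic layout: planted structures get their configured chromosomes;
    # everything else cycles over autosomes 6..10, spaced 10 kb apart
    snp_chrom = {}
    gene_chrom = {}
    snp_cursor = 0
    gene_cursor = 0
    truth = GroundTruth()

    for bf in config.planted_bifans:
        s_idx = (snp_cursor, snp_cursor + 1)
        g_idx = (gene_cursor, gene_cursor + 1)
        snp_cursor += 2
        gene_cursor += 2
        snp_chrom[s_idx[0]] = bf.source_chroms[0]
        snp_chrom[s_idx[1]] = bf.source_chroms[1]
        gene_chrom[g_idx[0]] = bf.target_chroms[0]
        gene_chrom[g_idx[1]] = bf.target_chroms[1]
        signs = tuple(
            +1 if bf.effects[i][j] > 0 else -1 for i in (0, 1) for j in (0, 1)
        )
        consistent = classify_consistency(signs)
        truth.bifans.append(
            {
                "snp_ids": [_snp_id(i) for i in s_idx],
                "gene_ids": [_gene_id(j) for j in g_idx],
                "effects": [list(row) for row in bf.effects],
                "expected_sign_config": list(signs),
                "expected_consistent": consistent,
                "expected_category": list(classify_category(signs))
                if consistent
                else None,
                "expected_triplet_kinds": ["mutual", "mutual"],
            }
        )

    for md in config.planted_mediations:
        s_idx = snp_cursor
        g_idx = (gene_cursor, gene_cursor + 1)
        snp_cursor += 1
        gene_cursor += 2
        snp_chrom[s_idx] = md.chrom
        gene_chrom[g_idx[0]] = md.chrom
        gene_chrom[g_idx[1]] = md.chrom
        truth.mediations.append(
            {
                "snp_id": _snp_id(s_idx),
                "gene_ids": [_gene_id(j) for j in g_idx],
                "snp_to_g1": md.snp_to_g1,
                "g1_to_g2": md.g1_to_g2,
                "expected_kind": "directional",
                "expected_directional_target": _gene_id(g_idx[0]),
            }
        )

    truth.null_genes = [_gene_id(j) for j in range(gene_cursor, g)]

    filler_chroms = ["6", "7", "8", "9", "10"]
    per_chrom_snp: dict[str, int] = {}
    snps = []
    for i in range(m):
        chrom = snp_chrom.get(i, filler_chroms[i % len(filler_chroms)])
        k = per_chrom_snp.get(chrom, 0)
        per_chrom_snp[chrom] = k + 1
        snps.append(
            SnpRecord(
                snp_id=_snp_id(i),
                chrom=chrom,
                pos=10_000 * (k + 1),
                maf=float(realized_maf[i]),
                category="exon",
            )
        )

    per_chrom_gene: dict[str, int] = {}
    genes = []
    for j in range(g):
        chrom = gene_chrom.get(j, filler_chroms[j % len(filler_chroms)])
        k = per_chrom_gene.get(chrom, 0)
        per_chrom_gene[chrom] = k + 1
        start = 5_000_000 + 10_000 * k
        genes.append(
            GeneRecord(gene_id=_gene_id(j), chrom=chrom, start=start, end=start + 4_999)
        )

    # expression: noise first, then planted effects layered on top
    values = rng.normal(0.0, config.noise_sd, size=(n, g))
    gc = 0
    sc = 0
    for bf in config.planted_bifans:
        for j_local, j in enumerate((gc, gc + 1)):
            values[:, j] += (
                bf.effects[0][j_local] * counts[:, sc]
                + bf.effects[1][j_local] * counts[:, sc + 1]
            )
        gc += 2
        sc += 2
    for md in config.planted_mediations:
        values[:, gc] += md.snp_to_g1 * counts[:, sc]
        values[:, gc + 1] += md.g1_to_g2 * values[:, gc]
        gc += 2
        sc += 1

    samples = [f"S{i:03d}" for i in range(n)]
    geno = GenotypeMatrix(samples=samples, snps=snps, counts=counts)
    expr = ExpressionMatrix(samples=list(samples), genes=genes, values=values)
    return geno, expr, truth


def realized_ld(geno: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Pearson correlation of allele counts between two SNPs."""
    a = geno.snp_counts(snp_a)
    b = geno.snp_counts(snp_b)
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("monomorphic SNP: LD undefined")
    return float(np.corrcoef(a, b)[0, 1])


def write_dataset(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    truth: GroundTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the simulated dataset as the pipeline's file-based inputs.

    Emits a genotype dosage TSV, expression TSV, gene-span BED, and
    exon/TF BED files that reproduce the in-memory SNP categories when
    read back through :mod:`esnpquartets.io`, plus the ground truth as
    JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "expression": outdir / "expression.tsv",
        "genes_bed": outdir / "genes.bed",
        "exons_bed": outdir / "exons.bed",
        "tfs_bed": outdir / "tfs.bed",
        "ground_truth": outdir / "ground_truth.json",
    }
    qio.write_genotypes(geno, paths["genotypes"])
    qio.write_expression(expr, paths["expression"])
    with open(paths["genes_bed"], "w") as fh:
        for g in expr.genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")
    with open(paths["exons_bed"], "w") as fe, open(paths["tfs_bed"], "w") as ft:
        for s in geno.snps:
            line = f"{s.chrom}\t{s.pos - 1}\t{s.pos}\n"
            if s.category in ("exon", "both"):
                fe.write(line)
            if s.category in ("tf", "both"):
                ft.write(line)
    truth.to_json(paths["ground_truth"])
    return paths
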