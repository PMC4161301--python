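"""Core in-memory containers shared by every pipeline stage.

Conventions
-----------
* All genomic coordinates are 1-based inclusive (the VCF convention).
  BED inputs are converted on read.
* Genotypes are minor-allele counts in {0, 1, 2}; missing calls are
  stored as ``numpy.nan`` in a float matrix.
* The minor allele is cohort-relative: it is re-derived from the loaded
  (and, after :func:`esnpquartets.io.intersect_samples`, intersected)
  samples, so a count column always has mean allele frequency <= 0.5
  up to the tie at exactly 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Annotation categories a SNP can carry.  Sources for association
#: scanning are restricted to {exon, tf, both} by default; "other"
#: SNPs are retained (they can act as intermediate s3 candidates) but
#: are excluded from source candidacy.
SNP_CATEGORIES = ("exon", "tf", "both", "other")


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP: identity, position and annotation category."""

    snp_id: str
    chrom: str
    pos: int
    maf: float
    category: str = "other"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.snp_id}: pos must be >= 1, got {self.pos}")
        if not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValueError(f"SNP {self.snp_id}: maf {self.maf} outside [0, 0.5]")
        if self.category not in SNP_CATEGORIES:
            raise ValueError(
                f"SNP {self.snp_id}: category {self.category!r} not one of {SNP_CATEGORIES}"
            )


@dataclass(frozen=True)
class GeneRecord:
    """One gene: identity and genomic span (1-based inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"Gene {self.gene_id}: start {self.start} > end {self.end}"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether a genomic position falls within this gene's span."""
        return normalize_chrom(chrom) == normalize_chrom(self.chrom) and (
            self.start <= pos <= self.end
        )


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so chromosome names compare as strings."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele counts with per-SNP metadata.

    ``counts`` is float with shape (n_samples, n_snps); missing
    genotypes are NaN.
    """

    samples: list[str]
    snps: list[SnpRecord]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._snp_lookup[snp_id]
        except AttributeError:
            self._snp_lookup = {s.snp_id: i for i, s in enumerate(self.snps)}
            return self._snp_lookup[snp_id]

    def snp_counts(self, snp_id: str) -> np.ndarray:
        """Minor-allele count vector for one SNP (NaN = missing)."""
        return self.counts[:, self.snp_index(snp_id)]

    def snp(self, snp_id: str) -> SnpRecord:
        return self.snps[self.snp_index(snp_id)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return GenotypeMatrix(
            samples=list(sample_ids),
            snps=list(self.snps),
            counts=self.counts[idx, :],
        )


@dataclass
class ExpressionMatrix:
    """Samples x genes normalized expression with per-gene spans.

    No missing values: genes with missing entries are dropped at load
    time.  Inputs are assumed already normalized (e.g. quantile
    normalized); this package performs no normalization.
    """

    samples: list[str]
    genes: list[GeneRecord]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.genes)} genes"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_lookup[gene_id]
        except AttributeError:
            self._gene_lookup = {g.gene_id: i for i, g in enumerate(self.genes)}
            return self._gene_lookup[gene_id]

    def gene_values(self, gene_id: str) -> np.ndarray:
        return self.values[:, self.gene_index(gene_id)]

    def gene(self, gene_id: str) -> GeneRecord:
        return self.genes[self.gene_index(gene_id)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return ExpressionMatrix(
            samples=list(sample_ids),
            genes=list(self.genes),
            values=self.values[idx, :],
        )


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP-gene additive linear-regression result.

    ``direction`` is "up" iff the slope per minor-allele copy is
    positive, i.e. the minor allele up-regulates the transcript.
    """

    snp_id: str
    gene_id: str
    n_used: int
    beta: float
    t_stat: float
    p_value: float
    direction: str
    perfect_fit: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")
        expected = "up" if self.beta > 0 else "down"
        if self.beta != 0 and self.direction != expected:
            raise ValueError("direction inconsistent with sign(beta)")


@dataclass(frozen=True)
class Triplet:
    """One SNP associated with two genes, classified by conditioning.

    ``kind`` is "mutual" when both SNP-gene associations remain
    nominally significant given the respective other gene's expression,
    "directional" when exactly one survives.  Candidates where neither
    survives are never stored.  Gene order is canonical:
    ``gene1_id < gene2_id``.
    """

    snp_id: str
    gene1_id: str
    gene2_id: str
    p1: float
    p2: float
    p1_given_g2: float
    p2_given_g1: float
    kind: str
    directional_target: str | None = None

    def __post_init__(self) -> None:
        if self.gene1_id >= self.gene2_id:
            raise ValueError("triplet genes must be in canonical (sorted) order")
        if self.kind not in ("mutual", "directional"):
            raise ValueError(f"unknown triplet kind {self.kind!r}")
        if self.kind == "directional" and self.directional_target not in (
            self.gene1_id,
            self.gene2_id,
        ):
            raise ValueError("directional triplet needs a member directional_target")
        if self.kind == "mutual" and self.directional_target is not None:
            raise ValueError("mutual triplet carries no directional_target")

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.gene1_id, self.gene2_id)

    @property
    def worse_p(self) -> float:
        """The larger (binding) marginal p-value; the ranking key."""
        return max(self.p1, self.p2)


@dataclass
class Quartet:
    """Two source SNPs jointly associated with the same two target genes.

    Canonical ordering: ``snp1_id < snp2_id`` and ``gene1_id < gene2_id``.
    Filter provenance and characterization labels are filled in as the
    quartet moves through the pipeline.
    """

    snp1_id: str
    snp2_id: str
    gene1_id: str
    gene2_id: str
    triplet1_kind: str
    triplet2_kind: str
    marginal_p: dict[tuple[str, str], float] = field(default_factory=dict)
    coop_p: dict[tuple[str, str], float] = field(default_factory=dict)
    passed_cooperating: bool | None = None
    collinear: bool = False
    passed_intermediate: bool | None = None
    sign_config: tuple[int, int, int, int] | None = None
    consistent: bool | None = None
    category: tuple[str, str] | None = None
    perm_index: int | None = None

    def __post_init__(self) -> None:
        if self.snp1_id >= self.snp2_id:
            raise ValueError("quartet SNPs must be in canonical (sorted) order")
        if self.gene1_id >= self.gene2_id:
            raise ValueError("quartet genes must be in canonical (sorted) order")

    @property
    def snp_pair(self) -> tuple[str, str]:
        return (self.snp1_id, self.snp2_id)

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.gene1_id, self.gene2_id)

    @property
    def dependency_class(self) -> str:
        """Deterministic map from the unordered pair of triplet kinds."""
        kinds = frozenset([self.triplet1_kind, self.triplet2_kind])
        if kinds == {"mutual"}:
            return "mutual_mutual"
        if kinds == {"directional"}:
            return "directional_directional"
        return "mixed"

    @property
    def worst_marginal_p(self) -> float:
        """Max of the four marginal association p-values (dedup key)."""
        return max(self.marginal_p.values())

    def key(self) -> tuple[str, str, str, str]:
        return (self.snp1_id, self.snp2_id, self.gene1_id, self.gene2_id)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Sort a pair of identifiers lexicographically."""
    return (a, b) if a < b else (b, a)
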