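"""Sample-permutation null, per-run pipeline counts and empirical FDR.

Shuffling which genotype profile belongs to which sample breaks every
SNP-gene cross-link while leaving the correlation structure among the
genotype profiles and among the expression profiles untouched — each
block keeps its internal LD / co-expression structure.  Running the
full discovery pipeline on each permuted dataset yields the null
distribution of association-pair, triplet and quartet counts; pooling
the permuted quartets gives the "permuted set" used for all
real-vs-permuted comparisons.

Conventions:

* ``empirical_p`` (primary) uses the add-one rule
  (1 + #{perm >= real}) / (1 + n_perms), which can never return 0 at a
  finite number of permutations; the raw proportion is also reported.
* ``empirical_fdr`` = mean(perm counts) / real count, capped at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .association import ASSOC_THRESHOLD, associate_all, DEFAULT_SOURCE_CATEGORIES
from .datatypes import ExpressionMatrix, GenotypeMatrix, Quartet
from .quartets import assemble_quartets, filter_quartets
from .triplets import NOMINAL_ALPHA, build_triplets

logger = logging.getLogger(__name__)

DEFAULT_N_PERMS = 100


@dataclass
class PermutationRun:
    """Counts and surviving quartets for one permuted dataset."""

    perm_index: int
    seed: int
    n_assoc_pairs: int
    n_triplets: int
    n_quartets: int
    n_cooperating: int
    n_unique_targets: int
    quartets: list[Quartet] = field(default_factory=list)


@dataclass
class PermutedSet:
    """All quartets pooled across permutations, tagged with perm_index."""

    quartets: list[Quartet]

    @property
    def size(self) -> int:
        return len(self.quartets)


def permute_samples(
    geno: GenotypeMatrix, seed: int | None = None, permutation=None
) -> GenotypeMatrix:
    """Reassign genotype profiles to sample labels uniformly at random.

    The sample ID list is unchanged (so alignment with the expression
    matrix is preserved) but row ``i`` of the returned count matrix is
    the genotype profile of a randomly chosen original sample.  Per-SNP
    marginals and SNP-SNP correlations are identical before and after;
    only SNP-gene links are broken.

    An explicit ``permutation`` (index array, e.g. the identity) takes
    precedence over ``seed``.
    """
    if permutation is not None:
        perm = np.asarray(permutation)
        if sorted(perm.tolist()) != list(range(geno.n_samples)):
            raise ValueError("permutation must be a rearrangement of sample indices")
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(geno.n_samples)
    return GenotypeMatrix(
        samples=list(geno.samples),
        snps=list(geno.snps),
        counts=geno.counts[perm, :],
    )


def run_discovery(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    threshold: float = ASSOC_THRESHOLD,
    alpha: float = NOMINAL_ALPHA,
    source_categories=DEFAULT_SOURCE_CATEGORIES,
):
    """associate -> triplets -> quartets with all filters.

    Returns (assocs, triplets, unfiltered quartets, final quartets,
    per-stage counts).  Shared by the real-data pipeline and every
    permutation run.
    """
    assocs = associate_all(geno, expr, threshold, source_categories)
    trips = build_triplets(assocs, geno, expr, alpha)
    raw_quartets = assemble_quartets(trips)
    final, counts = filter_quartets(raw_quartets, trips, geno, expr, alpha)
    counts = {
        "assoc_pairs": len(assocs),
        "triplets": len(trips),
        **counts,
    }
    return assocs, trips, raw_quartets, final, counts


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Per-permutation seeds from one master seed via a counter."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def run_null(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    n_perms: int = DEFAULT_N_PERMS,
    base_threshold: float = ASSOC_THRESHOLD,
    seeds: list[int] | None = None,
    master_seed: int = 0,
    alpha: float = NOMINAL_ALPHA,
    source_categories=DEFAULT_SOURCE_CATEGORIES,
) -> list[PermutationRun]:
    """Run the full discovery pipeline on each of ``n_perms`` permutations."""
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    if seeds is None:
        seeds = derive_seeds(master_seed, n_perms)
    if len(seeds) != n_perms:
        raise ValueError("need one seed per permutation")
    runs: list[PermutationRun] = []
    for i, seed in enumerate(seeds):
        try:
            perm_geno = permute_samples(geno, seed)
            assocs, trips, raw, final, counts = run_discovery(
                perm_geno, expr, base_threshold, alpha, source_categories
            )
        except Exception as exc:
            raise RuntimeError(f"permutation {i} (seed {seed}) failed") from exc
        for q in final:
            q.perm_index = i
        runs.append(
            PermutationRun(
                perm_index=i,
                seed=seed,
                n_assoc_pairs=counts["assoc_pairs"],
                n_triplets=counts["triplets"],
                n_quartets=counts["assembled"],
                n_cooperating=counts["cooperating"],
                n_unique_targets=counts["unique_targets"],
                quartets=final,
            )
        )
    return runs


def pool_permuted(runs: list[PermutationRun]) -> PermutedSet:
    """Combine all surviving quartets across permutations into one set."""
    pooled: list[Quartet] = []
    for run in runs:
        pooled.extend(run.quartets)
    return PermutedSet(quartets=pooled)


@dataclass(frozen=True)
class EmpiricalStats:
    """Empirical significance of a real-data count against permutations."""

    empirical_p: float          # add-one convention (primary)
    empirical_p_raw: float      # raw proportion #{perm >= real}/n_perms
    empirical_fdr: float | None  # mean(perm)/real, capped at 1; None if real=0


def empirical_stats(real_count: int, perm_counts: list[int]) -> EmpiricalStats:
    """Empirical p (add-one and raw) and empirical FDR for a count."""
    if not perm_counts:
        raise ValueError("perm_counts is empty")
    if real_count < 0 or any(c < 0 for c in perm_counts):
        raise ValueError("counts must be non-negative")
    arr = np.asarray(perm_counts)
    n = arr.size
    n_ge = int(np.sum(arr >= real_count))
    p_add_one = (1 + n_ge) / (1 + n)
    p_raw = n_ge / n
    if real_count == 0:
        fdr = None
    else:
        fdr = min(float(arr.mean()) / real_count, 1.0)
    return EmpiricalStats(
        empirical_p=float(p_add_one), empirical_p_raw=float(p_raw), empirical_fdr=fdr
    )
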