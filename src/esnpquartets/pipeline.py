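"""End-to-end orchestration: configuration, artifact files and the run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as qio
from .association import ASSOC_THRESHOLD, DEFAULT_SOURCE_CATEGORIES, is_cis
from .characterize import characterize_quartets
from .permutation import (
    DEFAULT_N_PERMS,
    empirical_stats,
    pool_permuted,
    run_discovery,
    run_null,
)
from .triplets import NOMINAL_ALPHA

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs, outputs and tuning knobs for a full run."""

    genotypes: str
    expression: str
    gene_bed: str
    exon_bed: str | None = None
    tf_bed: str | None = None
    outdir: str = "results"
    assoc_threshold: float = ASSOC_THRESHOLD
    nominal_alpha: float = NOMINAL_ALPHA
    n_perms: int = DEFAULT_N_PERMS
    master_seed: int = 0
    source_categories: list[str] = field(
        default_factory=lambda: sorted(DEFAULT_SOURCE_CATEGORIES)
    )

    def __post_init__(self) -> None:
        if not (0 < self.assoc_threshold < 1) or not (0 < self.nominal_alpha < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.n_perms < 0:
            raise ValueError("n_perms must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_associations(assocs, geno, expr, path: Path) -> None:
    rows = []
    for r in assocs:
        snp = geno.snp(r.snp_id)
        gene = expr.gene(r.gene_id)
        rows.append(
            {
                "snp_id": r.snp_id,
                "gene_id": r.gene_id,
                "chrom_snp": snp.chrom,
                "pos_snp": snp.pos,
                "chrom_gene": gene.chrom,
                "n_used": r.n_used,
                "beta": r.beta,
                "t_stat": r.t_stat,
                "p_value": r.p_value,
                "direction": r.direction,
                "cis_trans": "cis" if is_cis(snp, gene) else "trans",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "snp_id", "gene_id", "chrom_snp", "pos_snp", "chrom_gene",
            "n_used", "beta", "t_stat", "p_value", "direction", "cis_trans",
        ],
    ).to_csv(path, sep="\t", index=False)


def _write_triplets(trips, path: Path) -> None:
    pd.DataFrame(
        [
            {
                "snp_id": t.snp_id,
                "gene1_id": t.gene1_id,
                "gene2_id": t.gene2_id,
                "p1": t.p1,
                "p2": t.p2,
                "p1_given_g2": t.p1_given_g2,
                "p2_given_g1": t.p2_given_g1,
                "kind": t.kind,
                "directional_target": t.directional_target or "",
            }
            for t in trips
        ],
        columns=[
            "snp_id", "gene1_id", "gene2_id", "p1", "p2",
            "p1_given_g2", "p2_given_g1", "kind", "directional_target",
        ],
    ).to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute io -> associate -> triplets -> quartets -> permutations -> characterize.

    Writes associations.tsv, triplets.tsv, quartets.tsv,
    permutation_summary.tsv, permuted_quartets.tsv,
    characterization_report.json and manifest.json into
    ``config.outdir``.  Returns the manifest dict (per-stage counts,
    config hash, seeds).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "io"
    try:
        geno = qio.load_genotypes(config.genotypes, config.exon_bed, config.tf_bed)
        expr = qio.load_expression(
            config.expression, config.gene_bed, sample_ids=geno.samples
        )
        qio.check_id_collisions(geno, expr)
        geno, expr = qio.intersect_samples(geno, expr)

        stage = "discovery"
        cats = frozenset(config.source_categories)
        assocs, trips, raw_quartets, final, counts = run_discovery(
            geno, expr, config.assoc_threshold, config.nominal_alpha, cats
        )
        _write_associations(assocs, geno, expr, out / "associations.tsv")
        _write_triplets(trips, out / "triplets.tsv")

        stage = "characterize"
        betas = {(r.snp_id, r.gene_id): r.beta for r in assocs}
        char_rows = characterize_quartets(final, geno, expr, betas)
        pd.DataFrame(char_rows).to_csv(out / "quartets.tsv", sep="\t", index=False)
        with open(out / "characterization_report.json", "w") as fh:
            json.dump(char_rows, fh, indent=2, default=str)

        manifest = {
            "config_hash": config.config_hash(),
            "master_seed": config.master_seed,
            "n_samples": geno.n_samples,
            "n_snps": geno.n_snps,
            "n_genes": expr.n_genes,
            "stage_counts": counts,
            "permutations": None,
        }

        if config.n_perms > 0:
            stage = "permutation"
            runs = run_null(
                geno,
                expr,
                n_perms=config.n_perms,
                base_threshold=config.assoc_threshold,
                master_seed=config.master_seed,
                alpha=config.nominal_alpha,
                source_categories=cats,
            )
            pd.DataFrame(
                [
                    {
                        "perm_index": r.perm_index,
                        "seed": r.seed,
                        "n_assoc_pairs": r.n_assoc_pairs,
                        "n_triplets": r.n_triplets,
                        "n_quartets": r.n_quartets,
                        "n_cooperating": r.n_cooperating,
                        "n_unique_targets": r.n_unique_targets,
                    }
                    for r in runs
                ]
            ).to_csv(out / "permutation_summary.tsv", sep="\t", index=False)
            pooled = pool_permuted(runs)
            pd.DataFrame(
                [
                    {
                        "perm_index": q.perm_index,
                        "snp1_id": q.snp1_id,
                        "snp2_id": q.snp2_id,
                        "gene1_id": q.gene1_id,
                        "gene2_id": q.gene2_id,
                    }
                    for q in pooled.quartets
                ]
            ).to_csv(out / "permuted_quartets.tsv", sep="\t", index=False)
            es = empirical_stats(
                counts["unique_targets"], [r.n_unique_targets for r in runs]
            )
            manifest["permutations"] = {
                "n_perms": config.n_perms,
                "seeds": [r.seed for r in runs],
                "permuted_set_size": pooled.size,
                "empirical_p": es.empirical_p,
                "empirical_p_raw": es.empirical_p_raw,
                "empirical_fdr": es.empirical_fdr,
            }
        else:
            manifest["permutations"] = {"n_perms": 0, "skipped": True}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
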