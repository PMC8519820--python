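"""End-to-end orchestration: filter -> fingerprint -> prune -> relate.

Thin glue over the stage modules so the CLI, the synthetic benchmark and
tests all run the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ldscaffold.fingerprint import Fingerprint, SimilarityConfig, fingerprints_for_matrix
from ldscaffold.popvar_io import (
    AccessionPanel,
    FilterReport,
    GenotypeMatrix,
    SiteFilterConfig,
    SiteRecord,
    filter_sites,
)
from ldscaffold.relations import Relation, RelationConfig, all_vs_all, prune_widespread
from ldscaffold.simpop import SimConfig

__all__ = [
    "PipelineResult",
    "run_pipeline",
    "subset_accessions",
    "benchmark_config",
    "benchmark_site_filter",
]


@dataclass
class PipelineResult:
    filtered: GenotypeMatrix
    report: FilterReport
    fingerprints: list[Fingerprint]
    relations: list[Relation]


def run_pipeline(
    matrix: GenotypeMatrix,
    site_cfg: SiteFilterConfig | None = None,
    sim_cfg: SimilarityConfig | None = None,
    rel_cfg: RelationConfig | None = None,
) -> PipelineResult:
    """Run site filtering, fingerprinting, widespread-pattern pruning and
    the all-vs-all relation comparison on one genotype matrix."""
    site_cfg = site_cfg or SiteFilterConfig()
    sim_cfg = sim_cfg or SimilarityConfig()
    rel_cfg = rel_cfg or RelationConfig()
    filtered, report = filter_sites(matrix, site_cfg)
    fps = fingerprints_for_matrix(filtered, sim_cfg)
    pruned, _ = prune_widespread(fps, sim_cfg, rel_cfg)
    relations = all_vs_all(pruned, sim_cfg, rel_cfg)
    return PipelineResult(filtered=filtered, report=report, fingerprints=pruned, relations=relations)


def subset_accessions(matrix: GenotypeMatrix, n: int) -> GenotypeMatrix:
    """Restrict a matrix to its first ``n`` accessions (panel order)."""
    if not 1 <= n <= len(matrix.panel):
        raise ValueError(f"cannot take {n} accessions from a panel of {len(matrix.panel)}")
    panel = AccessionPanel(matrix.panel.names[:n])
    sites = {
        contig: [
            SiteRecord(
                contig=r.contig,
                pos=r.pos,
                ref_allele=r.ref_allele,
                alt_alleles=r.alt_alleles,
                calls=r.calls[:n].copy(),
                depths=None if r.depths is None else r.depths[:n].copy(),
                total_depth=r.total_depth,
            )
            for r in recs
        ]
        for contig, recs in matrix.sites.items()
    }
    return GenotypeMatrix(panel=panel, sites=sites, contig_lengths=dict(matrix.contig_lengths))


def benchmark_config(seed: int, n_founders: int = 8, n_accessions: int = 50) -> SimConfig:
    """The default fixed-seed synthetic benchmark: 2 chromosomes of
    10 Mbp, 50 accessions, 8 founders, 3.5 SNPs/kbp, ~40 contigs.

    The population is carrier-limited: variants are mostly
    founder-private (strongly skewed site frequency spectrum) and only
    40% of each genome derives from the shared founder pool, so pattern
    detectability genuinely depends on how many accessions happen to
    share a haplotype — the regime in which panel size and founder
    relatedness drive relation recovery.
    """
    return SimConfig(
        seed=seed,
        n_chromosomes=2,
        chromosome_length=10_000_000,
        n_founders=n_founders,
        n_accessions=n_accessions,
        variant_density=3.5,
        recombination_rate=12.0,
        relatedness=0.4,
        clade_weight_power=4.0,
        het_fraction=0.02,
        missing_rate=0.012,
        genotype_error_rate=0.0005,
        contig_length_mean=500_000,
        contig_length_sd=120_000,
        contig_length_min=150_000,
        flip_probability=0.5,
    )


def benchmark_site_filter() -> SiteFilterConfig:
    """Site filter used by the recovery benchmark.

    An absolute carrier floor (three ref and three alt genotypes)
    replaces the role of the fraction-based MAF threshold so that every
    panel size faces the identical site-inclusion rule; a fractional
    cutoff would flip from two to three required carriers between 30 and
    50 accessions and confound the panel-size comparison.
    """
    return SiteFilterConfig(min_ref_genotypes=3, min_alt_genotypes=3)
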