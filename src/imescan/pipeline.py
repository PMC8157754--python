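"""End-to-end orchestration of the motif-discovery and validation stages.

``run_discovery`` chains the full candidate scan on a corpus directory
(genome + GFF3 + VCF + condition expression): intron extraction, SNP
filtering and masking, the four-criterion hexamer selection, and the
co-expression refinement against occurrence-matched controls.
``run_allelic`` runs the allelic-variant validation for a motif list
against per-accession genotypes and expression.

SNP-filter defaults here are proportional to the synthetic cohort size
(min_minor=10 of up to 400 haploid alleles ~ 2.5% minor-allele fraction,
min_called=300 = 75% call rate); the per-operation defaults keep the
published large-cohort values (50 / 500), which assume thousands of
haploid calls per site.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation_io as ann
from . import variants_io as var
from . import kmer_stats as km
from . import coexpression as co
from . import allelic_effects as al


@dataclass
class DiscoveryConfig:
    k: int = 6
    trim: int = 3
    bins: int = 10
    n_sim_entropy: int = 10_000
    n_sim_contrast: int = 10_000
    alpha: float = 0.05
    min_minor: int = 10
    min_called: int = 300
    coexpr_threshold: float = 0.05
    control_tol: float = 0.10
    max_controls: int | None = 50
    max_pairs: int = 200_000
    min_intron_length: int = 10
    utr_extension: int = 5


@dataclass
class DiscoveryResult:
    introns: list
    first_introns: list
    snps: var.SnpTable
    assignment: pd.DataFrame
    stats: pd.DataFrame
    candidates: list[str]
    effects: dict
    refined: list[str]
    conservation: var.ConservationSummary


def load_introns(
    gff: str, fasta: str, min_length: int = 10, utr_extension: int = 5
) -> tuple[list, ann.GenomeAnnotation]:
    annotation = ann.read_gff3(str(gff))
    introns = ann.extract_introns(annotation, min_length=min_length)
    introns = ann.flag_utr5_introns(introns, annotation, extension=utr_extension)
    introns = ann.fetch_sequences(introns, str(fasta))
    return introns, annotation


def run_discovery(
    corpus_dir: str, seed: int = 0, config: DiscoveryConfig | None = None
) -> DiscoveryResult:
    cfg = config or DiscoveryConfig()
    d = Path(corpus_dir)
    rng = np.random.default_rng(seed)

    introns, annotation = load_introns(
        d / "annotation.gff3",
        d / "genome.fa",
        min_length=cfg.min_intron_length,
        utr_extension=cfg.utr_extension,
    )
    first, _other = ann.split_first_other(introns)

    snps = var.filter_snps(
        str(d / "variants.vcf"), min_minor_count=cfg.min_minor, min_called=cfg.min_called
    )
    snps_in, assignment = var.snps_in_intervals(snps, introns, trim=cfg.trim)
    masked = var.masked_intron_sequences(introns, assignment)
    conservation = var.conservation_summary(first, assignment, k=cfg.k, trim=cfg.trim)

    stats = km.compute_kmer_statistics(
        introns,
        masked_sequences=masked,
        k=cfg.k,
        trim=cfg.trim,
        bins=cfg.bins,
        n_sim_entropy=cfg.n_sim_entropy,
        n_sim_contrast=cfg.n_sim_contrast,
        seed=rng,
    )
    stats = km.select_candidates(stats, alpha=cfg.alpha)
    candidates = list(stats.index[stats["candidate"]])

    expr = co.read_expression_tsv(d / "expr_conditions.tsv", provenance="condition")
    gene_filter = co.filter_expressed_genes(expr, introns, mode="condition")
    utr_ok = co.utr5_genes(introns)
    gene_filter = [g for g in gene_filter if g in utr_ok] or gene_filter

    table = km.count_kmers(introns, k=cfg.k, trim=cfg.trim)
    effects = {}
    for motif in candidates:
        effects[motif] = co.coexpression_effect(
            motif,
            expr,
            first,
            table,
            gene_filter=gene_filter,
            tol=cfg.control_tol,
            max_controls=cfg.max_controls,
            max_pairs=cfg.max_pairs,
            seed=rng,
        )
    refined = co.refine_candidates(effects, threshold=cfg.coexpr_threshold)

    return DiscoveryResult(
        introns=introns,
        first_introns=first,
        snps=snps_in,
        assignment=assignment,
        stats=stats,
        candidates=candidates,
        effects=effects,
        refined=refined,
        conservation=conservation,
    )


@dataclass
class AllelicConfig:
    min_minor: int = 10
    min_called: int = 300
    sig_alpha: float = 0.05
    min_group: int = 2
    accession_threshold: float = 1.0


def run_allelic(
    corpus_dir: str,
    motifs: list[str],
    config: AllelicConfig | None = None,
    introns: list | None = None,
) -> tuple[list[al.AllelicSummary], pd.DataFrame]:
    cfg = config or AllelicConfig()
    d = Path(corpus_dir)
    if introns is None:
        introns, _ = load_introns(d / "annotation.gff3", d / "genome.fa")
    first, _ = ann.split_first_other(introns)
    genotypes = var.filter_snps(
        str(d / "variants.vcf"), min_minor_count=cfg.min_minor, min_called=cfg.min_called
    )
    expr = co.read_expression_tsv(d / "expr_accessions.tsv", provenance="accession")
    gene_filter = co.filter_expressed_genes(
        expr, introns, mode="accession", accession_threshold=cfg.accession_threshold
    )
    summaries = []
    for motif in motifs:
        per_gene = al.motif_allele_effects(
            motif, first, genotypes, expr, gene_filter=gene_filter, min_group=cfg.min_group
        )
        s = al.summarize_motif(motif, per_gene, sig_alpha=cfg.sig_alpha)
        if s is not None:
            summaries.append(s)
    table = al.allelic_table(summaries) if summaries else pd.DataFrame()
    return summaries, table
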