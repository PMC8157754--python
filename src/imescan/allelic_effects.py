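"""Allelic-variant tests: do natural mutations in a motif lower expression?

For each gene carrying a motif in its first intron, accessions are split
into a canonical set (reference motif intact at every covered position)
and a variant set (>= 1 alternate allele anywhere in the motif footprint).
Accession-level expression of the two sets is compared per gene (Welch
two-sample t-test; Cohen's d signed canonical-minus-variant, so positive d
means the intact motif is the higher-expressed allele), and the per-gene d
distribution is summarised per motif. Across motifs, positive-median
counts of candidates vs non-candidate control hexamers feed a one-sided
Fisher test, and the candidate positive count feeds a two-sided exact
binomial test with p0 = 0.5.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import IntronRecord, reverse_complement
from .coexpression import cohens_d
from .kmer_stats import bh_fdr
from .variants_io import SnpTable

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT_IUPAC = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_reverse_complement(motif: str) -> str:
    return motif.translate(_COMPLEMENT_IUPAC)[::-1]


def iupac_regex(motif: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[b]}]" for b in motif.upper()))


@dataclass
class MotifLocus:
    """All occurrences of a motif within one gene's first intron."""

    gene_id: str
    intron_id: str
    chrom: str
    motif: str
    offsets: list[int] = field(default_factory=list)
    genomic_positions: set[int] = field(default_factory=set)


def _overlapping_matches(pattern: re.Pattern, seq: str) -> list[int]:
    out = []
    i = 0
    while True:
        m = pattern.search(seq, i)
        if m is None:
            return out
        out.append(m.start())
        i = m.start() + 1


def locate_motif(introns: list[IntronRecord], motif: str) -> list[MotifLocus]:
    """All occurrences of an IUPAC motif (either strand) per intron.

    Offsets are transcript-oriented; the genomic footprint of every
    occurrence is recorded for genotype lookup.
    """
    if len(motif) < 4:
        raise ValueError("motif must be at least 4 bp")
    fwd = iupac_regex(motif)
    rev = iupac_regex(iupac_reverse_complement(motif))
    length = len(motif)
    loci = []
    for rec in introns:
        offsets = sorted(
            set(_overlapping_matches(fwd, rec.sequence))
            | set(_overlapping_matches(rev, rec.sequence))
        )
        if not offsets:
            continue
        positions: set[int] = set()
        for off in offsets:
            if rec.strand == "+":
                positions.update(range(rec.start + off, rec.start + off + length))
            else:
                positions.update(range(rec.end - off - length, rec.end - off))
        loci.append(
            MotifLocus(
                gene_id=rec.gene_id,
                intron_id=rec.intron_id,
                chrom=rec.chrom,
                motif=motif,
                offsets=offsets,
                genomic_positions=positions,
            )
        )
    return loci


def split_allele_sets(
    locus: MotifLocus, genotypes: SnpTable
) -> tuple[list[str], list[str]]:
    """Split accessions into canonical (intact motif) and variant sets.

    An accession is a variant iff it carries >= 1 alternate allele at any
    genomic position covered by any occurrence of the motif in the gene;
    accessions with missing calls at every covered site are dropped. Genes
    whose motif footprint contains no SNP yield an empty variant set.
    """
    if genotypes.genotypes is None or genotypes.accessions is None:
        raise ValueError("per-accession genotypes required")
    sites = genotypes.sites
    on_chrom = sites["chrom"] == locus.chrom
    covered = sites["pos"].isin(locus.genomic_positions) & on_chrom
    idx = np.flatnonzero(covered.to_numpy())
    if len(idx) == 0:
        return list(genotypes.accessions), []
    gt = genotypes.genotypes[idx]  # (n_sites_covered, n_accessions)
    any_alt = (gt > 0).any(axis=0)
    any_called = (gt >= 0).any(axis=0)
    canonical = [
        a
        for j, a in enumerate(genotypes.accessions)
        if any_called[j] and not any_alt[j]
    ]
    variant = [a for j, a in enumerate(genotypes.accessions) if any_alt[j]]
    return canonical, variant


def allele_effect(
    gene_id: str,
    sets: tuple[list[str], list[str]],
    accession_expr: pd.DataFrame,
    min_group: int = 2,
) -> tuple[float, float] | None:
    """Cohen's d (canonical minus variant) and Welch-t p for one gene."""
    canonical, variant = sets
    if gene_id not in accession_expr.index:
        return None
    row = accession_expr.loc[gene_id]
    x = row[[a for a in canonical if a in row.index]].to_numpy(dtype=float)
    y = row[[a for a in variant if a in row.index]].to_numpy(dtype=float)
    if len(x) < min_group or len(y) < min_group:
        logger.debug("gene %s skipped: group sizes %d/%d", gene_id, len(x), len(y))
        return None
    d = cohens_d(x, y).cohens_d
    p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    return d, p


@dataclass
class AllelicSummary:
    """Per-motif summary of per-gene allele effects (Table-4-style row)."""

    motif: str
    per_gene: pd.DataFrame  # gene, n_canonical, n_variant, cohens_d, t_p
    mean_d: float
    median_d: float
    t_p: float  # one-sample t vs 0, raw (FDR applied across motifs)
    n_genes: int
    mean_d_sig: float
    median_d_sig: float
    n_sig: int
    n_sig_positive: int
    wilcoxon_p_sig: float  # raw (FDR applied across motifs)


def motif_allele_effects(
    motif: str,
    first_introns: list[IntronRecord],
    genotypes: SnpTable,
    accession_expr: pd.DataFrame,
    gene_filter=None,
    min_group: int = 2,
) -> pd.DataFrame:
    """Per-gene allele effects for one motif across all harbouring genes."""
    allowed = set(gene_filter) if gene_filter is not None else None
    rows = []
    for locus in locate_motif(first_introns, motif):
        if allowed is not None and locus.gene_id not in allowed:
            continue
        canonical, variant = split_allele_sets(locus, genotypes)
        if not variant:
            continue  # no natural variation at the locus: untestable, not an error
        res = allele_effect(
            locus.gene_id, (canonical, variant), accession_expr, min_group
        )
        if res is None:
            continue
        d, p = res
        if np.isnan(d):
            continue
        rows.append((locus.gene_id, len(canonical), len(variant), d, p))
    return pd.DataFrame(
        rows, columns=["gene", "n_canonical", "n_variant", "cohens_d", "t_p"]
    )


def summarize_motif(
    motif: str, per_gene: pd.DataFrame, sig_alpha: float = 0.05
) -> AllelicSummary | None:
    """Summarise a per-gene effect table into a Table-4-style row.

    The "significant genes" subset keeps genes whose per-gene two-sample
    test has p < sig_alpha (uncorrected — a filter, not a selection); its d
    distribution gets a Wilcoxon signed-rank test against 0.
    """
    if len(per_gene) == 0:
        return None
    d = per_gene["cohens_d"].to_numpy()
    t_p = (
        float(stats.ttest_1samp(d, 0.0).pvalue) if len(d) >= 2 else float("nan")
    )
    sig = per_gene[per_gene["t_p"] < sig_alpha]
    ds = sig["cohens_d"].to_numpy()
    if len(ds) >= 2 and np.any(ds != 0):
        wil_p = float(stats.wilcoxon(ds).pvalue)
    else:
        wil_p = float("nan")
    return AllelicSummary(
        motif=motif,
        per_gene=per_gene,
        mean_d=float(d.mean()),
        median_d=float(np.median(d)),
        t_p=t_p,
        n_genes=len(d),
        mean_d_sig=float(ds.mean()) if len(ds) else float("nan"),
        median_d_sig=float(np.median(ds)) if len(ds) else float("nan"),
        n_sig=len(ds),
        n_sig_positive=int((ds > 0).sum()),
        wilcoxon_p_sig=wil_p,
    )


def allelic_table(summaries: list[AllelicSummary]) -> pd.DataFrame:
    """Cross-motif summary table with FDR applied within each test family."""
    df = pd.DataFrame(
        {
            "motif": [s.motif for s in summaries],
            "mean_d": [s.mean_d for s in summaries],
            "median_d": [s.median_d for s in summaries],
            "t_p_fdr": bh_fdr([s.t_p for s in summaries]),
            "mean_d_sig": [s.mean_d_sig for s in summaries],
            "median_d_sig": [s.median_d_sig for s in summaries],
            "n_genes": [s.n_genes for s in summaries],
            "n_sig": [s.n_sig for s in summaries],
            "n_sig_positive": [s.n_sig_positive for s in summaries],
            "wilcoxon_p_fdr": bh_fdr([s.wilcoxon_p_sig for s in summaries]),
        }
    ).set_index("motif")
    return df


def cross_motif_enrichment(
    candidate_summaries: list[AllelicSummary],
    control_summaries: list[AllelicSummary],
    use_median: bool = True,
) -> tuple[float, float, np.ndarray]:
    """Positive-sign enrichment of candidates over control hexamers.

    Fisher exact, one-sided (greater), on [[cand+, cand-], [ctrl+, ctrl-]];
    two-sided exact binomial on the candidate positive count at p0 = 0.5.
    """

    def _positive(s: AllelicSummary) -> bool:
        value = s.median_d if use_median else s.mean_d
        return value > 0

    cand = [_positive(s) for s in candidate_summaries]
    ctrl = [_positive(s) for s in control_summaries]
    table = np.array(
        [
            [sum(cand), len(cand) - sum(cand)],
            [sum(ctrl), len(ctrl) - sum(ctrl)],
        ]
    )
    binom_p = float(
        stats.binomtest(sum(cand), len(cand), 0.5, alternative="two-sided").pvalue
    )
    if len(ctrl) == 0:
        return float("nan"), binom_p, table
    fisher_p = float(stats.fisher_exact(table, alternative="greater")[1])
    return fisher_p, binom_p, table


def sign_tests(n_positive: int, n_total: int, controls: tuple[int, int]) -> tuple[float, float]:
    """Direct-form cross-motif tests from printed counts.

    ``controls`` = (control positives, control negatives). Returns the
    one-sided Fisher p for the 2x2 table and the two-sided binomial p at
    p0 = 0.5 for the candidate counts.
    """
    table = np.array(
        [[n_positive, n_total - n_positive], [controls[0], controls[1]]]
    )
    fisher_p = float(stats.fisher_exact(table, alternative="greater")[1])
    binom_p = float(
        stats.binomtest(n_positive, n_total, 0.5, alternative="two-sided").pvalue
    )
    return fisher_p, binom_p
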