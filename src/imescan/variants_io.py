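"""Population-SNP handling: filtering, intron intersection, masking, density.

SNPs from a population VCF are reduced to biallelic single-nucleotide sites
passing a minor-allele-count and a called-allele-count threshold (alleles
counted as haploid counts, i.e. per chromosome copy). Sites falling inside
introns — after excluding a few bp at each intron end to keep the nearly
invariant splice sites out of the statistics — are used to mask intron
sequences position-wise, which turns k-mer counting into a conservation
measurement: the ratio of masked to unmasked counts of a k-mer is its
conservation rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .annotation_io import IntronRecord

logger = logging.getLogger(__name__)

MASK_CHAR = "*"


@dataclass
class SnpTable:
    """Filtered SNP sites, optionally with per-accession allele dosages.

    ``sites`` columns: chrom, pos (0-based), ref, alt, minor_count, called.
    ``genotypes``: int8 array (n_sites x n_accessions) of alternate-allele
    dosages, -1 for missing calls; ``accessions`` names its columns.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray | None = None
    accessions: list[str] | None = None

    def __len__(self) -> int:
        return len(self.sites)

    def subset(self, index) -> "SnpTable":
        idx = np.asarray(index)
        gt = self.genotypes[idx] if self.genotypes is not None else None
        return SnpTable(
            self.sites.iloc[idx].reset_index(drop=True), gt, self.accessions
        )

    def positions(self, chrom: str) -> np.ndarray:
        sub = self.sites[self.sites["chrom"] == chrom]
        return sub["pos"].to_numpy()


@dataclass
class ConservationSummary:
    """Corpus-level SNP density and the expected k-mer conservation C_r."""

    n_snp: int
    n_bp: int
    k: int

    @property
    def density(self) -> float:
        return self.n_snp / self.n_bp

    @property
    def expected_conservation(self) -> float:
        return expected_conservation(self.density, self.k)


def read_vcf(path: str, with_genotypes: bool = True) -> SnpTable:
    """Read single-nucleotide records from a VCF (multi-allelic sites split).

    Per-accession genotypes become alternate-allele dosages (haploid count
    per accession: 0, 1 or 2; -1 missing). Records lacking GT are summarised
    from AC/AN when present; a VCF with neither GT nor AC/AN is rejected.
    """
    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    rows = []
    dosages = []
    has_samples = len(accessions) > 0
    for var in vcf:
        if var.REF is None or len(var.REF) != 1:
            continue
        alts = [a for a in var.ALT if len(a) == 1 and a in "ACGT"]
        if not alts:
            continue
        if has_samples:
            gt = np.asarray(var.genotype.array())[:, :2]
            missing = (gt < 0).any(axis=1)
            dose = (gt > 0).sum(axis=1).astype(np.int8)
            dose[missing] = -1
            called = int(2 * (~missing).sum())
            alt_count = int(dose[~missing].sum())
        else:
            an = var.INFO.get("AN")
            ac = var.INFO.get("AC")
            if an is None or ac is None:
                raise ValueError(
                    f"VCF record {var.CHROM}:{var.POS} lacks both GT and AC/AN"
                )
            called = int(an)
            alt_count = int(ac if np.isscalar(ac) else sum(ac))
            dose = None
        minor = min(alt_count, called - alt_count)
        rows.append(
            (var.CHROM, var.POS - 1, var.REF, ",".join(alts), minor, called)
        )
        if dose is not None:
            dosages.append(dose)
    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "minor_count", "called"]
    )
    gt = np.asarray(dosages, dtype=np.int8) if dosages else None
    return SnpTable(sites, gt, accessions if has_samples else None)


def filter_snps(
    snps: SnpTable | str, min_minor_count: int = 50, min_called: int = 500
) -> SnpTable:
    """Keep sites with minor-allele haploid count >= ``min_minor_count`` and
    called haploid alleles >= ``min_called``."""
    if not isinstance(snps, SnpTable):
        snps = read_vcf(snps)
    keep = (
        (snps.sites["minor_count"] >= min_minor_count)
        & (snps.sites["called"] >= min_called)
    ).to_numpy()
    return snps.subset(np.flatnonzero(keep))


def snps_in_intervals(
    snps: SnpTable, intervals: list[IntronRecord], trim: int = 3
) -> tuple[SnpTable, pd.DataFrame]:
    """SNPs inside introns, excluding ``trim`` bp at each intron end.

    Returns the subset SnpTable and an assignment frame (site_index,
    intron_id, offset) with transcript-oriented intron-relative offsets.
    A site inside two overlapping introns is assigned to each.
    """
    pos_by_chrom: dict[str, np.ndarray] = {}
    idx_by_chrom: dict[str, np.ndarray] = {}
    for chrom, sub in snps.sites.groupby("chrom", sort=False):
        order = np.argsort(sub["pos"].to_numpy(), kind="stable")
        pos_by_chrom[chrom] = sub["pos"].to_numpy()[order]
        idx_by_chrom[chrom] = sub.index.to_numpy()[order]
    hits = []
    for rec in intervals:
        pos = pos_by_chrom.get(rec.chrom)
        if pos is None:
            continue
        lo, hi = rec.start + trim, rec.end - trim
        if hi <= lo:
            continue
        a, b = np.searchsorted(pos, [lo, hi])
        for p, site_idx in zip(pos[a:b], idx_by_chrom[rec.chrom][a:b]):
            offset = p - rec.start if rec.strand == "+" else rec.end - 1 - p
            hits.append((int(site_idx), rec.intron_id, int(offset)))
    assign = pd.DataFrame(hits, columns=["site_index", "intron_id", "offset"])
    kept = np.unique(assign["site_index"].to_numpy()) if len(assign) else np.array([], int)
    remap = {old: new for new, old in enumerate(kept)}
    sub = snps.subset(kept)
    if len(assign):
        assign["site_index"] = assign["site_index"].map(remap)
    return sub, assign


def mask_sequence(
    sequence: str, snp_offsets, mask: str = MASK_CHAR
) -> str:
    """Replace SNP positions with a non-nucleotide symbol, length-preserving."""
    if not len(snp_offsets):
        return sequence
    chars = list(sequence)
    for off in snp_offsets:
        if not 0 <= off < len(chars):
            raise IndexError(
                f"SNP offset {off} outside sequence of length {len(chars)}"
            )
        chars[off] = mask
    return "".join(chars)


def masked_intron_sequences(
    introns: list[IntronRecord], assignment: pd.DataFrame
) -> dict[str, str]:
    """Per-intron masked sequences from an snps_in_intervals assignment."""
    offsets = (
        assignment.groupby("intron_id")["offset"].apply(list).to_dict()
        if len(assignment)
        else {}
    )
    return {
        rec.intron_id: mask_sequence(rec.sequence, offsets.get(rec.intron_id, []))
        for rec in introns
    }


def conservation_summary(
    introns: list[IntronRecord], assignment: pd.DataFrame, k: int = 6, trim: int = 3
) -> ConservationSummary:
    """N_SNP / N_bp over the trimmed intron set, and the derived C_r."""
    n_bp = sum(max(0, rec.length - 2 * trim) for rec in introns)
    ids = {rec.intron_id for rec in introns}
    if len(assignment):
        n_snp = int(assignment["intron_id"].isin(ids).sum())
    else:
        n_snp = 0
    return ConservationSummary(n_snp=n_snp, n_bp=n_bp, k=k)


def expected_conservation(density: float, k: int) -> float:
    """Chance that a k-mer contains no SNP under uniform SNP placement:
    (1 - density) ** k."""
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"SNP density must be in [0, 1], got {density}")
    if k < 1:
        raise ValueError("k must be >= 1")
    return (1.0 - density) ** k


def snp_density_profile(
    introns: list[IntronRecord],
    snps: SnpTable,
    flank: int = 20,
) -> pd.Series:
    """Per-position relative SNP frequency around the 5' splice site.

    Positions 1..flank are the first bases of each intron (transcript
    orientation); positions -flank..-1 are the last bases of the preceding
    exon. Frequency at a position = (# introns with a SNP there) /
    (# introns covering it); positions covered by no intron are NaN.
    """
    snp_pos = {
        chrom: set(sub["pos"]) for chrom, sub in snps.sites.groupby("chrom")
    }
    index = list(range(-flank, 0)) + list(range(1, flank + 1))
    hits = pd.Series(0.0, index=index)
    cover = pd.Series(0.0, index=index)
    for rec in introns:
        chrom_snps = snp_pos.get(rec.chrom, set())
        for j in range(1, flank + 1):  # intron interior
            if j > rec.length:
                break
            g = rec.start + j - 1 if rec.strand == "+" else rec.end - j
            cover[j] += 1
            if g in chrom_snps:
                hits[j] += 1
        for j in range(1, flank + 1):  # preceding exon (upstream of 5' site)
            g = rec.start - j if rec.strand == "+" else rec.end + j - 1
            cover[-j] += 1
            if g in chrom_snps:
                hits[-j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = hits / cover
    freq[cover == 0] = np.nan
    return freq


def write_sites_tsv(snps: SnpTable, assignment: pd.DataFrame, path: str) -> None:
    """0-based TSV of intronic sites: chrom, pos, intron_id, intron_offset."""
    merged = assignment.merge(
        snps.sites[["chrom", "pos"]], left_on="site_index", right_index=True
    )
    merged[["chrom", "pos", "intron_id", "offset"]].to_csv(
        path, sep="\t", index=False, header=["chrom", "pos", "intron_id", "intron_offset"]
    )
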