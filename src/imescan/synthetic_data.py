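"""Self-contained synthetic corpus with known planted truth.

Emulates the statistical structure of a plant genome + population-variant
+ expression study at desk scale: an AT-rich multi-gene genome (GC ~ 0.32)
with GT..AG introns whose first introns are longer (lognormal, mean ~260
bp) than other introns (~160 bp); a planted hexamer written into the first
introns of a gene subset at 5'-biased (Beta-distributed) relative
positions; population SNPs at ~0.016 per bp with locally suppressed
density inside planted motif copies (mimicking purifying selection on a
functional element); and two expression matrices — a condition-wise matrix
in which motif genes share a latent expression factor plus an elevated
mean, and an accession-wise matrix in which accessions carrying a mutation
inside a gene's planted motif lose a fixed amount of (log) expression.

Every planted quantity is recorded in a JSON-serialisable truth object, so
downstream statistics can be validated against ground truth. All outputs
are plain-text standard formats readable by this package's own readers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .annotation_io import (
    Gene,
    GenomeAnnotation,
    IntronRecord,
    Transcript,
    reverse_complement,
)

BASES = np.array(list("ACGT"))


@dataclass
class SyntheticTruth:
    """Planted ground truth of one synthetic corpus."""

    motif: str
    motif_genes: list[str] = field(default_factory=list)
    occurrences: dict[str, list[int]] = field(default_factory=dict)
    motif_suppression: float = 0.2
    latent_loading: float = 0.6
    level_shift: float = 0.4
    allele_delta: float = 0.5
    noise_sd: float = 1.0
    position_beta: tuple[float, float] = (2.0, 5.0)
    variant_accessions: dict[str, list[str]] = field(default_factory=dict)
    low_expressed_genes: list[str] = field(default_factory=list)
    seed: int | None = None

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["position_beta"] = tuple(data["position_beta"])
        return cls(**data)


# ---------------------------------------------------------------------------
# genome + annotation


def _lognormal_lengths(rng, mean: float, sigma: float, size: int, minimum: int):
    mu = np.log(mean) - sigma**2 / 2
    return np.maximum(np.round(rng.lognormal(mu, sigma, size)).astype(int), minimum)


def generate_genome(
    n_genes: int = 500,
    n_chroms: int = 5,
    exons_per_gene: tuple[int, int] = (2, 6),
    first_intron_mean: float = 260.0,
    other_intron_mean: float = 160.0,
    intron_sigma: float = 0.55,
    exon_mean: float = 200.0,
    gc: float = 0.32,
    utr_intron_frac: float = 0.35,
    alt_transcript_frac: float = 0.15,
    seed=None,
) -> tuple[dict[str, np.ndarray], GenomeAnnotation]:
    """Random gene models on random AT-rich chromosomes.

    A ``utr_intron_frac`` fraction of genes start their CDS after the first
    intron, placing that intron inside the 5'UTR; an ``alt_transcript_frac``
    fraction (of genes with >= 3 exons) get a second isoform in which the
    first intron is retained (its flanking exons merged).
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genomes: dict[str, list] = {f"chr{c + 1}": [] for c in range(n_chroms)}
    cursors = {c: 0 for c in genomes}
    genes: list[Gene] = []

    for gi in range(n_genes):
        gene_id = f"G{gi + 1:04d}"
        chrom = f"chr{gi % n_chroms + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        exon_lens = _lognormal_lengths(rng, exon_mean, 0.45, n_ex, 60)
        intron_lens = np.concatenate(
            [
                _lognormal_lengths(rng, first_intron_mean, intron_sigma, 1, 30),
                _lognormal_lengths(rng, other_intron_mean, intron_sigma, n_ex - 2, 12),
            ]
        )
        # transcript-local exon intervals
        local_exons = []
        pos = 0
        for e, ln in enumerate(exon_lens):
            local_exons.append((pos, pos + int(ln)))
            if e < n_ex - 1:
                pos += int(ln) + int(intron_lens[e])
        tx_len = local_exons[-1][1]
        utr_intron = rng.random() < utr_intron_frac and n_ex >= 2
        if utr_intron:
            u2 = int(rng.integers(10, min(60, exon_lens[1] - 30)))
            local_utr5 = [local_exons[0], (local_exons[1][0], local_exons[1][0] + u2)]
            cds_from = local_exons[1][0] + u2
        else:
            u1 = int(rng.integers(20, max(21, exon_lens[0] - 30)))
            local_utr5 = [(0, u1)]
            cds_from = u1
        local_cds = [
            (max(s, cds_from), e) for s, e in local_exons if e > cds_from
        ]

        gap = int(rng.integers(300, 900))
        gene_start = cursors[chrom] + gap
        gene_end = gene_start + tx_len

        def to_genomic(iv):
            s, e = iv
            if strand == "+":
                return (gene_start + s, gene_start + e)
            return (gene_end - e, gene_end - s)

        exons = sorted(to_genomic(iv) for iv in local_exons)
        utr5 = sorted(to_genomic(iv) for iv in local_utr5)
        cds = sorted(to_genomic(iv) for iv in local_cds)
        transcripts = [Transcript(f"{gene_id}.1", exons, utr5, cds)]
        if n_ex >= 3 and rng.random() < alt_transcript_frac:
            # first intron retained: merge the two promoter-proximal exons
            if strand == "+":
                merged = [(exons[0][0], exons[1][1])] + exons[2:]
            else:
                merged = exons[:-2] + [(exons[-2][0], exons[-1][1])]
            transcripts.append(Transcript(f"{gene_id}.2", sorted(merged), utr5, cds))
        genes.append(Gene(gene_id, chrom, strand, transcripts))
        cursors[chrom] = gene_end

    chrom_arrays = {}
    for chrom in genomes:
        length = cursors[chrom] + int(rng.integers(300, 900))
        chrom_arrays[chrom] = rng.choice(BASES, size=max(length, 100), p=p)

    # enforce canonical GT..AG splice boundaries in transcript orientation
    for gene in genes:
        arr = chrom_arrays[gene.chrom]
        tx = gene.transcripts[0]
        exons = sorted(tx.exons)
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            if gene.strand == "+":
                arr[e1], arr[e1 + 1] = "G", "T"
                arr[s2 - 2], arr[s2 - 1] = "A", "G"
            else:
                arr[s2 - 2], arr[s2 - 1] = "A", "C"
                arr[e1], arr[e1 + 1] = "C", "T"
    return chrom_arrays, GenomeAnnotation(genes)


def _first_intron_intervals(annotation: GenomeAnnotation) -> dict[str, tuple]:
    """gene_id -> (chrom, start, end, strand) of the gene's first intron."""
    out = {}
    for gene in annotation.genes:
        tx = gene.transcripts[0]
        exons = sorted(tx.exons)
        gaps = [(e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:])]
        if not gaps:
            continue
        gap = gaps[0] if gene.strand == "+" else gaps[-1]
        out[gene.id] = (gene.chrom, gap[0], gap[1], gene.strand)
    return out


def plant_motifs(
    genome: dict[str, np.ndarray],
    annotation: GenomeAnnotation,
    motif: str = "TTTCGA",
    gene_fraction: float = 0.3,
    occurrences_per_intron: int = 2,
    position_beta: tuple[float, float] = (2.0, 5.0),
    trim: int = 3,
    seed=None,
    truth: SyntheticTruth | None = None,
) -> SyntheticTruth:
    """Write motif copies into first introns of a random gene subset.

    Relative positions are drawn from a Beta distribution (default (2, 5):
    5'-biased, clearly non-uniform); copies are non-overlapping and stay
    clear of the ``trim``-bp splice-site margin. The genome is modified in
    place; planted genes and transcript-oriented offsets go into the truth.
    """
    rng = np.random.default_rng(seed)
    L = len(motif)
    if truth is None:
        truth = SyntheticTruth(motif=motif)
    truth.motif = motif
    truth.position_beta = tuple(position_beta)
    firsts = _first_intron_intervals(annotation)
    eligible = [
        g
        for g, (_, s, e, _) in firsts.items()
        if (e - s) >= 2 * trim + occurrences_per_intron * (L + 2)
    ]
    n_pick = int(round(gene_fraction * len(annotation.genes)))
    picked = sorted(
        str(g)
        for g in rng.choice(eligible, size=min(n_pick, len(eligible)), replace=False)
    )
    for gene_id in picked:
        chrom, s, e, strand = firsts[gene_id]
        length = e - s
        offsets: list[int] = []
        for _ in range(occurrences_per_intron):
            for _try in range(50):
                rel = rng.beta(*position_beta)
                off = trim + int(rel * (length - 2 * trim - L))
                if all(abs(off - o) >= L for o in offsets):
                    offsets.append(off)
                    break
        offsets.sort()
        arr = genome[chrom]
        for off in offsets:
            if strand == "+":
                arr[s + off : s + off + L] = list(motif)
            else:
                arr[e - off - L : e - off] = list(reverse_complement(motif))
        truth.occurrences[gene_id] = offsets
    truth.motif_genes = list(picked)
    return truth


# ---------------------------------------------------------------------------
# variants


def generate_variants(
    genome: dict[str, np.ndarray],
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    n_accessions: int = 200,
    base_rate: float = 0.016,
    motif_suppression: float = 0.2,
    ensure_motif_snp: float = 0.0,
    p_common: float = 0.6,
    common_maf: tuple[float, float] = (0.10, 0.45),
    rare_maf: tuple[float, float] = (0.002, 0.02),
    missing_rate: float = 0.02,
    seed=None,
):
    """Population SNPs over gene bodies with suppression in planted motifs.

    Sites are placed per-base Bernoulli at ``base_rate`` (scaled by
    ``motif_suppression`` inside planted motif footprints). Accessions are
    inbred/homozygous, so each contributes 0 or 2 haploid alternate
    alleles; the allele-frequency spectrum is a two-point mixture of common
    and rare sites so a minor-allele-count filter separates them. With
    ``ensure_motif_snp`` > 0, each planted motif gains a common SNP inside
    one of its copies with that probability (for allelic-effect studies).

    Returns (sites, genotypes, accessions): sites is a list of
    (chrom, pos, ref, alt), genotypes an int8 dosage array, and the truth
    gains the per-gene variant accession sets.
    """
    rng = np.random.default_rng(seed)
    truth.motif_suppression = motif_suppression
    accessions = [f"acc{i + 1:04d}" for i in range(n_accessions)]
    L = len(truth.motif)
    firsts = _first_intron_intervals(annotation)
    motif_footprint: dict[str, set[int]] = {}
    for gene_id, offsets in truth.occurrences.items():
        chrom, s, e, strand = firsts[gene_id]
        pos: set[int] = set()
        for off in offsets:
            if strand == "+":
                pos.update(range(s + off, s + off + L))
            else:
                pos.update(range(e - off - L, e - off))
        motif_footprint[gene_id] = pos
    footprint_by_chrom: dict[str, set[int]] = {}
    for gene_id, pos in motif_footprint.items():
        footprint_by_chrom.setdefault(firsts[gene_id][0], set()).update(pos)

    site_keys: set[tuple[str, int]] = set()
    sites: list[tuple[str, int, str, str]] = []
    mafs: list[float] = []

    def add_site(chrom: str, p: int, maf: float) -> None:
        if (chrom, p) in site_keys:
            return
        site_keys.add((chrom, p))
        ref = str(genome[chrom][p])
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        sites.append((chrom, p, ref, alt))
        mafs.append(maf)

    def draw_maf() -> float:
        if rng.random() < p_common:
            return float(rng.uniform(*common_maf))
        return float(rng.uniform(*rare_maf))

    for gene in annotation.genes:
        span = gene.transcripts[0].span
        fp = footprint_by_chrom.get(gene.chrom)
        positions = np.arange(span[0], span[1])
        rate = np.full(len(positions), base_rate)
        if fp:
            fp_arr = np.fromiter(fp, dtype=np.int64)
            rate[np.isin(positions, fp_arr)] *= motif_suppression
        hit = rng.random(len(positions)) < rate
        for p in positions[hit]:
            add_site(gene.chrom, int(p), draw_maf())

    if ensure_motif_snp > 0:
        for gene_id in truth.motif_genes:
            if rng.random() >= ensure_motif_snp:
                continue
            pos = sorted(motif_footprint[gene_id])
            p = int(rng.choice(pos))
            add_site(firsts[gene_id][0], p, float(rng.uniform(0.35, 0.5)))

    order = sorted(range(len(sites)), key=lambda i: (sites[i][0], sites[i][1]))
    sites = [sites[i] for i in order]
    mafs = [mafs[i] for i in order]

    gt = np.zeros((len(sites), n_accessions), dtype=np.int8)
    for i, maf in enumerate(mafs):
        carriers = rng.random(n_accessions) < maf
        gt[i, carriers] = 2
        missing = rng.random(n_accessions) < missing_rate
        gt[i, missing] = -1

    # record per-gene variant accession sets (>=1 alt allele in the footprint)
    pos_index = {(c, p): i for i, (c, p, _, _) in enumerate(sites)}
    for gene_id in truth.motif_genes:
        chrom = firsts[gene_id][0]
        rows = [
            pos_index[(chrom, p)]
            for p in motif_footprint[gene_id]
            if (chrom, p) in pos_index
        ]
        if rows:
            carrier = (gt[rows] > 0).any(axis=0)
            truth.variant_accessions[gene_id] = [
                a for j, a in enumerate(accessions) if carrier[j]
            ]
        else:
            truth.variant_accessions[gene_id] = []
    return sites, gt, accessions


# ---------------------------------------------------------------------------
# expression


def _first_intron_g_content(
    genome: dict[str, np.ndarray], annotation: GenomeAnnotation, trim: int = 3
) -> dict[str, float]:
    out = {}
    for gene_id, (chrom, s, e, strand) in _first_intron_intervals(annotation).items():
        seq = "".join(genome[chrom][s:e])
        if strand == "-":
            seq = reverse_complement(seq)
        core = seq[trim : len(seq) - trim]
        out[gene_id] = core.count("G") / max(len(core), 1)
    return out


def generate_expression(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    genome: dict[str, np.ndarray] | None = None,
    n_conditions: int = 300,
    latent_loading: float = 0.6,
    level_shift: float = 0.4,
    allele_delta: float = 0.5,
    noise_sd: float = 1.0,
    baseline_mean: float = 3.0,
    baseline_sd: float = 1.0,
    g_content_coef: float = 0.5,
    low_expr_frac: float = 0.10,
    accessions: list[str] | None = None,
    seed=None,
):
    """Condition-wise and accession-wise (log-scale) expression matrices.

    Condition matrix: value = baseline_g + level_shift*[motif gene]
    + latent_loading*[motif gene]*f_c + N(0, noise_sd), with f_c a shared
    per-condition factor — motif genes are both up-shifted and
    co-expressed. Accession matrix: value = baseline_g + level_shift*[motif
    gene] - allele_delta*[accession mutated in the gene's motif] + noise,
    so the planted per-gene allele effect is d = delta/noise_sd. The gene
    baseline carries a moderate G-content term (emulating the empirically
    informative compositional signal) and a small fraction of genes are
    lowly expressed to exercise expression filters.
    """
    rng = np.random.default_rng(seed)
    truth.latent_loading = latent_loading
    truth.level_shift = level_shift
    truth.allele_delta = allele_delta
    truth.noise_sd = noise_sd
    gene_ids = [g.id for g in annotation.genes]
    n = len(gene_ids)
    motif = np.array([g in set(truth.motif_genes) for g in gene_ids])

    if genome is not None and g_content_coef != 0:
        gfrac = _first_intron_g_content(genome, annotation)
        gvals = np.array([gfrac.get(g, np.nan) for g in gene_ids])
        mu, sd = np.nanmean(gvals), np.nanstd(gvals)
        gz = np.where(np.isnan(gvals), 0.0, (gvals - mu) / (sd if sd else 1.0))
    else:
        gz = np.zeros(n)

    baseline = baseline_mean + g_content_coef * gz + baseline_sd * rng.normal(size=n)
    low_candidates = np.flatnonzero(~motif)
    n_low = int(round(low_expr_frac * n))
    low_idx = rng.choice(low_candidates, size=min(n_low, len(low_candidates)), replace=False)
    baseline[low_idx] = rng.normal(-1.0, 0.5, size=len(low_idx))
    truth.low_expressed_genes = [gene_ids[i] for i in sorted(low_idx)]

    f_c = rng.normal(size=n_conditions)
    cond = (
        baseline[:, None]
        + level_shift * motif[:, None]
        + latent_loading * np.outer(motif, f_c)
        + rng.normal(scale=noise_sd, size=(n, n_conditions))
    )
    import pandas as pd

    cond_df = pd.DataFrame(
        cond, index=gene_ids, columns=[f"cond{j + 1:04d}" for j in range(n_conditions)]
    )
    cond_df.attrs["provenance"] = "condition"

    acc_df = None
    if accessions is not None:
        variant = np.zeros((n, len(accessions)), dtype=bool)
        acc_index = {a: j for j, a in enumerate(accessions)}
        for i, g in enumerate(gene_ids):
            for a in truth.variant_accessions.get(g, ()):  # mutated motif
                variant[i, acc_index[a]] = True
        acc = (
            baseline[:, None]
            + level_shift * motif[:, None]
            - allele_delta * variant
            + rng.normal(scale=noise_sd, size=(n, len(accessions)))
        )
        acc_df = pd.DataFrame(acc, index=gene_ids, columns=accessions)
        acc_df.attrs["provenance"] = "accession"
    return cond_df, acc_df


# ---------------------------------------------------------------------------
# interval annotations + folding energies


def _random_intervals(genome, n, min_len, max_len, rng):
    chroms = sorted(genome)
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        ln = int(rng.integers(min_len, max_len))
        start = int(rng.integers(0, max(1, len(genome[chrom]) - ln)))
        out.append((chrom, start, start + ln))
    return sorted(out)


def generate_aux_annotations(genome, annotation, trim: int = 3, seed=None):
    """Random DMR/CNS/TE intervals and fabricated per-intron folding energies."""
    rng = np.random.default_rng(seed)
    aux = {
        "dmr_c": _random_intervals(genome, 150, 50, 300, rng),
        "dmr_cg": _random_intervals(genome, 150, 50, 300, rng),
        "cns": _random_intervals(genome, 200, 20, 150, rng),
        "te": _random_intervals(genome, 100, 80, 400, rng),
    }
    energies = {}
    for gene_id, (chrom, s, e, strand) in _first_intron_intervals(annotation).items():
        length = e - s
        energies[f"{gene_id}|1"] = float(-0.3 * (length + 40) * rng.uniform(0.85, 1.15))
    return aux, energies


# ---------------------------------------------------------------------------
# writers


def write_fasta(genome: dict[str, np.ndarray], path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = "".join(genome[chrom])
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_gff3(annotation: GenomeAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in annotation.genes:
            span_lo = min(t.span[0] for t in gene.transcripts)
            span_hi = max(t.span[1] for t in gene.transcripts)
            fh.write(
                f"{gene.chrom}\tsynth\tgene\t{span_lo + 1}\t{span_hi}\t.\t"
                f"{gene.strand}\t.\tID={gene.id}\n"
            )
            for tx in gene.transcripts:
                s, e = tx.span
                fh.write(
                    f"{gene.chrom}\tsynth\tmRNA\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
                    f"ID={tx.id};Parent={gene.id}\n"
                )
                for kind, ivs, phase in (
                    ("exon", tx.exons, "."),
                    ("five_prime_UTR", tx.utr5, "."),
                    ("CDS", tx.cds, "0"),
                ):
                    for s0, e0 in ivs:
                        fh.write(
                            f"{gene.chrom}\tsynth\t{kind}\t{s0 + 1}\t{e0}\t.\t"
                            f"{gene.strand}\t{phase}\tParent={tx.id}\n"
                        )


def write_vcf(sites, genotypes, accessions, genome, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(genome):
            fh.write(f"##contig=<ID={chrom},length={len(genome[chrom])}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(accessions)
            + "\n"
        )
        code = {0: "0/0", 2: "1/1", -1: "./."}
        for i, (chrom, pos, ref, alt) in enumerate(sites):
            gts = "\t".join(code[int(d)] for d in genotypes[i])
            fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def write_bed(intervals, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def write_fold_energy(energies: dict[str, float], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("intron_id\tenergy\n")
        for k in sorted(energies):
            fh.write(f"{k}\t{energies[k]:.3f}\n")


def read_fold_energy(path: str) -> dict[str, float]:
    out = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            k, v = line.split("\t")
            out[k] = float(v)
    return out


# ---------------------------------------------------------------------------
# one-call corpus


def simulate_corpus(
    out_dir: str,
    seed: int = 0,
    n_genes: int = 500,
    n_accessions: int = 200,
    motif: str = "TTTCGA",
    gene_fraction: float = 0.3,
    occurrences_per_intron: int = 2,
    position_beta: tuple[float, float] = (2.0, 5.0),
    base_rate: float = 0.016,
    motif_suppression: float = 0.2,
    ensure_motif_snp: float = 0.0,
    n_conditions: int = 300,
    latent_loading: float = 0.6,
    level_shift: float = 0.4,
    allele_delta: float = 0.5,
    noise_sd: float = 1.0,
    g_content_coef: float = 0.5,
    low_expr_frac: float = 0.10,
    **genome_kwargs,
) -> tuple[dict[str, Path], SyntheticTruth]:
    """Generate and write a complete corpus; returns (paths, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_genome, s_plant, s_var, s_expr, s_aux = ss.spawn(5)

    genome, annotation = generate_genome(n_genes=n_genes, seed=s_genome, **genome_kwargs)
    truth = plant_motifs(
        genome,
        annotation,
        motif=motif,
        gene_fraction=gene_fraction,
        occurrences_per_intron=occurrences_per_intron,
        position_beta=position_beta,
        seed=s_plant,
    )
    truth.seed = seed
    sites, gt, accessions = generate_variants(
        genome,
        annotation,
        truth,
        n_accessions=n_accessions,
        base_rate=base_rate,
        motif_suppression=motif_suppression,
        ensure_motif_snp=ensure_motif_snp,
        seed=s_var,
    )
    cond_df, acc_df = generate_expression(
        annotation,
        truth,
        genome=genome,
        n_conditions=n_conditions,
        latent_loading=latent_loading,
        level_shift=level_shift,
        allele_delta=allele_delta,
        noise_sd=noise_sd,
        g_content_coef=g_content_coef,
        low_expr_frac=low_expr_frac,
        accessions=accessions,
        seed=s_expr,
    )
    aux, energies = generate_aux_annotations(genome, annotation, seed=s_aux)

    paths = {
        "genome": out / "genome.fa",
        "gff": out / "annotation.gff3",
        "vcf": out / "variants.vcf",
        "expr_conditions": out / "expr_conditions.tsv",
        "expr_accessions": out / "expr_accessions.tsv",
        "dmr_c": out / "dmr_c.bed",
        "dmr_cg": out / "dmr_cg.bed",
        "cns": out / "cns.bed",
        "te": out / "te.bed",
        "fold_energy": out / "fold_energy.tsv",
        "truth": out / "truth.json",
    }
    write_fasta(genome, paths["genome"])
    write_gff3(annotation, paths["gff"])
    write_vcf(sites, gt, accessions, genome, paths["vcf"])
    cond_df.to_csv(paths["expr_conditions"], sep="\t", index_label="gene")
    acc_df.to_csv(paths["expr_accessions"], sep="\t", index_label="gene")
    write_bed(aux["dmr_c"], paths["dmr_c"])
    write_bed(aux["dmr_cg"], paths["dmr_cg"])
    write_bed(aux["cns"], paths["cns"])
    write_bed(aux["te"], paths["te"])
    write_fold_energy(energies, paths["fold_energy"])
    truth.to_json(paths["truth"])
    return paths, truth
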