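"""Gene-annotation parsing and intron extraction.

Introns are inferred as the gaps between consecutive exons of each mRNA.
All coordinates are handled internally as 0-based half-open intervals
(GFF3 input is converted from 1-based inclusive on read; BED output is
native 0-based half-open), so interval lengths are always ``end - start``.

"First intron" is a per-gene notion: among all transcripts of a gene, the
intron with transcript-oriented rank 1 whose 5' end lies closest to the
gene's TSS (ties broken by longest transcript, then lexicographic
transcript id). For minus-strand genes this is the genomically 3'-most
exon gap. Sequences are reported in transcript orientation (5'->3' of the
mRNA), which is the frame in which intron-mediated enhancement distances
and positional statistics are defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gffutils
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Transcript:
    id: str
    exons: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    transcripts: list[Transcript]

    def tss(self) -> int:
        """Gene-level TSS: outermost transcript start in transcript orientation."""
        starts = [t.span for t in self.transcripts]
        if self.strand == "+":
            return min(s for s, _ in starts)
        return max(e for _, e in starts)


@dataclass
class GenomeAnnotation:
    genes: list[Gene]

    def __post_init__(self) -> None:
        self._by_id = {g.id: g for g in self.genes}

    def gene(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]


@dataclass
class IntronRecord:
    """One intron of one gene, in transcript orientation.

    ``rank`` counts introns 5'->3' along the mRNA (1 = promoter-proximal);
    ``dist_tss``/``dist_cds`` measure from the transcript start / translation
    start to the intron's 5' end (``dist_cds`` negative for introns upstream
    of the start codon, i.e. 5'UTR introns).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    rank: int
    is_first: bool = False
    in_utr5: bool = False
    sequence: str = ""
    dist_tss: int = 0
    dist_cds: int = 0
    dup_index: int = 0  # disambiguates distinct intervals sharing (gene, rank)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def intron_id(self) -> str:
        base = f"{self.gene_id}|{self.rank}"
        return base if self.dup_index == 0 else f"{base}.{self.dup_index}"

    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end


def read_gff3(path: str) -> GenomeAnnotation:
    """Parse a GFF3 file (gene/mRNA/exon/five_prime_UTR/CDS) into GenomeAnnotation."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype="mRNA"):
            exons = [(f.start - 1, f.end) for f in db.children(t, featuretype="exon")]
            utr5 = [
                (f.start - 1, f.end)
                for f in db.children(t, featuretype="five_prime_UTR")
            ]
            cds = [(f.start - 1, f.end) for f in db.children(t, featuretype="CDS")]
            if not exons:
                continue
            transcripts.append(
                Transcript(t.id, sorted(exons), sorted(utr5), sorted(cds))
            )
        if transcripts:
            genes.append(Gene(g.id, g.seqid, g.strand, transcripts))
    return GenomeAnnotation(genes)


def _transcript_introns(gene: Gene, tx: Transcript) -> list[IntronRecord] | None:
    exons = sorted(tx.exons)
    for (s1, e1), (s2, _) in zip(exons, exons[1:]):
        if s2 < e1:
            return None  # overlapping exons: malformed transcript
    gaps = [(e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:])]
    n = len(gaps)
    if gene.strand == "+":
        tx_start = exons[0][0]
        cds_start = min((s for s, _ in tx.cds), default=None)
    else:
        tx_start = exons[-1][1]
        cds_start = max((e for _, e in tx.cds), default=None)
    records = []
    for i, (s, e) in enumerate(gaps):
        rank = i + 1 if gene.strand == "+" else n - i
        if gene.strand == "+":
            dist_tss = s - tx_start
            dist_cds = s - cds_start if cds_start is not None else 0
        else:
            dist_tss = tx_start - e
            dist_cds = cds_start - e if cds_start is not None else 0
        records.append(
            IntronRecord(
                gene_id=gene.id,
                transcript_id=tx.id,
                chrom=gene.chrom,
                start=s,
                end=e,
                strand=gene.strand,
                rank=rank,
                dist_tss=dist_tss,
                dist_cds=dist_cds,
            )
        )
    return records


def extract_introns(
    annotation: GenomeAnnotation, min_length: int = 10
) -> list[IntronRecord]:
    """Infer introns from exon gaps; drop introns shorter than ``min_length``.

    Duplicate intervals contributed by several transcripts of one gene are
    collapsed to a single record carrying the minimum transcript-oriented
    rank. Per gene, the rank-1 intron closest to the gene TSS is flagged
    ``is_first`` (at most one per gene).
    """
    out: list[IntronRecord] = []
    for gene in annotation.genes:
        seen: dict[tuple[int, int], IntronRecord] = {}
        for tx in gene.transcripts:
            recs = _transcript_introns(gene, tx)
            if recs is None:
                logger.warning(
                    "transcript %s of gene %s has overlapping exons; rejected",
                    tx.id,
                    gene.id,
                )
                continue
            for rec in recs:
                if rec.length < min_length:
                    continue
                key = (rec.start, rec.end)
                prev = seen.get(key)
                if prev is None or rec.rank < prev.rank:
                    seen[key] = rec
        gene_recs = sorted(seen.values(), key=lambda r: (r.start, r.end))
        firsts = [r for r in gene_recs if r.rank == 1]
        if firsts:
            tss = gene.tss()
            tx_len = {
                t.id: t.span[1] - t.span[0] for t in gene.transcripts
            }

            def _first_key(r: IntronRecord) -> tuple:
                return (
                    abs(r.five_prime() - tss),
                    -tx_len.get(r.transcript_id, 0),
                    r.transcript_id,
                )

            chosen = min(firsts, key=_first_key)
            chosen.is_first = True
        by_rank: dict[int, list[IntronRecord]] = {}
        for r in gene_recs:
            by_rank.setdefault(r.rank, []).append(r)
        for recs in by_rank.values():
            if len(recs) > 1:
                recs.sort(key=lambda r: (not r.is_first, r.start))
                for i, r in enumerate(recs):
                    r.dup_index = i
        out.extend(gene_recs)
    return out


def flag_utr5_introns(
    introns: list[IntronRecord],
    annotation: GenomeAnnotation,
    extension: int = 5,
) -> list[IntronRecord]:
    """Set ``in_utr5`` where the length-extended intron overlaps a 5'UTR.

    The intron interval is extended by ``extension`` bp on both ends and
    tested for >=1 bp overlap against every annotated 5'UTR interval of its
    own gene (any transcript). Genes without annotated 5'UTRs yield False.
    """
    utr_by_gene: dict[str, list[tuple[int, int]]] = {}
    for gene in annotation.genes:
        ivs = [iv for t in gene.transcripts for iv in t.utr5]
        if ivs:
            utr_by_gene[gene.id] = ivs
    out = []
    for rec in introns:
        s, e = rec.start - extension, rec.end + extension
        hit = any(
            s < ue and us < e for us, ue in utr_by_gene.get(rec.gene_id, ())
        )
        out.append(replace(rec, in_utr5=hit))
    return out


def fetch_sequences(introns: list[IntronRecord], genome) -> list[IntronRecord]:
    """Fill intron sequences from a FASTA (path or pyfaidx.Fasta).

    Minus-strand records are reverse-complemented so sequences read 5'->3'
    along the mRNA; output is uppercased.
    """
    fa = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    out = []
    for rec in introns:
        if rec.chrom not in fa:
            raise KeyError(f"chromosome {rec.chrom!r} absent for {rec.intron_id}")
        chrom_len = len(fa[rec.chrom])
        if rec.start < 0 or rec.end > chrom_len:
            raise ValueError(
                f"intron {rec.intron_id} interval [{rec.start},{rec.end}) "
                f"outside {rec.chrom} (length {chrom_len})"
            )
        seq = str(fa[rec.chrom][rec.start : rec.end]).upper()
        if rec.strand == "-":
            seq = reverse_complement(seq)
        out.append(replace(rec, sequence=seq))
    return out


def split_first_other(
    introns: list[IntronRecord],
) -> tuple[list[IntronRecord], list[IntronRecord]]:
    first = [r for r in introns if r.is_first]
    other = [r for r in introns if not r.is_first]
    return first, other


def write_intron_bed(introns: list[IntronRecord], path: str) -> None:
    """BED6: name=gene_id|rank, score=length."""
    with open(path, "w") as fh:
        for r in sorted(introns, key=lambda r: (r.chrom, r.start, r.end)):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.intron_id}\t{r.length}\t{r.strand}\n"
            )


def read_intron_bed(path: str) -> list[IntronRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")
            gene_id, rank = name.rsplit("|", 1)
            dup = 0
            if "." in rank:
                rank, dup_s = rank.split(".", 1)
                dup = int(dup_s)
            out.append(
                IntronRecord(
                    gene_id=gene_id,
                    transcript_id="",
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    rank=int(rank),
                    is_first=int(rank) == 1 and dup == 0,
                    dup_index=dup,
                )
            )
    return out


def write_intron_fasta(introns: list[IntronRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in introns:
            fh.write(f">{r.intron_id} {r.chrom}:{r.start}-{r.end}({r.strand})\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")
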