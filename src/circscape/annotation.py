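"""Gene annotation container: genes, transcripts, exons and derived features.

Coordinates follow the GTF convention throughout: 1-based, inclusive on both
ends, stranded. Introns are the gaps between consecutive exons of a
transcript; linear junctions are the ordered exon pairs those gaps connect.
Both are deduplicated by exact genomic coordinates across transcripts, which
matches the "unique annotated junction" notion used downstream.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterator

import gffutils


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    gene_id: str
    transcript_id: str
    number: int  # 1-based rank in transcript, 5'->3'

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"exon end < start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Intron:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Exon] = field(default_factory=list)
    # genomic CDS interval; None for noncoding transcripts
    cds: tuple[int, int] | None = None

    def exons_5to3(self) -> list[Exon]:
        """Exons in transcript (5'->3') order."""
        rev = self.strand == "-"
        return sorted(self.exons, key=lambda e: e.start, reverse=rev)

    def introns(self) -> list[Intron]:
        ex = sorted(self.exons, key=lambda e: e.start)
        out = []
        for a, b in zip(ex, ex[1:]):
            if b.start > a.end + 1:
                out.append(
                    Intron(self.chrom, a.end + 1, b.start - 1, self.strand, self.gene_id)
                )
        return out

    def junctions(self) -> list[tuple[Exon, Exon]]:
        """Consecutive exon pairs in genomic order (left, right)."""
        ex = sorted(self.exons, key=lambda e: e.start)
        return list(zip(ex, ex[1:]))


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def exons(self) -> list[Exon]:
        """All exons of all transcripts, deduplicated by coordinates."""
        seen: dict[tuple[int, int], Exon] = {}
        for tx in self.transcripts.values():
            for e in tx.exons:
                seen.setdefault((e.start, e.end), e)
        return sorted(seen.values(), key=lambda e: e.start)

    def introns(self) -> list[Intron]:
        seen: dict[tuple[int, int], Intron] = {}
        for tx in self.transcripts.values():
            for i in tx.introns():
                seen.setdefault((i.start, i.end), i)
        return sorted(seen.values(), key=lambda i: i.start)

    def junctions(self) -> list[tuple[Exon, Exon]]:
        seen: dict[tuple[int, int, int, int], tuple[Exon, Exon]] = {}
        for tx in self.transcripts.values():
            for a, b in tx.junctions():
                seen.setdefault((a.start, a.end, b.start, b.end), (a, b))
        return sorted(seen.values(), key=lambda p: (p[0].start, p[1].start))


class GenomeAnnotation:
    """Indexed gene annotation with per-chromosome exon-boundary lookups."""

    def __init__(self, genes: dict[str, Gene]):
        self.genes = genes
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in genes.values():
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for gl in self._by_chrom.values():
            gl.sort(key=lambda g: g.start)

    def __len__(self) -> int:
        return len(self.genes)

    def genes_on(self, chrom: str) -> list[Gene]:
        return self._by_chrom.get(chrom, [])

    def iter_genes(self) -> Iterator[Gene]:
        yield from self.genes.values()

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_gtf(cls, path: str | os.PathLike) -> "GenomeAnnotation":
        db = gffutils.create_db(
            str(path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
        genes: dict[str, Gene] = {}
        for gf in db.features_of_type("gene"):
            gid = gf.attributes["gene_id"][0]
            genes[gid] = Gene(gid, gf.seqid, gf.strand, gf.start, gf.end)
        for tf in db.features_of_type("transcript"):
            gid = tf.attributes["gene_id"][0]
            tid = tf.attributes["transcript_id"][0]
            if gid not in genes:  # gene feature absent: synthesize
                genes[gid] = Gene(gid, tf.seqid, tf.strand, tf.start, tf.end)
            genes[gid].transcripts[tid] = Transcript(tid, gid, tf.seqid, tf.strand)
        for ef in db.features_of_type("exon"):
            gid = ef.attributes["gene_id"][0]
            tid = ef.attributes["transcript_id"][0]
            tx = genes[gid].transcripts[tid]
            tx.exons.append(
                Exon(ef.seqid, ef.start, ef.end, ef.strand, gid, tid, len(tx.exons) + 1)
            )
        for cf in db.features_of_type("CDS"):
            gid = cf.attributes["gene_id"][0]
            tid = cf.attributes["transcript_id"][0]
            tx = genes[gid].transcripts[tid]
            if tx.cds is None:
                tx.cds = (cf.start, cf.end)
            else:
                tx.cds = (min(tx.cds[0], cf.start), max(tx.cds[1], cf.end))
        # renumber exons 5'->3'
        for g in genes.values():
            for tx in g.transcripts.values():
                ordered = tx.exons_5to3()
                tx.exons = [
                    Exon(e.chrom, e.start, e.end, e.strand, e.gene_id, e.transcript_id, i + 1)
                    for i, e in enumerate(ordered)
                ]
        return cls(genes)

    def to_gtf(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for g in sorted(self.genes.values(), key=lambda g: (g.chrom, g.start)):
                attrs = f'gene_id "{g.gene_id}";'
                fh.write(
                    f"{g.chrom}\tcircscape\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                for tid in sorted(g.transcripts):
                    tx = g.transcripts[tid]
                    ta = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
                    tstart = min(e.start for e in tx.exons)
                    tend = max(e.end for e in tx.exons)
                    fh.write(
                        f"{g.chrom}\tcircscape\ttranscript\t{tstart}\t{tend}\t.\t{g.strand}\t.\t{ta}\n"
                    )
                    for e in sorted(tx.exons, key=lambda e: e.start):
                        ea = ta + f' exon_number "{e.number}";'
                        fh.write(
                            f"{g.chrom}\tcircscape\texon\t{e.start}\t{e.end}\t.\t{g.strand}\t.\t{ea}\n"
                        )
                    if tx.cds is not None:
                        fh.write(
                            f"{g.chrom}\tcircscape\tCDS\t{tx.cds[0]}\t{tx.cds[1]}\t.\t{g.strand}\t0\t{ta}\n"
                        )

    # --------------------------------------------------------------- queries

    def classify_exon_region(self, gene_id: str, exon: Exon) -> str:
        """Region class of an exon: CDS, 3UTR, 5UTR or noncoding.

        Uses the first transcript (in id order) of the gene that contains the
        exon; a transcript without CDS is noncoding.
        """
        gene = self.genes[gene_id]
        for tid in sorted(gene.transcripts):
            tx = gene.transcripts[tid]
            if any(e.start == exon.start and e.end == exon.end for e in tx.exons):
                if tx.cds is None:
                    return "noncoding"
                cs, ce = tx.cds
                if exon.start <= ce and exon.end >= cs:
                    return "CDS"
                # downstream of CDS in transcript orientation is 3'UTR
                if (gene.strand == "+" and exon.start > ce) or (
                    gene.strand == "-" and exon.end < cs
                ):
                    return "3UTR"
                return "5UTR"
        return "noncoding"


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract(genome: dict[str, str], chrom: str, start: int, end: int, strand: str) -> str:
    """Strand-oriented genomic substring, 1-based inclusive coordinates."""
    if chrom not in genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    seq = genome[chrom]
    if start < 1 or end > len(seq):
        raise ValueError(
            f"coordinates {chrom}:{start}-{end} outside chromosome of length {len(seq)}"
        )
    sub = seq[start - 1 : end]
    return revcomp(sub) if strand == "-" else sub
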