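"""Construction of the confident back-splice catalog.

Candidates come from per-sample CIRI2-style prediction tables. A candidate
enters the confident set when it (a) lies on a primary chromosome, (b) can be
matched to acceptor and donor exons of a single annotated gene with at most
1 bp boundary discrepancy per end, and (c) clears the cohort expression
filter: detected in at least a quarter of samples, or supported by >= 20
back-splice reads in at least three samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .annotation import Exon, GenomeAnnotation

#: default primary-chromosome set (human-style); chrM/chrY are never primary
DEFAULT_PRIMARY_CHROMS = frozenset({f"chr{i}" for i in range(1, 23)} | {"chrX"})

CIRI2_COLUMNS = {
    "circRNA_ID": "circRNA_ID",
    "chr": "chr",
    "circRNA_start": "circRNA_start",
    "circRNA_end": "circRNA_end",
    "junction_reads": "junction_reads",
    "#junction_reads": "junction_reads",
    "strand": "strand",
    "circRNA_type": "circRNA_type",
}
_MANDATORY = [
    "circRNA_ID",
    "chr",
    "circRNA_start",
    "circRNA_end",
    "junction_reads",
    "strand",
    "circRNA_type",
]


@dataclass
class CircCandidate:
    chrom: str
    start: int  # 1-based
    end: int  # 1-based, >= start
    strand: str  # + - or .
    circ_type: str  # exon / intron / intergenic
    per_sample_bsj_reads: dict[str, int] = field(default_factory=dict)
    source_gene: str | None = None

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"


@dataclass
class ConfidentCircRNA:
    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    acceptor_exon: Exon
    donor_exon: Exon
    boundary_discrepancy: tuple[int, int]  # (start end-offsets, candidate minus exon)
    isoform_index: int = 0
    per_sample_bsj_reads: dict[str, int] = field(default_factory=dict)


@dataclass
class Rejection:
    candidate: CircCandidate
    reason: str  # no-gene / cross-gene / boundary


def read_ciri2(path, sample_id: str | None = None):
    """Parse a CIRI2-style TSV into candidates.

    Returns (candidates, errors) where errors is a list of
    "line N: reason" strings for malformed rows. Raises ValueError if a
    mandatory column is missing from the header.
    """
    import os

    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(str(path)))[0]
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        header = [CIRI2_COLUMNS.get(c.strip(), c.strip()) for c in header_line.split("\t")]
        for col in _MANDATORY:
            if col not in header:
                raise ValueError(f"CIRI2 table missing mandatory column {col!r}")
        idx = {c: header.index(c) for c in _MANDATORY}
        candidates: list[CircCandidate] = []
        errors: list[str] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                chrom = fields[idx["chr"]].strip()
                start = int(fields[idx["circRNA_start"]])
                end = int(fields[idx["circRNA_end"]])
                reads = int(fields[idx["junction_reads"]])
                strand = fields[idx["strand"]].strip()
                circ_type = fields[idx["circRNA_type"]].strip()
            except (IndexError, ValueError) as exc:
                errors.append(f"line {lineno}: unparseable row ({exc})")
                continue
            if end < start:
                errors.append(f"line {lineno}: end < start ({chrom}:{start}-{end})")
                continue
            if reads < 0:
                errors.append(f"line {lineno}: negative junction_reads")
                continue
            if strand not in {"+", "-", "."}:
                errors.append(f"line {lineno}: invalid strand {strand!r}")
                continue
            candidates.append(
                CircCandidate(chrom, start, end, strand, circ_type, {sample_id: reads})
            )
    return candidates, errors


def merge_candidates(per_sample: list[list[CircCandidate]]) -> list[CircCandidate]:
    """Merge per-sample candidate lists on (chrom, start, end, strand)."""
    merged: dict[tuple, CircCandidate] = {}
    for cands in per_sample:
        for c in cands:
            if c.key in merged:
                for s, n in c.per_sample_bsj_reads.items():
                    merged[c.key].per_sample_bsj_reads[s] = (
                        merged[c.key].per_sample_bsj_reads.get(s, 0) + n
                    )
            else:
                merged[c.key] = CircCandidate(
                    c.chrom, c.start, c.end, c.strand, c.circ_type,
                    dict(c.per_sample_bsj_reads), c.source_gene,
                )
    return sorted(merged.values(), key=lambda c: c.key)


def filter_blacklist(candidates, primary_chromosomes=None) -> list[CircCandidate]:
    """Drop candidates on chrM, chrY and non-primary contigs."""
    primary = (
        DEFAULT_PRIMARY_CHROMS if primary_chromosomes is None else set(primary_chromosomes)
    )
    primary = primary - {"chrM", "chrY"}
    return [c for c in candidates if c.chrom in primary]


def annotate_candidate(
    candidate: CircCandidate, annotation: GenomeAnnotation, tol: int = 1
):
    """Match a candidate's boundaries to exons of one gene.

    Returns a ConfidentCircRNA on success, else a Rejection with reason
    no-gene / cross-gene / boundary. Unstranded candidates are matched on
    both strands; ties break on smaller total boundary discrepancy, then
    lexicographic gene id.
    """
    strands = ["+", "-"] if candidate.strand == "." else [candidate.strand]
    matches = []
    left_hit_genes: set[str] = set()
    right_hit_genes: set[str] = set()
    any_gene = False
    for gene in annotation.genes_on(candidate.chrom):
        if gene.strand not in strands:
            continue
        if gene.end < candidate.start - tol or gene.start > candidate.end + tol:
            continue
        any_gene = True
        exons = gene.exons()
        left = [e for e in exons if abs(e.start - candidate.start) <= tol]
        right = [e for e in exons if abs(e.end - candidate.end) <= tol]
        if left:
            left_hit_genes.add(gene.gene_id)
        if right:
            right_hit_genes.add(gene.gene_id)
        if left and right:
            le = min(left, key=lambda e: (abs(e.start - candidate.start), e.start))
            re_ = min(right, key=lambda e: (abs(e.end - candidate.end), e.start))
            d = (candidate.start - le.start, candidate.end - re_.end)
            # acceptor = 5'-most exon of the circle; donor = 3'-most
            if gene.strand == "+":
                acceptor, donor = le, re_
            else:
                acceptor, donor = re_, le
            matches.append((abs(d[0]) + abs(d[1]), gene.gene_id, acceptor, donor, d, gene))
    if matches:
        matches.sort(key=lambda m: (m[0], m[1]))
        _, gene_id, acceptor, donor, d, gene = matches[0]
        return ConfidentCircRNA(
            circ_id=candidate.circ_id,
            chrom=candidate.chrom,
            start=candidate.start,
            end=candidate.end,
            strand=gene.strand,
            gene_id=gene_id,
            acceptor_exon=acceptor,
            donor_exon=donor,
            boundary_discrepancy=d,
            per_sample_bsj_reads=dict(candidate.per_sample_bsj_reads),
        )
    if not any_gene:
        return Rejection(candidate, "no-gene")
    if left_hit_genes and right_hit_genes and not (left_hit_genes & right_hit_genes):
        return Rejection(candidate, "cross-gene")
    return Rejection(candidate, "boundary")


def filter_expression(
    candidates,
    n_samples: int,
    min_fraction: float = 0.25,
    min_reads: int = 20,
    min_support_samples: int = 3,
):
    """Cohort expression filter.

    Keep a candidate iff it is expressed (>= 1 read) in at least
    ceil(min_fraction * n_samples) samples OR has >= min_reads reads in at
    least min_support_samples samples.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    need_expressed = math.ceil(min_fraction * n_samples)
    kept = []
    for c in candidates:
        counts = list(c.per_sample_bsj_reads.values())
        n_expressed = sum(1 for v in counts if v >= 1)
        n_supported = sum(1 for v in counts if v >= min_reads)
        if n_expressed >= need_expressed or n_supported >= min_support_samples:
            kept.append(c)
    return kept


def assign_isoform_indices(circs: list[ConfidentCircRNA]) -> list[ConfidentCircRNA]:
    """Number circRNA isoforms within each gene by genomic position."""
    by_gene: dict[str, list[ConfidentCircRNA]] = {}
    for c in circs:
        by_gene.setdefault(c.gene_id, []).append(c)
    for gl in by_gene.values():
        gl.sort(key=lambda c: (c.start, c.end))
        for i, c in enumerate(gl, start=1):
            c.isoform_index = i
    return circs


def catalog_stats(circs: list[ConfidentCircRNA], annotation: GenomeAnnotation):
    """Summary tables of a confident set.

    Returns a dict with 'isoforms_per_gene' (gene_id, n_isoforms),
    'exons_per_circ' (circ_id, n_exons: annotated exons between acceptor and
    donor inclusive) and 'acceptor_region' (circ_id, region class).
    """
    iso = (
        pd.Series([c.gene_id for c in circs], dtype=object)
        .value_counts()
        .rename_axis("gene_id")
        .rename("n_isoforms")
        .reset_index()
        .sort_values("gene_id")
        .reset_index(drop=True)
        if circs
        else pd.DataFrame(columns=["gene_id", "n_isoforms"])
    )
    exon_rows = []
    region_rows = []
    for c in circs:
        gene = annotation.genes[c.gene_id]
        n_ex = sum(
            1
            for e in gene.exons()
            if e.start >= c.start - 1 and e.end <= c.end + 1
        )
        exon_rows.append({"circ_id": c.circ_id, "n_exons": n_ex})
        region_rows.append(
            {
                "circ_id": c.circ_id,
                "region": annotation.classify_exon_region(c.gene_id, c.acceptor_exon),
            }
        )
    return {
        "isoforms_per_gene": iso,
        "exons_per_circ": pd.DataFrame(exon_rows, columns=["circ_id", "n_exons"]),
        "acceptor_region": pd.DataFrame(region_rows, columns=["circ_id", "region"]),
    }
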