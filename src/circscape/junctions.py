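"""Junction pseudo-reference construction and junction-spanning read counting.

Each confident circRNA contributes one back-splice contig: the last `flank`
nucleotides of the donor exon spliced to the first `flank` of the acceptor
exon (strand-oriented), so back-splice contigs are exactly 2*flank long with
the breakpoint in the middle. Every unique annotated linear exon-exon
junction of the host gene contributes a linear contig at full exon lengths.
A fragment counts toward a contig when at least one mate's primary
alignment covers the breakpoint window with sufficient mapping quality and
the pair is in first-mate-reverse / second-mate-forward orientation.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import pandas as pd
import pysam

from .annotation import GenomeAnnotation, extract
from .catalog import ConfidentCircRNA

BSJ_CONTIG_LEN_FLANK = 80  # default per-side flank; bsj contigs are 2x this


@dataclass
class Contig:
    name: str
    sequence: str
    junction_offset: int  # 1-based position of the last base before the breakpoint
    kind: str  # 'bsj' or 'linear'
    gene_id: str
    circ_id: str | None = None
    # genomic intervals of the two joined exons (linear contigs only)
    exon_pair: tuple[tuple[int, int], tuple[int, int]] | None = None


@dataclass
class JunctionReference:
    contigs: dict[str, Contig] = field(default_factory=dict)
    linear_by_gene: dict[str, list[str]] = field(default_factory=dict)
    #: circ_id -> linear contig names external to the back-splice span
    external: dict[str, set[str]] = field(default_factory=dict)
    #: circ_id -> gene_id for retained circRNAs
    circ_gene: dict[str, str] = field(default_factory=dict)
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (circ_id, reason)

    def bsj_contigs(self) -> list[Contig]:
        return [c for c in self.contigs.values() if c.kind == "bsj"]

    def to_files(self, fasta_path, sidecar_path) -> None:
        from .annotation import write_fasta

        write_fasta({c.name: c.sequence for c in self.contigs.values()}, fasta_path)
        rows = []
        for c in self.contigs.values():
            ext_for = (
                ";".join(
                    sorted(ci for ci, names in self.external.items() if c.name in names)
                )
                if c.kind == "linear"
                else ""
            )
            rows.append(
                {
                    "name": c.name,
                    "kind": c.kind,
                    "gene_id": c.gene_id,
                    "circ_id": c.circ_id or "",
                    "junction_offset": c.junction_offset,
                    "length": len(c.sequence),
                    "external_for": ext_for,
                }
            )
        pd.DataFrame(rows).to_csv(sidecar_path, sep="\t", index=False)


def build_junction_reference(
    circs: list[ConfidentCircRNA],
    annotation: GenomeAnnotation,
    genome: dict[str, str],
    flank: int = BSJ_CONTIG_LEN_FLANK,
) -> JunctionReference:
    """Build back-splice and linear junction contigs for a confident set.

    circRNAs whose donor or acceptor exon is shorter than `flank` are dropped
    (untrimmable), as are all circRNAs of genes without any linear junction.
    """
    ref = JunctionReference()
    genes = sorted({c.gene_id for c in circs})
    for gene_id in genes:
        gene = annotation.genes[gene_id]
        names = []
        for a, b in gene.junctions():  # genomic order (left, right)
            if gene.strand == "+":
                upstream, downstream = a, b  # transcript 5' exon first
            else:
                upstream, downstream = b, a
            u_seq = extract(genome, gene.chrom, upstream.start, upstream.end, gene.strand)
            d_seq = extract(genome, gene.chrom, downstream.start, downstream.end, gene.strand)
            name = f"{gene_id}|lin|{a.start}-{a.end}|{b.start}-{b.end}"
            if name in ref.contigs:
                continue
            ref.contigs[name] = Contig(
                name=name,
                sequence=u_seq + d_seq,
                junction_offset=len(u_seq),
                kind="linear",
                gene_id=gene_id,
                exon_pair=((a.start, a.end), (b.start, b.end)),
            )
            names.append(name)
        ref.linear_by_gene[gene_id] = names

    for circ in circs:
        gene_id = circ.gene_id
        if not ref.linear_by_gene.get(gene_id):
            ref.dropped.append((circ.circ_id, "no-linear-junction"))
            continue
        donor, acceptor = circ.donor_exon, circ.acceptor_exon
        if donor.length < flank or acceptor.length < flank:
            ref.dropped.append((circ.circ_id, "untrimmable"))
            continue
        d_seq = extract(genome, circ.chrom, donor.start, donor.end, circ.strand)
        a_seq = extract(genome, circ.chrom, acceptor.start, acceptor.end, circ.strand)
        name = f"{circ.circ_id}|bsj"
        ref.contigs[name] = Contig(
            name=name,
            sequence=d_seq[-flank:] + a_seq[:flank],
            junction_offset=flank,
            kind="bsj",
            gene_id=gene_id,
            circ_id=circ.circ_id,
        )
        ref.circ_gene[circ.circ_id] = gene_id
        span = (circ.start - 1, circ.end + 1)  # 1 bp tolerance for boundary drift
        ext = set()
        for lname in ref.linear_by_gene[gene_id]:
            (a_iv, b_iv) = ref.contigs[lname].exon_pair
            a_in = a_iv[0] >= span[0] and a_iv[1] <= span[1]
            b_in = b_iv[0] >= span[0] and b_iv[1] <= span[1]
            if not a_in and not b_in:
                ext.add(lname)
        ref.external[circ.circ_id] = ext
    return ref


def _orientation_ok(read: pysam.AlignedSegment) -> bool:
    """First mate reverse / second mate forward."""
    if not read.is_paired:
        return False
    if read.is_read1:
        return read.is_reverse and not read.mate_is_reverse
    return (not read.is_reverse) and read.mate_is_reverse


def count_junction_reads(
    sam_path,
    ref: JunctionReference,
    min_mapq: int = 13,
    min_overhang: int = 5,
) -> dict[str, int]:
    """Count junction-spanning fragments per contig from one SAM file.

    A fragment counts once for a contig when at least one mate's primary
    alignment covers [junction_offset - min_overhang + 1,
    junction_offset + min_overhang] (1-based), MAPQ >= min_mapq, and pair
    orientation is first-mate-reverse / second-mate-forward.
    """
    counts = {name: 0 for name in ref.contigs}
    seen: set[tuple[str, str]] = set()
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            name = read.reference_name
            if name not in ref.contigs:
                print(f"warning: alignment to unknown contig {name!r} skipped", file=sys.stderr)
                continue
            if read.mapping_quality < min_mapq or not _orientation_ok(read):
                continue
            offset = ref.contigs[name].junction_offset
            win_start, win_end = offset - min_overhang + 1, offset + min_overhang
            # reference_start is 0-based; covered 1-based interval:
            cov_start = read.reference_start + 1
            cov_end = read.reference_end  # 1-based inclusive end
            if cov_start <= win_start and cov_end >= win_end:
                key = (read.query_name, name)
                if key not in seen:
                    seen.add(key)
                    counts[name] += 1
    return counts


def count_samples(
    sam_paths: dict[str, str],
    ref: JunctionReference,
    min_mapq: int = 13,
    min_overhang: int = 5,
) -> pd.DataFrame:
    """Counts for several samples as a contigs x samples DataFrame."""
    data = {
        sample: count_junction_reads(path, ref, min_mapq, min_overhang)
        for sample, path in sam_paths.items()
    }
    return pd.DataFrame(data, dtype=int).reindex(list(ref.contigs))


def matrices_to_contig_counts(
    ref: JunctionReference, bsj_counts: pd.DataFrame, linear_counts: pd.DataFrame
) -> pd.DataFrame:
    """Assemble a contigs x samples count frame from circ-/junction-keyed
    matrices (circ rows are mapped to their bsj contig names)."""
    bsj = bsj_counts.rename(index=lambda c: f"{c}|bsj")
    combined = pd.concat([bsj, linear_counts])
    return combined.reindex(list(ref.contigs)).fillna(0).astype(int)


def summarize_bsj_linear(counts: pd.DataFrame, ref: JunctionReference) -> pd.DataFrame:
    """Per-circRNA per-sample back-splice and linear junction summaries.

    Columns: circ_id, gene_id, sample, bsj, linear_all_mean,
    linear_external_mean (NaN when the circ has no external linear junction).
    """
    rows = []
    for circ_id, gene_id in ref.circ_gene.items():
        bsj_name = f"{circ_id}|bsj"
        lin_names = ref.linear_by_gene[gene_id]
        ext_names = sorted(ref.external.get(circ_id, set()))
        for sample in counts.columns:
            lin_vals = counts.loc[lin_names, sample]
            ext_mean = (
                float(counts.loc[ext_names, sample].mean()) if ext_names else float("nan")
            )
            rows.append(
                {
                    "circ_id": circ_id,
                    "gene_id": gene_id,
                    "sample": sample,
                    "bsj": int(counts.loc[bsj_name, sample]),
                    "linear_all_mean": float(lin_vals.mean()),
                    "linear_external_mean": ext_mean,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["circ_id", "gene_id", "sample", "bsj", "linear_all_mean", "linear_external_mean"],
    )
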