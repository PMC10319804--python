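"""Self-contained synthetic cohort generator.

Generates a small genome with multi-exon genes, a truth set of back-spliced
circRNAs, an Alu-like repeat track biased toward circRNA-flanking introns,
negative-binomial cohort count matrices with a group-wise circRNA
suppression effect, and pre-aligned junction reads. Everything is a
deterministic function of the SimSpec (including its seed), so downstream
stages are testable without any external data.

The generator emulates the structure of a tumor cohort profiled for
circRNAs: genes hosting circRNAs carry long, repeat-seeded flanking
introns; back-splice counts in one designated sample group are multiplied
by a suppression factor before sampling; a minority of "specific" circRNAs
is elevated in the focal cohort relative to simulated control cohorts.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Exon, Gene, GenomeAnnotation, Intron, Transcript, revcomp
from .catalog import ConfidentCircRNA
from .junctions import JunctionReference

GENES_PER_CHROM = 50
INTERGENIC_GAP = 500
ALU_LENGTH = 300

# fixed Alu-like 300-mer; only interval overlap matters downstream
_alu_rng = np.random.default_rng(271828)
ALU_LIKE = "".join(_alu_rng.choice(list("ACGT"), size=ALU_LENGTH))


@dataclass
class SimSpec:
    n_genes: int = 100
    exons_per_gene_range: tuple[int, int] = (6, 9)
    exon_len_range: tuple[int, int] = (100, 250)
    intron_len_range: tuple[int, int] = (400, 1200)
    alu_seed_fraction: float = 0.3
    n_samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"HR_nMNA": 20, "MNA": 20}
    )
    circ_fraction: float = 0.4
    suppression_factor: float = 0.5
    suppressed_group: str = "MNA"
    nb_dispersion: float = 0.2
    mean_gene_count: float = 200.0
    n_specific: int = 10
    specific_fold: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for name in ("exons_per_gene_range", "exon_len_range", "intron_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ValueError(f"invalid range {name}={lo, hi}")
        if not 0.0 <= self.alu_seed_fraction <= 1.0:
            raise ValueError("alu_seed_fraction must be in [0, 1]")
        if not 0.0 <= self.circ_fraction <= 1.0:
            raise ValueError("circ_fraction must be in [0, 1]")
        if self.suppression_factor <= 0:
            raise ValueError("suppression_factor must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.mean_gene_count <= 0:
            raise ValueError("mean_gene_count must be > 0")
        if not self.n_samples_per_group:
            raise ValueError("need at least one sample group")
        if any(n <= 0 for n in self.n_samples_per_group.values()):
            raise ValueError("all group sizes must be positive")
        if self.suppressed_group not in self.n_samples_per_group:
            raise ValueError(
                f"suppressed group {self.suppressed_group!r} not among groups "
                f"{sorted(self.n_samples_per_group)}"
            )


@dataclass(frozen=True)
class TruthCirc:
    circ_id: str
    gene_id: str
    acceptor_index: int  # 1-based exon rank in transcript order
    donor_index: int  # >= acceptor_index
    baseline_mean: float


@dataclass
class TruthSet:
    circ_records: list[TruthCirc]
    specific_ids: list[str]
    suppressed_group: str


@dataclass
class SyntheticGenome:
    genome: dict[str, str]
    annotation: GenomeAnnotation
    repeats: list[tuple[str, int, int, str, int, str]]  # BED6, 0-based half-open
    truth: TruthSet


def _rng(spec: SimSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed % (2**31), stream])


def generate_annotation(spec: SimSpec) -> SyntheticGenome:
    """Generate genome FASTA sequences, gene annotation, repeat track and truth.

    Genes are laid out non-overlapping, ~50 per chromosome, strand
    alternating. circRNA host genes get uniformly long introns (2x a single
    per-gene draw from intron_len_range) so that flanking introns of
    circRNAs are longer than those of non-circ genes; the Alu-like 300-mer
    is planted with probability sqrt(f) in circ-flanking introns and f^2 in
    all other introns, f = alu_seed_fraction.
    """
    rng = _rng(spec, 0)
    n_circ = int(round(spec.circ_fraction * spec.n_genes))
    circ_gene_idx = set(
        rng.choice(spec.n_genes, size=n_circ, replace=False).tolist()
    ) if n_circ else set()

    genes: dict[str, Gene] = {}
    chrom_seqs: dict[str, list[str]] = {}
    repeats: list[tuple[str, int, int, str, int, str]] = []
    truth_records: list[TruthCirc] = []

    cursor = 0
    chrom = ""
    chrom_parts: list[str] = []

    def flush_chrom():
        if chrom:
            chrom_seqs[chrom] = chrom_parts.copy()

    for gi in range(spec.n_genes):
        if gi % GENES_PER_CHROM == 0:
            flush_chrom()
            chrom = f"chr{gi // GENES_PER_CHROM + 1}"
            chrom_parts = []
            cursor = 0
        gene_id = f"G{gi + 1:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        is_circ_gene = gi in circ_gene_idx

        n_ex = int(rng.integers(spec.exons_per_gene_range[0], spec.exons_per_gene_range[1] + 1))
        if is_circ_gene:
            n_ex = max(n_ex, 6)
        exon_lens = rng.integers(
            spec.exon_len_range[0], spec.exon_len_range[1] + 1, size=n_ex
        ).tolist()
        if is_circ_gene:
            base_intron = int(rng.integers(spec.intron_len_range[0], spec.intron_len_range[1] + 1))
            intron_lens = [2 * base_intron] * (n_ex - 1)
        else:
            intron_lens = rng.integers(
                spec.intron_len_range[0], spec.intron_len_range[1] + 1, size=n_ex - 1
            ).tolist()

        # intergenic gap then gene body
        gap_seq = "".join(rng.choice(list("ACGT"), size=INTERGENIC_GAP))
        chrom_parts.append(gap_seq)
        cursor += INTERGENIC_GAP
        gene_start = cursor + 1  # 1-based

        exon_ivs: list[tuple[int, int]] = []
        intron_ivs: list[tuple[int, int]] = []
        pos = gene_start
        for k in range(n_ex):
            exon_ivs.append((pos, pos + exon_lens[k] - 1))
            pos += exon_lens[k]
            if k < n_ex - 1:
                intron_ivs.append((pos, pos + intron_lens[k] - 1))
                pos += intron_lens[k]
        gene_end = pos - 1
        body_len = gene_end - gene_start + 1
        body = rng.choice(list("ACGT"), size=body_len)

        # exon numbering 5'->3'
        genomic_order = list(range(n_ex))
        tx_order = genomic_order if strand == "+" else genomic_order[::-1]
        tid = f"{gene_id}.t1"
        exons = []
        for rank, k in enumerate(tx_order, start=1):
            s, e = exon_ivs[k]
            exons.append(Exon(chrom, s, e, strand, gene_id, tid, rank))
        tx = Transcript(tid, gene_id, chrom, strand, exons)
        # CDS spans the internal exons; ~5% of genes stay noncoding
        if rng.random() > 0.05 and n_ex >= 3:
            internal = [exon_ivs[k] for k in genomic_order[1:-1]]
            tx.cds = (min(s for s, _ in internal), max(e for _, e in internal))
        gene = Gene(gene_id, chrom, strand, gene_start, gene_end, {tid: tx})

        # one in five non-circ genes gets a second transcript with one
        # internal exon extended 30 nt into the downstream intron
        if not is_circ_gene and n_ex >= 4 and rng.random() < 0.2:
            k_ext = int(rng.integers(1, n_ex - 1))
            if intron_lens[k_ext - 1 if k_ext == n_ex - 1 else k_ext] > 60:
                tid2 = f"{gene_id}.t2"
                exons2 = []
                for rank, k in enumerate(tx_order, start=1):
                    s, e = exon_ivs[k]
                    if k == k_ext and k < n_ex - 1:
                        e = e + 30
                    exons2.append(Exon(chrom, s, e, strand, gene_id, tid2, rank))
                tx2 = Transcript(tid2, gene_id, chrom, strand, exons2)
                tx2.cds = tx.cds
                gene.transcripts[tid2] = tx2

        # truth circRNA on this gene
        flank_intron_idx: set[int] = set()
        if is_circ_gene:
            # transcript-order acceptor rank 2; donor rank in [2, n_ex-3]
            # leaving >= 2 free introns outside the flanks
            d_max = n_ex - 3
            donor_rank = int(rng.integers(2, max(2, d_max) + 1))
            acceptor_rank = 2
            acc_k = tx_order[acceptor_rank - 1]
            don_k = tx_order[donor_rank - 1]
            span_start = min(exon_ivs[acc_k][0], exon_ivs[don_k][0])
            span_end = max(exon_ivs[acc_k][1], exon_ivs[don_k][1])
            circ_id = f"{chrom}:{span_start}-{span_end}:{strand}"
            baseline = float(
                spec.mean_gene_count * 0.1 * rng.lognormal(0.0, 0.5)
            )
            truth_records.append(
                TruthCirc(circ_id, gene_id, acceptor_rank, donor_rank, baseline)
            )
            # flanking introns (genomic indices adjacent to the span)
            left_k = min(acc_k, don_k)
            right_k = max(acc_k, don_k)
            if left_k - 1 >= 0:
                flank_intron_idx.add(left_k - 1)
            if right_k <= n_ex - 2:
                flank_intron_idx.add(right_k)

        # Alu seeding
        f = spec.alu_seed_fraction
        p_flank = math.sqrt(f)
        p_other = f * f
        for ii, (is_, ie) in enumerate(intron_ivs):
            p = p_flank if ii in flank_intron_idx else p_other
            if rng.random() < p:
                ilen = ie - is_ + 1
                alu = ALU_LIKE[: min(ALU_LENGTH, ilen)]
                max_off = ilen - len(alu)
                off = int(rng.integers(0, max_off + 1)) if max_off > 0 else 0
                a_start = is_ + off  # 1-based genomic
                body[a_start - gene_start : a_start - gene_start + len(alu)] = list(alu)
                repeats.append(
                    (chrom, a_start - 1, a_start - 1 + len(alu), "AluLike", 0, "+")
                )

        chrom_parts.append("".join(body))
        cursor = gene_end
        genes[gene_id] = gene

    flush_chrom()
    genome = {c: "".join(parts) for c, parts in chrom_seqs.items()}

    # specific circRNAs
    specific_ids: list[str] = []
    if truth_records and spec.n_specific > 0:
        k = min(spec.n_specific, len(truth_records))
        idx = _rng(spec, 1).choice(len(truth_records), size=k, replace=False)
        specific_ids = sorted(truth_records[i].circ_id for i in idx)

    truth = TruthSet(truth_records, specific_ids, spec.suppressed_group)
    return SyntheticGenome(genome, GenomeAnnotation(genes), repeats, truth)


def truth_to_circs(
    annotation: GenomeAnnotation, truth: TruthSet
) -> list[ConfidentCircRNA]:
    """Materialize truth circRNAs as annotated records (exact boundaries)."""
    out = []
    for rec in truth.circ_records:
        gene = annotation.genes[rec.gene_id]
        tx = gene.transcripts[f"{rec.gene_id}.t1"]
        ordered = tx.exons_5to3()
        acceptor = ordered[rec.acceptor_index - 1]
        donor = ordered[rec.donor_index - 1]
        start = min(acceptor.start, donor.start)
        end = max(acceptor.end, donor.end)
        out.append(
            ConfidentCircRNA(
                circ_id=rec.circ_id,
                chrom=gene.chrom,
                start=start,
                end=end,
                strand=gene.strand,
                gene_id=rec.gene_id,
                acceptor_exon=acceptor,
                donor_exon=donor,
                boundary_discrepancy=(0, 0),
            )
        )
    return out


@dataclass
class CohortCounts:
    bsj: pd.DataFrame  # circ_id x samples
    linear: pd.DataFrame  # linear junction contig name x samples
    genes: pd.DataFrame  # gene_id x samples
    tx_tpm: pd.DataFrame  # transcript_id x samples
    metadata: pd.DataFrame  # sample_id, group, library_factor


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    mu = np.clip(mu, 1e-9, None)
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _linear_contig_names(gene: Gene) -> list[str]:
    return [
        f"{gene.gene_id}|lin|{a.start}-{a.end}|{b.start}-{b.end}"
        for a, b in gene.junctions()
    ]


def simulate_cohort_counts(
    annotation: GenomeAnnotation,
    truth: TruthSet,
    spec: SimSpec,
    apply_specific_fold: bool = True,
    stream: int = 2,
) -> CohortCounts:
    """Draw cohort count matrices with the planted group effect.

    Back-splice means in the suppressed group are multiplied by
    spec.suppression_factor before negative-binomial sampling; specific
    circRNAs are multiplied by spec.specific_fold in every sample (they are
    elevated in this, the focal, cohort) unless apply_specific_fold=False
    (control cohorts).
    """
    if truth.suppressed_group not in spec.n_samples_per_group:
        raise ValueError(f"unknown suppressed group {truth.suppressed_group!r}")
    rng = _rng(spec, stream)
    gene_ids = sorted(annotation.genes)
    base_rng = _rng(spec, 99)  # shared across focal and control cohorts
    gene_base = {
        g: float(spec.mean_gene_count * base_rng.lognormal(0.0, 0.5)) for g in gene_ids
    }

    samples, groups = [], []
    for group in sorted(spec.n_samples_per_group):
        for i in range(spec.n_samples_per_group[group]):
            samples.append(f"{group}_s{i:03d}")
            groups.append(group)
    lib = rng.lognormal(0.0, 0.3, size=len(samples))

    specific = set(truth.specific_ids)
    circ_ids = [r.circ_id for r in truth.circ_records]
    circ_base = {r.circ_id: r.baseline_mean for r in truth.circ_records}

    lin_names: list[str] = []
    lin_gene: list[str] = []
    for g in gene_ids:
        for name in _linear_contig_names(annotation.genes[g]):
            lin_names.append(name)
            lin_gene.append(g)

    n_s = len(samples)
    gene_mat = np.zeros((len(gene_ids), n_s), dtype=int)
    lin_mat = np.zeros((len(lin_names), n_s), dtype=int)
    bsj_mat = np.zeros((len(circ_ids), n_s), dtype=int)

    gene_mu = np.array([gene_base[g] for g in gene_ids])
    lin_mu = np.array([gene_base[g] for g in lin_gene])
    for j, (sample, group) in enumerate(zip(samples, groups)):
        gene_mat[:, j] = _nb_draw(rng, gene_mu * lib[j], spec.nb_dispersion)
        lin_mat[:, j] = _nb_draw(rng, lin_mu * lib[j], spec.nb_dispersion)
        mu_c = np.array([circ_base[c] for c in circ_ids]) * lib[j]
        if group == truth.suppressed_group:
            mu_c = mu_c * spec.suppression_factor
        if apply_specific_fold and specific:
            mask = np.array([c in specific for c in circ_ids])
            mu_c = np.where(mask, mu_c * spec.specific_fold, mu_c)
        bsj_mat[:, j] = _nb_draw(rng, mu_c, spec.nb_dispersion)

    # transcript TPMs from gene counts split by fixed isoform weights
    tx_rows, tx_len, tx_weight, tx_gene_idx = [], [], [], []
    for gi, g in enumerate(gene_ids):
        gene = annotation.genes[g]
        tids = sorted(gene.transcripts)
        w = [0.7, 0.3] if len(tids) == 2 else [1.0]
        for tid, wt in zip(tids, w):
            tx_rows.append(tid)
            tx_len.append(sum(e.length for e in gene.transcripts[tid].exons))
            tx_weight.append(wt)
            tx_gene_idx.append(gi)
    tx_counts = gene_mat[tx_gene_idx, :] * np.array(tx_weight)[:, None]
    rate = tx_counts / np.array(tx_len, dtype=float)[:, None]
    col_tot = rate.sum(axis=0)
    col_tot[col_tot == 0] = 1.0
    tpm = rate / col_tot * 1e6

    meta = pd.DataFrame(
        {"sample_id": samples, "group": groups, "library_factor": lib}
    )
    return CohortCounts(
        bsj=pd.DataFrame(bsj_mat, index=circ_ids, columns=samples),
        linear=pd.DataFrame(lin_mat, index=lin_names, columns=samples),
        genes=pd.DataFrame(gene_mat, index=gene_ids, columns=samples),
        tx_tpm=pd.DataFrame(tpm, index=tx_rows, columns=samples),
        metadata=meta,
    )


def simulate_control_cohort(
    annotation: GenomeAnnotation,
    truth: TruthSet,
    spec: SimSpec,
    n_samples: int,
    label: str,
    stream: int,
) -> pd.DataFrame:
    """Back-splice counts for a control cohort: no suppression, no specific fold."""
    control_spec = SimSpec(
        **{
            **spec.__dict__,
            "n_samples_per_group": {label: n_samples},
            "suppressed_group": label,
            "suppression_factor": 1.0,
        }
    )
    control_truth = TruthSet(truth.circ_records, truth.specific_ids, label)
    cc = simulate_cohort_counts(
        annotation, control_truth, control_spec, apply_specific_fold=False, stream=stream
    )
    return cc.bsj


@dataclass
class DecoySpec:
    n_low_mapq: int = 0
    n_secondary: int = 0
    n_wrong_orientation: int = 0
    n_nonspanning: int = 0


def simulate_junction_reads(
    ref: JunctionReference,
    bsj_counts: pd.DataFrame,
    linear_counts: pd.DataFrame,
    out_dir,
    spec: SimSpec,
    read_len: int = 75,
    min_overhang: int = 5,
    decoys: DecoySpec | None = None,
    export_fastq: bool = False,
) -> dict[str, str]:
    """Emit one SAM file per sample with exactly the counted spanning pairs.

    For every contig and sample, the count-matrix cell number of read pairs
    is written as primary records spanning the breakpoint window with MAPQ
    60 and first-mate-reverse / second-mate-forward orientation. Decoy
    records per class carry "decoy|<class>" read-name prefixes and must not
    be counted downstream. Returns {sample: sam path}.
    """
    import pysam

    if read_len < 2 * min_overhang:
        raise ValueError(
            f"read_len {read_len} shorter than minimum spanning overhang {2 * min_overhang}"
        )
    decoys = decoys or DecoySpec()
    os.makedirs(out_dir, exist_ok=True)
    rng = _rng(spec, 7)
    contig_names = list(ref.contigs)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": c.name, "LN": len(c.sequence)} for c in ref.contigs.values()
            ],
        }
    )
    name_to_id = {n: i for i, n in enumerate(contig_names)}

    def contig_for_row(row_name: str, frame: str) -> str | None:
        if frame == "bsj":
            name = f"{row_name}|bsj"
            return name if name in ref.contigs else None
        return row_name if row_name in ref.contigs else None

    def make_pair(qname, contig, s1, s2, mapq=60, flag1=83, flag2=163):
        L = len(ref.contigs[contig].sequence)
        seq = ref.contigs[contig].sequence
        a1 = pysam.AlignedSegment(header)
        a1.query_name = qname
        a1.flag = flag1
        a1.reference_id = name_to_id[contig]
        a1.reference_start = s1 - 1
        a1.mapping_quality = mapq
        a1.cigartuples = [(0, read_len)]
        a1.next_reference_id = name_to_id[contig]
        a1.next_reference_start = s2 - 1
        a1.template_length = -(s1 + read_len - s2)
        a1.query_sequence = seq[s1 - 1 : s1 - 1 + read_len]
        a2 = pysam.AlignedSegment(header)
        a2.query_name = qname
        a2.flag = flag2
        a2.reference_id = name_to_id[contig]
        a2.reference_start = s2 - 1
        a2.mapping_quality = mapq
        a2.cigartuples = [(0, read_len)]
        a2.next_reference_id = name_to_id[contig]
        a2.next_reference_start = s1 - 1
        a2.template_length = s1 + read_len - s2
        a2.query_sequence = seq[s2 - 1 : s2 - 1 + read_len]
        return a1, a2

    def spanning_start(contig) -> tuple[int, int]:
        o = ref.contigs[contig].junction_offset
        L = len(ref.contigs[contig].sequence)
        lo = max(1, o + min_overhang - read_len + 1)
        hi = min(o - min_overhang + 1, L - read_len + 1)
        if hi < lo:
            raise ValueError(f"contig {contig} too short for spanning reads")
        s1 = int(rng.integers(lo, hi + 1))
        s2 = max(1, s1 - int(rng.integers(0, 41)))
        return s1, s2

    paths: dict[str, str] = {}
    samples = list(bsj_counts.columns)
    for sample in samples:
        path = os.path.join(str(out_dir), f"{sample}.sam")
        with pysam.AlignmentFile(path, "wh", header=header) as out:
            serial = 0
            for frame_name, frame in (("bsj", bsj_counts), ("linear", linear_counts)):
                for row_name, count in frame[sample].items():
                    contig = contig_for_row(str(row_name), frame_name)
                    if contig is None or count <= 0:
                        continue
                    for _ in range(int(count)):
                        serial += 1
                        s1, s2 = spanning_start(contig)
                        for rec in make_pair(f"frag{serial:08d}", contig, s1, s2):
                            out.write(rec)
            # decoys
            def decoy_contig():
                return contig_names[int(rng.integers(0, len(contig_names)))]

            for i in range(decoys.n_low_mapq):
                c = decoy_contig()
                s1, s2 = spanning_start(c)
                for rec in make_pair(f"decoy|lowmapq|{i}", c, s1, s2, mapq=5):
                    out.write(rec)
            for i in range(decoys.n_secondary):
                c = decoy_contig()
                s1, s2 = spanning_start(c)
                for rec in make_pair(
                    f"decoy|secondary|{i}", c, s1, s2, flag1=83 | 256, flag2=163 | 256
                ):
                    out.write(rec)
            for i in range(decoys.n_wrong_orientation):
                c = decoy_contig()
                s1, s2 = spanning_start(c)
                # first mate forward / second reverse
                for rec in make_pair(f"decoy|orient|{i}", c, s2, s1, flag1=99, flag2=147):
                    out.write(rec)
            for i in range(decoys.n_nonspanning):
                c = decoy_contig()
                o = ref.contigs[c].junction_offset
                L = len(ref.contigs[c].sequence)
                if o - min_overhang >= read_len:
                    s = 1
                elif L - (o + min_overhang) >= read_len:
                    s = o + min_overhang + 1
                else:
                    continue
                for rec in make_pair(f"decoy|nonspan|{i}", c, s, s):
                    out.write(rec)
        paths[sample] = path
        if export_fastq:
            _sam_to_fastq(path, read_len)
    return paths


def _sam_to_fastq(sam_path: str, read_len: int) -> None:
    import pysam

    base = sam_path[:-4]
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh, open(
        base + "_R1.fastq", "w"
    ) as r1, open(base + "_R2.fastq", "w") as r2:
        for read in fh:
            if read.is_secondary or read.is_supplementary:
                continue
            seq = read.query_sequence
            if read.is_reverse:
                seq = revcomp(seq)
            out = r1 if read.is_read1 else r2
            out.write(f"@{read.query_name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_ciri2_tables(sim: SyntheticGenome, counts: CohortCounts, outdir) -> dict[str, str]:
    """Per-sample CIRI2-style prediction tables from the truth back-splice counts."""
    os.makedirs(outdir, exist_ok=True)
    by_gene = {r.circ_id: r.gene_id for r in sim.truth.circ_records}
    paths = {}
    for sample in counts.bsj.columns:
        path = os.path.join(str(outdir), f"{sample}.tsv")
        with open(path, "w") as fh:
            fh.write(
                "circRNA_ID\tchr\tcircRNA_start\tcircRNA_end\t#junction_reads\t"
                "strand\tcircRNA_type\tgene_id\n"
            )
            for circ_id, n in counts.bsj[sample].items():
                chrom, span, strand = str(circ_id).split(":")
                start, end = span.split("-")
                fh.write(
                    f"{circ_id}\t{chrom}\t{start}\t{end}\t{int(n)}\t{strand}\texon\t"
                    f"{by_gene[str(circ_id)]}\n"
                )
        paths[sample] = path
    return paths


def write_simulation(outdir, sim: SyntheticGenome, counts: CohortCounts) -> None:
    """Write genome/annotation/repeats/counts/truth to a directory."""
    from .annotation import write_fasta

    os.makedirs(outdir, exist_ok=True)
    write_fasta(sim.genome, os.path.join(outdir, "genome.fa"))
    sim.annotation.to_gtf(os.path.join(outdir, "annotation.gtf"))
    with open(os.path.join(outdir, "repeats.bed"), "w") as fh:
        for chrom, s, e, name, score, strand in sim.repeats:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{score}\t{strand}\n")
    counts.bsj.rename_axis("feature").to_csv(os.path.join(outdir, "bsj_counts.tsv"), sep="\t")
    counts.linear.rename_axis("feature").to_csv(
        os.path.join(outdir, "linear_counts.tsv"), sep="\t"
    )
    counts.genes.rename_axis("gene_id").to_csv(os.path.join(outdir, "gene_counts.tsv"), sep="\t")
    counts.tx_tpm.rename_axis("transcript_id").to_csv(
        os.path.join(outdir, "tx_tpm.tsv"), sep="\t"
    )
    counts.metadata.to_csv(os.path.join(outdir, "metadata.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(
            {
                "circ_records": [r.__dict__ for r in sim.truth.circ_records],
                "specific_ids": sim.truth.specific_ids,
                "suppressed_group": sim.truth.suppressed_group,
            },
            fh,
            indent=1,
        )
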