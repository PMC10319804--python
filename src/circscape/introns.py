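"""Putative circRNA sequences, length-matched controls and intron selection.

The putative sequence of an exonic circRNA splices together all annotated
exons of its host gene lying between the back-splice boundaries (longest
exon wins on overlap). The control sequence splices all exons strictly
upstream or strictly downstream of the circle — whichever side gives the
longer product — and is symmetrically trimmed to the circRNA length.
Flanking introns are the longest introns up- and downstream of the circle;
control introns are picked greedily (longest first, non-overlapping) until
their cumulative length reaches that of the flanks. Repeat (Alu) overlap of
flank vs control introns is compared with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .annotation import GenomeAnnotation, Intron, extract, revcomp
from .catalog import ConfidentCircRNA
from .stats import fisher_2x2, rank_test

MIN_INTRON_LEN = 15


@dataclass
class CircSequence:
    circ_id: str
    sequence: str
    exon_chain: list[tuple[int, int]]  # genomic intervals, transcript order


@dataclass
class ControlSequence:
    circ_id: str
    sequence: str
    side: str  # upstream / downstream (transcript orientation)
    length_matched: bool


@dataclass
class FlankSet:
    circ_id: str
    gene_id: str
    chrom: str
    upstream_intron: tuple[int, int] | None  # genomic 1-based inclusive
    downstream_intron: tuple[int, int] | None
    control_introns: list[tuple[int, int]] = field(default_factory=list)

    @property
    def flank_cumulative(self) -> int:
        tot = 0
        for iv in (self.upstream_intron, self.downstream_intron):
            if iv is not None:
                tot += iv[1] - iv[0] + 1
        return tot

    @property
    def control_cumulative(self) -> int:
        return sum(e - s + 1 for s, e in self.control_introns)


def _resolve_overlaps(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Keep the longest interval in each overlap cluster (ties: leftmost)."""
    ivs = sorted(set(intervals))
    out: list[tuple[int, int]] = []
    cluster: list[tuple[int, int]] = []
    for iv in ivs:
        if cluster and iv[0] <= max(e for _, e in cluster):
            cluster.append(iv)
        else:
            if cluster:
                out.append(max(cluster, key=lambda x: (x[1] - x[0], -x[0])))
            cluster = [iv]
    if cluster:
        out.append(max(cluster, key=lambda x: (x[1] - x[0], -x[0])))
    return out


def build_circ_sequence(
    circ: ConfidentCircRNA, annotation: GenomeAnnotation, genome: dict[str, str]
) -> CircSequence:
    """Splice all annotated gene exons between the back-splice boundaries.

    Overlapping exon variants resolve to the longest; the terminal exon
    boundaries are replaced by the candidate's own coordinates so that
    back-splice boundary discrepancies of +-1 nt are preserved in the
    sequence.
    """
    gene = annotation.genes[circ.gene_id]
    in_span = [
        e.interval
        for e in gene.exons()
        if e.start >= circ.start - 1 and e.end <= circ.end + 1
    ]
    if not in_span:
        raise ValueError(f"no annotated exons inside {circ.circ_id}")
    chain = _resolve_overlaps(in_span)
    # impose the candidate's boundaries on the terminal exons
    first = (circ.start, chain[0][1])
    last = (chain[-1][0], circ.end)
    if len(chain) == 1:
        chain = [(circ.start, circ.end)]
    else:
        chain = [first] + chain[1:-1] + [last]
    seq_plus = "".join(extract(genome, circ.chrom, s, e, "+") for s, e in chain)
    if circ.strand == "-":
        seq = revcomp(seq_plus)
        chain_tx = chain[::-1]
    else:
        seq = seq_plus
        chain_tx = chain
    return CircSequence(circ.circ_id, seq, chain_tx)


def build_control_sequence(
    circ: ConfidentCircRNA,
    annotation: GenomeAnnotation,
    genome: dict[str, str],
    circ_length: int | None = None,
) -> ControlSequence | None:
    """Length-matched spliced control sequence from outside the circle.

    Splices all gene exons strictly 5' of the acceptor and, separately, all
    strictly 3' of the donor; the longer spliced product is chosen and, if
    longer than the circRNA sequence, trimmed by floor(excess/2) from the
    start and ceil(excess/2) from the end. If both sides are shorter, the
    longer one is returned unpadded and flagged length_matched=False.
    Returns None when the gene has no exons outside the span.
    """
    gene = annotation.genes[circ.gene_id]
    if circ_length is None:
        circ_length = len(build_circ_sequence(circ, annotation, genome).sequence)
    left = _resolve_overlaps(
        [e.interval for e in gene.exons() if e.end < circ.start]
    )
    right = _resolve_overlaps(
        [e.interval for e in gene.exons() if e.start > circ.end]
    )
    if circ.strand == "+":
        up_ivs, down_ivs = left, right
    else:
        up_ivs, down_ivs = right, left

    def splice(ivs: list[tuple[int, int]]) -> str:
        seq_plus = "".join(extract(genome, circ.chrom, s, e, "+") for s, e in ivs)
        return revcomp(seq_plus) if circ.strand == "-" else seq_plus

    up_seq, down_seq = splice(up_ivs), splice(down_ivs)
    if not up_seq and not down_seq:
        return None
    side, seq = max(
        [("upstream", up_seq), ("downstream", down_seq)], key=lambda t: len(t[1])
    )
    if len(seq) >= circ_length:
        excess = len(seq) - circ_length
        lead, tail = excess // 2, excess - excess // 2
        seq = seq[lead : len(seq) - tail]
        return ControlSequence(circ.circ_id, seq, side, True)
    return ControlSequence(circ.circ_id, seq, side, False)


def select_flanking_and_control_introns(
    circ: ConfidentCircRNA,
    annotation: GenomeAnnotation,
    min_len: int = MIN_INTRON_LEN,
) -> FlankSet:
    """Longest up/downstream flanking introns plus greedy control introns.

    Controls are the longest gene introns (>= min_len) that do not overlap
    the circle span, the flanks, or each other, added until their cumulative
    length reaches the cumulative flank length. Intervals stay independent
    (no splicing).
    """
    gene = annotation.genes[circ.gene_id]
    introns = [i for i in gene.introns() if i.length >= min_len]
    # flanking introns are the ones immediately adjacent to the circle
    # boundaries (longest annotated variant of that gap; 1 bp slack for
    # back-splice boundary discrepancies)
    left = [i for i in introns if circ.start - 2 <= i.end <= circ.start]
    right = [i for i in introns if circ.end <= i.start <= circ.end + 2]
    if circ.strand == "+":
        up_pool, down_pool = left, right
    else:
        up_pool, down_pool = right, left

    def longest(pool: list[Intron]) -> tuple[int, int] | None:
        if not pool:
            return None
        best = max(pool, key=lambda i: (i.length, -i.start))
        return (best.start, best.end)

    up = longest(up_pool)
    down = longest(down_pool)
    fs = FlankSet(circ.circ_id, circ.gene_id, circ.chrom, up, down)

    def overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
        return a[0] <= b[1] and b[0] <= a[1]

    blocked = [iv for iv in (up, down, (circ.start, circ.end)) if iv is not None]
    target = fs.flank_cumulative
    for i in sorted(introns, key=lambda i: (-i.length, i.start)):
        if fs.control_cumulative >= target:
            break
        iv = (i.start, i.end)
        if any(overlaps(iv, b) for b in blocked):
            continue
        fs.control_introns.append(iv)
        blocked.append(iv)
    return fs


def _repeat_trees(repeats) -> dict[str, IntervalTree]:
    """Interval trees from BED6-style (chrom, start0, end0, ...) rows."""
    trees: dict[str, IntervalTree] = {}
    for row in repeats:
        chrom, s, e = row[0], int(row[1]), int(row[2])
        if e > s:
            trees.setdefault(chrom, IntervalTree()).addi(s, e)
    return trees


def _has_repeat(tree: IntervalTree | None, start1: int, end1: int) -> bool:
    if tree is None:
        return False
    return bool(tree.overlap(start1 - 1, end1))  # 1-based inclusive -> 0-based half-open


def alu_enrichment(flank_sets: list[FlankSet], repeats) -> dict[str, dict]:
    """Fisher tables of repeat overlap: flank vs control introns.

    Strata: 'upstream', 'downstream', 'combined'. Intersection means >= 1 bp
    overlap with a repeat interval. Control introns are shared across
    strata. Empty strata yield a table with p = None.
    """
    trees = _repeat_trees(repeats)
    up, down, controls = [], [], []
    for fs in flank_sets:
        tree = trees.get(fs.chrom)
        if fs.upstream_intron:
            up.append(_has_repeat(tree, *fs.upstream_intron))
        if fs.downstream_intron:
            down.append(_has_repeat(tree, *fs.downstream_intron))
        for iv in fs.control_introns:
            controls.append(_has_repeat(tree, *iv))

    ctrl_hit = sum(controls)
    ctrl_miss = len(controls) - ctrl_hit
    out = {}
    for name, flags in (
        ("upstream", up),
        ("downstream", down),
        ("combined", up + down),
    ):
        hit = sum(flags)
        miss = len(flags) - hit
        table = [[hit, miss], [ctrl_hit, ctrl_miss]]
        if len(flags) == 0 or len(controls) == 0:
            out[name] = {"table": table, "odds_ratio": None, "p_value": None}
        else:
            odds, p = fisher_2x2(table, alternative="two-sided")
            out[name] = {"table": table, "odds_ratio": odds, "p_value": p}
    return out


def intron_length_compare(
    flank_sets: list[FlankSet],
    annotation: GenomeAnnotation,
    control_genes: list[str],
    min_len: int = MIN_INTRON_LEN,
) -> dict:
    """Flanking-intron lengths vs intron lengths of non-circ control genes."""
    flank_lengths = []
    for fs in flank_sets:
        for iv in (fs.upstream_intron, fs.downstream_intron):
            if iv is not None:
                flank_lengths.append(iv[1] - iv[0] + 1)
    if not flank_lengths:
        raise ValueError("no flanking introns to compare")
    control_lengths = [
        i.length
        for g in control_genes
        for i in annotation.genes[g].introns()
        if i.length >= min_len
    ]
    if not control_lengths:
        raise ValueError("no control introns to compare")
    stat, p = rank_test(flank_lengths, control_lengths, alternative="two-sided")
    return {
        "flank_mean": float(pd.Series(flank_lengths).mean()),
        "control_mean": float(pd.Series(control_lengths).mean()),
        "n_flank": len(flank_lengths),
        "n_control": len(control_lengths),
        "p_value": p,
    }
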