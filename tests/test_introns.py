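"""circRNA sequence assembly, control sequences, intron selection, Alu tests."""

import math

import numpy as np
import pytest
from scipy.special import comb

from circscape import introns as intr
from circscape import simulate as sim
from circscape.annotation import Exon, Gene, GenomeAnnotation, Transcript
from circscape.catalog import ConfidentCircRNA
from circscape.stats import fisher_2x2


def _gene_with_exons(intervals, strand="+", gene_id="G1", extra_tx=None):
    tid = gene_id + ".t1"
    exons = [
        Exon("chr1", s, e, strand, gene_id, tid, i + 1) for i, (s, e) in enumerate(intervals)
    ]
    txs = {tid: Transcript(tid, gene_id, "chr1", strand, exons)}
    if extra_tx:
        tid2 = gene_id + ".t2"
        exons2 = [
            Exon("chr1", s, e, strand, gene_id, tid2, i + 1)
            for i, (s, e) in enumerate(extra_tx)
        ]
        txs[tid2] = Transcript(tid2, gene_id, "chr1", strand, exons2)
    gene = Gene(gene_id, "chr1", strand,
                min(s for s, _ in intervals), max(e for _, e in intervals), txs)
    return GenomeAnnotation({gene_id: gene})


def _genome(n=20000, seed=0):
    rng = np.random.default_rng(seed)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=n))}


def _circ(ann, start, end, gene_id="G1"):
    gene = ann.genes[gene_id]
    exons = gene.exons()
    acceptor = next(e for e in exons if e.start == start)
    donor = next(e for e in exons if e.end == end)
    if gene.strand == "-":
        acceptor, donor = donor, acceptor
    return ConfidentCircRNA(
        f"chr1:{start}-{end}:{gene.strand}", "chr1", start, end, gene.strand,
        gene_id, acceptor, donor, (0, 0),
    )


class TestCircSequence:
    def test_simple_three_exon_splice(self):
        ivs = [(1, 100), (201, 300), (401, 450), (601, 680), (801, 900)]
        ann = _gene_with_exons(ivs)
        genome = _genome()
        circ = _circ(ann, 201, 680)
        cs = intr.build_circ_sequence(circ, ann, genome)
        expected = "".join(genome["chr1"][s - 1 : e] for s, e in [(201, 300), (401, 450), (601, 680)])
        assert cs.sequence == expected
        assert len(cs.sequence) == 100 + 50 + 80

    def test_longest_exon_wins_on_overlap(self):
        ivs = [(1, 100), (201, 300), (401, 450), (601, 680)]
        # variant transcript extends exon 2 by 20 nt (overlapping, longer)
        ann = _gene_with_exons(ivs, extra_tx=[(1, 100), (201, 320), (401, 450), (601, 680)])
        genome = _genome()
        circ = _circ(ann, 201, 680)
        cs = intr.build_circ_sequence(circ, ann, genome)
        assert len(cs.sequence) == 120 + 50 + 80

    def test_minus_strand_is_reverse_complement(self):
        from circscape.annotation import revcomp

        ivs = [(1, 100), (201, 300), (401, 500)]
        ann = _gene_with_exons(ivs, strand="-")
        genome = _genome()
        circ = _circ(ann, 201, 500)
        cs = intr.build_circ_sequence(circ, ann, genome)
        plus = genome["chr1"][200:300] + genome["chr1"][400:500]
        assert cs.sequence == revcomp(plus)

    def test_no_exons_in_span_raises(self):
        ann = _gene_with_exons([(1, 100), (901, 1000)])
        circ = ConfidentCircRNA("chr1:300-600:+", "chr1", 300, 600, "+", "G1",
                                ann.genes["G1"].exons()[0], ann.genes["G1"].exons()[0], (0, 0))
        with pytest.raises(ValueError):
            intr.build_circ_sequence(circ, ann, _genome())


class TestControlSequence:
    def test_symmetric_trim_of_longer_side(self):
        # upstream spliced 300 nt, downstream 200 nt, circ 230 nt
        ivs = [(1, 150), (201, 350), (401, 470), (601, 760), (1001, 1200)]
        ann = _gene_with_exons(ivs)
        genome = _genome()
        circ = _circ(ann, 401, 760)  # exons 3+4: 70+160 = 230 nt
        ctrl = intr.build_control_sequence(circ, ann, genome, 230)
        assert ctrl.side == "upstream" and ctrl.length_matched
        up = genome["chr1"][0:150] + genome["chr1"][200:350]  # 300 nt
        assert ctrl.sequence == up[35:265]
        assert len(ctrl.sequence) == 230

    def test_exact_length_control_unmodified(self):
        ivs = [(1, 100), (201, 300), (401, 500)]
        ann = _gene_with_exons(ivs)
        genome = _genome()
        circ = _circ(ann, 201, 500)  # 200 nt circle, upstream exon 100 nt
        ctrl = intr.build_control_sequence(circ, ann, genome, 100)
        assert len(ctrl.sequence) == 100 and ctrl.length_matched

    def test_no_outside_exons_absent(self):
        ivs = [(1, 100), (201, 300)]
        ann = _gene_with_exons(ivs)
        circ = _circ(ann, 1, 300)
        assert intr.build_control_sequence(circ, ann, _genome(), 200) is None

    def test_shorter_both_sides_flagged(self):
        ivs = [(1, 50), (201, 400), (601, 800), (1001, 1040)]
        ann = _gene_with_exons(ivs)
        circ = _circ(ann, 201, 800)  # 400 nt circle; outside exons 50 and 40
        ctrl = intr.build_control_sequence(circ, ann, _genome(), 400)
        assert not ctrl.length_matched and len(ctrl.sequence) == 50


class TestFlankSelection:
    def test_greedy_control_trace(self):
        """Flanks 1000+2000; disjoint introns of 2500 and 900 elsewhere are
        both picked as controls (cumulative 3400 >= 3000)."""
        # exons and the gaps between them:
        # e1 (1,100) |1000| e2 (1101,1200) |100| e3 (1301,1400) |2000|
        # e4 (3401,3500) |2500| e5 (6001,6100) |900| e6 (7001,7100)
        ivs = [(1, 100), (1101, 1200), (1301, 1400), (3401, 3500),
               (6001, 6100), (7001, 7100)]
        ann = _gene_with_exons(ivs)
        circ = _circ(ann, 1101, 1400)  # e2..e3; adjacent introns 1000 and 2000
        fs = intr.select_flanking_and_control_introns(circ, ann)
        assert fs.upstream_intron == (101, 1100)
        assert fs.downstream_intron == (1401, 3400)
        assert fs.control_introns == [(3501, 6000), (6101, 7000)]
        assert fs.control_cumulative == 3400 >= fs.flank_cumulative == 3000

    def test_14nt_intron_ignored(self):
        ivs = [(1, 100), (115, 200), (401, 500)]  # first gap is 14 nt
        ann = _gene_with_exons(ivs)
        circ = _circ(ann, 115, 500)
        fs = intr.select_flanking_and_control_introns(circ, ann)
        assert fs.upstream_intron is None

    def test_circ_at_gene_edge_has_no_upstream(self):
        ivs = [(1, 100), (301, 400), (601, 700)]
        ann = _gene_with_exons(ivs)
        circ = _circ(ann, 1, 400)
        fs = intr.select_flanking_and_control_introns(circ, ann)
        assert fs.upstream_intron is None
        assert fs.downstream_intron == (401, 600)

    def test_synthetic_world_invariants(self, world):
        """Non-overlap and cumulative-length constraints hold for every
        synthetic circRNA."""
        circs = sim.truth_to_circs(world.annotation, world.truth)
        for circ in circs:
            fs = intr.select_flanking_and_control_introns(circ, world.annotation)
            ivs = fs.control_introns + [
                iv for iv in (fs.upstream_intron, fs.downstream_intron) if iv
            ] + [(circ.start, circ.end)]
            for i in range(len(ivs)):
                for j in range(i + 1, len(ivs)):
                    a, b = ivs[i], ivs[j]
                    assert a[1] < b[0] or b[1] < a[0], (circ.circ_id, a, b)
            assert fs.control_cumulative >= fs.flank_cumulative
            for s, e in fs.control_introns:
                assert e - s + 1 >= 15


class TestAluEnrichment:
    def test_extreme_table_matches_hypergeometric(self):
        flank_sets = []
        repeats = []
        # 10 circs whose flanks (both) carry a repeat; controls never do
        for i in range(10):
            base = 10000 * (i + 1)
            fs = intr.FlankSet(f"c{i}", "g", "chr1",
                               (base, base + 99), (base + 200, base + 299),
                               [(base + 400, base + 499)])
            flank_sets.append(fs)
            repeats.append(("chr1", base - 1 + 10, base - 1 + 40, "AluLike", 0, "+"))
            repeats.append(("chr1", base - 1 + 210, base - 1 + 240, "AluLike", 0, "+"))
        out = intr.alu_enrichment(flank_sets, repeats)
        up = out["upstream"]
        assert up["table"] == [[10, 0], [0, 10]]
        # hypergeometric enumeration: the two extreme tables (all hits in one
        # row) are the only ones as unlikely as observed, each 1/C(20,10)
        expected = 2.0 / comb(20, 10)
        assert up["p_value"] == pytest.approx(expected, rel=1e-9)

    def test_identical_rates_give_p_one(self):
        flank_sets = []
        repeats = []
        for i in range(8):
            base = 10000 * (i + 1)
            fs = intr.FlankSet(f"c{i}", "g", "chr1", (base, base + 99), None,
                               [(base + 400, base + 499)])
            flank_sets.append(fs)
            if i % 2 == 0:  # half of flanks and half of controls carry a repeat
                repeats.append(("chr1", base - 1, base + 99, "AluLike", 0, "+"))
                repeats.append(("chr1", base - 1 + 400, base + 499, "AluLike", 0, "+"))
        out = intr.alu_enrichment(flank_sets, repeats)
        assert out["upstream"]["p_value"] == pytest.approx(1.0)

    def test_empty_stratum_reported_absent(self):
        fs = intr.FlankSet("c", "g", "chr1", None, None, [(100, 200)])
        out = intr.alu_enrichment([fs], [])
        assert out["upstream"]["p_value"] is None

    def test_synthetic_seeding_biased_to_flanks_is_detected(self):
        spec = sim.SimSpec(seed=19, alu_seed_fraction=0.35)
        w = sim.generate_annotation(spec)
        circs = sim.truth_to_circs(w.annotation, w.truth)
        flank_sets = [
            intr.select_flanking_and_control_introns(c, w.annotation) for c in circs
        ]
        out = intr.alu_enrichment(flank_sets, w.repeats)
        assert out["combined"]["p_value"] < 0.01
        assert out["combined"]["odds_ratio"] > 1


class TestIntronLengthCompare:
    def test_planted_longer_circ_introns(self, world):
        circs = sim.truth_to_circs(world.annotation, world.truth)
        flank_sets = [
            intr.select_flanking_and_control_introns(c, world.annotation) for c in circs
        ]
        circ_genes = {c.gene_id for c in circs}
        control_genes = sorted(set(world.annotation.genes) - circ_genes)
        res = intr.intron_length_compare(flank_sets, world.annotation, control_genes)
        assert res["flank_mean"] > res["control_mean"]
        assert res["p_value"] < 0.01

    def test_empty_circ_set_raises(self, world):
        with pytest.raises(ValueError):
            intr.intron_length_compare([], world.annotation, list(world.annotation.genes))


class TestFisherOracle:
    def test_fisher_matches_hypergeometric_enumeration(self):
        """Two-sided Fisher p equals summing hypergeometric probabilities of
        tables as or less likely, for all margins with total <= 14."""
        def oracle(a, b, c, d):
            n = a + b + c + d
            r1, c1 = a + b, a + c
            denom = comb(n, c1)
            def pr(x):
                if x < max(0, c1 - (c + d)) or x > min(r1, c1):
                    return 0.0
                return comb(r1, x) * comb(n - r1, c1 - x) / denom
            p_obs = pr(a)
            return sum(pr(x) for x in range(0, min(r1, c1) + 1)
                       if pr(x) <= p_obs * (1 + 1e-9))
        rng = np.random.default_rng(2)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 5, size=4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            _, p = fisher_2x2([[a, b], [c, d]])
            assert p == pytest.approx(oracle(int(a), int(b), int(c), int(d)), abs=1e-9)
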