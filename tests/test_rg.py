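"""Reference-guided core: CCR detection, junction correction, isoforms."""
import numpy as np
import pytest

import rollcirc as rc
from rollcirc.align import AlignedSegment, SegmentChain
from rollcirc.core import Annotation, Gene, Genome, Transcript
from rollcirc.rg import (
    BSJ, build_isoform, build_pseudo_ref, correct_bsj, correct_fsj,
    detect_ccr, detect_fsj, tandem_genome_filter,
)


def _seg(qs, qe, rs, re, chrom="chr1", strand="+", blocks=None):
    blocks = blocks or [(rs, re)]
    qblocks = []
    q = qs
    for bs, be in blocks:
        qblocks.append((q, q + (be - bs)))
        q += be - bs
    return AlignedSegment(
        read_id="r", chrom=chrom, strand=strand, qstart=qs, qend=qe,
        rstart=rs, rend=re, blocks=blocks, qblocks=qblocks,
        matches=qe - qs, score=float(qe - qs),
    )


def _chain(*segs):
    return [SegmentChain("r", list(segs))]


class TestDetectCcr:
    def test_constructed_chiastic_pair(self):
        ccr = detect_ccr(
            _chain(_seg(0, 300, 500, 800), _seg(300, 900, 200, 800)),
            read_len=900,
        )
        assert ccr is not None
        assert ccr.potential_bsj == (200, 800)
        assert ccr.ccr_type == "normal"
        assert ccr.copy_count == pytest.approx(900 / 600, abs=0.01)

    def test_single_segment_is_linear(self):
        assert detect_ccr(_chain(_seg(0, 500, 100, 600)), read_len=500) is None

    def test_cross_chromosome_pair_is_inter_fusion(self):
        segs = [
            _seg(0, 300, 100, 400, chrom="chr1"),
            _seg(300, 600, 5000, 5300, chrom="chr2"),
            _seg(600, 900, 100, 400, chrom="chr1"),
        ]
        ccr = detect_ccr(_chain(*segs), read_len=900)
        assert ccr.ccr_type == "inter-chrom fusion"

    def test_same_chrom_below_distance_not_fusion(self):
        # 0.5 Mbp apart: falls back to normal handling of the major locus
        segs = [
            _seg(0, 300, 100, 400),
            _seg(300, 600, 500_000, 500_300),
            _seg(600, 900, 100, 400),
        ]
        ccr = detect_ccr(_chain(*segs), read_len=900)
        assert ccr is None or ccr.ccr_type == "normal"

    def test_tandem_exact_copies_detected(self):
        # start_offset 0: copies restart at the same reference position
        segs = [_seg(0, 600, 200, 800), _seg(600, 1200, 200, 800)]
        ccr = detect_ccr(_chain(*segs), read_len=1200)
        assert ccr is not None
        assert ccr.potential_bsj == (200, 800)


class TestPseudoRef:
    def test_definitional_construction(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        g = Genome({"chr1": seq})
        pseudo, seam = build_pseudo_ref(g, "chr1", 200, 800)
        assert pseudo == seq[650:800] + seq[200:350]
        assert len(pseudo) == 300 and seam == 150

    def test_chromosome_edge_clipping(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        g = Genome({"chr1": seq})
        # donor-side flank clipped by the chromosome start
        pseudo, seam = build_pseudo_ref(g, "chr1", 20, 120)
        # span 100 < flank: flanks clip to the circle span
        assert seam == 100
        assert pseudo == seq[20:120] + seq[20:120]

    def test_span_below_minimum_rejected(self):
        g = Genome({"chr1": "ACGT" * 1000})
        with pytest.raises(ValueError):
            build_pseudo_ref(g, "chr1", 100, 130)


class TestCorrectBsj:
    @pytest.fixture()
    def world(self):
        rng = np.random.default_rng(3)
        seq = list("".join(rng.choice(list("ACGT"), 3000)))
        # annotated exon boundaries 200/800 with back-splice motif context
        seq[198:200] = "AG"
        seq[800:802] = "GT"
        # a planted motif pair at (1200, 1900) with no annotation
        seq[1198:1200] = "AG"
        seq[1900:1902] = "GT"
        g = Genome({"chr1": "".join(seq)})
        ann = Annotation(
            [Gene("g1", "chr1", "+", [Transcript("t1", [(200, 800)])])]
        )
        return g, ann

    def test_mode_plus_annotation(self, world):
        g, ann = world
        cands = [(200, 800, f"r{i}", "+") for i in range(9)]
        cands.append((202, 800, "r9", "+"))
        out = correct_bsj(cands, ann, g, "chr1")
        assert len(out) == 1
        b = out[0]
        assert (b.acceptor_start, b.donor_end) == (200, 800)
        assert b.provenance == "annotation-snapped"
        assert b.support_reads == 10

    def test_motif_snap_without_annotation(self, world):
        g, _ = world
        cands = [(1203, 1897, f"r{i}", "+") for i in range(5)]
        out = correct_bsj(cands, None, g, "chr1")
        b = out[0]
        assert (b.acceptor_start, b.donor_end) == (1200, 1900)
        assert b.provenance == "motif-snapped"
        assert b.motif == "GT/AG"

    def test_fallback_to_read_consensus(self, world):
        g, _ = world
        # region with no motif: candidates keep their modal position
        cands = [(2203, 2797, f"r{i}", "+") for i in range(4)]
        cands.append((2205, 2797, "r9", "+"))
        out = correct_bsj(cands, None, g, "chr1")
        b = out[0]
        assert b.provenance in ("read-consensus", "motif-snapped")
        if b.provenance == "read-consensus":
            assert (b.acceptor_start, b.donor_end) == (2203, 2797)

    def test_idempotent(self, world):
        g, ann = world
        cands = [(201, 799, f"r{i}", "+") for i in range(6)]
        first = correct_bsj(cands, ann, g, "chr1")
        again = correct_bsj(
            [(b.acceptor_start, b.donor_end, r, "+")
             for b in first for r in b.read_ids],
            ann, g, "chr1",
        )
        assert [(b.acceptor_start, b.donor_end) for b in first] == [
            (b.acceptor_start, b.donor_end) for b in again
        ]

    def test_nearby_distinct_junctions_split(self, world):
        g, ann = world
        # 9 reads at the annotated pair, 4 at the motif pair shifted by 15:
        # plant a second acceptor motif 15 nt from the annotated one
        seq = list(g.chromosomes["chr1"])
        seq[183:185] = "AG"
        g2 = Genome({"chr1": "".join(seq)})
        cands = [(200, 800, f"a{i}", "+") for i in range(9)]
        cands += [(185, 800, f"b{i}", "+") for i in range(4)]
        out = correct_bsj(cands, ann, g2, "chr1")
        keys = {(b.acceptor_start, b.donor_end) for b in out}
        assert (200, 800) in keys and (185, 800) in keys


class TestFsj:
    def test_detect_from_copy_blocks(self):
        seg = _seg(0, 500, 200, 800, blocks=[(200, 300), (400, 800)])
        ccr = detect_ccr(_chain(seg, _seg(500, 1000, 200, 800,
                                          blocks=[(200, 300), (400, 800)])),
                         read_len=1000)
        fsjs = detect_fsj(ccr)
        assert (300, 400) in fsjs

    def test_snap_to_annotation(self):
        ann = Annotation(
            [Gene("g", "chr1", "+",
                  [Transcript("t", [(100, 300), (400, 800)])])]
        )
        out = correct_fsj([(302, 399)], ann, "chr1")
        fsj = out[(302, 399)]
        assert (fsj.donor_end, fsj.acceptor_start) == (300, 400)
        assert fsj.annotated

    def test_cohort_mode_corrects_minority(self):
        out = correct_fsj([(300, 400), (300, 400), (300, 405)], None, "chr1")
        assert (out[(300, 405)].donor_end,
                out[(300, 405)].acceptor_start) == (300, 400)
        assert not out[(300, 405)].annotated


class TestBuildIsoform:
    def _ccr(self, copy_blocks):
        segs = []
        q = 0
        for blocks in copy_blocks:
            total = sum(e - s for s, e in blocks)
            segs.append(
                _seg(q, q + total, blocks[0][0], blocks[-1][1], blocks=blocks)
            )
            q += total
        return detect_ccr(_chain(*segs), read_len=q)

    def test_unanimous_copies(self):
        blocks = [(200, 300), (400, 800)]
        ccr = self._ccr([blocks, blocks, blocks])
        bsj = BSJ("chr1", 200, 800, "+")
        fmap = correct_fsj(detect_fsj(ccr), None, "chr1")
        iso = build_isoform(ccr, bsj, fmap)
        assert iso.blocks == blocks
        assert iso.length == 500

    def test_majority_rules_on_disputed_exon(self):
        with_exon = [(200, 300), (320, 360), (400, 800)]
        without = [(200, 300), (400, 800)]
        ccr = self._ccr([without, with_exon, without])
        bsj = BSJ("chr1", 200, 800, "+")
        fmap = correct_fsj(detect_fsj(ccr), None, "chr1")
        iso = build_isoform(ccr, bsj, fmap)
        assert iso.blocks == without

    def test_single_copy_degenerate_vote(self):
        blocks = [(200, 350), (500, 800)]
        ccr = self._ccr([blocks, blocks])
        bsj = BSJ("chr1", 200, 800, "+")
        fmap = correct_fsj(detect_fsj(ccr), None, "chr1")
        iso = build_isoform(ccr, bsj, fmap)
        assert iso.blocks == blocks


class TestTandemGenomeFilter:
    def _iso(self, g, a, d):
        return rc.CircIsoform("i", "chr1", a, d, "+", [(a, d)])

    def test_pure_tandem_span_dropped(self, rng):
        monomer = "".join(rng.choice(list("ACGT"), 60))
        seq = "".join(rng.choice(list("ACGT"), 500)) + monomer * 6 + \
              "".join(rng.choice(list("ACGT"), 500))
        g = Genome({"chr1": seq})
        assert tandem_genome_filter(self._iso(g, 500, 860), g) is False

    def test_random_span_kept(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 2000))
        g = Genome({"chr1": seq})
        # brute-force confirms no tandem period >= 1.2 copies in the span
        span = seq[500:1000]
        for p in range(30, len(span) // 2):
            m = sum(a == b for a, b in zip(span, span[p:]))
            assert m < 0.8 * (len(span) - p) or (len(span) / p) < 1.2
        assert tandem_genome_filter(self._iso(g, 500, 1000), g) is True

    def test_low_coverage_duplication_kept(self, rng):
        uniq = "".join(rng.choice(list("ACGT"), 400))
        dup = "".join(rng.choice(list("ACGT"), 60))
        seq = "x".join([""]) + uniq + dup + dup + "".join(
            rng.choice(list("ACGT"), 200)
        )
        g = Genome({"chr1": seq})
        # duplication covers ~120/520 nt of the span: below the 80% rule
        assert tandem_genome_filter(self._iso(g, 0, 520), g) is True
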