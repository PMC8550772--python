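"""Aligner behaviour: examples, oracle agreement, SAM adaptor fixed point."""
import numpy as np
import pytest

import rollcirc as rc
from rollcirc.align import (
    GenomeIndex, SpliceAlignParams, local_align, place_junction,
    read_sam, realign_to_pseudo_ref, splice_align, write_sam,
)
from rollcirc.core import Genome, PrimerSet, revcomp

P1 = PrimerSet().P1


def _affine_sw_oracle(a, b, match=2, mismatch=-4, gap_open=-4, gap_ext=-2):
    """Exhaustive affine-gap Smith-Waterman returning (best score,
    min identity, max identity) over all optimal local paths."""
    n, m = len(a), len(b)
    NEG = -10**9
    # states: M (diagonal), X (gap in b), Y (gap in a); value: score
    M = np.full((n + 1, m + 1), 0.0)
    X = np.full((n + 1, m + 1), NEG, dtype=float)
    Y = np.full((n + 1, m + 1), NEG, dtype=float)
    # identity range per cell for the M state
    Mlo = np.zeros((n + 1, m + 1)); Mhi = np.zeros((n + 1, m + 1))
    Xlo = np.zeros((n + 1, m + 1)); Xhi = np.zeros((n + 1, m + 1))
    Ylo = np.zeros((n + 1, m + 1)); Yhi = np.zeros((n + 1, m + 1))
    best, blo, bhi = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            ident = 1 if a[i - 1] == b[j - 1] else 0
            opts = [
                (M[i - 1][j - 1], Mlo[i - 1][j - 1], Mhi[i - 1][j - 1]),
                (X[i - 1][j - 1], Xlo[i - 1][j - 1], Xhi[i - 1][j - 1]),
                (Y[i - 1][j - 1], Ylo[i - 1][j - 1], Yhi[i - 1][j - 1]),
                (0.0, 0, 0),
            ]
            top = max(o[0] for o in opts)
            lo = min(o[1] for o in opts if o[0] == top)
            hi = max(o[2] for o in opts if o[0] == top)
            val = top + s
            if val < 0:
                M[i][j], Mlo[i][j], Mhi[i][j] = 0.0, 0, 0
            else:
                M[i][j] = val
                Mlo[i][j], Mhi[i][j] = lo + ident, hi + ident
            # gap states
            xo = [(M[i - 1][j] + gap_open, Mlo[i - 1][j], Mhi[i - 1][j]),
                  (X[i - 1][j] + gap_ext, Xlo[i - 1][j], Xhi[i - 1][j])]
            topx = max(o[0] for o in xo)
            X[i][j] = topx
            Xlo[i][j] = min(o[1] for o in xo if o[0] == topx)
            Xhi[i][j] = max(o[2] for o in xo if o[0] == topx)
            yo = [(M[i][j - 1] + gap_open, Mlo[i][j - 1], Mhi[i][j - 1]),
                  (Y[i][j - 1] + gap_ext, Ylo[i][j - 1], Yhi[i][j - 1])]
            topy = max(o[0] for o in yo)
            Y[i][j] = topy
            Ylo[i][j] = min(o[1] for o in yo if o[0] == topy)
            Yhi[i][j] = max(o[2] for o in yo if o[0] == topy)
            if M[i][j] > best:
                best, blo, bhi = M[i][j], Mlo[i][j], Mhi[i][j]
            elif M[i][j] == best and best > 0:
                blo = min(blo, Mlo[i][j])
                bhi = max(bhi, Mhi[i][j])
    return best, int(blo), int(bhi)


class TestLocalAlign:
    def test_primer_self_alignment_full_identity(self):
        assert local_align(P1, P1).identity_count == len(P1) == 23

    def test_against_exhaustive_dp_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            a = "".join(rng.choice(list("ACGT"), int(rng.integers(10, 60))))
            b = "".join(rng.choice(list("ACGT"), int(rng.integers(10, 60))))
            res = local_align(a, b)
            score, lo, hi = _affine_sw_oracle(a, b)
            assert res.score == score
            assert lo <= res.identity_count <= hi

    def test_revcomp_primer_scores_below_identity(self):
        score, lo, hi = _affine_sw_oracle(P1, revcomp(P1))
        res = local_align(P1, revcomp(P1))
        assert res.score == score
        assert res.identity_count <= hi < 23

    def test_empty_sequence(self):
        assert local_align(P1, "").identity_count == 0
        assert local_align("", P1).score == 0


class TestSpliceAlign:
    @pytest.fixture(scope="class")
    def world(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 20_000))
        # plant GT..AG intron motif at [1200, 1500)
        seq = seq[:1200] + "GT" + seq[1202:1498] + "AG" + seq[1500:]
        g = Genome({"chr1": seq})
        return g, GenomeIndex(g)

    def test_exact_substring_single_block(self, world):
        g, idx = world
        chains = splice_align(g.chromosomes["chr1"][1000:1400], idx)
        seg = chains[0].segments[0]
        assert seg.blocks == [(1000, 1400)]
        assert seg.strand == "+"

    def test_planted_splice_two_blocks(self, world):
        g, idx = world
        s = g.chromosomes["chr1"]
        chains = splice_align(s[1000:1200] + s[1500:1700], idx)
        seg = chains[0].segments[0]
        assert seg.blocks == [(1000, 1200), (1500, 1700)]

    def test_reverse_strand(self, world):
        g, idx = world
        chains = splice_align(revcomp(g.chromosomes["chr1"][2000:2300]), idx)
        seg = chains[0].segments[0]
        assert seg.blocks == [(2000, 2300)]
        assert seg.strand == "-"

    def test_empty_query_raises(self, world):
        _, idx = world
        with pytest.raises(ValueError):
            splice_align("", idx)

    def test_rolling_read_yields_one_segment_per_copy(self, world):
        g, idx = world
        s = g.chromosomes["chr1"]
        circ = s[3000:3500]
        read = (circ[100:] + circ * 3)[:1500]  # 0.8 + 3 copies -> 4 pieces
        chains = splice_align(read, idx)
        segs = chains[0].segments
        assert len(segs) == 4
        assert segs[1].blocks == [(3000, 3500)]
        assert segs[0].blocks == [(3100, 3500)]

    def test_error_free_linear_reads_recover_exact_boundaries(self):
        genome = rc.make_genome(1, 80_000, 0.0, seed=17)
        genome, ann = rc.make_annotation(genome, n_genes=5, seed=18)
        idx = GenomeIndex(genome)
        for g in ann.genes[:3]:
            t = g.transcripts[0]
            seq = "".join(genome.fetch(g.chrom, s, e) for s, e in t.exons)
            chains = splice_align(seq, idx)
            seg = chains[0].segments[0]
            assert seg.blocks == t.exons


class TestSamAdaptor:
    def test_parse_emit_fixed_point(self, indexed_world, tmp_path):
        genome, ann, truths, idx = indexed_world
        rng = np.random.default_rng(5)
        t = truths[0]
        err = rc.ErrorModel(0, 0, 0)
        all_chains = []
        lengths = {}
        for i in range(3):
            read = rc.simulate_rcrt_read(
                t, 2.0, int(rng.integers(0, len(t.seq))),
                "second_strand" if i % 2 else "first_strand",
                err, rng=rng, read_id=f"r{i}",
            )
            chains = splice_align(read.sequence, idx, read_id=f"r{i}")
            all_chains.append(chains[0])
            lengths[f"r{i}"] = len(read.sequence)
        p1, p2 = tmp_path / "a.sam", tmp_path / "b.sam"
        write_sam(all_chains, genome, p1, lengths)
        parsed = read_sam(p1)
        write_sam(list(parsed.values()), genome, p2, lengths)
        reparsed = read_sam(p2)
        for rid in parsed:
            s1 = [(s.chrom, s.strand, tuple(s.blocks), tuple(s.qblocks))
                  for s in parsed[rid].segments]
            s2 = [(s.chrom, s.strand, tuple(s.blocks), tuple(s.qblocks))
                  for s in reparsed[rid].segments]
            assert s1 == s2


class TestRealignPseudoRef:
    def _setup(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        g = Genome({"chr1": seq})
        a, d = 3000, 3500
        circ = seq[a:d]
        read = (circ * 3)[:1400]
        pseudo, seam = rc.build_pseudo_ref(g, "chr1", a, d)
        return read, pseudo, seam

    def test_error_free_crossings_offset_zero(self):
        read, pseudo, seam = self._setup()
        res = realign_to_pseudo_ref(read, pseudo, seam)
        assert len(res) >= 2
        assert all(off == 0 and ok for off, ok in res)

    def test_deletion_at_seam_flags_false(self):
        read, pseudo, seam = self._setup()
        # read crosses seam at multiples of 500; delete 2 nt at the first
        mut = read[:499] + read[501:]
        res = realign_to_pseudo_ref(mut[:700], pseudo, seam)
        assert res
        assert res[0][1] is False
        assert res[0][0] == -2

    def test_read_on_one_side_only_empty(self):
        read, pseudo, seam = self._setup()
        rng = np.random.default_rng(4)
        other = "".join(rng.choice(list("ACGT"), 400))
        assert realign_to_pseudo_ref(other, pseudo, seam) == []


class TestPlaceJunction:
    def test_prefers_motif_on_tie(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        # exons [100,300) and [600,800), GT..AG planted
        ref = seq[:300] + "GT" + seq[302:598] + "AG" + seq[600:]
        query = ref[100:300] + ref[600:800]
        d, a, qs = place_junction(query, ref, 290, 290 + 100 - 90, 110, 610)
        # anchored at q=290<->r=300-10 ... check it lands on the motif
        d2, a2, _ = place_junction(query, ref, 195, 295, 205, 605)
        assert (d2, a2) == (300, 600)
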