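"""Filters at their printed boundaries, classification, AS events,
quantification."""
import numpy as np
import pytest

import rollcirc as rc
from rollcirc.core import Annotation, Gene, Genome, Transcript
from rollcirc.postprocess import (
    ASEvent, PipelineConfig, annotate_known, classify_circ_type,
    detect_as_events, junction_fidelity_filter, quantify,
    repeat_proximity_filter, unsplicing_filter,
)
from rollcirc.rg import BSJ, CircIsoform


def _iso(blocks, strand="+", iid="i", chrom="chr1", reads=1):
    return CircIsoform(
        iid, chrom, blocks[0][0], blocks[-1][1], strand, list(blocks),
        read_ids={f"{iid}_{k}" for k in range(reads)}, support_reads=reads,
    )


class TestUnsplicingFilter:
    @pytest.mark.parametrize(
        "bs,lin,keep",
        [
            (2, 28, False),   # 0.067 < 0.1
            (5, 0, True),     # 1.0
            (1, 9, True),     # exactly 0.1: '<0.1' drops strictly below
            (1, 10, False),   # 0.0909
        ],
    )
    def test_boundaries(self, bs, lin, keep):
        assert unsplicing_filter(bs, lin) is keep


class TestJunctionFidelityFilter:
    def test_three_of_five_kept(self):
        flags = {"BSJ": [True, True, True, False, False]}
        assert junction_fidelity_filter(flags) is True

    def test_exactly_half_dropped(self):
        flags = {"BSJ": [True, True, False, False]}
        assert junction_fidelity_filter(flags) is False

    def test_every_junction_rule(self):
        flags = {
            "BSJ": [True] * 5,
            (300, 400): [True, True, False, False, False],  # 40%
        }
        assert junction_fidelity_filter(flags) is False


class TestRepeatProximityFilter:
    TRACK = [("chr1", 1000, 1200)]

    def test_both_ends_near_repeat_dropped(self):
        # acceptor 10 bp left of repeat, donor 10 bp right of it
        assert repeat_proximity_filter(("chr1", 990, 1210), self.TRACK) is False

    def test_one_end_only_kept(self):
        assert repeat_proximity_filter(("chr1", 1100, 1700), self.TRACK) is True

    def test_exactly_30bp_counts_as_proximal(self):
        assert repeat_proximity_filter(("chr1", 970, 1230), self.TRACK) is False
        assert repeat_proximity_filter(("chr1", 969, 1230), self.TRACK) is True

    def test_missing_track_keeps_everything(self):
        assert repeat_proximity_filter(("chr1", 1000, 1200), None) is True


class TestFusionDistanceBoundary:
    def test_one_base_over_a_megabase_triggers(self):
        from rollcirc.fusion import FusionCircRNA

        make = lambda gap: FusionCircRNA(
            "f", "chr1", [(0, 100)], "+", "chr1",
            [(100 + gap, 200 + gap)], "+", (100, 100 + gap),
            (200 + gap, 0),
        )
        make(1_000_001)  # constructs fine
        with pytest.raises(ValueError):
            make(1_000_000)


class TestClassify:
    @pytest.fixture(scope="class")
    def ann(self):
        g1 = Gene("g1", "chr1", "+",
                  [Transcript("t1", [(1000, 1200), (1500, 1700),
                                     (2000, 2200)])])
        g2 = Gene("g2", "chr1", "+", [Transcript("t2", [(5000, 5300)])])
        g3 = Gene("g3", "chr1", "-", [Transcript("t3", [(8000, 8400)])])
        return Annotation([g1, g2, g3])

    def test_exonic(self, ann):
        assert classify_circ_type(
            _iso([(1000, 1200), (1500, 1700)]), ann) == "exonic"

    def test_intronic(self, ann):
        assert classify_circ_type(_iso([(1250, 1450)]), ann) == "intronic"

    def test_read_through_spans_two_genes(self, ann):
        iso = _iso([(2000, 2200), (5000, 5300)])
        assert classify_circ_type(iso, ann) == "read_through"

    def test_nss_novel_boundary_inside_gene(self, ann):
        assert classify_circ_type(
            _iso([(1100, 1700)]), ann) == "nss"

    def test_novel_utr_extends_past_terminal_exon(self, ann):
        assert classify_circ_type(
            _iso([(5000, 5450)]), ann) == "novel_utr"

    def test_antisense(self, ann):
        assert classify_circ_type(
            _iso([(8100, 8300)], strand="+"), ann) == "antisense"

    def test_intergenic(self, ann):
        assert classify_circ_type(_iso([(3000, 3400)]), ann) == "intergenic"

    def test_total_and_deterministic(self, ann, rng):
        for _ in range(50):
            s = int(rng.integers(500, 9000))
            e = s + int(rng.integers(60, 1500))
            iso = _iso([(s, e)], strand="+" if rng.random() < 0.5 else "-")
            t1 = classify_circ_type(iso, ann)
            t2 = classify_circ_type(iso, ann)
            assert t1 == t2
            assert t1 in ("exonic", "intronic", "nss", "intergenic",
                          "novel_utr", "antisense", "read_through")


# ---------------------------------------------------------------------------
# AS events vs a brute-force oracle
# ---------------------------------------------------------------------------

def _as_oracle(x, y):
    """Independent enumeration of AS events from per-base exon masks and
    junction sets."""
    span = (x.acceptor_start, x.donor_end)
    size = span[1] - span[0]
    mask = lambda iso: np.array(
        [any(s <= p < e for s, e in iso.blocks)
         for p in range(span[0], span[1])]
    )
    mx, my = mask(x), mask(y)
    introns = lambda iso: {
        (iso.blocks[i][1], iso.blocks[i + 1][0])
        for i in range(len(iso.blocks) - 1)
    }
    ix, iy = introns(x), introns(y)
    events = set()
    strand = x.strand if x.strand in "+-" else "+"
    for inc, exc, i_inc, i_exc, m_exc in (
        (x, y, ix, iy, my), (y, x, iy, ix, mx)
    ):
        # ES: an internal block of inc entirely intron in exc, with the
        # spanning intron of exc matching inc's two flanking junctions
        for bi in range(1, len(inc.blocks) - 1):
            s, e = inc.blocks[bi]
            big = (inc.blocks[bi - 1][1], inc.blocks[bi + 1][0])
            if big in i_exc and not m_exc[s - span[0] : e - span[0]].any():
                events.add(("ES", (s, e)))
        # IR: an intron of exc exonic in inc, where the contiguous exonic
        # run of inc spans exactly the two flanking exons of exc
        inc_mask = mask(inc)
        runs = []
        p = 0
        while p < size:
            if inc_mask[p]:
                q = p
                while q < size and inc_mask[q]:
                    q += 1
                runs.append((p + span[0], q + span[0]))
                p = q
            else:
                p += 1
        run_set = set(runs)
        for bi in range(len(exc.blocks) - 1):
            (S, d) = exc.blocks[bi]
            (a, E) = exc.blocks[bi + 1]
            if (S, E) in run_set and (S, E) in set(inc.blocks):
                events.add(("IR", (d, a)))
    for d1, a1 in ix:
        for d2, a2 in iy:
            if (d1, a1) == (d2, a2) or min(a1, a2) <= max(d1, d2):
                continue
            if d1 == d2 and a1 != a2:
                et = "A3SS" if strand == "+" else "A5SS"
                events.add((et, (min(a1, a2), max(a1, a2))))
            elif a1 == a2 and d1 != d2:
                et = "A5SS" if strand == "+" else "A3SS"
                events.add((et, (min(d1, d2), max(d1, d2))))
    return events


def _random_chain_pair(rng, span=(1000, 4000)):
    """Two exon chains over one BSJ with shared boundary pool (so ES/IR/A3/A5
    coincidences actually occur)."""
    pool = np.sort(rng.choice(
        np.arange(span[0] + 50, span[1] - 50, 25), size=14, replace=False
    ))

    def chain():
        cuts = sorted(rng.choice(pool, size=2 * int(rng.integers(1, 5)),
                                 replace=False))
        blocks = [(span[0], int(cuts[0]))]
        for i in range(1, len(cuts) - 1, 2):
            blocks.append((int(cuts[i]), int(cuts[i + 1])))
        blocks.append((int(cuts[-1]), span[1]))
        return [(s, e) for s, e in blocks if e > s]

    return chain(), chain()


class TestAsEvents:
    def test_exon_skip_example(self):
        a = _iso([(1000, 1100), (1300, 1400), (1600, 1700)], iid="a")
        b = _iso([(1000, 1100), (1600, 1700)], iid="b")
        events = detect_as_events([a, b])
        es = [e for e in events if e.event_type == "ES"]
        assert len(es) == 1
        assert es[0].region == (1300, 1400)
        assert es[0].delta_length == 100

    def test_intron_retention_example(self):
        a = _iso([(1000, 1700)], iid="a")
        b = _iso([(1000, 1300), (1400, 1700)], iid="b")
        events = detect_as_events([a, b])
        ir = [e for e in events if e.event_type == "IR"]
        assert len(ir) == 1
        assert ir[0].region == (1300, 1400)
        assert ir[0].delta_length == 100

    def test_a3ss_a5ss_strand_mirroring(self):
        plus_a = _iso([(1000, 1300), (1400, 1700)], iid="a")
        plus_b = _iso([(1000, 1300), (1450, 1700)], iid="b")
        ev = detect_as_events([plus_a, plus_b])
        assert {e.event_type for e in ev} == {"A3SS"}
        minus_a = _iso([(1000, 1300), (1400, 1700)], "-", iid="a")
        minus_b = _iso([(1000, 1300), (1450, 1700)], "-", iid="b")
        ev = detect_as_events([minus_a, minus_b])
        assert {e.event_type for e in ev} == {"A5SS"}

    def test_matches_brute_force_oracle_on_random_pairs(self, rng):
        mismatches = 0
        for k in range(1000):
            bx, by = _random_chain_pair(rng)
            x = _iso(bx, iid="x")
            y = _iso(by, iid="y")
            got = {
                (e.event_type, e.region) for e in detect_as_events([x, y])
            }
            want = _as_oracle(x, y)
            if got != want:
                mismatches += 1
                if mismatches <= 3:
                    print("chains", bx, by)
                    print("got", sorted(got))
                    print("want", sorted(want))
        assert mismatches == 0


class TestQuantify:
    def test_ratios_normalise_per_bsj(self):
        isos = [
            _iso([(1000, 1400)], iid="i1", reads=8),
            _iso([(1000, 1200), (1300, 1400)], iid="i2", reads=2),
        ]
        iso_df, bsj_df = quantify({"s1": isos})
        assert sorted(iso_df["ratio_s1"]) == [0.2, 0.8]
        assert iso_df["ratio_s1"].sum() == pytest.approx(1.0)
        assert bsj_df["count_s1"].iloc[0] == 10

    def test_delta_ratio_between_samples(self):
        a = [_iso([(1000, 1400)], iid="i1", reads=8),
             _iso([(1000, 1200), (1300, 1400)], iid="i2", reads=2)]
        b = [_iso([(1000, 1400)], iid="i1", reads=5),
             _iso([(1000, 1200), (1300, 1400)], iid="i2", reads=5)]
        iso_df, _ = quantify({"A": a, "B": b})
        i1 = iso_df[iso_df.n_blocks == 1].iloc[0]
        assert i1["delta_ratio"] == pytest.approx(0.3)

    def test_high_quality_flag_at_five_reads(self):
        isos = [_iso([(1000, 1400)], iid="i1", reads=5),
                _iso([(2000, 2400)], iid="i2", reads=4)]
        iso_df, _ = quantify({"s": isos})
        assert iso_df.set_index("isoform_id")["hq_s"].to_dict() == {
            "i1": True, "i2": False
        }


class TestAnnotateKnown:
    KNOWN = [("chr1", 1000, 1400)]

    def test_exact_and_tolerant_match(self):
        flags = annotate_known(
            [("chr1", 1000, 1400), ("chr1", 1001, 1399), ("chr1", 1005, 1400)],
            self.KNOWN,
        )
        assert flags == [True, True, False]

    def test_no_database_all_unknown(self):
        assert annotate_known([("chr1", 1000, 1400)], None) == [False]


class TestConfig:
    def test_defaults_match_method_thresholds(self):
        c = PipelineConfig()
        assert c.min_qscore == 7.0
        assert c.pseudo_flank == 150
        assert c.unsplicing_min == 0.1
        assert c.junction_fidelity_bp == 4
        assert c.repeat_proximity_bp == 30
        assert c.fusion_min_distance == 1_000_000
        assert c.high_quality_min_reads == 5
        assert c.train_fraction == 0.75

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(min_qscore=-1)
        with pytest.raises(ValueError):
            PipelineConfig(train_fraction=1.5)


class TestFilterOrderIndependence:
    def test_filters_commute(self):
        """Each filter is a pure predicate, so any application order gives
        the same surviving set."""
        import itertools

        cases = [
            dict(uns=(5, 10), fid={"BSJ": [True, True, False]},
                 rep=("chr1", 5000, 6000)),
            dict(uns=(1, 30), fid={"BSJ": [True] * 4},
                 rep=("chr1", 990, 1210)),
            dict(uns=(9, 1), fid={"BSJ": [True, False]},
                 rep=("chr1", 100, 5000)),
        ]
        track = [("chr1", 1000, 1200)]
        preds = [
            lambda c: unsplicing_filter(*c["uns"]),
            lambda c: junction_fidelity_filter(c["fid"]),
            lambda c: repeat_proximity_filter(c["rep"], track),
        ]
        baseline = [all(p(c) for p in preds) for c in cases]
        for order in itertools.permutations(preds):
            assert [all(p(c) for p in order) for c in cases] == baseline
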