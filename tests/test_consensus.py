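"""Period detection, consensus polishing, internal-repeat screen, merging."""
import edlib
import numpy as np
import pytest

import rollcirc as rc
from rollcirc.consensus import (
    call_consensus, detect_period, make_pseudo_query, merge_rg_crg,
    screen_internal_repeats, segment_copies,
)
from rollcirc.evaluation import oracle_period, periods_agree
from rollcirc.formats import Read
from rollcirc.rg import CircIsoform


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestDetectPeriod:
    def test_exact_tandem(self, rng):
        m = _rand(rng, 100)
        p, c = detect_period(m * 4)
        assert p == 100 and c == pytest.approx(4.0)

    def test_period_below_minimum_rejected(self, rng):
        m = _rand(rng, 20)
        assert detect_period(m * 4) is None

    def test_copy_number_below_minimum_rejected(self, rng):
        m = _rand(rng, 200)
        assert detect_period(m + m[:80]) is None  # 1.4 copies

    def test_linear_read_none(self, rng):
        assert detect_period(_rand(rng, 1200)) is None

    def test_agrees_with_exhaustive_oracle_on_noisy_reads(self, rng):
        err = rc.ErrorModel(0.02, 0.0175, 0.0125)
        n_agree = n = 0
        for _ in range(30):
            period = int(rng.integers(60, 400))
            m = _rand(rng, period)
            noisy, _ = err.apply(m * 5, rng)
            det = detect_period(noisy)
            orc = oracle_period(noisy)
            if det is None or orc is None:
                continue
            n += 1
            n_agree += periods_agree(det[0], orc)
        assert n >= 25
        assert n_agree / n >= 0.95


class TestCallConsensus:
    def test_exact_copies_reproduce_monomer(self, rng):
        m = _rand(rng, 150)
        cs = call_consensus(m * 3, 150)
        assert cs.monomer == m
        assert cs.copy_number == pytest.approx(3.0)

    def test_noisy_copies_polish_toward_truth(self, rng):
        """Monte-Carlo: majority vote across 5 copies with 5% errors must
        give >=99% mean identity to the true monomer."""
        err = rc.ErrorModel(0.02, 0.0175, 0.0125)
        idents = []
        for _ in range(40):
            m = _rand(rng, 300)
            noisy, quals = err.apply(m * 5, rng)
            res = detect_period(noisy)
            if res is None:
                continue
            cs = call_consensus(Read("x", noisy, quals), res[0])
            if cs is None:
                continue
            d = edlib.align(cs.monomer, m, mode="NW")["editDistance"]
            idents.append(1 - d / max(len(cs.monomer), len(m)))
        assert len(idents) >= 35
        assert np.mean(idents) >= 0.99

    def test_consensus_beats_single_copy_error(self, rng):
        """Polishing must strictly reduce error vs any raw copy for >=3
        copies with independent errors."""
        err = rc.ErrorModel(0.02, 0.02, 0.01)
        wins = trials = 0
        for _ in range(20):
            m = _rand(rng, 250)
            noisy, quals = err.apply(m * 4, rng)
            res = detect_period(noisy)
            if res is None:
                continue
            cs = call_consensus(Read("x", noisy, quals), res[0])
            if cs is None:
                continue
            cons_err = edlib.align(cs.monomer, m, mode="NW")["editDistance"]
            bounds = segment_copies(noisy, res[0])
            copy_errs = []
            for s, e in zip(bounds, bounds[1:]):
                copy_errs.append(
                    edlib.align(noisy[s:e], m, mode="NW")["editDistance"]
                )
            trials += 1
            wins += cons_err < min(copy_errs)
        assert trials >= 15
        assert wins / trials >= 0.9

    def test_chimeric_copies_rejected(self, rng):
        a, b = _rand(rng, 200), _rand(rng, 200)
        assert call_consensus(a + b + a + b, 200) is None or \
            call_consensus(a + b, 400) is not None  # the true period is 400


class TestScreen:
    def test_dinucleotide_repeat_removed(self):
        assert screen_internal_repeats("AT" * 60) is False

    def test_unique_monomer_passes(self, rng):
        m = _rand(rng, 400)
        # brute-force internal period scan confirms no strong repeat
        strong = False
        for p in range(2, 200):
            matches = sum(a == b for a, b in zip(m, m[p:]))
            if matches > 0.9 * (len(m) - p) and (len(m) - p) > 20:
                strong = True
        assert not strong
        assert screen_internal_repeats(m) is True

    def test_thirty_base_internal_tandem_scores_above_threshold(self, rng):
        # 30 exact internal matches: score 60 > 40 -> removed
        rep = _rand(rng, 30)
        m = _rand(rng, 150) + rep + rep + _rand(rng, 150)
        assert screen_internal_repeats(m) is False


class TestPseudoQuery:
    def test_triplication(self, rng):
        from rollcirc.consensus import ConsensusSequence

        m = _rand(rng, 300)
        cs = ConsensusSequence("r", m, 300, 3.0, [0, 300, 600])
        q = make_pseudo_query(cs)
        assert q == m * 3 and len(q) == 900

    def test_empty_monomer_rejected(self):
        from rollcirc.consensus import ConsensusSequence

        cs = ConsensusSequence("r", "", 300, 3.0, [0])
        with pytest.raises(ValueError):
            make_pseudo_query(cs)


def _iso(rid_set, blocks=((200, 800),), source="RG"):
    iso = CircIsoform(
        "i", "chr1", blocks[0][0], blocks[-1][1], "+", list(blocks),
        read_ids=set(rid_set), support_reads=len(rid_set), source=source,
    )
    return iso


class TestMerge:
    def test_same_isoform_support_summed(self):
        out = merge_rg_crg([_iso({"a", "b", "c"})],
                           [_iso({"d", "e"}, source="cRG")])
        assert len(out) == 1
        assert out[0].support_reads == 5

    def test_shared_read_counted_once(self):
        out = merge_rg_crg([_iso({"a", "b"})], [_iso({"b"}, source="cRG")])
        assert out[0].support_reads == 2

    def test_disjoint_sets_concatenate(self):
        out = merge_rg_crg(
            [_iso({"a"})], [_iso({"b"}, blocks=((900, 1400),), source="cRG")]
        )
        assert len(out) == 2

    def test_commutative_and_idempotent(self):
        a = [_iso({"a", "b"})]
        b = [_iso({"c"}, blocks=((900, 1400),), source="cRG")]
        ab = merge_rg_crg(a, b)
        ba = merge_rg_crg(b, a)
        key = lambda i: (i.acceptor_start, i.support_reads)
        assert sorted(map(key, ab)) == sorted(map(key, ba))
        again = merge_rg_crg(ab, ab)
        assert sorted(map(key, again)) == sorted(map(key, ab))
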