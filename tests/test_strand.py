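"""Strand-origin labelling, features, classifier, isoform adjustment."""
import numpy as np
import pytest

import rollcirc as rc
from rollcirc.align import AlignedSegment, SegmentChain
from rollcirc.core import Genome, PrimerSet, revcomp
from rollcirc.rg import CCR, CircIsoform, detect_ccr
from rollcirc.strand import (
    StrandLabel, adjust_strand, extract_features, label_from_fsj,
    train_classifier,
)

P = PrimerSet()


def _ccr(aligned_strand="+", chrom="chr1"):
    seg = AlignedSegment("r1", chrom, aligned_strand, 0, 100, 200, 300,
                         [(200, 300)], [(0, 100)])
    return CCR("r1", chrom, aligned_strand, "normal", [seg], [seg],
               [(200, 300)], (200, 300), 2.0)


class TestLabelFromFsj:
    def _genome(self, donor_motif, acceptor_motif):
        rng = np.random.default_rng(1)
        seq = list("".join(rng.choice(list("ACGT"), 1000)))
        seq[300:302] = donor_motif
        seq[398:400] = acceptor_motif
        return Genome({"chr1": "".join(seq)})

    def test_gtag_plus_aligned_plus_is_second_strand(self):
        g = self._genome("GT", "AG")
        lab = label_from_fsj(_ccr("+"), [(300, 400)], g)
        assert lab.label == "second_strand"
        assert lab.source == "FSJ-motif"

    def test_ctac_plus_aligned_is_first_strand(self):
        g = self._genome("CT", "AC")
        lab = label_from_fsj(_ccr("+"), [(300, 400)], g)
        assert lab.label == "first_strand"

    def test_conflicting_motifs_give_none(self):
        rng = np.random.default_rng(2)
        seq = list("".join(rng.choice(list("ACGT"), 1000)))
        seq[300:302] = "GT"; seq[398:400] = "AG"   # + transcript
        seq[500:502] = "CT"; seq[598:600] = "AC"   # - transcript
        g = Genome({"chr1": "".join(seq)})
        assert label_from_fsj(_ccr("+"), [(300, 400), (500, 600)], g) is None

    def test_no_fsj_gives_none(self):
        g = self._genome("GT", "AG")
        assert label_from_fsj(_ccr("+"), [], g) is None


class TestFeatures:
    def test_exact_p1_at_read_start(self, rng):
        read = P.P1 + "".join(rng.choice(list("ACGT"), 300))
        f = extract_features(read)
        assert f[0] == 23  # end5 vs P1

    def test_alphabet_disjoint_t24(self, rng):
        read = "".join(rng.choice(list("CG"), 200)) + "A" * 30
        f = extract_features(read)
        # 3' window is all A/C/G: zero identical bases with T24, full with A24
        assert f[8] == 0      # end3 vs T24
        assert f[11] == 24    # end3 vs revcomp(T24) = A24

    def test_features_match_local_align_directly(self, rng):
        from rollcirc.align import local_align

        read = "".join(rng.choice(list("ACGT"), 250))
        f = extract_features(read)
        pats = P.patterns()
        names = ["P1", "P2", "T24", "rcP1", "rcP2", "rcT24"]
        for i, name in enumerate(names):
            assert f[i] == local_align(read[:100], pats[name]).identity_count
            assert f[6 + i] == local_align(read[-100:], pats[name]).identity_count

    def test_short_read_uses_whole_sequence(self):
        f = extract_features(P.P1)
        assert f[0] == 23


class TestTrainClassifier:
    def _dataset(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        err = rc.ErrorModel(0.02, 0.02, 0.01)
        feats, labels = [], []
        insert = "".join(rng.choice(list("ACGT"), 400))
        for i in range(n):
            orient = "second_strand" if i % 2 else "first_strand"
            n6 = "".join(rng.choice(list("ACGT"), 6))
            layout = P.P2 + P.T24 + insert + revcomp(n6) + revcomp(P.P1)
            if orient == "first_strand":
                layout = revcomp(layout)
            seq, _ = err.apply(layout, rng)
            feats.append(extract_features(seq))
            labels.append(orient)
        return np.vstack(feats), labels

    def test_split_sizes_75_25(self):
        X, y = self._dataset(100)
        model, acc, auc = train_classifier(X, y, seed=1)
        # a 100-sample set splits 75/25; perfectly separable features
        assert acc >= 0.95 and auc >= 0.98

    def test_intact_primers_perfectly_separable(self):
        X, y = self._dataset(80, seed=3)
        _, acc, auc = train_classifier(X, y, seed=2)
        assert acc == 1.0

    def test_deterministic_given_seed(self):
        X, y = self._dataset(80, seed=4)
        r1 = train_classifier(X, y, seed=5)[1:]
        r2 = train_classifier(X, y, seed=5)[1:]
        assert r1 == r2

    def test_single_class_raises(self):
        X, y = self._dataset(60)
        with pytest.raises(ValueError, match="class"):
            train_classifier(X, ["first_strand"] * 60, seed=0)


class TestAdjustStrand:
    def _iso(self, motif="non-canonical", strand=".", reads=("a", "b", "c")):
        return CircIsoform(
            "i", "chr1", 200, 800, strand, [(200, 800)],
            read_ids=set(reads), support_reads=len(reads), bsj_motif=motif,
        )

    def test_majority_prediction_sets_strand(self):
        iso = self._iso(reads=("a", "b", "c", "d", "e"))
        preds = {
            r: StrandLabel(r, "second_strand", "predicted")
            for r in ("a", "b", "c", "d")
        }
        preds["e"] = StrandLabel("e", "first_strand", "predicted")
        aligned = {r: "+" for r in "abcde"}
        out = adjust_strand([iso], preds, aligned)
        assert out[0].strand == "+"

    def test_canonical_motif_wins_over_predictions(self):
        iso = self._iso(motif="GT/AG", strand="-")
        preds = {r: StrandLabel(r, "second_strand", "predicted")
                 for r in ("a", "b", "c")}
        out = adjust_strand([iso], preds, {r: "+" for r in "abc"})
        assert out[0].strand == "-"

    def test_tie_leaves_ambiguous_flag(self):
        iso = self._iso(reads=("a", "b", "c", "d"))
        preds = {
            "a": StrandLabel("a", "second_strand", "predicted"),
            "b": StrandLabel("b", "second_strand", "predicted"),
            "c": StrandLabel("c", "first_strand", "predicted"),
            "d": StrandLabel("d", "first_strand", "predicted"),
        }
        out = adjust_strand([iso], preds, {r: "+" for r in "abcd"})
        assert out[0].strand == "."
        assert out[0].strand_flagged
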