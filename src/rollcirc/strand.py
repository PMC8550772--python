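"""Strand-origin classification of reads from primer-identity features.

Which cDNA strand a read represents decides the transcript strand of the
circRNA it came from.  Reads whose forward splice junctions carry the
canonical GT/AG motif can be labelled directly (the motif fixes the
transcript strand, the alignment fixes the read strand); those labels train
a random-forest classifier on twelve Smith–Waterman identity features — the
maximum identical bases between each 100-nt end of the *raw* (untrimmed)
read and P1, P2, T24 and their reverse complements — which then predicts
the strand of every clean read, including reads without FSJs.  Isoforms with
non-canonical or conflicting junction motifs get their strand adjusted by
the majority predicted transcript strand of their supporting reads.

Label convention: ``second_strand`` means the read sequence is
transcript-sense (second-strand cDNA starts with P2+T24); ``first_strand``
reads are antisense and begin with P1.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .align import local_align
from .core import Genome, PrimerSet
from .rg import CCR, CircIsoform

FEATURE_NAMES = [
    f"{end}_{pat}"
    for end in ("end5", "end3")
    for pat in ("P1", "P2", "T24", "rcP1", "rcP2", "rcT24")
]


@dataclass
class StrandLabel:
    read_id: str
    label: str  # 'first_strand' | 'second_strand'
    source: str  # 'FSJ-motif' | 'predicted'


# ---------------------------------------------------------------------------
# labelling from FSJ motifs
# ---------------------------------------------------------------------------

def label_from_fsj(
    ccr: CCR,
    fsj_pairs: Sequence[Tuple[int, int]],
    genome: Genome,
) -> Optional[StrandLabel]:
    """Transcript strand from the FSJ motif, combined with the aligned strand.

    A GT..AG intron on the genomic plus strand means the transcript runs
    plus; CT..AC means minus.  A read aligned to the transcript strand is
    second-strand (sense).  Conflicting motifs across FSJs yield ``None``.
    """
    if not fsj_pairs:
        return None
    ref = genome.chromosomes.get(ccr.chrom)
    if ref is None:
        return None
    tx_strands = set()
    for d, a in set(fsj_pairs):
        donor = ref[d : d + 2]
        acceptor = ref[a - 2 : a]
        if donor == "GT" and acceptor == "AG":
            tx_strands.add("+")
        elif donor == "CT" and acceptor == "AC":
            tx_strands.add("-")
    if len(tx_strands) != 1:
        return None
    tx = tx_strands.pop()
    label = "second_strand" if ccr.aligned_strand == tx else "first_strand"
    return StrandLabel(ccr.read_id, label, "FSJ-motif")


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def extract_features(
    raw_seq: str, primers: PrimerSet | None = None, window: int = 100
) -> np.ndarray:
    """Twelve identity counts: each 100-nt read end vs the six patterns."""
    primers = primers or PrimerSet()
    pats = primers.patterns()
    end5 = raw_seq[:window]
    end3 = raw_seq[-window:]
    feats = []
    for end in (end5, end3):
        for name in ("P1", "P2", "T24", "rcP1", "rcP2", "rcT24"):
            feats.append(local_align(end, pats[name]).identity_count)
    return np.array(feats, dtype=np.int64)


def feature_matrix(
    raw_seqs: Sequence[str], primers: PrimerSet | None = None
) -> np.ndarray:
    return np.vstack([extract_features(s, primers) for s in raw_seqs])


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------

def train_classifier(
    features: np.ndarray,
    labels: Sequence[str],
    train_fraction: float = 0.75,
    seed: int = 0,
    n_estimators: int = 100,
):
    """Stratified 75/25 split, random forest fit, holdout accuracy and AUC.

    Returns ``(model, accuracy, auc)``.  Raises if fewer than two classes or
    fewer than 50 labelled examples are available.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import accuracy_score, roc_auc_score
    from sklearn.model_selection import train_test_split

    y = np.asarray(labels)
    X = np.asarray(features)
    if len(set(y)) < 2:
        raise ValueError(
            "only one strand class labelled; skip strand adjustment"
        )
    if len(y) < 50:
        raise ValueError(f"need >=50 labelled reads, got {len(y)}")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, stratify=y, random_state=seed
    )
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    model.fit(X_tr, y_tr)
    acc = float(accuracy_score(y_te, model.predict(X_te)))
    pos = model.classes_[1]
    proba = model.predict_proba(X_te)[:, 1]
    auc = float(roc_auc_score((y_te == pos).astype(int), proba))
    return model, acc, auc


def predict_strand(
    model, features: np.ndarray, read_ids: Sequence[str]
) -> Dict[str, StrandLabel]:
    preds = model.predict(np.asarray(features))
    return {
        rid: StrandLabel(rid, str(p), "predicted")
        for rid, p in zip(read_ids, preds)
    }


# ---------------------------------------------------------------------------
# isoform strand adjustment
# ---------------------------------------------------------------------------

def adjust_strand(
    isoforms: Sequence[CircIsoform],
    predictions: Dict[str, StrandLabel],
    aligned_strands: Dict[str, str],
) -> List[CircIsoform]:
    """Set the strand of non-canonical isoforms by the majority predicted
    transcript strand of their supporting reads.

    Canonical GT/AG isoforms keep their motif-derived strand regardless of
    predictions.  ``aligned_strands`` maps read_id to the strand the read
    aligned to; a second-strand (sense) read's transcript strand equals its
    aligned strand, a first-strand read's is the opposite.  Ties leave the
    strand ambiguous ('.') and flag the isoform.
    """
    out = []
    for iso in isoforms:
        if iso.bsj_motif == "GT/AG" and iso.strand in "+-":
            out.append(iso)
            continue
        votes: Counter = Counter()
        for rid in iso.read_ids:
            pred = predictions.get(rid)
            aln = aligned_strands.get(rid)
            if pred is None or aln not in "+-":
                continue
            if pred.label == "second_strand":
                votes[aln] += 1
            else:
                votes["+" if aln == "-" else "-"] += 1
        if not votes:
            iso.strand_flagged = True
            out.append(iso)
            continue
        top = votes.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            iso.strand = "."
            iso.strand_flagged = True
        else:
            iso.strand = top[0][0]
        out.append(iso)
    return out
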