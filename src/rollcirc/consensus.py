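"""De novo self-correction: tandem-period detection, rolling-copy consensus
calling, the internal-repeat screen, and merging of reference-guided (RG)
and consensus-RG (cRG) isoform sets.

A rolling-circle read is a noisy tandem array of one monomer.  The period is
found from the self-similarity of shared k-mers (the dominant spacing between
repeated k-mers), the copies are segmented by successive alignment of the
first copy, and the monomer is polished by per-column majority vote across
copies.  The polished monomer, triplicated, can be re-fed to the
reference-guided detector (cRG mode) to rescue reads whose raw error rate
defeats direct alignment.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .formats import Read

_K = 9


@dataclass
class ConsensusSequence:
    read_id: str
    monomer: str
    period: int
    copy_number: float
    copy_boundaries: List[int]
    passed_screen: bool = True

    def __post_init__(self) -> None:
        if self.period < 30:
            raise ValueError("period must be >= 30")


# ---------------------------------------------------------------------------
# period detection
# ---------------------------------------------------------------------------

def _kmer_positions(seq: str, k: int = _K) -> Dict[str, List[int]]:
    pos: Dict[str, List[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        pos[seq[i : i + k]].append(i)
    return pos


def detect_period(
    read: Read | str,
    min_period: int = 30,
    min_copy: float = 1.5,
    k: int = _K,
    max_occ: int = 30,
) -> Optional[Tuple[int, float]]:
    """Dominant tandem period of a read, or ``None``.

    Spacings between consecutive occurrences of each repeated k-mer vote in a
    histogram; the strongest spacing window gives a coarse period which is
    refined by self-overlap alignment.  Returns ``(period, copy_number)``
    subject to ``period >= min_period`` and ``copy_number >= min_copy``.
    """
    seq = read.sequence if isinstance(read, Read) else read
    n = len(seq)
    if n < 2 * min_period:
        return None
    max_period = int(n / min_copy)
    votes = np.zeros(max_period + 1, dtype=np.int64)
    for positions in _kmer_positions(seq, k).values():
        if len(positions) < 2 or len(positions) > max_occ:
            continue
        for a, b in zip(positions, positions[1:]):
            d = b - a
            if min_period <= d <= max_period:
                votes[d] += 1
    if votes.sum() == 0:
        return None
    # smooth over +/-3 nt to absorb indel drift between copies
    kernel = np.ones(7, dtype=np.int64)
    smooth = np.convolve(votes, kernel, mode="same")
    d0 = int(np.argmax(smooth))
    support = int(smooth[d0])
    if support < max(8, 0.12 * d0):
        return None
    # prefer the fundamental over a harmonic: check d0/2, d0/3
    for div in (3, 2):
        cand = d0 // div
        if cand >= min_period and smooth[cand] >= 0.6 * support:
            d0 = cand
            support = int(smooth[cand])
    period = _refine_period(seq, d0)
    if period is None or period < min_period:
        return None
    copy_number = n / period
    if copy_number < min_copy:
        return None
    return period, copy_number


def _self_overlap_identity(seq: str, p: int) -> float:
    a, b = seq[: len(seq) - p], seq[p:]
    if not a:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def _refine_period(seq: str, d0: int, window: int = 8) -> Optional[int]:
    best_p, best_i = None, -1.0
    for p in range(max(2, d0 - window), d0 + window + 1):
        if p >= len(seq):
            break
        ident = _self_overlap_identity(seq, p)
        if ident > best_i:
            best_i, best_p = ident, p
    if best_p is None or best_i < 0.55:
        return None
    return best_p


# ---------------------------------------------------------------------------
# copy segmentation and consensus
# ---------------------------------------------------------------------------

def segment_copies(seq: str, period: int, slack: float = 0.25) -> List[int]:
    """Copy start boundaries (ascending, starting at 0); the final partial
    copy, if any, runs from the last boundary to the end of the read."""
    bounds = [0]
    template = seq[:period]
    w = max(8, int(slack * period))
    pos = 0
    while pos + period + period // 2 <= len(seq):
        lo = pos + period - w
        hi = min(len(seq), pos + period + w + len(template))
        res = edlib.align(template, seq[lo:hi], mode="HW", task="locations")
        if res["editDistance"] < 0 or res["editDistance"] > 0.45 * period:
            pos += period
        else:
            pos = lo + (res["locations"][0][0] or 0)
        if pos <= bounds[-1]:
            pos = bounds[-1] + period
        bounds.append(pos)
    return bounds


def call_consensus(
    read: Read | str,
    period: int,
    min_identity: float = 0.60,
) -> Optional[ConsensusSequence]:
    """Majority-vote monomer across the segmented rolling copies.

    Copies are aligned to the first full copy; each template column takes the
    majority base (ties broken by the highest summed base quality, then
    alphabetically), deletions vote as gaps, and insertion runs seen in more
    than half the copies are spliced in.  Returns ``None`` when a copy fails
    the identity check (chimeric read).
    """
    if isinstance(read, Read):
        seq, quals, rid = read.sequence, read.qualities, read.read_id
    else:
        seq, rid = read, "seq"
        quals = np.full(len(seq), 20, dtype=np.int16)
    bounds = segment_copies(seq, period)
    copies: List[Tuple[int, int]] = [
        (bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)
    ]
    tail = len(seq) - bounds[-1]
    if tail >= 0.8 * period:
        copies.append((bounds[-1], len(seq)))
    if not copies:
        return None
    t_lo, t_hi = copies[0]
    template = seq[t_lo:t_hi]
    n_copies = len(copies)

    base_votes: List[Counter] = [Counter() for _ in range(len(template))]
    qual_votes: List[Counter] = [Counter() for _ in range(len(template))]
    ins_votes: List[Counter] = [Counter() for _ in range(len(template) + 1)]
    for lo, hi in copies:
        copy = seq[lo:hi]
        res = edlib.align(copy, template, mode="NW", task="path")
        ident = 1.0 - res["editDistance"] / max(len(copy), len(template))
        if ident < min_identity:
            return None
        ti = 0  # template position
        ci = lo  # read position
        pending_ins = ""
        for num, op in _cigar_ops(res["cigar"]):
            if op in ("=", "X", "M"):
                if pending_ins:
                    ins_votes[ti][pending_ins] += 1
                    pending_ins = ""
                for _ in range(num):
                    base_votes[ti][seq[ci]] += 1
                    qual_votes[ti][seq[ci]] += int(quals[ci])
                    ti += 1
                    ci += 1
            elif op == "D":  # template base unmatched -> deletion in copy
                if pending_ins:
                    ins_votes[ti][pending_ins] += 1
                    pending_ins = ""
                for _ in range(num):
                    base_votes[ti]["-"] += 1
                    ti += 1
            elif op == "I":  # extra copy bases -> insertion vs template
                pending_ins += seq[ci : ci + num]
                ci += num
        if pending_ins:
            ins_votes[ti][pending_ins] += 1

    out: List[str] = []
    half = n_copies / 2.0
    for t in range(len(template) + 1):
        if ins_votes[t]:
            total_ins = sum(ins_votes[t].values())
            if total_ins > half:
                out.append(ins_votes[t].most_common(1)[0][0])
        if t == len(template):
            break
        votes = base_votes[t]
        if not votes:
            continue
        top = max(votes.values())
        cands = sorted(b for b, v in votes.items() if v == top)
        if len(cands) > 1:
            cands.sort(key=lambda b: (-qual_votes[t][b], b))
        best = cands[0]
        if best != "-":
            out.append(best)
    monomer = "".join(out)
    if abs(len(monomer) - period) > 0.1 * period + 5:
        return None
    return ConsensusSequence(
        read_id=rid,
        monomer=monomer,
        period=period,
        copy_number=len(seq) / period,
        copy_boundaries=bounds,
    )


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


# ---------------------------------------------------------------------------
# internal repeat screen
# ---------------------------------------------------------------------------

def screen_internal_repeats(
    cs: ConsensusSequence | str,
    score_threshold: float = 40.0,
    span_fraction: float = 0.5,
    match: int = 2,
    mismatch: int = -5,
    indel: int = -7,
) -> bool:
    """``True`` iff the monomer passes (no strong internal tandem repeat).

    For every candidate internal period the monomer is compared to itself at
    that offset; the best-scoring contiguous repeat run (match/mismatch
    weights as given; the indel weight applies when the offset comparison is
    re-anchored) is evaluated against the score threshold, and the repeat's
    genomic span against half the monomer length.
    """
    monomer = cs.monomer if isinstance(cs, ConsensusSequence) else cs
    n = len(monomer)
    if n < 4:
        return True
    arr = np.frombuffer(monomer.encode("ascii"), dtype=np.uint8)
    best_score, best_span = 0.0, 0
    for p in range(2, n // 2 + 1):
        m = arr[: n - p] == arr[p:]
        contrib = np.where(m, float(match), float(mismatch))
        # best contiguous run (Kadane via cumulative minima)
        c = np.concatenate(([0.0], np.cumsum(contrib)))
        run_best = float(np.max(c[1:] - np.minimum.accumulate(c[:-1])))
        if run_best > best_score:
            best_score = run_best
        if run_best > 0:
            # span of the repeat region ~ run length + one period
            ends = c[1:] - np.minimum.accumulate(c[:-1])
            j = int(np.argmax(ends))
            i = int(np.argmin(c[: j + 1]))
            span = (j + 1 - i) + p
            if run_best >= 0.5 * score_threshold and span > best_span:
                best_span = span
    if best_score > score_threshold:
        return False
    if best_span > span_fraction * n:
        return False
    return True


def make_pseudo_query(cs: ConsensusSequence) -> str:
    """Triplicated monomer used as the cRG query."""
    if not cs.monomer:
        raise ValueError("empty consensus monomer")
    return cs.monomer * 3


# ---------------------------------------------------------------------------
# RG / cRG merge
# ---------------------------------------------------------------------------

def merge_rg_crg(rg_isoforms: Sequence, crg_isoforms: Sequence) -> List:
    """Union of RG and cRG isoform sets.

    Isoforms identical in BSJ and exon chain merge; a read contributing via
    both routes is counted once.  Commutative and idempotent.
    """
    merged: Dict[tuple, object] = {}
    for iso in list(rg_isoforms) + list(crg_isoforms):
        key = (iso.chrom, iso.strand, tuple(iso.blocks))
        if key not in merged:
            import copy

            m = copy.deepcopy(iso)
            m.read_ids = set(iso.read_ids)
            merged[key] = m
        else:
            m = merged[key]
            m.read_ids |= set(iso.read_ids)
            if getattr(iso, "source", "RG") != getattr(m, "source", "RG"):
                m.source = "RG+cRG"
    out = list(merged.values())
    for m in out:
        m.support_reads = len(m.read_ids)
    out.sort(key=lambda i: (i.chrom, i.blocks[0][0], i.blocks[-1][1]))
    return out
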