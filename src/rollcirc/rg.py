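"""Reference-guided (RG) circRNA detection.

A rolling-circle read aligns as several collinear pieces over one locus whose
query order runs *against* the reference order — chiastic overlapping
segments.  Such reads are candidate circRNA reads (CCRs).  The boundaries of
the chiastic overlap give a rough back-splice junction (BSJ); per-read
junctions are refined by match-count realignment across the junction
context, then corrected cohort-wide by clustering, annotation snapping, and
canonical-motif (GT/AG) snapping.  Forward splice junctions (FSJs) come from
the skipped reference regions inside each rolling copy and are corrected the
same way; the full-length isoform is the per-junction majority vote across a
read's rolling copies.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .align import AlignedSegment, SegmentChain, place_junction, _kmer_codes
from .core import Annotation, Genome, revcomp, snap

MIN_CIRC_SPAN = 50
MIN_INTRON = 30
FUSION_MIN_DISTANCE = 1_000_000


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class BSJ:
    """A back-splice junction, stored genome-ordered: ``acceptor_start`` is
    the first base of the circle, ``donor_end`` its half-open end; the
    transcript strand is carried separately."""

    chrom: str
    acceptor_start: int
    donor_end: int
    strand: str  # '+', '-' or '.'
    support_reads: int = 0
    read_ids: Set[str] = field(default_factory=set)
    motif: str = "non-canonical"  # 'GT/AG' or 'non-canonical'
    provenance: str = "read-consensus"

    def __post_init__(self) -> None:
        if self.acceptor_start >= self.donor_end:
            raise ValueError("acceptor_start must be < donor_end")

    @property
    def span(self) -> int:
        return self.donor_end - self.acceptor_start

    @property
    def key(self) -> Tuple[str, int, int]:
        return (self.chrom, self.acceptor_start, self.donor_end)


@dataclass(frozen=True)
class FSJ:
    chrom: str
    donor_end: int
    acceptor_start: int
    strand: str = "."
    annotated: bool = False


@dataclass
class CCR:
    """A candidate circRNA read: its circle-locus segments (sense frame),
    potential BSJ(s) and rolling-copy structures."""

    read_id: str
    chrom: str
    aligned_strand: str  # strand the (majority of the) read aligned to
    ccr_type: str  # 'normal' | 'intra-chrom fusion' | 'inter-chrom fusion'
    segments: List[AlignedSegment]  # circle-locus copies, sense-frame order
    all_segments: List[AlignedSegment]
    bsj_pairs: List[Tuple[int, int]]  # (acceptor_start, donor_end) per pair
    potential_bsj: Tuple[int, int]
    copy_count: float
    source: str = "RG"

    def copy_blocks(self) -> List[List[Tuple[int, int]]]:
        return [list(s.blocks) for s in self.segments]


@dataclass
class CircIsoform:
    isoform_id: str
    chrom: str
    acceptor_start: int
    donor_end: int
    strand: str
    blocks: List[Tuple[int, int]]
    read_ids: Set[str] = field(default_factory=set)
    support_reads: int = 0
    circ_type: Optional[str] = None
    source: str = "RG"
    bsj_motif: str = "non-canonical"
    strand_flagged: bool = False

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("isoform needs >=1 block")
        if self.blocks[0][0] != self.acceptor_start or self.blocks[-1][1] != self.donor_end:
            raise ValueError("blocks must span [acceptor_start, donor_end)")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def bsj_key(self) -> Tuple[str, int, int]:
        return (self.chrom, self.acceptor_start, self.donor_end)

    def exon_chain(self) -> Tuple[Tuple[int, int], ...]:
        return tuple(self.blocks)


# ---------------------------------------------------------------------------
# CCR detection
# ---------------------------------------------------------------------------

def _sense_frame(segments: List[AlignedSegment], read_len: int) -> List[AlignedSegment]:
    """Flip minus-strand segments into the frame of the reverse-complemented
    read so that query and reference ascend together for every segment."""
    out = []
    for s in segments:
        if s.strand == "+":
            out.append(s)
        else:
            qb = [(read_len - qe, read_len - qs) for qs, qe in s.qblocks]
            out.append(
                AlignedSegment(
                    read_id=s.read_id, chrom=s.chrom, strand=s.strand,
                    qstart=read_len - s.qend, qend=read_len - s.qstart,
                    rstart=s.rstart, rend=s.rend,
                    blocks=list(s.blocks), qblocks=qb,
                    matches=s.matches, edits=s.edits, score=s.score,
                )
            )
    return out


def detect_ccr(
    chains: Sequence[SegmentChain],
    read_len: Optional[int] = None,
    min_span: int = MIN_CIRC_SPAN,
    fusion_min_distance: int = FUSION_MIN_DISTANCE,
) -> Optional[CCR]:
    """Recognise a candidate circRNA read from its alignment segments.

    A chiastic pair is two same-locus segments whose query order is inverted
    relative to their reference order (the later query segment re-starts at
    or before the earlier one's reference start, with overlapping spans).
    Rolling reads that separately visit two loci (different chromosomes, or
    >1 Mbp apart) in an A-B-A pattern are typed as fusion CCRs.  Linear
    reads return ``None``.
    """
    segs = [s for chain in chains for s in chain.segments]
    if len(segs) < 2:
        return None
    if read_len is None:
        read_len = max(s.qend for s in segs)
    read_id = segs[0].read_id

    # majority aligned strand; analyse in that strand's sense frame
    strand_len = Counter()
    for s in segs:
        strand_len[s.strand] += s.qlen
    aligned_strand = strand_len.most_common(1)[0][0]
    segs = [s for s in segs if s.strand == aligned_strand]
    segs = _sense_frame(segs, read_len)
    if aligned_strand == "-":
        segs.sort(key=lambda s: s.qstart)
    else:
        segs.sort(key=lambda s: s.qstart)

    # cluster segments into loci (same chrom, within fusion_min_distance)
    loci: List[dict] = []
    for s in segs:
        placed = False
        for loc in loci:
            if s.chrom == loc["chrom"] and (
                min(s.rend, loc["end"]) - max(s.rstart, loc["start"])
                > -fusion_min_distance
            ):
                loc["start"] = min(loc["start"], s.rstart)
                loc["end"] = max(loc["end"], s.rend)
                loc["segs"].append(s)
                placed = True
                break
        if not placed:
            loci.append(
                dict(chrom=s.chrom, start=s.rstart, end=s.rend, segs=[s])
            )
    loci = [l for l in loci if sum(s.qlen for s in l["segs"]) >= 50]
    if not loci:
        return None

    if len(loci) >= 2:
        ccr = _detect_fusion_ccr(
            segs, loci, read_id, aligned_strand, fusion_min_distance
        )
        if ccr is not None:
            return ccr
        # fall through: analyse the dominant locus as a normal CCR

    loc = max(loci, key=lambda l: sum(s.qlen for s in l["segs"]))
    lsegs = sorted(loc["segs"], key=lambda s: s.qstart)
    pairs: List[Tuple[int, int]] = []
    for a, b in zip(lsegs, lsegs[1:]):
        if b.rstart <= a.rstart + 10 and min(a.rend, b.rend) - max(a.rstart, b.rstart) > 0:
            acc, don = b.rstart, a.rend
            if don - acc >= min_span:
                pairs.append((acc, don))
    if not pairs:
        return None
    potential = Counter(pairs).most_common(1)[0][0]
    span = potential[1] - potential[0]
    copy_count = sum(s.qlen for s in lsegs) / span
    return CCR(
        read_id=read_id,
        chrom=loc["chrom"],
        aligned_strand=aligned_strand,
        ccr_type="normal",
        segments=lsegs,
        all_segments=segs,
        bsj_pairs=pairs,
        potential_bsj=potential,
        copy_count=copy_count,
    )


def _detect_fusion_ccr(segs, loci, read_id, aligned_strand, fusion_min_distance):
    if len(loci) > 2:
        return None  # unresolvable chimera; fusion module rejects >=3 loci
    la, lb = loci
    # require the rolling A-B-A alternation in query order
    order = []
    for s in segs:
        tag = "A" if s in la["segs"] else "B"
        if not order or order[-1][0] != tag:
            order.append([tag, 0])
        order[-1][1] += s.qlen
    pattern = "".join(t for t, _ in order)
    if len(pattern) < 3:
        return None
    if la["chrom"] == lb["chrom"]:
        gap = max(la["start"], lb["start"]) - min(la["end"], lb["end"])
        if gap <= fusion_min_distance:
            return None
        ccr_type = "intra-chrom fusion"
    else:
        ccr_type = "inter-chrom fusion"
    monomer_span = (la["end"] - la["start"]) + (lb["end"] - lb["start"])
    copy_count = sum(s.qlen for s in segs) / max(monomer_span, 1)
    return CCR(
        read_id=read_id,
        chrom=f"{la['chrom']}|{lb['chrom']}",
        aligned_strand=aligned_strand,
        ccr_type=ccr_type,
        segments=sorted(segs, key=lambda s: s.qstart),
        all_segments=segs,
        bsj_pairs=[],
        potential_bsj=(la["start"], la["end"]),
        copy_count=copy_count,
    )


# ---------------------------------------------------------------------------
# per-read junction refinement
# ---------------------------------------------------------------------------

def refine_bsj(ccr: CCR, read_seq: str, genome: Genome) -> List[Tuple[int, int]]:
    """Re-place each chiastic crossing at base resolution.

    For every consecutive copy pair the junction is re-scored over all splits
    of the intervening query bases between the donor-side and acceptor-side
    reference context (with a canonical-motif bonus), which is equivalent to
    realigning the read across the junction of a pseudo-reference built from
    the rough candidate.  Returns refined (acceptor_start, donor_end) pairs.
    """
    seq = read_seq if ccr.aligned_strand == "+" else revcomp(read_seq)
    ref = genome.chromosomes[ccr.chrom]
    refined: List[Tuple[int, int]] = []
    segs = ccr.segments
    for a, b in zip(segs, segs[1:]):
        if b.rstart > a.rstart + 10:
            continue
        q_e, g_e = a.qblocks[-1][1], a.blocks[-1][1]
        q_s, g_s = b.qblocks[0][0], b.blocks[0][0]
        # a strong motif bonus keeps noisy reads anchored on the canonical
        # back-splice dinucleotides instead of drifting with indel jitter
        d_end, a_start, _ = place_junction(
            seq, ref, q_e, g_e, q_s, g_s, motif_bonus=2.5
        )
        if d_end - a_start >= MIN_CIRC_SPAN:
            refined.append((a_start, d_end))
    return refined


# ---------------------------------------------------------------------------
# pseudo-reference
# ---------------------------------------------------------------------------

def build_pseudo_ref(
    genome: Genome,
    chrom: str,
    acceptor_start: int,
    donor_end: int,
    flank: int = 150,
) -> Tuple[str, int]:
    """Donor-side flank followed by acceptor-side flank: the sequence reads
    as the circRNA does across its BSJ.  Flanks are clipped at chromosome
    edges and at the circle span (for circles shorter than the flank, the
    read context around the junction is circle sequence, not genomic flank).
    Returns ``(sequence, seam_index)``.
    """
    span = donor_end - acceptor_start
    if span < MIN_CIRC_SPAN:
        raise ValueError(f"candidate span {span} < {MIN_CIRC_SPAN}")
    f_len = min(flank, span)
    left = genome.fetch(chrom, donor_end - f_len, donor_end)
    right = genome.fetch(chrom, acceptor_start, acceptor_start + f_len)
    return left + right, len(left)


# ---------------------------------------------------------------------------
# BSJ correction
# ---------------------------------------------------------------------------

def _motif_positions(
    ref: str, pos: int, window: int, pattern: str, before: bool
) -> List[int]:
    """Positions p within +/-window of pos where ``pattern`` sits immediately
    before p (before=True) or at p (before=False)."""
    out = []
    for p in range(pos - window, pos + window + 1):
        if before:
            if ref[p - 2 : p] == pattern:
                out.append(p)
        else:
            if ref[p : p + 2] == pattern:
                out.append(p)
    return out


def correct_bsj(
    candidates: Sequence[Tuple[int, int, str, str]],
    annotation: Optional[Annotation],
    genome: Genome,
    chrom: str,
    cluster_tol: int = 20,
    snap_window: int = 10,
) -> List[BSJ]:
    """Cluster per-read BSJ candidates and correct each cluster.

    ``candidates`` are ``(acceptor_start, donor_end, read_id,
    aligned_strand)``.  Within a cluster the corrected position is chosen by
    priority: annotated exon boundaries on both ends within ``snap_window``
    of the evidence mode, else a position pair carrying the back-splice
    motif (acceptor preceded by AG, donor followed by GT on the plus strand;
    AC/CT mirrored on minus), else the evidence mode itself.  Ties break
    toward annotation, then the modal read position, then leftmost.
    """
    if not candidates:
        return []
    ref = genome.chromosomes[chrom]
    cands = sorted(candidates, key=lambda c: (c[0], c[1]))
    clusters: List[List[Tuple[int, int, str, str]]] = []
    for c in cands:
        placed = False
        for cl in clusters:
            a0, d0 = cl[0][0], cl[0][1]
            if abs(c[0] - a0) <= cluster_tol and abs(c[1] - d0) <= cluster_tol:
                cl.append(c)
                placed = True
                break
        if not placed:
            clusters.append([c])

    # two distinct circRNAs can have BSJs closer than cluster_tol (e.g. an
    # annotated and a novel acceptor ~15 nt apart): sub-split any cluster
    # whose well-supported exact positions snap onto different junctions
    clusters = _subsplit_clusters(clusters, annotation, genome, chrom,
                                  snap_window)

    out: List[BSJ] = []
    starts = annotation.exon_starts(chrom) if annotation else set()
    ends = annotation.exon_ends(chrom) if annotation else set()
    for cl in clusters:
        pair_counts = Counter((a, d) for a, d, _, _ in cl)
        top = max(pair_counts.values())
        mode_a, mode_d = min(p for p, v in pair_counts.items() if v == top)
        read_ids = {r for _, _, r, _ in cl}
        strand_votes = Counter(s for _, _, _, s in cl)

        ann_a = snap(mode_a, [s for s in starts if abs(s - mode_a) <= snap_window],
                     snap_window)
        ann_d = snap(mode_d, [e for e in ends if abs(e - mode_d) <= snap_window],
                     snap_window)

        best = None  # (rank, dist, a, d, strand, provenance, motif)
        if ann_a is not None and ann_d is not None and ann_d - ann_a >= MIN_CIRC_SPAN:
            strand = _annotation_strand(annotation, chrom, ann_a, ann_d)
            motif = _bsj_motif(ref, ann_a, ann_d, strand)
            best = (0, abs(ann_a - mode_a) + abs(ann_d - mode_d),
                    ann_a, ann_d, strand, "annotation-snapped", motif)
        if best is None:
            # among motif-bearing positions, prefer the pair most read
            # candidates agree on exactly (junction refinement pushes reads
            # onto the true motif), then proximity to the mode
            for strand, mot_a, mot_d in (("+", "AG", "GT"), ("-", "AC", "CT")):
                a_opts = _motif_positions(ref, mode_a, snap_window, mot_a, True)
                d_opts = _motif_positions(ref, mode_d, snap_window, mot_d, False)
                if ann_a is not None:
                    a_opts = [ann_a] + a_opts
                if ann_d is not None:
                    d_opts = [ann_d] + d_opts
                for a in a_opts:
                    for d in d_opts:
                        if d - a < MIN_CIRC_SPAN:
                            continue
                        votes = pair_counts.get((a, d), 0)
                        dist = abs(a - mode_a) + abs(d - mode_d)
                        cand = (1, -votes, dist, a, d, strand,
                                "motif-snapped", "GT/AG")
                        if best is None or cand[:3] < best[:3] or (
                            cand[:3] == best[:3] and (a, d) < (best[3], best[4])
                        ):
                            best = cand
            if best is not None:
                best = (best[0], best[2], best[3], best[4], best[5],
                        best[6], best[7])
        if best is None:
            strand = strand_votes.most_common(1)[0][0]
            motif = _bsj_motif(ref, mode_a, mode_d, None)
            strand_final = strand if motif == "non-canonical" else (
                "+" if ref[mode_a - 2 : mode_a] == "AG" else "-"
            )
            best = (2, 0, mode_a, mode_d, strand_final, "read-consensus", motif)

        _, _, a, d, strand, prov, motif = best
        out.append(
            BSJ(
                chrom=chrom, acceptor_start=a, donor_end=d,
                strand=strand or ".", support_reads=len(read_ids),
                read_ids=read_ids, motif=motif, provenance=prov,
            )
        )
    # clusters that corrected onto the same junction merge
    merged: Dict[Tuple[str, int, int], BSJ] = {}
    for b in out:
        prev = merged.get(b.key)
        if prev is None:
            merged[b.key] = b
        else:
            prev.read_ids |= b.read_ids
            prev.support_reads = len(prev.read_ids)
            if prev.provenance == "read-consensus":
                prev.provenance = b.provenance
                prev.strand = b.strand
                prev.motif = b.motif
    return list(merged.values())


def _subsplit_clusters(
    clusters, annotation, genome, chrom, snap_window
):
    """Split clusters containing several distinct, well-supported junctions.

    Exact candidate positions holding at least two reads are snapped
    (annotation first, then motif); positions that snap onto different
    corrected junctions define sub-clusters, and every member joins the
    nearest representative.  Jittered candidates all snap onto the same
    junction and leave the cluster intact.
    """
    ref = genome.chromosomes[chrom]
    starts = annotation.exon_starts(chrom) if annotation else set()
    ends = annotation.exon_ends(chrom) if annotation else set()

    def snap_pair(a, d):
        sa = snap(a, [s for s in starts if abs(s - a) <= snap_window], snap_window)
        sd = snap(d, [e for e in ends if abs(e - d) <= snap_window], snap_window)
        if sa is not None and sd is not None:
            return (sa, sd)
        best = None
        for mot_a, mot_d in (("AG", "GT"), ("AC", "CT")):
            a_opts = _motif_positions(ref, a, snap_window, mot_a, True)
            d_opts = _motif_positions(ref, d, snap_window, mot_d, False)
            for aa in ([sa] if sa is not None else a_opts):
                for dd in ([sd] if sd is not None else d_opts):
                    dist = abs(aa - a) + abs(dd - d)
                    if best is None or dist < best[0]:
                        best = (dist, (aa, dd))
        return best[1] if best else (a, d)

    out = []
    for cl in clusters:
        pair_counts = Counter((a, d) for a, d, _, _ in cl)
        reps = [p for p, v in pair_counts.items() if v >= 2]
        if not reps:
            reps = [max(pair_counts, key=pair_counts.get)]
        snapped = {}
        for p in reps:
            snapped.setdefault(snap_pair(*p), []).append(p)
        if len(snapped) <= 1:
            out.append(cl)
            continue
        rep_list = [min(v) for v in snapped.values()]
        groups = {r: [] for r in rep_list}
        for c in cl:
            nearest = min(
                rep_list, key=lambda r: abs(r[0] - c[0]) + abs(r[1] - c[1])
            )
            groups[nearest].append(c)
        out.extend(g for g in groups.values() if g)
    return out


def _annotation_strand(annotation, chrom, a, d) -> Optional[str]:
    genes = annotation.genes_overlapping(chrom, a, d) if annotation else []
    strands = {g.strand for g in genes}
    return strands.pop() if len(strands) == 1 else None


def _bsj_motif(ref: str, a: int, d: int, strand: Optional[str]) -> str:
    plus = ref[a - 2 : a] == "AG" and ref[d : d + 2] == "GT"
    minus = ref[a - 2 : a] == "AC" and ref[d : d + 2] == "CT"
    if strand == "+":
        return "GT/AG" if plus else "non-canonical"
    if strand == "-":
        return "GT/AG" if minus else "non-canonical"
    return "GT/AG" if (plus or minus) else "non-canonical"


# ---------------------------------------------------------------------------
# FSJ detection and correction
# ---------------------------------------------------------------------------

def detect_fsj(ccr: CCR, min_intron: int = MIN_INTRON) -> List[Tuple[int, int]]:
    """All (donor_end, acceptor_start) forward-splice gaps in the CCR's
    rolling copies (duplicates across copies retained for voting)."""
    acc, don = ccr.potential_bsj
    out = []
    for blocks in ccr.copy_blocks():
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if s2 - e1 >= min_intron and e1 > acc - 50 and s2 < don + 50:
                out.append((e1, s2))
    return out


def correct_fsj(
    fsj_pairs: Sequence[Tuple[int, int]],
    annotation: Optional[Annotation],
    chrom: str,
    snap_window: int = 10,
) -> Dict[Tuple[int, int], FSJ]:
    """Correct a cohort of FSJs observed at one BSJ.

    Each junction snaps to annotated splice sites within the window; junctions
    without annotation snap to the cohort's modal junction; the rest stay
    as observed with ``annotated=False``.  Annotation is never overridden by
    the cohort vote.
    """
    starts = annotation.exon_starts(chrom) if annotation else set()
    ends = annotation.exon_ends(chrom) if annotation else set()
    counts = Counter(fsj_pairs)

    # first pass: annotation snapping
    snapped: Dict[Tuple[int, int], Tuple[int, int, bool]] = {}
    cohort_weight: Counter = Counter()
    for (d, a), n in counts.items():
        sd = snap(d, [e for e in ends if abs(e - d) <= snap_window], snap_window)
        sa = snap(a, [s for s in starts if abs(s - a) <= snap_window], snap_window)
        if sd is not None and sa is not None:
            snapped[(d, a)] = (sd, sa, True)
            cohort_weight[(sd, sa, True)] += n
        else:
            cohort_weight[(d, a, False)] += n

    out: Dict[Tuple[int, int], FSJ] = {}
    for (d, a), n in counts.items():
        if (d, a) in snapped:
            sd, sa, _ = snapped[(d, a)]
            out[(d, a)] = FSJ(chrom, sd, sa, annotated=True)
            continue
        # cohort mode within the window (annotation-snapped entries included)
        best = None
        for (cd, ca, ann), w in cohort_weight.items():
            if abs(cd - d) <= snap_window and abs(ca - a) <= snap_window:
                cand = (w, ann, -(abs(cd - d) + abs(ca - a)), -cd, -ca)
                if best is None or cand > best[0]:
                    best = (cand, (cd, ca, ann))
        if best is not None and best[1][:2] != (d, a):
            cd, ca, ann = best[1]
            out[(d, a)] = FSJ(chrom, cd, ca, annotated=ann)
        else:
            out[(d, a)] = FSJ(chrom, d, a, annotated=False)
    return out


# ---------------------------------------------------------------------------
# isoform construction
# ---------------------------------------------------------------------------

def build_isoform(
    ccr: CCR,
    bsj: BSJ,
    fsj_map: Dict[Tuple[int, int], FSJ],
    isoform_id: str = "iso",
    min_intron: int = MIN_INTRON,
    junction_match_tol: int = 10,
) -> Optional[CircIsoform]:
    """Majority-vote exon chain across the read's rolling copies.

    Every corrected junction is voted on by the copies that fully contain
    its position (partial terminal copies only vote on junctions inside
    their extent); junctions present in a strict majority of votable copies
    become introns of the isoform.
    """
    acc, don = bsj.acceptor_start, bsj.donor_end
    copies = ccr.copy_blocks()
    if not copies:
        return None

    junctions: Set[Tuple[int, int]] = set()
    copy_juncs: List[Set[Tuple[int, int]]] = []
    for blocks in copies:
        js = set()
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if s2 - e1 >= min_intron:
                fsj = fsj_map.get((e1, s2))
                if fsj is None:
                    continue
                j = (fsj.donor_end, fsj.acceptor_start)
                if acc < j[0] and j[1] < don:
                    js.add(j)
                    junctions.add(j)
        copy_juncs.append(js)

    accepted: List[Tuple[int, int]] = []
    for j in sorted(junctions):
        votable = present = 0
        for blocks, js in zip(copies, copy_juncs):
            lo = max(blocks[0][0], acc)
            hi = min(blocks[-1][1], don)
            if lo <= j[0] - 2 and hi >= j[1] + 2:
                votable += 1
                if j in js or any(
                    abs(jj[0] - j[0]) <= junction_match_tol
                    and abs(jj[1] - j[1]) <= junction_match_tol
                    for jj in js
                ):
                    present += 1
        if votable and present * 2 > votable:
            accepted.append(j)

    blocks: List[Tuple[int, int]] = []
    cur = acc
    for d, a in sorted(accepted):
        if d <= cur or a >= don:
            continue
        blocks.append((cur, d))
        cur = a
    blocks.append((cur, don))
    blocks = [(s, e) for s, e in blocks if e > s]
    if not blocks:
        return None
    return CircIsoform(
        isoform_id=isoform_id,
        chrom=bsj.chrom,
        acceptor_start=acc,
        donor_end=don,
        strand=bsj.strand,
        blocks=blocks,
        read_ids={ccr.read_id},
        support_reads=1,
        source=ccr.source,
        bsj_motif=bsj.motif,
    )


# ---------------------------------------------------------------------------
# tandem-repeat genome filter
# ---------------------------------------------------------------------------

def tandem_genome_filter(
    isoform: CircIsoform,
    genome: Genome,
    copy_threshold: float = 1.2,
    min_period: int = 30,
    min_coverage: float = 0.8,
    k: int = 11,
) -> bool:
    """``True`` = keep.  Drops isoforms whose genomic span is itself a tandem
    array (period >= ``min_period``, copy number >= ``copy_threshold``,
    covering >= ``min_coverage`` of the span): their rolling-read signature
    can arise from misalignment against the genomic repeat rather than from
    a circular template.
    """
    span = genome.fetch(isoform.chrom, isoform.acceptor_start, isoform.donor_end)
    n = len(span)
    if n < 2 * min_period:
        return True
    codes, valid = _kmer_codes(span, k)
    pos_by_code: Dict[int, int] = {}
    votes: Counter = Counter()
    for i in range(len(codes)):
        if not valid[i]:
            continue
        c = int(codes[i])
        if c in pos_by_code:
            d = i - pos_by_code[c]
            if min_period <= d <= n - min_period:
                votes[d] += 1
        pos_by_code[c] = i
    arr = np.frombuffer(span.encode("ascii"), dtype=np.uint8)
    for d, v in votes.most_common(5):
        if v < 5:
            break
        m = arr[: n - d] == arr[d:]
        # longest run with >=80% identity, greedy scan
        best = run = miss = 0
        for x in m:
            if x:
                run += 1
                miss = 0
            elif miss < max(2, run // 10):
                miss += 1
                run += 1
            else:
                best = max(best, run)
                run = miss = 0
        best = max(best, run)
        covered = best + d
        if covered / d >= copy_threshold and covered >= min_coverage * n:
            return False
    return True
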