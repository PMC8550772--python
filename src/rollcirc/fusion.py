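"""Fusion circRNA (f-circRNA) detection.

An f-circRNA joins two distant genomic loci — different chromosomes, or more
than 1 Mbp apart on the same chromosome — into one circle.  Its rolling
reads visit the two loci alternately (A-B-A-B in query order), exposing two
junctions: J1 joining the end of the A monomer half to the start of the B
half, and J2 joining the end of B back to the start of A.  One of the two is
the genomic fusion point and the other the back-splice, but reads alone
cannot tell which; both are reported symmetrically.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .core import Annotation, Genome, snap
from .rg import CCR, FUSION_MIN_DISTANCE

Junction = Tuple[str, int, str, int]  # (chromA, posA, chromB, posB)


@dataclass
class FusionCircRNA:
    fusion_id: str
    chrom_a: str
    blocks_a: List[Tuple[int, int]]
    strand_a: str
    chrom_b: str
    blocks_b: List[Tuple[int, int]]
    strand_b: str
    junction_ab: Tuple[int, int]  # (end of A, start of B)
    junction_ba: Tuple[int, int]  # (end of B, start of A)
    read_ids: Set[str] = field(default_factory=set)
    support_reads: int = 0
    ratio: float = 0.0
    high_quality: bool = False
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.chrom_a == self.chrom_b:
            gap = max(self.blocks_a[0][0], self.blocks_b[0][0]) - min(
                self.blocks_a[-1][1], self.blocks_b[-1][1]
            )
            if gap <= FUSION_MIN_DISTANCE:
                raise ValueError(
                    "same-chromosome fusion loci must be >1 Mbp apart"
                )

    @property
    def junction_pair_key(self) -> Tuple:
        return (
            self.chrom_a, self.junction_ab, self.chrom_b, self.junction_ba
        )

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks_a) + sum(
            e - s for s, e in self.blocks_b
        )


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_fcirc(
    ccr: CCR,
    fusion_min_distance: int = FUSION_MIN_DISTANCE,
) -> Optional[FusionCircRNA]:
    """Extract an f-circRNA candidate from a fusion-typed CCR.

    Segments are grouped into two locus clusters; the rolling A-B-A pattern
    in query order yields the two junctions.  CCRs resolving to three or
    more loci are rejected as unresolvable chimeras.
    """
    if ccr.ccr_type not in ("intra-chrom fusion", "inter-chrom fusion"):
        return None
    segs = sorted(ccr.segments, key=lambda s: s.qstart)
    clusters: List[dict] = []
    for s in segs:
        placed = False
        for cl in clusters:
            if s.chrom == cl["chrom"] and (
                min(s.rend, cl["end"]) - max(s.rstart, cl["start"])
                > -fusion_min_distance
            ):
                cl["start"] = min(cl["start"], s.rstart)
                cl["end"] = max(cl["end"], s.rend)
                cl["segs"].append(s)
                placed = True
                break
        if not placed:
            clusters.append(dict(chrom=s.chrom, start=s.rstart, end=s.rend,
                                 segs=[s]))
    if len(clusters) != 2:
        return None
    ca, cb = clusters
    # query order must alternate A-B-A... with at least one return to A
    tags = []
    for s in segs:
        t = "A" if s in ca["segs"] else "B"
        if not tags or tags[-1] != t:
            tags.append(t)
    if len(tags) < 3:
        return None

    blocks_a = _merge_blocks([b for s in ca["segs"] for b in s.blocks])
    blocks_b = _merge_blocks([b for s in cb["segs"] for b in s.blocks])
    # junctions from query-consecutive segment transitions
    ab_votes: Counter = Counter()
    ba_votes: Counter = Counter()
    for s1, s2 in zip(segs, segs[1:]):
        t1 = "A" if s1 in ca["segs"] else "B"
        t2 = "A" if s2 in ca["segs"] else "B"
        if t1 == "A" and t2 == "B":
            ab_votes[(s1.rend, s2.rstart)] += 1
        elif t1 == "B" and t2 == "A":
            ba_votes[(s1.rend, s2.rstart)] += 1
    if not ab_votes or not ba_votes:
        return None
    j_ab = ab_votes.most_common(1)[0][0]
    j_ba = ba_votes.most_common(1)[0][0]
    strand = ccr.aligned_strand
    cand = FusionCircRNA(
        fusion_id=f"fcirc_{ccr.read_id}",
        chrom_a=ca["chrom"], blocks_a=blocks_a, strand_a=strand,
        chrom_b=cb["chrom"], blocks_b=blocks_b, strand_b=strand,
        junction_ab=j_ab, junction_ba=j_ba,
        read_ids={ccr.read_id}, support_reads=1,
    )
    return _canonicalize(cand)


def _canonicalize(c: FusionCircRNA) -> FusionCircRNA:
    """Order the loci by genomic position so the same fusion always reports
    the same A/B assignment regardless of which locus a read enters first."""
    if (c.chrom_a, c.blocks_a[0][0]) <= (c.chrom_b, c.blocks_b[0][0]):
        return c
    return FusionCircRNA(
        fusion_id=c.fusion_id,
        chrom_a=c.chrom_b, blocks_a=c.blocks_b, strand_a=c.strand_b,
        chrom_b=c.chrom_a, blocks_b=c.blocks_a, strand_b=c.strand_a,
        junction_ab=c.junction_ba, junction_ba=c.junction_ab,
        read_ids=c.read_ids, support_reads=c.support_reads,
    )


def refine_fcirc_junctions(
    cand: FusionCircRNA,
    ccr: CCR,
    sense_seq: str,
    genome: Genome,
) -> FusionCircRNA:
    """Re-place both fusion junctions at base resolution.

    Each locus transition in the read is re-scored over all splits of the
    intervening query bases between the two loci's reference contexts (the
    two-reference form of the splice-junction placement used in RG mode),
    with a bonus for the canonical splice motif across the fusion.
    """
    from .align import place_junction

    segs = sorted(ccr.segments, key=lambda s: s.qstart)
    ab_votes: Counter = Counter()
    ba_votes: Counter = Counter()
    for s1, s2 in zip(segs, segs[1:]):
        if s1.chrom == s2.chrom and abs(s2.rstart - s1.rend) < FUSION_MIN_DISTANCE:
            continue
        ref_l = genome.chromosomes[s1.chrom]
        ref_r = genome.chromosomes[s2.chrom]
        d, a, _ = place_junction(
            sense_seq, ref_l,
            s1.qblocks[-1][1], s1.blocks[-1][1],
            s2.qblocks[0][0], s2.blocks[0][0],
            ref_right=ref_r,
        )
        in_a = s1.chrom == cand.chrom_a and any(
            bs - 50 <= s1.rstart <= be + 50 for bs, be in cand.blocks_a
        )
        if in_a:
            ab_votes[(d, a)] += 1
        else:
            ba_votes[(d, a)] += 1
    if ab_votes:
        cand.junction_ab = ab_votes.most_common(1)[0][0]
    if ba_votes:
        cand.junction_ba = ba_votes.most_common(1)[0][0]
    # pin outer block edges to the refined junctions
    cand.blocks_a = _pin_edges(
        cand.blocks_a, cand.junction_ba[1], cand.junction_ab[0]
    )
    cand.blocks_b = _pin_edges(
        cand.blocks_b, cand.junction_ab[1], cand.junction_ba[0]
    )
    return cand


def _pin_edges(
    blocks: List[Tuple[int, int]], start: int, end: int
) -> List[Tuple[int, int]]:
    blocks = sorted(blocks)
    if abs(blocks[0][0] - start) <= 40:
        blocks[0] = (start, blocks[0][1])
    if abs(blocks[-1][1] - end) <= 40:
        blocks[-1] = (blocks[-1][0], end)
    return [(s, e) for s, e in blocks if e > s]


def _merge_blocks(blocks: List[Tuple[int, int]], tol: int = 10) -> List[Tuple[int, int]]:
    blocks = sorted(blocks)
    out: List[List[int]] = []
    for s, e in blocks:
        if out and s <= out[-1][1] + tol:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


# ---------------------------------------------------------------------------
# junction correction and merging
# ---------------------------------------------------------------------------

def correct_fusion_junctions(
    candidates: Sequence[FusionCircRNA],
    annotation: Optional[Annotation],
    genome: Genome,
    cluster_tol: int = 20,
    snap_window: int = 10,
) -> List[FusionCircRNA]:
    """Cluster per-read f-circ candidates on their junction pair and correct
    each cluster's junctions by annotation snapping, else the cohort mode.

    Isoforms with the same corrected junction pair but different block
    structures are kept separate; singletons without annotation support are
    flagged low-confidence.
    """
    # snap per-read junctions to annotated exon boundaries first so that
    # read-level jitter does not fragment the clusters
    for c in candidates:
        c.junction_ab, _ = _snap_junction(
            c.junction_ab, c.chrom_a, c.chrom_b, annotation, snap_window,
            end_first=True,
        )
        c.junction_ba, _ = _snap_junction(
            c.junction_ba, c.chrom_b, c.chrom_a, annotation, snap_window,
            end_first=True,
        )
    clusters: List[List[FusionCircRNA]] = []
    for c in sorted(
        candidates,
        key=lambda f: (f.chrom_a, f.junction_ab, f.chrom_b, f.junction_ba),
    ):
        placed = False
        for cl in clusters:
            r = cl[0]
            if (
                r.chrom_a == c.chrom_a
                and r.chrom_b == c.chrom_b
                and all(
                    abs(x - y) <= cluster_tol
                    for x, y in zip(
                        r.junction_ab + r.junction_ba,
                        c.junction_ab + c.junction_ba,
                    )
                )
            ):
                cl.append(c)
                placed = True
                break
        if not placed:
            clusters.append([c])

    out: List[FusionCircRNA] = []
    for fi, cl in enumerate(clusters):
        ab_mode = Counter(c.junction_ab for c in cl).most_common(1)[0][0]
        ba_mode = Counter(c.junction_ba for c in cl).most_common(1)[0][0]
        chrom_a, chrom_b = cl[0].chrom_a, cl[0].chrom_b
        ab, ann_ab = _snap_junction(ab_mode, chrom_a, chrom_b, annotation,
                                    snap_window, end_first=True)
        ba, ann_ba = _snap_junction(ba_mode, chrom_b, chrom_a, annotation,
                                    snap_window, end_first=True)
        # group by exon-chain structure (annotation-snapped internal
        # junctions) within the junction-pair cluster; internal junctions
        # that are neither annotated nor seen in a majority of members are
        # alignment noise and get merged away
        snapped_a = [
            _snap_blocks(c.blocks_a, chrom_a, annotation, snap_window,
                         ba[1], ab[0])
            for c in cl
        ]
        snapped_b = [
            _snap_blocks(c.blocks_b, chrom_b, annotation, snap_window,
                         ab[1], ba[0])
            for c in cl
        ]
        for which, snapped, chrom in (("a", snapped_a, chrom_a),
                                      ("b", snapped_b, chrom_b)):
            votes: Counter = Counter()
            for blocks in snapped:
                for j in _internal_junctions(blocks):
                    votes[j] += 1
            ends = annotation.exon_ends(chrom) if annotation else set()
            starts = annotation.exon_starts(chrom) if annotation else set()
            half = len(cl) / 2.0
            keep = {
                j for j, v in votes.items()
                if v > half or (j[0] in ends and j[1] in starts)
            }
            for i, blocks in enumerate(snapped):
                snapped[i] = _merge_unvoted(blocks, keep)
        by_struct: Dict[Tuple, List[FusionCircRNA]] = {}
        for c, ba_blocks, bb_blocks in zip(cl, snapped_a, snapped_b):
            key = (tuple(ba_blocks), tuple(bb_blocks))
            by_struct.setdefault(key, []).append(c)
        for si, (struct, members) in enumerate(sorted(by_struct.items())):
            reads = set().union(*(m.read_ids for m in members))
            rep = members[0]
            out.append(
                FusionCircRNA(
                    fusion_id=f"fcirc{fi + 1:03d}.{si + 1}",
                    chrom_a=chrom_a, blocks_a=list(struct[0]),
                    strand_a=rep.strand_a,
                    chrom_b=chrom_b, blocks_b=list(struct[1]),
                    strand_b=rep.strand_b,
                    junction_ab=ab, junction_ba=ba,
                    read_ids=reads, support_reads=len(reads),
                    low_confidence=(
                        len(reads) == 1 and not (ann_ab and ann_ba)
                    ),
                )
            )
    return out


def _internal_junctions(blocks: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    return [
        (blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1)
    ]


def _merge_unvoted(
    blocks: List[Tuple[int, int]], keep: Set[Tuple[int, int]]
) -> List[Tuple[int, int]]:
    out = [list(blocks[0])]
    for i in range(1, len(blocks)):
        j = (blocks[i - 1][1], blocks[i][0])
        if j in keep:
            out.append(list(blocks[i]))
        else:
            out[-1][1] = blocks[i][1]
    return [(s, e) for s, e in out]


def _snap_blocks(
    blocks: Sequence[Tuple[int, int]],
    chrom: str,
    annotation: Optional[Annotation],
    window: int,
    outer_start: int,
    outer_end: int,
) -> List[Tuple[int, int]]:
    """Pin outer edges to the corrected junctions; snap internal edges to
    annotated splice sites where possible.

    Internal splice edges carry more alignment jitter than the corrected
    junctions (no cohort vote has touched them yet), so they snap within a
    wider window."""
    starts = annotation.exon_starts(chrom) if annotation else set()
    ends = annotation.exon_ends(chrom) if annotation else set()
    internal = max(25, window)
    out = []
    blocks = sorted(blocks)
    for i, (s, e) in enumerate(blocks):
        if i == 0 and abs(s - outer_start) <= 40:
            s = outer_start
        else:
            sn = snap(s, [x for x in starts if abs(x - s) <= internal], internal)
            s = sn if sn is not None else s
        if i == len(blocks) - 1 and abs(e - outer_end) <= 40:
            e = outer_end
        else:
            en = snap(e, [x for x in ends if abs(x - e) <= internal], internal)
            e = en if en is not None else e
        if e > s:
            out.append((s, e))
    return out


def _snap_junction(
    junction: Tuple[int, int],
    chrom_from: str,
    chrom_to: str,
    annotation: Optional[Annotation],
    window: int,
    end_first: bool,
) -> Tuple[Tuple[int, int], bool]:
    """Snap (end-of-from-locus, start-of-to-locus) to annotated exon
    boundaries within the window; returns (junction, fully_annotated)."""
    if annotation is None:
        return junction, False
    end_pos, start_pos = junction
    se = snap(
        end_pos,
        [e for e in annotation.exon_ends(chrom_from) if abs(e - end_pos) <= window],
        window,
    )
    ss = snap(
        start_pos,
        [s for s in annotation.exon_starts(chrom_to) if abs(s - start_pos) <= window],
        window,
    )
    return (
        (se if se is not None else end_pos, ss if ss is not None else start_pos),
        se is not None and ss is not None,
    )


def quantify_fcirc(
    isoforms: Sequence[FusionCircRNA],
    high_quality_min_reads: int = 5,
) -> List[FusionCircRNA]:
    """Transcript ratios among f-circ isoforms sharing a junction pair."""
    totals: Dict[Tuple, int] = {}
    for iso in isoforms:
        k = iso.junction_pair_key
        totals[k] = totals.get(k, 0) + iso.support_reads
    for iso in isoforms:
        iso.ratio = iso.support_reads / totals[iso.junction_pair_key]
        iso.high_quality = iso.support_reads >= high_quality_min_reads
    return list(isoforms)
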