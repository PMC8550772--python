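"""Filtration, classification, alternative-splicing calls, quantification.

Three independent read-evidence filters remove artifact circRNAs:

* **unsplicing filter** — a genuine back-splice should account for a
  reasonable share of the reads informative at its locus; loci where back-
  spliced reads are <10% of (back-spliced + linear boundary-spanning) reads
  are linear-residual artifacts;
* **junction fidelity** — every junction (BSJ and each FSJ) must be
  supported edit-free within +/-4 bases by strictly more than half of the
  isoform's reads;
* **repeat proximity** — a BSJ whose *both* ends lie within 30 bp of a
  repeat element is discarded (alignment around repeats is untrustworthy).

Kept circRNAs are assigned one of seven types, pairwise-compared for
internal AS events (ES/A3SS/A5SS/IR), and quantified: an isoform's count is
its full-length read support, a BSJ's count the sum over its isoforms, and
the transcript ratio the isoform's share of its BSJ count.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .core import Annotation, Gene
from .rg import BSJ, CircIsoform

CIRC_TYPES = (
    "read_through", "exonic", "intronic", "nss", "novel_utr",
    "antisense", "intergenic",
)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline in one place."""

    min_qscore: float = 7.0
    pseudo_flank: int = 150
    cluster_tol: int = 20
    snap_window: int = 10
    min_copy_crg: float = 1.5
    min_period: int = 30
    genome_tandem_copy: float = 1.2
    repeat_screen_score: float = 40.0
    unsplicing_min: float = 0.1
    unsplicing_mode: str = "locus-share"  # or 'motif-share'
    junction_fidelity_bp: int = 4
    junction_fidelity_fraction: float = 0.5
    repeat_proximity_bp: int = 30
    fusion_min_distance: int = 1_000_000
    high_quality_min_reads: int = 5
    train_fraction: float = 0.75

    def __post_init__(self) -> None:
        for name in (
            "min_qscore", "pseudo_flank", "cluster_tol", "snap_window",
            "min_copy_crg", "min_period", "genome_tandem_copy",
            "repeat_screen_score", "unsplicing_min", "junction_fidelity_bp",
            "repeat_proximity_bp", "fusion_min_distance",
            "high_quality_min_reads",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("junction_fidelity_fraction", "train_fraction",
                     "unsplicing_min"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass(frozen=True)
class ASEvent:
    event_type: str  # 'ES' | 'A3SS' | 'A5SS' | 'IR'
    bsj_key: Tuple[str, int, int]
    region: Tuple[int, int]  # variable region, 0-based half-open
    inclusion_id: str
    exclusion_id: str
    delta_length: int


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def unsplicing_filter(
    n_backsplice: int,
    n_linear_spanning: int,
    min_ratio: float = 0.1,
) -> bool:
    """``True`` = keep.  ratio = BS / (BS + linear); drop strictly below
    ``min_ratio`` (a locus dominated by linear reads crossing the BSJ
    boundaries is a linear-residual artifact)."""
    total = n_backsplice + n_linear_spanning
    if total == 0:
        return False
    return n_backsplice / total >= min_ratio


def junction_fidelity_filter(
    per_junction_flags: Dict[object, Sequence[bool]],
    min_fraction: float = 0.5,
) -> bool:
    """``True`` = keep iff for *every* junction strictly more than
    ``min_fraction`` of its supporting reads are edit-free within the
    fidelity window.  ``per_junction_flags`` maps a junction key to one
    boolean per supporting read."""
    for flags in per_junction_flags.values():
        flags = list(flags)
        if not flags:
            return False
        if sum(flags) <= min_fraction * len(flags):
            return False
    return True


def repeat_proximity_filter(
    bsj: BSJ | Tuple[str, int, int],
    repeat_track: Optional[Sequence[Tuple[str, int, int]]],
    proximity_bp: int = 30,
) -> bool:
    """``True`` = keep.  Drop iff BOTH BSJ ends are within ``proximity_bp``
    (inclusive) of — or inside — a repeat interval."""
    if repeat_track is None:
        return True
    if isinstance(bsj, BSJ):
        chrom, a, d = bsj.chrom, bsj.acceptor_start, bsj.donor_end
    else:
        chrom, a, d = bsj

    def near(pos: int) -> bool:
        return any(
            c == chrom and s - proximity_bp <= pos <= e + proximity_bp
            for c, s, e in repeat_track
        )

    return not (near(a) and near(d))


# ---------------------------------------------------------------------------
# seven-type classification
# ---------------------------------------------------------------------------

def classify_circ_type(
    isoform: CircIsoform, annotation: Annotation, motif_ok: bool = True
) -> str:
    """Assign one of the seven circRNA types.

    Decision ladder: read-through (spans two same-strand genes) > exonic
    (both BSJ ends at annotated exon boundaries of one strand-concordant
    gene) > intronic (inside a single intron, strand-concordant) > NSS
    (inside a gene, strand-concordant, >=1 novel boundary) > novel UTR
    (extends past the terminal exon of an overlapped gene) > antisense
    (gene overlap on the opposite strand only) > intergenic.
    """
    chrom = isoform.chrom
    a, d = isoform.acceptor_start, isoform.donor_end
    genes = annotation.genes_overlapping(chrom, a, d)
    if not genes:
        return "intergenic"
    same = [g for g in genes if isoform.strand not in "+-" or g.strand == isoform.strand]
    touching = [g for g in same if g.start < d and g.end > a]

    # (1) read-through: BSJ ends fall in two distinct same-strand genes
    start_genes = {g.gene_id for g in same if g.start <= a < g.end}
    end_genes = {g.gene_id for g in same if g.start < d <= g.end}
    if start_genes and end_genes and not (start_genes & end_genes):
        return "read_through"

    starts = annotation.exon_starts(chrom)
    ends = annotation.exon_ends(chrom)
    a_annot = a in starts
    d_annot = d in ends
    for g in touching:
        if g.start <= a and d <= g.end:
            if a_annot and d_annot:
                return "exonic"
    # (3) intronic
    for g in touching:
        for t in g.transcripts:
            for is_, ie in t.introns():
                if is_ <= a and d <= ie:
                    return "intronic"
    # (4) NSS: within a strand-concordant gene, unannotated boundary
    for g in touching:
        if g.start <= a and d <= g.end:
            return "nss"
    # (5) novel UTR: overlaps a same-strand gene but extends past its ends
    if touching:
        return "novel_utr"
    # (6) antisense: only opposite-strand gene overlap
    return "antisense"


# ---------------------------------------------------------------------------
# alternative-splicing events
# ---------------------------------------------------------------------------

def _introns(blocks: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    return [
        (blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1)
    ]


def detect_as_events(
    isoforms: Sequence[CircIsoform],
) -> List[ASEvent]:
    """Pairwise internal AS events among isoforms sharing a BSJ.

    ES — an internal exon of one isoform absent from the other, flanking
    junctions shared; A3SS/A5SS — one shared intron boundary, the other
    shifted (3'/5' assigned on the transcript strand); IR — an intron of one
    isoform fully exonic in the other with identical outer block edges.
    Events are deduplicated by (type, coordinates) across pairs.
    """
    events: Dict[Tuple, ASEvent] = {}
    by_bsj: Dict[Tuple, List[CircIsoform]] = {}
    for iso in isoforms:
        by_bsj.setdefault(iso.bsj_key, []).append(iso)
    for key, group in by_bsj.items():
        if len(group) < 2:
            continue
        for x, y in combinations(group, 2):
            for ev in _pair_events(x, y):
                events.setdefault((ev.event_type, ev.bsj_key, ev.region), ev)
    return sorted(
        events.values(), key=lambda e: (e.bsj_key, e.region, e.event_type)
    )


def _pair_events(x: CircIsoform, y: CircIsoform) -> List[ASEvent]:
    out: List[ASEvent] = []
    strand = x.strand if x.strand in "+-" else "+"
    ix, iy = _introns(x.blocks), _introns(y.blocks)
    sx, sy = set(ix), set(iy)
    key = x.bsj_key

    # ES: exon of x spanned by a single intron of y with shared flanks
    for inc, exc, their_introns in ((x, y, sy), (y, x, sx)):
        blocks = inc.blocks
        inc_introns = _introns(blocks)
        for i in range(1, len(blocks) - 1):
            exon = blocks[i]
            big = (blocks[i - 1][1], blocks[i + 1][0])
            if big in their_introns and (
                inc_introns[i - 1][0] == big[0] and inc_introns[i][1] == big[1]
            ):
                out.append(
                    ASEvent("ES", key, exon, inc.isoform_id, exc.isoform_id,
                            exon[1] - exon[0])
                )

    # IR: an intron of the spliced form is exonic in the retained form, and
    # the retained block's outer edges equal the spliced flanking exon edges
    for retained, spliced in ((x, y), (y, x)):
        rblocks = set(retained.blocks)
        for k in range(len(spliced.blocks) - 1):
            (S, d) = spliced.blocks[k]
            (a, E) = spliced.blocks[k + 1]
            if (S, E) in rblocks:
                out.append(
                    ASEvent("IR", key, (d, a), retained.isoform_id,
                            spliced.isoform_id, a - d)
                )

    # A3SS / A5SS: introns sharing exactly one boundary
    for d1, a1 in sx:
        for d2, a2 in sy:
            if (d1, a1) == (d2, a2):
                continue
            if d1 == d2 and a1 != a2 and _overlap(d1, a1, d2, a2):
                etype = "A3SS" if strand == "+" else "A5SS"
                region = (min(a1, a2), max(a1, a2))
                inc = x if a1 < a2 else y  # longer exon = inclusion
                exc = y if inc is x else x
                out.append(
                    ASEvent(etype, key, region, inc.isoform_id,
                            exc.isoform_id, abs(a1 - a2))
                )
            elif a1 == a2 and d1 != d2 and _overlap(d1, a1, d2, a2):
                etype = "A5SS" if strand == "+" else "A3SS"
                region = (min(d1, d2), max(d1, d2))
                inc = x if d1 > d2 else y
                exc = y if inc is x else x
                out.append(
                    ASEvent(etype, key, region, inc.isoform_id,
                            exc.isoform_id, abs(d1 - d2))
                )
    return out


def _overlap(d1, a1, d2, a2) -> bool:
    return min(a1, a2) - max(d1, d2) > 0


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def quantify(
    isoforms_by_sample: Dict[str, Sequence[CircIsoform]],
    high_quality_min_reads: int = 5,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-isoform and per-BSJ count tables across samples.

    The isoform table carries, per sample, the full-length read count, the
    transcript ratio (count / total count at the isoform's BSJ in that
    sample) and a high-quality flag (count >= ``high_quality_min_reads``);
    with exactly two samples a ``delta_ratio`` column is added.
    """
    iso_rows: Dict[Tuple, dict] = {}
    bsj_rows: Dict[Tuple, dict] = {}
    samples = list(isoforms_by_sample)
    for sample, isos in isoforms_by_sample.items():
        bsj_tot: Dict[Tuple, int] = {}
        for iso in isos:
            bsj_tot[iso.bsj_key] = bsj_tot.get(iso.bsj_key, 0) + iso.support_reads
        for iso in isos:
            k = (iso.chrom, iso.acceptor_start, iso.donor_end,
                 tuple(iso.blocks))
            row = iso_rows.setdefault(
                k,
                dict(
                    isoform_id=iso.isoform_id, chrom=iso.chrom,
                    start=iso.acceptor_start, end=iso.donor_end,
                    strand=iso.strand, n_blocks=len(iso.blocks),
                    length=iso.length, circ_type=iso.circ_type,
                ),
            )
            row[f"count_{sample}"] = iso.support_reads
            row[f"ratio_{sample}"] = iso.support_reads / bsj_tot[iso.bsj_key]
            row[f"hq_{sample}"] = iso.support_reads >= high_quality_min_reads
            bk = iso.bsj_key
            brow = bsj_rows.setdefault(
                bk,
                dict(chrom=bk[0], start=bk[1], end=bk[2], strand=iso.strand),
            )
            brow[f"count_{sample}"] = bsj_tot[bk]
    iso_df = pd.DataFrame(list(iso_rows.values()))
    bsj_df = pd.DataFrame(list(bsj_rows.values()))
    for df in (iso_df, bsj_df):
        for s in samples:
            for col in (f"count_{s}", f"ratio_{s}"):
                if col in df.columns:
                    df[col] = df[col].fillna(0)
    if len(samples) == 2 and not iso_df.empty:
        a, b = samples
        iso_df["delta_ratio"] = (
            iso_df[f"ratio_{a}"] - iso_df[f"ratio_{b}"]
        ).abs()
    return iso_df, bsj_df


def annotate_known(
    bsjs: Sequence[BSJ | Tuple[str, int, int]],
    known: Optional[Sequence[Tuple[str, int, int]]],
    tolerance: int = 2,
) -> List[bool]:
    """Flag each BSJ as known iff both ends match a known BSJ within
    +/-``tolerance`` nt.  With no known list, everything is unknown."""
    if not known:
        return [False] * len(bsjs)
    out = []
    for b in bsjs:
        if isinstance(b, BSJ):
            chrom, a, d = b.chrom, b.acceptor_start, b.donor_end
        else:
            chrom, a, d = b
        out.append(
            any(
                c == chrom and abs(s - a) <= tolerance and abs(e - d) <= tolerance
                for c, s, e in known
            )
        )
    return out
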