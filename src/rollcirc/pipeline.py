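"""End-to-end orchestration: clean -> align -> RG -> cRG -> strand ->
filter -> classify -> AS -> quantify -> fusion.

The per-stage record counts and the effective configuration are collected
into a run manifest, and one global seed fans out to per-stage seeds by
stable hashing so stages stay reproducible independently of each other.
"""
from __future__ import annotations

import logging
import zlib
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from . import align as al
from . import consensus as cons
from . import fusion as fus
from . import postprocess as pp
from . import rg
from . import strand as st
from .core import Annotation, Genome, PrimerSet, revcomp
from .formats import CleanRead, Read, quality_filter, trim_and_split

log = logging.getLogger(__name__)


def derive_seed(seed: int, stage: str) -> int:
    return (zlib.crc32(stage.encode()) ^ seed) % (2**31)


@dataclass
class PipelineResult:
    isoforms: List[rg.CircIsoform] = field(default_factory=list)
    bsjs: List[rg.BSJ] = field(default_factory=list)
    as_events: List[pp.ASEvent] = field(default_factory=list)
    fusion_isoforms: List[fus.FusionCircRNA] = field(default_factory=list)
    strand_accuracy: Optional[float] = None
    strand_auc: Optional[float] = None
    dropped: Dict[str, int] = field(default_factory=dict)
    manifest: Dict[str, object] = field(default_factory=dict)


@dataclass
class _ReadState:
    clean: CleanRead
    chains: List[al.SegmentChain] = field(default_factory=list)
    ccr: Optional[rg.CCR] = None
    sense_seq: str = ""
    fsj_raw: List[Tuple[int, int]] = field(default_factory=list)


def run_pipeline(
    reads: Sequence[Read],
    genome: Genome,
    annotation: Optional[Annotation],
    config: pp.PipelineConfig | None = None,
    seed: int = 0,
    primers: PrimerSet | None = None,
    known_bsjs: Optional[Sequence[Tuple[str, int, int]]] = None,
    enable_crg: bool = True,
) -> PipelineResult:
    config = config or pp.PipelineConfig()
    primers = primers or PrimerSet()
    result = PipelineResult()
    manifest: Dict[str, object] = {"seed": seed, "config": vars(config).copy()}
    result.manifest = manifest

    # ---- stage 1: clean ---------------------------------------------------
    manifest["n_raw_reads"] = len(reads)
    kept = quality_filter(reads, config.min_qscore)
    manifest["n_quality_pass"] = len(kept)
    states: Dict[str, _ReadState] = {}
    for r in kept:
        for cr in trim_and_split(r, primers):
            states[cr.read_id] = _ReadState(clean=cr)
    manifest["n_clean_reads"] = len(states)

    # ---- stage 2: align + CCR detection (RG mode) -------------------------
    index = al.GenomeIndex(genome)
    params = al.SpliceAlignParams()
    for stt in states.values():
        try:
            stt.chains = al.splice_align(
                stt.clean.sequence, index, params, read_id=stt.clean.read_id
            )
        except ValueError:
            stt.chains = []
        ccr = rg.detect_ccr(
            stt.chains,
            read_len=len(stt.clean.sequence),
            fusion_min_distance=config.fusion_min_distance,
        )
        if ccr is not None:
            stt.ccr = ccr
            stt.sense_seq = (
                stt.clean.sequence
                if ccr.aligned_strand == "+"
                else revcomp(stt.clean.sequence)
            )
    n_ccr_rg = sum(1 for s in states.values() if s.ccr is not None)
    manifest["n_ccr_rg"] = n_ccr_rg

    # ---- stage 3: cRG mode on reads without an RG call --------------------
    n_crg = 0
    if enable_crg:
        for stt in states.values():
            if stt.ccr is not None:
                continue
            res = cons.detect_period(
                stt.clean, min_period=config.min_period,
                min_copy=config.min_copy_crg,
            )
            if res is None:
                continue
            period, _ = res
            cs = cons.call_consensus(stt.clean, period)
            if cs is None or not cons.screen_internal_repeats(
                cs, config.repeat_screen_score
            ):
                continue
            query = cons.make_pseudo_query(cs)
            try:
                chains = al.splice_align(
                    query, index, params, read_id=stt.clean.read_id
                )
            except ValueError:
                continue
            ccr = rg.detect_ccr(
                chains, read_len=len(query),
                fusion_min_distance=config.fusion_min_distance,
            )
            if ccr is None or ccr.ccr_type != "normal":
                continue
            ccr.source = "cRG"
            stt.ccr = ccr
            stt.sense_seq = query if ccr.aligned_strand == "+" else revcomp(query)
            n_crg += 1
    manifest["n_ccr_crg"] = n_crg

    # ---- stage 4: BSJ refinement + correction -----------------------------
    per_chrom: Dict[str, List[Tuple[int, int, str, str]]] = defaultdict(list)
    fusion_ccrs: List[rg.CCR] = []
    for stt in states.values():
        ccr = stt.ccr
        if ccr is None:
            continue
        if ccr.ccr_type != "normal":
            fusion_ccrs.append(ccr)
            continue
        refined = rg.refine_bsj(ccr, _read_for(ccr, stt), genome)
        for a, d in refined:
            per_chrom[ccr.chrom].append((a, d, ccr.read_id, ccr.aligned_strand))
    bsjs: List[rg.BSJ] = []
    for chrom, cands in per_chrom.items():
        bsjs.extend(
            rg.correct_bsj(
                cands, annotation, genome, chrom,
                cluster_tol=config.cluster_tol,
                snap_window=config.snap_window,
            )
        )
    manifest["n_bsj_clusters"] = len(bsjs)
    read_to_bsj: Dict[str, rg.BSJ] = {}
    for b in bsjs:
        for rid in b.read_ids:
            prev = read_to_bsj.get(rid)
            if prev is None or b.support_reads > prev.support_reads:
                read_to_bsj[rid] = b

    # ---- stage 5: FSJ correction + isoform construction -------------------
    cohorts: Dict[Tuple, List[_ReadState]] = defaultdict(list)
    for stt in states.values():
        if stt.ccr is None or stt.ccr.ccr_type != "normal":
            continue
        b = read_to_bsj.get(stt.ccr.read_id)
        if b is not None:
            cohorts[b.key].append(stt)
    bsj_by_key = {b.key: b for b in bsjs}

    iso_map: Dict[Tuple, rg.CircIsoform] = {}
    iso_read_flags: Dict[Tuple, Dict[object, List[bool]]] = {}
    bsj_read_flags: Dict[Tuple, List[bool]] = defaultdict(list)
    for key, members in cohorts.items():
        b = bsj_by_key[key]
        fsj_all: List[Tuple[int, int]] = []
        for stt in members:
            stt.fsj_raw = rg.detect_fsj(stt.ccr)
            fsj_all.extend(stt.fsj_raw)
        fsj_map = rg.correct_fsj(
            fsj_all, annotation, b.chrom, snap_window=config.snap_window
        )
        # a non-annotated junction seen by a single read of a well-covered
        # BSJ is alignment noise, not a novel isoform
        if len(members) >= 3:
            support: Counter = Counter()
            for stt in members:
                seen = {
                    (fsj_map[j].donor_end, fsj_map[j].acceptor_start)
                    for j in stt.fsj_raw if j in fsj_map
                }
                support.update(seen)
            fsj_map = {
                raw: fsj for raw, fsj in fsj_map.items()
                if fsj.annotated
                or support[(fsj.donor_end, fsj.acceptor_start)] >= 2
            }
        for stt in members:
            iso = rg.build_isoform(stt.ccr, b, fsj_map)
            if iso is None:
                continue
            ik = (iso.chrom, iso.acceptor_start, iso.donor_end,
                  tuple(iso.blocks))
            if ik not in iso_map:
                iso.isoform_id = f"iso{len(iso_map) + 1:05d}"
                iso_map[ik] = iso
                iso_read_flags[ik] = defaultdict(list)
            else:
                prev = iso_map[ik]
                prev.read_ids |= iso.read_ids
                if iso.source != prev.source:
                    prev.source = "RG+cRG"
            # junction fidelity flags for this read; the BSJ flag pools at
            # the BSJ level (all its reads observe the same junction), FSJ
            # flags stay with the isoform chain
            flags = _junction_flags(
                stt, b, iso, genome, config.junction_fidelity_bp,
                config.pseudo_flank,
            )
            for jk, ok in flags.items():
                if jk == "BSJ":
                    bsj_read_flags[key].append(ok)
                else:
                    iso_read_flags[ik][jk].append(ok)
    for iso in iso_map.values():
        iso.support_reads = len(iso.read_ids)
    manifest["n_isoforms_raw"] = len(iso_map)

    # ---- stage 6: genomic tandem filter -----------------------------------
    dropped = Counter()
    surviving: Dict[Tuple, rg.CircIsoform] = {}
    for ik, iso in iso_map.items():
        if rg.tandem_genome_filter(
            iso, genome,
            copy_threshold=config.genome_tandem_copy,
            min_period=config.min_period,
        ):
            surviving[ik] = iso
        else:
            dropped["genome_tandem"] += 1
    iso_map = surviving

    # ---- stage 7: strand classification -----------------------------------
    labels: List[st.StrandLabel] = []
    feats = []
    label_states = []
    for stt in states.values():
        if stt.ccr is None or stt.ccr.ccr_type != "normal":
            continue
        lab = st.label_from_fsj(stt.ccr, stt.fsj_raw, genome)
        if lab is not None:
            labels.append(lab)
            label_states.append(stt)
    aligned_strands = {
        stt.ccr.read_id: stt.ccr.aligned_strand
        for stt in states.values()
        if stt.ccr is not None
    }
    manifest["n_fsj_labelled"] = len(labels)
    predictions: Dict[str, st.StrandLabel] = {}
    if len(labels) >= 50 and len({l.label for l in labels}) == 2:
        X = st.feature_matrix(
            [stt.clean.raw_sequence or stt.clean.sequence
             for stt in label_states],
            primers,
        )
        try:
            model, acc, auc = st.train_classifier(
                X, [l.label for l in labels],
                train_fraction=config.train_fraction,
                seed=derive_seed(seed, "strand"),
            )
            result.strand_accuracy = acc
            result.strand_auc = auc
            all_states = [s for s in states.values() if s.ccr is not None]
            Xall = st.feature_matrix(
                [s.clean.raw_sequence or s.clean.sequence for s in all_states],
                primers,
            )
            predictions = st.predict_strand(
                model, Xall, [s.ccr.read_id for s in all_states]
            )
        except ValueError as exc:
            log.warning("strand classifier skipped: %s", exc)
    isoforms = st.adjust_strand(
        list(iso_map.values()), predictions, aligned_strands
    )

    # ---- stage 8: evidence filters ----------------------------------------
    linear_crossings = _linear_crossings(states, bsj_by_key)
    final: List[rg.CircIsoform] = []
    for iso in isoforms:
        ik = (iso.chrom, iso.acceptor_start, iso.donor_end, tuple(iso.blocks))
        b = bsj_by_key.get(iso.bsj_key)
        n_bs = b.support_reads if b else iso.support_reads
        if not pp.unsplicing_filter(
            n_bs, linear_crossings.get(iso.bsj_key, 0), config.unsplicing_min
        ):
            dropped["unsplicing"] += 1
            continue
        flags = dict(iso_read_flags.get(ik, {}))
        flags["BSJ"] = bsj_read_flags.get(iso.bsj_key, [])
        if not pp.junction_fidelity_filter(
            flags, config.junction_fidelity_fraction
        ):
            dropped["junction_fidelity"] += 1
            continue
        if not pp.repeat_proximity_filter(
            iso.bsj_key, genome.repeat_track or None, config.repeat_proximity_bp
        ):
            dropped["repeat_proximity"] += 1
            continue
        final.append(iso)
    result.dropped = dict(dropped)
    manifest["n_isoforms_final"] = len(final)

    # ---- stage 9: classify, AS, quantify ----------------------------------
    if annotation is not None:
        for iso in final:
            iso.circ_type = pp.classify_circ_type(iso, annotation)
    result.as_events = pp.detect_as_events(final)
    result.isoforms = final
    kept_keys = {iso.bsj_key for iso in final}
    result.bsjs = [b for b in bsjs if b.key in kept_keys]
    if known_bsjs is not None:
        flags = pp.annotate_known(result.bsjs, known_bsjs)
        manifest["n_known_bsjs"] = int(sum(flags))

    # ---- stage 10: fusion --------------------------------------------------
    fcands = []
    for ccr in fusion_ccrs:
        cand = fus.detect_fcirc(ccr, config.fusion_min_distance)
        if cand is not None:
            stt = states.get(ccr.read_id)
            if stt is not None:
                cand = fus.refine_fcirc_junctions(
                    cand, ccr, stt.sense_seq, genome
                )
            fcands.append(cand)
    manifest["n_fusion_ccrs"] = len(fusion_ccrs)
    fisos = fus.correct_fusion_junctions(
        fcands, annotation, genome,
        cluster_tol=config.cluster_tol, snap_window=config.snap_window,
    )
    result.fusion_isoforms = fus.quantify_fcirc(
        fisos, config.high_quality_min_reads
    )
    manifest["n_fusion_isoforms"] = len(result.fusion_isoforms)
    return result


def _read_for(ccr: rg.CCR, stt: _ReadState) -> str:
    if ccr.source == "cRG":
        # the CCR was called on the triplicated consensus; sense_seq holds it
        return stt.sense_seq if ccr.aligned_strand == "+" else revcomp(stt.sense_seq)
    return stt.clean.sequence


def _junction_flags(
    stt: _ReadState,
    bsj: rg.BSJ,
    iso: rg.CircIsoform,
    genome: Genome,
    fidelity_bp: int,
    flank: int,
) -> Dict[object, bool]:
    """Per-read edit-free flags for the BSJ and every isoform FSJ.

    A read passes a junction if at least one of its rolling passes aligns
    edit-free within the +/-4 bp window (rolling copies give several
    independent observations of each junction).
    """
    flags: Dict[object, bool] = {}
    ref = genome.chromosomes[bsj.chrom]
    # junction context from the *spliced* circle sequence: reads carry the
    # mature circRNA, so genomic flanks would diverge inside short terminal
    # exons of multi-exon isoforms
    circle = "".join(ref[s:e] for s, e in iso.blocks)
    f = min(flank, len(circle))
    pseudo, seam = circle[-f:] + circle[:f], f
    # every rolling pass of the read across the BSJ is an independent
    # observation; check each crossing (segment transition) separately so
    # short circles are not limited to a single measurable crossing
    bsj_ok = False
    segs = stt.ccr.segments
    pad = 25
    for s1, s2 in zip(segs, segs[1:]):
        if s2.rstart > s1.rstart + 10:
            continue
        qc = (s1.qblocks[-1][1] + s2.qblocks[0][0]) // 2
        # clip the junction context to what the read can actually cover, so
        # crossings near the read ends remain measurable
        l_avail = min(seam, qc + pad)
        r_avail = min(len(pseudo) - seam, len(stt.sense_seq) - qc + pad)
        if l_avail < fidelity_bp + 4 or r_avail < fidelity_bp + 4:
            continue
        sub_pseudo = pseudo[seam - l_avail : seam + r_avail]
        lo = max(0, qc - l_avail - pad)
        hi = min(len(stt.sense_seq), qc + r_avail + pad)
        crossings = al.realign_to_pseudo_ref(
            stt.sense_seq[lo:hi], sub_pseudo, l_avail,
            fidelity_bp=fidelity_bp, max_crossings=1,
        )
        if any(ok for _, ok in crossings):
            bsj_ok = True
            break
    if not bsj_ok:
        # window placement depends on noisy block edges; fall back to
        # scanning the whole read for seam crossings before giving up
        crossings = al.realign_to_pseudo_ref(
            stt.sense_seq, pseudo, seam, fidelity_bp=fidelity_bp
        )
        bsj_ok = any(ok for _, ok in crossings)
    flags["BSJ"] = bsj_ok
    seq = stt.sense_seq
    ctx = 30  # junction context per side; specific enough at desk scale
    for j in range(len(iso.blocks) - 1):
        d, a = iso.blocks[j][1], iso.blocks[j + 1][0]
        jctx = ref[max(0, d - ctx) : d] + ref[a : a + ctx]
        seam = min(ctx, d)
        crossings = al.realign_to_pseudo_ref(
            seq, jctx, seam, fidelity_bp=fidelity_bp
        )
        flags[(d, a)] = any(ok for _, ok in crossings)
    return flags


def _linear_crossings(
    states: Dict[str, _ReadState],
    bsj_by_key: Dict[Tuple, rg.BSJ],
    margin: int = 10,
) -> Dict[Tuple, int]:
    """Reads aligning continuously (within one exon block) across a BSJ
    boundary, per BSJ — the linear-evidence denominator of the unsplicing
    filter."""
    # collect all blocks per chromosome once
    blocks_by_chrom: Dict[str, List[Tuple[int, int, str]]] = defaultdict(list)
    for stt in states.values():
        rid = stt.clean.read_id
        if stt.ccr is not None:
            continue  # circRNA reads are the numerator, not the denominator
        for chain in stt.chains:
            for seg in chain.segments:
                for bs, be in seg.blocks:
                    blocks_by_chrom[seg.chrom].append((bs, be, rid))
    out: Dict[Tuple, int] = {}
    for key, b in bsj_by_key.items():
        rids = set()
        for bs, be, rid in blocks_by_chrom.get(b.chrom, ()):
            for pos in (b.acceptor_start, b.donor_end):
                if bs + margin <= pos <= be - margin:
                    rids.add(rid)
        out[key] = len(rids)
    return out
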