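"""Synthetic data: genome, annotation, circRNA truths, and rolling-circle
amplicon reads.

The read architecture emulates the library the pipeline targets: rolling
circular reverse transcription (RCRT) around a circRNA template primed by
P1-N6, second-strand synthesis anchored by P2-T24, and PCR with P1/P2.  An
error-free second-strand read is laid out as::

    P2 + T24 + <rolling copies of the circRNA, round(copies * L) bases,
                starting at start_offset> + revcomp(N6) + revcomp(P1)

and a first-strand read is its reverse complement (it begins with P1).
Linear residual reads carry the same primer architecture around a single,
non-rolling insert.  A configurable indel-dominated error model emulates
nanopore noise; per-base qualities are emitted consistent with the error
rate, so the mean read qscore reflects the simulated accuracy.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import Annotation, Gene, Genome, PrimerSet, Transcript, revcomp
from .formats import Read, write_bed12

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

NORMAL_CLASSES = (
    "exonic", "intronic", "nss", "intergenic", "novel_utr",
    "antisense", "read_through",
)


# ---------------------------------------------------------------------------
# error model
# ---------------------------------------------------------------------------

@dataclass
class ErrorModel:
    """Per-base substitution/insertion/deletion rates.

    Default rates (3% sub / 3% ins / 2% del, ~8% total) correspond to
    mid-accuracy nanopore reads: hard enough to exercise junction correction
    and consensus polishing without making recovery impossible.
    """

    substitution: float = 0.03
    insertion: float = 0.03
    deletion: float = 0.02

    def __post_init__(self) -> None:
        for r in (self.substitution, self.insertion, self.deletion):
            if not 0.0 <= r < 1.0:
                raise ValueError(f"error rate {r} outside [0, 1)")

    @property
    def total(self) -> float:
        return self.substitution + self.insertion + self.deletion

    @property
    def mean_quality(self) -> int:
        if self.total <= 0:
            return 40
        return int(round(-10.0 * math.log10(self.total)))

    def apply(self, seq: str, rng: np.random.Generator) -> Tuple[str, np.ndarray]:
        """Corrupt ``seq``; returns (sequence, qualities)."""
        n = len(seq)
        if n == 0:
            return "", np.empty(0, dtype=np.int16)
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        codes = np.searchsorted(_BASES, codes)  # ACGT -> 0..3 (input is ACGT)
        if self.total == 0:
            quals = np.full(n, self.mean_quality, dtype=np.int16)
            return seq, quals
        keep = rng.random(n) >= self.deletion
        sub = keep & (rng.random(n) < self.substitution)
        ins = rng.random(n) < self.insertion
        codes = codes.copy()
        codes[sub] = (codes[sub] + rng.integers(1, 4, int(sub.sum()))) % 4
        counts = keep.astype(np.int64) + ins.astype(np.int64)
        total = int(counts.sum())
        out = np.zeros(total, dtype=np.int64)
        ends = np.cumsum(counts)
        starts = ends - counts
        out[starts[keep]] = codes[keep]
        ins_pos = (starts + keep.astype(np.int64))[ins]
        out[ins_pos] = rng.integers(0, 4, int(ins.sum()))
        new_seq = _BASES[out].tobytes().decode("ascii")
        q = self.mean_quality
        quals = (q + rng.integers(-1, 2, total)).clip(2, 41).astype(np.int16)
        return new_seq, quals


# ---------------------------------------------------------------------------
# circRNA truth
# ---------------------------------------------------------------------------

@dataclass
class CircTruth:
    """A ground-truth circRNA isoform.

    ``blocks`` are ``(chrom, start, end)`` exon blocks in genomic order; the
    monomer sequence is their concatenation (reverse-complemented for minus
    strand).  Fusion truths carry blocks on two loci; all other classes are
    single-locus.
    """

    circ_id: str
    truth_class: str
    strand: str
    blocks: List[Tuple[str, int, int]]
    seq: str
    weight: float = 1.0

    @property
    def chrom(self) -> str:
        return self.blocks[0][0]

    @property
    def start(self) -> int:
        return min(s for _, s, _ in self.blocks)

    @property
    def end(self) -> int:
        return max(e for _, _, e in self.blocks)

    @property
    def length(self) -> int:
        return sum(e - s for _, s, e in self.blocks)

    @property
    def bsj(self) -> Tuple[str, int, int, str]:
        """(chrom, acceptor_start, donor_end, strand); single-locus only."""
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def is_fusion(self) -> bool:
        return self.truth_class == "fusion"

    def exon_chain(self) -> Tuple[Tuple[int, int], ...]:
        return tuple(sorted((s, e) for _, s, e in self.blocks))


def _truth_seq(genome: Genome, blocks, strand) -> str:
    seq = "".join(genome.fetch(c, s, e) for c, s, e in blocks)
    return revcomp(seq) if strand == "-" else seq


# ---------------------------------------------------------------------------
# genome / annotation generation
# ---------------------------------------------------------------------------

def make_genome(
    n_chrom: int,
    chrom_len: int,
    repeat_fraction: float = 0.0,
    seed: int = 0,
) -> Genome:
    """A random genome with planted tandem repeats covering approximately
    ``repeat_fraction`` of each chromosome."""
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_len < 10_000:
        raise ValueError("chrom_len must be >= 10,000")
    if not 0.0 <= repeat_fraction < 0.5:
        raise ValueError("repeat_fraction must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    chroms: Dict[str, str] = {}
    track: List[Tuple[str, int, int]] = []
    for ci in range(n_chrom):
        name = f"chr{ci + 1}"
        arr = _BASES[rng.integers(0, 4, chrom_len)]
        covered = 0
        target = repeat_fraction * chrom_len
        guard = 0
        while covered < target and guard < 10_000:
            guard += 1
            mlen = int(rng.integers(20, 120))
            ncopy = int(rng.integers(3, 7))
            span = mlen * ncopy
            pos = int(rng.integers(100, chrom_len - span - 100))
            if any(s - span < pos < e + span for c, s, e in track if c == name):
                continue
            monomer = arr[pos : pos + mlen]
            for j in range(1, ncopy):
                arr[pos + j * mlen : pos + (j + 1) * mlen] = monomer
            track.append((name, pos, pos + span))
            covered += span
        chroms[name] = arr.tobytes().decode("ascii")
    track.sort()
    return Genome(chroms, track)


def _plant(chars: Dict[str, bytearray], chrom: str, pos: int, motif: str) -> None:
    if 0 <= pos and pos + len(motif) <= len(chars[chrom]):
        chars[chrom][pos : pos + len(motif)] = motif.encode("ascii")


def _plant_clear(ctx, chrom: str, start: int, end: int) -> bool:
    """Whether boundary motifs may be planted at [start, end) without
    touching the frozen sequence or junction context of an earlier truth."""
    for pos in (start - 2, start, end, end + 2):
        for c, rs, re in ctx.get("reserved", ()):
            if c == chrom and rs <= pos < re:
                return False
    return True


def _plant_boundary_motifs(
    chars: Dict[str, bytearray], chrom: str, start: int, end: int, strand: str
) -> None:
    """Plant the flanking back-splice/splice dinucleotides for an exon-like
    block: AG|block|GT on plus (genomically), AC|block|CT on minus."""
    if strand == "+":
        _plant(chars, chrom, start - 2, "AG")
        _plant(chars, chrom, end, "GT")
    else:
        _plant(chars, chrom, start - 2, "AC")
        _plant(chars, chrom, end, "CT")


def make_annotation(
    genome: Genome,
    n_genes: int = 20,
    seed: int = 0,
    exons_range: Tuple[int, int] = (3, 8),
    exon_len_range: Tuple[int, int] = (80, 300),
    intron_len_range: Tuple[int, int] = (60, 400),
    intergenic_gap: Tuple[int, int] = (800, 3000),
) -> Tuple[Genome, Annotation]:
    """Place gene models and plant canonical splice motifs into the genome.

    Every exon gets its flanking dinucleotides planted (AG upstream, GT
    downstream on the plus strand; AC/CT mirrored on minus), so both forward
    splice junctions and back-splices at annotated boundaries carry the
    canonical motif.  Returns the (motif-planted) genome copy and the
    annotation.  Gene placement avoids the repeat track.
    """
    rng = np.random.default_rng(seed)
    chars = {c: bytearray(s, "ascii") for c, s in genome.chromosomes.items()}
    chrom_names = list(genome.chromosomes)
    cursors = {c: 500 for c in chrom_names}
    genes: List[Gene] = []
    gi = 0
    attempts = 0
    while gi < n_genes and attempts < n_genes * 20:
        attempts += 1
        # fill the relatively emptiest chromosome next
        open_chroms = [
            c for c in chrom_names
            if cursors[c] + intergenic_gap[0] + 3000 < genome.chrom_len(c)
        ]
        if not open_chroms:
            break
        chrom = min(
            open_chroms, key=lambda c: cursors[c] / genome.chrom_len(c)
        )
        cursor = cursors[chrom] + int(rng.integers(*intergenic_gap))
        n_ex = int(rng.integers(exons_range[0], exons_range[1] + 1))
        exons: List[Tuple[int, int]] = []
        pos = cursor
        for _ in range(n_ex):
            elen = int(rng.integers(*exon_len_range))
            exons.append((pos, pos + elen))
            pos += elen + int(rng.integers(*intron_len_range))
        gene_end = exons[-1][1]
        if gene_end + 500 > genome.chrom_len(chrom):
            cursors[chrom] = genome.chrom_len(chrom)  # chromosome full
            if all(cursors[c] + 3000 > genome.chrom_len(c) for c in chrom_names):
                break
            continue
        if any(
            c == chrom and s - 50 < gene_end and e + 50 > cursor
            for c, s, e in genome.repeat_track
        ):
            cursors[chrom] = gene_end + 100
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G{gi + 1:04d}"
        for s, e in exons:
            _plant_boundary_motifs(chars, chrom, s, e, strand)
        genes.append(Gene(gid, chrom, strand, [Transcript(gid + ".t1", exons)]))
        cursors[chrom] = gene_end
        gi += 1
    if gi < n_genes:
        raise ValueError(
            f"could not place {n_genes} genes on this genome (placed {gi})"
        )
    new_genome = Genome(
        {c: bytes(b).decode("ascii") for c, b in chars.items()},
        list(genome.repeat_track),
    )
    return new_genome, Annotation(genes)


# ---------------------------------------------------------------------------
# circRNA truth generation
# ---------------------------------------------------------------------------

class TruthError(ValueError):
    """A requested truth class is impossible on the given genome/annotation."""


def make_circ_truth(
    genome: Genome,
    annotation: Annotation,
    counts_per_class: Dict[str, int],
    seed: int = 0,
    length_range: Tuple[int, int] = (100, 2000),
    weight_sigma: float = 0.6,
) -> Tuple[Genome, List[CircTruth]]:
    """Draw ground-truth circRNAs of the requested classes.

    Classes: ``exonic``, ``intronic``, ``nss``, ``intergenic``,
    ``novel_utr``, ``antisense``, ``read_through``, ``fusion``, plus the
    variant classes ``es_variant`` / ``ir_variant`` which re-use an exonic
    truth's back-splice junction with one exon skipped / one intron retained
    (isoform pairs for alternative-splicing detection).

    Novel (unannotated) boundaries get canonical splice dinucleotides planted
    into the genome so that motif-based junction correction applies to them;
    the (possibly mutated) genome copy is returned alongside the truths.
    """
    rng = np.random.default_rng(seed)
    chars = {c: bytearray(s, "ascii") for c, s in genome.chromosomes.items()}
    work = Genome(
        {c: s for c, s in genome.chromosomes.items()}, list(genome.repeat_track)
    )

    truths: List[CircTruth] = []
    used_bsj: set = set()
    exonic_pool: List[CircTruth] = []
    # spans whose boundary context must stay untouched by later motif
    # planting (a plant inside an earlier truth would desynchronise that
    # truth's frozen sequence from the final genome)
    ctx: Dict[str, list] = {"reserved": []}
    idx = 0

    def new_id() -> str:
        nonlocal idx
        idx += 1
        return f"circ{idx:04d}"

    def sync() -> None:
        for c in work.chromosomes:
            work.chromosomes[c] = bytes(chars[c]).decode("ascii")

    order = [
        "exonic", "read_through", "intronic", "nss", "intergenic",
        "novel_utr", "antisense", "fusion", "es_variant", "ir_variant",
    ]
    unknown = set(counts_per_class) - set(order)
    if unknown:
        raise TruthError(f"unknown truth classes: {sorted(unknown)}")
    for cls in order:
        n = counts_per_class.get(cls, 0)
        made = 0
        tries = 0
        while made < n:
            tries += 1
            if tries > n * 200 + 500:
                raise TruthError(
                    f"cannot generate {n} truths of class {cls!r} "
                    f"(made {made}) on this genome/annotation"
                )
            t = _MAKERS[cls](
                work, chars, annotation, rng, length_range, exonic_pool,
                new_id, ctx
            )
            if t is None:
                continue
            key = (t.chrom, t.start, t.end, tuple(t.exon_chain()))
            if key in used_bsj or t.length < 50:
                idx -= 1
                continue
            used_bsj.add(key)
            for c, bs, be in t.blocks:
                ctx["reserved"].append((c, bs - 8, be + 8))
            sync()
            t.seq = (
                _truth_seq(work, t.blocks, t.strand)
                if not t.is_fusion
                else _truth_seq(work, [t.blocks[0]], "+")
                + _truth_seq(work, [t.blocks[1]], "+")
            )
            t.weight = float(np.exp(rng.normal(0.0, weight_sigma)))
            truths.append(t)
            if cls == "exonic" and len(t.blocks) >= 3:
                exonic_pool.append(t)
            made += 1
    sync()
    return work, truths


def _pick_exon_run(
    t: Transcript, rng, length_range, min_exons: int = 1
) -> Optional[Tuple[int, int]]:
    n = len(t.exons)
    runs = []
    for i in range(n):
        L = 0
        for j in range(i, n):
            L += t.exons[j][1] - t.exons[j][0]
            if L > length_range[1]:
                break
            if L >= length_range[0] and j - i + 1 >= min_exons:
                runs.append((i, j))
    if not runs:
        return None
    return runs[int(rng.integers(0, len(runs)))]


def _make_exonic(work, chars, ann, rng, length_range, pool, new_id, ctx):
    if not len(ann):
        raise TruthError("exonic circRNAs need gene annotation")
    g = ann.genes[int(rng.integers(0, len(ann)))]
    t = g.transcripts[0]
    run = _pick_exon_run(t, rng, length_range)
    if run is None:
        return None
    i, j = run
    blocks = [(g.chrom, s, e) for s, e in t.exons[i : j + 1]]
    return CircTruth(new_id(), "exonic", g.strand, blocks, "", 1.0)


def _make_intronic(work, chars, ann, rng, length_range, pool, new_id, ctx):
    cands = [
        (g, iv)
        for g in ann.genes
        for iv in g.transcripts[0].introns()
        if iv[1] - iv[0] >= length_range[0] + 30
    ]
    if not cands:
        raise TruthError("no intron long enough for an intronic circRNA")
    g, (is_, ie) = cands[int(rng.integers(0, len(cands)))]
    max_len = min(length_range[1], ie - is_ - 20)
    L = int(rng.integers(length_range[0], max_len + 1)) if max_len > length_range[0] else max_len
    s = int(rng.integers(is_ + 10, ie - L - 10 + 1)) if ie - L - 10 + 1 > is_ + 10 else is_ + 10
    if not _plant_clear(ctx, g.chrom, s, s + L):
        return None
    _plant_boundary_motifs(chars, g.chrom, s, s + L, g.strand)
    return CircTruth(new_id(), "intronic", g.strand, [(g.chrom, s, s + L)], "", 1.0)


def _make_nss(work, chars, ann, rng, length_range, pool, new_id, ctx):
    g = ann.genes[int(rng.integers(0, len(ann)))]
    t = g.transcripts[0]
    run = _pick_exon_run(t, rng, length_range)
    if run is None:
        return None
    i, j = run
    if i == 0:  # keep the novel boundary inside the gene body
        return None
    exons = list(t.exons[i : j + 1])
    # shift the acceptor boundary to a novel position inside the upstream
    # intron
    s0, e0 = exons[0]
    shift = int(rng.integers(15, 60))
    prev_end = t.exons[i - 1][1]
    new_s = max(prev_end + 10, s0 - shift)
    if new_s == s0 or new_s in ann.exon_starts(g.chrom):
        return None
    exons[0] = (new_s, e0)
    if not _plant_clear(ctx, g.chrom, new_s, exons[-1][1]):
        return None
    _plant_boundary_motifs(chars, g.chrom, new_s, exons[-1][1], g.strand)
    blocks = [(g.chrom, s, e) for s, e in exons]
    return CircTruth(new_id(), "nss", g.strand, blocks, "", 1.0)


def _intergenic_gaps(work: Genome, ann: Annotation, margin: int = 300):
    gaps = []
    for chrom in work.chromosomes:
        spans = sorted(
            (g.start, g.end) for g in ann.genes if g.chrom == chrom
        )
        prev = 0
        for s, e in spans + [(work.chrom_len(chrom), work.chrom_len(chrom))]:
            if s - prev > 2 * margin:
                gaps.append((chrom, prev + margin, s - margin))
            prev = max(prev, e)
    return gaps


def _make_intergenic(work, chars, ann, rng, length_range, pool, new_id, ctx):
    gaps = [
        g for g in _intergenic_gaps(work, ann)
        if g[2] - g[1] >= length_range[0] + 20
    ]
    if not gaps:
        raise TruthError("no intergenic gap wide enough")
    chrom, lo, hi = gaps[int(rng.integers(0, len(gaps)))]
    max_len = min(length_range[1], hi - lo - 10)
    L = int(rng.integers(length_range[0], max_len + 1)) if max_len > length_range[0] else max_len
    s = int(rng.integers(lo, hi - L + 1))
    if any(
        c == chrom and rs - 40 < s + L and re + 40 > s
        for c, rs, re in work.repeat_track
    ):
        return None
    strand = "+" if rng.random() < 0.5 else "-"
    if not _plant_clear(ctx, chrom, s, s + L):
        return None
    _plant_boundary_motifs(chars, chrom, s, s + L, strand)
    return CircTruth(new_id(), "intergenic", strand, [(chrom, s, s + L)], "", 1.0)


def _make_novel_utr(work, chars, ann, rng, length_range, pool, new_id, ctx):
    g = ann.genes[int(rng.integers(0, len(ann)))]
    t = g.transcripts[0]
    ext = int(rng.integers(80, 200))
    # extend past the downstream terminal exon (genomically rightmost)
    nxt = [h.start for h in ann.genes if h.chrom == g.chrom and h.start > t.end]
    limit = min(nxt) - 50 if nxt else work.chrom_len(g.chrom) - 50
    new_end = t.end + ext
    if new_end >= limit:
        return None
    ls, le = t.exons[-1]
    blocks = [(g.chrom, s, e) for s, e in t.exons[:-1]] + [(g.chrom, ls, new_end)]
    # keep only a tail of exons within the length budget
    while sum(e - s for _, s, e in blocks) > length_range[1] and len(blocks) > 1:
        blocks = blocks[1:]
    if sum(e - s for _, s, e in blocks) < max(50, length_range[0] // 2):
        return None
    if not _plant_clear(ctx, g.chrom, blocks[0][1], new_end):
        return None
    _plant_boundary_motifs(chars, g.chrom, blocks[0][1], new_end, g.strand)
    return CircTruth(new_id(), "novel_utr", g.strand, blocks, "", 1.0)


def _make_antisense(work, chars, ann, rng, length_range, pool, new_id, ctx):
    g = ann.genes[int(rng.integers(0, len(ann)))]
    strand = "-" if g.strand == "+" else "+"
    span = g.end - g.start
    max_len = min(length_range[1], span - 40)
    if max_len < length_range[0]:
        return None
    L = int(rng.integers(length_range[0], max_len + 1))
    s = g.start + int(rng.integers(10, span - L - 10 + 1))
    # avoid colliding with annotated boundaries (keeps the class unambiguous)
    if any(abs(s - b) < 12 for b in ann.exon_starts(g.chrom) | ann.exon_ends(g.chrom)):
        return None
    if any(abs(s + L - b) < 12 for b in ann.exon_starts(g.chrom) | ann.exon_ends(g.chrom)):
        return None
    if not _plant_clear(ctx, g.chrom, s, s + L):
        return None
    _plant_boundary_motifs(chars, g.chrom, s, s + L, strand)
    return CircTruth(new_id(), "antisense", strand, [(g.chrom, s, s + L)], "", 1.0)


def _make_read_through(work, chars, ann, rng, length_range, pool, new_id, ctx):
    pairs = []
    by_chrom: Dict[str, List[Gene]] = {}
    for g in ann.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.start)
        for a, b in zip(gs, gs[1:]):
            if a.strand == b.strand:
                pairs.append((a, b))
    if not pairs:
        raise TruthError("read-through circRNAs need two adjacent same-strand genes")
    a, b = pairs[int(rng.integers(0, len(pairs)))]
    ta, tb = a.transcripts[0], b.transcripts[0]
    na = int(rng.integers(1, min(2, len(ta.exons)) + 1))
    nb = int(rng.integers(1, min(2, len(tb.exons)) + 1))
    blocks = [(a.chrom, s, e) for s, e in ta.exons[-na:]] + [
        (b.chrom, s, e) for s, e in tb.exons[:nb]
    ]
    return CircTruth(new_id(), "read_through", a.strand, blocks, "", 1.0)


def _make_fusion(work, chars, ann, rng, length_range, pool, new_id, ctx):
    exons = [
        (g.chrom, s, e, g)
        for g in ann.genes
        for s, e in g.transcripts[0].exons
        if e - s >= 80
    ]
    pairs = [
        (x, y)
        for xi, x in enumerate(exons)
        for y in exons[xi + 1 :]
        if x[0] != y[0] or abs(x[1] - y[1]) > 1_000_000
    ]
    if not pairs:
        raise TruthError(
            "fusion truths need loci on different chromosomes or >1 Mbp apart"
        )
    x, y = pairs[int(rng.integers(0, len(pairs)))]
    blocks = [(x[0], x[1], x[2]), (y[0], y[1], y[2])]
    return CircTruth(new_id(), "fusion", "+", blocks, "", 1.0)


def _make_es_variant(work, chars, ann, rng, length_range, pool, new_id, ctx):
    if not pool:
        raise TruthError("es_variant needs an exonic truth with >=3 exons")
    base = pool[int(rng.integers(0, len(pool)))]
    drop = int(rng.integers(1, len(base.blocks) - 1))
    blocks = [b for k, b in enumerate(base.blocks) if k != drop]
    return CircTruth(new_id(), "exonic", base.strand, blocks, "", 1.0)


def _make_ir_variant(work, chars, ann, rng, length_range, pool, new_id, ctx):
    if not pool:
        raise TruthError("ir_variant needs an exonic truth with >=2 exons")
    base = pool[int(rng.integers(0, len(pool)))]
    k = int(rng.integers(0, len(base.blocks) - 1))
    c, s1, e1 = base.blocks[k]
    _, s2, e2 = base.blocks[k + 1]
    blocks = base.blocks[:k] + [(c, s1, e2)] + base.blocks[k + 2 :]
    return CircTruth(new_id(), "exonic", base.strand, blocks, "", 1.0)


_MAKERS = {
    "exonic": _make_exonic,
    "intronic": _make_intronic,
    "nss": _make_nss,
    "intergenic": _make_intergenic,
    "novel_utr": _make_novel_utr,
    "antisense": _make_antisense,
    "read_through": _make_read_through,
    "fusion": _make_fusion,
    "es_variant": _make_es_variant,
    "ir_variant": _make_ir_variant,
}


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_rcrt_read(
    circ: CircTruth,
    copies: float,
    start_offset: int,
    orientation: str,
    err: ErrorModel,
    primers: PrimerSet | None = None,
    rng: Optional[np.random.Generator] = None,
    read_id: str = "read",
) -> Read:
    """One rolling-circle amplicon read from a circRNA truth."""
    primers = primers or PrimerSet()
    rng = rng or np.random.default_rng(0)
    if copies < 0.3:
        raise ValueError("copies must be >= 0.3")
    monomer = circ.seq
    L = len(monomer)
    if not 0 <= start_offset < L:
        raise ValueError("start_offset outside the circle")
    if orientation not in ("first_strand", "second_strand"):
        raise ValueError(f"unknown orientation {orientation!r}")
    n_bases = int(round(copies * L))
    rolled = monomer[start_offset:] + monomer * (n_bases // L + 2)
    insert = rolled[:n_bases]
    n6 = _BASES[rng.integers(0, 4, 6)].tobytes().decode("ascii")
    layout = primers.P2 + primers.T24 + insert + revcomp(n6) + revcomp(primers.P1)
    if orientation == "first_strand":
        layout = revcomp(layout)
    seq, quals = err.apply(layout, rng)
    return Read(read_id, seq, quals)


def simulate_linear_read(
    insert_seq: str,
    err: ErrorModel,
    primers: PrimerSet | None = None,
    rng: Optional[np.random.Generator] = None,
    read_id: str = "linread",
    orientation: str = "second_strand",
) -> Read:
    """A linear-residual read: same primer architecture, single insert."""
    primers = primers or PrimerSet()
    rng = rng or np.random.default_rng(0)
    n6 = _BASES[rng.integers(0, 4, 6)].tobytes().decode("ascii")
    layout = primers.P2 + primers.T24 + insert_seq + revcomp(n6) + revcomp(primers.P1)
    if orientation == "first_strand":
        layout = revcomp(layout)
    seq, quals = err.apply(layout, rng)
    return Read(read_id, seq, quals)


@dataclass
class LibraryConfig:
    """Study conditions for a simulated library."""

    mean_reads_per_circ: int = 20
    copy_geometric_p: float = 0.4  # mean rolling copies ~= 2.5
    truncate_fraction: float = 0.05  # reads with damaged terminal primers
    linear_fraction: float = 0.15  # linear residual reads (of circ read count)
    low_quality_fraction: float = 0.02  # reads below the qscore cutoff
    error: ErrorModel = field(default_factory=ErrorModel)


def simulate_library(
    truths: Sequence[CircTruth],
    annotation: Annotation,
    genome: Genome,
    config: LibraryConfig | None = None,
    seed: int = 0,
    primers: PrimerSet | None = None,
) -> Tuple[List[Read], List[dict]]:
    """Simulate a full RCRT library.

    Returns the reads and a per-read truth table (read_id, circ_id or
    'linear', orientation, copies, truncated flag).
    """
    config = config or LibraryConfig()
    primers = primers or PrimerSet()
    rng = np.random.default_rng(seed)
    weights = np.array([t.weight for t in truths], dtype=float)
    total = config.mean_reads_per_circ * len(truths)
    counts = rng.multinomial(total, weights / weights.sum())
    low_err = ErrorModel(0.10, 0.09, 0.06)  # qscore ~6: below the cutoff

    reads: List[Read] = []
    table: List[dict] = []
    rid = 0
    for t, n in zip(truths, counts):
        for _ in range(int(n)):
            rid += 1
            copies = float(rng.geometric(config.copy_geometric_p))
            copies = max(0.6, copies + float(rng.uniform(-0.5, 0.5)))
            offset = int(rng.integers(0, len(t.seq)))
            orient = "first_strand" if rng.random() < 0.5 else "second_strand"
            err = config.error
            lowq = rng.random() < config.low_quality_fraction
            if lowq:
                err = low_err
            read = simulate_rcrt_read(
                t, copies, offset, orient, err, primers, rng, f"r{rid:06d}"
            )
            trunc = rng.random() < config.truncate_fraction
            if trunc:
                read = _truncate_end(read, rng)
            reads.append(read)
            table.append(
                dict(read_id=read.read_id, circ_id=t.circ_id, copies=copies,
                     orientation=orient, truncated=trunc, low_quality=lowq)
            )
    n_linear = int(config.linear_fraction * total)
    transcripts = [
        (g, g.transcripts[0]) for g in annotation.genes
    ]
    for _ in range(n_linear):
        rid += 1
        g, tr = transcripts[int(rng.integers(0, len(transcripts)))]
        seq = "".join(genome.fetch(g.chrom, s, e) for s, e in tr.exons)
        if g.strand == "-":
            seq = revcomp(seq)
        orient = "first_strand" if rng.random() < 0.5 else "second_strand"
        read = simulate_linear_read(
            seq, config.error, primers, rng, f"r{rid:06d}", orient
        )
        reads.append(read)
        table.append(
            dict(read_id=read.read_id, circ_id="linear", copies=1.0,
                 orientation=orient, truncated=False, low_quality=False)
        )
    return reads, table


def _truncate_end(read: Read, rng: np.random.Generator) -> Read:
    cut = int(rng.integers(10, 46))
    if len(read) <= cut + 50:
        return read
    if rng.random() < 0.5:
        return Read(read.read_id, read.sequence[cut:], read.qualities[cut:])
    return Read(read.read_id, read.sequence[:-cut], read.qualities[:-cut])


# ---------------------------------------------------------------------------
# truth output
# ---------------------------------------------------------------------------

def write_truth(truths: Sequence[CircTruth], outdir: str | Path) -> None:
    """truth.bed (BED12 exon chains, single-locus classes), truth_fusion.tsv
    (two-locus records), truth_abundance.tsv (circ_id, class, weight)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    normal = [t for t in truths if not t.is_fusion]
    recs = [
        dict(
            chrom=t.chrom, start=t.start, end=t.end,
            name=f"{t.circ_id}|{t.truth_class}", strand=t.strand,
            blocks=[(s, e) for _, s, e in t.blocks],
        )
        for t in normal
    ]
    write_bed12(recs, outdir / "truth.bed")
    with open(outdir / "truth_fusion.tsv", "w") as fh:
        fh.write("circ_id\tchromA\tstartA\tendA\tchromB\tstartB\tendB\n")
        for t in truths:
            if t.is_fusion:
                (ca, sa, ea), (cb, sb, eb) = t.blocks
                fh.write(f"{t.circ_id}\t{ca}\t{sa}\t{ea}\t{cb}\t{sb}\t{eb}\n")
    with open(outdir / "truth_abundance.tsv", "w") as fh:
        fh.write("circ_id\tclass\tweight\n")
        for t in truths:
            fh.write(f"{t.circ_id}\t{t.truth_class}\t{t.weight:.6g}\n")
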