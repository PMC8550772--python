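"""File formats and read cleaning.

FASTQ/FASTA readers and writers, GENCODE-dialect GTF, BED6/BED12, the result
tables, and the read-cleaning stage (mean-quality filter, primer trimming,
chimera splitting).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import edlib
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Annotation, Gene, Genome, PrimerSet, Transcript, revcomp

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass
class Read:
    """A long read with per-base Phred qualities.

    ``mean_qscore`` follows the basecaller convention: the Phred transform of
    the *mean per-base error probability*, not the mean of the Phred values.
    """

    read_id: str
    sequence: str
    qualities: np.ndarray  # int array, Phred (Sanger) scale

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )

    @property
    def mean_qscore(self) -> float:
        if len(self.qualities) == 0:
            return 0.0
        perr = np.power(10.0, -self.qualities / 10.0)
        return float(-10.0 * math.log10(float(perr.mean())))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CleanRead(Read):
    """A cleaned read: primers trimmed, chimeras split.

    The untrimmed source sequence is preserved (``raw_sequence``) because the
    strand classifier takes its features from the 100-nt flanking windows of
    the *raw* read — trimming must not destroy that evidence.
    """

    raw_sequence: str = ""
    trimmed_5p: bool = False
    trimmed_3p: bool = False
    split_index: Optional[int] = None  # 0-based piece index if from a chimera
    primer_5p: Optional[str] = None  # pattern name detected at the 5' end
    primer_3p: Optional[str] = None


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream reads from a 4-line FASTQ file; malformed records raise with
    the offending record named."""
    n = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            n += 1
            yield Read(
                rec.id,
                str(rec.seq).upper(),
                np.asarray(rec.letter_annotations["phred_quality"]),
            )
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record #{n + 1} in {path}: {exc}") from exc


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = [int(q) for q in r.qualities]
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


def quality_filter(reads: Iterable[Read], min_qscore: float = 7.0) -> List[Read]:
    """Keep reads with mean qscore >= ``min_qscore`` (boundary inclusive)."""
    return [r for r in reads if r.mean_qscore >= min_qscore]


# ---------------------------------------------------------------------------
# primer trimming and chimera splitting
# ---------------------------------------------------------------------------

@dataclass
class _PrimerHit:
    name: str  # pattern name, e.g. "P1" or "rcP2"
    start: int
    end: int
    identity: float

    @property
    def forward(self) -> bool:
        return not self.name.startswith("rc")


def _find_primer_hits(
    seq: str, primers: PrimerSet, min_identity: float
) -> List[_PrimerHit]:
    hits: List[_PrimerHit] = []
    for name, pat in primers.patterns().items():
        if "T24" in name:
            continue  # homopolymer tracts are trimmed separately
        max_ed = int(len(pat) * (1.0 - min_identity))
        res = edlib.align(pat, seq, mode="HW", task="locations", k=max_ed)
        if res["editDistance"] < 0:
            continue
        ident = (len(pat) - res["editDistance"]) / len(pat)
        last_end = -10**9
        for s, e in res["locations"]:
            if s is None:
                s = 0
            if s - last_end < len(pat) // 2:
                continue
            hits.append(_PrimerHit(name, s, e + 1, ident))
            last_end = e + 1
    # P1 and P2 share a restriction-site core, so a strong hit of one primer
    # often shadows a weaker, shifted hit of the other: keep only the best
    # hit among mutually overlapping ones
    hits.sort(key=lambda h: (-h.identity, h.end - h.start))
    kept: List[_PrimerHit] = []
    for h in hits:
        if all(
            min(h.end, k.end) - max(h.start, k.start) <= 5 for k in kept
        ):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def _strip_homopolymer(seq: str, base: str, from_start: bool, limit: int = 40) -> int:
    """Length of a terminal homopolymer run (one mismatch tolerated while the
    run continues)."""
    n = 0
    miss = 0
    rng = range(len(seq)) if from_start else range(len(seq) - 1, -1, -1)
    for i in rng:
        if n >= limit:
            break
        if seq[i] == base:
            n += 1 + miss
            miss = 0
        elif miss == 0 and n > 0:
            miss = 1
        else:
            break
    return n


def trim_and_split(
    read: Read,
    primers: PrimerSet | None = None,
    min_identity: float = 0.75,
    end_window: int = 150,
    split_gap: int = 50,
) -> List[CleanRead]:
    """Trim terminal primers and split chimeric reads.

    A chimeric junction is a reverse-oriented primer hit followed by a
    forward-oriented hit within ``split_gap`` nt (adapter-adapter, i.e. the
    tail of one amplicon abutting the head of the next); the read is split
    between the two hits.  Terminal primer matches (identity >=
    ``min_identity`` over the primer length, inside ``end_window`` of either
    end) are removed together with the adjacent poly-T/poly-A tract.
    """
    primers = primers or PrimerSet()
    seq = read.sequence
    hits = _find_primer_hits(seq, primers, min_identity)

    # chimera split points: rc-hit then fwd-hit, close together, both internal
    cut_points: List[int] = []
    for h1, h2 in zip(hits, hits[1:]):
        if (
            not h1.forward
            and h2.forward
            and 0 <= h2.start - h1.end <= split_gap
            and h1.end > end_window
            and h2.start < len(seq) - end_window
        ):
            cut_points.append((h1.end + h2.start) // 2)

    pieces: List[Tuple[int, int]] = []
    prev = 0
    for c in cut_points:
        pieces.append((prev, c))
        prev = c
    pieces.append((prev, len(seq)))

    out: List[CleanRead] = []
    for idx, (ps, pe) in enumerate(pieces):
        sub = seq[ps:pe]
        sub_hits = [h for h in hits if h.start >= ps and h.end <= pe]
        s, e = 0, len(sub)
        p5 = p3 = None
        t5 = t3 = False
        for h in sub_hits:
            hs, he = h.start - ps, h.end - ps
            if hs < min(end_window, len(sub)) and h.forward and he > s:
                s, p5, t5 = he, h.name, True
            if he > max(len(sub) - end_window, 0) and not h.forward and hs < e:
                e, p3, t3 = hs, h.name, True
        # poly-T after the 5' primer (second-strand reads), poly-A before the
        # 3' primer (reverse complement of the T24 tract)
        if t5:
            s += _strip_homopolymer(sub[s:e], "T", from_start=True)
        if t3:
            e -= _strip_homopolymer(sub[s:e], "A", from_start=False)
        if e - s < 30:
            continue
        suffix = f"_part{idx}" if len(pieces) > 1 else ""
        out.append(
            CleanRead(
                read_id=read.read_id + suffix,
                sequence=sub[s:e],
                qualities=read.qualities[ps + s : ps + e],
                raw_sequence=read.sequence,
                trimmed_5p=t5,
                trimmed_3p=t3,
                split_index=idx if len(pieces) > 1 else None,
                primer_5p=p5,
                primer_3p=p3,
            )
        )
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Genome:
    chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not chroms:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(chroms)


def write_fasta(genome: Genome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF (GENCODE dialect) and BED
# ---------------------------------------------------------------------------

def write_gtf(annotation: Annotation, path: str | Path) -> None:
    """Emit gene/transcript/exon features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for g in annotation:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\trollcirc\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                ta = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{g.chrom}\trollcirc\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                    f"{g.strand}\t.\t{ta}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{g.chrom}\trollcirc\texon\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\t{ta}\n"
                    )


def _parse_gtf_attrs(text: str) -> Dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip('"')
    return out


def read_gtf(path: str | Path, genome: Genome | None = None) -> Annotation:
    """Read a GENCODE-dialect GTF into an :class:`Annotation`.

    Exon features are grouped by transcript_id/gene_id; coordinates are
    converted from 1-based inclusive to 0-based half-open.  Unordered exons
    are sorted with a warning.
    """
    tx: Dict[str, List[Tuple[int, int]]] = {}
    tx_meta: Dict[str, Tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{ln}: not a GTF line")
            chrom, _, feat, start, end, _, strand, _, attrs = f[:9]
            if feat != "exon":
                continue
            a = _parse_gtf_attrs(attrs)
            tid, gid = a.get("transcript_id"), a.get("gene_id", "NA")
            if tid is None:
                raise ValueError(f"{path}:{ln}: exon without transcript_id")
            s, e = int(start) - 1, int(end)
            if genome is not None:
                if chrom not in genome or e > genome.chrom_len(chrom):
                    raise ValueError(
                        f"{path}:{ln}: exon {chrom}:{s}-{e} outside genome"
                    )
            tx.setdefault(tid, []).append((s, e))
            tx_meta[tid] = (gid, chrom, strand)

    genes: Dict[str, Gene] = {}
    for tid, exons in tx.items():
        gid, chrom, strand = tx_meta[tid]
        if exons != sorted(exons):
            log.warning("transcript %s: exons unordered in GTF, sorting", tid)
            exons = sorted(exons)
        g = genes.get(gid)
        if g is None:
            g = genes[gid] = Gene(gid, chrom, strand, [])
        g.transcripts.append(Transcript(tid, exons))
    return Annotation(list(genes.values()))


def read_bed(path: str | Path) -> List[Tuple[str, int, int]]:
    """BED3+ intervals, 0-based half-open (extra columns ignored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_bed12(records: Sequence[dict], path: str | Path) -> None:
    """Write BED12 lines from dicts with keys chrom/start/end/name/score/
    strand/blocks (absolute 0-based half-open block intervals)."""
    with open(path, "w") as fh:
        for r in records:
            blocks = sorted(r["blocks"])
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - r["start"]) for s, _ in blocks)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r["chrom"], r["start"], r["end"], r["name"],
                        r.get("score", 0), r.get("strand", "."),
                        r["start"], r["end"], "0,0,0",
                        len(blocks), sizes + ",", starts + ",",
                    )
                )
                + "\n"
            )


def read_bed12(path: str | Path) -> List[dict]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            score, strand = f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
            out.append(
                dict(chrom=chrom, start=start, end=end, name=name,
                     score=score, strand=strand, blocks=blocks)
            )
    return out
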