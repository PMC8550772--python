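"""Core genomic containers shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; conversion
to/from 1-based GTF happens only at the file boundary (:mod:`rollcirc.formats`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Sequence, Tuple

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMP)[::-1]


@dataclass
class Genome:
    """An in-memory genome: chromosome name -> sequence, plus a repeat track.

    The repeat track is a list of ``(chrom, start, end)`` intervals flagging
    low-complexity / repetitive regions, used by the repeat-proximity filter.
    """

    chromosomes: Dict[str, str]
    repeat_track: List[Tuple[str, int, int]] = field(default_factory=list)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.chromosomes[chrom]
        start = max(0, start)
        end = min(len(seq), end)
        if start >= end:
            return ""
        return seq[start:end]

    def chrom_len(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes


@dataclass
class Transcript:
    transcript_id: str
    exons: List[Tuple[int, int]]  # strand-agnostic genomic order, sorted

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> List[Tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: List[Transcript]

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


class Annotation:
    """Gene models plus the lookup indexes the junction correctors need."""

    def __init__(self, genes: Sequence[Gene]):
        self.genes: List[Gene] = list(genes)
        # per-chrom sorted boundary arrays and splice-site sets
        self._exon_starts: Dict[str, set] = {}
        self._exon_ends: Dict[str, set] = {}
        self._rebuild()

    def _rebuild(self) -> None:
        self._exon_starts.clear()
        self._exon_ends.clear()
        for g in self.genes:
            ss = self._exon_starts.setdefault(g.chrom, set())
            ee = self._exon_ends.setdefault(g.chrom, set())
            for t in g.transcripts:
                for s, e in t.exons:
                    ss.add(s)
                    ee.add(e)

    def exon_starts(self, chrom: str) -> set:
        return self._exon_starts.get(chrom, set())

    def exon_ends(self, chrom: str) -> set:
        return self._exon_ends.get(chrom, set())

    def genes_overlapping(self, chrom: str, start: int, end: int) -> List[Gene]:
        return [
            g
            for g in self.genes
            if g.chrom == chrom and g.start < end and g.end > start
        ]

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class PrimerSet:
    """The library's fixed primer/anchor sequences.

    P1 primes first-strand cDNA synthesis (P1-N6: P1 followed by a random
    hexamer); the second strand is anchored by P2-T24 (P2 followed by 24 Ts).
    PCR amplification uses P1 and P2 alone, so every intact amplicon carries
    P1 at one end and P2 at the other.
    """

    P1: str = "GTCGACGGCGCGCCGGATCCATA"
    P2: str = "ATATCTCGAGGGCGCGCCGGATCC"
    T24: str = "T" * 24
    N6: str = "N" * 6  # placeholder; the simulator draws a random hexamer

    def patterns(self) -> Dict[str, str]:
        """The six patterns used for strand features: P1/P2/T24 and RCs."""
        return {
            "P1": self.P1,
            "P2": self.P2,
            "T24": self.T24,
            "rcP1": revcomp(self.P1),
            "rcP2": revcomp(self.P2),
            "rcT24": revcomp(self.T24),
        }


def snap(pos: int, sites: Sequence[int], window: int) -> int | None:
    """Nearest site within ``window`` of ``pos`` (ties toward the left)."""
    best = None
    best_d = window + 1
    for s in sites:
        d = abs(s - pos)
        if d < best_d or (d == best_d and best is not None and s < best):
            best, best_d = s, d
    return best if best_d <= window else None
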