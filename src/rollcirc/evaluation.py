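"""Benchmark experiments: simulate under the study conditions, run the
pipeline, and measure recovery.

Each function generates its own inputs from a seed, executes the relevant
part of the pipeline, and returns measured quantities.  They are used by the
test suite and by ``scripts/acceptance.py``.

Problem sizes are desk-scale by design: a few-hundred-kilobase synthetic
genome and a few thousand reads exercise every stage of the method while a
full run stays in the minutes range on one CPU.
"""
from __future__ import annotations

from collections import defaultdict
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from . import consensus as cons
from . import fusion as fus
from . import postprocess as pp
from . import rg
from . import strand as st
from . import synth
from .core import Annotation, Genome, PrimerSet, revcomp
from .formats import Read
from .pipeline import derive_seed, run_pipeline

E2E_CLASS_COUNTS = {
    "exonic": 110, "intronic": 12, "nss": 20, "intergenic": 16,
    "novel_utr": 10, "antisense": 10, "read_through": 4,
    "es_variant": 10, "ir_variant": 8,
}  # 200 truths, exonic-dominated like real libraries


def make_study_library(
    seed: int,
    class_counts: Optional[Dict[str, int]] = None,
    n_chrom: int = 2,
    chrom_len: int = 250_000,
    n_genes: int = 40,
    mean_reads: int = 20,
    error: Optional[synth.ErrorModel] = None,
    library: Optional[synth.LibraryConfig] = None,
):
    """Genome + annotation + truths + reads under the default conditions."""
    genome = synth.make_genome(n_chrom, chrom_len, 0.02, seed=derive_seed(seed, "genome"))
    genome, ann = synth.make_annotation(
        genome, n_genes=n_genes, seed=derive_seed(seed, "annotation")
    )
    genome, truths = synth.make_circ_truth(
        genome, ann, class_counts or E2E_CLASS_COUNTS,
        seed=derive_seed(seed, "truth"),
    )
    if library is None:
        library = synth.LibraryConfig(mean_reads_per_circ=mean_reads)
        if error is not None:
            library.error = error
    reads, table = synth.simulate_library(
        truths, ann, genome, library, seed=derive_seed(seed, "library")
    )
    return genome, ann, truths, reads, table


def eligible_truths(
    truths, table, min_reads: int = 5, min_mean_copies: float = 1.5
) -> List:
    """Truths with enough usable read support to be recoverable by design."""
    copies = defaultdict(list)
    for row in table:
        if row["circ_id"] != "linear" and not row["low_quality"]:
            copies[row["circ_id"]].append(row["copies"])
    return [
        t for t in truths
        if not t.is_fusion
        and len(copies[t.circ_id]) >= min_reads
        and np.mean(copies[t.circ_id]) >= min_mean_copies
    ]


def measure_recovery(result, truths) -> Dict[str, float]:
    found = {(i.chrom, i.acceptor_start, i.donor_end) for i in result.isoforms}
    chains = {
        ((i.chrom, i.acceptor_start, i.donor_end), i.exon_chain())
        for i in result.isoforms
    }
    n = len(truths)
    bsj_hit = sum(1 for t in truths if (t.chrom, t.start, t.end) in found)
    chain_hit = sum(
        1 for t in truths
        if ((t.chrom, t.start, t.end), t.exon_chain()) in chains
    )
    return dict(
        n_truths=n,
        bsj_recovery=bsj_hit / n if n else 0.0,
        chain_recovery=chain_hit / n if n else 0.0,
    )


# ---------------------------------------------------------------------------
# end-to-end benchmarks
# ---------------------------------------------------------------------------

def e2e_benchmark(seed: int = 1) -> Dict[str, float]:
    """Recovery of 200 mixed-class truths at ~8% read error, 20x depth."""
    genome, ann, truths, reads, table = make_study_library(seed)
    result = run_pipeline(reads, genome, ann, seed=seed)
    elig = eligible_truths(truths, table)
    out = measure_recovery(result, elig)
    out["n_reads"] = len(reads)
    out["strand_accuracy"] = result.strand_accuracy
    out["strand_auc"] = result.strand_auc
    out["result"] = result
    out["truths"] = truths
    out["table"] = table
    return out


def errorfree_benchmark(seed: int = 1, n_scale: float = 0.25) -> Dict[str, float]:
    """Exactness on error-free reads: every simulated circRNA must come back
    with base-exact BSJ and exon chain."""
    counts = {
        k: max(1, int(v * n_scale)) for k, v in E2E_CLASS_COUNTS.items()
    }
    lib = synth.LibraryConfig(
        mean_reads_per_circ=10,
        truncate_fraction=0.0,
        low_quality_fraction=0.0,
        error=synth.ErrorModel(0.0, 0.0, 0.0),
    )
    genome, ann, truths, reads, table = make_study_library(
        seed, class_counts=counts, chrom_len=150_000, n_genes=30, library=lib
    )
    result = run_pipeline(reads, genome, ann, seed=seed)
    elig = eligible_truths(truths, table, min_reads=2, min_mean_copies=1.2)
    out = measure_recovery(result, elig)
    out["n_reads"] = len(reads)
    return out


# ---------------------------------------------------------------------------
# consensus benchmark
# ---------------------------------------------------------------------------

def oracle_period(seq: str, min_period: int = 30, min_copy: float = 1.5,
                  harmonic_slack: float = 0.05) -> Optional[int]:
    """Exhaustive-period oracle.

    Every candidate period is scored by the adjacent-copy identity of the
    first two putative copies.  Because any multiple of the fundamental
    period scores essentially the same identity (copy pairs vs copy-pair
    pairs), the argmax is then walked down its near-divisors: if a period
    near p/k scores within ``harmonic_slack`` of p, the fundamental is
    below, and the descent repeats until stable.
    """
    idents: Dict[int, float] = {}
    max_p = int(len(seq) / min_copy)
    for p in range(min_period, max_p + 1):
        a, b = seq[:p], seq[p : 2 * p]
        if not b:
            break
        lim = max(10, int(0.4 * p))  # identities below 60% never compete
        d = edlib.align(a, b, mode="NW", task="distance", k=lim)["editDistance"]
        idents[p] = 1.0 - d / p if d >= 0 else -1.0
    if not idents:
        return None
    p_best = max(idents, key=idents.get)
    while True:
        moved = False
        for k in (2, 3, 4, 5):
            target = p_best / k
            if target < min_period:
                continue
            w = max(2, int(0.02 * p_best))
            window = [
                q for q in range(int(target) - w, int(target) + w + 1)
                if q in idents
            ]
            if not window:
                continue
            q_best = max(window, key=idents.get)
            if idents[q_best] >= idents[p_best] - harmonic_slack:
                p_best = q_best
                moved = True
                break
        if not moved:
            return p_best


def periods_agree(p_det: int, p_orc: int, indel_rate: float = 0.03) -> bool:
    """Equivalence band for two period estimates of one noisy tandem read.

    Copy lengths inside the read drift by indels, so an estimator anchored
    on different copies is off by ~sqrt(indel_rate * p) bases (1 sigma).
    Two independent estimates therefore differ by up to
    3 * sqrt(2 * indel_rate * p) in ~99.7% of cases; that 3-sigma band
    (never below 4 nt) defines agreement.
    """
    p = min(p_det, p_orc)
    tol = max(4, int(np.ceil(3.0 * np.sqrt(2.0 * indel_rate * p))))
    return abs(p_det - p_orc) <= tol


def consensus_benchmark(
    seed: int = 1,
    n_reads: int = 1000,
    copies: int = 5,
    error_rate: float = 0.05,
    period_range: Tuple[int, int] = (100, 1000),
    agreement_tol: int = 2,
) -> Dict[str, float]:
    """Period detection vs the exhaustive oracle, and consensus identity to
    the true monomer, on synthetic tandem reads."""
    rng = np.random.default_rng(derive_seed(seed, "consensus"))
    err = synth.ErrorModel(
        substitution=error_rate * 0.4,
        insertion=error_rate * 0.35,
        deletion=error_rate * 0.25,
    )
    agree = detected = 0
    identities: List[float] = []
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in range(n_reads):
        period = int(rng.integers(period_range[0], period_range[1] + 1))
        monomer = bases[rng.integers(0, 4, period)].tobytes().decode()
        noisy, quals = err.apply(monomer * copies, rng)
        read = Read(f"t{i}", noisy, quals)
        res = cons.detect_period(read)
        if res is None:
            continue
        detected += 1
        p_det = res[0]
        p_orc = oracle_period(noisy)
        if p_orc is not None and periods_agree(p_det, p_orc):
            agree += 1
        cs = cons.call_consensus(read, p_det)
        if cs is not None:
            d = edlib.align(cs.monomer, monomer, mode="NW", task="distance")[
                "editDistance"
            ]
            identities.append(1.0 - d / max(len(cs.monomer), period))
    return dict(
        n_reads=n_reads,
        detected=detected,
        period_agreement=agree / detected if detected else 0.0,
        mean_consensus_identity=float(np.mean(identities)) if identities else 0.0,
    )


# ---------------------------------------------------------------------------
# strand benchmark
# ---------------------------------------------------------------------------

def strand_benchmark(
    seed: int = 1,
    n_circ: int = 40,
    mean_reads: int = 12,
    truncate_fraction: float = 0.10,
) -> Dict[str, float]:
    """Classifier holdout metrics on a library with primer-damaged reads."""
    lib = synth.LibraryConfig(
        mean_reads_per_circ=mean_reads,
        truncate_fraction=truncate_fraction,
        low_quality_fraction=0.0,
    )
    counts = {"exonic": int(n_circ * 0.7), "intergenic": int(n_circ * 0.3)}
    genome, ann, truths, reads, table = make_study_library(
        seed, class_counts=counts, chrom_len=150_000, n_genes=30, library=lib
    )
    labels = [
        "second_strand" if row["orientation"] == "second_strand"
        else "first_strand"
        for row in table if row["circ_id"] != "linear"
    ]
    feats = st.feature_matrix(
        [r.sequence for r, row in zip(reads, table) if row["circ_id"] != "linear"]
    )
    model, acc, auc = st.train_classifier(
        feats, labels, seed=derive_seed(seed, "strand-bench")
    )
    return dict(n_reads=len(labels), accuracy=acc, auc=auc)


# ---------------------------------------------------------------------------
# fusion benchmark
# ---------------------------------------------------------------------------

def make_fusion_truth_set(
    seed: int,
    n_inter: int = 10,
    n_intra: int = 5,
) -> Tuple[Genome, Annotation, List[synth.CircTruth]]:
    """Fusion truths on a genome with one long chromosome so that both
    inter-chromosomal and >1 Mbp intra-chromosomal pairs exist."""
    genome = synth.make_genome(1, 2_600_000, 0.0, seed=derive_seed(seed, "fg"))
    g2 = synth.make_genome(1, 200_000, 0.0, seed=derive_seed(seed, "fg2"))
    genome.chromosomes["chr2"] = g2.chromosomes["chr1"]
    genome, ann = synth.make_annotation(
        genome, n_genes=36, seed=derive_seed(seed, "fa"),
        intergenic_gap=(40_000, 80_000),
    )
    rng = np.random.default_rng(derive_seed(seed, "ft"))
    chr1_genes = [g for g in ann.genes if g.chrom == "chr1"]
    chr2_genes = [g for g in ann.genes if g.chrom == "chr2"]
    truths: List[synth.CircTruth] = []

    def exon_of(g, idx=0):
        return g.transcripts[0].exons[idx]

    for i in range(n_inter):
        ga = chr1_genes[int(rng.integers(0, len(chr1_genes)))]
        gb = chr2_genes[int(rng.integers(0, len(chr2_genes)))]
        ea, eb = exon_of(ga), exon_of(gb)
        blocks = [("chr1", ea[0], ea[1]), ("chr2", eb[0], eb[1])]
        seq = genome.fetch("chr1", *ea) + genome.fetch("chr2", *eb)
        truths.append(
            synth.CircTruth(f"fusion_inter{i:02d}", "fusion", "+", blocks, seq)
        )
    for i in range(n_intra):
        lo = [g for g in chr1_genes if g.end < 700_000]
        hi = [g for g in chr1_genes if g.start > 1_800_000]
        if not lo or not hi:
            raise ValueError("gene layout cannot support intra-chrom fusions")
        ga = lo[int(rng.integers(0, len(lo)))]
        gb = hi[int(rng.integers(0, len(hi)))]
        ea, eb = exon_of(ga), exon_of(gb)
        blocks = [("chr1", ea[0], ea[1]), ("chr1", eb[0], eb[1])]
        seq = genome.fetch("chr1", *ea) + genome.fetch("chr1", *eb)
        truths.append(
            synth.CircTruth(f"fusion_intra{i:02d}", "fusion", "+", blocks, seq)
        )
    for t in truths:
        t.weight = 1.0
    return genome, ann, truths


def fusion_benchmark(
    seed: int = 1,
    error: Optional[synth.ErrorModel] = None,
    reads_per_fusion: int = 10,
) -> Dict[str, float]:
    """Junction exactness for simulated inter- and intra-chromosomal
    f-circRNAs."""
    genome, ann, truths = make_fusion_truth_set(seed)
    err = error if error is not None else synth.ErrorModel()
    lib = synth.LibraryConfig(
        mean_reads_per_circ=reads_per_fusion,
        truncate_fraction=0.0,
        low_quality_fraction=0.0,
        linear_fraction=0.0,
        error=err,
    )
    reads, table = synth.simulate_library(
        truths, ann, genome, lib, seed=derive_seed(seed, "fusion-lib")
    )
    result = run_pipeline(reads, genome, ann, seed=seed, enable_crg=False)
    truth_pairs = defaultdict(list)
    for t in truths:
        (ca, sa, ea), (cb, sb, eb) = t.blocks
        truth_pairs[(ca, (ea, sb), cb, (eb, sa))].append(t.circ_id)
    support = defaultdict(int)
    for row in table:
        support[row["circ_id"]] += 1
    found_exact = set()
    for f in result.fusion_isoforms:
        key = (f.chrom_a, f.junction_ab, f.chrom_b, f.junction_ba)
        for cid in truth_pairs.get(key, ()):
            found_exact.add(cid)
    eligible = [t.circ_id for t in truths if support[t.circ_id] >= 5]
    hit = sum(1 for cid in eligible if cid in found_exact)
    return dict(
        n_fusions=len(truths),
        n_eligible=len(eligible),
        junction_exact=hit / len(eligible) if eligible else 0.0,
        n_isoforms=len(result.fusion_isoforms),
    )


def fusion_ratio_benchmark(
    seed: int = 1,
    n_major: int = 30,
    n_minor: int = 10,
) -> Dict[str, float]:
    """A planted 3:1 two-isoform f-circRNA mixture; recovered transcript
    ratios should sit inside the binomial sampling bounds."""
    genome, ann, _ = make_fusion_truth_set(seed, n_inter=1, n_intra=0)
    g1 = next(
        g for g in ann.genes
        if g.chrom == "chr1" and len(g.transcripts[0].exons) >= 2
    )
    g2 = next(g for g in ann.genes if g.chrom == "chr2")
    e1, e2 = g1.transcripts[0].exons[:2]
    eb = g2.transcripts[0].exons[0]
    # isoform 1: spliced A locus (two exons); isoform 2: intron retained
    blocks1 = [("chr1", e1[0], e1[1]), ("chr1", e2[0], e2[1]),
               ("chr2", eb[0], eb[1])]
    seq1 = (genome.fetch("chr1", *e1) + genome.fetch("chr1", *e2)
            + genome.fetch("chr2", *eb))
    blocks2 = [("chr1", e1[0], e2[1]), ("chr2", eb[0], eb[1])]
    seq2 = genome.fetch("chr1", e1[0], e2[1]) + genome.fetch("chr2", *eb)
    t1 = synth.CircTruth("fmix_major", "fusion", "+", blocks1, seq1, 3.0)
    t2 = synth.CircTruth("fmix_minor", "fusion", "+", blocks2, seq2, 1.0)
    lib = synth.LibraryConfig(
        mean_reads_per_circ=(n_major + n_minor) // 2,
        truncate_fraction=0.0, low_quality_fraction=0.0, linear_fraction=0.0,
        error=synth.ErrorModel(),
    )
    rng = np.random.default_rng(derive_seed(seed, "fmix"))
    reads = []
    n_reads = {"fmix_major": n_major, "fmix_minor": n_minor}
    rid = 0
    for t in (t1, t2):
        for _ in range(n_reads[t.circ_id]):
            rid += 1
            copies = max(1.6, float(rng.geometric(0.4)) + float(rng.uniform(-0.5, 0.5)))
            reads.append(
                synth.simulate_rcrt_read(
                    t, copies, int(rng.integers(0, len(t.seq))),
                    "second_strand" if rng.random() < 0.5 else "first_strand",
                    lib.error, None, rng, f"fm{rid:04d}",
                )
            )
    result = run_pipeline(reads, genome, ann, seed=seed, enable_crg=False)
    # measure within the best-supported junction pair (stray read-jitter
    # clusters hold a handful of reads at most)
    by_key = defaultdict(list)
    for f in result.fusion_isoforms:
        by_key[f.junction_pair_key].append(f)
    if not by_key:
        return dict(n_isoforms=0, major_ratio=0.0,
                    expected=n_major / (n_major + n_minor),
                    n_reads=n_major + n_minor)
    main = max(
        by_key.values(), key=lambda fs: sum(f.support_reads for f in fs)
    )
    major = max(f.ratio for f in main)
    return dict(
        n_isoforms=len(main),
        major_ratio=major,
        expected=n_major / (n_major + n_minor),
        n_reads=sum(f.support_reads for f in main),
    )


# ---------------------------------------------------------------------------
# quantification benchmark
# ---------------------------------------------------------------------------

def quantification_benchmark(seed: int = 1, n_circ: int = 40,
                             mean_reads: int = 20) -> Dict[str, float]:
    """Correlation between planted abundance and recovered read counts, and
    the per-BSJ transcript-ratio normalisation."""
    counts = {"exonic": int(n_circ * 0.8), "intergenic": int(n_circ * 0.2)}
    genome, ann, truths, reads, table = make_study_library(
        seed, class_counts=counts, chrom_len=200_000, n_genes=30,
        mean_reads=mean_reads,
    )
    result = run_pipeline(reads, genome, ann, seed=seed)
    by_key = {}
    for iso in result.isoforms:
        k = (iso.chrom, iso.acceptor_start, iso.donor_end)
        by_key[k] = by_key.get(k, 0) + iso.support_reads
    weights, recovered = [], []
    for t in truths:
        k = (t.chrom, t.start, t.end)
        weights.append(t.weight)
        recovered.append(by_key.get(k, 0))
    r = float(np.corrcoef(weights, recovered)[0, 1])
    iso_df, _ = pp.quantify({"s": result.isoforms})
    sums = iso_df.groupby(["chrom", "start", "end"])["ratio_s"].sum()
    return dict(
        n_truths=len(truths),
        pearson_r=r,
        max_ratio_sum_error=float((sums - 1.0).abs().max()) if len(sums) else 0.0,
    )
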