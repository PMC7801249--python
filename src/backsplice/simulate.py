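"""Synthetic benchmark generator and evaluator.

The generator emulates the published benchmark design: a multi-gene
genome with canonical intron signals (GT-AG by default, configurable
fractions of GC-AG and AT-AC), a truth set of 200 back-spliced
transcripts, 6000 junction-spanning paired-end 100 bp reads distributed
over them, and linear background reads.  Reads are emitted both as FASTQ
(for end-to-end runs through a real chimeric-aware mapper) and as a
truth-derived SAM in which the simulator plays the aligner, writing the
correct chiastic primary + supplementary split records — so the full
pipeline is testable with no external binary.

The library is simulated as strand-specific (R1 carries the RNA sense
strand); true circles are placed over internal exon ranges so that both
back-splice boundaries carry genuine splice signals.  Sequencing error
is a uniform per-base substitution model.

Predictions are scored against the truth with TP/FP/FN, sensitivity
TP/(TP+FN), precision TP/(TP+FP) and F1 = 2*TP/(2*TP+FP+FN).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pysam

from .io import (GeneModel, GenomeSequence, Transcript, revcomp,
                 write_fasta, write_gff3, write_fastq, write_tsv)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_SNP = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}

#: genomic dinucleotides (donor-side, acceptor-side) for a + strand intron
_DONOR_ACCEPTOR = {"GT-AG": ("GT", "AG"), "GC-AG": ("GC", "AG"),
                   "AT-AC": ("AT", "AC")}


@dataclass
class SimConfig:
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    n_genes: int = 300
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (120, 300)
    intron_length: tuple[int, int] = (80, 400)
    gc_ag_fraction: float = 0.05
    at_ac_fraction: float = 0.02
    n_circrnas: int = 200
    n_bsj_reads: int = 6000
    read_length: int = 100
    paired: bool = True
    insert_mean: float = 250.0
    insert_sd: float = 25.0
    error_rate: float = 0.0
    n_background_reads: int = 6000
    min_anchor: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_bsj_reads < 2 * self.n_circrnas:
            raise ValueError("need at least 2 BSJ reads per circRNA")
        if self.exon_length[0] < self.read_length + 2 * 0:
            # boundary exons must hold a read arm (read_length - min_anchor)
            if self.exon_length[0] < self.read_length - self.min_anchor:
                raise ValueError("minimum exon length too short for read arms")


@dataclass
class TruthCirc:
    chrom: str
    start: int
    end: int
    strand: str
    transcript_id: str
    n_reads: int = 0

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class SimTruth:
    circs: list[TruthCirc] = field(default_factory=list)

    def keys(self) -> set[tuple[str, int, int, str]]:
        return {c.key for c in self.circs}


@dataclass
class Metrics:
    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------

def simulate_genome_annotation(config: SimConfig,
                               rng: np.random.Generator | None = None
                               ) -> tuple[GenomeSequence, list[GeneModel]]:
    """Random genome with non-overlapping genes and canonical introns.

    Every intron is written with its splice-site dinucleotides (a
    configurable fraction GC-AG / AT-AC, the rest GT-AG), on the gene's
    strand, so annotation-free signal checking works on the simulated
    genome.  Deterministic under the config seed.
    """
    rng = rng or np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    seqs = {
        name: rng.choice(_BASES, size=config.chromosome_length)
        for name in chrom_names
    }
    genes: list[GeneModel] = []
    per_chrom = np.array_split(np.arange(config.n_genes),
                               config.n_chromosomes)
    for ci, gene_idx in enumerate(per_chrom):
        chrom = chrom_names[ci]
        arr = seqs[chrom]
        cursor = 1
        for gi in gene_idx:
            n_ex = int(rng.integers(config.exons_per_gene[0],
                                    config.exons_per_gene[1] + 1))
            ex_lens = rng.integers(config.exon_length[0],
                                   config.exon_length[1] + 1, size=n_ex)
            in_lens = rng.integers(config.intron_length[0],
                                   config.intron_length[1] + 1,
                                   size=n_ex - 1)
            gap = int(rng.integers(200, 1000))
            start = cursor + gap
            length = int(ex_lens.sum() + in_lens.sum())
            if start + length - 1 > config.chromosome_length:
                raise ValueError(
                    f"genes do not fit chromosome {chrom}; reduce n_genes "
                    f"or enlarge chromosome_length")
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = start
            introns = []
            for k in range(n_ex):
                exons.append((pos, pos + int(ex_lens[k]) - 1))
                pos += int(ex_lens[k])
                if k < n_ex - 1:
                    introns.append((pos, pos + int(in_lens[k]) - 1))
                    pos += int(in_lens[k])
            # stamp splice signals into the genome
            for istart, iend in introns:
                r = rng.random()
                if r < config.at_ac_fraction:
                    sig = "AT-AC"
                elif r < config.at_ac_fraction + config.gc_ag_fraction:
                    sig = "GC-AG"
                else:
                    sig = "GT-AG"
                donor, acceptor = _DONOR_ACCEPTOR[sig]
                if strand == "+":
                    left, right = donor, acceptor
                else:
                    left, right = revcomp(acceptor), revcomp(donor)
                arr[istart - 1] = left[0].encode()
                arr[istart] = left[1].encode()
                arr[iend - 2] = right[0].encode()
                arr[iend - 1] = right[1].encode()
            tid = f"t{gi}"
            gene = GeneModel(gene_id=f"g{gi}", chrom=chrom, strand=strand,
                             transcripts=[Transcript(tid, exons)])
            genes.append(gene)
            cursor = start + length
    genome = GenomeSequence(
        {name: arr.tobytes().decode() for name, arr in seqs.items()})
    return genome, genes


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def _mutate(seq: str, error_rate: float,
            rng: np.random.Generator) -> tuple[str, list[int]]:
    """Apply uniform substitutions; returns (sequence, 0-based positions)."""
    if error_rate <= 0:
        return seq, []
    hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
    if hits.size == 0:
        return seq, []
    out = list(seq)
    for i in hits:
        out[i] = _SNP[out[i]][int(rng.integers(3))]
    return "".join(out), [int(i) for i in hits]


def _sam_record(header, name, flag, chrom, pos, cigar, seq, nm, as_score,
                sa=None, rnext=None, pnext=None):
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.flag = flag
    rec.reference_id = header.get_tid(chrom)
    rec.reference_start = pos - 1
    rec.mapping_quality = 60
    rec.cigarstring = cigar
    rec.query_sequence = seq
    rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    tags = [("NM", int(nm)), ("AS", int(as_score))]
    if sa:
        tags.append(("SA", sa))
    rec.tags = tags
    if rnext is not None:
        rec.next_reference_id = header.get_tid(rnext)
        rec.next_reference_start = pnext - 1
    return rec


@dataclass
class SimReads:
    fastq1: list[tuple[str, str, str]]
    fastq2: list[tuple[str, str, str]]
    sam_records: list
    header: "pysam.AlignmentHeader"
    truth: SimTruth


def _spliced_blocks(exons: list[tuple[int, int]], lo: int, hi: int
                    ) -> list[tuple[int, int]]:
    """Genomic blocks covered by spliced positions [lo, hi] (1-based on the
    + strand spliced sequence)."""
    blocks = []
    offset = 0
    for es, ee in exons:
        elen = ee - es + 1
        s = max(lo, offset + 1)
        e = min(hi, offset + elen)
        if s <= e:
            blocks.append((es + (s - offset - 1), es + (e - offset - 1)))
        offset += elen
    return blocks


def _blocks_to_cigar(blocks: list[tuple[int, int]],
                     lead_clip: int, trail_clip: int) -> str:
    parts = []
    if lead_clip:
        parts.append(f"{lead_clip}S")
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1] - 1
            parts.append(f"{gap}N")
        parts.append(f"{e - s + 1}M")
    if trail_clip:
        parts.append(f"{trail_clip}S")
    return "".join(parts)


def simulate_circ_reads(genome: GenomeSequence,
                        annotation: list[GeneModel],
                        config: SimConfig,
                        rng: np.random.Generator | None = None) -> SimReads:
    """Sample true circles, BSJ reads, mates and linear background reads.

    Circles are placed over internal exon ranges of randomly chosen
    multi-exon transcripts; BSJ read totals are distributed multinomially
    with a floor of two reads per circle.  Each BSJ read spans the seam
    with at least ``min_anchor`` bases on both sides; its arms stay
    within the boundary exons so the truth SAM holds exactly two chiastic
    segments per read.  Mates are placed inside the circle.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    rl = config.read_length
    eligible = [(g, g.transcripts[0]) for g in annotation
                if len(g.transcripts[0].exons) >= 3]
    if len(eligible) < config.n_circrnas:
        raise ValueError(
            f"only {len(eligible)} transcripts with >=3 exons; "
            f"cannot place {config.n_circrnas} circRNAs")
    chosen = rng.choice(len(eligible), size=config.n_circrnas, replace=False)

    truth = SimTruth()
    circ_info = []
    for idx in sorted(int(i) for i in chosen):
        gene, tr = eligible[idx]
        k = len(tr.exons)
        a = int(rng.integers(2, k))          # internal range: exons a..b
        b = int(rng.integers(a, k))
        start = tr.exons[a - 1][0]
        end = tr.exons[b - 1][1]
        truth.circs.append(TruthCirc(gene.chrom, start, end, gene.strand,
                                     tr.transcript_id))
        circ_info.append((gene, tr, a, b))

    n_extra = config.n_bsj_reads - 2 * config.n_circrnas
    extra = rng.multinomial(n_extra,
                            np.full(config.n_circrnas, 1 / config.n_circrnas))
    for tc, e in zip(truth.circs, extra):
        tc.n_reads = 2 + int(e)

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": genome.length(name)} for name in genome],
    })

    fastq1: list[tuple[str, str, str]] = []
    fastq2: list[tuple[str, str, str]] = []
    records = []
    qual = "I" * rl

    for ci, ((gene, tr, a, b), tc) in enumerate(zip(circ_info, truth.circs)):
        chrom, strand = gene.chrom, gene.strand
        start, end = tc.start, tc.end
        exon_first = tr.exons[a - 1]
        exon_last = tr.exons[b - 1]
        circ_exons = tr.exons[a - 1:b]
        for rj in range(tc.n_reads):
            rid = f"circ{ci}_r{rj}"
            # donor-arm length in RNA terms, constrained to boundary exons
            if strand == "+":
                hi_exon, lo_exon = exon_last, exon_first
            else:
                hi_exon, lo_exon = exon_first, exon_last
            amin = max(config.min_anchor,
                       rl - (lo_exon[1] - lo_exon[0] + 1))
            amax = min(rl - config.min_anchor, hi_exon[1] - hi_exon[0] + 1)
            alen = int(rng.integers(amin, amax + 1))
            blen = rl - alen
            if strand == "+":
                part1 = genome.fetch(chrom, end - alen + 1, end)
                part2 = genome.fetch(chrom, start, start + blen - 1)
                seq = part1 + part2
            else:
                part1 = revcomp(genome.fetch(chrom, start, start + alen - 1))
                part2 = revcomp(genome.fetch(chrom, end - blen + 1, end))
                seq = part1 + part2
            seq, errs = _mutate(seq, config.error_rate, rng)
            nm1 = sum(1 for p in errs if p < alen)
            nm2 = len(errs) - nm1
            fastq1.append((rid, seq, qual))
            # SAM: two chiastic segments, longer arm primary
            if strand == "+":
                seg1 = (chrom, end - alen + 1, "+", f"{alen}M{blen}S",
                        nm1, alen - 2 * nm1)
                seg2 = (chrom, start, "+", f"{alen}S{blen}M",
                        nm2, blen - 2 * nm2)
                stored1 = stored2 = seq
                flagstrand = 0
            else:
                seg1 = (chrom, start, "-", f"{blen}S{alen}M",
                        nm1, alen - 2 * nm1)
                seg2 = (chrom, end - blen + 1, "-", f"{blen}M{alen}S",
                        nm2, blen - 2 * nm2)
                stored1 = stored2 = revcomp(seq)
                flagstrand = 0x10
            primary, supp = (seg1, seg2) if alen >= blen else (seg2, seg1)
            sa_of = lambda s: f"{s[0]},{s[1]},{s[2]},{s[3]},60,{s[4]};"
            base_flag = (0x1 | 0x40) if config.paired else 0
            # mate inside the circle, within one exon
            mate_rec = None
            if config.paired:
                ex = circ_exons[int(rng.integers(len(circ_exons)))]
                mstart = int(rng.integers(ex[0], ex[1] - rl + 2))
                mseq_fwd = genome.fetch(chrom, mstart, mstart + rl - 1)
                if strand == "+":
                    mate_read = revcomp(mseq_fwd)   # R2 antisense of RNA
                    mate_flag = 0x1 | 0x80 | 0x10
                else:
                    mate_read = mseq_fwd
                    mate_flag = 0x1 | 0x80
                mate_read, merrs = _mutate(mate_read, config.error_rate, rng)
                fastq2.append((rid, mate_read, qual))
                mstored = (revcomp(mate_read) if mate_flag & 0x10
                           else mate_read)
                mate_rec = _sam_record(
                    header, rid, mate_flag, chrom, mstart, f"{rl}M",
                    mstored, len(merrs), rl - 2 * len(merrs),
                    rnext=chrom, pnext=primary[1])
                base_flag |= 0x20 if (mate_flag & 0x10) else 0
            records.append(_sam_record(
                header, rid, base_flag | flagstrand, primary[0], primary[1],
                primary[3], stored1, primary[4], primary[5],
                sa=sa_of(supp),
                rnext=chrom if config.paired else None,
                pnext=(mate_rec.reference_start + 1) if mate_rec else None))
            records.append(_sam_record(
                header, rid, base_flag | flagstrand | 0x800, supp[0],
                supp[1], supp[3], stored1, supp[4], supp[5],
                sa=sa_of(primary),
                rnext=chrom if config.paired else None,
                pnext=(mate_rec.reference_start + 1) if mate_rec else None))
            if mate_rec is not None:
                records.append(mate_rec)

    # linear background reads from transcripts without a circle
    circ_tids = {tc.transcript_id for tc in truth.circs}
    linear = [(g, g.transcripts[0]) for g in annotation
              if g.transcripts[0].transcript_id not in circ_tids]
    if not linear:
        linear = [(g, g.transcripts[0]) for g in annotation]
    for li in range(config.n_background_reads):
        gene, tr = linear[int(rng.integers(len(linear)))]
        spliced_len = sum(e - s + 1 for s, e in tr.exons)
        if spliced_len < rl:
            continue
        rid = f"lin{li}"
        lo = int(rng.integers(1, spliced_len - rl + 2))
        hi = lo + rl - 1
        # spliced + strand coordinates; RNA sense depends on gene strand
        blocks = _spliced_blocks(tr.exons, lo, hi)
        plus_seq = "".join(genome.fetch(gene.chrom, s, e) for s, e in blocks)
        read = plus_seq if gene.strand == "+" else revcomp(plus_seq)
        read, errs = _mutate(read, config.error_rate, rng)
        fastq1.append((rid, read, qual))
        flag = (0x1 | 0x40) if config.paired else 0
        if gene.strand == "-":
            flag |= 0x10
        stored = read if gene.strand == "+" else revcomp(read)
        cigar = _blocks_to_cigar(blocks, 0, 0)
        records.append(_sam_record(
            header, rid, flag, gene.chrom, blocks[0][0], cigar, stored,
            len(errs), rl - 2 * len(errs)))
        if config.paired:
            # mate: another window of the same transcript
            mlo = int(rng.integers(1, spliced_len - rl + 2))
            mblocks = _spliced_blocks(tr.exons, mlo, mlo + rl - 1)
            mplus = "".join(genome.fetch(gene.chrom, s, e)
                            for s, e in mblocks)
            mate_read = revcomp(mplus) if gene.strand == "+" else mplus
            mate_read, merrs = _mutate(mate_read, config.error_rate, rng)
            fastq2.append((rid, mate_read, qual))
            mflag = 0x1 | 0x80 | (0x10 if gene.strand == "+" else 0)
            mstored = revcomp(mate_read) if mflag & 0x10 else mate_read
            records.append(_sam_record(
                header, rid, mflag, gene.chrom, mblocks[0][0],
                _blocks_to_cigar(mblocks, 0, 0), mstored, len(merrs),
                rl - 2 * len(merrs)))

    return SimReads(fastq1=fastq1, fastq2=fastq2, sam_records=records,
                    header=header, truth=truth)


def write_sim_outputs(sim: SimReads, out_dir: str | os.PathLike,
                      prefix: str = "sim") -> dict[str, str]:
    """Write FASTQ(s), SAM and truth TSV; returns the path map."""
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    paths["fastq1"] = os.path.join(out_dir, f"{prefix}_R1.fastq")
    write_fastq(sim.fastq1, paths["fastq1"])
    if sim.fastq2:
        paths["fastq2"] = os.path.join(out_dir, f"{prefix}_R2.fastq")
        write_fastq(sim.fastq2, paths["fastq2"])
    paths["sam"] = os.path.join(out_dir, f"{prefix}.sam")
    with pysam.AlignmentFile(paths["sam"], "w", header=sim.header) as fh:
        for rec in sim.sam_records:
            fh.write(rec)
    paths["truth"] = os.path.join(out_dir, f"{prefix}_truth.tsv")
    write_truth_tsv(sim.truth, paths["truth"])
    return paths


def write_truth_tsv(truth: SimTruth, path) -> None:
    cols = ["chrom", "start", "end", "strand", "transcript", "n_reads"]
    rows = [{"chrom": c.chrom, "start": c.start, "end": c.end,
             "strand": c.strand, "transcript": c.transcript_id,
             "n_reads": c.n_reads} for c in truth.circs]
    write_tsv(rows, cols, path)


def read_truth_tsv(path) -> SimTruth:
    truth = SimTruth()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, strand, tid, n = line.rstrip("\n").split("\t")
            truth.circs.append(TruthCirc(chrom, int(start), int(end),
                                         strand, tid, int(n)))
    return truth


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(predictions: list[tuple[str, int, int, str]],
             truth: SimTruth | list[tuple[str, int, int, str]],
             tolerance: int = 0) -> Metrics:
    """Score predicted junction keys against the truth set.

    A prediction matches a still-unmatched truth circle on the same
    chromosome and strand with both coordinates within ``tolerance``.
    """
    truth_keys = list(truth.keys() if isinstance(truth, SimTruth) else truth)
    unmatched = set(range(len(truth_keys)))
    tp = fp = 0
    for chrom, start, end, strand in predictions:
        hit = None
        for ti in unmatched:
            tc, ts, te, tstr = truth_keys[ti]
            if (tc == chrom and tstr == strand
                    and abs(ts - start) <= tolerance
                    and abs(te - end) <= tolerance):
                hit = ti
                break
        if hit is None:
            fp += 1
        else:
            tp += 1
            unmatched.remove(hit)
    return Metrics(tp=tp, fp=fp, fn=len(unmatched))


def write_metrics_tsv(metrics: Metrics, path) -> None:
    cols = ["tp", "fp", "fn", "sensitivity", "precision", "f1"]
    write_tsv([{"tp": metrics.tp, "fp": metrics.fp, "fn": metrics.fn,
                "sensitivity": f"{metrics.sensitivity:.4f}",
                "precision": f"{metrics.precision:.4f}",
                "f1": f"{metrics.f1:.4f}"}], cols, path)
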