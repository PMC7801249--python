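"""Back-splice junction calling from chiastic split reads.

A read spanning a back-splice junction (BSJ) aligns in two segments whose
order along the read is *reversed* relative to their order on the
reference (chiastic): the 5' part of the read maps downstream of the 3'
part.  Candidates are screened with plant-specific criteria: a 20 kb
default / 100 kb maximum genomic span (plant circRNAs are short), strict
per-segment mismatch and alignment-score thresholds (plant genomes are
rich in duplicated sequence), donor/acceptor adjustment within a 5 bp
window, and splice-signal classification covering the major (GT-AG,
GC-AG) and minor (AT-AC) spliceosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .io import (AlignmentSegment, GeneModel, GenomeSequence,
                 SplitReadAlignment, revcomp, write_tsv, to_bed6)

log = logging.getLogger(__name__)

SIGNAL_PRIORITY = ("GT-AG", "GC-AG", "AT-AC")
_SIGNALS = {("GT", "AG"): "GT-AG", ("GC", "AG"): "GC-AG", ("AT", "AC"): "AT-AC"}


@dataclass
class DetectionConfig:
    """Screening thresholds for candidate back-splice junctions."""
    default_length: int = 20_000     # spans above this are flagged "long"
    max_length: int = 100_000        # spans above this are rejected
    max_shift: int = 5               # donor/acceptor adjustment window (bp)
    min_junction_reads: int = 2
    max_mismatches: int = 2          # per segment
    min_score_fraction: float = 0.8  # of segment read length
    require_paired_consistency: bool = True

    def __post_init__(self):
        if not (0 < self.default_length <= self.max_length):
            raise ValueError("need 0 < default_length <= max_length")
        if self.min_junction_reads < 1:
            raise ValueError("min_junction_reads must be >= 1")


@dataclass
class BackspliceCandidate:
    """A putative circRNA junction.

    ``start`` is the acceptor (5' boundary of the circle) and ``end`` the
    donor (3' boundary), both 1-based inclusive, so the circularized
    genomic interval is ``[start, end]``.
    """
    chrom: str
    start: int
    end: int
    strand: str
    signal: str = "none"             # GT-AG / GC-AG / AT-AC / none
    acceptor_offset: int = 0
    donor_offset: int = 0
    read_ids: list[str] = field(default_factory=list)
    circ_type: str = "intergenic"
    flags: set[str] = field(default_factory=set)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}|{self.end}({self.strand})"


def _segment_passes(seg: AlignmentSegment, config: DetectionConfig) -> bool:
    if seg.mismatches > config.max_mismatches:
        return False
    if seg.score is not None:
        return seg.score >= config.min_score_fraction * seg.read_length
    # no AS tag: fall back to matched-bases proxy
    return (seg.read_length - seg.mismatches) >= \
        config.min_score_fraction * seg.read_length


def chiastic_candidate(split_read: SplitReadAlignment,
                       config: DetectionConfig | None = None
                       ) -> BackspliceCandidate | None:
    """Call a BSJ candidate from one split read, or None.

    Requires exactly two segments on the same chromosome and strand, both
    passing the per-segment mismatch/score thresholds, in chiastic order:
    on the + strand the segment earlier in the read maps strictly
    downstream of the later one (mirrored on the - strand).  Colinear
    splits are linear splice junctions and yield nothing.
    """
    config = config or DetectionConfig()
    if split_read.ambiguous or len(split_read.segments) != 2:
        return None
    first, second = split_read.sorted_segments()
    if first.chrom != second.chrom or first.strand != second.strand:
        return None
    if not (_segment_passes(first, config) and _segment_passes(second, config)):
        return None
    if first.strand == "+":
        if first.ref_start <= second.ref_end:     # colinear or overlapping
            return None
        start, end = second.ref_start, first.ref_end
    else:
        if second.ref_start <= first.ref_end:
            return None
        start, end = first.ref_start, second.ref_end
    return BackspliceCandidate(
        chrom=first.chrom, start=start, end=end, strand=first.strand,
        read_ids=[split_read.read_id],
    )


def check_splice_signal(genome: GenomeSequence,
                        cand: BackspliceCandidate,
                        acceptor_offset: int = 0,
                        donor_offset: int = 0) -> str:
    """Classify the intron-side dinucleotides flanking a junction.

    On the + strand the donor-side dinucleotide is genome[end+1..end+2]
    and the acceptor-side genome[start-2..start-1]; on the - strand the
    same test is applied to the reverse complement with donor/acceptor
    roles mirrored.  A junction at a chromosome edge has signal "none".
    """
    start = cand.start + acceptor_offset
    end = cand.end + donor_offset
    if start >= end:
        return "none"
    clen = genome.length(cand.chrom)
    if start - 2 < 1 or end + 2 > clen:
        return "none"
    left = genome.fetch(cand.chrom, start - 2, start - 1)
    right = genome.fetch(cand.chrom, end + 1, end + 2)
    if cand.strand == "+":
        donor, acceptor = right, left
    else:
        donor, acceptor = revcomp(left), revcomp(right)
    return _SIGNALS.get((donor, acceptor), "none")


def adjust_backsplice_site(genome: GenomeSequence,
                           cand: BackspliceCandidate,
                           max_shift: int = 5) -> BackspliceCandidate:
    """Search +-max_shift bp around both junction boundaries for a
    canonical splice signal.

    Offset pairs are visited in increasing total shift |da|+|dd|; ties are
    broken by signal priority GT-AG > GC-AG > AT-AC, then by smaller
    donor shift.  If the candidate already has a signal at (0, 0), or no
    signal exists anywhere in the window, it is returned unchanged.
    """
    best: tuple[int, int, int, int, int] | None = None
    best_hit: tuple[int, int, str] | None = None
    for da in range(-max_shift, max_shift + 1):
        for dd in range(-max_shift, max_shift + 1):
            sig = check_splice_signal(genome, cand, da, dd)
            if sig == "none":
                continue
            rank = (abs(da) + abs(dd), SIGNAL_PRIORITY.index(sig),
                    abs(dd), abs(da), dd)
            if best is None or rank < best:
                best = rank
                best_hit = (da, dd, sig)
    if best_hit is None:
        return cand
    da, dd, sig = best_hit
    return replace(cand, start=cand.start + da, end=cand.end + dd,
                   signal=sig, acceptor_offset=da, donor_offset=dd)


def annotation_boundary_snap(cand: BackspliceCandidate,
                             annotation: list[GeneModel] | None,
                             max_shift: int = 5
                             ) -> BackspliceCandidate | None:
    """Snap a candidate to matching annotated exon boundaries.

    Annotation and splice signal are complementary evidence: a junction
    whose boundaries coincide with exon boundaries of one transcript
    (within ``max_shift``) is accepted at those boundaries even when the
    signal classifier says none — the two flanking introns of a back-
    splice need not share a signal class.  Returns the snapped candidate
    (minimal total shift) or None if no transcript matches.
    """
    if not annotation:
        return None
    best = None
    for gene in annotation:
        if gene.chrom != cand.chrom or gene.strand != cand.strand:
            continue
        for tr in gene.transcripts:
            starts = [es for es, _ in tr.exons
                      if abs(es - cand.start) <= max_shift]
            ends = [ee for _, ee in tr.exons
                    if abs(ee - cand.end) <= max_shift]
            for es in starts:
                for ee in ends:
                    if es >= ee:
                        continue
                    shift = abs(es - cand.start) + abs(ee - cand.end)
                    rank = (shift, es, ee)
                    if best is None or rank < best[0]:
                        best = (rank, es, ee)
    if best is None:
        return None
    _, es, ee = best
    return replace(cand, start=es, end=ee,
                   acceptor_offset=es - cand.start,
                   donor_offset=ee - cand.end,
                   flags=cand.flags | {"annotation-snapped"})


def paired_end_consistent(cand: BackspliceCandidate,
                          mate_segments: list[AlignmentSegment] | None,
                          slack: int = 5) -> bool:
    """A junction read's mate must fall inside the inferred circle.

    True iff the mate aligns within [start - slack, end + slack] on the
    same chromosome; single-end data (no mate) is vacuously consistent.
    """
    if not mate_segments:
        return True
    for seg in mate_segments:
        if (seg.chrom == cand.chrom
                and seg.ref_start >= cand.start - slack
                and seg.ref_end <= cand.end + slack):
            return True
    return False


def aggregate_and_filter(candidates: list[BackspliceCandidate],
                         config: DetectionConfig | None = None,
                         consistent_reads: set[str] | None = None
                         ) -> list[BackspliceCandidate]:
    """Pool per-read candidates by junction key and apply the filters.

    Candidates are grouped by (chrom, start, end, strand) *after* site
    adjustment.  Groups survive iff they have >= min_junction_reads
    supporting reads and genomic span <= max_length; spans above the
    default threshold are kept but flagged "long".  When paired-end
    consistency is required, at least one supporting read must be in
    ``consistent_reads`` (None disables the check, e.g. single-end data).
    """
    config = config or DetectionConfig()
    pooled: dict[tuple, BackspliceCandidate] = {}
    for cand in candidates:
        kept = pooled.get(cand.key)
        if kept is None:
            pooled[cand.key] = replace(
                cand, read_ids=list(cand.read_ids), flags=set(cand.flags))
        else:
            kept.read_ids.extend(cand.read_ids)
            kept.flags |= cand.flags
    out: list[BackspliceCandidate] = []
    for cand in pooled.values():
        cand.read_ids = sorted(set(cand.read_ids))
        if cand.span > config.max_length:
            continue
        if len(cand.read_ids) < config.min_junction_reads:
            continue
        if (config.require_paired_consistency
                and consistent_reads is not None
                and not any(r in consistent_reads for r in cand.read_ids)):
            continue
        if cand.span > config.default_length:
            cand.flags.add("long")
        out.append(cand)
    out.sort(key=lambda c: (c.chrom, c.start, c.end, c.strand))
    return out


def classify_circ_type(cand: BackspliceCandidate,
                       annotation: list[GeneModel] | None,
                       tolerance: int = 5) -> str:
    """Type a junction as exonic, intronic or intergenic.

    Exonic: some transcript has an exon starting at ``start`` and an exon
    ending at ``end`` (each within +-tolerance, same transcript).
    Intronic: the interval lies wholly inside one intron of some
    transcript.  Otherwise intergenic.  Without annotation every
    candidate is intergenic and flagged "no-annotation".
    """
    if not annotation:
        cand.flags.add("no-annotation")
        return "intergenic"
    for gene in annotation:
        if gene.chrom != cand.chrom:
            continue
        for tr in gene.transcripts:
            if not tr.exons:
                continue
            start_ok = any(abs(es - cand.start) <= tolerance
                           for es, _ in tr.exons)
            end_ok = any(abs(ee - cand.end) <= tolerance
                         for _, ee in tr.exons)
            if start_ok and end_ok:
                return "exonic"
    for gene in annotation:
        if gene.chrom != cand.chrom:
            continue
        for tr in gene.transcripts:
            for istart, iend in tr.introns():
                if istart <= cand.start and cand.end <= iend:
                    return "intronic"
    return "intergenic"


def detect_candidates(split_reads: list[SplitReadAlignment],
                      genome: GenomeSequence,
                      annotation: list[GeneModel] | None = None,
                      config: DetectionConfig | None = None,
                      paired: bool = False) -> list[BackspliceCandidate]:
    """Full detection pass: chiastic calling, site adjustment, paired-end
    consistency, pooling/filtering and annotation typing."""
    config = config or DetectionConfig()
    mates: dict[tuple[str, int], list[AlignmentSegment]] = {}
    if paired:
        for sr in split_reads:
            mates[(sr.read_id, sr.mate)] = sr.segments
    per_read: list[BackspliceCandidate] = []
    consistent: set[str] = set()
    n_ambiguous = sum(1 for sr in split_reads if sr.ambiguous)
    for sr in split_reads:
        cand = chiastic_candidate(sr, config)
        if cand is None:
            continue
        snapped = annotation_boundary_snap(cand, annotation, config.max_shift)
        if snapped is not None:
            cand = snapped
            cand.signal = check_splice_signal(genome, cand)
        else:
            cand = adjust_backsplice_site(genome, cand, config.max_shift)
        if paired:
            other = 1 if sr.mate == 2 else 2
            mate_segs = mates.get((sr.read_id, other))
            if paired_end_consistent(cand, mate_segs):
                consistent.add(sr.read_id)
        per_read.append(cand)
    if n_ambiguous:
        log.info("detect: %d ambiguous split read(s) excluded", n_ambiguous)
    filtered = aggregate_and_filter(
        per_read, config, consistent if paired else None)
    for cand in filtered:
        cand.circ_type = classify_circ_type(cand, annotation,
                                            tolerance=config.max_shift)
    return filtered


def write_candidates_tsv(candidates: list[BackspliceCandidate],
                         path) -> None:
    cols = ["chrom", "start", "end", "strand", "junction_reads", "signal",
            "circ_type", "flags"]
    rows = [{
        "chrom": c.chrom, "start": c.start, "end": c.end, "strand": c.strand,
        "junction_reads": len(c.read_ids), "signal": c.signal,
        "circ_type": c.circ_type,
        "flags": ",".join(sorted(c.flags)) or ".",
    } for c in candidates]
    write_tsv(rows, cols, path)


def read_candidates_tsv(path) -> list[BackspliceCandidate]:
    """Read back a candidates TSV (supporting read ids are not restored;
    placeholder ids preserve the junction-read count)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, strand, nreads, signal, ctype, flags = \
                line.rstrip("\n").split("\t")[:8]
            cand = BackspliceCandidate(
                chrom=chrom, start=int(start), end=int(end), strand=strand,
                signal=signal, circ_type=ctype,
                read_ids=[f"read{i}" for i in range(int(nreads))],
                flags=set() if flags == "." else set(flags.split(",")))
            out.append(cand)
    return out


def write_candidates_bed(candidates: list[BackspliceCandidate], path) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(to_bed6(c.chrom, c.start, c.end, c.name,
                             len(c.read_ids), c.strand) + "\n")
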