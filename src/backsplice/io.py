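"""Readers/writers and coordinate arithmetic shared by the whole pipeline.

Conventions
-----------
* All coordinates are 1-based and inclusive internally.  BED-style output
  converts to 0-based half-open at the writer boundary only.
* Read intervals of alignment segments are expressed in *read orientation*
  (the orientation of the bases as sequenced), so that segments of one read
  can be ordered along the read regardless of mapping strand.
"""

from __future__ import annotations

import io as _io
import os
import re
import logging
from dataclasses import dataclass, field

import pysam
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC ambiguity codes other than N are collapsed to N on load.
_IUPAC_EXTRA = set("RYSWKMBDHV")
_VALID_CHARS = set("ACGTN") | _IUPAC_EXTRA


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Genome sequences
# ---------------------------------------------------------------------------

class GenomeSequence:
    """In-memory genome: chromosome name -> uppercase DNA string.

    Lookups use 1-based inclusive coordinates; ``fetch(c, s, e)`` returns a
    string of length ``e - s + 1``.  Queries running off a chromosome edge
    raise ``IndexError`` (callers that tolerate edges must clamp first).
    """

    def __init__(self, sequences: dict[str, str] | None = None):
        self._seqs: dict[str, str] = {}
        if sequences:
            for name, seq in sequences.items():
                self.add(name, seq)

    def add(self, name: str, seq: str) -> None:
        if name in self._seqs:
            raise FormatError(f"duplicate sequence name: {name!r}")
        seq = seq.upper()
        bad = set(seq) - _VALID_CHARS
        if bad:
            raise FormatError(
                f"record {name!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        if set(seq) & _IUPAC_EXTRA:
            seq = re.sub("[" + "".join(sorted(_IUPAC_EXTRA)) + "]", "N", seq)
        self._seqs[name] = seq

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __iter__(self):
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def items(self):
        return self._seqs.items()

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Substring of ``chrom`` for the 1-based inclusive interval."""
        seq = self._seqs[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise IndexError(
                f"interval {chrom}:{start}-{end} outside 1..{len(seq)}"
            )
        return seq[start - 1:end]

    def fetch_clamped(self, chrom: str, start: int, end: int) -> str:
        """Like :meth:`fetch` but truncated at chromosome edges."""
        seq = self._seqs[chrom]
        return seq[max(start, 1) - 1:min(end, len(seq))]


def read_fasta(path: str | os.PathLike) -> GenomeSequence:
    """Load a FASTA file into a :class:`GenomeSequence`.

    Multi-line records are concatenated and uppercased; duplicate record
    names and non-IUPAC characters are format errors.
    """
    genome = GenomeSequence()
    with open(path) as fh:
        first = fh.read(1)
        if first == "":
            raise FormatError(f"{path}: empty FASTA file")
        if first != ">":
            raise FormatError(f"{path}: FASTA must begin with '>'")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            genome.add(rec.id, str(rec.seq))
    if len(genome) == 0:
        raise FormatError(f"{path}: no FASTA records")
    return genome


def write_fasta(genome: GenomeSequence | dict[str, str],
                path: str | os.PathLike, width: int = 60) -> None:
    items = genome.items() if hasattr(genome, "items") else genome
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | os.PathLike) -> list[tuple[str, str, str]]:
    """Read FASTQ (Phred+33) into ``(read id, sequence, quality)`` tuples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq).upper(), quals))
    return out


def write_fastq(reads: list[tuple[str, str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Gene models (GFF3)
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # 1-based incl.

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)


def read_gff3(path: str | os.PathLike,
              known_chroms: set[str] | None = None) -> list[GeneModel]:
    """Parse gene/mRNA/exon features from a GFF3 file into GeneModels.

    Exons are grouped per transcript via their Parent attribute and sorted
    by start.  Exons whose Parent does not resolve are skipped with a
    logged count; transcripts without exons are kept but flagged
    ``no-exons``.  Genes on chromosomes absent from ``known_chroms`` (when
    given) are flagged ``unplaced``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    genes: list[GeneModel] = []
    skipped = 0
    for g in db.features_of_type("gene", order_by="start"):
        model = GeneModel(gene_id=g.id, chrom=g.seqid, strand=g.strand)
        if known_chroms is not None and g.seqid not in known_chroms:
            model.flags.add("unplaced")
        for t in db.children(g, level=1):
            if t.featuretype not in ("mRNA", "transcript"):
                continue
            tr = Transcript(transcript_id=t.id)
            for ex in db.children(t, featuretype="exon", order_by="start"):
                tr.exons.append((ex.start, ex.end))
            tr.exons.sort()
            if not tr.exons:
                model.flags.add("no-exons")
            model.transcripts.append(tr)
        genes.append(model)
    # exons whose Parent resolves to nothing at all
    for ex in db.features_of_type("exon"):
        parents = list(db.parents(ex, level=1))
        if not parents:
            skipped += 1
    if skipped:
        log.warning("read_gff3: skipped %d exon(s) with unresolvable Parent", skipped)
    return genes


def write_gff3(genes: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            starts = [t.span[0] for t in g.transcripts if t.exons]
            ends = [t.span[1] for t in g.transcripts if t.exons]
            gs, ge = (min(starts), max(ends)) if starts else (1, 1)
            fh.write(f"{g.chrom}\t.\tgene\t{gs}\t{ge}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            for t in g.transcripts:
                ts, te = t.span if t.exons else (gs, ge)
                fh.write(f"{g.chrom}\t.\tmRNA\t{ts}\t{te}\t.\t{g.strand}\t.\t"
                         f"ID={t.transcript_id};Parent={g.gene_id}\n")
                for i, (es, ee) in enumerate(t.exons, 1):
                    fh.write(f"{g.chrom}\t.\texon\t{es}\t{ee}\t.\t{g.strand}\t.\t"
                             f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n")


# ---------------------------------------------------------------------------
# CIGAR arithmetic
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_READ_CONSUMING = set("MIS=X")
_REF_CONSUMING = set("MDN=X")


def parse_cigar(cigar: str) -> tuple[list[tuple[int, str]], int, int]:
    """Parse a CIGAR string.

    Returns ``(ops, read_span, ref_span)`` where read span sums M/I/S/=/X
    lengths and reference span sums M/D/N/=/X; hard clips consume neither.
    """
    if not cigar or cigar == "*":
        raise FormatError("empty CIGAR")
    ops: list[tuple[int, str]] = []
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise FormatError(f"malformed CIGAR: {cigar!r}")
        ops.append((int(m.group(1)), m.group(2)))
        pos = m.end()
    if pos != len(cigar):
        raise FormatError(f"malformed CIGAR: {cigar!r}")
    read_span = sum(n for n, op in ops if op in _READ_CONSUMING)
    ref_span = sum(n for n, op in ops if op in _REF_CONSUMING)
    return ops, read_span, ref_span


def _clip_lengths(ops: list[tuple[int, str]]) -> tuple[int, int]:
    """(leading, trailing) soft+hard clip lengths of a CIGAR op list."""
    lead = trail = 0
    i = 0
    while i < len(ops) and ops[i][1] in "SH":
        lead += ops[i][0]
        i += 1
    j = len(ops) - 1
    while j >= i and ops[j][1] in "SH":
        trail += ops[j][0]
        j -= 1
    return lead, trail


# ---------------------------------------------------------------------------
# Split-read alignments (SAM)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentSegment:
    """One aligned piece of a read: a read interval mapped to a reference
    interval.  Read coordinates are 1-based inclusive in read orientation."""
    read_start: int
    read_end: int
    chrom: str
    ref_start: int
    ref_end: int
    strand: str           # '+' or '-'
    mismatches: int = 0
    score: float | None = None

    @property
    def read_length(self) -> int:
        return self.read_end - self.read_start + 1


@dataclass
class SplitReadAlignment:
    read_id: str
    mate: int                      # 1 or 2; 0 for single-end
    segments: list[AlignmentSegment]
    read_length: int
    ambiguous: bool = False        # >2 segments or excessive read overlap

    def sorted_segments(self) -> list[AlignmentSegment]:
        return sorted(self.segments, key=lambda s: (s.read_start, s.read_end))


#: Mappers often re-align a few bases on both sides of a split; up to this
#: many bases of read-coordinate overlap between two segments is tolerated.
READ_OVERLAP_TOLERANCE = 5


def _segment_from_cigar(chrom: str, pos: int, strand: str, cigar: str,
                        mismatches: int, score: float | None
                        ) -> tuple[AlignmentSegment, int]:
    """Build a segment from SAM fields; also return the full read length."""
    ops, read_span, ref_span = parse_cigar(cigar)
    lead, trail = _clip_lengths(ops)
    aligned = read_span - sum(n for n, op in ops if op == "S")
    # total read length counts hard clips too
    total = lead + aligned + trail
    if strand == "+":
        rstart, rend = lead + 1, lead + aligned
    else:
        rstart, rend = trail + 1, trail + aligned
    seg = AlignmentSegment(
        read_start=rstart, read_end=rend, chrom=chrom,
        ref_start=pos, ref_end=pos + ref_span - 1,
        strand=strand, mismatches=mismatches, score=score,
    )
    return seg, total


def _nm_to_mismatches(nm: int, ops: list[tuple[int, str]]) -> int:
    indel = sum(n for n, op in ops if op in "ID")
    return max(0, nm - indel)


def load_split_reads(sam_path: str | os.PathLike) -> list[SplitReadAlignment]:
    """Load a SAM file into per-(read, mate) split alignments.

    Primary and supplementary records are combined; supplementary
    alignments encoded only in the ``SA`` tag are rehydrated from the tag
    (hard-clip lengths restore read coordinates), so both encodings yield
    identical results.  Unmapped reads and reads with only secondary
    records are dropped.  Reads with more than two segments, or with
    segments overlapping by more than ``READ_OVERLAP_TOLERANCE`` bases on
    the read, are marked ambiguous.
    """
    groups: dict[tuple[str, int], dict] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        if fh.nreferences == 0:
            raise FormatError(f"{sam_path}: SAM header has no @SQ lines")
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            mate = 0
            if rec.is_paired:
                mate = 1 if rec.is_read1 else 2
            key = (rec.query_name, mate)
            entry = groups.setdefault(key, {"segs": {}, "length": 0})
            strand = "-" if rec.is_reverse else "+"
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            ops, _, _ = parse_cigar(rec.cigarstring)
            score = float(rec.get_tag("AS")) if rec.has_tag("AS") else None
            seg, total = _segment_from_cigar(
                rec.reference_name, rec.reference_start + 1, strand,
                rec.cigarstring, _nm_to_mismatches(nm, ops), score)
            sig = (seg.chrom, seg.ref_start, seg.strand, seg.read_start, seg.read_end)
            entry["segs"][sig] = seg
            entry["length"] = max(entry["length"], total)
            if rec.has_tag("SA"):
                for sa in rec.get_tag("SA").rstrip(";").split(";"):
                    rname, spos, sstrand, scigar, _mapq, snm = sa.split(",")
                    sops, _, _ = parse_cigar(scigar)
                    sseg, stotal = _segment_from_cigar(
                        rname, int(spos), sstrand, scigar,
                        _nm_to_mismatches(int(snm), sops), None)
                    ssig = (sseg.chrom, sseg.ref_start, sseg.strand,
                            sseg.read_start, sseg.read_end)
                    entry["segs"].setdefault(ssig, sseg)
                    entry["length"] = max(entry["length"], stotal)

    out: list[SplitReadAlignment] = []
    for (rid, mate), entry in groups.items():
        segs = sorted(entry["segs"].values(),
                      key=lambda s: (s.read_start, s.read_end))
        aln = SplitReadAlignment(read_id=rid, mate=mate, segments=segs,
                                 read_length=entry["length"])
        if len(segs) > 2:
            aln.ambiguous = True
        elif len(segs) == 2:
            overlap = segs[0].read_end - segs[1].read_start + 1
            if overlap > READ_OVERLAP_TOLERANCE:
                aln.ambiguous = True
        out.append(aln)
    out.sort(key=lambda a: (a.read_id, a.mate))
    return out


# ---------------------------------------------------------------------------
# Tabular output helpers
# ---------------------------------------------------------------------------

def write_tsv(rows: list[dict], columns: list[str],
              path: str | os.PathLike) -> None:
    """TSV writer with a single commented header line."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def to_bed6(chrom: str, start: int, end: int, name: str, score: int,
            strand: str) -> str:
    """Convert a 1-based inclusive interval to a BED6 line."""
    return f"{chrom}\t{start - 1}\t{end}\t{name}\t{score}\t{strand}"
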