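"""Full-length circRNA sequence extraction.

Exonic circRNAs are spliced from the exons of each transcript whose exon
boundaries match the back-splice junction; one isoform is emitted per
distinct exon chain, so a single junction shared by several transcripts
can yield several isoforms.  Intronic and intergenic circRNAs (and exonic
ones whose matching transcript has no exon inside the circle) fall back
to the genomic span.  Alternative splicing *within* a circRNA beyond the
annotated transcript structures is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .detect import BackspliceCandidate
from .io import GeneModel, GenomeSequence, revcomp, write_fasta, write_tsv


@dataclass
class IsoformRecord:
    source: str                       # transcript id or "genomic"
    sequence: str
    exon_chain: tuple[tuple[int, int], ...]   # genomic exon intervals used
    flags: set[str] = field(default_factory=set)


@dataclass
class CircRNA:
    candidate: BackspliceCandidate
    verified_reads: int = 0
    isoforms: list[IsoformRecord] = field(default_factory=list)

    @property
    def name(self) -> str:
        return self.candidate.name


def _genomic_isoform(genome: GenomeSequence, cand: BackspliceCandidate,
                     flags: set[str] | None = None) -> IsoformRecord:
    seq = genome.fetch(cand.chrom, cand.start, cand.end)
    if cand.strand == "-":
        seq = revcomp(seq)
    return IsoformRecord(source="genomic", sequence=seq,
                         exon_chain=((cand.start, cand.end),),
                         flags=flags or set())


def extract_full_length(genome: GenomeSequence,
                        annotation: list[GeneModel] | None,
                        circ: CircRNA | BackspliceCandidate,
                        tolerance: int = 5) -> list[IsoformRecord]:
    """Extract the spliced (exonic) or genomic full-length sequence(s).

    For exonic circRNAs, every transcript whose exon boundaries match the
    junction within ``tolerance`` contributes the concatenation of its
    exons lying inside ``[start, end]``; duplicate exon chains are
    collapsed.  Minus-strand isoforms are reverse complemented.
    """
    cand = circ.candidate if isinstance(circ, CircRNA) else circ
    if cand.circ_type != "exonic" or not annotation:
        return [_genomic_isoform(genome, cand)]
    isoforms: list[IsoformRecord] = []
    seen_chains: set[tuple] = set()
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
            if not (start_ok and end_ok):
                continue
            chain = tuple((max(es, cand.start), min(ee, cand.end))
                          for es, ee in tr.exons
                          if es <= cand.end and ee >= cand.start)
            if not chain:
                continue
            if chain in seen_chains:
                continue
            seen_chains.add(chain)
            seq = "".join(genome.fetch(cand.chrom, s, e) for s, e in chain)
            if cand.strand == "-":
                seq = revcomp(seq)
            isoforms.append(IsoformRecord(
                source=tr.transcript_id, sequence=seq, exon_chain=chain))
    if not isoforms:
        # matching transcript had no exon inside the interval
        return [_genomic_isoform(genome, cand, flags={"genomic-fallback"})]
    return isoforms


def attach_sequences(genome: GenomeSequence,
                     annotation: list[GeneModel] | None,
                     circs: list[CircRNA], tolerance: int = 5) -> None:
    for circ in circs:
        circ.isoforms = extract_full_length(genome, annotation, circ,
                                            tolerance)


def write_circ_fasta(circs: list[CircRNA], path) -> None:
    """FASTA with one record per isoform, id ``chrom:start|end(strand)#k``."""
    records: dict[str, str] = {}
    for circ in circs:
        for k, iso in enumerate(circ.isoforms, 1):
            records[f"{circ.name}#{k}"] = iso.sequence
    write_fasta(records, path)


def write_circrna_tsv(circs: list[CircRNA], path) -> None:
    cols = ["chrom", "start", "end", "strand", "verified_reads", "signal",
            "circ_type", "flags"]
    rows = [{
        "chrom": c.candidate.chrom, "start": c.candidate.start,
        "end": c.candidate.end, "strand": c.candidate.strand,
        "verified_reads": c.verified_reads, "signal": c.candidate.signal,
        "circ_type": c.candidate.circ_type,
        "flags": ",".join(sorted(c.candidate.flags)) or ".",
    } for c in circs]
    write_tsv(rows, cols, path)


def read_circrna_tsv(path) -> list[CircRNA]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, strand, nver, signal, ctype, flags = \
                line.rstrip("\n").split("\t")[:8]
            cand = BackspliceCandidate(
                chrom=chrom, start=int(start), end=int(end), strand=strand,
                signal=signal, circ_type=ctype, read_ids=["verified"],
                flags=set() if flags == "." else set(flags.split(",")))
            out.append(CircRNA(candidate=cand, verified_reads=int(nver)))
    return out


def write_isoform_tsv(circs: list[CircRNA], path) -> None:
    cols = ["circ", "source", "length", "n_exons"]
    rows = []
    for circ in circs:
        for iso in circ.isoforms:
            rows.append({"circ": circ.name, "source": iso.source,
                         "length": len(iso.sequence),
                         "n_exons": len(iso.exon_chain)})
    write_tsv(rows, cols, path)
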