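"""Pseudo-reference verification of candidate back-splice junctions.

For each candidate a junction sequence is built by concatenating the
donor-side flank with the acceptor-side flank — the sequence a true
BSJ-spanning read must cross.  Raw reads are then re-screened against
these entries ("second alignment"): a read verifies a candidate iff it
matches a contiguous window spanning the seam with a minimum anchor on
each side and at most a small number of mismatches.

The original workflow re-maps reads with an external aligner; here the
second pass is an internal seed-and-extend ungapped matcher (exact 20-mer
seeding on the seam region, ungapped extension), so the pipeline runs
with no external binary.  The contract — seam-spanning match, anchor
lengths, mismatch cap — is identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .detect import BackspliceCandidate
from .io import GenomeSequence, revcomp, write_fasta, write_tsv

SEED_LENGTH = 20


@dataclass
class PseudoRefEntry:
    candidate_id: str
    sequence: str        # donor-side flank + acceptor-side flank
    flank: int           # effective flank length used
    seam: int            # 0-based index of the first acceptor-side base
    flags: set[str] = field(default_factory=set)


@dataclass
class VerificationResult:
    candidate_id: str
    verified_reads: int
    anchors: list[tuple[int, int]] = field(default_factory=list)
    mismatch_counts: list[int] = field(default_factory=list)
    read_ids: list[str] = field(default_factory=list)


def build_pseudoref(genome: GenomeSequence,
                    candidates: list[BackspliceCandidate],
                    flank: int = 100) -> list[PseudoRefEntry]:
    """Junction-flank entries, one per candidate.

    For a + strand candidate the entry is
    ``genome[end-f+1..end] + genome[start..start+f-1]`` with
    ``f = min(flank, circle length)`` — the flank never wraps around the
    circle.  Minus-strand entries are the reverse complement.  Flanks
    truncated at a chromosome edge flag the entry.
    """
    entries = []
    for cand in candidates:
        f = min(flank, cand.span)
        flags: set[str] = set()
        clen = genome.length(cand.chrom)
        donor_lo, donor_hi = cand.end - f + 1, cand.end
        acc_lo, acc_hi = cand.start, cand.start + f - 1
        if donor_lo < 1 or acc_hi > clen:
            flags.add("edge-truncated")
        donor_side = genome.fetch_clamped(cand.chrom, donor_lo, donor_hi)
        acceptor_side = genome.fetch_clamped(cand.chrom, acc_lo, acc_hi)
        seq = donor_side + acceptor_side
        seam = len(donor_side)
        if cand.strand == "-":
            seq = revcomp(seq)
            seam = len(seq) - seam
        entries.append(PseudoRefEntry(
            candidate_id=cand.name, sequence=seq, flank=f, seam=seam,
            flags=flags))
    return entries


def _count_mismatches(a: str, b: str, limit: int) -> int:
    """Mismatches between equal-length strings, early exit above limit."""
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def _read_spans_seam(read: str, entry: PseudoRefEntry, offset: int,
                     min_anchor: int, max_mismatch: int
                     ) -> tuple[int, int, int] | None:
    """Check one ungapped placement of ``read`` at ``offset`` in the entry.

    The read may overhang the entry; the matched window is the overlap.
    Returns (left anchor, right anchor, mismatches) if the overlap spans
    the seam with both anchors >= min_anchor and has <= max_mismatch
    mismatches; else None.
    """
    seq = entry.sequence
    lo = max(offset, 0)
    hi = min(offset + len(read), len(seq))
    if hi <= lo:
        return None
    left = entry.seam - lo
    right = hi - entry.seam
    if left < min_anchor or right < min_anchor:
        return None
    mm = _count_mismatches(read[lo - offset:hi - offset], seq[lo:hi],
                           max_mismatch)
    if mm > max_mismatch:
        return None
    return left, right, mm


def _seam_kmer_index(entries: list[PseudoRefEntry],
                     k: int) -> dict[str, list[tuple[int, int]]]:
    """k-mer -> [(entry index, k-mer start)] over seam-spanning k-mers."""
    index: dict[str, list[tuple[int, int]]] = {}
    for ei, entry in enumerate(entries):
        lo = max(0, entry.seam - k + 1)
        hi = min(len(entry.sequence) - k, entry.seam - 1)
        for p in range(lo, hi + 1):
            kmer = entry.sequence[p:p + k]
            index.setdefault(kmer, []).append((ei, p))
    return index


def verify_junction(reads: list[tuple[str, str, str]] | list[tuple[str, str]],
                    entries: list[PseudoRefEntry],
                    min_anchor: int = 10,
                    max_mismatch: int = 2,
                    seed_length: int = SEED_LENGTH
                    ) -> list[VerificationResult]:
    """Re-screen raw reads against the pseudo-reference.

    Each read (tried in both orientations) verifies an entry at most once:
    it must match a contiguous, ungapped window spanning the seam with at
    least ``min_anchor`` bases on each side and at most ``max_mismatch``
    mismatches.  Matching is exact ``seed_length``-mer seeding on the
    seam-spanning region followed by ungapped extension over the full
    read.
    """
    index = _seam_kmer_index(entries, seed_length)
    results = {e.candidate_id: VerificationResult(e.candidate_id, 0)
               for e in entries}
    for item in reads:
        rid, seq = item[0], item[1].upper()
        if len(seq) < 2 * min_anchor:
            continue
        hit_entries: dict[int, tuple[int, int, int]] = {}
        for oriented in (seq, revcomp(seq)):
            for rp in range(0, len(oriented) - seed_length + 1):
                kmer = oriented[rp:rp + seed_length]
                for ei, ep in index.get(kmer, ()):
                    if ei in hit_entries:
                        continue
                    placement = _read_spans_seam(
                        oriented, entries[ei], ep - rp,
                        min_anchor, max_mismatch)
                    if placement is not None:
                        hit_entries[ei] = placement
        for ei, (left, right, mm) in hit_entries.items():
            res = results[entries[ei].candidate_id]
            res.verified_reads += 1
            res.anchors.append((left, right))
            res.mismatch_counts.append(mm)
            res.read_ids.append(rid)
    return [results[e.candidate_id] for e in entries]


def finalize_circrnas(candidates: list[BackspliceCandidate],
                      results: list[VerificationResult],
                      min_verified: int = 2) -> list["CircRNA"]:
    """Keep candidates whose verified read count reaches ``min_verified``."""
    from .sequence import CircRNA
    by_id = {r.candidate_id: r for r in results}
    kept = []
    for cand in candidates:
        res = by_id.get(cand.name)
        if res is None or res.verified_reads < min_verified:
            continue
        kept.append(CircRNA(candidate=cand, verified_reads=res.verified_reads))
    kept.sort(key=lambda c: (c.candidate.chrom, c.candidate.start,
                             c.candidate.end, c.candidate.strand))
    return kept


def write_pseudoref_fasta(entries: list[PseudoRefEntry], path) -> None:
    write_fasta({e.candidate_id: e.sequence for e in entries}, path)


def write_verification_tsv(results: list[VerificationResult], path) -> None:
    cols = ["candidate", "verified_reads", "mean_mismatches"]
    rows = [{
        "candidate": r.candidate_id,
        "verified_reads": r.verified_reads,
        "mean_mismatches": (round(sum(r.mismatch_counts) / len(r.mismatch_counts), 3)
                            if r.mismatch_counts else 0.0),
    } for r in results]
    write_tsv(rows, cols, path)
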