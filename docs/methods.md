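# Methods

## Detection model

A back-splice junction (BSJ) joins a splice donor at genomic coordinate
`end` (the circle's 3′ boundary) to an acceptor at `start` (5′
boundary), `start < end`, both 1-based inclusive.  A read crossing the
junction aligns in two segments in chiastic order: on the + strand the
segment earlier in the read maps strictly downstream of the later one
(mirrored on the − strand).  Candidate calling consumes SAM split
alignments (primary + supplementary records, or the `SA` tag —
hard-clipped supplementary records are rehydrated into read coordinates
so both encodings are equivalent) and applies, per read:

* exactly two segments, same chromosome, same strand.  Opposite-strand
  segment pairs are excluded: a back-splice joins same-strand exons, and
  opposite-strand chimeras are far more often template-switching or
  mapping artifacts.  More than two segments, or more than 5 bp of
  read-coordinate overlap between segments, marks the read ambiguous
  (mappers re-align a few bases on both sides of a split, so a small
  overlap is tolerated).
* per-segment mismatches ≤ 2 and alignment score ≥ 0.8 × segment length
  (the `AS` tag when present, otherwise matched-bases as a proxy).
  These strict criteria suppress false positives from the duplicated
  sequence that is pervasive in plant genomes.  The upstream aligner's
  own multiple-seed maximum-likelihood machinery is not re-implemented;
  the deterministic chiastic-geometry test plus these thresholds
  reproduces its observable contract on the benchmark.

Candidates are pooled by `(chrom, start, end, strand)` **after** site
adjustment, so reads whose raw sites differ but adjust to the same
junction support one candidate.  Pooled filters: ≥ 2 junction reads
(configurable; the value is this package's choice), genomic span
≤ 100 kb (rejected above), spans > 20 kb kept but flagged `long`
(plant circRNAs are predominantly short; reporting rather than dropping
keeps the long tail visible).  Thresholds apply to genomic span — the
quantity known before any annotation — with spliced length recorded
separately on extracted isoforms.  For paired-end data at least one
supporting read's mate must fall inside `[start−5, end+5]`; single-end
data skips the check with a logged notice.

### Splice signals and site adjustment

The intron-side dinucleotides are read directly from the genome: on the
+ strand the donor-side pair is `genome[end+1..end+2]` and the
acceptor-side `genome[start−2..start−1]`; the − strand applies the same
test on the reverse complement with roles mirrored.  `(GT,AG)`,
`(GC,AG)` and `(AT,AC)` (the U12 minor spliceosome) are canonical;
anything else is `none`.  When no signal is present at the raw site,
offset pairs `(δa, δd) ∈ [−5, 5]²` are searched in increasing total
shift, ties broken by class priority GT-AG > GC-AG > AT-AC, then by
smaller donor shift (and deterministically thereafter).

Annotation is complementary evidence: when a candidate's boundaries
match exon boundaries of one transcript within ±5 bp, the candidate
snaps to those exon boundaries and the signal search is skipped.  This
matters because the two introns flanking a back-splice are *different*
introns and need not share a signal class — a circle can legitimately
show, say, an AT donor with an AG acceptor, which the pair-based
classifier calls `none`; without the annotation snap the ±5 bp search
would drag such junctions onto a nearby spurious signal.  Typing is
exonic (both boundaries match exons of one transcript, ±5 bp), intronic
(wholly inside one intron), else intergenic.

## Verification (pseudo-reference)

For each candidate a junction entry is built as donor-side flank +
acceptor-side flank, `f = min(flank, circle length)` bases each (the
flank never wraps the circle); − strand entries are reverse
complemented.  Default flank = read length — a junction-spanning read
can never need more.  Raw reads are re-screened against these entries:
a read (tried in both orientations) verifies an entry iff it matches a
contiguous, ungapped window spanning the seam with ≥ 10 bases on each
side and ≤ 2 mismatches, implemented as exact 20-mer seeding on the
seam-spanning region followed by ungapped extension.  The original
workflow re-maps with an external aligner; the internal matcher keeps
the contract (seam-spanning, anchors, mismatch cap) while requiring no
external binary — gapped or quality-aware re-alignment is deliberately
out of scope.  Candidates with ≥ 2 verified reads become circRNAs.

## Full-length sequences

Exonic circRNAs: every transcript whose exon boundaries match the BSJ
(±5 bp) contributes the concatenation of its exons inside
`[start, end]`; one isoform is emitted per *distinct exon chain* (a
merged exon union would fabricate a transcript no annotation supports).
Intronic/intergenic circles, and exonic ones whose matching transcript
has no exon inside the interval, fall back to the genomic span.
Alternative splicing within circRNAs beyond annotated transcript
structures is not modelled.

## miRNA sites

Cleavage sites use the standard plant penalty scheme: mismatch 1.0,
G:U wobble 0.5, bulged nucleotide 1.0, all doubled across miRNA
positions 2–13; sites score < 3.0 (the published cutoff; every penalty
is configurable).  Alignment is a dynamic program over the antiparallel
duplex allowing at most one contiguous bulge of ≤ 5 nt per side; a
target-side bulge between miRNA positions *i* and *i+1* is doubled when
position *i+1* lies in 2–13.  One semi-global pass (free target flanks)
scans each miRNA–target pair; overlapping sites keep the best score.
T and U are equivalent; sequences are normalized at load.  circRNA
targets are scanned on the circularized sequence (the target extended by
its own prefix, hits de-duplicated by modular position) so sites may
wrap the BSJ seam.

Sponge (endogenous target mimic) sites satisfy three rules: (R1)
perfect Watson–Crick pairing at miRNA positions 2–8; (R2) one bulge of
1–5 unpaired target nucleotides opposite miRNA positions 9–11 (inserted
after position 9 or 10) and no other bulge; (R3) ≤ 4 combined
mismatches + G:U pairs over the remaining positions.  The original
tools' exact filter set is cited but not published; R1–R3 encode the
standard criteria from that literature and are configuration, not a
claim about the original implementation.  Classification is exclusive:
a duplex matching the mimic rules is reported as a sponge site and any
overlapping cleavage call for the same miRNA/target is dropped.

## ceRNA pairs, networks, GO

Every circRNA–mRNA pair sharing ≥ 1 miRNA is tested per pair (the
alternative — a pooled contingency — answers a different question);
p = `P(X ≥ k)`, `X ~ Hypergeometric(N, K, n)` with N the miRNA universe
(default: distinct miRNAs in the input FASTA, overridable for
species-level universes), computed through scipy's log-space survival
function.  Benjamini–Hochberg (statsmodels) is applied across all
tested pairs at α = 0.05; no correction was named in the source method,
so BH is adopted as the field default (configurable to none or
Bonferroni in spirit via α = 1).  Retained pairs define the network:
`circ binds miRNA` and `miRNA targets mRNA` edges, deterministic order,
SIF or typed TSV for Cytoscape.

GO assignment treats a circRNA's retained mRNA partners as a gene set
and tests each term hypergeometrically against the background of all
genes in the two-column gene→GO table, BH per circRNA, q ≤ α reported.
With an OBO ontology (only `id`, `name`, `is_a` are parsed),
annotations propagate to ancestors before testing.

## Simulator

The generator emulates the published benchmark design and its defaults
are that stated world: 200 circRNAs, 6000 BSJ reads, paired-end 100 bp,
error-free by default (the benchmark also ran a noisy regime; the
acceptance script uses 0.5% uniform per-base substitution).  Values the
design leaves open were fixed once at realistic levels: a 2 × 1 Mb
genome holding 300 non-overlapping genes of 4–8 exons (exons
120–300 bp — at least one read arm — introns 80–400 bp), 5% GC-AG and
2% AT-AC introns stamped into the sequence on the gene's strand, 6000
linear background reads, multinomial read allocation over circles with
a floor of two reads (the design fixes totals, not per-circle depth),
and a strand-specific library (R1 carries RNA sense), so the truth
strand is recoverable.  Circles are placed over internal exon ranges so
both junction boundaries carry genuine splice signals.  Reads are
emitted as FASTQ and as a truth-derived SAM in which the simulator
plays the aligner (correct chiastic primary + supplementary records,
`SA`/`NM`/`AS` tags with `AS = length − 2·mismatches`); the FASTQ path
supports end-to-end runs through a real mapper.  Everything is
deterministic under the seed.

What a green benchmark does *not* establish: the synthetic genome has
no repeat families, no paralogy, no coverage or quality-score structure,
and the truth-derived SAM contains no mapping error — so the measured
sensitivity/precision bound the idealized pipeline, not performance on
real plant genomes, where the original benchmark numbers (measured on
real genome annotations) are the reference.

## Numerical and interface choices

* Coordinates 1-based inclusive throughout; BED output converts to
  0-based half-open at the writer only.
* Match tolerance for evaluation defaults to 0 (exact BSJ coordinates);
  ±5 mirrors the adjustment window when comparing against external
  callers.  Precision is defined 0 when no predictions are made.
* FASTA ambiguity codes beyond N are collapsed to N at load; duplicate
  record names and non-IUPAC characters are format errors.
* Ties anywhere (site adjustment, site collapsing, output ordering) are
  broken deterministically so identical inputs give identical bytes.
* Known limitations: no fusion (inter-chromosomal) circRNAs, no
  BAM/CRAM input (text SAM only), no thermodynamic miRNA scoring, no
  degradome evidence, no KEGG enrichment.
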