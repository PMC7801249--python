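"""High-level pipeline stages tying the modules together.

Each stage is a plain function over in-memory objects; the CLI is a thin
wrapper adding file I/O and logging.
"""

from __future__ import annotations

import logging

from . import detect as _detect
from . import verify as _verify
from .cerna import build_cerna_pairs, annotate_circ_go
from .detect import BackspliceCandidate, DetectionConfig
from .io import GeneModel, GenomeSequence, load_split_reads
from .mirna import MirnaConfig, scan_interactions, scan_targets
from .sequence import CircRNA, attach_sequences
from .simulate import Metrics, SimTruth, evaluate

log = logging.getLogger(__name__)


def detect_stage(genome: GenomeSequence, sam_path,
                 annotation: list[GeneModel] | None = None,
                 config: DetectionConfig | None = None,
                 paired: bool | None = None) -> list[BackspliceCandidate]:
    """SAM -> filtered, typed back-splice candidates."""
    split_reads = load_split_reads(sam_path)
    if paired is None:
        paired = any(sr.mate for sr in split_reads)
    if not paired:
        log.info("detect: single-end data, paired-end consistency skipped")
    cands = _detect.detect_candidates(split_reads, genome, annotation,
                                      config, paired=paired)
    log.info("detect: %d split-read groups in, %d candidates out",
             len(split_reads), len(cands))
    return cands


def verify_stage(genome: GenomeSequence,
                 candidates: list[BackspliceCandidate],
                 reads: list[tuple[str, str, str]],
                 flank: int | None = None,
                 min_anchor: int = 10,
                 max_mismatch: int = 2,
                 min_verified: int = 2) -> list[CircRNA]:
    """Candidates + raw reads -> verified circRNAs via the pseudoRef."""
    if flank is None:
        flank = max((len(seq) for _, seq, *_ in reads), default=100)
    entries = _verify.build_pseudoref(genome, candidates, flank=flank)
    results = _verify.verify_junction(reads, entries, min_anchor=min_anchor,
                                      max_mismatch=max_mismatch)
    circs = _verify.finalize_circrnas(candidates, results,
                                      min_verified=min_verified)
    log.info("verify: %d candidates in, %d verified circRNAs out",
             len(candidates), len(circs))
    return circs


def sequence_stage(genome: GenomeSequence,
                   annotation: list[GeneModel] | None,
                   circs: list[CircRNA], tolerance: int = 5) -> list[CircRNA]:
    attach_sequences(genome, annotation, circs, tolerance=tolerance)
    n_iso = sum(len(c.isoforms) for c in circs)
    log.info("sequence: %d circRNAs, %d isoform sequences", len(circs), n_iso)
    return circs


def mirna_stage(mirnas: dict[str, str], circs: list[CircRNA],
                mrnas: dict[str, str] | None = None,
                config: MirnaConfig | None = None):
    """Scan circRNAs (circular, seam-wrapping) and mRNAs (linear) for
    miRNA cleavage and sponge sites."""
    circ_seqs = {f"{c.name}#{k}": iso.sequence
                 for c in circs for k, iso in enumerate(c.isoforms, 1)}
    circ_sites = scan_interactions(mirnas, circ_seqs, config,
                                   circular=set(circ_seqs))
    mrna_sites = []
    if mrnas:
        mrna_sites = scan_targets(mirnas, mrnas, config)
    log.info("mirna: %d circ sites, %d mRNA sites",
             len(circ_sites), len(mrna_sites))
    return circ_sites, mrna_sites


def cerna_stage(circ_sites, mrna_sites, mirnas: dict[str, str],
                alpha: float = 0.05):
    pairs = build_cerna_pairs(circ_sites, mrna_sites, set(mirnas),
                              alpha=alpha)
    log.info("cerna: %d pairs retained at q <= %g", len(pairs), alpha)
    return pairs


def go_stage(pairs, gene2go, ontology=None, alpha: float = 0.05):
    results = annotate_circ_go(pairs, gene2go, ontology, alpha=alpha)
    n_terms = sum(len(v) for v in results.values())
    log.info("go: %d circRNAs annotated, %d enriched terms",
             len(results), n_terms)
    return results


def evaluate_stage(circs: list[CircRNA] | list[BackspliceCandidate],
                   truth: SimTruth, tolerance: int = 0) -> Metrics:
    preds = []
    for c in circs:
        cand = c.candidate if isinstance(c, CircRNA) else c
        preds.append((cand.chrom, cand.start, cand.end, cand.strand))
    metrics = evaluate(preds, truth, tolerance=tolerance)
    log.info("evaluate: TP=%d FP=%d FN=%d sens=%.4f prec=%.4f F1=%.4f",
             metrics.tp, metrics.fp, metrics.fn, metrics.sensitivity,
             metrics.precision, metrics.f1)
    return metrics
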