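"""ceRNA pair testing, network export and GO-based function assignment.

A circRNA and an mRNA sharing miRNA binding sites compete for the same
miRNAs (a ceRNA pair).  For each circRNA-mRNA pair sharing at least one
miRNA the overlap is tested with a hypergeometric test: with N miRNAs in
the universe, K hitting the circRNA and n hitting the mRNA, the p-value
is P(X >= k) for X ~ Hypergeometric(N, K, n).  P-values are adjusted with
Benjamini-Hochberg across all tested pairs; pairs with q <= alpha form
the circRNA-miRNA-mRNA network.  Functions are assigned per circRNA as
the GO terms enriched among its ceRNA mRNA partners (hypergeometric
against the annotated background, BH per circRNA).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import write_tsv
from .mirna import MirnaTargetSite


@dataclass
class CeRNAPair:
    circ_id: str
    mrna_id: str
    shared_mirnas: tuple[str, ...]
    k: int   # shared miRNAs
    K: int   # miRNAs hitting the circRNA
    n: int   # miRNAs hitting the mRNA
    N: int   # miRNA universe size
    p: float
    q: float = 1.0


@dataclass
class GOResult:
    term_id: str
    term_name: str
    k: int   # partner genes carrying the term
    K: int   # background genes carrying the term
    n: int   # partner set size
    N: int   # background size
    p: float
    q: float = 1.0


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the population size, K the number of successes in it, n the
    sample size.  Computed in log space (scipy) for stability.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return 1.0
    if k > min(K, n):
        return 0.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method="fdr_bh")[1]


def _sites_by_sequence(sites: list[MirnaTargetSite]) -> dict[str, set[str]]:
    hit: dict[str, set[str]] = {}
    for s in sites:
        hit.setdefault(s.target_id, set()).add(s.mirna_id)
    return hit


def build_cerna_pairs(circ_sites: list[MirnaTargetSite],
                      mrna_sites: list[MirnaTargetSite],
                      universe: set[str] | list[str],
                      alpha: float = 0.05) -> list[CeRNAPair]:
    """Hypergeometric shared-miRNA test for every circRNA-mRNA pair.

    Pairs sharing no miRNA are not tested; BH is applied across all
    tested pairs and pairs with q <= alpha are returned.
    """
    universe = set(universe)
    N = len(universe)
    if N == 0:
        raise ValueError("empty miRNA universe")
    circ_hits = _sites_by_sequence(circ_sites)
    mrna_hits = _sites_by_sequence(mrna_sites)
    pairs: list[CeRNAPair] = []
    for circ_id in sorted(circ_hits):
        cm = circ_hits[circ_id] & universe
        for mrna_id in sorted(mrna_hits):
            mm = mrna_hits[mrna_id] & universe
            shared = cm & mm
            if not shared:
                continue
            p = hypergeom_sf(len(shared), N, len(cm), len(mm))
            pairs.append(CeRNAPair(
                circ_id=circ_id, mrna_id=mrna_id,
                shared_mirnas=tuple(sorted(shared)),
                k=len(shared), K=len(cm), n=len(mm), N=N, p=p))
    if not pairs:
        return []
    q = bh_adjust([pr.p for pr in pairs])
    for pr, qv in zip(pairs, q):
        pr.q = float(qv)
    return [pr for pr in pairs if pr.q <= alpha]


def export_network(pairs: list[CeRNAPair], path, fmt: str = "SIF") -> None:
    """Write the circRNA-miRNA-mRNA network for Cytoscape.

    SIF edges: ``circ binds miRNA`` and ``miRNA targets mRNA`` for each
    retained pair's shared miRNAs; TSV writes one edge per line with node
    types.  Output ordering is deterministic.
    """
    fmt = fmt.upper()
    if fmt not in ("SIF", "TSV"):
        raise ValueError(f"unknown network format: {fmt}")
    edges: list[tuple[str, str, str, str, str]] = []
    seen = set()
    for pr in sorted(pairs, key=lambda x: (x.circ_id, x.mrna_id)):
        for mir in pr.shared_mirnas:
            e1 = (pr.circ_id, "binds", mir, "circRNA", "miRNA")
            e2 = (mir, "targets", pr.mrna_id, "miRNA", "mRNA")
            for e in (e1, e2):
                if e not in seen:
                    seen.add(e)
                    edges.append(e)
    with open(path, "w") as fh:
        if fmt == "SIF":
            for a, rel, b, _, _ in edges:
                fh.write(f"{a}\t{rel}\t{b}\n")
        else:
            fh.write("#source\trelation\ttarget\tsource_type\ttarget_type\n")
            for a, rel, b, ta, tb in edges:
                fh.write(f"{a}\t{rel}\t{b}\t{ta}\t{tb}\n")


# ---------------------------------------------------------------------------
# GO annotation
# ---------------------------------------------------------------------------

@dataclass
class Ontology:
    """Minimal ontology: term names and is_a parents."""
    names: dict[str, str] = field(default_factory=dict)
    parents: dict[str, set[str]] = field(default_factory=dict)

    def ancestors(self, term: str) -> set[str]:
        out: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            for parent in self.parents.get(t, ()):
                if parent not in out:
                    out.add(parent)
                    stack.append(parent)
        return out


def read_obo(path: str | os.PathLike) -> Ontology:
    """Parse id / name / is_a from an OBO-format ontology file."""
    onto = Ontology()
    cur: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line == "[Term]":
                cur = None
            elif line.startswith("id:") and cur is None:
                cur = line[3:].strip()
            elif line.startswith("name:") and cur:
                onto.names.setdefault(cur, line[5:].strip())
            elif line.startswith("is_a:") and cur:
                parent = line[5:].strip().split("!")[0].strip()
                onto.parents.setdefault(cur, set()).add(parent)
    return onto


def read_gene2go(path: str | os.PathLike) -> dict[str, set[str]]:
    """Two-column tab-delimited gene -> GO term table (one pair per line;
    a semicolon-separated term list in column 2 is also accepted)."""
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                continue
            gene = fields[0]
            for term in fields[1].split(";"):
                term = term.strip()
                if term:
                    table.setdefault(gene, set()).add(term)
    return table


def annotate_circ_go(pairs: list[CeRNAPair],
                     gene2go: dict[str, set[str]],
                     ontology: Ontology | None = None,
                     alpha: float = 0.05) -> dict[str, list[GOResult]]:
    """GO enrichment of each circRNA's ceRNA mRNA partners.

    The background is every gene in the gene2go table; with an ontology,
    annotations are propagated to ancestor terms before testing.  BH is
    applied per circRNA; terms with q <= alpha are reported.  circRNAs
    with no retained partners map to an empty list.
    """
    annot: dict[str, set[str]] = {}
    for gene, terms in gene2go.items():
        full = set(terms)
        if ontology is not None:
            for t in terms:
                full |= ontology.ancestors(t)
        annot[gene] = full
    background = set(annot)
    N = len(background)
    term_counts: dict[str, int] = {}
    for terms in annot.values():
        for t in terms:
            term_counts[t] = term_counts.get(t, 0) + 1

    partners: dict[str, set[str]] = {}
    for pr in pairs:
        partners.setdefault(pr.circ_id, set()).add(pr.mrna_id)

    out: dict[str, list[GOResult]] = {}
    for circ_id in sorted(partners):
        genes = partners[circ_id] & background
        n = len(genes)
        results: list[GOResult] = []
        if n:
            local: dict[str, int] = {}
            for g in genes:
                for t in annot[g]:
                    local[t] = local.get(t, 0) + 1
            for term in sorted(local):
                k, K = local[term], term_counts[term]
                p = hypergeom_sf(k, N, K, n)
                name = ontology.names.get(term, term) if ontology else term
                results.append(GOResult(term_id=term, term_name=name,
                                        k=k, K=K, n=n, N=N, p=p))
            q = bh_adjust([r.p for r in results])
            for r, qv in zip(results, q):
                r.q = float(qv)
            results = [r for r in results if r.q <= alpha]
            results.sort(key=lambda r: (r.p, r.term_id))
        out[circ_id] = results
    return out


def write_cerna_tsv(pairs: list[CeRNAPair], path) -> None:
    cols = ["circ", "mrna", "k", "K", "n", "N", "p", "q", "shared_mirnas"]
    rows = [{"circ": pr.circ_id, "mrna": pr.mrna_id, "k": pr.k, "K": pr.K,
             "n": pr.n, "N": pr.N, "p": f"{pr.p:.6g}", "q": f"{pr.q:.6g}",
             "shared_mirnas": ",".join(pr.shared_mirnas)} for pr in pairs]
    write_tsv(rows, cols, path)


def write_go_tsv(results: dict[str, list[GOResult]], path) -> None:
    cols = ["circ", "term", "name", "k", "K", "n", "N", "p", "q"]
    rows = []
    for circ_id in sorted(results):
        for r in results[circ_id]:
            rows.append({"circ": circ_id, "term": r.term_id, "name": r.term_name,
                         "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                         "p": f"{r.p:.6g}", "q": f"{r.q:.6g}"})
    write_tsv(rows, cols, path)
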