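"""Plant miRNA binding-site prediction on circRNA and mRNA sequences.

Two site kinds are reported:

* **cleavage** sites — near-perfect antiparallel duplexes scored with the
  standard plant penalty scheme (mismatch 1, G:U wobble 0.5, bulged
  nucleotide 1, all doubled across miRNA positions 2-13); sites with
  score below the cutoff (default 3) are reported.
* **mimic** (sponge / endogenous target mimic) sites — duplexes with a
  perfectly paired seed (miRNA positions 2-8), a 1-5 nt bulge of target
  nucleotides opposite miRNA positions 9-11 that blocks cleavage, no
  other bulge, and at most 4 mismatches plus G:U pairs elsewhere.  These
  rules encode the common endogenous-target-mimic criteria and are fully
  configurable; they are this package's stand-in for the exact filters of
  the original tools.

Alignment allows at most one contiguous bulge on each side (miRNA /
target), each of at most ``max_bulge`` nucleotides.  T and U are treated
as identical; sequences are normalized to DNA at load.  circRNA targets
are scanned on the circularized sequence, so a site may wrap the
back-splice seam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

INF = float("inf")

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


def normalize(seq: str) -> str:
    """Uppercase and convert RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def _pair_class(mir_base: str, target_base: str) -> str:
    """'|' Watson-Crick, 'o' G:U wobble, 'x' mismatch."""
    if _WC.get(mir_base) == target_base:
        return "|"
    if (mir_base == "G" and target_base == "T") or \
       (mir_base == "T" and target_base == "G"):
        return "o"
    return "x"


@dataclass
class MirnaConfig:
    score_cutoff: float = 3.0
    doubled_region: tuple[int, int] = (2, 13)   # miRNA positions, 1-based
    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    bulge_penalty: float = 1.0
    max_bulge: int = 5
    seed_region: tuple[int, int] = (2, 8)       # mimic rule R1
    mimic_bulge_sizes: tuple[int, int] = (1, 5)  # rule R2: nt in target bulge
    mimic_bulge_after: tuple[int, ...] = (9, 10)  # bulge sits after these positions
    mimic_max_mm_gu: int = 4                     # rule R3


@dataclass
class MirnaTargetSite:
    mirna_id: str
    target_id: str
    start: int          # 1-based inclusive on the target (5'->3')
    end: int
    kind: str           # "cleavage" | "mimic"
    score: float
    pairing: str        # one column per alignment position, miRNA 5'->3'

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _penalty(cls: str, mir_pos: int, config: MirnaConfig) -> float:
    if cls == "|":
        return 0.0
    base = {"o": config.gu_penalty, "x": config.mismatch_penalty,
            "-": config.bulge_penalty}[cls]
    lo, hi = config.doubled_region
    if lo <= mir_pos <= hi:
        base *= 2.0
    return base


# DP bulge-state encoding per side: 0 = unused, 1..max_bulge = open run of
# that many nucleotides, CLOSED = run finished (cannot reopen).
def _closed(max_bulge: int) -> int:
    return max_bulge + 1


def _align_window(mirna: str, window: str, config: MirnaConfig
                  ) -> tuple[float, str]:
    """Global antiparallel alignment of a miRNA against one target window.

    The window is given 5'->3'; the miRNA pairs antiparallel, so miRNA
    position 1 pairs near the window's 3' end.  Returns the minimal score
    and the pairing string (miRNA 5'->3' columns).
    """
    m, w = len(mirna), len(window)
    if w < m - config.max_bulge:
        raise ValueError(
            f"window length {w} shorter than miRNA length {m} - max_bulge")
    wrev = window[::-1]
    CL = _closed(config.max_bulge)
    ns = CL + 1
    # dp[(i, j, a, b)] = (cost, parent move); sparse dict keyed by tuple
    dp: dict[tuple[int, int, int, int], float] = {(0, 0, 0, 0): 0.0}
    parent: dict[tuple, tuple] = {}

    def relax(key, cost, par, move):
        if cost < dp.get(key, INF):
            dp[key] = cost
            parent[key] = (par, move)

    for i in range(m + 1):
        for j in range(w + 1):
            for a in range(ns):
                for b in range(ns):
                    cur = dp.get((i, j, a, b), INF)
                    if cur == INF:
                        continue
                    ca = CL if 1 <= a <= config.max_bulge else a
                    cb = CL if 1 <= b <= config.max_bulge else b
                    if i < m and j < w:
                        cls = _pair_class(mirna[i], wrev[j])
                        relax((i + 1, j + 1, ca, cb),
                              cur + _penalty(cls, i + 1, config),
                              (i, j, a, b), cls)
                    if i < m and a != CL and a < config.max_bulge:
                        # unpaired miRNA nucleotide (miRNA-side bulge)
                        relax((i + 1, j, a + 1, cb),
                              cur + _penalty("-", i + 1, config),
                              (i, j, a, b), "A")
                    if j < w and b != CL and b < config.max_bulge:
                        # unpaired target nucleotide (target-side bulge)
                        relax((i, j + 1, ca, b + 1),
                              cur + _penalty("-", min(i + 1, m), config),
                              (i, j, a, b), "B")
    best_key, best = None, INF
    for a in range(ns):
        for b in range(ns):
            c = dp.get((m, w, a, b), INF)
            if c < best:
                best, best_key = c, (m, w, a, b)
    if best_key is None:
        return INF, ""
    moves = []
    key = best_key
    while key in parent:
        key, move = parent[key]
        moves.append(move)
    moves.reverse()
    pairing = "".join("-" if mv in ("A", "B") else mv for mv in moves)
    return best, pairing


def score_site(mirna: str, window: str,
               config: MirnaConfig | None = None) -> tuple[float, str]:
    """Score one candidate site: minimal penalty over all alignments with
    at most one bulge per side, and the pairing string achieving it."""
    config = config or MirnaConfig()
    return _align_window(normalize(mirna), normalize(window), config)


def _candidate_sites(mirna: str, target: str, config: MirnaConfig
                     ) -> list[tuple[float, int, int, str]]:
    """All sites scoring below the cutoff: (score, start, end, pairing),
    1-based target coordinates, overlaps NOT yet collapsed.

    One semi-global pass (free target flanks) per miRNA-target pair; the
    window alignment is re-run only on reported sites to recover the
    pairing string.
    """
    m, L = len(mirna), len(target)
    if L == 0 or m == 0:
        return []
    trev = target[::-1]
    CL = _closed(config.max_bulge)
    # dp maps (i, j, a, b) -> (cost, jstart); free prefix in the target
    dp: dict[tuple[int, int, int, int], tuple[float, int]] = {
        (0, j, 0, 0): (0.0, j) for j in range(L + 1)}

    def relax(key, val):
        if val < dp.get(key, (INF, -1)):
            dp[key] = val

    for i in range(m + 1):
        for j in range(L + 1):
            for a in range(CL + 1):
                for b in range(CL + 1):
                    cur = dp.get((i, j, a, b))
                    if cur is None:
                        continue
                    cost, jstart = cur
                    ca = CL if 1 <= a <= config.max_bulge else a
                    cb = CL if 1 <= b <= config.max_bulge else b
                    if i < m and j < L:
                        cls = _pair_class(mirna[i], trev[j])
                        relax((i + 1, j + 1, ca, cb),
                              (cost + _penalty(cls, i + 1, config), jstart))
                    if i < m and a != CL and a < config.max_bulge:
                        relax((i + 1, j, a + 1, cb),
                              (cost + _penalty("-", i + 1, config), jstart))
                    if j < L and b != CL and b < config.max_bulge:
                        relax((i, j + 1, ca, b + 1),
                              (cost + _penalty("-", min(i + 1, m), config),
                               jstart))
    out = []
    for j in range(1, L + 1):
        best: tuple[float, int] | None = None
        for a in range(CL + 1):
            for b in range(CL + 1):
                v = dp.get((m, j, a, b))
                if v is not None and (best is None or v < best):
                    best = v
        if best is None or best[0] >= config.score_cutoff:
            continue
        score, jstart = best
        # trev[jstart..j-1]  ->  original 1-based [L-j+1 .. L-jstart]
        start, end = L - j + 1, L - jstart
        _, pairing = _align_window(mirna, target[start - 1:end], config)
        out.append((score, start, end, pairing))
    return out


def _collapse(sites: list[MirnaTargetSite]) -> list[MirnaTargetSite]:
    """Per (miRNA, target), keep the best-scoring site among overlaps."""
    kept: list[MirnaTargetSite] = []
    for site in sorted(sites, key=lambda s: (s.mirna_id, s.target_id,
                                             s.score, s.end - s.start,
                                             s.start)):
        clash = any(k.mirna_id == site.mirna_id
                    and k.target_id == site.target_id
                    and k.start <= site.end and site.start <= k.end
                    for k in kept)
        if not clash:
            kept.append(site)
    kept.sort(key=lambda s: (s.target_id, s.mirna_id, s.start))
    return kept


def _dedupe_circular(sites: list[MirnaTargetSite], true_len: int
                     ) -> list[MirnaTargetSite]:
    """Map extended-sequence coordinates back to the circle and de-dupe
    hits found twice (once linear, once across the seam)."""
    seen = set()
    out = []
    for s in sites:
        start = ((s.start - 1) % true_len) + 1
        end = ((s.end - 1) % true_len) + 1
        key = (s.mirna_id, s.target_id, start, s.kind)
        if key in seen:
            continue
        seen.add(key)
        out.append(MirnaTargetSite(s.mirna_id, s.target_id, start, end,
                                   s.kind, s.score, s.pairing))
    return out


def scan_targets(mirnas: dict[str, str], targets: dict[str, str],
                 config: MirnaConfig | None = None,
                 circular: set[str] | frozenset[str] = frozenset()
                 ) -> list[MirnaTargetSite]:
    """Scan every target with every miRNA for cleavage-type sites.

    ``circular`` names targets to scan as circles: the sequence is
    extended by its own prefix so windows may wrap the back-splice seam,
    and duplicate hits are removed by modular position.
    """
    config = config or MirnaConfig()
    sites: list[MirnaTargetSite] = []
    for tid, tseq in targets.items():
        tseq = normalize(tseq)
        is_circ = tid in circular
        scan_seq = tseq
        if is_circ and len(tseq) > 0:
            ext = max(len(normalize(m)) for m in mirnas.values()) \
                + config.max_bulge - 1
            scan_seq = tseq + tseq[:ext]
        for mid, mseq in mirnas.items():
            mseq = normalize(mseq)
            found = [
                MirnaTargetSite(mid, tid, s, e, "cleavage", sc, pairing)
                for sc, s, e, pairing in _candidate_sites(mseq, scan_seq,
                                                          config)
            ]
            if is_circ:
                found = _dedupe_circular(found, len(tseq))
            sites.extend(found)
    return _collapse(sites)


def detect_target_mimic(mirna_id: str, mirna: str,
                        target_id: str, target: str,
                        config: MirnaConfig | None = None,
                        circular: bool = False) -> list[MirnaTargetSite]:
    """Endogenous-target-mimic (miRNA sponge) sites on one target.

    Rules: (R1) perfect Watson-Crick pairing at the seed (miRNA positions
    2-8); (R2) a single bulge of 1-5 unpaired target nucleotides opposite
    miRNA positions 9-11, and no other bulge; (R3) at most 4 combined
    mismatches + G:U pairs over the remaining positions.
    """
    config = config or MirnaConfig()
    mseq = normalize(mirna)
    tseq = normalize(target)
    m = len(mseq)
    true_len = len(tseq)
    if circular and true_len:
        tseq = tseq + tseq[:m + config.max_bulge - 1]
    trev = tseq[::-1]
    L = len(trev)
    seed_lo, seed_hi = config.seed_region
    bmin, bmax = config.mimic_bulge_sizes
    sites: list[MirnaTargetSite] = []
    for j0 in range(L):          # trev index paired with miRNA position 1
        for gap_after in config.mimic_bulge_after:
            for bulge in range(bmin, bmax + 1):
                if j0 + m + bulge > L:
                    continue
                pairing = []
                mmgu = 0
                ok = True
                for i in range(1, m + 1):
                    j = j0 + (i - 1) + (bulge if i > gap_after else 0)
                    cls = _pair_class(mseq[i - 1], trev[j])
                    pairing.append(cls)
                    if i == gap_after:
                        pairing.append("-" * bulge)
                    if seed_lo <= i <= seed_hi:
                        if cls != "|":
                            ok = False
                            break
                    elif cls != "|":
                        mmgu += 1
                if not ok or mmgu > config.mimic_max_mm_gu:
                    continue
                # trev[j0 .. j0+m+bulge-1] -> original coordinates
                end = L - j0
                start = L - (j0 + m + bulge) + 1
                score = mmgu + config.bulge_penalty * bulge
                sites.append(MirnaTargetSite(
                    mirna_id, target_id, start, end, "mimic",
                    float(score), "".join(pairing)))
    sites = _collapse(sites)
    if circular and true_len:
        sites = _dedupe_circular(sites, true_len)
    return sites


def scan_interactions(mirnas: dict[str, str], targets: dict[str, str],
                      config: MirnaConfig | None = None,
                      circular: set[str] | frozenset[str] = frozenset()
                      ) -> list[MirnaTargetSite]:
    """Cleavage and mimic sites together, exclusively classified.

    A duplex satisfying the mimic rules is a sponge site, not a cleavage
    site: cleavage calls overlapping a mimic call for the same miRNA and
    target are dropped.
    """
    config = config or MirnaConfig()
    cleavage = scan_targets(mirnas, targets, config, circular)
    mimics: list[MirnaTargetSite] = []
    for tid, tseq in targets.items():
        for mid, mseq in mirnas.items():
            mimics.extend(detect_target_mimic(
                mid, mseq, tid, tseq, config, circular=tid in circular))
    kept_cleavage = []
    for site in cleavage:
        shadowed = any(m.mirna_id == site.mirna_id
                       and m.target_id == site.target_id
                       and m.start <= site.end and site.start <= m.end
                       for m in mimics)
        if not shadowed:
            kept_cleavage.append(site)
    out = kept_cleavage + mimics
    out.sort(key=lambda s: (s.target_id, s.mirna_id, s.start, s.kind))
    return out


def write_sites_tsv(sites: list[MirnaTargetSite], path) -> None:
    from .io import write_tsv
    cols = ["mirna", "target", "start", "end", "kind", "score", "pairing"]
    rows = [{"mirna": s.mirna_id, "target": s.target_id, "start": s.start,
             "end": s.end, "kind": s.kind, "score": s.score,
             "pairing": s.pairing} for s in sites]
    write_tsv(rows, cols, path)
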