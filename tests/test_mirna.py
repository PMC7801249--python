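"""Penalty-scored miRNA target sites and target-mimic (sponge) rules."""

import numpy as np
import pytest

from backsplice.io import revcomp
from backsplice.mirna import (MirnaConfig, detect_target_mimic,
                              scan_interactions, scan_targets, score_site)

WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


def perfect_window(mirna):
    """Target window pairing every miRNA base by Watson-Crick rules."""
    return revcomp(mirna)


def window_from_trev(trev):
    """Build a 5'->3' window from the reversed-target string in which
    index i-1 pairs miRNA position i."""
    return "".join(trev)[::-1]


def brute_force_min_score(mirna, window, config=None):
    """Enumerate every global alignment with at most one contiguous bulge
    of <= max_bulge nt per side; return the minimal penalty score."""
    config = config or MirnaConfig()
    M, W = len(mirna), len(window)
    trev = window[::-1]
    lo, hi = config.doubled_region

    def pen(base, pos):
        return base * (2.0 if lo <= pos <= hi else 1.0)

    def pair_pen(mb, tb, pos):
        if WC[mb] == tb:
            return 0.0
        if (mb, tb) in (("G", "T"), ("T", "G")):
            return pen(config.gu_penalty, pos)
        return pen(config.mismatch_penalty, pos)

    best = float("inf")
    for bm in range(0, config.max_bulge + 1):
        bt = W - (M - bm)
        if not (0 <= bt <= config.max_bulge):
            continue
        a_starts = [None] if bm == 0 else range(0, M - bm + 1)
        b_gaps = [None] if bt == 0 else range(0, M + 1)
        for a0 in a_starts:
            for g in b_gaps:
                if a0 is not None and g is not None and a0 < g < a0 + bm:
                    continue          # target bulge cannot split a miRNA run
                cost = 0.0
                paired_before = 0
                for i in range(1, M + 1):
                    in_a = a0 is not None and a0 < i <= a0 + bm
                    if in_a:
                        cost += pen(config.bulge_penalty, i)
                        continue
                    j = paired_before + (bt if (g is not None and g < i)
                                         else 0)
                    cost += pair_pen(mirna[i - 1], trev[j], i)
                    paired_before += 1
                if g is not None:
                    cost += bt * pen(config.bulge_penalty, min(g + 1, M))
                best = min(best, cost)
    return best


@pytest.fixture
def mirna21():
    rng = np.random.default_rng(5)
    return "".join(rng.choice(list("ACGT"), 21))


class TestScoreSite:
    def test_perfect_duplex_scores_zero(self, mirna21):
        score, pairing = score_site(mirna21, perfect_window(mirna21))
        assert score == 0.0
        assert pairing == "|" * 21

    def test_gu_outside_doubled_region(self, mirna21):
        trev = [WC[b] for b in mirna21]
        m = list(mirna21)
        m[14] = "G"            # position 15: G:U wobble, not doubled
        trev[14] = "T"
        score, pairing = score_site("".join(m), window_from_trev(trev))
        assert score == 0.5
        assert pairing[14] == "o"

    def test_mismatch_in_doubled_region(self, mirna21):
        trev = [WC[b] for b in mirna21]
        m = list(mirna21)
        m[4] = "A"             # position 5: A:G mismatch, doubled
        trev[4] = "G"
        score, pairing = score_site("".join(m), window_from_trev(trev))
        assert score == 2.0
        assert pairing[4] == "x"

    def test_u_and_t_equivalent(self, mirna21):
        w = perfect_window(mirna21)
        assert score_site(mirna21.replace("T", "U"), w)[0] == \
            score_site(mirna21, w)[0]

    def test_window_too_short_rejected(self, mirna21):
        with pytest.raises(ValueError):
            score_site(mirna21, "ACGT")

    def test_single_mismatch_strictly_increases_score(self, mirna21):
        w0 = perfect_window(mirna21)
        for i in range(len(w0)):
            for b in "ACGT":
                if b == w0[i]:
                    continue
                w = w0[:i] + b + w0[i + 1:]
                assert score_site(mirna21, w)[0] > 0.0

    def test_agrees_with_brute_force_enumeration(self):
        """DP equals exhaustive alignment enumeration on random pairs."""
        rng = np.random.default_rng(17)
        for _ in range(40):
            m = int(rng.integers(8, 12))
            mirna = "".join(rng.choice(list("ACGT"), m))
            wlen = int(rng.integers(m - 2, m + 3))
            window = "".join(rng.choice(list("ACGT"), wlen))
            cfg = MirnaConfig(max_bulge=2, score_cutoff=1e9)
            got, _ = score_site(mirna, window, cfg)
            assert got == pytest.approx(
                brute_force_min_score(mirna, window, cfg)), (mirna, window)


class TestScanTargets:
    def test_embedded_perfect_site_found(self, mirna21):
        rng = np.random.default_rng(9)
        flank5 = "".join(rng.choice(list("ACGT"), 40))
        flank3 = "".join(rng.choice(list("ACGT"), 39))
        target = flank5 + perfect_window(mirna21) + flank3
        sites = scan_targets({"mir1": mirna21}, {"t1": target})
        exact = [s for s in sites if s.score == 0.0]
        assert len(exact) == 1
        assert (exact[0].start, exact[0].end) == (41, 61)
        assert exact[0].kind == "cleavage"

    def test_hopeless_target_yields_nothing(self):
        assert scan_targets({"m": "A" * 21}, {"t": "A" * 80}) == []

    def test_overlapping_sites_collapsed_to_best(self, mirna21):
        target = perfect_window(mirna21)
        sites = scan_targets({"mir1": mirna21}, {"t1": target + "AA"})
        assert len(sites) == 1
        assert sites[0].score == 0.0

    def test_wraparound_site_on_circular_target(self, mirna21):
        rng = np.random.default_rng(21)
        flank = "".join(rng.choice(list("ACGT"), 60))
        linear = flank + perfect_window(mirna21)
        rotated = linear[-10:] + linear[:-10]    # hit now spans the seam
        hits_circ = scan_targets({"m": mirna21}, {"t": rotated},
                                 circular={"t"})
        assert any(s.score == 0.0 for s in hits_circ)
        hits_linear = scan_targets({"m": mirna21}, {"t": rotated})
        assert not any(s.score == 0.0 for s in hits_linear)


class TestTargetMimic:
    def _mimic_target(self, mirna, bulge="TTT", gap_after=10):
        trev = [WC[b] for b in mirna]
        trev = trev[:gap_after] + list(bulge) + trev[gap_after:]
        return window_from_trev(trev)

    def test_bulged_duplex_is_mimic(self, mirna21):
        target = self._mimic_target(mirna21)
        sites = detect_target_mimic("m", mirna21, "t", target)
        assert len(sites) >= 1
        assert all(s.kind == "mimic" for s in sites)
        assert "-" in sites[0].pairing

    def test_perfect_complement_is_not_mimic(self, mirna21):
        assert detect_target_mimic("m", mirna21, "t",
                                   perfect_window(mirna21)) == []

    def test_bulge_opposite_seed_rejected(self, mirna21):
        target = self._mimic_target(mirna21, gap_after=4)
        assert detect_target_mimic("m", mirna21, "t", target) == []

    def test_seed_mismatch_rejected(self, mirna21):
        trev = [WC[b] for b in mirna21]
        trev[3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[trev[3]]  # pos 4
        trev = trev[:10] + list("TTT") + trev[10:]
        assert detect_target_mimic("m", mirna21, "t",
                                   window_from_trev(trev)) == []

    def test_too_many_mismatches_rejected(self, mirna21):
        trev = [WC[b] for b in mirna21]
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for pos in (14, 16, 18, 20, 21):          # 5 > max 4 outside seed
            trev[pos - 1] = flip[trev[pos - 1]]
        trev = trev[:10] + list("TTT") + trev[10:]
        assert detect_target_mimic("m", mirna21, "t",
                                   window_from_trev(trev)) == []

    def test_cleavage_and_mimic_exclusive(self, mirna21):
        """A mimic duplex is never double-reported as a cleavage site at
        the same coordinates."""
        target = self._mimic_target(mirna21, bulge="T")  # 1 nt bulge
        sites = scan_interactions({"m": mirna21}, {"t": target})
        mimics = [s for s in sites if s.kind == "mimic"]
        cleavages = [s for s in sites if s.kind == "cleavage"]
        assert mimics
        for c in cleavages:
            assert not any(m.start <= c.end and c.start <= m.end
                           for m in mimics)
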