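"""Target prediction: penalty scheme, inhibition rule, scanner equivalence."""

import random

import pytest

from srnamir import targets as tg
from srnamir._util import revcomp

MIR = "TTGACAGAAGATAGAGAGCAC"  # 21 nt


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _perfect(mirna):
    return tg._align_ungapped(mirna, revcomp(mirna))


def _with_mismatch(mirna, pos):
    """Ungapped alignment with a forced mismatch at miRNA position pos."""
    site = list(revcomp(mirna))
    idx = len(mirna) - pos  # site index pairing miRNA position pos
    bad = {"A": "C", "C": "A", "G": "A", "T": "C"}[mirna[pos - 1]]
    site[idx] = bad
    return tg._align_ungapped(mirna, "".join(site))


def _with_gu(mirna, pos):
    """Replace the target base at miRNA position pos with a G:U wobble."""
    site = list(revcomp(mirna))
    idx = len(mirna) - pos
    wob = {"G": "T", "T": "G"}
    base = mirna[pos - 1]
    assert base in wob, "position must hold G or T for a wobble"
    site[idx] = wob[base]
    return tg._align_ungapped(mirna, "".join(site))


class TestScoreDuplex:
    def test_perfect_complement_is_zero(self):
        assert tg.score_duplex(_perfect(MIR)) == 0.0

    def test_gu_in_seed_is_doubled(self):
        # position 5 holds a C in MIR; use a miRNA with G at position 5
        mir = "TTGAGAGAAGATAGAGAGCAC"
        aln = _with_gu(mir, 5)
        assert aln.states[4] == tg.GU
        assert tg.score_duplex(aln) == 1.0

    def test_mismatch_and_gap_outside_seed(self):
        # mismatch at position 20 (1.0) plus a bulged miRNA base at 16 (2.0)
        site = list(revcomp(MIR))
        idx = len(MIR) - 20
        site[idx] = {"A": "C", "C": "A", "G": "A", "T": "C"}[MIR[19]]
        site_s = "".join(site)
        # removing the site base at index L-16 bulges out miRNA position 16
        aln = tg._align_mirna_gap(MIR, site_s[:5] + site_s[6:], 16)
        assert tg.score_duplex(aln) == 3.0

    def test_seed_mismatches_exceed_cutoff(self):
        aln = _with_mismatch(MIR, 4)
        assert tg.score_duplex(aln) == 2.0  # doubled inside seed

    def test_monotone_in_mismatches(self):
        base = _perfect(MIR)
        prev = tg.score_duplex(base)
        for pos in range(1, len(MIR) + 1):
            aln = _with_mismatch(MIR, pos)
            assert tg.score_duplex(aln) >= prev
        # cumulative mismatches only increase the score
        site = list(revcomp(MIR))
        scores = []
        for pos in (1, 15, 20):
            idx = len(MIR) - pos
            site[idx] = {"A": "C", "C": "A", "G": "A", "T": "C"}[MIR[pos - 1]]
            scores.append(
                tg.score_duplex(tg._align_ungapped(MIR, "".join(site)))
            )
        assert scores == sorted(scores)

    def test_positions_outside_seed_weigh_equally(self):
        scores = {tg.score_duplex(_with_mismatch(MIR, p)) for p in (14, 17, 21)}
        assert scores == {1.0}


class TestClassifyInhibition:
    def test_perfect_is_cleavage(self):
        assert tg.classify_inhibition(_perfect(MIR)) == "Cleavage"

    def test_central_mismatch_is_translation(self):
        assert tg.classify_inhibition(_with_mismatch(MIR, 10)) == "Translation"

    def test_central_gu_still_cleavage(self):
        mir = "TTGACAGAAGTTAGAGAGCAC"  # T at position 11 allows a wobble
        aln = _with_gu(mir, 11)
        assert aln.states[10] == tg.GU
        assert tg.classify_inhibition(aln) == "Cleavage"


def brute_force_hits(mirna, transcripts, cutoff):
    """Exhaustive offset x variant search, independent of the scanner."""
    L = len(mirna)
    found = {}
    for tid, tseq in transcripts.items():
        for width in (L - 1, L, L + 1):
            for start in range(0, len(tseq) - width + 1):
                aln = tg.best_site_alignment(mirna, tseq[start : start + width])
                if aln is None:
                    continue
                score = tg.score_duplex(aln)
                if score <= cutoff:
                    key = (tid, start)
                    if key not in found or score < found[key]:
                        found[key] = score
    return found


class TestScanTranscripts:
    def test_planted_perfect_site(self):
        rng = random.Random(2)
        t = {"t1": _random_seq(rng, 100) + revcomp(MIR) + _random_seq(rng, 100)}
        hits = tg.scan_transcripts("m", MIR, t)
        assert any(h.site_start == 100 and h.expectation == 0.0 for h in hits)
        best = min(hits, key=lambda h: h.expectation)
        assert best.inhibition == "Cleavage"

    def test_four_seed_mismatches_rejected(self):
        site = list(revcomp(MIR))
        for pos in (3, 5, 7, 9):
            idx = len(MIR) - pos
            site[idx] = {"A": "C", "C": "A", "G": "A", "T": "C"}[MIR[pos - 1]]
        rng = random.Random(3)
        t = {"t1": _random_seq(rng, 60) + "".join(site) + _random_seq(rng, 60)}
        aln = tg.best_site_alignment(MIR, "".join(site))
        assert tg.score_duplex(aln) == 8.0
        assert not any(h.site_start == 60 for h in tg.scan_transcripts("m", MIR, t))

    def test_matches_brute_force_oracle(self):
        rng = random.Random(5)
        mirnas = [MIR, _random_seq(rng, 21)]
        transcripts = {}
        for i in range(10):
            seq = _random_seq(rng, 200)
            if i < 8:  # plant a near-perfect site
                mir = mirnas[i % 2]
                site = list(revcomp(mir))
                if i % 3 == 0:  # one non-seed mismatch
                    site[2] = {"A": "C", "C": "A", "G": "A", "T": "C"}[mir[18]]
                off = rng.randint(20, 150)
                seq = seq[:off] + "".join(site) + seq[off + len(site) :]
            transcripts[f"t{i}"] = seq
        for mir in mirnas:
            oracle = brute_force_hits(mir, transcripts, 3.0)
            hits = tg.scan_transcripts("m", mir, transcripts, 3.0)
            got = {(h.transcript_id, h.site_start): h.expectation for h in hits}
            assert got == oracle

    def test_hit_counts_non_increasing_with_stricter_cutoff(self):
        rng = random.Random(7)
        t = {"t1": _random_seq(rng, 150) + revcomp(MIR) + _random_seq(rng, 150)}
        counts = [
            len(tg.scan_transcripts("m", MIR, t, cutoff)) for cutoff in (4.0, 3.0, 1.0, 0.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_all_hits_respect_cutoff(self):
        rng = random.Random(8)
        t = {"t1": _random_seq(rng, 120) + revcomp(MIR) + _random_seq(rng, 120)}
        for cutoff in (0.0, 2.0, 3.0):
            assert all(
                h.expectation <= cutoff
                for h in tg.scan_transcripts("m", MIR, t, cutoff)
            )

    def test_strict_mode_excludes_exact_cutoff(self):
        site = list(revcomp(MIR))
        idx = len(MIR) - 20
        site[idx] = {"A": "C", "C": "A", "G": "A", "T": "C"}[MIR[19]]
        idx = len(MIR) - 16
        site[idx] = {"A": "C", "C": "A", "G": "A", "T": "C"}[MIR[15]]
        # two non-seed mismatches: score 2.0; add one more for 3.0
        idx = len(MIR) - 14
        site[idx] = {"A": "C", "C": "A", "G": "A", "T": "C"}[MIR[13]]
        t = {"t1": "A" * 30 + "".join(site) + "A" * 30}
        aln = tg.best_site_alignment(MIR, "".join(site))
        assert tg.score_duplex(aln) == 3.0
        loose = tg.scan_transcripts("m", MIR, t, 3.0, strict=False)
        strict = tg.scan_transcripts("m", MIR, t, 3.0, strict=True)
        assert any(h.site_start == 30 for h in loose)
        assert not any(h.site_start == 30 for h in strict)

    def test_empty_transcripts(self):
        assert tg.scan_transcripts("m", MIR, {}) == []
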