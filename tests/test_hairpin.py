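"""Hairpin discovery: genome anchoring, precursor evaluation, naming."""

import random

import pytest

from srnamir import hairpin as hp
from srnamir._util import revcomp
from srnamir.sequence_io import SmallRNATag

RNG = random.Random(17)


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def ideal_hairpin(mature="TTGACAGAAGATAGAGAGCAC", pad=3, loop=8, seed=2):
    """Perfect inverted repeat: (pad+mature+pad) + loop + revcomp."""
    rng = random.Random(seed)
    stem = _random_seq(rng, pad) + mature + _random_seq(rng, pad)
    precursor = stem + _random_seq(rng, loop) + revcomp(stem)
    return precursor, (pad, pad + len(mature))


# mutate a mature-partner base so the pair becomes non-canonical (no wobble)
_BREAK = {"A": "C", "C": "A", "G": "A", "T": "C"}


class TestGenomeMatch:
    def test_plus_strand(self):
        rng = random.Random(1)
        g = {"chr": _random_seq(rng, 500)}
        tag = g["chr"][100:121]
        loci = hp.genome_match(tag, g)
        assert hp.GenomeLocus("chr", 100, 121, "+") in loci

    def test_minus_strand(self):
        rng = random.Random(2)
        g = {"chr": _random_seq(rng, 500)}
        tag = revcomp(g["chr"][100:121])
        assert hp.GenomeLocus("chr", 100, 121, "-") in hp.genome_match(tag, g)

    def test_multi_locus_matches_naive_scan(self):
        rng = random.Random(3)
        tag = _random_seq(rng, 21)
        g = {"chr": tag + _random_seq(rng, 50) + tag + _random_seq(rng, 50) + revcomp(tag)}
        loci = hp.genome_match(tag, g)
        naive = []
        for s in range(len(g["chr"]) - 20):
            if g["chr"][s : s + 21] == tag:
                naive.append((s, "+"))
            if g["chr"][s : s + 21] == revcomp(tag):
                naive.append((s, "-"))
        assert sorted((l.start, l.strand) for l in loci) == sorted(naive)
        assert len(loci) == 3


class TestExtractWindows:
    def test_centered_locus(self):
        rng = random.Random(4)
        g = {"chr": _random_seq(rng, 1000)}
        locus = hp.GenomeLocus("chr", 500, 521, "+")
        wins = hp.extract_precursor_windows(locus, g, flank=150)
        assert len(wins) == 2
        for window, ms, me in wins:
            assert len(window) == 191
            assert window[ms:me] == g["chr"][500:521]

    def test_clipped_at_boundary(self):
        rng = random.Random(5)
        g = {"chr": _random_seq(rng, 1000)}
        locus = hp.GenomeLocus("chr", 10, 31, "+")
        for window, ms, me in hp.extract_precursor_windows(locus, g, flank=150):
            assert window[ms:me] == g["chr"][10:31]

    def test_minus_strand_round_trip(self):
        rng = random.Random(6)
        g = {"chr": _random_seq(rng, 1000)}
        tag_plus = g["chr"][400:421]
        locus = hp.GenomeLocus("chr", 400, 421, "-")
        for window, ms, me in hp.extract_precursor_windows(locus, g, flank=100):
            # window is the revcomp of the + strand extraction
            assert window[ms:me] == revcomp(tag_plus)
            assert revcomp(window) in g["chr"]

    def test_bad_flank(self):
        with pytest.raises(ValueError):
            hp.extract_precursor_windows(
                hp.GenomeLocus("chr", 0, 21, "+"), {"chr": "A" * 100}, flank=0
            )


class TestEvaluateHairpin:
    def test_ideal_hairpin_passes(self):
        pre, mat = ideal_hairpin()
        ok, cand = hp.evaluate_hairpin(pre, mat)
        assert ok
        assert cand.duplex_mismatches == 0
        assert cand.arm == "5p"
        assert cand.paired_fraction_mature == 1.0
        assert cand.loop_length >= 3

    def test_star_has_two_nt_overhang_geometry(self):
        pre, (ms, me) = ideal_hairpin()
        ok, cand = hp.evaluate_hairpin(pre, (ms, me))
        assert ok
        # for a perfect duplex the star is the revcomp of the mature shifted 2
        star_expected = pre[len(pre) - me - 2 + 2 - 2 : len(pre) - ms + 2 - 2]
        n = len(pre)
        lo, hi = (n - 1 - (me - 1)) + 2, (n - 1 - ms) + 2
        assert cand.star_seq == pre[lo : hi + 1]
        assert len(cand.star_seq) == me - ms

    def test_mature_across_loop_fails(self):
        pre, _ = ideal_hairpin(pad=3, loop=8)
        stem_len = (len(pre) - 8) // 2
        # interval straddling the terminal loop
        ok, _ = hp.evaluate_hairpin(pre, (stem_len - 10, stem_len + 8 + 3))
        assert not ok

    def test_3p_arm_mature(self):
        mature = "TTGACAGAAGATAGAGAGCAC"
        rng = random.Random(9)
        stem = _random_seq(rng, 4) + mature + _random_seq(rng, 4)
        pre = revcomp(stem) + _random_seq(rng, 9) + stem
        ms = len(stem) + 9 + 4
        ok, cand = hp.evaluate_hairpin(pre, (ms, ms + len(mature)))
        assert ok
        assert cand.arm == "3p"

    @pytest.mark.parametrize("n_mut,default_pass", [(3, True), (5, False)])
    def test_duplex_mismatch_threshold(self, n_mut, default_pass):
        """Point-mutated ideal hairpin; mismatches counted on the duplex."""
        mature = "TTGACAGAAGATAGAGAGCAC"
        pre, (ms, me) = ideal_hairpin(mature, pad=6, loop=10, seed=31)
        n = len(pre)
        stem = (n - 10) // 2
        pre_l = list(pre)
        structure = ["."] * n
        broken = set()
        for k in range(n_mut):  # break spaced pairs inside the mature
            i = ms + 2 + 3 * k
            pre_l[n - 1 - i] = _BREAK[pre[i]]
            broken.add(i)
        for i in range(stem):  # the ideal pairing minus the broken pairs
            if i not in broken:
                structure[i] = "("
                structure[n - 1 - i] = ")"
        mutated = "".join(pre_l)
        from srnamir.folding import structure_energy

        db = "".join(structure)
        fold = (db, structure_energy(mutated, db))
        ok_default, cand = hp.evaluate_hairpin(mutated, (ms, me), fold=fold)
        assert cand.duplex_mismatches == n_mut
        assert cand.bulge_asymmetry == 0
        assert ok_default is default_pass
        relaxed = hp.HairpinParams(max_duplex_mismatches=5)
        ok_relaxed, _ = hp.evaluate_hairpin(mutated, (ms, me), relaxed, fold=fold)
        assert ok_relaxed

    def test_threshold_monotonicity(self):
        """Tightening mfe_max or min_paired never converts fail into pass."""
        cases = []
        for seed in range(6):
            pre, mat = ideal_hairpin(pad=4, loop=9, seed=seed)
            cases.append((pre, mat))
        rng = random.Random(0)
        cases.append(("".join(rng.choice("ACGT") for _ in range(80)), (10, 31)))
        for pre, mat in cases:
            results = []
            for mfe_max, min_paired in [(-10, 0.4), (-18, 0.6), (-30, 0.8)]:
                params = hp.HairpinParams(
                    mfe_max=mfe_max, min_paired_fraction=min_paired
                )
                results.append(hp.evaluate_hairpin(pre, mat, params)[0])
            # pass set shrinks as thresholds tighten
            for loose, tight in zip(results, results[1:]):
                assert loose or not tight

    def test_mature_outside_precursor_errors(self):
        pre, _ = ideal_hairpin()
        with pytest.raises(ValueError):
            hp.evaluate_hairpin(pre, (0, len(pre) + 5))


class TestMatchMirbase:
    REF = {
        "nta-miR156a": "TTGACAGAAGATAGAGAGCAC",
        "nta-miR156e": "TTGATAGAAGATAGAGAGCAC",
        "nta-miR172a": "AGAATCATGATGATGCTGCAT",
    }

    def test_identity(self):
        assert hp.match_mirbase("TTGACAGAAGATAGAGAGCAC", self.REF) == (
            "nta-miR156a",
            0,
        )

    def test_published_pair_distance_one(self):
        # the two printed 21-mers differ at a single position
        a, e = self.REF["nta-miR156a"], self.REF["nta-miR156e"]
        assert sum(x != y for x, y in zip(a, e)) == 1
        assert hp.alignment_distance(a, e) == 1

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            hp.match_mirbase("TTGACAGAAGATAGAGAGCAC", {})

    def test_overhang_convention_matches_exhaustive_offsets(self):
        rng = random.Random(41)

        def oracle(a, b):
            best = len(a) + len(b)
            for off in range(-len(a), len(b) + 1):
                ham = overlap = 0
                for k in range(len(a)):
                    p = k + off
                    if 0 <= p < len(b):
                        overlap += 1
                        ham += a[k] != b[p]
                best = min(best, ham + (len(a) - overlap) + (len(b) - overlap))
            return best

        for _ in range(60):
            a = _random_seq(rng, rng.randint(18, 24))
            b = _random_seq(rng, rng.randint(18, 24))
            assert hp.alignment_distance(a, b) == oracle(a, b)
        # deletion case: 21-mer vs its 20-mer with one internal deletion
        a = _random_seq(rng, 21)
        b = a[:10] + a[11:]
        assert hp.alignment_distance(a, b) == oracle(a, b)


class TestClassifyAndName:
    def _candidate(self, seq, count=50):
        pre, mat = ideal_hairpin(seq, pad=4, loop=9, seed=len(seq))
        ok, cand = hp.evaluate_hairpin(pre, mat)
        assert ok
        return hp.Candidate(SmallRNATag(seq, count, count), cand, [])

    def test_conserved_vs_new_threshold(self):
        ref = {"osa-miR156a": "TTGACAGAAGATAGAGAGCAC"}
        exact = self._candidate("TTGACAGAAGATAGAGAGCAC")
        three_off = self._candidate("TTGACAGAAGATAGACACACC")
        assert hp.alignment_distance(three_off.tag.sequence, exact.tag.sequence) >= 3
        records = hp.classify_and_name([exact, three_off], ref)
        by_seq = {r.mature_seq: r for r in records}
        assert by_seq["TTGACAGAAGATAGAGAGCAC"].klass == "conserved"
        assert by_seq["TTGACAGAAGATAGAGAGCAC"].family == "nta-miR156"
        assert by_seq["TTGACAGAAGATAGACACACC"].klass == "new"

    def test_new_family_single_linkage(self):
        # 5-sequence toy set: a~b (distance 1), c~d (distance 2), e alone
        base1 = "GGATTCCGGATTACGGATTCC"
        base2 = "CCTTAAGGCCATATCCTTAGG"
        base3 = "ACACACGTGTGTACACACGTG"
        seqs = {
            "a": base1,
            "b": base1[:5] + ("A" if base1[5] != "A" else "C") + base1[6:],
            "c": base2,
            "d": base2[:3] + ("G" if base2[3] != "G" else "T") + base2[4:8]
            + ("G" if base2[8] != "G" else "T") + base2[9:],
            "e": base3,
        }
        # independent single-linkage oracle on pairwise distances
        roots = hp._single_linkage(list(seqs.values()), 2)
        assert roots[0] == roots[1]
        assert roots[2] == roots[3]
        assert len(set(roots)) == 3
        ref = {"xxx-miR9999": "T" * 21}
        cands = [self._candidate(s, count=100 - 10 * i) for i, s in enumerate(seqs.values())]
        records = hp.classify_and_name(cands, ref)
        fam = {r.mature_seq: r.family for r in records}
        assert fam[seqs["a"]] == fam[seqs["b"]] == "nta-miRn1"
        assert fam[seqs["c"]] == fam[seqs["d"]] == "nta-miRn2"
        assert fam[seqs["e"]] == "nta-miRn3"
        names = {r.mature_seq: r.name for r in records}
        assert names[seqs["a"]] == "nta-miRn1a"
        assert names[seqs["b"]] == "nta-miRn1b"
        assert names[seqs["e"]] == "nta-miRn3"

    def test_star_partner_named_with_suffix(self):
        mature = "TTGACAGAAGATAGAGAGCAC"
        pre, mat = ideal_hairpin(mature, pad=6, loop=10, seed=8)
        ok, cand = hp.evaluate_hairpin(pre, mat)
        assert ok
        star_seq = cand.star_seq
        ok2, cand2 = hp.evaluate_hairpin(
            pre, (pre.index(star_seq), pre.index(star_seq) + len(star_seq))
        )
        assert ok2
        ref = {"ath-miR156a": mature}
        records = hp.classify_and_name(
            [
                hp.Candidate(SmallRNATag(mature, 100, 100), cand, []),
                hp.Candidate(SmallRNATag(star_seq, 5, 5), cand2, []),
            ],
            ref,
        )
        by_seq = {r.mature_seq: r for r in records}
        assert by_seq[mature].name == "nta-miR156"
        assert by_seq[star_seq].name == "nta-miR156*"
        assert by_seq[star_seq].is_star


class TestRecordInvariants:
    def test_class_consistency_enforced(self):
        pre, mat = ideal_hairpin()
        _, cand = hp.evaluate_hairpin(pre, mat)
        with pytest.raises(ValueError):
            hp.MiRNARecord(
                "x", "fam", "A" * 21, "conserved", "ref", 5, cand
            )
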