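"""Genome-anchored miRNA hairpin discovery.

Candidate tags are located on the genomic references by exact match, a
precursor window around each locus is folded with the package's MFE dynamic
program, and the fold is screened against community-standard plant miRNA
annotation criteria (mature on one arm of a single stem-loop, a mostly
paired mature:star duplex with limited mismatches and asymmetric bulges, a
stable fold).  Surviving candidates are split into conserved miRNAs (close
homologs of a known mature reference) and new miRNAs, and named.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._util import revcomp
from .folding import fold_mfe, pair_table
from .sequence_io import SmallRNATag

DEFAULT_FLANK = 150
DEFAULT_MFE_MAX = -18.0
DEFAULT_MAX_DUPLEX_MISMATCHES = 4
DEFAULT_MAX_BULGE_ASYMMETRY = 2
DEFAULT_MIN_PAIRED_FRACTION = 0.60
DEFAULT_MAX_CONSERVED_MISMATCHES = 2  # "fewer than 3" homology mismatches


@dataclass(frozen=True)
class GenomeLocus:
    source_id: str
    start: int  # 0-based half-open
    end: int
    strand: str  # '+' or '-'


@dataclass
class HairpinCandidate:
    precursor_seq: str
    structure: str
    mfe: float
    mature_start: int  # offsets on the precursor sense strand, half-open
    mature_end: int
    arm: str | None = None  # '5p' or '3p'
    star_seq: str = ""
    paired_fraction_mature: float = 0.0
    duplex_mismatches: int = 0
    bulge_asymmetry: int = 0
    loop_length: int = 0

    @property
    def mature_seq(self) -> str:
        return self.precursor_seq[self.mature_start : self.mature_end]


@dataclass
class HairpinParams:
    mfe_max: float = DEFAULT_MFE_MAX
    max_duplex_mismatches: int = DEFAULT_MAX_DUPLEX_MISMATCHES
    max_bulge_asymmetry: int = DEFAULT_MAX_BULGE_ASYMMETRY
    min_paired_fraction: float = DEFAULT_MIN_PAIRED_FRACTION


@dataclass
class MiRNARecord:
    name: str
    family: str
    mature_seq: str
    klass: str  # 'conserved' or 'new'
    best_match: str | None
    mismatches: int | None
    precursor: HairpinCandidate
    loci: list[GenomeLocus] = field(default_factory=list)
    count_a: int = 0
    count_b: int = 0
    is_star: bool = False

    @property
    def ml(self) -> int:
        return len(self.mature_seq)

    def __post_init__(self) -> None:
        conserved = self.mismatches is not None and self.mismatches <= (
            DEFAULT_MAX_CONSERVED_MISMATCHES
        )
        if (self.klass == "conserved") != conserved and not self.is_star:
            raise ValueError(
                f"{self.name}: class {self.klass!r} inconsistent with "
                f"mismatches={self.mismatches}"
            )


def genome_match(tag: str, genome: Mapping[str, str]) -> list[GenomeLocus]:
    """All loci where the tag occurs exactly (reverse complement on '-')."""
    loci: list[GenomeLocus] = []
    rc = revcomp(tag)
    for name, seq in genome.items():
        for query, strand in ((tag, "+"), (rc, "-")):
            start = seq.find(query)
            while start != -1:
                loci.append(GenomeLocus(name, start, start + len(tag), strand))
                start = seq.find(query, start + 1)
    return loci


def extract_precursor_windows(
    locus: GenomeLocus, genome: Mapping[str, str], flank: int = DEFAULT_FLANK
) -> list[tuple[str, int, int]]:
    """Candidate precursor windows around a locus.

    Two windows per locus -- mature near the window 3' end (long upstream
    flank) and near the 5' end (long downstream flank) -- clipped at source
    boundaries; '-' strand loci are reverse complemented so the mature
    offsets are always on the precursor sense strand.
    Returns (window_seq, mature_start, mature_end) triples.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    seq = genome[locus.source_id]
    n = len(seq)
    spans = [
        (max(0, locus.start - flank), min(n, locus.end + 20)),
        (max(0, locus.start - 20), min(n, locus.end + flank)),
    ]
    out = []
    seen = set()
    for ws, we in spans:
        if (ws, we) in seen:
            continue
        seen.add((ws, we))
        window = seq[ws:we]
        if locus.strand == "+":
            ms, me = locus.start - ws, locus.end - ws
        else:
            window = revcomp(window)
            ms, me = we - locus.end, we - locus.start
        out.append((window, ms, me))
    return out


def _hairpin_loops(pt) -> list[tuple[int, int]]:
    """Closed intervals (i+1, j-1) of hairpin loops (innermost pairs)."""
    loops = []
    for i, j in enumerate(pt):
        if j > i and all(pt[k] == -1 for k in range(i + 1, j)):
            loops.append((i + 1, j - 1))
    return loops


def evaluate_hairpin(
    precursor: str,
    mature_offsets: tuple[int, int],
    params: HairpinParams | None = None,
    fold: tuple[str, float] | None = None,
) -> tuple[bool, HairpinCandidate]:
    """Fold a precursor and score it against the miRNA structural criteria.

    Pass requires: mature entirely on one arm of a single stem-loop (no base
    in a terminal loop, partners strictly monotone); mature:star duplex
    mismatches and total asymmetric bulge within limits; mature mostly
    paired; fold stable (mfe <= mfe_max); terminal loop >= 3 nt.  The star
    is placed with the canonical 2-nt 3' overhang.
    """
    params = params or HairpinParams()
    ms, me = mature_offsets
    if not (0 <= ms < me <= len(precursor)):
        raise ValueError(f"mature interval ({ms},{me}) outside precursor")
    structure, mfe = fold if fold is not None else fold_mfe(precursor)
    pt = pair_table(structure)
    cand = HairpinCandidate(precursor, structure, mfe, ms, me)

    mature_positions = list(range(ms, me))
    paired = [k for k in mature_positions if pt[k] != -1]
    cand.paired_fraction_mature = len(paired) / len(mature_positions)
    if not paired:
        return False, cand

    partners = [int(pt[k]) for k in paired]
    if all(p >= me for p in partners):
        cand.arm = "5p"
    elif all(p < ms for p in partners):
        cand.arm = "3p"
    else:
        return False, cand  # mature straddles the terminal loop / stems
    # single helix side: partners strictly decrease along the mature
    monotone = all(q < p for p, q in zip(partners, partners[1:]))

    # terminal loop of the mature's stem: descend along the leftmost branch
    i = paired[-1] if cand.arm == "5p" else int(pt[paired[0]])
    j = int(pt[i])
    while True:
        inner = next((k for k in range(i + 1, j) if pt[k] > k), None)
        if inner is None:
            break
        i, j = inner, int(pt[inner])
    cand.loop_length = j - i - 1
    in_terminal_loop = any(
        lo <= k <= hi for k in mature_positions for lo, hi in _hairpin_loops(pt)
    )

    # duplex geometry: mismatches face each other, bulges are asymmetric
    mism = paired[0] - ms + (me - 1 - paired[-1])  # frayed mature ends
    asym = 0
    for k1, k2 in zip(paired, paired[1:]):
        d_m = k2 - k1 - 1
        d_s = abs(int(pt[k1]) - int(pt[k2])) - 1
        mism += min(d_m, d_s)
        asym += abs(d_m - d_s)
    cand.duplex_mismatches = mism
    cand.bulge_asymmetry = asym

    # star with canonical 2-nt 3' overhang (extrapolate frayed mature ends)
    first, last = paired[0], paired[-1]
    p_ms = int(pt[first]) + (first - ms)
    p_me = int(pt[last]) - (me - 1 - last)
    lo = max(0, min(p_me, p_ms) + 2)
    hi = min(len(precursor) - 1, max(p_me, p_ms) + 2)
    cand.star_seq = precursor[lo : hi + 1]

    ok = (
        monotone
        and not in_terminal_loop
        and mism <= params.max_duplex_mismatches
        and asym <= params.max_bulge_asymmetry
        and cand.paired_fraction_mature >= params.min_paired_fraction
        and mfe <= params.mfe_max
        and cand.loop_length >= 3
    )
    return ok, cand


def alignment_distance(a: str, b: str) -> int:
    """Best ungapped end-to-end distance: overlap Hamming + overhang bases."""
    la, lb = len(a), len(b)
    best = la + lb
    for off in range(-(la - 1), lb):
        lo_a = max(0, -off)
        hi_a = min(la, lb - off)
        overlap = hi_a - lo_a
        if overlap <= 0:
            continue
        ham = sum(1 for k in range(lo_a, hi_a) if a[k] != b[k + off])
        d = ham + (la - overlap) + (lb - overlap)
        if d < best:
            best = d
    return best


def match_mirbase(
    mature_seq: str, mature_reference_set: Mapping[str, str]
) -> tuple[str, int]:
    """Closest reference mature (ties broken lexicographically by name)."""
    if not mature_reference_set:
        raise ValueError("empty mature reference set")
    best_name, best_d = None, None
    for name in sorted(mature_reference_set):
        d = alignment_distance(mature_seq, mature_reference_set[name])
        if best_d is None or d < best_d:
            best_name, best_d = name, d
    return best_name, best_d


_FAMILY_RE = re.compile(r"(miR\d+)", re.IGNORECASE)


def family_of(mirbase_name: str) -> str:
    """Family token of a mature miRNA name: 'xyz-miR156a' -> 'miR156'."""
    m = _FAMILY_RE.search(mirbase_name)
    return m.group(1) if m else mirbase_name


@dataclass
class Candidate:
    """A tag that passed hairpin evaluation, pre-classification."""

    tag: SmallRNATag
    hairpin: HairpinCandidate
    loci: list[GenomeLocus]


def _single_linkage(seqs: Sequence[str], max_dist: int) -> list[int]:
    """Cluster ids by single linkage at alignment distance <= max_dist."""
    n = len(seqs)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if alignment_distance(seqs[i], seqs[j]) <= max_dist:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    return [find(i) for i in range(n)]


_SUFFIXES = "abcdefghijklmnopqrstuvwxyz"


def _letter(i: int) -> str:
    # a..z, then aa, ab, ... for pathological family sizes
    s = ""
    while True:
        s = _SUFFIXES[i % 26] + s
        i = i // 26 - 1
        if i < 0:
            return s


def classify_and_name(
    candidates: Sequence[Candidate],
    mirbase_set: Mapping[str, str],
    max_conserved_mismatches: int = DEFAULT_MAX_CONSERVED_MISMATCHES,
    species_prefix: str = "nta",
) -> list[MiRNARecord]:
    """Split passing candidates into conserved/new miRNAs and name them.

    Conserved: within ``max_conserved_mismatches`` of a reference mature;
    family inherited from the match.  New: families formed by single-linkage
    grouping among new matures, named {prefix}-miRn1, -miRn2, ... with letter
    suffixes inside multi-member families.  A candidate whose sequence equals
    the computed star of a better-supported candidate is reported as that
    miRNA's star ("*" suffix).
    """
    ordered = sorted(candidates, key=lambda c: (-c.tag.total, c.tag.sequence))
    by_seq = {c.tag.sequence: c for c in ordered}

    star_parent: dict[str, Candidate] = {}  # star seq -> parent candidate
    for c in ordered:
        star = c.hairpin.star_seq
        partner = by_seq.get(star)
        if (
            partner is not None
            and partner.tag.sequence != c.tag.sequence
            and partner.tag.total <= c.tag.total
            and c.tag.sequence not in star_parent  # parents are not stars
            and partner.tag.sequence not in star_parent
        ):
            star_parent[partner.tag.sequence] = c

    matched = {
        c.tag.sequence: match_mirbase(c.tag.sequence, mirbase_set) for c in ordered
    }
    non_star = [c for c in ordered if c.tag.sequence not in star_parent]
    conserved = [
        c for c in non_star if matched[c.tag.sequence][1] <= max_conserved_mismatches
    ]
    new = [c for c in non_star if matched[c.tag.sequence][1] > max_conserved_mismatches]

    records: dict[str, MiRNARecord] = {}

    # conserved families from the matched reference names
    fam_members: dict[str, list[Candidate]] = {}
    for c in conserved:
        fam_members.setdefault(family_of(matched[c.tag.sequence][0]), []).append(c)
    for fam, members in fam_members.items():
        for i, c in enumerate(members):
            suffix = _letter(i) if len(members) > 1 else ""
            name = f"{species_prefix}-{fam}{suffix}"
            records[c.tag.sequence] = MiRNARecord(
                name,
                f"{species_prefix}-{fam}",
                c.tag.sequence,
                "conserved",
                matched[c.tag.sequence][0],
                matched[c.tag.sequence][1],
                c.hairpin,
                c.loci,
                c.tag.count_a,
                c.tag.count_b,
            )

    # new families by single linkage among new matures
    seqs = [c.tag.sequence for c in new]
    roots = _single_linkage(seqs, max_conserved_mismatches)
    clusters: dict[int, list[Candidate]] = {}
    for c, r in zip(new, roots):
        clusters.setdefault(r, []).append(c)
    for fam_idx, members in enumerate(
        sorted(clusters.values(), key=lambda ms: (-ms[0].tag.total, ms[0].tag.sequence)),
        start=1,
    ):
        fam = f"{species_prefix}-miRn{fam_idx}"
        for i, c in enumerate(members):
            suffix = _letter(i) if len(members) > 1 else ""
            records[c.tag.sequence] = MiRNARecord(
                f"{fam}{suffix}",
                fam,
                c.tag.sequence,
                "new",
                matched[c.tag.sequence][0],
                matched[c.tag.sequence][1],
                c.hairpin,
                c.loci,
                c.tag.count_a,
                c.tag.count_b,
            )

    # stars inherit name/family/class from their parent
    out = list(records.values())
    for star_seq, parent in star_parent.items():
        c = by_seq[star_seq]
        pr = records.get(parent.tag.sequence)
        if pr is None:
            continue
        out.append(
            MiRNARecord(
                pr.name + "*",
                pr.family,
                star_seq,
                pr.klass,
                matched[star_seq][0],
                matched[star_seq][1],
                c.hairpin,
                c.loci,
                c.tag.count_a,
                c.tag.count_b,
                is_star=True,
            )
        )
    out.sort(key=lambda r: (-(r.count_a + r.count_b), r.name))
    return out


def discover(
    tags: Sequence[SmallRNATag],
    genome: Mapping[str, str],
    mirbase_set: Mapping[str, str],
    assignments: Mapping[str, str] | None = None,
    flank: int = DEFAULT_FLANK,
    params: HairpinParams | None = None,
    min_candidate_count: int = 5,
    max_conserved_mismatches: int = DEFAULT_MAX_CONSERVED_MISMATCHES,
    species_prefix: str = "nta",
) -> list[MiRNARecord]:
    """Full discovery pass: anchor, fold, screen, classify and name.

    Tags annotated to a non-miRNA class are excluded when ``assignments`` is
    given; tags below ``min_candidate_count`` total redundant reads are not
    examined.  A tag passing at any locus is counted once (best-MFE passing
    window retained; all loci recorded).
    """
    params = params or HairpinParams()
    candidates: list[Candidate] = []
    for tag in tags:
        if tag.total < min_candidate_count:
            continue
        if assignments is not None and assignments.get(tag.sequence, "unannotated") != (
            "unannotated"
        ):
            continue
        loci = genome_match(tag.sequence, genome)
        if not loci:
            continue
        best: HairpinCandidate | None = None
        for locus in loci:
            for window, ms, me in extract_precursor_windows(locus, genome, flank):
                if "N" in window:
                    continue
                ok, cand = evaluate_hairpin(window, (ms, me), params)
                if ok and (best is None or cand.mfe < best.mfe):
                    best = cand
        if best is not None:
            candidates.append(Candidate(tag, best, loci))
    return classify_and_name(
        candidates, mirbase_set, max_conserved_mismatches, species_prefix
    )
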