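"""Plant miRNA target prediction by seed-weighted complementarity scoring.

Each transcript is scanned on the sense strand for sites whose
miRNA:target duplex scores at or below a cutoff (default 3.0 points) under
the community-standard plant scheme: mismatch 1.0, G:U wobble 0.5, gap
(bulge) 2.0, every penalty doubled within the seed region (miRNA positions
2-13 counted from the 5' end).  A hit is labelled Cleavage when the central
positions (9-11) are fully paired (G:U counts as pairing), otherwise
Translation (translational repression).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from ._util import normalize_seq, revcomp

MATCH, GU, MISMATCH, GAP_MIRNA, GAP_TARGET = "match", "GU", "mismatch", "gap_mirna", "gap_target"

DEFAULT_CUTOFF = 3.0
SEED_RANGE = (2, 13)  # inclusive, miRNA positions from the 5' end (1-based)
CENTRAL_RANGE = (9, 11)
PENALTY = {MISMATCH: 1.0, GU: 0.5, GAP_MIRNA: 2.0, GAP_TARGET: 2.0, MATCH: 0.0}

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}  # G:U wobble in DNA letters


@dataclass(frozen=True)
class DuplexAlignment:
    """miRNA (5'->3') vs target site (sense strand) pairing states.

    ``states`` is one entry per alignment column, 5'->3' along the miRNA;
    ``positions`` gives each column's miRNA position (1-based; a target-gap
    column carries the position of the following miRNA base).
    """

    mirna_seq: str
    site_seq: str
    states: tuple[str, ...]
    positions: tuple[int, ...]


@dataclass(frozen=True)
class TargetHit:
    mirna_name: str
    transcript_id: str
    site_start: int  # 0-based on the transcript
    site_seq: str
    expectation: float
    inhibition: str  # 'Cleavage' or 'Translation'
    alignment: DuplexAlignment = field(compare=False)


def _pair_state(mirna_base: str, target_base: str) -> str:
    pair = (mirna_base, target_base)
    if pair in _WC:
        return MATCH
    if pair in _GU:
        return GU
    return MISMATCH


def score_duplex(
    alignment: DuplexAlignment,
    seed: tuple[int, int] = SEED_RANGE,
    penalties: Mapping[str, float] = PENALTY,
) -> float:
    """Expectation points: per-column penalties, doubled in the seed."""
    total = 0.0
    for state, pos in zip(alignment.states, alignment.positions):
        p = penalties[state] if state in (MISMATCH, GU) else (
            penalties[GAP_MIRNA] if state in (GAP_MIRNA, GAP_TARGET) else 0.0
        )
        if seed[0] <= pos <= seed[1]:
            p *= 2.0
        total += p
    return total


def classify_inhibition(
    alignment: DuplexAlignment, central: tuple[int, int] = CENTRAL_RANGE
) -> str:
    """Translation iff a mismatch or gap falls on the central positions."""
    for state, pos in zip(alignment.states, alignment.positions):
        if central[0] <= pos <= central[1] and state not in (MATCH, GU):
            return "Translation"
    return "Cleavage"


def _align_ungapped(mirna: str, site: str) -> DuplexAlignment:
    """Site length == miRNA length; miRNA 5' end pairs the site 3' end."""
    L = len(mirna)
    states = tuple(_pair_state(mirna[k], site[L - 1 - k]) for k in range(L))
    return DuplexAlignment(mirna, site, states, tuple(range(1, L + 1)))


def _align_mirna_gap(mirna: str, site: str, g: int) -> DuplexAlignment:
    """miRNA base at 1-based position g is bulged out (unpaired); site is L-1 long."""
    L = len(mirna)
    states, positions = [], []
    si = len(site) - 1  # consume site 3'->5'
    for k in range(L):
        pos = k + 1
        if pos == g:
            states.append(GAP_MIRNA)
            positions.append(pos)
        else:
            states.append(_pair_state(mirna[k], site[si]))
            positions.append(pos)
            si -= 1
    return DuplexAlignment(mirna, site, tuple(states), tuple(positions))


def _align_target_gap(mirna: str, site: str, g: int) -> DuplexAlignment:
    """A target base is bulged out before miRNA position g; site is L+1 long."""
    L = len(mirna)
    states, positions = [], []
    si = len(site) - 1
    for k in range(L):
        pos = k + 1
        if pos == g:
            states.append(GAP_TARGET)
            positions.append(pos)
            si -= 1
        states.append(_pair_state(mirna[k], site[si]))
        positions.append(pos)
        si -= 1
    return DuplexAlignment(mirna, site, tuple(states), tuple(positions))


def best_site_alignment(mirna: str, site: str) -> DuplexAlignment | None:
    """Best-scoring alignment of a miRNA against one candidate site.

    The site may be L-1, L or L+1 bases long (single-gap variants).
    """
    L = len(mirna)
    cands: list[DuplexAlignment] = []
    if len(site) == L:
        cands.append(_align_ungapped(mirna, site))
    elif len(site) == L - 1:
        cands.extend(_align_mirna_gap(mirna, site, g) for g in range(1, L + 1))
    elif len(site) == L + 1:
        cands.extend(_align_target_gap(mirna, site, g) for g in range(2, L + 1))
    if not cands:
        return None
    return min(cands, key=score_duplex)


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
# base-pair penalty between a miRNA base (row) and a target base (column)
_P4 = np.ones((4, 4))
for _a, _b in ((0, 3), (3, 0), (2, 1), (1, 2)):
    _P4[_a, _b] = 0.0
for _a, _b in ((2, 3), (3, 2)):
    _P4[_a, _b] = PENALTY[GU]


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, -1) for c in seq], dtype=np.int64)


def _candidate_starts(
    mirna: str, tseq: str, cutoff: float, seed: tuple[int, int]
) -> list[tuple[int, int]]:
    """(width_delta, start) pairs whose alignment may score <= cutoff.

    Vectorized pre-scan: accumulates per-offset duplex scores for the
    ungapped alignment and every single-gap variant at every transcript
    offset; exact scores are recomputed symbolically for the survivors.
    """
    L = len(mirna)
    m = _encode(mirna)
    t = _encode(tseq)
    n = len(t)
    if n < L - 1 or (m < 0).any():
        return []
    tt = np.where(t < 0, 0, t)
    M = _P4[m[:, None], tt[None, :]]
    M[:, t < 0] = PENALTY[MISMATCH]  # N in transcript never pairs
    w = np.array([2.0 if seed[0] <= k + 1 <= seed[1] else 1.0 for k in range(L)])
    Mw = M * w[:, None]

    def gapw(pos: int) -> float:
        return PENALTY[GAP_MIRNA] * (2.0 if seed[0] <= pos <= seed[1] else 1.0)

    tol = 1e-9
    out: set[tuple[int, int]] = set()
    n0 = n - L + 1  # ungapped, width L
    if n0 > 0:
        S = np.zeros(n0)
        for k in range(L):
            off = L - 1 - k
            S += Mw[k, off : off + n0]
        out.update((0, int(s)) for s in np.nonzero(S <= cutoff + tol)[0])
    n1 = n - (L - 1) + 1  # one miRNA base bulged out, width L-1
    if n1 > 0:
        for g in range(1, L + 1):
            if gapw(g) > cutoff + tol:
                continue
            S = np.full(n1, gapw(g))
            for k in range(L):
                if k == g - 1:
                    continue
                off = (L - 2 - k) if k < g - 1 else (L - 1 - k)
                S += Mw[k, off : off + n1]
            out.update((-1, int(s)) for s in np.nonzero(S <= cutoff + tol)[0])
    n2 = n - (L + 1) + 1  # one target base bulged out, width L+1
    if n2 > 0:
        for g in range(2, L + 1):
            if gapw(g) > cutoff + tol:
                continue
            S = np.full(n2, gapw(g))
            for k in range(L):
                off = (L - k) if k < g - 1 else (L - 1 - k)
                S += Mw[k, off : off + n2]
            out.update((1, int(s)) for s in np.nonzero(S <= cutoff + tol)[0])
    return sorted(out)


def scan_transcripts(
    mirna_name: str,
    mirna_seq: str,
    transcripts: Mapping[str, str],
    cutoff: float = DEFAULT_CUTOFF,
    strict: bool = False,
) -> list[TargetHit]:
    """All target sites scoring <= cutoff (< cutoff when ``strict``).

    Considers every ungapped offset plus single-gap variants (one bulged
    base on either strand); reports the best alignment per site start,
    sorted by expectation then position.
    """
    mirna = normalize_seq(mirna_seq)
    L = len(mirna)
    hits: list[TargetHit] = []
    for tid, tseq in transcripts.items():
        tseq = normalize_seq(tseq)
        best_at: dict[int, tuple[float, DuplexAlignment]] = {}
        for dw, start in _candidate_starts(mirna, tseq, cutoff, SEED_RANGE):
            site = tseq[start : start + L + dw]
            aln = best_site_alignment(mirna, site)
            if aln is None:
                continue
            score = score_duplex(aln)
            accept = score < cutoff if strict else score <= cutoff
            if accept:
                prev = best_at.get(start)
                if prev is None or score < prev[0]:
                    best_at[start] = (score, aln)
        for start, (score, aln) in best_at.items():
            hits.append(
                TargetHit(
                    mirna_name,
                    tid,
                    start,
                    aln.site_seq,
                    score,
                    classify_inhibition(aln),
                    aln,
                )
            )
    hits.sort(key=lambda h: (h.expectation, h.transcript_id, h.site_start))
    return hits


def scan_all(
    mirnas: Iterable[tuple[str, str]],
    transcripts: Mapping[str, str],
    cutoff: float = DEFAULT_CUTOFF,
    strict: bool = False,
) -> list[TargetHit]:
    hits: list[TargetHit] = []
    for name, seq in mirnas:
        hits.extend(scan_transcripts(name, seq, transcripts, cutoff, strict))
    return hits
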