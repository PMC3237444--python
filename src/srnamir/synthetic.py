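"""Synthetic study generator: toy genome, planted hairpins, two libraries.

Emulates the design of a two-condition plant small-RNA study: a toy genome
carrying planted miRNA hairpins, structural-ncRNA reference sets, a
transcript set with planted target sites, and two sequencing libraries
(condition A = before, condition B = after) in which each planted miRNA has
a known fold change.  Background reads are degradation fragments of the
genome with the characteristic bimodal 21/24-nt length profile, plus
rRNA/tRNA/snRNA/snoRNA/repeat fragments in configurable shares.

Everything is driven by a single integer seed; identical seeds produce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._util import revcomp
from .datasets import load_mature_reference
from .hairpin import (
    GenomeLocus,
    HairpinParams,
    alignment_distance,
    evaluate_hairpin,
)
from .sequence_io import ReadRecord, trim_adapter

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_BASES = np.array(list("ACGT"))

#: degradation fragment length weights, 18..30 nt (peaks at 21 and 24)
LENGTH_WEIGHTS = {
    18: 3, 19: 4, 20: 6, 21: 17, 22: 7, 23: 8, 24: 15,
    25: 5, 26: 4, 27: 3, 28: 3, 29: 2, 30: 2,
}


@dataclass
class SyntheticParams:
    n_conserved: int = 20
    n_new: int = 10
    genome_length: int = 200_000
    library_size: int = 200_000
    read_length: int = 36
    adapter: str = DEFAULT_ADAPTER
    #: per-miRNA mean depth in the lower-expressed condition (log-uniform)
    depth_range: tuple[int, int] = (300, 2000)
    #: pool of true fold magnitudes cycled over planted miRNAs
    fold_pool: tuple[float, ...] = (1.0, 1.5, 2.5, 3.0, 4.0, 6.0)
    star_fraction: float = 0.05
    error_rate: float = 0.001
    #: library share of each structural-RNA class (rest is degradation)
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "rRNA": 0.10,
            "tRNA": 0.08,
            "snRNA": 0.0005,
            "snoRNA": 0.0003,
            "repeat": 0.02,
        }
    )
    n_transcripts: int = 50
    transcript_length: int = 500
    translation_site_fraction: float = 0.3


@dataclass
class PlantedMiRNA:
    name: str
    mature_seq: str
    star_seq: str
    precursor_seq: str
    locus: GenomeLocus  # mature locus on the toy genome
    arm: str
    conserved: bool
    source_match: str | None  # reference entry a conserved mature was drawn from
    mutations: int
    fold_sign: str  # '+' = higher after, '-' = higher before
    fold_magnitude: float
    depth_before: float
    depth_after: float


@dataclass
class PlantedSite:
    mirna_name: str
    transcript_id: str
    offset: int
    inhibition: str


@dataclass
class TruthManifest:
    seed: int
    planted: list[PlantedMiRNA]
    ncrna_refs: dict[str, list[str]]
    transcripts: dict[str, str]
    sites: list[PlantedSite]
    library_size: int
    adapter: str


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _mutate(rng: np.random.Generator, seq: str, k: int) -> str:
    s = list(seq)
    pos = rng.choice(len(s), size=k, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != s[p]]
        s[p] = choices[rng.integers(0, 3)]
    return "".join(s)


def _usable_mature(seq: str, adapter: str) -> bool:
    """Mature must survive adapter trimming intact and be 18-24 nt."""
    if not (18 <= len(seq) <= 24):
        return False
    return trim_adapter(seq + adapter, adapter) == seq


def _build_hairpin(
    rng: np.random.Generator, mature: str, arm: str
) -> tuple[str, int, str]:
    """Perfect inverted-repeat hairpin holding the mature on the given arm.

    Returns (precursor, mature offset, star sequence); retries pads until
    the fold passes the default structural criteria.
    """
    for _ in range(25):
        pad5 = _random_seq(rng, int(rng.integers(8, 13)))
        pad3 = _random_seq(rng, int(rng.integers(8, 13)))
        loop = _random_seq(rng, int(rng.integers(8, 13)))
        stem = pad5 + mature + pad3
        if arm == "5p":
            hairpin = stem + loop + revcomp(stem)
            offset = len(pad5)
        else:
            hairpin = revcomp(stem) + loop + stem
            offset = len(stem) + len(loop) + len(pad5)
        ok, cand = evaluate_hairpin(
            hairpin, (offset, offset + len(mature)), HairpinParams()
        )
        if ok and cand.arm == arm:
            return hairpin, offset, cand.star_seq
    raise RuntimeError("failed to build a passing hairpin")  # pragma: no cover


def build_toy_genome(
    params: SyntheticParams | None = None, seed: int = 0
) -> tuple[dict[str, str], TruthManifest]:
    """Generate the toy genome with planted hairpins and all references."""
    params = params or SyntheticParams()
    rng = np.random.default_rng(seed)
    reference = load_mature_reference()
    ref_names = sorted(reference)

    # conserved matures: reference entries with <= 2 mutations
    planted: list[PlantedMiRNA] = []
    chosen = [
        n
        for n in ref_names
        if _usable_mature(reference[n], params.adapter)
    ]
    if params.n_conserved > len(chosen):
        raise ValueError("not enough usable reference matures to plant")
    pick = rng.choice(len(chosen), size=params.n_conserved, replace=False)
    matures: list[tuple[str, bool, str | None, int]] = []
    seen: set[str] = set()
    for idx in pick:
        src = chosen[int(idx)]
        k = int(rng.integers(0, 3))
        for _ in range(20):
            seq = _mutate(rng, reference[src], k) if k else reference[src]
            if seq not in seen and _usable_mature(seq, params.adapter):
                break
        seen.add(seq)
        matures.append((seq, True, src, k))

    # new matures: >= 4 mismatches from every reference entry
    refs = [reference[n] for n in ref_names]
    while sum(1 for m in matures if not m[1]) < params.n_new:
        seq = _random_seq(rng, int(rng.integers(20, 23)))
        if seq in seen or not _usable_mature(seq, params.adapter):
            continue
        if min(alignment_distance(seq, r) for r in refs) < 4:
            continue
        seen.add(seq)
        matures.append((seq, False, None, -1))

    # hairpins and genome placement
    genome = list(_random_seq(rng, params.genome_length))
    gap = 200
    cursor = gap
    folds = list(params.fold_pool)
    for i, (seq, conserved, src, k) in enumerate(matures):
        arm = "5p" if rng.random() < 0.5 else "3p"
        hairpin, offset, star = _build_hairpin(rng, seq, arm)
        lo = cursor + int(rng.integers(0, gap))
        hi = lo + len(hairpin)
        if hi + gap > params.genome_length:
            raise ValueError("genome too short to place all planted hairpins")
        genome[lo:hi] = list(hairpin)
        cursor = hi + gap
        mag = folds[i % len(folds)]
        sign = "+" if i % 2 == 0 else "-"
        lod, hid = params.depth_range
        depth = float(np.exp(rng.uniform(np.log(lod), np.log(hid))))
        depth_before = depth * mag if sign == "-" else depth
        depth_after = depth if sign == "-" else depth * mag
        planted.append(
            PlantedMiRNA(
                name=f"planted_{i + 1}",
                mature_seq=seq,
                star_seq=star,
                precursor_seq=hairpin,
                locus=GenomeLocus("toy_chr1", lo + offset, lo + offset + len(seq), "+"),
                arm=arm,
                conserved=conserved,
                source_match=src,
                mutations=k,
                fold_sign=sign,
                fold_magnitude=mag,
                depth_before=depth_before,
                depth_after=depth_after,
            )
        )
    genome_str = "".join(genome)

    ncrna = {
        "rRNA": [_random_seq(rng, 1500) for _ in range(2)],
        "tRNA": [_random_seq(rng, 75) for _ in range(5)],
        "snRNA": [_random_seq(rng, 150) for _ in range(3)],
        "snoRNA": [_random_seq(rng, 100) for _ in range(3)],
        "repeat": [_random_seq(rng, 400) for _ in range(3)],
    }

    # transcripts with planted target sites
    transcripts: dict[str, str] = {}
    sites: list[PlantedSite] = []
    for t in range(params.n_transcripts):
        tid = f"TOY-U{300000 + t}"
        transcripts[tid] = _random_seq(rng, params.transcript_length)
    tids = sorted(transcripts)
    for i, pm in enumerate(planted):
        tid = tids[i % len(tids)]
        site = revcomp(pm.mature_seq)
        label = "Cleavage"
        if rng.random() < params.translation_site_fraction:
            # central mismatch (miRNA position 10): translational repression
            pos10 = len(site) - 10  # site index pairing miRNA position 10
            mir_base = pm.mature_seq[9]
            bad = {"A": "C", "C": "A", "G": "A", "T": "C"}[mir_base]
            site = site[:pos10] + bad + site[pos10 + 1 :]
            label = "Translation"
        tseq = transcripts[tid]
        off = int(rng.integers(50, len(tseq) - len(site) - 50))
        transcripts[tid] = tseq[:off] + site + tseq[off + len(site) :]
        sites.append(PlantedSite(pm.name, tid, off, label))

    manifest = TruthManifest(
        seed=seed,
        planted=planted,
        ncrna_refs=ncrna,
        transcripts=transcripts,
        sites=sites,
        library_size=params.library_size,
        adapter=params.adapter,
    )
    return {"toy_chr1": genome_str}, manifest


def _fragment_reads(
    rng: np.random.Generator, sources: Sequence[str], n: int
) -> list[str]:
    """n fragments of the source sequences with the 18-30 nt length profile."""
    lengths = np.array(sorted(LENGTH_WEIGHTS))
    weights = np.array([LENGTH_WEIGHTS[l] for l in lengths], dtype=float)
    weights /= weights.sum()
    out = []
    src_idx = rng.integers(0, len(sources), n)
    lens = rng.choice(lengths, size=n, p=weights)
    for si, ln in zip(src_idx, lens):
        src = sources[int(si)]
        if len(src) <= ln:
            out.append(src)
            continue
        start = int(rng.integers(0, len(src) - ln))
        out.append(src[start : start + int(ln)])
    return out


def _apply_errors(rng: np.random.Generator, reads: list[str], rate: float) -> list[str]:
    if rate <= 0:
        return reads
    out = []
    for r in reads:
        nerr = rng.binomial(len(r), rate)
        if nerr:
            s = list(r)
            for p in rng.choice(len(s), size=nerr, replace=False):
                choices = [b for b in "ACGT" if b != s[p]]
                s[p] = choices[rng.integers(0, 3)]
            r = "".join(s)
        out.append(r)
    return out


def simulate_libraries(
    genome: Mapping[str, str],
    manifest: TruthManifest,
    params: SyntheticParams | None = None,
    seed: int | None = None,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Simulate both libraries as raw (adapter-bearing) read records.

    miRNA reads are Poisson at the planted depths; the rest of each library
    is filled with structural-RNA fragments at the configured shares and
    genomic degradation background.
    """
    params = params or SyntheticParams()
    rng = np.random.default_rng(manifest.seed + 1 if seed is None else seed)
    genome_seqs = [genome[k] for k in sorted(genome)]

    libraries: list[list[str]] = []
    for cond in ("before", "after"):
        inserts: list[str] = []
        for pm in manifest.planted:
            depth = pm.depth_before if cond == "before" else pm.depth_after
            count = int(rng.poisson(depth)) if depth > 0 else 0
            inserts.extend([pm.mature_seq] * count)
            star_count = int(rng.poisson(depth * params.star_fraction))
            inserts.extend([pm.star_seq] * star_count)
        n_fill = params.library_size - len(inserts)
        if n_fill <= 0:
            raise ValueError("library size too small for the planted depths")
        class_names = sorted(params.class_fractions)
        n_class = {
            c: int(round(params.class_fractions[c] * params.library_size))
            for c in class_names
        }
        if sum(n_class.values()) > n_fill:
            raise ValueError("class fractions leave no room for background")
        for c in class_names:
            inserts.extend(
                _fragment_reads(rng, manifest.ncrna_refs[c], n_class[c])
            )
        n_bg = n_fill - sum(n_class.values())
        inserts.extend(_fragment_reads(rng, genome_seqs, n_bg))
        inserts = _apply_errors(rng, inserts, params.error_rate)
        order = rng.permutation(len(inserts))
        libraries.append([inserts[i] for i in order])

    out = []
    for lib_idx, inserts in enumerate(libraries):
        recs = []
        for i, ins in enumerate(inserts):
            raw = (ins + manifest.adapter)[: params.read_length]
            if len(raw) < params.read_length:
                raw = raw + "A" * (params.read_length - len(raw))
            recs.append(
                ReadRecord(f"lib{lib_idx}_r{i}", raw, "I" * len(raw))
            )
        out.append(recs)
    return out[0], out[1]


def write_fastq(records: Sequence[ReadRecord], path) -> None:
    with open(path, "w") as f:
        for r in records:
            f.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def write_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w") as f:
        for name in seqs:
            f.write(f">{name}\n{seqs[name]}\n")
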