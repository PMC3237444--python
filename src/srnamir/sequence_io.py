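"""FASTQ ingest, 3' adapter trimming, length filtering and tag collapsing.

A sequencing library enters as raw single-end reads; what the rest of the
pipeline consumes are *tags*: unique 18-30 nt insert sequences with per-library
redundant read counts (library A = before the treatment contrast, library B =
after).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence, TextIO

import pandas as pd

from ._util import normalize_seq

DEFAULT_ADAPTER_3P = "TGGAATTCTCGGGTGCCAAGG"  # Illumina TruSeq small-RNA 3' adapter
MIN_TAG_LEN = 18
MAX_TAG_LEN = 30


@dataclass(frozen=True)
class ReadRecord:
    """One sequencer read; quality is optional phred text of equal length."""

    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class SmallRNATag:
    """A unique small-RNA sequence with redundant counts per library."""

    sequence: str
    count_a: int
    count_b: int

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (MIN_TAG_LEN <= n <= MAX_TAG_LEN):
            raise ValueError(f"tag length {n} outside [{MIN_TAG_LEN}, {MAX_TAG_LEN}]")
        if "N" in self.sequence:
            raise ValueError("tag contains N")
        if self.count_a < 0 or self.count_b < 0:
            raise ValueError("negative tag count")
        if self.count_a + self.count_b < 1:
            raise ValueError("tag with zero total count")

    @property
    def total(self) -> int:
        return self.count_a + self.count_b


def parse_fastq(stream: TextIO) -> Iterator[ReadRecord]:
    """Parse 4-line FASTQ records, yielding one ReadRecord per record.

    Raises ValueError naming the (0-based) record index on malformed input.
    """
    lines = iter(stream)
    idx = 0
    while True:
        header = next(lines, None)
        if header is None:
            return
        header = header.rstrip("\n")
        if not header:  # ignore trailing blank line
            continue
        if not header.startswith("@"):
            raise ValueError(f"FASTQ record {idx}: header does not start with '@'")
        try:
            seq = next(lines).rstrip("\n")
            plus = next(lines).rstrip("\n")
            qual = next(lines).rstrip("\n")
        except StopIteration:
            raise ValueError(f"FASTQ record {idx}: truncated record") from None
        if not plus.startswith("+"):
            raise ValueError(f"FASTQ record {idx}: missing '+' separator line")
        if len(seq) != len(qual):
            raise ValueError(
                f"FASTQ record {idx}: sequence/quality length mismatch "
                f"({len(seq)} vs {len(qual)})"
            )
        yield ReadRecord(header[1:].split()[0] if len(header) > 1 else "", seq, qual)
        idx += 1


def trim_adapter(
    sequence: str,
    adapter3: str = DEFAULT_ADAPTER_3P,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
) -> str | None:
    """Return the insert preceding the leftmost 3' adapter match, else None.

    A match anchors the adapter prefix at some read offset with at least
    ``min_overlap`` aligned bases and a mismatch rate at most
    ``max_mismatch_rate``.  Reads without a clear adapter are rejected
    (returns None): only adapter-bearing reads carry a complete insert.
    """
    if not adapter3:
        raise ValueError("empty adapter")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seq = normalize_seq(sequence)
    ad = normalize_seq(adapter3)
    n = len(seq)
    for pos in range(0, n - min_overlap + 1):
        overlap = min(len(ad), n - pos)
        allowed = int(max_mismatch_rate * overlap)
        mism = 0
        for a, b in zip(seq[pos : pos + overlap], ad):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        else:
            return seq[:pos]
    return None


def length_filter(sequence: str, min_len: int = MIN_TAG_LEN, max_len: int = MAX_TAG_LEN) -> bool:
    """Accept trimmed inserts of 18-30 nt containing no N."""
    return min_len <= len(sequence) <= max_len and "N" not in sequence


def mean_quality(quality: str, offset: int = 33) -> float:
    return sum(ord(c) - offset for c in quality) / len(quality)


def clean_reads(
    records: Iterable[ReadRecord],
    adapter3: str = DEFAULT_ADAPTER_3P,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
    min_mean_quality: float | None = None,
) -> Iterator[str]:
    """Trim + filter a read stream down to clean insert sequences."""
    for rec in records:
        if min_mean_quality is not None and rec.quality is not None:
            if mean_quality(rec.quality) < min_mean_quality:
                continue
        insert = trim_adapter(rec.sequence, adapter3, min_overlap, max_mismatch_rate)
        if insert is not None and length_filter(insert, min_len, max_len):
            yield insert


def collapse(reads_a: Iterable[str], reads_b: Iterable[str]) -> list[SmallRNATag]:
    """Collapse clean reads from both libraries into unique tags.

    Redundant totals are conserved exactly: sum(count_a) == len(reads_a).
    Tags are returned sorted by descending total count then sequence, which
    makes downstream naming deterministic.
    """
    ca = Counter(normalize_seq(r) for r in reads_a)
    cb = Counter(normalize_seq(r) for r in reads_b)
    tags = [
        SmallRNATag(seq, ca.get(seq, 0), cb.get(seq, 0))
        for seq in set(ca) | set(cb)
    ]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags


def size_distribution(tags: Sequence[SmallRNATag]) -> pd.DataFrame:
    """Per-length unique/redundant counts per library (lengths 18-30)."""
    idx = range(MIN_TAG_LEN, MAX_TAG_LEN + 1)
    df = pd.DataFrame(
        0,
        index=pd.Index(idx, name="length"),
        columns=["unique_a", "redundant_a", "unique_b", "redundant_b"],
    )
    for t in tags:
        if t.count_a:
            df.loc[t.length, "unique_a"] += 1
            df.loc[t.length, "redundant_a"] += t.count_a
        if t.count_b:
            df.loc[t.length, "unique_b"] += 1
            df.loc[t.length, "redundant_b"] += t.count_b
    return df


def write_tags_tsv(tags: Sequence[SmallRNATag], path) -> None:
    with open(path, "w") as f:
        f.write("sequence\tlength\tcount_a\tcount_b\n")
        for t in tags:
            f.write(f"{t.sequence}\t{t.length}\t{t.count_a}\t{t.count_b}\n")


def read_tags_tsv(path) -> list[SmallRNATag]:
    df = pd.read_csv(path, sep="\t")
    return [
        SmallRNATag(r.sequence, int(r.count_a), int(r.count_b))
        for r in df.itertuples()
    ]


def write_tags_fasta(tags: Sequence[SmallRNATag], library: str, path) -> None:
    """FASTA with headers tag{i}_x{count} for one library ('a' or 'b')."""
    attr = f"count_{library}"
    with open(path, "w") as f:
        i = 0
        for t in tags:
            count = getattr(t, attr)
            if count > 0:
                f.write(f">tag{i}_x{count}\n{t.sequence}\n")
                i += 1
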