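"""Annotation cascade: assign each tag to its first matching ncRNA class.

Tags matching rRNA, tRNA, snRNA, snoRNA or repeat references (exact
full-length substring on either strand) are removed from miRNA discovery;
the remainder is "unannotated".  The summary mirrors the published
annotation-and-distribution table: per-class unique and redundant counts per
library with redundant/unique ratios at two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from ._util import normalize_seq, revcomp, round_half_up
from .sequence_io import SmallRNATag

DEFAULT_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat")
UNANNOTATED = "unannotated"

#: separator that can never occur inside a tag (tags are ACGT-only)
_SEP = "#"


class ReferenceIndex:
    """Exact substring index over a set of reference sequences, both strands."""

    def __init__(self, sequences: Iterable[str], class_name: str):
        seqs = [normalize_seq(s) for s in sequences]
        if not seqs:
            raise ValueError(f"empty reference set for class {class_name!r}")
        self.class_name = class_name
        fwd = _SEP.join(seqs)
        rev = _SEP.join(revcomp(s) for s in seqs)
        self._haystack = fwd + _SEP + rev

    @classmethod
    def from_fasta(cls, path, class_name: str) -> "ReferenceIndex":
        seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
        return cls(seqs, class_name)

    def __contains__(self, tag: str) -> bool:
        return normalize_seq(tag) in self._haystack


def classify_tag(
    tag: str | SmallRNATag,
    indexes: Mapping[str, ReferenceIndex],
    priority_order: Sequence[str] = DEFAULT_PRIORITY,
) -> str:
    """First class in priority order whose index contains the tag."""
    seq = tag.sequence if isinstance(tag, SmallRNATag) else tag
    for name in priority_order:
        idx = indexes.get(name)
        if idx is not None and seq in idx:
            return name
    return UNANNOTATED


def classify_all(
    tags: Sequence[SmallRNATag],
    indexes: Mapping[str, ReferenceIndex],
    priority_order: Sequence[str] = DEFAULT_PRIORITY,
) -> dict[str, str]:
    """Tag sequence -> class name for every tag (deterministic, order-free)."""
    return {t.sequence: classify_tag(t, indexes, priority_order) for t in tags}


@dataclass(frozen=True)
class ClassSummary:
    class_name: str
    unique_a: int
    redundant_a: int
    unique_b: int
    redundant_b: int

    @property
    def ratio_a(self) -> float | None:
        return round_half_up(self.redundant_a / self.unique_a) if self.unique_a else None

    @property
    def ratio_b(self) -> float | None:
        return round_half_up(self.redundant_b / self.unique_b) if self.unique_b else None


def summarize_classes(
    tags: Sequence[SmallRNATag],
    assignments: Mapping[str, str],
    class_order: Sequence[str] | None = None,
) -> list[ClassSummary]:
    """Per-class unique/redundant bookkeeping plus an exact total row.

    Classes partition the tags, so per-library columns over non-total rows
    sum to the total row by construction.
    """
    acc: dict[str, list[int]] = {}
    for t in tags:
        cls = assignments[t.sequence]
        row = acc.setdefault(cls, [0, 0, 0, 0])
        if t.count_a:
            row[0] += 1
            row[1] += t.count_a
        if t.count_b:
            row[2] += 1
            row[3] += t.count_b
    if class_order is None:
        class_order = list(DEFAULT_PRIORITY) + [UNANNOTATED]
        class_order = [c for c in class_order if c in acc] + sorted(
            set(acc) - set(class_order)
        )
    out = [ClassSummary(c, *acc.get(c, [0, 0, 0, 0])) for c in class_order]
    out.append(
        ClassSummary(
            "total",
            sum(s.unique_a for s in out),
            sum(s.redundant_a for s in out),
            sum(s.unique_b for s in out),
            sum(s.redundant_b for s in out),
        )
    )
    return out


def summary_frame(summaries: Sequence[ClassSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "class_name": [s.class_name for s in summaries],
            "unique_a": [s.unique_a for s in summaries],
            "redundant_a": [s.redundant_a for s in summaries],
            "ratio_a": [s.ratio_a for s in summaries],
            "unique_b": [s.unique_b for s in summaries],
            "redundant_b": [s.redundant_b for s in summaries],
            "ratio_b": [s.ratio_b for s in summaries],
        }
    )


def clean_library_sizes(summaries: Sequence[ClassSummary]) -> tuple[int, int]:
    """Redundant reads remaining after rRNA/tRNA/snRNA/snoRNA removal.

    This is the normalization basis for expression: total redundant reads
    minus the four structural-RNA classes (repeats and miRNAs stay in).
    """
    removed = {"rRNA", "tRNA", "snRNA", "snoRNA"}
    total_a = total_b = rem_a = rem_b = 0
    for s in summaries:
        if s.class_name == "total":
            total_a, total_b = s.redundant_a, s.redundant_b
        elif s.class_name in removed:
            rem_a += s.redundant_a
            rem_b += s.redundant_b
    return total_a - rem_a, total_b - rem_b
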