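"""Normalized expression and signed fold changes between two libraries.

Counts are normalized to reads per million clean reads (library total after
structural-ncRNA removal).  The fold change is the ratio of the larger to
the smaller normalized count, signed '+' when the miRNA is up-regulated in
library B (after the treatment) and '-' when down.  When exactly one
library's count is zero the fold magnitude is reported as the nonzero
normalized count itself (the published zero-count convention); records with
zero in both libraries are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from ._util import round_half_up

DEFAULT_SCALE = 1_000_000.0
MARK_THRESHOLD = 2.0


@dataclass(frozen=True)
class ExpressionRecord:
    """One expression-table row (family/seq metadata + normalized counts)."""

    name: str
    family: str
    mature_seq: str
    c_reads: float  # normalized count, library A (before)
    t_reads: float  # normalized count, library B (after)
    sign: str  # '+' up-regulated after, '-' down
    fold: float  # magnitude, >= 1 except under the zero-count convention

    @property
    def ml(self) -> int:
        return len(self.mature_seq)

    @property
    def total_reads(self) -> float:
        return self.c_reads + self.t_reads

    @property
    def signed_fold(self) -> float:
        return self.fold if self.sign == "+" else -self.fold

    @property
    def marked(self) -> bool:
        return self.fold > MARK_THRESHOLD


def normalize(raw_count: float, clean_library_size: float, scale: float = DEFAULT_SCALE) -> float:
    """raw * scale / clean_library_size (counts per million clean reads)."""
    if clean_library_size <= 0:
        raise ValueError("clean library size must be positive")
    return raw_count * scale / clean_library_size


def fold_change(c_reads: float, t_reads: float) -> tuple[str, float]:
    """(sign, magnitude) of the between-library fold change.

    Magnitude = max/min when both counts are positive; the nonzero count
    itself when exactly one is zero.  Raises on a both-zero record.
    """
    if c_reads < 0 or t_reads < 0:
        raise ValueError("negative normalized count")
    if c_reads == 0 and t_reads == 0:
        raise ValueError("fold change undefined for a both-zero record")
    sign = "+" if t_reads > c_reads else "-"
    if c_reads > 0 and t_reads > 0:
        mag = max(c_reads, t_reads) / min(c_reads, t_reads)
    else:
        mag = max(c_reads, t_reads)
    return sign, mag


def quantify(
    mirnas: Iterable,
    clean_size_a: float,
    clean_size_b: float,
    scale: float = DEFAULT_SCALE,
) -> list[ExpressionRecord]:
    """Build expression records for discovered miRNAs (MiRNARecord-likes).

    Both-zero records are dropped (no pseudocounts).
    """
    out = []
    for m in mirnas:
        if m.count_a == 0 and m.count_b == 0:
            continue
        c = normalize(m.count_a, clean_size_a, scale)
        t = normalize(m.count_b, clean_size_b, scale)
        sign, mag = fold_change(c, t)
        out.append(ExpressionRecord(m.name, m.family, m.mature_seq, c, t, sign, mag))
    return out


def flag_marked(records: Sequence[ExpressionRecord]) -> tuple[list[ExpressionRecord], list[ExpressionRecord]]:
    """(up, down) subsets with fold magnitude strictly > 2, sorted by magnitude."""
    up = sorted(
        (r for r in records if r.marked and r.sign == "+"), key=lambda r: -r.fold
    )
    down = sorted(
        (r for r in records if r.marked and r.sign == "-"), key=lambda r: -r.fold
    )
    return up, down


def expression_frame(records: Sequence[ExpressionRecord], ascii_minus: bool = True) -> pd.DataFrame:
    """TSV-ready table mirroring the published expression-table columns."""
    minus = "-" if ascii_minus else "−"
    return pd.DataFrame(
        {
            "Family": [r.family for r in records],
            "Mature miRNA": [r.mature_seq for r in records],
            "ML": [r.ml for r in records],
            "C Reads": [round_half_up(r.c_reads, 1) for r in records],
            "T Reads": [round_half_up(r.t_reads, 1) for r in records],
            "Total Reads": [round_half_up(r.total_reads, 1) for r in records],
            "Fold change": [
                ("+" if r.sign == "+" else minus) + f"{round_half_up(r.fold, 2):g}"
                for r in records
            ],
            "Name": [r.name for r in records],
        }
    )
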