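"""Loaders for the small reference tables packaged with srnamir.

The packaged files are the worked-example inputs of the toolkit: a
miRBase-style mature miRNA reference (plant mature sequences, DNA alphabet)
and the published per-class annotation summary and miRNA expression tables
used by the documentation examples and the acceptance checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
from Bio import SeqIO

from ._util import normalize_seq


def _data_path(name: str):
    return resources.files("srnamir.data").joinpath(name)


def load_mature_reference() -> dict[str, str]:
    """Name -> mature sequence (DNA alphabet) of the packaged reference set."""
    with resources.as_file(_data_path("mature_mirnas.fasta")) as p:
        return {
            rec.id: normalize_seq(str(rec.seq)) for rec in SeqIO.parse(str(p), "fasta")
        }


def load_annotation_summary() -> pd.DataFrame:
    """Published per-class unique/redundant read counts for both libraries."""
    with resources.as_file(_data_path("annotation_summary_published.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_conserved_expression() -> pd.DataFrame:
    """Published conserved-miRNA expression rows (normalized counts + folds)."""
    with resources.as_file(_data_path("conserved_mirnas_published.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_star_expression() -> pd.DataFrame:
    """Published miRNA-star expression rows."""
    with resources.as_file(_data_path("star_mirnas_published.tsv")) as p:
        return pd.read_csv(p, sep="\t")
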