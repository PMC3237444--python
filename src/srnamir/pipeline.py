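"""Pipeline orchestration: run every stage and emit the report files.

The run directory receives TSV reports shaped like the published tables
(annotation summary, conserved/star/new expression tables, target hits),
the per-length size distribution, an MFE summary over discovered
precursors, precursor sequences/structures, and a machine-readable run
manifest (version, seed, config hash, stage counts, report checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from . import __version__, annotate, datasets, expression, sequence_io, synthetic
from ._util import normalize_seq, round_half_up
from .config import RunConfig
from .hairpin import MiRNARecord, discover
from .targets import scan_all

log = logging.getLogger("srnamir")

REPORT_NAMES = (
    "table1_annotation.tsv",
    "table2_conserved.tsv",
    "table3_star.tsv",
    "new_mirnas.tsv",
    "targets.tsv",
    "size_distribution.tsv",
    "mfe_summary.tsv",
)


def _read_fasta(path) -> dict[str, str]:
    return {
        rec.id: normalize_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }


def report_fold_flags(
    records: Sequence[expression.ExpressionRecord],
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """(up, down) name/magnitude lists of >2-fold records, magnitude desc."""
    up, down = expression.flag_marked(records)
    return (
        [(r.name, r.fold) for r in up],
        [(r.name, r.fold) for r in down],
    )


def _mfe_summary(records: Sequence[MiRNARecord]) -> pd.DataFrame:
    rows = []
    for label, subset in (
        ("new", [r for r in records if r.klass == "new" and not r.is_star]),
        ("conserved", [r for r in records if r.klass == "conserved" and not r.is_star]),
        ("all", [r for r in records if not r.is_star]),
    ):
        mfes = [r.precursor.mfe for r in subset]
        rows.append(
            {
                "class": label,
                "n": len(mfes),
                "mfe_min": round_half_up(min(mfes), 1) if mfes else None,
                "mfe_max": round_half_up(max(mfes), 1) if mfes else None,
                "mfe_mean": round_half_up(sum(mfes) / len(mfes), 1) if mfes else None,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline; returns a result bundle with file paths.

    Deterministic given (config, seed): rerunning yields byte-identical
    reports.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    synthetic_mode = config.fastq_a is None
    manifest = None
    if synthetic_mode:
        log.info("stage simulate: generating synthetic inputs (seed=%d)", config.seed)
        params = config.synthetic_params()
        genome, manifest = synthetic.build_toy_genome(params, config.seed)
        lib_a, lib_b = synthetic.simulate_libraries(genome, manifest, params)
        indexes = {
            c: annotate.ReferenceIndex(seqs, c)
            for c, seqs in manifest.ncrna_refs.items()
        }
        mirbase = datasets.load_mature_reference()
        transcripts = manifest.transcripts
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        synthetic.write_fasta(genome, inputs / "genome.fasta")
        synthetic.write_fastq(lib_a, inputs / "library_a.fastq")
        synthetic.write_fastq(lib_b, inputs / "library_b.fastq")
        synthetic.write_fasta(transcripts, inputs / "transcripts.fasta")
        for c, seqs in manifest.ncrna_refs.items():
            synthetic.write_fasta(
                {f"{c}_{i}": s for i, s in enumerate(seqs)}, inputs / f"{c}.fasta"
            )
        reads_a = list(
            sequence_io.clean_reads(
                lib_a,
                config.adapter,
                config.adapter_min_overlap,
                config.adapter_max_mismatch_rate,
                config.min_len,
                config.max_len,
                config.min_mean_quality,
            )
        )
        reads_b = list(
            sequence_io.clean_reads(
                lib_b,
                config.adapter,
                config.adapter_min_overlap,
                config.adapter_max_mismatch_rate,
                config.min_len,
                config.max_len,
                config.min_mean_quality,
            )
        )
    else:
        log.info("stage ingest: reading FASTQ libraries")
        genome = _read_fasta(config.genome_fasta)
        indexes = {
            c: annotate.ReferenceIndex.from_fasta(p, c)
            for c, p in config.ncrna_fastas.items()
        }
        mirbase = (
            _read_fasta(config.mirbase_fasta)
            if config.mirbase_fasta
            else datasets.load_mature_reference()
        )
        transcripts = (
            _read_fasta(config.transcripts_fasta) if config.transcripts_fasta else {}
        )

        def _clean(path):
            with open(path) as fh:
                return list(
                    sequence_io.clean_reads(
                        sequence_io.parse_fastq(fh),
                        config.adapter,
                        config.adapter_min_overlap,
                        config.adapter_max_mismatch_rate,
                        config.min_len,
                        config.max_len,
                        config.min_mean_quality,
                    )
                )

        reads_a, reads_b = _clean(config.fastq_a), _clean(config.fastq_b)

    log.info("stage collapse: %d + %d clean reads", len(reads_a), len(reads_b))
    tags = sequence_io.collapse(reads_a, reads_b)
    assert sum(t.count_a for t in tags) == len(reads_a)
    assert sum(t.count_b for t in tags) == len(reads_b)
    log.info("stage collapse: %d unique tags", len(tags))
    sequence_io.write_tags_tsv(tags, out / "tags.tsv")
    sizes = sequence_io.size_distribution(tags)
    sizes.to_csv(out / "size_distribution.tsv", sep="\t")

    log.info("stage annotate: cascade over %d tags", len(tags))
    assignments = annotate.classify_all(tags, indexes)

    log.info("stage discover: hairpin search")
    records = discover(
        tags,
        genome,
        mirbase,
        assignments,
        flank=config.flank,
        params=config.hairpin_params(),
        min_candidate_count=config.min_candidate_count,
        max_conserved_mismatches=config.max_conserved_mismatches,
        species_prefix=config.species_prefix,
    )
    log.info("stage discover: %d miRNA records", len(records))

    # fold discovered miRNAs back into the class summary
    klass_of = {
        r.mature_seq: ("conserved_miRNA" if r.klass == "conserved" else "novel_miRNA")
        for r in records
    }
    final_assignments = {
        seq: klass_of.get(seq, cls) for seq, cls in assignments.items()
    }
    order = list(annotate.DEFAULT_PRIORITY) + [
        "conserved_miRNA",
        "novel_miRNA",
        annotate.UNANNOTATED,
    ]
    summaries = annotate.summarize_classes(tags, final_assignments, order)
    annotate.summary_frame(summaries).to_csv(
        out / "table1_annotation.tsv", sep="\t", index=False
    )
    for s in summaries:
        log.info(
            "annotation %s: unique %d/%d redundant %d/%d",
            s.class_name, s.unique_a, s.unique_b, s.redundant_a, s.redundant_b,
        )

    log.info("stage quantify")
    if config.norm_basis == "clean":
        size_a, size_b = annotate.clean_library_sizes(summaries)
    else:
        size_a, size_b = len(reads_a), len(reads_b)
    exprs = expression.quantify(records, size_a, size_b, config.norm_scale)
    by_name = {e.name: e for e in exprs}
    star_names = {r.name for r in records if r.is_star}
    conserved_names = {
        r.name for r in records if r.klass == "conserved" and not r.is_star
    }
    new_names = {r.name for r in records if r.klass == "new" and not r.is_star}

    def _table(names):
        recs = [by_name[n] for n in sorted(names) if n in by_name]
        return expression.expression_frame(recs, config.ascii_minus)

    _table(conserved_names).to_csv(out / "table2_conserved.tsv", sep="\t", index=False)
    _table(star_names).to_csv(out / "table3_star.tsv", sep="\t", index=False)
    _table(new_names).to_csv(out / "new_mirnas.tsv", sep="\t", index=False)

    up, down = report_fold_flags(exprs)
    pd.DataFrame(
        [("up", n, m) for n, m in up] + [("down", n, m) for n, m in down],
        columns=["direction", "name", "fold"],
    ).to_csv(out / "fold_flags.tsv", sep="\t", index=False)

    log.info("stage targets: scanning %d transcripts", len(transcripts))
    hits = scan_all(
        [(r.name, r.mature_seq) for r in records],
        transcripts,
        config.target_cutoff,
        config.target_strict,
    )
    fold_by_name = {e.name: e.signed_fold for e in exprs}
    pd.DataFrame(
        {
            "Name of miRNA": [h.mirna_name for h in hits],
            "Targets": [h.transcript_id for h in hits],
            "Site start": [h.site_start for h in hits],
            "Expectation": [h.expectation for h in hits],
            "Inhibition": [h.inhibition for h in hits],
            "Change Fold": [
                round_half_up(fold_by_name[h.mirna_name], 2)
                if h.mirna_name in fold_by_name
                else None
                for h in hits
            ],
        }
    ).to_csv(out / "targets.tsv", sep="\t", index=False)

    _mfe_summary(records).to_csv(out / "mfe_summary.tsv", sep="\t", index=False)
    with open(out / "precursors.fasta", "w") as f, open(
        out / "precursors_structure.txt", "w"
    ) as g:
        for r in records:
            f.write(f">{r.name}\n{r.precursor.precursor_seq}\n")
            g.write(
                f">{r.name}\n{r.precursor.precursor_seq}\n"
                f"{r.precursor.structure} ({r.precursor.mfe:.1f})\n"
            )

    checksums = {
        name: hashlib.sha256((out / name).read_bytes()).hexdigest()
        for name in REPORT_NAMES
    }
    run_manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "synthetic_mode": synthetic_mode,
        "counts": {
            "clean_reads_a": len(reads_a),
            "clean_reads_b": len(reads_b),
            "unique_tags": len(tags),
            "mirnas": len(records),
            "target_hits": len(hits),
        },
        "clean_library_sizes": [size_a, size_b],
        "report_checksums": checksums,
    }
    with open(out / "run_manifest.json", "w") as f:
        json.dump(run_manifest, f, indent=2, sort_keys=True)

    return {
        "outdir": out,
        "tags": tags,
        "assignments": final_assignments,
        "summaries": summaries,
        "records": records,
        "expression": exprs,
        "hits": hits,
        "truth": manifest,
        "manifest": run_manifest,
    }
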