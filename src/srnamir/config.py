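"""Run configuration: every tunable threshold of the pipeline in one place."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from typing import Any

import yaml

from .expression import DEFAULT_SCALE
from .hairpin import (
    DEFAULT_FLANK,
    DEFAULT_MAX_BULGE_ASYMMETRY,
    DEFAULT_MAX_CONSERVED_MISMATCHES,
    DEFAULT_MAX_DUPLEX_MISMATCHES,
    DEFAULT_MFE_MAX,
    DEFAULT_MIN_PAIRED_FRACTION,
    HairpinParams,
)
from .sequence_io import DEFAULT_ADAPTER_3P, MAX_TAG_LEN, MIN_TAG_LEN
from .synthetic import SyntheticParams
from .targets import DEFAULT_CUTOFF


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips through YAML unchanged."""

    seed: int = 0
    # inputs; None -> generated synthetically
    fastq_a: str | None = None
    fastq_b: str | None = None
    genome_fasta: str | None = None
    mirbase_fasta: str | None = None  # None -> packaged mature reference
    transcripts_fasta: str | None = None
    ncrna_fastas: dict[str, str] = field(default_factory=dict)  # class -> path
    # read cleaning
    adapter: str = DEFAULT_ADAPTER_3P
    min_len: int = MIN_TAG_LEN
    max_len: int = MAX_TAG_LEN
    adapter_min_overlap: int = 6
    adapter_max_mismatch_rate: float = 0.1
    min_mean_quality: float | None = None
    # hairpin discovery
    flank: int = DEFAULT_FLANK
    min_candidate_count: int = 5
    mfe_max: float = DEFAULT_MFE_MAX
    max_duplex_mismatches: int = DEFAULT_MAX_DUPLEX_MISMATCHES
    max_bulge_asymmetry: int = DEFAULT_MAX_BULGE_ASYMMETRY
    min_paired_fraction: float = DEFAULT_MIN_PAIRED_FRACTION
    max_conserved_mismatches: int = DEFAULT_MAX_CONSERVED_MISMATCHES
    species_prefix: str = "nta"
    # expression
    norm_scale: float = DEFAULT_SCALE
    norm_basis: str = "clean"  # 'clean' or 'raw' library totals
    fold_flag_threshold: float = 2.0
    # target prediction
    target_cutoff: float = DEFAULT_CUTOFF
    target_strict: bool = False
    # reporting
    ascii_minus: bool = True
    # synthetic-mode parameters (used when inputs are None)
    synthetic: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError(
                f"min_len {self.min_len} > max_len {self.max_len}"
            )
        if not (MIN_TAG_LEN - 10 <= self.min_len and self.max_len <= MAX_TAG_LEN + 20):
            raise ValueError("length bounds outside supported range")
        if self.flank <= 0:
            raise ValueError("flank must be positive")
        if self.mfe_max > 0:
            raise ValueError("mfe_max must be <= 0")
        if not 0 <= self.min_paired_fraction <= 1:
            raise ValueError("min_paired_fraction must be in [0, 1]")
        if self.norm_basis not in ("clean", "raw"):
            raise ValueError("norm_basis must be 'clean' or 'raw'")
        if self.norm_scale <= 0 or self.target_cutoff < 0:
            raise ValueError("scales and cutoffs must be positive")
        if self.adapter_min_overlap < 1:
            raise ValueError("adapter_min_overlap must be >= 1")
        SyntheticParams(**self.synthetic)  # raises on unknown keys

    def hairpin_params(self) -> HairpinParams:
        return HairpinParams(
            mfe_max=self.mfe_max,
            max_duplex_mismatches=self.max_duplex_mismatches,
            max_bulge_asymmetry=self.max_bulge_asymmetry,
            min_paired_fraction=self.min_paired_fraction,
        )

    def synthetic_params(self) -> SyntheticParams:
        return SyntheticParams(adapter=self.adapter, **self.synthetic)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
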