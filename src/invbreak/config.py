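"""Pipeline configuration and the analysis thresholds.

All thresholds used across the pipeline live in :class:`ConfigDefaults` so a
single structured config file (YAML) can override any of them.  The defaults
are the operating point of the comparative-mapping protocol this package
implements: a stringent e-value and minimum hit length for mapping markers
onto the target genome, a minimum marker count per syntenic segment, a
permissive e-value for cross-species (outgroup) similarity, and the protein
duplicate criteria (identity / coverage / e-value) used for the enrichment
analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ConfigDefaults", "PipelineConfig", "ParameterError"]


class ParameterError(ValueError):
    """A parameter violates its documented precondition."""


@dataclass
class ConfigDefaults:
    """Analysis thresholds, overridable from a config file.

    Attributes
    ----------
    max_evalue_map:
        Maximum e-value for a marker hit to be retained when mapping markers
        onto the target chromosome.
    min_hit_length:
        Minimum alignment length (bp) for a retained marker hit.
    min_markers:
        Minimum number of markers required to accept a syntenic segment
        (whitelisted marker sets are exempt).
    max_evalue_outgroup:
        Maximum e-value for similarity against the outgroup (ancestral
        arrangement) genome when narrowing breakpoint regions; permissive to
        accommodate the larger phylogenetic distance.
    dup_evalue / dup_identity / dup_coverage:
        Protein-pair criteria for calling two adjacent genes duplicates:
        alignment passing an e-value-equivalent score cutoff, percent
        identity above ``dup_identity`` and hit length above
        ``dup_coverage`` x (shortest query length).
    neutral_rate:
        Neutral substitution rate, substitutions/site/myr, used for dating
        inversion-associated duplications.
    invdup_evalue:
        Maximum e-value for similarity blocks between the two junction
        sequences of one inversion (inverted-duplication detection).
    k_stray:
        Number of interleaved out-of-order markers tolerated (and orphaned)
        inside one collinear run during segment calling.
    max_rank_jump:
        Largest gap in source rank allowed between consecutive markers of
        one run; a larger jump is a diagonal change, i.e. a segment break,
        even when the rank order stays monotone.
    tile_merge_gap:
        Outgroup similarity tiles closer than this (bp) are merged when
        computing similarity loss.
    tsd_len_min / tsd_len_max:
        Search range (bp) for target-site-duplication candidates flanking a
        TE insertion.
    te_min_match:
        Minimum match length (bp) for reporting a TE fragment annotation.
    dup_chain_gap:
        Similarity blocks closer than this (bp) are chained into one
        duplication segment.
    """

    max_evalue_map: float = 1e-20
    min_hit_length: int = 50
    min_markers: int = 9
    max_evalue_outgroup: float = 1e-3
    dup_evalue: float = 1e-30
    dup_identity: float = 33.0
    dup_coverage: float = 0.57
    neutral_rate: float = 0.0111
    invdup_evalue: float = 9e-10
    k_stray: int = 1
    max_rank_jump: int = 10
    tile_merge_gap: int = 100
    tsd_len_min: int = 4
    tsd_len_max: int = 12
    te_min_match: int = 18
    dup_chain_gap: int = 1000

    def __post_init__(self) -> None:
        for name in (
            "max_evalue_map",
            "min_hit_length",
            "min_markers",
            "max_evalue_outgroup",
            "dup_evalue",
            "dup_identity",
            "dup_coverage",
            "neutral_rate",
            "invdup_evalue",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"threshold {name!r} must be positive")

    def replace(self, **overrides: Any) -> "ConfigDefaults":
        return dataclasses.replace(self, **overrides)

    @classmethod
    def from_mapping(cls, mapping: dict[str, Any]) -> "ConfigDefaults":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class PipelineConfig:
    """Full pipeline configuration: thresholds, paths, seed, verbosity."""

    thresholds: ConfigDefaults = field(default_factory=ConfigDefaults)
    seed: int = 1
    outdir: str = "invbreak_out"
    verbosity: str = "info"
    # synthetic-data scenario parameters (the demo pipeline input)
    chrom_length: int = 34_000_000
    marker_spacing_mean: int = 13_800
    n_inversions_a: int = 7
    n_inversions_b: int = 3
    dropout: float = 0.0
    orphan_rate: float = 0.0

    _KNOWN = {
        "thresholds",
        "seed",
        "outdir",
        "verbosity",
        "chrom_length",
        "marker_spacing_mean",
        "n_inversions_a",
        "n_inversions_b",
        "dropout",
        "orphan_rate",
    }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ParameterError("config file must contain a mapping")
        unknown = set(raw) - cls._KNOWN
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        thresholds = ConfigDefaults.from_mapping(raw.pop("thresholds", {}) or {})
        return cls(thresholds=thresholds, **raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        """Stable hash of the effective configuration (for the manifest)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
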