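"""Threshold configuration for every stage of the atlas pipeline.

All cutoffs used anywhere in the package live in a single immutable
:class:`ThresholdConfig` so that a run is fully described by one object.
Defaults follow the published atlas conventions: detection at 1 FPKM,
fivefold elevation, fiftyfold high enrichment, group sizes 2–7, the
display-network filters (≤5 tissues, ≥3 genes), the novel-transcript
rules (>200 nt, >1 exon), the annotation-evidence thresholds
(bitscore >500, pident >50 %, E-value <1e-20), the cross-species
overlap thresholds (E-value ≤1e-5, identity ≥30 %) and the iBAQ
observable-peptide window (6–30 aa, no missed cleavages).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .exceptions import ValidationError

__all__ = ["ThresholdConfig", "load_config"]


@dataclass(frozen=True)
class ThresholdConfig:
    #: FPKM below which a gene is undetected in a tissue.
    detect_min: float = 1.0
    #: Fold ratio defining tissue_enriched / group_enriched / tissue_enhanced.
    fold_elevated: float = 5.0
    #: Fold ratio above which a tissue_enriched gene is "highly" enriched.
    fold_high: float = 50.0
    #: Smallest tissue set considered for group enrichment.
    group_size_min: int = 2
    #: Largest tissue set considered for group enrichment.
    group_size_max: int = 7
    #: Group nodes with more member tissues are dropped from the display network.
    network_max_tissues: int = 5
    #: Group nodes with fewer member genes are dropped from the display network.
    network_min_genes: int = 3
    #: Novel transcripts must be strictly longer than this (nt).
    novel_min_length: int = 200
    #: Novel transcripts must have strictly more exons than this.
    novel_min_exons: int = 1
    #: Annotation hits must have a bit score strictly above this.
    annot_min_bitscore: float = 500.0
    #: Annotation hits must have percent identity strictly above this.
    annot_min_pident: float = 50.0
    #: Annotation hits must have an E-value strictly below this.
    annot_max_evalue: float = 1e-20
    #: Cross-species overlap hits must have E-value at most this.
    overlap_max_evalue: float = 1e-5
    #: Cross-species overlap hits must have identity at least this (%).
    overlap_min_identity: float = 30.0
    #: Shortest peptide counted as observable for iBAQ (aa).
    ibaq_pep_len_min: int = 6
    #: Longest peptide counted as observable for iBAQ (aa).
    ibaq_pep_len_max: int = 30
    #: Missed cleavages allowed in the theoretical digest.
    ibaq_missed_cleavages: int = 0
    #: FPKM cut list for the detected-genes-per-abundance-stratum summary.
    abundance_bins: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0, 10000.0)

    def __post_init__(self) -> None:
        positive = (
            "detect_min", "fold_elevated", "fold_high", "group_size_min",
            "group_size_max", "network_max_tissues", "network_min_genes",
            "novel_min_length", "novel_min_exons", "annot_min_bitscore",
            "annot_min_pident", "annot_max_evalue", "overlap_max_evalue",
            "overlap_min_identity", "ibaq_pep_len_min", "ibaq_pep_len_max",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValidationError(f"config field {name!r} must be strictly positive")
        if self.ibaq_missed_cleavages < 0:
            raise ValidationError("ibaq_missed_cleavages must be >= 0")
        if self.group_size_min < 2:
            raise ValidationError("group_size_min must be >= 2")
        if self.group_size_max < self.group_size_min:
            raise ValidationError("group_size_max must be >= group_size_min")
        if self.fold_high < self.fold_elevated:
            raise ValidationError("fold_high must be >= fold_elevated")
        if self.ibaq_pep_len_min > self.ibaq_pep_len_max:
            raise ValidationError("ibaq_pep_len_min must be <= ibaq_pep_len_max")
        bins = tuple(float(b) for b in self.abundance_bins)
        if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])):
            raise ValidationError("abundance_bins must be strictly increasing")
        if any(b <= 0 for b in bins):
            raise ValidationError("abundance_bins must be strictly positive")
        object.__setattr__(self, "abundance_bins", bins)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["abundance_bins"] = list(self.abundance_bins)
        return d

    def replace(self, **overrides: Any) -> "ThresholdConfig":
        return dataclasses.replace(self, **overrides)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "ThresholdConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "abundance_bins" in kwargs:
            kwargs["abundance_bins"] = tuple(kwargs["abundance_bins"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ValidationError(f"config file {path} must hold a key: value mapping")
        return cls.from_mapping(data)

    def sha256(self) -> str:
        """Stable hash of the resolved configuration, for run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def load_config(path: str | Path | None = None, **overrides: Any) -> ThresholdConfig:
    """Load a config file (YAML mapping of field names) and apply overrides.

    Overrides win over the file, which wins over the defaults.
    """
    cfg = ThresholdConfig.from_yaml(path) if path is not None else ThresholdConfig()
    overrides = {k: v for k, v in overrides.items() if v is not None}
    if overrides:
        cfg = cfg.replace(**overrides)
    return cfg
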