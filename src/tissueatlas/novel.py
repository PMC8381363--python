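"""Novel-transcript retention and annotation-evidence filtering.

Assembled transcripts compared against the reference annotation with
gffcompare carry a one-letter class code; code ``u`` marks intergenic
(unknown) transcripts, the novel candidates. A candidate is retained
when it is also longer than 200 nt and has more than one exon.

Novel genes are then screened against protein/domain databases; a query
counts as annotated by a database when at least one hit passes the
evidence thresholds (bit score > 500, percent identity > 50, E-value
< 1e-20).

The transcript table columns (transcript_id, gene_id, class_code,
length, exon_count) map 1:1 onto gffcompare ``.tmap`` output fields
(qry_id, qry_gene_id, class_code, len, num_exons); no GTF parsing is
done here. Hit tables are BLAST/DIAMOND tabular (outfmt 6) rows with an
added ``database`` column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import ThresholdConfig
from .exceptions import FormatError, ValidationError

__all__ = [
    "TranscriptRecord",
    "AnnotationHit",
    "filter_novel_transcripts",
    "filter_annotation_hits",
    "annotation_counts",
    "read_transcript_table",
    "write_transcript_table",
    "read_hit_table",
]

DATABASES = ("NR", "SwissProt", "eggNOG", "KEGG", "Pfam")


@dataclass(frozen=True)
class TranscriptRecord:
    transcript_id: str
    gene_id: str
    class_code: str
    length: int
    exon_count: int

    def __post_init__(self) -> None:
        if len(self.class_code) != 1:
            raise ValidationError(
                f"{self.transcript_id}: class_code must be one character, got {self.class_code!r}"
            )
        if self.length <= 0:
            raise ValidationError(f"{self.transcript_id}: length must be positive")
        if self.exon_count < 1:
            raise ValidationError(f"{self.transcript_id}: exon_count must be >= 1")


@dataclass(frozen=True)
class AnnotationHit:
    query_id: str
    database: str
    bitscore: float
    pident: float
    evalue: float

    def __post_init__(self) -> None:
        if not 0 <= self.pident <= 100:
            raise ValidationError(f"{self.query_id}: pident must be in [0, 100]")
        if self.evalue < 0:
            raise ValidationError(f"{self.query_id}: evalue must be >= 0")
        if self.bitscore < 0:
            raise ValidationError(f"{self.query_id}: bitscore must be >= 0")


def filter_novel_transcripts(
    records: Sequence[TranscriptRecord], config: ThresholdConfig | None = None
) -> list[TranscriptRecord]:
    """Keep class code 'u' transcripts longer than the length cut with >1 exon.

    All three bounds are strict; input order is preserved.
    """
    cfg = config or ThresholdConfig()
    return [
        r
        for r in records
        if r.class_code == "u"
        and r.length > cfg.novel_min_length
        and r.exon_count > cfg.novel_min_exons
    ]


def _hit_passes(hit: AnnotationHit, cfg: ThresholdConfig) -> bool:
    return (
        hit.bitscore > cfg.annot_min_bitscore
        and hit.pident > cfg.annot_min_pident
        and hit.evalue < cfg.annot_max_evalue
    )


def filter_annotation_hits(
    hits: Sequence[AnnotationHit], config: ThresholdConfig | None = None
) -> dict[str, set[str]]:
    """Annotated query sets per database, plus their union under 'union'.

    A query is annotated by a database iff at least one of its hits to
    that database passes all three evidence thresholds.
    """
    cfg = config or ThresholdConfig()
    per_db: dict[str, set[str]] = {}
    union: set[str] = set()
    for hit in hits:
        if _hit_passes(hit, cfg):
            per_db.setdefault(hit.database, set()).add(hit.query_id)
            union.add(hit.query_id)
    per_db["union"] = union
    return per_db


def annotation_counts(
    hits: Sequence[AnnotationHit], config: ThresholdConfig | None = None
) -> dict[str, int]:
    """Distinct annotated-query counts per database and in the union."""
    return {db: len(qs) for db, qs in filter_annotation_hits(hits, config).items()}


# -- TSV adapters ------------------------------------------------------

TRANSCRIPT_COLUMNS = ("transcript_id", "gene_id", "class_code", "length", "exon_count")
HIT_COLUMNS = ("query_id", "database", "bitscore", "pident", "evalue")


def read_transcript_table(path: str | Path) -> list[TranscriptRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str, "class_code": str})
    missing = set(TRANSCRIPT_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        TranscriptRecord(
            transcript_id=str(r.transcript_id),
            gene_id=str(r.gene_id),
            class_code=str(r.class_code),
            length=int(r.length),
            exon_count=int(r.exon_count),
        )
        for r in frame.itertuples(index=False)
    ]


def write_transcript_table(records: Sequence[TranscriptRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "gene_id": r.gene_id,
                "class_code": r.class_code,
                "length": r.length,
                "exon_count": r.exon_count,
            }
            for r in records
        ],
        columns=list(TRANSCRIPT_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


def read_hit_table(path: str | Path) -> list[AnnotationHit]:
    frame = pd.read_csv(path, sep="\t", dtype={"query_id": str, "database": str})
    missing = set(HIT_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        AnnotationHit(
            query_id=str(r.query_id),
            database=str(r.database),
            bitscore=float(r.bitscore),
            pident=float(r.pident),
            evalue=float(r.evalue),
        )
        for r in frame.itertuples(index=False)
    ]
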