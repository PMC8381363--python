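"""iBAQ protein ranking and cross-species milk-proteome overlap.

iBAQ (intensity-based absolute quantification) divides a protein's
summed MS intensity by its number of theoretically observable tryptic
peptides, giving a quantity proportional to molar abundance that can be
ranked across proteins. The theoretical digest follows the standard
trypsin rule — cleave C-terminal to K or R, suppressed when the next
residue is P — and a peptide is observable when its length falls in the
configured window (default 6–30 aa, no missed cleavages).

Cross-species overlap counts, per species, the distinct query proteins
with at least one alignment hit to the human milk proteome passing
E-value ≤ 1e-5 and identity ≥ 30 %.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import ThresholdConfig
from .exceptions import FormatError, MappingError, ValidationError
from .specificity import pct

__all__ = [
    "ProteinEntry",
    "IbaqResult",
    "tryptic_digest",
    "compute_ibaq",
    "overlap_analysis",
    "read_fasta_proteins",
    "write_fasta_proteins",
    "read_intensities",
    "ibaq_to_frame",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinEntry:
    accession: str
    sequence: str
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValidationError(f"{self.accession}: invalid residue(s) {sorted(bad)}")
        if self.intensity < 0:
            raise ValidationError(f"{self.accession}: negative intensity")


@dataclass(frozen=True)
class IbaqResult:
    accession: str
    n_observable_peptides: int
    ibaq: float
    rank: int


def tryptic_digest(
    sequence: str,
    missed_cleavages: int = 0,
    suppress_proline: bool = True,
) -> list[str]:
    """In-silico trypsin digest of a protein sequence.

    Cleaves after every K or R, except (by default) when the following
    residue is P. With ``missed_cleavages = m`` the result contains
    every fully cleaved peptide plus every merge of up to ``m + 1``
    consecutive fully cleaved peptides, ordered by start position then
    length; the zero-missed peptides concatenate to the input.
    """
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValidationError(f"invalid residue(s) {sorted(bad)} in sequence")
    if missed_cleavages < 0:
        raise ValidationError("missed_cleavages must be >= 0")
    boundaries = [0]
    for i, residue in enumerate(sequence[:-1]):
        if residue in "KR" and (not suppress_proline or sequence[i + 1] != "P"):
            boundaries.append(i + 1)
    boundaries.append(len(sequence))
    base = [sequence[a:b] for a, b in zip(boundaries, boundaries[1:])]
    peptides = []
    for i in range(len(base)):
        for span in range(1, min(missed_cleavages + 1, len(base) - i) + 1):
            peptides.append("".join(base[i : i + span]))
    return peptides


def count_observable_peptides(sequence: str, config: ThresholdConfig | None = None) -> int:
    """Number of tryptic peptides inside the observable length window."""
    cfg = config or ThresholdConfig()
    peptides = tryptic_digest(sequence, missed_cleavages=cfg.ibaq_missed_cleavages)
    return sum(cfg.ibaq_pep_len_min <= len(p) <= cfg.ibaq_pep_len_max for p in peptides)


def compute_ibaq(
    entries: Sequence[ProteinEntry], config: ThresholdConfig | None = None
) -> tuple[list[IbaqResult], list[str]]:
    """iBAQ values and 1-based descending ranks for a set of proteins.

    Returns ``(results, undefined)`` where ``undefined`` lists accessions
    with zero observable peptides (iBAQ undefined, excluded from the
    ranking). Ties are broken by accession so the ranking is stable.
    """
    cfg = config or ThresholdConfig()
    scored, undefined = [], []
    for entry in entries:
        n_obs = count_observable_peptides(entry.sequence, cfg)
        if n_obs == 0:
            undefined.append(entry.accession)
        else:
            scored.append((entry.accession, n_obs, entry.intensity / n_obs))
    scored.sort(key=lambda t: (-t[2], t[0]))
    results = [
        IbaqResult(accession=acc, n_observable_peptides=n, ibaq=value, rank=i + 1)
        for i, (acc, n, value) in enumerate(scored)
    ]
    return results, undefined


def overlap_analysis(
    hits: pd.DataFrame,
    totals: Mapping[str, int],
    config: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Cross-species overlap table from an alignment hit table.

    ``hits`` needs columns query_id, species, pident, evalue; ``totals``
    maps each species to its total self-protein count. Per species the
    overlap is the number of distinct queries with >=1 passing hit and
    the fraction is the integer percentage of the species total.
    """
    required = {"query_id", "species", "pident", "evalue"}
    missing = required - set(hits.columns)
    if missing:
        raise FormatError(f"hit table missing column(s) {sorted(missing)}")
    cfg = config or ThresholdConfig()
    unknown = set(hits["species"]) - set(totals)
    if unknown:
        raise MappingError(f"species without totals: {sorted(unknown)}")
    passing = hits[
        (hits["evalue"] <= cfg.overlap_max_evalue)
        & (hits["pident"] >= cfg.overlap_min_identity)
    ]
    rows = []
    for species in sorted(totals):
        n_total = int(totals[species])
        if n_total <= 0:
            raise ValidationError(f"species {species!r}: total must be positive")
        n_overlap = passing.loc[passing["species"] == species, "query_id"].nunique()
        if n_overlap > n_total:
            raise ValidationError(
                f"species {species!r}: {n_overlap} overlapping queries exceed total {n_total}"
            )
        rows.append(
            {
                "species": species,
                "n_total": n_total,
                "n_overlap": int(n_overlap),
                "fraction": pct(n_overlap, n_total),
            }
        )
    return pd.DataFrame(rows, columns=["species", "n_total", "n_overlap", "fraction"])


# -- file adapters -----------------------------------------------------

def read_fasta_proteins(
    fasta_path: str | Path, intensities: Mapping[str, float] | None = None
) -> list[ProteinEntry]:
    """Load proteins from FASTA, attaching intensities by accession."""
    entries = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        intensity = 0.0 if intensities is None else float(intensities.get(record.id, 0.0))
        entries.append(ProteinEntry(record.id, str(record.seq).upper(), intensity))
    if not entries:
        raise FormatError(f"{fasta_path}: no FASTA records found")
    return entries


def write_fasta_proteins(entries: Sequence[ProteinEntry], fasta_path: str | Path) -> None:
    records = [
        SeqRecord(Seq(e.sequence), id=e.accession, description="") for e in entries
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


def read_intensities(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV of accession and summed intensity."""
    frame = pd.read_csv(path, sep="\t", dtype={"accession": str})
    missing = {"accession", "intensity"} - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return dict(zip(frame["accession"], frame["intensity"].astype(float)))


def ibaq_to_frame(results: Sequence[IbaqResult]) -> pd.DataFrame:
    """iBAQ report table with the log10 column used for abundance plots."""
    import numpy as np

    frame = pd.DataFrame(
        [
            {
                "accession": r.accession,
                "n_observable_peptides": r.n_observable_peptides,
                "ibaq": r.ibaq,
                "rank": r.rank,
            }
            for r in results
        ],
        columns=["accession", "n_observable_peptides", "ibaq", "rank"],
    )
    with np.errstate(divide="ignore"):
        frame["log10_ibaq"] = np.where(
            frame["ibaq"] > 0, np.log10(frame["ibaq"].to_numpy(dtype=float)), -float("inf")
        ) if len(frame) else []
    return frame
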