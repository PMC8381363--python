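"""Synthetic inputs with known ground truth for every pipeline stage.

The atlas generator plants, per gene, a specificity category and a
per-tissue mean FPKM profile that satisfies that category's defining
inequalities (and fails the competing ones) with a configurable margin;
replicate samples are the means perturbed by multiplicative log-normal
noise, the dominant dispersion pattern of RNA-seq abundance estimates.
Companion generators emit transcript tables with exactly one violated
retention rule per non-retained record, annotation/overlap hit tables
with planted pass labels, and toy proteomes assembled from tryptic
peptides of known lengths so observable-peptide counts are known by
construction.

All generators are fully deterministic under their seed.

A note on tissue-enhanced planting: a gene whose top tissue is, say,
10× the mean of the others almost always also satisfies the fivefold
group rule for the pair {top, runner-up} (for n tissues with runner-up
s ≥ baseline b, top ≥ 10·mean(others) forces (top+s)/2 ≥ 5·mean(rest)),
and the precedence order then classifies it group-enriched. Feasible
tissue-enhanced profiles therefore live in a narrow fold window
(≈5–8× for typical tissue counts); this generator plants them at the
largest feasible fold given the requested margin, which caps the
effective margin for this one category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .config import ThresholdConfig
from .exceptions import ValidationError
from .io import ExpressionMatrix, TissueProfile
from .novel import AnnotationHit, TranscriptRecord, DATABASES
from .proteomics import ProteinEntry
from .specificity import CATEGORY_ORDER

__all__ = [
    "AtlasSimSpec",
    "AtlasData",
    "generate_atlas",
    "generate_transcripts",
    "generate_annotation_hits",
    "generate_proteome",
    "ProteomeData",
]

#: Default planted category mix, shaped like a real tissue atlas
#: (most genes ubiquitous or enhanced, a few percent undetected).
DEFAULT_PROPORTIONS = {
    "not_detected": 0.03,
    "tissue_enriched": 0.16,
    "group_enriched": 0.10,
    "tissue_enhanced": 0.21,
    "expressed_in_all": 0.42,
    "mixed": 0.08,
}


@dataclass(frozen=True)
class AtlasSimSpec:
    """Parameters of a planted expression atlas."""

    n_genes: int = 1000
    n_tissues: int = 16
    replicates_per_tissue: int = 3
    #: category name -> fraction of genes planted in it (sums to 1).
    category_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    #: planted fold-change range for enriched/group genes (log-uniform).
    fold_range_elevated: tuple[float, float] = (10.0, 50.0)
    #: background FPKM range for non-elevated tissues (log-uniform).
    baseline_fpkm_range: tuple[float, float] = (2.0, 20.0)
    #: log-normal sigma of multiplicative replicate noise.
    replicate_noise_sigma: float = 0.2
    #: planted inequalities hold/fail with at least this factor (where feasible).
    margin: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        props = {c: float(self.category_proportions.get(c, 0.0)) for c in CATEGORY_ORDER}
        unknown = set(self.category_proportions) - set(CATEGORY_ORDER)
        if unknown:
            raise ValidationError(f"unknown categories in proportions: {sorted(unknown)}")
        if any(p < 0 for p in props.values()):
            raise ValidationError("category proportions must be non-negative")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValidationError("category proportions must sum to 1")
        object.__setattr__(self, "category_proportions", props)
        if self.n_genes < 1 or self.n_tissues < 2 or self.replicates_per_tissue < 1:
            raise ValidationError("n_genes >= 1, n_tissues >= 2, replicates >= 1 required")
        if self.replicate_noise_sigma < 0:
            raise ValidationError("replicate_noise_sigma must be >= 0")
        if self.margin < 1.0:
            raise ValidationError("margin must be >= 1")
        lo, hi = self.fold_range_elevated
        if not (0 < lo <= hi):
            raise ValidationError("fold_range_elevated must be a positive interval")
        lo, hi = self.baseline_fpkm_range
        if not (0 < lo <= hi):
            raise ValidationError("baseline_fpkm_range must be a positive interval")
        needs_three = ("group_enriched", "tissue_enhanced")
        if self.n_tissues < 3 and any(props[c] > 0 for c in needs_three):
            raise ValidationError(
                "group_enriched / tissue_enhanced planting needs >= 3 tissues"
            )


class AtlasData(NamedTuple):
    matrix: ExpressionMatrix  # genes x samples FPKM with replicate noise
    metadata: pd.DataFrame  # sample_id, tissue, donor_id
    truth: pd.DataFrame  # planted_category, planted_tissues, planted_fold
    profile: TissueProfile  # genes x tissues true mean FPKM


def _assign_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n genes over the categories."""
    raw = {c: n * p for c, p in proportions.items()}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    leftover = n - sum(counts.values())
    order = sorted(raw, key=lambda c: (raw[c] - counts[c], c), reverse=True)
    for c in order[:leftover]:
        counts[c] += 1
    return counts


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def generate_atlas(spec: AtlasSimSpec, config: ThresholdConfig | None = None) -> AtlasData:
    """Generate a planted atlas: replicate matrix, metadata, truth, mean profile."""
    cfg = config or ThresholdConfig()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n, nt = spec.n_genes, spec.n_tissues
    tissues = [f"tissue{i + 1:02d}" for i in range(nt)]
    d = cfg.detect_min
    fe = cfg.fold_elevated
    m = spec.margin
    b_lo, b_hi = spec.baseline_fpkm_range
    f_lo, f_hi = spec.fold_range_elevated

    counts = _assign_counts(n, spec.category_proportions)
    categories = [c for c in CATEGORY_ORDER for _ in range(counts[c])]
    rng.shuffle(categories)

    means = np.zeros((n, nt))
    planted_tissues: list[tuple[str, ...]] = []
    planted_fold = np.full(n, np.nan)

    for g, cat in enumerate(categories):
        if cat == "not_detected":
            means[g] = rng.uniform(0.0, d / (2.0 * m), size=nt)
            planted_tissues.append(())
        elif cat == "expressed_in_all":
            # spread ratio <= 3 so every fivefold rule fails with margin 5/3
            means[g] = _log_uniform(rng, 3.0 * d, 9.0 * d, size=nt)
            planted_tissues.append(())
        elif cat == "tissue_enriched":
            others = _log_uniform(rng, b_lo, b_hi, size=nt - 1)
            fold = _log_uniform(rng, f_lo, f_hi)
            t = int(rng.integers(nt))
            row = np.empty(nt)
            row[np.arange(nt) != t] = others
            row[t] = fold * others.max()
            means[g] = row
            planted_tissues.append((tissues[t],))
            planted_fold[g] = fold
        elif cat == "group_enriched":
            k = int(rng.integers(cfg.group_size_min, min(cfg.group_size_max, nt - 1) + 1))
            members = rng.choice(nt, size=k, replace=False)
            comp = _log_uniform(rng, b_lo, b_hi, size=nt - k)
            fold = _log_uniform(rng, f_lo, f_hi)
            target = fold * comp.mean()
            jitter = rng.uniform(0.85, 1.15, size=k)
            member_vals = target * jitter / jitter.mean()  # exact planted group mean
            # keep members strictly above every complement tissue so the
            # top-k tissues are exactly the planted group
            if comp.size and member_vals.min() <= 1.25 * comp.max():
                comp *= member_vals.min() / (1.25 * comp.max())
            fold = member_vals.mean() / comp.mean()
            row = np.empty(nt)
            mask = np.zeros(nt, dtype=bool)
            mask[members] = True
            row[mask] = member_vals
            row[~mask] = comp
            means[g] = row
            planted_tissues.append(tuple(sorted(tissues[t] for t in members)))
            planted_fold[g] = fold
        elif cat == "tissue_enhanced":
            # pattern: top v, one support s = 5b/3, baseline b elsewhere.
            # feasible window: fe*mean(others) <= v < min(fe*s, 2*fe*b - s) = 25b/3
            b = _log_uniform(rng, b_lo, b_hi)
            s = fe * b / 3.0
            lower = fe * (s + (nt - 2) * b) / (nt - 1)
            upper = 0.97 * (2.0 * fe * b - s)
            lo = lower * m
            if lo >= upper:
                v = math.sqrt(lower * upper)  # margin capped by feasibility
            else:
                v = _log_uniform(rng, lo, upper)
            t, t_sup = rng.choice(nt, size=2, replace=False)
            row = np.full(nt, b)
            row[t_sup] = s
            row[t] = v
            means[g] = row
            planted_tissues.append((tissues[int(t)],))
            planted_fold[g] = v / ((s + (nt - 2) * b) / (nt - 1))
        elif cat == "mixed":
            # detected tissues at 1.5-2.2x the cutoff, the rest at 0.6-0.9x:
            # every mean-vs-mean ratio stays <= 2.2/0.6 < 5, so no fold rule
            # fires, yet the gene is detected somewhere but not everywhere
            n_det = max(1, math.ceil(nt / 2))
            det = rng.choice(nt, size=n_det, replace=False)
            row = rng.uniform(0.6 * d, 0.9 * d, size=nt)
            row[det] = rng.uniform(1.5 * d, 2.2 * d, size=n_det)
            means[g] = row
            planted_tissues.append(())
        else:  # pragma: no cover
            raise ValidationError(f"unplantable category {cat!r}")

    sample_ids, sample_tissue, donor_ids = [], [], []
    for tissue in tissues:
        for r in range(spec.replicates_per_tissue):
            sample_ids.append(f"{tissue}_r{r + 1}")
            sample_tissue.append(tissue)
            donor_ids.append(f"donor{r + 1:02d}")
    metadata = pd.DataFrame(
        {"sample_id": sample_ids, "tissue": sample_tissue, "donor_id": donor_ids}
    )

    reps = spec.replicates_per_tissue
    noise = rng.lognormal(mean=0.0, sigma=spec.replicate_noise_sigma, size=(n, nt, reps))
    samples = (means[:, :, None] * noise).reshape(n, nt * reps)
    gene_ids = [f"gene{i + 1:05d}" for i in range(n)]
    matrix = ExpressionMatrix(
        values=pd.DataFrame(samples, index=gene_ids, columns=sample_ids), unit="FPKM"
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "planted_category": categories,
            "planted_tissues": [";".join(t) for t in planted_tissues],
            "planted_fold": planted_fold,
        }
    )
    profile = TissueProfile(values=pd.DataFrame(means, index=gene_ids, columns=tissues))
    return AtlasData(matrix=matrix, metadata=metadata, truth=truth, profile=profile)


# -- transcript and hit generators ------------------------------------

OTHER_CLASS_CODES = "=cjeiopxsm"


def generate_transcripts(
    n: int,
    retain_fraction: float,
    seed: int = 0,
    config: ThresholdConfig | None = None,
) -> tuple[list[TranscriptRecord], list[bool]]:
    """Transcript records with planted retention labels.

    Exactly ``round(n * retain_fraction)`` records pass the novelty
    filter; each non-retained record violates exactly one of the three
    rules (class code, length, exon count) so every predicate is
    exercised.
    """
    if not 0.0 <= retain_fraction <= 1.0:
        raise ValidationError("retain_fraction must be in [0, 1]")
    cfg = config or ThresholdConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    n_keep = int(round(n * retain_fraction))
    keep = np.zeros(n, dtype=bool)
    keep[rng.choice(n, size=n_keep, replace=False)] = True
    records, violation = [], 0
    for i in range(n):
        class_code = "u"
        length = int(rng.integers(cfg.novel_min_length + 1, 5000))
        exons = int(rng.integers(cfg.novel_min_exons + 1, 12))
        if not keep[i]:
            mode = violation % 3
            violation += 1
            if mode == 0:
                class_code = OTHER_CLASS_CODES[int(rng.integers(len(OTHER_CLASS_CODES)))]
            elif mode == 1:
                length = int(rng.integers(50, cfg.novel_min_length + 1))  # <= cut
            else:
                exons = cfg.novel_min_exons  # at the exclusive bound
        records.append(
            TranscriptRecord(
                transcript_id=f"TCONS{i + 1:06d}",
                gene_id=f"XLOC{i // 3 + 1:06d}",
                class_code=class_code,
                length=length,
                exon_count=exons,
            )
        )
    return records, keep.tolist()


def generate_annotation_hits(
    n_queries: int,
    pass_fraction: float,
    seed: int = 0,
    config: ThresholdConfig | None = None,
) -> tuple[list[AnnotationHit], list[bool]]:
    """Annotation hit table with planted pass labels (one hit per query).

    Passing hits clear all three evidence thresholds; failing hits
    violate exactly one of them, cycling through the three predicates.
    """
    if not 0.0 <= pass_fraction <= 1.0:
        raise ValidationError("pass_fraction must be in [0, 1]")
    cfg = config or ThresholdConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    n_pass = int(round(n_queries * pass_fraction))
    passing = np.zeros(n_queries, dtype=bool)
    passing[rng.choice(n_queries, size=n_pass, replace=False)] = True
    hits, violation = [], 0
    for i in range(n_queries):
        bitscore = rng.uniform(cfg.annot_min_bitscore * 1.1, cfg.annot_min_bitscore * 3)
        pident = rng.uniform(cfg.annot_min_pident * 1.1, 100.0)
        evalue = 10.0 ** rng.uniform(-80.0, np.log10(cfg.annot_max_evalue) - 1.0)
        if not passing[i]:
            mode = violation % 3
            violation += 1
            if mode == 0:
                bitscore = rng.uniform(0.0, cfg.annot_min_bitscore)
            elif mode == 1:
                pident = rng.uniform(0.0, cfg.annot_min_pident)
            else:
                evalue = 10.0 ** rng.uniform(np.log10(cfg.annot_max_evalue) + 1.0, 0.0)
        hits.append(
            AnnotationHit(
                query_id=f"novel{i + 1:05d}",
                database=DATABASES[int(rng.integers(len(DATABASES)))],
                bitscore=float(bitscore),
                pident=float(pident),
                evalue=float(evalue),
            )
        )
    return hits, passing.tolist()


# -- proteome generator ------------------------------------------------

# residues used inside construction peptides: no K/R (would add cleavage
# sites) and no P (would suppress the intended boundary cleavages)
_NO_KR = "ACDEFGHILMNQSTVWY"
_NO_KRP = _NO_KR


class ProteomeData(NamedTuple):
    entries: list[ProteinEntry]
    observable_counts: list[int]  # peptides in the length window, by construction
    hits: pd.DataFrame  # overlap hit table: query_id, species, pident, evalue
    hit_pass: list[bool]


def _random_peptide(rng: np.random.Generator, length: int, terminal_kr: bool) -> str:
    if terminal_kr and length == 1:
        return "KR"[int(rng.integers(2))]
    body_len = length - 1 if terminal_kr else length
    chars = [
        _NO_KRP[int(rng.integers(len(_NO_KRP)))] if i == 0 else _NO_KR[int(rng.integers(len(_NO_KR)))]
        for i in range(body_len)
    ]
    if terminal_kr:
        chars.append("KR"[int(rng.integers(2))])
    return "".join(chars)


def generate_proteome(
    n: int,
    seed: int = 0,
    pass_fraction: float = 0.5,
    species: str = "synthetic",
    config: ThresholdConfig | None = None,
) -> ProteomeData:
    """Toy proteome assembled from tryptic peptides of known lengths.

    Every peptide except the last ends in K/R and no peptide starts with
    P, so the trypsin rule recovers exactly the construction peptides;
    the observable count under the configured length window is recorded
    during assembly. A companion overlap hit table plants a known
    passing fraction against the thresholds.
    """
    if n < 1:
        raise ValidationError("need n >= 1 proteins")
    cfg = config or ThresholdConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    entries, observable = [], []
    for i in range(n):
        n_pep = int(rng.integers(3, 12))
        lengths = []
        for _ in range(n_pep):
            if rng.random() < 0.7:
                lengths.append(int(rng.integers(cfg.ibaq_pep_len_min, cfg.ibaq_pep_len_max + 1)))
            elif rng.random() < 0.5 and cfg.ibaq_pep_len_min > 1:
                lengths.append(int(rng.integers(1, cfg.ibaq_pep_len_min)))
            else:
                lengths.append(int(rng.integers(cfg.ibaq_pep_len_max + 1, cfg.ibaq_pep_len_max + 15)))
        peptides = [
            _random_peptide(rng, L, terminal_kr=(j < n_pep - 1))
            for j, L in enumerate(lengths)
        ]
        entries.append(
            ProteinEntry(
                accession=f"PROT{i + 1:05d}",
                sequence="".join(peptides),
                intensity=float(10.0 ** rng.uniform(5.0, 9.0)),
            )
        )
        observable.append(
            sum(cfg.ibaq_pep_len_min <= L <= cfg.ibaq_pep_len_max for L in lengths)
        )

    n_pass = int(round(n * pass_fraction))
    passing = np.zeros(n, dtype=bool)
    passing[rng.choice(n, size=n_pass, replace=False)] = True
    rows, violation = [], 0
    for i, entry in enumerate(entries):
        pident = rng.uniform(cfg.overlap_min_identity, 100.0)
        evalue = 10.0 ** rng.uniform(-40.0, np.log10(cfg.overlap_max_evalue))
        if not passing[i]:
            if violation % 2 == 0:
                pident = rng.uniform(0.0, cfg.overlap_min_identity * 0.95)
            else:
                evalue = 10.0 ** rng.uniform(np.log10(cfg.overlap_max_evalue) + 0.5, 0.0)
            violation += 1
        rows.append(
            {"query_id": entry.accession, "species": species,
             "pident": float(pident), "evalue": float(evalue)}
        )
    hits = pd.DataFrame(rows, columns=["query_id", "species", "pident", "evalue"])
    return ProteomeData(entries=entries, observable_counts=observable, hits=hits, hit_pass=passing.tolist())
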