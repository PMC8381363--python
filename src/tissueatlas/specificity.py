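"""Six-category expression-specificity classification.

Every gene in a tissues-averaged FPKM profile is assigned exactly one of
six categories, following the classification scheme established for
human tissue atlases:

``not_detected``
    FPKM below the detection cutoff (default 1) in every tissue.
``tissue_enriched``
    the top tissue is detected and at least ``fold_elevated`` (default
    5×) above the second-highest tissue. Calls with fold at or above
    ``fold_high`` (default 50×) are flagged highly enriched.
``group_enriched``
    some set of 2–7 tissues, all detected, has mean FPKM at least
    ``fold_elevated`` times the mean of the remaining tissues.
``tissue_enhanced``
    the top tissue is detected and at least ``fold_elevated`` times the
    mean of all other tissues.
``expressed_in_all``
    detected in every tissue.
``mixed``
    everything else (detected somewhere, but no rule above applies).

The rules are applied in that precedence order, which makes the six
classes a partition. For the group search it suffices to test top-``k``
prefixes of the tissues sorted by descending expression: the ``k``
highest-expressing tissues simultaneously maximise the group mean and
minimise the complement mean among all size-``k`` sets, and their
minimum is the largest of any size-``k`` set, so if the prefix fails the
detection or fold rule every other set of that size fails too. The
smallest qualifying prefix is reported.
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ThresholdConfig
from .exceptions import UndefinedStatisticError, ValidationError
from .io import TissueProfile

__all__ = [
    "Category",
    "SpecificityCall",
    "CategorySummary",
    "classify_gene",
    "classify_all",
    "elevated_transcript_fraction",
    "detected_gene_counts",
    "calls_to_frame",
    "frame_to_calls",
    "round_half_away",
    "pct",
]

ELEVATED = ("tissue_enriched", "group_enriched", "tissue_enhanced")


class Category(str, enum.Enum):
    NOT_DETECTED = "not_detected"
    TISSUE_ENRICHED = "tissue_enriched"
    GROUP_ENRICHED = "group_enriched"
    TISSUE_ENHANCED = "tissue_enhanced"
    EXPRESSED_IN_ALL = "expressed_in_all"
    MIXED = "mixed"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical category order used in summaries and reports.
CATEGORY_ORDER = tuple(c.value for c in Category)


@dataclass(frozen=True)
class SpecificityCall:
    """Classification outcome for one gene."""

    gene_id: str
    category: Category
    elevated_tissues: tuple[str, ...] = ()
    fold_change: float = float("nan")
    highly_enriched: bool = False

    @property
    def is_elevated(self) -> bool:
        return self.category.value in ELEVATED


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (printed-number convention)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def pct(count: float, total: float, ndigits: int = 0) -> float:
    """Percentage of ``count`` in ``total`` rounded half away from zero."""
    if total <= 0:
        raise UndefinedStatisticError("percentage of an empty total is undefined")
    return round_half_away(100.0 * count / total, ndigits)


def classify_gene(
    expression: Sequence[float] | np.ndarray,
    tissues: Sequence[str],
    config: ThresholdConfig | None = None,
    gene_id: str = "",
) -> SpecificityCall:
    """Classify a single gene from its per-tissue FPKM vector.

    ``tissues`` names the entries of ``expression``; ties in expression
    are broken by lexicographic tissue name so the call is deterministic.
    """
    cfg = config or ThresholdConfig()
    values = np.asarray(expression, dtype=float)
    n = values.size
    if n < 2:
        raise ValidationError(f"gene {gene_id!r}: need >=2 tissues, got {n}")
    if len(tissues) != n:
        raise ValidationError(f"gene {gene_id!r}: {len(tissues)} tissue names for {n} values")
    if np.any(values < 0) or np.any(~np.isfinite(values)):
        raise ValidationError(f"gene {gene_id!r}: expression must be finite and non-negative")

    names = np.asarray(tissues, dtype=object)
    # descending expression, lexicographic tissue name as tie-break
    order = np.lexsort((names, -values))
    sv = values[order]
    sn = names[order]
    fe = cfg.fold_elevated

    if sv[0] < cfg.detect_min:
        return SpecificityCall(gene_id, Category.NOT_DETECTED)

    top, second = float(sv[0]), float(sv[1])
    if top >= fe * second:
        fold = math.inf if second == 0 else top / second
        return SpecificityCall(
            gene_id,
            Category.TISSUE_ENRICHED,
            elevated_tissues=(str(sn[0]),),
            fold_change=fold,
            highly_enriched=fold >= cfg.fold_high,
        )

    csum = np.cumsum(sv)
    total = csum[-1]
    k_max = min(cfg.group_size_max, n - 1)
    for k in range(cfg.group_size_min, k_max + 1):
        if sv[k - 1] < cfg.detect_min:
            break  # smaller values only from here on
        mean_g = csum[k - 1] / k
        mean_c = (total - csum[k - 1]) / (n - k)
        if mean_g >= fe * mean_c:
            fold = math.inf if mean_c == 0 else float(mean_g) / float(mean_c)
            return SpecificityCall(
                gene_id,
                Category.GROUP_ENRICHED,
                elevated_tissues=tuple(str(t) for t in sn[:k]),
                fold_change=fold,
            )

    mean_rest = (total - top) / (n - 1)
    if top >= fe * mean_rest:
        fold = math.inf if mean_rest == 0 else top / float(mean_rest)
        return SpecificityCall(
            gene_id,
            Category.TISSUE_ENHANCED,
            elevated_tissues=(str(sn[0]),),
            fold_change=fold,
        )

    if sv[-1] >= cfg.detect_min:
        return SpecificityCall(gene_id, Category.EXPRESSED_IN_ALL)
    return SpecificityCall(gene_id, Category.MIXED)


@dataclass
class CategorySummary:
    """Per-category gene counts and the derived printed-style percentages."""

    counts: dict[str, int]
    per_tissue_enriched: Counter = field(default_factory=Counter)
    per_tissue_elevated: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        self.counts = {c: int(self.counts.get(c, 0)) for c in CATEGORY_ORDER}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def category_pct(self, ndigits: int = 0) -> dict[str, float]:
        """Share of each category in the total, integer % by default."""
        return {c: pct(n, self.total, ndigits) for c, n in self.counts.items()}

    def elevated_count(self) -> int:
        return sum(self.counts[c] for c in ELEVATED)

    def elevated_pct(self, ndigits: int = 0) -> float:
        return pct(self.elevated_count(), self.total, ndigits)

    def tissue_enriched_pct(self, tissue: str, ndigits: int = 1) -> float:
        """Per-tissue share of tissue-enriched genes (one decimal, as printed)."""
        return pct(self.per_tissue_enriched.get(tissue, 0), self.total, ndigits)

    @classmethod
    def from_calls(cls, calls: Sequence[SpecificityCall], tissues: Sequence[str] = ()) -> "CategorySummary":
        counts = Counter(c.category.value for c in calls)
        enriched: Counter = Counter({t: 0 for t in tissues})
        elevated: Counter = Counter({t: 0 for t in tissues})
        for call in calls:
            if call.category is Category.TISSUE_ENRICHED:
                enriched[call.elevated_tissues[0]] += 1
            if call.is_elevated:
                for t in call.elevated_tissues:
                    elevated[t] += 1
        return cls(counts=dict(counts), per_tissue_enriched=enriched, per_tissue_elevated=elevated)

    @classmethod
    def from_counts(
        cls,
        counts: dict[str, int],
        per_tissue_enriched: dict[str, int] | None = None,
    ) -> "CategorySummary":
        return cls(counts=counts, per_tissue_enriched=Counter(per_tissue_enriched or {}))

    def to_frame(self) -> pd.DataFrame:
        shares = self.category_pct()
        return pd.DataFrame(
            {
                "category": list(CATEGORY_ORDER),
                "count": [self.counts[c] for c in CATEGORY_ORDER],
                "pct": [shares[c] for c in CATEGORY_ORDER],
            }
        )


def classify_all(
    profile: TissueProfile, config: ThresholdConfig | None = None
) -> tuple[list[SpecificityCall], CategorySummary]:
    """Classify every gene of a tissue profile and summarise the atlas."""
    cfg = config or ThresholdConfig()
    tissues = profile.tissues
    if len(tissues) < 2:
        raise ValidationError("classification needs a profile with >=2 tissues")
    values = profile.values.to_numpy(dtype=float)
    calls: list[SpecificityCall] = []
    for gene_id, row in zip(profile.gene_ids, values):
        try:
            calls.append(classify_gene(row, tissues, cfg, gene_id=gene_id))
        except ValidationError:
            raise
    summary = CategorySummary.from_calls(calls, tissues=tissues)
    return calls, summary


def elevated_transcript_fraction(
    profile: TissueProfile, calls: Sequence[SpecificityCall], tissue: str
) -> float:
    """Percent of a tissue's FPKM mass carried by genes elevated there.

    A gene counts as elevated in ``tissue`` when it is tissue_enriched,
    group_enriched or tissue_enhanced with ``tissue`` among its elevated
    tissues.
    """
    if tissue not in profile.tissues:
        raise ValidationError(f"tissue {tissue!r} not in profile")
    col = profile.values[tissue]
    total = float(col.sum())
    if total <= 0:
        raise UndefinedStatisticError(f"tissue {tissue!r} has zero total FPKM")
    elevated_genes = [
        c.gene_id for c in calls if c.is_elevated and tissue in c.elevated_tissues
    ]
    mass = float(col.loc[elevated_genes].sum()) if elevated_genes else 0.0
    return 100.0 * mass / total


def detected_gene_counts(
    profile: TissueProfile, bins: Sequence[float] | None = None
) -> pd.DataFrame:
    """Per-tissue counts of genes at or above each FPKM cut.

    Returns a tissues × cuts DataFrame; counts are weakly decreasing
    across increasing cuts because the strata are nested.
    """
    cuts = tuple(ThresholdConfig().abundance_bins if bins is None else bins)
    if any(b2 <= b1 for b1, b2 in zip(cuts, cuts[1:])):
        raise ValidationError("abundance cuts must be strictly increasing")
    values = profile.values.to_numpy(dtype=float)
    data = {f">={c:g}": (values >= c).sum(axis=0) for c in cuts}
    return pd.DataFrame(data, index=profile.tissues)


# -- call table serialization -----------------------------------------

CALL_COLUMNS = ("gene_id", "category", "elevated_tissues", "fold_change", "highly_enriched")


def calls_to_frame(calls: Sequence[SpecificityCall]) -> pd.DataFrame:
    """Render calls as the canonical TSV-ready table."""
    rows = [
        {
            "gene_id": c.gene_id,
            "category": c.category.value,
            "elevated_tissues": ";".join(c.elevated_tissues),
            "fold_change": "inf" if math.isinf(c.fold_change) else (
                "" if math.isnan(c.fold_change) else repr(float(c.fold_change))
            ),
            "highly_enriched": str(c.highly_enriched).lower(),
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=list(CALL_COLUMNS))


def frame_to_calls(frame: pd.DataFrame) -> list[SpecificityCall]:
    calls = []
    for row in frame.itertuples(index=False):
        fold = getattr(row, "fold_change")
        if pd.isna(fold) or fold == "":
            fold_val = float("nan")
        else:
            fold_val = float(fold)
        tissues = getattr(row, "elevated_tissues")
        tissues = () if (pd.isna(tissues) or tissues == "") else tuple(str(tissues).split(";"))
        calls.append(
            SpecificityCall(
                gene_id=str(row.gene_id),
                category=Category(row.category),
                elevated_tissues=tissues,
                fold_change=fold_val,
                highly_enriched=str(row.highly_enriched).lower() == "true",
            )
        )
    return calls
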