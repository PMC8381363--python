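"""Sample-to-sample Spearman similarity and average-linkage clustering.

Global expression profiles are compared on TPM: the pairwise Spearman
rank correlation ρ between samples is the similarity, 1 − ρ the
distance, and samples are merged by average linkage (UPGMA on the
correlation distance). The merge tree is serialised as Newick with the
merge heights encoded as node depths (a child's branch length is the
parent's merge height minus the child's own merge height).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .exceptions import UndefinedStatisticError, ValidationError
from .io import ExpressionMatrix

__all__ = ["SimilarityResult", "spearman_similarity"]


@dataclass
class SimilarityResult:
    correlation: pd.DataFrame
    linkage: np.ndarray
    newick: str


def _to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"


def spearman_similarity(matrix: ExpressionMatrix) -> SimilarityResult:
    """Pairwise Spearman ρ between samples plus the average-linkage tree.

    Requires a TPM matrix with at least two samples. A sample whose
    expression vector is constant has no rank variance and therefore no
    defined correlation; it is reported by name.
    """
    if matrix.unit != "TPM":
        raise ValidationError("similarity analysis is defined on TPM matrices")
    samples = matrix.sample_ids
    if len(samples) < 2:
        raise ValidationError("need >=2 samples for similarity analysis")
    values = matrix.values.to_numpy(dtype=float)
    constant = [s for s, col in zip(samples, values.T) if np.ptp(col) == 0]
    if constant:
        raise UndefinedStatisticError(
            f"constant expression, Spearman undefined for sample(s): {constant}"
        )
    ranks = np.apply_along_axis(rankdata, 0, values)
    rho = np.corrcoef(ranks, rowvar=False)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    corr = pd.DataFrame(rho, index=samples, columns=samples)

    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    newick = _to_newick(linkage, list(samples))
    return SimilarityResult(correlation=corr, linkage=linkage, newick=newick)
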