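import itertools

import numpy as np
import pandas as pd
import pytest

from tissueatlas import AtlasSimSpec, ThresholdConfig, generate_atlas


@pytest.fixture(scope="session")
def config() -> ThresholdConfig:
    return ThresholdConfig()


@pytest.fixture(scope="session")
def noiseless_atlas():
    spec = AtlasSimSpec(n_genes=300, n_tissues=12, replicates_per_tissue=3,
                        replicate_noise_sigma=0.0, seed=11)
    return generate_atlas(spec)


@pytest.fixture()
def toy_matrix_frame():
    """3 genes x 4 samples (2 tissues x 2 replicates) FPKM table."""
    return pd.DataFrame(
        {
            "liver_r1": [4.0, 0.0, 7.3],
            "liver_r2": [6.0, 0.0, 7.3],
            "lung_r1": [1.0, 2.0, 0.5],
            "lung_r2": [3.0, 2.0, 0.5],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )


@pytest.fixture()
def toy_metadata():
    return pd.DataFrame(
        {
            "sample_id": ["liver_r1", "liver_r2", "lung_r1", "lung_r2"],
            "tissue": ["liver", "liver", "lung", "lung"],
            "donor_id": ["d1", "d2", "d1", "d2"],
        }
    )


def brute_force_category(values, tissues, cfg: ThresholdConfig) -> str:
    """Independent classifier: exhaustive enumeration of all tissue subsets.

    Follows the category definitions directly, enumerating every subset
    of size group_size_min..group_size_max for the group rule instead of
    the top-k prefix shortcut used by the implementation.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if v.max() < cfg.detect_min:
        return "not_detected"
    order = np.lexsort((np.asarray(tissues, dtype=object), -v))
    sv = v[order]
    if sv[0] >= cfg.fold_elevated * sv[1]:
        return "tissue_enriched"
    for k in range(cfg.group_size_min, min(cfg.group_size_max, n - 1) + 1):
        for subset in itertools.combinations(range(n), k):
            group = v[list(subset)]
            if group.min() < cfg.detect_min:
                continue
            rest = np.delete(v, list(subset))
            if group.mean() >= cfg.fold_elevated * rest.mean():
                return "group_enriched"
    if sv[0] >= cfg.fold_elevated * (v.sum() - sv[0]) / (n - 1):
        return "tissue_enhanced"
    if v.min() >= cfg.detect_min:
        return "expressed_in_all"
    return "mixed"
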