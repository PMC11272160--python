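"""Shared fixtures: one simulated time course and one reference atlas.

Both are session-scoped so the heavier stages (LSI fit, consecutive
contrasts) run once for the whole suite.  Seeds are fixed constants so
every run sees identical data.
"""

import numpy as np
import pandas as pd
import pytest

import amniowave as aw

TIME_COURSE_SEED = 11
ATLAS_SEED = 7


@pytest.fixture(scope="session")
def sim_config():
    return aw.SimConfig(seed=TIME_COURSE_SEED)


@pytest.fixture(scope="session")
def time_course(sim_config):
    """(CountMatrix, StageTruth) under the default study design."""
    return aw.generate_time_course(sim_config)


@pytest.fixture(scope="session")
def norm_course(time_course):
    """Filtered and median-ratio-normalized time course."""
    matrix, _ = time_course
    filtered = aw.filter_low_expression(matrix)
    sf = aw.size_factors_median_ratio(filtered)
    return aw.normalize_counts(filtered, sf)


@pytest.fixture(scope="session")
def contrasts_course(norm_course):
    return aw.consecutive_contrasts(norm_course)


@pytest.fixture(scope="session")
def assignment_course(contrasts_course):
    return aw.assign_stages(contrasts_course)


@pytest.fixture(scope="session")
def atlas_config():
    return aw.AtlasConfig(seed=ATLAS_SEED)


@pytest.fixture(scope="session")
def atlas_bundle(atlas_config):
    """(ReferenceAtlas, ClusterTruth) with a fitted LSI model attached."""
    atlas, truth = aw.generate_reference_atlas(atlas_config)
    atlas.lsi = aw.fit_lsi(atlas, n_components=30)
    return atlas, truth


@pytest.fixture(scope="session")
def cluster_bulks(atlas_bundle, atlas_config):
    """Four bulk samples per cluster, drawn from pooled cluster profiles."""
    atlas, _ = atlas_bundle
    parts = [
        aw.generate_bulk_from_cluster(atlas, label, n_samples=4, depth=1_000_000, seed=100 + i)
        for i, label in enumerate(atlas_config.clusters)
    ]
    return aw.CountMatrix(
        pd.concat([p.counts for p in parts], axis=1),
        pd.concat([p.sample_meta for p in parts]),
    )


def toy_count_matrix(counts, gene_ids=None, sample_ids=None, timepoints=None):
    """Small helper for hand-built fixtures."""
    counts = np.asarray(counts)
    genes = gene_ids or [f"g{i + 1}" for i in range(counts.shape[0])]
    samples = sample_ids or [f"s{j + 1}" for j in range(counts.shape[1])]
    meta = pd.DataFrame(
        {
            "timepoint_hr": timepoints if timepoints is not None else np.nan,
            "condition": "toy",
            "replicate": range(1, counts.shape[1] + 1),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return aw.CountMatrix(
        pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples), meta
    )
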