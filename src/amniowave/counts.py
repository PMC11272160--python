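"""Count-matrix container, expression filters, normalization, and sample PCA.

The central object is :class:`CountMatrix`: a genes x samples table of raw
non-negative integer read counts plus per-sample metadata (timepoint in
hours, condition, replicate).  Downstream stages consume a
:class:`NormalizedMatrix` produced by median-of-ratios (DESeq2-style) size
factors, which corrects for sequencing-depth differences without touching
gene length (counts are gene-level, compared only across samples).

Orientation is fixed package-wide: genes are rows, samples are columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import ConfigurationError, NormalizationError

logger = logging.getLogger(__name__)

#: Expected sample-metadata columns and their pandas dtypes.
SAMPLE_META_COLUMNS = ("timepoint_hr", "condition", "replicate")


@dataclass
class CountMatrix:
    """Raw gene x sample counts with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers; index = gene IDs, columns =
        sample IDs, both unique.
    sample_meta
        DataFrame indexed by sample ID with columns ``timepoint_hr``
        (float or NaN), ``condition`` (str), ``replicate`` (int).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ConfigurationError(f"duplicate gene IDs: {list(dupes[:5])}")
        if self.counts.columns.has_duplicates:
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise ConfigurationError(f"duplicate sample IDs: {list(dupes[:5])}")
        values = self.counts.to_numpy()
        if values.size and (np.asarray(values) < 0).any():
            raise ConfigurationError("counts contain negative values")
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ConfigurationError("counts are not integral")
            self.counts = self.counts.round().astype(np.int64)
        missing = self.counts.columns.difference(self.sample_meta.index)
        if len(missing):
            raise ConfigurationError(f"sample_meta missing samples: {list(missing[:5])}")
        # keep metadata aligned to column order
        self.sample_meta = self.sample_meta.loc[self.counts.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.sample_meta.copy())

    def subset_samples(self, samples) -> "CountMatrix":
        samples = list(samples)
        return CountMatrix(self.counts[samples], self.sample_meta.loc[samples])


@dataclass
class NormalizedMatrix:
    """Depth-normalized expression values (count / size factor).

    ``values[g, s] == counts[g, s] / size_factors[s]`` exactly; a log2 view
    with a pseudocount is available via :meth:`log2`.
    """

    values: pd.DataFrame
    size_factors: pd.Series
    sample_meta: pd.DataFrame
    pseudocount: float = 1.0
    _log2_cache: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def log2(self) -> pd.DataFrame:
        """log2(value + pseudocount), cached."""
        if self._log2_cache is None:
            self._log2_cache = np.log2(self.values + self.pseudocount)
        return self._log2_cache


def filter_low_expression(
    matrix: CountMatrix,
    min_any_sample: int = 10,
    max_le: float = 30.0,
) -> CountMatrix:
    """Drop weakly detected genes with the two standard count filters.

    A gene is kept iff (a) at least one sample has >= ``min_any_sample``
    reads, and then (b) its maximum count across samples exceeds ``max_le``.
    The two rules are applied in that order and each logs how many genes it
    removed.  An empty result is legal (logged as a warning).
    """
    gene_max = matrix.counts.max(axis=1)

    keep_a = gene_max >= min_any_sample
    logger.info(
        "detection filter (no sample >= %d reads): removed %d of %d genes",
        min_any_sample, int((~keep_a).sum()), matrix.n_genes,
    )
    counts = matrix.counts.loc[keep_a]

    keep_b = counts.max(axis=1) > max_le
    logger.info(
        "maximum-count filter (max <= %.1f reads): removed %d of %d genes",
        max_le, int((~keep_b).sum()), counts.shape[0],
    )
    counts = counts.loc[keep_b]

    if counts.shape[0] == 0:
        logger.warning("all genes removed by expression filters")
    return CountMatrix(counts, matrix.sample_meta.copy())


def size_factors_median_ratio(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (DESeq2 convention).

    The per-gene reference is the geometric mean across samples, computed in
    log space and restricted to genes with strictly positive counts in every
    sample; each sample's factor is the median over those genes of
    count / reference.
    """
    c = matrix.counts.to_numpy(dtype=float)
    all_positive = (c > 0).all(axis=1)
    if not all_positive.any():
        raise NormalizationError(
            "no gene has positive counts in every sample; "
            "median-ratio normalization needs at least one — pre-filter the matrix"
        )
    log_c = np.log(c[all_positive])
    log_ref = log_c.mean(axis=1)
    sf = np.exp(np.median(log_c - log_ref[:, None], axis=0))
    return pd.Series(sf, index=matrix.counts.columns, name="size_factor")


def normalize_counts(
    matrix: CountMatrix,
    size_factors: pd.Series,
    pseudocount: float = 1.0,
) -> NormalizedMatrix:
    """Divide each sample's counts by its size factor."""
    missing = matrix.counts.columns.difference(size_factors.index)
    if len(missing):
        raise KeyError(f"size factors missing for samples: {list(missing)}")
    sf = size_factors.loc[matrix.counts.columns]
    if (sf <= 0).any():
        raise NormalizationError("size factors must be strictly positive")
    values = matrix.counts / sf
    return NormalizedMatrix(
        values=values,
        size_factors=sf,
        sample_meta=matrix.sample_meta.copy(),
        pseudocount=pseudocount,
    )


def select_variable_genes(norm: NormalizedMatrix, n: int) -> list[str]:
    """Top-``n`` genes by variance of log2 expression across samples.

    Descending variance; exact ties broken by gene ID lexicographic order.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if n > len(norm.gene_ids):
        raise ValueError(f"n={n} exceeds the {len(norm.gene_ids)} available genes")
    variances = norm.log2().var(axis=1, ddof=1)
    order = sorted(variances.index, key=lambda g: (-variances[g], g))
    return order[:n]


def pca_embed(
    norm: NormalizedMatrix,
    genes: list[str] | None = None,
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on gene-centered log2 expression.

    Samples are observations, the selected genes are features (centered per
    gene).  The sign of each component is fixed so that its
    largest-magnitude gene loading is positive.

    Returns
    -------
    coordinates
        samples x components DataFrame (columns ``PC1``..``PCk``).
    variance_explained
        fraction of variance per component, non-increasing.
    """
    if genes is None:
        genes = norm.gene_ids
    genes = list(genes)
    missing = set(genes) - set(norm.gene_ids)
    if missing:
        raise ValueError(f"genes not in matrix: {sorted(missing)[:5]}")
    log2 = norm.log2().loc[genes]
    n_samples = log2.shape[1]
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > min(len(genes), n_samples):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_genes, n_samples)="
            f"{min(len(genes), n_samples)}"
        )
    X = log2.T.to_numpy(dtype=float)            # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    # deterministic sign: largest-|loading| positive per component
    for k in range(n_components):
        loading = pca.components_[k]
        if loading[np.argmax(np.abs(loading))] < 0:
            coords[:, k] *= -1
            pca.components_[k] *= -1
    columns = [f"PC{k + 1}" for k in range(n_components)]
    frame = pd.DataFrame(coords, index=log2.columns, columns=columns)
    return frame, pca.explained_variance_ratio_.copy()
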