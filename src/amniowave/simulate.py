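"""Synthetic data with planted ground truth for the whole pipeline.

Two generators:

* :func:`generate_time_course` — triplicate bulk RNA-seq counts over a
  BMP4-style stimulation grid (0, 0.5, 1, 3, 6, 12, 24, 48 hr by default)
  in which designated genes switch from a baseline negative-binomial mean
  to ``activation_fold`` times that mean at a stage-specific onset hour.
  The planted stage of every gene is returned as machine-readable truth.

* :func:`generate_reference_atlas` — a clustered single-cell reference
  laid along a differentiation trajectory (Epiblast -> PrimitiveStreak ->
  TBXTlow -> Amnion -> NascentMesoderm by default) with cluster-exclusive
  marker genes, negative-binomial counts, and synthesized 2-D embedding
  coordinates (cluster centers on a line plus Gaussian jitter), so no
  embedding algorithm ever runs in tests.

Counts follow the standard RNA-seq negative-binomial convention
``variance = mu + dispersion * mu**2``; ``dispersion = 0`` degrades to
Poisson.  Per-sample library sizes are log-normal with zero log-mean so the
expected geometric mean of the size factors is one.  All randomness flows
from a single integer seed through ``numpy.random.default_rng``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cascade import STAGE_LABELS
from .counts import CountMatrix
from .errors import ConfigurationError
from .projection import ReferenceAtlas

BACKGROUND = "background"

DEFAULT_TIMEPOINTS = (0.0, 0.5, 1.0, 3.0, 6.0, 12.0, 24.0, 48.0)
DEFAULT_ONSETS = {
    "immediate": 1.0,
    "early": 3.0,
    "intermediate-1": 12.0,
    "intermediate-2": 24.0,
    "late": 48.0,
}
DEFAULT_CLUSTERS = ("Epiblast", "PrimitiveStreak", "TBXTlow", "Amnion", "NascentMesoderm")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with variance mu + dispersion * mu^2 (Poisson when dispersion = 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


@dataclass
class SimConfig:
    """Design of the synthetic bulk time course."""

    timepoints_hr: tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    n_genes_total: int = 2000
    n_genes_per_stage: dict[str, int] = field(
        default_factory=lambda: {label: 100 for label in STAGE_LABELS}
    )
    activation_fold: float = 8.0
    baseline_mean_log_mu: float = 4.0
    baseline_mean_log_sigma: float = 1.0
    nb_dispersion: float = 0.05
    libsize_log_sigma: float = 0.15
    onset_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ONSETS))
    seed: int = 0
    activation_shape: str = "step"   # or "sigmoid" (logistic in log-fold, half-time = onset)

    def validate(self) -> None:
        tps = tuple(self.timepoints_hr)
        if len(tps) < 2 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ConfigurationError("timepoints_hr must be strictly increasing")
        if tps[0] != 0:
            raise ConfigurationError("timepoints_hr must start at 0")
        if self.n_replicates < 1:
            raise ConfigurationError(f"n_replicates must be positive, got {self.n_replicates}")
        if self.n_genes_total < 1:
            raise ConfigurationError("n_genes_total must be positive")
        staged = sum(self.n_genes_per_stage.values())
        if staged > self.n_genes_total:
            raise ConfigurationError(
                f"n_genes_per_stage sums to {staged} > n_genes_total={self.n_genes_total}"
            )
        if any(v < 0 for v in self.n_genes_per_stage.values()):
            raise ConfigurationError("n_genes_per_stage entries must be non-negative")
        for stage in self.n_genes_per_stage:
            if stage not in self.onset_map:
                raise ConfigurationError(f"onset_map missing stage {stage!r}")
        for stage, onset in self.onset_map.items():
            if onset not in tps:
                raise ConfigurationError(
                    f"onset_map[{stage!r}]={onset} is not a member of timepoints_hr"
                )
        if self.activation_fold <= 1:
            raise ConfigurationError(f"activation_fold must exceed 1, got {self.activation_fold}")
        if self.nb_dispersion < 0:
            raise ConfigurationError(f"nb_dispersion must be >= 0, got {self.nb_dispersion}")
        if self.libsize_log_sigma < 0:
            raise ConfigurationError(f"libsize_log_sigma must be >= 0, got {self.libsize_log_sigma}")
        if self.baseline_mean_log_sigma < 0:
            raise ConfigurationError("baseline_mean_log_sigma must be >= 0")
        if self.activation_shape not in ("step", "sigmoid"):
            raise ConfigurationError(f"activation_shape must be 'step' or 'sigmoid', got {self.activation_shape!r}")


@dataclass
class StageTruth:
    """Planted stage of every simulated gene (staged waves plus background)."""

    stages: pd.Series   # gene_id -> stage label

    def genes_in_stage(self, label: str) -> list[str]:
        return list(self.stages.index[self.stages == label])

    def stage_counts(self) -> dict[str, int]:
        return self.stages.value_counts().to_dict()

    def to_csv(self, path: str | Path) -> None:
        out = self.stages.rename("label")
        out.index.name = "id"
        out.to_csv(path)


def generate_time_course(config: SimConfig) -> tuple[CountMatrix, StageTruth]:
    """Simulate the bulk time course and return counts with planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tps = tuple(config.timepoints_hr)
    n_genes = config.n_genes_total
    gene_ids = [f"G{i + 1:06d}" for i in range(n_genes)]

    # stage assignment: shuffle so waves are interleaved through the matrix
    labels = np.array([BACKGROUND] * n_genes, dtype=object)
    staged_positions = rng.permutation(n_genes)
    cursor = 0
    for stage in STAGE_LABELS:
        count = config.n_genes_per_stage.get(stage, 0)
        labels[staged_positions[cursor:cursor + count]] = stage
        cursor += count
    truth = StageTruth(pd.Series(labels, index=gene_ids, name="stage"))

    baseline = np.exp(
        rng.normal(config.baseline_mean_log_mu, config.baseline_mean_log_sigma, n_genes)
    )

    log_fold = np.log(config.activation_fold)
    multiplier = np.ones((n_genes, len(tps)))
    for stage in STAGE_LABELS:
        members = labels == stage
        if not members.any():
            continue
        onset = config.onset_map[stage]
        for j, t in enumerate(tps):
            if config.activation_shape == "step":
                m = config.activation_fold if t >= onset else 1.0
            else:
                m = float(np.exp(log_fold / (1.0 + np.exp(-(t - onset)))))
            multiplier[members, j] = m

    sample_ids, tp_of_sample = [], []
    for t in tps:
        for r in range(1, config.n_replicates + 1):
            sample_ids.append(f"T{t:g}_R{r}")
            tp_of_sample.append(t)
    size_factors = np.exp(rng.normal(0.0, config.libsize_log_sigma, len(sample_ids)))

    tp_index = {t: j for j, t in enumerate(tps)}
    mean_matrix = np.empty((n_genes, len(sample_ids)))
    for s, t in enumerate(tp_of_sample):
        mean_matrix[:, s] = baseline * multiplier[:, tp_index[t]] * size_factors[s]
    counts = _nb_draw(rng, mean_matrix, config.nb_dispersion)

    meta = pd.DataFrame(
        {
            "timepoint_hr": tp_of_sample,
            "condition": "BMP4",
            "replicate": [int(s.rsplit("_R", 1)[1]) for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        meta,
    )
    return matrix, truth


@dataclass
class AtlasConfig:
    """Design of the synthetic single-cell reference atlas."""

    n_cells: int = 1500
    clusters: tuple[str, ...] = DEFAULT_CLUSTERS
    cells_per_cluster: dict[str, int] | None = None
    n_genes: int = 2000
    n_markers_per_cluster: int = 100
    marker_weight: float = 5.0
    cell_depth_mean: int = 5000
    depth_log_sigma: float = 0.2
    nb_dispersion: float = 0.1
    cluster_separation: float = 10.0
    within_cluster_sd: float = 0.5
    seed: int = 0

    def resolved_cells_per_cluster(self) -> dict[str, int]:
        if self.cells_per_cluster is not None:
            return dict(self.cells_per_cluster)
        base, extra = divmod(self.n_cells, len(self.clusters))
        return {
            label: base + (1 if i < extra else 0)
            for i, label in enumerate(self.clusters)
        }

    def validate(self) -> None:
        if len(set(self.clusters)) != len(self.clusters):
            raise ConfigurationError("cluster labels must be unique")
        sizes = self.resolved_cells_per_cluster()
        unknown = set(sizes) - set(self.clusters)
        if unknown:
            raise ConfigurationError(f"cells_per_cluster names unknown clusters {sorted(unknown)}")
        if sum(sizes.values()) != self.n_cells:
            raise ConfigurationError(
                f"cells_per_cluster sums to {sum(sizes.values())} but n_cells={self.n_cells}"
            )
        if any(v < 1 for v in sizes.values()):
            raise ConfigurationError("every cluster needs at least one cell")
        if self.n_markers_per_cluster * len(self.clusters) > self.n_genes:
            raise ConfigurationError("marker blocks exceed n_genes")
        if self.cluster_separation <= 0:
            raise ConfigurationError("cluster_separation must be positive")
        if self.within_cluster_sd <= 0:
            raise ConfigurationError("within_cluster_sd must be positive")
        if self.cell_depth_mean < 1:
            raise ConfigurationError("cell_depth_mean must be positive")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")


@dataclass
class ClusterTruth:
    """Known cluster of every atlas cell (and of bulks derived from clusters)."""

    cells: pd.Series                       # cell_id -> cluster label
    samples: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def to_csv(self, path: str | Path) -> None:
        out = pd.concat([self.cells, self.samples]).rename("label")
        out.index.name = "id"
        out.to_csv(path)


def generate_reference_atlas(config: AtlasConfig) -> tuple[ReferenceAtlas, ClusterTruth]:
    """Simulate a clustered, embedded, labeled single-cell reference.

    Cluster expression programs share a common log-normal background; each
    cluster additionally expresses its own exclusive marker block (zero
    mean everywhere else), so marker genes separate clusters both in count
    space and after TF-IDF weighting.  Embedding centers sit on a line at
    ``cluster_separation`` spacing in trajectory order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes = config.resolved_cells_per_cluster()
    gene_ids = [f"G{i + 1:06d}" for i in range(config.n_genes)]

    background_weights = np.exp(rng.normal(0.0, 1.0, config.n_genes))
    mean_background = float(background_weights.mean())
    n_markers = config.n_markers_per_cluster

    programs = {}
    for i, label in enumerate(config.clusters):
        weights = background_weights.copy()
        block = slice(i * n_markers, (i + 1) * n_markers)
        # exclusive markers: zero outside their own cluster
        for j, other in enumerate(config.clusters):
            if other != label:
                weights[j * n_markers:(j + 1) * n_markers] = 0.0
        weights[block] = config.marker_weight * mean_background
        programs[label] = weights / weights.sum()

    cell_ids, cell_labels, columns = [], [], []
    for label in config.clusters:
        program = programs[label]
        for c in range(sizes[label]):
            cell_id = f"{label}_c{c + 1}"
            depth = config.cell_depth_mean * np.exp(rng.normal(0.0, config.depth_log_sigma))
            counts = _nb_draw(rng, program * depth, config.nb_dispersion)
            cell_ids.append(cell_id)
            cell_labels.append(label)
            columns.append(counts)
    counts = pd.DataFrame(
        np.column_stack(columns),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=cell_ids,
    )

    centers = {label: np.array([i * config.cluster_separation, 0.0])
               for i, label in enumerate(config.clusters)}
    coords = np.vstack([
        centers[label] + rng.normal(0.0, config.within_cluster_sd, 2)
        for label in cell_labels
    ])
    embedding = pd.DataFrame(coords, index=cell_ids, columns=["x", "y"])
    labels = pd.Series(cell_labels, index=cell_ids, name="cluster")
    atlas = ReferenceAtlas(counts=counts, labels=labels, embedding=embedding)
    return atlas, ClusterTruth(cells=labels.copy())


def cluster_centers(atlas: ReferenceAtlas) -> pd.DataFrame:
    """Mean embedding coordinate per cluster (rows in first-seen order)."""
    return atlas.embedding.groupby(atlas.labels, sort=False).mean()


def generate_bulk_from_cluster(
    atlas: ReferenceAtlas,
    cluster: str,
    n_samples: int,
    depth: int,
    seed: int = 0,
) -> CountMatrix:
    """Bulk samples drawn multinomially from a cluster's pooled profile.

    The source cluster is recorded in the bulk metadata ``condition``
    column as the expected projection label.
    """
    members = atlas.labels.index[atlas.labels == cluster]
    if len(members) == 0:
        raise KeyError(f"cluster {cluster!r} not present in atlas")
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    pooled = atlas.counts[list(members)].sum(axis=1).to_numpy(dtype=float)
    proportions = pooled / pooled.sum()
    rng = np.random.default_rng(seed)
    draws = np.column_stack([rng.multinomial(depth, proportions) for _ in range(n_samples)])
    sample_ids = [f"{cluster}_bulk{j + 1}" for j in range(n_samples)]
    meta = pd.DataFrame(
        {
            "timepoint_hr": np.nan,
            "condition": cluster,
            "replicate": list(range(1, n_samples + 1)),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CountMatrix(
        pd.DataFrame(draws, index=atlas.counts.index.copy(), columns=sample_ids), meta
    )
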