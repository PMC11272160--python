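"""Projection of bulk RNA-seq samples onto an annotated single-cell atlas.

The procedure mirrors how bulk samples are placed on a reference embryo
atlas: each bulk profile is multinomially downsampled to ``n_cells``
pseudo-single-cells at single-cell depth, the pseudo-cells are embedded in
the reference's latent space (log TF-IDF followed by truncated SVD — LSI),
transferred into the reference's 2-D embedding by inverse-distance-weighted
k-nearest-neighbor interpolation, summarized by their medoid, and finally
assigned the cluster label of the Euclidean-nearest reference cell.

The reference embedding (e.g. a published UMAP) is consumed as given and
never re-fitted here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .counts import CountMatrix
from .errors import ConfigurationError


@dataclass
class ReferenceAtlas:
    """Annotated single-cell reference: counts, cluster labels, 2-D embedding.

    ``counts`` is genes x cells (non-negative integers); ``labels`` maps
    every cell to its cluster; ``embedding`` holds one (x, y) row per cell.
    A fitted :class:`LSIModel` may be attached after :func:`fit_lsi`.
    """

    counts: pd.DataFrame
    labels: pd.Series
    embedding: pd.DataFrame
    lsi: "LSIModel | None" = None

    def __post_init__(self) -> None:
        cells = self.counts.columns
        if not cells.equals(self.labels.index.astype(cells.dtype)) and set(cells) != set(self.labels.index):
            raise ConfigurationError("labels do not cover the atlas cells")
        if set(cells) != set(self.embedding.index):
            raise ConfigurationError("embedding does not cover the atlas cells")
        self.labels = self.labels.loc[cells]
        self.embedding = self.embedding.loc[cells, ["x", "y"]].astype(float)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def cluster_labels(self) -> list[str]:
        return list(pd.unique(self.labels))

    def median_cell_depth(self) -> int:
        return int(np.median(self.counts.sum(axis=0)))


@dataclass
class LSIModel:
    """Log TF-IDF + truncated SVD model fitted on a reference atlas.

    The transform is: TF[g, c] = count / column total; IDF[g] =
    log(1 + n_cells / (1 + n cells expressing g)); X = log1p(TF * IDF *
    scale_constant); coordinates = X^T V where V holds the top right
    singular vectors over genes.
    """

    gene_ids: list[str]
    idf: np.ndarray
    components: np.ndarray        # k x n_genes, orthonormal rows
    singular_values: np.ndarray   # k, non-increasing
    scale_constant: float = 1e4
    n_components: int = 30
    drop_first_component: bool = False

    def __post_init__(self) -> None:
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.components.shape[0]), atol=1e-8):
            raise ConfigurationError("LSI components are not orthonormal")
        if not np.all(np.isfinite(self.idf)):
            raise ConfigurationError("IDF weights are not finite")

    @property
    def kept_components(self) -> np.ndarray:
        return self.components[1:] if self.drop_first_component else self.components

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_ids": self.gene_ids,
            "idf": self.idf.tolist(),
            "components": self.components.tolist(),
            "singular_values": self.singular_values.tolist(),
            "scale_constant": self.scale_constant,
            "n_components": self.n_components,
            "drop_first_component": self.drop_first_component,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "LSIModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            gene_ids=payload["gene_ids"],
            idf=np.asarray(payload["idf"]),
            components=np.asarray(payload["components"]),
            singular_values=np.asarray(payload["singular_values"]),
            scale_constant=payload["scale_constant"],
            n_components=payload["n_components"],
            drop_first_component=payload["drop_first_component"],
        )


@dataclass
class PseudoCellSet:
    """Multinomial pseudo-single-cells downsampled from one bulk column."""

    source_sample_id: str
    counts: pd.DataFrame   # genes x n_cells
    depth: int
    seed: int

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class ProjectionResult:
    """Placement of one bulk sample on the reference atlas."""

    sample_id: str
    medoid_xy: tuple[float, float]
    nearest_cell_id: str
    transferred_label: str
    euclidean_distance: float
    pseudo_cell_xy: np.ndarray = field(repr=False)
    seed: int = 0
    params: dict = field(default_factory=dict, repr=False)


def _log_tfidf(counts: np.ndarray, idf: np.ndarray, scale: float, what: str) -> np.ndarray:
    """columns = observations; returns observations x genes matrix."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = int(np.where(totals == 0)[0][0])
        raise ValueError(f"{what} column {bad} has zero total count")
    tf = counts / totals
    return np.log1p((tf * idf[:, None]) * scale).T


def fit_lsi(
    atlas: ReferenceAtlas,
    n_components: int = 30,
    scale_constant: float = 1e4,
    drop_first_component: bool = False,
) -> LSIModel:
    """Fit the log TF-IDF / truncated SVD model on the reference counts.

    Component signs are fixed (largest-magnitude gene weight positive) so
    repeated fits are identical.
    """
    counts = atlas.counts.to_numpy(dtype=float)
    n_genes, n_cells = counts.shape
    if counts.size == 0:
        raise ValueError("atlas counts are empty")
    if n_components > min(n_genes, n_cells):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_genes, n_cells)={min(n_genes, n_cells)}"
        )
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = atlas.cell_ids[int(np.where(totals == 0)[0][0])]
        raise ValueError(f"atlas cell {bad!r} has zero total count")
    n_expressing = (counts > 0).sum(axis=1)
    idf = np.log(1.0 + n_cells / (1.0 + n_expressing))
    X = _log_tfidf(counts, idf, scale_constant, "atlas")   # cells x genes
    # deterministic dense SVD; reference atlases here are a few thousand
    # genes x cells so the full decomposition is cheap
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    components = vt[:n_components]
    for k in range(components.shape[0]):
        row = components[k]
        if row[np.argmax(np.abs(row))] < 0:
            components[k] = -row
    return LSIModel(
        gene_ids=atlas.gene_ids,
        idf=idf,
        components=components,
        singular_values=s[:n_components].copy(),
        scale_constant=scale_constant,
        n_components=n_components,
        drop_first_component=drop_first_component,
    )


def transform_lsi(model: LSIModel, counts: pd.DataFrame) -> np.ndarray:
    """Project query profiles (genes x m) into the model's LSI space.

    The query gene universe is reconciled with the model's: genes the model
    knows but the query lacks are zero-filled, extra query genes are
    dropped (both counted and reported via the return's metadata-free
    contract — callers log).  Returns an m x k coordinate array.
    """
    query = counts.reindex(model.gene_ids, fill_value=0).to_numpy(dtype=float)
    X = _log_tfidf(query, model.idf, model.scale_constant, "query")
    return X @ model.kept_components.T


def reference_lsi_coordinates(model: LSIModel, atlas: ReferenceAtlas) -> np.ndarray:
    """LSI coordinates of the reference cells themselves (cells x k)."""
    return transform_lsi(model, atlas.counts)


def downsample_pseudocells(
    bulk_column: pd.Series,
    n_cells: int = 100,
    depth: int = 5000,
    seed: int = 0,
    sample_id: str | None = None,
) -> PseudoCellSet:
    """Split a bulk profile into multinomial pseudo-single-cells.

    Each pseudo-cell is an independent multinomial(``depth``, bulk gene
    proportions) draw; draw ``i`` uses the stream seeded ``seed + i`` so
    cells are individually reproducible.
    """
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    if n_cells <= 0:
        raise ValueError(f"n_cells must be positive, got {n_cells}")
    total = float(bulk_column.sum())
    if total <= 0:
        raise ValueError("bulk column has zero total count")
    proportions = bulk_column.to_numpy(dtype=float) / total
    draws = np.empty((len(bulk_column), n_cells), dtype=np.int64)
    for i in range(n_cells):
        rng = np.random.default_rng(seed + i)
        draws[:, i] = rng.multinomial(depth, proportions)
    sid = sample_id if sample_id is not None else str(bulk_column.name)
    frame = pd.DataFrame(
        draws, index=bulk_column.index, columns=[f"{sid}_pc{i}" for i in range(n_cells)]
    )
    return PseudoCellSet(source_sample_id=sid, counts=frame, depth=depth, seed=seed)


def umap_transfer(
    ref_lsi: np.ndarray,
    ref_embedding: np.ndarray,
    query_lsi: np.ndarray,
    k_neighbors: int = 15,
) -> np.ndarray:
    """Place query points in the reference 2-D embedding by weighted kNN.

    Each query point receives the inverse-distance-weighted average of its
    ``k_neighbors`` nearest reference cells' embedding coordinates, with
    distances measured in LSI space.  A query at distance 0 from a
    reference cell copies that cell's coordinates exactly.
    """
    ref_lsi = np.asarray(ref_lsi, dtype=float)
    ref_embedding = np.asarray(ref_embedding, dtype=float)
    query_lsi = np.atleast_2d(np.asarray(query_lsi, dtype=float))
    if ref_lsi.shape[0] == 0:
        raise ValueError("reference is empty")
    if k_neighbors > ref_lsi.shape[0]:
        raise ValueError(
            f"k_neighbors={k_neighbors} exceeds the {ref_lsi.shape[0]} reference cells"
        )
    distances = cdist(query_lsi, ref_lsi)
    out = np.empty((query_lsi.shape[0], 2), dtype=float)
    for i, row in enumerate(distances):
        nearest = np.argpartition(row, k_neighbors - 1)[:k_neighbors]
        nearest = nearest[np.argsort(row[nearest], kind="stable")]
        d = row[nearest]
        if d[0] == 0.0:
            out[i] = ref_embedding[nearest[0]]
            continue
        weights = 1.0 / d
        weights /= weights.sum()
        out[i] = weights @ ref_embedding[nearest]
    return out


def medoid(points: np.ndarray) -> tuple[int, np.ndarray]:
    """Member point minimizing the summed Euclidean distance to all members.

    Ties break to the lowest index.  Returns (index, point).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 0:
        raise ValueError("medoid of an empty point set is undefined")
    sums = cdist(points, points).sum(axis=1)
    index = int(np.argmin(sums))   # argmin takes the first minimum
    return index, points[index].copy()


def nearest_reference_cell(atlas: ReferenceAtlas, point) -> tuple[str, str, float]:
    """Euclidean-nearest atlas cell in embedding space; ties to lowest index."""
    coords = atlas.embedding.to_numpy(dtype=float)
    point = np.asarray(point, dtype=float).reshape(1, 2)
    distances = cdist(point, coords)[0]
    index = int(np.argmin(distances))
    cell_id = atlas.cell_ids[index]
    return cell_id, str(atlas.labels.iloc[index]), float(distances[index])


def map_samples_to_atlas(
    atlas: ReferenceAtlas,
    bulk: CountMatrix,
    n_components: int = 30,
    n_cells: int = 100,
    depth: int | None = None,
    k_neighbors: int = 15,
    seed: int = 0,
) -> list[ProjectionResult]:
    """End-to-end projection of every bulk sample onto the atlas.

    Per sample: downsample to pseudo-cells -> LSI transform -> embedding
    transfer -> medoid -> nearest reference cell.  ``depth`` defaults to
    the atlas's median per-cell total so pseudo-cells are statistically
    comparable to reference cells.  Sample ``j`` derives its pseudo-cell
    seed as ``seed + j * 100003`` (a prime stride keeping streams disjoint).
    """
    overlap = set(atlas.gene_ids) & set(bulk.gene_ids)
    if not overlap:
        raise ValueError("bulk and atlas share no genes")
    model = atlas.lsi
    if model is None or model.n_components != n_components:
        model = fit_lsi(atlas, n_components=n_components)
        atlas.lsi = model
    if depth is None:
        depth = atlas.median_cell_depth()
    ref_coords = reference_lsi_coordinates(model, atlas)
    ref_embedding = atlas.embedding.to_numpy(dtype=float)
    params = {
        "n_components": n_components,
        "n_cells": n_cells,
        "depth": int(depth),
        "k_neighbors": k_neighbors,
    }

    results = []
    for j, sample_id in enumerate(bulk.sample_ids):
        sample_seed = seed + j * 100003
        try:
            pseudo = downsample_pseudocells(
                bulk.counts[sample_id], n_cells=n_cells, depth=depth,
                seed=sample_seed, sample_id=sample_id,
            )
            query_coords = transform_lsi(model, pseudo.counts)
            placed = umap_transfer(ref_coords, ref_embedding, query_coords, k_neighbors)
            _, medoid_point = medoid(placed)
            cell_id, label, distance = nearest_reference_cell(atlas, medoid_point)
        except Exception as exc:
            raise type(exc)(f"sample {sample_id!r}: {exc}") from exc
        results.append(
            ProjectionResult(
                sample_id=sample_id,
                medoid_xy=(float(medoid_point[0]), float(medoid_point[1])),
                nearest_cell_id=cell_id,
                transferred_label=label,
                euclidean_distance=distance,
                pseudo_cell_xy=placed,
                seed=sample_seed,
                params=params,
            )
        )
    return results


def projection_results_frame(results: list[ProjectionResult]) -> pd.DataFrame:
    """Tabular view of projection results for TSV export."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "medoid_x": [r.medoid_xy[0] for r in results],
            "medoid_y": [r.medoid_xy[1] for r in results],
            "nearest_cell_id": [r.nearest_cell_id for r in results],
            "transferred_label": [r.transferred_label for r in results],
            "distance": [r.euclidean_distance for r in results],
            "seed": [r.seed for r in results],
        }
    ).set_index("sample_id")
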